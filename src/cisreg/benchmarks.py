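"""Seeded end-to-end recovery experiments on synthetic ground truth.

Each function runs one full pipeline stage on generated data and measures
how well the known truth is recovered: planted-motif family recovery, SV
type/breakpoint recovery and false-call rate, balancing residuals, planted-
loop percentile ranking, GP credible-band coverage.  These are the
package's standing benchmarks; the test suite asserts thresholds on them
and ``scripts/acceptance.py`` reports their values.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import hic, motifs, simulate, svscan, trends
from .genomics import Convention, GenomicInterval

__all__ = [
    "motif_family_recovery",
    "sv_recovery",
    "sv_false_call_rate",
    "kr_balance_residual",
    "loop_percentile_experiment",
    "gp_band_coverage",
    "vst_roundtrip_error",
]


def motif_family_recovery(seed: int, n_cases: int = 20) -> float:
    """Fraction of planted-motif cases whose family tops the Tier-1 ranking.

    Each case plants one consensus site and one maximally disruptive SNV;
    recovery means the planted family is ranked first among Tier-1
    disruptions for that variant.
    """
    data = simulate.gen_motif_scenario(
        simulate.MotifScenario(seed=seed, n_cases=n_cases))
    truth = data.manifest.set_index("seq")
    hits = 0
    for v in data.variants:
        _, ranking = motifs.rank_disruptions(v, data.pwms, data.seqs[v.chrom],
                                             flank_bp=30)
        if ranking[1] and ranking[1][0][0] == truth.loc[v.chrom, "family"]:
            hits += 1
    return hits / len(data.variants)


@dataclass
class SVRecoveryResult:
    n_events: int
    n_recovered: int            # correct type, breakpoints within tolerance
    breakpoint_mae: float       # mean |called - true| over recovered events
    tolerance_bp: float

    @property
    def recovery_rate(self) -> float:
        return self.n_recovered / self.n_events


def _one_sv_replicate(seed: int, rng: np.random.Generator):
    del_size = int(rng.integers(1500, 8001))
    inv_size = int(rng.integers(1500, 8001))
    events = (
        simulate.SVEvent("deletion", "chrA", 10_001, del_size),
        simulate.SVEvent("inversion", "chrA", 40_001, inv_size),
        simulate.SVEvent("translocation", "chrB", int(rng.integers(10_001, 20_001)),
                         0, chrom2="chrC", pos2=int(rng.integers(8_001, 12_001))),
    )
    scen = simulate.SVScenario(
        seed=seed,
        chrom_lengths=(("chrA", 70_000), ("chrB", 30_000), ("chrC", 20_000)),
        events=events,
    )
    return scen


def sv_recovery(seed: int, n_replicates: int = 50) -> SVRecoveryResult:
    """Planted-SV recovery across seeded replicates at 30x pair coverage.

    Per replicate one heterozygous deletion, inversion and translocation
    (sizes 1.5-8 kb) are planted; an event counts as recovered when a call
    of the correct type places every breakpoint within 2 sigma (insert-size
    sigma = 50 bp) of truth.
    """
    rng = np.random.default_rng([seed, 77])
    tol = 2 * 50.0
    n_events = n_recovered = 0
    errors = []
    with tempfile.TemporaryDirectory() as tmp:
        for rep in range(n_replicates):
            scen = _one_sv_replicate(seed * 1000 + rep, rng)
            sam = Path(tmp) / f"rep{rep}.sam"
            truth = simulate.gen_sv_scenario(scen, sam)
            calls = svscan.scan_sv(sam)
            for t in truth.itertuples():
                n_events += 1
                cands = [c for c in calls if c.svtype == t.svtype
                         and c.chrom == t.chrom and abs(c.start - t.start) <= tol]
                if t.svtype in ("deletion", "inversion"):
                    cands = [c for c in cands if abs(c.end - t.end) <= tol]
                if not cands:
                    continue
                c = min(cands, key=lambda c: abs(c.start - t.start))
                n_recovered += 1
                errors.append(abs(c.start - t.start))
                if t.svtype in ("deletion", "inversion"):
                    errors.append(abs(c.end - t.end))
    return SVRecoveryResult(n_events, n_recovered,
                            float(np.mean(errors)) if errors else float("nan"),
                            tol)


def sv_false_call_rate(seed: int, genome_bp: int = 1_000_000) -> float:
    """Calls per 10 Mb on an SV-free genome at 30x pair coverage."""
    scen = simulate.SVScenario(seed=seed, chrom_lengths=(("chrA", genome_bp),))
    with tempfile.TemporaryDirectory() as tmp:
        sam = Path(tmp) / "clean.sam"
        simulate.gen_sv_scenario(scen, sam)
        calls = svscan.scan_sv(sam)
    return len(calls) * 10_000_000 / genome_bp


def kr_balance_residual(seed: int, n_matrices: int = 3, tol: float = 1e-8) -> float:
    """Worst row-sum deviation after balancing seeded biased matrices.

    The residual is recomputed independently from the balanced matrix, not
    taken from the solver.
    """
    worst = 0.0
    for k in range(n_matrices):
        data = simulate.gen_hic_scenario(
            simulate.HicScenario(seed=seed + k, n_bins=150, n_loops=5,
                                 n_null_loops=5))
        cm, w = hic.kr_balance(hic.ContactMatrix("chr1", data.counts), tol=tol)
        act = ~np.isnan(w)
        rowsums = np.nansum(cm.balanced[act], axis=1)
        worst = max(worst, float(np.abs(rowsums / rowsums.mean() - 1).max()))
    return worst


def _bin_loop(i: int, j: int, bin_size: int) -> hic.Loop:
    return hic.Loop(
        GenomicInterval("chr1", i * bin_size, (i + 1) * bin_size,
                        Convention.ZERO_BASED_HALF_OPEN),
        GenomicInterval("chr1", j * bin_size, (j + 1) * bin_size,
                        Convention.ZERO_BASED_HALF_OPEN),
    )


def loop_percentile_experiment(seed: int, n_loops: int = 200,
                               enrichment: float = 3.0,
                               n_bins: int = 600) -> tuple[float, float]:
    """Mean percentile of planted and of extra null loops against the
    distance-matched null strength distribution.

    Planted loops are enriched blocks on a distance-decay background; nulls
    are anchor pairs with the same distance distribution and no enrichment.
    """
    data = simulate.gen_hic_scenario(simulate.HicScenario(
        seed=seed, n_bins=n_bins, n_loops=n_loops, n_null_loops=n_loops,
        loop_enrichment=enrichment))
    cm, _ = hic.kr_balance(hic.ContactMatrix("chr1", data.counts))
    planted = [hic.loop_strength(cm, _bin_loop(i, j, data.bin_size))
               for i, j in data.planted]
    nulls = [hic.loop_strength(cm, _bin_loop(i, j, data.bin_size))
             for i, j in data.nulls]
    planted_pct = float(np.mean([hic.percentile_rank(s, nulls) for s in planted]))
    null_pct = float(np.mean([hic.percentile_rank(s, nulls) for s in nulls]))
    return planted_pct, null_pct


def gp_band_coverage(seed: int, n_replicates: int = 50, n_cells: int = 100,
                     noise_sd: float = 0.3) -> float:
    """Fraction of grid points where the 95% band contains the true curve,
    averaged over seeded noisy-trend replicates (alternating falling and
    rising sigmoids, the expression patterns of a silenced vs an induced
    gene over differentiation)."""
    covered = []
    for rep in range(n_replicates):
        trend = "decreasing_sigmoid" if rep % 2 == 0 else "increasing_sigmoid"
        data = simulate.gen_expression_scenario(simulate.ExprScenario(
            seed=seed * 1000 + rep, n_cells=n_cells, trend=trend,
            noise_sd=noise_sd))
        t = data.table.pseudotime.values
        series = trends.ExpressionSeries(t, data.table[data.gene].values,
                                         data.gene)
        grid = np.linspace(t.min(), t.max(), 50)
        fit = trends.fit_gp_trend(series, grid=grid, seed=rep)
        truth = data.truth_at(grid)
        covered.append(np.mean((truth >= fit.lower) & (truth <= fit.upper)))
    return float(np.mean(covered))


def vst_roundtrip_error(n_points: int = 2000) -> float:
    """Max round-trip error |inverse_vst(vst(y)) - y| / max(1, y) over a
    log-spaced grid of [0, 1e4] (absolute below 1, relative above)."""
    ys = np.concatenate([[0.0], np.logspace(-6, 4, n_points)])
    back = trends.inverse_vst(trends.vst(ys))
    return float(np.max(np.abs(back - ys) / np.maximum(1.0, ys)))
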