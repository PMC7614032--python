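"""Seeded synthetic-data generators with known ground truth.

Every analysis stage in this package gets a generator producing inputs in
the same standard formats real data would arrive in, plus a truth manifest:

* motif stage  — background DNA with planted PWM consensus instances and,
  for each, a single SNV at the motif's most informative position that
  ablates the site;
* SV stage     — paired-end alignments over a small genome carrying planted
  >= 1 kb deletions / insertions / inversions / translocations, emitted
  with the breakpoint signatures of real libraries (inflated inserts,
  same-strand pairs, interchromosomal mates, soft-clipped junction reads,
  and the halved interior depth of heterozygous deletions);
* Hi-C stage   — distance-decaying contact matrices with multiplicative
  per-bin biases, Poisson counts, planted enriched loop blocks, and
  distance-matched decoy anchor pairs for null comparisons;
* expression   — smooth pseudotime trends (sigmoids or constant) under
  multiplicative lognormal noise.

Each generator is a pure function of its scenario: the same scenario gives
byte-identical output.  RNG streams are derived from (seed, stage id) so
adding a stage never perturbs another stage's data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .genomics import Variant, VariantTable
from .motifs import BASES, PWM, revcomp

__all__ = [
    "MotifScenario",
    "SVEvent",
    "SVScenario",
    "HicScenario",
    "ExprScenario",
    "default_pwm_counts",
    "build_pwms",
    "write_jaspar_pfm",
    "gen_motif_scenario",
    "gen_sv_scenario",
    "gen_hic_scenario",
    "gen_expression_scenario",
]

# per-stage RNG stream ids
_STREAM_MOTIF, _STREAM_SV, _STREAM_HIC, _STREAM_EXPR = 11, 22, 33, 44


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


# ---------------------------------------------------------------------------
# Motif scenario
# ---------------------------------------------------------------------------

# Synthetic PFMs for beta-cell-relevant TF families: consensus base gets 17
# of 20 counts per column, so the consensus scores 1.0 after normalisation
# and a consensus-breaking SNV costs a large score fraction.
_DEFAULT_CONSENSI = {
    ("MS0001.1", "NFATC1"): "TTTTCCAT",
    ("MS0002.1", "NKX2-2"): "TTAAGTGG",
    ("MS0003.1", "FOXA2"): "TGTTTACT",
    ("MS0004.1", "HIC2"): "ATGCCCAC",
    ("MS0005.1", "TEAD1"): "ACATTCCT",
    ("MS0006.1", "SMAD3"): "AGTCTAGAC",
    ("MS0007.1", "GATA4"): "CAGATAAG",
    ("MS0008.1", "PDX1"): "GCTAATGG",
    ("MS0009.1", "NEUROD1"): "GCAGCTGC",
    ("MS0010.1", "MAFA"): "TGCTGACG",
    ("MS0011.1", "PAX6"): "TTCACGCA",
    ("MS0012.1", "RFX6"): "GGTTGCCA",
}


def default_pwm_counts() -> dict[tuple[str, str], np.ndarray]:
    """L x 4 count matrices (A,C,G,T) for the built-in synthetic motif set."""
    out = {}
    for key, consensus in _DEFAULT_CONSENSI.items():
        L = len(consensus)
        counts = np.ones((L, 4))
        for i, b in enumerate(consensus):
            counts[i, BASES.index(b)] = 17
        out[key] = counts
    return out


def build_pwms(background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
               pseudocount_total: float = 0.8) -> list[PWM]:
    """The built-in synthetic motif set as scored PWMs."""
    bg = np.asarray(background, dtype=float)
    pwms = []
    for (mid, sym), counts in default_pwm_counts().items():
        totals = counts.sum(axis=1, keepdims=True)
        prob = (counts + pseudocount_total * bg) / (totals + pseudocount_total)
        pwms.append(PWM(mid, sym, prob, bg))
    return pwms


def write_jaspar_pfm(path, counts: Optional[dict] = None) -> None:
    """Write count matrices in JASPAR PFM text (">ID NAME" + 4 count rows)."""
    counts = counts or default_pwm_counts()
    with open(path, "w") as fh:
        for (mid, sym), mat in counts.items():
            fh.write(f">{mid} {sym}\n")
            for bi, b in enumerate(BASES):
                row = " ".join(f"{int(v):3d}" for v in mat[:, bi])
                fh.write(f"{b} [ {row} ]\n")


@dataclass(frozen=True)
class MotifScenario:
    seed: int = 0
    n_cases: int = 20
    seq_len: int = 300
    base_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    pseudocount_total: float = 0.8


@dataclass
class MotifScenarioData:
    seqs: dict                 # sequence name -> DNA string
    manifest: pd.DataFrame     # seq, motif_id, gene_symbol, family, start, strand
    variants: VariantTable     # one ablating SNV per planted motif
    pwms: list                 # the PWM set used for planting
    background: np.ndarray


def _random_seq(rng: np.random.Generator, n: int, freqs: Sequence[float]) -> str:
    return "".join(rng.choice(list(BASES), size=n, p=np.asarray(freqs) / np.sum(freqs)))


def gen_motif_scenario(scenario: MotifScenario) -> MotifScenarioData:
    """Background DNA with one planted consensus + ablating SNV per case.

    Each case is an independent sequence with one PWM consensus planted at a
    random interior position on a random strand, and a single SNV at the
    motif's most informative column changing the consensus base to the
    motif's least likely base there — the maximal single-base disruption.
    """
    from .motifs import family_of

    rng = _rng(scenario.seed, _STREAM_MOTIF)
    pwms = build_pwms(scenario.base_freqs, scenario.pseudocount_total)
    max_len = max(p.length for p in pwms)
    if max_len > scenario.seq_len // 10:
        raise ValueError("PWM length must be <= sequence length / 10")
    seqs, rows = {}, []
    variants = VariantTable()
    for case in range(scenario.n_cases):
        name = f"case{case:03d}"
        pwm = pwms[case % len(pwms)]
        L = pwm.length
        seq = list(_random_seq(rng, scenario.seq_len, scenario.base_freqs))
        start0 = int(rng.integers(scenario.seq_len // 4,
                                  3 * scenario.seq_len // 4 - L))
        strand = "+" if rng.random() < 0.5 else "-"
        planted = pwm.consensus if strand == "+" else revcomp(pwm.consensus)
        seq[start0:start0 + L] = planted
        seq = "".join(seq)
        # most informative column and its worst base, in motif coordinates
        lo = pwm.log_odds
        j = int(lo.max(axis=1).argmax())
        worst = BASES[int(pwm.prob[j].argmin())]
        if strand == "+":
            var_off = start0 + j
            ref_b, alt_b = pwm.consensus[j], worst
        else:
            var_off = start0 + (L - 1 - j)
            ref_b = revcomp(pwm.consensus[j])
            alt_b = revcomp(worst)
        assert seq[var_off] == ref_b
        seqs[name] = seq
        rows.append({
            "seq": name, "motif_id": pwm.motif_id, "gene_symbol": pwm.gene_symbol,
            "family": family_of(pwm.gene_symbol), "start": start0 + 1,
            "strand": strand,
        })
        variants.add(Variant(name, var_off + 1, ref_b, alt_b,
                             sample_id=f"proband{case:03d}", inheritance="de_novo"))
    return MotifScenarioData(
        seqs=seqs,
        manifest=pd.DataFrame(rows),
        variants=variants,
        pwms=pwms,
        background=np.asarray(scenario.base_freqs, dtype=float),
    )


# ---------------------------------------------------------------------------
# SV scenario
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SVEvent:
    """A planted structural variant; ``start`` is the 1-based first affected
    base.  Translocations join chrom:start to chrom2:pos2."""

    svtype: str                # deletion | insertion | inversion | translocation
    chrom: str
    start: int
    size: int = 0
    chrom2: Optional[str] = None
    pos2: Optional[int] = None
    het: bool = True

    def __post_init__(self):
        if self.svtype not in ("deletion", "insertion", "inversion", "translocation"):
            raise ValueError(f"unknown SV type {self.svtype}")
        if self.svtype != "translocation" and self.size < 1000:
            raise ValueError(f"{self.svtype} events must be >= 1 kb, got {self.size}")
        if self.svtype == "translocation" and (self.chrom2 is None or self.pos2 is None):
            raise ValueError("translocation needs chrom2 and pos2")


@dataclass(frozen=True)
class SVScenario:
    seed: int = 0
    chrom_lengths: tuple = (("chrA", 100_000),)
    events: tuple = ()
    coverage: float = 30.0
    read_len: int = 100
    insert_mean: float = 400.0
    insert_sd: float = 50.0


@dataclass(frozen=True)
class _Segment:
    ref_chrom: Optional[str]   # None for novel inserted sequence
    ref_start: int             # 0-based
    ref_end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


def _validate_events(chrom_lengths: dict, events: Sequence[SVEvent]) -> None:
    spans: dict[str, list] = {c: [] for c in chrom_lengths}
    translocated = set()
    for ev in events:
        if ev.chrom not in chrom_lengths:
            raise ValueError(f"event on unknown chromosome {ev.chrom}")
        if ev.svtype == "translocation":
            translocated.update([ev.chrom, ev.chrom2])
            continue
        s0 = ev.start - 1
        e0 = s0 + (0 if ev.svtype == "insertion" else ev.size)
        if s0 < 0 or e0 > chrom_lengths[ev.chrom]:
            raise ValueError(f"event {ev} outside chromosome bounds")
        for a, b in spans[ev.chrom]:
            if s0 < b and a < max(e0, s0 + 1):
                raise ValueError(f"overlapping events on {ev.chrom}")
        spans[ev.chrom].append((s0, max(e0, s0 + 1)))
    for c in translocated:
        if spans.get(c):
            raise ValueError(
                f"chromosome {c} is involved in a translocation and cannot carry "
                "other events in the same scenario"
            )


def _variant_contigs(chrom_lengths: dict, events: Sequence[SVEvent]) -> dict[str, list]:
    """Donor contigs (segment lists) for the variant haplotype."""
    contigs: dict[str, list] = {}
    by_chrom: dict[str, list] = {c: [] for c in chrom_lengths}
    translocs = []
    for ev in events:
        if ev.svtype == "translocation":
            translocs.append(ev)
        else:
            by_chrom[ev.chrom].append(ev)
    handled = set()
    for ev in translocs:
        la, lb = chrom_lengths[ev.chrom], chrom_lengths[ev.chrom2]
        pa0, pb0 = ev.start - 1, ev.pos2 - 1
        contigs[f"der_{ev.chrom}"] = [_Segment(ev.chrom, 0, pa0),
                                      _Segment(ev.chrom2, pb0, lb)]
        contigs[f"der_{ev.chrom2}"] = [_Segment(ev.chrom2, 0, pb0),
                                       _Segment(ev.chrom, pa0, la)]
        handled.update([ev.chrom, ev.chrom2])
    for chrom, L in chrom_lengths.items():
        if chrom in handled:
            continue
        segs: list[_Segment] = []
        cur = 0
        for ev in sorted(by_chrom[chrom], key=lambda e: e.start):
            s0 = ev.start - 1
            if cur < s0:
                segs.append(_Segment(chrom, cur, s0))
            if ev.svtype == "deletion":
                cur = s0 + ev.size
            elif ev.svtype == "inversion":
                segs.append(_Segment(chrom, s0, s0 + ev.size, "-"))
                cur = s0 + ev.size
            elif ev.svtype == "insertion":
                segs.append(_Segment(None, 0, ev.size))
                cur = s0
        if cur < L:
            segs.append(_Segment(chrom, cur, L))
        contigs[chrom] = segs
    return contigs


@dataclass
class _Mapped:
    chrom: str
    pos0: int
    aligned: int
    strand: str
    clip5: int
    clip3: int


def _map_read(segs: list, offsets: list, a: int, b: int, strand: str,
              min_aligned: int = 20) -> Optional[_Mapped]:
    """Map donor interval [a, b) to the reference via the segment list."""
    best, best_olap = None, 0
    for seg, off in zip(segs, offsets):
        lo, hi = max(a, off), min(b, off + seg.length)
        if hi - lo > best_olap:
            best, best_olap, blo, bhi, boff = seg, hi - lo, lo, hi, off
    if best is None or best.ref_chrom is None or best_olap < min_aligned:
        return None
    lclip, rclip = blo - a, b - bhi
    if best.strand == "+":
        return _Mapped(best.ref_chrom, best.ref_start + (blo - boff), best_olap,
                       strand, lclip, rclip)
    flipped = "-" if strand == "+" else "+"
    return _Mapped(best.ref_chrom, best.ref_start + (boff + best.length - bhi),
                   best_olap, flipped, rclip, lclip)


def gen_sv_scenario(scenario: SVScenario, sam_path, truth_path=None) -> pd.DataFrame:
    """Simulate a paired-end library over planted SVs and write SAM text.

    Fragments are sampled uniformly per haplotype at the stated coverage
    with Normal(insert_mean, insert_sd) fragment sizes; heterozygous events
    put half the fragments on an unaltered reference haplotype.  Reads
    crossing a breakpoint are soft-clipped at the junction; reads landing in
    novel inserted sequence are unmapped and dropped with their mates.

    Returns (and optionally writes) the truth table of planted events.
    """
    chrom_lengths = dict(scenario.chrom_lengths)
    events = list(scenario.events)
    _validate_events(chrom_lengths, events)
    rng = _rng(scenario.seed, _STREAM_SV)
    rl = scenario.read_len

    ref_contigs = {c: [_Segment(c, 0, L)] for c, L in chrom_lengths.items()}
    var_contigs = _variant_contigs(chrom_lengths, events)
    hom = [ev for ev in events if not ev.het]
    hap1 = var_contigs if hom == events and events else ref_contigs
    # haplotype 1 is the reference unless every event is homozygous
    haplotypes = [hap1, var_contigs]

    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": L} for c, L in chrom_lengths.items()],
    })
    tid = {c: i for i, c in enumerate(chrom_lengths)}

    frag_id = 0
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for hap_i, contigs in enumerate(haplotypes):
            for cname, segs in sorted(contigs.items()):
                offsets, cum = [], 0
                for s in segs:
                    offsets.append(cum)
                    cum += s.length
                clen = cum
                n_frags = int(round(scenario.coverage / 2 * clen / (2 * rl)))
                isizes = rng.normal(scenario.insert_mean, scenario.insert_sd,
                                    size=n_frags)
                isizes = np.maximum(isizes, 2 * rl + 2).astype(int)
                starts = rng.integers(0, np.maximum(clen - isizes, 1))
                for f, isize in zip(starts, isizes):
                    frag_id += 1
                    r1 = _map_read(segs, offsets, int(f), int(f) + rl, "+")
                    r2 = _map_read(segs, offsets, int(f) + int(isize) - rl,
                                   int(f) + int(isize), "-")
                    if r1 is None or r2 is None:
                        continue
                    _write_pair(out, header, tid, f"frag{frag_id:08d}", r1, r2, rl)
    truth = pd.DataFrame([
        {
            "svtype": ev.svtype, "chrom": ev.chrom, "start": ev.start,
            "end": (ev.start if ev.svtype in ("insertion", "translocation")
                    else ev.start + ev.size - 1),
            "size": ev.size, "chrom2": ev.chrom2 or "", "pos2": ev.pos2 or "",
            "het": ev.het,
        }
        for ev in events
    ], columns=["svtype", "chrom", "start", "end", "size", "chrom2", "pos2", "het"])
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return truth


def _write_pair(out, header, tid, qname: str, r1: _Mapped, r2: _Mapped,
                rl: int) -> None:
    for me, mate, first in ((r1, r2, True), (r2, r1, False)):
        a = pysam.AlignedSegment(header)
        a.query_name = qname
        flag = 0x1 | (0x40 if first else 0x80)
        if me.strand == "-":
            flag |= 0x10
        if mate.strand == "-":
            flag |= 0x20
        a.flag = flag
        a.reference_id = tid[me.chrom]
        a.reference_start = me.pos0
        a.mapping_quality = 60
        cig = []
        if me.clip5:
            cig.append((4, me.clip5))
        cig.append((0, me.aligned))
        if me.clip3:
            cig.append((4, me.clip3))
        a.cigartuples = cig
        a.next_reference_id = tid[mate.chrom]
        a.next_reference_start = mate.pos0
        if me.chrom == mate.chrom:
            left = min(me.pos0, mate.pos0)
            right = max(me.pos0 + me.aligned, mate.pos0 + mate.aligned)
            span = right - left
            a.template_length = span if me.pos0 <= mate.pos0 else -span
        else:
            a.template_length = 0
        a.query_sequence = "A" * rl
        a.query_qualities = pysam.qualitystring_to_array("I" * rl)
        out.write(a)


# ---------------------------------------------------------------------------
# Hi-C scenario
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HicScenario:
    seed: int = 0
    n_bins: int = 400
    bin_size: int = 5000
    contact_scale: float = 5000.0   # expected counts on the diagonal
    decay_gamma: float = 1.0
    bias_range: tuple = (0.5, 2.0)
    n_loops: int = 50
    loop_enrichment: float = 3.0
    loop_halfwidth: int = 2         # enriched block spans +/- this many bins
    min_loop_distance: int = 20     # bins
    max_loop_distance: int = 60
    n_null_loops: int = 50

    def __post_init__(self):
        if self.n_bins < 50:
            raise ValueError("need at least 50 bins")


@dataclass
class HicScenarioData:
    counts: np.ndarray
    bias: np.ndarray
    planted: list      # [(bin_i, bin_j)]
    nulls: list        # distance-matched decoy anchor pairs
    bin_size: int
    chrom: str = "chr1"

    def to_coo_text(self, path) -> None:
        with open(path, "w") as fh:
            n = self.counts.shape[0]
            for i in range(n):
                for j in range(i, n):
                    if self.counts[i, j] > 0:
                        fh.write(f"{i}\t{j}\t{self.counts[i, j]:.0f}\n")

    def loops_bedpe(self, path, which: str = "planted") -> None:
        pairs = self.planted if which == "planted" else self.nulls
        with open(path, "w") as fh:
            for i, j in pairs:
                fh.write(f"{self.chrom}\t{i * self.bin_size}\t{(i + 1) * self.bin_size}\t"
                         f"{self.chrom}\t{j * self.bin_size}\t{(j + 1) * self.bin_size}\n")


def gen_hic_scenario(scenario: HicScenario) -> HicScenarioData:
    """Distance-decay contact matrix with biases and planted enriched loops.

    Expected counts are scale / (1 + |i-j|)^gamma, multiplied by the outer
    product of a per-bin bias vector, then Poisson sampled on the upper
    triangle and mirrored.  Each planted loop multiplies the expected counts
    of a (2h+1) x (2h+1) block around its anchor pair by the enrichment.
    Distance-matched decoy pairs (enrichment 1) are returned for null
    comparisons.
    """
    rng = _rng(scenario.seed, _STREAM_HIC)
    n = scenario.n_bins
    i, j = np.indices((n, n))
    dist = np.abs(i - j)
    expected = scenario.contact_scale / (1.0 + dist) ** scenario.decay_gamma
    bias = rng.uniform(*scenario.bias_range, size=n)
    expected = expected * np.outer(bias, bias)

    h = scenario.loop_halfwidth
    occupied: set = set()

    d_max = min(scenario.max_loop_distance, n - 2 * h - 2)
    if scenario.min_loop_distance > d_max:
        raise ValueError("matrix too small for the requested loop distances")

    def _draw_pair() -> tuple[int, int]:
        for _ in range(10_000):
            d = int(rng.integers(scenario.min_loop_distance, d_max + 1))
            a = int(rng.integers(h, n - d - h))
            b = a + d
            key_cells = {(a + da, b + db) for da in range(-h, h + 1)
                         for db in range(-h, h + 1)}
            if not (key_cells & occupied):
                occupied.update(key_cells)
                return a, b
        raise RuntimeError("could not place non-overlapping loops; too many requested")

    planted = [_draw_pair() for _ in range(scenario.n_loops)]
    nulls = [_draw_pair() for _ in range(scenario.n_null_loops)]
    for a, b in planted:
        expected[a - h:a + h + 1, b - h:b + h + 1] *= scenario.loop_enrichment
        expected[b - h:b + h + 1, a - h:a + h + 1] *= scenario.loop_enrichment

    upper = np.triu(rng.poisson(np.triu(expected)))
    counts = upper + np.triu(upper, 1).T
    return HicScenarioData(counts.astype(float), bias, planted, nulls,
                           scenario.bin_size)


# ---------------------------------------------------------------------------
# Expression scenario
# ---------------------------------------------------------------------------

_TRENDS = ("decreasing_sigmoid", "increasing_sigmoid", "constant")


@dataclass(frozen=True)
class ExprScenario:
    seed: int = 0
    n_cells: int = 200
    trend: str = "decreasing_sigmoid"
    noise_sd: float = 0.3           # lognormal sigma on the multiplicative noise
    level_high: float = 5.0         # plateau expression
    level_low: float = 0.02         # extinguished expression
    midpoint: float = 0.5           # sigmoid centre on the [0, 1] pseudotime axis
    steepness: float = 12.0
    gene: str = "GENE"

    def __post_init__(self):
        if self.n_cells < 20:
            raise ValueError("need at least 20 cells")
        if self.trend not in _TRENDS:
            raise ValueError(f"trend must be one of {_TRENDS}")


def _truth_fn(s: ExprScenario):
    if s.trend == "constant":
        return lambda t: np.full_like(np.asarray(t, dtype=float), s.level_high)
    sign = 1.0 if s.trend == "decreasing_sigmoid" else -1.0

    def f(t):
        t = np.asarray(t, dtype=float)
        return s.level_low + (s.level_high - s.level_low) / (
            1.0 + np.exp(sign * s.steepness * (t - s.midpoint)))
    return f


@dataclass
class ExprScenarioData:
    table: pd.DataFrame        # cell, pseudotime, <gene>
    truth_grid: np.ndarray
    truth_values: np.ndarray
    gene: str
    truth_fn: object = None    # callable t -> true expression

    def truth_at(self, t) -> np.ndarray:
        return self.truth_fn(t)


def gen_expression_scenario(scenario: ExprScenario,
                            n_grid: int = 100) -> ExprScenarioData:
    """Pseudotime expression table y = f(t) * lognormal noise with truth curve."""
    rng = _rng(scenario.seed, _STREAM_EXPR)
    t = np.sort(rng.uniform(0.0, 1.0, size=scenario.n_cells))
    f = _truth_fn(scenario)
    noise = (np.exp(rng.normal(0.0, scenario.noise_sd, size=scenario.n_cells))
             if scenario.noise_sd > 0 else np.ones(scenario.n_cells))
    y = f(t) * noise
    table = pd.DataFrame({
        "cell": [f"cell{i:04d}" for i in range(scenario.n_cells)],
        "pseudotime": t,
        scenario.gene: y,
    })
    grid = np.linspace(0.0, 1.0, n_grid)
    return ExprScenarioData(table, grid, f(grid), scenario.gene, truth_fn=f)
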