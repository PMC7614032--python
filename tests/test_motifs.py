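"""PWM scoring, variant application, spanning-match scanning and ranking."""

import math

import numpy as np
import pytest

from cisreg import simulate
from cisreg.genomics import Variant
from cisreg.motifs import (
    BASES,
    PWM,
    AmbiguousBaseError,
    Locus,
    NoSpanningWindowError,
    apply_variant,
    assign_tier,
    disruption_score,
    family_of,
    genome_base_frequencies,
    max_spanning_match,
    rank_disruptions,
    read_jaspar,
    revcomp,
    score_window,
)

UNIFORM = np.full(4, 0.25)


def consensus_pwm(consensus: str, p: float = 1.0, background=UNIFORM) -> PWM:
    prob = np.full((len(consensus), 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        prob[i, BASES.index(b)] = p
    return PWM("TEST.1", "TEST1", prob, background)


# ------------------------------------------------------------------ scoring

class TestScoring:
    def test_background_pwm_scores_zero_everywhere(self):
        pwm = PWM("BG.1", "BG1", np.tile(UNIFORM, (5, 1)), UNIFORM)
        for window in ("ACGTA", "TTTTT", "GCGCG"):
            assert score_window(pwm, window) == pytest.approx(0.0)

    def test_consensus_window_scores_4ln4(self):
        pwm = consensus_pwm("ACGT")
        assert score_window(pwm, "ACGT") == pytest.approx(4 * math.log(4))
        assert pwm.max_score == pytest.approx(4 * math.log(4))

    def test_ambiguous_base_raises(self):
        with pytest.raises(AmbiguousBaseError):
            score_window(consensus_pwm("ACGT"), "ACNT")

    def test_exhaustive_windows_never_exceed_max_score(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            prob = rng.dirichlet(np.ones(4) * 0.5, size=6)
            pwm = PWM("R.1", "R1", prob, UNIFORM)
            scores = []
            for code in range(4 ** 6):
                window = "".join(BASES[(code // 4 ** k) % 4] for k in range(6))
                scores.append(score_window(pwm, window))
            assert max(scores) == pytest.approx(pwm.max_score)
            assert all(s <= pwm.max_score + 1e-12 for s in scores)

    def test_consensus_norm_score_is_one(self):
        pwm = consensus_pwm("TGTTTAC", p=0.85)
        assert score_window(pwm, "TGTTTAC") / pwm.max_score == pytest.approx(1.0)


class TestBackgroundFrequencies:
    def test_uniform(self):
        assert genome_base_frequencies(["ACGT"]) == pytest.approx([0.25] * 4)

    def test_ambiguity_codes_excluded(self):
        assert genome_base_frequencies(["AAAN"]) == pytest.approx([1, 0, 0, 0])

    def test_no_acgt_content_rejected(self):
        with pytest.raises(ValueError):
            genome_base_frequencies(["NNNN"])

    def test_planted_gc_recovered_within_two_percent(self):
        rng = np.random.default_rng(0)
        freqs = np.array([0.2, 0.3, 0.3, 0.2])  # 60% GC
        seq = "".join(rng.choice(list(BASES), size=10_000, p=freqs))
        assert genome_base_frequencies([seq]) == pytest.approx(freqs, abs=0.02)


# ------------------------------------------------------------- apply_variant

class TestApplyVariant:
    def test_snv_substitution(self):
        alt, ref_loc, alt_loc = apply_variant("AACGTT", 1, Variant("c", 3, "C", "G"))
        assert alt == "AAGGTT"
        assert ref_loc.offsets == alt_loc.offsets == (2,)

    def test_deletion_junction(self):
        v = Variant("c", 2, "ACG", "A")  # padded: deletes bases 3-4
        alt, ref_loc, alt_loc = apply_variant("AACGTT", 1, v)
        assert alt == "AATT"
        assert ref_loc.offsets == (2, 3)
        assert alt_loc.junction and alt_loc.offsets == (1, 2)

    def test_insertion_locus_spans_inserted_bases(self):
        v = Variant("c", 3, "C", "CTT")
        alt, ref_loc, alt_loc = apply_variant("AACGTT", 1, v)
        assert alt == "AACTTGTT"
        assert len(alt) == 6 + 2
        assert ref_loc.junction
        assert alt_loc.offsets == (2, 3, 4, 5)  # inserted bases + both flanks

    def test_reference_mismatch_names_position(self):
        with pytest.raises(ValueError, match="3"):
            apply_variant("AACGTT", 1, Variant("c", 3, "G", "T"))


# ------------------------------------------------------- max spanning match

def oracle_best_hit(pwm: PWM, seq: str, locus: Locus):
    """Independent exhaustive enumeration of all locus-spanning windows."""
    best = None
    for start in range(len(seq) - pwm.length + 1):
        if not locus.spanned_by(start, pwm.length):
            continue
        window = seq[start:start + pwm.length]
        for strand in "+-":
            w = window if strand == "+" else revcomp(window)
            try:
                s = sum(
                    math.log(max(pwm.prob[i, BASES.index(b)], 1e-10) / 0.25)
                    for i, b in enumerate(w)
                )
            except ValueError:
                continue
            if best is None or s > best[0] + 1e-12:
                best = (s, start, strand)
    return best


class TestMaxSpanningMatch:
    def test_planted_consensus_is_found_with_norm_one(self):
        pwm = consensus_pwm("TGTTTAC", p=0.85)
        seq = "AAAAAA" + "TGTTTAC" + "AAAAAA"
        hit = max_spanning_match(pwm, seq, Locus((8,)))
        assert hit.start == 6 and hit.strand == "+"
        assert hit.norm_score == pytest.approx(1.0)

    def test_consensus_outside_spanning_windows_is_not_reported(self):
        pwm = consensus_pwm("TGTTTAC", p=0.85)
        # consensus planted far from the locus: no spanning window reaches it
        seq = "TGTTTAC" + "A" * 30
        hit = max_spanning_match(pwm, seq, Locus((30,)))
        assert hit.start != 0
        assert hit.raw_score < score_window(pwm, "TGTTTAC")

    def test_palindrome_ties_break_to_plus_strand(self):
        pwm = consensus_pwm("ACGT", p=0.85)  # ACGT is its own reverse complement
        seq = "AAACGTAA"
        hit = max_spanning_match(pwm, seq, Locus((3,)))
        assert hit.strand == "+"

    def test_no_spanning_window_raises(self):
        pwm = consensus_pwm("ACGTACGT")
        with pytest.raises(NoSpanningWindowError):
            max_spanning_match(pwm, "ACG", Locus((1,)))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_oracle_on_random_cases(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(4, 11))
        prob = rng.dirichlet(np.ones(4) * 0.7, size=L)
        pwm = PWM(f"R{seed}.1", f"R{seed}", prob, UNIFORM)
        n = int(rng.integers(25, 51))
        seq = "".join(rng.choice(list(BASES), size=n))
        locus = Locus((int(rng.integers(L, n - L)),))
        hit = max_spanning_match(pwm, seq, locus)
        s, start, strand = oracle_best_hit(pwm, seq, locus)
        assert hit.raw_score == pytest.approx(s)
        assert (hit.start, hit.strand) == (start, strand)


# ------------------------------------------------------- tiers and families

class TestTiersAndFamilies:
    @pytest.mark.parametrize("score,tier", [
        (0.60, 1), (0.95, 1), (0.45, 2), (0.599, 2), (0.449, None), (-0.2, None),
    ])
    def test_tier_boundaries(self, score, tier):
        assert assign_tier(score) == tier

    def test_disruption_is_antisymmetric(self, motif_data):
        v = motif_data.variants[0]
        seq = motif_data.seqs[v.chrom]
        pwm = motif_data.pwms[0]
        alt_seq, ref_loc, alt_loc = apply_variant(seq, 1, v)
        ref_hit = max_spanning_match(pwm, seq, ref_loc)
        alt_hit = max_spanning_match(pwm, alt_seq, alt_loc)
        d = disruption_score(ref_hit, alt_hit)
        # swap roles: mutate the mutated sequence back to reference
        back = Variant(v.chrom, v.pos, v.alt, v.ref)
        ref2, loc_a, loc_b = apply_variant(alt_seq, 1, back)
        assert ref2 == seq
        d_swapped = disruption_score(
            max_spanning_match(pwm, alt_seq, loc_a),
            max_spanning_match(pwm, ref2, loc_b),
        )
        assert d_swapped == pytest.approx(-d)

    @pytest.mark.parametrize("symbol,family", [
        ("NKX2-2", "NKX2"), ("HIC2", "HIC"), ("FOXA2", "FOX"),
        ("NFATC1", "NFATC"), ("TEAD1", "TEAD"), ("GATA4", "GATA"),
        ("FOX", "FOX"),
    ])
    def test_family_mapping(self, symbol, family):
        assert family_of(symbol) == family


# ------------------------------------------------------------------ ranking

class TestRankDisruptions:
    def test_planted_family_ranks_first_in_tier1(self, motif_data):
        truth = motif_data.manifest.set_index("seq")
        for v in motif_data.variants:
            records, ranking = rank_disruptions(
                v, motif_data.pwms, motif_data.seqs[v.chrom], flank_bp=30)
            assert ranking[1], "planted site should produce a Tier-1 record"
            assert ranking[1][0][0] == truth.loc[v.chrom, "family"]

    def test_motif_free_background_tiers_match_exhaustive_oracle(self):
        # random PWMs over a motif-free background: every reference score and
        # tier must agree with exhaustive window enumeration, and on this
        # background no chance match reaches the Tier-1 threshold
        rng = np.random.default_rng(0)
        pwms = [PWM(f"W{i}.1", f"W{i}", rng.dirichlet(np.ones(4) * 0.7, size=8),
                    UNIFORM) for i in range(5)]
        seq = "".join(rng.choice(list(BASES), size=200))
        v = Variant("c", 100, seq[99], "A" if seq[99] != "A" else "C")
        records, ranking = rank_disruptions(v, pwms, seq, flank_bp=30)
        pwm_by_id = {p.motif_id: p for p in pwms}
        for r in records:
            pwm = pwm_by_id[r.motif_id]
            s, _, _ = oracle_best_hit(pwm, seq[100 - 31: 100 + 30], Locus((30,)))
            assert r.ref_hit.norm_score == pytest.approx(s / pwm.max_score)
            assert r.tier == assign_tier(r.ref_hit.norm_score)
        assert ranking[1] == []

    def test_same_family_overlapping_pwms_collapse_to_strongest(self, motif_data):
        v = motif_data.variants[0]
        seq = motif_data.seqs[v.chrom]
        base = motif_data.pwms[0]  # the planted NFATC1 motif
        twin = PWM("MS9999.1", "NFATC2", base.prob, base.background)
        records, ranking = rank_disruptions(v, [base, twin], seq, flank_bp=30)
        assert len(ranking[1]) == 1
        family, rec = ranking[1][0]
        assert family == "NFATC"
        assert rec.disruption == pytest.approx(
            max(r.disruption for r in records if r.tier == 1))

    def test_variant_outside_reference_rejected(self, motif_data):
        v = Variant("c", 10_000, "A", "T")
        with pytest.raises(ValueError):
            rank_disruptions(v, motif_data.pwms, "ACGT" * 50, flank_bp=30)


# --------------------------------------------------------------- jaspar I/O

class TestJaspar:
    def test_pseudocount_free_column(self, tmp_path):
        p = tmp_path / "m.pfm"
        p.write_text(">M1 GENE1\nA [ 10 0 ]\nC [ 0 0 ]\nG [ 0 10 ]\nT [ 0 0 ]\n")
        (pwm,) = read_jaspar(p, pseudocount_total=0.0)
        assert pwm.prob[0] == pytest.approx([1, 0, 0, 0])

    def test_zero_column_becomes_background(self, tmp_path):
        p = tmp_path / "m.pfm"
        p.write_text(">M1 GENE1\nA [ 0 9 ]\nC [ 0 0 ]\nG [ 0 0 ]\nT [ 0 1 ]\n")
        (pwm,) = read_jaspar(p, pseudocount_total=0.8)
        assert pwm.prob[0] == pytest.approx([0.25] * 4)

    def test_two_motif_fixture_roundtrip(self, tmp_path):
        p = tmp_path / "set.pfm"
        simulate.write_jaspar_pfm(p)
        pwms = read_jaspar(p)
        assert len(pwms) == 12
        by_id = {w.gene_symbol: w for w in pwms}
        assert by_id["FOXA2"].consensus == "TGTTTACT"
        assert all(w.max_score > 0 for w in pwms)

    def test_uninformative_pwm_rejected(self, tmp_path):
        p = tmp_path / "flat.pfm"
        p.write_text(">M1 FLAT1\nA [ 5 5 ]\nC [ 5 5 ]\nG [ 5 5 ]\nT [ 5 5 ]\n")
        with pytest.raises(ValueError, match="information"):
            read_jaspar(p)
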