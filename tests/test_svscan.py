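"""Insert-size model, discordant-pair classification, clustering and calling."""

import random

import numpy as np
import pytest

from cisreg import simulate, svscan
from cisreg.svscan import (
    InsertSizeModel,
    ReadAlignment,
    ReadPairRecord,
    call_svs,
    classify_pair,
    cluster_discordant,
    collapse_duplicates,
    compute_depth,
    fit_insert_model,
    read_sam,
    refine_breakpoints,
    scan_sv,
)

READ_LEN = 100


def make_pair(chrom="chrA", pos=1000, insert=400, strand1="+", strand2="-",
              chrom2=None, pos2=None, qname="q"):
    """An FR pair with the given outer insert unless mate overrides given."""
    r1 = ReadAlignment(chrom, pos, pos + READ_LEN - 1, strand1, 60)
    if chrom2 is None:
        mpos = pos + insert - READ_LEN
        r2 = ReadAlignment(chrom, mpos, mpos + READ_LEN - 1, strand2, 60)
    else:
        r2 = ReadAlignment(chrom2, pos2, pos2 + READ_LEN - 1, strand2, 60)
    return ReadPairRecord(qname, r1, r2)


def concordant_background(n=200, insert=400, start=1, step=50):
    return [make_pair(pos=start + i * step, insert=insert, qname=f"bg{i}")
            for i in range(n)]


class TestInsertModel:
    def test_constant_inserts_give_degenerate_bounds(self):
        model = fit_insert_model(concordant_background(150))
        assert (model.median, model.sigma) == (400.0, 0.0)
        assert (model.lower, model.upper) == (400.0, 400.0)

    def test_normal_inserts_recover_parameters(self):
        rng = np.random.default_rng(1)
        pairs = [make_pair(pos=1000 + 10 * i, insert=int(x), qname=f"p{i}")
                 for i, x in enumerate(rng.normal(400, 50, size=10_000))]
        model = fit_insert_model(pairs)
        assert model.median == pytest.approx(400, abs=3)
        assert model.sigma == pytest.approx(50, abs=5)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="100"):
            fit_insert_model(concordant_background(99))


class TestClassify:
    @pytest.fixture()
    def model(self):
        return InsertSizeModel(median=400, sigma=50, lower=200, upper=600, n_pairs=500)

    def test_interchromosomal_first(self, model):
        p = make_pair(chrom2="chrB", pos2=5000)
        assert classify_pair(p, model) == "interchromosomal"

    def test_same_strand_is_inversion_signal(self, model):
        p = make_pair(strand1="+", strand2="+")
        assert classify_pair(p, model) == "inverted_orientation"

    def test_insert_boundaries(self, model):
        assert classify_pair(make_pair(insert=601), model) == "long_insert"
        assert classify_pair(make_pair(insert=600), model) == "concordant"
        assert classify_pair(make_pair(insert=400), model) == "concordant"
        assert classify_pair(make_pair(insert=199), model) == "short_insert"


class TestClustering:
    @pytest.fixture()
    def model(self):
        return InsertSizeModel(median=400, sigma=50, lower=200, upper=600, n_pairs=500)

    def test_single_event_single_cluster(self, model):
        pairs = [make_pair(pos=10_000 + 30 * i, insert=4900, qname=f"d{i}")
                 for i in range(5)]
        (cluster,) = cluster_discordant(pairs, model)
        assert cluster.svclass == "long_insert" and cluster.support == 5

    def test_two_distant_events_two_clusters(self, model):
        near = [make_pair(pos=10_000 + 30 * i, insert=4900, qname=f"a{i}")
                for i in range(4)]
        far = [make_pair(pos=110_000 + 30 * i, insert=4900, qname=f"b{i}")
               for i in range(4)]
        clusters = cluster_discordant(near + far, model)
        assert len(clusters) == 2
        assert sorted(c.support for c in clusters) == [4, 4]

    def test_empty_input(self, model):
        assert cluster_discordant([], model) == []

    def test_calls_invariant_under_input_order(self, model):
        pairs = [make_pair(pos=10_000 + 25 * i, insert=4900, qname=f"d{i}")
                 for i in range(6)]
        pairs += concordant_background(120)
        shuffled = pairs[:]
        random.Random(5).shuffle(shuffled)
        calls_a = call_svs(cluster_discordant(pairs, model), model)
        calls_b = call_svs(cluster_discordant(shuffled, model), model)
        assert calls_a == calls_b


class TestCalling:
    @pytest.fixture()
    def model(self):
        return InsertSizeModel(median=400, sigma=50, lower=200, upper=600, n_pairs=500)

    def test_deletion_size_from_insert_excess(self, model):
        pairs = [make_pair(pos=10_000 + 30 * i, insert=4900, qname=f"d{i}")
                 for i in range(6)]
        (call,) = call_svs(cluster_discordant(pairs, model), model)
        assert call.svtype == "deletion"
        # all inserts are 4900 -> excess exactly 4500
        assert call.size == pytest.approx(4500, abs=2 * model.sigma / np.sqrt(6))

    def test_sub_kilobase_size_suppressed(self, model):
        pairs = [make_pair(pos=10_000 + 30 * i, insert=1200, qname=f"d{i}")
                 for i in range(6)]  # excess 800 bp
        assert call_svs(cluster_discordant(pairs, model), model) == []

    def test_support_floor(self, model):
        pairs = [make_pair(pos=10_000 + 30 * i, insert=4900, qname=f"d{i}")
                 for i in range(2)]
        assert call_svs(cluster_discordant(pairs, model), model) == []

    def test_small_insertion_called_with_lower_bound_flag(self, model):
        pairs = [make_pair(pos=10_000 + 30 * i, insert=150, qname=f"i{i}")
                 for i in range(5)]  # deficit 250 bp
        (call,) = call_svs(cluster_discordant(pairs, model), model, min_size=100)
        assert call.svtype == "insertion"
        assert call.size_is_lower_bound
        assert call.size == pytest.approx(250)

    def test_no_call_below_floors_property(self, model):
        rng = np.random.default_rng(9)
        pairs = [make_pair(pos=int(p), insert=int(i), qname=f"r{k}",
                           strand2=rng.choice(["+", "-"]))
                 for k, (p, i) in enumerate(zip(
                     rng.integers(1000, 500_000, 300),
                     rng.normal(900, 700, 300).clip(200)))]
        calls = call_svs(cluster_discordant(pairs, model), model)
        for c in calls:
            assert c.support >= 3
            assert c.size is None or c.size >= 1000


class TestRefinement:
    def test_clip_stacks_snap_breakpoints_and_depth_flags(self, sv_sam):
        sam_path, truth = sv_sam
        calls = scan_sv(sam_path)
        dele = [c for c in calls if c.svtype == "deletion"]
        assert len(dele) == 1
        t = truth[truth.svtype == "deletion"].iloc[0]
        assert dele[0].start == t.start and dele[0].end == t.end
        assert dele[0].clip_support >= 2
        # heterozygous: interior depth about half the flank depth
        assert dele[0].depth_discontinuity

    def test_no_signal_flags_ambiguous(self):
        model = InsertSizeModel(median=400, sigma=50, lower=200, upper=600,
                                n_pairs=500)
        pairs = [make_pair(pos=10_000 + 30 * i, insert=4900, qname=f"d{i}")
                 for i in range(6)]
        # uniform coverage with no depth step across the event (the
        # repeat-mediated signature: discordant inserts but flat depth)
        background = [make_pair(pos=5_000 + 10 * i, insert=400, qname=f"bg{i}")
                      for i in range(2000)]
        (call,) = call_svs(cluster_discordant(pairs, model), model)
        refined = refine_breakpoints(call, pairs + background)
        assert refined.ambiguous_breakpoints
        assert (refined.start, refined.end) == (call.start, call.end)


class TestSamIO:
    HEADER = "@HD\tVN:1.6\n@SQ\tSN:chrA\tLN:100000\n"

    def test_proper_pair_insert(self, tmp_path):
        sam = self.HEADER + (
            "q1\t99\tchrA\t1001\t60\t100M\t=\t1301\t400\t" + "A" * 100 + "\t" + "I" * 100 + "\n"
            "q1\t147\tchrA\t1301\t60\t100M\t=\t1001\t-400\t" + "A" * 100 + "\t" + "I" * 100 + "\n"
        )
        p = tmp_path / "x.sam"
        p.write_text(sam)
        (pair,) = read_sam(p)
        assert pair.insert == 400
        assert pair.proper_orientation

    def test_low_mapq_filtered(self, tmp_path):
        sam = self.HEADER + (
            "q1\t99\tchrA\t1001\t10\t100M\t=\t1301\t400\t*\t*\n"
            "q1\t147\tchrA\t1301\t60\t100M\t=\t1001\t-400\t*\t*\n"
        )
        p = tmp_path / "x.sam"
        p.write_text(sam)
        assert read_sam(p) == []  # one mate gone -> no joined pair

    def test_clip_lengths_parsed(self, tmp_path):
        sam = self.HEADER + (
            "q1\t99\tchrA\t1001\t60\t50S50M\t=\t1301\t400\t" + "A" * 100 + "\t*\n"
            "q1\t147\tchrA\t1301\t60\t50M50S\t=\t1001\t-400\t" + "A" * 100 + "\t*\n"
        )
        p = tmp_path / "x.sam"
        p.write_text(sam)
        (pair,) = read_sam(p)
        assert pair.r1.clip5 == 50 and pair.r1.clip3 == 0
        assert pair.r2.clip3 == 50 and pair.r2.clip5 == 0

    def test_duplicates_collapsed(self):
        pairs = [make_pair(qname="a"), make_pair(qname="b"),
                 make_pair(pos=2000, qname="c")]
        assert len(collapse_duplicates(pairs)) == 2

    def test_call_writers(self, tmp_path, sv_sam):
        sam_path, _ = sv_sam
        calls = scan_sv(sam_path)
        bedpe, vcf = tmp_path / "c.bedpe", tmp_path / "c.vcf"
        svscan.write_calls_bedpe(calls, bedpe)
        svscan.write_calls_vcf(calls, vcf)
        assert len(bedpe.read_text().splitlines()) == len(calls)
        body = [l for l in vcf.read_text().splitlines() if not l.startswith("#")]
        assert len(body) == len(calls)
        assert any("SVTYPE=DEL" in l for l in body)


class TestEndToEnd:
    def test_planted_events_recovered_with_types_and_breakpoints(self, sv_sam):
        sam_path, truth = sv_sam
        calls = scan_sv(sam_path)
        sigma = 50.0
        for t in truth.itertuples():
            matching = [
                c for c in calls
                if c.svtype == t.svtype and c.chrom == t.chrom
                and abs(c.start - t.start) <= 2 * sigma
            ]
            assert matching, f"planted {t.svtype} at {t.chrom}:{t.start} missed"
            if t.svtype in ("deletion", "inversion"):
                assert abs(matching[0].end - t.end) <= 2 * sigma
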