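import numpy as np
import pytest

from cisreg import simulate
from cisreg.genomics import Convention, GenomicInterval
from cisreg.hic import Loop


@pytest.fixture(scope="session")
def motif_data():
    """One seeded motif scenario shared across motif tests."""
    return simulate.gen_motif_scenario(simulate.MotifScenario(seed=11, n_cases=6))


@pytest.fixture(scope="session")
def sv_sam(tmp_path_factory):
    """A seeded simulated library with one het deletion, inversion and
    translocation, written as SAM text."""
    path = tmp_path_factory.mktemp("sv") / "planted.sam"
    scen = simulate.SVScenario(
        seed=7,
        chrom_lengths=(("chrA", 120_000), ("chrB", 60_000), ("chrC", 40_000)),
        events=(
            simulate.SVEvent("deletion", "chrA", 30_001, 4500),
            simulate.SVEvent("inversion", "chrA", 70_001, 3000),
            simulate.SVEvent("translocation", "chrB", 30_001, 0,
                             chrom2="chrC", pos2=20_001),
        ),
    )
    truth = simulate.gen_sv_scenario(scen, path)
    return path, truth


def make_loop(i: int, j: int, bin_size: int = 5000, chrom: str = "chr1") -> Loop:
    return Loop(
        GenomicInterval(chrom, i * bin_size, (i + 1) * bin_size,
                        Convention.ZERO_BASED_HALF_OPEN),
        GenomicInterval(chrom, j * bin_size, (j + 1) * bin_size,
                        Convention.ZERO_BASED_HALF_OPEN),
    )
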