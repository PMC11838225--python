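import numpy as np
import pytest

import cenfiber as cf


@pytest.fixture
def single_cen_genome():
    """One 30-kb chromosome with a single-block 227-bp protected centromere."""
    cde = (8, 165, 25)
    total = sum(cde)
    start = 15_000 - total // 2
    cen = cf.CentromereModel("chr1", start, start + total, "single", 227, cde)
    genome = cf.build_genome(1, 30_000, 0.6, [cen], seed=11)
    layout = cf.layout_chromatin(genome, seed=12)
    return genome, layout, cen


@pytest.fixture
def double_cen_genome():
    """One 30-kb chromosome with a (147, 30, 147) double-block centromere."""
    start = 15_000 - 162
    cen = cf.CentromereModel("chr1", start, start + 324, "double", (147, 30, 147))
    genome = cf.build_genome(1, 30_000, 0.6, [cen], seed=21)
    layout = cf.layout_chromatin(genome, seed=22)
    return genome, layout, cen


@pytest.fixture
def small_fibers(single_cen_genome):
    genome, layout, cen = single_cen_genome
    fibers = cf.simulate_fibers(
        genome, layout, 60, (15_000, 3_000), cf.MethylationParams(), seed=13
    )
    return fibers, cen


def make_fiber(methylatable, methylated, fiber_id="f1", chrom="chr1", start=0, end=None):
    methylatable = np.asarray(methylatable, dtype=np.int64)
    if end is None:
        end = int(methylatable[-1]) + 10 if methylatable.size else start + 100
    return cf.Fiber(
        fiber_id=fiber_id,
        chrom=chrom,
        start=start,
        end=end,
        methylated_sites=np.asarray(methylated, dtype=np.int64),
        methylatable_sites=methylatable,
    )
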