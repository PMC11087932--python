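import numpy as np
import pytest

from gliocnv.deletion_baseline import DeletionBaseline, load_default_baseline
from gliocnv.genome_model import (GenomeBuild, MarkerCatalog, build_bin_grid,
                                  exclusion_mask)
from gliocnv.normalization import CorrectedProfile


@pytest.fixture(scope="session")
def hg38_build():
    return GenomeBuild.load("hg38")


@pytest.fixture(scope="session")
def hg38_grid(hg38_build):
    return build_bin_grid(hg38_build)


@pytest.fixture(scope="session")
def hg38_mask(hg38_grid):
    return exclusion_mask(hg38_grid)


@pytest.fixture(scope="session")
def hg38_catalog(hg38_build):
    return MarkerCatalog.default(hg38_build)


@pytest.fixture(scope="session")
def default_baseline():
    return load_default_baseline()


@pytest.fixture(scope="session")
def ideal_baseline():
    """The exact homozygous-deletion relation copy(t) = 2 - 2t."""
    return DeletionBaseline(slope=-2.0, intercept=2.0, residual_sd=0.0,
                            n_points=9, t_range=(0.1, 0.9),
                            provenance="analytic ideal")


@pytest.fixture
def toy_build():
    """Two chromosomes (3 Mb with a centromere gap, 2 Mb without)."""
    return GenomeBuild(
        name="toy",
        chrom_lengths={"chr1": 3_000_000, "chr2": 2_000_000},
        arm_boundaries={"chr1": 1_600_000},
        gap_regions=(("chr1", 1_500_000, 1_700_000),),
    )


@pytest.fixture
def toy_grid(toy_build):
    return build_bin_grid(toy_build, 500_000)


def make_profile(grid, log2, valid=None, sample_id="test"):
    log2 = np.asarray(log2, dtype=float)
    if valid is None:
        valid = np.isfinite(log2)
    return CorrectedProfile(grid=grid,
                            log2_ratio=np.where(valid, log2, np.nan),
                            valid=np.asarray(valid, dtype=bool),
                            sample_id=sample_id)
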