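import numpy as np
import pytest

from nct import pipeline, synthetic_data
from nct.genome_io import BinGrid, CoverageTrack, GeneModel, build_bin_grid


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run on the default synthetic genome, shared by all
    tests that inspect end-to-end behaviour."""
    return pipeline.run_synthetic_pipeline(
        synthetic_data.SimulationConfig(seed=7), pipeline.PipelineConfig(seed=7)
    )


@pytest.fixture
def small_grid() -> BinGrid:
    """A 500-bp single-chromosome grid (10 bins of 50 bp) with no counts."""
    return build_bin_grid({"chrA": 500}, 50)


def fill_counts(grid: BinGrid, library: str, strand, per_chrom: dict) -> None:
    """Install integer count arrays directly on a grid (test shortcut)."""
    grid.counts[(library, strand)] = {
        chrom: np.asarray(vals, dtype=np.int64) for chrom, vals in per_chrom.items()
    }


@pytest.fixture
def two_exon_gene() -> GeneModel:
    return GeneModel("g1", "chrA", 101, 400, "+", exons=[(101, 200), (301, 400)])
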