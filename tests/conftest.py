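import numpy as np
import pytest

from cqcov.simulate import GenomeBlueprint, SampleSpec, SegmentSpec, build_genome


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def mixed_blueprint():
    """One contig of each segment class at 10 kb."""
    return GenomeBlueprint(
        [
            SegmentSpec("auto1", 10_000, "AUTOSOME"),
            SegmentSpec("xlin1", 10_000, "X_LINKED"),
            SegmentSpec("ylin1", 10_000, "Y_LINKED"),
            SegmentSpec("dupc1", 10_000, "DUP_COLLAPSED"),
        ],
        seed=7,
    )
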