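import numpy as np
import pytest

from molclass import synth, training
from molclass.compiler import InputScale, LinearClassifierSpec


@pytest.fixture(scope="session")
def hcc_cohort():
    """Synthetic two-class expression cohort at study scale, with ground truth."""
    config = synth.GeneratorConfig(seed=42)
    matrix, truth = synth.generate_expression(config)
    return config, matrix, truth


@pytest.fixture(scope="session")
def trained(hcc_cohort):
    """Classifier trained on the synthetic cohort (spec, panels, ranking)."""
    _, matrix, _ = hcc_cohort
    return training.train_classifier(matrix, seed=7)


@pytest.fixture(scope="session")
def molecular_spec(hcc_cohort, trained):
    """The trained five-feature classifier rebased onto the 0.1-10 pM panel scale."""
    config, _, _ = hcc_cohort
    spec, _, _ = trained
    lo, hi = config.concentration_range_pM
    return spec.with_input_scale(InputScale(float(np.log2(lo)), float(np.log2(hi))))


@pytest.fixture
def printed_two_input_spec():
    """The published demonstration classifier Signal = 1.5*I1 - 2*I4."""
    return LinearClassifierSpec(
        features=("Input1", "Input4"),
        weights=(1.5, -2.0),
        bias=0.0,
        positive_class="positive",
        negative_class="negative",
    )
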