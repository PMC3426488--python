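import numpy as np
import pytest
from hypothesis import settings

from minens import PredictionTable, generate, paper_like_config

# property tests must behave identically on every machine
settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

# The nine-predictor vote row used throughout the contribution-score
# docs: six Nucleus votes, two Cytosol, one Mitochondrion, truth Cytosol.
WORKED_ROW = (
    "Cytosol",
    "Nucleus",
    "Nucleus",
    "Mitochondrion",
    "Nucleus",
    "Cytosol",
    "Nucleus",
    "Nucleus",
    "Nucleus",
)
WORKED_TRUTH = "Cytosol"
WORKED_CONTRIBUTIONS = (10.0, -10.0, -10.0, -5.0, -10.0, 10.0, -10.0, -10.0, -10.0)


@pytest.fixture
def worked_table() -> PredictionTable:
    """Single-protein table holding the worked vote example."""
    return PredictionTable(
        protein_ids=["prot1"],
        predictor_names=[f"pred{i}" for i in range(1, 10)],
        predictions=np.array([list(WORKED_ROW)], dtype=object),
        true_labels=[WORKED_TRUTH],
    )


@pytest.fixture
def yeast_table():
    """Mid-sized yeast-profile synthetic table (fixed seed)."""
    return generate(paper_like_config("yeast_lowres", n_proteins=400, seed=7)).table


def random_table(n: int, p: int, seed: int, labels=("A", "B", "C")) -> PredictionTable:
    """Unstructured random table for oracle comparisons."""
    rng = np.random.default_rng(seed)
    preds = rng.choice(labels, size=(n, p)).astype(object)
    truth = rng.choice(labels, size=n).tolist()
    return PredictionTable(
        protein_ids=[f"P{i}" for i in range(n)],
        predictor_names=[f"pred{j}" for j in range(p)],
        predictions=preds,
        true_labels=truth,
    )
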