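"""Shared fixtures: tiny hand-checkable tables and a separable cohort."""

import numpy as np
import pandas as pd
import pytest

from sndsubtype import (
    CohortConfig,
    ExpressionTable,
    LabelTable,
    simulate_cohort,
)


@pytest.fixture
def tiny_table() -> ExpressionTable:
    """3 genes x 2 samples with distinct, easily ranked values."""
    return ExpressionTable(
        pd.DataFrame(
            [[5.0, 2.5], [1.0, 7.0], [3.0, 4.25]],
            index=["g1", "g2", "g3"],
            columns=["S1", "S2"],
        )
    )


@pytest.fixture
def tiny_labels() -> LabelTable:
    return LabelTable(["S1", "S2"], ["PN", "ME"], class_set=["PN", "NE", "CL", "ME"])


@pytest.fixture(scope="session")
def separable_cohort():
    """4 well-separated classes x 100 samples, 100 genes, effect 2 SD.

    A nearest-centroid oracle certifies separability >= 0.99 before any
    network is asked to reach 0.95 on it.
    """
    config = CohortConfig(
        n_genes=100,
        n_samples_per_class={c: 100 for c in ("C1", "C2", "C3", "C4")},
        signature_size=10,
        effect_size=2.0,
        seed=7,
    )
    return simulate_cohort(config)


def int_labels(labels: LabelTable) -> np.ndarray:
    lut = {c: i for i, c in enumerate(sorted(set(labels.labels)))}
    return np.array([lut[l] for l in labels.labels])
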