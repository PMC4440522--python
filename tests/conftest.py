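import numpy as np
import pandas as pd
import pytest

from gepa.expression_io import ExpressionTable

SAMPLES = ["ES", "MCP", "CM", "SM", "EC"]


@pytest.fixture
def samples():
    return list(SAMPLES)


@pytest.fixture
def normalized_table(samples):
    """Tiny classifier-ready table: one CM-specific, one flat, one geometric-decay gene."""
    data = pd.DataFrame(
        {
            "ES": [2.0, 50.0, 160.0],
            "MCP": [30.0, 52.0, 80.0],
            "CM": [100.0, 51.0, 40.0],
            "SM": [12.0, 50.0, 20.0],
            "EC": [2.0, 49.0, 10.0],
        },
        index=["gene_cm", "gene_flat", "gene_decay"],
    )[samples]
    return ExpressionTable(data, normalized=True)


@pytest.fixture
def raw_table(samples):
    data = pd.DataFrame(
        {
            "ES": [0.0, 3.0, 0.0],
            "MCP": [1.0, 1.0, 0.0],
            "CM": [5.0, 2.0, 0.0],
            "SM": [2.0, 2.0, 0.0],
            "EC": [1.0, 1.0, 0.0],
        },
        index=["g1", "g2", "g_zero"],
    )[samples]
    return ExpressionTable(data, normalized=False)


def brute_force_classify(values, threshold):
    """Independent oracle for the classification rule, written pairwise.

    Returns ("enriched", k) with the cut after the k highest samples, or
    ("gradient"/"even", None).  Deliberately implemented with plain Python
    sorting and an explicit ratio list, unlike the numpy scan under test.
    """
    idx = sorted(range(len(values)), key=lambda i: (-values[i], i))
    sv = [values[i] for i in idx]
    ratios = [sv[k] / sv[k + 1] for k in range(len(sv) - 1)]
    for k, r in enumerate(ratios):
        if r >= threshold:
            return "enriched", set(idx[: k + 1])
    if sv[0] / sv[-1] < threshold:
        return "even", None
    return "gradient", None
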