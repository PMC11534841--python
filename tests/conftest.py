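import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import volagree as va

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def hand_grid() -> np.ndarray:
    """3 subjects × 2 observers worked example with known ANOVA sums."""
    return np.array([[10.0, 12.0], [20.0, 18.0], [30.0, 33.0]])


@pytest.fixture
def hand_matrix(hand_grid) -> va.AnnotationMatrix:
    return va.AnnotationMatrix.from_wide(hand_grid)


@pytest.fixture
def cohort100() -> tuple[va.AnnotationMatrix, dict]:
    """Default 100×5 synthetic cohort, fixed seed."""
    return va.generate(va.SyntheticConfig(seed=42))


def brute_force_mean_squares(Y: np.ndarray) -> tuple[float, float, float]:
    """Independent ANOVA oracle: explicit elementwise loops over sums of squares."""
    n, m = Y.shape
    grand = sum(Y[i][j] for i in range(n) for j in range(m)) / (n * m)
    row = [sum(Y[i][j] for j in range(m)) / m for i in range(n)]
    col = [sum(Y[i][j] for i in range(n)) / n for j in range(m)]
    ss_s = m * sum((r - grand) ** 2 for r in row)
    ss_o = n * sum((c - grand) ** 2 for c in col)
    ss_r = sum(
        (Y[i][j] - row[i] - col[j] + grand) ** 2 for i in range(n) for j in range(m)
    )
    return ss_s / (n - 1), ss_o / (m - 1), ss_r / ((n - 1) * (m - 1))


@pytest.fixture
def brute_ms():
    return brute_force_mean_squares


def make_long(matrix: va.AnnotationMatrix) -> pd.DataFrame:
    return matrix.to_long()
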