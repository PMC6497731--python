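import numpy as np
import pytest

from hci.datatypes import ExpressionMatrix, LabelVector


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expression(rng):
    """10 features x 6 samples, strictly positive, no structure."""
    values = rng.lognormal(mean=1.0, sigma=0.5, size=(10, 6))
    return ExpressionMatrix(
        values,
        feature_ids=[f"g{i}" for i in range(10)],
        sample_ids=[f"s{j}" for j in range(6)],
    )


@pytest.fixture
def two_cluster_points(rng):
    """Two well-separated Gaussian clouds as a (d, n) pattern plus labels."""
    a = rng.normal(0.0, 0.1, size=(2, 15))
    b = rng.normal(5.0, 0.1, size=(2, 15))
    Y = np.hstack([a, b])
    labels = np.array([0] * 15 + [1] * 15)
    return Y, labels


def pairwise_ari(x, y):
    """Pair-enumeration oracle for the adjusted Rand index.

    Counts agreements over all sample pairs and applies the
    Hubert-Arabie chance correction computed from the same counts.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    n = len(x)
    n11 = n00 = n10 = n01 = 0
    for i in range(n):
        for j in range(i + 1, n):
            sx = x[i] == x[j]
            sy = y[i] == y[j]
            if sx and sy:
                n11 += 1
            elif sx and not sy:
                n10 += 1
            elif not sx and sy:
                n01 += 1
            else:
                n00 += 1
    total = n11 + n10 + n01 + n00
    expected = (n11 + n10) * (n11 + n01) / total
    maximum = 0.5 * ((n11 + n10) + (n11 + n01))
    if maximum == expected:
        return 1.0 if n10 + n01 == 0 else 0.0
    return (n11 - expected) / (maximum - expected)


def pairwise_rdc(points, labels):
    """All-pairs oracle for RDC = mean within / mean between distance."""
    points = np.asarray(points)
    labels = np.asarray(labels)
    win, btw = [], []
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(points[i] - points[j]))
            (win if labels[i] == labels[j] else btw).append(d)
    return float(np.mean(win)) / float(np.mean(btw))
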