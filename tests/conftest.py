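import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def dcor_bruteforce(x, y):
    """Literal-transcription distance correlation oracle with explicit loops.

    Builds the pairwise Euclidean distance matrices, double-centers them with
    the four-term formula, and evaluates the ratio of 1/n^2 sums directly.
    O(n^2) per matrix entry on purpose: this is the independent check for the
    vectorised implementation, not a usable algorithm.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float).T).T
    y = np.atleast_2d(np.asarray(y, dtype=float).T).T
    n = x.shape[0]
    a = np.zeros((n, n))
    b = np.zeros((n, n))
    for k in range(n):
        for l in range(n):
            a[k, l] = np.sqrt(((x[k] - x[l]) ** 2).sum())
            b[k, l] = np.sqrt(((y[k] - y[l]) ** 2).sum())

    def center(m):
        row = np.array([m[k, :].sum() / n for k in range(n)])
        col = np.array([m[:, l].sum() / n for l in range(n)])
        grand = m.sum() / (n * n)
        out = np.zeros((n, n))
        for k in range(n):
            for l in range(n):
                out[k, l] = m[k, l] - row[k] - col[l] + grand
        return out

    A = center(a)
    B = center(b)
    num = sum(A[k, l] * B[k, l] for k in range(n) for l in range(n)) / (n * n)
    dxx = sum(A[k, l] ** 2 for k in range(n) for l in range(n)) / (n * n)
    dyy = sum(B[k, l] ** 2 for k in range(n) for l in range(n)) / (n * n)
    if dxx <= 0 or dyy <= 0:
        return 0.0
    return np.sqrt(max(num / np.sqrt(dxx * dyy), 0.0))
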