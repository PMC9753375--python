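"""Independent brute-force oracles used to check dynamic-programming code."""

import numpy as np


def dtak_bruteforce(K: np.ndarray) -> float:
    """Exhaustive maximum over monotone alignment paths.

    A path starts at cell (0, 0) — contributing twice its local similarity —
    and moves by (1,0), (0,1) or (1,1) steps to (n-1, m-1); diagonal steps
    contribute twice the entered cell's similarity, axial steps once.  The
    score of the best path divided by n+m equals the DTAK value.  Exponential
    in n+m; for tiny segments only.
    """
    n, m = K.shape
    best = [-np.inf]

    def rec(i: int, j: int, score: float) -> None:
        if i == n - 1 and j == m - 1:
            if score > best[0]:
                best[0] = score
            return
        if i + 1 < n:
            rec(i + 1, j, score + K[i + 1, j])
        if j + 1 < m:
            rec(i, j + 1, score + K[i, j + 1])
        if i + 1 < n and j + 1 < m:
            rec(i + 1, j + 1, score + 2.0 * K[i + 1, j + 1])

    rec(0, 0, 2.0 * K[0, 0])
    return best[0] / (n + m)


def local_kernel_table(X: np.ndarray, Y: np.ndarray, sigma: float) -> np.ndarray:
    d2 = ((X[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * sigma**2))


def dtak_bruteforce_normalized(X: np.ndarray, Y: np.ndarray, sigma: float) -> float:
    kxy = dtak_bruteforce(local_kernel_table(X, Y, sigma))
    kxx = dtak_bruteforce(local_kernel_table(X, X, sigma))
    kyy = dtak_bruteforce(local_kernel_table(Y, Y, sigma))
    return kxy / np.sqrt(kxx * kyy)
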