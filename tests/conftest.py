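import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def stockwell_oracle(x: np.ndarray, fs: float) -> np.ndarray:
    """Literal triple-loop evaluation of the discrete S-transform.

    S[m, n] = sum_k X[(k+n) mod N] exp(-2 pi^2 k^2 / n^2) exp(-2j pi k m / N)
    with X the 1/N-normalized DFT computed by direct summation, and the
    zero voice set to the signal mean.  O(N^3); test fixture only.
    """
    x = np.asarray(x, dtype=np.float64)
    N = len(x)
    X = np.array(
        [sum(x[j] * np.exp(-2j * np.pi * k * j / N) for j in range(N)) / N for k in range(N)]
    )
    S = np.empty((N, N), dtype=complex)
    S[0] = np.mean(x)
    for n in range(1, N):
        for m in range(N):
            S[n, m] = sum(
                X[(k + n) % N]
                * np.exp(-2 * np.pi**2 * k**2 / n**2)
                * np.exp(-2j * np.pi * k * m / N)
                for k in range(N)
            )
    return S
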