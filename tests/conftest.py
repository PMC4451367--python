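"""Shared fixtures and brute-force oracles.

The oracles here recompute correlation sums by explicit double loops over
all vector pairs; they are deliberately slow and independent of the
package's optimized kernels.
"""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")


def naive_embed(x, m, L):
    n_v = len(x) - (m - 1) * L
    return np.array([[x[i + k * L] for k in range(m)] for i in range(n_v)])


def naive_correlation_integral(x, m, L, eps, theiler=0):
    """Fraction of unordered vector pairs within Chebyshev eps (H(0)=1)."""
    v = naive_embed(x, m, L)
    n_v = len(v)
    count, total = 0, 0
    for i in range(n_v - 1):
        for j in range(i + 1 + theiler, n_v):
            total += 1
            if np.max(np.abs(v[i] - v[j])) <= eps:
                count += 1
    return count / total


def naive_joint_counts(x, m, L, eps, theiler=0):
    """Matching-pair counts at dims m and m+1 over the shared template set."""
    n_t = len(x) - m * L
    cm = cm1 = 0
    for i in range(n_t - 1):
        for j in range(i + 1 + theiler, n_t):
            dm = max(abs(x[i + k * L] - x[j + k * L]) for k in range(m))
            if dm <= eps:
                cm += 1
                if max(dm, abs(x[i + m * L] - x[j + m * L])) <= eps:
                    cm1 += 1
    return cm, cm1


@pytest.fixture(scope="session")
def fgn_medium():
    """One moderately long persistent fGn realization shared across tests."""
    from msekit import FgnSpec, simulate_fgn

    return simulate_fgn(FgnSpec(hurst=0.7, n=4096, sigma2=1.0, seed=11))
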