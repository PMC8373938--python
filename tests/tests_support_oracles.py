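"""Independent metric oracles used by the test suite.

These deliberately use different algorithms from the package: RMSD via
the quaternion (Horn) eigenvalue method and TM-score via an exhaustive
window-seed search, so agreement is a genuine cross-check rather than
the same code run twice.
"""

import numpy as np

from cgfold import evaluate
from cgfold.evaluate import tm_d0


def quaternion_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Optimal-superposition RMSD from the largest eigenvalue of the
    Horn quaternion matrix."""
    x = a - a.mean(axis=0)
    y = b - b.mean(axis=0)
    M = x.T @ y
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(x ** 2) + np.sum(y ** 2) - 2.0 * lam) / len(a)
    return float(np.sqrt(max(msd, 0.0)))


def tm_brute_force(model: np.ndarray, native: np.ndarray) -> float:
    """TM-score by exhaustive seeding: every window start for a rich set
    of window lengths, each refined to convergence."""
    L = len(model)
    d0 = tm_d0(L)
    seeds = [np.arange(L)]
    for w in sorted({L, max(L // 2, 4), max(L // 3, 4), max(L // 4, 4),
                     min(10, L), min(7, L), min(6, L), min(5, L), 4}):
        for start in range(0, L - w + 1):
            seeds.append(np.arange(start, start + w))
    return evaluate._tm_from_seeds(model, native, d0, seeds, max_iter=60)
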