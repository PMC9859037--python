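"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check: exact
p-values come from exhaustive word enumeration, repeat chaining from
subset enumeration, and superposition RMSD from Horn's closed-form
quaternion eigenvalue method (no SVD).
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pprscan.recognition_code import load_code_table


@pytest.fixture(scope="session")
def code_table():
    return load_code_table()


# --- oracle: exhaustive p-values over all 4^w words --------------------------

def enumerate_pvalues(int_scores: np.ndarray, bg: np.ndarray):
    """Map integer total score -> exact P(score >= t) by enumerating words."""
    w = int_scores.shape[0]
    totals: dict[int, float] = {}
    for word in itertools.product(range(4), repeat=w):
        t = int(sum(int_scores[i, b] for i, b in enumerate(word)))
        prob = float(np.prod([bg[b] for b in word]))
        totals[t] = totals.get(t, 0.0) + prob
    scores = sorted(totals)
    surv = {}
    acc = 0.0
    for t in reversed(scores):
        acc += totals[t]
        surv[t] = acc
    return surv


# --- oracle: brute-force non-overlapping window selection --------------------

def brute_force_chain(starts, values, width, offset, bonus, slack):
    """Best total over every non-overlapping subset, by enumeration."""
    n = len(starts)
    best_total, best_subset = 0.0, ()
    for mask in range(1, 1 << n):
        idx = [i for i in range(n) if mask >> i & 1]
        ok = all(starts[j] - starts[i] >= width
                 for i, j in zip(idx, idx[1:]))
        if not ok:
            continue
        total = sum(values[i] - offset for i in idx)
        total += bonus * sum(
            abs((starts[j] - starts[i]) - width) <= slack
            for i, j in zip(idx, idx[1:])
        )
        if total > best_total + 1e-12:
            best_total, best_subset = total, tuple(idx)
    return best_total, best_subset


# --- oracle: Horn quaternion superposition RMSD ------------------------------

def horn_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Optimal rigid-fit RMSD via the largest eigenvalue of Horn's 4x4
    quaternion matrix; independent of the Kabsch/SVD route."""
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    s = b0.T @ a0
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    n_mat = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = float(np.linalg.eigvalsh(n_mat)[-1])
    ss = float((a0 ** 2).sum() + (b0 ** 2).sum())
    return float(np.sqrt(max(ss - 2.0 * lam, 0.0) / len(a)))


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random proper rotation and a translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    return rot, rng.normal(0.0, 50.0, size=3)
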