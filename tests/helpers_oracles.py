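"""Independent oracles used by the unit and acceptance suites.

These deliberately avoid the package's own solver paths: the elastic-net
global oracle enumerates sign patterns and solves each candidate KKT
system directly; the AUC oracle enumerates all pairs.
"""

import itertools

import numpy as np


def elnet_global_oracle(b, R, lambda1, lambda2, tol=1e-9):
    """Global minimiser of γᵀ(R+λ2I)γ − 2bᵀγ + 2λ1‖γ‖₁ for p ≤ 5 by
    exhaustive sign-pattern enumeration + KKT solve."""
    b = np.asarray(b, dtype=float)
    p = b.size
    assert p <= 5
    best_obj, best_gamma = np.inf, np.zeros(p)
    M = R + lambda2 * np.eye(p)
    for signs in itertools.product((-1, 0, 1), repeat=p):
        s = np.asarray(signs, dtype=float)
        A = np.flatnonzero(s != 0)
        gamma = np.zeros(p)
        if len(A):
            try:
                gamma[A] = np.linalg.solve(M[np.ix_(A, A)], b[A] - lambda1 * s[A])
            except np.linalg.LinAlgError:
                continue
            if np.any(np.sign(gamma[A]) != s[A]):
                continue
        grad_inactive = b - M @ gamma
        Z = np.flatnonzero(s == 0)
        if len(Z) and np.any(np.abs(grad_inactive[Z]) > lambda1 + tol):
            continue
        obj = float(gamma @ M @ gamma - 2 * b @ gamma + 2 * lambda1 * np.abs(gamma).sum())
        if obj < best_obj:
            best_obj, best_gamma = obj, gamma
    return best_gamma, best_obj


def auc_all_pairs(score, labels):
    """AUC by explicit enumeration of all case/control pairs."""
    score = np.asarray(score, dtype=float)
    labels = np.asarray(labels)
    cases = score[labels == 1]
    controls = score[labels == 0]
    total = 0.0
    for c in cases:
        for d in controls:
            if c > d:
                total += 1.0
            elif c == d:
                total += 0.5
    return total / (len(cases) * len(controls))
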