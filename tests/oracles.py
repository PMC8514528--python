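"""Independent brute-force oracles used by the test suite.

Each function re-derives a quantity by a route independent of the
package implementation it checks: naive agglomeration, residual
regression, exhaustive conditioning-subset search, nested least squares.
"""

from itertools import combinations

import numpy as np
import pandas as pd

from traitspace.network import fisher_z_test, partial_corr


def naive_wpgma(D):
    """O(n^3) WPGMA oracle over a dict of pair distances, lowest-index ties."""
    n = D.shape[0]
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    merges = []
    nxt = n
    while len(active) > 1:
        h, (a, b) = min(
            (dist[(min(a, b), max(a, b))], (min(a, b), max(a, b)))
            for i, a in enumerate(active)
            for b in active[i + 1:]
        )
        for c in active:
            if c not in (a, b):
                da = dist[(min(a, c), max(a, c))]
                db = dist[(min(b, c), max(b, c))]
                dist[(c, nxt)] = (da + db) / 2.0
        merges.append((a, b, h))
        active = [c for c in active if c not in (a, b)] + [nxt]
        nxt += 1
    return merges


def residual_regression_partial(X, i, j, S):
    """Partial correlation by correlating regression residuals."""
    S = list(S)
    if not S:
        return np.corrcoef(X[:, i], X[:, j])[0, 1]
    Z = np.column_stack([np.ones(len(X)), X[:, S]])
    ri = X[:, i] - Z @ np.linalg.lstsq(Z, X[:, i], rcond=None)[0]
    rj = X[:, j] - Z @ np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
    return np.corrcoef(ri, rj)[0, 1]


def exhaustive_skeleton(X, alpha):
    """Remove edge (i, j) iff ANY subset of the remaining variables accepts independence."""
    n, p = X.shape
    C = np.corrcoef(X, rowvar=False)
    edges = set()
    for i, j in combinations(range(p), 2):
        keep = True
        others = [v for v in range(p) if v not in (i, j)]
        for size in range(len(others) + 1):
            for S in combinations(others, size):
                rec = fisher_z_test(partial_corr(C, i, j, S), n, size, alpha)
                if not rec.significant:
                    keep = False
                    break
            if not keep:
                break
        if keep:
            edges.add(frozenset((str(i), str(j))))
    return edges


def random_population_corr(rng, p):
    """Random sparse-precision population correlation matrix (faithful generically)."""
    while True:
        omega = np.zeros((p, p))
        for i, j in combinations(range(p), 2):
            if rng.random() < 0.4:
                omega[i, j] = omega[j, i] = rng.uniform(0.25, 0.6) * rng.choice([-1, 1])
        np.fill_diagonal(omega, np.abs(omega).sum(axis=1) + rng.uniform(0.5, 1.0, p))
        C = np.linalg.inv(omega)
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        if np.linalg.eigvalsh(C).min() > 1e-6:
            return C


def type2_nested_ss(y, A, B):
    """Type-II sums of squares from residual-SS differences of nested fits."""
    y = np.asarray(y, dtype=float)
    a = pd.get_dummies(pd.Series(A), drop_first=True).to_numpy(float)
    b = pd.get_dummies(pd.Series(B), drop_first=True).to_numpy(float)
    ab = np.einsum("ni,nj->nij", a, b).reshape(len(y), -1)
    one = np.ones((len(y), 1))

    def rss(*blocks):
        X = np.hstack((one, *blocks)) if blocks else one
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    return {
        "A": rss(b) - rss(a, b),
        "B": rss(a) - rss(a, b),
        "A:B": rss(a, b) - rss(a, b, ab),
        "Residual": rss(a, b, ab),
    }


def covariance_form_alpha(X):
    """Cronbach's alpha from the item covariance matrix: k/(k-1)(1 - tr(S)/1'S1)."""
    S = np.cov(np.asarray(X), rowvar=False, ddof=1)
    k = S.shape[0]
    return k / (k - 1) * (1 - np.trace(S) / S.sum())
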