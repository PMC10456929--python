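"""Shared statistical primitives.

Implements the Benjamini-Hochberg step-up from first principles (it is an
explicit contract of this package, cross-checked against statsmodels in the
test suite), a residual-sum-of-squares nested-model F-test vectorised over a
feature matrix, and pooled/Welch two-group comparisons used by the per-sex
knockout contrasts.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( p_(j) * n / j ), clipped to [0, 1], returned in
    the original order.  NaN inputs yield NaN outputs and do not count
    toward n.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    n = pv.size
    if n == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    scaled = pv[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    qv = np.empty(n)
    qv[order] = q
    out[ok] = qv
    return out


def rss_fit(X: np.ndarray, Y: np.ndarray):
    """Least-squares residual sum of squares of Y (n x k) on design X (n x p).

    Returns ``(rss, rank)`` where rss has one entry per column of Y.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return (resid ** 2).sum(axis=0), int(rank)


def nested_f_test(X_full: np.ndarray, X_null: np.ndarray, Y: np.ndarray):
    """F-test comparing nested linear models by their residual sums of squares.

    F = ((RSS0 - RSS1) / d_extra) / (RSS1 / d_resid) with d_extra the rank
    difference of the designs and d_resid = n - rank(full).  ``Y`` may be a
    vector or an (n x k) matrix; one F and p per column.  Columns whose full
    model fits perfectly (RSS1 ~ 0) get p = 0 when the null fits worse and
    p = 1 otherwise.  Raises ``ValueError`` on a design with no residual
    degrees of freedom or no extra parameters (rank-deficient interaction).
    """
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    n = Y.shape[0]
    rss1, rank1 = rss_fit(X_full, Y)
    rss0, rank0 = rss_fit(X_null, Y)
    d_extra = rank1 - rank0
    d_resid = n - rank1
    if d_extra <= 0 or d_resid <= 0:
        raise ValueError(
            f"degenerate nested design: rank full={rank1}, null={rank0}, n={n}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss1) / d_extra) / (rss1 / d_resid)
    p = sps.f.sf(f, d_extra, d_resid)
    # perfect fits: the F statistic is 0/0
    tiny = rss1 <= 1e-12 * np.maximum(rss0, 1e-300)
    if tiny.any():
        p = np.where(tiny & (rss0 > 1e-12), 0.0, p)
        p = np.where(tiny & (rss0 <= 1e-12), 1.0, p)
        f = np.where(tiny, np.inf, f)
        f = np.where(tiny & (rss0 <= 1e-12), 0.0, f)
    if squeeze:
        return float(f[0]), float(p[0])
    return f, p


def two_group_test(Y: np.ndarray, in_group_a: np.ndarray, welch: bool = False):
    """Two-sided comparison of group A vs group B column-wise.

    Pooled mode is the classical equal-variance t-test (equivalent to the
    two-group OLS Wald test); ``welch=True`` uses Satterthwaite degrees of
    freedom.  Returns ``(estimate, t, p)`` with estimate = mean_A - mean_B
    on the scale of ``Y``.  Columns with zero variance in both groups get
    estimate 0 (when means agree) and p = 1.
    """
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    a = Y[np.asarray(in_group_a, bool)]
    b = Y[~np.asarray(in_group_a, bool)]
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 samples")
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    est = ma - mb
    if welch:
        se2 = va / na + vb / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = np.full(Y.shape[1], na + nb - 2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / np.sqrt(se2)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    zero = se2 <= 0
    if np.any(zero):
        t = np.where(zero, 0.0, t)
        p = np.where(zero & (np.abs(est) < 1e-12), 1.0, np.where(zero, 0.0, p))
    if squeeze:
        return float(est[0]), float(t[0]), float(p[0])
    return est, t, p


def spearman(x, y, min_exact_n: int = 10):
    """Spearman rho with average ranks and a two-sided p-value.

    Ranks ties by their average, then correlates the ranks; p comes from
    the t approximation for n >= ``min_exact_n`` and from an exact
    permutation enumeration below it (a safety net — the association stage
    filters to n >= 15 before calling this).  Constant input yields
    ``(nan, nan)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return np.nan, np.nan
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = np.corrcoef(rx, ry)[0, 1]
    if n < min_exact_n:
        from itertools import permutations
        obs = abs(rho)
        count = 0
        total = 0
        for perm in permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        return float(rho), count / total
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return float(rho), float(p)


def spearman_matrix(X: np.ndarray, Y: np.ndarray):
    """All-pairs Spearman rho and t-approximation p for complete matrices.

    ``X`` (n x a) against ``Y`` (n x b) -> ``(rho, p)`` of shape (a, b).
    Requires complete data (no NaN); the caller handles pairwise deletion.
    """
    n = X.shape[0]
    RX = np.apply_along_axis(sps.rankdata, 0, X)
    RY = np.apply_along_axis(sps.rankdata, 0, Y)
    RX = (RX - RX.mean(axis=0)) / RX.std(axis=0, ddof=0)
    RY = (RY - RY.mean(axis=0)) / RY.std(axis=0, ddof=0)
    rho = RX.T @ RY / n
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return rho, p
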