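"""Independent brute-force oracles used to validate the implementation.

Each oracle recomputes a quantity from its definition by a route disjoint
from the package code: the dip via linear programming over piecewise-linear
unimodal envelopes of the ecdf, BH by trying every step-up cut point, the
omnibus statistic by a double loop over the grid with scipy's contingency
test and a from-scratch trend score test.
"""

import numpy as np
from scipy import stats
from scipy.optimize import linprog


# ---------------------------------------------------------------------------
# dip: minimize sup |F_n - G| over unimodal cdfs G by LP.
# G is piecewise linear with knots at the unique data values and one jump
# allowed at the mode; for each candidate mode position an LP in the knot
# values minimizes the tube half-width d.


def dip_lp(x):
    x = np.sort(np.asarray(x, float))
    n = x.size
    u, counts = np.unique(x, return_counts=True)
    K = u.size
    if K == 1:
        return 0.0
    top = np.cumsum(counts) / n
    bot = np.concatenate(([0.0], top[:-1]))
    best = np.inf
    for t in range(K):
        best = min(best, _lp_mode_at_knot(u, top, bot, t))
    for t in range(K - 1):
        best = min(best, _lp_mode_in_gap(u, top, bot, t))
    return best


def _lp_solve(A, b, nv):
    c = np.zeros(nv)
    c[-1] = 1.0
    bounds = [(0.0, 1.0)] * (nv - 1) + [(0.0, None)]
    res = linprog(c, A_ub=np.array(A), b_ub=np.array(b), bounds=bounds,
                  method="highs")
    assert res.success
    return res.fun


def _lp_tube(A, b, K, nv, top, bot, mode_knot=None, h_idx=None):
    d = nv - 1
    for s in range(K):
        for sign in (1.0, -1.0):
            row = np.zeros(nv)
            row[s] = sign
            row[d] = -1.0
            A.append(row)
            b.append(sign * top[s])
        tgt = h_idx if (mode_knot is not None and s == mode_knot) else s
        for sign in (1.0, -1.0):
            row = np.zeros(nv)
            row[tgt] = sign
            row[d] = -1.0
            A.append(row)
            b.append(sign * bot[s])


def _lp_mono(A, b, K, nv):
    for s in range(K - 1):
        row = np.zeros(nv)
        row[s] = 1.0
        row[s + 1] = -1.0
        A.append(row)
        b.append(0.0)


def _lp_slope_row(nv, i, j, k, u, concave=False):
    row = np.zeros(nv)
    a = 1.0 / (u[j] - u[i])
    c = 1.0 / (u[k] - u[j])
    row[i] = -a
    row[j] = a + c
    row[k] = -c
    return -row if concave else row


def _lp_mode_at_knot(u, top, bot, t):
    K = u.size
    nv = K + 2          # g_0..g_{K-1}, h (left limit at the mode), d
    h = K
    A, b = [], []
    _lp_tube(A, b, K, nv, top, bot, mode_knot=t, h_idx=h)
    _lp_mono(A, b, K, nv)
    row = np.zeros(nv)
    row[h] = 1.0
    row[t] = -1.0
    A.append(row)
    b.append(0.0)
    if t > 0:
        row = np.zeros(nv)
        row[t - 1] = 1.0
        row[h] = -1.0
        A.append(row)
        b.append(0.0)
    left_vars = list(range(t)) + [h]
    left_pos = list(range(t)) + [t]
    for a_i in range(len(left_vars) - 2):
        i, j, k = left_vars[a_i], left_vars[a_i + 1], left_vars[a_i + 2]
        pi, pj, pk = left_pos[a_i], left_pos[a_i + 1], left_pos[a_i + 2]
        row = np.zeros(nv)
        ai = 1.0 / (u[pj] - u[pi])
        ck = 1.0 / (u[pk] - u[pj])
        row[i] -= ai
        row[j] += ai + ck
        row[k] -= ck
        A.append(row)
        b.append(0.0)
    for j in range(t + 1, K - 1):
        A.append(_lp_slope_row(nv, j - 1, j, j + 1, u, concave=True))
        b.append(0.0)
    return _lp_solve(A, b, nv)


def _lp_mode_in_gap(u, top, bot, t):
    K = u.size
    nv = K + 1
    A, b = [], []
    _lp_tube(A, b, K, nv, top, bot)
    _lp_mono(A, b, K, nv)
    for j in range(1, t):
        A.append(_lp_slope_row(nv, j - 1, j, j + 1, u))
        b.append(0.0)
    for j in range(t + 2, K - 1):
        A.append(_lp_slope_row(nv, j - 1, j, j + 1, u, concave=True))
        b.append(0.0)
    return _lp_solve(A, b, nv)


# ---------------------------------------------------------------------------
# BH by exhaustive threshold search


def bh_rejections_brute(p, alpha):
    """Step-up rejection count by checking every cut point."""
    p = np.sort(np.asarray(p, float))
    m = p.size
    best = 0
    for i in range(m, 0, -1):
        if p[i - 1] <= alpha * i / m:
            best = i
            break
    return best


# ---------------------------------------------------------------------------
# omnibus statistic by independent double loop


def cochran_armitage_neglogp(table_low, table_total):
    """Two-sided Cochran-Armitage trend -log p from first principles."""
    r = np.asarray(table_low, float)
    n = np.asarray(table_total, float)
    s = np.arange(1, r.size + 1, dtype=float)
    big_n = n.sum()
    pbar = r.sum() / big_n
    t = np.sum(s * (r - n * pbar))
    var = pbar * (1 - pbar) * (np.sum(n * s**2) - np.sum(n * s) ** 2 / big_n)
    if var <= 0 or pbar in (0.0, 1.0):
        return 0.0
    z = abs(t) / np.sqrt(var)
    pval = 2 * stats.norm.sf(z)
    return -np.log(pval)


def omnibus_statistic_brute(p, x, quantiles, category_counts, continuous=True):
    """Recompute the omnibus max statistic with scipy's chi-square
    contingency test and the trend oracle."""
    import pandas as pd

    p = np.asarray(p, float)
    t_best = 0.0
    if continuous:
        cats = []
        xf = np.asarray(x, float)
        for n_cat in category_counts:
            # same binning rule (right-closed quantile bins), independent code
            edges = np.unique(np.quantile(xf, np.linspace(0, 1, n_cat + 1)[1:-1]))
            codes = np.searchsorted(edges, xf, side="left")
            if np.unique(codes).size >= 2:
                cats.append(codes.astype(int))
    else:
        cats = [pd.factorize(np.asarray(x), sort=True)[0]]
    for q in quantiles:
        low = p <= np.quantile(p, q)
        if low.all() or not low.any():
            continue
        for codes in cats:
            tab = pd.crosstab(low, codes).to_numpy()
            if tab.shape[0] < 2 or tab.shape[1] < 2:
                continue
            chi2 = stats.chi2_contingency(tab, correction=False)
            t_best = max(t_best, -np.log(chi2.pvalue))
            if continuous:
                n_tot = tab.sum(axis=0)
                r_low = tab[1] if low.sum() == tab[1].sum() else tab[0]
                t_best = max(
                    t_best, cochran_armitage_neglogp(r_low, n_tot)
                )
    return t_best
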