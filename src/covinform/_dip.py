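"""Hartigan's dip statistic of unimodality.

The dip of a sample is the sup-norm distance between its empirical
distribution function and the closest unimodal distribution function,

    dip = min_{G unimodal} sup_x |F_n(x) - G(x)|,

where a unimodal cdf is convex up to its mode and concave after it (a single
atom is allowed at the mode).  The dip lies in (0, 0.25]: it approaches 0.25
for a balanced two-point sample and 1/(2n) for a perfectly unimodal one.
Large values indicate multimodality.  The statistic is invariant under
strictly increasing transformations of the data.

The implementation is exact.  It bisects on the candidate distance ``d`` and
decides feasibility of a unimodal fit within the tube ``[F_n - d, F_n + d]``
by splitting at every candidate mode position: the left prefix must admit an
increasing convex function inside the tube (possible iff ``2d`` is at least
the maximal gap between the ecdf and its greatest convex minorant), the
right suffix an increasing concave one (least concave majorant, mirrored),
and the minimal attainable end value of the convex piece must not exceed the
maximal attainable start value of the concave piece.  The last condition is
evaluated with an upper envelope of supporting lines; the steepest
supporting slope at each knot is found on the lower convex hull of the tube
ceiling.  When the junction condition is slack at the minorant/majorant
bound — the typical unimodal-sample case — no bisection is needed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic"]

_ATOL = 1e-12


def dip_statistic(values) -> float:
    """Exact dip statistic of a 1-d sample.

    Parameters
    ----------
    values : array_like
        Sample of at least 4 finite observations.

    Returns
    -------
    float
        The dip, in ``(0, 0.25]``.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("dip statistic requires at least 4 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip statistic requires finite values")
    u, counts = np.unique(x, return_counts=True)
    n = x.size
    top = np.cumsum(counts) / n          # F_n(u_s)
    bot = np.concatenate(([0.0], top[:-1]))  # F_n(u_s^-)
    K = u.size
    if K == 1:
        # degenerate one-value sample: an atom fits exactly; report the
        # attainable floor instead of zero
        return 1.0 / (2.0 * n)

    l_req, l_req_knot = _minorant_gaps(u, top, bot)
    ur, topr, botr = -u[::-1], 1.0 - bot[::-1], 1.0 - top[::-1]
    r_rev, r_rev_knot = _minorant_gaps(ur, topr, botr)
    r_req, r_req_knot = r_rev[::-1], r_rev_knot[::-1]

    # best achievable ignoring the junction between the two pieces
    unc = min(
        np.minimum.reduce(np.maximum(l_req[:-1], r_req[1:]), initial=np.inf),
        np.minimum.reduce(np.maximum(l_req_knot, r_req_knot), initial=np.inf),
    ) / 2.0

    def feasible(d: float) -> bool:
        min_end_gap, min_end_knot = _convex_min_end(u, top, bot, d)
        mr_gap_rev, mr_knot_rev = _convex_min_end(ur, topr, botr, d)
        max_start_gap = 1.0 - mr_gap_rev[::-1]
        max_start_knot = 1.0 - mr_knot_rev[::-1]
        two_d = 2.0 * d + _ATOL
        ok = (
            (l_req[:-1] <= two_d)
            & (r_req[1:] <= two_d)
            & (min_end_gap[:-1] <= max_start_gap[1:] + _ATOL)
        )
        if ok.any():
            return True
        ok = (
            (l_req_knot <= two_d)
            & (r_req_knot <= two_d)
            & (min_end_knot <= max_start_knot + _ATOL)
        )
        return bool(ok.any())

    if feasible(unc):
        return max(unc, 1.0 / (2.0 * n))
    lo, hi = unc, 0.25
    while not feasible(hi):  # pragma: no cover - tube of 0.25 always works
        hi *= 2.0
    while hi - lo > _ATOL:
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            hi = mid
        else:
            lo = mid
    return max(hi, 1.0 / (2.0 * n))


def _minorant_gaps(u, top, bot):
    """Running max gap between the ecdf and the greatest convex minorant.

    Returns arrays over prefixes 0..t: ``gap_all[t]`` uses the jump tops at
    every knot of the prefix; ``gap_excl[t]`` excludes the top of the final
    knot t (the mode-at-an-atom variant, where only the pre-jump level of
    the last knot constrains the convex piece).
    """
    K = u.size
    gap_all = np.empty(K)
    gap_excl = np.empty(K)
    hull = [0]
    seg_max = [0.0]          # per hull segment: max of top - hull inside it
    gap_excl[0] = 0.0
    gap_all[0] = top[0] - bot[0]
    for t in range(1, K):
        while len(hull) >= 2:
            i, j = hull[-2], hull[-1]
            if (bot[j] - bot[i]) * (u[t] - u[i]) >= (bot[t] - bot[i]) * (u[j] - u[i]):
                hull.pop()
                seg_max.pop()
            else:
                break
        a = hull[-1]
        g = 0.0
        if t - a > 1:
            s = np.arange(a, t)
            hv = bot[a] + (bot[t] - bot[a]) * (u[s] - u[a]) / (u[t] - u[a])
            g = float(np.max(top[s] - hv))
        else:
            g = top[a] - bot[a]
        hull.append(t)
        seg_max.append(g)
        running = max(seg_max)
        gap_excl[t] = running
        gap_all[t] = max(running, top[t] - bot[t])
    return gap_all, gap_excl


def _convex_min_end(u, top, bot, d):
    """Minimal end value of an increasing convex function in the tube.

    ``min_end_gap[t]`` ends at knot t subject to the full tube there (mode
    lies in the open gap after t); ``min_end_knot[t]`` ends at the pre-jump
    level of knot t (mode at the atom t itself).  Lower bounds on the end
    value are supporting lines through an earlier tube ceiling point and a
    later tube floor point; per knot only the steepest such line matters,
    found on the lower hull of the ceiling.
    """
    K = u.size
    lo = top - d
    hi = bot + d
    min_end_gap = np.empty(K)
    min_end_knot = np.empty(K)
    hull = []                # lower hull of (u_s, hi_s)
    ln_u, ln_v, ln_s = [], [], []    # active supporting lines
    for t in range(K):
        ut = u[t]
        env = 0.0
        best_slope = 0.0
        if ln_u:
            vals = [v + s * (ut - a) for a, v, s in zip(ln_u, ln_v, ln_s)]
            env = max(vals)
            k = vals.index(env)
            best_slope = ln_s[k]
            if len(ln_u) > 8:
                keep = [
                    i
                    for i in range(len(ln_u))
                    if ln_s[i] > best_slope or vals[i] >= env - 1e-14
                ]
                ln_u = [ln_u[i] for i in keep]
                ln_v = [ln_v[i] for i in keep]
                ln_s = [ln_s[i] for i in keep]
        min_end_knot[t] = max(bot[t] - d, env, 0.0)
        min_end_gap[t] = max(lo[t], env, 0.0)
        slope = 0.0
        if hull:
            slope = max(0.0, _steepest(u, hi, hull, ut, lo[t]))
        ln_u.append(ut)
        ln_v.append(lo[t])
        ln_s.append(slope)
        while len(hull) >= 2:
            i, j = hull[-2], hull[-1]
            if (hi[j] - hi[i]) * (ut - u[i]) >= (hi[t] - hi[i]) * (u[j] - u[i]):
                hull.pop()
            else:
                break
        hull.append(t)
    return min_end_gap, min_end_knot


def _steepest(u, hi, hull, uq, vq):
    """Max slope from a hull vertex (u_s, hi_s) up to the point (uq, vq).

    The slope is unimodal over the hull vertices, so ternary search applies.
    """
    # nearly coincident knots can drive slopes to the float limit; the max
    # is still well-defined
    with np.errstate(over="ignore"):
        a, b = 0, len(hull) - 1
        while b - a > 2:
            m1 = a + (b - a) // 3
            m2 = b - (b - a) // 3
            f1 = (vq - hi[hull[m1]]) / (uq - u[hull[m1]])
            f2 = (vq - hi[hull[m2]]) / (uq - u[hull[m2]])
            if f1 < f2:
                a = m1 + 1
            else:
                b = m2
        return max(
            (vq - hi[hull[i]]) / (uq - u[hull[i]]) for i in range(a, b + 1)
        )
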