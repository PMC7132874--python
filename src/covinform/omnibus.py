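"""Permutation omnibus test for p-value/covariate dependence.

A covariate is useful for covariate-adaptive FDR control only if it is
informative about the null probability or power of the hypotheses, either of
which induces dependence between the covariate and the association p-values.
Because the signal is typically sparse and the dependence possibly
non-monotone, rank correlation tests have little power.  The omnibus test
instead

1. dichotomizes the p-values at a grid of low quantiles (zooming into the
   small-p region where signal lives),
2. slices a continuous covariate into 2..32 equal-size categories (capturing
   non-linear dependence),
3. scores each dichotomization x categorization by a chi-square independence
   test and, for ordered slices, a Cochran-Armitage trend test (regaining
   power under monotone dependence), and
4. takes the maximum of all -log p-values as the omnibus statistic, whose
   significance is assessed by permuting the covariate.

A variant restricted to p > 0.5 (with an evenly spread quantile grid) checks
the complementary requirement that the covariate be independent of the
p-values under the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import CovariateColumn, PValueStudy

logger = logging.getLogger(__name__)

__all__ = [
    "OmnibusConfig",
    "OmnibusResult",
    "OmnibusTest",
    "omnibus_test",
    "omnibus_statistic",
    "null_independence_test",
    "dichotomize",
    "categorize",
    "chisq_score",
    "trend_score",
    "decorrelate_subsample",
    "spearman_pvalue",
    "kruskal_pvalue",
]

DEFAULT_CUTOFF_QUANTILES = (0.001, 0.005, 0.01, 0.05, 0.1, 0.2)
NULL_CHECK_QUANTILES = (0.1, 0.2, 0.4, 0.6, 0.8, 0.9)
DEFAULT_CATEGORY_COUNTS = (2, 4, 8, 16, 32)


@dataclass(frozen=True)
class OmnibusConfig:
    """Grids and permutation settings of the omnibus test."""

    p_cutoff_quantiles: tuple = DEFAULT_CUTOFF_QUANTILES
    category_counts: tuple = DEFAULT_CATEGORY_COUNTS
    n_permutations: int = 999
    seed: int | None = None
    mode: str = "informativeness"

    def __post_init__(self):
        q = np.asarray(self.p_cutoff_quantiles, dtype=float)
        if q.size == 0 or np.any((q <= 0) | (q >= 1)) or np.any(np.diff(q) <= 0):
            raise ValueError("cutoff quantiles must be increasing within (0, 1)")
        c = np.asarray(self.category_counts, dtype=int)
        if c.size and (np.any(c < 2) or np.any(np.diff(c) <= 0)):
            raise ValueError("category counts must be increasing and >= 2")
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")
        if self.mode not in ("informativeness", "null_independence"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class OmnibusResult:
    """Observed statistic, permutation distribution and omnibus p-value."""

    t_obs: float
    q_matrix: pd.DataFrame
    t_perm: np.ndarray
    pval: float
    config: OmnibusConfig
    covariate_name: str = "x"
    n_used: int = 0

    def summary(self) -> str:
        k = self.t_perm.size
        lines = [
            "Omnibus informativeness test"
            if self.config.mode == "informativeness"
            else "Omnibus null-independence check",
            f"covariate: {self.covariate_name}    features used: {self.n_used}",
            f"observed statistic t_obs = {self.t_obs:.4f}"
            f"    permutations K = {k}",
            f"omnibus p-value = {self.pval:.4g}"
            f"  (attainable minimum {1.0 / (k + 1):.4g})",
            "",
            "component -log p scores (rows: p-value cutoff quantile):",
            self.q_matrix.round(3).to_string(),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# building blocks


def dichotomize(p, cutoff_quantile: float) -> np.ndarray:
    """Binary indicator of p-values at or below the given quantile of p.

    The cutoff is the linear-interpolation (type 7) quantile of the observed
    p-values; ties at the cutoff fall into the low class.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if not 0 < cutoff_quantile < 1:
        raise ValueError("cutoff quantile must be in (0, 1)")
    return p <= np.quantile(p, cutoff_quantile)


def categorize(x, n_cat: int) -> np.ndarray | None:
    """Slice a continuous covariate into n_cat equal-size ordered categories.

    Returns integer codes 0..L-1 ordered by x, with L <= n_cat when tied
    quantile breakpoints force categories to merge; None when fewer than two
    categories survive (the combination is then skipped).
    """
    if n_cat < 2:
        raise ValueError("need at least two categories")
    x = np.asarray(x, dtype=float)
    inner = np.unique(np.quantile(x, np.linspace(0, 1, n_cat + 1)[1:-1]))
    # right-closed bins (ties at a breakpoint fall into the lower category);
    # duplicate breakpoints merge the affected categories
    codes = np.searchsorted(inner, x, side="left")
    _, codes = np.unique(codes, return_inverse=True)
    n_levels = codes.max() + 1
    if n_levels < 2:
        return None
    if n_levels < n_cat:
        logger.debug("tied breakpoints: %d categories merged to %d", n_cat, n_levels)
    return codes.astype(int)


def _chisq_neglogp(r, n_per_cat, n_low, n_total):
    """-log p of the Pearson chi-square test on the 2 x L table with low-p
    counts ``r`` per category; 0 for degenerate tables."""
    keep = n_per_cat > 0
    r = r[keep]
    n_l = n_per_cat[keep]
    L = n_l.size
    if L < 2 or n_low == 0 or n_low == n_total:
        return 0.0
    e = n_l * (n_low / n_total)
    chi2 = (n_total**2 / (n_low * (n_total - n_low))) * np.sum((r - e) ** 2 / n_l)
    return -stats.chi2.logsf(chi2, L - 1)


def _trend_neglogp(r, n_per_cat, n_low, n_total):
    """-log p of the two-sided Cochran-Armitage trend test with integer
    scores 1..L; 0 for degenerate tables."""
    keep = n_per_cat > 0
    r = r[keep]
    n_l = n_per_cat[keep]
    L = n_l.size
    if L < 2 or n_low == 0 or n_low == n_total:
        return 0.0
    s = np.arange(1, L + 1, dtype=float)
    pbar = n_low / n_total
    t_stat = np.sum(s * (r - n_l * pbar))
    var = pbar * (1 - pbar) * (np.sum(n_l * s**2) - np.sum(n_l * s) ** 2 / n_total)
    if var <= 0:
        return 0.0
    z = abs(t_stat) / np.sqrt(var)
    return -(np.log(2.0) + stats.norm.logsf(z))


def chisq_score(p_binary, x_categorical) -> float:
    """-log p of the chi-square independence test of a binary p-value class
    against a categorical covariate (no continuity correction)."""
    p_binary = np.asarray(p_binary, dtype=bool)
    codes, _ = pd.factorize(np.asarray(x_categorical))
    n_per_cat = np.bincount(codes)
    r = np.bincount(codes[p_binary], minlength=n_per_cat.size).astype(float)
    return _chisq_neglogp(r, n_per_cat, int(p_binary.sum()), p_binary.size)


def trend_score(p_binary, x_ordered) -> float:
    """-log p of the two-sided Cochran-Armitage trend test of a binary
    p-value class against ordered category codes."""
    p_binary = np.asarray(p_binary, dtype=bool)
    codes = np.asarray(x_ordered, dtype=int)
    codes = codes - codes.min()
    n_per_cat = np.bincount(codes)
    r = np.bincount(codes[p_binary], minlength=n_per_cat.size).astype(float)
    return _trend_neglogp(r, n_per_cat, int(p_binary.sum()), p_binary.size)


# ---------------------------------------------------------------------------
# the omnibus machinery


class _Engine:
    """Precomputed structures shared by the observed and permuted statistics.

    The dichotomized p-value classes are prefixes of the p-sorted order and
    the category sizes are invariant under covariate permutation, so the
    expected counts, chi-square scale factors and trend-test variances are
    all fixed; per permutation only the low-p counts per category change.
    The -log p transforms are applied in one vectorized pass per batch.
    """

    def __init__(self, p, cov: CovariateColumn, config: OmnibusConfig):
        self.m = p.size
        self.order = np.argsort(p, kind="stable")
        p_sorted = p[self.order]
        cutoffs = np.quantile(p, config.p_cutoff_quantiles)
        self.prefix_sizes = np.searchsorted(p_sorted, cutoffs, side="right")
        self.quantiles = config.p_cutoff_quantiles
        self.continuous = cov.kind == "continuous"
        self.codes = []          # per categorization: codes aligned with p
        self.labels = []
        if self.continuous:
            for n_cat in config.category_counts:
                codes = categorize(cov.x, n_cat)
                if codes is None:
                    logger.debug("skipping n_cat=%d: too few distinct values", n_cat)
                    continue
                self.codes.append(codes)
                self.labels.append(n_cat)
        else:
            codes, _ = pd.factorize(cov.x, sort=True)
            if np.unique(codes).size < 2:
                raise ValueError("covariate untestable: fewer than 2 levels")
            self.codes.append(codes)
            self.labels.append("cat")
        if not self.codes:
            raise ValueError("covariate untestable: all categorizations degenerate")
        self.n_per_cat = [np.bincount(c) for c in self.codes]
        # fixed pieces of the test statistics, per (cutoff i, categorization j)
        m = self.m
        ks = self.prefix_sizes.astype(float)
        self._valid_k = (self.prefix_sizes > 0) & (self.prefix_sizes < m)
        self._chi2_df = np.array([n_l.size - 1 for n_l in self.n_per_cat])
        with np.errstate(divide="ignore", invalid="ignore"):
            self._chi2_scale = np.where(
                self._valid_k, m**2 / (ks * (m - ks)), 0.0
            )
        self._expected = [
            np.outer(ks / m, n_l.astype(float)) for n_l in self.n_per_cat
        ]  # per j: (I, L_j)
        if self.continuous:
            pbar = ks / m
            self._trend_var = []
            self._trend_centre = []
            for n_l in self.n_per_cat:
                s = np.arange(1, n_l.size + 1, dtype=float)
                var = (
                    pbar
                    * (1 - pbar)
                    * (np.sum(n_l * s**2) - np.sum(n_l * s) ** 2 / m)
                )
                self._trend_var.append(var)          # per cutoff i
                self._trend_centre.append(pbar * np.sum(n_l * s))
            self._scores = [
                np.arange(1, n_l.size + 1, dtype=float) for n_l in self.n_per_cat
            ]

    def raw_stats(self, sigma):
        """Chi-square and (continuous only) trend |z| statistics for one
        covariate ordering; shape (I, J)."""
        n_i = len(self.prefix_sizes)
        n_j = len(self.codes)
        chi2 = np.zeros((n_i, n_j))
        z = np.zeros((n_i, n_j)) if self.continuous else None
        for j, (codes, n_l) in enumerate(zip(self.codes, self.n_per_cat)):
            in_order = codes[sigma]
            expected = self._expected[j]
            for i, k in enumerate(self.prefix_sizes):
                if not self._valid_k[i]:
                    continue
                r = np.bincount(in_order[:k], minlength=n_l.size).astype(float)
                chi2[i, j] = self._chi2_scale[i] * np.sum(
                    (r - expected[i]) ** 2 / n_l
                )
                if self.continuous:
                    var = self._trend_var[j][i]
                    if var > 0:
                        t_stat = np.sum(self._scores[j] * r) - self._trend_centre[j][i]
                        z[i, j] = abs(t_stat) / np.sqrt(var)
        return chi2, z

    @staticmethod
    def _neglogp(chi2, df, z):
        """-log p for a batch of raw statistics; chi2 has shape (..., I, J)
        with df per j; z may be None."""
        q1 = -stats.chi2.logsf(chi2, df)
        q1 = np.where(chi2 > 0, q1, 0.0)
        if z is None:
            return q1, None
        q2 = -(np.log(2.0) + stats.norm.logsf(z))
        q2 = np.where(z > 0, q2, 0.0)
        return q1, q2

    def statistic(self, perm=None):
        """Omnibus statistic and component scores for a covariate ordering."""
        sigma = self.order if perm is None else perm[self.order]
        chi2, z = self.raw_stats(sigma)
        q1, q2 = self._neglogp(chi2, self._chi2_df, z)
        t_obs = max(q1.max(), q2.max()) if self.continuous else q1.max()
        return t_obs, q1, q2

    def q_frame(self, q1, q2):
        idx = pd.Index(self.quantiles, name="p_quantile")
        if self.continuous:
            cols = {}
            for j, lab in enumerate(self.labels):
                cols[f"chisq.{lab}"] = q1[:, j]
                cols[f"trend.{lab}"] = q2[:, j]
            return pd.DataFrame(cols, index=idx)
        return pd.DataFrame({"chisq": q1[:, 0]}, index=idx)


class OmnibusTest:
    """Model object for the omnibus informativeness test.

    Parameters
    ----------
    pvalues : PValueStudy or array_like
        Per-feature association p-values.
    covariate : CovariateColumn or array_like
        Candidate covariate; plain arrays are wrapped with the given kind.
    kind : str
        ``"continuous"`` or ``"categorical"`` (ignored when a
        CovariateColumn is passed).
    config : OmnibusConfig, optional

    Missing covariate entries are excluded pairwise together with their
    p-values before testing.
    """

    def __init__(self, pvalues, covariate, kind="continuous", config=None):
        if isinstance(pvalues, PValueStudy):
            p = pvalues.p
        else:
            p = np.asarray(pvalues, dtype=float)
        if not isinstance(covariate, CovariateColumn):
            covariate = CovariateColumn(covariate, kind=kind)
        if covariate.x.shape[0] != p.size:
            raise ValueError("p-values and covariate differ in length")
        keep = ~covariate.missing
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("excluding %d features with missing covariate", n_dropped)
            covariate = CovariateColumn(
                covariate.x[keep], covariate.kind, covariate.name
            )
            p = p[keep]
        self.p = p
        self.covariate = covariate
        self.config = config or OmnibusConfig()
        self._engine = _Engine(self.p, self.covariate, self.config)

    def statistic(self):
        """Observed omnibus statistic and the component score matrix."""
        t_obs, q1, q2 = self._engine.statistic()
        return t_obs, self._engine.q_frame(q1, q2)

    def fit(self, n_permutations=None, seed=None) -> OmnibusResult:
        """Run the permutation test.

        The covariate vector is permuted (equivalent to permuting the
        p-values under the exchangeable null) and the full grid statistic is
        recomputed with the same configuration for each permutation.
        """
        config = self.config
        if n_permutations is not None or seed is not None:
            config = replace(
                config,
                n_permutations=n_permutations or config.n_permutations,
                seed=seed if seed is not None else config.seed,
            )
        rng = np.random.default_rng(config.seed)
        engine = self._engine
        t_obs, q1, q2 = engine.statistic()
        k = config.n_permutations
        m = engine.m
        chi2_all = []
        z_all = []
        for _ in range(k):
            perm = rng.permutation(m)
            chi2_b, z_b = engine.raw_stats(perm[engine.order])
            chi2_all.append(chi2_b)
            z_all.append(z_b)
        q1_perm, q2_perm = engine._neglogp(
            np.stack(chi2_all),
            engine._chi2_df,
            np.stack(z_all) if engine.continuous else None,
        )
        t_perm = q1_perm.max(axis=(1, 2))
        if engine.continuous:
            t_perm = np.maximum(t_perm, q2_perm.max(axis=(1, 2)))
        pval = (1.0 + np.sum(t_perm >= t_obs)) / (1.0 + k)
        return OmnibusResult(
            t_obs=t_obs,
            q_matrix=engine.q_frame(q1, q2),
            t_perm=t_perm,
            pval=pval,
            config=config,
            covariate_name=self.covariate.name,
            n_used=m,
        )


def omnibus_statistic(p, covariate, config=None, kind="continuous"):
    """Observed omnibus statistic (no permutations)."""
    return OmnibusTest(p, covariate, kind=kind, config=config).statistic()


def omnibus_test(p, covariate, config=None, kind="continuous") -> OmnibusResult:
    """One-call interface: build the test and run the permutations."""
    return OmnibusTest(p, covariate, kind=kind, config=config).fit()


def null_independence_test(
    p, covariate, config=None, kind="continuous"
) -> OmnibusResult:
    """Omnibus check of p-value/covariate independence under the null.

    Restricts to p > 0.5 (dominantly null p-values) and spreads the cutoff
    quantiles evenly over the retained distribution; a significant result
    signals a violation of the independence-under-the-null assumption
    required by covariate-adaptive FDR procedures.
    """
    p = np.asarray(p if not isinstance(p, PValueStudy) else p.p, dtype=float)
    if not isinstance(covariate, CovariateColumn):
        covariate = CovariateColumn(covariate, kind=kind)
    keep = p > 0.5
    n_kept = int(keep.sum())
    if n_kept < 20:
        raise ValueError(
            f"only {n_kept} p-values above 0.5; null-independence check "
            "needs a null-dominated tail"
        )
    if n_kept < 100:
        logger.warning("only %d p-values above 0.5; check will be unstable", n_kept)
    base = config or OmnibusConfig()
    cfg = replace(
        base, p_cutoff_quantiles=NULL_CHECK_QUANTILES, mode="null_independence"
    )
    sub = CovariateColumn(covariate.x[keep], covariate.kind, covariate.name)
    return OmnibusTest(p[keep], sub, config=cfg).fit()


# ---------------------------------------------------------------------------
# helpers around the test


def decorrelate_subsample(
    p, threshold: float = 0.05, floor: int = 5000
) -> np.ndarray:
    """Indices of a stride-subsample with near-zero lag-1 autocorrelation.

    The permutation null assumes exchangeable features, which autocorrelated
    p-values along the genome violate.  The stride grows 1, 2, 3, ... until
    the lag-1 autocorrelation of the retained sequence is below ``threshold``
    in absolute value, or thinning further would drop below ``floor``
    retained features (the best stride so far is then returned).
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if m <= max(floor, 2):
        if m > 2 and abs(_lag1_autocorr(p)) >= threshold:
            logger.warning(
                "sequence of length %d is below the retention floor; "
                "returned unchanged with |r1| >= %g",
                m,
                threshold,
            )
        return np.arange(m)
    best = np.arange(m)
    best_r = abs(_lag1_autocorr(p))
    stride = 1
    while True:
        idx = np.arange(0, m, stride)
        if idx.size < floor:
            logger.warning(
                "retention floor %d reached at stride %d with |r1| = %.3f",
                floor,
                stride,
                best_r,
            )
            return best
        r = abs(_lag1_autocorr(p[idx]))
        if r < best_r:
            best, best_r = idx, r
        if r < threshold:
            return idx
        stride += 1


def _lag1_autocorr(x) -> float:
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    denom = np.sum(xc**2)
    if denom == 0:
        return 0.0
    return float(np.sum(xc[:-1] * xc[1:]) / denom)


def spearman_pvalue(p, x) -> float:
    """Naive continuous-covariate baseline: Spearman rank correlation test."""
    return float(stats.spearmanr(np.asarray(x, float), np.asarray(p, float)).pvalue)


def kruskal_pvalue(p, x) -> float:
    """Naive categorical-covariate baseline: Kruskal-Wallis test of the
    p-value distribution across covariate levels."""
    p = np.asarray(p, dtype=float)
    codes, levels = pd.factorize(np.asarray(x))
    groups = [p[codes == l] for l in range(len(levels))]
    return float(stats.kruskal(*groups).pvalue)
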