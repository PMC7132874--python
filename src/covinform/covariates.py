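"""Per-feature covariates for covariate-adaptive multiple testing on EWAS data.

Statistical covariates summarise each CpG's methylation distribution (mean,
spread, shape, reliability); biological/technical covariates come straight
from the probe annotation.  All are candidates for informing the prior null
probability or the power of the per-CpG association test:

==============  =========================================================
mean            mean Beta-value
sd.b / sd.m     standard deviation of the Beta-value / M-value
mad             median absolute deviation of the Beta-value (x 1.4826)
dip             Hartigan dip statistic of the Beta-value distribution
precision       inverse precision of a beta distribution matched by moments
direction       sign of the per-feature regression slope on the phenotype
icc.b / icc.m   intraclass correlation across technical replicates
refgene.pos, cpg.loc, chr, dhs, probe.type   from the probe annotation
==============  =========================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._dip import dip_statistic
from .io import CovariateColumn, MethylationStudy

logger = logging.getLogger(__name__)

__all__ = [
    "beta_to_m",
    "m_to_beta",
    "compute_precision",
    "compute_dip",
    "compute_direction",
    "compute_icc",
    "build_covariate_table",
    "encode_covariate",
    "CovariateBasis",
]


def beta_to_m(beta):
    """M-value transform, M = log2(beta / (1 - beta)).

    Association testing is conventionally done on M-values because they are
    closer to homoscedastic; the transform is the base-2 logit and is
    strictly increasing on (0, 1).
    """
    beta = np.asarray(beta, dtype=float)
    if np.any((beta <= 0) | (beta >= 1)):
        raise ValueError("Beta-values must lie strictly in (0, 1); clip upstream")
    return np.log2(beta / (1.0 - beta))


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`."""
    p2 = np.exp2(np.asarray(m, dtype=float))
    return p2 / (1.0 + p2)


def compute_precision(mean, sd):
    """Inverse precision of a beta distribution matched by moments.

    precision = 1 / (mean (1 - mean) / sd^2 - 1).  A beta distribution with
    the given mean and variance has concentration mean(1-mean)/sd^2 - 1;
    small concentration (large inverse precision) means a U-shaped,
    bimodal-prone Beta-value distribution.  Undefined (NaN, with a warning)
    when sd^2 >= mean (1 - mean), which no beta distribution attains.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    limit = mean * (1.0 - mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 1.0 / (limit / sd**2 - 1.0)
    bad = sd**2 >= limit
    if np.any(bad):
        logger.warning(
            "precision undefined for %d features (variance at the beta bound)",
            int(np.sum(bad)),
        )
        out = np.where(bad, np.nan, out)
    if out.ndim == 0:
        return float(out)
    return out


def compute_dip(values) -> float:
    """Hartigan dip statistic (see :mod:`covinform._dip`)."""
    return dip_statistic(values)


def compute_direction(m_matrix, phenotype):
    """Sign of the per-feature simple regression slope of M-value on phenotype.

    Returns an array of ``"positive"`` / ``"negative"``; a slope of exactly
    zero counts as positive (deterministic tie rule, measure zero for
    continuous data).
    """
    m_matrix = np.atleast_2d(np.asarray(m_matrix, dtype=float))
    phenotype = np.asarray(phenotype, dtype=float)
    centred = phenotype - phenotype.mean()
    if np.all(centred == 0):
        raise ValueError("constant phenotype: regression direction undefined")
    slope_sign = m_matrix @ centred  # slope numerator; denominator > 0
    return np.where(slope_sign >= 0, "positive", "negative")


def compute_icc(values, replicate_group):
    """One-way ANOVA intraclass correlation ICC(1) across replicate groups.

    ICC = (MSB - MSW) / (MSB + (k0 - 1) MSW) with k0 the balanced group
    size, or for unbalanced designs the standard one-way ANOVA correction
    k0 = (N - sum k_i^2 / N) / (g - 1).  The raw value is reported without
    truncation (it can reach -1); NaN when there is no variance at all.
    """
    values = np.asarray(values, dtype=float)
    groups = pd.Series(np.asarray(replicate_group))
    codes, uniques = pd.factorize(groups)
    g = len(uniques)
    if g < 2:
        raise ValueError("ICC requires >= 2 replicate groups")
    sizes = np.bincount(codes)
    if np.all(sizes < 2):
        raise ValueError("ICC requires at least one group with >= 2 members")
    n_tot = values.size
    grand = values.mean()
    group_means = np.bincount(codes, weights=values) / sizes
    ssb = float(np.sum(sizes * (group_means - grand) ** 2))
    ssw = float(np.sum((values - group_means[codes]) ** 2))
    msb = ssb / (g - 1)
    msw = ssw / (n_tot - g)
    k0 = (n_tot - np.sum(sizes**2) / n_tot) / (g - 1)
    denom = msb + (k0 - 1.0) * msw
    if denom == 0:
        logger.warning("ICC undefined: no variance within or between groups")
        return np.nan
    return (msb - msw) / denom


STATISTICAL_COVARIATES = ("mean", "sd.b", "sd.m", "mad", "dip", "precision")
ANNOTATION_COVARIATES = ("refgene.pos", "cpg.loc", "chr", "dhs", "probe.type")


def build_covariate_table(study: MethylationStudy, phenotype=None) -> list[CovariateColumn]:
    """All applicable covariates for a methylation study.

    Always emits mean, sd.b, sd.m, mad, dip and precision (continuous).
    Adds direction (categorical) when a phenotype is available, icc.b and
    icc.m when technical replicates are present, and the five annotation
    covariates when the study carries an annotation table.
    """
    beta = study.beta
    m_values = beta_to_m(beta)
    if phenotype is None:
        phenotype = study.phenotype
    mean = beta.mean(axis=1)
    sd_b = beta.std(axis=1, ddof=1)
    sd_m = m_values.std(axis=1, ddof=1)
    mad = stats.median_abs_deviation(beta, axis=1, scale="normal")
    dip = np.array([dip_statistic(row) for row in beta])
    precision = compute_precision(mean, sd_b)
    cols = [
        CovariateColumn(mean, "continuous", "mean"),
        CovariateColumn(sd_b, "continuous", "sd.b"),
        CovariateColumn(sd_m, "continuous", "sd.m"),
        CovariateColumn(mad, "continuous", "mad"),
        CovariateColumn(dip, "continuous", "dip"),
        CovariateColumn(precision, "continuous", "precision"),
    ]
    if phenotype is not None and np.ptp(np.asarray(phenotype, dtype=float)) > 0:
        direction = compute_direction(m_values, phenotype)
        try:
            cols.append(CovariateColumn(direction, "categorical", "direction"))
        except ValueError:
            logger.info("direction is constant across features; skipped")
    if study.replicate_group is not None:
        icc_b = np.array([compute_icc(row, study.replicate_group) for row in beta])
        icc_m = np.array([compute_icc(row, study.replicate_group) for row in m_values])
        cols.append(CovariateColumn(icc_b, "continuous", "icc.b"))
        cols.append(CovariateColumn(icc_m, "continuous", "icc.m"))
    if study.annotation is not None:
        ann = study.annotation.table
        for name in ANNOTATION_COVARIATES:
            vals = ann[name].astype(str).to_numpy()
            if len(pd.unique(vals)) >= 2:
                cols.append(CovariateColumn(vals, "categorical", name))
            else:
                logger.info("annotation covariate %s is constant; skipped", name)
    return cols


@dataclass
class CovariateBasis:
    """Design-matrix expansion of a covariate for regression-based FDR.

    Continuous covariates get a natural cubic spline basis with 6 degrees of
    freedom (interior knots at equally spaced quantiles, boundary knots at
    the data range); categorical covariates get treatment indicators with
    the first level as reference.
    """

    matrix: np.ndarray
    names: list[str]
    source: str


def _natural_cubic_spline(x: np.ndarray, df: int) -> np.ndarray:
    """Natural cubic spline basis (without intercept), df columns.

    Standard truncated-power construction: boundary knots at min/max,
    df - 1 interior knots at equally spaced quantiles; the natural
    (linear-beyond-boundary) constraint reduces the cubic basis to
    N_1(x) = x and N_{k+1} = d_k - d_{K-1} for K = df + 1 knots, where
    d_k(x) = [(x - t_k)_+^3 - (x - t_K)_+^3] / (t_K - t_k).
    """
    qs = np.linspace(0, 1, df + 1)
    knots = np.quantile(x, qs)
    knots = np.unique(knots)
    if knots.size < 3:
        raise ValueError("too few distinct values for a spline basis")
    t_last = knots[-1]
    t_penult = knots[-2]

    def d(k):
        num = np.clip(x - knots[k], 0, None) ** 3 - np.clip(x - t_last, 0, None) ** 3
        return num / (t_last - knots[k])

    d_pen = (
        np.clip(x - t_penult, 0, None) ** 3 - np.clip(x - t_last, 0, None) ** 3
    ) / (t_last - t_penult)
    cols = [x] + [d(k) - d_pen for k in range(knots.size - 2)]
    return np.column_stack(cols)


def encode_covariate(col: CovariateColumn, df: int = 6) -> CovariateBasis:
    """Expand a covariate into a regression basis.

    Continuous: natural cubic spline, 6 df by default; the basis degree
    degrades gracefully when there are fewer than df + 1 distinct values.
    Categorical: indicator columns, first level (declared order, else
    lexicographic) dropped as reference.
    """
    if col.kind == "continuous":
        x = np.asarray(col.x, dtype=float)
        finite = x[np.isfinite(x)]
        n_distinct = np.unique(finite).size
        if n_distinct < 2:
            raise ValueError(f"covariate {col.name!r} is constant; uninformative")
        use_df = min(df, n_distinct - 1)
        if use_df < df:
            logger.warning(
                "covariate %s has %d distinct values; spline df reduced to %d",
                col.name,
                n_distinct,
                use_df,
            )
        if use_df == 1:
            mat = x[:, None]
        else:
            mat = _natural_cubic_spline(x, use_df)
        names = [f"{col.name}.ns{i+1}" for i in range(mat.shape[1])]
        return CovariateBasis(mat, names, col.name)
    levels = list(col.levels)
    observed = set(map(str, pd.unique(col.x[~pd.isna(col.x)])))
    levels = [l for l in levels if l in observed]
    if len(levels) < 2:
        raise ValueError(f"covariate {col.name!r} has < 2 observed levels")
    ref, rest = levels[0], levels[1:]
    xs = col.x.astype(str)
    mat = np.column_stack([(xs == l).astype(float) for l in rest])
    names = [f"{col.name}.{l}" for l in rest]
    return CovariateBasis(mat, names, col.name)
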