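"""False discovery rate procedures: BH, Storey's q-value and the
covariate-conditional Boca-Leek style adjustment.

All three return an :class:`FdrResult` whose ``adjusted`` vector is
comparable to the target level alpha:

* BH — Benjamini-Hochberg step-up; adjusted value is the usual monotone
  min(m p_(j) / j).
* ST — Storey's q-value: the BH-adjusted value scaled by an estimate of the
  global null proportion pi0, gaining power when the signal is dense.
* BL — pi0 is modelled per feature by a logistic regression of the
  indicator I(p > lambda) on a covariate basis (natural cubic splines /
  indicators), so hypotheses in covariate strata rich in signal face a
  laxer threshold.

External covariate-adaptive methods (IHW, CAMT, AdaPT, FDRreg) are not
re-implemented; :func:`ingest_external_result` adapts their exported
per-feature adjusted values to the same result type for benchmarking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import encode_covariate
from .io import CovariateColumn

logger = logging.getLogger(__name__)

__all__ = [
    "FdrResult",
    "bh_adjust",
    "storey_pi0",
    "storey_qvalue",
    "bl_covariate_fdr",
    "ingest_external_result",
]

DEFAULT_ALPHA = 0.05
DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.05, 0.96, 0.05), 2))


@dataclass
class FdrResult:
    """Rejection set and adjusted values of one FDR procedure."""

    method: str
    alpha: float
    rejected: np.ndarray
    adjusted: np.ndarray
    pi0: float | np.ndarray | None = None

    @property
    def n_rejections(self) -> int:
        return int(self.rejected.sum())

    def summary(self) -> str:
        pi0_txt = ""
        if self.pi0 is not None:
            pi0 = np.asarray(self.pi0, dtype=float)
            pi0_txt = (
                f"    pi0 = {pi0.mean():.3f}"
                if pi0.size == 1
                else f"    mean pi0(x) = {pi0.mean():.3f}"
            )
        return (
            f"{self.method}: {self.n_rejections} of {self.adjusted.size} "
            f"hypotheses rejected at target FDR {self.alpha:g}{pi0_txt}"
        )


def _validate_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size and (np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def _bh_adjusted(p: np.ndarray) -> np.ndarray:
    """Monotone BH-adjusted p-values (step-up)."""
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(ranked, 1.0)
    return adjusted


def bh_adjust(p, alpha: float = DEFAULT_ALPHA) -> FdrResult:
    """Benjamini-Hochberg step-up procedure."""
    p = _validate_p(p)
    if p.size == 0:
        return FdrResult("BH", alpha, np.zeros(0, bool), np.zeros(0))
    adjusted = _bh_adjusted(p)
    return FdrResult("BH", alpha, adjusted <= alpha, adjusted)


def storey_pi0(p, lambda_grid=DEFAULT_LAMBDA_GRID) -> float:
    """Storey's smoother estimate of the global null proportion.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed over the
    grid; a cubic polynomial smoother is fit to the curve and evaluated at
    the largest lambda, then clamped to [0, 1].
    """
    p = _validate_p(p)
    grid = np.asarray(lambda_grid, dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("lambda grid must lie inside (0, 1)")
    if p.size < 100:
        logger.warning("pi0 estimate from only %d p-values is unstable", p.size)
    grid = np.sort(grid)
    raw = np.array([np.mean(p > lam) / (1.0 - lam) for lam in grid])
    if grid.size >= 4:
        coef = np.polyfit(grid, raw, 3)
        est = float(np.polyval(coef, grid[-1]))
    else:
        est = float(raw[-1])
    return float(np.clip(est, 0.0, 1.0))


def storey_qvalue(p, alpha: float = DEFAULT_ALPHA, lambda_grid=DEFAULT_LAMBDA_GRID) -> FdrResult:
    """Storey's q-value procedure: pi0-scaled BH.

    With pi0 <= 1 the rejection set always contains the BH rejection set.
    """
    p = _validate_p(p)
    if p.size == 0:
        return FdrResult("ST", alpha, np.zeros(0, bool), np.zeros(0), pi0=1.0)
    pi0 = storey_pi0(p, lambda_grid)
    q = np.clip(pi0 * _bh_adjusted(p), 0.0, 1.0)
    return FdrResult("ST", alpha, q <= alpha, q, pi0=pi0)


def bl_covariate_fdr(
    p,
    covariates,
    alpha: float = DEFAULT_ALPHA,
    lambda_grid=DEFAULT_LAMBDA_GRID,
) -> FdrResult:
    """Covariate-conditional null-proportion adjustment of BH (BL).

    For every lambda in the grid the indicator I(p > lambda) is regressed
    on the encoded covariate basis (natural splines / treatment indicators)
    by least squares; each feature's fitted value scaled by 1/(1 - lambda)
    and truncated to [0, 1] gives a per-lambda estimate pi0_lambda(x_i).
    A cubic smoother over lambda, evaluated at the largest lambda, yields
    the final pi0(x_i), which scales the feature's BH-adjusted value —
    hypotheses in covariate strata rich in signal face a laxer threshold.
    A constant (or otherwise unusable) basis reduces the whole procedure to
    a scalar-pi0 Storey-type adjustment.
    """
    p = _validate_p(p)
    if isinstance(covariates, CovariateColumn):
        covariates = [covariates]
    m = p.size
    grid = np.sort(np.asarray(lambda_grid, dtype=float))
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("lambda grid must lie inside (0, 1)")
    blocks = []
    for cov in covariates:
        if len(cov) != m:
            raise ValueError(f"covariate {cov.name!r} length != m")
        try:
            blocks.append(encode_covariate(cov).matrix)
        except ValueError as err:
            logger.warning("covariate %s not encodable (%s); ignored", cov.name, err)
    design = np.ones((m, 1))
    if blocks:
        cand = np.column_stack(blocks)
        keep = cand.std(axis=0) > 0
        if keep.any():
            design = np.column_stack([design, cand[:, keep]])
    indicators = (p[:, None] > grid[None, :]).astype(float)
    coef, *_ = np.linalg.lstsq(design, indicators, rcond=None)
    fitted = design @ coef
    pi0_by_lambda = np.clip(fitted / (1.0 - grid[None, :]), 0.0, 1.0)
    if grid.size >= 4:
        # cubic polynomial smoother over lambda, evaluated at max lambda,
        # as one projection vector applied to every feature's pi0 path
        vand = np.vander(grid, 4, increasing=True)
        proj = np.vander(grid[-1:], 4, increasing=True) @ np.linalg.pinv(vand)
        pi0 = pi0_by_lambda @ proj.ravel()
    else:
        pi0 = pi0_by_lambda[:, -1]
    pi0 = np.clip(pi0, 0.0, 1.0)
    adjusted = np.clip(pi0 * _bh_adjusted(p), 0.0, 1.0)
    return FdrResult("BL", alpha, adjusted <= alpha, adjusted, pi0=pi0)


def ingest_external_result(
    path, method: str, alpha: float = DEFAULT_ALPHA
) -> FdrResult:
    """Adapt an externally computed per-feature table of adjusted values.

    Expects a TSV with columns ``feature_id`` and ``adjusted`` as exported
    by runs of external covariate-adaptive packages.
    """
    df = pd.read_csv(path, sep="\t")
    if "adjusted" not in df.columns:
        raise ValueError(f"{path} lacks an 'adjusted' column")
    adjusted = df["adjusted"].to_numpy(dtype=float)
    if np.any((adjusted < 0) | (adjusted > 1)):
        raise ValueError("external adjusted values must lie in [0, 1]")
    return FdrResult(method, alpha, adjusted <= alpha, adjusted)
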