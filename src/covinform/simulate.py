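"""Generative frameworks for method evaluation.

Two designs are provided:

* a p-value-level simulator for studying the omnibus informativeness test:
  the null probability of hypothesis i follows a logistic model
  pi0_i = expit(eta0 + c x_i) in a (standardized) covariate, z-scores are
  N(0,1) under the null and N(2.68, 1) under the alternative, and
  p_i = 1 - Phi(z_i);

* a methylation-level simulator for studying FDR procedures: a synthetic
  two-group Beta-value template with autocorrelated features stands in for
  a resampled real control group, differential features (drawn from the
  same logistic pi0 model) receive an M-value shift f in one group, and
  per-feature p-values come from the two-group linear regression on
  M-values.  With ``correlated_signals`` the covariate follows an AR(1)
  process along the genome so that differential CpGs cluster.

Intercepts eta0 of 3.5 / 2.5 / 1.5 give expected signal fractions of about
3% / 8% / 18% when the covariate carries no information (c = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit

from .covariates import beta_to_m, m_to_beta
from .io import CovariateColumn, MethylationStudy, PValueStudy

__all__ = [
    "PvalueSimConfig",
    "MethylSimConfig",
    "SimulatedStudy",
    "pi0_from_covariate",
    "simulate_pvalue_study",
    "generate_synthetic_template",
    "inject_signals_and_test",
]


@dataclass(frozen=True)
class PvalueSimConfig:
    """Settings of the p-value-level simulator."""

    m: int = 10_000
    covariate_family: str = "continuous"   # or "categorical"
    eta0: float = 2.5                      # 3.5 sparse / 2.5 medium / 1.5 dense
    c: float = 0.0                         # dependence strength
    monotone: bool = True                  # False: covariate enters squared
    mu_alt: float = 2.68                   # alternative z-score mean
    seed: int | None = None

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be positive")
        if self.covariate_family not in ("continuous", "categorical"):
            raise ValueError(f"unknown covariate family {self.covariate_family!r}")
        if self.c < 0:
            raise ValueError("dependence coefficient c must be >= 0")


@dataclass(frozen=True)
class MethylSimConfig:
    """Settings of the methylation-level simulator."""

    m: int = 2_000
    n_per_group: int = 80
    effect_f: float = 0.33                 # M-value shift: 0.27 / 0.33 / 0.45
    eta0: float = 2.5
    c: float = 0.0                         # 0 / 1 / 1.5 in the reference grid
    correlated_signals: bool = False
    signal_ar: float = 0.75                # AR coefficient of the covariate
    template_rho: float = 0.75             # AR(1) correlation of the template
    seed: int | None = None

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        if self.effect_f < 0:
            raise ValueError("effect size must be >= 0")
        if not 0 <= self.template_rho < 1:
            raise ValueError("template_rho must lie in [0, 1)")


@dataclass
class SimulatedStudy:
    """Simulated p-values with covariate and ground truth."""

    p: np.ndarray
    x: CovariateColumn
    truth: np.ndarray
    pi0_vector: np.ndarray
    config: object = None

    def as_pvalue_study(self) -> PValueStudy:
        return PValueStudy(p=self.p, truth=self.truth)


def pi0_from_covariate(eta0: float, c: float, x) -> np.ndarray:
    """Per-hypothesis null probability from the logistic model
    pi0_i = exp(eta0 + c x_i) / (1 + exp(eta0 + c x_i))."""
    return expit(eta0 + c * np.asarray(x, dtype=float))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


def simulate_pvalue_study(config: PvalueSimConfig) -> SimulatedStudy:
    """Draw one study from the p-value-level design.

    The covariate is standard normal (continuous) or uniform on {1..5}
    (categorical); it is standardized before entering the pi0 model, and
    enters squared when ``monotone`` is False (a non-monotone dependence
    invisible to rank correlation).  The covariate handed to the analyst is
    the raw draw, not the transformed one.
    """
    rng = np.random.default_rng(config.seed)
    if config.covariate_family == "categorical":
        x_raw = rng.integers(1, 6, size=config.m).astype(float)
        kind = "categorical"
    else:
        x_raw = rng.standard_normal(config.m)
        kind = "continuous"
    x_model = _standardize(x_raw)
    if not config.monotone:
        x_model = x_model**2
    pi0 = pi0_from_covariate(config.eta0, config.c, x_model)
    truth = (rng.random(config.m) > pi0).astype(int)
    z = rng.standard_normal(config.m) + config.mu_alt * truth
    p = stats.norm.sf(z)
    x_col = CovariateColumn(
        x_raw if kind == "continuous" else x_raw.astype(int), kind=kind, name="x"
    )
    return SimulatedStudy(p=p, x=x_col, truth=truth, pi0_vector=pi0, config=config)


def _ar1(rng, shape, rho: float) -> np.ndarray:
    """AR(1) noise along the last axis with unit marginal variance."""
    eps = rng.standard_normal(shape)
    if rho == 0:
        return eps
    out = np.empty_like(eps)
    out[..., 0] = eps[..., 0]
    scale = np.sqrt(1.0 - rho**2)
    for i in range(1, shape[-1]):
        out[..., i] = rho * out[..., i - 1] + scale * eps[..., i]
    return out


def generate_synthetic_template(
    m: int = 2_000,
    n: int = 160,
    template_rho: float = 0.75,
    seed: int | None = None,
    noise_scale: tuple = (0.4, 0.8),
) -> MethylationStudy:
    """Synthetic methylation template with array-like correlation structure.

    Baseline per-feature M-values follow the bimodal methylation landscape
    (hypo- and hypermethylated modes around M = -/+ 2.5 plus a small
    intermediate fraction); sample-level noise is AR(1) along the feature
    order with coefficient ``template_rho``, so neighbouring features are
    correlated across samples as neighbouring CpGs are on arrays.  Features
    carry synthetic chr13 positions in feature order.
    """
    rng = np.random.default_rng(seed)
    comp = rng.choice(3, size=m, p=(0.45, 0.45, 0.10))
    mu = np.where(
        comp == 0,
        rng.normal(-2.5, 0.8, size=m),
        np.where(comp == 1, rng.normal(2.5, 0.8, size=m), rng.normal(0.0, 1.0, size=m)),
    )
    sigma = rng.uniform(*noise_scale, size=m)
    noise = _ar1(rng, (n, m), template_rho).T * sigma[:, None]
    m_values = mu[:, None] + noise
    beta = m_to_beta(m_values)
    feature_ids = np.array([f"cg{i:08d}" for i in range(m)])
    return MethylationStudy(
        beta=beta,
        feature_ids=feature_ids,
        sample_ids=np.array([f"s{j:04d}" for j in range(n)]),
        phenotype=np.zeros(n),
    )


def inject_signals_and_test(
    template: MethylationStudy, config: MethylSimConfig
) -> SimulatedStudy:
    """Two-group differential-methylation simulation on a template.

    Samples are split into two groups of ``n_per_group``; differential
    status is drawn from the logistic pi0 model in the simulated covariate
    (independent normal, or AR(1) along the genome for clustered signals);
    differential features get the M-value shift ``effect_f`` added in group
    two; per-feature p-values come from the two-group linear regression
    (equal-variance t test) on M-values.
    """
    rng = np.random.default_rng(config.seed)
    n_needed = 2 * config.n_per_group
    if template.n_samples < n_needed:
        raise ValueError(
            f"template has {template.n_samples} samples; {n_needed} needed"
        )
    m = template.n_features
    cols = rng.permutation(template.n_samples)[:n_needed]
    g1 = cols[: config.n_per_group]
    g2 = cols[config.n_per_group :]
    if config.correlated_signals:
        # AR(1) with unit innovation variance, as in arima.sim(ar = rho)
        x = _ar1(rng, (m,), config.signal_ar) / np.sqrt(1 - config.signal_ar**2)
    else:
        x = rng.standard_normal(m)
    pi0 = pi0_from_covariate(config.eta0, config.c, x)
    h = (rng.random(m) > pi0).astype(int)
    m1 = beta_to_m(template.beta[:, g1])
    m2 = beta_to_m(template.beta[:, g2])
    m2 = m2 + config.effect_f * h[:, None]
    t_res = stats.ttest_ind(m1, m2, axis=1)
    truth = h if config.effect_f > 0 else np.zeros_like(h)
    return SimulatedStudy(
        p=np.asarray(t_res.pvalue),
        x=CovariateColumn(x, "continuous", "x"),
        truth=truth,
        pi0_vector=pi0,
        config=config,
    )
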