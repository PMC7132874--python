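"""Evaluation harness for the omnibus test and the FDR procedures.

Reproduces the two simulation experiments at configurable scale: rejection
rates of the omnibus test versus naive rank tests over a grid of signal
densities and dependence strengths, and average false discovery proportion /
true positive rate of BH, ST and BL on the methylation-level simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .fdr import bh_adjust, bl_covariate_fdr, storey_qvalue
from .omnibus import (
    OmnibusConfig,
    OmnibusTest,
    kruskal_pvalue,
    spearman_pvalue,
)
from .simulate import (
    MethylSimConfig,
    PvalueSimConfig,
    generate_synthetic_template,
    inject_signals_and_test,
    simulate_pvalue_study,
)

__all__ = [
    "BenchmarkResult",
    "fdp_tpr",
    "run_fdr_benchmark",
    "run_omnibus_benchmark",
    "rank_covariates",
]


@dataclass
class BenchmarkResult:
    """Per-replicate metrics plus per-setting aggregates."""

    per_rep: pd.DataFrame
    aggregate: pd.DataFrame
    master_seed: int | None = None

    def summary(self) -> str:
        return self.aggregate.round(4).to_string()


def fdp_tpr(rejected, truth) -> tuple[float, float]:
    """False discovery proportion and true positive rate of a rejection set.

    FDP counts 0 when nothing is rejected; TPR counts 0 when there are no
    true signals.
    """
    rejected = np.asarray(rejected, dtype=bool)
    truth = np.asarray(truth).astype(bool)
    if rejected.size != truth.size:
        raise ValueError("rejected and truth differ in length")
    n_rej = rejected.sum()
    n_sig = truth.sum()
    fdp = float((rejected & ~truth).sum() / max(n_rej, 1))
    tpr = float((rejected & truth).sum() / max(n_sig, 1))
    return fdp, tpr


_FDR_METHODS = {
    "BH": lambda p, x, a: bh_adjust(p, a),
    "ST": lambda p, x, a: storey_qvalue(p, a),
    "BL": lambda p, x, a: bl_covariate_fdr(p, x, a),
}


def run_fdr_benchmark(
    settings,
    methods=("BH", "ST", "BL"),
    reps: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    template_m: int | None = None,
) -> BenchmarkResult:
    """FDP/TPR of FDR procedures over a grid of methylation simulations.

    ``settings`` is an iterable of :class:`MethylSimConfig`; each is run
    ``reps`` times on a fresh synthetic template, with per-replicate seeds
    derived as ``seed + replicate`` so cells can be re-run independently.
    """
    unknown = set(methods) - set(_FDR_METHODS)
    if unknown:
        raise ValueError(f"unknown FDR methods: {sorted(unknown)}")
    rows = []
    for cfg in settings:
        if not isinstance(cfg, MethylSimConfig):
            raise ValueError(f"settings must be MethylSimConfig, got {type(cfg)}")
        m = template_m or cfg.m
        for rep in range(reps):
            rep_seed = seed + rep
            template = generate_synthetic_template(
                m=m,
                n=2 * cfg.n_per_group,
                template_rho=cfg.template_rho,
                seed=rep_seed,
            )
            sim = inject_signals_and_test(template, replace(cfg, m=m, seed=rep_seed))
            for name in methods:
                res = _FDR_METHODS[name](sim.p, sim.x, alpha)
                fdp, tpr = fdp_tpr(res.rejected, sim.truth)
                rows.append(
                    {
                        "eta0": cfg.eta0,
                        "effect_f": cfg.effect_f,
                        "c": cfg.c,
                        "correlated": cfg.correlated_signals,
                        "rep": rep,
                        "method": name,
                        "FDP": fdp,
                        "TPR": tpr,
                        "n_rejections": res.n_rejections,
                    }
                )
    per_rep = pd.DataFrame(rows)
    keys = ["eta0", "effect_f", "c", "correlated", "method"]
    agg = per_rep.groupby(keys, sort=False).agg(
        FDP_mean=("FDP", "mean"),
        FDP_se=("FDP", lambda v: v.std(ddof=1) / np.sqrt(len(v))),
        TPR_mean=("TPR", "mean"),
        TPR_se=("TPR", lambda v: v.std(ddof=1) / np.sqrt(len(v))),
    )
    return BenchmarkResult(per_rep, agg.reset_index(), master_seed=seed)


def run_omnibus_benchmark(
    settings,
    reps: int = 100,
    n_permutations: int = 199,
    seed: int = 0,
    level: float = 0.05,
    naive: bool = True,
) -> BenchmarkResult:
    """Rejection rate of the omnibus and naive tests over simulated studies.

    ``settings`` is an iterable of :class:`PvalueSimConfig`.  The naive
    baseline is Spearman's rank test for continuous covariates and the
    Kruskal-Wallis test for categorical ones.
    """
    rows = []
    for cfg in settings:
        if not isinstance(cfg, PvalueSimConfig):
            raise ValueError(f"settings must be PvalueSimConfig, got {type(cfg)}")
        for rep in range(reps):
            rep_seed = seed + rep
            sim = simulate_pvalue_study(replace(cfg, seed=rep_seed))
            test = OmnibusTest(
                sim.p,
                sim.x,
                config=OmnibusConfig(n_permutations=n_permutations, seed=rep_seed),
            )
            fit = test.fit()
            row = {
                "family": cfg.covariate_family,
                "monotone": cfg.monotone,
                "eta0": cfg.eta0,
                "c": cfg.c,
                "rep": rep,
                "omnibus_p": fit.pval,
                "omnibus_reject": fit.pval <= level,
            }
            if naive:
                if cfg.covariate_family == "continuous":
                    naive_p = spearman_pvalue(sim.p, sim.x.x)
                else:
                    naive_p = kruskal_pvalue(sim.p, sim.x.x)
                row["naive_p"] = naive_p
                row["naive_reject"] = naive_p <= level
            rows.append(row)
    per_rep = pd.DataFrame(rows)
    keys = ["family", "monotone", "eta0", "c"]
    cols = {"omnibus_rate": ("omnibus_reject", "mean")}
    if naive:
        cols["naive_rate"] = ("naive_reject", "mean")
    agg = per_rep.groupby(keys, sort=False).agg(**cols).reset_index()
    n = per_rep.groupby(keys, sort=False).size().to_numpy()
    agg["omnibus_se"] = np.sqrt(agg["omnibus_rate"] * (1 - agg["omnibus_rate"]) / n)
    if naive:
        agg["naive_se"] = np.sqrt(agg["naive_rate"] * (1 - agg["naive_rate"]) / n)
    return BenchmarkResult(per_rep, agg, master_seed=seed)


def rank_covariates(counts: pd.DataFrame) -> pd.DataFrame:
    """Rank covariates by detection count within each dataset.

    ``counts`` is datasets x covariates.  Higher counts get higher ranks;
    ties receive the mean rank.  Returns the rank table with the same shape.
    """
    counts = pd.DataFrame(counts)
    if counts.empty:
        raise ValueError("empty counts table")
    ranks = counts.apply(
        lambda row: stats.rankdata(row.to_numpy(), method="average"), axis=1,
        result_type="expand",
    )
    ranks.columns = counts.columns
    return ranks
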