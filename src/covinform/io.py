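"""Domain containers and tabular readers/writers.

The package moves between three tabular shapes: a feature-by-sample matrix
of methylation Beta-values with a sample phenotype table, an Infinium-450K
style probe annotation table, and a per-feature table of association
p-values with one or more candidate covariates.  Everything is plain TSV/CSV
with a header row; pandas does the parsing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Beta-values are clipped into [EPS, 1 - EPS] so the M-value transform
#: (a logit) stays finite; rounded public data routinely contains 0 and 1.
EPS = 1e-6

REFGENE_LEVELS = ("5'UTR", "TSS1500", "TSS200", "1stExon", "Body", "3'-UTR", "Non_gene")
CPG_LOC_LEVELS = ("OpenSea", "N_Shelf", "N_Shore", "Island", "S_Shore", "S_Shelf")
ANNOTATION_COLUMNS = ("chr", "pos", "refgene.pos", "cpg.loc", "dhs", "probe.type")


class AlignmentError(ValueError):
    """Row/column dimensions of related tables do not line up."""


@dataclass
class AnnotationTable:
    """Per-probe annotation in the 450K manifest dialect.

    ``table`` has columns chr, pos, refgene.pos, cpg.loc, dhs, probe.type
    indexed by probe id.  Multi-valued gene-region entries (semicolon
    separated, as in the manifest) are collapsed to the first listed;
    missing gene annotation becomes ``Non_gene``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation table missing columns: {missing}")
        t = self.table.copy()
        region = t["refgene.pos"].astype("string").str.split(";").str[0]
        region = region.fillna("Non_gene").replace("", "Non_gene")
        t["refgene.pos"] = region
        bad = set(t["refgene.pos"].unique()) - set(REFGENE_LEVELS)
        if bad:
            raise ValueError(f"unknown gene-region categories: {sorted(bad)}")
        bad = set(t["cpg.loc"].dropna().unique()) - set(CPG_LOC_LEVELS)
        if bad:
            raise ValueError(f"unknown CpG-island categories: {sorted(bad)}")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class MethylationStudy:
    """A Beta-value matrix with per-sample phenotype.

    beta is features x samples, strictly inside (0, 1) after clipping.
    """

    beta: np.ndarray
    feature_ids: np.ndarray
    sample_ids: np.ndarray
    phenotype: np.ndarray
    replicate_group: np.ndarray | None = None
    annotation: AnnotationTable | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.feature_ids = np.asarray(self.feature_ids)
        self.sample_ids = np.asarray(self.sample_ids)
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        m, n = self.beta.shape
        if self.feature_ids.size != m:
            raise AlignmentError(
                f"{self.feature_ids.size} feature ids for {m} matrix rows"
            )
        if self.sample_ids.size != n or self.phenotype.size != n:
            raise AlignmentError(
                f"beta has {n} samples but {self.sample_ids.size} sample ids "
                f"and {self.phenotype.size} phenotype values"
            )
        if pd.Index(self.feature_ids).has_duplicates:
            raise ValueError("feature ids must be unique")
        if self.replicate_group is not None:
            self.replicate_group = np.asarray(self.replicate_group)
            if self.replicate_group.size != n:
                raise AlignmentError("replicate_group length != sample count")
        if self.annotation is not None and len(self.annotation) != m:
            raise AlignmentError("annotation rows != feature count")
        n_clip = int(np.sum((self.beta <= 0) | (self.beta >= 1)))
        if n_clip:
            logger.warning(
                "clipped %d Beta-values outside (0,1) to [%g, %g]", n_clip, EPS, 1 - EPS
            )
        self.beta = np.clip(self.beta, EPS, 1 - EPS)

    @property
    def n_features(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]


@dataclass
class PValueStudy:
    """Per-feature association p-values, optionally with ground truth.

    ``truth`` marks genuinely differential features (1) in simulations.
    ``position_order`` carries a genomic ordering of the features for the
    autocorrelation-based down-sampler.
    """

    p: np.ndarray
    feature_ids: np.ndarray | None = None
    position_order: np.ndarray | None = None
    truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 1:
            raise ValueError("p must be one-dimensional")
        if np.any((self.p < 0) | (self.p > 1) | ~np.isfinite(self.p)):
            bad = np.flatnonzero(~((self.p >= 0) & (self.p <= 1)))
            raise ValueError(f"p-values outside [0, 1] at rows {bad[:10].tolist()}")
        for name in ("feature_ids", "position_order", "truth"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.size != self.m:
                    raise AlignmentError(f"{name} length {v.size} != m = {self.m}")
                setattr(self, name, v)

    @property
    def m(self) -> int:
        return self.p.size


@dataclass
class CovariateColumn:
    """One per-feature covariate with its declared measurement kind."""

    x: np.ndarray
    kind: str
    name: str = "x"
    levels: tuple = field(default=None)

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "continuous":
            self.x = np.asarray(self.x, dtype=float)
        else:
            self.x = np.asarray(self.x)
            observed = pd.unique(self.x[~pd.isna(self.x)])
            if self.levels is None:
                self.levels = tuple(sorted(map(str, observed)))
            if len([l for l in self.levels if l in set(map(str, observed))]) < 2:
                raise ValueError(
                    f"categorical covariate {self.name!r} needs >= 2 observed levels"
                )

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of missing entries (excluded pairwise at test time)."""
        if self.kind == "continuous":
            return ~np.isfinite(self.x)
        return pd.isna(self.x) | (self.x.astype(str) == "")

    def __len__(self) -> int:
        return self.x.size


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    try:
        return pd.read_csv(path, sep=sep, float_precision="round_trip")
    except ValueError as err:  # re-raise with file context
        raise ValueError(f"could not parse {path}: {err}") from err


def load_methylation_study(
    beta_path,
    phenotype_path,
    annotation_path=None,
    *,
    phenotype_column: str = "phenotype",
    replicate_column: str | None = None,
) -> MethylationStudy:
    """Read a Beta matrix (first column: probe id), phenotype table and
    optional annotation table into an aligned :class:`MethylationStudy`."""
    beta_df = _read_table(beta_path)
    feature_ids = beta_df.iloc[:, 0].to_numpy()
    beta = beta_df.iloc[:, 1:]
    non_numeric = beta.columns[
        ~beta.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())
    ]
    if len(non_numeric):
        raise ValueError(
            f"non-numeric Beta entries in sample columns {list(non_numeric)}"
        )
    pheno_df = _read_table(phenotype_path)
    if phenotype_column not in pheno_df.columns:
        raise ValueError(f"phenotype table lacks column {phenotype_column!r}")
    if len(pheno_df) != beta.shape[1]:
        raise AlignmentError(
            f"phenotype table has {len(pheno_df)} rows for {beta.shape[1]} samples"
        )
    replicate = (
        pheno_df[replicate_column].to_numpy() if replicate_column else None
    )
    annotation = None
    if annotation_path is not None:
        ann = _read_table(annotation_path)
        if "probe.id" in ann.columns:
            ann = ann.set_index("probe.id").reindex(feature_ids).reset_index()
        annotation = AnnotationTable(ann)
    return MethylationStudy(
        beta=beta.to_numpy(dtype=float),
        feature_ids=feature_ids,
        sample_ids=beta.columns.to_numpy(),
        phenotype=pheno_df[phenotype_column].to_numpy(dtype=float),
        replicate_group=replicate,
        annotation=annotation,
    )


def load_pvalue_covariate_table(
    path,
    p_column: str = "p",
    covariate_columns: tuple = (),
    kinds: tuple = (),
    feature_column: str | None = None,
) -> tuple[PValueStudy, list[CovariateColumn]]:
    """Read a per-feature table of p-values plus covariate columns.

    Rows with a missing p-value are dropped (and counted in the log); rows
    with a missing covariate value are kept and flagged per covariate.
    """
    if len(covariate_columns) != len(kinds):
        raise ValueError("covariate_columns and kinds differ in length")
    bad_kinds = set(kinds) - {"continuous", "categorical"}
    if bad_kinds:
        raise ValueError(f"unknown covariate kind labels: {sorted(bad_kinds)}")
    df = _read_table(path)
    for col in (p_column, *covariate_columns):
        if col not in df.columns:
            raise ValueError(f"table {path} lacks column {col!r}")
    n_missing_p = int(df[p_column].isna().sum())
    if n_missing_p:
        logger.warning("dropped %d rows with missing p-values", n_missing_p)
        df = df[df[p_column].notna()]
    study = PValueStudy(
        p=df[p_column].to_numpy(dtype=float),
        feature_ids=df[feature_column].to_numpy() if feature_column else None,
    )
    covariates = [
        CovariateColumn(x=df[col].to_numpy(), kind=kind, name=col)
        for col, kind in zip(covariate_columns, kinds)
    ]
    return study, covariates


def write_pvalue_covariate_table(path, study: PValueStudy, covariates=()) -> None:
    """Write p-values and covariates as TSV with deterministic column order."""
    data = {}
    if study.feature_ids is not None:
        data["feature_id"] = study.feature_ids
    data["p"] = study.p
    for cov in covariates:
        data[cov.name] = cov.x
    if study.truth is not None:
        data["truth"] = study.truth
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
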