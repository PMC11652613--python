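"""Multiregion cohort data model and delimited-file I/O.

A :class:`MultiregionCohort` bundles a gene x sample expression matrix
(log-scale values), per-sample metadata mapping each sample to a patient,
a region within that patient and a tissue label, and an optional patient
survival table.  Every pipeline stage consumes this one container.

File formats are plain delimited text (tab for ``.tsv``, comma for
``.csv``; the delimiter is chosen from the extension, never sniffed):

* expression — gene x sample matrix, first column gene id, header row of
  sample ids;
* metadata   — columns ``sample_id, patient_id, region_id, tissue``;
* survival   — columns ``patient_id, time, event`` with ``event`` in {0,1};
* signature  — two columns ``gene, coefficient`` (header optional).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "MultiregionCohort",
    "GeneSignature",
    "load_cohort",
    "write_cohort",
    "load_signature",
    "write_signature",
    "subset_tumor",
    "collapse_probes",
]

TISSUE_TUMOR = "tumor"
TISSUE_NORMAL = "normal"


class CohortValidationError(ValueError):
    """Raised when a cohort or signature violates its structural invariants."""


@dataclass(frozen=True)
class SampleMeta:
    """One physical sample: a region of a patient's tumor or normal tissue."""

    sample_id: str
    patient_id: str
    region_id: str
    tissue: str

    def __post_init__(self) -> None:
        if self.tissue not in (TISSUE_TUMOR, TISSUE_NORMAL):
            raise CohortValidationError(
                f"sample {self.sample_id!r}: tissue must be "
                f"'{TISSUE_TUMOR}' or '{TISSUE_NORMAL}', got {self.tissue!r}"
            )


@dataclass
class MultiregionCohort:
    """Expression matrix + sample map + optional patient survival.

    Parameters
    ----------
    expression : pandas.DataFrame
        Gene x sample matrix of log-scale expression values.  Columns must
        equal the sample ids of ``samples`` in order.
    samples : list of SampleMeta
        One entry per expression column, same order.
    survival : pandas.DataFrame, optional
        Indexed by patient id with columns ``time`` (days, > 0) and
        ``event`` (1 = event observed, 0 = censored).
    """

    expression: pd.DataFrame
    samples: list[SampleMeta]
    survival: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate sample ids: {dup}")
        if list(self.expression.columns) != ids:
            extra = [c for c in self.expression.columns if c not in set(ids)]
            if extra:
                raise CohortValidationError(
                    f"samples in matrix but not metadata: {extra}"
                )
            missing = [i for i in ids if i not in set(self.expression.columns)]
            if missing:
                raise CohortValidationError(
                    f"samples in metadata but not matrix: {missing}"
                )
            # same set, wrong order: reorder matrix to metadata order
            self.expression = self.expression[ids]
        pr = [(s.patient_id, s.region_id) for s in self.samples]
        if len(set(pr)) != len(pr):
            dup = sorted({p for p in pr if pr.count(p) > 1})
            raise CohortValidationError(
                f"duplicate (patient_id, region_id) pairs: {dup}"
            )
        if self.expression.index.isnull().any() or (
            self.expression.index.astype(str) == ""
        ).any():
            raise CohortValidationError("expression matrix has missing gene ids")
        if not self.expression.index.is_unique:
            dup = self.expression.index[self.expression.index.duplicated()]
            raise CohortValidationError(
                f"duplicate gene ids in expression matrix: {sorted(set(dup))[:5]}"
            )
        vals = self.expression.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            bad = np.argwhere(
                ~np.vectorize(lambda v: isinstance(v, (int, float, np.number)))(vals)
            )
            g, s = bad[0]
            raise CohortValidationError(
                f"non-numeric expression value at gene "
                f"{self.expression.index[g]!r}, sample {self.expression.columns[s]!r}"
            )
        if self.survival is not None:
            surv = self.survival
            for col in ("time", "event"):
                if col not in surv.columns:
                    raise CohortValidationError(f"survival table lacks column {col!r}")
            if (surv["time"] <= 0).any():
                bad = surv.index[surv["time"] <= 0].tolist()
                raise CohortValidationError(f"non-positive survival times for {bad}")
            if not surv["event"].isin([0, 1]).all():
                raise CohortValidationError("survival event must be 0 or 1")
            known = {s.patient_id for s in self.samples}
            orphans = [p for p in surv.index if p not in known]
            if orphans:
                raise CohortValidationError(
                    f"survival patients absent from samples: {orphans}"
                )

    # -- convenience accessors ------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def patient_ids(self) -> list[str]:
        """Unique patient ids, in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.patient_id, None)
        return list(seen)

    @property
    def genes(self) -> pd.Index:
        return self.expression.index

    def patient_of(self) -> pd.Series:
        """sample_id -> patient_id, aligned with the expression columns."""
        return pd.Series(
            {s.sample_id: s.patient_id for s in self.samples},
            name="patient_id",
        ).reindex(self.expression.columns)

    def regions_by_patient(self) -> dict[str, list[str]]:
        """patient_id -> list of that patient's sample ids (metadata order)."""
        out: dict[str, list[str]] = {}
        for s in self.samples:
            out.setdefault(s.patient_id, []).append(s.sample_id)
        return out

    def patient_mean_expression(self) -> pd.DataFrame:
        """Gene x patient matrix averaging each patient's regions."""
        return self.expression.T.groupby(self.patient_of()).mean().T

    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class GeneSignature:
    """A named linear risk model: ordered (gene, coefficient) terms."""

    name: str
    terms: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.terms) < 1:
            raise CohortValidationError(f"signature {self.name!r} has no terms")
        genes = [g for g, _ in self.terms]
        if len(set(genes)) != len(genes):
            dup = sorted({g for g in genes if genes.count(g) > 1})
            raise CohortValidationError(
                f"signature {self.name!r}: duplicate genes {dup}"
            )

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.terms]

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(dict(self.terms), name=self.name, dtype=float)

    def __len__(self) -> int:
        return len(self.terms)


# ----------------------------------------------------------------------
# I/O


def _sep_for(path: str | os.PathLike) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def load_cohort(
    expr_path: str | os.PathLike,
    meta_path: str | os.PathLike,
    survival_path: str | os.PathLike | None = None,
    log1p: bool = False,
) -> MultiregionCohort:
    """Read a cohort from delimited files.

    ``log1p=True`` applies log2(x + 1) on load, for linear-scale inputs
    such as TPM; expression is otherwise assumed already log-transformed.
    Sample order follows the metadata file.
    """
    expr = pd.read_csv(expr_path, sep=_sep_for(expr_path), index_col=0)
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)
    for col in expr.columns:
        if not np.issubdtype(expr[col].dtype, np.number):
            coerced = pd.to_numeric(expr[col], errors="coerce")
            bad = expr.index[coerced.isna() & expr[col].notna()]
            raise CohortValidationError(
                f"non-numeric expression value at gene {bad[0]!r}, sample {col!r}"
            )
    if log1p:
        expr = np.log2(expr + 1.0)

    meta = pd.read_csv(meta_path, sep=_sep_for(meta_path), dtype=str)
    required = {"sample_id", "patient_id", "region_id", "tissue"}
    missing = required - set(meta.columns)
    if missing:
        raise CohortValidationError(f"metadata lacks columns: {sorted(missing)}")
    samples = [
        SampleMeta(r.sample_id, r.patient_id, r.region_id, r.tissue)
        for r in meta.itertuples()
    ]

    present = set(expr.columns)
    absent = [s.sample_id for s in samples if s.sample_id not in present]
    if absent:
        raise CohortValidationError(
            f"samples in metadata but not in expression matrix: {absent}"
        )
    extra = [c for c in expr.columns if c not in {s.sample_id for s in samples}]
    if extra:
        raise CohortValidationError(f"samples in matrix but not metadata: {extra}")
    expr = expr[[s.sample_id for s in samples]]

    survival = None
    if survival_path is not None:
        surv = pd.read_csv(survival_path, sep=_sep_for(survival_path))
        for col in ("patient_id", "time", "event"):
            if col not in surv.columns:
                raise CohortValidationError(f"survival table lacks column {col!r}")
        surv["patient_id"] = surv["patient_id"].astype(str)
        survival = surv.set_index("patient_id")[["time", "event"]].astype(float)
        survival["event"] = survival["event"].astype(int)

    return MultiregionCohort(expression=expr, samples=samples, survival=survival)


def write_cohort(
    cohort: MultiregionCohort,
    expr_path: str | os.PathLike,
    meta_path: str | os.PathLike,
    survival_path: str | os.PathLike | None = None,
    float_format: str | None = None,
) -> None:
    """Write a cohort back to delimited files (lossless round-trip)."""
    sep = _sep_for(expr_path)
    expr = cohort.expression.copy()
    expr.index.name = "gene"
    expr.to_csv(expr_path, sep=sep, float_format=float_format)
    meta = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "patient_id": s.patient_id,
                "region_id": s.region_id,
                "tissue": s.tissue,
            }
            for s in cohort.samples
        ]
    )
    meta.to_csv(meta_path, sep=_sep_for(meta_path), index=False)
    if survival_path is not None and cohort.survival is not None:
        surv = cohort.survival.reset_index()
        surv.columns = ["patient_id", "time", "event"]
        surv.to_csv(survival_path, sep=_sep_for(survival_path), index=False)


def load_signature(path: str | os.PathLike, name: str | None = None) -> GeneSignature:
    """Read a two-column (gene, coefficient) signature file; order preserved."""
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise CohortValidationError(
            f"signature file {path} needs two columns (gene, coefficient)"
        )
    df = df.iloc[:, :2]
    df.columns = ["gene", "coefficient"]
    # tolerate an optional header row
    first = df.iloc[0]
    try:
        float(first["coefficient"])
    except (TypeError, ValueError):
        df = df.iloc[1:]
        if df.empty:
            raise CohortValidationError(f"signature file {path} has no terms")
    coefs = pd.to_numeric(df["coefficient"], errors="coerce")
    if coefs.isna().any():
        bad = df.loc[coefs.isna(), "gene"].tolist()
        raise CohortValidationError(
            f"non-numeric coefficient for genes {bad} in {path}"
        )
    sig_name = name or os.path.splitext(os.path.basename(str(path)))[0]
    return GeneSignature(
        name=sig_name,
        terms=list(zip(df["gene"].astype(str), coefs.astype(float))),
    )


def write_signature(signature: GeneSignature, path: str | os.PathLike) -> None:
    sep = _sep_for(path)
    with open(path, "w") as fh:
        for gene, coef in signature.terms:
            fh.write(f"{gene}{sep}{float(coef)!r}\n")


# ----------------------------------------------------------------------
# transformations


def subset_tumor(cohort: MultiregionCohort) -> MultiregionCohort:
    """Keep tumor-tissue samples only; heterogeneity is a tumor property.

    Idempotent.  Raises if no tumor sample remains.
    """
    kept = [s for s in cohort.samples if s.tissue == TISSUE_TUMOR]
    if not kept:
        raise CohortValidationError("cohort has no tumor samples")
    expr = cohort.expression[[s.sample_id for s in kept]]
    surv = None
    if cohort.survival is not None:
        patients = {s.patient_id for s in kept}
        surv = cohort.survival.loc[[p for p in cohort.survival.index if p in patients]]
    return MultiregionCohort(expression=expr, samples=kept, survival=surv)


def collapse_probes(
    expression: pd.DataFrame, probe_to_gene: pd.Series
) -> pd.DataFrame:
    """Map probe rows to gene symbols, keeping the probe with the highest
    mean expression when several probes hit one gene.

    ``probe_to_gene`` maps probe id -> gene symbol; probes without a
    mapping are dropped.
    """
    mapped = expression.loc[expression.index.intersection(probe_to_gene.index)]
    genes = probe_to_gene.reindex(mapped.index)
    means = mapped.mean(axis=1)
    order = means.sort_values(ascending=False).index
    best: dict[str, str] = {}
    for probe in order:
        best.setdefault(str(genes[probe]), probe)
    out = mapped.loc[list(best.values())]
    out.index = pd.Index(list(best.keys()), name="gene")
    return out.sort_index()
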