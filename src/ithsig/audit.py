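"""Linear risk scoring and the multiregion sampling-bias audit.

A signature's risk score for a sample is sum_i coefficient_i x
expression_i over the signature genes present in the matrix.  Samples are
stratified at the cohort-median score (high requires score strictly above
the cutoff).  On a multiregion cohort, each tumor region is scored and
classified; a patient whose regions all fall below the cutoff is
"concordant low risk", all above "concordant high risk", and a mixture is
"discordant".  A signature is flagged as exhibiting substantial sampling
bias on a cohort when more than half of its patients are discordant.

Two dispersion statistics complete the audit: the per-patient SD of
region scores (how much the score depends on which region was sampled)
and the cohort-wide score variance (how much the score discriminates
between samples at all).  A sampling-robust signature has low per-patient
dispersion but high cohort variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import GeneSignature, MultiregionCohort

__all__ = [
    "RiskProfile",
    "ConcordanceSummary",
    "risk_score",
    "stratify",
    "region_concordance",
    "risk_dispersion",
    "score_variance",
    "SignatureBiasAudit",
    "BiasAuditResult",
]

CONCORDANT_LOW = "concordant_low"
CONCORDANT_HIGH = "concordant_high"
DISCORDANT = "discordant"

BIAS_THRESHOLD = 0.5  # discordant fraction above which a cohort is "biased"


def risk_score(
    signature: GeneSignature, cohort: MultiregionCohort
) -> pd.Series:
    """Per-sample linear risk score; missing signature genes are dropped.

    The dropped gene ids are available on the result as
    ``scores.attrs["dropped_genes"]``.  Zero overlap is a hard error —
    silently scoring with nothing would be meaningless.
    """
    coefs = signature.coefficients
    present = coefs.index.intersection(cohort.expression.index)
    if len(present) == 0:
        raise ValueError(
            f"signature {signature.name!r}: none of its genes "
            f"{list(coefs.index)} are in the cohort matrix"
        )
    dropped = [g for g in coefs.index if g not in set(present)]
    scores = coefs[present] @ cohort.expression.loc[present]
    scores.name = signature.name
    scores.attrs["dropped_genes"] = dropped
    return scores


@dataclass
class RiskProfile:
    """Per-sample scores, the cutoff used, and high/low classes."""

    scores: pd.Series
    cutoff: float
    cutoff_policy: str  # "cohort_median" or "supplied"

    def __post_init__(self) -> None:
        if not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")

    @property
    def classes(self) -> pd.Series:
        # ties at the cutoff are classed low: high requires score > cutoff
        return pd.Series(
            np.where(self.scores > self.cutoff, "high", "low"),
            index=self.scores.index,
            name="risk_class",
        )


def stratify(scores: pd.Series, cutoff: float | None = None) -> RiskProfile:
    """Split samples at the median score (or a supplied cutoff)."""
    if cutoff is None:
        if len(scores) < 2:
            raise ValueError("median stratification needs >= 2 samples")
        cutoff_val = float(np.median(scores))
        policy = "cohort_median"
    else:
        cutoff_val = float(cutoff)
        policy = "supplied"
    return RiskProfile(scores=scores, cutoff=cutoff_val, cutoff_policy=policy)


@dataclass
class ConcordanceSummary:
    """Per-patient concordance labels plus the cohort bias verdict."""

    labels: pd.Series  # patient -> label
    n_regions: pd.Series  # patient -> region count
    discordant_fraction: float
    biased: bool
    profile: RiskProfile

    def summary(self) -> str:
        counts = self.labels.value_counts()
        return (
            f"Multiregion sampling-bias audit ({self.profile.scores.name})\n"
            f"  patients: {len(self.labels)}  "
            f"(multiregion: {(self.n_regions >= 2).sum()})\n"
            f"  concordant low:  {counts.get(CONCORDANT_LOW, 0)}\n"
            f"  concordant high: {counts.get(CONCORDANT_HIGH, 0)}\n"
            f"  discordant:      {counts.get(DISCORDANT, 0)}\n"
            f"  discordant fraction: {self.discordant_fraction:.3f}"
            f"  -> biased: {self.biased}"
        )


def region_concordance(
    cohort: MultiregionCohort,
    signature: GeneSignature,
    cutoff: float | None = None,
) -> ConcordanceSummary:
    """Score every tumor region, classify at the cohort-median cutoff and
    label each patient by the set of its regions' classes."""
    scores = risk_score(signature, cohort)
    profile = stratify(scores, cutoff)
    classes = profile.classes
    patient_of = cohort.patient_of()
    labels: dict[str, str] = {}
    n_regions: dict[str, int] = {}
    for patient, cls in classes.groupby(patient_of, sort=False):
        n_regions[patient] = len(cls)
        kinds = set(cls)
        if kinds == {"low"}:
            labels[patient] = CONCORDANT_LOW
        elif kinds == {"high"}:
            labels[patient] = CONCORDANT_HIGH
        else:
            labels[patient] = DISCORDANT
    label_s = pd.Series(labels, name="label")
    frac = float((label_s == DISCORDANT).mean())
    return ConcordanceSummary(
        labels=label_s,
        n_regions=pd.Series(n_regions, name="n_regions"),
        discordant_fraction=frac,
        biased=frac > BIAS_THRESHOLD,
        profile=profile,
    )


def risk_dispersion(
    cohort: MultiregionCohort, signature: GeneSignature
) -> tuple[pd.Series, float]:
    """Sample SD of each multiregion patient's region scores.

    Returns (per-patient SD over patients with >= 2 regions, mean of
    those SDs).
    """
    scores = risk_score(signature, cohort)
    grouped = scores.groupby(cohort.patient_of(), sort=False)
    sds = grouped.std(ddof=1)[grouped.size() >= 2]
    if sds.empty:
        raise ValueError("no patient has >= 2 regions")
    sds.name = "risk_sd"
    return sds, float(sds.mean())


def score_variance(
    cohort: MultiregionCohort, signature: GeneSignature
) -> float:
    """Sample variance (ddof=1) of the risk score across all samples."""
    scores = risk_score(signature, cohort)
    if len(scores) < 2:
        raise ValueError("score variance needs >= 2 samples")
    return float(scores.var(ddof=1))


@dataclass
class BiasAuditResult:
    """Audit of one or more signatures on one multiregion cohort."""

    table: pd.DataFrame  # per signature: discordant_fraction, biased, ...
    concordance: dict[str, ConcordanceSummary]

    def summary(self) -> str:
        lines = ["Signature sampling-bias audit"]
        for name, row in self.table.iterrows():
            lines.append(
                f"  {name}: discordant={row['discordant_fraction']:.3f} "
                f"biased={bool(row['biased'])} "
                f"mean_region_sd={row['mean_dispersion']:.4f} "
                f"score_var={row['score_variance']:.4f}"
            )
        return "\n".join(lines)


class SignatureBiasAudit:
    """Model-style front end auditing signatures for multiregion bias.

    fit() computes, per signature: the discordant patient fraction with
    the >50% bias flag, the mean per-patient region-score SD, and the
    cohort score variance.
    """

    def __init__(
        self, cohort: MultiregionCohort, signatures: list[GeneSignature]
    ) -> None:
        if not signatures:
            raise ValueError("at least one signature required")
        self.cohort = cohort
        self.signatures = signatures

    def fit(self) -> BiasAuditResult:
        rows = []
        summaries: dict[str, ConcordanceSummary] = {}
        for sig in self.signatures:
            conc = region_concordance(self.cohort, sig)
            _, mean_sd = risk_dispersion(self.cohort, sig)
            rows.append(
                {
                    "signature": sig.name,
                    "n_genes": len(sig),
                    "discordant_fraction": conc.discordant_fraction,
                    "biased": conc.biased,
                    "mean_dispersion": mean_sd,
                    "score_variance": score_variance(self.cohort, sig),
                }
            )
            summaries[sig.name] = conc
        table = pd.DataFrame(rows).set_index("signature")
        return BiasAuditResult(table=table, concordance=summaries)
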