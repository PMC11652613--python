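"""Per-gene intratumor / intertumor heterogeneity scores and quadrants.

Intratumor heterogeneity of a gene is the dispersion of its expression
across the regions of one tumor, averaged over patients that contribute
at least two tumor regions.  Intertumor heterogeneity is the dispersion
across patients when a single region is drawn uniformly at random per
patient, averaged over repeated draws (10 by default).

Plotting intertumor (x) against intratumor (y) score and cutting both
axes at their means partitions genes into four quadrants:

    Q1  low inter, high intra      Q3  high inter, high intra
    Q2  low inter, low intra       Q4  high inter, low intra

Q4 genes — stable within a tumor yet discriminative between tumors — are
the candidate pool for sampling-robust prognostic signatures.  "High"
means >= the mean threshold on both axes.

Dispersion metrics: SD (ddof=1), MAD (scaled by 1.4826 so it estimates
the SD under normality), CV = SD/mean.  Genes whose relevant mean is
within 1e-8 of zero get CV = NaN and are excluded from CV-based analyses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MultiregionCohort

__all__ = [
    "HeterogeneityTable",
    "intra_heterogeneity",
    "inter_heterogeneity",
    "inter_heterogeneity_exhaustive",
    "assign_quadrants",
    "metric_agreement",
    "quadrant_enrichment",
    "expressed_gene_filter",
    "HeterogeneityAnalysis",
]

METRICS = ("SD", "MAD", "CV")
_MEAN_GUARD = 1e-8

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")


def _dispersion(values: np.ndarray, metric: str, axis: int = -1) -> np.ndarray:
    """Row-wise dispersion of a 2-D block (genes x observations)."""
    if metric == "SD":
        return values.std(axis=axis, ddof=1)
    if metric == "MAD":
        return stats.median_abs_deviation(values, axis=axis, scale="normal")
    if metric == "CV":
        sd = values.std(axis=axis, ddof=1)
        mean = values.mean(axis=axis)
        out = np.divide(sd, mean, out=np.full_like(sd, np.nan),
                        where=np.abs(mean) >= _MEAN_GUARD)
        return out
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def intra_heterogeneity(
    cohort: MultiregionCohort, metric: str = "SD"
) -> pd.Series:
    """Mean within-patient dispersion per gene.

    For every patient with >= 2 tumor regions the metric is computed
    across that patient's regions; the per-gene score is the mean over
    those patients.  Pooling all regions of all patients would conflate
    inter- with intratumor variation, so aggregation is always
    per-patient first.
    """
    by_patient = cohort.regions_by_patient()
    eligible = {p: s for p, s in by_patient.items() if len(s) >= 2}
    if not eligible:
        raise ValueError("no patient has >= 2 tumor regions")
    expr = cohort.expression
    per_patient = np.stack(
        [
            _dispersion(expr[samp].to_numpy(), metric)
            for samp in eligible.values()
        ],
        axis=1,
    )
    valid = ~np.isnan(per_patient)
    counts = valid.sum(axis=1)
    sums = np.where(valid, per_patient, 0.0).sum(axis=1)
    score = np.divide(sums, counts, out=np.full(len(sums), np.nan),
                      where=counts > 0)
    return pd.Series(score, index=expr.index, name=f"intra_{metric}")


def _region_index_lists(cohort: MultiregionCohort) -> list[np.ndarray]:
    cols = {c: j for j, c in enumerate(cohort.expression.columns)}
    return [
        np.asarray([cols[s] for s in samples])
        for samples in cohort.regions_by_patient().values()
    ]


def inter_heterogeneity(
    cohort: MultiregionCohort,
    metric: str = "SD",
    n_reps: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Mean across-patient dispersion per gene over random region draws.

    Each repetition picks one tumor region uniformly at random per
    patient (independently across repetitions; single-region patients
    contribute their region deterministically), computes the metric
    across the selected values, and the score is the mean over
    ``n_reps`` repetitions.  Bit-reproducible for a fixed seed.
    """
    groups = _region_index_lists(cohort)
    if len(groups) < 2:
        raise ValueError("intertumor score needs >= 2 patients")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    values = cohort.expression.to_numpy()
    rng = np.random.default_rng(seed)
    total = np.zeros(values.shape[0])
    for _ in range(n_reps):
        picks = [g[rng.integers(len(g))] for g in groups]
        total += _dispersion(values[:, picks], metric)
    return pd.Series(
        total / n_reps, index=cohort.expression.index, name=f"inter_{metric}"
    )


def inter_heterogeneity_exhaustive(
    cohort: MultiregionCohort, metric: str = "SD", max_combinations: int = 100_000
) -> pd.Series:
    """Exact expectation of the intertumor score over all region choices.

    Enumerates every combination of one region per patient; only feasible
    on small cohorts (guarded by ``max_combinations``).  The Monte-Carlo
    estimator of :func:`inter_heterogeneity` converges to this value as
    ``n_reps`` grows.
    """
    groups = _region_index_lists(cohort)
    if len(groups) < 2:
        raise ValueError("intertumor score needs >= 2 patients")
    n_comb = int(np.prod([len(g) for g in groups]))
    if n_comb > max_combinations:
        raise ValueError(
            f"{n_comb} combinations exceed max_combinations={max_combinations}"
        )
    values = cohort.expression.to_numpy()
    total = np.zeros(values.shape[0])
    for picks in itertools.product(*groups):
        total += _dispersion(values[:, list(picks)], metric)
    return pd.Series(
        total / n_comb, index=cohort.expression.index, name=f"inter_{metric}"
    )


@dataclass
class HeterogeneityTable:
    """Per-gene heterogeneity scores with quadrant labels.

    thresholds are the arithmetic means of the two axes over all scored
    genes; quadrant is a pure function of (intra, inter, thresholds).
    """

    table: pd.DataFrame  # columns: intra, inter, quadrant
    metric: str
    thresholds: tuple[float, float]  # (mean_intra, mean_inter)
    n_reps: int = 10
    seed: int = 0

    @property
    def quadrant(self) -> pd.Series:
        return self.table["quadrant"]

    def quadrant_counts(self) -> pd.Series:
        return self.table["quadrant"].value_counts().reindex(QUADRANTS, fill_value=0)

    def genes_in(self, quadrant: str) -> pd.Index:
        return self.table.index[self.table["quadrant"] == quadrant]

    def summary(self) -> str:
        counts = self.quadrant_counts()
        lines = [
            f"Heterogeneity quadrants ({self.metric}; "
            f"thresholds intra={self.thresholds[0]:.4f}, "
            f"inter={self.thresholds[1]:.4f}; n_reps={self.n_reps})",
            "  Q1 (low inter, high intra): %d" % counts["Q1"],
            "  Q2 (low inter, low intra):  %d" % counts["Q2"],
            "  Q3 (high inter, high intra): %d" % counts["Q3"],
            "  Q4 (high inter, low intra): %d" % counts["Q4"],
            "  total genes: %d" % counts.sum(),
        ]
        return "\n".join(lines)


def assign_quadrants(
    intra: pd.Series,
    inter: pd.Series,
    metric: str = "SD",
    n_reps: int = 10,
    seed: int = 0,
) -> HeterogeneityTable:
    """Partition genes into Q1-Q4 by mean-threshold cuts on both axes."""
    if set(intra.index) != set(inter.index):
        only_a = set(intra.index) - set(inter.index)
        only_b = set(inter.index) - set(intra.index)
        raise ValueError(
            f"gene universes differ (intra-only: {len(only_a)}, "
            f"inter-only: {len(only_b)})"
        )
    inter = inter.reindex(intra.index)
    mean_intra = float(intra.mean())
    mean_inter = float(inter.mean())
    hi_intra = intra >= mean_intra
    hi_inter = inter >= mean_inter
    quadrant = pd.Series(
        np.where(
            hi_inter,
            np.where(hi_intra, "Q3", "Q4"),
            np.where(hi_intra, "Q1", "Q2"),
        ),
        index=intra.index,
        name="quadrant",
    )
    table = pd.DataFrame(
        {"intra": intra.to_numpy(), "inter": inter.to_numpy(), "quadrant": quadrant}
    )
    table.index = intra.index
    return HeterogeneityTable(
        table=table,
        metric=metric,
        thresholds=(mean_intra, mean_inter),
        n_reps=n_reps,
        seed=seed,
    )


def metric_agreement(cohort: MultiregionCohort) -> pd.DataFrame:
    """Pairwise Pearson correlation of intra scores under SD, MAD and CV.

    Returns a frame indexed by metric pair with columns r, p, n.  Genes
    with an undefined CV are dropped pairwise.
    """
    scores = {m: intra_heterogeneity(cohort, m) for m in METRICS}
    if len(cohort.expression) < 3:
        raise ValueError("metric agreement needs >= 3 genes")
    rows = []
    for a, b in itertools.combinations(METRICS, 2):
        x, y = scores[a], scores[b]
        keep = x.notna() & y.notna()
        r, p = stats.pearsonr(x[keep], y[keep])
        rows.append({"pair": f"{a}-{b}", "r": r, "p": p, "n": int(keep.sum())})
    return pd.DataFrame(rows).set_index("pair")


def quadrant_enrichment(
    table: HeterogeneityTable, genes: set[str] | list[str]
) -> pd.DataFrame:
    """Observed vs expected quadrant share of a gene set.

    expected = each quadrant's share of the scored universe; observed =
    that quadrant's share of the query genes (after dropping genes not in
    the universe); fold = observed / expected, NaN when both are zero.
    """
    universe = set(table.table.index)
    query = [g for g in dict.fromkeys(genes) if g in universe]
    n_dropped = len(set(genes)) - len(query)
    if not query:
        raise ValueError("no query gene is in the scored universe")
    counts = table.quadrant_counts()
    expected = counts / counts.sum()
    obs_counts = (
        table.table.loc[query, "quadrant"]
        .value_counts()
        .reindex(QUADRANTS, fill_value=0)
    )
    observed = obs_counts / len(query)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(
            (expected == 0) & (observed == 0),
            np.nan,
            observed / expected.replace(0, np.nan),
        )
    out = pd.DataFrame(
        {
            "observed_frac": observed,
            "expected_frac": expected,
            "fold": fold,
            "n_query": obs_counts,
        }
    )
    out.attrs["n_dropped"] = n_dropped
    return out


def expressed_gene_filter(
    cohort: MultiregionCohort, mean_quantile: float | None = None
) -> pd.Index:
    """Genes considered 'expressed': nonzero variance across tumor samples,
    optionally also above a mean-expression quantile (default off)."""
    expr = cohort.expression
    keep = expr.var(axis=1, ddof=1) > 0
    if mean_quantile is not None:
        means = expr.mean(axis=1)
        keep &= means >= means.quantile(mean_quantile)
    return expr.index[keep]


class HeterogeneityAnalysis:
    """Model-style front end: score a tumor-only cohort and fit quadrants.

    Parameters
    ----------
    cohort : MultiregionCohort
        Tumor-only multiregion cohort (use :func:`ithsig.subset_tumor`).
    metric : {"SD", "MAD", "CV"}
        Dispersion metric for both axes.
    n_reps : int
        Random single-region draws for the intertumor score.
    mean_quantile : float, optional
        Optional extra expressed-gene filter.

    ``fit(seed)`` returns the :class:`HeterogeneityTable`.
    """

    def __init__(
        self,
        cohort: MultiregionCohort,
        metric: str = "SD",
        n_reps: int = 10,
        mean_quantile: float | None = None,
    ) -> None:
        if metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        self.cohort = cohort
        self.metric = metric
        self.n_reps = n_reps
        self.mean_quantile = mean_quantile

    def fit(self, seed: int = 0) -> HeterogeneityTable:
        keep = expressed_gene_filter(self.cohort, self.mean_quantile)
        sub = MultiregionCohort(
            expression=self.cohort.expression.loc[keep],
            samples=list(self.cohort.samples),
            survival=self.cohort.survival,
        )
        intra = intra_heterogeneity(sub, self.metric)
        inter = inter_heterogeneity(sub, self.metric, self.n_reps, seed)
        ok = intra.notna() & inter.notna()
        return assign_quadrants(
            intra[ok], inter[ok], metric=self.metric, n_reps=self.n_reps, seed=seed
        )
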