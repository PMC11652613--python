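"""Survival-model evaluation utilities.

Harrell's concordance index, Kaplan-Meier curves with the two-group
log-rank test, multivariate Cox adjustment, IPCW time-dependent AUC, and
fixed-effect pooling of per-study hazard ratios with Cochran's Q / I^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "harrell_cindex",
    "km_logrank",
    "multivariate_cox",
    "time_dependent_auc",
    "pool_hr",
    "MetaResult",
    "as_survival_frame",
]


def as_survival_frame(survival: pd.DataFrame) -> pd.DataFrame:
    """Validate and coerce a (time, event) table; at least one event."""
    surv = survival[["time", "event"]].astype(float)
    if (surv["time"] <= 0).any():
        raise ValueError("survival times must be > 0")
    if not surv["event"].isin([0.0, 1.0]).all():
        raise ValueError("event must be 0 or 1")
    if surv["event"].sum() < 1:
        raise ValueError("at least one event is required")
    return surv


def harrell_cindex(scores: pd.Series | np.ndarray, survival: pd.DataFrame) -> float:
    """Harrell's concordance index: higher score should mean earlier failure.

    A pair (i, j) is comparable when the patient with the shorter time
    has an observed event and the times differ, or when the times are
    tied and exactly one patient has an event (the censored patient is
    known to have survived longer).  Concordant pairs score 1, tied
    scores 0.5.  Vectorized O(n^2); fine up to a few thousand patients.
    """
    surv = as_survival_frame(survival)
    s = np.asarray(scores, dtype=float)
    t = surv["time"].to_numpy()
    e = surv["event"].to_numpy().astype(bool)
    if len(s) != len(t):
        raise ValueError("scores and survival must have equal length")

    ti, tj = t[:, None], t[None, :]
    ei = e[:, None]
    # i is the known-shorter-survival member of the pair
    comparable = (ei & (ti < tj)) | (ei & (ti == tj) & ~e[None, :])
    np.fill_diagonal(comparable, False)
    n_pairs = comparable.sum()
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    si, sj = s[:, None], s[None, :]
    concordant = (si > sj) & comparable
    tied = (si == sj) & comparable
    return float((concordant.sum() + 0.5 * tied.sum()) / n_pairs)


@dataclass
class KMLogrankResult:
    curves: dict[str, pd.DataFrame]  # group -> (time, survival) frame
    chi2: float
    p: float
    warnings: list[str]

    def summary(self) -> str:
        head = ", ".join(f"{g} (n={len(c)})" for g, c in self.curves.items())
        return f"log-rank {head}: chi2={self.chi2:.4f}, p={self.p:.4g}"


def km_logrank(classes: pd.Series, survival: pd.DataFrame) -> KMLogrankResult:
    """Kaplan-Meier curves per class plus the two-group log-rank test."""
    surv = as_survival_frame(survival.loc[classes.index])
    groups = sorted(classes.unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    warnings: list[str] = []
    curves: dict[str, pd.DataFrame] = {}
    masks = {}
    for g in groups:
        mask = classes == g
        if mask.sum() == 0:
            raise ValueError(f"group {g!r} is empty")
        masks[g] = mask
        if surv.loc[mask.to_numpy(), "event"].sum() == 0:
            warnings.append(f"group {g!r} has zero events")
        kmf = KaplanMeierFitter()
        kmf.fit(
            surv.loc[mask.to_numpy(), "time"],
            surv.loc[mask.to_numpy(), "event"],
            label=str(g),
        )
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    a, b = groups
    res = logrank_test(
        surv.loc[masks[a].to_numpy(), "time"],
        surv.loc[masks[b].to_numpy(), "time"],
        event_observed_A=surv.loc[masks[a].to_numpy(), "event"],
        event_observed_B=surv.loc[masks[b].to_numpy(), "event"],
    )
    return KMLogrankResult(
        curves=curves,
        chi2=float(res.test_statistic),
        p=float(res.p_value),
        warnings=warnings,
    )


def multivariate_cox(
    design: pd.DataFrame, survival: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Joint Cox proportional-hazards fit (Efron ties) of all covariates.

    Returns a frame with hr, ci_low, ci_high, log_hr, se, p per
    covariate.  Rank-deficient designs are rejected with the offending
    columns named; fewer than ~10 events per covariate earns a warning
    in ``result.attrs``.
    """
    surv = as_survival_frame(survival.loc[design.index])
    X = design.astype(float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy()]))
    if rank < X.shape[1] + 1:
        # identify a minimal set of collinear columns by greedy QR-style scan
        bad = []
        kept: list[str] = []
        for col in X.columns:
            trial = X[kept + [col]].to_numpy()
            trial = np.column_stack([np.ones(len(X)), trial])
            if np.linalg.matrix_rank(trial) < trial.shape[1]:
                bad.append(col)
            else:
                kept.append(col)
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    df = X.copy()
    df["time"] = surv["time"].to_numpy()
    df["event"] = surv["event"].to_numpy()
    cph = CoxPHFitter(alpha=alpha)
    cph.fit(df, duration_col="time", event_col="event")
    out = pd.DataFrame(
        {
            "hr": np.exp(cph.params_),
            "ci_low": np.exp(cph.confidence_intervals_.iloc[:, 0]),
            "ci_high": np.exp(cph.confidence_intervals_.iloc[:, 1]),
            "log_hr": cph.params_,
            "se": cph.standard_errors_,
            "p": cph.summary["p"],
        }
    )
    epc = surv["event"].sum() / X.shape[1]
    if epc < 10:
        out.attrs["warning"] = (
            f"only {epc:.1f} events per covariate (>= 10 recommended)"
        )
    return out


def time_dependent_auc(
    scores: pd.Series | np.ndarray,
    survival: pd.DataFrame,
    eval_times: list[float] | np.ndarray,
) -> pd.Series:
    """IPCW cumulative-case / dynamic-control AUC(t) with Kaplan-Meier
    censoring weights.  Times with no case or no control are NaN."""
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    surv = as_survival_frame(survival)
    s = np.asarray(scores, dtype=float)
    y = Surv.from_arrays(surv["event"].astype(bool), surv["time"])
    t = surv["time"].to_numpy()
    e = surv["event"].to_numpy().astype(bool)
    out = pd.Series(np.nan, index=pd.Index(eval_times, name="time"), name="auc")
    t_max = t.max()
    for et in np.asarray(eval_times, dtype=float):
        has_case = bool(((t <= et) & e).any())
        has_control = bool((t > et).any())
        if not has_case or not has_control or et >= t_max:
            continue
        try:
            auc, _ = cumulative_dynamic_auc(y, y, s, [et])
            out.loc[et] = float(auc[0])
        except ValueError:
            continue
    return out


@dataclass
class MetaResult:
    """Fixed-effect inverse-variance pooling with Cochran's Q and I^2."""

    pooled_log_hr: float
    se: float
    Q: float
    I2: float
    p_het: float
    n_studies: int

    @property
    def pooled_hr(self) -> float:
        return float(np.exp(self.pooled_log_hr))

    def summary(self) -> str:
        lo = np.exp(self.pooled_log_hr - 1.96 * self.se)
        hi = np.exp(self.pooled_log_hr + 1.96 * self.se)
        return (
            f"Fixed-effect pooled HR = {self.pooled_hr:.3f} "
            f"[{lo:.3f}, {hi:.3f}] over {self.n_studies} studies; "
            f"Q = {self.Q:.3f}, I2 = {100 * self.I2:.1f}%, "
            f"p_het = {self.p_het:.4g}"
        )


def pool_hr(log_hrs: np.ndarray | list, ses: np.ndarray | list) -> MetaResult:
    """Fixed-effect inverse-variance pooling of per-study log hazard ratios."""
    lhr = np.asarray(log_hrs, dtype=float)
    se = np.asarray(ses, dtype=float)
    if lhr.shape != se.shape or lhr.ndim != 1:
        raise ValueError("log_hrs and ses must be equal-length 1-D")
    if len(lhr) < 2:
        raise ValueError("pooling needs >= 2 studies")
    if (se <= 0).any():
        raise ValueError("standard errors must be > 0")
    w = 1.0 / se**2
    pooled = float((w * lhr).sum() / w.sum())
    pooled_se = float(np.sqrt(1.0 / w.sum()))
    Q = float((w * (lhr - pooled) ** 2).sum())
    df = len(lhr) - 1
    I2 = max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    p_het = float(stats.chi2.sf(Q, df))
    return MetaResult(
        pooled_log_hr=pooled,
        se=pooled_se,
        Q=Q,
        I2=I2,
        p_het=p_het,
        n_studies=len(lhr),
    )
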