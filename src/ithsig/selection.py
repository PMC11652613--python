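"""Prognostic gene selection and the multi-learner survival benchmark.

The pipeline mirrors the standard heterogeneity-aware signature recipe:

1. univariate Cox screen over candidate genes (Wald p < 0.05, no
   multiplicity correction — the screen is a filter, not an inference);
2. LASSO-penalized Cox refinement, the penalty chosen to maximize the
   5-fold cross-validated concordance index;
3. a benchmark of survival learners (stepwise Cox by AIC, ridge, elastic
   net, LASSO, random survival forest, gradient-boosted Cox) trained on
   the refined gene set, ranked by the mean of the internal
   cross-validated C-index and the C-index on each external validation
   cohort.

Expression is standardized per cohort (mean 0, SD 1 per gene) before any
penalized fit, so exported coefficients live on the standardized scale
and transfer across platforms.  Fold assignment depends only on
(k, seed, a hash of the patient order) and is therefore stable across
runs and machines.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._cox import cox_univariate_batch, coxph_fit, coxph_null_loglik
from .cohort import GeneSignature, MultiregionCohort
from .evaluation import harrell_cindex

__all__ = [
    "univariate_cox",
    "lasso_refine",
    "LearnerSpec",
    "LEARNER_REGISTRY",
    "available_learners",
    "fit_learner",
    "FittedLearner",
    "benchmark_select",
    "BenchmarkResult",
    "cv_folds",
]


# ----------------------------------------------------------------------
# helpers


def _standardize(X: pd.DataFrame) -> pd.DataFrame:
    """Per-column (gene) standardization; constant columns become 0."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    Z = (X - mean).div(sd.where(sd > 0, 1.0), axis=1)
    return Z.fillna(0.0)


def cv_folds(patient_ids: list[str], k: int, seed: int) -> np.ndarray:
    """Deterministic fold labels in {0..k-1} per patient.

    The stream is keyed by (seed, CRC32 of the joined patient ids), so
    the assignment depends only on k, seed and the patient order.
    """
    key = zlib.crc32("|".join(map(str, patient_ids)).encode())
    rng = np.random.default_rng([seed, key])
    n = len(patient_ids)
    if k < 2 or k > n:
        raise ValueError(f"k={k} must be in [2, n_patients={n}]")
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = f
    return folds


def _surv_arrays(survival: pd.DataFrame):
    return survival["time"].to_numpy(float), survival["event"].to_numpy(int)


def _sksurv_y(survival: pd.DataFrame):
    from sksurv.util import Surv

    return Surv.from_arrays(
        survival["event"].astype(bool).to_numpy(), survival["time"].to_numpy(float)
    )


# ----------------------------------------------------------------------
# univariate screen


def univariate_cox(
    expr: pd.DataFrame,
    survival: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Single-covariate Cox fit per gene; select genes with Wald p < alpha.

    ``expr`` is gene x patient (one value per patient); ``survival`` is
    indexed by the same patients.  Genes that fail to converge (constant
    expression, monotone likelihood) are flagged and excluded from the
    selection; their count is what a run manifest should report.
    """
    patients = [p for p in expr.columns if p in survival.index]
    if len(patients) < len(expr.columns):
        missing = set(expr.columns) - set(patients)
        raise ValueError(f"patients without survival: {sorted(missing)[:5]}")
    surv = survival.loc[patients]
    if surv["event"].sum() < 10:
        raise ValueError(">= 10 events required for the univariate screen")
    time, event = _surv_arrays(surv)
    X = expr[patients].to_numpy().T  # patients x genes
    fit = cox_univariate_batch(X, time, event)
    from scipy import stats

    p = 2.0 * stats.norm.sf(np.abs(fit["wald"]))
    res = pd.DataFrame(
        {
            "log_hr": fit["log_hr"],
            "hr": np.exp(fit["log_hr"]),
            "se": fit["se"],
            "wald": fit["wald"],
            "p": p,
            "converged": fit["converged"],
        },
        index=expr.index,
    )
    selected = res.index[(res["converged"]) & (res["p"] < alpha)].tolist()
    res.attrs["n_nonconverged"] = int((~res["converged"]).sum())
    return res, selected


# ----------------------------------------------------------------------
# LASSO refinement


def lasso_refine(
    expr: pd.DataFrame,
    survival: pd.DataFrame,
    k: int = 5,
    seed: int = 123,
    n_alphas: int = 100,
    l1_ratio: float = 1.0,
    se_rule: bool = True,
) -> tuple[list[str], pd.DataFrame]:
    """L1-penalized Cox over a 100-point penalty path, tuned by the mean
    k-fold cross-validated C-index.

    The CV curve is typically flat near its maximum, so penalties whose
    mean C-index is within one standard error of the best are treated as
    statistically tied and the tie goes to the strongest penalty (the
    sparsest model) — the usual one-standard-error convention.
    ``se_rule=False`` takes the plain argmax instead.

    Returns (genes with nonzero coefficient at the chosen penalty, a
    per-penalty table of mean CV C-index and selected-gene counts).
    Raises when no penalty on the path selects at least one gene.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis

    patients = list(expr.columns)
    surv = survival.loc[patients]
    Z = _standardize(expr.T)  # patients x genes
    y = _sksurv_y(surv)

    path_model = CoxnetSurvivalAnalysis(
        l1_ratio=l1_ratio, n_alphas=n_alphas, alpha_min_ratio=0.01,
        fit_baseline_model=False,
    )
    path_model.fit(Z.to_numpy(), y)
    alphas = np.asarray(path_model.alphas_)

    folds = cv_folds(patients, k, seed)
    time, event = _surv_arrays(surv)
    cv_scores = np.zeros((k, len(alphas)))
    cv_scores[:] = np.nan
    for f in range(k):
        tr, te = folds != f, folds == f
        m = CoxnetSurvivalAnalysis(
            l1_ratio=l1_ratio, alphas=alphas, fit_baseline_model=False
        )
        m.fit(Z.to_numpy()[tr], y[tr])
        te_surv = surv.iloc[te]
        for j, a in enumerate(alphas):
            try:
                pred = m.predict(Z.to_numpy()[te], alpha=float(a))
            except ValueError:
                continue
            if np.ptp(pred) == 0:
                cv_scores[f, j] = 0.5
            else:
                cv_scores[f, j] = harrell_cindex(pred, te_surv)
    mean_c = np.nanmean(cv_scores, axis=0)

    coefs = path_model.coef_  # genes x alphas
    n_sel = (np.abs(coefs) > 0).sum(axis=0)
    table = pd.DataFrame(
        {"alpha": alphas, "mean_cv_cindex": mean_c, "n_selected": n_sel}
    )
    usable = (n_sel >= 1) & np.isfinite(mean_c)
    if not usable.any():
        raise ValueError("degenerate penalty path: no penalty selects >= 1 gene")
    argmax = int(np.flatnonzero(usable)[np.nanargmax(mean_c[usable])])
    if se_rule:
        fold_at_max = cv_scores[:, argmax]
        se = float(np.nanstd(fold_at_max, ddof=1) / np.sqrt(np.isfinite(fold_at_max).sum()))
        tied = usable & (mean_c >= mean_c[argmax] - se)
    else:
        tied = usable & (mean_c >= mean_c[argmax] - 1e-12)
    best = int(np.flatnonzero(tied)[0])  # alphas descend: first = strongest penalty
    genes = expr.index[np.abs(coefs[:, best]) > 0].tolist()
    table.attrs["best_alpha"] = float(alphas[best])
    table.attrs["argmax_alpha"] = float(alphas[argmax])
    return genes, table


# ----------------------------------------------------------------------
# learner registry


@dataclass(frozen=True)
class LearnerSpec:
    """One benchmark learner: name, fixed parameters, availability."""

    name: str
    params: dict = field(default_factory=dict)
    available: bool = True


LEARNER_REGISTRY: dict[str, LearnerSpec] = {
    "StepCoxForward": LearnerSpec("StepCoxForward", {"direction": "forward"}),
    "StepCoxBackward": LearnerSpec("StepCoxBackward", {"direction": "backward"}),
    "StepCoxBoth": LearnerSpec("StepCoxBoth", {"direction": "both"}),
    "Ridge": LearnerSpec("Ridge", {"n_lambdas": 25}),
    "Enet": LearnerSpec(
        "Enet", {"alpha_grid": tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))}
    ),
    "LassoCV": LearnerSpec("LassoCV", {"n_alphas": 50}),
    "RSF": LearnerSpec("RSF", {"n_estimators": 1000}),
    "GBM": LearnerSpec(
        "GBM",
        {
            "n_estimators": 10_000,
            "learning_rate": 0.001,
            "max_depth": 3,
            "min_samples_leaf": 10,
        },
    ),
    # single-ecosystem learners without a maintained Python implementation;
    # kept in the registry so requests for them fail loudly, not silently
    "CoxBoost": LearnerSpec(
        "CoxBoost", {"maxstepno": 500, "K": 10, "type": "verweij"}, available=False
    ),
    "plsRcox": LearnerSpec("plsRcox", {"nt": 5}, available=False),
    "SuperPC": LearnerSpec(
        "SuperPC",
        {
            "type": "survival",
            "s0.perc": 0.5,
            "n.threshold": 20,
            "n.fold": 10,
            "n.components": 3,
            "min.features": 5,
        },
        available=False,
    ),
    "SurvivalSVM": LearnerSpec("SurvivalSVM", {"gamma.mu": 1}, available=False),
}


def available_learners() -> list[LearnerSpec]:
    return [s for s in LEARNER_REGISTRY.values() if s.available]


@dataclass
class FittedLearner:
    """A trained scoring rule: patient expression -> risk score.

    Higher score always means higher hazard (the orientation is checked
    on the training data and flipped if needed).  ``coefficients`` is a
    standardized-scale Series for linear learners, None otherwise.
    """

    name: str
    genes: list[str]
    _predict_z: callable
    coefficients: pd.Series | None
    sign: float = 1.0
    train_cindex: float = np.nan

    def predict(self, X: pd.DataFrame) -> pd.Series:
        """Score patients; X is patient x gene, standardized per cohort.

        Genes absent from X contribute 0 after standardization (the
        linear-model equivalent of dropping the term).
        """
        Z = _standardize(X)
        missing = [g for g in self.genes if g not in Z.columns]
        for g in missing:
            Z[g] = 0.0
        Z = Z[self.genes]
        raw = np.asarray(self._predict_z(Z.to_numpy()), dtype=float)
        return pd.Series(self.sign * raw, index=X.index, name=self.name)

    @property
    def n_selected(self) -> int:
        if self.coefficients is None:
            return len(self.genes)
        return int((self.coefficients != 0).sum())

    def to_signature(self, name: str | None = None) -> GeneSignature | None:
        if self.coefficients is None:
            return None
        nz = self.coefficients[self.coefficients != 0] * self.sign
        if nz.empty:
            return None
        return GeneSignature(
            name=name or self.name, terms=list(zip(nz.index, nz.to_numpy()))
        )


def _stepwise_cox(Z: np.ndarray, time, event, columns, direction: str):
    """AIC-guided stepwise Cox selection over standardized columns."""
    p = Z.shape[1]
    null_aic = -2.0 * coxph_null_loglik(time, event)

    def fit_aic(cols: list[int]):
        if not cols:
            return None, null_aic
        f = coxph_fit(Z[:, cols], time, event)
        return f, f.aic

    if direction == "backward":
        current = list(range(p))
        fit, aic = fit_aic(current)
        improved = True
        while improved and current:
            improved = False
            best = (aic, None)
            for c in current:
                trial = [x for x in current if x != c]
                _, a = fit_aic(trial)
                if a < best[0] - 1e-9:
                    best = (a, c)
            if best[1] is not None:
                current.remove(best[1])
                fit, aic = fit_aic(current)
                improved = True
    else:
        current: list[int] = []
        fit, aic = None, null_aic
        improved = True
        while improved:
            improved = False
            best = (aic, None)
            for c in range(p):
                if c in current:
                    continue
                _, a = fit_aic(current + [c])
                if a < best[0] - 1e-9:
                    best = (a, c)
            if best[1] is not None:
                current.append(best[1])
                fit, aic = fit_aic(current)
                improved = True
                if direction == "both":
                    dropped = True
                    while dropped and len(current) > 1:
                        dropped = False
                        dbest = (aic, None)
                        for c in current:
                            trial = [x for x in current if x != c]
                            _, a = fit_aic(trial)
                            if a < dbest[0] - 1e-9:
                                dbest = (a, c)
                        if dbest[1] is not None:
                            current.remove(dbest[1])
                            fit, aic = fit_aic(current)
                            dropped = True
    coefs = pd.Series(0.0, index=columns)
    if fit is not None and current:
        coefs.iloc[current] = fit.beta
    return coefs


def _cv_best_penalty(Z, surv, penalties, fit_fn, k, seed, patients):
    """Generic inner-CV penalty pick by mean held-out C-index."""
    folds = cv_folds(patients, k, seed)
    scores = np.full((k, len(penalties)), np.nan)
    for f in range(k):
        tr, te = folds != f, folds == f
        preds = fit_fn(Z[tr], surv.iloc[tr], Z[te])
        for j, pred in enumerate(preds):
            if pred is None:
                continue
            if np.ptp(pred) == 0:
                scores[f, j] = 0.5
            else:
                scores[f, j] = harrell_cindex(pred, surv.iloc[te])
    mean_c = np.nanmean(scores, axis=0)
    if np.all(np.isnan(mean_c)):
        raise ValueError("all penalties failed in cross-validation")
    return int(np.nanargmax(mean_c)), mean_c


def fit_learner(
    spec: LearnerSpec,
    X: pd.DataFrame,
    survival: pd.DataFrame,
    seed: int = 123,
    k_inner: int = 5,
) -> FittedLearner:
    """Train one registry learner on patient x gene expression.

    Penalty-tuned learners (Ridge, Enet, LassoCV) pick their penalty by
    ``k_inner``-fold CV on the training data; tree ensembles take the
    registry's fixed parameters and are seeded deterministically.
    """
    if not spec.available:
        avail = sorted(s.name for s in available_learners())
        raise ValueError(
            f"learner {spec.name!r} is not available; available: {avail}"
        )
    patients = list(X.index)
    surv = survival.loc[patients]
    Z = _standardize(X)
    Zv = Z.to_numpy()
    genes = list(X.columns)
    time, event = _surv_arrays(surv)
    coefficients: pd.Series | None = None
    model = None

    if spec.name.startswith("StepCox"):
        coefficients = _stepwise_cox(
            Zv, time, event, genes, spec.params["direction"]
        )
        beta = coefficients.to_numpy()
        predict_z = lambda z: z @ beta  # noqa: E731

    elif spec.name == "Ridge":
        from sksurv.linear_model import CoxPHSurvivalAnalysis

        lambdas = np.logspace(-3, 3, spec.params.get("n_lambdas", 25))
        y = _sksurv_y(surv)

        def fit_fold(Ztr, surv_tr, Zte):
            ytr = _sksurv_y(surv_tr)
            out = []
            for lam in lambdas:
                try:
                    m = CoxPHSurvivalAnalysis(alpha=float(lam))
                    m.fit(Ztr, ytr)
                    out.append(m.predict(Zte))
                except Exception:
                    out.append(None)
            return out

        best, _ = _cv_best_penalty(Zv, surv, lambdas, fit_fold, k_inner, seed, patients)
        model = CoxPHSurvivalAnalysis(alpha=float(lambdas[best]))
        model.fit(Zv, y)
        coefficients = pd.Series(model.coef_, index=genes)
        beta = coefficients.to_numpy()
        predict_z = lambda z: z @ beta  # noqa: E731

    elif spec.name in ("Enet", "LassoCV"):
        from sksurv.linear_model import CoxnetSurvivalAnalysis

        y = _sksurv_y(surv)
        l1_grid = (
            list(spec.params.get("alpha_grid", ()))
            if spec.name == "Enet"
            else [1.0]
        )
        n_alphas = spec.params.get("n_alphas", 50)
        best_combo = None  # (mean_c, l1, alpha_value)
        for l1 in l1_grid:
            path = CoxnetSurvivalAnalysis(
                l1_ratio=float(l1), n_alphas=n_alphas, alpha_min_ratio=0.01,
                fit_baseline_model=False,
            )
            path.fit(Zv, y)
            alphas = np.asarray(path.alphas_)

            def fit_fold(Ztr, surv_tr, Zte, _l1=float(l1), _alphas=alphas):
                ytr = _sksurv_y(surv_tr)
                m = CoxnetSurvivalAnalysis(
                    l1_ratio=_l1, alphas=_alphas, fit_baseline_model=False
                )
                m.fit(Ztr, ytr)
                out = []
                for a in _alphas:
                    try:
                        out.append(m.predict(Zte, alpha=float(a)))
                    except ValueError:
                        out.append(None)
                return out

            best_j, mean_c = _cv_best_penalty(
                Zv, surv, alphas, fit_fold, k_inner, seed, patients
            )
            score = mean_c[best_j]
            if best_combo is None or score > best_combo[0]:
                best_combo = (score, float(l1), float(alphas[best_j]), alphas)
        _, l1_best, alpha_best, alphas = best_combo
        model = CoxnetSurvivalAnalysis(
            l1_ratio=l1_best, alphas=alphas, fit_baseline_model=False
        )
        model.fit(Zv, y)
        j = int(np.argmin(np.abs(np.asarray(model.alphas_) - alpha_best)))
        coefficients = pd.Series(model.coef_[:, j], index=genes)
        beta = coefficients.to_numpy()
        predict_z = lambda z: z @ beta  # noqa: E731

    elif spec.name == "RSF":
        from sksurv.ensemble import RandomSurvivalForest

        model = RandomSurvivalForest(
            n_estimators=spec.params["n_estimators"],
            random_state=seed,
            n_jobs=1,
        )
        model.fit(Zv, _sksurv_y(surv))
        predict_z = model.predict

    elif spec.name == "GBM":
        from sksurv.ensemble import GradientBoostingSurvivalAnalysis

        model = GradientBoostingSurvivalAnalysis(
            n_estimators=spec.params["n_estimators"],
            learning_rate=spec.params["learning_rate"],
            max_depth=spec.params["max_depth"],
            min_samples_leaf=spec.params["min_samples_leaf"],
            random_state=seed,
        )
        model.fit(Zv, _sksurv_y(surv))
        predict_z = model.predict

    else:
        raise ValueError(f"unknown learner {spec.name!r}")

    fitted = FittedLearner(
        name=spec.name,
        genes=genes,
        _predict_z=predict_z,
        coefficients=coefficients,
    )
    raw = fitted.predict(X)
    if np.ptp(raw.to_numpy()) > 0:
        c = harrell_cindex(raw, surv)
        if c < 0.5:  # normalize orientation: higher score = higher hazard
            fitted.sign = -1.0
            c = 1.0 - c
        fitted.train_cindex = c
    else:
        fitted.train_cindex = 0.5
    return fitted


# ----------------------------------------------------------------------
# benchmark


@dataclass
class BenchmarkResult:
    """C-index table of the learner benchmark and the winning signature."""

    cindex: pd.DataFrame  # learner x dataset
    mean_cindex: pd.Series
    winner: str
    signature: GeneSignature | None
    nonlinear_winner: bool
    fitted: dict[str, FittedLearner]
    failures: dict[str, str]
    k: int = 5
    seed: int = 123

    def summary(self) -> str:
        lines = [f"Learner benchmark (k={self.k}, seed={self.seed})"]
        order = self.mean_cindex.sort_values(ascending=False).index
        for name in order:
            row = self.cindex.loc[name]
            cells = "  ".join(f"{d}={v:.3f}" for d, v in row.items())
            lines.append(f"  {name:<16s} mean={self.mean_cindex[name]:.3f}  {cells}")
        for name, why in self.failures.items():
            lines.append(f"  {name:<16s} FAILED: {why}")
        lines.append(f"  winner: {self.winner}"
                     + (" (non-linear scoring rule)" if self.nonlinear_winner else ""))
        return "\n".join(lines)


def _patient_level(cohort: MultiregionCohort, genes: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reduce a cohort to one expression value per patient (region mean)
    and align its survival table; survival is a patient attribute."""
    if cohort.survival is None:
        raise ValueError("cohort has no survival table")
    expr = cohort.patient_mean_expression()
    keep = [g for g in genes if g in expr.index]
    X = expr.loc[keep].T
    patients = [p for p in X.index if p in cohort.survival.index]
    return X.loc[patients], cohort.survival.loc[patients]


def benchmark_select(
    candidates: list[str],
    train: MultiregionCohort,
    validations: list[MultiregionCohort],
    learners: list[LearnerSpec] | None = None,
    k: int = 5,
    seed: int = 123,
    signature_name: str = "benchmark_winner",
) -> BenchmarkResult:
    """Rank learners by mean C-index over internal CV and external cohorts.

    Internal score: mean held-out C-index over k folds of the training
    cohort.  External scores: the full-train model applied to each
    validation cohort.  The winner maximizes the unweighted mean of the
    internal and external scores; ties break toward fewer selected genes,
    then lexicographic name.  The winner's signature is exported when the
    learner is coefficient-based; otherwise the fitted scoring rule is
    returned flagged as non-linear.
    """
    if not validations:
        raise ValueError("at least one validation cohort is required")
    if learners is None:
        learners = available_learners()
    missing = [g for g in candidates if g not in train.genes]
    if missing:
        raise ValueError(f"candidate genes absent from training cohort: {missing[:5]}")

    X_train, surv_train = _patient_level(train, candidates)
    ext = [
        (f"validation_{i + 1}", *_patient_level(v, candidates))
        for i, v in enumerate(validations)
    ]
    patients = list(X_train.index)
    folds = cv_folds(patients, k, seed)

    datasets = ["internal_cv"] + [name for name, _, _ in ext]
    rows: dict[str, dict[str, float]] = {}
    fitted_full: dict[str, FittedLearner] = {}
    failures: dict[str, str] = {}
    for spec in learners:
        try:
            fold_scores = []
            for f in range(k):
                tr = X_train.iloc[folds != f]
                te = X_train.iloc[folds == f]
                fl = fit_learner(spec, tr, surv_train, seed=seed)
                pred = fl.predict(te)
                if np.ptp(pred.to_numpy()) == 0:
                    fold_scores.append(0.5)
                else:
                    fold_scores.append(harrell_cindex(pred, surv_train.loc[te.index]))
            full = fit_learner(spec, X_train, surv_train, seed=seed)
            scores = {"internal_cv": float(np.mean(fold_scores))}
            for name, Xv, surv_v in ext:
                pred = full.predict(Xv)
                if np.ptp(pred.to_numpy()) == 0:
                    scores[name] = 0.5
                else:
                    scores[name] = harrell_cindex(pred, surv_v)
            rows[spec.name] = scores
            fitted_full[spec.name] = full
        except Exception as exc:  # learner disqualified, benchmark goes on
            failures[spec.name] = f"{type(exc).__name__}: {exc}"

    if not rows:
        raise ValueError(f"every learner failed: {failures}")
    cindex = pd.DataFrame(rows).T.reindex(columns=datasets)
    mean_c = cindex.mean(axis=1)
    order = sorted(
        mean_c.index,
        key=lambda n: (-mean_c[n], fitted_full[n].n_selected, n),
    )
    winner = order[0]
    signature = fitted_full[winner].to_signature(signature_name)
    return BenchmarkResult(
        cindex=cindex,
        mean_cindex=mean_c.rename("mean_cindex"),
        winner=winner,
        signature=signature,
        nonlinear_winner=signature is None,
        fitted=fitted_full,
        failures=failures,
        k=k,
        seed=seed,
    )
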