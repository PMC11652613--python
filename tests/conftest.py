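import numpy as np
import pandas as pd
import pytest

from ithsig import MultiregionCohort, SampleMeta


def make_cohort(values, patients, tissues=None, survival=None, genes=None):
    """Build a small cohort from a 2-D list (genes x samples)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_g, n_s = values.shape
    genes = genes or [f"g{i + 1}" for i in range(n_g)]
    tissues = tissues or ["tumor"] * n_s
    counts: dict[str, int] = {}
    samples = []
    for j, (p, t) in enumerate(zip(patients, tissues)):
        counts[p] = counts.get(p, 0) + 1
        samples.append(SampleMeta(f"{p}_s{counts[p]}", p, f"R{counts[p]}", t))
    expr = pd.DataFrame(values, index=genes, columns=[s.sample_id for s in samples])
    surv = None
    if survival is not None:
        surv = pd.DataFrame(survival, columns=["time", "event"])
        surv.index = pd.Index(sorted(set(patients), key=patients.index), name="patient_id")
    return MultiregionCohort(expression=expr, samples=samples, survival=surv)


@pytest.fixture
def two_patient_cohort():
    """The worked example: P1 regions (1,3), P2 regions (5,7)."""
    return make_cohort([[1.0, 3.0, 5.0, 7.0]], ["P1", "P1", "P2", "P2"])


@pytest.fixture
def censored_fixture():
    """20 patients, random scores, ~35% censoring, with score ties."""
    rng = np.random.default_rng(42)
    scores = pd.Series(np.round(rng.normal(size=20), 1))
    surv = pd.DataFrame(
        {
            "time": np.round(rng.exponential(100, 20), 0) + 1,
            "event": (rng.random(20) < 0.65).astype(int),
        }
    )
    if surv["event"].sum() == 0:
        surv.loc[0, "event"] = 1
    return scores, surv
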