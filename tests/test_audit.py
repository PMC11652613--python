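"""Risk scoring, stratification and the multiregion sampling-bias audit."""

import numpy as np
import pandas as pd
import pytest

import ithsig as it
from ithsig.audit import (
    CONCORDANT_HIGH,
    CONCORDANT_LOW,
    DISCORDANT,
    region_concordance,
    risk_dispersion,
    risk_score,
    score_variance,
    stratify,
)

from conftest import make_cohort


def sig(name="s", **terms):
    return it.GeneSignature(name=name, terms=list(terms.items()))


class TestRiskScore:
    def test_hand_arithmetic(self):
        cohort = make_cohort([[2.0], [1.0]], ["P1"], genes=["g1", "g2"])
        s = risk_score(sig(g1=0.5, g2=-1.0), cohort)
        assert s.iloc[0] == pytest.approx(0.0)

    def test_linearity_in_coefficients(self):
        rng = np.random.default_rng(0)
        cohort = make_cohort(rng.normal(size=(5, 8)),
                             [f"P{i}" for i in range(8)])
        base = sig(**{f"g{i + 1}": c for i, c in enumerate(rng.normal(size=5))})
        doubled = it.GeneSignature("2x", [(g, 2 * c) for g, c in base.terms])
        np.testing.assert_allclose(
            risk_score(doubled, cohort), 2 * risk_score(base, cohort)
        )

    def test_matches_brute_force_dot_product(self):
        rng = np.random.default_rng(7)
        cohort = make_cohort(rng.normal(size=(30, 20)),
                             [f"P{i}" for i in range(20)])
        genes = rng.choice(cohort.genes, 10, replace=False)
        coefs = rng.normal(size=10)
        s = risk_score(it.GeneSignature("r", list(zip(genes, coefs))), cohort)
        for j, sample in enumerate(cohort.sample_ids):
            expected = sum(
                c * cohort.expression.loc[g, sample] for g, c in zip(genes, coefs)
            )
            assert s.loc[sample] == pytest.approx(expected)

    def test_missing_genes_dropped_and_reported(self):
        cohort = make_cohort([[1.0, 2.0]], ["P1", "P2"], genes=["g1"])
        s = risk_score(sig(g1=1.0, ghost=5.0), cohort)
        np.testing.assert_allclose(s, [1.0, 2.0])
        assert s.attrs["dropped_genes"] == ["ghost"]

    def test_zero_overlap_is_hard_error(self):
        cohort = make_cohort([[1.0, 2.0]], ["P1", "P2"], genes=["g1"])
        with pytest.raises(ValueError, match="ghost"):
            risk_score(sig(ghost=1.0), cohort)


class TestStratify:
    def test_median_cutoff_hand_case(self):
        scores = pd.Series([0.1, 0.15, 0.2, 0.8, 0.9, 0.95])
        prof = stratify(scores)
        assert prof.cutoff == pytest.approx(0.5)
        assert list(prof.classes) == ["low"] * 3 + ["high"] * 3

    def test_supplied_cutoff(self):
        prof = stratify(pd.Series([-1.0, 1.0]), cutoff=0.0)
        assert list(prof.classes) == ["low", "high"]
        assert prof.cutoff_policy == "supplied"

    def test_affine_shift_leaves_classes_unchanged(self):
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.normal(size=11))
        a, b = stratify(scores), stratify(scores + 7.5)
        assert b.cutoff == pytest.approx(a.cutoff + 7.5)
        assert (a.classes == b.classes).all()

    def test_all_identical_scores_all_low(self):
        prof = stratify(pd.Series([2.0, 2.0, 2.0]))
        assert (prof.classes == "low").all()

    def test_tie_at_cutoff_is_low(self):
        prof = stratify(pd.Series([1.0, 2.0, 3.0, 4.0]), cutoff=3.0)
        assert list(prof.classes) == ["low", "low", "low", "high"]


class TestRegionConcordance:
    def test_three_patient_worked_example(self):
        # region scores P1 (0.2, 0.8), P2 (0.9, 0.95), P3 (0.1, 0.15)
        cohort = make_cohort(
            [[0.2, 0.8, 0.9, 0.95, 0.1, 0.15]],
            ["P1", "P1", "P2", "P2", "P3", "P3"],
        )
        summary = region_concordance(cohort, sig(g1=1.0))
        assert summary.profile.cutoff == pytest.approx(0.5)
        assert summary.labels.to_dict() == {
            "P1": DISCORDANT, "P2": CONCORDANT_HIGH, "P3": CONCORDANT_LOW
        }
        assert summary.discordant_fraction == pytest.approx(1 / 3)
        assert not summary.biased

    def test_zero_region_noise_never_discordant(self):
        cfg = it.SyntheticConfig(
            n_patients=12, regions_per_patient=3,
            archetypes=[it.GeneArchetype("Q4-like", 10, tau=1.0, sigma=0.0)],
        )
        cohort, truth = it.generate_cohort(cfg)
        signature = it.GeneSignature(
            "truth", [(g, 1.0) for g in cohort.genes[:5]]
        )
        summary = region_concordance(cohort, signature)
        assert summary.discordant_fraction == 0.0

    def test_single_region_patients_cannot_be_discordant(self):
        cohort = make_cohort([[0.1, 0.9, 0.5]], ["P1", "P2", "P3"])
        summary = region_concordance(cohort, sig(g1=1.0))
        assert summary.discordant_fraction == 0.0
        assert (summary.n_regions == 1).all()

    def test_biased_flag_requires_majority_discordant(self):
        # 2 of 3 patients straddle the supplied cutoff -> biased
        # (a median split of six scores always balances 3/3, so a 2/3
        # discordant pattern needs an external cutoff)
        cohort = make_cohort(
            [[0.2, 0.8, 0.3, 0.9, 0.6, 0.7]],
            ["P1", "P1", "P2", "P2", "P3", "P3"],
        )
        summary = region_concordance(cohort, sig(g1=1.0), cutoff=0.5)
        assert summary.discordant_fraction == pytest.approx(2 / 3)
        assert summary.biased

    def test_labels_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(1, 12))
        patients = [f"P{i // 3}" for i in range(12)]
        a = region_concordance(make_cohort(values, patients), sig(g1=1.0))
        b = region_concordance(make_cohort(np.exp(values), patients), sig(g1=1.0))
        # exp() of scores is a strictly increasing transform of the scores
        # only for a single positive-coefficient gene, as here
        pd.testing.assert_series_equal(a.labels, b.labels)

    def test_labels_invariant_to_region_order(self):
        values = np.array([[0.2, 0.8, 0.9, 0.95, 0.1, 0.15]])
        patients = ["P1", "P1", "P2", "P2", "P3", "P3"]
        a = region_concordance(make_cohort(values, patients), sig(g1=1.0))
        perm = [1, 0, 3, 2, 5, 4]
        b = region_concordance(
            make_cohort(values[:, perm], [patients[i] for i in perm]), sig(g1=1.0)
        )
        pd.testing.assert_series_equal(
            a.labels.sort_index(), b.labels.sort_index()
        )


class TestDispersionAndVariance:
    def test_per_patient_sd_hand_case(self):
        cohort = make_cohort([[0.2, 0.8, 0.5, 0.5]], ["P1", "P1", "P2", "P2"])
        sds, mean_sd = risk_dispersion(cohort, sig(g1=1.0))
        assert sds["P1"] == pytest.approx(0.42426, abs=1e-5)
        assert sds["P2"] == pytest.approx(0.0)
        assert mean_sd == pytest.approx(sds.mean())

    def test_translation_invariance(self):
        cohort = make_cohort(
            [[0.2, 0.8, 0.5, 0.6], [1.0, 1.0, 1.0, 1.0]],
            ["P1", "P1", "P2", "P2"],
        )
        a, _ = risk_dispersion(cohort, sig(g1=1.0))
        b, _ = risk_dispersion(cohort, sig(g1=1.0, g2=100.0))  # adds constant
        pd.testing.assert_series_equal(a, b)

    def test_no_multiregion_patient_errors(self):
        cohort = make_cohort([[1.0, 2.0]], ["P1", "P2"])
        with pytest.raises(ValueError, match=">= 2 regions"):
            risk_dispersion(cohort, sig(g1=1.0))

    def test_score_variance_hand_cases(self):
        flat = make_cohort([[1.0, 1.0, 1.0]], ["P1", "P2", "P3"])
        assert score_variance(flat, sig(g1=1.0)) == 0.0
        two = make_cohort([[0.0, 2.0]], ["P1", "P2"])
        assert score_variance(two, sig(g1=1.0)) == pytest.approx(2.0)
        assert score_variance(two, sig(g1=2.0)) == pytest.approx(8.0)


class TestBiasAuditModel:
    def test_audit_table_shape_and_flags(self):
        rng = np.random.default_rng(3)
        cohort = make_cohort(
            rng.normal(size=(6, 12)), [f"P{i // 3}" for i in range(12)]
        )
        sigs = [sig("a", g1=1.0), sig("b", g2=1.0, g3=-0.5)]
        result = it.SignatureBiasAudit(cohort, sigs).fit()
        assert list(result.table.index) == ["a", "b"]
        assert {"discordant_fraction", "biased", "mean_dispersion",
                "score_variance"} <= set(result.table.columns)
        assert result.table["discordant_fraction"].between(0, 1).all()
        assert "sampling-bias audit" in result.summary()

    def test_q4_signature_beats_q1_signature_on_dispersion(self):
        # matched size and |beta|; only the variance split differs
        wins_disp, wins_disc, wins_var = 0, 0, 0
        n_seeds = 12
        for seed in range(n_seeds):
            cfg = it.SyntheticConfig(
                n_patients=60, regions_per_patient=3,
                archetypes=[
                    it.GeneArchetype("Q1-like", 10, mu=6, tau=0.2, sigma=1.0),
                    it.GeneArchetype("Q2-like", 10, mu=6, tau=0.2, sigma=0.2),
                    it.GeneArchetype("Q4-like", 10, mu=6, tau=1.0, sigma=0.2),
                ],
                seed=100 + seed,
            )
            cohort, truth = it.generate_cohort(cfg)
            by_label = {
                lab: truth.labels.index[truth.labels == lab]
                for lab in ("Q1-like", "Q2-like", "Q4-like")
            }
            sigs = {
                lab: it.GeneSignature(lab, [(g, 1.0) for g in genes])
                for lab, genes in by_label.items()
            }
            _, d1 = risk_dispersion(cohort, sigs["Q1-like"])
            _, d4 = risk_dispersion(cohort, sigs["Q4-like"])
            wins_disp += d4 < d1
            c1 = region_concordance(cohort, sigs["Q1-like"]).discordant_fraction
            c4_ = region_concordance(cohort, sigs["Q4-like"]).discordant_fraction
            wins_disc += c4_ <= c1
            v2 = score_variance(cohort, sigs["Q2-like"])
            v4 = score_variance(cohort, sigs["Q4-like"])
            wins_var += v4 > v2
        assert wins_disp == n_seeds  # dispersion gap is deterministic in sign
        assert wins_disc >= n_seeds - 1
        assert wins_var == n_seeds
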