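"""Longitudinal model: design encoding, likelihood, fitting, fold changes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nucleoquant.exceptions import DomainError, InsufficientDataError
from nucleoquant.longitudinal import (
    FoldChangeEstimate,
    LmmParams,
    LongitudinalMixedModel,
    encode_design,
    forest_table,
    joint_log_likelihood,
)
from nucleoquant.simulate import GenerativeParams, StudyDesign, simulate_study

MET3 = ("Pse", "Ino", "MTA")


def small_study(mets=MET3, seed=5, **kwargs):
    design = StudyDesign(metabolites=mets)
    params = GenerativeParams(metabolites=mets, **kwargs)
    return simulate_study(design, params, seed=seed)


class TestEncodeDesign:
    def test_column_count_pooled(self):
        table, _ = small_study(mets=tuple(f"M{i}" for i in range(11)),
                               seed=1)
        d = encode_design(table)
        # 1 + (11-1) + (3-1) + (11-1)(3-1)
        assert d.X.shape[1] == 33
        assert len(d.fixed_names) == 33
        assert d.time_levels == ["pre", "24h", "post"]

    def test_column_count_unpooled(self):
        table, _ = small_study(mets=tuple(f"M{i}" for i in range(11)), seed=1)
        d = encode_design(table, pooling="none")
        assert d.X.shape[1] == 1 + 10 + 6 + 60

    def test_single_metabolite_reduces_to_time_model(self):
        table, _ = small_study(mets=("Ino",), seed=2)
        d = encode_design(table)
        assert d.fixed_names == ["intercept", "TIME[24h]", "TIME[post]"]

    def test_duplicate_sample_metabolite_rejected(self):
        table, _ = small_study(seed=3)
        dup = pd.concat([table, table.head(1)], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            encode_design(dup)

    def test_metabolite_missing_at_baseline_warns(self):
        table, _ = small_study(seed=3)
        drop = table[~((table["analyte_code"] == "MTA") & (table["time_point"] == "pre"))]
        with pytest.warns(UserWarning, match="baseline"):
            encode_design(drop)


def _random_params(design, rng):
    M = len(design.metabolites)
    return LmmParams(
        beta=rng.normal(size=design.X.shape[1]),
        Sigma_ID=0.09 * (np.eye(M) + 0.5 * (np.ones((M, M)) - np.eye(M))),
        tau_sample=0.25,
        sigma_met=rng.uniform(0.2, 0.6, M),
    )


class TestJointLikelihood:
    def test_zero_residuals_closed_form(self):
        table, _ = small_study(seed=4)
        d = encode_design(table.head(12))
        M = len(d.metabolites)
        s = 0.37
        params = LmmParams(
            beta=np.zeros(d.X.shape[1]),
            Sigma_ID=np.eye(M),
            tau_sample=1.0,
            sigma_met=np.full(M, s),
        )
        d.y = d.X @ params.beta  # zero residuals
        b = np.zeros((len(d.patient_ids), M))
        u = np.zeros(len(d.sample_ids))
        ll = joint_log_likelihood(params, d, b, u)
        n = d.y.size
        data_term = -n * np.log(s * np.sqrt(2 * np.pi))
        re_term = (
            stats.multivariate_normal.logpdf(np.zeros(M), cov=np.eye(M)) * len(d.patient_ids)
            + stats.norm.logpdf(0.0, scale=1.0) * len(d.sample_ids)
        )
        assert ll == pytest.approx(data_term + re_term, rel=1e-12)

    def test_matches_brute_force_row_sum(self):
        table, _ = small_study(seed=6)
        d = encode_design(table.head(10))
        rng = np.random.default_rng(1)
        params = _random_params(d, rng)
        M = len(d.metabolites)
        b = rng.normal(0, 0.3, (len(d.patient_ids), M))
        u = rng.normal(0, 0.25, len(d.sample_ids))
        ll = joint_log_likelihood(params, d, b, u)
        brute = 0.0
        for i in range(d.y.size):
            mu = d.X[i] @ params.beta + b[d.patient_idx[i], d.met_idx[i]] + u[d.sample_idx[i]]
            brute += stats.norm.logpdf(d.y[i], mu, params.sigma_met[d.met_idx[i]])
        for j in range(len(d.patient_ids)):
            brute += stats.multivariate_normal.logpdf(b[j], np.zeros(M), params.Sigma_ID)
        brute += float(np.sum(stats.norm.logpdf(u, scale=params.tau_sample)))
        assert ll == pytest.approx(brute, rel=1e-12)

    def test_doubling_sigma_lowers_data_term_by_nlog2(self):
        table, _ = small_study(seed=7)
        d = encode_design(table.head(20))
        M = len(d.metabolites)
        base = LmmParams(np.zeros(d.X.shape[1]), np.eye(M), 1.0, np.full(M, 0.5))
        d.y = d.X @ base.beta
        b = np.zeros((len(d.patient_ids), M))
        u = np.zeros(len(d.sample_ids))
        doubled = LmmParams(base.beta, base.Sigma_ID, base.tau_sample, 2 * base.sigma_met)
        n = d.y.size
        assert joint_log_likelihood(doubled, d, b, u) == pytest.approx(
            joint_log_likelihood(base, d, b, u) - n * np.log(2), rel=1e-12
        )

    def test_invalid_sigma_rejected(self):
        table, _ = small_study(seed=8)
        d = encode_design(table.head(10))
        M = len(d.metabolites)
        params = LmmParams(np.zeros(d.X.shape[1]), np.eye(M), 1.0, np.zeros(M))
        with pytest.raises(DomainError):
            joint_log_likelihood(params, d, np.zeros((len(d.patient_ids), M)),
                                 np.zeros(len(d.sample_ids)))


class TestFit:
    def test_degenerate_recovery(self):
        """Near-deterministic data: fixed effects recovered tightly."""
        table, truth = small_study(seed=9, id_sd=0.0, tau_sample=0.0,
                                   sigma_met={m: 0.01 for m in MET3})
        fit = LongitudinalMixedModel(backend="reml").fit(table)
        folds = {f.metabolite: f.fold for f in fit.fold_changes()
                 if f.contrast.startswith("24h")}
        assert folds["MTA"] == pytest.approx(0.5, rel=0.01)
        assert folds["Ino"] == pytest.approx(1.7, rel=0.01)
        assert folds["Pse"] == pytest.approx(1.0, rel=0.01)

    def test_row_permutation_invariance(self):
        table, _ = small_study(seed=10)
        fit_a = LongitudinalMixedModel(backend="reml").fit(table)
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        fit_b = LongitudinalMixedModel(backend="reml").fit(shuffled)
        fa = {(f.metabolite, f.contrast): f.fold for f in fit_a.fold_changes()}
        fb = {(f.metabolite, f.contrast): f.fold for f in fit_b.fold_changes()}
        for k in fa:
            assert fb[k] == pytest.approx(fa[k], rel=1e-5)

    def test_variance_component_recovery(self):
        """sigma per metabolite within 25% and diuresis SD within 30% of truth."""
        table, truth = small_study(seed=11)
        fit = LongitudinalMixedModel(backend="reml").fit(table)
        for m in MET3:
            assert fit.sigma_met_[m] == pytest.approx(truth["sigma_met"][m], rel=0.25)
        assert fit.tau_sample_ == pytest.approx(truth["tau_sample"], rel=0.30)

    def test_reference_metabolite_does_not_change_folds(self):
        table, _ = small_study(seed=12)
        fit_a = LongitudinalMixedModel(reference_metabolite="Ino").fit(table)
        fit_b = LongitudinalMixedModel(reference_metabolite="MTA").fit(table)
        fa = {(f.metabolite, f.contrast): f.fold for f in fit_a.fold_changes()}
        fb = {(f.metabolite, f.contrast): f.fold for f in fit_b.fold_changes()}
        for k in fa:
            assert fb[k] == pytest.approx(fa[k], rel=1e-4)

    def test_common_sample_shift_absorbed_by_diuresis_term(self):
        """A per-sample multiplicative shift moves tau, not the fold changes.

        The shifts (one per sample, shared by all its metabolites, centered
        within each time level so no artificial time effect is introduced)
        mimic residual diuresis variation; the SAMPLE intercept exists to
        absorb exactly this.
        """
        table, _ = small_study(seed=13)
        rng = np.random.default_rng(99)
        samples = table[["sample_id", "time_point"]].drop_duplicates()
        samples["shift"] = rng.normal(0, 0.35, len(samples))
        samples["shift"] -= samples.groupby("time_point")["shift"].transform("mean")
        shifts = dict(zip(samples["sample_id"], samples["shift"]))
        shifted = table.copy()
        shifted["logDV"] = shifted["logDV"] + shifted["sample_id"].map(shifts)
        shifted["normalized_ratio"] = np.exp(shifted["logDV"])
        fit_a = LongitudinalMixedModel(backend="reml").fit(table)
        fit_b = LongitudinalMixedModel(backend="reml").fit(shifted)
        assert fit_b.tau_sample_ > fit_a.tau_sample_
        fa = {(f.metabolite, f.contrast): f.fold for f in fit_a.fold_changes()}
        fb = {(f.metabolite, f.contrast): f.fold for f in fit_b.fold_changes()}
        for k in fa:
            assert fb[k] == pytest.approx(fa[k], rel=0.05)

    def test_baseline_fold_is_one(self):
        table, _ = small_study(seed=14)
        fit = LongitudinalMixedModel().fit(table)
        assert fit.baseline_fold("MTA") == 1.0
        assert all(not f.contrast.startswith("pre") for f in fit.fold_changes())

    def test_sklearn_param_interface(self):
        m = LongitudinalMixedModel(pooling="none", backend="ml")
        params = m.get_params()
        assert params["pooling"] == "none"
        m.set_params(backend="reml")
        assert m.backend == "reml"


class TestForestTable:
    def _est(self, met, fold, lo, hi):
        return FoldChangeEstimate(met, "24h vs pre", fold,
                                  (fold * 0.9, fold * 1.1), (lo, hi))

    def test_band_annotation(self):
        table = forest_table([
            self._est("Ino", 1.7, 1.3, 2.2),
            self._est("Pse", 1.0, 0.9, 1.1),
            self._est("MTA", 0.5, 0.4, 0.62),
        ])
        flagged = table.set_index("metabolite")["excludes_band"]
        assert flagged["Ino"] and flagged["MTA"] and not flagged["Pse"]

    def test_rows_sorted_by_metabolite(self):
        table = forest_table([
            self._est("U", 1.0, 0.9, 1.1),
            self._est("Ino", 1.0, 0.9, 1.1),
        ])
        assert list(table["metabolite"]) == ["Ino", "U"]

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            forest_table([])
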