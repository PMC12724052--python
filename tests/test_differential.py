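"""Covariate-adjusted per-protein linear models, BH adjustment, and the
GSEA ranking derived from them."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adipoproteo.differential import (
    OK,
    SKIPPED_MIN_N,
    DesignSpec,
    bh_adjust,
    differential_table,
    fit_protein_models,
    ranking_for_gsea,
)
from adipoproteo.errors import ConfigurationError, ValidationError
from adipoproteo.io_formats import SampleMetadata
from adipoproteo.preprocess import filter_proteins, normalize, zeros_to_missing
from adipoproteo.simulate import SynthConfig, generate_proteome

from conftest import make_matrix


def simple_meta(n_pat, n_ctl, rng=None):
    """Metadata with covariates constant/balanced so toys stay interpretable."""
    rng = rng or np.random.default_rng(0)
    out = []
    for i in range(n_pat + n_ctl):
        is_pat = i < n_pat
        out.append(SampleMetadata(
            sample_id=f"S{i + 1}", group="patient" if is_pat else "control",
            sex="female", presurgery_weightloss_pct=0.0, sleep_apnea=False,
            lipid_med=False, bp_med=False, age=40.0 + rng.normal(0, 5),
        ))
    return out


class TestBhAdjust:
    def naive_bh(self, p):
        """Textbook max-min step-up: q_i = min_{j: p_j >= p_i} min(m*p_j/rank_j, 1)."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        ranked = p[order]
        q = np.empty(m)
        for i in range(m):
            q[i] = min(min(m * ranked[j] / (j + 1) for j in range(i, m)), 1.0)
        out = np.empty(m)
        out[order] = q
        return out

    def test_hand_computed_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.2]),
                           [0.04, 0.04, 0.04, 0.2])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == 0.37

    def test_equal_ps_collapse(self):
        assert np.allclose(bh_adjust([0.01] * 10), [0.01] * 10)

    def test_exhaustive_grid_matches_textbook_definition(self):
        grid = [0.0, 0.01, 0.04, 0.2, 0.5, 1.0]
        for length in (1, 2, 3, 4):
            for combo in itertools.product(grid, repeat=length):
                assert np.allclose(bh_adjust(list(combo)), self.naive_bh(combo)), combo

    def test_matches_statsmodels_on_random_input(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.random(200) ** 2
        assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_monotone_and_dominates_raw_p(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestFitProteinModels:
    def test_no_covariate_balanced_groups_recovers_mean_difference(self):
        rng = np.random.default_rng(0)
        n_pat = n_ctl = 8
        meta = simple_meta(n_pat, n_ctl)
        design = DesignSpec(covariates=())
        vals = rng.normal(10, 1, size=(5, n_pat + n_ctl))
        vals[:, n_pat:] += np.array([1.0, -2.0, 0.0, 0.5, 3.0])[:, None]
        m = make_matrix(vals, samples=[f"S{i + 1}" for i in range(16)], normalized=True)
        res = fit_protein_models(m, meta, design, min_n=4)
        for r, planted in zip(res, [1.0, -2.0, 0.0, 0.5, 3.0]):
            observed_diff = (m.values.loc[r.accession].iloc[n_pat:].mean()
                             - m.values.loc[r.accession].iloc[:n_pat].mean())
            # group coded {0, 2}: coefficient is per coding unit
            assert r.coef_group * design.coding_gap == pytest.approx(observed_diff,
                                                                     abs=1e-10)

    def test_agrees_with_statsmodels_ols(self):
        import statsmodels.api as sm

        cfg = SynthConfig(seed=3, n_proteins=30, n_patients=20, n_controls=12,
                          adipose_size=5, blood_size=5, frac_de=0.0,
                          n_contaminated_patients=0, n_contaminated_controls=0,
                          missing_rate=0.0)
        raw, meta, *_ = generate_proteome(cfg)
        m = normalize(zeros_to_missing(filter_proteins(raw)[0]))
        design = DesignSpec()
        res = fit_protein_models(m, meta, design)
        X = design.build_matrix(meta).loc[m.samples]
        for r in res[:10]:
            y = m.values.loc[r.accession]
            fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
            g = design.terms().index("group")
            assert r.coef_group == pytest.approx(fit.params[g], rel=1e-8)
            assert r.se["group"] == pytest.approx(fit.bse[g], rel=1e-8)
            assert r.pval_group == pytest.approx(fit.pvalues[g], rel=1e-6)

    def test_protein_higher_in_controls_gets_positive_coefficient(self):
        rng = np.random.default_rng(5)
        meta = simple_meta(10, 10)
        vals = rng.normal(10, 0.5, size=(3, 20))
        vals[0, 10:] += 4.0  # higher in controls
        m = make_matrix(vals, samples=[f"S{i + 1}" for i in range(20)], normalized=True)
        res = fit_protein_models(m, meta, DesignSpec(covariates=()), min_n=4)
        assert res[0].coef_group > 0
        tab = differential_table(res)
        assert tab.loc[0, "coef_obesity"] == -tab.loc[0, "coef"]

    def test_sparse_protein_skipped_without_pvalue(self):
        rng = np.random.default_rng(6)
        meta = simple_meta(10, 10)
        vals = rng.normal(10, 1, size=(2, 20))
        vals[0, 3:] = np.nan  # present in only 3 samples
        m = make_matrix(vals, samples=[f"S{i + 1}" for i in range(20)], normalized=True)
        res = fit_protein_models(m, meta, DesignSpec(covariates=()), min_n=8)
        assert res[0].status == SKIPPED_MIN_N
        assert res[0].pval == {} and res[0].fdr == {}
        assert res[1].status == OK

    def test_globally_collinear_design_is_configuration_error(self):
        meta = simple_meta(10, 10)
        # sleep_apnea constant (all False) makes that column collinear with
        # the intercept
        m = make_matrix(np.random.default_rng(7).normal(10, 1, size=(3, 20)),
                        samples=[f"S{i + 1}" for i in range(20)], normalized=True)
        with pytest.raises(ConfigurationError, match="rank deficient"):
            fit_protein_models(m, meta, DesignSpec(covariates=("sleep_apnea",)))


class TestRankingForGsea:
    def _results(self):
        cfg = SynthConfig(seed=11, n_proteins=60, n_patients=12, n_controls=8,
                          adipose_size=10, blood_size=10, frac_de=0.1,
                          n_contaminated_patients=0, n_contaminated_controls=0)
        raw, meta, *_ = generate_proteome(cfg)
        m = normalize(zeros_to_missing(filter_proteins(raw)[0]))
        return fit_protein_models(m, meta)

    def test_orientation_flip_negates_every_statistic(self):
        res = self._results()
        obesity = ranking_for_gsea(res, "obesity")
        control = ranking_for_gsea(res, "control")
        ob = dict(zip(obesity.items, obesity.stats))
        co = dict(zip(control.items, control.stats))
        assert set(ob) == set(co)
        for g in ob:
            assert ob[g] == pytest.approx(-co[g], abs=1e-12)

    def test_ranking_is_sorted_t_statistics(self):
        res = self._results()
        ranked = ranking_for_gsea(res, "obesity")
        expected = sorted((-r.tstat["group"] for r in res if r.status == OK),
                          reverse=True)
        assert np.allclose(ranked.stats, expected)

    def test_unknown_orientation_rejected(self):
        with pytest.raises(ValidationError):
            ranking_for_gsea(self._results(), "sideways")


class TestPlantedTruthRecovery:
    def test_planted_effects_recovered_and_null_fdp_controlled(self):
        """Planted 1.5 log-unit shifts at n=40/15 are found at FDR < 0.05 and
        a null run makes no confident false calls (single-seed smoke; the
        multi-seed versions live in the acceptance suite)."""
        cfg = SynthConfig(seed=21, n_proteins=500, n_patients=40, n_controls=15,
                          adipose_size=60, blood_size=70, frac_de=0.1,
                          n_contaminated_patients=0, n_contaminated_controls=0)
        raw, meta, _, _, truth = generate_proteome(cfg)
        m = normalize(zeros_to_missing(filter_proteins(raw)[0]))
        tab = differential_table(fit_protein_models(m, meta)).set_index("accession")
        called = set(tab.index[tab["fdr"] < 0.05])
        recall = len(called & truth.de_proteins) / len(truth.de_proteins)
        fdp = len(called - truth.de_proteins) / max(len(called), 1)
        assert recall >= 0.8
        assert fdp <= 0.1
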