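"""Filtering, zero handling, and the glog normalization contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from adipoproteo.errors import ContractError, EstimationError
from adipoproteo.preprocess import (
    apply_vsn,
    filter_proteins,
    fit_vsn,
    normalize,
    zeros_to_missing,
)
from adipoproteo.simulate import multiplicative_additive_matrix

from conftest import make_matrix


class TestFilterProteins:
    def test_six_record_toy_reconciles_under_precedence(self):
        # 1 reverse, 1 contaminant, 1 single-peptide, 3 clean -> 3 kept
        m = make_matrix(
            np.ones((6, 2)),
            peptides=[5, 3, 1, 2, 4, 9],
            reverse=[True, False, False, False, False, False],
            contaminant=[False, True, False, False, False, False],
        )
        kept, rep = filter_proteins(m)
        assert kept.n_proteins == 3
        assert (rep.n_removed_reverse, rep.n_removed_contaminant,
                rep.n_removed_unique_peptides) == (1, 1, 1)
        assert rep.n_kept == rep.n_input - 3

    def test_reverse_takes_precedence_over_other_flags(self):
        # a reverse hit that is also a contaminant with 1 peptide counts once
        m = make_matrix(np.ones((2, 2)), peptides=[1, 2],
                        reverse=[True, False], contaminant=[True, False])
        _, rep = filter_proteins(m)
        assert rep.n_removed_reverse == 1
        assert rep.n_removed_contaminant == 0
        assert rep.n_removed_unique_peptides == 0

    def test_single_peptide_protein_removed(self):
        m = make_matrix(np.ones((2, 2)), peptides=[1, 2])
        kept, _ = filter_proteins(m)
        assert list(kept.records["n_unique_peptides"]) == [2]

    def test_idempotent(self):
        m = make_matrix(np.ones((4, 2)), peptides=[1, 2, 3, 4],
                        reverse=[True, False, False, False])
        once, rep1 = filter_proteins(m)
        twice, rep2 = filter_proteins(once)
        assert list(once.records["accession"]) == list(twice.records["accession"])
        assert rep2.n_kept == rep2.n_input

    def test_empty_matrix_allowed(self):
        m = make_matrix(np.ones((0, 2)))
        kept, rep = filter_proteins(m)
        assert kept.n_proteins == 0
        assert rep.as_dict() == {"n_input": 0, "n_removed_reverse": 0,
                                 "n_removed_contaminant": 0,
                                 "n_removed_unique_peptides": 0, "n_kept": 0}


class TestZerosToMissing:
    def test_cellwise_zero_becomes_missing_nonzero_untouched(self):
        m = make_matrix([[0.0, 17.3], [1.0, 0.0]])
        out = zeros_to_missing(m)
        assert np.isnan(out.values.iloc[0, 0])
        assert out.values.iloc[0, 1] == 17.3
        assert np.isnan(out.values.iloc[1, 1])

    def test_all_zero_row_is_retained_fully_missing(self):
        m = make_matrix([[0.0, 0.0], [1.0, 2.0]])
        out = zeros_to_missing(m)
        assert out.n_proteins == 2
        assert out.values.iloc[0].isna().all()

    def test_rowwise_mode_only_clears_zero_total_rows(self):
        m = make_matrix([[0.0, 5.0], [0.0, 0.0]])
        out = zeros_to_missing(m, mode="row")
        assert out.values.iloc[0, 0] == 0.0  # row total nonzero: cell kept
        assert out.values.iloc[1].isna().all()


class TestFitApplyVsn:
    def test_identical_samples_fit_symmetric(self):
        rng = np.random.default_rng(0)
        x = np.exp(rng.normal(8, 1.5, size=60))
        m = make_matrix(np.column_stack([x, x]))
        model = fit_vsn(m)
        assert model.scales.iloc[1] == pytest.approx(model.scales.iloc[0], abs=1e-8)
        assert model.offsets.iloc[1] == pytest.approx(model.offsets.iloc[0], abs=1e-8)

    def test_exact_proportionality_gives_inverse_scales(self):
        rng = np.random.default_rng(1)
        x = np.exp(rng.normal(8, 1.5, size=60))
        m = make_matrix(np.column_stack([x, 2.0 * x]))
        model = fit_vsn(m)
        assert model.scales.iloc[1] == pytest.approx(model.scales.iloc[0] / 2.0, rel=1e-6)

    def test_single_sample_is_estimation_error(self):
        m = make_matrix(np.ones((20, 1)))
        with pytest.raises(EstimationError):
            fit_vsn(m)

    def test_too_few_observed_proteins_is_estimation_error(self):
        m = make_matrix(np.full((5, 3), 10.0))
        with pytest.raises(EstimationError):
            fit_vsn(m)

    def test_transform_values_match_direct_arsinh(self):
        m = make_matrix([[0.0, 1e6], [1.0, 2.0]])
        model = fit_vsn(make_matrix(np.exp(np.random.default_rng(2)
                                           .normal(8, 1.5, size=(60, 2)))))
        # unit model: a=0, b=1 on both samples
        unit = type(model)(offsets=model.offsets * 0.0, scales=model.scales * 0.0 + 1.0)
        out = apply_vsn(m, unit)
        assert out.values.iloc[0, 0] == 0.0
        assert out.values.iloc[0, 1] == pytest.approx(np.log(2e6), abs=1e-6)
        assert out.normalized

    def test_missing_stays_missing(self):
        m = make_matrix(np.exp(np.random.default_rng(3).normal(8, 1, size=(40, 3))))
        m.values.iloc[5, 1] = np.nan
        out = normalize(m)
        assert np.isnan(out.values.iloc[5, 1])
        assert out.mask.to_numpy().sum() == 1

    def test_sample_mismatch_is_contract_error(self):
        m1 = make_matrix(np.exp(np.random.default_rng(4).normal(8, 1, size=(40, 2))))
        m2 = make_matrix(np.exp(np.random.default_rng(5).normal(8, 1, size=(40, 3))))
        with pytest.raises(ContractError):
            apply_vsn(m2, fit_vsn(m1))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_within_sample(self, seed):
        rng = np.random.default_rng(seed)
        m = make_matrix(np.exp(rng.normal(8, 2, size=(30, 4))))
        out = normalize(m)
        for j in range(4):
            raw = m.values.iloc[:, j].to_numpy()
            tra = out.values.iloc[:, j].to_numpy()
            assert np.array_equal(np.argsort(raw, kind="stable"),
                                  np.argsort(tra, kind="stable"))


class TestVarianceStabilization:
    def test_sd_mean_trend_is_flattened_on_noise_model(self):
        """Under x = m*exp(eta) + eps the transform should remove the strong
        raw SD-vs-mean trend (robust slope shrinks by orders of magnitude)."""
        m = multiplicative_additive_matrix(800, 16, seed=10)
        X = m.values.to_numpy()
        rank = stats.rankdata(np.nanmean(X, axis=1))
        before = stats.theilslopes(np.nanstd(X, axis=1, ddof=1), rank).slope
        out = normalize(m)
        Y = out.values.to_numpy()
        ok = (~np.isnan(Y)).sum(axis=1) >= 3
        after = stats.theilslopes(np.nanstd(Y[ok], axis=1, ddof=1),
                                  stats.rankdata(np.nanmean(Y[ok], axis=1))).slope
        assert abs(after) < abs(before) * 1e-2
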