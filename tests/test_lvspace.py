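"""Latent-space operations: standardization, projection, dedup, batch check."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lvtool import lvspace, synthgen
from lvtool.containers import ParameterError, PlierModel


def _df(arr, prefix="g"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])],
    )


class TestZscore:
    def test_closed_form_row(self):
        Z, flagged = lvspace.zscore_genes(_df([[1, 2, 3]]))
        assert np.allclose(Z.to_numpy(), [[-1, 0, 1]])
        assert flagged == []

    def test_constant_row_flagged_zero(self):
        Z, flagged = lvspace.zscore_genes(_df([[5, 5, 5], [1, 2, 3]]))
        assert np.allclose(Z.iloc[0], 0)
        assert flagged == ["g0"]

    def test_single_sample_rejected(self):
        with pytest.raises(ParameterError):
            lvspace.zscore_genes(_df([[1], [2]]))

    @given(
        st.lists(
            st.lists(st.floats(-50, 50), min_size=4, max_size=4),
            min_size=2,
            max_size=6,
        )
    )
    def test_rows_standardized_or_flagged(self, rows):
        Z, flagged = lvspace.zscore_genes(_df(rows))
        vals = Z.to_numpy()
        for i, gene in enumerate(Z.index):
            if gene in flagged:
                assert np.all(vals[i] == 0)
            else:
                assert abs(vals[i].mean()) < 1e-12
                assert abs(vals[i].std(ddof=1) - 1) < 1e-9


class TestProjection:
    def test_single_lv_least_squares(self):
        model = PlierModel(_df([[1.0], [1.0]]).rename(columns={"s0": "LV1"}), 0.0)
        Y = _df([[3.0, 0.0], [3.0, 0.0]])
        B = lvspace.project_lv(model, Y)
        assert B.loc["LV1", "s0"] == pytest.approx(3.0)
        assert B.loc["LV1", "s1"] == pytest.approx(0.0)

    def test_zero_matrix_maps_to_zero(self, small_model):
        Y = pd.DataFrame(
            0.0, index=small_model.genes, columns=["a", "b", "c"]
        )
        assert np.all(lvspace.project_lv(small_model, Y).to_numpy() == 0)

    def test_noiseless_recovery(self):
        model = synthgen.gen_model(200, 10, 0.2, seed=7, lambda2=1e-8)
        rng = np.random.default_rng(8)
        B_true = rng.standard_normal((10, 6))
        Y = pd.DataFrame(
            model.loadings.to_numpy() @ B_true,
            index=model.genes,
            columns=[f"s{j}" for j in range(6)],
        )
        B = lvspace.project_lv(model, Y).to_numpy()
        rel = np.abs(B - B_true).max() / np.abs(B_true).max()
        assert rel < 1e-6

    def test_linearity(self, small_model, rng):
        cols = [f"s{j}" for j in range(4)]
        Y1 = pd.DataFrame(
            rng.standard_normal((120, 4)), index=small_model.genes, columns=cols
        )
        Y2 = pd.DataFrame(
            rng.standard_normal((120, 4)), index=small_model.genes, columns=cols
        )
        lhs = lvspace.project_lv(small_model, Y1 + Y2).to_numpy()
        rhs = (
            lvspace.project_lv(small_model, Y1) + lvspace.project_lv(small_model, Y2)
        ).to_numpy()
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_low_overlap_error_names_fraction(self, small_model, rng):
        Y = pd.DataFrame(
            rng.standard_normal((5, 3)),
            index=list(small_model.genes[:5]),
            columns=["a", "b", "c"],
        )
        with pytest.raises(ParameterError, match="0.04"):
            lvspace.project_lv(small_model, Y)


class TestDedup:
    def test_identical_pair_drops_later(self, rng):
        Z = np.abs(rng.standard_normal((50, 10)))
        Z[:, 7] = Z[:, 2]
        model = PlierModel(_df(Z).rename(columns=lambda c: c.replace("s", "LV")), 1.0)
        retained = lvspace.dedup_lvs(model)
        assert len(retained) == 9
        assert "LV2" in retained and "LV7" not in retained

    def test_orthogonal_columns_all_kept(self):
        Z = np.eye(6)[:, :4]
        model = PlierModel(_df(Z).rename(columns=lambda c: c.replace("s", "LV")), 1.0)
        assert len(lvspace.dedup_lvs(model)) == 4

    def test_idempotent(self, rng):
        Z = np.abs(rng.standard_normal((40, 12)))
        Z[:, 5] = Z[:, 1] + 0.01 * np.abs(rng.standard_normal(40))
        model = PlierModel(_df(Z).rename(columns=lambda c: c.replace("s", "LV")), 1.0)
        retained = lvspace.dedup_lvs(model)
        again = lvspace.dedup_lvs(model.subset(retained))
        assert list(again) == list(retained)

    def test_retained_pairs_below_threshold(self, rng):
        Z = np.abs(rng.standard_normal((30, 15)))
        Z[:, 4] = Z[:, 0] * 1.5
        model = PlierModel(_df(Z).rename(columns=lambda c: c.replace("s", "LV")), 1.0)
        retained = lvspace.dedup_lvs(model, threshold=0.5)
        sub = model.loadings[retained].to_numpy()
        corr = np.corrcoef(sub, rowvar=False)
        off = corr[~np.eye(len(retained), dtype=bool)]
        assert off.max() <= 0.5

    def test_threshold_validation(self, small_model):
        with pytest.raises(ParameterError):
            lvspace.dedup_lvs(small_model, threshold=0.0)


class TestTopVariable:
    def test_count_is_ceiling(self, rng):
        B = _df(rng.standard_normal((100, 10)), prefix="LV")
        assert len(lvspace.top_variable_lvs(B, 0.05)) == 5
        assert len(lvspace.top_variable_lvs(B, 0.051)) == 6

    def test_constant_lv_never_selected(self, rng):
        arr = rng.standard_normal((10, 8))
        arr[3] = 2.0
        B = _df(arr, prefix="LV")
        assert "LV3" not in lvspace.top_variable_lvs(B, 0.5)

    def test_matches_exhaustive_sd_ranking(self, rng):
        B = _df(rng.standard_normal((50, 20)), prefix="LV")
        got = lvspace.top_variable_lvs(B, 0.2)
        sd = B.std(axis=1, ddof=1)
        expected = list(sd.sort_values(ascending=False, kind="stable").index[:10])
        assert got == expected

    def test_fraction_validation(self, rng):
        B = _df(rng.standard_normal((10, 5)), prefix="LV")
        with pytest.raises(ParameterError):
            lvspace.top_variable_lvs(B, 0.0)


class TestBatchAssessment:
    @staticmethod
    def _confounded_cohort(batch_shift, seed):
        model = synthgen.gen_model(200, 15, 0.2, seed=seed)
        return synthgen.gen_cohort(
            model,
            {"cNF": 8, "MPNST": 8},
            planted_per_class=2,
            effect_size=1.0,
            noise_sd=0.5,
            batch_map={"cNF": "studyA", "MPNST": "studyB"},
            batch_shift=batch_shift,
            batch_gene_frac=0.2,
            seed=seed + 1,
        )

    def test_planted_batch_detected(self):
        expr, meta, truth = self._confounded_cohort(batch_shift=2.0, seed=31)
        res = lvspace.pca_batch_assessment(expr, truth.lv_scores, meta)
        assert res["p_value"] < 0.01
        # batch structure inflates between-study spread, so the *normalized*
        # within-study distances are the smaller ones in the batched space
        assert res["median_gene"] < res["median_lv"]

    def test_swapping_inputs_flips_direction(self):
        expr, meta, truth = self._confounded_cohort(batch_shift=2.0, seed=37)
        fwd = lvspace.pca_batch_assessment(expr, truth.lv_scores, meta)
        rev = lvspace.pca_batch_assessment(truth.lv_scores, expr, meta)
        assert fwd["p_value"] == pytest.approx(rev["p_value"], rel=1e-9)
        assert (fwd["median_gene"] > fwd["median_lv"]) != (
            rev["median_gene"] > rev["median_lv"]
        )

    def test_singleton_studies_skipped_and_all_skipped_errors(self, rng):
        expr = _df(rng.standard_normal((20, 4)))
        B = _df(rng.standard_normal((5, 4)), prefix="LV")
        meta = pd.DataFrame(
            {
                "sample_id": [f"s{j}" for j in range(4)],
                "tumor_type": ["cNF"] * 4,
                "study_id": ["a", "b", "c", "d"],
            }
        )
        with pytest.raises(ParameterError):
            lvspace.pca_batch_assessment(expr, B, meta)
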