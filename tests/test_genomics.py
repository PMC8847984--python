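"""SNV/CNV retention, lesion association, and OPLS modeling."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from metac.core.types import ExpressionMatrix
from metac.genomics import (
    call_cnv,
    cnv_call_matrix,
    cnv_dual_association,
    cnv_gene_filters,
    filter_snvs,
    lesion_fraction_association,
    opls_fit,
    selected_genes,
    snv_gene_matrix,
)
from metac.synthetic_data import GeneratorConfig, generate_cohort, generate_genomics

from oracles import mw_enumeration


def variant(sample, gene, cls, sift=None, poly=None):
    return {
        "sample_id": sample, "gene": gene, "effect_class": cls,
        "sift_deleterious": sift, "polyphen_damaging": poly,
    }


class TestFilterSnvs:
    def test_truncating_class_retained_regardless_of_predictions(self):
        df = pd.DataFrame([variant("s1", "RB1", "stopgain", sift=False)])
        kept, report = filter_snvs(df)
        assert len(kept) == 1 and report["n_retained"] == 1

    def test_nonsynonymous_needs_both_predictions_damaging(self):
        df = pd.DataFrame(
            [
                variant("s1", "A", "nonsynonymous_snv", True, False),
                variant("s1", "B", "nonsynonymous_snv", True, True),
            ]
        )
        kept, _ = filter_snvs(df)
        assert kept["gene"].tolist() == ["B"]
        kept_or, _ = filter_snvs(df, rule="or")
        assert set(kept_or["gene"]) == {"A", "B"}

    def test_other_class_and_missing_predictions_dropped(self):
        df = pd.DataFrame(
            [
                variant("s1", "A", "other"),
                variant("s1", "B", "nonsynonymous_snv"),
            ]
        )
        kept, report = filter_snvs(df)
        assert len(kept) == 0
        assert report["n_missing_predictions"] == 1

    def test_idempotent(self):
        df = pd.DataFrame(
            [variant("s1", "A", "splice"), variant("s2", "B", "nonsynonymous_snv", True, True)]
        )
        once, _ = filter_snvs(df)
        twice, _ = filter_snvs(once)
        pd.testing.assert_frame_equal(once, twice)


class TestSnvGeneMatrix:
    def test_frequency_boundary_inclusive(self):
        samples = [f"s{i}" for i in range(100)]
        df = pd.DataFrame(
            [variant("s0", "A", "stopgain"), variant("s1", "A", "stopgain"),
             variant("s0", "B", "stopgain")]
        )
        mat, freq = snv_gene_matrix(df, samples, min_freq=0.02)
        assert list(mat.index) == ["A"]  # 2/100 kept, 1/100 dropped
        assert freq["A"] == pytest.approx(0.02)

    def test_duplicate_records_count_once(self):
        samples = [f"s{i}" for i in range(10)]
        df = pd.DataFrame(
            [variant("s0", "A", "stopgain"), variant("s0", "A", "splice")]
        )
        mat, freq = snv_gene_matrix(df, samples, min_freq=0.0)
        assert freq["A"] == pytest.approx(0.1)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            snv_gene_matrix(pd.DataFrame([variant("s0", "A", "stopgain")]), [])


class TestCallCnv:
    @pytest.mark.parametrize(
        "cn, call",
        [(0, "loss"), (1, "loss"), (2, "neutral"), (3, "neutral"), (4, "gain"), (7, "gain")],
    )
    def test_thresholds(self, cn, call):
        assert call_cnv(cn) == call

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            call_cnv(-1)

    def test_total_monotone_step_function(self):
        order = {"loss": 0, "neutral": 1, "gain": 2}
        calls = [order[str(call_cnv(cn))] for cn in range(10)]
        assert calls == sorted(calls)


class TestCnvGeneFilters:
    def _expr(self, zero_counts):
        samples = [f"s{i}" for i in range(100)]
        vals = np.ones((len(zero_counts), 100))
        for g, nz in enumerate(zero_counts):
            vals[g, :nz] = 0.0
        return ExpressionMatrix(
            pd.DataFrame(vals, index=[f"g{g}" for g in range(len(zero_counts))],
                         columns=samples),
            "linear",
        )

    def _calls(self, n_genes, loss_counts):
        samples = [f"s{i}" for i in range(100)]
        mat = pd.DataFrame("neutral", index=[f"g{g}" for g in range(n_genes)],
                           columns=samples)
        for g, nl in enumerate(loss_counts):
            mat.iloc[g, :nl] = "loss"
        return mat

    def test_expression_filter_is_strict(self):
        # 3 zeros of 100 -> nonzero fraction 0.97, not > 0.97 -> dropped
        expr = self._expr([3, 2])
        calls = self._calls(2, [5, 5])
        assert cnv_gene_filters(calls, expr) == ["g1"]

    def test_cnv_filter_is_inclusive(self):
        expr = self._expr([0, 0])
        calls = self._calls(2, [3, 2])  # 3% kept, 2% dropped
        assert cnv_gene_filters(calls, expr) == ["g0"]


class TestLesionAssociation:
    def test_complete_separation_gives_exact_minimum_p(self):
        samples = [f"s{i}" for i in range(10)]
        lesions = pd.DataFrame(
            [[True] * 5 + [False] * 5], index=["G"], columns=samples
        )
        high = [0.90, 0.91, 0.92, 0.93, 0.94]
        low = [0.10, 0.11, 0.12, 0.13, 0.14]
        fractions = pd.Series(high + low, index=samples)
        tab = lesion_fraction_association(lesions, fractions)
        _, p_oracle = mw_enumeration(high, low)
        assert tab.loc["G", "p_value"] == pytest.approx(p_oracle)
        assert tab.loc["G", "p_value"] == pytest.approx(2 / 252, rel=1e-6)
        assert tab.loc["G", "direction"] == 1.0

    def test_independent_lesions_give_uniform_p(self):
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(200):
            samples = [f"s{i}" for i in range(40)]
            lesions = pd.DataFrame(
                [rng.random(40) < 0.3], index=["G"], columns=samples
            )
            fractions = pd.Series(rng.uniform(0, 1, 40), index=samples)
            tab = lesion_fraction_association(lesions, fractions)
            if len(tab):
                pvals.append(tab["p_value"].iloc[0])
        from scipy import stats as sps

        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_small_groups_skipped(self):
        samples = [f"s{i}" for i in range(5)]
        lesions = pd.DataFrame([[True, False, False, False, False]],
                               index=["G"], columns=samples)
        fractions = pd.Series(np.linspace(0, 1, 5), index=samples)
        assert len(lesion_fraction_association(lesions, fractions)) == 0


class TestCnvDualAssociation:
    def test_planted_block_fully_selected(self, default_cohort):
        truth = default_cohort["truth"]
        expr = default_cohort["expr"]
        calls = cnv_call_matrix(default_cohort["cnv"], list(expr.sample_ids))
        kept = cnv_gene_filters(calls, expr)
        tab = cnv_dual_association(
            calls.loc[kept], expr, truth.fractions["MetB"]
        )
        assert set(selected_genes(tab)) == set(truth.block_genes)
        loss_rows = tab[tab["lesion"] == "loss"]
        assert (loss_rows["expression_direction"] == -1).all()
        assert (loss_rows["fraction_direction"] == 1).all()

    def test_expression_only_or_fraction_only_not_selected(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(60)]
        carrier = np.array([True] * 20 + [False] * 40)
        calls = pd.DataFrame(
            [np.where(carrier, "loss", "neutral")] * 2, index=["gE", "gF"],
            columns=samples,
        )
        fractions = pd.Series(
            np.where(carrier, 0.7, 0.2) + rng.normal(0, 0.02, 60), index=samples
        ).clip(0, 1)
        expr = ExpressionMatrix(
            pd.DataFrame(
                {
                    s: [
                        # gE: expression responds to lesion; gF: does not
                        50.0 * (0.25 if carrier[i] else 1.0) * (1 + rng.normal(0, 0.05)),
                        30.0 * (1 + rng.normal(0, 0.05)),
                    ]
                    for i, s in enumerate(samples)
                },
                index=["gE", "gF"],
            ),
            "linear",
        )
        tab = cnv_dual_association(calls, expr, fractions)
        sel = selected_genes(tab)
        assert "gE" in sel and "gF" not in sel

    def test_null_selection_rate_near_alpha_squared(self):
        rng = np.random.default_rng(42)
        n_genes, n_samples = 3000, 100
        samples = [f"s{i}" for i in range(n_samples)]
        carrier = rng.random((n_genes, n_samples)) < 0.2
        calls = pd.DataFrame(
            np.where(carrier, "loss", "neutral"),
            index=[f"g{i}" for i in range(n_genes)], columns=samples,
        )
        expr = ExpressionMatrix(
            pd.DataFrame(rng.lognormal(3, 1, (n_genes, n_samples)),
                         index=calls.index, columns=samples),
            "linear",
        )
        fractions = pd.Series(rng.uniform(0, 1, n_samples), index=samples)
        tab = cnv_dual_association(calls, expr, fractions, alpha=0.05)
        loss = tab[tab["lesion"] == "loss"]
        rate = loss["selected"].mean()
        expected = 0.05**2
        se = np.sqrt(expected * (1 - expected) / len(loss))
        assert abs(rate - expected) <= 3 * se + 1e-12


class TestOpls:
    @staticmethod
    def random_instance(rng, n=40, m=8, n_orth=1):
        X = pd.DataFrame(rng.normal(size=(n, m)),
                         columns=[f"v{i}" for i in range(m)])
        beta = rng.normal(size=m)
        y = pd.Series(X.to_numpy() @ beta + rng.normal(0, 0.5, n))
        return X, y

    def test_rank_one_aligned_x_has_null_orthogonal_loadings(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=30)
        X = pd.DataFrame(np.outer(t, [1.0, 2.0, -1.0]) + rng.normal(0, 1e-9, (30, 3)),
                         columns=list("abc"))
        y = pd.Series(t * 2.0)
        model = opls_fit(X, y, n_orth=1)
        assert np.abs(model.orth_loadings[0]).max() < 1e-3
        assert model.r2y > 0.999

    def test_fitted_values_match_pls_with_extra_component(self):
        rng = np.random.default_rng(2)
        for n_orth in (1, 2):
            X, y = self.random_instance(rng, n_orth=n_orth)
            model = opls_fit(X, y, n_orth=n_orth)
            Xc = (X - X.mean()) / X.std(ddof=1)
            pls = PLSRegression(n_components=n_orth + 1, scale=False).fit(
                Xc.to_numpy(), (y - y.mean()).to_numpy()
            )
            yhat_pls = pls.predict(Xc.to_numpy()).ravel() + y.mean()
            np.testing.assert_allclose(model.fitted(), yhat_pls, atol=1e-6)

    def test_predictive_scores_orthogonal_to_orthogonal_scores(self):
        rng = np.random.default_rng(3)
        X, y = self.random_instance(rng)
        model = opls_fit(X, y, n_orth=2)
        for t_o in model.orth_scores:
            assert abs(model.pred_scores @ t_o) < 1e-8

    def test_shuffled_response_has_nonpositive_expected_q2(self):
        # Q2 of a permuted response is negative in expectation (individual
        # shuffles fluctuate around it), so the check averages shuffles
        rng = np.random.default_rng(4)
        X, y = self.random_instance(rng, n=70)
        q2s = [
            opls_fit(X, pd.Series(rng.permutation(y.to_numpy())), n_orth=1).q2
            for _ in range(20)
        ]
        assert np.mean(q2s) <= 0.0
        assert np.median(q2s) <= 0.0

    def test_zero_variance_column_dropped_and_rank_guard(self):
        rng = np.random.default_rng(5)
        X, y = self.random_instance(rng)
        X["dead"] = 1.0
        model = opls_fit(X, y, n_orth=1)
        assert "dead" not in model.feature_names
        with pytest.raises(ValueError, match="rank"):
            opls_fit(X.iloc[:, :3], y, n_orth=5)

    def test_knockdown_block_gets_negative_predictive_loadings(self, default_cohort):
        truth = default_cohort["truth"]
        expr = default_cohort["expr"].to_linear()
        X = expr.values.loc[truth.block_genes].T
        model = opls_fit(X, truth.fractions["MetB"], n_orth=1)
        assert (model.pred_loadings < 0).all()
        assert model.q2 > 0
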