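"""Quantile normalization, fraction solvers, aggregation, dominant calls."""

import numpy as np
import pandas as pd
import pytest

from metac.core.types import (
    ExpressionMatrix,
    SampleAnnotation,
    SignatureMatrix,
    fractions_frame,
)
from metac.deconvolution import (
    DeconvolutionConfig,
    aggregate_replicates,
    call_dominant,
    estimate_cohort,
    quantile_normalize,
    solve_fractions_nnls,
    solve_fractions_svr,
)
from metac.synthetic_data import GeneratorConfig, generate_cohort

from conftest import make_signature
from oracles import simplex_grid

NO_QN = DeconvolutionConfig(quantile_normalize=False)


class TestQuantileNormalize:
    def test_permuted_columns_become_identical_after_sorting(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 10, 20)
        df = pd.DataFrame({"s1": a, "s2": rng.permutation(a)},
                          index=[f"g{i}" for i in range(20)])
        out = quantile_normalize(ExpressionMatrix(df, "linear"))
        np.testing.assert_allclose(
            np.sort(out.values["s1"]), np.sort(out.values["s2"])
        )

    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"s1": [1.0, 5.0, 3.0], "s2": [1.0, 5.0, 3.0]},
                          index=list("abc"))
        out = quantile_normalize(ExpressionMatrix(df, "linear"))
        np.testing.assert_allclose(out.values, df.values)

    def test_hand_computed_three_by_three(self):
        df = pd.DataFrame(
            {"s1": [5.0, 1.0, 3.0], "s2": [2.0, 4.0, 6.0], "s3": [3.0, 2.0, 1.0]},
            index=list("abc"),
        )
        out = quantile_normalize(ExpressionMatrix(df, "linear")).values
        # reference quantiles: mean of per-sample sorted values
        np.testing.assert_allclose(out["s1"], [14 / 3, 4 / 3, 3.0])
        np.testing.assert_allclose(out["s2"], [4 / 3, 3.0, 14 / 3])
        np.testing.assert_allclose(out["s3"], [14 / 3, 3.0, 4 / 3])

    def test_ties_get_average_of_tied_target_quantiles(self):
        df = pd.DataFrame(
            {"s1": [1.0, 1.0, 2.0], "s2": [10.0, 20.0, 30.0]}, index=list("abc")
        )
        out = quantile_normalize(ExpressionMatrix(df, "linear")).values
        ref = np.sort(df.values, axis=0).mean(axis=1)
        np.testing.assert_allclose(
            out["s1"], [(ref[0] + ref[1]) / 2, (ref[0] + ref[1]) / 2, ref[2]]
        )


class TestSolvers:
    def test_exact_two_component_mixture_recovered(self):
        sig = make_signature()
        mix = 0.7 * sig.values["MetA"] + 0.3 * sig.values["MetB"]
        est = solve_fractions_svr(mix, sig)
        np.testing.assert_allclose(est.fractions, [0.7, 0.3, 0.0], atol=1e-3)
        est_nnls = solve_fractions_nnls(mix, sig)
        np.testing.assert_allclose(est_nnls.fractions, [0.7, 0.3, 0.0], atol=1e-9)

    def test_pure_profile_gives_unit_vector(self):
        sig = make_signature()
        est = solve_fractions_svr(sig.values["MetC"], sig)
        np.testing.assert_allclose(est.fractions, [0.0, 0.0, 1.0], atol=1e-3)
        assert est.dominant == "MetC"

    def test_mixture_outside_reference_span_flagged_degenerate(self):
        # references live on the first genes, the mixture only on the rest
        vals = np.zeros((6, 3))
        vals[:3] = [[4.0, 1.0, 1.0], [1.0, 4.0, 1.0], [1.0, 1.0, 4.0]]
        sig = SignatureMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(6)],
                         columns=["MetA", "MetB", "MetC"]),
            "linear",
        )
        mix = pd.Series([0.0] * 3 + [5.0, 7.0, 9.0], index=sig.gene_ids)
        est = solve_fractions_nnls(mix, sig)
        assert est.degenerate
        np.testing.assert_allclose(est.fractions, [1 / 3] * 3)

    def test_nnls_beats_simplex_grid_oracle(self):
        rng = np.random.default_rng(4)
        sig = make_signature(n_per_subtype=7, seed=4)
        S = sig.values.to_numpy()
        for _ in range(5):
            f = rng.dirichlet([1, 1, 1])
            mix = pd.Series(S @ f * (1 + rng.normal(0, 0.05, S.shape[0])),
                            index=sig.gene_ids).clip(lower=0)
            est = solve_fractions_nnls(mix, sig)
            # nnls optimizes over a superset of the simplex: its residual
            # cannot exceed the best 0.01-resolution simplex point
            m = mix.to_numpy()
            best_grid = min(np.sum((S @ g - m) ** 2) for g in simplex_grid(0.01))
            assert est.rmse**2 * S.shape[0] <= best_grid + 1e-9

    def test_svr_and_nnls_agree_on_exact_mixtures(self):
        rng = np.random.default_rng(2)
        sig = make_signature(seed=2)
        for _ in range(5):
            f = rng.dirichlet([2, 1, 1])
            mix = pd.Series(sig.values.to_numpy() @ f, index=sig.gene_ids)
            a = solve_fractions_svr(mix, sig).fractions
            b = solve_fractions_nnls(mix, sig).fractions
            assert np.abs(a - b).max() < 0.05


class TestEstimateCohort:
    def test_pure_profile_cohort_yields_identity(self):
        sig = make_signature()
        expr = ExpressionMatrix(
            sig.values.rename(columns={"MetA": "s1", "MetB": "s2", "MetC": "s3"}),
            "linear",
        )
        ests = estimate_cohort(expr, sig, NO_QN)
        mat = np.array([e.fractions for e in ests])
        np.testing.assert_allclose(mat, np.eye(3), atol=1e-3)

    def test_noiseless_generator_cohort_recovered(self):
        cfg = GeneratorConfig(
            seed=5, n_samples=30, n_genes=400, n_marker_per_subtype=17,
            noise_sigma_log2=0.0,
        )
        expr, _, truth = generate_cohort(cfg)
        sig = SignatureMatrix(truth.profiles.loc[truth.all_markers], "linear")
        ests = estimate_cohort(expr, sig, NO_QN)
        for e in ests:
            err = np.abs(e.fractions - truth.fractions.loc[e.sample_id].to_numpy())
            assert err.max() < 1e-3

    def test_sample_permutation_equivariance_and_gene_order_invariance(self):
        cfg = GeneratorConfig(seed=6, n_samples=6, n_genes=400,
                              n_marker_per_subtype=17)
        expr, _, truth = generate_cohort(cfg)
        sig = SignatureMatrix(truth.profiles.loc[truth.all_markers], "linear")
        base = {e.sample_id: e.fractions for e in estimate_cohort(expr, sig, NO_QN)}
        perm = expr.subset(samples=list(reversed(expr.sample_ids)))
        for e in estimate_cohort(perm, sig, NO_QN):
            np.testing.assert_allclose(e.fractions, base[e.sample_id], atol=1e-9)
        rng = np.random.default_rng(0)
        shuffled_genes = list(rng.permutation(expr.gene_ids))
        gperm = expr.subset(genes=shuffled_genes)
        for e in estimate_cohort(gperm, sig, NO_QN):
            np.testing.assert_allclose(e.fractions, base[e.sample_id], atol=1e-9)


class TestAggregateAndDominant:
    @staticmethod
    def _annotation(rows):
        df = pd.DataFrame(rows).set_index("sample_id")
        return SampleAnnotation(df)

    def _estimate(self, sid, fractions):
        from metac.core.types import FractionEstimate

        dom, tie = call_dominant(np.asarray(fractions))
        return FractionEstimate(sid, np.asarray(fractions, float), 0.1, 0.9, dom, tie)

    def test_replicates_averaged_and_renormalized(self):
        ann = self._annotation(
            [
                {"sample_id": "a", "patient_id": "p1", "timepoint_id": "T0",
                 "treatment_state": "hormone_naive", "metastatic_site": "bone",
                 "survival_time": 1.0, "event": True},
                {"sample_id": "b", "patient_id": "p1", "timepoint_id": "T0",
                 "treatment_state": "hormone_naive", "metastatic_site": "bone",
                 "survival_time": 1.0, "event": True},
            ]
        )
        out = aggregate_replicates(
            [self._estimate("a", [0.8, 0.1, 0.1]), self._estimate("b", [0.6, 0.3, 0.1])],
            ann,
        )
        assert len(out) == 1
        np.testing.assert_allclose(out[0].fractions, [0.7, 0.2, 0.1])

    def test_single_sample_group_unchanged(self):
        ann = self._annotation(
            [{"sample_id": "a", "patient_id": "p1", "timepoint_id": "T0",
              "treatment_state": "hormone_naive", "metastatic_site": "bone",
              "survival_time": 1.0, "event": True}]
        )
        est = self._estimate("a", [0.5, 0.25, 0.25])
        out = aggregate_replicates([est], ann)
        assert out == [est]

    def test_two_timepoints_stay_separate(self):
        ann = self._annotation(
            [
                {"sample_id": "a", "patient_id": "p1", "timepoint_id": "T0",
                 "treatment_state": "hormone_naive", "metastatic_site": "bone",
                 "survival_time": 1.0, "event": True},
                {"sample_id": "b", "patient_id": "p1", "timepoint_id": "T1",
                 "treatment_state": "castration_resistant", "metastatic_site": "bone",
                 "survival_time": 1.0, "event": True},
            ]
        )
        out = aggregate_replicates(
            [self._estimate("a", [0.9, 0.05, 0.05]), self._estimate("b", [0.2, 0.7, 0.1])],
            ann,
        )
        assert len(out) == 2

    @pytest.mark.parametrize(
        "fractions, expected, tie",
        [
            ([0.6, 0.3, 0.1], "MetA", False),
            ([0.2, 0.5, 0.3], "MetB", False),
            ([0.5, 0.5, 0.0], "MetA", True),
            ([1 / 3, 1 / 3, 1 / 3], "MetA", True),
        ],
    )
    def test_dominant_call_and_tie_rule(self, fractions, expected, tie):
        dom, flag = call_dominant(np.array(fractions))
        assert (dom, flag) == (expected, tie)

    def test_fraction_frame_round_trip(self):
        ests = [self._estimate("a", [0.6, 0.3, 0.1])]
        frame = fractions_frame(ests)
        assert frame.loc["a", "dominant"] == "MetA"
        np.testing.assert_allclose(frame.loc["a", ["MetA", "MetB", "MetC"]].astype(float),
                                   [0.6, 0.3, 0.1])
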