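"""DDI/non-DDI ensemble: preprocessing, NSC, PCA, clustering, overall call."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_average_linkage
from gentox.tgxddi import (
    DDI,
    NON_DDI,
    UNCLASSIFIABLE,
    BiomarkerMatrix,
    ConcentrationCall,
    TgxDdiClassifier,
    TrainingSet,
    classify_hclust,
    classify_nsc,
    classify_pca,
    fit_nsc,
    overall_ddi_call,
    preprocess_expression,
)


def _conditions_matrix(rows: dict[tuple, np.ndarray], genes) -> BiomarkerMatrix:
    values = pd.DataFrame(rows, index=genes).T
    values.index.names = ["compound", "concentration"]
    return BiomarkerMatrix(values=values)


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------


class TestPreprocess:
    def _design(self, samples, controls):
        rows = []
        for s in samples:
            rows.append((s, "X", 10.0, 1, False))
        for c in controls:
            rows.append((c, "DMSO", 0.0, 1, True))
        return pd.DataFrame(
            rows, columns=["sample", "compound", "concentration", "replicate",
                           "is_control"]
        ).set_index("sample")

    def test_identical_counts_give_zero_fold_change(self):
        counts = pd.DataFrame(
            {"t1": [10, 20, 30], "c1": [10, 20, 30]},
            index=["gA", "gB", "gC"],
        )
        out = preprocess_expression(counts, self._design(["t1"], ["c1"]))
        assert np.allclose(out.values.to_numpy(), 0.0)

    def test_probe_collapse_is_mean_on_log_scale(self):
        # two probes of one gene with log2(CPM+1) values 2 and 4 -> 3
        lib = 1_000_000
        counts = pd.DataFrame(
            {"t1": [3, 15, lib - 18], "c1": [3, 15, lib - 18]},
            index=["p1", "p2", "other"],
        )
        probe_map = {"p1": "gA", "p2": "gA", "other": "gB"}
        # log2(3+1)=2, log2(15+1)=4 exactly at equal library sizes
        out = preprocess_expression(
            counts, self._design(["t1"], ["c1"]), probe_map=probe_map
        )
        # fold-change is 0 (treated == control); check the collapse directly
        cpm = counts / counts.sum() * 1e6
        logc = np.log2(cpm + 1)
        collapsed = logc.loc[["p1", "p2"]].mean()
        assert collapsed["t1"] == pytest.approx(3.0)
        assert set(out.genes) == {"gA", "gB"}

    def test_cpm_columns_sum_to_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(40, 4)),
            index=[f"g{i}" for i in range(40)],
            columns=["t1", "t2", "c1", "c2"],
        )
        cpm = counts / counts.sum() * 1e6
        assert np.allclose(cpm.sum(axis=0), 1e6)

    def test_missing_design_sample_rejected(self):
        counts = pd.DataFrame({"t1": [1], "mystery": [1]}, index=["g"])
        with pytest.raises(ValueError, match="absent from design"):
            preprocess_expression(counts, self._design(["t1"], []))

    def test_cytotoxic_condition_dropped(self):
        counts = pd.DataFrame(
            {"t1": [10, 20], "t2": [30, 10], "c1": [10, 20]},
            index=["gA", "gB"],
        )
        design = pd.DataFrame(
            [("t1", "X", 10.0, 1, False), ("t2", "X", 30.0, 1, False),
             ("c1", "DMSO", 0.0, 1, True)],
            columns=["sample", "compound", "concentration", "replicate", "is_control"],
        ).set_index("sample")
        out = preprocess_expression(
            counts, design, viability={("X", 30.0): 20.0}
        )
        assert ("X", 30.0) not in out.conditions
        assert ("X", 10.0) in out.conditions


# --------------------------------------------------------------------------
# NSC
# --------------------------------------------------------------------------


class TestNSC:
    def test_delta_zero_centroids_equal_class_means(self, small_training):
        model = fit_nsc(small_training, delta=0.0)
        for k, cls in enumerate(model.classes):
            mean = small_training.matrix[small_training.labels == cls].mean(axis=0)
            assert np.allclose(model.shrunken_centroids[k], mean.to_numpy())

    def test_full_shrinkage_collapses_to_overall_centroid(self, small_training):
        model = fit_nsc(small_training, delta=1e6)
        for k in range(2):
            assert np.allclose(
                model.shrunken_centroids[k], model.overall_centroid
            )

    def test_centroids_match_hand_computation(self, small_training):
        """Explicit elementwise evaluation of the shrunken-centroid formulas."""
        delta = 0.8
        model = fit_nsc(small_training, delta=delta)
        X = small_training.matrix.to_numpy()
        y = small_training.labels.to_numpy()
        n = len(y)
        for k, cls in enumerate(model.classes):
            nk = (y == cls).sum()
            mk = np.sqrt(1.0 / nk + 1.0 / n)
            for j in range(X.shape[1]):
                xbar = X[:, j].mean()
                xbar_k = X[y == cls, j].mean()
                # pooled within-class SD over both classes
                ss = sum(
                    ((X[y == c2, j] - X[y == c2, j].mean()) ** 2).sum()
                    for c2 in model.classes
                )
                sj = np.sqrt(ss / (n - 2))
                d_kj = (xbar_k - xbar) / (mk * (sj + model.s0))
                d_shr = np.sign(d_kj) * max(abs(d_kj) - delta, 0.0)
                expected = xbar + mk * (sj + model.s0) * d_shr
                assert model.shrunken_centroids[k, j] == pytest.approx(expected)

    def test_shrunken_deviations_never_exceed_unshrunken(self, small_training):
        m0 = fit_nsc(small_training, delta=0.0)
        m1 = fit_nsc(small_training, delta=0.5)
        dev0 = np.abs(m0.shrunken_centroids - m0.overall_centroid)
        dev1 = np.abs(m1.shrunken_centroids - m1.overall_centroid)
        assert np.all(dev1 <= dev0 + 1e-12)

    def test_posteriors_sum_to_one_and_match_formula(self, small_training):
        model = fit_nsc(small_training, delta=0.2)
        rng = np.random.default_rng(1)
        for _ in range(20):
            profile = rng.normal(0, 2, 4)
            post, _ = classify_nsc(model, profile)
            assert sum(post.values()) == pytest.approx(1.0)
            # brute-force discriminant evaluation
            scale = (model.s + model.s0) ** 2
            deltas = [
                ((profile - model.shrunken_centroids[k]) ** 2 / scale).sum()
                - 2 * np.log(model.priors[k])
                for k in range(2)
            ]
            expected = np.exp(-0.5 * np.array(deltas))
            expected /= expected.sum()
            assert post[model.classes[0]] == pytest.approx(expected[0])

    def test_centroid_self_classification(self, small_training):
        model = fit_nsc(small_training, delta=0.0)
        post, call = classify_nsc(model, model.shrunken_centroids[0])
        assert post[DDI] > 0.90
        assert call == DDI

    def test_equidistant_profile_unclassifiable(self, small_training):
        model = fit_nsc(small_training, delta=0.0)
        midpoint = model.shrunken_centroids.mean(axis=0)
        post, call = classify_nsc(model, midpoint)
        assert post[DDI] == pytest.approx(0.5)
        assert call == UNCLASSIFIABLE

    def test_degenerate_training_rejected(self):
        genes = ["g1", "g2"]
        matrix = pd.DataFrame(
            {"D0": [1, 1], "D1": [1, 1], "N0": [0, 0], "N1": [0, 0]},
            index=genes,
        ).T
        labels = pd.Series({"D0": DDI, "D1": DDI, "N0": NON_DDI, "N1": NON_DDI})
        with pytest.raises(ValueError, match="zero within-class variance"):
            fit_nsc(TrainingSet(matrix=matrix, labels=labels))


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------


class TestPCA:
    def test_ddi_training_chemical_projects_negative(self, small_training):
        samples = _conditions_matrix(
            {("X", 1.0): small_training.matrix.loc["D0"].to_numpy()},
            small_training.genes,
        )
        out = classify_pca(small_training, samples)
        assert out["pc1"].iloc[0] < 0
        assert out["call"].iloc[0] == DDI

    def test_training_mean_projects_to_zero_and_nonddi(self, small_training):
        mean = small_training.matrix.mean(axis=0).to_numpy()
        samples = _conditions_matrix({("X", 1.0): mean}, small_training.genes)
        out = classify_pca(small_training, samples)
        assert out["pc1"].iloc[0] == pytest.approx(0.0, abs=1e-10)
        assert out["call"].iloc[0] == NON_DDI  # PC1 == 0 is the non-DDI side

    def test_zero_profile_projection_arithmetic(self, small_training):
        """An all-zero profile projects to -(training means) . loading."""
        samples = _conditions_matrix(
            {("X", 1.0): np.zeros(4)}, small_training.genes
        )
        out = classify_pca(small_training, samples)
        from gentox.tgxddi import _pca_axis

        center, sd, axis, _ = _pca_axis(small_training)
        expected = (np.zeros(4) - center) @ axis
        assert out["pc1"].iloc[0] == pytest.approx(expected)

    def test_round_trip_training_scores(self, small_training):
        """Projecting the training set reproduces its own fitted scores."""
        from gentox.tgxddi import _pca_axis

        center, sd, axis, train_scores = _pca_axis(small_training)
        samples = _conditions_matrix(
            {
                (chem, 1.0): small_training.matrix.loc[chem].to_numpy()
                for chem in small_training.matrix.index
            },
            small_training.genes,
        )
        out = classify_pca(small_training, samples)
        assert np.allclose(out["pc1"].to_numpy(), train_scores)


# --------------------------------------------------------------------------
# hierarchical clustering
# --------------------------------------------------------------------------


class TestHclust:
    def test_sample_identical_to_ddi_chemical(self, small_training):
        samples = _conditions_matrix(
            {("X", 1.0): small_training.matrix.loc["D1"].to_numpy()},
            small_training.genes,
        )
        out = classify_hclust(small_training, samples)
        assert out["call"].iloc[0] == DDI

    def test_sample_at_blob_centers(self, small_training):
        ddi_center = small_training.matrix[small_training.labels == DDI].mean(axis=0)
        non_center = small_training.matrix[small_training.labels == NON_DDI].mean(axis=0)
        samples = _conditions_matrix(
            {("X", 1.0): ddi_center.to_numpy(), ("Y", 1.0): non_center.to_numpy()},
            small_training.genes,
        )
        out = classify_hclust(small_training, samples)
        assert out.loc[("X", 1.0), "call"] == DDI
        assert out.loc[("Y", 1.0), "call"] == NON_DDI

    def test_far_orthogonal_sample_unclassifiable(self, small_training):
        """A distant outlier forms its own top-level branch."""
        far = np.array([0.0, 0.0, 0.0, 300.0])
        samples = _conditions_matrix({("X", 1.0): far}, small_training.genes)
        out = classify_hclust(small_training, samples)
        assert out["call"].iloc[0] == UNCLASSIFIABLE

    def test_agrees_with_brute_force_linkage(self, small_training):
        """scipy average-linkage top split matches a naive implementation."""
        rng = np.random.default_rng(3)
        for trial in range(20):
            X = np.vstack(
                [
                    small_training.matrix.to_numpy(),
                    rng.normal(0, 1.5, size=(rng.integers(1, 5), 4)),
                ]
            )
            from scipy.cluster.hierarchy import fcluster, linkage

            assign = fcluster(linkage(X, "average"), t=2, criterion="maxclust")
            scipy_parts = {
                frozenset(np.nonzero(assign == c)[0].tolist())
                for c in np.unique(assign)
            }
            brute = {
                frozenset(c) for c in brute_force_average_linkage(X, k=2)
            }
            assert scipy_parts == brute


# --------------------------------------------------------------------------
# overall call and end-to-end classifier
# --------------------------------------------------------------------------


class TestOverallCall:
    def _call(self, method, call, conc=1.0):
        return ConcentrationCall(condition=("X", conc), method=method, call=call)

    def test_all_negative(self):
        calls = [self._call(m, NON_DDI) for m in ("NSC", "PCA", "HC")]
        assert overall_ddi_call(calls) == NON_DDI

    def test_single_positive_anywhere_wins(self):
        calls = [
            self._call("NSC", NON_DDI, 1.0),
            self._call("PCA", UNCLASSIFIABLE, 1.0),
            self._call("HC", DDI, 10.0),
        ]
        assert overall_ddi_call(calls) == DDI

    def test_all_unclassifiable_is_negative(self):
        calls = [self._call(m, UNCLASSIFIABLE) for m in ("NSC", "PCA", "HC")]
        assert overall_ddi_call(calls) == NON_DDI

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            overall_ddi_call([])


class TestClassifierEndToEnd:
    def test_recovers_truth_on_simulated_study(self):
        from gentox.simulate import SimulationConfig, simulate_expression_study

        cfg = SimulationConfig(seed=21)
        training, samples, truth = simulate_expression_study(cfg)
        clf = TgxDdiClassifier(training)
        calls = clf.overall_calls(samples)
        for compound, label in truth.class_label.items():
            assert calls[compound] == label
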