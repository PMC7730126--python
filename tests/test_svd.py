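import numpy as np
import pandas as pd
import pytest

from morphoscreen.effects import PHENOTYPES
from morphoscreen.svd import (
    measurement_contributions,
    pc_phenotype_correlation,
    phenotype_cooccurrence_clustering,
    scale_features,
    select_components,
    svd_decompose,
)


def frame(X, prefix="m"):
    df = pd.DataFrame(X, columns=[f"{prefix}{i}" for i in range(X.shape[1])])
    df.insert(0, "well_id", "A1")
    df.insert(1, "colony_id", range(len(df)))
    return df


class TestScaleFeatures:
    def test_zscore_definition(self):
        rng = np.random.default_rng(0)
        Z, dropped = scale_features(frame(rng.normal(3, 7, (40, 5))))
        assert dropped == []
        assert np.all(np.abs(Z.mean(axis=0)) < 1e-10)
        assert np.all(np.abs(Z.std(axis=0, ddof=0) - 1) < 1e-10)

    def test_constant_column_dropped_and_logged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 4))
        X[:, 2] = 5.0
        Z, dropped = scale_features(frame(X))
        assert dropped == ["m2"]
        assert "m2" not in Z.columns

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        Z, _ = scale_features(frame(rng.normal(size=(25, 3))))
        Z2, _ = scale_features(frame(np.asarray(Z)))
        assert np.allclose(np.asarray(Z), np.asarray(Z2))

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            scale_features(frame(np.ones((10, 3))))


class TestSVDDecompose:
    def test_rank_one_matrix(self):
        u = np.arange(1, 9, dtype=float)[:, None]
        v = np.array([[2.0, -1.0, 0.5]])
        res = svd_decompose(u @ v)
        assert np.isclose(res.variance_explained[0], 1.0)
        assert np.all(res.variance_explained[1:] < 1e-20)

    def test_matches_covariance_eigen_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 6))
        X -= X.mean(axis=0)
        res = svd_decompose(X)
        # independent oracle: eigendecomposition of X^T X
        evals, evecs = np.linalg.eigh(X.T @ X)
        order = np.argsort(evals)[::-1]
        assert np.allclose(res.singular_values**2, evals[order], atol=1e-8)
        for k in range(6):
            v = evecs[:, order[k]]
            assert min(
                np.abs(res.loadings[:, k] - v).max(),
                np.abs(res.loadings[:, k] + v).max(),
            ) < 1e-8
        recon = res.colony_scores @ np.diag(res.singular_values) @ res.loadings.T
        assert np.abs(recon - X).max() < 1e-8

    def test_variance_explained_properties(self):
        rng = np.random.default_rng(4)
        res = svd_decompose(rng.normal(size=(30, 8)))
        assert np.isclose(res.variance_explained.sum(), 1.0)
        assert np.all(np.diff(res.variance_explained) <= 1e-12)

    def test_sign_convention_reproducible(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 5))
        a, b = svd_decompose(X), svd_decompose(X.copy())
        assert np.allclose(a.loadings, b.loadings)
        for k in range(5):
            j = np.argmax(np.abs(a.loadings[:, k]))
            assert a.loadings[j, k] > 0

    def test_nonfinite_rejected(self):
        X = np.ones((5, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            svd_decompose(X)


class TestSelectComponents:
    def test_simple_threshold(self):
        res = svd_decompose(np.diag([4.0, 2.0]) @ np.eye(2))
        res.variance_explained = np.array([0.8, 0.2])
        assert select_components(res, threshold=0.73, max_k=10) == [0]

    def test_ten_component_selection(self):
        # engineered spectrum: cumulative variance crosses 0.73 at k = 10
        shares = np.array([0.15, 0.10, 0.09, 0.074, 0.065,
                           0.06, 0.06, 0.06, 0.05, 0.041])
        rest = (1 - shares.sum()) / 10
        full = np.concatenate([shares, np.full(10, rest)])
        res = svd_decompose(np.eye(20))
        res.variance_explained = full
        sel = select_components(res, threshold=0.73, max_k=10)
        assert len(sel) == 10
        assert np.cumsum(full)[9] >= 0.73

    def test_floor_of_one(self):
        res = svd_decompose(np.eye(3))
        assert select_components(res, threshold=0.0) == [0]


class TestAssociations:
    def build_planted(self, n_wells=30, colonies_per_well=20, seed=0):
        """All three features track the well's polarized frequency, so the
        first component is the frequency direction by construction."""
        rng = np.random.default_rng(seed)
        wells = [f"W{i}" for i in range(n_wells)]
        freqs = rng.uniform(0, 1, n_wells)
        rows, well_col = [], []
        for w, f in zip(wells, freqs):
            for _ in range(colonies_per_well):
                rows.append([f * 40.0 + rng.normal(0, 0.5),
                             -f * 3.0 + rng.normal(0, 0.05),
                             f * 10.0 + rng.normal(0, 0.2)])
                well_col.append(w)
        df = pd.DataFrame(rows, columns=["m0", "m1", "m2"])
        profiles = pd.DataFrame({
            "well_id": wells,
            "f_polarized": freqs,
            "f_non_polarized": 1 - freqs,
            "f_spread": 0.0,
            "f_inverted": 0.0,
            "n_colonies": colonies_per_well,
        })
        return df, pd.Series(well_col), profiles

    def test_planted_feature_dominates_pc1(self):
        df, wells, profiles = self.build_planted()
        Z, _ = scale_features(df, ["m0", "m1", "m2"])
        res = svd_decompose(Z)
        assoc = pc_phenotype_correlation(res, wells, profiles, components=[0])
        row = assoc[(assoc.component == 0) & (assoc.phenotype == "polarized")]
        assert abs(row["pcc"].iloc[0]) >= 0.95

    def test_constant_frequency_flagged_undefined(self):
        df, wells, profiles = self.build_planted()
        Z, _ = scale_features(df, ["m0", "m1", "m2"])
        res = svd_decompose(Z)
        assoc = pc_phenotype_correlation(res, wells, profiles, components=[0])
        spread = assoc[assoc.phenotype == "spread"].iloc[0]
        assert spread["undefined"]
        assert np.isnan(spread["pcc"])

    def test_permutation_null_bounds_correlation(self):
        df, wells, profiles = self.build_planted(seed=1)
        Z, _ = scale_features(df, ["m0", "m1", "m2"])
        res = svd_decompose(Z)
        rng = np.random.default_rng(6)
        n = len(wells)
        hits = 0
        n_perm = 50
        for _ in range(n_perm):
            permuted = pd.Series(rng.permutation(wells.to_numpy()))
            assoc = pc_phenotype_correlation(res, permuted, profiles,
                                             components=[0])
            r = assoc[assoc.phenotype == "polarized"]["pcc"].iloc[0]
            if abs(r) > 3 / np.sqrt(n):
                hits += 1
        assert hits / n_perm <= 0.05

    def test_well_level_variant(self):
        df, wells, profiles = self.build_planted()
        Z, _ = scale_features(df, ["m0", "m1", "m2"])
        res = svd_decompose(Z)
        assoc = pc_phenotype_correlation(res, wells, profiles,
                                         components=[0], well_level=True)
        row = assoc[assoc.phenotype == "polarized"]
        assert abs(row["pcc"].iloc[0]) >= 0.95
        assert row["n"].iloc[0] == profiles.shape[0]


class TestContributions:
    def test_planted_family_dominance(self):
        # a component whose loadings live entirely in the intensity block
        from morphoscreen.svd import SVDResult

        cols = [f"i{k}" for k in range(3)] + [f"t{k}" for k in range(3)]
        families = {c: ("intensity" if c.startswith("i") else "texture")
                    for c in cols}
        V = np.zeros((6, 2))
        V[:3, 0] = np.array([0.6, 0.64, 0.48])
        V[3:, 1] = 1 / np.sqrt(3)
        res = SVDResult(np.zeros((10, 2)), V, np.array([2.0, 1.0]),
                        np.array([0.8, 0.2]), cols)
        out = measurement_contributions(res, 0, families, top_n=2)
        assert out["families"]["intensity"]["share"] >= 0.99
        assert out["families"]["texture"]["share"] <= 0.01

    def test_top_sets_disjoint_and_unit_norm(self):
        rng = np.random.default_rng(8)
        df = frame(rng.normal(size=(40, 10)))
        cols = [c for c in df.columns if c.startswith("m")]
        Z, _ = scale_features(df, cols)
        res = svd_decompose(Z)
        out = measurement_contributions(
            res, 0, {c: "intensity" for c in cols}, top_n=4
        )
        pos = {n for n, _ in out["top_positive"]}
        neg = {n for n, _ in out["top_negative"]}
        assert pos.isdisjoint(neg)
        assert np.isclose((res.loadings[:, 0] ** 2).sum(), 1.0)

    def test_unknown_family_raises(self):
        rng = np.random.default_rng(9)
        df = frame(rng.normal(size=(20, 4)))
        cols = [c for c in df.columns if c.startswith("m")]
        Z, _ = scale_features(df, cols)
        res = svd_decompose(Z)
        with pytest.raises(KeyError):
            measurement_contributions(res, 0, {cols[0]: "intensity"})


class TestCooccurrenceClustering:
    def planted_profiles(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.1, 0.6, n)
        pol = base + rng.normal(0, 0.05, n)
        npol = 0.8 * base + rng.normal(0, 0.05, n)     # r ~ 0.8 with pol
        inv = 0.9 - base + rng.normal(0, 0.05, n)      # anti-correlated
        spread = rng.uniform(0, 0.3, n)
        return pd.DataFrame({
            "well_id": [f"W{i}" for i in range(n)],
            "f_polarized": pol, "f_non_polarized": npol,
            "f_spread": spread, "f_inverted": inv,
        })

    def test_first_merge_polarized_with_non_polarized(self):
        out = phenotype_cooccurrence_clustering(self.planted_profiles())
        assert set(out["first_merge"]) == {"polarized", "non_polarized"}

    def test_identical_vectors_merge_at_zero(self):
        prof = self.planted_profiles()
        prof["f_non_polarized"] = prof["f_polarized"]
        out = phenotype_cooccurrence_clustering(prof)
        assert out["linkage"][0, 2] < 1e-12

    def test_leaves_are_the_four_phenotypes(self):
        out = phenotype_cooccurrence_clustering(self.planted_profiles())
        assert out["labels"] == list(PHENOTYPES)
        assert out["linkage"].shape == (3, 4)

    def test_degenerate_profiles_rejected(self):
        prof = pd.DataFrame({
            "well_id": ["a", "b", "c"],
            "f_polarized": [0.25] * 3, "f_non_polarized": [0.25] * 3,
            "f_spread": [0.25] * 3, "f_inverted": [0.25] * 3,
        })
        with pytest.raises(ValueError):
            phenotype_cooccurrence_clustering(prof)
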