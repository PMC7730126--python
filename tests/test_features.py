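import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from morphoscreen import features as F
from morphoscreen.render import render_colony, ColonyIntensityParams

NOISELESS = ColonyIntensityParams(texture_amplitude=0.0, rim_clump_amplitude=0.0)


def disk_mask(radius, pad=4):
    side = 2 * (radius + pad) + 1
    mask = np.zeros((side, side), bool)
    rr, cc = draw_disk((radius + pad, radius + pad), radius)
    mask[rr, cc] = True
    return mask


def random_blob(seed, size=80):
    rng = np.random.default_rng(seed)
    mask = np.zeros((size, size), bool)
    rr, cc = draw_disk((size // 2, size // 2), 12)
    mask[rr, cc] = True
    for _ in range(6):
        cy, cx = rng.integers(size // 2 - 14, size // 2 + 14, 2)
        rr, cc = draw_disk((cy, cx), rng.integers(4, 10))
        keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
        mask[rr[keep], cc[keep]] = True
    from skimage.measure import label

    lab = label(mask, connectivity=2)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


class TestManifest:
    def test_contract_102_three_families(self):
        assert F.N_FEATURES == 102
        assert len(F.FEATURE_NAMES) == 102
        fams = pd.Series(F.FEATURE_FAMILIES)
        assert set(fams.unique()) == {"areashape", "intensity", "texture"}
        counts = fams.value_counts()
        assert counts["areashape"] == 20
        assert counts["intensity"] == 30
        assert counts["texture"] == 52

    def test_manifest_json(self, tmp_path):
        import json

        path = tmp_path / "manifest.json"
        F.write_manifest(path)
        payload = json.loads(path.read_text())
        assert payload["n_features"] == 102
        assert payload["families"] == F.FEATURE_FAMILIES


class TestAreaShape:
    def test_disk_limits(self):
        mask = disk_mask(50)
        out = F.areashape_features(mask)
        assert out["eccentricity"] < 0.05
        assert 1.0 <= out["compactness"] <= 1.1
        assert abs(out["area"] - np.pi * 50**2) <= 0.02 * np.pi * 50**2
        assert abs(out["form_factor"] * out["compactness"] - 1.0) < 1e-9

    def test_two_to_one_ellipse_eccentricity(self):
        side = 140
        mask = np.zeros((side, side), bool)
        rr, cc = draw_ellipse(side // 2, side // 2, 30, 60)
        mask[rr, cc] = True
        out = F.areashape_features(mask)
        assert abs(out["eccentricity"] - np.sqrt(1 - 0.25)) < 0.03

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_blob_definition_bounds(self, seed):
        mask = random_blob(seed)
        out = F.areashape_features(mask)
        assert out["compactness"] >= 1.0
        assert out["solidity"] <= 1.0 + 1e-12
        assert out["area"] == mask.sum()

    def test_degenerate_masks_rejected(self):
        with pytest.raises(ValueError):
            F.areashape_features(np.zeros((10, 10), bool))
        two = np.zeros((10, 10), bool)
        two[1:4, 1:4] = True
        two[6:9, 6:9] = True
        with pytest.raises(ValueError):
            F.areashape_features(two)


class TestIntensity:
    def test_constant_disk(self):
        mask = disk_mask(20)
        pixels = np.where(mask, 500.0, 0.0)
        out = F.intensity_features(mask, pixels)
        assert out["std"] == 0.0
        assert out["mass_displacement"] < 1e-9
        assert out["edge_mean"] == out["interior_mean"]
        assert out["edge_interior_ratio"] == 1.0

    def test_inverted_patch_edge_exceeds_interior(self):
        patch, mask = render_colony("inverted", 30, NOISELESS)
        out = F.intensity_features(mask, patch)
        assert out["edge_mean"] > out["interior_mean"]

    def test_order_statistics_identities(self):
        rng = np.random.default_rng(5)
        mask = disk_mask(15)
        pixels = rng.uniform(100, 900, mask.shape) * mask
        out = F.intensity_features(mask, pixels)
        assert out["min"] <= out["median"] <= out["max"]
        assert np.isclose(out["integrated"], out["mean"] * mask.sum())
        assert out["q25"] <= out["median"] <= out["q75"]


class TestRadialDistribution:
    def test_uniform_disk_flat(self):
        mask = disk_mask(30)
        pixels = np.where(mask, 700.0, 0.0)
        out = F.radial_distribution(mask, pixels)
        for r in range(1, 5):
            assert out[f"radial_cv_ring{r}"] == 0.0
            assert abs(out[f"mean_frac_ring{r}"] - 1.0) <= 0.05

    def test_polarized_annulus_peaks_in_second_ring(self):
        patch, mask = render_colony("polarized", 40, NOISELESS)
        out = F.radial_distribution(mask, patch)
        fracs = [out[f"frac_at_d_ring{r}"] for r in range(1, 5)]
        # the actin-belt annulus sits at ~0.45 relative radius -> ring 2
        assert np.argmax(fracs) == 1

    def test_half_bright_disk_high_angular_cv(self):
        mask = disk_mask(30)
        pixels = np.where(mask, 100.0, 0.0)
        pixels[:, : pixels.shape[1] // 2] *= 10
        out = F.radial_distribution(mask, pixels)
        for r in range(1, 5):
            assert out[f"radial_cv_ring{r}"] > 0.5

    def test_fracs_sum_to_one(self):
        patch, mask = render_colony("inverted", 25, NOISELESS)
        out = F.radial_distribution(mask, patch)
        assert np.isclose(sum(out[f"frac_at_d_ring{r}"] for r in range(1, 5)), 1.0)


class TestTexture:
    def test_constant_patch_degenerate_statistics(self):
        mask = disk_mask(12)
        pixels = np.where(mask, 400.0, 0.0)
        out = F.texture_features(mask, pixels)
        assert out["texture_contrast_d1_mean"] == 0.0
        assert out["texture_asm_d1_mean"] == 1.0
        assert out["texture_variance_d1_mean"] == 0.0

    def test_checkerboard_maximizes_contrast(self):
        mask = np.ones((24, 24), bool)
        yy, xx = np.mgrid[:24, :24]
        checker = ((yy + xx) % 2) * 1000.0
        smooth = yy * 10.0
        flat = np.full((24, 24), 5.0)
        contrasts = [
            F.texture_features(mask, img)["texture_contrast_d1_mean"]
            for img in (checker, smooth, flat)
        ]
        assert np.argmax(contrasts) == 0

    def test_glcm_normalized(self):
        rng = np.random.default_rng(2)
        mask = disk_mask(10)
        pixels = rng.uniform(0, 100, mask.shape)
        q = F.quantize(mask, pixels)
        P = F.masked_glcm(q, mask, 1, 0.0)
        assert np.isclose(P.sum(), 1.0)

    def test_glcm_matches_direct_construction(self):
        # independent oracle: count neighbor pairs by hand on a toy patch
        q = np.array(
            [[0, 1, 1, 2],
             [2, 0, 1, 3],
             [3, 3, 0, 1],
             [1, 2, 2, 0]], dtype=np.uint8
        )
        mask = np.ones((4, 4), bool)
        mask[0, 0] = False
        direct = np.zeros((F.N_GRAY_LEVELS, F.N_GRAY_LEVELS))
        for y in range(4):
            for x in range(3):
                if mask[y, x] and mask[y, x + 1]:
                    direct[q[y, x], q[y, x + 1]] += 1
                    direct[q[y, x + 1], q[y, x]] += 1
        direct /= direct.sum()
        P = F.masked_glcm(q, mask, 1, 0.0)
        assert np.allclose(P, direct)

    def test_haralick_on_known_matrix(self):
        # two-level checker co-occurrence: all mass off-diagonal
        P = np.zeros((8, 8))
        P[0, 1] = P[1, 0] = 0.5
        out = F.haralick_statistics(P)
        assert np.isclose(out["asm"], 0.5)
        assert np.isclose(out["contrast"], 1.0)
        assert np.isclose(out["correlation"], -1.0)
        assert np.isclose(out["entropy"], 1.0)


@pytest.fixture(scope="module")
def colony():
    rng = np.random.default_rng(9)
    patch, mask = render_colony("non_polarized", 20, rng=rng)
    return mask, patch


class TestInvariances:

    def test_translation_invariance(self, colony):
        mask, patch = colony
        base = F.colony_features(mask, patch)
        big_mask = np.zeros((161, 161), bool)
        big_img = np.zeros((161, 161))
        big_mask[40 : 40 + mask.shape[0], 55 : 55 + mask.shape[1]] = mask
        big_img[40 : 40 + mask.shape[0], 55 : 55 + mask.shape[1]] = patch
        moved = F.colony_features(big_mask, big_img)
        for name in F.FEATURE_NAMES:
            assert np.isclose(base[name], moved[name], rtol=1e-8, atol=1e-9), name

    def test_intensity_scaling_covariance(self, colony):
        mask, patch = colony
        base = F.colony_features(mask, patch)
        scaled = F.colony_features(mask, 3.0 * patch)
        for name in ("mean", "min", "max", "integrated", "edge_mean"):
            assert np.isclose(scaled[name], 3.0 * base[name])
        invariant = ["eccentricity", "compactness", "edge_interior_ratio"]
        invariant += [f"radial_cv_ring{r}" for r in range(1, 5)]
        invariant += [f"mean_frac_ring{r}" for r in range(1, 5)]
        invariant += [n for n in F.FEATURE_NAMES if n.startswith("texture_")]
        for name in invariant:
            assert np.isclose(base[name], scaled[name], rtol=1e-9, atol=1e-12), name


class TestFeatureTable:
    def test_shape_and_determinism(self, mini_plate, tmp_path):
        table = mini_plate["table"]
        feature_cols = [c for c in table.columns
                        if c not in ("well_id", "colony_id")]
        assert len(feature_cols) == 102
        assert list(feature_cols) == list(F.FEATURE_NAMES)
        n_segmented = sum(r.n_colonies for r in mini_plate["results"])
        assert len(table) == n_segmented
        assert np.isfinite(table[feature_cols].to_numpy()).all()
        rerun = F.feature_table(mini_plate["results"], mini_plate["images"])
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        table.to_csv(a, index=False)
        rerun.to_csv(b, index=False)
        assert a.read_bytes() == b.read_bytes()

    def test_linear_probe_separates_phenotypes(self, mini_plate):
        # the premise of the screen: a tiny interpretable feature subset
        # already separates the four architectures
        from sklearn.linear_model import LogisticRegression
        from sklearn.preprocessing import StandardScaler

        lab = mini_plate["labelled"]
        X = StandardScaler().fit_transform(
            lab[["edge_interior_ratio", "eccentricity", "area"]]
        )
        probe = LogisticRegression(max_iter=2000).fit(X, lab["phenotype"])
        assert probe.score(X, lab["phenotype"]) >= 0.90
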