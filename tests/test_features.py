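"""MM morphology, CL co-localization, DG encoder, view independence."""

import numpy as np
import pandas as pd
import pytest

from hdspath.bags import SlideBag
from hdspath.features import (GlobalEncoderConfig, GlobalEncoderModel,
                              colocalization_scores, morphological_features,
                              triple_junction_density,
                              view_independence_tests)
from hdspath.tilemap import BLANK, TissueMap


def _map(rows):
    return TissueMap("s", np.array(rows, dtype=object))


class TestMorphology:
    def test_all_tumor_map(self):
        mm = morphological_features(_map([["Tumor"] * 4] * 4))
        assert mm["mm_tumor_area_fraction"] == 1.0
        assert mm["mm_tumor_component_count"] == 1
        assert mm["mm_tumor_largest_component_fraction"] == 1.0
        assert mm["mm_tumor_boundary_to_area"] == 0.0
        assert mm["mm_necrosis_area_fraction"] == 0.0
        assert mm["mm_necrosis_component_count"] == 0.0

    def test_diagonal_cells_are_two_components(self):
        mm = morphological_features(_map([["Tumor", "NormalLiver"],
                                          ["NormalLiver", "Tumor"]]))
        assert mm["mm_tumor_component_count"] == 2

    def test_half_tumor_boundary_enumeration(self):
        rows = [["Tumor", "Tumor", "NormalLiver", "NormalLiver"]] * 4
        mm = morphological_features(_map(rows))
        assert mm["mm_tumor_area_fraction"] == 0.5
        assert mm["mm_tumor_component_count"] == 1
        assert mm["mm_tumor_boundary_to_area"] == 4 / 8

    def test_blank_edges_not_counted_as_boundary(self):
        rows = [["Tumor", BLANK], ["Tumor", BLANK]]
        mm = morphological_features(_map(rows))
        assert mm["mm_tumor_boundary_to_area"] == 0.0
        assert mm["mm_tumor_area_fraction"] == 1.0  # of non-Blank cells

    def test_all_blank_rejected(self):
        with pytest.raises(ValueError, match="Blank"):
            morphological_features(_map([[BLANK, BLANK]]))

    def test_fractions_in_unit_interval(self, rng):
        from hdspath.cohort import simulate_tissue_map

        for seed in range(5):
            mm = morphological_features(
                simulate_tissue_map((10, 10), "high_risk", seed=seed))
            for k, v in mm.items():
                if "fraction" in k:
                    assert 0.0 <= v <= 1.0, k


class TestColocalization:
    def test_checkerboard_full_crossing(self):
        rows = [["Tumor" if (r + c) % 2 else "Necrosis" for c in range(4)]
                for r in range(4)]
        cl = colocalization_scores(_map(rows), n_perm=10, seed=0)
        assert cl["cl_J_necrosis_tumor"] == 1.0

    def test_two_band_adjacency_enumeration(self):
        # cols 0-1 Tumor, cols 2-3 Necrosis: 4 crossing edges of the 14
        # incident to Necrosis
        rows = [["Tumor", "Tumor", "Necrosis", "Necrosis"]] * 4
        cl = colocalization_scores(_map(rows), n_perm=10, seed=0)
        assert cl["cl_J_necrosis_tumor"] == pytest.approx(4 / 14)

    def test_absent_class_scores_zero(self):
        rows = [["Tumor", "Tumor"], ["NormalLiver", "Fibrosis"]]
        cl = colocalization_scores(_map(rows), n_perm=10, seed=0)
        assert cl["cl_J_lymphocyte_tumor"] == 0.0
        assert cl["cl_triple_junction_density"] == 0.0

    def test_min_permutations_enforced(self):
        with pytest.raises(ValueError, match="n_perm"):
            colocalization_scores(_map([["Tumor", "Necrosis"]]), n_perm=5)

    def test_j_scores_bounded_and_rotation_invariant(self):
        from hdspath.cohort import simulate_tissue_map

        for seed in range(4):
            tmap = simulate_tissue_map((10, 10), "high_risk", seed=seed)
            base = colocalization_scores(tmap, n_perm=10, seed=1)
            for k, v in base.items():
                if k.startswith("cl_J") or "density" in k:
                    assert 0.0 <= v <= 1.0, k
            for transform in (np.rot90, np.fliplr):
                other = TissueMap("s", transform(tmap.labels).copy())
                got = colocalization_scores(other, n_perm=10, seed=1)
                for k in base:
                    if k.startswith("cl_J") or "density" in k:
                        assert got[k] == pytest.approx(base[k]), k

    def test_triple_junction_monotone_under_relabeling(self):
        """Relabeling a Normal cell adjacent to all three key classes to any
        of them cannot decrease the triple-junction density (3x3 sweep)."""
        rng = np.random.default_rng(0)
        cats = ["Tumor", "Necrosis", "Lymphocyte", "NormalLiver"]
        checked = 0
        for _ in range(200):
            labels = rng.choice(cats, size=(3, 3)).astype(object)
            tmap = _map(labels)
            base = triple_junction_density(tmap)
            for r in range(3):
                for c in range(3):
                    if labels[r, c] != "NormalLiver":
                        continue
                    neigh = {labels[r + dr, c + dc]
                             for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))
                             if 0 <= r + dr < 3 and 0 <= c + dc < 3}
                    if not {"Tumor", "Necrosis", "Lymphocyte"} <= neigh:
                        continue
                    for new in ("Tumor", "Necrosis", "Lymphocyte"):
                        mod = labels.copy()
                        mod[r, c] = new
                        assert triple_junction_density(_map(mod)) >= base
                        checked += 1
        assert checked > 10

    def test_permutation_z_null_calibration(self):
        """On spatially unstructured maps the enrichment z is ~N(0,1)."""
        rng = np.random.default_rng(3)
        cats = ["Tumor", "Necrosis", "Lymphocyte", "NormalLiver", "Fibrosis"]
        zs = []
        for seed in range(40):
            labels = rng.choice(cats, size=(8, 8)).astype(object)
            cl = colocalization_scores(_map(labels), n_perm=60, seed=seed)
            zs.append(cl["cl_z_necrosis_tumor"])
        assert abs(np.mean(zs)) < 0.4
        assert 0.6 < np.std(zs) < 1.6


@pytest.fixture(scope="module")
def fitted(small_cohort):
    surv = small_cohort.survival_frame()
    cfg = GlobalEncoderConfig(epochs=5, seed=3)
    return GlobalEncoderModel(small_cohort.bags, surv, cfg).fit(), small_cohort


class TestGlobalEncoder:
    def test_same_seed_identical_embeddings(self, small_cohort):
        surv = small_cohort.survival_frame()
        cfg = GlobalEncoderConfig(epochs=3, seed=5)
        e1 = GlobalEncoderModel(small_cohort.bags, surv, cfg).fit()
        e2 = GlobalEncoderModel(small_cohort.bags, surv, cfg).fit()
        np.testing.assert_array_equal(e1.embed(small_cohort.bags[0]),
                                      e2.embed(small_cohort.bags[0]))

    def test_embedding_width_fixed(self, fitted):
        enc, cohort = fitted
        for bag in cohort.bags[:5]:
            assert enc.embed(bag).shape == (enc.config.embed_dim,)

    def test_instance_order_and_duplication_invariance(self, fitted, rng):
        enc, _ = fitted
        x = rng.normal(size=(9, 16))
        bag = SlideBag("zz", {"Tumor": x[:5], "Necrosis": x[5:]})
        perm = SlideBag("zz", {"Tumor": x[:5][::-1].copy(),
                               "Necrosis": x[5:][::-1].copy()})
        dup = SlideBag("zz", {"Tumor": np.vstack([x[:5]] * 2),
                              "Necrosis": np.vstack([x[5:]] * 2)})
        np.testing.assert_allclose(enc.embed(bag), enc.embed(perm), atol=1e-12)
        np.testing.assert_allclose(enc.embed(bag), enc.embed(dup), atol=1e-12)

    def test_token_cap_respected(self, fitted, rng):
        from hdspath.features import _canonical_tokens

        bag = SlideBag("big", {"Tumor": rng.normal(size=(300, 16))})
        tokens = _canonical_tokens(bag, 128, seed=0)
        assert tokens.shape == (128, 16)

    def test_loss_decreases(self, fitted):
        enc, _ = fitted
        assert enc.train_history[-1] < enc.train_history[0]

    def test_zero_events_rejected(self, small_cohort):
        surv = small_cohort.survival_frame().copy()
        surv["event"] = 0
        with pytest.raises(ValueError, match="no events"):
            GlobalEncoderModel(small_cohort.bags, surv)

    def test_empty_bag_rejected(self, fitted):
        enc, _ = fitted
        with pytest.raises(ValueError, match="empty"):
            enc.embed(SlideBag("e", {}))


class TestViewIndependence:
    def test_identical_views_are_dependent(self, rng):
        s = rng.normal(size=200)
        out = view_independence_tests({"a": s, "b": s.copy()})
        assert out.loc[0, "p"] < 1e-10
        assert out.loc[0, "independent"] is False or not out.loc[0, "independent"]

    def test_hand_computed_two_by_two(self):
        # table {30, 20 / 20, 30} has chi2 = 4.0 (uncorrected)
        a = np.concatenate([np.zeros(50), np.ones(50)])
        b = np.concatenate([np.zeros(30), np.ones(20),
                            np.zeros(20), np.ones(30)])
        out = view_independence_tests({"a": a, "b": b})
        assert out.loc[0, "chi2"] == pytest.approx(4.0)

    def test_degenerate_margin_flagged(self):
        out = view_independence_tests({"a": np.zeros(10),
                                       "b": np.arange(10.0)})
        assert "degenerate" in out.loc[0, "note"]
        assert np.isnan(out.loc[0, "chi2"])
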