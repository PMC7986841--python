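import numpy as np
import pytest

from implantheat import safety
from implantheat.phantom import TissueModel
from implantheat.properties import COCRMO, LABEL_METAL, LABEL_MUSCLE, MUSCLE


@pytest.fixture()
def toy_model():
    """20^3 muscle block with a 3^3 metal implant at its center."""
    shape = (20, 20, 20)
    labels = np.full(shape, LABEL_MUSCLE, dtype=np.int16)
    labels[9:12, 9:12, 9:12] = LABEL_METAL
    return TissueModel(
        spacing=0.002, labels=labels,
        implant_mask=labels == LABEL_METAL,
        property_table={LABEL_MUSCLE: MUSCLE, LABEL_METAL: COCRMO},
    )


class TestMaxDeltaT:
    def test_zero_field(self, toy_model):
        assert safety.max_delta_T(np.zeros(toy_model.shape)) == 0.0

    def test_single_hot_voxel(self, toy_model):
        dT = np.zeros(toy_model.shape)
        dT[3, 4, 5] = 2.5
        assert safety.max_delta_T(dT) == 2.5

    def test_whole_body_max_bounds_region_max(self, toy_model):
        rng = np.random.default_rng(0)
        dT = rng.uniform(0, 3, toy_model.shape)
        roi = safety.RegionOfInfluence((0.02, 0.02, 0.02)).mask(toy_model)
        assert safety.max_delta_T(dT) >= safety.max_delta_T(dT, roi)

    def test_empty_mask_rejected(self, toy_model):
        with pytest.raises(ValueError):
            safety.max_delta_T(np.zeros(toy_model.shape),
                               np.zeros(toy_model.shape, bool))


class TestMassAboveThreshold:
    def test_no_voxel_above(self, toy_model):
        masses = safety.mass_above_threshold(np.zeros(toy_model.shape), toy_model, 1.0)
        assert all(v == 0.0 for v in masses.values())

    def test_three_muscle_voxels(self, toy_model):
        """3 voxels of 2 mm muscle (rho = 1090): 3 * 8e-9 m^3 * 1090 kg/m^3."""
        dT = np.zeros(toy_model.shape)
        dT[0, 0, 0] = dT[0, 0, 1] = dT[0, 0, 2] = 1.5
        masses = safety.mass_above_threshold(dT, toy_model, 1.0)
        assert masses["muscle"] == pytest.approx(0.02616)

    def test_implant_voxels_excluded(self, toy_model):
        dT = np.zeros(toy_model.shape)
        dT[toy_model.implant_mask] = 5.0
        masses = safety.mass_above_threshold(dT, toy_model, 1.0)
        assert all(v == 0.0 for v in masses.values())

    def test_monotone_in_threshold(self, toy_model):
        rng = np.random.default_rng(5)
        dT = rng.uniform(0, 4, toy_model.shape)
        m1 = safety.mass_above_threshold(dT, toy_model, 1.0)
        m3 = safety.mass_above_threshold(dT, toy_model, 3.0)
        for k in m1:
            assert m3[k] <= m1[k]

    def test_nonpositive_threshold_rejected(self, toy_model):
        with pytest.raises(ValueError):
            safety.mass_above_threshold(np.zeros(toy_model.shape), toy_model, 0.0)


class TestTimeToThreshold:
    def test_exact_step_crossing(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        m = np.array([0.0, 0.5, 1.5, 2.0])
        # crosses 1.0 between steps 1 and 2: interpolate (1-0.5)/(1.5-0.5)
        assert safety.time_to_threshold(t, m, 1.0) == pytest.approx(1.5)

    def test_hand_computed_interpolation(self):
        t = np.array([0.0, 2.0, 4.0])
        m = np.array([0.0, 0.8, 2.4])
        # running max crosses 1.0 at 2 + (1.0-0.8)/(2.4-0.8)*2 = 2.25
        assert safety.time_to_threshold(t, m, 1.0) == pytest.approx(2.25)

    def test_never_crossing_returns_none(self):
        t = np.linspace(0, 10, 11)
        m = np.full(11, 0.2)
        assert safety.time_to_threshold(t, m, 1.0) is None

    def test_nonmonotone_series_uses_running_max(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        m = np.array([0.0, 1.2, 0.5, 0.9])
        out = safety.time_to_threshold(t, m, 1.0)
        assert out == pytest.approx(1.0 / 1.2, rel=1e-12)


class TestDistanceProfile:
    def test_adjacent_voxel_distance_is_one_spacing(self, toy_model):
        dist = safety.distance_to_implant(toy_model)
        surf = safety.implant_surface(toy_model)
        # a face neighbor of the surface shell
        assert dist[12, 10, 10] == pytest.approx(toy_model.spacing)
        assert np.allclose(dist[surf], 0.0)
        assert dist.min() >= 0

    def test_matches_brute_force_nearest_neighbor(self, toy_model):
        dist = safety.distance_to_implant(toy_model)
        surf_pts = np.argwhere(safety.implant_surface(toy_model))
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.integers(0, 20, size=3)
            brute = np.sqrt(((surf_pts - p) ** 2).sum(axis=1).min()) * toy_model.spacing
            assert dist[tuple(p)] == pytest.approx(brute, rel=1e-12)

    def test_profile_sorted_and_labeled(self, toy_model):
        dT = np.zeros(toy_model.shape)
        d, v, tissue = safety.distance_profile(dT, toy_model)
        assert np.all(np.diff(d) >= 0)
        assert set(tissue) == {"muscle"}
        # implant voxels excluded
        assert d.size == int((toy_model.body_mask() & ~toy_model.implant_mask).sum())

    def test_csv_export(self, tmp_path, toy_model):
        path = tmp_path / "profile.csv"
        safety.distance_profile_csv(str(path), np.zeros(toy_model.shape), toy_model)
        header = path.read_text().splitlines()[0]
        assert header == "distance_m,delta_T_K,tissue"


class TestRegionOfInfluence:
    def test_box_contains_implant_bbox(self, toy_model):
        roi = safety.RegionOfInfluence().mask(toy_model)
        assert (roi | ~toy_model.implant_mask).all()

    def test_default_dimensions(self):
        assert safety.DEFAULT_ROI_SIZE == (0.217, 0.188, 0.282)

    def test_box_smaller_than_implant_rejected(self, toy_model):
        with pytest.raises(ValueError):
            safety.RegionOfInfluence((0.002, 0.002, 0.002)).mask(toy_model)


def test_report_roundtrip(tmp_path, toy_model):
    report = safety.SafetyReport(
        case="P3",
        max_delta_T={360.0: 2.2},
        max_delta_T_roi={360.0: 2.0},
        heated_mass_g={1.0: {"muscle": 12.5}, 3.0: {"muscle": 0.0}},
        time_to_threshold_s={1.0: 66.0, 3.0: None},
    )
    path = tmp_path / "report.json"
    report.to_json(str(path))
    import json

    payload = json.loads(path.read_text())
    assert payload["max_delta_T_K"]["360.0"] == 2.2
    assert payload["time_to_threshold_s"]["3.0"] is None


def test_report_rejects_inverted_crossing_times():
    with pytest.raises(ValueError):
        safety.SafetyReport(
            case="P1", max_delta_T={}, max_delta_T_roi={},
            heated_mass_g={}, time_to_threshold_s={1.0: 50.0, 3.0: 20.0},
        )
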