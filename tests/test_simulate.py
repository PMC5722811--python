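import numpy as np
import pandas as pd
import pytest

from hipshape.outcomes import frame_to_readings, croft_grade
from hipshape.procrustes import procrustes_distance
from hipshape.simulate import (
    SimulationConfig,
    generate_cohort,
    make_deformation_fields,
    make_hip_template,
    plant_outcomes,
    sample_shapes,
)


class TestTemplate:
    def test_default_has_58_points_and_key_roles(self, template):
        assert template.P == 58
        assert template.reference.shape == (58, 2)
        expected_keys = {
            "medial_acetabular", "lateral_acetabular_1", "lateral_acetabular_2",
            "femoral_head", "femoral_neck_superior", "femoral_neck_inferior",
            "greater_trochanter", "lesser_trochanter",
        }
        assert set(template.key_points) == expected_keys
        for name, idx in template.key_points.items():
            assert template.roles[idx] == f"key:{name}"

    def test_right_sided_orientation(self, template):
        """Lateral acetabular key points sit at greater x than the medial one."""
        ref = template.reference
        med = ref[template.key_points["medial_acetabular"], 0]
        for k in ("lateral_acetabular_1", "lateral_acetabular_2"):
            assert ref[template.key_points[k], 0] > med

    def test_unit_centroid_size_after_standardization(self, template):
        pts = template.reference - template.reference.mean(axis=0)
        pts = pts / np.linalg.norm(pts)
        assert np.linalg.norm(pts) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(pts.mean(axis=0), 0, atol=1e-12)

    def test_deterministic(self):
        t1, t2 = make_hip_template(), make_hip_template()
        np.testing.assert_array_equal(t1.reference, t2.reference)

    def test_segments_partition_all_points(self, template):
        covered = sorted(
            i for lo, hi in template.segments.values() for i in range(lo, hi)
        )
        assert covered == list(range(58))

    def test_smaller_point_counts_allocate(self):
        t = make_hip_template(P=30)
        assert t.P == 30
        assert t.reference.shape == (30, 2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            make_hip_template(P=10)


class TestDeformationFields:
    def test_orthonormal(self, fields):
        G = fields.fields @ fields.fields.T
        np.testing.assert_allclose(G, np.eye(len(fields.labels)), atol=1e-10)

    def test_cam_raw_support_limited_to_head_neck_junction(self, template, fields):
        cam = fields.raw[fields.labels.index("cam_like")].reshape(-1, 2)
        allowed = set()
        for seg in ("femoral_head", "superior_neck"):
            lo, hi = template.segments[seg]
            allowed |= set(range(lo, hi))
        moving = {i for i in range(template.P) if np.linalg.norm(cam[i]) > 1e-12}
        assert moving <= allowed

    def test_pincer_raw_support_on_acetabulum(self, template, fields):
        pincer = fields.raw[fields.labels.index("pincer_like")].reshape(-1, 2)
        lo, hi = template.segments["acetabulum"]
        outside = np.delete(pincer, range(lo, hi), axis=0)
        assert np.abs(outside).max() == 0.0

    def test_pincer_extends_acetabular_coverage(self, template, fields):
        """+2 SD of the pincer field widens the arc the acetabulum subtends
        around the femoral head centre."""
        from hipshape.simulate import _HEAD_CENTER

        lo, hi = template.segments["acetabulum"]
        pincer = fields.fields[fields.labels.index("pincer_like")]

        def coverage(points):
            rel = points[lo:hi] - _HEAD_CENTER
            ang = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
            return abs(ang[-1] - ang[0])

        base = coverage(template.reference)
        deformed = template.reference + 2 * 3.0 * pincer.reshape(-1, 2)
        assert coverage(deformed) > base

    def test_orthogonal_to_similarity_directions(self, template, fields):
        from hipshape.simulate import _similarity_tangent_basis

        sim = _similarity_tangent_basis(template.reference)
        np.testing.assert_allclose(sim @ fields.fields.T, 0, atol=1e-10)


class TestSampleShapes:
    def test_zero_variation_gives_pure_similarity_copies(self):
        cfg = SimulationConfig(n=5, mode_sds=(0, 0, 0, 0), landmark_noise_sd=0.0,
                               seed=3)
        shapes, _ = sample_shapes(cfg)
        t = make_hip_template()
        for s in shapes:
            assert procrustes_distance(s.points, t.reference) < 1e-10

    def test_loading_sds_match_config(self):
        cfg = SimulationConfig(n=2000, seed=4)
        _, scores = sample_shapes(cfg)
        sds = scores[[c for c in scores if c.startswith("loading_")]].std(ddof=1)
        np.testing.assert_allclose(sds.to_numpy(), cfg.mode_sds, rtol=0.05)

    def test_seed_determinism(self):
        a1, s1 = sample_shapes(SimulationConfig(n=10, seed=7))
        a2, s2 = sample_shapes(SimulationConfig(n=10, seed=7))
        b, _ = sample_shapes(SimulationConfig(n=10, seed=8))
        for x, y in zip(a1, a2):
            np.testing.assert_array_equal(x.points, y.points)
        pd.testing.assert_frame_equal(s1, s2)
        assert not np.array_equal(a1[0].points, b[0].points)


@pytest.fixture(scope="module")
def null_cohort():
    """n=10,000 with all planted effects zeroed: pure intercepts."""
    cfg = SimulationConfig(n=10_000, seed=12)
    for m in cfg.outcome_models.values():
        m["log_or"] = {}
        m["covariate_log_or"] = {}
    return generate_cohort(cfg)


class TestPlantOutcomes:

    def test_prevalence_calibration_at_null(self, null_cohort):
        rhoa = (null_cohort.readings["croft_grade"] >= 2).mean()
        assert rhoa == pytest.approx(0.071, abs=0.01)
        assert null_cohort.pain["pain_internal_rotation"].mean() == pytest.approx(
            0.114, abs=0.012
        )
        assert (null_cohort.pain["walking_pain_raw"] >= 1).mean() == pytest.approx(
            0.202, abs=0.015
        )
        assert null_cohort.pain["womac"].mean() == pytest.approx(0.9, abs=0.1)

    def test_every_case_has_osteophyte_or_jsn(self, null_cohort):
        readings = frame_to_readings(null_cohort.readings)
        for r in readings:
            if croft_grade(r) >= 2:
                assert r.osteophyte_any or r.jsn_any

    def test_womac_right_skewed_within_range(self, null_cohort):
        w = null_cohort.pain["womac"]
        assert w.between(0, 20).all()
        assert (w == 0).mean() > 0.5
        assert w.mean() < w.std() * 2  # long right tail

    def test_planted_effect_visible_on_true_scores(self):
        cfg = SimulationConfig(n=8000, seed=13)
        cohort = generate_cohort(cfg)
        z = cohort.true_scores["loading_pincer_like"]
        z = (z - z.mean()) / z.std()
        case = (cohort.readings["croft_grade"] >= 2).to_numpy()
        # planted log-OR log(1.23): cases should have higher pincer loadings
        assert z[case].mean() > z[~case].mean()


class TestGenerateCohort:
    def test_smoke_cohort_tables_join_one_to_one(self):
        cohort = generate_cohort(SimulationConfig(n=100, seed=5))
        ids = {c.image_id for c in cohort.landmarks}
        assert len(ids) == 100
        for table in (cohort.true_scores, cohort.covariates, cohort.readings,
                      cohort.pain):
            assert set(table["image_id"]) == ids
            assert table["image_id"].is_unique

    def test_write_bundle(self, tmp_path):
        cohort = generate_cohort(SimulationConfig(n=20, seed=6))
        out = cohort.write(tmp_path / "cohort")
        for name in ("landmarks.csv", "true_scores.csv", "covariates.csv",
                     "readings.csv", "pain.csv", "truth.json", "template.json"):
            assert (out / name).exists()

    def test_covariate_distributions(self):
        cohort = generate_cohort(SimulationConfig(n=3000, seed=9))
        cov = cohort.covariates
        assert cov["age"].mean() == pytest.approx(72.8, abs=0.5)
        assert cov["height"].mean() == pytest.approx(174.4, abs=0.5)
        assert cov["weight"].mean() == pytest.approx(83.6, abs=1.0)
        assert (cov["race"] == "white").mean() == pytest.approx(0.907, abs=0.02)
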