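import math

import numpy as np
import pytest

from contactq import (
    BandConfig,
    BandProfile,
    MembraneTrace,
    compute_average_distance,
    compute_band_profile,
    compute_ermicc,
    compute_total_contact_length,
    distance_to_trace,
    generate_scene,
    measure_mitochondrion,
    measure_scene,
    perimeter,
    SceneSpec,
)

from conftest import circle_trace, square_trace


def make_profile(**bands):
    """BandProfile with bands given as keyword 'b<i>'=length."""
    l = np.zeros(30)
    for k, v in bands.items():
        l[int(k[1:]) - 1] = v
    return BandProfile(BandConfig(), l, np.cumsum(l))


class TestBandConfig:
    def test_defaults_cover_30nm_in_1nm_steps(self):
        c = BandConfig()
        assert c.step_nm == 1.0 and c.n_bands == 30 and c.max_distance_nm == 30.0

    @pytest.mark.parametrize("kwargs", [
        dict(step_nm=0.0), dict(n_bands=0),
        dict(er_resample_step_nm=0.6),          # > step/2
        dict(distance_quantum_nm=-1.0),
    ])
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            BandConfig(**kwargs)


class TestPerimeter:
    def test_square(self):
        assert perimeter(square_trace(100.0)) == pytest.approx(400.0)

    def test_circle_one_degree_sampling(self):
        p = perimeter(circle_trace(500.0, 360))
        assert p == pytest.approx(2 * math.pi * 500, rel=5e-5)

    def test_translation_invariance(self):
        t = circle_trace(500.0, 360)
        moved = t.transformed(translation_nm=(1e6, 1e6))
        assert perimeter(moved) == pytest.approx(perimeter(t), rel=1e-12)

    def test_open_trace_rejected(self):
        er = MembraneTrace("e", "ER", np.array([[0, 0], [1, 0]], float), False)
        with pytest.raises(ValueError, match="closed"):
            perimeter(er)


class TestDistanceToTrace:
    segment = MembraneTrace("s", "ER", np.array([[-100.0, 0.0], [100.0, 0.0]]),
                            closed=False)

    def test_perpendicular_foot(self):
        assert distance_to_trace((0.0, 10.0), self.segment) == pytest.approx(10.0)

    def test_beyond_endpoint(self):
        d = distance_to_trace((200.0, 10.0), self.segment)
        assert d == pytest.approx(math.hypot(100.0, 10.0))

    def test_vertex_is_zero(self):
        assert distance_to_trace((100.0, 0.0), self.segment) == 0.0


class TestBandProfile:
    def test_straight_edge_parallel_er(self):
        """ER parallel to a straight MOM edge at distance 5.5 lands in band 6."""
        mom = MembraneTrace("m", "MOM", np.array(
            [[0.0, 0.0], [1000.0, 0.0], [1000.0, 2000.0], [0.0, 2000.0]]), True)
        er = MembraneTrace("e", "ER", np.array([[100.0, -5.5], [300.0, -5.5]]),
                           closed=False)
        prof = compute_band_profile(mom, [er])
        assert prof.incremental_length[5] == pytest.approx(200.0, abs=1e-6)
        assert prof.incremental_length.sum() == pytest.approx(200.0, abs=1e-6)

    def test_concentric_arc_band_15(self, concentric_arc_scene):
        mom, er = concentric_arc_scene
        prof = compute_band_profile(mom, [er])
        expected = (math.pi / 2) * 515
        assert prof.incremental_length[14] == pytest.approx(expected, rel=0.005)
        others = np.delete(prof.incremental_length, 14)
        assert others.sum() == pytest.approx(0.0, abs=1e-9)

    def test_er_beyond_range_excluded(self):
        mom = circle_trace(500.0)
        far = circle_trace(560.0, 500, object_id="far", role="ER")
        prof = compute_band_profile(mom, [far])
        assert prof.incremental_length.sum() == 0.0

    def test_no_er_gives_zero_profile(self):
        prof = compute_band_profile(circle_trace(500.0), [])
        assert np.all(prof.incremental_length == 0)

    def test_conservation_invariants(self):
        scene, _ = generate_scene(SceneSpec(seed=5, n_mitochondria=2))
        for mom in scene.mom_traces:
            prof = compute_band_profile(mom, scene.er_traces)
            l, L = prof.incremental_length, prof.cumulative_length
            assert np.all(l >= 0)
            assert np.all(np.diff(L) >= -1e-12)
            assert L[-1] == pytest.approx(l.sum(), abs=1e-6)


class TestAverageDistance:
    def test_two_band_weighted_mean(self):
        prof = make_profile(b10=30.0, b20=10.0)
        assert compute_average_distance(prof) == pytest.approx(12.5)

    @pytest.mark.parametrize("k", [1, 7, 30])
    def test_single_band_gives_band_edge(self, k):
        prof = make_profile(**{f"b{k}": 42.0})
        assert compute_average_distance(prof) == pytest.approx(k * 1.0)

    def test_zero_contact_is_missing(self):
        assert math.isnan(compute_average_distance(make_profile()))

    def test_step_scales_distance(self):
        c = BandConfig(step_nm=2.0, n_bands=15, er_resample_step_nm=0.1)
        l = np.zeros(15)
        l[9] = 5.0
        prof = BandProfile(c, l, np.cumsum(l))
        assert compute_average_distance(prof) == pytest.approx(20.0)


class TestTotalLengthAndErmicc:
    def test_total_examples(self):
        assert compute_total_contact_length(make_profile()) == 0.0
        assert compute_total_contact_length(make_profile(b6=200.0)) == 200.0
        assert compute_total_contact_length(
            make_profile(b10=30.0, b20=10.0)) == pytest.approx(40.0)

    def test_ermicc_identity(self):
        assert compute_ermicc(15.0 * 300.0, 300.0, 15.0) == pytest.approx(1.0)

    def test_ermicc_zero_contact_convention(self):
        assert compute_ermicc(0.0, 1000.0, math.nan) == 0.0

    def test_ermicc_missing_d_with_contact_is_error(self):
        with pytest.raises(ValueError, match="missing"):
            compute_ermicc(10.0, 1000.0, math.nan)

    def test_ermicc_requires_positive_perimeter(self):
        with pytest.raises(ValueError):
            compute_ermicc(1.0, 0.0, 5.0)


class TestMeasureMitochondrion:
    def test_no_er_zero_contact(self):
        m = measure_mitochondrion(circle_trace(500.0), [])
        assert m.L_nm == 0 and m.ermicc_per_nm == 0 and m.zero_contact
        assert math.isnan(m.D_nm)

    def test_concentric_closed_form(self, concentric_arc_scene):
        mom, er = concentric_arc_scene
        m = measure_mitochondrion(mom, [er])
        L = (math.pi / 2) * 515
        P = 2 * math.pi * 500
        assert m.D_nm == pytest.approx(15.0, abs=1e-9)
        assert m.ermicc_per_nm == pytest.approx(L / (P * 15.0), rel=0.02)
        assert m.ermicc_per_nm == pytest.approx(0.01717, rel=0.02)

    def test_ermicc_consistency(self, concentric_arc_scene):
        mom, er = concentric_arc_scene
        m = measure_mitochondrion(mom, [er])
        assert m.ermicc_per_nm == pytest.approx(m.L_nm / (m.P_nm * m.D_nm),
                                                rel=1e-12)

    def test_rigid_motion_invariance(self):
        scene, _ = generate_scene(SceneSpec(seed=9, n_mitochondria=1))
        mom, ers = scene.mom_traces[0], scene.er_traces
        base = measure_mitochondrion(mom, ers)
        rot, shift = 1.1, (12345.0, -6789.0)
        mom2 = mom.transformed(rotation_rad=rot, translation_nm=shift)
        ers2 = [e.transformed(rotation_rad=rot, translation_nm=shift) for e in ers]
        moved = measure_mitochondrion(mom2, ers2)
        for attr in ("P_nm", "L_nm", "D_nm", "ermicc_per_nm"):
            assert getattr(moved, attr) == pytest.approx(
                getattr(base, attr), rel=1e-6)

    def test_scaling_law(self, concentric_arc_scene):
        """Doubling the scene doubles L, P, D and halves ERMICC (band edges
        align exactly for this fixture: 15 nm -> 30 nm)."""
        mom, er = concentric_arc_scene
        base = measure_mitochondrion(mom, [er])
        m2 = measure_mitochondrion(mom.transformed(scale=2.0),
                                   [er.transformed(scale=2.0)])
        assert m2.P_nm == pytest.approx(2 * base.P_nm, rel=1e-9)
        assert m2.L_nm == pytest.approx(2 * base.L_nm, rel=1e-9)
        assert m2.D_nm == pytest.approx(2 * base.D_nm, rel=1e-9)
        assert m2.ermicc_per_nm == pytest.approx(base.ermicc_per_nm / 2, rel=1e-9)

    def test_translating_er_away_monotone(self):
        """Rigidly moving one ER trace away from the MOM never increases L
        and never decreases D (while contact remains)."""
        mom = MembraneTrace("m", "MOM", np.array(
            [[0.0, 0.0], [1000.0, 0.0], [1000.0, 2000.0], [0.0, 2000.0]]), True)
        base = np.array([[200.0, -3.0], [420.0, -8.0], [700.0, -3.5]])
        prev_L, prev_D = np.inf, 0.0
        for shift in (0.0, 5.0, 12.0, 20.0, 26.0, 45.0):
            er = MembraneTrace("e", "ER", base - [0.0, shift], closed=False)
            m = measure_mitochondrion(mom, [er])
            assert m.L_nm <= prev_L + 1e-9
            if m.L_nm > 0:
                assert m.D_nm >= prev_D - 1e-9
                prev_D = m.D_nm
            prev_L = m.L_nm


class TestMeasureScene:
    def test_tables_shape_and_consistency(self):
        scene, _ = generate_scene(SceneSpec(seed=3, n_mitochondria=3),
                                  group="WT", cell_id="c1")
        metrics, bands = measure_scene(scene)
        assert len(metrics) == 3
        assert set(metrics.group) == {"WT"}
        assert len(bands) == 3 * 30
        for _, row in metrics.iterrows():
            b = bands[bands.mito_id == row.mito_id]
            assert b.l_i_nm.sum() == pytest.approx(row.L_nm, abs=1e-6)
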