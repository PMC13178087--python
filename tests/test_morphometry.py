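"""TAIM, OIMR, the total index and the per-patient averaging protocol."""

import numpy as np
import pytest

from mitomorph import (
    AnnotationScene,
    MembraneSet,
    MorphometryError,
    PatientRecord,
    Polygon,
    Polyline,
    ProtocolViolation,
    compute_patient,
    oimr_for_mitochondrion,
    patient_oimr,
    patient_taim,
    taim_for_scene,
    total_index,
)

from conftest import membrane_scene, membrane_with_oimr, square


def taim_scene_from(regions, mitochondria, mid="s"):
    return AnnotationScene(
        micrograph_id=mid,
        magnification=5000,
        interfibrillar_regions=regions,
        mitochondria=mitochondria,
    )


class TestTaimForScene:
    def test_half_filled_region(self, taim_scene):
        assert taim_for_scene(taim_scene) == pytest.approx(50.0)

    def test_partial_overlap_is_clipped(self):
        # 2x2 mitochondrion straddling the region edge: only area 2 counts
        region = square(0, 0, 10)
        mito = Polygon([(-1, 4), (1, 4), (1, 6), (-1, 6)])
        scene = taim_scene_from([region], [mito])
        assert taim_for_scene(scene) == pytest.approx(2.0)

    def test_no_mitochondria_is_an_error_not_zero(self):
        scene = taim_scene_from([square(0, 0, 10)], [])
        with pytest.raises(MorphometryError, match="not a 0%"):
            taim_for_scene(scene)

    def test_no_region_rejected(self):
        scene = taim_scene_from([], [square(0, 0, 2)])
        with pytest.raises(MorphometryError):
            taim_for_scene(scene)

    def test_adding_interior_mitochondrion_is_monotone(self):
        region = square(0, 0, 10)
        mitos = [square(1, 1, 2)]
        before = taim_for_scene(taim_scene_from([region], list(mitos)))
        mitos.append(square(6, 6, 2))
        after = taim_for_scene(taim_scene_from([region], mitos))
        assert after > before

    def test_similarity_invariance(self, taim_scene):
        # scale by 3, rotate 30 degrees, translate: TAIM unchanged
        theta = np.pi / 6
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )

        def xform(poly):
            return Polygon(3.0 * poly.coords @ rot.T + [17.0, -4.0])

        moved = taim_scene_from(
            [xform(r) for r in taim_scene.interfibrillar_regions],
            [xform(m) for m in taim_scene.mitochondria],
        )
        assert taim_for_scene(moved) == pytest.approx(50.0, rel=1e-9)


class TestOimr:
    def test_equal_lengths_give_100(self):
        ms = MembraneSet(
            "m1", square(0, 0, 10), [Polyline([(0, 0), (40, 0)])]
        )
        assert oimr_for_mitochondrion(ms) == pytest.approx(100.0)

    def test_constructed_31_percent(self, membrane_31):
        assert oimr_for_mitochondrion(membrane_31) == pytest.approx(31.0)

    def test_scale_invariance(self, membrane_31):
        scaled = MembraneSet(
            "m1",
            Polygon(3.0 * membrane_31.outer.coords),
            [Polyline(3.0 * t.coords) for t in membrane_31.inner_traces],
        )
        assert oimr_for_mitochondrion(scaled) == pytest.approx(31.0)

    def test_inner_traces_are_summed(self):
        # splitting one trace into cristae leaves the value unchanged
        whole = membrane_with_oimr(25.0)
        L = 100.0 * 40 / 25.0
        split = MembraneSet(
            "m1",
            square(0, 0, 10),
            [
                Polyline([(0, 0), (L / 4, 0)]),
                Polyline([(0, 1), (L / 4, 1)]),
                Polyline([(0, 2), (L / 2, 2)]),
            ],
        )
        assert oimr_for_mitochondrion(split) == pytest.approx(
            oimr_for_mitochondrion(whole)
        )


class TestPatientAveraging:
    def test_constant_input(self):
        scenes = [membrane_scene([31.0] * 3, f"s{i}") for i in range(3)]
        assert patient_oimr(scenes) == pytest.approx(31.0)

    def test_mean_within_one_scene(self):
        with pytest.warns(UserWarning):  # single micrograph: protocol warning
            value = patient_oimr([membrane_scene([20.0, 30.0, 40.0])])
        assert value == pytest.approx(30.0)

    def test_balanced_grand_mean_equals_mean_of_scene_means(self, rng):
        values = rng.uniform(15, 60, (3, 3))
        scenes = [membrane_scene(list(row), f"s{i}") for i, row in enumerate(values)]
        grand = patient_oimr(scenes)
        scene_means = values.mean(axis=1).mean()
        assert grand == pytest.approx(scene_means)

    def test_unbalanced_uses_equal_mitochondrion_weights(self):
        scenes = [
            membrane_scene([10.0], "s0"),
            membrane_scene([20.0, 30.0, 40.0], "s1"),
        ]
        with pytest.warns(UserWarning):
            value = patient_oimr(scenes)
        assert value == pytest.approx(25.0)  # (10+20+30+40)/4, not (10+30)/2

    def test_strict_mode_enforces_3x3(self):
        scenes = [membrane_scene([31.0] * 3, f"s{i}") for i in range(2)]
        with pytest.raises(ProtocolViolation, match="3 micrographs"):
            patient_oimr(scenes, strict=True)

    def test_patient_taim_mean(self):
        scenes = []
        for i, pct in enumerate([40.0, 45.0, 50.0]):
            # region 10x10 with one mitochondrion of area pct
            side = np.sqrt(pct)
            scenes.append(
                AnnotationScene(
                    micrograph_id=f"t{i}",
                    magnification=5000,
                    interfibrillar_regions=[square(0, 0, 10)],
                    mitochondria=[square(1, 1, side)],
                )
            )
        assert patient_taim(scenes) == pytest.approx(45.0)

    def test_single_scene_is_identity(self, taim_scene):
        with pytest.warns(UserWarning):
            value = patient_taim([taim_scene])
        assert value == pytest.approx(50.0)

    def test_empty_inputs_rejected(self):
        with pytest.raises(MorphometryError):
            patient_taim([])
        with pytest.raises(MorphometryError):
            patient_oimr([])


class TestTotalIndex:
    def test_cohort_median_arithmetic(self):
        assert total_index(43.7, 31.0) == pytest.approx(1.4097, abs=5e-5)
        assert round(total_index(43.7, 31.0), 2) == 1.41

    def test_group_median_arithmetic(self):
        assert total_index(42.0, 35.0) == pytest.approx(1.2)

    def test_identity_for_equal_inputs(self):
        for x in (0.5, 31.0, 99.0):
            assert total_index(x, x) == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(MorphometryError):
            total_index(0.0, 31.0)
        with pytest.raises(MorphometryError):
            total_index(43.7, -1.0)

    def test_monotonicity(self):
        # decreasing in OIMR at fixed TAIM, increasing in TAIM at fixed OIMR
        assert total_index(43.7, 31.0) > total_index(43.7, 35.0)
        assert total_index(49.0, 31.0) > total_index(43.7, 31.0)


class TestComputePatient:
    def test_full_pipeline(self, taim_scene):
        record = PatientRecord(
            patient_id="P1",
            group_label=1,
            scenes_5000x=[taim_scene],
            scenes_15000x=[membrane_scene([25.0] * 3, f"s{i}") for i in range(3)],
        )
        with pytest.warns(UserWarning):  # one 5000x scene instead of three
            result = compute_patient(record)
        assert result.taim_pct == pytest.approx(50.0)
        assert result.oimr_pct == pytest.approx(25.0)
        assert result.total_index == pytest.approx(2.0)
        assert result.n_micrographs_5000x == 1
        assert result.n_mitochondria_15000x == 9
        assert result.rounded()["total_index"] == 2.0
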