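"""Tissue-layer assignment, regional summaries, sign conventions."""

import numpy as np
import pytest

from dbsdeform import (
    CubicCurveModel,
    InvalidArgumentError,
    InvalidFrontiersError,
    MissingLayerError,
    TissueFrontiers,
    assign_layers,
    deformation_profile,
    frenet_profile,
    orient_signs,
    regional_summary,
    make_ground_truth_curve,
)
from dbsdeform.geometry import DeformationProfile


def _straight_model(length=70.0):
    return CubicCurveModel(
        np.array([[0, 0, 0], [0, 0, length], [0, 0, 0], [0, 0, 0]], float),
        1.0, 0.0, length,
    )


def _frontiers(ce=4.0, gw=25.0, wd=40.0, chord=70.0):
    return TissueFrontiers(ce, gw, wd, chord)


class TestFrontiers:
    @pytest.mark.parametrize(
        "args", [(0.0, 25, 40, 70), (25, 4, 40, 70), (4, 25, 80, 70), (4, 25, 40, 30)]
    )
    def test_ordering_enforced(self, args):
        with pytest.raises(InvalidFrontiersError):
            TissueFrontiers(*args)


class TestAssignLayers:
    def test_straight_electrode_layer_counts(self):
        # direct interval counting on 100 uniform samples of a 70 mm lead
        prof = deformation_profile(_straight_model())
        labels = assign_layers(prof, _frontiers())
        counts = {l: int((labels == l).sum())
                  for l in ("subdural", "gyration", "wms", "deep_brain")}
        expected = {"subdural": 6, "gyration": 30, "wms": 21, "deep_brain": 43}
        for layer, n in expected.items():
            assert abs(counts[layer] - n) <= 1

    def test_tiny_subdural_segment(self):
        prof = deformation_profile(_straight_model())
        labels = assign_layers(prof, TissueFrontiers(0.01, 35.0, 68.0, 70.0))
        assert (labels == "subdural").sum() <= 1
        assert set(np.unique(labels)) <= {"subdural", "gyration", "wms", "deep_brain"}

    def test_labels_monotone_on_curved_electrodes(self):
        order = {l: i for i, l in enumerate(("subdural", "gyration", "wms", "deep_brain"))}
        for seed in range(5):
            curve = make_ground_truth_curve(
                "directional", "left", (1.5, -1.0, 0.8), 68.0, seed=seed
            )
            prof = deformation_profile(curve.as_model())
            labels = assign_layers(prof, _frontiers(chord=68.0))
            ranks = np.array([order[l] for l in labels])
            assert np.all(np.diff(ranks) >= 0)

    def test_frontier_beyond_measured_chord_raises(self):
        prof = deformation_profile(_straight_model(35.0))
        with pytest.raises(InvalidFrontiersError):
            assign_layers(prof, _frontiers(chord=70.0))  # wms_deep 40 > chord 35


class TestRegionalSummary:
    def _constant_profile(self, c=0.5):
        n = 100
        arc = np.linspace(0, 70.0, n)
        return DeformationProfile(
            t=np.linspace(0, 1, n), arc_mm=arc,
            deviations=np.full((n, 3), c),
            curvature=np.full(n, c), torsion=np.full(n, c),
            torsion_defined=np.ones(n, dtype=bool),
            chord_start=np.zeros(3), chord_end=np.array([0, 0, 70.0]),
        )

    def test_constant_profile_means(self):
        prof = self._constant_profile(0.5)
        labels = assign_layers(prof, _frontiers())
        for s in regional_summary(prof, labels):
            for value in (s.x_mm, s.y_mm, s.z_mm, s.torsion_per_mm, s.curvature_per_mm):
                assert value == pytest.approx(0.5)

    def test_linear_deviation_layer_means_match_interval_midpoints(self):
        # closed-form oracle: mean of arc/10 over each distance interval
        prof = self._constant_profile()
        prof.deviations = np.zeros((100, 3))
        prof.deviations[:, 0] = prof.arc_mm / 10.0
        frontiers = _frontiers()
        labels = assign_layers(prof, frontiers)
        bounds = {"gyration": (4.0, 25.0), "wms": (25.0, 40.0), "deep_brain": (40.0, 70.0)}
        for s in regional_summary(prof, labels):
            lo, hi = bounds[s.layer]
            analytic = (lo + hi) / 2.0 / 10.0
            assert abs(s.x_mm - analytic) / analytic < 0.02

    def test_torsion_flag_propagation(self):
        prof = self._constant_profile(0.5)
        labels = assign_layers(prof, _frontiers())
        prof.torsion_defined[labels == "wms"] = False
        out = {s.layer: s for s in regional_summary(prof, labels)}
        assert np.isnan(out["wms"].torsion_per_mm)
        assert out["gyration"].torsion_per_mm == pytest.approx(0.5)
        assert out["deep_brain"].torsion_per_mm == pytest.approx(0.5)

    def test_empty_layer_raises(self):
        prof = self._constant_profile()
        labels = np.array(["gyration"] * 100, dtype=object)
        with pytest.raises(MissingLayerError, match="wms"):
            regional_summary(prof, labels)

    def test_conservation_of_whole_electrode_mean(self):
        """Whole-lead mean equals the count-weighted mean over all segments."""
        curve = make_ground_truth_curve("non_directional", "right", (1.0, 0.4, -0.6),
                                        70.0, seed=3)
        prof = frenet_profile(curve.as_model(), deformation_profile(curve.as_model()))
        labels = assign_layers(prof, _frontiers())
        summaries = {s.layer: s for s in regional_summary(prof, labels)}
        sub = labels == "subdural"
        total = sum(
            summaries[l].x_mm * summaries[l].n_samples for l in summaries
        ) + prof.deviations[sub, 0].sum()
        assert total / prof.n_samples == pytest.approx(prof.deviations[:, 0].mean())


class TestOrientSigns:
    def test_identity_and_idempotence(self):
        prof_curve = make_ground_truth_curve("non_directional", "left", (0.5, 0, 0),
                                             70.0, seed=1)
        prof = frenet_profile(prof_curve.as_model(), deformation_profile(prof_curve.as_model()))
        labels = assign_layers(prof, _frontiers())
        s = regional_summary(prof, labels)[0]
        once = orient_signs(s, "left")
        twice = orient_signs(once, "left")
        assert once.x_mm == s.x_mm and once.oriented
        assert twice == once

    def test_unknown_hemisphere_rejected(self):
        prof_curve = make_ground_truth_curve("non_directional", "left", (0.5, 0, 0),
                                             70.0, seed=1)
        prof = frenet_profile(prof_curve.as_model(), deformation_profile(prof_curve.as_model()))
        s = regional_summary(prof, assign_layers(prof, _frontiers()))[0]
        with pytest.raises(InvalidArgumentError):
            orient_signs(s, "bilateral")

    def test_mirrored_chain_negates_x_exactly_once(self):
        """End-to-end mirror: the same anatomy seen from the other hemisphere
        flips only the x deviation sign."""
        left = make_ground_truth_curve("non_directional", "left", (0.7, 0.3, -0.2),
                                       70.0, seed=2)
        mirrored = CubicCurveModel(left.coeffs * [-1, 1, 1], 1.0, 0.0, 70.0)
        p_left = deformation_profile(left.as_model())
        p_right = deformation_profile(mirrored)
        np.testing.assert_allclose(p_right.deviations[:, 0], -p_left.deviations[:, 0],
                                   atol=1e-9)
        np.testing.assert_allclose(p_right.deviations[:, 1:], p_left.deviations[:, 1:],
                                   atol=1e-9)
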