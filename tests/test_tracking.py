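"""Tracker fidelity: sub-pixel recovery, equivariance, compensation."""

import numpy as np
import pytest
from scipy import ndimage

from seeme.synthetic import SceneConfig, generate_pore_field, generate_pore_texture
from seeme.tracking import (
    ROIError,
    ROISpec,
    DisplacementField,
    compensate_global_motion,
    detect_pores,
    roi_mean_displacement,
    summarize_roi,
    track_landmarks,
)


@pytest.fixture(scope="module")
def texture():
    cfg = SceneConfig(seed=7)
    img, centers = generate_pore_field(cfg)
    return img, centers


def _translate(img, dx, dy):
    spline = ndimage.spline_filter(img, order=3)
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]].astype(float)
    return ndimage.map_coordinates(
        spline, [yy - dy, xx - dx], order=3, prefilter=False, mode="nearest"
    )


class TestDetectPores:
    def test_uniform_frame_yields_no_landmarks(self):
        with pytest.warns(UserWarning, match="no pore-like"):
            lm = detect_pores(np.full((64, 64), 128.0))
        assert len(lm) == 0

    def test_recovers_generated_blobs(self, texture):
        img, centers = texture
        lm = detect_pores(img)
        assert len(lm) >= len(centers) - 2
        from scipy.spatial import cKDTree

        d, _ = cKDTree(centers).query(lm.positions)
        assert (d <= 1.0).all()

    def test_suppression_radius(self):
        img = np.full((40, 40), 200.0)
        for cx in (20.0, 21.0):  # two blobs 1 px apart
            yy, xx = np.mgrid[0:40, 0:40]
            img -= 80 * np.exp(-((xx - cx) ** 2 + (yy - 20.0) ** 2) / (2 * 1.5**2))
        lm = detect_pores(img, min_separation_px=2)
        assert len(lm) == 1


class TestTrackLandmarks:
    def test_static_frames_zero_displacement(self, texture):
        img, _ = texture
        lm = detect_pores(img)
        field = track_landmarks([img] * 4, lm)
        assert np.abs(field.dx).max() < 1e-6
        assert np.abs(field.dy).max() < 1e-6
        assert field.valid.all()

    def test_global_translation_recovered(self, texture):
        """+2 px/frame rigid shift: median per-frame dx within [1.8, 2.2]."""
        img, _ = texture
        frames = [img] + [_translate(img, 2.0 * k, 0.0) for k in (1, 2, 3)]
        lm = detect_pores(img)
        field = track_landmarks(frames, lm)
        steps = np.diff(field.dx, axis=0)
        med = np.median(steps, axis=1)
        assert ((med > 1.8) & (med < 2.2)).all()

    def test_translation_equivariance(self, texture):
        """Shifting all frames by a constant shifts the field by it."""
        img, _ = texture
        shifted = _translate(img, 1.5, -0.75)
        lm = detect_pores(img)
        field = track_landmarks([img, shifted], lm)
        v = field.valid[1]
        assert np.median(field.dx[1, v]) == pytest.approx(1.5, abs=0.05)
        assert np.median(field.dy[1, v]) == pytest.approx(-0.75, abs=0.05)

    def test_frame_size_mismatch_rejected(self, texture):
        img, _ = texture
        lm = detect_pores(img)
        with pytest.raises(ValueError, match="size mismatch"):
            track_landmarks([img, img[:-2]], lm)

    def test_roi_response_amplitude_recovered(self, short_response_session):
        """Injected 3-px eye response tracked within 10%."""
        sess = short_response_session
        lm = detect_pores(sess.frames[0])
        field = track_landmarks(sess.frames, lm, fps=sess.fps)
        field, _ = compensate_global_motion(field)
        md = roi_mean_displacement(field, sess.rois["eyes"])
        assert md.max() == pytest.approx(3.0, rel=0.10)

    def test_sinusoidal_subpixel_fidelity(self):
        """Oscillatory sub-pixel ROI motion recovered within 20%."""
        from seeme.synthetic import InjectedResponse, simulate_session
        from seeme.detection import CommandEvent

        for amp in (0.5, 2.0):
            cfg = SceneConfig(seed=13)
            ev = [CommandEvent("EYES", 6.0, 1)]
            resp = [
                InjectedResponse(
                    roi_id="eyes", onset_s=6.0, amplitude_px=amp,
                    waveform="sine", latency_s=1.0, duration_s=8.0,
                )
            ]
            sess = simulate_session(cfg, ev, resp, tail_s=18.0)
            lm = detect_pores(sess.frames[0])
            field = track_landmarks(sess.frames, lm, fps=cfg.fps)
            field, _ = compensate_global_motion(field)
            md = roi_mean_displacement(field, sess.rois["eyes"])
            assert md.max() == pytest.approx(amp, rel=0.20)

    def test_agrees_with_dense_optical_flow_oracle(self, texture):
        """Independent check: skimage dense iLK flow on a warped pair."""
        from skimage.registration import optical_flow_ilk

        img, _ = texture
        warped = _translate(img, 1.2, 0.6)
        lm = detect_pores(img)
        field = track_landmarks([img, warped], lm)
        # iLK returns the flow warping `warped` back onto `img`, i.e. the
        # negative of the forward landmark displacement
        v, u = optical_flow_ilk(warped, img, radius=7)
        xi = np.clip(np.round(lm.positions[:, 0]).astype(int), 0, img.shape[1] - 1)
        yi = np.clip(np.round(lm.positions[:, 1]).astype(int), 0, img.shape[0] - 1)
        ok = field.valid[1]
        assert np.median(np.abs(field.dx[1, ok] + u[yi, xi][ok])) < 0.2
        assert np.median(np.abs(field.dy[1, ok] + v[yi, xi][ok])) < 0.2


class TestCompensation:
    def test_pure_global_shift_flagged_and_removed(self, texture):
        img, _ = texture
        frames = [img, _translate(img, 3.0, 0.0), img, img]
        lm = detect_pores(img)
        field = track_landmarks(frames, lm)
        comp, flags = compensate_global_motion(field, artifact_threshold_px=1.0)
        assert flags.tolist() == [False, True, False, False]
        for t in range(4):
            v = comp.valid[t]
            assert np.hypot(
                np.median(comp.dx[t, v]), np.median(comp.dy[t, v])
            ) < 0.1

    def test_no_motion_video_unflagged(self, texture):
        img, _ = texture
        lm = detect_pores(img)
        field = track_landmarks([img] * 3, lm)
        _, flags = compensate_global_motion(field)
        assert not flags.any()

    def test_roi_response_survives_compensation(self, short_response_session):
        """Median subtraction attenuates a minority-ROI response < 15%."""
        sess = short_response_session
        lm = detect_pores(sess.frames[0])
        field = track_landmarks(sess.frames, lm, fps=sess.fps)
        raw_peak = roi_mean_displacement(field, sess.rois["eyes"]).max()
        comp, _ = compensate_global_motion(field)
        comp_peak = roi_mean_displacement(comp, sess.rois["eyes"]).max()
        inside = sess.rois["eyes"].contains(field.ref_positions)
        assert inside.mean() < 0.5  # ROI is a minority of landmarks
        assert comp_peak >= 0.85 * raw_peak


class TestSummarizeROI:
    def _roi(self):
        return ROISpec("box", np.array([[0, 0], [10, 0], [10, 10], [0, 10]]))

    def _field(self, dx, dy, pos):
        t, n = dx.shape
        return DisplacementField(
            dx=dx, dy=dy, valid=np.ones((t, n), bool),
            ids=np.arange(n), ref_positions=pos, fps=1.0,
        )

    def test_zero_field_zero_trace(self):
        f = self._field(np.zeros((5, 2)), np.zeros((5, 2)),
                        np.array([[5.0, 5.0], [6.0, 6.0]]))
        trace = summarize_roi(f, self._roi())
        assert (trace.values == 0).all()
        assert (trace.n_landmarks == 2).all()

    def test_single_moving_landmark_hand_computed(self):
        """1 px/frame for 5 frames -> trace of ones over those steps."""
        t = 7
        dx = np.zeros((t, 1))
        dx[1:6, 0] = np.arange(1, 6)  # moves 1 px/frame for 5 frames
        dx[6, 0] = 5.0  # then holds position
        f = self._field(dx, np.zeros((t, 1)), np.array([[5.0, 5.0]]))
        trace = summarize_roi(f, self._roi())
        np.testing.assert_allclose(trace.values, [0, 1, 1, 1, 1, 1, 0])

    def test_empty_roi_raises_with_name(self):
        f = self._field(np.zeros((3, 1)), np.zeros((3, 1)),
                        np.array([[50.0, 50.0]]))
        with pytest.raises(ROIError, match="box"):
            summarize_roi(f, self._roi())

    def test_trace_peak_near_injected_response(self, short_response_session):
        sess = short_response_session
        lm = detect_pores(sess.frames[0])
        field = track_landmarks(sess.frames, lm, fps=sess.fps)
        field, _ = compensate_global_motion(field)
        trace = summarize_roi(field, sess.rois["eyes"])
        resp = sess.ground_truth.trials[0]
        # injected ramp peaks mid-waveform; trace (a rate) peaks in the ramp
        peak_t = trace.times[np.argmax(trace.values)]
        onset = resp.onset_s
        assert onset <= peak_t <= onset + 11.0


def test_polygon_self_intersection_rejected():
    bow_tie = np.array([[0, 0], [10, 10], [10, 0], [0, 10]])
    with pytest.raises(ValueError, match="self-intersect"):
        ROISpec("bad", bow_tie)
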