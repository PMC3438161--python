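import numpy as np
import pytest

from poletrack import (SimConfig, classify_focus, detect_condensation,
                       detect_foci, extract_centerline, render_static_snapshot,
                       segment_frame, track_foci)
from poletrack.foci import Focus, FocusTrack, detection_threshold

from oracles import brute_force_foci, brute_force_matching


def make_focus(frame, s, length=10.0, cls="internal"):
    return Focus(frame_index=frame, cell_label=1, pixel=(0, 0),
                 intensity=100.0, s_um=s, p_norm=s / length, focus_class=cls)


def make_track(ps, start_frame=0):
    foci = [make_focus(start_frame + i, p * 10.0) for i, p in enumerate(ps)]
    return FocusTrack(cell_track_id=0,
                      frames=list(range(start_frame, start_frame + len(ps))),
                      foci=foci)


class TestClassify:
    def test_midcell_is_internal(self):
        assert classify_focus(2.5, 5.0, d_pole=0.5) == "internal"

    def test_pole_is_polar(self):
        assert classify_focus(0.0, 7.0, d_pole=0.5) == "polar"

    def test_boundary_inclusive(self):
        assert classify_focus(0.5, 5.0, d_pole=0.5) == "polar"


class TestDetectFoci:
    def test_noise_free_one_focus_per_rendered_spot(self):
        cfg = SimConfig(noise_sd=0.0)
        stack, truth = render_static_snapshot([5.0, 6.0], [0.5, 0.4], cfg)
        img = stack.phase[0]
        masks = segment_frame(img, cfg.pixel_size)
        for m in masks:
            extract_centerline(m, cfg.pixel_size, image=img)
        foci = detect_foci(stack.fluor[0], masks)
        by_cell = {}
        for f in foci:
            by_cell.setdefault(f.cell_label, []).append(f)
        assert len(by_cell) == 2
        for fs in by_cell.values():
            assert sum(f.focus_class == "polar" for f in fs) == 2
            assert sum(f.focus_class == "internal" for f in fs) == 1
        # internal foci at the rendered positions
        internals = sorted((f for f in foci if f.focus_class == "internal"),
                           key=lambda f: f.p_norm)
        for f, expect in zip(internals, [0.4, 0.5]):
            assert f.p_norm == pytest.approx(expect, abs=1.5 * cfg.pixel_size / 5.0)

    def test_every_focus_pixel_inside_its_mask(self, small_movie_result):
        res = small_movie_result
        for t, foci in res.foci_by_frame.items():
            pix_of = {m.label: set(map(tuple, m.pixels))
                      for m in res.masks_by_frame[t]}
            for f in foci:
                assert f.pixel in pix_of[f.cell_label]
                assert 0.0 <= f.p_norm <= 1.0

    def test_tie_break_first_in_row_major_order(self):
        cfg = SimConfig(noise_sd=0.0)
        stack, _ = render_static_snapshot([5.0], [0.5], cfg)
        img = stack.phase[0]
        masks = segment_frame(img, cfg.pixel_size)
        for m in masks:
            extract_centerline(m, cfg.pixel_size, image=img)
        # flat-top synthetic fluor: a plateau of equal maxima in one region
        fluor = np.zeros_like(img)
        m = masks[0]
        r, c = m.pixels[len(m.pixels) // 2]
        fluor[r:r + 2, c:c + 2] = 500.0
        foci = detect_foci(fluor, masks, threshold=100.0)
        assert len(foci) == 1
        assert foci[0].pixel == (r, c)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            cfg = SimConfig(seed=int(rng.integers(1000)))
            n = int(rng.integers(1, 4))
            lengths = list(rng.uniform(3.0, 7.0, n))
            pos = list(rng.uniform(0.2, 0.8, n))
            stack, _ = render_static_snapshot(lengths, pos, cfg,
                                              seed=int(rng.integers(10000)))
            img = stack.phase[0]
            fluor = stack.fluor[0]
            masks = segment_frame(img, cfg.pixel_size)
            for m in masks:
                extract_centerline(m, cfg.pixel_size, image=img)
            thr = detection_threshold(fluor)
            got = {(f.cell_label, *f.pixel)
                   for f in detect_foci(fluor, masks,
                                        min_separation_um=0.0)}
            pixel_sets = {m.label: set(map(tuple, m.pixels)) for m in masks
                          if m.measurable}
            expected = set()
            for lab, pset in pixel_sets.items():
                for _mi, r, c in brute_force_foci(fluor, [pset], thr):
                    expected.add((lab, r, c))
            assert got == expected

    def test_mask_without_bright_pixel_yields_no_foci(self):
        cfg = SimConfig(noise_sd=0.0)
        stack, _ = render_static_snapshot([5.0], [0.5], cfg)
        img = stack.phase[0]
        masks = segment_frame(img, cfg.pixel_size)
        for m in masks:
            extract_centerline(m, cfg.pixel_size, image=img)
        dark = np.zeros_like(img)
        assert detect_foci(dark, masks, threshold=10.0) == []


class TestTrackFoci:
    def test_stationary_focus_single_track(self):
        by_frame = {f: [make_focus(f, 5.0)] for f in range(10)}
        tracks = track_foci(by_frame, max_step_um=0.5)
        assert len(tracks) == 1
        assert len(tracks[0]) == 10

    def test_large_jumps_terminate_tracks_instead_of_swapping(self):
        by_frame = {0: [make_focus(0, 3.0), make_focus(0, 7.0)],
                    1: [make_focus(1, 7.0), make_focus(1, 3.0)]}
        tracks = track_foci(by_frame, max_step_um=1.0)
        # foci at the same positions link straight across; a swap would
        # need two 4-µm jumps which the gate forbids
        assert len(tracks) == 2
        for tr in tracks:
            assert len(tr) == 2
            assert abs(tr.s[1] - tr.s[0]) <= 1e-9

    def test_gated_link_rejected(self):
        by_frame = {0: [make_focus(0, 2.0)], 1: [make_focus(1, 4.0)]}
        tracks = track_foci(by_frame, max_step_um=1.0)
        assert sorted(len(t) for t in tracks) == [1, 1]

    def test_matches_brute_force_bipartite_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n0, n1 = rng.integers(0, 4), rng.integers(0, 4)
            s0 = list(np.round(rng.uniform(0, 8, n0), 3))
            s1 = list(np.round(rng.uniform(0, 8, n1), 3))
            f0 = [make_focus(0, s) for s in s0]
            f1 = [make_focus(1, s) for s in s1]
            idx0 = {id(f): i for i, f in enumerate(f0)}
            idx1 = {id(f): i for i, f in enumerate(f1)}
            tracks = track_foci({0: f0, 1: f1}, max_step_um=1.5)
            got = set()
            for tr in tracks:
                if len(tr) == 2:
                    got.add((idx0[id(tr.foci[0])], idx1[id(tr.foci[1])]))
            assert got == brute_force_matching(s0, s1, 1.5)


class TestCondensation:
    def test_constant_track_condenses_at_first_frame(self):
        tr = make_track([0.5] * 6, start_frame=3)
        ev = detect_condensation(tr, 0.05, 3, frame_interval=10.0)
        assert ev is not None
        assert ev.condensation_frame == 3
        assert ev.condensation_time == 30.0
        assert ev.p_at_condensation == pytest.approx(0.5)

    def test_wander_then_settle_sequence(self):
        # stability scan over p = .30 .62 .48 .50 .51 .50 finds the third
        # observation as the first stable start
        tr = make_track([0.30, 0.62, 0.48, 0.50, 0.51, 0.50])
        ev = detect_condensation(tr, epsilon=0.05, k_frames=3)
        assert ev is not None
        assert ev.condensation_frame == tr.frames[2]

    def test_alternating_track_never_condenses(self):
        tr = make_track([0.3, 0.7] * 10)
        assert detect_condensation(tr, 0.05, 3) is None

    def test_track_shorter_than_window_returns_none(self):
        tr = make_track([0.5, 0.5])
        assert detect_condensation(tr, 0.05, 3) is None
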