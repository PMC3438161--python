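"""End-to-end orchestration: movie and snapshot analysis, evaluation
against ground truth, and file-based runs with manifests.

The movie pipeline chains segmentation -> centerline measurement -> cell
tracking -> focus detection -> focus tracking -> condensation detection ->
per-pole growth-rate estimation, and aggregates the headline statistics
(septum placement, condensation-to-division delay, fast/slow pole rates,
asymmetry) into a JSON-serialisable summary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as ptio
from .analysis import (PlacementStats, asymmetry_stats, central_fraction,
                       pole_growth_rates, summarize_population)
from .config import SimConfig
from .foci import (Focus, FocusTrack, SeptumEvent, detect_condensation,
                   detect_foci, track_foci)
from .lineage import CellTrack, DivisionEvent, track_cells
from .render import ImageStack, render_movie, render_static_snapshot
from .segmentation import CellMask, extract_centerline, segment_frame
from .simulate import simulate_population

log = logging.getLogger(__name__)

__all__ = [
    "AnalysisParams", "MovieResult", "SnapshotResult",
    "analyze_movie", "analyze_snapshot", "evaluate_against_truth",
    "run_simulate", "run_analyze",
]

__version__ = "0.1.0"


@dataclass
class AnalysisParams:
    """Tunables of the measurement pipeline (all in physical units)."""

    min_area_px: int = 50
    threshold: float | None = None   # fixed phase threshold; None = Otsu
    k_mad: float = 5.0               # focus detection: median + k * MAD
    d_pole: float = 0.5              # µm; polar/internal cutoff
    max_step_um: float = 0.3         # focus-track gating distance
    epsilon: float = 0.05            # condensation stability band (fraction)
    k_frames: int = 3                # condensation stability window
    iou_min: float = 0.3             # cell-track linking threshold


@dataclass
class MovieResult:
    """Everything the movie pipeline measured."""

    masks_by_frame: list[list[CellMask]]
    foci_by_frame: dict[int, list[Focus]]
    tracks: list[CellTrack]
    divisions: list[DivisionEvent]
    focus_tracks: list[FocusTrack]
    septum_events: dict[int, SeptumEvent]      # cell track id -> event
    growth_records: list
    delays_min: list[float]
    placement: PlacementStats | None
    summary: dict
    counts: dict = field(default_factory=dict)


@dataclass
class SnapshotResult:
    masks: list[CellMask]
    foci: list[Focus]
    stats: PlacementStats
    counts: dict = field(default_factory=dict)


def _segment_stack(stack: ImageStack, params: AnalysisParams,
                   counts: dict) -> list[list[CellMask]]:
    masks_by_frame: list[list[CellMask]] = []
    n_unmeasurable = 0
    for t in range(stack.n_frames):
        frame = stack.phase[t]
        masks = segment_frame(frame, stack.pixel_size, params.min_area_px,
                              threshold=params.threshold, counts=counts)
        for m in masks:
            m.frame_index = t
            extract_centerline(m, stack.pixel_size, image=frame)
            if not m.measurable:
                n_unmeasurable += 1
        masks_by_frame.append(masks)
    counts["unmeasurable_masks"] = n_unmeasurable
    return masks_by_frame


def analyze_movie(stack: ImageStack,
                  params: AnalysisParams | None = None) -> MovieResult:
    """Run the full measurement pipeline on a two-channel movie.

    Returns a :class:`MovieResult`; ``result.summary`` holds the headline
    statistics (mean fast/slow pole rates, mean fast:slow ratio, fraction
    faster-on-shorter, Pearson asymmetry correlation, mean
    condensation-to-division delay, and the central-band fraction of septum
    positions).
    """
    params = params or AnalysisParams()
    counts: dict = {}
    dt = stack.frame_interval
    masks_by_frame = _segment_stack(stack, params, counts)
    tracks, divisions = track_cells(masks_by_frame, params.iou_min,
                                    frame_interval=dt)

    foci_by_frame: dict[int, list[Focus]] = {}
    for t in range(stack.n_frames):
        foci_by_frame[t] = detect_foci(stack.fluor[t], masks_by_frame[t],
                                       k_mad=params.k_mad,
                                       d_pole=params.d_pole)
    counts["foci_detected"] = sum(len(v) for v in foci_by_frame.values())

    # organise internal foci per cell track
    track_by_frame_label = {(f, tr.labels[f]): tr.track_id
                            for tr in tracks for f in tr.frames}
    foci_of_track: dict[int, dict[int, list[Focus]]] = {}
    for t, foci in foci_by_frame.items():
        for f in foci:
            tid = track_by_frame_label.get((t, f.cell_label))
            if tid is None:
                continue
            foci_of_track.setdefault(tid, {}).setdefault(t, []).append(f)

    focus_tracks: list[FocusTrack] = []
    septum_events: dict[int, SeptumEvent] = {}
    track_of_id = {tr.track_id: tr for tr in tracks}
    for tid, by_frame in foci_of_track.items():
        ftracks = track_foci(by_frame, params.max_step_um, cell_track_id=tid)
        focus_tracks.extend(ftracks)
        events = [ev for ev in (detect_condensation(ft, params.epsilon,
                                                    params.k_frames, dt)
                                for ft in ftracks) if ev is not None]
        if events:
            # the true septal spot marks the division site, so its track
            # persists to the end of the cell track; patch tracks die early.
            cell_end = track_of_id[tid].end_frame
            events.sort(key=lambda e: (e.track.frames[-1] < cell_end - 1,
                                       e.condensation_frame, -len(e.track)))
            septum_events[tid] = events[0]
    counts["focus_tracks"] = len(focus_tracks)
    counts["septum_events"] = len(septum_events)

    # per-division growth records
    masks_at = {(m.frame_index, m.label): m
                for frame in masks_by_frame for m in frame}
    track_of = {tr.track_id: tr for tr in tracks}
    records = []
    delays: list[float] = []
    n_skipped = 0
    for div in divisions:
        ev = septum_events.get(div.parent_track_id)
        if ev is None:
            n_skipped += 1
            continue
        parent = track_of[div.parent_track_id]
        cond_f = ev.condensation_frame
        if cond_f not in parent.labels:
            n_skipped += 1
            continue
        pmask = masks_at.get((cond_f, parent.labels[cond_f]))
        if pmask is None or not pmask.measurable:
            n_skipped += 1
            continue
        # stationary septal spot: average its position over the stable phase
        ft = ev.track
        stable_p = [f.p_norm for fr, f in zip(ft.frames, ft.foci)
                    if fr >= cond_f]
        p_hat = float(np.median(stable_p))
        length_sep = float(pmask.length_um)
        t_sep = cond_f * dt
        t_div = div.division_time if div.division_time is not None else (
            (div.division_frame + 1) * dt)
        delays.append(t_div - t_sep)

        d1, d2 = (track_of[d] for d in div.daughter_track_ids)
        m1 = masks_at.get((d1.birth_frame, d1.labels[d1.birth_frame]))
        m2 = masks_at.get((d2.birth_frame, d2.labels[d2.birth_frame]))
        if (m1 is None or m2 is None or not m1.measurable
                or not m2.measurable or pmask.pole_a is None):
            n_skipped += 1
            continue

        def dist(mask: CellMask, pole: tuple[float, float]) -> float:
            cr, cc = mask.centroid
            return math.hypot(cr - pole[0], cc - pole[1])

        if dist(m1, pmask.pole_a) > dist(m2, pmask.pole_a):
            m1, m2 = m2, m1   # m1 is the pole-A (side A) daughter
        try:
            rec = pole_growth_rates(
                div.parent_track_id, t_sep, t_div,
                side_a_at_sep=p_hat * length_sep,
                side_b_at_sep=(1.0 - p_hat) * length_sep,
                side_a_at_div=float(m1.length_um),
                side_b_at_div=float(m2.length_um))
        except ValueError as err:
            log.warning("division of track %d not usable: %s",
                        div.parent_track_id, err)
            n_skipped += 1
            continue
        records.append(rec)
    counts["divisions"] = len(divisions)
    counts["growth_records"] = len(records)
    counts["divisions_skipped"] = n_skipped

    placement = None
    if septum_events:
        positions = [ev.p_at_condensation for ev in septum_events.values()]
        lengths = []
        for tid, ev in septum_events.items():
            tr = track_of[tid]
            m = masks_at.get((ev.condensation_frame,
                              tr.labels.get(ev.condensation_frame)))
            lengths.append(m.length_um if m is not None and m.measurable
                           else np.nan)
        ok = ~np.isnan(lengths)
        placement = PlacementStats(
            positions=positions,
            central_frac=central_fraction(positions),
            lengths=list(np.asarray(lengths)[ok]),
            mean_length=float(np.nanmean(lengths)),
            sd_length=float(np.nanstd(lengths, ddof=1))
            if ok.sum() > 1 else 0.0,
        )

    summary: dict = {
        "n_tracks": len(tracks),
        "n_divisions": len(divisions),
        "n_septum_events": len(septum_events),
        "n_growth_records": len(records),
        "mean_delay_min": float(np.mean(delays)) if delays else float("nan"),
        "central_fraction": (placement.central_frac
                             if placement is not None else float("nan")),
    }
    if records:
        summary.update(asymmetry_stats(records))
    result = MovieResult(masks_by_frame, foci_by_frame, tracks, divisions,
                         focus_tracks, septum_events, records, delays,
                         placement, summary, counts)
    return result


def analyze_snapshot(stack: ImageStack,
                     params: AnalysisParams | None = None) -> SnapshotResult:
    """Measure a static frame: segment, measure lengths, detect foci, and
    summarise placement over three-spot cells."""
    params = params or AnalysisParams()
    counts: dict = {}
    frame = stack.phase[0]
    masks = segment_frame(frame, stack.pixel_size, params.min_area_px,
                          threshold=params.threshold, counts=counts)
    for m in masks:
        extract_centerline(m, stack.pixel_size, image=frame)
    counts["unmeasurable_masks"] = sum(not m.measurable for m in masks)
    foci = detect_foci(stack.fluor[0], masks, k_mad=params.k_mad,
                       d_pole=params.d_pole)
    foci_by_cell: dict[int, list[Focus]] = {}
    for f in foci:
        foci_by_cell.setdefault(f.cell_label, []).append(f)
    lengths_by_cell = {m.label: float(m.length_um)
                       for m in masks if m.measurable}
    lengths = list(lengths_by_cell.values())
    stats = summarize_population(
        lengths,
        foci_by_cell={k: v for k, v in foci_by_cell.items()
                      if k in lengths_by_cell},
        lengths_by_cell=lengths_by_cell,
    )
    counts["foci_detected"] = len(foci)
    counts["three_spot_cells"] = stats.n_three_spot or 0
    return SnapshotResult(masks, foci, stats, counts)


# ---------------------------------------------------------------------------
# evaluation against generator ground truth

def evaluate_against_truth(result: MovieResult, truth: pd.DataFrame,
                           pixel_size: float,
                           frame_interval: float) -> dict:
    """Compare pipeline output with the generator's truth table.

    Matches each truth cell to the mask containing its midpoint, then
    scores length errors (µm), division recovery within ±1 frame, and
    condensation-frame errors.
    """
    masks_at = {(m.frame_index, m.label): m
                for frame in result.masks_by_frame for m in frame}
    shape = next(iter(masks_at.values())).shape if masks_at else None
    label_imgs: dict[int, np.ndarray] = {}
    for (f, _lab), m in masks_at.items():
        img = label_imgs.setdefault(f, np.zeros(shape, dtype=np.int32))
        img[m.pixels[:, 0], m.pixels[:, 1]] = m.label
    label_of_cell: dict[tuple[int, int], int] = {}
    length_errors: list[float] = []
    for row in truth.itertuples():
        img = label_imgs.get(row.frame)
        if img is None:
            continue
        mid_r = int(round((row.pole_a_row + row.pole_b_row) / 2))
        mid_c = int(round((row.pole_a_col + row.pole_b_col) / 2))
        lab = int(img[mid_r, mid_c])
        if lab == 0:
            continue
        label_of_cell[(row.frame, row.cell_id)] = lab
        m = masks_at[(row.frame, lab)]
        if m.measurable:
            length_errors.append(abs(m.length_um - row.length_um))

    track_by_frame_label = {(f, tr.labels[f]): tr.track_id
                            for tr in result.tracks for f in tr.frames}
    # truth divisions: last rendered frame of each dividing cell
    truth_divs = truth[truth.event.fillna("").str.contains("division")]
    found = 0
    for row in truth_divs.itertuples():
        lab = label_of_cell.get((row.frame, row.cell_id))
        tid = track_by_frame_label.get((row.frame, lab))
        hit = any(d.parent_track_id == tid
                  and abs(d.division_frame - row.frame) <= 1
                  for d in result.divisions)
        found += bool(hit)

    cond_errors: list[int] = []
    truth_cond = truth[truth.event.fillna("").str.contains("condensation")]
    for row in truth_cond.itertuples():
        lab = label_of_cell.get((row.frame, row.cell_id))
        tid = track_by_frame_label.get((row.frame, lab))
        ev = result.septum_events.get(tid)
        if ev is not None:
            cond_errors.append(ev.condensation_frame - row.frame)

    return {
        "n_truth_rows": len(truth),
        "n_matched_rows": len(label_of_cell),
        "median_abs_length_error_um": (float(np.median(length_errors))
                                       if length_errors else float("nan")),
        "median_abs_length_error_px": (float(np.median(length_errors))
                                       / pixel_size
                                       if length_errors else float("nan")),
        "n_truth_divisions": len(truth_divs),
        "n_divisions_recovered": found,
        "n_spurious_divisions": len(result.divisions) - found,
        "condensation_frame_errors": cond_errors,
    }


# ---------------------------------------------------------------------------
# file-based runs

def run_simulate(config: SimConfig, out_dir: str | Path,
                 seed: int | None = None) -> Path:
    """Simulate and render a movie; write TIFFs, truth CSV, config snapshot
    and manifest into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    used_seed = config.seed if seed is None else seed
    truths = simulate_population(config, used_seed)
    stack, truth = render_movie(truths, config, used_seed)
    ptio.write_stack(stack, out)
    ptio.write_truth(truth, out / "truth.csv")
    config.to_yaml(out / "config.yaml")
    ptio.write_manifest(
        out / "manifest.json", config=config.to_dict(), seed=used_seed,
        version=__version__, inputs={},
        outputs={"phase": "phase.tif", "fluor": "fluor.tif",
                 "truth": "truth.csv"},
        counts={"cells_simulated": len(truths),
                "truth_rows": len(truth),
                "frames": stack.n_frames})
    return out


def run_analyze(in_dir: str | Path, out_dir: str | Path,
                params: AnalysisParams | None = None,
                evaluate: bool = True) -> MovieResult:
    """Analyse a rendered movie directory end to end and write all stage
    outputs (masks, cells, foci, lineage, stats, JSON report, manifest)."""
    import json

    src = Path(in_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack = ptio.read_stack(src)
    result = analyze_movie(stack, params)

    ptio.write_masks(result.masks_by_frame, stack.shape, out / "masks.tif")
    ptio.write_cells_csv(result.masks_by_frame, out / "cells.csv")
    ptio.write_foci_csv(result.foci_by_frame, None, out / "foci.csv")
    lengths = {(m.frame_index, m.label): m.length_um
               for frame in result.masks_by_frame for m in frame}
    ptio.write_lineage_csvs(result.tracks, result.divisions, lengths, out)
    if result.placement is not None:
        ptio.write_histogram_csv(result.placement.lengths,
                                 out / "length_histogram.csv")
    report = dict(result.summary)
    truth_path = src / "truth.csv"
    if evaluate and truth_path.exists():
        truth = ptio.read_truth(truth_path)
        report["evaluation"] = evaluate_against_truth(
            result, truth, stack.pixel_size, stack.frame_interval)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    ptio.write_manifest(
        out / "manifest.json", config=vars(params or AnalysisParams()),
        seed=-1, version=__version__,
        inputs={"movie": str(src)},
        outputs={"report": "report.json"},
        counts=result.counts)
    return result


def simulate_snapshot_population(mean_um: float, sd_um: float, n: int,
                                 config: SimConfig, seed: int,
                                 ) -> tuple[ImageStack, pd.DataFrame,
                                            list[float]]:
    """Draw ``n`` truth lengths from Normal(mean, sd) (truncated at
    ``config.min_length``) with mid-cell-offset spot positions, and render
    the static three-spot scene."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
    lengths: list[float] = []
    while len(lengths) < n:
        x = rng.normal(mean_um, sd_um)
        if x > config.min_length:
            lengths.append(float(x))
    pos = np.clip(0.5 + rng.normal(0.0, config.placement_offset_sd, n),
                  0.02, 0.98)
    stack, truth = render_static_snapshot(lengths, list(pos), config,
                                          seed=seed)
    return stack, truth, lengths
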