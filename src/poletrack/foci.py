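"""Fluorescent focus detection, classification, tracking and condensation.

Foci are detected as the maximal-intensity pixel of each connected
above-threshold region inside a cell mask, the threshold being the frame's
background median plus ``k`` median absolute deviations.  Each focus is
projected onto its cell's centerline to obtain an arclength coordinate
``s`` (µm from pole A) and the normalized position ``p = s / L``; a focus is
polar when it lies within ``d_pole`` of either pole, internal otherwise.
Internal foci are linked frame-to-frame within a cell track by optimal
assignment on |Δs| with a gating distance, and a track's condensation event
is the earliest run of ``k_frames`` consecutive positions that stay within
±epsilon of their forward running median — the moment a wandering patch
becomes a stable septal spot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import label as nd_label
from scipy.optimize import linear_sum_assignment

from .segmentation import CellMask

log = logging.getLogger(__name__)

__all__ = [
    "Focus", "FocusTrack", "SeptumEvent",
    "detect_foci", "classify_focus", "track_foci", "detect_condensation",
]


@dataclass
class Focus:
    """One detected fluorescent spot."""

    frame_index: int
    cell_label: int
    pixel: tuple[int, int]
    intensity: float
    s_um: float           # arclength from pole A
    p_norm: float         # s / L in [0, 1]
    focus_class: str      # "polar" | "internal"


@dataclass
class FocusTrack:
    """An internal focus followed over consecutive frames of one cell."""

    cell_track_id: int
    frames: list[int] = field(default_factory=list)
    foci: list[Focus] = field(default_factory=list)

    @property
    def p(self) -> np.ndarray:
        return np.array([f.p_norm for f in self.foci])

    @property
    def s(self) -> np.ndarray:
        return np.array([f.s_um for f in self.foci])

    def __len__(self) -> int:
        return len(self.foci)


@dataclass
class SeptumEvent:
    """Condensation of a wandering patch into a stable septal spot."""

    cell_track_id: int
    condensation_frame: int
    condensation_time: float | None
    p_at_condensation: float
    track: FocusTrack


def detection_threshold(fluor_image: np.ndarray, k_mad: float = 5.0) -> float:
    """Background median + k * MAD over the whole frame."""
    img = np.asarray(fluor_image, dtype=float)
    med = float(np.median(img))
    mad = float(np.median(np.abs(img - med)))
    return med + k_mad * mad


def classify_focus(s_um: float, length_um: float,
                   d_pole: float = 0.5) -> str:
    """Polar iff the focus lies within ``d_pole`` µm of either pole
    (boundary inclusive), internal otherwise."""
    return "polar" if min(s_um, length_um - s_um) <= d_pole else "internal"


def detect_foci(fluor_image: np.ndarray, masks: Sequence[CellMask],
                k_mad: float = 5.0, d_pole: float = 0.5,
                threshold: float | None = None,
                min_separation_um: float = 0.25) -> list[Focus]:
    """Detect foci as maximal-intensity pixels of candidate regions.

    Within each measurable mask, candidate pixels are those whose
    fluorescence exceeds the frame threshold; each connected candidate
    region yields exactly one focus at its maximal-intensity pixel (ties
    resolved to the first pixel in row-major order).  The focus inherits the
    containing cell's label and is projected onto the nearest centerline
    point for its arclength coordinate.

    Two maxima closer than ``min_separation_um`` along the centerline are
    one physical focus whose region was transiently split by noise; only
    the brighter is kept (non-maximum suppression, the same rationale as
    the one-focus-per-region rule that stops PSF shoulders from double
    counting).

    A mask with no pixel above threshold simply yields no foci.
    """
    img = np.asarray(fluor_image, dtype=float)
    thr = detection_threshold(img, k_mad) if threshold is None else threshold
    out: list[Focus] = []
    for mask in masks:
        if not mask.measurable or mask.centerline is None:
            continue
        pix = mask.pixels
        r0, c0 = pix[:, 0].min(), pix[:, 1].min()
        r1, c1 = pix[:, 0].max() + 1, pix[:, 1].max() + 1
        local = np.zeros((r1 - r0, c1 - c0), bool)
        local[pix[:, 0] - r0, pix[:, 1] - c0] = True
        sub = img[r0:r1, c0:c1]
        cand = local & (sub > thr)
        if not cand.any():
            continue
        cell_foci: list[Focus] = []
        labels, n = nd_label(cand, structure=np.ones((3, 3), int))
        for lab in range(1, n + 1):
            coords = np.argwhere(labels == lab)      # row-major order
            vals = sub[coords[:, 0], coords[:, 1]]
            best = int(np.argmax(vals))              # first max in row-major
            rr, cc = coords[best] + (r0, c0)
            d2 = ((mask.centerline[:, 0] - rr) ** 2
                  + (mask.centerline[:, 1] - cc) ** 2)
            idx = int(np.argmin(d2))
            s = float(mask.arclength_um[idx])
            length = float(mask.length_um)
            cell_foci.append(Focus(
                frame_index=mask.frame_index,
                cell_label=mask.label,
                pixel=(int(rr), int(cc)),
                intensity=float(vals[best]),
                s_um=s,
                p_norm=s / length,
                focus_class=classify_focus(s, length, d_pole),
            ))
        # non-maximum suppression along the centerline
        cell_foci.sort(key=lambda f: (-f.intensity, f.s_um))
        kept: list[Focus] = []
        for f in cell_foci:
            if all(abs(f.s_um - k.s_um) >= min_separation_um for k in kept):
                kept.append(f)
        kept.sort(key=lambda f: f.s_um)
        out.extend(kept)
    return out


def track_foci(foci_by_frame: Mapping[int, Sequence[Focus]],
               max_step_um: float = 0.3,
               cell_track_id: int = 0) -> list[FocusTrack]:
    """Link internal foci of one cell track across frames.

    Consecutive frames are matched by optimal assignment minimising the
    total arclength displacement; any link with |Δs| > ``max_step_um`` is
    rejected, and unlinked foci start new tracks.  Ties are deterministic
    (smaller |Δs|, then frame-order index).
    """
    frames = sorted(foci_by_frame)
    tracks: list[FocusTrack] = []
    active: dict[int, FocusTrack] = {}  # index of focus in previous frame
    prev: list[Focus] = []
    prev_frame: int | None = None
    for f in frames:
        cur = [x for x in foci_by_frame[f] if x.focus_class == "internal"]
        new_active: dict[int, FocusTrack] = {}
        if prev and cur and prev_frame == f - 1:
            cost = np.full((len(prev), len(cur)), 1e9)
            for i, a in enumerate(prev):
                for j, b in enumerate(cur):
                    d = abs(b.s_um - a.s_um)
                    if d <= max_step_um:
                        cost[i, j] = d
            ri, cj = linear_sum_assignment(cost)
            for i, j in zip(ri, cj):
                if cost[i, j] < 1e9:
                    tr = active[i]
                    tr.frames.append(f)
                    tr.foci.append(cur[j])
                    new_active[j] = tr
        for j, b in enumerate(cur):
            if j not in new_active:
                tr = FocusTrack(cell_track_id=cell_track_id,
                                frames=[f], foci=[b])
                tracks.append(tr)
                new_active[j] = tr
        active = new_active
        prev = cur
        prev_frame = f
    # tracks were appended on creation; order by first frame then position
    tracks.sort(key=lambda t: (t.frames[0], t.foci[0].s_um))
    return tracks


def detect_condensation(track: FocusTrack, epsilon: float = 0.05,
                        k_frames: int = 3,
                        frame_interval: float | None = None,
                        ) -> SeptumEvent | None:
    """Earliest frame from which the track is stable for ``k_frames`` frames.

    Stability at start index ``i``: for each of the next ``k_frames``
    observations, the position stays within ±``epsilon`` of the forward
    running median computed from ``i``.  Returns ``None`` when the track is
    shorter than ``k_frames`` or never stabilises.
    """
    p = track.p
    n = len(p)
    if n < k_frames:
        return None
    for i in range(0, n - k_frames + 1):
        ok = True
        for j in range(i, i + k_frames):
            med = float(np.median(p[i:j + 1]))
            if abs(p[j] - med) > epsilon:
                ok = False
                break
        if ok:
            frame = track.frames[i]
            return SeptumEvent(
                cell_track_id=track.cell_track_id,
                condensation_frame=frame,
                condensation_time=(None if frame_interval is None
                                   else frame * frame_interval),
                p_at_condensation=float(np.median(p[i:i + k_frames])),
                track=track,
            )
    return None
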