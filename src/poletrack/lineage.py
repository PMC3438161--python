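"""Frame-to-frame cell tracking, division detection and lineage trees.

Masks are linked between consecutive frames by pixel overlap: a successor
mask is attached to the predecessor with which it shares the most pixels,
and the link is kept when the intersection-over-union reaches ``iou_min``.
A division is declared when one mask at frame t is succeeded by two masks at
t+1, each overlapping the parent with IoU at least ``iou_min / 2`` — the
one-into-two topology change of the label image, which is observable in the
phase channel once the daughters separate.  Lineages are binary forests: a
track has zero or two daughters and at most one parent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .segmentation import CellMask

log = logging.getLogger(__name__)

__all__ = ["CellTrack", "DivisionEvent", "track_cells"]


@dataclass
class CellTrack:
    """One cell followed over a contiguous run of frames."""

    track_id: int
    birth_frame: int
    labels: dict[int, int] = field(default_factory=dict)  # frame -> label
    parent_track_id: int | None = None
    daughter_track_ids: list[int] = field(default_factory=list)

    @property
    def end_frame(self) -> int:
        return max(self.labels)

    @property
    def frames(self) -> list[int]:
        return sorted(self.labels)


@dataclass
class DivisionEvent:
    """A one-into-two topology change between consecutive frames."""

    parent_track_id: int
    daughter_track_ids: tuple[int, int]
    division_frame: int          # parent's last frame
    division_time: float | None  # time of the daughters' first frame
    parent_length_um: float | None = None
    daughter_lengths_um: tuple[float, float] | None = None


def _label_image(masks: Sequence[CellMask], shape: tuple[int, int]
                 ) -> np.ndarray:
    img = np.zeros(shape, dtype=np.int32)
    for m in masks:
        img[m.pixels[:, 0], m.pixels[:, 1]] = m.label
    return img


def _overlaps(lab0: np.ndarray, lab1: np.ndarray
              ) -> dict[tuple[int, int], int]:
    both = (lab0 > 0) & (lab1 > 0)
    pairs, counts = np.unique(
        np.stack([lab0[both], lab1[both]]), axis=1, return_counts=True
    ) if both.any() else (np.empty((2, 0), int), np.empty(0, int))
    return {(int(a), int(b)): int(n)
            for (a, b), n in zip(pairs.T, counts)}


def track_cells(masks_by_frame: Sequence[Sequence[CellMask]],
                iou_min: float = 0.3,
                frame_interval: float | None = None,
                ) -> tuple[list[CellTrack], list[DivisionEvent]]:
    """Link per-frame masks into tracks and detect divisions.

    Parameters
    ----------
    masks_by_frame:
        One list of :class:`CellMask` per frame, labels unique per frame.
    iou_min:
        Minimum IoU for a frame-to-frame continuation link; daughters of a
        division must each reach ``iou_min / 2`` against the parent.
    frame_interval:
        Minutes per frame; fills ``DivisionEvent.division_time``.

    Returns
    -------
    (tracks, divisions).  Tracks have contiguous frames; a track that
    divides ends at the division frame and its daughters begin on the next
    frame.  Daughter lengths are recorded when the masks are measured.
    """
    tracks: list[CellTrack] = []
    divisions: list[DivisionEvent] = []
    if not masks_by_frame:
        return tracks, divisions

    shape = None
    for frame_masks in masks_by_frame:
        for m in frame_masks:
            shape = m.shape
            break
        if shape:
            break
    if shape is None:
        return tracks, divisions

    active: dict[int, CellTrack] = {}  # current-frame label -> track
    first = 0
    for m in masks_by_frame[0]:
        tr = CellTrack(track_id=len(tracks), birth_frame=first,
                       labels={first: m.label})
        tracks.append(tr)
        active[m.label] = tr

    for t in range(len(masks_by_frame) - 1):
        cur = list(masks_by_frame[t])
        nxt = list(masks_by_frame[t + 1])
        areas0 = {m.label: m.area_px for m in cur}
        areas1 = {m.label: m.area_px for m in nxt}
        lab0 = _label_image(cur, shape)
        lab1 = _label_image(nxt, shape)
        inter = _overlaps(lab0, lab1)

        # each next-frame mask picks its best predecessor by overlap
        best_parent: dict[int, tuple[int, int]] = {}  # next label -> (parent, inter)
        for (a, b), n in inter.items():
            if b not in best_parent or n > best_parent[b][1]:
                if b in best_parent and n > best_parent[b][1]:
                    log.info("frame %d: mask %d overlaps two parents; "
                             "keeping larger overlap", t + 1, b)
                best_parent[b] = (a, n)

        children: dict[int, list[int]] = {}
        for b, (a, _n) in best_parent.items():
            children.setdefault(a, []).append(b)

        new_active: dict[int, CellTrack] = {}
        for a, kids in children.items():
            if a not in active:
                continue
            parent_track = active[a]

            def iou(b: int) -> float:
                n = inter[(a, b)]
                return n / (areas0[a] + areas1[b] - n)

            kids_iou = sorted(((iou(b), b) for b in kids), reverse=True)
            if len(kids) == 1:
                i, b = kids_iou[0]
                if i >= iou_min:
                    parent_track.labels[t + 1] = b
                    new_active[b] = parent_track
                continue
            top2 = [kb for kb in kids_iou[:2] if kb[0] >= iou_min / 2]
            if len(top2) == 2:
                if len(kids) > 2:
                    log.info("frame %d: parent %d split into %d pieces; "
                             "keeping two largest", t + 1, a, len(kids))
                d_tracks = []
                for _i, b in top2:
                    dt = CellTrack(track_id=len(tracks), birth_frame=t + 1,
                                   labels={t + 1: b},
                                   parent_track_id=parent_track.track_id)
                    tracks.append(dt)
                    new_active[b] = dt
                    d_tracks.append(dt)
                parent_track.daughter_track_ids = [d.track_id
                                                  for d in d_tracks]
                masks1 = {m.label: m for m in nxt}
                dl = tuple(masks1[b].length_um for _i, b in top2)
                masks0 = {m.label: m for m in cur}
                divisions.append(DivisionEvent(
                    parent_track_id=parent_track.track_id,
                    daughter_track_ids=(d_tracks[0].track_id,
                                        d_tracks[1].track_id),
                    division_frame=t,
                    division_time=(None if frame_interval is None
                                   else (t + 1) * frame_interval),
                    parent_length_um=masks0[a].length_um,
                    daughter_lengths_um=(dl if None not in dl else None),
                ))
            elif kids_iou and kids_iou[0][0] >= iou_min:
                # only one plausible successor; treat as continuation
                _i, b = kids_iou[0]
                parent_track.labels[t + 1] = b
                new_active[b] = parent_track

        # unlinked next-frame masks start fresh tracks
        for m in nxt:
            if m.label not in new_active:
                tr = CellTrack(track_id=len(tracks), birth_frame=t + 1,
                               labels={t + 1: m.label})
                tracks.append(tr)
                new_active[m.label] = tr
        active = new_active

    return tracks, divisions
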