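"""Render simulated cells into noisy two-channel image stacks.

The phase channel draws each cell as a dark capsule (rectangle with
semicircular caps) on a bright background, binary before convolution with a
Gaussian PSF; additive Gaussian noise comes last.  The fluorescence channel
carries 2-D Gaussian foci: one at each pole throughout, plus an internal
patch (broad, wandering) before condensation and a tight septal spot after.
During the final pre-division frames the capsule is locally constricted at
the septum (invagination); at division the daughters are drawn with a small
clear gap at the division plane.

Cells are laid out on a grid of non-overlapping slots, one per founder
lineage, all horizontal.  A founder keeps its centre fixed; after a division
each daughter is anchored at the septum plane (shifted outward by half the
separation gap), so growth extends away from the division site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import SimConfig
from .simulate import CellTruth, movie_length

__all__ = [
    "ImageStack",
    "PlacementError",
    "render_movie",
    "render_static_snapshot",
    "draw_capsule",
    "add_gaussian_spot",
    "TRUTH_COLUMNS",
]

TRUTH_COLUMNS = [
    "frame", "cell_id", "length_um",
    "pole_a_row", "pole_a_col", "pole_b_row", "pole_b_col",
    "septum_pos_norm", "spot_pos_norm", "spot_row", "spot_col", "event",
]


class PlacementError(RuntimeError):
    """A cell would overlap a neighbour or leave the field of view."""


@dataclass
class ImageStack:
    """A two-channel grayscale movie with physical calibration.

    ``phase`` and ``fluor`` are (time, row, col) float arrays sharing shape;
    intensities are non-negative.
    """

    phase: np.ndarray
    fluor: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        if self.phase.shape != self.fluor.shape:
            raise ValueError("phase and fluor channels must share shape")
        if self.phase.ndim != 3:
            raise ValueError("expected (time, row, col) arrays")

    @property
    def n_frames(self) -> int:
        return self.phase.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase.shape[1:]


# ---------------------------------------------------------------------------
# low-level drawing primitives (shared with tests)

def draw_capsule(canvas: np.ndarray, tip_a: tuple[float, float],
                 tip_b: tuple[float, float], radius: float,
                 value: float) -> np.ndarray:
    """Paint a filled capsule (stadium) of tip-to-tip axis ``tip_a``→``tip_b``
    onto ``canvas`` in place.

    ``radius`` is the half-width in pixels; the capsule's total length along
    the axis is the tip distance (the segment of the distance test is inset
    by ``radius`` at both ends).  Returns the boolean mask painted.
    """
    (r0, c0), (r1, c1) = tip_a, tip_b
    length = math.hypot(r1 - r0, c1 - c0)
    if length < 2 * radius:
        raise PlacementError("capsule shorter than its width")
    ur, uc = (r1 - r0) / length, (c1 - c0) / length
    a = (r0 + ur * radius, c0 + uc * radius)
    b = (r1 - ur * radius, c1 - uc * radius)

    rmin = max(0, int(math.floor(min(r0, r1) - radius - 1)))
    rmax = min(canvas.shape[0], int(math.ceil(max(r0, r1) + radius + 2)))
    cmin = max(0, int(math.floor(min(c0, c1) - radius - 1)))
    cmax = min(canvas.shape[1], int(math.ceil(max(c0, c1) + radius + 2)))
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    # distance from each pixel centre to segment a-b
    ar, ac = rr - a[0], cc - a[1]
    br, bc = b[0] - a[0], b[1] - a[1]
    seg2 = br * br + bc * bc
    t = np.clip((ar * br + ac * bc) / seg2, 0.0, 1.0) if seg2 > 0 else 0.0
    dr = ar - t * br
    dc = ac - t * bc
    inside = dr * dr + dc * dc <= radius * radius
    canvas[rmin:rmax, cmin:cmax][inside] = value
    full = np.zeros(canvas.shape, bool)
    full[rmin:rmax, cmin:cmax] = inside
    return full


def add_gaussian_spot(canvas: np.ndarray, center: tuple[float, float],
                      sigma: float, amplitude: float) -> None:
    """Add an isotropic 2-D Gaussian of peak ``amplitude`` in place."""
    r0, c0 = center
    ext = int(math.ceil(4.5 * sigma)) + 1
    rmin = max(0, int(math.floor(r0 - ext)))
    rmax = min(canvas.shape[0], int(math.ceil(r0 + ext)) + 1)
    cmin = max(0, int(math.floor(c0 - ext)))
    cmax = min(canvas.shape[1], int(math.ceil(c0 + ext)) + 1)
    if rmin >= rmax or cmin >= cmax:
        return
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    canvas[rmin:rmax, cmin:cmax] += amplitude * np.exp(-d2 / (2 * sigma**2))


# ---------------------------------------------------------------------------
# scene layout

@dataclass
class _Geom:
    """Placement of one cell on one frame (pixel units, horizontal)."""
    cell: CellTruth
    row: float
    x_left: float
    x_right: float

    @property
    def length_px(self) -> float:
        return self.x_right - self.x_left


def _lineage_anchors(founder: CellTruth, by_parent: dict[int, list[CellTruth]],
                     cfg: SimConfig) -> dict[int, tuple[str, float]]:
    """Anchor rule per cell in lineage-local µm coordinates.

    Founder: centre fixed at 0.  Daughter A: right edge fixed at the septum
    plane minus half the separation gap; daughter B: left edge at the plane
    plus half the gap.  Recursion handles further generations.
    """
    anchors: dict[int, tuple[str, float]] = {founder.cell_id: ("center", 0.0)}
    stack = [founder]
    g = cfg.separation_gap / 2.0
    while stack:
        cell = stack.pop()
        kids = by_parent.get(cell.cell_id, [])
        if not kids or cell.division_time is None:
            continue
        t_div = cell.division_time
        left, _right = _span(cell, anchors[cell.cell_id], t_div)
        xs = left + cell.septum_position_norm * cell.length_at(t_div)
        # children are appended in (A, B) order by the simulator
        kid_a, kid_b = kids
        anchors[kid_a.cell_id] = ("right", xs - g)
        anchors[kid_b.cell_id] = ("left", xs + g)
        stack.extend(kids)
    return anchors


def _span(cell: CellTruth, anchor: tuple[str, float],
          t: float) -> tuple[float, float]:
    kind, x = anchor
    length = cell.length_at(t)
    if kind == "center":
        return x - length / 2.0, x + length / 2.0
    if kind == "right":
        return x - length, x
    return x, x + length


def _layout_movie(truths: list[CellTruth], cfg: SimConfig,
                  n_frames: int) -> tuple[list[list[_Geom]], tuple[int, int]]:
    """Per-frame geometries and the canvas shape."""
    founders = [c for c in truths if c.parent_id is None]
    by_parent: dict[int, list[CellTruth]] = {}
    for c in truths:
        if c.parent_id is not None:
            by_parent.setdefault(c.parent_id, []).append(c)
    for kids in by_parent.values():
        kids.sort(key=lambda c: c.cell_id)

    px = cfg.pixel_size
    margin = max(10, int(math.ceil(3 * cfg.psf_sigma_px)),
                 int(math.ceil(2 * cfg.cell_width_px)))

    by_id = {c.cell_id: c for c in truths}
    roots: dict[int, int] = {}
    for c in truths:
        node = c
        while node.parent_id is not None:
            node = by_id[node.parent_id]
        roots[c.cell_id] = node.cell_id

    per_lineage: list[tuple[CellTruth, float, float]] = []
    geoms_local: dict[int, list[tuple[CellTruth, float, float]]] = {
        f: [] for f in range(n_frames)
    }
    lineage_of: dict[int, int] = {}
    for founder in founders:
        anchors = _lineage_anchors(founder, by_parent, cfg)
        lin_cells = [c for c in truths if roots[c.cell_id] == founder.cell_id]
        lo, hi = math.inf, -math.inf
        for c in lin_cells:
            anc = anchors[c.cell_id]
            for f in c.frames(n_frames):
                t = f * cfg.frame_interval
                l, r = _span(c, anc, t)
                lo, hi = min(lo, l), max(hi, r)
                geoms_local[f].append((c, l, r))
                lineage_of[c.cell_id] = founder.cell_id
        per_lineage.append((founder, lo, hi))

    width_um = max((hi - lo) for _, lo, hi in per_lineage)
    slot_w = int(math.ceil(width_um / px)) + 2 * margin
    slot_h = int(math.ceil(cfg.cell_width_px)) + 2 * margin
    n = len(founders)
    ncols = int(math.ceil(math.sqrt(n)))
    nrows = int(math.ceil(n / ncols))
    shape = (nrows * slot_h, ncols * slot_w)

    slot_of = {f.cell_id: i for i, (f, _, _) in enumerate(per_lineage)}
    offsets: dict[int, tuple[float, float]] = {}
    for founder, lo, hi in per_lineage:
        i = slot_of[founder.cell_id]
        r, c = divmod(i, ncols)
        row_center = r * slot_h + slot_h / 2.0
        col_center = c * slot_w + slot_w / 2.0
        # centre the lineage's full extent in its slot
        offsets[founder.cell_id] = (row_center,
                                    col_center - (lo + hi) / 2.0 / px)

    frames_geoms: list[list[_Geom]] = []
    for f in range(n_frames):
        geoms: list[_Geom] = []
        for cell, l, r in geoms_local[f]:
            row, xoff = offsets[lineage_of[cell.cell_id]]
            geoms.append(_Geom(cell, row, xoff + l / px, xoff + r / px))
        geoms.sort(key=lambda g: g.cell.cell_id)
        frames_geoms.append(geoms)

    for geoms in frames_geoms:
        for g in geoms:
            if (g.x_left < 2 or g.x_right > shape[1] - 2
                    or g.row < 2 or g.row > shape[0] - 2):
                raise PlacementError("cell left the field of view")
    return frames_geoms, shape


# ---------------------------------------------------------------------------
# frame rendering

def _render_frame(geoms: list[_Geom], cfg: SimConfig, shape: tuple[int, int],
                  frame: int, rng: np.random.Generator | None,
                  static_spots: dict[int, float] | None = None,
                  ) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Render one frame; returns (phase, fluor, truth rows)."""
    sig = cfg.psf_sigma_px
    hw = cfg.cell_width_px / 2.0
    phase = np.full(shape, cfg.background_level, dtype=np.float64)
    fluor = np.full(shape, cfg.fluor_background, dtype=np.float64)
    rows: list[dict] = []

    for g in geoms:
        cell = g.cell
        mask = draw_capsule(phase, (g.row, g.x_left), (g.row, g.x_right), hw,
                            cfg.background_level - cfg.cell_contrast)
        spot_pos = (static_spots.get(cell.cell_id) if static_spots is not None
                    else cell.spot_position_at(frame))
        xs_px = None
        if spot_pos is not None:
            xs_px = g.x_left + spot_pos * g.length_px

        # invagination: local width constriction in the final frames
        if (static_spots is None and cell.division_frame is not None
                and 0 < cell.division_frame - frame <= cfg.invagination_frames):
            sep_px = g.x_left + cell.septum_position_norm * g.length_px
            rr, cc = np.nonzero(mask)
            notch = (np.abs(cc - sep_px) <= 1.5) & (np.abs(rr - g.row) > 0.55 * hw)
            phase[rr[notch], cc[notch]] = cfg.background_level

        # fluorescence: two polar foci, plus the internal patch/spot
        for pole_x in (g.x_left + hw, g.x_right - hw):
            add_gaussian_spot(fluor, (g.row, pole_x), sig, cfg.focus_amplitude)
        if spot_pos is not None:
            if static_spots is None and frame < cell.condensation_frame:
                add_gaussian_spot(fluor, (g.row, xs_px),
                                  sig * cfg.patch_sigma_factor,
                                  cfg.patch_amplitude)
            else:
                add_gaussian_spot(fluor, (g.row, xs_px), sig,
                                  cfg.focus_amplitude)

        events = []
        if static_spots is None:
            if frame == cell.birth_frame and cell.parent_id is not None:
                events.append("birth")
            if frame == cell.appearance_frame:
                events.append("appearance")
            if frame == cell.condensation_frame:
                events.append("condensation")
            if cell.division_frame is not None and frame == cell.division_frame - 1:
                events.append("division")
        t = frame * cfg.frame_interval
        rows.append({
            "frame": frame,
            "cell_id": cell.cell_id,
            "length_um": (g.length_px * cfg.pixel_size if static_spots is not None
                          else cell.length_at(t)),
            "pole_a_row": g.row, "pole_a_col": g.x_left,
            "pole_b_row": g.row, "pole_b_col": g.x_right,
            "septum_pos_norm": cell.septum_position_norm,
            "spot_pos_norm": np.nan if spot_pos is None else spot_pos,
            "spot_row": np.nan if spot_pos is None else g.row,
            "spot_col": np.nan if spot_pos is None else xs_px,
            "event": "+".join(events),
        })

    phase = gaussian_filter(phase, sig, mode="nearest")
    if rng is not None and cfg.noise_sd > 0:
        phase = phase + rng.normal(0.0, cfg.noise_sd, shape)
        fluor = fluor + rng.normal(0.0, cfg.noise_sd, shape)
    np.clip(phase, 0.0, None, out=phase)
    np.clip(fluor, 0.0, None, out=fluor)
    return phase.astype(np.float32), fluor.astype(np.float32), rows


def render_movie(truths: list[CellTruth], config: SimConfig,
                 seed: int | None = None,
                 ) -> tuple[ImageStack, pd.DataFrame]:
    """Render a simulated population into a two-channel movie.

    Parameters
    ----------
    truths:
        Output of :func:`~poletrack.simulate.simulate_population` (same
        config).
    config:
        Generator configuration; ``noise_sd = 0`` gives a fully
        deterministic render.
    seed:
        Overrides ``config.seed`` for the noise streams.

    Returns
    -------
    (stack, truth_table):
        The :class:`ImageStack` and a per-frame per-cell ground-truth table
        with columns ``TRUTH_COLUMNS``.
    """
    if not truths:
        raise ValueError("truths must be non-empty")
    n_frames = movie_length(truths, config)
    frames_geoms, shape = _layout_movie(truths, config, n_frames)
    master = config.seed if seed is None else seed
    rng = (np.random.default_rng(np.random.SeedSequence([int(master), 2]))
           if config.noise_sd > 0 else None)

    phase = np.empty((n_frames, *shape), dtype=np.float32)
    fluor = np.empty_like(phase)
    all_rows: list[dict] = []
    for f in range(n_frames):
        ph, fl, rows = _render_frame(frames_geoms[f], config, shape, f, rng)
        phase[f], fluor[f] = ph, fl
        all_rows.extend(rows)
    truth = pd.DataFrame(all_rows, columns=TRUTH_COLUMNS)
    stack = ImageStack(phase, fluor, config.pixel_size, config.frame_interval)
    return stack, truth


def render_static_snapshot(lengths: list[float],
                           spot_positions_norm: list[float],
                           config: SimConfig,
                           seed: int | None = None,
                           ) -> tuple[ImageStack, pd.DataFrame]:
    """Render a single frame of static three-spot cells.

    Each cell carries two polar foci plus one internal focus at the given
    normalized position.  Mirrors the static-microscopy experiment in which
    cells with an internal septal spot were photographed once and measured.

    Parameters
    ----------
    lengths:
        True cell lengths in µm (one cell each).
    spot_positions_norm:
        Normalized internal-spot positions, each strictly inside (0, 1).

    Returns
    -------
    (stack, truth_table): a one-frame :class:`ImageStack` and the truth
    table (zero rows when ``lengths`` is empty).
    """
    if len(lengths) != len(spot_positions_norm):
        raise ValueError("lengths and spot positions must have equal count")
    for p in spot_positions_norm:
        if not (0.0 < p < 1.0):
            raise ValueError(f"spot position {p} outside (0, 1)")
    master = config.seed if seed is None else seed
    rng = (np.random.default_rng(np.random.SeedSequence([int(master), 3]))
           if config.noise_sd > 0 else None)

    if not lengths:
        shape = (64, 64)
        ph, fl, _ = _render_frame([], config, shape, 0, rng, static_spots={})
        stack = ImageStack(ph[None], fl[None], config.pixel_size,
                           config.frame_interval)
        return stack, pd.DataFrame(columns=TRUTH_COLUMNS)

    px = config.pixel_size
    margin = max(10, int(math.ceil(3 * config.psf_sigma_px)),
                 int(math.ceil(2 * config.cell_width_px)))
    slot_w = int(math.ceil(max(lengths) / px)) + 2 * margin
    slot_h = int(math.ceil(config.cell_width_px)) + 2 * margin
    n = len(lengths)
    ncols = int(math.ceil(math.sqrt(n)))
    nrows = int(math.ceil(n / ncols))
    shape = (nrows * slot_h, ncols * slot_w)

    geoms: list[_Geom] = []
    spots: dict[int, float] = {}
    for i, (length, p) in enumerate(zip(lengths, spot_positions_norm)):
        r, c = divmod(i, ncols)
        row = r * slot_h + slot_h / 2.0
        xc = c * slot_w + slot_w / 2.0
        lpx = length / px
        cell = CellTruth(
            cell_id=i, parent_id=None, generation=0, birth_time=0.0,
            birth_length=length, pole_rate_a=0.0, pole_rate_b=0.0,
            pole_a_is_fast=True, septum_position_norm=p,
            appearance_time=0.0, condensation_time=0.0, division_time=None,
            side_length_a0=p * length, side_length_b0=(1 - p) * length,
            birth_frame=0, appearance_frame=0, condensation_frame=0,
            division_frame=None, frame_interval=config.frame_interval,
        )
        geoms.append(_Geom(cell, row, xc - lpx / 2.0, xc + lpx / 2.0))
        spots[i] = p

    ph, fl, rows = _render_frame(geoms, config, shape, 0, rng,
                                 static_spots=spots)
    stack = ImageStack(ph[None], fl[None], config.pixel_size,
                       config.frame_interval)
    return stack, pd.DataFrame(rows, columns=TRUTH_COLUMNS)
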