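"""Ground-truth simulation of bipolar-growing rod cells.

Each cell carries two pole-specific exponential elongation rates from birth.
The cell is conceptually split at the (eventual) septum plane into side A
(toward pole A, the left/lexicographically-smaller pole) and side B; each
side elongates as ``side_x(t) = side_x0 * exp(rate_x * (t - t_sep))`` where
``t_sep`` is the condensation time at which the septum position is fixed.
Division is triggered by a timer started at condensation — not by a length
threshold, mirroring the observation that cell length is not a division cue
in mycobacteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import ConfigurationError, SimConfig

__all__ = ["CellTruth", "simulate_population", "movie_length"]


@dataclass
class CellTruth:
    """Ground-truth trajectory of one simulated cell.

    Times are absolute minutes; ``pole_rate_a`` belongs to pole A (the pole
    rendered on the left).  ``side_length_a0``/``side_length_b0`` are the
    septum-to-pole distances at condensation time, the anchor point of each
    side's exponential.  ``division_time``/``division_frame`` are ``None``
    for cells whose division falls outside the simulated movie.
    """

    cell_id: int
    parent_id: int | None
    generation: int
    birth_time: float
    birth_length: float
    pole_rate_a: float
    pole_rate_b: float
    pole_a_is_fast: bool
    septum_position_norm: float
    appearance_time: float
    condensation_time: float
    division_time: float | None
    side_length_a0: float
    side_length_b0: float
    birth_frame: int
    appearance_frame: int
    condensation_frame: int
    division_frame: int | None
    #: normalized patch position per frame, appearance..condensation-1
    patch_positions: dict[int, float] = field(default_factory=dict)
    frame_interval: float = 10.0

    # -- analytic lengths --------------------------------------------------
    def side_a(self, t: float) -> float:
        return self.side_length_a0 * math.exp(
            self.pole_rate_a * (t - self.condensation_time)
        )

    def side_b(self, t: float) -> float:
        return self.side_length_b0 * math.exp(
            self.pole_rate_b * (t - self.condensation_time)
        )

    def length_at(self, t: float) -> float:
        """Total length (µm) at absolute time ``t``, sum of both sides."""
        return self.side_a(t) + self.side_b(t)

    def spot_position_at(self, frame: int) -> float | None:
        """Normalized internal spot position at ``frame``; ``None`` before
        the patch appears."""
        if frame < self.appearance_frame:
            return None
        if frame < self.condensation_frame:
            return self.patch_positions[frame]
        return self.septum_position_norm

    def frames(self, n_frames: int) -> range:
        """Frames on which this cell is rendered in an ``n_frames`` movie."""
        end = n_frames if self.division_frame is None else min(
            n_frames, self.division_frame
        )
        return range(self.birth_frame, end)

    def length_series(self, n_frames: int) -> np.ndarray:
        """Per-frame total length (µm) over the cell's rendered frames."""
        return np.array(
            [self.length_at(f * self.frame_interval) for f in self.frames(n_frames)]
        )


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  low: float = 0.0) -> float:
    """Normal draw redrawn (not clamped) until strictly above ``low``;
    a degenerate (sd = 0) distribution returns its mean when feasible."""
    if sd == 0.0:
        if mean < low:
            raise ConfigurationError(
                f"degenerate draw: mean {mean} below lower bound {low}"
            )
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > low:
            return x
    raise ConfigurationError("truncated normal: too many redraws")


def _reflect(x: float, lo: float, hi: float) -> float:
    width = hi - lo
    y = (x - lo) % (2.0 * width)
    return lo + (width - abs(y - width))


def _wander_path(rng: np.random.Generator, cfg: SimConfig,
                 start_frame: int, end_frame: int) -> dict[int, float]:
    """Reflected Gaussian random walk on normalized position; one value per
    frame in [start_frame, end_frame)."""
    path: dict[int, float] = {}
    if end_frame <= start_frame:
        return path
    x = rng.uniform(cfg.wander_lo, cfg.wander_hi)
    path[start_frame] = x
    for f in range(start_frame + 1, end_frame):
        x = _reflect(x + rng.normal(0.0, cfg.wander_step_sd),
                     cfg.wander_lo, cfg.wander_hi)
        path[f] = x
    return path


def _draw_placement(rng: np.random.Generator, cfg: SimConfig) -> float:
    """Septum position: mid-cell plus Gaussian offset, clamped into (0, 1)."""
    p = 0.5 + rng.normal(0.0, cfg.placement_offset_sd)
    return min(max(p, 0.02), 0.98)


def _founder_rates(rng: np.random.Generator, cfg: SimConfig,
                   p: float) -> tuple[float, float, bool]:
    """Draw one fast and one slow rate and assign them to sides.

    The fast rate lands on the side that is shorter at placement with
    probability ``fast_on_short_prob`` (side A is shorter iff p < 0.5; an
    exact tie is resolved by a fair coin).  Returns (rate_a, rate_b,
    pole_a_is_fast).
    """
    fast = _trunc_normal(rng, cfg.fast_rate_mean, cfg.fast_rate_sd)
    slow = _trunc_normal(rng, cfg.slow_rate_mean, cfg.slow_rate_sd)
    a_shorter = bool(rng.integers(0, 2)) if p == 0.5 else p < 0.5
    fast_on_short = rng.random() < cfg.fast_on_short_prob
    if a_shorter == fast_on_short:
        return fast, slow, True
    return slow, fast, False


def _make_cell(
    rng: np.random.Generator,
    cfg: SimConfig,
    cell_id: int,
    parent: CellTruth | None,
    birth_time: float,
    birth_length: float,
    p: float,
    rate_a: float,
    rate_b: float,
    pole_a_is_fast: bool,
    generation: int,
) -> CellTruth:
    dt = cfg.frame_interval
    birth_frame = int(math.ceil(birth_time / dt - 1e-9))

    appearance_delay = max(0.0, rng.normal(cfg.appearance_delay_mean,
                                           cfg.appearance_delay_sd))
    appearance_frame = max(birth_frame + 1,
                           int(round((birth_time + appearance_delay) / dt)))
    k = max(1, int(round(rng.normal(cfg.condensation_frames_mean,
                                    cfg.condensation_frames_sd))))
    condensation_frame = appearance_frame + k
    condensation_time = condensation_frame * dt
    division_time = condensation_time + cfg.invagination_delay
    division_frame = int(math.ceil(division_time / dt - 1e-9))

    # Anchor side lengths at t_sep so the total at birth equals the drawn
    # birth length: L_sep = L0 / (p e^{-ra d} + (1-p) e^{-rb d}).
    d = condensation_time - birth_time
    denom = p * math.exp(-rate_a * d) + (1.0 - p) * math.exp(-rate_b * d)
    length_sep = birth_length / denom

    return CellTruth(
        cell_id=cell_id,
        parent_id=None if parent is None else parent.cell_id,
        generation=generation,
        birth_time=birth_time,
        birth_length=birth_length,
        pole_rate_a=rate_a,
        pole_rate_b=rate_b,
        pole_a_is_fast=pole_a_is_fast,
        septum_position_norm=p,
        appearance_time=appearance_frame * dt,
        condensation_time=condensation_time,
        division_time=division_time,
        side_length_a0=p * length_sep,
        side_length_b0=(1.0 - p) * length_sep,
        birth_frame=birth_frame,
        appearance_frame=appearance_frame,
        condensation_frame=condensation_frame,
        division_frame=division_frame,
        patch_positions=_wander_path(rng, cfg, appearance_frame,
                                     condensation_frame),
        frame_interval=dt,
    )


def simulate_population(config: SimConfig,
                        seed: int | None = None) -> list[CellTruth]:
    """Simulate a population of bipolar-growing rod cells.

    Founders are born at t=0 with lengths from the configured birth
    distribution; an internal patch appears after a random delay, wanders,
    condenses at the drawn septum position, and the cell divides
    ``invagination_delay`` minutes later.  Daughter birth lengths equal the
    parental side lengths at division exactly (conservation).  Daughters are
    recursed while their birth falls inside the movie.

    Parameters
    ----------
    config:
        Validated :class:`~poletrack.config.SimConfig`.
    seed:
        Overrides ``config.seed`` when given; identical config + seed gives
        identical output.

    Returns
    -------
    list of :class:`CellTruth`, founders first, then daughters in birth
    order.
    """
    config.validate()
    master = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([int(master), 1]))

    founders: list[CellTruth] = []
    next_id = 0
    for _ in range(config.n_cells):
        length0 = _trunc_normal(rng, config.birth_length_mean,
                                config.birth_length_sd, low=config.min_length)
        p = _draw_placement(rng, config)
        rate_a, rate_b, a_fast = _founder_rates(rng, config, p)
        founders.append(_make_cell(rng, config, next_id, None, 0.0, length0,
                                   p, rate_a, rate_b, a_fast, generation=0))
        next_id += 1

    if config.n_frames is None:
        n_frames = max(c.division_frame for c in founders) + 3
    else:
        n_frames = config.n_frames

    cells = list(founders)
    queue = list(founders)
    while queue:
        parent = queue.pop(0)
        if parent.division_frame is None or parent.division_frame >= n_frames:
            parent.division_time = None
            parent.division_frame = None
            continue
        t_div = parent.division_time
        for side in ("a", "b"):
            if side == "a":
                # daughter A inherits parent pole A on its left (old pole);
                # its right pole is new (at the septum).
                length0 = parent.side_a(t_div)
                old_rate = parent.pole_rate_a
                old_is_fast = parent.pole_a_is_fast
            else:
                # daughter B: new pole left (at the septum), old pole right.
                length0 = parent.side_b(t_div)
                old_rate = parent.pole_rate_b
                old_is_fast = not parent.pole_a_is_fast

            p = _draw_placement(rng, config)
            if config.inherit_old_pole_rate:
                new_class = ((config.slow_rate_mean, config.slow_rate_sd)
                             if old_is_fast
                             else (config.fast_rate_mean, config.fast_rate_sd))
                new_rate = _trunc_normal(rng, *new_class)
                if side == "a":
                    rate_a, rate_b, a_fast = old_rate, new_rate, old_is_fast
                else:
                    rate_a, rate_b, a_fast = new_rate, old_rate, not old_is_fast
            else:
                rate_a, rate_b, a_fast = _founder_rates(rng, config, p)

            cell = _make_cell(rng, config, next_id, parent, t_div, length0,
                              p, rate_a, rate_b, a_fast,
                              generation=parent.generation + 1)
            next_id += 1
            cells.append(cell)
            queue.append(cell)

    for c in cells:
        if c.division_frame is not None and c.division_frame >= n_frames:
            c.division_time = None
            c.division_frame = None
    return cells


def movie_length(truths: list[CellTruth], config: SimConfig) -> int:
    """Number of frames implied by ``config`` (auto mode: last founder
    division plus a short tail)."""
    if config.n_frames is not None:
        return config.n_frames
    divs = [c.division_frame for c in truths
            if c.parent_id is None and c.division_frame is not None]
    return (max(divs) + 3) if divs else 12
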