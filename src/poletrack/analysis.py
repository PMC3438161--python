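"""Population statistics: septum placement, per-pole growth rates,
asymmetry, and length variability.

The headline quantities are (i) the normalized septum position
``p = s / L`` and the fraction of positions inside the central 20% band
``|p - 0.5| <= 0.1``; (ii) per-side exponential elongation rates between
septum placement and division, ``r = ln(L_div / L_sep) / (t_div - t_sep)``
for each septum-to-pole side; (iii) the fast:slow ratio and whether the
faster side was the shorter one at placement; and (iv) an unpaired
rank-sum comparison of length variability between populations, run on
absolute deviations from each sample's median.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sp_stats
from scipy.stats import rankdata

log = logging.getLogger(__name__)

__all__ = [
    "PoleGrowthRecord", "PlacementStats",
    "relative_position", "central_fraction", "pole_growth_rates",
    "asymmetry_stats", "length_variability_test", "summarize_population",
    "pearson_definitional",
]


@dataclass
class PoleGrowthRecord:
    """Per-cell estimates of the two pole elongation rates (min^-1).

    Side A/B are the septum-to-pole segments at placement time ``t_sep``;
    at division the corresponding daughter lengths are used.  ``ratio`` is
    undefined (None) when the slow-side estimate is non-positive.
    """

    track_id: int
    t_sep: float
    t_div: float
    side_a_at_sep: float
    side_b_at_sep: float
    side_a_at_div: float
    side_b_at_div: float
    r_a: float = field(init=False)
    r_b: float = field(init=False)

    def __post_init__(self) -> None:
        if self.t_div <= self.t_sep:
            raise ValueError("t_div must exceed t_sep")
        for v in (self.side_a_at_sep, self.side_b_at_sep,
                  self.side_a_at_div, self.side_b_at_div):
            if v <= 0:
                raise ValueError("side lengths must be positive")
        dt = self.t_div - self.t_sep
        self.r_a = math.log(self.side_a_at_div / self.side_a_at_sep) / dt
        self.r_b = math.log(self.side_b_at_div / self.side_b_at_sep) / dt

    @property
    def r_fast(self) -> float:
        return max(self.r_a, self.r_b)

    @property
    def r_slow(self) -> float:
        return min(self.r_a, self.r_b)

    @property
    def ratio(self) -> float | None:
        """fast:slow rate ratio; undefined for a non-growing slow side."""
        if self.r_slow <= 0:
            return None
        return self.r_fast / self.r_slow

    @property
    def faster_on_shorter(self) -> bool:
        """True when the faster side was the shorter one at placement
        (a tie in rates counts as False)."""
        if self.r_a == self.r_b:
            return False
        shorter_is_a = self.side_a_at_sep < self.side_b_at_sep
        faster_is_a = self.r_a > self.r_b
        return shorter_is_a == faster_is_a

    @property
    def asymmetry_at_sep(self) -> float:
        """Signed relative side-length difference at placement."""
        return ((self.side_a_at_sep - self.side_b_at_sep)
                / (self.side_a_at_sep + self.side_b_at_sep))


@dataclass
class PlacementStats:
    """Summary of septum positions and cell lengths for one population."""

    positions: list[float]
    central_frac: float | None
    lengths: list[float]
    mean_length: float
    sd_length: float
    n_three_spot: int | None = None
    note: str = ""


def relative_position(s: float, length: float) -> tuple[float, float]:
    """Normalized position ``p = s / L`` and folded position
    ``q = min(p, 1 - p)``.

    Raises for non-positive length or ``s`` outside [0, L].
    """
    if length <= 0:
        raise ValueError("cell length must be positive")
    if not (0.0 <= s <= length):
        raise ValueError("arclength s must lie in [0, L]")
    p = s / length
    return p, min(p, 1.0 - p)


def central_fraction(positions: Sequence[float],
                     band_width: float = 0.2) -> float:
    """Fraction of normalized positions within the central band.

    A position counts when ``|p - 0.5| <= band_width / 2`` (boundary
    inclusive); the default band covers the central 20% of cell length.
    An empty input is an error, never a silent zero.
    """
    if len(positions) == 0:
        raise ValueError("central_fraction of an empty position list")
    if not (0.0 < band_width <= 1.0):
        raise ValueError("band_width must be in (0, 1]")
    p = np.asarray(positions, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("positions must lie in [0, 1]")
    half = band_width / 2.0
    return float(np.count_nonzero(np.abs(p - 0.5) <= half + 1e-12) / len(p))


def pole_growth_rates(track_id: int, t_sep: float, t_div: float,
                      side_a_at_sep: float, side_b_at_sep: float,
                      side_a_at_div: float, side_b_at_div: float,
                      ) -> PoleGrowthRecord:
    """Per-side exponential rates between septum placement and division.

    ``r_side = ln(side_at_div / side_at_sep) / (t_div - t_sep)`` — the
    two-time-point estimator used with cell lengths measured at initial
    septum placement and at division, assuming exponential growth.  A
    non-growing side yields r <= 0; the record is kept (and its ratio
    reported as undefined) rather than discarded.
    """
    rec = PoleGrowthRecord(track_id, t_sep, t_div,
                           side_a_at_sep, side_b_at_sep,
                           side_a_at_div, side_b_at_div)
    if rec.r_slow <= 0:
        log.info("track %d: non-growing side (r_slow=%.3g); excluded from "
                 "ratio statistics", track_id, rec.r_slow)
    return rec


def pearson_definitional(x: Sequence[float], y: Sequence[float]
                         ) -> tuple[float, float]:
    """Pearson correlation from its definitional sums, with the two-sided
    p-value from the t transform.

    Returns (nan, nan) when either variable has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    dx = x - x.sum() / n
    dy = y - y.sum() / n
    sxx = float((dx * dx).sum())
    syy = float((dy * dy).sum())
    if sxx == 0.0 or syy == 0.0:
        return float("nan"), float("nan")
    r = float((dx * dy).sum() / math.sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(sp_stats.t.sf(abs(t), df=n - 2))
    return r, p


def asymmetry_stats(records: Sequence[PoleGrowthRecord]) -> dict:
    """Asymmetry summary over per-cell growth records.

    Reports the fraction of cells growing faster on the side that was
    shorter at placement, the mean of per-cell fast:slow ratios and the
    ratio of mean rates (both readings of a population ratio), and the
    Pearson correlation (with p-value) between the signed relative
    side-length difference at placement and the rate difference
    ``r_a - r_b``.
    """
    records = list(records)
    n = len(records)
    if n == 0:
        raise ValueError("no growth records")
    frac_fos = sum(r.faster_on_shorter for r in records) / n
    ratios = [r.ratio for r in records if r.ratio is not None]
    r_fast = np.array([r.r_fast for r in records])
    r_slow = np.array([r.r_slow for r in records])
    out = {
        "n_records": n,
        "n_ratio_valid": len(ratios),
        "fraction_faster_on_shorter": frac_fos,
        "mean_r_fast": float(r_fast.mean()),
        "mean_r_slow": float(r_slow.mean()),
        "mean_ratio": float(np.mean(ratios)) if ratios else float("nan"),
        "ratio_of_means": (float(r_fast.mean() / r_slow.mean())
                           if r_slow.mean() > 0 else float("nan")),
    }
    if n >= 3:
        x = [r.asymmetry_at_sep for r in records]
        y = [r.r_a - r.r_b for r in records]
        r_p, p_p = pearson_definitional(x, y)
        out["pearson_r"] = r_p
        out["pearson_p"] = p_p
    else:
        out["pearson_r"] = float("nan")
        out["pearson_p"] = float("nan")
    return out


def _rank_sum_exact_p(dev_a: np.ndarray, dev_b: np.ndarray) -> float:
    """Two-sided exact p for the rank-sum of sample A by enumerating all
    labelings of the pooled values (midranks for ties)."""
    pooled = np.concatenate([dev_a, dev_b])
    ranks = rankdata(pooled)
    n_a = len(dev_a)
    w_obs = float(ranks[:n_a].sum())
    ws = np.array([ranks[list(c)].sum()
                   for c in itertools.combinations(range(len(pooled)), n_a)])
    lo = float(np.mean(ws <= w_obs + 1e-9))
    hi = float(np.mean(ws >= w_obs - 1e-9))
    return min(1.0, 2.0 * min(lo, hi))


def _rank_sum_normal_p(dev_a: np.ndarray, dev_b: np.ndarray) -> float:
    """Normal approximation with tie correction and continuity correction."""
    pooled = np.concatenate([dev_a, dev_b])
    n_a, n_b = len(dev_a), len(dev_b)
    n = n_a + n_b
    ranks = rankdata(pooled)
    w = float(ranks[:n_a].sum())
    mu = n_a * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return min(1.0, 2.0 * float(sp_stats.norm.sf(z)))


def length_variability_test(lengths_a: Sequence[float],
                            lengths_b: Sequence[float],
                            exact_max_n: int = 12) -> tuple[float, float]:
    """Rank-based two-sample test of length variability.

    Each sample is reduced to absolute deviations from its own median, and
    the deviations are compared with an unpaired rank-sum test: a shift in
    deviation magnitudes indicates different spread.  The null distribution
    is enumerated exactly when the combined sample size is at most
    ``exact_max_n``; otherwise a normal approximation with tie correction
    is used.

    Returns
    -------
    (W, p): the rank-sum of sample A's deviations and the two-sided
    p-value.  Identical pooled deviations give p = 1.
    """
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per sample")
    dev_a = np.abs(a - np.median(a))
    dev_b = np.abs(b - np.median(b))
    pooled = np.concatenate([dev_a, dev_b])
    ranks = rankdata(pooled)
    w = float(ranks[:len(a)].sum())
    if np.ptp(pooled) == 0:
        return w, 1.0
    if len(pooled) <= exact_max_n:
        return w, _rank_sum_exact_p(dev_a, dev_b)
    return w, _rank_sum_normal_p(dev_a, dev_b)


def summarize_population(lengths: Sequence[float],
                         foci_by_cell: dict[int, list] | None = None,
                         lengths_by_cell: dict[int, float] | None = None,
                         band_width: float = 0.2) -> PlacementStats:
    """Placement and length summary for one population.

    When ``foci_by_cell`` (cell id -> list of :class:`~poletrack.foci.Focus`)
    is given, the statistics are restricted to three-spot cells — exactly
    two polar foci plus one internal focus — and the internal-focus
    positions feed the central-band fraction; ``lengths_by_cell`` then maps
    the same cell ids to their measured lengths.  Without foci the summary
    covers lengths only.
    """
    if foci_by_cell is not None:
        if lengths_by_cell is None:
            raise ValueError("lengths_by_cell required with foci_by_cell")
        sel_lengths: list[float] = []
        positions: list[float] = []
        for cid, foci in foci_by_cell.items():
            polar = [f for f in foci if f.focus_class == "polar"]
            internal = [f for f in foci if f.focus_class == "internal"]
            if len(polar) == 2 and len(internal) == 1:
                sel_lengths.append(lengths_by_cell[cid])
                positions.append(internal[0].p_norm)
        note = ""
        if not positions:
            note = "no three-spot cells; placement stats unavailable"
            sel_lengths = list(lengths)
        lengths_arr = np.asarray(sel_lengths, dtype=float)
        central = central_fraction(positions, band_width) if positions else None
    else:
        positions = []
        central = None
        note = "lengths only (no foci supplied)"
        lengths_arr = np.asarray(lengths, dtype=float)
    if lengths_arr.size == 0:
        raise ValueError("no cells to summarise")
    mean = float(lengths_arr.mean())
    sd = float(lengths_arr.std(ddof=1)) if lengths_arr.size > 1 else 0.0
    return PlacementStats(
        positions=positions,
        central_frac=central,
        lengths=lengths_arr.tolist(),
        mean_length=mean,
        sd_length=sd,
        n_three_spot=len(positions) if foci_by_cell is not None else None,
        note=note,
    )
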