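"""Summary statistics of evolved Oli populations.

Extinction tables (per-transfer founder survival and cumulative extinction),
qPCR relative-slope fitness, fold-fraction estimation from quantification
curves, and genome-length distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .readprep import UniqueSeqTable

__all__ = [
    "GrowthCurve",
    "extinction_table",
    "check_extinction_consistency",
    "relative_slope",
    "estimate_initial_extended",
    "fold_fraction",
    "length_stats",
    "SlopeQualityError",
]


class SlopeQualityError(ValueError):
    """No acceptable log-linear window found in a growth curve."""


@dataclass
class GrowthCurve:
    """Total signal (copy number or fluorescence proxy) after each cycle.

    ``totals[0]`` is the pre-amplification input; entry c is the total after
    cycle c.
    """

    totals: np.ndarray

    def __post_init__(self) -> None:
        self.totals = np.asarray(self.totals, dtype=float)
        if np.any(self.totals < 0):
            raise ValueError("growth curve totals must be non-negative")

    @property
    def cycles(self) -> np.ndarray:
        return np.arange(len(self.totals))

    @property
    def plateau(self) -> float:
        return float(self.totals.max())


def _truncate3(x: float) -> float:
    """Truncate (not round) to 3 decimals, as the extinction table reports."""
    return math.floor(x * 1000) / 1000


def extinction_table(
    ancestor_counts: Sequence[int] | Sequence[set],
    transfers: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-transfer extinction summary of founder lineages.

    Input is either the number of transfer-1 unique sequences still present
    at each sampled transfer, or per-transfer sets of surviving founders
    (e.g. from a genealogy network), in transfer order.  Columns:
    transfer, n_ancestors, n_extinctions (vs the previous sampled transfer),
    cumulative_extinctions, and scaled_cumulative (cumulative divided by the
    transfer-1 count, truncated to three decimals).
    """
    series = [len(x) if isinstance(x, (set, frozenset)) else int(x) for x in ancestor_counts]
    if len(series) < 2:
        raise ValueError("need at least 2 transfers")
    if series[0] < 1:
        raise ValueError("transfer-1 ancestor count must be positive")
    if any(b > a for a, b in zip(series, series[1:])):
        raise ValueError("ancestor counts must be non-increasing over transfers")
    if transfers is None:
        transfers = [1, 3, 7, 11][: len(series)] if len(series) <= 4 else list(
            range(1, len(series) + 1)
        )
    if len(transfers) != len(series):
        raise ValueError("transfers and counts must align")
    extinctions = [0] + [a - b for a, b in zip(series, series[1:])]
    cumulative = np.cumsum(extinctions)
    scaled = [_truncate3(c / series[0]) for c in cumulative]
    return pd.DataFrame(
        {
            "transfer": list(transfers),
            "n_ancestors": series,
            "n_extinctions": extinctions,
            "cumulative_extinctions": cumulative,
            "scaled_cumulative": scaled,
        }
    )


def check_extinction_consistency(
    n_ancestors: Sequence[int], n_extinctions: Sequence[int]
) -> list[int]:
    """Indices where a reported interval extinction count contradicts the
    ancestor-count differences (reported != count[i-1] - count[i])."""
    bad = []
    for i in range(1, len(n_ancestors)):
        if n_extinctions[i] != n_ancestors[i - 1] - n_ancestors[i]:
            bad.append(i)
    return bad


def _best_log_linear_window(
    totals: np.ndarray, min_window: int
) -> tuple[int, int, float, float]:
    """(start, stop, slope, r2) of the best log-linear window.

    Candidate windows are every contiguous run of >= ``min_window`` cycles
    that overlaps the 10-90% band of the plateau (a pure doubling curve
    spends fewer than ``min_window`` cycles strictly inside the band, so
    windows may extend into the adjacent exponential rise).  The window with
    the highest R^2 of the log-signal linear fit wins; ties prefer longer,
    then earlier, windows.
    """
    totals = np.asarray(totals, dtype=float)
    if np.any(totals <= 0):
        first_pos = int(np.argmax(totals > 0))
        totals = totals[first_pos:]
        offset = first_pos
    else:
        offset = 0
    n = len(totals)
    if n < min_window + 1:
        raise SlopeQualityError("curve shorter than the minimum window")
    plateau = totals.max()
    in_band = (totals >= 0.1 * plateau) & (totals <= 0.9 * plateau)
    if not in_band.any():
        raise SlopeQualityError("no cycles between 10% and 90% of plateau")
    band_lo = int(np.argmax(in_band))
    band_hi = n - 1 - int(np.argmax(in_band[::-1]))
    log_s = np.log(totals)
    best = None
    for start in range(0, n - min_window):
        for stop in range(start + min_window, n):
            if stop < band_lo or start > band_hi:
                continue  # window must overlap the band
            x = np.arange(start, stop + 1)
            y = log_s[start: stop + 1]
            slope, intercept = np.polyfit(x, y, 1)
            fitted = slope * x + intercept
            ss_res = float(np.sum((y - fitted) ** 2))
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
            key = (r2, stop - start, -start)
            if best is None or key > best[0]:
                best = (key, start + offset, stop + offset, float(slope), r2)
    _, start, stop, slope, r2 = best
    return start, stop, slope, r2


def relative_slope(
    curve: GrowthCurve,
    standards: Iterable[GrowthCurve],
    min_window: int = 5,
    min_r2: float = 0.99,
) -> float:
    """Log-linear growth slope standardised to the pre-extended standards.

    The slope of log-signal per cycle over the best-fitting window (see
    ``_best_log_linear_window``) divided by the mean slope of the standards.
    A population identical to a standard scores exactly 1; a purely linear
    (never self-primed) population scores far below 1.  Raises
    SlopeQualityError when no window reaches ``min_r2``.
    """
    standards = list(standards)
    if not standards:
        raise ValueError("need at least one standard curve")
    *_, s_slope, s_r2 = zip(
        *[_best_log_linear_window(s.totals, min_window) for s in standards]
    )
    if max(s_r2) < min_r2:
        raise SlopeQualityError("no standard has an acceptable log-linear window")
    _, _, slope, r2 = _best_log_linear_window(curve.totals, min_window)
    if r2 < min_r2:
        raise SlopeQualityError(f"best window R^2 = {r2:.4f} < {min_r2}")
    return slope / float(np.mean(s_slope))


def estimate_initial_extended(
    curve: GrowthCurve,
    standard_curves: dict[int, GrowthCurve],
    threshold_fraction: float = 0.5,
) -> float:
    """qPCR-style quantification of the self-primed starting copies.

    Standards are growth curves of known pre-extended starting copy numbers.
    The threshold-crossing cycle (interpolated, threshold at a fixed fraction
    of the smallest standard plateau) is regressed on log10(known copies);
    the sample's crossing cycle is inverted through that standard line.  The
    threshold sits high (default 50% of plateau) so the linear growth of
    unextended molecules contributes little at crossing.
    """
    if len(standard_curves) < 2:
        raise ValueError("need >= 2 standards for a standard line")
    threshold = threshold_fraction * min(s.plateau for s in standard_curves.values())

    def crossing(totals: np.ndarray) -> float:
        above = np.flatnonzero(totals >= threshold)
        if len(above) == 0:
            raise SlopeQualityError("curve never reaches the threshold")
        i = int(above[0])
        if i == 0:
            return 0.0
        lo, hi = totals[i - 1], totals[i]
        return i - 1 + (threshold - lo) / (hi - lo)

    known = sorted(standard_curves)
    cts = [crossing(standard_curves[k].totals) for k in known]
    slope, intercept = np.polyfit(cts, np.log10(known), 1)
    ct = crossing(curve.totals)
    return float(10 ** (slope * ct + intercept))


def fold_fraction(qpcr_estimate: float, total_molecules: float) -> float:
    """Proportion of the population able to fold and self-prime.

    The ratio of qPCR-detected (self-primed) molecules to the fluorometric
    total, clamped at 1 (measurement noise can push the ratio above 1).
    """
    if qpcr_estimate < 0 or total_molecules <= 0:
        raise ValueError("molecule counts must be positive")
    return min(qpcr_estimate / total_molecules, 1.0)


def length_stats(
    table: UniqueSeqTable, threshold_bp: int = 75
) -> tuple[pd.Series, float]:
    """Abundance-weighted genome-length histogram and long-molecule fraction.

    Returns (histogram indexed by length, proportion of reads strictly longer
    than ``threshold_bp``).
    """
    if threshold_bp < 1:
        raise ValueError("threshold must be >= 1")
    if len(table) == 0:
        raise ValueError("empty table")
    counts: dict[int, int] = {}
    over = 0
    total = 0
    for seq, count in table:
        n = len(seq)
        counts[n] = counts.get(n, 0) + count
        total += count
        if n > threshold_bp:
            over += count
    hist = pd.Series(counts, name="reads").sort_index()
    hist.index.name = "length"
    return hist, over / total
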