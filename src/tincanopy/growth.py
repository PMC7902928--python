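"""Temporal growth-pattern classification from two-date canopy metrics.

Comparing a plot's canopy metrics between consecutive flights reveals how
the canopy developed: growing outward (more ground cover at constant
height), growing upward (taller with either pyramid-like or even height
gain), lodging (the canopy bulk collapses to lower heights while the
footprint is maintained or spreads) or senescing (volume, cover and
height all decline).  Classification is rule-based over relative metric
changes and area-weighted height-decile shifts, with explicit, overridable
thresholds; a season of flights is summarized into per-interval labels and
a maturity class (early varieties senesce well before the season ends;
late ones keep growing to the final flight).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import CanopyMetrics

log = logging.getLogger(__name__)

EPS = 1e-6

GROWTH_LABELS = ("sideways_growth", "vertical_pyramid_growth", "vertical_even_growth",
                 "vertical_even_growth_raised_base")
ALL_LABELS = GROWTH_LABELS + ("lodging", "senescence", "mixed", "no_change")


@dataclass
class GrowthDelta:
    """Relative metric changes between two flights of one plot.

    Relative deltas are (v2 − v1) / max(v1, ε); ``quantile_shifts`` holds
    the change of the area-weighted height deciles q10…q90 in meters, and
    ``base_height`` the date-1 median height used to normalize shift
    magnitudes (keeps classification scale-invariant).
    """

    plot_id: str
    date_1: str | float
    date_2: str | float
    d_volume: float
    d_cover: float
    d_mean_h: float
    d_max_h: float
    quantile_shifts: np.ndarray  # deciles q10..q90, meters
    base_height: float = 0.0

    def __post_init__(self) -> None:
        self.quantile_shifts = np.asarray(self.quantile_shifts, dtype=float)
        if self.quantile_shifts.shape != (9,):
            raise ValueError("quantile_shifts must hold the 9 deciles q10..q90")


@dataclass
class PatternThresholds:
    """Decision thresholds for the growth-pattern rules.

    tau: minimum relative change treated as a real increase/decrease.
    tau_small: dead band below which a change counts as "no change".
    tau_h: maximum |relative max-height change| compatible with purely
        sideways growth.
    rho: decile-shift ratio separating pyramid-like from even growth.
    tau_base: q10 shift, as a fraction of the date-1 median height, above
        which even growth is flagged as having a raised base.
    """

    tau: float = 0.10
    tau_small: float = 0.03
    tau_h: float = 0.05
    rho: float = 2.0
    tau_base: float = 0.5

    def __post_init__(self) -> None:
        for name in ("tau", "tau_small", "tau_h", "rho", "tau_base"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class PatternLabel:
    label: str
    evidence: dict[str, bool] = dc_field(default_factory=dict)


@dataclass
class SeasonProfile:
    plot_id: str
    intervals: list[tuple[tuple[str | float, str | float], PatternLabel]]
    maturity_class: str  # early | intermediate | late | undetermined
    lodging_observed: bool = False


def _rel(v1: float, v2: float) -> float:
    return (v2 - v1) / max(v1, EPS)


def compute_growth_delta(m1: CanopyMetrics, m2: CanopyMetrics) -> GrowthDelta:
    """Relative metric deltas and height-decile shifts between two flights."""
    if m1.plot_id != m2.plot_id:
        raise ValueError(f"mismatched plots {m1.plot_id!r} vs {m2.plot_id!r}")
    if _date_key(m1.date) >= _date_key(m2.date):
        raise ValueError("m1 must precede m2")
    p = np.arange(1, 10) / 10.0
    q1 = m1.histogram.quantile(p) if m1.histogram is not None else np.zeros(9)
    q2 = m2.histogram.quantile(p) if m2.histogram is not None else np.zeros(9)
    base = float(m1.histogram.quantile(0.5)) if m1.histogram is not None else m1.mean_height
    return GrowthDelta(
        plot_id=m1.plot_id, date_1=m1.date, date_2=m2.date,
        d_volume=_rel(m1.volume_m3, m2.volume_m3),
        d_cover=_rel(m1.ground_cover_m2, m2.ground_cover_m2),
        d_mean_h=_rel(m1.mean_height, m2.mean_height),
        d_max_h=_rel(m1.max_height, m2.max_height),
        quantile_shifts=np.asarray(q2) - np.asarray(q1),
        base_height=base)


def classify_pattern(delta: GrowthDelta,
                     thresholds: PatternThresholds | None = None) -> PatternLabel:
    """Assign a canopy-development pattern to a two-date transition.

    Rules are evaluated in a fixed priority order (senescence, lodging,
    sideways, vertical pyramid, vertical even with raised base, vertical
    even, no change); a transition matching none is labelled ``mixed``
    with the rule evidence recorded.
    """
    t = thresholds or PatternThresholds()
    q = delta.quantile_shifts
    lower = float(q[:3].mean())  # q10-q30
    upper = float(q[6:].mean())  # q70-q90
    base_norm = max(delta.base_height, EPS)

    ev: dict[str, bool] = {}
    ev["volume_down"] = delta.d_volume < -t.tau
    ev["cover_down"] = delta.d_cover < -t.tau
    ev["mean_down"] = delta.d_mean_h < -t.tau
    ev["cover_maintained"] = delta.d_cover >= -t.tau_small
    ev["cover_up"] = delta.d_cover > t.tau
    ev["max_stable"] = abs(delta.d_max_h) < t.tau_h
    ev["max_up"] = delta.d_max_h > t.tau
    ev["mean_up"] = delta.d_mean_h > t.tau
    ev["top_heavy_shift"] = upper > t.rho * max(lower, EPS) and upper > 0
    pos = q[q > t.tau_small * base_norm]
    ev["shifts_uniform"] = len(pos) > 0 and pos.max() <= t.rho * pos.min()
    ev["base_raised"] = q[0] > t.tau_base * base_norm
    ev["all_small"] = bool(
        max(abs(delta.d_volume), abs(delta.d_cover),
            abs(delta.d_mean_h), abs(delta.d_max_h)) < t.tau_small)

    if ev["volume_down"] and ev["cover_down"] and ev["mean_down"]:
        return PatternLabel("senescence", ev)
    if ev["mean_down"] and ev["cover_maintained"]:
        return PatternLabel("lodging", ev)
    if ev["cover_up"] and ev["max_stable"]:
        return PatternLabel("sideways_growth", ev)
    if ev["max_up"] and ev["top_heavy_shift"]:
        return PatternLabel("vertical_pyramid_growth", ev)
    if ev["mean_up"] and ev["shifts_uniform"]:
        if ev["base_raised"]:
            return PatternLabel("vertical_even_growth_raised_base", ev)
        return PatternLabel("vertical_even_growth", ev)
    if ev["all_small"]:
        return PatternLabel("no_change", ev)
    return PatternLabel("mixed", ev)


def _date_key(date: str | float) -> float:
    """Sortable numeric key for a date given as a number (e.g. DAP) or ISO string."""
    if isinstance(date, (int, float, np.integer, np.floating)):
        return float(date)
    return pd.Timestamp(date).timestamp()


def season_profile(metrics: Sequence[CanopyMetrics],
                   thresholds: PatternThresholds | None = None,
                   early_season_fraction: float = 0.8) -> SeasonProfile:
    """Label each between-flight interval and infer a maturity class.

    ``early``: senescence first appears before ``early_season_fraction``
    of the season span has elapsed; ``late``: the final interval is still
    a growth pattern; ``intermediate`` otherwise; ``undetermined`` with
    fewer than 3 flights.  Lodging anywhere in the season is flagged.
    """
    if len(metrics) < 2:
        raise ValueError("need at least 2 flights")
    keys = [_date_key(m.date) for m in metrics]
    if any(k2 <= k1 for k1, k2 in zip(keys, keys[1:])):
        raise ValueError("flights must be sorted by strictly increasing date")
    intervals = []
    for m1, m2 in zip(metrics, metrics[1:]):
        label = classify_pattern(compute_growth_delta(m1, m2), thresholds)
        intervals.append(((m1.date, m2.date), label))

    lodging = any(lab.label == "lodging" for _, lab in intervals)
    if len(metrics) < 3:
        maturity = "undetermined"
    else:
        span = keys[-1] - keys[0]
        cutoff = keys[0] + early_season_fraction * span
        first_senescence = next(
            (_date_key(iv[1]) for (iv, lab) in intervals if lab.label == "senescence"),
            None)
        if first_senescence is not None and first_senescence < cutoff:
            maturity = "early"
        elif intervals[-1][1].label in GROWTH_LABELS:
            maturity = "late"
        else:
            maturity = "intermediate"
    return SeasonProfile(plot_id=metrics[0].plot_id, intervals=intervals,
                         maturity_class=maturity, lodging_observed=lodging)


def season_profile_table(profile: SeasonProfile) -> pd.DataFrame:
    """Season profile as a tidy table (one row per interval)."""
    rows = [{
        "plot_id": profile.plot_id,
        "date_1": d1, "date_2": d2,
        "label": lab.label,
        "maturity_class": profile.maturity_class,
        "lodging_observed": profile.lodging_observed,
    } for (d1, d2), lab in profile.intervals]
    return pd.DataFrame(rows)
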