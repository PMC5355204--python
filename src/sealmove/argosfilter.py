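"""Speed-distance-angle (SDA) filtering of Argos location tracks.

The filter removes implausible satellite fixes in three rules:

1. every fix with quality class Z is removed;
2. a fix whose implied swim speed from the previous retained fix exceeds
   ``max_speed_mps`` is removed, unless it lies within ``keep_radius_km`` of
   that fix (fast successive fixes close together are genuine);
3. a fix is removed when the turning angle at it exceeds 165° with an
   incoming leg > 2.5 km, or exceeds 155° with an incoming leg > 5 km
   (sharp long out-and-back spikes are Argos error, not swimming).

Removal iterates to a fixpoint: after each removal the scan resumes against
the updated neighbours, so secondary spikes uncovered by a removal are also
caught. The retained track is a subsequence of the input; coordinates are
never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .geodesy import great_circle_km, turning_angle_deg

LC_QUALITY_ORDER = {"3": 0, "2": 1, "1": 2, "0": 3, "A": 4, "B": 5, "Z": 6}

DEFAULT_ANGLE_RULES = ((2.5, 165.0), (5.0, 155.0))


@dataclass
class FilterReport:
    """Bookkeeping of what the SDA filter removed and why."""

    n_input: int = 0
    n_removed_z: int = 0
    n_removed_speed: int = 0
    n_removed_angle: int = 0
    n_removed_duplicate: int = 0
    removed_by_class: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return (self.n_removed_z + self.n_removed_speed
                + self.n_removed_angle + self.n_removed_duplicate)

    @property
    def removed_fraction(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_z": self.n_removed_z,
            "n_removed_speed": self.n_removed_speed,
            "n_removed_angle": self.n_removed_angle,
            "n_removed_duplicate": self.n_removed_duplicate,
            "n_removed": self.n_removed,
            "removed_fraction": self.removed_fraction,
            "removed_by_class": dict(self.removed_by_class),
        }


def _dedupe_timestamps(track: pd.DataFrame, report: FilterReport) -> pd.DataFrame:
    """Among exactly simultaneous fixes keep the highest-quality class."""
    if track["timestamp"].is_unique:
        return track
    order = track["lc"].map(LC_QUALITY_ORDER)
    keep = (track.assign(_q=order)
            .sort_values(["timestamp", "_q"], kind="stable")
            .drop_duplicates("timestamp", keep="first")
            .drop(columns="_q")
            .sort_index())
    n_dropped = len(track) - len(keep)
    report.n_removed_duplicate += n_dropped
    for lc in track.loc[~track.index.isin(keep.index), "lc"]:
        report.removed_by_class[lc] = report.removed_by_class.get(lc, 0) + 1
    return keep


def sda_filter(track: pd.DataFrame,
               max_speed_mps: float = 2.5,
               keep_radius_km: float = 5.0,
               angle_rules=DEFAULT_ANGLE_RULES):
    """Apply the SDA filter to one animal's time-sorted track.

    Parameters
    ----------
    track : DataFrame with columns timestamp, lon, lat, lc (one animal).
    max_speed_mps : swim-speed threshold (rule 2).
    keep_radius_km : fixes within this distance of the previous retained fix
        are exempt from the speed rule.
    angle_rules : iterable of (min_leg_km, max_angle_deg) pairs (rule 3).

    Returns
    -------
    (retained, report) : the retained subsequence (same columns, original
    order) and a :class:`FilterReport`.
    """
    report = FilterReport(n_input=len(track))
    if len(track) == 0:
        return track.copy(), report
    ts = pd.to_datetime(track["timestamp"])
    if not ts.is_monotonic_increasing:
        raise ValueError("track must be time-sorted within each animal")

    track = _dedupe_timestamps(track.assign(timestamp=ts), report)
    lc = track["lc"].astype(str).to_numpy()
    lon = track["lon"].to_numpy(float)
    lat = track["lat"].to_numpy(float)
    t = track["timestamp"].astype("int64").to_numpy() / 1e9  # epoch seconds

    def _mark_removed(i, reason):
        setattr(report, f"n_removed_{reason}",
                getattr(report, f"n_removed_{reason}") + 1)
        report.removed_by_class[lc[i]] = report.removed_by_class.get(lc[i], 0) + 1

    kept = []
    for i in range(len(track)):
        if lc[i] == "Z":
            _mark_removed(i, "z")
        else:
            kept.append(i)

    def _violates(pos: int) -> str | None:
        """Rule violated by the fix at position ``pos`` of the kept list."""
        i = kept[pos]
        if pos > 0:
            p = kept[pos - 1]
            leg_km = great_circle_km(lon[p], lat[p], lon[i], lat[i])
            dt = t[i] - t[p]
            if dt > 0 and leg_km * 1000.0 / dt > max_speed_mps \
                    and leg_km > keep_radius_km:
                return "speed"
            if pos < len(kept) - 1:
                n = kept[pos + 1]
                try:
                    ang = turning_angle_deg((lon[p], lat[p]), (lon[i], lat[i]),
                                            (lon[n], lat[n]))
                except ValueError:
                    ang = None  # coincident points: angle undefined, no removal
                if ang is not None:
                    for min_leg, max_ang in angle_rules:
                        if leg_km > min_leg and ang > max_ang:
                            return "angle"
        return None

    # Fixpoint scan: find the first violating fix, remove it, resume one
    # position back (only the predecessor's status can have changed).
    pos = 1
    while pos < len(kept):
        reason = _violates(pos)
        if reason is None:
            pos += 1
            continue
        _mark_removed(kept[pos], reason)
        del kept[pos]
        pos = max(1, pos - 1)

    return track.iloc[kept].copy(), report


def filter_tracks(locations: pd.DataFrame, **kwargs):
    """Apply :func:`sda_filter` per animal to a multi-animal location table.

    Returns (filtered DataFrame, dict animal_id -> FilterReport).
    """
    pieces, reports = [], {}
    for animal, sub in locations.groupby("animal_id", sort=False):
        kept, rep = sda_filter(sub, **kwargs)
        pieces.append(kept)
        reports[animal] = rep
    out = (pd.concat(pieces, ignore_index=False) if pieces
           else locations.iloc[0:0].copy())
    return out, reports


class SDAFilter(TransformerMixin, BaseEstimator):
    """Stateless sklearn-style transformer wrapping :func:`filter_tracks`.

    ``transform`` filters a multi-animal location table; per-animal
    :class:`FilterReport` objects are exposed as ``reports_`` afterwards.
    """

    def __init__(self, max_speed_mps: float = 2.5, keep_radius_km: float = 5.0,
                 angle_rules=DEFAULT_ANGLE_RULES):
        self.max_speed_mps = max_speed_mps
        self.keep_radius_km = keep_radius_km
        self.angle_rules = angle_rules

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out, reports = filter_tracks(
            X, max_speed_mps=self.max_speed_mps,
            keep_radius_km=self.keep_radius_km, angle_rules=self.angle_rules)
        self.reports_ = reports
        return out
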