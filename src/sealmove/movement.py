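"""Distance-from-haul-out metrics.

A seal's at-sea movement is summarized per at-sea bout: the great-circle
distance from the last haul-out fix (the bout's anchor) to every at-sea fix
of the subsequent at-sea period, and the single maximum of that series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .geodesy import great_circle_km


@dataclass
class AtSeaBout:
    """Maximal run of at-sea fixes anchored at the preceding haul-out fix."""

    animal_id: str
    bout_id: int
    anchor: pd.Series            # last haul-out fix before the bout
    fixes: pd.DataFrame          # ordered at-sea fixes


def segment_bouts(track: pd.DataFrame) -> list[AtSeaBout]:
    """Split one animal's time-sorted track into anchored at-sea bouts.

    A bout is a maximal run of fixes with ``hauled_out == 0`` delimited by
    haul-out fixes. A leading at-sea run with no preceding haul-out has no
    anchor and is dropped with a warning.
    """
    if not pd.to_datetime(track["timestamp"]).is_monotonic_increasing:
        raise ValueError("track must be time-sorted")
    animal = str(track["animal_id"].iloc[0]) if len(track) else ""
    hauled = track["hauled_out"].astype(int).to_numpy()
    if len(track) and (hauled == 1).sum() == 0:
        warnings.warn(f"{animal}: no haul-out fix in track; no bouts")
        return []

    bouts: list[AtSeaBout] = []
    anchor_pos = None
    run_start = None
    for i, h in enumerate(hauled):
        if h == 1:
            if run_start is not None:
                if anchor_pos is not None:
                    bouts.append(AtSeaBout(animal, len(bouts),
                                           track.iloc[anchor_pos],
                                           track.iloc[run_start:i]))
                run_start = None
            anchor_pos = i
        else:
            if run_start is None:
                run_start = i
                if anchor_pos is None:
                    warnings.warn(f"{animal}: leading at-sea run without a "
                                  "prior haul-out dropped")
    if run_start is not None and anchor_pos is not None:
        bouts.append(AtSeaBout(animal, len(bouts), track.iloc[anchor_pos],
                               track.iloc[run_start:]))
    return bouts


def haulout_distances(bout: AtSeaBout) -> pd.DataFrame:
    """Great-circle distance (km) from the anchor to each bout fix.

    Returns one row per fix (animal_id, bout_id, timestamp, dist_km,
    is_bout_max); ``is_bout_max`` marks the single fix at maximum distance.
    """
    if len(bout.fixes) == 0:
        raise ValueError("empty bout")
    d = great_circle_km(bout.anchor["lon"], bout.anchor["lat"],
                        bout.fixes["lon"].to_numpy(),
                        bout.fixes["lat"].to_numpy())
    out = pd.DataFrame({
        "animal_id": bout.animal_id,
        "bout_id": bout.bout_id,
        "timestamp": pd.to_datetime(bout.fixes["timestamp"]).to_numpy(),
        "dist_km": d,
    })
    out["is_bout_max"] = False
    out.loc[out["dist_km"].idxmax(), "is_bout_max"] = True
    return out


def track_distances(locations: pd.DataFrame) -> pd.DataFrame:
    """Per-fix haul-out distances for a multi-animal location table."""
    pieces = []
    for _, sub in locations.groupby("animal_id", sort=False):
        for bout in segment_bouts(sub):
            pieces.append(haulout_distances(bout))
    if not pieces:
        return pd.DataFrame(columns=["animal_id", "bout_id", "timestamp",
                                     "dist_km", "is_bout_max"])
    return pd.concat(pieces, ignore_index=True)
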