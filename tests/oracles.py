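"""Independent brute-force oracles used by the test suite.

Everything here is written from the rule definitions, not from the package
implementation: distances and angles with their own spherical formulas, the
SDA filter as a naive remove-first-and-rescan loop, and the dive-focus
statistic as exact pair enumeration.
"""

from __future__ import annotations

import itertools
import math

R_EARTH = 6371.0


def hav_km(lon1, lat1, lon2, lat2):
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * R_EARTH * math.asin(min(1.0, math.sqrt(a)))


def bearing(lon1, lat1, lon2, lat2):
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    y = math.sin(dl) * math.cos(p2)
    x = math.cos(p1) * math.sin(p2) - math.sin(p1) * math.cos(p2) * math.cos(dl)
    return math.atan2(y, x)


def turn_deg(a, b, c):
    """Deviation at b from straight continuation of a->b, degrees in [0,180]."""
    d = math.degrees(abs(bearing(*b, *c) - bearing(*a, *b))) % 360.0
    return min(d, 360.0 - d)


def brute_force_sda(fixes, max_speed_mps=2.5, keep_radius_km=5.0,
                    angle_rules=((2.5, 165.0), (5.0, 155.0))):
    """Reference SDA filter: drop class Z, then repeatedly rebuild the full
    violation list from scratch and remove the first violating fix.

    ``fixes`` is a list of dicts with keys t (epoch seconds), lon, lat, lc.
    Returns the retained indices into the input list.
    """
    kept = [i for i, f in enumerate(fixes) if f["lc"] != "Z"]

    def first_violation():
        for j in range(1, len(kept)):
            cur = fixes[kept[j]]
            prev = fixes[kept[j - 1]]
            leg = hav_km(prev["lon"], prev["lat"], cur["lon"], cur["lat"])
            dt = cur["t"] - prev["t"]
            if dt > 0 and leg * 1000.0 / dt > max_speed_mps and leg > keep_radius_km:
                return j
            if j < len(kept) - 1:
                nxt = fixes[kept[j + 1]]
                pa = (prev["lon"], prev["lat"])
                pb = (cur["lon"], cur["lat"])
                pc = (nxt["lon"], nxt["lat"])
                if pa != pb and pb != pc:
                    ang = turn_deg(pa, pb, pc)
                    for min_leg, max_ang in angle_rules:
                        if leg > min_leg and ang > max_ang:
                            return j
        return None

    while True:
        j = first_violation()
        if j is None:
            return kept
        del kept[j]


def pair_focus(counts):
    """Dive focus by exact pair enumeration: the fraction of unordered dive
    pairs sharing a bin."""
    dives = list(itertools.chain.from_iterable(
        [i] * int(c) for i, c in enumerate(counts)))
    pairs = list(itertools.combinations(range(len(dives)), 2))
    if not pairs:
        return float("nan")
    same = sum(1 for i, j in pairs if dives[i] == dives[j])
    return same / len(pairs)
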