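"""Geometric H-bond detection and named COM-distance stability metrics.

An H-bond is purely geometric: donor–acceptor distance strictly below a
cutoff (default 3.5 Å) and donor–hydrogen–acceptor angle strictly above a
minimum (default 120°).  Bifurcated geometries (one donor–acceptor pair
satisfied through more than one hydrogen) count once per (donor, acceptor)
pair.  Counts between two groups are direction-agnostic: A-donor to
B-acceptor plus B-donor to A-acceptor.

COM-distance metrics track named interactions (e.g. a salt bridge or a
hydrophobic cluster) as the distance between the centers of mass of two
atom groups; :func:`detect_contact_event` finds the first sustained
threshold crossing, the rule used for contact-formation events such as a
carboxylate moving into coordination range of a metal ion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_io import AtomicModel, Trajectory

__all__ = ["HBondCriteria", "DistanceMetricSpec", "find_hbonds",
           "hbond_count_series", "com_distance_series", "detect_contact_event"]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric H-bond thresholds (strict inequalities on both)."""

    max_da_distance: float = 3.5   # Å, donor–acceptor
    min_dha_angle: float = 120.0   # degrees, donor–hydrogen–acceptor

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.min_dha_angle <= 180:
            raise ValueError("angle cutoff must be in (0, 180]")


@dataclass
class DistanceMetricSpec:
    """A named COM-distance metric with an optional event rule."""

    name: str
    serials_a: tuple
    serials_b: tuple
    threshold: float | None = None   # Å
    direction: str = "below"         # below | above
    hold_time: float = 1.0           # ns the crossing must persist

    def __post_init__(self) -> None:
        if self.threshold is not None and self.threshold <= 0:
            raise ValueError("event threshold must be positive")
        if self.direction not in ("below", "above"):
            raise ValueError("direction must be 'below' or 'above'")


def _group_dha(model: AtomicModel, serials) -> tuple:
    """(donor_rows, hydrogen_rows, acceptor_rows) within one group."""
    rows = model.index_of(np.asarray(serials, dtype=np.int64))
    role = model.role[rows].astype(str)
    donors = rows[role == "donor"]
    hydros = rows[role == "hydrogen"]
    accept = rows[np.isin(role, ("acceptor", "donor"))]  # donors may accept
    for h in hydros:
        if int(model.donor_link[h]) < 0:
            raise ValueError(f"hydrogen serial {int(model.serial[h])} has no donor link")
    return donors, hydros, accept


def find_hbonds(model: AtomicModel, group_a, group_b,
                criteria: HBondCriteria = HBondCriteria(),
                coords: np.ndarray | None = None) -> list:
    """H-bonds between two atom groups in one frame.

    Returns a sorted list of ``(donor_serial, hydrogen_serial,
    acceptor_serial)`` triples, at most one per (donor, acceptor) pair
    (the hydrogen with the best — largest — D-H-A angle is kept), with
    donor and acceptor in different groups.  Symmetric in the group labels.
    """
    xyz = np.asarray(coords if coords is not None else model.xyz, dtype=float)
    da, ha, aa = _group_dha(model, group_a)
    db, hb, ab = _group_dha(model, group_b)
    bonds = {}
    for donors, hydros, acceptors in ((da, ha, ab), (db, hb, aa)):
        if len(donors) == 0 or len(acceptors) == 0:
            continue
        donor_of = {int(model.serial[d]): d for d in donors}
        for h in hydros:
            d = donor_of.get(int(model.donor_link[h]))
            if d is None:
                continue
            for a in acceptors:
                if a == d:
                    continue
                dist = float(np.linalg.norm(xyz[a] - xyz[d]))
                if dist >= criteria.max_da_distance:
                    continue
                v1 = xyz[d] - xyz[h]
                v2 = xyz[a] - xyz[h]
                cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if angle <= criteria.min_dha_angle:
                    continue
                key = (int(model.serial[d]), int(model.serial[a]))
                prev = bonds.get(key)
                if prev is None or angle > prev[1]:
                    bonds[key] = (int(model.serial[h]), angle)
    return sorted((d, h, a) for (d, a), (h, _) in bonds.items())


def hbond_count_series(traj: Trajectory, model: AtomicModel, group_a, group_b,
                       criteria: HBondCriteria = HBondCriteria(),
                       stride: int = 1) -> pd.DataFrame:
    """Per-frame H-bond counts between two groups: time_ns, count."""
    rows = [(float(traj.times[k]),
             len(find_hbonds(model, group_a, group_b, criteria,
                             coords=traj.coords[k])))
            for k in range(0, traj.n_frames, stride)]
    return pd.DataFrame(rows, columns=["time_ns", "count"])


def com_distance_series(traj: Trajectory, model: AtomicModel,
                        spec: DistanceMetricSpec) -> np.ndarray:
    """Per-frame |COM(A) − COM(B)| in Å; shape (n_frames, 2)."""
    if len(spec.serials_a) == 0 or len(spec.serials_b) == 0:
        raise ValueError(f"metric {spec.name!r} has an empty selection")
    ia = model.index_of(np.asarray(spec.serials_a, dtype=np.int64))
    ib = model.index_of(np.asarray(spec.serials_b, dtype=np.int64))
    d = np.linalg.norm(traj.coords[:, ia].mean(axis=1)
                       - traj.coords[:, ib].mean(axis=1), axis=1)
    return np.column_stack([traj.times, d])


def detect_contact_event(series: np.ndarray, spec: DistanceMetricSpec):
    """First sustained threshold crossing of a (time, value) series.

    Returns the time at which the series first crosses ``spec.threshold``
    in ``spec.direction`` and stays across it for at least
    ``spec.hold_time``, or ``None`` if no such crossing exists.  Appending
    frames after a detected event cannot change the result.
    """
    s = np.asarray(series, dtype=float)
    if len(s) == 0:
        raise ValueError("empty series")
    if spec.threshold is None:
        raise ValueError(f"metric {spec.name!r} has no event threshold")
    t, v = s[:, 0], s[:, 1]
    if spec.hold_time > t[-1] - t[0]:
        raise ValueError("hold time exceeds the series time span")
    across = v < spec.threshold if spec.direction == "below" else v > spec.threshold
    i = 0
    n = len(t)
    while i < n:
        if not across[i]:
            i += 1
            continue
        j = i
        while j < n and across[j]:
            j += 1
        sustained = (t[j - 1] - t[i] >= spec.hold_time) or (
            j == n and t[-1] - t[i] >= spec.hold_time)
        if sustained:
            return float(t[i])
        i = j
    return None
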