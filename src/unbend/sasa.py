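"""Shrake–Rupley solvent-accessible surface area and buried-interface area.

SASA is computed by deterministic quadrature: each atom's sphere is
expanded by the probe radius (default 1.4 Å, a water-sized probe) and
covered with a golden-spiral point set; the accessible area is the
fraction of points not inside any neighbouring expanded sphere times the
expanded-sphere area.  The deterministic point set makes every area
bit-stable across runs.

The buried SASA of part A with respect to part B — the interface metric
used throughout the unbending analysis — is SASA(A alone) minus
SASA(A in the presence of B); restricting the per-atom sum to one domain
gives that domain's share of the interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_io import AtomicModel, Trajectory

__all__ = ["SasaParams", "SasaResult", "sphere_points", "sasa",
           "buried_sasa", "buried_sasa_series"]


@dataclass(frozen=True)
class SasaParams:
    """Quadrature parameters: probe radius (Å) and points per atom."""

    probe_radius: float = 1.4
    n_points: int = 960

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe radius must be >= 0")
        if self.n_points < 12:
            raise ValueError("need at least 12 sphere points")


@dataclass
class SasaResult:
    """Per-atom accessible areas (Ų) with their serials, and the total."""

    serials: np.ndarray
    areas: np.ndarray
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = float(np.sum(self.areas))

    def subset_total(self, serials) -> float:
        """Summed area over a subset of the computed atoms."""
        want = np.isin(self.serials, np.asarray(serials))
        return float(np.sum(self.areas[want]))


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral point set on the unit sphere, shape (n, 3)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _sasa_areas(xyz: np.ndarray, radii: np.ndarray, subset_idx: np.ndarray,
                params: SasaParams) -> np.ndarray:
    """Accessible area of each subset atom in the context of all atoms."""
    pts = sphere_points(params.n_points)
    expanded = radii + params.probe_radius
    areas = np.empty(len(subset_idx))
    # spatial binning: cell size = largest possible interaction distance
    max_r = float(expanded.max())
    cell = 2.0 * max_r
    keys = np.floor(xyz / cell).astype(np.int64)
    bins: dict = {}
    for i, key in enumerate(map(tuple, keys)):
        bins.setdefault(key, []).append(i)

    for out_i, i in enumerate(subset_idx):
        ri = expanded[i]
        key = tuple(keys[i])
        neigh = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    neigh.extend(bins.get((key[0] + dx, key[1] + dy, key[2] + dz), ()))
        neigh = np.array([j for j in neigh if j != i], dtype=int)
        if len(neigh):
            delta = xyz[neigh] - xyz[i]
            d2 = np.einsum("ij,ij->i", delta, delta)
            close = d2 < (ri + expanded[neigh]) ** 2
            neigh = neigh[close]
        if len(neigh) == 0:
            areas[out_i] = 4.0 * np.pi * ri * ri
            continue
        surf = xyz[i] + ri * pts
        free = np.ones(len(pts), dtype=bool)
        order = np.argsort(np.einsum("ij,ij->i", xyz[neigh] - xyz[i],
                                     xyz[neigh] - xyz[i]))
        for j in neigh[order]:
            if not free.any():
                break
            dj = surf[free] - xyz[j]
            inside = np.einsum("ij,ij->i", dj, dj) < expanded[j] ** 2
            idx = np.flatnonzero(free)
            free[idx[inside]] = False
        areas[out_i] = 4.0 * np.pi * ri * ri * free.sum() / len(pts)
    return areas


def sasa(model: AtomicModel, subset=None, context=None,
         params: SasaParams = SasaParams(),
         coords: np.ndarray | None = None) -> SasaResult:
    """Shrake–Rupley SASA of ``subset`` atoms within ``context`` atoms.

    ``subset`` and ``context`` are serial lists (defaults: all atoms;
    subset must be within context).  ``coords`` overrides the model's own
    coordinates, e.g. with one trajectory frame.
    """
    all_serials = model.serial
    ctx = np.asarray(context if context is not None else all_serials, dtype=np.int64)
    sub = np.asarray(subset if subset is not None else ctx, dtype=np.int64)
    if not np.all(np.isin(sub, ctx)):
        raise ValueError("subset atoms must be contained in the context")
    ctx_rows = model.index_of(ctx)
    xyz = (coords if coords is not None else model.xyz)[ctx_rows]
    radii = model.radius[ctx_rows]
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        bad = ctx[~np.isfinite(radii) | (radii <= 0)]
        raise ValueError(f"missing/invalid radius for serials {bad.tolist()}")
    pos_in_ctx = {int(s): k for k, s in enumerate(ctx)}
    subset_idx = np.array([pos_in_ctx[int(s)] for s in sub], dtype=int)
    areas = _sasa_areas(np.asarray(xyz, dtype=float), radii, subset_idx, params)
    return SasaResult(serials=sub.copy(), areas=areas)


def buried_sasa(model: AtomicModel, part_a, part_b, restrict=None,
                params: SasaParams = SasaParams(),
                coords: np.ndarray | None = None) -> float:
    """Interface area buried between two disjoint parts, in Ų.

    Computed as SASA(A alone) − SASA(A with B present).  With ``restrict``
    (a serial list), the per-atom sums on both sides are limited to the
    restricted atoms of A, giving a per-domain share of the interface.
    """
    a = np.asarray(part_a, dtype=np.int64)
    b = np.asarray(part_b, dtype=np.int64)
    if np.intersect1d(a, b).size:
        raise ValueError("part A and part B overlap")
    sub = a if restrict is None else np.intersect1d(a, np.asarray(restrict))
    alone = sasa(model, subset=sub, context=a, params=params, coords=coords)
    together = sasa(model, subset=sub, context=np.concatenate([a, b]),
                    params=params, coords=coords)
    return alone.total - together.total


def buried_sasa_series(traj: Trajectory, model: AtomicModel, part_a, part_b,
                       domains: dict | None = None,
                       params: SasaParams = SasaParams(),
                       stride: int = 1) -> pd.DataFrame:
    """Per-frame buried SASA, long format: time_ns, domain, buried_area_A2.

    ``domains`` maps a domain label to the serial list to restrict to; a
    ``total`` row (the full A/B interface, no restriction) is always
    emitted.  ``stride`` subsamples frames.
    """
    rows = []
    restrictions = {"total": None}
    if domains:
        restrictions.update(domains)
    for k in range(0, traj.n_frames, stride):
        frame = traj.coords[k]
        t = float(traj.times[k])
        for label, restrict in restrictions.items():
            val = buried_sasa(model, part_a, part_b, restrict=restrict,
                              params=params, coords=frame)
            rows.append((t, label, val))
    return pd.DataFrame(rows, columns=["time_ns", "domain", "buried_area_A2"])
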