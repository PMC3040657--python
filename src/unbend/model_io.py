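"""Structure/trajectory data model, PDB and series I/O, selections, geometry.

The central containers are :class:`AtomicModel` (a flat, array-backed atom
table with per-atom annotations needed by the surface-area and H-bond
analyses), :class:`DomainMap` (named residue-range sets per chain, with
composite selections such as ``headpiece``), and :class:`Trajectory`
(time-stamped coordinate frames over a fixed topology).

Geometry primitives (COM, Kabsch superposition, RMSD and extension series)
live here because every downstream analysis builds on them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "AtomicModel",
    "DomainMap",
    "Trajectory",
    "Selection",
    "VDW_RADII",
    "read_pdb",
    "write_pdb",
    "read_annotations",
    "write_annotations",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "resolve_selection",
    "com",
    "kabsch_superpose",
    "rmsd_series",
    "extension_series",
    "default_integrin_domain_map",
]

#: van der Waals radii (Å) by element; ``BEAD`` is the pseudo-atom default.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "BEAD": 1.80}

_ROLES = ("none", "donor", "hydrogen", "acceptor")


class PDBParseError(ValueError):
    """Raised for malformed fixed-width PDB records; carries the line number."""


class ValidationError(ValueError):
    """Raised when an atom table violates a structural invariant."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class AtomicModel:
    """Flat atom table with per-atom annotations.

    Attributes
    ----------
    serial : (n,) int array, unique atom serial numbers.
    name : (n,) str array, short atom names (e.g. ``CA``).
    resname : (n,) str array, residue names.
    resid : (n,) int array, 1-based residue numbers.
    chain : (n,) str array, single-character chain identifiers.
    xyz : (n, 3) float array, positions in Å.
    radius : (n,) float array, vdW radii in Å (all > 0).
    role : (n,) str array, H-bond role: none | donor | hydrogen | acceptor.
    donor_link : (n,) int array, for hydrogens the serial of the attached
        donor heavy atom; -1 elsewhere.
    hydrophobic : (n,) bool array.
    element : (n,) str array, element symbol or ``BEAD`` for pseudo-atoms.
    """

    serial: np.ndarray
    name: np.ndarray
    resname: np.ndarray
    resid: np.ndarray
    chain: np.ndarray
    xyz: np.ndarray
    radius: np.ndarray
    role: np.ndarray
    donor_link: np.ndarray
    hydrophobic: np.ndarray
    element: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.serial)
        self.serial = np.asarray(self.serial, dtype=np.int64)
        self.resid = np.asarray(self.resid, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(n, 3)
        self.radius = np.asarray(self.radius, dtype=float)
        self.donor_link = np.asarray(self.donor_link, dtype=np.int64)
        self.hydrophobic = np.asarray(self.hydrophobic, dtype=bool)
        for attr in ("name", "resname", "chain", "role", "element"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=object))

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    def validate(self) -> None:
        if len(np.unique(self.serial)) != self.n_atoms:
            seen, dups = set(), []
            for s in self.serial:
                if s in seen:
                    dups.append(int(s))
                seen.add(int(s))
            raise ValidationError(f"duplicate atom serials: {sorted(set(dups))}")
        if np.any(self.radius <= 0):
            bad = self.serial[self.radius <= 0]
            raise ValidationError(f"non-positive radius for serials {bad.tolist()}")
        if not np.all(np.isfinite(self.xyz)):
            raise ValidationError("non-finite coordinates")
        bad_roles = set(self.role) - set(_ROLES)
        if bad_roles:
            raise ValidationError(f"unknown H-bond roles: {sorted(bad_roles)}")
        serial_set = {int(s): str(r) for s, r in zip(self.serial, self.role)}
        for s, role, link in zip(self.serial, self.role, self.donor_link):
            if role == "hydrogen":
                if int(link) not in serial_set:
                    raise ValidationError(
                        f"hydrogen serial {int(s)} links to missing atom {int(link)}")
                if serial_set[int(link)] != "donor":
                    raise ValidationError(
                        f"hydrogen serial {int(s)} links to non-donor atom {int(link)}")

    def index_of(self, serials) -> np.ndarray:
        """Row indices of the given serials (order-preserving)."""
        order = np.argsort(self.serial)
        pos = np.searchsorted(self.serial, serials, sorter=order)
        pos = np.clip(pos, 0, self.n_atoms - 1)
        idx = order[pos]
        if not np.array_equal(self.serial[idx], np.asarray(serials)):
            missing = set(np.asarray(serials).tolist()) - set(self.serial.tolist())
            raise KeyError(f"serials not in model: {sorted(missing)}")
        return idx

    def copy(self) -> "AtomicModel":
        return AtomicModel(*(np.array(getattr(self, f), copy=True) for f in (
            "serial", "name", "resname", "resid", "chain", "xyz", "radius",
            "role", "donor_link", "hydrophobic", "element")))

    def __eq__(self, other) -> bool:  # field-wise equality on retained fields
        if not isinstance(other, AtomicModel):
            return NotImplemented
        for f in ("serial", "resid", "donor_link", "hydrophobic"):
            if not np.array_equal(getattr(self, f), getattr(other, f)):
                return False
        for f in ("name", "resname", "chain", "role", "element"):
            if not np.array_equal(getattr(self, f).astype(str),
                                  getattr(other, f).astype(str)):
                return False
        return (np.allclose(self.xyz, other.xyz, atol=1e-3)
                and np.allclose(self.radius, other.radius, atol=1e-6))


@dataclass
class DomainMap:
    """Named residue-range sets per chain plus composite selections.

    ``ranges`` maps ``(chain, domain)`` to an ordered list of inclusive
    1-based ``(start, stop)`` residue ranges.  ``composites`` maps a set
    name (``headpiece``, ``pull_head``, ...) to a list of members, each
    either ``(chain, domain)`` or an explicit ``(chain, start, stop)``.
    """

    ranges: dict = field(default_factory=dict)
    composites: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (chain, dom), rng in self.ranges.items():
            spans = sorted((int(a), int(b)) for a, b in rng)
            for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                if a2 <= b1:
                    raise ValidationError(
                        f"overlapping ranges in domain {dom!r} chain {chain!r}")
            self.ranges[(chain, dom)] = spans

    def domains(self, chain: str | None = None) -> list:
        return [d for (c, d) in self.ranges if chain is None or c == chain]

    def members(self, composite: str) -> list:
        if composite not in self.composites:
            raise KeyError(
                f"unknown composite {composite!r}; known: {sorted(self.composites)}")
        return self.composites[composite]

    def to_yaml(self, path) -> None:
        doc = {
            "domains": [
                {"chain": c, "name": d, "ranges": [[a, b] for a, b in rng]}
                for (c, d), rng in self.ranges.items()
            ],
            "composites": {
                name: [list(m) for m in members]
                for name, members in self.composites.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DomainMap":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        ranges = {(d["chain"], d["name"]): [tuple(r) for r in d["ranges"]]
                  for d in doc.get("domains", [])}
        composites = {name: [tuple(m) for m in members]
                      for name, members in doc.get("composites", {}).items()}
        return cls(ranges=ranges, composites=composites)


def default_integrin_domain_map() -> DomainMap:
    """Domain architecture of the αVβ3 ectodomain.

    Chain A is the α(V) subunit, chain B the β(3) subunit.  The ranges are
    the standard crystallographic domain boundaries; ``headpiece`` /
    ``tailpiece`` composites follow the conventional split at the knees
    (α 1–600 | 601–956; β 1–472 | 473–690).  The pull/constraint composites
    are the Cα groups used for COM pulling of the βA or β-propeller domain
    and the βTD anchor.
    """
    ranges = {
        ("A", "beta-propeller"): [(1, 438)],
        ("A", "thigh"): [(439, 600)],
        ("A", "calf-1"): [(601, 738)],
        ("A", "calf-2"): [(739, 956)],
        ("B", "PSI"): [(1, 57)],
        ("B", "hybrid"): [(58, 110), (354, 434)],
        ("B", "betaA"): [(111, 353)],
        ("B", "EGF1"): [(435, 472)],
        ("B", "EGF2"): [(473, 522)],
        ("B", "EGF3"): [(523, 559)],
        ("B", "EGF4"): [(560, 599)],
        ("B", "beta-ankle"): [(600, 605)],
        ("B", "betaTD"): [(606, 690)],
    }
    composites = {
        "headpiece": [("A", 1, 600), ("B", 1, 472)],
        "tailpiece": [("A", 601, 956), ("B", 473, 690)],
        "pull_betaA": [("B", 113, 117), ("B", 151, 156), ("B", 190, 197),
                       ("B", 244, 250), ("B", 306, 310), ("B", 329, 332)],
        "pull_propeller": [("A", 22, 26), ("A", 97, 101), ("A", 160, 164),
                           ("A", 225, 229), ("A", 279, 283), ("A", 343, 347),
                           ("A", 407, 411)],
        "constrain_betaTD": [("B", 610, 620), ("B", 639, 642), ("B", 656, 658),
                             ("B", 665, 670), ("B", 679, 682)],
    }
    return DomainMap(ranges=ranges, composites=composites)


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology.

    times are in ns (strictly increasing); coords has shape
    (n_frames, n_atoms, 3) in Å.
    """

    times: np.ndarray
    coords: np.ndarray
    topology: AtomicModel | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must have shape (frames, atoms, 3)")
        if len(self.times) != len(self.coords):
            raise ValidationError("times/coords length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("frame times must be strictly increasing")
        if self.topology is not None and self.coords.shape[1] != self.topology.n_atoms:
            raise ValidationError("frame atom count differs from topology")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class Selection:
    """Declarative atom selection.

    Predicates combine conjunctively; ``domains`` and ``composites`` draw
    residue ranges from a :class:`DomainMap`.  Resolution is deterministic:
    the result is the sorted list of matching serials.
    """

    chain: str | None = None
    residue_ranges: tuple = ()          # ((start, stop), ...) inclusive
    atom_names: tuple = ()              # () = any
    domains: tuple = ()                 # ((chain, domain_name), ...)
    composites: tuple = ()              # composite names from the map
    serials: tuple = ()                 # explicit serials (unioned in)
    ca_only: bool = False               # keep one CA atom per residue


# ---------------------------------------------------------------------------
# PDB I/O (v3.3 fixed-width)
# ---------------------------------------------------------------------------


def _element_of(name: str, explicit: str) -> str:
    explicit = explicit.strip().upper()
    if explicit == "BD":          # pseudo-bead marker used by write_pdb
        return "BEAD"
    if explicit:
        return explicit
    stripped = name.strip()
    return stripped[:1].upper() if stripped else "BEAD"


def read_pdb(path, annotations=None) -> AtomicModel:
    """Read ATOM/HETATM records from a PDB v3.3 file.

    Per-atom annotations (radius, H-bond role, donor link, hydrophobic
    flag) are taken from the optional sidecar ``annotations`` CSV if
    given; otherwise radii come from :data:`VDW_RADII` by element and a
    minimal chemical heuristic assigns roles: N/O atoms are donors and
    acceptors, and any hydrogen within 1.2 Å of a donor heavy atom is
    recorded as that donor's hydrogen.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec not in ("ATOM  ", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(
                    f"line {lineno}: record too short for coordinate columns")
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                resname = line[17:20].strip()
                chain = line[21]
                resid = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise PDBParseError(f"line {lineno}: {exc}") from exc
            element = _element_of(name, line[76:78] if len(line) >= 78 else "")
            rows.append((serial, name, resname, chain, resid, x, y, z, element))
    n = len(rows)
    serial = np.array([r[0] for r in rows], dtype=np.int64)
    model = AtomicModel(
        serial=serial,
        name=np.array([r[1] for r in rows], dtype=object),
        resname=np.array([r[2] for r in rows], dtype=object),
        resid=np.array([r[4] for r in rows], dtype=np.int64),
        chain=np.array([r[3] for r in rows], dtype=object),
        xyz=np.array([(r[5], r[6], r[7]) for r in rows], dtype=float).reshape(n, 3),
        radius=np.array([VDW_RADII.get(r[8], VDW_RADII["BEAD"]) for r in rows]),
        role=np.array(["none"] * n, dtype=object),
        donor_link=np.full(n, -1, dtype=np.int64),
        hydrophobic=np.zeros(n, dtype=bool),
        element=np.array([r[8] for r in rows], dtype=object),
    )
    if len(np.unique(model.serial)) != n:
        model.validate()  # raises naming the duplicates
    if annotations is not None:
        _apply_annotations(model, annotations)
    else:
        _heuristic_roles(model)
    model.validate()
    return model


def _heuristic_roles(model: AtomicModel) -> None:
    """N/O heavy atoms are donors+acceptors; nearest H within 1.2 Å links."""
    heavy = np.isin(model.element, ("N", "O"))
    model.role[heavy] = "acceptor"
    hyd = model.element == "H"
    if not np.any(hyd):
        return
    heavy_idx = np.flatnonzero(heavy)
    for hi in np.flatnonzero(hyd):
        if len(heavy_idx) == 0:
            break
        d = np.linalg.norm(model.xyz[heavy_idx] - model.xyz[hi], axis=1)
        j = int(np.argmin(d))
        if d[j] <= 1.2:
            di = heavy_idx[j]
            model.role[di] = "donor"
            model.role[hi] = "hydrogen"
            model.donor_link[hi] = model.serial[di]


def write_pdb(model: AtomicModel, path) -> None:
    """Write PDB v3.3 fixed-width ATOM records with TER between chains."""
    model.validate()
    if np.any(model.serial > 99999):
        raise ValueError("atom serial > 99999 cannot be encoded in PDB format")
    if np.any(model.resid > 9999):
        raise ValueError("residue number > 9999 cannot be encoded in PDB format")
    lines = []
    prev_chain = None
    for i in range(model.n_atoms):
        chain = str(model.chain[i])
        if prev_chain is not None and chain != prev_chain:
            lines.append("TER")
        prev_chain = chain
        name = str(model.name[i])
        # PDB name column convention: 1-char element names start at col 14
        padded = f" {name:<3s}" if len(name) < 4 else name
        element = str(model.element[i])
        el = element if element != "BEAD" else "BD"
        lines.append(
            f"ATOM  {int(model.serial[i]):5d} {padded:<4.4s} "
            f"{str(model.resname[i]):<3.3s} {chain:1.1s}{int(model.resid[i]):4d}    "
            f"{model.xyz[i, 0]:8.3f}{model.xyz[i, 1]:8.3f}{model.xyz[i, 2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {el:>2.2s}"
        )
    lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_annotations(model: AtomicModel, path) -> None:
    """Sidecar annotation CSV: serial, radius, role, donor_link, hydrophobic."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["serial", "radius", "role", "donor_link", "hydrophobic"])
        for i in range(model.n_atoms):
            w.writerow([int(model.serial[i]), f"{model.radius[i]:.4f}",
                        str(model.role[i]), int(model.donor_link[i]),
                        int(model.hydrophobic[i])])


def read_annotations(path) -> dict:
    """Read a sidecar annotation CSV into ``{serial: row-dict}``."""
    out = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[int(row["serial"])] = {
                "radius": float(row["radius"]),
                "role": row["role"],
                "donor_link": int(row["donor_link"]),
                "hydrophobic": bool(int(row["hydrophobic"])),
            }
    return out


def _apply_annotations(model: AtomicModel, annotations) -> None:
    table = annotations if isinstance(annotations, dict) else read_annotations(annotations)
    for i, s in enumerate(model.serial):
        row = table.get(int(s))
        if row is None:
            continue
        model.radius[i] = row["radius"]
        model.role[i] = row["role"]
        model.donor_link[i] = row["donor_link"]
        model.hydrophobic[i] = row["hydrophobic"]


# ---------------------------------------------------------------------------
# trajectory I/O (plain columnar text)
# ---------------------------------------------------------------------------


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """One row per frame: time_ns, x1, y1, z1, x2, ... (repr precision)."""
    n = traj.n_atoms
    header = ["time_ns"] + [f"{ax}{i + 1}" for i in range(n) for ax in "xyz"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for t, frame in zip(traj.times, traj.coords):
            w.writerow([repr(float(t))] + [repr(float(v)) for v in frame.ravel()])


def read_trajectory_csv(path, topology: AtomicModel | None = None) -> Trajectory:
    times, frames = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        n = (len(header) - 1) // 3
        for row in reader:
            times.append(float(row[0]))
            frames.append(np.array(row[1:], dtype=float).reshape(n, 3))
    return Trajectory(times=np.array(times), coords=np.array(frames),
                      topology=topology)


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------


def _ranges_for(dmap: DomainMap, member) -> list:
    """Expand a composite member into (chain, start, stop) triples."""
    if len(member) == 2:
        chain, dom = member
        if (chain, dom) not in dmap.ranges:
            known = sorted(d for _, d in dmap.ranges)
            raise KeyError(f"unknown domain {dom!r} for chain {chain!r}; "
                           f"known domains: {known}")
        return [(chain, a, b) for a, b in dmap.ranges[(chain, dom)]]
    chain, a, b = member
    return [(chain, int(a), int(b))]


def resolve_selection(model: AtomicModel, dmap: DomainMap | None,
                      spec: Selection) -> np.ndarray:
    """Resolve a :class:`Selection` to a sorted unique array of serials."""
    mask = np.ones(model.n_atoms, dtype=bool)
    if spec.chain is not None:
        mask &= model.chain.astype(str) == spec.chain
    if spec.atom_names:
        mask &= np.isin(model.name.astype(str), spec.atom_names)

    triples = []
    for rng in spec.residue_ranges:
        if len(rng) == 3:
            triples.append((rng[0], int(rng[1]), int(rng[2])))
        else:
            triples.append((spec.chain, int(rng[0]), int(rng[1])))
    for member in spec.domains:
        triples.extend(_ranges_for(_require_map(dmap), member))
    for name in spec.composites:
        for member in _require_map(dmap).members(name):
            triples.extend(_ranges_for(dmap, member))

    if triples:
        range_mask = np.zeros(model.n_atoms, dtype=bool)
        chains = model.chain.astype(str)
        for chain, a, b in triples:
            m = (model.resid >= a) & (model.resid <= b)
            if chain is not None:
                m &= chains == chain
            range_mask |= m
        mask &= range_mask

    serials = set(model.serial[mask].tolist())
    serials.update(int(s) for s in spec.serials)
    serials &= set(model.serial.tolist())
    out = np.array(sorted(serials), dtype=np.int64)
    if spec.ca_only and len(out):
        idx = model.index_of(out)
        keep = []
        seen = set()
        for s, i in zip(out, idx):
            key = (str(model.chain[i]), int(model.resid[i]))
            if str(model.name[i]) == "CA" and key not in seen:
                seen.add(key)
                keep.append(int(s))
        out = np.array(keep, dtype=np.int64)
    return out


def _require_map(dmap: DomainMap | None) -> DomainMap:
    if dmap is None:
        raise ValueError("selection uses domain names but no DomainMap given")
    return dmap


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------


def com(positions: np.ndarray, indices=None, weights=None) -> np.ndarray:
    """Weighted mean position of the selected rows (uniform by default)."""
    pos = np.asarray(positions, dtype=float)
    if indices is not None:
        pos = pos[np.asarray(indices, dtype=int)]
    if len(pos) == 0:
        raise ValueError("COM of an empty selection")
    if weights is None:
        return pos.mean(axis=0)
    w = np.asarray(weights, dtype=float)
    return (pos * w[:, None]).sum(axis=0) / w.sum()


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``; the
    rotation is proper (det = +1).
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    if len(mob) < 3:
        raise ValueError("need at least 3 fit atoms")
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    p, q = mob - mc, ref - rc
    # degenerate (collinear) sets have rank < 2 covariance
    if np.linalg.matrix_rank(p, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) fit atom set")
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = rc - rot @ mc
    fitted = mob @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return rot, trans, rmsd


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(traj: Trajectory, reference: np.ndarray, indices,
                superpose: bool = True) -> np.ndarray:
    """Per-frame RMSD (Å) of the selected atoms against a reference frame.

    With ``superpose`` (the default, the standard Cα-RMSD convention) each
    frame is first Kabsch-fit onto the reference using the same selection.
    Returns an array of shape (n_frames, 2): time_ns, rmsd_A.
    """
    idx = np.asarray(indices, dtype=int)
    ref = np.asarray(reference, dtype=float)[idx]
    out = np.empty((traj.n_frames, 2))
    for k, frame in enumerate(traj.coords):
        mob = frame[idx]
        if superpose:
            _, _, r = kabsch_superpose(mob, ref)
        else:
            r = _rmsd(mob, ref)
        out[k] = (traj.times[k], r)
    return out


def extension_series(traj: Trajectory, pull_indices, constraint_indices) -> np.ndarray:
    """Pull-COM-to-constraint-COM distance change from frame 0.

    Extension is the increase of distance between the pulled and the
    constrained locations; frame 0 maps to exactly 0.  Returns an array of
    shape (n_frames, 2): time_ns, extension_A.
    """
    pi = np.asarray(pull_indices, dtype=int)
    ci = np.asarray(constraint_indices, dtype=int)
    if len(pi) == 0 or len(ci) == 0:
        raise ValueError("empty pull or constraint selection")
    d = np.linalg.norm(traj.coords[:, pi].mean(axis=1)
                       - traj.coords[:, ci].mean(axis=1), axis=1)
    out = np.column_stack([traj.times, d - d[0]])
    out[0, 1] = 0.0
    return out
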