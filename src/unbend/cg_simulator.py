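"""Coarse-grained synthetic-data engine: bent two-chain model + pulling dynamics.

This module builds a pseudo-atomic stand-in for a bent integrin-like
ectodomain and runs overdamped Langevin dynamics under the pulling
protocols used in steered-MD studies (free, constant-velocity with a
moving virtual spring F = k(vt−x), constant force), so that every
downstream analysis — buried SASA, H-bonds, hinge angles, extension,
waiting times — can be exercised end to end at desk scale.

Architecture of the built model (two chains, twelve domains, twelve
beads each):

* chain A (α-analog): β-propeller — thigh — calf-1 — calf-2, with a
  "genu" elbow between thigh and calf-1;
* chain B (β-analog): PSI — hybrid — βA head cluster, then
  EGF1 — EGF2 — EGF3 — EGF4 — βTD leg, with a knee in the EGF1/EGF2
  region.

The bent hairpin is held by breakable interface contacts: polar contacts
(donor/hydrogen/acceptor bead triplets satisfying the geometric H-bond
criterion) between hybrid and βTD, and hydrophobic contacts between
hybrid and EGF4.  Knee bending angles carry double-well potentials (one
well at the bent geometry, one at 180°), so the molecule is bistable:
the bent state is trapped behind the contact + knee barrier, a partially
extended state relaxes back, and a fully extended state is metastable on
simulation time scales.  Each energy scale is its own, chosen for the
desk-scale system; the pipeline mirrors protocol and analysis shapes,
not the absolute forces/times of any all-atom system.

Units: Å, ns, pN, pN·Å throughout (see :mod:`unbend.constants`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba import njit

from .constants import kbt, spring_kcal_to_pn_per_a
from .model_io import AtomicModel, DomainMap, Trajectory

__all__ = ["CgConfig", "CgTopology", "PullingProtocol", "SimParams",
           "build_bent_model", "run_dynamics", "snapshot_restart",
           "potential_energy", "SimulationUnstable"]


class SimulationUnstable(RuntimeError):
    """Raised when a time step moves a bead farther than the guard allows."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CgConfig:
    """Geometry and energy scales of the synthetic bent molecule.

    Lengths in Å, spring constants in pN/Å, angle stiffness in
    pN·Å/rad², well depths / barriers in pN·Å.
    """

    beads_per_domain: int = 12
    domain_radius: float = 6.0         # bead-shell radius
    link_length: float = 30.0          # adjacent domain center spacing, chain B
    link_length_alpha: float = 70.0    # chain A spacing (fewer, larger domains,
                                       # so both legs have equal contours)
    contact_distance: float = 20.0     # hybrid center to βTD / EGF4 center
    bent_head_tail: float = 45.0       # built |COM(βA) − COM(βTD)|
    chain_separation: float = 16.0     # y-offset of chain A
    stalk_length: float = 8.5          # interface bead reach from center
    contact_rest: float = 3.0          # built donor–acceptor distance
    contact_break: float = 8.0         # capture/break radius
    n_polar: int = 4                   # hybrid–βTD H-bonding contacts
    n_hydrophobic: int = 3             # hybrid–EGF4 contacts
    eps_polar: float = 200.0           # well depth per polar contact
    eps_hydrophobic: float = 140.0     # well depth per hydrophobic contact
    k_intra: float = 20.0              # all-pairs springs within a domain
    k_link: float = 200.0              # inter-domain backbone links
    k_angle: float = 2000.0            # single-well (straight/shape) angles
    k_head_angle: float = 200.0        # soft head-tuck angle (hybrid vertex)
    knee_barrier: float = 350.0        # double-well barrier height (β-knee)
    knee_barrier_alpha: float = 600.0  # α-genu barrier; higher, so the α
                                       # knee holds until the interface
                                       # ruptures and both knees then open
                                       # under the shared tension
    k_pin: float = 250.0               # zero-rest pin springs forming the
                                       # mechanical hinge at each backbone
                                       # joint (isotropic attachment)
    pin_offset: float = 3.0            # half-separation of the pin pair
                                       # along the hinge axis, Å
    k_twist: float = 400.0             # torsion restraint per backbone link
                                       # (pN·Å, cosine form); domains must
                                       # not spin freely about the link axis
    k_zip: float = 60.0                # α/β leg-leg coupling springs (the
                                       # closed-legs contacts); zipping the
                                       # lower legs closes the kinematic
                                       # loop so the two knees open as one
    k_plane: float = 400.0             # chain-planarity (center dihedral)
                                       # restraint, pN·Å cosine form; stops
                                       # the folded arm precessing out of
                                       # the bending plane
    genu_stalk: float = 27.0           # axial reach of genu marker beads
    genu_offset: float = 9.0           # radial offset of genu marker beads
    min_center_separation: float = 13.0
    bead_radius: float = 1.8
    hydrogen_radius: float = 1.2

    def __post_init__(self) -> None:
        if self.beads_per_domain < 12:
            raise ValueError("domains need at least 12 beads")
        if self.contact_break <= self.contact_rest:
            raise ValueError("break radius must exceed the contact rest length")
        if self.contact_distance <= self.link_length / 2:
            raise ValueError("contact_distance too small for the hairpin geometry")


@dataclass
class CgTopology:
    """Bonded and breakable interaction lists over the bead table.

    All index arrays are 0-based rows into the model's atom table.
    ``angles`` entries are (domain_a, vertex_domain, domain_b, kind,
    theta0, theta_ext) where kind is ``single`` (harmonic about theta0)
    or ``double`` (two wells, theta0 bent and theta_ext straight).
    """

    domains: dict                      # name -> bead row array
    domain_order: list                 # names in center-array order
    springs: np.ndarray                # (m, 2) int rows
    spring_rest: np.ndarray            # (m,)
    spring_k: np.ndarray               # (m,)
    angles: list                       # see above, domain names
    contacts: np.ndarray               # (c, 2) int rows
    contact_rest: np.ndarray
    contact_break: np.ndarray
    contact_k: np.ndarray
    contact_eps: np.ndarray
    contact_class: list                # 'polar' | 'hydrophobic' | 'genu'
    dihedrals: np.ndarray = None       # (q, 4) twist restraints per link
    dihedral_phi0: np.ndarray = None   # built twist angles (rad)
    center_dihedrals: np.ndarray = None    # (p, 4) domain-index quads
    center_dihedral_phi0: np.ndarray = None
    spring_tether: np.ndarray = None   # (m,) bool: one-sided (stretch-only)

    def validate(self, n_atoms: int) -> None:
        for arr in (self.springs, self.contacts):
            if arr.size and (arr.min() < 0 or arr.max() >= n_atoms):
                raise ValueError("topology references beads outside the model")
        if np.any(self.contact_break <= self.contact_rest):
            raise ValueError("contact break radius must exceed rest length")


@dataclass
class PullingProtocol:
    """Pulling mode and selections.

    ``spring_k`` and ``constraint_k`` are in pN/Å (use
    :func:`unbend.constants.spring_kcal_to_pn_per_a` for
    kcal mol⁻¹ Å⁻² inputs), ``speed`` in Å/ns, ``force`` in pN.
    ``direction`` is ``fixed`` (unit vector from constraint COM to pull
    COM at t = 0) or ``tracking`` (recomputed every step).
    """

    mode: str = "free"                 # free | constant-velocity | constant-force
    pull_serials: tuple = ()
    constraint_serials: tuple = ()
    spring_k: float = spring_kcal_to_pn_per_a(0.5)
    speed: float = 2.0
    force: float = 0.0
    direction: str = "fixed"
    constraint_k: float = spring_kcal_to_pn_per_a(10.0)

    def __post_init__(self) -> None:
        if self.mode not in ("free", "constant-velocity", "constant-force"):
            raise ValueError(f"unknown pulling mode {self.mode!r}")
        if self.direction not in ("fixed", "tracking"):
            raise ValueError(f"unknown direction policy {self.direction!r}")
        if self.spring_k < 0 or self.constraint_k < 0:
            raise ValueError("spring constants must be >= 0")
        if self.mode != "free" and len(self.pull_serials) == 0:
            raise ValueError(f"{self.mode} mode requires a pull selection")
        if self.mode == "constant-velocity" and self.speed <= 0:
            raise ValueError("constant-velocity mode requires a positive speed")
        if self.mode == "constant-force" and self.force <= 0:
            raise ValueError("constant-force mode requires a positive force")


@dataclass
class SimParams:
    """Thermostat and integration constants for overdamped Langevin."""

    temperature: float = 300.0     # K
    gamma: float = 1.0             # pN·ns/Å per bead
    dt: float = 0.002              # ns
    duration: float = 10.0         # ns
    save_stride: int = 50          # steps between saved frames
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0 or self.save_stride < 1:
            raise ValueError("dt, duration and save_stride must be positive")
        if self.gamma <= 0 or self.temperature < 0:
            raise ValueError("gamma must be positive, temperature >= 0")


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------


def _icosahedron() -> np.ndarray:
    """The 12 unit-sphere vertices of a regular icosahedron."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array([
        (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
        (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
        (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
    ], dtype=float)
    return v / np.linalg.norm(v[0])


def _perp_pair(u: np.ndarray) -> tuple:
    """Two unit vectors orthogonal to u and to each other."""
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def _circle_intersection(p: np.ndarray, rp: float, q: np.ndarray, rq: float,
                         prefer_high_x: bool = True) -> np.ndarray:
    """Intersection of two circles in the xz-plane (y = 0), as a 3-vector."""
    d = q - p
    dist = np.hypot(d[0], d[2])
    if dist > rp + rq or dist < abs(rp - rq) or dist == 0:
        raise ValueError("bent geometry infeasible: circles do not intersect "
                         "(adjust link_length / contact_distance / bent_head_tail)")
    a = (rp ** 2 - rq ** 2 + dist ** 2) / (2 * dist)
    h = np.sqrt(max(0.0, rp ** 2 - a ** 2))
    ex = np.array([d[0], 0.0, d[2]]) / dist
    ez = np.array([-ex[2], 0.0, ex[0]])
    cand = [p + a * ex + h * ez, p + a * ex - h * ez]
    cand.sort(key=lambda r: -r[0] if prefer_high_x else r[0])
    return cand[0]


def _domain_centers(cfg: CgConfig) -> dict:
    """Domain center positions of the bent (hairpin) conformation."""
    L, D = cfg.link_length, cfg.contact_distance
    y = cfg.chain_separation
    centers = {}
    # chain B leg: βTD anchored at the origin, leg rising along +z
    centers["betaTD"] = np.array([0.0, 0.0, 0.0])
    centers["EGF4"] = np.array([0.0, 0.0, L])
    centers["EGF3"] = np.array([0.0, 0.0, 2 * L])
    centers["EGF2"] = np.array([0.0, 0.0, 3 * L])
    # hybrid wedged against βTD and EGF4 (the folded-back headpiece)
    hx = np.sqrt(D ** 2 - (L / 2) ** 2)
    centers["hybrid"] = np.array([hx, 0.0, L / 2])
    # EGF1 closes the hairpin: one link from EGF2, two links from hybrid
    centers["EGF1"] = _circle_intersection(centers["EGF2"], L,
                                           centers["hybrid"], 2 * L)
    centers["PSI"] = 0.5 * (centers["EGF1"] + centers["hybrid"])
    # βA head: one link from hybrid, bent head-tail distance from βTD
    centers["betaA"] = _circle_intersection(centers["hybrid"], L,
                                            centers["betaTD"], cfg.bent_head_tail)
    # chain A mirrors the fold at a y-offset; its three long links give the
    # α-leg the same extended contour as the seven-link β path
    La = cfg.link_length_alpha
    centers["beta-propeller"] = centers["betaA"] + np.array([0.0, y, 0.0])
    centers["calf-2"] = np.array([0.0, y, 0.0])
    centers["calf-1"] = np.array([0.0, y, La])
    prop, c1 = centers["beta-propeller"], centers["calf-1"]
    mid = 0.5 * (prop + c1)
    span = np.hypot(prop[0] - c1[0], prop[2] - c1[2])
    if span >= 2 * La:
        raise ValueError("bent geometry infeasible: alpha elbow cannot close")
    h = np.sqrt(La ** 2 - (span / 2) ** 2)
    ex = np.array([c1[0] - prop[0], 0.0, c1[2] - prop[2]]) / span
    up = np.array([ex[2], 0.0, -ex[0]])
    if up[2] < 0:
        up = -up
    centers["thigh"] = mid + h * up
    return centers


#: chain membership and backbone order of the twelve domains.
CHAIN_A = ["beta-propeller", "thigh", "calf-1", "calf-2"]
CHAIN_B = ["PSI", "hybrid", "betaA", "EGF1", "EGF2", "EGF3", "EGF4", "betaTD"]
#: consecutive-domain backbone links (plus the two inter-chain couplings).
BACKBONE = [("beta-propeller", "thigh"), ("thigh", "calf-1"),
            ("calf-1", "calf-2"),
            ("betaA", "hybrid"), ("hybrid", "PSI"), ("PSI", "EGF1"),
            ("EGF1", "EGF2"), ("EGF2", "EGF3"), ("EGF3", "EGF4"),
            ("EGF4", "betaTD"),
            ("beta-propeller", "betaA"), ("calf-2", "betaTD")]
#: links realized as mechanical hinges: two coincident-bead pin pairs on
#: the bending axis (free bend, stiff twist/rock).  The remaining links
#: (head region and inter-chain couplings) use plain bead-pair springs.
PINNED = [("beta-propeller", "thigh"), ("thigh", "calf-1"),
          ("calf-1", "calf-2"), ("PSI", "EGF1"), ("EGF1", "EGF2"),
          ("EGF2", "EGF3"), ("EGF3", "EGF4"), ("EGF4", "betaTD"),
          ("beta-propeller", "betaA"), ("calf-2", "betaTD")]
#: bending-angle terms: (end, vertex, end, kind); 'double' = bistable knee,
#: 'soft' = weak harmonic (the head tuck, so interface escape is governed by
#: the contacts rather than a strong closing torque).
ANGLE_TERMS = [
    ("beta-propeller", "thigh", "calf-1", "double_a"),  # α-genu
    ("thigh", "calf-1", "calf-2", "double_a"),          # α-genu, lower
    ("EGF3", "EGF2", "EGF1", "double"),                 # β-knee
    ("EGF2", "EGF1", "PSI", "double"),                  # β-knee, upper
    ("PSI", "hybrid", "betaA", "single"),               # head stays tucked
    ("hybrid", "PSI", "EGF1", "single"),
    ("EGF4", "EGF3", "EGF2", "single"),
    ("betaTD", "EGF4", "EGF3", "single"),
]


def _angle_between(a: np.ndarray, v: np.ndarray, b: np.ndarray) -> float:
    u1, u2 = a - v, b - v
    cosang = float(u1 @ u2 / (np.linalg.norm(u1) * np.linalg.norm(u2)))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def build_bent_model(cfg: CgConfig = CgConfig()):
    """Build the bent pseudo-atomic model.

    Returns ``(AtomicModel, CgTopology, DomainMap)``.  The built geometry
    is an exact mechanical equilibrium of its own topology: every spring
    and contact rest length and every angle equilibrium is set to the
    as-built value, so a zero-temperature free run does not move.
    """
    centers = _domain_centers(cfg)
    names_in_order = CHAIN_A + CHAIN_B
    pts = _icosahedron() * cfg.domain_radius
    n_extra = cfg.beads_per_domain - 12
    if n_extra:
        from .sasa import sphere_points
        extra = sphere_points(n_extra + 12)[:n_extra] * cfg.domain_radius
    # per-bead tables
    chain_l, names_l, xyz_l, role_l, link_l, phob_l, radius_l, domain_l = (
        [], [], [], [], [], [], [], [])

    def add_bead(chain, name, pos, domain, role="none", donor_pos=None,
                 hydrophobic=False, radius=None):
        chain_l.append(chain)
        names_l.append(name)
        xyz_l.append(np.asarray(pos, dtype=float))
        role_l.append(role)
        link_l.append(donor_pos)      # resolved to serials later
        phob_l.append(hydrophobic)
        radius_l.append(cfg.bead_radius if radius is None else radius)
        domain_l.append(domain)
        return len(xyz_l) - 1

    hyb = centers["hybrid"]
    u_td = (centers["betaTD"] - hyb)
    u_td /= np.linalg.norm(u_td)
    u_e4 = (centers["EGF4"] - hyb)
    u_e4 /= np.linalg.norm(u_e4)
    e1, e2 = _perp_pair(u_td)
    f1, _ = _perp_pair(u_e4)
    polar_spread = [1.5 * e1, -1.5 * e1, 1.5 * e2, -1.5 * e2]
    phob_spread = [np.zeros(3), 1.5 * f1, -1.5 * f1]

    contact_rows = []   # (i, j, rest, eps, class)
    pin_registry = {}   # (link index, sign) -> [bead of da, bead of db]
    # pin positions: joint midpoint +- pin_offset along the hinge axis
    # (the geometry is planar, so the bending axis is global y)
    y_hat = np.array([0.0, 1.0, 0.0])
    pin_positions = {dom: [] for dom in CHAIN_A + CHAIN_B}
    for li, (da, db) in enumerate(PINNED):
        # ball joint at the first domain's center: bending about the pin
        # axis leaves every center-center distance unchanged
        for sign in (1.0, -1.0):
            p = centers[da] + sign * cfg.pin_offset * y_hat
            pin_positions[da].append(((li, sign), p))
            pin_positions[db].append(((li, sign), p))
    for chain, domain_names in (("A", CHAIN_A), ("B", CHAIN_B)):
        for dom in domain_names:
            c = centers[dom]
            special = []
            for key, p in pin_positions[dom]:
                bead = add_bead(chain, "PN", p, dom)
                pin_registry.setdefault(key, []).append(bead)
                special.append(bead)
            if dom == "hybrid":
                for k in range(cfg.n_polar):
                    dpos = c + cfg.stalk_length * u_td + polar_spread[k]
                    di = add_bead(chain, "ND", dpos, dom, role="donor")
                    hpos = dpos + 1.0 * u_td
                    add_bead(chain, "HD", hpos, dom, role="hydrogen",
                             donor_pos=di, radius=cfg.hydrogen_radius)
                    special.extend([di, di + 1])
                for k in range(cfg.n_hydrophobic):
                    ppos = c + cfg.stalk_length * u_e4 + phob_spread[k]
                    pi = add_bead(chain, "CB", ppos, dom, hydrophobic=True)
                    special.append(pi)
            elif dom == "betaTD":
                for k in range(cfg.n_polar):
                    apos = (hyb + cfg.stalk_length * u_td + polar_spread[k]
                            + cfg.contact_rest * u_td)
                    ai = add_bead(chain, "OA", apos, dom, role="acceptor")
                    special.append(ai)
            elif dom == "EGF4":
                for k in range(cfg.n_hydrophobic):
                    bpos = (hyb + cfg.stalk_length * u_e4 + phob_spread[k]
                            + cfg.contact_rest * u_e4)
                    bi = add_bead(chain, "CB", bpos, dom, hydrophobic=True)
                    special.append(bi)
            elif dom == "thigh":
                # extension marker (acidic-sidechain analog) at the genu
                d_ax = centers["calf-1"] - c
                d_ax /= np.linalg.norm(d_ax)
                n_out = _genu_normal(centers, "thigh")
                gpos = c + cfg.genu_stalk * d_ax + cfg.genu_offset * n_out
                special.append(add_bead(chain, "CG", gpos, dom))
            elif dom == "calf-1":
                # genu-ion analog facing the thigh marker
                d_ax = centers["thigh"] - c
                d_ax /= np.linalg.norm(d_ax)
                n_out = _genu_normal(centers, "calf-1")
                gpos = c + cfg.genu_stalk * d_ax + cfg.genu_offset * n_out
                special.append(add_bead(chain, "ION", gpos, dom))
            n_shell = cfg.beads_per_domain - len(special)
            shell = pts[:n_shell] if n_shell <= 12 else np.vstack([pts, extra])
            for p in shell[:n_shell]:
                add_bead(chain, "CA", c + p, dom)

    xyz = np.vstack(xyz_l)
    n = len(xyz)
    serial = np.arange(1, n + 1, dtype=np.int64)
    donor_link = np.full(n, -1, dtype=np.int64)
    for i, dp in enumerate(link_l):
        if dp is not None:
            donor_link[i] = serial[dp]

    # residue numbering: 1 residue per bead, numbered per chain in backbone
    # order (PSI..betaTD for chain B), so the shipped DomainMap resolves
    resid = np.zeros(n, dtype=np.int64)
    dmap_ranges = {}
    bpd = cfg.beads_per_domain
    order_by_chain = {"A": CHAIN_A, "B": ["PSI", "hybrid", "betaA", "EGF1",
                                         "EGF2", "EGF3", "EGF4", "betaTD"]}
    rows_by_domain = {}
    dom_arr = np.array(domain_l, dtype=object)
    chain_arr = np.array(chain_l, dtype=object)
    for chain, order in order_by_chain.items():
        for di, dom in enumerate(order):
            rows = np.flatnonzero((dom_arr == dom) & (chain_arr == chain))
            rows_by_domain[dom] = rows
            start = di * bpd + 1
            resid[rows] = start + np.arange(len(rows))
            dmap_ranges[(chain, dom)] = [(start, start + bpd - 1)]

    model = AtomicModel(
        serial=serial,
        name=np.array(names_l, dtype=object),
        resname=np.array(["BEA"] * n, dtype=object),
        resid=resid,
        chain=chain_arr,
        xyz=xyz,
        radius=np.array(radius_l, dtype=float),
        role=np.array(role_l, dtype=object),
        donor_link=donor_link,
        hydrophobic=np.array(phob_l, dtype=bool),
        element=np.array(["H" if r == "hydrogen" else "BEAD" for r in role_l],
                         dtype=object),
    )
    model.validate()
    _check_overlap(centers, cfg)

    topo = _build_topology(model, cfg, centers, rows_by_domain, pin_registry)
    for (i, j), cls, eps in _contact_list(model, cfg, rows_by_domain):
        rest = float(np.linalg.norm(xyz[i] - xyz[j]))
        contact_rows.append((i, j, rest, eps, cls))
    topo = _attach_contacts(topo, contact_rows, cfg)
    topo.validate(n)

    dmap = DomainMap(ranges=dmap_ranges, composites={
        "headpiece": [("A", 1, 2 * bpd), ("B", 1, 4 * bpd)],
        "tailpiece": [("A", 2 * bpd + 1, 4 * bpd), ("B", 4 * bpd + 1, 8 * bpd)],
        "pull_betaA": [("B", 2 * bpd + 1, 3 * bpd)],
        "constrain_betaTD": [("B", 7 * bpd + 1, 8 * bpd)],
    })
    return model, topo, dmap


def _genu_normal(centers: dict, dom: str) -> np.ndarray:
    """In-plane normal at the α-genu pointing to the elbow's outer side."""
    prop, thigh, c1 = (centers["beta-propeller"], centers["thigh"],
                       centers["calf-1"])
    axis = c1 - thigh if dom == "thigh" else thigh - c1
    axis = axis / np.linalg.norm(axis)
    apex = thigh - 0.5 * (prop + c1)   # outward direction of the elbow
    n_out = apex - (apex @ axis) * axis
    return n_out / np.linalg.norm(n_out)


def _check_overlap(centers: dict, cfg: CgConfig) -> None:
    names = list(centers)
    adjacent = {frozenset(p) for p in BACKBONE}
    adjacent |= {frozenset(("hybrid", "betaTD")), frozenset(("hybrid", "EGF4"))}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = float(np.linalg.norm(centers[a] - centers[b]))
            if frozenset((a, b)) in adjacent:
                continue
            if d < cfg.min_center_separation:
                raise ValueError(
                    f"domains {a!r} and {b!r} overlap ({d:.1f} Å apart; "
                    f"minimum {cfg.min_center_separation} Å)")


def _build_topology(model, cfg, centers, rows_by_domain,
                    pin_registry) -> CgTopology:
    springs, rest, ks, tether = [], [], [], []
    xyz = model.xyz
    # rigid-ish domains: all bead pairs within each domain
    for dom, rows in rows_by_domain.items():
        for a in range(len(rows)):
            for b in range(a + 1, len(rows)):
                i, j = int(rows[a]), int(rows[b])
                springs.append((i, j))
                rest.append(float(np.linalg.norm(xyz[i] - xyz[j])))
                ks.append(cfg.k_intra)
                tether.append(False)
    # pinned joints: pair up the coincident pin beads (zero-rest springs
    # are isotropically stiff, so each joint bends freely about the pin
    # axis but resists twist and rocking)
    for key, beads in pin_registry.items():
        if len(beads) != 2:
            raise ValueError(f"pin pairing failed for joint {key}")
        springs.append((int(beads[0]), int(beads[1])))
        rest.append(0.0)
        ks.append(cfg.k_pin)
        tether.append(False)
    # leg-leg zip springs (closed legs): nearest bead pair of each coupled
    # domain pair, at the built distance.  The lower-leg pairs keep the
    # same separation in the bent and extended states, so they are plain
    # springs; the thigh-EGF1 pair comes closer on extension and is a
    # stretch-only tether.
    for da, db, teth_flag in (("thigh", "EGF1", True),
                              ("calf-1", "EGF2", False),
                              ("calf-1", "EGF3", False),
                              ("calf-1", "EGF4", False),
                              ("calf-2", "EGF3", False),
                              ("calf-2", "EGF4", False)):
        ra, rb = rows_by_domain[da], rows_by_domain[db]
        dmat = np.linalg.norm(xyz[ra][:, None, :] - xyz[rb][None, :, :], axis=2)
        a, b = np.unravel_index(np.argmin(dmat), dmat.shape)
        springs.append((int(ra[a]), int(rb[b])))
        rest.append(float(dmat[a, b]))
        ks.append(cfg.k_zip)
        tether.append(teth_flag)
    # remaining links: the two nearest cross-domain bead pairs
    pinned_set = {frozenset(p) for p in PINNED}
    for da, db in BACKBONE:
        if frozenset((da, db)) in pinned_set:
            continue
        ra, rb = rows_by_domain[da], rows_by_domain[db]
        d = np.linalg.norm(xyz[ra][:, None, :] - xyz[rb][None, :, :], axis=2)
        flat = np.argsort(d, axis=None)
        used_a, used_b = set(), set()
        picked = 0
        for f in flat:
            a, b = np.unravel_index(f, d.shape)
            if a in used_a or b in used_b:
                continue
            used_a.add(a)
            used_b.add(b)
            i, j = int(ra[a]), int(rb[b])
            springs.append((i, j))
            rest.append(float(d[a, b]))
            ks.append(cfg.k_link)
            tether.append(False)
            picked += 1
            if picked == 2:
                break
    # angle equilibria from the as-built bead-mean centers (these differ
    # from the design centers wherever a domain carries interface beads)
    bead_centers = {dom: xyz[rows].mean(axis=0)
                    for dom, rows in rows_by_domain.items()}
    # twist restraints: one dihedral per backbone link, built from the two
    # nearest (link) beads plus the most off-axis flank bead of each domain
    dihedrals, phi0s = [], []
    pinned_set2 = {frozenset(p) for p in PINNED}
    unpinned_intra = [p for p in BACKBONE
                      if p not in (("beta-propeller", "betaA"),
                                   ("calf-2", "betaTD"))
                      and frozenset(p) not in pinned_set2]
    for da, db in unpinned_intra:
        ra, rb = rows_by_domain[da], rows_by_domain[db]
        ca, cb = xyz[ra].mean(axis=0), xyz[rb].mean(axis=0)
        axis = cb - ca
        axis = axis / np.linalg.norm(axis)
        la = ra[np.argmin(np.linalg.norm(xyz[ra] - cb, axis=1))]
        lb = rb[np.argmin(np.linalg.norm(xyz[rb] - ca, axis=1))]
        def _flanks(rows, center, link_bead, n_fl=1):
            rows = rows[rows != link_bead]
            rel = xyz[rows] - center
            perp = rel - np.outer(rel @ axis, axis)
            best = np.argsort(-np.linalg.norm(perp, axis=1))
            return rows[best[:n_fl]]
        for fa, fb in zip(_flanks(ra, ca, la), _flanks(rb, cb, lb)):
            quad = (int(fa), int(la), int(lb), int(fb))
            phi = _dihedral_angle(xyz[quad[0]], xyz[quad[1]], xyz[quad[2]],
                                  xyz[quad[3]])
            dihedrals.append(quad)
            phi0s.append(phi)
    # chain-planarity restraints on consecutive domain-center quadruplets
    order = {d: i for i, d in enumerate(CHAIN_A + CHAIN_B)}
    bead_centers_arr = np.array([xyz[rows_by_domain[d]].mean(axis=0)
                                 for d in CHAIN_A + CHAIN_B])
    chain_b_order = ["betaA", "hybrid", "PSI", "EGF1", "EGF2", "EGF3",
                     "EGF4", "betaTD"]
    candidates = [tuple(CHAIN_A)]
    candidates += [tuple(chain_b_order[w:w + 4])
                   for w in range(len(chain_b_order) - 3)]
    # cross quads anchoring the folded arm and head azimuth to the leg;
    # a quad only acts where its interior angles are well bent, so the
    # straight leg segments contribute none
    candidates += [("betaA", "hybrid", "EGF4", "betaTD"),
                   ("PSI", "hybrid", "betaTD", "EGF4"),
                   ("EGF1", "EGF2", "betaTD", "hybrid"),
                   ("betaA", "hybrid", "EGF1", "EGF2")]
    cquads, cphi0 = [], []
    for names in candidates:
        quad = [order[nm] for nm in names]
        pts = [bead_centers_arr[q] for q in quad]
        a1 = _angle_between(pts[0], pts[1], pts[2])
        a2 = _angle_between(pts[1], pts[2], pts[3])
        lo, hi = np.radians(20.0), np.radians(160.0)
        if not (lo <= a1 <= hi and lo <= a2 <= hi):
            continue
        cquads.append(quad)
        cphi0.append(_dihedral_angle(*pts))
    angles = []
    for da, dv, db, kind in ANGLE_TERMS:
        theta0 = _angle_between(bead_centers[da], bead_centers[dv],
                                bead_centers[db])
        angles.append((da, dv, db, kind, theta0, np.pi))
    domain_order = CHAIN_A + CHAIN_B
    return CgTopology(
        domains={d: np.asarray(r, dtype=int) for d, r in rows_by_domain.items()},
        domain_order=domain_order,
        springs=np.array(springs, dtype=int),
        spring_rest=np.array(rest, dtype=float),
        spring_k=np.array(ks, dtype=float),
        spring_tether=np.array(tether, dtype=bool),
        angles=angles,
        contacts=np.empty((0, 2), dtype=int),
        contact_rest=np.empty(0), contact_break=np.empty(0),
        contact_k=np.empty(0), contact_eps=np.empty(0), contact_class=[],
        dihedrals=np.array(dihedrals, dtype=int),
        dihedral_phi0=np.array(phi0s, dtype=float),
        center_dihedrals=np.array(cquads, dtype=int),
        center_dihedral_phi0=np.array(cphi0, dtype=float),
    )


def _contact_list(model, cfg, rows_by_domain):
    """Breakable-contact bead pairs: polar, hydrophobic, and the genu marker."""
    name = model.name.astype(str)
    out = []
    donors = [i for i in rows_by_domain["hybrid"] if name[i] == "ND"]
    accept = [i for i in rows_by_domain["betaTD"] if name[i] == "OA"]
    for d, a in zip(sorted(donors), sorted(accept)):
        out.append(((int(d), int(a)), "polar", cfg.eps_polar))
    ph_h = [i for i in rows_by_domain["hybrid"] if name[i] == "CB"]
    ph_e = [i for i in rows_by_domain["EGF4"] if name[i] == "CB"]
    for p, q in zip(sorted(ph_h), sorted(ph_e)):
        out.append(((int(p), int(q)), "hydrophobic", cfg.eps_hydrophobic))
    return out


def _attach_contacts(topo: CgTopology, contact_rows, cfg: CgConfig) -> CgTopology:
    if not contact_rows:
        return topo
    pairs = np.array([(i, j) for i, j, *_ in contact_rows], dtype=int)
    rest = np.array([r for _, _, r, _, _ in contact_rows], dtype=float)
    eps = np.array([e for _, _, _, e, _ in contact_rows], dtype=float)
    cls = [c for *_, c in contact_rows]
    width = cfg.contact_break - cfg.contact_rest
    k = 2.0 * eps / width ** 2
    brk = rest + width
    return replace(topo, contacts=pairs, contact_rest=rest, contact_break=brk,
                   contact_k=k, contact_eps=eps, contact_class=cls)


# ---------------------------------------------------------------------------
# forces and energies
# ---------------------------------------------------------------------------


def _angle_rows(topo: CgTopology):
    order = {d: i for i, d in enumerate(topo.domain_order)}
    return [(order[da], order[dv], order[db], kind, th0, the)
            for da, dv, db, kind, th0, the in topo.angles]


def _center_matrix(topo: CgTopology, n_atoms: int) -> np.ndarray:
    m = np.zeros((len(topo.domain_order), n_atoms))
    for i, dom in enumerate(topo.domain_order):
        rows = topo.domains[dom]
        m[i, rows] = 1.0 / len(rows)
    return m


def _dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (rad) of four points about the p1-p2 axis."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(m @ n2, n1 @ n2))


def _dihedral_energy_force(pos, quads, phi0, k_twist):
    """Harmonic twist restraints; analytic gradient per quadruplet."""
    f = np.zeros_like(pos)
    energy = 0.0
    for q in range(len(quads)):
        i, j, k, l = quads[q]
        b1 = pos[j] - pos[i]
        b2 = pos[k] - pos[j]
        b3 = pos[l] - pos[k]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        n1sq, n2sq = n1 @ n1, n2 @ n2
        nb2 = np.linalg.norm(b2)
        # no well-defined torque near collinearity; skip inside ~17 deg
        min1 = 0.04 * (b1 @ b1) * (nb2 * nb2)
        min2 = 0.04 * (b3 @ b3) * (nb2 * nb2)
        if n1sq < min1 or n2sq < min2:
            continue
        m = np.cross(n1, b2 / nb2)
        phi = np.arctan2(m @ n2, n1 @ n2)
        dphi = phi - phi0[q]
        # cosine form: torque bounded by k_twist, periodic in the twist
        energy += k_twist * (1.0 - np.cos(dphi))
        du = k_twist * np.sin(dphi)
        dphi_di = (nb2 / n1sq) * n1
        dphi_dl = -(nb2 / n2sq) * n2
        c12 = (b1 @ b2) / (nb2 * nb2)
        c32 = (b3 @ b2) / (nb2 * nb2)
        dphi_dj = -(1.0 + c12) * dphi_di + c32 * dphi_dl
        dphi_dk = -(dphi_di + dphi_dj + dphi_dl)
        f[i] -= du * dphi_di
        f[j] -= du * dphi_dj
        f[k] -= du * dphi_dk
        f[l] -= du * dphi_dl
    return energy, f


class _AngleTable:
    """Vectorized bending-angle terms over the domain-center array."""

    def __init__(self, angle_rows, knee_barrier: float, k_angle: float,
                 k_head: float = 200.0, knee_barrier_alpha: float | None = None):
        if knee_barrier_alpha is None:
            knee_barrier_alpha = knee_barrier
        self.ia = np.array([r[0] for r in angle_rows], dtype=int)
        self.iv = np.array([r[1] for r in angle_rows], dtype=int)
        self.ib = np.array([r[2] for r in angle_rows], dtype=int)
        self.double = np.array([r[3].startswith("double")
                                for r in angle_rows])
        self.th0 = np.array([r[4] for r in angle_rows], dtype=float)
        self.the = np.array([r[5] for r in angle_rows], dtype=float)
        self.norm = ((self.the - self.th0) / 2.0) ** 4
        self.kb = np.array([knee_barrier_alpha if r[3] == "double_a"
                            else knee_barrier for r in angle_rows])
        self.ka = np.array([k_head if r[3] == "soft" else k_angle
                            for r in angle_rows], dtype=float)

    def energy_force(self, centers: np.ndarray):
        u1 = centers[self.ia] - centers[self.iv]
        u2 = centers[self.ib] - centers[self.iv]
        n1 = np.sqrt(np.einsum("ij,ij->i", u1, u1))
        n2 = np.sqrt(np.einsum("ij,ij->i", u2, u2))
        h1 = u1 / n1[:, None]
        h2 = u2 / n2[:, None]
        cosang = np.clip(np.einsum("ij,ij->i", h1, h2), -1.0, 1.0)
        theta = np.arccos(cosang)
        sin_t = np.maximum(np.sqrt(1.0 - cosang ** 2), 1e-8)
        p, q = theta - self.th0, theta - self.the
        e_single = 0.5 * self.ka * p ** 2
        du_single = self.ka * p
        e_double = self.kb * (p * q) ** 2 / self.norm
        du_double = self.kb * 2.0 * p * q * (p + q) / self.norm
        energy = float(np.sum(np.where(self.double, e_double, e_single)))
        du = np.where(self.double, du_double, du_single)
        da = (cosang[:, None] * h1 - h2) / (n1 * sin_t)[:, None]
        db = (cosang[:, None] * h2 - h1) / (n2 * sin_t)[:, None]
        f = np.zeros_like(centers)
        np.add.at(f, self.ia, -du[:, None] * da)
        np.add.at(f, self.ib, -du[:, None] * db)
        np.add.at(f, self.iv, du[:, None] * (da + db))
        return energy, f


def _angle_energy_force(centers: np.ndarray, angle_rows, knee_barrier: float,
                        k_angle: float):
    """Energy and per-center forces of all bending-angle terms."""
    return _AngleTable(angle_rows, knee_barrier, k_angle).energy_force(centers)


class _PairTable:
    """Fused springs + truncated contacts with a precomputed incidence map."""

    def __init__(self, topo: CgTopology, n_atoms: int):
        pairs = np.vstack([topo.springs, topo.contacts]).astype(int)
        self.i = pairs[:, 0]
        self.j = pairs[:, 1]
        self.rest = np.concatenate([topo.spring_rest, topo.contact_rest])
        self.k = np.concatenate([topo.spring_k, topo.contact_k])
        self.brk = np.concatenate([np.full(len(topo.springs), np.inf),
                                   topo.contact_break])
        st = (topo.spring_tether if topo.spring_tether is not None
              else np.zeros(len(topo.springs), dtype=bool))
        self.tether = np.concatenate([st, np.zeros(len(topo.contacts),
                                                   dtype=bool)])
        m = len(pairs)
        self.b = np.zeros((n_atoms, m))
        self.b[self.i, np.arange(m)] = 1.0
        self.b[self.j, np.arange(m)] = -1.0

    def forces(self, pos: np.ndarray) -> np.ndarray:
        d = pos[self.j] - pos[self.i]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        coef = np.where(r < self.brk, self.k * (r - self.rest), 0.0)
        coef /= np.maximum(r, 1e-12)
        return self.b @ (coef[:, None] * d)


@njit(fastmath=False)
def _dihedral_grads(p0, p1, p2, p3, phi0, kt):
    """(du·dphi/dr) for the four points; zeros near collinearity."""
    out = np.zeros((4, 3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq = n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2
    n2sq = n2[0] ** 2 + n2[1] ** 2 + n2[2] ** 2
    nb2sq = b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2
    b1sq = b1[0] ** 2 + b1[1] ** 2 + b1[2] ** 2
    b3sq = b3[0] ** 2 + b3[1] ** 2 + b3[2] ** 2
    if n1sq < 0.04 * b1sq * nb2sq or n2sq < 0.04 * b3sq * nb2sq:
        return out
    nb2 = np.sqrt(nb2sq)
    mvec = np.cross(n1, b2 / nb2)
    phi = np.arctan2(mvec @ n2, n1 @ n2)
    du = kt * np.sin(phi - phi0)
    g0 = (nb2 / n1sq) * n1
    g3 = -(nb2 / n2sq) * n2
    c12 = (b1 @ b2) / nb2sq
    c32 = (b3 @ b2) / nb2sq
    g1 = -(1.0 + c12) * g0 + c32 * g3
    g2 = -(g0 + g1 + g3)
    for c in range(3):
        out[0, c] = du * g0[c]
        out[1, c] = du * g1[c]
        out[2, c] = du * g2[c]
        out[3, c] = du * g3[c]
    return out


@njit(fastmath=False)
def _force_kernel(pos, pi, pj, rest, kk, brk, teth, dom, dom_count,
                  ia, iv, ib, is_double, th0, the, well_norm, kb, ka,
                  quads, phi0, k_twist, cquads, cphi0, k_plane):
    """Bonded + contact + bending forces in one compiled pass.

    ``dom`` maps each bead to its domain index; angle terms act on domain
    centers with the gradient distributed uniformly over each domain's
    beads.
    """
    n = pos.shape[0]
    f = np.zeros((n, 3))
    for e in range(pi.shape[0]):
        i, j = pi[e], pj[e]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < brk[e] and r > 1e-12 and not (teth[e] and r < rest[e]):
            c = kk[e] * (r - rest[e]) / r
            f[i, 0] += c * dx
            f[i, 1] += c * dy
            f[i, 2] += c * dz
            f[j, 0] -= c * dx
            f[j, 1] -= c * dy
            f[j, 2] -= c * dz
    nd = dom_count.shape[0]
    centers = np.zeros((nd, 3))
    for b in range(n):
        d = dom[b]
        centers[d, 0] += pos[b, 0]
        centers[d, 1] += pos[b, 1]
        centers[d, 2] += pos[b, 2]
    for d in range(nd):
        centers[d, 0] /= dom_count[d]
        centers[d, 1] /= dom_count[d]
        centers[d, 2] /= dom_count[d]
    fcent = np.zeros((nd, 3))
    for a in range(ia.shape[0]):
        A, V, B = ia[a], iv[a], ib[a]
        u1 = centers[A] - centers[V]
        u2 = centers[B] - centers[V]
        n1 = np.sqrt(u1[0] ** 2 + u1[1] ** 2 + u1[2] ** 2)
        n2 = np.sqrt(u2[0] ** 2 + u2[1] ** 2 + u2[2] ** 2)
        h1 = u1 / n1
        h2 = u2 / n2
        cosang = h1[0] * h2[0] + h1[1] * h2[1] + h1[2] * h2[2]
        if cosang > 1.0:
            cosang = 1.0
        elif cosang < -1.0:
            cosang = -1.0
        theta = np.arccos(cosang)
        sin_t = np.sqrt(1.0 - cosang * cosang)
        if sin_t < 1e-8:
            sin_t = 1e-8
        p = theta - th0[a]
        q = theta - the[a]
        if is_double[a]:
            du = kb[a] * 2.0 * p * q * (p + q) / well_norm[a]
        else:
            du = ka[a] * p
        da = (cosang * h1 - h2) / (n1 * sin_t)
        db = (cosang * h2 - h1) / (n2 * sin_t)
        for c in range(3):
            fcent[A, c] -= du * da[c]
            fcent[B, c] -= du * db[c]
            fcent[V, c] += du * (da[c] + db[c])
    # chain-planarity restraints on center quadruplets
    for q in range(cquads.shape[0]):
        g = _dihedral_grads(centers[cquads[q, 0]], centers[cquads[q, 1]],
                            centers[cquads[q, 2]], centers[cquads[q, 3]],
                            cphi0[q], k_plane)
        for a in range(4):
            for c in range(3):
                fcent[cquads[q, a], c] -= g[a, c]
    for b in range(n):
        d = dom[b]
        w = 1.0 / dom_count[d]
        f[b, 0] += fcent[d, 0] * w
        f[b, 1] += fcent[d, 1] * w
        f[b, 2] += fcent[d, 2] * w
    # twist (dihedral) restraints on the backbone links
    for q in range(quads.shape[0]):
        g = _dihedral_grads(pos[quads[q, 0]], pos[quads[q, 1]],
                            pos[quads[q, 2]], pos[quads[q, 3]],
                            phi0[q], k_twist)
        for a in range(4):
            for c in range(3):
                f[quads[q, a], c] -= g[a, c]
    return f


def _pair_forces(pos, pairs, rest, k, brk=None, tether=None):
    """Harmonic (optionally truncated) pair forces; returns (energy, forces)."""
    f = np.zeros_like(pos)
    if len(pairs) == 0:
        return 0.0, f
    d = pos[pairs[:, 1]] - pos[pairs[:, 0]]
    r = np.sqrt(np.einsum("ij,ij->i", d, d))
    active = np.ones(len(r), dtype=bool) if brk is None else r < brk
    if tether is not None:
        active &= ~(tether & (r < rest))
    stretch = np.where(active, r - rest, 0.0)
    energy = float(np.sum(0.5 * k * stretch ** 2))
    if brk is not None:
        # well depth offset keeps U continuous (0) at the break radius
        depth = 0.5 * k * (brk - rest) ** 2
        energy -= float(np.sum(depth[active]))
    fmag = (k * stretch / np.maximum(r, 1e-12))[:, None] * d
    n = len(pos)
    for c in range(3):
        f[:, c] = (np.bincount(pairs[:, 0], weights=fmag[:, c], minlength=n)
                   - np.bincount(pairs[:, 1], weights=fmag[:, c], minlength=n))
    return energy, f


def potential_energy(pos: np.ndarray, topo: CgTopology,
                     cfg: CgConfig = CgConfig()) -> float:
    """Total bonded + contact potential energy (pN·Å) of one frame."""
    e_s, _ = _pair_forces(pos, topo.springs, topo.spring_rest, topo.spring_k,
                          tether=topo.spring_tether)
    e_c, _ = _pair_forces(pos, topo.contacts, topo.contact_rest,
                          topo.contact_k, brk=topo.contact_break)
    cmat = _center_matrix(topo, len(pos))
    e_a, _ = _AngleTable(_angle_rows(topo), cfg.knee_barrier, cfg.k_angle,
                         cfg.k_head_angle,
                         cfg.knee_barrier_alpha).energy_force(cmat @ pos)
    e_d = 0.0
    if topo.dihedrals is not None and len(topo.dihedrals):
        e_d, _ = _dihedral_energy_force(pos, np.asarray(topo.dihedrals),
                                        np.asarray(topo.dihedral_phi0),
                                        cfg.k_twist)
    if topo.center_dihedrals is not None and len(topo.center_dihedrals):
        e_cd, _ = _dihedral_energy_force(cmat @ pos,
                                         np.asarray(topo.center_dihedrals),
                                         np.asarray(topo.center_dihedral_phi0),
                                         cfg.k_plane)
        e_d += e_cd
    return e_s + e_c + e_a + e_d


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def run_dynamics(model: AtomicModel, topo: CgTopology,
                 protocol: PullingProtocol, params: SimParams,
                 cfg: CgConfig = CgConfig(),
                 initial_coords: np.ndarray | None = None):
    """Overdamped Langevin (Euler–Maruyama) run under a pulling protocol.

    Per bead and step: dx = (F/γ)·dt + sqrt(2·kB·T·dt/γ)·ξ.  The pulling
    force acts on the pull-selection COM (distributed equally over the
    pulled beads) along the direction policy's unit vector; the
    constraint COM is tethered to its starting position by a harmonic
    spring.  Returns ``(Trajectory, force_record)`` where the force
    record is a DataFrame with one row per saved frame: time_ns, fx, fy,
    fz (pN), spring force (pN), spring coordinate x (Å), pull COM and
    constraint COM.

    Same seed + same inputs reproduce the trajectory bit for bit.
    """
    pos = np.array(initial_coords if initial_coords is not None else model.xyz,
                   dtype=float)
    n = len(pos)
    dt, gamma = params.dt, params.gamma
    # Euler stability bound on the stiffest per-bead coupling
    k_eff = (cfg.k_intra * (cfg.beads_per_domain - 1)
             + max(cfg.k_link, cfg.k_pin)
             + (float(topo.contact_k.max()) if len(topo.contact_k) else 0.0)
             + protocol.spring_k)
    if len(protocol.constraint_serials):
        k_eff += protocol.constraint_k / len(protocol.constraint_serials)
    if dt >= 2.0 * gamma / k_eff:
        raise ValueError(
            f"time step {dt} ns unstable: require dt < 2*gamma/k_max = "
            f"{2.0 * gamma / k_eff:.4g} ns")

    pull_idx = (model.index_of(np.asarray(protocol.pull_serials, dtype=np.int64))
                if len(protocol.pull_serials) else np.empty(0, dtype=int))
    con_idx = (model.index_of(np.asarray(protocol.constraint_serials,
                                         dtype=np.int64))
               if len(protocol.constraint_serials) else np.empty(0, dtype=int))

    anchor = pos[con_idx].mean(axis=0) if len(con_idx) else None
    pull_com0 = pos[pull_idx].mean(axis=0) if len(pull_idx) else None
    if protocol.mode != "free" or (len(pull_idx) and len(con_idx)):
        if len(con_idx) and len(pull_idx):
            u0 = pull_com0 - anchor
            u0 = u0 / np.linalg.norm(u0)
        else:
            u0 = np.array([1.0, 0.0, 0.0])
    else:
        u0 = np.array([1.0, 0.0, 0.0])

    angle_table = _AngleTable(_angle_rows(topo), cfg.knee_barrier, cfg.k_angle,
                              cfg.k_head_angle, cfg.knee_barrier_alpha)
    pair_table = _PairTable(topo, n)
    if topo.dihedrals is not None and len(topo.dihedrals):
        dihedral_quads = np.asarray(topo.dihedrals, dtype=np.int64)
        dihedral_phi0 = np.asarray(topo.dihedral_phi0, dtype=float)
    else:
        dihedral_quads = np.empty((0, 4), dtype=np.int64)
        dihedral_phi0 = np.empty(0, dtype=float)
    if topo.center_dihedrals is not None and len(topo.center_dihedrals):
        center_quads = np.asarray(topo.center_dihedrals, dtype=np.int64)
        center_phi0 = np.asarray(topo.center_dihedral_phi0, dtype=float)
    else:
        center_quads = np.empty((0, 4), dtype=np.int64)
        center_phi0 = np.empty(0, dtype=float)
    dom = np.zeros(n, dtype=np.int64)
    dom_count = np.zeros(len(topo.domain_order), dtype=np.int64)
    for di, dname in enumerate(topo.domain_order):
        rows = topo.domains[dname]
        dom[rows] = di
        dom_count[di] = len(rows)
    noise_amp = np.sqrt(2.0 * kbt(params.temperature) * dt / gamma)
    rng = np.random.default_rng(params.seed)
    n_steps = int(round(params.duration / dt))

    times, frames, records = [], [], []

    def pulling(step_pos, t):
        """(force vector on pull COM, scalar spring force, coordinate x)."""
        if protocol.mode == "free" or not len(pull_idx):
            return np.zeros(3), 0.0, 0.0
        pcom = step_pos[pull_idx].mean(axis=0)
        if protocol.direction == "tracking" and len(con_idx):
            u = pcom - step_pos[con_idx].mean(axis=0)
            u = u / np.linalg.norm(u)
        else:
            u = u0
        x = float((pcom - pull_com0) @ u)
        if protocol.mode == "constant-velocity":
            fmag = protocol.spring_k * (protocol.speed * t - x)
        else:
            fmag = protocol.force
        return fmag * u, fmag, x

    def record(t, step_pos):
        fvec, fmag, x = pulling(step_pos, t)
        pcom = step_pos[pull_idx].mean(axis=0) if len(pull_idx) else np.zeros(3)
        ccom = step_pos[con_idx].mean(axis=0) if len(con_idx) else np.zeros(3)
        times.append(t)
        frames.append(step_pos.copy())
        records.append((t, fvec[0], fvec[1], fvec[2], fmag, x,
                        pcom[0], pcom[1], pcom[2], ccom[0], ccom[1], ccom[2]))

    record(0.0, pos)
    for step in range(1, n_steps + 1):
        t_prev = (step - 1) * dt
        f = _force_kernel(pos, pair_table.i, pair_table.j, pair_table.rest,
                          pair_table.k, pair_table.brk, pair_table.tether,
                          dom, dom_count,
                          angle_table.ia, angle_table.iv, angle_table.ib,
                          angle_table.double, angle_table.th0,
                          angle_table.the, angle_table.norm,
                          angle_table.kb, angle_table.ka,
                          dihedral_quads, dihedral_phi0, cfg.k_twist,
                          center_quads, center_phi0, cfg.k_plane)
        if len(con_idx):
            ccom = pos[con_idx].mean(axis=0)
            f[con_idx] += (-protocol.constraint_k * (ccom - anchor)
                           / len(con_idx))
        fvec, _, _ = pulling(pos, t_prev)
        if len(pull_idx):
            f[pull_idx] += fvec / len(pull_idx)
        disp = f * (dt / gamma)
        if params.temperature > 0:
            disp = disp + noise_amp * rng.standard_normal((n, 3))
        step_max = float(np.abs(disp).max())
        if step_max > 5.0:
            raise SimulationUnstable(
                f"step {step} (t = {step * dt:.3f} ns): max per-bead "
                f"displacement {step_max:.2f} Å exceeds the 5 Å guard")
        pos = pos + disp
        if step % params.save_stride == 0:
            record(step * dt, pos)

    traj = Trajectory(times=np.array(times), coords=np.array(frames),
                      topology=model)
    rec = pd.DataFrame(records, columns=[
        "time_ns", "fx_pN", "fy_pN", "fz_pN", "spring_force_pN",
        "spring_coord_A", "pull_com_x", "pull_com_y", "pull_com_z",
        "constraint_com_x", "constraint_com_y", "constraint_com_z"])
    return traj, rec


def snapshot_restart(traj: Trajectory, frame_index: int) -> np.ndarray:
    """Coordinates of one saved frame, as the starting state of a new run.

    Pass the result as ``initial_coords`` to :func:`run_dynamics` with a
    new protocol (typically ``free``) to reproduce relaxation experiments
    from partially- or fully-extended snapshots.
    """
    if not -traj.n_frames <= frame_index < traj.n_frames:
        raise IndexError(
            f"frame {frame_index} out of range (trajectory has "
            f"{traj.n_frames} frames)")
    return np.array(traj.coords[frame_index], dtype=float)
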