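"""Parametric generation of ideal coiled-coil barrels, three-helix connector
units and fragment libraries.

All backbones are built from ideal internal coordinates (bond lengths, bond
angles and torsions) by sequential NeRF placement, so every fixture satisfies
peptide bond-length invariants by construction.  Helices are straight (the
superhelical twist of real coiled coils is absorbed into the per-residue
helical twist, which is solved numerically so the heptad seam stays in
phase), arranged on a circle of radius R0 about the z axis with the a/d
interface seam spun to face the barrel lumen.  These fixtures emulate the
geometry of experimental barrel seeds closely enough to exercise
knobs-into-holes detection, lumen profiling, fragment search and scaffold
assembly without any structure downloads.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .geometry import (BackboneModel, Chain, HelixSegment, Residue, Transform,
                       helix_axis)
from .registers import REGISTER_CYCLE, HeptadSequence

__all__ = [
    "CrickParams",
    "FixtureSpec",
    "HTHGeometry",
    "make_barrel",
    "make_hth_unit",
    "make_loop_library",
    "make_connectable_entry",
    "build_ideal_helix",
    "close_gap_torsions",
]

# ideal backbone internal coordinates (angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.8
ANGLE_C_CA_CB = 110.5

ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

#: typical distance (A) from CA to the side-chain heavy-atom centroid, used to
#: place a pseudo side-chain atom so fixtures pack like all-atom models
SIDE_CHAIN_CENTROID_DIST = {
    "A": 1.53, "C": 2.1, "D": 2.5, "E": 3.0, "F": 3.4, "H": 3.0, "I": 2.5,
    "K": 3.4, "L": 2.6, "M": 2.9, "N": 2.5, "P": 1.9, "Q": 3.1, "R": 4.0,
    "S": 1.9, "T": 1.9, "V": 2.0, "W": 3.9, "Y": 3.8,
}


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement of atom D given reference atoms A-B-C, the C-D bond
    length, the B-C-D angle and the A-B-C-D torsion."""
    theta = np.deg2rad(angle_deg)
    phi = np.deg2rad(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(theta),
                        bond * np.sin(theta) * np.cos(phi),
                        bond * np.sin(theta) * np.sin(phi)])
    return c + bc * d_local[0] + m * d_local[1] + n * d_local[2]


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees (IUPAC convention: trans = 180)."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


class ChainBuilder:
    """Sequential NeRF backbone builder.

    Torsions are supplied per residue as (phi, psi); omega is fixed trans
    (180 deg).  O is placed from psi (O trans to the following N); CB is
    placed tetrahedrally for non-Gly residues.
    """

    def __init__(self, angle_n_ca_c: float = ANGLE_N_CA_C) -> None:
        # seed residue in an arbitrary frame
        self.angle_n_ca_c = angle_n_ca_c
        self.N = [np.array([0.0, 0.0, 0.0])]
        self.CA = [np.array([BOND_N_CA, 0.0, 0.0])]
        theta = np.deg2rad(angle_n_ca_c)
        self.C = [self.CA[0] + BOND_CA_C * np.array([-np.cos(theta), np.sin(theta), 0.0])]
        self.psis: list[float] = []
        self.phis: list[float] = [np.nan]

    def __len__(self) -> int:
        return len(self.N)

    def add_residue(self, psi_prev: float, phi: float, omega: float = 180.0) -> None:
        i = len(self.N) - 1
        n = _place_atom(self.N[i], self.CA[i], self.C[i], BOND_C_N,
                        ANGLE_CA_C_N, psi_prev)
        ca = _place_atom(self.CA[i], self.C[i], n, BOND_N_CA,
                         ANGLE_C_N_CA, omega)
        c = _place_atom(self.C[i], n, ca, BOND_CA_C, self.angle_n_ca_c, phi)
        self.N.append(n)
        self.CA.append(ca)
        self.C.append(c)
        self.psis.append(psi_prev)
        self.phis.append(phi)

    def next_backbone(self, psi_prev: float, phi: float):
        """Positions (N, CA, C) the next residue would take, without committing."""
        i = len(self.N) - 1
        n = _place_atom(self.N[i], self.CA[i], self.C[i], BOND_C_N,
                        ANGLE_CA_C_N, psi_prev)
        ca = _place_atom(self.CA[i], self.C[i], n, BOND_N_CA, ANGLE_C_N_CA, 180.0)
        c = _place_atom(self.C[i], n, ca, BOND_CA_C, self.angle_n_ca_c, phi)
        return n, ca, c

    def to_residues(self, sequence: str, psi_last: float = -47.0,
                    registers: list[str] | None = None,
                    start_number: int = 1) -> list[Residue]:
        n_res = len(self.N)
        assert len(sequence) == n_res
        psis = self.psis + [psi_last]
        out = []
        for i in range(n_res):
            name = ONE_TO_THREE[sequence[i]]
            res = Residue(start_number + i, name)
            res.atoms["N"] = self.N[i].copy()
            res.atoms["CA"] = self.CA[i].copy()
            res.atoms["C"] = self.C[i].copy()
            res.atoms["O"] = _place_atom(self.N[i], self.CA[i], self.C[i],
                                         BOND_C_O, ANGLE_CA_C_O, psis[i] + 180.0)
            if name != "GLY":
                cb = _place_atom(self.N[i], self.C[i], self.CA[i],
                                 BOND_CA_CB, ANGLE_C_CA_CB, 122.6)
                res.atoms["CB"] = cb
                # pseudo side-chain tip: extends the CA->CB direction so the
                # side-chain centroid lands at the residue-typical distance
                target = SIDE_CHAIN_CENTROID_DIST.get(sequence[i], BOND_CA_CB)
                if target > BOND_CA_CB + 0.05:
                    u = (cb - self.CA[i]) / BOND_CA_CB
                    res.atoms["CG"] = self.CA[i] + u * (2.0 * target - BOND_CA_CB)
            if registers is not None:
                res.register = registers[i]
            out.append(res)
        return out


# ---------------------------------------------------------------------------
# Helix twist/rise solving
# ---------------------------------------------------------------------------

def _helix_twist_rise(phi: float, psi: float, n_res: int = 40,
                      tau: float = ANGLE_N_CA_C):
    b = ChainBuilder(tau)
    for _ in range(n_res - 1):
        b.add_residue(psi, phi)
    ca = np.array(b.CA)
    centroids = np.array([ca[i:i + 4].mean(axis=0) for i in range(len(ca) - 3)])
    center = centroids.mean(axis=0)
    _, _, vt = np.linalg.svd(centroids - center)
    axis = vt[0]
    if np.dot(axis, centroids[-1] - centroids[0]) < 0:
        axis = -axis
    proj = (ca - center) @ axis
    rise = float(np.polyfit(np.arange(len(ca)), proj, 1)[0])
    # unwound angular positions about the axis
    perp = ca - center - np.outer(proj, axis)
    u = perp[0] / np.linalg.norm(perp[0])
    v = np.cross(axis, u)
    ang = np.unwrap(np.arctan2(perp @ v, perp @ u))
    twist = float(np.degrees(np.polyfit(np.arange(len(ca)), ang, 1)[0]))
    return abs(twist), rise


@functools.lru_cache(maxsize=32)
def solve_helix_torsions(residues_per_turn: float,
                         rise: float) -> tuple[float, float, float]:
    """Find (phi, psi, tau) giving the requested helical twist and rise.

    tau is the N-CA-C backbone angle, allowed to relax a few degrees from
    ideal (as it does in real helices) because twist and rise are strongly
    coupled at fixed bond angles.  Solved once per parameter pair by least
    squares and cached.  residues_per_turn = 3.5 keeps the heptad seam
    exactly in phase for straight-helix barrel fixtures.
    """
    target_twist = 360.0 / residues_per_turn

    def resid(x):
        t, r = _helix_twist_rise(x[0], x[1], tau=x[2])
        return [t - target_twist, 20.0 * (r - rise), 0.1 * (x[2] - ANGLE_N_CA_C)]

    sol = least_squares(resid, x0=[-60.0, -41.0, 108.0], diff_step=1e-3,
                        bounds=([-80.0, -65.0, 100.0], [-40.0, -20.0, 118.0]),
                        xtol=1e-12, ftol=1e-14, gtol=1e-14)
    return float(sol.x[0]), float(sol.x[1]), float(sol.x[2])


def build_ideal_helix(sequence: str, residues_per_turn: float = 3.5,
                      rise: float = 1.51,
                      registers: list[str] | None = None) -> list[Residue]:
    """Straight ideal helix, axis along +z (N at low z), centered at the origin."""
    phi, psi, tau = solve_helix_torsions(residues_per_turn, rise)
    b = ChainBuilder(tau)
    for _ in range(len(sequence) - 1):
        b.add_residue(psi, phi)
    residues = b.to_residues(sequence, psi_last=psi, registers=registers)
    model = BackboneModel([Chain("A", residues)],
                          [HelixSegment("A", 1, len(residues))])
    ax = helix_axis(model.helices[0], model)
    # rotate axis onto +z, center on origin
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(ax.direction, z)
    s = np.linalg.norm(v)
    c = float(np.dot(ax.direction, z))
    if s < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)
    mid = 0.5 * (ax.start_point + ax.end_point)
    t = Transform(R, -R @ mid)
    for r in residues:
        for a in r.atoms:
            r.atoms[a] = t.apply(r.atoms[a])
    return residues


# ---------------------------------------------------------------------------
# Barrel fixtures
# ---------------------------------------------------------------------------

#: canonical superhelical radii (A) by oligomer order for straight-helix fixtures
DEFAULT_RADII = {2: 4.9, 3: 6.3, 4: 6.8, 5: 7.0, 6: 8.5, 7: 9.5, 8: 11.0}


@dataclass
class CrickParams:
    """Geometry of an ideal barrel fixture.

    orientation is a per-helix tuple of +1 (up, N->C along +z) / -1 (down);
    interface_phase_deg spins each helix about its own axis relative to the
    'a/d seam inward' reference.
    """

    n: int
    radius: float | None = None          # superhelical radius R0 (A)
    pitch: float = np.inf                # superhelical pitch (A); inf = straight
    helix_radius: float = 2.26           # alpha-helix CA radius R1 (A), informational
    residues_per_turn: float = 3.5
    rise_per_residue: float = 1.51
    orientation: tuple[int, ...] = ()
    #: seam spin relative to 'a/d centroid dead inward'; the default offsets
    #: the seams so side chains interdigitate knobs-into-holes instead of
    #: colliding tip-to-tip (the analogue of the coiled-coil packing angle)
    interface_phase_deg: float = 25.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("oligomer order n must be >= 2")
        if self.radius is None:
            self.radius = DEFAULT_RADII.get(self.n, 1.55 * self.n)
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not self.orientation:
            self.orientation = (1,) * self.n
        if len(self.orientation) != self.n:
            raise ValueError("orientation list length must equal n")
        if any(o not in (-1, 1) for o in self.orientation):
            raise ValueError("orientations must be +1 (up) or -1 (down)")

    @classmethod
    def antiparallel(cls, n: int, **kw) -> "CrickParams":
        if n % 2:
            raise ValueError("alternating up/down needs even n")
        return cls(n=n, orientation=tuple(1 if k % 2 == 0 else -1
                                          for k in range(n)), **kw)


@dataclass
class FixtureSpec:
    """Reproducible fixture recipe: geometry + sequence + noise + seed."""

    params: CrickParams
    n_heptads: int = 4
    sequence: HeptadSequence | None = None
    noise_sd: float = 0.0
    seed: int = 0


def _default_barrel_sequence(n_heptads: int) -> HeptadSequence:
    # ALIA rule (the parallel-heptamer seed rule) over a neutral background
    residues = []
    for _ in range(n_heptads):
        residues.extend(list("ALEEIAQ"))  # g a b c d e f
    return HeptadSequence(residues, offset="g")


def _oriented_helix(template: list[Residue], spin_deg: float, up: bool,
                    tilt_deg: float = 0.0) -> list[Residue]:
    """Spin template helix about z, optionally flip down (pi about x), tilt
    about x (tangential lean used for superhelical pitch emulation)."""
    ops = [Transform.rotation_about_axis(np.zeros(3), np.array([0, 0, 1.0]),
                                         np.deg2rad(spin_deg))]
    if not up:
        ops.append(Transform.rotation_about_axis(np.zeros(3), np.array([1.0, 0, 0]),
                                                 np.pi))
    if tilt_deg:
        ops.append(Transform.rotation_about_axis(np.zeros(3), np.array([1.0, 0, 0]),
                                                 np.deg2rad(tilt_deg)))
    out = [r.copy() for r in template]
    for op in ops:
        for r in out:
            for a in r.atoms:
                r.atoms[a] = op.apply(r.atoms[a])
    return out


def _interface_spin(residues: list[Residue]) -> float:
    """Mean azimuth (deg) of a/d-position CB directions for an axis-aligned helix."""
    vecs = []
    for r in residues:
        if r.register in ("a", "d") and "CB" in r.atoms and "CA" in r.atoms:
            v = r.atoms["CB"] - r.atoms["CA"]
            vecs.append(v[:2] / np.linalg.norm(v[:2]))
    if not vecs:  # fall back to all CB
        for r in residues:
            if "CB" in r.atoms:
                v = r.atoms["CB"] - r.atoms["CA"]
                vecs.append(v[:2] / np.linalg.norm(v[:2]))
    m = np.mean(vecs, axis=0)
    return float(np.degrees(np.arctan2(m[1], m[0])))


def make_barrel(params: CrickParams, n_heptads: int = 4,
                sequence: HeptadSequence | None = None,
                noise_sd: float = 0.0, seed: int = 0) -> BackboneModel:
    """Ideal n-helix barrel: one chain per helix, CB included, helices annotated.

    Helices of 7*n_heptads residues stand on a circle of radius R0 with their
    a/d seams spun toward the axis; 'down' helices are flipped through a
    rotation of pi about a radial axis, so alternating orientation lists give
    antiparallel barrels.  All-parallel barrels are exactly Cn-symmetric.
    Gaussian coordinate noise (noise_sd, A) is reproducible from *seed*.
    """
    seq = sequence or _default_barrel_sequence(n_heptads)
    if len(seq) != 7 * n_heptads:
        raise ValueError("sequence length must be 7 * n_heptads")
    template = build_ideal_helix(str(seq), params.residues_per_turn,
                                 params.rise_per_residue, registers=list(seq.register))
    # spin the seam inward: after placing at azimuth theta the inward direction
    # is theta+180, so pre-spin the template seam onto +180 deg.
    seam = _interface_spin(template)
    base_spin = 180.0 - seam + params.interface_phase_deg
    tilt = 0.0
    if np.isfinite(params.pitch) and params.pitch != 0:
        tilt = np.degrees(np.arctan2(2 * np.pi * params.radius, abs(params.pitch)))
        tilt *= np.sign(params.pitch)
    rng = np.random.default_rng(seed)
    model = BackboneModel()
    from .geometry import _CHAIN_IDS
    for k in range(params.n):
        theta = 360.0 * k / params.n
        up = params.orientation[k] == 1
        helix = _oriented_helix(template, base_spin, up, tilt)
        rot = Transform.rotation_about_axis(np.zeros(3), np.array([0, 0, 1.0]),
                                            np.deg2rad(theta))
        offset = params.radius * np.array([np.cos(np.deg2rad(theta)),
                                           np.sin(np.deg2rad(theta)), 0.0])
        for r in helix:
            for a in r.atoms:
                xyz = rot.apply(r.atoms[a]) + offset
                if noise_sd > 0:
                    xyz = xyz + rng.normal(0.0, noise_sd, 3)
                r.atoms[a] = xyz
        cid = _CHAIN_IDS[k]
        model.chains.append(Chain(cid, helix))
        model.helices.append(HelixSegment(cid, 1, len(helix)))
    return model


def make_barrel_from_spec(spec: FixtureSpec) -> BackboneModel:
    return make_barrel(spec.params, spec.n_heptads, spec.sequence,
                       spec.noise_sd, spec.seed)


# ---------------------------------------------------------------------------
# Loop closure
# ---------------------------------------------------------------------------

def close_gap_torsions(prefix_residues: list[Residue], target_residues: list[Residue],
                       loop_sequence: str, seed: int = 0,
                       max_starts: int = 12, tol: float = 0.15,
                       avoid_coords: np.ndarray | None = None,
                       clearance: float = 2.7):
    """Find loop torsions connecting the end of *prefix* to the start of *target*.

    Builds ``len(loop_sequence)`` residues forward from the last residue of
    the prefix by NeRF and least-squares-fits the free torsions (psi of the
    last prefix residue, phi/psi of each loop residue, phi of the first
    target residue) so that the implied next residue lands on the target's
    first N/CA/C.  If *avoid_coords* is given, loop CA positions closer than
    *clearance* (A) to any of those coordinates add soft penalty residuals,
    steering the closure away from the rest of the structure.  Returns
    (loop_residues, max_coord_error).  Raises RuntimeError if no start
    converges below *tol* (A).
    """
    n_loop = len(loop_sequence)
    if n_loop < 1:
        raise ValueError("need at least one loop residue")
    anchor = prefix_residues[-1]
    tgt = np.array([target_residues[0].atoms[a] for a in ("N", "CA", "C")])
    avoid_tree = None
    if avoid_coords is not None and len(avoid_coords):
        from scipy.spatial import cKDTree
        avoid_tree = cKDTree(np.asarray(avoid_coords, float))

    def build(x):
        b = ChainBuilder()
        # re-seed builder at the anchor residue's frame
        b.N = [anchor.atoms["N"].copy()]
        b.CA = [anchor.atoms["CA"].copy()]
        b.C = [anchor.atoms["C"].copy()]
        psi_anchor = x[0]
        torsions = x[1:].reshape(n_loop + 1, 2)
        b.add_residue(psi_anchor, torsions[0][0])
        for i in range(1, n_loop):
            b.add_residue(torsions[i - 1][1], torsions[i][0])
        nxt = b.next_backbone(torsions[n_loop - 1][1], torsions[n_loop][0])
        return b, np.array(nxt)

    def resid(x):
        b, nxt = build(x)
        out = (nxt - tgt).ravel()
        if avoid_tree is not None:
            pts = np.concatenate([np.asarray(b.N[1:n_loop + 1]),
                                  np.asarray(b.CA[1:n_loop + 1]),
                                  np.asarray(b.C[1:n_loop + 1])])
            dmin, _ = avoid_tree.query(pts)
            out = np.concatenate([out, np.maximum(0.0, clearance - dmin)])
        return out

    rng = np.random.default_rng(seed)
    best = None
    for trial in range(max_starts):
        x0 = np.empty(1 + 2 * (n_loop + 1))
        x0[0] = -47.0 + rng.normal(0, 20)
        # bias loop starts away from the helical basin so closed turns read
        # as loops, not helix continuations
        x0[1::2] = rng.uniform(-150, 150, n_loop + 1)
        x0[2::2] = rng.uniform(-60, 170, n_loop + 1)
        sol = least_squares(resid, x0, xtol=1e-10, ftol=1e-10, max_nfev=250)
        err = float(np.max(np.abs(sol.fun[:9])))
        pen = float(np.max(sol.fun[9:], initial=0.0))
        key = (pen > 0.7, err + 0.1 * pen)
        if best is None or key < best[0]:
            best = (key, err, sol.x)
        if err < tol / 2 and pen < 0.7:
            break
    _, err, x = best
    if err > tol:
        raise RuntimeError(f"loop closure did not converge (max error {err:.2f} A)")
    b, _ = build(x)
    torsions = x[1:].reshape(n_loop + 1, 2)
    # materialise loop residues (skip the re-seeded anchor at index 0)
    psis = [x[0]] + [torsions[i][1] for i in range(n_loop)]
    residues = []
    for i in range(1, n_loop + 1):
        name = ONE_TO_THREE[loop_sequence[i - 1]]
        res = Residue(i, name)
        res.atoms["N"] = b.N[i].copy()
        res.atoms["CA"] = b.CA[i].copy()
        res.atoms["C"] = b.C[i].copy()
        res.atoms["O"] = _place_atom(b.N[i], b.CA[i], b.C[i], BOND_C_O,
                                     ANGLE_CA_C_O, psis[i] + 180.0)
        if name != "GLY":
            res.atoms["CB"] = _place_atom(b.N[i], b.C[i], b.CA[i], BOND_CA_CB,
                                          ANGLE_C_CA_CB, 122.6)
        residues.append(res)
    return residues, err


# ---------------------------------------------------------------------------
# Helix-turn-helix-turn-helix units
# ---------------------------------------------------------------------------

@dataclass
class HTHGeometry:
    """Placement parameters for a three-helix connector unit on an n-barrel."""

    n: int = 7
    inner_radius: float | None = None
    outer_offset: float = 10.0        # radial offset of buttressing helices (A)
    central_len: int = 25             # residues; ~38 A, spans the barrel height
    outer_len: int = 22
    turn_len: int = 5
    tilt_deg: float = 8.0             # tangential lean of outer helices
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inner_radius is None:
            self.inner_radius = DEFAULT_RADII.get(self.n, 1.55 * self.n)


_TURN_SEQ = "GSGSGSGSGS"


def make_hth_unit(handedness: str = "right",
                  geometry: HTHGeometry | None = None) -> BackboneModel:
    """Helix-turn-helix-turn-helix connector unit as a single chain.

    Chain order: buttressing helix (down, at azimuth -180/n deg), turn,
    central helix (up, at azimuth 0, radius R0 -- the helix pre-aligned onto
    one inner barrel helix), turn, buttressing helix (down, at +180/n deg).
    The two buttressing helices are congruent, so Cn-rotated copies of the
    unit overlap pairwise and can be reconciled during scaffold assembly.
    The left-handed unit is the mirror image (through the xz plane) of the
    right-handed one, emulating the opposite tertiary twist of lower-order
    coiled coils.
    """
    if handedness not in ("left", "right"):
        raise ValueError("handedness must be 'left' or 'right'")
    geo = geometry or HTHGeometry()
    r0 = geo.inner_radius
    half_ang = 180.0 / geo.n

    central_seq = _default_barrel_sequence((geo.central_len + 6) // 7)
    central_template = build_ideal_helix(str(central_seq)[:geo.central_len],
                                         registers=list(central_seq.register)[:geo.central_len])
    outer_seq = ("EALKA" * 6)[:geo.outer_len]
    outer_template = build_ideal_helix(outer_seq)

    def place(template, spin, up, tilt, azimuth, radius):
        helix = _oriented_helix(template, spin, up, tilt)
        rot = Transform.rotation_about_axis(np.zeros(3), np.array([0, 0, 1.0]),
                                            np.deg2rad(azimuth))
        off = radius * np.array([np.cos(np.deg2rad(azimuth)),
                                 np.sin(np.deg2rad(azimuth)), 0.0])
        for r in helix:
            for a in r.atoms:
                r.atoms[a] = rot.apply(r.atoms[a]) + off
        return helix

    seam_c = _interface_spin(central_template)
    seam_o = _interface_spin(outer_template)
    central = place(central_template, 180.0 - seam_c, True, 0.0, 0.0, r0)
    h1 = place(outer_template, 180.0 - seam_o, False, geo.tilt_deg,
               -half_ang, r0 + geo.outer_offset)
    h3 = place(outer_template, 180.0 - seam_o, False, geo.tilt_deg,
               +half_ang, r0 + geo.outer_offset)

    turn_seq_1 = _TURN_SEQ[:geo.turn_len]
    turn_seq_2 = _TURN_SEQ[:geo.turn_len]
    turn1, _ = close_gap_torsions(h1, central, turn_seq_1, seed=geo.seed)
    turn2, _ = close_gap_torsions(central, h3, turn_seq_2, seed=geo.seed + 1)

    chain = Chain("A")
    helices: list[HelixSegment] = []
    num = 1
    for block, is_helix in ((h1, True), (turn1, False), (central, True),
                            (turn2, False), (h3, True)):
        start = num
        for r in block:
            rr = r.copy()
            rr.number = num
            chain.residues.append(rr)
            num += 1
        if is_helix:
            helices.append(HelixSegment("A", start, num - 1))
    model = BackboneModel([chain], helices)

    if handedness == "left":
        mirror = np.diag([1.0, -1.0, 1.0])
        for r in model.chains[0].residues:
            for a in r.atoms:
                r.atoms[a] = mirror @ r.atoms[a]
    return model


# ---------------------------------------------------------------------------
# Fragment libraries
# ---------------------------------------------------------------------------

def make_loop_library(n_entries: int = 5, loop_lens=(2, 3, 4, 5, 6, 7),
                      seed: int = 1, helix_len: int = 12):
    """Synthetic helix-loop-helix fragment library, reproducible from *seed*.

    Each entry is one chain: an ideal helix, a loop of randomized (valid)
    torsions and a second helix continued by NeRF from the loop end, so
    geometries vary but bonds are ideal throughout.  Loop lengths cycle
    through *loop_lens*.
    """
    from .connectors import FragmentLibrary, LibraryEntry

    rng = np.random.default_rng(seed)
    phi_h, psi_h, tau_h = solve_helix_torsions(3.5, 1.51)
    entries = []
    for e in range(n_entries):
        loop_len = int(loop_lens[e % len(loop_lens)])
        b = ChainBuilder(tau_h)
        for _ in range(helix_len - 1):
            b.add_residue(psi_h, phi_h)
        for _ in range(loop_len):
            b.add_residue(float(rng.uniform(-60, 170)), float(rng.uniform(-150, -40)))
        for _ in range(helix_len):
            b.add_residue(psi_h, phi_h)
        seq = "A" * helix_len + "G" * loop_len + "A" * helix_len
        residues = b.to_residues(seq, psi_last=psi_h)
        model = BackboneModel([Chain("A", residues)],
                              [HelixSegment("A", 1, helix_len),
                               HelixSegment("A", helix_len + loop_len + 1,
                                            2 * helix_len + loop_len)])
        entries.append(LibraryEntry(f"frag_{e:03d}", model))
    return FragmentLibrary(entries)


def make_connectable_entry(barrel: BackboneModel, helix_i: HelixSegment,
                           helix_j: HelixSegment, loop_len: int = 5,
                           source_id: str = "bridge_000", seed: int = 0):
    """A helix-loop-helix library entry that bridges two helices of *barrel*.

    The entry copies the two helices and closes the gap with an ideal-geometry
    loop, emulating a database fragment that happens to match the query stubs
    exactly; searching the barrel's stub pair against a library containing
    this entry retrieves it at RMSD ~ 0 and its loop can be grafted back.
    """
    from .connectors import LibraryEntry

    res_i = [r.copy() for r in barrel.segment_residues(helix_i)]
    res_j = [r.copy() for r in barrel.segment_residues(helix_j)]
    skip = {(helix_i.chain_id, res_i[-1].number), (helix_j.chain_id, res_j[0].number)}
    gap_mid = 0.5 * (res_i[-1].atoms["C"] + res_j[0].atoms["N"])
    avoid = np.array([r.atoms[a] for cid, r in barrel.residues()
                      for a in ("N", "CA", "C", "O") if a in r.atoms
                      and (cid, r.number) not in skip
                      and np.linalg.norm(r.atoms["CA"] - gap_mid) < 20.0])
    loop, _ = close_gap_torsions(res_i, res_j, "G" * loop_len, seed=seed,
                                 avoid_coords=avoid)
    chain = Chain("A")
    num = 1
    for block in (res_i, loop, res_j):
        for r in block:
            rr = r.copy()
            rr.number = num
            chain.residues.append(rr)
            num += 1
    model = BackboneModel([chain],
                          [HelixSegment("A", 1, len(res_i)),
                           HelixSegment("A", len(res_i) + loop_len + 1, num - 1)])
    return LibraryEntry(source_id, model)
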