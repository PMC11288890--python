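"""Backbone geometry: structure I/O, superposition, helix detection and Cn symmetry.

The in-memory container is :class:`BackboneModel`, a light hierarchy of
chains and residues holding backbone (N, CA, C, O) and optionally CB /
side-chain coordinates in angstroms.  PDB reading and writing go through
``gemmi``; superposition uses the Kabsch algorithm via
``scipy.spatial.transform``.
"""

from __future__ import annotations

import copy as _copy
import string
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

__all__ = [
    "Transform",
    "Residue",
    "Chain",
    "HelixSegment",
    "HelixAxis",
    "BackboneModel",
    "read_pdb",
    "write_pdb",
    "kabsch_superpose",
    "backbone_rmsd",
    "detect_helices",
    "helix_axis",
    "termini_gap",
    "fit_cn_axis",
    "apply_cn",
    "middle_turn_mapping",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: C(i)-N(i+1) peptide-bond distance window used by model validation (angstrom)
PEPTIDE_BOND_RANGE = (1.2, 1.45)


class GeometryError(ValueError):
    """Raised on degenerate geometric input (too few points, collinear sets, ...)."""


@dataclass
class Transform:
    """Rigid-body transform: ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3):
            raise GeometryError("rotation must be 3x3")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise GeometryError("rotation must be proper (det = +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def rotation_about_axis(cls, point: np.ndarray, direction: np.ndarray,
                            angle: float) -> "Transform":
        """Rotation by *angle* (radians) about the line through *point* along *direction*."""
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        R = Rotation.from_rotvec(angle * d).as_matrix()
        p = np.asarray(point, dtype=float)
        return cls(R, p - R @ p)


@dataclass
class Residue:
    number: int
    name: str  # three-letter code
    atoms: dict[str, np.ndarray] = field(default_factory=dict)
    register: str | None = None  # optional heptad label (a-g), carried by fixtures

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C"))

    def copy(self) -> "Residue":
        return Residue(self.number, self.name,
                       {k: v.copy() for k, v in self.atoms.items()}, self.register)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


@dataclass
class HelixSegment:
    """A run of alpha-helical residues on one chain (inclusive residue numbers)."""

    chain_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class HelixAxis:
    start_point: np.ndarray
    end_point: np.ndarray
    direction: np.ndarray  # unit vector, N -> C


@dataclass
class BackboneModel:
    chains: list[Chain] = field(default_factory=list)
    helices: list[HelixSegment] = field(default_factory=list)

    # -- bookkeeping ------------------------------------------------------
    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def residues(self):
        for c in self.chains:
            for r in c.residues:
                yield c.chain_id, r

    def segment_residues(self, seg: HelixSegment) -> list[Residue]:
        ch = self.chain(seg.chain_id)
        return [r for r in ch.residues if seg.start <= r.number <= seg.end]

    def coords(self, atom_set=BACKBONE_ATOMS) -> np.ndarray:
        pts = []
        for _, r in self.residues():
            for a in atom_set:
                if a in r.atoms:
                    pts.append(r.atoms[a])
        return np.asarray(pts, dtype=float)

    def all_atom_coords(self) -> np.ndarray:
        pts = []
        for _, r in self.residues():
            pts.extend(r.atoms.values())
        return np.asarray(pts, dtype=float)

    def copy(self) -> "BackboneModel":
        return BackboneModel([c.copy() for c in self.chains],
                             [_copy.copy(h) for h in self.helices])

    def transformed(self, t: Transform) -> "BackboneModel":
        out = self.copy()
        for c in out.chains:
            for r in c.residues:
                for a in r.atoms:
                    r.atoms[a] = t.apply(r.atoms[a])
        return out

    def validate_bonds(self, tolerance_range=PEPTIDE_BOND_RANGE) -> list[tuple]:
        """Return residue pairs whose C(i)-N(i+1) distance falls outside the
        peptide-bond window.  An empty list means the chain is covalently sane."""
        bad = []
        lo, hi = tolerance_range
        for c in self.chains:
            for r1, r2 in zip(c.residues, c.residues[1:]):
                if "C" in r1.atoms and "N" in r2.atoms:
                    d = float(np.linalg.norm(r2.atoms["N"] - r1.atoms["C"]))
                    if not (lo <= d <= hi):
                        bad.append((c.chain_id, r1.number, r2.number, d))
        return bad


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_pdb(path) -> BackboneModel:
    """Read a PDB file into a :class:`BackboneModel`.

    Residues missing any of N/CA/C are skipped with a warning.  Only the
    first model is used; for alternate locations the first conformer as
    stored by gemmi (highest occupancy first after ``remove_alternative_
    conformations``) is kept.
    """
    st = gemmi.read_structure(str(path))
    st.remove_alternative_conformations()
    st.remove_hydrogens()
    model = BackboneModel()
    for g_chain in st[0]:
        chain = Chain(g_chain.name)
        for g_res in g_chain:
            if not gemmi.find_tabulated_residue(g_res.name) or \
                    not gemmi.find_tabulated_residue(g_res.name).is_amino_acid():
                continue
            res = Residue(g_res.seqid.num, g_res.name)
            for atom in g_res:
                pos = atom.pos
                res.atoms[atom.name] = np.array([pos.x, pos.y, pos.z])
            if not res.has_backbone():
                warnings.warn(
                    f"residue {g_chain.name}/{g_res.seqid.num} {g_res.name} lacks "
                    "complete backbone; skipped", stacklevel=2)
                continue
            chain.residues.append(res)
        if chain.residues:
            model.chains.append(chain)
    return model


def write_pdb(model: BackboneModel, path) -> None:
    """Write ATOM/TER/END records via gemmi (coordinates to 3 decimals)."""
    st = gemmi.Structure()
    st.name = "barrelforge"
    g_model = gemmi.Model("1")
    for chain in model.chains:
        g_chain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            g_res = gemmi.Residue()
            g_res.name = res.name
            g_res.seqid = gemmi.SeqId(res.number, " ")
            for name, xyz in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(name[0])
                atom.pos = gemmi.Position(*[float(v) for v in xyz])
                atom.occ = 1.0
                atom.b_iso = 20.0
                g_res.add_atom(atom)
            g_chain.add_residue(g_res)
        g_model.add_chain(g_chain)
    st.add_model(g_model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[Transform, float]:
    """Least-squares rigid superposition of *mobile* onto *target* (Kabsch).

    Returns the optimal proper-rotation transform and the residual RMSD in
    angstroms.  Requires >= 3 non-collinear points in each set.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("coordinate sets must be matching (N, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError("need at least 3 points for superposition")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    a, b = target - tc, mobile - mc
    # collinearity: second singular value of either centered set ~ 0
    for pts in (a, b):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[1] < 1e-8 * max(sv[0], 1.0):
            raise GeometryError("degenerate (collinear) point set")
    rot, rssd = Rotation.align_vectors(a, b)
    R = rot.as_matrix()
    t = tc - R @ mc
    rmsd = float(rssd / np.sqrt(n))
    return Transform(R, t), rmsd


def _resolve_pairs(model_a: BackboneModel, model_b: BackboneModel,
                   residue_mapping) -> list[tuple[Residue, Residue]]:
    if residue_mapping is None:
        ra = [r for _, r in model_a.residues()]
        rb = [r for _, r in model_b.residues()]
        if len(ra) != len(rb):
            raise GeometryError(
                "models differ in residue count; supply an explicit residue_mapping")
        return list(zip(ra, rb))
    pairs = []
    for (ca, na), (cb, nb) in residue_mapping:
        res_a = next((r for r in model_a.chain(ca).residues if r.number == na), None)
        res_b = next((r for r in model_b.chain(cb).residues if r.number == nb), None)
        if res_a is None or res_b is None:
            raise GeometryError(f"mapping pair ({ca}{na}, {cb}{nb}) not resolvable")
        pairs.append((res_a, res_b))
    return pairs


def backbone_rmsd(model_a: BackboneModel, model_b: BackboneModel,
                  atom_set=BACKBONE_ATOMS, residue_mapping=None) -> float:
    """Backbone RMSD (default atoms N, CA, C, O) after optimal superposition.

    ``residue_mapping`` is a list of ``((chain_a, num_a), (chain_b, num_b))``
    pairs; by default residues are paired in order (models must then have
    equal residue counts).
    """
    pairs = _resolve_pairs(model_a, model_b, residue_mapping)
    if not pairs:
        raise GeometryError("empty residue mapping")
    xa, xb = [], []
    for res_a, res_b in pairs:
        for a in atom_set:
            if a in res_a.atoms and a in res_b.atoms:
                xa.append(res_a.atoms[a])
                xb.append(res_b.atoms[a])
    _, rmsd = kabsch_superpose(np.asarray(xb), np.asarray(xa))
    return rmsd


def middle_turn_mapping(model_a: BackboneModel, model_b: BackboneModel,
                        n_central: int = 7):
    """Residue mapping over the central *n_central* residues of each helix.

    Helices are paired in model order (use barrel cyclic order upstream);
    within a pair, residues are matched outward from the helix midpoints.
    Used for 'middle helical turns' comparisons between crystal structures
    and design models.
    """
    if len(model_a.helices) != len(model_b.helices):
        raise GeometryError("models have different helix counts")
    mapping = []
    for ha, hb in zip(model_a.helices, model_b.helices):
        ra = model_a.segment_residues(ha)
        rb = model_b.segment_residues(hb)
        k = min(n_central, len(ra), len(rb))
        sa = (len(ra) - k) // 2
        sb = (len(rb) - k) // 2
        for i in range(k):
            mapping.append(((ha.chain_id, ra[sa + i].number),
                            (hb.chain_id, rb[sb + i].number)))
    return mapping


# ---------------------------------------------------------------------------
# Helix detection and axes
# ---------------------------------------------------------------------------

def detect_helices(model: BackboneModel, min_length: int = 7) -> list[HelixSegment]:
    """Find maximal alpha-helical runs per chain.

    A residue window is helical when CA(i)->CA(i+4) is in the alpha-helical
    range (~6.2 A) and the local rise CA(i)->CA(i+1) is bonded-scale.  Runs
    shorter than *min_length* residues are dropped.
    """
    segments: list[HelixSegment] = []
    for chain in model.chains:
        ca = np.array([r.atoms["CA"] for r in chain.residues])
        nums = [r.number for r in chain.residues]
        n = len(ca)
        if n < 5:
            continue
        d14 = np.linalg.norm(ca[4:] - ca[:-4], axis=1)
        d11 = np.linalg.norm(ca[1:] - ca[:-1], axis=1)
        flags = np.zeros(n - 4, dtype=bool)
        for i in range(n - 4):
            contiguous = np.all(np.abs(np.array(nums[i:i + 5]) - nums[i] -
                                       np.arange(5)) == 0)
            flags[i] = (contiguous and 4.8 <= d14[i] <= 6.8 and
                        np.all((3.2 <= d11[i:i + 4]) & (d11[i:i + 4] <= 4.2)))
        i = 0
        while i < len(flags):
            if flags[i]:
                j = i
                while j + 1 < len(flags) and flags[j + 1]:
                    j += 1
                if (j + 4) - i + 1 >= min_length:
                    segments.append(HelixSegment(chain.chain_id, nums[i], nums[j + 4]))
                i = j + 1
            else:
                i += 1
    return segments


def helix_axis(segment: HelixSegment, model: BackboneModel) -> HelixAxis:
    """Helix axis by least-squares line fit through sliding 4-residue CA centroids.

    The 4-residue window averages out the helical wobble (3.6 residues/turn),
    so the centroids lie on the local axis.  Direction points N->C.
    """
    residues = model.segment_residues(segment)
    if len(residues) < 7:
        raise GeometryError("helix segment too short for axis fit (< 7 residues)")
    ca = np.array([r.atoms["CA"] for r in residues])
    centroids = np.array([ca[i:i + 4].mean(axis=0) for i in range(len(ca) - 3)])
    center = centroids.mean(axis=0)
    _, _, vt = np.linalg.svd(centroids - center)
    direction = vt[0]
    if np.dot(direction, centroids[-1] - centroids[0]) < 0:
        direction = -direction
    direction = direction / np.linalg.norm(direction)
    start = center + np.dot(centroids[0] - center, direction) * direction
    end = center + np.dot(centroids[-1] - center, direction) * direction
    return HelixAxis(start, end, direction)


def termini_gap(model: BackboneModel, helix_i: HelixSegment,
                helix_j: HelixSegment) -> float:
    """Distance (A) from the C-terminal carbonyl C of helix_i to the N-terminal N of helix_j."""
    res_i = model.segment_residues(helix_i)
    res_j = model.segment_residues(helix_j)
    if not res_i or not res_j:
        raise GeometryError("helix segments resolve to no residues")
    c_atom = res_i[-1].atoms.get("C")
    n_atom = res_j[0].atoms.get("N")
    if c_atom is None or n_atom is None:
        raise GeometryError("terminal backbone atoms missing")
    return float(np.linalg.norm(n_atom - c_atom))


# ---------------------------------------------------------------------------
# Cn symmetry
# ---------------------------------------------------------------------------

def _perpendicular_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, d)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    return u, np.cross(d, u)


def _cn_cost(model_coords_by_chain, point, direction, n) -> float:
    t = Transform.rotation_about_axis(point, direction, 2 * np.pi / n)
    cents = np.array([c.mean(axis=0) for c in model_coords_by_chain])
    total, count = 0.0, 0
    for k, coords in enumerate(model_coords_by_chain):
        rotated = t.apply(coords)
        target = int(np.argmin(np.linalg.norm(cents - rotated.mean(axis=0), axis=1)))
        other = model_coords_by_chain[target]
        if len(other) == len(coords):
            total += float(np.sum((rotated - other) ** 2))
            count += len(coords)
    return np.sqrt(total / count) if count else np.inf


def fit_cn_axis(model: BackboneModel, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Estimate the Cn symmetry axis (point on axis, unit direction).

    Initialised from the principal component of the backbone coordinates
    (barrel helices run along the symmetry axis) and refined by minimising
    the copy-to-copy RMSD under a 2*pi/n rotation with nearest-chain
    re-assignment.
    """
    if n < 2:
        raise GeometryError("Cn symmetry needs n >= 2")
    coords_by_chain = [np.array([a for r in c.residues
                                 for a in (r.atoms[x] for x in BACKBONE_ATOMS
                                           if x in r.atoms)])
                       for c in model.chains]
    allc = np.vstack(coords_by_chain)
    center = allc.mean(axis=0)
    _, _, vt = np.linalg.svd(allc - center)
    d0 = vt[0] / np.linalg.norm(vt[0])
    if _cn_cost(coords_by_chain, center, d0, n) < 1e-6:
        return center, d0
    u, v = _perpendicular_basis(d0)

    def unpack(x):
        a, b, p, q = x
        d = d0 + a * u + b * v
        d = d / np.linalg.norm(d)
        return center + p * u + q * v, d

    def cost(x):
        pt, d = unpack(x)
        return _cn_cost(coords_by_chain, pt, d, n)

    res = minimize(cost, np.zeros(4), method="Nelder-Mead",
                   options={"maxiter": 400, "xatol": 1e-6, "fatol": 1e-10})
    return unpack(res.x)


_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def apply_cn(unit: BackboneModel, n: int,
             axis: tuple[np.ndarray, np.ndarray] | None = None) -> BackboneModel:
    """Replicate *unit* n times by rotations of 2*pi*k/n about *axis* and merge.

    *axis* defaults to the global z axis through the origin.  Chains of the
    merged model are re-lettered sequentially (copy 0 keeps position order).
    """
    if n < 1:
        raise GeometryError("n must be >= 1")
    if axis is None:
        axis = (np.zeros(3), np.array([0.0, 0.0, 1.0]))
    point, direction = axis
    out = BackboneModel()
    idx = 0
    for k in range(n):
        t = Transform.rotation_about_axis(point, direction, 2 * np.pi * k / n)
        copy_k = unit.transformed(t)
        for chain, orig in zip(copy_k.chains, unit.chains):
            new_id = _CHAIN_IDS[idx % len(_CHAIN_IDS)]
            for h in unit.helices:
                if h.chain_id == chain.chain_id:
                    out.helices.append(HelixSegment(new_id, h.start, h.end))
            chain.chain_id = new_id
            idx += 1
            out.chains.append(chain)
    return out
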