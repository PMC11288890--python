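"""Socket-style knobs-into-holes (KIH) detection and barrel classification.

A residue is a *knob* when its side-chain center packs within a distance
cutoff (7.0 A by default; 7.5 A is a common looser variant) of at least four
side-chain centers on a single other helix -- those four nearest residues are
its *hole*.  Helix pairs sharing reciprocated knobs form coiled-coil
interfaces; a cyclic path of such interfaces visiting every helix is the
signature of an alpha-helical barrel, as opposed to bundles whose KIH
interactions run only between isolated helix pairs.  Openness (a continuous
solvent-accessible lumen versus a collapsed core) is measured by profiling
the largest axis-centered clearance circle along the barrel axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .geometry import (BACKBONE_ATOMS, BackboneModel, HelixSegment,
                       fit_cn_axis, helix_axis)

__all__ = [
    "SideChainCenter",
    "Knob",
    "KIHGraph",
    "LumenProfile",
    "side_chain_centers",
    "find_knobs",
    "build_kih_graph",
    "lumen_profile",
    "classify_open",
    "DEFAULT_PACKING_CUTOFF",
    "OPEN_THRESHOLD_WATER",
    "OPEN_THRESHOLD_DPH",
]

#: Socket-convention packing cutoff (A); 7.5 is the documented looser variant
DEFAULT_PACKING_CUTOFF = 7.0

#: lumen-radius threshold (A) for a water-sized channel
OPEN_THRESHOLD_WATER = 2.8
#: threshold (A) for a channel that can accommodate the DPH reporter dye
OPEN_THRESHOLD_DPH = 4.5

#: Bondi van der Waals radii (A) by element
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}


class KIHError(ValueError):
    pass


@dataclass
class SideChainCenter:
    chain_id: str
    residue_number: int
    residue_name: str
    center: np.ndarray
    fallback: str = ""  # "", "CA" (Gly), or "CB-proxy"


@dataclass
class Knob:
    chain_id: str
    residue_number: int
    hole_chain_id: str
    hole_residues: tuple[int, int, int, int]
    distances: tuple[float, ...]
    register_type: str = "unknown"  # "a", "d" or "unknown"
    complementary: bool = False


@dataclass
class KIHGraph:
    graph: nx.Graph
    knobs: list[Knob]
    orientations: dict[tuple[str, str], str]  # edge -> "parallel"/"antiparallel"
    barrel_cycle: list[str] | None

    @property
    def is_barrel(self) -> bool:
        return self.barrel_cycle is not None


@dataclass
class LumenProfile:
    stations: np.ndarray  # axial coordinate (A)
    radii: np.ndarray     # max inscribed clearance radius at each station (A)

    @property
    def min_radius(self) -> float:
        return float(np.min(self.radii))


# ---------------------------------------------------------------------------
# Side-chain centers
# ---------------------------------------------------------------------------

def side_chain_centers(model: BackboneModel) -> list[SideChainCenter]:
    """Centroid of side-chain heavy atoms per residue.

    Gly falls back to CA.  Residues carrying only backbone + CB use CB (the
    'CB proxy' for backbone-only models).  A residue with neither CB nor
    side-chain atoms (and not Gly) raises, instructing CB-proxy
    reconstruction upstream.
    """
    out = []
    backbone = set(BACKBONE_ATOMS)
    for chain in model.chains:
        for res in chain.residues:
            side = {k: v for k, v in res.atoms.items() if k not in backbone}
            if res.name == "GLY":
                out.append(SideChainCenter(chain.chain_id, res.number, res.name,
                                           res.atoms["CA"].copy(), "CA"))
            elif side:
                fallback = "CB-proxy" if set(side) == {"CB"} else ""
                center = np.mean(list(side.values()), axis=0)
                out.append(SideChainCenter(chain.chain_id, res.number, res.name,
                                           center, fallback))
            else:
                raise KIHError(
                    f"residue {chain.chain_id}/{res.number} has no side-chain atoms "
                    "or CB; reconstruct CB (proxy mode) before KIH analysis")
    return out


def _helix_of(model: BackboneModel):
    """Map (chain_id, residue_number) -> helix index."""
    lookup = {}
    for h_idx, seg in enumerate(model.helices):
        for num in range(seg.start, seg.end + 1):
            lookup[(seg.chain_id, num)] = h_idx
    return lookup


# ---------------------------------------------------------------------------
# Knob detection
# ---------------------------------------------------------------------------

def find_knobs(model: BackboneModel,
               cutoff: float = DEFAULT_PACKING_CUTOFF) -> list[Knob]:
    """All knob residues of *model* at the given packing cutoff.

    Requires ``model.helices`` to be populated (see
    :func:`barrelforge.geometry.detect_helices`).  Register type (a/d) is
    assigned afterwards from the 3/4-residue spacing of knobs along their own
    helix, the heptad signature of coiled-coil interfaces.
    """
    if cutoff <= 0:
        raise KIHError("packing cutoff must be positive")
    if not model.helices:
        raise KIHError("no helices on model; run detect_helices first")
    centers = side_chain_centers(model)
    lookup = _helix_of(model)
    centers = [c for c in centers if (c.chain_id, c.residue_number) in lookup]
    helix_idx = np.array([lookup[(c.chain_id, c.residue_number)] for c in centers])
    pts = np.array([c.center for c in centers])
    knobs: list[Knob] = []
    for i, c in enumerate(centers):
        d = np.linalg.norm(pts - pts[i], axis=1)
        for h in np.unique(helix_idx):
            if h == helix_idx[i]:
                continue
            mask = (helix_idx == h) & (d <= cutoff)
            if int(np.sum(mask)) >= 4:
                cand = np.where(mask)[0]
                order = cand[np.argsort(d[cand], kind="stable")][:4]
                hole = tuple(centers[j].residue_number for j in order)
                knobs.append(Knob(c.chain_id, c.residue_number,
                                  centers[order[0]].chain_id, hole,
                                  tuple(float(d[j]) for j in order)))
    _assign_register_types(knobs, model)
    _mark_complementary(knobs)
    return knobs


def _assign_register_types(knobs: list[Knob], model: BackboneModel) -> None:
    # Prefer the model's own register annotation (fixtures carry it); fall
    # back to knob-spacing heptad arithmetic: a -> d is +3 residues, d -> a +4.
    annotated = {}
    for chain in model.chains:
        for res in chain.residues:
            if res.register:
                annotated[(chain.chain_id, res.number)] = res.register
    by_helix: dict[tuple[str, str], list[Knob]] = {}
    for k in knobs:
        key = (k.chain_id, k.hole_chain_id)
        by_helix.setdefault(key, []).append(k)
    for key, ks in by_helix.items():
        ks.sort(key=lambda k: k.residue_number)
        for k in ks:
            reg = annotated.get((k.chain_id, k.residue_number))
            if reg in ("a", "d"):
                k.register_type = reg
        if all(k.register_type != "unknown" for k in ks):
            continue
        nums = [k.residue_number for k in ks]
        for idx, k in enumerate(ks):
            if k.register_type != "unknown":
                continue
            gap_next = nums[idx + 1] - nums[idx] if idx + 1 < len(nums) else None
            gap_prev = nums[idx] - nums[idx - 1] if idx > 0 else None
            if gap_next == 3 or gap_prev == 4:
                k.register_type = "a"
            elif gap_next == 4 or gap_prev == 3:
                k.register_type = "d"


def _mark_complementary(knobs: list[Knob]) -> None:
    hole_members: dict[tuple[str, str], set[int]] = {}
    for k in knobs:
        hole_members.setdefault((k.hole_chain_id, k.chain_id), set()).update(
            k.hole_residues)
    for k in knobs:
        members = hole_members.get((k.chain_id, k.hole_chain_id), set())
        k.complementary = k.residue_number in members


# ---------------------------------------------------------------------------
# Graph and topology
# ---------------------------------------------------------------------------

def build_kih_graph(model: BackboneModel, knobs: list[Knob]) -> KIHGraph:
    """Helix-interaction graph with orientations and barrel-cycle detection.

    An edge between two helices requires at least two knobs with at least one
    in each direction (reciprocated packing).  Orientation comes from the
    sign of the helix-axis dot product.  The barrel cycle, if any, is the
    longest simple cycle in the graph (ties broken lexicographically by the
    node sequence), canonically rotated to start from its smallest node.
    """
    lookup = _helix_of(model)
    g = nx.Graph()
    chain_of = {}
    for h_idx, seg in enumerate(model.helices):
        g.add_node(h_idx)
        chain_of[h_idx] = seg.chain_id

    directed: dict[tuple[int, int], int] = {}
    for k in knobs:
        hi = lookup.get((k.chain_id, k.residue_number))
        hj = lookup.get((k.hole_chain_id, k.hole_residues[0]))
        if hi is None or hj is None or hi == hj:
            continue
        directed[(hi, hj)] = directed.get((hi, hj), 0) + 1

    axes = [helix_axis(seg, model) for seg in model.helices]
    orientations: dict[tuple[str, str], str] = {}
    for (hi, hj), cnt in sorted(directed.items()):
        if hi < hj:
            back = directed.get((hj, hi), 0)
            if cnt + back >= 2 and back >= 1 and cnt >= 1:
                g.add_edge(hi, hj, n_knobs=cnt + back)
                dot = float(np.dot(axes[hi].direction, axes[hj].direction))
                orient = "parallel" if dot > 0 else "antiparallel"
                orientations[(chain_of[hi], chain_of[hj])] = orient
                g.edges[hi, hj]["orientation"] = orient

    cycle = _longest_cycle(g)
    barrel = [chain_of[h] for h in cycle] if cycle else None
    return KIHGraph(g, knobs, orientations, barrel)


def _longest_cycle(g: nx.Graph) -> list[int] | None:
    best: list[int] | None = None
    for cyc in nx.simple_cycles(g):
        if len(cyc) < 3:
            continue
        canon = _canonical_cycle(cyc)
        if best is None or (len(canon), [-c for c in canon]) > \
                (len(best), [-c for c in best]):
            best = canon
    return best


def _canonical_cycle(cyc: list[int]) -> list[int]:
    i = cyc.index(min(cyc))
    rotated = cyc[i:] + cyc[:i]
    reverse = [rotated[0]] + rotated[1:][::-1]
    return min(rotated, reverse)


# ---------------------------------------------------------------------------
# Lumen profiling
# ---------------------------------------------------------------------------

def lumen_profile(model: BackboneModel,
                  axis: tuple[np.ndarray, np.ndarray] | None = None,
                  probe_step: float = 1.0) -> LumenProfile:
    """Maximal inscribed channel radius along the barrel axis.

    At each axial station the clearance radius is the largest circle centered
    on the axis that avoids every van-der-Waals-inflated heavy atom.  *axis*
    defaults to a Cn fit over the helices present.
    """
    if axis is None:
        axis = fit_cn_axis(model, max(2, len(model.helices)))
    point, direction = axis
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)

    coords, radii = [], []
    for _, res in model.residues():
        for name, xyz in res.atoms.items():
            coords.append(xyz)
            radii.append(VDW_RADII.get(name[0], 1.7))
    coords = np.asarray(coords)
    radii = np.asarray(radii)

    rel = coords - point
    z = rel @ direction
    radial = np.linalg.norm(rel - np.outer(z, direction), axis=1)

    # profile only the helical core: trim half a turn off each end
    z_lo, z_hi = np.percentile(z, [5, 95])
    stations = np.arange(z_lo, z_hi + probe_step / 2, probe_step)
    profile = np.empty_like(stations)
    for s_idx, s in enumerate(stations):
        dz = np.abs(z - s)
        hit = dz < radii
        if not np.any(hit):
            profile[s_idx] = float(np.min(radial))
            continue
        slab = np.sqrt(radii[hit] ** 2 - dz[hit] ** 2)
        profile[s_idx] = max(0.0, float(np.min(radial[hit] - slab)))
    return LumenProfile(stations, profile)


def classify_open(profile: LumenProfile,
                  threshold: float = OPEN_THRESHOLD_WATER) -> str:
    """'open' if the narrowest point of the lumen still clears *threshold* (A)."""
    return "open" if profile.min_radius >= threshold else "collapsed"
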