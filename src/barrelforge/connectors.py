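"""Backbone fragment search and helix connection.

A miniature tertiary-fragment search in the spirit of MASTER: query *stubs*
(short backbone windows cut from the C-terminal end of one helix and the
N-terminal end of the next) are matched against a library of
helix-loop-helix fragments by joint rigid superposition of both windows;
hits below an RMSD cutoff donate their intervening loop, which is grafted
to fuse the two helices into one chain.  For parallel barrels, a
helix-turn-helix-turn-helix unit is replicated about the Cn axis and its
overlapping buttressing helices reconciled, closing an n-inner /
(n-1)-buttressing single-chain scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (BACKBONE_ATOMS, BackboneModel, Chain, GeometryError,
                       HelixSegment, Residue, Transform, backbone_rmsd,
                       fit_cn_axis, kabsch_superpose)

__all__ = [
    "StubPair",
    "FragmentLibrary",
    "LibraryEntry",
    "FragmentHit",
    "GraftResult",
    "ClashError",
    "stub_pair_from_helices",
    "search_connectors",
    "graft_connector",
    "assemble_parallel_scaffold",
    "select_unit_handedness",
]

DEFAULT_STUB_WINDOW = 5
DEFAULT_LOOP_RMSD_CUTOFF = 1.0
DEFAULT_HTH_RMSD_CUTOFF = 1.5
CLASH_DISTANCE = 2.0


class ClashError(ValueError):
    def __init__(self, clashes):
        self.clashes = clashes
        super().__init__(f"{len(clashes)} backbone clash(es) < {CLASH_DISTANCE} A: "
                         + "; ".join(str(c) for c in clashes[:5]))


@dataclass
class StubPair:
    """Two equal-length contiguous backbone windows flanking a gap to bridge."""

    residues_a: list[Residue]  # C-terminal window of the upstream helix
    residues_b: list[Residue]  # N-terminal window of the downstream helix

    def __post_init__(self) -> None:
        if len(self.residues_a) != len(self.residues_b) or not self.residues_a:
            raise GeometryError("stub windows must be nonempty and equal length")

    @property
    def window(self) -> int:
        return len(self.residues_a)

    def coords(self) -> np.ndarray:
        pts = []
        for r in self.residues_a + self.residues_b:
            for a in BACKBONE_ATOMS:
                pts.append(r.atoms[a])
        return np.asarray(pts)


@dataclass
class LibraryEntry:
    source_id: str
    model: BackboneModel  # single chain with complete backbone


@dataclass
class FragmentLibrary:
    entries: list[LibraryEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.source_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("library entry ids must be unique")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class FragmentHit:
    source_id: str
    range_a: tuple[int, int]  # matched residue numbers in the entry (inclusive)
    range_b: tuple[int, int]
    transform: Transform      # entry frame -> query frame
    rmsd: float
    loop_residues: list[Residue]  # entry residues between the windows (entry frame)


@dataclass
class GraftResult:
    model: BackboneModel
    junctions: list[tuple[int, float]]  # (new residue number before bond, C-N distance)
    renumbering: dict[tuple[str, int], tuple[str, int]]

    @property
    def unreconciled(self) -> list[tuple[int, float]]:
        return [(n, d) for n, d in self.junctions if not 1.2 <= d <= 1.45]


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------

def stub_pair_from_helices(model: BackboneModel, helix_i: HelixSegment,
                           helix_j: HelixSegment,
                           window: int = DEFAULT_STUB_WINDOW) -> StubPair:
    """Cut the search stubs: last *window* residues of helix_i, first of helix_j."""
    res_i = model.segment_residues(helix_i)
    res_j = model.segment_residues(helix_j)
    if len(res_i) < window or len(res_j) < window:
        raise GeometryError("helix shorter than stub window")
    return StubPair([r.copy() for r in res_i[-window:]],
                    [r.copy() for r in res_j[:window]])


def search_connectors(query: StubPair, library: FragmentLibrary,
                      rmsd_cutoff: float = DEFAULT_LOOP_RMSD_CUTOFF,
                      max_loop_len: int = 7,
                      min_loop_len: int = 0) -> list[FragmentHit]:
    """Scan every window pair of every library entry against the query stubs.

    Both windows are superposed jointly (a single Kabsch fit over 2 x window
    backbone atoms), so a hit's loop is guaranteed to land between the query
    helices under one rigid transform.  Hits with RMSD <= cutoff are returned
    sorted by ascending RMSD with a stable (source_id, position) tie-break.
    """
    if len(library) == 0:
        raise ValueError("empty fragment library")
    w = query.window
    target = query.coords()
    hits: list[FragmentHit] = []
    any_long_enough = False
    for entry in library.entries:
        chain = entry.model.chains[0]
        residues = chain.residues
        n = len(residues)
        if n < 2 * w:
            continue
        any_long_enough = True
        coords = np.array([[r.atoms[a] for a in BACKBONE_ATOMS] for r in residues])
        for i in range(0, n - 2 * w + 1):
            j_min = i + w + min_loop_len
            j_max = min(i + w + max_loop_len, n - w)
            for j in range(j_min, j_max + 1):
                mobile = np.vstack([coords[i:i + w].reshape(-1, 3),
                                    coords[j:j + w].reshape(-1, 3)])
                try:
                    transform, rmsd = kabsch_superpose(mobile, target)
                except GeometryError:
                    continue
                if rmsd <= rmsd_cutoff:
                    loop = [residues[k].copy() for k in range(i + w, j)]
                    hits.append(FragmentHit(
                        entry.source_id,
                        (residues[i].number, residues[i + w - 1].number),
                        (residues[j].number, residues[j + w - 1].number),
                        transform, rmsd, loop))
    if not any_long_enough:
        import warnings
        warnings.warn("all library entries shorter than the combined stub windows",
                      stacklevel=2)
    hits.sort(key=lambda h: (h.rmsd, h.source_id, h.range_a[0], h.range_b[0]))
    return hits


# ---------------------------------------------------------------------------
# Grafting
# ---------------------------------------------------------------------------

def _backbone_coords(residues) -> np.ndarray:
    return np.array([r.atoms[a] for r in residues for a in BACKBONE_ATOMS
                     if a in r.atoms])


def graft_connector(barrel: BackboneModel, hit: FragmentHit,
                    helix_i: HelixSegment, helix_j: HelixSegment) -> GraftResult:
    """Splice the hit's loop between helix_i's chain and helix_j's chain.

    The loop coordinates are mapped by the hit's alignment transform, the two
    chains are merged into one (keeping helix_i's chain id) and renumbered
    contiguously from 1.  Junction C-N distances are reported; any backbone
    atom of the placed loop closer than 2 A to a non-adjacent barrel backbone
    atom raises :class:`ClashError`.
    """
    chain_i = barrel.chain(helix_i.chain_id)
    chain_j = barrel.chain(helix_j.chain_id)
    if chain_i is chain_j:
        raise GeometryError("helices already on the same chain")
    loop = []
    for r in hit.loop_residues:
        rr = r.copy()
        for a in rr.atoms:
            rr.atoms[a] = hit.transform.apply(rr.atoms[a])
        loop.append(rr)

    # clash screen: loop backbone vs everything except the flanking residues
    loop_bb = _backbone_coords(loop)
    clashes = []
    if len(loop_bb):
        flank = {(chain_i.chain_id, chain_i.residues[-1].number),
                 (chain_j.chain_id, chain_j.residues[0].number)}
        for cid, res in barrel.residues():
            if (cid, res.number) in flank:
                continue
            for a in BACKBONE_ATOMS:
                if a not in res.atoms:
                    continue
                d = np.linalg.norm(loop_bb - res.atoms[a], axis=1)
                if np.any(d < CLASH_DISTANCE):
                    clashes.append((cid, res.number, a, float(d.min())))
        if clashes:
            raise ClashError(clashes)

    merged = Chain(chain_i.chain_id)
    renumbering: dict[tuple[str, int], tuple[str, int]] = {}
    num = 1
    for source_id, block in ((chain_i.chain_id, chain_i.residues),
                             (None, loop),
                             (chain_j.chain_id, chain_j.residues)):
        for r in block:
            rr = r.copy()
            if source_id is not None:
                renumbering[(source_id, rr.number)] = (merged.chain_id, num)
            rr.number = num
            merged.residues.append(rr)
            num += 1

    junctions = []
    for k in range(len(merged.residues) - 1):
        r1, r2 = merged.residues[k], merged.residues[k + 1]
        d = float(np.linalg.norm(r2.atoms["N"] - r1.atoms["C"]))
        if not 1.2 <= d <= 1.45 or r1.number == len(chain_i.residues) or \
                r1.number == len(chain_i.residues) + len(loop):
            junctions.append((r1.number, d))

    out = BackboneModel()
    out.chains.append(merged)
    for c in barrel.chains:
        if c.chain_id not in (chain_i.chain_id, chain_j.chain_id):
            out.chains.append(c.copy())
    # helix bookkeeping through the renumbering
    for seg in barrel.helices:
        if seg.chain_id in (chain_i.chain_id, chain_j.chain_id):
            new_start = renumbering[(seg.chain_id, seg.start)]
            new_end = renumbering[(seg.chain_id, seg.end)]
            out.helices.append(HelixSegment(merged.chain_id, new_start[1], new_end[1]))
        else:
            out.helices.append(HelixSegment(seg.chain_id, seg.start, seg.end))
    out.helices.sort(key=lambda s: (s.chain_id != merged.chain_id, s.chain_id, s.start))
    return GraftResult(out, junctions, renumbering)


# ---------------------------------------------------------------------------
# Cn scaffold assembly
# ---------------------------------------------------------------------------

def select_unit_handedness(n: int) -> str:
    """Tertiary twist of the connector unit by barrel order.

    Five-helix barrels have pronounced left-handed supercoils, so their
    connector is left-handed; six and above are straighter and take the
    right-handed unit.
    """
    if not 5 <= n <= 8:
        raise ValueError("supported barrel orders are 5-8")
    return "left" if n == 5 else "right"


def assemble_parallel_scaffold(inner_barrel: BackboneModel,
                               hth_unit: BackboneModel, n: int,
                               tolerance: float = DEFAULT_HTH_RMSD_CUTOFF) -> GraftResult:
    """Close a single-chain scaffold: n inner helices + (n-1) buttressing.

    The unit (buttressing helix, turn, central helix, turn, buttressing
    helix, pre-aligned with its central helix on one inner barrel helix) is
    replicated about the barrel's Cn axis.  The trailing buttressing helix of
    copy k overlaps the leading one of copy k+1; the overlap RMSD is the
    symmetry-fit check (error above *tolerance*), and overlapping coordinates
    are averaged.  The chain threads inner -> buttressing -> inner, dropping
    the unused outer helix at the seam, for 2n-1 helices in total.
    """
    if n < 2:
        raise GeometryError("n must be >= 2")
    if len(hth_unit.helices) != 3 or len(hth_unit.chains) != 1:
        raise GeometryError("unit must be a single chain with three helices")
    axis = fit_cn_axis(inner_barrel, n)

    h1_seg, h2_seg, h3_seg = hth_unit.helices
    unit_chain = hth_unit.chains[0]

    def block(a, b):
        return [r for r in unit_chain.residues if a <= r.number <= b]

    h1 = block(h1_seg.start, h1_seg.end)
    t1 = block(h1_seg.end + 1, h2_seg.start - 1)
    h2 = block(h2_seg.start, h2_seg.end)
    t2 = block(h2_seg.end + 1, h3_seg.start - 1)
    h3 = block(h3_seg.start, h3_seg.end)
    if len(h1) != len(h3):
        raise GeometryError("buttressing helices must have equal lengths")

    def rotated(residues, k, sign):
        t = Transform.rotation_about_axis(axis[0], axis[1],
                                          sign * 2 * np.pi * k / n)
        out = []
        for r in residues:
            rr = r.copy()
            for a in rr.atoms:
                rr.atoms[a] = t.apply(rr.atoms[a])
            out.append(rr)
        return out

    # the unit may wind either way around the axis; pick the rotation sense
    # that brings copy k+1's leading helix onto copy k's trailing helix
    def overlap_rmsd(sign):
        a = _backbone_coords(rotated(h3, 0, sign))
        b = _backbone_coords(rotated(h1, 1, sign))
        return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))

    sign = 1 if overlap_rmsd(1) <= overlap_rmsd(-1) else -1
    fit = overlap_rmsd(sign)
    if fit > tolerance:
        raise GeometryError(
            f"unit does not close under Cn symmetry (overlap RMSD {fit:.2f} A "
            f"> {tolerance} A)")

    def averaged_outer(k):
        trail = rotated(h3, k, sign)
        lead = rotated(h1, k + 1, sign)
        out = []
        for r_t, r_l in zip(trail, lead):
            rr = r_t.copy()
            for a in rr.atoms:
                if a in r_l.atoms:
                    rr.atoms[a] = 0.5 * (r_t.atoms[a] + r_l.atoms[a])
            out.append(rr)
        return out

    chain = Chain("A")
    helices: list[HelixSegment] = []
    junctions: list[tuple[int, float]] = []
    num = 1

    def append(blockres, is_helix):
        nonlocal num
        start = num
        for r in blockres:
            rr = r.copy()
            rr.number = num
            chain.residues.append(rr)
            num += 1
        if is_helix:
            helices.append(HelixSegment("A", start, num - 1))

    for k in range(n):
        append(rotated(h2, k, sign), True)          # inner helix k
        if k < n - 1:
            append(rotated(t2, k, sign), False)     # turn up->outer
            append(averaged_outer(k), True)         # buttressing helix k
            append(rotated(t1, k + 1, sign), False)  # turn outer->next inner

    for a, b in zip(chain.residues, chain.residues[1:]):
        d = float(np.linalg.norm(b.atoms["N"] - a.atoms["C"]))
        if not 1.2 <= d <= 1.45:
            junctions.append((a.number, d))

    model = BackboneModel([chain], helices)
    renum = {("A", r.number): ("A", r.number) for r in chain.residues}
    return GraftResult(model, junctions, renum)
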