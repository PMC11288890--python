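"""Heptad registers and rationally seeded sequence generation.

Coiled-coil sequences repeat with a seven-residue period labelled
``gabcdef``.  The g, a, d and e sites line the helix-helix interfaces and
largely determine oligomer order and topology; b, c and f face solvent.
A *seed rule* assigns amino acids to g-a-d-e (optionally per heptad), and a
*background* fills b/c with 'bar-magnet' Glu/Lys charge blocks (Glu in the
N-terminal half, Lys in the C-terminal half, favouring antiparallel
neighbour pairing) and cycles f through helix-favouring polar residues with
a single Trp chromophore per chain.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "REGISTER_CYCLE",
    "STANDARD_AA",
    "SeedRule",
    "BackgroundSpec",
    "HeptadSequence",
    "enumerate_seed_rules",
    "build_seed_peptide",
    "thread_rule_onto_scaffold",
    "pairwise_identity",
    "read_fasta",
    "write_fasta",
    "annotation_table",
]

#: heptad labels in cyclic order; sequences here start at g by convention,
#: matching the helical-wheel presentation of barrel interfaces.
REGISTER_CYCLE = "gabcdef"

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

HYDROPHOBIC_AA = set("AVLIMFWYC")


class ValidationError(ValueError):
    pass


def _check_residue(res: str, where: str) -> str:
    if len(res) != 1 or res.upper() not in STANDARD_AA:
        raise ValidationError(f"{where}: {res!r} is not a standard amino acid")
    return res.upper()


@dataclass(frozen=True)
class SeedRule:
    """Amino-acid assignment for the g-a-d-e interface sites.

    ``a_res``/``d_res`` are tuples with one entry per heptad, or length-1
    tuples applied uniformly.  ``g_res`` and ``e_res`` are single residues.
    """

    g_res: str
    a_res: tuple[str, ...]
    d_res: tuple[str, ...]
    e_res: str
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "g_res", _check_residue(self.g_res, "g"))
        object.__setattr__(self, "e_res", _check_residue(self.e_res, "e"))
        object.__setattr__(self, "a_res",
                           tuple(_check_residue(r, "a") for r in self.a_res))
        object.__setattr__(self, "d_res",
                           tuple(_check_residue(r, "d") for r in self.d_res))
        if not self.a_res or not self.d_res:
            raise ValidationError("a_res and d_res must be nonempty")
        if not self.name:
            object.__setattr__(self, "name", self._default_name())

    def _default_name(self) -> str:
        if len(self.a_res) == 1 and len(self.d_res) == 1:
            return f"{self.g_res}{self.a_res[0]}{self.d_res[0]}{self.e_res}"
        # per-heptad rules: append heptad indices to each a/d pair
        parts = [f"{a}{d}{i + 1}" for i, (a, d) in
                 enumerate(zip(self._cycle(self.a_res, len(self.a_res)),
                               self._cycle(self.d_res, len(self.d_res))))]
        return f"{self.g_res}-{''.join(parts)}-{self.e_res}"

    @staticmethod
    def _cycle(vals: tuple[str, ...], n: int) -> list[str]:
        if len(vals) == 1:
            return [vals[0]] * n
        return list(vals[:n])

    def per_heptad(self, n_heptads: int) -> list[tuple[str, str, str, str]]:
        """(g, a, d, e) for each heptad, expanding uniform rules."""
        for vals, lab in ((self.a_res, "a"), (self.d_res, "d")):
            if len(vals) not in (1, n_heptads):
                raise ValidationError(
                    f"{lab}_res has length {len(vals)}; expected 1 or {n_heptads}")
        a = self._cycle(self.a_res, n_heptads)
        d = self._cycle(self.d_res, n_heptads)
        return [(self.g_res, a[h], d[h], self.e_res) for h in range(n_heptads)]


@dataclass
class BackgroundSpec:
    """Solvent-facing background: per-heptad b/c charges and an f-position cycle."""

    b_c_pattern: list[str]
    f_cycle: list[str]
    n_heptads: int
    single_trp: bool = True

    def __post_init__(self) -> None:
        if len(self.b_c_pattern) != self.n_heptads:
            raise ValidationError("b_c_pattern length must equal n_heptads")
        for r in self.b_c_pattern:
            if _check_residue(r, "b/c") not in ("E", "K"):
                raise ValidationError("bar-magnet charges must be Glu (E) or Lys (K)")
        if not self.f_cycle:
            raise ValidationError("f_cycle must be nonempty")
        self.f_cycle = [_check_residue(r, "f") for r in self.f_cycle]

    @classmethod
    def default(cls, n_heptads: int) -> "BackgroundSpec":
        """Bar-magnet Glu block then Lys block at b/c; f = Gln/Lys/Trp/Lys cycle."""
        half = (n_heptads + 1) // 2
        pattern = ["E"] * half + ["K"] * (n_heptads - half)
        return cls(pattern, ["Q", "K", "W", "K"], n_heptads)

    def f_residues(self) -> list[str]:
        out = [self.f_cycle[h % len(self.f_cycle)] for h in range(self.n_heptads)]
        if self.single_trp:
            seen = False
            for i, r in enumerate(out):
                if r == "W":
                    if seen:
                        out[i] = "K"  # one chromophore per chain
                    seen = True
        return out


@dataclass
class HeptadSequence:
    """An amino-acid sequence with per-residue heptad register labels."""

    residues: list[str]
    offset: str = "g"
    name: str = ""
    register: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.residues = [_check_residue(r, "sequence") for r in self.residues]
        if self.offset not in REGISTER_CYCLE:
            raise ValidationError(f"offset {self.offset!r} not a register label")
        if not self.register:
            k = REGISTER_CYCLE.index(self.offset)
            self.register = [REGISTER_CYCLE[(k + i) % 7]
                             for i in range(len(self.residues))]
        if len(self.register) != len(self.residues):
            raise ValidationError("register length must equal sequence length")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return "".join(self.residues)

    def positions(self, label: str) -> list[int]:
        """0-based indices carrying register *label*."""
        return [i for i, lab in enumerate(self.register) if lab == label]

    def residues_at(self, label: str) -> list[str]:
        return [self.residues[i] for i in self.positions(label)]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def enumerate_seed_rules(g_set, a_set, d_set, e_res) -> list[SeedRule]:
    """Cartesian product of interface assignments, in lexicographic g-a-d order.

    Each rule is named by its one-letter codes in g-a-d-e order (e.g. "LLIA"
    for Leu-Leu-Ile-Ala).
    """
    g = sorted(_check_residue(r, "g") for r in g_set)
    a = sorted(_check_residue(r, "a") for r in a_set)
    d = sorted(_check_residue(r, "d") for r in d_set)
    e = _check_residue(e_res, "e")
    if not (g and a and d):
        raise ValidationError("all residue sets must be nonempty")
    return [SeedRule(gg, (aa,), (dd,), e)
            for gg, aa, dd in itertools.product(g, a, d)]


def build_seed_peptide(rule: SeedRule, background: BackgroundSpec,
                       name: str | None = None) -> HeptadSequence:
    """Install a seed rule into the background over ``background.n_heptads`` heptads.

    The sequence starts at register g, so each heptad reads g-a-b-c-d-e-f:
    g/a/d/e from the rule, b/c from the bar-magnet pattern, f from the cycle.
    """
    n = background.n_heptads
    if n < 1:
        raise ValidationError("need at least one heptad")
    gade = rule.per_heptad(n)
    f_res = background.f_residues()
    residues: list[str] = []
    for h in range(n):
        g, a, d, e = gade[h]
        bc = background.b_c_pattern[h]
        residues.extend([g, a, bc, bc, d, e, f_res[h]])
    return HeptadSequence(residues, offset="g", name=name or rule.name)


def thread_rule_onto_scaffold(scaffold: list[HeptadSequence],
                              rule: SeedRule) -> tuple[list[HeptadSequence], int]:
    """Rewrite every g/a/d/e position of each scaffold sequence per *rule*.

    All other positions are untouched.  Returns the new sequences and the
    number of positions whose residue actually changed, so seeded designs
    can report how much of the interface was rewritten (e.g. swapping the
    49 a/d sites of a seven-helix central barrel between design rules).
    """
    out: list[HeptadSequence] = []
    changed = 0
    for seq in scaffold:
        if not seq.register:
            raise ValidationError("scaffold sequence lacks register annotation")
        new_res = list(seq.residues)
        for label in "gade":
            idx = seq.positions(label)
            if not idx:
                continue
            if label == "g":
                vals = [rule.g_res] * len(idx)
            elif label == "e":
                vals = [rule.e_res] * len(idx)
            else:
                per = rule.a_res if label == "a" else rule.d_res
                vals = [per[0]] * len(idx) if len(per) == 1 else \
                    [per[min(k, len(per) - 1)] for k in range(len(idx))]
            for i, v in zip(idx, vals):
                if new_res[i] != v:
                    changed += 1
                new_res[i] = v
        out.append(HeptadSequence(new_res, offset=seq.offset, name=seq.name,
                                  register=list(seq.register)))
    return out, changed


def pairwise_identity(seq1, seq2) -> float:
    """Percent identity of two equal-length sequences (gapless comparison).

    Designed families share a fixed scaffold length, so no alignment is
    performed; unequal lengths are an error.
    """
    s1 = str(seq1)
    s2 = str(seq2)
    if len(s1) != len(s2):
        raise ValidationError("sequences must have equal length (gapless comparison)")
    if not s1:
        raise ValidationError("empty sequences")
    matches = sum(1 for x, y in zip(s1, s2) if x == y)
    return 100.0 * matches / len(s1)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_fasta(seqs: list[HeptadSequence], path) -> None:
    """FASTA with the register string encoded in the description line."""
    records = []
    for i, s in enumerate(seqs):
        rec = SeqRecord(Seq(str(s)), id=s.name or f"seq{i + 1}",
                        description=f"register={''.join(s.register)}")
        records.append(rec)
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[HeptadSequence]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        register = None
        for token in rec.description.split():
            if token.startswith("register="):
                register = list(token[len("register="):])
        if register:
            seq = HeptadSequence(list(str(rec.seq)), offset=register[0],
                                 name=rec.id, register=register)
        else:
            seq = HeptadSequence(list(str(rec.seq)), name=rec.id)
        out.append(seq)
    return out


def annotation_table(seq: HeptadSequence) -> pd.DataFrame:
    """Per-position annotation (1-based position, residue, register label)."""
    return pd.DataFrame({
        "position": range(1, len(seq) + 1),
        "residue": seq.residues,
        "register": seq.register,
    })
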