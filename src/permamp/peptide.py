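"""Peptide representation, cyclic-permutation libraries, and helical-wheel geometry.

A cyclic sequence permutation reads a peptide sequence from each start
position around a circle, producing length-preserving rotations that keep
the residue composition (and hence every composition-only descriptor)
fixed while reordering the sequence.  Terminal chemistry (N-acetylation,
C-amidation) is carried as metadata, never as sequence characters.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

N_TERMINI = ("free", "acetyl")
C_TERMINI = ("free", "amide")


class PeptideError(ValueError):
    """Raised for invalid peptide definitions or parameters."""


@dataclass(frozen=True)
class Peptide:
    """A peptide chain with optional terminal modifications.

    Parameters
    ----------
    name : str
        Non-empty label.
    sequence : str
        One-letter codes over the 20 canonical amino acids, length >= 2.
    n_terminus : {"free", "acetyl"}
    c_terminus : {"free", "amide"}
    """

    name: str
    sequence: str
    n_terminus: str = "free"
    c_terminus: str = "free"

    def __post_init__(self) -> None:
        if not self.name:
            raise PeptideError("peptide name must be non-empty")
        if len(self.sequence) < 2:
            raise PeptideError(
                f"peptide {self.name!r}: sequence must have length >= 2, "
                f"got {len(self.sequence)}"
            )
        for pos, aa in enumerate(self.sequence, start=1):
            if aa not in CANONICAL_AA:
                raise PeptideError(
                    f"peptide {self.name!r}: non-canonical residue {aa!r} "
                    f"at position {pos}"
                )
        if self.n_terminus not in N_TERMINI:
            raise PeptideError(f"n_terminus must be one of {N_TERMINI}")
        if self.c_terminus not in C_TERMINI:
            raise PeptideError(f"c_terminus must be one of {C_TERMINI}")

    def __len__(self) -> int:
        return len(self.sequence)

    def modified_label(self) -> str:
        """Chemical-style label, e.g. ``Ac-KKWR...-NH2``."""
        left = "Ac-" if self.n_terminus == "acetyl" else ""
        right = "-NH2" if self.c_terminus == "amide" else ""
        return f"{left}{self.sequence}{right}"


@dataclass(frozen=True)
class LibraryMember:
    """One rotation of a parent peptide."""

    peptide: Peptide
    start_offset: int  # left-rotation amount, 1..L-1
    duplicate: bool = False  # True if the rotated sequence repeats an earlier one


@dataclass(frozen=True)
class PermutationLibrary:
    """Parent peptide plus its L-1 cyclic rotations, in rotation order."""

    parent: Peptide
    members: tuple[LibraryMember, ...]

    def __post_init__(self) -> None:
        for m in self.members:
            if sorted(m.peptide.sequence) != sorted(self.parent.sequence):
                raise PeptideError(
                    f"member {m.peptide.name!r} is not a rotation of the parent"
                )

    def peptides(self) -> list[Peptide]:
        """Parent followed by all members, in order."""
        return [self.parent] + [m.peptide for m in self.members]

    def __len__(self) -> int:
        return len(self.members)


def rotate(sequence: str, k: int) -> str:
    """Left-rotate ``sequence`` by ``k`` (reading from position k+1 onward)."""
    k = k % len(sequence)
    return sequence[k:] + sequence[:k]


def cyclic_permutations(
    parent: Peptide, names: Mapping[int, str] | None = None
) -> PermutationLibrary:
    """Generate all L-1 cyclic rotations of a parent peptide.

    Member ``k`` (k = 1..L-1) carries sequence ``parent[k:] + parent[:k]`` —
    the sequence read clockwise starting from position k+1 of the parent
    placed on a circle.  Terminal modifications are inherited unchanged.
    Rotations of a periodic parent that repeat an earlier sequence are kept
    and flagged ``duplicate`` so the member count is always L-1.

    Parameters
    ----------
    names : mapping of start_offset -> name, optional
        Caller-supplied naming (e.g. ``{1: "W5K01", ...}``); members without
        an entry get ``"<parent>_rot<k>"``.
    """
    L = len(parent.sequence)
    seen = {parent.sequence}
    members = []
    for k in range(1, L):
        seq = rotate(parent.sequence, k)
        name = (names or {}).get(k, f"{parent.name}_rot{k:02d}")
        pep = Peptide(name, seq, parent.n_terminus, parent.c_terminus)
        members.append(LibraryMember(pep, start_offset=k, duplicate=seq in seen))
        seen.add(seq)
    return PermutationLibrary(parent=parent, members=tuple(members))


@dataclass(frozen=True)
class WheelEntry:
    residue_index: int
    residue: str
    angle_deg: float


@dataclass(frozen=True)
class WheelProjection:
    """Helical-wheel placement of residues at ``delta_deg`` per residue.

    Residue i sits at angle (i * delta_deg) mod 360, with residue 0 at the
    reference angle 0.  The default 100 deg/residue is the ideal alpha-helix
    periodicity (3.6 residues/turn).
    """

    entries: tuple[WheelEntry, ...]
    delta_deg: float = 100.0

    def unit_vectors(self) -> list[tuple[float, float]]:
        """Per-residue (cos, sin) of the wheel angle, in sequence order."""
        return [
            (math.cos(math.radians(e.angle_deg)), math.sin(math.radians(e.angle_deg)))
            for e in self.entries
        ]


def helical_wheel(p: Peptide, delta_deg: float = 100.0) -> WheelProjection:
    """Project a peptide onto a helical wheel."""
    if delta_deg <= 0:
        raise PeptideError(f"delta_deg must be positive, got {delta_deg}")
    entries = tuple(
        WheelEntry(i, aa, (i * delta_deg) % 360.0)
        for i, aa in enumerate(p.sequence)
    )
    return WheelProjection(entries=entries, delta_deg=delta_deg)


# ---------------------------------------------------------------------------
# FASTA and CSV interfaces.  Terminal modifications travel in the FASTA
# description line as key=value tokens, never as sequence characters.

def _description(p: Peptide, extra: dict[str, str] | None = None) -> str:
    tokens = {"nterm": p.n_terminus, "cterm": p.c_terminus}
    tokens.update(extra or {})
    return " ".join(f"{k}={v}" for k, v in tokens.items())


def _parse_tokens(description: str) -> dict[str, str]:
    out = {}
    for tok in description.split():
        if "=" in tok:
            k, _, v = tok.partition("=")
            out[k] = v
    return out


def write_fasta(peptides: Iterable[Peptide] | PermutationLibrary, path: str | Path) -> None:
    """Write peptides (or a whole library, parent first) to FASTA."""
    records = []
    if isinstance(peptides, PermutationLibrary):
        lib = peptides
        records.append(
            SeqRecord(Seq(lib.parent.sequence), id=lib.parent.name,
                      description=_description(lib.parent, {"role": "parent"}))
        )
        for m in lib.members:
            extra = {"role": "member", "start_offset": str(m.start_offset)}
            if m.duplicate:
                extra["duplicate"] = "true"
            records.append(
                SeqRecord(Seq(m.peptide.sequence), id=m.peptide.name,
                          description=_description(m.peptide, extra))
            )
    else:
        for p in peptides:
            records.append(
                SeqRecord(Seq(p.sequence), id=p.name, description=_description(p))
            )
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[Peptide]:
    """Read peptides from FASTA written by :func:`write_fasta`."""
    peptides = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = _parse_tokens(rec.description)
        peptides.append(
            Peptide(
                name=rec.id,
                sequence=str(rec.seq),
                n_terminus=tokens.get("nterm", "free"),
                c_terminus=tokens.get("cterm", "free"),
            )
        )
    return peptides


def read_library_fasta(path: str | Path) -> PermutationLibrary:
    """Reconstruct a :class:`PermutationLibrary` from its FASTA round-trip."""
    parent = None
    members = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = _parse_tokens(rec.description)
        pep = Peptide(rec.id, str(rec.seq), tokens.get("nterm", "free"),
                      tokens.get("cterm", "free"))
        if tokens.get("role") == "parent":
            parent = pep
        else:
            members.append(
                LibraryMember(pep, start_offset=int(tokens["start_offset"]),
                              duplicate=tokens.get("duplicate") == "true")
            )
    if parent is None:
        raise PeptideError(f"no parent record (role=parent) found in {path}")
    members.sort(key=lambda m: m.start_offset)
    return PermutationLibrary(parent=parent, members=tuple(members))


def wheel_to_csv(peptides: Iterable[Peptide], path: str | Path,
                 delta_deg: float = 100.0) -> None:
    """Export helical-wheel coordinates (one row per residue) for plotting."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "residue_index", "residue", "angle_deg", "cos", "sin"])
        for p in peptides:
            wheel = helical_wheel(p, delta_deg)
            for entry, (c, s) in zip(wheel.entries, wheel.unit_vectors()):
                w.writerow([p.name, entry.residue_index, entry.residue,
                            f"{entry.angle_deg:.6g}", f"{c:.9f}", f"{s:.9f}"])
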