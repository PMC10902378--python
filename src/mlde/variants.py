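"""Protein variant identities.

A variant is a set of point substitutions relative to a named parent
sequence.  The canonical name is the underscore-joined substitution
string in ascending position order (e.g. ``F97W_L241M``); a variant with
no substitutions is named after its parent.  Names are the single source
of identity throughout the package — full sequences are derived from
them, never stored as identity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

#: The 20 standard amino acids, alphabetical one-letter codes.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_SUB_RE = re.compile(r"^([A-Z])([0-9]+)([A-Z])$")


@dataclass(frozen=True, order=True)
class Substitution:
    """One point substitution: parent residue, 1-based position, new residue."""

    position: int
    wt: str
    mut: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be 1-based positive, got {self.position}")
        for res, label in ((self.wt, "parent"), (self.mut, "mutant")):
            if res not in AA_ALPHABET:
                raise ValueError(f"{label} residue {res!r} is not a standard amino acid")

    def __str__(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"

    @classmethod
    def parse(cls, token: str) -> "Substitution":
        m = _SUB_RE.match(token)
        if m is None:
            raise ValueError(f"malformed substitution token {token!r} (expected e.g. F97W)")
        wt, pos, mut = m.groups()
        return cls(position=int(pos), wt=wt, mut=mut)


@dataclass(frozen=True)
class ProteinVariant:
    """A named set of substitutions relative to a parent."""

    parent: str
    substitutions: tuple[Substitution, ...]

    def __post_init__(self) -> None:
        subs = tuple(sorted(self.substitutions))
        positions = [s.position for s in subs]
        if len(set(positions)) != len(positions):
            dup = next(p for p in positions if positions.count(p) > 1)
            raise ValueError(f"duplicate substitution at position {dup}")
        object.__setattr__(self, "substitutions", subs)

    @property
    def name(self) -> str:
        if not self.substitutions:
            return self.parent
        return "_".join(str(s) for s in self.substitutions)

    @property
    def residue_map(self) -> dict[int, str]:
        """Map position -> substituted residue (substituted sites only)."""
        return {s.position: s.mut for s in self.substitutions}

    def residue_at(self, position: int, parent_sequence: str | None = None) -> str:
        """Residue at ``position``, falling back to the parent sequence."""
        for s in self.substitutions:
            if s.position == position:
                return s.mut
        if parent_sequence is None:
            raise ValueError(
                f"position {position} not substituted and no parent sequence given"
            )
        if position > len(parent_sequence):
            raise ValueError(f"position {position} beyond parent length {len(parent_sequence)}")
        return parent_sequence[position - 1]

    def apply(self, parent_sequence: str) -> str:
        """Full mutated sequence, validating parent letters on the way."""
        self.validate_against(parent_sequence)
        seq = list(parent_sequence)
        for s in self.substitutions:
            seq[s.position - 1] = s.mut
        return "".join(seq)

    def validate_against(self, parent_sequence: str) -> None:
        for s in self.substitutions:
            if s.position > len(parent_sequence):
                raise ValueError(
                    f"substitution {s} beyond parent length {len(parent_sequence)}"
                )
            actual = parent_sequence[s.position - 1]
            if actual != s.wt:
                raise ValueError(
                    f"substitution {s} inconsistent with parent at position "
                    f"{s.position}: parent has {actual!r}, name says {s.wt!r}"
                )


def parse_variant(name: str, parent: str = "WT") -> ProteinVariant:
    """Parse an underscore-joined substitution string into a variant.

    The parent's own name (or empty string) parses to the zero-substitution
    variant.
    """
    name = name.strip()
    if name == "" or name == parent:
        return ProteinVariant(parent=parent, substitutions=())
    subs = tuple(Substitution.parse(tok) for tok in name.split("_"))
    return ProteinVariant(parent=parent, substitutions=subs)


def variant_from_residues(
    residues: Mapping[int, str],
    parent_residues: Mapping[int, str],
    parent: str = "WT",
) -> ProteinVariant:
    """Build a variant from a site -> residue assignment.

    Sites whose residue equals the parent residue contribute no
    substitution; the remaining sites become substitutions whose wild-type
    letter is taken from ``parent_residues``.
    """
    subs = []
    for pos, res in residues.items():
        if pos not in parent_residues:
            raise ValueError(f"site {pos} has no declared parent residue")
        if res != parent_residues[pos]:
            subs.append(Substitution(position=pos, wt=parent_residues[pos], mut=res))
    return ProteinVariant(parent=parent, substitutions=tuple(subs))


def unique_names(variants: Iterable[ProteinVariant]) -> list[str]:
    names = [v.name for v in variants]
    if len(set(names)) != len(names):
        raise ValueError("variant names are not unique")
    return names
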