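"""Combinatorial library design-space arithmetic.

Degenerate-codon expansion under the standard genetic code, theoretical
library sizes, observed/expected screening coverage, knowledge-filtered
library enumeration, acquisition of screening candidates from a ranked
list, and screening-burden accounting.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .variants import ProteinVariant, Substitution

#: IUPAC nucleotide degeneracy codes.
IUPAC_NT: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_STOP = "*"


def _translate(codon: str) -> str:
    if codon in standard_dna_table.stop_codons:
        return _STOP
    return standard_dna_table.forward_table[codon]


@dataclass(frozen=True)
class DegenerateCodon:
    """A degenerate codon, its concrete expansion and translation multiset."""

    triplet: str
    codons: tuple[str, ...]
    translation: Counter = field(compare=False)

    @property
    def residues(self) -> set[str]:
        return {r for r in self.translation if r != _STOP}

    @property
    def n_stops(self) -> int:
        return self.translation.get(_STOP, 0)


def expand_degenerate_codon(triplet: str) -> DegenerateCodon:
    """Expand three IUPAC symbols into concrete codons and residues.

    The translation is a multiset over the 20 residues and the stop
    symbol ``*``; its size equals the expansion size (the product of the
    per-position degeneracies).
    """
    triplet = triplet.upper()
    if len(triplet) != 3:
        raise ValueError(f"codon must have 3 symbols, got {triplet!r}")
    for sym in triplet:
        if sym not in IUPAC_NT:
            raise ValueError(f"invalid IUPAC nucleotide symbol {sym!r}")
    codons = tuple(
        "".join(bases) for bases in itertools.product(*(IUPAC_NT[s] for s in triplet))
    )
    translation = Counter(_translate(c) for c in codons)
    return DegenerateCodon(triplet=triplet, codons=codons, translation=translation)


@dataclass(frozen=True)
class CodonScheme:
    """A mixture of degenerate codons with primer mixing ratios."""

    codons: tuple[DegenerateCodon, ...]
    ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.codons) != len(self.ratios):
            raise ValueError("one mixing ratio per degenerate codon required")
        if any(r <= 0 for r in self.ratios):
            raise ValueError("mixing ratios must be positive")

    @property
    def all_codons(self) -> tuple[str, ...]:
        return tuple(c for dc in self.codons for c in dc.codons)

    @property
    def residues(self) -> set[str]:
        return set().union(*(dc.residues for dc in self.codons))

    @property
    def n_stops(self) -> int:
        return sum(dc.n_stops for dc in self.codons)

    def residue_probabilities(self) -> dict[str, float]:
        """Probability of drawing each residue from the primer mixture.

        Each pool contributes proportionally to its ratio; concrete
        codons within a pool are equiprobable.
        """
        total = sum(self.ratios)
        probs: dict[str, float] = {}
        for dc, ratio in zip(self.codons, self.ratios):
            per_codon = ratio / total / len(dc.codons)
            for codon in dc.codons:
                res = _translate(codon)
                probs[res] = probs.get(res, 0.0) + per_codon
        return probs


def scheme_22c() -> CodonScheme:
    """The 22-codon trick: NDT/VHG/TGG mixed 12:9:1.

    The ratio is proportional to each pool's codon count, so all 22
    concrete codons are equiprobable; the union covers all 20 residues
    with no stop codons, with leucine and valine each encoded twice.
    """
    return CodonScheme(
        codons=(
            expand_degenerate_codon("NDT"),
            expand_degenerate_codon("VHG"),
            expand_degenerate_codon("TGG"),
        ),
        ratios=(12.0, 9.0, 1.0),
    )


def scheme_nnk() -> CodonScheme:
    """Single-pool NNK saturation: 32 codons, 20 residues plus one stop."""
    return CodonScheme(codons=(expand_degenerate_codon("NNK"),), ratios=(1.0,))


def theoretical_size(per_site_counts: Sequence[int]) -> int:
    """Product of per-site residue counts — the full combinatorial space."""
    if len(per_site_counts) == 0:
        raise ValueError("need at least one site count")
    counts = [int(c) for c in per_site_counts]
    if any(c < 1 for c in counts):
        raise ValueError(f"site counts must be >= 1, got {counts}")
    return int(np.prod(counts, dtype=np.int64))


def observed_coverage(unique_count: int, theoretical: int) -> float:
    """Percent of the theoretical space confirmed present (sequencing)."""
    if theoretical == 0:
        raise ValueError("theoretical size must be > 0")
    if not 0 <= unique_count <= theoretical:
        raise ValueError(
            f"unique count {unique_count} outside [0, {theoretical}]"
        )
    return 100.0 * unique_count / theoretical


def expected_coverage(
    variant_probabilities: Sequence[float], transformants: int
) -> float:
    """Expected percent of distinct variants seen after T independent draws.

    Under the independent-draws (binomial) model each variant v with
    per-transformant probability p_v is observed with probability
    1 - (1 - p_v)^T; the expected coverage is the mean over variants.
    Probabilities may sum to less than 1 (remainder = parent or
    off-target reads).
    """
    p = np.asarray(variant_probabilities, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one variant probability")
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if np.any(p > 1):
        raise ValueError(f"probability {p.max():g} exceeds 1")
    if p.sum() > 1 + 1e-9:
        raise ValueError(f"probabilities sum to {p.sum():g} > 1")
    if transformants < 0:
        raise ValueError("transformants must be >= 0")
    return 100.0 * float(np.mean(1.0 - (1.0 - p) ** transformants))


@dataclass(frozen=True)
class CoverageEstimate:
    """Bookkeeping for one library's design-space coverage."""

    theoretical: int
    observed_unique: int | None = None
    transformants: int | None = None
    observed_pct: float | None = None
    expected_pct: float | None = None

    @classmethod
    def from_counts(
        cls,
        theoretical: int,
        observed_unique: int | None = None,
        transformants: int | None = None,
        variant_probabilities: Sequence[float] | None = None,
    ) -> "CoverageEstimate":
        obs = (
            observed_coverage(observed_unique, theoretical)
            if observed_unique is not None
            else None
        )
        exp = (
            expected_coverage(variant_probabilities, transformants)
            if variant_probabilities is not None and transformants is not None
            else None
        )
        return cls(
            theoretical=theoretical,
            observed_unique=observed_unique,
            transformants=transformants,
            observed_pct=obs,
            expected_pct=exp,
        )


@dataclass(frozen=True)
class LibraryDesign:
    """A knowledge-filtered combinatorial design.

    ``modulated`` maps each varied position to its allowed residues (in
    enumeration order); ``fixed`` substitutions are appended to every
    member.  Wild-type letters come from the parent sequence, or from an
    explicit ``wt_residues`` map when no sequence is at hand.
    """

    parent_name: str
    modulated: dict[int, str]
    fixed: tuple[Substitution, ...] = ()
    parent_sequence: str | None = None
    wt_residues: dict[int, str] | None = None

    def __post_init__(self) -> None:
        for pos, allowed in self.modulated.items():
            if len(allowed) == 0:
                raise ValueError(f"empty allowed-residue set at site {pos}")
        fixed_positions = {s.position for s in self.fixed}
        overlap = fixed_positions & set(self.modulated)
        if overlap:
            raise ValueError(
                f"fixed substitutions conflict with modulated sites: {sorted(overlap)}"
            )

    def wt_at(self, position: int) -> str:
        if self.wt_residues is not None and position in self.wt_residues:
            return self.wt_residues[position]
        if self.parent_sequence is not None:
            if position > len(self.parent_sequence):
                raise ValueError(f"site {position} beyond parent sequence")
            return self.parent_sequence[position - 1]
        raise ValueError(
            f"no wild-type residue known for site {position}; supply a parent "
            "sequence or wt_residues"
        )

    @property
    def size(self) -> int:
        return theoretical_size([len(a) for a in self.modulated.values()])


def build_filtered_library(design: LibraryDesign) -> list[ProteinVariant]:
    """Enumerate the full Cartesian product of the design.

    Sites ascend, residues follow the declared alphabet order, and every
    member carries the design's fixed substitutions — a deterministic
    order suitable for reproducible plate maps.
    """
    sites = sorted(design.modulated)
    alphabets = [design.modulated[s] for s in sites]
    members: list[ProteinVariant] = []
    for combo in itertools.product(*alphabets):
        subs = list(design.fixed)
        for pos, res in zip(sites, combo):
            wt = design.wt_at(pos)
            if res != wt:
                subs.append(Substitution(position=pos, wt=wt, mut=res))
        members.append(
            ProteinVariant(parent=design.parent_name, substitutions=tuple(subs))
        )
    return members


def acquire(
    ranked: pd.DataFrame,
    n_top: int,
    n_explore: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Greedy-exploitation acquisition with random exploratory picks.

    Takes the ``n_top`` best-ranked candidates plus ``n_explore`` drawn
    uniformly without replacement from the remainder (seeded).  The
    returned frame keeps the ranking columns and adds ``provenance``
    (``exploit`` / ``explore``).
    """
    if n_top < 0 or n_explore < 0:
        raise ValueError("selection sizes must be >= 0")
    if n_top + n_explore > len(ranked):
        raise ValueError(
            f"cannot select {n_top}+{n_explore} from {len(ranked)} candidates"
        )
    exploit = ranked.iloc[:n_top].copy()
    exploit["provenance"] = "exploit"
    rest = ranked.iloc[n_top:]
    rng = np.random.default_rng(seed)
    pick = np.sort(rng.choice(len(rest), size=n_explore, replace=False)) if n_explore else []
    explore = rest.iloc[list(pick)].copy()
    explore["provenance"] = "explore"
    return pd.concat([exploit, explore])


def screening_reduction(reference_size: float, filtered_size: float) -> float:
    """Fold reduction in screening burden versus a reference design."""
    if reference_size <= 0 or filtered_size <= 0:
        raise ValueError("sizes must be > 0")
    return reference_size / filtered_size
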