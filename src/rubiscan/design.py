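"""Reference design of a single-substitution rubisco library.

A deep mutational scan of a protein of length L enumerates, for every
mutable position, the 19 amino-acid substitutions away from the wild-type
residue.  For the 466-residue Form II rubisco scanned here, every position
except the initiator methionine is mutable, giving 465 x 19 = 8,835
designed variants.  The design also carries the codon-level coding
sequence used to synthesize long reads and to classify consensus
sequences back onto the designed set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from Bio.Data import CodonTable

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

WILD_TYPE = "WT"
INVALID = "INVALID"

# One representative codon per amino acid (lexicographically smallest in the
# standard table); used to build synthetic coding sequences deterministically.
_standard = CodonTable.unambiguous_dna_by_id[1]
CODON_FOR_AA: dict[str, str] = {}
for _codon in sorted(_standard.forward_table):
    CODON_FOR_AA.setdefault(_standard.forward_table[_codon], _codon)

#: Catalytic residues of the scanned rubisco that anchor the synthetic
#: reference: active-site lysines, the KDGE motif aspartate/glutamate and
#: the carbamate-stabilizing histidine.  Substitutions at these positions
#: define the zero-activity ("dead") fitness baseline.
CATALYTIC_ANCHORS: dict[int, str] = {
    1: "M",
    166: "K",
    191: "K",
    193: "D",
    194: "E",
    287: "H",
    329: "K",
}

#: Default dead-panel positions (catalytic residues, excluding position 1).
DEFAULT_DEAD_POSITIONS: tuple[int, ...] = (166, 191, 193, 194, 287, 329)


class EmptyDesignError(ValueError):
    """Raised when a design has no mutable positions."""


@dataclass(frozen=True, order=True)
class DesignedVariant:
    """A single amino-acid substitution, 1-based position."""

    position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.mut_aa == self.wt_aa:
            raise ValueError(f"mut_aa equals wt_aa at position {self.position}")

    @property
    def variant_id(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


def all_single_substitutions(
    protein: str, mutable_positions: Iterable[int]
) -> tuple[DesignedVariant, ...]:
    """Enumerate the 19 substitutions at every mutable (1-based) position."""
    variants = []
    for pos in sorted(set(mutable_positions)):
        if not 1 <= pos <= len(protein):
            raise ValueError(f"position {pos} outside 1..{len(protein)}")
        wt = protein[pos - 1]
        for aa in AMINO_ACIDS:
            if aa != wt:
                variants.append(DesignedVariant(pos, wt, aa))
    return tuple(variants)


@dataclass(frozen=True)
class ReferenceDesign:
    """A reference protein plus its designed single-substitution library.

    Positions are 1-based with position 1 the initiator methionine.
    """

    protein: str
    mutable_positions: tuple[int, ...]
    variants: tuple[DesignedVariant, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.protein:
            raise EmptyDesignError("empty design: no protein sequence")
        if not self.mutable_positions:
            raise EmptyDesignError("empty design: no mutable positions")
        if not self.variants:
            object.__setattr__(
                self,
                "variants",
                all_single_substitutions(self.protein, self.mutable_positions),
            )

    @property
    def cds(self) -> str:
        """Coding sequence of the reference (one codon per residue)."""
        return "".join(CODON_FOR_AA[aa] for aa in self.protein)

    @property
    def variant_ids(self) -> tuple[str, ...]:
        return tuple(v.variant_id for v in self.variants)

    def variant_cds(self, variant: DesignedVariant) -> str:
        """Coding sequence with the variant's codon substituted in."""
        codons = [self.protein[i] for i in range(len(self.protein))]
        seq = [CODON_FOR_AA[aa] for aa in codons]
        seq[variant.position - 1] = CODON_FOR_AA[variant.mut_aa]
        return "".join(seq)

    def dead_panel(self, positions: Iterable[int] | None = None) -> tuple[str, ...]:
        """Variant ids at the dead-panel (catalytic) positions."""
        if positions is None:
            positions = [p for p in DEFAULT_DEAD_POSITIONS if p <= len(self.protein)]
        pos = set(positions)
        missing = pos - set(self.mutable_positions)
        if missing:
            raise ValueError(f"dead positions not in design: {sorted(missing)}")
        return tuple(v.variant_id for v in self.variants if v.position in pos)


def synthetic_protein(length: int = 466, seed: int = 0) -> str:
    """A random protein sequence anchored at the catalytic residues.

    Real sequence identity is irrelevant to the statistics under test; the
    catalytic anchors are pinned so the canonical dead-panel positions carry
    their canonical residues whenever the sequence is long enough.
    """
    rng = np.random.default_rng([0xD5, seed])
    seq = list(rng.choice(list(AMINO_ACIDS), size=length))
    for pos, aa in CATALYTIC_ANCHORS.items():
        if pos <= length:
            seq[pos - 1] = aa
    return "".join(seq)


def make_design(
    protein: str | None = None,
    length: int = 466,
    mutable_positions: Iterable[int] | None = None,
    seed: int = 0,
) -> ReferenceDesign:
    """Build a design; defaults mirror a full scan (all positions but Met1)."""
    if protein is None:
        protein = synthetic_protein(length=length, seed=seed)
    if mutable_positions is None:
        mutable_positions = range(2, len(protein) + 1)
    return ReferenceDesign(protein, tuple(mutable_positions))
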