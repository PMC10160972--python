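"""Single-substitution library model for a mutagenized kinase domain.

A saturation-mutagenesis library replaces each codon of a target domain
(here the 60-residue DHp domain of a histidine kinase, numbered in
full-protein coordinates) with an NNS degenerate codon: any base at the
first two positions, C or G at the third.  The 32 NNS codons encode all
20 amino acids plus the amber stop TAG, so the amino-acid library over a
domain of length L contains 19*L single substitutions.

This module enumerates that library and calls variants from
domain-spanning nucleotide reads.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

from Bio.Data.CodonTable import unambiguous_dna_by_id

#: The 20 standard amino acids in alphabetical one-letter order.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_CODON_TABLE = unambiguous_dna_by_id[1]  # the standard genetic code


def translate_codon(codon: str) -> str:
    """Translate a single codon under the standard genetic code.

    Returns ``"*"`` for a stop codon.
    """
    codon = codon.upper()
    if codon in _CODON_TABLE.stop_codons:
        return "*"
    return _CODON_TABLE.forward_table[codon]


@dataclass(frozen=True, order=True)
class Variant:
    """One amino-acid substitution, e.g. ``A255R``.

    Positions are 1-based full-protein residue numbers (never
    domain-local), matching the convention used for variant labels such
    as D286V.
    """

    position: int
    mut_aa: str
    wt_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa not in AA_ALPHABET or self.mut_aa not in AA_ALPHABET:
            raise ValueError(f"non-standard amino acid in {self.wt_aa}{self.position}{self.mut_aa}")
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"substitution {self.wt_aa}{self.position}{self.mut_aa} is synonymous")

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label

    @classmethod
    def from_label(cls, label: str) -> "Variant":
        """Parse a label like ``"A255R"``."""
        if len(label) < 3:
            raise ValueError(f"malformed variant label {label!r}")
        wt, pos, mut = label[0], label[1:-1], label[-1]
        if not pos.isdigit():
            raise ValueError(f"malformed variant label {label!r}")
        return cls(position=int(pos), mut_aa=mut, wt_aa=wt)


@dataclass
class DomainRegion:
    """A contiguous protein region targeted by mutagenesis.

    ``start`` and ``end`` are 1-based inclusive residue indices in
    full-protein numbering.  ``nt_sequence``, when present, is the
    in-frame coding sequence of exactly the same region.
    """

    protein_id: str
    start: int
    end: int
    aa_sequence: str
    nt_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        self.aa_sequence = self.aa_sequence.upper()
        if self.end - self.start + 1 != len(self.aa_sequence):
            raise ValueError(
                f"{self.protein_id}: region {self.start}-{self.end} does not match "
                f"sequence length {len(self.aa_sequence)}"
            )
        if len(self.aa_sequence) == 0:
            raise ValueError(f"{self.protein_id}: empty region")
        bad = set(self.aa_sequence) - set(AA_ALPHABET)
        if bad:
            raise ValueError(f"{self.protein_id}: non-standard residues {sorted(bad)}")
        if self.nt_sequence is not None:
            self.nt_sequence = self.nt_sequence.upper()
            if len(self.nt_sequence) != 3 * len(self.aa_sequence):
                raise ValueError(
                    f"{self.protein_id}: nucleotide length {len(self.nt_sequence)} is not "
                    f"3 x {len(self.aa_sequence)}"
                )
            translated = "".join(
                translate_codon(self.nt_sequence[i : i + 3])
                for i in range(0, len(self.nt_sequence), 3)
            )
            if translated != self.aa_sequence:
                raise ValueError(f"{self.protein_id}: nt_sequence does not translate to aa_sequence")

    @property
    def length(self) -> int:
        return len(self.aa_sequence)

    @property
    def positions(self) -> range:
        return range(self.start, self.end + 1)

    def aa_at(self, position: int) -> str:
        if not self.start <= position <= self.end:
            raise ValueError(f"position {position} outside region {self.start}-{self.end}")
        return self.aa_sequence[position - self.start]

    def codon_at(self, position: int) -> str:
        if self.nt_sequence is None:
            raise ValueError(f"{self.protein_id}: region has no nucleotide sequence")
        i = 3 * (position - self.start)
        return self.nt_sequence[i : i + 3]


@dataclass(frozen=True)
class CodonSet:
    """A degenerate codon family with its encoded amino acids."""

    codons: frozenset[str]
    encoded_aas: frozenset[str]
    stop_codons: frozenset[str]
    pattern: str = "NNS"


def enumerate_nns_codons() -> CodonSet:
    """Enumerate the NNS codon family (N = A/C/G/T, S = C/G).

    The family has 32 codons covering all 20 amino acids; TAG is the
    only stop codon it contains.
    """
    codons = frozenset(
        a + b + c for a, b, c in itertools.product("ACGT", "ACGT", "CG")
    )
    stops = frozenset(c for c in codons if translate_codon(c) == "*")
    aas = frozenset(translate_codon(c) for c in codons) - {"*"}
    return CodonSet(codons=codons, encoded_aas=aas, stop_codons=stops)


def enumerate_single_substitutions(region: DomainRegion) -> list[Variant]:
    """All 19*L single amino-acid substitutions over ``region``.

    Deterministic order: position ascending, mutant amino acid
    alphabetical.
    """
    variants = []
    for position in region.positions:
        wt = region.aa_at(position)
        for mut in AA_ALPHABET:
            if mut != wt:
                variants.append(Variant(position=position, mut_aa=mut, wt_aa=wt))
    return variants


# Outcome kinds for call_variant
WILD_TYPE = "wild_type"
NONSENSE = "nonsense"
REJECTED = "rejected"


@dataclass(frozen=True)
class VariantCall:
    """Outcome of calling one read against the reference region."""

    kind: str  # "wild_type" | "variant" | "nonsense" | "rejected"
    variant: Optional[Variant] = None
    reason: str = ""

    @property
    def key(self) -> str:
        """Count-table key: the variant label, ``"WT"`` or ``"nonsense"``."""
        if self.kind == "variant":
            assert self.variant is not None
            return self.variant.label
        if self.kind == WILD_TYPE:
            return "WT"
        return self.kind


def call_variant(read_nt: str, reference: DomainRegion) -> VariantCall:
    """Call a domain-spanning read as wild type, a single substitution, or rejected.

    The library is built by codon replacement, so reads are compared
    codon-wise against the reference coding sequence:

    * wrong length or ambiguous bases -> rejected (indels are artifacts);
    * zero mismatching codons, or one synonymous codon change -> wild type;
    * one codon change encoding a stop -> nonsense (tallied separately);
    * one codon change encoding another residue -> that ``Variant``;
    * two or more mismatching codons -> rejected.
    """
    if reference.nt_sequence is None:
        raise ValueError("reference region has no nucleotide sequence")
    read = read_nt.upper()
    if len(read) != len(reference.nt_sequence):
        return VariantCall(REJECTED, reason="length_mismatch")
    if set(read) - set("ACGT"):
        return VariantCall(REJECTED, reason="ambiguous_bases")

    mismatched = [
        i
        for i in range(0, len(read), 3)
        if read[i : i + 3] != reference.nt_sequence[i : i + 3]
    ]
    if not mismatched:
        return VariantCall(WILD_TYPE)
    if len(mismatched) > 1:
        return VariantCall(REJECTED, reason="multiple_codon_mismatches")

    i = mismatched[0]
    position = reference.start + i // 3
    aa = translate_codon(read[i : i + 3])
    wt = reference.aa_at(position)
    if aa == "*":
        return VariantCall(NONSENSE)
    if aa == wt:
        return VariantCall(WILD_TYPE, reason="synonymous")
    return VariantCall("variant", variant=Variant(position=position, mut_aa=aa, wt_aa=wt))
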