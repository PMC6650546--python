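"""Immutable genetic-code and nucleobase chemistry tables.

The whole package works on the standard bacterial genetic code (NCBI
translation table 11, whose sense-codon assignments coincide with the
universal code): 61 sense codons, 3 stop codons, and the familiar
degeneracy structure (Met and Trp are single-codon amino acids; Ile is
the lone 3-fold family; Leu, Ser and Arg are 6-fold).

Elemental accounting of transcripts uses the atomic composition of the
four RNA nucleobases only (adenine C5H5N5, guanine C5H5N5O, cytosine
C4H5N3O, uracil C4H4N2O2).  The ribose-phosphate backbone contributes
an identical constant per residue and cancels in every comparison the
pipeline makes, so it is deliberately left out.

The split of the 20 standard amino acids into a "prebiotic"
(metabolically inexpensive) half and a "modern" (expensive) half
follows the consensus early-amino-acid set of the origin-of-life
literature: Gly, Ala, Asp, Glu, Val, Ser, Ile, Leu, Pro, Thr.
"""

from __future__ import annotations

from collections import namedtuple

from Bio.Data import CodonTable as _BioCodonTable

__all__ = [
    "ElementCounts",
    "CODON_TO_AA",
    "STOP_CODONS",
    "SENSE_CODONS",
    "AMINO_ACIDS",
    "SYNONYMOUS_FAMILIES",
    "DEGENERACY",
    "BASE_ATOMS",
    "PREBIOTIC_AMINO_ACIDS",
    "MODERN_AMINO_ACIDS",
    "PYRIMIDINES",
    "PURINES",
    "translate",
    "base_atom_counts",
    "codons_of",
    "dna_to_rna",
    "reverse_complement_rna",
    "CodonValidationError",
]

ElementCounts = namedtuple("ElementCounts", ["C", "H", "N", "O"])

_TABLE = _BioCodonTable.unambiguous_dna_by_id[11]

#: codon (DNA alphabet) -> one-letter amino acid, 61 sense codons
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(CODON_TO_AA.values())))

#: amino acid -> tuple of synonymous codons (DNA alphabet, sorted)
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in AMINO_ACIDS
}

#: amino acid -> family size (1, 2, 3, 4 or 6)
DEGENERACY: dict[str, int] = {aa: len(f) for aa, f in SYNONYMOUS_FAMILIES.items()}

#: RNA base -> atoms of C, H, N, O in the free nucleobase
BASE_ATOMS: dict[str, ElementCounts] = {
    "A": ElementCounts(C=5, H=5, N=5, O=0),
    "G": ElementCounts(C=5, H=5, N=5, O=1),
    "C": ElementCounts(C=4, H=5, N=3, O=1),
    "U": ElementCounts(C=4, H=4, N=2, O=2),
}

PYRIMIDINES = frozenset("CU")
PURINES = frozenset("AG")

#: amino acids plausibly available before biosynthetic pathways evolved
PREBIOTIC_AMINO_ACIDS: frozenset[str] = frozenset("GADEVSILPT")
#: the complementary, biosynthetically expensive half
MODERN_AMINO_ACIDS: frozenset[str] = frozenset(AMINO_ACIDS) - PREBIOTIC_AMINO_ACIDS

_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


class CodonValidationError(ValueError):
    """A DNA string is not a valid coding sequence."""


def dna_to_rna(seq: str) -> str:
    """Transcribe the sense strand: T -> U."""
    return seq.replace("T", "U")


def reverse_complement_rna(seq: str) -> str:
    """Reverse complement of an RNA string (e.g. codon -> anticodon)."""
    return "".join(_RNA_COMPLEMENT[b] for b in reversed(seq))


def codons_of(dna: str) -> list[str]:
    """Split a validated DNA string into consecutive triplets."""
    return [dna[i : i + 3] for i in range(0, len(dna), 3)]


def base_atom_counts(base: str) -> ElementCounts:
    """Atomic C/H/N/O composition of one RNA nucleobase.

    ``T`` is accepted as a DNA-alphabet alias for ``U`` (the pipeline
    reasons about transcripts, so thymine never appears chemically).
    """
    b = base.upper().replace("T", "U")
    try:
        return BASE_ATOMS[b]
    except KeyError:
        raise ValueError(f"unknown base {base!r}") from None


def translate(cds: str) -> str:
    """Translate a coding sequence under the bacterial code.

    A single terminal stop codon is allowed and dropped.  Internal stop
    codons, non-ACGT characters and lengths that are not a multiple of
    three raise :class:`CodonValidationError`.
    """
    seq = cds.upper()
    if not seq:
        raise CodonValidationError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise CodonValidationError(f"non-ACGT characters: {sorted(bad)}")
    if len(seq) % 3 != 0:
        raise CodonValidationError(f"length {len(seq)} not a multiple of 3")
    codons = codons_of(seq)
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    protein = []
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise CodonValidationError(f"internal stop codon {codon} at codon {i}")
        protein.append(CODON_TO_AA[codon])
    return "".join(protein)
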