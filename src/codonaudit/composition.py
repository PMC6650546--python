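"""Nucleotide- and amino-acid-level composition metrics of single CDSs.

Conventions: GC3, amino-acid usage and the per-codon element demand are
codon-family metrics and therefore exclude the terminal stop codon;
whole-sequence GC and pyrimidine fraction include it, because the stop
codon is transcribed and paid for.  The two conventions differ by well
under 1% for realistic gene lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _scistats

from .genetic_code import (
    AMINO_ACIDS,
    BASE_ATOMS,
    ElementCounts,
    MODERN_AMINO_ACIDS,
    PREBIOTIC_AMINO_ACIDS,
    PYRIMIDINES,
)
from .io import CodingSequence

__all__ = [
    "gc_content",
    "gc3_content",
    "pyrimidine_fraction",
    "element_per_codon",
    "amino_acid_usage",
    "composition_record",
    "composition_table",
    "ClassUsageResult",
    "class_usage_comparison",
]


def gc_content(seq: str) -> float:
    """(G + C) / length of any non-empty ACGT/ACGU string."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def gc3_content(cds: CodingSequence) -> float:
    """Fraction of sense codons whose third base is G or C."""
    if not cds.codons:
        raise ValueError(f"{cds.gene_id}: no sense codons")
    third = [c[2] for c in cds.codons]
    return sum(b in "GC" for b in third) / len(third)


def pyrimidine_fraction(cds: CodingSequence) -> float:
    """(C + U) / length over the whole transcript (sense strand)."""
    rna = cds.dna.replace("T", "U")
    if not rna:
        raise ValueError(f"{cds.gene_id}: empty sequence")
    return sum(b in PYRIMIDINES for b in rna) / len(rna)


def element_per_codon(cds: CodingSequence) -> ElementCounts:
    """Mean C/H/N/O nucleobase atoms per sense codon (stop excluded)."""
    if not cds.codons:
        raise ValueError(f"{cds.gene_id}: no sense codons")
    totals = np.zeros(4)
    for codon in cds.codons:
        for base in codon.replace("T", "U"):
            totals += BASE_ATOMS[base]
    return ElementCounts(*(totals / len(cds.codons)))


def amino_acid_usage(protein: str) -> dict[str, float]:
    """Per-amino-acid fractional usage of a protein; sums to 1."""
    if not protein:
        raise ValueError("empty protein")
    n = len(protein)
    return {aa: protein.count(aa) / n for aa in AMINO_ACIDS}


def composition_record(cds: CodingSequence) -> dict:
    """All composition metrics of one CDS as a flat record."""
    atoms = element_per_codon(cds)
    rec = {
        "gene_id": cds.gene_id,
        "length_codons": len(cds.codons),
        "gc": gc_content(cds.dna),
        "gc3": gc3_content(cds),
        "pyrimidine_fraction": pyrimidine_fraction(cds),
        "atoms_C_per_codon": atoms.C,
        "atoms_H_per_codon": atoms.H,
        "atoms_N_per_codon": atoms.N,
        "atoms_O_per_codon": atoms.O,
    }
    usage = amino_acid_usage(cds.protein)
    for aa in AMINO_ACIDS:
        rec[f"usage_{aa}"] = usage[aa]
    return rec


def composition_table(sequences: list[CodingSequence]) -> pd.DataFrame:
    """Composition records for a list of CDSs, one row per gene."""
    return pd.DataFrame([composition_record(c) for c in sequences])


@dataclass
class ClassUsageResult:
    """Prebiotic-vs-modern amino-acid usage comparison of a gene set."""

    prebiotic_values: np.ndarray  # one value per (protein, prebiotic aa)
    modern_values: np.ndarray
    median_prebiotic: float
    median_modern: float
    t_statistic: float
    p_value: float
    confidence_level: float = 0.99


def class_usage_comparison(
    proteins: list[str],
    prebiotic: frozenset[str] = PREBIOTIC_AMINO_ACIDS,
    modern: frozenset[str] = MODERN_AMINO_ACIDS,
) -> ClassUsageResult:
    """Compare usage of inexpensive (prebiotic) vs expensive amino acids.

    For every protein the fractional usage of each of the 20 amino acids
    is computed; the 10 prebiotic values and the 10 modern values per
    protein are pooled into two samples and compared with a two-sided
    Welch t test (reported at the 99% confidence convention).
    """
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    if not prebiotic or not modern:
        raise ValueError("amino-acid classes must be non-empty")
    pre, mod = [], []
    for protein in proteins:
        usage = amino_acid_usage(protein)
        pre.extend(usage[aa] for aa in sorted(prebiotic))
        mod.extend(usage[aa] for aa in sorted(modern))
    pre = np.asarray(pre)
    mod = np.asarray(mod)
    t, p = _scistats.ttest_ind(pre, mod, equal_var=False)
    return ClassUsageResult(
        prebiotic_values=pre,
        modern_values=mod,
        median_prebiotic=float(np.median(pre)),
        median_modern=float(np.median(mod)),
        t_statistic=float(t),
        p_value=float(p),
    )
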