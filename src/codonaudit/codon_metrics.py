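"""Codon usage bias metrics: RSCU, CAI, ENC and percentile ranks.

RSCU (relative synonymous codon usage) is the observed count of a codon
divided by its expected count under uniform use within its synonymous
family; 1.0 is the neutral line.  CAI (codon adaptation index) is the
geometric mean of per-codon relative adaptiveness w against a reference
codon-usage set; here two references are used throughout the pipeline,
the whole genome and the ribosomal-protein genes.  ENC (effective
number of codons) is Wright's estimator, ranging from 20 (one codon per
amino acid) to 61 (uniform use of all sense codons).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .genetic_code import (
    CODON_TO_AA,
    DEGENERACY,
    SENSE_CODONS,
    SYNONYMOUS_FAMILIES,
)
from .io import CodingSequence

__all__ = [
    "codon_counts",
    "rscu",
    "relative_adaptiveness",
    "cai",
    "ENCRecord",
    "enc",
    "percentile_ranks",
    "median_rscu_profile",
    "accuracy_regression_inputs",
]

#: family sizes with more than one synonymous codon, used by ENC
_ENC_CLASS_WEIGHTS = {2: 9, 3: 1, 4: 5, 6: 3}


def codon_counts(source) -> Counter:
    """Count sense codons of a CDS, a codon list, or many CDSs pooled."""
    counts: Counter = Counter()
    if isinstance(source, CodingSequence):
        counts.update(source.codons)
    elif isinstance(source, (list, tuple)) and source and isinstance(
        source[0], CodingSequence
    ):
        for cds in source:
            counts.update(cds.codons)
    else:
        counts.update(source)
    for codon in list(counts):
        if codon not in CODON_TO_AA:
            raise ValueError(f"not a sense codon: {codon!r}")
    return counts


def rscu(counts) -> dict[str, float]:
    """RSCU per sense codon: RSCU_c = k * n_c / sum over the family.

    Codons of amino acids absent from the input are flagged as absent
    with ``nan`` (a gene expresses no preference about families it never
    uses), not as 0.
    """
    counts = codon_counts(counts) if not isinstance(counts, Counter) else counts
    if sum(counts.values()) == 0:
        raise ValueError("no codons counted")
    out: dict[str, float] = {}
    for family in SYNONYMOUS_FAMILIES.values():
        k = len(family)
        total = sum(counts.get(c, 0) for c in family)
        for c in family:
            out[c] = k * counts.get(c, 0) / total if total > 0 else math.nan
    return out


def relative_adaptiveness(
    reference_counts, pseudocount: float = 0.5
) -> dict[str, float]:
    """Per-codon relative adaptiveness w of a reference codon usage.

    w_c = RSCU_c / max RSCU within the codon's family, computed after
    adding ``pseudocount`` to every sense-codon count so that codons
    unobserved in the reference get a small positive w instead of 0.
    """
    counts = codon_counts(reference_counts)
    if sum(counts.values()) == 0:
        raise ValueError("empty reference")
    adjusted = Counter({c: counts.get(c, 0) + pseudocount for c in SENSE_CODONS})
    values = rscu(adjusted)
    w: dict[str, float] = {}
    for family in SYNONYMOUS_FAMILIES.values():
        top = max(values[c] for c in family)
        for c in family:
            w[c] = values[c] / top
    return w


def cai(cds: CodingSequence, w: dict[str, float]) -> float:
    """Codon adaptation index: geometric mean of w over the CDS's codons.

    Single-codon families (Met, Trp) and stop codons are excluded, the
    classic convention: they carry no synonymous choice.
    """
    log_sum = 0.0
    n = 0
    for codon in cds.codons:
        if DEGENERACY[CODON_TO_AA[codon]] == 1:
            continue
        wc = w[codon]
        if wc <= 0:
            raise ValueError(f"non-positive adaptiveness for {codon}")
        log_sum += math.log(wc)
        n += 1
    if n == 0:
        raise ValueError(f"{cds.gene_id}: only single-codon families present")
    return math.exp(log_sum / n)


@dataclass
class ENCRecord:
    gene_id: str
    enc: float
    #: mean homozygosity per degeneracy class (2, 3, 4, 6); nan if missing
    f_bar: dict[int, float] = field(default_factory=dict)
    clipped: bool = False


def enc(cds: CodingSequence) -> ENCRecord:
    """Wright's effective number of codons for one CDS.

    Per family with sample size n >= 2 the codon homozygosity is
    F = (n * sum p^2 - 1) / (n - 1); class means F_k feed
    ENC = 2 + 9/F_2 + 1/F_3 + 5/F_4 + 3/F_6.  A missing 3-fold class is
    imputed as (F_2 + F_4)/2; any other missing class drops its term
    and the partial sum is rescaled so that its ceiling maps to 61.
    Estimates above 61 are clipped down to 61; values below 20 are left
    untouched so that defects surface instead of being hidden.
    """
    counts = codon_counts(cds)
    f_hat: dict[int, list[float]] = {k: [] for k in _ENC_CLASS_WEIGHTS}
    for aa, family in SYNONYMOUS_FAMILIES.items():
        k = len(family)
        if k == 1:
            continue
        n = sum(counts.get(c, 0) for c in family)
        if n < 2:
            continue
        sum_p2 = sum((counts.get(c, 0) / n) ** 2 for c in family)
        f_hat[k].append((n * sum_p2 - 1) / (n - 1))
    f_bar = {
        k: (float(np.mean(v)) if v else math.nan) for k, v in f_hat.items()
    }
    if math.isnan(f_bar[3]) and not (math.isnan(f_bar[2]) or math.isnan(f_bar[4])):
        f_bar = dict(f_bar)
        f_bar[3] = (f_bar[2] + f_bar[4]) / 2
        imputed3 = True
    else:
        imputed3 = False
    present = {
        k for k, fb in f_bar.items() if not math.isnan(fb) and fb > 0
    }
    if not present:
        raise ValueError(f"{cds.gene_id}: too short to estimate any codon family")
    partial = 2.0 + sum(_ENC_CLASS_WEIGHTS[k] / f_bar[k] for k in present)
    ceiling = 2.0 + sum(_ENC_CLASS_WEIGHTS[k] * k for k in present)
    value = partial * 61.0 / ceiling
    clipped = value > 61.0
    value = min(value, 61.0)
    report_f_bar = dict(f_bar)
    if imputed3:
        report_f_bar[3] = f_bar[3]
    return ENCRecord(gene_id=cds.gene_id, enc=value, f_bar=report_f_bar, clipped=clipped)


def percentile_ranks(values) -> np.ndarray:
    """Percentile rank of each value within its own distribution.

    rank(x) = 100 * #{v <= x} / N, so the maximum is always 100 and
    ties share the same rank.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values")
    return 100.0 * (arr[:, None] >= arr[None, :]).mean(axis=1)


def median_rscu_profile(sequences: list[CodingSequence]) -> dict[str, float]:
    """Per-codon median RSCU across a gene set's members.

    Genes in which a codon's amino acid is absent contribute nothing for
    that codon (nan-aware median); a codon absent from every gene stays
    nan.
    """
    if not sequences:
        raise ValueError("empty gene set")
    per_gene = [rscu(codon_counts(cds)) for cds in sequences]
    out: dict[str, float] = {}
    for codon in SENSE_CODONS:
        vals = [r[codon] for r in per_gene if not math.isnan(r[codon])]
        out[codon] = float(np.median(vals)) if vals else math.nan
    return out


def accuracy_regression_inputs(sequences: list[CodingSequence]):
    """Per amino acid (degeneracy >= 2): (median max-RSCU, median usage).

    The x variable is the largest across-gene median RSCU among the
    amino acid's codons (how sharply its preferred codon is favored);
    the y variable is the median fractional usage of the amino acid
    across the set's proteins.  Amino acids absent from every protein
    are dropped and reported.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two genes")
    from .composition import amino_acid_usage

    medians = median_rscu_profile(sequences)
    usages = [amino_acid_usage(cds.protein) for cds in sequences]
    pairs: dict[str, tuple[float, float]] = {}
    dropped: list[str] = []
    for aa, family in SYNONYMOUS_FAMILIES.items():
        if len(family) < 2:
            continue
        max_rscu = max(
            (medians[c] for c in family if not math.isnan(medians[c])),
            default=math.nan,
        )
        if math.isnan(max_rscu):
            dropped.append(aa)
            continue
        med_usage = float(np.median([u[aa] for u in usages]))
        pairs[aa] = (max_rscu, med_usage)
    return pairs, dropped
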