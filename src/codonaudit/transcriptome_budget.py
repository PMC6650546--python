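"""Abundance-weighted ribonucleotide and elemental budgets.

The "transcriptome" here is the abundance-weighted pool of all
transcribed CDSs (no rRNA/tRNA species): each gene's base counts are
weighted by its normalized mRNA abundance, summed, and normalized to
fractions.  Operon-removal shifts, random-combination nulls, per-set
element deltas and abundance-vs-element correlations all build on this
object.

Two averaging conventions coexist deliberately: the transcriptome
budget is abundance-weighted, while set-level per-codon element means
are unweighted across member genes (each gene is one observation of a
coding strategy).  Both are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _scistats

from .composition import element_per_codon, pyrimidine_fraction
from .genetic_code import ElementCounts, PYRIMIDINES
from .io import CodingSequence, ExpressionTable, GeneSetMap

__all__ = [
    "RibonucleotideBudget",
    "transcriptome_composition",
    "RemovalShift",
    "removal_effect",
    "NullSummary",
    "random_combination_null",
    "element_delta",
    "abundance_element_correlation",
    "transcribed_universe",
]

_BASES = ("A", "G", "C", "U")


@dataclass
class RibonucleotideBudget:
    """Fractions of A, G, C, U over the abundance-weighted transcriptome."""

    fractions: dict[str, float]
    #: genes present in the expression table but lacking a sequence
    missing_sequences: list[str] = field(default_factory=list)

    @property
    def purine_fraction(self) -> float:
        return self.fractions["A"] + self.fractions["G"]

    @property
    def pyrimidine_fraction(self) -> float:
        return self.fractions["C"] + self.fractions["U"]

    @property
    def gc_fraction(self) -> float:
        return self.fractions["G"] + self.fractions["C"]

    @property
    def u_fraction(self) -> float:
        return self.fractions["U"]


def _base_counts(cds: CodingSequence) -> np.ndarray:
    rna = cds.dna.replace("T", "U")
    return np.array([rna.count(b) for b in _BASES], dtype=float)


def transcriptome_composition(
    expression: ExpressionTable, sequences: list[CodingSequence]
) -> RibonucleotideBudget:
    """Total ribonucleotide composition of the transcriptome.

    Each base's pool count is sum over genes of abundance * count in
    the full transcript (stop codon included; it is transcribed).
    Scaling all abundances leaves the fractions unchanged.
    """
    by_id = {c.gene_id: c for c in sequences}
    totals = np.zeros(4)
    missing = []
    used = 0
    for gene, abundance in expression.abundance.items():
        cds = by_id.get(gene)
        if cds is None:
            missing.append(gene)
            continue
        if abundance > 0:
            totals += abundance * _base_counts(cds)
            used += 1
    if used == 0:
        raise ValueError("no overlap between expression table and sequences")
    fractions = dict(zip(_BASES, totals / totals.sum()))
    return RibonucleotideBudget(fractions=fractions, missing_sequences=sorted(missing))


@dataclass
class RemovalShift:
    """Composition change, in percentage points, when a set is removed."""

    set_label: str
    #: per-base shift: budget(all) - budget(all minus set)
    base_shifts_pp: dict[str, float]
    purine_shift_pp: float
    gc_shift_pp: float
    u_shift_pp: float


def removal_effect(
    expression: ExpressionTable,
    sequences: list[CodingSequence],
    gene_sets: GeneSetMap,
    set_label: str,
) -> RemovalShift:
    """Effect of deleting one gene set's transcripts from the transcriptome.

    Shifts are budget(all) - budget(without set), in percentage points;
    removing a set with zero abundance gives all-zero shifts, and the
    four base shifts always sum to zero.
    """
    members = set(gene_sets.members(set_label, universe=[c.gene_id for c in sequences]))
    if not members:
        raise ValueError(f"unknown or empty set {set_label!r}")
    full = transcriptome_composition(expression, sequences)
    kept_dict = {g: a for g, a in expression.abundance.items() if g not in members}
    if not any(a > 0 for a in kept_dict.values()):
        raise ValueError("removal empties the transcriptome")
    reduced = transcriptome_composition(ExpressionTable(kept_dict), sequences)
    shifts = {
        b: 100.0 * (full.fractions[b] - reduced.fractions[b]) for b in _BASES
    }
    return RemovalShift(
        set_label=set_label,
        base_shifts_pp=shifts,
        purine_shift_pp=shifts["A"] + shifts["G"],
        gc_shift_pp=shifts["G"] + shifts["C"],
        u_shift_pp=shifts["U"],
    )


@dataclass
class NullSummary:
    """Random-combination null for one statistic and one focal set."""

    statistic: str
    focal_set: str
    focal_value: float
    direction: str  # "greater" or "less": how a draw beats the focal set
    n_draws: int
    k: int
    exceedance: float
    sampled_means: np.ndarray
    seed: int


_STATISTICS = {
    "pyrimidine_per_base": lambda cds: pyrimidine_fraction(cds),
    "atoms_C_per_codon": lambda cds: element_per_codon(cds).C,
    "atoms_H_per_codon": lambda cds: element_per_codon(cds).H,
    "atoms_N_per_codon": lambda cds: element_per_codon(cds).N,
    "atoms_O_per_codon": lambda cds: element_per_codon(cds).O,
}

#: the direction in which the planted/focal operon is expected to be
#: extreme: pyrimidine-rich, element-cheap in C/H/N, element-costly in O
DEFAULT_DIRECTIONS = {
    "pyrimidine_per_base": "greater",
    "atoms_C_per_codon": "less",
    "atoms_H_per_codon": "less",
    "atoms_N_per_codon": "less",
    "atoms_O_per_codon": "greater",
}


def random_combination_null(
    sequences: list[CodingSequence],
    focal_ids: list[str],
    statistic: str,
    seed: int,
    k: int = 3,
    n_draws: int = 1000,
    direction: str | None = None,
) -> NullSummary:
    """Compare a focal gene set against random k-gene combinations.

    Draws ``n_draws`` samples of ``k`` distinct sequences (without
    replacement within a draw, draws independent), computes the mean
    statistic per draw, and reports the exceedance: the fraction of
    draws strictly beyond the focal-set mean in the stated direction
    ("greater": draw mean > focal; "less": draw mean < focal).
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if k > len(sequences):
        raise ValueError("k larger than the candidate pool")
    direction = direction or DEFAULT_DIRECTIONS[statistic]
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    fn = _STATISTICS[statistic]
    values = np.array([fn(c) for c in sequences])
    by_id = {c.gene_id: i for i, c in enumerate(sequences)}
    try:
        focal_idx = [by_id[g] for g in focal_ids]
    except KeyError as exc:
        raise ValueError(f"focal gene missing from sequences: {exc}") from exc
    if not focal_idx:
        raise ValueError("empty focal set")
    focal_value = float(values[focal_idx].mean())
    rng = np.random.default_rng(seed)
    n = len(sequences)
    means = np.empty(n_draws)
    for i in range(n_draws):
        means[i] = values[rng.choice(n, size=k, replace=False)].mean()
    if direction == "greater":
        exceed = float(np.mean(means > focal_value))
    else:
        exceed = float(np.mean(means < focal_value))
    return NullSummary(
        statistic=statistic,
        focal_set=",".join(focal_ids),
        focal_value=focal_value,
        direction=direction,
        n_draws=n_draws,
        k=k,
        exceedance=exceed,
        sampled_means=means,
        seed=seed,
    )


def transcribed_universe(
    expression: ExpressionTable, sequences: list[CodingSequence], floor: float = 0.0
) -> list[CodingSequence]:
    """Genes counted as transcribed: abundance strictly above ``floor``."""
    return [
        c
        for c in sequences
        if c.gene_id in expression and expression.get(c.gene_id) > floor
    ]


def element_delta(
    sequences: list[CodingSequence],
    gene_sets: GeneSetMap,
    transcribed_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-set mean atoms/codon minus the genome-scale mean, per element.

    Means are unweighted across member genes.  The "genome" row is zero
    by construction, and for any partition of the universe the
    size-weighted deltas sum to zero per element.
    """
    if transcribed_ids is not None:
        universe = [c for c in sequences if c.gene_id in set(transcribed_ids)]
    else:
        universe = list(sequences)
    if not universe:
        raise ValueError("empty transcribed universe")
    atoms = {c.gene_id: np.array(element_per_codon(c)) for c in universe}
    genome_mean = np.mean([atoms[g] for g in atoms], axis=0)
    ids = [c.gene_id for c in universe]
    rows = []
    for label in ["genome"] + gene_sets.labels:
        members = [g for g in gene_sets.members(label, universe=ids) if g in atoms]
        if not members:
            continue
        set_mean = np.mean([atoms[g] for g in members], axis=0)
        delta = set_mean - genome_mean
        rows.append(
            {
                "set_label": label,
                "n_genes": len(members),
                **{
                    f"mean_{el}_per_codon": set_mean[i]
                    for i, el in enumerate(ElementCounts._fields)
                },
                **{
                    f"delta_{el}": delta[i]
                    for i, el in enumerate(ElementCounts._fields)
                },
            }
        )
    return pd.DataFrame(rows)


def abundance_element_correlation(
    expression: ExpressionTable, sequences: list[CodingSequence]
) -> pd.DataFrame:
    """Pearson r (with Fisher-z 95% CI) of atoms/codon vs mRNA abundance.

    A genome-wide cost-abundance trend would show up here; a focal
    operon that is cheap *and* abundant without such a trend is the
    interesting case.
    """
    paired = [c for c in sequences if c.gene_id in expression]
    if len(paired) < 3:
        raise ValueError("need at least three genes with both data types")
    abundance = np.array([expression.get(c.gene_id) for c in paired])
    if np.ptp(abundance) == 0:
        raise ValueError("zero variance in abundance")
    atoms = np.array([element_per_codon(c) for c in paired])
    rows = []
    n = len(paired)
    for i, el in enumerate(ElementCounts._fields):
        x = atoms[:, i]
        if np.ptp(x) == 0:
            raise ValueError(f"zero variance in {el} per codon")
        r, p = _scistats.pearsonr(x, abundance)
        z = math.atanh(max(min(r, 1 - 1e-15), -1 + 1e-15))
        half = 1.959963984540054 / math.sqrt(n - 3)
        rows.append(
            {
                "element": el,
                "pearson_r": float(r),
                "p_value": float(p),
                "ci95_low": math.tanh(z - half),
                "ci95_high": math.tanh(z + half),
                "n": n,
            }
        )
    return pd.DataFrame(rows)
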