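"""Synthetic genomes with a planted, pmoCAB-like operon signature.

The generator emulates the statistical structure the audit assumes in
real data, so every pipeline stage can be exercised end to end without
downloads:

* a GC3-rich background codon-usage profile for the bulk of the genes
  (the genomic norm of a type Ia-like genome, where GC3 exceeds GC);
* a ribosomal gene set whose profile prefers pyrimidine-ending codons,
  standing in for the codon usage of highly expressed genes;
* a planted three-gene operon whose profile is (a) low in GC3 so that
  GC3 < GC, (b) pyrimidine-enriched at the third position, and
  (c) rank-correlated with the ribosomal profile's preferred codons
  while being sharper, i.e. divergent in frequency from the genome at
  large;
* a tRNA pool whose gene copy numbers are proportional to the
  background codon usage (Watson-Crick anticodons), optionally
  excluding anticodons with cytosine at the 3' end, after which a
  coverage pass guarantees every sense codon stays readable by adding
  single-copy anticodons;
* log-normally distributed transcript abundances with the planted
  operon boosted to the top of the distribution.

Amino-acid composition is drawn from a fixed global frequency vector
(configurable per gene set) rather than varying per gene, which keeps
the usage regressions interpretable.  For the planted set the
per-family sharpness of codon preference scales with the amino acid's
usage, planting the linear max-RSCU vs usage structure that the
translation-accuracy regression is designed to detect.

A single integer seed governs every draw; it is recorded in the truth
record, and a fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .genetic_code import (
    AMINO_ACIDS,
    SYNONYMOUS_FAMILIES,
    reverse_complement_rna,
    dna_to_rna,
)
from .io import (
    CodingSequence,
    ExpressionTable,
    GeneSetMap,
    TRNAPool,
    write_cds_fasta,
    write_expression_table,
    write_gene_sets,
    write_json,
    write_trna_pool,
)
from .trna_adaptation import PairingRule, absolute_adaptiveness

__all__ = [
    "UsageProfile",
    "make_profile",
    "SyntheticGenomeSpec",
    "SyntheticDataset",
    "generate_genome",
    "DEFAULT_AA_FREQS",
    "PLANTED_AA_FREQS",
]

#: global amino-acid frequencies typical of a bacterial proteome
DEFAULT_AA_FREQS: dict[str, float] = {
    "A": 0.095, "C": 0.012, "D": 0.054, "E": 0.058, "F": 0.039,
    "G": 0.074, "H": 0.022, "I": 0.060, "K": 0.044, "L": 0.105,
    "M": 0.024, "N": 0.040, "P": 0.044, "Q": 0.039, "R": 0.055,
    "S": 0.058, "T": 0.054, "V": 0.072, "W": 0.012, "Y": 0.029,
}

#: planted-operon amino-acid frequencies, tilted toward residues whose
#: codons are pyrimidine-rich at the first two positions (F, L, S, P,
#: I, T, V, Y), which together with the third-position preference makes
#: the planted transcripts pyrimidine-majority
PLANTED_AA_FREQS: dict[str, float] = {
    "A": 0.070, "C": 0.012, "D": 0.045, "E": 0.040, "F": 0.060,
    "G": 0.060, "H": 0.020, "I": 0.070, "K": 0.030, "L": 0.130,
    "M": 0.022, "N": 0.030, "P": 0.060, "Q": 0.028, "R": 0.035,
    "S": 0.090, "T": 0.070, "V": 0.065, "W": 0.008, "Y": 0.055,
}


@dataclass
class UsageProfile:
    """Per amino-acid family: probability vector over synonymous codons."""

    probs: dict[str, dict[str, float]]

    def __post_init__(self):
        for aa, vec in self.probs.items():
            total = sum(vec.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"{aa}: family probabilities sum to {total}")
            if any(p < 0 for p in vec.values()):
                raise ValueError(f"{aa}: negative probability")

    def family(self, aa: str) -> tuple[list[str], np.ndarray]:
        vec = self.probs[aa]
        codons = sorted(vec)
        return codons, np.array([vec[c] for c in codons])

    def prob(self, codon: str) -> float:
        from .genetic_code import CODON_TO_AA

        return self.probs[CODON_TO_AA[codon]][codon]

    def expected_codon_usage(self, aa_freqs: dict[str, float]) -> dict[str, float]:
        """Genome-wide expected codon frequencies under aa_freqs."""
        total = sum(aa_freqs.values())
        usage: dict[str, float] = {}
        for aa, vec in self.probs.items():
            for codon, p in vec.items():
                usage[codon] = aa_freqs.get(aa, 0.0) / total * p
        return usage


_RULE_WEIGHTS = {
    "none": {"A": 1.0, "C": 1.0, "G": 1.0, "T": 1.0},
    # prefer C over G among strong bases and T over A among weak ones
    "pyrimidine": {"A": 0.6, "C": 1.5, "G": 0.6, "T": 1.5},
    "purine": {"A": 1.5, "C": 0.6, "G": 1.5, "T": 0.6},
}


def make_profile(
    target_gc3: float,
    bias_strength: float,
    preferred_rule: str = "none",
    family_strength: dict[str, float] | None = None,
) -> UsageProfile:
    """Build a codon-usage profile tilted by third-base composition.

    Within each synonymous family, a codon's weight is ``target_gc3``
    if its third base is G/C and ``1 - target_gc3`` otherwise,
    multiplied by the ``preferred_rule`` third-base ranking and raised
    to the power ``bias_strength`` (0 gives uniform families; large
    values collapse each family onto its preferred codon).
    ``family_strength`` optionally scales the exponent per amino acid,
    which is how the accuracy-regression structure is planted.
    """
    if not 0.0 <= target_gc3 <= 1.0:
        raise ValueError("target_gc3 must be a fraction in [0, 1]")
    if bias_strength < 0:
        raise ValueError("bias_strength must be >= 0")
    rank = _RULE_WEIGHTS[preferred_rule]
    probs: dict[str, dict[str, float]] = {}
    for aa, family in SYNONYMOUS_FAMILIES.items():
        exponent = bias_strength * (family_strength or {}).get(aa, 1.0)
        weights = []
        for codon in family:
            third = codon[2]
            gc_w = target_gc3 if third in "GC" else 1.0 - target_gc3
            weights.append((max(gc_w, 1e-12) * rank[third]) ** exponent)
        weights = np.asarray(weights)
        weights = weights / weights.sum()
        probs[aa] = dict(zip(family, weights))
    return UsageProfile(probs)


@dataclass
class SyntheticGenomeSpec:
    """Study conditions for one synthetic genome.

    Defaults plant a strong, pmoCAB-like signature: a three-gene operon
    with low GC3, pyrimidine enrichment, ribosomal-like codon ranking
    and top-of-distribution expression, inside a genome of 300
    background genes and 20 ribosomal genes.  ``planted_enabled=False``
    draws the operon from the background conditions, abolishing every
    signature (the negative control).
    """

    n_background: int = 300
    n_ribosomal: int = 20
    n_planted: int = 3
    planted_label: str = "planted_operon"

    # gene lengths in codons: lognormal, clipped below
    length_meanlog: float = 5.3
    length_sdlog: float = 0.35
    min_length: int = 80
    #: fixed planted-gene lengths (codons), sized like a real pmoCAB
    #: operon (pmoC ~252, pmoA ~414, pmoB ~415 residues); recycled if
    #: n_planted differs from 3
    planted_lengths: tuple[int, ...] = (252, 414, 415)

    background_gc3: float = 0.72
    background_strength: float = 1.2
    background_rule: str = "none"

    ribosomal_gc3: float = 0.35
    ribosomal_strength: float = 1.5
    ribosomal_rule: str = "pyrimidine"

    planted_gc3: float = 0.18
    planted_strength: float = 3.0
    planted_rule: str = "pyrimidine"
    #: scale per-family sharpness with amino-acid usage (accuracy link)
    planted_accuracy_link: bool = True

    aa_freqs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AA_FREQS))
    planted_aa_freqs: dict[str, float] = field(
        default_factory=lambda: dict(PLANTED_AA_FREQS)
    )

    # expression model: lognormal with multiplicative set boosts
    expression_meanlog: float = 2.0
    expression_sdlog: float = 1.5
    ribosomal_boost: float = 10.0
    planted_boost: float = 50.0

    # tRNA pool: copies proportional to background codon usage
    trna_total: int = 120
    exclude_c3_anticodons: bool = True

    planted_enabled: bool = True
    seed: int = 0

    def __post_init__(self):
        if min(self.n_background, self.n_ribosomal, self.n_planted) <= 0:
            raise ValueError("gene counts must be positive")
        if self.min_length < 2:
            raise ValueError("min_length must be at least 2 codons")


@dataclass
class SyntheticDataset:
    """Everything one pipeline run consumes, plus the planted truth."""

    sequences: list[CodingSequence]
    gene_sets: GeneSetMap
    trna_pool: TRNAPool
    expression: ExpressionTable
    truth: dict

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cds_fasta(self.sequences, out / "cds.fasta")
        write_gene_sets(self.gene_sets, out / "gene_sets.tsv")
        write_trna_pool(self.trna_pool, out / "trna_pool.tsv")
        write_expression_table(self.expression, out / "expression.tsv")
        write_json(self.truth, out / "truth.json")


def _accuracy_family_strength(aa_freqs: dict[str, float]) -> dict[str, float]:
    """Sharper codon preference for more-used amino acids."""
    u_max = max(aa_freqs.values())
    return {aa: 0.1 + 2.9 * (u / u_max) for aa, u in aa_freqs.items()}


def _sample_gene(
    rng: np.random.Generator,
    profile: UsageProfile,
    aa_freqs: dict[str, float],
    n_codons: int,
) -> str:
    aa_list = sorted(aa_freqs)
    p = np.array([aa_freqs[a] for a in aa_list])
    p = p / p.sum()
    residues = rng.choice(len(aa_list), size=n_codons - 1, p=p)
    codons = ["ATG"]
    for idx in residues:
        aa = aa_list[idx]
        fam_codons, fam_p = profile.family(aa)
        codons.append(fam_codons[rng.choice(len(fam_codons), p=fam_p)])
    codons.append("TAA")
    return "".join(codons)


def _build_trna_pool(
    profile: UsageProfile,
    aa_freqs: dict[str, float],
    trna_total: int,
    exclude_c3: bool,
) -> TRNAPool:
    usage = profile.expected_codon_usage(aa_freqs)
    copies: dict[str, int] = {}
    for codon, u in sorted(usage.items()):
        anticodon = reverse_complement_rna(dna_to_rna(codon))
        if exclude_c3 and anticodon.endswith("C"):
            continue
        n = round(u * trna_total)
        if n > 0:
            copies[anticodon] = copies.get(anticodon, 0) + n
    pool = TRNAPool(copies)
    # coverage pass: every sense codon must stay readable; unreadable
    # codons get a minimal-supply Watson-Crick anticodon (tGCN = 1)
    rule = PairingRule.default()
    _, unreadable = absolute_adaptiveness(pool, rule)
    for codon in unreadable:
        anticodon = reverse_complement_rna(dna_to_rna(codon))
        pool.copies[anticodon] = pool.copies.get(anticodon, 0) + 1
    return pool


def generate_genome(spec: SyntheticGenomeSpec) -> SyntheticDataset:
    """Draw one synthetic genome, tRNA pool and expression table.

    The returned truth record stores every planted parameter and the
    seed, so parameter-recovery tests can compare the pipeline's
    verdict with what was actually planted.
    """
    rng = np.random.default_rng(spec.seed)

    background = make_profile(
        spec.background_gc3, spec.background_strength, spec.background_rule
    )
    ribosomal = make_profile(
        spec.ribosomal_gc3, spec.ribosomal_strength, spec.ribosomal_rule
    )
    if spec.planted_enabled:
        planted_aa = spec.planted_aa_freqs
        fam_strength = (
            _accuracy_family_strength(planted_aa)
            if spec.planted_accuracy_link
            else None
        )
        planted = make_profile(
            spec.planted_gc3,
            spec.planted_strength,
            spec.planted_rule,
            family_strength=fam_strength,
        )
    else:
        planted_aa = spec.aa_freqs
        planted = background

    plan = (
        [("bg", background, spec.aa_freqs)] * spec.n_background
        + [("ribo", ribosomal, spec.aa_freqs)] * spec.n_ribosomal
        + [("planted", planted, planted_aa)] * spec.n_planted
    )
    n_genes = len(plan)
    lengths = np.maximum(
        spec.min_length,
        np.round(
            rng.lognormal(spec.length_meanlog, spec.length_sdlog, size=n_genes)
        ).astype(int),
    )
    # planted genes get realistic operon-scale lengths
    for i in range(spec.n_planted):
        lengths[spec.n_background + spec.n_ribosomal + i] = spec.planted_lengths[
            i % len(spec.planted_lengths)
        ]

    sequences: list[CodingSequence] = []
    assignments: dict[str, str] = {}
    counters = {"bg": 0, "ribo": 0, "planted": 0}
    prefix = {"bg": "g", "ribo": "ribo", "planted": "pln"}
    for (kind, profile, freqs), n_codons in zip(plan, lengths):
        counters[kind] += 1
        gene_id = f"{prefix[kind]}{counters[kind]:04d}"
        dna = _sample_gene(rng, profile, freqs, int(n_codons))
        sequences.append(CodingSequence(gene_id, dna))
        if kind == "ribo":
            assignments[gene_id] = "ribosomal"
        elif kind == "planted":
            assignments[gene_id] = spec.planted_label

    gene_sets = GeneSetMap(assignments)
    pool = _build_trna_pool(
        background, spec.aa_freqs, spec.trna_total, spec.exclude_c3_anticodons
    )

    abundance = rng.lognormal(
        spec.expression_meanlog, spec.expression_sdlog, size=n_genes
    )
    boosts = {
        "bg": 1.0,
        "ribo": spec.ribosomal_boost,
        "planted": spec.planted_boost if spec.planted_enabled else 1.0,
    }
    expr = {
        cds.gene_id: float(a * boosts[kind])
        for cds, a, (kind, _, _) in zip(sequences, abundance, plan)
    }

    truth = {
        "seed": spec.seed,
        "planted_enabled": spec.planted_enabled,
        "planted_genes": gene_sets.members(spec.planted_label),
        "ribosomal_genes": gene_sets.members("ribosomal"),
        "spec": {
            k: v
            for k, v in dataclasses.asdict(spec).items()
            if not isinstance(v, dict)
        },
    }
    return SyntheticDataset(
        sequences=sequences,
        gene_sets=gene_sets,
        trna_pool=pool,
        expression=ExpressionTable(expr),
        truth=truth,
    )
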