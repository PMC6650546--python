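"""End-to-end orchestration of the codon-level operon audit.

The audit runs, in order: per-gene composition; RSCU/CAI/ENC codon
metrics against two references (whole genome and ribosomal proteins);
the ENC ~ GC3 linear model; tAI plus the codon-tRNA network and
RSCU-cutoff access curves; the translation-accuracy regression
(max-RSCU vs amino-acid usage) per operon; the prebiotic-vs-modern
amino-acid class comparison; and, when an expression table is present,
the transcriptome ribonucleotide/elemental budgets with operon-removal
shifts, random-combination nulls, per-set element deltas and
abundance-element correlations.  A PERMANOVA on per-gene RSCU vectors
tests whether the source set structures codon usage at all.

Percentile ranks are computed within a single input genome (one FASTA
is one organism); batch studies loop organisms independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .codon_metrics import (
    accuracy_regression_inputs,
    cai,
    codon_counts,
    enc,
    median_rscu_profile,
    percentile_ranks,
    relative_adaptiveness,
    rscu,
)
from .composition import class_usage_comparison, composition_table
from .genetic_code import SENSE_CODONS
from .io import (
    GENOME_LABEL,
    RIBOSOMAL_LABEL,
    CodingSequence,
    ExpressionTable,
    GeneSetMap,
    TRNAPool,
    ValidationError,
    write_report,
)
from .stats import (
    DegenerateStatisticsError,
    linear_fit,
    permanova,
    welch_t_test,
)
from .transcriptome_budget import (
    DEFAULT_DIRECTIONS,
    abundance_element_correlation,
    element_delta,
    random_combination_null,
    removal_effect,
    transcribed_universe,
    transcriptome_composition,
)
from .trna_adaptation import (
    PairingRule,
    absolute_adaptiveness,
    access_curve,
    access_equality_test,
    build_network,
    tai,
)

__all__ = ["AuditConfig", "AuditReport", "run_audit"]


@dataclass
class AuditConfig:
    """Tunable knobs of one audit run."""

    pseudocount: float = 0.5
    ribosomal_label: str = RIBOSOMAL_LABEL
    cutoff_step: float = 0.01
    cutoff_max: float = 2.0
    null_k: int = 3
    null_draws: int = 1000
    n_permutations: int = 999
    expression_floor: float = 0.0
    inosine: bool = True
    seed: int = 0
    #: operon labels to treat as focal sets; None = every non-ribosomal label
    focal_sets: list[str] | None = None
    #: stage toggles
    with_network: bool = True
    with_budget: bool = True


@dataclass
class AuditReport:
    """Output contract of :func:`run_audit`."""

    per_gene: pd.DataFrame
    set_summary: pd.DataFrame
    stats: dict
    network_edges: pd.DataFrame | None = None
    access_curves: pd.DataFrame | None = None
    budget: dict | None = None
    removal_shifts: pd.DataFrame | None = None
    element_delta: pd.DataFrame | None = None
    nulls: dict | None = None
    metadata: dict = field(default_factory=dict)

    def write(self, out_dir):
        return write_report(self, out_dir)


def _set_label_column(
    sequences: list[CodingSequence], gene_sets: GeneSetMap
) -> list[str]:
    return [
        gene_sets.label_of(c.gene_id) or "background" for c in sequences
    ]


def run_audit(
    sequences: list[CodingSequence],
    gene_sets: GeneSetMap,
    trna_pool: TRNAPool | None = None,
    expression: ExpressionTable | None = None,
    config: AuditConfig | None = None,
) -> AuditReport:
    """Run the full audit and return its report.

    ``trna_pool`` and ``expression`` are optional: without a pool the
    tAI/network stages are skipped, without expression the budget
    stages are skipped; everything else completes.  Idempotent for a
    fixed config and seed.
    """
    cfg = config or AuditConfig()
    if not sequences:
        raise ValidationError("no coding sequences")
    ids = [c.gene_id for c in sequences]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate gene ids")
    missing = gene_sets.missing_from(ids)
    if missing:
        raise ValidationError(f"labeled genes absent from FASTA: {missing}")

    focal_sets = cfg.focal_sets
    if focal_sets is None:
        focal_sets = [
            lb for lb in gene_sets.labels if lb != cfg.ribosomal_label
        ]

    stats: dict = {}
    warnings: dict = {}

    # ---- composition -----------------------------------------------------
    per_gene = composition_table(sequences)
    per_gene.insert(1, "set_label", _set_label_column(sequences, gene_sets))

    # ---- codon metrics ---------------------------------------------------
    genome_counts = codon_counts(sequences)
    w_genome = relative_adaptiveness(genome_counts, cfg.pseudocount)
    ribo_ids = set(gene_sets.members(cfg.ribosomal_label))
    ribo_seqs = [c for c in sequences if c.gene_id in ribo_ids]
    if not ribo_seqs:
        raise ValidationError(
            f"reference set {cfg.ribosomal_label!r} absent: "
            "CAI against the ribosomal reference is part of the audit"
        )
    w_ribo = relative_adaptiveness(codon_counts(ribo_seqs), cfg.pseudocount)

    per_gene["cai_genome"] = [cai(c, w_genome) for c in sequences]
    per_gene["cai_ribosome"] = [cai(c, w_ribo) for c in sequences]
    enc_records = [enc(c) for c in sequences]
    per_gene["enc"] = [r.enc for r in enc_records]
    per_gene["pct_cai_genome"] = percentile_ranks(per_gene["cai_genome"])
    per_gene["pct_cai_ribosome"] = percentile_ranks(per_gene["cai_ribosome"])
    per_gene["pct_enc"] = percentile_ranks(per_gene["enc"])

    fit = linear_fit(per_gene["gc3"], per_gene["enc"])
    stats["enc_gc3_fit"] = dataclasses.asdict(fit)

    # ---- PERMANOVA on RSCU vectors --------------------------------------
    matrix = np.array(
        [
            [
                0.0 if math.isnan(v := rscu(codon_counts(c))[codon]) else v
                for codon in SENSE_CODONS
            ]
            for c in sequences
        ]
    )
    labels = per_gene["set_label"].tolist()
    try:
        pres = permanova(
            matrix, labels, n_permutations=cfg.n_permutations, seed=cfg.seed
        )
        stats["permanova_rscu"] = dataclasses.asdict(pres)
    except DegenerateStatisticsError as exc:
        stats["permanova_rscu"] = {"error": str(exc)}

    # ---- tAI, network, access curves ------------------------------------
    network_edges = None
    access_curves = None
    if trna_pool is not None:
        rule = PairingRule.default(inosine=cfg.inosine)
        W, unreadable = absolute_adaptiveness(trna_pool, rule)
        warnings["unreadable_codons"] = unreadable
        tai_records = [tai(c, W) for c in sequences]
        per_gene["tai"] = [r.tai for r in tai_records]
        per_gene["tai_skipped_codons"] = [r.skipped_codons for r in tai_records]
        per_gene["pct_tai"] = percentile_ranks(per_gene["tai"])

        if cfg.with_network:
            profiles = {
                GENOME_LABEL: median_rscu_profile(sequences),
                cfg.ribosomal_label: median_rscu_profile(ribo_seqs),
            }
            for label in focal_sets:
                members = set(gene_sets.members(label))
                profiles[label] = median_rscu_profile(
                    [c for c in sequences if c.gene_id in members]
                )
            network_edges = build_network(profiles, trna_pool, rule)
            cutoffs = np.round(
                np.arange(0.0, cfg.cutoff_max + 1e-9, cfg.cutoff_step),
                10,
            )
            curves = []
            stats["access_equality"] = {}
            for label, profile in profiles.items():
                curve = access_curve(profile, trna_pool, rule, cutoffs)
                curve.insert(0, "set_label", label)
                curves.append(curve)
                low = int(curve["accessible_copies"].iloc[0])
                high = int(curve["accessible_copies"].iloc[-1])
                try:
                    res = access_equality_test(low, high, trna_pool.total)
                    stats["access_equality"][label] = dataclasses.asdict(res)
                except DegenerateStatisticsError as exc:
                    stats["access_equality"][label] = {"error": str(exc)}
            access_curves = pd.concat(curves, ignore_index=True)

        # tAI percentile contrast: each focal set vs all other genes
        stats["tai_percentile_t"] = {}
        for label in focal_sets:
            members = set(gene_sets.members(label))
            inside = per_gene.loc[
                per_gene["gene_id"].isin(members), "pct_tai"
            ].to_numpy()
            outside = per_gene.loc[
                ~per_gene["gene_id"].isin(members), "pct_tai"
            ].to_numpy()
            if inside.size >= 2 and outside.size >= 2:
                try:
                    res = welch_t_test(inside, outside)
                    stats["tai_percentile_t"][label] = dataclasses.asdict(res)
                except DegenerateStatisticsError as exc:
                    stats["tai_percentile_t"][label] = {"error": str(exc)}

    # ---- accuracy regression & class usage per focal set -----------------
    stats["accuracy_regression"] = {}
    stats["class_usage"] = {}
    for label in focal_sets + [cfg.ribosomal_label]:
        members = set(gene_sets.members(label))
        subset = [c for c in sequences if c.gene_id in members]
        if len(subset) >= 2:
            pairs, dropped = accuracy_regression_inputs(subset)
            xs = [v[0] for v in pairs.values()]
            ys = [v[1] for v in pairs.values()]
            try:
                fit = linear_fit(xs, ys)
                stats["accuracy_regression"][label] = {
                    **dataclasses.asdict(fit),
                    "n_amino_acids": len(pairs),
                    "dropped": dropped,
                }
            except DegenerateStatisticsError as exc:
                stats["accuracy_regression"][label] = {"error": str(exc)}
            cls = class_usage_comparison([c.protein for c in subset])
            stats["class_usage"][label] = {
                "median_prebiotic": cls.median_prebiotic,
                "median_modern": cls.median_modern,
                "t_statistic": cls.t_statistic,
                "p_value": cls.p_value,
            }

    # ---- transcriptome budgets -------------------------------------------
    budget = None
    removal_shifts = None
    deltas = None
    nulls = None
    if expression is not None and cfg.with_budget:
        comp = transcriptome_composition(expression, sequences)
        budget = {
            "fractions": comp.fractions,
            "purine_fraction": comp.purine_fraction,
            "pyrimidine_fraction": comp.pyrimidine_fraction,
            "gc_fraction": comp.gc_fraction,
            "u_fraction": comp.u_fraction,
            "missing_sequences": comp.missing_sequences,
        }
        shift_rows = []
        for label in focal_sets + [cfg.ribosomal_label]:
            try:
                sh = removal_effect(expression, sequences, gene_sets, label)
            except ValueError:
                continue
            shift_rows.append(
                {
                    "set_label": label,
                    **{f"shift_{b}_pp": v for b, v in sh.base_shifts_pp.items()},
                    "purine_shift_pp": sh.purine_shift_pp,
                    "gc_shift_pp": sh.gc_shift_pp,
                    "u_shift_pp": sh.u_shift_pp,
                }
            )
        removal_shifts = pd.DataFrame(shift_rows)

        transcribed = transcribed_universe(
            expression, sequences, cfg.expression_floor
        )
        deltas = element_delta(
            sequences, gene_sets, [c.gene_id for c in transcribed]
        )
        nulls = {}
        for label in focal_sets:
            members = gene_sets.members(label)
            transcribed_members = [
                g for g in members if g in {c.gene_id for c in transcribed}
            ]
            if not transcribed_members:
                continue
            nulls[label] = {}
            for statistic in DEFAULT_DIRECTIONS:
                summary = random_combination_null(
                    transcribed,
                    transcribed_members,
                    statistic,
                    seed=cfg.seed,
                    k=cfg.null_k,
                    n_draws=cfg.null_draws,
                )
                nulls[label][statistic] = {
                    "focal_value": summary.focal_value,
                    "direction": summary.direction,
                    "n_draws": summary.n_draws,
                    "k": summary.k,
                    "exceedance": summary.exceedance,
                    "seed": summary.seed,
                }
        stats["abundance_element_correlation"] = abundance_element_correlation(
            expression, sequences
        ).to_dict(orient="records")

    # ---- per-set summary --------------------------------------------------
    metric_cols = [
        c
        for c in per_gene.columns
        if c
        not in ("gene_id", "set_label")
        and not c.startswith("usage_")
        and per_gene[c].dtype.kind in "fi"
    ]
    summary_rows = []
    for label in [GENOME_LABEL] + gene_sets.labels:
        members = set(gene_sets.members(label, universe=ids))
        sub = per_gene[per_gene["gene_id"].isin(members)]
        row = {"set_label": label, "n_genes": len(sub)}
        for col in metric_cols:
            row[f"median_{col}"] = (
                float(sub[col].median()) if len(sub) else math.nan
            )
        summary_rows.append(row)
    set_summary = pd.DataFrame(summary_rows)

    rule_hash = PairingRule.default().table_hash if trna_pool is not None else None
    metadata = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "n_genes": len(sequences),
        "warnings": warnings,
        "s_table_sha256": rule_hash,
    }
    return AuditReport(
        per_gene=per_gene,
        set_summary=set_summary,
        stats=stats,
        network_edges=network_edges,
        access_curves=access_curves,
        budget=budget,
        removal_shifts=removal_shifts,
        element_delta=deltas,
        nulls=nulls,
        metadata=metadata,
    )
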