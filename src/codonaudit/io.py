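"""Readers and writers for every file the audit pipeline touches.

Input formats
-------------
* coding sequences: FASTA, one record per CDS (DNA, sense strand);
* tRNA pool: TSV with columns ``anticodon`` (5'->3', RNA or DNA
  alphabet) and ``copies`` (tRNA gene copy number, tGCN);
* expression: TSV with columns ``gene_id`` and ``abundance``
  (normalized mRNA units, non-negative);
* gene sets: TSV with columns ``gene_id`` and ``set_label``.

All tabular output is tab-delimited UTF-8 with a header row and "."
decimals, chosen for diff-ability; statistics go to JSON with sorted
keys so that a fixed input and seed yields byte-identical reports.

Anticodons are stored 5'->3'; the codon a tRNA reads is the reverse
complement (in RNA).  Normalizing at the boundary prevents the classic
orientation bug from leaking into the adaptation metrics.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .genetic_code import CodonValidationError, codons_of, translate

__all__ = [
    "ValidationError",
    "CodingSequence",
    "GeneSetMap",
    "TRNAPool",
    "ExpressionTable",
    "read_cds_fasta",
    "read_trna_pool",
    "read_expression_table",
    "read_gene_sets",
    "write_cds_fasta",
    "write_trna_pool",
    "write_expression_table",
    "write_gene_sets",
    "write_report",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.10g"

GENOME_LABEL = "genome"
RIBOSOMAL_LABEL = "ribosomal"


class ValidationError(ValueError):
    """An input file or table violates its contract."""


class CodingSequence:
    """A single validated CDS: id, DNA, derived codons and protein.

    The terminal stop codon (if present) is kept in :attr:`dna` but
    excluded from :attr:`codons`, so codon-family metrics see sense
    codons only while whole-transcript metrics see the full sequence.
    """

    __slots__ = ("gene_id", "dna", "codons", "protein")

    def __init__(self, gene_id: str, dna: str):
        if not gene_id:
            raise ValidationError("empty gene id")
        seq = dna.upper()
        try:
            protein = translate(seq)
        except CodonValidationError as exc:
            raise ValidationError(f"{gene_id}: {exc}") from exc
        self.gene_id = gene_id
        self.dna = seq
        codons = codons_of(seq)
        if len(codons) == len(protein) + 1:
            codons = codons[:-1]  # drop terminal stop
        self.codons = codons
        self.protein = protein

    def __len__(self) -> int:
        return len(self.codons)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"CodingSequence({self.gene_id!r}, {len(self.codons)} codons)"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CodingSequence)
            and self.gene_id == other.gene_id
            and self.dna == other.dna
        )

    def __hash__(self) -> int:
        return hash((self.gene_id, self.dna))


@dataclass
class GeneSetMap:
    """Assignment of gene ids to named sets.

    ``ribosomal`` is a reserved label for the highly-expressed reference
    set; ``genome`` is implicit (every gene belongs to it) and may not
    be assigned explicitly.  A gene carries at most one explicit label.
    """

    assignments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for gene, label in self.assignments.items():
            if label == GENOME_LABEL:
                raise ValidationError(
                    f"{gene}: label {GENOME_LABEL!r} is implicit and reserved"
                )

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    @property
    def operon_labels(self) -> list[str]:
        return [lb for lb in self.labels if lb != RIBOSOMAL_LABEL]

    def members(self, label: str, universe: Iterable[str] | None = None) -> list[str]:
        if label == GENOME_LABEL:
            if universe is None:
                raise ValueError("the implicit 'genome' set needs a gene universe")
            return list(universe)
        return sorted(g for g, lb in self.assignments.items() if lb == label)

    def label_of(self, gene_id: str) -> str | None:
        return self.assignments.get(gene_id)

    def missing_from(self, universe: Iterable[str]) -> list[str]:
        """Labeled genes absent from a universe of known gene ids."""
        known = set(universe)
        return sorted(g for g in self.assignments if g not in known)


@dataclass
class TRNAPool:
    """Anticodon (5'->3' RNA triplet) -> tRNA gene copy number."""

    copies: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        clean: dict[str, int] = {}
        for anticodon, n in self.copies.items():
            ac = anticodon.upper().replace("T", "U")
            if len(ac) != 3 or set(ac) - set("ACGU"):
                raise ValidationError(f"malformed anticodon {anticodon!r}")
            n = int(n)
            if n < 0:
                raise ValidationError(f"negative copy number for {anticodon}")
            clean[ac] = clean.get(ac, 0) + n
        if not any(v > 0 for v in clean.values()):
            raise ValidationError("tRNA pool has no anticodon with copies > 0")
        self.copies = clean

    @property
    def total(self) -> int:
        return sum(self.copies.values())

    def get(self, anticodon: str) -> int:
        return self.copies.get(anticodon, 0)


@dataclass
class ExpressionTable:
    """Gene id -> normalized mRNA abundance (non-negative, finite)."""

    abundance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        import math

        for gene, value in self.abundance.items():
            v = float(value)
            if not math.isfinite(v):
                raise ValidationError(f"{gene}: non-finite abundance")
            if v < 0:
                raise ValidationError(f"{gene}: negative abundance {v}")
            self.abundance[gene] = v
        if self.abundance and not any(v > 0 for v in self.abundance.values()):
            raise ValidationError("no gene with positive abundance")

    def get(self, gene_id: str, default: float = 0.0) -> float:
        return self.abundance.get(gene_id, default)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.abundance


# ---------------------------------------------------------------------------
# readers


def read_cds_fasta(path, on_invalid: str = "error"):
    """Load a CDS FASTA into validated :class:`CodingSequence` objects.

    Parameters
    ----------
    on_invalid:
        ``"error"`` (default) raises on the first invalid record;
        ``"skip"`` drops invalid records and returns them in the second
        element of the tuple.

    Returns
    -------
    (sequences, rejected) where rejected is a list of (id, reason).
    """
    if on_invalid not in ("error", "skip"):
        raise ValueError("on_invalid must be 'error' or 'skip'")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"{path}: empty FASTA")
    seen: set[str] = set()
    sequences: list[CodingSequence] = []
    rejected: list[tuple[str, str]] = []
    for rec in records:
        if rec.id in seen:
            raise ValidationError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        try:
            sequences.append(CodingSequence(rec.id, str(rec.seq)))
        except ValidationError as exc:
            if on_invalid == "error":
                raise
            rejected.append((rec.id, str(exc)))
    return sequences, rejected


def _read_two_column_tsv(path, col_a: str, col_b: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.empty:
        raise ValidationError(f"{path}: empty table")
    missing = {col_a, col_b} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_trna_pool(path) -> TRNAPool:
    """Read a tRNA pool TSV (columns ``anticodon``, ``copies``).

    DNA and RNA alphabets are both accepted; duplicate anticodons are
    summed after normalization to RNA.
    """
    df = _read_two_column_tsv(path, "anticodon", "copies")
    copies: dict[str, int] = {}
    for anticodon, n in zip(df["anticodon"], df["copies"]):
        ac = str(anticodon).upper().replace("T", "U")
        if len(ac) != 3 or set(ac) - set("ACGU"):
            raise ValidationError(f"{path}: malformed anticodon {anticodon!r}")
        copies[ac] = copies.get(ac, 0) + int(n)
    return TRNAPool(copies)


def read_expression_table(path) -> ExpressionTable:
    df = _read_two_column_tsv(path, "gene_id", "abundance")
    table: dict[str, float] = {}
    for gene, value in zip(df["gene_id"], df["abundance"]):
        gene = str(gene)
        if gene in table:
            raise ValidationError(f"{path}: duplicate gene {gene}")
        table[gene] = float(value)
    return ExpressionTable(table)


def read_gene_sets(path) -> GeneSetMap:
    df = _read_two_column_tsv(path, "gene_id", "set_label")
    assignments: dict[str, str] = {}
    for gene, label in zip(df["gene_id"], df["set_label"]):
        gene, label = str(gene), str(label)
        if gene in assignments and assignments[gene] != label:
            raise ValidationError(
                f"{path}: gene {gene} assigned to both "
                f"{assignments[gene]!r} and {label!r}"
            )
        assignments[gene] = label
    return GeneSetMap(assignments)


# ---------------------------------------------------------------------------
# writers


def write_cds_fasta(sequences: Iterable[CodingSequence], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cds in sequences:
            fh.write(f">{cds.gene_id}\n")
            for i in range(0, len(cds.dna), 70):
                fh.write(cds.dna[i : i + 70] + "\n")


def write_trna_pool(pool: TRNAPool, path) -> None:
    df = pd.DataFrame(
        sorted(pool.copies.items()), columns=["anticodon", "copies"]
    )
    df.to_csv(path, sep="\t", index=False)


def write_expression_table(table: ExpressionTable, path) -> None:
    df = pd.DataFrame(
        sorted(table.abundance.items()), columns=["gene_id", "abundance"]
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_gene_sets(gene_sets: GeneSetMap, path) -> None:
    df = pd.DataFrame(
        sorted(gene_sets.assignments.items()), columns=["gene_id", "set_label"]
    )
    df.to_csv(path, sep="\t", index=False)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "tolist"):  # numpy array
        return obj.tolist()
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def write_json(payload, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_report(report, out_dir) -> list[Path]:
    """Write an :class:`~codonaudit.pipeline.AuditReport` to a directory.

    Emits per-gene metrics, per-set summary, network edge list, access
    curves, budget tables and a statistics JSON.  Given identical
    inputs and seed the files are byte-identical across runs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _tsv(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p, sep="\t", index=False, float_format=FLOAT_FORMAT, na_rep="NA")
        written.append(p)

    _tsv(report.per_gene, "per_gene_metrics.tsv")
    _tsv(report.set_summary, "set_summary.tsv")
    if report.network_edges is not None:
        _tsv(report.network_edges, "network_edges.tsv")
    if report.access_curves is not None:
        _tsv(report.access_curves, "access_curves.tsv")
    if report.removal_shifts is not None:
        _tsv(report.removal_shifts, "removal_shifts.tsv")
    if report.element_delta is not None:
        _tsv(report.element_delta, "element_delta.tsv")

    p = out / "statistics.json"
    write_json(report.stats, p)
    written.append(p)
    if report.nulls is not None:
        p = out / "null_summaries.json"
        write_json(report.nulls, p)
        written.append(p)
    if report.budget is not None:
        p = out / "budget.json"
        write_json(report.budget, p)
        written.append(p)
    p = out / "run_metadata.json"
    write_json(report.metadata, p)
    written.append(p)
    return written
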