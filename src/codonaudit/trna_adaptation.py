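"""tRNA adaptation index (tAI), codon-tRNA networks and access curves.

The tAI treats the tRNA pool of a genome as the supply side of
translation.  Each sense codon receives an absolute adaptiveness

    W_c = sum over pairable anticodons of (1 - s) * tGCN,

where tGCN is the tRNA gene copy number and s is the selective
constraint of the codon:anticodon pairing geometry (0 for Watson-Crick
pairs, larger for wobble pairs).  Normalized adaptiveness
w_c = W_c / max W feeds a geometric mean over a gene's codons, the tAI.

Pairing geometry: the anticodon is stored 5'->3'; its bases 3 and 2
must be Watson-Crick complementary to codon bases 1 and 2, while the
anticodon's first (wobble) base reads the codon's third base under the
rules of the shipped selective-constraint table.  Anticodons beginning
with A are treated as inosine-modified (reading U, C and A), the
standard assumption for bacteria; the table row is marked so the
behavior can be toggled off.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .genetic_code import (
    CODON_TO_AA,
    SENSE_CODONS,
    dna_to_rna,
    reverse_complement_rna,
)
from .io import CodingSequence, TRNAPool

__all__ = [
    "PairingRule",
    "absolute_adaptiveness",
    "TAIRecord",
    "tai",
    "build_network",
    "access_curve",
    "access_equality_test",
]

_RNA_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class PairingRule:
    """Allowed (codon third base, anticodon first base) pairs.

    ``constraints`` maps the pair to its selective constraint s in
    [0, 1]; ``classes`` maps it to "watson_crick" or "wobble".
    Forbidden pairs are simply absent.  The default table ships with
    the package as editable data, not code, and its hash is reported in
    run metadata so divergent s choices stay traceable.
    """

    constraints: dict[tuple[str, str], float]
    classes: dict[tuple[str, str], str]
    table_hash: str = ""

    @classmethod
    def default(cls, inosine: bool = True) -> "PairingRule":
        """Load the packaged selective-constraint table.

        ``inosine=False`` drops the rows that model A-starting
        anticodons as inosine-modified.
        """
        import io as _io

        ref = resources.files("codonaudit").joinpath("data/wobble_s_table.tsv")
        raw = ref.read_bytes()
        return cls.from_table(
            pd.read_csv(_io.BytesIO(raw), sep="\t"),
            table_hash=hashlib.sha256(raw).hexdigest(),
            inosine=inosine,
        )

    @classmethod
    def from_table(
        cls, df: pd.DataFrame, table_hash: str = "", inosine: bool = True
    ) -> "PairingRule":
        constraints: dict[tuple[str, str], float] = {}
        classes: dict[tuple[str, str], str] = {}
        for row in df.itertuples(index=False):
            if not inosine and getattr(row, "inosine", 0):
                continue
            key = (str(row.codon_third), str(row.anticodon_first))
            s = float(row.s)
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"selective constraint out of [0,1]: {s}")
            constraints[key] = s
            classes[key] = str(row.pairing_class)
        wc = [s for (k, s) in constraints.items() if classes[k] == "watson_crick"]
        wob = [s for (k, s) in constraints.items() if classes[k] == "wobble"]
        if wc and wob and max(wc) >= min(wob):
            raise ValueError("Watson-Crick pairs must have the smallest s")
        return cls(constraints=constraints, classes=classes, table_hash=table_hash)

    def pairable(self, codon: str, anticodon: str) -> bool:
        """Can this anticodon (5'->3' RNA) read this codon (DNA or RNA)?"""
        c = dna_to_rna(codon.upper())
        a = anticodon.upper().replace("T", "U")
        if _RNA_WC[c[0]] != a[2] or _RNA_WC[c[1]] != a[1]:
            return False
        return (c[2], a[0]) in self.constraints

    def s_of(self, codon: str, anticodon: str) -> float:
        c = dna_to_rna(codon.upper())
        a = anticodon.upper().replace("T", "U")
        return self.constraints[(c[2], a[0])]

    def class_of(self, codon: str, anticodon: str) -> str:
        c = dna_to_rna(codon.upper())
        a = anticodon.upper().replace("T", "U")
        return self.classes[(c[2], a[0])]


def absolute_adaptiveness(
    pool: TRNAPool, rule: PairingRule | None = None
) -> tuple[dict[str, float], list[str]]:
    """W per sense codon plus the list of codons no tRNA can read.

    W_c sums (1 - s) * tGCN over every pool anticodon pairable with c.
    Doubling every copy number doubles every W and leaves the
    normalized w (hence the tAI) unchanged.
    """
    rule = rule or PairingRule.default()
    W: dict[str, float] = {}
    unreadable: list[str] = []
    for codon in SENSE_CODONS:
        total = 0.0
        for anticodon, copies in pool.copies.items():
            if copies > 0 and rule.pairable(codon, anticodon):
                total += (1.0 - rule.s_of(codon, anticodon)) * copies
        W[codon] = total
        if total == 0.0:
            unreadable.append(codon)
    return W, unreadable


@dataclass
class TAIRecord:
    gene_id: str
    tai: float
    #: codons of the gene that no tRNA in the pool could read
    skipped_codons: int = 0
    w: dict[str, float] = field(default_factory=dict)


def tai(cds: CodingSequence, W: dict[str, float]) -> TAIRecord:
    """tRNA adaptation index of one CDS.

    Geometric mean of w_c = W_c / max W over the gene's sense codons
    (stop codons never appear; AUG is included).  Codons with W = 0 are
    excluded from the mean and counted in ``skipped_codons`` rather
    than zeroing the whole index.
    """
    w_max = max(W.values())
    if w_max <= 0:
        raise ValueError("every codon has W = 0")
    w = {c: W[c] / w_max for c in W}
    log_sum = 0.0
    n = 0
    skipped = 0
    for codon in cds.codons:
        wc = w[codon]
        if wc <= 0:
            skipped += 1
            continue
        log_sum += math.log(wc)
        n += 1
    if n == 0:
        raise ValueError(f"{cds.gene_id}: all codons unreadable by the pool")
    return TAIRecord(
        gene_id=cds.gene_id,
        tai=math.exp(log_sum / n),
        skipped_codons=skipped,
        w=w,
    )


def build_network(
    set_profiles: dict[str, dict[str, float]],
    pool: TRNAPool,
    rule: PairingRule | None = None,
) -> pd.DataFrame:
    """Bipartite codon-anticodon edge list with pairing attributes.

    One row per allowed (codon, pool anticodon) pair, carrying the
    pairing class, selective constraint s, the anticodon's tGCN, the
    codon's amino acid and one median-RSCU column per gene set in
    ``set_profiles``.  The frame converts directly to a networkx
    bipartite graph via :func:`to_networkx`.
    """
    if not set_profiles:
        raise ValueError("need at least one gene-set RSCU profile")
    rule = rule or PairingRule.default()
    rows = []
    for codon in SENSE_CODONS:
        for anticodon in sorted(pool.copies):
            if not rule.pairable(codon, anticodon):
                continue
            row = {
                "codon": dna_to_rna(codon),
                "anticodon": anticodon,
                "amino_acid": CODON_TO_AA[codon],
                "pairing_class": rule.class_of(codon, anticodon),
                "s": rule.s_of(codon, anticodon),
                "tGCN": pool.get(anticodon),
            }
            for label, profile in set_profiles.items():
                row[f"median_RSCU_{label}"] = profile.get(codon, math.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def to_networkx(edges: pd.DataFrame):
    """Edge-list frame -> networkx bipartite graph (codons vs anticodons)."""
    import networkx as nx

    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_node(row.codon, bipartite="codon", amino_acid=row.amino_acid)
        g.add_node(row.anticodon, bipartite="anticodon", tGCN=row.tGCN)
        g.add_edge(
            row.codon, row.anticodon, pairing_class=row.pairing_class, s=row.s
        )
    return g


def access_curve(
    profile: dict[str, float],
    pool: TRNAPool,
    rule: PairingRule | None = None,
    cutoffs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Accessible tRNA copies as a function of an RSCU cutoff.

    At cutoff t an anticodon is accessible if it can read at least one
    codon whose set-median RSCU is >= t; the series sums the tGCN of
    accessible anticodons and is non-increasing in t.  The default grid
    runs from 0.0 to 2.0 in steps of 0.01.
    """
    rule = rule or PairingRule.default()
    if cutoffs is None:
        cutoffs = np.round(np.arange(0.0, 2.0 + 1e-9, 0.01), 2)
    # best (largest) RSCU among codons each anticodon can read
    best: dict[str, float] = {}
    for anticodon in pool.copies:
        values = [
            profile.get(c, math.nan)
            for c in SENSE_CODONS
            if rule.pairable(c, anticodon)
        ]
        values = [v for v in values if not math.isnan(v)]
        best[anticodon] = max(values) if values else -math.inf
    rows = []
    for t in cutoffs:
        copies = sum(
            pool.get(ac) for ac, b in best.items() if b >= t
        )
        rows.append({"cutoff": float(t), "accessible_copies": int(copies)})
    return pd.DataFrame(rows)


def access_equality_test(
    accessible_low: int, accessible_high: int, pool_total: int
):
    """Chi-square test of equal accessible-tRNA proportions.

    Compares accessible copies / total pool copies at the low (t = 0)
    and high (t = 2) ends of the RSCU cutoff grid.
    """
    from .stats import chi_square_proportions

    return chi_square_proportions(
        accessible_low, pool_total, accessible_high, pool_total
    )
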