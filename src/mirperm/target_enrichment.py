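"""miRNA target selection, overlap accounting, and Fisher-exact enrichment.

Predicted miRNA→mRNA target pairs come with a 0–100 confidence score; only
pairs scoring strictly above the cutoff (default 70) are treated as targets.
Per-function enrichment of a target set against a named gene set uses the
one-sided Fisher exact test (hypergeometric upper tail) over the gene
universe, and results across several miRNAs are combined by the arithmetic
mean of the per-miRNA p-values ("average p-value"), with an additional flag
for functions enriched below the cutoff in *every* miRNA's target set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .expression_io import GeneSetCollection


@dataclass(frozen=True)
class OverlapSummary:
    total_unique: int
    shared: dict[str, int] = field(hash=False)
    n_shared_ge2: int = 0


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    per_mirna_p: dict[str, float] = field(hash=False)
    average_p: float = 1.0
    enriched: bool = False
    enriched_in_all: bool = False


def select_targets(table: pd.DataFrame, mirna_id: str, score_cut: float = 70.0) -> frozenset[str]:
    """Genes targeted by ``mirna_id`` with score strictly above ``score_cut``."""
    rows = table[(table["mirna_id"] == mirna_id) & (table["score"] > score_cut)]
    return frozenset(rows["gene_id"].astype(str))


def overlap_summary(target_sets: dict[str, frozenset[str]]) -> OverlapSummary:
    """Union size, per-gene multiplicity, and count of genes shared by >= 2 miRNAs."""
    if not target_sets:
        raise ValueError("need at least one target set")
    counts: Counter[str] = Counter()
    for genes in target_sets.values():
        counts.update(set(genes))
    shared = dict(counts)
    return OverlapSummary(
        total_unique=len(shared),
        shared=shared,
        n_shared_ge2=sum(1 for c in shared.values() if c >= 2),
    )


def fisher_enrichment(target_set, gene_set, universe) -> float:
    """One-sided (enrichment) Fisher exact p-value.

    Equals the hypergeometric upper tail P(X >= k) for k = |target ∩ set|
    drawing |target| genes from a universe containing |set| annotated genes.
    """
    universe = frozenset(universe)
    target_set = frozenset(target_set)
    gene_set = frozenset(gene_set)
    if len(universe) < 2:
        raise ValueError("universe must contain >= 2 genes")
    if not target_set <= universe:
        raise ValueError("target set is not a subset of the universe")
    if not gene_set <= universe:
        raise ValueError("gene set is not a subset of the universe")
    k = len(target_set & gene_set)
    return float(hypergeom.sf(k - 1, len(universe), len(gene_set), len(target_set)))


def enrich_across_mirnas(
    target_sets: dict[str, frozenset[str]],
    collection: GeneSetCollection,
    p_cut: float = 0.005,
) -> list[EnrichmentResult]:
    """Fisher enrichment of every gene set against every miRNA's target set.

    Returns one record per gene set, sorted by average p-value ascending.
    ``enriched`` flags average_p < p_cut; ``enriched_in_all`` additionally
    requires the per-miRNA p to fall below the cutoff for every miRNA.
    """
    if not target_sets:
        raise ValueError("need at least one target set")
    results = []
    for name in collection.names:
        members = collection.members(name)
        per_p = {
            mirna: fisher_enrichment(targets, members, collection.universe)
            for mirna, targets in target_sets.items()
        }
        avg = sum(per_p.values()) / len(per_p)
        results.append(
            EnrichmentResult(
                set_name=name,
                per_mirna_p=per_p,
                average_p=avg,
                enriched=avg < p_cut,
                enriched_in_all=all(p < p_cut for p in per_p.values()),
            )
        )
    results.sort(key=lambda r: (r.average_p, r.set_name))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Flatten enrichment results for TSV output (one row per gene set)."""
    rows = []
    for r in results:
        row: dict[str, object] = {"set_name": r.set_name, "average_p": r.average_p,
                                  "enriched": r.enriched,
                                  "enriched_in_all": r.enriched_in_all}
        for mirna, p in r.per_mirna_p.items():
            row[f"p[{mirna}]"] = p
        rows.append(row)
    return pd.DataFrame(rows)
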