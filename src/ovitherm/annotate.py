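"""SNP-to-gene assignment and over-representation testing.

A SNP inside a gene body is assigned that gene; otherwise the nearest
gene within a strict < 10 kbp flank is assigned with a ``*`` suffix
(the near-gene convention).  When two genes fall within the flank the
two nearest are joined by ``-``.  Unmapped SNPs (including unplaced
markers) get ``-``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ovitherm.io import UNPLACED, GeneModel
from ovitherm.gwas import GwasRecord


class ValidationError(ValueError):
    pass


def _distance(pos: int, gene: GeneModel) -> int:
    """bp distance from a SNP to a gene; 0 inside the gene body."""
    if gene.start <= pos <= gene.end:
        return 0
    return gene.start - pos if pos < gene.start else pos - gene.end


def map_snps_to_genes(records: list[GwasRecord], genes: list[GeneModel],
                      flank_bp: int = 10_000) -> list[GwasRecord]:
    """Fill the ``gene`` field of GWAS records by genomic proximity.

    Deterministic and independent of record order; ties broken by
    smallest distance then lexicographic gene id.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(str(g.chrom), []).append(g)
    out = []
    for r in records:
        if r.pos == UNPLACED or str(r.chrom) not in by_chrom:
            out.append(replace(r, gene="-"))
            continue
        cands = sorted(
            ((d, g.gene_id) for g in by_chrom[str(r.chrom)]
             if (d := _distance(r.pos, g)) < flank_bp),
            key=lambda t: (t[0], t[1]))
        if not cands:
            out.append(replace(r, gene="-"))
        elif cands[0][0] == 0:
            out.append(replace(r, gene=cands[0][1]))
        else:
            label = "-".join(gid for _, gid in cands[:2]) + "*"
            out.append(replace(r, gene=label))
    return out


@dataclass(frozen=True)
class EnrichmentRecord:
    set_id: str
    overlap: int
    set_size: int
    list_size: int
    universe_size: int
    pvalue: float
    qvalue: float


def hypergeom_enrichment(gene_list: set[str], gene_sets: dict[str, set[str]],
                         universe: set[str]) -> list[EnrichmentRecord]:
    """One-sided hypergeometric over-representation test per gene set.

    ``P(X >= k)`` for overlap k between the gene list and each set,
    both intersected with the universe; Benjamini-Hochberg correction
    across sets.
    """
    if not universe:
        raise ValidationError("empty gene universe")
    gene_list = set(gene_list) & universe
    n_univ = len(universe)
    n_list = len(gene_list)
    rows = []
    for set_id in sorted(gene_sets):
        members = gene_sets[set_id] & universe
        k = len(gene_list & members)
        p = float(stats.hypergeom.sf(k - 1, n_univ, len(members), n_list))
        rows.append((set_id, k, len(members), p))
    if not rows:
        return []
    qvals = multipletests([p for *_, p in rows], method="fdr_bh")[1]
    return [EnrichmentRecord(set_id, k, size, n_list, n_univ,
                             min(p, 1.0), float(q))
            for (set_id, k, size, p), q in zip(rows, qvals)]


def read_gmt(path: str) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (set id, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(parts[2:])
    return sets
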