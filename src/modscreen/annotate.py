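"""Assign variants to genes within ±1 kb of gene bodies and classify site classes.

A variant is assigned to every gene whose body, widened by the window
(default 1000 bp, inclusive at exactly 1000), contains its position.
Inside a body the site class comes from the containing sub-interval
(exon beats UTR if both contain the position; otherwise intron); in the
flank it is upstream or downstream according to the gene's strand.
Variants hitting several genes are resolved to one by the priority
exon > UTR > intron > flank, with smaller distance then lexicographic
gene ID as tie-breaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .datatypes import AnnotationSet, Gene, SNPGeneAssignment

__all__ = [
    "GeneIndex",
    "assign_snp_to_genes",
    "resolve_unique_assignment",
    "candidate_gene_table",
    "CandidateTable",
]

DEFAULT_WINDOW = 1000

_PRIORITY = {"exon": 0, "UTR5": 1, "UTR3": 1, "intron": 2, "upstream": 3, "downstream": 3}

_FEATURE_CLASS = {"exon": "exon", "five_prime_UTR": "UTR5", "three_prime_UTR": "UTR3"}


class GeneIndex:
    """Interval-tree index over gene bodies, one tree per chromosome.

    intervaltree uses half-open intervals; closed 1-based gene bodies
    [start, end] are stored as [start, end + 1).
    """

    def __init__(self, ann: AnnotationSet) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for chrom, genes in ann.by_chrom().items():
            tree = IntervalTree()
            for g in genes:
                tree[g.start:g.end + 1] = g
            self._trees[chrom] = tree

    def query(self, chrom: str, pos: int, window: int) -> list[Gene]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(pos - window, pos + window + 1)
        return sorted((iv.data for iv in hits), key=lambda g: g.gene_id)


def _classify(gene: Gene, pos: int) -> tuple[str, int]:
    """Site class and distance of a position relative to one gene."""
    if gene.start <= pos <= gene.end:
        in_exon = any(ft == "exon" and s <= pos <= e for ft, s, e in gene.features)
        if in_exon:
            return "exon", 0
        for ft, s, e in gene.features:
            if ft in ("five_prime_UTR", "three_prime_UTR") and s <= pos <= e:
                return _FEATURE_CLASS[ft], 0
        return "intron", 0
    if pos < gene.start:
        dist = gene.start - pos
        side = "upstream" if gene.strand == "+" else "downstream"
    else:
        dist = pos - gene.end
        side = "downstream" if gene.strand == "+" else "upstream"
    return side, dist


def assign_snp_to_genes(chrom: str, pos: int, ann: AnnotationSet | GeneIndex,
                        window: int = DEFAULT_WINDOW) -> list[SNPGeneAssignment]:
    """All gene assignments for one variant within ±window of a gene body.

    Returns one assignment per overlapping gene (possibly several, or an
    empty list when no gene is near).  Pass a prebuilt :class:`GeneIndex`
    to amortize the tree construction over many variants.
    """
    index = ann if isinstance(ann, GeneIndex) else GeneIndex(ann)
    out = []
    for gene in index.query(chrom, pos, window):
        site_class, dist = _classify(gene, pos)
        if dist <= window:
            out.append(SNPGeneAssignment(chrom=chrom, pos=pos, gene_id=gene.gene_id,
                                         site_class=site_class, distance=dist))
    return out


def resolve_unique_assignment(assignments: list[SNPGeneAssignment]) -> SNPGeneAssignment:
    """Pick the single winner by exon > UTR > intron > flank priority.

    Ties at equal priority go to the smaller distance, then to the
    lexicographically smaller gene ID.
    """
    if not assignments:
        raise ValueError("cannot resolve an empty assignment list")
    return min(assignments, key=lambda a: (_PRIORITY[a.site_class], a.distance, a.gene_id))


@dataclass
class CandidateTable:
    """Candidate-gene tabulation for a set of top variants.

    ``multi`` keeps every gene a variant supports (a variant may back
    several candidates); ``site_class_counts`` follows the resolved
    unique assignment of each assigned variant.
    """

    multi: pd.DataFrame
    unique_genes: list[str]
    site_class_counts: dict[str, int]
    n_unassigned: int
    unique: pd.DataFrame = field(default_factory=pd.DataFrame)


def candidate_gene_table(top: pd.DataFrame, ann: AnnotationSet,
                         window: int = DEFAULT_WINDOW) -> CandidateTable:
    """Tabulate candidate genes for the variants passing the p threshold.

    ``top`` needs chrom and pos columns (other columns are carried
    through to the per-assignment table).
    """
    index = GeneIndex(ann)
    multi_rows = []
    uniq_rows = []
    classes = {c: 0 for c in ("exon", "UTR5", "UTR3", "intron", "upstream", "downstream")}
    genes: set[str] = set()
    n_unassigned = 0
    for row in top.itertuples(index=False):
        assigns = assign_snp_to_genes(row.chrom, int(row.pos), index, window)
        if not assigns:
            n_unassigned += 1
            continue
        for a in assigns:
            genes.add(a.gene_id)
            multi_rows.append((a.chrom, a.pos, a.gene_id, a.site_class, a.distance))
        best = resolve_unique_assignment(assigns)
        classes[best.site_class] += 1
        uniq_rows.append((best.chrom, best.pos, best.gene_id, best.site_class, best.distance))
    cols = ["chrom", "pos", "gene", "site_class", "distance"]
    return CandidateTable(
        multi=pd.DataFrame(multi_rows, columns=cols),
        unique=pd.DataFrame(uniq_rows, columns=cols),
        unique_genes=sorted(genes),
        site_class_counts=classes,
        n_unassigned=n_unassigned,
    )
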