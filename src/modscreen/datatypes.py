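"""Core in-memory containers shared across pipeline stages.

Conventions used throughout the package:

* Lines are fully inbred and homozygous, so genotype dosages take the
  diploid values 0 or 2 (missing entries are ``NaN`` and are mean-imputed
  per variant before any matrix computation).
* Genomic coordinates are 1-based, fully closed intervals (the GFF3
  convention).
* Phenotype units are µg glucose (or protein) per fly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "Gene",
    "AnnotationSet",
    "SNPGeneAssignment",
    "GeneSetCollection",
    "InteractionGraph",
]

#: Required columns of a phenotype table (protein is optional).
PHENOTYPE_COLUMNS = ("strain", "replicate", "condition", "glucose")

#: Sub-interval feature types recognized inside a gene body.
GENE_FEATURE_TYPES = ("exon", "five_prime_UTR", "three_prime_UTR")


@dataclass
class GenotypeMatrix:
    """Lines x variants dosage matrix for a panel of inbred lines.

    Parameters
    ----------
    line_ids
        Ordered strain identifiers, one per row of ``dosages``.
    variants
        Per-variant records with columns ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt``.  Positions are strictly increasing within each
        chromosome.
    dosages
        ``(n_lines, n_variants)`` float array with entries in {0, 2} or
        ``NaN`` for missing calls.
    """

    line_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional")
        if self.dosages.shape != (len(self.line_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.variants)} variants"
            )
        required = {"chrom", "pos", "ref", "alt"}
        missing = required - set(self.variants.columns)
        if missing:
            raise ValueError(f"variant table lacks columns: {sorted(missing)}")
        for _, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing within chromosome")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def alt_frequency(self) -> np.ndarray:
        """Realized alt-allele frequency per variant, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per variant."""
        f = self.alt_frequency()
        return np.minimum(f, 1.0 - f)

    def imputed_dosages(self) -> np.ndarray:
        """Dosages with missing entries replaced by the per-variant mean."""
        X = self.dosages.copy()
        if np.isnan(X).any():
            col_mean = np.nanmean(X, axis=0)
            idx = np.where(np.isnan(X))
            X[idx] = col_mean[idx[1]]
        return X

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the variant columns in ``index`` (order preserved)."""
        return GenotypeMatrix(
            line_ids=list(self.line_ids),
            variants=self.variants.iloc[index].reset_index(drop=True),
            dosages=self.dosages[:, index],
        )


@dataclass
class KinshipMatrix:
    """Centered marker-based genetic relatedness matrix K.

    Symmetric, positive semidefinite (to numerical tolerance) and with
    zero row sums: centering each variant column makes the constant
    vector an exact null direction.
    """

    line_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"K must be {n}x{n}, got {self.values.shape}")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("K must be symmetric")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)


@dataclass
class Gene:
    """A gene body with typed sub-intervals (1-based, closed).

    ``features`` holds ``(type, start, end)`` triples for exons and UTRs;
    introns are the gaps between exon/UTR intervals inside the body.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    features: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        for ftype, s, e in self.features:
            if ftype not in GENE_FEATURE_TYPES:
                raise ValueError(f"{self.gene_id}: unknown feature type {ftype}")
            if s > e or s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: feature {ftype} outside gene body")


@dataclass
class AnnotationSet:
    """Collection of annotated genes, indexable by chromosome."""

    genes: list[Gene]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene IDs in annotation")

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        return out

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass(frozen=True)
class SNPGeneAssignment:
    """One variant-to-gene assignment with its site class.

    ``distance`` is 0 for variants inside the gene body, otherwise the
    base-pair distance to the nearest body boundary (at most the window).
    ``site_class`` is one of exon, UTR5, UTR3, intron, upstream,
    downstream; flank classes occur iff distance > 0.
    """

    chrom: str
    pos: int
    gene_id: str
    site_class: str
    distance: int

    def __post_init__(self) -> None:
        flank = self.site_class in ("upstream", "downstream")
        if flank != (self.distance > 0):
            raise ValueError(
                f"{self.gene_id}@{self.chrom}:{self.pos}: site class "
                f"{self.site_class} inconsistent with distance {self.distance}"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style: name, description, member IDs)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


class InteractionGraph:
    """Undirected physical-interaction edge list.

    Self-loops are rejected; duplicate edges are collapsed keeping the
    maximum weight.  Weights live in (0, 1] and default to 1.0.
    """

    def __init__(self, edges: list[tuple[str, str]] | list[tuple[str, str, float]] = ()) -> None:
        self._edges: dict[frozenset, float] = {}
        for edge in edges:
            if len(edge) == 2:
                a, b = edge
                w = 1.0
            else:
                a, b, w = edge
            self.add_edge(a, b, w)

    def add_edge(self, a: str, b: str, weight: float = 1.0) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        if not (0.0 < weight <= 1.0):
            raise ValueError(f"weight must be in (0, 1], got {weight}")
        key = frozenset((a, b))
        self._edges[key] = max(self._edges.get(key, 0.0), weight)

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for key, w in self._edges.items():
            a, b = sorted(key)
            out.append((a, b, w))
        return sorted(out)

    def nodes(self) -> set[str]:
        out: set[str] = set()
        for key in self._edges:
            out.update(key)
        return out

    def __len__(self) -> int:
        return len(self._edges)
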