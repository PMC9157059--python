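"""Synthetic data with the statistical structure of an inbred-panel modifier screen.

The generators emulate a reference panel of ~200 fully inbred, fully
homozygous lines crossed to a sensitized donor strain: biallelic SNPs with
an allele-frequency spectrum that includes rare alleles, cryptic
relatedness among lines (Balding–Nichols cluster divergence), replicate
pooled-fly glucose measurements per strain, and planted causal variants of
known per-allele effect.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import AnnotationSet, Gene, GeneSetCollection, GenotypeMatrix, InteractionGraph

__all__ = [
    "MAFSpectrum",
    "SimConfig",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_annotation",
    "simulate_gene_sets",
    "simulate_interactions",
]

# Autosome arm names used for small chromosome counts (the screen design
# analyzes autosomes only; no X is ever simulated).
_ARM_NAMES = ("2L", "2R", "3L", "3R")


def _chrom_names(n: int) -> list[str]:
    if n <= len(_ARM_NAMES):
        return list(_ARM_NAMES[:n])
    return list(_ARM_NAMES) + [f"auto{i}" for i in range(5, n + 1)]


@dataclass
class MAFSpectrum:
    """Minor-allele-frequency spectrum: a beta/uniform bulk plus a rare tail.

    With probability ``rare_fraction`` a variant's ancestral MAF is drawn
    uniformly from (``rare_low``, 0.05); otherwise from the bulk
    distribution rescaled to [0.05, 0.5].  ``dist`` is "beta" (parameters
    ``a``, ``b``) or "uniform".
    """

    dist: str = "beta"
    a: float = 0.8
    b: float = 0.8
    rare_fraction: float = 0.3
    rare_low: float = 0.005

    def __post_init__(self) -> None:
        if self.dist not in ("beta", "uniform"):
            raise ValueError("dist must be 'beta' or 'uniform'")
        if not 0.0 <= self.rare_fraction <= 1.0:
            raise ValueError("rare_fraction must be in [0, 1]")
        if not 0.0 < self.rare_low < 0.05:
            raise ValueError("rare_low must be in (0, 0.05)")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` ancestral minor-allele frequencies."""
        rare = rng.random(size) < self.rare_fraction
        if self.dist == "beta":
            bulk = rng.beta(self.a, self.b, size)
        else:
            bulk = rng.random(size)
        maf = 0.05 + bulk * 0.45
        maf[rare] = rng.uniform(self.rare_low, 0.05, int(rare.sum()))
        return maf


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic screen.

    Defaults mirror the screen design: ~200 inbred lines, 3 replicate
    samples of pooled flies per strain, glucose in µg/fly with strain
    means spanning roughly 0.4–2.4 µg/fly.

    Parameters
    ----------
    n_lines, n_variants, n_chromosomes
        Panel size; autosomes only.
    maf_spectrum
        Ancestral allele-frequency spectrum (includes a rare tail with
        MAF < 0.05 — the screen deliberately keeps rare alleles).
    n_clusters, fst
        Balding–Nichols population structure: lines fall into
        ``n_clusters`` groups whose allele frequencies diverge from the
        ancestral frequency with parameter ``fst`` in [0, 1).
    causal_variants
        ``(variant_index, effect)`` pairs; effect is in phenotype units
        (µg/fly) per alt-allele copy, so a dosage-2 line shifts by
        2 x effect relative to a dosage-0 line.
    h2_polygenic
        Fraction in [0, 1) controlling the polygenic background drawn
        from MVN(0, sigma_g^2 K); sigma_g^2 is set so the ratio of
        polygenic to strain-mean residual variance (the LMM's lambda)
        equals h2 / (1 - h2).
    n_reps_per_strain
        Replicate samples per strain (3–5 in the screen design).
    sigma_e
        Residual s.d. of a single replicate sample, µg/fly.
    baseline
        Grand-mean glucose, µg/fly.
    missing_rate
        Fraction of genotype calls set to missing.
    """

    n_lines: int = 200
    n_variants: int = 5000
    n_chromosomes: int = 4
    chrom_length: int = 1_000_000
    maf_spectrum: MAFSpectrum = field(default_factory=MAFSpectrum)
    n_clusters: int = 1
    fst: float = 0.0
    causal_variants: list[tuple[int, float]] = field(default_factory=list)
    h2_polygenic: float = 0.0
    n_reps_per_strain: int = 3
    sigma_e: float = 0.25
    baseline: float = 1.2
    condition: str = "2wk_fasted"
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lines", "n_variants", "n_chromosomes", "n_reps_per_strain"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if not 0.0 <= self.h2_polygenic < 1.0:
            raise ValueError("h2_polygenic must be in [0, 1)")
        if self.sigma_e <= 0:
            raise ValueError("sigma_e must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for idx, eff in self.causal_variants:
            if idx >= self.n_variants or idx < 0:
                raise ValueError(
                    f"causal variant index {idx} out of range for {self.n_variants} variants"
                )
            if not np.isfinite(eff):
                raise ValueError("causal effect sizes must be finite")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Named independent stream derived from the config seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stream + 1)[stream])


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw a lines x variants homozygous dosage matrix.

    Per-variant ancestral frequencies come from ``cfg.maf_spectrum``;
    cluster-level frequencies are Balding–Nichols perturbations
    ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` around the ancestral ``p``, which
    makes the realized kinship matrix non-trivial when ``fst > 0``.
    Fully inbred lines carry dosage 0 or 2 (never 1).
    """
    rng = cfg.rng(0)
    m, n = cfg.n_variants, cfg.n_lines

    p_anc = cfg.maf_spectrum.draw(rng, m)
    # randomly fold: the alt allele is the minor allele only half the time
    flip = rng.random(m) < 0.5
    p_anc = np.where(flip, 1.0 - p_anc, p_anc)

    cluster_of = rng.integers(0, cfg.n_clusters, size=n)
    if cfg.fst > 0.0 and cfg.n_clusters > 1:
        f = cfg.fst
        shape1 = p_anc * (1.0 - f) / f
        shape2 = (1.0 - p_anc) * (1.0 - f) / f
        p_clust = rng.beta(
            np.broadcast_to(shape1, (cfg.n_clusters, m)),
            np.broadcast_to(shape2, (cfg.n_clusters, m)),
        )
    else:
        p_clust = np.broadcast_to(p_anc, (cfg.n_clusters, m)).copy()

    # one founder haplotype per fully inbred line -> homozygous dosage
    dos = 2.0 * (rng.random((n, m)) < p_clust[cluster_of, :])

    if cfg.missing_rate > 0.0:
        dos[rng.random((n, m)) < cfg.missing_rate] = np.nan

    chroms = _chrom_names(cfg.n_chromosomes)
    per_chrom = np.array_split(np.arange(m), cfg.n_chromosomes)
    chrom_col = np.empty(m, dtype=object)
    pos_col = np.empty(m, dtype=int)
    for c_idx, var_idx in enumerate(per_chrom):
        k = len(var_idx)
        pos = np.sort(rng.choice(np.arange(1, cfg.chrom_length + 1), size=k, replace=False))
        chrom_col[var_idx] = chroms[c_idx]
        pos_col[var_idx] = pos

    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, m)]
    alt = np.array([bases[(np.flatnonzero(bases == r)[0] + o) % 4] for r, o in
                    zip(ref, rng.integers(1, 4, m))])

    variants = pd.DataFrame(
        {"chrom": chrom_col, "pos": pos_col, "ref": ref, "alt": alt,
         "ancestral_freq": p_anc}
    )
    line_ids = [f"line_{i:03d}" for i in range(n)]
    gm = GenotypeMatrix(line_ids=line_ids, variants=variants, dosages=dos)
    gm.cluster_of = cluster_of  # exposed for structure-aware tests
    return gm


def _polygenic_sigma_g2(cfg: SimConfig) -> float:
    """Scalar sigma_g^2 multiplying K so the LMM's lambda = h2/(1-h2).

    The mixed model's lambda is the ratio of the scalar variance
    components with K taken as-is (u ~ MVN(0, lambda tau_inv K) against
    residual tau_inv I on strain means), so planting lambda means
    sigma_g^2 = lambda * sigma_e^2 / n_reps with no diagonal
    normalization of K.
    """
    if cfg.h2_polygenic == 0.0:
        return 0.0
    resid_strain_var = cfg.sigma_e**2 / cfg.n_reps_per_strain
    lam = cfg.h2_polygenic / (1.0 - cfg.h2_polygenic)
    return lam * resid_strain_var


def simulate_phenotypes(G: GenotypeMatrix, cfg: SimConfig) -> pd.DataFrame:
    """Replicate glucose measurements per strain, µg/fly.

    Strain genetic value = sum of causal effects x dosage plus a
    polygenic draw from MVN(0, sigma_g^2 K) where K is the centered GRM
    of ``G``.  Each strain then gets ``n_reps_per_strain`` replicates
    with independent N(0, sigma_e^2) noise, truncated at 0 (glucose is a
    concentration; the truncation is a mild, documented deviation from
    Gaussianity).
    """
    from .gwas import compute_centered_grm

    rng = cfg.rng(1)
    n = G.n_lines
    X = G.imputed_dosages()

    genetic = np.zeros(n)
    for idx, eff in cfg.causal_variants:
        if idx >= G.n_variants:
            raise ValueError(f"causal index {idx} out of range for genotype matrix")
        genetic += eff * X[:, idx]

    if cfg.h2_polygenic > 0.0:
        K = compute_centered_grm(G).values
        sg2 = _polygenic_sigma_g2(cfg)
        # K is PSD up to roundoff; jitter keeps the factorization stable
        L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
        genetic += np.sqrt(sg2) * (L @ rng.standard_normal(n))

    rows = []
    for i, strain in enumerate(G.line_ids):
        mu = cfg.baseline + genetic[i]
        for rep in range(1, cfg.n_reps_per_strain + 1):
            val = mu + cfg.sigma_e * rng.standard_normal()
            rows.append((strain, rep, cfg.condition, max(val, 0.0)))
    return pd.DataFrame(rows, columns=["strain", "replicate", "condition", "glucose"])


@dataclass
class AnnotationConfig:
    """Layout parameters for the synthetic gene annotation."""

    gene_length_range: tuple[int, int] = (2000, 8000)
    intergenic_gap_range: tuple[int, int] = (3000, 12000)
    utr_length: int = 200
    n_exons_range: tuple[int, int] = (1, 4)
    overlap_fraction: float = 0.0


def _build_gene(gene_id: str, chrom: str, start: int, length: int, strand: str,
                rng: np.random.Generator, acfg: AnnotationConfig) -> Gene:
    """One gene whose UTR/exon/intron sub-intervals tile the body exactly."""
    end = start + length - 1
    utr = min(acfg.utr_length, max(1, length // 10))
    inner_start = start + utr
    inner_end = end - utr
    n_exons = int(rng.integers(acfg.n_exons_range[0], acfg.n_exons_range[1] + 1))
    inner_len = inner_end - inner_start + 1
    n_exons = max(1, min(n_exons, inner_len // 200))

    features: list[tuple[str, int, int]] = []
    left_utr = "five_prime_UTR" if strand == "+" else "three_prime_UTR"
    right_utr = "three_prime_UTR" if strand == "+" else "five_prime_UTR"
    features.append((left_utr, start, inner_start - 1))
    features.append((right_utr, inner_end + 1, end))

    # split the inner region into exons separated by introns (gaps)
    if n_exons == 1:
        features.append(("exon", inner_start, inner_end))
    else:
        cuts = np.sort(rng.choice(np.arange(1, inner_len), size=2 * n_exons - 2, replace=False))
        bounds = np.concatenate(([0], cuts, [inner_len]))
        for k in range(n_exons):
            s = inner_start + int(bounds[2 * k])
            e = inner_start + int(bounds[2 * k + 1]) - 1
            if k == n_exons - 1:
                e = inner_end
            if s <= e:
                features.append(("exon", s, e))
    return Gene(gene_id=gene_id, chrom=chrom, start=start, end=end, strand=strand,
                features=sorted(features, key=lambda f: f[1]))


def simulate_annotation(cfg: SimConfig, acfg: AnnotationConfig | None = None) -> AnnotationSet:
    """Tile each chromosome with genes separated by intergenic gaps.

    Gaps exceed 2 kb so some variants land > 1 kb from every gene body;
    with ``overlap_fraction > 0`` that fraction of genes is shifted back
    to overlap the previous gene's flank, producing multi-gene hits.
    """
    acfg = acfg or AnnotationConfig()
    rng = cfg.rng(2)
    genes: list[Gene] = []
    gid = 0
    for chrom in _chrom_names(cfg.n_chromosomes):
        cursor = int(rng.integers(1000, 4000))
        prev: Gene | None = None
        while True:
            length = int(rng.integers(*acfg.gene_length_range))
            start = cursor
            if prev is not None and acfg.overlap_fraction > 0 and rng.random() < acfg.overlap_fraction:
                # slide this gene back into the previous gene's body/flank
                start = max(1, prev.end - int(rng.integers(200, 1500)))
            if start + length - 1 > cfg.chrom_length - 1000:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            gene = _build_gene(f"gene{gid:05d}", chrom, start, length, strand, rng, acfg)
            genes.append(gene)
            gid += 1
            prev = gene
            cursor = max(cursor, gene.end) + int(rng.integers(*acfg.intergenic_gap_range))
    return AnnotationSet(genes=genes)


def simulate_gene_sets(ann: AnnotationSet, causal_genes: list[str], cfg: SimConfig,
                       n_sets: int = 50, size_range: tuple[int, int] = (5, 100),
                       enriched_size: int = 10,
                       enriched_name: str = "planted_enriched") -> GeneSetCollection:
    """Random gene sets plus one planted set containing all causal genes."""
    universe = ann.gene_ids()
    unknown = set(causal_genes) - set(universe)
    if unknown:
        raise ValueError(f"causal genes not in annotation: {sorted(unknown)}")
    hi = min(size_range[1], len(universe))
    if size_range[0] > len(universe) or enriched_size > len(universe):
        raise ValueError("requested set size exceeds gene universe")
    rng = cfg.rng(3)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for i in range(n_sets):
        size = int(rng.integers(size_range[0], hi + 1))
        members = set(rng.choice(universe, size=size, replace=False))
        name = f"random_set_{i:03d}"
        sets[name] = members
        descriptions[name] = "random background set"
    if causal_genes:
        filler_pool = [g for g in universe if g not in causal_genes]
        extra = max(0, enriched_size - len(causal_genes))
        members = set(causal_genes) | set(rng.choice(filler_pool, size=extra, replace=False))
        sets[enriched_name] = members
        descriptions[enriched_name] = "planted set containing the causal genes"
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def simulate_interactions(ann: AnnotationSet, candidates: list[str], cfg: SimConfig,
                          n_direct_pairs: int = 2, n_bridged_pairs: int = 2,
                          n_random_edges: int = 50) -> InteractionGraph:
    """Random edges plus planted candidate motifs of known counts.

    Plants ``n_direct_pairs`` candidate–candidate edges and
    ``n_bridged_pairs`` candidate–bridge–candidate paths (bridge nodes
    are fresh non-candidate IDs), then adds random edges over the gene
    universe avoiding extra candidate–candidate contacts.
    """
    rng = cfg.rng(4)
    need = 2 * (n_direct_pairs + n_bridged_pairs)
    if len(candidates) < need:
        raise ValueError(f"need >= {need} candidates, got {len(candidates)}")
    graph = InteractionGraph()
    pool = list(candidates)
    rng.shuffle(pool)
    for i in range(n_direct_pairs):
        graph.add_edge(pool[2 * i], pool[2 * i + 1])
    off = 2 * n_direct_pairs
    for i in range(n_bridged_pairs):
        a, b = pool[off + 2 * i], pool[off + 2 * i + 1]
        bridge = f"bridge{i:03d}"
        graph.add_edge(a, bridge)
        graph.add_edge(bridge, b)

    universe = [g for g in ann.gene_ids() if g not in candidates]
    attempts = 0
    while len(graph) < n_direct_pairs + 2 * n_bridged_pairs + n_random_edges and attempts < 50 * n_random_edges:
        attempts += 1
        a, b = rng.choice(universe, size=2, replace=False)
        w = float(np.round(rng.uniform(0.05, 1.0), 3))
        try:
            graph.add_edge(str(a), str(b), w)
        except ValueError:
            continue
    return graph
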