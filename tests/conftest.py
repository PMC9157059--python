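import numpy as np
import pandas as pd
import pytest

from modscreen import (
    AnnotationSet,
    Gene,
    compute_centered_grm,
    simulate_genotypes,
    simulate_phenotypes,
    strain_means,
)
from modscreen.simulate import SimConfig


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(n_lines=60, n_variants=300, n_chromosomes=2, seed=11)


@pytest.fixture(scope="session")
def small_genotypes(small_cfg):
    return simulate_genotypes(small_cfg)


@pytest.fixture(scope="session")
def small_screen(small_cfg, small_genotypes):
    """Genotypes, phenotypes, strain means and GRM for a small null screen."""
    pheno = simulate_phenotypes(small_genotypes, small_cfg)
    y = strain_means(pheno, small_cfg.condition)
    K = compute_centered_grm(small_genotypes)
    return small_genotypes, pheno, y, K


@pytest.fixture()
def two_gene_annotation() -> AnnotationSet:
    """Two plus-strand genes on one chromosome with known sub-intervals.

    geneA: body 1000-4999, UTR5 1000-1199, exons 1200-1999 & 3000-3799,
    UTR3 4800-4999 (intron 2000-2999 and 3800-4799).
    geneB: body 8000-9999, single exon between the UTRs.
    """
    gene_a = Gene(
        gene_id="geneA", chrom="2L", start=1000, end=4999, strand="+",
        features=[("five_prime_UTR", 1000, 1199), ("exon", 1200, 1999),
                  ("exon", 3000, 3799), ("three_prime_UTR", 4800, 4999)],
    )
    gene_b = Gene(
        gene_id="geneB", chrom="2L", start=8000, end=9999, strand="+",
        features=[("five_prime_UTR", 8000, 8199), ("exon", 8200, 9799),
                  ("three_prime_UTR", 9800, 9999)],
    )
    return AnnotationSet(genes=[gene_a, gene_b])


def make_phenotypes(groups: dict[str, list[float]], condition: str = "c") -> pd.DataFrame:
    """Replicate table from a strain -> measurements mapping."""
    rows = [(s, i + 1, condition, v)
            for s, vals in groups.items() for i, v in enumerate(vals)]
    return pd.DataFrame(rows, columns=["strain", "replicate", "condition", "glucose"])


def random_annotation(rng: np.random.Generator, chrom_length: int = 60_000,
                      n_genes: int = 8) -> AnnotationSet:
    """Random annotation fixture with irregular gene spacing, for oracles."""
    genes = []
    cursor = int(rng.integers(1, 3000))
    for i in range(n_genes):
        length = int(rng.integers(1000, 6000))
        start = cursor
        end = start + length - 1
        if end > chrom_length:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        utr = int(rng.integers(50, 300))
        inner_s, inner_e = start + utr, end - utr
        mid = int(rng.integers(inner_s + 100, inner_e - 100))
        features = [("five_prime_UTR", start, start + utr - 1),
                    ("exon", inner_s, mid - 50),
                    ("exon", mid + 50, inner_e),
                    ("three_prime_UTR", inner_e + 1, end)]
        genes.append(Gene(gene_id=f"g{i}", chrom="2L", start=start, end=end,
                          strand=strand, features=features))
        # gaps from overlapping (negative) to wide, so flanks sometimes collide
        cursor = end + int(rng.integers(-1500, 6000))
        cursor = max(cursor, end - length // 2)
    return AnnotationSet(genes=genes)
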