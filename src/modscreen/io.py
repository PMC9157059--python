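"""Readers and writers for the pipeline's interchange formats.

Genotypes travel as VCF (homozygous GT records) or as a TSV dosage
table; annotation as GFF3 (1-based closed coordinates); gene sets as
GMT; phenotypes and interaction edges as TSV with header.  VCF parsing
uses cyvcf2 and GFF3 parsing uses gffutils; the writers emit the
plain-text forms directly.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datatypes import AnnotationSet, Gene, GeneSetCollection, GenotypeMatrix, InteractionGraph

__all__ = [
    "write_vcf", "read_vcf",
    "write_dosage_tsv", "read_dosage_tsv",
    "write_gff3", "read_gff3",
    "write_gmt", "read_gmt",
    "write_phenotypes", "read_phenotypes",
    "write_edges", "read_edges",
]


# ---------------------------------------------------------------- genotypes

def write_vcf(G: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write one record per variant with homozygous GT calls (0/0, 1/1, ./.)."""
    chroms = list(dict.fromkeys(G.variants["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=modscreen\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.line_ids) + "\n")
        for j, row in enumerate(G.variants.itertuples(index=False)):
            calls = []
            for dose in G.dosages[:, j]:
                if np.isnan(dose):
                    calls.append("./.")
                elif dose == 0:
                    calls.append("0/0")
                else:
                    calls.append("1/1")
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Parse a VCF into a dosage matrix.

    Homozygous-ref calls become 0, homozygous-alt 2, missing ``./.``
    NaN.  Residual heterozygous calls in an inbred panel are treated as
    missing.  Multi-allelic records are kept with comma-joined ALT (so
    downstream biallelic filtering can count them) with dosage taken
    against the first alternate allele.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, doses = [], []
    for var in vcf:
        alt = ",".join(var.ALT) if var.ALT else "."
        rows.append((var.CHROM, var.POS, var.REF, alt))
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types
        d = np.full(len(samples), np.nan)
        d[gt == 0] = 0.0
        d[gt == 3] = 2.0
        doses.append(d)
    vcf.close()
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosages = np.column_stack(doses) if doses else np.empty((len(samples), 0))
    return GenotypeMatrix(line_ids=samples, variants=variants, dosages=dosages)


def write_dosage_tsv(G: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Variant-major TSV: chrom, pos, ref, alt, then one dosage column per line."""
    df = G.variants[["chrom", "pos", "ref", "alt"]].copy()
    for i, line in enumerate(G.line_ids):
        df[line] = G.dosages[i, :]
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path: str | os.PathLike) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    meta = ["chrom", "pos", "ref", "alt"]
    lines = [c for c in df.columns if c not in meta]
    return GenotypeMatrix(
        line_ids=lines,
        variants=df[meta].copy(),
        dosages=df[lines].to_numpy(dtype=float).T,
    )


# --------------------------------------------------------------- annotation

def write_gff3(ann: AnnotationSet, path: str | os.PathLike) -> None:
    """GFF3 with gene parents and exon/UTR children (introns are implicit gaps)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ann.genes:
            fh.write(f"{g.chrom}\tmodscreen\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            for k, (ftype, s, e) in enumerate(g.features):
                fh.write(f"{g.chrom}\tmodscreen\t{ftype}\t{s}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={g.gene_id}.{ftype}.{k};Parent={g.gene_id}\n")


def read_gff3(path: str | os.PathLike) -> AnnotationSet:
    """Load gene/exon/UTR features from GFF3 via gffutils."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    genes = []
    for grec in db.features_of_type("gene"):
        feats = []
        for child in db.children(grec.id):
            if child.featuretype in ("exon", "five_prime_UTR", "three_prime_UTR"):
                feats.append((child.featuretype, child.start, child.end))
        genes.append(Gene(gene_id=grec.id, chrom=grec.seqid, start=grec.start,
                          end=grec.end, strand=grec.strand,
                          features=sorted(feats, key=lambda f: (f[1], f[0]))))
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return AnnotationSet(genes=genes)


# ---------------------------------------------------------------- gene sets

def write_gmt(coll: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name in sorted(coll.sets):
            desc = coll.descriptions.get(name, "")
            members = "\t".join(sorted(coll.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, desc, members = parts[0], parts[1], parts[2:]
            sets[name] = set(m for m in members if m)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


# --------------------------------------------------------------- phenotypes

def write_phenotypes(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    from .phenotype import validate_phenotype_table

    return validate_phenotype_table(pd.read_csv(path, sep="\t", na_values=["NA"]))


# -------------------------------------------------------------------- edges

def write_edges(graph: InteractionGraph, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("geneA\tgeneB\tweight\n")
        for a, b, w in graph.edges():
            fh.write(f"{a}\t{b}\t{w:g}\n")


def read_edges(path: str | os.PathLike) -> InteractionGraph:
    df = pd.read_csv(path, sep="\t")
    graph = InteractionGraph()
    has_weight = "weight" in df.columns
    for row in df.itertuples(index=False):
        w = float(row.weight) if has_weight and pd.notna(row.weight) else 1.0
        graph.add_edge(str(row.geneA), str(row.geneB), w)
    return graph
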