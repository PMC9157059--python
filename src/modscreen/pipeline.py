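"""End-to-end orchestration: simulate -> phenostats -> gwa -> annotate -> gsea -> network.

A run is driven by one structured YAML config (see
:data:`DEFAULT_CONFIG` for the schema and defaults) and writes every
stage's output plus a manifest (parameters, seeds, input hashes,
package version) into a run directory.  Re-running with an unchanged
config skips completed stages unless forced; fixed seeds make the
stochastic stages byte-reproducible.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .annotate import candidate_gene_table
from .datatypes import GenotypeMatrix
from .gsea import gsea_permutation_test, rank_genes
from .gwas import compute_centered_grm, filter_variants, lmm_association, top_variants
from .network import extract_candidate_subnetwork
from .phenotype import anova_strain_effect, strain_means
from .simulate import MAFSpectrum, SimConfig, simulate_annotation, simulate_gene_sets, \
    simulate_genotypes, simulate_interactions, simulate_phenotypes

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "write_report", "ConfigError"]

logger = logging.getLogger("modscreen")

STAGES = ("simulate", "phenostats", "gwa", "annotate", "gsea", "network")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "condition": "2wk_fasted",
    "stages": {s: True for s in STAGES},
    "inputs": {  # used when the simulate stage is off
        "genotypes": None, "phenotypes": None, "annotation": None,
        "gene_sets": None, "edges": None,
    },
    "simulate": {
        "n_lines": 200, "n_variants": 5000, "n_chromosomes": 4,
        "chrom_length": 1_000_000, "n_clusters": 1, "fst": 0.0,
        "maf": {"dist": "beta", "a": 0.8, "b": 0.8, "rare_fraction": 0.3},
        "causal_variants": [], "h2_polygenic": 0.0,
        "n_reps_per_strain": 3, "sigma_e": 0.25, "baseline": 1.2,
        "missing_rate": 0.0, "n_gene_sets": 50, "n_random_edges": 50,
    },
    "gwa": {"min_maf": None, "exclude_chromosomes": [], "mode": "null_lambda_reused",
            "method": "reml", "threshold": 1e-4},
    "annotate": {"window": 1000},
    "gsea": {"n_perm": 1000, "min_genes": 3, "min_genes_strict": False,
             "alpha": 0.05, "weight_exponent": 1.0},
    "network": {},
}


class ConfigError(ValueError):
    """Raised when a run config violates the documented schema."""


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key not in base:
            raise ConfigError(f"unknown config field: {path + key!r}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val, path + key + ".")
        else:
            out[key] = val
    return out


def load_config(path: str | os.PathLike | None = None,
                overrides: dict | None = None) -> dict:
    """Merge a YAML config file and overrides onto the defaults."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("config file must contain a YAML mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    if cfg["gwa"]["mode"] not in ("null_lambda_reused", "per_variant_lambda"):
        raise ConfigError("gwa.mode must be null_lambda_reused or per_variant_lambda")
    if not cfg["stages"]["simulate"]:
        for key in ("genotypes", "phenotypes"):
            p = cfg["inputs"][key]
            if p is None or not Path(p).exists():
                raise ConfigError(f"inputs.{key} must point to an existing file "
                                  "when the simulate stage is off")
    return cfg


def _sim_config(cfg: dict) -> SimConfig:
    s = cfg["simulate"]
    return SimConfig(
        n_lines=s["n_lines"], n_variants=s["n_variants"],
        n_chromosomes=s["n_chromosomes"], chrom_length=s["chrom_length"],
        maf_spectrum=MAFSpectrum(**s["maf"]),
        n_clusters=s["n_clusters"], fst=s["fst"],
        causal_variants=[tuple(cv) for cv in s["causal_variants"]],
        h2_polygenic=s["h2_polygenic"], n_reps_per_strain=s["n_reps_per_strain"],
        sigma_e=s["sigma_e"], baseline=s["baseline"],
        condition=cfg["condition"], missing_rate=s["missing_rate"], seed=cfg["seed"],
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_digest(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(cfg: dict, outdir: str | os.PathLike, force: bool = False) -> Path:
    """Execute the enabled stages and return the run directory.

    Stage outputs are TSV/VCF/GFF3/GMT files in ``outdir``; a
    ``manifest.json`` records parameters, seeds, versions and output
    hashes.  A completed run with an identical config is not recomputed
    unless ``force``.
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        return _run(cfg, outdir, force, __version__)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(cfg: dict, outdir: Path, force: bool, version: str) -> Path:
    digest = _config_digest(cfg)
    manifest_path = outdir / "manifest.json"
    manifest: dict = {"config": cfg, "config_digest": digest, "version": version,
                      "seed": cfg["seed"], "stages": {}, "outputs": {}}
    if manifest_path.exists() and not force:
        old = json.loads(manifest_path.read_text())
        if old.get("config_digest") == digest and all(
                (outdir / f).exists() for f in old.get("outputs", {})):
            logger.info("run already complete for this config; skipping (use force to redo)")
            return outdir

    condition = cfg["condition"]
    stage_on = cfg["stages"]

    def record(stage: str, params: dict, files: list[Path]) -> None:
        manifest["stages"][stage] = params
        for f in files:
            manifest["outputs"][f.name] = _sha256(f)
        logger.info("stage %s done: %s", stage, ", ".join(f.name for f in files))

    # ---- stage: simulate (or load inputs)
    ann = gene_sets = edges = None
    scfg = _sim_config(cfg)
    if stage_on["simulate"]:
        G = simulate_genotypes(scfg)
        pheno = simulate_phenotypes(G, scfg)
        ann = simulate_annotation(scfg)
        causal_genes = _causal_gene_ids(G, ann, scfg)
        gene_sets = simulate_gene_sets(ann, causal_genes, scfg,
                                       n_sets=cfg["simulate"]["n_gene_sets"])
        candidates_for_net = causal_genes if len(causal_genes) >= 8 else ann.gene_ids()[:8]
        edges = simulate_interactions(ann, candidates_for_net, scfg,
                                      n_random_edges=cfg["simulate"]["n_random_edges"])
        files = [outdir / "genotypes.vcf", outdir / "genotypes.dosage.tsv",
                 outdir / "phenotypes.tsv", outdir / "annotation.gff3",
                 outdir / "gene_sets.gmt", outdir / "interactions.tsv"]
        mio.write_vcf(G, files[0])
        mio.write_dosage_tsv(G, files[1])
        mio.write_phenotypes(pheno, files[2])
        mio.write_gff3(ann, files[3])
        mio.write_gmt(gene_sets, files[4])
        mio.write_edges(edges, files[5])
        record("simulate", {"seed": scfg.seed, "n_lines": scfg.n_lines,
                            "n_variants": scfg.n_variants}, files)
    else:
        G = _load_genotypes(cfg["inputs"]["genotypes"])
        pheno = mio.read_phenotypes(cfg["inputs"]["phenotypes"])
        if cfg["inputs"]["annotation"]:
            ann = mio.read_gff3(cfg["inputs"]["annotation"])
        if cfg["inputs"]["gene_sets"]:
            gene_sets = mio.read_gmt(cfg["inputs"]["gene_sets"])
        if cfg["inputs"]["edges"]:
            edges = mio.read_edges(cfg["inputs"]["edges"])

    # ---- stage: phenotype statistics
    y = strain_means(pheno, condition)
    if stage_on["phenostats"]:
        anova = anova_strain_effect(pheno, condition)
        stats_df = pd.DataFrame([
            ("n_strains", len(y)),
            ("mean_glucose", y.mean()),
            ("min_strain_mean", y.min()),
            ("max_strain_mean", y.max()),
            ("anova_F", anova.f_statistic),
            ("anova_p", anova.p_value),
            ("anova_df_between", anova.df_between),
            ("anova_df_within", anova.df_within),
        ], columns=["statistic", "value"])
        f = outdir / "phenotype_stats.tsv"
        stats_df.to_csv(f, sep="\t", index=False)
        ymeans = y.rename("mean_glucose").rename_axis("strain").reset_index()
        f2 = outdir / "strain_means.tsv"
        ymeans.to_csv(f2, sep="\t", index=False)
        record("phenostats", {"condition": condition}, [f, f2])

    # ---- stage: association
    res = hits = None
    if stage_on["gwa"]:
        gcfg = cfg["gwa"]
        Gf, report = filter_variants(
            G, min_maf=gcfg["min_maf"],
            exclude_chromosomes=set(gcfg["exclude_chromosomes"]))
        K = compute_centered_grm(Gf)
        y_al = y.loc[[s for s in Gf.line_ids if s in y.index]]
        if len(y_al) != len(Gf.line_ids):
            missing = set(Gf.line_ids) - set(y.index)
            raise ConfigError(f"strains missing phenotype data: {sorted(missing)[:5]}...")
        res = lmm_association(y_al, Gf, K, mode=gcfg["mode"], method=gcfg["method"],
                              add_bh=True)
        hits = top_variants(res, gcfg["threshold"])
        f = outdir / "association.tsv"
        res.to_csv(f, sep="\t", index=False, na_rep="NA")
        f2 = outdir / "top_variants.tsv"
        hits.to_csv(f2, sep="\t", index=False, na_rep="NA")
        record("gwa", {"mode": gcfg["mode"], "threshold": gcfg["threshold"],
                       "filter": report.__dict__}, [f, f2])

    # ---- stage: annotation of top variants
    cand = None
    if stage_on["annotate"]:
        if ann is None or hits is None:
            raise ConfigError("annotate stage needs an annotation input and gwa output")
        cand = candidate_gene_table(hits, ann, window=cfg["annotate"]["window"])
        f = outdir / "candidate_assignments.tsv"
        cand.multi.to_csv(f, sep="\t", index=False)
        f2 = outdir / "candidate_unique.tsv"
        cand.unique.to_csv(f2, sep="\t", index=False)
        f3 = outdir / "site_class_summary.tsv"
        pd.DataFrame(
            list(cand.site_class_counts.items()) + [
                ("unassigned_variants", cand.n_unassigned),
                ("unique_genes", len(cand.unique_genes)),
            ], columns=["class", "count"],
        ).to_csv(f3, sep="\t", index=False)
        record("annotate", {"window": cfg["annotate"]["window"]}, [f, f2, f3])

    # ---- stage: GSEA
    if stage_on["gsea"]:
        if cand is None or res is None or gene_sets is None:
            raise ConfigError("gsea stage needs annotate output and a gene-set input")
        if cand.unique.empty:
            logger.warning("no assigned candidate variants; skipping GSEA")
        else:
            # rank the whole gene universe: every tested variant contributes
            full_cand = candidate_gene_table(res.dropna(subset=["p"]), ann,
                                             window=cfg["annotate"]["window"])
            ranked = rank_genes(full_cand.unique, res)
            gs = cfg["gsea"]
            es_results = gsea_permutation_test(
                ranked, gene_sets, n_perm=gs["n_perm"], seed=cfg["seed"],
                min_genes=gs["min_genes"], min_genes_strict=gs["min_genes_strict"],
                alpha=gs["alpha"], weight_exponent=gs["weight_exponent"])
            f = outdir / "gsea.tsv"
            pd.DataFrame(
                [(r.name, r.n_genes, r.es, r.p_value, ",".join(r.leading_edge))
                 for r in es_results],
                columns=["set", "n_genes", "es", "p", "leading_edge"],
            ).to_csv(f, sep="\t", index=False)
            record("gsea", {"n_perm": gs["n_perm"], "alpha": gs["alpha"],
                            "min_genes": gs["min_genes"]}, [f])

    # ---- stage: interaction subnetwork
    if stage_on["network"]:
        if cand is None or edges is None:
            raise ConfigError("network stage needs annotate output and an edge-list input")
        sub = extract_candidate_subnetwork(set(cand.unique_genes), edges)
        f = outdir / "subnetwork_edges.tsv"
        with open(f, "w") as fh:
            fh.write("geneA\tgeneB\tweight\n")
            for a, b, w in sub.edges:
                fh.write(f"{a}\t{b}\t{w:g}\n")
        f2 = outdir / "subnetwork_nodes.tsv"
        with open(f2, "w") as fh:
            fh.write("gene\trole\n")
            for g in sorted(sub.candidates):
                fh.write(f"{g}\tcandidate\n")
            for g in sorted(sub.bridges):
                fh.write(f"{g}\tbridge\n")
        record("network", {"n_candidates_in": len(cand.unique_genes),
                           "n_retained": sub.n_connected_candidates}, [f, f2])

    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return outdir


def _load_genotypes(path: str) -> GenotypeMatrix:
    if str(path).endswith((".vcf", ".vcf.gz")):
        return mio.read_vcf(path)
    return mio.read_dosage_tsv(path)


def _causal_gene_ids(G: GenotypeMatrix, ann, scfg: SimConfig) -> list[str]:
    """Genes within the assignment window of the planted causal variants."""
    from .annotate import GeneIndex, assign_snp_to_genes

    index = GeneIndex(ann)
    out: list[str] = []
    for idx, _ in scfg.causal_variants:
        row = G.variants.iloc[idx]
        for a in assign_snp_to_genes(row["chrom"], int(row["pos"]), index):
            if a.gene_id not in out:
                out.append(a.gene_id)
    return out


def write_report(outdir: str | os.PathLike) -> Path:
    """Summarize a run directory into report.tsv (one row per completed stage)."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {outdir}")
    manifest = json.loads(manifest_path.read_text())
    rows: list[tuple[str, str, object]] = []
    for stage in manifest["stages"]:
        if stage == "simulate":
            geno = pd.read_csv(outdir / "genotypes.dosage.tsv", sep="\t", usecols=["chrom"])
            rows.append((stage, "n_variants_simulated", len(geno)))
        elif stage == "phenostats":
            df = pd.read_csv(outdir / "phenotype_stats.tsv", sep="\t")
            for _, r in df.iterrows():
                rows.append((stage, r["statistic"], r["value"]))
        elif stage == "gwa":
            res = pd.read_csv(outdir / "association.tsv", sep="\t", usecols=["p"])
            hits = pd.read_csv(outdir / "top_variants.tsv", sep="\t")
            rows.append((stage, "n_variants_tested", int(res["p"].notna().sum())))
            rows.append((stage, "n_top_variants", len(hits)))
        elif stage == "annotate":
            df = pd.read_csv(outdir / "site_class_summary.tsv", sep="\t")
            for _, r in df.iterrows():
                rows.append((stage, r["class"], int(r["count"])))
        elif stage == "gsea":
            df = pd.read_csv(outdir / "gsea.tsv", sep="\t")
            rows.append((stage, "n_significant_sets", len(df)))
        elif stage == "network":
            nodes = pd.read_csv(outdir / "subnetwork_nodes.tsv", sep="\t")
            rows.append((stage, "n_retained_candidates",
                         int((nodes["role"] == "candidate").sum())))
            rows.append((stage, "n_bridges", int((nodes["role"] == "bridge").sum())))
    report = pd.DataFrame(rows, columns=["stage", "metric", "value"])
    path = outdir / "report.tsv"
    report.to_csv(path, sep="\t", index=False)
    return path
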