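"""Gene-set enrichment on a GWAS-derived gene ranking.

Genes are scored by the best (smallest) p-value among their uniquely
assigned variants, score = -log10(min p), and ranked descending.  For a
gene set S the enrichment score is the signed maximum deviation of the
weighted Kolmogorov–Smirnov running sum

    P_hit(i)  = sum_{j<=i, j in S} |s_j|^w / N_R,   N_R = sum_{j in S} |s_j|^w
    P_miss(i) = sum_{j<=i, j not in S} 1 / (N - N_H)

walked down the ranked list.  Significance comes from permuting gene
labels on the fixed score vector (set sizes preserved); output keeps
positively enriched sets (ES > 0) with at least ``min_genes`` members in
the universe and permutation p below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GeneSetCollection
from .gwas import top_variants  # noqa: F401  (re-export convenience)

__all__ = [
    "rank_genes",
    "enrichment_score",
    "gsea_permutation_test",
    "ESResult",
]

#: -log10 score assigned to a numerically zero p-value.
MAX_SCORE = float(-np.log10(np.finfo(float).tiny))


def rank_genes(unique_assignments: pd.DataFrame, res: pd.DataFrame) -> pd.DataFrame:
    """Score genes by their best assigned variant and sort descending.

    ``unique_assignments`` is the resolved one-gene-per-variant table
    (columns chrom, pos, gene); ``res`` the association results keyed by
    (chrom, pos) with a ``p`` column.  Gene score = -log10(min p over
    the gene's variants), capped at :data:`MAX_SCORE` for p = 0.  Ties
    are broken by gene ID so the ordering is total.
    """
    if unique_assignments.empty:
        raise ValueError("no assignments to rank")
    pmap = res.set_index(["chrom", "pos"])["p"]
    keys = list(zip(unique_assignments["chrom"], unique_assignments["pos"]))
    pvals = pmap.reindex(keys).to_numpy(dtype=float)
    if np.isnan(pvals).any():
        raise ValueError("some assigned variants have no p-value in the results")
    df = pd.DataFrame({"gene": unique_assignments["gene"].to_numpy(), "p": pvals})
    best = df.groupby("gene", sort=False)["p"].min()
    with np.errstate(divide="ignore"):
        score = -np.log10(best.to_numpy())
    score = np.minimum(score, MAX_SCORE)
    ranked = pd.DataFrame({"gene": best.index.to_numpy(), "score": score})
    ranked = ranked.sort_values(["score", "gene"], ascending=[False, True],
                                kind="mergesort").reset_index(drop=True)
    return ranked


def _running_deviation(scores: np.ndarray, member: np.ndarray,
                       weight_exponent: float) -> np.ndarray:
    """P_hit - P_miss along the ranked list (scores already in rank order)."""
    N = len(scores)
    n_hit = int(member.sum())
    if n_hit == 0:
        raise ValueError("gene set has no member in the ranked universe")
    if n_hit == N:
        raise ValueError("gene set equals the entire universe: ES undefined")
    w = np.abs(scores) ** weight_exponent
    hit_w = np.where(member, w, 0.0)
    n_r = hit_w.sum()
    if n_r == 0.0:
        raise ValueError("all member scores are zero: ES undefined")
    p_hit = np.cumsum(hit_w) / n_r
    p_miss = np.cumsum(~member) / (N - n_hit)
    return p_hit - p_miss


def enrichment_score(ranked: pd.DataFrame, gene_set: set[str],
                     weight_exponent: float = 1.0,
                     ) -> tuple[float, np.ndarray, list[str]]:
    """ES, the running sum, and the leading-edge genes for one set.

    ``ranked`` is the output of :func:`rank_genes` (descending scores).
    The ES is the running sum's value at its maximum absolute deviation;
    the leading edge contains the member genes at or before that rank
    for positive ES (at or after it for negative ES).
    """
    genes = ranked["gene"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    member = np.isin(genes, list(gene_set))
    dev = _running_deviation(scores, member, weight_exponent)
    i_ext = int(np.argmax(np.abs(dev)))
    es = float(dev[i_ext])
    if es >= 0:
        leading = [g for g, m in zip(genes[: i_ext + 1], member[: i_ext + 1]) if m]
    else:
        leading = [g for g, m in zip(genes[i_ext:], member[i_ext:]) if m]
    return es, dev, leading


@dataclass
class ESResult:
    """Enrichment outcome for one gene set."""

    name: str
    n_genes: int           # members present in the ranked universe
    es: float
    p_value: float
    leading_edge: list[str]


def _permutation_es(scores: np.ndarray, n_hit: int, n_perm: int,
                    weight_exponent: float, rng: np.random.Generator,
                    chunk: int = 256) -> np.ndarray:
    """Null ES distribution: membership labels permuted, sizes preserved."""
    N = len(scores)
    w = np.abs(scores) ** weight_exponent
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        # b random membership indicators of size n_hit each
        r = rng.random((b, N))
        idx = np.argpartition(r, n_hit - 1, axis=1)[:, :n_hit]
        member = np.zeros((b, N), dtype=bool)
        np.put_along_axis(member, idx, True, axis=1)
        hit_w = np.where(member, w[None, :], 0.0)
        n_r = hit_w.sum(axis=1, keepdims=True)
        # a permutation with all-zero member weights gives ES = nan -> resample-free
        with np.errstate(invalid="ignore", divide="ignore"):
            p_hit = np.cumsum(hit_w, axis=1) / n_r
        p_miss = np.cumsum(~member, axis=1) / (N - n_hit)
        dev = p_hit - p_miss
        ext = np.take_along_axis(dev, np.nanargmax(np.abs(dev), axis=1)[:, None], axis=1)[:, 0]
        out[done:done + b] = ext
        done += b
    return out


def gsea_permutation_test(ranked: pd.DataFrame, coll: GeneSetCollection,
                          n_perm: int = 1000, seed: int = 0, min_genes: int = 3,
                          min_genes_strict: bool = False, alpha: float = 0.05,
                          weight_exponent: float = 1.0,
                          positive_only: bool = True,
                          apply_filters: bool = True) -> list[ESResult]:
    """Permutation GSEA over a collection, with the screen's output filters.

    The null permutes gene labels on the fixed ranked scores, preserving
    each set's universe size; p = (1 + #{perm ES >= observed ES}) /
    (1 + n_perm) for the positive side (the +1 smoothing avoids zero
    p-values).  With ``apply_filters`` the output keeps sets with ES > 0,
    membership >= min_genes (or > min_genes when ``min_genes_strict``),
    and p < alpha, sorted ascending by p.  Set ``apply_filters=False``
    to get every set's ES and p unfiltered.  Sets with no overlap with
    the universe are dropped with a warning.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    genes = ranked["gene"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    universe = set(genes)

    results: list[ESResult] = []
    null_cache: dict[int, np.ndarray] = {}
    for name in sorted(coll.sets):
        members_in = coll.sets[name] & universe
        n_in = len(members_in)
        if n_in == 0:
            import warnings

            warnings.warn(f"gene set {name!r} has no overlap with the ranked universe",
                          stacklevel=2)
            continue
        if n_in == len(universe):
            continue  # degenerate: set equals universe, ES undefined
        es, _, leading = enrichment_score(ranked, members_in, weight_exponent)
        if n_in not in null_cache:
            null_cache[n_in] = _permutation_es(scores, n_in, n_perm, weight_exponent, rng)
        null = null_cache[n_in]
        if positive_only:
            p = (1.0 + np.sum(null >= es)) / (1.0 + n_perm)
        else:
            p = (1.0 + np.sum(np.abs(null) >= abs(es))) / (1.0 + n_perm)
        results.append(ESResult(name=name, n_genes=n_in, es=es, p_value=float(p),
                                leading_edge=leading))

    if apply_filters:
        keep = []
        for r in results:
            size_ok = r.n_genes > min_genes if min_genes_strict else r.n_genes >= min_genes
            if r.es > 0 and size_ok and r.p_value < alpha:
                keep.append(r)
        results = keep
    return sorted(results, key=lambda r: (r.p_value, r.name))
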