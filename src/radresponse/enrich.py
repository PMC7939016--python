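"""Over-representation analysis (ORA) and pathway comparison utilities.

ORA tests a query gene list against each gene set with the hypergeometric
upper tail P[X ≥ k] conditioned on a measured-gene universe, adjusting
across sets with Benjamini-Hochberg.  The universe defaults to the genes
that survived the detection filter on the panel, not the genome: enrichment
must be conditioned on what was measured.

An Enrichr-style combined score c = ln(p)·z ranks cell-type enrichments,
with z the rank-deviation z-score of the set against a background of
seeded random queries.  Significant pathways can be exported as a bipartite
pathway-gene network, and cohorts compared at the pathway-set level.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSet

DEFAULT_PATHWAY_FDR = 0.2


def hypergeometric_ora(query: Sequence[str], sets: Sequence[GeneSet],
                       universe: Sequence[str],
                       fdr_threshold: float = DEFAULT_PATHWAY_FDR) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Query genes outside the universe are dropped with a warning; sets are
    intersected with the universe.  Returns one row per testable set with
    k (overlap), n (query size), K (set size), N (universe size), p
    (upper tail), BH ``fdr``, ``significant`` (fdr < threshold) and the
    overlap gene list.
    """
    universe = pd.Index(pd.unique(pd.Series(list(universe))))
    query_in = [g for g in dict.fromkeys(query) if g in set(universe)]
    dropped = len(dict.fromkeys(query)) - len(query_in)
    if dropped:
        warnings.warn(f"{dropped} query gene(s) outside the universe dropped")
    if not query_in:
        raise ValueError("query is empty after intersecting with the universe")
    qset = set(query_in)
    N, n = len(universe), len(query_in)
    rows = []
    for gs in sets:
        members = [g for g in gs.genes if g in set(universe)]
        if not members:
            warnings.warn(f"gene set {gs.name!r}: no overlap with the universe, skipped")
            continue
        K = len(members)
        overlap = sorted(qset.intersection(members))
        k = len(overlap)
        # P[X ≥ k], X ~ Hypergeom(N, K, n); k = 0 gives exactly 1
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": gs.name, "k": k, "n": n, "K": K, "N": N,
                     "p": min(p, 1.0), "overlap_genes": ",".join(overlap)})
    if not rows:
        raise ValueError("no testable gene sets")
    table = pd.DataFrame(rows).set_index("set")
    table["fdr"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table["significant"] = table["fdr"] < fdr_threshold
    return table.sort_values(["p", "fdr"])


def combined_score(p: float, z: float) -> float:
    """Enrichr combined score c = ln(p) · z (positive when a small p meets a
    negative rank-deviation z)."""
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]; zero p underflows — use log-space p")
    return float(np.log(p) * z)


def enrichment_z_scores(query: Sequence[str], sets: Sequence[GeneSet],
                        universe: Sequence[str], n_background: int = 200,
                        seed: int = 0) -> pd.DataFrame:
    """Rank-deviation z-scores and combined scores by seeded resampling.

    For ``n_background`` random queries of the same size, each set's rank
    (ascending p) is recorded; z = (observed rank − mean rank) / sd rank.
    A set enriched in the real query ranks better than in random queries,
    giving a negative z and (with a small p) a positive combined score.
    """
    rng = np.random.default_rng(seed)
    obs = hypergeometric_ora(query, sets, universe, fdr_threshold=1.0)
    names = obs.index
    obs_rank = pd.Series(stats.rankdata(obs["p"].to_numpy()), index=names)
    universe = list(dict.fromkeys(universe))
    n = int(obs["n"].iloc[0])
    ranks = np.empty((n_background, len(names)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(n_background):
            rand_query = rng.choice(universe, size=n, replace=False)
            bg = hypergeometric_ora(rand_query, sets, universe, fdr_threshold=1.0)
            ranks[b] = stats.rankdata(bg["p"].reindex(names).to_numpy())
    mean, sd = ranks.mean(axis=0), ranks.std(axis=0, ddof=1)
    sd[sd == 0] = np.nan
    z = (obs_rank.to_numpy() - mean) / sd
    out = obs.copy()
    out["z"] = z
    out["combined_score"] = [combined_score(p, zz) if np.isfinite(zz) else np.nan
                             for p, zz in zip(out["p"], z)]
    return out


def build_network(results: pd.DataFrame, max_sets: int | None = None):
    """Bipartite pathway-gene network of the significant ORA results.

    Returns an (edges DataFrame, pairwise shared-gene DataFrame) tuple; the
    edge list is also exportable as TSV.  ``max_sets`` keeps only the
    highest-ranked (smallest-p) significant sets.
    """
    import networkx as nx

    sig = results[results["significant"]].sort_values("p")
    if max_sets is not None:
        sig = sig.head(max_sets)
    if sig.empty:
        warnings.warn("no significant sets; empty network")
        return (pd.DataFrame(columns=["pathway", "gene"]),
                pd.DataFrame(columns=["set_a", "set_b", "shared_genes"]))
    g = nx.Graph()
    members: dict[str, set[str]] = {}
    edge_rows = []
    for name, row in sig.iterrows():
        genes = [x for x in str(row["overlap_genes"]).split(",") if x]
        members[name] = set(genes)
        g.add_node(name, kind="pathway")
        for gene in genes:
            g.add_node(gene, kind="gene")
            g.add_edge(name, gene)
            edge_rows.append((name, gene))
    edges = pd.DataFrame(edge_rows, columns=["pathway", "gene"]) \
        .sort_values(["pathway", "gene"]).reset_index(drop=True)
    names = list(members)
    shared = [(a, b, len(members[a] & members[b]))
              for i, a in enumerate(names) for b in names[i + 1:]]
    return edges, pd.DataFrame(shared, columns=["set_a", "set_b", "shared_genes"])


def compare_pathway_sets(cohort_results: Mapping[str, Sequence[str]]) -> dict:
    """Pairwise and all-cohort overlap of significant pathway names.

    Returns ``pairwise`` (DataFrame with intersection size and Jaccard) and
    ``shared_by_all`` (sorted list).
    """
    if len(cohort_results) < 2:
        raise ValueError("need at least two cohorts to compare")
    named = {k: set(v) for k, v in cohort_results.items()}
    names = list(named)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = named[a] & named[b]
            union = named[a] | named[b]
            rows.append({"cohort_a": a, "cohort_b": b,
                         "intersection": len(inter),
                         "jaccard": len(inter) / len(union) if union else np.nan,
                         "shared": ",".join(sorted(inter))})
    shared_all = set.intersection(*named.values())
    return {"pairwise": pd.DataFrame(rows),
            "shared_by_all": sorted(shared_all)}
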