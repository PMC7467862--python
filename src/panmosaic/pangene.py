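"""Pan-gene presence–absence variation: reciprocal best hits, positional
syntelog clusters, core/dispensable/singleton labels, pan/core curves and
tandem-duplication enrichment of singletons.

Pairwise similarity scores are an input (a BLAST-like table, or the
synthetic panel's identity-derived scores); RBH pairs are the mutual unique
best hits per line pair, clusters are connected components of the RBH
graph restricted to collinear edges (gene-rank offset within
``max_rank_offset``), and a cluster's size counts distinct lines.  The
singleton-vs-tandem enrichment uses Fisher's exact test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .ltr_synteny import pan_core_by_order, pan_core_curve as _pan_core_curve

__all__ = ["GeneRecord", "SyntelogCluster", "reciprocal_best_hits",
           "build_clusters", "classify_pav", "pan_core_genes",
           "tandem_enrichment"]


@dataclass
class GeneRecord:
    line: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    tandem_group: str | None = None
    max_tpm: float | None = None


@dataclass
class SyntelogCluster:
    cluster_id: int
    members: frozenset            # of (line, gene_id)
    size: int                     # distinct lines
    copy_profile: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# RBH
# ---------------------------------------------------------------------------

def reciprocal_best_hits(scores: pd.DataFrame) -> pd.DataFrame:
    """Reciprocal best hits per line pair.

    ``scores`` columns: line_a, gene_a, line_b, gene_b, score (higher is
    better; both orientations of a pair may be present and are pooled).
    Returns rows (line_a, gene_a, line_b, gene_b, score, tie) with
    line_a < line_b; exact ties are broken by lexicographically smaller
    partner id and flagged.
    """
    req = {"line_a", "gene_a", "line_b", "gene_b", "score"}
    if not req <= set(scores.columns):
        raise InputError(f"score table needs columns {sorted(req)}")
    # canonical orientation
    flip = scores.line_a > scores.line_b
    canon = scores.copy()
    canon.loc[flip, ["line_a", "gene_a", "line_b", "gene_b"]] = (
        scores.loc[flip, ["line_b", "gene_b", "line_a", "gene_a"]].to_numpy())
    def _bests(pairs):
        """gene -> (score, partner); equal-score partners resolved to the
        lexicographically smaller id and remembered as ties."""
        best: dict[str, tuple] = {}
        ties: set[str] = set()
        for g, partner, score in pairs:
            cur = best.get(g)
            if cur is None or (-score, partner) < cur:
                if cur is not None and cur[0] == -score:
                    ties.add(g)
                best[g] = (-score, partner)
            elif cur[0] == -score:
                ties.add(g)
        return best, ties

    out_rows = []
    for (la, lb), sub in canon.groupby(["line_a", "line_b"], sort=True):
        rows = list(sub.itertuples())
        best_a, tie_a = _bests((r.gene_a, r.gene_b, r.score) for r in rows)
        best_b, tie_b = _bests((r.gene_b, r.gene_a, r.score) for r in rows)
        for ga, (negs, gb) in sorted(best_a.items()):
            hit = best_b.get(gb)
            if hit is not None and hit[1] == ga:
                out_rows.append(dict(line_a=la, gene_a=ga, line_b=lb,
                                     gene_b=gb, score=-negs,
                                     tie=ga in tie_a or gb in tie_b))
    return pd.DataFrame(out_rows,
                        columns=["line_a", "gene_a", "line_b", "gene_b",
                                 "score", "tie"])


# ---------------------------------------------------------------------------
# Clusters
# ---------------------------------------------------------------------------

def _gene_ranks(genes: pd.DataFrame) -> dict[tuple[str, str], tuple[str, int]]:
    """(line, gene_id) -> (chrom, collinear rank along the chromosome)."""
    ranks = {}
    for (line, chrom), sub in genes.groupby(["line", "chrom"]):
        ordered = sub.sort_values("start")
        for k, gid in enumerate(ordered.gene_id):
            ranks[(line, gid)] = (chrom, k)
    return ranks


def build_clusters(rbh_pairs: pd.DataFrame, genes: pd.DataFrame,
                   max_rank_offset: int = 10) -> list[SyntelogCluster]:
    """Syntelog clusters: connected components of the position-consistent
    RBH graph.  An edge is kept when both genes lie on the same chromosome
    name with gene-rank offset <= ``max_rank_offset``; every gene appears
    in exactly one cluster (singletons included)."""
    ranks = _gene_ranks(genes)
    parent: dict = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    nodes = [(r.line, r.gene_id) for r in genes.itertuples()]
    for n in nodes:
        parent.setdefault(n, n)
    for r in rbh_pairs.itertuples():
        a = (r.line_a, r.gene_a)
        b = (r.line_b, r.gene_b)
        ca, ka = ranks.get(a, (None, None))
        cb, kb = ranks.get(b, (None, None))
        if ca is None or cb is None:
            continue
        if ca == cb and abs(ka - kb) <= max_rank_offset:
            union(a, b)
    comp: dict = {}
    for n in nodes:
        comp.setdefault(find(n), []).append(n)
    clusters = []
    for cid, members in enumerate(sorted(comp.values(), key=lambda m: sorted(m)[0])):
        profile: dict[str, int] = {}
        for line, _g in members:
            profile[line] = profile.get(line, 0) + 1
        clusters.append(SyntelogCluster(cid, frozenset(members),
                                        size=len(profile), copy_profile=profile))
    return clusters


# ---------------------------------------------------------------------------
# PAV
# ---------------------------------------------------------------------------

def classify_pav(clusters: list[SyntelogCluster], n_lines: int):
    """Per-gene PAV labels (core iff cluster spans all lines, singleton iff
    one line, dispensable otherwise) and the per-line histogram of genes by
    cluster size."""
    labels: dict[tuple[str, str], str] = {}
    hist_rows = []
    for cl in clusters:
        if cl.size == n_lines:
            lab = "core"
        elif cl.size == 1:
            lab = "singleton"
        else:
            lab = "dispensable"
        for line, gid in cl.members:
            labels[(line, gid)] = lab
            hist_rows.append((line, cl.size))
    hist = (pd.DataFrame(hist_rows, columns=["line", "cluster_size"])
            .groupby(["line", "cluster_size"]).size()
            .rename("n_genes").reset_index())
    return labels, hist


def pan_core_genes(clusters: list[SyntelogCluster], lines: list[str],
                   orderings: str | int = "all", seed: int = 0) -> pd.DataFrame:
    """Pan/core gene-cluster curve over line orderings (see the fl-LTR
    pan/core curve for semantics)."""
    sets = [frozenset(cl.copy_profile) for cl in clusters]
    return _pan_core_curve(sets, lines, orderings=orderings, seed=seed)


# ---------------------------------------------------------------------------
# Tandem enrichment
# ---------------------------------------------------------------------------

def tandem_enrichment(singletons: set, tandem_genes: set, universe: set):
    """Fisher exact test of tandem-duplicate enrichment among singletons.

    2x2 table: [singleton & tandem, singleton & not] vs [other & tandem,
    other & not].  Returns (odds_ratio, p_two_sided); degenerate margins
    give (nan, 1.0).
    """
    s_t = len(singletons & tandem_genes)
    s_n = len(singletons - tandem_genes)
    others = universe - singletons
    o_t = len(others & tandem_genes)
    o_n = len(others - tandem_genes)
    table = np.array([[s_t, s_n], [o_t, o_n]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return float("nan"), 1.0
    res = stats.fisher_exact(table, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
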