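"""Guilt-by-association co-expression network on the highest reciprocal rank.

For every gene pair the Pearson correlation of their log-expression profiles
is computed; each gene then ranks all other genes by decreasing correlation
(ordinal ranks, 1 = best).  The highest reciprocal rank of a pair is

    HRR(i, j) = max(rank_i(j), rank_j(i)),

a mutual-rank statistic: a small HRR means the two genes sit near the top of
each other's neighbour lists.  Around a set of bait (known pathway) genes,
every pair with ``HRR < tau`` (default 100, strict) is captured into an
undirected network, whose communities are found by fast-greedy (Clauset-
Newman-Moore) modularity agglomeration.  Candidates are reported per bait,
ordered by ascending HRR.

Rank ties are broken by ascending gene id so HRR stays integral and every
step is deterministic; modularity is unweighted, with PCC/HRR kept as edge
attributes only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "pcc_matrix",
    "rank_neighbors",
    "hrr",
    "build_network",
    "modularity",
    "fast_greedy_communities",
    "CommunityPartition",
    "CandidateReport",
    "candidate_report",
    "profile_filter",
    "network_edge_table",
    "write_graphml",
]


def pcc_matrix(log_expr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of gene rows (genes x samples input).

    Zero-variance genes cannot be correlated; they are excluded with a
    warning naming them.  Requires >= 3 samples.
    """
    if log_expr.shape[1] < 3:
        raise ValueError("need >= 3 samples to correlate expression profiles")
    values = log_expr.to_numpy(dtype=float)
    keep = values.std(axis=1) > 0
    dropped = list(log_expr.index[~keep])
    if dropped:
        warnings.warn(f"excluding {len(dropped)} zero-variance genes: {dropped[:5]}", stacklevel=2)
    genes = log_expr.index[keep]
    corr = np.corrcoef(values[keep])
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=genes, columns=genes)


def rank_neighbors(corr: pd.DataFrame) -> pd.DataFrame:
    """Ordinal neighbour ranks per row: 1 = highest PCC, self = 0.

    Ties in PCC are broken by ascending gene id, so ranks are a permutation
    of 1..(n-1) in every row regardless of gene input order.
    """
    genes = corr.index
    n = len(genes)
    # id-rank used for deterministic tie-breaks
    id_order = np.argsort(np.argsort(genes.to_numpy().astype(str)))
    values = corr.to_numpy()
    ranks = np.zeros((n, n), dtype=np.int64)
    positions = np.arange(n)
    for i in range(n):
        order = np.lexsort((id_order, -values[i]))
        order = order[order != i]
        row = np.zeros(n, dtype=np.int64)
        row[order] = positions[: n - 1] + 1
        ranks[i] = row
    return pd.DataFrame(ranks, index=genes, columns=genes)


def hrr(rank_matrix: pd.DataFrame) -> pd.DataFrame:
    """Highest reciprocal rank: elementwise max of the two directed ranks."""
    values = rank_matrix.to_numpy()
    return pd.DataFrame(
        np.maximum(values, values.T), index=rank_matrix.index, columns=rank_matrix.columns
    )


def build_network(
    hrr_matrix: pd.DataFrame,
    baits: list[str],
    tau: int = 100,
    capture: str = "bait-anchored",
    pcc: pd.DataFrame | None = None,
) -> nx.Graph:
    """Capture the co-expression network around bait genes at ``HRR < tau``.

    ``bait-anchored`` (default) keeps only edges touching at least one bait;
    ``all-pairs`` additionally connects captured non-bait genes to each other
    under the same strict threshold.  Node attribute ``is_bait`` marks baits;
    edges carry ``hrr`` (and ``pcc`` when a correlation matrix is given).
    """
    if capture not in ("bait-anchored", "all-pairs"):
        raise ValueError(f"unknown capture mode {capture!r}")
    genes = list(hrr_matrix.index)
    present = [b for b in baits if b in hrr_matrix.index]
    if not present:
        raise ValueError("no bait gene present in the HRR matrix")
    H = hrr_matrix.to_numpy()
    pos = {g: i for i, g in enumerate(genes)}
    bait_set = set(present)
    G = nx.Graph()
    for b in sorted(present):
        G.add_node(b, is_bait=True)
    edges: set[tuple[str, str]] = set()
    for b in sorted(present):
        i = pos[b]
        for j, g in enumerate(genes):
            if g == b:
                continue
            if H[i, j] < tau:
                edges.add((min(b, g), max(b, g)))
    captured = sorted(set(u for e in edges for u in e) | bait_set)
    if capture == "all-pairs":
        for ui, u in enumerate(captured):
            for v in captured[ui + 1 :]:
                if H[pos[u], pos[v]] < tau:
                    edges.add((u, v))
    for g in captured:
        if g not in G:
            G.add_node(g, is_bait=False)
    for u, v in sorted(edges):
        attrs = {"hrr": int(H[pos[u], pos[v]])}
        if pcc is not None:
            attrs["pcc"] = float(pcc.loc[u, v])
        G.add_edge(u, v, **attrs)
    if G.number_of_edges() == 0:
        warnings.warn("no pair under the HRR threshold; baits are isolated", stacklevel=2)
    return G


def modularity(network: nx.Graph, partition: dict[str, int]) -> float:
    """Unweighted Newman modularity Q = sum_c (e_c - a_c^2).

    ``e_c`` is the fraction of edges inside community c and ``a_c`` the
    fraction of edge ends attached to c.  Requires >= 1 edge.
    """
    m = network.number_of_edges()
    if m == 0:
        raise ValueError("modularity is undefined on an edgeless network")
    nodes = set(network.nodes)
    if not nodes <= set(partition):
        raise ValueError("partition does not cover the node set")
    e: dict[int, float] = {}
    a: dict[int, float] = {}
    for u, v in network.edges:
        cu, cv = partition[u], partition[v]
        if cu == cv:
            e[cu] = e.get(cu, 0.0) + 1.0 / m
        a[cu] = a.get(cu, 0.0) + 0.5 / m
        a[cv] = a.get(cv, 0.0) + 0.5 / m
    return float(sum(e.get(c, 0.0) - a[c] ** 2 for c in a))


@dataclass
class CommunityPartition:
    """Node -> community id map plus the modularity of the partition."""

    communities: dict[str, int]
    modularity: float

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, c in self.communities.items():
            out.setdefault(c, []).append(node)
        return {c: sorted(ms) for c, ms in sorted(out.items())}


def fast_greedy_communities(network: nx.Graph) -> CommunityPartition:
    """Clauset-Newman-Moore greedy modularity agglomeration, deterministic.

    Starts from singleton communities and repeatedly merges the connected
    community pair with the largest modularity gain, breaking ties on the
    lexicographically smallest pair of community labels (a community is
    labelled by its smallest member id).  The partition attaining the highest
    modularity along the merge path is returned.  Isolated nodes remain
    singleton communities.
    """
    m = network.number_of_edges()
    if m == 0:
        raise ValueError("community detection is undefined on an edgeless network")
    # community state: label -> members; e[frozen pair] edge fractions
    members: dict[str, set[str]] = {str(v): {v} for v in network.nodes}
    a = {str(v): network.degree(v) / (2.0 * m) for v in network.nodes}
    e_between: dict[tuple[str, str], float] = {}
    e_within = {str(v): 0.0 for v in network.nodes}
    for u, v in network.edges:
        cu, cv = str(u), str(v)
        if cu == cv:
            continue
        key = (min(cu, cv), max(cu, cv))
        e_between[key] = e_between.get(key, 0.0) + 1.0 / m

    def snapshot() -> dict[str, int]:
        labels = sorted(members)
        return {node: i for i, label in enumerate(labels) for node in members[label]}

    q = sum(e_within[c] - a[c] ** 2 for c in members)
    best_q, best_partition = q, snapshot()
    while e_between:
        # pick the merge with maximal dQ; ties -> smallest (label, label) pair
        best_pair, best_dq = None, None
        for (c1, c2) in e_between:
            # e_between stores the full between fraction; dQ = 2(e_ij - a_i a_j)
            # with e_ij the half-fraction, i.e. dQ = e_between - 2 a_i a_j
            dq = 2.0 * (e_between[(c1, c2)] / 2.0 - a[c1] * a[c2])
            if best_dq is None or dq > best_dq + 1e-15 or (
                abs(dq - best_dq) <= 1e-15 and (c1, c2) < best_pair
            ):
                best_pair, best_dq = (c1, c2), dq
        c1, c2 = best_pair
        new = min(c1, c2)
        gone = c2 if new == c1 else c1
        members[new] |= members.pop(gone)
        e_within[new] = e_within[new] + e_within.pop(gone) + e_between.pop((c1, c2))
        a[new] = a[new] + a.pop(gone)
        # reroute between-community fractions touching the removed label
        for key in [k for k in e_between if gone in k]:
            other = key[0] if key[1] == gone else key[1]
            val = e_between.pop(key)
            if other == new:
                e_within[new] += val
            else:
                nk = (min(new, other), max(new, other))
                e_between[nk] = e_between.get(nk, 0.0) + val
        q += best_dq
        if q > best_q + 1e-12:
            best_q, best_partition = q, snapshot()
    return CommunityPartition(communities=best_partition, modularity=float(best_q))


@dataclass
class CandidateReport:
    """Per-bait ranked candidates and per-community composition tables."""

    candidates: pd.DataFrame  # bait, gene, hrr, pcc, community, shared, keywords
    communities: pd.DataFrame  # community, size, n_baits, baits


def candidate_report(
    network: nx.Graph,
    partition: CommunityPartition,
    annotations: pd.DataFrame | None = None,
) -> CandidateReport:
    """Rank each bait's non-bait neighbours and summarize the communities.

    Candidates sort by ascending HRR, then descending PCC, then gene id.
    ``annotations`` (transcript_id, keyword rows) adds a keywords column.
    """
    comm = partition.communities
    if not set(network.nodes) <= set(comm):
        raise ValueError("partition does not cover the network")
    kw_of: dict[str, str] = {}
    if annotations is not None:
        for tid, sub in annotations.groupby("transcript_id"):
            kw_of[tid] = ";".join(sorted(sub["keyword"]))
    rows = []
    baits = sorted(n for n, d in network.nodes(data=True) if d.get("is_bait"))
    for b in baits:
        cands = []
        for g in network.neighbors(b):
            if network.nodes[g].get("is_bait"):
                continue
            d = network.edges[b, g]
            cands.append((d["hrr"], -d.get("pcc", 0.0), g))
        for hrr_val, neg_pcc, g in sorted(cands):
            rows.append(
                {
                    "bait": b,
                    "gene": g,
                    "hrr": hrr_val,
                    "pcc": -neg_pcc,
                    "community": comm[g],
                    "shared_community": comm[g] == comm[b],
                    "keywords": kw_of.get(g, ""),
                }
            )
    cand_df = pd.DataFrame(
        rows, columns=["bait", "gene", "hrr", "pcc", "community", "shared_community", "keywords"]
    )
    crow = []
    for c, ms in partition.members().items():
        bs = [x for x in ms if x in set(baits)]
        crow.append(
            {"community": c, "size": len(ms), "n_baits": len(bs), "baits": ";".join(bs)}
        )
    comm_df = pd.DataFrame(crow).sort_values("size", ascending=False).reset_index(drop=True)
    return CandidateReport(candidates=cand_df, communities=comm_df)


def profile_filter(
    candidates: list[str],
    tpm: pd.DataFrame,
    meta: pd.DataFrame,
    pattern_tissues: tuple[str, ...] = ("YL", "YS"),
) -> list[str]:
    """Keep candidates whose tissue-mean TPM peaks in the pattern's tissues.

    The default pattern keeps genes maximal in the young aerial parts.
    """
    meta_idx = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    tissues = sorted(set(meta_idx["tissue"]))
    unknown = set(pattern_tissues) - set(tissues)
    if unknown:
        raise ValueError(f"unknown tissues in pattern: {sorted(unknown)}")
    missing = [c for c in candidates if c not in tpm.index]
    if missing:
        raise ValueError(f"candidates missing from TPM matrix: {missing[:3]}")
    tissue_means = pd.DataFrame(
        {
            t: tpm[[s for s in meta_idx.index[meta_idx["tissue"] == t] if s in tpm.columns]].mean(
                axis=1
            )
            for t in tissues
        }
    )
    kept = []
    for c in candidates:
        peak = tissue_means.loc[c].idxmax()
        if peak in pattern_tissues:
            kept.append(c)
    return kept


def network_edge_table(network: nx.Graph) -> pd.DataFrame:
    """Edge list (u, v, pcc, hrr) sorted for reproducible output."""
    rows = [
        {
            "u": min(u, v),
            "v": max(u, v),
            "pcc": d.get("pcc", np.nan),
            "hrr": d["hrr"],
        }
        for u, v, d in network.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["u", "v", "pcc", "hrr"]).sort_values(["u", "v"]).reset_index(
        drop=True
    )


def write_graphml(
    network: nx.Graph,
    path,
    partition: CommunityPartition | None = None,
    annotations: pd.DataFrame | None = None,
) -> None:
    """GraphML export with is_bait, community and keyword node attributes."""
    G = nx.Graph()
    kw_of: dict[str, str] = {}
    if annotations is not None:
        for tid, sub in annotations.groupby("transcript_id"):
            kw_of[tid] = ";".join(sorted(sub["keyword"]))
    for n in sorted(network.nodes):
        attrs = {"is_bait": bool(network.nodes[n].get("is_bait", False))}
        if partition is not None:
            attrs["community"] = int(partition.communities[n])
        if kw_of:
            attrs["keywords"] = kw_of.get(n, "")
        G.add_node(n, **attrs)
    for u, v in sorted((min(u, v), max(u, v)) for u, v in network.edges):
        G.add_edge(u, v, **network.edges[u, v])
    nx.write_graphml(G, path)
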