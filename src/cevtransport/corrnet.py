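"""Transport-metric correlations, ranked lists, and interaction networks.

Spearman rank correlations between per-donor feature values (protein or
gene-product intensities, blood counts, nanoparticle features) and the
transport metrics are recorded only when the test p-value is <= 0.05;
non-significant coefficients are set to 0. The recorded-rho matrix feeds
hierarchical clustering; per-metric correlation results feed ranked lists
(score = (1 - p) * sign(rho)) for enrichment export, with multi-metric
lists merged by each gene's best (minimum) rank. Protein-interaction
edges (STRING-style combined scores) are filtered at >= 0.7 and grouped
by greedy modularity-based community clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import networkx as nx
from networkx.algorithms.community import greedy_modularity_communities
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "CorrResult",
    "spearman_thresholded",
    "correlation_cluster",
    "ranked_list",
    "merge_ranked_lists",
    "count_metric_overlaps",
    "metric_totals",
    "filter_edges",
    "community_clusters",
    "minimal_term_cover",
    "read_string_edges",
    "write_ranked_list",
]

SIGNIFICANCE_P = 0.05
EDGE_SCORE_MIN = 0.7

NOT_COMPUTED = "not_computed"


@dataclass(frozen=True)
class CorrResult:
    """One Spearman correlation with the p <= 0.05 recording rule applied.

    ``recorded`` is ``rho`` when the test is significant, 0 otherwise, and
    ``None`` when fewer than 3 complete pairs were available (not
    computed — distinct from a non-significant 0).
    """

    rho: Optional[float]
    p: Optional[float]
    recorded: Optional[float]
    n: int


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    """Exact two-sided permutation p for small n (<= 9), mid-ranks kept."""
    from itertools import permutations

    n = len(rx)
    rx = rx - rx.mean()
    denom = np.sqrt((rx**2).sum() * ((ry - ry.mean()) ** 2).sum())
    if denom == 0:
        return 1.0
    target = abs(rho)
    count = 0
    total = 0
    ry_c = ry - ry.mean()
    for perm in permutations(range(n)):
        r = float((rx * ry_c[list(perm)]).sum() / denom)
        if abs(r) >= target - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_thresholded(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = SIGNIFICANCE_P,
    min_n: int = 3,
) -> CorrResult:
    """Spearman rank correlation with the significance-recording rule.

    Missing pairs are dropped first; fewer than ``min_n`` complete pairs
    yields a not-computed result. Ties get mid-ranks. The two-sided
    p-value is exact (permutation) for n <= 9 and uses the
    t-approximation otherwise; ``recorded`` is rho when p <= alpha,
    else 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < min_n:
        return CorrResult(rho=None, p=None, recorded=None, n=n)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    denom = np.sqrt(((rx - rx.mean()) ** 2).sum() * ((ry - ry.mean()) ** 2).sum())
    if denom == 0:
        return CorrResult(rho=None, p=None, recorded=None, n=n)
    rho = float(((rx - rx.mean()) * (ry - ry.mean())).sum() / denom)
    if n <= 9:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        # t-approximation
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    recorded = rho if p <= alpha else 0.0
    return CorrResult(rho=rho, p=p, recorded=recorded, n=n)


def correlation_matrix(
    features: pd.DataFrame, targets: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Recorded-rho matrix between feature rows (and target rows).

    ``features`` (and ``targets``) are feature-by-observation tables; the
    result holds the recorded coefficient (0 unless p <= 0.05, NaN when
    not computable) for every feature pair, or feature x target pair when
    ``targets`` is given.
    """
    right = features if targets is None else targets
    out = pd.DataFrame(index=features.index, columns=right.index, dtype=float)
    for fi in features.index:
        for ti in right.index:
            res = spearman_thresholded(features.loc[fi], right.loc[ti])
            out.loc[fi, ti] = np.nan if res.recorded is None else res.recorded
    return out


def correlation_cluster(
    recorded: pd.DataFrame, method: str = "complete"
) -> Tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Hierarchically cluster rows and columns of a recorded-rho matrix.

    Complete linkage on the Euclidean distance of recorded-rho rows
    (columns likewise); constant rows cluster by their values like any
    other row and deterministic scipy ordering is used throughout.
    Returns (reordered matrix, row linkage, column linkage).
    """
    M = recorded.to_numpy(dtype=float)
    if np.isnan(M).any():
        raise ValueError("recorded matrix must not contain missing values")
    if (M.std(axis=1) == 0).any():
        import warnings

        warnings.warn("constant rows present; they carry no clustering signal")

    def order(mat: np.ndarray) -> np.ndarray:
        if mat.shape[0] < 2:
            return np.arange(mat.shape[0])
        Z = linkage(mat, method=method, metric="euclidean")
        return leaves_list(Z)

    row_order = order(M)
    col_order = order(M.T)
    reordered = recorded.iloc[row_order, col_order]
    Zr = linkage(M, method=method) if M.shape[0] > 1 else np.empty((0, 4))
    Zc = linkage(M.T, method=method) if M.shape[1] > 1 else np.empty((0, 4))
    return reordered, Zr, Zc


def ranked_list(corr: Mapping[str, CorrResult]) -> pd.DataFrame:
    """Genes ranked by ``(1 - p) * sign(rho)``, descending.

    Correlating genes end up at the top, anti-correlating at the bottom.
    Not-computed genes are omitted. Returns columns ``score`` and
    ``rank`` (1-based).
    """
    rows = {
        g: (1.0 - r.p) * np.sign(r.rho)
        for g, r in corr.items()
        if r.p is not None and r.rho is not None
    }
    if not rows:
        return pd.DataFrame(columns=["score", "rank"])
    s = pd.Series(rows, name="score").sort_values(ascending=False, kind="mergesort")
    out = s.to_frame()
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def merge_ranked_lists(per_metric: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Merge per-metric ranked lists by each gene's best (minimum) rank.

    A gene highly ranked by any included metric stays at the top of the
    merged list, matching the lists' purpose as enrichment input. Returns
    columns ``merged_rank`` plus the per-metric ranks, sorted by merged
    rank (gene name breaks ties).
    """
    if not per_metric:
        raise ValueError("need at least one metric's ranked list")
    ranks = pd.DataFrame(
        {m: df["rank"] for m, df in per_metric.items()}
    )
    merged = ranks.min(axis=1, skipna=True)
    out = ranks.copy()
    out["merged_rank"] = merged
    out = out.dropna(subset=["merged_rank"])
    # stable sort by merged rank, gene name breaking ties
    return out.sort_index(kind="mergesort").sort_values("merged_rank", kind="mergesort")


def count_metric_overlaps(
    corr_tk: Mapping[str, CorrResult],
    corr_rms: Mapping[str, CorrResult],
    corr_vdv: Mapping[str, CorrResult],
) -> pd.DataFrame:
    """Partition significantly correlating genes by metric subset and sign.

    Rows are the 7 nonempty subsets of {TK, RMS, VDV} (a gene significant
    for several metrics with mixed signs contributes to the positive
    partition for its positively correlated subset and to the negative
    partition for the negative subset); columns are ``positive`` and
    ``negative`` counts. Per-metric totals are computed by
    :func:`metric_totals`, never stored.
    """
    subsets = [
        ("TK",),
        ("RMS",),
        ("VDV",),
        ("TK", "RMS"),
        ("RMS", "VDV"),
        ("TK", "VDV"),
        ("TK", "RMS", "VDV"),
    ]
    labels = ["+".join(s) if len(s) > 1 else f"{s[0]} only" for s in subsets]
    counts = pd.DataFrame(0, index=labels, columns=["positive", "negative"])
    genes = set(corr_tk) | set(corr_rms) | set(corr_vdv)
    by_metric = {"TK": corr_tk, "RMS": corr_rms, "VDV": corr_vdv}
    for g in genes:
        for sign_name, sgn in (("positive", 1), ("negative", -1)):
            sig = tuple(
                m
                for m in ("TK", "RMS", "VDV")
                if g in by_metric[m]
                and by_metric[m][g].recorded is not None
                and np.sign(by_metric[m][g].recorded) == sgn
            )
            if sig:
                label = "+".join(sig) if len(sig) > 1 else f"{sig[0]} only"
                counts.loc[label, sign_name] += 1
    return counts


def metric_totals(overlap_counts: pd.DataFrame) -> pd.DataFrame:
    """Per-metric totals from the 7-subset partition (sum of the four
    subsets containing each metric, positives and negatives separately)."""
    totals = pd.DataFrame(0, index=["TK", "RMS", "VDV"], columns=overlap_counts.columns)
    for label, row in overlap_counts.iterrows():
        members = label.replace(" only", "").split("+")
        for m in members:
            totals.loc[m] += row
    return totals


def filter_edges(
    edges: pd.DataFrame, min_score: float = EDGE_SCORE_MIN
) -> Tuple[pd.DataFrame, Set[str]]:
    """Keep interaction edges with combined score >= ``min_score``.

    ``edges`` has columns ``protein1, protein2, combined_score``; scores
    supplied on the 0-1000 database scale are divided by 1000. Returns
    the retained edges and the set of nodes left isolated (to be omitted
    from network figures).
    """
    required = {"protein1", "protein2", "combined_score"}
    if not required.issubset(edges.columns):
        raise ValueError(f"edge table needs columns {sorted(required)}")
    scores = edges["combined_score"].to_numpy(dtype=float)
    if np.any(scores < 0) or np.any(scores > 1000):
        raise ValueError("combined scores must lie in [0, 1] or [0, 1000]")
    if np.any(scores > 1.0):
        scores = scores / 1000.0
    edges = edges.assign(combined_score=scores)
    kept = edges[edges["combined_score"] >= min_score].reset_index(drop=True)
    all_nodes = set(edges["protein1"]) | set(edges["protein2"])
    connected = set(kept["protein1"]) | set(kept["protein2"])
    return kept, all_nodes - connected


def community_clusters(edges: pd.DataFrame) -> Dict[str, int]:
    """Modularity-based community partition of a filtered edge set.

    Greedy modularity agglomeration (the family the GLay visualization
    plugin implements) with deterministic ordering: nodes are inserted in
    sorted order and communities are numbered by their lexicographically
    smallest member. Returns node -> community id.
    """
    if len(edges) == 0:
        raise ValueError("need a nonempty edge set")
    G = nx.Graph()
    for n in sorted(set(edges["protein1"]) | set(edges["protein2"])):
        G.add_node(n)
    for _, row in edges.iterrows():
        G.add_edge(row["protein1"], row["protein2"], weight=float(row["combined_score"]))
    comms = greedy_modularity_communities(G)
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    return {node: i for i, members in enumerate(comms) for node in members}


def minimal_term_cover(term_to_genes: Mapping[str, Set[str]]) -> List[str]:
    """Greedy set cover: the smallest term list explaining all genes.

    Terms are chosen by maximal number of still-uncovered genes
    (lexicographic tie-break) until every gene of the union is covered.
    """
    universe = set().union(*term_to_genes.values()) if term_to_genes else set()
    uncovered = set(universe)
    chosen: List[str] = []
    while uncovered:
        best = max(
            sorted(term_to_genes),
            key=lambda t: len(term_to_genes[t] & uncovered),
        )
        gain = len(term_to_genes[best] & uncovered)
        if gain == 0:
            break
        chosen.append(best)
        uncovered -= term_to_genes[best]
    return chosen


def read_string_edges(path) -> pd.DataFrame:
    """Read a STRING-style edge TSV (``protein1 protein2 combined_score``)."""
    df = pd.read_csv(path, sep=r"\s+")
    required = {"protein1", "protein2", "combined_score"}
    if not required.issubset(df.columns):
        raise ValueError(f"edge file needs columns {sorted(required)}")
    bad = df["combined_score"].isna()
    if bad.any():
        raise ValueError(f"malformed edge record at line {int(bad.idxmax()) + 2}")
    return df


def write_ranked_list(ranked: pd.DataFrame, path) -> None:
    """Two-column (gene, score) TSV compatible with enrichment upload."""
    ranked[["score"]].to_csv(path, sep="\t", header=False)
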