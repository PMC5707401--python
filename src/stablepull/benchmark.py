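"""Functional-coherence benchmarking of called interactomes.

The premise is guilt by association: genuine interaction partners tend
to act in the same biological process, so a high GO semantic similarity
between bait and prey is evidence for a physiological interaction.  The
calibration uses a reference interaction network: pairs connected by an
edge form the positive similarity distribution, all disconnected pairs
form the null.  The empirical false discovery rate of a candidate
similarity threshold t is the fraction of null pairs scoring at or above
t; the working threshold is the smallest observed similarity with
empirical FDR below alpha.  Interactor lists ranked by SILAC enrichment
are then scored with precision-recall curves in which a pair is "true"
when its similarity reaches the threshold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoherenceBenchmark",
    "PRCurve",
    "ReferenceNetwork",
    "build_null",
    "compare_distributions",
    "disconnected_pair_count",
    "empirical_fdr_threshold",
    "precision_recall_curve",
    "read_edge_list",
    "write_edge_list",
]


@dataclass(frozen=True)
class ReferenceNetwork:
    """Undirected simple graph: node set N, edge set L (distinct pairs)."""

    nodes: tuple[str, ...]
    edges: frozenset  # of frozenset({u, v})

    @classmethod
    def from_edges(cls, nodes, edge_pairs) -> "ReferenceNetwork":
        nodes = tuple(sorted(set(nodes)))
        node_set = set(nodes)
        edges = set()
        for u, v in edge_pairs:
            if u == v:
                raise ValueError(f"self edge rejected: {u}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge endpoint not in node set: {(u, v)}")
            e = frozenset((u, v))
            if e in edges:
                raise ValueError(f"duplicate edge rejected: {(u, v)}")
            edges.add(e)
        return cls(nodes=nodes, edges=frozenset(edges))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def n_disconnected(self) -> int:
        return disconnected_pair_count(self.n_nodes, self.n_edges)


def disconnected_pair_count(n_nodes: int, n_edges: int) -> int:
    """Size of the disconnected-pair null universe: N(N-1)/2 - L."""
    total = n_nodes * (n_nodes - 1) // 2
    if n_edges > total:
        raise ValueError(
            f"{n_edges} edges exceed the {total} possible pairs of "
            f"{n_nodes} nodes")
    return total - n_edges


def read_edge_list(path) -> ReferenceNetwork:
    """Two-column TSV edge list; '#' comments and an optional header."""
    pairs = []
    nodes = set()
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")[:2]
            if i == 0 and cols[0].lower() in ("source", "node1", "protein1",
                                              "gene1", "gene_a", "protein_a"):
                continue
            pairs.append((cols[0], cols[1]))
            nodes.update(cols)
    return ReferenceNetwork.from_edges(nodes, pairs)


def write_edge_list(network: ReferenceNetwork, path) -> None:
    with open(path, "w") as fh:
        for e in sorted(tuple(sorted(e)) for e in network.edges):
            fh.write(f"{e[0]}\t{e[1]}\n")


@dataclass
class CoherenceBenchmark:
    """Positive/null similarity distributions and the derived threshold."""

    wi_connected: np.ndarray
    wi_null: np.ndarray
    null_mode: str
    n_excluded_connected: int = 0
    n_excluded_null: int = 0
    fdr_alpha: float | None = None
    wi_threshold: float | None = None
    mwu_p: float | None = None

    def summary(self) -> dict:
        def _stats(a):
            a = np.asarray(a, dtype=float)
            if a.size == 0:
                return {"n": 0}
            return {"n": int(a.size), "median": float(np.median(a)),
                    "mean": float(np.mean(a)), "q1": float(np.quantile(a, .25)),
                    "q3": float(np.quantile(a, .75))}
        return {
            "connected": _stats(self.wi_connected),
            "null": _stats(self.wi_null),
            "excluded_unscorable": {"connected": self.n_excluded_connected,
                                    "null": self.n_excluded_null},
            "null_mode": self.null_mode,
            "fdr_alpha": self.fdr_alpha,
            "wi_threshold": self.wi_threshold,
            "mwu_p": self.mwu_p,
        }


def _iter_disconnected(network: ReferenceNetwork):
    for u, v in itertools.combinations(network.nodes, 2):
        if frozenset((u, v)) not in network.edges:
            yield u, v


def _sample_disconnected(network: ReferenceNetwork, n: int, seed: int):
    """Seeded uniform sample (without replacement) of disconnected pairs."""
    total = network.n_disconnected()
    if n >= total:
        return list(_iter_disconnected(network))
    rng = np.random.default_rng(seed)
    nodes = network.nodes
    m = len(nodes)
    chosen: set[frozenset] = set()
    out = []
    while len(out) < n:
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        e = frozenset((nodes[i], nodes[j]))
        if e in chosen or e in network.edges:
            continue
        chosen.add(e)
        out.append(tuple(sorted(e)))
    return out


def build_null(network: ReferenceNetwork, similarity_fn, *,
               mode: str = "auto", n_samples: int = 100_000,
               seed: int = 0, exhaustive_limit: int = 100_000,
               ) -> CoherenceBenchmark:
    """Score connected and disconnected pairs with ``similarity_fn``.

    ``similarity_fn(u, v)`` returns a similarity, with -1 marking an
    unscorable (unannotated) pair; such pairs are excluded from both
    distributions with their counts recorded.  The null covers every
    disconnected pair (``exhaustive``) or a seeded uniform sample of
    ``n_samples`` of them (``sampled``); ``auto`` picks exhaustive when
    the null universe has at most ``exhaustive_limit`` pairs.
    """
    if network.n_edges == 0:
        raise ValueError("reference network has no edges; cannot build the "
                         "positive distribution")
    if mode == "auto":
        mode = ("exhaustive" if network.n_disconnected() <= exhaustive_limit
                else "sampled")

    connected, excl_c = [], 0
    for e in sorted(tuple(sorted(e)) for e in network.edges):
        wi = similarity_fn(*e)
        if wi == -1:
            excl_c += 1
        else:
            connected.append(wi)

    if mode == "exhaustive":
        null_pairs = _iter_disconnected(network)
        mode_tag = "exhaustive"
    elif mode == "sampled":
        null_pairs = _sample_disconnected(network, n_samples, seed)
        mode_tag = f"sampled(n={n_samples}, seed={seed})"
    else:
        raise ValueError(f"unknown null mode {mode!r}")

    null, excl_n = [], 0
    for u, v in null_pairs:
        wi = similarity_fn(u, v)
        if wi == -1:
            excl_n += 1
        else:
            null.append(wi)

    return CoherenceBenchmark(
        wi_connected=np.asarray(connected, dtype=float),
        wi_null=np.asarray(null, dtype=float),
        null_mode=mode_tag,
        n_excluded_connected=excl_c,
        n_excluded_null=excl_n,
    )


def empirical_fdr_threshold(benchmark: CoherenceBenchmark,
                            alpha: float = 0.10) -> float:
    """Smallest observed similarity whose null exceedance is below alpha.

    FDR(t) = #{null >= t} / #null.  Candidate thresholds are the distinct
    observed similarities (connected and null pooled); the returned
    threshold is the smallest candidate with FDR(t) < alpha, and the
    invariant FDR(threshold) < alpha is asserted on every call.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    null = np.sort(np.asarray(benchmark.wi_null, dtype=float))
    if null.size == 0:
        raise ValueError("empty null distribution")
    candidates = np.unique(np.concatenate([benchmark.wi_connected, null]))
    # exceedance count via right-open search on the sorted null
    exceed = null.size - np.searchsorted(null, candidates, side="left")
    fdr = exceed / null.size
    ok = np.nonzero(fdr < alpha)[0]
    if ok.size == 0:
        raise ValueError(
            f"no observed similarity reaches empirical FDR < {alpha}; "
            "consider a larger alpha")
    threshold = float(candidates[ok[0]])
    achieved = float(np.mean(null >= threshold))
    assert achieved < alpha, "empirical FDR guarantee violated"
    benchmark.fdr_alpha = alpha
    benchmark.wi_threshold = threshold
    return threshold


def compare_distributions(benchmark: CoherenceBenchmark) -> float:
    """Two-sided Mann-Whitney U p-value, connected vs null similarities.

    Uses the exact distribution at small n and the tie-corrected normal
    approximation otherwise (scipy's ``method="auto"``).
    """
    if benchmark.wi_connected.size == 0 or benchmark.wi_null.size == 0:
        raise ValueError("both distributions must be nonempty")
    res = stats.mannwhitneyu(benchmark.wi_connected, benchmark.wi_null,
                             alternative="two-sided", method="auto")
    benchmark.mwu_p = float(res.pvalue)
    return benchmark.mwu_p


@dataclass
class PRCurve:
    """Precision-recall points over a ranked interactor list.

    ``points`` has one row per rank k with the pair, its ranking score,
    precision and recall after including the top k pairs, and an
    ``is_cutoff`` marker at the enrichment-cutoff operating point.
    """

    points: pd.DataFrame
    n_true_total: int
    cutoff_rank: int | None = None
    no_true_warning: bool = False

    def operating_point(self) -> tuple[float, float] | None:
        if self.cutoff_rank is None or self.cutoff_rank == 0:
            return None
        row = self.points.iloc[self.cutoff_rank - 1]
        return float(row["precision"]), float(row["recall"])

    def area(self) -> float:
        """Average precision: sum of precision * recall increments."""
        rec = self.points["recall"].to_numpy()
        prec = self.points["precision"].to_numpy()
        prev = np.concatenate([[0.0], rec[:-1]])
        return float(np.sum(prec * (rec - prev)))


def precision_recall_curve(ranked_pairs, truth_fn, *,
                           cutoff_rank: int | None = None) -> PRCurve:
    """Build a PR curve over score-ranked bait-prey pairs.

    ``ranked_pairs`` is an iterable of ``(pair_id, score)``; pairs are
    ordered by score descending with ties broken by pair ID, then taken
    in one pair at a time.  ``truth_fn(pair_id)`` says whether the pair
    is functionally coherent (pairs with sentinel similarity -1 must
    return False).  precision_k = #true in top k / k; recall_k = #true
    in top k / #true in the whole list.  With no true pair in the list,
    recall is reported as 0 with a warning flag.
    """
    ordered = sorted(ranked_pairs, key=lambda ps: (-ps[1], str(ps[0])))
    truths = np.array([bool(truth_fn(p)) for p, _ in ordered])
    n_true_total = int(truths.sum())
    k = np.arange(1, len(ordered) + 1)
    cum_true = np.cumsum(truths)
    precision = cum_true / k
    recall = (cum_true / n_true_total if n_true_total
              else np.zeros_like(precision))
    points = pd.DataFrame({
        "k": k,
        "pair": [p for p, _ in ordered],
        "score": [s for _, s in ordered],
        "is_true": truths,
        "precision": precision,
        "recall": recall,
    })
    points["is_cutoff"] = False
    if cutoff_rank is not None and 0 < cutoff_rank <= len(points):
        points.loc[cutoff_rank - 1, "is_cutoff"] = True
    return PRCurve(points=points, n_true_total=n_true_total,
                   cutoff_rank=cutoff_rank,
                   no_true_warning=(n_true_total == 0 and len(ordered) > 0))
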