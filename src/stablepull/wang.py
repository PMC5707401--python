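"""Wang graph-based semantic similarity over an ontology DAG.

Wang's measure scores two ontology terms by how much of their weighted
ancestor structure they share.  For an anchor term A, every ancestor t
receives a *semantic contribution* S_A(t): S_A(A) = 1, and walking each
child->parent edge multiplies the contribution by the relation weight
(0.8 for ``is_a``, 0.6 for ``part_of`` by convention), keeping the best
path per ancestor:

    S_A(t) = max over edges (c -> t, rel), c in A's closure, of
             w_rel * S_A(c)

The semantic value SV(A) is the sum of S_A over A's closure, and

    sim(A, B) = sum_{t in common closure} (S_A(t) + S_B(t))
                / (SV(A) + SV(B))        in [0, 1].

Gene-level similarity aggregates a term-set-by-term-set similarity
matrix; the default combiner is the best-match average (BMA).  A gene
with no term in the chosen namespace cannot be scored: its similarity is
reported as the sentinel -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import obonet

__all__ = [
    "DEFAULT_WEIGHTS",
    "Ontology",
    "SimilarityScore",
    "gene_similarity",
    "parse_obo",
    "read_annotations",
    "s_values",
    "term_similarity",
    "write_annotations",
]

DEFAULT_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


class OntologyError(ValueError):
    pass


@dataclass
class Ontology:
    """A term DAG with typed child->parent edges and namespaces.

    ``parents[t]`` lists ``(parent, relation)`` pairs; relations are
    ``is_a`` or ``part_of``.  ``alt_ids`` maps merged/secondary IDs to
    their primary term.  S-value maps are memoized per (term, weights).
    """

    parents: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    namespace: dict[str, str] = field(default_factory=dict)
    name: dict[str, str] = field(default_factory=dict)
    alt_ids: dict[str, str] = field(default_factory=dict)
    _svalue_cache: dict = field(default_factory=dict, repr=False)
    _pairsim_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- construction -------------------------------------------------
    @classmethod
    def from_edges(cls, edges: list[tuple[str, str, str]],
                   namespace: dict[str, str] | None = None,
                   names: dict[str, str] | None = None) -> "Ontology":
        """Build from ``(child, parent, relation)`` triples."""
        parents: dict[str, list[tuple[str, str]]] = {}
        terms = set()
        for child, parent, rel in edges:
            terms.update((child, parent))
            parents.setdefault(child, []).append((parent, rel))
        for t in terms:
            parents.setdefault(t, [])
        ns = dict(namespace or {})
        for t in terms:
            ns.setdefault(t, "biological_process")
        return cls(parents=parents, namespace=ns, name=dict(names or {}))

    def validate(self) -> None:
        for child, plist in self.parents.items():
            for parent, rel in plist:
                if parent not in self.parents:
                    raise OntologyError(
                        f"dangling parent: {child} -> {parent} ({rel}) "
                        "references an undeclared term")
        g = nx.DiGraph((c, p) for c, pl in self.parents.items()
                       for p, _ in pl)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        raise OntologyError(f"ontology contains a cycle: {cycle}")

    # -- queries ------------------------------------------------------
    def __contains__(self, term: str) -> bool:
        return term in self.parents or term in self.alt_ids

    @property
    def terms(self) -> list[str]:
        return sorted(self.parents)

    def resolve(self, term: str) -> str:
        """Map an alt_id alias to its primary term (identity otherwise)."""
        if term in self.parents:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        raise KeyError(f"unknown term {term!r}")

    def roots(self) -> list[str]:
        return sorted(t for t, pl in self.parents.items() if not pl)

    def ancestor_closure(self, term: str) -> set[str]:
        """The term itself plus all its ancestors."""
        term = self.resolve(term)
        closure = {term}
        stack = [term]
        while stack:
            for parent, _ in self.parents[stack.pop()]:
                if parent not in closure:
                    closure.add(parent)
                    stack.append(parent)
        return closure

    def s_values(self, term: str,
                 weights: dict[str, float] | None = None) -> dict[str, float]:
        """Semantic contributions S_term(t) for every t in the closure."""
        w = weights or DEFAULT_WEIGHTS
        for rel, val in w.items():
            if not (0 < val < 1):
                raise ValueError(
                    f"semantic weight for {rel!r} must lie in (0, 1), "
                    f"got {val}")
        term = self.resolve(term)
        key = (term, tuple(sorted(w.items())))
        cached = self._svalue_cache.get(key)
        if cached is not None:
            return cached

        closure = self.ancestor_closure(term)
        # edges point child -> parent, so a topological order of the
        # induced subgraph visits descendants before their ancestors
        sub = nx.DiGraph()
        sub.add_nodes_from(closure)
        for c in closure:
            for p, rel in self.parents[c]:
                if p in closure:
                    sub.add_edge(c, p, rel=rel)
        s = {term: 1.0}
        for node in nx.topological_sort(sub):
            if node not in s:  # unreachable upward of term: impossible, guard
                continue
            for _, parent, data in sub.out_edges(node, data=True):
                cand = w[data["rel"]] * s[node]
                if cand > s.get(parent, 0.0):
                    s[parent] = cand
        self._svalue_cache[key] = s
        return s


def parse_obo(path) -> Ontology:
    """Read an OBO 1.2 file into an :class:`Ontology`.

    Obsolete terms are dropped; ``alt_id`` aliases resolve to their
    primary term.  Cycles and edges to undeclared terms raise
    :class:`OntologyError`.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    declared = {n for n, d in graph.nodes(data=True) if d}
    parents: dict[str, list[tuple[str, str]]] = {t: [] for t in declared}
    namespace: dict[str, str] = {}
    names: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        if not data:
            continue
        namespace[node] = data.get("namespace", "biological_process")
        names[node] = data.get("name", node)
        for alias in data.get("alt_id", []):
            alt_ids[alias] = node
    # obonet edges run child -> parent, keyed by relation
    for child, parent, rel in graph.edges(keys=True):
        if rel not in ("is_a", "part_of"):
            continue
        if child not in declared or parent not in declared:
            raise OntologyError(
                f"edge {child} -[{rel}]-> {parent} references an "
                "undeclared term")
        parents[child].append((parent, rel))
    ont = Ontology(parents=parents, namespace=namespace, name=names,
                   alt_ids=alt_ids)
    return ont


def s_values(term: str, ontology: Ontology,
             weights: dict[str, float] | None = None) -> dict[str, float]:
    """Functional wrapper around :meth:`Ontology.s_values`."""
    return ontology.s_values(term, weights)


def term_similarity(a: str, b: str, ontology: Ontology,
                    weights: dict[str, float] | None = None, *,
                    cross_namespace: str = "error") -> float:
    """Wang similarity of two terms in [0, 1].

    Symmetric; 1 iff the terms coincide; 0 when the ancestor closures are
    disjoint.  Terms in different namespaces raise by default
    (``cross_namespace="zero"`` returns 0 instead).
    """
    a = ontology.resolve(a)
    b = ontology.resolve(b)
    if ontology.namespace.get(a) != ontology.namespace.get(b):
        if cross_namespace == "zero":
            return 0.0
        raise ValueError(
            f"terms {a} and {b} live in different namespaces "
            f"({ontology.namespace.get(a)} vs {ontology.namespace.get(b)})")
    wkey = tuple(sorted((weights or DEFAULT_WEIGHTS).items()))
    key = (min(a, b), max(a, b), wkey)
    cached = ontology._pairsim_cache.get(key)
    if cached is not None:
        return cached
    sa = ontology.s_values(a, weights)
    sb = ontology.s_values(b, weights)
    common = sa.keys() & sb.keys()
    if not common:
        sim = 0.0
    else:
        sim = (sum(sa[t] + sb[t] for t in common)
               / (sum(sa.values()) + sum(sb.values())))
    ontology._pairsim_cache[key] = sim
    return sim


@dataclass(frozen=True)
class SimilarityScore:
    """Gene-level similarity; ``wi == -1`` marks an unscorable pair."""

    wi: float
    combiner: str
    n_terms_a: int
    n_terms_b: int


def gene_similarity(terms_a, terms_b, ontology: Ontology, *,
                    combiner: str = "bma",
                    weights: dict[str, float] | None = None,
                    namespace: str | None = None) -> SimilarityScore:
    """Aggregate term-level Wang similarities into a gene-level score.

    Term sets are optionally restricted to one namespace; unknown terms
    are ignored.  An empty set on either side yields the sentinel -1.
    Combiners: ``bma`` (best-match average, default), ``max``, ``mean``.
    """
    def clean(terms):
        out = []
        for t in terms:
            if t not in ontology:
                continue
            r = ontology.resolve(t)
            if namespace is None or ontology.namespace.get(r) == namespace:
                out.append(r)
        return sorted(set(out))

    ta, tb = clean(terms_a), clean(terms_b)
    if not ta or not tb:
        return SimilarityScore(wi=-1.0, combiner=combiner,
                               n_terms_a=len(ta), n_terms_b=len(tb))
    sims = [[term_similarity(x, y, ontology, weights, cross_namespace="zero")
             for y in tb] for x in ta]
    if combiner == "bma":
        row_max = sum(max(row) for row in sims)
        col_max = sum(max(sims[i][j] for i in range(len(ta)))
                      for j in range(len(tb)))
        wi = (row_max + col_max) / (len(ta) + len(tb))
    elif combiner == "max":
        wi = max(max(row) for row in sims)
    elif combiner == "mean":
        wi = sum(sum(row) for row in sims) / (len(ta) * len(tb))
    else:
        raise ValueError(f"unknown combiner {combiner!r}")
    return SimilarityScore(wi=float(wi), combiner=combiner,
                           n_terms_a=len(ta), n_terms_b=len(tb))


def read_annotations(path) -> dict[str, set[str]]:
    """Read a two-column ``gene<TAB>term`` annotation file."""
    annotations: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            annotations.setdefault(gene, set()).add(term)
    return annotations


def write_annotations(annotations: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")
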