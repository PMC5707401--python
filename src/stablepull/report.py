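"""Functional categorization of called interactors and reference overlap.

Interactors are grouped into curated categories (e.g. "RNA" for
posttranscriptional processes, "Ubiquitin" for the ubiquitin system) by
matching their annotated terms — or any ancestor of them — against
curated term lists, with a fixed precedence resolving multi-category
hits; everything else falls into "Other".  Called interactor sets can
also be intersected with a static list of previously reported partners
(e.g. a HIPPIE export) through a user-supplied identifier mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

from .wang import Ontology

__all__ = [
    "CategoryScheme",
    "OverlapReport",
    "categorize",
    "load_category_scheme",
    "overlap_with_reference",
]

OTHER = "Other"


@dataclass
class CategoryScheme:
    """Named curated term sets plus a precedence order.

    ``precedence`` resolves genes hitting several categories; "Other" is
    always the implicit complement and never listed.
    """

    categories: dict[str, set[str]]
    precedence: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.categories or all(not v for v in self.categories.values()):
            raise ValueError("empty category scheme")
        if not self.precedence:
            self.precedence = list(self.categories)
        unknown = set(self.precedence) - set(self.categories)
        if unknown:
            raise ValueError(f"precedence names unknown categories: {unknown}")


def load_category_scheme(path) -> CategoryScheme:
    """Load a scheme from YAML: ``categories: {name: [terms]}`` plus an
    optional ``precedence: [names]`` list."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cats = {name: set(terms) for name, terms in raw["categories"].items()}
    return CategoryScheme(categories=cats,
                          precedence=list(raw.get("precedence", [])))


def default_category_scheme() -> CategoryScheme:
    """The bundled RNA/Ubiquitin stand-in scheme (user-replaceable)."""
    from importlib.resources import files

    path = files("stablepull.data").joinpath("default_categories.yaml")
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    cats = {name: set(terms) for name, terms in raw["categories"].items()}
    return CategoryScheme(categories=cats,
                          precedence=list(raw.get("precedence", [])))


def categorize(genes, annotations: dict[str, set[str]], ontology: Ontology,
               scheme: CategoryScheme) -> tuple[pd.Series, pd.Series]:
    """Assign one category per gene and tally the assignments.

    A gene matches a category when any of its terms, or any ancestor of
    them, is in the category's term set; the first matching category in
    precedence order wins.  Unannotated or unmatched genes are "Other".
    Returns ``(per-gene category, per-category tally)``; the tally sums
    to the number of genes.
    """
    result = {}
    for gene in genes:
        closure: set[str] = set()
        for term in annotations.get(gene, ()):
            if term in ontology:
                closure |= ontology.ancestor_closure(term)
        label = OTHER
        for cat in scheme.precedence:
            if closure & scheme.categories[cat]:
                label = cat
                break
        result[gene] = label
    per_gene = pd.Series(result, name="category")
    order = scheme.precedence + [OTHER]
    tally = per_gene.value_counts().reindex(order, fill_value=0)
    tally.name = "n_interactors"
    return per_gene, tally


@dataclass(frozen=True)
class OverlapReport:
    """Intersection of a called interactor set with a reference list."""

    reference_name: str
    n_overlap: int
    n_total: int
    overlap_ids: tuple[str, ...]

    @property
    def fraction(self) -> float:
        return self.n_overlap / self.n_total if self.n_total else 0.0

    def as_dict(self) -> dict:
        return {"reference": self.reference_name,
                "n_overlap": self.n_overlap, "n_total": self.n_total,
                "fraction": self.fraction,
                "overlap_ids": list(self.overlap_ids)}


def overlap_with_reference(called_ids, reference_ids, *,
                           reference_name: str = "reference",
                           id_map: dict[str, str] | None = None,
                           ) -> OverlapReport:
    """Exact set intersection after optional identifier harmonization.

    ``id_map`` translates called identifiers into the reference's
    identifier space (static mapping, no live lookups).
    """
    called = list(dict.fromkeys(called_ids))  # order-preserving unique
    if id_map:
        mapped = [id_map.get(c, c) for c in called]
    else:
        mapped = called
    ref = set(reference_ids)
    hits = tuple(m for m in mapped if m in ref)
    return OverlapReport(reference_name=reference_name, n_overlap=len(hits),
                         n_total=len(called), overlap_ids=hits)
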