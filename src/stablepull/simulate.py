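"""Seeded synthetic pulldowns, ontologies, annotations and networks.

The generator emulates the statistical structure a stable-interactor
pulldown produces when differentially labeled cells are mixed before
lysis: background binders and lysate-formed (transient) associations
show equalized label occurrence, i.e. log2 heavy/light ratios around 0,
while planted stable interactors sit at a positive mean log2 shift.
Each replicate redraws ratios independently, rows drop out at random
(partial detection), and a configurable fraction of rows carries the
decoy/contaminant flags.  The triple-label ("conventional") protocol
additionally emits an RNase-effect channel in which RNA-dependent
interactors shift negative, and plants its transient binders at the
stable effect size — post-lysis mixing cannot discriminate them, which
is exactly the contrast the benchmarking stage measures.

A toy ontology with a designated functional subtree, annotations that
place the bait and the stable interactors in that subtree, and a
reference network whose edges preferentially connect functionally
similar genes complete a fully self-contained test bed: every planted
quantity is recorded in a ground-truth table.

All randomness flows from one ``numpy`` generator per call; identical
configuration and seed give byte-identical written artifacts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .quant import QuantTable, write_protein_groups
from .wang import Ontology, gene_similarity, write_annotations
from .benchmark import ReferenceNetwork, write_edge_list

__all__ = [
    "OntologySpec",
    "SimulationConfig",
    "generate_ontology",
    "generate_pulldown",
    "generate_reference_network",
    "simulate_to_dir",
    "write_obo",
]

BAIT_GENE = "BAIT"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic pulldown experiment."""

    seed: int = 0
    n_background: int = 500
    n_true: int = 20
    n_transient: int = 30
    n_replicates: int = 3
    effect_log2: float = 2.0       # mean log2 shift of stable interactors
    background_sd: float = 0.5     # sd of background log2 ratios
    detect_prob: float = 0.9       # per-replicate detection probability
    contaminant_frac: float = 0.05
    protocol: str = "adapted"      # "adapted" | "conventional"
    rnase_dependent_frac: float = 0.3
    rnase_effect_log2: float = -1.5  # mean RNase-channel shift when dependent

    def __post_init__(self) -> None:
        for name in ("n_background", "n_true", "n_transient", "n_replicates"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("detect_prob", "contaminant_frac",
                     "rnase_dependent_frac"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.background_sd <= 0:
            raise ValueError("background_sd must be > 0")
        if self.protocol not in ("adapted", "conventional"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.n_background + self.n_true + self.n_transient == 0:
            raise ValueError("empty experiment: no protein groups requested")


@dataclass(frozen=True)
class OntologySpec:
    """Shape of the toy ontology and of the gene annotations."""

    n_roots: int = 1
    depth: int = 4          # levels below each root
    branching: int = 3      # children per term
    part_of_frac: float = 0.2
    terms_per_gene: float = 3.0
    unannotated_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.depth < 1 or self.branching < 1 or self.n_roots < 1:
            raise ValueError("n_roots, depth and branching must be >= 1")
        for name in ("part_of_frac", "unannotated_frac"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.terms_per_gene <= 0:
            raise ValueError("terms_per_gene must be > 0")

    @property
    def n_terms(self) -> int:
        per_root = sum(self.branching ** d for d in range(self.depth + 1))
        return self.n_roots * per_root


def _class_table(config: SimulationConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    n_real = config.n_background + config.n_true + config.n_transient
    n_contam = int(round(config.contaminant_frac * n_real))
    classes = (["stable"] * config.n_true
               + ["transient"] * config.n_transient
               + ["background"] * config.n_background
               + ["contaminant"] * n_contam)
    n = len(classes)
    truth = pd.DataFrame({
        "protein_id": [f"P{i + 1:05d}" for i in range(n)],
        "gene_name": [f"G{i + 1:05d}" for i in range(n)],
        "klass": classes,
    })
    truth["rna_dependent"] = False
    n_dep = int(round(config.rnase_dependent_frac * config.n_true))
    if n_dep:
        dep = rng.choice(config.n_true, size=n_dep, replace=False)
        truth.loc[np.sort(dep), "rna_dependent"] = True
    return truth


def generate_pulldown(config: SimulationConfig,
                      ) -> tuple[list[QuantTable], pd.DataFrame]:
    """Simulate one experiment: per-replicate tables plus ground truth.

    Ratios are redrawn independently per replicate: background and
    contaminant rows (and transient rows under the adapted protocol)
    from Normal(0, background_sd) in log2, stable rows (and transient
    rows under the conventional protocol) from
    Normal(effect_log2, background_sd).  Intensities are log-normal,
    peptide evidence is Poisson-like with at least one peptide, and each
    row is missing from a replicate with probability 1 - detect_prob.
    Contaminant rows carry one of the MaxQuant-style "+" flags.
    """
    rng = np.random.default_rng(config.seed)
    truth = _class_table(config, rng)
    n = len(truth)
    klass = truth["klass"].to_numpy()
    is_stable = klass == "stable"
    is_transient = klass == "transient"
    is_contam = klass == "contaminant"
    elevated = is_stable.copy()
    if config.protocol == "conventional":
        elevated |= is_transient

    flag_choice = rng.integers(0, 3, size=n)  # which "+" flag a contaminant gets
    rna_dep = truth["rna_dependent"].to_numpy()

    tables = []
    for r in range(config.n_replicates):
        mu = np.where(elevated, config.effect_log2, 0.0)
        log2_ratio = rng.normal(mu, config.background_sd)
        lam = np.where(is_stable | is_contam, 6.0, 4.0)
        peptides = 1 + rng.poisson(lam)
        unique = rng.binomial(peptides, 0.85)
        ratio_count = rng.poisson(1.0 + 0.8 * peptides)
        log_mean = np.where(is_stable | is_contam, 17.0, 16.0)
        intensity = rng.lognormal(mean=log_mean, sigma=1.5)
        detected = rng.random(n) < config.detect_prob

        df = pd.DataFrame({
            "protein_group_id": truth["protein_id"],
            "gene_name": truth["gene_name"],
            "ratio_hl": np.exp2(log2_ratio),
            "ratio_count": ratio_count,
            "peptides": peptides,
            "unique_peptides": unique,
            "intensity": intensity,
            "only_by_site": is_contam & (flag_choice == 0),
            "reverse": is_contam & (flag_choice == 1),
            "contaminant": is_contam & (flag_choice == 2),
            "ratio_rnase": np.nan,
        })
        if config.protocol == "conventional":
            mu_rnase = np.where(is_stable & rna_dep,
                                config.rnase_effect_log2, 0.0)
            df["ratio_rnase"] = np.exp2(
                rng.normal(mu_rnase, config.background_sd))
        df = df[detected].reset_index(drop=True)
        tables.append(QuantTable(replicate_id=f"rep{r + 1}",
                                 protocol=config.protocol, data=df))
    return tables, truth


def _tree_terms(spec: OntologySpec) -> tuple[list[tuple[str, str]], list[str]]:
    """Term IDs plus (child, parent) pairs of the b-ary forest."""
    edges = []
    term_ids = []
    counter = itertools.count(1)

    def new_term() -> str:
        return f"T:{next(counter):07d}"

    for _ in range(spec.n_roots):
        root = new_term()
        term_ids.append(root)
        level = [root]
        for _ in range(spec.depth):
            nxt = []
            for parent in level:
                for _ in range(spec.branching):
                    child = new_term()
                    term_ids.append(child)
                    edges.append((child, parent))
                    nxt.append(child)
            level = nxt
    return edges, term_ids


def generate_ontology(spec: OntologySpec, truth: pd.DataFrame | None = None,
                      seed: int = 0, bait: str = BAIT_GENE,
                      ) -> tuple[Ontology, dict[str, set[str]]]:
    """Build a toy DAG ontology and gene annotations with planted coherence.

    Terms form ``n_roots`` complete ``branching``-ary trees of the given
    depth; each child->parent edge is typed ``part_of`` with probability
    ``part_of_frac`` and ``is_a`` otherwise.  The first child of the
    first root anchors the *functional module*: a shallow pool made of
    the anchor term and its direct children.  The bait and every
    stable-class gene draw their terms from this pool — emulating
    complex members annotated to the same specific process — while all
    other genes draw uniformly from the non-root terms, and
    ``unannotated_frac`` of the non-stable genes receive no annotation
    at all (their similarity is later the sentinel -1).
    """
    rng = np.random.default_rng(seed)
    tree_edges, term_ids = _tree_terms(spec)
    rels = np.where(rng.random(len(tree_edges)) < spec.part_of_frac,
                    "part_of", "is_a")
    typed = [(c, p, rel) for (c, p), rel in zip(tree_edges, rels)]
    names = {t: f"synthetic term {i + 1}"
             for i, t in enumerate(term_ids)}
    ontology = Ontology.from_edges(typed, names=names) if typed else Ontology(
        parents={t: [] for t in term_ids},
        namespace={t: "biological_process" for t in term_ids}, name=names)

    roots = ontology.roots()
    non_root = [t for t in term_ids if t not in roots]
    # functional module: first child of the first root plus its children
    first_children = sorted(c for c, pl in ontology.parents.items()
                            if any(p == roots[0] for p, _ in pl))
    if first_children:
        anchor = first_children[0]
        subtree = sorted({anchor} | {
            c for c, pl in ontology.parents.items()
            if any(p == anchor for p, _ in pl)})
    else:  # depth-0 degenerate forest
        subtree = list(term_ids)

    annotations: dict[str, set[str]] = {}

    def draw_terms(pool) -> set[str]:
        k = max(1, int(rng.poisson(spec.terms_per_gene)))
        k = min(k, len(pool))
        idx = rng.choice(len(pool), size=k, replace=False)
        return {pool[i] for i in np.sort(idx)}

    annotations[bait] = draw_terms(subtree)
    if truth is not None:
        genes = truth["gene_name"].tolist()
        stable = set(truth.loc[truth["klass"] == "stable", "gene_name"])
        other_pool = non_root if non_root else list(term_ids)
        for gene in genes:
            if gene in stable:
                annotations[gene] = draw_terms(subtree)
            elif rng.random() < spec.unannotated_frac:
                continue
            else:
                annotations[gene] = draw_terms(other_pool)
    return ontology, annotations


def generate_reference_network(genes, annotations: dict[str, set[str]],
                               n_edges: int, seed: int,
                               ontology: Ontology, *,
                               coherence_weight: float = 10.0,
                               ) -> ReferenceNetwork:
    """Sample a network whose edges favor functionally similar gene pairs.

    Every unordered pair gets weight ``0.02 + coherence_weight * wi**2``
    (wi clipped at 0), and ``n_edges`` distinct pairs are drawn without
    replacement with probability proportional to weight, so connected
    pairs stochastically dominate disconnected ones in similarity.
    """
    genes = sorted(set(genes))
    pairs = list(itertools.combinations(genes, 2))
    if n_edges > len(pairs):
        raise ValueError(
            f"n_edges={n_edges} exceeds the {len(pairs)} possible pairs")
    rng = np.random.default_rng(seed)
    weights = np.empty(len(pairs))
    for i, (u, v) in enumerate(pairs):
        wi = gene_similarity(annotations.get(u, ()), annotations.get(v, ()),
                             ontology).wi
        weights[i] = 0.02 + coherence_weight * max(wi, 0.0) ** 2
    chosen = rng.choice(len(pairs), size=n_edges, replace=False,
                        p=weights / weights.sum())
    edge_pairs = [pairs[i] for i in np.sort(chosen)]
    return ReferenceNetwork.from_edges(genes, edge_pairs)


def write_obo(ontology: Ontology, path) -> None:
    """Serialize to OBO 1.2 with a deterministic stanza order."""
    lines = ["format-version: 1.2", "ontology: synthetic", ""]
    for term in ontology.terms:
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {ontology.name.get(term, term)}")
        lines.append(f"namespace: {ontology.namespace.get(term, 'biological_process')}")
        for parent, rel in sorted(ontology.parents[term]):
            if rel == "is_a":
                lines.append(f"is_a: {parent} ! {ontology.name.get(parent, parent)}")
            else:
                lines.append(f"relationship: {rel} {parent} "
                             f"! {ontology.name.get(parent, parent)}")
        lines.append("")
    lines += ["[Typedef]", "id: part_of", "name: part of", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def simulate_to_dir(config: SimulationConfig, outdir,
                    ontology_spec: OntologySpec | None = None,
                    n_network_edges: int | None = None) -> dict:
    """Write a complete synthetic study to ``outdir``; returns a manifest.

    Artifacts: one proteinGroups-dialect TSV per replicate, a
    ground-truth TSV, an OBO ontology, a gene-term annotation TSV, an
    edge-list TSV for the reference network, and a YAML manifest listing
    them together with the configuration.
    """
    import os

    spec = ontology_spec or OntologySpec()
    os.makedirs(outdir, exist_ok=True)
    tables, truth = generate_pulldown(config)
    ontology, annotations = generate_ontology(spec, truth, seed=config.seed)
    genes = [BAIT_GENE] + truth["gene_name"].tolist()
    if n_network_edges is None:
        n_network_edges = min(4 * len(genes), len(genes) * (len(genes) - 1) // 2)
    network = generate_reference_network(genes, annotations, n_network_edges,
                                         config.seed, ontology)

    paths = {}
    for t in tables:
        p = os.path.join(outdir, f"proteinGroups_{t.replicate_id}.tsv")
        write_protein_groups(t, p)
        paths[t.replicate_id] = p
    truth_path = os.path.join(outdir, "ground_truth.tsv")
    truth.to_csv(truth_path, sep="\t", index=False)
    obo_path = os.path.join(outdir, "ontology.obo")
    write_obo(ontology, obo_path)
    ann_path = os.path.join(outdir, "annotations.tsv")
    write_annotations(annotations, ann_path)
    net_path = os.path.join(outdir, "network.tsv")
    write_edge_list(network, net_path)

    manifest = {
        "config": asdict(config),
        "ontology_spec": asdict(spec),
        "bait": BAIT_GENE,
        "replicates": sorted(paths.values()),
        "ground_truth": truth_path,
        "ontology": obo_path,
        "annotations": ann_path,
        "network": net_path,
        "n_network_edges": int(n_network_edges),
    }
    with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
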