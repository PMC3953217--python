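"""Self-contained synthetic fixtures for the whole pipeline.

Generators for: toy controlled vocabularies (written as OBO), MITAB 2.5
interaction files with a planted detection-method -> interaction-type
signal, gold-standard pair lists, pathway groupings with
subcategory-structured type compositions, annotation corpora for semantic
similarity, and typed networks with planted motifs.  Every generator is
deterministic per seed and writes the same formats the real pipeline reads,
alongside a truth table for evaluation.

The planted signal model: each interaction draws a latent type (or none);
each detection method is present independently with probability
sigma(logit(baseline) + signal[method, type]).  Conditional independence of
methods given the type matches the structure logistic regression can
recover, which makes AUC expectations analyzable.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ontology import Ontology, Term, load_obo
from .pipeline import RunConfig

__all__ = [
    "GeneratorConfig",
    "PlantedNetworkConfig",
    "METHOD_ROOT",
    "METHOD_EXPERIMENTAL",
    "ENZYMATIC_STUDY",
    "TYPE_ROOT",
    "PHYSICAL_ASSOCIATION",
    "DIRECT_INTERACTION",
    "ENZYMATIC_REACTION",
    "COVALENT_BINDING",
    "SPECIFIC_TYPE_ROOTS",
    "DEFAULT_METHODS",
    "DEFAULT_TYPES",
    "DEFAULT_ASSAY_MAP",
    "method_ontology_obo",
    "type_ontology_obo",
    "to_obo",
    "generate_ontology",
    "default_signal",
    "generate_interactions",
    "generate_typed_network",
    "generate_gold_standard",
    "generate_pathways",
    "generate_annotations",
    "make_fixtures",
]

# --------------------------------------------------------------------------
# Built-in toy psi-mi-like vocabularies.  Accessions follow the MI:NNNN
# shape so the fixtures round-trip through the MITAB reader.

METHOD_ROOT = "MI:0001"            # interaction detection method
METHOD_EXPERIMENTAL = "MI:0045"    # experimental interaction detection
BIOCHEMICAL = "MI:0401"
ENZYMATIC_STUDY = "MI:0415"
PHOSPHATASE_ASSAY = "MI:0841"
PROTEASE_ASSAY = "MI:0435"

TYPE_ROOT = "MI:0190"              # interaction type
ASSOCIATION = "MI:0914"
PHYSICAL_ASSOCIATION = "MI:0915"
DIRECT_INTERACTION = "MI:0407"
ENZYMATIC_REACTION = "MI:0414"
COVALENT_BINDING = "MI:0195"
PHOSPHORYLATION = "MI:0217"
DEPHOSPHORYLATION = "MI:0203"
CLEAVAGE = "MI:0194"
UBIQUITINATION = "MI:0204"

SPECIFIC_TYPE_ROOTS = (ENZYMATIC_REACTION, COVALENT_BINDING)

DEFAULT_METHODS = tuple(f"MI:{500 + i:04d}" for i in range(1, 13))
DEFAULT_TYPES = (PHOSPHORYLATION, CLEAVAGE, UBIQUITINATION)
DEFAULT_ASSAY_MAP = {
    PHOSPHATASE_ASSAY: DEPHOSPHORYLATION,
    PROTEASE_ASSAY: CLEAVAGE,
}

_METHOD_TERMS = [
    Term(METHOD_ROOT, "interaction detection method"),
    Term(METHOD_EXPERIMENTAL, "experimental interaction detection",
         frozenset({METHOD_ROOT})),
    Term(BIOCHEMICAL, "biochemical", frozenset({METHOD_EXPERIMENTAL})),
    Term(ENZYMATIC_STUDY, "enzymatic study", frozenset({BIOCHEMICAL})),
    Term(PHOSPHATASE_ASSAY, "phosphatase assay", frozenset({ENZYMATIC_STUDY})),
    Term(PROTEASE_ASSAY, "protease assay", frozenset({ENZYMATIC_STUDY})),
] + [
    Term(m, f"detection method {i + 1}", frozenset({METHOD_EXPERIMENTAL}))
    for i, m in enumerate(DEFAULT_METHODS)
]

_TYPE_TERMS = [
    Term(TYPE_ROOT, "interaction type"),
    Term(ASSOCIATION, "association", frozenset({TYPE_ROOT})),
    Term(PHYSICAL_ASSOCIATION, "physical association", frozenset({ASSOCIATION})),
    Term(DIRECT_INTERACTION, "direct interaction",
         frozenset({PHYSICAL_ASSOCIATION})),
    Term(ENZYMATIC_REACTION, "enzymatic reaction",
         frozenset({DIRECT_INTERACTION})),
    Term(COVALENT_BINDING, "covalent binding", frozenset({DIRECT_INTERACTION})),
    Term(PHOSPHORYLATION, "phosphorylation reaction",
         frozenset({ENZYMATIC_REACTION})),
    Term(DEPHOSPHORYLATION, "dephosphorylation reaction",
         frozenset({ENZYMATIC_REACTION})),
    Term(CLEAVAGE, "cleavage reaction", frozenset({ENZYMATIC_REACTION})),
    Term(UBIQUITINATION, "ubiquitination reaction",
         frozenset({ENZYMATIC_REACTION})),
]


def to_obo(terms: Sequence[Term], ontology_name: str = "synthetic") -> str:
    """Serialize terms as a minimal OBO 1.2 document (sorted, stable)."""
    lines = [f"format-version: 1.2", f"ontology: {ontology_name}", ""]
    for t in sorted(terms, key=lambda t: t.term_id):
        lines.append("[Term]")
        lines.append(f"id: {t.term_id}")
        lines.append(f"name: {t.name}")
        for p in sorted(t.parents):
            lines.append(f"is_a: {p}")
        lines.append("")
    return "\n".join(lines)


def method_ontology_obo() -> str:
    """OBO text of the toy detection-method vocabulary."""
    return to_obo(_METHOD_TERMS, "synthetic-detection-methods")


def type_ontology_obo() -> str:
    """OBO text of the toy interaction-type vocabulary."""
    return to_obo(_TYPE_TERMS, "synthetic-interaction-types")


def generate_ontology(
    n_levels: int,
    branching: int,
    seed: int,
    extra_edges: int = 0,
    prefix: str = "SYN",
) -> tuple[Ontology, str]:
    """Random rooted tree vocabulary, optionally with extra is_a edges (DAG).

    Levels count the root: ``n_levels=2, branching=3`` gives 4 terms.
    Extra edges connect a term to a second parent at a strictly shallower
    level, so the graph stays acyclic.  Deterministic per seed.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    rng = np.random.default_rng(seed)
    levels: list[list[str]] = [[f"{prefix}:0000"]]
    terms = {f"{prefix}:0000": set()}
    counter = 1
    for level in range(1, n_levels):
        current = []
        for parent in levels[level - 1]:
            for _ in range(branching):
                tid = f"{prefix}:{counter:04d}"
                counter += 1
                terms[tid] = {parent}
                current.append(tid)
        levels.append(current)
    non_root = [t for lvl in levels[1:] for t in lvl]
    depth = {t: lv for lv, lvl in enumerate(levels) for t in lvl}
    for _ in range(extra_edges):
        child = non_root[int(rng.integers(len(non_root)))]
        shallower = [t for t in terms if depth[t] < depth[child]
                     and t not in terms[child]]
        if shallower:
            terms[child].add(shallower[int(rng.integers(len(shallower)))])
    term_objs = [
        Term(tid, f"synthetic term {tid}", frozenset(ps))
        for tid, ps in terms.items()
    ]
    obo = to_obo(term_objs, "synthetic-random")
    return load_obo(io.StringIO(obo)), obo


# --------------------------------------------------------------------------
# MITAB generator with planted method -> type signal.


@dataclass
class GeneratorConfig:
    """Study conditions for the planted-signal MITAB generator.

    Defaults are the standard fixture: 5,000 interactions over 1,500
    proteins, 12 candidate detection methods, 3 specific interaction types
    each driven by 3 dedicated methods at log-odds 3.0, baseline method
    probability 0.3, 30% of interactions carrying a latent specific type of
    which 25% are labeled in the MITAB type column (the rest stay at the
    high-level 'physical association', mimicking the sparse labeling of
    real compendia).
    """

    n_interactions: int = 5000
    n_proteins: int = 1500
    methods: tuple[str, ...] = DEFAULT_METHODS
    types: tuple[str, ...] = DEFAULT_TYPES
    signal: Mapping[tuple[str, str], float] | None = None
    planted_log_odds: float = 3.0
    baseline_method_prob: float = 0.3
    fraction_typed: float = 0.3
    labeled_fraction: float = 0.25
    duplicate_fraction: float = 0.1
    assay_fraction: float = 0.05
    seed: int = 0

    def resolved_signal(self) -> dict[tuple[str, str], float]:
        if self.signal is not None:
            return dict(self.signal)
        return default_signal(self.methods, self.types, self.planted_log_odds)


def default_signal(
    methods: Sequence[str],
    types: Sequence[str],
    log_odds: float,
    methods_per_type: int = 3,
) -> dict[tuple[str, str], float]:
    """Block-diagonal signal: type j is driven by its own block of methods."""
    sig: dict[tuple[str, str], float] = {}
    for j, t in enumerate(types):
        block = methods[j * methods_per_type:(j + 1) * methods_per_type]
        for m in block:
            sig[(m, t)] = log_odds
    return sig


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


_NAMES = {t.term_id: t.name for t in _METHOD_TERMS + _TYPE_TERMS}


def _cv_field(term_ids: Iterable[str]) -> str:
    ids = sorted(term_ids)
    if not ids:
        return "-"
    return "|".join(
        f'psi-mi:"{t}"({_NAMES.get(t, "synthetic term")})' for t in ids
    )


def generate_interactions(
    config: GeneratorConfig,
) -> tuple[str, pd.DataFrame]:
    """MITAB 2.5 text plus a truth table of latent types.

    Each unique protein pair draws a latent type (or none); methods appear
    with probability sigma(logit(baseline) + signal[m, type]).  A
    ``labeled_fraction`` of typed pairs carry their type in MITAB column
    12; all others are labeled 'physical association' only.  A
    ``duplicate_fraction`` of pairs emit a second redundant record with a
    subset of the annotations, exercising deduplication.

    Returns ``(mitab_text, truth)`` with truth columns pair_a, pair_b,
    true_type ('' for untyped), labeled, n_methods.
    """
    rng = np.random.default_rng(config.seed)
    signal = config.resolved_signal()
    base_logit = math.log(
        config.baseline_method_prob / (1 - config.baseline_method_prob)
    )
    pairs: set[tuple[str, str]] = set()
    while len(pairs) < config.n_interactions:
        i, j = rng.integers(0, config.n_proteins, size=2)
        if i == j:
            continue
        a, b = f"P{min(i, j):05d}", f"P{max(i, j):05d}"
        pairs.add((a, b))
    ordered = sorted(pairs)
    rng.shuffle(ordered)
    lines: list[str] = []
    truth_rows = []
    for a, b in ordered:
        typed = rng.random() < config.fraction_typed
        true_type = (
            config.types[int(rng.integers(len(config.types)))] if typed else ""
        )
        methods = {
            m
            for m in config.methods
            if rng.random()
            < _sigmoid(base_logit + signal.get((m, true_type), 0.0))
        }
        labeled = typed and rng.random() < config.labeled_fraction
        type_field = {true_type} if labeled else {PHYSICAL_ASSOCIATION}
        if (
            config.assay_fraction
            and true_type == CLEAVAGE
            and rng.random() < config.assay_fraction
        ):
            methods.add(PROTEASE_ASSAY)
        lines.append(_mitab_line(a, b, methods, type_field))
        if rng.random() < config.duplicate_fraction and methods:
            sub = set(
                rng.choice(sorted(methods),
                           size=max(1, len(methods) // 2), replace=False)
            )
            lines.append(_mitab_line(b, a, sub, {PHYSICAL_ASSOCIATION}))
        truth_rows.append(
            {
                "pair_a": a,
                "pair_b": b,
                "true_type": true_type,
                "labeled": labeled,
                "n_methods": len(methods),
            }
        )
    truth = pd.DataFrame(truth_rows).sort_values(
        ["pair_a", "pair_b"], kind="stable"
    ).reset_index(drop=True)
    return "\n".join(lines) + "\n", truth


def _mitab_line(
    a: str, b: str, methods: Iterable[str], types: Iterable[str]
) -> str:
    cols = ["-"] * 15
    cols[0] = f"uniprotkb:{a}"
    cols[1] = f"uniprotkb:{b}"
    cols[6] = _cv_field(methods)
    cols[8] = "synthetic"
    cols[11] = _cv_field(types)
    return "\t".join(cols)


# --------------------------------------------------------------------------
# Typed networks with planted motifs.


@dataclass
class PlantedNetworkConfig:
    """Erdos-Renyi typed background plus one single-type clique."""

    n_nodes: int = 60
    background_edge_prob: float = 0.04
    clique_size: int = 6
    clique_type: str = DEFAULT_TYPES[0]
    background_types: tuple[str, ...] = DEFAULT_TYPES
    seed: int = 0

    def __post_init__(self):
        if self.clique_size > self.n_nodes:
            raise ValueError("clique_size must not exceed n_nodes")


def generate_typed_network(
    config: PlantedNetworkConfig,
) -> list[tuple[str, str, str]]:
    """Typed edge list (protein_a, protein_b, type_id), one row per edge-type.

    Background edges get a uniformly random type; the first ``clique_size``
    nodes are fully interconnected with ``clique_type`` edges (planted
    motif truth: all C(clique_size, 3) triangles of that single type).
    """
    rng = np.random.default_rng(config.seed)
    nodes = [f"N{i:04d}" for i in range(config.n_nodes)]
    edges: dict[tuple[str, str], str] = {}
    for i in range(config.n_nodes):
        for j in range(i + 1, config.n_nodes):
            if rng.random() < config.background_edge_prob:
                t = config.background_types[
                    int(rng.integers(len(config.background_types)))
                ]
                edges[(nodes[i], nodes[j])] = t
    for i in range(config.clique_size):
        for j in range(i + 1, config.clique_size):
            edges[(nodes[i], nodes[j])] = config.clique_type
    return [(a, b, t) for (a, b), t in sorted(edges.items())]


# --------------------------------------------------------------------------
# Validation fixtures: gold standards, pathways, annotation corpora.


def generate_gold_standard(
    truth: pd.DataFrame,
    type_id: str,
    recall: float = 0.8,
    precision: float = 0.9,
    rng: np.random.Generator | int | None = None,
) -> list[tuple[str, str]]:
    """Noisy gold-standard pair list for one type.

    True-type pairs enter with probability ``recall``; false pairs from the
    rest of the truth table are added so that the expected true fraction of
    the list is ``precision``.
    """
    rng = np.random.default_rng(rng)
    pos = truth[truth["true_type"] == type_id]
    neg = truth[truth["true_type"] != type_id]
    keep = pos[rng.random(len(pos)) < recall]
    n_false = int(round(len(keep) * (1 - precision) / max(precision, 1e-9)))
    n_false = min(n_false, len(neg))
    false_rows = neg.iloc[
        rng.choice(len(neg), size=n_false, replace=False)
    ] if n_false else neg.iloc[:0]
    out = [(r.pair_a, r.pair_b) for r in keep.itertuples()]
    out += [(r.pair_a, r.pair_b) for r in false_rows.itertuples()]
    return sorted(out)


def generate_pathways(
    typed_pairs: Mapping[str, Sequence[tuple[str, str]]],
    n_subcategories: int = 4,
    pathways_per_subcategory: int = 6,
    pairs_per_pathway: int = 30,
    structured: bool = True,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Pathway membership table with subcategory-level type compositions.

    Each subcategory draws a Dirichlet rate vector over the types; every
    pathway in it samples member pairs with types at those rates, so
    profiles correlate within subcategories.  With ``structured=False`` all
    pathways share one uniform rate vector (null for the correlation test).
    """
    rng = np.random.default_rng(rng)
    types = sorted(typed_pairs)
    rows = []
    for s in range(n_subcategories):
        if structured:
            rates = rng.dirichlet(np.full(len(types), 0.4))
        else:
            rates = np.full(len(types), 1.0 / len(types))
        for p in range(pathways_per_subcategory):
            pid = f"path{s:02d}_{p:02d}"
            sub = f"subcat{s:02d}"
            chosen_types = rng.choice(
                len(types), size=pairs_per_pathway, p=rates
            )
            for t_idx in chosen_types:
                pool = typed_pairs[types[t_idx]]
                a, b = pool[int(rng.integers(len(pool)))]
                rows.append(
                    {
                        "pathway_id": pid,
                        "subcategory": sub,
                        "protein_a": a,
                        "protein_b": b,
                        "native_type": types[t_idx],
                    }
                )
    return pd.DataFrame(rows)


def generate_annotations(
    proteins_by_type: Mapping[str, Iterable[str]],
    background_proteins: Iterable[str],
    terms_per_protein: int = 2,
    depth: int = 4,
    branching: int = 3,
    structured: bool = True,
    seed: int = 0,
) -> tuple[Ontology, dict[str, set[str]]]:
    """Annotation corpus where same-type proteins share deep terms.

    Builds a random GO-like tree with one branch reserved per type; proteins
    of a type draw their terms from that branch's leaves (``structured``),
    or uniformly from all leaves (null).  Background proteins always draw
    uniformly.
    """
    rng = np.random.default_rng(seed)
    types = sorted(proteins_by_type)
    onto, _ = generate_ontology(
        n_levels=depth, branching=max(branching, len(types)), seed=seed,
        prefix="GO"
    )
    leaves = sorted(t for t in onto.terms if not onto.descendants(t))
    root = next(iter(onto.roots))
    branch_of: dict[str, list[str]] = {}
    top_terms = sorted(t for t in onto.terms
                       if onto.terms[t].parents == frozenset({root}))
    for j, t in enumerate(types):
        sub = onto.subtree(top_terms[j % len(top_terms)])
        branch_of[t] = sorted(set(leaves) & sub)
    annotations: dict[str, set[str]] = {}
    for t in types:
        pool = branch_of[t] if structured else leaves
        for p in sorted(set(proteins_by_type[t])):
            annotations[p] = set(
                rng.choice(pool, size=min(terms_per_protein, len(pool)),
                           replace=False)
            )
    for p in sorted(set(background_proteins)):
        if p not in annotations:
            annotations[p] = set(
                rng.choice(leaves, size=min(terms_per_protein, len(leaves)),
                           replace=False)
            )
    return onto, annotations


# --------------------------------------------------------------------------
# One-stop fixture writer.


def make_fixtures(
    out_dir: str | Path,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> dict:
    """Write the complete fixture set plus a run config and manifest.

    Produces, under ``out_dir``: the toy method/type vocabularies (OBO),
    a planted-signal MITAB file with its truth table, the assay-to-type
    mapping, per-type gold standards, a subcategory-structured pathway
    file, an annotation corpus with its GO-like ontology, a planted typed
    network, a ready-to-run ``config.yaml`` and a ``fixtures.json``
    manifest of seeds and parameters.  Deterministic per seed.
    """
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = GeneratorConfig(seed=seed)
    seqs = np.random.SeedSequence(seed).spawn(4)

    (out / "methods.obo").write_text(method_ontology_obo())
    (out / "types.obo").write_text(type_ontology_obo())

    mitab, truth = generate_interactions(config)
    (out / "interactions.mitab").write_text(mitab)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)

    with open(out / "assay_map.tsv", "w") as fh:
        fh.write("# assay detection method\timplied interaction type\n")
        for assay, itype in sorted(DEFAULT_ASSAY_MAP.items()):
            fh.write(f"{assay}\t{itype}\n")

    gold_paths = {}
    rng_gold = np.random.default_rng(seqs[0])
    for t in config.types:
        pairs = generate_gold_standard(truth, t, rng=rng_gold)
        name = f"gold_{t.replace(':', '_')}.tsv"
        with open(out / name, "w") as fh:
            fh.write(f"# synthetic gold standard for {t}\n")
            for a, b in pairs:
                fh.write(f"{a}\t{b}\n")
        gold_paths[t] = name

    typed_pairs = {
        t: [(r.pair_a, r.pair_b)
            for r in truth[truth["true_type"] == t].itertuples()]
        for t in config.types
    }
    pathways = generate_pathways(typed_pairs, rng=np.random.default_rng(seqs[1]))
    with open(out / "pathways.tsv", "w") as fh:
        fh.write("# pathway_id\tsubcategory\tprotein_a\tprotein_b\tnative_type\n")
        for r in pathways.itertuples(index=False):
            fh.write(f"{r.pathway_id}\t{r.subcategory}\t{r.protein_a}\t"
                     f"{r.protein_b}\t{r.native_type}\n")

    proteins_by_type = {
        t: {p for pair in pairs for p in pair}
        for t, pairs in typed_pairs.items()
    }
    all_proteins = {p for r in truth.itertuples()
                    for p in (r.pair_a, r.pair_b)}
    ann_seed = int(np.random.default_rng(seqs[2]).integers(0, 2**31 - 1))
    ann_onto, annotations = generate_annotations(
        proteins_by_type, all_proteins, seed=ann_seed
    )
    (out / "annotation_ontology.obo").write_text(
        to_obo([ann_onto.terms[t] for t in sorted(ann_onto.terms)],
               "synthetic-annotation-ontology")
    )
    with open(out / "annotations.tsv", "w") as fh:
        fh.write("# entity_id\tterm_id\n")
        for entity in sorted(annotations):
            for term in sorted(annotations[entity]):
                fh.write(f"{entity}\t{term}\n")

    net_seed = int(np.random.default_rng(seqs[3]).integers(0, 2**31 - 1))
    edges = generate_typed_network(PlantedNetworkConfig(seed=net_seed))
    with open(out / "planted_network.tsv", "w") as fh:
        fh.write("# protein_a\tprotein_b\ttype_id\n")
        for a, b, t in edges:
            fh.write(f"{a}\t{b}\t{t}\n")

    run_config = RunConfig(
        ontology_methods="methods.obo",
        ontology_types="types.obo",
        mitab="interactions.mitab",
        assay_map="assay_map.tsv",
        gold_standards=gold_paths,
        pathways="pathways.tsv",
        annotations="annotations.tsv",
        annotation_ontology="annotation_ontology.obo",
        exclusion_root=ENZYMATIC_STUDY,
        specific_roots=list(SPECIFIC_TYPE_ROOTS),
        excluded_types=[ENZYMATIC_REACTION],
        seed=seed,
    )
    (out / "config.yaml").write_text(
        yaml.safe_dump(run_config.to_dict(), sort_keys=True)
    )

    manifest = {
        "seed": seed,
        "generator": {
            k: (dict(v) if isinstance(v, Mapping) else
                list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses_asdict(config).items()
        },
        "files": sorted(p.name for p in out.iterdir()
                        if p.name != "fixtures.json"),
    }
    (out / "fixtures.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return manifest


def dataclasses_asdict(config: GeneratorConfig) -> dict:
    import dataclasses

    d = dataclasses.asdict(config)
    if d.get("signal") is not None:
        d["signal"] = {f"{m}|{t}": v for (m, t), v in d["signal"].items()}
    return d
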