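"""End-to-end orchestration: ingest -> features -> enrich -> train ->
predict -> validate -> motifs.

Every stage is a pure function of (inputs, config, seed); per-stage random
substreams are derived deterministically from the single run seed, so two
runs with the same seed produce byte-identical artifacts and manifests.
Stages can be run individually (each reloads its prerequisites from the
run directory) or chained in memory with :func:`run`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from . import interactions as ia
from . import model as mdl
from . import motifs as mot
from . import ontology as onto
from . import validation as val

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineRunner", "run", "STAGES"]

STAGES = ("ingest", "features", "enrich", "train", "predict", "validate",
          "motifs")


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run.

    Parameter defaults follow the published protocol: rare-method cutoff
    200, minimum 20 positives per type, 10-fold cross-validation with 20
    repeats, 500 motif randomizations, 10 random groups for the semantic
    comparison, >=4 direct detection methods for the random-negative pool,
    negative sets of at least 100 interactions.
    """

    # inputs
    ontology_methods: str = ""
    ontology_types: str = ""
    mitab: str = ""
    assay_map: str | None = None
    gold_standards: dict[str, str] = field(default_factory=dict)
    pathways: str | None = None
    annotations: str | None = None
    annotation_ontology: str | None = None
    # vocabulary anchors
    exclusion_root: str | None = None
    specific_roots: list[str] = field(default_factory=list)
    excluded_types: list[str] = field(default_factory=list)
    # parameters
    min_count: int = 200
    min_positives: int = 20
    min_negatives: int = 100
    min_direct_methods: int = 4
    k: int = 10
    repeats: int = 20
    n_random_motifs: int = 500
    n_random_semantic: int = 10
    motif_swaps_per_edge: int = 10
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def resolve_paths(self, base: str | Path) -> "RunConfig":
        """Return a copy with relative input paths resolved against ``base``."""
        base = Path(base)

        def fix(p):
            return str(base / p) if p and not Path(p).is_absolute() else p

        d = self.to_dict()
        for key in ("ontology_methods", "ontology_types", "mitab", "assay_map",
                    "pathways", "annotations", "annotation_ontology"):
            d[key] = fix(d[key])
        d["gold_standards"] = {t: fix(p)
                               for t, p in d["gold_standards"].items()}
        return RunConfig.from_dict(d)


def _read_assay_map(path: str) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            assay, itype = line.split("\t")[:2]
            out[assay] = itype
    return out


class PipelineRunner:
    """Executes pipeline stages against a run directory.

    Intermediate results computed in this session are kept in memory;
    prerequisites of an individually invoked stage are reloaded from the
    artifacts a previous invocation wrote.
    """

    def __init__(self, config: RunConfig, out_dir: str | Path):
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        seqs = np.random.SeedSequence(config.seed).spawn(3)
        self._rng_train = np.random.default_rng(seqs[0])
        self._rng_semantic = np.random.default_rng(seqs[1])
        self._rng_motifs = np.random.default_rng(seqs[2])
        self._cache: dict[str, object] = {}

    # ---- lazily loaded state --------------------------------------------

    @property
    def ontology_methods(self) -> onto.Ontology:
        if "om" not in self._cache:
            self._cache["om"] = onto.load_obo(self.config.ontology_methods)
        return self._cache["om"]

    @property
    def ontology_types(self) -> onto.Ontology:
        if "ot" not in self._cache:
            self._cache["ot"] = onto.load_obo(self.config.ontology_types)
        return self._cache["ot"]

    @property
    def interactions(self) -> list[ia.UniqueInteraction]:
        if "inter" not in self._cache:
            path = self.out / "interactions.tsv"
            if not path.exists():
                raise FileNotFoundError(
                    "interactions.tsv missing — run the ingest stage first"
                )
            with open(path) as fh:
                self._cache["inter"] = ia.read_interaction_table(fh)
        return self._cache["inter"]

    @property
    def matrix(self) -> pd.DataFrame:
        if "matrix" not in self._cache:
            path = self.out / "feature_matrix.tsv"
            if not path.exists():
                raise FileNotFoundError(
                    "feature_matrix.tsv missing — run the features stage first"
                )
            self._cache["matrix"] = pd.read_csv(path, sep="\t",
                                                index_col="pair_id")
        return self._cache["matrix"]

    @property
    def predictors(self) -> dict[str, mdl.TypeLogisticModel]:
        if "predictors" not in self._cache:
            models_dir = self.out / "models"
            if not models_dir.is_dir():
                raise FileNotFoundError(
                    "models/ missing — run the train stage first"
                )
            predictors = {}
            for p in sorted(models_dir.glob("*.tsv")):
                m = _read_model(p, list(self.matrix.columns))
                predictors[m.type_id] = m
            self._cache["predictors"] = predictors
        return self._cache["predictors"]

    @property
    def typed_edges(self) -> dict[tuple[str, str], set[str]]:
        if "typed_edges" not in self._cache:
            path = self.out / "typed_edges.tsv"
            if not path.exists():
                raise FileNotFoundError(
                    "typed_edges.tsv missing — run the predict stage first"
                )
            edges: dict[tuple[str, str], set[str]] = {}
            with open(path) as fh:
                fh.readline()
                for line in fh:
                    a, b, t = line.rstrip("\n").split("\t")
                    edges.setdefault((a, b), set()).add(t)
            self._cache["typed_edges"] = edges
        return self._cache["typed_edges"]

    @property
    def pair_of(self) -> dict[str, tuple[str, str]]:
        return {ui.pair_id: ui.pair for ui in self.interactions}

    # ---- stages ----------------------------------------------------------

    def ingest(self) -> None:
        records = ia.read_mitab(self.config.mitab)
        inter = ia.deduplicate(records)
        inter = ia.propagate(self.ontology_methods, self.ontology_types, inter)
        if self.config.assay_map:
            inter = ia.map_assay_types(
                inter, _read_assay_map(self.config.assay_map),
                self.ontology_methods, self.ontology_types,
            )
        with open(self.out / "interactions.tsv", "w") as fh:
            ia.write_interaction_table(inter, fh)
        self._cache["inter"] = inter

    def features(self) -> None:
        matrix = feat.build_feature_matrix(
            self.interactions,
            exclusion_root=self.config.exclusion_root,
            min_count=self.config.min_count,
            ontology_methods=self.ontology_methods,
        )
        matrix.to_csv(self.out / "feature_matrix.tsv", sep="\t",
                      index_label="pair_id")
        self._cache["matrix"] = matrix

    def enrich(self) -> None:
        enr = feat.method_type_enrichment(self.interactions, self.matrix)
        feat.enrichment_table(enr).to_csv(
            self.out / "enrichment.tsv", sep="\t", index=False,
            float_format="%.6g",
        )

    def train(self) -> None:
        cfg = self.config
        types = mdl.eligible_types(
            self.interactions, self.ontology_types, cfg.specific_roots,
            min_positives=cfg.min_positives, excluded=cfg.excluded_types,
        )
        specific: set[str] = set()
        for root in cfg.specific_roots:
            specific |= self.ontology_types.subtree(root)
        predictors: dict[str, mdl.TypeLogisticModel] = {}
        cv_rows = []
        models_dir = self.out / "models"
        models_dir.mkdir(exist_ok=True)
        for t in types:
            model, cv = mdl.train_predictor(
                self.interactions, t, self.matrix, specific,
                k=cfg.k, repeats=cfg.repeats, rng=self._rng_train,
                min_negatives=cfg.min_negatives,
                min_direct_methods=cfg.min_direct_methods,
            )
            predictors[t] = model
            cv_rows.append(
                {"type_id": t, "mean_auc": cv.mean_auc,
                 "sd_auc": float(np.std(cv.aucs, ddof=1)),
                 "n_repeats": len(cv.aucs), "cutoff": model.cutoff_,
                 "stabilized": model.stabilized_}
            )
            _write_model(model, models_dir / f"{t.replace(':', '_')}.tsv")
        pd.DataFrame(cv_rows).to_csv(self.out / "cv_report.tsv", sep="\t",
                                     index=False, float_format="%.6g")
        self._cache["predictors"] = predictors

    def predict(self) -> None:
        scores, calls = mdl.predict_all(self.predictors, self.matrix)
        pair_of = self.pair_of
        score_arr = scores.to_numpy()
        call_arr = calls.to_numpy()
        rows = []
        for i, pid in enumerate(scores.index):
            a, b = pair_of[pid]
            for j, t in enumerate(scores.columns):
                rows.append((a, b, t, score_arr[i, j], bool(call_arr[i, j])))
        pd.DataFrame(
            rows, columns=["pair_a", "pair_b", "type_id", "score", "call"]
        ).to_csv(self.out / "predictions.tsv", sep="\t", index=False,
                 float_format="%.6g")
        typed_edges: dict[tuple[str, str], set[str]] = {}
        for i, pid in enumerate(calls.index):
            called = {t for j, t in enumerate(calls.columns) if call_arr[i, j]}
            if called:
                typed_edges[pair_of[pid]] = called
        with open(self.out / "typed_edges.tsv", "w") as fh:
            fh.write("protein_a\tprotein_b\ttype_id\n")
            for (a, b), ts in sorted(typed_edges.items()):
                for t in sorted(ts):
                    fh.write(f"{a}\t{b}\t{t}\n")
        self._cache["typed_edges"] = typed_edges
        self._cache["scores"] = scores
        self._cache["calls"] = calls

    def validate(self) -> None:
        cfg = self.config
        pair_of = self.pair_of
        universe = [pair_of[pid] for pid in self.matrix.index]
        scores = self._cache.get("scores")
        if scores is None:
            scores = self._scores_from_disk()
        typed_edges = self.typed_edges
        for type_id, path in sorted(cfg.gold_standards.items()):
            if not Path(path).exists():
                logger.warning("gold standard file %s missing, skipped", path)
                continue
            with open(path) as fh:
                gold = val.read_gold_standard(fh, type_id, provenance=path)
            already = [ui.pair for ui in self.interactions
                       if type_id in ui.types_closed]
            pred_pairs = [p for p, ts in typed_edges.items() if type_id in ts]
            score_map = (
                {pair_of[pid]: scores.at[pid, type_id]
                 for pid in scores.index}
                if type_id in scores.columns else None
            )
            try:
                res = val.gold_overlap(pred_pairs, gold, universe,
                                       already_typed=already,
                                       scores=score_map)
            except ValueError as exc:
                logger.warning("gold standard %s skipped: %s", type_id, exc)
                continue
            pd.DataFrame([dataclasses.asdict(res)]).assign(
                type_id=type_id
            ).to_csv(
                self.out / f"gold_overlap_{type_id.replace(':', '_')}.tsv",
                sep="\t", index=False, float_format="%.6g",
            )
        if cfg.annotations and cfg.annotation_ontology and not (
            Path(cfg.annotations).exists()
            and Path(cfg.annotation_ontology).exists()
        ):
            logger.warning("annotation inputs missing, semantic validation "
                           "skipped")
        elif cfg.annotations and cfg.annotation_ontology:
            ann_onto = onto.load_obo(cfg.annotation_ontology)
            with open(cfg.annotations) as fh:
                ann = val.read_annotations(fh)
            ic = onto.information_content(ann_onto, ann)
            typed_by_type: dict[str, list] = {}
            for pair, ts in typed_edges.items():
                for t in ts:
                    typed_by_type.setdefault(t, []).append(pair)
            sem = val.semantic_validation(
                typed_by_type, universe, ann, ann_onto, ic,
                n_random=cfg.n_random_semantic, rng=self._rng_semantic,
            )
            pd.DataFrame([dataclasses.asdict(s) for s in sem]).to_csv(
                self.out / "semantic_validation.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
        elif cfg.annotations or cfg.annotation_ontology:
            logger.warning("semantic validation skipped: need both "
                           "annotations and annotation_ontology")
        if cfg.pathways and not Path(cfg.pathways).exists():
            logger.warning("pathway file %s missing, skipped", cfg.pathways)
        elif cfg.pathways:
            with open(cfg.pathways) as fh:
                pathways = val.read_pathways(fh)
            profiles = val.pathway_profiles(pathways, typed_edges)
            try:
                intra, inter_r, p = val.profile_correlation(profiles)
                pd.DataFrame(
                    [{"intra_mean_r": intra, "inter_mean_r": inter_r,
                      "wilcoxon_p": p}]
                ).to_csv(self.out / "pathway_correlation.tsv", sep="\t",
                         index=False, float_format="%.6g")
            except ValueError as exc:
                logger.warning("pathway correlation skipped: %s", exc)

    def motifs(self) -> None:
        network = mot.TypedNetwork.from_edge_types(self.typed_edges)
        sig = mot.motif_significance(
            network, n_random=self.config.n_random_motifs,
            rng=self._rng_motifs,
            swaps_per_edge=self.config.motif_swaps_per_edge,
        )
        with open(self.out / "motifs.tsv", "w") as fh:
            mot.write_motif_table(sig, fh)

    def write_manifest(self) -> None:
        artifacts = {}
        for p in sorted(self.out.rglob("*")):
            if p.is_file() and p.name != "manifest.json":
                artifacts[str(p.relative_to(self.out))] = hashlib.sha256(
                    p.read_bytes()
                ).hexdigest()
        manifest = {
            "config": self.config.to_dict(),
            "seed": self.config.seed,
            "artifacts": artifacts,
            "manifest_hash": hashlib.sha256(
                json.dumps(artifacts, sort_keys=True).encode()
            ).hexdigest(),
        }
        (self.out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )

    def _scores_from_disk(self) -> pd.DataFrame:
        path = self.out / "predictions.tsv"
        if not path.exists():
            raise FileNotFoundError(
                "predictions.tsv missing — run the predict stage first"
            )
        df = pd.read_csv(path, sep="\t")
        pid = df["pair_a"] + "--" + df["pair_b"]
        return df.assign(pair_id=pid).pivot(
            index="pair_id", columns="type_id", values="score"
        )

    def run_stage(self, stage: str) -> None:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        getattr(self, stage)()


def run(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute all pipeline stages in order and write the manifest.

    Any stage failure aborts with the stage name; artifacts written so far
    are retained next to a FAILED marker.
    """
    runner = PipelineRunner(config, out_dir)
    marker = runner.out / "FAILED"
    if marker.exists():
        marker.unlink()
    for stage in STAGES:
        try:
            runner.run_stage(stage)
        except Exception:
            (runner.out / "FAILED").write_text(f"stage: {stage}\n")
            logger.error("pipeline failed at stage %r", stage)
            raise
    runner.write_manifest()
    return runner.out


def _write_model(model: mdl.TypeLogisticModel, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# type_id: {model.type_id}\n")
        fh.write(f"# intercept: {model.intercept_[0]:.10g}\n")
        fh.write(f"# cutoff: {model.cutoff_:.10g}\n")
        fh.write(f"# stabilized: {model.stabilized_}\n")
        fh.write("feature\tweight\n")
        for name, w in sorted(model.weights_.items()):
            fh.write(f"{name}\t{w:.10g}\n")


def _read_model(path: Path, feature_order: list[str]) -> mdl.TypeLogisticModel:
    meta: dict[str, str] = {}
    weights: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# "):
                key, _, value = line[2:].partition(": ")
                meta[key] = value
            elif line and not line.startswith("feature\t"):
                name, w = line.split("\t")
                weights[name] = float(w)
    model = mdl.TypeLogisticModel(type_id=meta["type_id"])
    model.classes_ = np.array([0, 1])
    model.coef_ = np.array([[weights[f] for f in feature_order]])
    model.intercept_ = np.array([float(meta["intercept"])])
    model.n_features_in_ = len(feature_order)
    model.feature_names_in_ = np.asarray(feature_order, dtype=object)
    model.weights_ = {f: weights[f] for f in feature_order}
    model.stabilized_ = meta.get("stabilized") == "True"
    model.cutoff_ = float(meta["cutoff"])
    return model
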