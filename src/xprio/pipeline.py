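"""Pipeline orchestration: simulate -> annotate -> features -> enrich ->
lme -> train -> predict -> validate, with a run manifest.

Each stage reads the previous stages' plain-text outputs from the run
directory and writes its own, so stages can be re-run individually; a
missing upstream output raises a dependency error naming the stage.  The
manifest records per-stage output checksums, parameters and seeds;
reruns with an identical configuration produce identical checksums
(manifests differ only in their timestamp).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as _annotation
from . import lme as _lme
from . import ml as _ml
from . import validation as _validation
from .features import (ConservationTrack, FeatureInputs, FeatureTable,
                       assemble_feature_table)
from .synth import (ADULT_TISSUES, FeatureEffect, SynthConfig,
                    default_feature_effects, generate_universe)

__all__ = ["PipelineConfig", "run", "STAGES"]

STAGES = ("simulate", "annotate", "features", "enrich", "lme",
          "train", "predict", "validate")


class DependencyError(RuntimeError):
    pass


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """One configuration file drives the whole run.

    Exactly one of ``input_dir`` (pre-existing input tables) or ``synth``
    (generate them) must be provided.  Every numeric convention has a key;
    defaults are the package's standard conventions.
    """

    out_dir: str = "xprio_run"
    input_dir: str | None = None
    synth: SynthConfig | None = None
    seed: int = 0
    n_tests_decile: int = 30          # Bonferroni family: 10 deciles x 3 metrics
    min_criteria: int = 1
    d: float = 0.05
    top_k: int = 5
    outer_folds: int = 10
    inner_folds: int = 5
    rule: str = "conjunction"
    registry: str = "default"         # default | light | dummy
    select: bool = True               # run the nested-CV tournament
    importance_repeats: int = 0       # 0 = skip permutation importance
    stages: tuple[str, ...] = STAGES

    def validate(self) -> None:
        if (self.input_dir is None) == (self.synth is None):
            raise PipelineConfigError(
                "exactly one of input_dir / synth must be provided")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineConfigError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synth", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "synth"})
        if synth is not None:
            fx = synth.pop("feature_effects", None)
            sc = SynthConfig(**synth)
            if fx:
                effects = default_feature_effects()
                for name, spec in fx.items():
                    effects[name] = FeatureEffect(
                        family=spec["family"],
                        params={c: tuple(v) for c, v in spec["params"].items()},
                        mult=spec.get("mult", 1.0))
                sc.feature_effects = effects
            cfg.synth = sc
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonable))


def _require(out: Path, stage: str, *names: str) -> None:
    for name in names:
        if not (out / name).exists():
            raise DependencyError(
                f"stage {stage!r}: missing upstream output {name!r}")


def _read_fasta(path: Path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def load_feature_inputs(indir: Path) -> FeatureInputs:
    """Load the feature-engineering inputs from a directory of text files."""
    track_df = pd.read_csv(indir / "conservation.bedGraph", sep="\t",
                           names=["chrom", "start", "end", "score"])
    return FeatureInputs(
        genes=pd.read_csv(indir / "genes.tsv", sep="\t"),
        transcripts=pd.read_csv(indir / "transcripts.bed", sep="\t"),
        constraint=pd.read_csv(indir / "constraint.tsv", sep="\t"),
        promoters=_read_fasta(indir / "promoters.fasta"),
        track=ConservationTrack.from_frame(track_df.assign(chrom=track_df["chrom"].astype(str))),
        expression=pd.read_csv(indir / "expression.tsv", sep="\t", index_col="symbol"),
        samples=pd.read_csv(indir / "samples.tsv", sep="\t", index_col="sample"),
        paralogues=pd.read_csv(indir / "paralogues.tsv", sep="\t"),
        chromosomes=pd.read_csv(indir / "chromosomes.tsv", sep="\t",
                                dtype={"chromosome": str}),
        tissue_groups={"cerebellar": ADULT_TISSUES["cerebellar"],
                       "brain": ADULT_TISSUES["brain"],
                       "nerve": ADULT_TISSUES["nerve"]},
    )


# ---------------------------------------------------------------------------
# stages (each returns {output name: path})

def stage_simulate(cfg: PipelineConfig, out: Path) -> dict[str, Path]:
    indir = out / "inputs"
    if cfg.synth is not None:
        universe = generate_universe(cfg.synth)
        return universe.write(indir)
    # pre-existing inputs: copy-free, reference them in place
    src = Path(cfg.input_dir)
    if not src.exists():
        raise DependencyError(f"stage 'simulate': input_dir {src} does not exist")
    indir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for f in sorted(src.iterdir()):
        if f.is_file():
            (indir / f.name).write_bytes(f.read_bytes())
            paths[f.name] = indir / f.name
    return paths


def stage_annotate(out: Path) -> dict[str, Path]:
    _require(out, "annotate", "inputs/genes.tsv")
    genes = pd.read_csv(out / "inputs/genes.tsv", sep="\t")
    annotated = _annotation.annotate_genes(genes)
    xci_path = out / "inputs/xci_calls.tsv"
    if xci_path.exists():
        xci = pd.read_csv(xci_path, sep="\t")
        consensus = {g: _annotation.consensus_xci(list(grp["call"]))
                     for g, grp in xci.groupby("gene")}
        annotated["xci_consensus"] = [
            consensus.get(s, "not_available") if c == "X" else ""
            for s, c in zip(annotated["symbol"], annotated["chromosome"].astype(str))]
    p = out / "annotated_genes.tsv"
    annotated.to_csv(p, sep="\t", index=False)
    return {"annotated_genes.tsv": p}


def stage_features(out: Path) -> dict[str, Path]:
    _require(out, "features", "inputs/genes.tsv", "inputs/transcripts.bed",
             "inputs/constraint.tsv", "inputs/promoters.fasta",
             "inputs/conservation.bedGraph", "inputs/expression.tsv",
             "inputs/samples.tsv", "inputs/paralogues.tsv",
             "inputs/chromosomes.tsv")
    table = assemble_feature_table(load_feature_inputs(out / "inputs"))
    p = out / "features.tsv"
    table.to_tsv(p)
    return {"features.tsv": p}


def stage_enrich(cfg: PipelineConfig, out: Path) -> dict[str, Path]:
    _require(out, "enrich", "features.tsv", "annotated_genes.tsv")
    table = FeatureTable.from_tsv(out / "features.tsv")
    ann = pd.read_csv(out / "annotated_genes.tsv", sep="\t").set_index("symbol")
    labels = ann["disorder_class"].reindex(table.genes)
    results = {}
    from .stats import decile_enrichment
    for metric in _lme.DEFAULT_METRICS:
        res = decile_enrichment(table.values[metric], labels,
                                n_tests=cfg.n_tests_decile)
        results[metric] = [r.to_dict() for r in res]
    p = out / "decile_enrichment.json"
    _write_json(p, results)
    return {"decile_enrichment.json": p}


def stage_lme(cfg: PipelineConfig, out: Path) -> dict[str, Path]:
    _require(out, "lme", "features.tsv", "annotated_genes.tsv")
    table = FeatureTable.from_tsv(out / "features.tsv")
    ann = pd.read_csv(out / "annotated_genes.tsv", sep="\t").set_index("symbol")
    labels = ann["disorder_class"].reindex(table.genes)
    clf = _lme.DecileLMEClassifier(min_criteria=cfg.min_criteria,
                                   n_tests=cfg.n_tests_decile)
    clf.fit(table.values, labels)
    status = clf.status(table.values)
    p_status = out / "lme_status.tsv"
    status.to_csv(p_status, sep="\t", index_label="symbol")
    p_summary = out / "lme_summary.json"
    _write_json(p_summary, clf.summary(table.values, by=labels))
    return {"lme_status.tsv": p_status, "lme_summary.json": p_summary}


def _make_registry(cfg: PipelineConfig):
    if cfg.registry == "default":
        return _ml.default_registry()
    if cfg.registry == "light":
        return _ml.default_registry(light=True)
    if cfg.registry == "dummy":
        return _ml.dummy_registry()
    raise PipelineConfigError(f"unknown registry {cfg.registry!r}")


def stage_train(cfg: PipelineConfig, out: Path) -> dict[str, Path]:
    _require(out, "train", "features.tsv", "annotated_genes.tsv")
    table = FeatureTable.from_tsv(out / "features.tsv")
    ann = pd.read_csv(out / "annotated_genes.tsv", sep="\t").set_index("symbol")
    sub = ann["subgroup"].reindex(table.genes)
    train_mask = sub.isin(["Cbi", "NDt"])
    X_train = table.values[train_mask]
    y_train = (sub[train_mask] == "Cbi").astype(int)

    model = _ml.DisorderGeneEnsemble(
        registry=_make_registry(cfg), top_k=cfg.top_k,
        outer_folds=cfg.outer_folds, inner_folds=cfg.inner_folds,
        d=cfg.d, rule=cfg.rule, select=cfg.select, random_state=cfg.seed)
    model.fit(X_train, y_train)

    paths = {}
    p = out / "cv_results.json"
    _write_json(p, {
        "results": [r.to_dict() for r in model.cv_results_],
        "ensemble": [name for name, _ in model.estimators_],
        "fdr": dataclasses.asdict(model.fdr_),
        "seed": cfg.seed,
        "folds": {"outer": cfg.outer_folds, "inner": cfg.inner_folds},
    })
    paths["cv_results.json"] = p

    preds = model.prediction_frame(table.values)
    preds["training_gene"] = train_mask
    p = out / "predictions.tsv"
    with open(p, "w") as fh:
        fh.write(f"# rule={cfg.rule}; d={cfg.d}; "
                 "probabilities are calibrated positive-class probabilities\n")
        preds.to_csv(fh, sep="\t", index_label="symbol", float_format="%.10g")
    paths["predictions.tsv"] = p

    if cfg.importance_repeats > 0:
        imp = _ml.permutation_importance(
            model.estimators_, model.scaler_.transform(X_train), y_train,
            n_repeats=cfg.importance_repeats, seed=cfg.seed)
        p = out / "importance.tsv"
        imp.sort_values(ascending=False).to_csv(p, sep="\t",
                                                index_label="feature")
        paths["importance.tsv"] = p
    return paths


def stage_predict(cfg: PipelineConfig, out: Path) -> dict[str, Path]:
    _require(out, "predict", "predictions.tsv", "annotated_genes.tsv")
    preds = pd.read_csv(out / "predictions.tsv", sep="\t", comment="#",
                        index_col="symbol")
    predicted = preds.index[preds["predicted"] & ~preds["training_gene"]]
    p = out / "predicted_genes.tsv"
    pd.Series(sorted(predicted), name="symbol").to_csv(p, sep="\t", index=False)
    return {"predicted_genes.tsv": p}


def stage_validate(out: Path) -> dict[str, Path]:
    _require(out, "validate", "predictions.tsv", "features.tsv",
             "inputs/variants.tsv", "inputs/domains.tsv",
             "inputs/db_membership.tsv", "annotated_genes.tsv")
    preds = pd.read_csv(out / "predictions.tsv", sep="\t", comment="#",
                        index_col="symbol")
    predicted = preds["predicted"].astype(bool)
    variants = pd.read_csv(out / "inputs/variants.tsv", sep="\t")
    domains = pd.read_csv(out / "inputs/domains.tsv", sep="\t")
    dbs = pd.read_csv(out / "inputs/db_membership.tsv", sep="\t")
    ann = pd.read_csv(out / "annotated_genes.tsv", sep="\t").set_index("symbol")

    damaging, filter_report = _validation.damaging_filter(variants)
    counts = damaging.groupby("gene").size().reindex(predicted.index).fillna(0)
    cds = pd.read_csv(out / "features.tsv", sep="\t", comment="#",
                      index_col="symbol")["cds_length"]
    report: dict = {"damaging_filter": {k: v for k, v in filter_report.items()
                                        if k != "per_gene"}}
    if predicted.any() and (~predicted).any():
        report["burden"] = _validation.burden_report(counts, predicted, cds)
        memberships = {row["gene"]: set(str(row["databases"]).split(";"))
                       if isinstance(row["databases"], str) and row["databases"]
                       else set()
                       for _, row in dbs.iterrows()}
        report["overlap"] = _validation.overlap_report(predicted, memberships)
    else:
        report["burden"] = {"skipped": "one prediction group is empty"}
        report["overlap"] = {"skipped": "one prediction group is empty"}
    pred_domains = domains[domains["gene"].isin(predicted.index[predicted])]
    report["domain"] = (_validation.domain_report(damaging, pred_domains)
                        if len(pred_domains) else {"skipped": "no predicted genes"})
    report["n_predicted"] = int(predicted.sum())
    p = out / "validation_report.json"
    _write_json(p, report)
    return {"validation_report.json": p}


# ---------------------------------------------------------------------------

def run(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the run manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
                      "seed": cfg.seed, "stages": []}
    dispatch = {
        "simulate": lambda: stage_simulate(cfg, out),
        "annotate": lambda: stage_annotate(out),
        "features": lambda: stage_features(out),
        "enrich": lambda: stage_enrich(cfg, out),
        "lme": lambda: stage_lme(cfg, out),
        "train": lambda: stage_train(cfg, out),
        "predict": lambda: stage_predict(cfg, out),
        "validate": lambda: stage_validate(out),
    }
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        paths = dispatch[stage]()
        manifest["stages"].append({
            "stage": stage,
            "seed": cfg.seed,
            "outputs": {str(Path(p).relative_to(out)): _sha256(Path(p))
                        for p in paths.values()},
        })
    _write_json(out / "manifest.json", manifest)
    return manifest
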