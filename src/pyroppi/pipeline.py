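"""End-to-end orchestration: score -> group -> survival -> enrichment ->
associate -> TMB -> drug, with validation, per-stage skip logging and a
machine-readable run manifest.

Outputs are plain TSVs plus one JSON manifest recording the package
version, every parameter, seeds, and per-stage row counts; re-running with
an identical config reproduces identical bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import pyroppi
from pyroppi import association, cohort, drugs, enrichment, scoring
from pyroppi.catalog import catalog_from_gmt, load_gmt, packaged_prg_catalog
from pyroppi.cohort import StratumSkipped

FLOAT_FMT = "%.10g"


class ValidationFailure(Exception):
    pass


class StageFailure(Exception):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and parameters of a full pipeline run.

    Optional inputs (mutations, scores, panel, annotation GMT) may be None;
    the corresponding stages are skipped with a logged reason.
    """

    expression: Path
    clinical: Path
    out_dir: Path
    catalog: Path | None = None          # None -> packaged PRG catalog
    mutations: Path | None = None
    scores: Path | None = None
    panel_expression: Path | None = None
    panel_drugs: Path | None = None
    annotation_gmt: Path | None = None   # gene sets for permutation GSEA
    alpha: float = 0.25
    normalize: bool = True
    split_rule: str = "median"
    endpoints: tuple[str, ...] = ("os", "dss", "dfs", "pfs")
    n_perm: int = 1000
    exome_mb: float = association.DEFAULT_EXOME_MB
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("expression", "clinical", "catalog", "mutations",
                     "scores", "panel_expression", "panel_drugs",
                     "annotation_gmt"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        self.out_dir = Path(self.out_dir)
        self.endpoints = tuple(self.endpoints)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_jsonable(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            out[k] = str(v) if isinstance(v, Path) else (
                list(v) if isinstance(v, tuple) else v)
        return out


def validate_inputs(config: RunConfig) -> dict:
    """Cross-table consistency checks; returns {'errors': [...], 'warnings': [...]}."""
    report: dict = {"errors": [], "warnings": []}
    for name in ("expression", "clinical"):
        p = getattr(config, name)
        if not p.exists():
            report["errors"].append(f"{name} file not found: {p}")
    if report["errors"]:
        return report
    try:
        expr = scoring.read_expression_tsv(config.expression)
    except ValueError as exc:
        report["errors"].append(f"expression: {exc}")
        return report
    try:
        ann = cohort.read_clinical_tsv(config.clinical)
    except ValueError as exc:
        report["errors"].append(f"clinical: {exc}")
        return report
    missing_clin = [s for s in expr.columns if s not in ann.index]
    if missing_clin:
        report["warnings"].append(
            f"{len(missing_clin)} scored samples absent from the clinical "
            f"table: {missing_clin[:5]}"
        )
    cat = catalog_from_gmt(config.catalog) if config.catalog else packaged_prg_catalog()
    measured = set(expr.index)
    for direction, gs in (("positive", cat.positive), ("negative", cat.negative)):
        if not gs.members & measured:
            report["errors"].append(
                f"no {direction}-regulator genes measured in the expression matrix"
            )
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    report = validate_inputs(config)
    if report["errors"]:
        raise ValidationFailure("; ".join(report["errors"]))
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "pyroppi",
        "version": pyroppi.__version__,
        "config": config.to_jsonable(),
        "validation_warnings": report["warnings"],
        "stages": {},
        "skips": {},
    }

    expr = scoring.read_expression_tsv(config.expression)
    ann = cohort.read_clinical_tsv(config.clinical)
    cat = catalog_from_gmt(config.catalog) if config.catalog else packaged_prg_catalog()
    params = scoring.EnrichmentParams(alpha=config.alpha, normalize=config.normalize)

    def emit(name: str, frame: pd.DataFrame, index: bool = True) -> None:
        frame.to_csv(out / f"{name}.tsv", sep="\t", float_format=FLOAT_FMT,
                     index=index)
        manifest["stages"][name] = {"rows": int(len(frame))}

    # --- score -------------------------------------------------------------
    try:
        ppi = scoring.compute_ppi(expr, cat, params)
    except Exception as exc:
        raise StageFailure("score", str(exc)) from exc
    emit("ppi", ppi)

    # --- differential tumor/normal ------------------------------------------
    diff_rows, diff_skips = [], {}
    for st in sorted(ann["cancer_type"].unique()):
        for fn, label in ((cohort.diff_ppi_unpaired, "unpaired"),
                          (cohort.diff_ppi_paired, "paired")):
            try:
                res = fn(ppi, ann, st)
                diff_rows.append(res.__dict__)
            except StratumSkipped as exc:
                diff_skips[f"{st}/{label}"] = str(exc)
    emit("differential", pd.DataFrame(diff_rows), index=False)
    manifest["skips"]["differential"] = diff_skips

    # --- groups + survival ---------------------------------------------------
    try:
        groups = cohort.split_groups(ppi, ann, rule=config.split_rule)
    except StratumSkipped as exc:
        raise StageFailure("groups", str(exc)) from exc
    emit("groups", groups)
    manifest["skips"]["groups"] = groups.attrs.get("skipped", {})
    scan, scan_skips = cohort.survival_scan(ppi, ann, endpoints=config.endpoints,
                                            rule=config.split_rule)
    emit("survival", scan, index=False)
    manifest["skips"]["survival"] = scan_skips

    # --- enrichment ----------------------------------------------------------
    if config.annotation_gmt is not None:
        sets = load_gmt(config.annotation_gmt)
        gsea_frames = []
        tumor = ann[ann["tissue"] == "tumor"]
        for st in sorted(groups["cancer_type"].unique()):
            g = groups[groups["cancer_type"] == st]
            try:
                ranked = enrichment.rank_genes(expr, g)
                res = enrichment.gsea_permutation(
                    ranked, sets, n_perm=config.n_perm, seed=config.seed)
            except ValueError as exc:
                manifest["skips"].setdefault("gsea", {})[st] = str(exc)
                continue
            res.insert(0, "stratum", st)
            gsea_frames.append(res)
        if gsea_frames:
            emit("gsea", pd.concat(gsea_frames, ignore_index=True), index=False)
    else:
        manifest["skips"]["gsea"] = "annotation GMT not provided"

    # --- associations --------------------------------------------------------
    if config.scores is not None:
        score_table = pd.read_csv(config.scores, sep="\t", index_col=0)
        assoc, assoc_skips = association.association_scan(
            ppi, score_table, method="spearman", ann=ann)
        emit("associations", assoc, index=False)
        manifest["skips"]["associations"] = assoc_skips
        subtype_rows = []
        if "immune_subtype" in ann.columns:
            try:
                subtype_rows.append(association.subtype_compare(ppi, ann))
            except StratumSkipped as exc:
                manifest["skips"]["subtypes"] = str(exc)
        if subtype_rows:
            flat = pd.json_normalize(subtype_rows, sep=".")
            for col in flat.columns:
                if flat[col].map(lambda v: isinstance(v, (list, dict))).any():
                    flat[col] = flat[col].map(json.dumps)
            emit("subtypes", flat, index=False)
    else:
        manifest["skips"]["associations"] = "score table not provided"

    # --- TMB ------------------------------------------------------------------
    if config.mutations is not None:
        mut = association.read_mutation_tsv(config.mutations)
        tumor_ids = ann.index[ann["tissue"] == "tumor"]
        tmb, qc = association.compute_tmb(mut, tumor_ids, exome_mb=config.exome_mb)
        emit("tmb", tmb.to_frame())
        manifest["stages"]["tmb"]["qc"] = qc
        freq = association.mutation_frequency(
            mut, ann, sorted(cat.all_members & set(expr.index)))
        emit("mutation_frequency", freq, index=False)
    else:
        manifest["skips"]["tmb"] = "mutation table not provided"

    # --- drug -----------------------------------------------------------------
    if config.panel_expression is not None and config.panel_drugs is not None:
        panel_expr = pd.read_csv(config.panel_expression, sep="\t", index_col=0)
        panel_drugs = pd.read_csv(config.panel_drugs, sep="\t", index_col=0)
        train_z, tumor_z, _ = drugs.homogenize(
            panel_expr, expr, min_shared=min(drugs.MIN_SHARED_GENES,
                                             len(panel_expr) // 2))
        comp_frames, pred_frames = [], []
        for drug in panel_drugs.index:
            try:
                model = drugs.fit_ridge_ic50(train_z, panel_drugs.loc[drug],
                                             drug=drug, seed=config.seed)
            except ValueError as exc:
                manifest["skips"].setdefault("drug", {})[drug] = str(exc)
                continue
            preds, comp, comp_skips = drugs.predict_and_compare(model, tumor_z, groups)
            pred_frames.append(preds.rename(drug))
            comp_frames.append(comp)
            if comp_skips:
                manifest["skips"].setdefault("drug", {})[drug] = comp_skips
        if pred_frames:
            emit("drug_predictions", pd.concat(pred_frames, axis=1))
        if comp_frames:
            emit("drug_comparison", pd.concat(comp_frames, ignore_index=True),
                 index=False)
        cellline = drugs.cellline_ppi_drug_correlation(
            panel_expr, panel_drugs, cat, params)
        emit("cellline_drug_correlation", cellline, index=False)
    else:
        manifest["skips"]["drug"] = "cell-line panel not provided"

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
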