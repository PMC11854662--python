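"""End-to-end orchestration: simulate/load -> segment -> extract ->
audit/harmonize -> model -> survival.

Stages communicate only through files in the output directory (full
precision CSV/JSON/NIfTI), so each stage can also be run on its own from
the CLI and a rerun with the same configuration and seed reproduces
every artifact bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import harmonization, modelling, phantom, radiomics, segmentation, survival
from .imaging_io import (
    FeatureTable,
    read_feature_table,
    read_volume,
    write_feature_table,
)

log = logging.getLogger("petww")


@dataclasses.dataclass
class PipelineConfig:
    """Single JSON-serialisable configuration driving every stage."""

    cohort: phantom.CohortSpec = dataclasses.field(default_factory=phantom.CohortSpec)
    phantom: phantom.PhantomSpec = dataclasses.field(default_factory=phantom.PhantomSpec)
    input_dir: str | None = None       # pre-existing volumes + manifest.csv instead of simulation
    min_lesion_voxels: int = 3
    bin_width_suv: float = radiomics.DEFAULT_BIN_WIDTH_SUV
    max_features: int = modelling.MAX_FEATURES
    nested_selection: bool = False
    alpha: float = harmonization.ALPHA

    @classmethod
    def from_json(cls, path_or_text: str | Path) -> "PipelineConfig":
        text = str(path_or_text)
        if not text.lstrip().startswith("{"):
            text = Path(text).read_text()
        raw = json.loads(text)
        kwargs = dict(raw)
        if "cohort" in raw:
            kwargs["cohort"] = phantom.CohortSpec(
                **{**raw["cohort"],
                   **{k: tuple(v) for k, v in raw["cohort"].items() if isinstance(v, list)}}
            )
        if "phantom" in raw:
            kwargs["phantom"] = phantom.PhantomSpec(
                **{**raw["phantom"],
                   **{k: tuple(v) for k, v in raw["phantom"].items() if isinstance(v, list)}}
            )
        return cls(**kwargs)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Generate the synthetic cohort and write volumes + manifest."""
    out = Path(out_dir) / "cohort"
    cohort = phantom.generate_cohort(config.cohort, config.phantom)
    manifest = phantom.write_cohort(cohort, out)
    (Path(out_dir) / "cohort_spec.json").write_text(config.cohort.to_json())
    (Path(out_dir) / "phantom_spec.json").write_text(config.phantom.to_json())
    log.info("simulate: %d subjects -> %s", config.cohort.n_subjects, out)
    return manifest


def _load_manifest(out_dir: Path, config: PipelineConfig) -> tuple[pd.DataFrame, Path]:
    base = Path(config.input_dir) if config.input_dir else out_dir / "cohort"
    manifest = base / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest at {manifest}; run the simulate stage first")
    return pd.read_csv(manifest), base


def stage_segment_extract(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Segment every subject and extract the 81-feature vector."""
    out_dir = Path(out_dir)
    mf, base = _load_manifest(out_dir, config)
    rows, seg_rows = [], []
    for rec in mf.itertuples():
        vol = read_volume(base / rec.volume)
        center = (rec.liver_center_x, rec.liver_center_y, rec.liver_center_z)
        lesions, stats = segmentation.segment_subject(
            vol, center, min_lesion_voxels=config.min_lesion_voxels
        )
        if lesions.n_lesions == 0:
            raise RuntimeError(
                f"segment: subject {rec.subject_id} has no lesion above the "
                f"PERCIST threshold {lesions.threshold:.3f}"
            )
        feats = radiomics.assemble_feature_vector(lesions, vol, config.bin_width_suv)
        rows.append({"subject_id": rec.subject_id, "scanner": rec.scanner, **feats})
        for les in lesions.lesions:
            seg_rows.append(
                {"subject_id": rec.subject_id, "label": les.label,
                 "mtv_cm3": les.mtv_cm3, "suvmax": les.suvmax, "suvmean": les.suvmean,
                 "threshold": lesions.threshold, "liver_mean": stats.mean,
                 "liver_sd": stats.sd}
            )
    table = FeatureTable(pd.DataFrame(rows))
    table.validate_layout(radiomics.FEATURE_COLUMNS)
    path = out_dir / "features_raw.csv"
    write_feature_table(table, path)
    pd.DataFrame(seg_rows).to_csv(out_dir / "lesions.csv", index=False, float_format="%.17g")
    log.info("extract: %d subjects x %d features", table.n_subjects, len(table.feature_columns))
    return path


def extract_cohort_features(
    cohort: "phantom.Cohort",
    min_lesion_voxels: int = 3,
    bin_width_suv: float = radiomics.DEFAULT_BIN_WIDTH_SUV,
    drop_zero_variance: bool = True,
) -> FeatureTable:
    """In-memory segment+extract over a generated cohort (no files)."""
    rows = []
    for vol, sid, scan in zip(cohort.volumes, cohort.subject_ids, cohort.scanner):
        lesions, _ = segmentation.segment_subject(
            vol, cohort.liver_center_mm, min_lesion_voxels=min_lesion_voxels
        )
        if lesions.n_lesions == 0:
            raise RuntimeError(f"subject {sid} has no supra-threshold lesion")
        feats = radiomics.assemble_feature_vector(lesions, vol, bin_width_suv)
        rows.append({"subject_id": sid, "scanner": scan, **feats})
    table = FeatureTable(pd.DataFrame(rows))
    if drop_zero_variance:
        sd = table.features().std(ddof=1)
        keep = [c for c in table.feature_columns if sd[c] > 0]
        table = FeatureTable(table.data[["subject_id", "scanner"] + keep].copy())
    return table


def stage_harmonize(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Scanner audit, ComBat, re-audit, and exclusion of resistant features."""
    out_dir = Path(out_dir)
    table = read_feature_table(out_dir / "features_raw.csv")
    mf, _ = _load_manifest(out_dir, config)

    audit_pre = harmonization.wilcoxon_scanner_test(table, alpha=config.alpha)
    harmonized, _model = harmonization.combat_harmonize(table)
    audit_post = harmonization.wilcoxon_scanner_test(harmonized, alpha=config.alpha)
    kept = harmonization.drop_unharmonized(harmonized, audit_post)

    ttt_p = harmonization.outcome_scanner_test(
        mf["ttt_months"].to_numpy(), table.scanner.to_numpy()
    )
    report = audit_pre.results.rename(columns={"p_raw": "p_raw_pre", "p_adj": "p_adj_pre",
                                               "significant": "significant_pre"})
    report[["p_raw_post", "p_adj_post", "significant_post"]] = audit_post.results[
        ["p_raw", "p_adj", "significant"]
    ]
    report["excluded"] = ~report.index.isin(kept.feature_columns)
    report.to_csv(out_dir / "scanner_audit.csv", float_format="%.17g")
    path = out_dir / "features_harmonized.csv"
    write_feature_table(kept, path)
    summary = {
        "n_significant_pre": audit_pre.n_significant,
        "n_significant_post": audit_post.n_significant,
        "excluded_features": audit_post.significant_features,
        "ttt_scanner_p": ttt_p,
    }
    (out_dir / "harmonization_summary.json").write_text(json.dumps(summary, indent=2))
    log.info(
        "harmonize: significant features %d -> %d; %d excluded",
        audit_pre.n_significant, audit_post.n_significant,
        len(audit_post.significant_features),
    )
    return path


def _modelling_inputs(config: PipelineConfig, out_dir: Path):
    table = read_feature_table(out_dir / "features_harmonized.csv")
    mf, _ = _load_manifest(out_dir, config)
    mf = mf.set_index("subject_id").loc[table.data["subject_id"]]
    # zero-variance columns cannot be z-scored; drop them up front
    feats = table.features()
    sd = feats.std(ddof=1)
    dead = list(sd.index[~(sd > 0)])
    if dead:
        log.info("modelling: dropping %d zero-variance feature(s): %s", len(dead), dead)
        keep = [c for c in table.feature_columns if c not in dead]
        table = FeatureTable(table.data[["subject_id", "scanner"] + keep].copy())
    return table, mf


def stage_model(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Forward-selected LR and SVM models, LOOCV-validated at k=1..max."""
    out_dir = Path(out_dir)
    table, mf = _modelling_inputs(config, out_dir)
    ttt = mf["ttt_months"].to_numpy(dtype=float)
    labels = modelling.median_class_labels(ttt).astype(int)

    reports = {}
    frames = []
    for kind, outcome in (("LR", ttt), ("SVM", labels)):
        rep = modelling.cv_report(
            table, outcome, kind,
            max_k=config.max_features, nested=config.nested_selection,
        )
        reports[kind] = rep
        frames.append(rep.metrics_frame())
        preds = pd.concat(
            [res["predictions"].assign(k=k) for k, res in sorted(rep.per_k.items())],
            ignore_index=True,
        )
        preds.to_csv(out_dir / f"predictions_{kind.lower()}.csv", index=False,
                     float_format="%.17g")
    pd.concat(frames, ignore_index=True).to_csv(
        out_dir / "cv_metrics.csv", index=False, float_format="%.17g"
    )
    payload = {
        kind: {
            "selected": rep.selected,
            "selection_scores": rep.selection_scores,
            "per_k": {
                str(k): {"features": res["features"], "train": res["train"],
                         "test": res["test"]}
                for k, res in sorted(rep.per_k.items())
            },
        }
        for kind, rep in reports.items()
    }
    path = out_dir / "cv_report.json"
    path.write_text(json.dumps(payload, indent=2))
    log.info("model: LR selected %s; SVM selected %s",
             reports["LR"].selected, reports["SVM"].selected)
    return path


def stage_survival(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Median-split KM screen on treated subjects."""
    out_dir = Path(out_dir)
    table, mf = _modelling_inputs(config, out_dir)
    screen = survival.median_split_screen(
        table,
        mf["ttt_months"].to_numpy(dtype=float),
        mf["event"].to_numpy(dtype=bool),
        treated_only=True,
        alpha=config.alpha,
    )
    path = out_dir / "km_screen.csv"
    screen.results.to_csv(path, float_format="%.17g")
    log.info("survival: %d/%d features significant on %d treated subjects",
             len(screen.significant_features), len(screen.results), screen.n_subjects)
    return path


def run_pipeline(config: PipelineConfig | dict | str | Path, out_dir: str | Path) -> dict:
    """Run every stage in order and return a summary report (also written
    as ``report.json``)."""
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_json(config)
    elif isinstance(config, dict):
        config = PipelineConfig.from_json(json.dumps(config))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.input_dir is None:
        stage_simulate(config, out_dir)
    stage_segment_extract(config, out_dir)
    stage_harmonize(config, out_dir)
    stage_model(config, out_dir)
    stage_survival(config, out_dir)

    harm = json.loads((out_dir / "harmonization_summary.json").read_text())
    cv = json.loads((out_dir / "cv_report.json").read_text())
    km = pd.read_csv(out_dir / "km_screen.csv")
    report = {
        "n_subjects": int(pd.read_csv(out_dir / "cohort" / "manifest.csv").shape[0])
        if config.input_dir is None else None,
        "harmonization": harm,
        "lr_selected": cv["LR"]["selected"],
        "svm_selected": cv["SVM"]["selected"],
        "lr_test": {k: v["test"] for k, v in cv["LR"]["per_k"].items()},
        "svm_test": {k: v["test"] for k, v in cv["SVM"]["per_k"].items()},
        "km_significant": km.loc[km["significant"], "feature"].tolist(),
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report
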