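"""End-to-end orchestration: subject table in, feature/diagnosis table out.

Per subject the pipeline (i) normalises the native T1-like volume,
(ii) registers it affinely to the stereotaxic template and resamples it
onto the template grid, (iii) segments the lateral ventricles by
patch-based label fusion, (iv) runs automated QC against the template
ventricle prior, (v) extracts the ventricular feature vector with the
lobar atlas and transform-derived ICV, and (vi) applies the linear SVM
to call "compatible with bvFTD" or "not compatible".  Subject-level
failures never abort the batch: the subject is reported with diagnosis
QC_FAIL and processing continues.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifier as clf
from .features import (LobarAtlas, QCThresholds, VentricleFeatures,
                       compute_features, qc_segmentation)
from .io_model import (AffineTransform, LabelVolume, SubjectRecord,
                       VolumeImage, read_label_volume, read_subject_table,
                       read_volume, write_feature_table, write_volume)
from .label_fusion import FusionParams, PatchLibrary, build_library, \
    segment_ventricles
from .preprocess import (RegistrationParams, estimate_icv,
                         normalize_intensity, register_affine,
                         resample_to_template)
from .synthetic import TemplateArtifacts, PhantomSpec, template_affine

log = logging.getLogger("ventra")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All pipeline settings; every field has a working default so `run`
    succeeds on generated fixtures with zero configuration."""

    template_dir: str = ""
    library_manifest: str = ""
    model_path: str = ""
    output_dir: str = "ventra_out"
    log_level: str = "INFO"
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    fusion: FusionParams = field(default_factory=FusionParams)
    qc: QCThresholds = field(default_factory=QCThresholds)
    bias_degree: int = 2
    y_cut_mm: float = -12.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        cfg = cls()
        scalar_keys = {"template_dir", "library_manifest", "model_path",
                       "output_dir", "log_level", "bias_degree", "y_cut_mm"}
        block_types = {"registration": RegistrationParams,
                       "fusion": FusionParams, "qc": QCThresholds}
        unknown = [k for k in raw
                   if k not in scalar_keys and k not in block_types]
        if unknown:
            raise ConfigError("unknown config keys: " + ", ".join(unknown))
        for k in scalar_keys & set(raw):
            setattr(cfg, k, raw[k])
        for name, typ in block_types.items():
            if name in raw:
                block = raw[name] or {}
                valid = {f.name for f in dataclasses.fields(typ)}
                bad = [k for k in block if k not in valid]
                if bad:
                    raise ConfigError(
                        f"unknown keys in config block '{name}': "
                        + ", ".join(bad))
                kw = {k: (tuple(v) if isinstance(v, list) else v)
                      for k, v in block.items()}
                setattr(cfg, name, typ(**kw))
        return cfg

    def echo(self) -> str:
        return yaml.safe_dump({
            "template_dir": self.template_dir,
            "library_manifest": self.library_manifest,
            "model_path": self.model_path,
            "output_dir": self.output_dir,
            "registration": dataclasses.asdict(self.registration),
            "fusion": dataclasses.asdict(self.fusion),
            "qc": dataclasses.asdict(self.qc),
            "bias_degree": self.bias_degree,
            "y_cut_mm": self.y_cut_mm,
        }, sort_keys=True)


# ---------------------------------------------------------------------------
# template-space artifact persistence
# ---------------------------------------------------------------------------

def save_template_artifacts(art: TemplateArtifacts, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(art.template, out / "template.nii.gz")
    write_volume(art.icv_mask, out / "icv_mask.nii.gz")
    write_volume(art.ventricle_prior, out / "ventricle_prior.nii.gz")
    art.atlas.save(out / "atlas.nii.gz", out / "atlas_codes.csv")
    with open(out / "template_spec.yaml", "w") as fh:
        yaml.safe_dump({
            "grid_shape": list(art.spec.grid_shape),
            "spacing_mm": art.spec.spacing_mm,
            "icv_semiaxes_mm": list(art.spec.icv_semiaxes_mm),
        }, fh)


def load_template_artifacts(in_dir) -> TemplateArtifacts:
    p = Path(in_dir)
    with open(p / "template_spec.yaml") as fh:
        meta = yaml.safe_load(fh)
    spec = PhantomSpec(grid_shape=tuple(meta["grid_shape"]),
                       spacing_mm=meta["spacing_mm"],
                       icv_semiaxes_mm=tuple(meta["icv_semiaxes_mm"]))
    return TemplateArtifacts(
        template=read_volume(p / "template.nii.gz"),
        icv_mask=read_label_volume(p / "icv_mask.nii.gz"),
        atlas=LobarAtlas.load(p / "atlas.nii.gz", p / "atlas_codes.csv"),
        ventricle_prior=read_label_volume(p / "ventricle_prior.nii.gz"),
        spec=spec,
    )


def save_library(pairs, out_dir) -> Path:
    """Write library NIfTIs and the image_path,label_path manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, lab) in enumerate(pairs):
        ip, lp = out / f"lib{i:02d}_image.nii.gz", out / f"lib{i:02d}_label.nii.gz"
        write_volume(img, ip)
        write_volume(lab, lp)
        rows.append({"image_path": ip.name, "label_path": lp.name})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_library(manifest_path, cfg: PipelineConfig) -> PatchLibrary:
    """Load and intensity-normalise library entries, build the candidate
    mask with the configured dilation."""
    mdir = Path(manifest_path).parent
    df = pd.read_csv(manifest_path)
    pairs = []
    for r in df.itertuples():
        img = read_volume(mdir / r.image_path)
        lab = read_label_volume(mdir / r.label_path)
        pairs.append((normalize_intensity(img, bias_degree=cfg.bias_degree),
                      lab))
    return build_library(pairs, d=cfg.fusion.dilation)


# ---------------------------------------------------------------------------
# per-subject processing
# ---------------------------------------------------------------------------

@dataclass
class SubjectResult:
    record: SubjectRecord
    features: VentricleFeatures | None
    diagnosis: str
    qc_reasons: list[str] = field(default_factory=list)
    error: str | None = None
    timings: dict = field(default_factory=dict)


def process_subject(rec: SubjectRecord, template_n: VolumeImage,
                    art: TemplateArtifacts, lib: PatchLibrary,
                    model: clf.SVMModel | None, cfg: PipelineConfig,
                    subject_out: Path | None = None) -> SubjectResult:
    """Run the full per-subject chain; exceptions become QC_FAIL."""
    timings: dict[str, float] = {}
    try:
        t0 = time.perf_counter()
        native = read_volume(rec.image_path)
        native_n = normalize_intensity(native, bias_degree=cfg.bias_degree)
        timings["normalize_s"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        transform = register_affine(native_n, template_n, cfg.registration)
        timings["register_s"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        in_template = resample_to_template(native_n, transform, template_n)
        seg, conf = segment_ventricles(in_template, lib, cfg.fusion)
        timings["segment_s"] = time.perf_counter() - t0

        qc = qc_segmentation(seg, art.ventricle_prior, cfg.qc,
                             atlas=art.atlas, y_cut=cfg.y_cut_mm)
        if subject_out is not None:
            subject_out.mkdir(parents=True, exist_ok=True)
            write_volume(in_template, subject_out / "t1_template.nii.gz")
            write_volume(seg, subject_out / "ventricles.nii.gz")
            write_volume(VolumeImage(conf, seg.affine),
                         subject_out / "confidence.nii.gz")
            transform.save(subject_out / "native_to_template.txt")
            with open(subject_out / "qc.json", "w") as fh:
                json.dump({"status": qc.status, "reasons": qc.reasons,
                           "overlap_with_prior": qc.overlap_with_prior,
                           "component_count": qc.component_count}, fh,
                          indent=1)
        if not qc.passed:
            return SubjectResult(rec, None, "QC_FAIL",
                                 qc_reasons=qc.reasons, timings=timings)

        icv = estimate_icv(transform, art.icv_mask)
        feats = compute_features(seg, art.atlas, icv=icv, age=rec.age,
                                 sex_code=rec.sex_code, y_cut=cfg.y_cut_mm)
        if model is not None:
            label, _ = clf.predict(model, feats.classifier_vector())
        else:
            label = "NA"
        return SubjectResult(rec, feats, label, qc_reasons=qc.reasons,
                             timings=timings)
    except Exception as exc:  # subject isolation: batch must continue
        log.warning("subject %s failed: %s", rec.id, exc)
        return SubjectResult(rec, None, "QC_FAIL", error=str(exc),
                             timings=timings)


def run_pipeline(subject_csv, cfg: PipelineConfig, resume: bool = False
                 ) -> Path:
    """Process every subject in the table; write features.csv and per-
    subject outputs under ``cfg.output_dir``.  Returns the output dir."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    run_log = open(out / "run.log", "a")

    def logline(msg):
        log.info(msg)
        run_log.write(msg + "\n")

    logline("ventra run started")
    logline("config:\n" + cfg.echo())

    records = read_subject_table(subject_csv)
    art = load_template_artifacts(cfg.template_dir)
    template_n = normalize_intensity(art.template,
                                     bias_degree=cfg.bias_degree)
    lib = load_library(cfg.library_manifest, cfg)
    model = (clf.load_model(cfg.model_path) if cfg.model_path
             else clf.load_reference_model())

    results: list[SubjectResult] = []
    for rec in records:
        sdir = out / rec.id
        cache = sdir / "features.json"
        if resume and cache.exists():
            with open(cache) as fh:
                cached = json.load(fh)
            feats = (None if cached["features"] is None
                     else _features_from_dict(cached["features"]))
            results.append(SubjectResult(rec, feats, cached["diagnosis"],
                                         qc_reasons=cached.get("qc_reasons",
                                                               [])))
            logline(f"{rec.id}: resumed from cache")
            continue
        t0 = time.perf_counter()
        res = process_subject(rec, template_n, art, lib, model, cfg,
                              subject_out=sdir)
        res.timings["total_s"] = time.perf_counter() - t0
        sdir.mkdir(parents=True, exist_ok=True)
        with open(cache, "w") as fh:
            json.dump({
                "diagnosis": res.diagnosis,
                "qc_reasons": res.qc_reasons,
                "features": (None if res.features is None
                             else res.features.as_dict()
                             | {"age": res.record.age,
                                "sex_code": res.record.sex_code}),
            }, fh, indent=1)
        stage_txt = " ".join(f"{k}={v:.1f}" for k, v in res.timings.items())
        logline(f"{rec.id}: diagnosis={res.diagnosis} {stage_txt}"
                + (f" error={res.error}" if res.error else ""))
        results.append(res)

    rows = [(r.record, r.features, r.diagnosis) for r in results]
    write_feature_table(rows, out / "features.csv")
    n_fail = sum(r.diagnosis == "QC_FAIL" for r in results)
    logline(f"run complete: {len(results)} subjects, {n_fail} QC failures")
    run_log.close()
    return out


def _features_from_dict(d: dict) -> VentricleFeatures:
    from .features import LOBES, HEMIS
    vol = {(lobe, hemi): d.get(f"vol_{lobe}_{hemi}", 0.0)
           for lobe in LOBES for hemi in HEMIS}
    return VentricleFeatures(
        icv=d["icv_mm3"], total_vol=d["total_vol_mm3"],
        total_vv_norm=d["total_vv_norm"],
        anterior_vol=d["anterior_vol_mm3"],
        posterior_vol=d["posterior_vol_mm3"], apr=d["apr"],
        apr_log=d["apr_log"], lr_frontal_log=d["lr_frontal_log"],
        lr_temporal_log=d["lr_temporal_log"], vol=vol,
        age=d.get("age", float("nan")), sex_code=d.get("sex_code", -1))


# ---------------------------------------------------------------------------
# train / evaluate on feature tables
# ---------------------------------------------------------------------------

def _labels_from_table(df: pd.DataFrame) -> np.ndarray:
    from .io_model import SchemaError
    if "true_label" not in df.columns:
        raise SchemaError("feature table has no true_label column")
    return (df["true_label"].astype(str) == "bvFTD").astype(int).to_numpy()


def _feature_matrix(df: pd.DataFrame) -> np.ndarray:
    from .io_model import SchemaError
    cols = list(clf.FEATURE_ORDER)
    if "sex_code" not in df.columns and "sex" in df.columns:
        df = df.assign(sex_code=(df["sex"].astype(str).str.lower()
                                 .isin(("male", "m", "1"))).astype(int))
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError("feature table missing columns: "
                          + ", ".join(missing))
    return df[cols].to_numpy(dtype=float)


def train_from_features(df: pd.DataFrame, C: float = 1.0,
                        class_weight: str = "balanced",
                        seed: int = 0) -> clf.SVMModel:
    """Train the SVM from a feature table with true labels."""
    ok = df["diagnosis"].ne("QC_FAIL") if "diagnosis" in df.columns \
        else pd.Series(True, index=df.index)
    df = df.loc[ok]
    return clf.train(_feature_matrix(df), _labels_from_table(df),
                     C=C, class_weight=class_weight, seed=seed)


def evaluate_features(df: pd.DataFrame, model: clf.SVMModel | None = None
                      ) -> dict:
    """Confusion metrics overall and against each negative subgroup,
    plus the TP/FN and FP/TN misclassification contrasts.

    Predictions come from an existing ``diagnosis`` column when present
    (QC_FAIL rows are dropped with a warning), otherwise from applying
    ``model`` to the feature columns.
    """
    import warnings as _w
    from .evaluation import (classification_metrics, confusion,
                             misclassification_report)

    y = _labels_from_table(df)
    if "diagnosis" in df.columns and df["diagnosis"].ne("NA").all():
        keep = df["diagnosis"].ne("QC_FAIL").to_numpy()
        if not keep.all():
            _w.warn(f"excluding {int((~keep).sum())} QC_FAIL subjects "
                    "from evaluation")
        df, y = df.loc[keep], y[keep]
        pred = (df["diagnosis"] == clf.LABEL_POSITIVE).astype(int).to_numpy()
    else:
        if model is None:
            raise ValueError("need a model when the table has no diagnosis")
        pred, _ = clf.predict_many(model, _feature_matrix(df))

    cm = confusion(y, pred)
    out = {"confusion": cm, "metrics": classification_metrics(cm),
           "per_group": {}}
    if "group" in df.columns:
        pos_mask = y == 1
        for grp in sorted(df.loc[~pos_mask.astype(bool), "group"].unique()):
            sel = pos_mask | (df["group"] == grp).to_numpy()
            if (sel & ~pos_mask).sum() == 0:
                continue
            cm_g = confusion(y[sel], pred[sel])
            try:
                out["per_group"][str(grp)] = classification_metrics(cm_g)
            except Exception as exc:
                _w.warn(f"subgroup {grp} skipped: {exc}")
    feat_cols = [c for c in ("age", "apr", "apr_log", "total_vv_norm",
                             "lr_frontal_log", "lr_temporal_log")
                 if c in df.columns]
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        out["misclassification"] = misclassification_report(
            df, y, pred, feature_columns=feat_cols)
    return out


def format_evaluation(out: dict) -> str:
    cm = out["confusion"]
    lines = ["confusion matrix (positive = bvFTD):",
             f"  tp={cm.tp} fn={cm.fn} fp={cm.fp} tn={cm.tn}",
             out["metrics"].formatted()]
    for grp, rep in out["per_group"].items():
        lines.append(f"vs {grp}: specificity "
                     f"{round(rep.specificity * 100):d}%")
    mis = out["misclassification"]
    if len(mis):
        lines.append("")
        lines.append(mis.to_string(index=False,
                                   float_format=lambda v: f"{v:.3g}"))
    return "\n".join(lines) + "\n"
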