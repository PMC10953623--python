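"""Shared fixtures: the synthetic template space, fused library, and the
expensive cohort experiments, built once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ventra.synthetic as syn
from ventra import classifier as clf
from ventra import experiments as exp
from ventra import pipeline as pl
from ventra.label_fusion import build_library
from ventra.preprocess import normalize_intensity


@pytest.fixture(scope="session")
def template_art() -> syn.TemplateArtifacts:
    return syn.make_template()


@pytest.fixture(scope="session")
def template_norm(template_art):
    return normalize_intensity(template_art.template)


@pytest.fixture(scope="session")
def fusion_library(template_art):
    pairs = [(normalize_intensity(im), lb)
             for im, lb in syn.make_library(template_art, k=5, seed=1)]
    return build_library(pairs, d=3)


@pytest.fixture(scope="session")
def seg_experiment() -> pd.DataFrame:
    """Ten-phantom cohort segmented twice (scan + contrast-shifted
    rescan); the main segmentation-quality benchmark."""
    return exp.segmentation_repeatability_experiment(seed=0, n_subjects=10)


@pytest.fixture(scope="session")
def classifier_experiment() -> dict:
    return exp.classifier_recovery_experiment(seed=0, n_per_group=200)


@pytest.fixture(scope="session")
def truth_features_cohort(template_art) -> pd.DataFrame:
    """Ground-truth feature vectors for a 200+200 cohort at the default
    effect sizes (no image synthesis)."""
    return syn.sample_cohort_features(
        syn.CohortSpec(groups=syn.default_groups(200, 200), seed=31),
        template_art)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, template_art):
    """On-disk template space, library, reference model and a small
    cohort (2 bvFTD-like, 2 psychiatric-like), as `make-fixtures` does."""
    out = tmp_path_factory.mktemp("fixtures")
    pl.save_template_artifacts(template_art, out / "template")
    pairs = syn.make_library(template_art, k=5, seed=1)
    manifest = pl.save_library(pairs, out / "library")
    feats = syn.sample_cohort_features(
        syn.CohortSpec(groups=syn.default_groups(60, 60), seed=5),
        template_art)
    model = pl.train_from_features(feats, seed=0)
    clf.save_model(model, out / "model.txt")
    syn.make_cohort(
        syn.CohortSpec(groups=syn.default_groups(2, 2), seed=9),
        out / "cohort", template_art)
    return out


@pytest.fixture(scope="session")
def pipeline_runs(fixture_dir, tmp_path_factory):
    """The same subject table processed twice with identical settings,
    plus one subject with an unreadable image path."""
    out_root = tmp_path_factory.mktemp("runs")
    subjects = pd.read_csv(fixture_dir / "cohort" / "subjects.csv")
    bad = subjects.iloc[[0]].assign(
        id="sub-broken", image_path=str(fixture_dir / "missing.nii.gz"))
    table = pd.concat([subjects, bad], ignore_index=True)
    subj_csv = out_root / "subjects.csv"
    table.to_csv(subj_csv, index=False)

    outs = []
    for name in ("run1", "run2"):
        cfg = pl.PipelineConfig(
            template_dir=str(fixture_dir / "template"),
            library_manifest=str(fixture_dir / "library" / "manifest.csv"),
            model_path=str(fixture_dir / "model.txt"),
            output_dir=str(out_root / name))
        outs.append(pl.run_pipeline(subj_csv, cfg))
    return outs
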