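"""End-to-end experiment orchestration.

Four experiments compose the stress-detection study, all running the same
chain preprocess -> segment -> extract features -> evaluate:

* ``feature_sets`` — compare the frequency features (set 1), time features
  (set 2) and their hybrid (set 3) across the classifiers.
* ``site_ablation`` — rebuild the system from each scalp site's electrodes
  (frontal, temporal, central, parietal, occipital) and compare.
* ``pc_search`` — sequential forward scan of the number of principal
  components retained from the hybrid feature set.
* ``electrode_minimal`` — single frontal electrodes and the small frontal
  fusions (Fp1+Fp2, Fp1+F8, Fp1+F7+F8), under both 5-fold and
  leave-one-subject-out validation.

A single master seed deterministically derives every stage seed, and each
run writes a metadata file (config echo, seeds, package versions) that
suffices to re-execute it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .evaluation import (ClassifierSpec, CLASSIFIER_KINDS, MetricReport,
                         reliability_gate, run_validation)
from .features import FeatureMatrix, build_feature_matrix, concat_feature_matrices
from .preprocessing import DenoiseSpec, FilterSpec, preprocess
from .reduction_selection import (channel_subset_evaluation, fusion_subsets,
                                  frontal_single_subsets,
                                  reports_to_table, sequential_forward_pc_search,
                                  site_subsets)
from .segmentation import segment_recording
from .signal_io import CohortManifest, load_cohort
from .synthetic_data import GeneratorConfig, iter_cohort

__all__ = [
    "ExperimentConfig",
    "stage_seed",
    "extract_cohort_features",
    "run_experiment",
]

log = logging.getLogger("msdeeg")

EXPERIMENTS = ("feature_sets", "site_ablation", "pc_search", "electrode_minimal")


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stage seed from the master seed and the stage name.

    Uses a seed sequence keyed by (master seed, crc32 of the stage name);
    the result is stable across platforms and kept below 2**31.
    """
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class ExperimentConfig:
    """One experiment run, with nested per-stage configuration blocks."""

    experiment: str = "feature_sets"
    task: str = "stress_vs_rest"
    seed: int = 0
    out_dir: str = "msd_run"
    generate: dict = field(default_factory=dict)   # GeneratorConfig overrides
    preprocess: dict = field(default_factory=dict)  # FilterSpec/DenoiseSpec/stages
    segment: dict = field(default_factory=lambda: {"window_s": 4.0, "stride_s": 1.0})
    features: dict = field(default_factory=lambda: {"feature_set": "set3"})
    selection: dict = field(default_factory=dict)   # max_k, pca_scope, subsets
    evaluate: dict = field(default_factory=dict)    # classifiers, scheme, ci_method

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"experiment must be one of {EXPERIMENTS}")
        if self.task not in ("stress_vs_rest", "levels"):
            raise ValueError("task must be stress_vs_rest or levels")
        if "group_split" in self.generate:  # YAML has no tuples
            self.generate["group_split"] = list(self.generate["group_split"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def classifier_specs(self) -> list[ClassifierSpec]:
        kinds = self.evaluate.get("classifiers", list(CLASSIFIER_KINDS))
        seed = stage_seed(self.seed, "classifier")
        return [ClassifierSpec(kind=k, seed=seed) for k in kinds]

    def filter_spec(self) -> FilterSpec:
        fields = {f.name for f in dataclasses.fields(FilterSpec)}
        return FilterSpec(**{k: v for k, v in self.preprocess.items() if k in fields})

    def denoise_spec(self) -> DenoiseSpec:
        fields = {f.name for f in dataclasses.fields(DenoiseSpec)}
        return DenoiseSpec(**{k: v for k, v in self.preprocess.items() if k in fields})

    def generator_config(self) -> GeneratorConfig:
        kwargs = dict(self.generate)
        kwargs.setdefault("seed", stage_seed(self.seed, "generate"))
        if "group_split" in kwargs:
            kwargs["group_split"] = tuple(kwargs["group_split"])
        return GeneratorConfig(**kwargs)


def extract_cohort_features(recordings, cfg: ExperimentConfig) -> FeatureMatrix:
    """Preprocess, segment and featurise recordings one at a time.

    Streaming keeps memory at one recording's trials rather than the whole
    cohort's.
    """
    fspec = cfg.filter_spec()
    dspec = cfg.denoise_spec()
    stages = {k: cfg.preprocess.get(k, True)
              for k in ("filter_stage", "denoise_stage", "smooth_stage")}
    parts = []
    n_rec = 0
    for rec in recordings:
        rec = preprocess(rec, fspec, dspec, **stages)
        segs = segment_recording(rec, **cfg.segment)
        parts.append(build_feature_matrix(
            segs,
            set_tag=cfg.features.get("feature_set", "set3"),
            root_moments=cfg.features.get("root_moments", True),
            ar_method=cfg.features.get("ar_method", "yule_walker"),
        ))
        n_rec += 1
        log.info("recording %d (%s/%s): %d trials",
                 n_rec, rec.subject_id, rec.state, parts[-1].n_trials)
    fm = concat_feature_matrices(parts)
    log.info("feature matrix: %d trials x %d features", fm.n_trials,
             len(fm.feature_names))
    return fm


def _cohort_recordings(cfg: ExperimentConfig, manifest: CohortManifest | None,
                       base_dir: str | Path = "."):
    if manifest is not None:
        yield from load_cohort(manifest, base_dir)
    else:
        for _entry, rec in iter_cohort(cfg.generator_config()):
            yield rec


def _report_to_json(obj) -> dict:
    if isinstance(obj, MetricReport):
        d = obj.to_dict()
        d["reliability_gate"] = reliability_gate(obj)
        return d
    return obj


def run_experiment(cfg: ExperimentConfig,
                   manifest: CohortManifest | None = None,
                   base_dir: str | Path = ".",
                   feature_matrix: FeatureMatrix | None = None) -> dict:
    """Execute one experiment and write its report bundle.

    With no manifest, a synthetic cohort is generated from the config's
    ``generate`` block. ``feature_matrix`` short-circuits the signal stages
    (useful to reuse one extraction across experiments). Returns the bundle
    as a dict; files are written under ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    eval_seed = stage_seed(cfg.seed, "folds")
    scheme = cfg.evaluate.get("scheme", "kfold5")
    ci_method = cfg.evaluate.get("ci_method", "t")
    specs = cfg.classifier_specs()

    if feature_matrix is None:
        feature_matrix = extract_cohort_features(
            _cohort_recordings(cfg, manifest, base_dir), cfg)
    fm = feature_matrix

    bundle: dict = {"experiment": cfg.experiment, "task": cfg.task}

    if cfg.experiment == "feature_sets":
        results = {}
        for tag in ("set1", "set2", "set3"):
            fm_tag = _restrict_feature_set(fm, tag)
            for spec in specs:
                rep = run_validation(fm_tag, spec, task=cfg.task,
                                     scheme=scheme, seed=eval_seed,
                                     ci_method=ci_method)
                results[(tag, spec.kind)] = rep
        bundle["reports"] = {f"{t}|{c}": _report_to_json(r)
                             for (t, c), r in results.items()}
        reports_to_table({k: v for k, v in results.items()}).to_csv(
            out / "feature_sets.csv", index=False)

    elif cfg.experiment == "site_ablation":
        subsets = cfg.selection.get("subsets") or site_subsets()
        results = channel_subset_evaluation(
            fm, subsets, specs, task=cfg.task, scheme=scheme,
            seed=eval_seed, ci_method=ci_method)
        bundle["reports"] = {f"{s}|{c}": _report_to_json(r)
                             for (s, c), r in results.items()}
        reports_to_table(results).to_csv(out / "site_ablation.csv", index=False)

    elif cfg.experiment == "pc_search":
        max_k = cfg.selection.get("max_k", min(60, len(fm.feature_names)))
        traces = {}
        for spec in specs:
            traces[spec.kind] = sequential_forward_pc_search(
                fm, spec, max_k=max_k, task=cfg.task, seed=eval_seed,
                pca_scope=cfg.selection.get("pca_scope", "fold"))
        bundle["traces"] = {k: t.to_dict() for k, t in traces.items()}
        pd.DataFrame({k: t.scores for k, t in traces.items()},
                     index=pd.Index(range(1, max_k + 1), name="n_components")
                     ).to_csv(out / "pc_search.csv")

    elif cfg.experiment == "electrode_minimal":
        subsets = dict(frontal_single_subsets())
        subsets.update(fusion_subsets())
        results = channel_subset_evaluation(
            fm, subsets, specs, task=cfg.task, scheme=scheme,
            seed=eval_seed, ci_method=ci_method)
        loso = channel_subset_evaluation(
            fm, fusion_subsets(), specs, task=cfg.task,
            scheme="leave_subject_out", seed=eval_seed, ci_method=ci_method)
        bundle["reports"] = {f"{s}|{c}": _report_to_json(r)
                             for (s, c), r in results.items()}
        bundle["reports_loso"] = {f"{s}|{c}": _report_to_json(r)
                                  for (s, c), r in loso.items()}
        reports_to_table(results).to_csv(out / "electrode_minimal.csv",
                                         index=False)
        reports_to_table(loso).to_csv(out / "electrode_minimal_loso.csv",
                                      index=False)

    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(bundle, fh, indent=2, default=str)
    _write_metadata(cfg, out, fm)
    return bundle


def _restrict_feature_set(fm: FeatureMatrix, tag: str) -> FeatureMatrix:
    """Column-subset a set-3 matrix down to set 1 or 2 (or pass through)."""
    from .features import _FEATURES_BY_SET

    if tag == fm.feature_set:
        return fm
    if fm.feature_set != "set3":
        raise ValueError(f"cannot derive {tag} from a {fm.feature_set} matrix")
    feats = _FEATURES_BY_SET[tag]
    cols = [f"{ch}__{f}" for ch in fm.channels for f in feats]
    return FeatureMatrix(data=fm.data[cols].copy(), labels=fm.labels,
                         feature_set=tag)


def _write_metadata(cfg: ExperimentConfig, out: Path, fm: FeatureMatrix) -> None:
    import sklearn
    import scipy

    meta = {
        "config": cfg.to_dict(),
        "stage_seeds": {s: stage_seed(cfg.seed, s)
                        for s in ("generate", "folds", "classifier")},
        "n_trials": fm.n_trials,
        "n_features": len(fm.feature_names),
        "versions": {
            "msdeeg": _pkg_version,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "run_metadata.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, default=str)
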