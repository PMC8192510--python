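"""End-to-end pipeline: simulate -> profile -> associate -> signature.

Every run writes a manifest (inputs, seeds, package versions, SHA-256
checksums of every output) so each number in the bundle is re-derivable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import default_contrast_spec, run_association_battery
from .ga import EvalParams, GAParams, GASignatureSelector
from .io import read_cohort, write_cohort, write_labels
from .profiling import ProfileClusterer, name_profiles
from .synthetic import Cohort, default_config, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str | Path = "immunosig_out"
    seed: int = 0
    #: None -> simulate with the study-calibrated defaults
    cohort_paths: tuple[str, str, str] | None = None
    n_subjects: int = 150
    k_profiles: int = 5
    target_profile: int = 2
    ga: GAParams = dataclasses.field(default_factory=GAParams)
    eval: EvalParams = dataclasses.field(default_factory=EvalParams)
    use_true_labels: bool = False


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    try:
        if config.cohort_paths is None:
            gen_cfg = default_config(seed=seed)
            gen_cfg.n_subjects = config.n_subjects
            cohort = generate_cohort(gen_cfg, seed=seed)
            source = {"kind": "simulated", "n_subjects": config.n_subjects, "seed": seed}
        else:
            cohort = read_cohort(*config.cohort_paths)
            source = {"kind": "files", "paths": [str(p) for p in config.cohort_paths]}
        paths = write_cohort(cohort, out)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate/read' failed: {exc}") from exc

    try:
        if config.use_true_labels and cohort.true_profile is not None:
            labels = cohort.true_profile.to_numpy()
            naming = None
        else:
            clusterer = ProfileClusterer(k_profiles=config.k_profiles).fit(cohort)
            naming = name_profiles(clusterer.labels_, cohort)
            labels = naming.relabel(clusterer.labels_)
        labels_path = write_labels(labels, cohort.subject_ids, out / "labels.csv")
        paths["labels"] = labels_path
        if naming is not None:
            naming_path = out / "naming.json"
            naming_path.write_text(json.dumps(
                {
                    "mapping": {str(k): v for k, v in naming.mapping.items()},
                    "confidence": naming.confidence,
                    "low_confidence": naming.low_confidence,
                },
                indent=2,
            ))
            paths["naming"] = naming_path
    except Exception as exc:
        raise RuntimeError(f"stage 'profile' failed: {exc}") from exc

    try:
        report = run_association_battery(
            cohort, labels, default_contrast_spec(config.target_profile), bh=True
        )
        assoc_path = out / "associations.csv"
        report.to_csv(assoc_path, index=False)
        paths["associations"] = assoc_path
    except Exception as exc:
        raise RuntimeError(f"stage 'associate' failed: {exc}") from exc

    try:
        y = np.asarray(labels) == config.target_profile
        selector = GASignatureSelector(
            **{f.name: getattr(config.ga, f.name) for f in dataclasses.fields(GAParams)
               if f.name != "seed"},
            n_eval_runs=config.eval.n_eval_runs,
            eval_cv_folds=config.eval.eval_cv_folds,
            seed=seed,
        )
        selector.fit(cohort.markers, y)
        ranked_path = out / "ranked_signatures.csv"
        selector.ranking_frame().to_csv(ranked_path, index=False)
        paths["ranked_signatures"] = ranked_path
        hist_path = out / "fitness_history.jsonl"
        with hist_path.open("w") as fh:
            for run, hist in enumerate(selector.histories_):
                fh.write(json.dumps({"run": run, "best_fitness": hist}) + "\n")
        paths["fitness_history"] = hist_path
    except Exception as exc:
        raise RuntimeError(f"stage 'signature' failed: {exc}") from exc

    manifest = {
        "created": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "source": source,
        "versions": {
            "immunosig": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": {k: {"path": str(p), "sha256": _sha256(Path(p))}
                    for k, p in paths.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
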