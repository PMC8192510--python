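"""Cohort file I/O: three CSV tables sharing a ``subject_id`` key.

Schema (documented in the README): ``markers.csv`` holds the numeric
marker panel, ``metabolic.csv`` the metabolic variables, ``therapy.csv``
the boolean therapy flags plus an optional ``profile`` column with planted
or assigned labels. All files are UTF-8, header row, RFC-4180 CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import Cohort, MarkerDef, OutcomeDef, SyntheticConfig

__all__ = ["write_cohort", "read_cohort", "write_config", "read_config",
           "write_labels", "read_labels"]


def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    """Write markers/metabolic/therapy CSVs (and the profile column when
    labels are present). Returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "markers": out / "markers.csv",
        "metabolic": out / "metabolic.csv",
        "therapy": out / "therapy.csv",
    }
    cohort.markers.to_csv(paths["markers"])
    cohort.metabolic.to_csv(paths["metabolic"])
    therapy = cohort.therapy.copy()
    if cohort.true_profile is not None:
        therapy["profile"] = cohort.true_profile
    therapy.to_csv(paths["therapy"])
    return paths


def _read_table(path, name: str, boolean: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="subject_id")
    for col in df.columns:
        series = df[col]
        if boolean:
            if series.dtype == bool:
                continue
            lowered = series.astype(str).str.lower()
            ok = lowered.isin(["true", "false", "0", "1"])
            if not ok.all():
                row = df.index[~ok][0]
                raise ValueError(
                    f"{name}: non-boolean cell at row {row!r}, column {col!r}"
                )
            df[col] = lowered.isin(["true", "1"])
        else:
            coerced = pd.to_numeric(series, errors="coerce")
            bad = coerced.isna() & series.notna()
            if bad.any():
                row = df.index[bad][0]
                raise ValueError(
                    f"{name}: non-numeric cell at row {row!r}, column {col!r}"
                )
            if coerced.isna().any():
                row = df.index[coerced.isna()][0]
                raise ValueError(
                    f"{name}: missing value at row {row!r}, column {col!r}"
                )
            df[col] = coerced
    return df


def read_cohort(markers_path, metabolic_path, therapy_path) -> Cohort:
    """Read and validate the three-table cohort schema; rows are aligned by
    a keyed join on ``subject_id`` (file row order is irrelevant)."""
    markers = _read_table(markers_path, "markers")
    metabolic = _read_table(metabolic_path, "metabolic")
    therapy_raw = pd.read_csv(therapy_path, index_col="subject_id")
    profile = None
    if "profile" in therapy_raw.columns:
        profile = therapy_raw.pop("profile").astype(int)
    therapy = _read_table_from_frame(therapy_raw, "therapy")

    ids = markers.index
    for name, df in [("metabolic", metabolic), ("therapy", therapy)]:
        missing = ids.difference(df.index).tolist() + df.index.difference(ids).tolist()
        if missing:
            raise ValueError(f"{name}: subject ids do not match markers: {missing}")
    metabolic = metabolic.loc[ids]
    therapy = therapy.loc[ids]
    true_profile = profile.loc[ids].rename("true_profile") if profile is not None else None
    return Cohort(markers, metabolic, therapy, true_profile)


def _read_table_from_frame(df: pd.DataFrame, name: str) -> pd.DataFrame:
    df = df.copy()
    for col in df.columns:
        series = df[col]
        if series.dtype == bool:
            continue
        lowered = series.astype(str).str.lower()
        ok = lowered.isin(["true", "false", "0", "1"])
        if not ok.all():
            row = df.index[~ok][0]
            raise ValueError(f"{name}: non-boolean cell at row {row!r}, column {col!r}")
        df[col] = lowered.isin(["true", "1"])
    return df


def write_labels(labels, subject_ids, path) -> Path:
    path = Path(path)
    pd.DataFrame({"subject_id": subject_ids, "profile": np.asarray(labels)}).to_csv(
        path, index=False
    )
    return path


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path)
    return pd.Series(df["profile"].to_numpy(), index=pd.Index(df["subject_id"], name="subject_id"), name="profile")


# --------------------------------------------------------------------------
# Config serialization
# --------------------------------------------------------------------------


def _config_to_dict(config: SyntheticConfig) -> dict:
    d = dataclasses.asdict(config)
    d["effect_matrix"] = np.asarray(config.effect_matrix).tolist()
    d["correlation_targets"] = [list(t) for t in config.correlation_targets]
    return d


def write_config(config: SyntheticConfig, path) -> Path:
    """Serialize a generator config as JSON (.json) or YAML (anything else)."""
    path = Path(path)
    d = _config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    return path


def read_config(path) -> SyntheticConfig:
    path = Path(path)
    d = yaml.safe_load(path.read_text())  # YAML is a JSON superset
    d["marker_defs"] = [MarkerDef(**m) for m in d["marker_defs"]]
    d["effect_matrix"] = np.asarray(d["effect_matrix"], dtype=float)
    d["correlation_targets"] = [tuple(t) for t in d["correlation_targets"]]
    d["outcome_defs"] = {
        k: OutcomeDef(**{**v, "means": tuple(v["means"]), "sds": tuple(v["sds"])})
        for k, v in d["outcome_defs"].items()
    }
    d["therapy_rates"] = {k: tuple(v) for k, v in d["therapy_rates"].items()}
    d["profile_proportions"] = tuple(d["profile_proportions"])
    d["activation_markers"] = tuple(d.get("activation_markers", ()))
    d["activation_outcomes"] = tuple(d.get("activation_outcomes", ()))
    cfg = SyntheticConfig(**d)
    cfg.validate()
    return cfg
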