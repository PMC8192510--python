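"""Synthetic immune-activation cohorts.

Generates subject-level data with the statistical structure the downstream
analysis assumes: five immune-activation (IA) profiles of fixed sizes
(43/22/39/41/5 in a 150-subject cohort), a 43-marker panel whose named
members carry profile-specific elevations, target inter-marker Spearman
correlations induced through a Gaussian copula, per-profile metabolic
outcome distributions, and per-profile therapy prevalences.

Markers are drawn as a latent multivariate normal whose pairwise latent
correlation for a Spearman target ``rho_S`` is ``2*sin(pi*rho_S/6)`` (the
exact normal-copula relation), shifted additively per profile on the
transform scale (in latent-SD units) and mapped back through the marker's
marginal transform (identity, moment-matched log-normal, or delta-scaled
logistic for percentages).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "MarkerDef",
    "OutcomeDef",
    "SyntheticConfig",
    "Cohort",
    "default_config",
    "generate_cohort",
    "null_config",
    "profile_recovery_config",
    "planted_signature_config",
    "PROFILE_SIGNATURES",
    "METABOLIC_COLUMNS",
    "THERAPY_COLUMNS",
]

N_PROFILES = 5

METABOLIC_COLUMNS = (
    "insulinemia",
    "glycemia",
    "triglycerides",
    "hdl",
    "ldl",
    "cholesterol",
    "waist",
    "hip",
    "systolic",
    "diastolic",
    "gamma_gt",
    "alcohol",
)

THERAPY_COLUMNS = ("antidiabetic", "antihyperlipidemic", "antihypertensive")

Transform = Literal["identity", "log", "logit"]
Scale = Literal["percent", "concentration"]


@dataclass(frozen=True)
class MarkerDef:
    """One marker of the panel, with its marginal distribution.

    ``baseline_mean``/``baseline_sd`` are in native units (percent of the
    parent population for ``percent`` markers, assay concentration units
    otherwise). ``transform`` chooses the scale on which the latent normal
    lives before back-transformation.
    """

    name: str
    scale: Scale
    baseline_mean: float
    baseline_sd: float
    transform: Transform = "identity"

    def validate(self) -> None:
        if self.baseline_sd <= 0:
            raise ValueError(f"marker {self.name!r}: baseline_sd must be > 0")
        if self.scale == "percent" and not (0.0 < self.baseline_mean < 100.0):
            raise ValueError(
                f"marker {self.name!r}: percent baseline_mean must be in (0, 100)"
            )
        if self.transform == "log" and self.baseline_mean <= 0:
            raise ValueError(
                f"marker {self.name!r}: log transform needs a positive mean"
            )


@dataclass(frozen=True)
class OutcomeDef:
    """A metabolic outcome with per-profile mean/SD and a marginal family.

    ``lognormal`` outcomes are moment-matched (the log-normal draw has
    exactly the configured mean and SD in expectation), which keeps
    right-skewed quantities such as gamma-GT or insulinemia positive.
    """

    name: str
    means: tuple[float, ...]
    sds: tuple[float, ...]
    distribution: Literal["normal", "lognormal"] = "normal"
    unit: str = ""

    def validate(self) -> None:
        if len(self.means) != N_PROFILES or len(self.sds) != N_PROFILES:
            raise ValueError(f"outcome {self.name!r}: need {N_PROFILES} means/sds")
        if any(s <= 0 for s in self.sds):
            raise ValueError(f"outcome {self.name!r}: all SDs must be > 0")
        if self.distribution == "lognormal" and any(m <= 0 for m in self.means):
            raise ValueError(f"outcome {self.name!r}: lognormal needs positive means")


@dataclass
class SyntheticConfig:
    """Full description of a synthetic cohort draw."""

    n_subjects: int = 150
    profile_proportions: tuple[float, ...] = (
        43 / 150,
        22 / 150,
        39 / 150,
        41 / 150,
        5 / 150,
    )
    marker_defs: list[MarkerDef] = field(default_factory=list)
    #: additive shifts per (profile, marker), in latent-SD units on the
    #: transform scale
    effect_matrix: np.ndarray = field(default_factory=lambda: np.zeros((N_PROFILES, 0)))
    correlation_targets: list[tuple[str, str, float]] = field(default_factory=list)
    outcome_defs: dict[str, OutcomeDef] = field(default_factory=dict)
    therapy_rates: dict[str, tuple[float, ...]] = field(default_factory=dict)
    #: markers whose (pre-shift) latent average defines the shared
    #: "activation" factor, and the outcomes loading on it
    activation_markers: tuple[str, ...] = ()
    activation_outcomes: tuple[str, ...] = ()
    activation_loading: float = 0.3
    draw_counts: Literal["fixed", "multinomial"] = "fixed"
    seed: int = 0

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.marker_defs]

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        props = np.asarray(self.profile_proportions, dtype=float)
        if props.shape != (N_PROFILES,) or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("profile_proportions must be length 5 and sum to 1")
        if np.any(props < 0):
            raise ValueError("profile_proportions must be non-negative")
        for m in self.marker_defs:
            m.validate()
        names = self.marker_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate marker names")
        eff = np.asarray(self.effect_matrix, dtype=float)
        if eff.shape != (N_PROFILES, len(names)):
            raise ValueError(
                f"effect_matrix must be {N_PROFILES} x {len(names)}, got {eff.shape}"
            )
        for a, b, rho in self.correlation_targets:
            if a not in names or b not in names:
                raise ValueError(f"correlation target ({a}, {b}) not in panel")
            if not abs(rho) < 1.0:
                raise ValueError(f"|target rho| must be < 1, got {rho}")
        for od in self.outcome_defs.values():
            od.validate()
        for t, rates in self.therapy_rates.items():
            r = np.asarray(rates, dtype=float)
            if r.shape != (N_PROFILES,) or np.any(r < 0) or np.any(r > 1):
                raise ValueError(f"therapy {t!r}: rates must be 5 values in [0, 1]")
        for m in self.activation_markers:
            if m not in names:
                raise ValueError(f"activation marker {m!r} not in panel")
        for o in self.activation_outcomes:
            if o not in self.outcome_defs:
                raise ValueError(f"activation outcome {o!r} not defined")
        if not 0.0 <= self.activation_loading < 1.0:
            raise ValueError("activation_loading must be in [0, 1)")


@dataclass
class Cohort:
    """The central exchange object: markers + metabolic panel + therapy flags.

    All three tables share the ``subject_id`` index; ``true_profile`` is the
    planted label (1-5) when the cohort is synthetic, ``None`` for data read
    from files without labels.
    """

    markers: pd.DataFrame
    metabolic: pd.DataFrame
    therapy: pd.DataFrame
    true_profile: pd.Series | None = None

    @property
    def subject_ids(self) -> pd.Index:
        return self.markers.index

    @property
    def n_subjects(self) -> int:
        return len(self.markers)

    @property
    def marker_names(self) -> list[str]:
        return list(self.markers.columns)

    def variable(self, name: str) -> pd.Series:
        """Look up a variable by name across tables, incl. derived ones.

        ``homa`` and ``waist_hip_ratio`` are computed per subject.
        """
        if name in self.markers.columns:
            return self.markers[name]
        if name in self.metabolic.columns:
            return self.metabolic[name]
        if name in self.therapy.columns:
            return self.therapy[name]
        if name == "homa":
            from .association import homa_ir

            return pd.Series(
                homa_ir(self.metabolic["glycemia"], self.metabolic["insulinemia"]),
                index=self.subject_ids,
                name="homa",
            )
        if name == "waist_hip_ratio":
            s = self.metabolic["waist"] / self.metabolic["hip"]
            s.name = "waist_hip_ratio"
            return s
        raise KeyError(f"unknown variable {name!r}")


# --------------------------------------------------------------------------
# Default calibration
# --------------------------------------------------------------------------

# Signature marker sets used both to plant profile effects and, downstream,
# to name recovered clusters. Signs: +1 elevated in that profile, -1 depleted.
PROFILE_SIGNATURES: dict[int, dict[str, int]] = {
    1: {"pct_naive_cd4": 1, "pct_naive_cd8": 1},
    2: {
        "pct_em_cd4": 1,
        "pct_exhausted_cd4": 1,
        "pct_cd57_cd4": 1,
        "scd163": 1,
        "tpa": 1,
        "stnfri": 1,
        "iga": 1,
    },
    3: {"pct_cd57_cd8": 1, "pct_em_cd8": 1},
    4: {"pct_activated_nk": 1},
    5: {"pct_monocytes": 1},
}

# Named panel members: (name, scale, baseline mean, baseline SD, transform).
# Baselines are the non-Profile-2 group summaries where the study prints
# them; the remainder (CD57+CD4, activated NK, monocytes, CRP) are
# free parameters set to values typical of a late-middle-aged cohort.
_NAMED_MARKERS: list[tuple[str, Scale, float, float, Transform]] = [
    ("pct_naive_cd4", "percent", 44.8, 14.2, "logit"),
    ("pct_naive_cd8", "percent", 39.3, 16.3, "logit"),
    ("pct_em_cd4", "percent", 9.0, 6.0, "logit"),
    ("pct_em_cd8", "percent", 8.4, 6.2, "logit"),
    ("pct_exhausted_cd4", "percent", 9.0, 5.0, "logit"),
    ("pct_cd57_cd4", "percent", 10.0, 6.0, "logit"),
    ("pct_cd57_cd8", "percent", 27.9, 16.0, "logit"),
    ("pct_hladr_cd4", "percent", 14.8, 10.7, "logit"),
    ("pct_hladr_cd8", "percent", 38.1, 17.0, "logit"),
    ("pct_activated_nk", "percent", 12.0, 6.0, "logit"),
    ("pct_monocytes", "percent", 6.0, 2.5, "logit"),
    ("stnfri", "concentration", 1.5, 0.4, "log"),
    ("scd163", "concentration", 639.0, 234.0, "log"),
    ("tpa", "concentration", 10.0, 6.0, "log"),
    ("iga", "concentration", 2.3, 0.9, "log"),
    ("crp", "concentration", 3.0, 2.5, "log"),
]

N_MARKERS = 43

# Profile-2 shifts derived from the printed Profile-2-vs-rest group
# summaries, expressed in rest-group SD units; unprinted members of the
# Profile-2 signature (CD57+CD4, CRP) get shifts consistent with the
# qualitative description (CD4 senescence, inflammation).
_PROFILE2_EFFECTS: dict[str, float] = {
    "pct_em_cd4": 2.5,  # 24+-13 vs 9+-6 %
    "pct_exhausted_cd4": 2.0,  # 19+-18 vs 9+-5 %
    "pct_cd57_cd4": 2.0,
    "pct_naive_cd4": -1.4,  # 24.9+-14.4 vs 44.8+-14.2 %
    "pct_naive_cd8": -0.9,  # 24.9+-8.3 vs 39.3+-16.3 %
    "pct_em_cd8": 1.0,  # 14.7+-9.7 vs 8.4+-6.2 %
    "pct_cd57_cd8": 0.55,  # 36.9+-17.0 vs 27.9+-16.0 %
    "pct_hladr_cd4": 0.7,  # 22.5+-11.3 vs 14.8+-10.7 %
    "pct_hladr_cd8": 0.6,  # 47.9+-18.5 vs 38.1+-17.0 %
    "stnfri": 0.5,  # 1.7+-0.4 vs 1.5+-0.4 mg/L
    "scd163": 1.3,  # 940+-398 vs 639+-234 ng/mL
    "tpa": 0.65,  # 14+-6 vs 10+-6 ng/mL
    "iga": 1.2,  # 3.4+-1.9 vs 2.3+-0.9 g/L
    "crp": 0.5,
}

_OTHER_PROFILE_EFFECTS: dict[int, dict[str, float]] = {
    1: {"pct_naive_cd4": 1.0, "pct_naive_cd8": 1.0},
    3: {"pct_cd57_cd8": 2.0, "pct_em_cd8": 1.5, "pct_hladr_cd8": 0.8},
    4: {"pct_activated_nk": 2.5},
    5: {"pct_monocytes": 2.5},
}

# Broader per-profile patterns over the panel (signs, unit magnitude). The
# five profiles were defined over the full 43-marker panel, so each carries
# structure beyond its headline markers; the unnamed (aux) panel members
# receive profile-specific blocks of moderate size. Used to give the aux
# markers profile structure in the default config and, scaled uniformly,
# by :func:`profile_recovery_config`.
PROFILE_EFFECT_PATTERNS: dict[int, dict[str, int]] = {
    1: {
        "pct_naive_cd4": 1, "pct_naive_cd8": 1, "pct_em_cd4": -1,
        "pct_em_cd8": -1, "pct_cd57_cd4": -1, "pct_cd57_cd8": -1,
        "aux_01": 1, "aux_02": 1, "aux_03": 1,
    },
    2: {
        "pct_em_cd4": 1, "pct_exhausted_cd4": 1, "pct_cd57_cd4": 1,
        "pct_naive_cd4": -1, "scd163": 1, "tpa": 1, "stnfri": 1,
        "iga": 1, "crp": 1, "aux_04": 1, "aux_05": 1, "aux_06": 1,
    },
    3: {
        "pct_cd57_cd8": 1, "pct_em_cd8": 1, "pct_hladr_cd8": 1,
        "pct_naive_cd8": -1, "aux_07": 1, "aux_08": 1, "aux_09": 1,
    },
    4: {"pct_activated_nk": 1, "aux_10": 1, "aux_11": 1, "aux_12": 1, "aux_13": 1},
    5: {"pct_monocytes": 1, "aux_14": 1, "aux_15": 1, "aux_16": 1, "aux_17": 1},
}

#: default magnitude (latent SD) of the aux-marker profile blocks
_AUX_EFFECT = 1.5

# Per-profile metabolic outcome summaries (profiles 1..5). Right-skewed
# quantities (printed SD comparable to the mean) use the log-normal family.
_OUTCOME_TABLE: dict[str, tuple[tuple[float, ...], tuple[float, ...], str, str]] = {
    "insulinemia": ((9.7, 13.3, 9.3, 10.1, 9.5), (5.6, 9.2, 5.4, 5.7, 7.3), "lognormal", "uU/mL"),
    "glycemia": ((5.54, 6.16, 5.36, 5.56, 5.40), (1.51, 1.70, 0.69, 0.82, 0.60), "normal", "mM"),
    "triglycerides": ((1.12, 1.54, 1.09, 1.15, 1.26), (0.64, 1.03, 0.54, 0.59, 0.57), "lognormal", "mM"),
    "hdl": ((0.65, 0.55, 0.60, 0.55, 0.58), (0.20, 0.14, 0.13, 0.13, 0.13), "normal", "mM"),
    "ldl": ((1.36, 1.40, 1.40, 1.49, 1.49), (0.30, 0.45, 0.43, 0.39, 0.38), "normal", "mM"),
    "cholesterol": ((2.22, 2.26, 2.20, 2.25, 2.31), (0.36, 0.55, 0.53, 0.42, 0.42), "normal", "mM"),
    "waist": ((85.5, 93.4, 87.6, 90.6, 90.8), (14.2, 14.0, 10.5, 13.3, 16.3), "normal", "cm"),
    "hip": ((99.5, 99.6, 102.2, 100.6, 97.2), (8.6, 8.7, 8.3, 8.6, 10.2), "normal", "cm"),
    "systolic": ((137.0, 141.0, 137.0, 138.0, 137.0), (20.0, 12.0, 17.0, 19.0, 20.0), "normal", "mmHg"),
    "diastolic": ((81.0, 84.0, 83.0, 82.0, 84.0), (11.0, 8.0, 10.0, 10.0, 9.0), "normal", "mmHg"),
    "gamma_gt": ((38.0, 76.0, 38.0, 38.0, 38.0), (34.0, 88.0, 34.0, 34.0, 34.0), "lognormal", "UI/L"),
    "alcohol": ((8.2, 6.1, 8.2, 8.2, 8.2), (22.1, 10.9, 22.1, 22.1, 22.1), "lognormal", "g/day"),
}

# Therapy counts per profile from the cohort characteristics table
# (counts over profile sizes 43/22/39/41/5).
_THERAPY_COUNTS: dict[str, tuple[int, ...]] = {
    "antidiabetic": (4, 3, 1, 1, 0),
    "antihyperlipidemic": (6, 8, 10, 6, 0),
    "antihypertensive": (8, 7, 10, 8, 0),
}

_PROFILE_SIZES = (43, 22, 39, 41, 5)

_CORRELATION_TARGETS = [
    ("scd163", "stnfri", 0.291),
    ("tpa", "stnfri", 0.230),
    ("scd163", "crp", 0.295),
    ("tpa", "crp", 0.344),
]


def _default_marker_defs() -> list[MarkerDef]:
    defs = [
        MarkerDef(name, scale, mean, sd, transform)
        for name, scale, mean, sd, transform in _NAMED_MARKERS
    ]
    n_aux = N_MARKERS - len(defs)
    defs.extend(
        MarkerDef(f"aux_{i:02d}", "concentration", 100.0, 20.0, "identity")
        for i in range(1, n_aux + 1)
    )
    return defs


def _effect_matrix(marker_defs: Sequence[MarkerDef]) -> np.ndarray:
    names = [m.name for m in marker_defs]
    eff = np.zeros((N_PROFILES, len(names)))
    for marker, shift in _PROFILE2_EFFECTS.items():
        eff[1, names.index(marker)] = shift
    for profile, shifts in _OTHER_PROFILE_EFFECTS.items():
        for marker, shift in shifts.items():
            eff[profile - 1, names.index(marker)] = shift
    for profile, pattern in PROFILE_EFFECT_PATTERNS.items():
        for marker, sign in pattern.items():
            if marker.startswith("aux_"):
                eff[profile - 1, names.index(marker)] = sign * _AUX_EFFECT
    return eff


def default_config(seed: int = 0) -> SyntheticConfig:
    """The study-calibrated configuration: 150 subjects, profile sizes
    43/22/39/41/5, the 43-marker panel with Profile-1..5 signatures, the
    printed per-profile metabolic summaries and therapy prevalences, and the
    four soluble-marker Spearman targets (0.291, 0.230, 0.295, 0.344)."""
    marker_defs = _default_marker_defs()
    outcome_defs = {
        name: OutcomeDef(name, means, sds, dist, unit)  # type: ignore[arg-type]
        for name, (means, sds, dist, unit) in _OUTCOME_TABLE.items()
    }
    therapy_rates = {
        t: tuple(c / n for c, n in zip(counts, _PROFILE_SIZES))
        for t, counts in _THERAPY_COUNTS.items()
    }
    cfg = SyntheticConfig(
        n_subjects=150,
        marker_defs=marker_defs,
        effect_matrix=_effect_matrix(marker_defs),
        correlation_targets=list(_CORRELATION_TARGETS),
        outcome_defs=outcome_defs,
        therapy_rates=therapy_rates,
        activation_markers=("scd163", "stnfri", "tpa", "iga", "crp"),
        activation_outcomes=("insulinemia",),
        activation_loading=0.3,
        seed=seed,
    )
    cfg.validate()
    return cfg


def null_config(seed: int = 0) -> SyntheticConfig:
    """Same panel and cohort layout, but no profile effects anywhere: all
    outcome means/SDs pooled, identical therapy rates, zero marker shifts.
    Used for type-I-error calibration."""
    cfg = default_config(seed=seed)
    pooled = {
        "insulinemia": (10.2, 6.3),
        "glycemia": (5.58, 1.17),
        "triglycerides": (1.19, 0.68),
        "hdl": (0.59, 0.16),
        "ldl": (1.42, 0.38),
        "cholesterol": (2.24, 0.45),
        "waist": (88.8, 13.3),
        "hip": (100.5, 8.6),
        "systolic": (138.0, 17.0),
        "diastolic": (83.0, 10.0),
        "gamma_gt": (43.0, 48.0),
        "alcohol": (7.9, 20.9),
    }
    cfg.outcome_defs = {
        name: replace(od, means=(pooled[name][0],) * 5, sds=(pooled[name][1],) * 5)
        for name, od in cfg.outcome_defs.items()
    }
    overall = {
        t: sum(c) / sum(_PROFILE_SIZES) for t, c in _THERAPY_COUNTS.items()
    }
    cfg.therapy_rates = {t: (overall[t],) * 5 for t in cfg.therapy_rates}
    cfg.effect_matrix = np.zeros_like(np.asarray(cfg.effect_matrix))
    cfg.correlation_targets = []
    cfg.activation_markers = ()
    cfg.activation_outcomes = ()
    cfg.validate()
    return cfg


def profile_recovery_config(effect_size: float, seed: int = 0) -> SyntheticConfig:
    """Default panel with every profile-signature marker shifted by a single
    uniform ``effect_size`` (in latent-SD units, signed by the signature).
    Used to study cluster recovery as a function of separation."""
    cfg = default_config(seed=seed)
    names = cfg.marker_names
    eff = np.zeros((N_PROFILES, len(names)))
    for profile, pattern in PROFILE_EFFECT_PATTERNS.items():
        for marker, sign in pattern.items():
            eff[profile - 1, names.index(marker)] = sign * effect_size
    cfg.effect_matrix = eff
    cfg.validate()
    return cfg


def planted_signature_config(
    effect_size: float = 1.5,
    signature_markers: tuple[str, ...] = ("pct_cd57_cd4", "iga", "scd163"),
    seed: int = 0,
) -> SyntheticConfig:
    """Default cohort layout with exactly the given markers elevated in
    Profile 2 (by ``effect_size`` latent SDs) and no other marker effects:
    the ground truth for signature-recovery experiments."""
    cfg = default_config(seed=seed)
    names = cfg.marker_names
    eff = np.zeros((N_PROFILES, len(names)))
    for marker in signature_markers:
        eff[1, names.index(marker)] = effect_size
    cfg.effect_matrix = eff
    cfg.correlation_targets = []
    cfg.activation_markers = ()
    cfg.activation_outcomes = ()
    cfg.validate()
    return cfg


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------


def _mixture_spearman(r: float, dx: np.ndarray, dy: np.ndarray, w: np.ndarray) -> float:
    """Population Spearman of (X, Y) where, conditional on a profile k
    drawn with weight w_k, (X, Y) is bivariate normal with means
    (dx_k, dy_k), unit variances and correlation r.

    rho_S = 12 P(X1 < X2, Y1 < Y3) - 3 with (X1, Y1) a joint draw and
    X2, Y3 independent marginal draws; each (k, l, m) component term is a
    bivariate-normal orthant probability with correlation r/2.
    """
    from scipy.stats import multivariate_normal

    k_idx, l_idx, m_idx = np.meshgrid(*[np.arange(len(w))] * 3, indexing="ij")
    pts = np.column_stack(
        [
            (dx[l_idx] - dx[k_idx]).ravel() / math.sqrt(2.0),
            (dy[m_idx] - dy[k_idx]).ravel() / math.sqrt(2.0),
        ]
    )
    bvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, r / 2.0], [r / 2.0, 1.0]])
    probs = bvn.cdf(pts).reshape(k_idx.shape)
    weights = w[k_idx] * w[l_idx] * w[m_idx]
    return 12.0 * float((weights * probs).sum()) - 3.0


def _solve_latent_r(target: float, dx: np.ndarray, dy: np.ndarray, w: np.ndarray) -> float:
    """Latent correlation whose profile-shift mixture attains the target
    cohort-level Spearman. With no shifts this reduces to the normal-copula
    closed form 2*sin(pi*rho_S/6)."""
    from scipy.optimize import brentq

    if np.ptp(dx) == 0 and np.ptp(dy) == 0:
        return 2.0 * math.sin(math.pi * target / 6.0)
    lo, hi = -0.999, 0.999
    f = lambda r: _mixture_spearman(r, dx, dy, w) - target
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(
            f"infeasible correlation targets: Spearman {target} unattainable "
            "given the configured profile shifts"
        )
    return float(brentq(f, lo, hi, xtol=1e-6))


def _latent_correlation(config: SyntheticConfig) -> np.ndarray:
    p = len(config.marker_defs)
    names = config.marker_names
    eff = np.asarray(config.effect_matrix, dtype=float)
    w = np.asarray(config.profile_proportions, dtype=float)
    corr = np.eye(p)
    for a, b, rho in config.correlation_targets:
        i, j = names.index(a), names.index(b)
        r = _solve_latent_r(rho, eff[:, i], eff[:, j], w)
        corr[i, j] = corr[j, i] = r
    return corr


def _fixed_counts(props: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n subjects to the 5 profiles."""
    raw = props * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _back_transform(mdef: MarkerDef, z: np.ndarray) -> np.ndarray:
    m, s = mdef.baseline_mean, mdef.baseline_sd
    if mdef.transform == "identity":
        x = m + s * z
        if mdef.scale == "percent":
            x = np.clip(x, 0.0, 100.0)
        return x
    if mdef.transform == "log":
        mu, sigma = _lognormal_params(m, s)
        return np.exp(mu + sigma * z)
    # logit: delta-method slope so the native-scale SD matches near baseline
    p0 = m / 100.0
    slope = s / (100.0 * p0 * (1.0 - p0))
    x = 100.0 * expit(logit(p0) + slope * z)
    return np.clip(x, 0.1, 99.9)


def generate_cohort(config: SyntheticConfig, seed: int | None = None) -> Cohort:
    """Draw one cohort. Deterministic given ``(config, seed)``.

    Stage streams (labels, markers, outcomes, therapy) are spawned from a
    single SeedSequence in a fixed order, so adding e.g. an outcome never
    perturbs the marker draw.

    Raises ``ValueError`` if the implied latent correlation matrix is not
    positive definite ("infeasible correlation targets").
    """
    config.validate()
    if seed is None:
        seed = config.seed
    n = config.n_subjects
    names = config.marker_names
    p = len(names)

    ss = np.random.SeedSequence(seed)
    rng_labels, rng_markers, rng_out, rng_ther = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    subject_ids = pd.Index([f"S{i + 1:04d}" for i in range(n)], name="subject_id")

    corr = _latent_correlation(config)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("infeasible correlation targets: latent correlation "
                         "matrix is not positive definite") from exc

    props = np.asarray(config.profile_proportions, dtype=float)
    if config.draw_counts == "fixed":
        counts = _fixed_counts(props, n)
    else:
        counts = rng_labels.multinomial(n, props)
    labels = np.repeat(np.arange(1, N_PROFILES + 1), counts)
    labels = labels[rng_labels.permutation(n)] if n else labels

    # markers: correlated latents, centred activation score, profile shifts
    z = rng_markers.standard_normal((n, p)) @ chol.T
    eff = np.asarray(config.effect_matrix, dtype=float)
    if config.activation_markers:
        idx = [names.index(m) for m in config.activation_markers]
        w = np.full(len(idx), 1.0 / len(idx))
        var = float(w @ corr[np.ix_(idx, idx)] @ w)
        activation = (z[:, idx] @ w) / math.sqrt(var) if n else np.zeros(0)
    else:
        activation = np.zeros(n)
    z_shifted = z + eff[labels - 1] if n else z
    markers = pd.DataFrame(
        {md.name: _back_transform(md, z_shifted[:, j]) for j, md in enumerate(config.marker_defs)},
        index=subject_ids,
    )

    # metabolic outcomes, conditional on profile (plus activation coupling)
    b = config.activation_loading
    metabolic = {}
    for col in METABOLIC_COLUMNS:
        od = config.outcome_defs.get(col)
        if od is None:
            continue
        e = rng_out.standard_normal(n)
        if col in config.activation_outcomes and b > 0:
            u = b * activation + math.sqrt(1.0 - b * b) * e
        else:
            u = e
        means = np.asarray(od.means)[labels - 1] if n else np.zeros(0)
        sds = np.asarray(od.sds)[labels - 1] if n else np.zeros(0)
        if od.distribution == "lognormal":
            with np.errstate(divide="ignore", invalid="ignore"):
                sigma2 = np.log1p((sds / means) ** 2)
                mu = np.log(means) - sigma2 / 2.0
            vals = np.exp(mu + np.sqrt(sigma2) * u)
        else:
            vals = means + sds * u
            if col in ("waist", "hip"):
                vals = np.maximum(vals, 1.0)
        metabolic[col] = vals
    metabolic_df = pd.DataFrame(metabolic, index=subject_ids)

    therapy = pd.DataFrame(
        {
            t: rng_ther.random(n) < np.asarray(rates)[labels - 1]
            if n
            else np.zeros(0, dtype=bool)
            for t, rates in config.therapy_rates.items()
        },
        index=subject_ids,
    )

    true_profile = pd.Series(labels, index=subject_ids, name="true_profile")
    return Cohort(markers, metabolic_df, therapy, true_profile)
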