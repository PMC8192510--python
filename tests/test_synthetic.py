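"""Generator: determinism, marginal/copula fidelity, planted structure."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

import immunosig as im
from immunosig.synthetic import _fixed_counts, _mixture_spearman, _solve_latent_r


def test_default_config_calibration():
    cfg = im.default_config()
    assert cfg.n_subjects == 150
    assert np.allclose(cfg.profile_proportions, np.array([43, 22, 39, 41, 5]) / 150)
    ins = cfg.outcome_defs["insulinemia"]
    assert ins.means[1] == 13.3 and ins.sds[1] == 9.2
    assert ("scd163", "stnfri", 0.291) in cfg.correlation_targets
    names = cfg.marker_names
    assert len(names) == 43 and len(set(names)) == 43
    # Profile-2 signature elevations present in the effect matrix
    eff = np.asarray(cfg.effect_matrix)
    for marker in ("pct_em_cd4", "pct_exhausted_cd4", "pct_cd57_cd4",
                   "scd163", "tpa", "stnfri", "iga"):
        assert eff[1, names.index(marker)] > 0


def test_generation_is_deterministic():
    cfg = im.default_config()
    a = im.generate_cohort(cfg, seed=42)
    b = im.generate_cohort(cfg, seed=42)
    assert a.markers.equals(b.markers)
    assert a.metabolic.equals(b.metabolic)
    assert a.therapy.equals(b.therapy)
    assert a.true_profile.equals(b.true_profile)
    c = im.generate_cohort(cfg, seed=43)
    assert not a.markers.equals(c.markers)


def test_empty_cohort():
    cfg = im.default_config()
    cfg.n_subjects = 0
    c = im.generate_cohort(cfg, seed=1)
    assert c.n_subjects == 0
    assert c.markers.shape == (0, 43)
    assert c.metabolic.shape[0] == 0 and c.therapy.shape[0] == 0


def test_fixed_profile_counts_and_ranges(default_cohort):
    counts = default_cohort.true_profile.value_counts().sort_index()
    assert counts.tolist() == [43, 22, 39, 41, 5]
    pct = [m.name for m in im.default_config().marker_defs if m.scale == "percent"]
    assert ((default_cohort.markers[pct] >= 0) & (default_cohort.markers[pct] <= 100)).all().all()
    assert (default_cohort.metabolic[["waist", "hip"]] > 0).all().all()
    assert not default_cohort.markers.isna().any().any()


def test_zero_noise_limit_recovers_configured_means():
    cfg = im.default_config()
    cfg.marker_defs = [replace(m, baseline_sd=m.baseline_sd * 1e-8) for m in cfg.marker_defs]
    cfg.outcome_defs = {
        k: replace(v, sds=tuple(s * 1e-8 for s in v.sds)) for k, v in cfg.outcome_defs.items()
    }
    cfg.effect_matrix = np.zeros_like(np.asarray(cfg.effect_matrix, dtype=float))
    c = im.generate_cohort(cfg, seed=5)
    lab = c.true_profile.to_numpy()
    ref = im.default_config().outcome_defs
    for var in ("insulinemia", "glycemia", "gamma_gt"):
        for p in range(1, 6):
            got = c.metabolic[var].to_numpy()[lab == p].mean()
            assert got == pytest.approx(ref[var].means[p - 1], abs=1e-6)


def test_copula_recovers_spearman_targets_at_large_n():
    cfg = im.default_config()
    cfg.n_subjects = 10_000
    c = im.generate_cohort(cfg, seed=7)
    for a, b, rho in cfg.correlation_targets:
        got = stats.spearmanr(c.markers[a], c.markers[b]).statistic
        assert got == pytest.approx(rho, abs=0.05)


def test_mixture_spearman_reduces_to_copula_closed_form():
    # no shifts: rho_S(r) must equal the bivariate-normal value 6*asin(r/2)/pi
    w = np.array([43, 22, 39, 41, 5]) / 150
    zeros = np.zeros(5)
    for rho in (0.1, 0.3):
        r = _solve_latent_r(rho, zeros, zeros, w)
        assert r == pytest.approx(2 * np.sin(np.pi * rho / 6), abs=1e-9)
        assert _mixture_spearman(r, zeros, zeros, w) == pytest.approx(rho, abs=1e-6)


def test_infeasible_correlation_targets_rejected():
    cfg = im.default_config()
    # a correlation triangle that cannot be embedded in a PSD matrix
    cfg.correlation_targets = [
        ("aux_01", "aux_02", 0.95),
        ("aux_02", "aux_03", 0.95),
        ("aux_01", "aux_03", -0.95),
    ]
    with pytest.raises(ValueError, match="infeasible"):
        im.generate_cohort(cfg, seed=0)


def test_largest_remainder_apportionment():
    assert _fixed_counts(np.array([43, 22, 39, 41, 5]) / 150, 150).tolist() == [43, 22, 39, 41, 5]
    assert _fixed_counts(np.array([0.5, 0.3, 0.1, 0.05, 0.05]), 7).sum() == 7


def test_multinomial_draws_vary_counts():
    cfg = im.default_config()
    cfg.draw_counts = "multinomial"
    counts = [
        im.generate_cohort(cfg, seed=s).true_profile.value_counts().sort_index().tolist()
        for s in range(5)
    ]
    assert any(c != [43, 22, 39, 41, 5] for c in counts)
    assert all(sum(c) == 150 for c in counts)


def test_config_validation_errors():
    cfg = im.default_config()
    cfg.profile_proportions = (0.5, 0.5, 0.0, 0.0, 0.1)
    with pytest.raises(ValueError, match="sum to 1"):
        cfg.validate()
    cfg = im.default_config()
    cfg.therapy_rates = {**cfg.therapy_rates, "antidiabetic": (1.5, 0, 0, 0, 0)}
    with pytest.raises(ValueError, match="antidiabetic"):
        cfg.validate()


def test_planted_signature_config_only_plants_three_markers():
    cfg = im.planted_signature_config(1.5)
    eff = np.asarray(cfg.effect_matrix)
    assert np.count_nonzero(eff) == 3
    assert np.count_nonzero(eff[1]) == 3
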