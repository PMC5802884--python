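"""Group-level analysis: baselines, ratios, mixed models, correlations."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from flashkit.reference import (
    BASE_INTENSITY,
    BASE_RATE,
    BRIGHT_CORRELATION,
    DIM_CORRELATION,
    reference_effect_table,
)
from flashkit.stats import (
    DegenerateDesignError,
    _model_frame,
    dark_baseline,
    degree_of_change,
    effect_table,
    fit_wavelength_model,
    intensity_rate_correlation,
    order_effect_test,
)

WAVELENGTHS = (444, 463, 488, 515, 533, 597, 628, 663)


def make_records(
    rng,
    n_specimens=6,
    rate_effects=None,
    intensity_effects=None,
    specimen_sd=3.0,
    resid_rate_sd=4.0,
    resid_int_sd=400.0,
    order_slope=0.0,
):
    """Synthetic per-segment records with a known mixed structure."""
    rate_effects = rate_effects or {}
    intensity_effects = intensity_effects or {}
    rows = []
    for s in range(n_specimens):
        b = rng.normal(0.0, specimen_sd)
        rows.append(
            dict(
                specimen=f"s{s:02d}",
                segment_index=1,
                phase="dark",
                wavelength=None,
                level=None,
                light_order=None,
                mean_peak_intensity=BASE_INTENSITY + 100 * b + rng.normal(0, resid_int_sd),
                flash_rate=BASE_RATE + b + rng.normal(0, resid_rate_sd),
            )
        )
        cells = [(w, lvl) for w in WAVELENGTHS for lvl in ("dim", "bright")]
        order = rng.permutation(len(cells)) + 1
        for i, (w, lvl) in enumerate(cells):
            rows.append(
                dict(
                    specimen=f"s{s:02d}",
                    segment_index=2 + 2 * i,
                    phase="light",
                    wavelength=w,
                    level=lvl,
                    light_order=float(order[i]),
                    mean_peak_intensity=BASE_INTENSITY
                    + intensity_effects.get((w, lvl), 0.0)
                    + 100 * b
                    + rng.normal(0, resid_int_sd),
                    flash_rate=BASE_RATE
                    + rate_effects.get((w, lvl), 0.0)
                    + b
                    + order_slope * order[i]
                    + rng.normal(0, resid_rate_sd),
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- baseline


def test_dark_baseline_of_identical_specimens():
    rng = np.random.default_rng(1)
    rec = make_records(rng, specimen_sd=0, resid_rate_sd=0, resid_int_sd=0)
    base_i, base_r = dark_baseline(rec)
    assert base_i == pytest.approx(BASE_INTENSITY)
    assert base_r == pytest.approx(BASE_RATE)


def test_dark_baseline_averages_first_dark_rates():
    rng = np.random.default_rng(2)
    rec = make_records(rng, n_specimens=6, specimen_sd=0, resid_rate_sd=0)
    rec.loc[rec.segment_index == 1, "flash_rate"] = [40, 44, 46, 42, 44, 43]
    assert dark_baseline(rec)[1] == pytest.approx(43.167, abs=5e-4)


def test_dark_baseline_single_specimen_uses_its_own_values():
    rng = np.random.default_rng(3)
    rec = make_records(rng, n_specimens=1)
    first = rec[rec.segment_index == 1].iloc[0]
    base_i, base_r = dark_baseline(rec)
    assert base_i == first.mean_peak_intensity
    assert base_r == first.flash_rate


def test_missing_initial_dark_is_an_error():
    rng = np.random.default_rng(4)
    rec = make_records(rng)
    rec = rec[~((rec.specimen == "s00") & (rec.phase == "dark"))]
    with pytest.raises(ValueError, match="dark"):
        dark_baseline(rec)


# ---------------------------------------------------------------- ratios


@pytest.mark.parametrize(
    "mean, base, expected",
    [(22.67, 43.167, 0.525), (5639.0, 5420.0, 1.040), (7.0, 7.0, 1.000)],
)
def test_degree_of_change_quotients(mean, base, expected):
    assert degree_of_change(mean, base) == pytest.approx(expected, abs=5e-4)


def test_degree_of_change_requires_positive_base():
    with pytest.raises(ValueError):
        degree_of_change(10.0, 0.0)


# ---------------------------------------------------------------- models


def test_constant_response_gives_zero_wavelength_coefficients():
    rng = np.random.default_rng(5)
    rec = make_records(rng, specimen_sd=0, resid_rate_sd=0, resid_int_sd=0)
    fit = fit_wavelength_model(rec, "rate", "dim")
    assert all(abs(c) < 1e-8 for c in fit.coefficients.values())


def test_single_specimen_design_is_degenerate():
    rng = np.random.default_rng(6)
    rec = make_records(rng, n_specimens=1)
    with pytest.raises(DegenerateDesignError):
        fit_wavelength_model(rec, "rate", "dim")


def test_all_missing_wavelength_flagged_unestimable():
    rng = np.random.default_rng(7)
    rec = make_records(rng)
    mask = (rec.wavelength == 488) & (rec.level == "bright")
    rec.loc[mask, "mean_peak_intensity"] = np.nan
    fit = fit_wavelength_model(rec, "intensity", "bright")
    assert 488 in fit.unestimable
    assert np.isnan(fit.p_values[488])
    assert not np.isnan(fit.p_values[444])


def test_known_rate_reduction_recovered_with_correct_sign():
    """A built-in 488 nm dim rate deficit is recovered as a negative
    coefficient in nearly every replicate."""
    neg = 0
    n_rep = 40
    for r in range(n_rep):
        rng = np.random.default_rng(100 + r)
        rec = make_records(rng, rate_effects={(488, "dim"): -25.0})
        fit = fit_wavelength_model(rec, "rate", "dim")
        neg += fit.coefficients[488] < 0 and fit.p_values[488] < 0.05
    assert neg >= 0.95 * n_rep


def test_mixed_model_matches_lme4_oracle(tmp_path):
    """Cross-check the crossed-intercept Gaussian fit against lme4."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript unavailable")
    rng = np.random.default_rng(8)
    rec = make_records(rng, n_specimens=5)
    fit = fit_wavelength_model(rec, "intensity", "dim")
    frame = _model_frame(rec, "intensity", "dim")
    csv = tmp_path / "frame.csv"
    frame.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        'suppressMessages(library(lme4))\n'
        f'd <- read.csv("{csv}")\n'
        'd$wavelength_c <- relevel(factor(d$wavelength_c), ref="dark")\n'
        'm <- lmer(y ~ wavelength_c + (1|specimen), data=d, REML=TRUE)\n'
        'cat(jsonlite::toJSON(as.list(fixef(m)), auto_unbox=TRUE))\n'
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    fe = json.loads(out.stdout)
    for wl, coef in fit.coefficients.items():
        assert coef == pytest.approx(fe[f"wavelength_c{wl}"], rel=1e-3, abs=1e-6)


def test_poisson_family_recovers_sign():
    rng = np.random.default_rng(9)
    rec = make_records(rng, rate_effects={(488, "dim"): -25.0})
    fit = fit_wavelength_model(rec, "rate", "dim", family="poisson")
    assert fit.coefficients[488] < 0


# ---------------------------------------------------------------- order test


def test_identical_likelihoods_give_zero_chi_square():
    rng = np.random.default_rng(10)
    rec = make_records(rng, specimen_sd=0, resid_rate_sd=0, resid_int_sd=0)
    chi2, p = order_effect_test(rec, "rate", "dim")
    assert chi2 == 0.0
    assert p == 1.0


def test_order_decay_detected_with_high_power():
    """A per-exposure rate decline yields a significant LRT in most
    replicates."""
    hits = 0
    n_rep = 30
    for r in range(n_rep):
        rng = np.random.default_rng(300 + r)
        rec = make_records(rng, order_slope=-1.0)
        chi2, p = order_effect_test(rec, "rate", "dim")
        hits += (chi2 > 0) and (p < 0.05)
    assert hits >= 0.8 * n_rep


def test_order_test_null_p_values_are_uniform():
    """Under a null order effect the LRT p-values follow U(0,1)."""
    ps = []
    for r in range(150):
        rng = np.random.default_rng(700 + r)
        rec = make_records(rng, n_specimens=5)
        ps.append(order_effect_test(rec, "rate", "dim")[1])
    stat, p = scipy.stats.kstest(ps, "uniform")
    assert p > 0.01, (stat, p)


def test_order_intercept_mode_runs():
    rng = np.random.default_rng(11)
    rec = make_records(rng, order_slope=-1.5)
    chi2, p = order_effect_test(rec, "rate", "dim", mode="intercept")
    assert chi2 >= 0.0 and 0.0 <= p <= 1.0


# ---------------------------------------------------------------- correlation


def test_published_dim_correlation_reproduced():
    table = reference_effect_table()
    assert intensity_rate_correlation(table, "dim") == pytest.approx(
        DIM_CORRELATION, abs=1e-3
    )


def test_published_bright_correlation_reproduced():
    table = reference_effect_table()
    assert intensity_rate_correlation(table, "bright") == pytest.approx(
        BRIGHT_CORRELATION, abs=1e-3
    )


def test_perfect_linear_tradeoff_gives_minus_one():
    x = np.array([1.0, 2.0, 3.5, 4.0, 6.0])
    table = pd.DataFrame(
        {
            "level": "dim",
            "wavelength": [444, 463, 488, 515, 533],
            "mean_intensity": x,
            "mean_rate": 10.0 - 2.0 * x,
        }
    )
    assert intensity_rate_correlation(table, "dim") == pytest.approx(-1.0)


def test_correlation_needs_three_wavelengths():
    table = reference_effect_table().iloc[:2]
    with pytest.raises(ValueError, match="3 wavelengths"):
        intensity_rate_correlation(table, "dim")


def test_correlation_scale_invariance():
    """Identical on raw means and degree-of-change ratios."""
    table = reference_effect_table()
    scaled = table.copy()
    scaled["mean_intensity"] = scaled["doc_intensity"]
    scaled["mean_rate"] = scaled["doc_rate"]
    for level in ("dim", "bright"):
        assert intensity_rate_correlation(scaled, level) == pytest.approx(
            intensity_rate_correlation(table, level), abs=2e-3
        )


# ---------------------------------------------------------------- effect table


def test_effect_table_shape_and_missing_propagation():
    rng = np.random.default_rng(12)
    rec = make_records(rng)
    mask = (rec.wavelength == 463) & (rec.level == "bright")
    rec.loc[mask, "mean_peak_intensity"] = np.nan
    rec.loc[mask, "flash_rate"] = 0.0
    table = effect_table(rec, fit_models=False)
    assert len(table) == 16
    cell = table[(table.wavelength == 463) & (table.level == "bright")].iloc[0]
    assert np.isnan(cell.mean_intensity)
    assert np.isnan(cell.doc_intensity)
    assert cell.mean_rate == 0.0
    # dim block precedes bright, matching the published layout
    assert list(table.level[:8]) == ["dim"] * 8
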