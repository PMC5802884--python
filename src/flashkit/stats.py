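"""Group-level analysis of flash morphology under ambient light.

Mirrors the study's analysis stage: light-exposure responses are
compared against the *initial* dark recordings (those taken before any
light exposure), wavelength enters a mixed model as a categorical fixed
effect with specimen — and, for flash-rate models, exposure order — as
random intercepts, the exposure-order effect is assessed by a
likelihood-ratio comparison, and the trade-off between brightening and
slowing is summarized as a Pearson correlation across wavelengths.

Records are plain pandas DataFrames with one row per analyzed segment,
columns: ``specimen, segment_index, phase, wavelength, level,
light_order, mean_peak_intensity, flash_rate`` (intensity may be NaN
where a specimen ceased flashing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "DegenerateDesignError",
    "WavelengthModelResult",
    "dark_baseline",
    "degree_of_change",
    "fit_wavelength_model",
    "order_effect_test",
    "intensity_rate_correlation",
    "effect_table",
]

Response = Literal["intensity", "rate"]

_RESPONSE_COLUMN = {"intensity": "mean_peak_intensity", "rate": "flash_rate"}


class DegenerateDesignError(ValueError):
    """The records cannot support the requested mixed-model design."""


def _initial_dark(records: pd.DataFrame) -> pd.DataFrame:
    """One row per specimen: the dark segment preceding all light exposures."""
    rows = []
    for specimen, grp in records.groupby("specimen", sort=True):
        dark = grp[grp["phase"] == "dark"]
        light = grp[grp["phase"] == "light"]
        if dark.empty:
            raise ValueError(f"{specimen}: no dark recording")
        first_dark = dark.loc[dark["segment_index"].idxmin()]
        if not light.empty and first_dark["segment_index"] > light["segment_index"].min():
            raise ValueError(
                f"{specimen}: no dark recording precedes the first light exposure"
            )
        rows.append(first_dark)
    return pd.DataFrame(rows)


def dark_baseline(records: pd.DataFrame) -> tuple[float, float]:
    """Dark base values: (mean peak intensity, mean flash rate).

    Per-specimen values from the initial dark recording (before any
    light exposure), averaged across specimens.
    """
    first = _initial_dark(records)
    intensities = first["mean_peak_intensity"].astype(float)
    if intensities.isna().all():
        raise ValueError("no initial-dark recording contains any flash")
    return float(intensities.mean()), float(first["flash_rate"].astype(float).mean())


def degree_of_change(group_mean: float, base_value: float) -> float:
    """Ratio of an exposure group mean to the dark base value."""
    if base_value is None or not np.isfinite(base_value) or base_value <= 0:
        raise ValueError("base value must be positive")
    return float(group_mean) / float(base_value)


@dataclass
class WavelengthModelResult:
    """A fitted wavelength mixed model and its per-wavelength tests."""

    response: str
    level: str
    family: str
    result: object  # statsmodels results instance
    coefficients: dict[int, float]
    p_values: dict[int, float]
    unestimable: tuple[int, ...]

    def summary(self) -> str:  # pragma: no cover - convenience passthrough
        return str(self.result.summary())


def _model_frame(
    records: pd.DataFrame, response: Response, level: str
) -> pd.DataFrame:
    col = _RESPONSE_COLUMN[response]
    light = records[(records["phase"] == "light") & (records["level"] == level)].copy()
    dark = _initial_dark(records).copy()
    dark["y"] = dark[col].astype(float)
    dark["wavelength_c"] = "dark"
    # one order level per baseline recording: the six initial darks are
    # independent recordings, not a shared exposure event, so they must
    # not receive a common order intercept (which would load the entire
    # order variance onto the dark reference mean)
    dark["order_c"] = "baseline_" + dark["specimen"].astype(str)
    dark["order_num"] = 0.0
    light["y"] = light[col].astype(float)
    light["wavelength_c"] = light["wavelength"].astype(int).astype(str)
    light["order_c"] = light["light_order"].astype(float).astype(int).astype(str)
    light["order_num"] = light["light_order"].astype(float)
    cols = ["specimen", "wavelength_c", "order_c", "order_num", "y"]
    frame = pd.concat([dark[cols], light[cols]], ignore_index=True)
    frame = frame.dropna(subset=["y"]).reset_index(drop=True)
    if frame.empty:
        raise DegenerateDesignError("no usable observations")
    if frame["specimen"].nunique() < 2:
        raise DegenerateDesignError(
            "mixed model needs records from at least two specimens"
        )
    return frame


def _fit_mixed(formula: str, frame: pd.DataFrame, vc: dict[str, str], reml: bool):
    # quasi-Newton optimizers occasionally report convergence at a poor
    # optimum on these small crossed designs; fit with two starts and
    # keep the higher likelihood
    frame = frame.copy()
    frame["_all"] = 1
    model = smf.mixedlm(formula, frame, groups="_all", re_formula="0", vc_formula=vc)
    candidates = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for method in (["powell"], ["lbfgs", "bfgs"]):
            try:
                res = model.fit(reml=reml, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if np.isfinite(res.llf):
                candidates.append((bool(np.isfinite(res.bse_fe).all()), res))
    if not candidates:
        raise DegenerateDesignError("mixed model failed to fit")
    finite = [res for ok, res in candidates if ok]
    pool = finite or [res for _, res in candidates]
    return max(pool, key=lambda res: res.llf)


def _wald_t_pvalues(result, df: float) -> pd.Series:
    """Two-sided p-values from a t reference with residual df.

    MixedLM reports normal-reference Wald tests; with a handful of
    specimens a t reference (df = observations - fixed parameters) is
    the safer small-sample choice.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tvals = result.fe_params / result.bse_fe
    return pd.Series(
        2.0 * scipy.stats.t.sf(np.abs(tvals), df=max(df, 1.0)), index=tvals.index
    )


def fit_wavelength_model(
    records: pd.DataFrame,
    response: Response = "rate",
    level: str = "dim",
    family: str = "gaussian",
    reml: bool = True,
) -> WavelengthModelResult:
    """Fit the per-level wavelength model for one response.

    Gaussian linear mixed model of the response on wavelength
    (categorical, initial dark as the reference level) with a specimen
    random intercept; flash-rate models additionally carry an
    exposure-order (1-16, "baseline" for initial dark) random intercept,
    which showed no effect on intensity and is dropped there.  The two
    exposure levels are always analyzed separately.  ``family="poisson"``
    instead fits a population-averaged Poisson GEE with exchangeable
    correlation within specimen, for rate treated as a count response.

    Returns per-wavelength contrasts against dark with t-reference Wald
    p-values; wavelengths with no usable observations (all specimens
    ceased) are flagged unestimable.
    """
    frame = _model_frame(records, response, level)
    wavelengths = sorted(
        int(w)
        for w in records.loc[records["phase"] == "light", "wavelength"].dropna().unique()
    )
    present = set(frame.loc[frame["wavelength_c"] != "dark", "wavelength_c"])
    unestimable = tuple(w for w in wavelengths if str(w) not in present)

    formula = "y ~ C(wavelength_c, Treatment('dark'))"
    if family == "gaussian":
        vc = {"specimen": "0 + C(specimen)"}
        if response == "rate":
            vc["order"] = "0 + C(order_c)"
        result = _fit_mixed(formula, frame, vc, reml=reml)
        params = result.fe_params
        pvals = _wald_t_pvalues(result, df=len(frame) - len(params))
    elif family == "poisson":
        import statsmodels.api as sm

        frame = frame.copy()
        frame["y"] = np.round(frame["y"]).astype(int)
        model = smf.gee(
            formula,
            groups="specimen",
            data=frame,
            family=sm.families.Poisson(),
            cov_struct=sm.cov_struct.Exchangeable(),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit()
        params = result.params
        pvals = pd.Series(result.pvalues, index=params.index)
    else:
        raise ValueError(f"unknown family {family!r}")

    coefficients: dict[int, float] = {}
    p_values: dict[int, float] = {}
    for wl in wavelengths:
        name = f"C(wavelength_c, Treatment('dark'))[T.{wl}]"
        if wl in unestimable or name not in params.index:
            coefficients[wl] = float("nan")
            p_values[wl] = float("nan")
        else:
            coefficients[wl] = float(params[name])
            p_values[wl] = float(pvals[name])
    return WavelengthModelResult(
        response=response,
        level=level,
        family=family,
        result=result,
        coefficients=coefficients,
        p_values=p_values,
        unestimable=unestimable,
    )


def order_effect_test(
    records: pd.DataFrame,
    response: Response = "rate",
    level: str = "dim",
    mode: Literal["slope", "intercept"] = "slope",
) -> tuple[float, float]:
    """Likelihood-ratio test for an exposure-order effect.

    Compares the light-exposure wavelength model with and without an
    exposure-order term by maximum likelihood (one extra parameter).
    ``mode="slope"`` (default) models order 1-16 as a numeric trend —
    the estimator matching a cumulative effect of previous exposures;
    ``mode="intercept"`` instead adds an order random intercept.
    Returns ``(chi_square, p)``; identical likelihoods give (0, 1).
    """
    frame = _model_frame(records, response, level)
    frame = frame[frame["wavelength_c"] != "dark"].reset_index(drop=True)
    if frame["specimen"].nunique() < 2:
        raise DegenerateDesignError("order test needs at least two specimens")
    # structural zero: a response fully determined by wavelength leaves the
    # order term literally nothing to explain (and a singular likelihood)
    if (frame.groupby("wavelength_c")["y"].nunique() <= 1).all():
        return 0.0, 1.0
    base_vc = {"specimen": "0 + C(specimen)"}
    reduced = _fit_mixed("y ~ C(wavelength_c)", frame, base_vc, reml=False)
    if mode == "slope":
        full = _fit_mixed("y ~ C(wavelength_c) + order_num", frame, base_vc, reml=False)
    elif mode == "intercept":
        vc = dict(base_vc, order="0 + C(order_c)")
        full = _fit_mixed("y ~ C(wavelength_c)", frame, vc, reml=False)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(scipy.stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return float(chi2), p


def intensity_rate_correlation(
    table: pd.DataFrame, level: str = "dim"
) -> float:
    """Pearson r between per-wavelength mean intensity and mean rate.

    Scale-invariant: identical whether computed on raw group means or on
    their degree-of-change ratios.  Requires at least three wavelengths
    with both means present.
    """
    rows = table[table["level"] == level].dropna(
        subset=["mean_intensity", "mean_rate"]
    )
    if len(rows) < 3:
        raise ValueError(
            f"need at least 3 wavelengths with both means, have {len(rows)}"
        )
    r, _ = scipy.stats.pearsonr(
        rows["mean_intensity"].astype(float), rows["mean_rate"].astype(float)
    )
    return float(r)


def effect_table(
    records: pd.DataFrame,
    fit_models: bool = True,
    family: str = "gaussian",
) -> pd.DataFrame:
    """Per-(wavelength, level) group summary with degree-of-change ratios.

    Group means and SDs are taken over specimens (intensity over
    specimens that flashed; a cell where every specimen ceased yields
    NaN intensity, never zero).  Ratios divide group means by the
    initial-dark base values.  With ``fit_models=True`` the mixed-model
    p-values per wavelength are attached.
    """
    base_intensity, base_rate = dark_baseline(records)
    light = records[records["phase"] == "light"]
    rows = []
    for (wl, level), grp in light.groupby(["wavelength", "level"], sort=True):
        intensities = grp["mean_peak_intensity"].astype(float).dropna()
        rates = grp["flash_rate"].astype(float)
        mean_int = float(intensities.mean()) if len(intensities) else float("nan")
        rows.append(
            {
                "wavelength": int(wl),
                "level": level,
                "mean_intensity": mean_int,
                "sd_intensity": float(intensities.std(ddof=1))
                if len(intensities) > 1
                else float("nan"),
                "doc_intensity": degree_of_change(mean_int, base_intensity)
                if np.isfinite(mean_int)
                else float("nan"),
                "mean_rate": float(rates.mean()),
                "sd_rate": float(rates.std(ddof=1)) if len(rates) > 1 else float("nan"),
                "doc_rate": degree_of_change(float(rates.mean()), base_rate),
                "n": int(len(grp)),
            }
        )
    table = pd.DataFrame(rows)
    if fit_models:
        for response in ("intensity", "rate"):
            col = f"p_{response}"
            table[col] = np.nan
            for level in table["level"].unique():
                try:
                    fit = fit_wavelength_model(
                        records, response=response, level=level, family=family
                    )
                except DegenerateDesignError:
                    continue
                for wl, p in fit.p_values.items():
                    mask = (table["wavelength"] == wl) & (table["level"] == level)
                    table.loc[mask, col] = p
    table = table.sort_values(["level", "wavelength"], ascending=[True, True])
    # dim block first, matching the published layout
    table["level"] = pd.Categorical(table["level"], categories=["dim", "bright"])
    return table.sort_values(["level", "wavelength"]).reset_index(drop=True)
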