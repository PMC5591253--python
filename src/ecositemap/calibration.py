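"""Per-ecoregion linear calibration of regimes on predicted soil properties.

Continuous soil moisture regime (SMR) maps are produced by regressing
field-assessed SMR (coded to class units) on model-predicted continuous
soil drainage; the soil nutrient regime (SNR) map uses the same linear
form on predicted clay content.  The published Acadian calibration is
SMR = 0.1997 + 0.9869*SD and the Maritime-Boreal one SMR = 0.2683 +
0.9500*SD, where SD is drainage in class units.  Calibrations are fitted
by ordinary least squares and applied elementwise without clamping —
values slightly outside the class range are a classification-time concern
(see :mod:`ecositemap.class_systems`).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from importlib import resources

import numpy as np
import yaml
from scipy import stats

from .class_systems import OrdinalClassSystem

__all__ = [
    "CalibrationError",
    "LinearCalibration",
    "fit_calibration",
    "predict_regime",
    "summarize_fit",
    "load_calibrations",
    "load_default_calibrations",
    "save_calibrations",
]


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class LinearCalibration:
    """OLS line converting a predicted soil property into a regime value.

    ``intercept`` and ``slope`` are in class units (per predictor unit);
    ``r_squared`` is the coefficient of determination of the fit and ``n``
    the number of plots behind it.
    """

    region: str
    response: str
    predictor: str
    intercept: float
    slope: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise CalibrationError(f"r_squared {self.r_squared} outside [0, 1]")
        if self.n < 3:
            raise CalibrationError(f"calibration needs n >= 3 plots, got {self.n}")

    def predict(self, x) -> np.ndarray:
        return predict_regime(self, x)

    def to_dict(self) -> dict:
        return asdict(self)


def fit_calibration(
    pairs,
    region: str,
    response: str,
    predictor: str,
) -> LinearCalibration:
    """Ordinary-least-squares fit of ``regime ~ predictor``.

    ``pairs`` is an iterable of ``(predictor value, regime value)``.
    Requires at least three pairs and non-degenerate predictor values.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise CalibrationError("pairs must be (predictor, regime) 2-tuples")
    if arr.shape[0] < 3:
        raise CalibrationError(f"need >= 3 pairs, got {arr.shape[0]}")
    if np.isnan(arr).any():
        raise CalibrationError("pairs contain NaN; drop missing plots before fitting")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0.0:
        raise CalibrationError("degenerate predictor: all values equal")
    if np.ptp(y) == 0.0:
        # constant response: flat line, perfect fit
        slope, intercept, r2 = 0.0, float(y[0]), 1.0
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        resid = y - (intercept + slope * x)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot
        r2 = min(max(r2, 0.0), 1.0)
    return LinearCalibration(
        region=region,
        response=response,
        predictor=predictor,
        intercept=intercept,
        slope=slope,
        r_squared=r2,
        n=int(arr.shape[0]),
    )


def predict_regime(cal: LinearCalibration, predictor_values) -> np.ndarray:
    """Elementwise ``intercept + slope * x``; NaN inputs propagate to NaN."""
    x = np.asarray(predictor_values, dtype=float)
    return cal.intercept + cal.slope * x


@dataclass(frozen=True)
class FitReport:
    r_squared: float
    residual_sd: float
    per_class_mean_residual: dict[str, float]


def summarize_fit(
    cal: LinearCalibration,
    pairs,
    system: OrdinalClassSystem | None = None,
) -> FitReport:
    """Residual diagnostics of a calibration on its fitting pairs.

    When ``system`` is given, mean residuals are reported per full class
    of the predictor values (binned with the system's full-mode rule).
    """
    arr = np.asarray(list(pairs), dtype=float)
    x, y = arr[:, 0], arr[:, 1]
    resid = y - predict_regime(cal, x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else min(max(1.0 - ss_res / ss_tot, 0.0), 1.0)
    dof = max(len(x) - 2, 1)
    per_class: dict[str, float] = {}
    if system is not None:
        labels = [system.value_to_class(v, mode="full") for v in x]
        for lab in system.classes:
            sel = [r for r, l in zip(resid, labels) if l == lab]
            if sel:
                per_class[lab] = float(np.mean(sel))
    return FitReport(
        r_squared=r2,
        residual_sd=float(np.sqrt(ss_res / dof)),
        per_class_mean_residual=per_class,
    )


# -- serialization -------------------------------------------------------


def load_calibrations(source) -> dict[tuple[str, str], LinearCalibration]:
    """Load calibrations keyed by ``(region, response)`` from YAML."""
    if hasattr(source, "read"):
        raw = yaml.safe_load(source)
    else:
        text = str(source)
        if "\n" not in text and text.endswith((".yaml", ".yml", ".json")):
            with open(text, "r", encoding="utf-8") as fh:
                raw = yaml.safe_load(fh)
        else:
            raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "calibrations" not in raw:
        raise CalibrationError("calibration config must contain a 'calibrations' list")
    out = {}
    for entry in raw["calibrations"]:
        cal = LinearCalibration(
            region=str(entry["region"]),
            response=str(entry["response"]),
            predictor=str(entry["predictor"]),
            intercept=float(entry["intercept"]),
            slope=float(entry["slope"]),
            r_squared=float(entry["r_squared"]),
            n=int(entry["n"]),
        )
        out[(cal.region, cal.response)] = cal
    return out


def load_default_calibrations() -> dict[tuple[str, str], LinearCalibration]:
    """The published per-ecoregion SMR ~ drainage calibrations."""
    text = resources.files("ecositemap.data").joinpath("calibrations.yaml").read_text()
    return load_calibrations(text)


def save_calibrations(cals, path) -> None:
    entries = [c.to_dict() for c in (cals.values() if isinstance(cals, dict) else cals)]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"calibrations": entries}, fh, sort_keys=False)
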