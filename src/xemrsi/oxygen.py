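"""Oxygenation models linking RBC spectral parameters to paO2 and sO2.

Four model families:

* simple linear regression (SLR) of RBC chemical shift (ppm) or linewidth
  (Hz) on arterial paO2 (mmHg), invertible to voxel-wise paO2 maps;
* multiple linear regression (MLR) of paO2 on shift, linewidth and their
  interaction;
* exponential / logarithmic shift-versus-oxygenation models,
  delta(sO2) = alpha*exp(beta*sO2) + delta0 and cs = a*ln(paO2) + b;
* a Hill-type oxygen-hemoglobin dissociation curve (ODC) utility,
  sO2 = paO2^n / (paO2^n + P50^n), with species-specific parameters.

Inversion always uses the model's own unrounded fitted coefficients:
coefficients printed to one or two significant figures are kept only as
rounding-validation constants and are numerically useless for prediction
(a 1-s.f. interaction coefficient moves predictions by thousands of mmHg).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import optimize, stats

__all__ = [
    "LinearShiftModel",
    "MLRModel",
    "OxShiftExpModel",
    "LogShiftModel",
    "ODCModel",
    "HUMAN_ODC",
    "PORCINE_ODC",
    "HUMAN_EXP_MODEL",
    "fit_slr",
    "fit_mlr",
    "fit_log_model",
    "fit_exp_model",
    "eval_exp_model",
    "predict_pao2",
    "odc",
]


@dataclass
class LinearShiftModel:
    """y = slope * paO2 + intercept, with y an RBC spectral parameter."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    y_name: str = "rbc_cs_ppm"

    def predict_y(self, pao2):
        return self.slope * np.asarray(pao2, dtype=float) + self.intercept

    def invert(self, y):
        """paO2 = (y - intercept) / slope."""
        if self.slope == 0:
            raise ZeroDivisionError("cannot invert a zero-slope calibration")
        return (np.asarray(y, dtype=float) - self.intercept) / self.slope

    def to_dict(self) -> dict:
        return {"kind": "slr", **asdict(self)}


@dataclass
class MLRModel:
    """paO2 = b_cs*cs + b_lw*lw + b_int*cs*lw + intercept."""

    b_cs: float
    b_lw: float
    b_interaction: float
    intercept: float
    p_values: dict
    r_squared: float
    n: int

    def predict(self, cs, lw):
        cs = np.asarray(cs, dtype=float)
        lw = np.asarray(lw, dtype=float)
        return (
            self.b_cs * cs
            + self.b_lw * lw
            + self.b_interaction * cs * lw
            + self.intercept
        )

    def to_dict(self) -> dict:
        return {"kind": "mlr", **asdict(self)}


@dataclass
class LogShiftModel:
    """cs = a * ln(paO2) + b."""

    a: float
    b: float
    r_squared: float
    n: int

    def predict_y(self, pao2):
        pao2 = np.asarray(pao2, dtype=float)
        return self.a * np.log(pao2) + self.b

    def to_dict(self) -> dict:
        return {"kind": "log", **asdict(self)}


@dataclass
class OxShiftExpModel:
    """delta(sO2) = alpha * exp(beta * sO2) + delta0 (ppm)."""

    alpha: float
    beta: float
    delta0: float
    direction: str = "increasing"  # human-increasing vs porcine-decreasing

    def __call__(self, so2):
        so2 = np.asarray(so2, dtype=float)
        if np.any((so2 < 0) | (so2 > 1.1)):
            raise ValueError("sO2 outside the model domain [0, 1.1]")
        return self.alpha * np.exp(self.beta * so2) + self.delta0

    def to_dict(self) -> dict:
        return {"kind": "exp", **asdict(self)}


@dataclass
class ODCModel:
    """Hill-type oxygen-hemoglobin dissociation curve."""

    species: str
    p50_mmhg: float
    hill_n: float
    citation: str = ""

    def __post_init__(self) -> None:
        if self.p50_mmhg <= 0 or self.hill_n <= 0:
            raise ValueError("P50 and Hill coefficient must be positive")


# Literature Hill parameterizations (the defaults used throughout).
HUMAN_ODC = ODCModel(
    "human", 26.8, 2.7,
    citation="Severinghaus JW. J Appl Physiol 46:599-602, 1979 (Hill approximation)",
)
PORCINE_ODC = ODCModel(
    "porcine", 34.0, 2.8,
    citation="Serianni R et al. J Appl Physiol 94:561-566, 2003 (porcine ODC)",
)

# Human whole-blood RBC-membrane shift separation vs sO2 (increasing).
HUMAN_EXP_MODEL = OxShiftExpModel(alpha=9.3e-4, beta=8.62, delta0=20.4)


def _check_xy(x, y, min_n):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} points")
    return x, y


def fit_slr(pao2, y, y_name: str = "rbc_cs_ppm") -> LinearShiftModel:
    """Ordinary least squares of an RBC spectral parameter on paO2."""
    x, y = _check_xy(pao2, y, 3)
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("constant predictor: rank-deficient design")
    res = stats.linregress(x, y)
    return LinearShiftModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
        y_name=y_name,
    )


def fit_mlr(cs, lw, pao2) -> MLRModel:
    """paO2 on [cs, lw, cs*lw] with intercept, via statsmodels OLS."""
    import statsmodels.api as sm

    cs = np.asarray(cs, dtype=float)
    lw = np.asarray(lw, dtype=float)
    pao2 = np.asarray(pao2, dtype=float)
    if not (cs.shape == lw.shape == pao2.shape) or cs.ndim != 1:
        raise ValueError("cs, lw, pao2 must be 1D arrays of equal length")
    if len(cs) < 5:
        raise ValueError("need at least 5 points for the interaction model")
    X = np.column_stack([cs, lw, cs * lw])
    names = ["rbc_cs", "rbc_lw", "rbc_cs_x_lw"]
    rank = np.linalg.matrix_rank(np.column_stack([np.ones_like(cs), X]))
    if rank < 4:
        # identify which column is redundant for the error message
        bad = []
        base = np.ones((len(cs), 1))
        for j, name in enumerate(names):
            cand = np.column_stack([base, X[:, : j + 1]])
            if np.linalg.matrix_rank(cand) == np.linalg.matrix_rank(base):
                bad.append(name)
            base = cand
        raise np.linalg.LinAlgError(
            f"rank-deficient design; collinear columns: {bad or names}"
        )
    model = sm.OLS(pao2, sm.add_constant(X)).fit()
    const, b_cs, b_lw, b_int = model.params
    p = model.pvalues
    return MLRModel(
        b_cs=float(b_cs),
        b_lw=float(b_lw),
        b_interaction=float(b_int),
        intercept=float(const),
        p_values={
            "intercept": float(p[0]),
            "rbc_cs": float(p[1]),
            "rbc_lw": float(p[2]),
            "rbc_cs_x_lw": float(p[3]),
        },
        r_squared=float(model.rsquared),
        n=len(cs),
    )


def fit_log_model(pao2, cs) -> LogShiftModel:
    """cs = a * ln(paO2) + b by least squares in the log predictor."""
    x, y = _check_xy(pao2, cs, 3)
    if np.any(x <= 0):
        raise ValueError("paO2 must be positive for the logarithmic model")
    res = stats.linregress(np.log(x), y)
    return LogShiftModel(
        a=float(res.slope), b=float(res.intercept),
        r_squared=float(res.rvalue**2), n=len(x),
    )


def fit_exp_model(so2, delta_ppm, direction: str = "increasing") -> OxShiftExpModel:
    """Fit delta = alpha*exp(beta*sO2) + delta0 by nonlinear least squares."""
    so2 = np.asarray(so2, dtype=float)
    delta = np.asarray(delta_ppm, dtype=float)

    def model(s, alpha, beta, delta0):
        return alpha * np.exp(beta * s) + delta0

    sign = 1.0 if direction == "increasing" else -1.0
    p0 = (sign * 1e-3, 8.0, float(np.median(delta)))
    popt, _ = optimize.curve_fit(model, so2, delta, p0=p0, maxfev=20000)
    return OxShiftExpModel(*map(float, popt), direction=direction)


def eval_exp_model(so2, model: OxShiftExpModel | None = None):
    """Evaluate the exponential shift model (human defaults if none given)."""
    return (model or HUMAN_EXP_MODEL)(so2)


def predict_pao2(maps, model, mode: str | None = None, mask=None):
    """Voxel-wise paO2 map (mmHg) from quantitative maps and a fitted model.

    ``maps`` is a :class:`xemrsi.maps.QuantMaps` or a dict holding
    ``cs_rbc`` (and ``lw_rbc`` for MLR).  SLR mode inverts the calibration
    cs = slope*paO2 + intercept; MLR mode evaluates the regression of
    paO2 on (cs, lw, cs*lw).  Outside-mask voxels are NaN.
    """
    get = maps.get if isinstance(maps, dict) else (lambda k: getattr(maps, k))
    cs = np.asarray(get("cs_rbc"), dtype=float)
    if mask is None:
        mask = ~np.isnan(cs) if isinstance(maps, dict) else maps.mask
    mode = mode or ("slr" if isinstance(model, LinearShiftModel) else "mlr")
    out = np.full(cs.shape, np.nan)
    if mode == "slr":
        if not isinstance(model, LinearShiftModel):
            raise TypeError("SLR mode requires a LinearShiftModel")
        out[mask] = model.invert(cs[mask])
    elif mode == "mlr":
        if not isinstance(model, MLRModel):
            raise TypeError("MLR mode requires an MLRModel")
        lw = np.asarray(get("lw_rbc"), dtype=float)
        out[mask] = model.predict(cs[mask], lw[mask])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def odc(pao2, model: ODCModel = PORCINE_ODC):
    """Hill ODC: sO2 = paO2^n / (paO2^n + P50^n), in [0, 1)."""
    pao2 = np.asarray(pao2, dtype=float)
    if np.any(pao2 < 0):
        raise ValueError("paO2 must be non-negative")
    ratio = (pao2 / model.p50_mmhg) ** model.hill_n
    return ratio / (1.0 + ratio)


def save_model(model, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def load_model(path: str | Path):
    d = json.loads(Path(path).read_text())
    kind = d.pop("kind")
    cls = {"slr": LinearShiftModel, "mlr": MLRModel,
           "log": LogShiftModel, "exp": OxShiftExpModel}[kind]
    return cls(**d)
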