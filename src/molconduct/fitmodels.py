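"""Boiling-point model forms, goodness of fit, and least-squares fitting.

Five model forms relate conduction ``c`` (or order ``n``) to the boiling
point ``b`` in degrees Celsius:

``linear``
    b = alpha * c + beta
``series_loglinear``
    b = alpha * c + beta + alpha1 * log_{alpha2}(alpha3 * c + alpha4)
``log_trig``
    b = alpha * c + beta
        + alpha1 * log_{alpha2}(alpha3 * c + alpha4) * sin(alpha5 * c + alpha6)
``e_series``
    the series_loglinear form applied to the fitted E-series conduction
    approximation (an alias at evaluation time)
``quad_conduction``
    c(E_n) = alpha * n^2 + beta * n + gamma + lambda / n  (linear in the
    constants, solved in closed form)

In ``alpha1 * log_{alpha2}(u)`` only the ratio ``k = alpha1 / ln(alpha2)`` is
identifiable, so the fitter works internally with ``k * ln(alpha3*c +
alpha4)``; the six-constant (alpha1, alpha2) spelling appears only in the
published parameter sets echoed from the packaged JSON config.  Sine
arguments are radians.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DomainError",
    "ModelForm",
    "FORMS",
    "ParameterSet",
    "FitResult",
    "paper_parameters",
    "r_squared",
    "evaluate",
    "fit",
    "quad_conduction_fit",
]

_PENALTY = 1e8  # finite objective outside the log domain keeps the search connected


class DomainError(ValueError):
    """A model was evaluated outside its domain (log argument or base)."""


@dataclass(frozen=True)
class ModelForm:
    form_id: str
    arity: int
    names: tuple


FORMS: dict[str, ModelForm] = {
    "linear": ModelForm("linear", 2, ("alpha", "beta")),
    "series_loglinear": ModelForm(
        "series_loglinear", 6, ("alpha", "beta", "alpha1", "alpha2", "alpha3", "alpha4")
    ),
    "e_series": ModelForm(
        "e_series", 6, ("alpha", "beta", "alpha1", "alpha2", "alpha3", "alpha4")
    ),
    "log_trig": ModelForm(
        "log_trig",
        8,
        ("alpha", "beta", "alpha1", "alpha2", "alpha3", "alpha4", "alpha5", "alpha6"),
    ),
    "quad_conduction": ModelForm("quad_conduction", 4, ("alpha", "beta", "gamma", "lambda")),
    # internal reparameterisations produced by the fitter
    "series_loglinear_k": ModelForm(
        "series_loglinear_k", 5, ("alpha", "beta", "k", "alpha3", "alpha4")
    ),
    "log_trig_k": ModelForm(
        "log_trig_k", 7, ("alpha", "beta", "k", "alpha3", "alpha4", "alpha5", "alpha6")
    ),
}


@dataclass(frozen=True)
class ParameterSet:
    """Named constants of one model form.

    ``provenance`` is ``"paper-printed"`` for the packaged published sets
    (treated as immutable reference values) or ``"fitted"`` for estimates.
    """

    form_id: str
    constants: tuple
    provenance: str = "fitted"
    source_label: str = ""

    def __post_init__(self):
        form = FORMS[self.form_id]
        if len(self.constants) != form.arity:
            raise ValueError(
                f"{self.form_id} needs {form.arity} constants, got {len(self.constants)}"
            )

    @property
    def names(self) -> tuple:
        return FORMS[self.form_id].names

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.constants))

    def __getitem__(self, name: str) -> float:
        return self.as_dict()[name]


@dataclass(frozen=True)
class FitResult:
    params: ParameterSet
    rss: float
    tss: float
    r_squared: float
    converged: bool
    iterations: int
    n_points: int = 0
    interpolating: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "form": self.params.form_id,
                "constants": self.params.as_dict(),
                "rss": self.rss,
                "tss": self.tss,
                "r_squared": self.r_squared,
                "converged": self.converged,
                "iterations": self.iterations,
                "n_points": self.n_points,
            },
            indent=1,
        )


def paper_parameters() -> dict[str, ParameterSet]:
    """The published constant tuples, keyed by equation label."""
    raw = json.loads(
        resources.files("molconduct.data").joinpath("constants.json").read_text()
    )
    out = {}
    for key, spec in raw.items():
        out[key] = ParameterSet(
            form_id=spec["form"],
            constants=tuple(spec["constants"]),
            provenance="paper-printed",
            source_label=spec.get("source_label", key),
        )
    return out


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination R^2 = 1 - RSS/TSS.

    1 is a perfect fit; 0 means the model does no better than the mean.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-D sequences")
    if obs.size < 2:
        raise ValueError("need at least two observations")
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss == 0:
        raise ValueError("zero total sum of squares: observations are all identical")
    rss = float(np.sum((obs - pred) ** 2))
    return 1.0 - rss / tss


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _log_term(k_or_a1, base, a3, a4, c, six_constant: bool):
    u = a3 * c + a4
    if np.any(np.asarray(u) <= 0):
        raise DomainError(f"log argument alpha3*c + alpha4 = {u} must be positive")
    if six_constant:
        if base <= 0 or base == 1:
            raise DomainError(f"log base alpha2 = {base} must be positive and != 1")
        return k_or_a1 * np.log(u) / math.log(base)
    return k_or_a1 * np.log(u)


def evaluate(params: ParameterSet, c):
    """Evaluate a model at conduction value(s) ``c`` (or order ``n`` for the
    quad_conduction form).  Returns a float for scalar input."""
    c_arr = np.asarray(c, dtype=float)
    p = params.constants
    fid = params.form_id
    if fid == "linear":
        val = p[0] * c_arr + p[1]
    elif fid in ("series_loglinear", "e_series"):
        a, b, a1, a2, a3, a4 = p
        val = a * c_arr + b + _log_term(a1, a2, a3, a4, c_arr, True)
    elif fid == "series_loglinear_k":
        a, b, k, a3, a4 = p
        val = a * c_arr + b + _log_term(k, None, a3, a4, c_arr, False)
    elif fid == "log_trig":
        a, b, a1, a2, a3, a4, a5, a6 = p
        val = a * c_arr + b + _log_term(a1, a2, a3, a4, c_arr, True) * np.sin(a5 * c_arr + a6)
    elif fid == "log_trig_k":
        a, b, k, a3, a4, a5, a6 = p
        val = a * c_arr + b + _log_term(k, None, a3, a4, c_arr, False) * np.sin(a5 * c_arr + a6)
    elif fid == "quad_conduction":
        a, b, g_, l = p
        val = a * c_arr**2 + b * c_arr + g_ + l / c_arr
    else:  # pragma: no cover
        raise ValueError(f"unknown form {fid}")
    return float(val) if np.isscalar(c) else val


def _to_internal(params: ParameterSet) -> tuple[str, tuple]:
    """Convert a published 6/8-constant set to the identifiable k-form."""
    p = params.constants
    if params.form_id in ("series_loglinear", "e_series"):
        a, b, a1, a2, a3, a4 = p
        return "series_loglinear_k", (a, b, a1 / math.log(a2), a3, a4)
    if params.form_id == "log_trig":
        a, b, a1, a2, a3, a4, a5, a6 = p
        return "log_trig_k", (a, b, a1 / math.log(a2), a3, a4, a5, a6)
    return params.form_id, p


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _penalised_model(form_id: str, p: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Model values with a large finite penalty outside the log domain."""
    if form_id == "linear":
        return p[0] * c + p[1]
    if form_id == "series_loglinear_k":
        a, b, k, a3, a4 = p
        u = a3 * c + a4
        bad = u <= 0
        safe = np.where(bad, 1.0, u)
        return np.where(bad, _PENALTY * (1 + np.abs(u)), a * c + b + k * np.log(safe))
    if form_id == "log_trig_k":
        a, b, k, a3, a4, a5, a6 = p
        u = a3 * c + a4
        bad = u <= 0
        safe = np.where(bad, 1.0, u)
        return np.where(
            bad, _PENALTY * (1 + np.abs(u)), a * c + b + k * np.log(safe) * np.sin(a5 * c + a6)
        )
    raise ValueError(f"cannot fit form {form_id}")  # pragma: no cover


def _default_starts(form_id: str, c: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Deterministic multi-start grid: a linear-fit backbone plus a small grid
    over the log coefficient and the log-argument slope; the offset is chosen
    to keep the argument positive over the data."""
    slope, intercept = np.polyfit(c, y, 1)
    cmin = float(np.min(c))
    starts = []
    for k0 in (5.0, 20.0, 60.0, 150.0, -20.0):
        for a3 in (0.01, 0.05, 0.2, 1.0, 10.0):
            a4 = 1.0 - a3 * cmin + 0.5
            base = [slope, intercept, k0, a3, a4]
            if form_id == "log_trig_k":
                base += [0.5, 0.0]
            starts.append(np.array(base))
    return starts


def fit(
    form_id: str,
    data: Sequence[tuple],
    init: ParameterSet | Sequence[float] | None = None,
    bounds: tuple | None = None,
) -> FitResult:
    """Least-squares fit of a model form to ``(c, bp)`` points.

    Deterministic: with ``init`` given, a single trust-region solve from that
    start; otherwise a fixed multi-start grid.  Non-convergence is reported
    through ``converged=False``, never as an exception.  Log-form fits are
    performed in the identifiable ``k = alpha1/ln(alpha2)`` parameterisation
    and reported under the ``*_k`` form id.
    """
    pts = [(float(a), float(b)) for a, b in data]
    c = np.array([a for a, _ in pts])
    y = np.array([b for _, b in pts])
    if form_id == "quad_conduction":
        return quad_conduction_fit(pts)

    if form_id == "linear":
        coef = np.polyfit(c, y, 1)
        pred = np.polyval(coef, c)
        tss = float(np.sum((y - y.mean()) ** 2))
        rss = float(np.sum((y - pred) ** 2))
        params = ParameterSet("linear", (float(coef[0]), float(coef[1])))
        r2 = 1.0 - rss / tss if tss > 0 else 1.0
        return FitResult(params, rss, tss, r2, True, 1, len(pts), len(pts) <= 2)

    if form_id in ("series_loglinear", "e_series", "series_loglinear_k"):
        internal = "series_loglinear_k"
    elif form_id in ("log_trig", "log_trig_k"):
        internal = "log_trig_k"
    else:
        raise ValueError(f"unknown form {form_id}")

    if init is not None:
        if isinstance(init, ParameterSet):
            _, p0 = _to_internal(init)
            starts = [np.array(p0, dtype=float)]
        else:
            starts = [np.array(init, dtype=float)]
    else:
        starts = _default_starts(internal, c, y)

    lsq_bounds = bounds if bounds is not None else (-np.inf, np.inf)
    best = None
    total_nfev = 0
    for p0 in starts:
        try:
            res = least_squares(
                lambda p: _penalised_model(internal, p, c) - y,
                p0,
                bounds=lsq_bounds,
                method="trf",
                max_nfev=20000,
            )
        except Exception:
            continue
        total_nfev += res.nfev
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        params = ParameterSet(internal, tuple(starts[0]))
        tss = float(np.sum((y - y.mean()) ** 2))
        return FitResult(params, math.inf, tss, -math.inf, False, total_nfev, len(pts))

    pred = _penalised_model(internal, best.x, c)
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(np.sum((y - pred) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    converged = bool(best.success) and not np.any(
        np.abs(pred) >= _PENALTY
    )
    params = ParameterSet(internal, tuple(float(v) for v in best.x))
    arity = FORMS[internal].arity
    return FitResult(params, rss, tss, r2, converged, total_nfev, len(pts), len(pts) <= arity)


def quad_conduction_fit(
    data: Sequence[tuple], fix_alpha: float | None = None
) -> FitResult:
    """Closed-form least squares of c(E_n) = alpha n^2 + beta n + gamma + lambda/n.

    Linear in the constants, so solved directly with ``numpy.linalg.lstsq``.
    ``fix_alpha`` constrains the quadratic coefficient (e.g. to 4/9) and fits
    the remaining three constants.
    """
    pts = [(float(a), float(b)) for a, b in data]
    if len(pts) < 4:
        raise ValueError("need at least 4 points")
    n = np.array([a for a, _ in pts])
    y = np.array([b for _, b in pts])
    if fix_alpha is None:
        design = np.column_stack([n**2, n, np.ones_like(n), 1.0 / n])
        target = y
    else:
        design = np.column_stack([n, np.ones_like(n), 1.0 / n])
        target = y - fix_alpha * n**2
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design (duplicate n values?)")
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    if fix_alpha is None:
        constants = tuple(float(v) for v in coef)
    else:
        constants = (float(fix_alpha),) + tuple(float(v) for v in coef)
    params = ParameterSet("quad_conduction", constants)
    pred = evaluate(params, n)
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(np.sum((y - pred) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    free = 4 if fix_alpha is None else 3
    return FitResult(params, rss, tss, r2, True, 1, len(pts), len(pts) <= free)
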