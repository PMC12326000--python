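"""Polymerization kinetics: exponential decay fits and the critical concentration.

The free-monomer signal during divalent-ion-induced polymerization decays
towards an asymptote; the asymptote, converted to concentration, is the
critical monomer concentration coexisting with polymer (to first
approximation the monomer-off K_D).  Single- and double-exponential
models are fitted and compared by reduced chi-square.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import InsufficientDataError, ValidationError
from .io_core import DecayCurve

MODEL_SINGLE = "single"
MODEL_DOUBLE = "double"

_MIN_POINTS = {MODEL_SINGLE: 6, MODEL_DOUBLE: 8}


@dataclass
class KineticsFit:
    model: str
    amplitudes: list[float]  # intensity units, sorted with rates
    rates: list[float]  # 1/time, descending
    asymptote: float  # intensity units
    reduced_chi2: float
    dof: int
    n_points: int
    converged: bool = True
    degenerate_rate: bool = False
    rate_stderrs: list[float] = field(default_factory=list)
    residual_rms: float = float("nan")


def _model_eval(t, amplitudes, rates, asymptote):
    out = np.full_like(t, asymptote, dtype=float)
    for a, k in zip(amplitudes, rates):
        out += a * np.exp(-k * t)
    return out


def fit_decay(
    curve: DecayCurve,
    model: str = MODEL_SINGLE,
    sigma: np.ndarray | None = None,
) -> KineticsFit:
    """Fit an exponential-plus-asymptote decay to a polymerization time course.

    Unequally sampled data (e.g. a fast acquisition block followed by a
    slow one) are handled natively.  ``sigma`` supplies per-point standard
    deviations for the chi-square; unit weights otherwise.  Rates of the
    double model are returned sorted descending.  Non-convergence is
    reported via ``converged=False``, not an exception.
    """
    if curve.kind != "kinetics":
        raise ValidationError(f"expected a kinetics curve, got kind={curve.kind!r}")
    t, i = curve.abscissa, curve.intensity
    if model not in _MIN_POINTS:
        raise ValidationError(f"unknown model {model!r}")
    if len(t) < _MIN_POINTS[model]:
        raise InsufficientDataError(
            f"{model} model needs >= {_MIN_POINTS[model]} points, got {len(t)}"
        )
    if np.any(np.diff(t) <= 0):
        raise ValidationError("time axis must be strictly increasing")
    w = np.ones_like(i) if sigma is None else 1.0 / np.asarray(sigma, dtype=float)

    scale = float(np.ptp(i))
    c0 = float(i.min())
    a0 = max(float(i[0]) - c0, 0.0)

    if scale <= 0 or a0 <= scale * 1e-12:
        # constant curve: amplitude 0, asymptote = the constant; rate meaningless
        n, p = len(t), 3 if model == MODEL_SINGLE else 5
        resid = i - i.mean()
        dof = n - p
        return KineticsFit(
            model=model,
            amplitudes=[0.0] * (1 if model == MODEL_SINGLE else 2),
            rates=[float("nan")] * (1 if model == MODEL_SINGLE else 2),
            asymptote=float(i.mean()),
            reduced_chi2=float(np.sum((w * resid) ** 2) / dof) if dof > 0 else 0.0,
            dof=dof,
            n_points=n,
            degenerate_rate=True,
        )

    # single-fit rate start: time at which the decaying part has halved
    span = i[0] - c0
    below = np.nonzero(i - c0 <= span / 2)[0]
    t_half = t[below[0]] if below.size and t[below[0]] > 0 else t[-1] / 2
    k0 = np.log(2.0) / t_half

    if model == MODEL_SINGLE:
        x0 = [a0, k0, c0]
        lb, ub = [0.0, 1e-12, 0.0], [np.inf, np.inf, np.inf]

        def residuals(theta):
            return w * (_model_eval(t, [theta[0]], [theta[1]], theta[2]) - i)

    else:
        # bracket the single rate by a log-spaced pair, amplitudes by a
        # linear solve at those fixed rates
        k1, k2 = 5 * k0, k0 / 5
        basis = np.column_stack(
            [np.exp(-k1 * t), np.exp(-k2 * t), np.ones_like(t)]
        )
        coef, *_ = np.linalg.lstsq(basis, i, rcond=None)
        a1, a2, c_lin = (max(float(v), 0.0) for v in coef)
        if a1 + a2 <= 0:
            a1 = a2 = a0 / 2
        x0 = [a1, k1, a2, k2, max(c_lin, 0.0)]
        lb = [0.0, 1e-12, 0.0, 1e-12, 0.0]
        ub = [np.inf] * 5

        def residuals(theta):
            return w * (
                _model_eval(t, [theta[0], theta[2]], [theta[1], theta[3]], theta[4]) - i
            )

    sol = least_squares(residuals, x0=x0, bounds=(lb, ub),
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if model == MODEL_SINGLE:
        amps, rates, asym = [sol.x[0]], [sol.x[1]], sol.x[2]
        rate_idx = [1]
    else:
        amps = [sol.x[0], sol.x[2]]
        rates = [sol.x[1], sol.x[3]]
        asym = sol.x[4]
        order = np.argsort(rates)[::-1]
        amps = [amps[j] for j in order]
        rates = [rates[j] for j in order]
        rate_idx = [[1, 3][j] for j in order]

    n = len(t)
    p = len(sol.x)
    dof = n - p
    chi2 = float(np.sum(sol.fun**2))
    stderrs = [float("nan")] * len(rates)
    if dof > 0:
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * chi2 / dof
            stderrs = [float(np.sqrt(max(cov[j, j], 0.0))) for j in rate_idx]
        except np.linalg.LinAlgError:
            pass
    return KineticsFit(
        model=model,
        amplitudes=[float(a) for a in amps],
        rates=[float(k) for k in rates],
        asymptote=float(asym),
        reduced_chi2=chi2 / dof if dof > 0 else float("nan"),
        dof=dof,
        n_points=n,
        converged=bool(sol.success),
        rate_stderrs=stderrs,
        residual_rms=float(np.sqrt(np.mean(sol.fun**2))),
    )


@dataclass
class ModelSelection:
    preferred: str
    chi2_ratio: float  # reduced chi2 of the lower / higher... see model_selection
    indistinguishable: bool


def model_selection(fit_single: KineticsFit, fit_double: KineticsFit) -> ModelSelection:
    """Prefer the model with lower reduced chi-square.

    ``chi2_ratio`` is reduced-chi2(double) / reduced-chi2(single); ratios
    within [0.9, 1.1] are flagged as indistinguishable.
    """
    if fit_single.n_points != fit_double.n_points:
        raise ValidationError("fits compare different data (point counts differ)")
    ratio = fit_double.reduced_chi2 / fit_single.reduced_chi2
    preferred = MODEL_DOUBLE if fit_double.reduced_chi2 < fit_single.reduced_chi2 else MODEL_SINGLE
    if fit_double.reduced_chi2 == fit_single.reduced_chi2:
        preferred = MODEL_SINGLE  # parsimony on a tie
    return ModelSelection(
        preferred=preferred,
        chi2_ratio=float(ratio),
        indistinguishable=bool(0.9 <= ratio <= 1.1),
    )


def critical_concentration(
    fit: KineticsFit,
    intensity_to_concentration: float,
) -> float:
    """Asymptote converted to uM monomer concentration.

    Approximates the K_D for monomer dissociation from polymer ends; the
    conversion factor is uM per intensity unit (1.0 when the curve is
    already in concentration units).
    """
    if not fit.converged:
        raise ValidationError(
            "refusing to convert a non-converged fit; inspect the fit diagnostics"
        )
    if intensity_to_concentration <= 0:
        raise ValidationError("intensity_to_concentration must be > 0")
    if fit.degenerate_rate:
        warnings.warn(
            "asymptote taken from a degenerate (constant-curve) fit", stacklevel=2
        )
    return fit.asymptote * intensity_to_concentration
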