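"""PFG-NMR diffusion: attenuation fits and hydrodynamic radii.

Signal intensity attenuates with gradient strength G as
``I = I0 * exp(-a D G^2)``.  The gradient calibration constant ``a`` is
unknown but identical for all species in one measurement, so only the
composite slope a*D is ever fitted; it cancels in the ratio used to
convert to a hydrodynamic radius against the internal DSS reference:
``Rh(analyte) = Rh(DSS) * D(DSS) / D(analyte)``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import ConfigurationError, InsufficientDataError, ValidationError
from .io_core import DecayCurve

#: Hydrodynamic radius of the DSS reference at 298 K, nm.
RH_DSS_NM = 0.346


@dataclass
class DiffusionFit:
    aD: float  # 1/(gradient unit)^2, composite exponent slope
    I0: float
    aD_stderr: float
    residual_rms: float
    calibration_tag: str = ""


@dataclass
class HydrodynamicResult:
    Rh: float  # nm
    Rh_reference: float  # nm
    D_ratio: float  # D(reference)/D(analyte)
    apparent_mass: float | None = None  # kg/mol
    reference_mass: float | None = None  # kg/mol
    reference_Rh_for_mass: float | None = None  # nm


def fit_attenuation(curve: DecayCurve) -> DiffusionFit:
    """Fit I = I0 exp(-aD G^2) to a diffusion decay.

    A weighted linear fit of ln I against G^2 supplies the start values,
    refined by a nonlinear fit on the exponential itself.  A flat curve
    (non-diffusing reference such as cross-linked polyacrylamide) yields
    aD = 0.
    """
    if curve.kind != "diffusion":
        raise ValidationError(f"expected a diffusion curve, got kind={curve.kind!r}")
    if len(curve) < 4:
        raise InsufficientDataError(f"need >= 4 points, got {len(curve)}")
    g2 = curve.abscissa**2
    i = curve.intensity
    if np.any(i <= 0):
        raise ValidationError("intensities must be > 0 for an attenuation fit")

    # ln-linear start: weights ~ I (error propagation for log-transformed data)
    w = i / i.max()
    coef = np.polyfit(g2, np.log(i), 1, w=w)
    slope0 = max(-coef[0], 0.0)
    i0_0 = float(np.exp(coef[1]))

    def residuals(theta):
        lo_i0, ad = theta
        return lo_i0 * np.exp(-ad * g2) - i

    sol = least_squares(
        residuals,
        x0=[i0_0, slope0],
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    i0, ad = sol.x
    if ad * g2.max() < 1e-9:  # no measurable decay over the gradient range
        ad = 0.0
    dof = len(i) - 2
    stderr = float("nan")
    if dof > 0:
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * (sol.fun @ sol.fun) / dof
            stderr = float(np.sqrt(max(cov[1, 1], 0.0)))
        except np.linalg.LinAlgError:
            pass
    return DiffusionFit(
        aD=float(ad),
        I0=float(i0),
        aD_stderr=stderr,
        residual_rms=float(np.sqrt(np.mean(sol.fun**2))),
        calibration_tag=curve.calibration_tag,
    )


def hydrodynamic_radius(
    fit_analyte: DiffusionFit,
    fit_reference: DiffusionFit,
    Rh_reference: float = RH_DSS_NM,
) -> HydrodynamicResult:
    """Stokes radius of the analyte relative to an internal reference.

    Both fits must come from the same gradient calibration (the unknown
    constant ``a`` cancels only then); curves carrying different
    calibration tags are rejected.
    """
    if (
        fit_analyte.calibration_tag
        and fit_reference.calibration_tag
        and fit_analyte.calibration_tag != fit_reference.calibration_tag
    ):
        raise ValidationError(
            "analyte and reference come from different gradient calibrations: "
            f"{fit_analyte.calibration_tag!r} vs {fit_reference.calibration_tag!r}"
        )
    if fit_analyte.aD <= 0:
        raise ValidationError(
            "analyte attenuation slope is zero: no measurable diffusion decay "
            "(gradient range too small or non-diffusing species)"
        )
    if fit_reference.aD <= 0:
        raise ValidationError("reference attenuation slope must be > 0")
    if Rh_reference <= 0:
        raise ValidationError("Rh_reference must be > 0")
    d_ratio = fit_reference.aD / fit_analyte.aD
    return HydrodynamicResult(
        Rh=Rh_reference * d_ratio,
        Rh_reference=Rh_reference,
        D_ratio=d_ratio,
    )


def apparent_mass(
    Rh: float,
    reference: tuple[float, float] | None,
) -> float:
    """Apparent molecular mass (kg/mol) by cubic scaling against a reference.

    ``reference`` is a (mass kg/mol, Rh nm) pair the user supplies, e.g.
    the sequence mass of a monomer with its ideal hydrodynamic radius.
    The result assumes compact, similarly shaped particles and is always
    labeled "apparent" in reports; there is no silent default reference.
    """
    if reference is None:
        raise ConfigurationError(
            "apparent_mass needs an explicit (mass, Rh) reference pair"
        )
    m_ref, rh_ref = reference
    if Rh <= 0 or m_ref <= 0 or rh_ref <= 0:
        raise ValidationError("Rh and reference values must be > 0")
    return m_ref * (Rh / rh_ref) ** 3
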