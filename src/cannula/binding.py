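"""Per-residue dissociation constants from ligand-depletion titrations.

The observed combined shift change of a residue during a titration with
total ligand concentration c_T follows the single-site depletion isotherm

    ddelta(c_T) = ddelta_N / (2 N M_T) *
                  (K_D + c_T + N M_T - sqrt((K_D + c_T + N M_T)^2 - 4 N M_T c_T))

with M_T the total protein concentration and N the (unknown) number of
ligands per site, fixed at 1 by convention; the fitted K_D values are
therefore apparent constants.
"""
from __future__ import annotations

import csv as _csv
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import InsufficientDataError, NoBindingError, ValidationError
from .io_core import ResidueId, TitrationSeries

AREA_BA1 = "BA1"
AREA_BA2 = "BA2"
AREA_UNASSIGNED = "unassigned"

_KD_BOUNDS = (1e-6, 1e6)  # mM
_PLATEAU_BOUNDS = (1e-6, 100.0)  # ppm


def isotherm(
    c_T: float | np.ndarray,
    K_D: float,
    M_T: float,
    N: float,
    delta_N_plateau: float,
) -> float | np.ndarray:
    """Ligand-depletion binding isotherm (shift change in ppm at total ligand c_T)."""
    if K_D <= 0 or M_T <= 0 or N <= 0 or delta_N_plateau <= 0:
        raise ValidationError("K_D, M_T, N and delta_N_plateau must all be > 0")
    c = np.asarray(c_T, dtype=float)
    if np.any(c < 0):
        raise ValidationError("c_T must be >= 0")
    s = K_D + c + N * M_T
    out = delta_N_plateau / (2 * N * M_T) * (s - np.sqrt(s * s - 4 * N * M_T * c))
    return float(out) if np.isscalar(c_T) else out


@dataclass
class BindingFitResult:
    residue: ResidueId
    K_D: float  # mM
    K_D_stderr: float  # mM
    delta_N_plateau: float  # ppm
    plateau_stderr: float  # ppm
    N_sites: int
    converged: bool
    residual_rms: float  # ppm
    ligand_name: str = ""


def fit_kd(series: TitrationSeries, N: int = 1) -> BindingFitResult:
    """Least-squares fit of (K_D, delta_N_plateau) to one titration series.

    Initialization: K_D at the total ligand concentration of half-maximal
    response, plateau at 1.1x the largest observed change.  A failed or
    bound-pinned optimization is returned with ``converged=False`` rather
    than raised, so batch fits over many residues keep going.
    """
    if N < 1:
        raise ValidationError("N must be a positive integer")
    c, d = series.c_t, series.delta
    if len(c) < 4:
        raise InsufficientDataError(
            f"{series.residue.label}: need >= 4 titration points, got {len(c)}"
        )
    dmax = d.max()
    if dmax <= 0:
        raise NoBindingError(f"{series.residue.label}: all shift changes are zero")
    m_t = series.protein_concentration

    half = np.argmin(np.abs(d - dmax / 2))
    k0 = max(float(c[half]), 1e-3)
    p0 = 1.1 * dmax

    def residuals(theta):
        kd, plateau = theta
        return isotherm(c, kd, m_t, N, plateau) - d

    sol = least_squares(
        residuals,
        x0=[k0, p0],
        bounds=([_KD_BOUNDS[0], _PLATEAU_BOUNDS[0]], [_KD_BOUNDS[1], _PLATEAU_BOUNDS[1]]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    kd, plateau = sol.x
    dof = len(c) - 2
    res_rms = float(np.sqrt(np.mean(sol.fun**2)))
    # linearized covariance at the optimum (the "+/-" of a standard fit report)
    stderr_kd = stderr_pl = float("nan")
    if dof > 0:
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * (sol.fun @ sol.fun) / dof
            stderr_kd, stderr_pl = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            pass
    at_bound = (
        kd <= _KD_BOUNDS[0] * 1.01
        or kd >= _KD_BOUNDS[1] * 0.99
        or plateau >= _PLATEAU_BOUNDS[1] * 0.99
    )
    return BindingFitResult(
        residue=series.residue,
        K_D=float(kd),
        K_D_stderr=float(stderr_kd),
        delta_N_plateau=float(plateau),
        plateau_stderr=float(stderr_pl),
        N_sites=N,
        converged=bool(sol.success and not at_bound),
        residual_rms=res_rms,
        ligand_name=series.ligand_name,
    )


@dataclass
class BindingAreaAssignment:
    residue: ResidueId
    area: str  # BA1 | BA2 | unassigned


def default_membership_table() -> dict[str, str]:
    """Residue-label -> area mapping shipped as editable package data."""
    out = {}
    with resources.files("cannula.data").joinpath("binding_areas.csv").open() as fh:
        for row in _csv.DictReader(fh):
            out[row["residue"].strip()] = row["area"].strip()
    return out


def load_membership_table(path: str | Path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for row in _csv.DictReader(fh):
            out[row["residue"].strip()] = row["area"].strip()
    return out


def assign_binding_areas(
    fits: Sequence[BindingFitResult],
    membership_table: Mapping[str, str] | None = None,
) -> list[BindingAreaAssignment]:
    """Attach binding-area labels; residues absent from the table are unassigned."""
    table = dict(membership_table) if membership_table is not None else default_membership_table()
    return [
        BindingAreaAssignment(
            residue=f.residue,
            area=table.get(f.residue.label, AREA_UNASSIGNED),
        )
        for f in fits
    ]


def area_summary(
    fits: Sequence[BindingFitResult],
    assignments: Sequence[BindingAreaAssignment],
) -> pd.DataFrame:
    """Per-(area, ligand) K_D statistics over converged fits.

    Areas with no converged fit are omitted with a warning.
    """
    area_of = {a.residue.position: a.area for a in assignments}
    rows = [
        {
            "area": area_of.get(f.residue.position, AREA_UNASSIGNED),
            "ligand": f.ligand_name,
            "K_D_mM": f.K_D,
        }
        for f in fits
        if f.converged
    ]
    dropped = {
        area_of.get(f.residue.position, AREA_UNASSIGNED)
        for f in fits
        if not f.converged
    } - {r["area"] for r in rows}
    for area in sorted(dropped):
        warnings.warn(f"area {area}: no converged fits, omitted from summary", stacklevel=2)
    if not rows:
        return pd.DataFrame(
            columns=["area", "ligand", "n", "mean", "median", "min", "max"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["area", "ligand"])["K_D_mM"]
        .agg(n="count", mean="mean", median="median", min="min", max="max")
        .reset_index()
    )
    return out
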