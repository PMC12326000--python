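"""Synthetic inputs for every pipeline stage.

Generators are pure functions of (scenario, seed): fixed seeds reproduce
output bit-for-bit.  Defaults encode the study conditions the analyses
were designed for — 0.17 mM protein titrated with CaCl2 doubling from
0.1 to 25.6 mM (MgCl2 to 51.2 mM), Gaussian shift noise of 0.002 ppm,
a 42 h polymerization time course sampled in two acquisition blocks
(100 points every 3.5 min, then 72 every 29.5 min) with 2% intensity
noise, and Gaussian-in-G^2 diffusion decays.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import binding
from .errors import ValidationError
from .io_core import (
    Atom,
    DecayCurve,
    PeakEntry,
    PeakList,
    ResidueId,
    SequenceRecord,
    StructureModel,
)

# ---------------------------------------------------------------------------
# reference sequence (synthetic stand-in)

#: SYNTHETIC 183-residue CanA-like sequence.  The true sequence is published
#: only as a figure; this stand-in places every residue whose identity and
#: position the accompanying analyses rely on (the mobile N-terminal segment
#: M1..A12, secondary-structure boundary residues, H28, all charged residues
#: of the ion-binding areas and the salt-bridge census, M166, C-terminal
#: G183) at its stated position, and fills the remaining positions so the
#: composition census (21 Asp+Glu, 12 Lys, 1 His, 0 Arg, 2 Met) and the
#: sequence mass (19.85 kg/mol) match the full-length recombinant protein.
CANA_SYNTHETIC_SEQUENCE = (
    "MTTQSPLNSFYATGTAQAVSEQIDQVAHLFSIEPKSSVYGTDDIQTWVVAIKDQANDTKLSSALSYAELS"
    "KLYFKTTPNLVGSTTETDPTLLASASELKPGLSNKTFSALIIQDKEDGVAWANDKATQASSSFWYYNDTD"
    "KISNYFVKIEVYTSVVKSSTEALESMNVDSLPISFSPVTLAVG"
)


def cana_like_sequence() -> SequenceRecord:
    """The synthetic full-length (M1..G183) CanA-like sequence record."""
    return SequenceRecord(name="CanA_synthetic", residues=CANA_SYNTHETIC_SEQUENCE)


# ---------------------------------------------------------------------------
# titrations

#: Apparent K_D (mM) of the truncated construct for Ca2+, per residue.
K1_CANA_CA_KD_MM = {
    "D57": 0.74, "E97": 0.74, "K99": 0.69, "D114": 0.58, "K115": 0.74,
    "E116": 0.73, "G183": 0.90, "D42": 24.0, "D140": 4.5, "E164": 7.0,
    "D169": 18.0,
}

#: Apparent K_D (mM) of the truncated construct for Mg2+, per residue.
K1_CANA_MG_KD_MM = {
    "D57": 3.3, "E97": 3.6, "K99": 4.0, "D114": 4.6, "K115": 3.7,
    "E116": 3.36, "G183": 5.0, "D42": 12.0, "D140": 9.3, "E164": 8.0,
    "D169": 11.1,
}

#: Default saturation shift changes (ppm).  Not printed anywhere; chosen once
#: at the scale of strong amide perturbations (high-affinity area residues
#: larger than low-affinity ones, the two strongest responders largest).
DEFAULT_PLATEAU_PPM = {
    "D57": 0.15, "E97": 0.15, "K99": 0.15, "D114": 0.15, "K115": 0.25,
    "E116": 0.30, "G183": 0.12, "D42": 0.08, "D140": 0.08, "E164": 0.08,
    "D169": 0.08,
}

#: Fraction of delta_comb carried by the 1H component when emitting peak lists.
DEFAULT_H_FRACTION = 0.6


def doubling_schedule(start: float, n_doublings: int) -> list[float]:
    """[0, start, 2*start, ...]: the doubling ladder used in the titrations."""
    return [0.0] + [start * 2**i for i in range(n_doublings + 1)]


@dataclass
class TitrationResidue:
    residue: ResidueId
    true_K_D: float  # mM
    true_delta_N: float  # ppm, saturation shift change
    h_fraction: float = DEFAULT_H_FRACTION


@dataclass
class TitrationScenario:
    residues: list[TitrationResidue]
    M_T: float = 0.17  # mM protein
    schedule: list[float] = field(
        default_factory=lambda: doubling_schedule(0.1, 8)  # 0 .. 25.6 mM
    )
    noise_sigma: float = 0.002  # ppm, per shift-component observation
    seed: int = 0
    ligand_name: str = "Ca2+"
    weight_N: float = 0.2

    def __post_init__(self):
        if self.schedule[0] != 0:
            raise ValidationError("titration schedule must start at 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")


def default_titration_scenario(ion: str = "Ca2+", seed: int = 0) -> TitrationScenario:
    """The default study-condition titration for the truncated construct."""
    if ion.lower().startswith("ca"):
        table, sched, name = K1_CANA_CA_KD_MM, doubling_schedule(0.1, 8), "Ca2+"
    elif ion.lower().startswith("mg"):
        table, sched, name = K1_CANA_MG_KD_MM, doubling_schedule(0.2, 8), "Mg2+"
    else:
        raise ValidationError(f"unknown ion {ion!r}")
    residues = [
        TitrationResidue(
            residue=ResidueId.from_label(lbl),
            true_K_D=kd,
            true_delta_N=DEFAULT_PLATEAU_PPM[lbl],
        )
        for lbl, kd in table.items()
    ]
    return TitrationScenario(residues=residues, schedule=sched,
                             seed=seed, ligand_name=name)


#: Deterministic base shifts: amide 1H near 8.2 ppm, 15N near 120 ppm.
def _base_shifts(rid: ResidueId) -> tuple[float, float]:
    return (8.2 + 0.3 * math.sin(rid.position), 118.0 + 8.0 * math.cos(rid.position))


def make_titration(
    scenario: TitrationScenario,
) -> tuple[list[PeakList], pd.DataFrame]:
    """Per-titration-point peak lists plus a truth table for recovery scoring.

    Shift changes follow the depletion isotherm exactly, split into 1H and
    15N components with the scenario's fixed ratio, plus independent
    Gaussian noise on each component.
    """
    rng = np.random.default_rng(scenario.seed)
    peaklists = []
    truth_rows = [
        {
            "residue": tr.residue.label,
            "true_K_D_mM": tr.true_K_D,
            "true_delta_N_ppm": tr.true_delta_N,
        }
        for tr in scenario.residues
    ]
    for c_t in scenario.schedule:
        entries = []
        for tr in scenario.residues:
            d = binding.isotherm(c_t, tr.true_K_D, scenario.M_T, 1, tr.true_delta_N)
            f = tr.h_fraction
            dh = f * d
            dn = math.sqrt(max(1 - f * f, 0.0)) * d / scenario.weight_N
            h0, n0 = _base_shifts(tr.residue)
            noise_h = rng.normal(0.0, scenario.noise_sigma) if scenario.noise_sigma else 0.0
            noise_n = (
                rng.normal(0.0, scenario.noise_sigma / scenario.weight_N)
                if scenario.noise_sigma
                else 0.0
            )
            entries.append(PeakEntry(tr.residue, h0 + dh + noise_h, n0 + dn + noise_n))
        peaklists.append(
            PeakList(
                condition_label=f"{scenario.ligand_name}_{c_t:g}mM",
                ligand_concentration=c_t,
                entries=entries,
            )
        )
    return peaklists, pd.DataFrame(truth_rows)


def titration_series_from_peaklists(
    peaklists: list[PeakList],
    protein_concentration: float,
    weight_N: float = 0.2,
    ligand_name: str = "",
) -> list:
    """Reduce a titration's peak lists to per-residue delta_comb series.

    The first list (c_T = 0) is the reference; series are clamped to the
    required (0, 0) first point.
    """
    from . import csp as _csp
    from .io_core import TitrationSeries

    ref = peaklists[0].by_position()
    series = []
    for pos in sorted(ref):
        pts = []
        ok = True
        for pl in peaklists:
            entry = pl.by_position().get(pos)
            if entry is None:
                ok = False
                break
            d = _csp.delta_comb(
                entry.delta_H - ref[pos].delta_H,
                entry.delta_N - ref[pos].delta_N,
                weight_N,
            )
            pts.append((pl.ligand_concentration, d))
        if not ok:
            continue
        pts[0] = (0.0, 0.0)
        series.append(
            TitrationSeries(
                residue=ref[pos].residue,
                points=pts,
                protein_concentration=protein_concentration,
                ligand_name=ligand_name,
            )
        )
    return series


# ---------------------------------------------------------------------------
# diffusion

def make_diffusion(
    aD_analyte: float,
    aD_reference: float,
    I0s: tuple[float, float] = (1.0, 1.0),
    gradients: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[DecayCurve, DecayCurve]:
    """(analyte, reference) Gaussian-in-G^2 decays with shared calibration.

    ``aD_analyte`` may be 0 to emulate the non-diffusing polyacrylamide
    control.  ``noise_sigma`` is absolute, in intensity units.
    """
    if aD_analyte < 0 or aD_reference < 0:
        raise ValidationError("attenuation slopes must be >= 0")
    g = np.linspace(0.0, 50.0, 11) if gradients is None else np.asarray(gradients, float)
    rng = np.random.default_rng(seed)
    curves = []
    for a_d, i0 in zip((aD_analyte, aD_reference), I0s):
        i = i0 * np.exp(-a_d * g**2)
        if noise_sigma:
            i = i + rng.normal(0.0, noise_sigma, size=g.shape)
        curves.append(
            DecayCurve(abscissa=g, intensity=i, kind="diffusion",
                       calibration_tag=f"sim-seed{seed}")
        )
    return curves[0], curves[1]


# ---------------------------------------------------------------------------
# kinetics

@dataclass
class KineticsScenario:
    """Forward model: biexponential decay plus offset, two sampling blocks.

    Time unit is hours; rates 1/h.  Intensities are in uM monomer
    equivalents (conversion factor 1).
    """

    amplitudes: tuple[float, float] = (580.512, 387.008)  # uM; 0.6/0.4 split
    rates: tuple[float, float] = (0.19, 0.03)  # 1/h, fast then slow
    asymptote: float = 2.48  # uM, the critical concentration
    blocks: tuple[tuple[int, float], ...] = ((100, 3.5 / 60), (72, 29.5 / 60))
    noise_sigma_fraction: float = 0.0  # of initial intensity
    seed: int = 0

    def __post_init__(self):
        if any(k <= 0 for k in self.rates):
            raise ValidationError("rates must be > 0")
        if any(a < 0 for a in self.amplitudes) or self.asymptote < 0:
            raise ValidationError("amplitudes and asymptote must be >= 0")


def default_kinetics_scenario(
    noise_sigma_fraction: float = 0.0, seed: int = 0
) -> KineticsScenario:
    """Study-condition polymerization decay: 0.97 mM protein decaying to the
    2.48 uM critical concentration with rate constants 0.19 and 0.03 (fast
    amplitude 60% of the decaying part), sampled 100 x 3.5 min + 72 x 29.5 min."""
    return KineticsScenario(noise_sigma_fraction=noise_sigma_fraction, seed=seed)


def block_time_axis(blocks) -> np.ndarray:
    """Concatenated time axis (h) of (n_points, dt) acquisition blocks."""
    t, now = [], 0.0
    for n, dt in blocks:
        for _ in range(n):
            t.append(now)
            now += dt
    return np.array(t)


def make_kinetics(scenario: KineticsScenario) -> tuple[DecayCurve, dict]:
    """A polymerization DecayCurve plus the generating truth parameters."""
    t = block_time_axis(scenario.blocks)
    i = np.full_like(t, scenario.asymptote)
    for a, k in zip(scenario.amplitudes, scenario.rates):
        i = i + a * np.exp(-k * t)
    if scenario.noise_sigma_fraction:
        rng = np.random.default_rng(scenario.seed)
        i = i + rng.normal(0.0, scenario.noise_sigma_fraction * i[0], size=t.shape)
    truth = {
        "amplitudes": list(scenario.amplitudes),
        "rates": list(scenario.rates),
        "asymptote": scenario.asymptote,
    }
    return DecayCurve(abscissa=t, intensity=i, kind="kinetics"), truth


# ---------------------------------------------------------------------------
# toy structures

@dataclass
class ToyResidue:
    position: int
    aa: str
    chain: str = "A"
    ca: tuple[float, float, float] | None = None  # nm; default on an extended chain
    extra_atoms: dict[str, tuple[float, float, float]] = field(default_factory=dict)


#: Backbone offsets (nm) around the CA of an idealized extended residue.
_BACKBONE_OFFSETS = {
    "N": (-0.12, 0.095, 0.0),
    "C": (0.12, 0.095, 0.0),
    "O": (0.135, 0.21, 0.0),
}
_CA_SPACING_NM = 0.38
_CHAIN_Y_SPACING_NM = 1.2
_MIN_ATOM_SEPARATION_NM = 0.08


def make_toy_structure(
    residues: list[ToyResidue], model_id: int = 1
) -> StructureModel:
    """A valid peptide structure from placement rules.

    Residues without an explicit CA are laid out on an extended chain
    (0.38 nm CA spacing along x, chains stacked along y); backbone N, C,
    O and a CB (except Gly) are placed at idealized offsets.  Side-chain
    atoms relevant to geometry analyses (NZ, OD1/OD2, OE1/OE2, ...) are
    given as explicit coordinates in ``extra_atoms``.  Clashing
    placements (any two atoms closer than 0.08 nm) are rejected.
    """
    atoms = []
    chain_index: dict[str, int] = {}
    for r in residues:
        chain_index.setdefault(r.chain, len(chain_index))
        if r.ca is None:
            ca = (
                r.position * _CA_SPACING_NM,
                chain_index[r.chain] * _CHAIN_Y_SPACING_NM,
                0.0,
            )
        else:
            ca = r.ca
        rid = ResidueId(r.position, r.aa)
        atoms.append(Atom(r.chain, rid, "CA", *ca, element="C"))
        for name, off in _BACKBONE_OFFSETS.items():
            atoms.append(
                Atom(r.chain, rid, name,
                     ca[0] + off[0], ca[1] + off[1], ca[2] + off[2],
                     element=name[0])
            )
        if r.aa != "G" and "CB" not in r.extra_atoms:
            atoms.append(Atom(r.chain, rid, "CB",
                              ca[0], ca[1] - 0.11, ca[2] + 0.1, element="C"))
        for name, pos in r.extra_atoms.items():
            atoms.append(Atom(r.chain, rid, name, *pos, element=name[0]))
    xyz = np.array([a.xyz for a in atoms])
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() < _MIN_ATOM_SEPARATION_NM:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise ValidationError(
            f"clashing placement: {atoms[i].name}/{atoms[i].residue.label} vs "
            f"{atoms[j].name}/{atoms[j].residue.label} at {d[i, j]:.3f} nm"
        )
    return StructureModel(model_id=model_id, atoms=atoms)


def make_salt_bridge_pair(
    distance_nm: float = 0.35, model_id: int = 1
) -> tuple[StructureModel, dict]:
    """A Lys/Asp pair with a known NZ-OD1 distance, plus the ground truth."""
    lys_ca = (0.0, 0.0, 0.0)
    nz = (0.0, 0.0, 0.45)
    od1 = (distance_nm, 0.0, 0.45)
    od2 = (distance_nm + 0.1, 0.0, 0.55)
    asp_ca = (distance_nm + 0.35, 0.0, 0.0)
    model = make_toy_structure(
        [
            ToyResidue(1, "K", ca=lys_ca, extra_atoms={"NZ": nz}),
            ToyResidue(3, "D", ca=asp_ca, extra_atoms={"OD1": od1, "OD2": od2}),
        ],
        model_id=model_id,
    )
    truth = {"pair": ("K1", "D3"), "min_NO_distance": distance_nm}
    return model, truth


def make_contact_dimer(
    contact_distance_nm: float = 0.3,
) -> tuple[StructureModel, dict]:
    """A two-chain dimer with exactly one inter-chain contact residue pair.

    Chain A residues 1-5 and chain B residues 1-5 sit on parallel extended
    chains 10 nm apart except residue 3 of each chain, whose CB atoms are
    brought within ``contact_distance_nm``.
    """
    far = 10.0
    res_a = [ToyResidue(i, "A", chain="A", ca=(i * 0.5, 0.0, 0.0)) for i in range(1, 6)]
    res_b = [ToyResidue(i, "A", chain="B", ca=(i * 0.5, far, 0.0)) for i in range(1, 6)]
    # pull the two contact side chains together halfway between the chains
    mid = far / 2
    res_a[2].extra_atoms["CB"] = (1.5, mid - contact_distance_nm / 2, 0.0)
    res_b[2].extra_atoms["CB"] = (1.5, mid + contact_distance_nm / 2, 0.0)
    model = make_toy_structure(res_a + res_b)
    truth = {"contact": ("A", 3, "B", 3), "distance": contact_distance_nm}
    return model, truth
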