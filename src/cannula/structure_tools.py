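"""Geometry analyses on monomer and polymer structures.

Covers salt-bridge detection (side-chain N-O distance below 0.4 nm),
sequence charge census and mass, solvent accessibility by a deterministic
Shrake-Rupley sampler, global and windowed local backbone RMSD after
optimal superposition, and interface-residue identification in
multi-chain assemblies.  All distances in nm, areas in nm^2.
"""
from __future__ import annotations

import csv as _csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.SeqUtils import molecular_weight

from . import csp
from .errors import ConfigurationError, ValidationError
from .io_core import Atom, ResidueId, SequenceRecord, StructureModel

#: Default side-chain N-O cutoff for a salt bridge, nm.
SALT_BRIDGE_CUTOFF_NM = 0.4

#: Water probe radius, nm (the conventional 1.4 Angstrom rolling sphere).
DEFAULT_PROBE_RADIUS_NM = 0.14

#: Relative accessibility above which a residue counts as a surface residue.
SURFACE_RELATIVE_ASA = 0.10

BACKBONE_ATOMS = ("N", "CA", "C")

#: van der Waals radii (nm) for elements occurring in proteins.
VDW_RADII_NM = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
    "SE": 0.190,
}

_BASIC_SIDE_ATOMS = {"K": ("NZ",)}
_ACIDIC_SIDE_ATOMS = {"D": ("OD1", "OD2"), "E": ("OE1", "OE2")}


# ---------------------------------------------------------------------------
# salt bridges

@dataclass(frozen=True)
class SaltBridge:
    basic_residue: ResidueId
    acidic_residue: ResidueId
    min_NO_distance: float  # nm
    model_id: int
    chain: str = "A"


def find_salt_bridges(
    models: Sequence[StructureModel],
    cutoff: float = SALT_BRIDGE_CUTOFF_NM,
) -> list[SaltBridge]:
    """Lys-to-carboxylate contacts below the N-O distance cutoff, per model.

    For every lysine NZ and every Asp OD1/OD2 or Glu OE1/OE2 in the same
    chain of each model, the minimum nitrogen-oxygen distance is taken;
    pairs under the cutoff are reported.  Residues missing their
    side-chain atoms are skipped with a warning.  Use
    :func:`salt_bridge_union` for the ensemble-level census (a pair
    counts if the criterion holds in at least one model).
    """
    if cutoff <= 0:
        raise ValidationError("cutoff must be > 0")
    bridges = []
    for model in models:
        for chain in model.chains():
            basics, acidics = [], []
            for ch, rid in model.residues(chain):
                if rid.one_letter in _BASIC_SIDE_ATOMS:
                    atoms = model.select(chain, [rid.position],
                                         _BASIC_SIDE_ATOMS[rid.one_letter])
                    if not atoms:
                        warnings.warn(
                            f"model {model.model_id} {chain}/{rid.label}: "
                            "NZ missing, residue skipped", stacklevel=2)
                        continue
                    basics.append((rid, atoms))
                elif rid.one_letter in _ACIDIC_SIDE_ATOMS:
                    atoms = model.select(chain, [rid.position],
                                         _ACIDIC_SIDE_ATOMS[rid.one_letter])
                    if not atoms:
                        warnings.warn(
                            f"model {model.model_id} {chain}/{rid.label}: "
                            "carboxyl oxygens missing, residue skipped", stacklevel=2)
                        continue
                    acidics.append((rid, atoms))
            for b_rid, b_atoms in basics:
                bxyz = np.array([a.xyz for a in b_atoms])
                for a_rid, a_atoms in acidics:
                    axyz = np.array([a.xyz for a in a_atoms])
                    d = np.linalg.norm(
                        bxyz[:, None, :] - axyz[None, :, :], axis=-1
                    ).min()
                    if d < cutoff:
                        bridges.append(SaltBridge(
                            basic_residue=b_rid,
                            acidic_residue=a_rid,
                            min_NO_distance=float(d),
                            model_id=model.model_id,
                            chain=chain,
                        ))
    return bridges


def salt_bridge_union(bridges: Iterable[SaltBridge]) -> set[tuple[str, str]]:
    """(basic, acidic) label pairs bridged in at least one model."""
    return {(b.basic_residue.label, b.acidic_residue.label) for b in bridges}


# ---------------------------------------------------------------------------
# sequence arithmetic

@dataclass
class ChargeCensus:
    n_asp: int
    n_glu: int
    n_lys: int
    n_arg: int
    n_his: int

    @property
    def n_negative(self) -> int:
        return self.n_asp + self.n_glu

    @property
    def n_positive_fixed(self) -> int:
        return self.n_lys + self.n_arg

    @property
    def net_charge_range(self) -> tuple[int, int]:
        """(His neutral, His protonated) net side-chain charge estimate."""
        base = self.n_positive_fixed - self.n_negative
        return (base, base + self.n_his)


def charge_census(seq: SequenceRecord) -> ChargeCensus:
    s = seq.residues
    return ChargeCensus(
        n_asp=s.count("D"),
        n_glu=s.count("E"),
        n_lys=s.count("K"),
        n_arg=s.count("R"),
        n_his=s.count("H"),
    )


def sequence_mass(seq: SequenceRecord) -> float:
    """Average (non-monoisotopic) polypeptide mass in kg/mol."""
    return molecular_weight(seq.residues, seq_type="protein") / 1000.0


# ---------------------------------------------------------------------------
# solvent accessibility (Shrake-Rupley)

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _radii(atoms: Sequence[Atom]) -> np.ndarray:
    out = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        el = a.element.upper()
        if el not in VDW_RADII_NM:
            raise ConfigurationError(
                f"no van der Waals radius for element {a.element!r} "
                f"(atom {a.name} in {a.chain}/{a.residue.label})"
            )
        out[i] = VDW_RADII_NM[el]
    return out


def atom_accessibility(
    atoms: Sequence[Atom],
    probe_radius: float = DEFAULT_PROBE_RADIUS_NM,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface (nm^2) by Shrake-Rupley sampling.

    Each atom's solvent-extended sphere is covered with ``n_points``
    deterministic test points; a point is accessible when outside every
    neighbour's extended sphere.
    """
    if probe_radius <= 0:
        raise ValidationError("probe_radius must be > 0")
    xyz = np.array([a.xyz for a in atoms])
    rad = _radii(atoms) + probe_radius
    unit = _sphere_points(n_points)
    asa = np.zeros(len(atoms))
    for i in range(len(atoms)):
        pts = xyz[i] + rad[i] * unit
        d = np.linalg.norm(xyz[i] - xyz, axis=1)
        neigh = np.nonzero((d < rad[i] + rad) & (np.arange(len(atoms)) != i))[0]
        buried = np.zeros(n_points, dtype=bool)
        for j in neigh:
            buried |= (
                np.einsum("ij,ij->i", pts - xyz[j], pts - xyz[j]) < rad[j] ** 2
            )
        asa[i] = (~buried).mean() * 4.0 * np.pi * rad[i] ** 2
    return asa


@dataclass
class ResidueAccessibility:
    residue: ResidueId
    chain: str
    asa: float  # nm^2
    relative_asa: float  # fraction of the Gly-X-Gly maximum, capped at 1
    is_surface: bool


@dataclass
class AccessibilityReport:
    entries: list[ResidueAccessibility]
    probe_radius: float
    n_points: int
    atom_asa: dict = field(default_factory=dict)  # (chain, pos, atom name) -> nm^2

    def surface_residues(self) -> list[ResidueId]:
        return [e.residue for e in self.entries if e.is_surface]


def _max_asa_table() -> dict[str, float]:
    out = {}
    with resources.files("cannula.data").joinpath("max_asa.csv").open() as fh:
        for row in _csv.DictReader(fh):
            out[row["aa"]] = float(row["max_asa_nm2"])
    return out


def accessibility(
    model: StructureModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS_NM,
    n_points: int = 960,
    chains: Iterable[str] | None = None,
) -> AccessibilityReport:
    """Per-residue accessible surface, relative accessibility and surface flag.

    Relative accessibility is the residue ASA over a theoretical
    Gly-X-Gly maximum, capped at 1 (an isolated residue exposes more
    surface than in the reference context); residues with more than 10%
    relative accessibility count as surface residues.
    """
    atoms = (
        model.atoms
        if chains is None
        else [a for a in model.atoms if a.chain in set(chains)]
    )
    asa = atom_accessibility(atoms, probe_radius, n_points)
    maxasa = _max_asa_table()
    per_res: dict[tuple[str, int], float] = {}
    rid_of: dict[tuple[str, int], ResidueId] = {}
    atom_asa = {}
    for a, area in zip(atoms, asa):
        key = (a.chain, a.residue.position)
        per_res[key] = per_res.get(key, 0.0) + float(area)
        rid_of[key] = a.residue
        atom_asa[(a.chain, a.residue.position, a.name)] = float(area)
    entries = []
    for key in sorted(per_res):
        rid = rid_of[key]
        rel = min(per_res[key] / maxasa[rid.one_letter], 1.0)
        entries.append(ResidueAccessibility(
            residue=rid,
            chain=key[0],
            asa=per_res[key],
            relative_asa=rel,
            is_surface=rel > SURFACE_RELATIVE_ASA,
        ))
    return AccessibilityReport(
        entries=entries,
        probe_radius=probe_radius,
        n_points=n_points,
        atom_asa=atom_asa,
    )


# ---------------------------------------------------------------------------
# superposition and RMSD

def _kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """RMSD of q onto p after optimal rotation+translation (Kabsch)."""
    pc, qc = p - p.mean(axis=0), q - q.mean(axis=0)
    h = qc.T @ pc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = pc - (rot @ qc.T).T
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def _matched_coords(
    a: StructureModel,
    b: StructureModel,
    positions: Iterable[int],
    atom_set: Sequence[str],
    chain_a: str | None,
    chain_b: str | None,
) -> tuple[np.ndarray, np.ndarray]:
    pa = {(x.residue.position, x.name): x.xyz
          for x in a.select(chain_a, positions, atom_set)}
    pb = {(x.residue.position, x.name): x.xyz
          for x in b.select(chain_b, positions, atom_set)}
    wanted = [(p, n) for p in sorted(set(positions)) for n in atom_set]
    missing = sorted({p for p, n in wanted if (p, n) not in pa or (p, n) not in pb})
    if missing:
        raise ValidationError(
            f"atoms {list(atom_set)} missing in one structure for residues {missing}"
        )
    return (np.array([pa[k] for k in wanted]), np.array([pb[k] for k in wanted]))


def rmsd_global(
    a: StructureModel,
    b: StructureModel,
    residue_range: tuple[int, int] | None = None,
    atom_set: Sequence[str] = BACKBONE_ATOMS,
    chain_a: str | None = None,
    chain_b: str | None = None,
) -> float:
    """Coordinate RMSD (nm) over a selection after optimal superposition."""
    if residue_range is None:
        pos_a = {r.position for _, r in a.residues(chain_a)}
        pos_b = {r.position for _, r in b.residues(chain_b)}
        positions = sorted(pos_a & pos_b)
    else:
        positions = list(range(residue_range[0], residue_range[1] + 1))
    if not positions:
        raise ValidationError("no shared residues in the requested selection")
    p, q = _matched_coords(a, b, positions, atom_set, chain_a, chain_b)
    return _kabsch_rmsd(p, q)


@dataclass
class RmsdProfileEntry:
    residue: ResidueId
    local_rmsd: float  # nm
    rmsd_class: str  # ns | significant | strong


@dataclass
class RmsdProfile:
    entries: list[RmsdProfileEntry]
    sigma0: float  # nm
    global_rmsd: float  # nm
    atom_set: tuple[str, ...]
    window: int


def rmsd_local_profile(
    a: StructureModel,
    b: StructureModel,
    atom_set: Sequence[str] = BACKBONE_ATOMS,
    window: int = 5,
    chain_a: str | None = None,
    chain_b: str | None = None,
) -> RmsdProfile:
    """Sliding-window local backbone RMSD between two structures.

    For each residue, the window of ``window`` consecutive shared residues
    centered on it is superposed and the central residue's RMSD over
    ``atom_set`` recorded.  The significance threshold sigma0 is the same
    iterative outlier-corrected RMS about zero used for shift
    perturbations; local RMSDs above sigma0 are significant, above
    2*sigma0 strong.
    """
    if window < 1 or window % 2 == 0:
        raise ValidationError("window must be a positive odd integer")
    rid_a = {r.position: r for _, r in a.residues(chain_a)}
    rid_b = {r.position: r for _, r in b.residues(chain_b)}
    shared = sorted(set(rid_a) & set(rid_b))
    if len(shared) < window:
        raise ValidationError(
            f"window {window} exceeds the {len(shared)} shared residues"
        )
    half = window // 2
    entries = []
    for idx in range(half, len(shared) - half):
        center = shared[idx]
        block = shared[idx - half : idx + half + 1]
        if block != list(range(center - half, center + half + 1)):
            continue  # chain break inside the window
        p, q = _matched_coords(a, b, block, atom_set, chain_a, chain_b)
        pc, qc = p - p.mean(axis=0), q - q.mean(axis=0)
        h = qc.T @ pc
        u, s, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
        diff = pc - (rot @ qc.T).T
        per_atom = np.sum(diff**2, axis=1)
        k = len(atom_set)
        central = per_atom[half * k : (half + 1) * k]
        entries.append(RmsdProfileEntry(
            residue=rid_a[center],
            local_rmsd=float(np.sqrt(np.mean(central))),
            rmsd_class="ns",
        ))
    sigma0 = csp.sigma0_corr([e.local_rmsd for e in entries])
    for e in entries:
        c = csp.classify(e.local_rmsd, sigma0)
        e.rmsd_class = {"none": "ns"}.get(c, c)
    return RmsdProfile(
        entries=entries,
        sigma0=sigma0,
        global_rmsd=rmsd_global(a, b, (shared[0], shared[-1]), atom_set,
                                chain_a, chain_b),
        atom_set=tuple(atom_set),
        window=window,
    )


# ---------------------------------------------------------------------------
# interfaces

def interface_residues(
    complex_models: Sequence[StructureModel],
    target_chain: str,
    distance_cutoff: float = 0.5,
    dasa_threshold: float = 0.01,
    probe_radius: float = DEFAULT_PROBE_RADIUS_NM,
    n_points: int = 480,
) -> dict[str, set[ResidueId]]:
    """Residues of ``target_chain`` in contact with each partner chain.

    A residue interacts with partner chain P when its accessible surface
    drops by more than ``dasa_threshold`` nm^2 upon adding P, or any of
    its heavy atoms lies within ``distance_cutoff`` nm of P.  The union
    over all supplied models is reported per partner chain.
    """
    out: dict[str, set[ResidueId]] = {}
    for model in complex_models:
        chains = model.chains()
        if target_chain not in chains:
            raise ValidationError(f"chain {target_chain!r} not in model {model.model_id}")
        partners = [c for c in chains if c != target_chain]
        if not partners:
            raise ValidationError("interface analysis needs at least two chains")
        alone = accessibility(model, probe_radius, n_points, chains=[target_chain])
        asa_alone = {e.residue.position: e.asa for e in alone.entries}
        t_atoms = [a for a in model.atoms if a.chain == target_chain
                   and not a.element.upper().startswith("H")]
        t_xyz = np.array([a.xyz for a in t_atoms])
        for partner in partners:
            out.setdefault(partner, set())
            pair = accessibility(model, probe_radius, n_points,
                                 chains=[target_chain, partner])
            asa_pair = {e.residue.position: e.asa for e in pair.entries
                        if e.chain == target_chain}
            p_xyz = np.array([a.xyz for a in model.atoms if a.chain == partner
                              and not a.element.upper().startswith("H")])
            dmin_per_atom = np.linalg.norm(
                t_xyz[:, None, :] - p_xyz[None, :, :], axis=-1
            ).min(axis=1)
            for _, rid in model.residues(target_chain):
                dasa = asa_alone[rid.position] - asa_pair.get(rid.position, 0.0)
                idx = [i for i, a in enumerate(t_atoms)
                       if a.residue.position == rid.position]
                close = bool(idx) and dmin_per_atom[idx].min() < distance_cutoff
                if dasa > dasa_threshold or close:
                    out[partner].add(rid)
    return out
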