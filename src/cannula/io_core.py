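"""Shared domain types and file I/O.

Length unit for coordinates is nm throughout the package; PDB files
(which use Angstrom) are converted on read and write.  Chemical shifts
are ppm, concentrations mM unless a function says otherwise.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from Bio import SeqIO

from .errors import FormatError, ValidationError

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

ANGSTROM_PER_NM = 10.0

PEAKLIST_HEADER = ["residue", "aa", "delta_H_ppm", "delta_N_ppm"]


@dataclass(frozen=True, order=True)
class ResidueId:
    """A residue in full-length recombinant numbering (M1 ... G183 for CanA).

    The truncated construct (first residue A12) is stored in the same frame
    so per-residue comparisons align by position.
    """

    position: int
    one_letter: str

    def __post_init__(self):
        if self.position < 1:
            raise ValidationError(f"residue position must be >= 1, got {self.position}")
        if self.one_letter not in CANONICAL_AA:
            raise ValidationError(
                f"non-canonical amino-acid code {self.one_letter!r} at position {self.position}"
            )

    @property
    def label(self) -> str:
        return f"{self.one_letter}{self.position}"

    @classmethod
    def from_label(cls, label: str) -> "ResidueId":
        return cls(position=int(label[1:]), one_letter=label[0].upper())


@dataclass
class PeakEntry:
    residue: ResidueId
    delta_H: float  # ppm, amide 1H
    delta_N: float  # ppm, amide 15N


@dataclass
class PeakList:
    """Amide peak positions at one experimental condition."""

    condition_label: str
    ligand_concentration: float  # mM total ligand (c_T)
    entries: list[PeakEntry] = field(default_factory=list)

    def __post_init__(self):
        if self.ligand_concentration < 0:
            raise ValidationError("ligand_concentration must be >= 0")
        seen = set()
        for e in self.entries:
            key = e.residue.position
            if key in seen:
                raise ValidationError(f"duplicate entry for residue {e.residue.label}")
            seen.add(key)

    def by_position(self) -> dict[int, PeakEntry]:
        return {e.residue.position: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class TitrationSeries:
    """Combined shift change of one residue across a ligand titration."""

    residue: ResidueId
    points: list[tuple[float, float]]  # (c_T mM, delta_comb ppm)
    protein_concentration: float  # mM (M_T)
    ligand_name: str = ""

    def __post_init__(self):
        cs = [c for c, _ in self.points]
        ds = [d for _, d in self.points]
        if any(b <= a for a, b in zip(cs, cs[1:])):
            raise ValidationError("c_T values must be strictly increasing")
        if self.points and (cs[0] != 0 or ds[0] != 0):
            raise ValidationError("titration must start at c_T = 0 with delta_comb = 0")
        if any(d < 0 for d in ds):
            raise ValidationError("delta_comb values must be >= 0")

    @property
    def c_t(self) -> np.ndarray:
        return np.array([c for c, _ in self.points], dtype=float)

    @property
    def delta(self) -> np.ndarray:
        return np.array([d for _, d in self.points], dtype=float)


@dataclass
class SequenceRecord:
    name: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValidationError(f"sequence {self.name!r} is empty")
        for i, aa in enumerate(self.residues, start=1):
            if aa not in CANONICAL_AA:
                raise ValidationError(
                    f"non-canonical residue {aa!r} at position {i} in {self.name!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Atom:
    chain: str
    residue: ResidueId
    name: str
    x: float  # nm
    y: float
    z: float
    element: str = ""

    def __post_init__(self):
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValidationError(f"non-finite coordinate on atom {self.name}")
        if not self.element:
            # heavy-atom PDB names start with the element symbol
            self.element = self.name.lstrip("0123456789")[0]

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class StructureModel:
    """One model of an atomic structure, coordinates in nm."""

    model_id: int
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for a in self.atoms:
            key = (a.chain, a.residue.position, a.name)
            if key in seen:
                raise ValidationError(
                    f"duplicate atom {a.name} in {a.chain}/{a.residue.label}"
                )
            seen.add(key)

    def chains(self) -> list[str]:
        out = []
        for a in self.atoms:
            if a.chain not in out:
                out.append(a.chain)
        return out

    def residues(self, chain: str | None = None) -> list[tuple[str, ResidueId]]:
        out, seen = [], set()
        for a in self.atoms:
            if chain is not None and a.chain != chain:
                continue
            key = (a.chain, a.residue.position)
            if key not in seen:
                seen.add(key)
                out.append((a.chain, a.residue))
        return out

    def select(
        self,
        chain: str | None = None,
        positions: Iterable[int] | None = None,
        atom_names: Iterable[str] | None = None,
    ) -> list[Atom]:
        positions = set(positions) if positions is not None else None
        atom_names = set(atom_names) if atom_names is not None else None
        return [
            a
            for a in self.atoms
            if (chain is None or a.chain == chain)
            and (positions is None or a.residue.position in positions)
            and (atom_names is None or a.name in atom_names)
        ]

    def coords(self, atoms: Sequence[Atom] | None = None) -> np.ndarray:
        atoms = self.atoms if atoms is None else atoms
        return np.array([[a.x, a.y, a.z] for a in atoms], dtype=float)


@dataclass
class DecayCurve:
    """Intensity decay, either vs gradient strength (diffusion) or time (kinetics).

    ``abscissa`` is the gradient strength G in instrument units for
    ``kind="diffusion"`` and time (any consistent unit) for ``kind="kinetics"``.
    """

    abscissa: np.ndarray
    intensity: np.ndarray
    kind: str  # "diffusion" | "kinetics"
    calibration_tag: str = ""  # diffusion curves sharing a gradient calibration

    def __post_init__(self):
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.kind not in ("diffusion", "kinetics"):
            raise ValidationError(f"unknown curve kind {self.kind!r}")
        if self.abscissa.shape != self.intensity.shape:
            raise ValidationError("abscissa and intensity must have the same length")
        if np.any(self.abscissa < 0):
            raise ValidationError("abscissa values must be non-negative")
        if np.any(np.diff(self.abscissa) < 0):
            raise ValidationError("abscissa must be non-decreasing")

    def __len__(self) -> int:
        return len(self.abscissa)


# ---------------------------------------------------------------------------
# peak lists

def read_peaklist(
    path: str | Path,
    dialect: str = "csv",
    condition_label: str = "",
    ligand_concentration: float = 0.0,
) -> PeakList:
    """Read a peak list.

    ``dialect="csv"`` is the canonical comma-separated layout with header
    ``residue,aa,delta_H_ppm,delta_N_ppm``; ``dialect="whitespace"`` accepts
    the same columns separated by arbitrary whitespace.  Rows whose shifts
    cannot be parsed are reported via a warning, never silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    text = path.read_text().strip()
    if not text:
        raise FormatError(f"empty peak list file: {path}")
    sep = {"csv": ",", "whitespace": None}.get(dialect)
    if dialect not in ("csv", "whitespace"):
        raise FormatError(f"unsupported peak-list dialect {dialect!r}")
    lines = text.splitlines()
    header = [h.strip() for h in lines[0].split(sep)]
    if header != PEAKLIST_HEADER:
        missing = [c for c in PEAKLIST_HEADER if c not in header]
        raise FormatError(
            f"{path}: bad header {header}; missing mandatory columns {missing}"
        )
    entries, bad_rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split(sep)]
        try:
            pos, aa = int(fields[0]), fields[1].upper()
            dh, dn = float(fields[2]), float(fields[3])
        except (ValueError, IndexError):
            bad_rows.append(lineno)
            continue
        entries.append(PeakEntry(ResidueId(pos, aa), dh, dn))
    if bad_rows:
        warnings.warn(
            f"{path}: skipped unparseable rows at lines {bad_rows}", stacklevel=2
        )
    return PeakList(
        condition_label=condition_label or path.stem,
        ligand_concentration=ligand_concentration,
        entries=entries,
    )


def write_peaklist(peaklist: PeakList, path: str | Path) -> None:
    """Write the canonical CSV dialect (round-trips byte-for-byte)."""
    lines = [",".join(PEAKLIST_HEADER)]
    for e in peaklist.entries:
        lines.append(
            f"{e.residue.position},{e.residue.one_letter},{e.delta_H:g},{e.delta_N:g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# sequences

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    records = [
        SequenceRecord(name=rec.id, residues=str(rec.seq).upper().replace(" ", ""))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# structures

def _one_letter(resname: str) -> str | None:
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_amino_acid():
        return None
    code = info.one_letter_code.upper()
    return code if code in CANONICAL_AA else None


def read_structure(path: str | Path, numbering_offset: int = 0) -> list[StructureModel]:
    """Read a PDB file into one StructureModel per MODEL record.

    Coordinates are converted Angstrom -> nm.  ``numbering_offset`` is added
    to every residue number, for depositions whose numbering does not start
    in the full-length frame.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: not a readable PDB file ({exc})") from exc
    models = []
    for i, model in enumerate(st, start=1):
        atoms = []
        for chain in model:
            for res in chain:
                code = _one_letter(res.name)
                if code is None:
                    continue  # waters, ligands, modified residues
                rid = ResidueId(res.seqid.num + numbering_offset, code)
                for atom in res:
                    atoms.append(
                        Atom(
                            chain=chain.name,
                            residue=rid,
                            name=atom.name,
                            x=atom.pos.x / ANGSTROM_PER_NM,
                            y=atom.pos.y / ANGSTROM_PER_NM,
                            z=atom.pos.z / ANGSTROM_PER_NM,
                            element=atom.element.name,
                        )
                    )
        if atoms:
            models.append(StructureModel(model_id=i, atoms=atoms))
    if not models:
        raise FormatError(f"{path}: no ATOM records for amino-acid residues")
    return models


_THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def write_structure(models: Sequence[StructureModel], path: str | Path) -> None:
    """Write models as a fixed-column PDB file (nm -> Angstrom)."""
    lines = []
    multi = len(models) > 1
    for model in models:
        if multi:
            lines.append(f"MODEL     {model.model_id:4d}")
        for serial, a in enumerate(model.atoms, start=1):
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}{_THREE_LETTER[a.residue.one_letter]:>4s} "
                f"{a.chain[:1]}{a.residue.position:4d}    "
                f"{a.x * ANGSTROM_PER_NM:8.3f}{a.y * ANGSTROM_PER_NM:8.3f}"
                f"{a.z * ANGSTROM_PER_NM:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# decay curves

def read_decay_csv(path: str | Path, kind: str) -> DecayCurve:
    """Read a two-column CSV (abscissa, intensity); extra columns ignored."""
    import pandas as pd

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need at least two columns")
    return DecayCurve(
        abscissa=df.iloc[:, 0].to_numpy(float),
        intensity=df.iloc[:, 1].to_numpy(float),
        kind=kind,
    )
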