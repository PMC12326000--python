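import pytest

from cannula.io_core import PeakEntry, PeakList, ResidueId
from cannula.synthetic_data import ToyResidue, make_toy_structure


@pytest.fixture
def reference_peaklist():
    """Ten residues with plausible amide shifts, ligand-free condition."""
    entries = [
        PeakEntry(ResidueId(pos, aa), 8.0 + 0.02 * i, 115.0 + 1.1 * i)
        for i, (pos, aa) in enumerate(
            [(24, "D"), (42, "D"), (57, "D"), (97, "E"), (99, "K"),
             (114, "D"), (115, "K"), (116, "E"), (140, "D"), (183, "G")]
        )
    ]
    return PeakList(condition_label="apo", ligand_concentration=0.0, entries=entries)


@pytest.fixture
def charged_toy_ensemble():
    """Two-model toy with one Lys/Asp pair bridged only in the first model."""
    def build(nz_x):
        return make_toy_structure(
            [
                ToyResidue(1, "K", ca=(0.0, 0.0, 0.0),
                           extra_atoms={"NZ": (nz_x, 0.0, 0.45)}),
                ToyResidue(3, "D", ca=(0.9, 0.0, 0.0),
                           extra_atoms={"OD1": (0.5, 0.0, 0.45),
                                        "OD2": (0.6, 0.0, 0.55)}),
                ToyResidue(5, "E", ca=(1.9, 0.0, 0.0),
                           extra_atoms={"OE1": (1.9, 0.0, 0.45),
                                        "OE2": (2.0, 0.0, 0.55)}),
            ],
        )

    near = build(0.15)   # NZ-OD1 0.35 nm
    far = build(-0.3)    # NZ-OD1 0.80 nm
    far.model_id = 2
    return [near, far]
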