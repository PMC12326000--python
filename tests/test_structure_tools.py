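import itertools

import numpy as np
import pytest

from cannula import structure_tools as st
from cannula.errors import ValidationError
from cannula.io_core import Atom, ResidueId, SequenceRecord, StructureModel
from cannula.synthetic_data import (
    ToyResidue,
    cana_like_sequence,
    make_contact_dimer,
    make_salt_bridge_pair,
    make_toy_structure,
)


def brute_force_bridges(model, cutoff=0.4):
    """Independent all-pairs scan over NZ x carboxylate-O atom distances."""
    found = set()
    for a, b in itertools.product(model.atoms, model.atoms):
        if a.name != "NZ" or b.name not in ("OD1", "OD2", "OE1", "OE2"):
            continue
        if a.chain == b.chain and np.linalg.norm(a.xyz - b.xyz) < cutoff:
            found.add((a.residue.label, b.residue.label))
    return found


class TestSaltBridges:
    def test_pair_under_cutoff_found_with_distance(self):
        model, truth = make_salt_bridge_pair(distance_nm=0.35)
        bridges = st.find_salt_bridges([model])
        assert len(bridges) == 1
        assert (bridges[0].basic_residue.label,
                bridges[0].acidic_residue.label) == truth["pair"]
        assert bridges[0].min_NO_distance == pytest.approx(0.35, abs=1e-9)

    def test_pair_beyond_cutoff_excluded(self):
        model, _ = make_salt_bridge_pair(distance_nm=0.45)
        assert st.find_salt_bridges([model]) == []

    def test_matches_brute_force_scan(self, charged_toy_ensemble):
        for model in charged_toy_ensemble:
            got = {
                (b.basic_residue.label, b.acidic_residue.label)
                for b in st.find_salt_bridges([model])
            }
            assert got == brute_force_bridges(model)

    def test_any_model_union_over_ensemble(self, charged_toy_ensemble):
        """A pair bridged in only one ensemble member still enters the census."""
        bridges = st.find_salt_bridges(charged_toy_ensemble)
        union = st.salt_bridge_union(bridges)
        assert ("K1", "D3") in union
        per_model = {b.model_id for b in bridges
                     if (b.basic_residue.label, b.acidic_residue.label) == ("K1", "D3")}
        assert per_model == {1}

    def test_missing_side_chain_warns_not_silently_skips(self):
        model = make_toy_structure([ToyResidue(1, "K"), ToyResidue(3, "D")])
        with pytest.warns(UserWarning, match="missing"):
            assert st.find_salt_bridges([model]) == []


class TestSequenceArithmetic:
    def test_minimal_sequences(self):
        c = st.charge_census(SequenceRecord("g", "G"))
        assert (c.n_asp, c.n_glu, c.n_lys, c.n_arg, c.n_his) == (0, 0, 0, 0, 0)
        c = st.charge_census(SequenceRecord("x", "DDKEH"))
        assert (c.n_asp, c.n_glu, c.n_lys, c.n_his) == (2, 1, 1, 1)
        assert c.net_charge_range == (-2, -1)

    def test_census_equals_naive_string_count(self):
        seq = cana_like_sequence()
        c = st.charge_census(seq)
        for aa, n in (("D", c.n_asp), ("E", c.n_glu), ("K", c.n_lys),
                      ("R", c.n_arg), ("H", c.n_his)):
            assert n == seq.residues.count(aa)

    def test_full_length_composition(self):
        """The synthetic full-length sequence carries the protein's stated
        charge inventory: 21 acidic residues, 12 lysines, one histidine, no
        arginine — a surplus of 8-9 negative charges."""
        c = st.charge_census(cana_like_sequence())
        assert c.n_negative == 21
        assert c.n_lys == 12
        assert c.n_his == 1 and c.n_arg == 0
        assert c.net_charge_range == (-9, -8)

    @pytest.mark.parametrize(
        "seq,expected,tol",
        [("G", 0.07507, 1e-4), ("GG", 0.13214, 2e-4)],
    )
    def test_mass_of_tiny_peptides_hand_summed(self, seq, expected, tol):
        # residue masses + one water, summed by hand from the standard table
        got = st.sequence_mass(SequenceRecord("x", seq))
        assert got == pytest.approx(expected, abs=tol)

    def test_full_length_mass(self):
        assert st.sequence_mass(cana_like_sequence()) == pytest.approx(19.85, abs=0.02)


def mc_atom_asa(atoms, probe, n=100_000, seed=0):
    """Monte-Carlo surface-point oracle, independent of the spiral sampler."""
    rng = np.random.default_rng(seed)
    xyz = np.array([a.xyz for a in atoms])
    rad = np.array([st.VDW_RADII_NM[a.element.upper()] for a in atoms]) + probe
    out = np.zeros(len(atoms))
    for i in range(len(atoms)):
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pts = xyz[i] + rad[i] * v
        exposed = np.ones(n, dtype=bool)
        for j in range(len(atoms)):
            if j == i:
                continue
            exposed &= np.sum((pts - xyz[j]) ** 2, axis=1) >= rad[j] ** 2
        out[i] = exposed.mean() * 4 * np.pi * rad[i] ** 2
    return out


class TestAccessibility:
    def test_isolated_residue_is_fully_exposed_surface(self):
        model = make_toy_structure([ToyResidue(1, "A")])
        report = st.accessibility(model)
        assert report.entries[0].relative_asa == pytest.approx(1.0)
        assert report.entries[0].is_surface

    def test_enclosed_atom_has_zero_asa(self):
        rid = ResidueId(1, "K")
        shell_dirs = st._sphere_points(80)
        atoms = [Atom("A", rid, "NZ", 0.0, 0.0, 0.0, element="N")]
        for k, d in enumerate(shell_dirs):
            atoms.append(Atom("A", rid, f"C{k}", *(0.28 * d), element="C"))
        asa = st.atom_accessibility(atoms)
        assert asa[0] == 0.0

    def test_matches_monte_carlo_oracle(self):
        model = make_toy_structure(
            [ToyResidue(i, aa) for i, aa in enumerate("AVGLS", start=1)]
        )
        det = st.atom_accessibility(model.atoms, n_points=2000)
        mc = mc_atom_asa(model.atoms, st.DEFAULT_PROBE_RADIUS_NM)
        # 5% relative agreement on every atom with appreciable surface
        mask = mc > 0.01
        assert np.all(np.abs(det[mask] - mc[mask]) / mc[mask] < 0.05)

    def test_exposed_fraction_never_grows_with_probe(self):
        """On a convex two-atom toy a larger probe can only bury a larger
        fraction of each sphere."""
        rid = ResidueId(1, "A")
        atoms = [Atom("A", rid, "C1", 0.0, 0.0, 0.0, element="C"),
                 Atom("A", rid, "C2", 0.3, 0.0, 0.0, element="C")]
        fracs = []
        for probe in (0.07, 0.14, 0.28):
            asa = st.atom_accessibility(atoms, probe_radius=probe)
            r = st.VDW_RADII_NM["C"] + probe
            fracs.append(asa / (4 * np.pi * r**2))
        assert np.all(np.diff(np.array(fracs), axis=0) <= 1e-12)

    def test_unknown_element_is_a_configuration_error(self):
        from cannula.errors import ConfigurationError

        atoms = [Atom("A", ResidueId(1, "A"), "FE1", 0, 0, 0, element="FE")]
        with pytest.raises(ConfigurationError, match="FE"):
            st.atom_accessibility(atoms)


def rigid_transform(model, angle=0.7, shift=(1.0, -2.0, 0.5)):
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    atoms = []
    for a in model.atoms:
        x, y, z = rot @ a.xyz + np.asarray(shift)
        atoms.append(Atom(a.chain, a.residue, a.name, x, y, z, element=a.element))
    return StructureModel(model_id=model.model_id + 1, atoms=atoms)


class TestRmsd:
    def _chain(self, n=9, wiggle=None):
        res = []
        for i in range(1, n + 1):
            ca = (i * 0.38, 0.05 * ((-1) ** i), 0.0)
            if wiggle and i in wiggle:
                ca = (ca[0], ca[1] + wiggle[i], ca[2])
            res.append(ToyResidue(i, "A", ca=ca))
        return make_toy_structure(res)

    def test_identical_structures_rmsd_zero(self):
        a = self._chain()
        assert st.rmsd_global(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        a = self._chain()
        b = rigid_transform(a)
        assert st.rmsd_global(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self):
        a = self._chain()
        b = self._chain(wiggle={4: 0.12})
        assert st.rmsd_global(a, b) == pytest.approx(st.rmsd_global(b, a), rel=1e-12)
        assert st.rmsd_global(a, b) > 0

    def test_missing_atoms_listed(self):
        a = self._chain(3)
        b = self._chain(5)
        with pytest.raises(ValidationError, match=r"\[4, 5\]"):
            st.rmsd_global(a, b, residue_range=(1, 5))

    def test_local_profile_zero_for_identical(self):
        a = self._chain()
        profile = st.rmsd_local_profile(a, a, window=5)
        assert all(e.local_rmsd == pytest.approx(0.0, abs=1e-12)
                   for e in profile.entries)
        assert all(e.rmsd_class == "ns" for e in profile.entries)

    def test_local_profile_peaks_at_displaced_residue(self):
        a = self._chain(11)
        b = self._chain(11, wiggle={6: 0.2})
        profile = st.rmsd_local_profile(a, b, window=5)
        peak = max(profile.entries, key=lambda e: e.local_rmsd)
        assert peak.residue.position == 6
        # independent per-window check: superpose residues 4..8 with scipy's
        # rotation estimator and measure the central residue directly
        from scipy.spatial.transform import Rotation

        p, q = st._matched_coords(a, b, range(4, 9), st.BACKBONE_ATOMS, None, None)
        pc, qc = p - p.mean(axis=0), q - q.mean(axis=0)
        rot, _ = Rotation.align_vectors(pc, qc)
        diff = pc - rot.apply(qc)
        central = diff[6:9]  # the 3 backbone atoms of residue 6
        expected = np.sqrt(np.mean(np.sum(central**2, axis=1)))
        assert peak.local_rmsd == pytest.approx(expected, rel=1e-6)
        assert peak.rmsd_class == "strong"

    def test_local_profile_symmetric(self):
        a = self._chain(11)
        b = self._chain(11, wiggle={6: 0.2, 3: 0.05})
        pa = st.rmsd_local_profile(a, b, window=5)
        pb = st.rmsd_local_profile(b, a, window=5)
        assert [e.local_rmsd for e in pa.entries] == pytest.approx(
            [e.local_rmsd for e in pb.entries], rel=1e-9
        )

    def test_window_must_fit(self):
        a = self._chain(3)
        with pytest.raises(ValidationError):
            st.rmsd_local_profile(a, a, window=5)


class TestInterfaces:
    def test_distant_chains_share_no_interface(self):
        res_a = [ToyResidue(i, "A", chain="A", ca=(i * 0.5, 0.0, 0.0))
                 for i in range(1, 4)]
        res_b = [ToyResidue(i, "A", chain="B", ca=(i * 0.5, 10.0, 0.0))
                 for i in range(1, 4)]
        model = make_toy_structure(res_a + res_b)
        out = st.interface_residues([model], "A")
        assert out == {"B": set()}

    def test_single_contact_pair_identified(self):
        model, truth = make_contact_dimer(contact_distance_nm=0.3)
        out = st.interface_residues([model], "A")
        assert {r.position for r in out["B"]} == {truth["contact"][1]}

    def test_monotone_in_distance_cutoff(self):
        model, _ = make_contact_dimer(contact_distance_nm=0.45)
        small = st.interface_residues([model], "A", distance_cutoff=0.4)
        large = st.interface_residues([model], "A", distance_cutoff=0.6)
        assert small["B"] <= large["B"]

    def test_single_chain_rejected(self):
        model = make_toy_structure([ToyResidue(1, "A")])
        with pytest.raises(ValidationError):
            st.interface_residues([model], "A")
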