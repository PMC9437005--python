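"""Synthetic chain generation, stoichiometries and mesh statistics."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from npcvoid.grids import GridSpec
from npcvoid.mesh import (BOND_LENGTH, PlacementError, apply_symmetry,
                          build_mesh_ensemble, chain_and_residue_totals,
                          charge_hydrophobicity_ratio, density_map,
                          generate_chain, generate_linker_chain,
                          interchain_contact_fraction, load_stoichiometry,
                          toy_stoichiometry)


class TestStoichiometries:
    def test_lin2016_chain_total(self):
        spec = load_stoichiometry("lin2016")
        n_chains, _ = chain_and_residue_totals(spec)
        assert n_chains == 160

    def test_kim2018_chain_total(self):
        spec = load_stoichiometry("kim2018")
        n_chains, _ = chain_and_residue_totals(spec)
        assert n_chains == 200

    def test_kim2018plus_residue_budget(self):
        # the extended yeast composition carries ~30% more residues
        _, base = chain_and_residue_totals(load_stoichiometry("kim2018"))
        _, plus = chain_and_residue_totals(load_stoichiometry("kim2018plus"))
        assert plus / base == pytest.approx(1.30, abs=0.02)

    def test_small_synthetic_totals(self):
        spec = toy_stoichiometry(2, 5)
        assert chain_and_residue_totals(spec) == (2, 10)

    def test_unknown_name(self):
        with pytest.raises(ValueError):
            load_stoichiometry("nonexistent2020")

    def test_deletion_variant_reduces_totals(self):
        spec = load_stoichiometry("lin2016")
        smaller = spec.without("Nsp1")
        n0, r0 = chain_and_residue_totals(spec)
        n1, r1 = chain_and_residue_totals(smaller)
        assert n0 - n1 == 32 and r0 - r1 == 32 * 467

    def test_roundtrip_through_yaml(self, tmp_path):
        import yaml

        data = {"name": "custom", "species": [
            {"name": "a", "copies": 2, "residue_range": [1, 30]}]}
        p = tmp_path / "stoich.yaml"
        p.write_text(yaml.safe_dump(data))
        spec = load_stoichiometry(str(p))
        assert chain_and_residue_totals(spec) == (2, 60)


class TestChainGeneration:
    def test_single_bead_chain_is_anchor(self):
        ch = generate_chain([1.0, 2.0, 3.0], 1, rng_seed=0)
        assert len(ch) == 1
        assert np.allclose(ch.positions[0], [1, 2, 3])

    def test_bond_lengths_and_interchain_distance(self):
        """Brute-force pairwise check of the growth constraints."""
        rng = np.random.default_rng(5)
        first = generate_chain([0, 0, 0], 100, rng=rng)
        second = generate_chain([30, 0, 0], 100, obstacles=first.positions,
                                rng=rng)
        for ch in (first, second):
            assert np.allclose(ch.bond_lengths(), BOND_LENGTH, atol=1e-6)
        cross = cdist(first.positions, second.positions)
        assert cross.min() >= 8.0

    def test_determinism_contract(self):
        a = generate_chain([0, 0, 0], 50, rng_seed=42)
        b = generate_chain([0, 0, 0], 50, rng_seed=42)
        c = generate_chain([0, 0, 0], 50, rng_seed=43)
        assert np.array_equal(a.positions, b.positions)
        assert not np.array_equal(a.positions, c.positions)

    def test_steric_grid_respected_beyond_skip(self):
        # everything above z = 5 is forbidden; anchor sits right below it
        gs = GridSpec((-200, -200, 5.0), (400.0, 400.0, 400.0), (1, 1, 1))
        from npcvoid.grids import ScalarGrid3D

        wall = ScalarGrid3D(gs, np.full((1, 1, 1), 10.0))
        ch = generate_chain([0, 0, 0], 60, steric_grids=[wall], rng_seed=1)
        assert np.all(ch.positions[3:, 2] < 5.0)

    def test_placement_failure_reports_residue(self):
        # box so tight that growth beyond the anchor is impossible
        from npcvoid.grids import ScalarGrid3D

        gs = GridSpec((-500, -500, -500), (1000.0, 1000.0, 1000.0), (1, 1, 1))
        wall = ScalarGrid3D(gs, np.full((1, 1, 1), 10.0))
        with pytest.raises(PlacementError) as exc:
            generate_chain([0, 0, 0], 30, steric_grids=[wall], rng_seed=0,
                           scaffold_skip=0, max_backtracks=20)
        assert exc.value.residue_index >= 1

    def test_linker_hits_both_anchors(self):
        ch = generate_linker_chain([0, 0, 0], [30, 0, 0], 20, rng_seed=3)
        assert np.allclose(ch.positions[0], [0, 0, 0])
        assert np.allclose(ch.positions[-1], [30, 0, 0], atol=1e-8)
        assert np.allclose(ch.bond_lengths(), BOND_LENGTH, atol=1e-6)

    def test_linker_too_short_fails(self):
        with pytest.raises(PlacementError):
            generate_linker_chain([0, 0, 0], [100, 0, 0], 5, rng_seed=0)

    def test_rg_grows_with_length(self):
        """Mean radius of gyration increases with chain length (50 seeds)."""
        means = []
        for length in (10, 30, 90):
            rgs = [generate_chain([0, 0, 0], length, rng_seed=s).radius_of_gyration()
                   for s in range(50)]
            means.append(np.mean(rgs))
        assert means[0] < means[1] < means[2]


class TestEnsemble:
    def test_reproducible_and_valid(self, toy_spec):
        e1 = build_mesh_ensemble(toy_spec, n_frames=3, rng_seed=9)
        e2 = build_mesh_ensemble(toy_spec, n_frames=3, rng_seed=9)
        for m1, m2 in zip(e1, e2):
            assert np.array_equal(m1.all_beads(), m2.all_beads())
        for m in e1:
            for ch in m.chains:
                assert np.allclose(ch.bond_lengths(), BOND_LENGTH, atol=1e-6)
            assert len({c.species for c in m.chains}) == 1

    def test_frame_ids_unique(self, toy_ensemble):
        ids = [m.frame_id for m in toy_ensemble]
        assert len(set(ids)) == len(ids)

    def test_species_deletion_leaves_other_chains_unchanged(self):
        """In a dilute mesh the per-chain seed streams make the surviving
        species' chains byte-identical after a deletion."""
        from npcvoid.mesh import Species, StoichiometrySpec

        spec = StoichiometrySpec("two", [
            Species("left", 2, (1, 20), "C"),
            Species("right", 2, (1, 20), "C"),
        ])
        spec.anchors["left"] = np.array([[-300.0, 0, 0], [-300.0, 80.0, 0]])
        spec.anchors["right"] = np.array([[300.0, 0, 0], [300.0, 80.0, 0]])
        spec.validate()
        full = build_mesh_ensemble(spec, n_frames=2, rng_seed=4)
        reduced = build_mesh_ensemble(spec.without("left"), n_frames=2,
                                      rng_seed=4)
        for mf, mr in zip(full, reduced):
            keep = [c for c in mf.chains if c.species == "right"]
            assert len(keep) == len(mr.chains) == 2
            for a, b in zip(keep, mr.chains):
                assert np.array_equal(a.positions, b.positions)


class TestContacts:
    def _two_chain_mesh(self, gap):
        from npcvoid.mesh import BeadChain, MeshConfiguration

        line = np.column_stack([np.arange(10) * BOND_LENGTH,
                                np.zeros(10), np.zeros(10)])
        return MeshConfiguration(chains=[
            BeadChain("a", line),
            BeadChain("b", line + np.array([0.0, gap, 0.0])),
        ])

    def test_far_apart_no_contacts(self):
        _, overall = interchain_contact_fraction(self._two_chain_mesh(25.0))
        assert overall == 0.0

    def test_overlapping_all_contacts(self):
        per, overall = interchain_contact_fraction(self._two_chain_mesh(1.0))
        assert overall == 1.0
        assert per == {"a": 1.0, "b": 1.0}

    def test_matches_exhaustive_pair_scan(self, toy_ensemble):
        mesh = toy_ensemble[0]
        _, overall = interchain_contact_fraction(mesh, cutoff=8.0)
        beads = mesh.all_beads()
        cid = mesh.chain_ids()
        d = cdist(beads, beads)
        contact = np.zeros(len(mesh.chains), dtype=bool)
        ii, jj = np.nonzero(d <= 8.0)
        inter = cid[ii] != cid[jj]
        contact[np.unique(cid[ii[inter]])] = True
        assert overall == pytest.approx(contact.mean())

    def test_nonincreasing_under_cutoff_reduction(self, toy_ensemble):
        mesh = toy_ensemble[0]
        fracs = [interchain_contact_fraction(mesh, cutoff=c)[1]
                 for c in (10.0, 8.0, 6.0, 4.0)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestDensityMap:
    def test_single_bead_unit_conversion(self):
        from npcvoid.mesh import BeadChain, MeshConfiguration

        mesh = MeshConfiguration(chains=[BeadChain("a", [[0.0, 0.0, 0.0]])])
        gs = GridSpec((-5, -5, -5), (10, 10, 10), (1, 1, 1))
        m = density_map([mesh], gs)
        # 120 Da in a (1 nm)^3 voxel = 199.3 mg/mL
        assert m.values[0, 0, 0] == pytest.approx(199.26, abs=0.1)

    def test_mass_conservation(self, toy_ensemble):
        gs = GridSpec.from_bounds((-120, -120, -160), (120, 120, 160), 10.0)
        m = density_map(toy_ensemble, gs)
        total = m.values.sum() * gs.voxel_volume / 1660.53907  # back to Da
        expected = toy_ensemble[0].n_beads * 120.0
        assert total == pytest.approx(expected, rel=0.01)

    def test_c8_symmetrization_idempotent(self, toy_ensemble):
        mesh = toy_ensemble[0]
        # offset the grid so no symmetry-equivalent bead sits on a bin edge
        gs = GridSpec.from_bounds((-120.5, -120.5, -160.5),
                                  (120.5, 120.5, 160.5), 10.0)
        once = density_map([apply_symmetry(mesh, "c8")], gs, symmetry="none")
        again = density_map([apply_symmetry(mesh, "c8")], gs, symmetry="c8")
        assert np.allclose(once.values, again.values, atol=1e-9)

    def test_empty_ensemble_rejected(self):
        gs = GridSpec((-5, -5, -5), (10, 10, 10), (1, 1, 1))
        with pytest.raises(ValueError):
            density_map([], gs)


class TestChargeHydrophobicity:
    def test_polyglycine_zero(self):
        assert charge_hydrophobicity_ratio("G" * 30) == 0.0

    def test_polyaspartate_pinned_scale(self):
        # |charge| = 1; KD(D) = -3.5 -> h = 1/9 -> ratio = 9
        assert charge_hydrophobicity_ratio("DDDD") == pytest.approx(9.0)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        seq = "MKVLLRAGDENSTWYFPHQCI"
        perm = "".join(rng.permutation(list(seq)))
        assert (charge_hydrophobicity_ratio(seq)
                == pytest.approx(charge_hydrophobicity_ratio(perm)))

    def test_fg_like_sequence_below_threshold(self):
        # FG-repeat-like stretch: hydrophobic, nearly uncharged
        seq = "FSFGAQTSFGAKPFGSTNFGQ" * 3
        assert charge_hydrophobicity_ratio(seq) < 0.3

    def test_unknown_letter_rejected(self):
        with pytest.raises(ValueError):
            charge_hydrophobicity_ratio("ABXZ")
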