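"""The four-component potential: indicators, totals, incremental deltas."""

import io
import random

import numpy as np
import pytest

from betalattice import (
    COIL,
    STRAND,
    Chain,
    EnergyParams,
    InteractionMatrix,
    System,
    energy_delta,
    total_energy,
)
from betalattice.energy import (
    chain_insertion_delta,
    chain_removal_delta,
    direction_interaction,
    eval_delta_applied,
    hb_indicator,
    solvent_indicator,
    steric_indicator,
)
from betalattice.fixtures import compact_cuboid_structure, random_system, seed_fibril
from betalattice.moves import MoveProposal, propose_local_move, propose_rigid_move

from conftest import one_hb_system, straight_three_mer
from _reference import brute_force_energy


class TestInteractionMatrix:
    def test_bundled_matrix_properties(self, matrix):
        e = matrix.entries
        assert np.array_equal(e, e.T)
        assert matrix.pair("SOL", "SOL") == 0.0
        # hydrophobic pairs strongly attractive, polar pairs nearly neutral
        assert matrix.pair("I", "I") < -40
        assert matrix.pair("F", "F") < -25
        assert abs(matrix.pair("D", "K")) < 10
        # solvent exposure: costly for hydrophobics, favourable for polars
        assert matrix.solvent("F") > 0 > matrix.solvent("D")
        # dyadic quantisation for exact bookkeeping
        assert np.all(e * 4 == np.round(e * 4))

    def test_file_round_trip(self, matrix):
        text = matrix.to_string()
        back = InteractionMatrix.from_file(io.StringIO(text))
        assert np.array_equal(back.entries, matrix.entries)

    def test_asymmetric_rejected(self):
        e = np.zeros((21, 21))
        e[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            InteractionMatrix(e)

    def test_nonzero_solvent_self_rejected(self):
        e = np.zeros((21, 21))
        e[20, 20] = -1.0
        with pytest.raises(ValueError, match="solvent"):
            InteractionMatrix(e)


class TestIndicators:
    def test_hb_lateral_strands(self, params):
        s = one_hb_system()
        assert hb_indicator(s, (0, 0), (1, 0), params) == 1
        assert hb_indicator(s, (1, 0), (0, 0), params) == 1

    def test_hb_requires_both_strand(self, params):
        s = one_hb_system()
        s.chains[1].states[0] = COIL
        assert hb_indicator(s, (0, 0), (1, 0), params) == 0

    def test_hb_requires_same_direction(self, params):
        s = one_hb_system()
        s.chains[1].dirs[0] = (0, 0, -1)
        assert hb_indicator(s, (0, 0), (1, 0), params) == 0

    def test_hb_perpendicularity_switchable(self):
        # side chains along the contact vector: excluded in strict mode only
        c1 = Chain("A", [(1, 1, 1)], [(0, 1, 0)], [STRAND])
        c2 = Chain("A", [(1, 2, 1)], [(0, 1, 0)], [STRAND])
        s = System(8, [c1, c2])
        assert hb_indicator(s, (0, 0), (1, 0), EnergyParams()) == 0
        loose = EnergyParams(hb_strict_perpendicular=False)
        assert hb_indicator(s, (0, 0), (1, 0), loose) == 1

    def test_direction_facing(self):
        c1 = Chain("A", [(1, 1, 1)], [(0, 1, 0)])
        c2 = Chain("A", [(1, 2, 1)], [(0, -1, 0)])
        s = System(8, [c1, c2])
        assert direction_interaction(s, (0, 0), (1, 0)) == 1

    def test_direction_parallel_lateral(self):
        c1 = Chain("A", [(1, 1, 1)], [(0, 0, 1)])
        c2 = Chain("A", [(1, 2, 1)], [(0, 0, 1)])
        s = System(8, [c1, c2])
        assert direction_interaction(s, (0, 0), (1, 0)) == 1

    def test_direction_pointing_away(self):
        c1 = Chain("A", [(1, 1, 1)], [(0, -1, 0)])
        c2 = Chain("A", [(1, 2, 1)], [(0, 1, 0)])
        s = System(8, [c1, c2])
        assert direction_interaction(s, (0, 0), (1, 0)) == 0

    def test_direction_parallel_along_contact(self):
        # parallel but pointing along the contact vector: no interaction
        c1 = Chain("A", [(1, 1, 1)], [(0, 1, 0)])
        c2 = Chain("A", [(1, 2, 1)], [(0, 1, 0)])
        s = System(8, [c1, c2])
        assert direction_interaction(s, (0, 0), (1, 0)) == 0

    def test_steric(self):
        s = straight_three_mer([(0, 0, 1), (0, 0, 1), (0, 0, -1)])
        assert steric_indicator(s, 0, 0) == 1
        assert steric_indicator(s, 0, 1) == 0
        with pytest.raises(IndexError):
            steric_indicator(s, 0, 2)

    def test_solvent_exposed_and_blocked(self):
        c1 = Chain("A", [(1, 1, 1)], [(0, 1, 0)])
        c2 = Chain("A", [(1, 2, 1)], [(0, 1, 0)])
        s = System(8, [c1, c2])
        assert solvent_indicator(s, (0, 0)) == 0  # points at the other chain
        assert solvent_indicator(s, (1, 0)) == 1  # points into vacuum

    def test_buried_core_residue_never_solvated(self):
        from betalattice import admissible_directions

        s = compact_cuboid_structure(3, 3, 4)
        chain = s.chains[0]
        checked = 0
        for ri, p in enumerate(chain.pos):
            if p in ((2, 2, 2), (2, 2, 3)):  # interior sites of the block
                for d in admissible_directions(s, 0, ri):
                    chain.dirs[ri] = d
                    assert solvent_indicator(s, (0, ri)) == 0
                    checked += 1
        assert checked > 0


class TestTotalEnergy:
    def test_two_residue_chain_zero_matrix(self, zero_matrix, params):
        chain = Chain("AA", [(1, 1, 1), (2, 1, 1)], [(0, 0, 1), (0, 0, -1)])
        s = System(8, [chain])
        assert total_energy(s, zero_matrix, params).total == 0.0

    def test_single_hydrogen_bond_scores_minus_fifty(self, zero_matrix, params):
        e = total_energy(one_hb_system(), zero_matrix, params)
        assert e.e_hb == -50.0
        assert e.total == -50.0

    def test_single_steric_pair_scores_plus_fiftyfive(self, zero_matrix, params):
        s = straight_three_mer([(0, 0, 1), (0, 0, 1), (0, 0, -1)])
        e = total_energy(s, zero_matrix, params)
        assert e.e_steric == 55.0
        assert e.total == 55.0

    def test_unknown_amino_acid_reported(self, matrix, params):
        chain = Chain("AZ", [(1, 1, 1), (2, 1, 1)], [(0, 0, 1), (0, 0, 1)])
        s = System(8, [chain])
        with pytest.raises(KeyError, match="residue 1"):
            total_energy(s, matrix, params)

    def test_oracle_equivalence_random_systems(self, matrix, params):
        rng = random.Random(7)
        for trial in range(120):
            s = random_system(random.Random(trial), n_chains=rng.randrange(1, 4),
                              length=rng.randrange(3, 13),
                              box=rng.choice([5, 8, 12]))
            mine = total_energy(s, matrix, params)
            ref = brute_force_energy(s, matrix, params)
            assert mine.e_hb == ref["e_hb"]
            assert mine.e_aa == ref["e_aa"]
            assert mine.e_solvent == ref["e_solvent"]
            assert mine.e_steric == ref["e_steric"]
            assert mine.total == ref["total"]

    def test_translation_and_relabel_invariance(self, matrix, params):
        s = random_system(random.Random(42), n_chains=2, length=8, box=10)
        e0 = total_energy(s, matrix, params).total
        for chain in s.chains:
            chain.pos = [s.wrap((x + 4, y + 1, z + 7)) for x, y, z in chain.pos]
        s.rebuild_occupancy()
        assert total_energy(s, matrix, params).total == e0
        s.chains.reverse()
        s.rebuild_occupancy()
        assert total_energy(s, matrix, params).total == e0

    def test_state_of_unbonded_residue_is_free(self, matrix, params):
        # with zero state energy, flipping a strand residue that has no
        # hydrogen-bond partner cannot change the energy
        s = seed_fibril(2, "TFTFTFT", box=12)
        # an isolated straight 3-mer far from the fibril: its middle
        # residue can be strand but has no partner, so its state is free
        chain = Chain("AAA", [(1, 8, 8), (2, 8, 8), (3, 8, 8)],
                      [(0, 0, 1), (0, 0, -1), (0, 0, 1)])
        s.add_chain(chain)
        e1 = total_energy(s, matrix, params).total
        chain.states[1] = STRAND
        assert total_energy(s, matrix, params).total == e1

    def test_hb_valence_capped_at_two(self, params, zero_matrix):
        # an internal strand residue has straight backbone occupying two of
        # the four perpendicular contact sites, leaving at most two
        # hydrogen-bond partners; build that maximal arrangement
        mid = Chain("AAA", [(3, 3, 3), (4, 3, 3), (5, 3, 3)],
                    [(0, 0, 1), (0, 0, 1), (0, 0, 1)], [COIL, STRAND, COIL])
        mid.dirs[0] = (0, 0, -1)
        mid.dirs[2] = (0, 0, -1)
        up = Chain("AAA", [(3, 4, 3), (4, 4, 3), (5, 4, 3)],
                   [(0, 0, -1), (0, 0, 1), (0, 0, -1)], [COIL, STRAND, COIL])
        down = Chain("AAA", [(3, 2, 3), (4, 2, 3), (5, 2, 3)],
                     [(0, 0, -1), (0, 0, 1), (0, 0, -1)], [COIL, STRAND, COIL])
        s = System(12, [mid, up, down])
        e = total_energy(s, zero_matrix, params)
        assert e.e_hb == 2 * params.eps_hb
        # the remaining perpendicular sites of the centre residue are its
        # own backbone: no further partner can be placed
        extra = Chain("A", [(5, 3, 3)], [(0, 0, 1)], [STRAND])
        s2 = System(12, [mid, up, down])
        with pytest.raises(ValueError):
            s2.add_chain(extra)


class TestEnergyDelta:
    def test_null_move_zero(self, matrix, params):
        s = random_system(random.Random(1), n_chains=1, length=6, box=10)
        prop = MoveProposal("side_chain_rotate", (0, 2), True, None,
                            [("dir", 0, 2, s.chains[0].dirs[2], s.chains[0].dirs[2])])
        assert energy_delta(s, prop, matrix, params).total == 0.0

    def test_side_chain_rotation_solvent_only(self, matrix, params):
        chain = Chain("F", [(5, 5, 5)], [(0, 0, 1)])
        s = System(12, [chain])
        prop = MoveProposal("side_chain_rotate", (0, 0), True, None,
                            [("dir", 0, 0, (0, 0, 1), (0, 1, 0))])
        d = energy_delta(s, prop, matrix, params)
        assert d.total == 0.0 and d.e_hb == 0.0 and d.e_aa == 0.0

    def test_delta_equals_full_recompute(self, matrix, params):
        s = random_system(random.Random(5), n_chains=2, length=9, box=9)
        rng = random.Random(11)
        for _ in range(400):
            prop = (propose_local_move(s, rng) if rng.random() < 0.8
                    else propose_rigid_move(s, rng))
            if not prop.valid:
                continue
            before = total_energy(s, matrix, params).total
            d, _ = eval_delta_applied(s, prop, matrix, params)
            after = total_energy(s, matrix, params).total
            assert d.total == after - before  # exact: dyadic energies
            if rng.random() < 0.5:
                prop.revert(s)

    def test_insertion_and_removal_deltas(self, matrix, params):
        s = random_system(random.Random(8), n_chains=2, length=7, box=9)
        rod = Chain("TFT", [(0, 0, 0), (0, 1, 0), (0, 2, 0)],
                    [(0, 0, 1), (0, 0, -1), (0, 0, 1)])
        if any(p in s.occ for p in rod.pos):
            pytest.skip("random layout occupies the probe sites")
        before = total_energy(s, matrix, params).total
        d_ins = chain_insertion_delta(s, rod, matrix, params)
        ci = s.add_chain(rod)
        mid = total_energy(s, matrix, params).total
        assert mid - before == d_ins.total
        d_rem = chain_removal_delta(s, ci, matrix, params)
        s.remove_chain(ci)
        assert total_energy(s, matrix, params).total - mid == d_rem.total
        assert d_rem.total == -d_ins.total
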