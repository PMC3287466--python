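import math

import numpy as np
import pytest

from rotamrf import fixtures as fx
from rotamrf.inference import exact_marginals, lbp
from rotamrf.interaction_graph import build_graph
from rotamrf.potentials import (
    EnergyParams,
    HBondParams,
    assemble_mrf,
    atom_pair_energy,
    boltzmann_potential,
    edge_energy,
    hbond_energy,
    prior_energy,
    vertex_energy,
)
from rotamrf.rotamer_library import RotamerRecord
from rotamrf.structure_io import build_side_chain

PARAMS = EnergyParams()


class TestAtomPairEnergy:
    def test_zero_beyond_contact(self):
        assert atom_pair_energy(4.0, 1.6, 1.6, PARAMS) == 0.0
        assert atom_pair_energy(3.2, 1.6, 1.6, PARAMS) == 0.0  # exactly r_ab

    def test_saturates_at_emax(self):
        assert atom_pair_energy(1.0, 1.6, 1.6, PARAMS) == 10.0
        lo = PARAMS.k_sc * 3.2
        assert atom_pair_energy(lo, 1.6, 1.6, PARAMS) == 10.0

    def test_linear_midpoint(self):
        r_ab = 3.2
        mid = (PARAMS.k_sc * r_ab + r_ab) / 2
        assert atom_pair_energy(mid, 1.6, 1.6, PARAMS) == pytest.approx(5.0)

    def test_continuous_nonincreasing_bounded(self):
        r_a = r_b = 1.45
        grid = np.linspace(0.0, 4.0, 10_000)
        vals = np.array([atom_pair_energy(d, r_a, r_b, PARAMS) for d in grid])
        assert np.all(np.diff(vals) <= 1e-12)
        assert np.max(np.abs(np.diff(vals))) < 10.0 * (grid[1] - grid[0]) / (
            (1 - PARAMS.k_sc) * (r_a + r_b)
        ) + 1e-9
        assert vals.min() >= 0.0 and vals.max() <= PARAMS.E_max


class TestPriorTerm:
    def test_zero_at_pmax(self):
        rec = RotamerRecord("SER", (1, 0, 0, 0), 0.4, (-60.0,))
        assert prior_energy(rec, 0.4, PARAMS) == 0.0

    def test_kd_at_pmax_over_e(self):
        p_max = 0.5
        rec = RotamerRecord("SER", (1, 0, 0, 0), p_max / math.e, (-60.0,))
        assert prior_energy(rec, p_max, PARAMS) == pytest.approx(3.0)

    def test_monotone_in_probability(self):
        energies = [
            prior_energy(RotamerRecord("SER", (1, 0, 0, 0), p, (-60.0,)), 0.5, PARAMS)
            for p in (0.5, 0.3, 0.1, 0.01, 0.0)
        ]
        assert energies == sorted(energies)
        assert np.isfinite(energies[-1])  # zero probability floored


class TestVertexEdgeEnergy:
    def test_isolated_vertex_top_rotamer_zero(self, bundle):
        graph = build_graph(bundle.residues, threshold=0.1, lib=bundle.library)
        i = 3
        rot = graph.candidates[i][0]
        assert vertex_energy(i, rot, bundle.residues, graph, PARAMS) == 0.0

    def test_clash_adds_emax_per_overlapping_pair(self, bundle):
        graph = build_graph(bundle.residues, lib=bundle.library)
        i = 5
        rot = graph.candidates[i][0]
        base = vertex_energy(i, rot, bundle.residues, graph, PARAMS)
        assert base >= prior_energy(rot, graph.candidates[i][0].probability, PARAMS)

    def test_edge_energy_symmetric(self, bundle):
        graph = build_graph(bundle.residues, lib=bundle.library)
        params = EnergyParams(hbond=HBondParams(enabled=False))
        for i, j in graph.edge_list()[:5]:
            ri = graph.candidates[i][0]
            rj = graph.candidates[j][-1]
            assert edge_energy(i, j, ri, rj, bundle.residues, params) == pytest.approx(
                edge_energy(j, i, rj, ri, bundle.residues, params), abs=1e-12
            )

    def test_gly_contributes_no_side_chain_pairs(self):
        pdb, residues = fx.make_backbone(
            fx.FixtureSpec(n_residues=3, sequence=["GLY", "SER", "GLY"])
        )
        from rotamrf.rotamer_library import lookup, parse_library

        lib = parse_library(fx.make_library(["SER"]))
        params = EnergyParams(hbond=HBondParams(enabled=False))
        rg = lookup(lib, "GLY", -60, -40)[0]
        rs = lookup(lib, "SER", -60, -40)[0]
        assert edge_energy(0, 1, rg, rs, residues, params) == edge_energy(
            1, 0, rs, rg, residues, params
        )
        assert edge_energy(0, 2, rg, rg, residues, params) == 0.0

    def test_distant_side_chains_no_energy(self):
        spec = fx.FixtureSpec(n_residues=2, sequence=["SER", "SER"], mode="extended")
        _, residues = fx.make_backbone(spec)
        # extended conformation: neighboring SER side chains stay > r_ab apart
        params = EnergyParams(hbond=HBondParams(enabled=False))
        from rotamrf.rotamer_library import lookup, parse_library

        lib = parse_library(fx.make_library(["SER"]))
        r = lookup(lib, "SER", None, None)[0]
        e = edge_energy(0, 1, r, r, residues, params)
        assert e >= 0.0


class TestHBond:
    def test_disabled_is_zero(self, bundle):
        params = HBondParams(enabled=False)
        res = bundle.residues
        c0 = build_side_chain(res[0], [-60.0] if res[0].aa != "VAL" else [-60.0])
        assert hbond_energy(res[0], res[1], c0, c0, params) == 0.0

    def test_no_donor_acceptor_pair_is_zero(self, helix):
        _, residues = helix
        val = type(residues[2])(index=0, aa="VAL", atoms=residues[2].atoms)
        leu = type(residues[5])(index=1, aa="LEU", atoms=residues[5].atoms)
        cv = build_side_chain(val, [-60.0])
        cl = build_side_chain(leu, [-60.0, 170.0])
        assert hbond_energy(val, leu, cv, cl, HBondParams()) == 0.0

    def test_optimum_geometry_scores_exactly_weight(self, helix):
        """A SER donor at exactly the optimal O–O distance contributes `weight`."""
        _, residues = helix
        params = HBondParams()
        ser = type(residues[2])(index=0, aa="SER", atoms=residues[2].atoms)
        conf = build_side_chain(ser, [-60.0])
        og = next(a for a in conf.atoms if a.name == "OG")
        cb = next(a for a in conf.atoms if a.name == "CB")
        # synthetic acceptor: ASP with a single OD1 along the CB->OG axis
        direction = og.position - cb.position
        direction /= np.linalg.norm(direction)
        from rotamrf.structure_io import AtomCoord, SideChainConformation

        acc = SideChainConformation(
            1, [], [AtomCoord("O", "OD1", og.position + params.distance_opt * direction)]
        )
        asp = type(ser)(index=1, aa="ASP", atoms=residues[5].atoms)
        e = hbond_energy(ser, asp, conf, acc, params)
        assert e == pytest.approx(params.weight)


class TestAssembleMRF:
    def test_single_residue_mrf(self):
        pdb, residues = fx.make_backbone(fx.FixtureSpec(n_residues=1))
        from rotamrf.rotamer_library import parse_library

        lib = parse_library(fx.make_library(["SER"]))
        graph = build_graph(residues, lib=lib)
        mrf = assemble_mrf(residues, graph)
        assert len(mrf.vertex_potentials) == 1
        assert mrf.edge_potentials == {}

    def test_all_potentials_positive(self, small_mrf):
        mrf, _ = small_mrf
        assert all(np.all(v > 0) for v in mrf.vertex_potentials.values())
        assert all(np.all(m > 0) for m in mrf.edge_potentials.values())

    def test_edge_matrix_transpose_consistency(self, small_mrf):
        mrf, _ = small_mrf
        for i, j in list(mrf.edge_potentials)[:3]:
            assert np.array_equal(mrf.edge_matrix(i, j), mrf.edge_matrix(j, i).T)

    def test_exact_joint_normalizes(self, bundle):
        graph = build_graph(bundle.residues[:3], lib=bundle.library)
        mrf = assemble_mrf(bundle.residues[:3], graph)
        ms = exact_marginals(mrf)
        for i in graph.vertices:
            assert ms[i].sum() == pytest.approx(1.0, abs=1e-12)

    def test_boltzmann_values(self):
        assert boltzmann_potential(0.0, 0.6) == 1.0
        assert boltzmann_potential(0.6, 0.6) == pytest.approx(math.exp(-1))

    def test_energy_shift_leaves_marginals_invariant(self, small_mrf):
        """Scaling one vertex potential (≡ shifting its energies) is a no-op."""
        mrf, graph = small_mrf
        base = lbp(mrf)
        shifted = {i: v.copy() for i, v in mrf.vertex_potentials.items()}
        shifted[2] = shifted[2] * 37.5  # exp(-ΔE/kBT) for a uniform ΔE
        from rotamrf.potentials import MarkovRandomField

        mrf2 = MarkovRandomField(graph, shifted, mrf.edge_potentials)
        pert = lbp(mrf2)
        for i in graph.vertices:
            assert np.max(np.abs(base[i] - pert[i])) < 1e-9
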