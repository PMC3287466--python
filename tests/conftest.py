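import numpy as np
import pytest

from rotamrf import fixtures as fx
from rotamrf.interaction_graph import build_graph
from rotamrf.potentials import EnergyParams, HBondParams, assemble_mrf


@pytest.fixture(scope="session")
def helix():
    """A 10-residue ideal poly-SER α-helix (PDB text + annotated residues)."""
    return fx.make_backbone(fx.FixtureSpec(n_residues=10, seed=1))


@pytest.fixture(scope="session")
def bundle():
    """Ground-truth bundle: helix, truth at the top library rotamer."""
    return fx.make_ground_truth_bundle(n_residues=12, truth_choice="top", seed=5)


@pytest.fixture(scope="session")
def small_mrf(bundle):
    graph = build_graph(bundle.residues, lib=bundle.library)
    params = EnergyParams(hbond=HBondParams(enabled=False))
    return assemble_mrf(bundle.residues, graph, params), graph


def max_belief_diff(a, b, vertices):
    return max(float(np.max(np.abs(a[i] - b[i]))) for i in vertices)
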