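"""Residue interaction graph: the MRF topology.

Two residues are joined by an edge when any pair of their Cα, Cβ and
carbonyl-O atoms lies strictly closer than the contact threshold (10 Å by
default).  Glycine, lacking Cβ, contributes only Cα and O.  Topology depends
on backbone atoms only; rotamers never prune edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .rotamer_library import RotamerLibrary, RotamerRecord, lookup
from .structure_io import ResidueBackbone

CONTACT_ATOMS = ("CA", "CB", "O")
DEFAULT_THRESHOLD = 10.0  # Å


@dataclass
class InteractionGraph:
    """Residue indices as vertices, contact pairs as undirected edges."""

    vertices: List[int]
    edges: Set[FrozenSet[int]]
    candidates: Dict[int, List[RotamerRecord]] = field(default_factory=dict)
    #: residues whose candidates came from the backbone-independent fallback
    fallback_vertices: Set[int] = field(default_factory=set)

    def neighbors(self, i: int) -> List[int]:
        return sorted(j for e in self.edges if i in e for j in e if j != i)

    def has_edge(self, i: int, j: int) -> bool:
        return frozenset((i, j)) in self.edges

    def edge_list(self) -> List[Tuple[int, int]]:
        return sorted(tuple(sorted(e)) for e in self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edge_list())
        return g

    def dump_edge_list(self) -> str:
        return "\n".join(f"{i}\t{j}" for i, j in self.edge_list()) + "\n"


def _contact_coords(res: ResidueBackbone) -> np.ndarray:
    names = [n for n in CONTACT_ATOMS if n in res.atoms]
    return np.stack([res.pos(n) for n in names])


def build_graph(
    residues: Sequence[ResidueBackbone],
    threshold: float = DEFAULT_THRESHOLD,
    lib: Optional[RotamerLibrary] = None,
) -> InteractionGraph:
    """Build the contact graph; optionally attach candidate rotamer lists.

    Edges obey a strict ``< threshold`` on the minimum Cα/Cβ/O cross-pair
    distance.  A k-d tree prunes candidate pairs; the strict comparison is
    applied to exact distances, so output is identical at any problem size.
    """
    coords, owner = [], []
    for res in residues:
        pts = _contact_coords(res)
        coords.append(pts)
        owner.extend([res.index] * len(pts))
    allpts = np.concatenate(coords)
    owner_arr = np.array(owner)
    tree = cKDTree(allpts)
    edges: Set[FrozenSet[int]] = set()
    for a, b in tree.query_pairs(r=threshold, output_type="ndarray"):
        i, j = owner_arr[a], owner_arr[b]
        if i == j:
            continue
        if np.linalg.norm(allpts[a] - allpts[b]) < threshold:
            edges.add(frozenset((int(i), int(j))))

    graph = InteractionGraph(vertices=[r.index for r in residues], edges=edges)
    if lib is not None:
        for res in residues:
            graph.candidates[res.index] = lookup(lib, res.aa, res.phi, res.psi)
            if res.phi is None or res.psi is None:
                graph.fallback_vertices.add(res.index)
    return graph
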