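"""Turn inferred marginals into the protein-dependent rotamer library.

Re-ranking sorts each residue's candidate rotamers by the updated marginal
probability (ties keep the input prior order); thresholding to the top
entry yields a side-chain prediction.  No clash resolution is attempted:
the top-1 assignment is a library readout, not a packed structure.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .inference import MarginalSet
from .interaction_graph import InteractionGraph
from .rotamer_library import RotamerRecord


@dataclass
class ProteinDependentLibrary:
    """Per-residue rotamer distributions, sorted by updated probability."""

    entries: Dict[int, List[Tuple[RotamerRecord, float]]]
    algorithm: str = ""
    converged: bool = True
    parameter_hash: str = ""
    provenance: Dict[str, str] = field(default_factory=dict)

    def probabilities(self, i: int) -> np.ndarray:
        return np.array([p for _, p in self.entries[i]])

    def records(self, i: int) -> List[RotamerRecord]:
        return [r for r, _ in self.entries[i]]


def parameter_hash(*objects) -> str:
    h = hashlib.sha256()
    for obj in objects:
        h.update(repr(obj).encode())
    return h.hexdigest()[:12]


def rerank(marginals: MarginalSet, graph: InteractionGraph) -> ProteinDependentLibrary:
    """Sort each residue's candidates by descending marginal probability.

    The sort is stable over the input (prior) order, so exact ties preserve
    the library's original ranking.  Probabilities are renormalized to sum
    to 1 per residue.
    """
    entries: Dict[int, List[Tuple[RotamerRecord, float]]] = {}
    for i, recs in graph.candidates.items():
        probs = np.asarray(marginals[i], dtype=float)
        if len(probs) != len(recs):
            raise ValueError(
                f"residue {i}: marginal length {len(probs)} != "
                f"{len(recs)} candidates"
            )
        probs = probs / probs.sum()
        order = sorted(range(len(recs)), key=lambda k: -probs[k])
        entries[i] = [(recs[k], float(probs[k])) for k in order]
    return ProteinDependentLibrary(
        entries,
        algorithm=marginals.algorithm,
        converged=marginals.converged,
    )


def predict_top1(lib: ProteinDependentLibrary) -> Dict[int, RotamerRecord]:
    """Most probable rotamer per residue (the library's point prediction)."""
    if not lib.entries:
        raise ValueError("empty protein-dependent library")
    return {i: recs[0][0] for i, recs in lib.entries.items()}
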