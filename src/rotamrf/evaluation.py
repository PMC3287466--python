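"""Scoring of rotamer libraries and predictions against true χ angles.

A predicted χ is correct when its wrap-around angular distance to the
experimental value is within 40° (strict).  Cumulative levels are judged
jointly: χ1+2 requires both χ1 and χ2 correct, and so on.  ALA and GLY
carry no χ and are excluded.  Optionally, 180°-symmetric χ angles
(PHE/TYR χ2, ASP χ2, GLU χ3, ARG NH χ4) can be folded before comparison;
the default leaves them unfolded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .library_output import ProteinDependentLibrary
from .rotamer_library import RotamerRecord
from .structure_io import CHI_COUNT

DEFAULT_CUTOFF = 40.0
LEVELS = ["chi1", "chi1+2", "chi1+2+3", "chi1+2+3+4"]

#: χ levels with a 180° end-group symmetry (used only when folding is on)
SYMMETRIC_CHI = {("ASP", 2), ("GLU", 3), ("PHE", 2), ("TYR", 2), ("ARG", 4)}


class EvaluationError(ValueError):
    pass


@dataclass
class ChiComparison:
    residue_index: int
    aa: str
    #: flags for cumulative levels χ1, χ1+2, ...; None where the aa lacks them
    levels: List[Optional[bool]]


def angular_distance(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def chi_correct(
    pred: float,
    true: float,
    cutoff: float = DEFAULT_CUTOFF,
    symmetric: bool = False,
) -> bool:
    """Wrap-around |Δχ| < cutoff; with ``symmetric`` also tries χ+180°."""
    if pred is None or true is None:
        raise EvaluationError("chi angle undefined")
    d = angular_distance(pred, true)
    if symmetric:
        d = min(d, angular_distance(pred + 180.0, true))
    return d < cutoff


def compare_chis(
    aa: str,
    pred: Sequence[Optional[float]],
    true: Sequence[Optional[float]],
    cutoff: float = DEFAULT_CUTOFF,
    fold_symmetric: bool = False,
) -> List[Optional[bool]]:
    """Cumulative per-level flags for one residue (None past its χ count)."""
    n = CHI_COUNT[aa]
    flags: List[Optional[bool]] = [None] * 4
    ok = True
    for k in range(n):
        if pred[k] is None or true[k] is None:
            ok = False
        else:
            sym = fold_symmetric and (aa, k + 1) in SYMMETRIC_CHI
            ok = ok and chi_correct(pred[k], true[k], cutoff, sym)
        flags[k] = ok
    return flags


def accuracy_table(
    predictions: Dict[int, Sequence[Optional[float]]],
    truths: Dict[int, Sequence[Optional[float]]],
    aas: Dict[int, str],
    cutoff: float = DEFAULT_CUTOFF,
    fold_symmetric: bool = False,
) -> pd.DataFrame:
    """Per-amino-acid and overall cumulative χ accuracies (percent).

    ``predictions``/``truths`` map residue index → χ list; ``aas`` maps
    index → 3-letter code.  Residues without χ (ALA/GLY) are skipped; the
    overall row is residue-weighted.
    """
    rows: List[ChiComparison] = []
    for i, aa in aas.items():
        if CHI_COUNT.get(aa, 0) == 0:
            continue
        if i not in predictions or i not in truths:
            raise EvaluationError(f"residue {i} missing from predictions or truths")
        rows.append(
            ChiComparison(i, aa, compare_chis(aa, predictions[i], truths[i],
                                              cutoff, fold_symmetric))
        )
    if not rows:
        raise EvaluationError("no scoreable residues")
    records = []
    for aa in sorted({r.aa for r in rows}) + ["ALL"]:
        sub = rows if aa == "ALL" else [r for r in rows if r.aa == aa]
        rec = {"aa": aa, "n": len(sub)}
        for k, name in enumerate(LEVELS):
            vals = [r.levels[k] for r in sub if r.levels[k] is not None]
            rec[name] = 100.0 * np.mean(vals) if vals else np.nan
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("aa")


def _first_correct_rank(
    recs: Sequence[RotamerRecord],
    true: Sequence[Optional[float]],
    level: int,
    cutoff: float,
    fold_symmetric: bool,
) -> Optional[int]:
    for rank, rec in enumerate(recs, start=1):
        flags = compare_chis(rec.aa, list(rec.chi_means) + [None] * 4,
                             true, cutoff, fold_symmetric)
        if flags[level - 1]:
            return rank
    return None


def average_first_correct_rank(
    lib: ProteinDependentLibrary,
    truths: Dict[int, Sequence[Optional[float]]],
    level: int = 1,
    cutoff: float = DEFAULT_CUTOFF,
    fold_symmetric: bool = False,
) -> Tuple[float, int]:
    """Mean 1-based rank of the first correct rotamer at a cumulative level.

    Residues whose list contains no correct rotamer at all are excluded from
    the mean and returned as a separate count (second element).
    """
    ranks, missing = [], 0
    for i, entries in lib.entries.items():
        aa = entries[0][0].aa
        if CHI_COUNT[aa] < level:
            continue
        r = _first_correct_rank([rec for rec, _ in entries], truths[i],
                                level, cutoff, fold_symmetric)
        if r is None:
            missing += 1
        else:
            ranks.append(r)
    if not ranks:
        raise EvaluationError("no residue with a correct rotamer at this level")
    return float(np.mean(ranks)), missing


def topk_correct_probability(
    lib: ProteinDependentLibrary,
    truths: Dict[int, Sequence[Optional[float]]],
    k: int = 1,
    level: int = 1,
    cutoff: float = DEFAULT_CUTOFF,
    fold_symmetric: bool = False,
) -> float:
    """Mean over residues of the probability mass on correct rotamers in the top k."""
    scores = []
    for i, entries in lib.entries.items():
        aa = entries[0][0].aa
        if CHI_COUNT[aa] < level:
            continue
        mass = 0.0
        for rec, p in entries[:k]:
            flags = compare_chis(aa, list(rec.chi_means) + [None] * 4,
                                 truths[i], cutoff, fold_symmetric)
            if flags[level - 1]:
                mass += p
        scores.append(mass)
    if not scores:
        raise EvaluationError("no scoreable residues at this level")
    return float(np.mean(scores))


def ranking_table(
    lib: ProteinDependentLibrary,
    truths: Dict[int, Sequence[Optional[float]]],
    cutoff: float = DEFAULT_CUTOFF,
    fold_symmetric: bool = False,
) -> pd.DataFrame:
    """Rank / top-k probability summary for χ1 and χ1+2."""
    records = []
    for level, name in ((1, "chi1"), (2, "chi1+2")):
        try:
            rank, missing = average_first_correct_rank(
                lib, truths, level, cutoff, fold_symmetric
            )
        except EvaluationError:
            continue
        rec = {"level": name, "avg_rank": rank, "no_correct": missing}
        for k in (1, 2, 3):
            rec[f"top{k}_prob"] = topk_correct_probability(
                lib, truths, k, level, cutoff, fold_symmetric
            )
        records.append(rec)
    if not records:
        raise EvaluationError("nothing to rank")
    return pd.DataFrame.from_records(records).set_index("level")
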