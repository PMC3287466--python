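"""Backbone-dependent rotamer libraries in Dunbrack-style text.

The whitespace-delimited format is both the method's input (a
backbone-dependent library: rotamer priors keyed by amino acid and a
10°-gridded (φ,ψ) bin) and, extended with a residue-index column, its output
(the protein-dependent library).  Both the 2002 interleaved (χ,σ pairs) and
the 2010 grouped (χ1..χ4 then σ1..σ4) column dialects are accepted; the
dialect is sniffed from the sign pattern of the trailing numeric columns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .structure_io import CHI_COUNT, wrap_angle

log = logging.getLogger(__name__)

PROB_FLOOR = 1e-6  # priors are floored before the log-prior energy term


class LibraryError(ValueError):
    pass


@dataclass(frozen=True)
class RotamerRecord:
    """One discrete side-chain conformation with its prior probability."""

    aa: str
    rotamer_id: Tuple[int, ...]
    probability: float
    chi_means: Tuple[float, ...]
    chi_sigmas: Tuple[float, ...] = ()

    def __post_init__(self):
        if self.probability < 0:
            raise ValueError("negative rotamer probability")
        if self.aa in CHI_COUNT and len(self.chi_means) != CHI_COUNT[self.aa]:
            raise ValueError(
                f"{self.aa} expects {CHI_COUNT[self.aa]} chi means, "
                f"got {len(self.chi_means)}"
            )

    def with_probability(self, p: float) -> "RotamerRecord":
        return RotamerRecord(self.aa, self.rotamer_id, p, self.chi_means, self.chi_sigmas)


@dataclass
class RotamerLibrary:
    """Rotamer records binned by (aa, φ-bin, ψ-bin), sorted by probability."""

    bins: Dict[Tuple[str, float, float], List[RotamerRecord]] = field(default_factory=dict)
    bin_width: float = 10.0

    def amino_acids(self) -> List[str]:
        return sorted({aa for aa, _, _ in self.bins})

    def bins_for(self, aa: str) -> List[Tuple[float, float]]:
        return sorted((p, s) for a, p, s in self.bins if a == aa)


def _sniff_dialect(rows: List[List[float]]) -> str:
    """Decide 2002 (interleaved χσ) vs 2010 (grouped) from sign patterns.

    σ columns are non-negative everywhere; χ-mean columns go negative for
    gauche− rotamers.  Columns 13–16 are χ3/χ4 positions only in the 2002
    layout; columns 10/12 are χ2/χ4 positions only in the 2010 layout.
    """
    neg = [any(r[c] < 0 for r in rows) for c in range(9, 17)]
    if neg[4] or neg[6]:   # cols 13, 15
        return "2002"
    if neg[1] or neg[3]:   # cols 10, 12
        return "2010"
    return "2002"


def parse_library(text: str, renorm_tol: float = 1e-3) -> RotamerLibrary:
    """Parse Dunbrack-style whitespace-delimited library text.

    Comment lines (#) are skipped.  Rows carry: aa, φ, ψ, count, r1..r4,
    probability, then eight χ/σ values in either dialect.  Per-bin
    probabilities are renormalized (with a warning) when they do not sum to
    1 within ``renorm_tol``.
    """
    raw: List[Tuple[int, str, List[float]]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 17:
            raise LibraryError(f"line {lineno}: expected ≥17 columns, got {len(parts)}")
        aa = parts[0].upper()
        if aa not in CHI_COUNT:
            raise LibraryError(f"line {lineno}: unknown amino acid {parts[0]!r}")
        try:
            vals = [float(x) for x in parts[1:17]]
        except ValueError as exc:
            raise LibraryError(f"line {lineno}: malformed row ({exc})") from exc
        raw.append((lineno, aa, vals))
    if not raw:
        raise LibraryError("library file contains no data rows")

    dialect = _sniff_dialect([[0.0] + v for _, _, v in raw])
    lib = RotamerLibrary()
    for lineno, aa, v in raw:
        phi, psi = v[0], v[1]
        rid = tuple(int(x) for x in v[3:7])
        prob = v[7]
        tail = v[8:16]
        if dialect == "2002":
            chis, sigs = tail[0::2], tail[1::2]
        else:
            chis, sigs = tail[:4], tail[4:]
        n = CHI_COUNT[aa]
        rec = RotamerRecord(
            aa=aa,
            rotamer_id=rid,
            probability=prob,
            chi_means=tuple(wrap_angle(c) for c in chis[:n]),
            chi_sigmas=tuple(sigs[:n]),
        )
        lib.bins.setdefault((aa, phi, psi), []).append(rec)

    for key, recs in lib.bins.items():
        total = sum(r.probability for r in recs)
        if total <= 0:
            raise LibraryError(f"bin {key}: zero total probability")
        if abs(total - 1.0) > renorm_tol:
            log.warning("bin %s probabilities sum to %.4f; renormalizing", key, total)
        recs[:] = sorted(
            (r.with_probability(r.probability / total) for r in recs),
            key=lambda r: -r.probability,
        )
    return lib


def _nearest_bin(centers: Sequence[float], value: float) -> float:
    def circdist(a, b):
        d = abs(a - b) % 360.0
        return min(d, 360.0 - d)

    return min(centers, key=lambda c: (circdist(c, value), c))


def lookup(
    lib: RotamerLibrary, aa: str, phi: Optional[float], psi: Optional[float]
) -> List[RotamerRecord]:
    """Candidate rotamers of ``aa`` at backbone (φ,ψ), nearest bin, wrapped.

    Zero-χ residues (ALA/GLY) always yield a single trivial record.  If φ or
    ψ is undefined (chain termini) the backbone-independent marginal over all
    of the amino acid's bins is returned instead, with a warning.
    """
    aa = aa.upper()
    if aa not in CHI_COUNT:
        raise LibraryError(f"unknown amino acid {aa!r}")
    if CHI_COUNT[aa] == 0:
        return [RotamerRecord(aa, (0, 0, 0, 0), 1.0, ())]
    keys = [(p, s) for a, p, s in lib.bins if a == aa]
    if not keys:
        raise LibraryError(f"no library bins for amino acid {aa}")
    if phi is None or psi is None:
        log.warning("undefined phi/psi for %s; backbone-independent fallback", aa)
        return marginal_over_bins(lib, aa)
    phis = sorted({p for p, _ in keys})
    psis = sorted({s for _, s in keys})
    key = (aa, _nearest_bin(phis, wrap_angle(phi)), _nearest_bin(psis, wrap_angle(psi)))
    return list(lib.bins[key])


def marginal_over_bins(lib: RotamerLibrary, aa: str) -> List[RotamerRecord]:
    """Average each rotamer class over all (φ,ψ) bins of ``aa`` (circular χ mean)."""
    groups: Dict[Tuple[int, ...], List[RotamerRecord]] = {}
    for (a, _, _), recs in lib.bins.items():
        if a != aa:
            continue
        for r in recs:
            groups.setdefault(r.rotamer_id, []).append(r)
    out = []
    for rid, recs in groups.items():
        p = sum(r.probability for r in recs) / len(recs)
        n = len(recs[0].chi_means)
        means = []
        for k in range(n):
            s = sum(math.sin(math.radians(r.chi_means[k])) for r in recs)
            c = sum(math.cos(math.radians(r.chi_means[k])) for r in recs)
            means.append(wrap_angle(math.degrees(math.atan2(s, c))))
        out.append(RotamerRecord(aa, rid, p, tuple(means)))
    total = sum(r.probability for r in out)
    out = [r.with_probability(r.probability / total) for r in out]
    return sorted(out, key=lambda r: -r.probability)


def floored_probability(p: float) -> float:
    """Prior floored to avoid infinite log-prior energies."""
    return max(p, PROB_FLOOR)


def _format_record(rec: RotamerRecord, phi: float, psi: float, prob: float) -> str:
    chis = list(rec.chi_means) + [0.0] * (4 - len(rec.chi_means))
    sigs = list(rec.chi_sigmas) + [0.0] * (4 - len(rec.chi_sigmas))
    inter = "  ".join(f"{c:8.1f} {s:6.1f}" for c, s in zip(chis, sigs))
    rid = " ".join(str(x) for x in rec.rotamer_id)
    return f"{rec.aa:<4s} {phi:6.0f} {psi:6.0f}  1  {rid}  {prob:.6f}  {inter}"


def write_library(lib: RotamerLibrary, header: str = "") -> str:
    """Serialize a backbone-dependent library in the 2002 dialect."""
    lines = [f"# {h}" for h in header.splitlines() if h]
    for (aa, phi, psi), recs in sorted(lib.bins.items()):
        for r in recs:
            lines.append(_format_record(r, phi, psi, r.probability))
    return "\n".join(lines) + "\n"


def write_protein_library(
    marginals,
    residues,
    candidates: Dict[int, List[RotamerRecord]],
    header: str = "",
) -> str:
    """Serialize the protein-dependent library: per-residue distributions.

    Same column layout as the input dialect plus a leading residue-index
    column; records per residue sorted by descending updated probability
    (stable, so ties keep prior order).  ``marginals`` maps residue index to
    a probability vector aligned with ``candidates[index]``.
    """
    lines = [f"# {h}" for h in header.splitlines() if h]
    for res in residues:
        recs = candidates[res.index]
        probs = marginals[res.index]
        if len(probs) != len(recs):
            raise LibraryError(
                f"residue {res.index}: marginal length {len(probs)} != "
                f"{len(recs)} candidates"
            )
        total = float(sum(probs))
        order = sorted(range(len(recs)), key=lambda k: -probs[k])
        phi = res.phi if res.phi is not None else 0.0
        psi = res.psi if res.psi is not None else 0.0
        for k in order:
            lines.append(
                f"{res.index:4d}  " + _format_record(recs[k], phi, psi, probs[k] / total)
            )
    return "\n".join(lines) + "\n"


def parse_protein_library(text: str) -> Dict[int, List[RotamerRecord]]:
    """Read back a protein-dependent library written by this package."""
    out: Dict[int, List[RotamerRecord]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        idx = int(parts[0])
        aa = parts[1].upper()
        if aa not in CHI_COUNT:
            raise LibraryError(f"line {lineno}: unknown amino acid {aa!r}")
        vals = [float(x) for x in parts[2:18]]
        rid = tuple(int(x) for x in vals[3:7])
        prob = vals[7]
        tail = vals[8:16]
        n = CHI_COUNT[aa]
        out.setdefault(idx, []).append(
            RotamerRecord(aa, rid, prob,
                          tuple(tail[0::2][:n]), tuple(tail[1::2][:n]))
        )
    if not out:
        raise LibraryError("empty protein-dependent library")
    return out
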