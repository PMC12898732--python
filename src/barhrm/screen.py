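"""Barcode-variant amplicon screening.

Aligns the two species' barcode sequences, locates the discriminatory
variants (SNPs and InDels), enumerates candidate amplicons flanking
them, and applies the HRM screening rules: retain candidates with
predicted or measured inter-species ΔTm > 0.3 °C, drop single-SNP
candidates with ΔTm < 0.4 °C, and rank the survivors toward the
empirical HRM optimum (100–200 bp, 40–60% GC, multi-polymorphic).

Primer design proper is out of scope; a variant-free, identical flank
of configurable width on each side of the window stands in for
primer-binding compatibility, and the flank substrings are recorded as
the nominal primer sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import thermo
from .io import get_logger

__all__ = [
    "PairwiseAlignment",
    "VariantSite",
    "AmpliconCandidate",
    "ScreenEntry",
    "ScreenReport",
    "align_global",
    "find_variant_sites",
    "enumerate_amplicons",
    "screen_candidates",
]

_IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


@dataclass
class PairwiseAlignment:
    seq_a_id: str
    seq_b_id: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences differ in length")

    def degapped_a(self) -> str:
        return self.aligned_a.replace("-", "")

    def degapped_b(self) -> str:
        return self.aligned_b.replace("-", "")


@dataclass(frozen=True)
class VariantSite:
    """A species-discriminatory site on the alignment (0-based column)."""

    column: int
    kind: str  # "SNP" or "InDel"
    allele_a: str
    allele_b: str

    @property
    def span(self) -> int:
        return max(len(self.allele_a), len(self.allele_b))


@dataclass
class AmpliconCandidate:
    name: str
    region: str
    start: int  # 0-based half-open on the degapped species-A sequence
    end: int
    amplicon_a: str
    amplicon_b: str
    length_a: int
    length_b: int
    gc_a: float
    gc_b: float
    tm_a: float
    tm_b: float
    n_variants: int
    variant_kinds: frozenset[str]
    primer_fwd: str = ""
    primer_rev: str = ""
    variants: tuple[VariantSite, ...] = ()

    @property
    def predicted_delta_tm(self) -> float:
        return abs(self.tm_a - self.tm_b)


@dataclass
class ScreenEntry:
    name: str
    delta_tm: float
    pass_stage1: bool
    excluded_single_snp: bool
    in_optimal_window: bool
    rank_score: float
    retained: bool


@dataclass
class ScreenReport:
    entries: list[ScreenEntry]
    nominated: Optional[str]
    delta_tm_source: str  # "predicted" or "measured"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(e) for e in self.entries])
        df["nominated"] = df["name"] == self.nominated
        return df


# ---------------------------------------------------------------------------
# Global alignment (Needleman–Wunsch, affine gaps)
# ---------------------------------------------------------------------------

_NEG = -1e30


def align_global(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
    a_id: str = "a",
    b_id: str = "b",
) -> PairwiseAlignment:
    """Optimal global alignment with affine gap penalties.

    A gap of length L costs ``gap_open + (L-1)*gap_extend``. Traceback
    ties break deterministically: diagonal, then up (gap in ``b``), then
    left (gap in ``a``).
    """
    a = a.upper()
    b = b.upper()
    if not a or not b:
        raise ValueError("align_global: empty sequence")
    n, m = len(a), len(b)

    # M: (i,j) aligned; X: a[i] over gap; Y: b[j] over gap.
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)

    # Traceback; preference diag > up > left at every decision.
    i, j = n, m
    finals = (M[n, m], X[n, m], Y[n, m])
    score = max(finals)
    state = "MXY"[int(np.argmax(finals))]
    out_a: list[str] = []
    out_b: list[str] = []
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            s = match if a[i - 1] == b[j - 1] else mismatch
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - s
            i, j = i - 1, j - 1
            for st, val in (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])):
                if abs(val - target) < eps:
                    state = st
                    break
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            target = X[i, j]
            i -= 1
            if abs(M[i, j] + gap_open - target) < eps:
                state = "M"
            elif abs(X[i, j] + gap_extend - target) < eps:
                state = "X"
            else:
                state = "Y"
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            target = Y[i, j]
            j -= 1
            if abs(M[i, j] + gap_open - target) < eps:
                state = "M"
            elif abs(Y[i, j] + gap_extend - target) < eps:
                state = "Y"
            else:
                state = "X"
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"

    return PairwiseAlignment(
        seq_a_id=a_id,
        seq_b_id=b_id,
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
        score=float(score),
    )


# ---------------------------------------------------------------------------
# Variant discovery
# ---------------------------------------------------------------------------

def _compatible(x: str, y: str) -> bool:
    """True if the IUPAC sets of two bases overlap (column is not a variant)."""
    return bool(_IUPAC_SETS.get(x, set()) & _IUPAC_SETS.get(y, set()))


def find_variant_sites(aln: PairwiseAlignment) -> list[VariantSite]:
    """Discriminatory columns: isolated substitutions become SNPs; maximal
    runs of gap-bearing columns merge into single InDel sites."""
    variants: list[VariantSite] = []
    a, b = aln.aligned_a, aln.aligned_b
    i = 0
    ncol = len(a)
    while i < ncol:
        if a[i] == "-" or b[i] == "-":
            j = i
            while j < ncol and (a[j] == "-" or b[j] == "-"):
                j += 1
            variants.append(VariantSite(column=i, kind="InDel", allele_a=a[i:j], allele_b=b[i:j]))
            i = j
        else:
            if not _compatible(a[i], b[i]):
                variants.append(VariantSite(column=i, kind="SNP", allele_a=a[i], allele_b=b[i]))
            i += 1
    return variants


# ---------------------------------------------------------------------------
# Amplicon enumeration
# ---------------------------------------------------------------------------

def enumerate_amplicons(
    aln: PairwiseAlignment,
    variants: Sequence[VariantSite],
    min_len: int = 100,
    max_len: int = 250,
    flank: int = 20,
    stride: int = 5,
    region: str = "",
    params: thermo.ThermoParams = thermo.DEFAULT_PARAMS,
) -> list[AmpliconCandidate]:
    """Enumerate candidate amplicon windows around the variant sites.

    A window qualifies when its degapped length in both species lies in
    [min_len, max_len], its first and last ``flank`` columns are
    identical (gap- and variant-free, the primer-binding surrogate), and
    it contains at least one variant strictly inside the flanks.
    Windows carrying the same variant set are deduplicated keeping the
    shortest (then leftmost).
    """
    if not variants:
        raise ValueError("enumerate_amplicons: no variant sites supplied")
    a, b = aln.aligned_a, aln.aligned_b
    ncol = len(a)

    identity = np.fromiter(
        (a[k] != "-" and b[k] != "-" and _compatible(a[k], b[k]) for k in range(ncol)),
        dtype=bool,
        count=ncol,
    )
    # Columns occupied by any variant (InDel runs occupy their whole span).
    var_cols = np.zeros(ncol, dtype=bool)
    for v in variants:
        var_cols[v.column : v.column + v.span] = True
    ident_prefix = np.concatenate(([0], np.cumsum(identity)))
    len_a_prefix = np.concatenate(([0], np.cumsum([c != "-" for c in a])))
    len_b_prefix = np.concatenate(([0], np.cumsum([c != "-" for c in b])))

    def run_identical(lo: int, hi: int) -> bool:
        return ident_prefix[hi] - ident_prefix[lo] == hi - lo

    best_by_varset: dict[frozenset, tuple[int, int, int]] = {}
    for s in range(0, ncol - 2 * flank, stride):
        if not run_identical(s, s + flank):
            continue
        for e in range(s + min_len, min(s + max_len, ncol) + 1, stride):
            la = int(len_a_prefix[e] - len_a_prefix[s])
            lb = int(len_b_prefix[e] - len_b_prefix[s])
            if not (min_len <= la <= max_len and min_len <= lb <= max_len):
                continue
            if e - flank < s + flank or not run_identical(e - flank, e):
                continue
            inside = [
                v for v in variants
                if v.column >= s + flank and v.column + v.span <= e - flank
            ]
            if not inside:
                continue
            key = frozenset((v.column, v.kind) for v in inside)
            cand = (max(la, lb), s, e)
            if key not in best_by_varset or cand < best_by_varset[key]:
                best_by_varset[key] = cand

    out: list[AmpliconCandidate] = []
    for idx, (key, (_, s, e)) in enumerate(
        sorted(best_by_varset.items(), key=lambda kv: (kv[1][1], kv[1][2]))
    ):
        amp_a = a[s:e].replace("-", "")
        amp_b = b[s:e].replace("-", "")
        inside = tuple(
            v for v in variants if v.column >= s + flank and v.column + v.span <= e - flank
        )
        fwd = a[s : s + flank]
        rev = thermo.reverse_complement(a[e - flank : e])
        out.append(
            AmpliconCandidate(
                name=f"AMP-{idx + 1:02d}",
                region=region,
                start=int(len_a_prefix[s]),
                end=int(len_a_prefix[e]),
                amplicon_a=amp_a,
                amplicon_b=amp_b,
                length_a=len(amp_a),
                length_b=len(amp_b),
                gc_a=thermo.gc_content(amp_a),
                gc_b=thermo.gc_content(amp_b),
                tm_a=thermo.predict_tm_nn(amp_a, params).tm_c,
                tm_b=thermo.predict_tm_nn(amp_b, params).tm_c,
                n_variants=len(inside),
                variant_kinds=frozenset(v.kind for v in inside),
                primer_fwd=fwd,
                primer_rev=rev,
                variants=inside,
            )
        )
    if not out:
        get_logger("screen").warning(
            "no amplicon window satisfies the length/flank constraints"
        )
    return out


# ---------------------------------------------------------------------------
# Screening rules
# ---------------------------------------------------------------------------

#: Retention threshold: inter-species ΔTm must exceed this (°C), strictly.
DELTA_TM_RETAIN = 0.3
#: Single-SNP candidates below this ΔTm (°C) are excluded.
DELTA_TM_SINGLE_SNP = 0.4
#: Empirical HRM optimum.
OPT_LEN = (100, 200)
OPT_GC = (0.40, 0.60)


def screen_candidates(
    cands: Sequence[AmpliconCandidate],
    delta_tm: Mapping[str, float] | None = None,
    weights: tuple[float, float, float, float] = (1.0, 0.5, 0.5, 0.5),
    delta_tm_cap: float = 1.5,
) -> ScreenReport:
    """Apply the ΔTm retention/exclusion rules and rank the survivors.

    ``delta_tm`` maps candidate name to a ΔTm in °C (measured peaks in
    assay mode); when omitted, the candidates' predicted ΔTm is used
    (design mode). Rank score rewards large (capped) ΔTm, length and GC
    inside the HRM optimum, and multi-polymorphic targets.
    """
    if not cands:
        raise ValueError("screen_candidates: empty candidate list")
    source = "measured" if delta_tm is not None else "predicted"
    w1, w2, w3, w4 = weights

    entries: list[ScreenEntry] = []
    for c in sorted(cands, key=lambda c: c.name):
        dt = delta_tm[c.name] if delta_tm is not None else c.predicted_delta_tm
        pass1 = dt > DELTA_TM_RETAIN
        excluded = (
            dt < DELTA_TM_SINGLE_SNP
            and c.n_variants == 1
            and c.variant_kinds == frozenset({"SNP"})
        )
        len_ok = all(OPT_LEN[0] <= L <= OPT_LEN[1] for L in (c.length_a, c.length_b))
        gc_ok = all(OPT_GC[0] <= g <= OPT_GC[1] for g in (c.gc_a, c.gc_b))
        score = (
            w1 * min(dt, delta_tm_cap)
            + w2 * float(len_ok)
            + w3 * float(gc_ok)
            + w4 * float(c.n_variants > 1)
        )
        entries.append(
            ScreenEntry(
                name=c.name,
                delta_tm=float(dt),
                pass_stage1=pass1,
                excluded_single_snp=excluded,
                in_optimal_window=len_ok and gc_ok,
                rank_score=score,
                retained=pass1 and not excluded,
            )
        )

    by_name = {c.name: c for c in cands}
    retained = [e for e in entries if e.retained]
    nominated = None
    if retained:
        nominated = min(
            retained,
            key=lambda e: (-e.rank_score, by_name[e.name].length_a, e.name),
        ).name
    return ScreenReport(entries=entries, nominated=nominated, delta_tm_source=source)
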