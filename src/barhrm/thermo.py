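"""Nearest-neighbor DNA duplex thermodynamics.

Predicts duplex melting temperature from the unified oligonucleotide
nearest-neighbor parameter set (stacked-dinucleotide ΔH/ΔS sums plus
terminal initiation terms), as

    Tm(K) = 1000·ΔH / (ΔS + R·ln(C_T / x)),

with ΔH in kcal/mol, ΔS in cal/(mol·K), R the gas constant, C_T the
total strand concentration and x the duplex-symmetry factor (4 for
non-self-complementary duplexes, 1 for palindromes, which also gain the
symmetry-entropy correction). The Celsius result is then salt-corrected,
by default with the classic additive term 16.6·log10([Na+]).

The model is calibrated on short oligos; applying it to 100–250 bp
amplicons (as HRM screening does) is a documented extrapolation — the
ranking of candidate amplicons, not the absolute Tm, is load-bearing.

Also provides GC content (fractional for ambiguity codes) and a
stem-loop (hairpin) screen that brute-force enumerates perfect
reverse-complement stems and scores them with NN stacking plus a fixed
loop-size penalty; it is a deliberately simplified surrogate for a full
minimum-free-energy fold and is used only to flag candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "ThermoParams",
    "TmPrediction",
    "HairpinReport",
    "gc_content",
    "reverse_complement",
    "predict_tm_nn",
    "hairpin_screen",
    "UNIFIED_NN",
]

#: Unified oligonucleotide NN parameters: dinucleotide -> (ΔH kcal/mol, ΔS cal/(mol·K)).
UNIFIED_NN: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}

#: Terminal initiation terms (ΔH kcal/mol, ΔS cal/(mol·K)).
INIT_GC = (0.1, -2.8)
INIT_AT = (2.3, 4.1)
#: Entropy correction for self-complementary duplexes, cal/(mol·K).
SYMMETRY_DS = -1.4
#: Gas constant, cal/(mol·K).
R_GAS = 1.987

#: Expected G+C contribution per IUPAC code.
_GC_WEIGHT = {
    "A": 0.0, "T": 0.0, "U": 0.0, "W": 0.0,
    "G": 1.0, "C": 1.0, "S": 1.0,
    "R": 0.5, "Y": 0.5, "K": 0.5, "M": 0.5, "N": 0.5,
    "B": 2.0 / 3.0, "V": 2.0 / 3.0,
    "D": 1.0 / 3.0, "H": 1.0 / 3.0,
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Hairpin loop-closure penalties by loop length, kcal/mol (>=7 uses the cap).
_LOOP_PENALTY = {3: 5.6, 4: 5.6, 5: 5.7, 6: 5.4}
_LOOP_PENALTY_CAP = 6.0
#: Hairpins more stable than this (kcal/mol at 37 degC) get flagged.
HAIRPIN_FLAG_DG = -2.0


@dataclass(frozen=True)
class ThermoParams:
    """NN parameter set and solution conditions for Tm prediction."""

    nn_table: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(UNIFIED_NN))
    init_gc: tuple[float, float] = INIT_GC
    init_at: tuple[float, float] = INIT_AT
    symmetry_ds: float = SYMMETRY_DS
    r: float = R_GAS
    c_t: float = 5e-8  # total strand concentration, mol/L (50 nM)
    na: float = 0.05  # sodium-equivalent concentration, mol/L (50 mM)
    salt_correction_mode: str = "celsius_additive"  # or "entropic"

    def __post_init__(self) -> None:
        if len(self.nn_table) != 16:
            raise ValueError("nn_table must contain all 16 dinucleotides")
        if self.c_t <= 0 or self.na <= 0:
            raise ValueError("strand and sodium concentrations must be positive")
        if self.salt_correction_mode not in ("celsius_additive", "entropic"):
            raise ValueError(f"unknown salt_correction_mode {self.salt_correction_mode!r}")

    def with_(self, **kwargs) -> "ThermoParams":
        return replace(self, **kwargs)


DEFAULT_PARAMS = ThermoParams()


@dataclass(frozen=True)
class TmPrediction:
    tm_c: float
    dH_total: float  # kcal/mol
    dS_total: float  # cal/(mol·K)
    gc_fraction: float
    length: int


@dataclass(frozen=True)
class HairpinReport:
    min_dG: float  # kcal/mol at the screening temperature; +inf if no stem
    stem_start: int = -1
    stem_len: int = 0
    loop_len: int = 0
    flagged: bool = False


def _check_unambiguous(sequence: str, op: str) -> str:
    seq = sequence.upper().replace("-", "")
    extra = set(seq) - set("ACGT")
    if extra:
        raise ValueError(
            f"{op}: ambiguity codes {sorted(extra)} present; resolve variants into "
            "concrete per-species sequences before thermodynamic prediction"
        )
    return seq


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def gc_content(sequence: str) -> float:
    """Fraction of G+C, counting ambiguity codes at their IUPAC expectation."""
    seq = sequence.upper().replace("-", "")
    if not seq:
        raise ValueError("gc_content: empty sequence")
    try:
        total = sum(_GC_WEIGHT[base] for base in seq)
    except KeyError as exc:
        raise ValueError(f"gc_content: invalid character {exc.args[0]!r}") from exc
    return total / len(seq)


def predict_tm_nn(sequence: str, params: ThermoParams = DEFAULT_PARAMS) -> TmPrediction:
    """Two-state NN melting temperature of a perfect duplex.

    The input is one strand of the duplex; by construction
    ``predict_tm_nn(s) == predict_tm_nn(reverse_complement(s))``.
    """
    seq = _check_unambiguous(sequence, "predict_tm_nn")
    n = len(seq)
    if n < 8:
        raise ValueError(f"predict_tm_nn: need length >= 8, got {n}")

    dh = 0.0  # kcal/mol
    ds = 0.0  # cal/(mol·K)
    for i in range(n - 1):
        h, s = params.nn_table[seq[i : i + 2]]
        dh += h
        ds += s
    for end in (seq[0], seq[-1]):
        h, s = params.init_gc if end in "GC" else params.init_at
        dh += h
        ds += s

    self_complementary = seq == reverse_complement(seq)
    if self_complementary:
        ds += params.symmetry_ds
        x = 1.0
    else:
        x = 4.0

    if params.salt_correction_mode == "entropic":
        ds_eff = ds + 0.368 * (n - 1) * math.log(params.na)
        tm_c = 1000.0 * dh / (ds_eff + params.r * math.log(params.c_t / x)) - 273.15
    else:
        tm_k = 1000.0 * dh / (ds + params.r * math.log(params.c_t / x))
        tm_c = tm_k - 273.15 + 16.6 * math.log10(params.na)

    return TmPrediction(
        tm_c=tm_c, dH_total=dh, dS_total=ds, gc_fraction=gc_content(seq), length=n
    )


def _stack_dg(arm: str, temp_k: float, params: ThermoParams) -> float:
    """ΔG (kcal/mol) of the stacked pairs along one stem arm at temp_k."""
    dg = 0.0
    for i in range(len(arm) - 1):
        h, s = params.nn_table[arm[i : i + 2]]
        dg += h - temp_k * s / 1000.0
    return dg


def hairpin_screen(
    sequence: str,
    temp_c: float = 37.0,
    min_stem: int = 4,
    min_loop: int = 3,
    params: ThermoParams = DEFAULT_PARAMS,
) -> HairpinReport:
    """Exhaustive perfect-stem hairpin screen.

    Enumerates every stem of >= ``min_stem`` perfectly reverse-complementary
    base pairs enclosing a loop of >= ``min_loop`` nt, scores each as NN
    stacking along the stem plus a loop-size penalty, and reports the
    minimum. ``flagged`` marks structures stable beyond −2.0 kcal/mol.
    """
    seq = _check_unambiguous(sequence, "hairpin_screen")
    n = len(seq)
    if n < 2 * min_stem + min_loop:
        raise ValueError(
            f"hairpin_screen: need length >= {2 * min_stem + min_loop}, got {n}"
        )
    temp_k = temp_c + 273.15
    pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}

    best = HairpinReport(min_dG=math.inf)
    # (p, q) is the outermost base pair; the stem extends inward.
    for p in range(n):
        for q in range(p + 2 * min_stem + min_loop - 1, n):
            if (seq[p], seq[q]) not in pairs:
                continue
            max_len = 1
            while (
                q - max_len - (p + max_len) - 1 >= min_loop
                and (seq[p + max_len], seq[q - max_len]) in pairs
            ):
                max_len += 1
            for stem_len in range(min_stem, max_len + 1):
                loop_len = q - p - 2 * stem_len + 1
                arm = seq[p : p + stem_len]
                loop_dg = _LOOP_PENALTY.get(loop_len, _LOOP_PENALTY_CAP)
                dg = _stack_dg(arm, temp_k, params) + loop_dg
                if dg < best.min_dG:
                    best = HairpinReport(
                        min_dG=dg, stem_start=p, stem_len=stem_len, loop_len=loop_len
                    )
    if math.isfinite(best.min_dG):
        best = replace(best, flagged=best.min_dG < HAIRPIN_FLAG_DG)
    return best
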