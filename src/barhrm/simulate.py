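"""Synthetic melt-curve and barcode-pair generator.

Stands in for instrument acquisitions: each melting domain is a
two-state logistic transition whose −dF/dT apex sits exactly at its Tm,
superposed on linear pre-/post-melt baselines with per-sample scale
variation and i.i.d. Gaussian fluorescence noise:

    F(T) = scale·[Σ_d w_d·θ_d(T)]·L_pre(T)
         + scale·[1 − Σ_d w_d·θ_d(T)]·L_post(T) + ε(T),
    θ_d(T) = 1 / (1 + exp((T − Tm_d)/width_d)).

Cohorts draw per-sample Tm (group center, or uniform within a group
range, plus Gaussian jitter) and can plant declared-label swaps that
change only the label as sold — never the generating model — emulating
market adulteration. A species-pair FASTA generator produces barcode
sequences differing by a configurable number of SNPs plus one AT-only
insertion (which lowers the second species' GC, hence its Tm).

Defaults emulate a 65–94 °C ramp read at 0.1 °C with a ~95 RFU melt
amplitude, 1 % fluorescence noise and 0.05 °C within-group Tm jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import thermo
from .io import BarcodeRecord, MeltCurve, write_melt_csv

__all__ = [
    "MeltModel",
    "GroupSpec",
    "CohortSpec",
    "temperature_grid",
    "simulate_curve",
    "simulate_cohort",
    "make_species_pair_fasta",
    "tm_with_dye_shift",
]

#: Default dye-stabilization offset added to NN-predicted Tm (°C); the
#: midpoint of the empirically observed 0.7–1.5 °C band.
DEFAULT_DYE_OFFSET = 1.1

#: Default melt-transition width (°C) and baseline parameters (RFU).
DEFAULT_WIDTH = 0.45
DEFAULT_PRE_LEVEL = 100.0
DEFAULT_POST_LEVEL = 5.0
DEFAULT_PRE_SLOPE = -0.3
DEFAULT_POST_SLOPE = -0.05
#: Per-sample scale is LogNormal(0, SCALE_SIGMA).
SCALE_SIGMA = 0.05


def temperature_grid(start: float = 65.0, stop: float = 94.0, step: float = 0.1) -> np.ndarray:
    """Inclusive constant-spacing grid; 65→94 at 0.1 gives 291 points."""
    n = int(round((stop - start) / step)) + 1
    return np.linspace(start, stop, n)


@dataclass
class MeltModel:
    """Multi-domain two-state melt model with linear baselines."""

    domains: list[tuple[float, float, float]]  # (tm_c, weight, width_c)
    pre_level: float = DEFAULT_PRE_LEVEL
    post_level: float = DEFAULT_POST_LEVEL
    pre_slope: float = DEFAULT_PRE_SLOPE
    post_slope: float = DEFAULT_POST_SLOPE
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.domains:
            raise ValueError("MeltModel needs at least one domain")
        wsum = sum(w for _, w, _ in self.domains)
        if not np.isclose(wsum, 1.0):
            raise ValueError(f"domain weights must sum to 1, got {wsum}")
        if any(w < 0 or width <= 0 for _, w, width in self.domains):
            raise ValueError("weights must be >= 0 and widths > 0")
        if self.pre_level <= self.post_level:
            raise ValueError("pre_level must exceed post_level")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @classmethod
    def single(cls, tm_c: float, width_c: float = DEFAULT_WIDTH, **kwargs) -> "MeltModel":
        return cls(domains=[(tm_c, 1.0, width_c)], **kwargs)


def simulate_curve(
    model: MeltModel,
    grid: np.ndarray,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    sample_id: str = "sim",
    declared_label: Optional[str] = None,
) -> MeltCurve:
    """One fluorescence trace; identical rng state gives identical output."""
    t = np.asarray(grid, dtype=float)
    t0 = t[0]
    theta = np.zeros_like(t)
    for tm_c, weight, width_c in model.domains:
        theta += weight / (1.0 + np.exp((t - tm_c) / width_c))
    pre = model.pre_level + model.pre_slope * (t - t0)
    post = model.post_level + model.post_slope * (t - t0)
    f = model.scale * (theta * pre + (1.0 - theta) * post)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        f = f + rng.normal(0.0, noise_sd, size=t.shape)
    # Fluorescence is reported in non-negative RFU.
    np.clip(f, 0.0, None, out=f)
    return MeltCurve(sample_id=sample_id, temperatures=t, fluorescence=f,
                     declared_label=declared_label)


@dataclass
class GroupSpec:
    """One cohort group; ``tm_center_c`` is a fixed center or a (lo, hi)
    range sampled uniformly per sample."""

    label: str
    n: int
    tm_center_c: float | tuple[float, float]
    tm_jitter_sd_c: float = 0.05
    width_c: float = DEFAULT_WIDTH
    model: Optional[MeltModel] = None  # template; domains overridden per sample

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.label!r}: n must be >= 1")
        if self.tm_jitter_sd_c < 0:
            raise ValueError(f"group {self.label!r}: jitter sd must be >= 0")


@dataclass
class CohortSpec:
    groups: list[GroupSpec]
    mislabeled: list[tuple[int, str]] = field(default_factory=list)  # (index, declared)
    noise_sd: float = 0.95  # RFU; 1% of the default 95-RFU amplitude
    grid_start: float = 65.0
    grid_stop: float = 94.0
    grid_step: float = 0.1
    scale_sigma: float = SCALE_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        labels = {g.label for g in self.groups}
        total = sum(g.n for g in self.groups)
        for idx, declared in self.mislabeled:
            if not (0 <= idx < total):
                raise ValueError(f"mislabeled index {idx} out of range [0, {total})")
            if declared not in labels:
                raise ValueError(f"declared label {declared!r} not among group labels")


def _sample_rng(seed: int, index: int) -> np.random.Generator:
    # Counter-derived substream: adding samples never reshuffles earlier ones.
    return np.random.default_rng([seed, index])


def simulate_cohort(
    spec: CohortSpec,
    curves_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> tuple[list[MeltCurve], pd.DataFrame]:
    """Generate a labeled cohort plus its truth table.

    Mislabeling swaps only the declared label; the generating model
    always follows the sample's true group. The truth table records
    sample_id, true/declared labels and the realized per-sample Tm.
    """
    grid = temperature_grid(spec.grid_start, spec.grid_stop, spec.grid_step)
    declared_overrides = dict(spec.mislabeled)

    curves: list[MeltCurve] = []
    rows = []
    index = 0
    for group in spec.groups:
        template = group.model or MeltModel.single(0.0, group.width_c)
        for _ in range(group.n):
            rng = _sample_rng(spec.seed, index)
            if isinstance(group.tm_center_c, tuple):
                center = rng.uniform(*group.tm_center_c)
            else:
                center = float(group.tm_center_c)
            true_tm = center + (rng.normal(0.0, group.tm_jitter_sd_c)
                                if group.tm_jitter_sd_c > 0 else 0.0)
            scale = float(np.exp(rng.normal(0.0, spec.scale_sigma))) if spec.scale_sigma > 0 else 1.0
            model = replace(template, domains=[(true_tm, 1.0, group.width_c)], scale=scale)
            sample_id = f"S{index:03d}"
            declared = declared_overrides.get(index, group.label)
            curves.append(
                simulate_curve(model, grid, spec.noise_sd, rng,
                               sample_id=sample_id, declared_label=declared)
            )
            rows.append(
                {
                    "sample_id": sample_id,
                    "true_label": group.label,
                    "declared_label": declared,
                    "true_tm_c": true_tm,
                    "scale": scale,
                }
            )
            index += 1

    truth = pd.DataFrame(rows)
    if curves_path is not None:
        write_melt_csv(curves, curves_path)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return curves, truth


#: Commercial root-product Tm ranges (°C) observed for the two species
#: with the selected amplicon; used as the default market-cohort centers.
PG_TM_RANGE = (87.8, 88.0)
PN_TM_RANGE = (88.4, 88.6)


def market_cohort_spec(
    seed: int,
    n_pg: int = 24,
    n_pn: int = 6,
    n_swaps: int = 4,
    tm_jitter_sd_c: float = 0.05,
    noise_sd: float = 0.95,
) -> CohortSpec:
    """30-sample market-surveillance cohort emulation.

    Two species groups with per-sample melting midpoints uniform in the
    species' product Tm ranges, 1 % fluorescence noise, and ``n_swaps``
    of the PN-generated samples sold under a "PG" declared label
    (adulteration). Truth always follows the generating group.
    """
    total = n_pg + n_pn
    if n_swaps > n_pn:
        raise ValueError("cannot swap more PN samples than exist")
    return CohortSpec(
        groups=[
            GroupSpec("PG", n_pg, PG_TM_RANGE, tm_jitter_sd_c=tm_jitter_sd_c),
            GroupSpec("PN", n_pn, PN_TM_RANGE, tm_jitter_sd_c=tm_jitter_sd_c),
        ],
        mislabeled=[(i, "PG") for i in range(total - n_swaps, total)],
        noise_sd=noise_sd,
        seed=seed,
    )


def make_species_pair_fasta(
    length: int = 400,
    n_snps: int = 3,
    indel_len: int = 12,
    gc_target: float = 0.6,
    seed: int = 0,
    edge_margin: int = 25,
    labels: tuple[str, str] = ("PG", "PN"),
    region: str = "ITS",
) -> tuple[BarcodeRecord, BarcodeRecord]:
    """Generate a species barcode pair differing by SNPs plus one AT-only
    insertion in the second species (dropping its GC fraction)."""
    if length < 200:
        raise ValueError("make_species_pair_fasta: length must be >= 200")
    if n_snps < 1:
        raise ValueError("make_species_pair_fasta: need n_snps >= 1")
    rng = np.random.default_rng(seed)
    interior = length - 2 * edge_margin
    if interior < n_snps + 1:
        raise ValueError("make_species_pair_fasta: sequence too short for requested variants")

    p_gc = gc_target / 2.0
    p_at = (1.0 - gc_target) / 2.0
    bases = np.array(list("ACGT"))
    seq_a = rng.choice(bases, size=length, p=[p_at, p_gc, p_gc, p_at])

    positions = rng.choice(np.arange(edge_margin, length - edge_margin),
                           size=n_snps + 1, replace=False)
    snp_pos = np.sort(positions[:n_snps])
    insert_pos = int(positions[-1])

    seq_b = seq_a.copy()
    for pos in snp_pos:
        alternatives = [b for b in "ACGT" if b != seq_b[pos]]
        seq_b[pos] = alternatives[rng.integers(len(alternatives))]

    b_list = list(seq_b)
    if indel_len > 0:
        insert = rng.choice(np.array(list("AT")), size=indel_len)
        b_list[insert_pos:insert_pos] = list(insert)

    rec_a = BarcodeRecord(id=f"{labels[0]}_ref", species_label=labels[0],
                          region=region, sequence="".join(seq_a))
    rec_b = BarcodeRecord(id=f"{labels[1]}_ref", species_label=labels[1],
                          region=region, sequence="".join(b_list))
    return rec_a, rec_b


def tm_with_dye_shift(
    sequence: str,
    params: thermo.ThermoParams = thermo.DEFAULT_PARAMS,
    dye_offset_c: float = DEFAULT_DYE_OFFSET,
) -> float:
    """Thermo-coupled group center: NN-predicted amplicon Tm plus the
    saturating-dye stabilization offset."""
    return thermo.predict_tm_nn(sequence, params).tm_c + dye_offset_c
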