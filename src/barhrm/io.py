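"""Readers, writers and shared domain containers.

Sequence data travel as FASTA (species/region metadata in ``key=value;``
header tokens), melt curves as long-format CSV (``sample_id,
temperature_c, fluorescence[, declared_label]``), trees as Newick.
"""

from __future__ import annotations

import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Phylo, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "BarcodeRecord",
    "MeltCurve",
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_melt_csv",
    "write_melt_csv",
    "read_newick",
    "write_newick",
    "get_logger",
]

#: IUPAC nucleotide codes accepted in barcode sequences (gap included).
IUPAC_DNA = set("ACGTRYSWKMBDHVN-")

#: Maximum allowed deviation from a constant temperature-grid spacing (°C).
GRID_SPACING_TOL = 1e-9


def get_logger(stage: str) -> logging.Logger:
    """Stage-named logger writing to stderr (results go to explicit paths)."""
    logger = logging.getLogger(f"barhrm.{stage}")
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[%(name)s] %(levelname)s: %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


@dataclass
class BarcodeRecord:
    """One species-labeled barcode sequence (e.g. an ITS2 or rbcL-accD read)."""

    id: str
    species_label: str = ""
    region: str = ""
    sequence: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise ValueError(f"record {self.id!r}: non-IUPAC characters {sorted(bad)}")

    def degapped(self) -> str:
        return self.sequence.replace("-", "")

    def slice_region(self, start: int, end: int) -> "BarcodeRecord":
        """Coordinate slice (0-based half-open) on the degapped sequence.

        Stands in for external region-annotation services (e.g. ITS2
        extraction): callers supply the coordinates.
        """
        seq = self.degapped()
        if not (0 <= start < end <= len(seq)):
            raise ValueError(f"slice [{start}, {end}) outside sequence of length {len(seq)}")
        return BarcodeRecord(self.id, self.species_label, self.region, seq[start:end])


@dataclass
class MeltCurve:
    """One sample's fluorescence-vs-temperature trace.

    ``declared_label`` is the label as sold/claimed; the true generating
    label (when known) lives in the cohort truth table, not here.
    """

    sample_id: str
    temperatures: np.ndarray
    fluorescence: np.ndarray
    declared_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise ValueError(f"sample {self.sample_id!r}: temperature/fluorescence length mismatch")
        if self.temperatures.size < 20:
            raise ValueError(f"sample {self.sample_id!r}: need >= 20 grid points")
        if self.temperatures.min() < 0 or self.temperatures.max() > 120:
            raise ValueError(f"sample {self.sample_id!r}: temperatures outside [0, 120] degC")
        diffs = np.diff(self.temperatures)
        if np.any(diffs <= 0):
            raise ValueError(f"sample {self.sample_id!r}: temperatures not strictly increasing")
        if np.max(np.abs(diffs - diffs.mean())) > GRID_SPACING_TOL:
            raise ValueError(f"sample {self.sample_id!r}: non-constant temperature grid")
        if np.any(self.fluorescence < 0):
            raise ValueError(f"sample {self.sample_id!r}: negative fluorescence")

    @property
    def step(self) -> float:
        return float(np.mean(np.diff(self.temperatures)))


@dataclass
class RunConfig:
    """Shared run parameters; a TOML file with the same keys can seed it."""

    grid_start_c: float = 65.0
    grid_stop_c: float = 94.0
    grid_step_c: float = 0.1
    smooth_width_c: float = 0.5
    peak_threshold_frac: float = 0.10
    window_mode: str = "auto"  # pre/post-melt window placement
    seed: int = 0
    strand_conc_m: float = 5e-8
    sodium_m: float = 0.05
    salt_correction_mode: str = "celsius_additive"

    def __post_init__(self) -> None:
        if not self.grid_start_c < self.grid_stop_c:
            raise ValueError("grid start must be below stop")
        if self.grid_step_c <= 0 or self.smooth_width_c <= 0:
            raise ValueError("grid step and window widths must be positive")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update(overrides)
        return cls(**data)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _parse_header_tokens(description: str) -> dict[str, str]:
    """Pull ``key=value;`` tokens out of a FASTA description line."""
    tokens: dict[str, str] = {}
    for word in description.split():
        for part in word.split(";"):
            if "=" in part:
                key, _, value = part.partition("=")
                tokens[key.strip()] = value.strip()
    return tokens


def read_fasta(path: str | Path) -> list[BarcodeRecord]:
    """Read barcode records; species/region parsed from header tokens.

    Headers may carry ``species=PG;region=ITS`` style tokens; absent
    tokens leave the fields empty. Duplicate ids are an error.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise ValueError(f"{path}: malformed FASTA (does not start with '>')")
    records: list[BarcodeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        tokens = _parse_header_tokens(rec.description)
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(
            BarcodeRecord(
                id=rec.id,
                species_label=tokens.get("species", ""),
                region=tokens.get("region", ""),
                sequence=seq,
            )
        )
    return records


def write_fasta(records: Iterable[BarcodeRecord], path: str | Path) -> None:
    seqrecords = []
    for rec in records:
        desc = []
        if rec.species_label:
            desc.append(f"species={rec.species_label};")
        if rec.region:
            desc.append(f"region={rec.region};")
        seqrecords.append(SeqRecord(Seq(rec.sequence), id=rec.id, description=" ".join(desc)))
    SeqIO.write(seqrecords, str(path), "fasta")


# ---------------------------------------------------------------------------
# Melt-curve CSV (long format)
# ---------------------------------------------------------------------------

_REQUIRED_COLS = ("sample_id", "temperature_c", "fluorescence")


def read_melt_csv(path: str | Path) -> list[MeltCurve]:
    """Read long-format melt curves, grouped by sample and sorted by temperature."""
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    curves: list[MeltCurve] = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        grp = grp.sort_values("temperature_c")
        temps = grp["temperature_c"].to_numpy(dtype=float)
        if np.any(np.diff(temps) == 0):
            raise ValueError(f"{path}: duplicated temperature row for sample {sample_id!r}")
        declared = None
        if "declared_label" in grp.columns:
            vals = grp["declared_label"].dropna().unique()
            declared = str(vals[0]) if len(vals) else None
        try:
            curve = MeltCurve(
                sample_id=str(sample_id),
                temperatures=temps,
                fluorescence=grp["fluorescence"].to_numpy(dtype=float),
                declared_label=declared,
            )
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
        curves.append(curve)
    return curves


def write_melt_csv(curves: Sequence[MeltCurve], path: str | Path) -> None:
    frames = []
    for c in curves:
        frame = pd.DataFrame(
            {
                "sample_id": c.sample_id,
                "temperature_c": c.temperatures,
                "fluorescence": c.fluorescence,
            }
        )
        if c.declared_label is not None:
            frame["declared_label"] = c.declared_label
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | Path) -> None:
    """Write a Bio.Phylo tree as Newick with bootstrap supports as node labels."""
    for clade in tree.find_clades():
        if clade.branch_length is not None and clade.branch_length < 0:
            raise ValueError(f"negative branch length on clade {clade.name!r}")
    Phylo.write(tree, str(path), "newick")


def read_newick(path: str | Path):
    return Phylo.read(str(path), "newick")
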