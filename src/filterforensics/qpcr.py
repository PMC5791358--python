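"""qPCR standard-curve calibration and genome-copy quantification.

A standard curve regresses mean quantification cycle (Cq) on log10 template
copies over a 10-fold dilution series; amplification efficiency is
``10^(-1/slope) - 1`` (a perfectly doubling reaction has slope -log2(10)
≈ -3.3219 and efficiency 1).  Sample Cq values are inverted through the
curve to copies per reaction, scaled by the template dilution (the study
design dilutes extracts 1:100 to dodge PCR inhibition), converted to genome
copies with organism-specific rRNA operon counts, and normalized to filter
area and, where dust mass is known, to mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

# rRNA operon copies per genome for the calibrant organisms.
OPERON_COPIES = {
    "bacteria_ecoli_o157": 7,
    "fungi_aniger": 54,
}


@dataclass
class QpcrRecord:
    """One sample × assay qPCR measurement (triplicate wells)."""

    sample_id: str
    assay: str  # e.g. "bacteria_16S", "fungi_18S"
    cq_triplicate: Sequence[float]
    dilution_factor: float = 100.0
    template_volume_uL: float = 2.0
    elution_volume_uL: float = 50.0
    melt_qc_pass: bool = True

    def __post_init__(self) -> None:
        self.cq_triplicate = [float(c) for c in self.cq_triplicate]
        for c in self.cq_triplicate:
            if not 0 < c < 45:
                raise ValueError(f"Cq {c} outside (0, 45) for {self.sample_id!r}")
        if self.dilution_factor < 1:
            raise ValueError("dilution factor must be >= 1")


@dataclass
class StandardCurve:
    points: list[tuple[float, float]]  # (log10_copies, mean_cq)
    slope: float
    intercept: float
    r_squared: float
    efficiency: float

    def cq_range(self) -> tuple[float, float]:
        cqs = [cq for _, cq in self.points]
        return min(cqs), max(cqs)


@dataclass
class GenomeQuantity:
    sample_id: str
    genome_copies: float  # per extract
    per_area: float  # copies / cm^2
    per_mass: Optional[float] = None  # copies / mg, vacuum only
    out_of_range: bool = False


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """OLS of mean Cq on log10 copies over a dilution series.

    Requires at least 3 points spanning at least 2 log10 units; the slope
    must be negative (more template amplifies earlier).
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 3:
        raise ValueError(f"standard curve needs >= 3 dilution points, got {len(pts)}")
    logs = np.array([x for x, _ in pts])
    if logs.max() - logs.min() < 2:
        raise ValueError("standard curve must span >= 2 log10 units")
    cqs = np.array([y for _, y in pts])
    res = stats.linregress(logs, cqs)
    if res.slope >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {res.slope:.4g}")
    efficiency = 10 ** (-1.0 / res.slope) - 1.0
    return StandardCurve(
        points=pts,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        efficiency=float(efficiency),
    )


def copies_from_cq(record: QpcrRecord, curve: StandardCurve) -> tuple[float, bool]:
    """Mean template copies per reaction, scaled back through the dilution.

    Each well is converted to the copy scale first (10^((cq − intercept)/slope))
    and the triplicate is averaged there, since copies — not cycles — are the
    quantity of interest.  Returns ``(copies, out_of_range)`` where the flag
    marks any well whose Cq falls outside the calibrated curve range.
    """
    lo, hi = curve.cq_range()
    out_of_range = False
    per_well = []
    for cq in record.cq_triplicate:
        if not lo <= cq <= hi:
            out_of_range = True
        per_well.append(10 ** ((cq - curve.intercept) / curve.slope))
    if out_of_range:
        warnings.warn(
            f"{record.sample_id}: Cq outside calibrated range [{lo:.2f}, {hi:.2f}]"
        )
    return float(np.mean(per_well)) * record.dilution_factor, out_of_range


def to_genomes(copies: float, organism: str, operon_map: dict[str, int] = OPERON_COPIES) -> float:
    """Convert rRNA gene copies to genome copies via operon counts per genome."""
    if copies < 0:
        raise ValueError("copies must be non-negative")
    if organism not in operon_map:
        raise KeyError(
            f"unknown organism {organism!r}; known: {sorted(operon_map)}"
        )
    return copies / operon_map[organism]


def normalize_quantity(
    genomes: float,
    sample_id: str,
    sampled_area_cm2: float,
    dust_mass_mg: Optional[float] = None,
    template_volume_uL: float = 2.0,
    elution_volume_uL: float = 50.0,
    out_of_range: bool = False,
) -> GenomeQuantity:
    """Scale per-reaction genomes to the whole extract, then per cm² (and per mg).

    The reaction holds ``template_volume_uL`` of the (already dilution-corrected)
    extract out of ``elution_volume_uL`` eluted, so whole-extract genomes are
    ``genomes * elution/template``.
    """
    if sampled_area_cm2 <= 0:
        raise ValueError(f"sampled area must be > 0, got {sampled_area_cm2}")
    total = genomes * (elution_volume_uL / template_volume_uL)
    per_mass = None
    if dust_mass_mg is not None:
        if dust_mass_mg <= 0:
            raise ValueError("dust mass must be > 0 when present")
        per_mass = total / dust_mass_mg
    return GenomeQuantity(
        sample_id=sample_id,
        genome_copies=total,
        per_area=total / sampled_area_cm2,
        per_mass=per_mass,
        out_of_range=out_of_range,
    )


def quantify(record: QpcrRecord, curve: StandardCurve, organism: str,
             sampled_area_cm2: float, dust_mass_mg: Optional[float] = None) -> GenomeQuantity:
    """Full chain Cq → copies → genomes → per-area/per-mass quantity."""
    copies, flag = copies_from_cq(record, curve)
    genomes = to_genomes(copies, organism)
    return normalize_quantity(
        genomes,
        record.sample_id,
        sampled_area_cm2,
        dust_mass_mg,
        template_volume_uL=record.template_volume_uL,
        elution_volume_uL=record.elution_volume_uL,
        out_of_range=flag,
    )


def bacteria_fungi_ratio(bacterial: float, fungal: float) -> float:
    """Ratio of bacterial to fungal quantity on matching units."""
    if fungal <= 0:
        raise ValueError("fungal quantity must be > 0 for a ratio")
    if bacterial < 0:
        raise ValueError("bacterial quantity must be non-negative")
    return bacterial / fungal
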