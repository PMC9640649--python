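"""Targeted-assay quantification and quality-control math.

Covers light/heavy SRM ratios, normalized dot products (dotp against a
library spectrum, rdotp between isotope channels) with their decision
gates, blank-injection carryover, mass error in ppm, qPCR amplification
efficiency from standard-curve slopes, and efficiency-corrected relative
quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TransitionSet",
    "QCRecord",
    "QpcrAssay",
    "PfafflMeasurement",
    "normalized_dotp",
    "rdotp_gate",
    "srm_ratio",
    "carryover_percent",
    "ppm_error",
    "amplification_efficiency",
    "pfaffl_ratio",
    "impute_nondetects",
]

# decision gates for the light/heavy channel correlation
RDOTP_INCLUDE = 0.9
RDOTP_EXCLUDE = 0.8
PPM_GATE = 10.0
EFFICIENCY_MIN = 0.95
EFFICIENCY_MAX = 1.05
MAX_CYCLE = 40.0


@dataclass(frozen=True)
class TransitionSet:
    """Transition-level peak areas for one peptide in one run."""

    run_id: str
    peptide_id: str
    transition_ids: tuple[str, ...]
    light_areas: tuple[float, ...]
    heavy_areas: tuple[float, ...]
    library_intensities: tuple[float, ...] = ()

    def __post_init__(self):
        n = len(self.transition_ids)
        if len(self.light_areas) != n or len(self.heavy_areas) != n:
            raise ValueError("transition vectors not aligned")
        if self.library_intensities and len(self.library_intensities) != n:
            raise ValueError("library vector not aligned")
        for vec in (self.light_areas, self.heavy_areas, self.library_intensities):
            if any(v < 0 for v in vec):
                raise ValueError("negative peak area")


@dataclass(frozen=True)
class QCRecord:
    peptide_id: str
    dotp: float
    rdotp: float
    mass_error_ppm: float
    decision: str  # include | exclude | review


@dataclass
class QpcrAssay:
    """Standard-curve calibrated qPCR assay for one target."""

    target_id: str
    slope: float
    cq: dict[str, float] = field(default_factory=dict)
    detected: dict[str, bool] = field(default_factory=dict)
    reference_ids: tuple[str, ...] = ()

    @property
    def efficiency(self) -> float:
        return amplification_efficiency(self.slope)[0]


@dataclass(frozen=True)
class PfafflMeasurement:
    e_target: float
    e_ref: float
    dcq_target: float
    dcq_ref: float

    @property
    def ratio(self) -> float:
        return pfaffl_ratio(self.e_target, self.e_ref, self.dcq_target, self.dcq_ref)


def normalized_dotp(
    observed: Sequence[float],
    reference: Sequence[float],
    sqrt_transform: bool = True,
) -> float:
    """Cosine similarity of two nonnegative intensity vectors.

    Intensities are square-root transformed by default, the usual
    convention for spectral-library dot products; pass
    ``sqrt_transform=False`` to compare raw intensities.
    """
    x = np.asarray(observed, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and aligned")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("intensities must be nonnegative")
    if not (x > 0).any() or not (y > 0).any():
        raise ValueError("all-zero intensity vector")
    if sqrt_transform:
        x = np.sqrt(x)
        y = np.sqrt(y)
    return float(np.dot(x, y) / (np.linalg.norm(x) * np.linalg.norm(y)))


def rdotp_gate(
    light_areas: Sequence[float],
    heavy_areas: Sequence[float],
    sqrt_transform: bool = True,
) -> tuple[float, str]:
    """Light/heavy channel correlation with inclusion gates.

    >= 0.9 include, <= 0.8 exclude, otherwise flagged for manual review.
    """
    rdotp = normalized_dotp(light_areas, heavy_areas, sqrt_transform=sqrt_transform)
    if rdotp >= RDOTP_INCLUDE:
        decision = "include"
    elif rdotp <= RDOTP_EXCLUDE:
        decision = "exclude"
    else:
        decision = "review"
    return rdotp, decision


def srm_ratio(ts: TransitionSet) -> float:
    """Light/heavy ratio from summed transition areas."""
    heavy = float(sum(ts.heavy_areas))
    if heavy <= 0:
        raise ValueError(f"peptide {ts.peptide_id}: heavy channel sums to zero")
    return float(sum(ts.light_areas)) / heavy


def carryover_percent(blank_area: float, preceding_area: float) -> float:
    """Residual signal in a blank injection as % of the preceding run."""
    if preceding_area <= 0:
        raise ValueError("preceding run area must be positive")
    if blank_area < 0:
        raise ValueError("blank area must be nonnegative")
    return 100.0 * blank_area / preceding_area


def ppm_error(observed_mz: float, theoretical_mz: float) -> tuple[float, bool]:
    """Signed mass error in ppm and the strict |ppm| < 10 gate flag."""
    if theoretical_mz <= 0:
        raise ValueError("theoretical m/z must be positive")
    ppm = 1e6 * (observed_mz - theoretical_mz) / theoretical_mz
    # small guard so values representing exactly 10 ppm fail the strict gate
    # despite binary-float rounding of the inputs
    return ppm, abs(ppm) < PPM_GATE - 1e-6


def amplification_efficiency(slope: float) -> tuple[float, bool]:
    """E = 10**(-1/slope) - 1 with the inclusive 95-105% acceptance gate."""
    if slope >= 0:
        raise ValueError("standard-curve slope must be negative")
    e = 10.0 ** (-1.0 / slope) - 1.0
    return e, EFFICIENCY_MIN <= e <= EFFICIENCY_MAX


def pfaffl_ratio(
    e_target: float,
    e_ref: float | Sequence[float],
    dcq_target: float,
    dcq_ref: float | Sequence[float],
) -> float:
    """Efficiency-corrected relative quantification.

    ratio = (1+E_target)**dCq_target / (1+E_ref)**dCq_ref, where each
    dCq = Cq(calibrator) - Cq(sample).  With several reference genes the
    reference term is the geometric mean of the per-reference terms.
    """
    e_refs = np.atleast_1d(np.asarray(e_ref, dtype=float))
    dcq_refs = np.atleast_1d(np.asarray(dcq_ref, dtype=float))
    if e_refs.shape != dcq_refs.shape:
        raise ValueError("reference efficiencies and dCq must align")
    if e_target < 0 or (e_refs < 0).any():
        raise ValueError("efficiencies must be nonnegative")
    target_term = (1.0 + e_target) ** dcq_target
    log_ref = np.mean(dcq_refs * np.log1p(e_refs))
    return float(target_term / math.exp(log_ref))


def impute_nondetects(
    cq: Sequence[float], detected: Sequence[bool], max_cycle: float = MAX_CYCLE
) -> np.ndarray:
    """Replace non-detected Cq values with the maximum cycle number."""
    cq = np.asarray(cq, dtype=float)
    detected = np.asarray(detected, dtype=bool)
    if cq.shape != detected.shape:
        raise ValueError("cq and detect flags must align")
    out = cq.copy()
    out[~detected] = max_cycle
    return out


def qc_record(
    ts: TransitionSet,
    observed_mz: float,
    theoretical_mz: float,
    sqrt_transform: bool = True,
) -> QCRecord:
    """Combined QC verdict for one peptide run.

    The decision follows the rdotp gates, additionally demoting an
    "include" to "review" when the library dotp fails the > 0.7 gate or
    the mass error fails the < 10 ppm gate.
    """
    if ts.library_intensities:
        dotp = normalized_dotp(
            ts.light_areas, ts.library_intensities, sqrt_transform=sqrt_transform
        )
    else:
        dotp = float("nan")
    rdotp, decision = rdotp_gate(
        ts.light_areas, ts.heavy_areas, sqrt_transform=sqrt_transform
    )
    ppm, ppm_ok = ppm_error(observed_mz, theoretical_mz)
    if decision == "include" and ((not math.isnan(dotp) and dotp <= 0.7) or not ppm_ok):
        decision = "review"
    return QCRecord(
        peptide_id=ts.peptide_id,
        dotp=dotp,
        rdotp=rdotp,
        mass_error_ppm=ppm,
        decision=decision,
    )
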