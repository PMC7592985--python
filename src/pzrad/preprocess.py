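"""Intensity preprocessing.

T2-weighted signal intensity has an arbitrary per-patient scale (coil load,
gain), so voxel intensities cannot be pooled across patients directly.  The
pipeline removes that scale by dividing each patient's T2WI by the
median + interquartile range (IQR) of a reference tissue; the reference is
chosen, among candidate tissues, as the one whose per-patient summaries are
most reproducible across the cohort, measured by the inter-patient
coefficient of variation (%interCV).  Quantitative diffusion channels
(ADC, eigenvalues) are in physical units and are used as-is by default.

Quantiles use linear interpolation between order statistics (numpy default,
"type 7"); %interCV uses the sample standard deviation (n-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import ROIMask, VoxelVolume


class EmptyRegionError(ValueError):
    """A required mask selects no voxels."""


class DegenerateReferenceError(ValueError):
    """Reference summaries are unusable (non-positive mean)."""


@dataclass
class ReferenceStats:
    """Per-cohort reproducibility record for one candidate reference tissue."""

    tissue_name: str
    per_patient_summary: list[tuple[str, float]]
    inter_cv_percent: float


def median_filter(vol: VoxelVolume, window: int = 3) -> VoxelVolume:
    """Slice-wise 2-D median filter with edge replication.

    Each in-slice voxel is replaced by the median of its window x window
    neighbourhood on the same axial slice; slices never mix.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    out = ndimage.median_filter(vol.data, size=(1, window, window), mode="nearest")
    return VoxelVolume(out, vol.spacing)


def reference_summary(vol: VoxelVolume, ref_mask: ROIMask) -> float:
    """median + IQR of the reference-tissue voxels (IQR = Q3 - Q1)."""
    ref_mask.check_companion(vol)
    values = vol.data[ref_mask.data]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise EmptyRegionError("reference mask selects no voxels")
    q1, med, q3 = np.percentile(values, [25.0, 50.0, 75.0])
    return float(med + (q3 - q1))


def inter_patient_cv(summaries: list[float]) -> float:
    """Inter-patient coefficient of variation, in percent.

    100 * sample SD / mean of the per-patient reference summaries; the
    sample SD uses the n-1 denominator.
    """
    arr = np.asarray(summaries, dtype=np.float64)
    if arr.size < 2:
        raise ValueError("need summaries from at least 2 patients")
    mean = arr.mean()
    if mean <= 0:
        raise DegenerateReferenceError(f"non-positive mean summary ({mean})")
    return float(100.0 * arr.std(ddof=1) / mean)


def choose_reference_tissue(candidates: list[ReferenceStats]) -> ReferenceStats:
    """Pick the candidate tissue with the lowest %interCV (ties: first wins)."""
    if not candidates:
        raise ValueError("no candidate reference tissues given")
    best = candidates[0]
    for cand in candidates[1:]:
        if cand.inter_cv_percent < best.inter_cv_percent:
            best = cand
    return best


def standardize_intensity(vol: VoxelVolume, divisor: float) -> VoxelVolume:
    """Divide every voxel by ``divisor`` (> 0).

    With ``divisor = reference_summary(vol, ref)`` the standardized volume
    has a reference summary of exactly 1, which removes the per-patient
    global intensity scale.
    """
    if not np.isfinite(divisor) or divisor <= 0:
        raise ValueError(f"divisor must be positive and finite, got {divisor}")
    return VoxelVolume(vol.data / divisor, vol.spacing)


def build_reference_stats(
    tissue_name: str, cases: list[tuple[str, VoxelVolume, ROIMask]]
) -> ReferenceStats:
    """Assemble ReferenceStats for one tissue over (patient_id, volume, mask)."""
    summaries = [(pid, reference_summary(v, m)) for pid, v, m in cases]
    cv = inter_patient_cv([s for _, s in summaries])
    return ReferenceStats(tissue_name, summaries, cv)
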