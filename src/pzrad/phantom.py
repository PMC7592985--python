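"""Synthetic mp-MRI phantom cohort.

Each phantom patient mimics the statistical structure the pipeline assumes
of real data, on a small grid: an ellipsoidal-crescent peripheral zone (PZ)
with one or two embedded lesion blobs; a T2WI channel in which lesions are
hypointense; a high-b DWI channel in which they are hyperintense; an ADC
map in which they are low (background ~1.6e-3 vs lesion ~0.8e-3 mm^2/s);
sorted positive DTI eigenvalue fields whose lesion values lower MD and
raise FA; a stable reference-tissue block outside the PZ; a smooth
low-order multiplicative field and Gaussian noise on the signal channels;
and a per-patient global intensity scale on the signal channels (T2WI,
high-b DWI) to exercise standardization — quantitative maps (ADC,
eigenvalues) are physical quantities and carry no scanner scale.

Two raters are emulated: rater 1 returns the true lesion mask; rater 2 a
morphologically perturbed copy whose disagreement is controlled by a radius
parameter (default calibrated so the inter-rater Dice falls around
0.7-0.85).

Everything is deterministic given (spec, seed): the same master seed
reproduces the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml
from scipy import ndimage

from .volume_io import DtiEigenvalues, PatientCase, ROIMask, VoxelVolume


class PhantomSpecError(ValueError):
    """Inconsistent phantom specification."""


@dataclass
class PhantomSpec:
    """Study conditions for the synthetic cohort."""

    shape: tuple[int, int, int] = (8, 64, 64)       # (slice, row, col)
    spacing: tuple[float, float, float] = (4.0, 1.5, 1.5)  # mm
    n_patients: int = 6
    lesions_per_patient: tuple[int, int] = (1, 2)
    lesion_radius_mm: tuple[float, float] = (4.5, 7.0)     # in-plane radius
    # channel means and lesion offsets (contrast = 0 gives the null phantom)
    t2_background: float = 1000.0
    t2_lesion_offset: float = -450.0
    dwi_background: float = 300.0
    dwi_lesion_offset: float = 280.0
    adc_background: float = 1.6e-3                  # mm^2/s
    adc_lesion_offset: float = -0.8e-3
    eig_background: tuple[float, float, float] = (2.1e-3, 1.7e-3, 1.3e-3)
    eig_lesion_offset: tuple[float, float, float] = (-0.85e-3, -0.85e-3, -0.75e-3)
    reference_mean: float = 420.0
    # noise standard deviations per channel
    t2_noise: float = 60.0
    dwi_noise: float = 25.0
    adc_noise: float = 8.0e-5
    eig_noise: float = 5.0e-5
    rician: bool = False
    field_amplitude: float = 0.08                   # smooth multiplicative bias
    patient_scale_range: tuple[float, float] = (0.7, 1.3)
    rater_perturb_radius: int = 1
    seed: int = 0

    def with_contrast_scale(self, s: float) -> "PhantomSpec":
        """Scale every lesion-vs-background contrast by ``s`` (0 = null)."""
        return replace(
            self,
            t2_lesion_offset=self.t2_lesion_offset * s,
            dwi_lesion_offset=self.dwi_lesion_offset * s,
            adc_lesion_offset=self.adc_lesion_offset * s,
            eig_lesion_offset=tuple(v * s for v in self.eig_lesion_offset),
        )

    def with_noise_scale(self, s: float) -> "PhantomSpec":
        return replace(
            self,
            t2_noise=self.t2_noise * s,
            dwi_noise=self.dwi_noise * s,
            adc_noise=self.adc_noise * s,
            eig_noise=self.eig_noise * s,
        )

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PhantomSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _pz_mask(spec: PhantomSpec) -> np.ndarray:
    """Posterior crescent between two ellipses on the central slices."""
    ns, nr, nc = spec.shape
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    cy, cx = 0.58 * nr, 0.5 * nc
    outer = ((rr - cy) / (0.30 * nr)) ** 2 + ((cc - cx) / (0.38 * nc)) ** 2
    inner = ((rr - cy) / (0.17 * nr)) ** 2 + ((cc - cx) / (0.26 * nc)) ** 2
    crescent = (outer <= 1.0) & (inner > 1.0) & (rr >= cy - 0.06 * nr)
    mask = np.zeros(spec.shape, dtype=bool)
    lo, hi = ns // 4, ns - ns // 4
    mask[lo:hi] = crescent
    return mask


def _reference_mask(spec: PhantomSpec) -> np.ndarray:
    ns, nr, nc = spec.shape
    mask = np.zeros(spec.shape, dtype=bool)
    mask[:, 2:max(3, nr // 8), 2:max(3, nc // 8)] = True
    return mask


def _lesion_mask(spec: PhantomSpec, pz: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """An ellipsoidal blob centred on a PZ voxel, clipped to the PZ."""
    zz, rr, cc = np.nonzero(pz)
    # keep centres away from the first/last PZ slice so blobs span slices
    zmid = (zz > zz.min()) & (zz < zz.max())
    if zmid.any():
        zz, rr, cc = zz[zmid], rr[zmid], cc[zmid]
    pick = int(rng.integers(len(zz)))
    cz, cr, ccol = zz[pick], rr[pick], cc[pick]
    a_mm = rng.uniform(*spec.lesion_radius_mm)
    ds, drr, dcc = spec.spacing
    z, r, c = np.meshgrid(
        np.arange(spec.shape[0]), np.arange(spec.shape[1]),
        np.arange(spec.shape[2]), indexing="ij",
    )
    ell = (
        ((z - cz) * ds / (1.2 * ds)) ** 2
        + ((r - cr) * drr / a_mm) ** 2
        + ((c - ccol) * dcc / a_mm) ** 2
    )
    return (ell <= 1.0) & pz


def perturb_mask(mask: ROIMask, radius: int, seed: int) -> ROIMask:
    """Rater-disagreement model: one random boundary perturbation.

    One of three in-plane perturbations is drawn — a translation, a
    dilation, or an erosion — with magnitude between 1 and ``radius``
    voxels (4-connected structure for the morphological ops).  Expected
    Dice against the input decreases monotonically with ``radius``;
    radius 0 returns the mask unchanged.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return mask.copy()
    rng = np.random.default_rng(seed)
    kind = rng.choice(("shift", "dilate", "erode"))
    magnitude = int(rng.integers(1, radius + 1))
    directions = ((0, 1), (0, -1), (1, 0), (-1, 0),
                  (1, 1), (1, -1), (-1, 1), (-1, -1))
    dr, dc = directions[int(rng.integers(8))]
    data = mask.data
    if kind == "shift":
        data = np.roll(data, (dr * magnitude, dc * magnitude), axis=(1, 2))
    elif kind == "dilate":  # grow one flank: union with shifted copies
        out = data.copy()
        for k in range(1, magnitude + 1):
            out |= np.roll(data, (dr * k, dc * k), axis=(1, 2))
        data = out
    else:  # shrink one flank: intersect with shifted copies
        out = data.copy()
        for k in range(1, magnitude + 1):
            out &= np.roll(data, (dr * k, dc * k), axis=(1, 2))
        if out.any():  # never erode a lesion away entirely
            data = out
    return ROIMask(data, mask.spacing, mask.label)


def mean_perturb_dice(spec: PhantomSpec, radius: int, n_draws: int = 50,
                      seed: int = 0) -> float:
    """Monte-Carlo mean Dice between a default lesion and its perturbations."""
    from .model import dice  # local import: model depends on nothing here

    rng = np.random.default_rng(seed)
    pz = _pz_mask(spec)
    vals = []
    for _ in range(n_draws):
        lesion = _lesion_mask(spec, pz, rng)
        r1 = ROIMask(lesion, spec.spacing, "rater1")
        r2 = perturb_mask(r1, radius, int(rng.integers(2**31)))
        vals.append(dice(r1, ROIMask(r2.data, spec.spacing, "rater1")))
    return float(np.mean(vals))


def calibrate_perturb_radius(spec: PhantomSpec, target: tuple[float, float] = (0.70, 0.85),
                             n_draws: int = 50, seed: int = 0) -> int:
    """Smallest radius whose mean perturbation Dice falls inside ``target``."""
    for radius in range(0, 6):
        d = mean_perturb_dice(spec, radius, n_draws, seed)
        if target[0] <= d <= target[1]:
            return radius
    raise PhantomSpecError("no radius reaches the target Dice band")


# ---------------------------------------------------------------------------
# Patient and cohort generation
# ---------------------------------------------------------------------------

def _smooth_field(shape: tuple[int, int, int], amplitude: float,
                  rng: np.random.Generator) -> np.ndarray:
    """1 + low-order polynomial in normalized coordinates (multiplicative)."""
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    z, r, c = np.meshgrid(*coords, indexing="ij")
    a = rng.uniform(-1.0, 1.0, size=5)
    poly = a[0] * z + a[1] * r + a[2] * c + a[3] * r * c + a[4] * (r**2 - c**2)
    return 1.0 + amplitude * poly


def _noise(shape, sd: float, rng: np.random.Generator, rician: bool) -> np.ndarray:
    if sd <= 0:
        return np.zeros(shape)
    if rician:
        return np.hypot(rng.normal(0, sd, shape), rng.normal(0, sd, shape))
    return rng.normal(0.0, sd, shape)


def generate_patient(spec: PhantomSpec, patient_seed: int,
                     patient_id: str | None = None,
                     scale: float | None = None) -> PatientCase:
    """One synthetic patient; bit-identical for identical (spec, seed)."""
    rng = np.random.default_rng(patient_seed)
    pz = _pz_mask(spec)
    ref = _reference_mask(spec)
    if (pz & ref).any():
        raise PhantomSpecError("reference tissue block overlaps the PZ")
    if scale is None:
        scale = float(rng.uniform(*spec.patient_scale_range))

    n_lesions = int(rng.integers(spec.lesions_per_patient[0],
                                 spec.lesions_per_patient[1] + 1))
    lesions: list[np.ndarray] = []
    occupied = np.zeros(spec.shape, dtype=bool)
    for _ in range(n_lesions):
        for _attempt in range(20):
            lesion = _lesion_mask(spec, pz, rng)
            if lesion.sum() == 0:
                continue
            if lesion.sum() > 0.5 * pz.sum():
                raise PhantomSpecError("lesion volume exceeds half the PZ")
            if not (lesion & occupied).any():
                break
        else:
            continue
        occupied |= lesion
        lesions.append(lesion)
    lesion_union = occupied

    sp = spec.spacing
    shape = spec.shape

    def signal_channel(background: float, offset: float, noise_sd: float,
                       with_ref: bool) -> np.ndarray:
        vol = np.full(shape, background, dtype=np.float64)
        vol[lesion_union] += offset
        if with_ref:
            vol[ref] = spec.reference_mean
        vol *= _smooth_field(shape, spec.field_amplitude, rng)
        vol += _noise(shape, noise_sd, rng, spec.rician)
        return vol * scale

    t2 = signal_channel(spec.t2_background, spec.t2_lesion_offset,
                        spec.t2_noise, with_ref=True)
    dwi = signal_channel(spec.dwi_background, spec.dwi_lesion_offset,
                         spec.dwi_noise, with_ref=False)

    adc = np.full(shape, spec.adc_background, dtype=np.float64)
    adc[lesion_union] += spec.adc_lesion_offset
    adc += _noise(shape, spec.adc_noise, rng, spec.rician)
    np.clip(adc, 1e-6, None, out=adc)

    eig_vols = []
    for bg, off in zip(spec.eig_background, spec.eig_lesion_offset):
        lam = np.full(shape, bg, dtype=np.float64)
        lam[lesion_union] += off
        lam += _noise(shape, spec.eig_noise, rng, spec.rician)
        np.clip(lam, 1e-6, None, out=lam)
        eig_vols.append(VoxelVolume(lam, sp))
    eig = DtiEigenvalues(*eig_vols)

    rater_masks = []
    for lesion in lesions:
        r1 = ROIMask(lesion, sp, "rater1")
        r2 = perturb_mask(r1, spec.rater_perturb_radius,
                          int(rng.integers(2**31)))
        rater_masks.append((r1, ROIMask(r2.data, sp, "rater2")))

    return PatientCase(
        patient_id=patient_id or f"phantom-{patient_seed:08d}",
        t2w=VoxelVolume(t2, sp),
        dwi_highb=VoxelVolume(dwi, sp),
        adc=VoxelVolume(adc, sp),
        eigenvalues=eig,
        pz=ROIMask(pz, sp, "PZ"),
        reference_tissue=ROIMask(ref, sp, "reference_tissue"),
        rater_masks=rater_masks,
    )


def generate_cohort(spec: PhantomSpec) -> list[PatientCase]:
    """Independent per-patient cases from the master seed."""
    if spec.n_patients < 1:
        raise PhantomSpecError("n_patients must be >= 1")
    seeds = np.random.SeedSequence(spec.seed).generate_state(spec.n_patients)
    return [
        generate_patient(spec, int(s % (2**31)), patient_id=f"P{i:03d}")
        for i, s in enumerate(seeds)
    ]
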