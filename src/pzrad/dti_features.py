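"""Diffusion-tensor scalar maps.

From the sorted tensor eigenvalues (lambda1 >= lambda2 >= lambda3, mm^2/s)
twenty voxel-wise maps are derived: eight anisotropy measures

    FA    fractional anisotropy   sqrt(3/2) * ||lam - MD|| / ||lam||
    RA    relative anisotropy     sqrt(sum((lam_i - MD)^2) / 3) / MD
    VR    volume ratio            lam1*lam2*lam3 / MD^3
    Cl    Westin linear           (lam1 - lam2) / tr
    Cp    Westin planar           2 (lam2 - lam3) / tr
    Cs    Westin spherical        3 lam3 / tr
    AC    axial-to-radial ratio   lam1 / RD        (pluggable, see below)
    mode  tensor-shape mode       3 sqrt(6) det(dev) / ||dev||^3

and twelve diffusivities

    MD = tr/3, lambda1..lambda3, RD = (lam2 + lam3)/2,
    d12 = lam1-lam2, d13 = lam1-lam3, d23 = lam2-lam3,
    VD = lam1*lam2*lam3, S12 = lam1*lam2, S13 = lam1*lam3, S23 = lam2*lam3.

The Westin measures use the trace denominator, so Cl + Cp + Cs = 1 wherever
tr > 0.  Ratio quantities are defined as 0 at voxels with tr = 0 (and AC as
0 where RD = 0).  "Attenuation coefficient" has no single convention in the
literature; this package uses the axial-to-radial diffusivity ratio and the
formula can be swapped via the ``ac_formula`` argument.

``trace`` (= 3 MD) is available as an alias through :func:`trace_map`; it is
not one of the twenty features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .preprocess import EmptyRegionError
from .volume_io import MISSING, DtiEigenvalues, ROIMask, VoxelVolume

#: Canonical map order: 8 anisotropy then 12 diffusivity identifiers.
DTI_MAP_NAMES = (
    "FA", "RA", "VR", "Cl", "Cp", "Cs", "AC", "mode",
    "MD", "lambda1", "lambda2", "lambda3", "RD",
    "d12", "d13", "d23", "VD", "S12", "S13", "S23",
)


@dataclass
class DtiMapSet:
    """The 20 named scalar maps for one case; NaN outside the analysis mask."""

    maps: dict[str, VoxelVolume]

    def __post_init__(self) -> None:
        if tuple(self.maps) != DTI_MAP_NAMES:
            raise ValueError("DtiMapSet must hold exactly the 20 canonical maps")

    def __getitem__(self, name: str) -> VoxelVolume:
        return self.maps[name]

    @property
    def names(self) -> tuple[str, ...]:
        return DTI_MAP_NAMES


def _default_ac(l1: np.ndarray, l2: np.ndarray, l3: np.ndarray) -> np.ndarray:
    rd = (l2 + l3) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ac = np.where(rd > 0, l1 / np.where(rd > 0, rd, 1.0), 0.0)
    return ac


def compute_dti_maps(
    eig: DtiEigenvalues,
    mask: ROIMask,
    ac_formula: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray] = _default_ac,
) -> DtiMapSet:
    """Evaluate all 20 scalar maps inside ``mask``; NaN elsewhere.

    Eigenvalues are already sorted non-negative by :class:`DtiEigenvalues`.
    Voxels with zero trace yield 0 for every ratio quantity (FA, RA, VR,
    Cl, Cp, Cs, AC, mode).
    """
    mask.check_companion(eig.lambda1)
    if mask.voxel_count == 0:
        raise EmptyRegionError("analysis mask is empty")
    m = mask.data
    l1 = eig.lambda1.data[m]
    l2 = eig.lambda2.data[m]
    l3 = eig.lambda3.data[m]

    tr = l1 + l2 + l3
    md = tr / 3.0
    pos = tr > 0
    safe_tr = np.where(pos, tr, 1.0)
    safe_md = np.where(pos, md, 1.0)

    dev1, dev2, dev3 = l1 - md, l2 - md, l3 - md
    dev_sq = dev1**2 + dev2**2 + dev3**2
    lam_sq = l1**2 + l2**2 + l3**2
    safe_lam = np.where(lam_sq > 0, lam_sq, 1.0)

    fa = np.where(pos, np.sqrt(1.5) * np.sqrt(dev_sq / safe_lam), 0.0)
    ra = np.where(pos, np.sqrt(dev_sq / 3.0) / safe_md, 0.0)
    vr = np.where(pos, l1 * l2 * l3 / safe_md**3, 0.0)
    cl = np.where(pos, (l1 - l2) / safe_tr, 0.0)
    cp = np.where(pos, 2.0 * (l2 - l3) / safe_tr, 0.0)
    cs = np.where(pos, 3.0 * l3 / safe_tr, 0.0)
    ac = np.where(pos, ac_formula(l1, l2, l3), 0.0)

    dev_norm = np.sqrt(dev_sq)
    safe_dev = np.where(dev_norm > 0, dev_norm, 1.0)
    mode = np.where(
        pos & (dev_norm > 0),
        3.0 * np.sqrt(6.0) * (dev1 * dev2 * dev3) / safe_dev**3,
        0.0,
    )
    # isotropic voxels have a zero deviatoric and a conventional mode of 0
    np.clip(mode, -1.0, 1.0, out=mode)

    values = {
        "FA": fa, "RA": ra, "VR": vr, "Cl": cl, "Cp": cp, "Cs": cs,
        "AC": ac, "mode": mode,
        "MD": md, "lambda1": l1, "lambda2": l2, "lambda3": l3,
        "RD": (l2 + l3) / 2.0,
        "d12": l1 - l2, "d13": l1 - l3, "d23": l2 - l3,
        "VD": l1 * l2 * l3, "S12": l1 * l2, "S13": l1 * l3, "S23": l2 * l3,
    }
    maps = {}
    for name in DTI_MAP_NAMES:
        grid = np.full(mask.shape, MISSING)
        grid[m] = values[name]
        maps[name] = VoxelVolume(grid, eig.spacing)
    return DtiMapSet(maps)


def trace_map(mapset: DtiMapSet) -> VoxelVolume:
    """Trace alias: tr = 3 * MD (not a 21st feature)."""
    md = mapset["MD"]
    return VoxelVolume(3.0 * md.data, md.spacing)
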