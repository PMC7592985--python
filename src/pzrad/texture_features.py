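"""Per-voxel texture feature extraction.

For every scalar channel (standardized T2WI, high-b DWI, ADC) 57 voxel-wise
feature maps are produced, in five families:

* gray level (1): the channel intensity itself;
* first-order (15): statistics of a sliding in-slice window — mean, 25th and
  75th percentile, variance, SD, median, IQR, mode, min, max, range,
  skewness, kurtosis, entropy, energy;
* second-order GLCM (19): Haralick-type statistics of a symmetric gray-level
  co-occurrence matrix accumulated over the four unit offsets at distance 1
  within the same window;
* edge-based (6): binary edge maps from Roberts, Prewitt, Sobel, Canny,
  Laplacian-of-Gaussian and zero-crossing detectors;
* gradient-based (16): directional responses (x, y, diagonal) and magnitude
  for Sobel/Prewitt/Roberts, plus central- and forward-difference x/y.

All window operators are 2-D and act per axial slice with edge replication,
with a 9 x 9 default window.  Window features are evaluated only at voxels
of the analysis mask (NaN elsewhere); edge and gradient maps are dense.

Conventions (each a config constant, none canonical in the literature):
first-order moments are population moments (variance ddof=0, kurtosis in
excess form) with degenerate values defined as 0 on constant windows;
first-order entropy/energy use a 64-bin histogram of the window over its own
range, entropy in bits; the GLCM quantizes each window to 32 equal-width
levels over the window's own range.  The feature list names both "contrast"
and "inertia" (classically the same quantity): contrast is computed from the
normalized co-occurrence probabilities and inertia from the raw pair counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from skimage import feature as skfeature

from .dti_features import DTI_MAP_NAMES, DtiMapSet
from .volume_io import MISSING, ROIMask, VoxelVolume

FIRST_ORDER_NAMES = (
    "mean", "p25", "p75", "variance", "sd", "median", "iqr", "mode",
    "min", "max", "range", "skewness", "kurtosis", "entropy", "energy",
)

GLCM_NAMES = (
    "glcm_variance", "glcm_sd", "contrast", "maximum_probability",
    "glcm_energy", "glcm_entropy", "correlation", "mcc", "inertia",
    "inverse_difference", "homogeneity", "dissimilarity", "cluster_shade",
    "sum_average", "sum_variance", "sum_of_squares", "sum_entropy",
    "difference_variance", "difference_entropy",
)

EDGE_NAMES = ("edge_roberts", "edge_prewitt", "edge_sobel", "edge_canny",
              "edge_log", "edge_zerocross")

GRADIENT_NAMES = (
    "sobel_x", "sobel_y", "sobel_diag", "sobel_mag",
    "prewitt_x", "prewitt_y", "prewitt_diag", "prewitt_mag",
    "roberts_x", "roberts_y", "roberts_diag", "roberts_mag",
    "central_x", "central_y", "forward_x", "forward_y",
)

#: 1 + 15 + 19 + 6 + 16 feature names per scalar channel, unprefixed.
CHANNEL_FEATURE_NAMES = (
    ("gray",) + FIRST_ORDER_NAMES + GLCM_NAMES + EDGE_NAMES + GRADIENT_NAMES
)

FIRST_ORDER_BINS = 64
GLCM_LEVELS = 32
#: slice offsets (drow, dcol) for 0, 45, 90, 135 degrees at distance 1
GLCM_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

METADATA_COLUMNS = ("patient_id", "slice", "row", "col", "label")


@dataclass
class FeatureMapSet:
    """The 57 feature maps of one scalar channel, keyed ``channel_feature``."""

    channel: str
    maps: dict[str, VoxelVolume]

    def __post_init__(self) -> None:
        expected = tuple(f"{self.channel}_{n}" for n in CHANNEL_FEATURE_NAMES)
        if tuple(self.maps) != expected:
            raise ValueError(
                f"channel {self.channel!r} must hold exactly the 57 canonical maps"
            )

    def __getitem__(self, name: str) -> VoxelVolume:
        return self.maps[name]


@dataclass
class NormalizationState:
    """Per-column (min, max) learned on training rows."""

    bounds: dict[str, tuple[float, float]]


def _check_window(window: int) -> int:
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    return window // 2


def _masked_windows(
    sl: np.ndarray, mask_sl: np.ndarray, window: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Windows (n, window*window) around each masked voxel, edge-replicated."""
    half = window // 2
    padded = np.pad(sl, half, mode="edge")
    views = sliding_window_view(padded, (window, window))
    rr, cc = np.nonzero(mask_sl)
    return views[rr, cc].reshape(len(rr), -1), rr, cc


# ---------------------------------------------------------------------------
# First-order window statistics
# ---------------------------------------------------------------------------

def _first_order_stats(win: np.ndarray, bins: int = FIRST_ORDER_BINS) -> dict[str, np.ndarray]:
    """Vectorized 15 first-order statistics for windows ``win`` (n, k)."""
    n, k = win.shape
    mean = win.mean(axis=1)
    var = win.var(axis=1)  # population variance
    sd = np.sqrt(var)
    p25, med, p75 = np.percentile(win, [25.0, 50.0, 75.0], axis=1)
    mn = win.min(axis=1)
    mx = win.max(axis=1)

    centered = win - mean[:, None]
    safe_sd = np.where(sd > 0, sd, 1.0)
    skew = np.where(sd > 0, (centered**3).mean(axis=1) / safe_sd**3, 0.0)
    kurt = np.where(sd > 0, (centered**4).mean(axis=1) / safe_sd**4 - 3.0, 0.0)

    # histogram over each window's own range; constant windows collapse to
    # a single occupied bin (entropy 0, energy 1, mode = the value)
    rng = mx - mn
    safe_rng = np.where(rng > 0, rng, 1.0)
    idx = np.floor((win - mn[:, None]) / safe_rng[:, None] * bins).astype(np.intp)
    np.clip(idx, 0, bins - 1, out=idx)
    flat = idx + bins * np.arange(n)[:, None]
    counts = np.bincount(flat.ravel(), minlength=n * bins).reshape(n, bins)
    p = counts / k
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0).sum(axis=1)
    energy = (p**2).sum(axis=1)
    # mode: centre of the most frequent bin, ties broken toward the lowest bin
    mode_bin = counts.argmax(axis=1)
    mode = mn + (mode_bin + 0.5) * rng / bins
    mode = np.where(rng > 0, mode, mn)

    return {
        "mean": mean, "p25": p25, "p75": p75, "variance": var, "sd": sd,
        "median": med, "iqr": p75 - p25, "mode": mode, "min": mn, "max": mx,
        "range": mx - mn, "skewness": skew, "kurtosis": kurt,
        "entropy": ent, "energy": energy,
    }


def first_order_maps(
    vol: VoxelVolume, mask: ROIMask, window: int = 9, bins: int = FIRST_ORDER_BINS
) -> dict[str, VoxelVolume]:
    """The 15 first-order statistic maps over a sliding in-slice window."""
    _check_window(window)
    mask.check_companion(vol)
    out = {n: np.full(vol.shape, MISSING) for n in FIRST_ORDER_NAMES}
    for s in range(vol.shape[0]):
        if not mask.data[s].any():
            continue
        win, rr, cc = _masked_windows(vol.data[s], mask.data[s], window)
        for name, val in _first_order_stats(win, bins).items():
            out[name][s, rr, cc] = val
    return {n: VoxelVolume(out[n], vol.spacing) for n in FIRST_ORDER_NAMES}


# ---------------------------------------------------------------------------
# GLCM statistics
# ---------------------------------------------------------------------------

def quantize_window(win: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width quantization of each window (n, w, w) over its own range."""
    mn = win.min(axis=(1, 2), keepdims=True)
    mx = win.max(axis=(1, 2), keepdims=True)
    rng = mx - mn
    safe = np.where(rng > 0, rng, 1.0)
    q = np.floor((win - mn) / safe * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def cooccurrence_counts(q: np.ndarray, levels: int) -> np.ndarray:
    """Symmetric pair counts (n, L, L) over the four distance-1 offsets."""
    n = q.shape[0]
    counts = np.zeros(n * levels * levels, dtype=np.float64)
    base = (np.arange(n) * levels * levels)[:, None]
    for dr, dc in GLCM_OFFSETS:
        r0, r1 = max(0, -dr), q.shape[1] - max(0, dr)
        c0, c1 = max(0, -dc), q.shape[2] - max(0, dc)
        a = q[:, r0:r1, c0:c1].reshape(n, -1)
        b = q[:, r0 + dr:r1 + dr, c0 + dc:c1 + dc].reshape(n, -1)
        np.add.at(counts, (base + a * levels + b).ravel(), 1.0)
        np.add.at(counts, (base + b * levels + a).ravel(), 1.0)
    return counts.reshape(n, levels, levels)


def glcm_statistics(counts: np.ndarray) -> dict[str, np.ndarray]:
    """The 19 statistics from symmetric co-occurrence counts (n, L, L)."""
    n, L, _ = counts.shape
    total = counts.sum(axis=(1, 2))
    p = counts / np.where(total > 0, total, 1.0)[:, None, None]
    i = np.arange(L, dtype=np.float64)
    diff = np.abs(i[:, None] - i[None, :])

    px = p.sum(axis=2)  # marginal over j (== py for a symmetric matrix)
    mu = (px * i).sum(axis=1)
    var = (px * (i[None, :] - mu[:, None]) ** 2).sum(axis=1)
    sd = np.sqrt(var)

    def plog2(x: np.ndarray) -> np.ndarray:
        return np.where(x > 0, x * np.log2(np.where(x > 0, x, 1.0)), 0.0)

    contrast = (p * diff**2).sum(axis=(1, 2))
    inertia = (counts * diff**2).sum(axis=(1, 2))
    energy = (p**2).sum(axis=(1, 2))
    entropy = -plog2(p).sum(axis=(1, 2))
    maxprob = p.max(axis=(1, 2))
    inv_diff = (p / (1.0 + diff)).sum(axis=(1, 2))
    homogeneity = (p / (1.0 + diff**2)).sum(axis=(1, 2))
    dissimilarity = (p * diff).sum(axis=(1, 2))

    ci = i[:, None] - mu[:, None, None]  # (n, L, 1) row deviation
    cj = i[None, :] - mu[:, None, None]  # (n, 1, L) column deviation
    safe_var = np.where(var > 0, var, 1.0)
    correlation = np.where(
        var > 0, (p * ci * cj).sum(axis=(1, 2)) / safe_var, 0.0
    )
    cluster_shade = (p * (ci + cj) ** 3).sum(axis=(1, 2))
    sum_of_squares = (p * ci**2).sum(axis=(1, 2))

    # sum and difference distributions p_{x+y}, p_{x-y}
    ks = np.arange(2 * L - 1, dtype=np.float64)
    sum_idx = (i[:, None] + i[None, :]).astype(np.intp).ravel()
    diff_idx = np.abs(i[:, None] - i[None, :]).astype(np.intp).ravel()
    p_flat = p.reshape(n, -1)
    p_sum = np.zeros((n, 2 * L - 1))
    p_diff = np.zeros((n, L))
    np.add.at(p_sum, (np.arange(n)[:, None], sum_idx[None, :]), p_flat)
    np.add.at(p_diff, (np.arange(n)[:, None], diff_idx[None, :]), p_flat)

    sum_avg = (p_sum * ks).sum(axis=1)
    sum_var = (p_sum * (ks[None, :] - sum_avg[:, None]) ** 2).sum(axis=1)
    sum_ent = -plog2(p_sum).sum(axis=1)
    kd = np.arange(L, dtype=np.float64)
    diff_avg = (p_diff * kd).sum(axis=1)
    diff_var = (p_diff * (kd[None, :] - diff_avg[:, None]) ** 2).sum(axis=1)
    diff_ent = -plog2(p_diff).sum(axis=1)

    mcc = _max_correlation_coefficient(p, px)

    return {
        "glcm_variance": var, "glcm_sd": sd, "contrast": contrast,
        "maximum_probability": maxprob, "glcm_energy": energy,
        "glcm_entropy": entropy, "correlation": correlation, "mcc": mcc,
        "inertia": inertia, "inverse_difference": inv_diff,
        "homogeneity": homogeneity, "dissimilarity": dissimilarity,
        "cluster_shade": cluster_shade, "sum_average": sum_avg,
        "sum_variance": sum_var, "sum_of_squares": sum_of_squares,
        "sum_entropy": sum_ent, "difference_variance": diff_var,
        "difference_entropy": diff_ent,
    }


def _max_correlation_coefficient(p: np.ndarray, px: np.ndarray) -> np.ndarray:
    """sqrt of the second-largest eigenvalue of Haralick's Q matrix.

    Q(i, j) = sum_k p(i,k) p(j,k) / (px(i) py(k)); rows/columns with a zero
    marginal contribute nothing.  Windows whose matrix occupies fewer than
    two gray levels get 0.
    """
    n, L, _ = p.shape
    safe_px = np.where(px > 0, px, 1.0)
    A = p / safe_px[:, :, None]          # p(i,k) / px(i)
    B = p / safe_px[:, None, :]          # p(j,k) / py(k)  (symmetric: py == px)
    Q = np.einsum("nik,njk->nij", A, B)
    eig = np.linalg.eigvals(Q)
    eig = np.sort(eig.real, axis=1)
    second = eig[:, -2]
    support = (px > 0).sum(axis=1)
    return np.where(support >= 2, np.sqrt(np.clip(second, 0.0, None)), 0.0)


def glcm_maps(
    vol: VoxelVolume,
    mask: ROIMask,
    window: int = 9,
    levels: int = GLCM_LEVELS,
    chunk: int = 2048,
) -> dict[str, VoxelVolume]:
    """The 19 GLCM statistic maps over a sliding in-slice window."""
    _check_window(window)
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    mask.check_companion(vol)
    out = {n: np.full(vol.shape, MISSING) for n in GLCM_NAMES}
    half = window // 2
    for s in range(vol.shape[0]):
        if not mask.data[s].any():
            continue
        padded = np.pad(vol.data[s], half, mode="edge")
        views = sliding_window_view(padded, (window, window))
        rr, cc = np.nonzero(mask.data[s])
        for start in range(0, len(rr), chunk):
            r = rr[start:start + chunk]
            c = cc[start:start + chunk]
            win = views[r, c]
            q = quantize_window(win, levels)
            stats = glcm_statistics(cooccurrence_counts(q, levels))
            for name, val in stats.items():
                out[name][s, r, c] = val
    return {n: VoxelVolume(out[n], vol.spacing) for n in GLCM_NAMES}


# ---------------------------------------------------------------------------
# Edge maps
# ---------------------------------------------------------------------------

_SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
_PREWITT_X = np.array([[-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0]])
_ROBERTS_X = np.array([[1.0, 0.0], [0.0, -1.0]])
_ROBERTS_Y = np.array([[0.0, 1.0], [-1.0, 0.0]])


def _grad_xy(sl: np.ndarray, op: str) -> tuple[np.ndarray, np.ndarray]:
    if op == "sobel":
        kx = _SOBEL_X
    elif op == "prewitt":
        kx = _PREWITT_X
    elif op == "roberts":
        gx = ndimage.correlate(sl, _ROBERTS_X, mode="nearest")
        gy = ndimage.correlate(sl, _ROBERTS_Y, mode="nearest")
        return gx, gy
    else:  # pragma: no cover
        raise ValueError(op)
    gx = ndimage.correlate(sl, kx, mode="nearest")
    gy = ndimage.correlate(sl, kx.T, mode="nearest")
    return gx, gy


def _zero_crossings(lap: np.ndarray, threshold: float) -> np.ndarray:
    """Mark sign changes between 4-neighbours whose jump exceeds threshold."""
    edges = np.zeros(lap.shape, dtype=bool)
    for axis in (0, 1):
        a = np.take(lap, np.arange(lap.shape[axis] - 1), axis=axis)
        b = np.take(lap, np.arange(1, lap.shape[axis]), axis=axis)
        crossing = (a * b < 0) & (np.abs(a - b) > threshold)
        # mark the pixel closer to the zero of the two
        first = np.abs(a) <= np.abs(b)
        idx = np.zeros(lap.shape, dtype=bool)
        if axis == 0:
            idx[:-1, :] |= crossing & first
            idx[1:, :] |= crossing & ~first
        else:
            idx[:, :-1] |= crossing & first
            idx[:, 1:] |= crossing & ~first
        edges |= idx
    return edges


def edge_maps(vol: VoxelVolume) -> dict[str, VoxelVolume]:
    """Six binary edge maps per slice, each with its automatic threshold.

    Gradient detectors (Roberts/Prewitt/Sobel) threshold the gradient
    magnitude at 4x its slice mean; Canny uses hysteresis thresholds at the
    0.7/0.9 magnitude quantiles (sigma = 1); LoG marks zero crossings of a
    sigma-2 Laplacian-of-Gaussian whose jump exceeds 0.75x the mean absolute
    response; zero-cross applies the same detector to the plain Laplacian.
    """
    if min(vol.shape[1:]) < 3:
        raise ValueError("slices must be at least 3 x 3 for edge detection")
    out = {n: np.zeros(vol.shape) for n in EDGE_NAMES}
    for s in range(vol.shape[0]):
        sl = vol.data[s]
        for op in ("roberts", "prewitt", "sobel"):
            gx, gy = _grad_xy(sl, op)
            mag = np.hypot(gx, gy)
            out[f"edge_{op}"][s] = mag > 4.0 * mag.mean()
        if np.ptp(sl) > 0:
            out["edge_canny"][s] = skfeature.canny(
                sl, sigma=1.0, low_threshold=0.70, high_threshold=0.90,
                use_quantiles=True,
            )
        # remove the DC level first: the discrete LoG kernel does not sum
        # exactly to zero, so a constant offset would leak into the response
        log = ndimage.gaussian_laplace(sl - sl.mean(), sigma=2.0, mode="nearest")
        out["edge_log"][s] = _zero_crossings(log, 0.75 * np.abs(log).mean())
        lap = ndimage.laplace(sl, mode="nearest")
        out["edge_zerocross"][s] = _zero_crossings(lap, 0.75 * np.abs(lap).mean())
    return {n: VoxelVolume(out[n], vol.spacing) for n in EDGE_NAMES}


# ---------------------------------------------------------------------------
# Gradient maps
# ---------------------------------------------------------------------------

def gradient_maps(vol: VoxelVolume) -> dict[str, VoxelVolume]:
    """Sixteen per-voxel gradient maps.

    Sobel, Prewitt and Roberts each contribute x, y, diagonal and magnitude
    responses (diagonal = (Gx + Gy)/sqrt(2), the 45-degree directional
    derivative); central differences (f[i+1] - f[i-1])/2 and forward
    differences f[i+1] - f[i] contribute x and y maps.  Kernels are applied
    by correlation with edge replication, unnormalized (a unit column ramp
    gives a Sobel x-response of 8).
    """
    if min(vol.shape[1:]) < 3:
        raise ValueError("slices must be at least 3 x 3 for gradient maps")
    out = {n: np.zeros(vol.shape) for n in GRADIENT_NAMES}
    central = np.array([-0.5, 0.0, 0.5])
    for s in range(vol.shape[0]):
        sl = vol.data[s]
        for op in ("sobel", "prewitt", "roberts"):
            gx, gy = _grad_xy(sl, op)
            out[f"{op}_x"][s] = gx
            out[f"{op}_y"][s] = gy
            out[f"{op}_diag"][s] = (gx + gy) / np.sqrt(2.0)
            out[f"{op}_mag"][s] = np.hypot(gx, gy)
        out["central_x"][s] = ndimage.correlate1d(sl, central, axis=1, mode="nearest")
        out["central_y"][s] = ndimage.correlate1d(sl, central, axis=0, mode="nearest")
        out["forward_x"][s] = ndimage.correlate1d(
            sl, np.array([0.0, -1.0, 1.0]), axis=1, mode="nearest"
        )
        out["forward_y"][s] = ndimage.correlate1d(
            sl, np.array([0.0, -1.0, 1.0]), axis=0, mode="nearest"
        )
    return {n: VoxelVolume(out[n], vol.spacing) for n in GRADIENT_NAMES}


# ---------------------------------------------------------------------------
# Channel extraction and matrix assembly
# ---------------------------------------------------------------------------

def extract_channel_features(
    vol: VoxelVolume,
    mask: ROIMask,
    channel: str,
    window: int = 9,
    levels: int = GLCM_LEVELS,
    bins: int = FIRST_ORDER_BINS,
) -> FeatureMapSet:
    """All 57 feature maps for one scalar channel, names prefixed by it."""
    gray = np.full(vol.shape, MISSING)
    gray[mask.data] = vol.data[mask.data]
    maps: dict[str, VoxelVolume] = {
        f"{channel}_gray": VoxelVolume(gray, vol.spacing)
    }
    for name, m in first_order_maps(vol, mask, window, bins).items():
        maps[f"{channel}_{name}"] = m
    for name, m in glcm_maps(vol, mask, window, levels).items():
        maps[f"{channel}_{name}"] = m
    for name, m in edge_maps(vol).items():
        maps[f"{channel}_{name}"] = m
    for name, m in gradient_maps(vol).items():
        maps[f"{channel}_{name}"] = m
    return FeatureMapSet(channel, maps)


def assemble_feature_matrix(
    channels: list[FeatureMapSet],
    dti: DtiMapSet | None,
    cancer: ROIMask,
    noncancer: ROIMask,
    patient_id: str,
) -> pd.DataFrame:
    """One row per labeled voxel; label +1 for cancer, -1 for noncancer.

    Voxels with any undefined feature are dropped (the drop count is stored
    in ``df.attrs['n_dropped']``).  Metadata columns come first.
    """
    if not channels and dti is None:
        raise ValueError("need at least one feature source")
    if (cancer.data & noncancer.data).any():
        raise ValueError("cancer and noncancer masks overlap")
    names: list[str] = []
    arrays: list[np.ndarray] = []
    for fs in channels:
        for name, vol in fs.maps.items():
            names.append(name)
            arrays.append(vol.data)
    if dti is not None:
        for name in DTI_MAP_NAMES:
            names.append(f"dti_{name}")
            arrays.append(dti[name].data)

    rows = []
    for mask_obj, label in ((cancer, 1), (noncancer, -1)):
        ss, rr, cc = np.nonzero(mask_obj.data)
        block = np.column_stack([a[ss, rr, cc] for a in arrays]) if len(ss) else \
            np.empty((0, len(arrays)))
        meta = pd.DataFrame(
            {"patient_id": patient_id, "slice": ss, "row": rr, "col": cc,
             "label": label}
        )
        rows.append(pd.concat([meta, pd.DataFrame(block, columns=names)], axis=1))
    df = pd.concat(rows, ignore_index=True)
    feature_block = df[names].to_numpy()
    keep = np.isfinite(feature_block).all(axis=1)
    n_dropped = int((~keep).sum())
    df = df.loc[keep].reset_index(drop=True)
    df.attrs["n_dropped"] = n_dropped
    df.attrs["feature_names"] = names
    return df


def feature_columns(df: pd.DataFrame) -> list[str]:
    """The feature columns of an assembled matrix (metadata excluded)."""
    return [c for c in df.columns if c not in METADATA_COLUMNS]


def minmax_fit_apply(
    df: pd.DataFrame, state: NormalizationState | None = None
) -> tuple[pd.DataFrame, NormalizationState]:
    """Min-max scale feature columns to [0, 1].

    With ``state=None`` the bounds are learned from ``df`` (the training
    rows); otherwise the given bounds are applied and out-of-range values
    are clipped to [0, 1].  Constant columns map to 0.
    """
    cols = feature_columns(df)
    if state is None:
        state = NormalizationState(
            {c: (float(df[c].min()), float(df[c].max())) for c in cols}
        )
        clip = False
    else:
        if set(state.bounds) != set(cols):
            raise ValueError("normalization state columns do not match matrix")
        clip = True
    out = df.copy()
    for c in cols:
        lo, hi = state.bounds[c]
        if hi > lo:
            scaled = (out[c].to_numpy() - lo) / (hi - lo)
        else:
            scaled = np.zeros(len(out))
        if clip:
            scaled = np.clip(scaled, 0.0, 1.0)
        out[c] = scaled
    return out, state
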