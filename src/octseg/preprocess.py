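"""OCT preprocessing chain: BM fit, ROI, CLAHE, registration, resize.

The chain follows the order: polynomial Bruch's-membrane (BM) fit, region-
of-interest masking (ILM to BM + 390 um), contrast-limited adaptive
histogram equalisation, shear-based registration of the RPE endpoints onto
one horizontal axis at 65 % image height, resize to the network input
size, and (train-time only) random rotation augmentation.

CLAHE is implemented in the integer-LUT dialect: per-tile 256-bin
histograms are clipped at ``max(1, round(clip_limit * tile_area / n_bins))``
with the excess redistributed uniformly, per-tile CDF mappings to [0, 255],
and each pixel bilinearly blended between the mappings of the four nearest
tile centres (clamping to the nearest tile at the borders).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize


@dataclass
class RoiBounds:
    """Per-column inclusive row bounds; a column with upper > lower is
    degenerate and zero-filled by :func:`mask_outside_roi`."""

    upper: np.ndarray
    lower: np.ndarray

    def __post_init__(self):
        self.upper = np.asarray(self.upper, dtype=int)
        self.lower = np.asarray(self.lower, dtype=int)
        if self.upper.shape != self.lower.shape:
            raise ValueError("upper/lower must have equal length")

    @property
    def degenerate(self) -> np.ndarray:
        return self.upper > self.lower


@dataclass
class ClaheParams:
    grid_size: tuple = (8, 8)
    clip_limit: float = 1.0
    n_bins: int = 256

    def __post_init__(self):
        if min(self.grid_size) < 1 or self.clip_limit <= 0 or self.n_bins < 2:
            raise ValueError("invalid CLAHE parameters")


@dataclass
class RegistrationParams:
    shear_per_column: float  # vertical shift per unit lateral distance (px/px)
    vertical_shift: float  # px
    anchor_fraction: float = 0.65

    def __post_init__(self):
        if not (0.0 < self.anchor_fraction < 1.0):
            raise ValueError("anchor_fraction must lie in (0, 1)")


def fit_bm(candidates, degree: int = 2, image_depth: int | None = None) -> np.ndarray:
    """Least-squares polynomial fit of the BM line over all columns.

    ``candidates`` is a per-column row-index array; missing entries are NaN
    and are ignored by the fit.  The fitted polynomial is evaluated at every
    column and clamped to the image depth when given.
    """
    y = np.asarray(candidates, dtype=float)
    x = np.arange(y.size, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < degree + 1:
        raise ValueError(f"need at least {degree + 1} BM candidates, got {int(ok.sum())}")
    coeffs = np.polyfit(x[ok], y[ok], deg=degree)
    fitted = np.polyval(coeffs, x)
    if image_depth is not None:
        fitted = np.clip(fitted, 0, image_depth - 1)
    return fitted


def compute_roi(ilm, bm, offset_um: float = 390.0, axial_resolution: float = 3.87,
                image_depth: int | None = None) -> RoiBounds:
    """ROI rows: upper = ILM, lower = BM + round(offset / axial resolution)."""
    ilm = np.asarray(ilm)
    bm = np.asarray(bm)
    if ilm.shape != bm.shape:
        raise ValueError("ilm and bm must have the same length")
    if axial_resolution <= 0:
        raise ValueError("axial_resolution must be positive")
    lower = np.round(bm).astype(int) + int(round(offset_um / axial_resolution))
    if image_depth is not None:
        lower = np.clip(lower, 0, image_depth - 1)
    return RoiBounds(upper=np.round(ilm).astype(int), lower=lower)


def mask_outside_roi(image: np.ndarray, roi: RoiBounds) -> np.ndarray:
    """Zero every pixel above ``roi.upper`` or below ``roi.lower``.

    Degenerate columns (upper > lower) are zero-filled entirely.
    """
    if image.shape[1] != roi.upper.size:
        raise ValueError("ROI length does not match image width")
    rows = np.arange(image.shape[0])[:, None]
    keep = (rows >= roi.upper[None, :]) & (rows <= roi.lower[None, :])
    keep &= ~roi.degenerate[None, :]
    out = image.copy()
    out[~keep] = 0
    return out


# ---------------------------------------------------------------------------
# CLAHE


def _tile_lut(hist: np.ndarray, clip: int, area: int, n_bins: int) -> np.ndarray:
    excess = int(np.sum(np.clip(hist - clip, 0, None)))
    hist = np.minimum(hist, clip)
    hist += excess // n_bins
    rem = excess % n_bins
    if rem:
        hist[:rem] += 1  # deterministic remainder rule: first bins
    cdf = np.cumsum(hist)
    return np.round(cdf * (255.0 / area)).astype(np.uint8)


def clahe(image: np.ndarray, params: ClaheParams | None = None) -> np.ndarray:
    if params is None:
        params = ClaheParams()
    img = np.asarray(image)
    if img.dtype != np.uint8:
        raise ValueError("CLAHE expects an 8-bit grayscale image")
    gh, gw = params.grid_size
    h, w = img.shape
    if h < gh or w < gw:
        raise ValueError("image smaller than CLAHE grid")
    th = -(-h // gh)  # ceil
    tw = -(-w // gw)
    pad_h, pad_w = th * gh - h, tw * gw - w
    padded = np.pad(img, ((0, pad_h), (0, pad_w)), mode="reflect") if (pad_h or pad_w) else img

    n_bins = params.n_bins
    area = th * tw
    clip = max(1, int(round(params.clip_limit * area / n_bins)))
    bin_of = (np.arange(256) * n_bins) // 256

    luts = np.empty((gh, gw, n_bins), dtype=np.uint8)
    for i in range(gh):
        for j in range(gw):
            tile = padded[i * th : (i + 1) * th, j * tw : (j + 1) * tw]
            hist = np.bincount(bin_of[tile.ravel()], minlength=n_bins)
            luts[i, j] = _tile_lut(hist, clip, area, n_bins)

    # bilinear blend between the four nearest tile-centre mappings
    ty = (np.arange(h) + 0.5) / th - 0.5
    tx = (np.arange(w) + 0.5) / tw - 0.5
    y0 = np.clip(np.floor(ty).astype(int), 0, gh - 1)
    x0 = np.clip(np.floor(tx).astype(int), 0, gw - 1)
    y1 = np.clip(y0 + 1, 0, gh - 1)
    x1 = np.clip(x0 + 1, 0, gw - 1)
    fy = np.clip(ty - np.floor(ty), 0.0, 1.0)
    fy[ty < 0] = 0.0
    fx = np.clip(tx - np.floor(tx), 0.0, 1.0)
    fx[tx < 0] = 0.0

    b = bin_of[padded[:h, :w]]
    v00 = luts[y0[:, None], x0[None, :], b].astype(float)
    v01 = luts[y0[:, None], x1[None, :], b].astype(float)
    v10 = luts[y1[:, None], x0[None, :], b].astype(float)
    v11 = luts[y1[:, None], x1[None, :], b].astype(float)
    fy2 = fy[:, None]
    fx2 = fx[None, :]
    out = (1 - fy2) * ((1 - fx2) * v00 + fx2 * v01) + fy2 * ((1 - fx2) * v10 + fx2 * v11)
    return np.round(out).astype(np.uint8)


def global_hist_equalize(image: np.ndarray) -> np.ndarray:
    """Plain global histogram equalisation in the same LUT dialect."""
    img = np.asarray(image)
    hist = np.bincount(img.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    lut = np.round(cdf * (255.0 / img.size)).astype(np.uint8)
    return lut[img]


# ---------------------------------------------------------------------------
# registration / resize / augmentation


def register(image: np.ndarray, mask: np.ndarray | None, rpe_left, rpe_right,
             anchor_fraction: float = 0.65):
    """Shear so both RPE endpoints share one row, then translate that row to
    ``round(anchor_fraction * depth)``.

    The shear pivots at the left endpoint (any pivot gives the same
    post-state thanks to the subsequent translation).  Images are resampled
    with linear interpolation, masks with nearest-neighbour; vacated pixels
    are zero-filled.
    """
    (cl, rl), (cr, rr) = rpe_left, rpe_right
    if cl == cr:
        raise ValueError("RPE endpoints must lie in distinct columns")
    if cl > cr:
        (cl, rl), (cr, rr) = (cr, rr), (cl, rl)
    depth, width = image.shape
    slope = (rr - rl) / (cr - cl)
    anchor_row = round(anchor_fraction * depth)
    shift = anchor_row - rl
    cols = np.arange(width, dtype=float)
    dy = shift - slope * (cols - cl)  # applied per-column vertical shift
    rows = np.arange(depth, dtype=float)[:, None]
    src_rows = rows - dy[None, :]
    src_cols = np.broadcast_to(cols[None, :], (depth, width))
    coords = np.stack([src_rows, src_cols])
    out_img = ndimage.map_coordinates(image.astype(float), coords, order=1,
                                      mode="constant", cval=0.0)
    out_img = np.round(np.clip(out_img, 0, 255)).astype(image.dtype)
    out_mask = None
    if mask is not None:
        if mask.shape != image.shape:
            raise ValueError("mask shape must match image shape")
        out_mask = ndimage.map_coordinates(mask, coords, order=0, mode="constant", cval=0)
    params = RegistrationParams(shear_per_column=-slope, vertical_shift=float(shift),
                                anchor_fraction=anchor_fraction)
    return out_img, out_mask, params


def resize(array: np.ndarray, target: int = 224, is_mask: bool = False) -> np.ndarray:
    """Resize to target x target: bilinear for images, nearest for masks."""
    if target < 1:
        raise ValueError("target size must be positive")
    if array.shape == (target, target):
        return array.copy()
    if is_mask:
        out = _sk_resize(array, (target, target), order=0, preserve_range=True,
                         anti_aliasing=False)
        return out.astype(array.dtype)
    out = _sk_resize(array.astype(float), (target, target), order=1, preserve_range=True,
                     anti_aliasing=False)
    if np.issubdtype(array.dtype, np.integer):
        return np.round(np.clip(out, 0, 255)).astype(array.dtype)
    return out.astype(array.dtype)


def augment_rotation(image: np.ndarray, mask: np.ndarray, rng,
                     max_degrees: float = 20.0, probability: float = 0.5):
    """With the given probability rotate image+mask by one shared angle
    drawn uniformly from [-max_degrees, +max_degrees]."""
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes must match")
    if rng.uniform() >= probability:
        return image, mask
    angle = rng.uniform(-max_degrees, max_degrees)
    img = ndimage.rotate(image.astype(float), angle, reshape=False, order=1,
                         mode="constant", cval=0.0)
    if np.issubdtype(image.dtype, np.integer):
        img = np.round(np.clip(img, 0, 255)).astype(image.dtype)
    else:
        img = img.astype(image.dtype)
    msk = ndimage.rotate(mask, angle, reshape=False, order=0, mode="constant", cval=0)
    return img, msk


def overlay_labels(irf: np.ndarray, srf: np.ndarray, ped: np.ndarray) -> np.ndarray:
    """Overlay per-class binary masks into one label map.

    Where classes overlap the highest class index wins (IRF=1 < SRF=2 <
    PED=3), so co-occurrence at a pixel is excluded by construction.
    """
    if not (irf.shape == srf.shape == ped.shape):
        raise ValueError("class masks must share a shape")
    out = np.zeros(irf.shape, dtype=np.uint8)
    out[irf > 0] = 1
    out[srf > 0] = 2
    out[ped > 0] = 3
    return out


# ---------------------------------------------------------------------------
# orchestration


def rpe_endpoints(rpe_line: np.ndarray, valid: np.ndarray | None = None):
    """Left/rightmost valid (column, row) points of the RPE line."""
    cols = np.arange(rpe_line.size)
    if valid is not None:
        cols = cols[valid]
        if cols.size < 2:
            raise ValueError("need at least two valid RPE columns")
    cl, cr = int(cols[0]), int(cols[-1])
    return (cl, float(rpe_line[cl])), (cr, float(rpe_line[cr]))


def preprocess_scan(image: np.ndarray, mask: np.ndarray | None, ilm: np.ndarray,
                    bm_candidates: np.ndarray, rpe_line: np.ndarray | None = None,
                    *, axial_resolution: float = 3.87, offset_um: float = 390.0,
                    bm_degree: int = 2, clahe_params: ClaheParams | None = None,
                    anchor_fraction: float = 0.65, target_size: int = 224):
    """Run the full chain on one scan; returns (image, mask, sidecar dict).

    When no pre-segmented RPE line is available the fitted BM endpoints act
    as the registration proxy.
    """
    depth = image.shape[0]
    bm = fit_bm(bm_candidates, degree=bm_degree, image_depth=depth)
    roi = compute_roi(ilm, bm, offset_um=offset_um, axial_resolution=axial_resolution,
                      image_depth=depth)
    out = mask_outside_roi(image, roi)
    out = clahe(out, clahe_params)
    line = rpe_line if rpe_line is not None else bm
    left, right = rpe_endpoints(np.asarray(line))
    out, out_mask, reg = register(out, mask, left, right, anchor_fraction=anchor_fraction)
    out = resize(out, target_size)
    if out_mask is not None:
        out_mask = resize(out_mask, target_size, is_mask=True)
    sidecar = {
        "bm_degree": bm_degree,
        "roi_upper": roi.upper.tolist(),
        "roi_lower": roi.lower.tolist(),
        "registration": {
            "shear_per_column": reg.shear_per_column,
            "vertical_shift": reg.vertical_shift,
            "anchor_fraction": reg.anchor_fraction,
        },
        "target_size": target_size,
    }
    return out, out_mask, sidecar
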