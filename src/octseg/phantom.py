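"""Synthetic SD-OCT B-scan phantoms with ground-truth lesions and layers.

The generator emulates the data regime of a Spectralis-style raster scan:
49-slice volumes from which 5 slices are drawn with a Gaussian sampler
centred on the middle slice, 512x496 8-bit B-scans, and the three nAMD
lesion classes with their anatomically constrained placement —

* IRF (label 1): hyporeflective blobs strictly between ILM and RPE,
* SRF (label 2): fluid pockets immediately above the RPE line,
* PED (label 3): domes where the RPE detaches from Bruch's membrane.

Pixel intensities are a layered reflectivity template multiplied by
gamma-distributed speckle with mean 1.  Scans containing no lesion are
rejected and resampled, matching a study population in which every scan
shows at least one lesion; the per-class Bernoulli rates are calibrated so
the *emitted* (lesion-conditional) presence frequencies converge to
``class_probs``.

The geometry is parameterised in fractions of image size, so the same code
produces 512x496 scans and miniature 64x64 phantoms for fast experiments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

CLASS_NAMES = {1: "IRF", 2: "SRF", 3: "PED"}
CLASS_IDS = {"IRF": 1, "SRF": 2, "PED": 3}
# overlay colours (Fig-style): IRF light blue, SRF dark red, PED yellow
CLASS_COLORS = {0: (0, 0, 0), 1: (135, 206, 250), 2: (139, 0, 0), 3: (255, 215, 0)}


@dataclass
class PhantomSpec:
    """Data-regime constants for a synthetic OCT dataset."""

    image_width: int = 512
    image_depth: int = 496
    axial_resolution: float = 3.87  # micrometres per pixel (Spectralis-typical)
    n_patients: int = 4
    volumes_per_patient: int = 1
    slices_per_volume: int = 49
    slices_sampled: int = 5
    slice_sigma: float = 6.0
    class_probs: tuple = (0.47, 0.37, 0.84)  # P(IRF), P(SRF), P(PED) among emitted scans
    speckle_shape: float = 4.0
    seed: int = 0

    def __post_init__(self):
        for name in ("image_width", "image_depth", "n_patients", "volumes_per_patient",
                     "slices_per_volume", "slices_sampled"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.slices_sampled > self.slices_per_volume:
            raise ValueError("slices_sampled must be <= slices_per_volume")
        if not all(0.0 <= p <= 1.0 for p in self.class_probs):
            raise ValueError("class_probs must lie in [0, 1]")
        if self.axial_resolution <= 0 or self.speckle_shape <= 0:
            raise ValueError("axial_resolution and speckle_shape must be positive")


@dataclass
class BScan:
    image: np.ndarray  # (depth, width) uint8, row 0 at top
    patient_id: str
    volume_id: str
    slice_index: int
    ilm: np.ndarray  # per-column row index of the internal limiting membrane
    axial_resolution: float


@dataclass
class LayerTruth:
    ilm: np.ndarray
    rpe: np.ndarray
    bm: np.ndarray

    def validate(self):
        if not (np.all(self.ilm < self.rpe) and np.all(self.rpe <= self.bm)):
            raise ValueError("layer ordering ilm < rpe <= bm violated")


def sample_slices(n_slices: int, center: float, sigma: float, k: int, rng) -> np.ndarray:
    """Draw ``k`` distinct slice indices with Gaussian weight around ``center``.

    Sampling is without replacement with mass proportional to a discretised
    Gaussian (Plackett-Luce successive draws, realised as Gumbel-top-k so
    that arbitrarily small ``sigma`` stays numerically exact).  ``sigma=0``
    degenerates to the ``k`` indices nearest the centre.
    """
    if k > n_slices:
        raise ValueError(f"cannot draw {k} distinct slices from {n_slices}")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    idx = np.arange(n_slices)
    dist = np.abs(idx - center)
    if sigma == 0 or 2.0 * sigma * sigma == 0.0:  # incl. subnormal sigma
        order = np.lexsort((idx, dist))
        return np.sort(order[:k])
    logw = -((idx - center) ** 2) / (2.0 * sigma**2)
    gumbel = -np.log(-np.log(rng.uniform(size=n_slices)))
    keys = logw + gumbel
    # -inf keys (underflowed weights) tie-break towards the centre,
    # matching the sigma -> 0 limit law
    order = np.lexsort((dist, -keys))
    return np.sort(order[:k])


def conditional_presence_probs(class_probs) -> np.ndarray:
    """Per-class Bernoulli rates whose lesion-conditional frequencies match
    ``class_probs``.

    Scans without any lesion are rejected, so raw Bernoulli rates ``q`` are
    solved from the fixed point ``q_c = p_c * Z`` with ``Z = P(>=1 lesion)
    = 1 - prod(1 - q_c)`` (independent classes).  Then
    ``P(class c | >= 1 lesion) = q_c / Z = p_c`` exactly.
    """
    p = np.asarray(class_probs, dtype=float)
    if p.max() == 0:
        raise ValueError("at least one class probability must be positive")
    z = 1.0
    for _ in range(200):
        q = np.clip(p * z, 0.0, 1.0)
        z_new = 1.0 - np.prod(1.0 - q)
        if abs(z_new - z) < 1e-12:
            break
        z = z_new
    if z <= 1e-9:
        raise ValueError("class_probs admit no lesion-conditional calibration")
    return np.clip(p * z, 0.0, 1.0)


def sample_presence(spec: PhantomSpec, rng) -> set:
    """Rejection-sample the set of lesion classes present in one scan."""
    q = conditional_presence_probs(spec.class_probs)
    for _ in range(10_000):
        draw = rng.uniform(size=3) < q
        if draw.any():
            return {name for name, hit in zip(("IRF", "SRF", "PED"), draw) if hit}
    raise RuntimeError("presence sampling failed to produce a lesion-bearing scan")


# ---------------------------------------------------------------------------
# geometry + rendering


def _smooth_curve(width, rng, amplitude):
    """Random smooth perturbation: low-frequency sinusoids."""
    u = np.linspace(0.0, 1.0, width)
    y = np.zeros(width)
    for freq in (1, 2, 3):
        y += rng.normal(0, 1) * np.sin(2 * np.pi * freq * u + rng.uniform(0, 2 * np.pi)) / freq
    y /= 2.0
    return amplitude * y


def _layer_geometry(spec: PhantomSpec, rng):
    w, d = spec.image_width, spec.image_depth
    u = np.linspace(-0.5, 0.5, w)
    bm = d * (rng.uniform(0.58, 0.70) + rng.uniform(0.05, 0.30) * (u**2 - 1 / 12))
    bm += _smooth_curve(w, rng, 0.01 * d)
    bm = np.clip(bm, 0.35 * d, 0.92 * d)
    gap = max(2, round(0.012 * d))
    thickness = d * rng.uniform(0.16, 0.22) + _smooth_curve(w, rng, 0.02 * d)
    # foveal dip around a random central column
    dip_c = rng.uniform(-0.15, 0.15)
    thickness -= 0.05 * d * np.exp(-((u - dip_c) ** 2) / (2 * 0.07**2))
    thickness = np.clip(thickness, max(0.10 * d, 7.0), 0.30 * d)
    return bm, gap, thickness


def _dome(width_px, x, xc, hw, hmax):
    t = np.clip(1.0 - ((x - xc) / hw) ** 2, 0.0, None)
    return hmax * t**1.2


def generate_bscan(spec: PhantomSpec, present_classes, rng,
                   patient_id: str = "P000", volume_id: str = "V0", slice_index: int = 0,
                   max_attempts: int = 25):
    """Render one phantom B-scan.

    Returns ``(BScan, mask, LayerTruth)`` where ``mask`` is a (depth, width)
    uint8 array with values 0=BG, 1=IRF, 2=SRF, 3=PED.  Placement is
    retried with fresh lesion geometry when a requested class cannot be
    placed (e.g. a dome collapses to nothing after rounding).
    """
    present = {c.upper() if isinstance(c, str) else CLASS_NAMES[c] for c in present_classes}
    unknown = present - set(CLASS_IDS)
    if unknown:
        raise ValueError(f"unknown lesion classes: {sorted(unknown)}")
    w, d = spec.image_width, spec.image_depth
    x = np.arange(w, dtype=float)

    last_err = None
    for _ in range(max_attempts):
        bm_f, gap, thickness = _layer_geometry(spec, rng)
        rpe_f = bm_f - gap
        if "PED" in present:
            for _ in range(rng.integers(1, 3)):
                xc = rng.uniform(0.15 * w, 0.85 * w)
                hw = rng.uniform(0.07, 0.18) * w
                lo = max(gap + 3, 0.04 * d)
                hmax = rng.uniform(lo, max(0.11 * d, lo + 2))
                rpe_f = rpe_f - _dome(w, x, xc, hw, hmax)
        ilm_f = rpe_f - thickness

        ilm = np.clip(np.round(ilm_f), 1, d - 4).astype(int)
        rpe = np.clip(np.round(rpe_f), 2, d - 3).astype(int)
        bm = np.clip(np.round(bm_f), 3, d - 2).astype(int)
        rpe = np.minimum(rpe, bm)  # dome may not dip below BM
        ilm = np.minimum(ilm, rpe - 1)

        mask = np.zeros((d, w), dtype=np.uint8)
        rows = np.arange(d)[:, None]

        srf_h = np.zeros(w)
        if "SRF" in present:
            for _ in range(rng.integers(1, 3)):
                xc = rng.uniform(0.15 * w, 0.85 * w)
                hw = rng.uniform(0.08, 0.20) * w
                hmax = rng.uniform(0.025, 0.09) * d
                srf_h = np.maximum(srf_h, _dome(w, x, xc, hw, hmax))
            srf_h = np.minimum(srf_h, np.maximum(rpe - ilm - 4, 0))

        if "IRF" in present:
            for _ in range(rng.integers(1, 5)):
                xc = rng.uniform(0.1 * w, 0.9 * w)
                rx = rng.uniform(0.015, 0.06) * w
                ry = rng.uniform(0.012, 0.045) * d
                band_lo = ilm + max(1, round(0.004 * d))
                band_hi = rpe - srf_h - max(2, round(0.006 * d))  # clear of SRF pocket
                ci = int(np.clip(round(xc), 0, w - 1))
                ry = min(ry, (band_hi[ci] - band_lo[ci]) / 2 - 1)  # fit the band
                if ry < 1:
                    continue
                rc = rng.uniform(band_lo[ci] + ry, band_hi[ci] - ry)
                ell = ((rows - rc) / max(ry, 1)) ** 2 + ((x[None, :] - xc) / max(rx, 1)) ** 2 <= 1.0
                inside = (rows >= band_lo[None, :]) & (rows <= band_hi[None, :])
                mask[ell & inside] = 1

        if "SRF" in present:
            region = (rows >= (rpe - srf_h)[None, :]) & (rows < rpe[None, :]) & (srf_h[None, :] >= 1)
            mask[region] = 2

        if "PED" in present:
            pocket = (rows > rpe[None, :]) & (rows < bm[None, :]) & ((bm - rpe)[None, :] > gap + 1)
            mask[pocket] = 3

        got = {CLASS_NAMES[c] for c in np.unique(mask) if c}
        if got == present:
            layers = LayerTruth(ilm=ilm, rpe=rpe, bm=bm)
            layers.validate()
            image = _render(spec, mask, layers, rng)
            scan = BScan(image=image, patient_id=patient_id, volume_id=volume_id,
                         slice_index=slice_index, ilm=ilm.copy(),
                         axial_resolution=spec.axial_resolution)
            return scan, mask, layers
        last_err = f"placed {sorted(got)} instead of {sorted(present)}"
    raise RuntimeError(f"could not place requested lesions after {max_attempts} attempts: {last_err}")


def _render(spec: PhantomSpec, mask, layers: LayerTruth, rng) -> np.ndarray:
    w, d = spec.image_width, spec.image_depth
    rows = np.arange(d)[:, None]
    ilm, rpe, bm = layers.ilm[None, :], layers.rpe[None, :], layers.bm[None, :]

    refl = np.full((d, w), 0.04)  # vitreous
    retina = (rows >= ilm) & (rows < rpe)
    refl[retina] = 0.40
    inner = (rows >= ilm) & (rows < ilm + max(2, round(0.008 * d)))  # bright RNFL
    refl[inner] = 0.62
    rpe_band = (rows >= rpe) & (rows < rpe + max(2, round(0.01 * d)))
    refl[rpe_band] = 0.88
    choroid = rows > bm
    depth_below = np.clip(rows - bm, 0, None)
    refl = np.where(choroid, np.clip(0.26 - 0.002 * depth_below, 0.08, None), refl)

    refl[mask == 1] = 0.06
    refl[mask == 2] = 0.08
    refl[mask == 3] = 0.30

    k = spec.speckle_shape
    speckle = rng.gamma(shape=k, scale=1.0 / k, size=(d, w))
    img = np.clip(refl * speckle, 0.0, 1.0)
    return np.round(img * 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# dataset on disk


def group_label(present) -> str:
    order = [c for c in ("IRF", "PED", "SRF") if c in present]
    return "+".join(order)


def save_mask_png(mask: np.ndarray, path):
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    palette = []
    for i in range(256):
        palette.extend(CLASS_COLORS.get(i, (0, 0, 0)))
    img.putpalette(palette)
    img.save(path)


def load_mask_png(path) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=np.uint8)


def generate_dataset(spec: PhantomSpec, out_dir) -> pd.DataFrame:
    """Write a phantom dataset (images, masks, layer CSVs, manifest.csv).

    Every emitted B-scan carries at least one lesion class; the manifest has
    one row per scan with columns patient_id, volume_id, slice_index,
    image_path, mask_path, ilm_path, groups.
    """
    out = Path(out_dir)
    for sub in ("images", "masks", "layers"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    rows = []
    for p in range(spec.n_patients):
        pid = f"P{p:03d}"
        for v in range(spec.volumes_per_patient):
            vid = f"V{v}"
            ss = np.random.SeedSequence([spec.seed, p, v])
            rng = np.random.default_rng(ss)
            centre = (spec.slices_per_volume - 1) / 2
            slices = sample_slices(spec.slices_per_volume, centre, spec.slice_sigma,
                                   spec.slices_sampled, rng)
            for s in slices:
                present = sample_presence(spec, rng)
                scan, mask, layers = generate_bscan(
                    spec, present, rng, patient_id=pid, volume_id=vid, slice_index=int(s)
                )
                stem = f"{pid}_{vid}_s{int(s):02d}"
                img_path = out / "images" / f"{stem}.png"
                mask_path = out / "masks" / f"{stem}.png"
                ilm_path = out / "layers" / f"{stem}.csv"
                Image.fromarray(scan.image, mode="L").save(img_path)
                save_mask_png(mask, mask_path)
                pd.DataFrame(
                    {"column": np.arange(spec.image_width),
                     "ilm": layers.ilm, "rpe": layers.rpe, "bm": layers.bm}
                ).to_csv(ilm_path, index=False)
                rows.append(
                    {"patient_id": pid, "volume_id": vid, "slice_index": int(s),
                     "image_path": str(img_path.relative_to(out)),
                     "mask_path": str(mask_path.relative_to(out)),
                     "ilm_path": str(ilm_path.relative_to(out)),
                     "groups": group_label(present)}
                )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_record(out_dir, row):
    """Load (image, mask, layers) for one manifest row."""
    out = Path(out_dir)
    image = np.asarray(Image.open(out / row["image_path"]), dtype=np.uint8)
    mask = load_mask_png(out / row["mask_path"])
    lay = pd.read_csv(out / row["ilm_path"])
    layers = LayerTruth(ilm=lay["ilm"].to_numpy(), rpe=lay["rpe"].to_numpy(),
                        bm=lay["bm"].to_numpy())
    return image, mask, layers
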