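"""Synthetic fluorescence images and nucleus / sarcomere morphometry.

The synthetic two-channel images stand in for confocal immunostains:
a nucleus channel (DAPI-like: elliptical nuclei of controlled area) and a
sarcomere channel (striated texture covering a controlled fraction of the
cell area).  Ground truth (ellipse parameters, exact areas, true positive
fraction) is carried alongside the pixels.

Nucleus segmentation follows the classic CellProfiler-style recipe: global
two-class Otsu threshold, shape-based declumping (distance-transform
watershed), size gates on the equivalent diameter, and discarding of
border-touching objects.  Areas are reported in um^2 via the pixel size.

Default pixel size is 0.05 um/px: for the stated 50-250 px size gates to
retain essentially all nuclei of populations with 22-36 um^2 mean area,
the 50 px minimum diameter must fall below
the populations' lower percentiles, which pins the pixel scale near this
value -- at coarser scales the minimum gate would clip or discard the
populations it was meant to keep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

#: Default physical pixel calibration, micrometres per pixel.
DEFAULT_PIXEL_SIZE_UM = 0.05


@dataclass
class NucleusTruth:
    center_px: tuple[float, float]
    semi_axes_px: tuple[float, float]
    orientation_rad: float
    area_um2: float  # pi * a * b in physical units


@dataclass
class SynthImage:
    nucleus_channel: np.ndarray
    sarcomere_channel: np.ndarray
    pixel_size_um: float
    nuclei: list[NucleusTruth] = field(default_factory=list)
    cell_mask: np.ndarray | None = None
    sarcomere_mask: np.ndarray | None = None

    @property
    def true_coverage_percent(self) -> float | None:
        if self.cell_mask is None or self.sarcomere_mask is None:
            return None
        return sarcomere_coverage(self.sarcomere_mask, self.cell_mask)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def synth_nucleus_image(
    n_nuclei: int,
    mean_area_um2: float = 35.7,
    sd_area_um2: float = 16.4,
    clump_fraction: float = 0.1,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    shape: tuple[int, int] = (1536, 1536),
    noise_sd: float = 0.05,
    blur_sigma_px: float = 2.0,
    rng: np.random.Generator | int | None = 0,
) -> SynthImage:
    """Render a seeded nucleus-channel image with exact ground truth.

    Areas are drawn log-normally around ``mean_area_um2``; a
    ``clump_fraction`` of nuclei is placed touching a partner (declumping
    work for the segmenter).  Nuclei never touch the image border, so the
    border filter removes nothing from the ground-truth population.
    """
    if n_nuclei < 0 or not (0.0 <= clump_fraction <= 1.0):
        raise ValueError("invalid generator parameters")
    rng = np.random.default_rng(rng)
    h, w = shape
    img = np.zeros(shape, dtype=float)
    occupancy = np.zeros(shape, dtype=bool)
    nuclei: list[NucleusTruth] = []
    mu, sigma = _lognormal_params(mean_area_um2, sd_area_um2) if n_nuclei else (0.0, 0.0)

    def try_place(center, a_px, b_px, theta, pad=3) -> bool:
        r0, c0 = center
        rr, cc = draw_ellipse(r0, c0, a_px + pad, b_px + pad, shape=shape, rotation=theta)
        if occupancy[rr, cc].any():
            return False
        margin = max(a_px, b_px) + pad
        if not (margin < r0 < h - margin and margin < c0 < w - margin):
            return False
        rr_i, cc_i = draw_ellipse(r0, c0, a_px, b_px, shape=shape, rotation=theta)
        img[rr_i, cc_i] = rng.uniform(0.85, 1.15)
        occupancy[rr, cc] = True
        area_um2 = np.pi * (a_px * pixel_size_um) * (b_px * pixel_size_um)
        nuclei.append(
            NucleusTruth(
                center_px=(r0, c0),
                semi_axes_px=(a_px, b_px),
                orientation_rad=theta,
                area_um2=float(area_um2),
            )
        )
        return True

    placed = 0
    for _ in range(n_nuclei):
        # size drawn once per nucleus; placement retries keep the size so
        # crowding does not select against large nuclei
        area = float(np.exp(mu + sigma * rng.standard_normal()))
        aspect = rng.uniform(0.7, 1.0)
        a_um = np.sqrt(area / (np.pi * aspect))
        a_px = a_um / pixel_size_um
        b_px = a_px * aspect
        theta = rng.uniform(0, np.pi)
        margin = a_px + 4
        if 2 * margin >= min(h, w):
            continue
        clumped = rng.uniform() < clump_fraction and placed > 0
        if clumped:
            r0 = c0 = 0.0  # set below relative to the partner
            # attach next to the previous nucleus with a slight overlap
            prev = nuclei[-1]
            phi = rng.uniform(0, 2 * np.pi)
            d = 0.95 * (max(prev.semi_axes_px) + a_px)
            r0 = prev.center_px[0] + d * np.sin(phi)
            c0 = prev.center_px[1] + d * np.cos(phi)
            # clumped partners may overlap the partner's padding ring
            rr_i, cc_i = draw_ellipse(r0, c0, a_px, b_px, shape=shape, rotation=theta)
            margin = max(a_px, b_px) + 3
            if margin < r0 < h - margin and margin < c0 < w - margin and len(rr_i):
                img[rr_i, cc_i] = rng.uniform(0.85, 1.15)
                occupancy[rr_i, cc_i] = True
                area_um2 = np.pi * (a_px * pixel_size_um) * (b_px * pixel_size_um)
                nuclei.append(
                    NucleusTruth((r0, c0), (a_px, b_px), theta, float(area_um2))
                )
                placed += 1
            continue
        for _attempt in range(80):
            r0 = rng.uniform(margin, h - margin)
            c0 = rng.uniform(margin, w - margin)
            if try_place((r0, c0), a_px, b_px, theta):
                placed += 1
                break

    if blur_sigma_px > 0:
        img = ndi.gaussian_filter(img, blur_sigma_px)
    if noise_sd > 0:
        img = img + noise_sd * rng.standard_normal(shape)
    return SynthImage(
        nucleus_channel=img,
        sarcomere_channel=np.zeros(shape),
        pixel_size_um=pixel_size_um,
        nuclei=nuclei,
    )


def synth_coverage_image(
    coverage_fraction: float,
    shape: tuple[int, int] = (256, 256),
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    stripe_period_px: float = 12.0,
    noise_sd: float = 0.05,
    rng: np.random.Generator | int | None = 0,
) -> SynthImage:
    """Render a sarcomere-channel image with known positive fraction.

    The cell mask is a large blobby region; the sarcomere-positive mask is
    the sub-region nearest a random focus scaled so its area fraction of
    the cell mask equals ``coverage_fraction`` (up to pixel quantization).
    Positive pixels carry a striated (sinusoidal) texture.
    """
    if not (0.0 <= coverage_fraction <= 1.0):
        raise ValueError("coverage_fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]

    # blobby cell mask: thresholded smoothed noise, biased to cover most of the frame
    blob = ndi.gaussian_filter(rng.standard_normal(shape), sigma=min(h, w) / 8.0)
    cell_mask = blob > np.quantile(blob, 0.2)

    # positive sub-region: pixels nearest a focus, grown to the target fraction
    fy, fx = rng.uniform(0, h), rng.uniform(0, w)
    dist = np.hypot(yy - fy, xx - fx)
    dist = np.where(cell_mask, dist, np.inf)
    n_cell = int(cell_mask.sum())
    n_pos = int(round(coverage_fraction * n_cell))
    sarc_mask = np.zeros(shape, dtype=bool)
    if n_pos > 0 and n_cell > 0:
        order = np.argsort(dist, axis=None)[:n_pos]
        sarc_mask.flat[order] = True

    theta = rng.uniform(0, np.pi)
    phase = rng.uniform(0, 2 * np.pi)
    stripes = 0.5 + 0.5 * np.sin(
        2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / stripe_period_px + phase
    )
    img = np.where(sarc_mask, 0.3 + 0.7 * stripes, np.where(cell_mask, 0.15, 0.0))
    if noise_sd > 0:
        img = img + noise_sd * rng.standard_normal(shape)
    return SynthImage(
        nucleus_channel=np.zeros(shape),
        sarcomere_channel=img,
        pixel_size_um=pixel_size_um,
        cell_mask=cell_mask,
        sarcomere_mask=sarc_mask,
    )


@dataclass
class NucleusObject:
    label: int
    pixel_count: int
    area_um2: float
    centroid_px: tuple[float, float]
    touches_border: bool


@dataclass
class SegmentationParams:
    min_diameter_px: float = 50.0
    max_diameter_px: float = 250.0
    declump: bool = True
    declump_smooth_px: float = 4.0
    otsu_bins: int = 256


def segment_nuclei(
    channel: np.ndarray,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    params: SegmentationParams = SegmentationParams(),
) -> tuple[list[NucleusObject], dict]:
    """Segment nuclei with the global-Otsu / declump / size / border recipe.

    Returns ``(kept_objects, accounting)``; accounting satisfies
    ``detected == kept + size_filtered + border_filtered`` (plus a
    ``degenerate`` flag for constant images).
    """
    img = np.asarray(channel, dtype=float)
    accounting = {"detected": 0, "kept": 0, "size_filtered": 0, "border_filtered": 0, "degenerate": False}
    if img.max() == img.min():
        accounting["degenerate"] = True
        return [], accounting
    img = (img - img.min()) / (img.max() - img.min())
    thr = threshold_otsu(img, nbins=params.otsu_bins)
    mask = img > thr
    mask = ndi.binary_fill_holes(mask)

    if params.declump:
        dist = ndi.distance_transform_edt(mask)
        dist_s = ndi.gaussian_filter(dist, params.declump_smooth_px)
        min_dist = max(3, int(round(params.min_diameter_px / 2)))
        peaks = peak_local_max(dist_s, min_distance=min_dist, labels=mask, exclude_border=False)
        markers = np.zeros_like(mask, dtype=int)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        if markers.max() == 0:
            labels = sk_label(mask)
        else:
            labels = watershed(-dist_s, markers, mask=mask)
    else:
        labels = sk_label(mask)

    h, w = mask.shape
    objects: list[NucleusObject] = []
    for region in regionprops(labels):
        accounting["detected"] += 1
        minr, minc, maxr, maxc = region.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        diameter = region.equivalent_diameter_area
        obj = NucleusObject(
            label=region.label,
            pixel_count=int(region.area),
            area_um2=float(region.area) * pixel_size_um**2,
            centroid_px=tuple(region.centroid),
            touches_border=touches,
        )
        if touches:
            accounting["border_filtered"] += 1
        elif not (params.min_diameter_px <= diameter <= params.max_diameter_px):
            accounting["size_filtered"] += 1
        else:
            accounting["kept"] += 1
            objects.append(obj)
    return objects, accounting


def nucleus_areas(
    objects: list[NucleusObject], pixel_size_um: float | None = None
) -> tuple[np.ndarray, dict]:
    """Areas (um^2) of segmented nuclei plus mean +/- sd summary."""
    if pixel_size_um is not None:
        areas = np.asarray([o.pixel_count * pixel_size_um**2 for o in objects])
    else:
        areas = np.asarray([o.area_um2 for o in objects])
    summary = {
        "n": int(areas.size),
        "mean_um2": float(areas.mean()) if areas.size else np.nan,
        "sd_um2": float(areas.std(ddof=1)) if areas.size > 1 else 0.0,
    }
    return areas, summary


def sarcomere_coverage(sarcomere_mask: np.ndarray, cell_mask: np.ndarray) -> float:
    """Percent of the cell area covered by sarcomere-positive signal.

    The positive mask is intersected with the cell mask; an empty cell mask
    yields 0 (degenerate, nothing to measure).
    """
    sarc = np.asarray(sarcomere_mask, dtype=bool)
    cell = np.asarray(cell_mask, dtype=bool)
    if sarc.shape != cell.shape:
        raise ValueError("masks must have the same shape")
    n_cell = int(cell.sum())
    if n_cell == 0:
        return 0.0
    n_pos = int((sarc & cell).sum())
    return 100.0 * n_pos / n_cell


def sarcomere_mask_from_texture(
    channel: np.ndarray,
    stripe_period_px: float = 12.0,
    energy_smooth_px: float = 8.0,
) -> np.ndarray:
    """Estimate the sarcomere-positive mask from striation texture energy.

    Band-passes the image around the striation frequency (difference of
    Gaussians), takes the local energy, and thresholds it with Otsu.  A
    stand-in for the manual (wand-tool) positive masks of the original
    workflow; ground-truth masks are preferred where available.
    """
    img = np.asarray(channel, dtype=float)
    fine = ndi.gaussian_filter(img, stripe_period_px / 6.0)
    coarse = ndi.gaussian_filter(img, stripe_period_px / 2.0)
    band = fine - coarse
    energy = ndi.gaussian_filter(band**2, energy_smooth_px)
    thr = threshold_otsu(energy)
    return energy > thr
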