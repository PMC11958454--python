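"""Cell segmentation and per-cell foci detection.

Mirrors the magic-wand style semi-automated cell outlining plus a per-ROI
threshold-and-label spot detector: the threshold for each cell is computed
from that cell's pixels only, connected components above it (8-connectivity)
that meet a minimum area become foci, and each focus carries its area and
raw integrated/mean intensity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import draw, filters, measure, morphology

__all__ = [
    "CellROI",
    "FocusRecord",
    "segment_cells",
    "detect_foci",
    "foci_to_frame",
    "aggregate_positive_fraction",
    "remove_outliers_iqr",
]


@dataclass
class CellROI:
    cell_id: int
    mask: np.ndarray                     # boolean, full image frame
    role: str = "unassigned"             # mother | daughter | unassigned
    pixel_size_um: float | None = None

    @property
    def area_um2(self) -> float | None:
        if self.pixel_size_um is None:
            return None
        return float(self.mask.sum()) * self.pixel_size_um ** 2


@dataclass
class FocusRecord:
    focus_id: int
    cell_id: int
    frame: int
    centroid: tuple[float, float]        # (row, col), 0-based pixel coords
    area_px: int
    area_um2: float | None
    integrated_intensity: float          # raw sum over the focus mask
    mean_intensity: float
    background_intensity: float          # median of in-cell non-focus pixels
    n_measure_px: int = 0                # pixels in the photometry mask
    mask: np.ndarray | None = None       # boolean, full frame (optional)

    @property
    def integrated_intensity_bgsub(self) -> float:
        n = self.n_measure_px or self.area_px
        return self.integrated_intensity - self.background_intensity * n


def rois_from_labels(label_image: np.ndarray, pixel_size_um: float | None = None,
                     roles: dict[int, str] | None = None) -> list[CellROI]:
    """Wrap an existing label mask (0 = background) as CellROIs, unchanged."""
    rois = []
    for lab in np.unique(label_image):
        if lab == 0:
            continue
        role = (roles or {}).get(int(lab), "unassigned")
        rois.append(CellROI(cell_id=int(lab), mask=label_image == lab,
                            role=role, pixel_size_um=pixel_size_um))
    return rois


def segment_cells(image: np.ndarray, seeds=None, radius_bounds=(3.0, 40.0),
                  n_rays: int = 90, pixel_size_um: float | None = None) -> list[CellROI]:
    """Segment cells from a brightfield image or pass a label mask through.

    Without seeds the image is treated as a label mask. With seeds, a
    magic-wand style ray-casting search runs from each seed: along each of
    ``n_rays`` directions the first strong intensity minimum (the dark cell
    rim typical of brightfield yeast) within ``radius_bounds`` pixels marks
    the boundary; the enclosed polygon becomes the cell mask. Masks are made
    disjoint by first-claim priority in seed order. A seed whose boundary
    search fails yields no ROI (a warning is emitted).
    """
    image = np.asarray(image)
    if seeds is None:
        if not np.issubdtype(image.dtype, np.integer):
            raise ValueError("without seeds, segment_cells expects an integer label mask")
        return rois_from_labels(image, pixel_size_um)

    r_min, r_max = radius_bounds
    claimed = np.zeros(image.shape, dtype=bool)
    img = image.astype(float)
    rois: list[CellROI] = []
    for k, (sr, sc) in enumerate(seeds):
        angles = np.linspace(0.0, 2.0 * math.pi, n_rays, endpoint=False)
        radii = np.arange(1.0, r_max + 1.0)
        rr = sr + radii[None, :] * np.sin(angles)[:, None]
        cc = sc + radii[None, :] * np.cos(angles)[:, None]
        inside = (rr >= 0) & (rr < image.shape[0] - 1) & (cc >= 0) & (cc < image.shape[1] - 1)
        prof = np.full(rr.shape, np.nan)
        ri = np.clip(rr.astype(int), 0, image.shape[0] - 1)
        ci = np.clip(cc.astype(int), 0, image.shape[1] - 1)
        prof[inside] = img[ri, ci][inside]
        boundary_r = np.full(n_rays, np.nan)
        for a in range(n_rays):
            p = prof[a]
            valid = ~np.isnan(p)
            if valid.sum() < 3:
                continue
            # darkest stretch along the ray beyond the minimum radius = rim;
            # take the midpoint of the contiguous dark run so the boundary
            # sits at the rim centre rather than its inner edge
            search = np.where(valid & (radii >= r_min))[0]
            if search.size == 0:
                continue
            pv = p[search]
            lo = pv.min()
            depth = np.nanmax(pv) - lo
            dark = pv <= lo + 0.25 * depth
            i_min = int(np.argmin(pv))
            i0 = i_min
            while i0 > 0 and dark[i0 - 1]:
                i0 -= 1
            i1 = i_min
            while i1 < dark.size - 1 and dark[i1 + 1]:
                i1 += 1
            boundary_r[a] = radii[search[(i0 + i1) // 2]]
        ok = ~np.isnan(boundary_r)
        if ok.sum() < n_rays // 2:
            warnings.warn(f"seed {k} at ({sr},{sc}): no enclosing boundary found")
            continue
        med = np.nanmedian(boundary_r)
        boundary_r[~ok] = med
        # clip outlier rays that shot past the rim
        boundary_r = np.clip(boundary_r, 0.5 * med, 1.5 * med)
        poly_r = sr + boundary_r * np.sin(angles)
        poly_c = sc + boundary_r * np.cos(angles)
        rr_fill, cc_fill = draw.polygon(poly_r, poly_c, shape=image.shape)
        mask = np.zeros(image.shape, dtype=bool)
        mask[rr_fill, cc_fill] = True
        mask &= ~claimed
        if not mask.any():
            warnings.warn(f"seed {k}: region fully claimed by earlier seeds")
            continue
        claimed |= mask
        rois.append(CellROI(cell_id=k + 1, mask=mask, pixel_size_um=pixel_size_um))
    return rois


_THRESHOLDERS = {"otsu", "mean", "percentile", "fixed"}


def _threshold(values: np.ndarray, method: str, percentile: float,
               fixed_value: float | None) -> float:
    if method == "otsu":
        if np.ptp(values) == 0:
            return float(values[0]) + 1.0  # uniform ROI: nothing suprathreshold
        return float(filters.threshold_otsu(values))
    if method == "mean":
        return float(values.mean())
    if method == "percentile":
        return float(np.percentile(values, percentile))
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("threshold_method='fixed' requires fixed_value")
        return float(fixed_value)
    raise ValueError(f"unknown threshold_method {method!r}")


def detect_foci(image: np.ndarray, cell_rois, threshold_method: str = "otsu",
                min_area_px: int = 4, fixed_value: float | None = None,
                percentile: float = 99.0, frame: int = 0,
                pixel_size_um: float | None = None,
                keep_masks: bool = False,
                measure_dilation_px: int = 2) -> list[FocusRecord]:
    """Detect fluorescent foci inside each cell ROI.

    The threshold is computed per ROI from that ROI's pixels only; connected
    components (8-connectivity) strictly above threshold with at least
    ``min_area_px`` pixels become FocusRecords. Centroid and area describe
    the thresholded object; the integrated intensity is measured over the
    object dilated by ``measure_dilation_px`` (clipped to the cell mask) so
    the PSF tails below threshold are included in the photometry.
    """
    if threshold_method not in _THRESHOLDERS:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    image = np.asarray(image)
    records: list[FocusRecord] = []
    fid = 0
    for roi in cell_rois:
        vals = image[roi.mask]
        if vals.size == 0:
            continue
        thr = _threshold(vals.astype(float), threshold_method, percentile, fixed_value)
        above = (image > thr) & roi.mask
        labels = measure.label(above, connectivity=2)
        bg_pool = image[roi.mask & ~above]
        background = float(np.median(bg_pool)) if bg_pool.size else 0.0
        psz = pixel_size_um if pixel_size_um is not None else roi.pixel_size_um
        for region in measure.regionprops(labels, intensity_image=image):
            if region.area < min_area_px:
                continue
            fid += 1
            core = labels == region.label
            if measure_dilation_px > 0:
                meas = morphology.dilation(
                    core, morphology.disk(measure_dilation_px)) & roi.mask
            else:
                meas = core
            integrated = float(image[meas].sum())
            records.append(FocusRecord(
                focus_id=fid, cell_id=roi.cell_id, frame=frame,
                centroid=tuple(region.centroid), area_px=int(region.area),
                area_um2=None if psz is None else float(region.area) * psz ** 2,
                integrated_intensity=integrated,
                mean_intensity=float(region.intensity_mean),
                background_intensity=background,
                n_measure_px=int(meas.sum()),
                mask=meas if keep_masks else None,
            ))
    return records


def foci_to_frame(records) -> pd.DataFrame:
    """Tabulate FocusRecords (the spot detector's output table)."""
    return pd.DataFrame([{
        "focus_id": r.focus_id, "cell_id": r.cell_id, "frame": r.frame,
        "row": r.centroid[0], "col": r.centroid[1],
        "area_px": r.area_px, "area_um2": r.area_um2,
        "integrated_intensity": r.integrated_intensity,
        "mean_intensity": r.mean_intensity,
        "integrated_intensity_bgsub": r.integrated_intensity_bgsub,
    } for r in records])


def aggregate_positive_fraction(foci, cells) -> float:
    """Percent of cells containing at least one detected focus."""
    cell_ids = {c.cell_id if isinstance(c, CellROI) else int(c) for c in cells}
    if not cell_ids:
        raise ValueError("aggregate_positive_fraction undefined for zero cells")
    positive = {f.cell_id if isinstance(f, FocusRecord) else int(f) for f in foci}
    return 100.0 * len(positive & cell_ids) / len(cell_ids)


def remove_outliers_iqr(values, k: float = 1.5) -> np.ndarray:
    """Drop values outside [Q1 - k*IQR, Q3 + k*IQR] (linear-interp quartiles)."""
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        warnings.warn("fewer than 4 values: IQR filter returns input unchanged")
        return values
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return values[(values >= lo) & (values <= hi)]
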