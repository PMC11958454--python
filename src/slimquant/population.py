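"""Condition-level statistics over detected aggregates.

Covers the four population readouts: colocalization of aggregate foci with
an organelle marker (centroid within a distance criterion of the organelle
mask), mother/daughter asymmetry of focus area and intensity, inheritance
scoring across a budding time-lapse, and two-condition hypothesis tests with
fold-change arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .detection import FocusRecord, remove_outliers_iqr

__all__ = [
    "ColocalizationResult",
    "InheritanceResult",
    "colocalize",
    "mother_daughter_stats",
    "inheritance_score",
    "compare_conditions",
    "fold_changes",
]


@dataclass
class ColocalizationResult:
    n_foci: int
    n_colocalized: int
    fraction: float                   # percent
    max_distance_nm: float


@dataclass
class InheritanceResult:
    frames: list[int]
    mother_counts: list[int]
    bud_counts: list[int]
    organelle_in_bud: list[bool]
    inherited_fraction: float         # bud share of foci at the final frame


def _centroids(foci) -> np.ndarray:
    pts = []
    for f in foci:
        if isinstance(f, FocusRecord):
            pts.append(f.centroid)
        else:
            pts.append(tuple(f))
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def colocalize(foci, organelle_mask: np.ndarray, pixel_size_nm: float,
               max_distance: float = 250.0) -> ColocalizationResult:
    """Fraction of foci whose centroid lies within ``max_distance`` (nm, the
    optical-resolution criterion by default) of the organelle mask."""
    pts = _centroids(foci)
    if pts.shape[0] == 0:
        raise ValueError("colocalization fraction undefined for zero foci")
    organelle_mask = np.asarray(organelle_mask, dtype=bool)
    if organelle_mask.any():
        dist_px = ndimage.distance_transform_edt(~organelle_mask)
    else:
        dist_px = np.full(organelle_mask.shape, np.inf)
    rows = np.clip(np.round(pts[:, 0]).astype(int), 0, organelle_mask.shape[0] - 1)
    cols = np.clip(np.round(pts[:, 1]).astype(int), 0, organelle_mask.shape[1] - 1)
    d_nm = dist_px[rows, cols] * pixel_size_nm
    n_coloc = int(np.sum(d_nm <= max_distance))
    return ColocalizationResult(n_foci=pts.shape[0], n_colocalized=n_coloc,
                                fraction=100.0 * n_coloc / pts.shape[0],
                                max_distance_nm=float(max_distance))


def mother_daughter_stats(foci, rois, iqr_k: float = 1.5) -> pd.DataFrame:
    """Per-role focus-metric summaries (IQR-filtered mean ± sd).

    Each focus is assigned the role of its cell ROI; roles without foci are
    reported with NaN summaries and flagged empty.
    """
    role_of = {r.cell_id: r.role for r in rois}
    rows = []
    by_role: dict[str, dict[str, list]] = {}
    for f in foci:
        role = role_of.get(f.cell_id)
        if role is None:
            raise ValueError(f"focus {f.focus_id} references unknown cell {f.cell_id}")
        d = by_role.setdefault(role, {"area": [], "intensity": []})
        d["area"].append(f.area_um2 if f.area_um2 is not None else f.area_px)
        d["intensity"].append(f.integrated_intensity)
    for role in sorted({r.role for r in rois}):
        d = by_role.get(role)
        if not d:
            rows.append({"role": role, "n_foci": 0, "empty": True,
                         "mean_area": np.nan, "sd_area": np.nan,
                         "mean_intensity": np.nan, "sd_intensity": np.nan})
            continue
        area = remove_outliers_iqr(d["area"], k=iqr_k)
        inten = remove_outliers_iqr(d["intensity"], k=iqr_k)
        rows.append({"role": role, "n_foci": len(d["area"]), "empty": False,
                     "mean_area": float(np.mean(area)),
                     "sd_area": float(np.std(area, ddof=1)) if area.size > 1 else 0.0,
                     "mean_intensity": float(np.mean(inten)),
                     "sd_intensity": float(np.std(inten, ddof=1)) if inten.size > 1 else 0.0})
    return pd.DataFrame(rows)


def inheritance_score(foci_by_frame, cell_masks_by_frame, organelle_masks_by_frame=None,
                      mother_label: int = 1, bud_label: int = 2) -> InheritanceResult:
    """Count aggregates in mother vs bud per time point.

    ``foci_by_frame`` maps frame -> foci (FocusRecords or (row, col) pairs);
    masks map frame -> label image (mother/bud) and boolean organelle mask.
    Frames without a cell mask are skipped with a warning. The inherited
    fraction is the bud's share of all foci at the final scored frame.
    """
    frames, mcounts, bcounts, oflags = [], [], [], []
    for frame in sorted(foci_by_frame):
        mask = cell_masks_by_frame.get(frame)
        if mask is None:
            warnings.warn(f"no cell mask for frame {frame}: skipped")
            continue
        pts = _centroids(foci_by_frame[frame])
        m = b = 0
        for r, c in pts:
            lab = mask[int(round(r)), int(round(c))]
            if lab == bud_label:
                b += 1
            else:
                m += 1
        frames.append(frame)
        mcounts.append(m)
        bcounts.append(b)
        if organelle_masks_by_frame is not None:
            org = organelle_masks_by_frame.get(frame)
            oflags.append(bool(org is not None and np.any(org & (mask == bud_label))))
        else:
            oflags.append(False)
    if not frames:
        raise ValueError("no scorable time points")
    total = mcounts[-1] + bcounts[-1]
    frac = bcounts[-1] / total if total else 0.0
    return InheritanceResult(frames=frames, mother_counts=mcounts,
                             bud_counts=bcounts, organelle_in_bud=oflags,
                             inherited_fraction=float(frac))


def compare_conditions(sample_a, sample_b, test: str = "mann_whitney"):
    """Two-sided comparison of two condition samples.

    ``student_t`` is Welch's unequal-variance t-test; ``mann_whitney`` uses
    exact enumeration for small tie-free samples and the tie-corrected
    normal approximation otherwise. Degenerate identical zero-variance
    samples under t return (0.0, 1.0) with a warning rather than NaN.
    Returns ``(statistic, p_value)``.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if test == "student_t":
        if a.size < 3 or b.size < 3:
            raise ValueError("t-test needs at least 3 values per sample")
        if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
            warnings.warn("identical zero-variance samples: p set to 1")
            return 0.0, 1.0
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if test == "mann_whitney":
        if a.size < 1 or b.size < 1:
            raise ValueError("U test needs at least 1 value per sample")
        has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "exact" if (max(a.size, b.size) <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def fold_changes(mean_a: float, mean_b: float) -> dict[str, float]:
    """Fold-change arithmetic between two condition means (a = reference).

    Reports the ratio b/a, the percent increase 100*(b-a)/a, and — because
    "a decrease of X%" is printed ambiguously in this field — both decrease
    conventions: percent_decrease = 100*(a-b)/a and remaining_percent =
    100*b/a.
    """
    if mean_a <= 0:
        raise ValueError("reference mean must be positive for fold changes")
    return {
        "factor": mean_b / mean_a,
        "percent_increase": 100.0 * (mean_b - mean_a) / mean_a,
        "percent_decrease": 100.0 * (mean_a - mean_b) / mean_a,
        "remaining_percent": 100.0 * mean_b / mean_a,
    }
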