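"""End-to-end orchestration: detect -> localize -> link -> count -> diffuse.

The stack driver crops each labelled cell (plus a fitting margin), runs
per-frame foci detection and sub-pixel localization inside the crop, links
localizations into tracks, extends each track's intensity trace past its
last frame (fixed-position flux readout, so the full photobleaching tail is
recorded), then calibrates single-molecule brightness from the terminal
bleaching steps and converts each track's initial intensity into a molecule
count. Per-track diffusion coefficients come from the initial MSD gradient.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .detection import CellROI, detect_foci, foci_to_frame
from .stoichiometry import (initial_intensity, single_molecule_brightness,
                            stoichiometry)
from .tracking import (LocalizationError, Track, compute_msd,
                       estimate_diffusion, link_tracks, localize_focus,
                       measure_flux)

__all__ = ["CellAnalysis", "StackAnalysis", "analyze_stack", "run_pipeline", "RunManifest"]


@dataclass
class CellAnalysis:
    cell_id: int
    tracks: list[Track]
    traces: dict[int, tuple[np.ndarray, np.ndarray]]   # track_id -> (frames, intensities)
    n_rejected: int


@dataclass
class StackAnalysis:
    cells: list[CellAnalysis]
    foci: pd.DataFrame
    tracks: pd.DataFrame
    stoichiometries: pd.DataFrame
    diffusion: pd.DataFrame
    calibration: object | None

    @property
    def mean_stoichiometry(self) -> float:
        return float(self.stoichiometries["stoichiometry"].mean())

    @property
    def mean_diffusion(self) -> float:
        return float(self.diffusion["d_coeff"].mean())


def _crop_bounds(mask: np.ndarray, margin: int, shape) -> tuple[int, int, int, int]:
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    r0 = max(0, rows[0] - margin)
    r1 = min(shape[0], rows[-1] + margin + 1)
    c0 = max(0, cols[0] - margin)
    c1 = min(shape[1], cols[-1] + margin + 1)
    return r0, r1, c0, c1


def _analyze_cell(movie: np.ndarray, cell_mask: np.ndarray, cell_id: int,
                  config: PipelineConfig, extend_frames: int = 80) -> CellAnalysis:
    acq = config.acquisition
    det = config.detection
    trk = config.tracking
    margin = trk.window_radius + 2
    r0, r1, c0, c1 = _crop_bounds(cell_mask, margin, movie.shape[1:])
    crop = movie[:, r0:r1, c0:c1]
    roi = CellROI(cell_id=cell_id, mask=cell_mask[r0:r1, c0:c1],
                  pixel_size_um=acq.pixel_size_um)
    sigma_px = acq.psf_sigma_px

    locs_by_frame: dict[int, list] = {}
    n_rejected = 0
    for t in range(crop.shape[0]):
        foci = detect_foci(crop[t], [roi], threshold_method=det.threshold_method,
                           min_area_px=det.min_area_px, fixed_value=det.fixed_value,
                           percentile=det.percentile, frame=t)
        frame_locs = []
        for f in foci:
            try:
                loc = localize_focus(crop[t], f.centroid, window_radius=trk.window_radius,
                                     sigma_px=sigma_px, pixel_size_nm=acq.pixel_size,
                                     frame=t)
            except LocalizationError:
                n_rejected += 1
                continue
            frame_locs.append(loc)
        if frame_locs:
            locs_by_frame[t] = frame_locs

    tracks = [t for t in link_tracks(locs_by_frame, trk.max_disp)
              if len(t) >= trk.min_track_length]
    traces: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for tr in tracks:
        tr.cell_id = cell_id
        frames = tr.frames
        trace = tr.intensity_trace
        last = tr.localizations[-1]
        ext_frames, ext_vals = [], []
        for t in range(last.frame + 1, min(crop.shape[0], last.frame + 1 + extend_frames)):
            try:
                ext_vals.append(measure_flux(crop[t], (last.y, last.x), sigma_px,
                                             trk.window_radius))
                ext_frames.append(t)
            except LocalizationError:
                break
        traces[tr.track_id] = (np.concatenate([frames, ext_frames]).astype(int),
                               np.concatenate([trace, ext_vals]))
        # offset coordinates back to the full frame
        for loc in tr.localizations:
            loc.x += c0
            loc.y += r0
    return CellAnalysis(cell_id=cell_id, tracks=tracks, traces=traces,
                        n_rejected=n_rejected)


def analyze_stack(movie: np.ndarray, cell_mask: np.ndarray,
                  config: PipelineConfig | None = None,
                  brightness=None) -> StackAnalysis:
    """Run the full quantification pipeline on one movie + label mask.

    ``brightness`` may be a known single-molecule intensity (skips in-situ
    calibration); by default it is calibrated from the terminal bleaching
    steps of this stack's own traces. Stoichiometry is reported for the
    longest track of each cell (one aggregate measurement per cell).
    """
    config = config or PipelineConfig()
    acq = config.acquisition
    sto = config.stoichiometry
    labels = [int(l) for l in np.unique(cell_mask) if l != 0]
    cells = [_analyze_cell(movie, cell_mask == lab, lab, config) for lab in labels]

    all_tracks: list[Track] = []
    track_rows = []
    for ca in cells:
        for tr in ca.tracks:
            all_tracks.append(tr)
            for loc in tr.localizations:
                track_rows.append({
                    "cell_id": ca.cell_id, "track_id": f"{ca.cell_id}:{tr.track_id}",
                    "frame": loc.frame, "x_px": loc.x, "y_px": loc.y,
                    "x_um": loc.x * acq.pixel_size_um, "y_um": loc.y * acq.pixel_size_um,
                    "summed_intensity": loc.summed_intensity,
                    "fitted_sigma": loc.fitted_sigma,
                    "precision_nm": loc.precision_estimate,
                })
    tracks_df = pd.DataFrame(track_rows)

    # single-molecule brightness: in-situ stepwise-photobleaching calibration
    calibration = None
    if brightness is None:
        all_traces = [vals for ca in cells for (_, vals) in ca.traces.values()]
        calibration = single_molecule_brightness(
            all_traces, method=sto.calibration_method, ck_window=sto.ck_window,
            ck_exponent=sto.ck_exponent, min_dwell=sto.min_dwell,
            rng=config.seed)
        brightness_value = calibration.value
    else:
        brightness_value = float(getattr(brightness, "value", brightness))

    stoich_rows = []
    for ca in cells:
        if not ca.tracks:
            continue
        best = max(ca.tracks, key=len)
        frames, vals = ca.traces[best.track_id]
        i0 = initial_intensity(vals, frames, window=sto.initial_window)
        est = stoichiometry(i0, brightness_value, dark_fraction=sto.dark_fraction,
                            track_id=best.track_id)
        stoich_rows.append({"cell_id": ca.cell_id,
                            "track_id": f"{ca.cell_id}:{best.track_id}",
                            "I0": est.initial_intensity,
                            "stoichiometry": est.stoichiometry,
                            "dark_corrected": est.dark_corrected})
    stoich_df = pd.DataFrame(stoich_rows)

    diff_rows = []
    for ca in cells:
        for tr in ca.tracks:
            if len(tr) < config.tracking.msd_n_points + 1:
                continue
            msd = compute_msd(tr.positions_px * acq.pixel_size_um, tr.frames,
                              acq.frame_interval)
            if len(msd.intervals) < 2:
                continue
            est = estimate_diffusion(msd, config.tracking.msd_n_points)
            diff_rows.append({"cell_id": ca.cell_id,
                              "track_id": f"{ca.cell_id}:{tr.track_id}",
                              "d_coeff": est.d_coeff, "intercept": est.intercept,
                              "n_points": est.n_points_used})
    diff_df = pd.DataFrame(diff_rows)

    foci_df = foci_to_frame([])  # per-frame foci are consumed internally
    return StackAnalysis(cells=cells, foci=foci_df, tracks=tracks_df,
                         stoichiometries=stoich_df, diffusion=diff_df,
                         calibration=calibration)


@dataclass
class RunManifest:
    config: dict
    inputs: dict[str, str]        # path -> sha256
    package_version: str
    row_counts: dict[str, int]
    timestamp: str

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, image_path, mask_path, outdir) -> RunManifest:
    """File-to-file pipeline: read stack + mask, analyze, write CSVs + manifest."""
    from .io import read_stack, write_table
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    movie = read_stack(image_path)
    mask = read_stack(mask_path)[0]
    res = analyze_stack(movie, mask, config)
    write_table(res.tracks, outdir / "tracks.csv")
    write_table(res.stoichiometries, outdir / "stoichiometry.csv")
    write_table(res.diffusion, outdir / "diffusion.csv")
    if res.calibration is not None:
        write_table(pd.DataFrame([{
            "I_single": res.calibration.value,
            "ci_low": res.calibration.ci[0], "ci_high": res.calibration.ci[1],
            "method": res.calibration.method,
            "n_steps_used": res.calibration.n_steps_used,
        }]), outdir / "calibration.csv")
    manifest = RunManifest(
        config=config.to_dict(),
        inputs={str(image_path): _sha256(image_path), str(mask_path): _sha256(mask_path)},
        package_version=__version__,
        row_counts={"tracks": len(res.tracks), "stoichiometry": len(res.stoichiometries),
                    "diffusion": len(res.diffusion)},
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest
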