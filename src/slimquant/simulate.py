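"""Synthetic microscopy with known ground truth.

Generates the two acquisition styles the analysis pipeline consumes:

* **Slimfield movies** — millisecond-sampled single-channel stacks in which
  each aggregate is a sub-resolution cluster of N fluorophores undergoing
  independent stochastic photobleaching, diffusing inside a cell boundary.
* **Confocal time-lapses** — two-channel, 10-minute-interval sequences of a
  mother/bud pair with an organelle marker that is inherited into the bud at
  a stage-specific time (vacuole early ~20 min, nucleus late ~60 min) while
  aggregates are retained in the mother.

Every simulated object carries a ground-truth record (true positions, true
molecule counts, per-fluorophore bleach frames) so each downstream stage can
be validated by parameter recovery rather than by eye.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import special

from .config import SimulationConfig

__all__ = [
    "DiskBounds",
    "MaskBounds",
    "AggregateGroundTruth",
    "SyntheticStack",
    "MotherBudGeometry",
    "simulate_brownian_track",
    "simulate_photobleaching",
    "render_stack",
    "simulate_slimfield_movie",
    "simulate_confocal_timelapse",
    "disk_mask",
]


# ---------------------------------------------------------------------------
# boundaries

class DiskBounds:
    """Circular cell boundary in µm; Brownian steps reflect at the rim."""

    def __init__(self, center: tuple[float, float], radius: float):
        if radius <= 0:
            raise ValueError("radius must be positive")
        self.center = np.asarray(center, dtype=float)
        self.radius = float(radius)

    def contains(self, point) -> bool:
        return float(np.hypot(*(np.asarray(point) - self.center))) <= self.radius

    def reflect(self, point):
        p = np.asarray(point, dtype=float)
        d = p - self.center
        r = float(np.hypot(*d))
        if r <= self.radius:
            return p
        # mirror across the circular rim; clamp pathological long jumps
        r_new = 2.0 * self.radius - r
        if r_new < 0:
            r_new = self.radius * 0.999
        return self.center + d / r * r_new


class MaskBounds:
    """Arbitrary boolean-mask boundary (pixel grid), reflecting per axis."""

    def __init__(self, mask: np.ndarray, pixel_size_um: float):
        self.mask = np.asarray(mask, dtype=bool)
        self.pixel_size_um = float(pixel_size_um)

    def _inside(self, x: float, y: float) -> bool:
        col = int(round(x / self.pixel_size_um))
        row = int(round(y / self.pixel_size_um))
        if not (0 <= row < self.mask.shape[0] and 0 <= col < self.mask.shape[1]):
            return False
        return bool(self.mask[row, col])

    def contains(self, point) -> bool:
        return self._inside(point[0], point[1])

    def reflect(self, point, previous=None):
        x, y = float(point[0]), float(point[1])
        if self._inside(x, y):
            return np.array([x, y])
        if previous is None:
            return np.array([x, y])
        px, py = float(previous[0]), float(previous[1])
        # try mirroring the offending displacement component(s)
        for cand in ((2 * px - x, y), (x, 2 * py - y), (2 * px - x, 2 * py - y)):
            if self._inside(*cand):
                return np.array(cand)
        return np.array([px, py])  # step rejected: stay put


def disk_mask(shape: tuple[int, int], center_px: tuple[float, float],
              radius_px: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center_px[0]) ** 2 + (cc - center_px[1]) ** 2 <= radius_px ** 2


# ---------------------------------------------------------------------------
# ground-truth containers

@dataclass
class AggregateGroundTruth:
    """True state of one simulated aggregate.

    ``trajectory`` holds the per-frame true centre in µm as (x, y) with x
    along image columns and y along rows. ``bleach_frames[i]`` is the first
    frame at which fluorophore i is no longer photoactive (np.inf = never);
    a fluorophore flagged dark is never photoactive at all.
    """

    aggregate_id: int
    true_n_molecules: int
    diffusion_coeff: float                  # µm²/s
    trajectory: np.ndarray                  # (n_frames, 2) µm
    bleach_frames: np.ndarray               # (n_molecules,) float, inf allowed
    dark_flags: np.ndarray                  # (n_molecules,) bool
    cell_label: int = 1

    def n_active(self, frame: int) -> int:
        return int(np.sum(~self.dark_flags & (self.bleach_frames > frame)))

    def active_counts(self, n_frames: int) -> np.ndarray:
        frames = np.arange(n_frames)[:, None]
        return np.sum(~self.dark_flags[None, :] & (self.bleach_frames[None, :] > frames), axis=1)


@dataclass
class SyntheticStack:
    """A rendered movie with its ground truth and cell mask."""

    movie: np.ndarray                       # (frames, rows, cols) uint16
    config: SimulationConfig
    truths: list[AggregateGroundTruth]
    cell_mask: np.ndarray                   # uint16 label image
    lineage: dict | None = None             # confocal fixtures only


# ---------------------------------------------------------------------------
# stochastic processes

def simulate_brownian_track(d_coeff: float, n_frames: int, frame_interval: float,
                            start, bounds=None, rng=None) -> np.ndarray:
    """Simulate a 2D Brownian trajectory (µm), reflecting at ``bounds``.

    Per-axis displacements are i.i.d. normal with variance 2*D*dt. With
    ``d_coeff=0`` the walker stays at ``start``.
    """
    if d_coeff < 0:
        raise ValueError("d_coeff must be non-negative")
    rng = np.random.default_rng(rng)
    start = np.asarray(start, dtype=float)
    if bounds is not None and not bounds.contains(start):
        raise ValueError("start position lies outside bounds")
    pos = np.empty((n_frames, 2))
    pos[0] = start
    if n_frames == 1:
        return pos
    sd = math.sqrt(2.0 * d_coeff * frame_interval)
    steps = rng.normal(0.0, sd, size=(n_frames - 1, 2))
    if bounds is None:
        pos[1:] = start + np.cumsum(steps, axis=0)
        return pos
    cur = start.copy()
    for t in range(1, n_frames):
        prop = cur + steps[t - 1]
        if isinstance(bounds, MaskBounds):
            cur = bounds.reflect(prop, previous=cur)
        else:
            cur = bounds.reflect(prop)
        pos[t] = cur
    return pos


def simulate_photobleaching(n_molecules: int, bleach_prob: float,
                            dark_fraction: float, n_frames: int, rng=None):
    """Per-fluorophore stochastic photobleaching.

    Each non-dark fluorophore is photoactive at frame 0 and survives each
    subsequent frame with probability 1 - bleach_prob, i.e. its bleach frame
    is geometric: the expected photoactive count at frame t is
    N*(1-p_dark)*(1-p_bleach)^t.

    Returns ``(counts, bleach_frames, dark_flags)`` where ``counts[t]`` is
    the photoactive count at frame t.
    """
    if not (0.0 <= bleach_prob <= 1.0) or not (0.0 <= dark_fraction < 1.0):
        raise ValueError("probabilities out of range")
    rng = np.random.default_rng(rng)
    dark = rng.random(n_molecules) < dark_fraction
    if bleach_prob == 0.0:
        bleach = np.full(n_molecules, np.inf)
    else:
        bleach = rng.geometric(bleach_prob, size=n_molecules).astype(float)
    frames = np.arange(n_frames)[:, None]
    counts = np.sum(~dark[None, :] & (bleach[None, :] > frames), axis=1)
    return counts, bleach, dark


# ---------------------------------------------------------------------------
# rendering

def _pixel_integrated_gaussian(rows, cols, y_px, x_px, sigma_px):
    """Fraction of a unit-flux PSF falling in each pixel (erf-integrated)."""
    s = sigma_px * math.sqrt(2.0)
    fx = 0.5 * (special.erf((cols + 0.5 - x_px) / s) - special.erf((cols - 0.5 - x_px) / s))
    fy = 0.5 * (special.erf((rows + 0.5 - y_px) / s) - special.erf((rows - 0.5 - y_px) / s))
    return fy[:, None] * fx[None, :]


def add_spot(signal: np.ndarray, x_px: float, y_px: float, flux: float,
             sigma_px: float) -> None:
    """Accumulate a pixel-integrated Gaussian spot into a signal frame."""
    if flux <= 0:
        return
    radius = int(math.ceil(6.0 * sigma_px + 2.0))
    r0 = max(0, int(round(y_px)) - radius)
    r1 = min(signal.shape[0], int(round(y_px)) + radius + 1)
    c0 = max(0, int(round(x_px)) - radius)
    c1 = min(signal.shape[1], int(round(x_px)) + radius + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    signal[r0:r1, c0:c1] += flux * _pixel_integrated_gaussian(rows, cols, y_px, x_px, sigma_px)


def render_stack(config: SimulationConfig, truths: Sequence[AggregateGroundTruth],
                 cell_mask: np.ndarray | None = None, *, noise: bool = True,
                 rng=None) -> SyntheticStack:
    """Render a movie from ground truth under the camera model.

    Pixel value = Poisson(PSF signal + background) + Gaussian read noise,
    clipped at zero and quantised to uint16. All fluorophores of one
    aggregate are co-located (aggregates are sub-resolution). With
    ``noise=False`` the expected signal is returned un-quantised, which makes
    photon conservation exactly checkable.
    """
    n_frames = config.n_frames
    rows, cols = config.image_shape
    px_um = config.pixel_size_um
    sigma_px = config.psf_sigma_px
    if cell_mask is None:
        cell_mask = np.ones((rows, cols), dtype=np.uint16)
    for tr in truths:
        if tr.trajectory.shape[0] < n_frames:
            raise ValueError(f"aggregate {tr.aggregate_id}: trajectory shorter than n_frames")
        xy_px = tr.trajectory[:n_frames] / px_um
        if (xy_px < -0.5).any() or (xy_px[:, 0] > cols - 0.5).any() or (xy_px[:, 1] > rows - 0.5).any():
            raise ValueError(f"aggregate {tr.aggregate_id}: trajectory leaves the image")

    rng = np.random.default_rng(config.rng_seed + 1 if rng is None else rng)
    counts = [tr.active_counts(n_frames) for tr in truths]

    if noise:
        movie = np.empty((n_frames, rows, cols), dtype=np.uint16)
    else:
        movie = np.empty((n_frames, rows, cols), dtype=np.float64)
    signal = np.empty((rows, cols), dtype=np.float64)
    for t in range(n_frames):
        signal[:] = config.background_photons
        for tr, cnt in zip(truths, counts):
            flux = cnt[t] * config.photons_per_fluorophore_per_frame
            x_um, y_um = tr.trajectory[t]
            add_spot(signal, x_um / px_um, y_um / px_um, flux, sigma_px)
        if noise:
            frame = rng.poisson(signal).astype(np.float64)
            if config.read_noise_sd > 0:
                frame += rng.normal(0.0, config.read_noise_sd, size=frame.shape)
            np.clip(frame, 0, 65535, out=frame)
            movie[t] = np.round(frame).astype(np.uint16)
        else:
            movie[t] = signal - config.background_photons
    return SyntheticStack(movie=movie, config=config, truths=list(truths),
                          cell_mask=np.asarray(cell_mask, dtype=np.uint16))


# ---------------------------------------------------------------------------
# turnkey fixtures

def simulate_slimfield_movie(config: SimulationConfig,
                             n_molecules: Sequence[int] | int,
                             d_coeff: float = 0.99,
                             cell_radius_um: float = 2.0,
                             noise: bool = True) -> SyntheticStack:
    """One aggregate per cell, cells laid out on a grid, full camera model.

    ``n_molecules`` may be a single count or one per aggregate; ``d_coeff``
    defaults to the unstressed cytoplasmic mobility scale (~1 µm²/s).
    """
    if np.isscalar(n_molecules):
        n_molecules = [int(n_molecules)]
    n_agg = len(n_molecules)
    rng = np.random.default_rng(config.rng_seed)
    px_um = config.pixel_size_um
    cell_r_px = cell_radius_um / px_um
    pitch = int(math.ceil(2 * cell_r_px + 6))
    grid = int(math.ceil(math.sqrt(n_agg)))
    shape = (grid * pitch, grid * pitch)
    cfg = SimulationConfig(**{**config.__dict__, "image_shape": shape})

    mask = np.zeros(shape, dtype=np.uint16)
    truths = []
    for k, n_mol in enumerate(n_molecules):
        gy, gx = divmod(k, grid)
        cy = gy * pitch + pitch / 2.0
        cx = gx * pitch + pitch / 2.0
        mask[disk_mask(shape, (cy, cx), cell_r_px)] = k + 1
        bounds = DiskBounds((cx * px_um, cy * px_um), cell_radius_um * 0.85)
        start = bounds.center + rng.normal(0, 0.2, 2)
        if not bounds.contains(start):
            start = bounds.center
        traj = simulate_brownian_track(d_coeff, cfg.n_frames, cfg.frame_interval,
                                       start, bounds, rng=rng)
        _, bleach, dark = simulate_photobleaching(
            n_mol, cfg.bleach_prob, cfg.dark_fraction, cfg.n_frames, rng=rng)
        truths.append(AggregateGroundTruth(
            aggregate_id=k, true_n_molecules=n_mol, diffusion_coeff=d_coeff,
            trajectory=traj, bleach_frames=bleach, dark_flags=dark,
            cell_label=k + 1))
    return render_stack(cfg, truths, mask, noise=noise, rng=np.random.default_rng(rng.integers(2**31)))


@dataclass
class MotherBudGeometry:
    """Mother cell with a bud nucleating at ``bud_start_frame`` and growing
    linearly to ``bud_max_radius_um`` by the final frame. Distances in µm."""

    mother_center_um: tuple[float, float] = (4.0, 4.0)
    mother_radius_um: float = 2.2
    bud_direction: tuple[float, float] = (1.0, 0.0)
    bud_max_radius_um: float = 1.3
    bud_start_frame: int = 1

    def bud_radius(self, frame: int, n_frames: int) -> float:
        if frame < self.bud_start_frame:
            return 0.0
        frac = (frame - self.bud_start_frame) / max(1, n_frames - 1 - self.bud_start_frame)
        return self.bud_max_radius_um * (0.25 + 0.75 * min(1.0, frac))

    def bud_center(self, frame: int, n_frames: int) -> np.ndarray:
        r = self.bud_radius(frame, n_frames)
        u = np.asarray(self.bud_direction, float)
        u = u / np.hypot(*u)
        return np.asarray(self.mother_center_um) + u * (self.mother_radius_um + r)


ORGANELLE_TRANSFER_MIN = {"vacuole": 20.0, "nucleus": 60.0}  # minutes into budding


def simulate_confocal_timelapse(config: SimulationConfig,
                                geometry: MotherBudGeometry | None = None,
                                organelle: Literal["vacuole", "nucleus"] = "vacuole",
                                inheritance_policy: Literal["retain", "transfer_one"] = "retain",
                                n_aggregates: int = 3,
                                aggregate_n_molecules: int = 100) -> SyntheticStack:
    """Two-channel mother/bud time-lapse (10 min frames over 90 min).

    Channel 1 (``movie``) carries the aggregate reporter; channel 2
    (``lineage['organelle_movie']``) the organelle marker. The organelle
    appears in the bud from its stage-specific frame on (vacuole ~20 min,
    nucleus ~60 min). Aggregates stay in the mother under the default
    ``retain`` policy; ``transfer_one`` moves one aggregate into the bud at
    the final frame.
    """
    geometry = geometry or MotherBudGeometry()
    cfg = SimulationConfig(**{**config.__dict__,
                              "frame_interval": 600.0, "n_frames": 10,
                              "bleach_prob": 0.0, "dark_fraction": 0.0})
    n_frames = cfg.n_frames
    rows, cols = cfg.image_shape
    px_um = cfg.pixel_size_um
    rng = np.random.default_rng(cfg.rng_seed)

    transfer_frame = int(round(ORGANELLE_TRANSFER_MIN[organelle] * 60.0 / cfg.frame_interval))

    def um_to_px(p):
        return (p[1] / px_um, p[0] / px_um)  # (row, col)

    cell_masks, organelle_masks = [], []
    mother_ctr = np.asarray(geometry.mother_center_um)
    org_radius_um = 0.8 if organelle == "vacuole" else 0.6
    org_offset = mother_ctr + np.array([-0.7, 0.4])
    for t in range(n_frames):
        labels = np.zeros((rows, cols), dtype=np.uint16)
        labels[disk_mask((rows, cols), um_to_px(mother_ctr),
                         geometry.mother_radius_um / px_um)] = 1
        br = geometry.bud_radius(t, n_frames)
        if br > 0:
            bud_m = disk_mask((rows, cols), um_to_px(geometry.bud_center(t, n_frames)), br / px_um)
            labels[bud_m & (labels == 0)] = 2
        cell_masks.append(labels)
        org = disk_mask((rows, cols), um_to_px(org_offset), org_radius_um / px_um)
        if t >= transfer_frame and br > 0:
            bud_ctr = geometry.bud_center(t, n_frames)
            org = org | disk_mask((rows, cols), um_to_px(bud_ctr),
                                  min(org_radius_um, 0.7 * br) / px_um)
        organelle_masks.append(org)

    bounds = DiskBounds(tuple(mother_ctr), geometry.mother_radius_um * 0.8)
    truths = []
    for k in range(n_aggregates):
        start = mother_ctr + rng.normal(0, 0.4, 2)
        if not bounds.contains(start):
            start = mother_ctr
        # slow confined motion: 10-min sampling makes fast diffusion meaningless
        d_conf = 5e-4
        traj = simulate_brownian_track(d_conf, n_frames, cfg.frame_interval, start,
                                       bounds, rng=rng)
        cell_label = 1
        if inheritance_policy == "transfer_one" and k == 0:
            traj[-1] = geometry.bud_center(n_frames - 1, n_frames)
        truths.append(AggregateGroundTruth(
            aggregate_id=k, true_n_molecules=aggregate_n_molecules,
            diffusion_coeff=d_conf, trajectory=traj,
            bleach_frames=np.full(aggregate_n_molecules, np.inf),
            dark_flags=np.zeros(aggregate_n_molecules, dtype=bool),
            cell_label=cell_label))

    stack = render_stack(cfg, truths, cell_masks[-1],
                         rng=np.random.default_rng(cfg.rng_seed + 1))

    org_movie = np.empty((n_frames, rows, cols), dtype=np.uint16)
    org_rng = np.random.default_rng(cfg.rng_seed + 2)
    for t in range(n_frames):
        lam = np.full((rows, cols), cfg.background_photons)
        lam[organelle_masks[t]] += 80.0
        org_movie[t] = np.clip(org_rng.poisson(lam), 0, 65535).astype(np.uint16)

    stack.lineage = {
        "roles": {1: "mother", 2: "daughter"},
        "cell_masks_per_frame": cell_masks,
        "organelle_masks_per_frame": organelle_masks,
        "organelle_movie": org_movie,
        "organelle": organelle,
        "transfer_frame": transfer_frame,
        "frame_interval_min": cfg.frame_interval / 60.0,
    }
    return stack
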