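"""Scaled-down 2D undersampled encoding chain.

The clinical acquisition this package models uses a heavily undersampled 3D
non-Cartesian readout: one interleaf of a rotating trajectory per
timepoint, anti-aliased with k-space-weighted view sharing, then gridded
and Fourier-transformed.  Reproducing that at 256^3 is a scanner-farm
problem, not a desk one, so this module implements a faithful 2D analog
that preserves the algorithmic structure end to end:

* a rotating single-interleaf trajectory (Archimedean spiral or radial
  spoke, golden-angle increments by default);
* an exact non-uniform DFT forward model with complex Gaussian noise;
* k-space-weighted view sharing — neighboring frames lend samples, with
  the k-space center taken only from the native frame and the periphery
  shared fully, blended piecewise-linearly in |k| between two radii;
* density-compensated Kaiser-Bessel gridding (oversampling 2, deapodized)
  followed by an inverse FFT per frame.

Everything here is 2D and single-coil; parallel imaging and iterative
reconstruction are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.special import i0 as bessel_i0

from .signal_model import SequenceSchedule, simulate_fingerprints

__all__ = [
    "GOLDEN_ANGLE_SPIRAL_DEG",
    "GOLDEN_ANGLE_RADIAL_DEG",
    "InvalidWindowError",
    "Trajectory",
    "KSpaceSeries",
    "make_trajectory",
    "sample_kspace",
    "view_share",
    "reconstruct_series",
    "fft2c",
    "ifft2c",
]

# Golden-angle increments: full-circle for spirals, half-circle for spokes
# (a spoke at theta covers theta+180 as well).
GOLDEN_ANGLE_SPIRAL_DEG = 360.0 * (1.0 - 2.0 / (1.0 + np.sqrt(5.0)))  # 137.5078
GOLDEN_ANGLE_RADIAL_DEG = 180.0 * (1.0 - 2.0 / (1.0 + np.sqrt(5.0)))  # 111.2461

DEFAULT_SPIRAL_TURNS = 8.0
# View-sharing k-radius thresholds (fractions of k_max): below r_lo only the
# native frame contributes, above r_hi neighbors share fully.
DEFAULT_R_LO_FRAC = 0.1
DEFAULT_R_HI_FRAC = 0.3


class InvalidWindowError(ValueError):
    pass


@dataclass(frozen=True)
class Trajectory:
    """Per-frame k-space sample coordinates, in cycles/FOV.

    ``coords`` has shape (n_frames, points_per_frame, 2); the k-space grid
    spacing is 1 cycle/FOV, so the Nyquist box is |k| <= matrix / 2.
    """

    matrix: int
    coords: np.ndarray
    kind: str
    angle_increment_deg: float

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def points_per_frame(self) -> int:
        return self.coords.shape[1]

    @property
    def k_max(self) -> float:
        return 0.5 * self.matrix


@dataclass
class KSpaceSeries:
    """Per-frame complex k-space samples aligned with a trajectory.

    Plain series carry one value per trajectory sample.  View-shared series
    instead carry ragged per-frame clouds (``coords``/``weights`` set), in
    which each borrowed sample keeps its source location and an averaging
    weight.
    """

    traj: Trajectory
    frames: List[np.ndarray]
    noise_sd: float = 0.0
    seed: Optional[int] = None
    coords: Optional[List[np.ndarray]] = None
    weights: Optional[List[np.ndarray]] = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_cloud(self, f: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(coords, values, weights) of frame ``f``."""
        if self.coords is not None:
            return self.coords[f], self.frames[f], self.weights[f]
        n = self.frames[f].shape[0]
        return self.traj.coords[f], self.frames[f], np.ones(n)


def make_trajectory(
    matrix: int,
    n_frames: int,
    points_per_frame: Optional[int] = None,
    kind: str = "spiral",
    angle_increment_deg: Optional[float] = None,
    n_turns: float = DEFAULT_SPIRAL_TURNS,
) -> Trajectory:
    """Build a rotating-interleaf 2D trajectory.

    Frame ``f`` is the base interleaf rotated by ``f * angle_increment``;
    the default increment is the golden angle appropriate to the kind.
    ``kind='cartesian'`` gives the fully sampled special case (every frame
    the complete Cartesian grid), used by oracle tests.
    """
    if matrix < 8:
        raise ValueError("matrix must be >= 8")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    k_max = 0.5 * matrix

    if kind == "cartesian":
        ax = np.arange(matrix) - matrix // 2
        kx, ky = np.meshgrid(ax, ax, indexing="ij")
        base = np.column_stack([kx.ravel(), ky.ravel()]).astype(float)
        coords = np.broadcast_to(base, (n_frames, base.shape[0], 2)).copy()
        return Trajectory(matrix, coords, kind, 0.0)

    if points_per_frame is None:
        points_per_frame = 4 * matrix
    if kind == "spiral":
        inc = GOLDEN_ANGLE_SPIRAL_DEG if angle_increment_deg is None else angle_increment_deg
        t = np.linspace(0.0, 1.0, points_per_frame)
        r = k_max * t
        theta0 = 2.0 * np.pi * n_turns * t
    elif kind == "radial":
        inc = GOLDEN_ANGLE_RADIAL_DEG if angle_increment_deg is None else angle_increment_deg
        r = k_max * np.linspace(-1.0, 1.0, points_per_frame)
        theta0 = np.zeros(points_per_frame)
    else:
        raise ValueError(f"unknown trajectory kind {kind!r}")

    rot = np.deg2rad(inc) * np.arange(n_frames)
    theta = theta0[None, :] + rot[:, None]
    coords = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=-1)
    # keep strictly inside the Nyquist box
    coords = np.clip(coords, -k_max, k_max * (1 - 2.0 / matrix))
    return Trajectory(int(matrix), coords, kind, float(inc))


def _centered_axis(n: int) -> np.ndarray:
    return np.arange(n) - n // 2


def fft2c(img: np.ndarray) -> np.ndarray:
    """Centered 2D FFT (image with index n//2 at the origin)."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img)))


def ifft2c(ksp: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(ksp)))


def sample_kspace(
    t1_map: np.ndarray,
    t2_map: np.ndarray,
    pd_map: np.ndarray,
    schedule: SequenceSchedule,
    traj: Trajectory,
    snr: Optional[float] = None,
    seed: int = 0,
) -> KSpaceSeries:
    """Forward-model the undersampled acquisition of a digital object.

    Frame ``f`` holds the non-uniform DFT, at that frame's coordinates, of
    the image whose voxel values are ``pd * fingerprint[f]`` for the
    voxel's (T1, T2).  Complex white Gaussian noise is added at the stated
    SNR, defined as (mean voxel signal magnitude over the object mask and
    all frames) / (complex noise SD per sample).
    """
    m = traj.matrix
    if t1_map.shape != (m, m) or t2_map.shape != (m, m) or pd_map.shape != (m, m):
        raise ValueError("map shapes must equal (matrix, matrix)")
    mask = pd_map > 0
    xs, ys = np.nonzero(mask)
    xc = (xs - m // 2).astype(float)
    yc = (ys - m // 2).astype(float)
    pd = pd_map[mask]

    pairs, inv = np.unique(
        np.column_stack([t1_map[mask], t2_map[mask]]), axis=0, return_inverse=True
    )
    fps = simulate_fingerprints(pairs[:, 0], pairs[:, 1], schedule)  # (u, n_t)
    voxel_sig = fps[inv] * pd[:, None]  # (n_vox, n_t)

    n_frames = traj.n_frames
    frames: List[np.ndarray] = []
    for f in range(n_frames):
        c = traj.coords[f]
        phase = np.exp(
            -2j * np.pi * (np.outer(c[:, 0], xc) + np.outer(c[:, 1], yc)) / m
        )
        frames.append(phase @ voxel_sig[:, f].astype(complex))

    noise_sd = 0.0
    if snr is not None:
        level = float(np.mean(np.abs(voxel_sig)))
        noise_sd = level / snr
        rng = np.random.default_rng(seed)
        for f in range(n_frames):
            n = frames[f].shape[0]
            frames[f] = frames[f] + noise_sd / np.sqrt(2.0) * (
                rng.standard_normal(n) + 1j * rng.standard_normal(n)
            )
    return KSpaceSeries(traj=traj, frames=frames, noise_sd=noise_sd, seed=seed)


def _temporal_kernel(offsets: np.ndarray, kernel: str, width: float) -> np.ndarray:
    if kernel == "uniform":
        return np.ones(offsets.size)
    if kernel == "gaussian":
        return np.exp(-0.5 * (offsets / width) ** 2)
    raise ValueError(f"unknown temporal kernel {kernel!r}")


def view_share(
    ks: KSpaceSeries,
    traj: Trajectory,
    window: int,
    kernel: str = "gaussian",
    kernel_width_frames: Optional[float] = None,
    r_lo_frac: float = DEFAULT_R_LO_FRAC,
    r_hi_frac: float = DEFAULT_R_HI_FRAC,
) -> KSpaceSeries:
    """k-space-weighted view sharing.

    Each output frame aggregates the samples of the ``window`` neighboring
    frames.  A borrowed sample's weight is its normalized temporal-kernel
    value multiplied by a k-radius blend: below ``r_lo_frac * k_max`` only
    the native frame contributes, above ``r_hi_frac * k_max`` frames share
    fully, with a linear ramp in between.  Weights sum to 1 over the
    contributing frames of every sample position, so a constant object is
    averaged, never double-counted.
    """
    if window < 1 or window % 2 == 0:
        raise InvalidWindowError("window must be an odd integer >= 1")
    n = ks.n_frames
    if window > 2 * n - 1:
        raise InvalidWindowError(f"window {window} exceeds 2*n_frames-1 = {2 * n - 1}")
    if window == 1:
        return KSpaceSeries(
            traj=ks.traj,
            frames=[f.copy() for f in ks.frames],
            noise_sd=ks.noise_sd,
            seed=ks.seed,
        )
    if kernel_width_frames is None:
        kernel_width_frames = window / 6.0

    half = window // 2
    k_max = traj.k_max
    r_lo = r_lo_frac * k_max
    r_hi = r_hi_frac * k_max
    radii = np.linalg.norm(traj.coords, axis=-1)  # (n_frames, p)

    out_frames: List[np.ndarray] = []
    out_coords: List[np.ndarray] = []
    out_weights: List[np.ndarray] = []
    for f in range(n):
        sources = np.arange(max(0, f - half), min(n, f + half + 1))
        offsets = sources - f
        h = _temporal_kernel(offsets.astype(float), kernel, kernel_width_frames)
        h = h / h.sum()
        h0 = h[offsets == 0][0]
        vals, coords, weights = [], [], []
        for src, d, hv in zip(sources, offsets, h):
            r = radii[src]
            lam = np.clip((r - r_lo) / max(r_hi - r_lo, 1e-12), 0.0, 1.0)
            if d == 0:
                w = hv + (1.0 - lam) * (1.0 - h0)
            else:
                w = lam * hv
            keep = w > 0.0
            if not np.any(keep):
                continue
            vals.append(ks.frames[src][keep])
            coords.append(traj.coords[src][keep])
            weights.append(w[keep])
        out_frames.append(np.concatenate(vals))
        out_coords.append(np.concatenate(coords))
        out_weights.append(np.concatenate(weights))
    return KSpaceSeries(
        traj=ks.traj,
        frames=out_frames,
        noise_sd=ks.noise_sd,
        seed=ks.seed,
        coords=out_coords,
        weights=out_weights,
    )


def _kaiser_bessel(u: np.ndarray, width: float, beta: float) -> np.ndarray:
    x = 1.0 - (2.0 * u / width) ** 2
    out = np.zeros_like(u)
    ok = x > 0
    out[ok] = bessel_i0(beta * np.sqrt(x[ok])) / bessel_i0(beta)
    return out


def _density_weights(coords: np.ndarray, traj: Trajectory) -> np.ndarray:
    """Analytic density compensation: |k| ramp for radial/spiral, flat for
    Cartesian, with a floor so DC samples keep finite weight."""
    if traj.kind == "cartesian":
        return np.ones(coords.shape[0])
    r = np.linalg.norm(coords, axis=-1)
    floor = traj.k_max / max(traj.points_per_frame, 1)
    return np.maximum(r, floor)


def reconstruct_series(
    ks: KSpaceSeries,
    traj: Trajectory,
    matrix: Optional[int] = None,
    oversampling: int = 2,
    kernel_width: int = 4,
) -> np.ndarray:
    """Gridding reconstruction of every frame.

    Density-compensated Kaiser-Bessel gridding onto a 2x-oversampled grid,
    inverse FFT, deapodization by the kernel's exact (FFT-computed)
    transform, and a center crop.  Returns a complex ``(n_frames, matrix,
    matrix)`` image series; the global scale is normalized per frame by the
    gridded density so that fully sampled Cartesian data reproduce the
    plain inverse FFT.
    """
    m = int(matrix if matrix is not None else traj.matrix)
    os_m = oversampling * m
    W = kernel_width
    beta = np.pi * np.sqrt(
        (W / oversampling) ** 2 * (oversampling - 0.5) ** 2 - 0.8
    )

    # deapodizer: transform of the gridding kernel, sampled on the os grid
    taps_ax = _centered_axis(os_m).astype(float)
    kern_1d = _kaiser_bessel(taps_ax, W, beta)
    apod_1d = np.real(np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(kern_1d))))
    apod_1d = apod_1d / apod_1d[os_m // 2]
    apod = np.outer(apod_1d, apod_1d)
    lo = os_m // 2 - m // 2
    apod_crop = apod[lo : lo + m, lo : lo + m]

    offs = np.arange(W) - (W // 2 - 1)  # kernel tap offsets around floor(p)
    out = np.empty((ks.n_frames, m, m), dtype=complex)
    for f in range(ks.n_frames):
        coords, vals, weights = ks.frame_cloud(f)
        dens = _density_weights(coords, traj) * weights
        wv = vals * dens
        # positions on the oversampled grid
        px = oversampling * coords[:, 0] + os_m // 2
        py = oversampling * coords[:, 1] + os_m // 2
        ix = np.floor(px).astype(int)[:, None] + offs[None, :]
        iy = np.floor(py).astype(int)[:, None] + offs[None, :]
        wx = _kaiser_bessel(px[:, None] - ix, W, beta)
        wy = _kaiser_bessel(py[:, None] - iy, W, beta)
        ixm = np.mod(ix, os_m)
        iym = np.mod(iy, os_m)
        flat = (
            ixm[:, :, None] * os_m + iym[:, None, :]
        ).ravel()
        contrib = (wv[:, None, None] * wx[:, :, None] * wy[:, None, :]).ravel()
        grid_r = np.bincount(flat, weights=contrib.real, minlength=os_m * os_m)
        grid_i = np.bincount(flat, weights=contrib.imag, minlength=os_m * os_m)
        grid = (grid_r + 1j * grid_i).reshape(os_m, os_m)
        # per-frame density normalization against the gridded sampling
        # density (keeps the Cartesian special case exactly calibrated)
        dens_contrib = (dens[:, None, None] * wx[:, :, None] * wy[:, None, :]).ravel()
        dens_total = np.bincount(flat, weights=dens_contrib, minlength=os_m * os_m).sum()
        img_os = ifft2c(grid)
        img = img_os[lo : lo + m, lo : lo + m] / apod_crop
        scale = (os_m * os_m) / max(dens_total, 1e-30)
        out[f] = img * scale
    return out
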