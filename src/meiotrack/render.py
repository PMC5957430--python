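"""Fluorescence movie rendering with a Gaussian PSF.

Each KT is rendered as an anisotropic 3D Gaussian blob (spinning-disc
acquisition emulation: 100 nm lateral pixels, 300 nm z spacing by
default) into a two-channel stack (KT channel, chromatin/nucleoplasm
proxy channel), with Poisson photon noise plus Gaussian camera noise.

Stack coordinates: 0-based voxel indices, a position in micrometres maps
to voxel ``pos/voxel - origin``, where the volume origin is chosen so
that the stack is centred on the coordinate origin of the simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

from .config import OpticsConfig


@dataclass
class ImageStackSeries:
    """Time series of 3D multi-channel stacks, axes (T, Z, C, Y, X)."""

    data: np.ndarray
    voxel_um_zyx: tuple
    frame_interval_s: float
    origin_um_zyx: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.data.ndim != 5:
            raise ValueError("image data must have axes (T, Z, C, Y, X)")
        if any(v <= 0 for v in self.voxel_um_zyx):
            raise ValueError("voxel sizes must be strictly positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def frame(self, t: int, channel: int = 0) -> np.ndarray:
        """One 3D (Z, Y, X) stack."""
        return self.data[t, :, channel]

    def write_tiff(self, path) -> None:
        vz, vy, vx = self.voxel_um_zyx
        tifffile.imwrite(
            path, self.data.astype(np.float32), imagej=True,
            metadata={
                "axes": "TZCYX",
                "spacing": vz,
                "unit": "um",
                "finterval": self.frame_interval_s,
                "origin_um_zyx": list(self.origin_um_zyx),
            },
            resolution=(1.0 / vx, 1.0 / vy),
        )

    @classmethod
    def read_tiff(cls, path) -> "ImageStackSeries":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = tf.imagej_metadata or {}
            vz = float(meta.get("spacing", 0.3))
            fint = float(meta.get("finterval", 10.0))
            origin = tuple(meta.get("origin_um_zyx", (0.0, 0.0, 0.0)))
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            vx = 0.1
            if xres is not None:
                num, den = xres.value
                vx = den / num
        if data.ndim == 4:  # single-channel series written without C axis
            data = data[:, :, None]
        return cls(data=data, voxel_um_zyx=(vz, vx, vx),
                   frame_interval_s=fint, origin_um_zyx=origin)


def _gaussian_blobs(shape_zyx, centers_vox, sigmas_vox, amplitudes):
    """Sum of separable 3D Gaussians, evaluated over the full stack."""
    nz, ny, nx = shape_zyx
    img = np.zeros(shape_zyx, dtype=float)
    zi = np.arange(nz)[:, None, None]
    yi = np.arange(ny)[None, :, None]
    xi = np.arange(nx)[None, None, :]
    for (cz, cy, cx), (sz, sy, sx), amp in zip(centers_vox, sigmas_vox,
                                               amplitudes):
        gz = np.exp(-0.5 * ((zi - cz) / sz) ** 2)
        gy = np.exp(-0.5 * ((yi - cy) / sy) ** 2)
        gx = np.exp(-0.5 * ((xi - cx) / sx) ** 2)
        img += amp * gz * gy * gx
    return img


def _apply_noise(img, optics: OpticsConfig, rng):
    noisy = rng.poisson(np.clip(img + optics.background, 0, None)).astype(float)
    if optics.read_noise_sigma > 0:
        noisy += rng.normal(0.0, optics.read_noise_sigma, img.shape)
    return noisy


def positions_to_voxels(pos_um: np.ndarray, optics: OpticsConfig,
                        origin_um_zyx) -> np.ndarray:
    """Map (N, 3) x/y/z um positions to fractional (N, 3) z/y/x voxels."""
    vz, vy, vx = optics.voxel_um_zyx
    oz, oy, ox = origin_um_zyx
    pos = np.atleast_2d(pos_um)
    return np.stack([(pos[:, 2] - oz) / vz,
                     (pos[:, 1] - oy) / vy,
                     (pos[:, 0] - ox) / vx], axis=1)


def default_origin(optics: OpticsConfig) -> tuple:
    """Volume origin (um, z/y/x) centring the stack on the coordinate origin."""
    nz, ny, nx = optics.shape_zyx
    vz, vy, vx = optics.voxel_um_zyx
    return (-(nz - 1) / 2 * vz, -(ny - 1) / 2 * vy, -(nx - 1) / 2 * vx)


def render_frame(kt_positions_um, optics: OpticsConfig, rng,
                 chromatin_positions_um=None, nucleoplasm_level=0.0,
                 origin_um_zyx=None, noise=True):
    """Render one two-channel (Z, C, Y, X) stack from true positions."""
    optics.validate()
    if origin_um_zyx is None:
        origin_um_zyx = default_origin(optics)
    vz, vy, vx = optics.voxel_um_zyx
    sig = (optics.psf_sigma_z_nm / 1000.0 / vz,
           optics.psf_sigma_xy_nm / 1000.0 / vy,
           optics.psf_sigma_xy_nm / 1000.0 / vx)
    centers = positions_to_voxels(kt_positions_um, optics, origin_um_zyx)
    nz, ny, nx = optics.shape_zyx
    bad = np.flatnonzero((centers < 0).any(axis=1)
                         | (centers >= [nz, ny, nx]).any(axis=1))
    if bad.size:
        raise ValueError(
            f"KT positions outside rendered volume at indices {bad.tolist()}")
    kt_img = _gaussian_blobs(optics.shape_zyx, centers,
                             [sig] * len(centers),
                             [optics.photon_scale] * len(centers))
    if chromatin_positions_um is not None and len(chromatin_positions_um):
        ch_centers = positions_to_voxels(chromatin_positions_um, optics,
                                         origin_um_zyx)
        ch_sig = (0.6 / vz, 0.5 / vy, 0.5 / vx)
        chrom = _gaussian_blobs(optics.shape_zyx, ch_centers,
                                [ch_sig] * len(ch_centers),
                                [0.4 * optics.photon_scale] * len(ch_centers))
    else:
        chrom = np.zeros(optics.shape_zyx)
    if nucleoplasm_level > 0:
        nuc_sig = (3.0 / vz, 3.5 / vy, 3.5 / vx)
        cz, cy, cx = (nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2
        chrom += _gaussian_blobs(optics.shape_zyx, [(cz, cy, cx)], [nuc_sig],
                                 [nucleoplasm_level * 0.2
                                  * optics.photon_scale])
    if noise:
        kt_img = _apply_noise(kt_img, optics, rng)
        chrom = _apply_noise(chrom, optics, rng)
    return np.stack([kt_img, chrom], axis=1)  # (Z, C, Y, X)


def render_movie(bundle, optics: OpticsConfig, seed: int,
                 frames=None) -> ImageStackSeries:
    """Render a trajectory bundle into a two-channel TZCYX stack series.

    ``frames`` optionally restricts rendering to a subset of frame
    indices (rendering full recordings is expensive; most analyses only
    need selected windows).
    """
    optics.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x726e]))
    origin = default_origin(optics)
    pos = bundle.positions
    all_frames = np.unique(pos["frame"].to_numpy())
    if frames is None:
        frames = all_frames
    frames = np.asarray(frames)
    sig = bundle.signals.set_index("frame")
    stacks = []
    for f in frames:
        sub = pos[pos["frame"] == f]
        kt_xyz = sub[["x_um", "y_um", "z_um"]].to_numpy()
        pair_centers = sub.groupby("pair_id")[["x_um", "y_um", "z_um"]] \
            .mean().to_numpy()
        level = float(sig.loc[f, "nucleoplasm"]) if f in sig.index else 0.0
        stacks.append(render_frame(kt_xyz, optics, rng,
                                   chromatin_positions_um=pair_centers,
                                   nucleoplasm_level=level,
                                   origin_um_zyx=origin))
    data = np.stack(stacks)  # (T, Z, C, Y, X)
    return ImageStackSeries(data=data, voxel_um_zyx=optics.voxel_um_zyx,
                            frame_interval_s=bundle.frame_interval_s,
                            origin_um_zyx=origin)


def render_pair_region(separation_nm: float, optics: OpticsConfig, rng,
                       shape_zyx=(9, 21, 21), angle_rad=None,
                       noise=True):
    """Render a small ROI holding one sister-KT pair split in-plane.

    The two point sources sit symmetrically about the ROI centre along
    an in-plane axis at ``angle_rad`` (random if None).  Returns
    ``(stack, true_positions_um)`` in ROI coordinates (origin at voxel
    (0,0,0) centre).
    """
    roi = OpticsConfig(**{**optics.__dict__, "shape_zyx": tuple(shape_zyx)})
    if angle_rad is None:
        angle_rad = rng.uniform(0, 2 * np.pi)
    d_um = separation_nm / 1000.0
    direction = np.array([np.cos(angle_rad), np.sin(angle_rad), 0.0])
    nz, ny, nx = shape_zyx
    vz, vy, vx = roi.voxel_um_zyx
    center_um = np.array([(nx - 1) / 2 * vx, (ny - 1) / 2 * vy,
                          (nz - 1) / 2 * vz])
    p1 = center_um + direction * d_um / 2
    p2 = center_um - direction * d_um / 2
    stack = render_frame(np.stack([p1, p2]), roi, rng,
                         origin_um_zyx=(0.0, 0.0, 0.0), noise=noise)
    return stack[:, 0], np.stack([p1, p2])
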