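"""Synthetic 3D TEE-like phantom of the LVOT and aortic root.

The phantom renders a bright tubular wall around a surface of revolution
whose radius profile has an LVOT segment, an annulus waist R_a, a sinus of
Valsalva bulge R_s and an ascending-aorta segment.  Each frame applies a
rigid pose (translation + rotation) and a radial pulsation factor peaking at
a programmed frame, then multiplies in a smoothed Rayleigh speckle field.
Optional signal dropouts and a stitching seam mimic the artifacts seen in
gated 3D acquisitions.  Exact per-frame ground truth (annulus center, plane
normal, diameter, area, perimeter) is returned alongside the volumes.

The phantom is a geometric stand-in for patient recordings: it exercises
edge detection, pose tracking and deformation recovery, not the physics of
ultrasound (no point-spread function, no attenuation, no scan conversion).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import interpolate, ndimage

from .io import VolumeSequence
from .transform import rotation_matrix

__all__ = ["PhantomConfig", "PhantomGroundTruth", "generate_phantom", "default_suite"]


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple = (96, 96, 96)
    spacing: float = 0.7  # mm, isotropic
    n_frames: int = 10
    frame_rate: float = 15.0  # volumes/s
    # radius profile (mm): z measured from the annulus plane; the LVOT
    # flares into the ventricular cavity at the bottom, as in mid-esophageal
    # views of the outflow tract
    lvot_radius: float = 11.0
    ventricle_radius: float = 16.0
    annulus_radius: float = 12.0
    sinus_radius: float = 16.0
    ascending_radius: float = 13.0
    sinus_z: float = 8.0
    tube_half_length: float = 24.0
    wall_thickness: float = 3.0
    wall_intensity: float = 180.0
    background_intensity: float = 20.0
    # echogenic fibrous/calcific annulus: the wall brightens in a band
    # around the annulus plane, as in the calcified valves of TAVI patients
    annulus_brightness: float = 2.0
    annulus_bright_sigma: float = 1.5  # mm
    # rigid motion over the cycle
    translation_amp: float = 3.0  # mm
    rotation_amp_deg: float = 5.0
    # radial pulsation
    pulse_amp: float = 0.05
    peak_frame: int = 3
    # speckle
    noise_level: float = 0.35  # 0 disables
    speckle_corr_vox: float = 1.5
    # artifacts
    dropout: bool = False
    dropout_center_z: float = 2.0  # mm above annulus
    dropout_halfangle_deg: float = 25.0
    stitching: bool = False
    stitch_offset: float = 25.0  # additive intensity step across the seam
    seed: int = 0


@dataclass
class PhantomGroundTruth:
    centers: np.ndarray  # (N, 3) annulus center, image mm
    normals: np.ndarray  # (N, 3) annulus plane normal
    diameters: np.ndarray  # (N,) true annulus diameter 2 R_a * pulse
    areas: np.ndarray
    perimeters: np.ndarray
    translations: np.ndarray  # (N, 3)
    rotations: np.ndarray  # (N, 3, 3)
    pulses: np.ndarray


def _radius_profile(cfg: PhantomConfig):
    z_knots = np.array(
        [
            -cfg.tube_half_length,
            -16.0,
            -10.0,
            -4.0,
            0.0,
            cfg.sinus_z,
            cfg.sinus_z + 6.0,
            cfg.tube_half_length,
        ]
    )
    r_knots = np.array(
        [
            cfg.ventricle_radius,
            cfg.lvot_radius,
            cfg.lvot_radius,
            cfg.lvot_radius * 0.3 + cfg.annulus_radius * 0.7,
            cfg.annulus_radius,
            cfg.sinus_radius,
            cfg.ascending_radius,
            cfg.ascending_radius,
        ]
    )
    return interpolate.PchipInterpolator(z_knots, r_knots)


def _pose(cfg: PhantomConfig, k: int):
    ph = 2.0 * np.pi * k / cfg.n_frames
    u = np.array([1.0, 0.5, 0.2])
    u /= np.linalg.norm(u)
    t = cfg.translation_amp * np.sin(ph) * u
    ang = np.deg2rad(cfg.rotation_amp_deg) * np.sin(ph)
    R = rotation_matrix(np.array([ang, 0.6 * ang, 0.0]))
    return t, R


def _pulse(cfg: PhantomConfig, k: int) -> float:
    return 1.0 + cfg.pulse_amp * float(np.exp(-((k - cfg.peak_frame) / 2.0) ** 2))


def generate_phantom(cfg: PhantomConfig):
    """Render the phantom sequence and its exact ground truth (seeded)."""
    shape = tuple(int(s) for s in cfg.shape)
    spacing = np.full(3, float(cfg.spacing))
    if cfg.annulus_radius >= cfg.sinus_radius:
        raise ValueError("annulus waist must be narrower than the sinus bulge")
    half_extent = (np.asarray(shape) - 1) * spacing / 2.0
    if cfg.sinus_radius + cfg.translation_amp + cfg.wall_thickness > half_extent.min():
        raise ValueError("phantom geometry exceeds the volume grid")
    origin = -half_extent
    rng = np.random.default_rng(cfg.seed)
    prof = _radius_profile(cfg)

    ax = [origin[i] + spacing[i] * np.arange(shape[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    P = np.stack([X, Y, Z], axis=-1)  # (nx, ny, nz, 3), world mm

    sigma_w = cfg.wall_thickness / 2.0
    frames = []
    centers, normals, diams, areas, perims = [], [], [], [], []
    ts, Rs, pulses = [], [], []
    for k in range(cfg.n_frames):
        t, R = _pose(cfg, k)
        pulse = _pulse(cfg, k)
        Q = (P - t) @ R  # R^T (p - t): world -> phantom model frame
        r = np.hypot(Q[..., 0], Q[..., 1])
        z = Q[..., 2]
        zc = np.clip(z, -cfg.tube_half_length, cfg.tube_half_length)
        Rwall = pulse * prof(zc)
        bright = 1.0 + cfg.annulus_brightness * np.exp(
            -0.5 * (z / cfg.annulus_bright_sigma) ** 2
        )
        wall = cfg.wall_intensity * bright * np.exp(
            -0.5 * ((r - Rwall) / sigma_w) ** 2
        )
        # taper the tube ends so the wall fades instead of being cut
        fade = np.clip((cfg.tube_half_length - np.abs(z)) / 4.0, 0.0, 1.0)
        img = cfg.background_intensity + wall * fade
        if cfg.dropout:
            # cone of attenuated signal near the annulus, fixed in world space
            ang = np.arctan2(P[..., 1], P[..., 0])
            in_cone = (np.abs(((ang - 0.5) + np.pi) % (2 * np.pi) - np.pi)
                       < np.deg2rad(cfg.dropout_halfangle_deg))
            near = np.abs(z - cfg.dropout_center_z) < 6.0
            img = np.where(in_cone & near, cfg.background_intensity + 0.1 * wall * fade, img)
        if cfg.stitching:
            img = img + cfg.stitch_offset * (P[..., 0] > 1.5)
        if cfg.noise_level > 0:
            ray = rng.rayleigh(scale=1.0, size=shape)
            ray = ndimage.gaussian_filter(ray, cfg.speckle_corr_vox)
            ray /= ray.mean()
            img = img * (1.0 + cfg.noise_level * (ray - 1.0))
        frames.append(img.astype(np.float32))
        d = 2.0 * cfg.annulus_radius * pulse
        centers.append(t + R @ np.zeros(3))
        normals.append(R @ np.array([0.0, 0.0, 1.0]))
        diams.append(d)
        areas.append(np.pi * (d / 2.0) ** 2)
        perims.append(np.pi * d)
        ts.append(t)
        Rs.append(R)
        pulses.append(pulse)

    seq = VolumeSequence(
        frames=frames,
        spacing=spacing,
        origin=origin,
        frame_times=np.arange(cfg.n_frames) / cfg.frame_rate,
    )
    gt = PhantomGroundTruth(
        centers=np.asarray(centers),
        normals=np.asarray(normals),
        diameters=np.asarray(diams),
        areas=np.asarray(areas),
        perimeters=np.asarray(perims),
        translations=np.asarray(ts),
        rotations=np.asarray(Rs),
        pulses=np.asarray(pulses),
    )
    return seq, gt


def default_suite() -> list[tuple[str, PhantomConfig]]:
    """Named phantom cases spanning the clinically plausible annulus range
    and the artifact modes discussed for gated 3D TEE."""
    base = PhantomConfig()
    return [
        ("clean-static", replace(base, noise_level=0.0, translation_amp=0.0,
                                 rotation_amp_deg=0.0, pulse_amp=0.0)),
        ("moving", base),
        ("pulsating", replace(base, translation_amp=1.0, pulse_amp=0.08)),
        ("wide-sinus", replace(base, annulus_radius=10.5, sinus_radius=17.5,
                               ascending_radius=12.0)),
        ("dropout", replace(base, dropout=True)),
        ("stitching", replace(base, stitching=True)),
        ("low-frame-rate", replace(base, n_frames=8, frame_rate=7.7)),
    ]
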