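"""Volume-sequence, mesh and result I/O.

Volumes are handled in physical coordinates: world mm = origin + index *
spacing with a diagonal, RAS-like affine.  Sequences can be a single 4D
NIfTI, or a directory of per-frame 3D NIfTI / MetaImage files (sorted by
filename).  Meshes are exported as legacy ASCII VTK polydata and Wavefront
OBJ; per-frame annulus measures go to CSV and the run summary to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeSequence",
    "read_sequence",
    "write_sequence",
    "write_results",
    "write_vtk_polydata",
    "write_obj",
]


@dataclass
class VolumeSequence:
    frames: list  # 3D float arrays, identical shape
    spacing: np.ndarray  # (3,) mm / voxel
    origin: np.ndarray  # (3,) mm of voxel (0,0,0)
    frame_times: np.ndarray  # (N,) seconds

    def __post_init__(self):
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent frame shapes: {sorted(shapes)}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple:
        return self.frames[0].shape

    @property
    def frame_rate(self) -> float:
        if len(self.frame_times) < 2:
            return float("nan")
        dt = np.diff(self.frame_times).mean()
        return 1.0 / dt if dt > 0 else float("nan")


class FormatError(RuntimeError):
    pass


def write_sequence(seq: VolumeSequence, path) -> Path:
    """Write a 4D NIfTI (diagonal affine from spacing/origin); frame times
    go into pixdim[4] as the mean frame interval."""
    path = Path(path)
    data = np.stack(seq.frames, axis=-1).astype(np.float32)
    affine = np.diag(list(seq.spacing) + [1.0])
    affine[:3, 3] = seq.origin
    img = nib.Nifti1Image(data, affine)
    dt = float(np.diff(seq.frame_times).mean()) if seq.n_frames > 1 else 1.0
    img.header["pixdim"][4] = dt
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def _load_3d(path: Path):
    if path.suffix in (".mhd", ".mha"):
        import SimpleITK as sitk

        im = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(im).T.astype(np.float32)  # -> x,y,z order
        spacing = np.asarray(im.GetSpacing(), dtype=float)
        origin = np.asarray(im.GetOrigin(), dtype=float)
        return arr, spacing, origin
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj).astype(np.float32)
    affine = img.affine
    spacing = np.abs(np.diag(affine)[:3])
    origin = affine[:3, 3].copy()
    return arr, spacing, origin


def read_sequence(path) -> VolumeSequence:
    """Read a 4D NIfTI file or a directory of per-frame 3D volumes."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p
            for p in path.iterdir()
            if p.suffix in (".mhd", ".mha")
            or p.name.endswith((".nii", ".nii.gz"))
        )
        if not files:
            raise FormatError(f"no volume files in {path}")
        frames, spacing, origin = [], None, None
        for f in files:
            arr, sp, orig = _load_3d(f)
            if arr.ndim != 3:
                raise FormatError(f"{f.name}: expected a 3D volume, got {arr.ndim}D")
            if spacing is None:
                spacing, origin, shape0 = sp, orig, arr.shape
            elif arr.shape != shape0 or not np.allclose(sp, spacing):
                raise FormatError(f"{f.name}: shape/spacing differs from {files[0].name}")
            frames.append(arr)
        dt = 1.0
        return VolumeSequence(
            frames=frames,
            spacing=spacing,
            origin=origin,
            frame_times=np.arange(len(frames)) * dt,
        )
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 4:
        raise FormatError(f"{path.name}: expected a 4D volume, got {data.ndim}D")
    affine = img.affine
    spacing = np.abs(np.diag(affine)[:3])
    origin = affine[:3, 3].copy()
    dt = float(img.header["pixdim"][4]) or 1.0
    frames = [data[..., k] for k in range(data.shape[-1])]
    return VolumeSequence(
        frames=frames,
        spacing=spacing,
        origin=origin,
        frame_times=np.arange(len(frames)) * dt,
    )


# ---------------------------------------------------------------------------
# Mesh export


def write_vtk_polydata(path, verts: np.ndarray, faces) -> Path:
    """Legacy ASCII VTK polydata writer (points + polygons)."""
    path = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        "annulustrack surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(verts)} float",
    ]
    for p in verts:
        lines.append(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
    n_idx = sum(len(f) + 1 for f in faces)
    lines.append(f"POLYGONS {len(faces)} {n_idx}")
    for f in faces:
        lines.append(" ".join([str(len(f))] + [str(int(i)) for i in f]))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_obj(path, verts: np.ndarray, faces) -> Path:
    path = Path(path)
    lines = [f"v {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}" for p in verts]
    for f in faces:
        lines.append("f " + " ".join(str(int(i) + 1) for i in f))
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Results


def write_results(result, outdir, config_echo: dict | None = None, seed=None) -> dict:
    """Write annulus.csv, summary.json and per-frame meshes; returns a
    manifest of the files written."""
    import pandas as pd

    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {}

    rows = []
    for res in result.annulus:
        rows.append(
            {
                "frame": res.frame_index,
                "valid": res.valid,
                "center_x": res.center[0],
                "center_y": res.center[1],
                "center_z": res.center[2],
                "major_d": res.major_d,
                "minor_d": res.minor_d,
                "area": res.area,
                "perimeter": res.perimeter,
                "area_derived_d": res.area_derived_d,
                "perimeter_derived_d": res.perimeter_derived_d,
            }
        )
    csv_path = outdir / "annulus.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False, float_format="%.6f")
    manifest["annulus_csv"] = str(csv_path)

    summary = {
        "status": result.status,
        "version": __version__,
        "seed": seed,
        "n_frames": len(result.annulus),
        "mid_systole_frame": result.mid_systole,
        "diagnostics": result.diagnostics,
    }
    if result.status == "ok" and result.mid_systole is not None:
        ms = result.annulus[result.mid_systole]
        summary["mid_systole"] = {
            "major_d": ms.major_d,
            "minor_d": ms.minor_d,
            "area": ms.area,
            "perimeter": ms.perimeter,
            "area_derived_d": ms.area_derived_d,
            "perimeter_derived_d": ms.perimeter_derived_d,
        }
    if config_echo:
        summary["config"] = config_echo
    json_path = outdir / "summary.json"
    json_path.write_text(json.dumps(summary, indent=2, default=_json_default))
    manifest["summary_json"] = str(json_path)

    if result.meshes:
        mesh_dir = outdir / "meshes"
        mesh_dir.mkdir(exist_ok=True)
        for k, (verts, faces) in enumerate(result.meshes):
            write_vtk_polydata(mesh_dir / f"frame_{k:03d}.vtk", verts, faces)
        manifest["meshes"] = str(mesh_dir)
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
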