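"""File formats: layout JSON, sinogram CSV/NPZ, reconstruction TIFF/NPZ.

NPZ writers are deterministic (fixed zip timestamps), so identical runs
produce byte-identical files; NPZ round trips are bit-exact.
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from pathlib import Path

import numpy as np
import tifffile

from .layout import GaussianSubunit, SubunitLayout
from .tomography import Reconstruction, Sinogram

__all__ = [
    "save_layout_json",
    "load_layout_json",
    "save_sinogram_csv",
    "load_sinogram_csv",
    "save_sinogram_npz",
    "load_sinogram_npz",
    "save_reconstruction",
    "load_reconstruction_npz",
]


def _savez_deterministic(path, **arrays) -> None:
    """np.savez with a fixed zip timestamp for reproducible bytes."""
    with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
        for name, arr in arrays.items():
            buf = _io.BytesIO()
            np.lib.format.write_array(buf, np.asarray(arr))
            info = zipfile.ZipInfo(f"{name}.npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())


# -- layouts ----------------------------------------------------------------


def save_layout_json(layout: SubunitLayout, path, metadata: dict | None = None) -> None:
    """Ground-truth layout record consumed by the evaluation stage."""
    doc = {
        "arena_size": layout.arena_size,
        "profile_kind": layout.profile_kind,
        "subunits": [
            {
                "cx": su.cx,
                "cy": su.cy,
                "sigma_major": su.sigma_major,
                "sigma_minor": su.sigma_minor,
                "orientation_rad": su.orientation,
                "weight": su.weight,
                "polarity": su.polarity,
            }
            for su in layout.subunits
        ],
    }
    if metadata:
        doc["metadata"] = metadata
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_layout_json(path) -> SubunitLayout:
    doc = json.loads(Path(path).read_text())
    subunits = [
        GaussianSubunit(
            cx=d["cx"],
            cy=d["cy"],
            sigma_major=d["sigma_major"],
            sigma_minor=d["sigma_minor"],
            orientation=d["orientation_rad"],
            weight=d["weight"],
            polarity=d["polarity"],
        )
        for d in doc["subunits"]
    ]
    return SubunitLayout(subunits, doc["arena_size"], doc["profile_kind"])


# -- sinograms --------------------------------------------------------------


def save_sinogram_csv(sino: Sinogram, path) -> None:
    """First column stripe angle in degrees; remaining columns are the
    position offsets (px) given in the header row."""
    head = "angle_deg_cyclic" if sino.cyclic else "angle_deg"
    lines = [",".join([head] + [repr(float(p)) for p in sino.positions])]
    for ang, row in zip(sino.angles, sino.responses):
        lines.append(",".join([repr(float(ang))] + [repr(float(v)) for v in row]))
    Path(path).write_text("\n".join(lines) + "\n")


def load_sinogram_csv(path) -> Sinogram:
    lines = Path(path).read_text().strip().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty sinogram file")
    header = lines[0].split(",")
    if header[0] not in ("angle_deg", "angle_deg_cyclic"):
        raise ValueError(f"{path}:1: expected an 'angle_deg' header column")
    try:
        positions = np.array([float(p) for p in header[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}:1: malformed position header: {exc}") from None
    angles, rows = [], []
    for ln, line in enumerate(lines[1:], start=2):
        cells = line.split(",")
        if len(cells) != len(positions) + 1:
            raise ValueError(f"{path}:{ln}: expected {len(positions) + 1} columns")
        try:
            vals = [float(c) for c in cells]
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: {exc}") from None
        angles.append(vals[0])
        rows.append(vals[1:])
    return Sinogram(
        np.array(rows), np.array(angles), positions,
        cyclic=header[0] == "angle_deg_cyclic",
    )


def save_sinogram_npz(sino: Sinogram, path) -> None:
    _savez_deterministic(
        path,
        responses=sino.responses,
        angles=sino.angles,
        positions=sino.positions,
        cyclic=np.array(sino.cyclic),
    )


def load_sinogram_npz(path) -> Sinogram:
    with np.load(path) as d:
        return Sinogram(
            d["responses"], d["angles"], d["positions"], cyclic=bool(d["cyclic"])
        )


# -- reconstructions --------------------------------------------------------


def save_reconstruction(recon: Reconstruction, path_prefix) -> None:
    """Writes <prefix>.npz (lossless) and <prefix>.tif (32-bit float)."""
    prefix = Path(path_prefix)
    _savez_deterministic(
        prefix.with_suffix(".npz"),
        values=recon.values,
        pixel_pitch=np.array(recon.pixel_pitch),
        center=np.array(recon.center),
    )
    tifffile.imwrite(
        prefix.with_suffix(".tif"),
        recon.values.astype(np.float32),
        metadata={"pixel_pitch": recon.pixel_pitch, "center": list(recon.center)},
    )


def load_reconstruction_npz(path) -> Reconstruction:
    with np.load(path) as d:
        return Reconstruction(
            d["values"], float(d["pixel_pitch"]), tuple(d["center"])
        )
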