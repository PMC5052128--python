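"""Volume containers and file formats.

In-memory convention: a volume is a 3D array indexed ``(slice, row, col)``
with the *sparse* acquisition axis (large inter-slice spacing) always first.
Physical positions are ``origin + index * spacing`` along axis-aligned grids,
in millimetres.  On disk, volumes are NIfTI-1 images whose affine encodes the
anisotropic spacing; scribbles are stored either as an ordered JSON point
list or as a label map (0 = unlabeled, 1 = foreground, 2 = background).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "LabelVolume",
    "ScribbleSet",
    "read_volume",
    "write_volume",
    "read_scribbles",
    "write_scribbles",
]


@dataclass
class Volume:
    """A 3D intensity grid with anisotropic voxel geometry.

    Parameters
    ----------
    data:
        Array of shape ``(n_slices, n_rows, n_cols)``.
    spacing:
        Voxel spacing in mm, ``(slice, row, col)`` order.  The slice spacing
        is typically several times the in-plane spacing.
    origin:
        Physical position of voxel ``(0, 0, 0)`` in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    slice_axis: int = 0  # always axis 0 in memory; kept for header round trips

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive numbers, got {self.spacing}")
        if self.slice_axis != 0:
            raise ValueError("in-memory volumes always have slice_axis == 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def physical_coords(self, indices: np.ndarray) -> np.ndarray:
        """Map ``(n, 3)`` voxel indices to mm positions on this grid."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


@dataclass
class LabelVolume(Volume):
    """A binary segmentation on the same grid as a :class:`Volume`."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("label volume must be binary (0/1)")
        self.data = self.data.astype(np.uint8)


@dataclass
class ScribbleSet:
    """Ordered foreground/background seed pixels in one slice.

    Point order matters: it records the stroke direction so that prefixes of
    a stated physical length can be taken, mimicking a user who draws
    incrementally.
    """

    slice_index: int
    fg_pixels: list[tuple[int, int]] = field(default_factory=list)
    bg_pixels: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fg_pixels = [(int(r), int(c)) for r, c in self.fg_pixels]
        self.bg_pixels = [(int(r), int(c)) for r, c in self.bg_pixels]
        overlap = set(self.fg_pixels) & set(self.bg_pixels)
        if overlap:
            raise ValueError(f"pixels labeled both fg and bg: {sorted(overlap)[:5]}")

    def prefix_by_length(self, fg_len_mm: float, bg_len_mm: float,
                         spacing_rc: tuple[float, float]) -> "ScribbleSet":
        """Truncate each stroke to a cumulative polyline length in mm."""
        return ScribbleSet(
            self.slice_index,
            _prefix(self.fg_pixels, fg_len_mm, spacing_rc),
            _prefix(self.bg_pixels, bg_len_mm, spacing_rc),
        )

    def total_length_mm(self, spacing_rc: tuple[float, float]) -> float:
        return polyline_length_mm(self.fg_pixels, spacing_rc) + polyline_length_mm(
            self.bg_pixels, spacing_rc
        )


def polyline_length_mm(points: list[tuple[int, int]],
                       spacing_rc: tuple[float, float]) -> float:
    """Cumulative Euclidean length of a pixel polyline, in mm."""
    if len(points) < 2:
        return 0.0
    p = np.asarray(points, dtype=float) * np.asarray(spacing_rc, dtype=float)
    return float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))


def _prefix(points: list[tuple[int, int]], length_mm: float,
            spacing_rc: tuple[float, float]) -> list[tuple[int, int]]:
    if length_mm <= 0 or not points:
        return []
    p = np.asarray(points, dtype=float) * np.asarray(spacing_rc, dtype=float)
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    keep = int(np.searchsorted(cum, length_mm, side="left")) + 1
    return points[: max(2, min(keep, len(points)))]


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with spacing in the affine.

    The in-memory ``(slice, row, col)`` array is stored transposed to
    ``(col, row, slice)`` so the file's last (k) axis is the sparse one.
    """
    arr = np.transpose(vol.data, (2, 1, 0))
    sp = vol.spacing
    affine = np.diag([sp[2], sp[1], sp[0], 1.0])
    affine[:3, 3] = [vol.origin[2], vol.origin[1], vol.origin[0]]
    img = nib.Nifti1Image(np.asarray(arr), affine)
    img.header.set_zooms((sp[2], sp[1], sp[0]))
    nib.save(img, str(path))


def read_volume(path: str | Path, as_labels: bool = False) -> Volume:
    """Read a 3D NIfTI file; the axis with the largest spacing becomes axis 0."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {img.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: degenerate voxel spacing {zooms}")
    data = np.asanyarray(img.dataobj)
    sparse_axis = int(np.argmax(zooms))
    order = [sparse_axis] + [a for a in (2, 1, 0) if a != sparse_axis]
    data = np.transpose(data, order)
    spacing = tuple(float(zooms[a]) for a in order)
    origin = tuple(float(img.affine[a, 3]) for a in order)
    cls = LabelVolume if as_labels else Volume
    return cls(data=data, spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------
# Scribbles
# ---------------------------------------------------------------------------

def write_scribbles(scribbles: ScribbleSet, path: str | Path,
                    volume_shape: tuple[int, int, int] | None = None,
                    spacing: tuple[float, float, float] | None = None) -> None:
    """Write scribbles as ordered JSON, or as a NIfTI label map for ``.nii`` paths."""
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            "slice_index": scribbles.slice_index,
            "fg": [list(p) for p in scribbles.fg_pixels],
            "bg": [list(p) for p in scribbles.bg_pixels],
        }
        path.write_text(json.dumps(payload, indent=1))
        return
    if volume_shape is None or spacing is None:
        raise ValueError("label-map output needs volume_shape and spacing")
    lab = np.zeros(volume_shape, dtype=np.uint8)
    s = scribbles.slice_index
    for r, c in scribbles.fg_pixels:
        lab[s, r, c] = 1
    for r, c in scribbles.bg_pixels:
        lab[s, r, c] = 2
    write_volume(Volume(lab, spacing), path)


def read_scribbles(path: str | Path) -> ScribbleSet:
    """Read scribbles from JSON (ordered) or a NIfTI label map (unordered)."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return ScribbleSet(
            slice_index=int(payload["slice_index"]),
            fg_pixels=[tuple(p) for p in payload["fg"]],
            bg_pixels=[tuple(p) for p in payload["bg"]],
        )
    vol = read_volume(path)
    lab = np.asarray(vol.data)
    slices = np.unique(np.nonzero(lab)[0])
    if slices.size != 1:
        raise ValueError(f"{path}: scribble label map must mark exactly one slice")
    s = int(slices[0])
    fg = [tuple(int(v) for v in p) for p in np.argwhere(lab[s] == 1)]
    bg = [tuple(int(v) for v in p) for p in np.argwhere(lab[s] == 2)]
    return ScribbleSet(slice_index=s, fg_pixels=fg, bg_pixels=bg)
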