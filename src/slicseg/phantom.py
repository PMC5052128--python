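"""Synthetic multi-view studies for end-to-end testing without patient data.

The generator emulates the acquisition pattern of sparsely sampled fetal
MRI: strongly anisotropic voxels (slice spacing several times the in-plane
pitch), a per-slice multiplicative gain that drifts across slices
(interleaved-acquisition inhomogeneity), small random in-plane translations
of individual slices (inter-slice motion), additive Gaussian noise, and a
smooth crescent- or ellipsoid-shaped foreground object in a textured
background.  Several views of the same scene are produced by sampling one
continuous object on grids whose sparse axis points along different common
axes, so the inter-view transforms are known exactly.

The background contains a dim base with slow undulation plus brighter,
stripe-textured blobs that imitate confounding maternal/fetal tissue.  Blob
intensity is capped so that, in the noiseless limit, a single threshold at
the midpoint of the foreground/background means still separates the object
exactly — the texture makes intensity statistics less informative without
breaking that invariant.

Nothing here simulates MRI physics; the phantom reproduces the geometric
and statistical failure modes the segmentation method targets, not the
appearance of real anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, skeletonize

from .io import LabelVolume, ScribbleSet, Volume, polyline_length_mm

__all__ = ["PhantomSpec", "MultiViewStudy", "generate_study", "auto_scribbles"]

SCRIBBLE_EROSION_PX = 3  # careful user: scribbles stay this far inside a region


@dataclass
class PhantomSpec:
    """Study-generation parameters.

    ``grid_shape`` is ``(rows, cols, n_slices)`` and ``spacing`` the matching
    ``(row, col, slice)`` mm triple; both may be a single triple applied to
    every view or one triple per view.  Intensities are arbitrary units;
    ``slice_gain_sd`` is the per-slice increment of a multiplicative
    log-gain random walk; ``motion_shift_sd`` the mm std of each slice's
    random in-plane translation.
    """

    grid_shape: tuple = (96, 96, 24)
    #: per-view (row, col, slice) mm: the second view is sparser through-plane,
    #: so the views carry complementary resolution like axial/sagittal scans
    spacing: tuple = ((1.0, 1.0, 4.0), (1.0, 1.0, 6.0))
    object_kind: str = "crescent"
    fg_intensity_mean: float = 120.0
    bg_intensity_mean: float = 95.0
    noise_sd: float = 2.5
    slice_gain_sd: float = 0.015
    motion_shift_sd: float = 1.0
    texture_amplitude: float = 10.0
    #: mm half-width of the linear intensity ramp across the object surface
    #: (point-spread/partial-volume blur); textures fade inside the ramp so
    #: the noiseless phantom stays exactly threshold-separable
    boundary_softness_mm: float = 2.0
    seed: int = 0

    def shapes_for(self, n_views: int) -> list[tuple[int, int, int]]:
        return _per_view(self.grid_shape, n_views, "grid_shape")

    def spacings_for(self, n_views: int) -> list[tuple[float, float, float]]:
        return _per_view(self.spacing, n_views, "spacing")

    def validate(self, n_views: int = 1) -> None:
        if self.object_kind not in ("ellipsoid", "crescent"):
            raise ValueError(f"unknown object_kind {self.object_kind!r}")
        for sd in (self.noise_sd, self.slice_gain_sd, self.motion_shift_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.fg_intensity_mean <= self.bg_intensity_mean:
            raise ValueError("foreground must be brighter than background")
        if self.texture_amplitude >= 0.6 * (self.fg_intensity_mean
                                            - self.bg_intensity_mean):
            raise ValueError(
                "texture_amplitude too large for the fg/bg contrast: the "
                "noiseless phantom would no longer be threshold-separable")
        for shape, sp in zip(self.shapes_for(n_views), self.spacings_for(n_views)):
            if min(shape) < 8:
                raise ValueError("grid dimensions must be >= 8")
            if not (sp[2] > sp[0] and sp[2] > sp[1]):
                raise ValueError("slice spacing must exceed in-plane spacing")
            if min(sp) <= 0:
                raise ValueError("spacing must be positive")


def _per_view(value, n_views: int, name: str) -> list[tuple]:
    value = list(value)
    if np.isscalar(value[0]):
        return [tuple(value)] * n_views
    out = [tuple(v) for v in value[:n_views]]
    while len(out) < n_views:  # repeat the last triple for extra views
        out.append(out[-1])
    return out


@dataclass
class MultiViewStudy:
    """K views of one scene with ground truth and exact view transforms."""

    volumes: list[Volume]
    truths: list[LabelVolume]
    view_transforms: list[np.ndarray]  # 4x4: local mm -> common mm
    applied_slice_shifts: list[np.ndarray] = field(default_factory=list)
    spec: PhantomSpec | None = None

    def __post_init__(self) -> None:
        if not (len(self.volumes) == len(self.truths) == len(self.view_transforms)):
            raise ValueError("volumes, truths and transforms must align")
        for t in self.truths:
            if t.data.sum() == 0:
                raise ValueError("a ground-truth mask is empty")


# ---------------------------------------------------------------------------
# continuous scene
# ---------------------------------------------------------------------------

class _Scene:
    """Continuous object + intensity model in common (mm) coordinates."""

    def __init__(self, spec: PhantomSpec, extent: float, rng: np.random.Generator):
        self.spec = spec
        m = extent
        self.center = np.full(3, m / 2.0)
        self.kind = spec.object_kind
        if self.kind == "ellipsoid":
            self.semi = np.array([0.30, 0.34, 0.26]) * m
        else:  # crescent: sphere A minus sphere B
            self.rA = 0.36 * m
            self.rB = 0.30 * m
            self.cB = self.center + np.array([0.0, 0.16 * m, 0.0])

        fg, bg = spec.fg_intensity_mean, spec.bg_intensity_mean
        amp = spec.texture_amplitude
        self.und_amp = amp / 3.0
        # blob peak stays below the fg/bg midpoint even with stripes + undulation
        self.blob_boost = max(0.0, 0.48 * (fg - bg) - amp - self.und_amp)
        n_blobs = 3
        centers = []
        while len(centers) < n_blobs:
            c = rng.uniform(0.1 * m, 0.9 * m, size=3)
            if np.linalg.norm(c - self.center) > 0.42 * m:
                centers.append(c)
        self.blob_centers = np.array(centers)
        self.blob_radius = 0.12 * m
        dirs = rng.normal(size=(n_blobs, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        self.stripe_k = dirs * (2 * np.pi / 4.0)  # 4 mm stripe wavelength
        self.stripe_phase = rng.uniform(0, 2 * np.pi, size=n_blobs)
        self.und_k = rng.normal(size=(2, 3)) * (2 * np.pi / (0.45 * m))
        self.und_phase = rng.uniform(0, 2 * np.pi, size=2)
        self.mottle_k = rng.normal(size=(2, 3)) * (2 * np.pi / (0.18 * m))
        self.mottle_phase = rng.uniform(0, 2 * np.pi, size=2)
        # fine foreground speckle (~2.5 mm wavelength): a texture signature
        # distinct from both the flat background and the blob stripes
        self.speckle_k = rng.normal(size=(3, 3)) * (2 * np.pi / 2.5)
        self.speckle_phase = rng.uniform(0, 2 * np.pi, size=3)
        self.speckle_amp = amp / 6.0

    def signed_distance(self, p: np.ndarray) -> np.ndarray:
        """Approximate signed distance to the object surface, > 0 inside."""
        if self.kind == "ellipsoid":
            q = (p - self.center) / self.semi
            return (1.0 - np.sqrt(np.sum(q ** 2, axis=-1))) * float(self.semi.min())
        dA = np.linalg.norm(p - self.center, axis=-1)
        dB = np.linalg.norm(p - self.cB, axis=-1)
        return np.minimum(self.rA - dA, dB - self.rB)

    def inside(self, p: np.ndarray) -> np.ndarray:
        return self.signed_distance(p) > 0

    def intensity(self, p: np.ndarray) -> np.ndarray:
        """Noiseless scene intensity.

        The mean structure ramps linearly from the background to the
        foreground level across ``2 * boundary_softness_mm`` around the
        surface; all texture components are scaled by ``|2 s - 1|`` (zero at
        the surface), so in the noiseless limit the intensity crosses the
        fg/bg midpoint exactly on the true surface.
        """
        spec = self.spec
        d = self.signed_distance(p)
        w = max(spec.boundary_softness_mm, 1e-9)
        s = np.clip(0.5 + d / (2.0 * w), 0.0, 1.0)
        envelope = np.abs(2.0 * s - 1.0)
        delta = spec.fg_intensity_mean - spec.bg_intensity_mean

        mottle = sum(
            np.sin(p @ k + ph) for k, ph in zip(self.mottle_k, self.mottle_phase)
        )
        speckle = sum(
            np.sin(p @ k + ph) for k, ph in zip(self.speckle_k, self.speckle_phase)
        )
        fg_tex = (self.und_amp / 2.0) * mottle + self.speckle_amp * speckle

        und = sum(np.sin(p @ k + ph) for k, ph in zip(self.und_k, self.und_phase))
        bg_tex = (self.und_amp / 2.0) * und
        for c, k, ph in zip(self.blob_centers, self.stripe_k, self.stripe_phase):
            prof = np.exp(-np.sum((p - c) ** 2, axis=-1) / (2 * self.blob_radius ** 2))
            bg_tex = bg_tex + prof * (self.blob_boost
                                      + spec.texture_amplitude * np.sin(p @ k + ph))
        # cap the background deviation below half the contrast so that even
        # overlapping blobs cannot push the background over the midpoint
        bg_tex = np.minimum(bg_tex, 0.48 * delta)

        inside = d > 0
        tex = np.where(inside, fg_tex, bg_tex)
        return spec.bg_intensity_mean + delta * s + envelope * tex


def _view_transform(view: int) -> np.ndarray:
    """Cyclic axis permutation: view v maps local axis a to common axis (a + v) % 3."""
    T = np.zeros((4, 4))
    T[3, 3] = 1.0
    for a in range(3):
        T[(a + view) % 3, a] = 1.0
    return T


def generate_study(spec: PhantomSpec, n_views: int) -> MultiViewStudy:
    """Generate ``n_views`` sparsely-sliced, perturbed volumes of one scene.

    Identical ``spec.seed`` yields bit-identical output.  Each view's sparse
    axis points along a different common axis (cyclic permutation), so two
    views have complementary through-plane resolution.
    """
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    spec.validate(n_views)
    shapes = spec.shapes_for(n_views)
    spacings = spec.spacings_for(n_views)
    extent = shapes[0][0] * spacings[0][0]  # rows * row-spacing of view 0

    root = np.random.SeedSequence(spec.seed)
    scene_seq, *view_seqs = root.spawn(1 + n_views)
    scene = _Scene(spec, extent, np.random.default_rng(scene_seq))

    volumes, truths, transforms, shifts_all = [], [], [], []
    for v in range(n_views):
        rows, cols, n_slices = shapes[v]
        sp_r, sp_c, sp_s = spacings[v]
        rng = np.random.default_rng(view_seqs[v])
        T = _view_transform(v)
        shifts = (rng.normal(0.0, spec.motion_shift_sd, size=(n_slices, 2))
                  if spec.motion_shift_sd > 0 else np.zeros((n_slices, 2)))
        # log-gain random walk, anchored at the middle slice (the start region)
        steps = rng.normal(0.0, spec.slice_gain_sd, size=n_slices)
        log_gain = np.cumsum(steps)
        log_gain -= log_gain[n_slices // 2]
        gains = np.exp(log_gain)

        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        data = np.empty((n_slices, rows, cols))
        truth = np.empty((n_slices, rows, cols), dtype=np.uint8)
        for s in range(n_slices):
            local = np.column_stack([
                np.full(rr.size, s * sp_s),
                rr.ravel() * sp_r + shifts[s, 0],
                cc.ravel() * sp_c + shifts[s, 1],
            ])
            p = local @ T[:3, :3].T + T[:3, 3]
            truth[s] = scene.inside(p).reshape(rows, cols)
            signal = gains[s] * scene.intensity(p)
            if spec.noise_sd > 0:
                signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)
            data[s] = signal.reshape(rows, cols)
        spacing = (sp_s, sp_r, sp_c)
        volumes.append(Volume(data, spacing))
        truths.append(LabelVolume(truth, spacing))
        transforms.append(T)
        shifts_all.append(shifts)
    return MultiViewStudy(volumes, truths, transforms, shifts_all, spec)


# ---------------------------------------------------------------------------
# automatic scribbles
# ---------------------------------------------------------------------------

def _longest_skeleton_path(region: np.ndarray) -> list[tuple[int, int]]:
    """Ordered pixel path: the diameter path of the region's skeleton graph."""
    skel = skeletonize(region)
    pts = np.argwhere(skel)
    if len(pts) == 0:
        return []
    if len(pts) == 1:
        return [tuple(pts[0])]
    index = {tuple(p): i for i, p in enumerate(map(tuple, pts))}
    adj: list[list[int]] = [[] for _ in pts]
    for i, (r, c) in enumerate(pts):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None:
                    adj[i].append(j)

    def bfs(start: int):
        parent = {start: -1}
        order = [start]
        for u in order:
            for w in adj[u]:
                if w not in parent:
                    parent[w] = u
                    order.append(w)
        return order[-1], parent

    far, _ = bfs(0)
    end, parent = bfs(far)
    path = []
    node = end
    while node != -1:
        path.append(tuple(pts[node]))
        node = parent[node]
    return path


def _take_prefix(path: list[tuple[int, int]], length_mm: float,
                 spacing_rc: tuple[float, float], what: str) -> list[tuple[int, int]]:
    if length_mm == 0:
        return []
    if not path:
        raise ValueError(f"no {what} scribble support in this slice")
    total = polyline_length_mm(path, spacing_rc)
    if total + 1e-9 < length_mm:
        raise ValueError(
            f"requested {length_mm} mm of {what} scribble, only {total:.1f} mm available")
    p = np.asarray(path, dtype=float) * np.asarray(spacing_rc)
    cum = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(p, axis=0), axis=1))])
    keep = int(np.searchsorted(cum, length_mm, side="left")) + 1
    return path[:keep]


def auto_scribbles(truth: LabelVolume, slice_index: int, fg_len_mm: float,
                   bg_len_mm: float, seed: int = 0) -> ScribbleSet:
    """Simulate user scribbles of given physical lengths in one slice.

    Strokes follow the skeleton of the foreground (respectively background)
    eroded by ``SCRIBBLE_EROSION_PX`` in-plane pixels, mimicking a careful
    user who stays away from boundaries; point order is recorded so prefixes
    of a stated length are well defined.  The ``seed`` selects the stroke
    direction.
    """
    mask = truth.data[slice_index].astype(bool)
    if not mask.any() or mask.all():
        raise ValueError("slice must contain both foreground and background")
    spacing_rc = truth.spacing[1:]
    selem = disk(SCRIBBLE_EROSION_PX)
    fg_region = ndimage.binary_erosion(mask, structure=selem, border_value=0)
    bg_region = ndimage.binary_erosion(~mask, structure=selem, border_value=0)
    rng = np.random.default_rng(seed)
    fg_path = _longest_skeleton_path(fg_region)
    # a user marks background close to the organ: prefer a stroke within a
    # band around the object, fall back to the whole background if short
    band = ndimage.binary_dilation(mask, structure=disk(1), iterations=25)
    bg_pixels: list[tuple[int, int]] = []
    for region in (bg_region & band, bg_region):
        path = _longest_skeleton_path(region)
        try:
            bg_pixels = _take_prefix(path, bg_len_mm, spacing_rc, "background")
            break
        except ValueError:
            continue
    else:
        raise ValueError("requested background scribble length not achievable")
    if rng.integers(2):
        fg_path = fg_path[::-1]
    if rng.integers(2):
        bg_pixels = bg_pixels[::-1]
    return ScribbleSet(
        slice_index=slice_index,
        fg_pixels=_take_prefix(fg_path, fg_len_mm, spacing_rc, "foreground"),
        bg_pixels=bg_pixels,
    )
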