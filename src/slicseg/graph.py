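"""CRF energies and their exact minimisation by max-flow/min-cut.

Two energies are built here.  The per-slice CRF couples per-pixel data terms
``-log p`` with a contrast-sensitive Potts pairwise term over the 8-connected
in-plane neighborhood (N1).  The multi-volume refinement energy adds, on top
of the per-slice terms of every volume, inter-slice edges between
face-adjacent voxels of consecutive slices (N2, weighted by probability
contrast) and inter-volume edges between physically nearest voxels of
different volumes (N3, probability contrast without a distance factor).

Both energies are submodular binary labeling problems, so the global minimum
is found exactly by a single s-t min cut.  Capacities are scaled to 64-bit
integers (factor 2**32) for the solver; hard constraints get a capacity
exceeding the total of all finite terms, which makes them unbreakable
without risking overflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow
from scipy.spatial import cKDTree

from .io import LabelVolume, Volume

__all__ = [
    "CrfParams",
    "CosegParams",
    "CorrespondenceSet",
    "unary_cost",
    "intensity_pairwise",
    "prob_pairwise_slice",
    "prob_pairwise_interimage",
    "crf_segment_slice",
    "crf_energy",
    "build_correspondences",
    "coseg_refine",
    "coseg_energy",
]

logger = logging.getLogger(__name__)

PROB_EPS = 1e-6
# float -> integer capacity scale for the solver; capped adaptively so that no
# capacity reaches 2**31 (the solver's integer range)
_MAX_SCALE = float(2 ** 21)
_CAP_LIMIT = 2.0 ** 31 - 16

#: unique in-plane offsets generating the 8-connected neighborhood
N1_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass
class CrfParams:
    """Per-slice CRF parameters: pairwise weight and intensity contrast scale."""

    lambda1: float = 40.0
    sigma1: float = 2.5

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.sigma1 <= 0:
            raise ValueError("require lambda1 >= 0 and sigma1 > 0")


@dataclass
class CosegParams:
    """Multi-volume refinement parameters.

    ``lambda1/sigma1`` weight the in-plane intensity term, ``lambda2/sigma2``
    the inter-slice probability term, ``lambda3/sigma3`` the inter-volume
    probability term.
    """

    lambda1: float = 40.0
    lambda2: float = 10.0
    lambda3: float = 3.0
    sigma1: float = 2.5
    sigma2: float = 0.005
    sigma3: float = 0.08

    def __post_init__(self) -> None:
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("lambdas must be >= 0")
        if min(self.sigma1, self.sigma2, self.sigma3) <= 0:
            raise ValueError("sigmas must be > 0")

    @property
    def crf(self) -> CrfParams:
        return CrfParams(self.lambda1, self.sigma1)


@dataclass
class CorrespondenceSet:
    """Unordered nearest-voxel pairs between different volumes.

    ``pairs`` has rows ``(volume_k1, flat_voxel_i, volume_k2, flat_voxel_j)``
    with ``k1 < k2`` (or ``k1 == k2`` forbidden); each unordered pair appears
    once.
    """

    pairs: np.ndarray
    volume_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 4)
        if self.pairs.size and np.any(self.pairs[:, 0] == self.pairs[:, 2]):
            raise ValueError("self-volume correspondence pairs are not allowed")

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# closed-form energy terms
# ---------------------------------------------------------------------------

def unary_cost(prob, label) -> np.ndarray | float:
    """Data term ``-log p(label)`` with the probability clamped to [eps, 1-eps]."""
    p = np.asarray(prob, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    p = np.clip(p, PROB_EPS, 1.0 - PROB_EPS)
    lab = np.asarray(label)
    out = np.where(lab == 1, -np.log(p), -np.log(1.0 - p))
    return float(out) if out.ndim == 0 else out


def intensity_pairwise(Ii, Ij, dist, sigma1) -> np.ndarray | float:
    """Contrast term ``1/dist * exp(-(Ii-Ij)^2 / (2 sigma1^2))``."""
    dist = np.asarray(dist, dtype=np.float64)
    if np.any(dist <= 0):
        raise ValueError("dist must be > 0")
    d = np.asarray(Ii, dtype=np.float64) - np.asarray(Ij, dtype=np.float64)
    out = np.exp(-(d ** 2) / (2.0 * sigma1 ** 2)) / dist
    return float(out) if out.ndim == 0 else out


def prob_pairwise_slice(Pi, Pj, dist, sigma2) -> np.ndarray | float:
    """Inter-slice term: as :func:`intensity_pairwise` on probabilities."""
    return intensity_pairwise(Pi, Pj, dist, sigma2)


def prob_pairwise_interimage(Pi, Pj, sigma3) -> np.ndarray | float:
    """Inter-volume term ``exp(-(Pi-Pj)^2 / (2 sigma3^2))`` — no distance factor;
    the constant weight of these edges is folded into lambda3."""
    d = np.asarray(Pi, dtype=np.float64) - np.asarray(Pj, dtype=np.float64)
    out = np.exp(-(d ** 2) / (2.0 * sigma3 ** 2))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# min-cut solver
# ---------------------------------------------------------------------------

def _min_cut(unary0: np.ndarray, unary1: np.ndarray,
             edges_i: np.ndarray, edges_j: np.ndarray,
             edge_w: np.ndarray,
             hard_fg: np.ndarray | None = None,
             hard_bg: np.ndarray | None = None) -> np.ndarray:
    """Exact minimiser of ``sum_i U_li(i) + sum_ij w_ij [l_i != l_j]``.

    Node ``i`` on the source side of the cut gets label 1 (paying
    ``unary1``), on the sink side label 0 (paying ``unary0``).  Potts edges
    are symmetric arcs of capacity ``w``.  ``hard_fg`` / ``hard_bg`` are
    boolean node masks whose label is forced: the corresponding terminal
    edge gets a capacity strictly above the sum of everything else incident
    to the node, which no minimum cut can pay.

    Costs are scaled to integers for the solver; the scale adapts so that
    every capacity stays inside the solver's 32-bit range.  Returns the 0/1
    label vector.
    """
    n = len(unary0)
    s, t = n, n + 1
    # per-node incident float total: bounds the useful capacity of any
    # terminal edge, and hence the scale we can afford
    node_sum = unary0 + unary1
    if len(edges_i):
        np.add.at(node_sum, edges_i, edge_w)
        np.add.at(node_sum, edges_j, edge_w)
    scale = min(_MAX_SCALE, _CAP_LIMIT / (float(node_sum.max()) + 1.0))
    cap_si = np.round(unary0 * scale).astype(np.int64)
    cap_it = np.round(unary1 * scale).astype(np.int64)
    cap_e = np.round(edge_w * scale).astype(np.int64)
    hard_cap = np.ceil(node_sum * scale).astype(np.int64) + 1
    if hard_fg is not None and hard_fg.any():
        cap_si = np.where(hard_fg, hard_cap, cap_si)  # cutting label 0 forbidden
    if hard_bg is not None and hard_bg.any():
        cap_it = np.where(hard_bg, hard_cap, cap_it)
    assert max(cap_si.max(initial=0), cap_it.max(initial=0),
               cap_e.max(initial=0)) < 2 ** 31

    rows = np.concatenate([edges_i, edges_j, np.full(n, s), np.arange(n)])
    cols = np.concatenate([edges_j, edges_i, np.arange(n), np.full(n, t)])
    caps = np.concatenate([cap_e, cap_e, cap_si, cap_it])
    keep = caps > 0
    graph = csr_matrix((caps[keep], (rows[keep], cols[keep])), shape=(n + 2, n + 2))
    logger.info("min cut: %d nodes, %d arcs, scale %.3g", n, graph.nnz, scale)
    result = maximum_flow(graph, s, t)
    residual = (graph - result.flow).tocsr()
    residual.data = np.where(residual.data > 0, residual.data, 0)
    residual.eliminate_zeros()
    order = breadth_first_order(residual, s, directed=True, return_predecessors=False)
    labels = np.zeros(n, dtype=np.uint8)
    reach = order[order < n]
    labels[reach] = 1
    return labels


# ---------------------------------------------------------------------------
# per-slice CRF
# ---------------------------------------------------------------------------

def _slice_edges(shape: tuple[int, int], intensity: np.ndarray,
                 spacing_rc: tuple[float, float], lambda1: float, sigma1: float,
                 flat_offset: int = 0):
    """N1 edge arrays (i, j, weight) for one slice, 8-connected."""
    H, W = shape
    idx = np.arange(H * W).reshape(H, W) + flat_offset
    ei, ej, ew = [], [], []
    for dr, dc in N1_OFFSETS:
        r0, r1 = max(0, -dr), H - max(0, dr)
        c0, c1 = max(0, -dc), W - max(0, dc)
        a = idx[r0:r1, c0:c1]
        b = idx[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        Ia = intensity[r0:r1, c0:c1]
        Ib = intensity[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        dist = float(np.hypot(dr * spacing_rc[0], dc * spacing_rc[1]))
        w = lambda1 * intensity_pairwise(Ia, Ib, dist, sigma1)
        ei.append(a.ravel())
        ej.append(b.ravel())
        ew.append(np.asarray(w).ravel())
    return np.concatenate(ei), np.concatenate(ej), np.concatenate(ew)


def _hard_masks(shape, hard_fg, hard_bg):
    def _mask(pixels):
        m = np.zeros(shape[0] * shape[1], dtype=bool)
        if pixels is not None:
            px = np.asarray(list(pixels), dtype=np.int64).reshape(-1, 2)
            m[px[:, 0] * shape[1] + px[:, 1]] = True
        return m

    fg, bg = _mask(hard_fg), _mask(hard_bg)
    if (fg & bg).any():
        raise ValueError("hard foreground and background sets overlap")
    return fg, bg


def crf_segment_slice(prob_map: np.ndarray, intensity: np.ndarray,
                      spacing_rc: tuple[float, float], params: CrfParams,
                      hard_fg=None, hard_bg=None) -> np.ndarray:
    """Globally minimise the per-slice CRF; returns a 2D 0/1 label array.

    ``prob_map`` holds the foreground posterior per pixel, ``intensity`` the
    slice gray values used by the contrast-sensitive Potts term.  Pixels in
    ``hard_fg``/``hard_bg`` are forced to their label via effectively
    infinite unary costs.
    """
    prob_map = np.asarray(prob_map, dtype=np.float64)
    intensity = np.asarray(intensity, dtype=np.float64)
    if prob_map.shape != intensity.shape or prob_map.ndim != 2:
        raise ValueError("prob_map and intensity must be 2D with equal shapes")
    if not (np.all(np.isfinite(prob_map)) and np.all(np.isfinite(intensity))):
        raise ValueError("non-finite inputs")
    H, W = prob_map.shape
    flat_p = prob_map.ravel()
    unary1 = np.asarray(unary_cost(flat_p, 1))
    unary0 = np.asarray(unary_cost(flat_p, 0))
    fg_mask, bg_mask = _hard_masks((H, W), hard_fg, hard_bg)
    ei, ej, ew = _slice_edges((H, W), intensity, spacing_rc,
                              params.lambda1, params.sigma1)
    labels = _min_cut(unary0, unary1, ei, ej, ew,
                      hard_fg=fg_mask, hard_bg=bg_mask)
    return labels.reshape(H, W)


def crf_energy(labels: np.ndarray, prob_map: np.ndarray, intensity: np.ndarray,
               spacing_rc: tuple[float, float], params: CrfParams) -> float:
    """Energy of a given slice labeling (data term + Potts term)."""
    lab = np.asarray(labels).ravel()
    e = float(np.sum(unary_cost(np.asarray(prob_map, dtype=float).ravel(), lab)))
    ei, ej, ew = _slice_edges(prob_map.shape, np.asarray(intensity, dtype=float),
                              spacing_rc, params.lambda1, params.sigma1)
    e += float(np.sum(ew * (lab[ei] != lab[ej])))
    return e


# ---------------------------------------------------------------------------
# multi-volume refinement
# ---------------------------------------------------------------------------

def _common_coords(vol: Volume, transform: np.ndarray) -> np.ndarray:
    """Voxel centres of a volume mapped to common space by a rigid 4x4 transform."""
    shape = vol.shape
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"),
                   axis=-1).reshape(-1, 3)
    local = vol.physical_coords(idx)
    T = np.asarray(transform, dtype=np.float64)
    if T.shape != (4, 4):
        raise ValueError("transforms must be 4x4 homogeneous matrices")
    return local @ T[:3, :3].T + T[:3, 3]


def build_correspondences(volumes: list[Volume],
                          transforms: list[np.ndarray]) -> CorrespondenceSet:
    """Nearest-voxel pairs across volumes (the N3 neighborhood).

    For every voxel of every volume, the physically nearest voxel over all
    *other* volumes is found via the rigid transforms into common space;
    each unordered pair is recorded once.
    """
    K = len(volumes)
    if K < 2:
        raise ValueError("correspondences need at least two volumes")
    if len(transforms) != K:
        raise ValueError("one transform per volume required")
    coords = [_common_coords(v, t) for v, t in zip(volumes, transforms)]
    trees = [cKDTree(c) for c in coords]
    sizes = tuple(int(v.data.size) for v in volumes)
    rows = []
    for k1 in range(K):
        best_d = np.full(sizes[k1], np.inf)
        best_j = np.zeros(sizes[k1], dtype=np.int64)
        best_k = np.zeros(sizes[k1], dtype=np.int64)
        for k2 in range(K):
            if k2 == k1:
                continue
            d, j = trees[k2].query(coords[k1])
            closer = d < best_d
            best_d[closer] = d[closer]
            best_j[closer] = j[closer]
            best_k[closer] = k2
        i = np.arange(sizes[k1], dtype=np.int64)
        rows.append(np.column_stack([np.full(sizes[k1], k1, dtype=np.int64), i,
                                     best_k, best_j]))
    pairs = np.concatenate(rows)
    # canonical order (smaller volume index first), then dedupe
    flip = pairs[:, 0] > pairs[:, 2]
    pairs[flip] = pairs[flip][:, [2, 3, 0, 1]]
    pairs = np.unique(pairs, axis=0)
    logger.info("correspondences: %d unique pairs", len(pairs))
    return CorrespondenceSet(pairs, sizes)


def _coseg_terms(volumes: list[Volume], prob_volumes: list[np.ndarray],
                 correspondences: CorrespondenceSet | None, params: CosegParams):
    """Unaries and all edge arrays of the joint refinement energy."""
    K = len(volumes)
    sizes = [int(v.data.size) for v in volumes]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    unary1 = []
    ei, ej, ew = [], [], []
    for k, (vol, P) in enumerate(zip(volumes, prob_volumes)):
        P = np.asarray(P, dtype=np.float64)
        if P.shape != vol.shape:
            raise ValueError("probability volume shape mismatch")
        if P.size == 0:
            raise ValueError("empty probability volume")
        unary1.append(P.ravel())
        n_slices = vol.shape[0]
        per_slice = sizes[k] // n_slices
        # N1: in-plane, intensity contrast
        for s in range(n_slices):
            a, b, w = _slice_edges(vol.shape[1:], vol.data[s].astype(np.float64),
                                   vol.spacing[1:], params.lambda1, params.sigma1,
                                   flat_offset=offsets[k] + s * per_slice)
            ei.append(a)
            ej.append(b)
            ew.append(w)
        # N2: face neighbors across adjacent slices, probability contrast
        if n_slices > 1 and params.lambda2 > 0:
            idx = np.arange(sizes[k]).reshape(vol.shape) + offsets[k]
            a = idx[:-1].ravel()
            b = idx[1:].ravel()
            w = params.lambda2 * prob_pairwise_slice(
                P[:-1].ravel(), P[1:].ravel(), vol.spacing[0], params.sigma2)
            ei.append(a)
            ej.append(b)
            ew.append(np.asarray(w))
    # N3: inter-volume correspondences, probability contrast, no distance factor
    if correspondences is not None and len(correspondences) and params.lambda3 > 0:
        pr = correspondences.pairs
        Pflat = [np.asarray(p, dtype=np.float64).ravel() for p in prob_volumes]
        gi = offsets[pr[:, 0]] + pr[:, 1]
        gj = offsets[pr[:, 2]] + pr[:, 3]
        Pi = _gather(Pflat, pr[:, 0], pr[:, 1])
        Pj = _gather(Pflat, pr[:, 2], pr[:, 3])
        w = params.lambda3 * prob_pairwise_interimage(Pi, Pj, params.sigma3)
        ei.append(gi)
        ej.append(gj)
        ew.append(np.asarray(w))
    unary1 = np.concatenate(unary1)
    return (np.asarray(unary_cost(unary1, 0)), np.asarray(unary_cost(unary1, 1)),
            np.concatenate(ei), np.concatenate(ej), np.concatenate(ew), offsets)


def _gather(flat_arrays: list[np.ndarray], ks: np.ndarray, idx: np.ndarray) -> np.ndarray:
    out = np.empty(len(ks), dtype=np.float64)
    for k, arr in enumerate(flat_arrays):
        sel = ks == k
        out[sel] = arr[idx[sel]]
    return out


def coseg_refine(volumes: list[Volume], prob_volumes: list[np.ndarray],
                 init_labels: list[LabelVolume] | None,
                 correspondences: CorrespondenceSet | None,
                 params: CosegParams) -> list[LabelVolume]:
    """Jointly refine all volumes' segmentations by one global min cut.

    ``prob_volumes`` are the stacked forest posteriors from the single-volume
    phase; ``init_labels`` are the initial segmentations (kept for interface
    symmetry and logging — the refinement energy penalises discrepancies
    softly instead of constraining to them).  Returns one label volume per
    input volume, the exact global minimiser of the joint energy.
    """
    if not volumes:
        raise ValueError("no volumes")
    if len(prob_volumes) != len(volumes):
        raise ValueError("one probability volume per volume required")
    unary0, unary1, ei, ej, ew, offsets = _coseg_terms(
        volumes, prob_volumes, correspondences, params)
    labels = _min_cut(unary0, unary1, ei, ej, ew)
    out = []
    for k, vol in enumerate(volumes):
        lab = labels[offsets[k]:offsets[k + 1]].reshape(vol.shape)
        out.append(LabelVolume(lab, vol.spacing, vol.origin))
    return out


def coseg_energy(labels_list: list[np.ndarray], volumes: list[Volume],
                 prob_volumes: list[np.ndarray],
                 correspondences: CorrespondenceSet | None,
                 params: CosegParams) -> float:
    """Energy of a given joint labeling of all volumes."""
    unary0, unary1, ei, ej, ew, offsets = _coseg_terms(
        volumes, prob_volumes, correspondences, params)
    lab = np.concatenate([np.asarray(l).ravel() for l in labels_list])
    e = float(np.sum(np.where(lab == 1, unary1, unary0)))
    e += float(np.sum(ew * (lab[ei] != lab[ej])))
    return e
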