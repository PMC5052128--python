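"""The full single-volume segmentation pipeline and study orchestration.

Phase 1 works on one volume: the user scribbles foreground and background in
a single start slice; an online random forest learns from those pixels'
ROI features, predicts a per-pixel foreground posterior for the slice, and a
CRF turns the posterior into a spatially regular labeling (the scribbles act
as hard constraints in that slice only).  The labeling is then propagated
slice by slice in both directions: the previous slice's result supplies new
training data automatically — the skeleton of the foreground as positive
samples and the background eroded by a disk (default radius 10 px) as
negative samples — the forest is updated online, and the next slice is
predicted and regularised the same way.  Propagation along a direction stops
when the foreground shrinks below a minimum area, which handles the organ's
ends (the criterion is an implementation choice; the slice-by-slice scheme
itself does not dictate one).

Three ablation variants isolate the contribution of each component:
``offline`` freezes the forest after the start slice, ``lowlevel`` restricts
features to intensity mean/sd, and ``nocrf`` replaces the CRF by thresholding
at 0.5 followed by largest-connected-component selection and morphological
opening/closing.

Phase 2 (:func:`run_study`) refines two or more views jointly with the
probability-based multi-volume graph cut.
"""

from __future__ import annotations

import copy
import logging
import tomllib
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.morphology import disk, skeletonize

from .features import FEATURE_NAMES, LOW_LEVEL_FEATURE_NAMES, extract_features
from .forest import ForestConfig, OnlineRandomForest
from .graph import (CosegParams, CrfParams, build_correspondences, coseg_refine,
                    crf_energy, crf_segment_slice)
from .io import LabelVolume, ScribbleSet, Volume
from .phantom import MultiViewStudy

__all__ = ["SegConfig", "SegResult", "harvest_training", "segment_start_slice",
           "propagate", "run_study"]

logger = logging.getLogger(__name__)

VARIANTS = ("full", "offline", "lowlevel", "nocrf")


@dataclass
class SegConfig:
    """All pipeline parameters, shipped with the reference defaults."""

    forest: ForestConfig = field(default_factory=ForestConfig)
    crf: CrfParams = field(default_factory=CrfParams)
    coseg: CosegParams = field(default_factory=CosegParams)
    erosion_radius_px: int = 10
    variant: str = "full"
    nocrf_threshold: float = 0.5
    stop_min_fg_px: int = 20
    #: halt a propagation direction when a slice's foreground exceeds this
    #: multiple of the start-slice area -- the start slice sits in the
    #: organ's widest region, so such growth indicates the self-training
    #: has failed on this slice
    stop_growth_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not 0 < self.nocrf_threshold < 1:
            raise ValueError("nocrf_threshold must lie in (0, 1)")
        if self.erosion_radius_px < 0:
            raise ValueError("erosion_radius_px must be >= 0")

    @property
    def feature_set(self) -> str:
        return "lowlevel" if self.variant == "lowlevel" else "full"

    @property
    def feature_names(self) -> tuple[str, ...]:
        return (LOW_LEVEL_FEATURE_NAMES if self.variant == "lowlevel"
                else FEATURE_NAMES)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_toml(cls, path) -> "SegConfig":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "SegConfig":
        kwargs = dict(doc)
        if "forest" in kwargs:
            kwargs["forest"] = ForestConfig(**kwargs["forest"])
        if "crf" in kwargs:
            kwargs["crf"] = CrfParams(**kwargs["crf"])
        if "coseg" in kwargs:
            kwargs["coseg"] = CosegParams(**kwargs["coseg"])
        return cls(**kwargs)


@dataclass
class SegResult:
    """Stacked phase-1 output for one volume."""

    prob_volume: Volume       # per-voxel foreground posterior (float32)
    label_volume: LabelVolume
    per_slice_log: list[dict]
    start_slice: int


def harvest_training(mask: np.ndarray, erosion_radius_px: int):
    """Automatic training data from a segmented slice.

    Positive pixels are the morphological skeleton of the foreground;
    negative pixels are the background eroded by a disk of the given radius
    (the image border erodes too).  Either set may be empty.
    """
    mask = np.asarray(mask).astype(bool)
    fg = skeletonize(mask)
    if erosion_radius_px > 0:
        bg = ndimage.binary_erosion(~mask, structure=disk(erosion_radius_px),
                                    border_value=0)
    else:
        bg = ~mask
    return np.argwhere(fg), np.argwhere(bg)


def _predict_slice(forest: OnlineRandomForest, slice_image: np.ndarray,
                   feature_set: str) -> np.ndarray:
    H, W = slice_image.shape
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    pixels = np.column_stack([rr.ravel(), cc.ravel()])
    fm = extract_features(slice_image, pixels, feature_set=feature_set)
    return forest.predict_proba(fm.values).reshape(H, W)


def _label_slice(probs: np.ndarray, slice_image: np.ndarray,
                 spacing_rc, config: SegConfig,
                 hard_fg=None, hard_bg=None) -> np.ndarray:
    if config.variant == "nocrf":
        mask = probs >= config.nocrf_threshold
        if mask.any():
            comp = cc_label(mask, connectivity=2)
            largest = np.argmax(np.bincount(comp.ravel())[1:]) + 1
            mask = comp == largest
            selem = disk(2)
            mask = ndimage.binary_opening(mask, structure=selem)
            mask = ndimage.binary_closing(mask, structure=selem)
        return mask.astype(np.uint8)
    return crf_segment_slice(probs, slice_image, spacing_rc, config.crf,
                             hard_fg=hard_fg, hard_bg=hard_bg)


def segment_start_slice(volume: Volume, scribbles: ScribbleSet,
                        config: SegConfig):
    """Learn from the scribbles and segment the start slice.

    Returns ``(probabilities, labels, forest)`` for that slice.  Scribbles
    are hard CRF constraints here (and only here).
    """
    if not scribbles.fg_pixels or not scribbles.bg_pixels:
        raise ValueError("start scribbles must contain both classes")
    if not 0 <= scribbles.slice_index < volume.n_slices:
        raise ValueError("start slice outside the volume")
    slice_image = volume.data[scribbles.slice_index].astype(np.float64)
    pixels = list(scribbles.fg_pixels) + list(scribbles.bg_pixels)
    labels = np.concatenate([np.ones(len(scribbles.fg_pixels)),
                             np.zeros(len(scribbles.bg_pixels))])
    fm = extract_features(slice_image, pixels, feature_set=config.feature_set,
                          slice_index=scribbles.slice_index)
    forest = OnlineRandomForest(copy.deepcopy(config.forest),
                                feature_names=config.feature_names)
    forest.update(fm.values, labels)
    probs = _predict_slice(forest, slice_image, config.feature_set)
    out = _label_slice(probs, slice_image, volume.spacing[1:], config,
                       hard_fg=scribbles.fg_pixels, hard_bg=scribbles.bg_pixels)
    return probs, out, forest


def propagate(volume: Volume, scribbles: ScribbleSet,
              config: SegConfig) -> SegResult:
    """Run the full slice-propagation pipeline over one volume.

    From the start slice the segmentation spreads toward increasing and
    decreasing slice indices independently, each direction with its own copy
    of the start-slice forest so neither direction's updates contaminate the
    other.
    """
    s0 = scribbles.slice_index
    probs0, labels0, forest0 = segment_start_slice(volume, scribbles, config)
    shape = volume.shape
    prob_vol = np.zeros(shape, dtype=np.float32)
    label_vol = np.zeros(shape, dtype=np.uint8)
    prob_vol[s0] = probs0
    label_vol[s0] = labels0
    spacing_rc = volume.spacing[1:]
    log: list[dict] = [{
        "slice": s0, "n_train_fg": len(scribbles.fg_pixels),
        "n_train_bg": len(scribbles.bg_pixels),
        "fg_area_px": int(labels0.sum()),
        "energy": crf_energy(labels0, probs0, volume.data[s0], spacing_rc,
                             config.crf),
    }]

    for direction in (1, -1):
        forest = forest0.copy()
        prev_labels = labels0
        s = s0 + direction
        while 0 <= s < shape[0]:
            if int(prev_labels.sum()) < config.stop_min_fg_px:
                logger.info("propagation stopped at slice %d (fg too small)", s)
                break
            # the organ is one structure: harvest from the main component so
            # spurious islands cannot feed the online training
            comp = cc_label(prev_labels.astype(bool), connectivity=2)
            if comp.max() > 1:
                largest = np.argmax(np.bincount(comp.ravel())[1:]) + 1
                prev_labels = (comp == largest).astype(np.uint8)
            fg_px, bg_px = harvest_training(prev_labels, config.erosion_radius_px)
            prev_image = volume.data[s - direction].astype(np.float64)
            n_fg, n_bg = len(fg_px), len(bg_px)
            if config.variant != "offline" and (n_fg or n_bg):
                pixels = np.concatenate([p for p in (fg_px, bg_px) if len(p)])
                y = np.concatenate([np.ones(n_fg), np.zeros(n_bg)])
                fm = extract_features(prev_image, pixels,
                                      feature_set=config.feature_set,
                                      slice_index=s - direction)
                forest.update(fm.values, y)
            slice_image = volume.data[s].astype(np.float64)
            probs = _predict_slice(forest, slice_image, config.feature_set)
            labels = _label_slice(probs, slice_image, spacing_rc, config)
            if int(labels.sum()) > config.stop_growth_factor * max(
                    int(labels0.sum()), config.stop_min_fg_px):
                logger.info("propagation stopped at slice %d (implausible "
                            "foreground growth)", s)
                break
            prob_vol[s] = probs
            label_vol[s] = labels
            log.append({
                "slice": s, "n_train_fg": n_fg, "n_train_bg": n_bg,
                "fg_area_px": int(labels.sum()),
                "energy": crf_energy(labels, probs, slice_image, spacing_rc,
                                     config.crf),
            })
            prev_labels = labels
            s += direction

    log.sort(key=lambda d: d["slice"])
    return SegResult(
        prob_volume=Volume(prob_vol, volume.spacing, volume.origin),
        label_volume=LabelVolume(label_vol, volume.spacing, volume.origin),
        per_slice_log=log,
        start_slice=s0,
    )


def run_study(study: MultiViewStudy, scribbles_per_view: list[ScribbleSet],
              config: SegConfig):
    """Phase 1 on every view, then joint multi-volume refinement.

    Returns ``(initial_results, refined_labels)``.  With a single view the
    refinement degenerates to a 3D probability-based refinement of that
    volume (no inter-volume term).
    """
    if len(scribbles_per_view) != len(study.volumes):
        raise ValueError("need one scribble set per view")
    results = [propagate(vol, scr, config)
               for vol, scr in zip(study.volumes, scribbles_per_view)]
    prob_volumes = [r.prob_volume.data.astype(np.float64) for r in results]
    init_labels = [r.label_volume for r in results]
    correspondences = None
    if len(study.volumes) >= 2:
        correspondences = build_correspondences(study.volumes,
                                                study.view_transforms)
    refined = coseg_refine(study.volumes, prob_volumes, init_labels,
                           correspondences, config.coseg)
    return results, refined
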