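"""Slide tiling, TLS patch labeling and scoring, FOV ranking, and immune
infiltration targets.

The workflow: a whole slide is tiled into square patches with a sliding
window; patches are labeled TLS / non-TLS from the quantity and intensity
of CD3+ and CD20+ cells (all-black patches are discarded); a training set
is assembled at a 1:10 positive:negative ratio; a fine-tuned model scores
patches with predicted probabilities (TLS scores); fields of view are
ranked by their TLS score and the cumulative fraction of T and B cells
captured by the first k acquired FOVs is compared across guided, scanning,
and random acquisition orders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label
from skimage.transform import resize

from .corpus import SlideImage
from .model import FineTunedModel

__all__ = [
    "SlidePatch",
    "FOVRecord",
    "tile_slide",
    "label_tls_patches",
    "assemble_tls_training_set",
    "score_patches",
    "score_heatmap",
    "build_fov_records",
    "rank_fovs",
    "captured_proportion",
    "mean_capture_curve",
    "infiltration_targets",
]


@dataclass
class SlidePatch:
    """A square window of a slide; windows are half-open [origin, origin+size)."""

    origin: tuple[int, int]
    size_px: int
    channels: dict[str, np.ndarray]
    label: str | None = None  # "TLS" | "non-TLS"
    score: float | None = None

    @property
    def dapi(self) -> np.ndarray:
        return self.channels["DAPI"]

    @property
    def center(self) -> tuple[float, float]:
        return (self.origin[0] + self.size_px / 2.0, self.origin[1] + self.size_px / 2.0)


@dataclass
class FOVRecord:
    """A field of view: scan-order id, pixel bounds, TLS score, cell counts."""

    fov_id: int
    bounds: tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open
    tls_score: float = 0.0
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def lymphocytes(self) -> int:
        return int(self.counts.get("T", 0) + self.counts.get("B", 0))


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------

def tile_slide(
    slide: SlideImage | np.ndarray,
    size_px: int,
    step_px: int,
    markers: dict[str, np.ndarray] | None = None,
) -> list[SlidePatch]:
    """Sliding-window tiling into square patches, row-major.

    Windows extending past the slide edge are dropped, giving
    (floor((H-size)/step)+1) * (floor((W-size)/step)+1) patches. Marker
    channels, when given, are cropped alongside the DAPI channel.
    """
    pixels = slide.pixels if isinstance(slide, SlideImage) else np.asarray(slide)
    H, W = pixels.shape
    if size_px > H or size_px > W:
        raise ValueError(f"patch size {size_px} exceeds slide dims {H}x{W}")
    if step_px < 1:
        raise ValueError("step_px must be >= 1")
    patches = []
    for r0 in range(0, H - size_px + 1, step_px):
        for c0 in range(0, W - size_px + 1, step_px):
            channels = {"DAPI": pixels[r0 : r0 + size_px, c0 : c0 + size_px]}
            if markers:
                for name, chan in markers.items():
                    channels[name] = chan[r0 : r0 + size_px, c0 : c0 + size_px]
            patches.append(SlidePatch(origin=(r0, c0), size_px=size_px, channels=channels))
    return patches


# ---------------------------------------------------------------------------
# TLS labeling and training-set assembly
# ---------------------------------------------------------------------------

def _count_marker_cells(channel: np.ndarray, threshold: float, min_area: int = 3) -> int:
    """Marker-positive cell count: connected components above threshold."""
    cc = cc_label(channel > threshold)
    if cc.max() == 0:
        return 0
    sizes = np.bincount(cc.ravel())[1:]
    return int((sizes >= min_area).sum())


def label_tls_patches(
    patches: list[SlidePatch],
    min_cells: int = 3,
    min_intensity: float = 0.01,
    marker_threshold: float = 0.2,
) -> list[SlidePatch]:
    """Label patches TLS / non-TLS from CD3 and CD20 content.

    Patches whose maximum over all channels is 0 (entirely black) are
    discarded. A patch is TLS iff it holds at least ``min_cells`` CD3+
    cells AND at least ``min_cells`` CD20+ cells AND its mean marker
    intensity is at least ``min_intensity``. Returns the retained, labeled
    patches.
    """
    out = []
    for p in patches:
        if "CD3" not in p.channels or "CD20" not in p.channels:
            raise ValueError("TLS labeling requires CD3 and CD20 channels")
        if max(chan.max() for chan in p.channels.values()) == 0:
            continue  # entirely black
        n_cd3 = _count_marker_cells(p.channels["CD3"], marker_threshold)
        n_cd20 = _count_marker_cells(p.channels["CD20"], marker_threshold)
        mean_marker = float(
            (p.channels["CD3"].mean() + p.channels["CD20"].mean()) / 2.0
        )
        is_tls = n_cd3 >= min_cells and n_cd20 >= min_cells and mean_marker >= min_intensity
        p.label = "TLS" if is_tls else "non-TLS"
        out.append(p)
    return out


def assemble_tls_training_set(
    patches: list[SlidePatch], neg_per_pos: int = 10, seed: int = 0
) -> list[SlidePatch]:
    """Keep all positives and subsample negatives to ``neg_per_pos`` x
    positives (the published 1:10 positive:negative ratio). If fewer
    negatives exist, all are kept with a warning."""
    pos = [p for p in patches if p.label == "TLS"]
    neg = [p for p in patches if p.label == "non-TLS"]
    if not pos:
        raise ValueError("training set needs at least one TLS-positive patch")
    want = neg_per_pos * len(pos)
    if len(neg) <= want:
        if len(neg) < want:
            import warnings

            warnings.warn(f"only {len(neg)} negatives available (wanted {want}); keeping all")
        chosen = neg
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(neg), size=want, replace=False)
        chosen = [neg[i] for i in sorted(idx)]
    return pos + chosen


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_patches(model: FineTunedModel, patches: list[SlidePatch]) -> np.ndarray:
    """Predicted TLS probability per patch (stored on each patch too).

    Patch DAPI crops are resized to the model's input side when needed.
    """
    if model.head.spec.task != "tls_score":
        raise ValueError(f"model head task is {model.head.spec.task!r}, need 'tls_score'")
    side = model.model.cfg.image_size
    stack = []
    for p in patches:
        img = p.dapi.astype(np.float64)
        if img.shape != (side, side):
            img = resize(img, (side, side), preserve_range=True, anti_aliasing=True)
        stack.append(img)
    scores = model.predict(np.stack(stack)).reshape(-1)
    for p, s in zip(patches, scores):
        p.score = float(s)
    return scores


def score_heatmap(patches: list[SlidePatch], slide_shape: tuple[int, int]) -> np.ndarray:
    """Per-pixel TLS-score heatmap: overlapping patch scores are averaged.

    Order-independent by construction (sum of scores / count per pixel);
    pixels covered by no patch are NaN.
    """
    total = np.zeros(slide_shape)
    count = np.zeros(slide_shape)
    for p in patches:
        if p.score is None:
            raise ValueError("patches must be scored before building a heatmap")
        r0, c0 = p.origin
        total[r0 : r0 + p.size_px, c0 : c0 + p.size_px] += p.score
        count[r0 : r0 + p.size_px, c0 : c0 + p.size_px] += 1
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, total / np.maximum(count, 1), np.nan)


# ---------------------------------------------------------------------------
# FOV records, ranking, capture curves
# ---------------------------------------------------------------------------

def build_fov_records(
    slide_shape: tuple[int, int],
    fov_px: int,
    centroids: pd.DataFrame,
    scored_patches: list[SlidePatch] | None = None,
    agg: str = "mean",
) -> list[FOVRecord]:
    """Partition the slide into a scan-ordered FOV grid with per-type cell
    counts and (optionally) a TLS score aggregated from member patches.

    A patch belongs to the FOV that contains its center; the FOV score is
    the mean (default) or max of member patch scores, 0 if it has none.
    """
    H, W = slide_shape
    fovs = []
    fid = 0
    for r0 in range(0, H - fov_px + 1, fov_px):
        for c0 in range(0, W - fov_px + 1, fov_px):
            r1, c1 = r0 + fov_px, c0 + fov_px
            inside = centroids[
                (centroids["row"] >= r0) & (centroids["row"] < r1)
                & (centroids["col"] >= c0) & (centroids["col"] < c1)
            ]
            counts = inside["cell_type"].value_counts().to_dict() if len(inside) else {}
            fovs.append(FOVRecord(fov_id=fid, bounds=(r0, c0, r1, c1), counts=counts))
            fid += 1
    if scored_patches is not None:
        for fov in fovs:
            r0, c0, r1, c1 = fov.bounds
            member = [
                p.score
                for p in scored_patches
                if r0 <= p.center[0] < r1 and c0 <= p.center[1] < c1
            ]
            if member:
                fov.tls_score = float(np.mean(member) if agg == "mean" else np.max(member))
    return fovs


def rank_fovs(
    fovs: list[FOVRecord],
    strategy: str = "guided",
    n_shuffles: int = 10,
    seed: int = 0,
) -> list[list[int]]:
    """Acquisition order(s) over FOV ids.

    guided: descending TLS score (ties broken by ascending fov_id);
    scanning: ascending fov_id; random: ``n_shuffles`` seeded permutations
    (capture curves are then averaged). Always returns a list of orderings.
    """
    if not fovs:
        raise ValueError("no FOVs to rank")
    ids = [f.fov_id for f in fovs]
    if strategy == "guided":
        order = sorted(fovs, key=lambda f: (-f.tls_score, f.fov_id))
        return [[f.fov_id for f in order]]
    if strategy == "scanning":
        return [sorted(ids)]
    if strategy == "random":
        rng = np.random.default_rng(seed)
        return [list(rng.permutation(ids)) for _ in range(n_shuffles)]
    raise ValueError(f"unknown strategy {strategy!r}")


def captured_proportion(ordering: list[int], fovs: list[FOVRecord]) -> np.ndarray:
    """Cumulative fraction of T+B cells captured by the first k FOVs.

    The curve is non-decreasing and ends at 1 (or stays 0 for a slide with
    no lymphocytes).
    """
    by_id = {f.fov_id: f for f in fovs}
    if sorted(ordering) != sorted(by_id):
        raise ValueError("ordering must be a permutation of the FOV ids")
    counts = np.array([by_id[i].lymphocytes for i in ordering], dtype=np.float64)
    total = counts.sum()
    if total == 0:
        return np.zeros(len(counts))
    return np.cumsum(counts) / total


def mean_capture_curve(orderings: list[list[int]], fovs: list[FOVRecord]) -> np.ndarray:
    """Average capture curve over several acquisition orders."""
    return np.mean([captured_proportion(o, fovs) for o in orderings], axis=0)


# ---------------------------------------------------------------------------
# Immune infiltration targets
# ---------------------------------------------------------------------------

def infiltration_targets(
    patches: list[SlidePatch], centroids: pd.DataFrame, mode: str = "density"
) -> np.ndarray:
    """Per-patch infiltration score from T and B cell counts.

    ``density`` (default) divides the T+B count by the patch area so scores
    are comparable across patch sizes; ``count`` returns the raw count.
    """
    if mode not in {"density", "count"}:
        raise ValueError(f"unknown mode {mode!r}")
    lymph = centroids[centroids["cell_type"].isin(["T", "B"])]
    out = np.zeros(len(patches))
    for i, p in enumerate(patches):
        r0, c0 = p.origin
        r1, c1 = r0 + p.size_px, c0 + p.size_px
        n = int(
            (
                (lymph["row"] >= r0) & (lymph["row"] < r1)
                & (lymph["col"] >= c0) & (lymph["col"] < c1)
            ).sum()
        )
        out[i] = n / (p.size_px**2) if mode == "density" else n
    return out
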