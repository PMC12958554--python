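"""Nucleus-crop corpora: extraction from whole-slide DAPI images, QC,
intensity normalization, HDF5 storage, and train/val/test splitting.

A corpus is built by cropping fixed physical-size windows (in µm) around
nucleus centroids from a single-channel fluorescence slide, filtering crops
by mean fluorescence intensity, normalizing each crop to [0, 1], and storing
the result in a single HDF5 file together with per-cell metadata, optional
labels, and split assignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

FORMAT_VERSION = "1.0"

__all__ = [
    "SlideImage",
    "NucleusImage",
    "ImageCorpus",
    "CorpusFormatError",
    "extract_nucleus_subimages",
    "qc_filter",
    "normalize_intensity",
    "write_corpus",
    "read_corpus",
    "split_corpus",
    "load_slide",
    "load_centroids",
]


class CorpusFormatError(ValueError):
    """Raised when an HDF5 corpus file is missing a required dataset/attribute."""


@dataclass
class SlideImage:
    """A single-channel whole-slide fluorescence image.

    Parameters
    ----------
    pixels : 2-D array of non-negative intensities (8/16-bit integer or float).
    pixel_size : physical size of one pixel in µm (must be positive).
    slide_id : identifier carried into crop provenance metadata.
    """

    pixels: np.ndarray
    pixel_size: float
    slide_id: str = "slide"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("slide pixels must be a non-empty 2-D array")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")


@dataclass
class NucleusImage:
    """One square single-channel nucleus crop plus provenance metadata."""

    pixels: np.ndarray
    centroid: tuple[int, int] = (0, 0)  # (row, col) in slide pixel coords
    window_um: float = 20.0
    source: str = "slide"
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("nucleus crop must be square")


@dataclass
class ImageCorpus:
    """An ordered collection of nucleus crops with optional labels and splits.

    ``pixels`` is a dense (n, S, S) float32 stack; ``meta`` carries one row per
    crop (cell_id, centroid_row, centroid_col, window_um, source). ``labels``
    and ``splits``, when present, are indexed by position and must cover every
    crop.
    """

    pixels: np.ndarray
    meta: pd.DataFrame
    labels: pd.Series | None = None
    splits: pd.Series | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3:
            raise ValueError("corpus pixels must be (n, S, S)")
        n = len(self.pixels)
        if len(self.meta) != n:
            raise ValueError("meta must have one row per image")
        for name in ("labels", "splits"):
            s = getattr(self, name)
            if s is not None and len(s) != n:
                raise ValueError(f"{name} must cover exactly the corpus cells")

    def __len__(self) -> int:
        return len(self.pixels)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.meta["cell_id"].to_numpy()

    def subset(self, idx: np.ndarray) -> "ImageCorpus":
        idx = np.asarray(idx)
        return ImageCorpus(
            pixels=self.pixels[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
            labels=None if self.labels is None else self.labels.iloc[idx].reset_index(drop=True),
            splits=None if self.splits is None else self.splits.iloc[idx].reset_index(drop=True),
        )

    def split_indices(self, name: str) -> np.ndarray:
        if self.splits is None:
            raise ValueError("corpus has no split assignment")
        return np.flatnonzero(self.splits.to_numpy() == name)

    def images(self) -> list[NucleusImage]:
        out = []
        for i in range(len(self)):
            row = self.meta.iloc[i]
            out.append(
                NucleusImage(
                    pixels=self.pixels[i],
                    centroid=(int(row["centroid_row"]), int(row["centroid_col"])),
                    window_um=float(row["window_um"]),
                    source=str(row["source"]),
                    cell_id=str(row["cell_id"]),
                )
            )
        return out

    @staticmethod
    def from_images(
        images: list[NucleusImage],
        labels: pd.Series | None = None,
        splits: pd.Series | None = None,
    ) -> "ImageCorpus":
        if not images:
            raise ValueError("cannot build a corpus from zero images")
        pixels = np.stack([im.pixels for im in images]).astype(np.float32)
        meta = pd.DataFrame(
            {
                "cell_id": [im.cell_id for im in images],
                "centroid_row": [im.centroid[0] for im in images],
                "centroid_col": [im.centroid[1] for im in images],
                "window_um": [im.window_um for im in images],
                "source": [im.source for im in images],
            }
        )
        return ImageCorpus(pixels, meta, labels=labels, splits=splits)


# ---------------------------------------------------------------------------
# Extraction and preprocessing
# ---------------------------------------------------------------------------

def extract_nucleus_subimages(
    slide: SlideImage,
    centroids: list[tuple[int, int]],
    window_um: float,
    cell_ids: list[str] | None = None,
) -> list[NucleusImage]:
    """Crop square windows of physical side ``window_um`` around centroids.

    The crop side in pixels is ``round(window_um / pixel_size)``; windows are
    half-open ``[start, start + S)`` with the centroid at ``start + S // 2``.
    Regions falling outside the slide are zero-padded, so every centroid
    yields a crop. Output order matches input order.
    """
    if not window_um > 0:
        raise ValueError(f"window_um must be > 0, got {window_um}")
    side = int(round(window_um / slide.pixel_size))
    if side < 1:
        raise ValueError("window_um smaller than one pixel")
    H, W = slide.pixels.shape
    if cell_ids is None:
        cell_ids = [f"{slide.slide_id}_{i}" for i in range(len(centroids))]
    out: list[NucleusImage] = []
    half = side // 2
    for cid, (r, c) in zip(cell_ids, centroids):
        r, c = int(round(r)), int(round(c))
        if not (0 <= r < H and 0 <= c < W):
            raise ValueError(f"centroid ({r}, {c}) outside slide bounds {H}x{W}")
        r0, c0 = r - half, c - half
        crop = np.zeros((side, side), dtype=np.float32)
        sr0, sc0 = max(r0, 0), max(c0, 0)
        sr1, sc1 = min(r0 + side, H), min(c0 + side, W)
        crop[sr0 - r0 : sr1 - r0, sc0 - c0 : sc1 - c0] = slide.pixels[sr0:sr1, sc0:sc1]
        out.append(
            NucleusImage(
                pixels=crop,
                centroid=(r, c),
                window_um=window_um,
                source=slide.slide_id,
                cell_id=cid,
            )
        )
    return out


def qc_filter(
    images: list[NucleusImage],
    min_mean: float = 0.0,
    max_mean: float = np.inf,
) -> tuple[list[NucleusImage], list[NucleusImage]]:
    """Partition crops by mean fluorescence intensity banding.

    A crop is kept iff ``min_mean <= mean(pixels) <= max_mean``. The two
    returned lists partition the input (kept first, rejected second).
    """
    if min_mean > max_mean:
        raise ValueError("min_mean must be <= max_mean")
    kept, rejected = [], []
    for im in images:
        (kept if min_mean <= float(im.pixels.mean()) <= max_mean else rejected).append(im)
    return kept, rejected


def normalize_intensity(
    image: NucleusImage, clip_percentiles: tuple[float, float] = (1.0, 99.0)
) -> NucleusImage:
    """Percentile-clip then min-max rescale a crop to [0, 1].

    Pixels are clipped to the [low, high] percentile band, then linearly
    rescaled so the band maps to [0, 1]. Constant crops map to all zeros
    (the rescale denominator would be zero).
    """
    low, high = clip_percentiles
    if not (0 <= low < high <= 100):
        raise ValueError(f"need 0 <= low < high <= 100, got {clip_percentiles}")
    px = np.asarray(image.pixels, dtype=np.float64)
    lo, hi = np.percentile(px, [low, high])
    if hi <= lo:
        out = np.zeros_like(px, dtype=np.float32)
    else:
        out = ((np.clip(px, lo, hi) - lo) / (hi - lo)).astype(np.float32)
    return NucleusImage(
        pixels=out,
        centroid=image.centroid,
        window_um=image.window_um,
        source=image.source,
        cell_id=image.cell_id,
    )


# ---------------------------------------------------------------------------
# HDF5 storage
# ---------------------------------------------------------------------------

def write_corpus(corpus: ImageCorpus, path) -> None:
    """Write a corpus to HDF5: ``/images`` (n, S, S float32, chunked per
    image), ``/meta`` columns, optional ``/labels`` and ``/splits``, and a
    ``format_version`` root attribute."""
    n, S, _ = corpus.pixels.shape
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.create_dataset("images", data=corpus.pixels, chunks=(1, S, S))
        g = f.create_group("meta")
        g.create_dataset("cell_id", data=corpus.meta["cell_id"].astype(str).to_numpy(dtype="S"))
        g.create_dataset("centroid_row", data=corpus.meta["centroid_row"].to_numpy(np.int64))
        g.create_dataset("centroid_col", data=corpus.meta["centroid_col"].to_numpy(np.int64))
        g.create_dataset("window_um", data=corpus.meta["window_um"].to_numpy(np.float64))
        g.create_dataset("source", data=corpus.meta["source"].astype(str).to_numpy(dtype="S"))
        if corpus.labels is not None:
            f.create_dataset("labels", data=corpus.labels.astype(str).to_numpy(dtype="S"))
        if corpus.splits is not None:
            f.create_dataset("splits", data=corpus.splits.astype(str).to_numpy(dtype="S"))


def read_corpus(path) -> ImageCorpus:
    """Read a corpus written by :func:`write_corpus` (lossless round-trip)."""
    with h5py.File(path, "r") as f:
        if "format_version" not in f.attrs:
            raise CorpusFormatError("missing root attribute 'format_version'")
        if "images" not in f:
            raise CorpusFormatError("missing dataset '/images'")
        if "meta" not in f:
            raise CorpusFormatError("missing group '/meta'")
        g = f["meta"]
        for col in ("cell_id", "centroid_row", "centroid_col", "window_um", "source"):
            if col not in g:
                raise CorpusFormatError(f"missing dataset '/meta/{col}'")
        pixels = f["images"][...]
        meta = pd.DataFrame(
            {
                "cell_id": [s.decode() for s in g["cell_id"][...]],
                "centroid_row": g["centroid_row"][...],
                "centroid_col": g["centroid_col"][...],
                "window_um": g["window_um"][...],
                "source": [s.decode() for s in g["source"][...]],
            }
        )
        labels = None
        if "labels" in f:
            labels = pd.Series([s.decode() for s in f["labels"][...]], name="label")
        splits = None
        if "splits" in f:
            splits = pd.Series([s.decode() for s in f["splits"][...]], name="split")
    return ImageCorpus(pixels, meta, labels=labels, splits=splits)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_corpus(
    corpus: ImageCorpus, fractions: tuple[float, ...], seed: int = 0
) -> ImageCorpus:
    """Assign each cell to train/val(/test) by a seeded random partition.

    ``fractions`` is (train, val) or (train, val, test) and must sum to 1.
    Non-train split sizes are ``round(fraction * n)``; the remainder goes to
    train, so (0.8, 0.2) on n=1000 gives 800/200 and (0.8, 0.1, 0.1) gives
    800/100/100. The same seed always yields the same partition.
    """
    if len(fractions) not in (2, 3):
        raise ValueError("fractions must be (train, val) or (train, val, test)")
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-8:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    n = len(corpus)
    names = ("train", "val", "test")[: len(fractions)]
    sizes = {name: int(round(f * n)) for name, f in zip(names[1:], fractions[1:])}
    sizes["train"] = n - sum(sizes.values())
    if sizes["train"] < 0:
        raise ValueError("rounded split sizes exceed corpus size")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=object)
    start = 0
    for name in names:
        assignment[perm[start : start + sizes[name]]] = name
        start += sizes[name]
    return ImageCorpus(
        pixels=corpus.pixels,
        meta=corpus.meta,
        labels=corpus.labels,
        splits=pd.Series(assignment, name="split"),
    )


# ---------------------------------------------------------------------------
# File loading helpers (TIFF/PNG slides, centroid CSVs)
# ---------------------------------------------------------------------------

def load_slide(path, pixel_size: float, slide_id: str | None = None) -> SlideImage:
    """Load a single-channel TIFF or PNG slide image."""
    import imageio.v3 as iio

    pixels = np.asarray(iio.imread(path))
    if pixels.ndim == 3:  # collapse trivial channel axes
        pixels = pixels[..., 0] if pixels.shape[-1] <= 4 else pixels[0]
    if slide_id is None:
        import os

        slide_id = os.path.splitext(os.path.basename(str(path)))[0]
    return SlideImage(pixels=pixels, pixel_size=pixel_size, slide_id=slide_id)


def load_centroids(path) -> pd.DataFrame:
    """Load a centroid table CSV with header ``cell_id,row,col``."""
    df = pd.read_csv(path)
    missing = {"cell_id", "row", "col"} - set(df.columns)
    if missing:
        raise ValueError(f"centroid CSV missing columns: {sorted(missing)}")
    return df
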