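"""Seeded generators for DAPI-like fixtures with known ground truth.

Nuclei are rendered as oriented ellipses with a controllable area, aspect
ratio, mean intensity, smooth multiplicative texture, and additive noise —
the minimal model covering the morphology axes the representation model is
supposed to capture. Screens, tissue slides with planted lymphocyte
aggregates, and morphology-linked expression profiles always come with
their ground truth (labels, shift vectors, masks, gene linkages) so every
downstream stage can be tested without external data.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .corpus import ImageCorpus, NucleusImage, SlideImage

__all__ = [
    "MorphParams",
    "SyntheticScreen",
    "generate_nucleus",
    "generate_labeled_cohort",
    "generate_perturbation_screen",
    "generate_tissue_slide",
    "generate_expression_profiles",
]

# relative amplitude of the smooth intra-nuclear texture field when enabled
_TEXTURE_AMP = 0.3


@dataclass(frozen=True)
class MorphParams:
    """Morphology of a synthetic nucleus population.

    area_px: expected foreground area in pixels.
    aspect_ratio: major/minor axis ratio, >= 1.
    mean_intensity: foreground intensity in (0, 1].
    texture_scale: correlation length (px) of the smooth intra-nuclear
        intensity field; 0 disables texture.
    noise_sd: sd of additive pixel noise.
    jitter: relative sd of per-cell variation of area and intensity.
    """

    area_px: float = 300.0
    aspect_ratio: float = 1.5
    mean_intensity: float = 0.7
    texture_scale: float = 3.0
    noise_sd: float = 0.03
    jitter: float = 0.1

    def __post_init__(self):
        if self.area_px <= 0:
            raise ValueError("area_px must be positive")
        if self.aspect_ratio < 1:
            raise ValueError("aspect_ratio must be >= 1")
        if not 0 < self.mean_intensity <= 1:
            raise ValueError("mean_intensity must be in (0, 1]")


def generate_nucleus(
    params: MorphParams, side_px: int = 56, seed: int | np.random.Generator = 0
) -> NucleusImage:
    """Render one nucleus crop: an oriented ellipse of the requested area
    and aspect ratio at a random orientation, modulated by smooth texture
    and additive noise, clipped to [0, 1]. Deterministic per seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    area = params.area_px * float(np.exp(rng.normal(0.0, params.jitter))) if params.jitter else params.area_px
    a = np.sqrt(area * params.aspect_ratio / np.pi)  # major semi-axis
    b = np.sqrt(area / (params.aspect_ratio * np.pi))
    if 2 * a > side_px:
        raise ValueError(
            f"nucleus (major axis {2 * a:.1f} px) does not fit in a {side_px} px crop"
        )
    theta = rng.uniform(0.0, np.pi)
    cy = cx = (side_px - 1) / 2.0
    yy, xx = np.mgrid[0:side_px, 0:side_px]
    y, x = yy - cy, xx - cx
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    intensity = params.mean_intensity
    if params.jitter:
        intensity = float(np.clip(intensity * np.exp(rng.normal(0.0, params.jitter)), 0.05, 1.0))
    img = np.where(mask, intensity, 0.0)
    if params.texture_scale > 0:
        tex = gaussian_filter(rng.standard_normal((side_px, side_px)), params.texture_scale)
        sd = tex.std()
        if sd > 0:
            img = img * (1.0 + _TEXTURE_AMP * tex / sd)
    img = gaussian_filter(img, 0.7)  # soften the rim, as optics would
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    return NucleusImage(pixels=np.clip(img, 0.0, 1.0).astype(np.float32))


def generate_labeled_cohort(
    class_params: dict[str, MorphParams],
    n_per_class: int,
    side_px: int = 56,
    seed: int = 0,
) -> ImageCorpus:
    """A labeled corpus with exactly ``n_per_class`` rendered nuclei per class."""
    if len(class_params) < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for cls in sorted(class_params):
        for i in range(n_per_class):
            im = generate_nucleus(class_params[cls], side_px, rng)
            im.cell_id = f"{cls}_{i}"
            im.source = "synthetic"
            images.append(im)
            labels.append(cls)
    return ImageCorpus.from_images(images, labels=pd.Series(labels, name="label"))


# ---------------------------------------------------------------------------
# Perturbation screens
# ---------------------------------------------------------------------------

@dataclass
class SyntheticScreen:
    """Ground-truth description of a synthetic perturbation screen.

    Non-planted cohorts are exchangeable with the control; planted cohorts
    have their representation mean shifted by ``shift_vectors[id]`` (in
    units of the per-axis SD, which is 1 in representation space).
    """

    cohort_ids: list[str]
    planted_significant: set[str]
    shift_vectors: dict[str, np.ndarray]
    modalities: dict[str, str] = field(default_factory=dict)
    control_params: MorphParams = field(default_factory=MorphParams)

    def __post_init__(self):
        if not self.planted_significant <= set(self.cohort_ids):
            raise ValueError("planted ids must be a subset of cohort ids")
        if set(self.shift_vectors) != self.planted_significant:
            raise ValueError("shift_vectors must cover exactly the planted ids")

    @staticmethod
    def random(
        n_groups: int,
        n_planted: int,
        shift_sd: float,
        rep_dim: int,
        seed: int = 0,
        modality_cycle: tuple[str, ...] = ("CP", "CRISPR", "ORF"),
    ) -> "SyntheticScreen":
        """A screen with ``n_planted`` groups shifted by ``shift_sd`` along
        random unit directions; modalities assigned round-robin."""
        rng = np.random.default_rng(seed)
        ids = [f"pert{i:03d}" for i in range(n_groups)]
        planted = set(rng.choice(ids, size=n_planted, replace=False).tolist())
        shifts = {}
        for g in sorted(planted):
            v = rng.standard_normal(rep_dim)
            shifts[g] = shift_sd * v / np.linalg.norm(v)
        mods = {g: modality_cycle[i % len(modality_cycle)] for i, g in enumerate(ids)}
        return SyntheticScreen(ids, planted, shifts, modalities=mods)


def generate_perturbation_screen(
    screen: SyntheticScreen,
    n_cells_per_group: int,
    rep_dim: int = 32,
    seed: int = 0,
    mode: str = "representation",
    n_control: int | None = None,
    side_px: int = 56,
):
    """Sample a screen: a control cohort plus one cohort per perturbation.

    ``mode="representation"`` returns ``(control, group_reps)`` where the
    control is N(0, I) in ``rep_dim`` dimensions, non-planted groups are
    drawn from the same distribution, and planted groups have their mean
    shifted by the screen's shift vector (per-axis SD = 1, so shifts are in
    SD units). ``mode="image"`` renders nucleus crops instead, mapping the
    shift magnitude onto nuclear area and intensity.
    """
    if n_cells_per_group < 10:
        raise ValueError("need at least 10 cells per group")
    rng = np.random.default_rng(seed)
    if mode == "representation":
        n_control = n_control or n_cells_per_group
        control = rng.standard_normal((n_control, rep_dim))
        groups = {}
        for g in screen.cohort_ids:
            x = rng.standard_normal((n_cells_per_group, rep_dim))
            if g in screen.planted_significant:
                x = x + screen.shift_vectors[g]
            groups[g] = x
        return control, groups
    if mode == "image":
        params = {"control": screen.control_params}
        base = screen.control_params
        for g in screen.cohort_ids:
            if g in screen.planted_significant:
                mag = float(np.linalg.norm(screen.shift_vectors[g]))
                params[g] = MorphParams(
                    area_px=base.area_px * (1.0 + 0.15 * mag),
                    aspect_ratio=base.aspect_ratio,
                    mean_intensity=min(1.0, base.mean_intensity * (1.0 + 0.05 * mag)),
                    texture_scale=base.texture_scale,
                    noise_sd=base.noise_sd,
                    jitter=base.jitter,
                )
            else:
                params[g] = base
        images, labels = [], []
        for g in ["control"] + screen.cohort_ids:
            for i in range(n_cells_per_group):
                im = generate_nucleus(params[g], side_px, rng)
                im.cell_id = f"{g}_{i}"
                images.append(im)
                labels.append(g)
        return ImageCorpus.from_images(images, labels=pd.Series(labels, name="group"))
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Tissue slides with planted lymphocyte aggregates
# ---------------------------------------------------------------------------

def _paint_spot(canvas: np.ndarray, r: int, c: int, radius: float, intensity: float) -> None:
    """Add a soft disk into the canvas in place."""
    R = int(np.ceil(radius * 2))
    H, W = canvas.shape
    r0, r1 = max(r - R, 0), min(r + R + 1, H)
    c0, c1 = max(c - R, 0), min(c + R + 1, W)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d2 = (yy - r) ** 2 + (xx - c) ** 2
    canvas[r0:r1, c0:c1] += intensity * np.exp(-d2 / (2.0 * (radius / 1.5) ** 2))


def generate_tissue_slide(
    slide_px: int,
    aggregates: list[tuple[tuple[int, int], float, float]],
    background_density: float = 5e-4,
    seed: int = 0,
):
    """A DAPI slide with dense lymphocyte aggregates on a sparse background.

    ``aggregates`` is a list of ((row, col) center, radius_px,
    lymphocyte_density) tuples; densities are cells per px^2. Inside each
    aggregate, small round nuclei labeled T or B (50/50) are placed
    uniformly; outside, sparser and larger nuclei labeled "other". Returns
    ``(slide, centroids, mask, markers)`` where ``mask`` marks aggregate
    pixels and ``markers`` holds rendered CD3 (T) and CD20 (B) channels.
    """
    rng = np.random.default_rng(seed)
    dapi = np.zeros((slide_px, slide_px))
    cd3 = np.zeros_like(dapi)
    cd20 = np.zeros_like(dapi)
    mask = np.zeros_like(dapi, dtype=bool)
    yy, xx = np.mgrid[0:slide_px, 0:slide_px]
    rows: list[dict] = []

    def add_cell(r: int, c: int, ctype: str):
        cid = f"cell{len(rows):05d}"
        if ctype == "other":
            radius, intensity = 4.0, 0.6
        else:
            radius, intensity = 2.5, 0.9
        _paint_spot(dapi, r, c, radius, intensity)
        if ctype == "T":
            _paint_spot(cd3, r, c, radius, 1.0)
        elif ctype == "B":
            _paint_spot(cd20, r, c, radius, 1.0)
        rows.append({"cell_id": cid, "row": r, "col": c, "cell_type": ctype})

    for (cr, cc), radius, density in aggregates:
        if not (0 <= cr < slide_px and 0 <= cc < slide_px):
            raise ValueError("aggregate center outside slide bounds")
        mask |= (yy - cr) ** 2 + (xx - cc) ** 2 <= radius**2
        n_cells = rng.poisson(density * np.pi * radius**2)
        for _ in range(n_cells):
            rho = radius * np.sqrt(rng.uniform())
            phi = rng.uniform(0, 2 * np.pi)
            r = int(np.clip(round(cr + rho * np.sin(phi)), 0, slide_px - 1))
            c = int(np.clip(round(cc + rho * np.cos(phi)), 0, slide_px - 1))
            add_cell(r, c, "T" if rng.uniform() < 0.5 else "B")

    n_bg = rng.poisson(background_density * slide_px * slide_px)
    placed = 0
    while placed < n_bg:
        r, c = rng.integers(0, slide_px, size=2)
        if mask[r, c]:
            continue
        add_cell(int(r), int(c), "other")
        placed += 1

    dapi = np.clip(dapi + rng.normal(0, 0.01, dapi.shape), 0.0, 1.0)
    slide = SlideImage(pixels=dapi.astype(np.float32), pixel_size=1.0, slide_id="synthetic_tissue")
    centroids = pd.DataFrame(rows)
    markers = {"CD3": np.clip(cd3, 0, 1).astype(np.float32),
               "CD20": np.clip(cd20, 0, 1).astype(np.float32)}
    return slide, centroids, mask, markers


# ---------------------------------------------------------------------------
# Morphology-linked expression profiles
# ---------------------------------------------------------------------------

_FEATURES = ("area", "aspect_ratio", "mean_intensity")


def generate_expression_profiles(
    corpus: ImageCorpus,
    linked_genes: dict[str, tuple[str, float]],
    n_noise_genes: int = 0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell expression: linked genes follow a morphological feature.

    Each linked gene is ``slope * z(feature) + noise`` where z() is the
    feature standardized across cells; noise genes are pure N(0, 1) noise.
    Features: area, aspect_ratio, mean_intensity (measured on each crop).
    Returns a (cells x genes) DataFrame indexed by cell_id.
    """
    from .analysis import morph_features

    for gene, (feat, _) in linked_genes.items():
        if feat not in _FEATURES:
            raise ValueError(f"unknown feature {feat!r} for gene {gene!r}; use one of {_FEATURES}")
    rng = np.random.default_rng(seed)
    feats = np.array([morph_features(self_px) for self_px in corpus.pixels])
    table = {name: feats[:, i] for i, name in enumerate(_FEATURES)}
    n = len(corpus)
    data = {}
    for gene, (feat, slope) in linked_genes.items():
        z = table[feat]
        sd = z.std()
        z = (z - z.mean()) / sd if sd > 0 else np.zeros_like(z)
        data[gene] = slope * z + rng.normal(0.0, noise_sd, n)
    for j in range(n_noise_genes):
        data[f"noise{j:04d}"] = rng.standard_normal(n)
    return pd.DataFrame(data, index=pd.Index(corpus.cell_ids, name="cell_id"))
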