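"""Slide preparation: tiling, background removal, stain and intensity normalization.

Input slides may be in-memory RGB arrays, plain or pyramidal TIFF files
(read via tifffile), or pre-tiled directories in the ``<col>_<row>.png``
layout.  Color normalization follows the Macenko percentile method; intensity
normalization is a global Z-score fitted on training tiles only.
"""

from __future__ import annotations

import json
import math
import os
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
import tifffile
from PIL import Image
from skimage.color import rgb2hsv
from skimage.transform import resize

__all__ = [
    "TileGrid",
    "StainReference",
    "ChannelStats",
    "tile_slide",
    "iter_tile_directory",
    "is_background",
    "fit_stain_reference",
    "macenko_normalize",
    "estimate_stain_matrix",
    "compute_channel_stats",
    "zscore",
    "zscore_inverse",
    "flip_augment",
    "MacenkoResult",
]

TILE_NAME_RE = re.compile(r"^(\d+)_(\d+)\.png$")


@dataclass
class TileGrid:
    """Tessellation of one slide into non-overlapping tiles.

    ``tiles`` holds ``(grid_col, grid_row, level0_x, level0_y)`` with level-0
    offsets in base-resolution pixels; ``kept_mask`` marks non-background
    tiles (parallel to ``tiles``).
    """

    slide_id: str
    tile_size_px: int = 512
    mpp: float = 0.5
    tiles: list[tuple[int, int, int, int]] = field(default_factory=list)
    kept_mask: list[bool] = field(default_factory=list)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "slide_id": self.slide_id,
                    "tile_size_px": self.tile_size_px,
                    "mpp": self.mpp,
                    "tiles": [list(t) for t in self.tiles],
                    "kept_mask": [bool(k) for k in self.kept_mask],
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "TileGrid":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            slide_id=d["slide_id"],
            tile_size_px=d["tile_size_px"],
            mpp=d["mpp"],
            tiles=[tuple(t) for t in d["tiles"]],
            kept_mask=[bool(k) for k in d["kept_mask"]],
        )


def _load_slide_levels(path: Path) -> list[np.ndarray]:
    """Read every pyramid level of a TIFF as an RGB array (finest first)."""
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        levels = [lvl.asarray() for lvl in series.levels]
    out = []
    for arr in levels:
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        out.append(arr[..., :3])
    return out


def _resample_to_mpp(img: np.ndarray, base_mpp: float, target_mpp: float) -> np.ndarray:
    """Area-average resample so the output pixel pitch equals target_mpp."""
    scale = base_mpp / target_mpp
    h = int(round(img.shape[0] * scale))
    w = int(round(img.shape[1] * scale))
    out = resize(img.astype(float) / 255.0, (h, w), order=1, anti_aliasing=scale < 1)
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def tile_slide(
    slide: np.ndarray | str | os.PathLike,
    slide_id: str | None = None,
    tile_size: int = 512,
    mpp: float = 0.5,
    base_mpp: float | None = None,
    remove_background: bool = True,
    sat_threshold: float = 0.07,
    tissue_fraction_min: float = 0.25,
) -> tuple[TileGrid, list[np.ndarray]]:
    """Tessellate a slide into non-overlapping ``tile_size`` tiles at ``mpp``.

    Accepts an RGB array (with ``base_mpp`` giving its pixel pitch), a TIFF
    path (pyramid levels are searched for one within 10% of the target mpp,
    otherwise the nearest finer level is resampled), or a pre-tiled directory.
    Partial edge tiles are discarded.  Grid coordinates are 0-based with the
    origin at the top-left; level-0 offsets are multiples of the effective
    stride.

    Returns the TileGrid (every tile, with ``kept_mask`` flagging tissue) and
    the list of kept tile images.
    """
    if isinstance(slide, (str, os.PathLike)):
        p = Path(slide)
        if not p.exists():
            raise IOError(f"slide not readable: {p}")
        if p.is_dir():
            return _tile_from_directory(p, slide_id or p.name, tile_size, mpp,
                                        remove_background, sat_threshold,
                                        tissue_fraction_min)
        levels = _load_slide_levels(p)
        if base_mpp is None:
            warnings.warn(
                f"{p.name}: no base-resolution metadata supplied; assuming "
                f"{mpp} um/pixel", stacklevel=2,
            )
            base_mpp = mpp
        img, eff_mpp, ds = _select_level(levels, base_mpp, mpp)
        slide_id = slide_id or p.stem
    else:
        img = np.asarray(slide)
        if base_mpp is None:
            warnings.warn("no base mpp supplied for array slide; assuming target",
                          stacklevel=2)
            base_mpp = mpp
        img, eff_mpp, ds = _select_level([img], base_mpp, mpp)
        if slide_id is None:
            slide_id = "slide"

    grid = TileGrid(slide_id=slide_id, tile_size_px=tile_size, mpp=eff_mpp)
    h, w = img.shape[:2]
    stride0 = int(round(tile_size * ds))  # stride in base-level pixels
    kept_tiles: list[np.ndarray] = []
    for row in range(h // tile_size):
        for col in range(w // tile_size):
            tile = img[row * tile_size:(row + 1) * tile_size,
                       col * tile_size:(col + 1) * tile_size]
            grid.tiles.append((col, row, col * stride0, row * stride0))
            keep = not (remove_background
                        and is_background(tile, sat_threshold, tissue_fraction_min))
            grid.kept_mask.append(keep)
            if keep:
                kept_tiles.append(tile)
    return grid, kept_tiles


def _select_level(levels: list[np.ndarray], base_mpp: float,
                  target_mpp: float) -> tuple[np.ndarray, float, float]:
    """Pick the pyramid level nearest the target mpp; resample if >10% off.

    Returns (image, effective mpp, downsample factor relative to level 0).
    """
    # Level mpp inferred from dimension ratio to the base level.
    base_h = levels[0].shape[0]
    mpps = [base_mpp * base_h / lvl.shape[0] for lvl in levels]
    ok = [i for i, m in enumerate(mpps)
          if abs(m - target_mpp) / target_mpp <= 0.10]
    if ok:
        i = min(ok, key=lambda j: abs(mpps[j] - target_mpp))
        return levels[i], mpps[i], mpps[i] / base_mpp
    finer = [i for i, m in enumerate(mpps) if m < target_mpp]
    if not finer:
        raise IOError(
            f"no pyramid level at or finer than {target_mpp} um/pixel "
            f"(available: {mpps})"
        )
    i = max(finer, key=lambda j: mpps[j])  # nearest finer level
    img = _resample_to_mpp(levels[i], mpps[i], target_mpp)
    return img, target_mpp, target_mpp / base_mpp


def iter_tile_directory(path: str | os.PathLike) -> Iterator[tuple[int, int, np.ndarray]]:
    """Yield ``(col, row, image)`` from a ``<col>_<row>.png`` tile directory."""
    p = Path(path)
    entries = []
    for f in p.iterdir():
        m = TILE_NAME_RE.match(f.name)
        if m:
            entries.append((int(m.group(1)), int(m.group(2)), f))
    for col, row, f in sorted(entries, key=lambda t: (t[1], t[0])):
        yield col, row, np.asarray(Image.open(f).convert("RGB"))


def _tile_from_directory(p: Path, slide_id: str, tile_size: int, mpp: float,
                         remove_background: bool, sat_threshold: float,
                         tissue_fraction_min: float) -> tuple[TileGrid, list[np.ndarray]]:
    grid = TileGrid(slide_id=slide_id, tile_size_px=tile_size, mpp=mpp)
    kept: list[np.ndarray] = []
    for col, row, img in iter_tile_directory(p):
        if img.shape[0] != tile_size or img.shape[1] != tile_size:
            raise ValueError(
                f"{slide_id}: tile {col}_{row} is {img.shape[:2]}, "
                f"expected {(tile_size, tile_size)}"
            )
        grid.tiles.append((col, row, col * tile_size, row * tile_size))
        keep = not (remove_background
                    and is_background(img, sat_threshold, tissue_fraction_min))
        grid.kept_mask.append(keep)
        if keep:
            kept.append(img)
    if not grid.tiles:
        raise IOError(f"no tiles found in {p}")
    return grid, kept


def is_background(tile: np.ndarray, sat_threshold: float = 0.07,
                  tissue_fraction_min: float = 0.25) -> bool:
    """True iff the tile's saturated-pixel fraction falls below the minimum.

    A pixel counts as tissue when its HSV saturation exceeds ``sat_threshold``;
    the tile is background when the tissue fraction is below
    ``tissue_fraction_min``.
    """
    sat = rgb2hsv(np.asarray(tile, dtype=np.uint8))[..., 1]
    return float((sat > sat_threshold).mean()) < tissue_fraction_min


# ---------------------------------------------------------------------------
# Macenko stain normalization
# ---------------------------------------------------------------------------

OD_FLOOR = 0.15        # beta: optical-density floor for pixel selection
ANGLE_PERCENTILES = (1.0, 99.0)   # alpha: robust angle extremes
CONC_PERCENTILE = 99.0


@dataclass
class StainReference:
    """Reference stain basis: 3x2 unit-norm OD directions + max concentrations."""

    stain_matrix: np.ndarray       # columns: hematoxylin, eosin
    max_concentrations: np.ndarray  # 99th-percentile concentration per stain

    def __post_init__(self):
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=float)
        self.max_concentrations = np.asarray(self.max_concentrations, dtype=float)
        norms = np.linalg.norm(self.stain_matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain_matrix columns must be unit-norm")
        if (self.stain_matrix < -1e-9).any():
            raise ValueError("stain_matrix entries must be non-negative")


class MacenkoResult(NamedTuple):
    image: np.ndarray
    degenerate: bool


def _optical_density(tile: np.ndarray) -> np.ndarray:
    rgb = np.asarray(tile, dtype=float)
    return -np.log(np.maximum(rgb, 1.0) / 255.0)


def estimate_stain_matrix(tile: np.ndarray,
                          od_floor: float = OD_FLOOR,
                          angle_percentiles: tuple[float, float] = ANGLE_PERCENTILES,
                          ) -> np.ndarray | None:
    """Estimate the 3x2 H/E stain-direction matrix of one tile (Macenko).

    Returns None when fewer than 100 pixels clear the OD floor (degenerate).
    """
    od = _optical_density(tile).reshape(-1, 3)
    od = od[(od > od_floor).any(axis=1)]
    if od.shape[0] < 100:
        return None
    cov = np.cov(od, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    basis = evecs[:, [2, 1]]  # top-2 eigenvectors (eigh is ascending)
    # Orient the basis so projections are positive on the first axis.
    proj = od @ basis
    if proj[:, 0].sum() < 0:
        basis[:, 0] *= -1
        proj[:, 0] *= -1
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(angles, angle_percentiles)
    v1 = basis @ np.array([math.cos(lo), math.sin(lo)])
    v2 = basis @ np.array([math.cos(hi), math.sin(hi)])
    v1 = np.abs(v1) / np.linalg.norm(v1)
    v2 = np.abs(v2) / np.linalg.norm(v2)
    # Hematoxylin has the larger blue-channel OD component.
    if v1[2] >= v2[2]:
        he = np.column_stack([v1, v2])
    else:
        he = np.column_stack([v2, v1])
    return he


def _concentrations(od_flat: np.ndarray, stain_matrix: np.ndarray) -> np.ndarray:
    c, *_ = np.linalg.lstsq(stain_matrix, od_flat.T, rcond=None)
    return np.maximum(c, 0.0)  # (2, n_pixels)


def fit_stain_reference(tiles: list[np.ndarray]) -> StainReference:
    """Fit the reference stain basis on a sample of tissue tiles."""
    ods = []
    mats = []
    for t in tiles:
        m = estimate_stain_matrix(t)
        if m is not None:
            mats.append(m)
            od = _optical_density(t).reshape(-1, 3)
            ods.append(od[(od > OD_FLOOR).any(axis=1)])
    if not mats:
        raise ValueError("no reference tile yields a non-degenerate stain estimate")
    # Average directions across tiles, renormalized.
    m = np.mean(mats, axis=0)
    m = m / np.linalg.norm(m, axis=0, keepdims=True)
    conc = _concentrations(np.vstack(ods), m)
    max_c = np.percentile(conc, CONC_PERCENTILE, axis=1)
    return StainReference(stain_matrix=m, max_concentrations=max_c)


def macenko_normalize(tile: np.ndarray, reference: StainReference) -> MacenkoResult:
    """Map a tile onto the reference stain basis and concentration scale.

    Degenerate tiles (fewer than 100 pixels above the OD floor, e.g. pure
    white) are returned unchanged with ``degenerate=True``.
    """
    tile = np.asarray(tile, dtype=np.uint8)
    m = estimate_stain_matrix(tile)
    if m is None:
        return MacenkoResult(tile.copy(), True)
    od_flat = _optical_density(tile).reshape(-1, 3)
    conc = _concentrations(od_flat, m)
    max_c = np.percentile(conc, CONC_PERCENTILE, axis=1)
    scale = np.divide(reference.max_concentrations, max_c,
                      out=np.ones(2), where=max_c > 1e-8)
    od_norm = (reference.stain_matrix @ (conc * scale[:, None])).T
    rgb = 255.0 * np.exp(-od_norm.reshape(tile.shape))
    return MacenkoResult(np.clip(np.rint(rgb), 0, 255).astype(np.uint8), False)


# ---------------------------------------------------------------------------
# Intensity normalization and augmentation
# ---------------------------------------------------------------------------

_CHANNELS = ("R", "G", "B")


@dataclass(frozen=True)
class ChannelStats:
    """Per-RGB-channel mean/std over the training tile population."""

    mean: np.ndarray
    std: np.ndarray


def compute_channel_stats(tiles: list[np.ndarray]) -> ChannelStats:
    """Pixel-wise per-channel mean and std over training tiles only."""
    if not tiles:
        raise ValueError("need at least one training tile")
    stack = np.concatenate([np.asarray(t, dtype=float).reshape(-1, 3)
                            for t in tiles], axis=0)
    mean = stack.mean(axis=0)
    std = stack.std(axis=0)
    for i, s in enumerate(std):
        if s <= 0:
            raise ValueError(f"zero-variance channel: {_CHANNELS[i]}")
    return ChannelStats(mean=mean, std=std)


def zscore(tile: np.ndarray, stats: ChannelStats) -> np.ndarray:
    """Standardize a tile with (training-set) channel statistics."""
    return (np.asarray(tile, dtype=float) - stats.mean) / stats.std


def zscore_inverse(tile: np.ndarray, stats: ChannelStats) -> np.ndarray:
    return np.asarray(tile, dtype=float) * stats.std + stats.mean


def flip_augment(tile: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random horizontal and vertical flips, each with probability 1/2.

    Training-time augmentation only; prediction uses normalization alone.
    """
    out = np.asarray(tile)
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[::-1, :]
    return out
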