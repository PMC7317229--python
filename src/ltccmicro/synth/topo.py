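"""Synthetic cell-surface topography maps.

Emulates a 10 x 10 µm scanning ion conductance microscopy (SICM) scan of
the cardiomyocyte surface: parallel Z-grooves at the sarcomere spacing,
of which only a controllable fraction is present (degraded surfaces lose
groove segments), and circular T-tubule openings sitting on groove lines
as deep depressions ("dark circles").  Ground truth (groove mask, kept
segment fraction, opening centers) is retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["TopoGenConfig", "TopographyMap", "gen_topography_map"]


@dataclass(frozen=True)
class TopoGenConfig:
    shape: tuple[int, int] = (256, 256)
    pixel_size: float = 10.0 / 256.0  # µm; default scan 10 x 10 µm
    groove_spacing: float = 1.9  # µm between Z-grooves (rows)
    groove_completeness: float = 1.0  # fraction of groove length present
    n_openings: int = 0
    groove_depth: float = 150.0  # nm
    opening_depth: float = 400.0  # nm
    opening_diameter: float = 0.7  # µm
    groove_width: float = 0.25  # µm
    noise_sd: float = 0.0  # nm
    segment_length: float = 1.0  # µm; granularity of groove loss
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.groove_completeness <= 1.0:
            raise ValueError("groove_completeness must be in [0, 1]")
        if self.n_openings < 0:
            raise ValueError("n_openings must be >= 0")
        if self.n_openings > 0 and self.groove_completeness == 0.0:
            raise ValueError("openings lie on grooves: completeness 0 admits no openings")
        if self.pixel_size <= 0 or self.groove_spacing <= 0:
            raise ValueError("pixel_size and groove_spacing must be positive")


@dataclass
class TopographyMap:
    """A surface height map in nm with physical pixel size in µm."""

    height: np.ndarray
    pixel_size: float
    truth_groove_mask: np.ndarray | None = None
    truth_kept_fraction: float | None = None
    truth_opening_centers: np.ndarray | None = None  # (n, 2) row, col
    config: TopoGenConfig | None = None

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(path, self.height.astype(np.float32),
                         metadata={"pixel_size_um": self.pixel_size, "units": "nm"})

    @classmethod
    def from_tiff(cls, path: str | Path, pixel_size: float) -> "TopographyMap":
        return cls(height=tifffile.imread(path).astype(np.float64), pixel_size=pixel_size)


def gen_topography_map(config: TopoGenConfig) -> TopographyMap:
    """Generate a synthetic SICM-like height map.

    Grooves run along the columns at rows spaced by ``groove_spacing``.
    Each groove is divided into ``segment_length`` pieces; a global
    random subset of segments totalling ``groove_completeness`` of the
    full groove length is kept.  ``n_openings`` circular depressions are
    centred on kept groove pixels with a minimum mutual separation.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.shape
    height = np.zeros((rows, cols))
    spacing_px = config.groove_spacing / config.pixel_size
    half_w = max(int(round(config.groove_width / config.pixel_size / 2)), 1)
    seg_px = max(int(round(config.segment_length / config.pixel_size)), 1)

    groove_rows = np.round(np.arange(spacing_px / 2.0, rows, spacing_px)).astype(int)
    groove_rows = groove_rows[groove_rows < rows]

    # enumerate (groove, segment) pieces and keep a random subset
    segments = [(r, c0, min(c0 + seg_px, cols))
                for r in groove_rows for c0 in range(0, cols, seg_px)]
    n_keep = int(round(config.groove_completeness * len(segments)))
    keep_idx = rng.permutation(len(segments))[:n_keep]
    mask = np.zeros((rows, cols), dtype=bool)
    for i in keep_idx:
        r, c0, c1 = segments[i]
        mask[max(r - half_w, 0):r + half_w + 1, c0:c1] = True
    height[mask] = -config.groove_depth

    kept_fraction = n_keep / len(segments) if segments else 0.0

    centers: list[tuple[int, int]] = []
    if config.n_openings > 0:
        rad_px = config.opening_diameter / config.pixel_size / 2.0
        min_sep = 3.0 * rad_px
        candidates = np.argwhere(mask[:, half_w * 2:cols - half_w * 2])
        candidates[:, 1] += half_w * 2
        order = rng.permutation(len(candidates))
        for i in order:
            r, c = candidates[i]
            if rad_px <= r < rows - rad_px and all(
                (r - rr) ** 2 + (c - cc) ** 2 >= min_sep**2 for rr, cc in centers
            ):
                centers.append((int(r), int(c)))
            if len(centers) == config.n_openings:
                break
        if len(centers) < config.n_openings:
            raise ValueError("could not place the requested openings on groove lines")
        yy, xx = np.mgrid[0:rows, 0:cols]
        for r, c in centers:
            d2 = (yy - r) ** 2 + (xx - c) ** 2
            bowl = -config.opening_depth * np.exp(-d2 / (2.0 * (rad_px / 1.5) ** 2))
            height = np.minimum(height, bowl)

    if config.noise_sd > 0:
        height = height + rng.normal(0.0, config.noise_sd, size=height.shape)

    return TopographyMap(
        height=height,
        pixel_size=config.pixel_size,
        truth_groove_mask=mask,
        truth_kept_fraction=float(kept_fraction),
        truth_opening_centers=np.array(centers, dtype=int).reshape(-1, 2),
        config=config,
    )
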