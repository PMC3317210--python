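"""Synthetic cryo-image phantoms with known ground truth.

Emulates block-face fluorescence phantoms of point-like sources: 10–15 µm
fluorescent microspheres or quantum-dot-labelled cells imaged at 8.8–15.6 µm
in-plane pixels and 40 µm sections, so each source spans roughly one pixel
and is rendered as a pixel-integrated 2D Gaussian.  Clusters of 1–5+
overlapping sources are placed on a separated grid; the red channel carries
the label signal (sources have I_R/I_G ≈ 8) over a smooth green-dominant
autofluorescent background (I_R/I_G ≈ 0.4); subsurface fluorescence bleeds
into shallower sections as a blurred, attenuated copy; and sectioned cells
split their intensity between two adjacent slices.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from scipy.special import erf

from .stack import ImageStack

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "PlacementError",
    "render_cell",
    "generate_phantom",
    "generate_culture_image",
]

_SQRT2 = np.sqrt(2.0)


class PlacementError(RuntimeError):
    """Raised when the requested clusters cannot be placed in the volume."""


@dataclass
class PhantomConfig:
    """Generator settings; defaults emulate a quantum-dot-cell phantom.

    ``intensity_cv`` is the fractional SD of per-cell total intensity:
    0.05 for microspheres (size/intensity varies by <5%), 0.15 for labelled
    cells.  ``bleed_fraction`` is the subsurface intensity fraction visible
    in the slice above a source (≈0.15–0.20).  Intensities are arbitrary
    digital numbers.
    """

    image_shape: tuple[int, int, int] = (10, 256, 256)
    pixel_size_um: float = 15.6
    section_um: float = 40.0
    n_clusters: int = 200
    cluster_size_pmf: dict[int, float] = field(
        default_factory=lambda: {1: 0.40, 2: 0.22, 3: 0.16, 4: 0.12, 5: 0.10})
    sigma_px: float = 1.0
    intensity_mean: float = 1000.0
    intensity_cv: float = 0.15
    min_sep_px: float = 0.8
    cell_diameter_um: float = 12.5
    background_level: float = 35.0
    background_rg_ratio: float = 0.4
    cell_rg_ratio: float = 8.0
    bleed_fraction: float = 0.17
    bleed_blur_px: float = 2.0
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_px <= 0:
            raise ValueError("sigma_px must be positive")
        if self.intensity_cv < 0:
            raise ValueError("intensity_cv must be non-negative")
        if not 0.0 <= self.bleed_fraction < 1.0:
            raise ValueError("bleed_fraction must be in [0, 1)")
        total = float(sum(self.cluster_size_pmf.values()))
        if not np.isclose(total, 1.0):
            raise ValueError("cluster_size_pmf must sum to 1")
        if any(int(k) < 1 for k in self.cluster_size_pmf):
            raise ValueError("cluster sizes must be integers >= 1")
        if min(self.image_shape) < 1:
            raise ValueError("image_shape entries must be positive")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["image_shape"] = list(self.image_shape)
        data["cluster_size_pmf"] = {int(k): float(v)
                                    for k, v in self.cluster_size_pmf.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PhantomConfig":
        data = dict(data)
        if "image_shape" in data:
            data["image_shape"] = tuple(int(v) for v in data["image_shape"])
        if "cluster_size_pmf" in data:
            data["cluster_size_pmf"] = {int(k): float(v) for k, v in
                                        data["cluster_size_pmf"].items()}
        return cls(**data)


@dataclass
class GroundTruth:
    """Per-cell and per-cluster truth records for a generated phantom.

    ``cells`` columns: cluster_id, cell_id, x, y, slice, z_frac, intensity
    (z_frac = fraction of the cell's intensity in slice+1).
    ``clusters`` columns: cluster_id, n_cells, z0, z1, y0, y1, x0, x1.
    """

    cells: pd.DataFrame
    clusters: pd.DataFrame

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def total_cells(self) -> int:
        return int(self.clusters["n_cells"].sum()) if len(self.clusters) else 0

    def save(self, directory: str | Path, prefix: str = "stack") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(directory / f"{prefix}_truth.csv", index=False)
        self.clusters.to_csv(directory / f"{prefix}_truth_clusters.csv",
                             index=False)

    @classmethod
    def load(cls, directory: str | Path, prefix: str = "stack") -> "GroundTruth":
        directory = Path(directory)
        cells = pd.read_csv(directory / f"{prefix}_truth.csv")
        clusters = pd.read_csv(directory / f"{prefix}_truth_clusters.csv")
        return cls(cells, clusters)


def _pixel_profile(center: float, n: int, sigma: float) -> np.ndarray:
    """Integral of a unit 1D Gaussian over each of n unit pixels."""
    edges = np.arange(n + 1) - 0.5
    cdf = 0.5 * (1.0 + erf((edges - center) / (sigma * _SQRT2)))
    return np.diff(cdf)


def render_cell(x_c: float, y_c: float, I_t: float, sigma_px: float,
                patch_shape: tuple[int, int]) -> np.ndarray:
    """Render one point source as a pixel-integrated isotropic 2D Gaussian.

    Each pixel value is the exact integral of the Gaussian over that pixel's
    unit square (error-function product), so the sum over an unbounded patch
    equals ``I_t`` for any sub-pixel placement — pixelation redistributes
    intensity between pixels but conserves the integral.

    Parameters
    ----------
    x_c, y_c : float
        Sub-pixel centre, x along columns and y along rows.
    I_t : float
        Total (integrated) intensity.
    sigma_px : float
        Gaussian width in pixels.
    patch_shape : (rows, cols)
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    if I_t <= 0:
        raise ValueError("I_t must be positive")
    rows, cols = patch_shape
    fy = _pixel_profile(y_c, rows, sigma_px)
    fx = _pixel_profile(x_c, cols, sigma_px)
    return I_t * np.outer(fy, fx)


def _add_cell(image: np.ndarray, x: float, y: float, amp: float,
              sigma: float) -> None:
    """Accumulate a rendered cell into a full-slice image (in place)."""
    if amp <= 0:
        return
    rows, cols = image.shape
    half = int(np.ceil(5.0 * sigma + 1.0))
    r0 = max(0, int(np.floor(y)) - half)
    r1 = min(rows, int(np.floor(y)) + half + 1)
    c0 = max(0, int(np.floor(x)) - half)
    c1 = min(cols, int(np.floor(x)) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    image[r0:r1, c0:c1] += render_cell(x - c0, y - r0, amp, sigma,
                                       (r1 - r0, c1 - c0))


def _sample_z_split(rng: np.random.Generator, cfg: PhantomConfig) -> float:
    """Fraction of a cell's volume sectioned into the next (deeper) slice.

    The cell centre sits at a uniform depth within its 40 µm section; when
    the spherical cell pokes through the bottom face, the spherical-cap
    volume fraction beyond the face ends up in the next section.  With
    diameter d and section thickness T this gives P(split) = (d/2)/T and
    split fractions in (0, 0.5).
    """
    r = cfg.cell_diameter_um / 2.0
    depth_below = cfg.section_um - rng.uniform(0.0, cfg.section_um)
    h = r - depth_below  # penetration depth into the next section
    if h <= 0:
        return 0.0
    return float(h * h * (3 * r - h) / (4 * r ** 3))


def _place_cluster_cells(rng: np.random.Generator, n: int, cx: float,
                         cy: float, min_sep: float) -> np.ndarray:
    """Place n cell centres near (cx, cy), pairwise >= min_sep apart.

    The first cell sits at the cluster seed; each later cell is dropped a
    touching-distance away from a random existing cell, so the cluster
    stays a single connected blob of mutually overlapping sources.
    """
    pts = [np.array([cx, cy])]
    max_radius = 3.0 * min_sep + 2.0
    for _ in range(1, n):
        for _attempt in range(200):
            anchor = pts[rng.integers(len(pts))]
            ang = rng.uniform(0.0, 2.0 * np.pi)
            dist = rng.uniform(min_sep, 1.6 * min_sep)
            cand = anchor + dist * np.array([np.cos(ang), np.sin(ang)])
            if np.hypot(cand[0] - cx, cand[1] - cy) > max_radius:
                continue
            if all(np.hypot(*(cand - p)) >= min_sep for p in pts):
                pts.append(cand)
                break
        else:
            raise PlacementError(
                f"could not place {n} cells with min_sep={min_sep}")
    return np.array(pts)


def generate_phantom(config: PhantomConfig) -> tuple[ImageStack, GroundTruth]:
    """Generate a two-channel phantom stack plus its ground truth.

    Clusters are assigned to distinct cells of a coarse grid (with random
    jitter) so that cluster bounding boxes stay separated by at least a
    3-sigma margin; raises :class:`PlacementError` when ``n_clusters``
    exceeds the number of grid sites.  Deterministic for a fixed seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_slices, rows, cols = cfg.image_shape

    cluster_radius = 3.0 * cfg.min_sep_px + 2.0 + 3.0 * cfg.sigma_px
    site = int(np.ceil(2.0 * cluster_radius + 3.0 * cfg.sigma_px + 2.0))
    n_sites_r, n_sites_c = rows // site, cols // site
    n_sites = n_sites_r * n_sites_c
    if cfg.n_clusters > n_sites:
        raise PlacementError(
            f"{cfg.n_clusters} clusters do not fit: only {n_sites} "
            f"separated sites of {site} px in a {rows}x{cols} image")

    sizes = np.array(sorted(cfg.cluster_size_pmf), dtype=int)
    probs = np.array([cfg.cluster_size_pmf[int(s)] for s in sizes])
    probs = probs / probs.sum()

    chosen_sites = rng.permutation(n_sites)[:cfg.n_clusters]

    signal_r = np.zeros(cfg.image_shape)
    cell_rows: list[dict] = []
    cluster_rows: list[dict] = []
    cell_id = 0
    for cid, s in enumerate(chosen_sites):
        sr, sc = divmod(int(s), n_sites_c)
        cy = sr * site + site / 2.0 + rng.uniform(-1.0, 1.0)
        cx = sc * site + site / 2.0 + rng.uniform(-1.0, 1.0)
        n_cells = int(rng.choice(sizes, p=probs))
        pts = _place_cluster_cells(rng, n_cells, cx, cy, cfg.min_sep_px)
        home = int(rng.integers(n_slices))
        z_lo, z_hi = home, home
        for (x, y) in pts:
            intensity = cfg.intensity_mean * (
                1.0 + cfg.intensity_cv * rng.standard_normal())
            intensity = max(intensity, 0.1 * cfg.intensity_mean)
            z_frac = 0.0
            if home < n_slices - 1:
                z_frac = _sample_z_split(rng, cfg)
            _add_cell(signal_r[home], x, y, (1.0 - z_frac) * intensity,
                      cfg.sigma_px)
            if z_frac > 0.0:
                _add_cell(signal_r[home + 1], x, y, z_frac * intensity,
                          cfg.sigma_px)
                z_hi = max(z_hi, home + 1)
            cell_rows.append(dict(cluster_id=cid, cell_id=cell_id,
                                  x=float(x), y=float(y), slice=home,
                                  z_frac=float(z_frac),
                                  intensity=float(intensity)))
            cell_id += 1
        pad = 3.0 * cfg.sigma_px
        cluster_rows.append(dict(
            cluster_id=cid, n_cells=n_cells, z0=z_lo, z1=z_hi,
            y0=float(pts[:, 1].min() - pad), y1=float(pts[:, 1].max() + pad),
            x0=float(pts[:, 0].min() - pad), x1=float(pts[:, 0].max() + pad)))

    signal_g = signal_r / cfg.cell_rg_ratio

    # Subsurface fluorescence: each imaged block face sees a blurred,
    # attenuated copy of everything still below it, built recursively from
    # the deepest section upward.
    if cfg.bleed_fraction > 0.0 and n_slices > 1:
        for chan in (signal_r, signal_g):
            for k in range(n_slices - 2, -1, -1):
                chan[k] += cfg.bleed_fraction * gaussian_filter(
                    chan[k + 1], cfg.bleed_blur_px)

    # Smooth autofluorescent background, spectrally green-dominant with a
    # uniform R/G ratio; same spatial field in both channels.
    if cfg.background_level > 0.0:
        field_ = gaussian_filter(
            rng.standard_normal(cfg.image_shape), (0, 16.0, 16.0))
        sd = field_.std()
        if sd > 0:
            field_ = 1.0 + 0.15 * field_ / sd
        else:  # pragma: no cover - degenerate tiny images
            field_ = np.ones(cfg.image_shape)
        field_ = np.clip(field_, 0.2, None) * cfg.background_level
        signal_g += field_
        signal_r += cfg.background_rg_ratio * field_

    if cfg.noise_sd > 0.0:
        signal_r = signal_r + rng.normal(0.0, cfg.noise_sd, cfg.image_shape)
        signal_g = signal_g + rng.normal(0.0, cfg.noise_sd, cfg.image_shape)
    signal_r = np.clip(signal_r, 0.0, None)
    signal_g = np.clip(signal_g, 0.0, None)

    cells = pd.DataFrame(
        cell_rows, columns=["cluster_id", "cell_id", "x", "y", "slice",
                            "z_frac", "intensity"])
    clusters = pd.DataFrame(
        cluster_rows, columns=["cluster_id", "n_cells", "z0", "z1",
                               "y0", "y1", "x0", "x1"])
    stack = ImageStack(signal_r, signal_g, cfg.pixel_size_um, cfg.section_um)
    return stack, GroundTruth(cells, clusters)


def generate_culture_image(config: PhantomConfig,
                           n_cells: int | None = None
                           ) -> tuple[ImageStack, GroundTruth]:
    """Single-slice image of well-separated single cells in culture.

    Mirrors the dish image used to pick the high hysteresis threshold:
    singleton clusters only, no sectioning splits and no subsurface
    bleed-through, but the same cell model, background and noise as the
    tissue phantom.
    """
    cfg = dataclasses.replace(
        config,
        image_shape=(1, config.image_shape[1], config.image_shape[2]),
        n_clusters=config.n_clusters if n_cells is None else n_cells,
        cluster_size_pmf={1: 1.0},
        bleed_fraction=0.0,
    )
    return generate_phantom(cfg)
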