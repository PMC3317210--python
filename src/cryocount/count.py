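"""Model-based enumeration of cells per cluster.

At cryo-imaging resolution a cell spans about one pixel, so cluster
boundaries carry no shape information; counting instead exploits the fixed
size and intensity of labelled cells.  A single-cell template (Gaussian
width sigma, total intensity I_t) is calibrated by least-squares fits to
singleton clusters — clusters confined to a single section whose volume and
integrated intensity sit under the dominant histogram peak.  For each
detected cluster the initial estimate ``N_i = integral(C_i) / I_t`` seeds a
candidate range ``N_i ± max(2, N_i * 0.30)``; for every candidate n the
optimal placement of n template cells (free sub-pixel centres x_c, y_c and
a sectioning split z_c apportioning I_t to the adjacent slice) minimises
the least-squares objective

    F_obj = sum_m (I_Gray - sum_n I_gauss)^2

over a patch two pixels larger than the thresholded cluster, subject to
pairwise centre separations >= D_min (about one cell diameter).  The n with
minimal F_obj is the cell count; when the two best objectives differ by
less than 20 % the result is flagged ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import least_squares, minimize
from scipy.stats import gaussian_kde

from .detect import Cluster
from .phantom import render_cell

__all__ = [
    "CellModel",
    "CellPlacement",
    "CandidateFit",
    "CountResult",
    "CalibrationError",
    "select_singletons",
    "singleton_ranges",
    "fit_single_cell",
    "calibrate_model",
    "initial_estimate",
    "candidate_range",
    "fit_n_cells",
    "count_cluster",
    "count_clusters",
    "extract_patch",
]

AMBIGUITY_THRESHOLD = 0.20     # relative F_obj gap flagged as ambiguous
MAX_ITERATIONS = 10_000        # optimizer iteration cap per candidate
RELATIVE_F_TOL = 1e-6          # relative objective-change convergence


class CalibrationError(RuntimeError):
    """Raised when no usable singleton clusters are available."""


@dataclass
class CellModel:
    """Calibrated single-cell template."""

    sigma: float       # Gaussian width, pixels
    intensity: float   # I_t, total intensity, digital units
    d_min: float       # minimum centre separation, pixels (~ cell diameter)

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.intensity <= 0 or self.d_min <= 0:
            raise ValueError("sigma, intensity and d_min must be positive")


@dataclass
class CellPlacement:
    """One template cell inside a cluster fit."""

    x_c: float
    y_c: float
    home_slice: int   # patch-local slice index holding (1 - z_c) of I_t
    z_c: float = 0.0  # fraction of I_t in home_slice + 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.z_c <= 1.0:
            raise ValueError("z_c must lie in [0, 1]")


@dataclass
class CandidateFit:
    n: int
    placements: list[CellPlacement]
    f_obj: float
    converged: bool
    n_iterations: int = 0


@dataclass
class CountResult:
    cluster_id: int
    n_init: int
    candidates: list[CandidateFit]
    chosen_n: int | None
    ambiguous: bool = False
    counted: bool = True

    @property
    def best(self) -> CandidateFit | None:
        conv = [c for c in self.candidates if c.converged]
        if not conv:
            return None
        return min(conv, key=lambda c: (c.f_obj, c.n))


# ---------------------------------------------------------------------------
# Single-cell calibration
# ---------------------------------------------------------------------------

def select_singletons(clusters: Sequence[Cluster],
                      volume_range: tuple[float, float],
                      intensity_range: tuple[float, float]
                      ) -> list[Cluster]:
    """Clusters assumed to be single cells.

    Only clusters contained within a single 2D section qualify (a 10–15 µm
    cell is 3–4x smaller than a 40 µm section, so nearly all single cells
    are unsectioned); their volume and integrated intensity must also fall
    inside the given ranges, chosen around the dominant histogram peaks.
    """
    if not clusters:
        raise CalibrationError("no clusters to select singletons from")
    v_lo, v_hi = volume_range
    i_lo, i_hi = intensity_range
    out = [cl for cl in clusters
           if cl.slice_span == 1
           and v_lo <= cl.volume <= v_hi
           and i_lo <= cl.integrated_intensity <= i_hi]
    if not out:
        raise CalibrationError("no singleton clusters in the given ranges")
    return out


def singleton_ranges(clusters: Sequence[Cluster], n_sd: float = 2.5
                     ) -> tuple[tuple[float, float], tuple[float, float]]:
    """Volume and intensity ranges around the single-cell histogram peak.

    The dominant intensity-histogram peak of a sparsely labelled specimen
    corresponds to single cells.  The peak is located on the single-slice
    clusters, the spread around it estimated robustly (median absolute
    deviation of the clusters within ±30 % of the peak), and the band set
    to ``peak ± n_sd * spread`` — wide enough for the cell-to-cell
    intensity variation yet below the two-cell peak at ~2x.
    """
    single_slice = [cl for cl in clusters if cl.slice_span == 1]
    if not single_slice:
        raise CalibrationError("no single-slice clusters for calibration")
    intens = np.array([cl.integrated_intensity for cl in single_slice])
    if intens.size >= 5 and np.ptp(intens) > 0:
        # Smoothed histogram mode: single cells are the largest class, so
        # the density peak marks the single-cell intensity.  The kernel
        # bandwidth is set to ~10 % of the typical cluster intensity —
        # narrow enough to keep the 1-cell and 2-cell peaks (spaced by one
        # cell intensity) distinct, unlike a global-variance rule which
        # oversmooths multi-class mixtures.
        std = float(intens.std(ddof=1))
        bw = 0.1 * float(np.median(intens))
        kde = gaussian_kde(intens, bw_method=bw / std if std > 0 else None)
        grid = np.linspace(intens.min(), intens.max(), 512)
        peak = float(grid[np.argmax(kde(grid))])
    else:
        peak = float(np.median(intens))
    near = intens[(intens > 0.7 * peak) & (intens < 1.3 * peak)]
    center = float(np.median(near)) if near.size else float(peak)
    mad = float(np.median(np.abs(near - center))) if near.size else 0.0
    spread = max(1.4826 * mad, 0.02 * center)
    i_lo = max(0.0, center - n_sd * spread)
    i_hi = min(center + n_sd * spread, 1.45 * center)
    in_band = [cl for cl in single_slice
               if i_lo <= cl.integrated_intensity <= i_hi]
    vols = np.array([cl.volume for cl in in_band]) if in_band else np.array([1])
    v_lo = max(1.0, np.percentile(vols, 1) - 2)
    v_hi = np.percentile(vols, 99) + 2
    return (float(v_lo), float(v_hi)), (float(i_lo), float(i_hi))


def fit_single_cell(patch: np.ndarray,
                    init: tuple[float, float, float, float] | None = None
                    ) -> tuple[float, float, float, float, float, bool]:
    """Least-squares fit of one pixel-integrated Gaussian to a 2D patch.

    Returns ``(sigma, I_t, x_c, y_c, residual, converged)``.  Initialised
    from image moments unless ``init = (sigma, I_t, x_c, y_c)`` is given;
    solved with a trust-region least-squares (Levenberg-Marquardt-type)
    optimizer.
    """
    patch = np.asarray(patch, dtype=float)
    rows, cols = patch.shape
    total = float(patch.sum())
    if init is None:
        if total <= 0:
            return (np.nan, np.nan, np.nan, np.nan, np.inf, False)
        yy, xx = np.mgrid[0:rows, 0:cols]
        y0 = float((yy * patch).sum() / total)
        x0 = float((xx * patch).sum() / total)
        var = ((yy - y0) ** 2 + (xx - x0) ** 2) * patch
        sig0 = float(np.sqrt(max(var.sum() / total / 2.0, 0.09)))
        init = (sig0, total, x0, y0)

    def residuals(p: np.ndarray) -> np.ndarray:
        sig, it, xc, yc = p
        model = render_cell(xc, yc, it, sig, patch.shape)
        return (model - patch).ravel()

    lo = [0.1, 1e-6, -2.0, -2.0]
    hi = [max(rows, cols), np.inf, cols + 1.0, rows + 1.0]
    x0 = np.clip(np.asarray(init, dtype=float), lo, hi)
    sol = least_squares(residuals, x0, bounds=(lo, hi), xtol=1e-10,
                        ftol=1e-10, max_nfev=2000)
    sig, it, xc, yc = sol.x
    resid = float(2.0 * sol.cost)
    return (float(sig), float(it), float(xc), float(yc), resid,
            bool(sol.success))


def _fit_single_cell_split(patch_home: np.ndarray,
                           patch_next: np.ndarray | None
                           ) -> tuple[float, float, bool]:
    """Fit one cell allowing a sectioning split into the next slice.

    The home slice holds ``(1 - z) I_t`` of a pixel-integrated Gaussian
    and the next slice ``z I_t`` at the same centre, so a sectioned
    singleton's full intensity is recovered even when its subsurface part
    fell below the detection threshold.  Returns ``(sigma, I_t,
    converged)``; with no next slice this reduces to the plain 2D fit.
    """
    sig0, it0, x0, y0, _, ok0 = fit_single_cell(patch_home)
    if patch_next is None:
        return sig0, it0, ok0
    if not (ok0 and np.isfinite(sig0)):
        return sig0, it0, False
    nxt = float(np.clip(patch_next, 0.0, None).sum())
    z0 = float(np.clip(nxt / (nxt + max(it0, 1e-9)), 0.0, 0.45))

    def residuals(p: np.ndarray) -> np.ndarray:
        sig, it, xc, yc, z = p
        cell = render_cell(xc, yc, it, sig, patch_home.shape)
        return np.concatenate([
            ((1.0 - z) * cell - patch_home).ravel(),
            (z * cell - patch_next).ravel()])

    rows, cols = patch_home.shape
    lo = [0.1, 1e-6, -2.0, -2.0, 0.0]
    hi = [max(rows, cols), np.inf, cols + 1.0, rows + 1.0, 1.0]
    start = np.clip([sig0, it0 / max(1.0 - z0, 0.5), x0, y0, z0], lo, hi)
    sol = least_squares(residuals, start, bounds=(lo, hi), xtol=1e-10,
                        ftol=1e-10, max_nfev=2000)
    sig, it = float(sol.x[0]), float(sol.x[1])
    return sig, it, bool(sol.success)


def calibrate_model(singletons: Sequence[Cluster], igray: np.ndarray,
                    d_min: float, pad: int = 2) -> CellModel:
    """Average single-cell fits into the cluster-counting template.

    Each singleton is fit on its bounding-box patch (padded by ``pad``
    pixels) together with the same window of the next slice, so cells
    sectioned across two slices contribute their full intensity;
    non-converged fits are excluded, and the template sigma and I_t are
    the arithmetic means of the remaining fits.  ``d_min`` (the
    approximate cell diameter, pixels) comes from configuration.
    """
    igray = np.asarray(igray, dtype=float)
    if igray.ndim == 2:
        igray = igray[None]
    sigmas, intensities = [], []
    for cl in singletons:
        z0, _, y0, y1, x0, x1 = cl.bbox
        patch, (r0, c0) = _patch_2d(igray[z0], (y0, y1, x0, x1), pad)
        patch_next = None
        if z0 + 1 < igray.shape[0]:
            patch_next = igray[z0 + 1, r0:r0 + patch.shape[0],
                               c0:c0 + patch.shape[1]]
        sig, it, ok = _fit_single_cell_split(patch, patch_next)
        if ok and np.isfinite(sig) and np.isfinite(it):
            sigmas.append(sig)
            intensities.append(it)
    if not sigmas:
        raise CalibrationError("all single-cell fits failed")
    return CellModel(sigma=float(np.mean(sigmas)),
                     intensity=float(np.mean(intensities)), d_min=d_min)


# ---------------------------------------------------------------------------
# Per-cluster counting
# ---------------------------------------------------------------------------

def initial_estimate(cluster_intensity: float, model: CellModel) -> int:
    """Initial cell-count guess ``N_i = integral(C_i) / I_t``, rounded to
    the nearest integer (half up) and floored at 1."""
    if model.intensity <= 0:
        raise ValueError("model intensity must be positive")
    n = int(np.floor(cluster_intensity / model.intensity + 0.5))
    return max(1, n)


def candidate_range(n_init: int) -> list[int]:
    """Candidate counts ``N_i ± max(2, N_i * 0.30)`` (half-width rounded
    half-up), clipped below at 1."""
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    half = max(2, int(np.floor(0.30 * n_init + 0.5)))
    return list(range(max(1, n_init - half), n_init + half + 1))


def _patch_2d(image: np.ndarray, bbox: tuple[int, int, int, int],
              pad: int) -> tuple[np.ndarray, tuple[int, int]]:
    y0, y1, x0, x1 = bbox
    r0, r1 = max(0, y0 - pad), min(image.shape[0], y1 + pad + 1)
    c0, c1 = max(0, x0 - pad), min(image.shape[1], x1 + pad + 1)
    return image[r0:r1, c0:c1], (r0, c0)


def extract_patch(igray: np.ndarray, cluster: Cluster, pad: int = 2
                  ) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Cluster's 3D patch of I_Gray: the bounding box padded by ``pad``
    pixels in x and y (full slice extent kept), so tail pixels missed by
    the low threshold still inform the model fit.  Returns the patch and
    its (z, y, x) origin in stack coordinates."""
    igray = np.asarray(igray, dtype=float)
    if igray.ndim == 2:
        igray = igray[None]
    z0, z1, y0, y1, x0, x1 = cluster.bbox
    r0, r1 = max(0, y0 - pad), min(igray.shape[1], y1 + pad + 1)
    c0, c1 = max(0, x0 - pad), min(igray.shape[2], x1 + pad + 1)
    return igray[z0:z1 + 1, r0:r1, c0:c1], (z0, r0, c0)


def _initial_placements(patch: np.ndarray, n: int, model: CellModel,
                        rng: np.random.Generator) -> list[CellPlacement]:
    """Seed n centres at the n brightest local maxima (ties broken by scan
    order); any remainder at the intensity-weighted centroid plus seeded
    jitter.  Maxima dimmer than 20 % of the patch maximum are ignored —
    they are residual noise in the padded margin, not cell peaks."""
    n_slices = patch.shape[0]
    footprint = np.ones((3,) * patch.ndim, dtype=bool)
    local_max = (patch == ndi.maximum_filter(patch, footprint=footprint))
    local_max &= patch > 0.2 * patch.max()
    coords = np.argwhere(local_max)
    if coords.size:
        order = np.argsort(-patch[tuple(coords.T)], kind="stable")
        coords = coords[order]
    total = patch.sum()
    if total > 0:
        com = ndi.center_of_mass(patch)
    else:
        com = tuple((s - 1) / 2.0 for s in patch.shape)
    placements: list[CellPlacement] = []
    for i in range(n):
        if i < len(coords):
            z, y, x = (int(coords[i][0]), float(coords[i][1]),
                       float(coords[i][2]))
        else:
            z = int(round(com[0]))
            y = float(com[1] + 0.5 * rng.standard_normal())
            x = float(com[2] + 0.5 * rng.standard_normal())
        z = min(max(z, 0), n_slices - 1)
        z_c = 0.0
        if n_slices > 1 and z < n_slices - 1:
            below = patch[z + 1].sum()
            here = patch[z].sum()
            z_c = float(np.clip(below / (here + below + 1e-12), 0.0, 0.4))
        placements.append(CellPlacement(x_c=x, y_c=y, home_slice=z, z_c=z_c))
    return placements


def _model_image(params: np.ndarray, homes: np.ndarray,
                 offsets: np.ndarray, has_z: np.ndarray, shape: tuple,
                 model: CellModel) -> np.ndarray:
    out = np.zeros(shape)
    for i, home in enumerate(homes):
        o = offsets[i]
        x, y = params[o], params[o + 1]
        z_c = float(np.clip(params[o + 2], 0.0, 1.0)) if has_z[i] else 0.0
        cell = render_cell(x, y, model.intensity, model.sigma, shape[1:])
        out[home] += (1.0 - z_c) * cell
        if z_c > 0.0:
            out[home + 1] += z_c * cell
    return out


def fit_n_cells(patch: np.ndarray, n: int, model: CellModel,
                seed: int | np.random.Generator = 0,
                init: list[CellPlacement] | None = None) -> CandidateFit:
    """Optimal placement of n template cells in a cluster patch.

    Minimises the least-squares objective with a Nelder-Mead simplex
    (derivative-free, robust to the non-smooth clipping of z_c); each cell
    contributes free ``x_c, y_c`` and, when a deeper slice exists in the
    patch, a split fraction ``z_c`` dividing I_t between its home slice and
    the next (clusters confined to one slice freeze z_c = 0).  Smooth
    quadratic penalties enforce pairwise separation >= D_min between cells
    sharing a home slice, keep z_c inside [0, 1] and keep centres inside
    the patch — every model cell must account for its full intensity
    within the fit region.  Deterministic for a fixed seed; iteration cap
    10,000, non-convergence flagged.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    patch = np.asarray(patch, dtype=float)
    if patch.ndim == 2:
        patch = patch[None]
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if init is None:
        init = _initial_placements(patch, n, model, rng)
    homes = np.array([p.home_slice for p in init], dtype=int)
    # z_c is a free parameter only for cells with a deeper neighbour slice
    # inside the patch; intensity may never be apportioned out of the fit
    # region (that would let surplus model cells vanish for free).
    has_z = homes + 1 < patch.shape[0]
    offsets = np.zeros(n, dtype=int)
    x0_list: list[float] = []
    for i, p in enumerate(init):
        offsets[i] = len(x0_list)
        x0_list.extend([p.x_c, p.y_c])
        if has_z[i]:
            x0_list.append(p.z_c)
    x0 = np.asarray(x0_list, dtype=float)
    penalty_w = 100.0 * model.intensity ** 2 / model.d_min ** 2
    n_rows, n_cols = patch.shape[1], patch.shape[2]

    def objective(params: np.ndarray) -> float:
        mdl = _model_image(params, homes, offsets, has_z, patch.shape, model)
        f = float(((patch - mdl) ** 2).sum())
        for i in range(n):
            xi, yi = params[offsets[i]], params[offsets[i] + 1]
            # centres must stay within the patch footprint
            f += penalty_w * (
                max(0.0, -0.5 - xi) ** 2 + max(0.0, xi - (n_cols - 0.5)) ** 2
                + max(0.0, -0.5 - yi) ** 2
                + max(0.0, yi - (n_rows - 0.5)) ** 2)
            if has_z[i]:
                zi = params[offsets[i] + 2]
                f += penalty_w * (np.clip(zi, 0.0, 1.0) - zi) ** 2
            for j in range(i + 1, n):
                if homes[i] != homes[j]:
                    continue
                dx = xi - params[offsets[j]]
                dy = yi - params[offsets[j] + 1]
                d = np.hypot(dx, dy)
                if d < model.d_min:
                    f += penalty_w * (model.d_min - d) ** 2
        return f

    f0 = objective(x0)
    fatol = RELATIVE_F_TOL * max(f0, 1.0)
    res = minimize(objective, x0, method="Nelder-Mead",
                   options=dict(maxiter=MAX_ITERATIONS,
                                maxfev=4 * MAX_ITERATIONS,
                                xatol=1e-4, fatol=fatol))
    placements = []
    for i in range(n):
        z_c = (float(np.clip(res.x[offsets[i] + 2], 0.0, 1.0))
               if has_z[i] else 0.0)
        placements.append(CellPlacement(
            x_c=float(res.x[offsets[i]]), y_c=float(res.x[offsets[i] + 1]),
            home_slice=int(homes[i]), z_c=z_c))
    converged = bool(res.success) or res.nit < MAX_ITERATIONS
    return CandidateFit(n=n, placements=placements, f_obj=float(res.fun),
                        converged=converged, n_iterations=int(res.nit))


def count_cluster(cluster: Cluster, igray: np.ndarray, model: CellModel,
                  seed: int | np.random.Generator = 0,
                  pad: int = 2) -> CountResult:
    """Estimate the number of cells in one cluster.

    Runs :func:`fit_n_cells` over the candidate range around the initial
    intensity-based estimate and picks the n with minimal F_obj (smaller n
    on exact ties).  The result is flagged ambiguous when the two best
    objectives differ by less than 20 % relatively.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    patch, _ = extract_patch(igray, cluster, pad)
    n_init = initial_estimate(cluster.integrated_intensity, model)
    candidates = [fit_n_cells(patch, n, model, rng)
                  for n in candidate_range(n_init)]
    converged = sorted((c for c in candidates if c.converged),
                       key=lambda c: (c.f_obj, c.n))
    if not converged:
        return CountResult(cluster.id, n_init, candidates, None,
                           ambiguous=False, counted=False)
    best = converged[0]
    ambiguous = False
    if len(converged) > 1:
        second = converged[1]
        denom = max(abs(best.f_obj), 1e-12)
        ambiguous = (second.f_obj - best.f_obj) / denom < AMBIGUITY_THRESHOLD
    return CountResult(cluster.id, n_init, candidates, best.n,
                       ambiguous=ambiguous)


def count_clusters(clusters: Sequence[Cluster], igray: np.ndarray,
                   model: CellModel, seed: int = 0,
                   pad: int = 2) -> list[CountResult]:
    """Count every cluster; per-cluster RNG streams derive from ``seed``
    so results do not depend on processing order."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(clusters))
    return [count_cluster(cl, igray, model,
                          np.random.default_rng(child), pad)
            for cl, child in zip(clusters, children)]
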