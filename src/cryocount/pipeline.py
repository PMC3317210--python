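"""End-to-end orchestration: preprocess -> detect -> calibrate -> count.

Thresholds that the original workflow set interactively are derived from
configuration and calibration images here: T_H from a culture image of
well-separated cells, T_L from the stack statistics, T_RG from the known
spectral ratios.  A per-object diagnostic report stands in for interactive
threshold tuning: it lists, for every candidate object, the statistics and
the threshold values needed to include or reject it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import count as count_mod
from . import detect as detect_mod
from .count import CellModel, CountResult
from .detect import Cluster, DetectConfig
from .phantom import PhantomConfig
from .preprocess import NextImageParams, PreprocessConfig, preprocess_stack
from .stack import ImageStack

__all__ = ["CountingConfig", "PipelineConfig", "PipelineResult",
           "run_pipeline", "calibrate_high_threshold", "threshold_report",
           "counts_to_frame"]


@dataclass
class CountingConfig:
    """Counting-stage knobs: the minimum centre separation (about one cell
    diameter, in micrometres so it scales with pixel size), the fit-patch
    padding, and the width of the singleton selection band."""

    cell_diameter_um: float = 12.5
    pad_px: int = 2
    singleton_band_sd: float = 2.5

    def d_min_px(self, pixel_size_um: float) -> float:
        return max(self.cell_diameter_um / pixel_size_um, 0.5)


@dataclass
class PipelineConfig:
    """Unified configuration for simulate/run/evaluate stages."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    counting: CountingConfig = field(default_factory=CountingConfig)
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["phantom"]["image_shape"] = list(self.phantom.image_shape)
        det = data["detect"]
        if det.get("ratio_high") in (np.inf, float("inf")):
            det["ratio_high"] = "inf"
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        phantom = PhantomConfig.from_dict(data.get("phantom", {}))
        pre = dict(data.get("preprocess", {}))
        if "next_image" in pre:
            pre["next_image"] = NextImageParams(**pre["next_image"])
        preprocess = PreprocessConfig(**pre)
        det = dict(data.get("detect", {}))
        if det.get("ratio_high") == "inf":
            det["ratio_high"] = np.inf
        detect = DetectConfig(**det)
        counting = CountingConfig(**data.get("counting", {}))
        return cls(phantom=phantom, preprocess=preprocess, detect=detect,
                   counting=counting, seed=int(data.get("seed", 0)))


@dataclass
class PipelineResult:
    igray: np.ndarray
    t_high: float
    t_low: float
    clusters: list[Cluster]
    rejected: list[tuple[Cluster, str]]
    model: CellModel
    counts: list[CountResult]

    @property
    def counts_by_id(self) -> dict[int, int]:
        return {r.cluster_id: r.chosen_n for r in self.counts
                if r.counted and r.chosen_n is not None}

    @property
    def total_cells(self) -> int:
        return int(sum(self.counts_by_id.values()))


def calibrate_high_threshold(culture_stack: ImageStack,
                             config: PreprocessConfig,
                             c: float = 1.4) -> float:
    """T_H from an image of cells in culture: preprocess it the same way
    as the tissue stack, segment the well-separated cells, and apply
    T_H = 0.6 * min cluster maximum."""
    igray = preprocess_stack(culture_stack, config)
    maxima = detect_mod.culture_cluster_maxima(igray, c)
    return detect_mod.compute_high_threshold(maxima)


def counts_to_frame(results: list[CountResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        cand = {c.n: c.f_obj for c in r.candidates}
        rows.append(dict(
            cluster_id=r.cluster_id, n_init=r.n_init,
            chosen_n=-1 if r.chosen_n is None else r.chosen_n,
            ambiguous=r.ambiguous, counted=r.counted,
            candidates=";".join(f"{n}:{f:.6g}" for n, f in sorted(cand.items())),
        ))
    return pd.DataFrame(rows, columns=["cluster_id", "n_init", "chosen_n",
                                       "ambiguous", "counted", "candidates"])


def threshold_report(stack: ImageStack, igray: np.ndarray,
                     clusters: list[Cluster]) -> pd.DataFrame:
    """Diagnostic report replacing interactive threshold selection.

    For each candidate object: its feature statistics and the T_RG, T_H
    and T_L values that would include or reject it (an object is included
    while T_H is below its maximum intensity, T_L below its minimum
    retained intensity, and T_RG below its median red/green voxel ratio).
    """
    rows = []
    igray3 = igray[None] if igray.ndim == 2 else igray
    for cl in clusters:
        zz, yy, xx = cl.voxels.T
        red = stack.red[zz, yy, xx]
        green = (stack.green[zz, yy, xx] if stack.green is not None
                 else np.zeros_like(red))
        with np.errstate(divide="ignore"):
            rg = np.where(green > 0, red / np.maximum(green, 1e-12), np.inf)
        vals = igray3[zz, yy, xx]
        rows.append(dict(
            id=cl.id, volume=cl.volume,
            integrated_intensity=cl.integrated_intensity,
            ratio=cl.intensity_volume_ratio, slice_span=cl.slice_span,
            t_high_to_include=float(vals.max()),
            t_low_to_include=float(vals.min()),
            t_rg_to_include=float(np.median(rg))))
    return pd.DataFrame(rows, columns=[
        "id", "volume", "integrated_intensity", "ratio", "slice_span",
        "t_high_to_include", "t_low_to_include", "t_rg_to_include"])


def run_pipeline(stack: ImageStack, config: PipelineConfig,
                 culture_stack: ImageStack | None = None,
                 seed: int | None = None) -> PipelineResult:
    """Run preprocessing, detection, calibration and counting on a stack.

    ``t_high`` is taken from the configuration when given, otherwise
    calibrated from ``culture_stack``; ``t_low`` likewise defaults to
    ``mu + c * sigma`` of I_Gray.  The counting seed defaults to the
    configuration seed.
    """
    cfg = config
    igray = preprocess_stack(stack, cfg.preprocess)

    t_high = cfg.detect.t_high
    if t_high is None:
        if culture_stack is None:
            raise ValueError("need either detect.t_high or a culture stack")
        t_high = calibrate_high_threshold(culture_stack, cfg.preprocess,
                                          cfg.detect.c)
    t_low = cfg.detect.t_low
    if t_low is None:
        t_low = detect_mod.compute_low_threshold(igray, cfg.detect.c)
    if not t_high > t_low:
        raise ValueError(
            f"derived t_high ({t_high:.3g}) must exceed t_low "
            f"({t_low:.3g}); check calibration images and c")

    mask = detect_mod.hysteresis_threshold(igray, t_high, t_low)
    clusters = detect_mod.connected_components(mask, igray)
    kept, rejected = detect_mod.reject_false_positives(
        clusters, cfg.detect.t_volume, cfg.detect.ratio_low,
        cfg.detect.ratio_high)

    v_range, i_range = count_mod.singleton_ranges(
        kept, cfg.counting.singleton_band_sd)
    singletons = count_mod.select_singletons(kept, v_range, i_range)
    model = count_mod.calibrate_model(
        singletons, igray,
        d_min=cfg.counting.d_min_px(stack.pixel_size_um),
        pad=cfg.counting.pad_px)

    results = count_mod.count_clusters(
        kept, igray, model,
        seed=cfg.seed if seed is None else seed,
        pad=cfg.counting.pad_px)
    return PipelineResult(igray=igray, t_high=float(t_high),
                          t_low=float(t_low), clusters=kept,
                          rejected=rejected, model=model, counts=results)
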