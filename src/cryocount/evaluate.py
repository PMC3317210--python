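"""Scoring of algorithm counts against ground truth or an expert reader.

Counts are compared cluster-by-cluster in a square contingency table
(true class x estimated class); agreement is summarised by Fleiss' kappa
(two raters: algorithm and reference) with its asymptotic standard error,
Cohen's kappa for comparison, one-vs-rest per-class sensitivity and
specificity, and the relative total-count error.  Feature histograms of
cluster volume and integrated intensity expose the single-cell peak used
for calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

from .detect import Cluster

__all__ = [
    "ContingencyTable",
    "build_contingency",
    "fleiss_kappa",
    "cohens_kappa",
    "sensitivity_specificity",
    "total_count_error",
    "feature_histograms",
    "match_clusters",
]


@dataclass
class ContingencyTable:
    """Square matrix of (true class, estimated class) tallies."""

    table: np.ndarray          # (K, K) non-negative integers
    classes: np.ndarray        # class labels, ascending

    @property
    def n_subjects(self) -> int:
        return int(self.table.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.table, index=self.classes,
                            columns=self.classes)


def build_contingency(true_counts: Sequence[int],
                      est_counts: Sequence[int]) -> ContingencyTable:
    """Tally paired (true, estimated) counts into a square table whose
    rows are the true class and columns the estimated class."""
    true_counts = np.asarray(true_counts, dtype=int)
    est_counts = np.asarray(est_counts, dtype=int)
    if true_counts.shape != est_counts.shape:
        raise ValueError("true and estimated count lists differ in length")
    if true_counts.size == 0:
        return ContingencyTable(np.zeros((0, 0), dtype=int),
                                np.array([], dtype=int))
    classes = np.unique(np.concatenate([true_counts, est_counts]))
    index = {c: i for i, c in enumerate(classes)}
    table = np.zeros((len(classes), len(classes)), dtype=int)
    for t, e in zip(true_counts, est_counts):
        table[index[t], index[e]] += 1
    return ContingencyTable(table, classes)


def _rating_matrix(table: ContingencyTable) -> np.ndarray:
    """Subjects x categories matrix of rating counts for two raters."""
    k = len(table.classes)
    rows = []
    for i in range(k):
        for j in range(k):
            m = table.table[i, j]
            if m == 0:
                continue
            row = np.zeros(k)
            row[i] += 1
            row[j] += 1
            rows.extend([row] * int(m))
    return np.array(rows)


def fleiss_kappa(table: ContingencyTable) -> tuple[float, float]:
    """Fleiss' kappa and its asymptotic standard error for the two-rater
    (algorithm vs reference) design.

    Each scored cluster is a subject rated twice.  Returns ``(nan, nan)``
    for degenerate input (no subjects, or a single category used, where
    chance agreement is 1 and kappa is undefined).
    """
    if table.n_subjects == 0:
        return (np.nan, np.nan)
    rat = _rating_matrix(table)
    p_j = rat.sum(axis=0) / rat.sum()
    if np.count_nonzero(p_j) < 2:
        return (np.nan, np.nan)
    kappa = float(_sm_fleiss_kappa(rat, method="fleiss"))
    # Fleiss-Nee-Landis asymptotic SE (under the chance-agreement model)
    n_sub, n_rat = rat.shape[0], 2.0
    q = p_j * (1.0 - p_j)
    sq = q.sum()
    var = (2.0 / (n_sub * n_rat * (n_rat - 1.0))) * (
        sq ** 2 - float((q * (1.0 - 2.0 * p_j)).sum())) / sq ** 2
    return kappa, float(np.sqrt(max(var, 0.0)))


def cohens_kappa(table: ContingencyTable) -> float:
    """Cohen's kappa of the same table, reported alongside Fleiss' kappa
    (for two raters the two chance-correction conventions differ only in
    how marginal rates are pooled)."""
    n = table.n_subjects
    if n == 0:
        return np.nan
    t = table.table / n
    po = float(np.trace(t))
    pe = float((t.sum(axis=1) * t.sum(axis=0)).sum())
    if pe >= 1.0:
        return np.nan
    return (po - pe) / (1.0 - pe)


def sensitivity_specificity(table: ContingencyTable) -> pd.DataFrame:
    """One-vs-rest per-class metrics.

    For class k: sensitivity = correctly-estimated-k / true-k and
    specificity = true-negative rate among clusters not truly k.  Classes
    without true instances get NaN sensitivity and are excluded from the
    mean; the frame carries a ``mean`` row over defined classes.
    """
    t = table.table.astype(float)
    n = t.sum()
    rows = []
    for i, cls in enumerate(table.classes):
        true_k = t[i].sum()
        est_k = t[:, i].sum()
        tp = t[i, i]
        sens = tp / true_k if true_k > 0 else np.nan
        tn = n - true_k - est_k + tp
        neg = n - true_k
        spec = tn / neg if neg > 0 else np.nan
        rows.append(dict(klass=int(cls), n_true=int(true_k),
                         sensitivity=sens, specificity=spec))
    frame = pd.DataFrame(rows)
    mean_row = dict(klass=-1, n_true=int(n),
                    sensitivity=float(np.nanmean(frame["sensitivity"]))
                    if frame["sensitivity"].notna().any() else np.nan,
                    specificity=float(np.nanmean(frame["specificity"]))
                    if frame["specificity"].notna().any() else np.nan)
    return pd.concat([frame, pd.DataFrame([mean_row])], ignore_index=True)


def total_count_error(true_counts: Sequence[int],
                      est_counts: Sequence[int]) -> float:
    """Relative error of the summed counts,
    ``|sum(est) - sum(true)| / sum(true)``."""
    s_true = float(np.sum(true_counts))
    s_est = float(np.sum(est_counts))
    if s_true == 0:
        raise ValueError("total true count is zero; error undefined")
    return abs(s_est - s_true) / s_true


def feature_histograms(clusters: Sequence[Cluster], bins: int = 50
                       ) -> dict[str, pd.DataFrame]:
    """Histograms of cluster volume and integrated intensity.

    The dominant intensity peak corresponds to single cells; the next peak
    sits near twice its intensity.  Returns per-feature frames with bin
    centres and counts.
    """
    out: dict[str, pd.DataFrame] = {}
    for name, values in (
            ("volume", np.array([c.volume for c in clusters], dtype=float)),
            ("integrated_intensity",
             np.array([c.integrated_intensity for c in clusters]))):
        if values.size == 0:
            out[name] = pd.DataFrame(columns=["bin_center", "count"])
            continue
        counts, edges = np.histogram(values, bins=bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        out[name] = pd.DataFrame({"bin_center": centers, "count": counts})
    return out


def match_clusters(truth_cells: pd.DataFrame,
                   clusters: Sequence[Cluster],
                   counts: dict[int, int] | None = None,
                   pad: float = 1.5) -> pd.DataFrame:
    """Assign ground-truth cells to detected clusters by position.

    Each true cell is matched to the detected cluster whose padded
    bounding box contains its (slice, y, x) centre (splits may place part
    of a cell one slice deeper, so the slice test allows slice or
    slice + 1).  Returns one row per true cluster with its true cell count
    and the estimated count of the matched detection (NaN when missed).
    Detected clusters matching no true cell are appended as spurious rows
    with true_n = 0.
    """
    rows = []
    matched_ids: set[int] = set()
    for cid, group in truth_cells.groupby("cluster_id"):
        hit = None
        for cl in clusters:
            z0, z1, y0, y1, x0, x1 = cl.bbox
            inside = ((group["y"] >= y0 - pad) & (group["y"] <= y1 + pad)
                      & (group["x"] >= x0 - pad) & (group["x"] <= x1 + pad)
                      & (group["slice"] >= z0 - 1) & (group["slice"] <= z1))
            if inside.any():
                hit = cl
                break
        est = np.nan
        if hit is not None:
            matched_ids.add(hit.id)
            if counts is not None:
                est = counts.get(hit.id, np.nan)
        rows.append(dict(true_cluster_id=int(cid), true_n=int(len(group)),
                         detected_id=np.nan if hit is None else hit.id,
                         est_n=est))
    for cl in clusters:
        if cl.id not in matched_ids:
            est = counts.get(cl.id, np.nan) if counts is not None else np.nan
            rows.append(dict(true_cluster_id=-1, true_n=0,
                             detected_id=cl.id, est_n=est))
    return pd.DataFrame(rows, columns=["true_cluster_id", "true_n",
                                       "detected_id", "est_n"])
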