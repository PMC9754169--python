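"""Evaluation protocol: per-position MAE in HU, per-slice-normalized SSIM,
improvement percentages, paired significance tests, and the mu rule for
choosing the half-gap parameter m.

Reconstruction quality is reported per target position (position k of
the 2m-1 slices in a gap, pooled over gaps and volumes), optionally
restricted to an organ mask, exactly the table layout used to compare
reconstructors: one row of per-position values plus their average, an
improvement row between methods, and pairwise p-values.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity

from .volume_io import DEFAULT_HU_WINDOW

__all__ = ["EvalReport", "MSelectionRule", "SignificanceResult", "mae",
           "ssim_per_slice", "improvement_pct", "significance_test",
           "select_m", "tabulate", "build_report"]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# metrics


def mae(pred: np.ndarray, true: np.ndarray, mask: np.ndarray | None = None,
        hu_window: tuple[float, float] | None = DEFAULT_HU_WINDOW) -> float:
    """Mean absolute voxelwise error, reported in HU.

    Inputs are on the normalized [0, 1] scale; differences are converted
    to HU by the window width (x2000 for the default [-1000, 1000]
    window). Pass ``hu_window=None`` to stay in native units. With a
    mask, only masked voxels enter the mean.
    """
    pred = np.asarray(pred, dtype=np.float64)
    true = np.asarray(true, dtype=np.float64)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    diff = np.abs(pred - true)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != pred.shape:
            raise ValueError(f"mask shape {mask.shape} != data shape {pred.shape}")
        if not mask.any():
            raise ValueError("empty evaluation mask")
        diff = diff[mask]
    scale = 1.0 if hu_window is None else (hu_window[1] - hu_window[0])
    return float(diff.mean() * scale)


def _minmax(x: np.ndarray) -> np.ndarray:
    ptp = x.max() - x.min()
    return (x - x.min()) / ptp


def ssim_per_slice(pred: np.ndarray, true: np.ndarray,
                   mask: np.ndarray | None = None, win_size: int = 7,
                   gaussian: bool = True, norm: str = "minmax") -> float:
    """Structural similarity after independent per-slice normalization.

    Each slice is min-max normalized (z-score selectable) before SSIM
    with the standard stabilization constants; the Gaussian window
    (sigma 1.5) is the default, a uniform window is available for
    cross-checking. With a mask the SSIM map is averaged over masked
    pixels; otherwise the standard mean score is returned. A slice with
    zero dynamic range cannot be normalized, so the pair is compared
    unnormalized (logged).
    """
    pred = np.asarray(pred, dtype=np.float64)
    true = np.asarray(true, dtype=np.float64)
    if pred.shape != true.shape or pred.ndim != 2:
        raise ValueError(f"expected equal-shape 2-D slices, got {pred.shape}, {true.shape}")
    if norm not in ("minmax", "zscore"):
        raise ValueError(f"unknown normalization {norm!r}")
    degenerate = np.ptp(pred) == 0 or np.ptp(true) == 0
    if degenerate:
        logger.info("constant slice: computing SSIM without per-slice normalization")
        p, t = pred, true
        data_range = max(np.ptp(np.concatenate([p.ravel(), t.ravel()])), 1e-12)
    elif norm == "minmax":
        p, t = _minmax(pred), _minmax(true)
        data_range = 1.0
    else:
        p = (pred - pred.mean()) / pred.std()
        t = (true - true.mean()) / true.std()
        data_range = max(np.ptp(np.concatenate([p.ravel(), t.ravel()])), 1e-12)
    kwargs = dict(win_size=win_size, data_range=data_range)
    if gaussian:
        kwargs.update(gaussian_weights=True, sigma=1.5,
                      use_sample_covariance=False)
    score, smap = structural_similarity(p, t, full=True, **kwargs)
    if mask is None:
        return float(score)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty evaluation mask")
    return float(smap[mask].mean())


def improvement_pct(reference: float, new: float, metric: str = "error") -> float:
    """Relative improvement of ``new`` over ``reference`` in percent.

    For error metrics (MAE): 100 (ref - new)/ref, positive when the new
    method has lower error. For similarity metrics (SSIM):
    100 (new - ref)/ref, positive when similarity increased.
    """
    if reference <= 0:
        raise ValueError(f"reference must be positive, got {reference}")
    if metric == "error":
        return 100.0 * (reference - new) / reference
    if metric == "similarity":
        return 100.0 * (new - reference) / reference
    raise ValueError(f"unknown metric kind {metric!r}")


@dataclass(frozen=True)
class SignificanceResult:
    p_value: float
    median_diff: float
    favors: str          # "A" (first sample smaller), "B", or "tie"
    degenerate: bool = False


def significance_test(errors_a, errors_b, method: str = "wilcoxon") -> SignificanceResult:
    """Two-sided paired test on matched absolute-error samples.

    Wilcoxon signed-rank by default (no normality assumption on paired
    error differences); a paired t-test is available. Identical samples
    are a degenerate case and are flagged rather than assigned
    significance.
    """
    a = np.asarray(errors_a, dtype=np.float64)
    b = np.asarray(errors_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    diff = a - b
    med = float(np.median(diff))
    favors = "tie" if med == 0 else ("A" if med < 0 else "B")
    if np.all(diff == 0):
        return SignificanceResult(p_value=1.0, median_diff=0.0, favors="tie",
                                  degenerate=True)
    if method == "wilcoxon":
        res = stats.wilcoxon(a, b, alternative="two-sided")
    elif method == "ttest":
        res = stats.ttest_rel(a, b)
    else:
        raise ValueError(f"unknown test {method!r}")
    return SignificanceResult(p_value=float(res.pvalue), median_diff=med, favors=favors)


# ---------------------------------------------------------------------------
# m selection


@dataclass(frozen=True)
class MSelectionRule:
    """Threshold mu on the maximum pixel-wise MAE (HU) tolerated for a given m."""

    mu: float

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")


def select_m(max_mae_by_m, rule: MSelectionRule) -> float:
    """Largest m whose maximum pixel-wise MAE stays within mu.

    ``max_mae_by_m`` is an ordered sequence of (m, max pixel-wise MAE in
    HU) with m increasing; growing m stops once the maximum exceeds mu.
    If even the smallest m exceeds mu it is returned with a warning.
    """
    table = list(max_mae_by_m)
    if not table:
        raise ValueError("empty m table")
    if any(m2 <= m1 for (m1, _), (m2, _) in zip(table, table[1:])):
        raise ValueError("m values must be strictly increasing")
    admissible = [m for m, max_mae in table if max_mae <= rule.mu]
    if not admissible:
        warnings.warn(
            f"smallest m={table[0][0]} already exceeds mu={rule.mu}; returning it",
            stacklevel=2)
        return table[0][0]
    return admissible[-1]


# ---------------------------------------------------------------------------
# report assembly


def tabulate(per_position: dict[str, list[float]],
             comparisons: list[tuple[str, str]] | None = None,
             metric: str = "error") -> pd.DataFrame:
    """Per-position table with an Average column and improvement rows.

    ``per_position`` maps method name to its 2m-1 per-position values
    (e.g. the printed cells of a results table); ``comparisons`` lists
    (new, reference) method pairs, defaulting to every method versus the
    first one. Improvement rows are computed cellwise and on the
    averages via :func:`improvement_pct`.
    """
    methods = list(per_position)
    n_pos = len(per_position[methods[0]])
    if any(len(v) != n_pos for v in per_position.values()):
        raise ValueError("all methods must report the same positions")
    cols = [f"Slice {k}" for k in range(1, n_pos + 1)] + ["Average"]
    rows = {}
    for method, values in per_position.items():
        values = [float(v) for v in values]
        rows[method] = values + [float(np.mean(values))]
    if comparisons is None:
        comparisons = [(m, methods[0]) for m in methods[1:]]
    for new, ref in comparisons:
        # a zero reference (perfect score) has no defined relative improvement
        rows[f"Improvement ({new} vs. {ref})"] = [
            improvement_pct(r, n, metric=metric) if r > 0 else float("nan")
            for r, n in zip(rows[ref], rows[new])
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


@dataclass
class EvalReport:
    """Table bundle: overall and per-organ MAE/SSIM plus p-values."""

    per_position_mae: pd.DataFrame
    per_position_ssim: pd.DataFrame | None = None
    per_organ_mae: dict[str, pd.DataFrame] = field(default_factory=dict)
    per_organ_ssim: dict[str, pd.DataFrame] = field(default_factory=dict)
    p_values: pd.DataFrame | None = None

    def to_csv(self, out_dir: str | os.PathLike) -> None:
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        self.per_position_mae.to_csv(os.path.join(out_dir, "mae.csv"))
        if self.per_position_ssim is not None:
            self.per_position_ssim.to_csv(os.path.join(out_dir, "ssim.csv"))
        for organ, df in self.per_organ_mae.items():
            df.to_csv(os.path.join(out_dir, f"mae_{organ}.csv"))
        for organ, df in self.per_organ_ssim.items():
            df.to_csv(os.path.join(out_dir, f"ssim_{organ}.csv"))
        if self.p_values is not None:
            self.p_values.to_csv(os.path.join(out_dir, "p_values.csv"))

    def to_json(self) -> dict:
        out = {"mae": self.per_position_mae.to_dict(orient="index")}
        if self.per_position_ssim is not None:
            out["ssim"] = self.per_position_ssim.to_dict(orient="index")
        out["per_organ_mae"] = {o: df.to_dict(orient="index")
                                for o, df in self.per_organ_mae.items()}
        out["per_organ_ssim"] = {o: df.to_dict(orient="index")
                                 for o, df in self.per_organ_ssim.items()}
        if self.p_values is not None:
            out["p_values"] = self.p_values.to_dict(orient="index")
        return out


def build_report(predictions: dict[str, np.ndarray], truth: np.ndarray,
                 organ_masks: dict[str, np.ndarray] | None = None,
                 hu_window: tuple[float, float] = DEFAULT_HU_WINDOW,
                 comparisons: list[tuple[str, str]] | None = None,
                 with_ssim: bool = True,
                 significance: str = "wilcoxon") -> EvalReport:
    """Assemble the full evaluation table set.

    ``predictions`` maps method name to an array of shape
    (n_gaps, 2m-1, H, W) pooling every evaluated gap; ``truth`` has the
    same shape. ``organ_masks`` maps organ name to a boolean array of
    that shape. MAE pools voxels across gaps per position; SSIM averages
    per-slice scores. p-values come from paired tests on per-gap,
    per-position mean absolute errors.
    """
    truth = np.asarray(truth)
    if truth.ndim != 4:
        raise ValueError(f"truth must be (n_gaps, targets, H, W), got {truth.shape}")
    n_gaps, n_pos = truth.shape[:2]
    for name, pred in predictions.items():
        if np.asarray(pred).shape != truth.shape:
            raise ValueError(f"method {name!r} shape {np.asarray(pred).shape} "
                             f"!= truth {truth.shape}")

    mae_cells = {
        name: [mae(np.asarray(pred)[:, k], truth[:, k], hu_window=hu_window)
               for k in range(n_pos)]
        for name, pred in predictions.items()
    }
    report = EvalReport(per_position_mae=tabulate(mae_cells, comparisons, "error"))

    if with_ssim:
        ssim_cells = {
            name: [float(np.mean([ssim_per_slice(np.asarray(pred)[g, k], truth[g, k])
                                  for g in range(n_gaps)]))
                   for k in range(n_pos)]
            for name, pred in predictions.items()
        }
        report.per_position_ssim = tabulate(ssim_cells, comparisons, "similarity")

    for organ, mask in (organ_masks or {}).items():
        mask = np.asarray(mask, dtype=bool)
        organ_cells = {}
        ssim_organ_cells = {}
        for name, pred in predictions.items():
            pred = np.asarray(pred)
            organ_cells[name] = [
                mae(pred[:, k], truth[:, k], mask=mask[:, k], hu_window=hu_window)
                for k in range(n_pos)
            ]
            if with_ssim:
                ssim_organ_cells[name] = [
                    float(np.mean([
                        ssim_per_slice(pred[g, k], truth[g, k], mask=mask[g, k])
                        for g in range(n_gaps) if mask[g, k].any()
                    ]))
                    for k in range(n_pos)
                ]
        report.per_organ_mae[organ] = tabulate(organ_cells, comparisons, "error")
        if with_ssim:
            report.per_organ_ssim[organ] = tabulate(ssim_organ_cells, comparisons,
                                                    "similarity")

    methods = list(predictions)
    if len(methods) > 1:
        per_sample = {
            name: np.abs(np.asarray(pred) - truth).mean(axis=(2, 3)).ravel()
            for name, pred in predictions.items()
        }
        rows = {}
        for i, a in enumerate(methods):
            for b in methods[i + 1:]:
                res = significance_test(per_sample[a], per_sample[b], method=significance)
                rows[f"{a} vs. {b}"] = {"p_value": res.p_value,
                                        "median_diff": res.median_diff,
                                        "favors": {"A": a, "B": b, "tie": "tie"}[res.favors]}
        report.p_values = pd.DataFrame.from_dict(rows, orient="index")
    return report
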