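"""Agreement between real and virtual IF images, and model comparisons.

SSIM is computed over stride-1 sliding windows (default 11 px, uniform
weights, population moments) after an optional Gaussian prefilter of both
images (default sigma 3) that suppresses registration/instrumentation noise
the translator cannot be expected to reproduce. The per-image value is the
mean of the per-window map

    (2 mu_x mu_y + c1)(2 sigma_xy + c2)
    -----------------------------------
    (mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2)

with the standard stabilizers c1 = (0.01 L)^2, c2 = (0.03 L)^2 for data
range L.

``compare_models`` runs the paired-model statistics battery per held-out
sample subset: Shapiro-Wilk normality is reported, two models are compared
with the Wilcoxon signed-rank test, three or more with the Friedman test
followed (on rejection) by the Nemenyi post-hoc on mean ranks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .datatypes import DegenerateImageError, InvalidSpecError


@dataclass
class SsimParams:
    window: int = 11
    k1: float = 0.01
    k2: float = 0.03
    data_range: float = 1.0
    prefilter_sigma: float = 3.0   # 0 disables the Gaussian prefilter
    gaussian_weights: bool = False
    weight_sigma: float = 1.5

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise InvalidSpecError("window must be odd and >= 3")
        if self.k1 <= 0 or self.k2 <= 0 or self.data_range <= 0:
            raise InvalidSpecError("stabilizers and data range must be positive")
        if self.prefilter_sigma < 0:
            raise InvalidSpecError("prefilter_sigma must be >= 0")

    @property
    def c1(self) -> float:
        return (self.k1 * self.data_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.data_range) ** 2


def ssim(x: np.ndarray, y: np.ndarray, params: SsimParams | None = None) -> float:
    """Mean windowed SSIM between two single-channel images."""
    params = params or SsimParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidSpecError("images must have the same dimensions")
    if x.ndim != 2:
        raise InvalidSpecError("images must be single-channel")
    w = params.window
    if min(x.shape) < w:
        raise InvalidSpecError(f"image smaller than the {w}-px window")
    if params.prefilter_sigma > 0:
        x = ndimage.gaussian_filter(x, params.prefilter_sigma, mode="reflect")
        y = ndimage.gaussian_filter(y, params.prefilter_sigma, mode="reflect")

    if params.gaussian_weights:
        def mean_f(a):
            return ndimage.gaussian_filter(a, params.weight_sigma, truncate=(w // 2) / params.weight_sigma)
    else:
        def mean_f(a):
            return ndimage.uniform_filter(a, w)

    half = w // 2
    crop = (slice(half, x.shape[0] - half), slice(half, x.shape[1] - half))
    mx = mean_f(x)[crop]
    my = mean_f(y)[crop]
    exx = mean_f(x * x)[crop]
    eyy = mean_f(y * y)[crop]
    exy = mean_f(x * y)[crop]
    vx = exx - mx * mx
    vy = eyy - my * my
    cxy = exy - mx * my
    c1, c2 = params.c1, params.c2
    s = ((2 * mx * my + c1) * (2 * cxy + c2)) / ((mx**2 + my**2 + c1) * (vx + vy + c2))
    return float(s.mean())


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation over flattened pixels."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise InvalidSpecError("images must have the same dimensions")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateImageError("correlation undefined for a constant image")
    return float(stats.pearsonr(x, y).statistic)


def nemenyi_friedman(matrix: np.ndarray, model_ids: List[str]) -> pd.DataFrame:
    """Nemenyi post-hoc p-values for a paired n x k score matrix.

    Mean-rank differences are scaled by sqrt(k(k+1)/(6n)) and referred to the
    studentized range distribution (infinite df), the classic post-hoc for
    the Friedman test.
    """
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    ranks = stats.rankdata(m, axis=1)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    q = np.abs(mean_ranks[:, None] - mean_ranks[None, :]) / se
    p = stats.studentized_range.sf(q * np.sqrt(2.0), k, np.inf)
    np.fill_diagonal(p, 1.0)
    return pd.DataFrame(p, index=model_ids, columns=model_ids)


def compare_models(scores: pd.DataFrame, metric: str = "ssim",
                   alpha: float = 0.05) -> dict:
    """Paired model comparison per sample subset.

    ``scores`` has columns [tile_id, sample_subset_id, model_id, <metric>].
    Within each subset every tile must carry a score under every model.
    Routing is by model count: 2 -> Wilcoxon signed-rank, >= 3 -> Friedman
    (+ Nemenyi post-hoc on rejection). Shapiro-Wilk normality is reported
    per model but does not gate the nonparametric route.
    """
    required = {"tile_id", "sample_subset_id", "model_id", metric}
    if not required.issubset(scores.columns):
        raise InvalidSpecError(f"scores table needs columns {sorted(required)}")
    report: Dict[str, dict] = {"alpha": alpha, "metric": metric, "subsets": {}}
    for subset, grp in scores.groupby("sample_subset_id"):
        pivot = grp.pivot_table(index="tile_id", columns="model_id",
                                values=metric, aggfunc="first")
        models = list(pivot.columns)
        if len(models) < 2:
            raise InvalidSpecError(f"subset {subset!r}: need >= 2 models")
        if pivot.isna().any().any():
            missing = pivot.index[pivot.isna().any(axis=1)].tolist()
            raise InvalidSpecError(
                f"subset {subset!r}: unpaired scores for tiles {missing[:5]}")
        m = pivot.to_numpy(float)
        entry: dict = {"n_tiles": int(m.shape[0]), "models": models}
        entry["shapiro"] = {
            mod: float(stats.shapiro(m[:, j]).pvalue) if np.ptp(m[:, j]) > 0 else 1.0
            for j, mod in enumerate(models)
        }
        if len(models) == 2:
            diffs = m[:, 0] - m[:, 1]
            if np.all(diffs == 0):
                entry["test"] = {"name": "wilcoxon", "statistic": 0.0, "pvalue": 1.0}
            else:
                res = stats.wilcoxon(m[:, 0], m[:, 1])
                entry["test"] = {"name": "wilcoxon",
                                 "statistic": float(res.statistic),
                                 "pvalue": float(res.pvalue)}
            entry["reject"] = bool(entry["test"]["pvalue"] < alpha)
            if entry["reject"]:
                entry["flagged_pairs"] = [tuple(models)]
        else:
            if np.all(m == m[:, [0]]):
                entry["test"] = {"name": "friedman", "statistic": 0.0, "pvalue": 1.0}
            else:
                res = stats.friedmanchisquare(*[m[:, j] for j in range(m.shape[1])])
                entry["test"] = {"name": "friedman",
                                 "statistic": float(res.statistic),
                                 "pvalue": float(res.pvalue)}
            entry["reject"] = bool(entry["test"]["pvalue"] < alpha)
            if entry["reject"]:
                ptab = nemenyi_friedman(m, models)
                entry["nemenyi"] = ptab.to_dict()
                flagged = []
                for i in range(len(models)):
                    for j in range(i + 1, len(models)):
                        if ptab.iloc[i, j] < alpha:
                            flagged.append((models[i], models[j]))
                entry["flagged_pairs"] = flagged
        report["subsets"][str(subset)] = entry
    return report
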