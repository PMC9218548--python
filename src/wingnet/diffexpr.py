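"""Negative-binomial differential expression between seasonal forms.

Counts are normalized by median-of-ratios size factors (a per-sample factor
equal to the median, over all-positive reference features, of that sample's
ratio to the per-feature geometric mean). Per stage, each feature gets a
Wald test of log2FC = log2(WS mean / DS mean): the NB variance is
mu + alpha*mu^2 with a per-feature method-of-moments dispersion shrunk
halfway toward a fitted mean-dispersion trend, the standard error follows by
the delta method, and two-sided p-values come from the normal reference
distribution. P-values are Benjamini-Hochberg adjusted within stage and
feature kind. The sign convention is fixed: positive log2FC means higher in
the wet-season (WS) form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from scipy import stats

from .matrix import ExpressionMatrix

#: floor for the shrunken dispersion
MIN_DISPERSION = 1e-8
#: half of the smallest nonzero normalized count stands in for an empty group
ZERO_GROUP_PSEUDO = 0.5


@dataclass
class DEResult:
    feature: str
    stage: str
    base_mean: float
    log2fc: float  # log2(WS mean / DS mean), positive = higher in WS
    p: float
    padj: float = float("nan")


def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors.

    Reference features are those with strictly positive counts in every
    sample; each sample's factor is the median over reference features of
    count / geometric-mean(feature).
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2:
        raise ValueError("counts must be 2-D (features x samples)")
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has all-positive counts; "
            "pseudo-reference fallback is disabled"
        )
    ref = arr[positive]
    log_geo = np.log(ref).mean(axis=1, keepdims=True)
    ratios = ref / np.exp(log_geo)
    return np.median(ratios, axis=0)


def normalized_counts(matrix: ExpressionMatrix) -> pd.DataFrame:
    sf = size_factors(matrix.counts)
    return matrix.counts / sf


def log_expression(matrix: ExpressionMatrix) -> pd.DataFrame:
    """log2(normalized count + 1), the scale used for correlations."""
    return np.log2(normalized_counts(matrix) + 1.0)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def _dispersion_trend(means: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Fit alpha_trend(mu) = a0 + a1/mu by least squares on the raw
    method-of-moments estimates (nonnegative coefficients)."""
    ok = (means > 0) & np.isfinite(disp)
    if ok.sum() < 2:
        return np.full_like(means, max(float(np.nanmedian(disp[ok])) if ok.any() else 0.0, 0.0))
    x = 1.0 / means[ok]
    y = disp[ok]
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / means
    trend[~np.isfinite(trend)] = a0
    return trend


def estimate_dispersions(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-feature NB dispersion: method of moments pooled within groups,
    then a 50/50 convex shrink toward the fitted mean-dispersion trend,
    one-sided — estimates below the trend are raised to it, guarding the
    Wald test against luck-driven small replicate variances at n = 4."""
    n_total = sum(len(g) for g in groups)
    k = len(groups)
    means = norm.mean(axis=1)
    ss = np.zeros(norm.shape[0])
    for g in groups:
        sub = norm[:, g]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled_var = ss / max(n_total - k, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (pooled_var - means) / means**2
    raw = np.where(np.isfinite(raw), raw, 0.0)
    raw = np.clip(raw, 0.0, None)
    trend = _dispersion_trend(means, raw)
    shrunk = np.maximum(0.5 * raw + 0.5 * trend, trend)
    return np.maximum(shrunk, MIN_DISPERSION)


def nb_wald_test(matrix: ExpressionMatrix, stage: str) -> list[DEResult]:
    """Per-feature WS-vs-DS Wald test at one stage.

    Requires >= 2 replicates per form at the stage. Returns one
    :class:`DEResult` per feature with BH-adjusted p-values across the
    features of this stage.
    """
    sub = matrix.stage_matrix(stage)
    ws = sub.form_samples("WS")
    ds = sub.form_samples("DS")
    if len(ws) < 2 or len(ds) < 2:
        raise ValueError(f"stage {stage}: need >= 2 replicates per form")
    counts = sub.counts.to_numpy(dtype=float)
    sf = size_factors(counts)
    norm = counts / sf
    cols = list(sub.counts.columns)
    iws = np.array([cols.index(s) for s in ws])
    ids = np.array([cols.index(s) for s in ds])
    alpha = estimate_dispersions(norm, [iws, ids])

    m_ws = norm[:, iws].mean(axis=1)
    m_ds = norm[:, ids].mean(axis=1)
    base_mean = norm.mean(axis=1)

    # delta-method variance of a group mean of normalized counts
    def mean_var(m: np.ndarray, idx: np.ndarray) -> np.ndarray:
        inv_sf = (1.0 / sf[idx]).sum()
        n = len(idx)
        return (m * inv_sf + alpha * m**2 * n) / n**2

    eps = ZERO_GROUP_PSEUDO
    mw = np.maximum(m_ws, eps)
    md = np.maximum(m_ds, eps)
    # difference of logs so a form-label swap negates the estimate exactly
    lfc = np.log2(mw) - np.log2(md)
    var_log = mean_var(mw, iws) / mw**2 + mean_var(md, ids) / md**2
    se = np.sqrt(var_log) / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    both_zero = (m_ws == 0) & (m_ds == 0)
    lfc[both_zero] = 0.0
    p[both_zero] = 1.0
    p = np.clip(p, 0.0, 1.0)
    padj = bh_adjust(p)
    return [
        DEResult(feature=f, stage=stage, base_mean=float(b),
                 log2fc=float(l), p=float(pp), padj=float(q))
        for f, b, l, pp, q in zip(sub.counts.index, base_mean, lfc, p, padj)
    ]


def de_all_stages(matrix: ExpressionMatrix) -> dict[str, list[DEResult]]:
    """Run the Wald test at every stage present in the metadata."""
    stages = list(dict.fromkeys(matrix.meta["stage"]))
    return {st: nb_wald_test(matrix, st) for st in stages}


def call_deg(
    results,
    padj_threshold: float = 0.05,
    lfc_threshold: float = 0.0,
    direction: str = "both",
) -> set[str]:
    """Features with padj < threshold and |log2FC| > threshold (strict).

    ``direction``: "both" (|log2FC|), "up" (higher in WS: log2FC > thr) or
    "down" (higher in DS: log2FC < -thr).
    """
    out = set()
    for r in results:
        if not r.padj < padj_threshold:
            continue
        if direction == "both":
            ok = abs(r.log2fc) > lfc_threshold
        elif direction == "up":
            ok = r.log2fc > lfc_threshold
        elif direction == "down":
            ok = r.log2fc < -lfc_threshold
        else:
            raise ValueError(f"unknown direction {direction!r}")
        if ok:
            out.add(r.feature)
    return out


def results_to_frame(results) -> pd.DataFrame:
    """Stable-order results table (feature id ascending)."""
    rows = [
        {
            "feature": r.feature, "stage": r.stage, "baseMean": r.base_mean,
            "log2FC": r.log2fc, "p": r.p, "padj": r.padj,
        }
        for r in sorted(results, key=lambda r: r.feature)
    ]
    return pd.DataFrame(rows, columns=["feature", "stage", "baseMean", "log2FC", "p", "padj"])
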