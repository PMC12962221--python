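"""Quantitative evaluation: nRMSE, SSIM, ROI statistics, agreement plots.

Metrics are computed inside an evaluation mask (object support); the
background is excluded.  nRMSE follows the convention
``100 · ‖q̂ − q‖₂ / ‖q‖₂`` (percent); SSIM uses the canonical
Gaussian-weighted window (σ = 1.5) with the data range taken from the
reference within the mask, computed slice-wise and averaged over masked
voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity

from .signal import QMapVolume

__all__ = [
    "nrmse",
    "ssim_metric",
    "bland_altman",
    "roi_means",
    "roi_regression",
    "EvaluationReport",
    "evaluate_maps",
    "compare_methods_report",
]

MAP_NAMES = ("i0", "t1f", "f", "kf")


class UndefinedMetricError(ValueError):
    pass


def nrmse(estimate, reference, mask=None) -> float:
    """Normalized root-mean-square error in percent."""
    est = np.asarray(estimate, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        est, ref = est[m], ref[m]
    denom = np.linalg.norm(ref)
    if denom == 0:
        raise UndefinedMetricError("reference is identically zero within the mask")
    return float(100.0 * np.linalg.norm(est - ref) / denom)


def ssim_metric(estimate, reference, mask=None, sigma: float = 1.5) -> float:
    """Mean SSIM over masked voxels, slice-wise over the last axis.

    Uses the canonical Gaussian-weighted window (σ = 1.5, 11×11 support)
    with population covariances; the data range is the reference range
    within the mask.  Border voxels inside the filter radius are excluded
    from the average, matching the reference implementation's cropping.
    """
    est = np.asarray(estimate, dtype=float)
    ref = np.asarray(reference, dtype=float)
    m = np.ones_like(ref, dtype=bool) if mask is None else np.asarray(mask, bool)
    ref_in = ref[m]
    drange = float(ref_in.max() - ref_in.min())
    if drange == 0:
        raise UndefinedMetricError("flat reference within the mask")
    if est.ndim == 2:
        est, ref, m = est[..., None], ref[..., None], m[..., None]
    pad = int(3.5 * sigma + 0.5)
    vals = []
    for z in range(ref.shape[-1]):
        mz = m[..., z].copy()
        mz[:pad], mz[-pad:], mz[:, :pad], mz[:, -pad:] = False, False, False, False
        if not mz.any():
            mz = m[..., z]  # image smaller than the filter support: keep all
        if not mz.any():
            continue
        _, smap = structural_similarity(
            ref[..., z],
            est[..., z],
            gaussian_weights=True,
            sigma=sigma,
            use_sample_covariance=False,
            data_range=drange,
            full=True,
        )
        vals.append(smap[mz])
    if not vals:
        raise UndefinedMetricError("mask empty after border cropping")
    return float(np.mean(np.concatenate(vals)))


def bland_altman(estimates, references) -> dict:
    """Agreement between paired values: bias and 95% limits of agreement."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("paired vectors must have equal length")
    diff = est - ref
    bias = float(diff.mean())
    sd = float(diff.std(ddof=0))
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "mean": ((est + ref) / 2.0).tolist(),
        "diff": diff.tolist(),
    }


def roi_means(volume, labels, roi_ids=None) -> dict:
    """Mean of ``volume`` within each label; absent labels map to NaN."""
    vol = np.asarray(volume, dtype=float)
    lab = np.asarray(labels)
    if roi_ids is None:
        roi_ids = sorted(int(v) for v in np.unique(lab) if v != 0)
    out = {}
    for rid in roi_ids:
        m = lab == rid
        out[int(rid)] = float(vol[m].mean()) if m.any() else float("nan")
    return out


def roi_regression(estimate_means, reference_means) -> dict:
    """OLS of estimates on references: slope, intercept, R² (squared
    Pearson correlation)."""
    x = np.asarray(reference_means, dtype=float)
    y = np.asarray(estimate_means, dtype=float)
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
    }


@dataclass
class EvaluationReport:
    table: pd.DataFrame

    def to_csv(self, path):
        self.table.to_csv(path, index=False)

    def to_json(self, path):
        self.table.to_json(path, orient="records", indent=1)


def evaluate_maps(
    estimate: QMapVolume,
    reference: QMapVolume,
    mask,
    labels=None,
    maps=MAP_NAMES,
) -> dict:
    """Per-map metric dict (nRMSE %, SSIM, and ROI statistics if labeled)."""
    out = {}
    for name in maps:
        entry = {
            "nrmse_pct": nrmse(estimate[name], reference[name], mask),
            "ssim": ssim_metric(estimate[name], reference[name], mask),
        }
        if labels is not None:
            est_m = roi_means(estimate[name], labels)
            ref_m = roi_means(reference[name], labels)
            ids = sorted(est_m)
            ev = [est_m[i] for i in ids]
            rv = [ref_m[i] for i in ids]
            entry["roi_means_estimate"] = est_m
            entry["roi_means_reference"] = ref_m
            if len(ids) >= 2:
                entry["regression"] = roi_regression(ev, rv)
                ba = bland_altman(ev, rv)
                entry["bland_altman"] = {
                    k: ba[k] for k in ("bias", "loa_low", "loa_high")
                }
        out[name] = entry
    return out


def compare_methods_report(
    methods, reference: QMapVolume, mask, labels=None, maps=MAP_NAMES
) -> EvaluationReport:
    """Tidy metric table for ``methods = [(name, QMapVolume), ...]``.

    One row per (method, map); stable ordering as given.
    """
    rows = []
    for mname, est in methods:
        metrics = evaluate_maps(est, reference, mask, labels=labels, maps=maps)
        for pname in maps:
            e = metrics[pname]
            row = {
                "method": mname,
                "map": pname,
                "nrmse_pct": e["nrmse_pct"],
                "ssim": e["ssim"],
            }
            if "regression" in e:
                row.update(
                    {
                        "slope": e["regression"]["slope"],
                        "intercept": e["regression"]["intercept"],
                        "r2": e["regression"]["r2"],
                        "ba_bias": e["bland_altman"]["bias"],
                        "ba_loa_low": e["bland_altman"]["loa_low"],
                        "ba_loa_high": e["bland_altman"]["loa_high"],
                    }
                )
            rows.append(row)
    return EvaluationReport(pd.DataFrame(rows))


def plot_bland_altman(ax, estimates, references, title=""):
    """Agreement plot: differences vs means, bias and 95% limits."""
    ba = bland_altman(estimates, references)
    ax.scatter(ba["mean"], ba["diff"], s=18)
    ax.axhline(ba["bias"], color="k")
    ax.axhline(ba["loa_low"], color="k", linestyle="--")
    ax.axhline(ba["loa_high"], color="k", linestyle="--")
    ax.set_xlabel("mean of estimate and reference")
    ax.set_ylabel("difference")
    ax.set_title(title)
    return ax


def plot_roi_regression(ax, estimates, references, title=""):
    reg = roi_regression(estimates, references)
    x = np.asarray(references, dtype=float)
    ax.scatter(x, estimates, s=24)
    xs = np.linspace(x.min(), x.max(), 10)
    ax.plot(xs, reg["slope"] * xs + reg["intercept"], "r-")
    ax.plot(xs, xs, "k--", linewidth=0.8)
    ax.set_xlabel("reference")
    ax.set_ylabel("estimate")
    ax.set_title(f"{title} R²={reg['r2']:.3f}")
    return ax
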