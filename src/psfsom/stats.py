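"""Shrinkage t-tests and FDR control for differential sink activity.

With few samples per class, per-sink variance estimates are noisy; the
two-sample t-statistic used here therefore shrinks each sink's pooled
variance towards the median pooled variance across all sinks, with a
data-driven shrinkage intensity in the spirit of the Opgen-Rhein/Strimmer
"shrinkage t".  Multiple testing is controlled with Benjamini-Hochberg
q-values, and a sink is called significant when both p < 0.05 and q < 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA_P = 0.05
ALPHA_Q = 0.2


@dataclass
class ShrinkageResult:
    t: np.ndarray
    p: np.ndarray
    pooled_var: np.ndarray
    shrunk_var: np.ndarray
    lam: float
    df: int


def shrinkage_t(group_a: np.ndarray, group_b: np.ndarray) -> ShrinkageResult:
    """Shrinkage two-sample t-statistics, one per row (sink).

    ``group_a``/``group_b`` are sink x sample arrays.  The per-sink pooled
    variance v_k is shrunk towards the across-sink median v_med:

        v*_k = lam * v_med + (1 - lam) * v_k,
        lam  = min(1, sum_k Var-hat(v_k) / sum_k (v_k - v_med)^2),

    where Var-hat(v_k) is the usual unbiased estimate of the sampling
    variance of a sample variance, computed from the pooled within-group
    squared residuals.  t_k = (mean_a - mean_b) / sqrt(v*_k (1/n_a + 1/n_b))
    with a two-sided p-value on n_a + n_b - 2 degrees of freedom.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if b.ndim == 1:
        b = b[None, :]
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 samples")
    df = n_a + n_b - 2

    resid = np.concatenate([a - a.mean(axis=1, keepdims=True),
                            b - b.mean(axis=1, keepdims=True)], axis=1)
    pooled = (resid ** 2).sum(axis=1) / df

    # sampling variance of each pooled variance, from the squared residuals
    n = n_a + n_b
    w = resid ** 2
    wbar = w.mean(axis=1, keepdims=True)
    var_hat = n / (n - 1) ** 3 * ((w - wbar) ** 2).sum(axis=1)

    v_med = float(np.median(pooled))
    denom = ((pooled - v_med) ** 2).sum()
    lam = 1.0 if denom == 0 else min(1.0, float(var_hat.sum()) / denom)
    shrunk = lam * v_med + (1.0 - lam) * pooled

    se = np.sqrt(shrunk * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (a.mean(axis=1) - b.mean(axis=1)) / se, 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return ShrinkageResult(t, p, pooled, shrunk, lam, df)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_psf(
    psf: pd.DataFrame,
    sheet: pd.DataFrame,
    disease_label: str,
    healthy_label: str,
    alpha_p: float = ALPHA_P,
    alpha_q: float = ALPHA_Q,
) -> pd.DataFrame:
    """Differential sink activity of one disease class versus controls.

    Works on log2 PSF.  ``delta`` is the mean log2 PSF of the disease class
    minus that of the healthy class (a log fold difference of pathway
    activity); t/p come from :func:`shrinkage_t` across all sinks jointly
    and q from BH.  ``significant`` is the double criterion
    (p < ``alpha_p``) and (q < ``alpha_q``).
    """
    cols = {
        label: sheet.loc[sheet["class_label"] == label, "sample_id"]
        .pipe(lambda s: [c for c in s if c in psf.columns])
        for label in (disease_label, healthy_label)
    }
    for label, cc in cols.items():
        if not cc:
            raise ValueError(f"class {label!r} absent from the PSF matrix")

    log_psf = np.log2(psf)
    a = log_psf[cols[disease_label]].to_numpy()
    b = log_psf[cols[healthy_label]].to_numpy()
    res = shrinkage_t(a, b)
    q = fdr_adjust(res.p)
    out = pd.DataFrame(
        {
            "sink_id": psf.index,
            "delta": a.mean(axis=1) - b.mean(axis=1),
            "t_shrink": res.t,
            "p_value": res.p,
            "q_value": q,
        }
    )
    out["significant"] = (out["p_value"] < alpha_p) & (out["q_value"] < alpha_q)
    return out


def differential_all_classes(
    psf: pd.DataFrame,
    sheet: pd.DataFrame,
    healthy_label: str,
    alpha_p: float = ALPHA_P,
    alpha_q: float = ALPHA_Q,
) -> dict[str, pd.DataFrame]:
    """Run :func:`differential_psf` for every non-control class."""
    out = {}
    for label in sorted(sheet["class_label"].unique()):
        if label == healthy_label:
            continue
        out[label] = differential_psf(
            psf, sheet, label, healthy_label, alpha_p=alpha_p, alpha_q=alpha_q
        )
    return out
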