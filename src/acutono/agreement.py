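"""Agreement between device and reference tonometer.

Two complementary views: an ordinary least-squares regression of prediction
on reference (the slope measures sensitivity, R the strength of the
correlation), and a Bland-Altman analysis of the differences, summarised as
bias and expanded measurement uncertainty U = k_p * SD(differences) with
coverage factor k_p = 2 (~95% coverage).  Differences are oriented
prediction - reference.  Tonometer approval requires U below 5 mm Hg
against the reference; the report states whether that limit is met.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import AgreementReport

__all__ = ["regression_analysis", "bland_altman", "ensemble_agreement", "plot_agreement"]

ISO_LIMIT_MMHG = 5.0


def regression_analysis(
    reference: np.ndarray, prediction: np.ndarray
) -> Tuple[float, float, float]:
    """OLS of prediction on reference: (slope, intercept, Pearson R)."""
    reference = np.asarray(reference, dtype=float)
    prediction = np.asarray(prediction, dtype=float)
    if reference.size != prediction.size or reference.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(reference) < 1e-15:
        raise ValueError("degenerate input: reference values are constant")
    fit = stats.linregress(reference, prediction)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


def bland_altman(
    reference: np.ndarray, prediction: np.ndarray, k_p: float = 2.0
) -> AgreementReport:
    """Bland-Altman report with expanded uncertainty U = k_p * SD(differences).

    The coverage factor is applied exactly as given (2.0, not the Gaussian
    1.96); the SD uses the n-1 sample denominator.
    """
    reference = np.asarray(reference, dtype=float)
    prediction = np.asarray(prediction, dtype=float)
    if reference.size != prediction.size or reference.size < 3:
        raise ValueError("need at least 3 paired values")
    d = prediction - reference
    bias = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    u = k_p * sd_diff
    try:
        slope, intercept, r = regression_analysis(reference, prediction)
    except ValueError:
        slope, intercept, r = np.nan, np.nan, np.nan
    return AgreementReport(
        n=int(reference.size),
        slope=slope,
        intercept=intercept,
        r=r,
        bias=bias,
        sd_diff=sd_diff,
        k_p=float(k_p),
        expanded_uncertainty=float(u),
        loa_lower=bias - u,
        loa_upper=bias + u,
        meets_iso_limit=bool(u < ISO_LIMIT_MMHG),
    )


def ensemble_agreement(ensemble, test: pd.DataFrame, k_p: float = 2.0,
                       label_column: str = "reference_iop") -> dict:
    """Per-selected-model agreement plus the averaged-prediction ensemble report.

    Returns mean and SD of the regression slope over the selected models,
    the mean per-model expanded uncertainty, and the report for the
    mean-of-models prediction (averaging over trials cannot increase the
    dispersion of the differences).
    """
    models = ensemble.selected_models
    if not models:
        raise ValueError("ensemble has no selected models")
    ref = test[label_column].to_numpy(dtype=float)
    reports = [bland_altman(ref, m.predict(test), k_p=k_p) for m in models]
    slopes = np.array([r.slope for r in reports])
    us = np.array([r.expanded_uncertainty for r in reports])
    mean_report = bland_altman(ref, ensemble.predict(test), k_p=k_p)
    return {
        "per_model": reports,
        "mean_slope": float(slopes.mean()),
        "sd_slope": float(slopes.std(ddof=1)) if slopes.size > 1 else 0.0,
        "mean_expanded_uncertainty": float(us.mean()),
        "ensemble_report": mean_report,
    }


def plot_agreement(
    reference: np.ndarray,
    prediction: np.ndarray,
    report: Optional[AgreementReport] = None,
    path=None,
):
    """Two-panel figure: regression scatter with fit line, and Bland-Altman
    scatter with bias and limit-of-agreement lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    reference = np.asarray(reference, dtype=float)
    prediction = np.asarray(prediction, dtype=float)
    if report is None:
        report = bland_altman(reference, prediction)

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 8))
    ax1.scatter(reference, prediction, s=12, alpha=0.7)
    grid = np.linspace(reference.min(), reference.max(), 50)
    ax1.plot(grid, report.slope * grid + report.intercept, "r-",
             label=f"slope {report.slope:.2f}, R {report.r:.2f}")
    ax1.plot(grid, grid, "k:", lw=0.8, label="identity")
    ax1.set_xlabel("reference IOP (mm Hg)")
    ax1.set_ylabel("device IOP (mm Hg)")
    ax1.legend()

    mean = 0.5 * (reference + prediction)
    diff = prediction - reference
    ax2.scatter(mean, diff, s=12, alpha=0.7)
    ax2.axhline(report.bias, color="r", label=f"bias {report.bias:.2f}")
    ax2.axhline(report.loa_upper, color="gray", ls="--",
                label=f"bias ± U = ±{report.expanded_uncertainty:.2f}")
    ax2.axhline(report.loa_lower, color="gray", ls="--")
    ax2.set_xlabel("mean of methods (mm Hg)")
    ax2.set_ylabel("device - reference (mm Hg)")
    ax2.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
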