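"""Morphometry summaries: box statistics and log-normal length fits.

Fibre lengths in lung tissue arise from repeated fragmentation, which
multiplies independent random factors and hence produces log-normal length
distributions; the fit here is the closed-form maximum-likelihood one
(mean and SD of the logs) with a Kolmogorov–Smirnov distance as a
goodness-of-fit figure.  Box summaries follow the Tukey convention: fences
at the quartiles ± 1.5 × the inter-quartile distance, whiskers at the most
extreme data values inside the fences, everything beyond reported
individually as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence, TYPE_CHECKING

import numpy as np
from scipy import stats as sps

if TYPE_CHECKING:  # pragma: no cover
    from .detect import ABTable

__all__ = ["BoxSummary", "LogNormalFit", "MorphometryReport",
           "box_summary", "fit_lognormal", "morphometry_report"]

#: quartile estimator used throughout (linear interpolation of order statistics)
QUARTILE_METHOD = "linear"


@dataclass
class BoxSummary:
    """Five-number box summary with Tukey fences and explicit outliers."""

    n: int
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: tuple[float, ...]
    quartile_method: str = QUARTILE_METHOD

    def to_dict(self) -> dict:
        d = asdict(self)
        d["outliers"] = list(self.outliers)
        return d


def box_summary(values: Sequence[float]) -> BoxSummary:
    """Box statistics of a sample.

    Quartiles by linear interpolation between order statistics; fences at
    q1 − 1.5·IQR and q3 + 1.5·IQR; whiskers are the extreme *data members*
    within the fences, so they always belong to the sample.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("box_summary needs at least one value")
    q1, med, q3 = np.percentile(x, [25, 50, 75], method=QUARTILE_METHOD)
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = x[(x < lo_fence) | (x > hi_fence)]
    return BoxSummary(
        n=int(x.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=float(inside.min()),
        whisker_hi=float(inside.max()),
        outliers=tuple(float(v) for v in np.sort(outliers)),
    )


@dataclass
class LogNormalFit:
    """Closed-form MLE of a log-normal and its KS goodness-of-fit distance."""

    mu_log: float
    sigma_log: float
    n: int
    gof_ks: float

    @property
    def median_um(self) -> float:
        return float(np.exp(self.mu_log))

    @property
    def mean_um(self) -> float:
        return float(np.exp(self.mu_log + self.sigma_log**2 / 2))

    def to_dict(self) -> dict:
        return asdict(self)


def fit_lognormal(values: Sequence[float]) -> LogNormalFit:
    """Fit log-normal parameters by maximum likelihood.

    µ_log and σ_log are the mean and (MLE, i.e. 1/n) SD of the log values;
    the KS distance is computed against the fitted distribution.  Reported
    as a distance, not a p-value: with estimated parameters the standard KS
    p-value would be anti-conservative anyway.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to fit a dispersion")
    if np.any(x <= 0):
        raise ValueError("log-normal fit requires strictly positive values")
    logs = np.log(x)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs, ddof=0))
    if sigma > 0:
        ks = float(sps.kstest(x, sps.lognorm(s=sigma, scale=np.exp(mu)).cdf).statistic)
    else:
        ks = float(np.mean(x != np.exp(mu)))  # degenerate: point mass
    return LogNormalFit(mu_log=mu, sigma_log=sigma, n=int(x.size), gof_ks=ks)


@dataclass
class MorphometryReport:
    """Per-sample morphometry of the accepted asbestos bodies."""

    n: int
    mean_length_um: float
    mean_width_um: float
    mean_volume_um3: float
    length_box: BoxSummary
    width_box: BoxSummary
    length_fit: LogNormalFit | None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_length_um": self.mean_length_um,
            "mean_width_um": self.mean_width_um,
            "mean_volume_um3": self.mean_volume_um3,
            "length_box": self.length_box.to_dict(),
            "width_box": self.width_box.to_dict(),
            "length_lognormal": self.length_fit.to_dict() if self.length_fit else None,
        }


def morphometry_report(ab_table: "ABTable") -> MorphometryReport:
    """Summarise accepted objects: means, box stats, log-normal length fit.

    Means are arithmetic means over accepted objects (lengths are the
    longest principal extents, widths the mean of the two shorter ones).
    The log-normal fit is skipped for fewer than two accepted objects.
    """
    accepted = ab_table.accepted
    if not accepted:
        raise ValueError("no accepted objects to summarise")
    lengths = np.array([o.length_um for o in accepted])
    widths = np.array([o.width_um for o in accepted])
    volumes = np.array([o.volume_um3 for o in accepted])
    return MorphometryReport(
        n=len(accepted),
        mean_length_um=float(lengths.mean()),
        mean_width_um=float(widths.mean()),
        mean_volume_um3=float(volumes.mean()),
        length_box=box_summary(lengths),
        width_box=box_summary(widths),
        length_fit=fit_lognormal(lengths) if len(accepted) >= 2 else None,
    )


def plot_morphometry(report: MorphometryReport, path: str) -> None:
    """Render QC box plots + length histogram to an image file (presentation
    only; no reported number depends on this)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    for ax, box, title in (
        (axes[0], report.length_box, "Length (µm)"),
        (axes[1], report.width_box, "Width (µm)"),
    ):
        stats_dict = {
            "med": box.median, "q1": box.q1, "q3": box.q3,
            "whislo": box.whisker_lo, "whishi": box.whisker_hi,
            "fliers": list(box.outliers), "label": title,
        }
        ax.bxp([stats_dict], showfliers=True)
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
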