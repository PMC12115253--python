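"""Non-compartmental metrics and prediction-error evaluation.

Model performance is judged by the prediction error of the peak concentration
and of the area under the concentration–time curve to the last observation,

.. math:: PE(\\%) = (\\mathrm{predicted}/\\mathrm{observed} - 1) \\cdot 100,

with the +/-50% interval taken as the acceptable margin.  Observed-data NCA
uses the observed sampling times only; predicted metrics are computed from the
simulation evaluated at the same times, so the comparison is grid-matched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ACCEPTABLE_MARGIN = 50.0  # percent


@dataclass(frozen=True)
class NCAMetrics:
    c_max: float  # mg/L
    t_max: float  # h
    auc_last: float  # mg*h/L


@dataclass(frozen=True)
class PEResult:
    study_id: str
    scenario: str
    pe_cmax: float  # %
    pe_auc: float  # %

    @property
    def within_margin_cmax(self) -> bool:
        return abs(self.pe_cmax) <= ACCEPTABLE_MARGIN

    @property
    def within_margin_auc(self) -> bool:
        return abs(self.pe_auc) <= ACCEPTABLE_MARGIN


@dataclass(frozen=True)
class PESummary:
    mean_pe: float
    min_pe: float
    max_pe: float
    n_studies: int
    fraction_within_margin: float


def nca(times, conc, method: str = "linear") -> NCAMetrics:
    """Cmax/Tmax and trapezoidal AUC to the last time point.

    ``method`` is ``"linear"`` (default) or ``"linuplogdown"`` (logarithmic
    trapezoid on strictly decreasing positive segments).  Ties for the maximum
    resolve to the earliest time.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.ndim != 1 or t.shape != c.shape or len(t) < 2:
        raise ValueError("need matching 1-D arrays with at least 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing (no duplicates)")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    imax = int(np.argmax(c))  # argmax returns the first (earliest) maximum
    if method == "linear":
        auc = float(np.trapezoid(c, t))
    elif method == "linuplogdown":
        auc = 0.0
        for k in range(len(t) - 1):
            dt = t[k + 1] - t[k]
            c0, c1 = c[k], c[k + 1]
            if c1 < c0 and c1 > 0:
                auc += dt * (c0 - c1) / np.log(c0 / c1)
            else:
                auc += dt * (c0 + c1) / 2.0
        auc = float(auc)
    else:
        raise ValueError(f"unknown AUC method {method!r}")
    return NCAMetrics(c_max=float(c[imax]), t_max=float(t[imax]), auc_last=auc)


def prediction_error(predicted: float, observed: float) -> float:
    """Percent prediction error, (predicted/observed - 1) * 100."""
    if observed <= 0:
        raise ValueError(f"observed metric must be positive, got {observed!r}")
    return (predicted / observed - 1.0) * 100.0


def evaluate_prediction(study_id: str, scenario: str, pred: NCAMetrics,
                        obs: NCAMetrics) -> PEResult:
    return PEResult(
        study_id=study_id, scenario=scenario,
        pe_cmax=prediction_error(pred.c_max, obs.c_max),
        pe_auc=prediction_error(pred.auc_last, obs.auc_last),
    )


def summarize(pe_values) -> PESummary:
    """Mean / min–max / within-margin summary of a list of PEs (%)."""
    pe = np.asarray(list(pe_values), dtype=float)
    if pe.size == 0:
        raise ValueError("cannot summarise an empty PE list")
    return PESummary(
        mean_pe=float(pe.mean()), min_pe=float(pe.min()), max_pe=float(pe.max()),
        n_studies=int(pe.size),
        fraction_within_margin=float(np.mean(np.abs(pe) <= ACCEPTABLE_MARGIN)),
    )


def pe_margin_plot(pe_by_study: dict[str, float], path: str, title: str = "") -> None:
    """Dot plot of PE per study with the +/-50% dashed margin lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    xs = np.arange(len(pe_by_study))
    ax.scatter(xs, list(pe_by_study.values()), color="k", zorder=3)
    ax.axhline(0.0, color="k")
    for y in (ACCEPTABLE_MARGIN, -ACCEPTABLE_MARGIN):
        ax.axhline(y, color="k", linestyle="--")
    ax.set_xticks(xs, list(pe_by_study.keys()), rotation=45, ha="right")
    ax.set_ylabel("prediction error (%)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


__all__ = ["NCAMetrics", "PEResult", "PESummary", "nca", "prediction_error",
           "evaluate_prediction", "summarize", "ACCEPTABLE_MARGIN",
           "pe_margin_plot"]
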