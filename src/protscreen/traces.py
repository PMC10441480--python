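"""Fluorescence time-series quantification.

Implements the standard trace summary quantities: percent change from
baseline (dF/F0), signal-to-noise ratio, exponential decay constant and time
constant (tau = 1/lambda), half-decay time, dynamic range (Fmax/F0), and the
SNR/tau performance score.  The baseline is the mean of a configurable
window of initial samples (50 for field-stimulation recordings, 30 for KCl
assays).  Traces are assumed background-corrected upstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

#: Sentinel for metrics that cannot be computed (failed fit / censored decay).
CENSORED = float("nan")

DEFAULT_BASELINE_WINDOW = 50
KCL_BASELINE_WINDOW = 30


@dataclass
class FluorescenceTrace:
    times: np.ndarray
    intensities: np.ndarray
    baseline_window: int = DEFAULT_BASELINE_WINDOW

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if not 0 < self.baseline_window < self.times.size:
            raise ValueError("baseline_window must be in (0, trace length)")

    @property
    def f0(self) -> float:
        """Baseline mean intensity."""
        return float(self.intensities[: self.baseline_window].mean())

    @property
    def baseline_sd(self) -> float:
        return float(self.intensities[: self.baseline_window].std(ddof=1))

    @property
    def peak_index(self) -> int:
        """Index of the response peak, searched after the baseline window
        (the baseline precedes the event trigger)."""
        w = self.baseline_window
        return w + int(np.argmax(self.intensities[w:]))

    @property
    def fmax(self) -> float:
        return float(self.intensities[self.peak_index])


@dataclass(frozen=True)
class TraceMetrics:
    f0: float
    fmax: float
    dff_max: float  # percent
    snr: float
    lambda_: float  # 1/s
    tau: float  # s
    half_decay_time: float  # s
    dynamic_range: float
    performance_score: float  # 1/s

    def as_dict(self) -> dict[str, float]:
        return {
            "f0": self.f0,
            "fmax": self.fmax,
            "dff_max": self.dff_max,
            "snr": self.snr,
            "lambda": self.lambda_,
            "tau": self.tau,
            "half_decay_time": self.half_decay_time,
            "dynamic_range": self.dynamic_range,
            "performance_score": self.performance_score,
        }


def compute_dff(f: float, f0: float) -> float:
    """Percent fluorescence change from baseline: (f - f0)/f0 * 100."""
    if f0 <= 0:
        raise ValueError(f"baseline must be positive, got {f0}")
    return (f - f0) / f0 * 100.0


def compute_snr(trace: FluorescenceTrace) -> float:
    """(Fmax - F0) / sd(baseline samples), sample sd (ddof=1)."""
    sd = trace.baseline_sd
    if sd == 0:
        raise ValueError("zero baseline standard deviation")
    return (trace.fmax - trace.f0) / sd


def fit_decay(
    trace: FluorescenceTrace, *, method: str = "loglinear", fit_floor: float = 0.05
) -> tuple[float, float]:
    """Fit the post-peak decay F(t) = e^{-lambda t} with the peak normalized
    to 1.0 and t = 0 at the peak.

    The decay is fit on the baseline-subtracted change in fluorescence, so a
    trace relaxing back to its baseline (not to zero) is handled correctly.
    ``method="loglinear"`` (default) is least squares on log-transformed
    values; ``method="nonlinear"`` uses scipy curve_fit.  Returns
    (lambda_, tau) with tau = 1/lambda; a failed fit (lambda <= 0) returns
    NaN sentinels.
    """
    ip = trace.peak_index
    f0 = trace.f0
    peak_delta = trace.intensities[ip] - f0
    if peak_delta <= 0:
        raise ValueError("no response above baseline; cannot fit a decay")
    t = trace.times[ip:] - trace.times[ip]
    f = (trace.intensities[ip:] - f0) / peak_delta
    if t.size < 3:
        raise ValueError("need >= 3 samples from the peak to fit a decay")
    if method == "loglinear":
        # samples below the floor are noise-dominated and would bias the
        # log-transformed fit; they are excluded, not an error
        ok = f > max(fit_floor, 1e-12)
        if not ok.all():
            logger.info("excluding %d below-floor samples from decay fit", int((~ok).sum()))
        if ok.sum() < 3:
            raise ValueError("fewer than 3 positive samples in the fit window")
        # least squares for log f = -lambda t (zero intercept at the peak)
        tt, lf = t[ok], np.log(f[ok])
        A = np.column_stack([tt, np.ones_like(tt)])
        (slope, _), *_ = np.linalg.lstsq(A, lf, rcond=None)
        lam = -float(slope)
    elif method == "nonlinear":
        try:
            (lam,), _ = optimize.curve_fit(
                lambda tt, l: np.exp(-l * tt), t, f, p0=[1.0], maxfev=10000
            )
            lam = float(lam)
        except RuntimeError:
            lam = -1.0
    else:
        raise ValueError(f"unknown fit method {method!r}")
    if lam <= 0:
        logger.warning("decay fit failed (lambda=%.4g <= 0)", lam)
        return CENSORED, CENSORED
    return lam, 1.0 / lam


def half_decay_time(trace: FluorescenceTrace) -> float:
    """Time from the peak to half-maximal dF/F0, linearly interpolated.

    Returns the NaN censoring sentinel if the trace never decays to
    half-max after the peak.
    """
    f0 = trace.f0
    dff = (trace.intensities - f0) / f0 * 100.0
    ip = trace.peak_index
    half = dff[ip] / 2.0
    post = dff[ip:]
    below = np.nonzero(post <= half)[0]
    if below.size == 0:
        logger.warning("trace never reaches half-max after peak; censored")
        return CENSORED
    j = below[0]
    t_post = trace.times[ip:]
    if j == 0:
        return 0.0
    # interpolate between samples j-1 (above half) and j (at/below half)
    f1, f2 = post[j - 1], post[j]
    t1, t2 = t_post[j - 1], t_post[j]
    t_cross = t1 + (f1 - half) / (f1 - f2) * (t2 - t1)
    return float(t_cross - t_post[0])


def dynamic_range(trace: FluorescenceTrace) -> float:
    """Fmax / F0."""
    f0 = trace.f0
    if f0 <= 0:
        raise ValueError(f"baseline must be positive, got {f0}")
    return trace.fmax / f0


def performance_score(snr: float, tau: float) -> float:
    """SNR divided by tau: rewards large, fast responses."""
    if not tau > 0:
        raise ValueError(f"tau must be positive, got {tau}")
    return snr / tau


def compute_metrics(trace: FluorescenceTrace, *, fit_method: str = "loglinear") -> TraceMetrics:
    f0 = trace.f0
    fmax = trace.fmax
    dff_max = compute_dff(fmax, f0)
    snr = compute_snr(trace)
    lam, tau = fit_decay(trace, method=fit_method)
    t_half = half_decay_time(trace)
    dr = dynamic_range(trace)
    score = performance_score(snr, tau) if np.isfinite(tau) and tau > 0 else CENSORED
    return TraceMetrics(
        f0=f0,
        fmax=fmax,
        dff_max=dff_max,
        snr=snr,
        lambda_=lam,
        tau=tau,
        half_decay_time=t_half,
        dynamic_range=dr,
        performance_score=score,
    )


# ---------------------------------------------------------------------------
# File I/O

def read_traces(path: str | Path, baseline_window: int = DEFAULT_BASELINE_WINDOW) -> dict[str, FluorescenceTrace]:
    """Read a trace CSV (time, intensity[, roi_id]) into traces keyed by ROI."""
    df = pd.read_csv(path)
    if "roi_id" not in df.columns:
        df["roi_id"] = "roi0"
    out = {}
    for roi, grp in df.groupby("roi_id", sort=False):
        out[str(roi)] = FluorescenceTrace(
            times=grp["time"].to_numpy(),
            intensities=grp["intensity"].to_numpy(),
            baseline_window=baseline_window,
        )
    return out


def write_metrics(metrics: dict[str, TraceMetrics], path: str | Path) -> None:
    rows = [{"roi_id": roi, **m.as_dict()} for roi, m in metrics.items()]
    pd.DataFrame(rows).to_csv(path, index=False)
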