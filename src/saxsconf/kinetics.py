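"""Single-exponential fitting of plasmid-nicking time courses.

Single-turnover nicking of supercoiled plasmid approaches completion as
f(t) = A (1 - exp(-k t)) with f(0) = 0 (reactions quenched at the zero-time
control); the observed rate constant k reflects the catalytic step.  Band
volumes from gel densitometry are converted to cleaved fractions per lane
before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["TimeCourse", "ExpFit", "normalize_lanes", "fit_single_exponential",
           "read_timecourse"]


@dataclass(frozen=True)
class TimeCourse:
    """Replicated cleaved-fraction series on a shared time grid (minutes)."""

    times: np.ndarray                 # (T,), minutes, ascending
    fractions: np.ndarray             # (R, T), each in [0, 1]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        f = np.atleast_2d(np.asarray(self.fractions, float))
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fractions", f)
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be >= 0 and strictly increasing")
        if f.shape[1] != t.size:
            raise ValueError("each replicate must cover every time point")
        if np.any((f < -1e-9) | (f > 1 + 1e-9)):
            raise ValueError("fractions must lie in [0, 1]")

    @property
    def replicate_count(self) -> int:
        return self.fractions.shape[0]

    def means(self) -> np.ndarray:
        return self.fractions.mean(axis=0)

    def sds(self) -> np.ndarray:
        return self.fractions.std(axis=0, ddof=1)


@dataclass(frozen=True)
class ExpFit:
    k: float               # min^-1
    amplitude: float
    k_stderr: float
    amp_stderr: float
    residual_sd: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("rate constant must be positive")
        if not (0 < self.amplitude <= 1.2):
            raise ValueError("amplitude must lie in (0, 1.2]")


def normalize_lanes(
    band_volumes: pd.DataFrame,
    zero_time: float = 0.0,
    per_lane_ratio: bool = True,
) -> TimeCourse:
    """Convert (time_min, replicate, sc, nicked, linear) band volumes to
    cleaved fractions.

    Default: fraction cleaved = 1 - [SC/(SC+N+L)]_t / [SC/(SC+N+L)]_0 —
    the within-lane supercoiled fraction first (cancelling lane-loading and
    scanner-gain differences), then normalisation to the zero-time lane.
    ``per_lane_ratio=False`` instead ratios the raw SC band to the
    zero-time SC band.
    """
    req = {"time_min", "replicate", "sc", "nicked", "linear"}
    if not req.issubset(band_volumes.columns):
        raise ValueError(f"band table needs columns {sorted(req)}")
    df = band_volumes.copy()
    total = df[["sc", "nicked", "linear"]].sum(axis=1)
    if (total <= 0).any():
        bad = df[total <= 0].iloc[0]
        raise ValueError(f"zero total band volume in lane t={bad.time_min} "
                         f"rep={bad.replicate}")
    if (df[["sc", "nicked", "linear"]] < 0).to_numpy().any():
        raise ValueError("band volumes must be >= 0")
    df["sc_frac"] = df["sc"] / total if per_lane_ratio else df["sc"]
    times = np.sort(df["time_min"].unique())
    if zero_time not in times:
        raise ValueError(f"zero-time lane (t={zero_time}) missing")
    series = []
    for rep, sub in df.groupby("replicate"):
        sub = sub.set_index("time_min").loc[times]
        ref = sub.loc[zero_time, "sc_frac"]
        if ref <= 0:
            raise ValueError(f"replicate {rep}: zero-time supercoiled signal is 0")
        series.append(np.clip(1.0 - sub["sc_frac"].to_numpy() / ref, 0.0, 1.0))
    return TimeCourse(times, np.vstack(series))


def read_timecourse(path) -> TimeCourse:
    """Read a TSV of band volumes or pre-normalised fractions.

    Columns either (time_min, replicate, sc, nicked, linear) or
    (time_min, replicate, fraction).
    """
    df = pd.read_csv(path, sep="\t")
    if "fraction" in df.columns:
        times = np.sort(df["time_min"].unique())
        series = [
            sub.set_index("time_min").loc[times, "fraction"].to_numpy()
            for _, sub in df.groupby("replicate")
        ]
        return TimeCourse(times, np.vstack(series))
    return normalize_lanes(df)


def fit_single_exponential(tc: TimeCourse) -> ExpFit:
    """Weighted nonlinear fit of f(t) = A (1 - exp(-k t)) to replicate means.

    Weights are 1/sd^2 across replicates where the replicate count is >= 2
    and all sds are positive; otherwise the fit is unweighted.  Initial
    guesses: A0 = max mean fraction, k0 = ln 2 / t_half from the first time
    the mean crosses A0/2.
    """
    if tc.times.size < 4:
        raise ValueError("need at least 4 distinct time points")
    y = tc.means()
    t = tc.times

    def model(t_, a, k):
        return a * (1.0 - np.exp(-k * t_))

    a0 = max(float(y.max()), 1e-3)
    above = np.nonzero(y >= a0 / 2)[0]
    t_half = t[above[0]] if above.size and t[above[0]] > 0 else max(t[t > 0][0], 1e-3)
    k0 = np.log(2.0) / t_half
    sigma = None
    if tc.replicate_count >= 2:
        sd = tc.sds()
        if np.all(sd > 0):
            sigma = sd
    try:
        popt, pcov = curve_fit(
            model, t, y, p0=[a0, k0], sigma=sigma, absolute_sigma=False,
            bounds=([0.0, 1e-9], [1.2, np.inf]), maxfev=500 * (t.size + 2),
        )
    except RuntimeError as exc:
        raise RuntimeError(f"single-exponential fit did not converge: {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    resid = y - model(t, *popt)
    return ExpFit(
        k=float(popt[1]),
        amplitude=float(popt[0]),
        k_stderr=float(perr[1]),
        amp_stderr=float(perr[0]),
        residual_sd=float(resid.std(ddof=1)),
    )
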