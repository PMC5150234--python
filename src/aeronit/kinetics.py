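"""Nitrification-potential incubation analysis.

Blank-corrects the measured NH4+/NO2-/NO3- time series, computes the
maximum nitrification rate per m3 of sampled air, and checks nitrogen
mass balance (ammonia consumed vs nitrite + nitrate produced).

The rate is a two-point calculation by default, using only the first and
last net ammonia concentrations:

    NNR_max = (net_NH4[0] - net_NH4[t]) * Q1 * 1000 / (t * Q2)

with Q1 the incubation volume (l), Q2 the sampled air volume (m3) and
the factor 1000 converting mg to ug, giving ug (NH4+-N) m-3 air h-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IncubationSeries",
    "NetSeries",
    "RateResult",
    "BalanceReport",
    "net_concentrations",
    "nnr_max",
    "nitrogen_balance",
]

_ANALYTES = ("nh4", "no2", "no3")


class NegativeNetWarning(UserWarning):
    """Blank exceeded the sample at some timepoint; net values kept."""


@dataclass(frozen=True)
class IncubationSeries:
    """Timed analyte concentrations (mg/l) for a sample and its blank."""

    sample: str
    times: tuple[float, ...]
    nh4_sample: np.ndarray
    nh4_blank: np.ndarray
    no2_sample: np.ndarray
    no2_blank: np.ndarray
    no3_sample: np.ndarray
    no3_blank: np.ndarray
    q1: float = 0.25
    q2: float = 48.0

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.times)
        object.__setattr__(self, "times", t)
        if not t or t[0] != 0 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("times must start at 0 and strictly increase")
        for name in (
            "nh4_sample", "nh4_blank", "no2_sample",
            "no2_blank", "no3_sample", "no3_blank",
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(t),):
                raise ValueError(f"{name} must match the time grid")
            if (arr < 0).any():
                raise ValueError(f"{name} has negative concentrations")
            object.__setattr__(self, name, arr)
        if self.q1 <= 0 or self.q2 <= 0:
            raise ValueError("Q1 and Q2 must be > 0")

    @property
    def t_end(self) -> float:
        return self.times[-1]

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for role in ("sample", "blank"):
            for analyte in _ANALYTES:
                values = getattr(self, f"{analyte}_{role}")
                for t, v in zip(self.times, values):
                    rows.append(
                        {
                            "time_h": t,
                            "analyte": analyte,
                            "role": role,
                            "replicate": 1,
                            "value_mg_per_l": v,
                        }
                    )
        return pd.DataFrame(rows)

    @classmethod
    def from_long_frame(
        cls, df: pd.DataFrame, sample: str = "", q1: float = 0.25, q2: float = 48.0
    ) -> "IncubationSeries":
        """Build from the long CSV layout (time_h, analyte, role,
        replicate, value_mg_per_l); replicates average per timepoint."""
        times = tuple(sorted(df["time_h"].unique()))
        cols = {}
        for role in ("sample", "blank"):
            for analyte in _ANALYTES:
                sub = df[(df["analyte"] == analyte) & (df["role"] == role)]
                means = sub.groupby("time_h")["value_mg_per_l"].mean()
                if tuple(means.index) != times:
                    raise ValueError(
                        f"{analyte}/{role} does not cover the shared time grid"
                    )
                cols[f"{analyte}_{role}"] = means.to_numpy()
        return cls(sample=sample, times=times, q1=q1, q2=q2, **cols)


@dataclass(frozen=True)
class NetSeries:
    """Blank-corrected concentrations; negatives preserved and flagged."""

    sample: str
    times: tuple[float, ...]
    nh4: np.ndarray
    no2: np.ndarray
    no3: np.ndarray
    has_negative: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_h": self.times, "nh4": self.nh4, "no2": self.no2, "no3": self.no3}
        )


@dataclass(frozen=True)
class RateResult:
    sample: str
    nnr_max: float  # ug (NH4+-N) m-3 air h-1
    net_start: float  # mg/l
    net_end: float  # mg/l
    method: str = "endpoint"


@dataclass(frozen=True)
class BalanceReport:
    sample: str
    times: tuple[float, ...]
    consumed: np.ndarray  # cumulative NH4 removed, mg/l
    produced: np.ndarray  # cumulative NO2+NO3 gained, mg/l
    imbalance: np.ndarray  # |consumed - produced| / max(consumed, eps)
    balanced: bool
    tolerance: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "nh4_consumed": self.consumed,
                "nox_produced": self.produced,
                "imbalance": self.imbalance,
            }
        )


def net_concentrations(series: IncubationSeries) -> NetSeries:
    """Net (sample minus blank) concentrations per analyte and timepoint.

    Negative nets (blank above sample) are preserved, not clipped, and
    raise a :class:`NegativeNetWarning`.
    """
    nets = {a: getattr(series, f"{a}_sample") - getattr(series, f"{a}_blank")
            for a in _ANALYTES}
    has_negative = any((v < 0).any() for v in nets.values())
    if has_negative:
        warnings.warn(
            f"sample {series.sample!r}: blank exceeds sample at some "
            "timepoints; net concentrations are negative there",
            NegativeNetWarning,
            stacklevel=2,
        )
    return NetSeries(
        sample=series.sample,
        times=series.times,
        nh4=nets["nh4"],
        no2=nets["no2"],
        no3=nets["no3"],
        has_negative=has_negative,
    )


def nnr_max(
    net: NetSeries,
    q1: float,
    t: float,
    q2: float,
    method: str = "endpoint",
) -> RateResult:
    """Maximum nitrification rate in ug (NH4+-N) m-3 air h-1.

    ``method="endpoint"`` (default) uses only the 0 h and ``t`` h net
    ammonia values; ``method="regression"`` fits a least-squares slope
    over all timepoints up to ``t`` instead.
    """
    if t <= 0:
        raise ValueError("t must be > 0")
    if q1 <= 0 or q2 <= 0:
        raise ValueError("Q1 and Q2 must be > 0")
    times = np.asarray(net.times)
    if not np.isclose(times, t).any() or times[0] != 0:
        raise ValueError(f"net series must contain timepoints 0 and {t}")
    idx_end = int(np.argmin(np.abs(times - t)))
    net_start = float(net.nh4[0])
    net_end = float(net.nh4[idx_end])
    if method == "endpoint":
        rate = (net_start - net_end) * q1 * 1000.0 / (t * q2)
    elif method == "regression":
        mask = times <= t + 1e-12
        fit = stats.linregress(times[mask], net.nh4[mask])
        rate = -fit.slope * q1 * 1000.0 / q2
    else:
        raise ValueError("method must be 'endpoint' or 'regression'")
    return RateResult(
        sample=net.sample,
        nnr_max=float(rate),
        net_start=net_start,
        net_end=net_end,
        method=method,
    )


def nitrogen_balance(
    net: NetSeries, tolerance: float = 0.10, eps: float = 1e-12
) -> BalanceReport:
    """Cumulative ammonia consumed vs nitrite + nitrate produced.

    The verdict is *balanced* when the final-timepoint imbalance
    fraction |consumed - produced| / max(consumed, eps) is <= tolerance.
    """
    consumed = net.nh4[0] - net.nh4
    nox = net.no2 + net.no3
    produced = nox - nox[0]
    imbalance = np.abs(consumed - produced) / np.maximum(consumed, eps)
    return BalanceReport(
        sample=net.sample,
        times=net.times,
        consumed=consumed,
        produced=produced,
        imbalance=imbalance,
        balanced=bool(imbalance[-1] <= tolerance),
        tolerance=tolerance,
    )
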