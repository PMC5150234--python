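"""Absolute qPCR quantification.

Fits log-linear standard curves, inverts them to copies per reaction,
converts copies to cells via per-assay gene copy numbers, and normalizes
to cells per m3 of sampled air.  Quality gates (amplification efficiency
within 90-110%, R^2 >= 0.99) raise warnings, not errors, so degraded
plates still flow through.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "AssayConfig",
    "AbundanceEstimate",
    "CopiesEstimate",
    "fit_standard_curve",
    "quantify_unknowns",
    "copies_to_cells",
    "cells_per_m3",
    "abundance_summaries",
    "quantify_plate",
]

# conventional per-cell marker gene copy numbers:
# 1 amoA per AOA / comammox cell, 2.5 amoA per AOB cell,
# 3.6 16S rRNA copies per average prokaryotic cell
DEFAULT_COPIES_PER_CELL = {
    "aoa": 1.0,
    "comammox": 1.0,
    "aob": 2.5,
    "archaea": 3.6,
    "bacteria": 3.6,
}


class QpcrQualityWarning(UserWarning):
    """Standard curve outside the usual efficiency / R^2 gates."""


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line of Cq on log10(copies)."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    n_levels: int
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")

    def copies_from_cq(self, cq: float) -> float:
        return 10.0 ** ((cq - self.intercept) / self.slope)


@dataclass(frozen=True)
class AssayConfig:
    """Constants turning copies per reaction into cells per m3 air.

    ``extract_scaleup`` is the reaction -> whole-extract factor (elution
    volume / template volume), left explicit because it is lab-specific;
    ``filter_fraction`` is the fraction of the filter extracted (e.g.
    0.25 for a quarter filter); ``air_volume`` is m3 of air sampled
    (144 m3 for 100 l/min over 24 h).
    """

    target_name: str
    copies_per_cell: float
    extract_scaleup: float = 1.0
    filter_fraction: float = 0.25
    air_volume: float = 144.0

    def __post_init__(self) -> None:
        if self.copies_per_cell <= 0:
            raise ValueError("copies_per_cell must be > 0")
        if not 0 < self.filter_fraction <= 1:
            raise ValueError("filter_fraction must be in (0, 1]")
        if self.air_volume <= 0:
            raise ValueError("air_volume must be > 0")
        if self.extract_scaleup <= 0:
            raise ValueError("extract_scaleup must be > 0")


@dataclass(frozen=True)
class CopiesEstimate:
    mean: float
    sd: float
    n_replicates: int
    no_amplification: bool = False


@dataclass(frozen=True)
class AbundanceEstimate:
    """Cells per m3 of air (mean +/- sd) for one target in one sample."""

    sample: str
    target_name: str
    cells_per_m3: float
    sd: float = 0.0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.cells_per_m3 < 0 or self.sd < 0:
            raise ValueError("abundance and sd must be >= 0")


def fit_standard_curve(standards) -> StandardCurve:
    """Fit Cq = slope * log10(copies) + intercept by least squares.

    ``standards`` is an iterable of (copies, cq) pairs or a DataFrame
    with ``copies``/``cq`` columns.  Needs >= 3 distinct dilution levels.
    Efficiency = 10^(-1/slope) - 1; curves with efficiency outside
    [0.90, 1.10] or R^2 < 0.99 are flagged with a warning.
    """
    if isinstance(standards, pd.DataFrame):
        copies = standards["copies"].to_numpy(dtype=float)
        cq = standards["cq"].to_numpy(dtype=float)
    else:
        pairs = [(float(c), float(q)) for c, q in standards]
        copies = np.array([p[0] for p in pairs])
        cq = np.array([p[1] for p in pairs])
    if (copies <= 0).any():
        raise ValueError("standard copies must be > 0")
    if np.unique(copies).size < 3:
        raise ValueError("need >= 3 distinct dilution levels")
    x = np.log10(copies)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log10(copies)")
    fit = stats.linregress(x, cq)
    r2 = float(fit.rvalue**2)
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    flags = []
    if not 0.90 <= efficiency <= 1.10:
        flags.append("efficiency_out_of_range")
    if r2 < 0.99:
        flags.append("low_r_squared")
    if flags:
        warnings.warn(
            f"standard curve quality: {', '.join(flags)} "
            f"(efficiency={efficiency:.3f}, R2={r2:.4f})",
            QpcrQualityWarning,
            stacklevel=2,
        )
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=min(r2, 1.0),
        efficiency=float(efficiency),
        n_levels=int(np.unique(copies).size),
        flags=tuple(flags),
    )


def quantify_unknowns(
    curve: StandardCurve, cqs, aggregate: str = "arithmetic"
) -> CopiesEstimate:
    """Invert the standard curve for replicate Cq values.

    Each replicate converts as copies = 10^((Cq - intercept) / slope);
    NaN Cq is the no-amplification sentinel and counts as zero copies.
    Replicates are averaged on the linear copies scale by default
    (``aggregate="geometric"`` averages log-scale over amplifying
    replicates instead).  All-sentinel input yields a flagged
    zero-copies estimate.
    """
    cqs = np.atleast_1d(np.asarray(cqs, dtype=float))
    if cqs.size == 0:
        raise ValueError("need >= 1 replicate Cq")
    if aggregate not in ("arithmetic", "geometric"):
        raise ValueError("aggregate must be 'arithmetic' or 'geometric'")
    amplified = ~np.isnan(cqs)
    if not amplified.any():
        return CopiesEstimate(
            mean=0.0, sd=0.0, n_replicates=int(cqs.size), no_amplification=True
        )
    copies = np.zeros(cqs.size)
    copies[amplified] = np.array([curve.copies_from_cq(c) for c in cqs[amplified]])
    if aggregate == "geometric":
        vals = copies[amplified]
        mean = float(np.exp(np.mean(np.log(vals))))
        sd = float(np.std(np.log(vals), ddof=1) if vals.size > 1 else 0.0)
    else:
        mean = float(copies.mean())
        sd = float(copies.std(ddof=1)) if copies.size > 1 else 0.0
    return CopiesEstimate(
        mean=mean,
        sd=sd,
        n_replicates=int(cqs.size),
        no_amplification=bool((~amplified).any()),
    )


def copies_to_cells(copies: float, copies_per_cell: float) -> float:
    """Gene copies -> cell equivalents via the per-cell copy number."""
    if copies_per_cell <= 0:
        raise ValueError("copies_per_cell must be > 0")
    if copies < 0:
        raise ValueError("copies must be >= 0")
    return copies / copies_per_cell


def cells_per_m3(
    cells_in_reaction: float,
    cfg: AssayConfig,
    sample: str = "",
    sd_cells: float = 0.0,
    n_replicates: int = 1,
) -> AbundanceEstimate:
    """Scale reaction-level cell counts to cells per m3 of sampled air.

    cells_per_m3 = cells * extract_scaleup / filter_fraction / air_volume.
    """
    if cells_in_reaction < 0:
        raise ValueError("cells_in_reaction must be >= 0")
    factor = cfg.extract_scaleup / cfg.filter_fraction / cfg.air_volume
    return AbundanceEstimate(
        sample=sample,
        target_name=cfg.target_name,
        cells_per_m3=cells_in_reaction * factor,
        sd=sd_cells * factor,
        n_replicates=n_replicates,
    )


def quantify_plate(
    standards: pd.DataFrame,
    unknowns: pd.DataFrame,
    cfg: AssayConfig,
    aggregate: str = "arithmetic",
) -> list[AbundanceEstimate]:
    """Full plate pipeline: fit curve, invert unknowns per sample, scale
    to cells per m3.  ``unknowns`` needs ``sample`` and ``cq`` columns."""
    curve = fit_standard_curve(standards)
    out = []
    for sample, grp in unknowns.groupby("sample", sort=True):
        est = quantify_unknowns(curve, grp["cq"].to_numpy(), aggregate=aggregate)
        cells = copies_to_cells(est.mean, cfg.copies_per_cell)
        cells_sd = est.sd / cfg.copies_per_cell
        out.append(
            cells_per_m3(
                cells,
                cfg,
                sample=str(sample),
                sd_cells=cells_sd,
                n_replicates=est.n_replicates,
            )
        )
    return out


_RATIO_PAIRS = [
    ("ratio_aoa_aob", "aoa", "aob"),
    ("ratio_aoa_comammox", "aoa", "comammox"),
    ("ratio_aob_comammox", "aob", "comammox"),
    ("proportion_aoa_archaea", "aoa", "archaea"),
    ("proportion_aob_bacteria", "aob", "bacteria"),
]


def abundance_summaries(estimates) -> pd.DataFrame:
    """Per-sample guild ratios and proportions.

    Targets are matched case-insensitively against aoa / aob / comammox /
    archaea / bacteria.  Zero denominators and missing pair members give
    NaN (undefined), never infinity.
    """
    by_sample: dict[str, dict[str, float]] = {}
    for est in estimates:
        by_sample.setdefault(est.sample, {})[est.target_name.lower()] = (
            est.cells_per_m3
        )
    rows = []
    for sample in sorted(by_sample):
        vals = by_sample[sample]
        row: dict[str, float | str] = {"sample": sample}
        for name, num, den in _RATIO_PAIRS:
            if num not in vals or den not in vals or vals[den] == 0:
                row[name] = float("nan")
            else:
                row[name] = vals[num] / vals[den]
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")
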