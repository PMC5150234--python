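"""Partition the measured maximum nitrification rate among AOA, AOB and
comammox.

Guild-specific rates come from cell abundance times an assumed in situ
cell-specific activity r_in (fmol NH3 cell-1 h-1):

    rate_g [ug N m-3 air h-1] = cells_g * r_in_g * Mr_N * 1e-9

(1 fmol N = Mr_N fg N; 1e-9 converts fg to ug).  Relative contributions
are rate_g / NNR_max for AOA and AOB; the comammox contribution is the
remainder 1 - RC_AOA - RC_AOB.  The remainder form is an inference — no
comammox cell-specific rate is available — and a direct-rate mode is
provided for sensitivity analysis.  Heterotrophic ammonia assimilation
is ignored by design (documented assumption), with an optional
fractional discount on NNR_max for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "MR_N",
    "RinScenario",
    "AttributionInput",
    "ContributionResult",
    "DEFAULT_SCENARIOS",
    "guild_rate",
    "attribute",
    "scenario_grid",
]

MR_N = 14.0  # relative molecular mass of nitrogen, g/mol
_FG_TO_UG = 1e-9


@dataclass(frozen=True)
class RinScenario:
    """One (AOA, AOB) pair of assumed cell-specific activities."""

    r_in_aoa: float  # fmol cell-1 h-1
    r_in_aob: float  # fmol cell-1 h-1
    label: str = ""

    def __post_init__(self) -> None:
        if self.r_in_aoa <= 0 or self.r_in_aob <= 0:
            raise ValueError("cell-specific rates must be > 0")
        if not self.label:
            object.__setattr__(
                self, "label", f"AOA{self.r_in_aoa:g}_AOB{self.r_in_aob:g}"
            )


# the four published scenario combinations, low/high per guild
DEFAULT_SCENARIOS = (
    RinScenario(0.5, 1.0),
    RinScenario(0.5, 50.0),
    RinScenario(208.0, 1.0),
    RinScenario(208.0, 50.0),
)


@dataclass(frozen=True)
class AttributionInput:
    sample: str
    cells_aoa: float  # cells m-3 air
    cells_aob: float  # cells m-3 air
    nnr_max: float  # ug (NH4+-N) m-3 air h-1
    mr_n: float = MR_N
    cells_comammox: float = 0.0  # only used in direct-rate mode

    def __post_init__(self) -> None:
        if self.cells_aoa < 0 or self.cells_aob < 0 or self.cells_comammox < 0:
            raise ValueError("cell abundances must be >= 0")
        if self.nnr_max <= 0:
            raise ValueError("nnr_max must be > 0")
        if self.mr_n <= 0:
            raise ValueError("mr_n must be > 0")


@dataclass(frozen=True)
class ContributionResult:
    """Relative contributions; the reported triple sums to 1 exactly.

    ``raw_*`` keep the unclamped fractions.  When raw AOA + AOB exceed
    1, the pair is rescaled proportionally to sum to 1, comammox is 0
    and ``clamped`` is set.
    """

    sample: str
    scenario: str
    rc_aoa: float
    rc_aob: float
    rc_comammox: float
    raw_aoa: float
    raw_aob: float
    raw_comammox: float
    clamped: bool

    def __post_init__(self) -> None:
        total = self.rc_aoa + self.rc_aob + self.rc_comammox
        if abs(total - 1.0) > 1e-12:
            raise ValueError("reported contributions must sum to 1")
        for v in (self.rc_aoa, self.rc_aob, self.rc_comammox):
            if not -1e-15 <= v <= 1 + 1e-12:
                raise ValueError("reported contributions must lie in [0, 1]")


def guild_rate(cells: float, r_in: float, mr_n: float = MR_N) -> float:
    """Guild ammonia-oxidation rate in ug (NH4+-N) m-3 air h-1."""
    if cells < 0 or r_in < 0 or mr_n <= 0:
        raise ValueError("cells and r_in must be >= 0, mr_n > 0")
    return cells * r_in * mr_n * _FG_TO_UG


def attribute(
    inp: AttributionInput,
    scen: RinScenario,
    r_in_comammox: float | None = None,
    heterotroph_discount: float = 0.0,
) -> ContributionResult:
    """Relative guild contributions for one sample under one scenario.

    Default mode treats comammox as the remainder.  Passing
    ``r_in_comammox`` switches to direct-rate mode: all three guild
    rates are computed and the triple is normalized to sum to 1.
    ``heterotroph_discount`` removes that fraction of NNR_max before
    partitioning (default 0: assimilation ignored).
    """
    if not 0 <= heterotroph_discount < 1:
        raise ValueError("heterotroph_discount must be in [0, 1)")
    available = inp.nnr_max * (1.0 - heterotroph_discount)
    raw_aoa = guild_rate(inp.cells_aoa, scen.r_in_aoa, inp.mr_n) / available
    raw_aob = guild_rate(inp.cells_aob, scen.r_in_aob, inp.mr_n) / available

    if r_in_comammox is not None:
        raw_com = guild_rate(inp.cells_comammox, r_in_comammox, inp.mr_n) / available
        total = raw_aoa + raw_aob + raw_com
        if total <= 0:
            raise ValueError("all guild rates are zero in direct-rate mode")
        return ContributionResult(
            sample=inp.sample,
            scenario=scen.label,
            rc_aoa=raw_aoa / total,
            rc_aob=raw_aob / total,
            rc_comammox=1.0 - raw_aoa / total - raw_aob / total,
            raw_aoa=raw_aoa,
            raw_aob=raw_aob,
            raw_comammox=raw_com,
            clamped=abs(total - 1.0) > 1e-12,
        )

    raw_com = 1.0 - raw_aoa - raw_aob
    if raw_aoa + raw_aob > 1.0:
        scale = 1.0 / (raw_aoa + raw_aob)
        rc_aoa, rc_aob = raw_aoa * scale, raw_aob * scale
        rc_aob = 1.0 - rc_aoa  # absorb rounding so the triple is exact
        return ContributionResult(
            sample=inp.sample,
            scenario=scen.label,
            rc_aoa=rc_aoa,
            rc_aob=rc_aob,
            rc_comammox=0.0,
            raw_aoa=raw_aoa,
            raw_aob=raw_aob,
            raw_comammox=raw_com,
            clamped=True,
        )
    return ContributionResult(
        sample=inp.sample,
        scenario=scen.label,
        rc_aoa=raw_aoa,
        rc_aob=raw_aob,
        rc_comammox=raw_com,
        raw_aoa=raw_aoa,
        raw_aob=raw_aob,
        raw_comammox=raw_com,
        clamped=False,
    )


def scenario_grid(
    inp: AttributionInput,
    extra_scenarios=(),
    **attribute_kwargs,
) -> pd.DataFrame:
    """Contributions across the four default scenarios plus any extras.

    Returns a long-format table (sample, scenario, guild, rc_raw,
    rc_reported, clamped), one block of three guild rows per scenario.
    """
    rows = []
    for scen in tuple(DEFAULT_SCENARIOS) + tuple(extra_scenarios):
        res = attribute(inp, scen, **attribute_kwargs)
        for guild, raw, reported in (
            ("AOA", res.raw_aoa, res.rc_aoa),
            ("AOB", res.raw_aob, res.rc_aob),
            ("comammox", res.raw_comammox, res.rc_comammox),
        ):
            rows.append(
                {
                    "sample": inp.sample,
                    "scenario": scen.label,
                    "guild": guild,
                    "rc_raw": raw,
                    "rc_reported": reported,
                    "clamped": res.clamped,
                }
            )
    return pd.DataFrame(rows)
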