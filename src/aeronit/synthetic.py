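"""Seeded generators for every input the pipeline consumes.

Each generator takes a frozen spec (loadable from YAML) carrying its own
seed, and returns both the simulated measurement tables and the ground
truth needed to test downstream stages.  Identical spec + seed yields
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .community import SequenceRecord

__all__ = [
    "ClusterSpec",
    "CommunitySpec",
    "QpcrPlateSpec",
    "IncubationSpec",
    "EnvTableSpec",
    "QpcrPlate",
    "IncubationTruth",
    "generate_sequences",
    "generate_qpcr_plate",
    "generate_incubation",
    "generate_env_table",
]

_BASES = "ACGT"

# molar mass of nitrogen; 1 fmol NH4+-N = MR_N * 1e-9 ug N
MR_N = 14.0
FMOL_TO_UG = MR_N * 1e-9


def _from_yaml(cls, path_or_str):
    if hasattr(path_or_str, "read"):
        data = yaml.safe_load(path_or_str.read())
    else:
        try:
            with open(path_or_str) as fh:
                data = yaml.safe_load(fh)
        except (OSError, ValueError):
            data = yaml.safe_load(path_or_str)
    return cls.from_dict(data)


@dataclass(frozen=True)
class ClusterSpec:
    label: str
    centroid_length: int
    within_divergence: float
    abundances: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "abundances", tuple(int(a) for a in self.abundances))
        if self.centroid_length < 100:
            raise ValueError(f"cluster {self.label!r}: length must be >= 100 nt")
        if self.within_divergence < 0:
            raise ValueError("within_cluster_divergence must be >= 0")
        if any(a < 0 for a in self.abundances):
            raise ValueError("abundances must be >= 0")


@dataclass(frozen=True)
class CommunitySpec:
    """Clustered sequence community with known OTU structure."""

    n_samples: int
    clusters: tuple[ClusterSpec, ...]
    between_divergence: float
    seed: int

    def __post_init__(self) -> None:
        clusters = tuple(
            c if isinstance(c, ClusterSpec) else ClusterSpec(**c) for c in self.clusters
        )
        object.__setattr__(self, "clusters", clusters)
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not clusters:
            raise ValueError("need at least one cluster")
        labels = [c.label for c in clusters]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate cluster labels")
        for c in clusters:
            if len(c.abundances) != self.n_samples:
                raise ValueError(
                    f"cluster {c.label!r}: abundances must have n_samples entries"
                )

    def validate_separable(self, cutoff: float = 0.03) -> None:
        """Reject divergence settings that complete-linkage clustering at
        ``cutoff`` could not resolve into the planted clusters."""
        w_max = max(c.within_divergence for c in self.clusters)
        if len(self.clusters) > 1 and not (
            self.between_divergence > cutoff + 2 * w_max
        ):
            raise ValueError(
                "clusters not separable: between_cluster_divergence "
                f"({self.between_divergence}) must exceed cutoff ({cutoff}) "
                f"+ 2 x within_cluster_divergence ({w_max})"
            )
        for c in self.clusters:
            n_mut = round(c.within_divergence / 2 * c.centroid_length)
            if 2 * n_mut > cutoff * c.centroid_length:
                raise ValueError(
                    f"cluster {c.label!r}: within-cluster pairs may exceed the "
                    f"clustering cutoff {cutoff}; reduce within_cluster_divergence"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "CommunitySpec":
        return cls(
            n_samples=d["n_samples"],
            clusters=tuple(ClusterSpec(**c) for c in d["clusters"]),
            between_divergence=d["between_divergence"],
            seed=d["seed"],
        )

    @classmethod
    def from_yaml(cls, src) -> "CommunitySpec":
        return _from_yaml(cls, src)


def _mutate(seq: np.ndarray, sites: np.ndarray, rng: np.random.Generator) -> None:
    # substitute each site with one of the 3 other bases, uniformly
    shift = rng.integers(1, 4, size=sites.size)
    seq[sites] = (seq[sites] + shift) % 4


def generate_sequences(
    spec: CommunitySpec, cutoff: float = 0.03
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Simulate clone-library sequences with planted cluster structure.

    Cluster centroids are derived from one ancestral sequence by mutating
    disjoint site sets of size round(between_divergence * L / 2), so any
    two centroids differ at ~between_divergence of sites.  Each sequence
    mutates exactly round(within_divergence * L / 2) sites away from its
    centroid (substitutions only, no indels), keeping within-cluster
    pairwise distances <= within_divergence deterministically.

    Returns ``(records, truth)`` where truth maps each sequence id to its
    sample and planted cluster.
    """
    spec.validate_separable(cutoff=cutoff)
    rng = np.random.default_rng(spec.seed)
    lengths = [c.centroid_length for c in spec.clusters]
    l_max, l_min = max(lengths), min(lengths)

    site_budget = sum(
        round(spec.between_divergence / 2 * c.centroid_length) for c in spec.clusters
    )
    if len(spec.clusters) > 1 and site_budget > l_min:
        raise ValueError(
            "clusters not separable: too many clusters for the requested "
            "between_cluster_divergence and sequence length"
        )

    base = rng.integers(0, 4, size=l_max)
    pool = rng.permutation(l_min)
    centroids = {}
    offset = 0
    for c in spec.clusters:
        cent = base[: c.centroid_length].copy()
        if len(spec.clusters) > 1:
            m = round(spec.between_divergence / 2 * c.centroid_length)
            sites = pool[offset : offset + m]
            offset += m
            _mutate(cent, sites, rng)
        centroids[c.label] = cent

    samples = [f"S{i + 1}" for i in range(spec.n_samples)]
    records: list[SequenceRecord] = []
    truth_rows = []
    base_arr = np.frombuffer(_BASES.encode(), dtype="S1")
    for c in spec.clusters:
        n_mut = round(c.within_divergence / 2 * c.centroid_length)
        for s_idx, sample in enumerate(samples):
            for k in range(c.abundances[s_idx]):
                seq = centroids[c.label].copy()
                if n_mut:
                    sites = rng.choice(c.centroid_length, size=n_mut, replace=False)
                    _mutate(seq, sites, rng)
                sid = f"{sample}|{c.label}|{k + 1}"
                bases = base_arr[seq].tobytes().decode()
                records.append(SequenceRecord(id=sid, sample=sample, bases=bases))
                truth_rows.append(
                    {"seq_id": sid, "sample": sample, "cluster": c.label}
                )
    truth = pd.DataFrame(truth_rows, columns=["seq_id", "sample", "cluster"])
    return records, truth


NO_AMPLIFICATION = float("nan")  # Cq sentinel for zero-template reactions


@dataclass(frozen=True)
class QpcrPlateSpec:
    """Standards + unknowns plate with a log-linear Cq response."""

    true_slope: float
    true_intercept: float
    dilution_top: float
    dilution_levels: int
    unknown_true_copies: dict[str, float]
    cq_noise_sd: float = 0.0
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "unknown_true_copies", dict(self.unknown_true_copies)
        )
        if self.true_slope >= 0:
            raise ValueError("true_slope must be negative")
        if self.dilution_levels < 4:
            raise ValueError("dilution_levels must be >= 4")
        if self.cq_noise_sd < 0:
            raise ValueError("cq_noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.dilution_top <= 0:
            raise ValueError("dilution_top must be > 0")
        if any(v < 0 for v in self.unknown_true_copies.values()):
            raise ValueError("unknown_true_copies must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "QpcrPlateSpec":
        return cls(**d)

    @classmethod
    def from_yaml(cls, src) -> "QpcrPlateSpec":
        return _from_yaml(cls, src)


@dataclass(frozen=True)
class QpcrPlate:
    """Simulated plate: standards and unknowns tables plus truth sidecar."""

    standards: pd.DataFrame  # copies, replicate, cq
    unknowns: pd.DataFrame  # sample, replicate, cq, no_amplification
    truth: pd.DataFrame  # sample, true_copies

    def to_plate_frame(self, target: str = "target") -> pd.DataFrame:
        """Single long-format plate table (well, role, sample, target,
        copies, cq) as written/read by the CLI."""
        rows = []
        well = 1
        for _, r in self.standards.iterrows():
            rows.append(
                {
                    "well": f"W{well}",
                    "role": "standard",
                    "sample": f"std_{r['copies']:.3g}",
                    "target": target,
                    "copies": r["copies"],
                    "cq": r["cq"],
                }
            )
            well += 1
        for _, r in self.unknowns.iterrows():
            rows.append(
                {
                    "well": f"W{well}",
                    "role": "unknown",
                    "sample": r["sample"],
                    "target": target,
                    "copies": float("nan"),
                    "cq": r["cq"],
                }
            )
            well += 1
        return pd.DataFrame(rows)


def generate_qpcr_plate(spec: QpcrPlateSpec) -> QpcrPlate:
    """Simulate a 10-fold dilution-series qPCR plate.

    Standards and unknowns are drawn from the line
    ``Cq = slope * log10(copies) + intercept`` with Gaussian Cq noise of
    sd ``cq_noise_sd`` per replicate (noise 0 puts every well exactly on
    the line).  Zero-copy unknowns yield a no-amplification sentinel
    (NaN Cq), never a number.
    """
    rng = np.random.default_rng(spec.seed)

    std_rows = []
    for level in range(spec.dilution_levels):
        copies = spec.dilution_top / 10.0**level
        true_cq = spec.true_slope * math.log10(copies) + spec.true_intercept
        for rep in range(1, spec.replicates + 1):
            cq = true_cq + (
                rng.normal(0.0, spec.cq_noise_sd) if spec.cq_noise_sd > 0 else 0.0
            )
            std_rows.append({"copies": copies, "replicate": rep, "cq": cq})

    unk_rows = []
    truth_rows = []
    for sample, copies in spec.unknown_true_copies.items():
        truth_rows.append({"sample": sample, "true_copies": copies})
        for rep in range(1, spec.replicates + 1):
            if copies <= 0:
                unk_rows.append(
                    {
                        "sample": sample,
                        "replicate": rep,
                        "cq": NO_AMPLIFICATION,
                        "no_amplification": True,
                    }
                )
                continue
            true_cq = spec.true_slope * math.log10(copies) + spec.true_intercept
            cq = true_cq + (
                rng.normal(0.0, spec.cq_noise_sd) if spec.cq_noise_sd > 0 else 0.0
            )
            unk_rows.append(
                {
                    "sample": sample,
                    "replicate": rep,
                    "cq": cq,
                    "no_amplification": False,
                }
            )

    return QpcrPlate(
        standards=pd.DataFrame(std_rows),
        unknowns=pd.DataFrame(unk_rows),
        truth=pd.DataFrame(truth_rows),
    )


@dataclass(frozen=True)
class IncubationSpec:
    """Zero-order nitrification incubation with paired blank.

    ``guild_cells`` (cells per m3 air) and ``guild_r_in`` (fmol per cell
    per hour) share keys; guilds named ``comammox`` (case-insensitive)
    route their product to nitrate, all others to nitrite.
    """

    guild_cells: dict[str, float]
    guild_r_in: dict[str, float]
    nh4_start: float
    timepoints: tuple[float, ...] = (0, 2, 4, 6, 8, 10, 12, 14, 16)
    blank_level: float = 0.0
    noise_sd: float = 0.0
    q1: float = 0.25
    q2: float = 48.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "guild_cells", dict(self.guild_cells))
        object.__setattr__(self, "guild_r_in", dict(self.guild_r_in))
        object.__setattr__(self, "timepoints", tuple(float(t) for t in self.timepoints))
        if set(self.guild_cells) != set(self.guild_r_in):
            raise ValueError("guild_cells and guild_r_in must share keys")
        if any(v < 0 for v in self.guild_cells.values()):
            raise ValueError("cell abundances must be >= 0")
        if any(v < 0 for v in self.guild_r_in.values()):
            raise ValueError("cell-specific rates must be >= 0")
        t = self.timepoints
        if not t or t[0] != 0 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("timepoints must start at 0 and strictly increase")
        if self.nh4_start < 0 or self.blank_level < 0:
            raise ValueError("concentrations must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.q1 <= 0 or self.q2 <= 0:
            raise ValueError("Q1 and Q2 must be > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "IncubationSpec":
        d = dict(d)
        if "timepoints" in d:
            d["timepoints"] = tuple(d["timepoints"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, src) -> "IncubationSpec":
        return _from_yaml(cls, src)

    def guild_rates_ug(self) -> dict[str, float]:
        """Per-guild ammonia oxidation rate in ug N per m3 air per hour."""
        return {
            g: self.guild_cells[g] * self.guild_r_in[g] * FMOL_TO_UG
            for g in self.guild_cells
        }

    def true_nnr_max(self) -> float:
        return sum(self.guild_rates_ug().values())

    def removal_rate_mg_per_l_h(self) -> float:
        """Total NH4+-N removal in flask-concentration units (mg/l/h)."""
        return self.true_nnr_max() * self.q2 / (self.q1 * 1000.0)


@dataclass(frozen=True)
class IncubationTruth:
    nnr_max: float  # ug N m-3 air h-1
    removal_rate: float  # mg/l/h in the flask
    rc: dict[str, float]  # planted relative contributions


def generate_incubation(spec: IncubationSpec):
    """Simulate an incubation time series with its paired blank.

    Ammonia declines at a constant (zero-order) rate; nitrite + nitrate
    rise to match exactly, so noiseless series conserve nitrogen at every
    timepoint.  Gaussian noise (sd ``noise_sd``, truncated at 0) applies
    per measured value.  Returns ``(series, truth)`` where series is an
    :class:`aeronit.kinetics.IncubationSeries`.
    """
    from .kinetics import IncubationSeries  # local import to avoid a cycle

    rate = spec.removal_rate_mg_per_l_h()
    t = np.asarray(spec.timepoints)
    consumed_end = rate * t[-1]
    if consumed_end > spec.nh4_start + 1e-12:
        raise ValueError(
            f"total removal rate {rate:.4g} mg/l/h would drive NH4 below zero "
            f"before {t[-1]} h (start {spec.nh4_start} mg/l)"
        )

    rates = spec.guild_rates_ug()
    total = sum(rates.values())
    if total > 0:
        no3_share = sum(v for g, v in rates.items() if g.lower() == "comammox") / total
    else:
        no3_share = 0.0

    consumed = rate * t
    nh4_sample = spec.blank_level + spec.nh4_start - consumed
    no2_sample = consumed * (1.0 - no3_share)
    no3_sample = consumed * no3_share
    zeros = np.zeros_like(t)
    series = {
        "nh4_sample": nh4_sample,
        "nh4_blank": np.full_like(t, spec.blank_level),
        "no2_sample": no2_sample,
        "no2_blank": zeros.copy(),
        "no3_sample": no3_sample,
        "no3_blank": zeros.copy(),
    }
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        for key in sorted(series):
            noisy = series[key] + rng.normal(0.0, spec.noise_sd, size=t.size)
            series[key] = np.clip(noisy, 0.0, None)

    truth = IncubationTruth(
        nnr_max=spec.true_nnr_max(),
        removal_rate=rate,
        rc={g: (v / total if total > 0 else 0.0) for g, v in rates.items()},
    )
    return (
        IncubationSeries(sample="synthetic", times=tuple(t), q1=spec.q1, q2=spec.q2, **series),
        truth,
    )


@dataclass(frozen=True)
class EnvTableSpec:
    """Environmental-factor table with planted monotone taxon links."""

    n_samples: int
    factors: tuple[str, ...]
    planted_links: tuple[tuple[str, str, int], ...]
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        object.__setattr__(
            self, "planted_links", tuple(tuple(l) for l in self.planted_links)
        )
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if len(set(self.factors)) != len(self.factors):
            raise ValueError("duplicate factor names")
        for taxon, factor, sign in self.planted_links:
            if sign not in (-1, 0, 1):
                raise ValueError("link signs must be -1, 0 or +1")
            if factor not in self.factors:
                raise ValueError(f"link references unknown factor {factor!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "EnvTableSpec":
        return cls(
            n_samples=d["n_samples"],
            factors=tuple(d["factors"]),
            planted_links=tuple(tuple(l) for l in d["planted_links"]),
            noise_sd=d.get("noise_sd", 0.0),
            seed=d.get("seed", 0),
        )

    @classmethod
    def from_yaml(cls, src) -> "EnvTableSpec":
        return _from_yaml(cls, src)


def generate_env_table(spec: EnvTableSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ``(factors, taxa)`` tables sharing a sample index.

    A +1/-1 link makes the taxon a signed copy of the factor plus
    Gaussian noise, so Spearman rho tends to +1/-1 as noise_sd drops; a
    0 link draws the taxon independently of every factor.
    """
    rng = np.random.default_rng(spec.seed)
    samples = [f"S{i + 1}" for i in range(spec.n_samples)]
    factors = pd.DataFrame(
        {f: rng.uniform(0.0, 1.0, size=spec.n_samples) for f in spec.factors},
        index=samples,
    )
    taxa: dict[str, np.ndarray] = {}
    for taxon, factor, sign in spec.planted_links:
        if sign == 0:
            signal = rng.uniform(0.0, 1.0, size=spec.n_samples)
        else:
            signal = sign * factors[factor].to_numpy()
        noise = (
            rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
            if spec.noise_sd > 0
            else 0.0
        )
        taxa[taxon] = taxa.get(taxon, 0.0) + signal + noise
    return factors, pd.DataFrame(taxa, index=samples)
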