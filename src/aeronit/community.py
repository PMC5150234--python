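"""Marker-gene community analysis: pairwise distances, OTU clustering,
alpha diversity and the shared-OTU sample network.

Sequences are clustered into operational taxonomic units (OTUs) with
furthest-neighbor (complete-linkage) agglomeration at a fractional
distance cutoff; 97% similarity corresponds to ``cutoff=0.03`` with an
inclusive boundary (pairs at exactly the cutoff still co-cluster).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

_ALPHABET = set("ACGTN-")
_ACGT = np.frombuffer(b"ACGT", dtype="S1")

__all__ = [
    "SequenceRecord",
    "DistanceMatrix",
    "OtuTable",
    "read_fasta",
    "write_fasta",
    "pairwise_distances",
    "cluster_otus",
    "diversity_indices",
    "shared_otu_network",
]


@dataclass(frozen=True)
class SequenceRecord:
    """One labelled marker-gene sequence.

    ``id`` must be unique within a record set; ``sample`` names the
    clone library the sequence came from.
    """

    id: str
    sample: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.bases.upper()) - _ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )
        object.__setattr__(self, "bases", self.bases.upper())

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise fractional distances in [0, 1].

    Entries may be NaN when a pair shares no comparable positions; such
    matrices are rejected at clustering time.
    """

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(np.nan_to_num(v), np.nan_to_num(v.T)):
            raise ValueError("distance matrix is not symmetric")
        if np.diag(v).any():
            raise ValueError("distance matrix diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if ((v < 0) | (v > 1)).any():
                raise ValueError("distances must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def has_undefined(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class OtuTable:
    """OTU-by-sample count matrix with one representative per OTU.

    ``counts`` is indexed by OTU id with one column per sample;
    ``representatives`` maps OTU id to the id of its most central member
    (minimum summed within-OTU distance, ties broken lexicographically);
    ``assignments`` maps every input sequence id to its OTU.
    """

    counts: pd.DataFrame
    representatives: dict[str, str] = field(default_factory=dict)
    assignments: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("OTU counts must be non-negative")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_sequences(self) -> int:
        return int(self.counts.values.sum())

    def percentages(self) -> pd.Series:
        """Percent of all sequences held by each OTU (sums to 100)."""
        total = self.counts.sum(axis=1)
        return 100.0 * total / total.sum()


def read_fasta(path_or_handle, sample_from_id: bool = True) -> list[SequenceRecord]:
    """Read sequences from FASTA.

    When ``sample_from_id`` is true, headers of the form
    ``sample|cluster|index`` yield the sample label from the first field;
    otherwise (or for plain headers) the whole id is used as the sample.
    """
    records = []
    for rec in SeqIO.parse(path_or_handle, "fasta"):
        sample = rec.id.split("|")[0] if sample_from_id and "|" in rec.id else rec.id
        records.append(SequenceRecord(id=rec.id, sample=sample, bases=str(rec.seq)))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in FASTA input")
    return records


def write_fasta(records, path_or_handle) -> None:
    bio = [
        _BioSeqRecord(Seq(r.bases), id=r.id, description="") for r in records
    ]
    if isinstance(path_or_handle, (str, bytes)) or hasattr(path_or_handle, "__fspath__"):
        with open(path_or_handle, "w") as fh:
            SeqIO.write(bio, fh, "fasta")
    else:
        SeqIO.write(bio, path_or_handle, "fasta")


def _encode(bases: str) -> np.ndarray:
    return np.frombuffer(bases.encode(), dtype="S1")


def _p_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Uncorrected p-distance over positions where both bases are ACGT."""
    ok = np.isin(a, _ACGT) & np.isin(b, _ACGT)
    n = int(ok.sum())
    if n == 0:
        return float("nan")
    return float(((a != b) & ok).sum() / n)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    # terminal gaps are free and excluded from the distance denominator
    aligner.end_gap_score = 0.0
    return aligner


def _aligned_p_distance(sa: str, sb: str, aligner: Align.PairwiseAligner) -> float:
    aln = aligner.align(sa, sb)[0]
    ga, gb = str(aln[0]), str(aln[1])
    a, b = _encode(ga), _encode(gb)
    non_gap = (a != b"-") & (b != b"-")
    idx = np.nonzero(non_gap)[0]
    if idx.size == 0:
        return float("nan")
    lo, hi = idx[0], idx[-1] + 1  # trim terminal-gap overhangs
    return _p_distance(a[lo:hi], b[lo:hi])


def pairwise_distances(records) -> DistanceMatrix:
    """All-pairs fractional sequence distances.

    Equal-length inputs are compared position-wise (p-distance over
    columns where both bases are unambiguous).  Unequal-length pairs are
    globally aligned first (match 1, mismatch -1, gap -2, terminal gaps
    free) and the p-distance is taken over the aligned core.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 sequences")
    ids = tuple(r.id for r in records)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    n = len(records)
    enc = [_encode(r.bases) for r in records]
    aligner = _make_aligner()
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if len(enc[i]) == len(enc[j]):
                dij = _p_distance(enc[i], enc[j])
            else:
                dij = _aligned_p_distance(records[i].bases, records[j].bases, aligner)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(ids=ids, values=d)


_LINKAGE_METHODS = {"complete", "single", "average"}


def cluster_otus(
    dm: DistanceMatrix,
    records=None,
    cutoff: float = 0.03,
    linkage: str = "complete",
) -> OtuTable:
    """Agglomerate sequences into OTUs at a distance ``cutoff``.

    Default linkage is furthest neighbor: two sequences co-cluster only
    if every cross-pair distance is <= cutoff.  ``records`` (when given)
    supplies per-sequence sample labels; otherwise each sequence id
    before the first ``|`` is used as its sample.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    if linkage not in _LINKAGE_METHODS:
        raise ValueError(f"linkage must be one of {sorted(_LINKAGE_METHODS)}")
    if dm.has_undefined:
        raise ValueError(
            "distance matrix contains undefined entries (no comparable positions)"
        )
    n = len(dm.ids)
    if n == 1:
        labels = np.array([1])
    else:
        z = hierarchy.linkage(dm.condensed(), method=linkage)
        labels = hierarchy.fcluster(z, t=cutoff, criterion="distance")

    if records is not None:
        sample_of = {r.id: r.sample for r in records}
    else:
        sample_of = {i: (i.split("|")[0] if "|" in i else i) for i in dm.ids}

    members: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        members.setdefault(int(lab), []).append(idx)

    # representative: minimum summed distance to cluster mates, ties by id
    reps, totals, rows = {}, {}, {}
    for lab, idxs in members.items():
        sub = dm.values[np.ix_(idxs, idxs)]
        sums = sub.sum(axis=1)
        order = sorted(range(len(idxs)), key=lambda k: (sums[k], dm.ids[idxs[k]]))
        reps[lab] = dm.ids[idxs[order[0]]]
        totals[lab] = len(idxs)
        rows[lab] = idxs

    samples = sorted({sample_of[i] for i in dm.ids})
    order = sorted(members, key=lambda lab: (-totals[lab], reps[lab]))
    otu_names = {lab: f"OTU{k + 1}" for k, lab in enumerate(order)}

    counts = pd.DataFrame(0, index=[otu_names[lab] for lab in order], columns=samples)
    assignment = {}
    for lab in order:
        for idx in rows[lab]:
            sid = dm.ids[idx]
            counts.loc[otu_names[lab], sample_of[sid]] += 1
            assignment[sid] = otu_names[lab]

    return OtuTable(
        counts=counts,
        representatives={otu_names[lab]: reps[lab] for lab in order},
        assignments=pd.Series(assignment, name="otu"),
    )


def _shannon(p: np.ndarray, base: float | None = None) -> float:
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def _chao1(counts: np.ndarray, bias_corrected: bool = True) -> float:
    counts = counts[counts > 0]
    s_obs = counts.size
    n1 = int((counts == 1).sum())
    n2 = int((counts == 2).sum())
    if bias_corrected:
        return s_obs + n1 * (n1 - 1) / (2.0 * (n2 + 1))
    if n2 == 0:
        return float("nan")
    return s_obs + n1 * n1 / (2.0 * n2)


def diversity_indices(
    otus: OtuTable, base: float | None = None, bias_corrected_chao1: bool = True
) -> pd.DataFrame:
    """Per-sample observed richness, Shannon entropy and Chao1 richness.

    Shannon defaults to natural log (nats); pass ``base=2`` for bits.
    Chao1 defaults to the bias-corrected form, which stays defined when
    no doubletons are present.
    """
    out = []
    for sample in otus.samples:
        c = otus.counts[sample].to_numpy(dtype=float)
        total = c.sum()
        if total <= 0:
            raise ValueError(f"sample {sample!r} has no sequences")
        out.append(
            {
                "sample": sample,
                "s_obs": int((c > 0).sum()),
                "shannon": _shannon(c / total, base=base),
                "chao1": _chao1(c, bias_corrected=bias_corrected_chao1),
            }
        )
    return pd.DataFrame(out).set_index("sample")


def shared_otu_network(otus: OtuTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bipartite OTU-sample edge list plus per-OTU occupancy flags.

    Returns ``(edges, otu_flags)``: edges hold one row per nonzero
    OTU/sample cell; an OTU is *shared* when present in >= 2 samples and
    *omnipresent* when present in every sample.
    """
    edges = []
    flags = []
    n_samples = len(otus.samples)
    for otu in otus.otu_ids:
        present = 0
        for sample in otus.samples:
            c = int(otus.counts.loc[otu, sample])
            if c > 0:
                edges.append({"otu": otu, "sample": sample, "count": c})
                present += 1
        flags.append(
            {
                "otu": otu,
                "n_samples": present,
                "shared": present >= 2,
                "unique": present == 1,
                "omnipresent": present == n_samples,
            }
        )
    return pd.DataFrame(edges), pd.DataFrame(flags).set_index("otu")
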