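"""Aligned-sequence handling: I/O, pairwise differences, corrected distances,
group divergence summaries, and clone-abundance tallies.

All distances are proportions (unitless) unless noted. Gap/ambiguity handling
follows the *pairwise deletion* convention by default: any column where either
sequence carries a gap or an IUPAC ambiguity code is excluded from the
comparison, mirroring how distance matrices are computed from partially
overlapping 16S rRNA gene fragments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

logger = logging.getLogger(__name__)

Source = Literal["mat", "enrichment", "reference", "synthetic"]
Policy = Literal["pairwise_deletion", "strict"]

#: Unambiguous nucleotide states; everything else (gaps, N, R, Y, ...) is
#: excluded under pairwise deletion.
CANONICAL = frozenset("ACGT")


class AlignmentShapeError(ValueError):
    """Sequences that should be aligned have unequal lengths."""


class DegenerateComparisonError(ValueError):
    """No columns left to compare after gap/ambiguity exclusion."""


class SaturationError(ValueError):
    """p-distance at or beyond the Jukes-Cantor saturation bound of 3/4."""


class EmptyInputError(ValueError):
    """An input file or collection contained no records."""


@dataclass
class SequenceRecord:
    """A single (possibly aligned) nucleotide sequence.

    ``seq`` is uppercased and RNA U residues are normalised to T on
    construction. ``description`` retains the full FASTA header; ``id`` is its
    first whitespace-delimited token.
    """

    id: str
    seq: str
    site_id: str | None = None
    source: Source = "synthetic"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        self.seq = self.seq.upper().replace("U", "T")

    def degapped(self) -> str:
        return self.seq.replace("-", "").replace(".", "")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Alignment:
    """An ordered collection of equal-length sequence records."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise EmptyInputError("alignment has no records")
        lengths = {len(r) for r in self.records}
        if len(lengths) > 1:
            raise AlignmentShapeError(
                f"unequal sequence lengths in alignment: {sorted(lengths)}"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dup}")

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, key: int | str) -> SequenceRecord:
        if isinstance(key, str):
            for r in self.records:
                if r.id == key:
                    return r
            raise KeyError(key)
        return self.records[key]

    def subset(self, ids: Iterable[str]) -> "Alignment":
        wanted = list(ids)
        index = {r.id: r for r in self.records}
        return Alignment([index[i] for i in wanted])

    def to_array(self) -> np.ndarray:
        """Byte matrix (n_records, length) of the uppercase sequences."""
        return np.frombuffer(
            "".join(r.seq for r in self.records).encode(), dtype="S1"
        ).reshape(len(self.records), self.length)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance (or identity) matrix over labelled taxa."""

    ids: list[str]
    data: np.ndarray
    kind: Literal["p_distance", "jc_corrected", "identity"] = "p_distance"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T):
            raise ValueError("distance matrix is not symmetric")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.data[i, j])

    def as_p_distance(self) -> np.ndarray:
        """p-distance view; identity matrices are flipped to 1 - identity."""
        if self.kind == "identity":
            return 1.0 - self.data
        if self.kind == "jc_corrected":
            raise ValueError("cannot recover p-distance from corrected matrix")
        return self.data


@dataclass
class GroupDivergenceSummary:
    """Min/max percent divergence between (or within) two sequence groups."""

    group_a: str
    group_b: str
    min_pct: float
    max_pct: float
    n_pairs: int


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path, aligned: bool = False, source: Source = "reference"):
    """Read FASTA records; returns an :class:`Alignment` when ``aligned``.

    U residues are normalised to T; the record id is the first
    whitespace-delimited header token and the full header is kept in
    ``description``.
    """
    records = [
        SequenceRecord(
            id=rec.id,
            seq=str(rec.seq),
            source=source,
            description=rec.description,
        )
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    if aligned:
        return Alignment(records)
    return records


def write_fasta(records: Alignment | Sequence[SequenceRecord], path: str | Path) -> None:
    recs = records.records if isinstance(records, Alignment) else list(records)
    bio = [
        _BioRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in recs
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# Pairwise comparison


def _comparable_mask(a: str, b: str, policy: Policy) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if len(a) != len(b):
        raise AlignmentShapeError(
            f"sequences have unequal lengths ({len(a)} vs {len(b)})"
        )
    arr_a = np.frombuffer(a.encode(), dtype="S1")
    arr_b = np.frombuffer(b.encode(), dtype="S1")
    canon = np.frombuffer(b"ACGT", dtype="S1")
    ok_a = np.isin(arr_a, canon)
    ok_b = np.isin(arr_b, canon)
    if policy == "strict":
        if not (ok_a.all() and ok_b.all()):
            raise ValueError(
                "strict policy forbids gaps/ambiguity codes in compared sequences"
            )
        mask = np.ones(len(arr_a), dtype=bool)
    else:
        mask = ok_a & ok_b
    return arr_a, arr_b, mask


def hamming_differences(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    policy: Policy = "pairwise_deletion",
) -> tuple[int, int]:
    """Count differing and compared columns between two aligned sequences.

    Returns ``(n_diff, n_compared)``. Under pairwise deletion, columns where
    either sequence has a gap or ambiguity code are dropped before counting.
    """
    sa = a.seq if isinstance(a, SequenceRecord) else a
    sb = b.seq if isinstance(b, SequenceRecord) else b
    arr_a, arr_b, mask = _comparable_mask(sa, sb, policy)
    n_compared = int(mask.sum())
    if n_compared == 0:
        raise DegenerateComparisonError("no comparable columns between sequences")
    n_diff = int((arr_a[mask] != arr_b[mask]).sum())
    return n_diff, n_compared


def pairwise_identity(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    policy: Policy = "pairwise_deletion",
) -> float:
    """Fraction of identical residues among compared columns, in [0, 1]."""
    n_diff, n_compared = hamming_differences(a, b, policy)
    return 1.0 - n_diff / n_compared


def jc_distance(p: float, saturated: float | None = None) -> float:
    """Jukes-Cantor corrected distance d = -(3/4) ln(1 - (4/3) p).

    Maps an observed proportion of differing sites to expected substitutions
    per site under the one-parameter model. ``p`` must lie below the
    saturation bound 0.75; at or beyond it, ``saturated`` is returned when
    given, otherwise :class:`SaturationError` is raised.
    """
    if p < 0:
        raise ValueError("p-distance cannot be negative")
    if p >= 0.75:
        if saturated is not None:
            return saturated
        raise SaturationError(f"p-distance {p} is at/beyond JC saturation (0.75)")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


# ---------------------------------------------------------------------------
# Distance matrices


def _pair_counts(aln: Alignment, policy: Policy) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (n_diff, n_compared) over all pairs of an alignment."""
    arr = aln.to_array()
    canon = np.frombuffer(b"ACGT", dtype="S1")
    valid = np.isin(arr, canon)
    if policy == "strict" and not valid.all():
        bad = [aln.ids[i] for i in np.nonzero(~valid.all(axis=1))[0]]
        raise ValueError(f"strict policy forbids gaps/ambiguity (records {bad})")
    valid_f = valid.astype(np.float64)
    n_compared = valid_f @ valid_f.T
    matches = np.zeros_like(n_compared)
    for base in b"ACGT":
        ind = ((arr == bytes([base])) & valid).astype(np.float64)
        matches += ind @ ind.T
    n_diff = n_compared - matches
    return n_diff, n_compared


def distance_matrix(
    aln: Alignment,
    kind: Literal["p_distance", "jc_corrected", "identity"] = "p_distance",
    policy: Policy = "pairwise_deletion",
) -> DistanceMatrix:
    """All-pairs distance (or identity) matrix of an alignment."""
    if len(aln) < 2:
        raise ValueError("distance matrix needs at least 2 records")
    n_diff, n_compared = _pair_counts(aln, policy)
    n = len(aln)
    zero = n_compared == 0
    np.fill_diagonal(zero, False)
    if zero.any():
        i, j = np.argwhere(zero)[0]
        raise DegenerateComparisonError(
            f"no comparable columns between {aln.ids[i]!r} and {aln.ids[j]!r}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_compared > 0, n_diff / np.maximum(n_compared, 1), 0.0)
    np.fill_diagonal(p, 0.0)
    if kind == "identity":
        data = 1.0 - p
    elif kind == "jc_corrected":
        sat = p >= 0.75
        if sat.any():
            i, j = np.argwhere(sat)[0]
            raise SaturationError(
                f"pair ({aln.ids[i]!r}, {aln.ids[j]!r}) is JC-saturated (p={p[i, j]:.3f})"
            )
        data = -0.75 * np.log1p(-(4.0 / 3.0) * p)
        np.fill_diagonal(data, 0.0)
    else:
        data = p
    return DistanceMatrix(ids=aln.ids, data=data, kind=kind)


def group_divergence(
    aln: Alignment, groups: dict[str, str], policy: Policy = "pairwise_deletion"
) -> list[GroupDivergenceSummary]:
    """Min/max percent p-distance within and among sequence groups.

    Every record must be assigned to exactly one group. Within-group
    summaries are omitted (with a log note) for singleton groups.
    """
    missing = [i for i in aln.ids if i not in groups]
    if missing:
        raise ValueError(f"records without group assignment: {missing}")
    dm = distance_matrix(aln, kind="p_distance", policy=policy)
    order: list[str] = []
    for i in aln.ids:
        if groups[i] not in order:
            order.append(groups[i])
    members = {g: [i for i, rid in enumerate(aln.ids) if groups[rid] == g] for g in order}
    out: list[GroupDivergenceSummary] = []
    for gi, ga in enumerate(order):
        for gb in order[gi:]:
            ia, ib = members[ga], members[gb]
            if ga == gb:
                if len(ia) < 2:
                    logger.info("group %r is a singleton; no within-group summary", ga)
                    continue
                vals = [dm.data[i, j] for k, i in enumerate(ia) for j in ia[k + 1:]]
            else:
                vals = [dm.data[i, j] for i in ia for j in ib]
            pct = 100.0 * np.asarray(vals)
            out.append(
                GroupDivergenceSummary(
                    group_a=ga,
                    group_b=gb,
                    min_pct=float(pct.min()),
                    max_pct=float(pct.max()),
                    n_pairs=len(vals),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Clone tallies and enrichment arithmetic


def clone_tally(
    records: Sequence[SequenceRecord],
) -> tuple[list[tuple[str, int]], int]:
    """Collapse a clone library to (distinct degapped sequence, copy count).

    Distinctness is exact string equality of the degapped uppercase sequence.
    Returns the tally sorted by descending count (ties by first occurrence)
    plus the number of singleton sequences.
    """
    if not records:
        raise EmptyInputError("clone_tally needs at least one record")
    counts: dict[str, int] = {}
    for r in records:
        key = r.degapped()
        counts[key] = counts.get(key, 0) + 1
    order = {seq: k for k, seq in enumerate(counts)}
    tally = sorted(counts.items(), key=lambda kv: (-kv[1], order[kv[0]]))
    singletons = sum(1 for _, c in tally if c == 1)
    return tally, singletons


def dilution_density_bound(
    highest_positive_dilution: float, inoculum_volume_ml: float = 0.1
) -> float:
    """Lower bound on source cell density from a dilution-to-extinction series.

    If the highest dilution that still yields growth is ``d`` and the
    inoculum volume is ``v`` mL, the source must have contained at least
    ``1 / (d * v)`` cells per mL. The default inoculum volume of 0.1 mL is a
    configurable convention.
    """
    if highest_positive_dilution <= 0 or highest_positive_dilution > 1:
        raise ValueError("dilution must be in (0, 1]")
    if inoculum_volume_ml <= 0:
        raise ValueError("inoculum volume must be positive")
    return 1.0 / (highest_positive_dilution * inoculum_volume_ml)
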