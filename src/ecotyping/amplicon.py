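"""In-silico PCR and restriction-fragment (RFLP) typing.

Primer matching uses IUPAC base-set semantics: a primer position matches a
template position when the two base sets intersect. Both strands are scanned;
minus-strand hits are reported in plus-strand coordinates (0-based,
half-open). Mismatch counting is positionally uniform — no 3'-end weighting —
which suffices for perfect-match/near-match screening of candidate templates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .seq_core import SequenceRecord

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes as 4-bit sets over (A, C, G, T).
_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_MASK = {code: sum(_BIT[b] for b in bases) for code, bases in IUPAC.items()}

_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")

#: Restriction enzymes available to :func:`digest`: recognition site and the
#: 0-based offset of the cut within it (top strand).
ENZYMES = {
    "MspI": ("CCGG", 1),   # C^CGG
    "HhaI": ("GCGC", 3),   # GCG^C
}


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class Primer:
    """An oligonucleotide primer, written 5'->3' as synthesized."""

    name: str
    seq: str
    role: Literal["forward", "reverse"] = "forward"

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace(" ", "").replace("U", "T")
        if not self.seq:
            raise ValueError(f"primer {self.name!r} has an empty sequence")
        bad = set(self.seq) - set(IUPAC)
        if bad:
            raise ValueError(f"primer {self.name!r} has non-IUPAC letters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AmpliconHit:
    """A predicted PCR product on a template (plus-strand coordinates)."""

    template_id: str
    fwd_start: int
    fwd_end: int
    rev_start: int
    rev_end: int
    amplicon_seq: str
    fwd_mismatches: int
    rev_mismatches: int

    @property
    def length(self) -> int:
        return self.rev_end - self.fwd_start


@dataclass
class RFLPProfile:
    """Fragment-length fingerprint of one sequence for a set of enzymes."""

    sequence_id: str
    enzyme_fragments: dict[str, list[int]]


def _mask_array(seq: str) -> np.ndarray:
    out = np.zeros(len(seq), dtype=np.uint8)
    for i, c in enumerate(seq):
        out[i] = _MASK.get(c, 0)  # gaps/unknowns match nothing
    return out


def _scan(primer_seq: str, template: str, max_mismatches: int) -> list[tuple[int, int]]:
    """Plus-strand sliding-window scan; returns (start, mismatches) pairs."""
    m, n = len(primer_seq), len(template)
    if m > n:
        return []
    p = _mask_array(primer_seq)
    t = _mask_array(template)
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    mismatches = ((windows & p) == 0).sum(axis=1)
    hits = np.nonzero(mismatches <= max_mismatches)[0]
    return [(int(i), int(mismatches[i])) for i in hits]


def match_primer(
    primer: Primer, template: SequenceRecord | str, max_mismatches: int = 0
) -> list[tuple[int, str, int]]:
    """All primer binding sites on a degapped template, both strands.

    Returns ``(position, strand, mismatches)`` tuples sorted by position,
    where ``position`` is the 0-based plus-strand start of the matched window
    and ``strand`` is ``"+"`` or ``"-"``. Minus-strand hits are windows where
    the reverse complement of the primer matches the plus strand.
    """
    tseq = template.seq if isinstance(template, SequenceRecord) else template
    tseq = tseq.upper().replace("-", "").replace(".", "")
    if len(primer) > len(tseq):
        logger.info("primer %s longer than template; no hits", primer.name)
        return []
    hits = [(pos, "+", mm) for pos, mm in _scan(primer.seq, tseq, max_mismatches)]
    rc = reverse_complement(primer.seq)
    hits += [(pos, "-", mm) for pos, mm in _scan(rc, tseq, max_mismatches)]
    return sorted(hits)


def in_silico_pcr(
    fwd: Primer,
    rev: Primer,
    template: SequenceRecord | str,
    max_mismatches: int = 0,
    max_len: int = 5000,
) -> list[AmpliconHit]:
    """Predict PCR products of a primer pair on a linear template.

    The reverse primer is given 5'->3' as synthesized (it anneals to the
    minus strand), so its reverse complement is searched on the plus strand
    downstream of each forward hit. One hit is emitted per compatible pair
    with product length <= ``max_len``; the amplicon includes both primer
    footprints.
    """
    tid = template.id if isinstance(template, SequenceRecord) else "template"
    tseq = template.seq if isinstance(template, SequenceRecord) else template
    tseq = tseq.upper().replace("-", "").replace(".", "")
    fwd_hits = _scan(fwd.seq, tseq, max_mismatches)
    rev_hits = _scan(reverse_complement(rev.seq), tseq, max_mismatches)
    out: list[AmpliconHit] = []
    for fstart, fmm in fwd_hits:
        fend = fstart + len(fwd)
        for rstart, rmm in rev_hits:
            rend = rstart + len(rev)
            if rend <= fstart:
                continue
            if rend - fstart > max_len:
                continue
            out.append(
                AmpliconHit(
                    template_id=tid,
                    fwd_start=fstart,
                    fwd_end=fend,
                    rev_start=rstart,
                    rev_end=rend,
                    amplicon_seq=tseq[fstart:rend],
                    fwd_mismatches=fmm,
                    rev_mismatches=rmm,
                )
            )
    return out


def digest(template: SequenceRecord | str, enzyme: str) -> list[int]:
    """Fragment lengths from an in-silico restriction digest (linear molecule).

    Every occurrence of the recognition site produces a cut (overlapping
    occurrences included, scanned left to right). Fragment lengths are
    returned sorted ascending and always sum to the template length.
    """
    if enzyme not in ENZYMES:
        raise KeyError(f"unknown enzyme {enzyme!r}; available: {sorted(ENZYMES)}")
    site, offset = ENZYMES[enzyme]
    tseq = template.seq if isinstance(template, SequenceRecord) else template
    tseq = tseq.upper().replace("-", "").replace(".", "")
    cuts = []
    start = 0
    while True:
        i = tseq.find(site, start)
        if i < 0:
            break
        cuts.append(i + offset)
        start = i + 1
    bounds = [0] + cuts + [len(tseq)]
    frags = [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
    return sorted(frags)


def rflp_profile(
    template: SequenceRecord, enzymes: Sequence[str] = ("MspI", "HhaI")
) -> RFLPProfile:
    return RFLPProfile(
        sequence_id=template.id,
        enzyme_fragments={e: digest(template, e) for e in enzymes},
    )


def _profiles_equivalent(
    a: RFLPProfile, b: RFLPProfile, size_tolerance: float, abs_floor: int
) -> bool:
    for enz in a.enzyme_fragments:
        fa, fb = a.enzyme_fragments[enz], b.enzyme_fragments[enz]
        if len(fa) != len(fb):
            return False
        for x, y in zip(sorted(fa), sorted(fb)):
            if abs(x - y) > max(size_tolerance * max(x, y), abs_floor):
                return False
    return True


def rflp_type_assign(
    profiles: Sequence[RFLPProfile],
    size_tolerance: float = 0.05,
    abs_floor: int = 4,
) -> dict[str, int]:
    """Group digestion profiles into RFLP types.

    Two profiles are gel-equivalent when, for every enzyme, they have the
    same fragment count and each size-ordered fragment pair differs by at
    most ``size_tolerance`` (relative to the larger fragment, with an
    absolute floor of ``abs_floor`` nt, emulating 2% agarose resolution).
    Types are the transitive closure of this relation, numbered from 1 by
    first occurrence.
    """
    enzyme_sets = {frozenset(p.enzyme_fragments) for p in profiles}
    if len(enzyme_sets) > 1:
        raise ValueError("profiles were digested with inconsistent enzyme sets")
    if size_tolerance == 0:
        abs_floor = 0
    n = len(profiles)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _profiles_equivalent(profiles[i], profiles[j], size_tolerance, abs_floor):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    type_of_root: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for i, p in enumerate(profiles):
        root = find(i)
        if root not in type_of_root:
            type_of_root[root] = len(type_of_root) + 1
        assignment[p.sequence_id] = type_of_root[root]
    return assignment


def builtin_primers() -> dict[str, Primer]:
    """The packaged primer set used for green-sulfur-bacteria 16S screening."""
    path = resources.files("ecotyping.data").joinpath("primers.tsv")
    primers: dict[str, Primer] = {}
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("name"):
            continue
        name, seq, role = line.split("\t")
        primers[name] = Primer(name=name, seq=seq, role=role)  # type: ignore[arg-type]
    return primers


def load_primers_tsv(path: str | Path) -> dict[str, Primer]:
    """Load primers from a TSV with columns name, sequence, role."""
    primers: dict[str, Primer] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.lower().startswith("name"):
            continue
        name, seq, role = line.split("\t")[:3]
        primers[name] = Primer(name=name, seq=seq, role=role)  # type: ignore[arg-type]
    return primers
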