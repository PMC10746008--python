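"""Fragment-based average nucleotide identity (ANI) between two genomes.

The query genome is chopped into consecutive non-overlapping fragments
(1020 nt by default, the Goris-style convention), each fragment is mapped to
its best location on the reference — k-mer seeding to find candidate windows,
then a banded edit-distance alignment (edlib) on both strands — and one-way
ANI is the mean identity of fragments retained at >= 70% identity over
>= 70% of their length. Two-way ANI is the mean of the two directions.
Record boundaries in multi-record genomes are respected: fragments never
span contigs.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import edlib

from .amplicon import reverse_complement
from .seq_core import SequenceRecord, read_fasta

logger = logging.getLogger(__name__)


@dataclass
class ANISettings:
    """All knobs of the fragment-mapping convention."""

    frag_len: int = 1020
    min_identity: float = 70.0   # percent
    min_coverage: float = 0.7    # fraction of fragment length
    kmer: int = 15
    seed_stride: int = 8
    band_fraction: float = 0.05  # alignment band as fraction of fragment length


@dataclass
class ANIResult:
    """One-way and two-way ANI between a query/reference genome pair."""

    ani_qr: float
    ani_rq: float
    two_way: float
    fragments_total: int
    fragments_used_qr: int
    fragments_used_rq: int
    undefined_qr: bool = False
    undefined_rq: bool = False


def _as_sequences(genome) -> list[str]:
    if isinstance(genome, str) and ("\n" not in genome) and Path(genome).suffix in (
        ".fa", ".fasta", ".fna",
    ) and Path(genome).exists():
        return [r.seq for r in read_fasta(genome)]
    if isinstance(genome, str):
        return [genome.upper().replace("-", "")]
    if isinstance(genome, SequenceRecord):
        return [genome.degapped()]
    return [
        (g.degapped() if isinstance(g, SequenceRecord) else g.upper().replace("-", ""))
        for g in genome
    ]


def fragment_genome(genome, frag_len: int = 1020) -> list[str]:
    """Chop a genome into consecutive non-overlapping fragments.

    Terminal remainders shorter than ``frag_len`` are discarded. Multi-record
    genomes are fragmented per record so no fragment spans a contig boundary.
    """
    if frag_len < 100:
        raise ValueError("fragment length must be >= 100 nt")
    fragments: list[str] = []
    for seq in _as_sequences(genome):
        n = len(seq) // frag_len
        if n == 0:
            logger.info("record shorter than fragment length; skipped")
        fragments.extend(seq[i * frag_len:(i + 1) * frag_len] for i in range(n))
    return fragments


class _ReferenceIndex:
    """Exact k-mer position index of a concatenated reference genome."""

    def __init__(self, sequences: list[str], k: int):
        self.k = k
        # concatenate with separators so spurious junction k-mers cannot form
        self.text = ("N" * k).join(sequences)
        self.index: dict[str, list[int]] = defaultdict(list)
        for i in range(len(self.text) - k + 1):
            kmer = self.text[i:i + k]
            if "N" not in kmer:
                self.index[kmer].append(i)


def _candidate_diagonals(fragment: str, ref: _ReferenceIndex, stride: int) -> list[int]:
    votes: dict[int, int] = defaultdict(int)
    k = ref.k
    for q in range(0, len(fragment) - k + 1, stride):
        for p in ref.index.get(fragment[q:q + k], ()):
            votes[(p - q) // 64] += 1
    if not votes:
        return []
    ranked = sorted(votes, key=votes.get, reverse=True)[:4]
    return [d * 64 for d in ranked]


def _align_window(fragment: str, ref_text: str, diag: int, band: int) -> float | None:
    # diag is quantised to 64-wide buckets; the window must absorb both the
    # bucket offset and the alignment band
    start = max(0, diag - band)
    end = min(len(ref_text), diag + len(fragment) + 64 + band)
    window = ref_text[start:end]
    if len(window) < len(fragment) // 2:
        return None
    max_dist = int(len(fragment) * 0.35)
    res = edlib.align(fragment, window, mode="HW", task="distance", k=max_dist)
    if res["editDistance"] < 0:
        return None
    return 100.0 * (1.0 - res["editDistance"] / len(fragment))


def map_fragment(
    fragment: str,
    reference,
    settings: ANISettings | None = None,
    _index: _ReferenceIndex | None = None,
) -> tuple[float, float]:
    """Best local match of a fragment on a reference genome (both strands).

    Returns ``(identity_percent, covered_fraction)``; ``(0, 0)`` when no
    k-mer seed places the fragment anywhere. The semi-global alignment spans
    the whole fragment, so a successful placement covers it entirely.
    """
    settings = settings or ANISettings()
    if _index is None:
        _index = _ReferenceIndex(_as_sequences(reference), settings.kmer)
    band = max(16, int(settings.band_fraction * len(fragment)))
    best: float | None = None
    for query in (fragment, reverse_complement(fragment)):
        for diag in _candidate_diagonals(query, _index, settings.seed_stride):
            ident = _align_window(query, _index.text, diag, band)
            if ident is not None and (best is None or ident > best):
                best = ident
    if best is None:
        return (0.0, 0.0)
    return (best, 1.0)


def _one_way(fragments: list[str], index: _ReferenceIndex, settings: ANISettings):
    identities = []
    for frag in fragments:
        ident, cov = map_fragment(frag, None, settings, _index=index)
        if ident >= settings.min_identity and cov >= settings.min_coverage:
            identities.append(ident)
    if not identities:
        return float("nan"), 0, True
    return sum(identities) / len(identities), len(identities), False


def ani_twoway(genome_a, genome_b, settings: ANISettings | None = None) -> ANIResult:
    """Reciprocal fragment-based ANI between two genomes.

    Per direction, fragments matching at >= ``min_identity`` percent over
    >= ``min_coverage`` of their length are retained and averaged; the
    two-way value is the mean of the defined directions.
    """
    settings = settings or ANISettings()
    seqs_a = _as_sequences(genome_a)
    seqs_b = _as_sequences(genome_b)
    if not any(seqs_a) or not any(seqs_b):
        raise ValueError("both genomes must be nonempty")
    frags_a = fragment_genome(seqs_a, settings.frag_len)
    frags_b = fragment_genome(seqs_b, settings.frag_len)
    idx_b = _ReferenceIndex(seqs_b, settings.kmer)
    idx_a = _ReferenceIndex(seqs_a, settings.kmer)
    ani_qr, used_qr, undef_qr = _one_way(frags_a, idx_b, settings)
    ani_rq, used_rq, undef_rq = _one_way(frags_b, idx_a, settings)
    defined = [v for v, u in ((ani_qr, undef_qr), (ani_rq, undef_rq)) if not u]
    two_way = sum(defined) / len(defined) if defined else float("nan")
    if undef_qr or undef_rq:
        logger.warning("ANI undefined in at least one direction (no retained fragments)")
    return ANIResult(
        ani_qr=ani_qr,
        ani_rq=ani_rq,
        two_way=two_way,
        fragments_total=len(frags_a) + len(frags_b),
        fragments_used_qr=used_qr,
        fragments_used_rq=used_rq,
        undefined_qr=undef_qr,
        undefined_rq=undef_rq,
    )


def ani_report_tsv(result: ANIResult, label_a: str = "A", label_b: str = "B") -> str:
    header = "query\treference\tani_qr\tani_rq\ttwo_way\tfragments_used_qr\tfragments_used_rq"
    row = (
        f"{label_a}\t{label_b}\t{result.ani_qr:.2f}\t{result.ani_rq:.2f}\t"
        f"{result.two_way:.2f}\t{result.fragments_used_qr}\t{result.fragments_used_rq}"
    )
    return header + "\n" + row + "\n"
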