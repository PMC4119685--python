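"""Raw-read processing: collapse, 3' adaptor trimming, QC summaries.

A small-RNA read is (5' adaptor removed by the basecaller) insert + 3'
adaptor + downstream bases. The stages here: collapse identical reads into
unique tags, find the 3' adaptor in each tag, classify the tag
(self-ligation / clean / nonclean), re-collapse the trimmed inserts, and
keep the "qualified" inserts — those within the length window and with a
collapsed read count of at least 2 — for mapping.

Matching is exact by default (``max_mismatch=0``): the adaptor must occur
verbatim, either in full or as a prefix of length >= ``min_overlap`` hanging
off the read end. The leftmost occurrence wins, which is the conservative
(shortest-insert) choice and makes results deterministic.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .reference import normalize_seq

log = logging.getLogger("mirseq")


@dataclass(frozen=True, order=True)
class UniqueTag:
    """A distinct read sequence with its occurrence count."""

    seq: str
    count: int

    def __post_init__(self):
        if not self.seq:
            raise ValueError("empty tag sequence")
        if self.count < 1:
            raise ValueError("tag count must be >= 1")


@dataclass
class TrimParams:
    """3' adaptor search parameters.

    adaptor      -- the 3' adaptor sequence (RNA accepted, normalized to DNA)
    min_overlap  -- minimum adaptor-prefix length required when the adaptor
                    runs off the read end (nt)
    max_mismatch -- mismatches tolerated inside the matched region
    """

    adaptor: str
    min_overlap: int = 8
    max_mismatch: int = 0

    def __post_init__(self):
        self.adaptor = normalize_seq(self.adaptor)
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if len(self.adaptor) < self.min_overlap:
            raise ValueError("adaptor shorter than min_overlap")


SELF_LIGATION = "self_ligation"
CLEAN = "clean"
NONCLEAN = "nonclean"


@dataclass(frozen=True)
class TrimResult:
    """Outcome of the 3' adaptor search for one tag.

    status=self_ligation  <=> adaptor found at position 0 (zero-length insert)
    status=clean          => insert = read[:adaptor_pos], length >= 1
    status=nonclean       => no acceptable adaptor occurrence
    """

    status: str
    insert: str | None = None
    adaptor_pos: int | None = None


@dataclass
class ReadProSummary:
    """Count-weighted library partition. Counts are exact; the percentage
    properties are derived views."""

    total_reads: int
    n_self_ligation: int
    n_nonclean: int
    n_clean: int
    n_qualified: int

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.total_reads if self.total_reads else 0.0

    @property
    def pct_self_ligation(self) -> float:
        return self._pct(self.n_self_ligation)

    @property
    def pct_nonclean(self) -> float:
        return self._pct(self.n_nonclean)

    @property
    def pct_clean(self) -> float:
        return self._pct(self.n_clean)

    @property
    def pct_qualified(self) -> float:
        return self._pct(self.n_qualified)


@dataclass
class ReadProResult:
    summary: ReadProSummary
    length_distribution: dict[int, float]
    qualified: list[UniqueTag]
    clean_tags: list[UniqueTag] = field(default_factory=list)


# ---------------------------------------------------------------------------
# collapsing


def _open_text(path: Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def iter_fastq_seqs(path) -> Iterator[str]:
    """Yield upper-cased sequences from a (possibly gzipped) FASTQ file,
    reporting the failing record index on malformed input."""
    path = Path(path)
    n = 0
    try:
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                n += 1
                yield str(rec.seq).upper()
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record at index {n} in {path}: {exc}") from exc


def collapse_reads(seqs: Iterable[str]) -> list[UniqueTag]:
    """Collapse an iterable of read sequences into unique tags, ordered by
    descending count then lexicographically."""
    counts = Counter(seqs)
    return [UniqueTag(seq=s, count=c)
            for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]


def collapse_fastq(fastq) -> list[UniqueTag]:
    """Collapse a FASTQ file into unique sequence tags (sum of counts equals
    the number of records)."""
    return collapse_reads(iter_fastq_seqs(fastq))


# ---------------------------------------------------------------------------
# adaptor search


def find_adaptor(seq: str, params: TrimParams) -> int | None:
    """Leftmost 0-based position of the 3' adaptor in ``seq``, or None.

    A position p is acceptable when the full adaptor matches ``seq[p:]``
    within ``max_mismatch`` mismatches, or when the adaptor runs off the read
    end and its prefix of length ``len(seq)-p >= min_overlap`` matches.
    """
    adaptor = params.adaptor
    la, ls = len(adaptor), len(seq)
    if params.max_mismatch == 0:
        # full occurrences come before any off-the-end occurrence
        p = seq.find(adaptor)
        if p != -1:
            return p
        for p in range(max(0, ls - la + 1), ls - params.min_overlap + 1):
            if seq[p:] == adaptor[: ls - p]:
                return p
        return None
    for p in range(ls):
        k = min(la, ls - p)
        if k < la and k < params.min_overlap:
            break
        mism = 0
        for a, b in zip(seq[p:p + k], adaptor[:k]):
            if a != b:
                mism += 1
                if mism > params.max_mismatch:
                    break
        if mism <= params.max_mismatch:
            return p
    return None


def classify_tag(tag: UniqueTag, params: TrimParams) -> TrimResult:
    """Classify one tag: adaptor at position 0 means a self-ligation read
    (5' adaptor ligated directly onto the 3' adaptor, no insert); any later
    position yields a clean read with the insert in front; no occurrence is
    nonclean."""
    p = find_adaptor(tag.seq, params)
    if p is None:
        return TrimResult(status=NONCLEAN)
    if p == 0:
        return TrimResult(status=SELF_LIGATION, adaptor_pos=0)
    return TrimResult(status=CLEAN, insert=tag.seq[:p], adaptor_pos=p)


# ---------------------------------------------------------------------------
# summaries


def length_histogram(tags: Iterable[UniqueTag]) -> dict[int, float]:
    """Count-weighted length distribution in percent, keyed by length (nt).

    Also usable on a mature-miRNA set (uniform counts) to produce the
    reference curve a well-made library should resemble.
    """
    counts: Counter[int] = Counter()
    total = 0
    for t in tags:
        counts[len(t.seq)] += t.count
        total += t.count
    if total == 0:
        return {}
    return {length: 100.0 * c / total for length, c in sorted(counts.items())}


def run_readpro(fastq, params: TrimParams, min_len: int = 15, max_len: int = 30,
                min_count: int = 2) -> ReadProResult:
    """Full raw-read processing stage.

    Collapses the FASTQ, classifies every tag, re-collapses the clean inserts
    (reads with different adaptor positions but identical inserts merge), and
    applies the qualification rule: insert length within [min_len, max_len]
    and collapsed count >= min_count. Inserts containing N survive trimming
    but are never qualified (exact matching cannot place them downstream).
    The length distribution is over all clean reads, count-weighted.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    tags = collapse_fastq(fastq)
    total = sum(t.count for t in tags)
    n_self = n_nonclean = n_clean = 0
    insert_counts: Counter[str] = Counter()
    for tag in tags:
        res = classify_tag(tag, params)
        if res.status == SELF_LIGATION:
            n_self += tag.count
        elif res.status == NONCLEAN:
            n_nonclean += tag.count
        else:
            n_clean += tag.count
            insert_counts[res.insert] += tag.count
    clean_tags = [UniqueTag(seq=s, count=c)
                  for s, c in sorted(insert_counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    qualified = [t for t in clean_tags
                 if min_len <= len(t.seq) <= max_len
                 and t.count >= min_count
                 and "N" not in t.seq]
    summary = ReadProSummary(
        total_reads=total, n_self_ligation=n_self, n_nonclean=n_nonclean,
        n_clean=n_clean, n_qualified=sum(t.count for t in qualified))
    return ReadProResult(summary=summary,
                         length_distribution=length_histogram(clean_tags),
                         qualified=qualified, clean_tags=clean_tags)


# ---------------------------------------------------------------------------
# collapsed FASTA dialect: >t<rank>_x<count>


def write_collapsed_fasta(tags: Iterable[UniqueTag], path) -> Path:
    """Write tags as ``>t<rank>_x<count>`` FASTA (rank from descending count,
    then lexicographic order)."""
    path = Path(path)
    ordered = sorted(tags, key=lambda t: (-t.count, t.seq))
    with open(path, "w") as fh:
        for rank, tag in enumerate(ordered, start=1):
            fh.write(f">t{rank}_x{tag.count}\n{tag.seq}\n")
    return path


def read_collapsed_fasta(path) -> list[UniqueTag]:
    """Read a ``>t<rank>_x<count>`` FASTA back into unique tags."""
    tags = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ident = rec.id
        if "_x" not in ident:
            raise ValueError(f"not a collapsed-FASTA header: >{ident}")
        count = int(ident.rsplit("_x", 1)[1])
        tags.append(UniqueTag(seq=normalize_seq(str(rec.seq)), count=count))
    return tags
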