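"""Mapping, classification and miRNA reporting.

Qualified tags are placed on pre-miRNA hairpins by exact substring matching
with progressive 3' soft-clipping: a tag is first tried unclipped, then with
its last 1..max_mod bases clipped, stopping at the smallest clip that yields
a hit. The clipped bases are the tag's 3' end modification, reported in
lower case with T shown as u (non-templated tails are dominated by
uridylation and adenylation, so the RNA alphabet reads naturally).

Tags that fail the hairpin search are classified against the remaining
reference categories in the fixed order rRNA -> tRNA -> mRNA -> ncRNA ->
genome (full-length exact match, no clipping; the genome is searched on both
strands), else "unknown". The first matching category wins, so every tag is
assigned exactly once.

Mature-miRNA reads yield: a TPM expression profile (the TPM denominator is
the total of mature-assigned read counts, so TPMs always sum to one
million), 3' modification pattern frequencies, isomiR tables keyed by
(5' shift, 3' shift, modification suffix), opposite-arm miRNA calls, and
detection counts.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .readpro import UniqueTag
from .reference import (Hairpin, MatureAnnotation, ReferenceIndexes,
                        ReferenceSet, SubstringIndex)

log = logging.getLogger("mirseq")

CATEGORY_KEYS = ("miRNA", "rRNA", "tRNA", "mRNA", "ncRNA", "genome", "unknown")

MATURE = "mature"
OPP_ARM = "opp_arm"
HAIRPIN_OTHER = "hairpin_other"


def display_suffix(tail: str) -> str:
    """Report form of a clipped 3' tail: lower case, T -> u."""
    return tail.lower().replace("t", "u")


def suffix_to_dna(suffix: str) -> str:
    """Inverse of :func:`display_suffix`."""
    return suffix.upper().replace("U", "T")


@dataclass(frozen=True)
class HairpinHit:
    """Placement of a tag on a hairpin.

    start/end are 1-based inclusive on the hairpin;
    ``hairpin[start..end] + dna(mod_suffix) == tag.seq``.
    """

    tag: UniqueTag
    hairpin: str
    start: int
    end: int
    mod_suffix: str = ""

    @property
    def matched_length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MatureAssignment:
    """A hit resolved against the hairpin's annotation.

    target is ``mature`` (shift5/shift3 defined, relative to the annotated
    mature: shift5 = start - mature.start, shift3 = end - mature.end),
    ``opp_arm`` (read sits on the unannotated arm) or ``hairpin_other``.
    """

    hit: HairpinHit
    target: str
    mature: str | None = None
    shift5: int | None = None
    shift3: int | None = None


@dataclass
class ExpressionProfile:
    """Per-mature raw counts (fractional after multi-map splitting) and TPM,
    both ordered by descending TPM."""

    raw_counts: dict[str, float]
    tpm: dict[str, float]

    @classmethod
    def from_raw(cls, raw: dict[str, float]) -> "ExpressionProfile":
        total = sum(raw.values())
        ordered = sorted(raw.items(), key=lambda kv: (-kv[1], kv[0]))
        raw_sorted = dict(ordered)
        tpm = {name: 1e6 * c / total for name, c in ordered} if total > 0 else {}
        return cls(raw_counts=raw_sorted, tpm=tpm)

    def top_share(self, k: int = 5) -> float:
        """Percentage of miRNA reads carried by the k most abundant matures."""
        if not self.tpm:
            return 0.0
        top = list(self.tpm.values())[:k]
        return sum(top) / 1e6 * 100.0


@dataclass(frozen=True)
class IsomiRRecord:
    """One isomiR of a mature miRNA: (5' shift, 3' shift, modification
    suffix) with the summed read count."""

    mature: str
    shift5: int
    shift3: int
    mod_suffix: str
    count: float


@dataclass
class OppMiRNA:
    """Reads clustering on the unannotated arm of a hairpin — a putative
    opposite-arm mature product. The defining span is the most abundant
    distinct matched span; isomiRs are expressed relative to it."""

    hairpin: str
    start: int
    end: int
    total_count: float
    isomirs: list[IsomiRRecord] = field(default_factory=list)


@dataclass
class DetectionCounts:
    detected_matures: int
    detected_premirnas: int
    detected_opp: int
    annotated_matures: int
    annotated_premirnas: int


@dataclass
class ClassificationResult:
    shares: dict[str, float]                       # category -> % of reads
    counts: dict[str, int]                         # category -> read count
    per_category: dict[str, list[UniqueTag]]
    mirna_hits: dict[str, list[HairpinHit]]        # tag seq -> hits


@dataclass
class ReadMapResult:
    classification: ClassificationResult
    assignments: list[MatureAssignment]
    profile: ExpressionProfile
    mod_frequencies: dict[str, float]
    isomirs: dict[str, list[IsomiRRecord]]
    opp_mirnas: list[OppMiRNA]
    detection: DetectionCounts


# ---------------------------------------------------------------------------
# alignment


def align_tag(tag: UniqueTag, index: SubstringIndex, max_mod: int = 3,
              min_match: int = 15) -> list[HairpinHit]:
    """Place a tag on hairpins with progressive 3' soft-clipping.

    Clip sizes c = 0, 1, ..., max_mod are tried in order and the search stops
    at the smallest c with at least one exact hit, so an unmodified placement
    is always preferred over a modified one. The clipped core must keep at
    least ``min_match`` nt. Returns every hit at the chosen clip level.
    """
    seq = tag.seq
    for c in range(max_mod + 1):
        core = seq[:-c] if c else seq
        if len(core) < min_match:
            break
        hits = index.find(core)
        if hits:
            suffix = display_suffix(seq[len(core):])
            return [HairpinHit(tag=tag, hairpin=name, start=off + 1,
                               end=off + len(core), mod_suffix=suffix)
                    for name, off, _strand in hits]
    return []


def classify_tags(tags: Sequence[UniqueTag], refs: ReferenceSet | ReferenceIndexes,
                  max_mod: int = 3, min_match: int = 15) -> ClassificationResult:
    """Assign every tag to its first matching category.

    Order: miRNA (hairpin hit, soft-clip allowed) -> rRNA -> tRNA -> mRNA ->
    ncRNA -> genome (both strands) -> unknown. Non-miRNA categories require a
    full-length exact match. Shares are count-weighted percentages of the
    input reads; all seven category keys are always present (absent reference
    categories simply score 0).
    """
    idx = refs if isinstance(refs, ReferenceIndexes) else ReferenceIndexes(refs)
    counts: dict[str, int] = {k: 0 for k in CATEGORY_KEYS}
    per_category: dict[str, list[UniqueTag]] = {k: [] for k in CATEGORY_KEYS}
    mirna_hits: dict[str, list[HairpinHit]] = {}
    for tag in tags:
        hits = align_tag(tag, idx.hairpins, max_mod=max_mod, min_match=min_match)
        if hits:
            cat = "miRNA"
            mirna_hits[tag.seq] = hits
        else:
            cat = "unknown"
            for name, cat_index in idx.categories:
                if cat_index.contains(tag.seq):
                    cat = name
                    break
        counts[cat] += tag.count
        per_category[cat].append(tag)
    total = sum(counts.values())
    shares = {k: (100.0 * v / total if total else 0.0) for k, v in counts.items()}
    return ClassificationResult(shares=shares, counts=counts,
                                per_category=per_category, mirna_hits=mirna_hits)


def assign_hit_to_mature(hit: HairpinHit, hairpin: Hairpin,
                         min_overlap_frac: float = 0.5) -> MatureAssignment:
    """Resolve a hairpin hit against the hairpin's mature annotations.

    The annotated mature with maximal overlap wins (ties go to the 5p arm);
    the read is a mature isomiR when the overlap covers at least
    ``min_overlap_frac`` of the matched span. Otherwise the read is
    ``opp_arm`` if the arm holding the span midpoint carries no annotation
    (midpoint <= hairpin midpoint means 5p), else ``hairpin_other``.
    """
    best: MatureAnnotation | None = None
    best_overlap = 0
    for m in sorted(hairpin.matures, key=lambda m: (m.arm != "5p", m.start)):
        overlap = min(hit.end, m.end) - max(hit.start, m.start) + 1
        if overlap > best_overlap:
            best, best_overlap = m, overlap
    if best is not None and best_overlap >= min_overlap_frac * hit.matched_length:
        return MatureAssignment(hit=hit, target=MATURE, mature=best.name,
                                shift5=hit.start - best.start,
                                shift3=hit.end - best.end)
    midpoint = (hit.start + hit.end) / 2
    arm = "5p" if midpoint <= (1 + len(hairpin.seq)) / 2 else "3p"
    if arm not in hairpin.annotated_arms():
        return MatureAssignment(hit=hit, target=OPP_ARM)
    return MatureAssignment(hit=hit, target=HAIRPIN_OTHER)


def assign_all(classification: ClassificationResult,
               refs: ReferenceSet) -> list[MatureAssignment]:
    """Resolve every miRNA-category hit of a classification run."""
    by_name = {hp.name: hp for hp in refs.hairpins}
    out = []
    for tag in classification.per_category["miRNA"]:
        for hit in classification.mirna_hits[tag.seq]:
            out.append(assign_hit_to_mature(hit, by_name[hit.hairpin]))
    return out


# ---------------------------------------------------------------------------
# per-tag mature resolution shared by profile / isomiR tables


def _mature_splits(assignments: Iterable[MatureAssignment]):
    """Group mature-target assignments by tag and split each tag's count
    equally across its distinct matures (1/k each; duplicate hits of the same
    mature are collapsed to the first)."""
    by_tag: dict[str, list[MatureAssignment]] = defaultdict(list)
    tag_count: dict[str, int] = {}
    for a in assignments:
        if a.target != MATURE:
            continue
        by_tag[a.hit.tag.seq].append(a)
        tag_count[a.hit.tag.seq] = a.hit.tag.count
    for seq, assigns in by_tag.items():
        per_mature: dict[str, MatureAssignment] = {}
        for a in assigns:
            per_mature.setdefault(a.mature, a)
        share = tag_count[seq] / len(per_mature)
        yield seq, tag_count[seq], per_mature, share


def build_profile(assignments: Iterable[MatureAssignment]) -> ExpressionProfile:
    """Per-mature expression. A tag hitting k distinct matures contributes
    count/k to each, so the total raw count equals the mature-assigned read
    count exactly and TPMs sum to one million."""
    raw: dict[str, float] = defaultdict(float)
    for _seq, _count, per_mature, share in _mature_splits(assignments):
        for name in per_mature:
            raw[name] += share
    return ExpressionProfile.from_raw(dict(raw))


def mod_pattern_frequencies(assignments: Iterable[MatureAssignment]) -> dict[str, float]:
    """Count-weighted frequency (%) of each 3' modification suffix over all
    mature-assigned reads; the empty suffix is the unmodified share. Each tag
    is counted once (its suffix is fixed by the clip level, not the hit)."""
    freq: Counter[str] = Counter()
    total = 0
    seen: set[str] = set()
    for a in assignments:
        if a.target != MATURE or a.hit.tag.seq in seen:
            continue
        seen.add(a.hit.tag.seq)
        freq[a.hit.mod_suffix] += a.hit.tag.count
        total += a.hit.tag.count
    return {s: 100.0 * c / total for s, c in
            sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))} if total else {}


def filter_frequent(frequencies: dict[str, float], min_pct: float = 1.0) -> dict[str, float]:
    """Report view: keep only patterns above ``min_pct`` percent."""
    return {s: f for s, f in frequencies.items() if f > min_pct}


def au_rich_share(frequencies: dict[str, float]) -> float:
    """Share (%) of modified reads whose suffix uses only a/u."""
    modified = {s: f for s, f in frequencies.items() if s}
    total = sum(modified.values())
    if total == 0:
        return 0.0
    rich = sum(f for s, f in modified.items() if set(s) <= {"a", "u"})
    return 100.0 * rich / total


def enumerate_isomirs(assignments: Iterable[MatureAssignment]
                      ) -> dict[str, list[IsomiRRecord]]:
    """IsomiR tables per mature, merged by (shift5, shift3, suffix) and
    sorted by descending count. Counts use the same 1/k multi-map split as
    the profile, so each mature's isomiR counts sum to its raw count."""
    table: dict[str, Counter] = defaultdict(Counter)
    for _seq, _count, per_mature, share in _mature_splits(assignments):
        for name, a in per_mature.items():
            table[name][(a.shift5, a.shift3, a.hit.mod_suffix)] += share
    out: dict[str, list[IsomiRRecord]] = {}
    for name, counter in table.items():
        records = [IsomiRRecord(mature=name, shift5=s5, shift3=s3,
                                mod_suffix=suf, count=c)
                   for (s5, s3, suf), c in counter.items()]
        records.sort(key=lambda r: (-r.count, r.shift5, r.shift3, r.mod_suffix))
        out[name] = records
    return out


def detect_opp_mirnas(assignments: Iterable[MatureAssignment],
                      opp_min_count: int = 2) -> list[OppMiRNA]:
    """Group opposite-arm reads per hairpin into putative opp-miRNAs.

    The defining span is the distinct matched span with the largest summed
    count (ties to the smaller start); the hairpin is reported only when the
    arm's total count reaches ``opp_min_count``. Member reads are re-keyed as
    isomiRs relative to the defining span.
    """
    per_hairpin: dict[str, list[MatureAssignment]] = defaultdict(list)
    for a in assignments:
        if a.target == OPP_ARM:
            per_hairpin[a.hit.hairpin].append(a)
    out = []
    for hp_name in sorted(per_hairpin):
        assigns = per_hairpin[hp_name]
        span_counts: Counter[tuple[int, int]] = Counter()
        for a in assigns:
            span_counts[(a.hit.start, a.hit.end)] += a.hit.tag.count
        total = sum(span_counts.values())
        if total < opp_min_count:
            continue
        (d_start, d_end), _ = max(span_counts.items(),
                                  key=lambda kv: (kv[1], -kv[0][0], -kv[0][1]))
        iso: Counter = Counter()
        for a in assigns:
            iso[(a.hit.start - d_start, a.hit.end - d_end, a.hit.mod_suffix)] += a.hit.tag.count
        records = [IsomiRRecord(mature=hp_name, shift5=s5, shift3=s3,
                                mod_suffix=suf, count=c)
                   for (s5, s3, suf), c in iso.items()]
        records.sort(key=lambda r: (-r.count, r.shift5, r.shift3, r.mod_suffix))
        out.append(OppMiRNA(hairpin=hp_name, start=d_start, end=d_end,
                            total_count=total, isomirs=records))
    return out


def detection_summary(profile: ExpressionProfile, refs: ReferenceSet,
                      opp: Sequence[OppMiRNA] = (),
                      other_hairpins: Iterable[str] = ()) -> DetectionCounts:
    """Detected vs annotated counts. A mature is detected when its raw count
    is positive; a pre-miRNA when any of its matures is detected or it
    carries opp-arm/other reads."""
    detected_matures = {n for n, c in profile.raw_counts.items() if c > 0}
    mature_to_hp = refs.mature_to_hairpins()
    detected_hp: set[str] = set()
    for name in detected_matures:
        detected_hp.update(mature_to_hp.get(name, ()))
    detected_hp.update(o.hairpin for o in opp)
    detected_hp.update(other_hairpins)
    return DetectionCounts(
        detected_matures=len(detected_matures),
        detected_premirnas=len(detected_hp),
        detected_opp=len(opp),
        annotated_matures=len({m.name for hp in refs.hairpins for m in hp.matures}),
        annotated_premirnas=len(refs.hairpins))


# ---------------------------------------------------------------------------
# isomiR alignment rendering (monospace block per hairpin)


def _fmt_count(c: float) -> str:
    return str(int(c)) if float(c).is_integer() else repr(round(c, 6))


def render_isomir_alignment(hairpin: Hairpin,
                            records: Sequence[IsomiRRecord]) -> str:
    """Monospace alignment of a hairpin's isomiRs.

    Line 1 is the hairpin sequence, lower case with mature regions upper
    case. Each record line is indented so that its first column is the
    record's hairpin start position; the matched body is upper case, the
    modification suffix lower case, followed by the read count and
    "shift5,shift3".
    """
    seq = hairpin.seq.lower()
    chars = list(seq)
    for m in hairpin.matures:
        for i in range(m.start - 1, m.end):
            chars[i] = chars[i].upper()
    lines = ["".join(chars)]
    by_name = {m.name: m for m in hairpin.matures}
    for rec in records:
        m = by_name.get(rec.mature)
        if m is None:
            raise ValueError(f"record for {rec.mature} does not belong to {hairpin.name}")
        start = m.start + rec.shift5
        end = m.end + rec.shift3
        if not (1 <= start <= end <= len(hairpin.seq)):
            raise ValueError(
                f"isomiR span {start}..{end} outside hairpin {hairpin.name}")
        body = hairpin.seq[start - 1:end].upper()
        lines.append(" " * (start - 1) + body + rec.mod_suffix
                     + f"  {_fmt_count(rec.count)} {rec.shift5},{rec.shift3}")
    return "\n".join(lines) + "\n"


_RECORD_RE = re.compile(
    r"^(?P<indent> *)(?P<body>[ACGTN]+)(?P<suffix>[acgun]*)"
    r"  (?P<count>[0-9.]+) (?P<s5>-?\d+),(?P<s3>-?\d+)$")


def parse_isomir_alignment(text: str, hairpin: Hairpin) -> list[IsomiRRecord]:
    """Parse a block produced by :func:`render_isomir_alignment` back into
    records (round-trip inverse, used for self-checks)."""
    lines = text.rstrip("\n").split("\n")
    records = []
    for line in lines[1:]:
        m = _RECORD_RE.match(line)
        if m is None:
            raise ValueError(f"unparsable isomiR line: {line!r}")
        start = len(m.group("indent")) + 1
        end = start + len(m.group("body")) - 1
        s5, s3 = int(m.group("s5")), int(m.group("s3"))
        mature = next((ma for ma in hairpin.matures
                       if ma.start == start - s5 and ma.end == end - s3), None)
        if mature is None:
            raise ValueError(f"no mature on {hairpin.name} consistent with line {line!r}")
        count = float(m.group("count"))
        records.append(IsomiRRecord(
            mature=mature.name, shift5=s5, shift3=s3,
            mod_suffix=m.group("suffix"),
            count=int(count) if count.is_integer() else count))
    return records


# ---------------------------------------------------------------------------
# whole stage


def run_readmap(tags: Sequence[UniqueTag], refs: ReferenceSet,
                max_mod: int = 3, min_match: int = 15,
                opp_min_count: int = 2) -> ReadMapResult:
    """Classify qualified tags and derive every miRNA report."""
    classification = classify_tags(tags, refs, max_mod=max_mod, min_match=min_match)
    assignments = assign_all(classification, refs)
    profile = build_profile(assignments)
    opp = detect_opp_mirnas(assignments, opp_min_count=opp_min_count)
    other_hp = {a.hit.hairpin for a in assignments if a.target == HAIRPIN_OTHER}
    return ReadMapResult(
        classification=classification,
        assignments=assignments,
        profile=profile,
        mod_frequencies=mod_pattern_frequencies(assignments),
        isomirs=enumerate_isomirs(assignments),
        opp_mirnas=opp,
        detection=detection_summary(profile, refs, opp, other_hairpins=other_hp))
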