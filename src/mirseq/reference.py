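"""miRBase-style reference handling.

Loads hairpin (pre-miRNA) and mature miRNA FASTA files, restricts them to one
species, locates each mature miRNA on its hairpin by exact substring search
(1-based inclusive coordinates, the convention used in all reports), assigns
arms by the midpoint rule, and builds exact-substring indexes for the ordered
non-miRNA reference categories (rRNA, tRNA, mRNA, ncRNA, genome).

Read placement deliberately uses exact substring matching rather than a
seed-and-extend aligner: with ~22 nt reads on short references, exact matching
is fully specifiable and testable against a naive scan, and 3' variation is
handled explicitly by soft-clipping at the mapping layer.
"""

from __future__ import annotations

import bisect
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

log = logging.getLogger("mirseq")

CATEGORY_ORDER = ("rRNA", "tRNA", "mRNA", "ncRNA", "genome")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_seq(seq: str) -> str:
    """Upper-case and convert RNA to DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class MatureAnnotation:
    """A mature miRNA located on its hairpin.

    Coordinates are 1-based inclusive, so ``hairpin.seq[start-1:end]`` equals
    the mature sequence. ``arm`` is ``"5p"`` if the mature's midpoint lies in
    the 5' half of the hairpin (ties go to 5p), else ``"3p"``.
    """

    name: str
    start: int
    end: int
    arm: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Hairpin:
    """A pre-miRNA with zero, one or two located mature annotations."""

    name: str
    seq: str
    matures: list[MatureAnnotation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seq)

    def mature_by_name(self, name: str) -> MatureAnnotation | None:
        for m in self.matures:
            if m.name == name:
                return m
        return None

    def annotated_arms(self) -> set[str]:
        return {m.arm for m in self.matures}


@dataclass
class ReferenceSet:
    """Hairpins plus the ordered non-miRNA reference categories.

    ``categories`` preserves the classification order rRNA -> tRNA -> mRNA ->
    ncRNA -> genome, with absent categories skipped. Each entry is
    ``(category name, {reference id: sequence})``.
    """

    hairpins: list[Hairpin]
    categories: list[tuple[str, dict[str, str]]] = field(default_factory=list)
    species: str = ""

    def hairpin_by_name(self, name: str) -> Hairpin | None:
        for hp in self.hairpins:
            if hp.name == name:
                return hp
        return None

    @property
    def n_matures(self) -> int:
        return sum(len(hp.matures) for hp in self.hairpins)

    def mature_to_hairpins(self) -> dict[str, list[str]]:
        """Mature name -> hairpin names carrying it (duplicated loci allowed)."""
        out: dict[str, list[str]] = {}
        for hp in self.hairpins:
            for m in hp.matures:
                out.setdefault(m.name, []).append(hp.name)
        return out


class SubstringIndex:
    """Exact-substring lookup over a collection of named references.

    Semantics are pinned to a naive scan: ``find(q)`` returns every
    ``(reference name, 0-based offset, strand)`` at which ``q`` occurs as an
    exact substring. With ``both_strands=True`` the reverse complement of each
    reference is searched as well and hits are reported with strand ``"-"``
    and the offset on the reverse-complemented sequence.

    Implemented as concatenated text with a separator that cannot occur in a
    DNA query, scanned with ``str.find``; reference boundaries are recovered
    by bisection. This is O(text) per query in the worst case but the
    references here (hairpins, small transcript sets) are short.
    """

    def __init__(self, seqs: Mapping[str, str] | Iterable[tuple[str, str]],
                 both_strands: bool = False):
        items = list(seqs.items()) if isinstance(seqs, Mapping) else list(seqs)
        self.names = [name for name, _ in items]
        self.both_strands = both_strands
        self._starts: list[int] = []
        parts = []
        pos = 0
        for _, seq in items:
            self._starts.append(pos)
            parts.append(seq)
            pos += len(seq) + 1
        self._text = "#".join(parts)
        if both_strands:
            self._rc_text = "#".join(revcomp(seq) for _, seq in items)
        else:
            self._rc_text = None

    def _scan(self, text: str, query: str, strand: str) -> list[tuple[str, int, str]]:
        hits = []
        i = text.find(query)
        while i != -1:
            ref_idx = bisect.bisect_right(self._starts, i) - 1
            hits.append((self.names[ref_idx], i - self._starts[ref_idx], strand))
            i = text.find(query, i + 1)
        return hits

    def find(self, query: str) -> list[tuple[str, int, str]]:
        if not query:
            raise ValueError("empty query")
        hits = self._scan(self._text, query, "+")
        if self._rc_text is not None:
            hits.extend(self._scan(self._rc_text, query, "-"))
        return hits

    def contains(self, query: str) -> bool:
        if not query:
            raise ValueError("empty query")
        if self._text.find(query) != -1:
            return True
        return self._rc_text is not None and self._rc_text.find(query) != -1


def build_substring_index(seqs, both_strands: bool = False) -> SubstringIndex:
    """Build a :class:`SubstringIndex`; an empty collection yields a valid
    index that returns no hits."""
    return SubstringIndex(seqs, both_strands=both_strands)


class ReferenceIndexes:
    """Pre-built substring indexes for a :class:`ReferenceSet`.

    The hairpin index is sense-strand only (reads are sequenced from the
    mature strand); the genome category, if present, is indexed on both
    strands. Transcript categories are sense-strand only.
    """

    def __init__(self, refs: ReferenceSet):
        self.refs = refs
        self.hairpins = build_substring_index(
            {hp.name: hp.seq for hp in refs.hairpins})
        self.categories: list[tuple[str, SubstringIndex]] = []
        for name, seqs in refs.categories:
            both = name == "genome"
            self.categories.append((name, build_substring_index(seqs, both_strands=both)))


# ---------------------------------------------------------------------------
# loading


def _species_match(identifier: str, species: str) -> bool:
    return identifier.lower().startswith(species.lower() + "-")


def _mature_stem(name: str) -> str:
    """Name stem used to pair a mature with its hairpin(s).

    miRBase mature ids carry an arm suffix (hsa-miR-21-5p) and use miR where
    hairpins use mir (hsa-mir-21); duplicated loci append a locus number to
    the hairpin (hsa-mir-121-1). The stem is the lower-cased id with a
    trailing -5p/-3p/* removed.
    """
    stem = name.lower()
    for suffix in ("-5p", "-3p", "*"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return stem


def _stem_compatible(mature_name: str, hairpin_name: str) -> bool:
    stem = _mature_stem(mature_name)
    hp = hairpin_name.lower()
    return hp == stem or hp.startswith(stem + "-")


def _read_fasta(path: Path) -> list[tuple[str, str]]:
    try:
        return [(rec.id, normalize_seq(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")]
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read FASTA {path}: {exc}") from exc


def locate_matures(hairpin: Hairpin,
                   mature_seqs: Sequence[tuple[str, str]]) -> list[MatureAnnotation]:
    """Place mature miRNAs on a hairpin by exact substring search.

    Each mature is placed at its first exact occurrence (1-based inclusive
    coordinates); a second occurrence triggers a warning and is ignored. The
    arm is 5p if the mature's midpoint is at or before the hairpin midpoint,
    else 3p. At most one mature is kept per arm (first wins, with a warning).
    """
    annotations: list[MatureAnnotation] = []
    taken_arms: set[str] = set()
    hp_mid = (1 + len(hairpin.seq)) / 2
    for name, seq in mature_seqs:
        off = hairpin.seq.find(seq)
        if off == -1:
            continue
        if hairpin.seq.find(seq, off + 1) != -1:
            log.warning("mature %s occurs more than once in %s; using first occurrence",
                        name, hairpin.name)
        start, end = off + 1, off + len(seq)
        arm = "5p" if (start + end) / 2 <= hp_mid else "3p"
        if arm in taken_arms:
            log.warning("hairpin %s already has a %s mature; skipping %s",
                        hairpin.name, arm, name)
            continue
        taken_arms.add(arm)
        annotations.append(MatureAnnotation(name=name, start=start, end=end, arm=arm))
    return annotations


def load_reference_set(hairpin_fasta, mature_fasta, species: str,
                       category_fastas: Mapping[str, object] | None = None) -> ReferenceSet:
    """Load a species' references from miRBase-style FASTA files.

    Only hairpin/mature records whose id begins with the species prefix
    (e.g. ``hsa-``) are retained; sequences are normalized U -> T. Matures
    are attached to name-stem-compatible hairpins at their first exact
    occurrence; a mature absent from every same-stem hairpin is skipped with
    a warning. Category FASTAs (keys among rRNA/tRNA/mRNA/ncRNA/genome, case
    insensitive) are loaded without species filtering — they come from
    databases that do not use the miRBase prefix convention.
    """
    hp_records = [(n, s) for n, s in _read_fasta(Path(hairpin_fasta))
                  if _species_match(n, species)]
    mat_records = [(n, s) for n, s in _read_fasta(Path(mature_fasta))
                   if _species_match(n, species)]
    if not hp_records:
        raise ValueError(f"empty reference: no hairpin records with species prefix {species!r}")

    hairpins = [Hairpin(name=n, seq=s) for n, s in hp_records]
    placed: set[str] = set()
    for hp in hairpins:
        candidates = [(n, s) for n, s in mat_records if _stem_compatible(n, hp.name)]
        hp.matures = locate_matures(hp, candidates)
        placed.update(m.name for m in hp.matures)
    for name, _ in mat_records:
        if name not in placed:
            log.warning("mature %s not found in any same-stem hairpin; skipped", name)

    categories: list[tuple[str, dict[str, str]]] = []
    if category_fastas:
        lowered = {k.lower(): v for k, v in category_fastas.items()}
        for cat in CATEGORY_ORDER:
            if cat.lower() in lowered:
                categories.append((cat, dict(_read_fasta(Path(lowered[cat.lower()])))))

    refs = ReferenceSet(hairpins=hairpins, categories=categories, species=species)
    log.info("loaded %d hairpins, %d located matures (species %s)",
             len(hairpins), refs.n_matures, species)
    return refs


# ---------------------------------------------------------------------------
# on-disk index directory (plain text: FASTA + TSV + JSON)


def save_index(refs: ReferenceSet, out_dir) -> Path:
    """Write a reloadable index directory (hairpin.fa, matures.tsv,
    <category>.fa, meta.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "hairpin.fa", "w") as fh:
        for hp in refs.hairpins:
            fh.write(f">{hp.name}\n{hp.seq}\n")
    with open(out / "matures.tsv", "w") as fh:
        fh.write("hairpin\tmature\tstart\tend\tarm\n")
        for hp in refs.hairpins:
            for m in hp.matures:
                fh.write(f"{hp.name}\t{m.name}\t{m.start}\t{m.end}\t{m.arm}\n")
    cat_files = {}
    for name, seqs in refs.categories:
        fname = f"{name.lower()}.fa"
        with open(out / fname, "w") as fh:
            for rid, seq in seqs.items():
                fh.write(f">{rid}\n{seq}\n")
        cat_files[name] = fname
    with open(out / "meta.json", "w") as fh:
        json.dump({"species": refs.species, "categories": cat_files}, fh, indent=2)
    return out


def load_index(index_dir) -> ReferenceSet:
    """Reload a :class:`ReferenceSet` written by :func:`save_index`."""
    d = Path(index_dir)
    if not (d / "meta.json").is_file():
        raise FileNotFoundError(f"not an index directory (no meta.json): {d}")
    meta = json.loads((d / "meta.json").read_text())
    hairpins = {n: Hairpin(name=n, seq=s) for n, s in _read_fasta(d / "hairpin.fa")}
    with open(d / "matures.tsv") as fh:
        header = fh.readline()
        assert header.startswith("hairpin")
        for line in fh:
            hp_name, name, start, end, arm = line.rstrip("\n").split("\t")
            hairpins[hp_name].matures.append(
                MatureAnnotation(name=name, start=int(start), end=int(end), arm=arm))
    categories = []
    for cat in CATEGORY_ORDER:
        if cat in meta["categories"]:
            categories.append((cat, dict(_read_fasta(d / meta["categories"][cat]))))
    return ReferenceSet(hairpins=list(hairpins.values()), categories=categories,
                        species=meta["species"])
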