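"""Deterministic synthetic small-RNA library generator with exact ground truth.

The generator emulates the structure of a 3'-adaptor-ligated small-RNA
library: each read is insert + 3' adaptor, padded with random downstream
bases or truncated to the read length. Inserts are drawn per read from a
configurable category mix — mature-miRNA isomiRs (5'/3' shifts plus a
non-templated 3' tail), fragments of rRNA/tRNA/mRNA/ncRNA decoy references,
"unknown" sequences matching nothing, zero-insert self-ligation reads, and
optionally adaptor-free (nonclean) reads.

Ground truth is exact by construction, not by expectation: every candidate
insert is pre-validated against the pipeline's own deterministic rules
before it may be planted. A miRNA combo (mature, shift5, shift3, suffix) is
admitted only if (a) the adaptor search finds the adaptor exactly at the
insert boundary and (b) hairpin placement round-trips to the planted combo
(unique hit, correct clip). Contaminant and unknown inserts must classify to
their intended category. Ambiguous candidates — e.g. a tail base that
extends the templated match — are excluded up front, so the bookkept
per-read labels coincide with what the pipeline reports, tag for tag.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .readpro import TrimParams, UniqueTag, find_adaptor
from .readmap import MATURE, align_tag, assign_hit_to_mature, suffix_to_dna
from .reference import Hairpin, ReferenceIndexes, ReferenceSet, locate_matures

DEFAULT_ADAPTOR = "TGGAATTCTCGGGTGCCAAGG"

#: Category mix of a well-prepared library: miRNA dominates, rRNA is the main
#: contaminant, self-ligation is rare (a high value flags a failed ligation).
DEFAULT_FRACTIONS = {
    "self_ligation": 0.01,
    "nonclean": 0.04,
    "miRNA": 0.60,
    "rRNA": 0.15,
    "tRNA": 0.05,
    "mRNA": 0.05,
    "ncRNA": 0.05,
    "unknown": 0.05,
}

#: Most reads match the annotated mature exactly; single-nucleotide 5'/3'
#: template shifts make up the rest.
DEFAULT_ISOMIR_MODEL = {
    (0, 0): 0.60,
    (1, 0): 0.08,
    (-1, 0): 0.05,
    (0, 1): 0.12,
    (0, -1): 0.10,
    (1, 1): 0.05,
}

#: 3' tails are dominated by uridylation, then adenylation (AU-rich overall);
#: the empty suffix is the unmodified share.
DEFAULT_MOD_MODEL = {
    "": 0.45,
    "u": 0.25,
    "a": 0.12,
    "uu": 0.08,
    "au": 0.04,
    "ua": 0.03,
    "g": 0.02,
    "c": 0.01,
}

_CATEGORY_KEYS = tuple(DEFAULT_FRACTIONS)
_CONTAMINANTS = ("rRNA", "tRNA", "mRNA", "ncRNA")


@dataclass
class SimConfig:
    """Study conditions for one synthetic library.

    n_reads      -- library size
    adaptor      -- 3' adaptor ligated to every insert
    fractions    -- category mix (must sum to 1)
    expression   -- per-mature weights; None means a 1/rank (Zipf) profile
                    over the reference's matures, the heavy-tailed shape of
                    real libraries
    isomir_model -- probabilities over (shift5, shift3) template shifts
    mod_model    -- probabilities over 3' tail suffixes (display alphabet)
    read_length  -- final read length (insert + adaptor padded/truncated)
    seed         -- RNG seed; (config, seed) -> byte-identical output
    min_len/max_len/min_count -- qualification rule used for ground-truth
                    roll-ups (matches the trimming stage defaults)
    """

    n_reads: int = 10_000
    adaptor: str = DEFAULT_ADAPTOR
    fractions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    expression: dict[str, float] | None = None
    isomir_model: dict[tuple[int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_ISOMIR_MODEL))
    mod_model: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MOD_MODEL))
    read_length: int = 50
    seed: int = 0
    min_len: int = 15
    max_len: int = 30
    min_count: int = 2
    min_overlap: int = 8

    def __post_init__(self):
        unknown_keys = set(self.fractions) - set(_CATEGORY_KEYS)
        if unknown_keys:
            raise ValueError(f"unknown fraction keys: {sorted(unknown_keys)}")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("fractions must be >= 0")
        if abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        for model in (self.isomir_model, self.mod_model):
            if any(p < 0 for p in model.values()):
                raise ValueError("model probabilities must be >= 0")

    def trim_params(self) -> TrimParams:
        return TrimParams(adaptor=self.adaptor, min_overlap=self.min_overlap)


@dataclass(frozen=True)
class SimRead:
    """Per-read ground-truth record."""

    category: str
    insert: str | None = None          # None for self-ligation / nonclean
    mature: str | None = None
    shift5: int | None = None
    shift3: int | None = None
    mod_suffix: str | None = None


@dataclass
class GroundTruth:
    """Per-read records plus roll-ups mirroring every pipeline report.

    Aggregates are pure bookkeeping over the records under the same
    qualification rule the trimming stage applies, so an end-to-end run must
    reproduce them exactly at tag level.
    """

    reads: list[SimRead]
    config: SimConfig
    # roll-ups
    total_reads: int = 0
    n_self_ligation: int = 0
    n_nonclean: int = 0
    n_clean: int = 0
    n_qualified: int = 0
    length_distribution: dict[int, float] = field(default_factory=dict)
    qualified_tags: list[UniqueTag] = field(default_factory=list)
    category_counts: dict[str, int] = field(default_factory=dict)
    category_shares: dict[str, float] = field(default_factory=dict)
    expression_raw: dict[str, float] = field(default_factory=dict)
    isomir_table: dict[str, dict[tuple[int, int, str], int]] = field(default_factory=dict)
    mod_frequencies: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_records(cls, reads: list[SimRead], config: SimConfig) -> "GroundTruth":
        gt = cls(reads=reads, config=config, total_reads=len(reads))
        insert_counts: Counter[str] = Counter()
        insert_info: dict[str, SimRead] = {}
        for r in reads:
            if r.category == "self_ligation":
                gt.n_self_ligation += 1
            elif r.category == "nonclean":
                gt.n_nonclean += 1
            else:
                gt.n_clean += 1
                insert_counts[r.insert] += 1
                insert_info.setdefault(r.insert, r)

        if gt.n_clean:
            length_counter: Counter[int] = Counter()
            for seq, c in insert_counts.items():
                length_counter[len(seq)] += c
            gt.length_distribution = {
                ln: 100.0 * c / gt.n_clean for ln, c in sorted(length_counter.items())}

        qualified = {
            seq: c for seq, c in insert_counts.items()
            if config.min_len <= len(seq) <= config.max_len and c >= config.min_count}
        gt.qualified_tags = [UniqueTag(seq=s, count=c) for s, c in
                             sorted(qualified.items(), key=lambda kv: (-kv[1], kv[0]))]
        gt.n_qualified = sum(qualified.values())

        cat_counts: Counter[str] = Counter()
        expr: Counter[str] = Counter()
        iso: dict[str, Counter] = {}
        mod: Counter[str] = Counter()
        n_mirna = 0
        for seq, c in qualified.items():
            r = insert_info[seq]
            cat_counts[r.category] += c
            if r.category == "miRNA":
                n_mirna += c
                expr[r.mature] += c
                iso.setdefault(r.mature, Counter())[(r.shift5, r.shift3, r.mod_suffix)] += c
                mod[r.mod_suffix] += c
        gt.category_counts = dict(cat_counts)
        total_q = gt.n_qualified
        gt.category_shares = {k: (100.0 * v / total_q if total_q else 0.0)
                              for k, v in cat_counts.items()}
        gt.expression_raw = dict(expr)
        gt.isomir_table = {m: dict(cnt) for m, cnt in iso.items()}
        gt.mod_frequencies = ({s: 100.0 * c / n_mirna for s, c in mod.items()}
                              if n_mirna else {})
        return gt


# ---------------------------------------------------------------------------
# toy references


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def make_toy_references(seed: int, n_hairpins: int = 20, hairpin_len: int = 80,
                        two_arm_frac: float = 0.4,
                        n_decoys_per_category: int = 4,
                        max_retries: int = 200) -> ReferenceSet:
    """Random hairpins with planted mature regions, plus non-miRNA decoys.

    Each hairpin gets a 5p mature of 20-23 nt near its 5' end; a fraction
    also gets a 3p mature near the 3' end. Every planted mature sequence is
    constructed to occur exactly once across the whole hairpin set, and the
    rRNA/tRNA/mRNA/ncRNA decoys are resampled until they contain no mature,
    so mapping ambiguity is ruled out by construction.
    """
    if n_hairpins < 1:
        raise ValueError("n_hairpins must be >= 1")
    rng = random.Random(seed)
    species = "syn"
    hairpins: list[Hairpin] = []
    mature_records: list[tuple[str, str]] = []   # (mature seq, hairpin name)

    for i in range(1, n_hairpins + 1):
        name = f"{species}-mir-{i}"
        for attempt in range(max_retries):
            seq = _random_seq(rng, hairpin_len)
            m5_len = rng.randint(20, 23)
            m5_start = rng.randint(4, 8)                      # 1-based
            m5 = seq[m5_start - 1: m5_start - 1 + m5_len]
            matures = [(f"{species}-miR-{i}-5p", m5)]
            if rng.random() < two_arm_frac:
                m3_len = rng.randint(20, 23)
                m3_end = hairpin_len - rng.randint(3, 7)      # 1-based
                m3 = seq[m3_end - m3_len: m3_end]
                matures.append((f"{species}-miR-{i}-3p", m3))
            all_prev = [hp.seq for hp in hairpins]
            ok = True
            for _, mseq in matures:
                if seq.count(mseq) != 1:
                    ok = False
                if any(prev.find(mseq) != -1 for prev in all_prev):
                    ok = False
            # previously planted matures must not reappear in the new hairpin
            if ok and any(seq.find(ms) != -1 for ms, _ in mature_records):
                ok = False
            if ok and len({ms for _, ms in matures}) == len(matures):
                hp = Hairpin(name=name, seq=seq)
                hp.matures = locate_matures(hp, matures)
                if len(hp.matures) == len(matures):
                    hairpins.append(hp)
                    mature_records.extend((mseq, name) for _, mseq in matures)
                    break
        else:
            raise RuntimeError(f"could not build a unique hairpin after {max_retries} tries")

    decoy_lengths = {"rRNA": 150, "tRNA": 75, "mRNA": 250, "ncRNA": 120}
    categories = []
    for cat in _CONTAMINANTS:
        seqs = {}
        for j in range(1, n_decoys_per_category + 1):
            for attempt in range(max_retries):
                seq = _random_seq(rng, decoy_lengths[cat])
                if not any(seq.find(mseq) != -1 for mseq, _ in mature_records):
                    seqs[f"{cat.lower()}-{j}"] = seq
                    break
            else:
                raise RuntimeError("could not build a mature-free decoy")
        categories.append((cat, seqs))
    return ReferenceSet(hairpins=hairpins, categories=categories, species=species)


# ---------------------------------------------------------------------------
# library simulation


def _classify_insert(insert: str, idx: ReferenceIndexes, max_mod: int,
                     min_match: int) -> str:
    tag = UniqueTag(seq=insert, count=1)
    if align_tag(tag, idx.hairpins, max_mod=max_mod, min_match=min_match):
        return "miRNA"
    for name, cat_index in idx.categories:
        if cat_index.contains(insert):
            return name
    return "unknown"


def _adaptor_pos_ok(insert: str, config: SimConfig) -> bool:
    """The adaptor (possibly truncated by the read length) must be found
    exactly at the insert boundary and keep >= min_overlap bases."""
    core = (insert + config.adaptor)[: config.read_length]
    if len(core) - len(insert) < config.min_overlap:
        return False
    return find_adaptor(core, config.trim_params()) == len(insert)


def _valid_mirna_combos(refs: ReferenceSet, idx: ReferenceIndexes,
                        config: SimConfig):
    """Per mature: the plantable (shift5, shift3, suffix) combos, their
    renormalized probabilities and insert sequences."""
    out = {}
    for hp in refs.hairpins:
        for m in hp.matures:
            combos, weights, inserts = [], [], []
            for (s5, s3), p_shift in config.isomir_model.items():
                start, end = m.start + s5, m.end + s3
                if not (1 <= start <= end <= len(hp.seq)):
                    continue
                core = hp.seq[start - 1:end]
                for suffix, p_mod in config.mod_model.items():
                    if p_shift * p_mod == 0:
                        continue
                    insert = core + suffix_to_dna(suffix)
                    if not (config.min_len <= len(insert) <= config.max_len):
                        continue
                    if not _adaptor_pos_ok(insert, config):
                        continue
                    tag = UniqueTag(seq=insert, count=1)
                    hits = align_tag(tag, idx.hairpins)
                    if len(hits) != 1:
                        continue
                    hit = hits[0]
                    if (hit.hairpin, hit.start, hit.end,
                            hit.mod_suffix) != (hp.name, start, end, suffix):
                        continue
                    a = assign_hit_to_mature(hit, hp)
                    if (a.target, a.mature, a.shift5, a.shift3) != (MATURE, m.name, s5, s3):
                        continue
                    combos.append((m.name, s5, s3, suffix))
                    weights.append(p_shift * p_mod)
                    inserts.append(insert)
            if combos:
                out[m.name] = (combos, weights, inserts)
    return out


def _build_pool(rng: random.Random, config: SimConfig, idx: ReferenceIndexes,
                category: str, refs: ReferenceSet, size: int,
                max_retries: int = 5000) -> list[str]:
    """Pre-validated insert pool for one contaminant/unknown category.

    Sampling from a finite pool keeps tag counts above the min_count filter
    at realistic library sizes.
    """
    pool: list[str] = []
    seen: set[str] = set()
    cat_seqs: list[str] = []
    if category != "unknown":
        cat_seqs = list(dict(refs.categories)[category].values())
    attempts = 0
    while len(pool) < size and attempts < max_retries:
        attempts += 1
        if category == "unknown":
            insert = _random_seq(rng, rng.randint(18, 26))
        else:
            ref = rng.choice(cat_seqs)
            ln = rng.randint(max(16, config.min_len), min(26, config.max_len))
            if len(ref) < ln:
                continue
            start = rng.randint(0, len(ref) - ln)
            insert = ref[start:start + ln]
        if insert in seen:
            continue
        seen.add(insert)
        if not _adaptor_pos_ok(insert, config):
            continue
        if _classify_insert(insert, idx, max_mod=3, min_match=15) != category:
            continue
        pool.append(insert)
    if not pool:
        raise RuntimeError(f"could not build an insert pool for category {category}")
    return pool


def _nonclean_pool(rng: random.Random, config: SimConfig, size: int = 50,
                   max_retries: int = 5000) -> list[str]:
    pool = []
    params = config.trim_params()
    attempts = 0
    while len(pool) < size and attempts < max_retries:
        attempts += 1
        seq = _random_seq(rng, config.read_length)
        if find_adaptor(seq, params) is None:
            pool.append(seq)
    if not pool:
        raise RuntimeError("could not build adaptor-free reads")
    return pool


def simulate_library(config: SimConfig, refs: ReferenceSet,
                     fastq_path) -> GroundTruth:
    """Write a synthetic FASTQ and return its exact ground truth.

    Reads are ``insert + adaptor`` padded with random bases (or truncated)
    to ``read_length``; self-ligation reads start with the adaptor at
    position 0; nonclean reads carry no adaptor at all. Quality strings are
    constant (no error model: matching downstream is exact, so errors would
    only relabel reads as nonclean/unknown).
    """
    rng = random.Random(config.seed)
    fastq_path = Path(fastq_path)
    if config.n_reads == 0:
        fastq_path.write_text("")
        return GroundTruth.from_records([], config)

    idx = ReferenceIndexes(refs)
    active = {k: v for k, v in config.fractions.items() if v > 0}
    if "miRNA" in active:
        combos = _valid_mirna_combos(refs, idx, config)
        if not combos:
            raise ValueError("miRNA fraction > 0 but no plantable mature combos")
        mature_names = sorted(combos)
        if config.expression is not None:
            expr_weights = [config.expression.get(m, 0.0) for m in mature_names]
        else:
            expr_weights = [1.0 / (i + 1) for i in range(len(mature_names))]
    pools = {}
    for cat in _CONTAMINANTS:
        if active.get(cat):
            pools[cat] = _build_pool(rng, config, idx, cat, refs,
                                     size=min(150, max(20, config.n_reads // 50)))
    if active.get("unknown"):
        pools["unknown"] = _build_pool(rng, config, idx, "unknown", refs,
                                       size=min(150, max(20, config.n_reads // 50)))
    if active.get("nonclean"):
        pools["nonclean"] = _nonclean_pool(rng, config)

    cats = list(active)
    weights = [active[c] for c in cats]
    drawn = rng.choices(cats, weights=weights, k=config.n_reads)

    records: list[SimRead] = []
    lines: list[str] = []
    L = config.read_length
    adaptor = config.adaptor
    for i, cat in enumerate(drawn):
        if cat == "self_ligation":
            core = adaptor[:L]
            record = SimRead(category=cat)
        elif cat == "nonclean":
            core = rng.choice(pools["nonclean"])
            record = SimRead(category=cat)
        elif cat == "miRNA":
            name = rng.choices(mature_names, weights=expr_weights, k=1)[0]
            c_list, c_weights, c_inserts = combos[name]
            j = rng.choices(range(len(c_list)), weights=c_weights, k=1)[0]
            _, s5, s3, suffix = c_list[j]
            insert = c_inserts[j]
            core = (insert + adaptor)[:L]
            record = SimRead(category=cat, insert=insert, mature=name,
                             shift5=s5, shift3=s3, mod_suffix=suffix)
        else:
            insert = rng.choice(pools[cat])
            core = (insert + adaptor)[:L]
            record = SimRead(category=cat, insert=insert)
        if len(core) < L:
            core += _random_seq(rng, L - len(core))
        records.append(record)
        lines.append(f"@r{i}\n{core}\n+\n{'I' * L}\n")

    with open(fastq_path, "w") as fh:
        fh.writelines(lines)
    return GroundTruth.from_records(records, config)
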