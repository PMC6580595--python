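"""Junction-read processing: trim, map, call, deduplicate, merge.

LM-PCR junction reads cross the transposon/genome boundary: a residual
transposon tag at the 5' end, then genomic sequence beginning at the TA
integration site, then (if the fragment is short) sequencing adapter. The
pipeline trims the tag and adapter, maps the genomic portion, snaps the
call to the junction TA, and collapses duplicate reads into unique
insertion events.

Convention (fixed here and mirrored by the read synthesizer): the
transposon tag ends immediately 5' of the TA, so the trimmed genomic
sequence begins with the TA. For a read mapped on the forward strand the
TA offset is the alignment start; on the reverse strand it is the
alignment end minus 2. Transposon orientation is recorded as the mapping
strand of the junction read; a global ``orientation_flip`` accommodates
the opposite terminal-repeat geometry.

The built-in exact-match mapper is intended for toy genomes; real screens
enter through :func:`load_alignments` (SAM/BAM produced by an external
aligner).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .genome import ReferenceGenome, reverse_complement

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["sample_id", "chrom", "pos", "orientation", "read_count"]

_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class JunctionRead:
    read_id: str
    sequence: str
    quality: Optional[str] = None


@dataclass(frozen=True)
class TrimmedRead:
    read_id: str
    genomic_sequence: str
    tag_found: bool
    tag_mismatches: int


@dataclass(frozen=True)
class Rejected:
    """Categorized rejection of a read at some pipeline stage."""

    reason: str  # no_tag | too_short | unmapped | multimapped | no_ta | blacklisted


@dataclass(frozen=True)
class InsertionCall:
    """One unique insertion event. ``pos`` is the 0-based offset of the TA's T."""

    sample_id: str
    chrom: str
    pos: int
    orientation: str
    read_count: int = 1


@dataclass
class InsertionDataset:
    """Unique insertion calls pooled across samples, plus the sample sheet.

    ``calls`` columns: sample_id, chrom, pos, orientation, read_count
    (and ``arm`` once merged against a sample sheet). Identical positions in
    different samples are distinct independent events; ``n_total`` is the
    number of unique events.
    """

    calls: pd.DataFrame
    samples: Dict[str, str] = field(default_factory=dict)  # sample_id -> arm

    def __post_init__(self) -> None:
        missing = [c for c in CALL_COLUMNS if c not in self.calls.columns]
        if missing:
            raise ValueError(f"calls frame missing columns: {missing}")
        if self.samples:
            unknown = set(self.calls["sample_id"]) - set(self.samples)
            if unknown:
                raise ValueError(f"samples absent from sample sheet: {sorted(unknown)}")
            if "arm" not in self.calls.columns:
                self.calls = self.calls.assign(
                    arm=self.calls["sample_id"].map(self.samples)
                )

    @property
    def n_total(self) -> int:
        return int(len(self.calls))

    def arm(self, which: str) -> pd.DataFrame:
        if "arm" not in self.calls.columns:
            raise ValueError("dataset has no arm labels; merge with a sample sheet first")
        return self.calls[self.calls["arm"] == which]

    def has_arm(self, which: str) -> bool:
        return which in set(self.samples.values())

    @classmethod
    def from_calls(
        cls, calls: Iterable[InsertionCall], samples: Optional[Dict[str, str]] = None
    ) -> "InsertionDataset":
        rows = [
            (c.sample_id, c.chrom, c.pos, c.orientation, c.read_count) for c in calls
        ]
        frame = pd.DataFrame(rows, columns=CALL_COLUMNS)
        return cls(calls=frame, samples=samples or {})

    def to_tsv(self, path: str | Path) -> None:
        self.calls.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, samples: Optional[Dict[str, str]] = None
    ) -> "InsertionDataset":
        frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
        return cls(calls=frame, samples=samples or {})

    def to_bed(self, path: str | Path) -> None:
        """BED6: chrom, ta_start, ta_start+2, sample_id, read_count, orientation."""
        with open(path, "w") as fh:
            for row in self.calls.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\t{row.pos}\t{row.pos + 2}\t{row.sample_id}\t"
                    f"{row.read_count}\t{row.orientation}\n"
                )


# ---------------------------------------------------------------------------
# Trimming


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_read(
    read: JunctionRead,
    transposon_tag: str,
    adapter: str = "",
    max_tag_mismatches: int = 1,
    min_genomic_len: int = 20,
    adapter_min_overlap: int = 8,
) -> TrimmedRead | Rejected:
    """Remove the 5' transposon tag and any 3' adapter.

    The tag must match the read prefix within ``max_tag_mismatches``.
    Adapter removal: an internal occurrence must cover the full adapter
    (<=1 mismatch); a partial occurrence is only removed as a read suffix
    of >= ``adapter_min_overlap`` bases (mismatch tolerated only at >= 10
    bases of overlap). Reads lacking the tag or whose genomic portion is
    shorter than ``min_genomic_len`` are rejected (no_tag | too_short).
    """
    seq = read.sequence.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"read {read.read_id!r} contains non-ACGTN characters: {sorted(bad)}")
    tag = transposon_tag.upper()
    if len(seq) < len(tag):
        return Rejected("no_tag")
    mism = _hamming(seq[: len(tag)], tag)
    if mism > max_tag_mismatches:
        return Rejected("no_tag")
    genomic = seq[len(tag):]

    if adapter:
        ad = adapter.upper()
        cut = None
        for i in range(len(genomic)):
            overlap = min(len(ad), len(genomic) - i)
            if overlap < len(ad) and i + overlap < len(genomic):
                continue  # internal partial matches are not adapter evidence
            if overlap < adapter_min_overlap:
                break
            allowed = 1 if overlap >= 10 else 0
            if _hamming(genomic[i : i + overlap], ad[:overlap]) <= allowed:
                cut = i
                break
        if cut is not None:
            genomic = genomic[:cut]

    if len(genomic) < min_genomic_len:
        return Rejected("too_short")
    return TrimmedRead(read.read_id, genomic, tag_found=True, tag_mismatches=mism)


# ---------------------------------------------------------------------------
# Mapping


def _find_occurrences(haystack: str, needle: str, limit: int) -> List[int]:
    hits: List[int] = []
    start = 0
    while len(hits) < limit:
        i = haystack.find(needle, start)
        if i < 0:
            break
        hits.append(i)
        start = i + 1
    return hits


def map_read_exact(
    trimmed: TrimmedRead, genome: ReferenceGenome
) -> Tuple[str, int, int, str] | Rejected:
    """Exact-match placement of the genomic portion on either strand.

    Returns ``(chrom, start, end, strand)`` for a unique hit, otherwise
    ``Rejected('unmapped')`` or ``Rejected('multimapped')``. Intended for
    toy genomes; genome-scale data should be aligned externally and
    ingested with :func:`load_alignments`.
    """
    seq = trimmed.genomic_sequence
    rc = reverse_complement(seq)
    queries = [(seq, "+")] if rc == seq else [(seq, "+"), (rc, "-")]
    hits: List[Tuple[str, int, str]] = []
    for chrom in genome.chrom_names:
        hay = genome.sequences[chrom]
        for query, strand in queries:
            for i in _find_occurrences(hay, query, limit=2):
                hits.append((chrom, i, strand))
                if len(hits) > 1:
                    return Rejected("multimapped")
    if not hits:
        return Rejected("unmapped")
    if len(hits) > 1:
        return Rejected("multimapped")
    chrom, start, strand = hits[0]
    return (chrom, start, start + len(seq), strand)


def load_alignments(
    sam_path: str | Path,
    sample_id: str,
    genome: Optional[ReferenceGenome] = None,
    min_mapq: int = 10,
) -> Iterator[Tuple[str, str, int, int, str]]:
    """Yield (read_id, chrom, start, end, strand) from SAM/BAM.

    Primary, mapped alignments with MAPQ >= ``min_mapq`` only; secondary
    and supplementary records are skipped. Coordinates are 0-based
    half-open. If ``genome`` is given, header sequence names must be a
    subset of its chromosomes.
    """
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
        if genome is not None:
            unknown = set(sam.references) - set(genome.chrom_names)
            if unknown:
                raise ValueError(
                    f"{sam_path}: header names absent from genome: {sorted(unknown)}"
                )
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            strand = "-" if rec.is_reverse else "+"
            yield (rec.query_name, rec.reference_name, rec.reference_start,
                   rec.reference_end, strand)


# ---------------------------------------------------------------------------
# Calling


def call_insertion(
    mapped: Tuple[str, int, int, str],
    genome: ReferenceGenome,
    require_ta: bool = True,
    orientation_flip: bool = False,
) -> Tuple[str, int, str] | Rejected:
    """Snap a mapped junction read to its TA site.

    By the trimming convention the genomic portion begins with the junction
    TA: forward-strand reads place it at the alignment start, reverse-strand
    reads at the alignment end minus 2. Returns ``(chrom, ta_position,
    orientation)`` or ``Rejected('no_ta')``.
    """
    chrom, start, end, strand = mapped
    length = genome.lengths[chrom]
    if start < 0 or end > length:
        raise ValueError(f"interval [{start}, {end}) outside {chrom} (length {length})")
    ta = start if strand == "+" else end - 2
    if require_ta and genome.sequences[chrom][ta : ta + 2] != "TA":
        return Rejected("no_ta")
    orientation = strand
    if orientation_flip:
        orientation = "-" if orientation == "+" else "+"
    return (chrom, ta, orientation)


# ---------------------------------------------------------------------------
# Deduplication, filtering, merging


def _blacklist_tree(blacklist_regions: Sequence[Tuple[str, int, int]]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for chrom, start, end in blacklist_regions:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def deduplicate_and_filter(
    candidates: Sequence[Tuple[str, int, str]],
    sample_id: str,
    min_reads: int = 1,
    blacklist_regions: Sequence[Tuple[str, int, int]] = (),
    merge_opposite_orientations: bool = False,
) -> Tuple[InsertionDataset, Counter]:
    """Collapse per-read candidates into unique insertion calls.

    Candidates (all from one sample) are collapsed on
    (chrom, ta_position, orientation); ``read_count`` is the number of
    collapsed reads. Calls inside blacklist regions or with fewer than
    ``min_reads`` supporting reads are removed. Returns the per-sample
    dataset and an attrition counter (in read units): blacklisted,
    low_support, duplicate_reads, retained_calls.
    """
    trees = _blacklist_tree(blacklist_regions)
    counts: Counter = Counter()
    attrition: Counter = Counter()
    for chrom, ta, orientation in candidates:
        if chrom in trees and trees[chrom].overlap(ta, ta + 2):
            attrition["blacklisted"] += 1
            continue
        counts[(chrom, ta, orientation)] += 1

    if merge_opposite_orientations:
        merged: Counter = Counter()
        for (chrom, ta, orientation), n in counts.items():
            # keep the orientation with more reads; ties resolve to '+'
            key = (chrom, ta)
            merged[key] += n
        by_site: Dict[Tuple[str, int], str] = {}
        for (chrom, ta, orientation), n in sorted(
            counts.items(), key=lambda kv: (-kv[1], kv[0][2])
        ):
            by_site.setdefault((chrom, ta), orientation)
        counts = Counter(
            {(chrom, ta, by_site[(chrom, ta)]): n for (chrom, ta), n in merged.items()}
        )

    calls: List[InsertionCall] = []
    for (chrom, ta, orientation), n in sorted(counts.items()):
        if n < min_reads:
            attrition["low_support"] += n
            continue
        calls.append(InsertionCall(sample_id, chrom, ta, orientation, read_count=n))
        attrition["retained_calls"] += 1
        attrition["duplicate_reads"] += n - 1
    dataset = InsertionDataset.from_calls(calls)
    return dataset, attrition


def merge_samples(
    per_sample: Dict[str, InsertionDataset], sample_sheet: Dict[str, str]
) -> InsertionDataset:
    """Pool per-sample call sets into one dataset with arm labels.

    Identical positions in different samples remain distinct independent
    events. Every sample in the data must appear in the sheet.
    """
    unknown = set(per_sample) - set(sample_sheet)
    if unknown:
        raise ValueError(f"samples missing from sample sheet: {sorted(unknown)}")
    frames = [ds.calls[CALL_COLUMNS] for ds in per_sample.values() if len(ds.calls)]
    if frames:
        calls = pd.concat(frames, ignore_index=True)
    else:
        calls = pd.DataFrame(columns=CALL_COLUMNS)
    calls = calls.sort_values(["chrom", "pos", "sample_id"]).reset_index(drop=True)
    return InsertionDataset(calls=calls, samples=dict(sample_sheet))


# ---------------------------------------------------------------------------
# Orchestration


def read_fastq(path: str | Path) -> Iterator[JunctionRead]:
    with pysam.FastxFile(str(path)) as fq:
        for rec in fq:
            yield JunctionRead(rec.name, rec.sequence, rec.quality)


def process_sample(
    reads: Iterable[JunctionRead],
    genome: ReferenceGenome,
    sample_id: str,
    transposon_tag: str,
    adapter: str = "",
    max_tag_mismatches: int = 1,
    min_genomic_len: int = 20,
    min_reads: int = 1,
    require_ta: bool = True,
    orientation_flip: bool = False,
    blacklist_regions: Sequence[Tuple[str, int, int]] = (),
    merge_opposite_orientations: bool = False,
) -> Tuple[InsertionDataset, Counter]:
    """Full per-sample pipeline: trim -> map -> call -> deduplicate.

    Returns the per-sample dataset and an exact read-unit attrition ledger:
    raw_reads = no_tag + too_short + unmapped + multimapped + no_ta
    + blacklisted + low_support + retained_calls + duplicate_reads.
    """
    attrition: Counter = Counter()
    candidates: List[Tuple[str, int, str]] = []
    for read in reads:
        attrition["raw_reads"] += 1
        trimmed = trim_read(
            read, transposon_tag, adapter,
            max_tag_mismatches=max_tag_mismatches,
            min_genomic_len=min_genomic_len,
        )
        if isinstance(trimmed, Rejected):
            attrition[trimmed.reason] += 1
            continue
        mapped = map_read_exact(trimmed, genome)
        if isinstance(mapped, Rejected):
            attrition[mapped.reason] += 1
            continue
        called = call_insertion(
            mapped, genome, require_ta=require_ta, orientation_flip=orientation_flip
        )
        if isinstance(called, Rejected):
            attrition[called.reason] += 1
            continue
        candidates.append(called)

    dataset, dedup_attrition = deduplicate_and_filter(
        candidates, sample_id,
        min_reads=min_reads,
        blacklist_regions=blacklist_regions,
        merge_opposite_orientations=merge_opposite_orientations,
    )
    attrition.update(dedup_attrition)
    return dataset, attrition


def attrition_balanced(attrition: Counter) -> bool:
    """Check the exact read-unit ledger produced by :func:`process_sample`."""
    sinks = (
        attrition["no_tag"] + attrition["too_short"] + attrition["unmapped"]
        + attrition["multimapped"] + attrition["no_ta"] + attrition["blacklisted"]
        + attrition["low_support"] + attrition["retained_calls"]
        + attrition["duplicate_reads"]
    )
    return attrition["raw_reads"] == sinks
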