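"""Reference genomes, TA-dinucleotide indexing, and gene counting regions.

The Sleeping Beauty transposase integrates exclusively at TA dinucleotides,
so the null sample space of an insertion screen is the set of genomic TA
sites. This module builds that index and constructs, for each gene, the
counting region used by the gCIS2 test: the transcription unit plus a
strand-aware upstream promoter window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pyfaidx

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceGenome:
    """An in-memory reference genome (uppercase DNA, ordered chromosomes)."""

    chrom_names: List[str]
    sequences: Dict[str, str]
    lengths: Dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.lengths = {}
        for name in self.chrom_names:
            seq = self.sequences[name]
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )
            self.lengths[name] = len(seq)

    @classmethod
    def from_dict(cls, sequences: Mapping[str, str]) -> "ReferenceGenome":
        upper = {name: seq.upper() for name, seq in sequences.items()}
        return cls(chrom_names=list(upper), sequences=upper)

    @classmethod
    def from_fasta(cls, path: str | Path, exclude_softmasked: bool = False) -> "ReferenceGenome":
        """Load a FASTA. With ``exclude_softmasked``, lowercase (soft-masked)
        bases become N so that masked regions carry no TA sites; otherwise
        they are uppercased and counted normally."""
        fa = pyfaidx.Fasta(str(path), sequence_always_upper=not exclude_softmasked)
        seqs = {}
        for name in fa.keys():
            seq = str(fa[name][:])
            if exclude_softmasked:
                seq = "".join("N" if b.islower() else b for b in seq).upper()
            seqs[name] = seq
        fa.close()
        return cls(chrom_names=list(seqs), sequences=seqs)

    def to_fasta(self, path: str | Path, line_width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in self.chrom_names:
                fh.write(f">{name}\n")
                seq = self.sequences[name]
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]


@dataclass
class TAIndex:
    """Sorted per-chromosome TA-site coordinates (offset of the T).

    A TA site at offset ``t`` occupies ``[t, t+2)``. TA is its own reverse
    complement, so each genomic site is counted exactly once regardless of
    strand.
    """

    positions: Dict[str, np.ndarray]

    @property
    def per_chrom_counts(self) -> Dict[str, int]:
        return {c: int(p.size) for c, p in self.positions.items()}

    @property
    def ta_total(self) -> int:
        return int(sum(p.size for p in self.positions.values()))

    def count_in_region(self, chrom: str, start: int, end: int) -> int:
        """Number of TA sites fully contained in ``[start, end)``."""
        if chrom not in self.positions:
            raise KeyError(f"unknown chromosome: {chrom!r}")
        if start > end:
            raise ValueError(f"start > end: [{start}, {end})")
        pos = self.positions[chrom]
        # whole dinucleotide inside the region: start <= t and t + 2 <= end
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end - 2, side="right")
        return int(max(hi - lo, 0))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\toffset\n")
            for chrom, pos in self.positions.items():
                for t in pos:
                    fh.write(f"{chrom}\t{t}\n")

    def summary(self) -> "pd.DataFrame":  # noqa: F821 - imported lazily
        import pandas as pd

        rows = [(c, n) for c, n in self.per_chrom_counts.items()]
        return pd.DataFrame(rows, columns=["chrom", "ta_count"])


def build_ta_index(genome: ReferenceGenome) -> TAIndex:
    """Scan every chromosome for TA dinucleotides.

    Sequences held in a :class:`ReferenceGenome` are uppercase A/C/G/T/N;
    soft-masking is resolved at FASTA load time (see
    :meth:`ReferenceGenome.from_fasta`). N-containing windows never match.
    """
    positions: Dict[str, np.ndarray] = {}
    for chrom in genome.chrom_names:
        seq = genome.sequences[chrom]
        if len(seq) < 2:
            positions[chrom] = np.empty(0, dtype=np.int64)
            continue
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        hits = np.flatnonzero((arr[:-1] == ord("T")) & (arr[1:] == ord("A")))
        positions[chrom] = hits.astype(np.int64)
    return TAIndex(positions=positions)


@dataclass
class GeneModel:
    """A gene's transcription unit plus its gCIS2 counting region.

    The counting region extends the transcription unit by ``promoter_window``
    bp upstream of the transcription start site (strand-aware), clamped to
    chromosome bounds. ``ta_count`` is the number of TA sites fully inside
    the counting region.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    region_start: int
    region_end: int
    ta_count: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start must be < tx_end")
        if not (self.region_start <= self.tx_start and self.tx_end <= self.region_end):
            raise ValueError(f"{self.gene_id}: counting region must contain the gene body")

    @property
    def region_length(self) -> int:
        return self.region_end - self.region_start


def make_gene_model(
    gene_id: str,
    chrom: str,
    strand: str,
    tx_start: int,
    tx_end: int,
    chrom_length: int,
    promoter_window: int,
    ta_index: Optional[TAIndex] = None,
) -> GeneModel:
    """Build a GeneModel with its strand-aware promoter extension."""
    if strand == "+":
        region_start = max(0, tx_start - promoter_window)
        region_end = min(chrom_length, tx_end)
    else:
        region_start = max(0, tx_start)
        region_end = min(chrom_length, tx_end + promoter_window)
    gm = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        region_start=region_start,
        region_end=region_end,
    )
    if ta_index is not None:
        gm.ta_count = ta_index.count_in_region(chrom, region_start, region_end)
    return gm


# ---------------------------------------------------------------------------
# Annotation parsing (BED12 / GFF3 / refFlat-style TSV)


def _detect_format(path: str | Path) -> str:
    name = str(path).lower()
    if name.endswith((".bed", ".bed12")):
        return "bed"
    if name.endswith((".gff", ".gff3")):
        return "gff3"
    return "refflat"


def _spans_from_bed(path: str | Path) -> List[tuple]:
    spans = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED record needs >= 6 fields")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name, strand = fields[3], fields[5]
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED record") from exc
            spans.append((name, chrom, strand, start, end))
    return spans


def _spans_from_refflat(path: str | Path) -> List[tuple]:
    # refFlat columns: geneName transcriptName chrom strand txStart txEnd ...
    spans = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: refFlat record needs >= 6 fields")
            try:
                name, chrom, strand = fields[0], fields[2], fields[3]
                start, end = int(fields[4]), int(fields[5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed refFlat record") from exc
            spans.append((name, chrom, strand, start, end))
    return spans


def _spans_from_gff3(path: str | Path) -> List[tuple]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    spans = []
    gene_types = ["gene"] if any(True for _ in db.features_of_type("gene")) else ["mRNA", "transcript"]
    for feat in db.all_features():
        if feat.featuretype not in gene_types:
            continue
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        spans.append((gene_id, feat.seqid, feat.strand, feat.start - 1, feat.end))
    return spans


def load_gene_models(
    annotation_path: str | Path,
    genome: ReferenceGenome,
    promoter_window: int = 40_000,
    ta_index: Optional[TAIndex] = None,
    fmt: Optional[str] = None,
) -> List[GeneModel]:
    """Load gene models and construct their counting regions.

    Accepts BED12 (or BED6+), GFF3, or refFlat-style TSV. Multiple records
    sharing a gene_id (transcript isoforms) are merged to the union of
    their spans. Genes on chromosomes absent from the genome are skipped
    with a warning. ``ta_index`` defaults to a fresh scan of ``genome``.
    """
    fmt = fmt or _detect_format(annotation_path)
    if fmt == "bed":
        spans = _spans_from_bed(annotation_path)
    elif fmt == "gff3":
        spans = _spans_from_gff3(annotation_path)
    elif fmt == "refflat":
        spans = _spans_from_refflat(annotation_path)
    else:
        raise ValueError(f"unknown annotation format: {fmt!r}")

    if ta_index is None:
        ta_index = build_ta_index(genome)

    merged: Dict[str, list] = {}
    for name, chrom, strand, start, end in spans:
        if name in merged:
            rec = merged[name]
            if rec[0] != chrom or rec[1] != strand:
                raise ValueError(
                    f"gene {name!r}: transcripts disagree on chromosome/strand"
                )
            rec[2] = min(rec[2], start)
            rec[3] = max(rec[3], end)
        else:
            merged[name] = [chrom, strand, start, end]

    models: List[GeneModel] = []
    for name, (chrom, strand, start, end) in merged.items():
        if chrom not in genome.lengths:
            logger.warning("gene %s on unknown chromosome %s: skipped", name, chrom)
            continue
        models.append(
            make_gene_model(
                name, chrom, strand, start, end,
                chrom_length=genome.lengths[chrom],
                promoter_window=promoter_window,
                ta_index=ta_index,
            )
        )
    return models


def gene_regions_to_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write counting regions as BED6 for inspection (0-based half-open)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.region_start}\t{g.region_end}\t{g.gene_id}\t"
                f"{g.ta_count}\t{g.strand}\n"
            )
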