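"""Synthetic screens with known ground truth.

Generates every input the pipeline consumes — toy reference genomes, gene
annotations, planted driver screens, and per-sample FASTQ junction reads —
with the statistical structure the analysis assumes: insertions restricted
to TA sites, Bernoulli orientations, and a Beta positional law along each
driver gene (Beta(1.5, 8) concentrates insertions near the 5' end, the
promoter-cluster signature; Beta(1, 1) is uniform).

The read synthesizer uses the same junction convention as the trimmer: a
read is transposon tag, then genomic sequence beginning at the insertion's
TA (reverse-complemented for minus-orientation events), padded with
sequencing adapter when the genomic flank is truncated at a chromosome
end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import GeneModel, ReferenceGenome, TAIndex, build_ta_index, make_gene_model, reverse_complement
from .reads import CALL_COLUMNS, InsertionDataset

DEFAULT_TAG = "GTGTATGTAAACTTCC"
DEFAULT_ADAPTER = "AGATCGGAAGAGC"

# TA sites closer than this to a chromosome end are never planted: a junction
# read there cannot carry a mappable genomic flank.
EDGE_BUFFER = 100


@dataclass(frozen=True)
class DriverSpec:
    """A planted driver gene: event count, orientation bias, positional law."""

    gene_id: str
    n_insertions: int
    same_orientation_fraction: float = 0.9
    beta_params: Tuple[float, float] = (1.5, 8.0)

    def __post_init__(self) -> None:
        if self.n_insertions < 1:
            raise ValueError("n_insertions must be >= 1")
        if not (0.0 <= self.same_orientation_fraction <= 1.0):
            raise ValueError("same_orientation_fraction must lie in [0, 1]")
        if min(self.beta_params) <= 0:
            raise ValueError("Beta parameters must be positive")


@dataclass
class GroundTruth:
    """True insertion events plus the generator parameters that made them.

    ``truth`` columns: sample_id, arm, chrom, pos, orientation, source
    (driver gene_id or "background").
    """

    truth: pd.DataFrame
    params: Dict = field(default_factory=dict)

    @property
    def sample_sheet(self) -> Dict[str, str]:
        return dict(
            self.truth[["sample_id", "arm"]].drop_duplicates().itertuples(index=False)
        )

    def to_dataset(self) -> InsertionDataset:
        calls = self.truth[["sample_id", "chrom", "pos", "orientation"]].copy()
        calls["read_count"] = 1
        calls = calls[CALL_COLUMNS].sort_values(["chrom", "pos", "sample_id"])
        return InsertionDataset(
            calls=calls.reset_index(drop=True), samples=self.sample_sheet
        )

    def to_tsv(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reference generation


def generate_reference(
    n_chrom: int = 2,
    chrom_len: int = 200_000,
    n_genes: int = 40,
    gene_len_range: Tuple[int, int] = (4_000, 15_000),
    seed: int = 0,
    min_gap: int = 200,
    edge_margin: int = 1_000,
) -> Tuple[ReferenceGenome, pd.DataFrame]:
    """An i.i.d.-uniform ACGT genome with non-overlapping genes.

    Genes are split evenly across chromosomes, placed with random gaps and
    random strands; transcription units never overlap (promoter windows
    may). Deterministic per seed. Returns the genome and a gene table
    (gene_id, chrom, strand, tx_start, tx_end).
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    sequences = {
        f"chr{i + 1}": "".join(rng.choice(bases, size=chrom_len))
        for i in range(n_chrom)
    }
    genome = ReferenceGenome.from_dict(sequences)

    per_chrom = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0)
                 for i in range(n_chrom)]
    lo, hi = gene_len_range
    rows = []
    gene_no = 0
    for ci, k in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        capacity = chrom_len - 2 * edge_margin - (k - 1) * min_gap
        if k * lo > capacity:
            raise ValueError(
                f"{chrom}: cannot pack {k} genes of >= {lo} bp into {capacity} bp"
            )
        for _ in range(200):
            lengths = rng.integers(lo, hi + 1, size=k)
            if lengths.sum() <= capacity:
                break
        else:
            raise ValueError(f"{chrom}: infeasible gene packing after 200 attempts")
        slack = int(capacity - lengths.sum())
        gaps = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1)))
        pos = edge_margin
        for j in range(k):
            pos += int(gaps[j])
            start = pos
            end = start + int(lengths[j])
            strand = "+" if rng.random() < 0.5 else "-"
            gene_no += 1
            rows.append((f"gene{gene_no:03d}", chrom, strand, start, end))
            pos = end + min_gap
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tx_start", "tx_end"])
    return genome, genes


def annotate(
    genome: ReferenceGenome,
    gene_table: pd.DataFrame,
    promoter_window: int,
    ta_index: Optional[TAIndex] = None,
) -> List[GeneModel]:
    """Turn a generated gene table into GeneModels with counting regions."""
    ta_index = ta_index or build_ta_index(genome)
    return [
        make_gene_model(
            r.gene_id, r.chrom, r.strand, r.tx_start, r.tx_end,
            chrom_length=genome.lengths[r.chrom],
            promoter_window=promoter_window,
            ta_index=ta_index,
        )
        for r in gene_table.itertuples(index=False)
    ]


def gene_table_to_bed12(gene_table: pd.DataFrame, path: str | Path) -> None:
    """Single-exon BED12 records for the generated annotation."""
    with open(path, "w") as fh:
        for r in gene_table.itertuples(index=False):
            size = r.tx_end - r.tx_start
            fh.write(
                f"{r.chrom}\t{r.tx_start}\t{r.tx_end}\t{r.gene_id}\t0\t{r.strand}\t"
                f"{r.tx_start}\t{r.tx_end}\t0\t1\t{size},\t0,\n"
            )


# ---------------------------------------------------------------------------
# Planting screens


def _eligible_positions(ta_index: TAIndex, genome: ReferenceGenome) -> Dict[str, np.ndarray]:
    out = {}
    for chrom, pos in ta_index.positions.items():
        length = genome.lengths[chrom]
        out[chrom] = pos[(pos >= EDGE_BUFFER) & (pos + 2 <= length - EDGE_BUFFER)]
    return out


def _draw_background(
    rng: np.random.Generator,
    eligible: Dict[str, np.ndarray],
    n_events: int,
    sample_ids: Sequence[str],
    arm: str,
    used: set,
) -> List[tuple]:
    """Uniform background over genome TA sites, split across samples."""
    chroms = list(eligible)
    weights = np.array([eligible[c].size for c in chroms], dtype=float)
    weights /= weights.sum()
    share = rng.multinomial(n_events, np.full(len(sample_ids), 1.0 / len(sample_ids)))
    rows = []
    for sample_id, k in zip(sample_ids, share):
        for _ in range(int(k)):
            for _attempt in range(100):
                chrom = chroms[rng.choice(len(chroms), p=weights)]
                pos = int(rng.choice(eligible[chrom]))
                ori = "+" if rng.random() < 0.5 else "-"
                key = (sample_id, chrom, pos, ori)
                if key not in used:
                    used.add(key)
                    rows.append((sample_id, arm, chrom, pos, ori, "background"))
                    break
            else:
                raise RuntimeError("could not place a unique background event")
    return rows


def plant_screen(
    genome: ReferenceGenome,
    genes: Sequence[GeneModel],
    drivers: Sequence[DriverSpec] = (),
    n_background: int = 2_000,
    n_selected_samples: int = 6,
    n_control_samples: int = 2,
    control_background: Optional[int] = None,
    seed: int = 0,
    ta_index: Optional[TAIndex] = None,
) -> GroundTruth:
    """Plant a screen: background everywhere, driver events in named genes.

    Background events are uniform over genome TA sites (fair-coin
    orientation), split across the selected samples; the control arm
    receives background only, by default at the same per-sample density.
    Driver events sample a position u from the driver's Beta law along the
    gene's counting region (5' to 3'), snap to the nearest in-region TA
    site, and take the gene's orientation with probability
    ``same_orientation_fraction``. Events are unique per (sample, chrom,
    position, orientation) by construction.
    """
    rng = np.random.default_rng(seed)
    ta_index = ta_index or build_ta_index(genome)
    eligible = _eligible_positions(ta_index, genome)
    gene_by_id = {g.gene_id: g for g in genes}
    if control_background is None:
        per_sample = n_background / max(n_selected_samples, 1)
        control_background = int(round(per_sample * n_control_samples))

    selected_ids = [f"S{i + 1}" for i in range(n_selected_samples)]
    control_ids = [f"C{i + 1}" for i in range(n_control_samples)]
    used: set = set()
    rows: List[tuple] = []

    rows += _draw_background(rng, eligible, n_background, selected_ids, "selected", used)
    if n_control_samples > 0 and control_background > 0:
        rows += _draw_background(rng, eligible, control_background, control_ids, "control", used)

    for drv in drivers:
        gene = gene_by_id.get(drv.gene_id)
        if gene is None:
            raise KeyError(f"driver gene {drv.gene_id!r} not in annotation")
        region_ta = eligible[gene.chrom]
        region_ta = region_ta[
            (region_ta >= gene.region_start) & (region_ta + 2 <= gene.region_end)
        ]
        if region_ta.size == 0:
            raise ValueError(f"gene {drv.gene_id}: no TA sites in counting region")
        a, b = drv.beta_params
        span = max(gene.region_length - 2, 1)
        for _ in range(drv.n_insertions):
            sample_id = selected_ids[rng.integers(len(selected_ids))]
            for _attempt in range(200):
                u = rng.beta(a, b)
                if gene.strand == "-":
                    u = 1.0 - u  # u is measured 5'->3' along the gene
                target = gene.region_start + u * span
                pos = int(region_ta[np.argmin(np.abs(region_ta - target))])
                same = rng.random() < drv.same_orientation_fraction
                ori = gene.strand if same else ("-" if gene.strand == "+" else "+")
                key = (sample_id, gene.chrom, pos, ori)
                if key not in used:
                    used.add(key)
                    rows.append((sample_id, "selected", gene.chrom, pos, ori, drv.gene_id))
                    break
                sample_id = selected_ids[rng.integers(len(selected_ids))]
            else:
                raise RuntimeError(
                    f"gene {drv.gene_id}: could not place {drv.n_insertions} unique events"
                )

    truth = pd.DataFrame(
        rows, columns=["sample_id", "arm", "chrom", "pos", "orientation", "source"]
    )
    params = dict(
        n_background=n_background,
        n_selected_samples=n_selected_samples,
        n_control_samples=n_control_samples,
        control_background=control_background,
        drivers=[
            (d.gene_id, d.n_insertions, d.same_orientation_fraction, d.beta_params)
            for d in drivers
        ],
        seed=seed,
    )
    return GroundTruth(truth=truth, params=params)


def choose_drivers(
    genes: Sequence[GeneModel],
    n_drivers: int = 10,
    n_insertions_range: Tuple[int, int] = (30, 60),
    same_orientation_fraction: float = 0.9,
    beta_params: Tuple[float, float] = (1.5, 8.0),
    seed: int = 0,
) -> List[DriverSpec]:
    """Pick driver genes at random and give each an event count in range."""
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(genes), size=n_drivers, replace=False)
    lo, hi = n_insertions_range
    return [
        DriverSpec(
            gene_id=genes[int(i)].gene_id,
            n_insertions=int(rng.integers(lo, hi + 1)),
            same_orientation_fraction=same_orientation_fraction,
            beta_params=beta_params,
        )
        for i in picks
    ]


# ---------------------------------------------------------------------------
# Read synthesis


def synthesize_reads(
    truth: GroundTruth,
    genome: ReferenceGenome,
    tag: str = DEFAULT_TAG,
    adapter: str = DEFAULT_ADAPTER,
    read_len: int = 50,
    reads_per_insertion: int = 3,
    error_rate: float = 0.0,
    seed: int = 0,
) -> Dict[str, List[Tuple[str, str, str]]]:
    """LM-PCR junction reads for every true insertion event.

    Each read is ``tag`` + genomic flank starting at the event's TA (read
    in the direction implied by the recorded orientation), padded with
    adapter (then A) to ``read_len`` if the flank is truncated at a
    chromosome end. Per-base substitution errors at ``error_rate``.
    Returns {sample_id: [(read_id, sequence, quality), ...]}.
    """
    if read_len <= len(tag):
        raise ValueError("read_len must exceed the tag length")
    rng = np.random.default_rng(seed)
    flank = read_len - len(tag)
    bases = np.array(list("ACGT"))
    out: Dict[str, List[Tuple[str, str, str]]] = {}
    qual = "I" * read_len
    for idx, ev in enumerate(truth.truth.itertuples(index=False)):
        seq = genome.sequences[ev.chrom]
        if ev.orientation == "+":
            genomic = seq[ev.pos : ev.pos + flank]
        else:
            genomic = reverse_complement(seq[max(0, ev.pos + 2 - flank) : ev.pos + 2])
        read = tag + genomic
        if len(read) < read_len:
            pad = (adapter + "A" * read_len)[: read_len - len(read)]
            read += pad
        for r in range(reads_per_insertion):
            arr = np.array(list(read))
            if error_rate > 0:
                hit = rng.random(read_len) < error_rate
                if hit.any():
                    subs = bases[rng.integers(0, 4, size=int(hit.sum()))]
                    # force a real substitution, never the original base
                    orig = arr[hit]
                    clash = subs == orig
                    while clash.any():
                        subs[clash] = bases[rng.integers(0, 4, size=int(clash.sum()))]
                        clash = subs == orig
                    arr[hit] = subs
            name = f"{ev.sample_id}:{ev.chrom}:{ev.pos}:{ev.orientation}:{idx}:{r}"
            out.setdefault(ev.sample_id, []).append(("".join(arr), name, qual))
    return {
        s: [(name, seq, q) for (seq, name, q) in reads] for s, reads in out.items()
    }


def write_fastq(
    reads_by_sample: Mapping[str, List[Tuple[str, str, str]]],
    outdir: str | Path,
    sample_sheet: Optional[Mapping[str, str]] = None,
) -> Path:
    """Write one FASTQ per sample plus a sample sheet TSV; returns the sheet path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sheet = outdir / "samples.tsv"
    with open(sheet, "w") as sh:
        sh.write("sample_id\tarm\tfastq\n")
        for sample_id, reads in reads_by_sample.items():
            fq = outdir / f"{sample_id}.fastq"
            with open(fq, "w") as fh:
                for name, seq, qual in reads:
                    fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
            arm = sample_sheet.get(sample_id, "selected") if sample_sheet else "selected"
            sh.write(f"{sample_id}\t{arm}\t{fq.name}\n")
    return sheet


# ---------------------------------------------------------------------------
# Presets


def default_reference(seed: int = 0) -> Tuple[ReferenceGenome, pd.DataFrame]:
    """The default toy genome: 2 chromosomes x 200 kb, 40 genes of 4-15 kb."""
    return generate_reference(seed=seed)


def recovery_reference(seed: int = 0) -> Tuple[ReferenceGenome, pd.DataFrame]:
    """A larger genome (4 x 500 kb, ~125k TA sites) for parameter-recovery
    studies, sized so planted drivers of 30-60 events stand out against a
    2,000-event background at FDR 1e-5."""
    return generate_reference(n_chrom=4, chrom_len=500_000, seed=seed)
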