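"""Matched random-TA null simulation and suite-level calibration bounds.

Each null dataset replaces every observed insertion event with a randomly
chosen TA site on the same chromosome, preserving per-chromosome event
counts — the natural null of a transposase that requires only a TA
dinucleotide. A suite of such datasets (20 by default) is analyzed by the
full gCIS2 pipeline to verify that no candidate genes arise by chance, and
to derive the mean 1st/99th-percentile bounds of per-gene skewness and
kurtosis against which experimental shape values are judged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import gcis
from .config import ScreenConfig
from .genome import GeneModel, TAIndex
from .reads import CALL_COLUMNS, InsertionDataset


@dataclass
class NullSuiteResult:
    """Summary of a suite of matched random-TA null datasets.

    ``skew_bounds`` / ``kurt_bounds`` are (low, high): the mean over sets of
    each set's 1st and 99th percentiles of per-gene g1 / g2, computed over
    genes with at least ``min_insertions_for_prediction`` events.
    """

    n_sets: int
    per_set_candidates: List[int]
    skew_bounds: Tuple[float, float]
    kurt_bounds: Tuple[float, float]
    per_set_table: pd.DataFrame = field(repr=False, default=None)


def observed_per_chrom_counts(dataset: InsertionDataset, arm: Optional[str] = None) -> Dict[str, int]:
    """Per-chromosome unique-event counts of an observed dataset."""
    calls = dataset.arm(arm) if arm else dataset.calls
    return {str(c): int(n) for c, n in calls.groupby("chrom").size().items()}


def simulate_null_dataset(
    ta_index: TAIndex,
    per_chrom_counts: Mapping[str, int],
    seed: int | np.random.Generator = 0,
    sample_id: str = "null_sim",
) -> InsertionDataset:
    """One matched random-TA dataset.

    For each chromosome, exactly ``per_chrom_counts[c]`` TA sites are drawn
    uniformly without replacement (two events at one site would collapse
    under the uniqueness key anyway); orientations are fair coin flips.
    Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for chrom, want in per_chrom_counts.items():
        avail = ta_index.positions.get(chrom)
        if avail is None:
            raise KeyError(f"chromosome {chrom!r} not in TA index")
        if want > avail.size:
            raise ValueError(
                f"{chrom}: requested {want} events but only {avail.size} TA sites"
            )
        pos = rng.choice(avail, size=want, replace=False)
        ori = rng.choice(np.array(["+", "-"]), size=want)
        for p, o in zip(pos, ori):
            rows.append((sample_id, chrom, int(p), str(o), 1))
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    calls = calls.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return InsertionDataset(calls=calls, samples={sample_id: "selected"})


def run_null_suite(
    per_chrom_counts: Mapping[str, int] | InsertionDataset,
    ta_index: TAIndex,
    genes: Sequence[GeneModel],
    config: ScreenConfig,
    n_sets: int = 20,
    base_seed: int = 0,
) -> NullSuiteResult:
    """Simulate and analyze ``n_sets`` matched null datasets.

    Accepts either explicit per-chromosome counts or an observed dataset to
    match. Each set is analyzed by the full candidate caller (no control
    filter — a simulated set has no control arm); per-gene skewness and
    kurtosis enter the percentile bounds only for genes with at least
    ``config.min_insertions_for_prediction`` events. Percentiles use linear
    interpolation between order statistics.
    """
    if isinstance(per_chrom_counts, InsertionDataset):
        per_chrom_counts = observed_per_chrom_counts(per_chrom_counts)

    per_set_candidates: List[int] = []
    set_rows = []
    for i in range(n_sets):
        ds = simulate_null_dataset(ta_index, per_chrom_counts, seed=base_seed + i)
        res = gcis.call_candidates(ds, genes, ta_index, config, no_control=True)
        n_cand = int(res["is_candidate"].sum())
        per_set_candidates.append(n_cand)
        shaped = res[res["observed"] >= config.min_insertions_for_prediction]
        g1 = shaped["skewness"].dropna().to_numpy()
        g2 = shaped["kurtosis"].dropna().to_numpy()
        p1_g1, p99_g1 = (np.percentile(g1, [1, 99]) if g1.size else (np.nan, np.nan))
        p1_g2, p99_g2 = (np.percentile(g2, [1, 99]) if g2.size else (np.nan, np.nan))
        set_rows.append((i, base_seed + i, n_cand, p1_g1, p99_g1, p1_g2, p99_g2))

    table = pd.DataFrame(
        set_rows,
        columns=["set", "seed", "candidates", "skew_p1", "skew_p99", "kurt_p1", "kurt_p99"],
    )
    skew_bounds = (float(table["skew_p1"].mean()), float(table["skew_p99"].mean()))
    kurt_bounds = (float(table["kurt_p1"].mean()), float(table["kurt_p99"].mean()))
    return NullSuiteResult(
        n_sets=n_sets,
        per_set_candidates=per_set_candidates,
        skew_bounds=skew_bounds,
        kurt_bounds=kurt_bounds,
        per_set_table=table,
    )
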