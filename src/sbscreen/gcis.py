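"""The gCIS2 test: gene-centric chi-squared enrichment of insertion events.

Because the Sleeping Beauty transposase shows essentially no integration
bias beyond requiring a TA dinucleotide, the expected number of insertion
events in a gene is proportional to the gene's TA content:

    E_g = N * TA_g / TA_total

where N is the total number of unique insertion events in the data set,
TA_g the TA sites in the gene's counting region (transcription unit plus
upstream promoter window), and TA_total the genome-wide TA count. Each
gene is scored by a two-cell Pearson goodness-of-fit statistic

    chi2 = (O - E)^2 / E + ((N - O) - (N - E))^2 / (N - E)

with an upper-tail p from the chi-squared distribution with 1 df, followed
by Benjamini-Hochberg FDR control across all genes with at least one
event. Candidate genes must be enriched (O > E), pass the FDR threshold,
be unique to the selected arm, and carry a defined mechanism prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import mechanism as mech
from .config import ScreenConfig
from .genome import GeneModel, TAIndex
from .reads import InsertionDataset

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "gene_id", "chrom", "region_start", "region_end", "strand", "ta_count",
    "observed", "expected", "chi2_stat", "p_value", "fdr", "direction",
    "control_observed", "unique_to_selected", "n_same", "same_orientation_fraction",
    "orientation_p", "mechanism", "antisense_bias", "skewness", "kurtosis",
    "is_candidate",
]


def expected_insertions(ta_gene: int, ta_total: int, n_total: int) -> float:
    """Expected insertion events in a gene under the uniform-TA null."""
    if ta_total <= 0:
        raise ValueError("ta_total must be positive (no TA sample space)")
    if ta_gene > ta_total:
        raise ValueError("ta_gene cannot exceed ta_total")
    if n_total < 0:
        raise ValueError("n_total must be >= 0")
    return n_total * ta_gene / ta_total


def gcis_chi2(
    observed: float, expected: float, n_total: int, yates: bool = False
) -> Tuple[float, float]:
    """Two-cell Pearson goodness-of-fit statistic and its 1-df p-value.

    The statistic is symmetric in enrichment vs depletion: it measures
    |O - E| on the in-gene / out-of-gene partition of the N events. With
    ``yates`` the deviation is reduced by 0.5 (floored at 0) in both cells.
    """
    if not (0 < expected < n_total):
        raise ValueError(f"expected must lie in (0, n_total); got E={expected}, N={n_total}")
    if observed > n_total:
        raise ValueError("observed cannot exceed n_total")
    d = abs(observed - expected)
    if yates:
        d = max(d - 0.5, 0.0)
    stat = d * d / expected + d * d / (n_total - expected)
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p


def mc_null_pvalue(
    observed: float,
    expected: float,
    n_total: int,
    reps: int = 100_000,
    rng: Optional[np.random.Generator] = None,
    mid_p: bool = True,
    yates: bool = False,
) -> float:
    """Monte-Carlo null p-value for the gCIS2 statistic.

    Re-places all N events uniformly over TA sites, so the in-gene count is
    Binomial(N, E/N); the p-value is the null probability that the two-cell
    statistic reaches the observed one. The null is discrete while the
    chi-squared reference is continuous, so by default the mid-p estimator
    is used (ties at the observed statistic count half), which centers the
    discrete null on the continuous reference. This is the independent
    oracle for :func:`gcis_chi2`, not a production code path.
    """
    rng = rng or np.random.default_rng()
    stat_obs, _ = gcis_chi2(observed, expected, n_total, yates=yates)
    draws = rng.binomial(n_total, expected / n_total, size=reps).astype(float)
    d = np.abs(draws - expected)
    if yates:
        d = np.maximum(d - 0.5, 0.0)
    stat_null = d * d / expected + d * d / (n_total - expected)
    if mid_p:
        greater = np.count_nonzero(stat_null > stat_obs + 1e-12)
        ties = np.count_nonzero(np.abs(stat_null - stat_obs) <= 1e-12)
        return (greater + 0.5 * ties) / reps
    return (1 + np.count_nonzero(stat_null >= stat_obs - 1e-12)) / (reps + 1)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Per-gene counting and the candidate caller


def _positions_by_chrom(calls: pd.DataFrame) -> Dict[str, np.ndarray]:
    out: Dict[str, np.ndarray] = {}
    for chrom, sub in calls.groupby("chrom", sort=False):
        out[str(chrom)] = np.sort(sub["pos"].to_numpy())
    return out


def count_events_in_gene(calls: pd.DataFrame, gene: GeneModel) -> pd.DataFrame:
    """Calls whose TA site lies fully inside the gene's counting region."""
    sub = calls[calls["chrom"] == gene.chrom]
    mask = (sub["pos"] >= gene.region_start) & (sub["pos"] + 2 <= gene.region_end)
    return sub[mask]


def _test_arm(
    arm_calls: pd.DataFrame,
    genes: Sequence[GeneModel],
    ta_total: int,
    config: ScreenConfig,
) -> pd.DataFrame:
    """Run the per-gene chi-squared test on one arm; BH across tested genes."""
    n_total = len(arm_calls)
    rows = []
    for gene in genes:
        if gene.ta_count <= 0:
            continue
        hits = count_events_in_gene(arm_calls, gene)
        observed = len(hits)
        if observed == 0:
            continue
        expected = expected_insertions(gene.ta_count, ta_total, n_total)
        if not (0 < expected < n_total):
            logger.warning(
                "gene %s skipped: expected %.3g outside (0, N=%d)",
                gene.gene_id, expected, n_total,
            )
            continue
        stat, p = gcis_chi2(observed, expected, n_total, yates=config.yates_correction)
        rows.append((gene, hits, observed, expected, stat, p))
    frame = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g, *_ in rows],
            "observed": [r[2] for r in rows],
            "expected": [r[3] for r in rows],
            "chi2_stat": [r[4] for r in rows],
            "p_value": [r[5] for r in rows],
        }
    )
    frame["fdr"] = bh_fdr(frame["p_value"].to_numpy()) if len(frame) else []
    frame.attrs["per_gene_hits"] = {r[0].gene_id: r[1] for r in rows}
    frame.attrs["genes"] = {r[0].gene_id: r[0] for r in rows}
    return frame


def call_candidates(
    dataset: InsertionDataset,
    genes: Sequence[GeneModel],
    ta_index: TAIndex,
    config: ScreenConfig,
    no_control: bool = False,
) -> pd.DataFrame:
    """The full gCIS2 analysis on a merged insertion dataset.

    For every gene with at least one selected-arm event: expected count,
    chi-squared, p, BH FDR; control-arm occupancy and the
    unique-to-selected filter; orientation-bias mechanism prediction and
    insertion-distribution shape (skewness / excess kurtosis). The returned
    frame is sorted by (fdr, -observed) and flags candidates: FDR <=
    threshold, enriched, unique to the selected arm, mechanism defined.

    With ``no_control`` the control filter is skipped (all genes count as
    unique to selected); otherwise a dataset without a control arm raises.
    """
    if "arm" not in dataset.calls.columns:
        if not no_control:
            raise ValueError(
                "dataset has no arm labels; merge with a sample sheet or pass no_control=True"
            )
        selected = dataset.calls
        control: Optional[pd.DataFrame] = None
    else:
        selected = dataset.arm("selected")
        has_control = dataset.has_arm("control")
        if not has_control and not no_control:
            raise ValueError(
                "no control arm in dataset; re-run with no_control=True (--no-control) "
                "to disable the unique-to-selected filter"
            )
        control = dataset.arm("control") if has_control else None
    if len(selected) == 0:
        raise ValueError("dataset has no selected-arm insertion events")

    ta_total = ta_index.ta_total
    sel = _test_arm(selected, genes, ta_total, config)
    hits_by_gene = sel.attrs["per_gene_hits"]
    gene_by_id = sel.attrs["genes"]

    if control is not None and len(control) > 0:
        control_counts = {
            g.gene_id: len(count_events_in_gene(control, g)) for g in genes
        }
        if config.control_mode == "not_significant":
            ctrl = _test_arm(control, genes, ta_total, config)
            ctrl_sig = set(
                ctrl.loc[
                    (ctrl["fdr"] <= config.fdr_threshold)
                    & (ctrl["observed"] > ctrl["expected"]),
                    "gene_id",
                ]
            )
            unique_fn = lambda gid: gid not in ctrl_sig
        else:  # zero_insertions
            unique_fn = lambda gid: control_counts.get(gid, 0) == 0
    else:
        control_counts = {}
        unique_fn = lambda gid: True

    records = []
    for row in sel.itertuples(index=False):
        gene = gene_by_id[row.gene_id]
        hits = hits_by_gene[row.gene_id]
        osum = mech.orientation_stats(
            hits["orientation"].tolist(), gene.strand,
            orientation_flip=config.orientation_flip,
        )
        label, antisense = mech.predict_mechanism(
            osum,
            min_insertions=config.min_insertions_for_prediction,
            alpha=config.orientation_alpha,
        )
        u = mech.normalized_positions(
            hits["pos"].to_numpy(), gene, gene_body_only=config.gene_body_only
        )
        g1, g2 = mech.skewness_kurtosis(
            u, bias_corrected=config.bias_corrected_moments
        )
        direction = "enriched" if row.observed > row.expected else "depleted"
        unique = bool(unique_fn(row.gene_id))
        is_candidate = (
            row.fdr <= config.fdr_threshold
            and direction == "enriched"
            and unique
            and label in ("over-expression", "disruption")
        )
        records.append(
            {
                "gene_id": row.gene_id,
                "chrom": gene.chrom,
                "region_start": gene.region_start,
                "region_end": gene.region_end,
                "strand": gene.strand,
                "ta_count": gene.ta_count,
                "observed": row.observed,
                "expected": row.expected,
                "chi2_stat": row.chi2_stat,
                "p_value": row.p_value,
                "fdr": row.fdr,
                "direction": direction,
                "control_observed": control_counts.get(row.gene_id, 0),
                "unique_to_selected": unique,
                "n_same": osum.n_same,
                "same_orientation_fraction": osum.f,
                "orientation_p": osum.orientation_p,
                "mechanism": label,
                "antisense_bias": antisense,
                "skewness": g1,
                "kurtosis": g2,
                "is_candidate": is_candidate,
            }
        )
    out = pd.DataFrame(records, columns=RESULT_COLUMNS)
    if len(out):
        out = out.sort_values(
            ["fdr", "observed"], ascending=[True, False]
        ).reset_index(drop=True)
    return out
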