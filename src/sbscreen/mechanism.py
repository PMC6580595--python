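"""Functional prediction from orientation bias and insertion-distribution shape.

Mutagenic Sleeping Beauty transposons carry an internal promoter: an
insertion in the same transcriptional orientation as a gene can drive its
over-expression, while orientation-indifferent insertions disrupt the
gene. For each gene with enough independent insertions the orientation
bias is tested with an exact two-sided binomial test against 0.5; a
significant same-sense majority predicts over-expression, anything else
predicts disruption.

Insertion clustering along the gene is summarized by the skewness and
excess kurtosis of normalized insertion positions u in [0, 1], measured
from the 5' end of the counting region in the gene's transcriptional
direction: positive skewness means 5' (promoter-side) clustering, high
kurtosis means a tight cluster — the signature of truncation-style
mechanisms. These shape values are reported for user interpretation only;
they never enter the candidate decision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

from .genome import GeneModel


@dataclass(frozen=True)
class OrientationSummary:
    n: int
    n_same: int
    f: float
    orientation_p: float


def normalized_positions(
    ta_positions: Sequence[int] | np.ndarray,
    gene: GeneModel,
    gene_body_only: bool = False,
) -> np.ndarray:
    """Map TA coordinates to u in [0, 1] along the gene's reading direction.

    u = (ta - region_start) / (region_length - 2), mirrored for minus-strand
    genes so u ~ 0 is always the promoter/5' end. The -2 makes the last
    insertable TA (whose dinucleotide ends at region_end) map to u = 1.
    """
    pos = np.asarray(ta_positions, dtype=float)
    start, end = (
        (gene.tx_start, gene.tx_end) if gene_body_only
        else (gene.region_start, gene.region_end)
    )
    if np.any((pos < start) | (pos + 2 > end)):
        raise ValueError(
            f"{gene.gene_id}: insertion outside region [{start}, {end}); pre-filter calls"
        )
    span = end - start - 2
    if span <= 0:
        return np.zeros_like(pos)
    u = (pos - start) / span
    u = np.clip(u, 0.0, 1.0)
    if gene.strand == "-":
        u = 1.0 - u
    return u


def orientation_stats(
    orientations: Sequence[str],
    gene_strand: str,
    orientation_flip: bool = False,
) -> OrientationSummary:
    """Count same-sense insertions and test against a fair coin.

    ``orientation_flip`` globally inverts the recorded transposon
    orientation before comparison (vector-geometry convention).
    """
    n = len(orientations)
    if n < 1:
        raise ValueError("orientation_stats requires at least one insertion")
    if orientation_flip:
        orientations = ["-" if o == "+" else "+" for o in orientations]
    n_same = sum(1 for o in orientations if o == gene_strand)
    p = stats.binomtest(n_same, n, p=0.5, alternative="two-sided").pvalue
    return OrientationSummary(n=n, n_same=n_same, f=n_same / n, orientation_p=float(p))


def predict_mechanism(
    summary: OrientationSummary,
    min_insertions: int = 5,
    alpha: float = 0.05,
) -> Tuple[str, bool]:
    """Predict over-expression vs disruption from orientation bias.

    Genes with fewer than ``min_insertions`` events get "NA". A significant
    same-sense majority (binomial p < alpha, f > 0.5) predicts
    over-expression; everything else predicts disruption. A significant
    ANTI-sense bias is still reported as disruption but flagged (second
    return value) since it is an unusual pattern worth inspection.
    """
    if summary.n < min_insertions:
        return "NA", False
    if summary.orientation_p < alpha and summary.f > 0.5:
        return "over-expression", False
    antisense = summary.orientation_p < alpha and summary.f < 0.5
    return "disruption", antisense


def skewness_kurtosis(
    positions_u: Sequence[float] | np.ndarray,
    bias_corrected: bool = False,
) -> Tuple[float, float]:
    """Moment-based skewness g1 and excess kurtosis g2 of positions.

    Plain 1/n central moments by default (g1 = m3 / m2^1.5,
    g2 = m4 / m2^2 - 3); ``bias_corrected`` switches to the small-sample
    adjusted estimators. NaN when the sample is too small or has zero
    variance: n >= 3 for the plain estimators; the adjusted kurtosis
    additionally needs n >= 4 (its correction factor is undefined below).
    """
    u = np.asarray(positions_u, dtype=float)
    n = u.size
    g1 = g2 = math.nan
    if n >= 3 and np.ptp(u) > 0:
        g1 = float(stats.skew(u, bias=not bias_corrected))
        if not bias_corrected or n >= 4:
            g2 = float(stats.kurtosis(u, fisher=True, bias=not bias_corrected))
    return g1, g2
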