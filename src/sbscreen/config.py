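"""Screen-wide configuration.

All thresholds and conventions used by the pipeline live in one dataclass so
that a run is fully described by (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

CONTROL_MODES = ("not_significant", "zero_insertions")


@dataclass
class ScreenConfig:
    """Thresholds and conventions for a Sleeping Beauty screen analysis.

    Parameters
    ----------
    fdr_threshold
        Benjamini-Hochberg q-value cutoff for calling a gene a candidate.
        Default 1e-5, the stringency used for pooled-population screens.
    min_insertions_for_prediction
        Minimum number of independent insertion events in a gene before a
        functional mechanism (over-expression vs disruption) is predicted;
        below this the prediction is NA. Default 5.
    promoter_window
        Strand-aware upstream extension of each transcription unit, in bp,
        forming the gene's counting region. Default 40,000 (the convention
        for mammalian genomes; scale down for toy genomes).
    orientation_alpha
        Two-sided binomial significance level for transposon orientation
        bias. Default 0.05.
    control_mode
        How "unique to the selected population" is decided:
        ``not_significant`` — the gene is not itself significant when the
        same test is run on the control arm; ``zero_insertions`` — the gene
        has no control-arm insertions at all.
    yates_correction
        Apply a continuity correction to the two-cell chi-squared statistic.
        Default off.
    min_reads
        Minimum supporting reads per unique insertion call. Default 1
        (read-depth filtering is screen-specific).
    min_mapq
        Minimum mapping quality when ingesting externally aligned SAM/BAM.
    require_ta
        Reject calls whose genomic position does not read "TA".
    orientation_flip
        Globally invert recorded transposon orientation, to accommodate
        which terminal repeat was sequenced relative to the internal
        promoter of the particular transposon vector.
    merge_opposite_orientations
        Merge calls at one TA that differ only in orientation (both junction
        ends of one insertion can be sequenced). Default off: orientation is
        part of the uniqueness key.
    exclude_softmasked
        Treat soft-masked (lowercase) reference bases as unusable for TA
        sites instead of uppercasing them.
    bias_corrected_moments
        Use small-sample adjusted skewness/kurtosis estimators instead of
        plain 1/n central moments.
    gene_body_only
        Compute insertion-distribution shape over the transcription unit
        only, excluding the promoter window.
    seed
        Base seed for all stochastic steps (null simulation, synthesis).
    """

    fdr_threshold: float = 1e-5
    min_insertions_for_prediction: int = 5
    promoter_window: int = 40_000
    orientation_alpha: float = 0.05
    control_mode: str = "not_significant"
    yates_correction: bool = False
    min_reads: int = 1
    min_mapq: int = 10
    require_ta: bool = True
    orientation_flip: bool = False
    merge_opposite_orientations: bool = False
    exclude_softmasked: bool = False
    bias_corrected_moments: bool = False
    gene_body_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_threshold <= 1.0):
            raise ValueError(f"fdr_threshold out of (0, 1]: {self.fdr_threshold}")
        if not (0.0 < self.orientation_alpha <= 1.0):
            raise ValueError(f"orientation_alpha out of (0, 1]: {self.orientation_alpha}")
        if self.promoter_window < 0:
            raise ValueError("promoter_window must be >= 0")
        if self.min_insertions_for_prediction < 1:
            raise ValueError("min_insertions_for_prediction must be >= 1")
        if self.control_mode not in CONTROL_MODES:
            raise ValueError(
                f"control_mode must be one of {CONTROL_MODES}, got {self.control_mode!r}"
            )

    @classmethod
    def from_yaml(cls, path: str) -> "ScreenConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def toy_config(**overrides) -> ScreenConfig:
    """Config preset scaled to the bundled synthetic genomes.

    The 40 kb promoter convention belongs to mammalian-scale genomes; on a
    few-hundred-kb toy chromosome it would make every counting region cover
    a large fraction of the genome. The toy preset uses a 2 kb window,
    keeping the region-to-genome ratio comparable to a human gene.
    """
    defaults = dict(promoter_window=2_000)
    defaults.update(overrides)
    return ScreenConfig(**defaults)
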