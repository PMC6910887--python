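"""Configuration dataclasses for every stage of the pipeline.

All thresholds live here so that a run can be reproduced from a single
plain-text (YAML) config file; ``PipelineConfig.to_dict`` is embedded in
every report so the resolved configuration is always logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

Interval = tuple[float, float]


@dataclass
class FilterConfig:
    """Candidate-SNP selection thresholds.

    min_panel_af
        Population alternate-allele frequency a site must *exceed* to be
        kept (sites at exactly the threshold are removed).
    min_total_depth
        Minimum ref+alt read count at a site.
    require_panel
        If True, sites must match the common-SNP panel on chrom, position
        and both alleles.
    het_min_minor_reads
        Minimum reads on *each* allele for a site to be called
        heterozygous observationally (the VCF genotype field is ignored).
    """

    min_panel_af: float = 0.05
    min_total_depth: int = 10
    require_panel: bool = True
    het_min_minor_reads: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_panel_af <= 0.5):
            raise ValueError(f"min_panel_af must be in [0, 0.5], got {self.min_panel_af}")
        if self.min_total_depth < 1:
            raise ValueError(f"min_total_depth must be >= 1, got {self.min_total_depth}")
        if self.het_min_minor_reads < 1:
            raise ValueError("het_min_minor_reads must be >= 1")


@dataclass
class IntervalConfig:
    """The three closed allele-fraction intervals used for interval counting.

    Defaults bracket the expected heterozygous allele fractions: 1/3 and
    2/3 for triploid genomes, 1/2 for diploid genomes, each widened to a
    band of +/- 0.05 to absorb binomial sampling noise at low coverage.
    """

    third: Interval = (0.28, 0.38)
    half: Interval = (0.45, 0.55)
    two_thirds: Interval = (0.62, 0.72)

    def __post_init__(self) -> None:
        ivs = [self.third, self.half, self.two_thirds]
        for lo, hi in ivs:
            if not (0.0 < lo <= hi < 1.0):
                raise ValueError(f"interval ({lo}, {hi}) must lie inside (0, 1)")
        ordered = sorted(ivs)
        for (_, hi), (lo2, _) in zip(ordered, ordered[1:]):
            if lo2 <= hi:
                raise ValueError("allele-fraction intervals must be pairwise disjoint")


@dataclass
class ClassifyConfig:
    """Decision thresholds for the ploidy verdict.

    The vertex (symmetry axis) of the fitted parabola must fall in
    ``[axis_lo, axis_hi]`` for a confident triploid call; the comparison
    is made after rounding to ``axis_round_dp`` decimals, and an extra
    ``axis_slack`` beyond the bounds still yields a triploid verdict but
    raises the ``axis_out_of_range`` flag (set ``strict_axis`` to demote
    such samples to ``triploid_low_confidence`` instead).
    """

    axis_lo: float = 0.45
    axis_hi: float = 0.55
    axis_round_dp: int = 2
    axis_slack: float = 0.01
    strict_axis: bool = False
    min_candidate_sites: int = 1000
    z_flag_threshold: float = 3.0
    ratio_cutoff: float = 2.0
    mosaic_band: Interval = (1.90, 2.10)

    def __post_init__(self) -> None:
        if self.axis_lo > self.axis_hi:
            raise ValueError("axis_lo must not exceed axis_hi")
        if self.axis_slack < 0:
            raise ValueError("axis_slack must be >= 0")


@dataclass
class UPDConfig:
    """Binning and run-calling thresholds for the UPD/LOH scan.

    het_min_minor_reads defaults to 2 here (stricter than candidate
    selection): a single discordant read at a ~10-15x site is far more
    likely a sequencing error than a second allele, and counting such
    sites as heterozygous pushes the apparent HSF of a true LOH region
    toward the 5% pink/green boundary.
    """

    bin_size: int = 1_000_000
    min_informative: int = 20
    pink_max_hsf: float = 0.05
    gap_overlap_frac: float = 0.5
    whole_chrom_frac: float = 0.90
    min_run: int = 5
    max_interruptions: int = 1
    het_min_minor_reads: int = 2

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be positive")
        if not (0.0 < self.whole_chrom_frac <= 1.0):
            raise ValueError("whole_chrom_frac must be in (0, 1]")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


@dataclass
class QCConfig:
    """X-chromosome contamination guard settings.

    x_tolerance is the relative excess of the X depth fraction over the
    sex-specific expectation that triggers the contamination flag.
    known_sex, when provided ("XX" or "XY"), overrides the heterozygosity
    based inference of apparent sex.
    """

    x_tolerance: float = 0.25
    sex_het_ratio_threshold: float = 0.5
    known_sex: Optional[str] = None

    def __post_init__(self) -> None:
        if self.x_tolerance < 0:
            raise ValueError("x_tolerance must be >= 0")
        if self.known_sex is not None and self.known_sex not in ("XX", "XY"):
            raise ValueError("known_sex must be 'XX', 'XY' or None")


@dataclass
class PipelineConfig:
    """Bundle of all stage configs; serialisable to/from a YAML file."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    intervals: IntervalConfig = field(default_factory=IntervalConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    upd: UPDConfig = field(default_factory=UPDConfig)
    qc: QCConfig = field(default_factory=QCConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(klass, key):
            sub = dict(d.get(key) or {})
            # YAML round-trips tuples as lists
            for k, v in sub.items():
                if isinstance(v, list):
                    sub[k] = tuple(v)
            return klass(**sub)

        return cls(
            filter=build(FilterConfig, "filter"),
            intervals=build(IntervalConfig, "intervals"),
            classify=build(ClassifyConfig, "classify"),
            upd=build(UPDConfig, "upd"),
            qc=build(QCConfig, "qc"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
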