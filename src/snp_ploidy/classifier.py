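"""Triploidy classification from the distribution of mutation ratios.

The mutation ratio (MR) of a heterozygous site is the fraction of reads
carrying the alternate allele — the B-allele fraction of array parlance.
A diploid heterozygote has one alternate allele in two, so its MR centres
on 1/2; a triploid heterozygote carries the alternate on one or two of
three homologues, so its MR centres on 1/3 or 2/3.

The classifier counts candidate heterozygous SNPs whose MR falls in three
closed intervals around 1/3, 1/2 and 2/3, normalises the three counts to
sum to one, and fits the unique parabola through the points
(1/3, y1), (1/2, y2), (2/3, y3).  With abscissae spaced h = 1/6 apart the
interpolating quadratic has the closed form

    a = 18 (y1 - 2 y2 + y3)
    b = 3 (y3 - y1) - a
    c = y2 - a/4 - b/2

and vertex (symmetry axis) at -b/(2a).  An upward-opening parabola
(a > 0, centre mass depleted) with axis near 1/2 is the triploid
signature; downward-opening (a < 0) is diploid.  Under the sum-to-one
normalisation, a > 0 is algebraically equivalent to the side-to-centre
count ratio (n_1/3 + n_2/3) / n_1/2 exceeding 2, so the parabola rule and
the ratio cutoff are the same classifier.

A Z-score of each sample's ratio against its batch's diploid reference
distribution is attached as auxiliary evidence; it never overrides the
parabola verdict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import ClassifyConfig, FilterConfig, IntervalConfig, PipelineConfig
from .filtering import filter_sites, select_heterozygous
from .sites import SNPPanel, SNPSite

VERDICTS = ("diploid", "triploid", "triploid_low_confidence", "inconclusive")


class DegenerateFitError(ValueError):
    """All three interval counts are zero; no parabola can be normalised."""


class UndefinedRatioError(ValueError):
    """The 1/2-interval count is zero; the ratio statistic is undefined."""


@dataclass(frozen=True)
class IntervalCounts:
    """Counts of candidate heterozygous SNPs per MR interval."""

    n_third: int
    n_half: int
    n_two_thirds: int
    n_candidates: int

    def __post_init__(self) -> None:
        if min(self.n_third, self.n_half, self.n_two_thirds) < 0:
            raise ValueError("interval counts must be non-negative")
        if self.n_third + self.n_half + self.n_two_thirds > self.n_candidates:
            raise ValueError("interval counts exceed candidate total")

    @property
    def n_in_intervals(self) -> int:
        return self.n_third + self.n_half + self.n_two_thirds


@dataclass(frozen=True)
class ParabolaFit:
    """Quadratic y = a x^2 + b x + c through the three normalised points."""

    a: float
    b: float
    c: float
    axis: Optional[float]  # -b/(2a); None when a == 0
    y1: float
    y2: float
    y3: float

    def __call__(self, x: float) -> float:
        return self.a * x * x + self.b * x + self.c


@dataclass(frozen=True)
class BatchStats:
    """Reference mean/SD of the ratio statistic within a sequencing batch."""

    mean: float
    sd: float
    n_reference: int


@dataclass
class PloidyCall:
    """Per-sample verdict with all supporting statistics."""

    sample_id: str
    verdict: str
    ratio: Optional[float] = None
    fit: Optional[ParabolaFit] = None
    z: Optional[float] = None
    counts: Optional[IntervalCounts] = None
    flags: set[str] = field(default_factory=set)
    batch_stats: Optional[BatchStats] = None

    @property
    def is_positive(self) -> bool:
        return self.verdict in ("triploid", "triploid_low_confidence")


# ---------------------------------------------------------------------------
# elementary statistics


def mutation_ratio(site: SNPSite) -> float:
    """Alt-supporting read fraction at one site (requires nonzero depth)."""
    total = site.ref_depth + site.alt_depth
    if total == 0:
        raise ValueError(f"{site.chrom}:{site.pos}: MR undefined at zero depth")
    return site.alt_depth / total


def mutation_ratios(sites: pd.DataFrame) -> np.ndarray:
    """Vectorised MR over a site table; raises if any site has zero depth."""
    ref = sites["ref_depth"].to_numpy(float)
    alt = sites["alt_depth"].to_numpy(float)
    total = ref + alt
    if np.any(total == 0):
        raise ValueError("MR undefined at zero total depth; depth-filter first")
    return alt / total


def count_intervals(
    mrs: Iterable[float], cfg: IntervalConfig | None = None
) -> IntervalCounts:
    """Count MRs in the closed 1/3, 1/2 and 2/3 intervals.

    MRs outside all three intervals contribute only to ``n_candidates``.
    """
    cfg = cfg or IntervalConfig()
    arr = np.asarray(list(mrs) if not isinstance(mrs, np.ndarray) else mrs, dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("mutation ratios must lie in [0, 1]")

    def in_iv(iv):
        return int(((arr >= iv[0]) & (arr <= iv[1])).sum())

    return IntervalCounts(
        n_third=in_iv(cfg.third),
        n_half=in_iv(cfg.half),
        n_two_thirds=in_iv(cfg.two_thirds),
        n_candidates=int(arr.size),
    )


def fit_parabola(counts: IntervalCounts) -> ParabolaFit:
    """Exact quadratic interpolation of the normalised interval counts.

    Ordinates are the counts normalised to sum to one; the parabola is
    the unique quadratic through (1/3, y1), (1/2, y2), (2/3, y3),
    computed in closed form (no iterative fitting).
    """
    total = counts.n_in_intervals
    if total == 0:
        raise DegenerateFitError("all three interval counts are zero")
    y1 = counts.n_third / total
    y2 = counts.n_half / total
    y3 = counts.n_two_thirds / total
    a = 18.0 * (y1 - 2.0 * y2 + y3)
    b = 3.0 * (y3 - y1) - a
    c = y2 - a / 4.0 - b / 2.0
    axis = None if a == 0.0 else -b / (2.0 * a)
    return ParabolaFit(a=a, b=b, c=c, axis=axis, y1=y1, y2=y2, y3=y3)


def ratio_statistic(counts: IntervalCounts) -> float:
    """Side-to-centre count ratio (n_1/3 + n_2/3) / n_1/2.

    Exceeds 2 exactly when the fitted parabola opens upward; this is the
    clustering cutoff separating triploid from diploid samples.
    """
    if counts.n_half == 0:
        raise UndefinedRatioError("no sites in the 1/2 interval")
    return (counts.n_third + counts.n_two_thirds) / counts.n_half


def batch_z(
    ratios: Sequence[float], robust: bool = True, cutoff: float = 2.0
) -> tuple[np.ndarray, BatchStats]:
    """Z-score each sample's ratio statistic against its batch.

    With ``robust=True`` the reference mean/SD use only samples whose
    ratio is at or below ``cutoff`` (presumed diploids), so triploids in
    the batch cannot inflate the reference and mask themselves.  SD is
    the sample standard deviation (ddof=1).  When the reference SD is
    zero all Z-scores are NaN (callers flag this).
    """
    arr = np.asarray(ratios, dtype=float)
    if arr.size < 3:
        raise ValueError(f"batch Z-test needs >= 3 samples, got {arr.size}")
    ref = arr[arr <= cutoff] if robust else arr
    if ref.size < 2:
        raise ValueError(
            f"batch Z-test needs >= 2 reference samples, got {ref.size}"
        )
    mean = float(ref.mean())
    sd = float(ref.std(ddof=1))
    stats = BatchStats(mean=mean, sd=sd, n_reference=int(ref.size))
    if sd == 0.0:
        return np.full(arr.shape, np.nan), stats
    return (arr - mean) / sd, stats


# ---------------------------------------------------------------------------
# verdict


def classify(
    fit: Optional[ParabolaFit],
    ratio: Optional[float],
    z: Optional[float],
    counts: IntervalCounts,
    cfg: ClassifyConfig | None = None,
    sample_id: str = "sample",
) -> PloidyCall:
    """Turn the fitted parabola into a ploidy verdict.

    Decision rule: triploid iff the parabola opens upward (a > 0) and its
    symmetry axis, rounded to ``cfg.axis_round_dp`` decimals, falls within
    [axis_lo, axis_hi] (a small ``axis_slack`` beyond the bounds is
    tolerated with an ``axis_out_of_range`` flag unless ``strict_axis``);
    a > 0 with the axis clearly off-centre gives triploid_low_confidence;
    a < 0 gives diploid.  Degenerate fits, undefined ratios and low site
    counts give inconclusive.  The Z-score only ever adds a flag.
    """
    cfg = cfg or ClassifyConfig()
    flags: set[str] = set()
    call = PloidyCall(sample_id=sample_id, verdict="inconclusive", ratio=ratio,
                      fit=fit, z=z, counts=counts, flags=flags)

    if counts.n_candidates < cfg.min_candidate_sites:
        flags.add("low_sites")
    if fit is None:
        flags.add("degenerate_fit")
    if ratio is None and counts.n_half == 0:
        flags.add("ratio_undefined")
    if z is not None and not math.isnan(z) and abs(z) >= cfg.z_flag_threshold:
        flags.add("z_outlier")
    if ratio is not None and cfg.mosaic_band[0] <= ratio <= cfg.mosaic_band[1]:
        # interval counts intermediate between the pure profiles
        flags.add("possible_mosaic")

    if "low_sites" in flags or fit is None or "ratio_undefined" in flags:
        return call
    if fit.a == 0.0:
        flags.add("degenerate_fit")
        return call

    if fit.a < 0.0:
        call.verdict = "diploid"
        return call

    axis = round(fit.axis, cfg.axis_round_dp)
    if cfg.axis_lo <= axis <= cfg.axis_hi:
        call.verdict = "triploid"
    elif (not cfg.strict_axis
          and cfg.axis_lo - cfg.axis_slack <= axis <= cfg.axis_hi + cfg.axis_slack):
        call.verdict = "triploid"
        flags.add("axis_out_of_range")
    else:
        call.verdict = "triploid_low_confidence"
        flags.add("axis_out_of_range")
    return call


# ---------------------------------------------------------------------------
# sample / batch drivers


def call_sample(
    sites: pd.DataFrame,
    panel: SNPPanel,
    cfg: PipelineConfig | None = None,
    sample_id: str = "sample",
    z: Optional[float] = None,
) -> PloidyCall:
    """Full single-sample chain: filter, select hets, count, fit, classify."""
    cfg = cfg or PipelineConfig()
    kept, _ = filter_sites(sites, panel, cfg.filter)
    hets = select_heterozygous(kept, cfg.filter)
    if hets.empty:
        counts = IntervalCounts(0, 0, 0, 0)
        return classify(None, None, z, counts, cfg.classify, sample_id)
    mrs = mutation_ratios(hets)
    counts = count_intervals(mrs, cfg.intervals)
    try:
        fit = fit_parabola(counts)
    except DegenerateFitError:
        fit = None
    try:
        ratio = ratio_statistic(counts)
    except UndefinedRatioError:
        ratio = None
    return classify(fit, ratio, z, counts, cfg.classify, sample_id)


def call_batch(
    samples: Mapping[str, pd.DataFrame],
    panel: SNPPanel,
    cfg: PipelineConfig | None = None,
    robust: bool = True,
) -> tuple[dict[str, PloidyCall], Optional[BatchStats]]:
    """Call every sample in a batch and attach within-batch Z-scores.

    Samples whose ratio statistic is undefined are excluded from the
    Z-test reference; if the batch is too small or the reference SD is
    zero, Z-scores stay absent/NaN and affected samples are flagged.
    """
    cfg = cfg or PipelineConfig()
    calls = {sid: call_sample(df, panel, cfg, sample_id=sid)
             for sid, df in samples.items()}
    with_ratio = [sid for sid, c in calls.items() if c.ratio is not None]
    stats: Optional[BatchStats] = None
    if len(with_ratio) >= 3:
        ratios = [calls[sid].ratio for sid in with_ratio]
        try:
            zs, stats = batch_z(ratios, robust=robust, cutoff=cfg.classify.ratio_cutoff)
        except ValueError:
            zs, stats = None, None
        if zs is not None:
            for sid, zval in zip(with_ratio, zs):
                c = calls[sid]
                c.z = float(zval)
                c.batch_stats = stats
                if math.isnan(zval):
                    c.flags.add("z_undefined")
                elif abs(zval) >= cfg.classify.z_flag_threshold:
                    c.flags.add("z_outlier")
    return calls, stats
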