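"""Sample-level quality guards.

Maternal cell contamination dilutes the triploid allele-fraction signal
toward diploid values and is the main source of false negatives.  The
admixed cells are always 46,XX, so in a male (single-X) fetus they leave
a depth footprint on the X chromosome: the X share of sequencing depth
drifts upward from the hemizygous expectation toward the XX expectation.
``x_fraction_check`` exploits this.  The guard is a flag, not a
quantitative contamination estimate.

``depth_titration`` answers "how much coverage does the classifier
need?" by simulating the same sample at a ladder of mean depths and
tracking the spread of the ratio statistic; it generates the data behind
a depth-requirement curve (the ratio stabilises by roughly 3x for
non-mosaic samples).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classifier import (UndefinedRatioError, count_intervals, mutation_ratios,
                         ratio_statistic)
from .config import FilterConfig, IntervalConfig, QCConfig
from .filtering import select_heterozygous
from .simulate import SimConfig, _is_x, make_panel, simulate_sample
from .sites import SNPPanel

logger = logging.getLogger(__name__)


@dataclass
class QCSummary:
    """X-fraction contamination check results.

    ``contamination_flag`` is None when the check is indeterminate (no X
    sites in the input).
    """

    x_depth_fraction: float
    autosome_depth_fraction_per_chrom: dict[str, float]
    contamination_flag: Optional[bool]
    mean_site_depth: float
    apparent_sex: Optional[str] = None
    x_het_rate: Optional[float] = None
    expected_x_fraction: Optional[float] = None
    x_autosome_dose: Optional[float] = None
    expected_x_dose: Optional[float] = None


def x_fraction_check(
    sites: pd.DataFrame, panel: SNPPanel, cfg: QCConfig | None = None
) -> QCSummary:
    """Flag possible maternal contamination from the X depth share.

    The test statistic is the X dosage: mean per-site depth on X relative
    to autosomes, which the admixture arithmetic predicts directly (1.0
    for two X doses, 0.5 for one, 0.65 for an XY fetus with 30% maternal
    reads) independent of how many panel sites sit on X.  Apparent sex
    (two doses vs one) is inferred from the X heterozygosity rate
    relative to autosomes unless ``cfg.known_sex`` is set.  The flag is
    raised when the dosage exceeds the sex-specific expectation by more
    than ``cfg.x_tolerance`` (relative) — the classic
    male-fetus-plus-maternal signature — and also when a sample that
    looks XX by heterozygosity shows a dosage well *below* the XX
    expectation, which is the same admixture seen from the other side
    (contamination fakes the X heterozygosity of an XX sample before it
    restores the full XX depth dose).  The reported ``x_depth_fraction``
    and its expectation (derived from the panel's X share of covered
    sites) are the same comparison on the genome-fraction scale.
    Sex-chromosome aneuploidies (e.g. 69,XXY) can trip this flag for
    dosage reasons; it marks samples for scrutiny, not rejection.
    """
    cfg = cfg or QCConfig()
    total = (sites["ref_depth"] + sites["alt_depth"]).to_numpy(np.int64)
    covered = total > 0
    if not covered.any():
        raise ValueError("no covered sites; cannot run QC")
    sub = sites[covered]
    total = total[covered]
    on_x = sub["chrom"].map(_is_x).to_numpy(bool)

    depth_by_chrom = pd.Series(total).groupby(sub["chrom"].to_numpy()).sum()
    grand = float(depth_by_chrom.sum())
    fractions = {c: float(v) / grand for c, v in depth_by_chrom.items()}
    x_frac = sum(v for c, v in fractions.items() if _is_x(c))
    auto_fracs = {c: v for c, v in fractions.items() if not _is_x(c)}
    mean_depth = float(total.mean())

    if not on_x.any() or on_x.all():
        logger.warning("need both X and autosomal sites: contamination check "
                       "indeterminate")
        return QCSummary(x_depth_fraction=x_frac,
                         autosome_depth_fraction_per_chrom=auto_fracs,
                         contamination_flag=None, mean_site_depth=mean_depth)

    het = ((sub["ref_depth"] >= 1) & (sub["alt_depth"] >= 1)).to_numpy(bool)
    x_het_rate = float(het[on_x].mean())
    auto_het_rate = float(het[~on_x].mean()) if (~on_x).any() else np.nan

    if cfg.known_sex is not None:
        apparent_sex = cfg.known_sex
    elif np.isnan(auto_het_rate) or auto_het_rate == 0:
        apparent_sex = "XX"
    else:
        apparent_sex = ("XY" if x_het_rate < cfg.sex_het_ratio_threshold * auto_het_rate
                        else "XX")

    # X dosage: mean per-site depth on X relative to autosomes
    dose = float(total[on_x].mean() / total[~on_x].mean())
    expected_dose = 1.0 if apparent_sex == "XX" else 0.5
    # the same expectation on the genome-fraction scale, for the report
    s_x = float(on_x.mean())
    expected = expected_dose * s_x / (1.0 - s_x + expected_dose * s_x)

    flag = dose > expected_dose * (1.0 + cfg.x_tolerance)
    if apparent_sex == "XX" and dose < expected_dose * (1.0 - cfg.x_tolerance):
        flag = True

    return QCSummary(
        x_depth_fraction=x_frac,
        autosome_depth_fraction_per_chrom=auto_fracs,
        contamination_flag=bool(flag),
        mean_site_depth=mean_depth,
        apparent_sex=apparent_sex,
        x_het_rate=x_het_rate,
        expected_x_fraction=expected,
        x_autosome_dose=dose,
        expected_x_dose=expected_dose,
    )


def depth_titration(
    sim_cfg: SimConfig,
    depths: Sequence[float],
    replicates: int = 50,
    seed: int = 0,
    filter_cfg: FilterConfig | None = None,
    interval_cfg: IntervalConfig | None = None,
) -> pd.DataFrame:
    """Ratio-statistic stability as a function of mean sequencing depth.

    Simulates ``replicates`` samples from ``sim_cfg`` at each target mean
    depth (shared panel, per-replicate seeds derived from ``seed``) and
    reports per-depth mean and SD of the ratio statistic, an
    ``instability`` column — the RMS deviation of the depth's replicate
    ratios from the deepest depth's mean, i.e. dispersion about the
    converged value, which is what "the curve is stable" means (plain
    replicate SD conflates this with the low-depth drift of the
    statistic itself) — and a Z-score of each depth's mean against the
    deepest depth's distribution.

    The site filter defaults to ``min_total_depth=2`` here — the ladder
    deliberately descends below the production depth cutoff, which would
    otherwise discard nearly all sites at 1-2x coverage.
    """
    if any(d <= 0 for d in depths):
        raise ValueError("target depths must be positive")
    filter_cfg = filter_cfg or FilterConfig(min_total_depth=2)
    interval_cfg = interval_cfg or IntervalConfig()

    ss = np.random.SeedSequence(seed)
    panel = make_panel(sim_cfg, np.random.default_rng(ss.spawn(1)[0]))
    rep_seeds = ss.spawn(len(depths) * replicates + 1)[1:]

    records = []
    idx = 0
    for depth in depths:
        cfg_d = replace(sim_cfg, mean_depth=float(depth))
        ratios = []
        for _ in range(replicates):
            rng = np.random.default_rng(rep_seeds[idx])
            idx += 1
            sites, _ = simulate_sample(cfg_d, panel=panel, rng=rng)
            total = sites["ref_depth"] + sites["alt_depth"]
            kept = sites[total >= filter_cfg.min_total_depth]
            hets = select_heterozygous(kept, filter_cfg)
            if hets.empty:
                continue
            counts = count_intervals(mutation_ratios(hets), interval_cfg)
            try:
                ratios.append(ratio_statistic(counts))
            except UndefinedRatioError:
                continue
        arr = np.asarray(ratios)
        records.append({
            "depth": float(depth),
            "n_valid": int(arr.size),
            "ratio_mean": float(arr.mean()) if arr.size else np.nan,
            "ratio_sd": float(arr.std(ddof=1)) if arr.size > 1 else np.nan,
        })
    table = pd.DataFrame(records)
    ref = table.iloc[int(np.argmax(table["depth"].to_numpy()))]
    with np.errstate(invalid="ignore"):
        table["instability"] = np.sqrt(
            table["ratio_sd"] ** 2 + (table["ratio_mean"] - ref["ratio_mean"]) ** 2)
    if ref["ratio_sd"] and not np.isnan(ref["ratio_sd"]) and ref["ratio_sd"] > 0:
        table["z_vs_deepest"] = (table["ratio_mean"] - ref["ratio_mean"]) / ref["ratio_sd"]
    else:
        table["z_vs_deepest"] = np.nan
    return table
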