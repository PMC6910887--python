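"""Candidate-SNP selection.

Two stages: ``filter_sites`` keeps sites that are known common SNPs with
adequate coverage, ``select_heterozygous`` keeps the subset where both
alleles are actually observed in the reads.  Heterozygosity is decided
observationally rather than from a genotype call, because genotype
callers assume a diploid model that is wrong for the very samples this
tool exists to find.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import FilterConfig
from .sites import SNPPanel


@dataclass
class FilterStats:
    """Per-criterion removal counts; removed + retained == input."""

    n_input: int = 0
    n_not_in_panel: int = 0
    n_low_af: int = 0
    n_low_depth: int = 0
    n_retained: int = 0

    def check_conservation(self) -> bool:
        return (self.n_not_in_panel + self.n_low_af + self.n_low_depth
                + self.n_retained) == self.n_input


def filter_sites(
    sites: pd.DataFrame, panel: SNPPanel, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, FilterStats]:
    """Keep sites that are in the panel, common enough, and covered enough.

    Criteria, applied in order (each removed site is counted once, under
    the first criterion it fails):

    1. the site matches the panel on chromosome, position and alleles;
    2. the panel *minor*-allele frequency ``min(af, 1 - af)`` exceeds
       ``cfg.min_panel_af`` (rare variants carry no ploidy information
       and are enriched for artifacts, whichever allele is rare);
    3. total read depth is at least ``cfg.min_total_depth``.

    Matched sites have ``panel_af`` filled from the panel.  Output rows
    keep their input order (subsequence of the input).
    """
    cfg = cfg or FilterConfig()
    stats = FilterStats(n_input=len(sites))
    if cfg.require_panel and len(panel) == 0:
        raise ValueError("panel is empty but require_panel is set")
    df = sites.copy()

    if cfg.require_panel:
        lut = panel.lookup()
        key = pd.MultiIndex.from_arrays([df["chrom"], df["pos"]])
        present = key.isin(lut.index)
        matched = lut.reindex(key[present])
        allele_ok = (
            (matched["ref"].to_numpy() == df.loc[present, "ref"].to_numpy())
            & (matched["alt"].to_numpy() == df.loc[present, "alt"].to_numpy())
        )
        in_panel = present.copy()
        in_panel[np.flatnonzero(present)[~allele_ok]] = False
        df.loc[in_panel, "panel_af"] = lut.reindex(key[in_panel])["af"].to_numpy()
        stats.n_not_in_panel = int((~in_panel).sum())
        df = df[in_panel]

    af = df["panel_af"].to_numpy(float)
    maf = np.minimum(af, 1.0 - af)
    af_ok = maf > cfg.min_panel_af
    if not cfg.require_panel:
        # user opted out of panel matching: unknown frequencies pass through
        af_ok = af_ok | np.isnan(af)
    stats.n_low_af = int((~af_ok).sum())
    df = df[af_ok]

    total = (df["ref_depth"] + df["alt_depth"]).to_numpy()
    depth_ok = total >= cfg.min_total_depth
    stats.n_low_depth = int((~depth_ok).sum())
    df = df[depth_ok]

    stats.n_retained = len(df)
    assert stats.check_conservation()
    return df.reset_index(drop=True), stats


def select_heterozygous(
    sites: pd.DataFrame, cfg: FilterConfig | None = None
) -> pd.DataFrame:
    """Keep sites where both alleles are supported by reads.

    A site is heterozygous (observationally) when ref and alt each carry
    at least ``cfg.het_min_minor_reads`` reads.  Extreme allele fractions
    that slip through (e.g. 1 of 25 reads) are harmless: they fall outside
    all three counting intervals downstream.
    """
    cfg = cfg or FilterConfig()
    m = cfg.het_min_minor_reads
    keep = (sites["ref_depth"] >= m) & (sites["alt_depth"] >= m)
    return sites[keep].reset_index(drop=True)
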