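"""Scan for uniparental isodisomy / loss of heterozygosity.

The genome is tiled with fixed-width bins (1 Mb by default, 0-based
half-open, last bin truncated at the chromosome end).  For each bin the
heterozygous-SNP frequency (HSF) is the fraction of informative sites —
covered panel SNPs passing the depth filter — that look heterozygous.
Isodisomic UPD removes heterozygosity, so affected bins show HSF at or
below 5% ("pink"); normal bins sit well above ("green").  Bins with too
few informative sites are "yellow" (poor data quality) and bins inside
declared assembly gaps are "gap"; neither contributes evidence.

Whole-chromosome UPD is called when nearly all informative bins of a
chromosome are pink; otherwise sufficiently long runs of consecutive pink
bins are reported as segmental calls.  Without parental genotypes the
method cannot distinguish isodisomic UPD from other causes of LOH, so
calls are reported as "consistent with UPD".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import UPDConfig
from .sites import SNPPanel

BIN_COLUMNS = ["chrom", "start", "end", "n_het", "n_informative", "hsf", "color"]


@dataclass(frozen=True)
class BinHSF:
    """One genomic bin with its heterozygous-SNP frequency and colour."""

    chrom: str
    start: int
    end: int
    n_het: int
    n_informative: int
    hsf: float  # NaN when the bin is yellow or gap
    color: str  # green | pink | yellow | gap


@dataclass(frozen=True)
class UPDCall:
    """A region of depressed heterozygosity consistent with isodisomic UPD."""

    chrom: str
    start: int
    end: int
    kind: str  # whole_chromosome | segmental
    n_pink_bins: int
    fraction_pink_of_informative: float


def bin_hsf(
    sites: pd.DataFrame, panel: SNPPanel, cfg: UPDConfig | None = None
) -> pd.DataFrame:
    """Per-bin heterozygous-SNP frequencies over the whole genome.

    ``sites`` must already be panel/depth-filtered with the same
    FilterConfig as the ploidy analysis, so every input site counts as
    informative.  Returns one row per bin of every chromosome in the
    panel's size table (columns :data:`BIN_COLUMNS`), ordered by
    chromosome then start.
    """
    cfg = cfg or UPDConfig()
    if not panel.chrom_sizes:
        raise ValueError("panel has no chromosome sizes; the scanner needs them")
    unknown = set(sites["chrom"].unique()) - set(panel.chrom_sizes)
    if unknown:
        raise ValueError(f"sites on chromosomes absent from the size table: {sorted(unknown)}")

    m = cfg.het_min_minor_reads
    is_het = (sites["ref_depth"] >= m) & (sites["alt_depth"] >= m)

    rows = []
    for chrom, length in panel.chrom_sizes.items():
        n_bins = int(np.ceil(length / cfg.bin_size))
        starts = np.arange(n_bins, dtype=np.int64) * cfg.bin_size
        ends = np.minimum(starts + cfg.bin_size, length)

        sub = sites[sites["chrom"] == chrom]
        bin_idx = (sub["pos"].to_numpy(np.int64) - 1) // cfg.bin_size
        n_inf = np.bincount(bin_idx, minlength=n_bins).astype(np.int64)
        n_het = np.bincount(bin_idx, weights=is_het[sub.index].to_numpy(float),
                            minlength=n_bins).astype(np.int64)

        gap_overlap = np.zeros(n_bins, dtype=np.int64)
        for gs, ge in panel.gaps.get(chrom, ()):
            gap_overlap += np.maximum(
                0, np.minimum(ends, ge) - np.maximum(starts, gs))

        widths = ends - starts
        is_gap = gap_overlap >= cfg.gap_overlap_frac * widths
        is_yellow = (~is_gap) & (n_inf < cfg.min_informative)
        with np.errstate(invalid="ignore", divide="ignore"):
            hsf = np.where(n_inf > 0, n_het / np.maximum(n_inf, 1), np.nan)
        hsf = np.where(is_gap | is_yellow, np.nan, hsf)
        color = np.where(
            is_gap, "gap",
            np.where(is_yellow, "yellow",
                     np.where(hsf <= cfg.pink_max_hsf, "pink", "green")))
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "n_het": n_het, "n_informative": n_inf, "hsf": hsf, "color": color,
        }))
    return pd.concat(rows, ignore_index=True)[BIN_COLUMNS]


def call_upd(bins: pd.DataFrame, cfg: UPDConfig | None = None) -> list[UPDCall]:
    """Call whole-chromosome and segmental UPD from coloured bins.

    A chromosome where at least ``whole_chrom_frac`` of its informative
    (green or pink) bins are pink yields one whole-chromosome call.
    Otherwise maximal runs of consecutive pink bins, tolerating up to
    ``max_interruptions`` yellow/gap bins strictly inside the run, are
    emitted as segmental calls when they contain >= ``min_run`` pink
    bins.  Green bins always terminate a run.  Output is independent of
    the input row order.
    """
    cfg = cfg or UPDConfig()
    calls: list[UPDCall] = []
    for chrom, sub in bins.groupby("chrom", sort=False):
        sub = sub.sort_values("start").reset_index(drop=True)
        colors = sub["color"].to_numpy()
        informative = np.isin(colors, ("green", "pink"))
        n_inf = int(informative.sum())
        n_pink = int((colors == "pink").sum())
        frac = n_pink / n_inf if n_inf else 0.0
        if n_inf > 0 and frac >= cfg.whole_chrom_frac:
            calls.append(UPDCall(
                chrom=chrom, start=int(sub["start"].iloc[0]),
                end=int(sub["end"].iloc[-1]), kind="whole_chromosome",
                n_pink_bins=n_pink, fraction_pink_of_informative=frac))
            continue
        calls.extend(_segmental_runs(chrom, sub, cfg))
    return calls


def _segmental_runs(chrom: str, sub: pd.DataFrame, cfg: UPDConfig) -> list[UPDCall]:
    colors = sub["color"].to_numpy()
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    runs: list[UPDCall] = []

    pink_idx: list[int] = []  # indices of pink bins in the current run
    interruptions = 0
    pending = 0  # yellow/gap bins seen since the last pink bin

    def close() -> None:
        nonlocal pink_idx, interruptions, pending
        if len(pink_idx) >= cfg.min_run:
            n_inf_run = int(np.isin(
                colors[pink_idx[0]: pink_idx[-1] + 1], ("green", "pink")).sum())
            runs.append(UPDCall(
                chrom=chrom, start=int(starts[pink_idx[0]]),
                end=int(ends[pink_idx[-1]]), kind="segmental",
                n_pink_bins=len(pink_idx),
                fraction_pink_of_informative=len(pink_idx) / n_inf_run))
        pink_idx, interruptions, pending = [], 0, 0

    for i, color in enumerate(colors):
        if color == "pink":
            if pink_idx and interruptions + pending > cfg.max_interruptions:
                close()
            interruptions += pending
            pending = 0
            pink_idx.append(i)
        elif color == "green":
            close()
        else:  # yellow or gap: only counts if a later pink continues the run
            if pink_idx:
                pending += 1
    close()
    return runs


def write_bins_tsv(bins: pd.DataFrame, path) -> None:
    """Emit the per-bin table (the data behind a genome-wide HSF plot)."""
    bins.to_csv(path, sep="\t", index=False, float_format="%.6g")
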