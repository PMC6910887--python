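"""Domain types and I/O for variant sites, SNP panels and result reports.

Sites are carried through the pipeline as a pandas DataFrame with the
columns in :data:`SITE_COLUMNS` (the "site table"); :class:`SNPSite` is
the validated single-record view of one row.  Coordinates in VCFs, site
tables and panel files are 1-based; all bin arithmetic and BED output
downstream are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "ref_depth", "alt_depth", "panel_af"]
VALID_BASES = frozenset("ACGT")


class SiteFormatError(ValueError):
    """Raised for malformed site tables, panels or VCF inputs."""


@dataclass(frozen=True)
class SNPSite:
    """One biallelic SNP with per-allele read depths.

    ``panel_af`` is the population alternate-allele frequency from the
    common-SNP panel, or ``None`` when the site is not (yet) matched.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    ref_depth: int
    alt_depth: int
    panel_af: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise SiteFormatError(
                f"{self.chrom}:{self.pos}: alleles must be single bases in ACGT, "
                f"got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise SiteFormatError(f"{self.chrom}:{self.pos}: ref and alt are identical")
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise SiteFormatError(f"{self.chrom}:{self.pos}: negative read depth")
        if self.pos < 1:
            raise SiteFormatError(f"{self.chrom}:{self.pos}: positions are 1-based")
        if self.panel_af is not None and not (0.0 <= self.panel_af <= 1.0):
            raise SiteFormatError(f"{self.chrom}:{self.pos}: panel_af outside [0, 1]")

    @property
    def total_depth(self) -> int:
        return self.ref_depth + self.alt_depth


def sites_to_frame(sites: Iterable[SNPSite]) -> pd.DataFrame:
    """Pack SNPSite records into the canonical site-table DataFrame."""
    rows = [
        (s.chrom, s.pos, s.ref, s.alt, s.ref_depth, s.alt_depth,
         np.nan if s.panel_af is None else s.panel_af)
        for s in sites
    ]
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return _coerce_site_frame(df)


def iter_sites(frame: pd.DataFrame) -> Iterator[SNPSite]:
    """Yield validated SNPSite records from a site-table DataFrame."""
    for row in frame.itertuples(index=False):
        yield SNPSite(
            chrom=row.chrom, pos=int(row.pos), ref=row.ref, alt=row.alt,
            ref_depth=int(row.ref_depth), alt_depth=int(row.alt_depth),
            panel_af=None if pd.isna(row.panel_af) else float(row.panel_af),
        )


def _coerce_site_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["pos"] = df["pos"].astype(np.int64)
    df["ref_depth"] = df["ref_depth"].astype(np.int64)
    df["alt_depth"] = df["alt_depth"].astype(np.int64)
    df["panel_af"] = df["panel_af"].astype(float)
    return df.reset_index(drop=True)


def empty_site_frame() -> pd.DataFrame:
    return _coerce_site_frame(pd.DataFrame(columns=SITE_COLUMNS))


@dataclass
class SNPPanel:
    """Common-SNP panel: positions, alleles, population allele frequencies.

    Also carries the genome geometry the UPD scanner needs: chromosome
    lengths and (optionally) assembly gap intervals (0-based half-open).
    """

    sites: pd.DataFrame  # columns chrom, pos, ref, alt, af
    chrom_sizes: Mapping[str, int] = field(default_factory=dict)
    gaps: Mapping[str, Sequence[tuple[int, int]]] = field(default_factory=dict)
    build: str = "custom"

    def __post_init__(self) -> None:
        req = ["chrom", "pos", "ref", "alt", "af"]
        if list(self.sites.columns)[: len(req)] != req:
            raise SiteFormatError(f"panel table must have columns {req}")
        if self.sites.duplicated(subset=["chrom", "pos"]).any():
            raise SiteFormatError("panel positions must be unique per chromosome")
        af = self.sites["af"].to_numpy(float)
        if len(af) and (np.nanmin(af) < 0 or np.nanmax(af) > 1):
            raise SiteFormatError("panel allele frequencies must lie in [0, 1]")
        for chrom, length in self.chrom_sizes.items():
            if length <= 0:
                raise SiteFormatError(f"chromosome {chrom} has non-positive length")
        for chrom, ivs in self.gaps.items():
            length = self.chrom_sizes.get(chrom)
            for start, end in ivs:
                if start < 0 or end <= start:
                    raise SiteFormatError(f"bad gap interval {chrom}:{start}-{end}")
                if length is not None and end > length:
                    raise SiteFormatError(f"gap {chrom}:{start}-{end} exceeds chromosome")

    def __len__(self) -> int:
        return len(self.sites)

    def lookup(self) -> pd.DataFrame:
        """Panel indexed by (chrom, pos) for vectorised joins."""
        return self.sites.set_index(["chrom", "pos"])


# ---------------------------------------------------------------------------
# readers


@dataclass
class VCFParseStats:
    """Per-file skip counters from VCF parsing."""

    n_kept: int = 0
    n_multiallelic: int = 0
    n_indel: int = 0
    n_no_allelic_depth: int = 0
    n_bad_alleles: int = 0


def read_vcf_sites(path: str | Path, sample_id: str) -> tuple[pd.DataFrame, VCFParseStats]:
    """Read biallelic SNPs with allelic depths for one sample from a VCF.

    Multi-allelic records, INDELs and records without a usable per-sample
    AD field are skipped and counted in the returned stats.  Sites with
    zero depth on both alleles are retained (downstream filters decide).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = pysam.VariantFile(str(path))
    if sample_id not in vcf.header.samples:
        raise KeyError(f"sample {sample_id!r} not in VCF header ({list(vcf.header.samples)})")
    stats = VCFParseStats()
    rows = []
    for rec in vcf:
        alts = rec.alts or ()
        if len(alts) != 1:
            stats.n_multiallelic += 1
            continue
        ref, alt = rec.ref, alts[0]
        if len(ref) != 1 or len(alt) != 1:
            stats.n_indel += 1
            continue
        if ref not in VALID_BASES or alt not in VALID_BASES:
            stats.n_bad_alleles += 1
            continue
        ad = rec.samples[sample_id].get("AD")
        if ad is None or len(ad) < 2 or ad[0] is None or ad[1] is None:
            stats.n_no_allelic_depth += 1
            continue
        rows.append((rec.chrom, rec.pos, ref, alt, int(ad[0]), int(ad[1]), np.nan))
        stats.n_kept += 1
    vcf.close()
    df = pd.DataFrame(rows, columns=SITE_COLUMNS) if rows else empty_site_frame()
    logger.info(
        "read %d sites for %s from %s (skipped: %d multiallelic, %d indel, "
        "%d without AD, %d non-ACGT)",
        stats.n_kept, sample_id, path, stats.n_multiallelic, stats.n_indel,
        stats.n_no_allelic_depth, stats.n_bad_alleles,
    )
    return _coerce_site_frame(df), stats


def read_site_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated site table (header row required, fixed order)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header != SITE_COLUMNS:
        raise SiteFormatError(
            f"{path}: expected header {SITE_COLUMNS}, found {header}"
        )
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        return empty_site_frame()
    out = {}
    out["chrom"] = df["chrom"]
    for col in ("pos", "ref_depth", "alt_depth"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals % 1 != 0)
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise SiteFormatError(f"{path}, line {line}: non-integer {col} {df[col][bad.idxmax()]!r}")
        out[col] = vals.astype(np.int64)
    out["ref"] = df["ref"]
    out["alt"] = df["alt"]
    out["panel_af"] = pd.to_numeric(df["panel_af"].mask(df["panel_af"] == ""),
                                    errors="coerce")
    frame = pd.DataFrame(out)[SITE_COLUMNS]
    # per-record validation (alleles, ranges) with line numbers
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            SNPSite(row.chrom, int(row.pos), row.ref, row.alt,
                    int(row.ref_depth), int(row.alt_depth),
                    None if pd.isna(row.panel_af) else float(row.panel_af))
        except SiteFormatError as exc:
            raise SiteFormatError(f"{path}, line {i + 2}: {exc}") from exc
    return _coerce_site_frame(frame)


def write_site_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a site-table DataFrame as TSV (inverse of read_site_table)."""
    df = frame[SITE_COLUMNS].copy()
    df["panel_af"] = df["panel_af"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    df.to_csv(path, sep="\t", index=False)


def read_panel(
    path: str | Path,
    sizes_path: str | Path | None = None,
    gaps_path: str | Path | None = None,
    build: str = "custom",
) -> SNPPanel:
    """Load a panel TSV (chrom, pos, ref, alt, af) plus optional geometry."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    req = ["chrom", "pos", "ref", "alt", "af"]
    if list(df.columns)[: len(req)] != req:
        raise SiteFormatError(f"{path}: expected columns {req}, found {list(df.columns)}")
    df["pos"] = df["pos"].astype(np.int64)
    sizes = read_chrom_sizes(sizes_path) if sizes_path else {}
    gaps = read_gaps_bed(gaps_path) if gaps_path else {}
    return SNPPanel(sites=df, chrom_sizes=sizes, gaps=gaps, build=build)


def write_panel(panel: SNPPanel, path: str | Path) -> None:
    panel.sites.to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    sizes: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        chrom, length = line.split("\t")[:2]
        sizes[chrom] = int(length)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    Path(path).write_text("".join(f"{c}\t{l}\n" for c, l in sizes.items()))


def read_gaps_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """BED (0-based half-open) of assembly gap intervals, keyed by chromosome."""
    gaps: dict[str, list[tuple[int, int]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        gaps.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    return gaps


# ---------------------------------------------------------------------------
# report writing


def write_report(call, upd_calls, out_dir: str | Path, config=None, qc=None) -> None:
    """Write the per-sample report (YAML key-value text) and a UPD BED track.

    Output is deterministic: the same call and config always serialise to
    byte-identical files.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    fit = call.fit
    doc = {
        "software": {"name": "snp-ploidy", "version": __version__},
        "sample_id": call.sample_id,
        "verdict": call.verdict,
        "ratio_statistic": _num(call.ratio),
        "parabola": None if fit is None else {
            "a": _num(fit.a), "b": _num(fit.b), "c": _num(fit.c),
            "axis": _num(fit.axis),
            "y": [_num(fit.y1), _num(fit.y2), _num(fit.y3)],
        },
        "z_score": _num(call.z),
        "n_candidate_sites": None if call.counts is None else int(call.counts.n_candidates),
        "interval_counts": None if call.counts is None else {
            "third": int(call.counts.n_third),
            "half": int(call.counts.n_half),
            "two_thirds": int(call.counts.n_two_thirds),
        },
        "flags": sorted(call.flags),
        "upd_calls": [
            {"chrom": u.chrom, "start": int(u.start), "end": int(u.end),
             "kind": u.kind, "n_pink_bins": int(u.n_pink_bins),
             "fraction_pink_of_informative": _num(u.fraction_pink_of_informative)}
            for u in upd_calls
        ],
    }
    if qc is not None:
        doc["qc"] = {
            "x_depth_fraction": _num(qc.x_depth_fraction),
            "apparent_sex": qc.apparent_sex,
            "contamination_flag": qc.contamination_flag,
            "mean_site_depth": _num(qc.mean_site_depth),
        }
    if config is not None:
        doc["config"] = config.to_dict()
    (out_dir / "report.yaml").write_text(yaml.safe_dump(doc, sort_keys=False))

    bed_lines = ["# UPD/LOH calls (0-based half-open); regions of depressed "
                 "heterozygosity consistent with isodisomic UPD"]
    for u in upd_calls:
        bed_lines.append(f"{u.chrom}\t{u.start}\t{u.end}\t{u.kind}\t{u.n_pink_bins}")
    (out_dir / "upd.bed").write_text("\n".join(bed_lines) + "\n")


def _num(v):
    if v is None:
        return None
    v = float(v)
    return None if np.isnan(v) else v
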