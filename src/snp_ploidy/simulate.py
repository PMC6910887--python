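"""Generative model for per-site allele-depth data.

Emulates what the classifier assumes about low-coverage WGS of fetal
(products-of-conception) tissue: a panel of common biallelic SNPs with
known population allele frequencies; fetal genotypes drawn per site
under Hardy-Weinberg at the configured ploidy; read depth Poisson; and
alternate-read counts binomial around the sample's alternate-allele DNA
fraction, which mixes the fetal genotype with an (independent) maternal
diploid genotype at the maternal-contamination weight and applies a
symmetric per-read error rate.  X-chromosome dosage follows the sex
karyotype, and the maternal admixture is always 46,XX — which is what
makes maternal contamination visible in the X depth fraction of male
fetuses.  Isodisomic UPD regions force fetal homozygosity.

Not modelled: GC/mappability bias, alignment artifacts, linkage between
neighbouring sites, or mother-fetus allele inheritance (the maternal
genotype is drawn independently from the same population frequency).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .sites import (SITE_COLUMNS, SNPPanel, _coerce_site_frame, write_chrom_sizes,
                    write_panel, write_site_table)

#: GRCh37 chromosome lengths (autosomes + X), the coordinate frame the
#: method was designed around.
HG19_CHROM_SIZES: dict[str, int] = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430, "chr4": 191154276,
    "chr5": 180915260, "chr6": 171115067, "chr7": 159138663, "chr8": 146364022,
    "chr9": 141213431, "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392, "chr16": 90354753,
    "chr17": 81195210, "chr18": 78077248, "chr19": 59128983, "chr20": 63025520,
    "chr21": 48129895, "chr22": 51304566, "chrX": 155270560,
}

_BASES = np.array(list("ACGT"))
_X_COPIES = {"XX": 2, "XY": 1, "XXX": 3, "XXY": 2, "XYY": 1}
_PLOIDY_SEXES = {"diploid": ("XX", "XY"), "triploid": ("XXX", "XXY", "XYY")}


@dataclass
class SimConfig:
    """Study conditions for one simulated sample.

    n_panel_sites is per chromosome; with the default genome (hg19
    autosomes + X) the default of 700 sites/chromosome yields roughly
    5000 candidate heterozygous SNPs after filtering, the scale at which
    the classifier is intended to operate.  mean_depth is the Poisson
    mean read depth at an autosomal site (15 by default, comfortably
    above the >=10-read site filter).  error_rate is the symmetric
    per-read miscall probability; maternal_fraction is the fraction of
    reads deriving from maternal (46,XX diploid) cells.

    Panel alternate-allele frequencies are uniform on ``af_range``; the
    default (0.05, 0.95) corresponds to a common-SNP panel thresholded
    at 5% minor-allele frequency, where the reference allele is the
    major allele only about half the time.  This symmetry is what keeps
    the 1/3 and 2/3 heterozygote classes of a triploid balanced and the
    parabola's symmetry axis near 1/2.
    """

    ploidy: str = "diploid"
    sex: str = "XX"
    genome: Mapping[str, int] = field(default_factory=lambda: dict(HG19_CHROM_SIZES))
    n_panel_sites: int = 700
    mean_depth: float = 15.0
    error_rate: float = 0.002
    maternal_fraction: float = 0.0
    mosaic_fraction: float = 0.0
    upd_regions: tuple[tuple[str, int, int], ...] = ()
    seed: int = 0
    af_range: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self) -> None:
        if self.ploidy not in _PLOIDY_SEXES:
            raise ValueError(f"ploidy must be one of {sorted(_PLOIDY_SEXES)}")
        if self.sex not in _PLOIDY_SEXES[self.ploidy]:
            raise ValueError(
                f"sex {self.sex!r} invalid for {self.ploidy} "
                f"(choose from {_PLOIDY_SEXES[self.ploidy]})")
        for name in ("maternal_fraction", "mosaic_fraction", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= (0.5 if name == "maternal_fraction" else 1.0)):
                raise ValueError(f"{name}={v} out of range")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.n_panel_sites < 1:
            raise ValueError("n_panel_sites must be >= 1")
        lo, hi = self.af_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("af_range must be an ordered pair inside [0, 1]")
        for chrom, s, e in self.upd_regions:
            if chrom not in self.genome or s < 0 or e <= s:
                raise ValueError(f"bad UPD region {chrom}:{s}-{e}")

    @property
    def n_copies(self) -> int:
        return 2 if self.ploidy == "diploid" else 3


@dataclass
class SampleTruth:
    """Latent state behind one simulated sample."""

    ploidy: str
    sex: str
    maternal_fraction: float
    mosaic_fraction: float
    upd_regions: tuple[tuple[str, int, int], ...]
    sites: pd.DataFrame  # chrom, pos, cn_fetal, k_fetal, k_maternal, p_alt


def make_panel(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> SNPPanel:
    """Draw a common-SNP panel: positions, distinct ref/alt bases, AFs."""
    rng = rng or np.random.default_rng(cfg.seed)
    frames = []
    for chrom, length in cfg.genome.items():
        n = min(cfg.n_panel_sites, length)
        pos = np.unique(rng.integers(1, length + 1, size=n))
        ref_i = rng.integers(0, 4, size=pos.size)
        alt_i = (ref_i + rng.integers(1, 4, size=pos.size)) % 4
        af = rng.uniform(cfg.af_range[0], cfg.af_range[1], size=pos.size)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos.astype(np.int64),
            "ref": _BASES[ref_i], "alt": _BASES[alt_i], "af": af,
        }))
    return SNPPanel(sites=pd.concat(frames, ignore_index=True),
                    chrom_sizes=dict(cfg.genome), build="simulated")


def simulate_sample(
    cfg: SimConfig,
    panel: Optional[SNPPanel] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, SampleTruth]:
    """Simulate read counts at every panel site for one sample.

    Returns the site table (with panel_af filled in) and the truth
    record.  Same seed, same panel -> identical output.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    if panel is None:
        panel = make_panel(cfg, rng)

    site_frames, truth_frames = [], []
    mf = cfg.maternal_fraction
    ploidy = cfg.n_copies
    for chrom, sub in panel.sites.groupby("chrom", sort=False):
        af = sub["af"].to_numpy(float)
        pos = sub["pos"].to_numpy(np.int64)
        n = af.size
        is_x = _is_x(chrom)
        cn_f = _X_COPIES[cfg.sex] if is_x else ploidy

        k_f = rng.binomial(cn_f, af)
        upd_mask = np.zeros(n, dtype=bool)
        for uchrom, us, ue in cfg.upd_regions:
            if uchrom == chrom:
                upd_mask |= (pos - 1 >= us) & (pos - 1 < ue)
        if upd_mask.any():
            k_f[upd_mask] = cn_f * rng.binomial(1, af[upd_mask])

        dose_f = k_f / cn_f
        if cfg.mosaic_fraction > 0 and not is_x and cn_f >= 2:
            dose_f = _mosaic_dose(k_f, cn_f, cfg.mosaic_fraction, rng)

        k_m = rng.binomial(2, af)
        w_f = (1.0 - mf) * (cn_f / ploidy)
        w_m = mf  # maternal cells are 46,XX: weight 1 on autosomes and X
        p = (w_f * dose_f + w_m * (k_m / 2.0)) / (w_f + w_m)
        p_err = p * (1.0 - cfg.error_rate) + (1.0 - p) * cfg.error_rate

        depth = rng.poisson(cfg.mean_depth * (w_f + w_m), size=n)
        alt = rng.binomial(depth, p_err)
        ref = depth - alt

        site_frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "ref": sub["ref"].to_numpy(),
            "alt": sub["alt"].to_numpy(), "ref_depth": ref, "alt_depth": alt,
            "panel_af": af,
        }))
        truth_frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "cn_fetal": cn_f, "k_fetal": k_f,
            "k_maternal": k_m, "p_alt": p, "is_upd": upd_mask,
        }))

    sites = _coerce_site_frame(pd.concat(site_frames, ignore_index=True)[SITE_COLUMNS])
    truth = SampleTruth(
        ploidy=cfg.ploidy, sex=cfg.sex, maternal_fraction=mf,
        mosaic_fraction=cfg.mosaic_fraction, upd_regions=cfg.upd_regions,
        sites=pd.concat(truth_frames, ignore_index=True))
    return sites, truth


def _mosaic_dose(
    k_f: np.ndarray, cn_f: int, mosaic_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Mix the primary-ploidy allele dose with a second cell line's.

    The minority line's genotype derives from the primary one by losing a
    random homologue (triploid primary) or duplicating one (diploid
    primary), so the two lines stay concordant, as in real mosaics.
    """
    if cn_f == 3:
        k_other = rng.hypergeometric(k_f, cn_f - k_f, 2)
        cn_other = 2
    else:
        k_other = k_f + rng.binomial(1, k_f / cn_f)
        cn_other = cn_f + 1
    return (1.0 - mosaic_fraction) * (k_f / cn_f) + mosaic_fraction * (k_other / cn_other)


def _is_x(chrom: str) -> bool:
    return chrom.lower().removeprefix("chr") == "x"


@dataclass
class BatchSim:
    """A batch of simulated samples sharing one panel."""

    panel: SNPPanel
    samples: dict[str, pd.DataFrame]
    truths: dict[str, SampleTruth]
    truth_table: pd.DataFrame  # sample_id, ploidy, sex, maternal_fraction


def simulate_batch(
    n_diploid: int,
    n_triploid: int,
    base_cfg: Optional[SimConfig] = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> BatchSim:
    """Simulate a sequencing batch: shared panel, independent samples.

    Per-sample seeds derive from ``seed`` via numpy SeedSequence spawning,
    so the whole batch is reproducible and samples are independent.
    Sexes cycle through the valid karyotypes for each ploidy.  When
    ``out_dir`` is given, writes site tables, the panel, chromosome
    sizes, and a truth manifest in the formats the readers consume.
    """
    if n_diploid < 0 or n_triploid < 0:
        raise ValueError("sample counts must be non-negative")
    base_cfg = base_cfg or SimConfig()
    ss = np.random.SeedSequence(seed)
    panel_rng = np.random.default_rng(ss.spawn(1)[0])
    panel = make_panel(base_cfg, panel_rng)

    specs: list[tuple[str, str, str]] = []
    for i in range(n_diploid):
        specs.append((f"DIP_{i + 1:03d}", "diploid",
                      _PLOIDY_SEXES["diploid"][i % 2]))
    for i in range(n_triploid):
        specs.append((f"TRI_{i + 1:03d}", "triploid",
                      _PLOIDY_SEXES["triploid"][i % 3]))

    samples: dict[str, pd.DataFrame] = {}
    truths: dict[str, SampleTruth] = {}
    child_seeds = ss.spawn(len(specs) + 1)[1:]
    for (sid, ploidy, sex), child in zip(specs, child_seeds):
        cfg = replace(base_cfg, ploidy=ploidy, sex=sex)
        sites, truth = simulate_sample(cfg, panel=panel,
                                       rng=np.random.default_rng(child))
        samples[sid] = sites
        truths[sid] = truth

    truth_table = pd.DataFrame(
        [(sid, t.ploidy, t.sex, t.maternal_fraction)
         for sid, t in truths.items()],
        columns=["sample_id", "ploidy", "sex", "maternal_fraction"])

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_panel(panel, out_dir / "panel.tsv")
        write_chrom_sizes(panel.chrom_sizes, out_dir / "chrom.sizes")
        truth_table.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
        manifest = []
        for sid, sites in samples.items():
            p = out_dir / f"{sid}.sites.tsv"
            write_site_table(sites, p)
            manifest.append((sid, p.name))
        pd.DataFrame(manifest, columns=["sample_id", "path"]).to_csv(
            out_dir / "manifest.tsv", sep="\t", index=False)

    return BatchSim(panel=panel, samples=samples, truths=truths,
                    truth_table=truth_table)
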