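"""Per-individual genomic diversity: heterozygosity metrics and ROH.

Heterozygotes per kbp divides the per-sample heterozygous genotype count by
the genome length (default 1,927,125,257 bp) and multiplies by 1000; the
heterozygosity ratio divides it by the count of homozygous-alternative
genotypes.  Runs of homozygosity follow the classic 50-SNP sliding-window
procedure with its documented defaults (<=1 het and <=5 missing per window,
5% hit fraction, >=100 SNPs, >=1000 kbp, <=50 kbp/SNP density, <=1000 kbp
internal gaps); this is an emulation of the cited tool's default behaviour,
with run-edge tie-breaking as implemented below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import GT_HET, GT_HOM_ALT, GT_MISSING, VariantTable

__all__ = [
    "DEFAULT_GENOME_LENGTH",
    "DiversityStats",
    "ROHSegment",
    "RohParams",
    "het_stats",
    "roh_scan",
    "total_roh",
]

DEFAULT_GENOME_LENGTH = 1_927_125_257


@dataclass(frozen=True)
class DiversityStats:
    sample_id: str
    n_het: int
    n_alt_hom: int
    genome_length: int
    het_per_kbp: float
    het_ratio: float  # NaN when n_alt_hom == 0

    @property
    def het_ratio_defined(self) -> bool:
        return self.n_alt_hom > 0


@dataclass(frozen=True)
class RohParams:
    window_snps: int = 50
    window_max_het: int = 1
    window_max_missing: int = 5
    hit_fraction: float = 0.05
    min_snps: int = 100
    min_length_bp: int = 1_000_000
    max_density_bp_per_snp: float = 50_000.0
    max_gap_bp: int = 1_000_000


@dataclass(frozen=True)
class ROHSegment:
    sample_id: str
    chrom: str
    start: int  # position of first member SNP, 1-based
    end: int  # position of last member SNP, inclusive
    n_snps: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def het_stats(
    vt: VariantTable, genome_length: int = DEFAULT_GENOME_LENGTH
) -> list[DiversityStats]:
    """Exact per-sample heterozygosity counts and derived metrics.

    Missing genotypes contribute to neither count.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    code = vt.gt_code
    out = []
    for j, sid in enumerate(vt.samples):
        n_het = int((code[:, j] == GT_HET).sum())
        n_alt_hom = int((code[:, j] == GT_HOM_ALT).sum())
        out.append(
            DiversityStats(
                sample_id=sid,
                n_het=n_het,
                n_alt_hom=n_alt_hom,
                genome_length=genome_length,
                het_per_kbp=n_het / genome_length * 1000.0,
                het_ratio=(n_het / n_alt_hom) if n_alt_hom > 0 else float("nan"),
            )
        )
    return out


def het_stats_frame(vt: VariantTable, genome_length: int = DEFAULT_GENOME_LENGTH) -> pd.DataFrame:
    rows = het_stats(vt, genome_length)
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "n_het": [r.n_het for r in rows],
            "n_alt_hom": [r.n_alt_hom for r in rows],
            "het_per_kbp": [r.het_per_kbp for r in rows],
            "het_ratio": [r.het_ratio for r in rows],
        }
    )


def _sample_chrom_roh(
    sid: str, chrom: str, pos: np.ndarray, code: np.ndarray, params: RohParams
) -> list[ROHSegment]:
    m = len(pos)
    w = params.window_snps
    if m < w:
        return []
    het = (code == GT_HET).astype(np.int64)
    mis = (code == GT_MISSING).astype(np.int64)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    n_win = m - w + 1
    starts = np.arange(n_win)
    win_het = chet[starts + w] - chet[starts]
    win_mis = cmis[starts + w] - cmis[starts]
    ok = (win_het <= params.window_max_het) & (win_mis <= params.window_max_missing)

    # per-SNP: fraction of overlapping windows that pass
    hit = np.zeros(m + 1, dtype=np.int64)
    tot = np.zeros(m + 1, dtype=np.int64)
    np.add.at(tot, starts, 1)
    np.add.at(tot, starts + w, -1)
    ok_starts = starts[ok]
    np.add.at(hit, ok_starts, 1)
    np.add.at(hit, ok_starts + w, -1)
    hit = np.cumsum(hit[:-1])
    tot = np.cumsum(tot[:-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(tot > 0, hit / tot, 0.0)
    in_run = frac >= params.hit_fraction

    segments: list[ROHSegment] = []
    i = 0
    while i < m:
        if not in_run[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and in_run[j + 1] and pos[j + 1] - pos[j] <= params.max_gap_bp:
            j += 1
        n_snps = j - i + 1
        length = int(pos[j] - pos[i] + 1)
        if (
            n_snps >= params.min_snps
            and length >= params.min_length_bp
            and length / n_snps <= params.max_density_bp_per_snp
        ):
            segments.append(
                ROHSegment(
                    sample_id=sid,
                    chrom=chrom,
                    start=int(pos[i]),
                    end=int(pos[j]),
                    n_snps=n_snps,
                )
            )
        i = j + 1
    return segments


def roh_scan(vt: VariantTable, params: RohParams | None = None) -> list[ROHSegment]:
    """Detect runs of homozygosity for every sample.

    Per sample and chromosome, 50-SNP windows are scored homozygous when
    they carry at most 1 het and 5 missing calls; a SNP joins a run when at
    least 5% of the windows overlapping it pass; maximal stretches of such
    SNPs (split at inter-SNP gaps beyond 1000 kbp) are emitted if they hold
    >= 100 SNPs, span >= 1000 kbp, and average <= 50 kbp per SNP.
    """
    params = params or RohParams()
    code = vt.gt_code
    segments: list[ROHSegment] = []
    for chrom in pd.unique(vt.chrom.astype(str)):
        rows = np.flatnonzero(vt.chrom.astype(str) == chrom)
        pos = vt.pos[rows]
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"variants on {chrom} are not position-sorted")
        for j, sid in enumerate(vt.samples):
            segments.extend(
                _sample_chrom_roh(sid, chrom, pos, code[rows, j], params)
            )
    return segments


def total_roh(segments: list[ROHSegment], samples: list[str] | None = None) -> pd.Series:
    """Total ROH length per sample (bp); zero for samples without segments."""
    totals: dict[str, int] = {s: 0 for s in (samples or [])}
    for seg in segments:
        totals[seg.sample_id] = totals.get(seg.sample_id, 0) + seg.length
    return pd.Series(totals, dtype=np.int64).sort_index()
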