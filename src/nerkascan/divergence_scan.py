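"""Eigenvector divergence scan with genomic-control correction and peaks.

Each variant's dosage is regressed (OLS) against a per-individual
quantitative score — typically a PC score, but any finite vector (e.g.
ancestry fractions) is accepted.  The per-variant chi-square statistic
``(beta/se)^2`` is deflated by the genomic inflation factor
``lambda = median(chi2) / median(chi2_1)`` before Bonferroni thresholding,
and significant variants are clustered into peaks by consecutive-gap
chaining (gap <= 100 kbp, at least five members).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import DosageMatrix

__all__ = [
    "CHI2_1_MEDIAN",
    "ScanResult",
    "Peak",
    "eigen_scan",
    "genomic_inflation_factor",
    "significant_set",
    "call_peaks",
    "run_scan",
]

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.4549364...
CHI2_CAP = 1e12
P_FLOOR = np.finfo(np.float64).tiny
LAMBDA_FLOOR = 1e-6
MIN_CALLED = 3


@dataclass
class ScanResult:
    chrom: np.ndarray
    pos: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    chi2: np.ndarray
    p_raw: np.ndarray
    valid: np.ndarray  # statistic defined (>=3 called, polymorphic)
    lambda_gc: float = np.nan
    p_adj: np.ndarray | None = None
    alpha: float = 0.01

    @property
    def m(self) -> int:
        """Number of variants actually interrogated."""
        return int(self.valid.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": self.chrom.astype(str),
                "pos": self.pos,
                "beta": self.beta,
                "se": self.se,
                "chi2": self.chi2,
                "p_raw": self.p_raw,
                "valid": self.valid,
            }
        )
        if self.p_adj is not None:
            df["p_adj"] = self.p_adj
        return df


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    n_sig: int
    lead_idx: int
    lead_pos: int
    lead_p: float
    member_idx: tuple[int, ...] = field(default=())

    @property
    def span(self) -> int:
        return self.end - self.start


def eigen_scan(dosages: DosageMatrix | np.ndarray, score: np.ndarray) -> ScanResult:
    """Per-variant OLS of ``score ~ a + b*dosage`` over called individuals.

    Vectorized across variants with per-variant missingness masks.  The test
    statistic is ``chi2 = (b/se)^2`` with a chi-square(1) p-value.  Variants
    monomorphic within the called set, or with fewer than three called
    individuals, are marked invalid and excluded from ``m``.  Perfect fits
    are capped at a large finite chi2 with the p-value floored at the
    smallest positive double.
    """
    if isinstance(dosages, DosageMatrix):
        values, chrom, pos = dosages.values, dosages.chrom, dosages.pos
    else:
        values = np.asarray(dosages, dtype=np.float64)
        chrom = np.array(["?"] * values.shape[0], dtype=object)
        pos = np.arange(values.shape[0], dtype=np.int64)
    y = np.asarray(score, dtype=np.float64)
    if not np.all(np.isfinite(y)):
        raise ValueError("score must be finite for every individual")
    mask = np.isfinite(values)
    g0 = np.where(mask, values, 0.0)
    mk = mask.astype(np.float64)
    n = mk.sum(axis=1)
    sg = g0.sum(axis=1)
    sgg = (g0 * g0).sum(axis=1)
    sy = mk @ y
    syy = mk @ (y * y)
    sgy = g0 @ y
    with np.errstate(divide="ignore", invalid="ignore"):
        sxx = sgg - sg * sg / n
        sxy = sgy - sg * sy / n
        syy_c = syy - sy * sy / n
        beta = sxy / sxx
        r2 = np.where(syy_c > 0, (sxy * sxy) / (sxx * syy_c), 0.0)
        r2 = np.clip(r2, 0.0, 1.0)
        chi2 = (n - 2) * r2 / (1.0 - r2)
    valid = (n >= MIN_CALLED) & (sxx > 0)
    chi2 = np.where(valid, np.minimum(chi2, CHI2_CAP), np.nan)
    chi2 = np.where(valid & ~np.isfinite(chi2), CHI2_CAP, chi2)
    beta = np.where(valid, beta, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.abs(beta) / np.sqrt(chi2)
        # beta == 0 with zero residual variance: flat score, se is 0 by limit
        se = np.where(valid & (chi2 == 0), np.sqrt(np.maximum(syy_c, 0.0) / np.maximum(n - 2, 1) / sxx), se)
    p_raw = np.where(valid, np.maximum(stats.chi2.sf(chi2, df=1), P_FLOOR), np.nan)
    return ScanResult(
        chrom=np.asarray(chrom),
        pos=np.asarray(pos),
        beta=beta,
        se=se,
        chi2=chi2,
        p_raw=p_raw,
        valid=valid,
    )


def genomic_inflation_factor(chi2s: np.ndarray) -> float:
    """Median observed chi-square over the chi-square(1) median, floored."""
    x = np.asarray(chi2s, dtype=np.float64)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite chi-square statistics")
    return max(float(np.median(x)) / CHI2_1_MEDIAN, LAMBDA_FLOOR)


def significant_set(scan: ScanResult, alpha: float = 0.01) -> np.ndarray:
    """Apply genomic control and Bonferroni; returns significant row indices.

    Fills ``scan.lambda_gc`` and ``scan.p_adj`` in place.  The Bonferroni
    denominator is ``m``, the count of variants with a defined statistic.
    """
    m = scan.m
    if m == 0:
        raise ValueError("no interrogated variants")
    if np.isnan(scan.lambda_gc):
        scan.lambda_gc = genomic_inflation_factor(scan.chi2[scan.valid])
    adj = np.full_like(scan.chi2, np.nan)
    adj[scan.valid] = np.maximum(
        stats.chi2.sf(scan.chi2[scan.valid] / scan.lambda_gc, df=1), P_FLOOR
    )
    scan.p_adj = adj
    scan.alpha = alpha
    threshold = alpha / m
    with np.errstate(invalid="ignore"):
        sig = scan.valid & (adj < threshold)
    return np.flatnonzero(sig)


def call_peaks(
    chrom: np.ndarray,
    pos: np.ndarray,
    p_adj: np.ndarray,
    sig_idx: np.ndarray,
    min_count: int = 5,
    max_gap: int = 100_000,
) -> list[Peak]:
    """Chain significant variants into peaks.

    Consecutive significant variants on one chromosome are chained whenever
    the gap between neighbours is <= ``max_gap`` (transitive chaining, so a
    peak may span more than ``max_gap``); chains with >= ``min_count``
    members are emitted.  The lead is the member with the lowest adjusted p.
    """
    sig_idx = np.asarray(sig_idx, dtype=np.int64)
    if sig_idx.size == 0:
        return []
    order = np.lexsort((pos[sig_idx], chrom[sig_idx].astype(str)))
    sig_sorted = sig_idx[order]
    peaks: list[Peak] = []
    chain: list[int] = [int(sig_sorted[0])]
    for i in sig_sorted[1:]:
        prev = chain[-1]
        same = str(chrom[i]) == str(chrom[prev])
        if same and int(pos[i]) - int(pos[prev]) <= max_gap:
            chain.append(int(i))
        else:
            peaks.extend(_emit(chain, chrom, pos, p_adj, min_count))
            chain = [int(i)]
    peaks.extend(_emit(chain, chrom, pos, p_adj, min_count))
    return peaks


def _emit(chain, chrom, pos, p_adj, min_count) -> list[Peak]:
    if len(chain) < min_count:
        return []
    ps = p_adj[chain]
    lead_local = int(np.nanargmin(ps))
    lead = chain[lead_local]
    return [
        Peak(
            chrom=str(chrom[chain[0]]),
            start=int(pos[chain[0]]),
            end=int(pos[chain[-1]]),
            n_sig=len(chain),
            lead_idx=int(lead),
            lead_pos=int(pos[lead]),
            lead_p=float(p_adj[lead]),
            member_idx=tuple(chain),
        )
    ]


def run_scan(
    dosages: DosageMatrix,
    score: np.ndarray,
    alpha: float = 0.01,
    min_count: int = 5,
    max_gap: int = 100_000,
) -> tuple[ScanResult, list[Peak]]:
    """Full scan: OLS, inflation correction, Bonferroni, peak calling."""
    scan = eigen_scan(dosages, score)
    sig = significant_set(scan, alpha=alpha)
    peaks = call_peaks(scan.chrom, scan.pos, scan.p_adj, sig, min_count, max_gap)
    return scan, peaks
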