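"""Genotype linkage disequilibrium: r², pair listing, blocks, window track.

r² is the squared Pearson correlation of alternate-allele dosages, computed
over individuals called in both variants (complete cases, no imputation).
Pair listing is exact all-pairs within a chromosome — O(m²) is accepted at
desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import DosageMatrix

__all__ = [
    "LDPair",
    "LDBlock",
    "genotype_r2",
    "pairwise_r2",
    "r2_to_lead",
    "chromosome_pairs",
    "block_around_lead",
    "longrange_track",
]

MIN_SHARED_CALLS = 3


@dataclass(frozen=True)
class LDPair:
    chrom: str
    idx_a: int
    idx_b: int
    pos_a: int
    pos_b: int
    r2: float

    @property
    def distance(self) -> int:
        return abs(self.pos_b - self.pos_a)


@dataclass(frozen=True)
class LDBlock:
    chrom: str
    lead_idx: int
    lead_pos: int
    member_idx: tuple[int, ...]
    member_pos: tuple[int, ...]
    min_r2: float

    @property
    def span(self) -> tuple[int, int]:
        return (min(self.member_pos), max(self.member_pos))

    @property
    def span_length(self) -> int:
        lo, hi = self.span
        return hi - lo


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over co-called
    individuals.  NaN when fewer than 3 shared calls or either vector is
    constant on the shared set."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < MIN_SHARED_CALLS:
        return float("nan")
    xs, ys = x[ok], y[ok]
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx <= 0.0 or vy <= 0.0:
        return float("nan")
    cov = float(xc @ yc)
    return min((cov * cov) / (vx * vy), 1.0)


def pairwise_r2(values: np.ndarray) -> np.ndarray:
    """All-pairs r² matrix with pairwise-complete observations.

    ``values``: (m, n) dosages with NaN for missing.  Entries are NaN when a
    pair shares < 3 calls or either member is constant on the shared set.
    The diagonal is 1 for non-constant variants.
    """
    x = np.asarray(values, dtype=np.float64)
    mask = np.isfinite(x).astype(np.float64)
    x0 = np.where(np.isfinite(x), x, 0.0)
    n_shared = mask @ mask.T
    sx = x0 @ mask.T  # sx[i,j] = sum of x_i over pair (i,j) support
    sxy = x0 @ x0.T
    sxx = (x0 * x0) @ mask.T
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sx.T / n_shared
        var_i = sxx - sx * sx / n_shared  # var of row variant on pair support
        var_j = var_i.T
        r2 = (cov * cov) / (var_i * var_j)
    bad = (n_shared < MIN_SHARED_CALLS) | (var_i <= 0) | (var_j <= 0)
    r2[bad] = np.nan
    return np.clip(r2, 0.0, 1.0, out=r2)


def r2_to_lead(values: np.ndarray, lead_row: int) -> np.ndarray:
    """r² of every row variant against one lead row (complete cases)."""
    x = np.asarray(values, dtype=np.float64)
    return np.array([genotype_r2(x[lead_row], x[i]) for i in range(x.shape[0])])


def chromosome_pairs(
    dosages: DosageMatrix, chrom: str, min_r2: float = 0.5
) -> list[LDPair]:
    """Every within-chromosome variant pair with r² >= ``min_r2`` (exact)."""
    on = np.flatnonzero(dosages.chrom.astype(str) == str(chrom))
    if len(on) == 0:
        raise KeyError(f"chromosome {chrom!r} not present")
    if len(on) < 2:
        return []
    sub = dosages.values[on]
    pos = dosages.pos[on]
    r2 = pairwise_r2(sub)
    ii, jj = np.triu_indices(len(on), k=1)
    keep = np.isfinite(r2[ii, jj]) & (r2[ii, jj] >= min_r2)
    pairs = []
    for i, j in zip(ii[keep], jj[keep]):
        a, b = (i, j) if pos[i] <= pos[j] else (j, i)
        pairs.append(
            LDPair(
                chrom=str(chrom),
                idx_a=int(on[a]),
                idx_b=int(on[b]),
                pos_a=int(pos[a]),
                pos_b=int(pos[b]),
                r2=float(r2[i, j]),
            )
        )
    pairs.sort(key=lambda p: (p.pos_a, p.pos_b))
    return pairs


def block_around_lead(
    dosages: DosageMatrix, lead_idx: int, min_r2: float = 0.3
) -> LDBlock:
    """All same-chromosome variants with r² to the lead >= ``min_r2``.

    The lead is always a member.  Raises if the lead is monomorphic (its r²
    is undefined against everything).
    """
    chrom = str(dosages.chrom[lead_idx])
    on = np.flatnonzero(dosages.chrom.astype(str) == chrom)
    lead_vec = dosages.values[lead_idx]
    finite = lead_vec[np.isfinite(lead_vec)]
    if finite.size == 0 or np.all(finite == finite[0]):
        raise ValueError(f"lead variant {chrom}:{dosages.pos[lead_idx]} is monomorphic")
    members = [int(lead_idx)]
    for i in on:
        if i == lead_idx:
            continue
        r2 = genotype_r2(lead_vec, dosages.values[i])
        if np.isfinite(r2) and r2 >= min_r2:
            members.append(int(i))
    members.sort(key=lambda i: int(dosages.pos[i]))
    return LDBlock(
        chrom=chrom,
        lead_idx=int(lead_idx),
        lead_pos=int(dosages.pos[lead_idx]),
        member_idx=tuple(members),
        member_pos=tuple(int(dosages.pos[i]) for i in members),
        min_r2=min_r2,
    )


def longrange_track(
    pairs: list[LDPair],
    chrom: str,
    chrom_length: int,
    window: int = 1_000_000,
    min_dist: int = 100_000,
) -> pd.DataFrame:
    """Count, per tiling window, distinct variants with a long-range partner.

    A variant contributes to its window when it has >= 1 partner at distance
    >= ``min_dist`` (variants are counted, not pairs).  Output columns:
    chrom, start (1-based), end (inclusive), count, log10_count
    (log10(count+1), the +1 offset handles empty windows).
    """
    positions: set[int] = set()
    for p in pairs:
        if p.chrom != str(chrom):
            continue
        if p.distance >= min_dist:
            positions.add(p.pos_a)
            positions.add(p.pos_b)
    starts = np.arange(1, max(int(chrom_length), 1) + 1, window)
    counts = np.zeros(len(starts), dtype=np.int64)
    for pos in positions:
        w = (pos - 1) // window
        if 0 <= w < len(starts):
            counts[w] += 1
    ends = np.minimum(starts + window - 1, int(chrom_length))
    return pd.DataFrame(
        {
            "chrom": str(chrom),
            "start": starts,
            "end": ends,
            "count": counts,
            "log10_count": np.log10(counts + 1.0),
        }
    )
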