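"""The three successive variant filters: basic, allele balance, LD prune.

Order matters and is fixed (basic -> balance -> prune); each filter is
idempotent.  Thresholds default to the study-standard values: MAF >= 0.05,
missingness <= 10%, balance ratio >= 0.2, and LD pruning at r² 0.4 in 20-kbp
windows keeping at most two linked variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ld_stats import pairwise_r2
from .variant_io import GT_HET, GT_MISSING, VariantTable, site_summaries, to_dosages

__all__ = [
    "FilterReport",
    "basic_filter",
    "allele_balance_filter",
    "ld_prune",
    "run_filter_chain",
]

RULES = (
    "non_biallelic",
    "indel",
    "failed_filter",
    "missingness",
    "maf",
    "allele_balance",
    "ld_prune",
)


@dataclass
class FilterReport:
    """Bookkeeping for one filter stage: counts must conserve."""

    stage: str
    n_input: int
    n_output: int
    removed: dict[str, int] = field(default_factory=dict)
    removed_ids: list[str] = field(default_factory=list)
    notes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.removed.values())
        if self.n_output + total != self.n_input:
            raise ValueError(
                f"{self.stage}: {self.n_output} kept + {total} removed != {self.n_input} input"
            )
        if any(v < 0 for v in self.removed.values()):
            raise ValueError("negative removal count")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"stage": self.stage, "rule": "input", "count": self.n_input}]
        for rule in RULES:
            if rule in self.removed:
                rows.append({"stage": self.stage, "rule": rule, "count": self.removed[rule]})
        for k, v in self.notes.items():
            rows.append({"stage": self.stage, "rule": f"note:{k}", "count": v})
        rows.append({"stage": self.stage, "rule": "output", "count": self.n_output})
        return pd.DataFrame(rows)


def basic_filter(
    vt: VariantTable, maf_min: float = 0.05, max_missing_frac: float = 0.10
) -> tuple[VariantTable, FilterReport]:
    """Keep biallelic SNPs with FILTER PASS/'.', call rate >= 1-max_missing,
    and MAF >= maf_min.  A variant failing several rules is charged to the
    first failing rule in the order non_biallelic, indel, failed_filter,
    missingness, maf."""
    n = vt.n_variants
    biallelic = vt.is_biallelic()
    snp = vt.is_snp()
    pass_filt = np.array([f in ("PASS", ".") for f in vt.filter_status], dtype=bool)
    summ = site_summaries(vt)
    n_missing = vt.n_samples - summ["n_called"].to_numpy()
    miss_ok = n_missing <= max_missing_frac * vt.n_samples + 1e-9
    maf = summ["maf"].to_numpy()
    maf_ok = summ["maf_defined"].to_numpy() & (maf >= maf_min - 1e-12)

    reason = np.full(n, "", dtype=object)
    reason[~maf_ok] = "maf"
    reason[~miss_ok] = "missingness"
    reason[~pass_filt] = "failed_filter"
    reason[biallelic & ~snp] = "indel"
    reason[~biallelic] = "non_biallelic"
    keep = reason == ""

    removed = {r: int((reason == r).sum()) for r in RULES if (reason == r).any()}
    ids = vt.variant_ids()
    report = FilterReport(
        stage="basic",
        n_input=n,
        n_output=int(keep.sum()),
        removed=removed,
        removed_ids=[ids[i] for i in np.flatnonzero(~keep)],
    )
    return vt.subset(keep), report


def allele_balance_filter(
    vt: VariantTable, min_ratio: float = 0.2
) -> tuple[VariantTable, FilterReport]:
    """Remove a variant when ANY heterozygous call shows allelic imbalance.

    The balance ratio is min(AD)/max(AD) per het call; ratios < ``min_ratio``
    trigger removal of the whole variant.  Het calls without AD, or with
    AD=(0,0), are uninformative: logged, never a removal trigger.  The rule
    deliberately ignores homozygous calls.
    """
    code = vt.gt_code
    het = code == GT_HET
    ad = vt.ad.astype(np.float64)
    has_ad = (vt.ad[:, :, 0] >= 0) & (vt.ad[:, :, 1] >= 0)
    informative = het & has_ad & (vt.ad.max(axis=2) > 0)
    lo = np.minimum(ad[:, :, 0], ad[:, :, 1])
    hi = np.maximum(ad[:, :, 0], ad[:, :, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(informative, lo / hi, np.nan)
    fails = np.nansum(np.where(rho < min_ratio, 1, 0), axis=1) > 0
    skipped_no_ad = int((het & ~has_ad).sum())
    uninformative = int((het & has_ad & (vt.ad.max(axis=2) == 0)).sum())

    keep = ~fails
    ids = vt.variant_ids()
    report = FilterReport(
        stage="allele_balance",
        n_input=vt.n_variants,
        n_output=int(keep.sum()),
        removed={"allele_balance": int(fails.sum())} if fails.any() else {},
        removed_ids=[ids[i] for i in np.flatnonzero(fails)],
        notes={"het_calls_without_ad": skipped_no_ad, "het_calls_ad_zero": uninformative},
    )
    return vt.subset(keep), report


def _prune_window(
    r2: np.ndarray, maf: np.ndarray, pos: np.ndarray, r2_thresh: float, max_linked: int
) -> list[int]:
    """Greedy removal inside one window; returns local indices removed.

    While any variant has >= max_linked partners at r² >= threshold, drop
    the highest-degree variant; ties broken by lower MAF, then by larger
    position.
    """
    k = len(pos)
    adj = np.zeros((k, k), dtype=bool)
    with np.errstate(invalid="ignore"):
        adj = np.isfinite(r2) & (r2 >= r2_thresh)
    np.fill_diagonal(adj, False)
    alive = np.ones(k, dtype=bool)
    removed: list[int] = []
    while True:
        deg = (adj & alive[None, :] & alive[:, None]).sum(axis=1)
        deg[~alive] = -1
        if deg.max(initial=-1) < max_linked:
            break
        cand = np.flatnonzero(deg == deg.max())
        # lower MAF first, then larger position
        order = sorted(cand, key=lambda i: (maf[i], -pos[i]))
        victim = order[0]
        alive[victim] = False
        removed.append(int(victim))
    return removed


def ld_prune(
    vt: VariantTable,
    window_bp: int = 20_000,
    r2_thresh: float = 0.4,
    max_linked: int = 2,
) -> tuple[VariantTable, FilterReport]:
    """Thin high-LD variants: in any 20-kbp span at most ``max_linked``
    variants remain that are pairwise in LD at r² >= ``r2_thresh``.

    A 20-kbp window slides left-to-right (anchored at each surviving
    variant); within the active window the graph of high-LD pairs is built
    and, while any variant has >= max_linked high-LD partners, the variant
    with the highest degree is removed (ties: lower MAF, then larger
    position).  This emulates the cited pruning plugin; it is not claimed to
    be a bit-exact clone.
    """
    n = vt.n_variants
    if n == 0:
        return vt, FilterReport(stage="ld_prune", n_input=0, n_output=0)
    dosages = to_dosages(vt)
    maf = site_summaries(vt)["maf"].to_numpy()
    alive = np.ones(n, dtype=bool)
    order = np.lexsort((vt.pos, vt.chrom.astype(str)))
    # per-chromosome contiguous runs in sorted order
    sorted_chrom = vt.chrom[order].astype(str)
    sorted_pos = vt.pos[order]
    for start in range(n):
        i = order[start]
        if not alive[i]:
            continue
        c = sorted_chrom[start]
        lo_pos = sorted_pos[start]
        window_local = [start]
        for j in range(start + 1, n):
            if sorted_chrom[j] != c or sorted_pos[j] > lo_pos + window_bp:
                break
            window_local.append(j)
        members = [order[j] for j in window_local if alive[order[j]]]
        if len(members) <= max_linked:
            continue
        sub = dosages.values[members]
        r2 = pairwise_r2(sub)
        removed_local = _prune_window(
            r2,
            maf[members],
            vt.pos[np.array(members)],
            r2_thresh,
            max_linked,
        )
        for li in removed_local:
            alive[members[li]] = False
    ids = vt.variant_ids()
    n_removed = int((~alive).sum())
    report = FilterReport(
        stage="ld_prune",
        n_input=n,
        n_output=int(alive.sum()),
        removed={"ld_prune": n_removed} if n_removed else {},
        removed_ids=[ids[i] for i in np.flatnonzero(~alive)],
    )
    return vt.subset(alive), report


def run_filter_chain(
    vt: VariantTable,
    maf_min: float = 0.05,
    max_missing_frac: float = 0.10,
    balance_min_ratio: float = 0.2,
    prune_window_bp: int = 20_000,
    prune_r2: float = 0.4,
    prune_max_linked: int = 2,
    stages: tuple[str, ...] = ("basic", "balance", "prune"),
) -> tuple[dict[str, VariantTable], list[FilterReport]]:
    """Apply the filter chain in study order, returning every intermediate."""
    out: dict[str, VariantTable] = {"input": vt}
    reports: list[FilterReport] = []
    current = vt
    for stage in stages:
        if stage == "basic":
            current, rep = basic_filter(current, maf_min, max_missing_frac)
        elif stage == "balance":
            current, rep = allele_balance_filter(current, balance_min_ratio)
        elif stage == "prune":
            current, rep = ld_prune(current, prune_window_bp, prune_r2, prune_max_linked)
        else:
            raise ValueError(f"unknown filter stage {stage!r}")
        out[stage] = current
        reports.append(rep)
    return out, reports
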