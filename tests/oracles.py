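"""Independent reference implementations used as test oracles.

Everything here is deliberately written from first principles (or delegates
to an unrelated library routine) and stays independent of the package code
paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def weir_cockerham_fst(genotypes: np.ndarray, labels: np.ndarray) -> float:
    """Multi-population Weir & Cockerham (1984) theta from diploid dosages.

    ``genotypes``: (loci, individuals) dosages in {0,1,2}, NaN = missing.
    Ratio-of-averages estimator: theta = sum(a) / sum(a+b+c) over loci.
    """
    g = np.asarray(genotypes, dtype=float)
    labels = np.asarray(labels)
    pops = np.unique(labels)
    r = len(pops)
    num = 0.0
    den = 0.0
    for locus in g:
        n_i, p_i, h_i = [], [], []
        for k in pops:
            sub = locus[labels == k]
            sub = sub[np.isfinite(sub)]
            if len(sub) == 0:
                break
            n_i.append(len(sub))
            p_i.append(sub.sum() / (2 * len(sub)))
            h_i.append((sub == 1).mean())
        else:
            n_i = np.array(n_i, dtype=float)
            p_i = np.array(p_i)
            h_i = np.array(h_i)
            n_bar = n_i.mean()
            if n_bar <= 1:
                continue
            n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)
            p_bar = (n_i * p_i).sum() / (r * n_bar)
            s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
            h_bar = (n_i * h_i).sum() / (r * n_bar)
            pq = p_bar * (1 - p_bar)
            a = (n_bar / n_c) * (
                s2 - (pq - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
            )
            b = (n_bar / (n_bar - 1)) * (
                pq - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
            )
            c = h_bar / 2
            num += a
            den += a + b + c
    return num / den


def per_locus_fst(genotypes: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-locus W&C theta (a/(a+b+c)); NaN where undefined."""
    out = np.empty(genotypes.shape[0])
    for i in range(genotypes.shape[0]):
        row = genotypes[i : i + 1]
        try:
            out[i] = weir_cockerham_fst(row, labels)
        except ZeroDivisionError:
            out[i] = np.nan
    return out


def ols_slope_test(x: np.ndarray, y: np.ndarray):
    """Two-pass textbook OLS of y ~ a + b*x: returns (beta, se, chi2, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    xb, yb = x.mean(), y.mean()
    sxx = ((x - xb) ** 2).sum()
    beta = ((x - xb) * (y - yb)).sum() / sxx
    alpha = yb - beta * xb
    resid = y - alpha - beta * x
    sigma2 = (resid**2).sum() / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    chi2 = (beta / se) ** 2
    return beta, se, chi2, stats.chi2.sf(chi2, df=1)


def pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation over complete cases via scipy."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    r, _ = stats.pearsonr(x[ok], y[ok])
    return r * r


def brute_force_prune(
    chrom: np.ndarray,
    pos: np.ndarray,
    dosages: np.ndarray,
    maf: np.ndarray,
    window_bp: int,
    r2_thresh: float,
    max_linked: int,
) -> np.ndarray:
    """Literal application of the documented pruning rule.

    Slide a window anchored at each surviving variant left-to-right (in
    (chrom, pos) order); within the window repeatedly drop the variant with
    the most partners at r² >= threshold (ties: lower MAF, then larger
    position) while any variant has >= max_linked partners.  Returns a
    boolean keep mask.
    """
    n = len(pos)
    order = sorted(range(n), key=lambda i: (str(chrom[i]), int(pos[i])))
    alive = np.ones(n, dtype=bool)
    for a_rank, i in enumerate(order):
        if not alive[i]:
            continue
        window = [
            j
            for j in order[a_rank:]
            if alive[j]
            and str(chrom[j]) == str(chrom[i])
            and int(pos[j]) <= int(pos[i]) + window_bp
        ]
        while True:
            degree = {}
            for a in window:
                if not alive[a]:
                    continue
                d = 0
                for b in window:
                    if b == a or not alive[b]:
                        continue
                    r2 = pearson_r2(dosages[a], dosages[b])
                    if np.isfinite(r2) and r2 >= r2_thresh:
                        d += 1
                degree[a] = d
            hot = [a for a, d in degree.items() if d >= max_linked]
            if not hot:
                break
            top = max(degree[a] for a in hot)
            cands = [a for a in degree if degree[a] == top]
            cands.sort(key=lambda a: (maf[a], -int(pos[a])))
            alive[cands[0]] = False
    return alive


def maximal_chains(
    chrom: np.ndarray, pos: np.ndarray, sig_idx: np.ndarray, max_gap: int
) -> list[list[int]]:
    """Enumerate maximal chains of significant variants by splitting the
    sorted list at chromosome changes and gaps > max_gap."""
    items = sorted(
        (str(chrom[i]), int(pos[i]), int(i)) for i in np.asarray(sig_idx, dtype=int)
    )
    chains: list[list[int]] = []
    for c, p, i in items:
        if (
            chains
            and str(chrom[chains[-1][-1]]) == c
            and p - int(pos[chains[-1][-1]]) <= max_gap
        ):
            chains[-1].append(i)
        else:
            chains.append([i])
    return chains


def adjusted_rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """ARI from the contingency table (independent of sklearn)."""
    a = np.asarray(a)
    b = np.asarray(b)
    ua, ub = np.unique(a), np.unique(b)
    table = np.array([[(np.logical_and(a == x, b == y)).sum() for y in ub] for x in ua])
    comb = lambda x: x * (x - 1) / 2.0
    sum_ij = comb(table).sum()
    sum_a = comb(table.sum(axis=1)).sum()
    sum_b = comb(table.sum(axis=0)).sum()
    n = comb(len(a))
    expected = sum_a * sum_b / n
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)
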