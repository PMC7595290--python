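from __future__ import annotations

import numpy as np
import pytest

from nerkascan.variant_io import VariantTable

N_TOY_SAMPLES = 140


def make_table(samples: list[str], rows: list[dict]) -> VariantTable:
    """Build a VariantTable from compact per-variant dicts.

    Each row: chrom, pos, ref, alt (tuple), filter (default PASS),
    codes (length n: 0/1/2/-1), optional ad overrides {sample_idx: (r, a)}.
    Default AD: hom ref (50,0), het (25,25), hom alt (0,50), missing unset.
    """
    n = len(samples)
    m = len(rows)
    chrom = np.array([r["chrom"] for r in rows], dtype=object)
    pos = np.array([r["pos"] for r in rows], dtype=np.int64)
    ref = np.array([r.get("ref", "A") for r in rows], dtype=object)
    alt = [tuple(r.get("alt", ("T",))) for r in rows]
    filt = np.array([r.get("filter", "PASS") for r in rows], dtype=object)
    gt = np.empty((m, n, 2), dtype=np.int8)
    ad = np.empty((m, n, 2), dtype=np.int32)
    dp = np.empty((m, n), dtype=np.int32)
    pair = {0: (0, 0), 1: (0, 1), 2: (1, 1), -1: (-1, -1)}
    default_ad = {0: (50, 0), 1: (25, 25), 2: (0, 50), -1: (-1, -1)}
    for i, r in enumerate(rows):
        codes = r["codes"]
        assert len(codes) == n
        for j, code in enumerate(codes):
            gt[i, j] = pair[code]
            ad[i, j] = default_ad[code]
            dp[i, j] = -1 if code == -1 else sum(default_ad[code])
        for j, (rd, al) in r.get("ad", {}).items():
            ad[i, j] = (rd, al)
            dp[i, j] = rd + al
    return VariantTable(
        samples=list(samples),
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        filter_status=filt,
        gt_alleles=gt,
        ad=ad,
        dp=dp,
    )


def codes(n: int, het: int = 0, hom_alt: int = 0, missing: int = 0) -> list[int]:
    """A genotype-code vector: first hets, then alt homs, then missing,
    padded with hom ref."""
    out = [1] * het + [2] * hom_alt + [-1] * missing
    out += [0] * (n - len(out))
    return out


@pytest.fixture(scope="session")
def toy_samples() -> list[str]:
    return [f"S{i:03d}" for i in range(N_TOY_SAMPLES)]


@pytest.fixture(scope="session")
def toy_table(toy_samples) -> VariantTable:
    """The hand-enumerable 12-variant toy cohort (140 samples).

    Expected survivors: basic drops v1-v5; balance drops v7; prune drops the
    largest-position member of the identical triple (v11 at 244000).
    """
    n = N_TOY_SAMPLES
    triple = codes(n, het=40, hom_alt=10)
    rows = [
        # v1: non-biallelic
        {"chrom": "chr1", "pos": 1_000, "alt": ("T", "G"), "codes": codes(n, het=30)},
        # v2: indel
        {"chrom": "chr1", "pos": 30_000, "ref": "AT", "alt": ("A",), "codes": codes(n, het=30)},
        # v3: failed GATK-style filter
        {"chrom": "chr1", "pos": 60_000, "filter": "q10", "codes": codes(n, het=30)},
        # v4: MAF 11/280 ~ 0.039 < 0.05
        {"chrom": "chr1", "pos": 90_000, "codes": codes(n, het=11)},
        # v5: 15 missing -> call rate 125/140 ~ 0.893 < 0.9
        {"chrom": "chr1", "pos": 120_000, "codes": codes(n, het=30, missing=15)},
        # v6: 14 missing -> call rate exactly 0.9, kept
        {"chrom": "chr1", "pos": 150_000, "codes": codes(n, het=30, missing=14)},
        # v7: one het with AD=(9,51): ratio 0.176 < 0.2 -> balance removal
        {"chrom": "chr1", "pos": 180_000, "codes": codes(n, het=30), "ad": {0: (9, 51)}},
        # v8: hets at AD=(10,40): ratio 0.25 -> kept
        {
            "chrom": "chr1",
            "pos": 210_000,
            "codes": codes(n, het=30),
            "ad": {j: (10, 40) for j in range(30)},
        },
        # v9-v11: identical genotypes (r2=1) within 5 kbp -> prune keeps 2
        {"chrom": "chr1", "pos": 240_000, "codes": triple},
        {"chrom": "chr1", "pos": 242_000, "codes": triple},
        {"chrom": "chr1", "pos": 244_000, "codes": triple},
        # v12: plain biallelic SNP, kept
        {"chrom": "chr1", "pos": 300_000, "codes": codes(n, het=28, hom_alt=14)},
    ]
    return make_table(toy_samples, rows)


def random_biallelic_table(rng: np.random.Generator, m: int, n: int, chroms=("chr1",)):
    """Random biallelic SNP table for property tests."""
    rows = []
    pos_used: dict[str, set] = {c: set() for c in chroms}
    for _ in range(m):
        c = str(rng.choice(list(chroms)))
        while True:
            p = int(rng.integers(1, 10_000_000))
            if p not in pos_used[c]:
                pos_used[c].add(p)
                break
        freqs = rng.uniform(0.05, 0.95)
        code = rng.binomial(2, freqs, size=n).astype(int)
        miss = rng.random(n) < 0.05
        code[miss] = -1
        rows.append({"chrom": c, "pos": p, "codes": list(code)})
    rows.sort(key=lambda r: (r["chrom"], r["pos"]))
    return make_table([f"S{i:03d}" for i in range(n)], rows)
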