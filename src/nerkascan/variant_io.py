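"""VCF and tabular I/O, plus genotype-to-dosage conversion.

The in-memory representation is a :class:`VariantTable`: per-record allele
metadata as object arrays plus dense per-sample genotype / allele-depth /
depth arrays.  Genotypes are stored as allele-index pairs so that
multiallelic records survive a read/write round trip; a derived diploid code
(hom-ref / het / hom-alt / missing) is what the analysis layers consume.

Coordinates are 1-based and inclusive throughout, following the VCF
convention.  Phase separators are accepted on input but everything is
treated (and re-written) as unphased.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GT_HOM_REF",
    "GT_HET",
    "GT_HOM_ALT",
    "GT_MISSING",
    "GenotypeCall",
    "VariantRecord",
    "VariantTable",
    "DosageMatrix",
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "to_dosages",
    "site_summaries",
    "read_table",
    "write_table",
]

# diploid genotype codes
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2
GT_MISSING = -1

_GT_NAMES = {GT_HOM_REF: "hom_ref", GT_HET: "het", GT_HOM_ALT: "hom_alt", GT_MISSING: "missing"}


class VcfParseError(ValueError):
    """Raised on malformed VCF input; message carries file context."""


@dataclass(frozen=True)
class GenotypeCall:
    """One diploid genotype with optional read evidence.

    ``ad`` is (ref_count, alt_count); ``dp`` the total read depth.  Both are
    ``None`` when the VCF did not carry them.
    """

    gt: int
    ad: tuple[int, int] | None = None
    dp: int | None = None

    def __post_init__(self) -> None:
        if self.gt not in _GT_NAMES:
            raise ValueError(f"unknown genotype code {self.gt}")
        if self.ad is not None and (self.ad[0] < 0 or self.ad[1] < 0):
            raise ValueError("allele depths must be non-negative")
        if self.dp is not None and self.dp < 0:
            raise ValueError("depth must be non-negative")

    @property
    def gt_name(self) -> str:
        return _GT_NAMES[self.gt]

    @property
    def is_missing(self) -> bool:
        return self.gt == GT_MISSING

    @property
    def balance_ratio(self) -> float | None:
        """min(AD)/max(AD), or None when AD is absent or uninformative (0,0)."""
        if self.ad is None:
            return None
        lo, hi = min(self.ad), max(self.ad)
        if hi == 0:
            return None
        return lo / hi


@dataclass(frozen=True)
class VariantRecord:
    """A single site with per-sample calls (view onto a VariantTable row)."""

    chrom: str
    pos: int
    ref: str
    alt: tuple[str, ...]
    filter_status: str
    calls: tuple[GenotypeCall, ...]

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt) == 1

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alt)


@dataclass
class VariantTable:
    """Position-sorted variants for one cohort.

    Arrays are parallel over variants (axis 0) and samples (axis 1):

    - ``gt_alleles``: (n_var, n_samples, 2) int8 allele indices, -1 = missing
    - ``ad``: (n_var, n_samples, 2) int32 (ref, alt) depths, -1 = unset
    - ``dp``: (n_var, n_samples) int32 depth, -1 = unset
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: list[tuple[str, ...]]
    filter_status: np.ndarray
    gt_alleles: np.ndarray
    ad: np.ndarray
    dp: np.ndarray
    _gt_code: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def gt_code(self) -> np.ndarray:
        """(n_var, n_samples) int8 diploid code; multiallelic alts collapse to 'alt'."""
        if self._gt_code is None:
            a = self.gt_alleles
            missing = (a < 0).any(axis=2)
            n_alt = (a > 0).sum(axis=2, dtype=np.int8)
            code = n_alt.copy()
            # two different non-ref alleles (e.g. 1/2) still count as het=1? No:
            # both non-ref -> hom_alt bucket unless alleles differ, then het.
            both_alt = (a[:, :, 0] > 0) & (a[:, :, 1] > 0)
            differ = a[:, :, 0] != a[:, :, 1]
            code[both_alt & differ] = GT_HET
            code[both_alt & ~differ] = GT_HOM_ALT
            code[missing] = GT_MISSING
            self._gt_code = code.astype(np.int8)
        return self._gt_code

    def record(self, i: int) -> VariantRecord:
        calls = []
        for j in range(self.n_samples):
            ad = None
            if self.ad[i, j, 0] >= 0 or self.ad[i, j, 1] >= 0:
                ad = (int(max(self.ad[i, j, 0], 0)), int(max(self.ad[i, j, 1], 0)))
            dp = int(self.dp[i, j]) if self.dp[i, j] >= 0 else None
            calls.append(GenotypeCall(int(self.gt_code[i, j]), ad=ad, dp=dp))
        return VariantRecord(
            chrom=str(self.chrom[i]),
            pos=int(self.pos[i]),
            ref=str(self.ref[i]),
            alt=tuple(self.alt[i]),
            filter_status=str(self.filter_status[i]),
            calls=tuple(calls),
        )

    def subset(self, rows: np.ndarray | Sequence[int]) -> "VariantTable":
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return VariantTable(
            samples=list(self.samples),
            chrom=self.chrom[rows],
            pos=self.pos[rows],
            ref=self.ref[rows],
            alt=[self.alt[int(r)] for r in rows],
            filter_status=self.filter_status[rows],
            gt_alleles=self.gt_alleles[rows],
            ad=self.ad[rows],
            dp=self.dp[rows],
        )

    def variant_ids(self) -> list[str]:
        return [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)]

    def is_biallelic(self) -> np.ndarray:
        return np.array([len(a) == 1 for a in self.alt], dtype=bool)

    def is_snp(self) -> np.ndarray:
        return np.array(
            [len(r) == 1 and all(len(x) == 1 for x in a) for r, a in zip(self.ref, self.alt)],
            dtype=bool,
        )

    def sort(self) -> "VariantTable":
        order = np.lexsort((self.pos, self.chrom))
        return self.subset(order)


@dataclass
class DosageMatrix:
    """Alternate-allele dosage, variants x samples; NaN marks missing calls.

    Missing entries are never imputed here — downstream consumers decide.
    """

    values: np.ndarray  # float64 (n_var, n_samples) in {0,1,2,NaN}
    chrom: np.ndarray
    pos: np.ndarray
    samples: list[str]
    source_rows: np.ndarray  # row index into the originating VariantTable

    @property
    def n_variants(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# reading


def _open_text(path) -> io.TextIOBase:
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def read_vcf(path) -> VariantTable:
    """Load a VCF v4.x file (plain or gzipped) into a :class:`VariantTable`.

    GT is required; AD and DP are picked up when present.  ``./.`` and ``.``
    genotypes become missing.  The FILTER column is retained verbatim.
    Non-diploid genotypes raise :class:`VcfParseError` naming the line.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise VcfParseError(f"{path}: malformed VCF header ({exc})") from exc

    samples = list(vcf.samples)
    n = len(samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[tuple[str, ...]] = []
    filts: list[str] = []
    gt_rows: list[np.ndarray] = []
    ad_rows: list[np.ndarray] = []
    dp_rows: list[np.ndarray] = []

    # count header lines so errors can name a 1-based file line
    header_lines = str(vcf.raw_header).count("\n")

    for k, rec in enumerate(vcf):
        line_no = header_lines + 1 + k
        g = np.asarray(rec.genotype.array(), dtype=np.int64)
        if g.shape[1] != 3:  # two alleles + phase flag
            raise VcfParseError(
                f"{path}: line {line_no} ({rec.CHROM}:{rec.POS}): ploidy != 2"
            )
        alleles = g[:, :2].astype(np.int8)
        ad = np.full((n, 2), -1, dtype=np.int32)
        try:
            raw_ad = rec.format("AD")
        except KeyError:
            raw_ad = None
        if raw_ad is not None:
            raw_ad = np.asarray(raw_ad)
            cols = min(2, raw_ad.shape[1])
            vals = raw_ad[:, :cols].astype(np.int64)
            vals[vals < 0] = -1  # cyvcf2 encodes '.' as a negative sentinel
            ad[:, :cols] = vals.astype(np.int32)
            unset = (ad < 0).any(axis=1)
            ad[unset] = -1
        dp = np.full(n, -1, dtype=np.int32)
        try:
            raw_dp = rec.format("DP")
        except KeyError:
            raw_dp = None
        if raw_dp is not None:
            vals = np.asarray(raw_dp).reshape(n, -1)[:, 0].astype(np.int64)
            vals[vals < 0] = -1
            dp = vals.astype(np.int32)

        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(tuple(rec.ALT) if rec.ALT else ())
        filts.append(rec.FILTER if rec.FILTER is not None else "PASS")
        gt_rows.append(alleles)
        ad_rows.append(ad)
        dp_rows.append(dp)
    vcf.close()

    m = len(poss)
    return VariantTable(
        samples=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=alts,
        filter_status=np.array(filts, dtype=object),
        gt_alleles=(
            np.stack(gt_rows) if m else np.empty((0, n, 2), dtype=np.int8)
        ),
        ad=np.stack(ad_rows) if m else np.empty((0, n, 2), dtype=np.int32),
        dp=np.stack(dp_rows) if m else np.empty((0, n), dtype=np.int32),
    )


# ---------------------------------------------------------------------------
# writing


def write_vcf(vt: VariantTable, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a VariantTable as VCF v4.2 (gzipped when path ends in .gz).

    Genotypes are emitted unphased; AD/DP are written as '.' when unset.
    """
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    lengths: dict[str, int] = {}
    for c, p in zip(vt.chrom, vt.pos):
        lengths[str(c)] = max(lengths.get(str(c), 0), int(p))
    if contig_lengths:
        lengths.update({str(k): int(v) for k, v in contig_lengths.items()})

    extra_filters = sorted(
        {str(f) for f in vt.filter_status if str(f) not in ("PASS", ".")}
    )
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=nerkascan\n")
        for c, ln in lengths.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        for f in extra_filters:
            fh.write(f'##FILTER=<ID={f},Description="{f}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(vt.samples)
            + "\n"
        )
        for i in range(vt.n_variants):
            alt_field = ",".join(vt.alt[i]) if vt.alt[i] else "."
            cells = []
            for j in range(vt.n_samples):
                a, b = vt.gt_alleles[i, j]
                gt = "./." if a < 0 or b < 0 else f"{a}/{b}"
                if vt.ad[i, j, 0] >= 0:
                    ad = f"{vt.ad[i, j, 0]},{vt.ad[i, j, 1]}"
                else:
                    ad = "."
                dp = str(vt.dp[i, j]) if vt.dp[i, j] >= 0 else "."
                cells.append(f"{gt}:{ad}:{dp}")
            fh.write(
                f"{vt.chrom[i]}\t{vt.pos[i]}\t.\t{vt.ref[i]}\t{alt_field}\t.\t"
                f"{vt.filter_status[i]}\t.\tGT:AD:DP\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# conversion & summaries


def to_dosages(vt: VariantTable) -> DosageMatrix:
    """Convert biallelic genotypes to alternate-allele dosages {0,1,2,NaN}.

    Raises ``ValueError`` if any record is multiallelic; run the basic filter
    first.
    """
    bi = vt.is_biallelic()
    if not bi.all():
        bad = int(np.flatnonzero(~bi)[0])
        raise ValueError(
            f"multiallelic record at {vt.chrom[bad]}:{vt.pos[bad]}; "
            "filter to biallelic sites before dosage conversion"
        )
    code = vt.gt_code.astype(np.float64)
    code[code == GT_MISSING] = np.nan
    return DosageMatrix(
        values=code,
        chrom=vt.chrom.copy(),
        pos=vt.pos.copy(),
        samples=list(vt.samples),
        source_rows=np.arange(vt.n_variants),
    )


def site_summaries(vt: VariantTable) -> pd.DataFrame:
    """Per-variant call rate and minor allele frequency.

    MAF is computed over called genotypes only.  Sites with zero called
    genotypes get call_rate 0 and NaN MAF with ``maf_defined`` False.
    """
    code = vt.gt_code
    called = code != GT_MISSING
    n_called = called.sum(axis=1)
    call_rate = n_called / max(vt.n_samples, 1)
    alt_dose = np.where(called, code, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_alt = np.where(n_called > 0, alt_dose / (2.0 * n_called), np.nan)
    maf = np.minimum(f_alt, 1.0 - f_alt)
    return pd.DataFrame(
        {
            "chrom": vt.chrom.astype(str),
            "pos": vt.pos,
            "n_called": n_called,
            "call_rate": call_rate,
            "f_alt": f_alt,
            "maf": maf,
            "maf_defined": n_called > 0,
        }
    )


# ---------------------------------------------------------------------------
# tabular helpers (trait / covariate / sample-sheet TSVs)


def read_table(path, index_col: str = "sample_id") -> pd.DataFrame:
    """Read a tab-separated table with a header; gzip-transparent."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t")
    if index_col in df.columns:
        df = df.set_index(index_col)
    return df


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")
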