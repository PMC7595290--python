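"""Truth-annotated multi-population genotype simulation.

Drift between populations follows the Balding–Nichols model: an ancestral
allele frequency ``p`` per locus, and per-population frequencies drawn from
``Beta(p(1-F)/F, (1-p)(1-F)/F)`` where ``F`` is the per-population drift
parameter.  On top of that baseline, features can be planted:

- ``divergent_haploblock`` — a span simulated as a rigid two-haplotype block
  (no intra-block recombination) with specified per-population haplotype
  frequencies, so within-block genotype r² is ~1 and strongly divergent
  blocks appear near-fixed between groups;
- ``artifact_site`` — individual loci whose heterozygous calls carry skewed
  allele depths (minor-read fraction 0.15), mimicking collapsed paralogs;
- ``sex_marker`` — a presence/absence marker (emitted in the sample sheet,
  not as a VCF site) carried by one sex but absent from one population's
  carriers.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .variant_io import (
    GT_MISSING,
    DosageMatrix,
    VariantTable,
    write_table,
    write_vcf,
)

__all__ = [
    "AdmixtureCline",
    "CohortDesign",
    "PlantedFeature",
    "SimulatedCohort",
    "draw_population_frequencies",
    "sample_genotypes",
    "attach_read_evidence",
    "simulate_cohort",
    "write_cohort",
]

ARTIFACT_HET_ALT_FRACTION = 0.15  # below the 0.2 balance threshold by design


@dataclass(frozen=True)
class AdmixtureCline:
    """Clinal admixture between two source populations.

    ``weights`` gives, for every individual of ``pop_a`` followed by every
    individual of ``pop_b`` (cohort order), the ancestry proportion drawn
    from ``pop_a``; locus frequencies mix as ``w*p_a + (1-w)*p_b``.
    """

    pop_a: int
    pop_b: int
    weights: tuple[float, ...]


@dataclass(frozen=True)
class CohortDesign:
    pop_sizes: tuple[int, ...]
    fst: tuple[float, ...]
    n_loci: int
    chrom_lengths: tuple[int, ...]
    mean_depth: float = 30.0
    missing_rate: float = 0.0
    admixture_cline: AdmixtureCline | None = None
    seed: int = 0
    chrom_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if sum(self.pop_sizes) < 2:
            raise ValueError("need at least 2 individuals in total")
        if len(self.fst) != len(self.pop_sizes):
            raise ValueError("one drift parameter F per population required")
        for f in self.fst:
            if not (0.0 <= f < 1.0):
                raise ValueError(f"F={f} outside [0,1); F=1 is degenerate")
        if not (0.0 <= self.missing_rate <= 0.10):
            raise ValueError("missing_rate must lie in [0, 0.10]")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not self.chrom_lengths:
            raise ValueError("at least one chromosome required")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.admixture_cline is not None:
            cl = self.admixture_cline
            npop = len(self.pop_sizes)
            if not (0 <= cl.pop_a < npop and 0 <= cl.pop_b < npop):
                raise ValueError("admixture cline population index out of range")
            expected = self.pop_sizes[cl.pop_a] + self.pop_sizes[cl.pop_b]
            if len(cl.weights) != expected:
                raise ValueError(
                    f"cline needs {expected} weights (pops {cl.pop_a}+{cl.pop_b})"
                )

    @property
    def n_pops(self) -> int:
        return len(self.pop_sizes)

    @property
    def n_individuals(self) -> int:
        return int(sum(self.pop_sizes))

    def chrom_ids(self) -> tuple[str, ...]:
        if self.chrom_names is not None:
            return self.chrom_names
        return tuple(f"chr{i + 1}" for i in range(len(self.chrom_lengths)))


@dataclass(frozen=True)
class PlantedFeature:
    """A deliberately inserted signal with recorded truth."""

    kind: str  # divergent_haploblock | artifact_site | sex_marker
    chrom: str = ""
    start: int = 0
    end: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        kinds = {"divergent_haploblock", "artifact_site", "sex_marker"}
        if self.kind not in kinds:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "divergent_haploblock":
            n = int(self.params.get("n_loci", 2))
            if n < 2:
                raise ValueError("a haploblock must span at least 2 loci")
            for p in self.params.get("pop_freqs", ()):
                if not (0.0 <= p <= 1.0):
                    raise ValueError("haploblock frequencies must be in [0,1]")
        if self.kind == "artifact_site" and self.params.get("n_loci", 1) < 1:
            raise ValueError("artifact feature needs at least one locus")


@dataclass
class SimulatedCohort:
    design: CohortDesign
    chrom: np.ndarray  # per locus
    pos: np.ndarray  # per locus, 1-based, strictly increasing per chrom
    ancestral_freqs: np.ndarray  # (n_loci,)
    pop_freqs: np.ndarray  # (n_loci, n_pops)
    genotypes: DosageMatrix  # dosages with NaN for missing
    pop_labels: np.ndarray  # (n_ind,) population index
    sex: np.ndarray  # (n_ind,) 'M'/'F'
    sdy_present: np.ndarray  # (n_ind,) 0/1
    admixture_weight: np.ndarray  # (n_ind,) NaN for non-cline individuals
    planted: list[PlantedFeature]
    truth_log: dict[int, np.ndarray]  # feature idx -> locus indices
    ad: np.ndarray | None = None  # (n_loci, n_ind, 2)
    dp: np.ndarray | None = None

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i:03d}" for i in range(self.design.n_individuals)]

    def to_variant_table(self) -> VariantTable:
        g = self.genotypes.values
        m, n = g.shape
        gt = np.empty((m, n, 2), dtype=np.int8)
        code = np.where(np.isnan(g), GT_MISSING, g).astype(np.int8)
        gt[:, :, 0] = np.where(code <= 0, np.where(code < 0, -1, 0), 1)
        gt[:, :, 1] = np.where(code < 0, -1, np.where(code == 2, 1, np.where(code == 1, 1, 0)))
        # het written as 0/1: first allele 0, second 1
        gt[:, :, 0][code == 1] = 0
        ad = self.ad if self.ad is not None else np.full((m, n, 2), -1, dtype=np.int32)
        dp = self.dp if self.dp is not None else np.full((m, n), -1, dtype=np.int32)
        return VariantTable(
            samples=self.sample_ids,
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=np.array(["A"] * m, dtype=object),
            alt=[("T",)] * m,
            filter_status=np.array(["PASS"] * m, dtype=object),
            gt_alleles=gt,
            ad=ad,
            dp=dp,
        )

    def feature_loci(self, kind: str) -> np.ndarray:
        """All locus indices of planted features of a kind, sorted."""
        out: list[np.ndarray] = []
        for idx, feat in enumerate(self.planted):
            if feat.kind == kind and idx in self.truth_log:
                out.append(self.truth_log[idx])
        if not out:
            return np.array([], dtype=np.int64)
        return np.unique(np.concatenate(out))


# ---------------------------------------------------------------------------
# locus placement


def _allocate_loci(design: CohortDesign, rng: np.random.Generator):
    """Place baseline loci on chromosomes proportional to length, then splice
    in loci demanded by planted features.  Positions strictly increase."""
    lengths = np.asarray(design.chrom_lengths, dtype=np.float64)
    share = lengths / lengths.sum()
    counts = np.floor(share * design.n_loci).astype(int)
    for k in np.argsort(-(share * design.n_loci - counts)):
        if counts.sum() >= design.n_loci:
            break
        counts[k] += 1
    while counts.sum() > design.n_loci:
        counts[int(np.argmax(counts))] -= 1
    chroms: list[str] = []
    poss: list[int] = []
    ids = design.chrom_ids()
    for ci, cnt in enumerate(counts):
        if cnt == 0:
            continue
        length = int(design.chrom_lengths[ci])
        picked: set[int] = set()
        while len(picked) < cnt:
            draw = rng.integers(1, length + 1, size=cnt - len(picked))
            picked.update(int(x) for x in draw)
        for p in sorted(picked):
            chroms.append(ids[ci])
            poss.append(p)
    return np.array(chroms, dtype=object), np.array(poss, dtype=np.int64)


def _splice_feature_loci(
    chrom: np.ndarray, pos: np.ndarray, planted: list[PlantedFeature]
) -> tuple[np.ndarray, np.ndarray, dict[int, np.ndarray]]:
    """Insert evenly spaced loci for each spanned feature; return truth map."""
    chrom_l = list(chrom)
    pos_l = [int(p) for p in pos]
    pending: dict[int, list[tuple[str, int]]] = {}
    for fi, feat in enumerate(planted):
        if feat.kind == "sex_marker":
            continue
        n = int(feat.params.get("n_loci", 2 if feat.kind == "divergent_haploblock" else 1))
        if n == 1:
            sites = [feat.start]
        else:
            sites = [
                int(round(feat.start + k * (feat.end - feat.start) / (n - 1)))
                for k in range(n)
            ]
        # keep positions unique
        uniq: list[int] = []
        for s in sites:
            while s in uniq:
                s += 1
            uniq.append(s)
        pending[fi] = [(feat.chrom, s) for s in uniq]
        for s in uniq:
            # drop any baseline locus colliding with a planted position
            for k in range(len(pos_l) - 1, -1, -1):
                if chrom_l[k] == feat.chrom and pos_l[k] == s:
                    del chrom_l[k], pos_l[k]
            chrom_l.append(feat.chrom)
            pos_l.append(s)
    chrom_a = np.array(chrom_l, dtype=object)
    pos_a = np.array(pos_l, dtype=np.int64)
    order = np.lexsort((pos_a, chrom_a.astype(str)))
    chrom_a, pos_a = chrom_a[order], pos_a[order]
    truth: dict[int, np.ndarray] = {}
    lookup = {(str(c), int(p)): i for i, (c, p) in enumerate(zip(chrom_a, pos_a))}
    for fi, sites in pending.items():
        truth[fi] = np.array(sorted(lookup[(c, p)] for c, p in sites), dtype=np.int64)
    return chrom_a, pos_a, truth


# ---------------------------------------------------------------------------
# frequencies


def draw_population_frequencies(
    design: CohortDesign,
    planted: list[PlantedFeature] | None = None,
    rng: np.random.Generator | None = None,
    chrom: np.ndarray | None = None,
    pos: np.ndarray | None = None,
    truth: dict[int, np.ndarray] | None = None,
):
    """Draw ancestral and per-population allele frequencies.

    Ancestral ``p ~ Uniform(0.05, 0.95)`` per locus; per-population
    frequencies follow Balding–Nichols drift with each population's ``F``.
    ``F=0`` populations copy ``p`` exactly.  Loci belonging to planted
    divergent haploblocks take the feature's per-population frequencies
    verbatim.

    Returns ``(chrom, pos, p, pop_freqs, truth)``.
    """
    planted = planted or []
    if rng is None:
        rng = np.random.default_rng(design.seed)
    if chrom is None or pos is None or truth is None:
        chrom, pos = _allocate_loci(design, rng)
        chrom, pos, truth = _splice_feature_loci(chrom, pos, planted)
    m = len(pos)
    p = rng.uniform(0.05, 0.95, size=m)
    pop_freqs = np.empty((m, design.n_pops))
    for k, f in enumerate(design.fst):
        if f == 0.0:
            pop_freqs[:, k] = p
        else:
            a = p * (1.0 - f) / f
            b = (1.0 - p) * (1.0 - f) / f
            pop_freqs[:, k] = rng.beta(a, b)
    for fi, feat in enumerate(planted):
        if feat.kind != "divergent_haploblock":
            continue
        freqs = feat.params.get("pop_freqs")
        if freqs is None:
            continue
        loci = truth[fi]
        for k in range(design.n_pops):
            pop_freqs[loci, k] = freqs[k]
    return chrom, pos, p, pop_freqs, truth


# ---------------------------------------------------------------------------
# genotypes


def _individual_frequencies(design: CohortDesign, pop_freqs: np.ndarray):
    """Per-individual locus frequencies and labels, honouring the cline."""
    labels = np.repeat(np.arange(design.n_pops), design.pop_sizes)
    n = design.n_individuals
    weights = np.full(n, np.nan)
    freqs = pop_freqs[:, labels]  # (m, n)
    cl = design.admixture_cline
    if cl is not None:
        idx_a = np.flatnonzero(labels == cl.pop_a)
        idx_b = np.flatnonzero(labels == cl.pop_b)
        cline_idx = np.concatenate([idx_a, idx_b])
        w = np.asarray(cl.weights, dtype=np.float64)
        weights[cline_idx] = w
        freqs = freqs.copy()
        freqs[:, cline_idx] = (
            w[None, :] * pop_freqs[:, [cl.pop_a] * len(w)]
            + (1.0 - w[None, :]) * pop_freqs[:, [cl.pop_b] * len(w)]
        )
    return freqs, labels, weights


def sample_genotypes(
    design: CohortDesign,
    pop_freqs: np.ndarray,
    planted: list[PlantedFeature],
    truth: dict[int, np.ndarray],
    rng: np.random.Generator,
    chrom: np.ndarray,
    pos: np.ndarray,
):
    """Sample dosages ``g ~ Binomial(2, p_k)`` per individual and locus.

    Haploblock loci are sampled at the block level: each individual draws two
    block haplotypes and every member locus shares the resulting dosage, so
    within-block genotype correlation is ~1.
    """
    freqs, labels, weights = _individual_frequencies(design, pop_freqs)
    m, n = freqs.shape
    g = rng.binomial(2, freqs).astype(np.float64)
    for fi, feat in enumerate(planted):
        if feat.kind != "divergent_haploblock":
            continue
        loci = truth[fi]
        block_freq = freqs[loci[0], :]  # all member loci share frequencies
        hap = rng.binomial(1, block_freq, size=(2, n)).sum(axis=0).astype(np.float64)
        g[loci, :] = hap[None, :]
    dosages = DosageMatrix(
        values=g,
        chrom=chrom,
        pos=pos,
        samples=[f"S{i:03d}" for i in range(n)],
        source_rows=np.arange(m),
    )
    return dosages, labels, weights


# ---------------------------------------------------------------------------
# read evidence


def attach_read_evidence(
    genotypes: np.ndarray,
    mean_depth: float,
    missing_rate: float,
    artifact_loci: np.ndarray,
    rng: np.random.Generator,
):
    """Simulate DP/AD per call and apply i.i.d. missingness.

    DP ~ Poisson(mean_depth), floored at 1.  Heterozygous calls draw alt
    reads Binomial(DP, 0.5) — at planted artifact loci Binomial(DP, 0.15) —
    clipped so both alleles keep at least one supporting read (a caller
    would not emit a het otherwise).  Homozygous calls carry zero reads of
    the other allele.  Missing calls get NaN dosage and unset AD/DP.

    Returns ``(genotypes_with_missing, ad, dp)``; genotypes array is a copy.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    g = np.asarray(genotypes, dtype=np.float64).copy()
    m, n = g.shape
    dp = np.maximum(rng.poisson(mean_depth, size=(m, n)), 1).astype(np.int32)
    ad = np.zeros((m, n, 2), dtype=np.int32)

    het = g == 1
    alt_frac = np.full((m, n), 0.5)
    if len(artifact_loci):
        alt_frac[artifact_loci, :] = ARTIFACT_HET_ALT_FRACTION
    alt_reads = rng.binomial(dp, alt_frac)
    alt_reads = np.clip(alt_reads, 1, np.maximum(dp - 1, 1))
    ad[:, :, 1] = np.where(het, alt_reads, 0)
    ad[:, :, 0] = np.where(het, dp - ad[:, :, 1], 0)
    hom_ref = g == 0
    hom_alt = g == 2
    ad[:, :, 0] = np.where(hom_ref, dp, ad[:, :, 0])
    ad[:, :, 1] = np.where(hom_alt, dp, ad[:, :, 1])

    if missing_rate > 0:
        miss = rng.random(size=(m, n)) < missing_rate
        g[miss] = np.nan
        ad[miss] = -1
        dp = dp.copy()
        dp[miss] = -1
    return g, ad, dp


# ---------------------------------------------------------------------------
# orchestration


def simulate_cohort(
    design: CohortDesign, planted: list[PlantedFeature] | None = None
) -> SimulatedCohort:
    """Run the full generator: frequencies, genotypes, read evidence, traits."""
    planted = list(planted or [])
    rng = np.random.default_rng(design.seed)
    chrom, pos, p, pop_freqs, truth = draw_population_frequencies(design, planted, rng)
    dosages, labels, weights = sample_genotypes(
        design, pop_freqs, planted, truth, rng, chrom, pos
    )
    artifact_loci = np.concatenate(
        [truth[fi] for fi, f in enumerate(planted) if f.kind == "artifact_site"]
        + [np.array([], dtype=np.int64)]
    ).astype(np.int64)
    g, ad, dp = attach_read_evidence(
        dosages.values, design.mean_depth, design.missing_rate, artifact_loci, rng
    )
    dosages.values = g

    n = design.n_individuals
    sex = np.where(rng.random(n) < 0.5, "M", "F").astype(object)
    sdy = (sex == "M").astype(np.int64)
    for fi, feat in enumerate(planted):
        if feat.kind != "sex_marker":
            continue
        neg_pop = feat.params.get("negative_pop")
        carrier_sex = feat.params.get("carrier_sex", "M")
        sdy = (sex == carrier_sex).astype(np.int64)
        if neg_pop is not None:
            sdy[(labels == int(neg_pop)) & (sex == carrier_sex)] = 0
        truth[fi] = np.array([], dtype=np.int64)
    return SimulatedCohort(
        design=design,
        chrom=chrom,
        pos=pos,
        ancestral_freqs=p,
        pop_freqs=pop_freqs,
        genotypes=dosages,
        pop_labels=labels,
        sex=sex,
        sdy_present=sdy,
        admixture_weight=weights,
        planted=planted,
        truth_log=truth,
        ad=ad,
        dp=dp,
    )


def write_cohort(cohort: SimulatedCohort, prefix) -> dict[str, Path]:
    """Write VCF, sample sheet, and truth log next to ``prefix``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": prefix.with_suffix(".vcf"),
        "samples": Path(str(prefix) + ".samples.tsv"),
        "truth": Path(str(prefix) + ".truth.tsv"),
    }
    lengths = dict(zip(cohort.design.chrom_ids(), cohort.design.chrom_lengths))
    write_vcf(cohort.to_variant_table(), paths["vcf"], contig_lengths=lengths)
    sheet = pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "pop_label": cohort.pop_labels,
            "admixture_weight": cohort.admixture_weight,
            "sex": cohort.sex.astype(str),
            "sdY_present": cohort.sdy_present,
        }
    )
    write_table(sheet, paths["samples"], index=False)
    rows = []
    for fi, feat in enumerate(cohort.planted):
        loci = cohort.truth_log.get(fi, np.array([], dtype=np.int64))
        rows.append(
            {
                "feature_kind": feat.kind,
                "chrom": feat.chrom,
                "start": feat.start,
                "end": feat.end,
                "locus_indices": ",".join(str(i) for i in loci),
            }
        )
    write_table(pd.DataFrame(rows, columns=["feature_kind", "chrom", "start", "end", "locus_indices"]), paths["truth"], index=False)
    return paths
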