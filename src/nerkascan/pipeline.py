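"""End-to-end pipeline: simulate/load -> filter -> structure -> scan ->
association -> LD -> diversity, driven by one YAML config and one seed.

Every stage writes plain-text artifacts (VCF/TSV) into the output
directory, the config is serialized verbatim alongside them, and a
machine-readable run log records per-stage input/output counts, wall time
and the seed.  Stage failures abort with the stage name in the exception.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc_mod
from . import diversity as div_mod
from . import divergence_scan as scan_mod
from . import filters as filt_mod
from . import ld_stats as ld_mod
from . import structure as struct_mod
from .synthetic_cohort import (
    AdmixtureCline,
    CohortDesign,
    PlantedFeature,
    simulate_cohort,
    write_cohort,
)
from .variant_io import read_table, read_vcf, to_dosages, write_table, write_vcf

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    input_vcf: str | None = None
    samples_tsv: str | None = None
    simulate: dict | None = None
    stages: tuple[str, ...] = (
        "simulate",
        "filter",
        "structure",
        "scan",
        "assoc",
        "ld",
        "diversity",
    )
    # thresholds default to the study-standard values
    maf_min: float = 0.05
    max_missing_frac: float = 0.10
    balance_min_ratio: float = 0.2
    prune_window_bp: int = 20_000
    prune_r2: float = 0.4
    prune_max_linked: int = 2
    n_pc: int = 6
    k_max: int = 8
    scan_alpha: float = 0.01
    peak_min_count: int = 5
    peak_max_gap: int = 100_000
    assoc_trait: str = "sdY_present"
    assoc_n_covar_pc: int = 2
    n_perm: int = 1000
    assoc_alpha: float = 0.01
    ld_min_r2: float = 0.5
    ld_block_r2: float = 0.3
    ld_min_dist: int = 100_000
    ld_window: int = 1_000_000
    genome_length: int = div_mod.DEFAULT_GENOME_LENGTH
    raw: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    known = {f for f in RunConfig.__dataclass_fields__ if f != "raw"}
    kwargs = {k: v for k, v in data.items() if k in known}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "stages" in kwargs:
        kwargs["stages"] = tuple(kwargs["stages"])
    return RunConfig(raw=data, **kwargs)


def _design_from_config(sim: dict, seed: int) -> tuple[CohortDesign, list[PlantedFeature]]:
    cline = None
    if sim.get("admixture_cline"):
        c = sim["admixture_cline"]
        weights = c.get("weights")
        if weights is None:
            n = c["n_weights"]
            weights = list(np.linspace(1.0, 0.0, n))
        cline = AdmixtureCline(
            pop_a=int(c["pop_a"]), pop_b=int(c["pop_b"]), weights=tuple(weights)
        )
    design = CohortDesign(
        pop_sizes=tuple(sim["pop_sizes"]),
        fst=tuple(sim["fst"]),
        n_loci=int(sim["n_loci"]),
        chrom_lengths=tuple(sim["chrom_lengths"]),
        mean_depth=float(sim.get("mean_depth", 30.0)),
        missing_rate=float(sim.get("missing_rate", 0.0)),
        admixture_cline=cline,
        seed=seed,
    )
    planted = [
        PlantedFeature(
            kind=f["kind"],
            chrom=f.get("chrom", ""),
            start=int(f.get("start", 0)),
            end=int(f.get("end", 0)),
            params=f.get("params", {}),
        )
        for f in sim.get("planted", [])
    ]
    return design, planted


class _StageTimer:
    def __init__(self, log: list, stage: str):
        self.log, self.stage = log, stage

    def __enter__(self):
        self.t0 = time.perf_counter()
        self.entry = {"stage": self.stage}
        return self.entry

    def __exit__(self, exc_type, exc, tb):
        self.entry["wall_seconds"] = round(time.perf_counter() - self.t0, 3)
        if exc is not None:
            self.entry["error"] = repr(exc)
            self.log.append(self.entry)
            raise RuntimeError(f"pipeline stage {self.stage!r} failed: {exc}") from exc
        self.log.append(self.entry)
        return False


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in study order; returns the output dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.raw or asdict_clean(config), fh, sort_keys=True)
    log: list[dict] = []
    seed = int(config.seed)

    samples_df = None
    vcf_path = config.input_vcf
    if "simulate" in config.stages and config.simulate is not None:
        with _StageTimer(log, "simulate") as entry:
            design, planted = _design_from_config(config.simulate, seed)
            cohort = simulate_cohort(design, planted)
            paths = write_cohort(cohort, out / "cohort")
            vcf_path = str(paths["vcf"])
            samples_df = read_table(paths["samples"])
            entry["n_variants"] = cohort.genotypes.n_variants
            entry["n_samples"] = design.n_individuals
            entry["seed"] = seed
    if vcf_path is None:
        raise ValueError("no input VCF: provide input_vcf or a simulate block")
    if samples_df is None and config.samples_tsv:
        samples_df = read_table(config.samples_tsv)

    vt = read_vcf(vcf_path)
    tables = {"input": vt}
    if "filter" in config.stages:
        with _StageTimer(log, "filter") as entry:
            tables, reports = filt_mod.run_filter_chain(
                vt,
                maf_min=config.maf_min,
                max_missing_frac=config.max_missing_frac,
                balance_min_ratio=config.balance_min_ratio,
                prune_window_bp=config.prune_window_bp,
                prune_r2=config.prune_r2,
                prune_max_linked=config.prune_max_linked,
            )
            write_table(
                pd.concat([r.to_frame() for r in reports], ignore_index=True),
                out / "filter_report.tsv",
                index=False,
            )
            for name in ("basic", "balance", "prune"):
                write_vcf(tables[name], out / f"filtered_{name}.vcf")
            entry["counts"] = {k: t.n_variants for k, t in tables.items()}

    scan_table = tables.get("balance", tables["input"])
    prune_table = tables.get("prune", scan_table)

    pca_res = model = None
    if "structure" in config.stages:
        with _StageTimer(log, "structure") as entry:
            dos = to_dosages(prune_table)
            n_pc = min(config.n_pc, dos.n_samples - 1, dos.n_variants)
            pca_res, model = struct_mod.run_structure(
                dos, n_pc=n_pc, k_max=min(config.k_max, dos.n_samples), seed=seed
            )
            scores = pd.DataFrame(
                pca_res.scores,
                columns=[f"PC{i + 1}" for i in range(pca_res.k)],
                index=pd.Index(prune_table.samples, name="sample_id"),
            )
            write_table(scores, out / "scores.tsv")
            clusters = pd.DataFrame(
                {"sample_id": prune_table.samples, "cluster": model.labels}
            )
            write_table(clusters, out / "clusters.tsv", index=False)
            write_table(
                pd.DataFrame(
                    {"k": list(model.bic), "bic": list(model.bic.values())}
                ),
                out / "bic.tsv",
                index=False,
            )
            write_table(
                pd.DataFrame(
                    {
                        "component": np.arange(1, pca_res.k + 1),
                        "eigenvalue": pca_res.eigenvalues,
                    }
                ),
                out / "scree.tsv",
                index=False,
            )
            entry["selected_k"] = model.k

    if "scan" in config.stages:
        with _StageTimer(log, "scan") as entry:
            if pca_res is None:
                raise ValueError("scan stage requires the structure stage")
            dos = to_dosages(scan_table)
            scan, peaks = scan_mod.run_scan(
                dos,
                pca_res.scores[:, 0],
                alpha=config.scan_alpha,
                min_count=config.peak_min_count,
                max_gap=config.peak_max_gap,
            )
            write_table(scan.to_frame(), out / "scan.tsv", index=False)
            write_table(_peaks_frame(peaks), out / "peaks.tsv", index=False)
            entry["lambda_gc"] = round(scan.lambda_gc, 6)
            entry["n_peaks"] = len(peaks)

    if "assoc" in config.stages:
        with _StageTimer(log, "assoc") as entry:
            if samples_df is None:
                raise ValueError("assoc stage requires a sample sheet")
            trait = samples_df.loc[scan_table.samples, config.assoc_trait].to_numpy(
                dtype=float
            )
            cov = None
            if pca_res is not None and config.assoc_n_covar_pc > 0:
                cov = pca_res.scores[:, : config.assoc_n_covar_pc]
            dos = to_dosages(scan_table)
            res = assoc_mod.run_association(
                dos,
                trait,
                cov,
                n_perm=config.n_perm,
                alpha=config.assoc_alpha,
                seed=seed,
            )
            df = res.to_frame()
            df["threshold_neglog10p"] = res.threshold
            write_table(df, out / "assoc.tsv", index=False)
            sig = res.significant()
            apeaks = scan_mod.call_peaks(
                res.chrom,
                res.pos,
                np.where(res.flagged, np.nan, res.p),
                sig,
                min_count=config.peak_min_count,
                max_gap=config.peak_max_gap,
            )
            write_table(_peaks_frame(apeaks), out / "assoc_peaks.tsv", index=False)
            entry["threshold"] = round(res.threshold, 4)
            entry["n_significant"] = int(len(sig))

    if "ld" in config.stages:
        with _StageTimer(log, "ld") as entry:
            dos = to_dosages(scan_table)
            rows = []
            track_rows = []
            chrom_len = {}
            for c in pd.unique(dos.chrom.astype(str)):
                chrom_len[c] = int(dos.pos[dos.chrom.astype(str) == c].max())
            for c, ln in chrom_len.items():
                pairs = ld_mod.chromosome_pairs(dos, c, min_r2=config.ld_min_r2)
                rows.extend(
                    {
                        "chrom": p.chrom,
                        "pos_a": p.pos_a,
                        "pos_b": p.pos_b,
                        "distance": p.distance,
                        "r2": p.r2,
                    }
                    for p in pairs
                )
                track = ld_mod.longrange_track(
                    pairs, c, ln, window=config.ld_window, min_dist=config.ld_min_dist
                )
                # BED-style export: 0-based half-open only in this file
                track_rows.append(
                    pd.DataFrame(
                        {
                            "chrom": track["chrom"],
                            "start0": track["start"] - 1,
                            "end": track["end"],
                            "count": track["count"],
                            "log10_count": track["log10_count"],
                        }
                    )
                )
            write_table(
                pd.DataFrame(rows, columns=["chrom", "pos_a", "pos_b", "distance", "r2"]),
                out / "ld_pairs.tsv",
                index=False,
            )
            write_table(
                pd.concat(track_rows, ignore_index=True)
                if track_rows
                else pd.DataFrame(columns=["chrom", "start0", "end", "count", "log10_count"]),
                out / "ld_track.tsv",
                index=False,
            )
            entry["n_pairs"] = len(rows)

    if "diversity" in config.stages:
        with _StageTimer(log, "diversity") as entry:
            het_source = tables.get("basic", tables["input"])
            write_table(
                div_mod.het_stats_frame(het_source, config.genome_length),
                out / "het_stats.tsv",
                index=False,
            )
            segs = div_mod.roh_scan(scan_table)
            write_table(
                pd.DataFrame(
                    [
                        {
                            "sample_id": s.sample_id,
                            "chrom": s.chrom,
                            "start": s.start,
                            "end": s.end,
                            "n_snps": s.n_snps,
                            "length": s.length,
                        }
                        for s in segs
                    ],
                    columns=["sample_id", "chrom", "start", "end", "n_snps", "length"],
                ),
                out / "roh.tsv",
                index=False,
            )
            totals = div_mod.total_roh(segs, samples=scan_table.samples)
            write_table(
                totals.rename("total_roh_bp").rename_axis("sample_id").reset_index(),
                out / "roh_totals.tsv",
                index=False,
            )
            entry["n_roh_segments"] = len(segs)

    with open(out / "run_log.json", "w") as fh:
        json.dump({"seed": seed, "stages": log}, fh, indent=2, sort_keys=True)
    return out


def asdict_clean(config: RunConfig) -> dict:
    d = asdict(config)
    d.pop("raw", None)
    d["stages"] = list(d["stages"])
    return d


def _peaks_frame(peaks) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "n_sig": p.n_sig,
                "lead_pos": p.lead_pos,
                "lead_p": p.lead_p,
            }
            for p in peaks
        ],
        columns=["chrom", "start", "end", "n_sig", "lead_pos", "lead_p"],
    )
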