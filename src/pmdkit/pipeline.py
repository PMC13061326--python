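"""End-to-end pipeline: simulate (optional) -> segment -> chip-norm -> repli
-> classify -> hyper -> pileup -> stats -> kinetics.

Every run writes its resolved configuration and a JSON report with per-stage
counts and SHA-256 hashes of all outputs next to the results; identical
config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import chip_repli, domains as da, kinetics as kin, segmentation, simulate, tracks
from .genome import ExclusionSet, GenomeLayout, read_bed, write_bed
from .tracks import BinnedTrack

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    outdir: str = "pmdkit_run"
    seed: int = 0
    simulate: bool = True
    window: int = 10_000
    chromatin_bin: int = 25_000
    min_length: int = 200_000
    min_coverage: int = 1
    hyper_threshold_pp: float = 5.0
    loess_span: float = 0.05
    timepoints: tuple = (0, 1, 2, 3, 4, 6, 12)
    # input paths used when simulate is False; unset stages are skipped
    meth_wt: Optional[str] = None
    meth_ko: Optional[str] = None
    chrom_sizes: Optional[str] = None
    exclude: Optional[str] = None
    chip: dict = field(default_factory=dict)   # mark -> {ip, input, ip_total, input_total}
    repli: dict = field(default_factory=dict)  # {early: [...], late: [...]}
    kinetics_table: Optional[str] = None
    stages: tuple = (
        "segment", "chip_norm", "repli", "classify", "hyper",
        "pileup", "stats", "kinetics",
    )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        if "timepoints" in raw:
            raw["timepoints"] = tuple(raw["timepoints"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["timepoints"] = list(self.timepoints)
        d["stages"] = list(self.stages)
        d.pop("outdir")  # location is not part of the scientific configuration
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns (and writes) the run report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    (out / "config_resolved.json").write_text(
        json.dumps(config.resolved(), indent=2, sort_keys=True) + "\n"
    )

    def fail(stage: str, exc: Exception):
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    # ---- inputs: simulated or from disk -------------------------------------
    sim_cfg = truth = None
    if config.simulate:
        try:
            sim_cfg = simulate.SimulationConfig(seed=config.seed, window=config.window)
            meth_wt, truth = simulate.simulate_methylome(sim_cfg, "WT")
            meth_ko, _ = simulate.simulate_methylome(sim_cfg, "KO")
            layout = sim_cfg.layout
            exclusions = truth.exclusions
            tracks.write_methylation(meth_wt, out / "meth_wt.cov")
            tracks.write_methylation(meth_ko, out / "meth_ko.cov")
            truth.to_bed(out / "ground_truth.bed")
            layout.to_file(out / "chrom.sizes")
            write_bed(list(exclusions.intervals), out / "exclusions.bed")
            chip_in: dict = {}
            for mark in ("H3K9me3", "H3K27me3"):
                ip, inp = simulate.simulate_chip(sim_cfg, mark, "WT", config.window)
                chip_in[mark] = {
                    "ip": ip, "input": inp,
                    "ip_total": simulate.chip_nominal_total(sim_cfg, ip),
                    "input_total": simulate.chip_nominal_total(sim_cfg, inp),
                }
            repli_in = {
                "early": [], "late": [],
            }
            for rep in (0, 1):
                e, l = simulate.simulate_repliseq(sim_cfg, "WT", config.window, rep)
                repli_in["early"].append(e)
                repli_in["late"].append(l)
            kin_table = simulate.simulate_timecourse(sim_cfg, config.timepoints)
            report["stages"]["simulate"] = {
                "n_domains": len(truth.domains),
                "n_planted_hyper": len(truth.hyper_set()),
                "n_cpgs_wt": len(meth_wt),
            }
        except Exception as exc:  # noqa: BLE001
            fail("simulate", exc)
    else:
        try:
            if not config.meth_wt or not config.chrom_sizes:
                raise PipelineError("need meth_wt and chrom_sizes when not simulating")
            for name in ("meth_wt", "chrom_sizes", "meth_ko", "exclude"):
                p = getattr(config, name)
                if p and not Path(p).exists():
                    raise PipelineError(f"missing {name} file: {p}")
            layout = GenomeLayout.from_file(config.chrom_sizes)
            meth_wt = tracks.read_methylation(config.meth_wt)
            meth_ko = (
                tracks.read_methylation(config.meth_ko) if config.meth_ko else None
            )
            exclusions = (
                ExclusionSet.build(read_bed(config.exclude), layout=layout)
                if config.exclude
                else ExclusionSet.empty()
            )
            chip_in = {}
            for mark, spec in config.chip.items():
                chip_in[mark] = {
                    "ip": BinnedTrack.from_bedgraph(spec["ip"], layout, config.window),
                    "input": BinnedTrack.from_bedgraph(spec["input"], layout, config.window),
                    "ip_total": float(spec["ip_total"]),
                    "input_total": float(spec["input_total"]),
                }
            repli_in = {
                "early": [BinnedTrack.from_bedgraph(p, layout, config.window)
                          for p in config.repli.get("early", [])],
                "late": [BinnedTrack.from_bedgraph(p, layout, config.window)
                         for p in config.repli.get("late", [])],
            }
            kin_table = (
                pd.read_csv(config.kinetics_table, sep="\t")
                if config.kinetics_table
                else None
            )
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            fail("inputs", exc)

    meth_wt_track = tracks.methylation_track(
        meth_wt, layout, config.window, config.min_coverage
    )

    pmds = hmds = None
    if "segment" in config.stages:
        try:
            pmds, hmds = segmentation.call_pmds(
                meth_wt, layout, exclusions,
                window=config.window, min_length=config.min_length,
                min_coverage=config.min_coverage, seed=config.seed,
            )
            write_bed([d.interval for d in pmds], out / "pmds.bed",
                      names=["PMD"] * len(pmds))
            write_bed([d.interval for d in hmds], out / "hmds.bed",
                      names=["HMD"] * len(hmds))
            report["stages"]["segment"] = {"n_pmds": len(pmds), "n_hmds": len(hmds)}
        except Exception as exc:  # noqa: BLE001
            fail("segment", exc)

    norm_chip: dict = {}
    if "chip_norm" in config.stages and chip_in:
        try:
            for mark, spec in chip_in.items():
                nc = chip_repli.normalize_chip(
                    spec["ip"], spec["input"], spec["ip_total"], spec["input_total"]
                )
                norm_chip[mark] = nc.track
                nc.track.to_bedgraph(out / f"chip_{mark}_ratio.bedgraph")
            report["stages"]["chip_norm"] = {"marks": sorted(norm_chip)}
        except Exception as exc:  # noqa: BLE001
            fail("chip_norm", exc)

    timing = None
    if "repli" in config.stages and repli_in["early"]:
        try:
            rt = chip_repli.replication_timing(
                repli_in["early"], repli_in["late"], span=config.loess_span
            )
            timing = rt.smoothed
            timing.to_bedgraph(out / "replication_timing.bedgraph")
            report["stages"]["repli"] = dict(rt.meta)
        except Exception as exc:  # noqa: BLE001
            fail("repli", exc)

    classification = None
    if "classify" in config.stages and pmds and {"H3K9me3", "H3K27me3"} <= set(norm_chip):
        try:
            classification = da.classify_pmds(
                pmds, norm_chip["H3K9me3"], norm_chip["H3K27me3"], seed=config.seed
            )
            _write_tsv(classification.table, out / "pmd_classes.tsv")
            counts = classification.table["label"].value_counts().to_dict()
            report["stages"]["classify"] = {k: int(v) for k, v in counts.items()}
        except Exception as exc:  # noqa: BLE001
            fail("classify", exc)

    hyper_table = None
    if "hyper" in config.stages and pmds and meth_ko is not None:
        try:
            ivs = [d.interval for d in pmds]
            wt_means = tracks.weighted_mean_methylation(meth_wt, ivs, config.min_coverage)
            ko_means = tracks.weighted_mean_methylation(meth_ko, ivs, config.min_coverage)
            hyper_table = da.call_hypermethylated(
                wt_means, ko_means, config.hyper_threshold_pp
            )
            hyper_table.insert(0, "chrom", [ivs[i].chrom for i in hyper_table["index"]])
            hyper_table.insert(1, "start", [ivs[i].start for i in hyper_table["index"]])
            hyper_table.insert(2, "end", [ivs[i].end for i in hyper_table["index"]])
            _write_tsv(hyper_table.drop(columns=["index"]), out / "hyper_calls.tsv")
            stage = {"n_hyper": int(hyper_table["hyper"].sum()),
                     "n_tested": int(len(hyper_table))}
            if truth is not None:
                from .genome import jaccard

                planted = truth.hyper_set()
                called_ivs = [
                    ivs[int(i)]
                    for i, h in zip(hyper_table["index"], hyper_table["hyper"])
                    if h
                ]
                stage["n_planted"] = len(planted)
                stage["hyper_recovered_exactly"] = bool(
                    len(called_ivs) == len(planted)
                    and (len(planted) == 0 or jaccard(called_ivs, planted) > 0.9)
                )
            report["stages"]["hyper"] = stage
        except Exception as exc:  # noqa: BLE001
            fail("hyper", exc)

    if "pileup" in config.stages and pmds:
        try:
            ivs = [d.interval for d in pmds]
            rank = tracks.interval_means(meth_wt_track, ivs)
            pm = da.pileup_matrix(
                ivs, meth_wt_track, binsize=config.window, rank_key=rank
            )
            cols = [f"bin_{i}" for i in range(pm.matrix.shape[1])]
            dfm = pd.DataFrame(pm.matrix, columns=cols)
            dfm.insert(0, "domain", [f"{v.chrom}:{v.start}-{v.end}" for v in pm.domains])
            _write_tsv(dfm, out / "pileup_meth_wt.tsv")
            report["stages"]["pileup"] = {"shape": list(pm.matrix.shape)}
        except Exception as exc:  # noqa: BLE001
            fail("pileup", exc)

    if "stats" in config.stages and pmds and hmds:
        try:
            stats_out: dict = {}
            if hyper_table is not None and classification is not None:
                hyper_flags = hyper_table["hyper"].to_numpy()
                k9_flags = np.array(
                    [l == "K9-marked" for l in classification.labels]
                )[hyper_table["index"].to_numpy()]
                table = [
                    [int((hyper_flags & k9_flags).sum()), int((hyper_flags & ~k9_flags).sum())],
                    [int((~hyper_flags & k9_flags).sum()), int((~hyper_flags & ~k9_flags).sum())],
                ]
                odds, p = da.fisher_exact(table, alternative="greater")
                stats_out["hyper_k9_enrichment"] = {
                    "table": table, "odds_ratio": odds, "p_one_sided": p,
                }
            if meth_ko is not None:
                ko_track = tracks.methylation_track(
                    meth_ko, layout, config.window, config.min_coverage
                )
                delta = ko_track.values - meth_wt_track.values
                pmd_delta = tracks.interval_means(
                    meth_wt_track.with_values(delta), [d.interval for d in pmds]
                )
                hmd_delta = tracks.interval_means(
                    meth_wt_track.with_values(delta), [d.interval for d in hmds]
                )
                stat, p = da.wilcoxon_rank_sum(
                    pmd_delta[~np.isnan(pmd_delta)], hmd_delta[~np.isnan(hmd_delta)]
                )
                stats_out["delta_meth_pmd_vs_hmd"] = {
                    "median_pmd": float(np.nanmedian(pmd_delta)),
                    "median_hmd": float(np.nanmedian(hmd_delta)),
                    "wilcoxon_p": p,
                }
            if timing is not None:
                _, rho, p = da.decile_analysis(meth_wt_track, timing)
                stats_out["meth_vs_timing"] = {"spearman_rho": rho, "p": p}
            (out / "stats.json").write_text(
                json.dumps(stats_out, indent=2, sort_keys=True) + "\n"
            )
            report["stages"]["stats"] = {"tests": sorted(stats_out)}
        except Exception as exc:  # noqa: BLE001
            fail("stats", exc)

    if "kinetics" in config.stages and kin_table is not None:
        try:
            fits = kin.fit_decay_table(kin_table)
            _write_tsv(fits, out / "kinetics_fits.tsv")
            stage = {"n_domains": int(len(fits))}
            if "class" in fits.columns:
                by_class = {
                    c: [
                        kin.KineticsFit(r.slope, r.intercept, r.final_level,
                                        (0.0, 6.0), int(r.n_points))
                        for r in grp.itertuples()
                    ]
                    for c, grp in fits.groupby("class")
                }
                summary, pairwise = kin.compare_classes(by_class)
                _write_tsv(summary, out / "kinetics_class_summary.tsv")
                _write_tsv(pairwise, out / "kinetics_class_tests.tsv")
                stage["classes"] = sorted(by_class)
            report["stages"]["kinetics"] = stage
        except Exception as exc:  # noqa: BLE001
            fail("kinetics", exc)

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "report.json":
            report["outputs"][p.name] = _sha256(p)
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
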