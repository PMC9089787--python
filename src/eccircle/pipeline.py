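"""End-to-end runs: simulate -> call -> profile -> AUC -> enrich -> motifs
-> partition -> group stats, archived as a plain directory of files.

A run directory contains the exact config (JSON) and package version that
produced it, per-sample BED/TSV outputs, pooled profiles and plots, and a
structured log with stage timings and record counts.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .calling import CallerConfig, call_eccdna, extract_junction_signals
from .context import junction_motifs, element_enrichment, simulate_expected_loci
from .io import read_alignments, write_records_bed
from .model import Genotype, Origin, SampleMeta
from .partition import classify_records, fetal_fraction
from .size import (
    CLUSTER1_WINDOW,
    CLUSTER2_WINDOW,
    cluster_auc,
    compute_epm,
    pool_profiles,
    size_profile,
)
from .simulate import (
    make_genome,
    scenario_preset,
    simulate_scenario,
    write_reference,
    write_sample,
)
from .stats import dunn_posthoc, kruskal_wallis, wilcoxon_rank_sum

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run bit-for-bit."""

    scenarios: List[str] = field(default_factory=lambda: ["wt", "d1l3ko"])
    n_samples: int = 3
    n_circles: int = 300
    seed: int = 7
    genome_chroms: int = 2
    genome_length: int = 200_000
    n_snps: int = 400
    caller: CallerConfig = field(default_factory=CallerConfig)
    cluster1_window: Tuple[int, int] = CLUSTER1_WINDOW
    cluster2_window: Tuple[int, int] = CLUSTER2_WINDOW
    n_sim_expected: int = 20_000
    make_plots: bool = True

    def to_json(self) -> str:
        d = asdict(self)
        d["version"] = __version__
        return json.dumps(d, indent=1, default=str)


def _sample_seed(base: int, si: int, rep: int) -> int:
    return (base * 100_003 + si * 101 + rep) % (2**31 - 1)


def run_pipeline(config: RunConfig, outdir) -> pd.DataFrame:
    """Execute all stages for every scenario and sample; returns the
    per-sample summary table (also written as summary.tsv)."""
    t_start = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: List[str] = []

    def note(msg: str) -> None:
        log.append(f"[{time.time() - t_start:8.2f}s] {msg}")

    (outdir / "config.json").write_text(config.to_json())

    ref = make_genome(
        n_chroms=config.genome_chroms,
        lengths=[config.genome_length] * config.genome_chroms,
        n_snps=config.n_snps,
        seed=config.seed,
    )
    write_reference(ref, outdir / "reference")
    note(
        f"reference: {config.genome_chroms} chromosomes x "
        f"{config.genome_length} bp, {len(ref.snps)} strain SNPs"
    )

    rows = []
    pooled_by_scenario: Dict[str, list] = {}
    for si, scen in enumerate(config.scenarios):
        scen_records: list = []
        for rep in range(config.n_samples):
            seed = _sample_seed(config.seed, si, rep)
            cfg = replace(
                scenario_preset(scen, seed=seed, n_circles=config.n_circles),
                name=f"{scen}_m{rep + 1}",
            )
            sample = simulate_scenario(cfg, ref)
            sdir = outdir / "samples"
            write_sample(sample, ref.genome_a, sdir)

            reader = read_alignments(
                sdir / f"{cfg.name}.sam", mapq_min=config.caller.mapq_min
            )
            extraction = extract_junction_signals(reader, ref.genome_a, config.caller)
            meta = SampleMeta(
                sample_id=cfg.name,
                genotype=cfg.genotype,
                library=cfg.library,
                mappable_reads=reader.mappable_reads,
            )
            records = call_eccdna(extraction.signals, config.caller, meta)

            if cfg.fetal_proportion > 0:
                records, _ = classify_records(records, sample.fragments, ref.snps)
            write_records_bed(records, sdir / f"{cfg.name}.loci.bed")
            scen_records.extend(records)

            profile = size_profile(records)
            auc = cluster_auc(
                profile, config.cluster1_window, config.cluster2_window
            )
            row = {
                "sample_id": cfg.name,
                "scenario": scen,
                "genotype": cfg.genotype.value,
                "n_loci": len(records),
                "mappable_reads": meta.mappable_reads,
                "epm": compute_epm(len(records), meta.mappable_reads),
                "auc1": auc.auc1,
                "auc2": auc.auc2,
                "auc_ratio": auc.auc_ratio,
            }
            if cfg.fetal_proportion > 0:
                n_f = sum(1 for r in records if r.origin is Origin.FETAL_SPECIFIC)
                n_s = sum(1 for r in records if r.origin is Origin.SHARED)
                if n_f + n_s:
                    ff = fetal_fraction(n_f, n_s)
                    row["fetal_fraction_pct"] = ff.percent
                    row["fetal_fraction_raw_pct"] = ff.raw_percent
            rows.append(row)
            note(
                f"{cfg.name}: {len(records)} loci from "
                f"{meta.mappable_reads} pairs "
                f"({extraction.n_ambiguous} ambiguous clips)"
            )
        pooled_by_scenario[scen] = scen_records

    # pooled profiles, AUC, enrichment, motifs per scenario
    pooled_rows = []
    profiles_tsv = []
    for scen, records in pooled_by_scenario.items():
        profile = size_profile(records)
        auc = cluster_auc(profile, config.cluster1_window, config.cluster2_window)
        pooled_rows.append(
            {
                "scenario": scen,
                "n_loci": len(records),
                "auc1": auc.auc1,
                "auc2": auc.auc2,
                "auc_ratio": auc.auc_ratio,
            }
        )
        for s, f in zip(profile.sizes, profile.freq):
            profiles_tsv.append({"scenario": scen, "size": int(s), "percent": f})

        if records:
            expected = simulate_expected_loci(
                ref.genome_a.chrom_sizes,
                [r.size for r in records],
                config.n_sim_expected,
                seed=config.seed,
            )
            enrich = element_enrichment(records, ref.elements, expected, seed=config.seed)
            pd.DataFrame(
                [
                    {
                        "element_class": e.element_class,
                        "observed_freq": e.observed_freq,
                        "expected_freq": e.expected_freq,
                        "fold_change": e.fold_change,
                        "n_sim": e.n_sim,
                    }
                    for e in enrich.values()
                ]
            ).to_csv(outdir / f"enrichment_{scen}.tsv", sep="\t", index=False)
            combos, skipped = junction_motifs(records, ref.genome_a, top_k=5)
            pd.DataFrame(
                [
                    {
                        "rank": c.rank,
                        "motif_I": c.motif_I,
                        "motif_II": c.motif_II,
                        "motif_III": c.motif_III,
                        "motif_IV": c.motif_IV,
                        "count": c.count,
                    }
                    for c in combos
                ]
            ).to_csv(outdir / f"motifs_{scen}.tsv", sep="\t", index=False)
        note(f"pooled {scen}: {len(records)} loci, auc_ratio={auc.auc_ratio}")

    summary = pd.DataFrame(rows)
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    pd.DataFrame(pooled_rows).to_csv(outdir / "summary_pooled.tsv", sep="\t", index=False)
    pd.DataFrame(profiles_tsv).to_csv(outdir / "profiles_pooled.tsv", sep="\t", index=False)

    # group comparison of per-sample AUC ratios
    groups = [
        [r["auc_ratio"] for r in rows if r["scenario"] == scen and r["auc_ratio"] is not None]
        for scen in config.scenarios
    ]
    stats_rows = []
    if len(groups) >= 3 and all(len(g) >= 1 for g in groups):
        kw = kruskal_wallis(groups)
        stats_rows.append(
            {"test": "kruskal_wallis", "statistic": kw.statistic, "p_value": kw.p_value}
        )
        for pw in dunn_posthoc(groups):
            stats_rows.append(
                {
                    "test": f"dunn[{config.scenarios[pw.group_i]} vs "
                    f"{config.scenarios[pw.group_j]}]",
                    "statistic": pw.z,
                    "p_value": pw.p_adjusted,
                }
            )
    elif len(groups) == 2 and all(len(g) >= 1 for g in groups):
        w = wilcoxon_rank_sum(groups[0], groups[1])
        stats_rows.append(
            {"test": w.method, "statistic": w.statistic, "p_value": w.p_value}
        )
    if stats_rows:
        pd.DataFrame(stats_rows).to_csv(outdir / "group_stats.tsv", sep="\t", index=False)

    if config.make_plots:
        _plot_profiles(pooled_by_scenario, outdir / "size_profiles.png")
        note("wrote size_profiles.png")

    note("done")
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return summary


def _plot_profiles(pooled_by_scenario, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for scen, records in pooled_by_scenario.items():
        profile = size_profile(records)
        ax.plot(profile.sizes, profile.freq, label=scen, lw=0.8)
    ax.set_xlabel("eccDNA size (bp)")
    ax.set_ylabel("frequency (%)")
    ax.set_xlim(0, 700)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
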