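"""End-to-end pipeline: simulate -> classify -> gcstar -> motifscan ->
profile -> density, driven by a single config mapping.

Every under-specified knob of the analysis surfaces in the config with a
documented default; stages log counts in and out of every filter so the
peak bookkeeping (KO removal, shared-peak removal, intergenic filter) can
be reproduced from the logs. Reruns with an identical config are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import classify as pc
from . import coverage as cov
from . import density as dens
from . import gcstar as gc
from . import motifs as mo
from . import simulate as sim
from .intervals import GenomicInterval, PeakSet, write_bed

logger = logging.getLogger("hotspotclass.pipeline")

__all__ = ["PipelineError", "load_config", "build_simulation_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise PipelineError("config file must contain a mapping")
    return config


def build_simulation_config(config: Mapping[str, Any]) -> sim.SimulationConfig:
    """SimulationConfig from the ``simulate`` section plus top-level seed."""
    section = dict(config.get("simulate") or {})
    kwargs: dict[str, Any] = {"seed": int(config.get("seed", 0))}
    simple = {
        "chrom_sizes", "background_gc", "n_common", "n_nonspecific",
        "n_background_promoters", "n_background_cpg", "n_genes", "gene_width",
        "promoter_width", "cpg_width", "cpg_frac_2a", "ctcf_frac",
        "min_separation", "edge_margin", "dmc1_width", "h3k4me3_width",
    }
    for key, value in section.items():
        if key in simple:
            kwargs[key] = value
        elif key == "n_sites":
            kwargs["n_sites"] = {
                (strain, cls): int(n)
                for strain, per_class in value.items()
                for cls, n in per_class.items()
            }
        elif key == "divergence":
            kwargs["divergence"] = sim.DivergenceConfig(**value)
        elif key == "coverage":
            kwargs["coverage"] = sim.CoverageConfig(**value)
        elif key == "peak_width":
            kwargs["peak_width"] = sim.PeakWidthLaw(**value)
        else:
            raise PipelineError(f"unknown simulate config key {key!r}")
    return sim.SimulationConfig(**kwargs)


def _classified_bed(classified, path: Path) -> None:
    ivs = [
        GenomicInterval(
            c.interval.chrom, c.interval.start, c.interval.end,
            name=f"{c.interval.name or 'peak'}|class={c.class_label}",
            score=c.interval.score,
        )
        for c in classified
    ]
    write_bed(PeakSet(intervals=ivs), path)


def _stat_dict(res: pc.StatTestResult) -> dict:
    return {
        "statistic": round(res.statistic, 6),
        "df": res.df,
        "p_value": float(f"{res.p_value:.6g}"),
    }


def run_pipeline(config: Mapping[str, Any], outdir: str | Path | None = None) -> dict:
    """Execute all stages on a synthetic dataset; returns the summary dict.

    Outputs land in ``outdir`` (or ``config['outdir']``): peak sets and
    annotations as BED, the truth table and GC* tables as TSV, coverage as
    bedGraph, densities as two-column tables, and ``summary.json``.
    """
    outdir = Path(outdir or config.get("outdir", "hotspotclass_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("hotspotclass")
    root_logger.addHandler(handler)
    try:
        return _run_stages(dict(config), outdir)
    finally:
        root_logger.removeHandler(handler)
        handler.close()


def _run_stages(config: dict, outdir: Path) -> dict:
    seed = int(config.get("seed", 0))
    summary: dict[str, Any] = {"seed": seed}

    # ----- simulate ------------------------------------------------------
    try:
        sim_config = build_simulation_config(config)
        genome = sim.simulate_genome(sim_config)
        data = sim.simulate_sites_and_peaks(sim_config, genome)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(f"stage 'simulate' failed: {exc}") from exc
    logger.info("simulate: %d truth sites, %d peak sets",
                len(data.truth), len(data.peaksets))
    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for key, ps in data.peaksets.items():
        write_bed(ps, peak_dir / f"{key}.bed")
    sim.write_fasta(genome, outdir / "genome.fa", seed=seed)
    data.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    ann = data.annotations
    for name, ivs in (
        ("promoters", ann.promoters), ("genes", ann.genes),
        ("cpg_islands", ann.cpg_islands),
    ):
        write_bed(PeakSet(intervals=ivs), outdir / f"{name}.bed")
    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom, size in sim_config.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")

    # ----- classify ------------------------------------------------------
    cls_cfg = dict(config.get("classify") or {})
    min_overlap = int(cls_cfg.get("min_overlap", 1))
    try:
        part = pc.partition_by_strain(
            data.peaksets["PRDM9_B6"], data.peaksets["PRDM9_RJ2"],
            data.peaksets["PRDM9_Prdm9KO"], min_overlap=min_overlap,
        )
        logger.info(
            "partition: B6 %d specific / %d common / %d KO-removed; "
            "RJ2 %d / %d / %d",
            len(part.specific_a), len(part.common_a), len(part.removed_a),
            len(part.specific_b), len(part.common_b), len(part.removed_b),
        )
        tables = {}
        classified = {}
        for strain, specific, other in (
            ("B6", part.specific_a, "RJ2"),
            ("RJ2", part.specific_b, "B6"),
        ):
            cl, table = pc.classify_all(
                specific,
                data.peaksets[f"DMC1_{strain}"],
                data.peaksets[f"H3K4me3_{strain}"],
                data.peaksets[f"H3K4me3_{other}"],
                min_overlap=min_overlap,
            )
            classified[strain] = cl
            tables[strain] = table
            _classified_bed(cl, outdir / f"classified_{strain}.bed")
            table.to_frame().to_csv(
                outdir / f"class_table_{strain}.tsv", sep="\t", index=False
            )
        # Spo11-KO classification against B6 evidence
        spo_kept = pc.partition_by_strain(
            data.peaksets["PRDM9_B6_Spo11KO"], data.peaksets["PRDM9_RJ2"],
            data.peaksets["PRDM9_Prdm9KO"], min_overlap=min_overlap,
        ).specific_a
        cl_spo, table_spo = pc.classify_all(
            spo_kept,
            data.peaksets["DMC1_B6"],
            data.peaksets["H3K4me3_B6"],
            data.peaksets["H3K4me3_RJ2"],
            min_overlap=min_overlap,
        )
        classified["B6_Spo11KO"] = cl_spo
        tables["B6_Spo11KO"] = table_spo
        _classified_bed(cl_spo, outdir / "classified_B6_Spo11KO.bed")
        chisq = pc.class_distribution_gof_chisq(table_spo, tables["B6"])
        with open(outdir / "chisq.json", "w") as fh:
            json.dump(_stat_dict(chisq), fh, sort_keys=True, indent=1)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'classify' failed: {exc}") from exc
    summary["class_counts"] = {
        strain: dict(sorted(t.counts.items())) for strain, t in tables.items()
    }
    summary["partition"] = {
        "B6": {"specific": len(part.specific_a), "common": len(part.common_a),
               "removed": len(part.removed_a)},
        "RJ2": {"specific": len(part.specific_b), "common": len(part.common_b),
                "removed": len(part.removed_b)},
    }
    summary["chisq_spo11ko_vs_b6"] = _stat_dict(chisq)

    # ----- gcstar --------------------------------------------------------
    gcfg = dict(config.get("gcstar") or {})
    bin_width = int(gcfg.get("bin_width", 10))
    extent = int(gcfg.get("extent", 2000))
    center_window = int(gcfg.get("center_window", 500))
    try:
        centers_c1 = data.class_centers("B6", "1")
        centers_c2 = data.class_centers("B6", "2A") + data.class_centers("B6", "2B")
        regions = [
            (chrom, max(0, c - extent - 1), c + extent + 1)
            for chrom, c in centers_c1 + centers_c2
        ]
        triples = sim.simulate_divergence(genome, data.truth, sim_config,
                                          regions=regions)
        pol = gc.polarize_substitutions(triples,
                                        exclude_cpg=bool(gcfg.get("exclude_cpg")))
        gc_summary = {}
        for tag, centers in (("class1", centers_c1), ("class2", centers_c2)):
            profiles = gc.build_profiles(
                pol.calls, pol.tallies, centers,
                bin_width=bin_width, extent=extent,
            )
            for lineage, prof in profiles.items():
                prof.bins.to_csv(
                    outdir / f"gcstar_{tag}_B6_{lineage}.tsv", sep="\t", index=False
                )
            test = gc.compare_lineages(
                profiles["domesticus"], profiles["castaneus"],
                center_window=center_window,
            )
            center_bin = profiles["domesticus"].bins
            center_val = center_bin.loc[center_bin["offset"] == 0, "gc_star"]
            gc_summary[tag] = {
                "center_gc_star_domesticus":
                    round(float(center_val.iloc[0]), 4) if len(center_val) else None,
                "lineage_test": _stat_dict(test),
            }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'gcstar' failed: {exc}") from exc
    summary["gc_star"] = gc_summary

    # ----- motifscan -----------------------------------------------------
    mcfg = dict(config.get("motifscan") or {})
    window = int(mcfg.get("window", 50))
    m_extent = int(mcfg.get("extent", 1000))
    try:
        truth_peaks = {
            (s, c): PeakSet(intervals=[
                GenomicInterval(ch, max(0, ce - 150), ce + 150)
                for ch, ce in data.class_centers(s, c)
            ])
            for s in ("B6", "RJ2") for c in ("1", "2A", "2B")
        }
        motif_summary = {}
        for pwm_name, strain in (("Dom2", "B6"), ("Cst", "RJ2")):
            pwm = sim_config.motifs[pwm_name]
            for cls in ("1", "2B"):
                densy = mo.positional_hit_density(
                    truth_peaks[(strain, cls)], genome, pwm,
                    window=window, extent=m_extent,
                )
                pd.DataFrame({"offset": densy.offsets, "count": densy.counts}).to_csv(
                    outdir / f"density_{pwm_name}_{strain}_class{cls}.tsv",
                    sep="\t", index=False,
                )
                motif_summary[f"{pwm_name}_{strain}_class{cls}"] = {
                    "total_hits": densy.total_hits,
                    "peak_offset": densy.peak_offset() if densy.total_hits else None,
                }
        # CTCF in class 2B with randomized control
        ctcf = sim_config.motifs["CTCF"]
        b6_2b = truth_peaks[("B6", "2B")]
        n_real = mo.motif_containing_count(b6_2b, genome, ctcf)
        _, n_ctrl = mo.randomized_control(
            b6_2b, sim_config.chrom_sizes,
            seed=int(mcfg.get("control_seed", seed + 1)),
            genome=genome, pwm=ctcf,
        )
        motif_summary["CTCF_B6_class2B"] = {
            "motif_containing": n_real, "randomized_control": n_ctrl,
        }
        logger.info("motifscan: CTCF-containing class 2B peaks %d (control %d)",
                    n_real, n_ctrl)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'motifscan' failed: {exc}") from exc
    summary["motifs"] = motif_summary

    # ----- profile -------------------------------------------------------
    pcfg = dict(config.get("profile") or {})
    mode = pcfg.get("mode", "input_subtract")
    p_extent = int(pcfg.get("extent", 2000))
    try:
        chip, inp = sim.simulate_coverage(data.peaksets["PRDM9_B6"], sim_config)
        chip.to_bedgraph(outdir / "PRDM9_B6_chip.bedgraph")
        inp.to_bedgraph(outdir / "PRDM9_B6_input.bedgraph")
        with open(outdir / "library_sizes.txt", "w") as fh:
            fh.write(f"PRDM9_B6_chip\t{chip.library_size}\n")
            fh.write(f"PRDM9_B6_input\t{inp.library_size}\n")
        sites = PeakSet(intervals=[
            GenomicInterval(ch, max(0, ce - 150), ce + 150)
            for ch, ce in data.class_centers("B6", "1")
        ])
        prof = cov.aggregate_profile(sites, chip, inp, extent=p_extent, mode=mode)
        pd.DataFrame(
            {"offset": prof.offsets, "value": prof.values}
        ).to_csv(outdir / "profile_PRDM9_B6_class1.tsv", sep="\t", index=False)
        summary["profile"] = {
            "mode": mode,
            "n_sites": prof.n_sites,
            "max_offset": prof.max_offset(),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'profile' failed: {exc}") from exc

    # ----- density -------------------------------------------------------
    dcfg = dict(config.get("density") or {})
    windows = [int(w) for w in dcfg.get("windows", [1_000_000])]
    try:
        c1 = [GenomicInterval(ch, max(0, ce - 150), ce + 150)
              for ch, ce in data.class_centers("RJ2", "1")]
        c2b = [GenomicInterval(ch, max(0, ce - 150), ce + 150)
               for ch, ce in data.class_centers("RJ2", "2B")]
        corr = {}
        for w in windows:
            res = dens.site_density_correlation(
                c1, c2b, sim_config.chrom_sizes, window=w
            )
            corr[str(w)] = {
                "pearson_r": round(res.pearson_r, 4),
                "spearman_r": round(res.spearman_r, 4),
                "n_windows": res.n_windows,
            }
        feats = dens.feature_overlap_percentages(classified["B6"], ann)
        feats.to_csv(outdir / "feature_percentages_B6.tsv", sep="\t", index=False)
        summary["density"] = {"class1_vs_class2B_RJ2": corr}
        summary["feature_percentages_B6"] = {
            row["class"]: {
                k: (None if pd.isna(row[k]) else round(float(row[k]), 2))
                for k in ("promoter", "genic", "intergenic", "cpg")
            }
            for _, row in feats.iterrows()
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'density' failed: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1)
    logger.info("pipeline complete: %s", outdir / "summary.json")
    return summary
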