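"""Stage orchestration: seeded end-to-end runs with a JSON manifest.

Each stage writes its outputs under the run directory and records them
(with SHA-256 checksums) in ``manifest.json`` together with the full
parameter set, so a rerun with the same configuration is byte-identical
and auditable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as annot
from . import callset, copynumber, io, stats
from .hotspots import hotspot_analysis
from .caller import CallerParams, call_numts, calls_to_frame, depth_track_from_records, scan_discordant
from .genome import demo_genome
from .simulate import (
    CohortDesign, NumtEvent, TissueSpec,
    simulate_cohort, simulate_longitudinal, simulate_read_evidence, lifespan_design,
)

STAGES = ("simulate", "call", "merge", "somatic", "hotspot", "annotate", "rates")
OPTIONAL_STAGES = ("mtdnacn",)

#: Default thresholds mirror the detection and testing criteria used
#: throughout the package: MAPQ 10, support 4, depth 5x, quality 50,
#: merge window +/-50 bp, 10 Mb bins, alpha 0.05.
DEFAULT_CONFIG = {
    "seed": 0,
    "genome": {"n_chroms": 3, "length": 20_000_000},
    "cohort": {
        "tissues": {"DLPFC": [30, 4.13], "cerebellum": [20, 0.75],
                    "PCC": [10, 1.71], "WB": [20, 3.62]},
    },
    "evidence": {"depth": 30.0, "vaf": 0.5, "event_length": 2000},
    "thresholds": {"min_mapq": 10, "min_support": 4, "min_depth": 5.0,
                   "min_qual": 50.0, "merge_window": 50},
    "hotspot": {"width": 10_000_000, "iterations": 1000, "alpha": 0.05},
    "rates": {"arms": ["none", "SURF1"]},
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _merge_config(config: dict | None) -> dict:
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key].update(value)
        else:
            out[key] = value
    return out


def run_pipeline(
    config: dict | None = None,
    stages: tuple[str, ...] = STAGES,
    outdir: str | Path = "numtpipe_run",
) -> dict:
    """Run an ordered subset of stages on the configured demo scenario.

    Later stages consume the in-memory artifacts of earlier ones; asking
    for a stage whose inputs were not produced raises with the name of the
    missing upstream stage.  Returns the manifest dict (also written to
    ``manifest.json``).
    """
    cfg = _merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg["seed"])
    ctx: dict = {}
    manifest: dict = {"seed": cfg["seed"], "parameters": cfg, "stages": {}}

    def record(stage: str, files: dict[str, Path]):
        manifest["stages"][stage] = {
            "outputs": {f.name: _sha256(f) for f in files.values()}
        }

    def need(stage: str, *keys):
        for key in keys:
            if key not in ctx:
                raise RuntimeError(
                    f"stage {stage!r} requires artifacts from an earlier stage "
                    f"(missing {key!r}); run the producing stage first"
                )

    for stage in stages:
        if stage == "simulate":
            model = demo_genome(**cfg["genome"])
            tissues = tuple(
                TissueSpec(name, int(n), float(rate))
                for name, (n, rate) in cfg["cohort"]["tissues"].items()
            )
            design = CohortDesign(tissues=tissues, age_effect_tissues=("DLPFC",))
            cohort = simulate_cohort(rng, model, design)
            lon = simulate_longitudinal(rng, model, lifespan_design())
            ev_cfg = cfg["evidence"]
            event = NumtEvent(
                chrom=model.names[0], position=model.chromosomes[model.names[0]] // 2,
                mt_start=100, mt_end=(100 + ev_cfg["event_length"]) % model.mt_length,
                length=ev_cfg["event_length"], vaf=ev_cfg["vaf"],
            )
            records = simulate_read_evidence(rng, event, ev_cfg["depth"], model)
            files = {
                "cohort_calls": outdir / "cohort_calls.tsv",
                "samples": outdir / "samples.tsv",
                "population_refs": outdir / "population_refs.tsv",
                "longitudinal": outdir / "longitudinal_counts.tsv",
                "evidence": outdir / "evidence.sam",
            }
            cohort.calls.to_csv(files["cohort_calls"], sep="\t", index=False)
            cohort.samples.to_csv(files["samples"], sep="\t", index=False)
            cohort.population_reference.to_csv(
                files["population_refs"], sep="\t", index=False, header=False
            )
            lon.counts.to_csv(files["longitudinal"], sep="\t", index=False)
            io.write_sam(records, files["evidence"], model)
            ctx.update(model=model, cohort=cohort, longitudinal=lon,
                       evidence=records, planted_event=event)
            record(stage, files)
        elif stage == "call":
            need(stage, "evidence", "model")
            th = cfg["thresholds"]
            params = CallerParams(
                min_mapq=th["min_mapq"], min_support=th["min_support"],
                min_depth=th["min_depth"], min_qual=th["min_qual"],
                mt_name=ctx["model"].mt_name,
            )
            clusters = scan_discordant(ctx["evidence"], params)
            track = depth_track_from_records(
                ctx["evidence"], ctx["model"].chromosomes
            )
            calls = call_numts(clusters, track, params, sample_id="demo")
            frame = calls_to_frame(calls)
            files = {"calls": outdir / "calls.vcf"}
            io.write_calls_vcf(frame, files["calls"], ctx["model"])
            ctx["calls"] = frame
            record(stage, files)
        elif stage == "merge":
            need(stage, "cohort", "model")
            unified = callset.merge_callsets(
                ctx["cohort"].calls, window=cfg["thresholds"]["merge_window"],
                samples=ctx["cohort"].samples["sample_id"].tolist(),
            )
            files = {"merged": outdir / "merged.vcf",
                     "loci": outdir / "merged_loci.tsv"}
            io.write_merged_vcf(unified, files["merged"], ctx["model"])
            unified.loci.to_csv(files["loci"], sep="\t", index=False)
            ctx["unified"] = unified
            record(stage, files)
        elif stage == "somatic":
            need(stage, "unified", "cohort")
            filtered, removed = callset.filter_population(
                ctx["unified"], ctx["cohort"].population_reference,
                window=cfg["thresholds"]["merge_window"],
            )
            exclusive = callset.exclusive_calls(
                filtered, ctx["cohort"].samples, grouping="tissue"
            )
            counts = callset.per_sample_counts(
                ctx["unified"], exclusive, ctx["cohort"].samples
            )
            files = {"somatic": outdir / "somatic_loci.tsv",
                     "counts": outdir / "per_sample_counts.tsv"}
            exclusive.loci.to_csv(files["somatic"], sep="\t", index=False)
            counts.to_csv(files["counts"], sep="\t", index=False)
            ctx["exclusive"] = exclusive
            ctx["removed_population"] = removed
            record(stage, files)
        elif stage == "hotspot":
            need(stage, "exclusive", "model")
            hs = hotspot_analysis(
                rng, ctx["exclusive"].loci, ctx["model"],
                width=cfg["hotspot"]["width"],
                n_iter=cfg["hotspot"]["iterations"],
                alpha=cfg["hotspot"]["alpha"],
            )
            files = {"hotspots": outdir / "hotspots.tsv"}
            hs.to_csv(files["hotspots"], sep="\t", index=False)
            ctx["hotspots"] = hs
            record(stage, files)
        elif stage == "annotate":
            need(stage, "exclusive", "model")
            cats = annot.classify_sites(ctx["exclusive"].loci, ctx["model"])
            tally = annot.enrichment_test(
                cats.value_counts().to_dict(), ctx["model"]
            )
            files = {"annotation": outdir / "genic_content.tsv"}
            tally.to_csv(files["annotation"], sep="\t", index=False)
            ctx["annotation"] = tally
            record(stage, files)
        elif stage == "rates":
            need(stage, "longitudinal")
            counts = ctx["longitudinal"].counts
            rows = []
            for arm, grp in counts.groupby("treatment"):
                fit = stats.fit_rate(grp["day"], grp["count"])
                rows.append(dict(
                    treatment=arm, slope_per_day=fit.slope,
                    rate_per_10_days=fit.rate_per_10_days,
                    r_squared=fit.r_squared, pvalue=fit.pvalue, n=fit.n,
                ))
            table = pd.DataFrame(rows)
            arm_a, arm_b = cfg["rates"]["arms"]
            sub = counts[counts.treatment.isin([arm_a, arm_b])].copy()
            sub["norm"] = stats.normalize_by_group_median(
                sub["count"].to_numpy(), sub["treatment"].to_numpy()
            )
            a = sub[sub.treatment == arm_a]
            b = sub[sub.treatment == arm_b]
            f, p = stats.compare_slopes(a["day"], a["norm"], b["day"], b["norm"],
                                        labels=(arm_a, arm_b))
            comparison = pd.DataFrame(
                [dict(arm_a=arm_a, arm_b=arm_b, f_statistic=f, pvalue=p)]
            )
            files = {"rates": outdir / "rates.tsv",
                     "slope_comparison": outdir / "slope_comparison.tsv"}
            table.to_csv(files["rates"], sep="\t", index=False)
            comparison.to_csv(files["slope_comparison"], sep="\t", index=False)
            ctx["rates"] = table
            record(stage, files)
        elif stage == "mtdnacn":
            need(stage, "model")
            model = ctx["model"]
            # synthetic coverage: flat 30x autosomes, mtDNAcn=200 worth of mtDNA
            track = {c: np.full(l, 30.0) for c, l in model.chromosomes.items()}
            track[model.mt_name] = np.full(model.mt_length, 3000.0)
            summary = copynumber.coverage_summary(track, model)
            cn = copynumber.compute_mtdnacn(summary)
            files = {"mtdnacn": outdir / "mtdnacn.tsv"}
            pd.DataFrame([dict(sample="demo", cov_mt=summary.cov_mt,
                               cov_autosomal=summary.cov_autosomal,
                               mtdnacn=cn)]).to_csv(files["mtdnacn"], sep="\t",
                                                    index=False)
            ctx["mtdnacn"] = cn
            record(stage, files)
        else:
            raise ValueError(f"unknown stage {stage!r}")

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
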