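"""End-to-end orchestration: regions -> counts -> TPM -> junctions ->
decomposition -> methylation/consensus/single-cell reports.

A single YAML config drives the run.  Inputs are either paths to the
standard formats each module reads or a ``simulate`` section, in which
case the synthetic generators write those same files first and the
pipeline consumes them through the ordinary readers.  The report is
machine-readable JSON, byte-identical across runs with the same seed and
inputs (no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .annotation import (
    RepeatFeature,
    build_quantification_regions,
    parse_gtf,
    read_repeat_features,
    write_gtf,
    write_regions_gtf,
)
from .consensus import consensus_divergence, filter_references_by_length, read_fasta, write_fasta
from .decomposition import (
    fit_contribution_model,
    fit_driver_model,
    group_compare,
    read_sample_table,
)
from .intervals import GenomicInterval
from .methylation import read_bedmethyl, summarize_region_methylation, write_bedmethyl
from .quantify import CountingPolicy, JunctionResult, classify_ltr_activity, count_reads, cpm, find_junction_reads, tpm_normalize
from .reads import read_block_table, read_sam, write_block_table
from .single_cell import (
    CellTable,
    composition_of_expressing_cells,
    fraction_expressing_by_celltype,
    patient_expressing_type_percentage,
    stratify_cells_by_expression,
)
from . import simulate as sim


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage name and cause."""


@dataclass
class PipelineConfig:
    output_dir: str
    seed: int = 0
    simulate: dict | None = None
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "output_dir" not in raw:
            raise ConfigError("config must set output_dir")
        return cls(**raw)

    def validate(self) -> None:
        for key, value in self.inputs.items():
            paths = value.values() if isinstance(value, dict) else [value]
            for p in paths:
                if not Path(p).exists():
                    raise ConfigError(f"input {key!r}: path does not exist: {p}")


def _parse_region_string(s: str) -> GenomicInterval:
    chrom, rng = s.rsplit(":", 1)
    start, end = rng.split("-")
    return GenomicInterval(chrom, int(start), int(end))


def _read_alignments(path: str | Path):
    path = Path(path)
    if path.suffix in {".sam", ".bam"}:
        return list(read_sam(path))
    return list(read_block_table(path))


def _simulate_inputs(config: PipelineConfig, outdir: Path) -> dict:
    """Write synthetic inputs as files and return the inputs mapping."""
    simconf = config.simulate or {}
    indir = outdir / "inputs"
    indir.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, Any] = {}

    locus = sim.LocusSpec(seed=config.seed, **simconf.get("locus", {}))
    write_gtf(sim.locus_transcripts(locus), indir / "locus.gtf")
    feats = sim.locus_repeat_features(locus) + [sim.locus_repeat_body(locus)]
    with open(indir / "repeats.bed", "w") as fh:
        for f in feats:
            iv = f.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{f.name}\t0\t{iv.strand}\n")
    inputs["annotation"] = str(indir / "locus.gtf")
    inputs["repeats"] = str(indir / "repeats.bed")

    reads_conf = dict(simconf.get("reads", {}))
    n_samples = int(reads_conf.pop("n_samples", 3))
    alignments = {}
    for i in range(n_samples):
        s = sim.LocusSpec(seed=config.seed + 1000 + i, **reads_conf)
        result = sim.simulate_reads(s)
        path = indir / f"reads_s{i:02d}.tsv"
        write_block_table(result.reads, path)
        alignments[f"s{i:02d}"] = str(path)
    inputs["alignments"] = alignments

    cohort = sim.default_cohort_spec(seed=config.seed + 2000, **simconf.get("cohort", {}))
    samples, _truth = sim.simulate_cohort(cohort)
    samples.to_csv(indir / "samples.tsv", sep="\t")
    inputs["samples"] = str(indir / "samples.tsv")

    meth_conf = dict(simconf.get("methylation", {}))
    ltr_s, ltr_e = locus.repeats["LTR5Hs"]
    region = GenomicInterval(locus.chrom, ltr_s, ltr_e)
    calls = sim.simulate_methylation(region, seed=config.seed + 3000, **meth_conf)
    write_bedmethyl(calls, indir / "methylation.tsv")
    inputs["methylation"] = str(indir / "methylation.tsv")
    config.params.setdefault("methylation", {}).setdefault(
        "region", f"{locus.chrom}:{ltr_s}-{ltr_e}"
    )

    msa = sim.simulate_msa(seed=config.seed + 4000, **simconf.get("msa", {}))
    write_fasta(msa, indir / "msa.fasta")
    inputs["msa"] = str(indir / "msa.fasta")

    cells = sim.simulate_cell_matrix(seed=config.seed + 5000, **simconf.get("cells", {}))
    cells.to_tsv(indir / "cells.tsv")
    inputs["cells"] = str(indir / "cells.tsv")
    return inputs


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the report dict (also written to ``report.json`` and
    summarised in ``summary.md``).  A stage failure aborts the run with
    :class:`PipelineError` naming the stage; outputs of completed stages
    are retained alongside a ``FAILED_<stage>`` marker.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            "simulate": config.simulate,
            "inputs": dict(config.inputs),
            "params": config.params,
        },
        "stages": {},
    }
    params = config.params
    current_stage = "preflight"

    try:
        if config.simulate is not None:
            current_stage = "simulate"
            config.inputs = {**_simulate_inputs(config, outdir), **config.inputs}
            report["stages"]["simulate"] = {"status": "ok", "inputs": config.inputs}
        config.validate()

        regions = None
        if "annotation" in config.inputs and "repeats" in config.inputs:
            current_stage = "regions"
            transcripts = parse_gtf(config.inputs["annotation"])
            feats = read_repeat_features(config.inputs["repeats"])
            rp = params.get("regions", {})
            body_name = rp.get("body_feature", "ERVK-7")
            body = next((f for f in feats if f.name == body_name), None)
            if body is None:
                raise ConfigError(f"repeat feature {body_name!r} not found")
            rules = rp.get("rules") or sim._default_region_rules()
            regions = build_quantification_regions(transcripts, body, rules)
            write_regions_gtf(regions, outdir / "regions.gtf")
            report["stages"]["regions"] = {
                "status": "ok",
                "effective_length": regions.effective_length,
            }

        count_table = None
        if regions is not None and "alignments" in config.inputs:
            current_stage = "counts"
            aln_paths = config.inputs["alignments"]
            if not isinstance(aln_paths, dict):
                aln_paths = {Path(p).stem: p for p in aln_paths}
            policy = CountingPolicy(**params.get("counting", {}))
            alignments = {s: _read_alignments(p) for s, p in sorted(aln_paths.items())}
            count_table = count_reads(alignments, regions, policy)
            count_table.counts.to_csv(outdir / "counts.tsv", sep="\t")
            tpm = tpm_normalize(count_table, regions.effective_length)
            tpm.to_csv(outdir / "tpm.tsv", sep="\t")
            report["stages"]["counts"] = {
                "status": "ok",
                "library_size": count_table.library_size,
                "skipped_unknown_chrom": count_table.skipped_unknown_chrom,
            }

            current_stage = "junctions"
            jp = params.get("junction", {})
            feats = read_repeat_features(config.inputs["repeats"])
            by_name = {f.name: f.interval for f in feats}
            a_name = jp.get("region_a", "LTR5Hs")
            b_name = jp.get("region_b", "HERVK-int")
            if a_name in by_name and b_name in by_name:
                results = []
                for s, reads in alignments.items():
                    n, _ids = find_junction_reads(reads, by_name[a_name], by_name[b_name], policy)
                    lib = count_table.library_size[s]
                    results.append(
                        JunctionResult(s, n, cpm(n, lib) if lib else 0.0)
                    )
                flags, summary = classify_ltr_activity(results, jp.get("threshold", 1))
                with open(outdir / "junctions.tsv", "w") as fh:
                    fh.write("sample_id\tjunction_count\tcpm\tactive\n")
                    for r in results:
                        fh.write(f"{r.sample_id}\t{r.junction_count}\t{r.cpm:.6g}\t{r.active}\n")
                report["stages"]["junctions"] = {"status": "ok", **summary}

        if "samples" in config.inputs:
            current_stage = "decomposition"
            samples = read_sample_table(config.inputs["samples"])
            eps = params.get("epsilon", 0.01)
            fit = fit_contribution_model(samples, epsilon=eps)
            contrib = fit.transform(samples)
            contrib.join(samples["group"]).to_csv(outdir / "contributions.tsv", sep="\t")
            group_stats = {}
            for gname, sub in contrib.join(samples["group"]).groupby("group"):
                group_stats[str(gname)] = {
                    "mean_log_ratio": float(sub["log_ratio"].mean()),
                    "median_log_ratio": float(sub["log_ratio"].median()),
                    "n": int(len(sub)),
                }
            correlations = {}
            for col, label in [("tpm_long", "long_vs_gene"), ("tpm_short", "short_vs_gene")]:
                rho, p = group_compare(samples[col], samples["tpm_gene"], test="spearman")
                correlations[label] = {"spearman_rho": rho, "p_value": p}
            report["stages"]["decomposition"] = {
                "status": "ok",
                "fit": {
                    "a": fit.a_,
                    "b": fit.b_,
                    "c": fit.intercept_,
                    "r_squared": fit.r_squared_,
                    "n": fit.n_samples_,
                },
                "group_log_ratio": group_stats,
                "correlations": correlations,
            }
            with open(outdir / "fit.json", "w") as fh:
                json.dump(report["stages"]["decomposition"]["fit"], fh, indent=2, sort_keys=True)

            driver_cols = {"copy_number", "tnf_score", "ifn_score"}
            if driver_cols <= set(samples.columns):
                current_stage = "drivers"
                drv = fit_driver_model(samples)
                drv.summary_frame().to_csv(outdir / "drivers.tsv", sep="\t")
                report["stages"]["drivers"] = {
                    "status": "ok",
                    "coefficients": {k: float(v) for k, v in drv.coef_.items()},
                    "p_values": {k: float(v) for k, v in drv.pvalues_.items()},
                }

        if "methylation" in config.inputs:
            current_stage = "methylation"
            mp = dict(params.get("methylation", {}))
            region = _parse_region_string(mp.pop("region"))
            calls = read_bedmethyl(config.inputs["methylation"])
            summary = summarize_region_methylation(calls, region, **mp)
            report["stages"]["methylation"] = {
                "status": "ok",
                **{k: (v if v == v else None) for k, v in dataclasses.asdict(summary).items()},
            }

        if "msa" in config.inputs:
            current_stage = "consensus"
            cp = params.get("consensus", {})
            msa = read_fasta(config.inputs["msa"])
            query_id = cp.get("query_id", "query")
            min_len = cp.get("min_len")
            if min_len is not None:
                refs = {k: v for k, v in msa.items() if k != query_id}
                kept, _discarded = filter_references_by_length(refs, min_len)
                msa = {**kept, query_id: msa[query_id]}
            diffs = consensus_divergence(msa, query_id, cp.get("min_consensus_freq", 0.8))
            report["stages"]["consensus"] = {
                "status": "ok",
                "n_diffs": len(diffs),
                "diffs": [dataclasses.asdict(d) for d in diffs],
            }

        if "cells" in config.inputs:
            current_stage = "single_cell"
            sc = params.get("single_cell", {})
            cells = CellTable.from_tsv(config.inputs["cells"])
            feature = sc.get("feature", sim.LONG)
            annotation_col = sc.get("annotation_col", "cell_type_detail")
            composition = composition_of_expressing_cells(
                cells, feature, annotation_col=annotation_col
            )
            fractions, omitted = fraction_expressing_by_celltype(
                cells,
                feature,
                min_cells_per_type=sc.get("min_cells_per_type", 600),
                annotation_col=annotation_col,
            )
            strata = stratify_cells_by_expression(
                cells, feature, high_threshold=sc.get("high_threshold", 10)
            )
            type_set = sc.get("type_set", ["tumor", "AT2", "fibroblast"])
            per_patient, (tstat, pval) = patient_expressing_type_percentage(
                cells, type_set, annotation_col=annotation_col
            )
            per_patient.to_csv(outdir / "patient_type_percentage.tsv", sep="\t")
            report["stages"]["single_cell"] = {
                "status": "ok",
                "feature": feature,
                "composition_pct": {str(k): float(v) for k, v in composition.items()},
                "fraction_expressing": {str(k): float(v) for k, v in fractions.items()},
                "omitted_small_types": [str(x) for x in omitted],
                "n_high": int((strata == "high").sum()),
                "n_low": int((strata == "low").sum()),
                "tissue_comparison": {
                    "t": tstat if tstat == tstat else None,
                    "p": pval if pval == pval else None,
                },
            }
    except ConfigError:
        raise
    except Exception as exc:
        (outdir / f"FAILED_{current_stage}").touch()
        report["stages"][current_stage] = {"status": "failed", "error": str(exc)}
        _write_report(report, outdir)
        raise PipelineError(f"stage {current_stage!r} failed: {exc}") from exc

    _write_report(report, outdir)
    return report


def _write_report(report: dict, outdir: Path) -> None:
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=False, default=str)
        fh.write("\n")
    lines = [f"# erviso run (version {report['version']}, seed {report['seed']})", ""]
    for stage, info in report["stages"].items():
        lines.append(f"## {stage}: {info.get('status', '?')}")
        for key, value in info.items():
            if key == "status":
                continue
            lines.append(f"- {key}: {json.dumps(value, sort_keys=True, default=str)}")
        lines.append("")
    (outdir / "summary.md").write_text("\n".join(lines))
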