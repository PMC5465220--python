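"""End-to-end orchestration: simulate -> normalize -> call -> synergy ->
enrich, and the plate growth screen, with a deterministic run manifest.

Every threshold actually used (read filter, pseudocount, SD multiplier,
consensus support, growth gates, motif linker range) is echoed in the
manifest JSON so a run can be reproduced bit-for-bit from it.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import __version__
from . import deviation as dv
from . import enrichment as en
from . import expression as ex
from . import growth as gr
from . import simulate as sim

__all__ = ["RunConfig", "run_expression_pipeline", "run_growth_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and paths for a pipeline run.

    Defaults are the study's printed values: >100-read background filter,
    pseudocount 1 before log2, +/-2 SD deviation cutoff, consensus support
    2, OD floor 0.055 with at most 5 decreases, R^2 > 0.9 and RMSE < 0.2
    fit gates, dual-motif linker 1-8 nt.
    """

    outdir: str = "pufpipe_out"
    seed: int = 0
    min_reads: int = 100
    pseudocount: float = 1.0
    sd_multiplier: float = 2.0
    min_support: int = 2
    qc_threshold: float = 0.9
    linker_min: int = 1
    linker_max: int = 8
    od_floor: float = 0.055
    max_decreases: int = 5
    r2_gate: float = 0.9
    rmse_gate: float = 0.2
    # inputs: paths, or None to simulate
    counts_path: str | None = None
    metadata_path: str | None = None
    plate_path: str | None = None
    layout_path: str | None = None
    gene_sets_path: str | None = None
    utr_fasta_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def _manifest(config: RunConfig, stage: str, extra: dict | None = None) -> dict:
    man = {
        "tool": "pufstress",
        "version": __version__,
        "stage": stage,
        "config": asdict(config),
    }
    if extra:
        man.update(extra)
    return man


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_expression_pipeline(
    config: RunConfig,
    matrix: ex.CountMatrix | None = None,
    gene_sets: list[en.GeneSet] | None = None,
) -> dict:
    """Filter -> size factors -> normalize -> QC -> ratios -> deviation
    calls -> synergy -> consensus -> enrichment; writes TSVs + manifest.

    When no matrix is given it is loaded from the configured paths, or
    simulated with the default design when no paths are configured either.
    Returns a dict of the in-memory results keyed by stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    if matrix is None:
        if config.counts_path and config.metadata_path:
            matrix = ex.read_counts(config.counts_path, config.metadata_path)
        else:
            design = sim.ExpressionDesign(seed=config.seed)
            matrix, truth = sim.simulate_counts(design)
            results["truth"] = truth
            sim.write_expression_files(matrix, truth, out)

    t0 = _stage("filter")
    filtered = ex.filter_background(matrix, min_reads=config.min_reads)
    t0 = _stage("normalize")
    factors = ex.size_factors(filtered)
    norm = ex.normalize(filtered, factors)
    norm.to_csv(out / "normalized.tsv", sep="\t", index_label="gene_id")
    results["filtered"] = filtered
    results["size_factors"] = factors
    results["normalized"] = norm

    _stage("qc")
    rho, flagged_pairs = ex.replicate_qc(norm, filtered.samples, config.qc_threshold)
    rho.to_csv(out / "qc_spearman.tsv", sep="\t")
    results["qc"] = rho
    results["qc_flagged"] = flagged_pairs

    _stage("ratios")
    samples = filtered.samples
    batches = sorted(samples["replicate_batch"].astype(str).unique())
    tps = set(samples["timepoint"])
    contrasts = [c for c in ("T45/T0", "Tend/T0") if c.split("/")[0] in tps]
    profiles: dict[tuple, ex.RatioProfile] = {}
    ratio_rows = []
    for strain in samples["strain"].unique():
        for batch in batches:
            for contrast in contrasts:
                try:
                    prof = ex.log_ratio(norm, samples, strain, batch, contrast,
                                        config.pseudocount)
                except KeyError:
                    continue  # incomplete batch (e.g. a missing replicate)
                profiles[(strain, batch, contrast)] = prof
                df = prof.log2_ratio.rename("log2_ratio").rename_axis("gene_id").reset_index()
                df.insert(0, "contrast", contrast)
                df.insert(0, "replicate_batch", batch)
                df.insert(0, "strain", strain)
                ratio_rows.append(df)
    pd.concat(ratio_rows).to_csv(out / "ratios.tsv", sep="\t", index=False)
    results["profiles"] = profiles

    _stage("deviation calls")
    parents = dict(sim.DEFAULT_PARENTS)
    dbl, s1, s2 = sim.DEFAULT_DOUBLE
    call_rows = []
    per_replicate_flags: dict[tuple, list[set]] = {}
    for (strain, batch, contrast), prof in profiles.items():
        if strain in parents:  # knockout vs parent trend caller
            key = (parents[strain], batch, contrast)
            if key not in profiles:
                continue
            res = dv.TrendDeviationModel(profiles[key], prof,
                                         config.sd_multiplier).fit()
        else:  # wild type: mean-deviation caller
            res = dv.MeanDeviationModel(prof, config.sd_multiplier).fit()
        df = res.calls.copy()
        df.insert(0, "contrast", contrast)
        df.insert(0, "replicate_batch", batch)
        df.insert(0, "strain", strain)
        call_rows.append(df)
        per_replicate_flags.setdefault((strain, contrast), []).append(res.flagged())
        results[("calls", strain, batch, contrast)] = res
    pd.concat(call_rows).to_csv(out / "deviation_calls.tsv", sep="\t", index=False)

    _stage("synergy")
    syn_rows = []
    for batch in batches:
        for contrast in contrasts:
            keys = [(dbl, batch, contrast), (s1, batch, contrast), (s2, batch, contrast)]
            if not all(k in profiles for k in keys):
                continue
            res = dv.SynergyModel(profiles[keys[0]], profiles[keys[1]],
                                  profiles[keys[2]], config.sd_multiplier).fit()
            df = res.calls.copy()
            df.insert(0, "contrast", contrast)
            df.insert(0, "replicate_batch", batch)
            syn_rows.append(df)
            per_replicate_flags.setdefault(("synergy", contrast), []).append(res.flagged())
            results[("synergy", batch, contrast)] = res
    if syn_rows:
        pd.concat(syn_rows).to_csv(out / "synergy_calls.tsv", sep="\t", index=False)

    _stage("consensus")
    consensus_rows = []
    consensus: dict[tuple, set] = {}
    for (label, contrast), sets in per_replicate_flags.items():
        cons = dv.replicate_consensus(sets, config.min_support)
        consensus[(label, contrast)] = cons
        consensus_rows += [dict(analysis=label, contrast=contrast, gene_id=g)
                           for g in sorted(cons)]
    pd.DataFrame(consensus_rows, columns=["analysis", "contrast", "gene_id"]).to_csv(
        out / "consensus.tsv", sep="\t", index=False)
    results["consensus"] = consensus

    if gene_sets is None and config.gene_sets_path:
        gene_sets = en.read_gmt(config.gene_sets_path)
    if gene_sets:
        _stage("enrichment")
        background = set(filtered.gene_ids)
        enr_rows = []
        for (label, contrast), flagged in consensus.items():
            for gs in gene_sets:
                r = en.gene_set_enrichment(flagged, gs, background)
                enr_rows.append(dict(analysis=label, contrast=contrast, set=gs.name,
                                     N=r.population, K=r.marked, n=r.sample,
                                     k=r.overlap, p=r.p))
        pd.DataFrame(enr_rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        results["enrichment"] = enr_rows

    _write_manifest(out, _manifest(config, "expression",
                                   {"n_genes_filtered": int(filtered.n_genes)}))
    return results


def run_growth_pipeline(config: RunConfig, curves: list[gr.GrowthCurve] | None = None) -> dict:
    """Per-well log-phase fits, per-condition normalized rates with n and SD.

    A strain lacking a valid untreated ("none") control is reported
    unnormalized with a warning.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    if curves is None:
        if not (config.plate_path and config.layout_path):
            raise ValueError("growth pipeline needs plate_path and layout_path (or curves)")
        layout_df = pd.read_csv(config.layout_path, sep="\t", dtype=str)
        layout = {r["well"]: (r["strain"], r["condition"]) for _, r in layout_df.iterrows()}
        curves = gr.read_plate_timeseries(config.plate_path, layout)

    fits = [
        gr.GrowthRateModel(c, config.od_floor, config.max_decreases,
                           config.r2_gate, config.rmse_gate).fit()
        for c in curves
    ]
    report = gr.fits_to_frame(fits, curves)

    # normalize each treated condition to the same strain's untreated control
    mu = {f.well_id: f for f in fits}
    controls: dict[str, list[gr.GrowthFit]] = {}
    for c in curves:
        if c.condition == "none" and mu[c.well_id].valid:
            controls.setdefault(c.strain, []).append(mu[c.well_id])

    norm_col = []
    for _, row in report.iterrows():
        fit = mu[row["well"]]
        ctrl = controls.get(row["strain"])
        if row["condition"] == "none" or not fit.valid or not ctrl:
            if row["condition"] != "none" and not ctrl:
                logger.warning("strain %s has no valid untreated control; "
                               "condition %s reported unnormalized",
                               row["strain"], row["condition"])
            norm_col.append(float("nan"))
        else:
            ctrl_mu = sum(f.slope for f in ctrl) / len(ctrl)
            norm_col.append(fit.slope / ctrl_mu)
    report["normalized_rate"] = norm_col
    report.to_csv(out / "growth_report.tsv", sep="\t", index=False)

    summ_rows = []
    grouped = report[report["normalized_rate"].notna()].groupby(["strain", "condition"])
    for (strain, condition), grp in grouped:
        agg = gr.aggregate_replicates(grp["normalized_rate"].tolist())
        summ_rows.append(dict(strain=strain, condition=condition,
                              normalized_rate=agg.normalized_rate, sd=agg.sd,
                              n=agg.n, low_n=agg.low_n))
    summary = pd.DataFrame(summ_rows,
                           columns=["strain", "condition", "normalized_rate",
                                    "sd", "n", "low_n"])
    summary.to_csv(out / "growth_summary.tsv", sep="\t", index=False)

    _write_manifest(out, _manifest(config, "growth", {"n_wells": len(curves)}))
    return {"fits": fits, "report": report, "summary": summary}
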