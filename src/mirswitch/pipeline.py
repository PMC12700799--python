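"""End-to-end orchestration: simulate (or load) data, then run the analysis
stages and write all tables plus a machine-readable run log.

Two input modes share the same stage logic:

* ``simulate: true`` (default) - everything is generated by the seeded
  simulator, ground truth included, so the whole analysis is verifiable;
* ``simulate: false`` - counts, catalogs, predictions, UTRs and CLASH reads
  are loaded from the paths named in the config.  Missing inputs for a
  requested stage fail pre-flight, before any computation.
"""

from __future__ import annotations

import hashlib
from dataclasses import replace
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
from Bio import SeqIO

from . import __version__
from .core import (
    CountMatrix,
    Genotype,
    load_counts,
    read_exclusion_list,
    read_hairpin_catalog,
    write_counts,
    write_hairpin_catalog,
    write_run_log,
)
from .quantify import class_fractions, normalize
from .simulate import (
    GroundTruth,
    SimulationParams,
    generate_catalog,
    generate_target_map,
    generate_utrs,
    hairpin_latents,
    simulate_clash_reads,
    simulate_expression,
    simulate_transcriptome,
)
from .stats import ago_enrichment, differential, score_correlation
from .strands import (
    LoadingParams,
    SubstrateForm,
    call_strands,
    detect_strand_switch,
    loading_table,
    score_catalog,
)
from .targets import (
    categorize_genes,
    filter_predictions,
    intersect_downregulated,
    target_shift_tests,
)
from .clash import (
    MirnaIndex,
    UtrIndex,
    annotate_strand_class,
    detect_hybrids,
    filter_hybrids,
    hybrid_summary,
    records_to_frame,
)

ALL_STAGES = ("quantify", "strands", "scores", "enrich", "targets", "clash")

_FILE_MODE_NEEDS = {
    "quantify": ["counts_tsv", "meta_tsv"],
    "strands": ["counts_tsv", "meta_tsv"],
    "scores": ["catalog_fasta", "catalog_table"],
    "enrich": ["counts_tsv", "meta_tsv", "ip_counts_tsv", "ip_meta_tsv"],
    "targets": ["predictions_tsv", "rnaseq_tsv", "rnaseq_meta_tsv", "counts_tsv", "meta_tsv"],
    "clash": ["clash_reads_fasta", "utr_fasta", "predictions_tsv", "catalog_fasta", "catalog_table"],
}


def _params_from_config(config: Mapping[str, Any]) -> SimulationParams:
    overrides = dict(config.get("params", {}))
    loading_over = overrides.pop("loading", {})
    params = SimulationParams(seed=int(config["seed"]), **overrides)
    if loading_over:
        params = replace(params, loading=LoadingParams(**loading_over))
    return params


def _preflight(config: Mapping[str, Any], stages: tuple[str, ...]) -> None:
    """Fail before any computation if a requested stage lacks its inputs."""
    if "seed" not in config:
        raise ValueError("config must set an explicit seed (no wall-clock seeding)")
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; expected subset of {ALL_STAGES}")
    if config.get("simulate", True):
        return
    for stage in stages:
        for key in _FILE_MODE_NEEDS.get(stage, []):
            if key not in config or not config[key]:
                raise ValueError(f"stage {stage!r} requires config key {key!r}")


def _read_fasta_dict(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper().replace("T", "U") for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(config: Mapping[str, Any]) -> dict[str, Any]:
    """Execute the configured stages and write every table under ``out_dir``.

    Returns a dict of in-memory results keyed by stage.  Identical config +
    seed gives byte-identical outputs.
    """
    stages = tuple(config.get("stages", ALL_STAGES))
    _preflight(config, stages)
    simulate = bool(config.get("simulate", True))
    out_dir = Path(config.get("out_dir", "mirswitch_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    params = _params_from_config(config)
    n_reps = int(config.get("n_replicates", 6))
    results: dict[str, Any] = {"params": params}

    # ---- inputs -----------------------------------------------------------
    gt: dict[Genotype, GroundTruth] = {}
    target_map: pd.DataFrame | None = None
    utrs = sites = None
    clash_reads: dict[str, list[tuple[str, str]]] = {}
    rna: CountMatrix | None = None
    ip: CountMatrix | None = None

    if simulate:
        catalog = generate_catalog(params.n_hairpins, params.seed)
        write_hairpin_catalog(catalog, out_dir / "catalog.fasta", out_dir / "catalog.tsv")
        latents = hairpin_latents(catalog, params)
        totals, ips = [], []
        for geno in (Genotype.WT, Genotype.HM):
            g, tot, ipm = simulate_expression(catalog, geno, params, n_reps, latents)
            gt[geno] = g
            totals.append(tot)
            ips.append(ipm)
        total = CountMatrix(
            pd.concat([t.data for t in totals], axis=1),
            {**totals[0].samples, **totals[1].samples},
        )
        ip = CountMatrix(
            pd.concat([t.data for t in ips], axis=1), {**ips[0].samples, **ips[1].samples}
        )
        write_counts(total, out_dir / "mirseq_raw.tsv", out_dir / "mirseq_meta.tsv")
        write_counts(ip, out_dir / "agoip_raw.tsv", out_dir / "agoip_meta.tsv")
        gt[Genotype.WT].strands.to_csv(out_dir / "truth_WT.tsv", sep="\t")
        gt[Genotype.HM].strands.to_csv(out_dir / "truth_HM.tsv", sep="\t")
        target_map = generate_target_map(catalog, params)
    else:
        catalog = (
            read_hairpin_catalog(config["catalog_fasta"], config["catalog_table"])
            if config.get("catalog_fasta")
            else []
        )
        total = load_counts(config["counts_tsv"], config["meta_tsv"]) if config.get("counts_tsv") else None
        if config.get("ip_counts_tsv"):
            ip = load_counts(config["ip_counts_tsv"], config["ip_meta_tsv"])
        if config.get("predictions_tsv"):
            target_map = pd.read_csv(config["predictions_tsv"], sep="\t")
        if config.get("rnaseq_tsv"):
            rna = load_counts(config["rnaseq_tsv"], config["rnaseq_meta_tsv"])
        if config.get("utr_fasta"):
            utrs = _read_fasta_dict(config["utr_fasta"])
        if config.get("clash_reads_fasta"):
            clash_reads["input"] = [
                (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(config["clash_reads_fasta"]), "fasta")
            ]

    # ---- normalization + exclusions ---------------------------------------
    total_norm = ip_norm = None
    if total is not None:
        total_norm = normalize(total, config.get("normalize_total", "spike_in"))
        if ip is not None:
            ip_norm = normalize(ip, config.get("normalize_ip", "total_mirna"))
        if config.get("exclude_list"):
            excl = read_exclusion_list(config["exclude_list"])
            if catalog:
                excl.validate_against(catalog)
            total_norm = excl.apply(total_norm)
            if ip_norm is not None:
                ip_norm = excl.apply(ip_norm)
        total_norm.data.to_csv(out_dir / "mirseq_normalized.tsv", sep="\t", index_label="species_id")
        if ip_norm is not None:
            ip_norm.data.to_csv(out_dir / "agoip_normalized.tsv", sep="\t", index_label="species_id")
        class_fractions(total).to_csv(out_dir / "class_fractions.tsv", sep="\t", index_label="sample_id")
        results["quantify"] = {"total": total_norm, "ip": ip_norm}

    wt_samples = total_norm.sample_ids(genotype=Genotype.WT) if total_norm is not None else []
    hm_samples = total_norm.sample_ids(genotype=Genotype.HM) if total_norm is not None else []
    if total_norm is not None:
        hairpin_ids = sorted(
            {rid[:-3] for rid in total_norm.data.index if rid.endswith("-5p")}
        )
    else:
        hairpin_ids = [h.hairpin_id for h in catalog]

    calls = {}
    if "strands" in stages and total_norm is not None:
        calls = call_strands(total_norm, hairpin_ids, wt_samples)
        pd.DataFrame(
            [
                {
                    "hairpin_id": c.hairpin_id,
                    "guide_arm": c.guide_arm,
                    "fraction_5p": c.fraction_5p,
                    "total_reads": c.total_reads,
                }
                for c in calls.values()
            ]
        ).set_index("hairpin_id").to_csv(out_dir / "strand_calls.tsv", sep="\t")
        if len(wt_samples) >= 2 and len(hm_samples) >= 2:
            switch = detect_strand_switch(calls, total_norm, wt_samples, hm_samples)
            switch.to_csv(out_dir / "switch_table.tsv", sep="\t", index_label="species_id")
            results["strands"] = {"calls": calls, "switch": switch}
        else:
            results["strands"] = {"calls": calls}

    if "scores" in stages and catalog:
        scores = score_catalog(catalog)
        scores.to_csv(out_dir / "scores.tsv", sep="\t")
        loads = pd.concat([loading_table(catalog, form, params.loading) for form in SubstrateForm])
        loads.to_csv(out_dir / "loading.tsv", sep="\t")
        results["scores"] = {"scores": scores, "loading": loads}

    if "enrich" in stages and ip_norm is not None and total_norm is not None:
        ip_cols = ip_norm.sample_ids(genotype=Genotype.HM) or list(ip_norm.data.columns)
        in_cols = hm_samples or list(total_norm.data.columns)
        enrich = ago_enrichment(ip_norm, total_norm, ip_samples=ip_cols, input_samples=in_cols)
        enrich.to_csv(out_dir / "enrichment_HM.tsv", sep="\t", index_label="species_id")
        results["enrich"] = {"enrichment": enrich}
        if "scores" in results and calls:
            scores = results["scores"]["scores"]
            passenger3p = [f"{hid}-3p" for hid, c in calls.items() if c.guide_arm == "5p"]
            corr_rows = []
            for col in ("s3p", "s5p"):
                sc = scores[col].copy()
                sc.index = [f"{hid}-3p" for hid in sc.index]
                corr = score_correlation(enrich["enrichment"], sc, subset=passenger3p)
                corr_rows.append({"score": col, **corr})
            corr_tab = pd.DataFrame(corr_rows).set_index("score")
            corr_tab.to_csv(out_dir / "score_correlation.tsv", sep="\t")
            results["enrich"]["correlation"] = corr_tab

    if "targets" in stages and target_map is not None:
        if simulate:
            gene_truth, rna = simulate_transcriptome(gt, target_map, params, n_reps)
            write_counts(rna, out_dir / "rnaseq_raw.tsv", out_dir / "rnaseq_meta.tsv")
            results.setdefault("targets", {})["gene_truth"] = gene_truth
        assert rna is not None
        rna_wt = rna.sample_ids(genotype=Genotype.WT)
        rna_hm = rna.sample_ids(genotype=Genotype.HM)
        diff = differential(rna, rna_wt, rna_hm)
        diff.to_csv(out_dir / "rnaseq_differential.tsv", sep="\t", index_label="gene_id")
        expression = rna.data[rna_wt].mean(axis=1)
        filtered = filter_predictions(target_map, expression)
        wt_ab = total_norm.data[wt_samples].mean(axis=1)
        hm_ab = total_norm.data[hm_samples].mean(axis=1)
        cats = categorize_genes(filtered, calls, wt_ab, hm_ab)
        cats.to_csv(out_dir / "gene_categories.tsv", sep="\t")
        shifts = target_shift_tests(cats, diff["log2fc"])
        pd.DataFrame(
            [
                {"category": k, "D": v.statistic, "p": v.p, "direction": v.direction,
                 "n_fg": v.n_fg, "n_bg": v.n_bg}
                for k, v in shifts.items()
            ]
        ).to_csv(out_dir / "target_shift_tests.tsv", sep="\t", index=False)
        results.setdefault("targets", {}).update(
            {"differential": diff, "categories": cats, "shifts": shifts}
        )

    if "clash" in stages and target_map is not None:
        if simulate:
            n_clash = int(config.get("clash_reads", 20000))
            utrs, sites = generate_utrs(target_map, catalog, params)
            for geno in (Genotype.WT, Genotype.HM):
                reads, truth = simulate_clash_reads(
                    gt[geno], catalog, target_map, utrs, sites, n_clash, params.seed
                )
                clash_reads[geno.value] = reads
                results.setdefault("clash", {}).setdefault(geno.value, {})["truth"] = truth
                with open(out_dir / f"clash_reads_{geno.value}.fasta", "w") as fh:
                    for rid, seq in reads:
                        fh.write(f">{rid}\n{seq}\n")
        mindex = MirnaIndex(catalog)
        uindex = UtrIndex(utrs)
        summary_rows = []
        for label, reads in clash_reads.items():
            records, failures = detect_hybrids(reads, mindex, uindex)
            records, _removed = filter_hybrids(records, target_map)
            records = annotate_strand_class(records, calls)
            records_to_frame(records).to_csv(out_dir / f"hybrids_{label}.tsv", sep="\t", index=False)
            summary = hybrid_summary(records, calls)
            bucket = results.setdefault("clash", {}).setdefault(label, {})
            bucket.update({"records": records, "failures": failures, "summary": summary})
            summary_rows.append(
                {
                    "sample": label,
                    "n_hybrids": summary["n_hybrids"],
                    "fraction_5p": summary["fraction_5p"],
                    "fraction_3p": summary["fraction_3p"],
                    "passenger_share_3p": summary["passenger_share_3p"],
                }
            )
        pd.DataFrame(summary_rows).to_csv(out_dir / "clash_summary.tsv", sep="\t", index=False)
        # CLASH-supported, significantly downregulated passenger-3p-target genes
        if "targets" in results and "categories" in results["targets"]:
            hm_records = results["clash"].get(Genotype.HM.value, {}).get("records", [])
            clash_genes = sorted({r.gene_id for r in hm_records})
            candidates = intersect_downregulated(
                results["targets"]["categories"],
                results["targets"]["differential"],
                clash_genes,
                q_cut=float(config.get("candidate_q_cut", 0.05)),
                fc_cut=float(config.get("candidate_fc_cut", 0.0)),
            )
            pd.Series(candidates, name="gene_id").to_csv(
                out_dir / "candidate_targets.tsv", sep="\t", index=False
            )
            results["clash"]["candidate_targets"] = candidates

    write_run_log(
        out_dir / "run_log.json",
        {
            "version": __version__,
            "seed": params.seed,
            "simulate": simulate,
            "stages": list(stages),
            "n_replicates": n_reps,
            "params": {k: str(v) for k, v in vars(params).items()},
        },
    )
    results["out_dir"] = out_dir
    return results


def output_digest(out_dir: str | Path) -> str:
    """SHA-256 over all TSV outputs of a run, for determinism checks."""
    h = hashlib.sha256()
    for path in sorted(Path(out_dir).glob("*.tsv")):
        h.update(path.name.encode())
        h.update(path.read_bytes())
    return h.hexdigest()
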