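"""End-to-end evaluation runs: parameter-recovery and calibration measurements.

Each function simulates data with the package's own generator, runs the
corresponding analysis stage, and measures how well the analysis recovers
the generator's ground truth.  These are the quantitative checks behind the
package's verification story; they are also what ``scripts/acceptance.py``
reports.
"""

from __future__ import annotations

import itertools
from dataclasses import replace

import numpy as np
import pandas as pd

from .core import CountMatrix, Genotype
from .clash import MirnaIndex, UtrIndex, detect_hybrids, filter_hybrids
from .quantify import count_species, normalize
from .simulate import (
    SimulationParams,
    generate_catalog,
    generate_target_map,
    generate_utrs,
    guide_truth,
    hairpin_latents,
    planted_switch_set,
    reads_from_counts,
    simulate_clash_reads,
    simulate_expression,
    simulate_transcriptome,
)
from .stats import ago_enrichment, differential, ks_shift, score_correlation
from .strands import (
    SubstrateForm,
    call_strands,
    classify_strands,
    detect_strand_switch,
    loading_table,
)
from .targets import GeneCategory, categorize_genes, filter_predictions, target_shift_tests


def _combined_total(catalog, params, n_reps, latents, genotypes=(Genotype.WT, Genotype.HM)):
    truths, totals, ips = {}, [], {}
    for g in genotypes:
        truths[g], tot, ip = simulate_expression(catalog, g, params, n_reps, latents)
        totals.append(tot)
        ips[g] = ip
    total = CountMatrix(
        pd.concat([t.data for t in totals], axis=1),
        {k: v for t in totals for k, v in t.samples.items()},
    )
    return truths, total, ips


# -- strand rule oracle ------------------------------------------------------

def strand_rule_grid_agreement(max_count: int = 300) -> dict:
    """Exhaustive comparison of classify_strands with a direct transcription of
    the >70% / >100-read rule over all integer count pairs in [0, max]^2."""
    mismatches = 0
    n = 0
    for c5 in range(max_count + 1):
        for c3 in range(max_count + 1):
            if c5 + c3 == 0:
                expected = "none"
            elif c5 / (c5 + c3) > 0.70 and c5 > 100:
                expected = "5p"
            elif c3 / (c5 + c3) > 0.70 and c3 > 100:
                expected = "3p"
            else:
                expected = "none"
            mismatches += classify_strands(c5, c3).guide_arm != expected
            n += 1
    return {"agreement": 1.0 - mismatches / n, "n": n}


# -- 5p loss and strand-switch recovery -------------------------------------

def loss_and_switch_metrics(seed: int, n_hairpins: int = 200, n_reps: int = 6) -> dict:
    params = SimulationParams(seed=seed, n_hairpins=n_hairpins)
    catalog = generate_catalog(n_hairpins, seed)
    latents = hairpin_latents(catalog, params)
    truths, total, _ = _combined_total(catalog, params, n_reps, latents)
    norm = normalize(total, "spike_in")
    wt = norm.sample_ids(genotype=Genotype.WT)
    hm = norm.sample_ids(genotype=Genotype.HM)
    calls = call_strands(norm, [h.hairpin_id for h in catalog], wt)
    guides = guide_truth(truths[Genotype.WT])

    diff = differential(norm, wt, hm)
    g5 = [f"{h}-5p" for h, g in guides.items() if g == "5p"]
    g3 = [f"{h}-3p" for h, g in guides.items() if g == "3p"]

    planted = planted_switch_set(truths[Genotype.WT], truths[Genotype.HM])
    table = detect_strand_switch(calls, norm, wt, hm)
    flagged = set(table.index[table["switched"]])
    tp = len(flagged & planted)
    precision = tp / len(flagged) if flagged else 1.0
    recall = tp / len(planted) if planted else 1.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    )
    return {
        "median_log2fc_5p_guide": float(diff.loc[g5, "log2fc"].median()),
        "median_abs_log2fc_3p_guide": float(diff.loc[g3, "log2fc"].abs().median()),
        "switch_precision": precision,
        "switch_recall": recall,
        "switch_f1": f1,
        "n_planted": len(planted),
        "n_flagged": len(flagged),
        "n_guide_3p_flagged": int(
            ((table["strand_class"] == "guide") & table["switched"]).sum()
        ),
        "n_hairpins": n_hairpins,
    }


# -- score-dependence of AGO enrichment -------------------------------------

def enrichment_correlation_metrics(
    seed: int, n_hairpins: int = 250, n_passengers: int = 100
) -> dict:
    """R^2 of log AGO enrichment against the 3p- and 5p-scores for simulated HM
    passenger 3p species, with deterministic (expectation-level) loading."""
    params = SimulationParams(seed=seed, n_hairpins=n_hairpins, noise=False)
    catalog = generate_catalog(n_hairpins, seed)
    latents = hairpin_latents(catalog, params)
    gt_wt, _, _ = simulate_expression(catalog, Genotype.WT, params, 6, latents)
    gt_hm, total_hm, ip_hm = simulate_expression(catalog, Genotype.HM, params, 6, latents)
    guides = guide_truth(gt_wt)
    passengers = [f"{h}-3p" for h, g in guides.items() if g == "5p"][:n_passengers]
    enrich = ago_enrichment(normalize(ip_hm, "total_mirna"), normalize(total_hm, "spike_in"))
    scores = gt_wt.scores
    s3 = scores["s3p"].copy()
    s3.index = [f"{h}-3p" for h in s3.index]
    s5 = scores["s5p"].copy()
    s5.index = [f"{h}-3p" for h in s5.index]
    c3 = score_correlation(enrich["enrichment"], s3, subset=passengers)
    c5 = score_correlation(enrich["enrichment"], s5, subset=passengers)
    return {"r2_s3p": c3["r2"], "r2_s5p": c5["r2"], "n": c3["n"]}


# -- loading hard zeros ------------------------------------------------------

def loading_hard_zero_metrics(seed: int, n_hairpins: int = 200) -> dict:
    catalog = generate_catalog(n_hairpins, seed)
    nick5 = loading_table(catalog, SubstrateForm.NICK_5P)
    nick3 = loading_table(catalog, SubstrateForm.NICK_3P)
    return {
        "max_p_load_5p_under_nick5p": float(nick5["p_load_5p"].max()),
        "max_p_load_3p_under_nick3p": float(nick3["p_load_3p"].max()),
        "n": n_hairpins,
    }


# -- target-class shifts -----------------------------------------------------

def target_shift_metrics(seed: int, repression_strength: float | None = None) -> dict:
    params = SimulationParams(seed=seed)
    if repression_strength is not None:
        params = replace(params, repression_strength=repression_strength)
    catalog = generate_catalog(params.n_hairpins, seed)
    latents = hairpin_latents(catalog, params)
    truths, total, _ = _combined_total(catalog, params, 6, latents)
    target_map = generate_target_map(catalog, params)
    _, rna = simulate_transcriptome(truths, target_map, params, 6)
    wt_r = rna.sample_ids(genotype=Genotype.WT)
    hm_r = rna.sample_ids(genotype=Genotype.HM)
    diff = differential(rna, wt_r, hm_r)
    norm = normalize(total, "spike_in")
    wt_s = norm.sample_ids(genotype=Genotype.WT)
    hm_s = norm.sample_ids(genotype=Genotype.HM)
    calls = call_strands(norm, [h.hairpin_id for h in catalog], wt_s)
    filtered = filter_predictions(target_map, rna.data[wt_r].mean(axis=1))
    cats = categorize_genes(
        filtered, calls, norm.data[wt_s].mean(axis=1), norm.data[hm_s].mean(axis=1)
    )
    shifts = target_shift_tests(cats, diff["log2fc"])
    return {
        "p_passenger_3p_targets_down": float(
            shifts[GeneCategory.PASSENGER_3P_TARGET.value].p
        ),
        "p_5p_targets_up": float(shifts[GeneCategory.FIVE_P_TARGET.value].p),
        "n_genes": int(params.n_genes),
    }


def target_null_calibration(seed: int, n_seeds: int = 50, alpha: float = 0.01) -> dict:
    """Fraction of null (r=0) simulations where both category tests stay
    non-significant at the working threshold."""
    ok = 0
    for k in range(n_seeds):
        res = target_shift_metrics(seed + 1000 + k, repression_strength=0.0)
        ok += (res["p_passenger_3p_targets_down"] >= alpha) and (
            res["p_5p_targets_up"] >= alpha
        )
    return {"fraction_both_nonsignificant": ok / n_seeds, "n_seeds": n_seeds}


# -- CLASH recovery ----------------------------------------------------------

def clash_metrics(seed: int, n_reads: int = 50000, n_hairpins: int = 200) -> dict:
    params = SimulationParams(seed=seed, n_hairpins=n_hairpins)
    catalog = generate_catalog(n_hairpins, seed)
    latents = hairpin_latents(catalog, params)
    truths, total, _ = _combined_total(catalog, params, 6, latents)
    norm = normalize(total, "spike_in")
    wt_s = norm.sample_ids(genotype=Genotype.WT)
    calls = call_strands(norm, [h.hairpin_id for h in catalog], wt_s)
    passenger_ids = {f"{h}-3p" for h, c in calls.items() if c.guide_arm == "5p"}
    target_map = generate_target_map(catalog, params)
    utrs, sites = generate_utrs(target_map, catalog, params)
    mindex, uindex = MirnaIndex(catalog), UtrIndex(utrs)

    out: dict = {"n_reads": n_reads}
    shares, planted_shares = {}, {}
    precisions, recalls = [], []
    for geno in (Genotype.WT, Genotype.HM):
        gt = truths[geno]
        reads, truth = simulate_clash_reads(
            gt, catalog, target_map, utrs, sites, n_reads, seed
        )
        records, _ = detect_hybrids(reads, mindex, uindex)
        records, _ = filter_hybrids(records, target_map)
        truth_pairs = {
            rid: (m, g)
            for rid, m, g in zip(truth.index, truth["mirna_id"], truth["gene_id"])
            if m
        }
        called = {r.read_id: (r.mirna_id, r.gene_id) for r in records}
        tp = sum(1 for rid, pair in called.items() if truth_pairs.get(rid) == pair)
        precisions.append(tp / len(called) if called else 0.0)
        recalls.append(tp / len(truth_pairs) if truth_pairs else 0.0)
        hyb3 = [r for r in records if r.arm == "3p"]
        shares[geno] = (
            sum(r.mirna_id in passenger_ids for r in hyb3) / len(hyb3) if hyb3 else np.nan
        )
        # planted share from the generator's sampling weights
        w = target_map["affinity"].to_numpy() * gt.strands["loaded"].reindex(
            target_map["mirna_id"]
        ).fillna(0.0).to_numpy()
        is3 = target_map["mirna_id"].str.endswith("-3p").to_numpy()
        w3 = w[is3]
        ids3 = target_map["mirna_id"][is3]
        planted_shares[geno] = float(
            w3[ids3.isin(passenger_ids).to_numpy()].sum() / w3.sum()
        )
    out["precision"] = float(min(precisions))
    out["recall"] = float(min(recalls))
    observed = shares[Genotype.HM] - shares[Genotype.WT]
    planted = planted_shares[Genotype.HM] - planted_shares[Genotype.WT]
    out["passenger_share_increase_observed_pct"] = float(100 * observed)
    out["passenger_share_increase_planted_pct"] = float(100 * planted)
    out["passenger_share_error_pp"] = float(100 * abs(observed - planted))
    return out


# -- statistical calibration -------------------------------------------------

def welch_null_calibration(seed: int, n_seeds: int = 50, n_hairpins: int = 100) -> dict:
    """WT-vs-WT splits: average fraction of species with q < 0.05."""
    fractions = []
    for k in range(n_seeds):
        params = SimulationParams(seed=seed + 2000 + k, n_hairpins=n_hairpins)
        catalog = generate_catalog(n_hairpins, seed + 2000 + k)
        latents = hairpin_latents(catalog, params)
        _, total, _ = simulate_expression(catalog, Genotype.WT, params, 12, latents)
        norm = normalize(total, "spike_in")
        cols = list(norm.data.columns)
        expressed = norm.data.index[norm.data.mean(axis=1) > 5]
        sub = CountMatrix(norm.data.loc[expressed], dict(norm.samples), norm.normalized)
        table = differential(sub, cols[:6], cols[6:])
        fractions.append(float((table["q"] < 0.05).mean()))
    return {"mean_fraction_q_lt_05": float(np.mean(fractions)), "n_seeds": n_seeds}


def ks_oracle_metrics(seed: int) -> dict:
    """Small-sample KS calibration against independent permutation oracles.

    (a) the default (exact) mode at n=4+5 against exhaustive enumeration of
    all 126 group assignments; (b) the asymptotic branch at n=50+50 against a
    seeded Monte-Carlo permutation null.
    """
    rng = np.random.default_rng(seed)
    fg = np.round(rng.normal(-0.5, 1.0, 4), 3)
    bg = np.round(rng.normal(0.0, 1.0, 5), 3)
    res = ks_shift(fg, bg, direction="down")
    pool = np.concatenate([fg, bg])

    def d_down(f, b):
        return max(float(np.mean(f <= x) - np.mean(b <= x)) for x in pool)

    d_obs = d_down(fg, bg)
    hits = total = 0
    for idx in itertools.combinations(range(len(pool)), len(fg)):
        mask = np.zeros(len(pool), bool)
        mask[list(idx)] = True
        hits += d_down(pool[mask], pool[~mask]) >= d_obs - 1e-12
        total += 1
    exact_oracle = hits / total

    fg2 = rng.normal(-0.5, 1.0, 50)
    bg2 = rng.normal(0.0, 1.0, 50)
    res2 = ks_shift(fg2, bg2, direction="down")
    pool2 = np.concatenate([fg2, bg2])
    xs = np.sort(pool2)

    def d2(f, b):
        return np.max(
            np.searchsorted(np.sort(f), xs, side="right") / len(f)
            - np.searchsorted(np.sort(b), xs, side="right") / len(b)
        )

    d_obs2 = d2(fg2, bg2)
    B = 4000
    hits2 = 0
    for _ in range(B):
        idx = rng.permutation(len(pool2))
        hits2 += d2(pool2[idx[:50]], pool2[idx[50:]]) >= d_obs2 - 1e-12
    return {
        "exact_mode_abs_error_vs_enumeration": abs(res.p - exact_oracle),
        "asymp_mode_abs_error_vs_mc": abs(res2.p - hits2 / B),
        "exact_mode_p": float(res.p),
        "asymp_mode_p": float(res2.p),
    }


# -- conservation / normalization suite --------------------------------------

def conservation_metrics(seed: int, n_hairpins: int = 30) -> dict:
    """Exact bookkeeping checks: read-class conservation, spike equalization,
    category partition, hybrid arm-fraction normalization."""
    params = SimulationParams(seed=seed, n_hairpins=n_hairpins, depth=5e3)
    catalog = generate_catalog(n_hairpins, seed)
    latents = hairpin_latents(catalog, params)
    truths, total, _ = _combined_total(catalog, params, 3, latents)

    # read-class conservation on emitted reads
    reads = reads_from_counts(catalog, total)
    counted, unassigned = count_species(reads, catalog, total.samples)
    conservation_violations = sum(
        int(counted.data[sid].sum() + unassigned[sid] != len(reads[sid]))
        for sid in counted.data.columns
    )

    norm = normalize(total, "spike_in")
    sums = np.array([m.spike_in_sum for m in norm.samples.values()])
    spike_max_rel_dev = float(np.abs(sums / sums.mean() - 1).max())

    target_map = generate_target_map(catalog, params)
    _, rna = simulate_transcriptome(truths, target_map, params, 3)
    wt_r = rna.sample_ids(genotype=Genotype.WT)
    wt_s = norm.sample_ids(genotype=Genotype.WT)
    hm_s = norm.sample_ids(genotype=Genotype.HM)
    calls = call_strands(norm, [h.hairpin_id for h in catalog], wt_s)
    filtered = filter_predictions(target_map, rna.data[wt_r].mean(axis=1))
    cats = categorize_genes(
        filtered, calls, norm.data[wt_s].mean(axis=1), norm.data[hm_s].mean(axis=1)
    )
    covered = set(filtered["gene_id"])
    partition_ok = set(cats.index) == covered and cats["category"].isin(
        [c.value for c in GeneCategory]
    ).all()

    utrs, sites = generate_utrs(target_map, catalog, params)
    gt_hm = truths[Genotype.HM]
    reads_c, _ = simulate_clash_reads(gt_hm, catalog, target_map, utrs, sites, 2000, seed)
    records, _ = detect_hybrids(reads_c, MirnaIndex(catalog), UtrIndex(utrs))
    from .clash import hybrid_summary

    summary = hybrid_summary(records, calls)
    arm_fraction_sum = float(summary["fraction_5p"] + summary["fraction_3p"])

    return {
        "read_class_conservation_violations": conservation_violations,
        "spike_in_max_relative_deviation": spike_max_rel_dev,
        "category_partition_ok": int(partition_ok),
        "arm_fraction_sum": arm_fraction_sum,
    }
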