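"""Target-prediction filtering, gene categorization and distribution-shift tests.

Genes are grouped by the predominant miRNA class predicted to target them:

* 5p-targets: cumulative WT abundance of predicted 5p-miRNA regulators
  exceeds that of all 3p regulators (guide + passenger) - these genes lose
  repression when 5p-miRNAs are abolished and should shift up;
* passenger-3p-targets: the gain in passenger 3p-miRNA targeting abundance
  (HM - WT) exceeds the loss of 5p targeting (WT - HM) - these genes acquire
  repression from strand-switched passengers and should shift down.

A gene satisfying both inequalities is assigned passenger-3p-target so the
two contrast sets stay disjoint.
"""

from __future__ import annotations

import enum
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import ShiftTestResult, ks_shift
from .strands import StrandCall


class GeneCategory(str, enum.Enum):
    FIVE_P_TARGET = "FIVE_P_TARGET"
    PASSENGER_3P_TARGET = "PASSENGER_3P_TARGET"
    NEITHER = "NEITHER"


def filter_predictions(
    predictions: pd.DataFrame,
    expression: pd.Series,
    top_fraction: float = 0.10,
    trim_fraction: float = 0.25,
    per_mirna: bool = True,
) -> pd.DataFrame:
    """Keep each miRNA's strongest predicted targets on moderately expressed genes.

    Within each miRNA's prediction list the ``ceil(top_fraction * n)`` targets
    with the most negative context scores survive (ties broken by gene id);
    then genes in the top and bottom ``trim_fraction`` of the expressed-gene
    abundance ranking are dropped.  With ``per_mirna=False`` the top fraction
    is taken over the pooled prediction list instead.
    """
    preds = predictions.drop_duplicates(subset=["mirna_id", "gene_id"]).copy()

    def _top(group: pd.DataFrame) -> pd.DataFrame:
        k = math.ceil(top_fraction * len(group))
        return group.sort_values(["context_score", "gene_id"]).head(k)

    if per_mirna:
        kept = (
            preds.groupby("mirna_id", group_keys=False, sort=False)[preds.columns]
            .apply(_top)
            .reset_index(drop=True)
        )
    else:
        kept = _top(preds).reset_index(drop=True)

    # stable value sort over a gene-id-sorted index: deterministic under ties
    expr = expression.loc[sorted(expression.index)].sort_values(kind="mergesort")
    n = len(expr)
    n_trim = int(np.floor(trim_fraction * n))
    middle = set(expr.index[n_trim : n - n_trim]) if n_trim > 0 else set(expr.index)
    out = kept[kept["gene_id"].isin(middle)].reset_index(drop=True)
    if out.empty:
        warnings.warn("no predictions survive filtering", stacklevel=2)
    return out


def _class_of(mirna_id: str, calls: Mapping[str, StrandCall]) -> str:
    """'5p', 'guide3p', 'passenger3p' or 'other' for a mature species id."""
    if mirna_id.endswith("-5p"):
        return "5p"
    if mirna_id.endswith("-3p"):
        call = calls.get(mirna_id[: -len("-3p")])
        if call is None or call.guide_arm == "none":
            return "other"
        return "guide3p" if call.guide_arm == "3p" else "passenger3p"
    return "other"


def categorize_genes(
    filtered: pd.DataFrame,
    strand_calls: Mapping[str, StrandCall],
    wt_abundances: pd.Series,
    hm_abundances: pd.Series,
) -> pd.DataFrame:
    """Cumulative targeting abundances and category per prediction-covered gene.

    Abundances are mean normalized miRNA reads (WT and HM).  Categories:
    FIVE_P_TARGET iff A5p_WT > A3p_guide_WT + A3pp_WT;
    PASSENGER_3P_TARGET iff (A3pp_HM - A3pp_WT) > (A5p_WT - A5p_HM); genes
    satisfying both go to PASSENGER_3P_TARGET; everything else NEITHER.
    """
    tab = filtered.copy()
    tab["cls"] = [_class_of(m, strand_calls) for m in tab["mirna_id"]]
    tab["wt_ab"] = wt_abundances.reindex(tab["mirna_id"]).fillna(0.0).to_numpy()
    tab["hm_ab"] = hm_abundances.reindex(tab["mirna_id"]).fillna(0.0).to_numpy()

    rows = []
    for gene, group in tab.groupby("gene_id"):
        a5_wt = float(group.loc[group["cls"] == "5p", "wt_ab"].sum())
        a5_hm = float(group.loc[group["cls"] == "5p", "hm_ab"].sum())
        a3g_wt = float(group.loc[group["cls"] == "guide3p", "wt_ab"].sum())
        a3pp_wt = float(group.loc[group["cls"] == "passenger3p", "wt_ab"].sum())
        a3pp_hm = float(group.loc[group["cls"] == "passenger3p", "hm_ab"].sum())
        if (a3pp_hm - a3pp_wt) > (a5_wt - a5_hm):
            cat = GeneCategory.PASSENGER_3P_TARGET
        elif a5_wt > (a3g_wt + a3pp_wt):
            cat = GeneCategory.FIVE_P_TARGET
        else:
            cat = GeneCategory.NEITHER
        rows.append(
            {
                "gene_id": gene,
                "category": cat.value,
                "A5p_WT": a5_wt,
                "A5p_HM": a5_hm,
                "A3p_guide_WT": a3g_wt,
                "A3pp_WT": a3pp_wt,
                "A3pp_HM": a3pp_hm,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def target_shift_tests(
    categories: pd.DataFrame,
    rnaseq_fc: pd.Series,
    min_genes: int = 3,
) -> dict[str, ShiftTestResult]:
    """One-sided KS of each category's fold-change distribution against the
    NEITHER background: 5p-targets tested for an upward shift (derepression),
    passenger-3p-targets for a downward shift (acquired repression)."""
    fc = rnaseq_fc.dropna()
    cat = categories["category"]
    bg = fc.reindex(cat.index[cat == GeneCategory.NEITHER.value]).dropna().to_numpy()
    out: dict[str, ShiftTestResult] = {}
    for name, direction in (
        (GeneCategory.FIVE_P_TARGET.value, "up"),
        (GeneCategory.PASSENGER_3P_TARGET.value, "down"),
    ):
        fg = fc.reindex(cat.index[cat == name]).dropna().to_numpy()
        if len(fg) < min_genes or len(bg) < min_genes:
            warnings.warn(f"category {name} has <{min_genes} genes; test skipped", stacklevel=2)
            continue
        out[name] = ks_shift(fg, bg, direction=direction)
    return out


def intersect_downregulated(
    categories: pd.DataFrame,
    rnaseq_table: pd.DataFrame,
    clash_genes: Sequence[str],
    q_cut: float = 0.05,
    fc_cut: float = 0.0,
) -> list[str]:
    """Candidate functional targets: passenger-3p-target genes supported by a
    CLASH hybrid and significantly downregulated (q < q_cut, log2FC < fc_cut)."""
    cat_genes = set(categories.index[categories["category"] == GeneCategory.PASSENGER_3P_TARGET.value])
    down = set(
        rnaseq_table.index[(rnaseq_table["q"] < q_cut) & (rnaseq_table["log2fc"] < fc_cut)]
    )
    return sorted(cat_genes & set(clash_genes) & down)
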