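"""Enrichment, differential-expression and distribution-shift statistics.

Conventions shared across the pipeline:

* AGO enrichment E = mean AGO-IP abundance (per-million-miRNA normalized)
  divided by mean input abundance (spike-in normalized), with a pseudocount
  added to both means.  E is a ratio, so correlations use log E.
* Differential expression is Welch's unequal-variance t-test (two-sided) on
  replicate groups with Benjamini-Hochberg adjustment.
* Distribution shifts use the one-sided two-sample Kolmogorov-Smirnov test;
  the direction is always an explicit argument, never inferred from data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import CountMatrix


@dataclass(frozen=True)
class ShiftTestResult:
    statistic: float  # one-sided KS D in the requested direction, in [0, 1]
    p: float
    direction: str  # 'up' | 'down'
    n_fg: int
    n_bg: int
    method: str = "auto"


# ---------------------------------------------------------------------------
# AGO-IP enrichment
# ---------------------------------------------------------------------------

def ago_enrichment(
    ip_matrix: CountMatrix,
    input_matrix: CountMatrix,
    pseudocount: float = 1.0,
    input_floor: float = 0.0,
    ip_samples: Sequence[str] | None = None,
    input_samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-species AGO enrichment E = (mean IP + c) / (mean input + c).

    IP counts are expected total-miRNA normalized and input counts spike-in
    normalized, mirroring the two library-size conventions of the assays.
    Species whose mean input falls below ``input_floor`` are excluded from the
    returned table and listed in its ``excluded`` attribute (``DataFrame.attrs``).
    """
    shared = ip_matrix.data.index.intersection(input_matrix.data.index)
    if len(shared) == 0:
        raise ValueError("IP and input matrices share no species")
    ip_cols = list(ip_samples) if ip_samples is not None else list(ip_matrix.data.columns)
    in_cols = list(input_samples) if input_samples is not None else list(input_matrix.data.columns)
    ip_mean = ip_matrix.data.loc[shared, ip_cols].mean(axis=1)
    in_mean = input_matrix.data.loc[shared, in_cols].mean(axis=1)
    keep = in_mean >= input_floor
    out = pd.DataFrame(
        {
            "ip_norm": ip_mean[keep],
            "input_norm": in_mean[keep],
            "enrichment": (ip_mean[keep] + pseudocount) / (in_mean[keep] + pseudocount),
            "low_evidence": (ip_mean[keep] == 0) & (in_mean[keep] == 0),
        }
    )
    out.attrs["excluded"] = list(shared[~keep])
    return out


# ---------------------------------------------------------------------------
# Welch differential expression
# ---------------------------------------------------------------------------

def differential(
    matrix: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-species log2FC (B over A), Welch's two-sided p and BH q.

    Species with zero variance in both groups and equal means get p = 1 by
    convention (no evidence against the null, not an error).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 replicates per group (variance undefined otherwise)")
    a = matrix.data[list(group_a)].to_numpy(dtype=float)
    b = matrix.data[list(group_b)].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant rows trigger a scipy precision warning; they are handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(b, a, axis=1, equal_var=False)
    degenerate = np.isnan(p)
    p = np.where(degenerate & np.isclose(mean_a, mean_b), 1.0, p)
    if np.isnan(p).any():
        # zero variance but different means: evidence is infinitely strong
        p = np.where(np.isnan(p), 0.0, p)
    q = sps.false_discovery_control(p, method="bh")
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "t": np.where(degenerate, 0.0, t),
            "p": p,
            "q": q,
        },
        index=matrix.data.index,
    )


# ---------------------------------------------------------------------------
# One-sided Kolmogorov-Smirnov shift test
# ---------------------------------------------------------------------------

EXACT_MAX_N = 16  # exact null distribution when n_fg + n_bg is at most this


def ks_shift(
    foreground: Sequence[float],
    background: Sequence[float],
    direction: str,
    method: str = "auto",
) -> ShiftTestResult:
    """One-sided KS test for a shift of ``foreground`` relative to ``background``.

    ``direction='down'`` tests whether foreground values are stochastically
    smaller than background (its empirical CDF lies above); ``'up'`` the
    opposite.  With ``method='auto'`` the exact null distribution is used
    when n_fg + n_bg <= 16, the asymptotic approximation otherwise.
    """
    fg = np.asarray(foreground, dtype=float)
    bg = np.asarray(background, dtype=float)
    if fg.size < 3 or bg.size < 3:
        raise ValueError("need >= 3 observations per side")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if method == "auto":
        method = "exact" if fg.size + bg.size <= EXACT_MAX_N else "asymp"
    # scipy semantics: alternative='greater' tests CDF(fg) > CDF(bg), i.e. fg
    # shifted down; 'less' tests fg shifted up.
    alternative = "greater" if direction == "down" else "less"
    res = sps.ks_2samp(fg, bg, alternative=alternative, method=method)
    p = float(min(res.pvalue, 1.0))
    if method == "asymp":
        # one-sided asymptotic with a continuity correction on D: the plain
        # exp(-2*ne*D^2) understates p by ~20% relative at moderate n; adding
        # 1/(6*ne) to D tracks the exact permutation null to ~0.005
        ne = fg.size * bg.size / (fg.size + bg.size)
        p = float(min(np.exp(-2.0 * ne * (res.statistic + 1.0 / (6.0 * ne)) ** 2), 1.0))
    return ShiftTestResult(
        statistic=float(res.statistic),
        p=p,
        direction=direction,
        n_fg=int(fg.size),
        n_bg=int(bg.size),
        method=method,
    )


# ---------------------------------------------------------------------------
# Score-enrichment correlation
# ---------------------------------------------------------------------------

def score_correlation(
    enrichment: pd.Series,
    scores: pd.Series,
    subset: Sequence[str] | None = None,
    log_enrichment: bool = True,
) -> dict:
    """Pearson R^2 and two-sided p between (log) enrichment and a strand score.

    Returns a dict with keys ``r2``, ``r``, ``p``, ``n`` and ``flag``;
    degenerate inputs (zero variance on either axis) are flagged rather than
    reported as a number.
    """
    idx = enrichment.index.intersection(scores.index)
    if subset is not None:
        idx = idx.intersection(pd.Index(subset))
    x = enrichment.loc[idx].astype(float)
    y = scores.loc[idx].astype(float)
    if log_enrichment:
        if (x <= 0).any():
            raise ValueError("enrichment must be positive to take logs")
        x = np.log(x)
    if len(idx) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return {"r2": np.nan, "r": np.nan, "p": np.nan, "n": len(idx), "flag": "zero_variance"}
    r, p = sps.pearsonr(x, y)
    return {"r2": float(r * r), "r": float(r), "p": float(p), "n": int(len(idx)), "flag": ""}
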