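"""Guide/passenger classification, 5'-end asymmetry scoring and the
end-accessibility-gated AGO loading model.

The model: AGO selects the duplex strand whose 5' end is most weakly paired
and has the most favorable 5'-terminal nucleotide (A/U over G/C).  Each
strand gets a score

    s = w(nt5) + gamma * dG3

where dG3 is the nearest-neighbor stacking free energy of the first three
base pairs at the strand's 5' end (kcal/mol; more negative = more stably
paired) and w weights the 5'-terminal nucleotide.  For an intact duplex the
two strands compete and the loading probability is a logistic function of
the score difference.  For nicked precursors - one strand still covalently
joined to the terminal loop - loading is gated by end accessibility: the
loop-attached strand cannot be loaded at all, and the free strand is loaded
according to its own score alone (for the 5p strand of a 3p-nicked
precursor, further attenuated by non-covalent occlusion of its 3' end by
the adjacent loop).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats
from ._nn import is_watson_crick, stack_energy
from .core import CountMatrix, HairpinAnnotation

GUIDE_FRACTION = 0.70
GUIDE_MIN_READS = 100.0

DEFAULT_NT5_WEIGHTS = {"A": 1.0, "U": 1.0, "G": 0.0, "C": 0.0}
DEFAULT_GAMMA = 0.25  # score units per kcal/mol


class SubstrateForm(str, enum.Enum):
    DUPLEX = "DUPLEX"
    NICK_5P = "NICK_5P"  # 5p strand covalently joined to the loop (RNase IIIb mutant)
    NICK_3P = "NICK_3P"  # 3p strand covalently joined to the loop (RNase IIIa mutant)


@dataclass(frozen=True)
class StrandCall:
    hairpin_id: str
    guide_arm: str  # '5p' | '3p' | 'none'
    fraction_5p: float
    total_reads: float
    basis_samples: tuple[str, ...] = ()
    zero_expression: bool = False

    @property
    def passenger_arm(self) -> str:
        if self.guide_arm == "5p":
            return "3p"
        if self.guide_arm == "3p":
            return "5p"
        return "none"


@dataclass(frozen=True)
class DeltaG3:
    """dG of the first-three-pair stacks at a strand's 5' end; unpaired positions
    contribute 0 and are flagged."""

    value: float
    paired: tuple[bool, bool, bool]

    @property
    def any_unpaired(self) -> bool:
        return not all(self.paired)


@dataclass(frozen=True)
class AsymmetryScores:
    hairpin_id: str
    nt5_5p: str
    nt5_3p: str
    dg3_5p: float
    dg3_3p: float
    s5p: float
    s3p: float

    @property
    def delta(self) -> float:
        return self.s5p - self.s3p


@dataclass(frozen=True)
class LoadingParams:
    """Logistic AGO-loading parameters.

    ``s0`` is the score midpoint for loading a single free strand from a
    nicked precursor.  It sits near the typical score of a weak (G/C-start)
    strand, so a guide 3p strand loads about as well from a nicked precursor
    as from the duplex (its usual competitor scores that low anyway), while
    a high-scoring passenger 3p strand - freed from a strong 5p competitor -
    loads far better.  ``tau`` is comparable to the score gap between
    A/U-start and G/C-start strands, making the switch selective for
    favorable 5' ends rather than uniform.
    """

    tau: float = 0.25  # logistic temperature, score units
    s0: float = -0.8  # score midpoint for single-strand (nicked) loading
    kappa: float = 0.9  # non-covalent 3'-end occlusion of the free 5p strand, [0,1)
    efficiency: float = 1.0  # overall duplex loading efficiency L

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if not 0 <= self.kappa < 1:
            raise ValueError("kappa must be in [0, 1)")


@dataclass(frozen=True)
class LoadingOutcome:
    p_load_5p: float
    p_load_3p: float
    blocked_5p: str = ""  # reason the 5p strand is blocked, if any
    blocked_3p: str = ""


# ---------------------------------------------------------------------------
# Guide / passenger classification
# ---------------------------------------------------------------------------

def classify_strands(
    counts_5p: float,
    counts_3p: float,
    hairpin_id: str = "",
    basis_samples: Sequence[str] = (),
) -> StrandCall:
    """Apply the guide-strand rule to one hairpin's mean WT normalized counts.

    The arm with >70% of the duplex's reads and a mean above 100 reads is the
    guide; the other arm is the passenger.  If neither arm qualifies the
    duplex is unclassified (``guide_arm='none'``) and is excluded from
    guide/passenger contrasts.
    """
    total = counts_5p + counts_3p
    if total <= 0:
        return StrandCall(hairpin_id, "none", 0.5, 0.0, tuple(basis_samples), zero_expression=True)
    frac5 = counts_5p / total
    if frac5 > GUIDE_FRACTION and counts_5p > GUIDE_MIN_READS:
        guide = "5p"
    elif (1.0 - frac5) > GUIDE_FRACTION and counts_3p > GUIDE_MIN_READS:
        guide = "3p"
    else:
        guide = "none"
    return StrandCall(hairpin_id, guide, frac5, total, tuple(basis_samples))


def call_strands(
    matrix: CountMatrix,
    hairpin_ids: Iterable[str],
    sample_ids: Sequence[str],
) -> dict[str, StrandCall]:
    """Guide/passenger calls for every hairpin from WT total-RNA samples.

    Uses the mean of the given (normalized) samples for each arm species.
    """
    means = matrix.data[list(sample_ids)].mean(axis=1)
    calls = {}
    for hid in hairpin_ids:
        c5 = float(means.get(f"{hid}-5p", 0.0))
        c3 = float(means.get(f"{hid}-3p", 0.0))
        calls[hid] = classify_strands(c5, c3, hid, basis_samples=sample_ids)
    return calls


# ---------------------------------------------------------------------------
# 5'-end thermodynamic asymmetry
# ---------------------------------------------------------------------------

def delta_g_first3(
    strand_seq: str,
    partner_seq: str,
    pairing: Mapping[int, int],
) -> DeltaG3:
    """Stacking free energy over the first three base pairs at the strand's 5' end.

    ``pairing`` maps strand positions to partner positions (both 0-based from
    each strand's own 5' end; antiparallel register).  A position that is
    absent from the map, or whose bases are not Watson-Crick complementary,
    counts as unpaired: it contributes 0 and breaks the stacks it would have
    joined.
    """
    for seq, name in ((strand_seq, "strand"), (partner_seq, "partner")):
        if set(seq) - set("ACGU"):
            raise ValueError(f"{name} sequence is not RNA (A/C/G/U)")
    paired: list[bool] = []
    partner_idx: list[int | None] = []
    for pos in range(3):
        j = pairing.get(pos)
        ok = (
            j is not None
            and 0 <= j < len(partner_seq)
            and is_watson_crick(strand_seq[pos], partner_seq[j])
        )
        paired.append(bool(ok))
        partner_idx.append(j if ok else None)
    total = 0.0
    for a in (0, 1):
        b = a + 1
        ja, jb = partner_idx[a], partner_idx[b]
        if paired[a] and paired[b] and ja is not None and jb == ja - 1:
            top = strand_seq[a] + strand_seq[b]
            bottom = partner_seq[ja] + partner_seq[jb]
            total += stack_energy(top, bottom)
    return DeltaG3(total, tuple(paired))  # type: ignore[arg-type]


def strand_score(
    nt5: str,
    dg3: float,
    nt5_weights: Mapping[str, float] | None = None,
    gamma: float = DEFAULT_GAMMA,
) -> float:
    """Asymmetry score for one strand: w(nt5) + gamma * dG3.

    Higher scores mean a more AGO-favorable 5' end (A/U identity, weak
    pairing).  dG3 is negative for stable pairing, so gamma > 0 penalizes
    stably paired 5' ends.
    """
    w = DEFAULT_NT5_WEIGHTS if nt5_weights is None else nt5_weights
    if nt5 not in w:
        raise ValueError(f"no weight for 5' nucleotide {nt5!r}")
    return w[nt5] + gamma * dg3


def score_duplex(
    hairpin: HairpinAnnotation,
    nt5_weights: Mapping[str, float] | None = None,
    gamma: float = DEFAULT_GAMMA,
) -> AsymmetryScores:
    """5p- and 3p-scores for one hairpin's annotated duplex."""
    fwd = dict(hairpin.duplex_pairs)
    rev = {j: i for i, j in hairpin.duplex_pairs}
    a5, a3 = hairpin.arm5p_seq, hairpin.arm3p_seq
    dg5 = delta_g_first3(a5, a3, fwd)
    dg3 = delta_g_first3(a3, a5, rev)
    return AsymmetryScores(
        hairpin_id=hairpin.hairpin_id,
        nt5_5p=a5[0],
        nt5_3p=a3[0],
        dg3_5p=dg5.value,
        dg3_3p=dg3.value,
        s5p=strand_score(a5[0], dg5.value, nt5_weights, gamma),
        s3p=strand_score(a3[0], dg3.value, nt5_weights, gamma),
    )


def score_catalog(
    catalog: Iterable[HairpinAnnotation],
    nt5_weights: Mapping[str, float] | None = None,
    gamma: float = DEFAULT_GAMMA,
) -> pd.DataFrame:
    rows = []
    for h in catalog:
        sc = score_duplex(h, nt5_weights, gamma)
        rows.append(
            {
                "hairpin_id": sc.hairpin_id,
                "nt5_5p": sc.nt5_5p,
                "nt5_3p": sc.nt5_3p,
                "dg3_5p": sc.dg3_5p,
                "dg3_3p": sc.dg3_3p,
                "s5p": sc.s5p,
                "s3p": sc.s3p,
                "delta": sc.delta,
            }
        )
    return pd.DataFrame(rows).set_index("hairpin_id")


# ---------------------------------------------------------------------------
# AGO loading model
# ---------------------------------------------------------------------------

def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def predict_loading(
    form: SubstrateForm,
    scores: AsymmetryScores,
    params: LoadingParams | None = None,
) -> LoadingOutcome:
    """Per-strand AGO loading probabilities for one processed precursor.

    DUPLEX: the two strands compete; p_5p = L*sigma(delta/tau) and
    p_3p = L*sigma(-delta/tau) (at most one AGO per duplex event).

    NICK_5P (5p joined to the loop): the 5p strand's 3' end is covalently
    blocked, so p_5p = 0 exactly; the free 3p strand is loaded on its own
    score, p_3p = sigma((s3p - s0)/tau) - independent of s5p.

    NICK_3P (3p joined to the loop): the 3p strand's 5' end is blocked at the
    MID domain, so p_3p = 0 exactly; the free 5p strand's 3' end is
    non-covalently occluded by the adjacent loop, p_5p =
    (1 - kappa)*sigma((s5p - s0)/tau).
    """
    p = params or LoadingParams()
    if form == SubstrateForm.DUPLEX:
        d = scores.delta / p.tau
        return LoadingOutcome(
            p_load_5p=p.efficiency * _sigmoid(d),
            p_load_3p=p.efficiency * _sigmoid(-d),
        )
    if form == SubstrateForm.NICK_5P:
        return LoadingOutcome(
            p_load_5p=0.0,
            p_load_3p=_sigmoid((scores.s3p - p.s0) / p.tau),
            blocked_5p="3p_end_covalently_joined_to_loop",
        )
    if form == SubstrateForm.NICK_3P:
        return LoadingOutcome(
            p_load_5p=(1.0 - p.kappa) * _sigmoid((scores.s5p - p.s0) / p.tau),
            p_load_3p=0.0,
            blocked_3p="5p_end_blocked_at_MID",
        )
    raise ValueError(f"unknown substrate form {form!r}")


def loading_table(
    catalog: Iterable[HairpinAnnotation],
    form: SubstrateForm,
    params: LoadingParams | None = None,
    nt5_weights: Mapping[str, float] | None = None,
    gamma: float = DEFAULT_GAMMA,
) -> pd.DataFrame:
    rows = []
    for h in catalog:
        sc = score_duplex(h, nt5_weights, gamma)
        out = predict_loading(form, sc, params)
        rows.append(
            {
                "hairpin_id": h.hairpin_id,
                "form": form.value,
                "p_load_5p": out.p_load_5p,
                "p_load_3p": out.p_load_3p,
                "blocked_5p": out.blocked_5p,
                "blocked_3p": out.blocked_3p,
            }
        )
    return pd.DataFrame(rows).set_index("hairpin_id")


# ---------------------------------------------------------------------------
# Strand-switch detection
# ---------------------------------------------------------------------------

def detect_strand_switch(
    calls: Mapping[str, StrandCall],
    matrix: CountMatrix,
    wt_samples: Sequence[str],
    hm_samples: Sequence[str],
    lfc_threshold: float = 1.0,
    q_threshold: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Flag passenger 3p-miRNAs upregulated in the hotspot mutant.

    Runs Welch differential expression (HM vs WT) on all 3p species, adjusts
    with Benjamini-Hochberg, and flags passenger 3p species with
    log2FC > ``lfc_threshold`` and q < ``q_threshold`` as "switched".  The
    returned table covers every 3p species with its strand class, so guide
    strands are auditable alongside.
    """
    if len(wt_samples) < 2 or len(hm_samples) < 2:
        raise ValueError("need >= 2 replicates per group for Welch's t-test")
    species = [rid for rid in matrix.data.index if rid.endswith("-3p")]
    sub = CountMatrix(matrix.data.loc[species], dict(matrix.samples), matrix.normalized)
    table = stats.differential(sub, wt_samples, hm_samples, pseudocount=pseudocount)
    strand_class = []
    for rid in table.index:
        hid = rid[: -len("-3p")]
        call = calls.get(hid)
        if call is None or call.guide_arm == "none":
            strand_class.append("unclassified")
        elif call.guide_arm == "3p":
            strand_class.append("guide")
        else:
            strand_class.append("passenger")
    table = table.copy()
    table["strand_class"] = strand_class
    table["switched"] = (
        (table["strand_class"] == "passenger")
        & (table["log2fc"] > lfc_threshold)
        & (table["q"] < q_threshold)
    )
    return table
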