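"""CLASH chimeric-read detection, prediction filtering and composition summaries.

A chimera is miRNA-first: the mature miRNA's 3' end is ligated to the 5' end
of its bound target fragment, so a callable read is a mature-miRNA prefix
(>= 16 nt, <= 1 mismatch) followed by a 3' UTR fragment (>= 18 nt, <= 2
mismatches, ungapped).  Reads in the reverse orientation are not called
(directionality is part of the ligation chemistry and is asserted by tests).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import HairpinAnnotation, species_arm
from .simulate import revcomp_rna
from .strands import StrandCall

MIN_MIRNA_MATCH = 16
MIN_TARGET_MATCH = 18
MIN_CHIMERA_LEN = 36


@dataclass(frozen=True)
class HybridRecord:
    read_id: str
    mirna_id: str
    arm: str
    mirna_match_len: int
    gene_id: str
    target_start: int  # 0-based half-open on the UTR
    target_end: int
    seed_match: str  # 8mer | 7mer-m8 | 7mer-A1 | 6mer | none
    strand_class: str = "unclassified"  # guide | passenger | unclassified


@dataclass(frozen=True)
class HybridParams:
    max_mirna_mismatches: int = 1
    max_target_mismatches: int = 2
    min_mirna_match: int = MIN_MIRNA_MATCH
    min_target_match: int = MIN_TARGET_MATCH
    anchor_k: int = 12  # exact word length seeding the target-side extension


# ---------------------------------------------------------------------------
# miRNA prefix index
# ---------------------------------------------------------------------------

class MirnaIndex:
    """Anchor index over mature miRNAs: with <= 1 mismatch in the first 16 nt,
    at least one of the two 8-mers is exact."""

    K = 8

    def __init__(self, catalog: Sequence[HairpinAnnotation]):
        self.mature: dict[str, str] = {}
        for h in catalog:
            self.mature[f"{h.hairpin_id}-5p"] = h.arm5p_seq
            self.mature[f"{h.hairpin_id}-3p"] = h.arm3p_seq
        self.anchors: dict[str, set[str]] = {}
        for mid, seq in self.mature.items():
            for off in (0, self.K):
                self.anchors.setdefault(seq[off : off + self.K], set()).add(mid)

    def longest_prefix(self, read: str, max_mm: int, min_len: int) -> tuple[str, int] | None:
        """Longest full-mature-miRNA prefix of ``read`` with <= max_mm
        mismatches; ties broken by id.  Returns (mirna_id, match_len)."""
        cands = set()
        cands |= self.anchors.get(read[: self.K], set())
        cands |= self.anchors.get(read[self.K : 2 * self.K], set())
        best: tuple[int, str] | None = None
        for mid in cands:
            seq = self.mature[mid]
            if len(seq) < min_len or len(read) < len(seq):
                continue
            mm = sum(1 for a, b in zip(seq, read) if a != b)
            if mm > max_mm:
                continue
            key = (-len(seq), mid)
            if best is None or key < best:
                best = key
        if best is None:
            return None
        return best[1], -best[0]


class UtrIndex:
    """Exact k-mer index over the UTR set for seeding ungapped extensions."""

    def __init__(self, utrs: Mapping[str, str], k: int = 12):
        self.k = k
        self.utrs = dict(utrs)
        self.words: dict[str, list[tuple[str, int]]] = {}
        for gene, seq in self.utrs.items():
            for i in range(len(seq) - k + 1):
                self.words.setdefault(seq[i : i + k], []).append((gene, i))

    def best_match(
        self, fragment: str, max_mm: int, min_len: int
    ) -> tuple[str, int, int] | None:
        """Best ungapped placement of ``fragment``: (gene, start, end) on the UTR.

        Seeded by exact k-words at a few fragment offsets; the placement with
        the fewest mismatches (ties by gene id, then position) wins, and must
        align at least ``min_len`` UTR bases with <= max_mm mismatches.
        """
        if len(fragment) < min_len:
            return None
        seen: set[tuple[str, int]] = set()
        best: tuple[int, str, int, int] | None = None
        offsets = range(0, min(len(fragment) - self.k, 6) + 1)
        for off in offsets:
            word = fragment[off : off + self.k]
            for gene, pos in self.words.get(word, ()):
                start = pos - off
                key_sp = (gene, start)
                if start < 0 or key_sp in seen:
                    continue
                seen.add(key_sp)
                utr = self.utrs[gene]
                end = min(start + len(fragment), len(utr))
                aligned = end - start
                if aligned < min_len:
                    continue
                mm = sum(1 for a, b in zip(fragment[: aligned], utr[start:end]) if a != b)
                if mm > max_mm:
                    continue
                key = (mm, gene, start, end)
                if best is None or key < best:
                    best = key
        if best is None:
            return None
        return best[1], best[2], best[3]


# ---------------------------------------------------------------------------
# Seed-match classification
# ---------------------------------------------------------------------------

def classify_seed_match(mirna_seq: str, target_fragment: str) -> str:
    """Canonical site type of the fragment for this miRNA (8mer > 7mer-m8 >
    7mer-A1 > 6mer > none), judged from miRNA positions 2-8."""
    core6 = revcomp_rna(mirna_seq[1:7])  # positions 2-7
    core7 = revcomp_rna(mirna_seq[1:8])  # positions 2-8 (adds m8)
    if core7 + "A" in target_fragment:
        return "8mer"
    if core7 in target_fragment:
        return "7mer-m8"
    if core6 + "A" in target_fragment:
        return "7mer-A1"
    if core6 in target_fragment:
        return "6mer"
    return "none"


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_hybrid(
    read_id: str,
    read_seq: str,
    mirna_index: MirnaIndex,
    utr_index: UtrIndex,
    params: HybridParams | None = None,
) -> tuple[HybridRecord | None, str]:
    """Call one read as a miRNA-target chimera, or explain why not.

    Returns (record, reason); reason is '' on success, otherwise one of
    'too_short', 'no_mirna_prefix', 'no_target_hit'.
    """
    params = params or HybridParams()
    read = read_seq.upper().replace("T", "U")
    if len(read) < MIN_CHIMERA_LEN:
        return None, "too_short"
    hit = mirna_index.longest_prefix(read, params.max_mirna_mismatches, params.min_mirna_match)
    if hit is None:
        return None, "no_mirna_prefix"
    mirna_id, mlen = hit
    suffix = read[mlen:]
    if len(suffix) < params.min_target_match:
        return None, "too_short"
    target = utr_index.best_match(suffix, params.max_target_mismatches, params.min_target_match)
    if target is None:
        return None, "no_target_hit"
    gene, start, end = target
    record = HybridRecord(
        read_id=read_id,
        mirna_id=mirna_id,
        arm=species_arm(mirna_id) or "",
        mirna_match_len=mlen,
        gene_id=gene,
        target_start=start,
        target_end=end,
        seed_match=classify_seed_match(mirna_index.mature[mirna_id], suffix),
    )
    return record, ""


def detect_hybrids(
    reads: Iterable[tuple[str, str]],
    mirna_index: MirnaIndex,
    utr_index: UtrIndex,
    params: HybridParams | None = None,
) -> tuple[list[HybridRecord], pd.Series]:
    """Call every read; returns (records, per-reason failure tally)."""
    records: list[HybridRecord] = []
    reasons: dict[str, int] = {"too_short": 0, "no_mirna_prefix": 0, "no_target_hit": 0}
    for rid, seq in reads:
        rec, reason = detect_hybrid(rid, seq, mirna_index, utr_index, params)
        if rec is not None:
            records.append(rec)
        else:
            reasons[reason] += 1
    return records, pd.Series(reasons, name="failures")


def filter_hybrids(
    records: Sequence[HybridRecord], predictions: pd.DataFrame
) -> tuple[list[HybridRecord], int]:
    """Keep only hybrids whose (miRNA, gene) pair is in the prediction table -
    the stated false-positive control.  Returns (kept, n_removed)."""
    allowed = set(zip(predictions["mirna_id"], predictions["gene_id"]))
    if not allowed:
        import warnings

        warnings.warn("empty prediction table: all hybrid records removed", stacklevel=2)
    kept = [r for r in records if (r.mirna_id, r.gene_id) in allowed]
    return kept, len(records) - len(kept)


def annotate_strand_class(
    records: Sequence[HybridRecord], strand_calls: Mapping[str, StrandCall]
) -> list[HybridRecord]:
    out = []
    for r in records:
        hid = r.mirna_id.rsplit("-", 1)[0]
        call = strand_calls.get(hid)
        if call is None or call.guide_arm == "none":
            cls = "unclassified"
        else:
            cls = "guide" if call.guide_arm == r.arm else "passenger"
        out.append(
            HybridRecord(
                r.read_id, r.mirna_id, r.arm, r.mirna_match_len, r.gene_id,
                r.target_start, r.target_end, r.seed_match, cls,
            )
        )
    return out


def records_to_frame(records: Sequence[HybridRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": r.read_id,
                "mirna_id": r.mirna_id,
                "arm": r.arm,
                "mirna_match_len": r.mirna_match_len,
                "gene_id": r.gene_id,
                "target_start": r.target_start,
                "target_end": r.target_end,
                "seed_match": r.seed_match,
                "strand_class": r.strand_class,
            }
            for r in records
        ],
        columns=[
            "read_id", "mirna_id", "arm", "mirna_match_len", "gene_id",
            "target_start", "target_end", "seed_match", "strand_class",
        ],
    )


def hybrid_summary(
    records: Sequence[HybridRecord],
    strand_calls: Mapping[str, StrandCall],
    mirna_expression: pd.Series | None = None,
) -> dict:
    """Composition of a hybrid set: arm fractions, passenger share of 3p
    hybrids, and per-miRNA hybrid counts normalized to total-RNA expression.

    With zero hybrids the fractions are NaN and ``defined`` is False.
    """
    records = annotate_strand_class(records, strand_calls)
    n = len(records)
    if n == 0:
        return {
            "defined": False,
            "n_hybrids": 0,
            "fraction_5p": float("nan"),
            "fraction_3p": float("nan"),
            "passenger_share_3p": float("nan"),
            "per_mirna": pd.DataFrame(columns=["hybrids", "expression", "normalized"]),
        }
    n5 = sum(1 for r in records if r.arm == "5p")
    n3 = sum(1 for r in records if r.arm == "3p")
    n3p_pass = sum(1 for r in records if r.arm == "3p" and r.strand_class == "passenger")
    counts = pd.Series([r.mirna_id for r in records]).value_counts()
    per = pd.DataFrame({"hybrids": counts})
    if mirna_expression is not None:
        expr = mirna_expression.reindex(per.index)
        per["expression"] = expr
        per["normalized"] = per["hybrids"] / expr.replace(0, np.nan)
    return {
        "defined": True,
        "n_hybrids": n,
        "fraction_5p": n5 / n,
        "fraction_3p": n3 / n,
        "passenger_share_3p": (n3p_pass / n3) if n3 else float("nan"),
        "per_mirna": per,
    }
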