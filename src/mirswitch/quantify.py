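"""Small-RNA read classification against a hairpin catalog and normalization.

Reads are assigned to one of four species classes per hairpin:

* FIVE_P / THREE_P - mature arm reads whose 5' start and 3' end both fall
  within ``end_tolerance`` (default 2 nt) of the annotated arm boundaries;
* FIVE_P_LOOP - unprocessed 5p+loop intermediates: start at the 5p arm but a
  3' end extending at least ``loop_min_extension`` (default 3 nt) past the
  arm into or through the loop.  The extension floor separates true nicked
  intermediates from templated 3' additions;
* THREE_P_LOOP - the symmetric RNase IIIa-mutant product (loop + 3p arm);
* UNASSIGNED - everything else, tallied per sample but kept out of the
  species matrix.

Matching is exact-substring up to ``max_mismatches`` (default 1), an
isomiR-tolerant approximation of collapsed canonical counting.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CountMatrix, HairpinAnnotation, SampleMeta

MIN_READ_LEN = 16


class ReadClass(str, enum.Enum):
    FIVE_P = "FIVE_P"
    THREE_P = "THREE_P"
    FIVE_P_LOOP = "FIVE_P_LOOP"
    THREE_P_LOOP = "THREE_P_LOOP"
    UNASSIGNED = "UNASSIGNED"


CLASS_TO_ARM = {
    ReadClass.FIVE_P: "5p",
    ReadClass.THREE_P: "3p",
    ReadClass.FIVE_P_LOOP: "5pLoop",
    ReadClass.THREE_P_LOOP: "3pLoop",
}


@dataclass(frozen=True)
class ClassifyParams:
    end_tolerance: int = 2
    max_mismatches: int = 1
    loop_min_extension: int = 3


def _mismatches(read: str, ref: str, start: int, limit: int) -> int:
    """Mismatch count of ``read`` laid on ``ref`` at offset ``start``; > limit
    is reported as limit + 1 (early exit)."""
    if start < 0 or start + len(read) > len(ref):
        return limit + 1
    mm = 0
    for i, ch in enumerate(read):
        if ref[start + i] != ch:
            mm += 1
            if mm > limit:
                return mm
    return mm


def _class_for_alignment(
    hairpin: HairpinAnnotation, start: int, end: int, params: ClassifyParams
) -> ReadClass:
    tol = params.end_tolerance
    a5, a3 = hairpin.arm5p, hairpin.arm3p
    if abs(start - a5.start) <= tol:
        if abs(end - a5.end) <= tol:
            return ReadClass.FIVE_P
        if end >= a5.end + params.loop_min_extension:
            return ReadClass.FIVE_P_LOOP
        return ReadClass.UNASSIGNED
    if abs(start - a3.start) <= tol:
        if abs(end - a3.end) <= tol:
            return ReadClass.THREE_P
        return ReadClass.UNASSIGNED
    # symmetric 3p+loop rule: ends at the 3p arm's 3' end, starts >= 3 nt
    # upstream of the 3p arm (i.e. within the loop or at the IIIb cut site)
    if abs(end - a3.end) <= tol and start <= a3.start - params.loop_min_extension:
        return ReadClass.THREE_P_LOOP
    return ReadClass.UNASSIGNED


def _candidate_starts(hairpin: HairpinAnnotation, params: ClassifyParams) -> list[int]:
    tol = params.end_tolerance
    anchors = {hairpin.arm5p.start, hairpin.arm3p.start, hairpin.arm5p.end}
    starts: set[int] = set()
    for a in anchors:
        for d in range(-tol, tol + 1):
            s = a + d
            if s >= 0:
                starts.add(s)
    return sorted(starts)


def classify_read(
    read_seq: str,
    hairpin: HairpinAnnotation,
    params: ClassifyParams | None = None,
) -> ReadClass:
    """Classify one read against one hairpin.  Reads shorter than 16 nt are
    rejected upstream; unmatched reads are UNASSIGNED, never an error."""
    params = params or ClassifyParams()
    if len(read_seq) < MIN_READ_LEN:
        raise ValueError(f"read shorter than {MIN_READ_LEN} nt")
    read = read_seq.upper().replace("T", "U")
    best: tuple[int, ReadClass] | None = None
    for start in _candidate_starts(hairpin, params):
        mm = _mismatches(read, hairpin.sequence, start, params.max_mismatches)
        if mm > params.max_mismatches:
            continue
        cls = _class_for_alignment(hairpin, start, start + len(read), params)
        if cls == ReadClass.UNASSIGNED:
            continue
        if best is None or mm < best[0]:
            best = (mm, cls)
    return best[1] if best else ReadClass.UNASSIGNED


class _CatalogIndex:
    """8-mer anchor index: a read aligned at a candidate start with <= 1
    mismatch has an exact match in at least one of its first two 8-mers."""

    K = 8

    def __init__(self, catalog: Sequence[HairpinAnnotation], params: ClassifyParams):
        self.params = params
        self.catalog = list(catalog)
        self.anchors: dict[str, set[tuple[int, int]]] = {}
        for hi, h in enumerate(self.catalog):
            for start in _candidate_starts(h, params):
                for word_off in (0, self.K):
                    kmer = h.sequence[start + word_off : start + word_off + self.K]
                    if len(kmer) == self.K:
                        self.anchors.setdefault(kmer, set()).add((hi, start))

    def assign(self, read: str) -> tuple[str, ReadClass] | None:
        """Best (hairpin_id, class) for a read, or None."""
        cands: set[tuple[int, int]] = set()
        cands |= self.anchors.get(read[: self.K], set())
        cands |= self.anchors.get(read[self.K : 2 * self.K], set())
        best: tuple[int, str, ReadClass] | None = None
        for hi, start in cands:
            h = self.catalog[hi]
            mm = _mismatches(read, h.sequence, start, self.params.max_mismatches)
            if mm > self.params.max_mismatches:
                continue
            cls = _class_for_alignment(h, start, start + len(read), self.params)
            if cls == ReadClass.UNASSIGNED:
                continue
            key = (mm, h.hairpin_id, cls)
            if best is None or key < best:
                best = key
        if best is None:
            return None
        return best[1], best[2]


def count_species(
    reads_by_sample: Mapping[str, Sequence[str]],
    catalog: Sequence[HairpinAnnotation],
    samples: Mapping[str, SampleMeta],
    params: ClassifyParams | None = None,
) -> tuple[CountMatrix, pd.Series]:
    """Count reads into (hairpin, class) species per sample.

    Returns a raw CountMatrix with the full species row index (zeros
    included) and a per-sample UNASSIGNED tally.  Per sample, class counts
    plus the UNASSIGNED tally always equal the number of input reads.
    """
    params = params or ClassifyParams()
    index = _CatalogIndex(catalog, params)
    species = [h.species_id(arm) for h in catalog for arm in ("5p", "3p", "5pLoop", "3pLoop")]
    data = pd.DataFrame(0, index=species, columns=list(reads_by_sample), dtype=int)
    unassigned = pd.Series(0, index=list(reads_by_sample), dtype=int)
    for sid, reads in reads_by_sample.items():
        for read in reads:
            read = read.upper().replace("T", "U")
            hit = index.assign(read) if len(read) >= MIN_READ_LEN else None
            if hit is None:
                unassigned[sid] += 1
            else:
                hid, cls = hit
                data.loc[f"{hid}-{CLASS_TO_ARM[cls]}", sid] += 1
    return CountMatrix(data, dict(samples), normalized="none"), unassigned


def class_fractions(matrix: CountMatrix, unassigned: pd.Series | None = None) -> pd.DataFrame:
    """Per-sample breakdown of read mass by species class (the stacked-bar view)."""
    cls_of = {"-5p": "FIVE_P", "-3p": "THREE_P", "-5pLoop": "FIVE_P_LOOP", "-3pLoop": "THREE_P_LOOP"}
    rows = {}
    for suffix, name in cls_of.items():
        mask = [rid.endswith(suffix) for rid in matrix.data.index]
        rows[name] = matrix.data.loc[mask].sum(axis=0)
    out = pd.DataFrame(rows).T
    if unassigned is not None:
        out.loc["UNASSIGNED"] = unassigned
    totals = out.sum(axis=0)
    return (out / totals.replace(0, np.nan)).T


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationFactor:
    sample_id: str
    mode: str
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError(f"{self.sample_id}: normalization factor must be > 0")


def normalization_factors(matrix: CountMatrix, mode: str) -> list[NormalizationFactor]:
    if mode == "spike_in":
        sums = {}
        for sid in matrix.data.columns:
            s = matrix.samples[sid].spike_in_sum
            if s <= 0:
                raise ValueError(f"sample {sid!r} has zero spike-in sum")
            sums[sid] = s
        target = float(np.mean(list(sums.values())))
        return [NormalizationFactor(sid, mode, target / s) for sid, s in sums.items()]
    if mode == "total_mirna":
        factors = []
        for sid in matrix.data.columns:
            total = float(matrix.data[sid].sum())
            if total <= 0:
                raise ValueError(f"sample {sid!r} has zero miRNA total")
            factors.append(NormalizationFactor(sid, mode, 1e6 / total))
        return factors
    raise ValueError(f"unknown normalization mode {mode!r}")


def normalize(matrix: CountMatrix, mode: str) -> CountMatrix:
    """Normalize a count matrix.

    ``spike_in``: scale each sample so its spike-in sum equals the
    across-sample mean spike-in sum (anchoring to the mean keeps the result
    invariant to sample order).  Spike-in counts in the sample metadata are
    rescaled alongside, which makes the operation idempotent.

    ``total_mirna``: counts per million assigned miRNA reads.
    """
    factors = {f.sample_id: f.factor for f in normalization_factors(matrix, mode)}
    data = matrix.data.astype(float).copy()
    samples: dict[str, SampleMeta] = {}
    for sid in data.columns:
        data[sid] = data[sid] * factors[sid]
        m = matrix.samples[sid]
        if mode == "spike_in":
            spikes = {k: v * factors[sid] for k, v in m.spike_in_counts.items()}
        else:
            spikes = dict(m.spike_in_counts)
        samples[sid] = SampleMeta(m.sample_id, m.genotype, m.assay, m.replicate, spikes)
    return CountMatrix(data, samples, normalized=mode)
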