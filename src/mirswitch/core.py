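"""Domain types and file I/O for the hairpin/strand-switch pipeline.

Coordinate convention: all intervals are 0-based, half-open, measured on the
hairpin sequence written 5'->3'.  Mature species are identified as
``<hairpin_id>-5p``, ``<hairpin_id>-3p``, ``<hairpin_id>-5pLoop`` and (for
RNase IIIa-mutant products) ``<hairpin_id>-3pLoop``.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")
ARM_MIN, ARM_MAX = 18, 25
LOOP_MIN = 4

#: suffixes used to build mature-species row ids
CLASS_SUFFIX = {"5p": "-5p", "3p": "-3p", "5pLoop": "-5pLoop", "3pLoop": "-3pLoop"}


class Genotype(str, enum.Enum):
    WT = "WT"
    HetKO = "HetKO"
    HM = "HM"
    IIIaMut = "IIIaMut"


class Assay(str, enum.Enum):
    total = "total"
    ago_ip = "ago_ip"
    rna_seq = "rna_seq"
    clash = "clash"


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open interval on the hairpin 5'->3' axis."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def slice(self, sequence: str) -> str:
        return sequence[self.start : self.end]


def _clean_rna(seq: str, *, context: str = "sequence") -> str:
    """Uppercase and transliterate DNA (T) to RNA (U); reject mixed/foreign alphabets."""
    s = seq.upper()
    if "T" in s and "U" in s:
        raise ValueError(f"{context}: mixed T/U alphabet")
    s = s.replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise ValueError(f"{context}: non-RNA characters {sorted(bad)}")
    return s


@dataclass(frozen=True)
class HairpinAnnotation:
    """A pre-miRNA hairpin: sequence plus arm/loop intervals and duplex pairing.

    ``duplex_pairs`` maps arm-local positions: index i on the 5p arm pairs with
    index j on the 3p arm (both 0-based from each arm's own 5' end).  The map
    describes the structural register of the processed duplex; whether a pair
    is Watson-Crick is decided from the sequence when energies are computed.
    """

    hairpin_id: str
    sequence: str
    arm5p: Interval
    loop: Interval
    arm3p: Interval
    overhang3p_len: int = 2
    duplex_pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _clean_rna(self.sequence, context=self.hairpin_id))
        if not (self.arm5p.end <= self.loop.start <= self.loop.end <= self.arm3p.start):
            raise ValueError(f"{self.hairpin_id}: overlapping intervals")
        if self.arm3p.end > len(self.sequence):
            raise ValueError(f"{self.hairpin_id}: interval out of bounds")
        for name, iv in (("arm5p", self.arm5p), ("arm3p", self.arm3p)):
            if not (ARM_MIN <= len(iv) <= ARM_MAX):
                raise ValueError(f"{self.hairpin_id}: {name} length {len(iv)} outside [{ARM_MIN}, {ARM_MAX}]")
        if len(self.loop) < LOOP_MIN:
            raise ValueError(f"{self.hairpin_id}: loop shorter than {LOOP_MIN} nt")
        for i5, i3 in self.duplex_pairs:
            if not (0 <= i5 < len(self.arm5p) and 0 <= i3 < len(self.arm3p)):
                raise ValueError(f"{self.hairpin_id}: pairing index out of arm bounds")

    # -- sequence accessors -------------------------------------------------
    @property
    def arm5p_seq(self) -> str:
        return self.arm5p.slice(self.sequence)

    @property
    def arm3p_seq(self) -> str:
        return self.arm3p.slice(self.sequence)

    @property
    def loop_seq(self) -> str:
        return self.loop.slice(self.sequence)

    @property
    def five_p_loop_seq(self) -> str:
        """The nicked-precursor 5p+loop intermediate (5p arm still joined to the loop)."""
        return self.sequence[self.arm5p.start : self.arm3p.start]

    @property
    def three_p_loop_seq(self) -> str:
        """The RNase IIIa-mutant product: loop still joined to the 3p arm."""
        return self.sequence[self.arm5p.end : self.arm3p.end]

    def mature_seq(self, arm: str) -> str:
        if arm == "5p":
            return self.arm5p_seq
        if arm == "3p":
            return self.arm3p_seq
        raise ValueError(f"unknown arm {arm!r}")

    def species_id(self, read_class: str) -> str:
        return self.hairpin_id + CLASS_SUFFIX[read_class]


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    genotype: Genotype
    assay: Assay
    replicate: int
    spike_in_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"{self.sample_id}: replicate must be >= 1")

    @property
    def spike_in_sum(self) -> float:
        return float(sum(self.spike_in_counts.values()))


@dataclass
class CountMatrix:
    """miRNA-species x sample counts plus sample metadata.

    ``data`` rows are species ids, columns are sample ids.  Raw matrices hold
    non-negative integers; normalized matrices (``normalized != "none"``) hold
    floats.
    """

    data: pd.DataFrame
    samples: dict[str, SampleMeta]
    normalized: str = "none"

    NORM_MODES = ("none", "spike_in", "total_mirna")

    def __post_init__(self) -> None:
        if self.normalized not in self.NORM_MODES:
            raise ValueError(f"unknown normalization mode {self.normalized!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate species row {dup!r}")
        missing = [c for c in self.data.columns if c not in self.samples]
        if missing:
            raise ValueError(f"samples missing metadata: {missing}")
        if (self.data.to_numpy() < 0).any():
            r, c = divmod(int((self.data.to_numpy() < 0).argmax()), self.data.shape[1])
            raise ValueError(
                f"negative count at ({self.data.index[r]!r}, {self.data.columns[c]!r})"
            )
        if self.normalized == "none":
            vals = self.data.to_numpy()
            if not (vals == vals.astype(int)).all():
                raise ValueError("raw count matrix must be integer-valued")

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.data.copy(), dict(self.samples), self.normalized)

    def sample_ids(self, genotype: Genotype | None = None, assay: Assay | None = None) -> list[str]:
        out = []
        for sid in self.data.columns:
            m = self.samples[sid]
            if genotype is not None and m.genotype != genotype:
                continue
            if assay is not None and m.assay != assay:
                continue
            out.append(sid)
        return out


@dataclass
class ExclusionList:
    """Hairpins excluded from downstream statistics (e.g. a clonally silenced
    chromosomal miRNA cluster), with a reason per id."""

    reasons: dict[str, str] = field(default_factory=dict)

    @property
    def hairpin_ids(self) -> set[str]:
        return set(self.reasons)

    def validate_against(self, catalog: Iterable[HairpinAnnotation]) -> None:
        known = {h.hairpin_id for h in catalog}
        unknown = self.hairpin_ids - known
        if unknown:
            raise ValueError(f"exclusion list names unknown hairpins: {sorted(unknown)}")

    def apply(self, matrix: CountMatrix) -> CountMatrix:
        """Drop all species rows belonging to excluded hairpins."""
        keep = [
            rid
            for rid in matrix.data.index
            if _hairpin_of_species(rid) not in self.hairpin_ids
        ]
        return CountMatrix(matrix.data.loc[keep].copy(), dict(matrix.samples), matrix.normalized)


def _hairpin_of_species(species_id: str) -> str:
    for suffix in CLASS_SUFFIX.values():
        if species_id.endswith(suffix):
            return species_id[: -len(suffix)]
    return species_id


def species_arm(species_id: str) -> str | None:
    """Return '5p', '3p', '5pLoop' or '3pLoop' for a mature-species id."""
    for arm, suffix in CLASS_SUFFIX.items():
        if species_id.endswith(suffix):
            return arm
    return None


# ---------------------------------------------------------------------------
# Catalog I/O
# ---------------------------------------------------------------------------

_ANN_COLUMNS = [
    "hairpin_id",
    "arm5p_start",
    "arm5p_end",
    "loop_start",
    "loop_end",
    "arm3p_start",
    "arm3p_end",
    "overhang3p_len",
    "duplex_pairs",
]


def _encode_pairs(pairs: tuple[tuple[int, int], ...]) -> str:
    return ";".join(f"{a}:{b}" for a, b in pairs) if pairs else "."


def _decode_pairs(text: str) -> tuple[tuple[int, int], ...]:
    if not text or text in (".", "nan"):
        return ()
    return tuple(tuple(int(x) for x in item.split(":")) for item in text.split(";"))  # type: ignore[misc]


def read_hairpin_catalog(fasta_path: str | Path, annotation_table_path: str | Path) -> list[HairpinAnnotation]:
    """Load and validate a hairpin catalog from FASTA + interval table.

    DNA input (T) is transliterated to RNA (U).  Every annotation row must
    have a FASTA record and vice versa; intervals must satisfy the
    :class:`HairpinAnnotation` invariants.
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    table = pd.read_csv(annotation_table_path, sep="\t", dtype={"hairpin_id": str})
    catalog: list[HairpinAnnotation] = []
    for _, row in table.iterrows():
        hid = row["hairpin_id"]
        if hid not in seqs:
            raise ValueError(f"annotation row {hid!r} has no FASTA record")
        catalog.append(
            HairpinAnnotation(
                hairpin_id=hid,
                sequence=seqs[hid],
                arm5p=Interval(int(row["arm5p_start"]), int(row["arm5p_end"])),
                loop=Interval(int(row["loop_start"]), int(row["loop_end"])),
                arm3p=Interval(int(row["arm3p_start"]), int(row["arm3p_end"])),
                overhang3p_len=int(row.get("overhang3p_len", 2)),
                duplex_pairs=_decode_pairs(str(row.get("duplex_pairs", "."))),
            )
        )
    extra = set(seqs) - {h.hairpin_id for h in catalog}
    if extra:
        raise ValueError(f"FASTA records missing annotation rows: {sorted(extra)}")
    return catalog


def write_hairpin_catalog(
    catalog: Iterable[HairpinAnnotation], fasta_path: str | Path, annotation_table_path: str | Path
) -> None:
    catalog = list(catalog)
    with open(fasta_path, "w") as fh:
        for h in catalog:
            fh.write(f">{h.hairpin_id}\n{h.sequence}\n")
    rows = [
        {
            "hairpin_id": h.hairpin_id,
            "arm5p_start": h.arm5p.start,
            "arm5p_end": h.arm5p.end,
            "loop_start": h.loop.start,
            "loop_end": h.loop.end,
            "arm3p_start": h.arm3p.start,
            "arm3p_end": h.arm3p.end,
            "overhang3p_len": h.overhang3p_len,
            "duplex_pairs": _encode_pairs(h.duplex_pairs),
        }
        for h in catalog
    ]
    pd.DataFrame(rows, columns=_ANN_COLUMNS).to_csv(annotation_table_path, sep="\t", index=False)


def write_catalog_gff3(catalog: Iterable[HairpinAnnotation], path: str | Path) -> None:
    """Export arm/loop intervals as GFF3 (1-based closed coordinates, per the format)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for h in catalog:
            for feat, iv in (("miRNA_5p_arm", h.arm5p), ("loop", h.loop), ("miRNA_3p_arm", h.arm3p)):
                fh.write(
                    f"{h.hairpin_id}\tmirswitch\t{feat}\t{iv.start + 1}\t{iv.end}\t.\t+\t.\t"
                    f"ID={h.hairpin_id}_{feat}\n"
                )


# ---------------------------------------------------------------------------
# Count-matrix I/O
# ---------------------------------------------------------------------------

def load_counts(tsv_path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Load a raw species x sample TSV plus a sample-metadata TSV.

    The metadata table has columns ``sample_id, genotype, assay, replicate,
    spike_in_counts`` where spike-in counts are encoded ``id=count;id=count``
    (or ``.`` for none).
    """
    table = pd.read_csv(tsv_path, sep="\t", index_col=0)
    meta = read_sample_meta(meta_path)
    for col in table.columns:
        if col not in meta:
            raise ValueError(f"sample {col!r} in counts header absent from metadata")
    for col in table.columns:
        series = pd.to_numeric(table[col], errors="coerce")
        if series.isna().any():
            row = table.index[series.isna().argmax()]
            raise ValueError(f"non-numeric count at ({row!r}, {col!r})")
        if (series < 0).any():
            row = table.index[(series < 0).argmax()]
            raise ValueError(f"negative count at ({row!r}, {col!r})")
        if not (series == series.astype(int)).all():
            row = table.index[(series != series.astype(int)).argmax()]
            raise ValueError(f"non-integer count at ({row!r}, {col!r})")
        table[col] = series.astype(int)
    return CountMatrix(table, {sid: meta[sid] for sid in table.columns}, normalized="none")


def _encode_spikes(spikes: Mapping[str, int]) -> str:
    return ";".join(f"{k}={v}" for k, v in sorted(spikes.items())) or "."


def _decode_spikes(text: str) -> dict[str, int]:
    if not text or text in (".", "nan"):
        return {}
    return {k: int(v) for k, v in (item.split("=") for item in text.split(";"))}


def read_sample_meta(path: str | Path) -> dict[str, SampleMeta]:
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    out: dict[str, SampleMeta] = {}
    for _, row in table.iterrows():
        out[row["sample_id"]] = SampleMeta(
            sample_id=row["sample_id"],
            genotype=Genotype(row["genotype"]),
            assay=Assay(row["assay"]),
            replicate=int(row["replicate"]),
            spike_in_counts=_decode_spikes(str(row.get("spike_in_counts", "."))),
        )
    return out


def write_counts(matrix: CountMatrix, tsv_path: str | Path, meta_path: str | Path | None = None) -> None:
    matrix.data.to_csv(tsv_path, sep="\t", index_label="species_id")
    if meta_path is not None:
        write_sample_meta(matrix.samples.values(), meta_path)


def write_sample_meta(samples: Iterable[SampleMeta], path: str | Path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "genotype": m.genotype.value,
            "assay": m.assay.value,
            "replicate": m.replicate,
            "spike_in_counts": _encode_spikes(m.spike_in_counts),
        }
        for m in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_exclusion_list(path: str | Path) -> ExclusionList:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return ExclusionList(dict(zip(table["hairpin_id"], table.get("reason", "excluded"))))


def write_exclusion_list(excl: ExclusionList, path: str | Path) -> None:
    pd.DataFrame(
        [{"hairpin_id": k, "reason": v} for k, v in sorted(excl.reasons.items())]
    ).to_csv(path, sep="\t", index=False)


def write_run_log(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
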