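"""Sequence and specimen handling for Z-linked strain-marker analysis.

The fall armyworm (*Spodoptera frugiperda*) consists of two host strains —
the C-strain (collected from corn, sorghum, cotton) and the R-strain (turf
and pasture grasses, rice, millet, alfalfa) — that are morphologically
indistinguishable and identified from Z-linked marker sequences.  This
module reads marker-segment alignments and specimen metadata, maps host
plants onto strain classes, applies the ambiguity-exclusion rule (male ZZ
specimens heterozygous anywhere in a segment yield ambiguous Sanger traces
and are dropped), and assembles per-marker alignments for the downstream
phylogenetic and population-genetic stages.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "HostClass",
    "Continent",
    "Sex",
    "Specimen",
    "MarkerSegmentDef",
    "SequenceRecord",
    "MarkerAlignment",
    "DEFAULT_HOST_MAP",
    "DEFAULT_SEGMENTS",
    "UnknownHostError",
    "classify_host",
    "load_host_map",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "write_metadata",
    "filter_usable",
    "build_alignment",
]

#: Residues considered unambiguous in a usable sequence.  Gaps are allowed
#: (aligned indels); every IUPAC ambiguity code marks a heterozygous or
#: low-quality call and renders the whole sequence unusable.
UNAMBIGUOUS = frozenset("ACGT-")

IUPAC_AMBIGUITY = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}


class HostClass(str, enum.Enum):
    C_HOST = "C"
    R_HOST = "R"


class Continent(str, enum.Enum):
    NA = "NA"
    SA = "SA"


class Sex(str, enum.Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"
    UNKNOWN = "UNKNOWN"


class UnknownHostError(ValueError):
    """Raised when a host plant is absent from the host→strain mapping."""


#: Host plant → strain class, per the survey's collection scheme.  The
#: mapping is deliberately total only on this vocabulary: unknown plants
#: raise instead of being silently guessed.
DEFAULT_HOST_MAP: dict[str, HostClass] = {
    "corn": HostClass.C_HOST,
    "sorghum": HostClass.C_HOST,
    "cotton": HostClass.C_HOST,
    "turf grass": HostClass.R_HOST,
    "turf grasses": HostClass.R_HOST,
    "pasture grass": HostClass.R_HOST,
    "pasture grasses": HostClass.R_HOST,
    "rice": HostClass.R_HOST,
    "millet": HostClass.R_HOST,
    "alfalfa": HostClass.R_HOST,
}


def classify_host(host_plant: str, host_map: dict[str, HostClass] | None = None) -> HostClass:
    """Map a host-plant name to its strain class (C_HOST or R_HOST).

    The lookup is case-insensitive and whitespace-trimmed but otherwise
    exact; a plant outside the configured vocabulary raises
    :class:`UnknownHostError` rather than being guessed.
    """
    table = DEFAULT_HOST_MAP if host_map is None else host_map
    key = host_plant.strip().lower()
    try:
        return table[key]
    except KeyError:
        raise UnknownHostError(f"unknown host plant: {host_plant!r}") from None


def load_host_map(path: str | Path) -> dict[str, HostClass]:
    """Load a host→class mapping from a two-column TSV (plant, class).

    Class column accepts ``C``/``C_HOST`` and ``R``/``R_HOST``.  Shipping
    the defaults as data means new plants can be added without code change.
    """
    table: dict[str, HostClass] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
        plant, cls = parts[0].strip().lower(), parts[1].strip().upper()
        if cls in ("C", "C_HOST"):
            table[plant] = HostClass.C_HOST
        elif cls in ("R", "R_HOST"):
            table[plant] = HostClass.R_HOST
        else:
            raise ValueError(f"{path}:{lineno}: unknown host class {parts[1]!r}")
    return table


@dataclass(frozen=True)
class Specimen:
    """One collected larva/moth with host, geography and usability context."""

    id: str
    host_plant: str
    host_class: HostClass
    country: str = ""
    region: str = ""
    continent: Continent = Continent.NA
    collection_date: str = ""
    sex: Sex = Sex.UNKNOWN


@dataclass(frozen=True)
class MarkerSegmentDef:
    """Definition of one exon+intron marker segment and its diagnostic SNP.

    ``diagnostic_site`` is a 1-based position in the segment's own alignment
    frame; ``c_allele``/``r_allele`` are the strain-diagnostic bases at that
    site.  ``exon_intron_boundaries`` is a list of 1-based inclusive
    ``(start, end, kind)`` blocks with ``kind`` in {"exon", "intron"};
    the diagnostic site must fall in an exon block.
    """

    marker: str
    segment_name: str
    segment_length_nominal: int
    diagnostic_site: int
    c_allele: str
    r_allele: str
    exon_intron_boundaries: tuple[tuple[int, int, str], ...]
    primers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.c_allele == self.r_allele:
            raise ValueError("c_allele and r_allele must differ")
        if not any(
            kind == "exon" and start <= self.diagnostic_site <= end
            for start, end, kind in self.exon_intron_boundaries
        ):
            raise ValueError(
                f"diagnostic site {self.diagnostic_site} of {self.segment_name} "
                "does not fall inside an exon block"
            )

    def region_kinds(self) -> list[str]:
        """Per-position region kind ("exon"/"intron") over the segment."""
        kinds = ["exon"] * self.segment_length_nominal
        for start, end, kind in self.exon_intron_boundaries:
            for i in range(start - 1, min(end, self.segment_length_nominal)):
                kinds[i] = kind
        return kinds

    def intron_positions(self) -> list[int]:
        """0-based positions lying in intron blocks."""
        return [i for i, k in enumerate(self.region_kinds()) if k == "intron"]


# Default segment layouts.  Diagnostic sites and alleles follow the marker
# assays (UBCie695 Ue199: C-strain 'C' / R-strain 'T'; TpiEI194 e5[183]:
# C-strain 'C' / R-strain 'T'; nesEI533 n299: C-strain 'T' / R-strain 'C').
# Exon/intron block coordinates are nominal defaults chosen so that each
# diagnostic site sits in an exon with an adjacent indel-prone intron;
# override per assay if exact boundaries are known.
DEFAULT_SEGMENTS: dict[str, MarkerSegmentDef] = {
    "UBCie695": MarkerSegmentDef(
        marker="UBC4",
        segment_name="UBCie695",
        segment_length_nominal=695,
        diagnostic_site=199,
        c_allele="C",
        r_allele="T",
        exon_intron_boundaries=((1, 260, "exon"), (261, 695, "intron")),
        primers=("u138F:ACCGGACACACCATACGAAG", "u557R:AGGGTAGCGCTTTCTACGTT"),
    ),
    "TpiEI194": MarkerSegmentDef(
        marker="TPI",
        segment_name="TpiEI194",
        segment_length_nominal=194,
        diagnostic_site=183,
        c_allele="C",
        r_allele="T",
        exon_intron_boundaries=((1, 47, "exon"), (48, 160, "intron"), (161, 194, "exon")),
        primers=("t412F:CCGGACTGAAGGTTATCGCTTG", "t1140R:GGTTGTCAGCGAATGCTTCCGC"),
    ),
    "nesEI533": MarkerSegmentDef(
        marker="NES",
        segment_name="nesEI533",
        segment_length_nominal=533,
        diagnostic_site=299,
        c_allele="T",
        r_allele="C",
        exon_intron_boundaries=((1, 230, "intron"), (231, 533, "exon")),
        primers=("n3212F:AGCAACGGGGTTAGACATGG", "n3907R:TCGGACGAGTTCAGGGAAAC"),
    ),
}


def _is_usable(residues: str) -> bool:
    return all(c in UNAMBIGUOUS for c in residues)


@dataclass(frozen=True)
class SequenceRecord:
    """One specimen's sequence for one marker segment."""

    specimen_id: str
    marker: str
    residues: str
    usable: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        object.__setattr__(self, "usable", _is_usable(self.residues))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class MarkerAlignment:
    """Equal-length usable sequences for one marker segment.

    ``column_map[i]`` gives, for alignment column ``i`` (0-based), the
    1-based position in the segment's reference frame, so the diagnostic
    site stays addressable after window extraction.
    """

    segment: MarkerSegmentDef
    records: list[SequenceRecord]
    column_map: list[int]
    outgroup_id: str | None = None

    def __post_init__(self) -> None:
        ids = [r.specimen_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate specimen ids in alignment: {dupes}")
        lengths = {len(r) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(f"unequal record lengths: {sorted(lengths)}")
        bad = [r.specimen_id for r in self.records if not r.usable]
        if bad:
            raise ValueError(f"unusable (ambiguous) records in alignment: {bad}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues) if self.records else 0

    def ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    def sequences(self) -> list[str]:
        return [r.residues for r in self.records]

    def diagnostic_column(self) -> int:
        """0-based alignment column holding the segment's diagnostic site."""
        try:
            return self.column_map.index(self.segment.diagnostic_site)
        except ValueError:
            raise ValueError(
                f"diagnostic site {self.segment.diagnostic_site} not covered "
                f"by this alignment window"
            ) from None

    def ingroup(self) -> "MarkerAlignment":
        """Alignment without the outgroup record (no-op if none set)."""
        if self.outgroup_id is None:
            return self
        recs = [r for r in self.records if r.specimen_id != self.outgroup_id]
        return MarkerAlignment(self.segment, recs, list(self.column_map), None)


def read_fasta(path: str | Path, marker: str = "") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    The specimen id is the first whitespace-delimited token of the header.
    Residues are uppercased; the ``usable`` flag is computed from the
    presence of IUPAC ambiguity codes.  Duplicate ids raise.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise ValueError(f"malformed FASTA {path}: {exc}") from exc
    for rec in parsed:
        if not rec.id:
            raise ValueError(f"malformed FASTA {path}: entry with empty header")
        if rec.id in seen:
            raise ValueError(f"duplicate specimen id in {path}: {rec.id}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, marker, str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, 70 columns per line."""
    seqs = [SeqRecord(Seq(r.residues), id=r.specimen_id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(seqs)


METADATA_COLUMNS = [
    "specimen_id",
    "host_plant",
    "host_class",
    "country",
    "region",
    "continent",
    "date",
    "sex",
]


def read_metadata(path: str | Path) -> dict[str, Specimen]:
    """Read the specimen metadata TSV into a dict keyed by specimen id."""
    # keep_default_na: the North America continent code "NA" is data here
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path} missing columns: {sorted(missing)}")
    specimens: dict[str, Specimen] = {}
    for row in df.itertuples(index=False):
        if row.specimen_id in specimens:
            raise ValueError(f"duplicate specimen id in metadata: {row.specimen_id}")
        specimens[row.specimen_id] = Specimen(
            id=row.specimen_id,
            host_plant=row.host_plant,
            host_class=HostClass(row.host_class),
            country=row.country,
            region=row.region,
            continent=Continent(row.continent),
            collection_date=row.date,
            sex=Sex(row.sex) if row.sex else Sex.UNKNOWN,
        )
    return specimens


def write_metadata(specimens: Iterable[Specimen], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "specimen_id": s.id,
                "host_plant": s.host_plant,
                "host_class": s.host_class.value,
                "country": s.country,
                "region": s.region,
                "continent": s.continent.value,
                "date": s.collection_date,
                "sex": s.sex.value,
            }
            for s in specimens
        ],
        columns=METADATA_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def filter_usable(
    records: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Partition records into (kept, excluded) on the ambiguity rule.

    Only unambiguous sequences enter the analyses; any IUPAC ambiguity code
    (typically a heterozygous ZZ male) excludes the whole sequence.
    """
    kept = [r for r in records if r.usable]
    excluded = [r for r in records if not r.usable]
    return kept, excluded


def build_alignment(
    records: Sequence[SequenceRecord],
    segment_def: MarkerSegmentDef,
    metadata: dict[str, Specimen],
    window: tuple[int, int] | None = None,
    outgroup_id: str | None = None,
) -> MarkerAlignment:
    """Assemble a :class:`MarkerAlignment` from usable records.

    ``window`` is a 1-based inclusive (start, end) range in the segment
    frame; by default the full nominal segment is used.  Records must be
    equal length and every non-outgroup specimen must appear in
    ``metadata``.  Gap-only columns are retained so positions stay stable.
    """
    bad = [r.specimen_id for r in records if not r.usable]
    if bad:
        raise ValueError(f"ambiguous records passed to build_alignment: {bad}")
    lengths = {len(r) for r in records}
    if len(lengths) > 1:
        by_len: dict[int, list[str]] = {}
        for r in records:
            by_len.setdefault(len(r), []).append(r.specimen_id)
        raise ValueError(f"unequal sequence lengths: { {k: v for k, v in sorted(by_len.items())} }")
    unknown = [
        r.specimen_id
        for r in records
        if r.specimen_id not in metadata and r.specimen_id != outgroup_id
    ]
    if unknown:
        raise ValueError(f"specimens absent from metadata: {unknown}")

    if window is None:
        window = (1, lengths.pop() if lengths else segment_def.segment_length_nominal)
    start, end = window
    if start < 1 or end < start:
        raise ValueError(f"invalid window {window}")
    sliced = [
        SequenceRecord(r.specimen_id, r.marker, r.residues[start - 1 : end]) for r in records
    ]
    column_map = list(range(start, start + (len(sliced[0]) if sliced else 0)))
    return MarkerAlignment(segment_def, sliced, column_map, outgroup_id)
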