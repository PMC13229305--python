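"""Candidate-marker discovery and diagnostic-SNP strain calling.

Covers the marker-discovery stage (splitting a Z-chromosome SNP VCF by
strain, biallelic/MAF filtering, gene-level candidate selection with a
physical-spacing rule, and the recombination-distance extrapolation that
motivates marker spacing) and the per-specimen diagnostic-SNP strain call
with its correspondence tables against other identification methods.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .seqdata import MarkerAlignment, MarkerSegmentDef, SequenceRecord

__all__ = [
    "GeneModel",
    "VariantSite",
    "RecombinationEstimate",
    "read_vcf",
    "read_gff3_genes",
    "split_variants_by_strain",
    "filter_biallelic_maf",
    "candidate_genes",
    "cm_estimate",
    "call_diagnostic_snp",
    "call_alignment_snps",
    "correspondence_table",
    "CorrespondenceResult",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene on the focal chromosome (1-based inclusive coordinates)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    n_introns: int
    insect_annotated: bool = False

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start")
        if self.n_introns < 0:
            raise ValueError(f"{self.gene_id}: negative intron count")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def gap_to(self, other: "GeneModel") -> int:
        """Base pairs between the two gene intervals (0 if overlapping)."""
        return max(0, other.start - self.end, self.start - other.end)

    def gap_to_position(self, pos: int) -> int:
        return max(0, self.start - pos, pos - self.end)


@dataclass(frozen=True)
class VariantSite:
    """One variant site with per-sample allele calls.

    ``sample_alleles`` maps sample id -> tuple of allele indexes into
    ``alleles`` (``None`` for missing calls).  ``allele_counts`` are the
    observed counts over non-missing calls of the carried sample set.
    """

    chrom: str
    pos: int
    alleles: tuple[str, ...]
    sample_alleles: dict[str, tuple[int | None, ...]]
    monomorphic: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")

    @property
    def allele_counts(self) -> tuple[int, ...]:
        counts = [0] * len(self.alleles)
        for calls in self.sample_alleles.values():
            for a in calls:
                if a is not None:
                    counts[a] += 1
        return tuple(counts)

    def observed_alleles(self) -> tuple[str, ...]:
        return tuple(a for a, c in zip(self.alleles, self.allele_counts) if c > 0)

    def maf(self) -> float:
        """Minor allele frequency over non-missing calls (0 if monomorphic)."""
        counts = sorted((c for c in self.allele_counts if c > 0), reverse=True)
        total = sum(counts)
        if total == 0 or len(counts) < 2:
            return 0.0
        return counts[1] / total


def read_vcf(path: str | Path) -> list[VariantSite]:
    """Read variant sites and per-sample calls from a VCF (v4.x) file."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    for var in vcf:
        alleles = tuple([var.REF] + list(var.ALT))
        calls: dict[str, tuple[int | None, ...]] = {}
        for sample, gt in zip(samples, var.genotypes):
            # cyvcf2 genotype rows are [allele1, allele2, ..., phased_flag]
            calls[sample] = tuple(a if a >= 0 else None for a in gt[:-1])
        sites.append(VariantSite(var.CHROM, var.POS, alleles, calls))
    return sites


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3_genes(path: str | Path, chrom: str | None = None) -> list[GeneModel]:
    """Read gene models from a GFF3 file.

    Intron counts come from an ``introns`` attribute on the gene line when
    present, otherwise from (number of exon children - 1) via the mRNA
    Parent chain (maximum over isoforms).  The "insect-annotated" flag is
    the boolean attribute ``insect_annotated``.
    """
    genes: dict[str, dict] = {}
    mrna_gene: dict[str, str] = {}
    exon_counts: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
        seqid, _, ftype, start, end, _, _, _, attrs_text = fields
        if chrom is not None and seqid != chrom:
            continue
        attrs = _parse_gff3_attributes(attrs_text)
        if ftype == "gene":
            gid = attrs.get("ID", f"gene:{lineno}")
            genes[gid] = {
                "chrom": seqid,
                "start": int(start),
                "end": int(end),
                "introns": int(attrs["introns"]) if "introns" in attrs else None,
                "insect": attrs.get("insect_annotated", "").lower() in ("1", "true", "yes"),
            }
        elif ftype == "mRNA":
            mid = attrs.get("ID")
            parent = attrs.get("Parent")
            if mid and parent:
                mrna_gene[mid] = parent
        elif ftype == "exon":
            parent = attrs.get("Parent", "")
            for p in parent.split(","):
                exon_counts[p] = exon_counts.get(p, 0) + 1
    models = []
    for gid, g in genes.items():
        n_introns = g["introns"]
        if n_introns is None:
            counts = [c for m, c in exon_counts.items() if mrna_gene.get(m) == gid]
            n_introns = max(counts) - 1 if counts else 0
        models.append(
            GeneModel(gid, g["chrom"], g["start"], g["end"], n_introns, g["insect"])
        )
    return models


def split_variants_by_strain(
    sites: list[VariantSite], strain_of_sample: dict[str, str]
) -> tuple[list[VariantSite], list[VariantSite]]:
    """Split sites into per-strain subsets with recomputed allele counts.

    Every sample must carry a strain label ("C" or "R"); both strains must
    be represented.  Sites monomorphic within a strain are retained with
    the ``monomorphic`` flag set.
    """
    if sites:
        unlabeled = sorted(
            set(sites[0].sample_alleles) - set(strain_of_sample)
        )
        if unlabeled:
            raise ValueError(f"samples without strain label: {unlabeled}")
    c_samples = {s for s, v in strain_of_sample.items() if v == "C"}
    r_samples = {s for s, v in strain_of_sample.items() if v == "R"}
    if not c_samples or not r_samples:
        raise ValueError("both strains must have at least one sample")

    def subset(site: VariantSite, samples: set[str]) -> VariantSite:
        calls = {s: a for s, a in site.sample_alleles.items() if s in samples}
        sub = replace(site, sample_alleles=calls)
        mono = len(sub.observed_alleles()) < 2
        return replace(sub, monomorphic=mono)

    c_sites = [subset(s, c_samples) for s in sites]
    r_sites = [subset(s, r_samples) for s in sites]
    return c_sites, r_sites


def filter_biallelic_maf(sites: list[VariantSite], maf_min: float = 0.05) -> list[VariantSite]:
    """Keep sites with exactly two observed alleles and MAF >= maf_min.

    ``maf_min = 0`` reduces to the biallelic filter alone.  MAF is computed
    from observed allele counts among non-missing calls only.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    return [
        s for s in sites if len(s.observed_alleles()) == 2 and s.maf() >= maf_min
    ]


def candidate_genes(
    genes: list[GeneModel],
    variable_site_counts: dict[str, tuple[int, int]],
    min_len: int = 2000,
    max_len: int = 7000,
    min_introns: int = 2,
    max_introns: int = 5,
    min_spacing_bp: int = 1_000_000,
    anchor_positions: tuple[int, ...] = (),
) -> list[GeneModel]:
    """Rank candidate marker genes under the discovery filters.

    A gene qualifies if its length is within [min_len, max_len], its intron
    count within [min_introns, max_introns], it is insect-annotated, and it
    has at least one within-strain variable site in *each* strain
    (``variable_site_counts[gene_id] = (n_C, n_R)``).  Qualifying genes are
    then accepted greedily by descending total variable-site count (gene id
    as the deterministic tie-break), skipping any gene closer than
    ``min_spacing_bp`` to an anchor position or a previously accepted
    candidate.
    """
    chroms = {g.chrom for g in genes}
    if len(chroms) > 1:
        raise ValueError(f"genes span multiple chromosomes: {sorted(chroms)}")
    qualifying = []
    for g in genes:
        n_c, n_r = variable_site_counts.get(g.gene_id, (0, 0))
        if (
            min_len <= g.length <= max_len
            and min_introns <= g.n_introns <= max_introns
            and g.insect_annotated
            and n_c >= 1
            and n_r >= 1
        ):
            qualifying.append((n_c + n_r, g))
    qualifying.sort(key=lambda t: (-t[0], t[1].gene_id))
    accepted: list[GeneModel] = []
    for _, g in qualifying:
        if any(g.gap_to_position(pos) < min_spacing_bp for pos in anchor_positions):
            continue
        if any(g.gap_to(other) < min_spacing_bp for other in accepted):
            continue
        accepted.append(g)
    return accepted


@dataclass(frozen=True)
class RecombinationEstimate:
    """Expected recombination between two loci from physical distance.

    cM = distance (Mb) x rate (cM/Mb); the recombinant fraction is capped
    at 50%, the maximum for unlinked loci.
    """

    distance_mb: float
    rate_cm_per_mb: float
    cm: float
    fraction_pct: float


def cm_estimate(distance_mb: float, rate_cm_per_mb: float) -> RecombinationEstimate:
    if distance_mb < 0 or rate_cm_per_mb < 0:
        raise ValueError("distance and rate must be >= 0")
    cm = distance_mb * rate_cm_per_mb
    return RecombinationEstimate(distance_mb, rate_cm_per_mb, cm, min(cm, 50.0))


def call_diagnostic_snp(
    record: SequenceRecord | str,
    segment_def: MarkerSegmentDef,
    diagnostic_column: int | None = None,
) -> str:
    """Call a specimen's strain from the diagnostic exon SNP.

    The base at the diagnostic site (1-based in the segment frame, or the
    explicit 0-based ``diagnostic_column`` of an extracted window) maps
    c_allele -> "C", r_allele -> "R"; any other residue, gap or ambiguity
    code yields "UNDETERMINED".
    """
    residues = record.residues if isinstance(record, SequenceRecord) else record
    col = diagnostic_column if diagnostic_column is not None else segment_def.diagnostic_site - 1
    if not 0 <= col < len(residues):
        raise ValueError(
            f"diagnostic position {col + 1} outside sequence of length {len(residues)}"
        )
    base = residues[col].upper()
    if base == segment_def.c_allele:
        return "C"
    if base == segment_def.r_allele:
        return "R"
    return "UNDETERMINED"


def call_alignment_snps(alignment: MarkerAlignment) -> dict[str, str]:
    """Diagnostic-SNP call for every record of a marker alignment."""
    col = alignment.diagnostic_column()
    return {
        r.specimen_id: call_diagnostic_snp(r, alignment.segment, diagnostic_column=col)
        for r in alignment.records
    }


@dataclass
class CorrespondenceResult:
    """Row-percentage agreement between two strain-calling methods."""

    counts: pd.DataFrame  # rows: method A classes, cols: method B classes
    percentages: pd.DataFrame
    n_excluded: int  # specimens UNDETERMINED under either method

    def agreement(self) -> float:
        """Overall percent agreement on the shared diagonal classes."""
        total = self.counts.values.sum()
        if total == 0:
            return float("nan")
        diag = sum(
            self.counts.at[c, c]
            for c in self.counts.index
            if c in self.counts.columns
        )
        return 100.0 * diag / total


def correspondence_table(
    calls_a: dict[str, str], calls_b: dict[str, str]
) -> CorrespondenceResult:
    """Cross-tabulate two call sets over their shared specimen universe.

    UNDETERMINED calls under either method are excluded from the
    percentages, with the excluded count reported.  Disjoint specimen sets
    raise.
    """
    shared = sorted(set(calls_a) & set(calls_b))
    if not shared:
        raise ValueError("call sets share no specimens")
    pairs = [(calls_a[s], calls_b[s]) for s in shared]
    n_excluded = sum(1 for a, b in pairs if "UNDETERMINED" in (a, b))
    kept = [(a, b) for a, b in pairs if "UNDETERMINED" not in (a, b)]
    df = pd.DataFrame(kept, columns=["a", "b"])
    counts = pd.crosstab(df["a"], df["b"]) if kept else pd.DataFrame()
    counts.index.name = "method_a"
    counts.columns.name = "method_b"
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return CorrespondenceResult(counts, pct, n_excluded)
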