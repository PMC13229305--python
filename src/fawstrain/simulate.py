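"""Synthetic cohort generator for the strain-marker analysis.

Emulates the statistical structure the downstream analysis assumes, without
any sequence downloads: three Z-linked exon+intron marker segments each
carrying one strain-diagnostic exon SNP; a low-diversity C-strain derived
from few founder haplotypes versus a high-diversity R-strain pool; founder
indels confined to introns; ZZ males drawing two independent haplotypes
whose mismatches emit IUPAC ambiguity codes (and are then excluded, as
heterozygous Sanger traces are); and collections structured by continent
and host-plant class, with a configurable fraction of specimens found on
the "wrong" strain's host.

The generator is a founder/resampling model, not a coalescent: each strain
is a small pool of founder haplotypes mutated from a shared ancestor, and
specimens are weighted draws from their strain's pool.  That is sufficient
to realize the assumed structure (fixed diagnostic difference, diversity
asymmetry, intronic indels, heterozygote exclusion) at O(n) cost.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqdata import (
    DEFAULT_SEGMENTS,
    IUPAC_AMBIGUITY,
    Continent,
    HostClass,
    MarkerSegmentDef,
    SequenceRecord,
    Sex,
    Specimen,
    write_fasta,
    write_metadata,
)

__all__ = [
    "SimulationConfig",
    "HaplotypePool",
    "CohortData",
    "build_pools",
    "simulate_cohort",
    "write_cohort",
]

BASES = "ACGT"

C_PLANTS = ("corn", "sorghum", "cotton")
R_PLANTS = ("turf grasses", "pasture grasses", "rice", "millet", "alfalfa")

#: Field-survey collection structure: specimens per (continent, host class).
TABLE_COLLECTION_SIZES: dict[tuple[Continent, HostClass], int] = {
    (Continent.NA, HostClass.C_HOST): 252,
    (Continent.NA, HostClass.R_HOST): 82,
    (Continent.SA, HostClass.C_HOST): 111,
    (Continent.SA, HostClass.R_HOST): 166,
}

OUTGROUP_ID = "OUTGROUP"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    theta_* are expected pairwise diversities per site (introns are the
    variable compartment); ``c_founders`` controls the severity of the
    C-strain bottleneck relative to the ``r_pool_haplotypes`` R lineages;
    ``strain_divergence`` is the substitutions/site accumulated on the
    C-strain founder branch after the strain split, shared by every C
    haplotype (this is what makes the C clade monophyletic);
    ``host_misassignment_rate`` is the probability a specimen is collected
    from the other strain's host plant (label only — the sequence is
    untouched).
    """

    seed: int = 0
    segment_defs: tuple[MarkerSegmentDef, ...] = tuple(DEFAULT_SEGMENTS.values())
    n_per_collection: dict[tuple[Continent, HostClass], int] = field(
        default_factory=lambda: dict(TABLE_COLLECTION_SIZES)
    )
    r_pool_haplotypes: int = 12
    c_founders: int = 2
    theta_intron: float = 0.04
    theta_exon: float = 0.008
    indel_rate: float = 0.25
    male_fraction: float = 0.5
    host_misassignment_rate: float = 0.05
    outgroup_divergence: float = 0.25
    strain_divergence: float = 0.04

    def __post_init__(self) -> None:
        for name in ("indel_rate", "male_fraction", "host_misassignment_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.c_founders < 1:
            raise ValueError("c_founders must be >= 1")
        if self.r_pool_haplotypes < 2:
            raise ValueError("r_pool_haplotypes must be >= 2")
        if self.c_founders > self.r_pool_haplotypes:
            raise ValueError("c_founders cannot exceed r_pool_haplotypes")
        if self.theta_exon > self.theta_intron:
            raise ValueError("theta_exon cannot exceed theta_intron")
        for name in ("theta_intron", "theta_exon", "outgroup_divergence", "strain_divergence"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class HaplotypePool:
    """Founder haplotypes and frequencies for one strain at one segment."""

    strain: str  # "C" or "R"
    haplotypes: tuple[str, ...]
    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(sum(self.frequencies) - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")
        if len(self.haplotypes) != len(self.frequencies):
            raise ValueError("haplotypes/frequencies length mismatch")


def _mutate(seq: np.ndarray, prob: np.ndarray | float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each non-gap position with prob. ``prob`` by a different base."""
    out = seq.copy()
    hit = (rng.random(seq.size) < prob) & (out != 4)
    idx = np.flatnonzero(hit)
    if idx.size:
        # shift by 1..3 mod 4 guarantees a different base
        out[idx] = (out[idx] + rng.integers(1, 4, size=idx.size)) % 4
    return out


_CODE = np.frombuffer(b"ACGT-", dtype=np.uint8)


def _encode(s: str) -> np.ndarray:
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    out = np.empty(arr.size, dtype=np.int8)
    for i, b in enumerate(_CODE):
        out[arr == b] = i
    return out


def _decode(a: np.ndarray) -> str:
    return _CODE[a].tobytes().decode()


def _apply_indels(
    hap: np.ndarray, segment: MarkerSegmentDef, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Delete (gap out) a 1-10 bp run per intron block with prob. ``rate``."""
    out = hap.copy()
    for start, end, kind in segment.exon_intron_boundaries:
        if kind != "intron" or end <= start:
            continue
        if rng.random() < rate:
            length = int(rng.integers(1, 11))
            lo = int(rng.integers(start - 1, max(end - length, start - 1) + 1))
            out[lo : min(lo + length, end)] = 4
    return out


def _segment_rng(config: SimulationConfig, segment_index: int, stream: int) -> np.random.Generator:
    # all streams derive from the single global seed by fixed offsets
    return np.random.default_rng([config.seed, segment_index, stream])


def _theta_profile(config: SimulationConfig, segment: MarkerSegmentDef) -> np.ndarray:
    kinds = segment.region_kinds()
    return np.array(
        [config.theta_intron if k == "intron" else config.theta_exon for k in kinds]
    )


def build_pools(
    config: SimulationConfig,
) -> dict[str, tuple[HaplotypePool, HaplotypePool, str]]:
    """Build per-segment (C pool, R pool, outgroup sequence).

    R haplotypes are independent lineages mutated from a segment ancestor at
    a per-lineage rate of theta/2 (so two lineages differ at ~theta per
    site).  The C pool is founded from ``c_founders`` lineages off a
    C-strain ancestor that carries ``strain_divergence`` substitutions/site
    relative to the shared ancestor.  Each pool is fixed for its strain's
    diagnostic allele; the outgroup diverges from the shared ancestor and
    carries neither constraint.
    """
    pools: dict[str, tuple[HaplotypePool, HaplotypePool, str]] = {}
    for si, segment in enumerate(config.segment_defs):
        L = segment.segment_length_nominal
        site = segment.diagnostic_site - 1
        theta = _theta_profile(config, segment)

        rng = _segment_rng(config, si, 0)
        ancestral = rng.integers(0, 4, size=L).astype(np.int8)

        r_haps = []
        for _ in range(config.r_pool_haplotypes):
            h = _mutate(ancestral, theta / 2.0, rng)
            h = _apply_indels(h, segment, config.indel_rate, rng)
            h[site] = BASES.index(segment.r_allele)
            r_haps.append(_decode(h))

        c_ancestor = _mutate(ancestral, config.strain_divergence, rng)
        c_haps = []
        for _ in range(config.c_founders):
            h = _mutate(c_ancestor, theta / 2.0, rng)
            h = _apply_indels(h, segment, config.indel_rate, rng)
            h[site] = BASES.index(segment.c_allele)
            c_haps.append(_decode(h))

        outgroup = _decode(_mutate(ancestral, config.outgroup_divergence, rng))

        c_pool = HaplotypePool(
            "C", tuple(c_haps), tuple([1.0 / len(c_haps)] * len(c_haps))
        )
        r_pool = HaplotypePool(
            "R", tuple(r_haps), tuple([1.0 / len(r_haps)] * len(r_haps))
        )
        pools[segment.segment_name] = (c_pool, r_pool, outgroup)
    return pools


def _combine_draws(a: str, b: str) -> tuple[str, int]:
    """Merge a male's two haplotype draws into one read, as a Sanger trace would.

    Base/base mismatches become IUPAC ambiguity codes.  The first gap-length
    mismatch acts like a heterozygous frameshift: everything downstream is
    emitted as 'N' (misaligned trace).  Returns (sequence, n differing
    columns between the raw draws).
    """
    n_diff = sum(1 for x, y in zip(a, b) if x != y)
    if n_diff == 0:
        return a, 0
    out: list[str] = []
    for i, (x, y) in enumerate(zip(a, b)):
        if x == y:
            out.append(x)
        elif x == "-" or y == "-":
            out.append("N" * (len(a) - i))
            break
        else:
            out.append(IUPAC_AMBIGUITY[frozenset((x, y))])
    return "".join(out), n_diff


@dataclass
class CohortData:
    """A simulated cohort: sequences, metadata and ground truth."""

    config: SimulationConfig
    pools: dict[str, tuple[HaplotypePool, HaplotypePool, str]]
    sequences: dict[str, list[SequenceRecord]]  # segment_name -> records (outgroup last)
    specimens: list[Specimen]
    truth: pd.DataFrame  # specimen_id, segment, true_strain, host_class, misassigned, sex, usable, n_hap_diffs

    @property
    def metadata(self) -> dict[str, Specimen]:
        return {s.id: s for s in self.specimens}


def simulate_cohort(config: SimulationConfig) -> CohortData:
    """Generate a full cohort under ``config`` (deterministic in the seed).

    Specimens are allocated to (continent, host class) cells per
    ``n_per_collection``.  With probability ``host_misassignment_rate`` a
    specimen's true strain is the one *not* matching its collection host
    (the sequence always follows the true strain; only the host label is
    discordant).  Females are hemizygous (one haplotype); males draw two
    haplotypes and, if the draws differ anywhere, the emitted sequence
    contains ambiguity codes and is unusable.
    """
    pools = build_pools(config)
    rng = np.random.default_rng([config.seed, 9001])

    specimens: list[Specimen] = []
    truth_rows: list[dict] = []
    sequences: dict[str, list[SequenceRecord]] = {
        seg.segment_name: [] for seg in config.segment_defs
    }

    counter = 0
    cells = sorted(config.n_per_collection.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value))
    for (continent, host_class), n in cells:
        for _ in range(n):
            counter += 1
            sid = f"SIM{counter:04d}"
            misassigned = bool(rng.random() < config.host_misassignment_rate)
            if misassigned:
                true_strain = "R" if host_class is HostClass.C_HOST else "C"
            else:
                true_strain = "C" if host_class is HostClass.C_HOST else "R"
            sex = Sex.MALE if rng.random() < config.male_fraction else Sex.FEMALE
            plants = C_PLANTS if host_class is HostClass.C_HOST else R_PLANTS
            plant = plants[int(rng.integers(0, len(plants)))]
            specimens.append(
                Specimen(
                    id=sid,
                    host_plant=plant,
                    host_class=host_class,
                    country="SIMLAND",
                    region=continent.value,
                    continent=continent,
                    collection_date="2020",
                    sex=sex,
                )
            )
            for segment in config.segment_defs:
                c_pool, r_pool, _ = pools[segment.segment_name]
                pool = c_pool if true_strain == "C" else r_pool
                k = len(pool.haplotypes)
                if sex is Sex.MALE:
                    i, j = rng.choice(k, size=2, p=pool.frequencies)
                    seq, n_diff = _combine_draws(pool.haplotypes[i], pool.haplotypes[j])
                else:
                    i = rng.choice(k, p=pool.frequencies)
                    seq, n_diff = pool.haplotypes[i], 0
                rec = SequenceRecord(sid, segment.marker, seq)
                sequences[segment.segment_name].append(rec)
                truth_rows.append(
                    {
                        "specimen_id": sid,
                        "segment": segment.segment_name,
                        "true_strain": true_strain,
                        "host_class": host_class.value,
                        "misassigned": misassigned,
                        "sex": sex.value,
                        "usable": rec.usable,
                        "n_hap_diffs": n_diff,
                    }
                )

    for segment in config.segment_defs:
        outgroup = pools[segment.segment_name][2]
        sequences[segment.segment_name].append(
            SequenceRecord(OUTGROUP_ID, segment.marker, outgroup)
        )

    truth = pd.DataFrame(truth_rows)
    return CohortData(config, pools, sequences, specimens, truth)


def write_cohort(cohort: CohortData, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort as one FASTA per segment plus metadata and truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, records in cohort.sequences.items():
        p = outdir / f"{name}.fasta"
        write_fasta(records, p)
        paths[name] = p
    meta_path = outdir / "metadata.tsv"
    write_metadata(cohort.specimens, meta_path)
    paths["metadata"] = meta_path
    truth_path = outdir / "truth.tsv"
    cohort.truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths
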