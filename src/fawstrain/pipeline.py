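"""End-to-end orchestration of the strain-marker validation analysis.

Runs, per marker segment and continent: ingest and usability filtering,
TN93 distances, NJ tree with bootstrap, outgroup rooting, C-strain clade
extraction, the three strain calls per specimen (host, clade, SNP) with
pooled correspondence tables, per-strain diversity, the six-comparison
divergence grid per marker (Fst/Dxy over host-class x continent
populations), and ANOVA/Tukey category summaries.  Everything is
reproducible from a config plus one seed, with estimator choices logged in
the report provenance.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .markers import call_alignment_snps, correspondence_table, CorrespondenceResult
from .phylo import (
    CladePartition,
    bootstrap_support,
    extract_strain_clade,
    fit_tn93_params,
    nni_refine,
    root_with_outgroup,
)
from .popstats import (
    DiversityStats,
    GroupComparison,
    anova_tukey,
    diversity_stats,
    dxy,
    fst_components,
)
from .seqdata import (
    Continent,
    MarkerSegmentDef,
    Specimen,
    build_alignment,
    filter_usable,
    read_fasta,
    read_metadata,
)

__all__ = [
    "DivergenceRecord",
    "GridSummary",
    "AnalysisConfig",
    "AnalysisReport",
    "GRID_COMPARISONS",
    "build_comparison_grid",
    "aggregate_grid",
    "load_reference_grid",
    "grid_category_groups",
    "run_full_analysis",
]

#: The six population comparisons per marker, in presentation order:
#: within-continent C-vs-R (x2), between-continent C-vs-R (x2), then the
#: two within-strain between-continent comparisons.
GRID_COMPARISONS: list[tuple[tuple[str, str], tuple[str, str], str]] = [
    (("C", "NA"), ("R", "NA"), "CSRS_WITHIN"),
    (("C", "NA"), ("R", "SA"), "CSRS_BETWEEN"),
    (("R", "NA"), ("C", "SA"), "CSRS_BETWEEN"),
    (("C", "SA"), ("R", "SA"), "CSRS_WITHIN"),
    (("C", "NA"), ("C", "SA"), "CSCS"),
    (("R", "NA"), ("R", "SA"), "RSRS"),
]


@dataclass(frozen=True)
class DivergenceRecord:
    """One population-pair divergence row (the unit of the comparison grid)."""

    marker: str
    pop1: tuple[str, str]  # (host class "C"/"R", continent "NA"/"SA")
    pop2: tuple[str, str]
    fst: float
    dxy: float
    category: str

    def __post_init__(self) -> None:
        strains = {self.pop1[0], self.pop2[0]}
        continents = {self.pop1[1], self.pop2[1]}
        expected = (
            "CSCS"
            if strains == {"C"}
            else "RSRS"
            if strains == {"R"}
            else "CSRS_WITHIN"
            if len(continents) == 1
            else "CSRS_BETWEEN"
        )
        if self.category != expected:
            raise ValueError(
                f"category {self.category} inconsistent with populations "
                f"{self.pop1} vs {self.pop2}"
            )


def build_comparison_grid(
    marker: str, groups: dict[tuple[str, str], list[str]]
) -> tuple[list[DivergenceRecord], list[str]]:
    """Compute the six-comparison Fst/Dxy grid for one marker.

    ``groups`` maps (host class, continent) to that population's usable
    sequences.  Comparisons whose populations are missing (or have < 2
    sequences) are omitted with a warning rather than silently dropped.
    """
    records: list[DivergenceRecord] = []
    warnings: list[str] = []
    for pop1, pop2, category in GRID_COMPARISONS:
        g1, g2 = groups.get(pop1), groups.get(pop2)
        if not g1 or not g2 or len(g1) < 2 or len(g2) < 2:
            warnings.append(
                f"{marker}: comparison {pop1} vs {pop2} omitted "
                "(population missing or < 2 sequences)"
            )
            continue
        records.append(
            DivergenceRecord(
                marker, pop1, pop2, fst_components(g1, g2).fst, dxy(g1, g2), category
            )
        )
    return records, warnings


@dataclass
class GridSummary:
    """Aggregates over a divergence grid (rounded only at presentation)."""

    n_records: int
    grand_mean_fst: float
    grand_mean_dxy: float
    category_mean_fst: dict[str, float]
    category_mean_dxy: dict[str, float]
    marker_category_mean_fst: dict[tuple[str, str], float]
    marker_category_mean_dxy: dict[tuple[str, str], float]

    def rounded(self, digits: int = 3) -> dict:
        return {
            "grand_mean_fst": round(self.grand_mean_fst, digits),
            "grand_mean_dxy": round(self.grand_mean_dxy, digits),
            "category_mean_fst": {
                k: round(v, digits) for k, v in self.category_mean_fst.items()
            },
            "category_mean_dxy": {
                k: round(v, digits) for k, v in self.category_mean_dxy.items()
            },
        }


def aggregate_grid(records: list[DivergenceRecord]) -> GridSummary:
    """Grand and per-category means of Fst and Dxy over grid records."""
    if not records:
        raise ValueError("aggregate_grid requires at least one record")
    df = pd.DataFrame(
        {
            "marker": [r.marker for r in records],
            "category": [r.category for r in records],
            "fst": [r.fst for r in records],
            "dxy": [r.dxy for r in records],
        }
    )
    cat_fst = df.groupby("category")["fst"].mean().to_dict()
    cat_dxy = df.groupby("category")["dxy"].mean().to_dict()
    mc = df.groupby(["marker", "category"])[["fst", "dxy"]].mean()
    return GridSummary(
        n_records=len(records),
        grand_mean_fst=float(df["fst"].mean()),
        grand_mean_dxy=float(df["dxy"].mean()),
        category_mean_fst=cat_fst,
        category_mean_dxy=cat_dxy,
        marker_category_mean_fst={k: float(v) for k, v in mc["fst"].items()},
        marker_category_mean_dxy={k: float(v) for k, v in mc["dxy"].items()},
    )


def load_reference_grid(path: str | Path | None = None) -> list[DivergenceRecord]:
    """Load a divergence grid from TSV (default: the packaged reference grid
    of the three markers from the Western Hemisphere field survey)."""
    if path is None:
        source = importlib.resources.files("fawstrain.data").joinpath(
            "reference_divergence_grid.tsv"
        )
        with importlib.resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        pop1 = (row.pop1_host, row.pop1_continent)
        pop2 = (row.pop2_host, row.pop2_continent)
        strains = {pop1[0], pop2[0]}
        continents = {pop1[1], pop2[1]}
        category = (
            "CSCS"
            if strains == {"C"}
            else "RSRS"
            if strains == {"R"}
            else "CSRS_WITHIN"
            if len(continents) == 1
            else "CSRS_BETWEEN"
        )
        records.append(
            DivergenceRecord(row.marker, pop1, pop2, float(row.fst), float(row.dxy), category)
        )
    return records


def grid_category_groups(
    records: list[DivergenceRecord], metric: str = "fst", pool_between_strain: bool = True
) -> dict[str, list[float]]:
    """Arrange grid values into labeled groups for ANOVA/Tukey.

    With ``pool_between_strain`` the two C-vs-R categories are pooled into
    one "CS-RS" group (the presentation used for the category bar plots),
    against "CS-CS" and "RS-RS".
    """
    groups: dict[str, list[float]] = {}
    for r in records:
        cat = r.category
        if pool_between_strain and cat in ("CSRS_WITHIN", "CSRS_BETWEEN"):
            cat = "CS-RS"
        elif cat == "CSCS":
            cat = "CS-CS"
        elif cat == "RSRS":
            cat = "RS-RS"
        groups.setdefault(cat, []).append(getattr(r, metric))
    return groups


# ---------------------------------------------------------------------------
# Full analysis


@dataclass
class AnalysisConfig:
    """Inputs and knobs for one full analysis run."""

    fasta_paths: dict[str, str | Path]  # segment_name -> FASTA path
    metadata_path: str | Path
    segment_defs: dict[str, MarkerSegmentDef]
    outgroup_id: str | None = None
    bootstrap_replicates: int = 100
    seed: int = 0
    do_ml: bool = False  # NNI-refined likelihood tree alongside NJ
    nni_max_rounds: int = 10


@dataclass
class MarkerContinentResult:
    """Tree-stage outputs for one marker segment on one continent."""

    segment_name: str
    continent: str
    n_usable: int
    n_excluded: int
    newick: str
    ml_newick: str | None
    partition: CladePartition
    ml_partition: CladePartition | None
    discordant_ids: list[str]  # clade calls that differ between NJ and ML


@dataclass
class AnalysisReport:
    """Everything one run produces, plus provenance."""

    tree_results: list[MarkerContinentResult]
    calls: pd.DataFrame  # specimen_id, segment, host_call, clade_call, snp_call
    correspondences: dict[tuple[str, str, str], CorrespondenceResult]
    diversity: list[DiversityStats]
    grid: list[DivergenceRecord]
    grid_warnings: list[str]
    grid_summary: GridSummary | None
    comparisons: dict[str, GroupComparison]
    provenance: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for tr in self.tree_results:
            (outdir / f"{tr.segment_name}_{tr.continent}_nj.nwk").write_text(tr.newick)
            if tr.ml_newick:
                (outdir / f"{tr.segment_name}_{tr.continent}_ml.nwk").write_text(
                    tr.ml_newick
                )
        self.calls.to_csv(outdir / "strain_calls.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "group_id": d.group_id,
                    "n": d.n,
                    "n_sites": d.n_sites,
                    "n_haplotypes": d.n_haplotypes,
                    "Hd": d.Hd,
                    "pi": d.pi,
                }
                for d in self.diversity
            ]
        ).to_csv(outdir / "diversity.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "marker": r.marker,
                    "pop1_host": r.pop1[0],
                    "pop1_continent": r.pop1[1],
                    "pop2_host": r.pop2[0],
                    "pop2_continent": r.pop2[1],
                    "fst": r.fst,
                    "dxy": r.dxy,
                    "category": r.category,
                }
                for r in self.grid
            ]
        ).to_csv(outdir / "divergence_grid.tsv", sep="\t", index=False)
        for (seg, a, b), corr in self.correspondences.items():
            corr.percentages.to_csv(outdir / f"correspondence_{seg}_{a}_vs_{b}.tsv", sep="\t")
        (outdir / "provenance.json").write_text(json.dumps(self.provenance, indent=2))


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _host_call(specimen: Specimen) -> str:
    return specimen.host_class.value


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run the whole pipeline on FASTA/TSV inputs (real or simulated).

    Continents are analyzed separately for trees; the host/clade/SNP
    correspondence percentages pool both continents.  The divergence grid
    uses host-class x continent populations of usable sequences.  Fully
    deterministic given config + seed.
    """
    stage = "ingest"
    try:
        metadata = read_metadata(config.metadata_path)
        raw = {
            name: read_fasta(path, marker=config.segment_defs[name].marker)
            for name, path in config.fasta_paths.items()
        }
    except Exception as exc:  # noqa: BLE001 - stage context
        raise StageError(stage, exc) from exc

    tree_results: list[MarkerContinentResult] = []
    call_rows: list[dict] = []
    diversity: list[DiversityStats] = []
    correspondences: dict[tuple[str, str, str], CorrespondenceResult] = {}
    grid: list[DivergenceRecord] = []
    grid_warnings: list[str] = []

    for seg_name, records in raw.items():
        segdef = config.segment_defs[seg_name]
        stage = f"usability_filter[{seg_name}]"
        try:
            kept, excluded = filter_usable(records)
        except Exception as exc:
            raise StageError(stage, exc) from exc

        clade_calls: dict[str, str] = {}
        ml_clade_calls: dict[str, str] = {}
        snp_calls: dict[str, str] = {}
        host_calls: dict[str, str] = {}

        for continent in (Continent.NA, Continent.SA):
            cont_records = [
                r
                for r in kept
                if (
                    r.specimen_id in metadata
                    and metadata[r.specimen_id].continent is continent
                )
            ]
            if len(cont_records) < 3:
                continue
            if config.outgroup_id is not None:
                og = [r for r in kept if r.specimen_id == config.outgroup_id]
                cont_records = cont_records + og
            stage = f"alignment[{seg_name},{continent.value}]"
            try:
                aln = build_alignment(
                    cont_records, segdef, metadata, outgroup_id=config.outgroup_id
                )
            except Exception as exc:
                raise StageError(stage, exc) from exc

            stage = f"tree[{seg_name},{continent.value}]"
            try:
                tree = bootstrap_support(
                    aln, B=config.bootstrap_replicates, seed=config.seed
                )
                if config.outgroup_id is not None:
                    rooted = root_with_outgroup(tree, config.outgroup_id)
                else:
                    rooted = tree
                host_labels = {
                    r.specimen_id: metadata[r.specimen_id].host_class
                    for r in aln.records
                    if r.specimen_id in metadata
                }
                if len(set(host_labels.values())) < 2:
                    grid_warnings.append(
                        f"{seg_name}/{continent.value}: single host class on this "
                        "continent; clade partition skipped"
                    )
                    continue
                partition = extract_strain_clade(rooted, host_labels)
                ml_partition = None
                ml_newick = None
                if config.do_ml:
                    params = fit_tn93_params(tree, aln)
                    ml_tree, _ = nni_refine(
                        tree, aln, params, max_rounds=config.nni_max_rounds
                    )
                    ml_rooted = (
                        root_with_outgroup(ml_tree, config.outgroup_id)
                        if config.outgroup_id is not None
                        else ml_tree
                    )
                    ml_partition = extract_strain_clade(ml_rooted, host_labels)
                    ml_newick = ml_rooted.as_string(schema="newick")
            except Exception as exc:
                raise StageError(stage, exc) from exc

            for sid in host_labels:
                clade_calls[sid] = "C" if sid in partition.c_clade_ids else "R"
                if ml_partition is not None:
                    ml_clade_calls[sid] = (
                        "C" if sid in ml_partition.c_clade_ids else "R"
                    )
            discordant = sorted(
                sid
                for sid in ml_clade_calls
                if sid in clade_calls and ml_clade_calls[sid] != clade_calls[sid]
            )
            tree_results.append(
                MarkerContinentResult(
                    seg_name,
                    continent.value,
                    n_usable=len(host_labels),
                    n_excluded=len(excluded),
                    newick=rooted.as_string(schema="newick"),
                    ml_newick=ml_newick,
                    partition=partition,
                    ml_partition=ml_partition,
                    discordant_ids=discordant,
                )
            )

            stage = f"diversity[{seg_name},{continent.value}]"
            try:
                ingroup = aln.ingroup()
                seq_of = {r.specimen_id: r.residues for r in ingroup.records}
                for strain, ids in (
                    ("C", partition.c_clade_ids),
                    ("R", partition.r_rest_ids),
                ):
                    seqs = [seq_of[i] for i in ids if i in seq_of]
                    if len(seqs) >= 2:
                        diversity.append(
                            diversity_stats(
                                f"{seg_name}:{continent.value}:{strain}", seqs
                            )
                        )
            except Exception as exc:
                raise StageError(stage, exc) from exc

            stage = f"snp_calls[{seg_name},{continent.value}]"
            try:
                snp_calls.update(
                    {
                        k: v
                        for k, v in call_alignment_snps(aln.ingroup()).items()
                    }
                )
            except Exception as exc:
                raise StageError(stage, exc) from exc
            host_calls.update(
                {sid: _host_call(metadata[sid]) for sid in host_labels}
            )

        stage = f"correspondence[{seg_name}]"
        try:
            if clade_calls and host_calls:
                correspondences[(seg_name, "clade", "host")] = correspondence_table(
                    clade_calls, host_calls
                )
            if snp_calls and clade_calls:
                correspondences[(seg_name, "snp", "clade")] = correspondence_table(
                    snp_calls, clade_calls
                )
            if snp_calls and host_calls:
                correspondences[(seg_name, "snp", "host")] = correspondence_table(
                    snp_calls, host_calls
                )
        except Exception as exc:
            raise StageError(stage, exc) from exc

        for sid in sorted(set(host_calls) | set(clade_calls) | set(snp_calls)):
            call_rows.append(
                {
                    "specimen_id": sid,
                    "segment": seg_name,
                    "host_call": host_calls.get(sid, "UNDETERMINED"),
                    "clade_call": clade_calls.get(sid, "UNDETERMINED"),
                    "snp_call": snp_calls.get(sid, "UNDETERMINED"),
                }
            )

        stage = f"grid[{seg_name}]"
        try:
            groups: dict[tuple[str, str], list[str]] = {}
            for r in kept:
                if r.specimen_id not in metadata:
                    continue
                sp = metadata[r.specimen_id]
                key = (sp.host_class.value, sp.continent.value)
                groups.setdefault(key, []).append(r.residues)
            seg_grid, seg_warn = build_comparison_grid(seg_name, groups)
            grid.extend(seg_grid)
            grid_warnings.extend(seg_warn)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    stage = "aggregate"
    try:
        grid_summary = aggregate_grid(grid) if grid else None
        comparisons: dict[str, GroupComparison] = {}
        for metric in ("fst", "dxy"):
            groups_m = grid_category_groups(grid, metric=metric)
            if len(groups_m) >= 2 and all(len(v) >= 2 for v in groups_m.values()):
                try:
                    comparisons[metric] = anova_tukey(groups_m)
                except ValueError:
                    pass  # degenerate ANOVA on tiny grids; reported as absent
    except Exception as exc:
        raise StageError(stage, exc) from exc

    provenance = {
        "package": "fawstrain",
        "version": __version__,
        "seed": config.seed,
        "bootstrap_replicates": config.bootstrap_replicates,
        "do_ml": config.do_ml,
        "estimators": {
            "distance": "TN93, pairwise deletion",
            "fst": "Hudson 1 - Hw/Hb, unweighted Hw, complete deletion",
            "dxy": "uncorrected mean between-population difference, complete deletion",
            "diversity_deletion": "complete within group",
            "t_test": "Welch two-tailed",
            "posthoc": "Tukey HSD (Tukey-Kramer on unbalanced groups)",
        },
        "grid_warnings": grid_warnings,
    }
    return AnalysisReport(
        tree_results=tree_results,
        calls=pd.DataFrame(call_rows),
        correspondences=correspondences,
        diversity=diversity,
        grid=grid,
        grid_warnings=grid_warnings,
        grid_summary=grid_summary,
        comparisons=comparisons,
        provenance=provenance,
    )
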