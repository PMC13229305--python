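"""Diversity and divergence statistics over marker-segment alignments.

Within-group variation is summarized by haplotype diversity (Hd) and
nucleotide diversity (pi); between-population divergence by Hudson-style
Fst (1 - Hw/Hb over mean pairwise differences) and uncorrected Dxy (mean
between-population per-site difference).  Group comparisons use Welch's
two-tailed t-test and one-way ANOVA with Tukey HSD (Tukey-Kramer on
unbalanced groups) plus a compact letter display at alpha = 0.05.

Site handling: *complete deletion* within each analysis group — columns
carrying a gap or ambiguity code in any sequence of the group (for Fst and
Dxy, of both populations pooled) are removed before counting.  This
mirrors the convention of the diversity software the workflow is modeled
on and deliberately differs from the pairwise deletion used for tree
distances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .phylo import encode_sequences

__all__ = [
    "DiversityStats",
    "FstResult",
    "TTestResult",
    "GroupComparison",
    "haplotype_diversity",
    "nucleotide_diversity",
    "diversity_stats",
    "fst_pairwise",
    "fst_components",
    "dxy",
    "t_test_two_tailed",
    "anova_tukey",
]


def _complete_deletion(seqs: list[str]) -> np.ndarray:
    """Encode sequences and drop columns with any gap/ambiguity in the group."""
    enc = encode_sequences([s.upper() for s in seqs])
    keep = np.all(enc < 4, axis=0)
    return enc[:, keep]


def _haplotype_counts(enc: np.ndarray) -> np.ndarray:
    """Multiplicities of distinct row patterns."""
    _, counts = np.unique(enc, axis=0, return_counts=True)
    return counts


def haplotype_diversity(seqs: list[str]) -> float:
    """Haplotype diversity Hd = (n/(n-1)) (1 - sum p_i^2).

    Haplotypes are distinguished on the sites surviving complete deletion
    within the group.
    """
    n = len(seqs)
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    enc = _complete_deletion(seqs)
    counts = _haplotype_counts(enc)
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def _mean_pairwise_within(enc: np.ndarray) -> float:
    """Mean per-site difference proportion over all within-group pairs."""
    n, L = enc.shape
    if L == 0:
        raise ValueError("zero comparable sites after complete deletion")
    haps, counts = np.unique(enc, axis=0, return_counts=True)
    total = 0.0
    for i in range(len(haps)):
        for j in range(i + 1, len(haps)):
            dij = np.count_nonzero(haps[i] != haps[j]) / L
            total += counts[i] * counts[j] * dij
    return total / (n * (n - 1) / 2)


def nucleotide_diversity(seqs: list[str]) -> float:
    """Nucleotide diversity pi: mean pairwise difference per comparable site.

    Equals (n/(n-1)) sum_i sum_j x_i x_j pi_ij, i.e. the unbiased average
    over all C(n,2) sequence pairs, computed on sites surviving complete
    deletion within the group.
    """
    n = len(seqs)
    if n < 2:
        raise ValueError("nucleotide diversity requires n >= 2")
    return float(_mean_pairwise_within(_complete_deletion(seqs)))


@dataclass(frozen=True)
class DiversityStats:
    """Within-group diversity summary."""

    group_id: str
    n: int
    n_sites: int
    n_haplotypes: int
    Hd: float
    pi: float


def diversity_stats(group_id: str, seqs: list[str]) -> DiversityStats:
    n = len(seqs)
    if n < 2:
        raise ValueError("diversity requires n >= 2")
    enc = _complete_deletion(seqs)
    counts = _haplotype_counts(enc)
    p = counts / n
    hd = float(n / (n - 1) * (1.0 - np.sum(p**2)))
    pi = float(_mean_pairwise_within(enc))
    return DiversityStats(group_id, n, enc.shape[1], len(counts), hd, pi)


def _cross_mean_pairwise(enc1: np.ndarray, enc2: np.ndarray) -> float:
    L = enc1.shape[1]
    if L == 0:
        raise ValueError("zero comparable sites after complete deletion")
    h1, c1 = np.unique(enc1, axis=0, return_counts=True)
    h2, c2 = np.unique(enc2, axis=0, return_counts=True)
    total = 0.0
    for i in range(len(h1)):
        diffs = np.count_nonzero(h1[i] != h2, axis=1) / L
        total += c1[i] * float(np.dot(c2, diffs))
    return total / (enc1.shape[0] * enc2.shape[0])


def _split_complete_deletion(pop1: list[str], pop2: list[str]) -> tuple[np.ndarray, np.ndarray]:
    enc = _complete_deletion(list(pop1) + list(pop2))
    return enc[: len(pop1)], enc[len(pop1) :]


@dataclass(frozen=True)
class FstResult:
    fst: float
    hw: float
    hb: float
    degenerate: bool = False


def fst_components(pop1_seqs: list[str], pop2_seqs: list[str]) -> FstResult:
    """Hudson-style Fst = 1 - Hw/Hb with its components.

    Hw is the unweighted mean of the two within-population mean pairwise
    differences per site; Hb the mean pairwise difference per site across
    populations.  Complete deletion is applied over the pooled pair.
    Hb = 0 yields Fst = 0 with the degeneracy flag set.  Values may be
    negative by sampling.
    """
    if len(pop1_seqs) < 2 or len(pop2_seqs) < 2:
        raise ValueError("each population needs >= 2 sequences")
    enc1, enc2 = _split_complete_deletion(pop1_seqs, pop2_seqs)
    hw = 0.5 * (_mean_pairwise_within(enc1) + _mean_pairwise_within(enc2))
    hb = _cross_mean_pairwise(enc1, enc2)
    if hb == 0.0:
        return FstResult(0.0, hw, hb, degenerate=True)
    return FstResult(1.0 - hw / hb, hw, hb, degenerate=False)


def fst_pairwise(pop1_seqs: list[str], pop2_seqs: list[str]) -> float:
    return fst_components(pop1_seqs, pop2_seqs).fst


def dxy(pop1_seqs: list[str], pop2_seqs: list[str]) -> float:
    """Uncorrected absolute divergence: mean between-population per-site
    difference over all cross pairs, on sites surviving complete deletion
    over the pooled populations."""
    if not pop1_seqs or not pop2_seqs:
        raise ValueError("both populations must be non-empty")
    enc1, enc2 = _split_complete_deletion(pop1_seqs, pop2_seqs)
    return float(_cross_mean_pairwise(enc1, enc2))


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    degenerate: bool = False


def t_test_two_tailed(values_a: list[float], values_b: list[float]) -> TTestResult:
    """Welch's unequal-variance two-tailed t-test.

    Degenerate inputs (zero variance in both groups) are flagged: equal
    means give p = 1, unequal means the p -> 0 limit.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, degenerate=True)
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return TTestResult(sign * np.inf, 0.0, degenerate=True)
    t, p = scipy.stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(t), float(p), degenerate=False)


@dataclass
class GroupComparison:
    """One-way ANOVA with Tukey HSD post-hoc and compact letter display."""

    groups: dict[str, list[float]]
    means: dict[str, float]
    sds: dict[str, float]
    F_stat: float
    p_anova: float
    tukey: list[tuple[str, str, float, float, bool]]  # (g1, g2, diff, p_adj, reject)
    letters: dict[str, str] = field(default_factory=dict)


def _compact_letter_display(
    names: list[str], means: dict[str, float], nonsig_pairs: set[frozenset]
) -> dict[str, str]:
    """Assign shared letters to groups not significantly different.

    Letters follow the maximal cliques of the non-significance graph,
    ordered by descending clique mean (the usual presentation convention).
    """
    order = sorted(names, key=lambda g: -means[g])
    cliques = []
    for r in range(len(order), 0, -1):
        for combo in itertools.combinations(order, r):
            if all(
                frozenset((a, b)) in nonsig_pairs
                for a, b in itertools.combinations(combo, 2)
            ):
                cs = set(combo)
                if not any(cs <= c for c in cliques):
                    cliques.append(cs)
    cliques.sort(key=lambda c: -max(means[g] for g in c))
    letters = {g: "" for g in names}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in order:
            if g in clique:
                letters[g] += letter
    return letters


def anova_tukey(groups: dict[str, list[float]], alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA over labeled groups with Tukey HSD post-hoc testing.

    Requires >= 2 groups of >= 2 values each; all-zero within-group
    variance is rejected as degenerate.  Adjusted p-values come from the
    studentized-range distribution (Tukey-Kramer on unbalanced designs);
    the compact letter display is computed at the given alpha.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if all(np.var(v) == 0.0 for v in arrays.values()):
        raise ValueError("degenerate ANOVA: zero within-group variance in every group")

    F, p = scipy.stats.f_oneway(*arrays.values())
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    tukey: list[tuple[str, str, float, float, bool]] = []
    nonsig: set[frozenset] = set()
    for row in zip(
        res.groupsunique[res._multicomp.pairindices[0]],
        res.groupsunique[res._multicomp.pairindices[1]],
        res.meandiffs,
        res.pvalues,
        res.reject,
    ):
        g1, g2, diff, padj, reject = str(row[0]), str(row[1]), float(row[2]), float(row[3]), bool(row[4])
        tukey.append((g1, g2, diff, padj, reject))
        if not reject:
            nonsig.add(frozenset((g1, g2)))
    means = {k: float(v.mean()) for k, v in arrays.items()}
    sds = {k: float(v.std(ddof=1)) for k, v in arrays.items()}
    letters = _compact_letter_display(list(groups), means, nonsig)
    return GroupComparison(
        groups={k: list(map(float, v)) for k, v in arrays.items()},
        means=means,
        sds=sds,
        F_stat=float(F),
        p_anova=float(p),
        tukey=tukey,
        letters=letters,
    )
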