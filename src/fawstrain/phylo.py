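"""Distance-based and likelihood-based phylogenetics for marker segments.

Implements the tree stage of the strain-marker workflow: Tamura–Nei (1993)
pairwise distances with pairwise deletion of gapped/ambiguous sites,
neighbor-joining with deterministic tie-breaking, outgroup rooting,
nonparametric bootstrap over alignment columns, Felsenstein-pruning
log-likelihood under the TN93 substitution model, greedy NNI hill-climbing
as a maximum-likelihood refinement of the NJ start tree, and extraction of
the C-strain clade (the monophyletic group best matching C-host labels).

Trees are :class:`dendropy.Tree` objects throughout; tip labels are
specimen ids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import scipy.linalg

from .seqdata import HostClass, MarkerAlignment

__all__ = [
    "TN93Params",
    "DistanceMatrix",
    "CladePartition",
    "SaturationError",
    "tn93_distance",
    "distance_matrix",
    "nj_tree",
    "root_with_outgroup",
    "bootstrap_support",
    "tn93_loglik",
    "fit_tn93_params",
    "nni_refine",
    "extract_strain_clade",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
PURINES = (0, 2)  # A, G
PYRIMIDINES = (1, 3)  # C, T


class SaturationError(ValueError):
    """A pairwise distance is undefined (logarithm argument <= 0)."""


def encode_sequences(seqs: list[str]) -> np.ndarray:
    """Encode sequences as an (n, L) int8 array; A,C,G,T -> 0..3, other -> 4."""
    n, L = len(seqs), len(seqs[0]) if seqs else 0
    arr = np.full((n, L), 4, dtype=np.int8)
    for i, s in enumerate(seqs):
        raw = np.frombuffer(s.encode(), dtype=np.uint8)
        for base, code in _BASE_INDEX.items():
            arr[i, raw == ord(base)] = code
    return arr


def _tn93_from_counts(
    n_sites: int, p1: float, p2: float, q: float, freqs: np.ndarray
) -> float:
    """Closed-form TN93 distance from substitution proportions and base freqs.

    p1/p2 are purine/pyrimidine transition proportions, q the transversion
    proportion, freqs the (A, C, G, T) frequencies pooled over the pair.
    Returns NaN when a logarithm argument is <= 0 (saturation).
    """
    gA, gC, gG, gT = freqs
    gR, gY = gA + gG, gC + gT
    k1 = 2.0 * gA * gG / gR if gR > 0 else 0.0
    k2 = 2.0 * gC * gT / gY if gY > 0 else 0.0
    k3 = 2.0 * (gR * gY)
    if k1 > 0:
        k3 -= 2.0 * gA * gG * gY / gR
    if k2 > 0:
        k3 -= 2.0 * gC * gT * gR / gY
    d = 0.0
    if k1 > 0:
        w1 = 1.0 - p1 / k1 - q / (2.0 * gR)
        if w1 <= 0:
            return math.nan
        d -= k1 * math.log(w1)
    elif p1 > 0:
        return math.nan
    if k2 > 0:
        w2 = 1.0 - p2 / k2 - q / (2.0 * gY)
        if w2 <= 0:
            return math.nan
        d -= k2 * math.log(w2)
    elif p2 > 0:
        return math.nan
    if gR > 0 and gY > 0:
        w3 = 1.0 - q / (2.0 * gR * gY)
        if w3 <= 0:
            return math.nan
        d -= k3 * math.log(w3)
    elif q > 0:
        return math.nan
    return max(d, 0.0)


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, float, float, float, np.ndarray]:
    """Comparable-site count, (P1, P2, Q) proportions and pooled base freqs."""
    valid = (a < 4) & (b < 4)
    n = int(valid.sum())
    if n == 0:
        return 0, 0.0, 0.0, 0.0, np.zeros(4)
    av, bv = a[valid], b[valid]
    diff = av != bv
    s = av[diff] + bv[diff]  # A<->G sums to 2, C<->T sums to 4
    prod = av[diff] * bv[diff]
    p1 = int(np.sum((s == 2) & (prod == 0))) / n  # A(0) <-> G(2)
    p2 = int(np.sum((s == 4) & (prod == 3))) / n  # C(1) <-> T(3)
    q = int(diff.sum()) / n - p1 - p2
    counts = np.bincount(av, minlength=4).astype(float) + np.bincount(bv, minlength=4)
    return n, p1, p2, q, counts / (2.0 * n)


def tn93_distance(seq_a: str, seq_b: str) -> float:
    """Tamura–Nei (1993) distance between two aligned sequences.

    Sites where either sequence carries a gap or ambiguity code are removed
    (pairwise deletion).  Returns substitutions/site; NaN when the distance
    is saturated.  Raises if the sequences differ in length or share no
    comparable site.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"sequence lengths differ: {len(seq_a)} vs {len(seq_b)}")
    enc = encode_sequences([seq_a.upper(), seq_b.upper()])
    n, p1, p2, q, freqs = _pair_counts(enc[0], enc[1])
    if n == 0:
        raise ValueError("zero comparable sites between the pair")
    return _tn93_from_counts(n, p1, p2, q, freqs)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise distances in substitutions/site."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxa must be unique")
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.taxa) + "\n")
            for name, row in zip(self.taxa, self.d):
                fh.write(name + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def distance_matrix(
    alignment: MarkerAlignment | list[str], taxa: list[str] | None = None
) -> DistanceMatrix:
    """All-pairs TN93 distance matrix for an alignment.

    Raises :class:`SaturationError` naming the offending pairs if any
    distance is saturated.
    """
    if isinstance(alignment, MarkerAlignment):
        seqs, names = alignment.sequences(), alignment.ids()
    else:
        seqs = list(alignment)
        names = taxa if taxa is not None else [f"t{i}" for i in range(len(seqs))]
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    enc = encode_sequences([s.upper() for s in seqs])
    n = len(seqs)
    d = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            nv, p1, p2, q, freqs = _pair_counts(enc[i], enc[j])
            if nv == 0:
                raise ValueError(f"zero comparable sites for pair ({names[i]}, {names[j]})")
            dij = _tn93_from_counts(nv, p1, p2, q, freqs)
            if math.isnan(dij):
                saturated.append((names[i], names[j]))
            d[i, j] = d[j, i] = dij
    if saturated:
        raise SaturationError(f"saturated pairs: {saturated}")
    return DistanceMatrix(list(names), d)


# ---------------------------------------------------------------------------
# Neighbor-joining


def nj_tree(matrix: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor-joining tree (unrooted) from a distance matrix.

    Deterministic: ties in the Q criterion are broken by the lowest pair of
    original taxon indices.  Negative branch lengths are clamped to zero
    with the deficit transferred to the sibling edge; the raw value is kept
    in the node annotation ``raw_length``.
    """
    n = len(matrix.taxa)
    if n < 3:
        raise ValueError("neighbor-joining requires at least 3 taxa")

    ns = dendropy.TaxonNamespace(matrix.taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes: list[dendropy.Node] = []
    for label in matrix.taxa:
        node = dendropy.Node(taxon=ns.get_taxon(label))
        nodes.append(node)

    D = matrix.d.astype(float).copy()
    active = list(range(n))  # indices into rows of D / nodes
    min_taxon = {i: i for i in range(n)}  # lowest original taxon index per cluster
    node_of = {i: nodes[i] for i in range(n)}
    next_row = n
    # grow D dynamically via dict-of-dict to keep code simple at these sizes
    dist = {i: {j: D[i, j] for j in active if j != i} for i in active}

    def set_length(node: dendropy.Node, raw: float) -> None:
        node.edge.length = max(raw, 0.0)
        node.annotations.add_new("raw_length", raw)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist[i][j] for j in active if j != i) for i in active}
        best = None
        best_key = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                qv = (m - 2) * dist[i][j] - r[i] - r[j]
                lo, hi = sorted((min_taxon[i], min_taxon[j]))
                key = (qv, lo, hi)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (i, j)
        i, j = best
        dij = dist[i][j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li_raw, li = li, 0.0
        else:
            li_raw = li
        if lj < 0:
            li += lj
            li = max(li, 0.0)
            lj_raw, lj = lj, 0.0
        else:
            lj_raw = lj
        parent = dendropy.Node()
        child_i, child_j = node_of[i], node_of[j]
        parent.add_child(child_i)
        parent.add_child(child_j)
        set_length(child_i, li_raw)
        child_i.edge.length = li
        set_length(child_j, lj_raw)
        child_j.edge.length = lj

        u = next_row
        next_row += 1
        dist[u] = {}
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dist[i][k] + dist[j][k] - dij)
            dist[u][k] = dist[k][u] = duk
        for k in active:
            dist[k].pop(i, None)
            dist[k].pop(j, None)
        del dist[i], dist[j]
        active = [k for k in active if k not in (i, j)] + [u]
        node_of[u] = parent
        min_taxon[u] = min(min_taxon[i], min_taxon[j])

    # final three-way join around a central node
    i, j, k = sorted(active, key=lambda c: min_taxon[c])
    center = dendropy.Node()
    vi = 0.5 * (dist[i][j] + dist[i][k] - dist[j][k])
    vj = 0.5 * (dist[i][j] + dist[j][k] - dist[i][k])
    vk = 0.5 * (dist[i][k] + dist[j][k] - dist[i][j])
    for c, v in ((i, vi), (j, vj), (k, vk)):
        node = node_of[c]
        center.add_child(node)
        set_length(node, v)
        node.edge.length = max(v, 0.0)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def root_with_outgroup(tree: dendropy.Tree, outgroup_id: str) -> dendropy.Tree:
    """Root a tree at the midpoint of the outgroup's pendant edge.

    Returns a new rooted tree; the input is not modified.  Idempotent when
    reapplied with the same outgroup.
    """
    rooted = tree.clone(depth=1)
    node = None
    for leaf in rooted.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label == outgroup_id:
            node = leaf
            break
    if node is None:
        raise ValueError(f"outgroup {outgroup_id!r} is not a tip of the tree")
    length = node.edge.length or 0.0
    parent = node.parent_node
    if parent is rooted.seed_node and len(parent.child_nodes()) == 2:
        # already rooted on this pendant edge; just re-balance the halves
        sib = [c for c in parent.child_nodes() if c is not node][0]
        total = length + (sib.edge.length or 0.0)
        node.edge.length = total / 2.0
        sib.edge.length = total / 2.0
    else:
        rooted.reroot_at_edge(node.edge, length1=length / 2.0, length2=length / 2.0)
    rooted.is_rooted = True
    return rooted


def ingroup_tips(tree: dendropy.Tree, outgroup_id: str) -> list[str]:
    return [
        lf.taxon.label
        for lf in tree.leaf_node_iter()
        if lf.taxon is not None and lf.taxon.label != outgroup_id
    ]


# ---------------------------------------------------------------------------
# Bootstrap


def _nontrivial_bipartitions(tree: dendropy.Tree, positive_only: bool = False) -> dict:
    """Map internal node -> normalized bipartition (frozenset of tip labels).

    Bipartitions are normalized to the side *not* containing the
    alphabetically first taxon, making them comparable across trees over
    the same taxa regardless of rooting.  With ``positive_only`` edges of
    zero length are skipped (an NJ resolution of a tie carries no signal).
    """
    all_tips = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor = min(all_tips)
    out = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        if positive_only and (node.edge.length or 0.0) <= 0.0:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = all_tips - side
        if 2 <= len(side) <= len(all_tips) - 2:
            out[node] = side
    return out


def bootstrap_support(
    alignment: MarkerAlignment,
    tree_builder=None,
    B: int = 100,
    seed: int = 0,
    reference_tree: dendropy.Tree | None = None,
) -> dendropy.Tree:
    """Attach column-resampling bootstrap supports to the reference tree.

    ``tree_builder`` maps an alignment to an unrooted tree (default: NJ on
    TN93 distances).  Each of the B replicates resamples alignment columns
    with replacement (gap columns travel with their column); the support of
    an internal edge is the percentage of completed replicates containing
    its bipartition.  Replicates with a saturated pair are skipped and
    counted in the annotation ``n_skipped_replicates``.  With no
    informative bipartitions (e.g. identical sequences) supports are 0.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if tree_builder is None:
        tree_builder = lambda aln: nj_tree(distance_matrix(aln))
    ref = reference_tree if reference_tree is not None else tree_builder(alignment)
    ref = ref.clone(depth=1)
    bipartitions = _nontrivial_bipartitions(ref)
    counts = {node: 0 for node in bipartitions}
    rng = np.random.default_rng(seed)
    L = alignment.n_columns
    seqs = alignment.sequences()
    skipped = 0
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        resampled = ["".join(s[c] for c in cols) for s in seqs]
        pseudo = MarkerAlignment(
            alignment.segment,
            [
                type(r)(r.specimen_id, r.marker, rs)
                for r, rs in zip(alignment.records, resampled)
            ],
            [alignment.column_map[c] for c in cols],
            alignment.outgroup_id,
        )
        try:
            rep_tree = tree_builder(pseudo)
        except SaturationError:
            skipped += 1
            continue
        rep_bips = set(_nontrivial_bipartitions(rep_tree, positive_only=True).values())
        for node, bip in bipartitions.items():
            if bip in rep_bips:
                counts[node] += 1
    done = B - skipped
    for node, bip in bipartitions.items():
        support = 100.0 * counts[node] / done if done > 0 else 0.0
        node.label = f"{support:g}"
        node.annotations.add_new("support", support)
    ref.annotations.add_new("n_skipped_replicates", skipped)
    return ref


def node_supports(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Bipartition -> support mapping for a tree annotated by bootstrap."""
    out = {}
    for node, bip in _nontrivial_bipartitions(tree).items():
        for ann in node.annotations:
            if ann.name == "support":
                out[bip] = float(ann.value)
    return out


# ---------------------------------------------------------------------------
# TN93 likelihood


@dataclass(frozen=True)
class TN93Params:
    """TN93 substitution-model parameters.

    ``base_freqs`` = (piA, piC, piG, piT); ``alpha_R``/``alpha_Y`` scale the
    purine and pyrimidine transition rates relative to the transversion
    rate ``beta``.  The rate matrix is normalized to one expected
    substitution per site per unit branch length.
    """

    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    alpha_R: float = 2.0
    alpha_Y: float = 2.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if abs(sum(self.base_freqs) - 1.0) > 1e-8 or min(self.base_freqs) <= 0:
            raise ValueError("base_freqs must be positive and sum to 1")
        if min(self.alpha_R, self.alpha_Y, self.beta) <= 0:
            raise ValueError("rate factors must be > 0")

    def rate_matrix(self) -> np.ndarray:
        """Normalized instantaneous rate matrix Q (rows: from, cols: to)."""
        pi = np.asarray(self.base_freqs)
        Q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                if (i, j) in ((0, 2), (2, 0)):
                    rate = self.alpha_R
                elif (i, j) in ((1, 3), (3, 1)):
                    rate = self.alpha_Y
                else:
                    rate = self.beta
                Q[i, j] = rate * pi[j]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(Q)))
        return Q / mu

    @staticmethod
    def empirical(alignment: MarkerAlignment, alpha_R: float = 2.0, alpha_Y: float = 2.0) -> "TN93Params":
        enc = encode_sequences(alignment.sequences())
        counts = np.bincount(enc[enc < 4].ravel(), minlength=4).astype(float)
        counts = np.maximum(counts, 1.0)
        freqs = counts / counts.sum()
        return TN93Params(tuple(freqs), alpha_R, alpha_Y, 1.0)


def _transition_matrices(tree: dendropy.Tree, params: TN93Params) -> dict:
    Q = params.rate_matrix()
    cache: dict[float, np.ndarray] = {}
    mats = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = node.edge.length or 0.0
        if t not in cache:
            cache[t] = scipy.linalg.expm(Q * t)
        mats[node] = cache[t]
    return mats


def tn93_loglik(
    tree: dendropy.Tree, alignment: MarkerAlignment, params: TN93Params
) -> float:
    """Log-likelihood of an alignment on a tree under TN93.

    Felsenstein pruning, vectorized over sites.  Gaps and ambiguity codes
    are treated as missing data (marginalized).  The tree may be rooted or
    carry a basal multifurcation; under this reversible model the value is
    invariant to root placement.
    """
    seq_of = {r.specimen_id: r.residues for r in alignment.records}
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [t for t in tips if t not in seq_of]
    if missing:
        raise ValueError(f"tips absent from alignment: {missing}")
    L = alignment.n_columns
    enc = {label: encode_sequences([seq_of[label]])[0] for label in tips}
    mats = _transition_matrices(tree, params)

    partial: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            codes = enc[node.taxon.label]
            arr = np.ones((L, 4))
            known = codes < 4
            arr[known] = 0.0
            arr[known, codes[known]] = 1.0
            partial[node] = arr
        else:
            arr = np.ones((L, 4))
            for child in node.child_nodes():
                arr = arr * (partial.pop(child) @ mats[child].T)
            partial[node] = arr
    root_partial = partial[tree.seed_node]
    pi = np.asarray(params.base_freqs)
    site_lik = root_partial @ pi
    if np.any(site_lik <= 0):
        return -math.inf
    return float(np.log(site_lik).sum())


def _golden_section_max(f, lo: float, hi: float, tol: float = 1e-2, max_iter: int = 40) -> float:
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if b - a < tol:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def fit_tn93_params(
    tree: dendropy.Tree, alignment: MarkerAlignment, n_passes: int = 2
) -> TN93Params:
    """Fit TN93 rate factors on a fixed tree.

    Base frequencies are empirical; alpha_R and alpha_Y are optimized
    coordinate-wise by golden-section search (beta normalized to 1) to
    maximize the pruning likelihood on the given tree.
    """
    base = TN93Params.empirical(alignment)
    aR, aY = base.alpha_R, base.alpha_Y
    for _ in range(n_passes):
        aR = _golden_section_max(
            lambda x: tn93_loglik(tree, alignment, TN93Params(base.base_freqs, x, aY)),
            0.05,
            20.0,
        )
        aY = _golden_section_max(
            lambda x: tn93_loglik(tree, alignment, TN93Params(base.base_freqs, aR, x)),
            0.05,
            20.0,
        )
    return TN93Params(base.base_freqs, aR, aY, 1.0)


def nni_refine(
    start_tree: dendropy.Tree,
    alignment: MarkerAlignment,
    params: TN93Params,
    max_rounds: int = 10,
) -> tuple[dendropy.Tree, list[float]]:
    """Greedy nearest-neighbor-interchange hill climb under TN93.

    Starting from (a copy of) ``start_tree``, repeatedly applies the first
    NNI move that strictly increases the log-likelihood, passing over all
    internal edges each round, until a local optimum or ``max_rounds``.
    Branch lengths are kept fixed.  Returns the refined tree and the
    log-likelihood trace (non-decreasing by construction).
    """
    tree = start_tree.clone(depth=1)
    trace = [tn93_loglik(tree, alignment, params)]
    for _ in range(max_rounds):
        improved = False
        internal_edges = [
            node
            for node in tree.preorder_node_iter()
            if (
                not node.is_leaf()
                and node.parent_node is not None
                and not node.parent_node.is_leaf()
            )
        ]
        for c in internal_edges:
            p = c.parent_node
            siblings = [s for s in p.child_nodes() if s is not c]
            children = list(c.child_nodes())
            done_move = False
            for s in siblings:
                for a in children:
                    # swap subtree a (child of c) with subtree s (child of p)
                    c.remove_child(a)
                    p.remove_child(s)
                    c.add_child(s)
                    p.add_child(a)
                    ll = tn93_loglik(tree, alignment, params)
                    if ll > trace[-1] + 1e-9:
                        trace.append(ll)
                        improved = True
                        done_move = True
                        break
                    # revert
                    c.remove_child(s)
                    p.remove_child(a)
                    c.add_child(a)
                    p.add_child(s)
                if done_move:
                    break
            if done_move:
                break
        if not improved:
            break
    return tree, trace


# ---------------------------------------------------------------------------
# Strain clade extraction


@dataclass
class CladePartition:
    """Partition of ingroup tips into the C-strain clade and the rest."""

    c_clade_ids: frozenset
    r_rest_ids: frozenset
    purity: float  # fraction of the clade on C-strain hosts
    recall: float  # fraction of C-host specimens inside the clade
    f1: float = field(default=0.0)


def extract_strain_clade(
    rooted_tree: dendropy.Tree, host_labels: dict[str, HostClass]
) -> CladePartition:
    """Select the clade best matching the C-host labels (max F1).

    Scans every internal node's tip set (excluding the full ingroup set)
    and picks the one maximizing F1 between clade membership and C-host
    labels; ties prefer the larger clade, then the earlier node in
    preorder.  The selected clade is monophyletic by construction.
    """
    tips = [
        lf.taxon.label for lf in rooted_tree.leaf_node_iter() if lf.taxon.label in host_labels
    ]
    if not tips:
        raise ValueError("no labeled tips in tree")
    classes = {host_labels[t] for t in tips}
    if len(classes) < 2:
        raise ValueError("degenerate labeling: all tips share one host class")
    c_tips = {t for t in tips if host_labels[t] is HostClass.C_HOST}
    all_tips = set(tips)

    best = None  # (f1, size, -preorder_index, clade)
    for idx, node in enumerate(rooted_tree.preorder_node_iter()):
        if node.is_leaf():
            continue
        clade = {
            lf.taxon.label for lf in node.leaf_iter() if lf.taxon.label in host_labels
        }
        if not clade or clade == all_tips:
            continue
        inter = len(clade & c_tips)
        f1 = 2.0 * inter / (len(clade) + len(c_tips))
        key = (f1, len(clade), -idx)
        if best is None or key > best[0]:
            best = (key, clade)
    if best is None:
        raise ValueError("tree has no proper internal clade")
    clade = best[1]
    purity = len(clade & c_tips) / len(clade)
    recall = len(clade & c_tips) / len(c_tips) if c_tips else 0.0
    return CladePartition(
        frozenset(clade), frozenset(all_tips - clade), purity, recall, best[0][0]
    )
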