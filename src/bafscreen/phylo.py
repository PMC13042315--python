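"""Distance-based phylogenetics: TN93/F84 distances, exact 1-D k-means panel
selection, Saitou-Nei neighbor joining with bootstrap, and placement
diagnostics for a focal (possibly contaminated) genome.

All sequences are assumed to share reference coordinates (consensus sequences
produced by mapping to the same reference), so no alignment step is needed.
Heterozygous IUPAC codes and N are treated as missing data and removed
pairwise — exactly how most distance software handles ambiguity, and the
reason contamination (which converts lineage-diagnostic sites into
heterozygous calls) silently shrinks distances between a contaminated genome
and both of its source lineages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from ._seq import encode

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "PhyloResult",
    "tn93_distance",
    "f84_distance",
    "distance_matrix",
    "kmeans_1d",
    "select_panel",
    "nj_tree",
    "write_phylip_distances",
    "bootstrap_support",
    "robinson_foulds",
    "placement_report",
]

_PURINE = np.array([True, False, True, False, False])


@dataclass
class Alignment:
    """Equal-length sequences over shared coordinates."""

    taxa: list[str]
    matrix: np.ndarray  # (n_taxa, L) uint8 codes, 4 = missing

    @classmethod
    def from_dict(cls, seqs: dict[str, str]) -> "Alignment":
        taxa = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError("sequences differ in length")
        return cls(taxa, np.vstack([encode(seqs[t]) for t in taxa]))

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxa.index(taxon)]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray  # symmetric, nan = undefined (saturated)
    pair_sites: np.ndarray  # usable-site counts per pair

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.taxa)
        for i in range(n):
            for j in range(i + 1, n):
                if not np.isfinite(self.matrix[i, j]):
                    out.append((self.taxa[i], self.taxa[j]))
        return out


def write_phylip_distances(D: "DistanceMatrix", path) -> None:
    """Square PHYLIP distance matrix (dnadist-style, 10-character name field).

    Names longer than 10 characters are truncated; undefined distances are
    written as -1.0, the conventional sentinel.
    """
    with open(path, "w") as fh:
        fh.write(f"{len(D.taxa):5d}\n")
        for i, name in enumerate(D.taxa):
            row = " ".join(
                f"{(x if np.isfinite(x) else -1.0):.6f}" for x in D.matrix[i]
            )
            fh.write(f"{name[:10]:<10s}{row}\n")


@dataclass
class PhyloResult:
    tree: dendropy.Tree
    supports: dict[frozenset, float]  # leafset-bipartition -> percent support
    n_replicates: int
    n_dropped: int = 0
    distance: DistanceMatrix | None = None


# ---------------------------------------------------------------------------
# pairwise distances
# ---------------------------------------------------------------------------


def _pair_counts(a: np.ndarray, b: np.ndarray):
    """Usable-site, transition and transversion counts plus pooled base counts."""
    mask = (a < 4) & (b < 4)
    aa, bb = a[mask], b[mask]
    n = aa.size
    if n == 0:
        raise ValueError("zero usable sites between the pair")
    diff = aa != bb
    pa, pb = _PURINE[aa], _PURINE[bb]
    ts1 = int((diff & pa & pb).sum())  # A<->G
    ts2 = int((diff & ~pa & ~pb).sum())  # C<->T
    tv = int((diff & (pa ^ pb)).sum())
    base_counts = np.bincount(aa, minlength=4) + np.bincount(bb, minlength=4)
    freqs = base_counts / base_counts.sum()
    xtab = np.bincount(aa.astype(np.int64) * 4 + bb, minlength=16).reshape(4, 4)
    return n, ts1, ts2, tv, freqs, xtab


def tn93_distance(seq_a, seq_b) -> float:
    """Tamura-Nei (1993) distance; nan when a log argument is non-positive.

    Sites where either sequence is not an unambiguous A/C/G/T are excluded
    pairwise. Base frequencies are empirical from the pooled pair.
    """
    a = seq_a if isinstance(seq_a, np.ndarray) else encode(seq_a)
    b = seq_b if isinstance(seq_b, np.ndarray) else encode(seq_b)
    if a.size != b.size:
        raise ValueError("sequences differ in length")
    n, ts1, ts2, tv, f, _ = _pair_counts(a, b)
    P1, P2, Q = ts1 / n, ts2 / n, tv / n
    if P1 == P2 == Q == 0:
        return 0.0
    pA, pC, pG, pT = f
    pR, pY = pA + pG, pC + pT
    if min(pA * pG, pC * pT, pR * pY) <= 0:
        return math.nan
    k1 = 2.0 * pA * pG / pR
    k2 = 2.0 * pC * pT / pY
    k3 = 2.0 * (pR * pY - pA * pG * pY / pR - pC * pT * pR / pY)
    w1 = 1.0 - P1 / k1 - Q / (2.0 * pR)
    w2 = 1.0 - P2 / k2 - Q / (2.0 * pY)
    w3 = 1.0 - Q / (2.0 * pR * pY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return math.nan
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def _f84_rates(freqs: np.ndarray, tstv_ratio: float):
    """F84 rate parameters (alpha_R, alpha_Y, beta=1) from the ts/tv ratio."""
    pA, pC, pG, pT = freqs
    pR, pY = pA + pG, pC + pT
    denom = pA * pG / pR + pC * pT / pY
    if denom <= 0:
        raise ValueError("degenerate base frequencies for F84")
    K = (tstv_ratio * pR * pY - pA * pG - pC * pT) / denom
    K = max(K, 0.0)
    return 1.0 + K / pR, 1.0 + K / pY


def _tn93_transition_matrix(
    t: float, freqs: np.ndarray, alpha_R: float, alpha_Y: float
) -> np.ndarray:
    """TN93-family transition probabilities at time t (beta = 1)."""
    pA, pC, pG, pT = freqs
    pR, pY = pA + pG, pC + pT
    e2 = math.exp(-t)
    e3 = math.exp(-(pR * alpha_R + pY) * t)
    e4 = math.exp(-(pY * alpha_Y + pR) * t)
    P = np.empty((4, 4))
    # order A C G T
    P[0, 0] = pA + pA * pY / pR * e2 + pG / pR * e3
    P[0, 2] = pG + pG * pY / pR * e2 - pG / pR * e3
    P[2, 0] = pA + pA * pY / pR * e2 - pA / pR * e3
    P[2, 2] = pG + pG * pY / pR * e2 + pA / pR * e3
    P[1, 1] = pC + pC * pR / pY * e2 + pT / pY * e4
    P[1, 3] = pT + pT * pR / pY * e2 - pT / pY * e4
    P[3, 1] = pC + pC * pR / pY * e2 - pC / pY * e4
    P[3, 3] = pT + pT * pR / pY * e2 + pC / pY * e4
    for i in (0, 2):
        P[i, 1] = pC * (1 - e2)
        P[i, 3] = pT * (1 - e2)
    for i in (1, 3):
        P[i, 0] = pA * (1 - e2)
        P[i, 2] = pG * (1 - e2)
    return P


def f84_distance(seq_a, seq_b, tstv_ratio: float = 0.5) -> float:
    """F84 maximum-likelihood distance at a fixed transition:transversion ratio.

    The default ratio of 0.5 corresponds, at equal base frequencies, to no
    transition bias (two transversion classes per transition class), in which
    case the estimate reduces to the Jukes-Cantor distance. The likelihood of
    the pairwise substitution counts is maximized over branch length
    numerically (the optimum is unique); nan is returned on saturation.
    """
    if tstv_ratio <= 0:
        raise ValueError("tstv_ratio must be positive")
    a = seq_a if isinstance(seq_a, np.ndarray) else encode(seq_a)
    b = seq_b if isinstance(seq_b, np.ndarray) else encode(seq_b)
    if a.size != b.size:
        raise ValueError("sequences differ in length")
    n, ts1, ts2, tv, freqs, xtab = _pair_counts(a, b)
    if ts1 + ts2 + tv == 0:
        return 0.0
    freqs = np.clip(freqs, 1e-9, None)
    freqs = freqs / freqs.sum()
    alpha_R, alpha_Y = _f84_rates(freqs, tstv_ratio)
    pA, pC, pG, pT = freqs
    pR, pY = pA + pG, pC + pT
    # expected substitutions per site per unit t, for rescaling t -> distance
    mu = 2 * pA * pG * alpha_R + 2 * pC * pT * alpha_Y + 2 * pR * pY

    def neg_ll(d: float) -> float:
        P = _tn93_transition_matrix(d / mu, freqs, alpha_R, alpha_Y)
        with np.errstate(divide="ignore"):
            logP = np.log(np.maximum(P, 1e-300))
        return -float((xtab * logP).sum())

    res = minimize_scalar(neg_ll, bounds=(1e-9, 5.0), method="bounded", options={"xatol": 1e-10})
    d = float(res.x)
    if d >= 4.99:  # pinned at the bound: saturated
        return math.nan
    return d


def distance_matrix(
    alignment: Alignment, model: str = "tn93", tstv_ratio: float = 0.5
) -> DistanceMatrix:
    """All pairwise distances under the chosen model (pairwise deletion)."""
    n = alignment.n_taxa
    D = np.zeros((n, n))
    S = np.zeros((n, n), dtype=int)
    for i in range(n):
        S[i, i] = alignment.matrix.shape[1]
        for j in range(i + 1, n):
            a, b = alignment.matrix[i], alignment.matrix[j]
            usable = int(((a < 4) & (b < 4)).sum())
            if model == "tn93":
                d = tn93_distance(a, b)
            elif model == "f84":
                d = f84_distance(a, b, tstv_ratio)
            else:
                raise ValueError(f"unknown model {model!r}")
            D[i, j] = D[j, i] = d
            S[i, j] = S[j, i] = usable
    return DistanceMatrix(list(alignment.taxa), D, S)


# ---------------------------------------------------------------------------
# 1-D k-means and panel selection
# ---------------------------------------------------------------------------


def kmeans_1d(values, K: int, seed: int | None = None) -> np.ndarray:
    """Globally optimal 1-D k-means by dynamic programming over sorted values.

    Returns a cluster label (0..K-1, ordered by cluster mean) per input value.
    Deterministic; `seed` is accepted for interface uniformity but unused.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if K > np.unique(x).size:
        raise ValueError(
            f"K={K} exceeds the number of distinct values ({np.unique(x).size})"
        )
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ps = np.concatenate([[0.0], np.cumsum(xs)])
    ps2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    def cost(j: int, i: int) -> float:
        # within-cluster SS of xs[j..i] inclusive
        m = i - j + 1
        s = ps[i + 1] - ps[j]
        return (ps2[i + 1] - ps2[j]) - s * s / m

    INF = float("inf")
    D = np.full((K + 1, n + 1), INF)
    back = np.zeros((K + 1, n + 1), dtype=int)
    D[0, 0] = 0.0
    for k in range(1, K + 1):
        for i in range(k, n + 1):
            best, bj = INF, k - 1
            for j in range(k - 1, i):
                v = D[k - 1, j] + cost(j, i - 1)
                if v < best - 1e-15:
                    best, bj = v, j
            D[k, i] = best
            back[k, i] = bj
    labels_sorted = np.empty(n, dtype=int)
    i = n
    for k in range(K, 0, -1):
        j = back[k, i]
        labels_sorted[j:i] = k - 1
        i = j
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def select_panel(
    distance_to_anchor: dict[str, float], K: int, seed: int = 0
) -> list[str]:
    """Cluster strains by their distance from an anchor strain into K groups
    and pick one strain uniformly at random per group."""
    ids = list(distance_to_anchor)
    labels = kmeans_1d([distance_to_anchor[i] for i in ids], K)
    rng = np.random.default_rng(seed)
    chosen = []
    for k in range(K):
        members = [i for i, lab in zip(ids, labels) if lab == k]
        chosen.append(members[int(rng.integers(len(members)))])
    return chosen


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Deterministic: among tied minimal Q entries the lowest (i, j) index pair
    wins. Negative branch lengths are clamped to zero with the deficit moved
    to the sister branch of the same join, preserving their sum.
    """
    bad = D.undefined_pairs()
    if bad:
        raise ValueError(f"undefined distances for pairs: {bad}")
    n = len(D.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")

    tns = dendropy.TaxonNamespace(D.taxa)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = []
    for label in D.taxa:
        nd = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(nd)
    dist = D.matrix.astype(float).copy()
    active = list(range(n))  # indices into `nodes`/rows of dist

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        k = int(np.argmin(q[iu]))  # row-major: lowest (i, j) on ties
        i, j = iu[0][k], iu[1][k]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[active[i]])
        nodes[active[i]].edge.length = li
        parent.add_child(nodes[active[j]])
        nodes[active[j]].edge.length = lj
        # distances from the new node to the remaining ones
        new_row = np.zeros(dist.shape[0] + 1)
        for t_idx, a in enumerate(active):
            if t_idx in (i, j):
                continue
            new_row[a] = 0.5 * (sub[i, t_idx] + sub[j, t_idx] - dij)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, : new_row.size - 1] = new_row[:-1]
        dist[: new_row.size - 1, -1] = new_row[:-1]
        nodes.append(parent)
        hi, lo = max(i, j), min(i, j)
        del active[hi], active[lo]
        active.append(len(nodes) - 1)

    center = dendropy.Node()
    if len(active) == 3:
        sub = dist[np.ix_(active, active)]
        ls = [
            0.5 * (sub[0, 1] + sub[0, 2] - sub[1, 2]),
            0.5 * (sub[0, 1] + sub[1, 2] - sub[0, 2]),
            0.5 * (sub[0, 2] + sub[1, 2] - sub[0, 1]),
        ]
        for a, l in zip(active, ls):
            center.add_child(nodes[a])
            nodes[a].edge.length = max(l, 0.0)
    else:  # exactly 2 left (possible only for 3-taxon input after 0 joins? guard)
        a, b = active
        center.add_child(nodes[a])
        nodes[a].edge.length = dist[a, b] / 2.0
        center.add_child(nodes[b])
        nodes[b].edge.length = dist[a, b] / 2.0
    tree.seed_node = center
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bootstrap and tree comparison
# ---------------------------------------------------------------------------


def _bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Nontrivial bipartitions as frozensets of the smaller leaf-label side."""
    all_taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_taxa - side
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def robinson_foulds(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds distance (symmetric bipartition difference)."""
    ba, bb = _bipartitions(tree_a), _bipartitions(tree_b)
    return len(ba ^ bb)


def bootstrap_support(
    alignment: Alignment,
    model: str = "tn93",
    n_reps: int = 100,
    seed: int = 0,
    tstv_ratio: float = 0.5,
) -> PhyloResult:
    """NJ tree with column-resampling bootstrap supports.

    Support for each internal bipartition of the full-data tree is the
    percentage of replicate trees containing it. Replicates in which some
    pairwise distance is undefined are dropped and counted; more than 20%
    drops is an error.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    full_D = distance_matrix(alignment, model, tstv_ratio)
    full_tree = nj_tree(full_D)
    target = _bipartitions(full_tree)
    counts = {bp: 0 for bp in target}

    rng = np.random.default_rng(seed)
    L = alignment.matrix.shape[1]
    dropped = 0
    used = 0
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        rep_aln = Alignment(alignment.taxa, alignment.matrix[:, idx])
        rep_D = distance_matrix(rep_aln, model, tstv_ratio)
        if rep_D.undefined_pairs():
            dropped += 1
            continue
        rep_bps = _bipartitions(nj_tree(rep_D))
        used += 1
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    if dropped > 0.2 * n_reps:
        raise RuntimeError(
            f"{dropped}/{n_reps} bootstrap replicates had undefined distances"
        )
    supports = {
        bp: (100.0 * c / used if used else 0.0) for bp, c in counts.items()
    }
    _attach_supports(full_tree, supports)
    return PhyloResult(
        tree=full_tree,
        supports=supports,
        n_replicates=used,
        n_dropped=dropped,
        distance=full_D,
    )


def _attach_supports(tree: dendropy.Tree, supports: dict[frozenset, float]) -> None:
    all_taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = min(side, all_taxa - side, key=lambda s: (len(s), sorted(s)))
        if key in supports:
            node.label = str(int(round(supports[key])))


def placement_report(
    tree: dendropy.Tree,
    focal: str,
    contaminant_lineage: set[str],
    recipient_lineage: set[str],
    baseline_tree: dendropy.Tree | None = None,
    outgroup: str | None = None,
) -> dict:
    """Diagnostics for where a focal taxon landed in the tree.

    ``sister_to_contaminant`` is true when, after rooting away from both
    lineages, the focal taxon's sibling subtree contains only contaminant-
    lineage taxa (the focal is nested within the smallest clade holding that
    lineage); ``within_recipient`` is the same test against the recipient
    lineage. ``rf`` is the unrooted Robinson-Foulds distance to the baseline
    tree when one is given.
    """
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if focal not in labels:
        raise ValueError(f"focal taxon {focal!r} not in tree")
    work = dendropy.Tree(tree)  # deep clone; original left untouched
    if outgroup is None:
        excluded = contaminant_lineage | recipient_lineage | {focal}
        candidates = sorted(labels - excluded)
        outgroup = candidates[0] if candidates else sorted(labels - {focal})[0]
    og_node = None
    for lf in work.leaf_node_iter():
        if lf.taxon.label == outgroup:
            og_node = lf
            break
    work.to_outgroup_position(og_node, update_bipartitions=False)

    focal_leaf = next(
        lf for lf in work.leaf_node_iter() if lf.taxon.label == focal
    )
    parent = focal_leaf.parent_node
    sibling_leaves = {
        lf.taxon.label
        for child in parent.child_nodes()
        if child is not focal_leaf
        for lf in child.leaf_iter()
    }
    report = {
        "focal": focal,
        "sibling_leaves": sorted(sibling_leaves),
        "sister_to_contaminant": bool(
            sibling_leaves and sibling_leaves <= set(contaminant_lineage)
        ),
        "within_recipient": bool(
            sibling_leaves and sibling_leaves <= set(recipient_lineage)
        ),
    }
    if baseline_tree is not None:
        report["rf"] = robinson_foulds(tree, baseline_tree)
    return report
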