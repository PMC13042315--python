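"""Simulation of within-species contaminated resequencing data.

This module is the stand-in for real short-read experiments: it builds a
reference genome, evolves a panel of lineages along a random tree, derives
recipient/contaminant strains of chosen ploidy and heterozygosity, and then
emulates sequencing a contaminated DNA mixture by drawing per-site read
allele counts. Mixing is modelled at the allele-count level: at a site
covered by ``d`` reads, ``m ~ Binomial(d, c)`` reads originate from the
contaminant, each read samples one haplotype of its strain of origin
uniformly, and is mis-read with probability ``error_rate`` (symmetric
ref <-> alt). B-allele-frequency statistics depend only on these per-site
origin proportions, so the count-level model reproduces what read-level
mixing followed by mapping would give, without the aligner. ``mix_fastq``
is provided for users who do have real reads.

Coordinates are 1-based throughout, matching VCF convention.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field

import dendropy
import numpy as np

from ._seq import decode, encode, mutate_sites, random_sequence

__all__ = [
    "ReferenceGenome",
    "LineagePanel",
    "StrainGenome",
    "MixtureSpec",
    "SiteRecord",
    "simulate_reference",
    "simulate_panel",
    "simulate_lineage_panel",
    "simulate_strain",
    "simulate_read_counts",
    "mix_fastq",
    "DEFAULT_CONTAMINATION_LEVELS",
]

#: contamination fractions used throughout the package's experiments
DEFAULT_CONTAMINATION_LEVELS = (0.0, 0.01, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50)

DEFAULT_DEPTH = 80.0
DEFAULT_ERROR_RATE = 0.002

# Minimum branch length, as a fraction of tree height, enforced on simulated
# panel trees so that lineages are resolvable (like named population lineages);
# a pure-birth draw can otherwise produce arbitrarily short internal edges that
# no finite alignment could recover.
MIN_BRANCH_FRACTION = 0.1


@dataclass
class SiteRecord:
    """One biallelic site: read depth and alternate-allele depth."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int
    alt_depth: int

    def __post_init__(self) -> None:
        if not 0 <= self.alt_depth <= self.depth:
            raise ValueError(
                f"alt_depth must satisfy 0 <= alt_depth <= depth, got "
                f"{self.alt_depth}/{self.depth} at {self.chrom}:{self.pos}"
            )

    @property
    def baf(self) -> float:
        return self.alt_depth / self.depth


@dataclass
class ReferenceGenome:
    """Ordered chromosomes of a haploid reference, held as coded arrays."""

    names: list[str]
    _seqs: dict[str, np.ndarray]

    @classmethod
    def from_strings(cls, chromosomes: list[tuple[str, str]]) -> "ReferenceGenome":
        names = [n for n, _ in chromosomes]
        seqs = {n: encode(s) for n, s in chromosomes}
        for n, a in seqs.items():
            if (a > 3).any():
                raise ValueError(f"chromosome {n} contains non-ACGT characters")
        return cls(names, seqs)

    def chrom_array(self, name: str) -> np.ndarray:
        return self._seqs[name]

    def chrom_str(self, name: str) -> str:
        return decode(self._seqs[name])

    def chrom_length(self, name: str) -> int:
        return int(self._seqs[name].size)

    @property
    def total_length(self) -> int:
        return int(sum(a.size for a in self._seqs.values()))

    def items(self):
        return [(n, self._seqs[n]) for n in self.names]


@dataclass
class StrainGenome:
    """Haplotype set of one strain, aligned to reference coordinates."""

    strain_id: str
    ploidy: int
    haplotypes: dict[str, np.ndarray]  # chrom -> (ploidy, L) uint8 codes
    lineage_id: str
    role: str  # recipient | contaminant | panel
    reference: ReferenceGenome

    def __post_init__(self) -> None:
        if self.ploidy not in (1, 2, 3, 4):
            raise ValueError(f"ploidy must be in 1..4, got {self.ploidy}")
        for name in self.reference.names:
            h = self.haplotypes[name]
            if h.shape != (self.ploidy, self.reference.chrom_length(name)):
                raise ValueError(
                    f"haplotype array for {name} has shape {h.shape}, expected "
                    f"({self.ploidy}, {self.reference.chrom_length(name)})"
                )

    def haplotype_strings(self, chrom: str) -> list[str]:
        return [decode(row) for row in self.haplotypes[chrom]]

    def heterozygous_site_count(self) -> int:
        """Sites at which not all haplotypes agree."""
        n = 0
        for a in self.haplotypes.values():
            if a.shape[0] > 1:
                n += int((a != a[0]).any(axis=0).sum())
        return n


@dataclass
class LineagePanel:
    """A lineage tree plus one haploid genome per tip."""

    tree: dendropy.Tree
    strains: dict[str, StrainGenome]
    divergence_target: float
    reference: ReferenceGenome

    @property
    def strain_ids(self) -> list[str]:
        return list(self.strains)

    def lineage_members(self, strain_id: str) -> set[str]:
        """All strains of the given strain's lineage, itself included.

        For a panel whose lineage ids are unique per tip this falls back to
        the tip plus its sister tips in the tree.
        """
        lin = self.strains[strain_id].lineage_id
        members = {s for s, g in self.strains.items() if g.lineage_id == lin}
        if members != {strain_id}:
            return members
        leaf = next(
            l for l in self.tree.leaf_node_iter() if l.taxon.label == strain_id
        )
        sibs = {
            l.taxon.label
            for ch in leaf.parent_node.child_nodes()
            if ch is not leaf
            for l in ch.leaf_iter()
        }
        return {strain_id} | sibs


@dataclass
class MixtureSpec:
    """Parameters of one contaminated sequencing experiment."""

    recipient_id: str
    contaminant_id: str | None
    c: float  # contaminant fraction of reads
    depth: float = DEFAULT_DEPTH  # mean reads per site (Poisson)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.c <= 1.0:
            raise ValueError(f"contamination fraction must be in [0, 1], got {self.c}")
        if self.depth <= 0:
            raise ValueError("mean depth must be positive")


def simulate_reference(
    n_chromosomes: int = 2,
    chrom_length: int = 50_000,
    seed: int = 0,
) -> ReferenceGenome:
    """Random reference genome of `n_chromosomes` equal-length chromosomes."""
    if n_chromosomes < 2:
        raise ValueError("need at least 2 chromosomes")
    if n_chromosomes * chrom_length < 10_000:
        raise ValueError("total genome length must be at least 10 kb")
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1:02d}" for i in range(n_chromosomes)]
    seqs = {n: random_sequence(chrom_length, rng) for n in names}
    return ReferenceGenome(names, seqs)


def _mean_pairwise_distance(tree: dendropy.Tree) -> float:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    total, npairs = 0.0, 0
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            total += pdm.patristic_distance(taxa[i], taxa[j])
            npairs += 1
    return total / npairs


def simulate_panel(
    reference: ReferenceGenome,
    n_strains: int,
    divergence_target: float,
    seed: int = 0,
) -> LineagePanel:
    """Evolve `n_strains` haploid lineages from the reference along a random tree.

    The topology is pure-birth; branch lengths are scaled so the mean pairwise
    patristic distance equals `divergence_target` (expected substitutions per
    site), with a floor of ``MIN_BRANCH_FRACTION`` of tree height per branch so
    every split is resolvable. Substitutions are single-rate (Jukes-Cantor
    style): along a branch of length b a fraction 3/4*(1-exp(-4b/3)) of sites
    is changed to a uniformly chosen different base.
    """
    if n_strains < 4:
        raise ValueError("need at least 4 strains (neighbor joining needs >= 4 taxa)")
    if not 0.0 <= divergence_target <= 0.05:
        raise ValueError("divergence_target must be in [0, 0.05]")

    rng = np.random.default_rng(seed)
    tree_rng = _pyrandom.Random(int(rng.integers(0, 2**31)))
    from dendropy.model import birthdeath

    tree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_strains,
        rng=tree_rng,
    )
    ids = [f"strain_{i + 1:02d}" for i in range(n_strains)]
    for taxon, sid in zip(tree.taxon_namespace, ids):
        taxon.label = sid

    if divergence_target > 0:
        scale = divergence_target / _mean_pairwise_distance(tree)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
        height = max(tree.calc_node_root_distances(return_leaf_distances_only=True))
        floor = MIN_BRANCH_FRACTION * height
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < floor:
                edge.length = floor
        # re-center on the divergence target after flooring
        scale = divergence_target / _mean_pairwise_distance(tree)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
    else:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = 0.0

    strains: dict[str, StrainGenome] = {}
    for sid, seqs in _evolve_on_tree(tree, reference, rng).items():
        strains[sid] = StrainGenome(
            strain_id=sid,
            ploidy=1,
            haplotypes={n: s[None, :].copy() for n, s in seqs.items()},
            lineage_id=sid,
            role="panel",
            reference=reference,
        )
    return LineagePanel(tree=tree, strains=strains, divergence_target=divergence_target, reference=reference)


def _evolve_on_tree(
    tree: dendropy.Tree, reference: ReferenceGenome, rng: np.random.Generator
) -> dict[str, dict[str, np.ndarray]]:
    """Evolve the reference along a tree under a single-rate process.

    Returns per-tip chromosome arrays. Along a branch of length b a fraction
    3/4*(1-exp(-4b/3)) of sites changes to a uniformly chosen different base.
    """
    node_seqs: dict[int, dict[str, np.ndarray]] = {}
    root = tree.seed_node
    node_seqs[id(root)] = {n: a.copy() for n, a in reference.items()}
    tips: dict[str, dict[str, np.ndarray]] = {}
    for node in tree.preorder_node_iter():
        if node is not root:
            parent = node_seqs[id(node.parent_node)]
            b = node.edge.length or 0.0
            p_sub = 0.75 * (1.0 - np.exp(-4.0 * b / 3.0))
            seqs = {}
            for name, parr in parent.items():
                child = parr.copy()
                if p_sub > 0:
                    hits = np.flatnonzero(rng.random(child.size) < p_sub)
                    mutate_sites(child, hits, rng)
                seqs[name] = child
            node_seqs[id(node)] = seqs
        if node.is_leaf():
            tips[node.taxon.label] = node_seqs[id(node)]
    return tips


def simulate_lineage_panel(
    reference: ReferenceGenome,
    n_lineages: int = 26,
    strains_per_lineage: int = 2,
    divergence_target: float = 0.005,
    seed: int = 0,
) -> LineagePanel:
    """Panel of distinct lineages radiating near the root, like a structured
    population (e.g. 26 named lineages with two strains each).

    Each lineage has its own stem branch from the root (length uniform on
    0.5-1.5 of the lineage scale) and short terminal branches per strain
    (uniform on 0.1-0.3 of it), so diagnostic variation is lineage-specific
    rather than shared tree-wide — the shape under which contamination between
    lineages is recognizable. Branch lengths are rescaled so the mean pairwise
    distance equals `divergence_target`. Tip labels are ``L<i>_s<j>``;
    ``lineage_id`` is ``L<i>``.
    """
    if n_lineages < 2 or strains_per_lineage < 1:
        raise ValueError("need >= 2 lineages with >= 1 strain each")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    stems = rng.uniform(0.5, 1.5, size=n_lineages)
    tips_len = rng.uniform(0.1, 0.3, size=(n_lineages, strains_per_lineage))
    for i in range(n_lineages):
        stem = dendropy.Node()
        stem.edge.length = float(stems[i])
        tree.seed_node.add_child(stem)
        for j in range(strains_per_lineage):
            label = f"L{i + 1:02d}_s{j + 1}"
            leaf = dendropy.Node(taxon=dendropy.Taxon(label=label))
            leaf.edge.length = float(tips_len[i, j])
            stem.add_child(leaf)
    tns.add_taxa([lf.taxon for lf in tree.leaf_node_iter()])
    if divergence_target > 0:
        scale = divergence_target / _mean_pairwise_distance(tree)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
    strains: dict[str, StrainGenome] = {}
    tip_seqs = _evolve_on_tree(tree, reference, rng)
    for label, seqs in tip_seqs.items():
        strains[label] = StrainGenome(
            strain_id=label,
            ploidy=1,
            haplotypes={n: s[None, :].copy() for n, s in seqs.items()},
            lineage_id=label.split("_")[0],
            role="panel",
            reference=reference,
        )
    return LineagePanel(
        tree=tree, strains=strains, divergence_target=divergence_target, reference=reference
    )


def most_divergent_pair(panel: LineagePanel) -> tuple[str, str]:
    """The pair of panel strains with the largest patristic distance.

    Mirrors how a contamination experiment picks its strains: a contaminant
    genetically distinct from the recipient, so cross-contamination is
    recognizable. Ties resolve to the lexicographically first pair.
    """
    pdm = panel.tree.phylogenetic_distance_matrix()
    taxa = sorted(panel.tree.taxon_namespace, key=lambda t: t.label)
    best, pair = -1.0, None
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            if d > best:
                best, pair = d, (taxa[i].label, taxa[j].label)
    return pair


def simulate_strain(
    panel: LineagePanel,
    lineage_id: str,
    ploidy: int,
    heterozygosity: float = 0.0,
    seed: int = 0,
    strain_id: str | None = None,
    role: str = "recipient",
) -> StrainGenome:
    """Derive a strain of given ploidy from one panel lineage.

    All haplotypes start as copies of the lineage sequence; for ploidy >= 2 a
    fraction ``heterozygosity`` of sites receives a private mutation carried by
    a uniformly chosen 1..ploidy-1 of the haplotypes, so approximately that
    fraction of sites differs between haplotypes. Haploids ignore
    heterozygosity.
    """
    if lineage_id not in panel.strains:
        raise KeyError(f"lineage {lineage_id!r} not in panel")
    if ploidy not in (1, 2, 3, 4):
        raise ValueError("ploidy must be in {1,2,3,4}")
    if not 0.0 <= heterozygosity <= 0.02:
        raise ValueError("heterozygosity must be in [0, 0.02]")

    rng = np.random.default_rng(seed)
    source = panel.strains[lineage_id]
    haplotypes: dict[str, np.ndarray] = {}
    for name, arr in source.haplotypes.items():
        base = arr[0]
        h = np.tile(base, (ploidy, 1))
        if ploidy >= 2 and heterozygosity > 0:
            pos = np.flatnonzero(rng.random(base.size) < heterozygosity)
            if pos.size:
                shift = rng.integers(1, 4, size=pos.size).astype(np.uint8)
                newbase = (base[pos] + shift) % 4
                ncopies = rng.integers(1, ploidy, size=pos.size)
                ranks = rng.random((pos.size, ploidy)).argsort(axis=1)
                carrier = ranks < ncopies[:, None]  # (n_sites, ploidy)
                for k in range(ploidy):
                    sel = pos[carrier[:, k]]
                    h[k, sel] = newbase[carrier[:, k]]
        haplotypes[name] = h
    return StrainGenome(
        strain_id=strain_id or f"{lineage_id}.{role}",
        ploidy=ploidy,
        haplotypes=haplotypes,
        lineage_id=lineage_id,
        role=role,
        reference=panel.reference,
    )


def _alt_fraction_arrays(
    ref: np.ndarray, haps: np.ndarray, alt: np.ndarray
) -> np.ndarray:
    """Per-site fraction of a strain's haplotypes carrying the chosen alt base."""
    return (haps == alt).mean(axis=0)


def simulate_read_counts(
    strain: StrainGenome,
    contaminant: StrainGenome | None,
    spec: MixtureSpec,
    *,
    error_rate: float = DEFAULT_ERROR_RATE,
    repeat_fraction: float = 0.01,
    invariant_fraction: float = 0.0,
    all_sites: bool = False,
    min_depth: int = 1,
) -> list[SiteRecord]:
    """Draw per-site read allele counts for a contaminated mixture.

    At every site where any haplotype (recipient or contaminant) differs from
    the reference, a record is emitted with total depth ``d ~ Poisson(depth)``
    (floored at `min_depth`), of which ``m ~ Binomial(d, c)`` reads come from
    the contaminant. Each read samples one haplotype of its strain uniformly
    and is flipped ref<->alt with probability `error_rate`. Invariant sites
    are omitted unless `all_sites` is set or a background `invariant_fraction`
    is requested (for consensus-caller experiments). A `repeat_fraction` of
    extra sites with uniform(0,1) allele fractions mimics repetitive regions,
    where mapped variants appear at arbitrary frequencies.
    """
    if spec.c > 0 and contaminant is None:
        raise ValueError("contamination fraction > 0 requires a contaminant strain")
    rng = np.random.default_rng(spec.seed)
    base_chars = "ACGT"
    records: list[SiteRecord] = []

    for name in strain.reference.names:
        ref = strain.reference.chrom_array(name)
        rh = strain.haplotypes[name]
        ch = contaminant.haplotypes[name] if contaminant is not None else None

        # choose the alt base per site: recipient's non-ref base takes priority
        alt = ref.copy()
        for row in rh[::-1]:
            diff = row != ref
            alt[diff] = row[diff]
        if ch is not None:
            for row in ch[::-1]:
                diff = (row != ref) & (alt == ref)
                alt[diff] = row[diff]

        variant = alt != ref
        if all_sites:
            pos = np.arange(ref.size)
        else:
            pos = np.flatnonzero(variant)
            if invariant_fraction > 0:
                inv = np.flatnonzero(~variant)
                k = int(round(invariant_fraction * inv.size))
                if k:
                    pos = np.sort(np.concatenate([pos, rng.choice(inv, size=k, replace=False)]))
        # invariant sites get an arbitrary distinct alt so errors can register
        novar = alt[pos] == ref[pos]
        alt_at = alt[pos].copy()
        alt_at[novar] = (ref[pos][novar] + 1) % 4

        f_r = _alt_fraction_arrays(ref[pos], rh[:, pos], alt_at)
        f_c = (
            _alt_fraction_arrays(ref[pos], ch[:, pos], alt_at)
            if ch is not None
            else np.zeros(pos.size)
        )

        d = rng.poisson(spec.depth, size=pos.size)
        d = np.maximum(d, min_depth)
        m = rng.binomial(d, spec.c)
        true_alt = rng.binomial(d - m, f_r) + rng.binomial(m, f_c)
        obs_alt = rng.binomial(true_alt, 1.0 - error_rate) + rng.binomial(
            d - true_alt, error_rate
        )

        chrom_records = [
            SiteRecord(
                chrom=name,
                pos=int(p) + 1,
                ref=base_chars[ref[p]],
                alt=base_chars[a],
                depth=int(dd),
                alt_depth=int(aa),
            )
            for p, a, dd, aa in zip(pos, alt_at, d, obs_alt)
        ]

        if repeat_fraction > 0 and not all_sites:
            n_rep = int(round(repeat_fraction * max(variant.sum(), 1)))
            if n_rep:
                inv = np.flatnonzero(~variant)
                rpos = rng.choice(inv, size=min(n_rep, inv.size), replace=False)
                u = rng.uniform(0.0, 1.0, size=rpos.size)
                rd = np.maximum(rng.poisson(spec.depth, size=rpos.size), min_depth)
                ra = rng.binomial(rd, u)
                for p, dd, aa in zip(rpos, rd, ra):
                    chrom_records.append(
                        SiteRecord(
                            chrom=name,
                            pos=int(p) + 1,
                            ref=base_chars[ref[p]],
                            alt=base_chars[(ref[p] + 1) % 4],
                            depth=int(dd),
                            alt_depth=int(aa),
                        )
                    )
                chrom_records.sort(key=lambda r: r.pos)
        records.extend(chrom_records)
    return records


# ---------------------------------------------------------------------------
# FASTQ-level mixing (for users with real reads)
# ---------------------------------------------------------------------------


def _open_maybe_gz(path, mode="rt"):
    import gzip

    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _read_fastq(path) -> list[tuple[str, str, str, str]]:
    recs = []
    with _open_maybe_gz(path) as fh:
        while True:
            lines = [fh.readline() for _ in range(4)]
            if not lines[0]:
                break
            if not lines[0].startswith("@") or not lines[2].startswith("+"):
                raise ValueError(f"malformed FASTQ record in {path}")
            recs.append(tuple(line.rstrip("\n") for line in lines))
    return recs


def mix_fastq(
    fastq_pair_a: tuple[str, str],
    fastq_pair_b: tuple[str, str],
    n_total_reads: int,
    c: float,
    seed: int,
    out_pair: tuple[str, str],
) -> tuple[int, int]:
    """Sample read pairs without replacement from two libraries and mix them.

    ``round(n_total*(1-c))`` pairs come from library a and ``round(n_total*c)``
    from b; the output order is shuffled but mate pairing (R1 with its R2) is
    preserved. Returns the (n_from_a, n_from_b) counts.
    """
    n_b = int(round(n_total_reads * c))
    n_a = n_total_reads - n_b
    rng = np.random.default_rng(seed)

    pairs = []
    for (r1, r2), need, label in (
        (fastq_pair_a, n_a, "a"),
        (fastq_pair_b, n_b, "b"),
    ):
        recs1, recs2 = _read_fastq(r1), _read_fastq(r2)
        if len(recs1) != len(recs2):
            raise ValueError(f"mate files of library {label} differ in read count")
        if len(recs1) < need:
            raise ValueError(
                f"library {label} file {r1} has only {len(recs1)} read pairs, "
                f"{need} requested"
            )
        idx = rng.choice(len(recs1), size=need, replace=False)
        pairs.extend((recs1[i], recs2[i]) for i in idx)

    order = rng.permutation(len(pairs))
    with _open_maybe_gz(out_pair[0], "wt") as f1, _open_maybe_gz(out_pair[1], "wt") as f2:
        for i in order:
            f1.write("\n".join(pairs[i][0]) + "\n")
            f2.write("\n".join(pairs[i][1]) + "\n")
    return n_a, n_b
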