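"""Distance trees and the identity-by-descent vs recurrence test.

If the deletions observed in two species are identical by descent, the
fused SD haplotypes of both species descend from a single ancestral fusion
and must form one clade exclusive of the reference paralogs. If the
deletions arose independently (recurrently), each species' fused haplotypes
instead cluster with that species' own reference SDs. The test builds
neighbor-joining trees from p-distances in regions chosen to avoid
gene-conversion tracts, attaches bootstrap support to every internal edge,
and votes per region.

Distances are uncorrected p-distances by default (divergences here are far
from saturation); a Jukes-Cantor correction is available as an option.
Neighbor joining is deterministic: ties in the Q criterion are broken
lexicographically on the pair of representative leaf labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from sdfusion.alignment import SDAlignment

__all__ = [
    "RegionPartition",
    "DistanceMatrix",
    "TreeResult",
    "pairwise_distances",
    "neighbor_joining",
    "bootstrap_support",
    "classify_fusion_origin",
    "nearest_reference_profile",
    "newick_of",
    "tree_bipartitions",
]

DEFAULT_REGIONS = (("region1", 0, 1000), ("region2", 4001, 7500), ("region3", 12000, None))


@dataclass
class RegionPartition:
    """Named, non-overlapping alignment regions used for per-region trees.

    An ``end`` of None means "to the end of the alignment".
    """

    regions: Sequence[tuple[str, int, int | None]] = DEFAULT_REGIONS

    def resolve(self, length: int) -> list[tuple[str, int, int]]:
        out = []
        for name, start, end in self.regions:
            e = length if end is None else int(end)
            if not (0 <= start < e <= length):
                raise ValueError(f"region {name} [{start}, {e}) outside alignment of length {length}")
            out.append((name, int(start), e))
        out_sorted = sorted(out, key=lambda r: r[1])
        for (_, _, e0), (_, s1, _) in zip(out_sorted, out_sorted[1:]):
            if s1 < e0:
                raise ValueError("regions overlap")
        return out


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("negative distances")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


@dataclass
class TreeResult:
    """An unrooted tree plus (optionally) bootstrap support per internal edge.

    ``support`` maps each internal bipartition of the topology — canonically
    the side *not* containing the lexicographically smallest leaf — to a
    bootstrap percentage in [0, 100]. Trees built without bootstrapping
    carry an empty mapping.
    """

    topology: str
    support: dict[frozenset, float] = field(default_factory=dict)
    _root: "object | None" = None

    def bipartitions(self) -> set[frozenset]:
        if self._root is not None:
            return set(tree_bipartitions(self._root))
        raise ValueError("tree was not built by this package; bipartitions unavailable")


# ---- distances ------------------------------------------------------------


def pairwise_distances(
    aln: SDAlignment,
    region: tuple[int, int] | None = None,
    jc_correction: bool = False,
) -> DistanceMatrix:
    """p-distances (differences per comparable site) over a region.

    Raises if any pair has zero comparable columns in the region.
    """
    if len(aln) < 2:
        raise ValueError("need at least two records")
    start, end = (0, aln.length) if region is None else region
    codes = aln.code_matrix()[:, start:end]
    n = codes.shape[0]
    valid = codes < 4
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            comp = valid[i] & valid[j]
            nc = int(comp.sum())
            if nc == 0:
                raise ValueError(
                    f"no comparable columns between {aln.records[i].label} and "
                    f"{aln.records[j].label} in [{start}, {end})"
                )
            p = float(((codes[i] != codes[j]) & comp).sum()) / nc
            if jc_correction:
                if p >= 0.75:
                    raise ValueError("p-distance beyond Jukes-Cantor saturation")
                p = -0.75 * np.log1p(-4.0 * p / 3.0)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(labels=aln.labels, d=d)


# ---- neighbor joining -----------------------------------------------------


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None, children=None):
        self.label = label
        self.children: list[tuple["_Node", float]] = children or []

    def leaves(self) -> list[str]:
        if self.label is not None:
            return [self.label]
        out: list[str] = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out


def newick_of(node: _Node, support: Mapping[frozenset, float] | None = None,
              all_leaves: frozenset | None = None) -> str:
    """Render a tree as newick; optional support values as internal labels."""
    smallest = min(all_leaves) if all_leaves else None

    def canon(leafset: frozenset) -> frozenset:
        if smallest is not None and smallest in leafset:
            return frozenset(all_leaves - leafset)
        return leafset

    def render(n: _Node, blen: float | None) -> str:
        if n.label is not None:
            body = n.label
        else:
            inner = ",".join(render(c, b) for c, b in n.children)
            tag = ""
            if support is not None and all_leaves is not None:
                key = canon(frozenset(n.leaves()))
                if key in support:
                    tag = f"{support[key]:g}"
            body = f"({inner}){tag}"
        return body if blen is None else f"{body}:{blen:g}"

    return render(node, None) + ";"


def tree_bipartitions(root: _Node) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, canonicalized.

    Each internal edge splits the leaves in two; the returned side is the
    one not containing the lexicographically smallest leaf.
    """
    all_leaves = frozenset(root.leaves())
    smallest = min(all_leaves)
    out: set[frozenset] = set()

    def walk(n: _Node) -> frozenset:
        if n.label is not None:
            return frozenset([n.label])
        below = frozenset()
        for c, _ in n.children:
            sub = walk(c)
            if 1 < len(sub) < len(all_leaves) - 1:
                side = sub if smallest not in sub else all_leaves - sub
                out.add(side)
            below = below | sub
        return below

    walk(root)
    return out


def neighbor_joining(dm: DistanceMatrix) -> TreeResult:
    """Agglomerative neighbor joining with the standard Q criterion.

    Deterministic: ties in Q are broken on the lexicographically smallest
    (min, max) pair of representative leaf labels; negative branch-length
    estimates are clamped to zero in the output (additive inputs are
    recovered exactly). Returns the unrooted topology as newick; supports
    are empty (see :func:`bootstrap_support`).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("non-finite distances")

    nodes: list[_Node] = [_Node(label=lab) for lab in dm.labels]
    reps: list[str] = list(dm.labels)  # representative (smallest) leaf per active node
    d = dm.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                if q[ii, jj] <= qmin + 1e-12 * max(1.0, abs(qmin)):
                    a, b = reps[active[ii]], reps[active[jj]]
                    key = (min(a, b), max(a, b))
                    if best is None or key < best[0]:
                        best = (key, ii, jj)
        _, ii, jj = best
        i, j = active[ii], active[jj]
        dij = sub[ii, jj]
        li = 0.5 * dij + (r[ii] - r[jj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)

        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        nodes.append(new)
        reps.append(min(reps[i], reps[j]))
        k = len(nodes) - 1
        # grow the distance matrix by one row/column for the new node
        newrow = np.zeros(k + 1)
        for ll in active:
            if ll in (i, j):
                continue
            newrow[ll] = 0.5 * (d[i, ll] + d[j, ll] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[k, : k] = newrow[:k]
        d[: k, k] = newrow[:k]
        active = [x for x in active if x not in (i, j)] + [k]

    # join the last three around an unrooted central node
    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    la = max(0.5 * (dab + dac - dbc), 0.0)
    lb = max(0.5 * (dab + dbc - dac), 0.0)
    lc = max(0.5 * (dac + dbc - dab), 0.0)
    root = _Node(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])

    return TreeResult(topology=newick_of(root), support={}, _root=root)


# ---- bootstrap ------------------------------------------------------------


def bootstrap_support(
    aln: SDAlignment,
    region: tuple[int, int] | None = None,
    n_reps: int = 100,
    seed: int = 0,
    jc_correction: bool = False,
) -> TreeResult:
    """NJ tree with bootstrap support over resampled alignment columns.

    Columns within the region are resampled with replacement ``n_reps``
    times; support of each internal edge of the original tree is the
    percentage of replicate trees containing the same bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    start, end = (0, aln.length) if region is None else region
    if end - start < 2:
        raise ValueError("region shorter than 2 columns")

    original = neighbor_joining(pairwise_distances(aln, (start, end), jc_correction))
    splits = original.bipartitions()
    counts = {s: 0 for s in splits}

    labels = aln.labels
    codes = aln.code_matrix()[:, start:end]
    nrec = codes.shape[0]
    valid = codes < 4
    pairs = [(i, j) for i in range(nrec) for j in range(i + 1, nrec)]
    diff_cols = np.stack([(codes[i] != codes[j]) & valid[i] & valid[j] for i, j in pairs])
    comp_cols = np.stack([valid[i] & valid[j] for i, j in pairs])

    rng = np.random.default_rng(seed)
    Lr = end - start
    for _ in range(n_reps):
        idx = rng.integers(0, Lr, size=Lr)
        nd = diff_cols[:, idx].sum(axis=1)
        nc = comp_cols[:, idx].sum(axis=1)
        if np.any(nc == 0):
            raise ValueError("bootstrap replicate lost all comparable columns for a pair")
        p = nd / nc
        if jc_correction:
            p = -0.75 * np.log1p(-4.0 * np.minimum(p, 0.7499) / 3.0)
        dmat = np.zeros((nrec, nrec))
        for (i, j), pij in zip(pairs, p):
            dmat[i, j] = dmat[j, i] = pij
        rep_tree = neighbor_joining(DistanceMatrix(labels=labels, d=dmat))
        rep_splits = rep_tree.bipartitions()
        for s in splits:
            if s in rep_splits:
                counts[s] += 1

    support = {s: 100.0 * counts[s] / n_reps for s in splits}
    root = original._root
    newick = newick_of(root, support=support, all_leaves=frozenset(labels))
    return TreeResult(topology=newick, support=support, _root=root)


# ---- classification -------------------------------------------------------


def _parse_label(label: str) -> tuple[str, str, str]:
    parts = label.split("|")
    if len(parts) != 3:
        raise ValueError(f"leaf label {label!r} does not follow species|role|id")
    return parts[0], parts[1], parts[2]


def classify_fusion_origin(
    trees: Mapping[str, TreeResult],
    labels: Sequence[str],
    support_threshold: float = 70.0,
) -> dict[str, str]:
    """Vote recurrent vs identical-by-descent per region and overall.

    A region votes ``recurrent`` when, for every species, some supported
    bipartition groups that species' fused haplotypes with at least one of
    that species' own reference SDs and nothing else (species-wise
    clustering). It votes ``identical_by_descent`` when a supported
    bipartition isolates all fused haplotypes of both species from every
    reference. Anything else — including both patterns at once — is
    ``ambiguous``. The overall call is the majority among regions that
    produced a supported vote; no supported votes, or a tie, is
    ``ambiguous``.

    Trees without bootstrap supports treat every edge of the topology as
    fully supported.
    """
    all_leaves = frozenset(labels)
    by_species_fused: dict[str, frozenset] = {}
    by_species_refs: dict[str, frozenset] = {}
    for lab in labels:
        sp, role, _ = _parse_label(lab)
        if role == "fusedSD":
            by_species_fused[sp] = by_species_fused.get(sp, frozenset()) | {lab}
        else:
            by_species_refs[sp] = by_species_refs.get(sp, frozenset()) | {lab}
    fused_species = sorted(by_species_fused)
    if not fused_species:
        raise ValueError("no fusedSD leaves among labels")
    for sp in fused_species:
        if not by_species_refs.get(sp):
            raise ValueError(f"species {sp!r} has fused leaves but no SD1/SD2 references")
    all_fused = frozenset().union(*by_species_fused.values())

    votes: dict[str, str] = {}
    for region, tree in trees.items():
        splits = tree.bipartitions()
        if tree.support:
            supported = {s for s in splits if tree.support.get(s, 0.0) >= support_threshold}
        else:
            supported = set(splits)
        sides = set()
        for s in supported:
            sides.add(s)
            sides.add(all_leaves - s)

        def species_clusters(sp: str) -> bool:
            fused = by_species_fused[sp]
            refs = by_species_refs[sp]
            for side in sides:
                if fused <= side and side <= fused | refs and side & refs:
                    return True
            return False

        recurrent = all(species_clusters(sp) for sp in fused_species)
        ibd = len(fused_species) > 1 and all_fused in sides
        if recurrent and not ibd:
            votes[region] = "recurrent"
        elif ibd and not recurrent:
            votes[region] = "identical_by_descent"
        else:
            votes[region] = "ambiguous"

    informative = [v for v in votes.values() if v != "ambiguous"]
    if not informative:
        overall = "ambiguous"
    else:
        n_rec = informative.count("recurrent")
        n_ibd = informative.count("identical_by_descent")
        overall = "recurrent" if n_rec > n_ibd else "identical_by_descent" if n_ibd > n_rec else "ambiguous"
    votes["overall"] = overall
    return votes


def nearest_reference_profile(
    aln: SDAlignment, partition: RegionPartition = RegionPartition()
) -> dict[tuple[str, str], str | tuple[str, ...]]:
    """Per region, the reference SD (SD1/SD2 of either species) closest to each haplotype.

    A haplotype whose nearest reference changes between regions indicates a
    region-specific sequence exchange between paralogs. Exact distance ties
    are reported as a sorted tuple of the tied reference labels. Keys are
    (record label, region name).
    """
    refs = [r for r in aln.records if r.role in ("SD1", "SD2")]
    if not refs:
        raise ValueError("alignment has no SD1/SD2 reference records")
    out: dict[tuple[str, str], str | tuple[str, ...]] = {}
    for name, start, end in partition.resolve(aln.length):
        dm = pairwise_distances(aln, (start, end))
        idx = {lab: i for i, lab in enumerate(dm.labels)}
        for recd in aln.records:
            cands = [r for r in refs if r.label != recd.label]
            dists = [(dm.d[idx[recd.label], idx[r.label]], r.label) for r in cands]
            best = min(d for d, _ in dists)
            tied = tuple(sorted(lab for d, lab in dists if d == best))
            out[(recd.label, name)] = tied[0] if len(tied) == 1 else tied
    return out
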