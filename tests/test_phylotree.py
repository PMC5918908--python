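"""Distances, neighbor joining, bootstrap and the fusion-origin classifier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdfusion.alignment import SDAlignment, SDRecord
from sdfusion.phylotree import (
    DistanceMatrix,
    RegionPartition,
    TreeResult,
    bootstrap_support,
    classify_fusion_origin,
    neighbor_joining,
    nearest_reference_profile,
    pairwise_distances,
)
from sdfusion.simlocus import SimConfig, simulate_locus


def _aln(*items):
    return SDAlignment([SDRecord(*i) for i in items])


# ---- random trees and their additive matrices (oracle machinery) ---------


def random_tree(n_leaves, rng):
    """Random unrooted binary tree as {frozenset(bipartition sides)} + path metric."""
    # sequential random attachment; edges carry random positive lengths
    labels = [f"L{i}" for i in range(n_leaves)]
    edges = {}  # node -> list of (node, length)

    def add_edge(a, b, ln):
        edges.setdefault(a, []).append((b, ln))
        edges.setdefault(b, []).append((a, ln))

    def remove_edge(a, b):
        edges[a] = [(x, l) for x, l in edges[a] if x != b]
        edges[b] = [(x, l) for x, l in edges[b] if x != a]

    next_internal = [0]

    def new_internal():
        next_internal[0] += 1
        return f"I{next_internal[0]}"

    add_edge(labels[0], labels[1], rng.uniform(0.5, 2.0))
    all_edges = [(labels[0], labels[1])]
    for lab in labels[2:]:
        a, b = all_edges[rng.integers(len(all_edges))]
        ln = [l for x, l in edges[a] if x == b][0]
        mid = new_internal()
        remove_edge(a, b)
        all_edges.remove((a, b))
        split = rng.uniform(0.25, 0.75) * ln
        add_edge(a, mid, split)
        add_edge(mid, b, ln - split)
        add_edge(mid, lab, rng.uniform(0.5, 2.0))
        all_edges += [(a, mid), (mid, b), (mid, lab)]

    # path lengths by BFS
    d = np.zeros((n_leaves, n_leaves))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, ln in edges[u]:
                if v not in dist:
                    dist[v] = dist[u] + ln
                    stack.append(v)
        for j, dst in enumerate(labels):
            d[i, j] = dist[dst]

    # true bipartitions: for each internal edge, leaves on one side
    splits = set()
    smallest = min(labels)
    for a, b in all_edges:
        if a.startswith("I") and b.startswith("I"):
            reach = {a}
            stack = [a]
            while stack:
                u = stack.pop()
                for v, _ in edges[u]:
                    if v != b and (u, v) != (a, b) and v not in reach:
                        if not (u == a and v == b):
                            reach.add(v)
                            stack.append(v)
            side = frozenset(x for x in reach if not x.startswith("I"))
            if 1 < len(side) < n_leaves - 1:
                splits.add(side if smallest not in side else frozenset(labels) - side)
        elif not a.startswith("I") or not b.startswith("I"):
            continue
    return labels, d, splits


def skbio_nj_bipartitions(labels, d):
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj

    tree = nj(SkDM(d, ids=labels))
    all_set = frozenset(labels)
    smallest = min(labels)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(labels) - 1:
            out.add(side if smallest not in side else all_set - side)
    return out


# ---- pairwise distances ---------------------------------------------------


def test_pairwise_distances_hand_counted():
    aln = _aln(
        ("h", "SD1", "a", "AAAAAAAAAA"),
        ("h", "SD2", "b", "AAAAAAAAAT"),
        ("h", "fusedSD", "c", "AATTAAAAAA"),
        ("h", "fusedSD", "d", "AATTAAAA-A"),
    )
    dm = pairwise_distances(aln)
    i = {lab: k for k, lab in enumerate(dm.labels)}
    assert dm.d[i["h|SD1|a"], i["h|SD2|b"]] == pytest.approx(1 / 10)
    assert dm.d[i["h|SD1|a"], i["h|fusedSD|c"]] == pytest.approx(2 / 10)
    assert dm.d[i["h|SD2|b"], i["h|fusedSD|c"]] == pytest.approx(3 / 10)
    assert dm.d[i["h|fusedSD|c"], i["h|fusedSD|d"]] == pytest.approx(0.0)  # gap excluded
    assert dm.d[i["h|SD1|a"], i["h|fusedSD|d"]] == pytest.approx(2 / 9)


def test_identical_pair_distance_zero_and_region_homogeneity(default_locus):
    cfg, aln, _ = default_locus
    dm_r1 = pairwise_distances(aln, (0, 1000))
    assert np.all(np.diag(dm_r1.d) == 0)
    assert np.all(dm_r1.d >= 0)


def test_zero_comparable_region_rejected():
    aln = _aln(("h", "SD1", "a", "AA--"), ("h", "SD2", "b", "AA--"))
    with pytest.raises(ValueError):
        pairwise_distances(aln, (2, 4))


# ---- neighbor joining -----------------------------------------------------


def test_nj_three_taxa_unique_topology_and_lengths():
    d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
    t = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
    assert t.bipartitions() == set()  # no internal edge with 3 taxa
    assert t.topology == "(a:1,b:2,c:3);"


def test_nj_recovers_known_five_taxon_tree_exactly():
    """Additive matrix from ((A:1,B:2):1,(C:1,D:1):2,E:4)."""
    labels = ["A", "B", "C", "D", "E"]
    paths = {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 5, ("A", "E"): 6,
             ("B", "C"): 6, ("B", "D"): 6, ("B", "E"): 7,
             ("C", "D"): 2, ("C", "E"): 7, ("D", "E"): 7}
    d = np.zeros((5, 5))
    for (x, y), v in paths.items():
        i, j = labels.index(x), labels.index(y)
        d[i, j] = d[j, i] = float(v)
    t = neighbor_joining(DistanceMatrix(labels, d))
    assert t.bipartitions() == {frozenset({"C", "D"}), frozenset({"C", "D", "E"})}
    # branch lengths recovered exactly: read them back off the newick
    assert "A:1" in t.topology and "B:2" in t.topology and "E:4" in t.topology


def test_nj_deterministic_under_ties():
    """A matrix with symmetric Q minima resolves by label order, stably."""
    labels = ["a", "b", "c", "d"]
    d = np.array(
        [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], dtype=float
    )
    t1 = neighbor_joining(DistanceMatrix(labels, d))
    t2 = neighbor_joining(DistanceMatrix(labels, d))
    assert t1.topology == t2.topology
    assert t1.bipartitions() == {frozenset({"c", "d"})}


def test_nj_rejects_tiny_or_nonfinite_input():
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))
    d = np.array([[0.0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0]])
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(["a", "b", "c"], d))


@given(st.integers(0, 10_000))
@settings(max_examples=20)
def test_nj_recovers_random_additive_trees(seed):
    """On an additive matrix NJ returns the generating topology (n <= 8)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    labels, d, true_splits = random_tree(n, rng)
    t = neighbor_joining(DistanceMatrix(labels, d))
    assert t.bipartitions() == true_splits


@given(st.integers(0, 10_000))
@settings(max_examples=20)
def test_nj_agrees_with_reference_implementation(seed):
    """Same topology as scikit-bio's NJ on generic random distance matrices."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    labels = [f"L{i}" for i in range(n)]
    x = rng.uniform(0.1, 1.0, size=(n, 6))
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))  # metric, generic
    np.fill_diagonal(d, 0.0)
    mine = neighbor_joining(DistanceMatrix(labels, d)).bipartitions()
    ref = skbio_nj_bipartitions(labels, d)
    assert mine == ref


# ---- bootstrap ------------------------------------------------------------


def test_bootstrap_saturated_signal_and_determinism():
    rng = np.random.default_rng(0)
    base = rng.choice(list("ACGT"), 400)
    grp2 = base.copy()
    grp2[::4] = np.where(grp2[::4] == "A", "C", "A")  # massive planted divergence
    def noisy(arr, k):
        out = arr.copy()
        out[k::37] = np.where(out[k::37] == "G", "T", "G")
        return "".join(out)

    aln = _aln(
        ("h", "SD1", "a", noisy(base, 1)),
        ("h", "SD2", "b", noisy(base, 2)),
        ("c", "SD1", "a", noisy(grp2, 1)),
        ("c", "SD2", "b", noisy(grp2, 2)),
    )
    t1 = bootstrap_support(aln, n_reps=100, seed=7)
    t2 = bootstrap_support(aln, n_reps=100, seed=7)
    assert t1.topology == t2.topology
    assert t1.support == t2.support
    [(split, supp)] = list(t1.support.items())
    assert supp == 100.0
    assert split in (frozenset({"c|SD1|a", "c|SD2|b"}), frozenset({"h|SD1|a", "h|SD2|b"}))


def test_bootstrap_supports_invariant_to_record_order(default_locus):
    cfg, aln, _ = default_locus
    reversed_aln = SDAlignment(list(reversed(aln.records)))
    t_fwd = bootstrap_support(aln, (0, 1000), n_reps=20, seed=3)
    t_rev = bootstrap_support(reversed_aln, (0, 1000), n_reps=20, seed=3)
    assert t_fwd.support == t_rev.support


def test_bootstrap_region_too_short_rejected(default_locus):
    _, aln, _ = default_locus
    with pytest.raises(ValueError):
        bootstrap_support(aln, (0, 1), n_reps=10, seed=0)


def test_species_split_edge_fully_supported(default_locus):
    """Region 1: the edge separating the two species' SD1+fused groups."""
    cfg, aln, _ = default_locus
    t = bootstrap_support(aln, (0, 1000), n_reps=100, seed=5)
    sp = cfg.species[0]
    side = frozenset([f"{sp}|SD1|ref"] + [f"{sp}|fusedSD|f{i}" for i in range(1, 8)])
    all_leaves = frozenset(aln.labels)
    match = {s for s in t.support if s in (side, all_leaves - side)}
    assert match, "species SD1+fused clade absent from region-1 tree"
    assert t.support[match.pop()] >= 95.0


# ---- classification -------------------------------------------------------


def _tree_with_support(splits_support):
    """A TreeResult stub carrying explicit bipartitions + supports."""
    t = TreeResult(topology=";", support=dict(splits_support))
    t.bipartitions = lambda: set(splits_support)  # type: ignore[method-assign]
    return t


LABELS = (
    ["h|SD1|ref", "h|SD2|ref"] + [f"h|fusedSD|f{i}" for i in (1, 2)]
    + ["c|SD1|ref", "c|SD2|ref"] + [f"c|fusedSD|f{i}" for i in (1, 2)]
)


def test_classifier_votes_recurrent_on_specieswise_clustering():
    h_side = frozenset(["h|SD1|ref", "h|fusedSD|f1", "h|fusedSD|f2"])
    c_side = frozenset(["c|SD1|ref", "c|fusedSD|f1", "c|fusedSD|f2"])
    tree = _tree_with_support({h_side: 99.0, c_side: 97.0})
    votes = classify_fusion_origin({"region1": tree}, LABELS)
    assert votes == {"region1": "recurrent", "overall": "recurrent"}


def test_classifier_votes_ibd_on_joint_fused_clade():
    fused = frozenset(l for l in LABELS if "fusedSD" in l)
    tree = _tree_with_support({fused: 93.0})
    votes = classify_fusion_origin({"region1": tree}, LABELS)
    assert votes == {"region1": "identical_by_descent", "overall": "identical_by_descent"}


def test_classifier_ambiguous_below_support_threshold():
    fused = frozenset(l for l in LABELS if "fusedSD" in l)
    tree = _tree_with_support({fused: 55.0})  # star-like: weak support
    votes = classify_fusion_origin({"region1": tree}, LABELS)
    assert votes["overall"] == "ambiguous"
    votes_lenient = classify_fusion_origin({"region1": tree}, LABELS, support_threshold=50)
    assert votes_lenient["overall"] == "identical_by_descent"


def test_classifier_conflicting_regions_ambiguous():
    h_side = frozenset(["h|SD1|ref", "h|fusedSD|f1", "h|fusedSD|f2"])
    c_side = frozenset(["c|SD1|ref", "c|fusedSD|f1", "c|fusedSD|f2"])
    fused = frozenset(l for l in LABELS if "fusedSD" in l)
    rec = _tree_with_support({h_side: 99.0, c_side: 99.0})
    ibd = _tree_with_support({fused: 99.0})
    votes = classify_fusion_origin({"region1": rec, "region3": ibd}, LABELS)
    assert votes["overall"] == "ambiguous"


def test_classifier_requires_references():
    with pytest.raises(ValueError):
        classify_fusion_origin({}, ["h|fusedSD|f1"])


def test_end_to_end_classification_both_scenarios(default_locus, ibd_locus):
    for (cfg, aln, truth), want in ((default_locus, "recurrent"),
                                    (ibd_locus, "identical_by_descent")):
        part = RegionPartition().resolve(aln.length)
        trees = {
            name: bootstrap_support(aln, (s, e), n_reps=100, seed=17)
            for name, s, e in part
        }
        votes = classify_fusion_origin(trees, aln.labels)
        assert votes["overall"] == want


# ---- nearest reference ----------------------------------------------------


def test_nearest_reference_flips_only_in_exchanged_region(default_locus):
    """The lineage-specific SD1/SD2 exchange shows up as a region-2 flip."""
    cfg, aln, _ = default_locus
    prof = nearest_reference_profile(aln)
    sp_a, sp_b = cfg.species  # exchange configured in sp_b ("chimp") region 2
    # species-A SD1 pairs with species-B SD2 in region 2, with SD1 elsewhere
    a_sd1 = f"{sp_a}|SD1|ref"
    assert prof[(a_sd1, "region1")] == f"{sp_b}|SD1|ref"
    assert prof[(a_sd1, "region2")] == f"{sp_b}|SD2|ref"
    assert prof[(a_sd1, "region3")] == f"{sp_b}|SD1|ref"


def test_nearest_reference_constant_without_lineage_exchange():
    cfg = SimConfig(seed=11, lineage_conversion_tracts={})
    aln, _ = simulate_locus(cfg)
    prof = nearest_reference_profile(aln)
    sp_a, sp_b = cfg.species
    for region in ("region1", "region2"):
        assert prof[(f"{sp_a}|SD1|ref", region)] == f"{sp_b}|SD1|ref"


def test_nearest_reference_reports_exact_ties():
    aln = _aln(
        ("h", "SD1", "ref", "AAAA"),
        ("h", "SD2", "ref", "AAAT"),
        ("c", "SD1", "ref", "AATT"),
        ("c", "fusedSD", "f1", "AAAC"),
    )
    prof = nearest_reference_profile(aln, RegionPartition([("all", 0, None)]))
    assert prof[("c|fusedSD|f1", "all")] == ("h|SD1|ref", "h|SD2|ref")
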