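"""Classical MDS and neighbour-joining: exactness and determinism."""

import numpy as np
import pytest

from strpopgen import (
    DistanceMatrix,
    classical_mds,
    heatmap_export,
    neighbor_joining,
    to_newick,
    tree_distances,
)


def _euclid(points):
    p = np.asarray(points, dtype=float)
    return np.sqrt(((p[:, None, :] - p[None, :, :]) ** 2).sum(-1))


def _random_additive_tree(rng, n_taxa):
    """A random binary tree as (adjacency, leaf labels); independent of
    the package's tree code.  Returns the leaf distance matrix."""
    labels = [f"T{i:02d}" for i in range(n_taxa)]
    nodes = list(range(n_taxa))
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in nodes}
    nxt = n_taxa
    active = nodes[:]
    while len(active) > 1:
        i, j = rng.choice(len(active), 2, replace=False)
        a, b = active[i], active[j]
        parent = nxt
        nxt += 1
        adj[parent] = []
        for child in (a, b):
            w = float(rng.uniform(0.1, 1.0))
            adj[parent].append((child, w))
            adj[child].append((parent, w))
        active = [x for x in active if x not in (a, b)] + [parent]
    D = np.zeros((n_taxa, n_taxa))
    for s in range(n_taxa):
        dist = {s: 0.0}
        stack = [s]
        while stack:
            cur = stack.pop()
            for nbr, w in adj[cur]:
                if nbr not in dist:
                    dist[nbr] = dist[cur] + w
                    stack.append(nbr)
        for t in range(n_taxa):
            D[s, t] = dist[t]
    D = (D + D.T) / 2  # per-row accumulation leaves ~1e-16 asymmetry
    return labels, D


# -- MDS ------------------------------------------------------------------


def test_mds_collinear_points_exact():
    D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
    res = classical_mds(DistanceMatrix(["A", "B", "C"], D), dims=1)
    emb = _euclid(res.coordinates)
    assert np.allclose(emb, D, atol=1e-9)
    assert abs(res.coordinates.mean()) < 1e-9  # centered


def test_mds_recovers_euclidean_distances(rng):
    pts = rng.normal(size=(12, 4))
    D = _euclid(pts)
    res = classical_mds(DistanceMatrix([f"P{i}" for i in range(12)], D), dims=4)
    assert np.abs(_euclid(res.coordinates) - D).max() < 1e-8
    assert np.all(np.diff(res.eigenvalues) <= 1e-9)  # descending


def test_mds_duplicate_rows_coincide(rng):
    pts = np.vstack([rng.normal(size=(4, 2)), rng.normal(size=(1, 2))])
    pts[4] = pts[0]  # duplicate population
    D = _euclid(pts)
    res = classical_mds(DistanceMatrix(list("ABCDE"), D), dims=2)
    assert np.allclose(res.coordinates[0], res.coordinates[4], atol=1e-9)


def test_mds_dim_truncation_warns():
    D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
    with pytest.warns(UserWarning, match="positive eigenvalues"):
        res = classical_mds(DistanceMatrix(["A", "B", "C"], D), dims=2)
    assert res.coordinates.shape[1] == 1  # collinear: one positive axis


def test_mds_agrees_with_skbio_pcoa(rng):
    skbio = pytest.importorskip("skbio")
    pts = rng.normal(size=(8, 3))
    D = _euclid(pts)
    dm = DistanceMatrix([f"P{i}" for i in range(8)], D)
    ours = classical_mds(dm, dims=3)
    ref = skbio.stats.ordination.pcoa(
        skbio.DistanceMatrix(D, ids=dm.labels), number_of_dimensions=3
    )
    assert np.allclose(
        np.sort(ours.eigenvalues[:3]), np.sort(ref.eigvals.values[:3]), atol=1e-8
    )
    assert np.allclose(
        _euclid(ours.coordinates), _euclid(ref.samples.values), atol=1e-8
    )


# -- neighbour joining ----------------------------------------------------


def test_nj_three_taxa_closed_form():
    D = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
    tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], D))
    lengths = {min(c.leaves()): l for c, l, _ in tree.children}
    assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
    assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
    assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)


def test_nj_exact_on_additive_matrices(rng):
    for n in (4, 6, 9):
        labels, D = _random_additive_tree(rng, n)
        tree = neighbor_joining(DistanceMatrix(labels, D))
        td = tree_distances(tree).loc[labels, labels].values
        assert np.abs(td - D).max() < 1e-9


def test_nj_matches_skbio(rng):
    skbio = pytest.importorskip("skbio")
    labels, D = _random_additive_tree(rng, 7)
    ours = tree_distances(neighbor_joining(DistanceMatrix(labels, D)))
    ref = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            assert ours.loc[a, b] == pytest.approx(
                ref.find(a).distance(ref.find(b)), abs=1e-6
            )


def test_nj_label_order_invariance(rng):
    labels, D = _random_additive_tree(rng, 6)
    base = tree_distances(neighbor_joining(DistanceMatrix(labels, D)))
    perm = rng.permutation(len(labels))
    labels2 = [labels[i] for i in perm]
    D2 = D[np.ix_(perm, perm)]
    other = tree_distances(neighbor_joining(DistanceMatrix(labels2, D2)))
    assert np.allclose(
        base.loc[labels, labels].values, other.loc[labels, labels].values, atol=1e-9
    )


def test_nj_requires_three_taxa():
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(["A", "B"], np.zeros((2, 2))))


def test_newick_round_trip_dendropy(rng):
    dendropy = pytest.importorskip("dendropy")
    labels, D = _random_additive_tree(rng, 6)
    tree = neighbor_joining(DistanceMatrix(labels, D))
    nwk = to_newick(tree)
    assert nwk.endswith(";")
    parsed = dendropy.Tree.get(data=nwk, schema="newick")
    pdm = parsed.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in parsed.taxon_namespace}
    ours = tree_distances(tree)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                ours.loc[a, b], abs=1e-5
            )


def test_newick_quotes_reserved_labels():
    D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
    tree = neighbor_joining(DistanceMatrix(["A B", "C(1)", "D"], D))
    nwk = to_newick(tree)
    assert "'A B'" in nwk and "'C(1)'" in nwk


def test_heatmap_export_ordering(rng):
    labels = [f"P{i}" for i in range(5)]
    pts = rng.normal(size=(5, 2))
    m = DistanceMatrix(labels, _euclid(pts))
    order = ["P3", "P1", "P0", "P4", "P2"]
    df = heatmap_export(m, order)
    assert list(df.index) == order and list(df.columns) == order
    with pytest.raises(KeyError):
        heatmap_export(m, ["P9"])
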