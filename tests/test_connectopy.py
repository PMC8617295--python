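import numpy as np
import pytest
import scipy.sparse as sp
import scipy.stats
from hypothesis import given, settings, strategies as st

from gradpain.connectopy import (
    Connectopy,
    VoxelGraph,
    align_connectopy,
    average_connectopy,
    build_graph,
    eta2,
    eta2_matrix,
    extract_connectopies,
    fingerprints,
    laplacian_eigenmaps,
    make_target_mask,
    reduce_target,
    seed_connectivity_probability,
    subdivide_connectopy,
    SimilarityMatrix,
)
from gradpain.errors import DataError
from gradpain.preprocess import clean, standardize
from gradpain.synthetic import PhantomSpec, make_phantom
from gradpain.volume import Mask


# --- target reduction --------------------------------------------------------


def test_reduce_target_rank_of_duplicated_voxels(rng):
    x = rng.standard_normal(30)
    U, s = reduce_target(np.column_stack([x, x]))
    assert U.shape[1] == 1 and s.shape == (1,)


def test_reduce_target_rank_bound_after_demeaning(rng):
    U, s = reduce_target(rng.standard_normal((50, 200)))
    assert U.shape[1] == 49


def test_reduce_target_all_zero_rejected():
    with pytest.raises(DataError, match="zero"):
        reduce_target(np.zeros((20, 5)))


def test_component_profiles_preserve_covariance_geometry(rng):
    """Pairwise distances between covariance profiles against all target
    voxels equal those against the singular-value-weighted components."""
    T, M, N = 40, 120, 15
    Xt = rng.standard_normal((T, M))
    Xt -= Xt.mean(axis=0)
    Xroi, _ = standardize(rng.standard_normal((T, N)))
    U, s = reduce_target(Xt)
    full = Xroi.T @ Xt            # N × M covariance profiles
    comp = Xroi.T @ (U * s)       # N × K
    d_full = np.linalg.norm(full[:, None] - full[None, :], axis=2)
    d_comp = np.linalg.norm(comp[:, None] - comp[None, :], axis=2)
    np.testing.assert_allclose(d_comp, d_full, rtol=1e-8, atol=1e-8)


# --- fingerprints ------------------------------------------------------------


def test_fingerprint_of_component_itself(rng):
    U, s = reduce_target(rng.standard_normal((60, 30)))
    comp0 = (U[:, 0] - U[:, 0].mean()) / U[:, 0].std()
    for sign, expected in ((1.0, 1.0), (-1.0, -1.0)):
        F = fingerprints((sign * comp0)[:, None], U, s)
        assert F.correlations[0, 0] == pytest.approx(expected, abs=1e-10)
        np.testing.assert_allclose(F.correlations[0, 1:], 0.0, atol=1e-8)


def test_fingerprints_match_naive_correlation_loop(rng):
    T, N, K = 30, 8, 5
    Xroi, _ = standardize(rng.standard_normal((T, N)))
    U, s = reduce_target(rng.standard_normal((T, K + 1)))
    F = fingerprints(Xroi, U, s)
    for i in range(N):
        for k in range(U.shape[1]):
            expected = np.corrcoef(Xroi[:, i], U[:, k])[0, 1]
            assert F.correlations[i, k] == pytest.approx(expected, abs=1e-12)


# --- eta squared -------------------------------------------------------------


def test_eta2_identical_profiles_is_one(rng):
    a = rng.standard_normal(12)
    assert eta2(a, a) == pytest.approx(1.0)


def test_eta2_hand_example_orthogonal_unit_profiles():
    # a=(1,0), b=(0,1): numerator = denominator = 1, so similarity 0
    assert eta2(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(0.0, abs=1e-15)


def test_eta2_matrix_matches_naive_pairwise_loop(rng):
    F = rng.standard_normal((10, 5))
    S = eta2_matrix(F).values
    for i in range(10):
        for j in range(10):
            assert S[i, j] == pytest.approx(max(eta2(F[i], F[j]), 0.0), abs=1e-12)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 10_000))
def test_eta2_matrix_symmetric_unit_diagonal_fuzz(seed):
    F = np.random.default_rng(seed).standard_normal((7, 4)) * 3
    S = eta2_matrix(F).values
    np.testing.assert_allclose(S, S.T, atol=1e-12)
    np.testing.assert_allclose(np.diag(S), 1.0)
    assert S.min() >= 0.0 and S.max() <= 1.0


def test_eta2_degenerate_constant_pair_defined_as_one(caplog):
    with caplog.at_level("WARNING"):
        assert eta2(np.full(4, 2.0), np.full(4, 2.0)) == 1.0
    assert "degenerate" in caplog.text


# --- graph -------------------------------------------------------------------


def test_build_graph_complete_on_all_ones():
    S = SimilarityMatrix(np.ones((8, 8)))
    graph = build_graph(S)
    assert graph.n_bridges == 0
    W = graph.weights.toarray()
    assert ((W > 0).sum(axis=1) > 0).all()


def test_build_graph_repairs_block_diagonal(caplog):
    S = np.zeros((12, 12))
    S[:6, :6] = 0.9
    S[6:, 6:] = 0.9
    np.fill_diagonal(S, 1.0)
    with caplog.at_level("WARNING"):
        graph = build_graph(SimilarityMatrix(S), k=3)
    assert graph.n_bridges >= 1
    n_comp = sp.csgraph.connected_components(graph.weights, directed=False)[0]
    assert n_comp == 1


def test_graph_edges_link_gradient_neighbours(clean_line_phantom):
    """On a 1-axis phantom the strongest edges connect voxels adjacent in g."""
    cvol, roi, cmask, g = clean_line_phantom
    target = make_target_mask(cmask, roi)
    Xroi, _ = standardize(cvol.timeseries(roi))
    Xt = cvol.timeseries(target)
    U, s = reduce_target(Xt - Xt.mean(axis=0))
    S = eta2_matrix(fingerprints(Xroi, U, s))
    graph = build_graph(S)
    W = graph.weights.tocoo()
    # mean |Δg| over graph edges is far below the all-pairs mean
    edge_dg = np.abs(g[W.row] - g[W.col]).mean()
    all_dg = np.abs(g[:, None] - g[None, :]).mean()
    assert edge_dg < 0.25 * all_dg


# --- eigenmaps ---------------------------------------------------------------


def path_graph(n, rng=None):
    W = np.zeros((n, n))
    for i in range(n - 1):
        w = 1.0 if rng is None else 0.5 + rng.random()
        W[i, i + 1] = W[i + 1, i] = w
    return W


def test_three_node_path_fiedler_vector():
    """Unit-weight 3-path: the generalized Fiedler vector is proportional to
    (1, 0, -1) with eigenvalue 1 (dense 3x3 oracle)."""
    maps = laplacian_eigenmaps(sp.csr_matrix(path_graph(3)), n_maps=1)
    c = maps[0]
    assert c.eigenvalue == pytest.approx(1.0, abs=1e-10)
    np.testing.assert_allclose(np.sort(c.values), [0.0, 0.5, 1.0], atol=1e-10)


def test_path_graph_dominant_map_monotone(rng):
    maps = laplacian_eigenmaps(sp.csr_matrix(path_graph(20, rng)), n_maps=2)
    v = maps[0].values
    diffs = np.diff(v)
    assert np.all(diffs > 0) or np.all(diffs < 0)


def test_sparse_solver_matches_dense_oracle(clean_line_phantom):
    cvol, roi, cmask, g = clean_line_phantom
    target = make_target_mask(cmask, roi)
    Xroi, _ = standardize(cvol.timeseries(roi))
    Xt = cvol.timeseries(target)
    U, s = reduce_target(Xt - Xt.mean(axis=0))
    graph = build_graph(eta2_matrix(fingerprints(Xroi, U, s)))
    dense = laplacian_eigenmaps(graph, n_maps=3, solver="dense")
    sparse = laplacian_eigenmaps(graph, n_maps=3, solver="sparse")
    for cd, cs in zip(dense, sparse):
        assert cs.eigenvalue == pytest.approx(cd.eigenvalue, abs=1e-8)
        err = min(np.abs(cs.values - cd.values).max(), np.abs(cs.values - (1 - cd.values)).max())
        assert err < 1e-6


def test_eigenpair_residual_invariant(rng):
    W = path_graph(30, rng)
    graph = VoxelGraph(sp.csr_matrix(W), k=1)
    deg = W.sum(axis=1)
    L = np.diag(deg) - W
    for c_map, raw in zip(laplacian_eigenmaps(graph, n_maps=3), range(3)):
        # recover the unscaled eigenvector via the rescaled one (affine map keeps the eigenspace
        # only together with the constant vector, so check the residual in that 2-space)
        v = c_map.values
        resid = L @ v - c_map.eigenvalue * deg * v
        # subtract the component explained by the constant-vector direction (eigenvalue 0)
        ones = np.ones_like(v)
        resid -= (resid @ ones) / (deg @ ones) * deg
        assert np.linalg.norm(resid) <= 1e-8 * np.linalg.norm(v)


def test_connectopies_invariant_to_target_voxel_permutation(rng):
    T, M, N = 50, 40, 20
    Xt = rng.standard_normal((T, M))
    Xt -= Xt.mean(axis=0)
    Xroi, _ = standardize(rng.standard_normal((T, N)))
    perm = rng.permutation(M)

    def run(Xtarget):
        U, s = reduce_target(Xtarget)
        graph = build_graph(eta2_matrix(fingerprints(Xroi, U, s)))
        return laplacian_eigenmaps(graph, n_maps=2)

    for a, b in zip(run(Xt), run(Xt[:, perm])):
        np.testing.assert_allclose(a.values, b.values, atol=1e-8)
        assert a.eigenvalue == pytest.approx(b.eigenvalue, abs=1e-12)


# --- alignment, averaging, subdivision --------------------------------------


def test_align_connectopy_flip_rules(rng):
    v = np.linspace(0, 1, 20)
    c = Connectopy(v, 0.1, 1)
    assert align_connectopy(c, v).values is v
    np.testing.assert_allclose(align_connectopy(c, 1 - v).values, 1 - v)
    coord = np.arange(20.0)
    out = align_connectopy(Connectopy(1 - v, 0.1, 1), coord)
    assert np.corrcoef(out.values, coord)[0, 1] > 0
    with pytest.raises(DataError, match="zero-variance"):
        align_connectopy(c, np.full(20, 3.0))


def test_average_connectopy_identity_and_cancellation():
    v = np.linspace(0, 1, 11)
    np.testing.assert_allclose(average_connectopy([v, v.copy()]), v)
    flat = average_connectopy([Connectopy(v, 0.1, 1), Connectopy(1 - v, 0.1, 1)])
    assert flat.std() < 1e-12  # unaligned maps cancel: documented hazard
    with pytest.raises(DataError, match="mismatch"):
        average_connectopy([v, np.linspace(0, 1, 12)])


def test_subdivision_interval_counts():
    roi = Mask(np.ones((10, 1, 1), bool), "roi")
    c = np.arange(0.05, 1.0, 0.1)  # 0.05, 0.15, ..., 0.95
    parts = subdivide_connectopy(c, roi, cuts=(0.3, 0.7))
    assert [p.data.sum() for p in parts] == [3, 4, 3]
    assert not np.any(parts[0].data & parts[1].data)
    assert np.array_equal(parts[0].data | parts[1].data | parts[2].data, roi.data)


def test_subdivision_degenerate_and_two_part():
    roi = Mask(np.ones((5, 1, 1), bool), "roi")
    parts = subdivide_connectopy(np.zeros(5), roi)
    assert [p.data.sum() for p in parts] == [5, 0, 0]
    halves = subdivide_connectopy(np.array([0.1, 0.2, 0.6, 0.9, 1.0]), roi, cuts=(0.5,))
    assert [p.data.sum() for p in halves] == [2, 3]


# --- seed connectivity -------------------------------------------------------


def test_seed_probability_single_subject_is_binary(clean_box_phantom):
    spec, cvol, roi, cmask, g = clean_box_phantom
    parts = subdivide_connectopy(g, roi)
    maps = seed_connectivity_probability([cvol], [cmask], parts)
    for m in maps:
        assert set(np.unique(m)) <= {0.0, 1.0}


def test_seed_probability_infinite_threshold_gives_zero(clean_box_phantom):
    spec, cvol, roi, cmask, g = clean_box_phantom
    parts = subdivide_connectopy(g, roi)
    maps = seed_connectivity_probability([cvol], [cmask], parts, z_thresh=np.inf)
    assert all(m.sum() == 0 for m in maps)


def test_seed_probability_localizes_to_matching_target_box():
    """The posterior (low-g) subdivision connects to target box A and the
    anterior one to box B: probability inside the matching box is high,
    elsewhere low."""
    spec = PhantomSpec(seed=21)
    vols, brains = [], []
    roi = parts = None
    for s in range(6):
        vol, roi, brain, g = make_phantom(PhantomSpec(seed=100 + s))
        cvol, cmask = clean(vol, brain)
        vols.append(cvol)
        brains.append(cmask)
        parts = subdivide_connectopy(g, roi)
    maps = seed_connectivity_probability(vols, brains, parts)

    def box_mask(box):
        m = np.zeros(spec.grid_shape, bool)
        m[box[0][0]:box[0][1], box[1][0]:box[1][1], box[2][0]:box[2][1]] = True
        return m

    networks = box_mask(spec.target_box_a) | box_mask(spec.target_box_b)
    for part_idx, box in ((0, spec.target_box_a), (2, spec.target_box_b)):
        inside = box_mask(box)
        background = ~networks & ~roi.data  # uncoupled voxels
        assert maps[part_idx][inside].mean() >= 0.8
        assert maps[part_idx][background].mean() <= 0.2


# --- end to end --------------------------------------------------------------


def test_noise_free_gradient_recovery_is_exactly_monotone(clean_line_phantom):
    cvol, roi, cmask, g = clean_line_phantom
    res = extract_connectopies(cvol, roi, cmask, align_axis=0)
    rho = scipy.stats.spearmanr(res.connectopies[0].values, g).statistic
    assert abs(rho) == 1.0


def test_noisy_gradient_recovery(clean_box_phantom):
    spec, cvol, roi, cmask, g = clean_box_phantom
    res = extract_connectopies(cvol, roi, cmask, align_axis=0)
    assert abs(np.corrcoef(res.connectopies[0].values, g)[0, 1]) >= 0.9
    for c in res.connectopies:
        assert c.values.min() == 0.0 and c.values.max() == 1.0
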