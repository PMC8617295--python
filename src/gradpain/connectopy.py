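"""Connectopic mapping: from voxel time series to spatial connectivity gradients.

The chain is the one used for gradient ("connectopy") extraction in
resting-state fMRI:

1. The target region's time series are reduced with a singular value
   decomposition; only numerically significant temporal components are kept.
   Working against the components preserves the geometry of the voxelwise
   connectivity profiles exactly (orthogonal invariance).
2. Each ROI voxel gets a *connectivity fingerprint*: its Pearson correlations
   with the target components.
3. Fingerprint similarity between ROI voxels is measured with the eta-squared
   coefficient, giving an N×N similarity matrix.
4. The similarity matrix is sparsified to a connected k-nearest-neighbour
   graph and decomposed with Laplacian eigenmaps (generalized eigenproblem
   L v = λ D v).  Eigenvectors of the smallest nonzero eigenvalues are the
   connectopies; each is affinely rescaled to [0, 1].

Eigenvector sign is arbitrary, so connectopies must be aligned to a spatial
reference (:func:`align_connectopy`) before group averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.ndimage
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from gradpain.errors import DataError, NumericalError
from gradpain.volume import BoldVolume, Mask, voxel_coordinates

log = logging.getLogger(__name__)

_BRIDGE_WEIGHT_FLOOR = 1e-6


@dataclass
class FingerprintMatrix:
    """Pearson correlations of N ROI voxels against K target components.

    ``correlations`` entries lie in [-1, 1]; ``singular_values`` carry the
    weight of each component in the original target data.
    """

    correlations: np.ndarray
    singular_values: np.ndarray

    def __post_init__(self) -> None:
        self.correlations = np.asarray(self.correlations, dtype=np.float64)
        self.singular_values = np.asarray(self.singular_values, dtype=np.float64)
        if np.abs(self.correlations).max(initial=0.0) > 1.0 + 1e-8:
            raise DataError("fingerprint entries must lie in [-1, 1]")


@dataclass
class SimilarityMatrix:
    """Symmetric N×N eta-squared similarity with unit diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        S = np.asarray(self.values, dtype=np.float64)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise DataError(f"similarity matrix must be square, got {S.shape}")
        if not np.allclose(S, S.T, atol=1e-10):
            raise DataError("similarity matrix must be symmetric")
        if S.min() < -1e-10 or S.max() > 1 + 1e-10:
            raise DataError("similarity values must lie in [0, 1]")
        self.values = np.clip(S, 0.0, 1.0)
        np.fill_diagonal(self.values, 1.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Connectopy:
    """One spatial connectivity gradient over the ROI voxels.

    ``values`` are affinely rescaled to [0, 1]; ``rank`` is 1 for the dominant
    gradient (smallest nonzero eigenvalue), written y1 in figures.
    """

    values: np.ndarray
    eigenvalue: float
    rank: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(v)):
            raise DataError("connectopy values must be finite")
        self.values = v


@dataclass
class VoxelGraph:
    """Sparse symmetric nonnegative adjacency over ROI voxels."""

    weights: sp.csr_matrix
    k: int
    n_bridges: int = 0


def reduce_target(X_target: np.ndarray, rank_tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """SVD-reduce a T × M matrix of demeaned target voxel time series.

    Returns orthonormal temporal components (T × K) and their singular values,
    keeping only components with singular value > ``rank_tol`` · σ₁
    (the numerical rank).
    """
    X = np.asarray(X_target, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 2:
        raise DataError("target matrix must be T x M with M >= 2")
    X = X - X.mean(axis=0)  # ensure per-voxel demeaning
    if not np.any(np.abs(X) > 0):
        raise DataError("target matrix is all zero after demeaning")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    K = int(np.sum(s > rank_tol * s[0]))
    # deterministic sign convention: positive sum of spatial loadings
    flip = np.sign(Vt[:K].sum(axis=1))
    flip[flip == 0] = 1.0
    return U[:, :K] * flip, s[:K]


def fingerprints(X_roi: np.ndarray, components: np.ndarray, singular_values: np.ndarray) -> FingerprintMatrix:
    """Correlate each ROI voxel time series with each target component.

    ``X_roi`` is T × N and assumed standardized per voxel.  The component
    representation is weighted by the singular values (i.e. the reduced target
    is U·S), but Pearson correlation is scale invariant, so the stored entries
    are plain correlations in [-1, 1]; the singular values travel alongside.
    """
    X = np.asarray(X_roi, dtype=np.float64)
    U = np.asarray(components, dtype=np.float64)
    s = np.asarray(singular_values, dtype=np.float64)
    if X.shape[0] != U.shape[0]:
        raise DataError(f"timepoints mismatch: ROI {X.shape[0]} vs components {U.shape[0]}")
    T = X.shape[0]
    Uc = U - U.mean(axis=0)
    usd = Uc.std(axis=0)
    keep = usd > 1e-14
    if not keep.all():
        log.warning("fingerprints: dropping %d zero-variance component(s)", int((~keep).sum()))
        Uc, usd, s = Uc[:, keep], usd[keep], s[keep]
    Xc = X - X.mean(axis=0)
    xsd = Xc.std(axis=0)
    xsd = np.where(xsd > 0, xsd, 1.0)
    corr = (Xc / xsd).T @ (Uc / usd) / T
    return FingerprintMatrix(correlations=np.clip(corr, -1.0, 1.0), singular_values=s)


def eta2(a: np.ndarray, b: np.ndarray) -> float:
    """Eta-squared similarity of two profiles.

    eta²(a,b) = 1 − Σ_k[(a_k−m_k)² + (b_k−m_k)²] / Σ_k[(a_k−M̄)² + (b_k−M̄)²]
    with m_k the pointwise pair mean and M̄ the grand mean of both profiles.
    Identical profiles give 1; a constant identical pair is defined as 1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    m = (a + b) / 2.0
    grand = m.mean()
    num = np.sum((a - m) ** 2 + (b - m) ** 2)
    den = np.sum((a - grand) ** 2 + (b - grand) ** 2)
    if den <= 1e-300:
        log.warning("eta2: degenerate constant pair, similarity defined as 1")
        return 1.0
    return float(1.0 - num / den)


def eta2_matrix(F: FingerprintMatrix | np.ndarray) -> SimilarityMatrix:
    """Full eta-squared similarity matrix over fingerprint rows (vectorized)."""
    A = F.correlations if isinstance(F, FingerprintMatrix) else np.asarray(F, dtype=np.float64)
    n, K = A.shape
    if n < 2 or K < 2:
        raise DataError("need at least 2 profiles of length >= 2")
    rowsum = A.sum(axis=1)
    rowsq = (A**2).sum(axis=1)
    G = A @ A.T
    num = 0.5 * (rowsq[:, None] + rowsq[None, :] - 2.0 * G)
    grand = (rowsum[:, None] + rowsum[None, :]) / (2.0 * K)
    den = rowsq[:, None] + rowsq[None, :] - 2.0 * K * grand**2
    degenerate = den <= 1e-12 * max(1.0, rowsq.max())
    if degenerate.sum() > n:  # off-diagonal degeneracies
        log.warning("eta2_matrix: %d degenerate pair(s) set to similarity 1", int(degenerate.sum() - n))
    S = np.where(degenerate, 1.0, 1.0 - num / np.where(degenerate, 1.0, den))
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(values=S)


def _knn_adjacency(S0: np.ndarray, k: int) -> np.ndarray:
    """Mutual k-nearest-neighbour adjacency from a zero-diagonal similarity.

    Neighbours tied with the k-th largest similarity are all included, so a
    saturated (all-equal) similarity yields the complete graph."""
    thresh = np.partition(S0, -k, axis=1)[:, -k]
    directed = (S0 >= thresh[:, None]) & (S0 > 0)
    mutual = directed & directed.T
    return np.where(mutual, S0, 0.0)


def build_graph(S: SimilarityMatrix, k: int | None = None) -> VoxelGraph:
    """Sparsify a similarity matrix into a connected weighted graph.

    Mutual k-nearest neighbours (default k = 10% of N, at least 6) on the
    zero-diagonal similarity; if the result is disconnected the neighbourhood
    is enlarged, and any remaining components are joined with the strongest
    available cross-component edges from the dense matrix.
    """
    S0 = S.values.copy()
    np.fill_diagonal(S0, 0.0)
    n = S0.shape[0]
    if k is None:
        k = max(6, int(round(0.10 * n)))
    k = min(k, n - 1)
    W = _knn_adjacency(S0, k)
    n_comp, labels = csgraph.connected_components(sp.csr_matrix(W), directed=False)
    n_bridges = 0
    if n_comp > 1:
        # mutual-rank bridging: join components through the pair whose
        # similarity is reciprocated, i.e. minimal rank_i(j) + rank_j(i);
        # one-sided attractions (a pathology of eta² near degenerate
        # fingerprints) are thereby excluded as bridges
        order = np.argsort(-S0, axis=1, kind="stable")
        rank = np.empty_like(order)
        rows = np.arange(n)[:, None]
        rank[rows, order] = np.arange(n)[None, :]
        mutual_rank = rank + rank.T
    while n_comp > 1:
        in0 = labels == labels[0]
        sub = mutual_rank[np.ix_(in0, ~in0)].astype(float)
        best = sub.min()
        cands = np.argwhere(sub == best)
        if len(cands) > 1:  # tie-break by strongest similarity
            sims = [S0[np.where(in0)[0][a], np.where(~in0)[0][b]] for a, b in cands]
            i_loc, j_loc = cands[int(np.argmax(sims))]
        else:
            i_loc, j_loc = cands[0]
        i = np.where(in0)[0][i_loc]
        j = np.where(~in0)[0][j_loc]
        W[i, j] = W[j, i] = max(S0[i, j], _BRIDGE_WEIGHT_FLOOR)
        n_bridges += 1
        n_comp, labels = csgraph.connected_components(sp.csr_matrix(W), directed=False)
    if n_bridges:
        log.warning("build_graph: added %d bridging edge(s) to connect the graph (k=%d)", n_bridges, k)
    else:
        log.info("build_graph: connected with k=%d", k)
    return VoxelGraph(weights=sp.csr_matrix(np.maximum(W, W.T)), k=k, n_bridges=n_bridges)


def _rescale01(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi - lo <= 0:
        raise NumericalError("cannot rescale a constant eigenvector to [0, 1]")
    return (v - lo) / (hi - lo)


def laplacian_eigenmaps(graph: VoxelGraph | sp.spmatrix | np.ndarray, n_maps: int = 3, solver: str = "auto") -> list[Connectopy]:
    """Solve the generalized eigenproblem L v = λ D v on a connected graph.

    Returns the eigenvectors of the ``n_maps`` smallest nonzero eigenvalues,
    each rescaled to [0, 1], in ascending eigenvalue order.  ``solver`` is
    ``"dense"`` (scipy.linalg.eigh), ``"sparse"`` (ARPACK shift-invert with a
    fixed start vector, hence deterministic) or ``"auto"``.
    """
    W = graph.weights if isinstance(graph, VoxelGraph) else sp.csr_matrix(graph)
    W = sp.csr_matrix(W).astype(np.float64)
    n = W.shape[0]
    if n < n_maps + 2:
        raise DataError(f"graph with {n} nodes too small for {n_maps} maps")
    if (W != W.T).nnz:
        raise DataError("graph adjacency must be symmetric")
    if W.data.size and W.data.min() < 0:
        raise DataError("graph weights must be nonnegative")
    deg = np.asarray(W.sum(axis=1)).ravel()
    if deg.min() <= 0:
        raise DataError("graph has an isolated node (zero degree)")
    D = sp.diags(deg)
    L = D - W
    if solver == "auto":
        solver = "dense" if n <= 600 else "sparse"
    if solver == "dense":
        vals, vecs = scipy.linalg.eigh(L.toarray(), np.diag(deg))
    elif solver == "sparse":
        v0 = np.full(n, 1.0 / np.sqrt(n))
        vals, vecs = spla.eigsh(L.tocsc(), k=n_maps + 1, M=D.tocsc(), sigma=0, which="LM", v0=v0)
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    else:
        raise DataError(f"unknown solver '{solver}'")
    # drop the trivial constant eigenvector (eigenvalue 0 on a connected graph)
    if vals[0] > 1e-8:
        raise NumericalError(f"smallest eigenvalue {vals[0]:.3e} not ~0; graph may be disconnected")
    sel = list(range(1, n_maps + 1))
    maps = []
    for rank, idx in enumerate(sel, start=1):
        v = vecs[:, idx]
        resid = np.linalg.norm(L @ v - vals[idx] * deg * v) / np.linalg.norm(v)
        if resid > 1e-6:
            raise NumericalError(f"eigenpair residual {resid:.2e} for map {rank}")
        maps.append(Connectopy(values=_rescale01(v), eigenvalue=float(vals[idx]), rank=rank))
    # deterministic order within numerically tied eigenvalues
    for a in range(len(maps) - 1):
        if abs(maps[a].eigenvalue - maps[a + 1].eigenvalue) < 1e-10:
            if tuple(maps[a + 1].values) < tuple(maps[a].values):
                log.warning("laplacian_eigenmaps: tie-break swap of maps %d/%d", a + 1, a + 2)
                maps[a], maps[a + 1] = maps[a + 1], maps[a]
                maps[a].rank, maps[a + 1].rank = a + 1, a + 2
    return maps


def align_connectopy(c: Connectopy, reference: np.ndarray) -> Connectopy:
    """Fix the arbitrary gradient sign against a spatial reference.

    If the Pearson correlation with ``reference`` is negative the map is
    flipped (c → 1 − c); the [0, 1] scaling is preserved.
    """
    ref = np.asarray(reference, dtype=np.float64)
    if ref.shape != c.values.shape:
        raise DataError("reference and connectopy voxel orders differ in length")
    if ref.std() <= 0:
        raise DataError("zero-variance alignment reference")
    r = np.corrcoef(c.values, ref)[0, 1]
    if r < 0:
        return Connectopy(values=1.0 - c.values, eigenvalue=c.eigenvalue, rank=c.rank)
    return c


def average_connectopy(connectopies: list[Connectopy] | list[np.ndarray]) -> np.ndarray:
    """Voxelwise mean of subject connectopies, rescaled to [0, 1].

    All subjects must already be sign-aligned to a common reference; averaging
    unaligned maps cancels (c and 1−c average to a flat map).
    """
    arrs = [c.values if isinstance(c, Connectopy) else np.asarray(c, float) for c in connectopies]
    n_vox = {a.shape for a in arrs}
    if len(n_vox) != 1:
        raise DataError(f"voxel-order mismatch across subjects: shapes {sorted(n_vox)}")
    mean = np.mean(arrs, axis=0)
    lo, hi = mean.min(), mean.max()
    return (mean - lo) / (hi - lo) if hi > lo else mean


def subdivide_connectopy(c: Connectopy | np.ndarray, roi: Mask, cuts: tuple[float, ...] = (0.3, 0.7)) -> list[Mask]:
    """Partition the ROI by connectopy value into len(cuts)+1 parts.

    With the default cuts the intervals are [0, 0.3], (0.3, 0.7], (0.7, 1]
    (posterior, middle, anterior for a posteroanterior dominant gradient).
    Empty parts produce a warning and an all-false grid.
    """
    v = c.values if isinstance(c, Connectopy) else np.asarray(c, float)
    if v.min() < -1e-12 or v.max() > 1 + 1e-12:
        raise DataError("connectopy values must lie in [0, 1] for subdivision")
    if v.shape[0] != roi.n_voxels:
        raise DataError("connectopy length does not match ROI voxel count")
    edges = (-np.inf,) + tuple(cuts) + (np.inf,)
    idx = roi.indices()
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        member = (v > lo) & (v <= hi) if np.isfinite(lo) else (v <= hi)
        grid = np.zeros(roi.data.shape, dtype=bool)
        grid[tuple(idx[member].T)] = True
        if not member.any():
            log.warning("subdivide_connectopy: empty part (%s, %s]", lo, hi)
            out.append(_EmptyMask(grid, label=f"{roi.label}_part{len(out)}", affine=roi.affine))
        else:
            out.append(Mask(grid, label=f"{roi.label}_part{len(out)}", affine=roi.affine))
    return out


class _EmptyMask(Mask):
    """Mask variant allowed to be empty (degenerate subdivision)."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)


def seed_connectivity_probability(
    volumes: list[BoldVolume],
    brains: list[Mask] | Mask,
    subdivisions: list[Mask],
    z_thresh: float = 2.0,
) -> list[np.ndarray]:
    """Group probability maps of suprathreshold connectivity per subdivision.

    For each subject and subdivision: the Pearson correlation of the
    subdivision's mean time series with every brain voxel is Fisher
    z-transformed, standardized by its sampling sd 1/sqrt(T−3), thresholded at
    Z > ``z_thresh`` and binarized.  The probability map is the voxelwise mean
    of the binary maps over subjects.
    """
    if not volumes:
        raise DataError("need at least one subject volume")
    if isinstance(brains, Mask):
        brains = [brains] * len(volumes)
    maps: list[np.ndarray | None] = [None] * len(subdivisions)
    for vol, brain in zip(volumes, brains):
        T = vol.n_timepoints
        Y = vol.timeseries(brain)
        Yc = Y - Y.mean(axis=0)
        ysd = Yc.std(axis=0)
        for si, sub in enumerate(subdivisions):
            if not sub.data.any():
                log.warning("seed_connectivity_probability: skipping empty subdivision %d", si)
                continue
            seed = vol.timeseries(sub).mean(axis=1)
            seed = seed - seed.mean()
            ssd = seed.std()
            if ssd <= 0:
                continue
            r = (Yc.T @ seed) / (T * np.where(ysd > 0, ysd, 1.0) * ssd)
            r[ysd <= 0] = 0.0
            z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12)) * np.sqrt(max(T - 3, 1))
            binary = np.zeros(brain.data.shape)
            binary[brain.data] = (z > z_thresh).astype(float)
            maps[si] = binary if maps[si] is None else maps[si] + binary
    return [(m / len(volumes)) if m is not None else np.zeros(brains[0].data.shape) for m in maps]


def make_target_mask(brain: Mask, roi: Mask, dilate_ring: int = 1) -> Mask:
    """Target = brain minus the ROI and a dilation ring around it, avoiding
    self-correlation leakage into the fingerprints."""
    roi_d = scipy.ndimage.binary_dilation(roi.data, iterations=dilate_ring) if dilate_ring else roi.data
    target = brain.data & ~roi_d
    if not target.any():
        raise DataError("target mask empty after removing ROI and its dilation ring")
    return Mask(target, label="target", affine=brain.affine)


@dataclass
class ConnectopyResult:
    connectopies: list[Connectopy]
    n_components: int
    graph: VoxelGraph
    roi_coordinates: np.ndarray = field(repr=False)


def extract_connectopies(
    volume: BoldVolume,
    roi: Mask,
    brain: Mask,
    n_maps: int = 3,
    k: int | None = None,
    align_axis: int | None = 1,
    dilate_ring: int = 1,
    solver: str = "auto",
) -> ConnectopyResult:
    """End-to-end gradient extraction for one cleaned (standardized) subject.

    ``align_axis`` selects the world axis used for sign alignment (default 1,
    the posterior→anterior y axis); pass None to skip alignment.
    """
    target = make_target_mask(brain, roi, dilate_ring)
    X_roi = volume.timeseries(roi)
    X_roi, degenerate = _restandardize(X_roi)
    X_target = volume.timeseries(target)
    X_target = X_target - X_target.mean(axis=0)
    U, s = reduce_target(X_target)
    F = fingerprints(X_roi, U, s)
    S = eta2_matrix(F)
    graph = build_graph(S, k=k)
    maps = laplacian_eigenmaps(graph, n_maps=n_maps, solver=solver)
    coords = voxel_coordinates(roi, volume.affine)
    if align_axis is not None:
        maps = [align_connectopy(c, coords[:, align_axis]) for c in maps]
    return ConnectopyResult(connectopies=maps, n_components=U.shape[1], graph=graph, roi_coordinates=coords)


def _restandardize(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    from gradpain.preprocess import standardize

    return standardize(Y)
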