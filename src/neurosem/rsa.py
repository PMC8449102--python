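"""Representational similarity analysis with spatio-temporal searchlights.

The currency of RSA is the dissimilarity matrix (DSM): items x items,
symmetric, zero diagonal. Neural DSMs use 1 - Pearson r between the
spatial patterns inside a searchlight patch (all vertices within 2 cm in
the same hemisphere); model DSMs use 1 - Pearson r between embedding
vectors, or absolute score differences for a one-dimensional model.
Neural and model DSMs are compared by Spearman rank correlation of their
vectorized upper triangles. Group-level inference on the per-subject
vertex x time-bin correlation maps uses a cluster-based permutation test
with random sign flips: suprathreshold one-sample t values are grouped
into spatio-temporally connected clusters, the cluster statistic is the
sum of member t values, and the null is the distribution of the maximum
cluster statistic over sign-flip permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse import csgraph
from scipy.spatial import cKDTree

from .synthetic import SourceEstimateSet, VertexMesh

__all__ = [
    "DSM",
    "SearchlightPatches",
    "RsaMap",
    "Cluster",
    "ClusterSet",
    "dsm_correlation",
    "dsm_euclidean",
    "build_patches",
    "neural_dsms",
    "rsa_spearman",
    "rsa_partial",
    "searchlight_rsa",
    "cluster_permutation_test",
    "mantel_test",
]

_RANGE_TOL = 1e-10


@dataclass
class DSM:
    """Items x items dissimilarity matrix: symmetric, zero diagonal.

    Correlation-metric entries lie in [0, 2]; Euclidean-metric entries
    are non-negative. Invariants are asserted on construction.
    """

    values: np.ndarray
    metric: str = "correlation"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("DSM must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("DSM must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("DSM diagonal must be exactly zero")
        if self.metric == "correlation":
            if v.min() < -_RANGE_TOL or v.max() > 2 + _RANGE_TOL:
                raise ValueError("correlation-metric DSM entries must lie in [0, 2]")
        elif np.any(v < -_RANGE_TOL):
            raise ValueError("distance-metric DSM entries must be >= 0")
        self.values = np.clip(0.5 * (v + v.T), 0.0, None)
        np.fill_diagonal(self.values, 0.0)

    @property
    def n_items(self) -> int:
        return self.values.shape[0]

    def triangle(self) -> np.ndarray:
        """Vectorized upper triangle, diagonal excluded."""
        iu = np.triu_indices(self.n_items, k=1)
        return self.values[iu]


@dataclass
class SearchlightPatches:
    """Per-vertex member sets: same-hemisphere vertices within ``radius`` cm."""

    members: list[np.ndarray]
    radius: float

    @property
    def n_vertices(self) -> int:
        return len(self.members)


@dataclass
class RsaMap:
    """Per-subject vertex x bin Spearman correlation maps."""

    data: np.ndarray  # (subjects, vertices, bins)
    bin_centers: np.ndarray  # ms

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("RSA maps must be (subjects, vertices, bins)")
        finite = self.data[np.isfinite(self.data)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("correlation values must lie in [-1, 1]")


@dataclass
class Cluster:
    """A connected suprathreshold (vertex, bin) set with its summed t statistic."""

    vertices: np.ndarray
    bins: np.ndarray
    stat: float  # sum of member t-values
    p_value: float

    @property
    def size(self) -> int:
        return len(self.vertices)


@dataclass
class ClusterSet:
    """Clusters from a cluster-based sign-flip permutation test."""

    clusters: list[Cluster]
    t_threshold: float
    cluster_p: float
    alpha: float
    n_perm: int
    null_max: np.ndarray = field(repr=False, default=None)
    t_map: np.ndarray = field(repr=False, default=None)

    @property
    def retained(self) -> list[Cluster]:
        """Clusters surviving the cluster-wide significance threshold."""
        return [c for c in self.clusters if c.p_value <= self.alpha]


def _dsm_values(d) -> np.ndarray:
    return d.values if isinstance(d, DSM) else np.asarray(d, dtype=float)


def dsm_correlation(features: np.ndarray, items: list[str] | None = None) -> DSM:
    """DSM with entry (i, j) = 1 - Pearson r between feature rows i and j.

    Raises on a constant row (undefined correlation), naming the item.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("features must be items x k with k >= 2")
    sd = X.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [items[b] for b in bad] if items else list(bad)
        raise ValueError(f"constant feature rows make correlation undefined: {names}")
    r = np.clip(np.corrcoef(X), -1.0, 1.0)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return DSM(values=d, metric="correlation")


def dsm_euclidean(scores: np.ndarray) -> DSM:
    """DSM for a one-dimensional model: entry (i, j) = |score_i - score_j|."""
    s = np.asarray(scores, dtype=float).ravel()
    if s.size < 2:
        raise ValueError("need at least 2 items")
    d = np.abs(s[:, None] - s[None, :])
    return DSM(values=d, metric="euclidean")


def build_patches(mesh: VertexMesh, radius: float = 2.0) -> SearchlightPatches:
    """Searchlight patches: all same-hemisphere vertices within ``radius`` cm
    (Euclidean) of each vertex, the vertex itself included."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    members: list[np.ndarray] = [None] * mesh.n_vertices
    for hemi in ("L", "R"):
        idx = np.flatnonzero(mesh.hemispheres == hemi)
        if idx.size == 0:
            continue
        tree = cKDTree(mesh.coordinates[idx])
        balls = tree.query_ball_point(mesh.coordinates[idx], r=radius)
        for local, ball in zip(range(idx.size), balls):
            members[idx[local]] = np.sort(idx[np.asarray(ball, dtype=int)])
    return SearchlightPatches(members=members, radius=radius)


def neural_dsms(
    data: np.ndarray, patches: SearchlightPatches, bin: int,
    items: list[str] | None = None,
) -> list[DSM]:
    """Searchlight DSMs for one subject at one time bin.

    ``data`` is (items, vertices, bins); for each vertex, the item feature
    vector is the signal over the patch members at that bin and the DSM is
    1 - Pearson r between items. Singleton patches are rejected (a
    correlation needs at least two features): increase the radius.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("data must be (items, vertices, bins)")
    out = []
    for v, member in enumerate(patches.members):
        if len(member) < 2:
            raise ValueError(
                f"patch of vertex {v} has {len(member)} member(s); "
                "increase the searchlight radius"
            )
        out.append(dsm_correlation(data[:, member, bin], items=items))
    return out


def _triangle(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def rsa_spearman(neural_dsm, model_dsm) -> float:
    """Spearman rank correlation between the two DSMs' upper triangles."""
    a = _triangle(_dsm_values(neural_dsm))
    b = _triangle(_dsm_values(model_dsm))
    if a.shape != b.shape:
        raise ValueError("DSM item counts differ")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant DSM triangle makes Spearman undefined")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def rsa_partial(neural_dsm, model_dsm, covariate_dsm) -> float:
    """Partial Spearman correlation of neural vs. model DSM, controlling for
    a covariate DSM; computed on the ranks of the vectorized triangles."""
    x = stats.rankdata(_triangle(_dsm_values(neural_dsm)))
    y = stats.rankdata(_triangle(_dsm_values(model_dsm)))
    z = stats.rankdata(_triangle(_dsm_values(covariate_dsm)))
    if x.shape != y.shape or x.shape != z.shape:
        raise ValueError("DSM item counts differ")
    if np.ptp(x) == 0 or np.ptp(y) == 0 or np.ptp(z) == 0:
        raise ValueError("constant DSM triangle makes Spearman undefined")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    denom = (1 - r_xz**2) * (1 - r_yz**2)
    if denom <= 1e-12:
        raise ValueError("model and covariate DSMs are collinear with the data")
    return float((r_xy - r_xz * r_yz) / np.sqrt(denom))


def searchlight_rsa(
    source: SourceEstimateSet,
    patches: SearchlightPatches,
    model_dsm,
    bins: np.ndarray | None = None,
) -> RsaMap:
    """Per-subject searchlight RSA maps: Spearman correlation between each
    searchlight DSM and the model DSM at every vertex and time bin.

    The searchlight feature vector is the spatial pattern at the single bin
    under consideration. ``bins`` restricts the analysis to a subset of bin
    indices (default: all).
    """
    model_tri = _triangle(_dsm_values(model_dsm))
    if np.ptp(model_tri) == 0:
        raise ValueError("constant model DSM triangle makes Spearman undefined")
    model_rank = stats.rankdata(model_tri)
    mr = model_rank - model_rank.mean()
    mr_norm = np.linalg.norm(mr)

    n_subj, n_items, n_vert, n_bins = source.data.shape
    bin_idx = np.arange(n_bins) if bins is None else np.asarray(bins, dtype=int)
    iu = np.triu_indices(n_items, k=1)
    maps = np.empty((n_subj, n_vert, bin_idx.size))
    for v, member in enumerate(patches.members):
        if len(member) < 2:
            raise ValueError(
                f"patch of vertex {v} has {len(member)} member(s); "
                "increase the searchlight radius"
            )
        patch = source.data[:, :, member, :]  # (subj, items, |patch|, bins)
        for bi, b in enumerate(bin_idx):
            for s in range(n_subj):
                feats = patch[s, :, :, b]
                with np.errstate(invalid="ignore", divide="ignore"):
                    r = np.clip(np.corrcoef(feats), -1.0, 1.0)
                tri = (1.0 - r)[iu]
                nr = stats.rankdata(tri)
                nr -= nr.mean()
                denom = np.linalg.norm(nr) * mr_norm
                # constant neural pattern (e.g. zero signal in a noiseless
                # simulation): correlation undefined, marked NaN in the map
                maps[s, v, bi] = np.dot(nr, mr) / denom if denom else np.nan
    return RsaMap(data=maps, bin_centers=source.bin_centers[bin_idx])


def _spatio_temporal_adjacency(
    spatial: sparse.spmatrix, n_bins: int
) -> sparse.csr_matrix:
    """Element adjacency over (vertex, bin): mesh edges within a bin plus
    consecutive bins at the same vertex; no diagonal moves."""
    n_vert = spatial.shape[0]
    time_adj = sparse.diags([True] * (n_bins - 1), 1, shape=(n_bins, n_bins), dtype=bool)
    time_adj = (time_adj + time_adj.T).astype(bool)
    adj = sparse.kron(spatial.astype(bool), sparse.identity(n_bins, dtype=bool))
    adj = adj + sparse.kron(sparse.identity(n_vert, dtype=bool), time_adj)
    return adj.tocsr()


def _t_maps(flat: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """One-sample t maps for many sign-flip assignments at once.

    ``flat`` is (subjects, elements); ``flips`` is (n, subjects) of +/-1.
    Sums of squares are flip-invariant, so each row costs one matrix product.
    Elements with zero variance get t = 0.
    """
    n_subj = flat.shape[0]
    sumsq = np.einsum("se,se->e", flat, flat)
    means = flips @ flat / n_subj
    var = (sumsq[None, :] - n_subj * means**2) / (n_subj - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n_subj)
    t[~np.isfinite(t)] = 0.0
    return t


def _clusters_from_t(
    t: np.ndarray, threshold: float, adjacency: sparse.csr_matrix
) -> list[tuple[np.ndarray, float]]:
    """Connected suprathreshold element sets with their t sums (one-sided, positive)."""
    above = np.flatnonzero(t > threshold)
    if above.size == 0:
        return []
    sub = adjacency[above][:, above]
    n_comp, labels = csgraph.connected_components(sub, directed=False)
    out = []
    for c in range(n_comp):
        elems = above[labels == c]
        out.append((elems, float(t[elems].sum())))
    return out


def cluster_permutation_test(
    maps,
    adjacency,
    cluster_p: float = 0.01,
    alpha: float = 0.05,
    n_perm: int = 5000,
    seed: int | None = None,
) -> ClusterSet:
    """Group-level cluster-based permutation test with random sign flips.

    Per (vertex, bin) element a one-sample t over subjects is computed;
    elements with t above the one-sided ``cluster_p`` quantile of the t
    distribution are grouped into spatio-temporally connected clusters
    whose statistic is the sum of member t values. The null distribution
    of the maximum cluster statistic is built by flipping each subject's
    map sign independently ``n_perm`` times; each cluster's p-value is the
    add-one fraction of null maxima reaching its statistic, and clusters
    with p <= ``alpha`` are retained. Only positive clusters are formed
    (negative model-brain similarity is not interpreted).

    ``maps`` is an :class:`RsaMap` or an array (subjects, vertices, bins);
    ``adjacency`` is a :class:`~neurosem.synthetic.VertexMesh` or a sparse
    vertex adjacency matrix.
    """
    data = maps.data if isinstance(maps, RsaMap) else np.asarray(maps, dtype=float)
    if data.ndim != 3:
        raise ValueError("maps must be (subjects, vertices, bins)")
    n_subj, n_vert, n_bins = data.shape
    if n_subj < 2:
        raise ValueError("cluster permutation test needs >= 2 subjects")
    spatial = adjacency.adjacency if isinstance(adjacency, VertexMesh) else adjacency
    if spatial.shape[0] != n_vert:
        raise ValueError("adjacency size does not match vertex count")
    adj = _spatio_temporal_adjacency(spatial, n_bins)

    flat = data.reshape(n_subj, n_vert * n_bins)
    t_threshold = float(stats.t.ppf(1.0 - cluster_p, df=n_subj - 1))
    t_obs = _t_maps(flat, np.ones((1, n_subj)))[0]
    observed = _clusters_from_t(t_obs, t_threshold, adj)

    rng = np.random.default_rng(seed)
    flips = rng.integers(0, 2, size=(n_perm, n_subj)) * 2 - 1
    t_null = _t_maps(flat, flips)
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        comps = _clusters_from_t(t_null[p], t_threshold, adj)
        if comps:
            null_max[p] = max(stat for _, stat in comps)

    clusters = []
    for elems, stat in sorted(observed, key=lambda c: -c[1]):
        p_val = (1.0 + np.count_nonzero(null_max >= stat)) / (1.0 + n_perm)
        clusters.append(
            Cluster(
                vertices=elems // n_bins,
                bins=elems % n_bins,
                stat=stat,
                p_value=float(p_val),
            )
        )
    return ClusterSet(
        clusters=clusters,
        t_threshold=t_threshold,
        cluster_p=cluster_p,
        alpha=alpha,
        n_perm=n_perm,
        null_max=null_max,
        t_map=t_obs.reshape(n_vert, n_bins),
    )


def mantel_test(
    dsm_a, dsm_b, n_perm: int = 5000, seed: int | None = None
) -> tuple[float, float]:
    """Mantel test for association between two DSMs (Spearman variant).

    The observed statistic is the Spearman correlation of the vectorized
    upper triangles. The null jointly permutes rows and columns of the
    second DSM; since a joint permutation only reindexes the triangle
    entries, their ranks are computed once and gathered per permutation.
    The p-value is two-sided on |rho| with the add-one estimator.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a = _dsm_values(dsm_a)
    b = _dsm_values(dsm_b)
    if a.shape != b.shape:
        raise ValueError("DSM item counts differ")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    ra = stats.rankdata(a[iu])
    rb = stats.rankdata(b[iu])
    if np.ptp(ra) == 0 or np.ptp(rb) == 0:
        raise ValueError("constant DSM triangle makes Spearman undefined")
    rho = float(np.corrcoef(ra, rb)[0, 1])

    # symmetric matrix of the triangle ranks, for cheap joint permutation
    R = np.zeros((n, n))
    R[iu] = rb
    R = R + R.T
    ra_c = ra - ra.mean()
    rb_sd = rb.std()
    denom = ra_c.std() * rb_sd * ra.size
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    rb_mean = rb.mean()
    for p in range(n_perm):
        perm = rng.permutation(n)
        vec = R[np.ix_(perm, perm)][iu]
        null[p] = np.dot(ra_c, vec - rb_mean) / denom
    p_val = (1.0 + np.count_nonzero(np.abs(null) >= abs(rho) - 1e-12)) / (1.0 + n_perm)
    return rho, float(p_val)
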