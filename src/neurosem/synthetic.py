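"""Synthetic data with the statistical structure the decoding and RSA analyses assume.

The generators produce (a) a word-embedding space with two Gaussian category
clusters (abstract vs. concrete), (b) a two-hemisphere vertex mesh on
head-sized spherical caps, (c) per-subject source estimates in which a
restricted set of vertices linearly encodes the embedding dimensions inside
a restricted time window, (d) sensor-level evoked responses obtained through
a distance-attenuated random leadfield, and (e) behavioural
category-typicality ratings on a 1-7 scale.

Design of the encoding model: signal at active vertex ``v``, time bin ``t``,
word ``w`` is ``profile[t] * sum_k W[v, k] * E[w, k]`` with encoding weights
``W`` shared across subjects and independent Gaussian noise per subject, so
that group-level statistics accumulate over subjects. A single scalar snr
(signal s.d. / noise s.d. within the active vertices and bins) controls
difficulty; ``snr=0`` yields pure noise and ``snr=inf`` noiseless data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .semantic import EmbeddingTable

__all__ = [
    "SyntheticConfig",
    "VertexMesh",
    "GroundTruth",
    "SourceEstimateSet",
    "EvokedSet",
    "gen_embedding_table",
    "gen_vertex_mesh",
    "default_active_vertices",
    "simulate_source_estimates",
    "simulate_sensor_evoked",
    "gen_ratings",
]

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))

# substream offsets so each generator draws from an independent stream
_STREAM_EMBED = 1
_STREAM_SOURCE = 2
_STREAM_SENSOR = 3
_STREAM_RATINGS = 4


@dataclass(frozen=True)
class SyntheticConfig:
    """Design constants of the simulated experiment.

    Defaults follow the emulated study: 118 nouns split 59/59 into
    abstract/concrete categories, 300-dimensional embeddings, 20 subjects,
    204 gradiometer channels, 2,562 source vertices per hemisphere, 1 kHz
    sampling, 0-800 ms epochs at 20-ms bins.

    Parameters
    ----------
    cluster_separation : float
        Distance between the two category centroids in embedding space, in
        units of the within-cluster standard deviation.
    snr : float
        Ratio of signal s.d. to noise s.d. within the active vertices and
        time bins. May be ``0`` (pure noise) or ``np.inf`` (noiseless).
    active_vertices : tuple of int, optional
        Vertex ids carrying signal; when ``None`` a contiguous 2-cm patch
        in the left hemisphere is chosen at simulation time.
    active_window : (float, float)
        Time window (ms) carrying signal; must lie inside ``epoch_window``.
    """

    n_words: int = 118
    n_abstract: int = 59
    embed_dim: int = 300
    cluster_separation: float = 5.0
    n_subjects: int = 20
    n_channels: int = 204
    n_vertices_per_hemisphere: int = 2562
    sfreq: float = 1000.0
    epoch_window: tuple[float, float] = (0.0, 800.0)
    bin_width: float = 20.0
    active_vertices: tuple[int, ...] | None = None
    active_window: tuple[float, float] = (300.0, 400.0)
    snr: float = 1.0
    head_radius_cm: float = 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_words": self.n_words,
            "n_abstract": self.n_abstract,
            "embed_dim": self.embed_dim,
            "n_subjects": self.n_subjects,
            "n_channels": self.n_channels,
            "n_vertices_per_hemisphere": self.n_vertices_per_hemisphere,
        }
        problems = [f"{k} must be > 0, got {v}" for k, v in counts.items() if v <= 0]
        if self.n_abstract > self.n_words:
            problems.append(
                f"n_abstract ({self.n_abstract}) exceeds n_words ({self.n_words})"
            )
        if self.cluster_separation < 0:
            problems.append(f"cluster_separation must be >= 0, got {self.cluster_separation}")
        if not (self.snr >= 0):  # also catches NaN
            problems.append(f"snr must be >= 0, got {self.snr}")
        if self.sfreq <= 0:
            problems.append(f"sfreq must be > 0, got {self.sfreq}")
        if self.bin_width <= 0:
            problems.append(f"bin_width must be > 0, got {self.bin_width}")
        t0, t1 = self.epoch_window
        a0, a1 = self.active_window
        if not t0 < t1:
            problems.append(f"epoch_window must be increasing, got {self.epoch_window}")
        if not (t0 <= a0 < a1 <= t1):
            problems.append(
                f"active_window {self.active_window} not inside epoch_window {self.epoch_window}"
            )
        if self.head_radius_cm <= 0:
            problems.append(f"head_radius_cm must be > 0, got {self.head_radius_cm}")
        if self.active_vertices is not None:
            n_vert = 2 * self.n_vertices_per_hemisphere
            bad = [v for v in self.active_vertices if not 0 <= v < n_vert]
            if bad:
                problems.append(f"active_vertices outside mesh range [0, {n_vert}): {bad}")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))

    @property
    def n_bins(self) -> int:
        t0, t1 = self.epoch_window
        return int(math.floor((t1 - t0) / self.bin_width))

    def bin_centers(self) -> np.ndarray:
        t0 = self.epoch_window[0]
        return t0 + self.bin_width * (np.arange(self.n_bins) + 0.5)


@dataclass
class VertexMesh:
    """Source-space vertices on two hemispheric spherical caps.

    ``coordinates`` are in cm, with the mid-sagittal plane at x = 0
    (x < 0 left hemisphere, x > 0 right). ``adjacency`` is a symmetric,
    irreflexive boolean sparse matrix over all vertices; edges never cross
    hemispheres.
    """

    coordinates: np.ndarray
    hemispheres: np.ndarray  # 'L' / 'R' per vertex
    adjacency: sparse.csr_matrix

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.hemispheres = np.asarray(self.hemispheres)
        n = self.coordinates.shape[0]
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("mesh coordinates must be finite")
        if self.hemispheres.shape != (n,):
            raise ValueError("one hemisphere label per vertex required")
        if not set(np.unique(self.hemispheres)) <= {"L", "R"}:
            raise ValueError("hemisphere labels must be 'L' or 'R'")
        adj = sparse.csr_matrix(self.adjacency).astype(bool)
        if adj.shape != (n, n):
            raise ValueError("adjacency shape must be (n_vertices, n_vertices)")
        if (adj != adj.T).nnz:
            raise ValueError("adjacency must be symmetric")
        if adj.diagonal().any():
            raise ValueError("adjacency must be irreflexive")
        self.adjacency = adj

    @property
    def n_vertices(self) -> int:
        return self.coordinates.shape[0]

    @property
    def vertex_ids(self) -> np.ndarray:
        return np.arange(self.n_vertices)


@dataclass
class GroundTruth:
    """The forward model a simulation was generated from.

    ``encoding_weights`` rows are nonzero only on the active vertices;
    ``temporal_profile`` is zero outside the active window.
    """

    encoding_weights: np.ndarray  # (n_vertices, embed_dim)
    temporal_profile: np.ndarray  # (n_bins,)
    leadfield: np.ndarray  # (n_channels, n_vertices)
    active_vertices: np.ndarray  # sorted vertex ids

    def __post_init__(self) -> None:
        inactive = np.setdiff1d(
            np.arange(self.encoding_weights.shape[0]), self.active_vertices
        )
        if np.any(self.encoding_weights[inactive] != 0):
            raise ValueError("encoding weights nonzero on inactive vertices")


@dataclass
class SourceEstimateSet:
    """Per-subject source estimates: (subjects, words, vertices, bins)."""

    data: np.ndarray
    bin_centers: np.ndarray  # ms
    words: list[str]
    bin_width: float  # ms

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("source data must be (subjects, words, vertices, bins)")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]


@dataclass
class EvokedSet:
    """Per-subject sensor-level evoked responses: (subjects, words, channels, samples)."""

    data: np.ndarray
    times: np.ndarray  # ms
    sfreq: float
    words: list[str]

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("evoked data must be (subjects, words, channels, samples)")
        if self.data.shape[3] != len(self.times):
            raise ValueError("time axis length mismatch")


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def gen_embedding_table(config: SyntheticConfig) -> EmbeddingTable:
    """Draw word vectors from two isotropic Gaussian category clusters.

    The abstract and concrete centroids are separated by
    ``cluster_separation`` along a random direction, with unit within-cluster
    standard deviation per dimension; deterministic given ``config.seed``.
    """
    if config.embed_dim < 2:
        raise ValueError("embed_dim must be >= 2 for a clustered embedding space")
    rng = _rng(config, _STREAM_EMBED)
    direction = rng.standard_normal(config.embed_dim)
    direction /= np.linalg.norm(direction)
    offset = 0.5 * config.cluster_separation * direction
    n_abs = config.n_abstract
    n_con = config.n_words - n_abs
    vectors = rng.standard_normal((config.n_words, config.embed_dim))
    vectors[:n_abs] += offset
    vectors[n_abs:] -= offset
    words = [f"abstract_{i:03d}" for i in range(n_abs)] + [
        f"concrete_{i:03d}" for i in range(n_con)
    ]
    categories = ["abstract"] * n_abs + ["concrete"] * n_con
    return EmbeddingTable(words=words, vectors=vectors, categories=categories)


def _cap_points(n: int, radius: float) -> np.ndarray:
    """Quasi-uniform Fibonacci-spiral points on a half-sphere cap (axis +x)."""
    i = np.arange(n)
    # cos(angle from axis) uniform over (0, 1]: covers exactly one hemisphere
    c = 1.0 - (i + 0.5) / n
    s = np.sqrt(1.0 - c**2)
    phi = i * _GOLDEN_ANGLE
    return radius * np.column_stack([c, s * np.cos(phi), s * np.sin(phi)])


def gen_vertex_mesh(config: SyntheticConfig, k_neighbors: int = 6) -> VertexMesh:
    """Place vertices quasi-uniformly on two hemispheric spherical caps.

    The left hemisphere occupies x < 0 and is the exact mirror image of the
    right about the mid-sagittal plane. Adjacency links each vertex to its
    ``k_neighbors`` nearest same-hemisphere neighbours (symmetrized).
    """
    n = config.n_vertices_per_hemisphere
    if n < 4:
        raise ValueError("n_vertices_per_hemisphere must be >= 4")
    right = _cap_points(n, config.head_radius_cm)
    left = right * np.array([-1.0, 1.0, 1.0])
    coords = np.vstack([left, right])
    hemis = np.array(["L"] * n + ["R"] * n)

    k = min(k_neighbors, n - 1)
    rows, cols = [], []
    for start in (0, n):
        block = coords[start : start + n]
        tree = cKDTree(block)
        _, idx = tree.query(block, k=k + 1)  # first neighbour is the point itself
        for i in range(n):
            for j in idx[i, 1:]:
                rows.append(start + i)
                cols.append(start + int(j))
    adj = sparse.coo_matrix(
        (np.ones(len(rows), dtype=bool), (rows, cols)), shape=(2 * n, 2 * n)
    ).tocsr()
    adj = (adj + adj.T).astype(bool)
    adj.setdiag(False)
    adj.eliminate_zeros()
    return VertexMesh(coordinates=coords, hemispheres=hemis, adjacency=adj)


def default_active_vertices(
    mesh: VertexMesh, radius_cm: float = 2.0, min_vertices: int = 5
) -> np.ndarray:
    """A contiguous left-hemisphere patch: all vertices within ``radius_cm``
    of the left vertex nearest the left-hemisphere centroid, extended to the
    ``min_vertices`` nearest vertices on meshes coarser than the radius."""
    left = np.flatnonzero(mesh.hemispheres == "L")
    centroid = mesh.coordinates[left].mean(axis=0)
    seed_vtx = left[np.argmin(np.linalg.norm(mesh.coordinates[left] - centroid, axis=1))]
    dists = np.linalg.norm(mesh.coordinates[left] - mesh.coordinates[seed_vtx], axis=1)
    in_ball = dists <= radius_cm
    if in_ball.sum() < min(min_vertices, left.size):
        k = min(min_vertices, left.size)
        in_ball = np.zeros_like(in_ball)
        in_ball[np.argsort(dists)[:k]] = True
    return np.sort(left[in_ball])


def _active_bin_mask(config: SyntheticConfig) -> np.ndarray:
    centers = config.bin_centers()
    a0, a1 = config.active_window
    return (centers >= a0) & (centers < a1)


def _sensor_positions(n_channels: int, radius: float) -> np.ndarray:
    """Quasi-uniform sensor helmet positions on a sphere outside the head."""
    i = np.arange(n_channels)
    c = 1.0 - 2.0 * (i + 0.5) / n_channels
    s = np.sqrt(1.0 - c**2)
    phi = i * _GOLDEN_ANGLE
    return radius * np.column_stack([s * np.cos(phi), s * np.sin(phi), c])


def simulate_source_estimates(
    embeddings: EmbeddingTable, mesh: VertexMesh, config: SyntheticConfig
) -> tuple[SourceEstimateSet, GroundTruth]:
    """Simulate per-subject source estimates under a linear encoding model.

    Signal at active vertex v, bin t, word w equals
    ``profile[t] * (W @ e_w)[v]`` with Gaussian encoding weights shared
    across subjects, scaled so the signal s.d. over the active
    vertices/bins/words equals ``config.snr`` against unit-s.d. noise that
    is independent across subjects and everywhere in the array.
    ``snr=inf`` gives noiseless data with unit signal s.d.
    """
    if embeddings.n_words != config.n_words:
        raise ValueError(
            f"embedding table has {embeddings.n_words} words, config says {config.n_words}"
        )
    rng = _rng(config, _STREAM_SOURCE)
    n_vert = mesh.n_vertices
    n_bins = config.n_bins

    if config.active_vertices is not None:
        active = np.sort(np.asarray(config.active_vertices, dtype=int))
        if active.size and active[-1] >= n_vert:
            raise ValueError("active_vertices outside mesh")
    else:
        active = default_active_vertices(mesh)

    profile = _active_bin_mask(config).astype(float)
    weights = np.zeros((n_vert, embeddings.dim))
    weights[active] = rng.standard_normal((active.size, embeddings.dim))

    # clean signal (words, vertices, bins), then scale to the requested snr
    clean = np.einsum("wk,vk,b->wvb", embeddings.vectors, weights, profile)
    active_sd = clean[:, active][:, :, profile > 0].std()
    if active_sd > 0:
        if np.isinf(config.snr):
            scale, noise_sd = 1.0 / active_sd, 0.0
        else:
            scale, noise_sd = config.snr / active_sd, 1.0
    else:  # no signal possible (snr handling still defines the noise floor)
        scale, noise_sd = 0.0, 0.0 if np.isinf(config.snr) else 1.0
    clean *= scale
    weights *= scale

    data = np.empty((config.n_subjects, config.n_words, n_vert, n_bins))
    for s in range(config.n_subjects):
        noise = rng.standard_normal((config.n_words, n_vert, n_bins)) if noise_sd else 0.0
        data[s] = clean + noise_sd * noise

    # leadfield: random gains attenuated with sensor-vertex distance
    sensors = _sensor_positions(config.n_channels, 1.2 * config.head_radius_cm)
    dists = np.linalg.norm(
        sensors[:, None, :] - mesh.coordinates[None, :, :], axis=2
    )
    lf_rng = _rng(config, _STREAM_SENSOR)
    leadfield = lf_rng.standard_normal((config.n_channels, n_vert)) * np.exp(
        -dists / 4.0
    )

    truth = GroundTruth(
        encoding_weights=weights,
        temporal_profile=profile,
        leadfield=leadfield,
        active_vertices=active,
    )
    source = SourceEstimateSet(
        data=data,
        bin_centers=config.bin_centers(),
        words=list(embeddings.words),
        bin_width=config.bin_width,
    )
    return source, truth


def simulate_sensor_evoked(
    source: SourceEstimateSet, truth: GroundTruth, config: SyntheticConfig
) -> EvokedSet:
    """Project source activity to sensors and upsample to ``sfreq``.

    Channel data is ``leadfield @ source`` per bin, expanded to samples by
    zero-order hold, plus independent sensor noise whose s.d. is set from
    the projected signal s.d. in the active window and ``config.snr``
    (``snr=inf`` adds none).
    """
    n_chan, n_vert = truth.leadfield.shape
    if n_vert != source.data.shape[2]:
        raise ValueError(
            f"leadfield has {n_vert} vertex columns, source has {source.data.shape[2]}"
        )
    rng = _rng(config, _STREAM_SENSOR + 100)
    projected = np.einsum("cv,swvb->swcb", truth.leadfield, source.data)

    active_bins = truth.temporal_profile > 0
    proj_sd = projected[..., active_bins].std() if active_bins.any() else projected.std()
    if np.isinf(config.snr):
        noise_sd = 0.0
    elif config.snr > 0:
        noise_sd = proj_sd / config.snr
    else:
        noise_sd = proj_sd if proj_sd > 0 else 1.0

    samples_per_bin = max(1, int(round(config.bin_width * config.sfreq / 1000.0)))
    sensor = np.repeat(projected, samples_per_bin, axis=3)
    if noise_sd:
        sensor = sensor + noise_sd * rng.standard_normal(sensor.shape)
    t0 = config.epoch_window[0]
    times = t0 + 1000.0 * np.arange(sensor.shape[3]) / config.sfreq
    return EvokedSet(data=sensor, times=times, sfreq=config.sfreq, words=list(source.words))


def gen_ratings(
    embeddings: EmbeddingTable,
    n_respondents: int = 10,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate category-typicality ratings on the behavioural 1-7 scale.

    Each respondent rates every word on every category: near 7 for the
    word's true category, near 1 otherwise, jittered by Gaussian noise of
    s.d. ``noise_sd`` and clipped to [1, 7]. Returns a long-format table
    with columns ``respondent``, ``word``, ``category``, ``rating``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if embeddings.categories is None:
        raise ValueError("embedding table carries no category labels")
    rng = np.random.default_rng(np.random.SeedSequence((seed, _STREAM_RATINGS)))
    categories = list(dict.fromkeys(embeddings.categories))
    rows = []
    for r in range(n_respondents):
        for word, true_cat in zip(embeddings.words, embeddings.categories):
            for cat in categories:
                base = 7.0 if cat == true_cat else 1.0
                rating = float(np.clip(base + noise_sd * rng.standard_normal(), 1.0, 7.0))
                rows.append((r, word, cat, rating))
    return pd.DataFrame(rows, columns=["respondent", "word", "category", "rating"])
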