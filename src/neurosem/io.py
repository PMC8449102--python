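"""HDF5 containers for evoked/source arrays and CSV I/O for ratings.

One container layout serves both array types: datasets ``data``, a time
axis and ``words`` labels, with ``sfreq``/``bin_width``, ``seed`` and a
JSON-encoded config string as attributes. Meshes ride along with source
sets (coordinates, hemisphere labels, adjacency edge list).
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd
from scipy import sparse

from .synthetic import EvokedSet, SourceEstimateSet, VertexMesh

__all__ = [
    "save_evoked_set",
    "load_evoked_set",
    "save_source_set",
    "load_source_set",
    "save_ratings",
    "load_ratings",
]

_STR = h5py.string_dtype(encoding="utf-8")


def _write_common(g, words, attrs: dict) -> None:
    g.create_dataset("words", data=np.array(words, dtype=_STR))
    for key, value in attrs.items():
        if value is not None:
            g.attrs[key] = value


def save_evoked_set(path, evoked: EvokedSet, config_json: str | None = None,
                    seed: int | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=evoked.data)
        f.create_dataset("times", data=evoked.times)
        _write_common(
            f, evoked.words,
            {"sfreq": evoked.sfreq, "kind": "evoked", "config": config_json, "seed": seed},
        )


def load_evoked_set(path) -> EvokedSet:
    with h5py.File(path, "r") as f:
        return EvokedSet(
            data=f["data"][()],
            times=f["times"][()],
            sfreq=float(f.attrs["sfreq"]),
            words=[w.decode() if isinstance(w, bytes) else w for w in f["words"][()]],
        )


def _write_mesh(g, mesh: VertexMesh) -> None:
    g.create_dataset("coordinates", data=mesh.coordinates)
    g.create_dataset("hemispheres", data=np.array(mesh.hemispheres, dtype=_STR))
    edges = np.column_stack(sparse.triu(mesh.adjacency, k=1).nonzero())
    g.create_dataset("edges", data=edges)


def _read_mesh(g) -> VertexMesh:
    coords = g["coordinates"][()]
    hemis = np.array(
        [h.decode() if isinstance(h, bytes) else h for h in g["hemispheres"][()]]
    )
    edges = g["edges"][()]
    n = coords.shape[0]
    adj = sparse.coo_matrix(
        (np.ones(len(edges), dtype=bool), (edges[:, 0], edges[:, 1])), shape=(n, n)
    )
    adj = (adj + adj.T).astype(bool).tocsr()
    return VertexMesh(coordinates=coords, hemispheres=hemis, adjacency=adj)


def save_source_set(path, source: SourceEstimateSet, mesh: VertexMesh | None = None,
                    config_json: str | None = None, seed: int | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=source.data)
        f.create_dataset("bin_centers", data=source.bin_centers)
        _write_common(
            f, source.words,
            {"bin_width": source.bin_width, "kind": "source", "config": config_json,
             "seed": seed},
        )
        if mesh is not None:
            _write_mesh(f.create_group("mesh"), mesh)


def load_source_set(path) -> tuple[SourceEstimateSet, VertexMesh | None]:
    with h5py.File(path, "r") as f:
        source = SourceEstimateSet(
            data=f["data"][()],
            bin_centers=f["bin_centers"][()],
            words=[w.decode() if isinstance(w, bytes) else w for w in f["words"][()]],
            bin_width=float(f.attrs["bin_width"]),
        )
        mesh = _read_mesh(f["mesh"]) if "mesh" in f else None
    return source, mesh


def save_ratings(path, ratings: pd.DataFrame) -> None:
    ratings.to_csv(path, index=False)


def load_ratings(path) -> pd.DataFrame:
    ratings = pd.read_csv(path)
    required = {"respondent", "word", "category", "rating"}
    missing = required - set(ratings.columns)
    if missing:
        raise ValueError(f"ratings CSV missing columns: {sorted(missing)}")
    return ratings
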