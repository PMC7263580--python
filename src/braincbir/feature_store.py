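"""PCA compression of raw descriptors and the persistent feature database.

The raw 4096-dim descriptor is redundant for retrieval, so it is projected
onto the top principal directions of the training descriptors: the sample
covariance's eigenvectors, obtained via SVD of the mean-centered data
matrix.  A descriptor x maps to y = U (x - mean) with U the k x 4096 matrix
of leading eigenvectors (default k = 1024).  Because U has orthonormal rows
the projection never increases Euclidean distances, so reduced-space
retrieval is a contraction of raw-space retrieval.

The database itself is a single HDF5 file holding one float32 vector matrix,
the image ids and labels, the fitted PCA transform, and a JSON metadata
attribute (schema version, dimensions, config digest).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .nn.network import DescriptorVector, MultiScaleNet, extract_descriptors

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

__all__ = [
    "PCAModel",
    "ReducedDescriptor",
    "FeatureDatabase",
    "fit_pca",
    "reduce",
    "reconstruct",
    "build_database",
]


@dataclass
class PCAModel:
    """Mean vector plus the top-k orthonormal principal directions
    (rows of ``components``) and their explained variances (descending)."""

    mean: np.ndarray
    components: np.ndarray  # (k, original_dim)
    explained_variance: np.ndarray

    @property
    def k(self) -> int:
        return self.components.shape[0]

    @property
    def original_dim(self) -> int:
        return self.components.shape[1]


@dataclass
class ReducedDescriptor:
    values: np.ndarray
    image_id: str = ""


def _as_matrix(descriptors) -> tuple[np.ndarray, list[str]]:
    vecs, ids = [], []
    for d in descriptors:
        if isinstance(d, (DescriptorVector, ReducedDescriptor)):
            vecs.append(np.asarray(d.values, dtype=np.float64))
            ids.append(d.image_id)
        else:
            vecs.append(np.asarray(d, dtype=np.float64))
            ids.append("")
    return np.stack(vecs), ids


def fit_pca(descriptors, k: int = 1024) -> PCAModel:
    """Fit PCA by SVD of the mean-centered descriptor matrix.

    ``components`` are the top-k right singular vectors, i.e. the leading
    eigenvectors of the sample covariance.  If ``k`` exceeds the numerical
    rank of the data it is clipped with a warning.  Each component's sign is
    fixed so its largest-magnitude entry is positive, making the fit
    byte-reproducible despite the inherent SVD sign ambiguity.
    """
    x, _ = _as_matrix(descriptors)
    n, d = x.shape
    if n < 2:
        raise ValueError("fit_pca requires at least 2 descriptors")
    if k < 1:
        raise ValueError("k must be >= 1")
    mean = x.mean(axis=0)
    xc = x - mean
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    tol = s.max(initial=0.0) * max(n, d) * np.finfo(np.float64).eps
    rank = int((s > tol).sum())
    if rank == 0:
        raise ValueError("degenerate input: all descriptors are identical")
    k_eff = min(k, rank)
    if k_eff < k:
        warnings.warn(
            f"requested k={k} exceeds data rank {rank}; clipping to {k_eff}",
            RuntimeWarning,
            stacklevel=2,
        )
        logger.warning("PCA k clipped from %d to data rank %d", k, k_eff)
    components = vt[:k_eff].copy()
    # sign convention: largest-|.| element of each component positive
    flip = components[np.arange(k_eff), np.abs(components).argmax(axis=1)] < 0
    components[flip] *= -1.0
    explained = (s[:k_eff] ** 2) / (n - 1)
    return PCAModel(mean=mean, components=components, explained_variance=explained)


def reduce(pca: PCAModel, d: DescriptorVector | np.ndarray) -> ReducedDescriptor:
    """Project a raw descriptor to the reduced space: y = U (x - mean)."""
    if isinstance(d, DescriptorVector):
        x, image_id = np.asarray(d.values, dtype=np.float64), d.image_id
    else:
        x, image_id = np.asarray(d, dtype=np.float64), ""
    if x.shape != (pca.original_dim,):
        raise ValueError(
            f"descriptor length {x.shape} does not match PCA input dim "
            f"{pca.original_dim}"
        )
    return ReducedDescriptor(
        values=pca.components @ (x - pca.mean), image_id=image_id
    )


def reconstruct(pca: PCAModel, r: ReducedDescriptor | np.ndarray) -> np.ndarray:
    """Back-project a reduced vector: x_hat = U^T y + mean."""
    y = r.values if isinstance(r, ReducedDescriptor) else np.asarray(r)
    return pca.components.T @ y + pca.mean


@dataclass
class FeatureDatabase:
    """Ordered (id, label, vector) records plus the PCA transform used to
    produce them (``pca`` is None for a raw 4096-dim database)."""

    ids: list[str]
    labels: np.ndarray
    vectors: np.ndarray  # (n_records, dim) float32
    pca: PCAModel | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate image ids in database")
        if self.vectors.shape[0] != len(self.ids) or len(self.labels) != len(self.ids):
            raise ValueError("ids, labels and vectors must agree in length")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def content_digest(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.vectors).tobytes())
        h.update(np.ascontiguousarray(self.labels).tobytes())
        h.update("\x00".join(self.ids).encode())
        return h.hexdigest()

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w") as f:
            f.create_dataset("vectors", data=self.vectors.astype(np.float32))
            f.create_dataset(
                "ids", data=np.array(self.ids, dtype=h5py.string_dtype())
            )
            f.create_dataset("labels", data=self.labels.astype(np.int64))
            if self.pca is not None:
                g = f.create_group("pca")
                g.create_dataset("mean", data=self.pca.mean)
                g.create_dataset("components", data=self.pca.components)
                g.create_dataset(
                    "explained_variance", data=self.pca.explained_variance
                )
            f.attrs["metadata"] = json.dumps(
                {"schema_version": SCHEMA_VERSION, **self.metadata}
            )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FeatureDatabase":
        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["metadata"])
            if meta.get("schema_version") != SCHEMA_VERSION:
                raise ValueError(
                    f"unsupported database schema {meta.get('schema_version')!r}"
                )
            pca = None
            if "pca" in f:
                pca = PCAModel(
                    mean=f["pca/mean"][...],
                    components=f["pca/components"][...],
                    explained_variance=f["pca/explained_variance"][...],
                )
            return cls(
                ids=[s.decode() if isinstance(s, bytes) else s for s in f["ids"][...]],
                labels=f["labels"][...],
                vectors=f["vectors"][...],
                pca=pca,
                metadata={k: v for k, v in meta.items() if k != "schema_version"},
            )


def build_database(
    network: MultiScaleNet,
    pca: PCAModel | None,
    images,
    out_path: str | Path | None = None,
    *,
    metadata: dict | None = None,
) -> FeatureDatabase:
    """Extract descriptors for every image, reduce them (unless ``pca`` is
    None), and assemble (and optionally persist) the feature database."""
    images = list(images)
    descriptors = extract_descriptors(network, images)
    if pca is not None:
        vectors = np.stack(
            [reduce(pca, d).values for d in descriptors]
        ).astype(np.float32)
    else:
        vectors = np.stack([d.values for d in descriptors]).astype(np.float32)
    db = FeatureDatabase(
        ids=[im.id for im in images],
        labels=np.array([im.label for im in images], dtype=np.int64),
        vectors=vectors,
        pca=pca,
        metadata={
            "feature_dim": network.cfg.feature_dim,
            "k": vectors.shape[1],
            **(metadata or {}),
        },
    )
    if out_path is not None:
        db.save(out_path)
    return db
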