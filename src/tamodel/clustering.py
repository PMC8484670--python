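"""Clustering of fitted kinetic-parameter vectors (PCA + DBSCAN).

Each TA pair's fitted full-model parameter vector (10 constants) is treated
as a feature vector characterising the pair.  Since kinetic constants
spread over orders of magnitude, the default preprocessing takes log10 of
strictly positive columns and then standardises every column (zero mean,
unit population variance) before projecting onto the first two principal
components.  DBSCAN on the 2-D scores (Euclidean metric, default
eps = 0.8, min_samples = 3) separates a dense central cluster from
low-density outliers; the number of clusters is decided by the algorithm,
not preset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA

from .fitting import FitResult
from .model import FULL_PARAM_NAMES

__all__ = [
    "ParameterMatrix",
    "Embedding",
    "ClusterAssignment",
    "build_matrix",
    "pca_embed",
    "dbscan_cluster",
    "cluster_report",
    "NOISE_LABEL",
]

NOISE_LABEL = -1  # DBSCAN's conventional label for outliers/noise


@dataclass(frozen=True)
class ParameterMatrix:
    """Pairs x parameters feature matrix after preprocessing."""

    pair_labels: tuple[str, ...]
    param_names: tuple[str, ...]
    values: np.ndarray
    preprocessing: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.pair_labels),
                            columns=list(self.param_names))


@dataclass(frozen=True)
class Embedding:
    """Per-pair scores on the leading principal components."""

    pair_labels: tuple[str, ...]
    coordinates: np.ndarray            # shape (n_pairs, n_components)
    explained_variance_ratio: np.ndarray

    @property
    def pc1(self) -> np.ndarray:
        return self.coordinates[:, 0]

    @property
    def pc2(self) -> np.ndarray:
        return self.coordinates[:, 1]


@dataclass(frozen=True)
class ClusterAssignment:
    """DBSCAN labels per pair; ``NOISE_LABEL`` marks outliers."""

    pair_labels: tuple[str, ...]
    labels: np.ndarray
    eps: float
    min_samples: int

    def as_dict(self) -> dict[str, int]:
        return {p: int(l) for p, l in zip(self.pair_labels, self.labels)}


def build_matrix(
    fit_results_full: Iterable[FitResult],
    preprocessing: str = "log10_standardize",
) -> ParameterMatrix:
    """Assemble the pairs x 10 feature matrix from full-model fits.

    ``log10_standardize`` (default): log10 of strictly positive columns —
    zeros in a non-negative column are offset by 1e-3 times the column's
    smallest positive value — then each column is centred and scaled to
    unit population variance.  ``standardize`` skips the log.  A constant
    column cannot be scaled and raises, naming the column.
    """
    fits = sorted(fit_results_full, key=lambda f: f.pair_label)
    if not fits:
        raise ValueError("no full-model fit results supplied")
    for f in fits:
        if f.variant_name != "full":
            raise ValueError(
                f"build_matrix expects full-model fits only; pair {f.pair_label!r} "
                f"carries variant {f.variant_name!r}"
            )
    labels = tuple(f.pair_label for f in fits)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate pair labels in fit results")
    raw = np.array([[getattr(f.params, n) for n in FULL_PARAM_NAMES] for f in fits])

    if preprocessing not in ("standardize", "log10_standardize"):
        raise ValueError(f"unknown preprocessing {preprocessing!r}")
    values = raw.copy()
    if preprocessing == "log10_standardize":
        for j, name in enumerate(FULL_PARAM_NAMES):
            col = values[:, j]
            pos = col[col > 0]
            if pos.size == 0:
                # an all-zero column stays linear; standardisation below
                # will reject it as constant
                continue
            offset = pos.min() * 1e-3
            values[:, j] = np.log10(np.where(col > 0, col, offset))
    mean = values.mean(axis=0)
    std = values.std(axis=0)  # population scaling (ddof=0)
    bad = [FULL_PARAM_NAMES[j] for j in np.nonzero(std == 0)[0]]
    if bad:
        raise ValueError(
            "cannot standardise constant parameter column(s): " + ", ".join(bad)
        )
    values = (values - mean) / std
    return ParameterMatrix(labels, FULL_PARAM_NAMES, values, preprocessing)


def pca_embed(matrix: ParameterMatrix, n_components: int = 2) -> Embedding:
    """Project the feature matrix onto its leading principal components.

    Component signs follow the convention that each axis's largest-
    magnitude loading is positive, so embeddings are reproducible across
    library versions.
    """
    X = matrix.values
    if X.shape[0] < n_components:
        raise ValueError(
            f"need at least {n_components} rows for {n_components} components, "
            f"got {X.shape[0]}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    for k in range(n_components):
        j = int(np.argmax(np.abs(pca.components_[k])))
        if pca.components_[k, j] < 0:
            coords[:, k] *= -1.0
    return Embedding(matrix.pair_labels, coords, pca.explained_variance_ratio_)


def dbscan_cluster(
    embedding: Embedding | np.ndarray,
    eps: float = 0.8,
    min_samples: int = 3,
    pair_labels: Sequence[str] | None = None,
) -> ClusterAssignment:
    """Density-based clustering (Euclidean) of the embedded pairs.

    Accepts either an ``Embedding`` or a raw coordinate array (so the
    full-dimensional parameter matrix can be clustered directly when
    desired).  Points in no dense region get ``NOISE_LABEL``.
    """
    if isinstance(embedding, Embedding):
        X = embedding.coordinates
        labels_in = embedding.pair_labels
    else:
        X = np.asarray(embedding, dtype=float)
        labels_in = tuple(pair_labels) if pair_labels is not None else tuple(
            str(i) for i in range(X.shape[0])
        )
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_samples < 1:
        raise ValueError("min_samples must be at least 1")
    if X.shape[0] == 0:
        return ClusterAssignment(labels_in, np.empty(0, dtype=int), eps, min_samples)
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(X)
    return ClusterAssignment(labels_in, labels.astype(int), eps, min_samples)


def cluster_report(
    assignment: ClusterAssignment, embedding: Embedding | None = None
) -> dict:
    """Memberships, sizes and outliers in serialisable form.

    Returns a dict with ``clusters`` (cluster id -> member pair list),
    ``outliers``, ``sizes``, the DBSCAN settings, and — when the embedding
    is supplied — a per-pair table of PC scores and labels plus the
    explained-variance ratios.
    """
    clusters: dict[int, list[str]] = {}
    outliers: list[str] = []
    for pair, label in zip(assignment.pair_labels, assignment.labels):
        if label == NOISE_LABEL:
            outliers.append(pair)
        else:
            clusters.setdefault(int(label), []).append(pair)
    report: dict = {
        "eps": assignment.eps,
        "min_samples": assignment.min_samples,
        "n_clusters": len(clusters),
        "clusters": {k: sorted(v) for k, v in sorted(clusters.items())},
        "sizes": {k: len(v) for k, v in sorted(clusters.items())},
        "outliers": sorted(outliers),
    }
    if embedding is not None:
        table = pd.DataFrame(
            {
                "pair": list(assignment.pair_labels),
                "PC1": embedding.pc1,
                "PC2": embedding.pc2 if embedding.coordinates.shape[1] > 1 else np.nan,
                "cluster_label": assignment.labels,
            }
        )
        report["table"] = table
        report["explained_variance_ratio"] = [
            float(v) for v in embedding.explained_variance_ratio
        ]
    return report


def plot_embedding(
    assignment: ClusterAssignment, embedding: Embedding, path: str
) -> None:
    """Basic PC1-vs-PC2 scatter; outliers marked with crosses."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    labels = assignment.labels
    for cid in sorted(set(labels)):
        mask = labels == cid
        if cid == NOISE_LABEL:
            ax.scatter(embedding.pc1[mask], embedding.pc2[mask], marker="x",
                       c="k", label="outliers")
        else:
            ax.scatter(embedding.pc1[mask], embedding.pc2[mask],
                       label=f"cluster {cid}")
    for pair, x, y in zip(assignment.pair_labels, embedding.pc1, embedding.pc2):
        ax.annotate(pair, (x, y), fontsize=7, xytext=(3, 3),
                    textcoords="offset points")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def format_report(report: Mapping) -> str:
    """Human-readable rendering of ``cluster_report`` output."""
    lines = [
        f"DBSCAN eps={report['eps']} min_samples={report['min_samples']}: "
        f"{report['n_clusters']} cluster(s), {len(report['outliers'])} outlier(s)",
    ]
    for cid, members in report["clusters"].items():
        lines.append(f"  cluster {cid} ({len(members)} pairs): " + ", ".join(members))
    if report["outliers"]:
        lines.append("  outliers: " + ", ".join(report["outliers"]))
    if "explained_variance_ratio" in report:
        evr = ", ".join(f"{v:.3f}" for v in report["explained_variance_ratio"])
        lines.append(f"  PCA explained-variance ratios: {evr}")
    return "\n".join(lines)
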