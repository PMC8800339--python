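"""K-means over top principal components with silhouette-based k selection."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples


@dataclass
class ClusterResult:
    chosen_k: int
    labels: np.ndarray  # 1-based cluster labels
    silhouette_by_k: dict[int, float]
    inertia: float
    between_ss: float
    total_ss: float
    seed: int
    restarts: int
    override_used: bool = False
    sample_ids: list[str] = field(default_factory=list)

    def silhouette_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.silhouette_by_k.items()), columns=["k", "avg_silhouette"]
        )


def kmeans_fit(
    scores: np.ndarray, k: int, restarts: int = 25, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Lloyd's algorithm with k-means++ seeding, best of ``restarts``.

    Returns 1-based labels and the within-cluster sum of squares.
    sklearn re-seeds empty clusters from the farthest points internally.
    """
    scores = np.asarray(scores, dtype=float)
    if k > scores.shape[0]:
        raise ValueError(f"k={k} exceeds n={scores.shape[0]} samples")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(scores)
    return labels + 1, float(km.inertia_)


def silhouette_width(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average silhouette width (Euclidean); singleton clusters score 0."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs >= 2 clusters")
    return float(silhouette_samples(np.asarray(scores, float), labels).mean())


def _partition_ss(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    center = scores.mean(axis=0)
    total = float(((scores - center) ** 2).sum())
    within = 0.0
    for lab in np.unique(labels):
        pts = scores[labels == lab]
        within += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total, within, total - within


def select_k(
    scores: np.ndarray,
    kmin: int = 2,
    kmax: int = 20,
    restarts: int = 25,
    seed: int = 0,
    override: int | None = None,
    sample_ids: list[str] | None = None,
) -> ClusterResult:
    """Fit k-means for every k in [kmin, kmax], pick argmax avg silhouette.

    The full silhouette-vs-k table is retained so a manual override (for
    example the second-best k) can be applied via config; the override k
    wins when given.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    kmax = min(kmax, n - 1)
    if kmax < kmin:
        raise ValueError(f"k range [{kmin}, {kmax}] empty for n={n}")
    sil: dict[int, float] = {}
    fits: dict[int, tuple[np.ndarray, float]] = {}
    for k in range(kmin, kmax + 1):
        labels, inertia = kmeans_fit(scores, k, restarts=restarts, seed=seed)
        fits[k] = (labels, inertia)
        sil[k] = silhouette_width(scores, labels)
    if override is not None:
        chosen = int(override)
        if chosen not in fits:
            labels, inertia = kmeans_fit(scores, chosen, restarts=restarts, seed=seed)
            fits[chosen] = (labels, inertia)
        used_override = True
    else:
        chosen = max(sil, key=lambda k: (sil[k], -k))
        used_override = False
    labels, inertia = fits[chosen]
    total, within, between = _partition_ss(scores, labels)
    return ClusterResult(
        chosen_k=chosen,
        labels=labels,
        silhouette_by_k=sil,
        inertia=within,
        between_ss=between,
        total_ss=total,
        seed=seed,
        restarts=restarts,
        override_used=used_override,
        sample_ids=list(sample_ids) if sample_ids is not None else [],
    )


def adjusted_rand_index(labels_a, labels_b) -> float:
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(labels_a, labels_b))


def write_labels(result: ClusterResult, path: str | Path) -> Path:
    path = Path(path)
    ids = result.sample_ids or [str(i) for i in range(len(result.labels))]
    pd.DataFrame({"id": ids, "cluster": result.labels}).to_csv(
        path, sep="\t", index=False
    )
    return path


def write_silhouette_table(result: ClusterResult, path: str | Path) -> Path:
    path = Path(path)
    result.silhouette_table().to_csv(path, sep="\t", index=False)
    return path
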