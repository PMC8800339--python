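"""Principal components with Patterson normalization, projection of
held-out samples, and iterative sigma-threshold outlier removal."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix


@dataclass
class Normalization:
    variant_ids: list[str]
    mean: np.ndarray  # per-variant mean call on fit samples
    scale: np.ndarray  # sqrt(p (1 - p))
    kept_mask: np.ndarray  # mask into the original variant list


@dataclass
class PCAModel:
    eigenvalues: np.ndarray  # descending, >= 0
    loadings: np.ndarray  # (M_kept, P), orthonormal columns
    fit_sample_ids: list[str]
    fit_scores: np.ndarray  # (n_fit, P)
    normalization: Normalization
    projected_sample_ids: list[str] = field(default_factory=list)
    projected_scores: np.ndarray | None = None
    outliers_per_iteration: list[list[str]] = field(default_factory=list)

    @property
    def variance_explained(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total

    @property
    def outliers(self) -> list[str]:
        return [s for it in self.outliers_per_iteration for s in it]


def patterson_normalize(
    cohort: GenotypeMatrix, fit_sample_ids: list[str] | None = None
) -> tuple[np.ndarray, Normalization]:
    """Center by fit-sample mean and scale by sqrt(p(1-p)).

    x_ij = (g_ij - mu_j) / sqrt(p_j (1 - p_j)) with mu_j the mean call and
    p_j = mu_j / 2 computed on fit samples only; missing calls become 0
    after centering; monomorphic variants are dropped.  Returns the
    normalized matrix for the fit samples plus the constants needed to
    project other samples.
    """
    if fit_sample_ids is None:
        fit_sample_ids = cohort.sample_ids
    idx = cohort.sample_indices(fit_sample_ids)
    g = cohort.calls[idx, :].astype(float)
    g[g < 0] = np.nan
    mu = np.nanmean(g, axis=0)
    p = mu / 2.0
    keep = np.isfinite(mu) & (p > 0) & (p < 1)
    if keep.sum() == 0:
        raise ValueError("all variants monomorphic on the fit samples")
    mu = mu[keep]
    scale = np.sqrt(p[keep] * (1 - p[keep]))
    x = (g[:, keep] - mu[None, :]) / scale[None, :]
    x = np.where(np.isnan(x), 0.0, x)
    norm = Normalization(
        variant_ids=[v for v, k in zip(cohort.variant_ids, keep) if k],
        mean=mu,
        scale=scale,
        kept_mask=keep,
    )
    return x, norm


def _fix_signs(loadings: np.ndarray, *score_sets: np.ndarray):
    """Deterministic sign: the largest-magnitude loading is positive."""
    for pidx in range(loadings.shape[1]):
        col = loadings[:, pidx]
        j = np.abs(col).argmax()
        if col[j] < 0:
            loadings[:, pidx] = -col
            for s in score_sets:
                if s is not None:
                    s[:, pidx] = -s[:, pidx]


def fit_pcs(
    cohort: GenotypeMatrix,
    fit_sample_ids: list[str] | None = None,
    n_pcs: int = 20,
) -> PCAModel:
    """Eigen-decomposition of the fit-sample covariance of normalized data.

    Scores are the fit samples' projections; eigenvalue p equals the
    sample variance of score column p.  Deterministic up to the fixed
    sign convention.
    """
    if fit_sample_ids is None:
        fit_sample_ids = cohort.sample_ids
    if len(fit_sample_ids) < 2:
        raise ValueError("need >= 2 fit samples")
    x, norm = patterson_normalize(cohort, fit_sample_ids)
    n_fit = x.shape[0]
    max_pcs = min(n_fit - 1, x.shape[1])
    if n_pcs > max_pcs:
        warnings.warn(
            f"rank supports only {max_pcs} PCs (requested {n_pcs})", stacklevel=2
        )
        n_pcs = max_pcs
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    order = np.argsort(s)[::-1]
    u, s, vt = u[:, order], s[order], vt[order, :]
    u, s, vt = u[:, :n_pcs], s[:n_pcs], vt[:n_pcs, :]
    eigenvalues = s**2 / (n_fit - 1)
    loadings = vt.T.copy()
    scores = u * s[None, :]
    _fix_signs(loadings, scores)
    return PCAModel(
        eigenvalues=eigenvalues,
        loadings=loadings,
        fit_sample_ids=list(fit_sample_ids),
        fit_scores=scores,
        normalization=norm,
    )


def project(cohort: GenotypeMatrix, model: PCAModel,
            sample_ids: list[str] | None = None) -> np.ndarray:
    """Project samples onto fitted PCs using the FIT samples' constants."""
    if sample_ids is None:
        sample_ids = cohort.sample_ids
    idx = cohort.sample_indices(sample_ids)
    norm = model.normalization
    lookup = {v: j for j, v in enumerate(cohort.variant_ids)}
    try:
        cols = np.array([lookup[v] for v in norm.variant_ids])
    except KeyError as exc:
        raise ValueError(f"cohort lacks model variant {exc.args[0]!r}") from None
    g = cohort.calls[np.ix_(idx, cols)].astype(float)
    g[g < 0] = np.nan
    x = (g - norm.mean[None, :]) / norm.scale[None, :]
    x = np.where(np.isnan(x), 0.0, x)
    return x @ model.loadings


def remove_outliers(
    cohort: GenotypeMatrix,
    fit_sample_ids: list[str] | None = None,
    n_pcs: int = 20,
    n_outlier_pcs: int = 10,
    sigma: float = 6.0,
    iterations: int = 5,
) -> PCAModel:
    """Iterative PCA outlier removal (sigma threshold on top PCs).

    Up to ``iterations`` times: fit PCs on the current fit set, flag fit
    samples whose score deviates from the per-PC mean by more than
    ``sigma`` standard deviations on any of the top ``n_outlier_pcs``
    PCs, drop them, and refit.  Stops early when nothing is flagged; the
    returned model is fit on the final clean set with the removal history
    attached.
    """
    fit = list(fit_sample_ids) if fit_sample_ids is not None else cohort.sample_ids
    history: list[list[str]] = []
    model = None
    for _ in range(max(iterations, 0)):
        model = fit_pcs(cohort, fit, n_pcs=n_pcs)
        scores = model.fit_scores[:, : min(n_outlier_pcs, model.fit_scores.shape[1])]
        mean = scores.mean(axis=0)
        sd = scores.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        flagged_mask = (np.abs(scores - mean) > sigma * sd).any(axis=1)
        flagged = [s for s, f in zip(fit, flagged_mask) if f]
        if not flagged:
            break
        history.append(flagged)
        fit = [s for s in fit if s not in set(flagged)]
        if not fit:
            raise ValueError("all fit samples flagged as outliers")
        model = None
    if model is None:  # removals happened on the last allowed iteration
        model = fit_pcs(cohort, fit, n_pcs=n_pcs)
    model.outliers_per_iteration = history
    return model


def attach_projection(cohort: GenotypeMatrix, model: PCAModel,
                      sample_ids: list[str]) -> PCAModel:
    model.projected_sample_ids = list(sample_ids)
    model.projected_scores = project(cohort, model, sample_ids)
    return model


def variance_explained(model: PCAModel) -> np.ndarray:
    """Per-PC fraction: eigenvalue over the sum of all computed eigenvalues."""
    return model.variance_explained


def select_top_pcs(fractions: np.ndarray, override: int | None = None) -> int:
    """Scree elbow: argmax of the second forward difference of the sorted
    variance-explained fractions; a config override wins when given."""
    if override is not None:
        return int(override)
    fr = np.sort(np.asarray(fractions, dtype=float))[::-1]
    if len(fr) < 3:
        raise ValueError("need >= 3 PCs for elbow detection")
    # second forward difference at PC p (1-based): f[p+2] - 2 f[p+1] + f[p]
    second = fr[2:] - 2 * fr[1:-1] + fr[:-2]
    if np.allclose(second, 0):
        warnings.warn("flat scree spectrum; defaulting to 2 PCs", stacklevel=2)
        return 2
    return max(2, int(second.argmax()) + 1)


def write_scores(model: PCAModel, path: str | Path,
                 labels: dict[str, str] | None = None) -> Path:
    """EIGENSOFT evec-style TSV: sample id, PC columns, group label."""
    path = Path(path)
    n_pcs = model.fit_scores.shape[1]
    rows = []
    for sid, sc in zip(model.fit_sample_ids, model.fit_scores):
        rows.append([sid, *sc, (labels or {}).get(sid, "fit")])
    if model.projected_scores is not None:
        for sid, sc in zip(model.projected_sample_ids, model.projected_scores):
            rows.append([sid, *sc, (labels or {}).get(sid, "projected")])
    cols = ["id", *[f"PC{i + 1}" for i in range(n_pcs)], "label"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    return path


def write_eigenvalues(model: PCAModel, path: str | Path) -> Path:
    path = Path(path)
    path.write_text("".join(f"{v:.10g}\n" for v in model.eigenvalues))
    return path
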