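"""Supervised ancestry-proportion estimation against fixed reference
frequencies, and continental-ancestry-group (CAG) assignment.

Reference per-SNP allele frequencies f are estimated once from labeled
reference samples and held fixed; each individual's proportion vector q
is then fit independently by EM on the binomial mixture likelihood

    l(q_i) = sum_j [ g_ij ln(sum_k q_ik f_kj) + (2 - g_ij) ln(sum_k q_ik (1 - f_kj)) ]

with missing genotypes omitted.  Individuals are independent, so the
E/M steps are vectorized across the whole cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix

FREQ_CLAMP = 1e-6
UNASSIGNED = "unassigned"


@dataclass
class AncestryModel:
    populations: list[str]
    f: np.ndarray  # (K, M) reference alt-allele frequencies, clamped
    variant_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.ndim != 2 or self.f.shape[0] != len(self.populations):
            raise ValueError("f must be (K populations x M variants)")
        if np.any(self.f <= 0) or np.any(self.f >= 1):
            raise ValueError("reference frequencies must lie strictly in (0,1)")


@dataclass
class AncestryProportions:
    sample_ids: list[str]
    populations: list[str]
    q: np.ndarray  # (n, K) simplex rows
    log_likelihood: float
    n_iter: int
    ll_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.q, columns=self.populations)
        df.insert(0, "id", self.sample_ids)
        return df


def reference_frequencies(
    cohort: GenotypeMatrix, labels: dict[str, list[str]]
) -> AncestryModel:
    """Estimate per-population alt-allele frequencies from labeled samples.

    ``labels`` maps population name -> sample ids.  Frequencies are
    clamped to [1e-6, 1 - 1e-6]; an all-missing SNP within a group is set
    to 0.5 with a warning.
    """
    pops = list(labels)
    rows = []
    for pop in pops:
        ids = labels[pop]
        if len(ids) < 2:
            raise ValueError(f"reference group {pop!r} needs >= 2 samples")
        calls = cohort.calls[cohort.sample_indices(ids), :]
        nonmiss = calls >= 0
        n = nonmiss.sum(axis=0)
        alt = np.where(nonmiss, calls, 0).sum(axis=0)
        empty = n == 0
        if empty.any():
            warnings.warn(
                f"{int(empty.sum())} all-missing SNPs in group {pop!r} set to 0.5",
                stacklevel=2,
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(empty, 0.5, alt / np.maximum(2.0 * n, 1.0))
        rows.append(f)
    f = np.clip(np.stack(rows), FREQ_CLAMP, 1 - FREQ_CLAMP)
    return AncestryModel(populations=pops, f=f, variant_ids=cohort.variant_ids)


def fit_q(
    cohort: GenotypeMatrix,
    model: AncestryModel,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> AncestryProportions:
    """Per-individual EM for ancestry proportions with f held fixed.

    Each of an individual's alt allele copies is allocated to population k
    proportionally to q_ik f_kj (reference copies to q_ik (1 - f_kj)); the
    M-step renormalizes allocated copies over 2x the non-missing SNP
    count.  Iterates until max |dq| < tol or ``max_iter``.  The
    log-likelihood is non-decreasing across iterations by EM construction
    and is returned per iteration in ``ll_trace``.
    """
    if model.variant_ids and model.variant_ids != cohort.variant_ids:
        raise ValueError("model and cohort must share the same variant list")
    f = model.f  # (K, M)
    K, m = f.shape
    g = cohort.calls.astype(float)
    miss = g < 0
    galt = np.where(miss, 0.0, g)
    gref = np.where(miss, 0.0, 2.0 - g)
    n_nonmiss = (~miss).sum(axis=1)
    if np.any(n_nonmiss == 0):
        raise ValueError("sample with zero non-missing genotypes")
    denom = (2.0 * n_nonmiss)[:, None]

    n = cohort.n_samples
    q = np.full((n, K), 1.0 / K)
    fc = 1.0 - f
    ll_trace = []
    ll_rows = np.zeros(n)
    # converged individuals are frozen and drop out of the update set
    active = np.arange(n)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        qa = q[active]
        p_alt = qa @ f  # (n_active, M)
        p_ref = qa @ fc
        ll_rows[active] = np.sum(
            galt[active] * np.log(p_alt) + gref[active] * np.log(p_ref), axis=1
        )
        ll = float(ll_rows.sum())
        if not np.isfinite(ll):
            raise ValueError("non-finite log-likelihood")
        ll_trace.append(ll)
        alloc = qa * ((galt[active] / p_alt) @ f.T + (gref[active] / p_ref) @ fc.T)
        q_new = alloc / denom[active]
        delta_rows = np.abs(q_new - qa).max(axis=1)
        q[active] = q_new
        if delta_rows.max() < tol:
            break
        active = active[delta_rows >= tol]
    # log-likelihood at the converged q
    ll = float(np.sum(galt * np.log(q @ f) + gref * np.log(q @ fc)))
    ll_trace.append(ll)
    return AncestryProportions(
        sample_ids=cohort.sample_ids,
        populations=list(model.populations),
        q=q,
        log_likelihood=ll,
        n_iter=n_iter,
        ll_trace=np.array(ll_trace),
    )


def assign_cag(
    proportions: AncestryProportions, threshold: float = 0.8
) -> pd.DataFrame:
    """Assign each sample to its majority ancestry group at the threshold.

    Label is argmax_k q_ik when max q >= threshold (inclusive), else
    ``"unassigned"``.
    """
    q = proportions.q
    best = q.argmax(axis=1)
    qmax = q.max(axis=1)
    labels = np.array(
        [
            proportions.populations[k] if qm >= threshold else UNASSIGNED
            for k, qm in zip(best, qmax)
        ]
    )
    return pd.DataFrame(
        {"id": proportions.sample_ids, "cag": labels, "q_max": qmax}
    )


def reference_pairwise_fst(cohort: GenotypeMatrix, labels: dict[str, list[str]]):
    """Pairwise Hudson Fst among the reference groups, plus the pair mean."""
    from .fst import pairwise_fst, summarize_pairs

    group_of = {}
    for pop, ids in labels.items():
        for s in ids:
            group_of[s] = pop
    matrix = pairwise_fst(cohort, group_of)
    summary = summarize_pairs(matrix)
    return matrix, summary["mean"]


def write_q_table(
    proportions: AncestryProportions, assignments: pd.DataFrame, path: str | Path
) -> Path:
    """TSV mirroring an ADMIXTURE .Q layout plus id and CAG columns."""
    df = proportions.to_frame()
    df = df.merge(assignments[["id", "cag"]], on="id")
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path
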