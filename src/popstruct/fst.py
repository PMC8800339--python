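"""Pairwise Hudson Fst between groups, ratio-of-averages across SNPs."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix


@dataclass
class FstMatrix:
    groups: list[str]
    values: np.ndarray  # symmetric, raw estimates (may be slightly negative)
    n_snps: np.ndarray | None = None  # usable SNP count per pair

    def __post_init__(self) -> None:
        k = len(self.groups)
        if self.values.shape != (k, k):
            raise ValueError("fst matrix shape inconsistent with group list")

    @property
    def clamped(self) -> np.ndarray:
        """Estimates clamped to the documented [0, 1] range."""
        return np.clip(self.values, 0.0, 1.0)

    def to_frame(self, clamp: bool = False) -> pd.DataFrame:
        v = self.clamped if clamp else self.values
        return pd.DataFrame(v, index=self.groups, columns=self.groups)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.groups)):
            for j in range(i + 1, len(self.groups)):
                rows.append(
                    (
                        self.groups[i],
                        self.groups[j],
                        self.values[i, j],
                        int(self.n_snps[i, j]) if self.n_snps is not None else None,
                    )
                )
        return pd.DataFrame(rows, columns=["group1", "group2", "fst", "n_snps"])


def hudson_components(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Hudson numerator and denominator.

    numerator   = (p1 - p2)^2 - p1(1-p1)/(2 n1 - 1) - p2(1-p2)/(2 n2 - 1)
    denominator = p1(1-p2) + p2(1-p1)

    ``n1``/``n2`` are diploid sample counts (scalars or per-SNP arrays);
    both must be >= 2 wherever used.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("need >= 2 non-missing diploids per group per SNP")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (2 * n1 - 1) - p2 * (1 - p2) / (2 * n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def hudson_fst_from_freqs(
    p1: np.ndarray, n1, p2: np.ndarray, n2
) -> float:
    """Ratio-of-averages Hudson Fst; zero-denominator SNPs are excluded."""
    num, den = hudson_components(p1, n1, p2, n2)
    ok = den > 0
    if ok.sum() == 0:
        raise ValueError("no usable SNPs (all denominators zero)")
    return float(num[ok].sum() / den[ok].sum())


def _group_freqs(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    nonmiss = calls >= 0
    n = nonmiss.sum(axis=0)
    alt = np.where(nonmiss, calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
    return p, n


def pairwise_fst(
    cohort: GenotypeMatrix, group_of: dict[str, str]
) -> FstMatrix:
    """Pairwise mean (ratio-of-averages) Hudson Fst between labeled groups.

    ``group_of`` maps sample id -> group name; unlisted samples are
    ignored.  Groups with fewer than 2 samples are excluded with a
    warning.  For each pair, SNPs with < 2 non-missing diploids in either
    group or a zero denominator are excluded from the sums.
    """
    members: dict[str, list[str]] = {}
    for sid in cohort.sample_ids:
        grp = group_of.get(sid)
        if grp is not None:
            members.setdefault(grp, []).append(sid)
    small = [g for g, ids in members.items() if len(ids) < 2]
    for g in small:
        warnings.warn(f"group {g!r} has < 2 samples; excluded from Fst", stacklevel=2)
        del members[g]
    groups = list(members)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")

    freq = {}
    for g in groups:
        calls = cohort.calls[cohort.sample_indices(members[g]), :]
        freq[g] = _group_freqs(calls)

    k = len(groups)
    values = np.zeros((k, k))
    n_snps = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            p1, n1 = freq[groups[i]]
            p2, n2 = freq[groups[j]]
            ok = (n1 >= 2) & (n2 >= 2)
            num, den = hudson_components(
                p1[ok], np.maximum(n1[ok], 2), p2[ok], np.maximum(n2[ok], 2)
            )
            use = den > 0
            if use.sum() == 0:
                raise ValueError(
                    f"no usable SNPs for pair ({groups[i]}, {groups[j]})"
                )
            est = float(num[use].sum() / den[use].sum())
            values[i, j] = values[j, i] = est
            n_snps[i, j] = n_snps[j, i] = int(use.sum())
    return FstMatrix(groups=groups, values=values, n_snps=n_snps)


def summarize_pairs(matrix: FstMatrix, clamp: bool = False) -> dict[str, float]:
    """Min/mean/max over the strictly-upper-triangle pair estimates."""
    k = len(matrix.groups)
    if k < 2:
        raise ValueError("need >= 1 pair to summarize")
    v = matrix.clamped if clamp else matrix.values
    iu = np.triu_indices(k, 1)
    vals = v[iu]
    return {
        "min": float(vals.min()),
        "mean": float(vals.mean()),
        "max": float(vals.max()),
    }


def write_phylip(matrix: FstMatrix, path: str | Path, clamp: bool = True) -> Path:
    """Write a phylip square distance matrix of mean Fst values.

    Names longer than 10 characters fall back to the relaxed (whitespace
    delimited) phylip dialect with a warning.
    """
    path = Path(path)
    v = matrix.clamped if clamp else matrix.values
    long_names = any(len(g) > 10 for g in matrix.groups)
    if long_names:
        warnings.warn(
            "group names exceed 10 characters; writing relaxed phylip", stacklevel=2
        )
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.groups)}\n")
        for i, g in enumerate(matrix.groups):
            name = g if long_names else f"{g:<10s}"
            row = " ".join(f"{v[i, j]:.6f}" for j in range(len(matrix.groups)))
            fh.write(f"{name} {row}\n")
    return path


def read_phylip(path: str | Path) -> FstMatrix:
    with open(path) as fh:
        n = int(fh.readline().strip())
        groups, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            groups.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return FstMatrix(groups=groups, values=np.array(rows))
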