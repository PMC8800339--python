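"""Genomic relationship estimation and greedy unrelated-subset selection."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix
from .qc import allele_frequency

DEFAULT_REL_CUTOFF = 0.025


@dataclass
class RelatednessMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric (n, n)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("relatedness matrix shape inconsistent with sample ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def grm(cohort: GenotypeMatrix, maf_floor: float = 0.05) -> RelatednessMatrix:
    """Standard normalized genomic relationship matrix.

    Entry (i, i') is the mean over SNPs of
    (g_ij - 2 p_j)(g_i'j - 2 p_j) / (2 p_j (1 - p_j)); missing calls are
    mean-imputed.  Variants with MAF below ``maf_floor`` are excluded.
    """
    freqs = allele_frequency(cohort)
    p = freqs["alt_freq"].to_numpy()
    usable = ~np.isnan(p) & (freqs["maf"].to_numpy() >= maf_floor)
    if usable.sum() == 0:
        raise ValueError("zero usable SNPs after MAF filter")
    p = p[usable]
    g = cohort.calls[:, usable].astype(float)
    g[g < 0] = np.nan
    centered = g - 2 * p[None, :]
    centered = np.where(np.isnan(centered), 0.0, centered)  # mean imputation
    scale = np.sqrt(2 * p * (1 - p))
    x = centered / scale[None, :]
    values = (x @ x.T) / len(p)
    return RelatednessMatrix(sample_ids=cohort.sample_ids, values=values)


def related_pairs(
    matrix: RelatednessMatrix, cutoff: float = DEFAULT_REL_CUTOFF
) -> list[tuple[str, str, float]]:
    """All off-diagonal pairs with relatedness strictly above ``cutoff``."""
    ids = matrix.sample_ids
    v = matrix.values
    out = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if v[i, j] > cutoff:
                out.append((ids[i], ids[j], float(v[i, j])))
    return out


def greedy_unrelated(
    pairs: list[tuple[str, str, float]] | list[tuple[str, str]],
    all_ids: list[str],
) -> tuple[list[str], list[str]]:
    """Iteratively drop the individual in the most remaining related pairs.

    Ties are broken by dropping the lexicographically larger id.  The kept
    set induces no input pair; order of ``all_ids`` is preserved in the
    keep list.
    """
    known = set(all_ids)
    edges = set()
    for pair in pairs:
        a, b = pair[0], pair[1]
        if a not in known or b not in known:
            raise ValueError(f"pair ({a}, {b}) references unknown sample id")
        if a != b:
            edges.add((min(a, b), max(a, b)))

    degree: dict[str, int] = {}
    for a, b in edges:
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1

    dropped = []
    active = set(edges)
    while active:
        worst = max(degree, key=lambda s: (degree[s], s))
        dropped.append(worst)
        active = {e for e in active if worst not in e}
        degree = {}
        for a, b in active:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1

    dropped_set = set(dropped)
    keep = [s for s in all_ids if s not in dropped_set]
    return keep, dropped


def write_pairs(pairs, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(pairs, columns=["id1", "id2", "value"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def write_id_list(ids: list[str], path: str | Path) -> Path:
    path = Path(path)
    path.write_text("".join(f"{s}\n" for s in ids))
    return path
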