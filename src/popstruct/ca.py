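"""Contingency tables, chi-square test, and correspondence analysis of
cluster x birth-place labels."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray  # (R, C) non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("count matrix shape inconsistent with labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


@dataclass
class CAResult:
    row_coords: np.ndarray  # (R, D) principal coordinates
    col_coords: np.ndarray  # (C, D)
    inertia_fractions: np.ndarray  # per-dimension, sums to 1 (0s if independent)
    total_inertia: float
    chi2: float
    dof: int
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def dim12_fraction(self, renormalize_2d: bool = False) -> tuple[float, float]:
        """Fractions for the first two dimensions, optionally renormalized
        so the pair sums to 1 (both conventions appear in the wild)."""
        fr = self.inertia_fractions
        d1 = float(fr[0]) if len(fr) > 0 else 0.0
        d2 = float(fr[1]) if len(fr) > 1 else 0.0
        if renormalize_2d and (d1 + d2) > 0:
            s = d1 + d2
            return d1 / s, d2 / s
        return d1, d2


def build_contingency(
    labels_a, labels_b, min_count: int = 10
) -> ContingencyTable:
    """Cross-tabulate paired labels, dropping missing pairs, then columns
    (birth categories) with total < ``min_count``, then empty rows.

    A category with exactly ``min_count`` observations is kept ("fewer
    than" is strict).
    """
    df = pd.DataFrame({"a": list(labels_a), "b": list(labels_b)})
    df = df.dropna()
    if df.empty:
        raise ValueError("no complete label pairs")
    tab = pd.crosstab(df["a"].astype(str), df["b"].astype(str))
    tab = tab.loc[:, tab.sum(axis=0) >= min_count]
    tab = tab.loc[tab.sum(axis=1) > 0, :]
    if tab.empty or tab.shape[1] == 0:
        raise ValueError("contingency table empty after filtering")
    return ContingencyTable(
        row_labels=[str(r) for r in tab.index],
        col_labels=[str(c) for c in tab.columns],
        counts=tab.to_numpy(),
    )


def chi_square(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square of independence, no continuity correction."""
    counts = table.counts
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    stat, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), int(dof), float(p)


def ca_fit(table: ContingencyTable) -> CAResult:
    """Standard correspondence analysis of a contingency table.

    P = counts/n; standardized residuals S = D_r^{-1/2}(P - r c^T)D_c^{-1/2};
    SVD of S gives principal coordinates D^{-1/2} U Sigma (rows) and
    D^{-1/2} V Sigma (columns); inertia fraction of dimension d is
    sigma_d^2 / sum sigma^2 and total inertia equals chi^2 / n.
    """
    counts = table.counts.astype(float)
    n = counts.sum()
    if n == 0:
        raise ValueError("empty contingency table")
    P = counts / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if np.any(r == 0) or np.any(c == 0):
        raise ValueError("zero margin in contingency table")
    dr = 1.0 / np.sqrt(r)
    dc = 1.0 / np.sqrt(c)
    S = dr[:, None] * (P - np.outer(r, c)) * dc[None, :]
    u, s, vt = np.linalg.svd(S, full_matrices=False)
    d = min(len(table.row_labels), len(table.col_labels)) - 1
    u, s, vt = u[:, :d], s[:d], vt[:d, :]
    total_inertia = float((s**2).sum())
    if total_inertia > 0:
        fractions = s**2 / total_inertia
    else:
        fractions = np.zeros(d)
    row_coords = dr[:, None] * u * s[None, :]
    col_coords = dc[:, None] * vt.T * s[None, :]
    chi2, dof, _ = chi_square(table)
    return CAResult(
        row_coords=row_coords,
        col_coords=col_coords,
        inertia_fractions=fractions,
        total_inertia=total_inertia,
        chi2=chi2,
        dof=dof,
        row_labels=table.row_labels,
        col_labels=table.col_labels,
    )


def read_region_map(path: str | Path) -> dict[str, str]:
    """Country -> region mapping CSV with columns (country, region)."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "country" not in cols or "region" not in cols:
        raise ValueError("region map CSV needs 'country' and 'region' columns")
    return dict(zip(df["country"].astype(str), df["region"].astype(str)))


def map_regions(countries, region_map: dict[str, str]) -> list:
    """Map country labels to regions; unmapped or missing become NA."""
    out = []
    for c in countries:
        if pd.isna(c):
            out.append(pd.NA)
        else:
            out.append(region_map.get(str(c), pd.NA))
    return out


def write_ca_result(result: CAResult, prefix: str | Path) -> dict[str, Path]:
    prefix = Path(prefix)
    dims = [f"Dim{i + 1}" for i in range(result.row_coords.shape[1])]
    rows = pd.DataFrame(result.row_coords, columns=dims)
    rows.insert(0, "label", result.row_labels)
    cols = pd.DataFrame(result.col_coords, columns=dims)
    cols.insert(0, "label", result.col_labels)
    inertia = pd.DataFrame(
        {
            "dimension": dims,
            "inertia_fraction": result.inertia_fractions,
        }
    )
    paths = {
        "rows": Path(f"{prefix}_row_coords.tsv"),
        "cols": Path(f"{prefix}_col_coords.tsv"),
        "inertia": Path(f"{prefix}_inertia.tsv"),
    }
    rows.to_csv(paths["rows"], sep="\t", index=False)
    cols.to_csv(paths["cols"], sep="\t", index=False)
    inertia.to_csv(paths["inertia"], sep="\t", index=False)
    return paths
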