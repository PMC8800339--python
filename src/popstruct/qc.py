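"""Allele-frequency, region-exclusion, and windowed LD-pruning filters."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix


@dataclass
class PruneParams:
    window_kb: float = 50.0
    step_kb: float = 10.0
    r2_threshold: float = 0.025
    maf: float = 0.0
    exclude_regions: list[tuple[str, int, int]] = field(default_factory=list)
    reference_sample_ids: list[str] | None = None
    window_units: str = "kb"  # "kb" or "snps" (PLINK's SNP-count dialect)

    def __post_init__(self) -> None:
        if not self.step_kb > 0 or self.window_kb < self.step_kb:
            raise ValueError("require window_kb >= step_kb > 0")
        if not 0 <= self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in [0,1]")
        if not 0 <= self.maf <= 1:
            raise ValueError("maf must be in [0,1]")
        if self.window_units not in ("kb", "snps"):
            raise ValueError("window_units must be 'kb' or 'snps'")


def allele_frequency(
    cohort: GenotypeMatrix, sample_subset: list[str] | None = None
) -> pd.DataFrame:
    """Per-variant alt-allele frequency and MAF over non-missing calls.

    A variant with no non-missing call gets NaN frequency.
    """
    calls = cohort.calls
    if sample_subset is not None:
        calls = calls[cohort.sample_indices(sample_subset), :]
    nonmiss = calls >= 0
    n = nonmiss.sum(axis=0)
    alt = np.where(nonmiss, calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(n > 0, alt / (2.0 * n), np.nan)
    maf = np.minimum(f, 1 - f)
    return pd.DataFrame(
        {"id": cohort.variant_ids, "alt_freq": f, "maf": maf, "n_nonmissing": n}
    )


def filter_maf(cohort: GenotypeMatrix, threshold: float,
               sample_subset: list[str] | None = None) -> GenotypeMatrix:
    freqs = allele_frequency(cohort, sample_subset)
    keep = freqs["maf"].to_numpy() >= threshold
    keep &= ~np.isnan(freqs["alt_freq"].to_numpy())
    return cohort.subset_variant_mask(keep)


def exclude_regions(
    cohort: GenotypeMatrix, regions: list[tuple[str, int, int]]
) -> GenotypeMatrix:
    """Remove variants inside 1-based inclusive (chrom, start, end) intervals."""
    if not regions:
        return cohort
    chrom = cohort.variants["chrom"].to_numpy()
    pos = cohort.variants["pos"].to_numpy()
    drop = np.zeros(cohort.n_variants, dtype=bool)
    for rchrom, start, end in regions:
        drop |= (chrom == str(rchrom)) & (pos >= start) & (pos <= end)
    return cohort.subset_variant_mask(~drop)


def read_regions_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read exclusion regions from BED (0-based half-open) as 1-based inclusive."""
    regions = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED record at line {line_no} of {path}")
            regions.append((parts[0], int(parts[1]) + 1, int(parts[2])))
    return regions


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two call vectors over complete pairs.

    Genotypic (composite) r-squared; returns 0 when either vector is
    constant on the complete pairs.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = (g1 >= 0) & (g2 >= 0)
    if ok.sum() < 2:
        raise ValueError("need >= 2 pairwise-complete samples for r^2")
    x, y = g1[ok], g2[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _pairwise_r2(calls: np.ndarray) -> np.ndarray:
    """r^2 matrix over a small block of variants (columns), missing-aware."""
    m = calls.shape[1]
    g = calls.astype(float)
    mask = g >= 0
    g = np.where(mask, g, 0.0)
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            ok = mask[:, i] & mask[:, j]
            n = ok.sum()
            if n < 2:
                continue
            x, y = g[ok, i], g[ok, j]
            vx = x.var()
            vy = y.var()
            if vx == 0 or vy == 0:
                continue
            cov = ((x - x.mean()) * (y - y.mean())).mean()
            out[i, j] = out[j, i] = cov * cov / (vx * vy)
    return out


def ld_prune(cohort: GenotypeMatrix, params: PruneParams) -> list[str]:
    """Greedy windowed LD pruning; returns the kept-variant id list.

    Guarantees that no retained pair closer than the window width has
    r^2 above the threshold on the reference subset: of each violating
    pair the lower-MAF member is removed (tie -> larger position).
    """
    variants = cohort.variants
    chrom = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy()
    for c in pd.unique(chrom):
        p = pos[chrom == c]
        if np.any(np.diff(p) < 0):
            raise ValueError("variants must be sorted by (chrom, pos)")

    work = cohort
    if params.exclude_regions:
        work = exclude_regions(work, params.exclude_regions)
    calls = work.calls
    if params.reference_sample_ids is not None:
        calls = calls[work.sample_indices(params.reference_sample_ids), :]

    freqs = allele_frequency(
        GenotypeMatrix(
            samples=pd.DataFrame({"id": [f"s{i}" for i in range(calls.shape[0])]}),
            variants=work.variants,
            calls=calls,
        )
    )
    maf = freqs["maf"].to_numpy()
    if params.maf > 0:
        pre_keep = (maf >= params.maf) & ~np.isnan(freqs["alt_freq"].to_numpy())
    else:
        pre_keep = ~np.isnan(freqs["alt_freq"].to_numpy())

    vchrom = work.variants["chrom"].to_numpy()
    vpos = work.variants["pos"].to_numpy()
    vids = np.array(work.variant_ids)
    kept = pre_keep.copy()

    window_bp = params.window_kb * 1000.0
    for c in pd.unique(vchrom):
        idx = np.flatnonzero((vchrom == c) & kept)
        # sweep left to right; for each variant test all kept predecessors
        # in range (position window or SNP-count window)
        for jj, j in enumerate(idx):
            if not kept[j]:
                continue
            for ii in range(jj - 1, -1, -1):
                i = idx[ii]
                if not kept[i]:
                    continue
                if params.window_units == "kb":
                    if vpos[j] - vpos[i] > window_bp:
                        break
                else:
                    if jj - ii > int(params.window_kb):
                        break
                r2 = _pairwise_r2(calls[:, [i, j]])[0, 1]
                if r2 > params.r2_threshold:
                    # drop the lower-MAF member; tie -> larger position
                    if (maf[i], -vpos[i]) < (maf[j], -vpos[j]):
                        kept[i] = False
                    else:
                        kept[j] = False
                        break
    return vids[kept].tolist()


def prune_certificate(
    cohort: GenotypeMatrix,
    kept_ids: list[str],
    params: PruneParams,
) -> float:
    """Exhaustive post-prune scan: max within-window r^2 over retained pairs."""
    sub = cohort.subset_variants(kept_ids)
    calls = sub.calls
    if params.reference_sample_ids is not None:
        calls = calls[sub.sample_indices(params.reference_sample_ids), :]
    chrom = sub.variants["chrom"].to_numpy()
    pos = sub.variants["pos"].to_numpy()
    window_bp = params.window_kb * 1000.0
    worst = 0.0
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                if params.window_units == "kb" and pos[j] - pos[i] > window_bp:
                    break
                if params.window_units == "snps" and b - a > int(params.window_kb):
                    break
                worst = max(worst, _pairwise_r2(calls[:, [i, j]])[0, 1])
    return worst


def write_keep_list(ids: list[str], path: str | Path) -> Path:
    path = Path(path)
    path.write_text("".join(f"{v}\n" for v in ids))
    return path


def read_keep_list(path: str | Path) -> list[str]:
    return [line.strip() for line in open(path) if line.strip()]
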