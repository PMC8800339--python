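"""Core genotype-matrix container shared by every analysis stage.

Genotype calls are stored as an ``int8`` matrix of alt-allele counts
(samples x variants) with ``-1`` marking a missing call.  Variant and
sample metadata travel alongside as pandas DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]
SAMPLE_COLUMNS = ["id", "population_label", "birth_country", "birth_region"]


def _as_variant_frame(variants: pd.DataFrame) -> pd.DataFrame:
    df = variants.reset_index(drop=True).copy()
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    df["pos"] = df["pos"].astype(np.int64)
    if (df["pos"] < 1).any():
        raise ValueError("variant positions must be 1-based (>= 1)")
    if (df["ref"] == df["alt"]).any():
        bad = df.loc[df["ref"] == df["alt"], "id"].iloc[0]
        raise ValueError(f"ref allele equals alt allele at variant {bad!r}")
    return df


def _as_sample_frame(samples: pd.DataFrame) -> pd.DataFrame:
    df = samples.reset_index(drop=True).copy()
    if "id" not in df.columns:
        raise ValueError("sample table must have an 'id' column")
    for col in SAMPLE_COLUMNS[1:]:
        if col not in df.columns:
            df[col] = pd.NA
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r}")
    return df


@dataclass
class GenotypeMatrix:
    """Samples x biallelic SNPs coded 0/1/2 alt-allele counts, -1 missing."""

    samples: pd.DataFrame
    variants: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = _as_sample_frame(self.samples)
        self.variants = _as_variant_frame(self.variants)
        calls = np.asarray(self.calls, dtype=np.int8)
        if calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        valid = np.isin(calls, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("calls must be in {0, 1, 2, -1}")
        self.calls = calls

    # -- basic views ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["id"].tolist()

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["id"].tolist()

    def calls_float(self) -> np.ndarray:
        """Calls as float with missing mapped to NaN."""
        g = self.calls.astype(float)
        g[self.calls == MISSING] = np.nan
        return g

    # -- subsetting ----------------------------------------------------
    def sample_indices(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples["id"])}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def subset_samples(self, ids) -> "GenotypeMatrix":
        idx = self.sample_indices(ids)
        return GenotypeMatrix(
            samples=self.samples.iloc[idx],
            variants=self.variants,
            calls=self.calls[idx, :],
        )

    def subset_variants(self, ids) -> "GenotypeMatrix":
        lookup = {v: i for i, v in enumerate(self.variants["id"])}
        idx = np.array([lookup[v] for v in ids], dtype=int)
        return GenotypeMatrix(
            samples=self.samples,
            variants=self.variants.iloc[idx],
            calls=self.calls[:, idx],
        )

    def subset_variant_mask(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            samples=self.samples,
            variants=self.variants.loc[mask],
            calls=self.calls[:, mask],
        )

    def concat_samples(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        if self.variant_ids != other.variant_ids:
            raise ValueError("sample concatenation requires identical variant lists")
        return GenotypeMatrix(
            samples=pd.concat([self.samples, other.samples], ignore_index=True),
            variants=self.variants,
            calls=np.vstack([self.calls, other.calls]),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.variant_ids == other.variant_ids
            and np.array_equal(self.calls, other.calls)
        )
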