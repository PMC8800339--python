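"""Synthetic structured-cohort generator with known truth.

Hierarchical Balding-Nichols frequencies (ancestral -> continent ->
subpopulation), binomial genotype sampling, continent-level admixture,
Mendelian parent-offspring pairs, and birth-place labels correlated with
subpopulation.  Everything is driven by a single :class:`PopulationSpec`
and one seeded generator stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import GenotypeMatrix

FREQ_CLAMP = 1e-6


@dataclass
class SubpopSpec:
    name: str
    fs: float  # divergence from the continent ancestor
    n: int
    region: str | None = None
    countries: dict[str, float] = field(default_factory=dict)
    is_reference: bool = False


@dataclass
class ContinentSpec:
    name: str
    fc: float  # divergence from the global ancestor
    subpops: list[SubpopSpec] = field(default_factory=list)


@dataclass
class AdmixedBlock:
    n: int
    alpha: list[float]  # Dirichlet concentrations, one per continent


@dataclass
class LDBlockSpec:
    """Duplicate ``n_tagged`` SNPs with per-allele flip probability ``eps``."""

    n_tagged: int
    eps: float = 0.01
    offset_bp: int = 1000


@dataclass
class PopulationSpec:
    continents: list[ContinentSpec]
    n_snps: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    admixed_blocks: list[AdmixedBlock] = field(default_factory=list)
    relative_pairs: int = 0
    label_concordance: float = 1.0
    missing_label_fraction: float = 0.0
    ld_block: LDBlockSpec | None = None
    n_chromosomes: int = 22
    snp_spacing_bp: int = 2000
    seed: int = 0

    def validate(self) -> None:
        if not self.continents:
            raise ValueError("at least one continent required")
        for cont in self.continents:
            if not 0 <= cont.fc < 1:
                raise ValueError(f"continent F must be in [0,1), got {cont.fc}")
            for sp in cont.subpops:
                if not 0 <= sp.fs < 1:
                    raise ValueError(f"subpop F must be in [0,1), got {sp.fs}")
                if sp.n < 0:
                    raise ValueError("subpop n must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        K = len(self.continents)
        for blk in self.admixed_blocks:
            if len(blk.alpha) != K:
                raise ValueError("admixed block alpha length must equal number of continents")
            if any(a <= 0 for a in blk.alpha):
                raise ValueError("Dirichlet concentrations must be > 0")
            if blk.n < 0:
                raise ValueError("admixed block n must be >= 0")
        if not 0 <= self.label_concordance <= 1:
            raise ValueError("label_concordance must be in [0,1]")
        if not 0 <= self.missing_label_fraction <= 1:
            raise ValueError("missing_label_fraction must be in [0,1]")
        if self.relative_pairs < 0:
            raise ValueError("relative_pairs must be >= 0")

    @property
    def continent_names(self) -> list[str]:
        return [c.name for c in self.continents]

    # -- config round trip --------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSpec":
        continents = [
            ContinentSpec(
                name=c["name"],
                fc=float(c["fc"]),
                subpops=[
                    SubpopSpec(
                        name=s["name"],
                        fs=float(s["fs"]),
                        n=int(s["n"]),
                        region=s.get("region"),
                        countries=dict(s.get("countries", {})),
                        is_reference=bool(s.get("is_reference", False)),
                    )
                    for s in c.get("subpops", [])
                ],
            )
            for c in d["continents"]
        ]
        blocks = [
            AdmixedBlock(n=int(b["n"]), alpha=[float(a) for a in b["alpha"]])
            for b in d.get("admixed_blocks", [])
        ]
        ld = d.get("ld_block")
        spec = cls(
            continents=continents,
            n_snps=int(d["n_snps"]),
            maf_range=tuple(d.get("maf_range", (0.05, 0.5))),
            admixed_blocks=blocks,
            relative_pairs=int(d.get("relative_pairs", 0)),
            label_concordance=float(d.get("label_concordance", 1.0)),
            missing_label_fraction=float(d.get("missing_label_fraction", 0.0)),
            ld_block=LDBlockSpec(
                n_tagged=int(ld["n_tagged"]),
                eps=float(ld.get("eps", 0.01)),
                offset_bp=int(ld.get("offset_bp", 1000)),
            )
            if ld
            else None,
            n_chromosomes=int(d.get("n_chromosomes", 22)),
            snp_spacing_bp=int(d.get("snp_spacing_bp", 2000)),
            seed=int(d.get("seed", 0)),
        )
        spec.validate()
        return spec

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PopulationSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class FrequencyTable:
    """Latent allele frequencies at each level of the hierarchy."""

    ancestral: np.ndarray  # (M,)
    continent: dict[str, np.ndarray]  # name -> (M,)
    subpop: dict[tuple[str, str], np.ndarray]  # (continent, subpop) -> (M,)


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    truth: pd.DataFrame  # id, continent, subpop, region, country + q_* columns
    relative_pairs: list[tuple[str, str]] = field(default_factory=list)
    continent_names: list[str] = field(default_factory=list)

    @property
    def truth_q(self) -> np.ndarray:
        cols = [f"q_{c}" for c in self.continent_names]
        return self.truth[cols].to_numpy(dtype=float)


def _bn_draw(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Balding-Nichols Beta draw around p with divergence f; f=0 copies p."""
    if f >= 1:
        raise ValueError("divergence F = 1 gives undefined Beta parameters")
    if f == 0:
        return p.copy()
    ratio = (1 - f) / f
    out = rng.beta(p * ratio, (1 - p) * ratio)
    return np.clip(out, FREQ_CLAMP, 1 - FREQ_CLAMP)


def draw_hierarchical_frequencies(
    spec: PopulationSpec, rng: np.random.Generator | None = None
) -> FrequencyTable:
    """Draw ancestral, continental, and subpopulation allele frequencies."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    lo, hi = spec.maf_range
    p = rng.uniform(lo, hi, size=spec.n_snps)
    p = np.clip(p, FREQ_CLAMP, 1 - FREQ_CLAMP)
    continent = {}
    subpop = {}
    for cont in spec.continents:
        pc = _bn_draw(rng, p, cont.fc)
        continent[cont.name] = pc
        for sp in cont.subpops:
            subpop[(cont.name, sp.name)] = _bn_draw(rng, pc, sp.fs)
    return FrequencyTable(ancestral=p, continent=continent, subpop=subpop)


def _variant_frame(spec: PopulationSpec, m: int) -> pd.DataFrame:
    per_chrom = int(np.ceil(m / spec.n_chromosomes))
    idx = np.arange(m)
    chrom = (idx // per_chrom + 1).astype(str)
    pos = (idx % per_chrom + 1) * spec.snp_spacing_bp
    bases = np.array(["A", "C", "G", "T"])
    ref = bases[idx % 4]
    alt = bases[(idx + 1) % 4]
    return pd.DataFrame(
        {"id": [f"rs{i + 1}" for i in idx], "chrom": chrom, "pos": pos, "ref": ref, "alt": alt}
    )


def simulate_genotypes(
    freqs: FrequencyTable, spec: PopulationSpec, rng: np.random.Generator | None = None
) -> SimulatedCohort:
    """Sample genotypes for every subpopulation and admixed block."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    m = spec.n_snps
    names = spec.continent_names
    K = len(names)
    fcont = np.stack([freqs.continent[c] for c in names])  # (K, M)

    blocks: list[np.ndarray] = []
    rows: list[dict] = []
    qs: list[np.ndarray] = []

    for cont in spec.continents:
        k = names.index(cont.name)
        for sp in cont.subpops:
            if sp.n == 0:
                continue
            pf = freqs.subpop[(cont.name, sp.name)]
            g = rng.binomial(2, pf[None, :], size=(sp.n, m)).astype(np.int8)
            blocks.append(g)
            onehot = np.zeros(K)
            onehot[k] = 1.0
            for i in range(sp.n):
                rows.append(
                    {
                        "id": f"{sp.name}_{i + 1:04d}",
                        "continent": cont.name,
                        "subpop": sp.name,
                        "is_reference": sp.is_reference,
                        "is_founder": True,
                    }
                )
                qs.append(onehot)

    for bi, blk in enumerate(spec.admixed_blocks):
        if blk.n == 0:
            continue
        q = rng.dirichlet(blk.alpha, size=blk.n)  # (n, K)
        cumq = np.cumsum(q, axis=1)
        g = np.zeros((blk.n, m), dtype=np.int8)
        snp_idx = np.arange(m)[None, :]
        for _copy in range(2):
            u = rng.random((blk.n, m))
            kidx = (u[:, :, None] > cumq[:, None, :]).sum(axis=2)
            pmat = fcont[kidx, snp_idx]
            g += (rng.random((blk.n, m)) < pmat).astype(np.int8)
        blocks.append(g)
        for i in range(blk.n):
            rows.append(
                {
                    "id": f"ADM{bi + 1}_{i + 1:04d}",
                    "continent": None,
                    "subpop": None,
                    "is_reference": False,
                    "is_founder": True,
                }
            )
            qs.append(q[i])

    if not blocks:
        raise ValueError("spec yields zero samples")
    calls = np.vstack(blocks)
    truth = pd.DataFrame(rows)
    for k, c in enumerate(names):
        truth[f"q_{c}"] = [q[k] for q in qs]
    truth["region"] = pd.NA
    truth["country"] = pd.NA

    samples = pd.DataFrame(
        {
            "id": truth["id"],
            "population_label": [
                cont if ref else pd.NA
                for cont, ref in zip(truth["continent"], truth["is_reference"])
            ],
        }
    )
    gm = GenotypeMatrix(samples=samples, variants=_variant_frame(spec, m), calls=calls)
    return SimulatedCohort(genotypes=gm, truth=truth, continent_names=names)


def add_relatives(
    cohort: SimulatedCohort,
    n_pairs: int,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> SimulatedCohort:
    """Append ``n_pairs`` offspring of random same-subpopulation founders.

    Each offspring receives one Mendelian allele per SNP from each parent;
    both parent-child id pairs are recorded.
    """
    if n_pairs == 0:
        return cohort
    if rng is None:
        rng = np.random.default_rng(seed)
    truth = cohort.truth
    # reference panels do not contribute relatives to the target cohort
    founders = truth[
        truth["is_founder"] & truth["subpop"].notna() & ~truth["is_reference"]
    ]
    by_subpop = founders.groupby("subpop", sort=False).indices
    eligible = [sp for sp, idx in by_subpop.items() if len(idx) >= 2]
    if not eligible:
        raise ValueError("no subpopulation has >= 2 founders")
    needed = 2 * n_pairs
    total = sum(len(by_subpop[sp]) for sp in eligible)
    if total < needed:
        raise ValueError(f"need {needed} founders for {n_pairs} pairs, have {total}")

    gm = cohort.genotypes
    calls = gm.calls
    new_rows = []
    new_calls = []
    pairs = list(cohort.relative_pairs)
    qcols = [f"q_{c}" for c in cohort.continent_names]
    for i in range(n_pairs):
        sp = eligible[rng.integers(len(eligible))]
        p1_loc, p2_loc = rng.choice(by_subpop[sp], size=2, replace=False)
        g1 = calls[p1_loc].astype(np.int16)
        g2 = calls[p2_loc].astype(np.int16)
        child = rng.binomial(1, g1 / 2.0) + rng.binomial(1, g2 / 2.0)
        new_calls.append(child.astype(np.int8))
        row = truth.iloc[p1_loc].to_dict()
        cid = f"{sp}_off{i + 1:03d}"
        row.update({"id": cid, "is_founder": False, "region": pd.NA, "country": pd.NA})
        q = (truth.iloc[p1_loc][qcols].to_numpy(float) + truth.iloc[p2_loc][qcols].to_numpy(float)) / 2
        for c, v in zip(qcols, q):
            row[c] = v
        new_rows.append(row)
        pairs.append((truth["id"].iat[p1_loc], cid))
        pairs.append((truth["id"].iat[p2_loc], cid))

    new_truth = pd.concat([truth, pd.DataFrame(new_rows)], ignore_index=True)
    add_samples = pd.DataFrame(
        {"id": [r["id"] for r in new_rows], "population_label": pd.NA}
    )
    new_gm = GenotypeMatrix(
        samples=pd.concat([gm.samples, add_samples], ignore_index=True),
        variants=gm.variants,
        calls=np.vstack([calls, np.stack(new_calls)]),
    )
    return SimulatedCohort(
        genotypes=new_gm,
        truth=new_truth,
        relative_pairs=pairs,
        continent_names=cohort.continent_names,
    )


def assign_birth_labels(
    cohort: SimulatedCohort,
    spec: PopulationSpec,
    rng: np.random.Generator | None = None,
) -> SimulatedCohort:
    """Attach region/country-of-birth labels correlated with subpopulation.

    With probability ``label_concordance`` a sample gets its own
    subpopulation's region (and a country drawn by that subpopulation's
    weights); otherwise a uniformly chosen other region.  A
    ``missing_label_fraction`` of samples gets no label.  Samples without a
    subpopulation (admixed) stay unlabeled.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    sub_info: dict[str, SubpopSpec] = {}
    for cont in spec.continents:
        for sp in cont.subpops:
            sub_info[sp.name] = sp
    regions = sorted({sp.region for sp in sub_info.values() if sp.region is not None})
    region_countries: dict[str, list[str]] = {r: [] for r in regions}
    for sp in sub_info.values():
        if sp.region is not None:
            region_countries[sp.region].extend(sp.countries or [f"{sp.region}_country"])

    truth = cohort.truth.copy()
    region_col = []
    country_col = []
    for _, row in truth.iterrows():
        sp_name = row["subpop"]
        if sp_name is None or pd.isna(sp_name) or sub_info[sp_name].region is None:
            region_col.append(pd.NA)
            country_col.append(pd.NA)
            continue
        sp = sub_info[sp_name]
        if rng.random() < spec.label_concordance or len(regions) < 2:
            region = sp.region
            if sp.countries:
                cnames = list(sp.countries)
                w = np.array(list(sp.countries.values()), dtype=float)
                country = cnames[rng.choice(len(cnames), p=w / w.sum())]
            else:
                country = f"{region}_country"
        else:
            others = [r for r in regions if r != sp.region]
            region = others[rng.integers(len(others))]
            pool = region_countries[region]
            country = pool[rng.integers(len(pool))]
        if rng.random() < spec.missing_label_fraction:
            region, country = pd.NA, pd.NA
        region_col.append(region)
        country_col.append(country)
    truth["region"] = region_col
    truth["country"] = country_col

    gm = cohort.genotypes
    samples = gm.samples.copy()
    samples["birth_region"] = truth["region"].to_numpy()
    samples["birth_country"] = truth["country"].to_numpy()
    new_gm = GenotypeMatrix(samples=samples, variants=gm.variants, calls=gm.calls)
    return SimulatedCohort(
        genotypes=new_gm,
        truth=truth,
        relative_pairs=cohort.relative_pairs,
        continent_names=cohort.continent_names,
    )


def _add_ld_blocks(
    cohort: SimulatedCohort, spec: PopulationSpec, rng: np.random.Generator
) -> SimulatedCohort:
    """Duplicate tagged SNPs with small flip probability to create LD."""
    blk = spec.ld_block
    gm = cohort.genotypes
    n_tag = min(blk.n_tagged, gm.n_variants)
    tag_idx = np.sort(rng.choice(gm.n_variants, size=n_tag, replace=False))
    g = gm.calls[:, tag_idx].astype(np.int16)
    miss = g < 0
    g = np.clip(g, 0, 2)
    flips_down = rng.binomial(g, blk.eps)
    flips_up = rng.binomial(2 - g, blk.eps)
    tag_calls = (g - flips_down + flips_up).astype(np.int8)
    tag_calls[miss] = -1

    tag_vars = gm.variants.iloc[tag_idx].copy()
    tag_vars["id"] = [f"{v}_tag" for v in tag_vars["id"]]
    tag_vars["pos"] = tag_vars["pos"] + blk.offset_bp

    variants = pd.concat([gm.variants, tag_vars], ignore_index=True)
    calls = np.hstack([gm.calls, tag_calls])
    order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy()))
    new_gm = GenotypeMatrix(
        samples=gm.samples, variants=variants.iloc[order], calls=calls[:, order]
    )
    return SimulatedCohort(
        genotypes=new_gm,
        truth=cohort.truth,
        relative_pairs=cohort.relative_pairs,
        continent_names=cohort.continent_names,
    )


def simulate(spec: PopulationSpec) -> SimulatedCohort:
    """Run the full generator: frequencies, genotypes, relatives, labels."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    freqs = draw_hierarchical_frequencies(spec, rng)
    cohort = simulate_genotypes(freqs, spec, rng)
    cohort = add_relatives(cohort, spec.relative_pairs, rng)
    cohort = assign_birth_labels(cohort, spec, rng)
    if spec.ld_block is not None:
        cohort = _add_ld_blocks(cohort, spec, rng)
    return cohort


def write_truth_tables(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write truth tables as TSV (sample truth + relative pairs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_path = outdir / "truth_samples.tsv"
    cohort.truth.to_csv(truth_path, sep="\t", index=False)
    pairs_path = outdir / "truth_relative_pairs.tsv"
    pd.DataFrame(cohort.relative_pairs, columns=["id1", "id2"]).to_csv(
        pairs_path, sep="\t", index=False
    )
    return {"truth_samples": truth_path, "truth_relative_pairs": pairs_path}
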