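"""Genotype input/output and id-based dataset merging.

Supported formats: VCF 4.x (GT field only, read via cyvcf2, written as
plain text), PLINK text PED/MAP (read + write, with a ``--ref-allele``
style sidecar so allele coding survives a round trip), and PLINK binary
BED/BIM/FAM (read-only).  Merging intersects variants by identifier,
never by position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import MISSING, GenotypeMatrix

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a (possibly bgzipped) VCF into a genotype matrix.

    Diploid GT fields map to alt-allele counts; phased and unphased calls
    are treated identically.  Half-calls are set to missing and counted in
    a warning; multi-allelic records are skipped with a warning.  A
    non-diploid call raises.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    var_rows = []
    columns = []
    n_half = 0
    n_multi = 0
    for line_no, rec in enumerate(vcf, start=1):
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        ref, alt = rec.REF, rec.ALT[0]
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        col = np.full(len(sample_ids), MISSING, dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            alleles = gt[:-1]  # last entry is the phased flag
            if len(alleles) != 2:
                raise ValueError(
                    f"non-diploid call for sample {sample_ids[i]} at record "
                    f"{line_no} ({rec.CHROM}:{rec.POS})"
                )
            a, b = alleles
            if a < 0 and b < 0:
                continue
            if a < 0 or b < 0:
                n_half += 1
                continue
            col[i] = (a > 0) + (b > 0)
        var_rows.append((vid, rec.CHROM, rec.POS, ref, alt))
        columns.append(col)
    vcf.close()

    if n_half:
        warnings.warn(f"{n_half} half-calls set to missing", stacklevel=2)
    if n_multi:
        warnings.warn(f"{n_multi} multi-allelic records skipped", stacklevel=2)

    variants = pd.DataFrame(var_rows, columns=["id", "chrom", "pos", "ref", "alt"])
    calls = (
        np.column_stack(columns)
        if columns
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    samples = pd.DataFrame({"id": sample_ids})
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(cohort: GenotypeMatrix, path: str | Path) -> Path:
    """Write a minimal GT-only VCF 4.2 text file."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(cohort.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "FORMAT"]
        fh.write("\t".join(header[:7] + ["INFO", "FORMAT"] + cohort.sample_ids) + "\n")
        for j, var in cohort.variants.iterrows():
            gts = "\t".join(_GT_STR[int(g)] for g in cohort.calls[:, j])
            row = f"{var.chrom}\t{var.pos}\t{var.id}\t{var.ref}\t{var.alt}\t.\t.\t.\tGT"
            fh.write(row + ("\t" + gts if cohort.n_samples else "") + "\n")
    return path


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

def write_ped(cohort: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write PLINK text PED/MAP plus a ``<prefix>.ref`` allele sidecar.

    The sidecar (variant id, ref allele, alt allele per line) pins the
    alt-allele coding, which plain PED/MAP cannot express; it mirrors the
    role of PLINK's ``--ref-allele`` input file.
    """
    prefix = Path(prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    ref_path = prefix.with_suffix(".ref")
    with open(map_path, "w") as fh:
        for _, var in cohort.variants.iterrows():
            fh.write(f"{var.chrom}\t{var.id}\t0\t{var.pos}\n")
    refs = cohort.variants["ref"].to_numpy()
    alts = cohort.variants["alt"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(cohort.sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            row = cohort.calls[i]
            for j in range(cohort.n_variants):
                g = row[j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [refs[j], refs[j]]
                elif g == 1:
                    fields += [refs[j], alts[j]]
                else:
                    fields += [alts[j], alts[j]]
            fh.write(" ".join(fields) + "\n")
    with open(ref_path, "w") as fh:
        for _, var in cohort.variants.iterrows():
            fh.write(f"{var.id}\t{var.ref}\t{var.alt}\n")
    return ped_path, map_path


def read_ped(prefix: str | Path) -> GenotypeMatrix:
    """Read PLINK text PED/MAP.

    Allele coding comes from a ``<prefix>.ref`` sidecar when present;
    otherwise ref is taken as the major observed allele (ties broken
    alphabetically).
    """
    prefix = Path(prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    ref_path = prefix.with_suffix(".ref")
    for p in (map_path, ped_path):
        if not p.exists():
            raise FileNotFoundError(p)

    var_rows = []
    with open(map_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"malformed MAP record at line {line_no} of {map_path}")
            chrom, vid, _cm, pos = parts[:4]
            var_rows.append((vid, chrom, int(pos)))
    n_var = len(var_rows)

    sample_ids = []
    rows_a = []
    rows_b = []
    with open(ped_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6 + 2 * n_var:
                raise ValueError(
                    f"malformed PED record at line {line_no} of {ped_path}: "
                    f"expected {6 + 2 * n_var} fields, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            rows_a.append(parts[6::2])
            rows_b.append(parts[7::2])
    a = np.array(rows_a, dtype="U1")
    b = np.array(rows_b, dtype="U1")

    if ref_path.exists():
        side = pd.read_csv(ref_path, sep="\t", header=None, names=["id", "ref", "alt"])
        alleles = dict(zip(side["id"], zip(side["ref"], side["alt"])))
    else:
        alleles = {}

    variants = []
    calls = np.full((len(sample_ids), n_var), MISSING, dtype=np.int8)
    for j, (vid, chrom, pos) in enumerate(var_rows):
        col_a, col_b = a[:, j], b[:, j]
        observed = sorted(
            {al for al in np.concatenate([col_a, col_b]) if al != "0"}
        )
        if len(observed) > 2:
            raise ValueError(f"variant {vid!r} has >2 alleles in PED file")
        if vid in alleles:
            ref, alt = alleles[vid]
        else:
            if not observed:
                ref, alt = "N", "A"
            elif len(observed) == 1:
                ref, alt = observed[0], "N"
            else:
                counts = {
                    al: int(np.sum(col_a == al) + np.sum(col_b == al))
                    for al in observed
                }
                # major allele is ref; alphabetical tie-break
                ref = sorted(observed, key=lambda al: (-counts[al], al))[0]
                alt = next(al for al in observed if al != ref)
        nonmiss = (col_a != "0") & (col_b != "0")
        calls[nonmiss, j] = (col_a[nonmiss] == alt).astype(np.int8) + (
            col_b[nonmiss] == alt
        ).astype(np.int8)
        variants.append((vid, chrom, pos, ref, alt))

    variants = pd.DataFrame(variants, columns=["id", "chrom", "pos", "ref", "alt"])
    samples = pd.DataFrame({"id": sample_ids})
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


# ---------------------------------------------------------------------------
# PLINK binary BED (read-only)
# ---------------------------------------------------------------------------

# 2-bit codes, variant-major: 0b00 hom A1, 0b01 missing, 0b10 het, 0b11 hom A2.
# A2 is treated as ref (PLINK's major-allele default), so alt counts A1.
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def read_bed(prefix: str | Path) -> GenotypeMatrix:
    """Read PLINK binary BED/BIM/FAM (SNP-major layout only)."""
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise FileNotFoundError(p)

    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, usecols=[1], names=["id"], dtype=str)

    raw = np.fromfile(bed_path, dtype=np.uint8)
    if len(raw) < 3 or raw[0] != 0x6C or raw[1] != 0x1B:
        raise ValueError(f"{bed_path} is not a PLINK BED file (bad magic)")
    if raw[2] != 0x01:
        raise ValueError("only SNP-major BED files are supported")
    n_samples, n_var = len(fam), len(bim)
    bytes_per_var = (n_samples + 3) // 4
    body = raw[3:]
    if len(body) != bytes_per_var * n_var:
        raise ValueError(f"{bed_path} truncated: unexpected byte count")
    body = body.reshape(n_var, bytes_per_var)
    # unpack 2-bit fields, little-endian within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(n_var, -1)[:, :n_samples]
    calls = _BED_DECODE[codes].T.copy()

    variants = pd.DataFrame(
        {
            "id": bim["id"],
            "chrom": bim["chrom"],
            "pos": bim["pos"],
            "ref": bim["a2"],
            "alt": bim["a1"],
        }
    )
    samples = pd.DataFrame({"id": fam["id"]})
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


# ---------------------------------------------------------------------------
# dispatch + metadata
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes, inferring format from the extension when not given."""
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        if suffix == "gz" and path.name.endswith(".vcf.gz"):
            suffix = "vcf"
        format = {"vcf": "vcf", "ped": "ped", "bed": "bed"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer genotype format from {path.name!r}")
    if format == "vcf":
        return read_vcf(path)
    if format == "ped":
        return read_ped(path.with_suffix(""))
    if format == "bed":
        return read_bed(path.with_suffix(""))
    raise ValueError(f"unsupported format {format!r}")


def write_genotypes(cohort: GenotypeMatrix, path: str | Path, format: str = "vcf"):
    if format == "vcf":
        return write_vcf(cohort, path)
    if format == "ped":
        return write_ped(cohort, Path(path).with_suffix(""))
    raise ValueError(f"unsupported write format {format!r} (BED is read-only)")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """TSV with sample id plus optional population/birth label columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "id" not in df.columns:
        raise ValueError("sample metadata must have an 'id' column")
    return df


def attach_metadata(cohort: GenotypeMatrix, meta: pd.DataFrame) -> GenotypeMatrix:
    merged = cohort.samples[["id"]].merge(meta, on="id", how="left")
    return GenotypeMatrix(samples=merged, variants=cohort.variants, calls=cohort.calls)


# ---------------------------------------------------------------------------
# merge
# ---------------------------------------------------------------------------

@dataclass
class MergeReport:
    n_shared_ids: int = 0
    n_duplicate_a: int = 0
    n_duplicate_b: int = 0
    n_allele_mismatch: int = 0
    n_swapped: int = 0
    n_strand_flipped: int = 0
    n_ambiguous_kept: int = 0
    n_merged: int = 0
    dropped_ids: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (k, getattr(self, k))
            for k in (
                "n_shared_ids",
                "n_duplicate_a",
                "n_duplicate_b",
                "n_allele_mismatch",
                "n_swapped",
                "n_strand_flipped",
                "n_ambiguous_kept",
                "n_merged",
            )
        ]
        return pd.DataFrame(rows, columns=["class", "count"])


def _is_ambiguous(ref: str, alt: str) -> bool:
    return _COMPLEMENT.get(ref) == alt


def merge_by_id(
    a: GenotypeMatrix, b: GenotypeMatrix
) -> tuple[GenotypeMatrix, MergeReport]:
    """Merge two cohorts on shared variant ids, concatenating samples.

    Keeps only ids present in both inputs, drops ids duplicated within
    either input, reconciles swapped ref/alt (recoding ``b`` 0<->2) and
    strand-flipped alleles, and drops irreconcilable allele pairs.
    Strand-ambiguous (A/T, C/G) SNPs are kept on a literal allele match,
    with a warning.
    """
    report = MergeReport()

    ids_a = pd.Series(a.variant_ids)
    ids_b = pd.Series(b.variant_ids)
    dup_a = set(ids_a[ids_a.duplicated(keep=False)])
    dup_b = set(ids_b[ids_b.duplicated(keep=False)])
    report.n_duplicate_a = len(dup_a)
    report.n_duplicate_b = len(dup_b)

    shared = [v for v in a.variant_ids if v in set(b.variant_ids)]
    report.n_shared_ids = len(shared)
    usable = [v for v in shared if v not in dup_a and v not in dup_b]

    b_index = {v: j for j, v in enumerate(b.variant_ids)}
    a_index = {v: j for j, v in enumerate(a.variant_ids)}

    keep_a_idx: list[int] = []
    keep_b_idx: list[int] = []
    recode_b: list[bool] = []
    n_ambig = 0
    for vid in usable:
        ja, jb = a_index[vid], b_index[vid]
        ra, aa = a.variants["ref"].iat[ja], a.variants["alt"].iat[ja]
        rb, ab = b.variants["ref"].iat[jb], b.variants["alt"].iat[jb]
        flip_rb = _COMPLEMENT.get(rb, "?")
        flip_ab = _COMPLEMENT.get(ab, "?")
        if (rb, ab) == (ra, aa):
            swap, flipped = False, False
        elif (ab, rb) == (ra, aa) and not _is_ambiguous(ra, aa):
            swap, flipped = True, False
        elif (flip_rb, flip_ab) == (ra, aa) and not _is_ambiguous(ra, aa):
            swap, flipped = False, True
        elif (flip_ab, flip_rb) == (ra, aa) and not _is_ambiguous(ra, aa):
            swap, flipped = True, True
        else:
            report.n_allele_mismatch += 1
            report.dropped_ids.append(vid)
            continue
        if _is_ambiguous(ra, aa):
            n_ambig += 1
        report.n_swapped += swap
        report.n_strand_flipped += flipped
        keep_a_idx.append(ja)
        keep_b_idx.append(jb)
        recode_b.append(swap)

    if not keep_a_idx:
        raise ValueError("no overlapping variants between inputs after filtering")
    if n_ambig:
        report.n_ambiguous_kept = n_ambig
        warnings.warn(
            f"{n_ambig} strand-ambiguous (A/T or C/G) SNPs kept on literal match",
            stacklevel=2,
        )

    calls_a = a.calls[:, keep_a_idx]
    calls_b = b.calls[:, keep_b_idx].copy()
    swap_mask = np.array(recode_b, dtype=bool)
    if swap_mask.any():
        sub = calls_b[:, swap_mask]
        recoded = sub.copy()
        recoded[sub == 0] = 2
        recoded[sub == 2] = 0
        calls_b[:, swap_mask] = recoded

    overlap = set(a.sample_ids) & set(b.sample_ids)
    if overlap:
        raise ValueError(f"sample ids present in both inputs: {sorted(overlap)[:5]}")

    merged = GenotypeMatrix(
        samples=pd.concat([a.samples, b.samples], ignore_index=True),
        variants=a.variants.iloc[keep_a_idx],
        calls=np.vstack([calls_a, calls_b]),
    )
    report.n_merged = merged.n_variants
    return merged, report
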