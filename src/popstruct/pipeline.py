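"""End-to-end orchestration: merge -> global LD prune -> supervised
admixture -> CAG assignment -> per-CAG (unrelated selection, LD prune,
PCA with projection and outlier removal, top-PC selection, K-means,
correspondence analysis, pairwise Fst).

Each run produces a manifest recording, per stage, the parameters and
the sample/variant counts flowing in and out, so count conservation can
be audited after the fact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import admixture as adm
from . import ca as ca_mod
from . import cluster as cl
from . import fst as fst_mod
from . import pca as pca_mod
from . import qc
from . import relatedness as rel
from . import sim
from .cohort import GenotypeMatrix
from .io import merge_by_id

log = logging.getLogger("popstruct.pipeline")

STAGES = [
    "merge",
    "global_ld_prune",
    "supervised_admixture",
    "cag_assignment",
    "unrelated_selection",
    "cag_ld_prune",
    "pca",
    "top_pc_selection",
    "kmeans",
    "correspondence",
    "fst",
]


@dataclass
class PipelineConfig:
    # synthetic mode
    synthetic: sim.PopulationSpec | None = None
    # real-data mode
    target_path: str | None = None
    reference_path: str | None = None
    metadata_path: str | None = None
    region_map_path: str | None = None
    exclude_regions_path: str | None = None
    # stage parameters (defaults as documented per stage)
    cag_threshold: float = 0.8
    admix_tol: float = 1e-6
    admix_max_iter: int = 1000
    prune_window_kb: float = 50.0
    prune_step_kb: float = 10.0
    prune_r2: float = 0.025
    cag_prune_r2: dict[str, float] = field(default_factory=dict)
    global_prune_maf: float = 0.05
    cag_prune_maf: float = 0.01
    rel_cutoff: float = 0.025
    rel_maf: float = 0.05
    n_pcs: int = 20
    outlier_pcs: int = 10
    outlier_sigma: float = 6.0
    outlier_iterations: int = 5
    top_pc_override: dict[str, int] = field(default_factory=dict)
    kmin: int = 2
    kmax: int = 20
    kmeans_restarts: int = 25
    k_override: dict[str, int] = field(default_factory=dict)
    ca_min_count: int = 10
    seed: int = 0
    outdir: str = "popstruct_run"

    def validate(self) -> None:
        if not 0 < self.cag_threshold <= 1:
            raise ValueError(f"cag_threshold must be in (0,1], got {self.cag_threshold}")
        for name, val in (
            ("prune_r2", self.prune_r2),
            ("global_prune_maf", self.global_prune_maf),
            ("cag_prune_maf", self.cag_prune_maf),
        ):
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must be in [0,1], got {val}")
        if self.prune_step_kb <= 0 or self.prune_window_kb < self.prune_step_kb:
            raise ValueError("require prune_window_kb >= prune_step_kb > 0")
        if self.outlier_sigma <= 0:
            raise ValueError("outlier_sigma must be > 0")
        if not 2 <= self.kmin <= self.kmax:
            raise ValueError("require 2 <= kmin <= kmax")
        if self.seed is None:
            raise ValueError("seed is required")
        if self.synthetic is None and (
            self.target_path is None or self.reference_path is None
        ):
            raise ValueError("either a synthetic spec or target+reference paths required")
        if self.synthetic is not None:
            self.synthetic.validate()

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = d.pop("synthetic", None)
        cfg = cls(
            synthetic=sim.PopulationSpec.from_dict(syn) if syn else None, **d
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunManifest:
    stages: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)
    base_dir: Path | None = None

    def _rel(self, path) -> str:
        path = Path(path)
        if self.base_dir is not None:
            try:
                return str(path.relative_to(self.base_dir))
            except ValueError:
                pass
        return str(path)

    def add(self, stage: str, params: dict, counts: dict, outputs=(), input_hash=""):
        self.stages.append(
            {
                "stage": stage,
                "params": params,
                "counts": counts,
                "outputs": [self._rel(o) for o in outputs],
                "input_hash": input_hash,
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {"stages": self.stages, "summary": self.summary},
            indent=2,
            sort_keys=True,
            default=str,
        )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path

    def manifest_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _cohort_hash(cohort: GenotypeMatrix) -> str:
    h = hashlib.sha256()
    h.update("\x00".join(cohort.sample_ids).encode())
    h.update("\x00".join(cohort.variant_ids).encode())
    h.update(np.ascontiguousarray(cohort.calls).tobytes())
    return h.hexdigest()[:16]


def _load_inputs(config: PipelineConfig):
    """Return (target cohort, reference cohort, reference labels, truth)."""
    if config.synthetic is not None:
        cohort = sim.simulate(config.synthetic)
        gm = cohort.genotypes
        is_ref = gm.samples["population_label"].notna().to_numpy()
        ref_ids = gm.samples.loc[is_ref, "id"].tolist()
        target_ids = gm.samples.loc[~is_ref, "id"].tolist()
        return gm.subset_samples(target_ids), gm.subset_samples(ref_ids), cohort
    from .io import attach_metadata, read_genotypes, read_sample_metadata

    target = read_genotypes(config.target_path)
    reference = read_genotypes(config.reference_path)
    if config.metadata_path:
        meta = read_sample_metadata(config.metadata_path)
        target = attach_metadata(target, meta)
        reference = attach_metadata(reference, meta)
    return target, reference, None


def _reference_labels(reference: GenotypeMatrix) -> dict[str, list[str]]:
    labels: dict[str, list[str]] = {}
    for sid, pop in zip(reference.sample_ids, reference.samples["population_label"]):
        if pd.notna(pop):
            labels.setdefault(str(pop), []).append(sid)
    if not labels:
        raise ValueError("reference cohort has no population labels")
    return labels


def run_framework(config: PipelineConfig) -> RunManifest:
    """Execute every stage in order and return the populated manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(base_dir=outdir)
    t0 = time.time()

    exclude = (
        qc.read_regions_bed(config.exclude_regions_path)
        if config.exclude_regions_path
        else []
    )

    # -- stage 1: merge -------------------------------------------------
    target, reference, truth = _load_inputs(config)
    try:
        merged, report = merge_by_id(target, reference)
    except ValueError as exc:
        raise RuntimeError(f"stage merge failed: {exc}") from exc
    report.to_frame().to_csv(outdir / "merge_report.tsv", sep="\t", index=False)
    ref_labels = _reference_labels(reference)
    target_ids = target.sample_ids
    ref_ids = reference.sample_ids
    manifest.add(
        "merge",
        {"n_target": target.n_samples, "n_reference": reference.n_samples},
        {
            "samples_in": target.n_samples + reference.n_samples,
            "samples_out": merged.n_samples,
            "variants_in": target.n_variants,
            "variants_out": merged.n_variants,
        },
        outputs=[outdir / "merge_report.tsv"],
        input_hash=_cohort_hash(merged),
    )

    # -- stage 2: global LD prune on the first reference group ----------
    first_ref_group = sorted(ref_labels)[0]
    prune_params = qc.PruneParams(
        window_kb=config.prune_window_kb,
        step_kb=config.prune_step_kb,
        r2_threshold=config.prune_r2,
        maf=config.global_prune_maf,
        exclude_regions=exclude,
        reference_sample_ids=ref_labels[first_ref_group],
    )
    try:
        kept = qc.ld_prune(merged, prune_params)
    except ValueError as exc:
        raise RuntimeError(f"stage global_ld_prune failed: {exc}") from exc
    qc.write_keep_list(kept, outdir / "pruned_variants.txt")
    pruned = merged.subset_variants(kept)
    manifest.add(
        "global_ld_prune",
        {
            "window_kb": config.prune_window_kb,
            "step_kb": config.prune_step_kb,
            "r2": config.prune_r2,
            "maf": config.global_prune_maf,
            "reference_group": first_ref_group,
        },
        {
            "samples_in": merged.n_samples,
            "samples_out": pruned.n_samples,
            "variants_in": merged.n_variants,
            "variants_out": pruned.n_variants,
        },
        outputs=[outdir / "pruned_variants.txt"],
    )

    # -- stage 3: supervised admixture ---------------------------------
    try:
        model = adm.reference_frequencies(pruned, ref_labels)
        target_pruned = pruned.subset_samples(target_ids)
        props = adm.fit_q(
            target_pruned, model, tol=config.admix_tol, max_iter=config.admix_max_iter
        )
        ref_fst_matrix, ref_fst_mean = adm.reference_pairwise_fst(pruned, ref_labels)
    except ValueError as exc:
        raise RuntimeError(f"stage supervised_admixture failed: {exc}") from exc
    manifest.add(
        "supervised_admixture",
        {
            "K": len(model.populations),
            "tol": config.admix_tol,
            "max_iter": config.admix_max_iter,
            "reference_mean_fst": round(ref_fst_mean, 6),
        },
        {
            "samples_in": len(target_ids),
            "samples_out": len(target_ids),
            "variants_in": pruned.n_variants,
            "variants_out": pruned.n_variants,
        },
    )

    # -- stage 4: CAG assignment at the threshold ----------------------
    assignments = adm.assign_cag(props, threshold=config.cag_threshold)
    adm.write_q_table(props, assignments, outdir / "ancestry_q.tsv")
    cag_members: dict[str, list[str]] = {}
    for sid, cag in zip(assignments["id"], assignments["cag"]):
        if cag != adm.UNASSIGNED:
            cag_members.setdefault(cag, []).append(sid)
    n_assigned = sum(len(v) for v in cag_members.values())
    manifest.add(
        "cag_assignment",
        {"threshold": config.cag_threshold},
        {
            "samples_in": len(target_ids),
            "samples_out": n_assigned,
            "unassigned": len(target_ids) - n_assigned,
            "per_cag": {k: len(v) for k, v in sorted(cag_members.items())},
        },
        outputs=[outdir / "ancestry_q.tsv"],
    )

    # -- stages 5-11: per-CAG analyses ---------------------------------
    per_cag_results: dict[str, dict] = {}
    stage_counts: dict[str, dict] = {s: {} for s in STAGES[4:]}
    stage_outputs: dict[str, list] = {s: [] for s in STAGES[4:]}

    for cag in sorted(cag_members):
        cdir = outdir / f"cag_{cag}"
        cdir.mkdir(exist_ok=True)
        members = cag_members[cag] + ref_labels.get(cag, [])
        cohort = merged.subset_samples(members)
        target_members = [s for s in members if s in set(cag_members[cag])]

        # 5. unrelated selection (MAF filter then GRM, PLINK-style cutoff)
        try:
            grm_matrix = rel.grm(cohort, maf_floor=config.rel_maf)
            pairs = rel.related_pairs(grm_matrix, cutoff=config.rel_cutoff)
            keep, drop = rel.greedy_unrelated(pairs, members)
        except ValueError as exc:
            raise RuntimeError(f"stage unrelated_selection[{cag}] failed: {exc}") from exc
        rel.write_pairs(pairs, cdir / "related_pairs.tsv")
        rel.write_id_list(keep, cdir / "unrelated_ids.txt")
        stage_counts["unrelated_selection"][cag] = {
            "samples_in": len(members),
            "samples_out": len(keep),
            "related_pairs": len(pairs),
            "dropped": len(drop),
        }
        stage_outputs["unrelated_selection"] += [cdir / "related_pairs.tsv"]

        # 6. per-CAG LD prune on the unrelated members
        cag_params = qc.PruneParams(
            window_kb=config.prune_window_kb,
            step_kb=config.prune_step_kb,
            r2_threshold=config.cag_prune_r2.get(cag, config.prune_r2),
            maf=config.cag_prune_maf,
            exclude_regions=exclude,
            reference_sample_ids=keep,
        )
        try:
            cag_kept = qc.ld_prune(cohort, cag_params)
        except ValueError as exc:
            raise RuntimeError(f"stage cag_ld_prune[{cag}] failed: {exc}") from exc
        qc.write_keep_list(cag_kept, cdir / "pruned_variants.txt")
        cag_cohort = cohort.subset_variants(cag_kept)
        stage_counts["cag_ld_prune"][cag] = {
            "samples_in": len(keep),
            "samples_out": len(keep),
            "variants_in": cohort.n_variants,
            "variants_out": cag_cohort.n_variants,
        }
        stage_outputs["cag_ld_prune"] += [cdir / "pruned_variants.txt"]

        # 7. PCA: fit on unrelated target members, project relateds + refs
        fit_ids = [s for s in keep if s in set(target_members)]
        project_ids = [s for s in members if s not in set(fit_ids)]
        try:
            pmodel = pca_mod.remove_outliers(
                cag_cohort,
                fit_sample_ids=fit_ids,
                n_pcs=config.n_pcs,
                n_outlier_pcs=config.outlier_pcs,
                sigma=config.outlier_sigma,
                iterations=config.outlier_iterations,
            )
            if project_ids:
                pca_mod.attach_projection(cag_cohort, pmodel, project_ids)
        except ValueError as exc:
            raise RuntimeError(f"stage pca[{cag}] failed: {exc}") from exc
        pca_mod.write_scores(pmodel, cdir / "pc_scores.tsv")
        pca_mod.write_eigenvalues(pmodel, cdir / "eigenvalues.txt")
        outliers = pmodel.outliers
        stage_counts["pca"][cag] = {
            "samples_in": len(fit_ids),
            "samples_out": len(pmodel.fit_sample_ids),
            "outliers_removed": len(outliers),
            "projected": len(project_ids),
            "n_pcs": len(pmodel.eigenvalues),
        }
        stage_outputs["pca"] += [cdir / "pc_scores.tsv", cdir / "eigenvalues.txt"]

        # 8. variance explained + top-PC selection
        fractions = pca_mod.variance_explained(pmodel)
        n_top = pca_mod.select_top_pcs(
            fractions, override=config.top_pc_override.get(cag)
        )
        stage_counts["top_pc_selection"][cag] = {
            "samples_in": len(pmodel.fit_sample_ids),
            "samples_out": len(pmodel.fit_sample_ids),
            "n_top_pcs": n_top,
        }

        # 9. K-means on top PCs of the target members (refs excluded)
        cluster_ids = list(pmodel.fit_sample_ids)
        cluster_scores = pmodel.fit_scores[:, :n_top]
        related_targets = [
            s for s in project_ids if s in set(target_members)
        ]
        if related_targets and pmodel.projected_scores is not None:
            proj_idx = [pmodel.projected_sample_ids.index(s) for s in related_targets]
            cluster_ids += related_targets
            cluster_scores = np.vstack(
                [cluster_scores, pmodel.projected_scores[proj_idx, :n_top]]
            )
        try:
            cres = cl.select_k(
                cluster_scores,
                kmin=config.kmin,
                kmax=min(config.kmax, len(cluster_ids) - 1),
                restarts=config.kmeans_restarts,
                seed=config.seed,
                override=config.k_override.get(cag),
                sample_ids=cluster_ids,
            )
        except ValueError as exc:
            raise RuntimeError(f"stage kmeans[{cag}] failed: {exc}") from exc
        cl.write_labels(cres, cdir / "kmeans_labels.tsv")
        cl.write_silhouette_table(cres, cdir / "silhouette_by_k.tsv")
        stage_counts["kmeans"][cag] = {
            "samples_in": len(cluster_ids),
            "samples_out": len(cluster_ids),
            "chosen_k": cres.chosen_k,
        }
        stage_outputs["kmeans"] += [cdir / "kmeans_labels.tsv"]

        # 10. correspondence analysis of cluster x birth region
        region_of = dict(
            zip(merged.samples["id"], merged.samples["birth_region"])
        )
        regions = [region_of.get(s) for s in cluster_ids]
        ca_info: dict = {"skipped": True}
        try:
            table = ca_mod.build_contingency(
                [str(c) for c in cres.labels], regions, min_count=config.ca_min_count
            )
            chi2, dof, pval = ca_mod.chi_square(table)
            cares = ca_mod.ca_fit(table)
            ca_mod.write_ca_result(cares, cdir / "ca")
            table.to_frame().to_csv(cdir / "contingency.tsv", sep="\t")
            d1, d2 = cares.dim12_fraction()
            ca_info = {
                "skipped": False,
                "chi2": chi2,
                "dof": dof,
                "p": pval,
                "dim1_fraction": round(d1, 6),
                "dim2_fraction": round(d2, 6),
            }
        except ValueError as exc:
            log.warning("CA skipped for %s: %s", cag, exc)
            ca_info = {"skipped": True, "reason": str(exc)}
        stage_counts["correspondence"][cag] = {
            "samples_in": len(cluster_ids),
            "samples_out": sum(1 for r in regions if pd.notna(r)),
            **ca_info,
        }

        # 11. pairwise Fst among K-means clusters (+ reference groups)
        group_of = {
            s: f"cluster{lab}" for s, lab in zip(cluster_ids, cres.labels)
        }
        for pop, ids in ref_labels.items():
            for s in ids:
                if s in set(members):
                    group_of[s] = f"ref_{pop}"
        fst_info: dict
        try:
            fmatrix = fst_mod.pairwise_fst(cag_cohort, group_of)
            fst_mod.write_phylip(fmatrix, cdir / "fst.phylip")
            fmatrix.to_long().to_csv(cdir / "fst_pairs.tsv", sep="\t", index=False)
            summary = fst_mod.summarize_pairs(fmatrix, clamp=True)
            fst_info = {k: round(v, 6) for k, v in summary.items()}
        except ValueError as exc:
            log.warning("Fst skipped for %s: %s", cag, exc)
            fst_info = {"skipped": True, "reason": str(exc)}
        stage_counts["fst"][cag] = {
            "samples_in": len(group_of),
            "samples_out": len(group_of),
            **fst_info,
        }
        stage_outputs["fst"] += [cdir / "fst.phylip"]

        per_cag_results[cag] = {
            "members": target_members,
            "fit_ids": fit_ids,
            "outliers": outliers,
            "cluster_ids": cluster_ids,
            "cluster_labels": cres.labels,
            "silhouette_by_k": cres.silhouette_by_k,
            "chosen_k": cres.chosen_k,
            "n_top_pcs": n_top,
            "ca": ca_info,
            "fst": fst_info,
        }

    for stage in STAGES[4:]:
        manifest.add(
            stage,
            {},
            stage_counts[stage],
            outputs=stage_outputs[stage],
        )

    manifest.summary = {
        "n_target": len(target_ids),
        "n_reference": len(ref_ids),
        "n_assigned": n_assigned,
        "n_unassigned": len(target_ids) - n_assigned,
        "per_cag_k": {c: per_cag_results[c]["chosen_k"] for c in per_cag_results},
        "reference_mean_fst": round(ref_fst_mean, 6),
        "seed": config.seed,
    }
    manifest.write(outdir / "manifest.json")
    log.info("pipeline finished in %.1f s", time.time() - t0)

    # stash non-manifest state for rehearse()
    manifest._state = {  # type: ignore[attr-defined]
        "proportions": props,
        "assignments": assignments,
        "per_cag": per_cag_results,
        "truth": truth,
        "merged": merged,
        "target_ids": target_ids,
        "reference_fst": ref_fst_matrix,
    }
    return manifest


def check_count_flow(manifest: RunManifest) -> None:
    """Raise if any stage's counts are internally inconsistent."""
    by_stage = {s["stage"]: s["counts"] for s in manifest.stages}
    cag_sizes = by_stage["cag_assignment"]["per_cag"]
    if sum(cag_sizes.values()) != by_stage["cag_assignment"]["samples_out"]:
        raise AssertionError("per-CAG sizes do not sum to assigned count")
    assigned = by_stage["cag_assignment"]
    if assigned["samples_in"] != assigned["samples_out"] + assigned["unassigned"]:
        raise AssertionError("assigned + unassigned != admixture input")
    for cag in cag_sizes:
        unrel = by_stage["unrelated_selection"][cag]
        if unrel["samples_in"] != unrel["samples_out"] + unrel["dropped"]:
            raise AssertionError(f"unrelated selection counts leak for {cag}")
        pca_c = by_stage["pca"][cag]
        if pca_c["samples_in"] != pca_c["samples_out"] + pca_c["outliers_removed"]:
            raise AssertionError(f"pca counts leak for {cag}")


def rehearse(config: PipelineConfig) -> dict:
    """Run the framework on a synthetic cohort and score it against truth."""
    if config.synthetic is None:
        raise ValueError("rehearse requires a synthetic spec")
    manifest = run_framework(config)
    state = manifest._state  # type: ignore[attr-defined]
    truth_cohort: sim.SimulatedCohort = state["truth"]
    truth = truth_cohort.truth.set_index("id")
    props: adm.AncestryProportions = state["proportions"]
    assignments: pd.DataFrame = state["assignments"]

    names = truth_cohort.continent_names
    qcols = [f"q_{c}" for c in names]
    # align truth q with estimated q (target samples only)
    est_pops = props.populations
    tq = truth.loc[props.sample_ids, [f"q_{p}" for p in est_pops]].to_numpy(float)
    qhat = props.q
    q_mae = float(np.abs(qhat - tq).mean())

    truth_qmax = tq.max(axis=1)
    truth_best = np.array([est_pops[i] for i in tq.argmax(axis=1)])
    cag = assignments.set_index("id").loc[props.sample_ids, "cag"].to_numpy()

    confident = truth_qmax >= 0.9
    acc = (
        float((cag[confident] == truth_best[confident]).mean())
        if confident.any()
        else float("nan")
    )
    admixed = truth_qmax <= 0.7
    unassigned_rate = (
        float((cag[admixed] == adm.UNASSIGNED).mean()) if admixed.any() else float("nan")
    )

    # clustering recovery + outlier false flags per CAG
    per_cag = {}
    for cname, res in state["per_cag"].items():
        ids = res["cluster_ids"]
        sub = truth.loc[[s for s in ids if s in truth.index]]
        subpops = sub["subpop"]
        known = subpops.notna().to_numpy()
        if known.sum() >= 2 and subpops[known].nunique() >= 1:
            ari = cl.adjusted_rand_index(
                np.array(res["cluster_labels"])[known], subpops[known].to_numpy()
            )
        else:
            ari = float("nan")
        founder_ids = set(
            truth.index[(truth["is_founder"]) & (truth["subpop"].notna())]
        )
        false_flags = [s for s in res["outliers"] if s in founder_ids]
        per_cag[cname] = {
            "chosen_k": res["chosen_k"],
            "n_true_subpops": int(subpops[known].nunique()),
            "ari_vs_truth": ari,
            "n_outliers": len(res["outliers"]),
            "n_false_outlier_flags": len(false_flags),
            "ca_dim12": (
                res["ca"].get("dim1_fraction", 0.0) + res["ca"].get("dim2_fraction", 0.0)
                if not res["ca"].get("skipped")
                else None
            ),
            "fst_summary": res["fst"],
        }

    # Fst recovery: estimated subpop Fst vs the latent-frequency oracle
    freqs = sim.draw_hierarchical_frequencies(
        config.synthetic, np.random.default_rng(config.synthetic.seed)
    )
    merged: GenotypeMatrix = state["merged"]
    founder = truth[(truth["is_founder"]) & truth["subpop"].notna()]
    group_of = dict(zip(founder.index, founder["subpop"]))
    group_of = {s: g for s, g in group_of.items() if s in set(merged.sample_ids)}
    est_matrix = fst_mod.pairwise_fst(merged, group_of)
    key_of = {sp.name: (c.name, sp.name) for c in config.synthetic.continents for sp in c.subpops}
    fst_errors = {}
    big_n = 1e9
    for i, g1 in enumerate(est_matrix.groups):
        for j in range(i + 1, len(est_matrix.groups)):
            g2 = est_matrix.groups[j]
            oracle = fst_mod.hudson_fst_from_freqs(
                freqs.subpop[key_of[g1]], big_n, freqs.subpop[key_of[g2]], big_n
            )
            fst_errors[f"{g1}|{g2}"] = {
                "estimate": float(est_matrix.values[i, j]),
                "oracle": oracle,
                "error": float(est_matrix.values[i, j] - oracle),
            }

    check_count_flow(manifest)
    report = {
        "q_mean_absolute_error": q_mae,
        "assignment_accuracy_qmax_ge_0.9": acc,
        "unassigned_rate_qmax_le_0.7": unassigned_rate,
        "per_cag": per_cag,
        "fst_recovery": fst_errors,
        "manifest_hash": manifest.manifest_hash(),
        "reference_mean_fst": manifest.summary["reference_mean_fst"],
    }
    (Path(config.outdir) / "rehearsal_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str)
    )
    return report


def default_rehearsal_config(seed: int = 0, outdir: str = "popstruct_rehearsal",
                             **spec_kwargs) -> PipelineConfig:
    """Pipeline config for the desk-scale synthetic rehearsal.

    The relatedness cutoff is raised from PLINK's 0.025 default to 0.1:
    GRM entries at a few thousand SNPs carry sampling noise with SD around
    1/sqrt(M) ~= 0.011, so the biobank-scale default would flag hundreds
    of spurious pairs here.  0.1 still sits far below the 0.45-0.5 of a
    true parent-offspring pair.
    """
    return PipelineConfig(
        synthetic=default_synthetic_spec(seed=seed, **spec_kwargs),
        rel_cutoff=0.1,
        seed=seed,
        outdir=outdir,
    )


def default_synthetic_spec(
    seed: int = 0,
    n_snps: int = 8000,
    n_per_subpop: int = 50,
    n_ref: int = 100,
    n_admixed: int = 60,
    relative_pairs: int = 10,
) -> sim.PopulationSpec:
    """Four continents at pairwise F ~= 0.1 with labeled reference panels,
    two subpopulations per continent, admixed samples, and related pairs."""
    continents = []
    fs_values = [0.01, 0.015]
    for ci, cname in enumerate(["AFR", "EUR", "SAS", "EAS"]):
        subpops = [
            sim.SubpopSpec(
                name=f"{cname}_S{k + 1}",
                fs=fs_values[k],
                n=n_per_subpop,
                region=f"{cname}_region{k + 1}",
                countries={
                    f"{cname}_country{k + 1}a": 0.7,
                    f"{cname}_country{k + 1}b": 0.3,
                },
            )
            for k in range(2)
        ]
        subpops.append(
            sim.SubpopSpec(
                name=f"{cname}_REF", fs=0.002, n=n_ref, is_reference=True
            )
        )
        continents.append(sim.ContinentSpec(name=cname, fc=0.1, subpops=subpops))
    return sim.PopulationSpec(
        continents=continents,
        n_snps=n_snps,
        maf_range=(0.1, 0.5),
        admixed_blocks=[sim.AdmixedBlock(n=n_admixed, alpha=[0.3, 0.3, 0.3, 0.3])],
        relative_pairs=relative_pairs,
        label_concordance=0.9,
        snp_spacing_bp=20000,  # sparse sites so chance LD does not dominate pruning
        seed=seed,
    )
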