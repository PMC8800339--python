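"""Self-contained evaluation scenarios used by the acceptance suite.

Each function simulates its own inputs from a seed, runs the relevant
package components, and returns plain-dict metrics, so the same code
backs both the pytest acceptance criteria and the standalone report
script.
"""

from __future__ import annotations

import numpy as np

from . import admixture as adm
from . import cluster as cl
from . import fst as fst_mod
from . import pca as pca_mod
from . import qc
from . import sim


def _four_reference_spec(seed: int, n_ref: int, n_admixed: int, n_snps: int,
                         alpha: float = 0.3) -> sim.PopulationSpec:
    return sim.PopulationSpec(
        continents=[
            sim.ContinentSpec(
                name, 0.1, [sim.SubpopSpec(f"{name}_R", 0.0, n_ref, is_reference=True)]
            )
            for name in ("P1", "P2", "P3", "P4")
        ],
        n_snps=n_snps,
        maf_range=(0.1, 0.5),
        admixed_blocks=[sim.AdmixedBlock(n=n_admixed, alpha=[alpha] * 4)],
        seed=seed,
    )


def admixture_recovery(seed: int = 0, n_individuals: int = 200,
                       n_snps: int = 5000, n_ref: int = 100) -> dict:
    """Criterion 1/2 scenario: supervised EM against four references at
    pairwise F = 0.1, Dirichlet(0.3) target proportions."""
    spec = _four_reference_spec(seed, n_ref, n_individuals, n_snps)
    cohort = sim.simulate(spec)
    gm = cohort.genotypes
    labels = {
        c: [s for s in gm.sample_ids if s.startswith(f"{c}_R")]
        for c in ("P1", "P2", "P3", "P4")
    }
    model = adm.reference_frequencies(gm, labels)
    targets = [s for s in gm.sample_ids if s.startswith("ADM")]
    props = adm.fit_q(gm.subset_samples(targets), model)
    truth = cohort.truth.set_index("id")
    tq = truth.loc[targets, [f"q_{p}" for p in props.populations]].to_numpy(float)

    assignments = adm.assign_cag(props, threshold=0.8)
    cag = assignments["cag"].to_numpy()
    truth_best = np.array([props.populations[i] for i in tq.argmax(axis=1)])
    qmax = tq.max(axis=1)
    confident = qmax >= 0.9
    admixed = qmax <= 0.7
    return {
        "n": n_individuals,
        "n_snps": n_snps,
        "q_mae": float(np.abs(props.q - tq).mean()),
        "ll_monotone": bool(np.all(np.diff(props.ll_trace) >= -1e-6)),
        "n_iter": props.n_iter,
        "n_confident": int(confident.sum()),
        "assignment_accuracy": float(
            (cag[confident] == truth_best[confident]).mean()
        ),
        "n_admixed": int(admixed.sum()),
        "unassigned_rate": float((cag[admixed] == adm.UNASSIGNED).mean()),
    }


def fst_recovery(seed: int = 0, f_values=(0.01, 0.05, 0.1),
                 n_per_group: int = 100, n_snps: int = 20000) -> dict:
    """Criterion 3: Hudson ratio-of-averages vs generating F, plus the
    split-half null of a single panmictic population."""
    estimates = {}
    for i, f_gen in enumerate(f_values):
        spec = sim.PopulationSpec(
            continents=[
                sim.ContinentSpec("A", f_gen, [sim.SubpopSpec("A1", 0.0, n_per_group)]),
                sim.ContinentSpec("B", f_gen, [sim.SubpopSpec("B1", 0.0, n_per_group)]),
            ],
            n_snps=n_snps,
            maf_range=(0.1, 0.5),
            seed=seed + i,
        )
        cohort = sim.simulate_genotypes(sim.draw_hierarchical_frequencies(spec), spec)
        group_of = {
            s: str(sp) for s, sp in zip(cohort.truth["id"], cohort.truth["subpop"])
        }
        est = fst_mod.pairwise_fst(cohort.genotypes, group_of).values[0, 1]
        estimates[f_gen] = {"estimate": float(est), "error": float(est - f_gen)}

    null_spec = sim.PopulationSpec(
        continents=[
            sim.ContinentSpec("C", 0.0, [sim.SubpopSpec("P", 0.0, 2 * n_per_group)])
        ],
        n_snps=n_snps,
        maf_range=(0.1, 0.5),
        seed=seed + 100,
    )
    null = sim.simulate_genotypes(
        sim.draw_hierarchical_frequencies(null_spec), null_spec
    )
    ids = null.genotypes.sample_ids
    group_of = {s: ("g1" if i < n_per_group else "g2") for i, s in enumerate(ids)}
    split = fst_mod.pairwise_fst(null.genotypes, group_of).values[0, 1]
    return {
        "n": n_per_group,
        "n_snps": n_snps,
        "by_f": estimates,
        "max_abs_error": max(abs(v["error"]) for v in estimates.values()),
        "split_half_null": float(split),
    }


def structure_clustering(seed: int = 0, n_per_subpop: int = 100,
                         n_snps: int = 20000) -> dict:
    """Criterion 4: three subpopulations at pairwise Fst ~0.01; silhouette
    scan over k = 2..20 on the elbow-selected top PCs."""
    spec = sim.PopulationSpec(
        continents=[
            sim.ContinentSpec(
                "C",
                0.0,
                [sim.SubpopSpec(f"P{i}", 0.005, n_per_subpop) for i in (1, 2, 3)],
            )
        ],
        n_snps=n_snps,
        maf_range=(0.1, 0.5),
        seed=seed,
    )
    cohort = sim.simulate_genotypes(sim.draw_hierarchical_frequencies(spec), spec)
    model = pca_mod.fit_pcs(cohort.genotypes, n_pcs=20)
    n_top = pca_mod.select_top_pcs(pca_mod.variance_explained(model))
    result = cl.select_k(
        model.fit_scores[:, :n_top], kmin=2, kmax=20, restarts=25, seed=seed
    )
    truth = cohort.truth.set_index("id").loc[model.fit_sample_ids, "subpop"]
    return {
        "n": 3 * n_per_subpop,
        "n_snps": n_snps,
        "n_top_pcs": n_top,
        "chosen_k": result.chosen_k,
        "ari": cl.adjusted_rand_index(result.labels, truth.to_numpy()),
    }


def outlier_removal(seed: int = 0, n_main: int = 500, n_outliers: int = 5,
                    n_snps: int = 5000) -> dict:
    """Criterion 5: planted F = 0.3 samples among a homogeneous cohort,
    flagged by the 10-PC / 6-sigma / 5-iteration rule."""
    spec = sim.PopulationSpec(
        continents=[
            sim.ContinentSpec("C", 0.0, [sim.SubpopSpec("MAIN", 0.0, n_main)]),
            sim.ContinentSpec("O", 0.3, [sim.SubpopSpec("OUT", 0.0, n_outliers)]),
        ],
        n_snps=n_snps,
        maf_range=(0.1, 0.5),
        seed=seed,
    )
    cohort = sim.simulate_genotypes(sim.draw_hierarchical_frequencies(spec), spec)
    model = pca_mod.remove_outliers(
        cohort.genotypes, n_pcs=20, n_outlier_pcs=10, sigma=6.0, iterations=5
    )
    flagged = set(model.outliers)
    planted = {s for s in cohort.genotypes.sample_ids if s.startswith("OUT")}
    return {
        "n": n_main + n_outliers,
        "n_snps": n_snps,
        "n_flagged": len(flagged),
        "n_planted_flagged": len(flagged & planted),
        "n_false_flags": len(flagged - planted),
        "iterations_used": len(model.outliers_per_iteration),
    }


def ld_prune_certificate(seed: int = 0, n_samples: int = 200,
                         n_snps: int = 300, n_tagged: int = 150) -> dict:
    """Criterion 6: prune an LD-block cohort, then exhaustively verify no
    retained within-window pair exceeds the threshold; check idempotence."""
    spec = sim.PopulationSpec(
        continents=[sim.ContinentSpec("C", 0.0, [sim.SubpopSpec("P", 0.0, n_samples)])],
        n_snps=n_snps,
        maf_range=(0.1, 0.5),
        ld_block=sim.LDBlockSpec(n_tagged=n_tagged, eps=0.01),
        snp_spacing_bp=5000,
        seed=seed,
    )
    cohort = sim.simulate(spec)
    params = qc.PruneParams(window_kb=50, step_kb=10, r2_threshold=0.025)
    kept = qc.ld_prune(cohort.genotypes, params)
    worst = qc.prune_certificate(cohort.genotypes, kept, params)
    again = qc.ld_prune(cohort.genotypes.subset_variants(kept), params)
    return {
        "n": cohort.genotypes.n_variants,
        "n_kept": len(kept),
        "max_retained_r2": float(worst),
        "idempotent": again == kept,
    }


def ca_identities(seed: int = 0, n_tables: int = 20) -> dict:
    """Criterion 7: inertia x n = chi-square on random tables; the
    block-diagonal and independence degenerate cases."""
    from . import ca as ca_mod

    rng = np.random.default_rng(seed)
    worst_identity = 0.0
    for _ in range(n_tables):
        shape = (int(rng.integers(2, 7)), int(rng.integers(2, 8)))
        counts = rng.integers(1, 80, size=shape)
        table = ca_mod.ContingencyTable(
            [f"r{i}" for i in range(shape[0])],
            [f"c{j}" for j in range(shape[1])],
            counts,
        )
        result = ca_mod.ca_fit(table)
        chi2, _, _ = ca_mod.chi_square(table)
        worst_identity = max(worst_identity, abs(result.total_inertia * table.n - chi2))

    block = ca_mod.ca_fit(
        ca_mod.ContingencyTable(["a", "b"], ["x", "y"], np.array([[20, 0], [0, 20]]))
    )
    indep = ca_mod.ca_fit(
        ca_mod.ContingencyTable(
            ["a", "b"], ["x", "y"], np.outer([10, 30], [15, 25]) // 5
        )
    )
    return {
        "n": n_tables,
        "max_identity_error": float(worst_identity),
        "block_diagonal_dim1": float(block.inertia_fractions[0]),
        "independence_inertia": float(indep.total_inertia),
    }


def rehearsal(seed: int = 0, outdir: str = "scratch/acceptance_rehearsal",
              check_determinism: bool = True) -> dict:
    """Criterion 8: full synthetic run-all with truth scoring and an
    optional bit-identical rerun check."""
    from .pipeline import default_rehearsal_config, rehearse

    report = rehearse(default_rehearsal_config(seed=seed, outdir=f"{outdir}_a"))
    rerun_identical = None
    if check_determinism:
        report_b = rehearse(default_rehearsal_config(seed=seed, outdir=f"{outdir}_b"))
        rerun_identical = report["manifest_hash"] == report_b["manifest_hash"]
    aris = [c["ari_vs_truth"] for c in report["per_cag"].values()]
    false_flags = sum(c["n_false_outlier_flags"] for c in report["per_cag"].values())
    fst_err = max(abs(v["error"]) for v in report["fst_recovery"].values())
    return {
        "n": len(report["per_cag"]),
        "report": report,
        "min_ari": float(min(aris)),
        "total_false_outlier_flags": int(false_flags),
        "max_fst_recovery_error": float(fst_err),
        "rerun_identical": rerun_identical,
    }
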