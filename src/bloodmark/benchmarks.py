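"""Standard evaluation scenarios with planted ground truth.

Each function freezes one benchmark condition of the pipeline — null
calibration, effect recovery, HEIDI discrimination, power-simulation
accuracy, AIC panel selection, Cox recovery, and the end-to-end planted
worlds — and measures the corresponding quantity by running the package on
freshly generated synthetic data. Problem sizes are the package's standard
benchmark conditions (see the methods note); everything is driven by a
single integer seed.
"""

from __future__ import annotations

import numpy as np

from . import mr, pipeline, power, prognosis, synthetic
from ._stats import spawn_rng
from .power import EffectVector
from .sumstats import harmonize

# benchmark locus architectures
CALIBRATION_ARCH = synthetic.QtlArchitecture(n_snps=8, maf=0.3, causal_idx=(0,),
                                             beta_im=(0.5,), ld_rho=0.9)
RECOVERY_ARCH = synthetic.QtlArchitecture(n_snps=12, maf=0.3, causal_idx=(0,),
                                          beta_im=(0.5,), ld_rho=0.9)
# denser LD so the colocalizing SNP can sit at r2 ~ 0.6 with the QTL top SNP
HEIDI_ARCH = synthetic.QtlArchitecture(n_snps=15, maf=0.3, causal_idx=(0,),
                                       beta_im=(0.5,), ld_rho=0.95)


def _one_locus(arch, beta_md, mediation, seed, n_per_cohort):
    """One two-sample SMR analysis on a fresh pair of cohorts."""
    qtl = synthetic.gen_qtl_sumstats(arch, n_per_cohort, seed=spawn_rng(seed, 1))
    disease = synthetic.DiseaseModel(beta_md_true=beta_md, prevalence=0.5,
                                     n_cases=n_per_cohort // 2,
                                     n_controls=n_per_cohort // 2)
    gwas = synthetic.gen_gwas_sumstats(arch, disease, mediation,
                                       seed=spawn_rng(seed, 2))
    pairs = harmonize(qtl.sumstats, gwas.sumstats)
    site = int(pairs["pos"].iloc[0])
    instruments = mr.select_cis_instruments(pairs, site, qtl.ld)
    if not instruments:
        return None
    assoc = mr.smr_multi(pairs, qtl.ld, instruments)
    p_heidi = mr.heidi_test(pairs, qtl.ld)
    return assoc, p_heidi


def null_calibration(seed: int, n_loci: int = 2_000,
                     n_per_cohort: int = 5_000) -> dict:
    """All-null loci: SMR rejection rate at alpha = 0.05 and inflation lambda."""
    ps = []
    for i in range(n_loci):
        out = _one_locus(CALIBRATION_ARCH, 0.0, "null", spawn_rng(seed, 50, i),
                         n_per_cohort)
        if out is not None:
            ps.append(out[0].p_smr)
    ps = np.asarray(ps)
    return {"n_loci": ps.size,
            "rejection_rate": float((ps < 0.05).mean()),
            "lambda": mr.inflation_lambda(ps).lam}


def recovery(seed: int, beta_md: float, n_reps: int = 200,
             n_per_cohort: int = 20_000) -> dict:
    """Shared-causal scenario: mean SMR estimate vs the planted effect."""
    est = []
    for i in range(n_reps):
        out = _one_locus(RECOVERY_ARCH, beta_md, "shared_causal",
                         spawn_rng(seed, 60, i), n_per_cohort)
        if out is not None:
            est.append(out[0].beta_md)
    est = np.asarray(est)
    return {"n_reps": est.size, "beta_true": beta_md,
            "mean_estimate": float(est.mean()),
            "mc_se": float(est.std(ddof=1) / np.sqrt(est.size))}


def heidi_discrimination(seed: int, n_reps: int = 500,
                         n_per_cohort: int = 20_000) -> dict:
    """HEIDI rejection under a shared causal SNP vs colocalization in LD."""
    out = {}
    for stream, mediation in ((70, "shared_causal"),
                              (71, "distinct_causal_in_ld")):
        rejected, tested = 0, 0
        for i in range(n_reps):
            res = _one_locus(HEIDI_ARCH, 0.3, mediation,
                             spawn_rng(seed, stream, i), n_per_cohort)
            if res is None or res[1] is None:
                continue
            tested += 1
            rejected += res[1] <= 0.05
        out[mediation] = rejected / tested if tested else np.nan
        out[f"n_tested_{mediation}"] = tested
    out["difference"] = out["distinct_causal_in_ld"] - out["shared_causal"]
    return out


def power_auc_grid(seed: int, betas=(0.0, 0.25, 0.5, 1.0, 2.0),
                   n_reps: int = 100, n_samples: int = 10_000) -> dict:
    """Median single-marker AUC across the standard effect grid."""
    out = {}
    for b in betas:
        ev = EffectVector([f"b{b}"], [b], [0.0])
        med_auc, _ = power.median_power(ev, n_reps=n_reps,
                                        n_samples=n_samples,
                                        seed=spawn_rng(seed, 80, int(b * 100)))
        out[float(b)] = med_auc
    return out


def aic_null_exclusion(seed: int, n_seeds: int = 50, n_reps: int = 100,
                       n_samples: int = 2_000) -> dict:
    """1 real + 5 exact-null markers: how often the AIC-optimal panel is
    exactly the real marker."""
    ev = EffectVector(["real", "n1", "n2", "n3", "n4", "n5"],
                      [1.0, 0, 0, 0, 0, 0], [0.0] * 6)
    clean = 0
    for s in range(n_seeds):
        rep = power.optimal_cross_omics(ev, n_reps=n_reps, n_samples=n_samples,
                                        seed=spawn_rng(seed, 90, s))
        clean += set(rep.optimal_markers) == {"real"}
    return {"n_seeds": n_seeds, "all_nulls_excluded_rate": clean / n_seeds}


def cox_hr_recovery(seed: int, true_hr: float = 2.0, n_reps: int = 200,
                    n: int = 400) -> dict:
    """Binary-score conversion cohorts: mean Cox HR vs the planted HR."""
    hrs, ev_frac = [], []
    for i in range(n_reps):
        rng = spawn_rng(seed, 95, i)
        score = (rng.random(n) < 0.5).astype(float)
        cohort = synthetic.gen_conversion_cohort(
            n, np.log(true_hr), censor_rate=0.5, max_followup_days=2_000.0,
            seed=rng, score=score)
        res = prognosis.cox_univariate(score > 0.5, cohort.time, cohort.event)
        hrs.append(res.hazard_ratio)
        ev_frac.append(cohort.event.mean())
    hrs = np.asarray(hrs)
    return {"n_reps": n_reps, "true_hr": true_hr,
            "mean_hr": float(hrs.mean()),
            "event_fraction": float(np.mean(ev_frac))}


def null_world_rate(seed: int, n_seeds: int = 20) -> dict:
    """Fraction of all-null demo worlds with zero pooled-Bonferroni hits."""
    clean = 0
    for s in range(n_seeds):
        out = pipeline.mr_stage(int(spawn_rng(seed, 96, s).integers(2 ** 31)),
                                n_causal=0)
        clean += out["report"]["n_significant_pooled"] == 0
    return {"n_seeds": n_seeds, "zero_hit_rate": clean / n_seeds}


def planted_world_recovery(seed: int, n_seeds: int = 3) -> dict:
    """Planted large-effect molecules recovered past Bonferroni, per seed."""
    recov = []
    for s in range(n_seeds):
        out = pipeline.mr_stage(int(spawn_rng(seed, 97, s).integers(2 ** 31)))
        recov.append(out["report"]["n_causal_recovered"])
    return {"n_seeds": n_seeds, "n_planted": 10,
            "min_recovered": int(min(recov)),
            "mean_recovered": float(np.mean(recov))}


def diagnostic_recovery(seed: int, n_seeds: int = 6) -> dict:
    """Planted 11-marker panels: recovery and frozen-validation AUC per seed."""
    hits, aucs, recovered = 0, [], []
    for s in range(n_seeds):
        out = pipeline.diagnostic_stage(
            int(spawn_rng(seed, 98, s).integers(2 ** 31)))
        rep = out["report"]
        aucs.append(rep["validation_auc"])
        recovered.append(rep["n_recovered_planted"])
        hits += (rep["n_recovered_planted"] >= 6
                 and rep["validation_auc"] >= 0.65)
    return {"n_seeds": n_seeds, "pass_rate": hits / n_seeds,
            "median_validation_auc": float(np.median(aucs)),
            "median_recovered": float(np.median(recovered))}


def prognosis_power(seed: int, n_seeds: int = 10) -> dict:
    """Planted ln(2.3) conversion effect: significant HR > 1 per seed."""
    hits, hrs = 0, []
    for s in range(n_seeds):
        out = pipeline.prognosis_stage(
            int(spawn_rng(seed, 99, s).integers(2 ** 31)))
        rep = out["report"]
        if rep.get("degenerate_groups"):
            continue
        hrs.append(rep["hazard_ratio"])
        hits += (rep["hazard_ratio"] > 1.0) and (rep["hr_p"] < 0.05)
    return {"n_seeds": n_seeds, "significant_rate": hits / n_seeds,
            "median_hr": float(np.median(hrs)) if hrs else np.nan}
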