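"""End-to-end orchestration: simulate -> MR -> power -> panels -> prognosis.

:func:`demo_end_to_end` runs the whole chain on a three-omic synthetic
disease with known ground truth and cross-references planted vs recovered
markers. :func:`run` drives the same stages from a :class:`RunConfig`
(YAML-serializable), writing TSV/JSON artifacts plus a manifest of content
hashes; a rerun with unchanged inputs skips completed stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._stats import spawn_rng
from . import mr, power, diagnostic, prognosis, synthetic
from .sumstats import harmonize

log = logging.getLogger(__name__)

STAGES = ("mr", "power", "diagnostic", "prognosis")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "bloodmark_run"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    mr_params: dict = field(default_factory=dict)
    power_params: dict = field(default_factory=dict)
    diagnostic_params: dict = field(default_factory=dict)
    prognosis_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        bad = set(cfg.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# --------------------------------------------------------------- MR stage

def _simulate_molecule(seed, idx, omic, beta_md, *, n_qtl, n_gwas_cases,
                       n_gwas_controls, n_snps, ld_rho, beta_im, maf):
    arch = synthetic.QtlArchitecture(n_snps=n_snps, maf=maf, causal_idx=(0,),
                                     beta_im=(beta_im,), ld_rho=ld_rho)
    qtl = synthetic.gen_qtl_sumstats(arch, n_qtl, seed=spawn_rng(seed, 100, idx),
                                     trait=f"{omic}_{idx}", omic=omic)
    disease = synthetic.DiseaseModel(beta_md_true=beta_md, prevalence=0.5,
                                     n_cases=n_gwas_cases,
                                     n_controls=n_gwas_controls)
    mediation = "shared_causal" if beta_md != 0 else "null"
    gwas = synthetic.gen_gwas_sumstats(arch, disease, mediation,
                                       seed=spawn_rng(seed, 101, idx))
    return qtl, gwas


def mr_stage(seed: int, *, n_per_omic: dict | None = None, n_causal: int = 10,
             beta_md_causal: float = 0.3, n_qtl: int = 10_000,
             n_gwas_cases: int = 5_000, n_gwas_controls: int = 5_000,
             n_snps: int = 12, ld_rho: float = 0.9, beta_im: float = 0.5,
             maf: float = 0.3, alpha: float = 0.05) -> dict:
    """Simulate a three-omic disease and run SMR + HEIDI + Bonferroni.

    The first ``n_causal`` molecules (spread across omics) carry a true
    liability effect ``beta_md_causal``; the rest are null.
    """
    n_per_omic = n_per_omic or {"RNA": 30, "methylation": 30, "protein": 10}
    molecules = [(omic, j) for omic, k in n_per_omic.items() for j in range(k)]
    n_total = len(molecules)
    causal = set(range(0, n_total, max(1, n_total // max(n_causal, 1)))[:n_causal]) \
        if n_causal else set()
    assocs, truth_beta = [], {}
    for idx, (omic, j) in enumerate(molecules):
        beta_md = beta_md_causal if idx in causal else 0.0
        qtl, gwas = _simulate_molecule(seed, idx, omic, beta_md,
                                       n_qtl=n_qtl, n_gwas_cases=n_gwas_cases,
                                       n_gwas_controls=n_gwas_controls,
                                       n_snps=n_snps, ld_rho=ld_rho,
                                       beta_im=beta_im, maf=maf)
        pairs = harmonize(qtl.sumstats, gwas.sumstats)
        site = int(pairs["pos"].iloc[0])
        instruments = mr.select_cis_instruments(pairs, site, qtl.ld)
        name = qtl.sumstats.trait
        truth_beta[name] = beta_md
        if not instruments:
            continue
        assoc = mr.smr_multi(pairs, qtl.ld, instruments, molecule=name,
                             disease="synthetic_disease", omic=omic)
        assoc.set_heidi(mr.heidi_test(pairs, qtl.ld))
        assocs.append(assoc)
    table = mr.associations_to_frame(assocs)
    thr_pooled = mr.bonferroni_threshold(alpha, n_total)
    sig = table[table["p_smr"] < thr_pooled]
    per_omic = {}
    for omic, k in n_per_omic.items():
        thr = mr.bonferroni_threshold(alpha, k)
        sub = table[table["omic"] == omic]
        lam = mr.inflation_lambda(sub["p_smr"]).lam if len(sub) >= 2 else np.nan
        per_omic[omic] = {"threshold": thr,
                          "n_significant": int((sub["p_smr"] < thr).sum()),
                          "lambda": lam}
    causal_names = {name for name, b in truth_beta.items() if b != 0}
    recovered = set(sig["molecule"]) & causal_names
    flags = sig["flag"].value_counts().to_dict()
    report = {
        "n_molecules": n_total,
        "n_tested": len(table),
        "pooled_threshold": thr_pooled,
        "n_significant_pooled": int(len(sig)),
        "per_omic": per_omic,
        "heidi_counts": {"plus": int(flags.get("+", 0)),
                         "minus": int(flags.get("-", 0)),
                         "untested": int(flags.get("untested", 0))},
        "n_causal_planted": len(causal_names),
        "n_causal_recovered": len(recovered),
    }
    return {"table": table, "report": report, "truth_beta": truth_beta}


# ------------------------------------------------------------- other stages

def power_stage(seed: int, table, *, n_reps: int = 50,
                n_samples: int = 2_000) -> dict:
    """Cross-omics optimal panel on the significant MR effect estimates."""
    sig = table[table["p_smr"] < mr.bonferroni_threshold(0.05, len(table))] \
        if len(table) else table
    if len(sig) == 0:
        return {"report": None, "note": "no significant markers to simulate"}
    effects = power.EffectVector(ids=list(sig["molecule"]),
                                 beta=sig["beta"].to_numpy(),
                                 se=sig["se"].to_numpy(),
                                 omic=list(sig["omic"]),
                                 p_smr=sig["p_smr"].to_numpy())
    rep = power.optimal_cross_omics(effects, n_reps=n_reps,
                                    n_samples=n_samples, seed=seed)
    return {"report": {
        "optimal_size": rep.optimal_size,
        "optimal_markers": rep.optimal_markers,
        "optimal_omics": rep.optimal_omics,
        "optimal_median_aic": rep.optimal_median_aic,
        "optimal_median_auc": rep.optimal_median_auc,
        "optimal_median_r2": rep.optimal_median_r2,
        "full_panel_median_auc": rep.median_auc,
    }}


def diagnostic_stage(seed: int, *, n_planted: int = 11, n_null: int = 489,
                     shift: float = 0.4, n_feature: int = 400,
                     n_train: int = 400, n_validate: int = 400,
                     n_mcmc: int = 1500, burn_in: int = 400) -> dict:
    """Planted-signal diagnostic panel: three independent cohort splits."""
    n_markers = n_planted + n_null
    effect = np.zeros(n_markers)
    effect[:n_planted] = shift
    cohorts = []
    for part, n in enumerate((n_feature, n_train, n_validate)):
        c = synthetic.gen_case_control_matrix(
            n // 2, n - n // 2, n_markers, effect,
            seed=spawn_rng(seed, 200, part))
        cohorts.append(c)
    feat, train, valid = cohorts
    smr_betas = {m: s for m, s in zip(feat.marker_ids, effect)}
    # nulls get a random SMR direction: direction-concordance must be earned
    rng = spawn_rng(seed, 201)
    for m in feat.marker_ids[n_planted:]:
        smr_betas[m] = rng.choice([-1.0, 1.0]) * 0.01
    model = diagnostic.build_diagnostic_panel(
        feat.matrix, feat.labels, train.matrix, train.labels,
        feat.marker_ids, smr_betas, n_mcmc=n_mcmc, burn_in=burn_in, seed=seed)
    metrics = diagnostic.validate_panel(model, valid.matrix, valid.labels,
                                        valid.marker_ids)
    planted = set(feat.marker_ids[:n_planted])
    recovered = planted & set(model.marker_ids)
    return {"model": model, "validation": metrics,
            "report": {"n_planted": n_planted,
                       "n_recovered_planted": len(recovered),
                       "panel_size": len(model.marker_ids),
                       "validation_auc": metrics["auc"],
                       "validation_accuracy": metrics["accuracy"]}}


def prognosis_stage(seed: int, *, log_hr: float = float(np.log(2.3)),
                    n_train: int = 600, n_validate: int = 329,
                    n_markers: int = 74, n_informative: int = 18,
                    marker_loading: float = 0.6, censor_rate: float = 0.2,
                    max_followup_days: float = 1000.0,
                    horizon_days: float = 300.0) -> dict:
    """Planted conversion-risk effect: panel, risk groups, univariate Cox."""
    train = synthetic.gen_conversion_cohort(
        n_train, log_hr, censor_rate, max_followup_days,
        seed=spawn_rng(seed, 300), n_markers=n_markers,
        n_informative=n_informative, marker_loading=marker_loading)
    valid = synthetic.gen_conversion_cohort(
        n_validate, log_hr, censor_rate, max_followup_days,
        seed=spawn_rng(seed, 301), n_markers=n_markers,
        n_informative=n_informative, marker_loading=marker_loading)
    records = pd.DataFrame({"sample": np.arange(train.time.size),
                            "time": train.time, "event": train.event})
    labels = prognosis.label_converters(records).to_numpy()
    model = prognosis.build_risk_model(train.matrix, labels,
                                       train.marker_ids, seed=seed)
    groups = prognosis.assign_risk_groups(model, valid.matrix, valid.marker_ids)
    if groups.all() or (~groups).all():
        return {"model": model, "report": {"degenerate_groups": True}}
    result = prognosis.cox_univariate(groups, valid.time, valid.event)
    summary = prognosis.nonconversion_summary(groups, valid.time, valid.event,
                                              horizon_days)
    return {"model": model, "result": result,
            "report": {"hazard_ratio": result.hazard_ratio,
                       "hr_p": result.hr_p,
                       "n_high": int(groups.sum()),
                       "n_low": int((~groups).sum()),
                       "panel_size": len(model.marker_ids),
                       "nonconversion": summary.to_dict("records")}}


def demo_end_to_end(seed: int = 0, *, mr_params: dict | None = None,
                    power_params: dict | None = None,
                    diagnostic_params: dict | None = None,
                    prognosis_params: dict | None = None) -> dict:
    """Full synthetic chain with a truth-vs-recovered cross-reference."""
    mr_out = mr_stage(seed, **(mr_params or {}))
    pw_out = power_stage(seed, mr_out["table"], **(power_params or {}))
    dx_out = diagnostic_stage(seed, **(diagnostic_params or {}))
    px_out = prognosis_stage(seed, **(prognosis_params or {}))
    hc = mr_out["report"]["heidi_counts"]
    assert hc["plus"] + hc["minus"] + hc["untested"] \
        == mr_out["report"]["n_significant_pooled"]
    return {"seed": seed,
            "mr": mr_out["report"],
            "power": pw_out.get("report"),
            "diagnostic": dx_out["report"],
            "prognosis": px_out["report"]}


# ------------------------------------------------------------------- runner

def _stage_runner(cfg: RunConfig, name: str):
    if name == "mr":
        return lambda: mr_stage(cfg.seed, **cfg.mr_params)
    if name == "power":
        def _power():
            import pandas as _pd
            table = _pd.read_csv(Path(cfg.out_dir) / "mr_associations.tsv",
                                 sep="\t")
            return power_stage(cfg.seed, table, **cfg.power_params)
        return _power
    if name == "diagnostic":
        return lambda: diagnostic_stage(cfg.seed, **cfg.diagnostic_params)
    if name == "prognosis":
        return lambda: prognosis_stage(cfg.seed, **cfg.prognosis_params)
    raise ValueError(name)


_STAGE_OUTPUTS = {"mr": ["mr_associations.tsv", "mr_report.json"],
                  "power": ["power_report.json"],
                  "diagnostic": ["diagnostic_report.json"],
                  "prognosis": ["prognosis_report.json"]}


def _write_stage(out_dir: Path, name: str, result: dict) -> None:
    if name == "mr":
        result["table"].to_csv(out_dir / "mr_associations.tsv", sep="\t",
                               index=False)
        (out_dir / "mr_report.json").write_text(
            json.dumps(result["report"], indent=2, default=float))
    else:
        (out_dir / f"{name}_report.json").write_text(
            json.dumps(result["report"], indent=2, default=float))


def run(config: RunConfig) -> dict:
    """Execute configured stages in order; returns the run manifest.

    The manifest records, per stage, the hash of its inputs (parameters,
    seed, upstream artifact hashes) and of its outputs. A rerun with an
    unchanged input hash and intact outputs skips the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    previous = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    manifest: dict = {"seed": config.seed, "stages": {}}
    upstream_hash = ""
    for name in STAGES:
        if not config.stages.get(name, True):
            continue
        params = getattr(config, f"{name}_params")
        in_hash = _hash_obj({"seed": config.seed, "params": params,
                             "upstream": upstream_hash})
        outputs = _STAGE_OUTPUTS[name]
        prev = previous.get("stages", {}).get(name)
        intact = all((out_dir / f).exists() for f in outputs)
        if prev and prev["input_hash"] == in_hash and intact:
            ok = all(_hash_file(out_dir / f) == prev["output_hashes"][f]
                     for f in outputs)
            if ok:
                log.info("run: stage %s unchanged; skipping", name)
                manifest["stages"][name] = prev
                upstream_hash = in_hash
                continue
            raise RuntimeError(
                f"stage '{name}': output file(s) do not match the manifest "
                f"(corrupted intermediate in {out_dir}); delete them to rerun")
        try:
            result = _stage_runner(config, name)()
        except FileNotFoundError as exc:
            raise RuntimeError(f"stage '{name}': missing upstream artifact "
                               f"({exc})") from exc
        _write_stage(out_dir, name, result)
        manifest["stages"][name] = {
            "input_hash": in_hash,
            "output_hashes": {f: _hash_file(out_dir / f) for f in outputs},
        }
        upstream_hash = in_hash
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
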