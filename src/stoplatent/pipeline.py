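"""End-to-end orchestration: QC -> winsorize -> LCA -> networks ->
invariance -> latent contrasts -> regional scan -> SSRT comparison.

The pipeline consumes the CSV bundle (symptoms, betas, covariates, qc,
sst_trials), runs every stage in the study order, and emits a JSON + CSV
report bundle stamped with the seed, the package version and a hash of the
effective configuration; identical inputs and configuration reproduce the
bundle byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cfa import FactorModelSpec, fit_cfa, fit_indices
from .efa import ExploratoryFactorAnalysis, efa_discard
from .invariance import compare_latent_means, invariance_ladder
from .lca import classify, enumerate_classes
from .lmm import fit_lmm, region_scan, sex_by_group_scan
from .sst import compute_ssrt, qc_filter, qc_from_trials, winsorize_betas

log = logging.getLogger("stoplatent")

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "load_region_config"]


@dataclass
class PipelineConfig:
    symptoms: str | Path | None = None
    betas: str | Path | None = None
    covariates: str | Path | None = None
    qc: str | Path | None = None
    sst_trials: str | Path | None = None
    out_dir: str | Path = "stoplatent_report"
    region_mode: str = "reliable"          # or "wholebrain"
    k_min: int = 1
    k_max: int = 5
    lca_starts: int = 50
    n_boot: int = 50
    fdr_alpha: float = 0.05
    reference_group: str | None = None     # default: the largest class
    seed: int = 0
    covariate_list: tuple[str, ...] = (
        "age", "sex", "race", "ethnicity", "caregiver_edu",
        "caregiver_marital", "family_income",
    )
    family_clustering: bool = False
    covariate_free_rerun: bool = False
    sex_interaction: bool = False

    def __post_init__(self):
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.k_min != 1:
            raise ValueError("class enumeration must start at K = 1")
        if self.region_mode not in ("reliable", "wholebrain"):
            raise ValueError("region_mode must be 'reliable' or 'wholebrain'")

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def load_region_config(mode: str = "reliable") -> dict:
    name = {"reliable": "regions_reliable.yaml",
            "wholebrain": "regions_wholebrain.yaml"}[mode]
    with resources.files("stoplatent.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

def validate_inputs(tables: dict[str, pd.DataFrame]) -> list[str]:
    """Schema checks over the input bundle; returns a list of violations."""
    violations: list[str] = []

    def need(tab, name, cols):
        if tab is None:
            return
        for c in cols:
            if c not in tab.columns:
                violations.append(f"{name}: missing column {c!r}")

    symptoms = tables.get("symptoms")
    if symptoms is not None:
        need(symptoms, "symptoms", ["subject_id"])
        for c in symptoms.columns:
            if c == "subject_id":
                continue
            vals = pd.to_numeric(symptoms[c], errors="coerce")
            bad = symptoms.index[~(vals.isin([0, 1]) | vals.isna())]
            if len(bad):
                violations.append(
                    f"symptoms: column {c!r} has non-binary values at rows "
                    f"{list(bad[:5])}"
                )

    betas = tables.get("betas")
    if betas is not None:
        need(betas, "betas", ["subject_id"])
        for c in betas.columns:
            if c == "subject_id":
                continue
            vals = pd.to_numeric(betas[c], errors="coerce")
            bad = betas.index[vals.isna() & betas[c].notna()]
            if len(bad):
                violations.append(
                    f"betas: non-numeric cell(s) in column {c!r} at rows "
                    f"{list(bad[:5])}"
                )

    covariates = tables.get("covariates")
    need(covariates, "covariates", ["subject_id", "site_id"])
    qc = tables.get("qc")
    need(qc, "qc", ["subject_id", "mean_fd_mm", "dof", "fs_qc", "perf_flag"])
    trials = tables.get("sst_trials")
    need(trials, "sst_trials",
         ["subject_id", "run", "trial_type", "ssd_ms", "responded", "rt_ms"])
    if trials is not None and "trial_type" in trials.columns:
        bad_types = set(trials["trial_type"].unique()) - {"go", "stop"}
        if bad_types:
            violations.append(f"sst_trials: unknown trial_type values {bad_types}")
    return violations


def _load_tables(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    tables = {}
    for key in ("symptoms", "betas", "covariates", "qc", "sst_trials"):
        path = getattr(config, key)
        if path is not None:
            tables[key] = pd.read_csv(path)
    return tables


def _max_efa_factors(k: int) -> int:
    m = 0
    for cand in (1, 2, 3):
        if (k - cand) ** 2 >= k + cand:
            m = cand
    return max(m, 1)


def _derive_network(betas, regions, seed) -> dict[str, list[str]]:
    """EFA ladder + discard criteria -> retained factor structure."""
    sub = betas[regions]
    results = {}
    for r in range(1, _max_efa_factors(len(regions)) + 1):
        results[r] = ExploratoryFactorAnalysis(
            n_factors=r, random_state=seed
        ).fit(sub)
    report = efa_discard(results, data=sub)
    if report.retained_structure is None:
        raise RuntimeError("no admissible factor structure for the region set")
    return report.retained_structure


def run_pipeline(config: PipelineConfig,
                 tables: dict[str, pd.DataFrame] | None = None) -> dict:
    """Execute the full analysis; returns the report dict and writes the bundle."""
    rng_seed = int(config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__, "seed": rng_seed,
        "config_hash": config.config_hash(),
        "config": {k: str(v) for k, v in asdict(config).items()},
    }

    def stage(name):
        log.info("stage: %s", name)

    if tables is None:
        tables = _load_tables(config)
    stage("validate")
    violations = validate_inputs(tables)
    if violations:
        raise ValueError("input schema violations: " + "; ".join(violations))

    symptoms = tables["symptoms"]
    betas = tables["betas"]
    covariates = tables["covariates"]

    # ---- QC ---------------------------------------------------------------
    stage("qc")
    if "qc" in tables:
        qc = tables["qc"].copy()
        if "sst_trials" in tables:
            trial_qc = qc_from_trials(tables["sst_trials"])
            qc = qc.merge(trial_qc, on="subject_id", how="left")
        else:
            qc["n_speedy_at_ssd50"] = 0
            qc["prop_ssd0"] = 0.0
        included, exclusions = qc_filter(qc)
        exclusions.to_csv(out / "qc_exclusions.csv", index=False)
        report["qc"] = {
            "n_total": len(exclusions),
            "n_included": len(included),
            "n_excluded": int(exclusions["excluded"].sum()),
        }
    else:
        included = list(betas["subject_id"])
        report["qc"] = {"n_total": len(included), "n_included": len(included),
                        "n_excluded": 0}

    imaging_mask = betas["subject_id"].isin(included)
    betas_inc = betas[imaging_mask].reset_index(drop=True)
    cov_inc = covariates.set_index("subject_id").loc[
        betas_inc["subject_id"]
    ].reset_index()

    # ---- winsorize --------------------------------------------------------
    stage("winsorize")
    betas_w, wins_report = winsorize_betas(betas_inc)
    betas_w.to_csv(out / "betas_winsorized.csv", index=False)
    report["winsorization"] = {
        "flagged_regions": wins_report["flagged_regions"],
        "mean_pct_altered_per_subject":
            float(wins_report["pct_altered_by_subject"].mean()),
        "max_pct_altered_per_subject":
            float(wins_report["pct_altered_by_subject"].max()),
    }

    # ---- LCA on the full phenotype sample ---------------------------------
    stage("lca")
    enum = enumerate_classes(
        symptoms, k_max=config.k_max, n_starts=config.lca_starts,
        n_boot=config.n_boot, seed=rng_seed, alpha=config.fdr_alpha,
    )
    enum.table.to_csv(out / "lca_enumeration.csv")
    enum.verdicts.to_csv(out / "lca_verdicts.csv")
    if enum.selected is None:
        raise RuntimeError("class enumeration selected no model: " + enum.note)
    K = enum.selected
    best = enum.fits[K]
    item_cols = [c for c in symptoms.columns if c != "subject_id"]
    labels_all = classify(best, symptoms[item_cols])
    posteriors = best.predict_proba(symptoms[item_cols])
    pd.DataFrame(
        posteriors, columns=[f"class{k + 1}" for k in range(K)]
    ).assign(subject_id=symptoms["subject_id"]).to_csv(
        out / "lca_posteriors.csv", index=False
    )
    labels_df = pd.DataFrame(
        {"subject_id": symptoms["subject_id"], "class": labels_all}
    )
    labels_df.to_csv(out / "lca_labels.csv", index=False)
    report["lca"] = {
        "selected_K": int(K), "note": enum.note,
        "class_proportions": best.weights_.tolist(),
        "smallest_class_pct": float(100 * best.weights_.min()),
    }

    # groups ordered by descending size; the largest class (typically the
    # low-symptom majority) is the reference unless overridden
    sizes = pd.Series(labels_all).value_counts()
    order = [f"class{k + 1}" for k in sizes.index]
    named = pd.Series([f"class{k + 1}" for k in labels_all])
    if config.reference_group and config.reference_group in order:
        order = ([config.reference_group]
                 + [g for g in order if g != config.reference_group])
    group_cat_all = pd.Categorical(named, categories=order, ordered=True)
    group_imaging = pd.Categorical(
        named[imaging_mask.to_numpy()], categories=order, ordered=True
    )

    # ---- covariate design --------------------------------------------------
    cov_cols = [c for c in config.covariate_list if c in cov_inc.columns]
    cov_model = cov_inc[cov_cols] if cov_cols else None
    # numeric covariates for the latent (MIMIC) models
    numeric_cov = None
    if cov_model is not None:
        num = {}
        for c in cov_model.columns:
            s = cov_model[c]
            if pd.api.types.is_numeric_dtype(s):
                num[c] = (s - s.mean()) / (s.std() if s.std() else 1.0)
            else:
                modal = s.mode().iloc[0]
                for lev in sorted(x for x in s.unique() if x != modal):
                    num[f"{c}__{lev}"] = (s == lev).astype(float)
        numeric_cov = pd.DataFrame(num)
    site_ids = cov_inc["site_id"] if "site_id" in cov_inc else None

    # ---- networks: EFA + CFA per contrast ----------------------------------
    stage("networks")
    regions_cfg = load_region_config(config.region_mode)
    if config.region_mode == "reliable":
        contrast_regions = {
            "response_inhibition": regions_cfg["response_inhibition"],
            "error_processing": regions_cfg["error_processing"],
        }
    else:
        parcels = regions_cfg["parcels"]
        contrast_regions = {
            "response_inhibition": [f"ri_{h}_{p}" for p in parcels
                                    for h in ("lh", "rh")
                                    if f"ri_{h}_{p}" in betas_w.columns],
            "error_processing": [f"ep_{h}_{p}" for p in parcels
                                 for h in ("lh", "rh")
                                 if f"ep_{h}_{p}" in betas_w.columns],
        }

    networks = {}
    contrasts_out = []
    ladder_out = {}
    for contrast, regions in contrast_regions.items():
        regions = [r for r in regions if r in betas_w.columns]
        structure = _derive_network(betas_w, regions, rng_seed)
        spec = FactorModelSpec(
            factors={f"{contrast}_{name}": inds
                     for name, inds in structure.items()},
            covariates=tuple(numeric_cov.columns) if numeric_cov is not None else (),
        )
        cfa_fit = fit_cfa(spec, betas_w, covariates=numeric_cov)
        idx = fit_indices(cfa_fit)
        networks[contrast] = {
            "structure": {k: list(v) for k, v in spec.factors.items()},
            "std_loadings": cfa_fit.standardized_loadings().round(4).to_dict(),
            "fit_indices": idx.as_dict(),
        }

        stage(f"invariance[{contrast}]")
        ladder = invariance_ladder(
            spec, betas_w, groups=group_imaging, covariates=numeric_cov
        )
        ladder_out[contrast] = {
            "attained": ladder.attained,
            "deltas": ladder.deltas.reset_index().to_dict("records"),
        }
        if ladder.attained == "scalar":
            scalar_fit = ladder.fits["scalar"]
            param_cov = None
            if config.family_clustering and "family_id" in cov_inc:
                param_cov = scalar_fit.cluster_robust_cov(
                    cov_inc["family_id"].to_numpy()
                )
            tab = compare_latent_means(scalar_fit, param_cov=param_cov)
            tab.insert(0, "contrast", contrast)
            contrasts_out.append(tab)
    report["networks"] = networks
    report["invariance"] = ladder_out
    if contrasts_out:
        contrasts_df = pd.concat(contrasts_out, ignore_index=True)
        contrasts_df.to_csv(out / "latent_contrasts.csv", index=False)
        report["latent_contrasts_file"] = "latent_contrasts.csv"

    # ---- regional scan ------------------------------------------------------
    stage("regions")
    scan_regions = [r for reg in contrast_regions.values() for r in reg
                    if r in betas_w.columns]
    regions_table = region_scan(
        betas_w, scan_regions, group_imaging, covariates=cov_model,
        site_ids=site_ids, alpha=config.fdr_alpha,
    )
    regions_table.drop(columns=["significant"]).to_csv(out / "regions.csv")
    report["regions_file"] = "regions.csv"
    if config.sex_interaction and cov_model is not None and "sex" in cov_model:
        cov_nosex = cov_model.drop(columns=["sex"])
        sex_table = sex_by_group_scan(
            betas_w, scan_regions, group_imaging, cov_model["sex"],
            covariates=cov_nosex, site_ids=site_ids, alpha=config.fdr_alpha,
        )
        sex_table.to_csv(out / "sex_by_group.csv")
        report["sex_by_group_file"] = "sex_by_group.csv"

    # ---- SSRT ---------------------------------------------------------------
    if "sst_trials" in tables:
        stage("ssrt")
        trials = tables["sst_trials"]
        ssrt_rows = []
        for sid, df in trials.groupby("subject_id", sort=False):
            res = compute_ssrt(df, subject_id=sid)
            ssrt_rows.append({"subject_id": sid, "ssrt_ms": res.ssrt_ms,
                              "p_respond_signal": res.p_respond_signal,
                              "valid": res.valid})
        ssrt_df = pd.DataFrame(ssrt_rows)
        ssrt_df.to_csv(out / "ssrt.csv", index=False)
        merged = betas_inc[["subject_id"]].merge(ssrt_df, on="subject_id")
        ok = merged["valid"] & merged["ssrt_ms"].notna()
        if ok.sum() > 50:
            res = fit_lmm(
                merged.loc[ok, "ssrt_ms"].to_numpy(float),
                pd.Series(np.asarray(group_imaging))[ok.to_numpy()],
                covariates=cov_model[ok.to_numpy()] if cov_model is not None else None,
                site_ids=site_ids[ok.to_numpy()] if site_ids is not None else None,
            )
            report["ssrt"] = {
                "mean_ms": float(merged.loc[ok, "ssrt_ms"].mean()),
                "sd_ms": float(merged.loc[ok, "ssrt_ms"].std()),
                "F": res.f_stat, "df_num": res.df_num,
                "df_den": res.df_den, "p": res.p_value,
            }

    # ---- covariate-free rerun ----------------------------------------------
    if config.covariate_free_rerun and contrasts_out:
        stage("covariate-free rerun")
        rerun = []
        for contrast, regions in contrast_regions.items():
            structure = networks[contrast]["structure"]
            spec0 = FactorModelSpec(factors=structure)
            ladder0 = invariance_ladder(spec0, betas_w, groups=group_imaging)
            if ladder0.attained == "scalar":
                tab0 = compare_latent_means(ladder0.fits["scalar"])
                tab0.insert(0, "contrast", contrast)
                rerun.append(tab0)
        if rerun:
            pd.concat(rerun, ignore_index=True).to_csv(
                out / "latent_contrasts_no_covariates.csv", index=False
            )
            report["covariate_free_file"] = "latent_contrasts_no_covariates.csv"

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
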