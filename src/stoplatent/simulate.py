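"""Synthetic-data generators emulating a stop-signal-task (SST) cohort study.

The generators produce every input the analysis pipeline consumes:

* binary K-SADS-style symptom items (4 irritability + 18 ADHD) drawn from a
  finite mixture of latent phenotype classes,
* region-level task-contrast beta weights with a latent coactivation-factor
  structure (group-shifted latent means, site intercepts, covariate effects),
* socio-demographic covariates with site and family structure,
* trial-level SST sessions driven by a one-up/one-down SSD staircase and an
  independent-race responder, plus scan-QC fields.

Defaults are calibrated to the published cohort conditions: four phenotype
classes with mixing proportions 9781/787/901/279 out of 11,748 (83.3 / 6.7 /
7.7 / 2.4 %), a single response-inhibition factor with standardized loadings
(0.91, 0.86, 0.68, 0.51), two correlated error-processing factors with
loadings (0.84, 0.93, 0.79) and (0.93, 0.98, 0.68), response-inhibition
latent means (0, 0.17, -0.17, -0.56) across classes, and 2-run x 180-trial
SST sessions with 30 stop trials per run tracking a 50% stop-success rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import check_rng

__all__ = [
    "PhenotypeGenConfig",
    "FactorBlock",
    "NeuroGenConfig",
    "SSTGenConfig",
    "generate_symptoms",
    "generate_covariates",
    "generate_betas",
    "generate_sst_session",
    "generate_qc",
    "generate_bundle",
    "IRRITABILITY_ITEMS",
    "ADHD_ITEMS",
    "DEFAULT_CLASS_NAMES",
]

IRRITABILITY_ITEMS = [f"irr_{i}" for i in range(1, 5)]
ADHD_ITEMS = [f"adhd_{i}" for i in range(1, 19)]

DEFAULT_CLASS_NAMES = ["td", "adhd_irr", "adhd", "irr"]

# Mixing proportions from the published class sizes 9781/787/901/279 of 11748
# (prints as 83.3/6.7/7.7/2.4%); using the counts keeps the simplex exact.
_DEFAULT_COUNTS = np.array([9781.0, 787.0, 901.0, 279.0])
DEFAULT_CLASS_PROPORTIONS = _DEFAULT_COUNTS / _DEFAULT_COUNTS.sum()


def _default_endorse_probs() -> np.ndarray:
    """Class-conditional endorsement probabilities (4 classes x 22 items).

    Qualitative calibration of the published class profiles (synthetic
    values; the source reports the profiles only graphically): high ~0.9,
    moderate ~0.5, low ~0.02-0.05.
    """
    p = np.empty((4, 22))
    # columns: 4 irritability then 18 ADHD items
    p[0, :4], p[0, 4:] = 0.02, 0.02   # typically developing
    p[1, :4], p[1, 4:] = 0.20, 0.90   # high ADHD + co-occurring irritability
    p[2, :4], p[2, 4:] = 0.05, 0.50   # moderate ADHD, low irritability
    p[3, :4], p[3, 4:] = 0.90, 0.05   # high irritability, low ADHD
    return p


@dataclass
class PhenotypeGenConfig:
    """Configuration of the latent-class symptom generator.

    ``class_proportions`` are the mixture weights pi_k; ``endorse_probs`` the
    class-conditional Bernoulli endorsement probabilities rho_kj.
    """

    n_classes: int = 4
    class_proportions: np.ndarray = field(
        default_factory=lambda: DEFAULT_CLASS_PROPORTIONS.copy()
    )
    endorse_probs: np.ndarray = field(default_factory=_default_endorse_probs)
    item_labels: list[str] = field(
        default_factory=lambda: IRRITABILITY_ITEMS + ADHD_ITEMS
    )
    seed: int | None = None

    def validate(self) -> None:
        pi = np.asarray(self.class_proportions, dtype=float)
        rho = np.asarray(self.endorse_probs, dtype=float)
        if pi.shape != (self.n_classes,):
            raise ValueError("class_proportions length must equal n_classes")
        if abs(pi.sum() - 1.0) > 1e-12 or (pi < 0).any():
            raise ValueError("class_proportions must be a probability vector summing to 1")
        if rho.shape != (self.n_classes, len(self.item_labels)):
            raise ValueError("endorse_probs must be (n_classes, n_items)")
        if ((rho < 0) | (rho > 1)).any():
            raise ValueError("endorse_probs must lie in [0, 1]")


def generate_symptoms(
    config: PhenotypeGenConfig, n: int, rng=None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw ``n`` subjects' binary symptom items from the class mixture.

    Returns (items table indexed by subject_id, true class labels).
    """
    config.validate()
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = check_rng(rng if rng is not None else config.seed)
    labels = rng.choice(config.n_classes, size=n, p=np.asarray(config.class_proportions, float))
    probs = np.asarray(config.endorse_probs, float)[labels]
    items = (rng.random((n, probs.shape[1])) < probs).astype(int)
    table = pd.DataFrame(items, columns=list(config.item_labels))
    table.insert(0, "subject_id", [f"sub-{i:06d}" for i in range(n)])
    return table, labels


# ---------------------------------------------------------------------------
# Region-level beta weights
# ---------------------------------------------------------------------------

@dataclass
class FactorBlock:
    """One latent factor: name, indicator region columns, standardized loadings."""

    name: str
    indicators: list[str]
    loadings: np.ndarray

    def __post_init__(self):
        self.loadings = np.asarray(self.loadings, dtype=float)
        if len(self.indicators) != self.loadings.size:
            raise ValueError(f"block {self.name}: indicators/loadings length mismatch")
        if (np.abs(self.loadings) >= 1).any():
            raise ValueError(f"block {self.name}: standardized loadings must lie in (-1, 1)")


def _default_ri_blocks() -> list[FactorBlock]:
    return [
        FactorBlock(
            "response_inhibition",
            ["ri_lh_inferior_parietal", "ri_lh_supramarginal",
             "ri_lh_lateral_occipital", "ri_lh_pars_orbitalis"],
            np.array([0.91, 0.86, 0.68, 0.51]),
        )
    ]


def _default_ep_blocks() -> list[FactorBlock]:
    return [
        FactorBlock(
            "error_processing_1",
            ["ep_rh_lateral_orbitofrontal", "ep_lh_lateral_orbitofrontal",
             "ep_lh_pars_orbitalis"],
            np.array([0.84, 0.93, 0.79]),
        ),
        FactorBlock(
            "error_processing_2",
            ["ep_rh_superior_parietal", "ep_lh_superior_parietal",
             "ep_lh_lateral_occipital"],
            np.array([0.93, 0.98, 0.68]),
        ),
    ]


@dataclass
class NeuroGenConfig:
    """Configuration of the latent-coactivation beta-weight generator.

    The measurement model per indicator i in factor block f is::

        beta_i = lambda_i * (alpha_g + gamma' x + zeta_f) + u_{site,i} + eps_i

    with Var(zeta) = 1, Cov(zeta_f, zeta_g) = factor_correlations, uniqueness
    eps_i ~ N(0, 1 - lambda_i^2) so the site/covariate-free implied indicator
    correlation is lambda_i * lambda_j within a block.
    """

    factor_blocks: list[FactorBlock] = field(
        default_factory=lambda: _default_ri_blocks() + _default_ep_blocks()
    )
    # rows: phenotype classes in DEFAULT_CLASS_NAMES order; cols: factors.
    # Response-inhibition latent means from the published group contrasts;
    # error-processing means 0 (null group differences reported).
    group_latent_means: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.0, 0.0, 0.0],
             [0.17, 0.0, 0.0],
             [-0.17, 0.0, 0.0],
             [-0.56, 0.0, 0.0]]
        )
    )
    # None -> default matrix for the default 3-factor set (RI/EP1/EP2 with
    # EP inter-factor correlation 0.4), identity otherwise
    factor_correlations: np.ndarray | None = None
    residual_variances: np.ndarray | None = None  # default 1 - lambda^2
    # covariate name -> per-factor coefficient vector on the latent factors
    covariate_effects: dict[str, np.ndarray] = field(default_factory=dict)
    site_sd: float = 0.15
    n_sites: int = 21
    seed: int | None = None

    @property
    def factor_names(self) -> list[str]:
        return [b.name for b in self.factor_blocks]

    @property
    def indicator_names(self) -> list[str]:
        return [name for b in self.factor_blocks for name in b.indicators]

    def validate(self) -> None:
        m = len(self.factor_blocks)
        if self.factor_correlations is None:
            if m == 3 and self.factor_names == [
                "response_inhibition", "error_processing_1", "error_processing_2"
            ]:
                self.factor_correlations = np.array(
                    [[1.0, 0.2, 0.2], [0.2, 1.0, 0.4], [0.2, 0.4, 1.0]]
                )
            else:
                self.factor_correlations = np.eye(m)
        G = np.asarray(self.group_latent_means, float)
        if G.ndim != 2 or G.shape[1] != m:
            raise ValueError("group_latent_means must be (n_groups, n_factors)")
        phi = np.asarray(self.factor_correlations, float)
        if phi.shape != (m, m):
            raise ValueError("factor_correlations must be (n_factors, n_factors)")
        if not np.allclose(phi, phi.T) or not np.allclose(np.diag(phi), 1.0):
            raise ValueError("factor_correlations must be a correlation matrix")
        if self.residual_variances is not None:
            rv = np.asarray(self.residual_variances, float)
            if rv.size != len(self.indicator_names) or (rv < 0).any():
                raise ValueError("residual_variances must be non-negative, one per indicator")


def generate_betas(
    config: NeuroGenConfig,
    class_labels: np.ndarray,
    covariates: pd.DataFrame | None = None,
    site_ids: np.ndarray | None = None,
    rng=None,
) -> pd.DataFrame:
    """Generate the subjects x regions beta-weight table.

    ``class_labels`` index rows of ``config.group_latent_means``; covariate
    effects are applied to the latent factors (numeric covariate columns
    named in ``config.covariate_effects``).
    """
    config.validate()
    rng = check_rng(rng if rng is not None else config.seed)
    labels = np.asarray(class_labels, dtype=int)
    n = labels.size
    G = np.asarray(config.group_latent_means, float)
    if labels.min() < 0 or labels.max() >= G.shape[0]:
        raise ValueError("class label outside the rows of group_latent_means")
    m = len(config.factor_blocks)

    eta = G[labels]  # (n, m) latent means
    for cov_name, coefs in config.covariate_effects.items():
        coefs = np.atleast_1d(np.asarray(coefs, float))
        if coefs.size != m:
            raise ValueError(f"covariate_effects[{cov_name!r}] must have one entry per factor")
        if covariates is None or cov_name not in covariates:
            raise ValueError(f"covariate {cov_name!r} required by config but not supplied")
        x = np.asarray(covariates[cov_name], float)
        eta = eta + np.outer(x, coefs)

    chol = np.linalg.cholesky(np.asarray(config.factor_correlations, float))
    eta = eta + rng.standard_normal((n, m)) @ chol.T

    cols = {}
    lam_all = []
    pos = 0
    rv = (np.asarray(config.residual_variances, float)
          if config.residual_variances is not None else None)
    if site_ids is None:
        site_ids = np.zeros(n, dtype=int)
    site_ids = np.asarray(site_ids, dtype=int)
    n_sites = max(config.n_sites, site_ids.max() + 1)

    for f, block in enumerate(config.factor_blocks):
        for j, (name, lam) in enumerate(zip(block.indicators, block.loadings)):
            theta = rv[pos] if rv is not None else max(1.0 - lam**2, 0.0)
            site_u = rng.normal(0.0, config.site_sd, size=n_sites)[site_ids]
            cols[name] = (lam * eta[:, f] + site_u
                          + rng.normal(0.0, np.sqrt(theta), size=n))
            lam_all.append(lam)
            pos += 1

    table = pd.DataFrame(cols)
    table.insert(0, "subject_id", [f"sub-{i:06d}" for i in range(n)])
    return table


# ---------------------------------------------------------------------------
# Covariates and QC fields
# ---------------------------------------------------------------------------

def generate_covariates(
    n: int,
    n_sites: int = 21,
    sibling_rate: float = 0.1,
    rng=None,
) -> pd.DataFrame:
    """Socio-demographic covariates with site and family structure.

    Independent draws calibrated to the published sample description (mean
    age 9.9 y (SD 0.6), 52.9% female, 78.4% white, 71.7% married caregivers).
    A ``sibling_rate`` fraction of subjects shares a family id in pairs.
    """
    rng = check_rng(rng)
    age = rng.normal(9.9, 0.6, size=n).round(2)
    sex = rng.choice(["F", "M"], size=n, p=[0.529, 0.471])
    race = rng.choice(
        ["white", "black", "asian", "other"], size=n, p=[0.784, 0.10, 0.05, 0.066]
    )
    ethnicity = rng.choice(["not_hispanic", "hispanic"], size=n, p=[0.80, 0.20])
    edu = rng.choice(
        ["lt_hs", "hs", "some_college", "bachelor", "postgrad"],
        size=n, p=[0.05, 0.15, 0.30, 0.30, 0.20],
    )
    marital = rng.choice(["married", "not_married"], size=n, p=[0.717, 0.283])
    income = rng.choice(
        ["lt_50k", "50_100k", "100_200k", "gt_200k"],
        size=n, p=[0.25, 0.30, 0.35, 0.10],
    )
    site = rng.integers(0, n_sites, size=n)

    family = np.arange(n)
    n_pairs = int(sibling_rate * n / 2)
    if n_pairs > 0:
        idx = rng.permutation(n)[: 2 * n_pairs]
        family[idx[n_pairs:]] = family[idx[:n_pairs]]

    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:06d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "race": race,
            "ethnicity": ethnicity,
            "caregiver_edu": edu,
            "caregiver_marital": marital,
            "family_income": income,
            "site_id": [f"site{s:02d}" for s in site],
            "family_id": [f"fam-{f:06d}" for f in family],
        }
    )


def generate_qc(n: int, rng=None) -> pd.DataFrame:
    """Scan-QC fields: mean framewise displacement, dof, FreeSurfer/performance flags."""
    rng = check_rng(rng)
    fd = np.exp(rng.normal(np.log(0.25), 0.6, size=n)).round(4)
    dof = np.maximum(rng.normal(650, 130, size=n), 50).round(0)
    fs_qc = (rng.random(n) < 0.97).astype(int)
    perf = (rng.random(n) < 0.95).astype(int)
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:06d}" for i in range(n)],
            "mean_fd_mm": fd,
            "dof": dof,
            "fs_qc": fs_qc,
            "perf_flag": perf,
        }
    )


# ---------------------------------------------------------------------------
# SST sessions
# ---------------------------------------------------------------------------

@dataclass
class SSTGenConfig:
    """Stop-signal task session generator settings.

    The staircase is one-up/one-down: a successful stop raises the SSD by
    ``ssd_step`` ms (harder), a failed stop lowers it (floored at
    ``ssd_min``), tracking ~50% stop success. Stop-trial outcomes follow an
    independent-race rule: the subject responds iff the go-process finishing
    time is below SSD + ``ssrt_true``. Go RTs are lognormal with median
    ``go_rt_distribution[0]`` ms and log-scale ``go_rt_distribution[1]``.
    """

    n_runs: int = 2
    trials_per_run: int = 180
    stop_per_run: int = 30
    ssd_start: float = 50.0
    ssd_step: float = 50.0
    ssd_min: float = 0.0
    go_rt_distribution: tuple[float, float] = (500.0, 0.25)
    ssrt_true: float = 280.0
    omission_prob: float = 0.02
    seed: int | None = None

    def validate(self) -> None:
        if self.stop_per_run > self.trials_per_run:
            raise ValueError("stop_per_run must not exceed trials_per_run")
        for name in ("ssd_start", "ssd_step", "ssd_min", "ssrt_true"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.omission_prob <= 1:
            raise ValueError("omission_prob must be a probability")


def generate_sst_session(
    config: SSTGenConfig, subject_seed=None, subject_id: str = "sub-000000"
) -> pd.DataFrame:
    """Simulate one subject's SST session as a trial-level event table.

    Columns: subject_id, run, trial_index, trial_type {go,stop}, ssd_ms,
    responded {0,1}, rt_ms (NaN for omissions / successful stops), correct.
    """
    config.validate()
    rng = check_rng(subject_seed if subject_seed is not None else config.seed)
    median, sigma = config.go_rt_distribution
    rows = []
    ssd = float(config.ssd_start)  # staircase persists across runs
    for run in range(1, config.n_runs + 1):
        is_stop = np.zeros(config.trials_per_run, dtype=bool)
        is_stop[rng.choice(config.trials_per_run, size=config.stop_per_run,
                           replace=False)] = True
        go_finish = median * np.exp(sigma * rng.standard_normal(config.trials_per_run))
        omit = rng.random(config.trials_per_run) < config.omission_prob
        for t in range(config.trials_per_run):
            if is_stop[t]:
                responded = int(go_finish[t] < ssd + config.ssrt_true)
                rows.append(
                    (subject_id, run, t, "stop", ssd,
                     responded, go_finish[t] if responded else np.nan,
                     1 - responded)
                )
                if responded:
                    ssd = max(ssd - config.ssd_step, config.ssd_min)
                else:
                    ssd = ssd + config.ssd_step
            else:
                responded = int(not omit[t])
                rows.append(
                    (subject_id, run, t, "go", np.nan,
                     responded, go_finish[t] if responded else np.nan,
                     responded)
                )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "run", "trial_index", "trial_type",
                 "ssd_ms", "responded", "rt_ms", "correct"],
    )


# ---------------------------------------------------------------------------
# Full input bundle
# ---------------------------------------------------------------------------

def generate_bundle(
    n: int,
    out_dir: str | Path | None = None,
    seed: int = 0,
    phenotype_config: PhenotypeGenConfig | None = None,
    neuro_config: NeuroGenConfig | None = None,
    sst_config: SSTGenConfig | None = None,
    with_sst: bool = True,
) -> dict[str, pd.DataFrame]:
    """Generate a coherent input bundle (symptoms, covariates, betas, SST, QC).

    When ``out_dir`` is given the tables are written as CSV files with the
    canonical names (symptoms.csv, covariates.csv, betas.csv, sst_trials.csv,
    qc.csv, labels_true.csv).
    """
    rng = np.random.default_rng(seed)
    pheno = phenotype_config or PhenotypeGenConfig()
    neuro = neuro_config or NeuroGenConfig()
    sstc = sst_config or SSTGenConfig()

    symptoms, labels = generate_symptoms(pheno, n, rng=rng)
    covariates = generate_covariates(n, n_sites=neuro.n_sites, rng=rng)
    site_codes = covariates["site_id"].str.slice(4).astype(int).to_numpy()
    cov_numeric = pd.DataFrame(
        {"age": (covariates["age"] - covariates["age"].mean()) / covariates["age"].std()}
    )
    betas = generate_betas(neuro, labels, covariates=cov_numeric,
                           site_ids=site_codes, rng=rng)
    qc = generate_qc(n, rng=rng)

    bundle = {
        "symptoms": symptoms,
        "covariates": covariates,
        "betas": betas,
        "qc": qc,
        "labels_true": pd.DataFrame(
            {"subject_id": symptoms["subject_id"], "true_class": labels}
        ),
    }
    if with_sst:
        seeds = rng.integers(0, 2**31 - 1, size=n)
        trials = pd.concat(
            [generate_sst_session(sstc, int(s), subject_id=f"sub-{i:06d}")
             for i, s in enumerate(seeds)],
            ignore_index=True,
        )
        bundle["sst_trials"] = trials

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        names = {
            "symptoms": "symptoms.csv",
            "covariates": "covariates.csv",
            "betas": "betas.csv",
            "qc": "qc.csv",
            "labels_true": "labels_true.csv",
            "sst_trials": "sst_trials.csv",
        }
        for key, df in bundle.items():
            df.to_csv(out / names[key], index=False)
    return bundle
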