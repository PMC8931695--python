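"""Stop-signal task behavior and quality control.

Covers the study-defined exclusion rules (motion, degrees of freedom,
FreeSurfer QC, behavioral performance flag, the SSD-coding screens),
integration-method SSRT with the standard behavioral adjustments (omission
replacement, premature stop responses counted as failed stops), and the
conditional winsorization of region-level beta weights (clip to mean +- 3 SD
only for regions that are both out-of-bounds and skewed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import skew

__all__ = [
    "QCRecord",
    "SSRTResult",
    "qc_from_trials",
    "qc_filter",
    "compute_ssrt",
    "winsorize_betas",
    "compare_ssrt_groups",
]


@dataclass
class QCRecord:
    """Per-subject scan/behavior QC fields feeding the exclusion rules."""

    subject_id: str
    mean_fd_mm: float | None = None
    dof: float | None = None
    fs_qc: int | None = None          # 1 = pass
    perf_flag: int | None = None      # 1 = pass
    n_speedy_at_ssd50: int | None = None
    prop_ssd0: float | None = None


@dataclass
class SSRTResult:
    subject_id: str
    ssrt_ms: float | None
    p_respond_signal: float
    nth_go_rt_ms: float | None
    mean_ssd_ms: float
    n_go: int
    n_omissions_replaced: int
    n_premature_stop: int
    valid: bool
    reason: str = ""


def qc_from_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Derive the trial-based QC fields per subject from an SST event table.

    Returns columns: subject_id, n_speedy_at_ssd50 (responses < 50 ms on
    stop trials with SSD = 50 ms), prop_ssd0 (share of stop trials at 0 ms).
    """
    rows = []
    for sid, df in trials.groupby("subject_id", sort=False):
        stop = df[df["trial_type"] == "stop"]
        speedy = int(((stop["ssd_ms"] == 50)
                      & (stop["responded"] == 1)
                      & (stop["rt_ms"] < 50)).sum())
        prop0 = float((stop["ssd_ms"] == 0).mean()) if len(stop) else 0.0
        rows.append({"subject_id": sid, "n_speedy_at_ssd50": speedy,
                     "prop_ssd0": prop0})
    return pd.DataFrame(rows)


_RULES = (
    ("fd", lambda r: r.mean_fd_mm is not None and r.mean_fd_mm >= 0.9,
     "mean FD >= 0.9 mm"),
    ("dof", lambda r: r.dof is not None and r.dof <= 200,
     "degrees of freedom <= 200"),
    ("fs_qc", lambda r: r.fs_qc is not None and r.fs_qc == 0,
     "FreeSurfer QC fail"),
    ("perf", lambda r: r.perf_flag is not None and r.perf_flag == 0,
     "SST performance check fail"),
    ("speedy", lambda r: r.n_speedy_at_ssd50 is not None and r.n_speedy_at_ssd50 > 0,
     "speedy (<50 ms) response at SSD = 50 ms"),
    ("ssd0", lambda r: r.prop_ssd0 is not None and r.prop_ssd0 >= 0.10,
     "stop trials at SSD = 0 ms >= 10%"),
)

_REQUIRED_FIELDS = ("mean_fd_mm", "dof", "fs_qc", "perf_flag",
                    "n_speedy_at_ssd50", "prop_ssd0")


def qc_filter(records) -> tuple[list[str], pd.DataFrame]:
    """Apply the exclusion rules; returns (included ids, exclusion table).

    A record is excluded when ANY rule triggers; missing required fields
    exclude with reason "missing:<field>". The exclusion table lists every
    subject with its triggering rules (empty string = included).
    """
    if isinstance(records, pd.DataFrame):
        records = [
            QCRecord(**{k: row.get(k) for k in
                        ("subject_id",) + _REQUIRED_FIELDS if k in row})
            for row in records.to_dict("records")
        ]
    included = []
    rows = []
    for rec in records:
        reasons = [f"missing:{f}" for f in _REQUIRED_FIELDS
                   if getattr(rec, f) is None or
                   (isinstance(getattr(rec, f), float) and np.isnan(getattr(rec, f)))]
        if not reasons:
            reasons = [msg for _, trig, msg in _RULES if trig(rec)]
        if reasons:
            rows.append({"subject_id": rec.subject_id, "excluded": True,
                         "reasons": "; ".join(reasons)})
        else:
            included.append(rec.subject_id)
            rows.append({"subject_id": rec.subject_id, "excluded": False,
                         "reasons": ""})
    return included, pd.DataFrame(rows)


def compute_ssrt(trials: pd.DataFrame, subject_id: str | None = None) -> SSRTResult:
    """Integration-method SSRT with behavioral adjustments.

    Go omissions are assigned the maximum observed go RT; premature
    responses on stop trials count toward p(respond | signal); the index
    into the ascending adjusted go-RT list is ceil(p * N_go); SSRT = nth go
    RT - mean SSD over all stop trials.
    """
    if subject_id is None:
        ids = trials["subject_id"].unique() if "subject_id" in trials else ["?"]
        subject_id = str(ids[0])
    go = trials[trials["trial_type"] == "go"]
    stop = trials[trials["trial_type"] == "stop"]
    if len(go) == 0 or len(stop) == 0:
        raise ValueError("need at least one go and one stop trial")
    p_respond = float((stop["responded"] == 1).mean())
    n_premature = int(((stop["responded"] == 1)
                       & (stop["rt_ms"] < stop["ssd_ms"])).sum())
    mean_ssd = float(stop["ssd_ms"].mean())
    go_rts = go["rt_ms"].to_numpy(dtype=float)
    omitted = ~np.isfinite(go_rts)
    n_omit = int(omitted.sum())
    if n_omit == len(go_rts):
        return SSRTResult(subject_id, None, p_respond, None, mean_ssd,
                          len(go_rts), n_omit, n_premature, False,
                          "all go trials omitted")
    max_rt = np.nanmax(go_rts)
    adj = np.where(omitted, max_rt, go_rts)
    adj.sort()
    if p_respond == 0:
        return SSRTResult(subject_id, None, 0.0, None, mean_ssd,
                          len(adj), n_omit, n_premature, False,
                          "no failed stops: p(respond|signal) = 0")
    nth_index = int(np.ceil(p_respond * len(adj)))
    nth = float(adj[min(nth_index, len(adj)) - 1])
    return SSRTResult(subject_id, nth - mean_ssd, p_respond, nth, mean_ssd,
                      len(adj), n_omit, n_premature, True)


def winsorize_betas(betas: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Conditional winsorization of region columns.

    A region is flagged "extreme-outlier" when at least one value lies
    outside mean +- 3 SD AND the column's absolute moment skewness
    (adjusted Fisher-Pearson) exceeds 2; flagged regions have out-of-bound
    values clipped to the boundary computed from the ORIGINAL column
    (single pass, no recomputation). The report gives the percentage of
    altered points per region and per subject.
    """
    region_cols = [c for c in betas.columns if c != "subject_id"]
    if len(betas) < 3:
        raise ValueError("need at least 3 subjects per region")
    out = betas.copy()
    flagged, skipped = [], []
    altered_by_region = {}
    altered_mask = np.zeros((len(betas), len(region_cols)), dtype=bool)
    for j, col in enumerate(region_cols):
        x = betas[col].to_numpy(dtype=float)
        sd = np.std(x, ddof=1)
        if sd == 0:
            skipped.append(col)
            altered_by_region[col] = 0.0
            continue
        mean = x.mean()
        lo, hi = mean - 3 * sd, mean + 3 * sd
        outside = (x < lo) | (x > hi)
        g1 = skew(x, bias=False)
        if outside.any() and abs(g1) > 2:
            flagged.append(col)
            out[col] = np.clip(x, lo, hi)
            altered_mask[:, j] = outside
            altered_by_region[col] = 100.0 * outside.mean()
        else:
            altered_by_region[col] = 0.0
    per_subject = 100.0 * altered_mask.mean(axis=1)
    report = {
        "flagged_regions": flagged,
        "skipped_zero_variance": skipped,
        "pct_altered_by_region": altered_by_region,
        "pct_altered_by_subject": pd.Series(
            per_subject,
            index=(betas["subject_id"] if "subject_id" in betas
                   else betas.index),
        ),
    }
    return out, report


def compare_ssrt_groups(ssrt, labels, covariates=None, site_ids=None):
    """Group comparison of SSRT via the site-random-intercept mixed model."""
    from .lmm import fit_lmm
    return fit_lmm(np.asarray(ssrt, float), labels,
                   covariates=covariates, site_ids=site_ids)
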