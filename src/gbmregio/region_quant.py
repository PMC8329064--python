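"""Tumour-region quantification from per-patient stacks of label masks.

Pixels of each region are counted across all masks of a patient and averaged
over the number of masks ("averaged pixel counting"), which normalises for
patients contributing different numbers of sections.  Areas are then
converted to per-patient fractions of total non-background tissue, and the
survival (or area) values screened for outliers with an iterative two-sided
Grubbs test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .segmentation import CLASS_MAP, TUMOUR_REGIONS, LabeledSlide
from .util import get_logger

log = get_logger("region_quant")


def averaged_pixel_count(masks) -> pd.Series:
    """Average per-region pixel counts over one patient's masks (BG excluded)."""
    mask_arrays = [m.mask if isinstance(m, LabeledSlide) else np.asarray(m)
                   for m in masks]
    if not mask_arrays:
        raise ValueError("patient has zero masks")
    counts = np.stack([np.bincount(m.ravel(), minlength=CLASS_MAP.n_classes)
                       for m in mask_arrays]).astype(float)
    return pd.Series(counts.mean(axis=0)[1:], index=list(TUMOUR_REGIONS))


def build_area_table(masks_by_patient) -> pd.DataFrame:
    """Patients x 7-regions table of averaged pixel counts."""
    rows = {pid: averaged_pixel_count(masks)
            for pid, masks in masks_by_patient.items()}
    table = pd.DataFrame(rows).T
    table.index.name = "patient_id"
    return table


def normalize_areas(table: pd.DataFrame) -> pd.DataFrame:
    """Per-patient region fractions of total non-BG tissue (rows sum to 1).

    Patients with zero total tissue are dropped with a logged warning.
    """
    totals = table.sum(axis=1)
    degenerate = totals <= 0
    if degenerate.any():
        log.warning("dropping %d patient(s) with zero tissue: %s",
                    int(degenerate.sum()),
                    ", ".join(map(str, table.index[degenerate])))
        table = table.loc[~degenerate]
        totals = totals[~degenerate]
    return table.div(totals, axis=0)


@dataclass
class GrubbsResult:
    """Audit trail of an iterative Grubbs screen."""

    kept: list[int]
    removed: list[int]
    trail: list[dict] = field(default_factory=list)


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value G_crit(n, alpha) from the
    upper alpha/(2n) Student-t quantile with n-2 degrees of freedom."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_screen(values, alpha: float = 0.05) -> GrubbsResult:
    """Iterative two-sided Grubbs outlier screen.

    At each iteration G = max|x_i - mean| / sd (sample sd, ddof=1); the most
    extreme value is removed while G exceeds the critical value, and the
    statistics are recomputed.  A zero-variance sample yields a no-outlier
    result with a warning.  The returned trail records (n, G, G_crit,
    removed index) per iteration.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("grubbs_screen expects a 1-d sequence")
    if len(x) < 3:
        raise ValueError("need at least 3 values")
    idx = list(range(len(x)))
    removed: list[int] = []
    trail: list[dict] = []
    while len(idx) >= 3:
        sub = x[idx]
        s = sub.std(ddof=1)
        if s == 0:
            log.warning("zero sample standard deviation; no outliers removable")
            break
        dev = np.abs(sub - sub.mean())
        j = int(np.argmax(dev))
        g = dev[j] / s
        gcrit = grubbs_critical(len(idx), alpha)
        step = {"n": len(idx), "G": float(g), "G_crit": float(gcrit),
                "removed": None}
        if g > gcrit:
            step["removed"] = idx[j]
            removed.append(idx[j])
            trail.append(step)
            idx.pop(j)
        else:
            trail.append(step)
            break
    return GrubbsResult(kept=idx, removed=removed, trail=trail)


def screen_cohort(area_fractions: pd.DataFrame, clinical: pd.DataFrame,
                  alpha: float = 0.05, target: str = "survival"):
    """Apply the Grubbs screen to a cohort.

    ``target`` selects what is screened: "survival" (default) screens the
    survival-day values; "areas" screens each region-area column and removes
    the union of flagged patients.  Returns ``(kept patient ids, audit)``
    where audit maps screened-variable name to its :class:`GrubbsResult`.
    """
    clin = clinical.set_index("patient_id") if "patient_id" in clinical else clinical
    shared = [p for p in area_fractions.index if p in clin.index]
    audit: dict[str, GrubbsResult] = {}
    if target == "survival":
        vals = clin.loc[shared, "survival_days"].to_numpy(dtype=float)
        res = grubbs_screen(np.log(vals), alpha=alpha)
        audit["survival"] = res
        kept = [shared[i] for i in res.kept]
    elif target == "areas":
        flagged: set[str] = set()
        for region in area_fractions.columns:
            res = grubbs_screen(area_fractions.loc[shared, region].to_numpy(),
                                alpha=alpha)
            audit[region] = res
            flagged |= {shared[i] for i in res.removed}
        kept = [p for p in shared if p not in flagged]
    else:
        raise ValueError("target must be 'survival' or 'areas'")
    log.info("Grubbs screen (%s): kept %d / %d patients",
             target, len(kept), len(shared))
    return kept, audit
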