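"""Paracrine ligand-receptor inference and median-split survival analysis.

Cluster-average expression from each pseudo-patient is scored with the
regularised-product statistic

    LRscore = sqrt(l * r) / (mu + sqrt(l * r)),   in [0, 1),

where ``l`` and ``r`` are the ligand and receptor cluster averages and
``mu`` the mean of the positive entries of the patient's cluster-average
matrix.  Pairs are kept when the receptor sits on the designated tumour
(neoplastic) cluster and the source cluster differs (paracrine), and then
filtered to (i) receptors that belong to the IT or CTmvp region signature
and (ii) pairs passing the score threshold in at least ``n_required``
patients.  Nominated genes are assessed with a median-split Kaplan-Meier /
log-rank comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .synthetic_data import ClusterExpression
from .util import get_logger

log = get_logger("interactions")


def lr_score(ligand_avg: float, receptor_avg: float, mu: float) -> float:
    """Regularised product score sqrt(l*r)/(mu + sqrt(l*r)); in [0, 1)."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if ligand_avg < 0 or receptor_avg < 0:
        raise ValueError("cluster averages must be >= 0")
    s = np.sqrt(ligand_avg * receptor_avg)
    return float(s / (mu + s))


def compute_mu(cluster_expr: ClusterExpression | dict) -> float:
    """Mean of the positive entries of the (concatenated) cluster-average
    matrix — the regularisation scale of :func:`lr_score`."""
    if isinstance(cluster_expr, ClusterExpression):
        vals = cluster_expr.values.to_numpy().ravel()
    else:
        vals = np.concatenate([ce.values.to_numpy().ravel()
                               for ce in cluster_expr.values()])
    pos = vals[vals > 0]
    if pos.size == 0:
        raise ValueError("cluster-average matrix has no positive entries")
    return float(pos.mean())


def find_paracrine_pairs(cluster_expr: dict[str, ClusterExpression],
                         lr_db: pd.DataFrame,
                         receiver_type: str = "neoplastic cell",
                         threshold: float = 0.5,
                         ) -> dict[str, pd.DataFrame]:
    """Score every (source cluster, receiver cluster, db pair) per patient.

    Only paracrine configurations (source != receiver cluster) are
    considered and only scores >= ``threshold`` kept.  A patient without a
    ``receiver_type`` cluster is an error naming that patient.
    """
    if not {"ligand", "receptor"} <= set(lr_db.columns):
        raise ValueError("lr_db needs 'ligand' and 'receptor' columns")
    out: dict[str, pd.DataFrame] = {}
    for pid, ce in cluster_expr.items():
        receivers = ce.clusters_of_type(receiver_type)
        if not receivers:
            raise ValueError(f"patient {pid} has no {receiver_type!r} cluster")
        mu = compute_mu(ce)
        rows = []
        for _, pair in lr_db.iterrows():
            lig, rec = pair["ligand"], pair["receptor"]
            if lig not in ce.values.index or rec not in ce.values.index:
                continue
            for rcv in receivers:
                r_avg = float(ce.values.loc[rec, rcv])
                for src in ce.values.columns:
                    if src == rcv:
                        continue  # paracrine only
                    l_avg = float(ce.values.loc[lig, src])
                    score = lr_score(l_avg, r_avg, mu)
                    if score >= threshold:
                        rows.append({
                            "ligand": lig, "receptor": rec,
                            "source_cluster": src,
                            "source_type": ce.cell_types[src],
                            "receiver_cluster": rcv,
                            "receiver_type": receiver_type,
                            "score": score})
        out[pid] = pd.DataFrame(
            rows, columns=["ligand", "receptor", "source_cluster",
                           "source_type", "receiver_cluster",
                           "receiver_type", "score"])
    return out


def filter_pairs(per_patient_pairs: dict[str, pd.DataFrame],
                 signatures: dict[str, set[str]],
                 n_required: int = 3) -> pd.DataFrame:
    """Apply the two nomination filters.

    Keep (ligand, receptor) pairs whose receptor belongs to the IT or CTmvp
    signature AND which were detected (passed the score threshold) in at
    least ``n_required`` patients.  Returns survivors with provenance: the
    carrying patients, detection count, and the signature region(s) of the
    receptor.
    """
    receptor_pool: dict[str, list[str]] = {}
    for region in ("IT", "CTmvp"):
        for g in signatures.get(region, set()):
            receptor_pool.setdefault(g, []).append(region)
    seen: dict[tuple[str, str], dict] = {}
    for pid, df in per_patient_pairs.items():
        if df.empty:
            continue
        for (lig, rec), sub in df.groupby(["ligand", "receptor"]):
            rec_d = seen.setdefault((lig, rec), {
                "ligand": lig, "receptor": rec, "patients": set(),
                "best_score": 0.0,
                "source_types": set()})
            rec_d["patients"].add(pid)
            rec_d["best_score"] = max(rec_d["best_score"], sub["score"].max())
            rec_d["source_types"] |= set(sub["source_type"])
    rows = []
    for (lig, rec), d in sorted(seen.items()):
        regions = receptor_pool.get(rec)
        if regions is None or len(d["patients"]) < n_required:
            continue
        rows.append({"ligand": lig, "receptor": rec,
                     "receptor_regions": ";".join(sorted(regions)),
                     "n_patients": len(d["patients"]),
                     "patients": ";".join(sorted(d["patients"])),
                     "source_types": ";".join(sorted(d["source_types"])),
                     "best_score": d["best_score"]})
    return pd.DataFrame(rows, columns=["ligand", "receptor", "receptor_regions",
                                       "n_patients", "patients",
                                       "source_types", "best_score"])


@dataclass
class SurvivalFit:
    """Median-split Kaplan-Meier comparison of one gene's expression."""

    curves: dict[str, pd.DataFrame]   # group -> columns: time, survival, n_risk, n_event
    chi2: float
    p_value: float
    group_sizes: dict[str, int]
    split_value: float


def km_logrank(expression, survival_days, event_flags=None,
               split: str | float = "median") -> SurvivalFit:
    """Kaplan-Meier curves and log-rank test for low vs high expression.

    Patients at or below the split value (default: the median; a float in
    (0, 1) selects another quantile) go to "low".  Censoring is supported
    through ``event_flags`` (1 = death observed); each group must contain at
    least one event.
    """
    expr = np.asarray(expression, dtype=float)
    surv = np.asarray(survival_days, dtype=float)
    if expr.shape != surv.shape or expr.ndim != 1:
        raise ValueError("expression and survival must be 1-d, equal length")
    if len(expr) < 4:
        raise ValueError("need at least 4 patients")
    events = (np.ones_like(surv, dtype=bool) if event_flags is None
              else np.asarray(event_flags, dtype=bool))
    q = 0.5 if split == "median" else float(split)
    cut = float(np.quantile(expr, q))
    low = expr <= cut
    groups = {"low": low, "high": ~low}
    for name, sel in groups.items():
        if sel.sum() == 0 or not events[sel].any():
            raise ValueError(f"group {name!r} has no observed events")
    curves = {}
    for name, sel in groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(surv[sel], events[sel], label=name)
        ev = kmf.event_table
        curves[name] = pd.DataFrame({
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_[name].to_numpy(),
            "n_risk": ev["at_risk"].reindex(
                kmf.survival_function_.index).to_numpy(),
            "n_event": ev["observed"].reindex(
                kmf.survival_function_.index).to_numpy(),
        })
    lr = logrank_test(surv[low], surv[~low], event_observed_A=events[low],
                      event_observed_B=events[~low])
    return SurvivalFit(curves=curves, chi2=float(lr.test_statistic),
                       p_value=float(lr.p_value),
                       group_sizes={"low": int(low.sum()),
                                    "high": int((~low).sum())},
                       split_value=cut)
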