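"""Region-specific gene signatures from correlation screens.

A gene is a marker of a region when its expression correlates positively
(rho > 0.1) and significantly (p < 0.05, uncorrected) with the region's
area, after a detection filter keeping genes expressed in at least 25
patients.  Markers are then partitioned by the sign of their survival
correlation, yielding the region signatures (e.g. IT^neg, CTmvp^neg,
CT^pos, CTpnz^pos) used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .util import get_logger

log = get_logger("signatures")


def filter_detected_genes(expr: pd.DataFrame, min_patients: int = 25):
    """Keep genes with strictly positive expression in >= ``min_patients``
    patients.  Returns ``(subset, report)`` with kept/dropped counts."""
    detected = (expr > 0).sum(axis=1)
    keep = detected >= min_patients
    report = {"kept": int(keep.sum()), "dropped": int((~keep).sum()),
              "min_patients": min_patients}
    log.info("detection filter: kept %d, dropped %d genes (>=%d patients)",
             report["kept"], report["dropped"], min_patients)
    return expr.loc[keep], report


def derive_signatures(rho: pd.DataFrame, p: pd.DataFrame,
                      rho_min: float = 0.1, p_max: float = 0.05,
                      ) -> dict[str, set[str]]:
    """Per-region marker sets: gene in signature(r) iff rho(g, r) > rho_min
    AND p(g, r) < p_max (both strict).  A gene may mark several regions."""
    if rho.shape != p.shape or list(rho.columns) != list(p.columns):
        raise ValueError("rho and p matrices must be aligned")
    out: dict[str, set[str]] = {}
    for region in rho.columns:
        sel = (rho[region] > rho_min) & (p[region] < p_max)
        out[region] = set(rho.index[sel.fillna(False)])
    return out


@dataclass
class RegionSignature:
    """One region's marker genes with their statistics and survival direction."""

    region: str
    genes: dict[str, dict[str, float]]          # gene -> rho_region/p_region/rho_survival/p_survival
    direction: dict[str, str] = field(default_factory=dict)  # pos | neg | unclassified

    def subset(self, direction: str) -> set[str]:
        return {g for g, d in self.direction.items() if d == direction}


def classify_by_survival(region: str, signature_genes, region_rho: pd.Series,
                         region_p: pd.Series, survival_rho: pd.Series,
                         survival_p: pd.Series, p_max: float = 0.05,
                         ) -> RegionSignature:
    """Partition a region's markers by survival-correlation direction.

    A gene is "pos" if its survival rho > 0 with p < ``p_max``, "neg" if
    rho < 0 with p < ``p_max``, else "unclassified".  A signature gene
    missing from the survival table is an error naming the gene.
    """
    genes: dict[str, dict[str, float]] = {}
    direction: dict[str, str] = {}
    for g in sorted(signature_genes):
        if g not in survival_rho.index or pd.isna(survival_rho[g]):
            raise KeyError(f"no survival correlation available for gene {g!r}")
        rs, ps = float(survival_rho[g]), float(survival_p[g])
        genes[g] = {"rho_region": float(region_rho[g]),
                    "p_region": float(region_p[g]),
                    "rho_survival": rs, "p_survival": ps}
        if ps < p_max and rs > 0:
            direction[g] = "pos"
        elif ps < p_max and rs < 0:
            direction[g] = "neg"
        else:
            direction[g] = "unclassified"
    return RegionSignature(region=region, genes=genes, direction=direction)


@dataclass(frozen=True)
class OverlapSummary:
    intersection: int
    only_a: int
    only_b: int
    jaccard: float


def compare_signatures(set_a, set_b) -> OverlapSummary:
    """Venn-style overlap of two gene sets (|A&B|, uniques, Jaccard)."""
    a, b = set(set_a), set(set_b)
    union = len(a | b)
    inter = len(a & b)
    return OverlapSummary(intersection=inter, only_a=len(a - b),
                          only_b=len(b - a),
                          jaccard=(inter / union) if union else 1.0)
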