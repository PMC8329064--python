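"""Correlation engine: Pearson and Spearman with t-approximation p-values.

Pearson area-vs-survival correlations are computed overall and stratified by
mutation carrier status; Spearman expression-vs-area correlations are
computed for every gene against every region (vectorised over genes).
p-values are two-sided from the t transform ``t = r sqrt((n-2)/(1-r^2))``
and are deliberately NOT corrected for multiple comparisons; the
``pvalue_diagnostics`` operation computes the distributional evidence
(per-region departure of the p-value distribution from uniformity, and the
dependence between region areas) that motivates reporting them raw.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .util import get_logger

log = get_logger("association")


class ConstantInputError(ValueError):
    """A correlation was requested on a constant vector (undefined)."""


@dataclass(frozen=True)
class CorrelationResult:
    """Coefficient, two-sided p and sample size for one pair of variables."""

    rho: float
    p_value: float
    n: int


def _t_pvalue(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def _check_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for constant input")
    return x, y


def pearson(x, y) -> CorrelationResult:
    """Sample Pearson r with two-sided t-approximation p."""
    x, y = _check_xy(x, y)
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    return CorrelationResult(rho=r, p_value=_t_pvalue(r, len(x)), n=len(x))


def spearman(x, y, exact: bool = False) -> CorrelationResult:
    """Spearman rho: Pearson on average ranks (ties get their mean rank).

    For tie-free data this equals ``1 - 6 sum(d^2) / (n (n^2-1))``.  The p
    is the t approximation; ``exact=True`` (n <= 9 only) replaces it with the
    exact permutation p-value ``P(|rho_perm| >= |rho|)``.
    """
    x, y = _check_xy(x, y)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    res = pearson(rx, ry)
    if exact:
        if len(x) > 9:
            raise ValueError("exact permutation p only supported for n <= 9")
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            rp = pearson(rx, np.asarray(perm))
            count += abs(rp.rho) >= abs(res.rho) - 1e-12
            total += 1
        return CorrelationResult(res.rho, count / total, res.n)
    return res


@dataclass
class StratifiedCorrelationTable:
    """Rows: ALL + one per mutation stratum; columns: the 7 regions."""

    pearson: dict[str, dict[str, CorrelationResult]]
    spearman: dict[str, dict[str, CorrelationResult]]
    stratum_sizes: dict[str, int] = field(default_factory=dict)

    def frame(self, which: str = "pearson", value: str = "rho") -> pd.DataFrame:
        cells = getattr(self, which)
        return pd.DataFrame({
            stratum: {region: getattr(res, value)
                      for region, res in row.items()}
            for stratum, row in cells.items()}).T


def _carriers(clinical: pd.DataFrame, gene: str) -> pd.Index:
    has = clinical["mutations"].fillna("").str.split(";").apply(
        lambda lst: gene in lst)
    return clinical.index[has]


def survival_region_correlations(areas: pd.DataFrame, clinical: pd.DataFrame,
                                 strata=()) -> StratifiedCorrelationTable:
    """Area-vs-survival correlations for ALL patients and per mutation stratum.

    Pearson is primary; Spearman is computed alongside as the outlier-robust
    companion.  Strata with fewer than 3 patients are skipped with a warning.
    """
    clin = clinical.set_index("patient_id") if "patient_id" in clinical else clinical
    shared = areas.index.intersection(clin.index)
    if len(shared) == 0:
        raise ValueError("no overlapping patients between areas and clinical")
    surv = clin.loc[shared, "survival_days"].astype(float)

    table = StratifiedCorrelationTable(pearson={}, spearman={})

    def add_stratum(name, pids):
        if len(pids) < 3:
            log.warning("stratum %s has %d patients (<3); skipped", name, len(pids))
            return
        prow, srow = {}, {}
        for region in areas.columns:
            a = areas.loc[pids, region].to_numpy()
            s = surv.loc[pids].to_numpy()
            try:
                prow[region] = pearson(a, s)
                srow[region] = spearman(a, s)
            except ConstantInputError:
                log.warning("constant input for stratum %s region %s", name, region)
        table.pearson[name] = prow
        table.spearman[name] = srow
        table.stratum_sizes[name] = len(pids)

    add_stratum("ALL", shared)
    for gene in strata:
        add_stratum(gene, shared.intersection(_carriers(clin, gene)))
    return table


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=1)


def gene_region_correlations(expr: pd.DataFrame, areas: pd.DataFrame):
    """Spearman rho and p for every (gene, region) pair, vectorised.

    ``expr`` is genes x patients, ``areas`` patients x regions; patients are
    aligned by id.  Genes with constant expression across the shared patients
    get NaN (correlation undefined) rather than a silent zero.  No multiple-
    testing correction is applied, by construction.
    """
    shared = [p for p in expr.columns if p in areas.index]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared patients")
    e = expr[shared].to_numpy(dtype=float)
    a = areas.loc[shared].to_numpy(dtype=float)
    n = len(shared)

    re = _rank_rows(e)
    ra = stats.rankdata(a, axis=0)
    re_c = re - re.mean(axis=1, keepdims=True)
    ra_c = ra - ra.mean(axis=0, keepdims=True)
    se = np.sqrt((re_c ** 2).sum(axis=1))
    sa = np.sqrt((ra_c ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (re_c @ ra_c) / np.outer(se, sa)
    rho = np.clip(rho, -1.0, 1.0)
    const = se == 0
    if const.any():
        log.warning("%d gene(s) constant across patients; correlations NaN",
                    int(const.sum()))
        rho[const, :] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    p[np.isnan(rho)] = np.nan
    rho_df = pd.DataFrame(rho, index=expr.index, columns=areas.columns)
    p_df = pd.DataFrame(p, index=expr.index, columns=areas.columns)
    return rho_df, p_df


def gene_survival_correlations(expr: pd.DataFrame, clinical: pd.DataFrame):
    """Spearman rho and p between each gene's expression and survival days."""
    clin = clinical.set_index("patient_id") if "patient_id" in clinical else clinical
    shared = [p for p in expr.columns if p in clin.index]
    surv = clin.loc[shared, "survival_days"].astype(float)
    rho, p = gene_region_correlations(
        expr[shared], pd.DataFrame({"survival": surv}))
    return rho["survival"], p["survival"]


@dataclass
class PValueDiagnostics:
    """Evidence behind reporting raw (uncorrected) p-values."""

    ks_distance: dict[str, float]
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]
    region_dependence: pd.DataFrame | None = None


def pvalue_diagnostics(p_frame: pd.DataFrame,
                       areas: pd.DataFrame | None = None) -> PValueDiagnostics:
    """Per-region KS distance of the p-values to Uniform(0,1), histogram
    summaries, and (if areas are given) the pairwise region-area Spearman
    matrix showing that the tests are not independent."""
    ks: dict[str, float] = {}
    hists: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for region in p_frame.columns:
        vals = p_frame[region].dropna().to_numpy()
        ks[region] = (float(stats.kstest(vals, "uniform").statistic)
                      if len(vals) else float("nan"))
        hists[region] = np.histogram(vals, bins=20, range=(0.0, 1.0))
    dep = None
    if areas is not None:
        regions = list(areas.columns)
        dep = pd.DataFrame(np.eye(len(regions)), index=regions, columns=regions)
        for i, ri in enumerate(regions):
            for j in range(i + 1, len(regions)):
                rj = regions[j]
                try:
                    res = spearman(areas[ri].to_numpy(), areas[rj].to_numpy())
                    dep.loc[ri, rj] = dep.loc[rj, ri] = res.rho
                except ConstantInputError:
                    dep.loc[ri, rj] = dep.loc[rj, ri] = np.nan
    return PValueDiagnostics(ks_distance=ks, histograms=hists,
                             region_dependence=dep)
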