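"""Synthetic glioblastoma study generator with planted ground truth.

Every input the pipeline consumes can be generated here: H&E-like slides with
8-class region masks (concentric LE/IT/CT anatomy, necrosis wrapped by
pseudopalisading and perinecrotic rings, scattered microvascular blobs),
patient cohorts with Dirichlet-distributed region areas and a log-linear
survival model with mutation-specific coefficients, expression matrices with
planted gene-region correlation effects, multi-source cell-type marker
references, and cluster-average expression with planted ligand-receptor
pairs.  Because the truth is recorded, every downstream stage is testable by
parameter recovery.

All generators flow from one integer seed through the stage-name splitting
scheme in :mod:`gbmregio.util` and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import CLASS_MAP, TUMOUR_REGIONS, LabeledSlide
from .util import child_seed, get_logger

log = get_logger("synthetic")


class InvalidLayoutError(ValueError):
    """Raised when slide layout parameters are geometrically impossible."""


# ---------------------------------------------------------------------------
# Slide geometry
# ---------------------------------------------------------------------------

# H&E-ish base colours per region: pinks/purples with region-specific tone so
# regions are learnable by colour+texture.  Not calibrated to real staining.
_REGION_BASE_RGB = {
    "BG": (245, 243, 245),
    "LE": (232, 205, 218),
    "IT": (214, 170, 205),
    "CT": (198, 140, 185),
    "CTmvp": (220, 120, 125),
    "CTpan": (150, 110, 170),
    "CTpnz": (228, 190, 170),
    "CTne": (120, 90, 85),
}

_DEFAULT_DENSITY = {"LE": 5.0, "IT": 15.0, "CT": 40.0, "CTmvp": 30.0,
                    "CTpan": 55.0, "CTpnz": 10.0, "CTne": 3.0}


@dataclass(frozen=True)
class SlideLayoutParams:
    """Geometry and texture of one synthetic slide.

    ``band_fractions`` give the radial width of the LE and IT rings and the
    CT core as fractions of the tissue radius (sum must be <= 1).
    ``nuclei_density`` is expected nuclei per 1000 px^2 of region area.
    """

    image_size: int = 192
    tissue_radius_fraction: float = 0.92
    band_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"LE": 0.14, "IT": 0.14, "CT": 0.72})
    necrosis_blob_count: int = 2
    mvp_blob_count: int = 3
    nuclei_density: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DENSITY))
    seed: int = 0
    # geometry details (pixels); None -> proportional to tissue radius
    necrosis_radius: float | None = None
    pan_width: float | None = None
    pnz_width: float | None = None
    mvp_radius: float | None = None
    # exact pixel-area targets (override the width-based ring geometry;
    # used when matching planted area fractions)
    pan_area: int | None = None
    pnz_area: int | None = None
    mvp_area: int | None = None

    def validate(self) -> None:
        if self.image_size < 64:
            raise InvalidLayoutError("image_size must be >= 64")
        if not (0 < self.tissue_radius_fraction <= 1):
            raise InvalidLayoutError("tissue_radius_fraction must be in (0, 1]")
        if sum(self.band_fractions.values()) > 1 + 1e-9:
            raise InvalidLayoutError("band fractions must sum to <= 1")
        if any(v < 0 for v in self.band_fractions.values()):
            raise InvalidLayoutError("band fractions must be >= 0")
        if any(v < 0 for v in self.nuclei_density.values()):
            raise InvalidLayoutError("nuclei densities must be >= 0")
        if self.necrosis_blob_count < 0 or self.mvp_blob_count < 0:
            raise InvalidLayoutError("blob counts must be >= 0")


def _disk_mask(shape, cy, cx, radius):
    yy, xx = np.ogrid[:shape[0], :shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2


def generate_tissue_slide(params: SlideLayoutParams) -> LabeledSlide:
    """Render one synthetic H&E-like slide and its 8-class label mask.

    Anatomy is concentric: an LE ring outermost, then IT, then the CT bulk.
    Necrosis (CTne) blobs inside CT are wrapped by a CTpan ring and then a
    CTpnz ring (so every CTne boundary pixel touches CTpan); CTmvp blobs are
    scattered in CT away from the necrotic complexes.  Nuclei centroids are
    drawn per region at the requested density and recorded on the returned
    slide.  Deterministic given ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    s = params.image_size
    c = (s - 1) / 2.0
    R = params.tissue_radius_fraction * s / 2.0
    yy, xx = np.ogrid[:s, :s]
    r = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)

    f_le = params.band_fractions.get("LE", 0.0)
    f_it = params.band_fractions.get("IT", 0.0)
    r_le_in = R * (1.0 - f_le)
    r_it_in = R * (1.0 - f_le - f_it)

    mask = np.zeros((s, s), dtype=np.uint8)
    mask[(r <= R) & (r > r_le_in)] = CLASS_MAP.index("LE")
    mask[(r <= r_le_in) & (r > r_it_in)] = CLASS_MAP.index("IT")
    ct_core = r <= r_it_in
    mask[ct_core] = CLASS_MAP.index("CT")

    pan_w = params.pan_width if params.pan_width is not None else max(2.0, 0.04 * R)
    pnz_w = params.pnz_width if params.pnz_width is not None else max(2.0, 0.05 * R)
    ne_r = (params.necrosis_radius if params.necrosis_radius is not None
            else max(2.0, 0.10 * R))
    mvp_r = (params.mvp_radius if params.mvp_radius is not None
             else max(1.5, 0.05 * R))

    # size jitter applies only to auto-sized blobs; explicit radii (as used
    # when matching planted area fractions) are honoured exactly
    ne_jitter = params.necrosis_radius is None
    mvp_jitter = params.mvp_radius is None

    ne = np.zeros((s, s), dtype=bool)
    margin = ne_r + pan_w + pnz_w + 2.0
    if params.necrosis_blob_count > 0 and r_it_in > margin + 2:
        for _ in range(params.necrosis_blob_count):
            rad = ne_r * (rng.uniform(0.8, 1.2) if ne_jitter else 1.0)
            rho = rng.uniform(0, max(r_it_in - margin, 1.0))
            th = rng.uniform(0, 2 * np.pi)
            ne |= _disk_mask((s, s), c + rho * np.sin(th), c + rho * np.cos(th), rad)
        ne &= ct_core
    if ne.any():
        dist = ndimage.distance_transform_edt(~ne)
        if params.pan_area is not None:
            # exact-area rings: assign the pixels closest to the necrotic
            # complex, forcing the 1-px shell so CTne/CTpan stay adjacent
            avail = ct_core & ~ne
            pan = np.zeros((s, s), dtype=bool)
            pnz = np.zeros((s, s), dtype=bool)
            # forced sparse shell: a greedy cover so every ne boundary pixel
            # has at least one 8-adjacent pan pixel, at ~1/3 the cost of a
            # full 1-px shell when the pan budget is tight
            interior = ndimage.binary_erosion(ne)
            boundary = np.argwhere(ne & ~interior)
            covered = np.zeros((s, s), dtype=bool)
            shell_px = []
            for (by, bx) in boundary:
                if covered[by, bx]:
                    continue
                found = False
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        qy, qx = by + dy, bx + dx
                        if (0 <= qy < s and 0 <= qx < s and avail[qy, qx]
                                and dist[qy, qx] <= 1.5):
                            pan[qy, qx] = True
                            shell_px.append((qy, qx))
                            # this pan pixel covers its whole neighbourhood
                            covered[max(qy - 1, 0):qy + 2,
                                    max(qx - 1, 0):qx + 2] = True
                            found = True
                            break
                    if found:
                        break
            cand = np.argwhere(avail & ~pan)   # raster order -> stable ties
            flat = dist[avail & ~pan]
            ordered = cand[np.argsort(flat, kind="stable")]
            n_pan = max(int(params.pan_area) - len(shell_px), 0)
            n_pnz = int(params.pnz_area or 0)
            sel = ordered[:n_pan]
            pan[sel[:, 0], sel[:, 1]] = True
            sel = ordered[n_pan:n_pan + n_pnz]
            pnz[sel[:, 0], sel[:, 1]] = True
        else:
            pan = (dist <= pan_w) & ~ne & ct_core
            pnz = (dist <= pan_w + pnz_w) & (dist > pan_w) & ct_core
        mask[pnz] = CLASS_MAP.index("CTpnz")
        mask[pan] = CLASS_MAP.index("CTpan")
        mask[ne] = CLASS_MAP.index("CTne")
        keep_out = ne | pan | pnz | ndimage.binary_dilation(
            ne | pan | pnz, iterations=2)
    else:
        keep_out = np.zeros((s, s), dtype=bool)

    if params.mvp_blob_count > 0 and r_it_in > mvp_r + 3:
        # area-targeted: keep placing blobs until the painted mvp area
        # reaches the target (crowded layouts would otherwise underfill
        # through clipping and rejection)
        target_px = (float(params.mvp_area) if params.mvp_area is not None
                     else params.mvp_blob_count * np.pi * mvp_r ** 2)
        placed = 0
        mvp_label = CLASS_MAP.index("CTmvp")
        for attempt in range(params.mvp_blob_count * 40 + 200):
            if placed >= params.mvp_blob_count and (
                    (mask == mvp_label).sum() >= 0.97 * target_px):
                break
            rad = mvp_r * (rng.uniform(0.8, 1.2) if mvp_jitter else 1.0)
            rho = rng.uniform(0, max(r_it_in - rad - 2, 1.0))
            th = rng.uniform(0, 2 * np.pi)
            blob = _disk_mask((s, s), c + rho * np.sin(th), c + rho * np.cos(th), rad)
            blob &= ct_core
            if not blob.any():
                continue
            # early attempts avoid the necrotic complex and other mvp blobs;
            # when a crowded layout keeps rejecting, blobs may displace the
            # outer pnz ring but never CTne or its CTpan shell (preserving
            # the necrosis-pseudopalisading adjacency)
            crowded = attempt >= params.mvp_blob_count * 20
            if not crowded:
                if (blob & keep_out).any():
                    continue
                if (blob & (mask == mvp_label)).any():
                    continue
            else:
                blob &= ~ne
                blob &= mask != CLASS_MAP.index("CTpan")
                blob &= mask != mvp_label
                remaining = target_px - (mask == mvp_label).sum()
                if blob.sum() < min(0.25 * np.pi * mvp_r ** 2,
                                    max(remaining, 5)):
                    continue
            mask[blob] = mvp_label
            placed += 1
        if placed < params.mvp_blob_count:
            log.debug("placed %d of %d mvp blobs", placed, params.mvp_blob_count)

    # --- texture ---------------------------------------------------------
    image = np.empty((s, s, 3), dtype=np.float32)
    for name in CLASS_MAP.labels:
        sel = mask == CLASS_MAP.index(name)
        image[sel] = _REGION_BASE_RGB[name]
    image += rng.normal(0.0, 6.0, size=image.shape)

    nuclei: dict[str, np.ndarray] = {}
    for name in TUMOUR_REGIONS:
        sel = np.argwhere(mask == CLASS_MAP.index(name))
        dens = params.nuclei_density.get(name, 0.0)
        if len(sel) == 0 or dens <= 0:
            nuclei[name] = np.empty((0, 2), dtype=np.int64)
            continue
        n = rng.poisson(dens * len(sel) / 1000.0)
        if n == 0:
            nuclei[name] = np.empty((0, 2), dtype=np.int64)
            continue
        pts = sel[rng.integers(0, len(sel), size=n)]
        nuclei[name] = pts
        for (py, px) in pts:
            y0, y1 = max(py - 1, 0), min(py + 2, s)
            x0, x1 = max(px - 1, 0), min(px + 2, s)
            image[y0:y1, x0:x1] = (70, 50, 120)  # haematoxylin-dark nucleus

    image = np.clip(image, 0, 255).astype(np.uint8)
    return LabeledSlide(image=image, mask=mask, nuclei=nuclei)


# ---------------------------------------------------------------------------
# Cohort: slides + clinical + true areas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortPlan:
    """Cohort-level generative plan.

    ``survival_coefficients`` maps ``(context, region)`` to the effect of the
    region's (cohort-standardised) normalised area on log survival days,
    where ``context`` is "ALL" or a mutated gene symbol (applied only to
    carriers).  All patients are deceased, matching a vital-status "dead"
    cohort filter.
    """

    n_patients: int = 100
    slides_per_patient: tuple[int, int] = (1, 3)
    mutation_frequencies: Mapping[str, float] = field(
        default_factory=lambda: {"PTEN": 0.35, "TP53": 0.35, "EGFR": 0.30,
                                 "PIK3R1": 0.30, "NF1": 0.15, "IDH1": 0.10})
    survival_coefficients: Mapping[tuple[str, str], float] = field(
        default_factory=dict)
    survival_noise_sd: float = 0.4
    seed: int = 0
    image_size: int = 128
    baseline_log_survival: float = float(np.log(450.0))
    #: Dirichlet concentration over the 7 regions, ordered as TUMOUR_REGIONS
    #: (LE, IT, CT, CTmvp, CTpan, CTpnz, CTne).  CT-dominant, matching the
    #: observation that resected tissue is mostly cellular tumour.
    area_alpha: tuple[float, ...] = (3.0, 3.0, 14.0, 1.5, 2.0, 2.5, 4.0)

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.survival_noise_sd < 0:
            raise ValueError("survival_noise_sd must be >= 0")
        for g, p in self.mutation_frequencies.items():
            if not (0 <= p <= 1):
                raise ValueError(f"mutation frequency for {g} not in [0,1]")


def _layout_for_fractions(frac: Mapping[str, float], image_size: int,
                          seed: int) -> SlideLayoutParams:
    """Translate 7-region area fractions into concentric-slide geometry."""
    tissue_rf = 0.92
    R = tissue_rf * image_size / 2.0
    area = np.pi * R ** 2
    f_le, f_it = frac["LE"], frac["IT"]
    # ring radii from target ring areas
    r_le_in = np.sqrt(max(1.0 - f_le, 0.0))
    r_it_in = np.sqrt(max(1.0 - f_le - f_it, 0.0))
    ne_area = frac["CTne"] * area
    n_ne = 1 if frac["CTne"] > 0 else 0
    ne_r = np.sqrt(max(ne_area, 1.0) / np.pi)
    pan_w = np.sqrt(ne_r ** 2 + frac["CTpan"] * area / np.pi) - ne_r
    pnz_w = (np.sqrt((ne_r + pan_w) ** 2 + frac["CTpnz"] * area / np.pi)
             - ne_r - pan_w)
    # many small mvp blobs are easier to place without clipping than few
    # large ones, so the painted area tracks the target closely
    mvp_r = max(2.5, 0.035 * R)
    n_mvp = int(round(frac["CTmvp"] * area / (np.pi * mvp_r ** 2)))
    if frac["CTmvp"] > 0 and n_mvp == 0:
        n_mvp = 1
        mvp_r = np.sqrt(max(frac["CTmvp"] * area, 1.0) / np.pi)
    return SlideLayoutParams(
        image_size=image_size, tissue_radius_fraction=tissue_rf,
        band_fractions={"LE": 1.0 - r_le_in, "IT": r_le_in - r_it_in,
                        "CT": r_it_in},
        necrosis_blob_count=n_ne, mvp_blob_count=n_mvp, seed=seed,
        necrosis_radius=float(ne_r), pan_width=float(max(pan_w, 1.0)),
        pnz_width=float(max(pnz_w, 1.0)), mvp_radius=float(mvp_r),
        pan_area=int(round(frac["CTpan"] * area)),
        pnz_area=int(round(frac["CTpnz"] * area)),
        mvp_area=int(round(frac["CTmvp"] * area)))


def generate_cohort(plan: CohortPlan):
    """Generate per-patient slide stacks, a clinical table and true areas.

    Returns ``(slides, clinical, true_area_table, truth)`` where ``slides``
    maps patient id to a list of :class:`LabeledSlide`, ``clinical`` has
    columns patient_id / survival_days / vital_status / mutations,
    ``true_area_table`` holds averaged per-region pixel counts measured from
    the generated masks (rows sum to mean tissue pixels), and ``truth``
    records the planted Dirichlet fractions and mutation indicators.
    """
    plan.validate()
    rng = np.random.default_rng(child_seed(plan.seed, "cohort"))
    patients = [f"P{i:04d}" for i in range(plan.n_patients)]
    alpha = np.asarray(plan.area_alpha, dtype=float)
    fractions = rng.dirichlet(alpha, size=plan.n_patients)
    lo, hi = plan.slides_per_patient
    n_slides = rng.integers(lo, hi + 1, size=plan.n_patients)

    muts = {}
    for gene, p in plan.mutation_frequencies.items():
        muts[gene] = rng.random(plan.n_patients) < p

    slides: dict[str, list[LabeledSlide]] = {}
    counts = np.zeros((plan.n_patients, len(TUMOUR_REGIONS)))
    for i, pid in enumerate(patients):
        frac = dict(zip(TUMOUR_REGIONS, fractions[i]))
        stack = []
        for k in range(int(n_slides[i])):
            layout = _layout_for_fractions(
                frac, plan.image_size,
                seed=child_seed(plan.seed, f"slide:{pid}:{k}"))
            stack.append(generate_tissue_slide(layout))
        slides[pid] = stack
        per_slide = np.stack([
            np.bincount(sl.mask.ravel(), minlength=8)[1:] for sl in stack])
        counts[i] = per_slide.mean(axis=0)

    true_area_table = pd.DataFrame(counts, index=pd.Index(patients, name="patient_id"),
                                   columns=list(TUMOUR_REGIONS))

    norm = true_area_table.div(true_area_table.sum(axis=1), axis=0)
    z = (norm - norm.mean()) / norm.std(ddof=0).replace(0.0, 1.0)
    log_surv = np.full(plan.n_patients, plan.baseline_log_survival)
    for (ctx, region), beta in plan.survival_coefficients.items():
        carrier = np.ones(plan.n_patients, dtype=bool) if ctx == "ALL" else muts.get(
            ctx, np.zeros(plan.n_patients, dtype=bool))
        log_surv = log_surv + beta * z[region].to_numpy() * carrier
    noise = rng.normal(0.0, plan.survival_noise_sd, size=plan.n_patients)
    survival_days = np.exp(log_surv + noise)

    clinical = pd.DataFrame({
        "patient_id": patients,
        "survival_days": survival_days,
        "vital_status": "dead",
        "mutations": [";".join(g for g in plan.mutation_frequencies if muts[g][i])
                      for i in range(plan.n_patients)],
    })
    truth = {"fractions": pd.DataFrame(fractions, index=patients,
                                       columns=list(TUMOUR_REGIONS)),
             "mutations": pd.DataFrame(muts, index=patients),
             "log_survival_noise": noise}
    return slides, clinical, true_area_table, truth


# ---------------------------------------------------------------------------
# Expression with planted markers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionPlan:
    """Plan for an FPKM-like expression matrix with planted region markers.

    A marker for region ``r`` follows ``log e = baseline_g + effect_size *
    z(area_r) + eps`` where ``z`` is the cohort-standardised normalised area
    and ``eps ~ N(0, expression_noise_sd)``; non-markers are independent of
    areas.  ``detection_dropout`` zeroes each (gene, patient) cell
    independently, exercising the detection filter downstream.
    """

    n_genes: int = 1000
    markers_per_region: int = 50
    effect_size: float = 1.5
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 1.0
    expression_noise_sd: float = 1.0
    detection_dropout: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 7 * self.markers_per_region:
            raise ValueError("n_genes must be >= 7 * markers_per_region")
        if not (0 <= self.detection_dropout < 1):
            raise ValueError("detection_dropout must be in [0, 1)")


def generate_expression(true_area_table: pd.DataFrame, plan: ExpressionPlan):
    """Generate ``(expr, marker_truth)``: genes x patients FPKM-like matrix
    plus the planted gene -> region map.  Deterministic given ``plan.seed``."""
    plan.validate()
    rng = np.random.default_rng(child_seed(plan.seed, "expression"))
    patients = list(true_area_table.index)
    n_pat = len(patients)
    norm = true_area_table.div(true_area_table.sum(axis=1), axis=0)
    z = ((norm - norm.mean()) / norm.std(ddof=0).replace(0.0, 1.0)).to_numpy()

    genes = [f"GENE{i:05d}" for i in range(plan.n_genes)]
    baseline = rng.normal(plan.baseline_log_mean, plan.baseline_log_sd,
                          size=plan.n_genes)
    log_e = baseline[:, None] + rng.normal(
        0.0, plan.expression_noise_sd, size=(plan.n_genes, n_pat))

    marker_truth: dict[str, str] = {}
    for ri, region in enumerate(TUMOUR_REGIONS):
        for j in range(plan.markers_per_region):
            gi = ri * plan.markers_per_region + j
            log_e[gi] += plan.effect_size * z[:, ri]
            marker_truth[genes[gi]] = region

    expr = np.exp(log_e)
    if plan.detection_dropout > 0:
        drop = rng.random(expr.shape) < plan.detection_dropout
        expr[drop] = 0.0
    return (pd.DataFrame(expr, index=pd.Index(genes, name="gene"),
                         columns=patients),
            marker_truth)


# ---------------------------------------------------------------------------
# Cell-type reference
# ---------------------------------------------------------------------------

_CANONICAL_TYPES = [
    ("microglial cell", "CL:0000129"),
    ("monocyte", "CL:0000576"),
    ("macrophage", "CL:0000235"),
    ("endothelial cell", "CL:0000115"),
    ("dendritic cell", "CL:0001056"),
    ("pericyte", "CL:0000669"),
    ("neoplastic cell", "CL:0001063"),
    ("T cell", "CL:0000084"),
    ("astrocyte", "CL:0000127"),
    ("oligodendrocyte", "CL:0000128"),
]


def generate_celltype_reference(n_types: int, entries_per_type: int,
                                genes_per_entry: int, seed: int,
                                gene_pools: Mapping[str, Sequence[str]] | None = None):
    """Generate a multi-source ranked marker reference.

    Each cell type contributes ``entries_per_type`` entries (one per mock
    source dataset).  Entries of one type share ~60% of their genes, with
    ranks permuted between sources, emulating partially concordant
    scRNA-seq marker lists.  ``gene_pools`` optionally pins a type's gene
    universe to caller-supplied symbols (used to tie the reference to planted
    signature genes); types without a pool get a disjoint synthetic universe.
    """
    if min(n_types, entries_per_type, genes_per_entry) < 1:
        raise ValueError("all counts must be >= 1")
    from .cell_ontology import CellTypeEntry

    rng = np.random.default_rng(child_seed(seed, "celltype_ref"))
    entries: list[CellTypeEntry] = []
    n_core = max(1, int(round(0.6 * genes_per_entry)))
    for t in range(n_types):
        if t < len(_CANONICAL_TYPES):
            name, cl = _CANONICAL_TYPES[t]
        else:
            name, cl = f"cell type {t}", f"CL:9{t:06d}"
        if gene_pools and name in gene_pools:
            pool = list(gene_pools[name])
            if len(pool) < genes_per_entry:
                pool = pool + [f"{name.replace(' ', '_').upper()}_X{j}"
                               for j in range(genes_per_entry * 3 - len(pool))]
        else:
            tag = name.replace(" ", "_").upper()
            pool = [f"{tag}_G{j}" for j in range(genes_per_entry * 3)]
        core = [pool[j] for j in rng.choice(len(pool), n_core, replace=False)]
        rest = [g for g in pool if g not in core]
        for e in range(entries_per_type):
            extra_idx = rng.choice(len(rest), genes_per_entry - n_core,
                                   replace=False)
            gene_list = core + [rest[j] for j in extra_idx]
            order = rng.permutation(len(gene_list))
            entries.append(CellTypeEntry(
                ontology_id=cl, cell_type_name=name, source_id=f"DS{e}",
                ranked_genes=tuple(gene_list[j] for j in order)))
    return entries


# ---------------------------------------------------------------------------
# Cluster-average expression with planted ligand-receptor pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LRPlan:
    """Plan for planting ligand-receptor pairs across pseudo-patients.

    Each pair is ``(ligand, receptor, source_type, receiver_type,
    n_patients)``: the pair is expressed (both genes well above the matrix
    mean in their clusters) in exactly the first ``n_patients``
    pseudo-patients and absent (receptor ~ 0) in the rest.
    """

    pairs: tuple[tuple[str, str, str, str, int], ...] = (
        ("RTN4", "GJB2", "pericyte", "neoplastic cell", 3),
        ("DCYL1", "DCYR1", "microglial cell", "neoplastic cell", 2),
    )
    n_background_genes: int = 40
    cluster_types: tuple[str, ...] = ("neoplastic cell", "microglial cell",
                                      "pericyte", "endothelial cell", "T cell")


@dataclass
class ClusterExpression:
    """Cluster-average expression for one pseudo-patient."""

    values: pd.DataFrame          # genes x cluster ids
    cell_types: dict[str, str]    # cluster id -> cell type label

    def clusters_of_type(self, cell_type: str) -> list[str]:
        return [c for c, t in self.cell_types.items() if t == cell_type]


def generate_cluster_expression(lr_plan: LRPlan, n_pseudo_patients: int = 3,
                                seed: int = 0):
    """Generate per-pseudo-patient cluster-average matrices plus LR truth.

    Returns ``(matrices, truth)`` where ``matrices`` maps patient id to
    :class:`ClusterExpression` (the receiver cluster is labelled
    "neoplastic cell") and ``truth`` lists each planted pair with the
    patients that carry it.
    """
    rng = np.random.default_rng(child_seed(seed, "cluster_expr"))
    genes = sorted({g for p in lr_plan.pairs for g in (p[0], p[1])} |
                   {f"BGGENE{j:03d}" for j in range(lr_plan.n_background_genes)})
    matrices: dict[str, ClusterExpression] = {}
    pids = [f"SC{i+1}" for i in range(n_pseudo_patients)]
    for i, pid in enumerate(pids):
        cluster_ids = [f"C{k}" for k in range(len(lr_plan.cluster_types))]
        cell_types = dict(zip(cluster_ids, lr_plan.cluster_types))
        vals = rng.lognormal(mean=-1.0, sigma=0.5,
                             size=(len(genes), len(cluster_ids)))
        df = pd.DataFrame(vals, index=pd.Index(genes, name="gene"),
                          columns=cluster_ids)
        for ligand, receptor, src_t, rcv_t, n_pat in lr_plan.pairs:
            src = [c for c, t in cell_types.items() if t == src_t]
            rcv = [c for c, t in cell_types.items() if t == rcv_t]
            if i < n_pat:
                df.loc[ligand, src] = rng.uniform(8.0, 12.0, size=len(src))
                df.loc[receptor, rcv] = rng.uniform(8.0, 12.0, size=len(rcv))
            else:
                df.loc[receptor, rcv] = 0.0
        matrices[pid] = ClusterExpression(values=df, cell_types=cell_types)
    truth = [{"ligand": p[0], "receptor": p[1], "source_type": p[2],
              "receiver_type": p[3], "patients": pids[:p[4]]}
             for p in lr_plan.pairs]
    return matrices, truth
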