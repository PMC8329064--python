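"""End-to-end orchestration of the region-signature analysis.

Stages (dependency order): simulate -> segment -> quantify -> correlate ->
signatures -> ontology -> interactions -> survival.  Every intermediate is
persisted under the output directory and a manifest records stage status,
parameters, seeds and package versions, so any stage can be re-run in
isolation and two runs with the same config and seed are bit-identical
(training outputs included: the numpy backend is deterministic).

The segmentation stage can be bypassed (``segment.skip``), in which case the
ground-truth masks feed region quantification directly — the first-class
path for testing the statistical stages without any training.
"""

from __future__ import annotations

import dataclasses
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from . import __version__
from .association import (gene_region_correlations, gene_survival_correlations,
                          pvalue_diagnostics, survival_region_correlations)
from .cell_ontology import CellTypeEntry, aggregate_and_call, score_reference
from .interactions import filter_pairs, find_paracrine_pairs, km_logrank
from .region_quant import build_area_table, normalize_areas, screen_cohort
from .segmentation import (DESK_PRESET, SegModelConfig, build_model,
                           extract_patches, normalize_patches, predict_mask,
                           train)
from .signatures import (classify_by_survival, derive_signatures,
                         filter_detected_genes)
from .synthetic_data import (CohortPlan, ExpressionPlan, LRPlan,
                             ClusterExpression, generate_celltype_reference,
                             generate_cluster_expression, generate_cohort,
                             generate_expression)
from .util import child_seed, get_logger, setup_logging

log = get_logger("pipeline")

STAGES = ("simulate", "segment", "quantify", "correlate", "signatures",
          "ontology", "interactions", "survival")


class StageError(RuntimeError):
    """A pipeline stage failed; partial state is persisted."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _from_dict(cls, data: Mapping, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) in section {section!r}: "
                         f"{', '.join(sorted(unknown))}")
    return cls(**data)


@dataclass(frozen=True)
class SimulateConfig:
    """Default study conditions: a 100-patient all-deceased cohort, 50
    planted markers per region at effect size 1.5, and region-survival
    coefficients following the qualitative pattern of the real cohort
    (CT/CTpnz favourable, IT/CTmvp adverse, a strong PIK3R1-specific IT
    effect)."""

    n_patients: int = 100
    image_size: int = 96
    slides_per_patient: tuple[int, int] = (1, 2)
    survival_noise_sd: float = 0.4
    mutation_frequencies: dict = field(default_factory=lambda: {
        "PTEN": 0.35, "TP53": 0.35, "EGFR": 0.30, "PIK3R1": 0.30})
    #: keys "CONTEXT:REGION" (CONTEXT = ALL or a gene symbol)
    survival_coefficients: dict = field(default_factory=lambda: {
        "ALL:CT": 0.6, "ALL:CTpnz": 0.4, "ALL:IT": -0.8, "ALL:CTmvp": -0.6,
        "PIK3R1:IT": -2.0})
    n_genes: int = 500
    markers_per_region: int = 50
    effect_size: float = 1.5
    detection_dropout: float = 0.05
    celltype_entries_per_type: int = 3
    celltype_genes_per_entry: int = 20
    n_celltypes: int = 6


@dataclass(frozen=True)
class SegmentConfig:
    skip: bool = True
    patch_size: int = 32
    train_slides: int = 4
    epochs: int = 6
    learning_rate: float = 2e-3
    dense_blocks_down: int = 2
    layers_per_block: int = 2
    growth_rate: int = 8
    dropout_rate: float = 0.0
    l2_strength: float = 1e-5


@dataclass(frozen=True)
class QuantifyConfig:
    alpha: float = 0.05
    screen_target: str = "survival"


@dataclass(frozen=True)
class CorrelateConfig:
    mutations: tuple[str, ...] | None = None   # None -> all simulated genes


@dataclass(frozen=True)
class SignaturesConfig:
    rho_min: float = 0.1
    p_max: float = 0.05
    min_patients: int = 25


@dataclass(frozen=True)
class OntologyConfig:
    query_region: str = "IT"
    query_size: int = 25
    sd_multiplier: float = 1.0


@dataclass(frozen=True)
class InteractionsConfig:
    threshold: float = 0.5
    n_required: int = 3
    receiver_type: str = "neoplastic cell"


@dataclass(frozen=True)
class SurvivalConfig:
    genes: tuple[str, ...] | None = None       # None -> nominated receptors


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    outdir: str = "gbmregio_out"
    log_level: str = "INFO"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)
    correlate: CorrelateConfig = field(default_factory=CorrelateConfig)
    signatures: SignaturesConfig = field(default_factory=SignaturesConfig)
    ontology: OntologyConfig = field(default_factory=OntologyConfig)
    interactions: InteractionsConfig = field(default_factory=InteractionsConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        data = dict(data)
        sections = {
            "simulate": SimulateConfig, "segment": SegmentConfig,
            "quantify": QuantifyConfig, "correlate": CorrelateConfig,
            "signatures": SignaturesConfig, "ontology": OntologyConfig,
            "interactions": InteractionsConfig, "survival": SurvivalConfig}
        kwargs = {}
        for key, sub_cls in sections.items():
            if key in data:
                sub = dict(data.pop(key))
                for k, v in sub.items():
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                kwargs[key] = _from_dict(sub_cls, sub, key)
        top = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - top
        if unknown:
            raise ValueError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# General-purpose expression loading helpers
# ---------------------------------------------------------------------------

def load_expression(path, id_map=None) -> pd.DataFrame:
    """Read a genes x samples TSV; optionally rename ids via a static
    two-column mapping table (e.g. ENSG -> symbol).  Unmapped ids are kept
    with a warning; duplicated symbols after mapping are suffixed."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().sum() > df[col].isna().sum():
            bad = df.index[coerced.isna() & df[col].notna()][0]
            raise ValueError(
                f"non-numeric cell at row {bad!r}, column {col!r}")
        df[col] = coerced
    if id_map is not None:
        if isinstance(id_map, (str, Path)):
            m = pd.read_csv(id_map, sep="\t", header=None)
            id_map = dict(zip(m.iloc[:, 0], m.iloc[:, 1]))
        unmapped = [g for g in df.index if g not in id_map]
        if unmapped:
            log.warning("%d id(s) not in mapping table; retained as-is",
                        len(unmapped))
        df.index = [id_map.get(g, g) for g in df.index]
        dup = df.index.duplicated(keep=False)
        if dup.any():
            log.info("%d duplicate symbol(s) after mapping; suffixed",
                     int(dup.sum()))
            counts: dict[str, int] = {}
            new_index = []
            for g, is_dup in zip(df.index, dup):
                if is_dup:
                    counts[g] = counts.get(g, 0) + 1
                    new_index.append(f"{g}_{counts[g]}")
                else:
                    new_index.append(g)
            df.index = new_index
    return df


def average_replicates(expr: pd.DataFrame, replicate_map: Mapping[str, str],
                       ) -> pd.DataFrame:
    """Average replicate sample columns per patient; singletons pass through."""
    missing = [c for c in expr.columns if c not in replicate_map]
    if missing:
        raise KeyError(f"column(s) missing from replicate map: {missing[:5]}")
    groups = pd.Series({c: replicate_map[c] for c in expr.columns})
    return expr.T.groupby(groups).mean().T


# ---------------------------------------------------------------------------
# Stage implementations (each loads inputs from outdir when not in memory)
# ---------------------------------------------------------------------------

class Pipeline:
    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.outdir)
        self.state: dict = {}
        self.manifest: dict = {"package_version": __version__,
                               "numpy_version": np.__version__,
                               "seed": config.seed, "stages": {}}

    # -- manifest ---------------------------------------------------------

    def _record(self, stage: str, status: str, **extra) -> None:
        self.manifest["stages"][stage] = {
            "status": status, "seed": child_seed(self.cfg.seed, stage),
            "params": dataclasses.asdict(getattr(self.cfg, stage)),
            "time": time.strftime("%Y-%m-%dT%H:%M:%S"), **extra}
        gio.write_json(self.manifest, self.out / "manifest.json")

    # -- stage: simulate --------------------------------------------------

    def simulate(self) -> None:
        c = self.cfg.simulate
        seed = child_seed(self.cfg.seed, "simulate")
        coeffs = {tuple(k.split(":", 1)): v
                  for k, v in c.survival_coefficients.items()}
        plan = CohortPlan(n_patients=c.n_patients, image_size=c.image_size,
                          slides_per_patient=tuple(c.slides_per_patient),
                          mutation_frequencies=dict(c.mutation_frequencies),
                          survival_coefficients=coeffs,
                          survival_noise_sd=c.survival_noise_sd, seed=seed)
        slides, clinical, true_areas, truth = generate_cohort(plan)
        eplan = ExpressionPlan(n_genes=c.n_genes,
                               markers_per_region=c.markers_per_region,
                               effect_size=c.effect_size,
                               detection_dropout=c.detection_dropout,
                               seed=seed)
        expr, marker_truth = generate_expression(true_areas, eplan)

        sdir = self.out / "slides"
        sdir.mkdir(parents=True, exist_ok=True)
        manifest_rows = []
        for pid, stack in slides.items():
            for k, sl in enumerate(stack):
                _, mp = gio.write_slide_pair(sl, sdir / f"{pid}_{k}")
                manifest_rows.append({"patient_id": pid,
                                      "mask_path": str(mp.relative_to(self.out))})
        gio.write_tsv(pd.DataFrame(manifest_rows), self.out / "mask_manifest.tsv",
                      index=False)
        gio.write_tsv(clinical, self.out / "clinical.tsv", index=False)
        gio.write_tsv(true_areas, self.out / "true_areas.tsv")
        gio.write_tsv(expr, self.out / "expression.tsv")
        gio.write_json(marker_truth, self.out / "marker_truth.json")

        # multi-source cell-type reference: microglia entries draw from the
        # planted markers of the ontology query region so recovery is testable
        it_markers = [g for g, r in marker_truth.items()
                      if r == self.cfg.ontology.query_region]
        reference = generate_celltype_reference(
            c.n_celltypes, c.celltype_entries_per_type,
            c.celltype_genes_per_entry, seed,
            gene_pools={"microglial cell": it_markers})
        gio.write_gmt(
            {f"{e.cell_type_name.replace(' ', '_')}|{e.source_id}":
                 list(e.ranked_genes) for e in reference},
            self.out / "celltype_reference.gmt",
            {f"{e.cell_type_name.replace(' ', '_')}|{e.source_id}":
                 f"{e.ontology_id}|{e.source_id}" for e in reference})

        # cluster-average matrices with a planted LR pair: the receptor is a
        # planted CTmvp marker so the signature filter can be exercised
        mvp_markers = [g for g, r in marker_truth.items() if r == "CTmvp"]
        lr_plan = LRPlan(pairs=(
            ("RTN4", mvp_markers[0], "pericyte", "neoplastic cell", 3),
            ("DECOYL", mvp_markers[1], "microglial cell", "neoplastic cell", 2)))
        matrices, lr_truth = generate_cluster_expression(lr_plan, 3, seed)
        cdir = self.out / "cluster_expression"
        cdir.mkdir(exist_ok=True)
        for pid, ce in matrices.items():
            gio.write_tsv(ce.values, cdir / f"{pid}.tsv")
            gio.write_json(ce.cell_types, cdir / f"{pid}_cell_types.json")
        lr_db = pd.DataFrame(
            [{"ligand": p[0], "receptor": p[1]} for p in lr_plan.pairs])
        gio.write_tsv(lr_db, self.out / "lr_db.tsv", index=False)
        gio.write_json(lr_truth, self.out / "lr_truth.json")

        self.state.update(slides=slides, clinical=clinical,
                          true_areas=true_areas, expr=expr,
                          marker_truth=marker_truth, reference=reference,
                          cluster_matrices=matrices, lr_db=lr_db)
        self._record("simulate", "complete",
                     n_patients=c.n_patients, n_genes=c.n_genes)

    # -- stage: segment ---------------------------------------------------

    def segment(self) -> None:
        c = self.cfg.segment
        if c.skip:
            log.info("segment: skipped; ground-truth masks feed quantification")
            self._record("segment", "skipped")
            return
        seed = child_seed(self.cfg.seed, "segment")
        slides = self.state.get("slides") or self._load_slides()
        all_slides = [sl for stack in slides.values() for sl in stack]
        tiles = []
        for sl in all_slides[:c.train_slides]:
            pset = normalize_patches(extract_patches(sl, c.patch_size))
            tiles.extend((it, mt) for it, mt, _, _ in pset.patches)
        cfg = SegModelConfig(
            dense_blocks_down=c.dense_blocks_down,
            layers_per_block=c.layers_per_block, growth_rate=c.growth_rate,
            dropout_rate=c.dropout_rate, l2_strength=c.l2_strength,
            epochs=c.epochs, learning_rate=c.learning_rate, seed=seed)
        model = build_model(cfg)
        n_val = max(1, len(tiles) // 5)
        model, history = train(model, tiles[n_val:], tiles[:n_val], cfg)
        model.save(self.out / "seg_model.zip")
        pdir = self.out / "masks_pred"
        pdir.mkdir(exist_ok=True)
        pred_masks: dict[str, list[np.ndarray]] = {}
        for pid, stack in slides.items():
            pred_masks[pid] = []
            for k, sl in enumerate(stack):
                m = predict_mask(model, sl, patch_size=c.patch_size)
                gio.write_mask_png(m, pdir / f"{pid}_{k}_pred.png")
                pred_masks[pid].append(m)
        self.state["pred_masks"] = pred_masks
        self._record("segment", "complete",
                     val_accuracy=history["val_accuracy"][-1],
                     n_train_tiles=len(tiles))

    def _load_slides(self):
        from .segmentation import LabeledSlide
        manifest = gio.read_mask_manifest(self.out / "mask_manifest.tsv")
        slides = {}
        for pid, paths in manifest.items():
            stack = []
            for mp in paths:
                mp = str(self.out / mp)
                mask = gio.read_mask_png(mp)
                img = gio.read_slide_png(mp.replace("_mask.png", ".png"))
                stack.append(LabeledSlide(img, mask))
            slides[pid] = stack
        self.state["slides"] = slides
        return slides

    # -- stage: quantify --------------------------------------------------

    def quantify(self) -> None:
        c = self.cfg.quantify
        if self.cfg.segment.skip:
            slides = self.state.get("slides") or self._load_slides()
            masks = {pid: [sl.mask for sl in stack]
                     for pid, stack in slides.items()}
        else:
            masks = self.state["pred_masks"]
        counts = build_area_table(masks)
        fractions = normalize_areas(counts)
        clinical = self.state.get("clinical")
        if clinical is None:
            clinical = pd.read_csv(self.out / "clinical.tsv", sep="\t")
            self.state["clinical"] = clinical
        kept, audit = screen_cohort(fractions, clinical, alpha=c.alpha,
                                    target=c.screen_target)
        gio.write_tsv(counts, self.out / "area_counts.tsv")
        gio.write_tsv(fractions, self.out / "area_fractions.tsv")
        gio.write_json({name: {"kept": r.kept, "removed": r.removed,
                               "trail": r.trail}
                        for name, r in audit.items()},
                       self.out / "grubbs_audit.json")
        gio.write_json({"kept_patients": kept}, self.out / "kept_patients.json")
        self.state.update(area_counts=counts, area_fractions=fractions,
                          kept_patients=kept)
        self._record("quantify", "complete", n_kept=len(kept),
                     n_removed=len(fractions) - len(kept))

    # -- stage: correlate -------------------------------------------------

    def _fractions(self) -> pd.DataFrame:
        if "area_fractions" not in self.state:
            self.state["area_fractions"] = gio.read_tsv(
                self.out / "area_fractions.tsv")
            self.state["kept_patients"] = gio.read_json(
                self.out / "kept_patients.json")["kept_patients"]
        return self.state["area_fractions"]

    def _clinical(self) -> pd.DataFrame:
        if "clinical" not in self.state:
            self.state["clinical"] = pd.read_csv(
                self.out / "clinical.tsv", sep="\t")
        return self.state["clinical"]

    def _expr(self) -> pd.DataFrame:
        if "expr" not in self.state:
            self.state["expr"] = gio.read_tsv(self.out / "expression.tsv")
        return self.state["expr"]

    def correlate(self) -> None:
        c = self.cfg.correlate
        fractions = self._fractions()
        clinical = self._clinical()
        kept = self.state.get("kept_patients", list(fractions.index))
        fr = fractions.loc[[p for p in kept if p in fractions.index]]
        strata = (list(c.mutations) if c.mutations is not None
                  else sorted(self.cfg.simulate.mutation_frequencies))
        table = survival_region_correlations(fr, clinical, strata)
        for which in ("pearson", "spearman"):
            gio.write_tsv(table.frame(which, "rho"),
                          self.out / f"survival_region_{which}_rho.tsv")
            gio.write_tsv(table.frame(which, "p_value"),
                          self.out / f"survival_region_{which}_p.tsv")
        expr = self._expr()
        detected, report = filter_detected_genes(
            expr[[p for p in expr.columns if p in fr.index]],
            self.cfg.signatures.min_patients)
        rho, p = gene_region_correlations(detected, fr)
        gio.write_tsv(rho, self.out / "gene_region_rho.tsv")
        gio.write_tsv(p, self.out / "gene_region_p.tsv")
        diag = pvalue_diagnostics(p, fr)
        gio.write_json({"ks_distance": diag.ks_distance,
                        "detection_filter": report},
                       self.out / "pvalue_diagnostics.json")
        if diag.region_dependence is not None:
            gio.write_tsv(diag.region_dependence,
                          self.out / "region_dependence.tsv")
        self.state.update(survival_table=table, gene_rho=rho, gene_p=p,
                          detected_expr=detected)
        self._record("correlate", "complete", n_detected=report["kept"],
                     n_strata=len(table.pearson))

    # -- stage: signatures ------------------------------------------------

    def signatures(self) -> None:
        c = self.cfg.signatures
        if "gene_rho" not in self.state:
            self.state["gene_rho"] = gio.read_tsv(self.out / "gene_region_rho.tsv")
            self.state["gene_p"] = gio.read_tsv(self.out / "gene_region_p.tsv")
            self.state["detected_expr"], _ = filter_detected_genes(
                self._expr(), c.min_patients)
        rho, p = self.state["gene_rho"], self.state["gene_p"]
        sigs = derive_signatures(rho, p, c.rho_min, c.p_max)
        surv_rho, surv_p = gene_survival_correlations(
            self.state["detected_expr"], self._clinical())
        classified = {}
        gmt: dict[str, set] = {}
        for region, genes in sigs.items():
            if not genes:
                continue
            rs = classify_by_survival(region, genes, rho[region], p[region],
                                      surv_rho, surv_p, c.p_max)
            classified[region] = rs
            for direction in ("pos", "neg", "unclassified"):
                sub = rs.subset(direction)
                if sub:
                    gmt[f"{region}_{direction}"] = sub
        gio.write_gmt(gmt, self.out / "signatures.gmt")
        gio.write_json({r: sorted(g) for r, g in sigs.items()},
                       self.out / "signatures.json")
        self.state.update(signatures=sigs, classified=classified,
                          gene_survival=(surv_rho, surv_p))
        self._record("signatures", "complete",
                     sizes={r: len(g) for r, g in sigs.items()})

    # -- stage: ontology --------------------------------------------------

    def ontology(self) -> None:
        c = self.cfg.ontology
        if "signatures" not in self.state:
            self.state["signatures"] = {
                k: set(v) for k, v in gio.read_json(
                    self.out / "signatures.json").items()}
            self.state["gene_rho"] = gio.read_tsv(self.out / "gene_region_rho.tsv")
        reference = self.state.get("reference") or self._load_reference()
        sigs = self.state["signatures"]
        rho = self.state["gene_rho"]
        genes = sorted(sigs.get(c.query_region, set()),
                       key=lambda g: -float(rho.loc[g, c.query_region]))
        query = genes[:c.query_size]
        if not query:
            raise ValueError(f"empty {c.query_region} signature; nothing to match")
        results = score_reference(query, reference)
        calls = aggregate_and_call(results, c.sd_multiplier)
        gio.write_tsv(calls, self.out / "celltype_calls.tsv", index=False)
        self.state["celltype_calls"] = calls
        self._record("ontology", "complete",
                     called=calls.loc[calls.called, "cell_type_name"].tolist())

    def _load_reference(self):
        ref = []
        for name, (desc, genes) in gio.read_gmt(
                self.out / "celltype_reference.gmt").items():
            cl, source = desc.split("|", 1)
            ref.append(CellTypeEntry(
                ontology_id=cl, cell_type_name=name.split("|")[0].replace("_", " "),
                source_id=source, ranked_genes=tuple(genes)))
        self.state["reference"] = ref
        return ref

    # -- stage: interactions ----------------------------------------------

    def interactions(self) -> None:
        c = self.cfg.interactions
        matrices = self.state.get("cluster_matrices") or self._load_clusters()
        lr_db = self.state.get("lr_db")
        if lr_db is None:
            lr_db = pd.read_csv(self.out / "lr_db.tsv", sep="\t")
        if "signatures" not in self.state:
            self.state["signatures"] = {
                k: set(v) for k, v in gio.read_json(
                    self.out / "signatures.json").items()}
        per_patient = find_paracrine_pairs(matrices, lr_db,
                                           receiver_type=c.receiver_type,
                                           threshold=c.threshold)
        for pid, df in per_patient.items():
            gio.write_tsv(df, self.out / f"pairs_{pid}.tsv", index=False)
        final = filter_pairs(per_patient, self.state["signatures"],
                             n_required=c.n_required)
        gio.write_tsv(final, self.out / "nominated_pairs.tsv", index=False)
        self.state["nominated_pairs"] = final
        self._record("interactions", "complete",
                     n_nominated=len(final),
                     pairs=[f"{r.ligand}:{r.receptor}"
                            for r in final.itertuples()])

    def _load_clusters(self):
        cdir = self.out / "cluster_expression"
        matrices = {}
        for p in sorted(cdir.glob("*.tsv")):
            pid = p.stem
            matrices[pid] = ClusterExpression(
                values=gio.read_tsv(p),
                cell_types=gio.read_json(cdir / f"{pid}_cell_types.json"))
        self.state["cluster_matrices"] = matrices
        return matrices

    # -- stage: survival --------------------------------------------------

    def survival(self) -> None:
        c = self.cfg.survival
        clinical = self._clinical().set_index("patient_id")
        expr = self._expr()
        if c.genes is not None:
            genes = list(c.genes)
        else:
            nominated = self.state.get("nominated_pairs")
            if nominated is None:
                nominated = pd.read_csv(self.out / "nominated_pairs.tsv", sep="\t")
            genes = sorted(set(nominated["receptor"])) if len(nominated) else []
        fits = {}
        for gene in genes:
            if gene not in expr.index:
                log.warning("gene %s absent from expression matrix; skipped", gene)
                continue
            shared = [p for p in expr.columns if p in clinical.index]
            fit = km_logrank(expr.loc[gene, shared].to_numpy(),
                             clinical.loc[shared, "survival_days"].to_numpy())
            fits[gene] = fit
            for group, curve in fit.curves.items():
                gio.write_tsv(curve, self.out / f"km_{gene}_{group}.tsv",
                              index=False)
        gio.write_json({g: {"chi2": f.chi2, "p_value": f.p_value,
                            "group_sizes": f.group_sizes}
                        for g, f in fits.items()},
                       self.out / "survival_tests.json")
        self.state["survival_fits"] = fits
        self._record("survival", "complete", genes=list(fits))


def run_pipeline(config: PipelineConfig, stages=None) -> Pipeline:
    """Execute the requested stages (default: all) in dependency order."""
    setup_logging(config.log_level)
    pipe = Pipeline(config)
    pipe.out.mkdir(parents=True, exist_ok=True)
    todo = list(STAGES) if stages is None else [s for s in STAGES if s in stages]
    for stage in todo:
        log.info("stage %s: start", stage)
        try:
            getattr(pipe, stage)()
        except Exception as exc:   # persist partial state, then abort
            pipe._record(stage, "failed", error=str(exc))
            raise StageError(stage, exc) from exc
        log.info("stage %s: done", stage)
    return pipe


def clean_outdir(path) -> None:
    p = Path(path)
    if p.exists():
        shutil.rmtree(p)
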