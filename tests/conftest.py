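"""Shared fixtures: synthetic cohorts and tile sets, generated once per session."""

import numpy as np
import pytest

import gbmregio as g

#: survival model mirroring the qualitative region-survival pattern:
#: central regions favourable, infiltrative regions adverse, plus a strong
#: PIK3R1-specific IT effect.
COEFFS = {("ALL", "CT"): 0.6, ("ALL", "CTpnz"): 0.4, ("ALL", "IT"): -0.8,
          ("ALL", "CTmvp"): -0.6, ("PIK3R1", "IT"): -2.0}


@pytest.fixture(scope="session")
def cohort100():
    """100-patient cohort with planted survival coefficients (ground truth)."""
    plan = g.CohortPlan(n_patients=100, seed=11, image_size=96,
                        survival_coefficients=COEFFS)
    slides, clinical, areas, truth = g.generate_cohort(plan)
    return {"slides": slides, "clinical": clinical, "areas": areas,
            "truth": truth, "plan": plan}


@pytest.fixture(scope="session")
def expr100(cohort100):
    """Expression for the 100-patient cohort: 50 planted markers per region."""
    plan = g.ExpressionPlan(n_genes=500, markers_per_region=50,
                            effect_size=1.5, seed=12)
    expr, marker_truth = g.generate_expression(cohort100["areas"], plan)
    return {"expr": expr, "marker_truth": marker_truth, "plan": plan}


@pytest.fixture(scope="session")
def cohort200():
    """200-patient cohort (small slides) for mutation-stratified recovery."""
    plan = g.CohortPlan(n_patients=200, seed=13, image_size=64,
                        slides_per_patient=(1, 1),
                        survival_coefficients=COEFFS)
    slides, clinical, areas, truth = g.generate_cohort(plan)
    return {"clinical": clinical, "areas": areas, "truth": truth}


@pytest.fixture(scope="session")
def texture_tiles():
    """25 structure-free 64x64 slides: 4 well-separated region textures."""
    tiles = []
    for i in range(25):
        p = g.SlideLayoutParams(image_size=64, necrosis_blob_count=0,
                                mvp_blob_count=0, seed=100 + i)
        sl = g.generate_tissue_slide(p)
        tiles.append((sl.image.astype(np.float32) / 255.0, sl.mask))
    return tiles
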