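"""Shared fixtures: small synthetic cohorts generated once per session.

All randomness is seeded; fixture problem sizes follow the simulation
studies described in the methods note (300 tumour samples for the
confounding analyses, 500 for the covariate models, a reduced 1,200-gene
transcriptome throughout).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from purityconn.connectivity import score_cohort
from purityconn.io import metadata_frame
from purityconn.signatures import all_drug_signatures, cohort_signatures, compute_cpm
from purityconn.stratify import mean_reference_score
from purityconn.synth import desk_config, generate_cohort, generate_drug_screen

COHORT_SEED = 1
MODELS_SEED = 2


@pytest.fixture(scope="session")
def tiny_screen():
    """A drug screen over the reduced transcriptome (cohort not used)."""
    cfg = desk_config(n_tumour=2, n_normal=3, seed=4)
    _, _, truth = generate_cohort(cfg)
    return generate_drug_screen(cfg, truth), truth, cfg


@pytest.fixture(scope="session")
def cohort300():
    """n=300 cohort scored against all drugs with permutation p-values."""
    cfg = desk_config(seed=COHORT_SEED)
    matrix, meta, truth = generate_cohort(cfg)
    screen = generate_drug_screen(cfg, truth)
    tumour_ids = [m.sample_id for m in meta if m.role == "tumour"]
    normal_ids = [m.sample_id for m in meta if m.role == "normal"]
    sigs = cohort_signatures(matrix, tumour_ids, normal_ids)
    drug_sigs = all_drug_signatures(screen)
    results = score_cohort(sigs, drug_sigs, n_perm=200, seed=5)
    cpm = compute_cpm(matrix)
    return {
        "config": cfg, "matrix": matrix, "meta": meta, "truth": truth,
        "screen": screen, "tumour_ids": tumour_ids, "normal_ids": normal_ids,
        "signatures": sigs, "drug_signatures": drug_sigs, "results": results,
        "purity": truth.samples["purity_pct"],
        "log_expr": np.log2(cpm[tumour_ids] + 1.0),
    }


@pytest.fixture(scope="session")
def cohort500():
    """n=500 cohort with the mean reference-inhibitor score as model outcome."""
    cfg = desk_config(n_tumour=500, seed=MODELS_SEED)
    matrix, meta, truth = generate_cohort(cfg)
    screen = generate_drug_screen(cfg, truth)
    tumour_ids = [m.sample_id for m in meta if m.role == "tumour"]
    normal_ids = [m.sample_id for m in meta if m.role == "normal"]
    sigs = cohort_signatures(matrix, tumour_ids, normal_ids)
    drug_sigs = all_drug_signatures(screen)
    results = score_cohort(sigs, drug_sigs, n_perm=0, compute_p=False)
    mean_ref = mean_reference_score(results, "HIFI-A", "HIFI-B").dropna()
    mdf = metadata_frame(meta)
    from purityconn.models import model_frame
    data = model_frame(mdf, mean_ref, "mean_ref_connectivity")
    rng = np.random.default_rng(99)
    data = data.copy()
    data["noise_cov"] = rng.normal(size=len(data))
    return {
        "config": cfg, "meta": meta, "truth": truth, "results": results,
        "signatures": sigs, "metadata_frame": mdf,
        "model_data": data, "mean_ref": mean_ref,
    }
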