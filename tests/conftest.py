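import numpy as np
import pandas as pd
import pytest

import pharmsig as ps


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small simulated training cohort shared across tests: 60 cell lines,
    8 genes (16 features), 2 drugs."""
    cfg = ps.TrainingCohortConfig.standard(
        n_samples=60, n_genes=8, n_drugs=2, n_nonzero=3, seed=42
    )
    expr, calls, responses, truth = ps.gen_training_cohort(cfg)
    panel = cfg.panel
    norm = ps.normalize_expression(expr, panel)
    mut = ps.binarize_mutations(calls, panel, list(expr.columns))
    features = ps.assemble_features(norm, mut, panel)
    return {
        "config": cfg,
        "expr": expr,
        "calls": calls,
        "responses": responses,
        "truth": truth,
        "panel": panel,
        "features": features,
        "mut": mut,
        "norm": norm,
    }


@pytest.fixture(scope="session")
def tiny_models(tiny_cohort):
    """Locked models trained on the tiny cohort with a reduced grid."""
    cfg = ps.SignatureConfig(
        alpha_grid=(0.5, 1.0), lambda_path_size=25, n_folds=5, seed=7
    )
    return ps.fit_all_drugs(tiny_cohort["features"], tiny_cohort["responses"], cfg)


@pytest.fixture()
def standardized_design():
    """20 x 5 design with exactly zero-mean, unit-sd columns, so the
    trainer's internal standardization is the identity and closed forms
    apply directly."""
    rng = np.random.default_rng(7)
    n, p = 20, 5
    x = rng.standard_normal((n, p))
    x = (x - x.mean(0)) / x.std(0)
    y = rng.standard_normal(n)
    feats = pd.DataFrame(
        x,
        columns=[f"G{j}:expr" for j in range(p)],
        index=[f"S{i}" for i in range(n)],
    )
    return feats, pd.Series(y, index=feats.index)
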