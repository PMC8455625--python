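"""Synthetic pharmacogenomic cohorts with known ground truth.

Three generators mirror the data the pipeline consumes:

* a *training* cohort of cell lines — per-gene log-normal FPKM expression,
  Bernoulli mutation status emitted as missense calls (plus decoy silent and
  intronic calls that the consequence filter must discard), and a per-drug
  response built from a sparse linear model over the same
  ``<GENE>:channel`` features the preprocessing produces, Gaussian noise
  added and then Z-scored per drug;
* an *external* cohort sharing the training truth but with per-gene batch
  shifts in expression (a platform effect that per-gene median centering
  must neutralize) and response reported as AUC via a monotone decreasing
  transform of the true linear predictor;
* a *clinical* cohort — binary treatment, a continuous signature score, and
  a binary response drawn from a logistic model with a treatment x score
  interaction, plus a percent-response column consistent with the 50%
  responder threshold.

Everything is a pure function of (config, seed); the returned truth records
make parameter-recovery tests possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import GenePanel, MutationCallTable, SampleAnnotations
from .preprocess import EXPR_SUFFIX, MUT_SUFFIX

_AMINO = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Configs and truth records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainingCohortConfig:
    """Study conditions for a simulated training cohort.

    Per-gene Bernoulli mutation rates and log2-scale expression means/SDs;
    per-drug truth is a sparse coefficient map over ``<GENE>:channel``
    features with intercept and response noise SD.
    """

    n_samples: int
    genes: tuple[str, ...]
    mutation_rates: tuple[float, ...]
    expr_means: tuple[float, ...]
    expr_sds: tuple[float, ...]
    drug_coefficients: dict  # drug -> {feature: coefficient}
    drug_intercepts: dict  # drug -> float
    noise_sd: float = 0.5
    decoy_rate: float = 0.05  # per gene-sample chance of a silent/intronic decoy call
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.genes)
        if not (len(self.mutation_rates) == len(self.expr_means) == len(self.expr_sds) == k):
            raise ValidationError("per-gene parameter vectors must match the gene list")
        if any(not 0.0 <= r <= 1.0 for r in self.mutation_rates):
            raise ValidationError("mutation rates must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        valid = {g + s for g in self.genes for s in (EXPR_SUFFIX, MUT_SUFFIX)}
        for drug, coefs in self.drug_coefficients.items():
            bad = set(coefs) - valid
            if bad:
                raise ValidationError(f"{drug}: coefficients on unknown features {sorted(bad)}")

    @property
    def panel(self) -> GenePanel:
        return GenePanel(self.genes)

    @classmethod
    def standard(
        cls,
        n_samples: int = 500,
        n_genes: int = 60,
        n_drugs: int = 10,
        n_nonzero: int = 5,
        noise_sd: float = 0.5,
        seed: int = 0,
    ) -> "TrainingCohortConfig":
        """Default study conditions: sparse planted signals (``n_nonzero``
        features per drug, effect magnitudes 0.5-1.5 of either sign) against
        realistic mutation frequencies (5-35%) and log2 expression levels."""
        rng = np.random.default_rng(seed)
        genes = tuple(f"G{i + 1:03d}" for i in range(n_genes))
        rates = tuple(rng.uniform(0.05, 0.35, n_genes).round(4))
        means = tuple(rng.uniform(1.0, 6.0, n_genes).round(4))
        sds = tuple(rng.uniform(0.6, 1.4, n_genes).round(4))
        features = [g + s for g in genes for s in (EXPR_SUFFIX, MUT_SUFFIX)]
        coef_map, intercepts = {}, {}
        for d in range(n_drugs):
            drug = f"DRUG{d + 1:02d}"
            chosen = rng.choice(len(features), size=n_nonzero, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_nonzero)
            mags = rng.uniform(0.5, 1.5, n_nonzero)
            coef_map[drug] = {
                features[j]: float(s * m) for j, s, m in zip(chosen, signs, mags)
            }
            intercepts[drug] = 0.0
        return cls(
            n_samples=n_samples, genes=genes, mutation_rates=rates,
            expr_means=means, expr_sds=sds, drug_coefficients=coef_map,
            drug_intercepts=intercepts, noise_sd=noise_sd, seed=seed,
        )


@dataclass(frozen=True)
class ClinicalCohortConfig:
    """Logistic-response clinical cohort: response probability is
    logit^{-1}(b0 + b_t*T + b_s*score + b_ts*T*score)."""

    n_patients: int = 100
    treatment_prob: float = 0.5
    b0: float = 0.0
    b_treatment: float = 0.0
    b_score: float = 0.0
    b_interaction: float = 0.0
    tumor_sites: tuple[str, ...] = ("prostate",)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.treatment_prob < 1.0:
            raise ValidationError("treatment_prob must lie in (0, 1)")
        if self.n_patients < 4:
            raise ValidationError("n_patients too small")


@dataclass(frozen=True)
class TrainingTruth:
    """Ground truth for recovery tests: the planted linear models and the
    noiseless linear predictor per drug/sample."""

    coefficients: dict
    intercepts: dict
    linear_predictor: pd.DataFrame  # drugs x samples, pre-noise, pre-z-score
    zscore_mean: dict
    zscore_sd: dict


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _simulate_expression(cfg: TrainingCohortConfig, rng, samples, shift=None) -> pd.DataFrame:
    k, n = len(cfg.genes), len(samples)
    means = np.asarray(cfg.expr_means, dtype=float)
    if shift is not None:
        means = means + np.asarray(shift, dtype=float)
    log2_vals = means[:, None] + np.asarray(cfg.expr_sds)[:, None] * rng.standard_normal((k, n))
    fpkm = np.clip(np.exp2(log2_vals) - 1.0, 0.0, None)
    return pd.DataFrame(fpkm, index=pd.Index(cfg.genes, name="gene"),
                        columns=pd.Index(samples, name="sample"))


def _simulate_calls(cfg: TrainingCohortConfig, rng, samples) -> tuple[MutationCallTable, pd.DataFrame]:
    k, n = len(cfg.genes), len(samples)
    status = (rng.random((k, n)) < np.asarray(cfg.mutation_rates)[:, None]).astype(np.int8)
    rows = []
    for i, gene in enumerate(cfg.genes):
        for j, sample in enumerate(samples):
            if status[i, j]:
                aa1, aa2 = rng.choice(list(_AMINO), 2)
                pos = int(rng.integers(1, 800))
                rows.append((sample, gene, "missense", f"{aa1}{pos}{aa2}"))
    # decoy non-coding calls: must not flip any mutation bit downstream
    decoys = rng.random((k, n)) < cfg.decoy_rate
    for i, gene in enumerate(cfg.genes):
        for j, sample in enumerate(samples):
            if decoys[i, j]:
                cls_ = "silent" if rng.random() < 0.5 else "intronic"
                rows.append((sample, gene, cls_, pd.NA))
    df = pd.DataFrame(rows, columns=["sample", "gene", "consequence", "protein_change"])
    mut = pd.DataFrame(status, index=pd.Index(cfg.genes, name="gene"),
                       columns=pd.Index(samples, name="sample"))
    return MutationCallTable(df), mut


def _model_features(expr_fpkm: pd.DataFrame, mut: pd.DataFrame) -> pd.DataFrame:
    """Features exactly as the preprocessing computes them: log2(FPKM+1)
    per-gene median centered, plus the binary mutation channel."""
    logged = np.log2(expr_fpkm + 1.0)
    centered = logged.sub(logged.median(axis=1), axis=0)
    blocks = {}
    for gene in expr_fpkm.index:
        blocks[gene + EXPR_SUFFIX] = centered.loc[gene].to_numpy()
        blocks[gene + MUT_SUFFIX] = mut.loc[gene].to_numpy(dtype=float)
    return pd.DataFrame(blocks, index=expr_fpkm.columns)


def _linear_predictor(cfg: TrainingCohortConfig, features: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for drug, coefs in cfg.drug_coefficients.items():
        lp = np.full(len(features), float(cfg.drug_intercepts.get(drug, 0.0)))
        for feat, beta in coefs.items():
            lp = lp + beta * features[feat].to_numpy()
        rows[drug] = lp
    out = pd.DataFrame(rows, index=features.index).T
    out.index.name = "drug"
    return out


def gen_training_cohort(cfg: TrainingCohortConfig):
    """Simulate (expression FPKM, mutation calls, z_ic50 response, truth).

    Response per drug: truth linear predictor over the preprocessed
    features, plus N(0, noise_sd^2), then Z-scored across samples — the
    per-drug standardization the training target uses.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = [f"CL{i + 1:04d}" for i in range(cfg.n_samples)]
    expr = _simulate_expression(cfg, rng, samples)
    calls, mut = _simulate_calls(cfg, rng, samples)
    features = _model_features(expr, mut)
    lp = _linear_predictor(cfg, features)
    rows = []
    zmean, zsd = {}, {}
    for drug in lp.index:
        y = lp.loc[drug].to_numpy() + cfg.noise_sd * rng.standard_normal(cfg.n_samples)
        mu, sd = float(y.mean()), float(y.std())
        if sd == 0:
            sd = 1.0
        zmean[drug], zsd[drug] = mu, sd
        z = (y - mu) / sd
        rows.extend((drug, s, "z_ic50", v) for s, v in zip(samples, z))
    responses = pd.DataFrame(rows, columns=["drug", "sample", "measure", "value"])
    truth = TrainingTruth(
        coefficients=dict(cfg.drug_coefficients),
        intercepts=dict(cfg.drug_intercepts),
        linear_predictor=lp, zscore_mean=zmean, zscore_sd=zsd,
    )
    return expr, calls, responses, truth


def gen_external_cohort(
    cfg: TrainingCohortConfig,
    *,
    batch_shift=0.0,
    n_samples: int | None = None,
    auc_noise_sd: float = 0.05,
    auc_scale: float = 2.0,
    seed: int | None = None,
):
    """Simulate a validation cohort sharing ``cfg``'s truth.

    Expression means receive a per-gene ``batch_shift`` (scalar or
    per-gene vector) before sampling — the platform effect that median
    centering must remove. Response is AUC: a monotone *decreasing*
    logistic transform of the drug's standardized true linear predictor,
    plus truncated Gaussian noise, clipped to [0, 1].
    """
    n = n_samples if n_samples is not None else cfg.n_samples
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    if np.isscalar(batch_shift):
        shift = np.full(len(cfg.genes), float(batch_shift))
    else:
        shift = np.asarray(batch_shift, dtype=float)
        if shift.shape != (len(cfg.genes),):
            raise ValidationError("batch_shift must be scalar or one value per gene")
    if auc_scale <= 0:
        raise ValidationError("auc_scale must be positive")
    samples = [f"XV{i + 1:04d}" for i in range(n)]
    expr = _simulate_expression(replace(cfg, n_samples=n), rng, samples, shift=shift)
    calls, mut = _simulate_calls(replace(cfg, n_samples=n), rng, samples)
    features = _model_features(expr, mut)
    lp = _linear_predictor(cfg, features)
    rows = []
    for drug in lp.index:
        v = lp.loc[drug].to_numpy()
        sd = v.std() or 1.0
        z = (v - v.mean()) / sd
        auc = 1.0 / (1.0 + np.exp(z * auc_scale / 2.0))  # decreasing in z
        auc = np.clip(auc + auc_noise_sd * rng.standard_normal(n), 0.0, 1.0)
        rows.extend((drug, s, "auc", a) for s, a in zip(samples, auc))
    responses = pd.DataFrame(rows, columns=["drug", "sample", "measure", "value"])
    return expr, calls, responses


def gen_clinical_cohort(cfg: ClinicalCohortConfig, score=None):
    """Simulate a treated/untreated clinical cohort.

    Returns ``(SampleAnnotations, score Series)``. ``response_binary`` is
    drawn from the logistic model; ``response_pct`` is sampled consistently
    with the 50% responder threshold (responders 51-100%, others 0-50%).
    The ``treatment`` column is categorical ("drug_of_interest" vs "other").
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    patients = [f"PT{i + 1:04d}" for i in range(n)]
    if score is None:
        score = pd.Series(rng.standard_normal(n), index=patients, name="score")
    else:
        score = np.asarray(score, dtype=float)
        if len(score) != n:
            raise ValidationError("score vector length must equal n_patients")
        score = pd.Series(score, index=patients, name="score")
    treated = (rng.random(n) < cfg.treatment_prob).astype(int)
    eta = (
        cfg.b0
        + cfg.b_treatment * treated
        + cfg.b_score * score.to_numpy()
        + cfg.b_interaction * treated * score.to_numpy()
    )
    prob = 1.0 / (1.0 + np.exp(-eta))
    response = (rng.random(n) < prob).astype(int)
    pct = np.where(
        response == 1, rng.uniform(51.0, 100.0, n), rng.uniform(0.0, 50.0, n)
    )
    sites = rng.choice(list(cfg.tumor_sites), size=n)
    df = pd.DataFrame(
        {
            "tumor_site": sites,
            "treatment": np.where(treated == 1, "drug_of_interest", "other"),
            "response_pct": pct,
            "response_binary": response,
        },
        index=pd.Index(patients, name="sample"),
    )
    return SampleAnnotations(df, ()), score


def gen_scan_cohort(
    n_samples: int = 300,
    n_genes: int = 10,
    n_drugs: int = 5,
    n_sites: int = 3,
    mutation_rate: float = 0.2,
    planted_effect: float = -1.0,
    planted_drug: str = "DRUG01",
    planted_gene: str = "G001",
    site_effect_sd: float = 0.5,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Score/mutation/annotation triplet for association-scan tests: scores
    are site effect + noise, plus ``planted_effect`` added to the planted
    (drug, gene) pair's scores in mutant samples. Returns
    ``(scores, mut, annotations, (planted_drug, planted_gene))``."""
    rng = np.random.default_rng(seed)
    samples = [f"TS{i + 1:04d}" for i in range(n_samples)]
    genes = [f"G{i + 1:03d}" for i in range(n_genes)]
    drugs = [f"DRUG{i + 1:02d}" for i in range(n_drugs)]
    sites = [f"site{i + 1}" for i in range(n_sites)]
    site_assign = rng.choice(sites, size=n_samples)
    site_effects = {d: dict(zip(sites, site_effect_sd * rng.standard_normal(n_sites)))
                    for d in drugs}
    mut = pd.DataFrame(
        (rng.random((n_genes, n_samples)) < mutation_rate).astype(np.int8),
        index=pd.Index(genes, name="gene"), columns=pd.Index(samples, name="sample"),
    )
    scores = {}
    for d in drugs:
        base = np.array([site_effects[d][s] for s in site_assign])
        y = base + noise_sd * rng.standard_normal(n_samples)
        if d == planted_drug:
            y = y + planted_effect * mut.loc[planted_gene].to_numpy()
        scores[d] = y
    score_df = pd.DataFrame(scores, index=samples).T
    score_df.index.name = "drug"
    ann = SampleAnnotations(
        pd.DataFrame({"tumor_site": site_assign}, index=pd.Index(samples, name="sample")), ()
    )
    return score_df, mut, ann, (planted_drug, planted_gene)
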