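"""Statistical validation of locked signatures.

Three analyses, mirroring how a cross-cohort signature is stress-tested:

* per-drug Pearson correlation between predicted scores and an external
  drug-response measure (negative AUC, since higher AUC means less
  sensitive while a lower score means predicted more sensitive), with
  Benjamini-Hochberg FDR across drugs;
* Welch two-sample t comparison of scores between biomarker-positive and
  -negative patients;
* a logistic treatment x score interaction model on a binary clinical
  endpoint — the test that separates a *predictive* biomarker (modifies the
  effect of one treatment) from a merely prognostic one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import SeparationError, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Pearson correlation with CI + p
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationResult:
    drug_id: str
    r: float
    ci_low: float
    ci_high: float
    p: float
    fdr: float
    n: int


def pearson_with_p(x, y) -> tuple[float, tuple[float, float], float]:
    """Pearson r with two-sided p (t reference on n-2 df) and 95% Fisher-z CI.

    Returns ``(r, (ci_low, ci_high), p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    n = len(x)
    if n < 3:
        raise ValidationError("pearson_with_p needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("pearson_with_p: constant input vector")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    # Fisher z 95% CI
    if abs(r) >= 1.0:
        ci = (r, r)
    else:
        zr = np.arctanh(r)
        half = 1.959963984540054 / np.sqrt(n - 3)
        ci = (float(np.tanh(zr - half)), float(np.tanh(zr + half)))
    return r, ci, float(p)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up adjustment
# ---------------------------------------------------------------------------


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    With p_(1) <= ... <= p_(m), adj_(i) = min_{j >= i} ( p_(j) * m / j ),
    capped at 1. Controls the FDR under independence/PRDS.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-d vector")
    if len(p) == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


# ---------------------------------------------------------------------------
# Score vs external response correlation (per drug + FDR)
# ---------------------------------------------------------------------------


def validate_against_response(
    scores: pd.DataFrame, responses: pd.DataFrame, *, auc_percent: bool = False
) -> list[CorrelationResult]:
    """Correlate each drug's signature scores with negative AUC.

    ``scores`` is drugs x samples; ``responses`` the long table with
    ``measure == 'auc'``. Per drug the Pearson correlation between the
    predicted score and -AUC over paired samples is computed (a sensitivity
    signature should predict low scores where AUC is high), then
    Benjamini-Hochberg adjusted across all tested drugs. Drugs with fewer
    than 3 paired samples are skipped with a warning.
    """
    auc = responses[responses["measure"] == "auc"].copy()
    if auc.empty:
        raise ValidationError("no auc rows in response table")
    if auc_percent:
        auc["value"] = auc["value"] / 100.0
    partial: list[tuple[str, float, tuple, float, int]] = []
    for drug, grp in auc.groupby("drug", sort=True):
        drug = str(drug)
        if drug not in scores.index:
            logger.warning("validate_against_response: no scores for %s", drug)
            continue
        paired = grp.set_index("sample")["value"]
        shared = paired.index.intersection(scores.columns)
        if len(shared) < 3:
            logger.warning(
                "validate_against_response: %s skipped (%d paired samples < 3)",
                drug, len(shared),
            )
            continue
        s = scores.loc[drug, shared].to_numpy(dtype=float)
        neg_auc = -paired.loc[shared].to_numpy(dtype=float)
        r, ci, p = pearson_with_p(s, neg_auc)
        partial.append((drug, r, ci, p, len(shared)))
    if not partial:
        raise ValidationError("no drug with >=3 paired samples to validate")
    fdrs = bh_adjust([p for _, _, _, p, _ in partial])
    return [
        CorrelationResult(drug, r, ci[0], ci[1], p, float(fdr), n)
        for (drug, r, ci, p, n), fdr in zip(partial, fdrs)
    ]


def correlation_table(results: list[CorrelationResult]) -> pd.DataFrame:
    """Flat export mirroring the standard per-drug validation table
    (drug, r, 95% CI low/high, p, FDR, n)."""
    return pd.DataFrame(
        [
            {
                "drug": r.drug_id,
                "r": r.r,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "fdr": r.fdr,
                "n": r.n,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Welch two-sample comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparisonResult:
    t: float
    df: float
    p: float
    mean_positive: float
    mean_negative: float
    n_positive: int
    n_negative: int

    @property
    def mean_difference(self) -> float:
        """positive-group mean minus negative-group mean; negative means the
        marker-positive group is predicted more sensitive."""
        return self.mean_positive - self.mean_negative

    @property
    def positive_more_sensitive(self) -> bool:
        return self.mean_difference < 0


def two_sample_t(scores, marker) -> GroupComparisonResult:
    """Welch (unequal-variance) unpaired two-sample t-test of scores between
    marker-positive and marker-negative samples."""
    scores = np.asarray(scores, dtype=float)
    marker = np.asarray(marker, dtype=bool)
    if scores.shape != marker.shape:
        raise ValidationError("scores and marker vectors differ in length")
    pos, neg = scores[marker], scores[~marker]
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError(
            f"each group needs >=2 samples (got {len(pos)} positive, {len(neg)} negative)"
        )
    if np.ptp(pos) == 0 and np.ptp(neg) == 0:
        # degenerate: both groups constant
        if pos[0] == neg[0]:
            return GroupComparisonResult(
                0.0, float(len(scores) - 2), 1.0,
                float(pos.mean()), float(neg.mean()), len(pos), len(neg),
            )
        raise ValidationError("both groups have zero variance with unequal means")
    res = stats.ttest_ind(pos, neg, equal_var=False)
    return GroupComparisonResult(
        float(res.statistic), float(res.df), float(res.pvalue),
        float(pos.mean()), float(neg.mean()), len(pos), len(neg),
    )


# ---------------------------------------------------------------------------
# Treatment x score interaction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InteractionResult:
    """Logistic fit of response ~ treatment + score + treatment:score.

    ``params``/``bse``/``pvalues`` are indexed by
    (intercept, treatment, score, treatment:score); p-values are Wald.
    A significant (and negative, for a sensitivity score) interaction is the
    signature of a predictive biomarker: the score modifies the response to
    the treatment rather than tracking outcome in every arm.
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    converged: bool
    n: int
    llf: float
    lr_interaction_p: float | None = None

    @property
    def interaction_coef(self) -> float:
        return float(self.params["treatment:score"])

    @property
    def interaction_p(self) -> float:
        return float(self.pvalues["treatment:score"])

    def summary(self) -> str:
        lines = [
            "Logistic interaction model: response ~ treatment + score + treatment:score",
            f"n = {self.n}, log-likelihood = {self.llf:.4f}",
            f"{'term':>18s} {'coef':>10s} {'se':>10s} {'wald p':>10s}",
        ]
        for term in self.params.index:
            lines.append(
                f"{term:>18s} {self.params[term]:>10.4f} "
                f"{self.bse[term]:>10.4f} {self.pvalues[term]:>10.4g}"
            )
        if self.lr_interaction_p is not None:
            lines.append(f"likelihood-ratio p (interaction): {self.lr_interaction_p:.4g}")
        return "\n".join(lines)


class TreatmentInteractionModel:
    """Model object for the predictive-biomarker interaction test."""

    TERMS = ("intercept", "treatment", "score", "treatment:score")

    def __init__(self, response, treatment, score) -> None:
        response = np.asarray(response, dtype=float)
        treatment = np.asarray(treatment, dtype=float)
        score = np.asarray(score, dtype=float)
        if not (len(response) == len(treatment) == len(score)):
            raise ValidationError("response, treatment and score lengths differ")
        if not np.isin(response, (0.0, 1.0)).all():
            raise ValidationError("response must be binary 0/1")
        if not np.isin(treatment, (0.0, 1.0)).all():
            raise ValidationError("treatment must be binary 0/1")
        if np.ptp(response) == 0:
            raise ValidationError("response is constant; interaction model undefined")
        if np.ptp(treatment) == 0:
            raise ValidationError("single treatment arm; interaction model undefined")
        if len(response) < 20:
            warnings.warn("interaction test with n < 20 is unreliable", stacklevel=3)
        self.response = response
        self.treatment = treatment
        self.score = score

    def fit(self, *, lr_test: bool = False, maxiter: int = 100) -> InteractionResult:
        y = self.response
        design = np.column_stack(
            [np.ones_like(y), self.treatment, self.score, self.treatment * self.score]
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, design).fit(disp=0, maxiter=maxiter, tol=1e-8)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise SeparationError(f"perfect separation in logistic fit: {exc}") from exc
        if not fit.mle_retvals.get("converged", False):
            raise SeparationError("logistic fit did not converge (possible separation)")
        # quasi-separation shows up as diverging coefficients; judge them on
        # the standardized-score scale so the check is unit-free
        score_sd = self.score.std() or 1.0
        scale = np.array([1.0, 1.0, score_sd, score_sd])
        if np.any(np.abs(fit.params * scale) > 15.0):
            raise SeparationError(
                "coefficients diverged (|beta| > 15 on standardized scale); "
                "complete or quasi-complete separation"
            )
        idx = pd.Index(self.TERMS, name="term")
        lr_p = None
        if lr_test:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reduced = sm.Logit(y, design[:, :3]).fit(disp=0, maxiter=maxiter, tol=1e-8)
            lr_stat = 2.0 * (fit.llf - reduced.llf)
            lr_p = float(stats.chi2.sf(max(lr_stat, 0.0), df=1))
        return InteractionResult(
            params=pd.Series(fit.params, index=idx),
            bse=pd.Series(fit.bse, index=idx),
            pvalues=pd.Series(fit.pvalues, index=idx),
            converged=True,
            n=len(y),
            llf=float(fit.llf),
            lr_interaction_p=lr_p,
        )


def interaction_test(response, treatment, score, *, lr_test: bool = False) -> InteractionResult:
    """Functional façade over :class:`TreatmentInteractionModel`."""
    return TreatmentInteractionModel(response, treatment, score).fit(lr_test=lr_test)
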