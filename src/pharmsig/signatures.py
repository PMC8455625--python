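"""Per-drug elastic-net response signatures.

The estimator solves, per drug,

    min_{b0, b}  (1/2n) * sum_i (y_i - b0 - x_i . b)^2
                 + lambda * ( alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2 )

where y is the per-drug Z-scored log-IC50 across cell lines and x holds the
``<GENE>:expr`` / ``<GENE>:mut`` features. alpha (the L1 proportion) and
lambda (penalty strength) are chosen by k-fold cross-validation on a grid:
alpha over a small fixed set spanning ridge-like to lasso, lambda along a
per-alpha log-spaced path descending from the data-derived lambda_max at
which every coefficient is exactly zero. Ties in CV error break toward the
sparser model (larger lambda, then larger alpha).

Features are standardized to unit variance internally (binary mutation
indicators included, no special casing) so lambda is comparable across
features; coefficients are reported back on the original feature scale.
After fitting, a model is *locked*: an immutable linear model (intercept +
named coefficients) applied unchanged to any later cohort. Its prediction
is the signature score — a predicted Z-scored IC50, lower meaning predicted
more sensitive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet

from .errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_GRID = (0.1, 0.325, 0.55, 0.775, 1.0)


@dataclass(frozen=True)
class SignatureConfig:
    """Training hyper-parameters.

    alpha_grid : candidate L1 proportions (1.0 = lasso, ->0 = ridge).
    lambda_path_size : number of log-spaced lambda values per alpha, from
        lambda_max down to lambda_min_ratio * lambda_max.
    lambda_grid : explicit lambda values overriding the automatic path
        (useful for fitting at a fixed penalty).
    n_folds : CV folds; fold assignment is a seeded round-robin over a
        shuffled sample order, so it depends only on (seed, n).
    """

    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    lambda_path_size: int = 100
    lambda_min_ratio: float = 1e-4
    lambda_grid: tuple[float, ...] | None = None
    n_folds: int = 10
    seed: int = 0
    standardize: bool = True
    max_iter: int = 20000
    tol: float = 1e-9

    def __post_init__(self) -> None:
        if not self.alpha_grid:
            raise ValidationError("alpha_grid is empty")
        for a in self.alpha_grid:
            if not 0.0 <= a <= 1.0:
                raise ValidationError(f"alpha {a} outside [0, 1]")
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")


class SignatureResults:
    """A locked linear signature: intercept + named coefficients.

    Immutable once constructed. ``predict`` aligns features by name, so the
    column order of the scored cohort is irrelevant; under the ``zero_fill``
    policy a feature absent from the cohort contributes 0, the neutral value
    for median-centered expression (cohort median) and for the mutation
    indicator (wild-type).
    """

    def __init__(
        self,
        drug_id: str,
        intercept: float,
        coefficients: pd.Series,
        alpha: float,
        lambda_: float,
        seed: int | None,
        cv_summary: pd.DataFrame | None,
        n_samples: int | None = None,
    ) -> None:
        self.drug_id = drug_id
        self.intercept = float(intercept)
        coefficients = coefficients.astype(float)
        coefficients.index.name = "feature"
        for name in coefficients.index:
            if ":" not in name or name.rsplit(":", 1)[1] not in ("expr", "mut"):
                raise ValidationError(f"coefficient name {name!r} violates <GENE>:channel")
        self.coefficients = coefficients
        self.coefficients.to_numpy().setflags(write=False)
        self.alpha = float(alpha)
        self.lambda_ = float(lambda_)
        self.seed = seed
        self.cv_summary = cv_summary
        self.n_samples = n_samples
        self.locked = True

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.coefficients.index)

    @property
    def nonzero(self) -> pd.Series:
        return self.coefficients[self.coefficients != 0.0]

    def predict(self, features: pd.DataFrame, missing_policy: str = "zero_fill") -> pd.Series:
        if missing_policy not in ("zero_fill", "error"):
            raise ValidationError(f"unknown missing_policy {missing_policy!r}")
        missing = [f for f in self.feature_names if f not in features.columns]
        if missing and missing_policy == "error":
            raise ValidationError(
                f"features missing for {self.drug_id!r}: {missing}"
            )
        if missing:
            logger.info(
                "predict[%s]: zero-filled %d absent features", self.drug_id, len(missing)
            )
        present = [f for f in self.feature_names if f in features.columns]
        x = features[present].to_numpy(dtype=float)
        beta = self.coefficients[present].to_numpy()
        scores = self.intercept + x @ beta
        return pd.Series(scores, index=features.index, name=self.drug_id)

    def summary(self) -> str:
        nz = self.nonzero
        lines = [
            f"Signature for {self.drug_id}",
            "=" * 40,
            f"alpha (L1 proportion): {self.alpha:.4g}",
            f"lambda (penalty):      {self.lambda_:.4g}",
            f"n training samples:    {self.n_samples}",
            f"features in namespace: {len(self.coefficients)}",
            f"nonzero coefficients:  {len(nz)}",
            f"intercept:             {self.intercept:.6g}",
            "-" * 40,
        ]
        for name, coef in nz.reindex(nz.abs().sort_values(ascending=False).index).items():
            lines.append(f"{name:>24s}  {coef:+.6g}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<SignatureResults {self.drug_id}: {len(self.nonzero)} nonzero terms, "
            f"alpha={self.alpha:.3g}, lambda={self.lambda_:.3g}>"
        )


def cv_fold_assignment(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic fold labels in [0, n_folds): shuffle sample positions by
    seed, then deal them round-robin. Depends only on (seed, n, n_folds)."""
    perm = np.random.RandomState(seed).permutation(n)
    folds = np.empty(n, dtype=int)
    folds[perm] = np.arange(n) % n_folds
    return folds


def _lambda_path(alpha: float, z: np.ndarray, y: np.ndarray, cfg: SignatureConfig) -> np.ndarray:
    """Log-spaced descending lambda path from the data-derived lambda_max.

    lambda_max = max_j |<z_j, y - ybar>| / (n * max(alpha, 1e-3)): the
    smallest penalty at which the lasso-type solution is identically zero.
    """
    n = len(y)
    resid = y - y.mean()
    lam_max = np.max(np.abs(z.T @ resid)) / (n * max(alpha, 1e-3))
    if lam_max <= 0:
        lam_max = 1e-3
    return np.logspace(
        np.log10(lam_max), np.log10(lam_max * cfg.lambda_min_ratio), cfg.lambda_path_size
    )


class SignatureModel:
    """Elastic-net signature model for one drug.

    Parameters
    ----------
    endog : per-sample response (Z-scored IC50), aligned by sample id to
        ``exog``; samples with missing response are dropped.
    exog : samples x features design matrix with ``<GENE>:channel`` columns.
    drug_id : label carried into the results.
    config : :class:`SignatureConfig`.
    """

    def __init__(
        self,
        endog: pd.Series,
        exog: pd.DataFrame,
        drug_id: str = "drug",
        config: SignatureConfig | None = None,
    ) -> None:
        config = config or SignatureConfig()
        shared = exog.index.intersection(endog.dropna().index)
        if len(shared) == 0:
            raise ValidationError(f"{drug_id}: no samples with both features and response")
        self.endog = endog.loc[shared].astype(float)
        self.exog = exog.loc[shared].astype(float)
        self.drug_id = drug_id
        self.config = config

    # -- internals ---------------------------------------------------------

    def _standardized(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        x = self.exog.to_numpy(dtype=float)
        mean = x.mean(axis=0)
        sd = x.std(axis=0)  # population sd; standardization is internal only
        active = sd > 0
        z = np.zeros_like(x)
        z[:, active] = (x[:, active] - mean[active]) / sd[active]
        if not self.config.standardize:
            z = x - mean  # centered but unscaled
            sd = np.ones_like(sd)
            active = np.ones_like(active)
        return z, mean, sd, active

    def _solve(self, z, y, alpha, lam, warm=None) -> np.ndarray:
        est = ElasticNet(
            alpha=lam,
            l1_ratio=alpha,
            fit_intercept=True,
            max_iter=self.config.max_iter,
            tol=self.config.tol,
        )
        if warm is not None:
            est.warm_start = True
            est.coef_ = warm[0].copy()
            est.intercept_ = warm[1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(z, y)
        return est.coef_, float(est.intercept_)

    # -- API ---------------------------------------------------------------

    def fit(self) -> SignatureResults:
        cfg = self.config
        y = self.endog.to_numpy(dtype=float)
        n = len(y)
        feature_names = list(self.exog.columns)
        run_cv = cfg.lambda_grid is None or len(cfg.lambda_grid) > 1 or len(cfg.alpha_grid) > 1
        if run_cv and n < 2 * cfg.n_folds:
            raise ValidationError(
                f"{self.drug_id}: {n} samples < 2*n_folds={2 * cfg.n_folds} required for CV"
            )
        if np.ptp(y) == 0.0:
            warnings.warn(
                f"{self.drug_id}: constant response; returning intercept-only model",
                stacklevel=2,
            )
            coefs = pd.Series(0.0, index=pd.Index(feature_names, name="feature"))
            return SignatureResults(
                self.drug_id, float(y.mean()), coefs,
                alpha=cfg.alpha_grid[-1], lambda_=np.inf, seed=cfg.seed,
                cv_summary=None, n_samples=n,
            )

        z, mean, sd, active = self._standardized()
        za = z[:, active]

        # hyper-parameter search
        if run_cv:
            alpha_sel, lam_sel, cv_summary = self._cross_validate(za, y)
        else:
            alpha_sel = cfg.alpha_grid[0]
            lam_sel = cfg.lambda_grid[0]
            cv_summary = None

        coef_std, intercept_std = self._solve(za, y, alpha_sel, lam_sel)

        # back-transform to the original feature scale
        beta = np.zeros(len(feature_names))
        beta[active] = coef_std / sd[active]
        intercept = intercept_std - float(np.dot(beta[active], mean[active]))
        coefs = pd.Series(beta, index=pd.Index(feature_names, name="feature"))
        return SignatureResults(
            self.drug_id, intercept, coefs,
            alpha=alpha_sel, lambda_=lam_sel, seed=cfg.seed,
            cv_summary=cv_summary, n_samples=n,
        )

    def _cross_validate(self, z: np.ndarray, y: np.ndarray):
        cfg = self.config
        n = len(y)
        folds = cv_fold_assignment(n, cfg.n_folds, cfg.seed)
        records = []
        best = None  # (mse, lam, alpha)
        for alpha in cfg.alpha_grid:
            lams = (
                np.asarray(cfg.lambda_grid, dtype=float)
                if cfg.lambda_grid is not None
                else _lambda_path(alpha, z, y, cfg)
            )
            lams = np.sort(lams)[::-1]  # descending for warm starts
            fold_mse = np.zeros((cfg.n_folds, len(lams)))
            for k in range(cfg.n_folds):
                tr, va = folds != k, folds == k
                warm = None
                for j, lam in enumerate(lams):
                    coef, b0 = self._solve(z[tr], y[tr], alpha, lam, warm=warm)
                    warm = (coef, b0)
                    pred = z[va] @ coef + b0
                    fold_mse[k, j] = float(np.mean((y[va] - pred) ** 2))
            mean_mse = fold_mse.mean(axis=0)
            for j, lam in enumerate(lams):
                records.append((alpha, float(lam), float(mean_mse[j])))
                # tie-break: smaller MSE wins; at equal MSE prefer larger
                # lambda, then larger alpha (the sparser model)
                cand = (mean_mse[j], -lam, -alpha)
                if best is None or cand < best[0]:
                    best = (cand, lam, alpha)
        cv_summary = pd.DataFrame(records, columns=["alpha", "lambda", "mean_cv_mse"])
        _, lam_sel, alpha_sel = best
        return float(alpha_sel), float(lam_sel), cv_summary


class SignatureModelSet:
    """Mapping drug_id -> :class:`SignatureResults` over a shared feature
    namespace; the unit that is serialized, locked, and applied to cohorts."""

    def __init__(self, results: dict[str, SignatureResults], feature_names=None) -> None:
        if not results:
            raise ValidationError("empty model set")
        names = feature_names
        for res in results.values():
            if names is None:
                names = res.feature_names
            elif tuple(res.feature_names) != tuple(names):
                raise ValidationError("models do not share a feature namespace")
        self._results = dict(results)
        self.feature_names = tuple(names)

    def __getitem__(self, drug: str) -> SignatureResults:
        return self._results[drug]

    def __contains__(self, drug: str) -> bool:
        return drug in self._results

    def __len__(self) -> int:
        return len(self._results)

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(self._results)

    def items(self):
        return self._results.items()

    def predict_scores(
        self, features: pd.DataFrame, missing_policy: str = "zero_fill"
    ) -> pd.DataFrame:
        """Drugs x samples matrix of signature scores (predicted Z-scored
        IC50; lower = predicted more sensitive)."""
        rows = {d: r.predict(features, missing_policy) for d, r in self.items()}
        out = pd.DataFrame(rows).T
        out.index.name = "drug"
        out.columns.name = "sample"
        if not np.isfinite(out.to_numpy()).all():
            raise ValidationError("non-finite entries in score matrix")
        return out


# ---------------------------------------------------------------------------
# Functional façade
# ---------------------------------------------------------------------------


def fit_signature(
    features: pd.DataFrame,
    y: pd.Series,
    config: SignatureConfig | None = None,
    drug_id: str = "drug",
) -> SignatureResults:
    """Train one locked elastic-net signature (see :class:`SignatureModel`)."""
    return SignatureModel(y, features, drug_id=drug_id, config=config).fit()


def fit_all_drugs(
    features: pd.DataFrame,
    responses: pd.DataFrame,
    config: SignatureConfig | None = None,
) -> SignatureModelSet:
    """Train one locked signature per eligible drug.

    ``responses`` is the long (drug, sample, measure, value) table;
    only ``z_ic50`` rows are used. Drugs with too few paired samples are
    reported in the returned set's ``skipped`` attribute (and logged), not
    silently dropped. Deterministic given ``config.seed``.
    """
    config = config or SignatureConfig()
    train = responses[responses["measure"] == "z_ic50"]
    if train.empty:
        raise ValidationError("no z_ic50 rows in response table")
    results: dict[str, SignatureResults] = {}
    skipped: dict[str, str] = {}
    for drug, grp in train.groupby("drug", sort=True):
        y = grp.set_index("sample")["value"]
        try:
            results[str(drug)] = fit_signature(features, y, config, drug_id=str(drug))
        except ValidationError as exc:
            skipped[str(drug)] = str(exc)
            logger.warning("fit_all_drugs: skipping %s (%s)", drug, exc)
    if not results:
        raise ValidationError(f"no eligible drugs; reasons: {skipped}")
    model_set = SignatureModelSet(results)
    model_set.skipped = skipped
    return model_set


def predict_scores(
    models: SignatureModelSet, features: pd.DataFrame, missing_policy: str = "zero_fill"
) -> pd.DataFrame:
    """Apply locked models to a cohort (see
    :meth:`SignatureModelSet.predict_scores`)."""
    return models.predict_scores(features, missing_policy)
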