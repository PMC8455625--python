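"""Pan-cancer mutation-drug sensitivity association scan.

For every (drug, gene) pair surviving a mutation-frequency filter (and an
optional drug allowlist restricting to clinically named agents), an ordinary
least squares model regresses that drug's signature scores on the gene's
binary mutation status plus a one-hot tumor-site block, so that pan-cancer
associations are separated from mere tissue enrichment. Pairs are ranked by
the mutation coefficient's t-statistic, ascending: the most negative t means
the mutation most strongly predicts sensitivity (a lower score). The top
fraction (ceiling) is carried forward as candidate biomarker-drug pairs.

No multiple-testing adjustment enters the ranking itself — the scan ranks
raw t — but BH-adjusted p-values are attached for context.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ValidationError
from .io import SampleAnnotations
from .validation import bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanConfig:
    min_mutation_freq: float = 0.05
    top_fraction: float = 0.01
    drug_allowlist: frozenset[str] | None = None
    rank_by_abs_t: bool = False  # two-sided discovery variant

    def __post_init__(self) -> None:
        if not 0.0 < self.min_mutation_freq < 1.0:
            raise ValidationError("min_mutation_freq must lie in (0, 1)")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValidationError("top_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class AssociationResult:
    drug_id: str
    gene: str
    coefficient: float
    t: float
    p: float
    fdr: float
    frequency: float
    rank: int


def _site_design(ann: SampleAnnotations, samples) -> tuple[np.ndarray, list[str]]:
    """One-hot tumor-site block minus the (lexicographically first) reference
    level. The mutation t-statistic is invariant to the reference choice."""
    sites = ann.df.loc[samples, "tumor_site"].astype(str)
    levels = sorted(sites.unique())
    if len(levels) < 2:
        raise ValidationError("mutation_drug_scan needs >=2 tumor sites")
    block = np.column_stack(
        [(sites == lvl).to_numpy(dtype=float) for lvl in levels[1:]]
    )
    return block, levels[1:]


def mutation_drug_scan(
    scores: pd.DataFrame,
    mut: pd.DataFrame,
    ann: SampleAnnotations,
    config: ScanConfig | None = None,
) -> list[AssociationResult]:
    """Scan all eligible (drug, gene) pairs; see module docstring.

    ``scores`` is drugs x samples, ``mut`` the binary genes x samples
    matrix. Pairs whose design is rank-deficient (e.g. a mutation perfectly
    confounded with one site) are skipped with a logged reason; ties in t
    break lexicographically on (drug, gene).
    """
    config = config or ScanConfig()
    samples = [s for s in scores.columns if s in mut.columns and s in ann.samples]
    if len(samples) < 5:
        raise ValidationError("too few samples shared across scores/mutations/annotations")
    site_block, _ = _site_design(ann, samples)
    m = mut[samples]
    freq = m.mean(axis=1)
    genes = [g for g in m.index if freq[g] >= config.min_mutation_freq]
    if not genes:
        raise ValidationError(
            f"no gene reaches the mutation frequency floor {config.min_mutation_freq}"
        )
    drugs = [
        d for d in scores.index
        if config.drug_allowlist is None or d in config.drug_allowlist
    ]
    if not drugs:
        raise ValidationError("no drug passes the allowlist")

    rows = []
    n_skipped = 0
    for drug in drugs:
        y = scores.loc[drug, samples].to_numpy(dtype=float)
        for gene in genes:
            x_mut = m.loc[gene].to_numpy(dtype=float)
            design = np.column_stack([np.ones(len(samples)), x_mut, site_block])
            if np.linalg.matrix_rank(design) < design.shape[1]:
                n_skipped += 1
                logger.info("scan: skipped (%s, %s): rank-deficient design", drug, gene)
                continue
            fit = sm.OLS(y, design).fit()
            rows.append(
                (str(drug), str(gene), float(fit.params[1]), float(fit.tvalues[1]),
                 float(fit.pvalues[1]), float(freq[gene]))
            )
    if not rows:
        raise ValidationError(f"all {n_skipped} candidate pairs were rank-deficient")
    if n_skipped:
        logger.info("scan: %d rank-deficient pairs skipped", n_skipped)

    fdrs = bh_adjust([r[4] for r in rows])
    if config.rank_by_abs_t:
        ordered = sorted(zip(rows, fdrs), key=lambda rf: (-abs(rf[0][3]), rf[0][0], rf[0][1]))
    else:
        ordered = sorted(zip(rows, fdrs), key=lambda rf: (rf[0][3], rf[0][0], rf[0][1]))
    return [
        AssociationResult(drug, gene, coef, t, p, float(fdr), f, rank)
        for rank, ((drug, gene, coef, t, p, f), fdr) in enumerate(ordered, start=1)
    ]


def top_fraction(results: list[AssociationResult], fraction: float) -> list[AssociationResult]:
    """First ceil(fraction * K) results by rank."""
    if not results:
        raise ValidationError("top_fraction: empty result list")
    if not 0.0 < fraction <= 1.0:
        raise ValidationError("fraction must lie in (0, 1]")
    k = math.ceil(fraction * len(results))
    ordered = sorted(results, key=lambda r: r.rank)
    return ordered[:k]


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    """TSV-ready (rank, drug, gene, coefficient, t, p, fdr, freq) table."""
    return pd.DataFrame(
        [
            {
                "rank": r.rank,
                "drug": r.drug_id,
                "gene": r.gene,
                "coefficient": r.coefficient,
                "t": r.t,
                "p": r.p,
                "fdr": r.fdr,
                "freq": r.frequency,
            }
            for r in results
        ]
    )
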