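"""Machine-checkable biomarker-drug indications.

Each FDA-style indication ("BRAF V600E/K melanoma is sensitive to
Dabrafenib") becomes a :class:`BiomarkerPredicate`: a drug, an optional
tumor-site filter, a rule that splits the cohort into marker-positive and
-negative samples, and the direction the indication expects. Evaluation
runs a Welch t-test of the drug's signature scores between the two groups
and grades the outcome concordant / borderline / discordant /
not-significant. Predicates load from a YAML config so the curated
indication list is data, not code.

Supported rules: ``mutation_in_genes``, ``wildtype_in_genes`` (its
complement), ``variant_match`` (specific protein changes, e.g. V600E/V600K),
``expression_above_quantile`` (e.g. above-median expression standing in for
a positivity stain), and ``annotation_flag`` (receptor status, promoter
methylation and similar phenotypic calls consumed as flags).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .io import MutationCallTable, SampleAnnotations, PROTEIN_ALTERING
from .validation import GroupComparisonResult, two_sample_t

RULES = (
    "mutation_in_genes",
    "wildtype_in_genes",
    "variant_match",
    "expression_above_quantile",
    "annotation_flag",
)


class Direction(str, Enum):
    SENSITIVE = "marker_more_sensitive"
    RESISTANT = "marker_more_resistant"


class Verdict(str, Enum):
    CONCORDANT = "concordant"
    BORDERLINE = "borderline"
    DISCORDANT = "discordant"
    NOT_SIGNIFICANT = "not_significant"


@dataclass(frozen=True)
class BiomarkerPredicate:
    name: str
    drug_id: str
    rule: str
    expected_direction: Direction
    cohort_filter: tuple[str, ...] = ()  # tumor_site values; empty = all
    genes: tuple[str, ...] = ()
    protein_changes: tuple[str, ...] = ()
    quantile: float | None = None
    flag: str | None = None

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValidationError(f"unknown rule {self.rule!r}; expected one of {RULES}")
        if self.rule in ("mutation_in_genes", "wildtype_in_genes") and not self.genes:
            raise ValidationError(f"{self.name}: rule {self.rule} needs a gene set")
        if self.rule == "variant_match" and (len(self.genes) != 1 or not self.protein_changes):
            raise ValidationError(
                f"{self.name}: variant_match needs exactly one gene and >=1 protein change"
            )
        if self.rule == "expression_above_quantile":
            if len(self.genes) != 1 or self.quantile is None:
                raise ValidationError(
                    f"{self.name}: expression_above_quantile needs one gene and a quantile"
                )
            if not 0.0 < self.quantile < 1.0:
                raise ValidationError(f"{self.name}: quantile must lie in (0, 1)")
        if self.rule == "annotation_flag" and not self.flag:
            raise ValidationError(f"{self.name}: annotation_flag needs a flag name")


@dataclass(frozen=True)
class ConcordanceEntry:
    predicate: BiomarkerPredicate
    comparison: GroupComparisonResult
    verdict: Verdict


def load_predicates(path) -> list[BiomarkerPredicate]:
    """Load predicates from a YAML file (a list of mappings)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not raw:
        raise ValidationError(f"{path}: expected a non-empty list of predicate entries")
    preds = []
    for entry in raw:
        preds.append(
            BiomarkerPredicate(
                name=entry["name"],
                drug_id=entry["drug"],
                rule=entry["rule"],
                expected_direction=Direction(entry["expected_direction"]),
                cohort_filter=tuple(entry.get("cohort_filter", []) or []),
                genes=tuple(str(g).upper() for g in entry.get("genes", []) or []),
                protein_changes=tuple(entry.get("protein_changes", []) or []),
                quantile=entry.get("quantile"),
                flag=entry.get("flag"),
            )
        )
    return preds


def _cohort_samples(predicate: BiomarkerPredicate, ann: SampleAnnotations) -> pd.Index:
    if not predicate.cohort_filter:
        return ann.samples
    if "tumor_site" not in ann.df.columns:
        raise ValidationError("annotations lack a tumor_site column for cohort filtering")
    mask = ann.df["tumor_site"].isin(predicate.cohort_filter)
    samples = ann.samples[mask]
    if len(samples) == 0:
        raise ValidationError(
            f"{predicate.name}: cohort filter {predicate.cohort_filter} selects 0 samples"
        )
    return samples


def build_marker_vector(
    predicate: BiomarkerPredicate,
    mut: pd.DataFrame | None,
    calls: MutationCallTable | None,
    expr: pd.DataFrame | None,
    ann: SampleAnnotations,
) -> pd.Series:
    """Boolean marker status over the predicate's cohort-filtered samples.

    ``mut`` is the binary genes x samples mutation matrix, ``expr`` the
    normalized genes x samples expression matrix. ``variant_match`` consults
    the raw call table's protein changes (protein-altering calls only);
    ``expression_above_quantile`` compares each sample against the quantile
    computed *within* the cohort filter, ties counting as negative.
    """
    samples = _cohort_samples(predicate, ann)
    rule = predicate.rule
    if rule in ("mutation_in_genes", "wildtype_in_genes"):
        if mut is None:
            raise ValidationError(f"{predicate.name}: mutation matrix required")
        missing = [g for g in predicate.genes if g not in mut.index]
        if missing:
            raise ValidationError(f"{predicate.name}: genes not in mutation matrix: {missing}")
        present = mut.loc[list(predicate.genes), samples].sum(axis=0) > 0
        marker = present if rule == "mutation_in_genes" else ~present
    elif rule == "variant_match":
        if calls is None:
            raise ValidationError(f"{predicate.name}: call table required for variant_match")
        gene = predicate.genes[0]
        df = calls.df
        hit = df[
            (df["gene"] == gene)
            & df["consequence"].isin(PROTEIN_ALTERING)
            & df["protein_change"].isin(predicate.protein_changes)
        ]
        carriers = set(hit["sample"])
        marker = pd.Series([s in carriers for s in samples], index=samples)
    elif rule == "expression_above_quantile":
        if expr is None:
            raise ValidationError(f"{predicate.name}: expression matrix required")
        gene = predicate.genes[0]
        if gene not in expr.index:
            raise ValidationError(f"{predicate.name}: gene {gene!r} not in expression matrix")
        usable = [s for s in samples if s in expr.columns]
        if not usable:
            raise ValidationError(f"{predicate.name}: no expression for cohort samples")
        vals = expr.loc[gene, usable].astype(float)
        cut = vals.quantile(predicate.quantile)
        marker = vals > cut  # strictly greater: ties are marker-negative
        samples = pd.Index(usable)
    else:  # annotation_flag
        if predicate.flag not in ann.flags:
            raise ValidationError(
                f"{predicate.name}: unknown flag {predicate.flag!r}; "
                f"declared flags: {list(ann.flags)}"
            )
        marker = ann.df.loc[samples, predicate.flag].fillna(False).astype(bool)
    marker = pd.Series(np.asarray(marker, dtype=bool), index=samples, name=predicate.name)
    return marker


def _verdict(
    expected: Direction, comparison: GroupComparisonResult,
    threshold: float, borderline: float,
) -> Verdict:
    observed_sensitive = comparison.positive_more_sensitive
    matches = (expected == Direction.SENSITIVE) == observed_sensitive
    if comparison.p < threshold:
        return Verdict.CONCORDANT if matches else Verdict.DISCORDANT
    if matches and comparison.p < borderline:
        return Verdict.BORDERLINE
    return Verdict.NOT_SIGNIFICANT


def evaluate_biomarkers(
    predicates: list[BiomarkerPredicate],
    scores: pd.DataFrame,
    ann: SampleAnnotations,
    *,
    mut: pd.DataFrame | None = None,
    calls: MutationCallTable | None = None,
    expr: pd.DataFrame | None = None,
    threshold: float = 0.05,
    borderline: float = 0.10,
) -> list[ConcordanceEntry]:
    """Welch-compare each predicate's marker groups on its drug's scores and
    grade concordance with the expected direction.

    The verdict is a pure function of (sign of the mean score difference,
    p-value, thresholds): significant and in the expected direction is
    concordant, significant the wrong way is discordant, expected-direction
    p in [threshold, borderline) is borderline, anything else is
    not-significant.
    """
    entries = []
    for pred in predicates:
        if pred.drug_id not in scores.index:
            raise ValidationError(f"{pred.name}: drug {pred.drug_id!r} not in score matrix")
        marker = build_marker_vector(pred, mut, calls, expr, ann)
        usable = [s for s in marker.index if s in scores.columns]
        if not usable:
            raise ValidationError(f"{pred.name}: no scored samples in cohort")
        s = scores.loc[pred.drug_id, usable].to_numpy(dtype=float)
        comparison = two_sample_t(s, marker.loc[usable].to_numpy())
        entries.append(
            ConcordanceEntry(
                pred, comparison,
                _verdict(pred.expected_direction, comparison, threshold, borderline),
            )
        )
    return entries


def concordance_table(entries: list[ConcordanceEntry]) -> pd.DataFrame:
    """Flat TSV-ready report of the concordance evaluation."""
    return pd.DataFrame(
        [
            {
                "biomarker": e.predicate.name,
                "drug": e.predicate.drug_id,
                "rule": e.predicate.rule,
                "expected": e.predicate.expected_direction.value,
                "n_positive": e.comparison.n_positive,
                "n_negative": e.comparison.n_negative,
                "mean_positive": e.comparison.mean_positive,
                "mean_negative": e.comparison.mean_negative,
                "t": e.comparison.t,
                "p": e.comparison.p,
                "verdict": e.verdict.value,
            }
            for e in entries
        ]
    )
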