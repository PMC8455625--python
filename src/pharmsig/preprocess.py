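"""Feature construction: binary mutation channel, log2 median-scaled
expression channel, and the samples x features design matrix.

The representation is deliberately platform-independent: mutations become a
binary present/absent indicator restricted to protein-coding-altering
consequence classes, and expression becomes log2(FPKM + 1) centered on the
per-gene cohort median, so location shifts between sequencing platforms
cancel out. Features are named ``<GENE>:expr`` and ``<GENE>:mut`` and
restricted to a harmonized cancer-gene panel.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import PROTEIN_ALTERING, GenePanel, MutationCallTable

logger = logging.getLogger(__name__)

EXPR_SUFFIX = ":expr"
MUT_SUFFIX = ":mut"


def binarize_mutations(
    calls: MutationCallTable, panel: GenePanel, samples
) -> pd.DataFrame:
    """Binary genes x samples mutation matrix.

    An entry is 1 iff the sample carries at least one call in that gene whose
    consequence class alters the protein-coding sequence (missense, nonsense,
    frameshift, in-frame indel, splice site). Silent / intronic / intergenic
    and other non-coding calls never set the bit. Samples without any call
    are wild-type (all-zero) columns; calls in genes off the panel are
    dropped with a logged count.
    """
    samples = list(samples)
    if not samples:
        raise ValidationError("binarize_mutations: empty sample list")
    panel_genes = list(panel)
    mat = pd.DataFrame(
        np.zeros((len(panel_genes), len(samples)), dtype=np.int8),
        index=pd.Index(panel_genes, name="gene"),
        columns=pd.Index(samples, name="sample"),
    )
    df = calls.df
    if len(df):
        coding = df[df["consequence"].isin(PROTEIN_ALTERING)]
        on_panel = coding[coding["gene"].isin(set(panel_genes))]
        dropped = len(coding) - len(on_panel)
        if dropped:
            logger.info("binarize_mutations: dropped %d calls in off-panel genes", dropped)
        in_cohort = on_panel[on_panel["sample"].isin(set(samples))]
        for gene, sample in zip(in_cohort["gene"], in_cohort["sample"]):
            mat.at[gene, sample] = 1
    return mat


def normalize_expression(
    raw: pd.DataFrame, panel: GenePanel, *, pseudocount: float = 1.0,
    global_median: bool = False,
) -> pd.DataFrame:
    """log2-transform and median-scale an FPKM matrix, restricted to panel.

    x' = log2(FPKM + pseudocount) - median(log2(FPKM + pseudocount)), the
    median taken per gene across the cohort's samples by default. With
    ``global_median=True`` a single cohort-wide median is subtracted instead
    (sensitivity-analysis mode).
    """
    if raw.shape[1] < 2:
        raise ValidationError(
            "normalize_expression needs >=2 samples (median centering is degenerate)"
        )
    keep = [g for g in panel if g in raw.index]
    sub = raw.loc[keep]
    logged = np.log2(sub + pseudocount)
    if global_median:
        centered = logged - np.median(logged.to_numpy())
    else:
        centered = logged.sub(logged.median(axis=1), axis=0)
    return centered


def harmonize_panel(panels: list[GenePanel]) -> GenePanel:
    """Intersect panels, keeping the first panel's order."""
    if not panels:
        raise ValidationError("harmonize_panel: no panels given")
    common = set(panels[0].genes)
    for p in panels[1:]:
        common &= set(p.genes)
    ordered = [g for g in panels[0] if g in common]
    if not ordered:
        raise ValidationError("harmonize_panel: empty intersection")
    return GenePanel(tuple(ordered))


def assemble_features(
    expr: pd.DataFrame | None, mut: pd.DataFrame | None, panel: GenePanel
) -> pd.DataFrame:
    """Samples x features design matrix with ``<GENE>:expr`` / ``<GENE>:mut``
    columns in panel order (expression channel first per gene).

    Samples are intersected between the two channels (logged when they
    differ); a gene missing from one channel simply contributes no column
    for it.
    """
    if expr is None and mut is None:
        raise ValidationError("assemble_features: need at least one channel")
    if expr is not None and mut is not None:
        shared = [s for s in expr.columns if s in set(mut.columns)]
        if not shared:
            raise ValidationError("assemble_features: disjoint sample sets")
        lost = (len(expr.columns) - len(shared)) + (len(mut.columns) - len(shared))
        if lost:
            logger.info("assemble_features: %d samples outside the channel intersection", lost)
    else:
        shared = list((expr if expr is not None else mut).columns)
    blocks = {}
    for gene in panel:
        if expr is not None and gene in expr.index:
            blocks[gene + EXPR_SUFFIX] = expr.loc[gene, shared].to_numpy(dtype=float)
        if mut is not None and gene in mut.index:
            blocks[gene + MUT_SUFFIX] = mut.loc[gene, shared].to_numpy(dtype=float)
    out = pd.DataFrame(blocks, index=pd.Index(shared, name="sample"))
    if out.columns.has_duplicates:
        raise ValidationError("assemble_features: duplicate feature names")
    return out


def split_channels(features: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inverse of :func:`assemble_features` column naming: return the
    (expression, mutation) sub-matrices, genes x samples."""
    expr_cols = [c for c in features.columns if c.endswith(EXPR_SUFFIX)]
    mut_cols = [c for c in features.columns if c.endswith(MUT_SUFFIX)]
    expr = features[expr_cols].T
    expr.index = pd.Index([c[: -len(EXPR_SUFFIX)] for c in expr_cols], name="gene")
    mut = features[mut_cols].T
    mut.index = pd.Index([c[: -len(MUT_SUFFIX)] for c in mut_cols], name="gene")
    return expr, mut


def write_feature_matrix(features: pd.DataFrame, path) -> None:
    features.to_csv(path, sep="\t", index_label="sample", float_format="%.17g")


def read_feature_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)
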