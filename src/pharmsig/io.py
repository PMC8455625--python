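"""Readers and writers for cohort-level inputs and locked signature models.

All tabular inputs are plain TSV. Gene-by-sample expression matrices carry
gene symbols in the first column; mutation calls are MAF-like long tables;
drug response is a long (drug, sample, measure, value) table; sample
annotations are one row per sample with a header convention for boolean
flags ("flag:<name>"). Locked models round-trip through a long-format TSV
with a ``#``-prefixed header block at full float precision.

Gene symbols are uppercased on ingest everywhere so the mutation, expression
and panel files harmonize across platforms, which is the premise of a
cross-cohort signature.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

# ---------------------------------------------------------------------------
# Controlled vocabulary for mutation consequence classes
# ---------------------------------------------------------------------------

CONSEQUENCE_CLASSES = (
    "missense",
    "nonsense",
    "frameshift",
    "inframe_indel",
    "splice_site",
    "silent",
    "intronic",
    "intergenic",
    "UTR",
    "other_noncoding",
)

#: Consequence classes counted as protein-coding-altering when binarizing
#: mutations. Silent, intronic and intergenic calls (and UTR/other
#: non-coding) are excluded.
PROTEIN_ALTERING = frozenset(
    {"missense", "nonsense", "frameshift", "inframe_indel", "splice_site"}
)

#: Synonym table mapping common variant-classification labels (MAF-style and
#: plain) onto the controlled vocabulary. Lookup is case-insensitive.
CONSEQUENCE_SYNONYMS = {
    "missense": "missense",
    "missense_mutation": "missense",
    "nonsense": "nonsense",
    "nonsense_mutation": "nonsense",
    "nonstop_mutation": "nonsense",
    "frameshift": "frameshift",
    "frame_shift_del": "frameshift",
    "frame_shift_ins": "frameshift",
    "frameshift_variant": "frameshift",
    "inframe_indel": "inframe_indel",
    "in_frame_del": "inframe_indel",
    "in_frame_ins": "inframe_indel",
    "splice_site": "splice_site",
    "splice_region": "splice_site",
    "silent": "silent",
    "synonymous": "silent",
    "intronic": "intronic",
    "intron": "intronic",
    "intergenic": "intergenic",
    "igr": "intergenic",
    "utr": "UTR",
    "3'utr": "UTR",
    "5'utr": "UTR",
    "3'flank": "other_noncoding",
    "5'flank": "other_noncoding",
    "rna": "other_noncoding",
    "lincrna": "other_noncoding",
    "other_noncoding": "other_noncoding",
}

#: MAF-conventional column aliases accepted by :func:`read_mutation_calls`.
MUTATION_COLUMN_ALIASES = {
    "hugo_symbol": "gene",
    "tumor_sample_barcode": "sample",
    "variant_classification": "consequence",
    "hgvsp_short": "protein_change",
}

_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n"}

MEASURES = ("z_ic50", "auc")


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationCallTable:
    """Long table of per-variant somatic calls.

    ``df`` has columns ``sample``, ``gene``, ``consequence`` (controlled
    vocabulary) and ``protein_change`` (may be missing/NA). Duplicate
    (sample, gene, change) rows are permitted; they collapse during
    binarization.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "gene", "consequence", "protein_change"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValidationError(f"mutation call table missing columns {sorted(missing)}")
        if len(self.df):
            if (self.df["sample"].astype(str).str.len() == 0).any():
                raise ValidationError("empty sample_id in mutation calls")
            if (self.df["gene"].astype(str).str.len() == 0).any():
                raise ValidationError("empty gene symbol in mutation calls")
            bad = set(self.df["consequence"]) - set(CONSEQUENCE_CLASSES)
            if bad:
                raise ValidationError(
                    f"consequence classes outside controlled vocabulary: {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class GenePanel:
    """Ordered, de-duplicated, case-normalized list of gene symbols."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("gene panel is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("gene panel contains duplicates")

    @classmethod
    def from_symbols(cls, symbols) -> "GenePanel":
        seen: dict[str, None] = {}
        for s in symbols:
            s = str(s).strip().upper()
            if s:
                seen.setdefault(s, None)
        return cls(tuple(seen))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, g) -> bool:
        return g in set(self.genes)


@dataclass(frozen=True)
class SampleAnnotations:
    """Per-sample clinical/phenotypic annotations.

    ``df`` is indexed by sample id and may contain ``tumor_site``,
    ``treatment``, ``response_pct``, ``response_binary`` and any number of
    boolean flag columns whose names are listed in ``flags``.
    """

    df: pd.DataFrame
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            dups = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated sample ids in annotations: {dups}")
        for f in self.flags:
            col = self.df[f].dropna()
            if not col.map(lambda v: isinstance(v, (bool, np.bool_))).all():
                raise ValidationError(f"flag column {f!r} is not strictly boolean")

    @property
    def samples(self) -> pd.Index:
        return self.df.index


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_tsv(path, **kw) -> pd.DataFrame:
    # exact float round-trips matter for locked models and score matrices
    try:
        return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip", **kw)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc


def read_mutation_calls(path) -> MutationCallTable:
    """Read a MAF-like TSV of somatic calls.

    Accepts either plain column names (sample, gene, consequence,
    protein_change) or MAF-conventional aliases (Tumor_Sample_Barcode,
    Hugo_Symbol, Variant_Classification, HGVSp_Short). Consequence strings
    are mapped to the controlled vocabulary via :data:`CONSEQUENCE_SYNONYMS`.
    """
    df = _read_tsv(path, dtype=str)
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        rename[col] = MUTATION_COLUMN_ALIASES.get(key, key)
    df = df.rename(columns=rename)
    for col in ("sample", "gene", "consequence"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if "protein_change" not in df.columns:
        df["protein_change"] = pd.NA

    def _map_consequence(raw: str) -> str:
        key = str(raw).strip().lower()
        if key not in CONSEQUENCE_SYNONYMS:
            raise FormatError(
                f"{path}: unknown consequence {raw!r}; accepted labels: "
                + ", ".join(sorted(CONSEQUENCE_SYNONYMS))
            )
        return CONSEQUENCE_SYNONYMS[key]

    if len(df):
        df["consequence"] = df["consequence"].map(_map_consequence)
        df["gene"] = df["gene"].astype(str).str.strip().str.upper()
        df["sample"] = df["sample"].astype(str).str.strip()
        # strip the HGVS "p." prefix so patterns like V600E match directly
        df["protein_change"] = df["protein_change"].map(
            lambda v: v[2:] if isinstance(v, str) and v.startswith("p.") else v
        )
    df = df[["sample", "gene", "consequence", "protein_change"]].reset_index(drop=True)
    return MutationCallTable(df)


def read_expression_table(path) -> pd.DataFrame:
    """Read a genes x samples FPKM matrix (first column = gene symbol).

    Returns a float DataFrame indexed by uppercased gene symbol. Duplicated
    gene symbols, negative values and non-numeric cells are rejected.
    """
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str).str.strip().str.upper()
    df.index.name = "gene"
    df.columns.name = "sample"
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated gene symbols {dups}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise FormatError(f"{path}: non-numeric value at gene {row!r}, sample {col!r}")
        df[col] = coerced
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values in expression matrix")
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative FPKM values")
    return df.astype(float)


def write_expression_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_drug_response(path) -> pd.DataFrame:
    """Read a long (drug, sample, measure, value) response table.

    ``measure`` must be ``z_ic50`` or ``auc``; duplicate (drug, sample,
    measure) keys are rejected.
    """
    df = _read_tsv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("drug", "sample", "measure", "value"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    df = df[["drug", "sample", "measure", "value"]].copy()
    df["measure"] = df["measure"].astype(str).str.strip().str.lower()
    unknown = set(df["measure"]) - set(MEASURES)
    if unknown:
        raise FormatError(
            f"{path}: unknown measure label(s) {sorted(unknown)}; expected {MEASURES}"
        )
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    dup = df.duplicated(subset=["drug", "sample", "measure"])
    if dup.any():
        first = df.loc[dup, ["drug", "sample", "measure"]].iloc[0].tolist()
        raise FormatError(f"{path}: duplicate (drug, sample, measure) key {first}")
    return df.reset_index(drop=True)


def read_gene_panel(path) -> GenePanel:
    """Read a one-symbol-per-line gene panel ('#' comments allowed)."""
    symbols = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                symbols.append(line)
    if not symbols:
        raise FormatError(f"{path}: gene panel file has no symbols")
    return GenePanel.from_symbols(symbols)


def write_gene_panel(panel: GenePanel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in panel:
            fh.write(g + "\n")


def _parse_flag(value, path, col):
    if pd.isna(value):
        return pd.NA
    key = str(value).strip().lower()
    if key in _TRUTHY:
        return True
    if key in _FALSY:
        return False
    raise FormatError(
        f"{path}: non-boolean value {value!r} in flag column {col!r} "
        f"(accepted: {sorted(_TRUTHY | _FALSY)})"
    )


def read_annotations(path) -> SampleAnnotations:
    """Read per-sample annotations.

    The first column is the sample id. Columns named ``flag:<name>`` are
    parsed as booleans under a documented truthy mapping (yes/no, true/false,
    1/0, case-insensitive); ``response_pct`` and ``response_binary`` are
    numeric; everything else stays categorical.
    """
    df = _read_tsv(path, dtype=str, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "sample"
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated sample ids {dups}")
    flags = []
    out = {}
    for col in df.columns:
        name = col.strip()
        if name.lower().startswith("flag:"):
            flag_name = name.split(":", 1)[1].strip()
            out[flag_name] = df[col].map(lambda v: _parse_flag(v, path, name))
            flags.append(flag_name)
        elif name in ("response_pct",):
            out[name] = pd.to_numeric(df[col], errors="raise")
        elif name in ("response_binary",):
            vals = pd.to_numeric(df[col], errors="raise")
            if not vals.dropna().isin([0, 1]).all():
                raise FormatError(f"{path}: response_binary must be 0/1")
            out[name] = vals
        else:
            out[name] = df[col]
    parsed = pd.DataFrame(out, index=df.index)
    return SampleAnnotations(parsed, tuple(flags))


def write_annotations(ann: SampleAnnotations, path) -> None:
    df = ann.df.copy()
    df = df.rename(columns={f: f"flag:{f}" for f in ann.flags})
    df.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# Locked-model serialization
# ---------------------------------------------------------------------------


def write_model_set(models, path) -> None:
    """Serialize a locked model set as a long-format TSV.

    A ``#``-prefixed header block records the shared feature namespace and
    one metadata line per drug (alpha, lambda, seed). Data rows are
    ``drug<TAB>term<TAB>coefficient`` with the term ``(Intercept)`` plus one
    row per *nonzero* coefficient; zero coefficients are omitted and
    restored on read from the namespace. Floats use 17 significant digits so
    the round trip is exact.
    """
    from .signatures import SignatureModelSet  # local import avoids a cycle

    if not isinstance(models, SignatureModelSet):
        raise ValidationError("write_model_set expects a SignatureModelSet")
    buf = _io.StringIO()
    buf.write("#feature_namespace\t" + ",".join(models.feature_names) + "\n")
    for drug, res in models.items():
        if not res.locked:
            raise ValidationError(f"model for {drug!r} is not locked")
        seed = "" if res.seed is None else repr(res.seed)
        buf.write(
            f"#model\t{drug}\talpha={res.alpha!r}\tlambda={res.lambda_!r}\tseed={seed}\n"
        )
    buf.write("drug\tterm\tcoefficient\n")
    for drug, res in models.items():
        buf.write(f"{drug}\t(Intercept)\t{res.intercept!r}\n")
        for term, coef in res.coefficients.items():
            if coef != 0.0:
                buf.write(f"{drug}\t{term}\t{coef!r}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_model_set(path):
    """Inverse of :func:`write_model_set` (exact float round trip)."""
    from .signatures import SignatureModelSet, SignatureResults

    namespace: list[str] | None = None
    meta: dict[str, dict] = {}
    rows: list[tuple[str, str, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        header_seen = False
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            if line.startswith("#feature_namespace\t"):
                namespace = [f for f in line.split("\t", 1)[1].split(",") if f]
                continue
            if line.startswith("#model\t"):
                parts = line.split("\t")
                drug = parts[1]
                kv = dict(p.split("=", 1) for p in parts[2:])
                meta[drug] = {
                    "alpha": float(kv["alpha"]),
                    "lambda": float(kv["lambda"]),
                    "seed": int(kv["seed"]) if kv.get("seed") else None,
                }
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields != ["drug", "term", "coefficient"]:
                    raise FormatError(f"{path}:{lineno}: unexpected header {fields}")
                header_seen = True
                continue
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            rows.append((fields[0], fields[1], float(fields[2])))
    if namespace is None:
        raise FormatError(f"{path}: missing #feature_namespace header")
    ns_set = set(namespace)
    per_drug: dict[str, dict[str, float]] = {}
    intercepts: dict[str, float] = {}
    for drug, term, coef in rows:
        if term == "(Intercept)":
            intercepts[drug] = coef
            per_drug.setdefault(drug, {})
        else:
            if term not in ns_set:
                raise FormatError(
                    f"{path}: term {term!r} for drug {drug!r} not in feature namespace"
                )
            if ":" not in term or term.rsplit(":", 1)[1] not in ("expr", "mut"):
                raise FormatError(f"{path}: unknown term suffix on {term!r}")
            per_drug.setdefault(drug, {})[term] = coef
    results = {}
    for drug in per_drug:
        if drug not in intercepts or math.isnan(intercepts[drug]):
            raise FormatError(f"{path}: drug {drug!r} has no (Intercept) row")
        m = meta.get(drug, {})
        coefs = pd.Series(
            [per_drug[drug].get(f, 0.0) for f in namespace],
            index=pd.Index(namespace, name="feature"),
            dtype=float,
        )
        results[drug] = SignatureResults(
            drug_id=drug,
            intercept=intercepts[drug],
            coefficients=coefs,
            alpha=m.get("alpha", float("nan")),
            lambda_=m.get("lambda", float("nan")),
            seed=m.get("seed"),
            cv_summary=None,
        )
    return SignatureModelSet(results, feature_names=tuple(namespace))


def write_score_matrix(scores: pd.DataFrame, path) -> None:
    """Export a drugs x samples score matrix as TSV (full precision)."""
    scores.to_csv(path, sep="\t", index_label="drug", float_format="%.17g")


def read_score_matrix(path) -> pd.DataFrame:
    df = _read_tsv(path, index_col=0)
    return df.astype(float)
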