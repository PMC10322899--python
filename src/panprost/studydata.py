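"""Domain types, flat-file I/O, clinical-dictionary validation, and gene harmonization.

The unit of analysis is a *study bundle*: one study's assays (log2 expression,
GISTIC-style discretized copy number, MAF-like mutations) together with a
clinical table conforming to a controlled data dictionary, all sharing a
sample namespace.  Gene symbols are harmonized to canonical (HGNC-style)
symbols through an alias dictionary before any cross-study analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_TOKENS = ["NA", ""]  # case-sensitive, per the data dictionary

SAMPLE_TYPES = ("primary", "metastatic", "normal", "BPH", "atrophic")
GRADE_GROUPS = ("<=6", "7", ">=8")

VARIANT_CLASSES = (
    "Silent",
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Nonstop_Mutation",
    "Frame_Shift_Ins",
    "Frame_Shift_Del",
    "In_Frame_Ins",
    "In_Frame_Del",
    "Splice_Site",
    "Translation_Start_Site",
    "Other",
)
MUTATION_STATUSES = ("matched_normal", "tumor_only")

CLINICAL_COLUMNS = (
    "sample_id",
    "patient_id",
    "sample_type",
    "grade_group",
    "gleason_primary",
    "gleason_secondary",
    "gleason_sum",
    "isup",
    "bcr_event",
    "time_to_bcr",
    "os_event",
    "time_to_os",
)


class ParseError(ValueError):
    """A flat file violates the declared format."""


class SchemaError(ValueError):
    """A required column is absent."""


class ContainmentError(ValueError):
    """Assay sample ids are not covered by the clinical table."""


class CoverageError(ValueError):
    """Too few signature genes present to score; carries a MatchReport."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


# ---------------------------------------------------------------------------
# Gene dictionary


@dataclass
class GeneDictionary:
    """Canonical symbol -> set of aliases, with optional priority targets.

    ``priority`` maps an ambiguous alias (one claimed by several canonical
    symbols) to the canonical symbol that wins; without a priority entry,
    rows carrying an ambiguous alias are dropped during harmonization.
    """

    entries: dict[str, set[str]] = field(default_factory=dict)
    priority: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        alias_owners: dict[str, list[str]] = {}
        for canonical, aliases in self.entries.items():
            if not canonical:
                raise ValueError("empty canonical symbol")
            for a in aliases:
                alias_owners.setdefault(a, []).append(canonical)
        for alias, owners in alias_owners.items():
            if alias in self.entries and alias not in owners:
                owners = owners + [alias]
            if len(owners) > 1 and alias not in self.priority:
                # allowed but only resolvable via priority; flag at resolve time
                pass
        self._alias_owners = alias_owners

    @classmethod
    def from_tsv(cls, path) -> "GeneDictionary":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if "canonical" not in df.columns or "alias" not in df.columns:
            raise SchemaError("alias dictionary needs 'canonical' and 'alias' columns")
        entries: dict[str, set[str]] = {}
        priority: dict[str, str] = {}
        for _, row in df.iterrows():
            entries.setdefault(row["canonical"], set())
            if row["alias"]:
                entries[row["canonical"]].add(row["alias"])
            if "priority" in df.columns and row.get("priority") in ("1", "true", "True"):
                priority[row["alias"]] = row["canonical"]
        return cls(entries=entries, priority=priority)

    def to_tsv(self, path) -> None:
        rows = []
        for canonical, aliases in self.entries.items():
            if not aliases:
                rows.append({"canonical": canonical, "alias": "", "priority": ""})
            for a in sorted(aliases):
                rows.append(
                    {
                        "canonical": canonical,
                        "alias": a,
                        "priority": "1" if self.priority.get(a) == canonical else "",
                    }
                )
        pd.DataFrame(rows, columns=["canonical", "alias", "priority"]).to_csv(
            path, sep="\t", index=False
        )

    def resolve(self, symbol: str) -> tuple[str | None, str]:
        """Map a symbol to its canonical form.

        Returns ``(canonical, status)`` with status one of ``canonical``
        (already canonical), ``alias`` (unambiguous alias), ``priority``
        (ambiguous alias resolved by priority), ``ambiguous`` (unresolvable,
        canonical is None) or ``unknown`` (kept verbatim).
        """
        if symbol in self.entries:
            return symbol, "canonical"
        owners = self._alias_owners.get(symbol, [])
        if len(owners) == 1:
            return owners[0], "alias"
        if len(owners) > 1:
            if symbol in self.priority:
                return self.priority[symbol], "priority"
            return None, "ambiguous"
        return symbol, "unknown"


# ---------------------------------------------------------------------------
# Assay matrices


def _read_matrix(path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    dupes = {s for s in samples if samples.count(s) > 1}
    if dupes:
        raise ParseError(f"duplicate sample header(s): {sorted(dupes)}")
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        dtype=str,
        keep_default_na=False,
        na_values=[],
    )
    if df.shape[1] != len(samples):
        raise ParseError("ragged rows: column count differs from header")
    values = df.where(~df.isin(MISSING_TOKENS), np.nan)
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric cell: {exc}") from exc
    values.index.name = "gene"
    return values


@dataclass
class ExpressionMatrix:
    """Genes x samples real matrix on log2 scale (or declared unknown)."""

    data: pd.DataFrame  # index: gene symbols, columns: sample ids
    scale_tag: str = "log2"

    def __post_init__(self) -> None:
        if self.scale_tag not in ("log2", "unknown"):
            raise ValueError(f"scale_tag must be 'log2' or 'unknown', got {self.scale_tag!r}")
        if self.data.columns.duplicated().any():
            raise ParseError("duplicate sample ids")
        with np.errstate(invalid="ignore"):
            arr = self.data.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValueError("non-finite (inf) expression values")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def write(self, path) -> None:
        out = self.data.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", na_rep="NA")


def read_expression(path, scale_tag: str = "log2") -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column ``gene``, header of sample ids).

    Duplicate gene rows are preserved here; :func:`harmonize_genes` collapses
    them.  ``NA`` and empty cells parse as missing, never as zero.
    """
    return ExpressionMatrix(data=_read_matrix(path), scale_tag=scale_tag)


@dataclass
class CopyNumberMatrix:
    """GISTIC-style discretized calls: -2 deep loss .. +2 amplification."""

    data: pd.DataFrame  # float frame holding integer calls with NaN for missing

    def __post_init__(self) -> None:
        arr = self.data.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        if ((finite != np.round(finite)).any()):
            raise ParseError("non-integer copy-number call")
        if finite.size and (finite.min() < -2 or finite.max() > 2):
            bad = sorted(set(finite[(finite < -2) | (finite > 2)]))
            raise ParseError(f"copy-number call(s) outside -2..2: {bad}")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def write(self, path) -> None:
        out = self.data.copy()
        out.index.name = "gene"
        # keep integer text form for non-missing cells
        out = out.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
        out.to_csv(path, sep="\t")


def read_gistic_matrix(path) -> CopyNumberMatrix:
    """Read a thresholded copy-number TSV; calls must lie in {-2,-1,0,1,2}."""
    return CopyNumberMatrix(data=_read_matrix(path))


# ---------------------------------------------------------------------------
# Mutations


@dataclass
class MutationTable:
    """Long-format somatic mutation calls (one row per sample/gene/variant)."""

    data: pd.DataFrame  # columns: sample_id, gene_symbol, variant_class, mutation_status

    def __post_init__(self) -> None:
        required = {"sample_id", "gene_symbol", "variant_class", "mutation_status"}
        missing = required - set(self.data.columns)
        if missing:
            raise SchemaError(f"MutationTable missing columns: {sorted(missing)}")
        bad = set(self.data["variant_class"]) - set(VARIANT_CLASSES)
        if bad:
            raise ValueError(f"variant_class outside vocabulary: {sorted(bad)}")
        if (self.data["sample_id"] == "").any() or (self.data["gene_symbol"] == "").any():
            raise ValueError("empty sample_id or gene_symbol in mutation table")

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())

    def write_maf(self, path) -> None:
        out = pd.DataFrame(
            {
                "Hugo_Symbol": self.data["gene_symbol"],
                "Tumor_Sample_Barcode": self.data["sample_id"],
                "Variant_Classification": self.data["variant_class"],
                "Mutation_Status": self.data["mutation_status"],
            }
        )
        out.to_csv(path, sep="\t", index=False)


def read_maf(path) -> MutationTable:
    """Read a tab-separated MAF.

    Requires ``Hugo_Symbol``, ``Tumor_Sample_Barcode`` and
    ``Variant_Classification``; unknown variant classes map to ``Other``
    with a logged warning.  ``Mutation_Status`` defaults to ``tumor_only``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    required = ["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"MAF missing required column(s): {missing}")
    classes = df["Variant_Classification"].copy()
    unknown = sorted(set(classes) - set(VARIANT_CLASSES))
    if unknown:
        logger.warning("unknown Variant_Classification mapped to Other: %s", unknown)
        classes = classes.where(classes.isin(VARIANT_CLASSES), "Other")
    status = df.get("Mutation_Status")
    if status is None:
        status = pd.Series(["tumor_only"] * len(df))
    else:
        status = status.where(status.isin(MUTATION_STATUSES), "tumor_only")
    return MutationTable(
        data=pd.DataFrame(
            {
                "sample_id": df["Tumor_Sample_Barcode"].to_numpy(),
                "gene_symbol": df["Hugo_Symbol"].to_numpy(),
                "variant_class": classes.to_numpy(),
                "mutation_status": status.to_numpy(),
            }
        )
    )


# ---------------------------------------------------------------------------
# Clinical table and validation


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations under the controlled data dictionary."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "sample_id" not in self.data.columns:
            raise SchemaError("clinical table requires a sample_id column")
        self.data = self.data.set_index(
            pd.Index(self.data["sample_id"], name="_sid"), drop=False
        ) if self.data.index.name != "_sid" else self.data

    @property
    def samples(self) -> list[str]:
        return list(self.data["sample_id"])

    def write(self, path) -> None:
        cols = [c for c in CLINICAL_COLUMNS if c in self.data.columns] + [
            c for c in self.data.columns if c not in CLINICAL_COLUMNS
        ]
        self.data[cols].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    df = df.where(~df.isin(MISSING_TOKENS), np.nan)
    for col in ("gleason_primary", "gleason_secondary", "gleason_sum", "isup",
                "bcr_event", "os_event"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("time_to_bcr", "time_to_os"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return ClinicalTable(data=df)


@dataclass
class Violation:
    field: str
    sample_id: str  # "-" for table-level rules
    rule: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(v.field, v.sample_id, v.rule, v.message) for v in self.violations],
            columns=["field", "sample_id", "rule", "message"],
        )


def _case_hint(value: str, allowed: tuple[str, ...]) -> str:
    for a in allowed:
        if value.lower() == a.lower():
            return f" (did you mean {a!r}? values are case-sensitive)"
    return ""


def validate_clinical(table: ClinicalTable) -> ValidationReport:
    """Check a clinical table against the data dictionary.

    Violations are data, not exceptions: a fully conformant table yields an
    empty report.  Case-only mismatches of controlled vocabulary get a
    normalization hint.
    """
    df = table.data
    out: list[Violation] = []

    dup = df["sample_id"][df["sample_id"].duplicated()].unique()
    for d in dup:
        out.append(Violation("sample_id", str(d), "unique", "duplicate sample_id"))

    def per_sample(col, rule, check, msg):
        if col not in df.columns:
            return
        for sid, val in zip(df["sample_id"], df[col]):
            if pd.isna(val):
                continue
            ok, extra = check(val)
            if not ok:
                out.append(Violation(col, str(sid), rule, msg(val) + extra))

    per_sample(
        "sample_type",
        "controlled_vocabulary",
        lambda v: (v in SAMPLE_TYPES, _case_hint(str(v), SAMPLE_TYPES)),
        lambda v: f"sample_type {v!r} not in {SAMPLE_TYPES}",
    )
    per_sample(
        "grade_group",
        "controlled_vocabulary",
        lambda v: (v in GRADE_GROUPS, ""),
        lambda v: f"grade_group {v!r} not in {GRADE_GROUPS}",
    )
    for col in ("bcr_event", "os_event"):
        per_sample(
            col,
            "binary_event",
            lambda v: (float(v) in (0.0, 1.0), ""),
            lambda v: f"event indicator must be 0 or 1, got {v!r}",
        )
    for col in ("time_to_bcr", "time_to_os"):
        per_sample(
            col,
            "nonnegative_time",
            lambda v: (float(v) >= 0, ""),
            lambda v: f"time must be >= 0 months, got {v!r}",
        )
    per_sample(
        "isup",
        "range",
        lambda v: (float(v) in (1, 2, 3, 4, 5), ""),
        lambda v: f"isup must be 1..5, got {v!r}",
    )
    per_sample(
        "gleason_sum",
        "range",
        lambda v: (2 <= float(v) <= 10, ""),
        lambda v: f"gleason_sum must be 2..10, got {v!r}",
    )
    if {"gleason_primary", "gleason_secondary", "gleason_sum"} <= set(df.columns):
        for sid, p, s, g in zip(
            df["sample_id"], df["gleason_primary"], df["gleason_secondary"], df["gleason_sum"]
        ):
            if pd.notna(p) and pd.notna(s) and pd.notna(g) and p + s != g:
                out.append(
                    Violation(
                        "gleason_sum",
                        str(sid),
                        "sum_consistency",
                        f"gleason_sum {g} != primary {p} + secondary {s}",
                    )
                )

    counts: dict[str, int] = {}
    if "sample_type" in df.columns:
        for st, n in df["sample_type"].value_counts(dropna=True).items():
            counts[f"sample_type:{st}"] = int(n)
    counts["n_samples"] = len(df)
    return ValidationReport(violations=out, counts=counts)


# ---------------------------------------------------------------------------
# Gene harmonization


def harmonize_genes(
    matrix: ExpressionMatrix,
    gene_dict: GeneDictionary,
    collapse_rule: str = "mean",
) -> tuple[ExpressionMatrix, list[dict]]:
    """Rename rows to canonical symbols and collapse duplicates.

    Aliases map to their canonical symbol; unknown symbols are kept verbatim
    and logged; an alias claimed by several canonical symbols without a
    priority flag drops the row (logged).  Rows sharing a canonical symbol
    after renaming are collapsed by ``mean`` or ``max_variance``.  Idempotent.
    """
    if collapse_rule not in ("mean", "max_variance"):
        raise ValueError(f"collapse_rule must be 'mean' or 'max_variance', got {collapse_rule!r}")
    log: list[dict] = []
    new_names: list[str | None] = []
    for sym in matrix.data.index:
        canonical, status = gene_dict.resolve(str(sym))
        if status == "ambiguous":
            log.append({"symbol": sym, "action": "dropped", "reason": "ambiguous alias"})
            new_names.append(None)
            continue
        if status == "unknown":
            log.append({"symbol": sym, "action": "kept", "reason": "unknown symbol"})
        elif status in ("alias", "priority") and canonical != sym:
            log.append({"symbol": sym, "action": "renamed", "reason": f"alias of {canonical}"})
        new_names.append(canonical)

    keep = [n is not None for n in new_names]
    data = matrix.data.iloc[np.flatnonzero(keep)].copy()
    data.index = pd.Index([n for n in new_names if n is not None], name="gene")

    if data.index.duplicated().any():
        dup_syms = data.index[data.index.duplicated()].unique()
        if collapse_rule == "mean":
            collapsed = data.groupby(level=0, sort=False).mean()
        else:  # max_variance: keep the row with the largest variance
            order = data.var(axis=1, ddof=1).fillna(-np.inf)
            pick = (
                pd.DataFrame({"v": order.to_numpy()}, index=data.index)
                .reset_index()
                .groupby("gene", sort=False)["v"]
                .idxmax()
            )
            collapsed = data.reset_index(drop=True).iloc[pick.to_numpy()]
            collapsed.index = pd.Index(pick.index, name="gene")
        # preserve first-occurrence order
        first_order = data.index.drop_duplicates()
        data = collapsed.loc[first_order]
        for sym in dup_syms:
            log.append({"symbol": sym, "action": "collapsed", "reason": collapse_rule})
    return ExpressionMatrix(data=data, scale_tag=matrix.scale_tag), log


# ---------------------------------------------------------------------------
# Gleason grouping


def map_gleason(
    primary=None, secondary=None, gleason_sum=None, isup=None
) -> str | None:
    """Map pathology grading to the grade groups <=6 / 7 / >=8.

    Precedence: reported sum > primary+secondary > ISUP group
    (ISUP 1 -> "<=6", 2-3 -> "7", 4-5 -> ">=8").  All inputs missing yields
    a missing grade group, not an error.
    """
    def _na(v):
        return v is None or (isinstance(v, float) and math.isnan(v))

    s = None
    if not _na(gleason_sum):
        s = int(gleason_sum)
    elif not _na(primary) and not _na(secondary):
        s = int(primary) + int(secondary)
    if s is not None:
        if not 2 <= s <= 10:
            raise ValueError(f"Gleason sum {s} outside 2..10")
        if s <= 6:
            return "<=6"
        if s == 7:
            return "7"
        return ">=8"
    if not _na(isup):
        i = int(isup)
        if i not in (1, 2, 3, 4, 5):
            raise ValueError(f"ISUP group {i} outside 1..5")
        return "<=6" if i == 1 else ("7" if i <= 3 else ">=8")
    return None


# ---------------------------------------------------------------------------
# Study bundle


@dataclass
class StudyBundle:
    """One study's assays plus clinical table under a shared sample namespace."""

    name: str
    clinical: ClinicalTable
    expression: ExpressionMatrix | None = None
    cna: CopyNumberMatrix | None = None
    mutations: MutationTable | None = None

    def __post_init__(self) -> None:
        if self.expression is None and self.cna is None and self.mutations is None:
            raise ValueError(f"study {self.name!r} has no assays")
        clin = set(self.clinical.samples)
        for label, ids in self._assay_samples().items():
            orphans = sorted(set(ids) - clin)
            if orphans:
                raise ContainmentError(
                    f"{label} sample(s) absent from clinical table: {orphans}"
                )

    def _assay_samples(self) -> dict[str, list[str]]:
        out = {}
        if self.expression is not None:
            out["gex"] = self.expression.samples
        if self.cna is not None:
            out["cna"] = self.cna.samples
        if self.mutations is not None:
            out["mut"] = self.mutations.samples
        return out

    def counts(self) -> dict[str, int]:
        """Per-assay and per-sample_type sample counts (Table-1-style bookkeeping)."""
        out = {label: len(ids) for label, ids in self._assay_samples().items()}
        if "sample_type" in self.clinical.data.columns:
            for st, n in self.clinical.data["sample_type"].value_counts(dropna=True).items():
                out[str(st)] = int(n)
        return out


def build_study(
    name: str,
    clinical: ClinicalTable,
    expression: ExpressionMatrix | None = None,
    cna: CopyNumberMatrix | None = None,
    mutations: MutationTable | None = None,
) -> StudyBundle:
    """Assemble a validated StudyBundle; orphan assay samples raise ContainmentError."""
    return StudyBundle(
        name=name, clinical=clinical, expression=expression, cna=cna, mutations=mutations
    )
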