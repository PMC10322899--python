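"""Gene-signature scoring engine.

Covers the androgen-receptor activity score and the three published
prostate-cancer risk scores (Oncotype DX-style grouped linear model,
Prolaris-style centered mean, Decipher-style signed percentile mean),
plus coverage classification of signature genes against a dataset
(1-to-1 match / 1-to-many / missing).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .studydata import CoverageError, ExpressionMatrix, GeneDictionary

logger = logging.getLogger(__name__)

NORMALIZATIONS = ("zscore", "percentile", "center")
COMBINATIONS = ("mean", "weighted_sum", "grouped_linear", "signed_percentile_mean")


@dataclass
class SignatureComponent:
    gene: str
    aliases: tuple[str, ...] = ()
    direction: int = 1
    weight: float = 1.0
    group: str | None = None


@dataclass
class SignatureModel:
    """A named signature: components, per-gene normalization, combination rule."""

    name: str
    components: list[SignatureComponent]
    normalization: str = "zscore"
    combination: str = "mean"
    group_weights: dict[str, float] = field(default_factory=dict)
    min_fraction: float = 0.5
    description: str = ""

    def __post_init__(self) -> None:
        genes = [c.gene for c in self.components]
        if len(set(genes)) != len(genes):
            raise ValueError(f"duplicate component genes in signature {self.name!r}")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.combination not in COMBINATIONS:
            raise ValueError(f"unknown combination {self.combination!r}")
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must lie in (0, 1]")
        if not all(np.isfinite(c.weight) for c in self.components):
            raise ValueError("component weights must be finite")
        if self.combination == "grouped_linear":
            for c in self.components:
                if c.group is None or c.group not in self.group_weights:
                    raise ValueError(
                        f"grouped_linear requires a weighted group for every component; "
                        f"{c.gene} has group {c.group!r}"
                    )

    @property
    def genes(self) -> list[str]:
        return [c.gene for c in self.components]

    def __len__(self) -> int:
        return len(self.components)

    def subset(self, drop: set[str]) -> "SignatureModel":
        """A copy of the model with the given genes removed (dropout benchmark)."""
        kept = [c for c in self.components if c.gene not in drop]
        if not kept:
            raise ValueError("cannot drop every gene from a signature")
        return SignatureModel(
            name=f"{self.name}-drop{len(self.components) - len(kept)}",
            components=kept,
            normalization=self.normalization,
            combination=self.combination,
            group_weights=dict(self.group_weights),
            min_fraction=1e-9,  # benchmark scores on whatever remains
            description=self.description,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureModel":
        comps = [
            SignatureComponent(
                gene=c["gene"],
                aliases=tuple(c.get("aliases", ())),
                direction=int(c.get("direction", 1)),
                weight=float(c.get("weight", 1.0)),
                group=c.get("group"),
            )
            for c in d["components"]
        ]
        return cls(
            name=d["name"],
            components=comps,
            normalization=d.get("normalization", "zscore"),
            combination=d.get("combination", "mean"),
            group_weights=dict(d.get("group_weights", {})),
            min_fraction=float(d.get("min_fraction", 0.5)),
            description=d.get("description", ""),
        )

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "description": self.description,
            "normalization": self.normalization,
            "combination": self.combination,
            "min_fraction": self.min_fraction,
            "group_weights": dict(self.group_weights),
            "components": [
                {
                    "gene": c.gene,
                    "aliases": list(c.aliases),
                    "direction": c.direction,
                    "weight": c.weight,
                    "group": c.group,
                }
                for c in self.components
            ],
        }


@dataclass
class MatchReport:
    """Coverage of signature genes in a dataset: single / multiple / missing."""

    signature: str
    categories: dict[str, str]  # gene -> "single" | "multiple" | "missing"
    matched_row: dict[str, str]  # gene -> matrix row symbol, for single matches

    @property
    def n_single(self) -> int:
        return sum(1 for v in self.categories.values() if v == "single")

    @property
    def n_multiple(self) -> int:
        return sum(1 for v in self.categories.values() if v == "multiple")

    @property
    def n_missing(self) -> int:
        return sum(1 for v in self.categories.values() if v == "missing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.categories), "category": list(self.categories.values())}
        )


@dataclass
class ScoreVector:
    """Per-sample signature score plus the genes that actually entered it."""

    name: str
    scores: pd.Series  # index: sample ids
    genes_used: list[str]

    @property
    def n_genes_used(self) -> int:
        return len(self.genes_used)


def classify_coverage(
    sig: SignatureModel,
    matrix: ExpressionMatrix,
    gene_dict: GeneDictionary | None = None,
) -> MatchReport:
    """Classify each signature gene against matrix rows.

    ``single``: exactly one row matches the gene or any of its aliases;
    ``multiple``: more than one (unusable 1-to-many match); ``missing``: none.
    A GeneDictionary contributes extra aliases when given.
    """
    rows = list(map(str, matrix.data.index))
    row_count: dict[str, int] = {}
    for r in rows:
        row_count[r] = row_count.get(r, 0) + 1
    categories: dict[str, str] = {}
    matched: dict[str, str] = {}
    for comp in sig.components:
        names = {comp.gene, *comp.aliases}
        if gene_dict is not None:
            extra = set()
            for n in list(names):
                if n in gene_dict.entries:
                    extra |= gene_dict.entries[n]
            names |= extra
        hits = [r for r in row_count if r in names]
        total = sum(row_count[r] for r in hits)
        if total == 0:
            categories[comp.gene] = "missing"
        elif total == 1:
            categories[comp.gene] = "single"
            matched[comp.gene] = hits[0]
        else:
            categories[comp.gene] = "multiple"
    return MatchReport(signature=sig.name, categories=categories, matched_row=matched)


def _normalize(values: pd.DataFrame, how: str) -> pd.DataFrame:
    """Per-gene normalization across samples.

    zscore uses the sample standard deviation (n-1); a zero-variance gene's
    z is set to 0 and logged.  percentile is the fractional average rank in
    (0, 1].  center subtracts the per-gene mean.
    """
    if how == "zscore":
        mu = values.mean(axis=1)
        sd = values.std(axis=1, ddof=1)
        zero = sd == 0
        if zero.any():
            logger.warning(
                "zero-variance gene(s) under zscore set to 0: %s",
                list(values.index[zero]),
            )
        sd = sd.replace(0, np.nan)
        out = values.sub(mu, axis=0).div(sd, axis=0)
        return out.fillna(0.0) if zero.any() else out
    if how == "percentile":
        n = values.shape[1]
        return values.rank(axis=1, method="average") / n
    if how == "center":
        return values.sub(values.mean(axis=1), axis=0)
    raise ValueError(f"unknown normalization {how!r}")


def score(
    sig: SignatureModel,
    matrix: ExpressionMatrix,
    gene_dict: GeneDictionary | None = None,
) -> ScoreVector:
    """Compute the per-sample signature score.

    Only genes with a single (1-to-1) match contribute; multiple matches are
    treated as unusable.  Raises CoverageError when fewer than
    ``sig.min_fraction`` of the signature's genes have a single match, and
    when zscore/percentile normalization is requested with < 3 samples.
    """
    report = classify_coverage(sig, matrix, gene_dict)
    frac = report.n_single / len(sig)
    if frac < sig.min_fraction:
        raise CoverageError(
            f"signature {sig.name!r}: only {report.n_single}/{len(sig)} genes "
            f"matched 1-to-1 (min_fraction={sig.min_fraction})",
            report=report,
        )
    if sig.normalization in ("zscore", "percentile") and matrix.data.shape[1] < 3:
        raise ValueError(
            f"{sig.normalization} normalization needs >= 3 samples, "
            f"got {matrix.data.shape[1]}"
        )

    comps = [c for c in sig.components if report.categories[c.gene] == "single"]
    rows = [report.matched_row[c.gene] for c in comps]
    sub = matrix.data.loc[rows]
    sub.index = pd.Index([c.gene for c in comps], name="gene")
    norm = _normalize(sub, sig.normalization)

    direction = pd.Series([c.direction for c in comps], index=norm.index, dtype=float)
    weight = pd.Series([c.weight for c in comps], index=norm.index, dtype=float)

    if sig.combination == "mean":
        scores = norm.mul(direction, axis=0).mean(axis=0)
    elif sig.combination == "weighted_sum":
        scores = norm.mul(direction * weight, axis=0).sum(axis=0)
    elif sig.combination == "grouped_linear":
        groups = pd.Series([c.group for c in comps], index=norm.index)
        scores = pd.Series(0.0, index=norm.columns)
        for g, w in sig.group_weights.items():
            members = groups.index[groups == g]
            if len(members):
                scores = scores + w * norm.loc[members].mul(
                    direction.loc[members], axis=0
                ).mean(axis=0)
    elif sig.combination == "signed_percentile_mean":
        pct = norm if sig.normalization == "percentile" else _normalize(sub, "percentile")
        up = direction.index[direction > 0]
        down = direction.index[direction < 0]
        up_mean = pct.loc[up].mean(axis=0) if len(up) else 0.0
        down_mean = pct.loc[down].mean(axis=0) if len(down) else 0.0
        scores = up_mean - down_mean
    else:  # pragma: no cover - guarded in SignatureModel
        raise ValueError(sig.combination)

    scores.name = sig.name
    return ScoreVector(name=sig.name, scores=scores, genes_used=[c.gene for c in comps])


def builtin_signatures() -> dict[str, SignatureModel]:
    """The signatures shipped as package data: ar, oncotype_dx, prolaris, decipher."""
    out: dict[str, SignatureModel] = {}
    pkg = resources.files("panprost").joinpath("data/signatures")
    for entry in sorted(pkg.iterdir(), key=lambda p: p.name):
        if entry.name.endswith(".json"):
            model = SignatureModel.from_dict(json.loads(entry.read_text("utf-8")))
            out[model.name] = model
    return out


def get_signature(name: str) -> SignatureModel:
    sigs = builtin_signatures()
    if name not in sigs:
        raise KeyError(f"unknown signature {name!r}; available: {sorted(sigs)}")
    return sigs[name]


def marker_score(marker_genes: list[str], matrix: ExpressionMatrix) -> ScoreVector:
    """Generic marker-program score: z-score + mean over available markers.

    Stand-in for per-sample cell-content estimates (e.g. an endothelial-like
    program) consumed by the survival analyses.
    """
    sig = SignatureModel(
        name="marker_program",
        components=[SignatureComponent(gene=g) for g in marker_genes],
        normalization="zscore",
        combination="mean",
        min_fraction=1e-9,
    )
    report = classify_coverage(sig, matrix)
    if report.n_single == 0:
        raise CoverageError("no marker genes present in the matrix", report=report)
    return score(sig, matrix)
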