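"""Binary alteration calls and mutual-exclusivity / co-occurrence statistics.

An alteration is any non-diploid copy-number call (including shallow +-1) or
any non-silent mutation.  Gene pairs are tested on the 2x2 table of altered
status with the odds ratio OR = (both * neither) / (a_only * b_only) and the
two-sided Fisher exact test, BH-adjusted across a screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metade import bh_adjust
from .studydata import CopyNumberMatrix, MutationTable

logger = logging.getLogger(__name__)

NON_SILENT_EXCLUDED = {"Silent"}


@dataclass
class AlterationMatrix:
    """Genes x samples binary alteration matrix with per-cell provenance."""

    calls: pd.DataFrame  # int 0/1
    provenance: pd.DataFrame  # {"cna","mutation","both","none"}
    has_cna: pd.Series  # per-sample assay availability flags
    has_mut: pd.Series

    def __post_init__(self) -> None:
        altered = self.calls.to_numpy() == 1
        prov = self.provenance.to_numpy()
        if not ((prov != "none") == altered).all():
            raise ValueError("provenance inconsistent with calls")

    @property
    def genes(self) -> list[str]:
        return list(self.calls.index)

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)


def binarize_alterations(
    cna: CopyNumberMatrix | None = None,
    mutations: MutationTable | None = None,
    gene_list: list[str] | None = None,
    deep_only: bool = False,
) -> AlterationMatrix:
    """Collapse CNA calls and mutations into a binary altered/unaltered matrix.

    Altered iff the CNA call is non-zero (calls of +-1 count unless
    ``deep_only``) or the sample carries >= 1 non-silent mutation in the gene.
    Samples lacking an assay contribute 0 from that assay and are flagged
    (alteration fractions are then acknowledged undercounts).
    """
    if cna is None and mutations is None:
        raise ValueError("need at least one of cna, mutations")

    cna_samples = list(cna.samples) if cna is not None else []
    mut_samples = list(mutations.samples) if mutations is not None else []
    samples = list(dict.fromkeys(cna_samples + mut_samples))

    cna_genes = set(cna.genes) if cna is not None else set()
    mut_genes = set(mutations.data["gene_symbol"]) if mutations is not None else set()
    if gene_list is None:
        genes = sorted(cna_genes | mut_genes)
    else:
        genes, dropped = [], []
        for g in gene_list:
            (genes if g in cna_genes | mut_genes else dropped).append(g)
        if dropped:
            logger.warning("gene(s) absent from both assays excluded: %s", dropped)
    if not genes:
        raise ValueError("no requested genes present in any assay")

    cna_hit = pd.DataFrame(False, index=genes, columns=samples)
    if cna is not None:
        sub = cna.data.reindex(index=genes, columns=samples)
        calls = sub.to_numpy(dtype=float)
        if deep_only:
            hit = np.abs(calls) == 2
        else:
            hit = np.nan_to_num(calls) != 0
        cna_hit.loc[:, :] = hit

    mut_hit = pd.DataFrame(False, index=genes, columns=samples)
    if mutations is not None:
        nonsilent = mutations.data[
            ~mutations.data["variant_class"].isin(NON_SILENT_EXCLUDED)
        ]
        for g, s in zip(nonsilent["gene_symbol"], nonsilent["sample_id"]):
            if g in mut_hit.index and s in mut_hit.columns:
                mut_hit.loc[g, s] = True

    both = cna_hit & mut_hit
    prov = pd.DataFrame("none", index=genes, columns=samples)
    prov = prov.mask(cna_hit, "cna").mask(mut_hit, "mutation").mask(both, "both")
    calls01 = (cna_hit | mut_hit).astype(int)
    has_cna = pd.Series([s in set(cna_samples) for s in samples], index=samples)
    has_mut = pd.Series([s in set(mut_samples) for s in samples], index=samples)
    return AlterationMatrix(calls=calls01, provenance=prov, has_cna=has_cna, has_mut=has_mut)


def alteration_frequency(am: AlterationMatrix) -> pd.DataFrame:
    """Fraction of samples altered per gene, with assay-availability counts."""
    n = am.calls.shape[1]
    if n < 1:
        raise ValueError("need >= 1 sample")
    altered = am.calls.sum(axis=1)
    return pd.DataFrame(
        {
            "n_altered": altered.astype(int),
            "n_samples": n,
            "frequency": altered / n,
            "n_with_cna": int(am.has_cna.sum()),
            "n_with_mut": int(am.has_mut.sum()),
        }
    )


def cna_gain_loss_frequency(cna: CopyNumberMatrix) -> pd.DataFrame:
    """Per-gene fraction of gain (call > 0) and loss (call < 0) samples;
    missing calls leave the denominator."""
    arr = cna.data.to_numpy(dtype=float)
    n_obs = np.sum(np.isfinite(arr), axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_gain = np.where(n_obs > 0, np.nansum(arr > 0, axis=1) / n_obs, np.nan)
        frac_loss = np.where(n_obs > 0, np.nansum(arr < 0, axis=1) / n_obs, np.nan)
    return pd.DataFrame(
        {"frac_gain": frac_gain, "frac_loss": frac_loss, "n_assayed": n_obs.astype(int)},
        index=cna.data.index,
    )


@dataclass
class PairTest:
    """One gene pair's 2x2 alteration table, odds ratio and exact test."""

    gene_a: str
    gene_b: str
    both: int
    a_only: int
    b_only: int
    neither: int
    odds_ratio: float
    odds_ratio_haldane: float
    p: float
    q: float | None = None
    star: bool = False

    @property
    def n_samples(self) -> int:
        return self.both + self.a_only + self.b_only + self.neither

    @property
    def label(self) -> str:
        if np.isnan(self.odds_ratio) or self.odds_ratio == 1.0:
            return "indeterminate"
        return "co-occurring" if self.odds_ratio > 1.0 else "exclusive"


def _odds_ratio(both: int, a_only: int, b_only: int, neither: int) -> tuple[float, float]:
    """(OR by the (both*neither)/(a_only*b_only) formula, Haldane-corrected OR)."""
    num, den = both * neither, a_only * b_only
    if den == 0:
        orr = np.nan if num == 0 else np.inf
    else:
        orr = num / den
    h = 0.5
    haldane = ((both + h) * (neither + h)) / ((a_only + h) * (b_only + h))
    return orr, haldane


def fisher_exact_p(both: int, a_only: int, b_only: int, neither: int) -> float:
    """Two-sided Fisher exact p for a 2x2 alteration table."""
    _, p = stats.fisher_exact([[both, a_only], [b_only, neither]], alternative="two-sided")
    return float(p)


def mutual_exclusivity(am: AlterationMatrix, gene_a: str, gene_b: str) -> PairTest:
    """Test one gene pair for co-occurrence (OR > 1) vs exclusivity (OR < 1)."""
    for g in (gene_a, gene_b):
        if g not in am.calls.index:
            raise KeyError(f"gene {g!r} not in alteration matrix")
    a = am.calls.loc[gene_a].to_numpy() == 1
    b = am.calls.loc[gene_b].to_numpy() == 1
    both = int(np.sum(a & b))
    a_only = int(np.sum(a & ~b))
    b_only = int(np.sum(~a & b))
    neither = int(np.sum(~a & ~b))
    orr, haldane = _odds_ratio(both, a_only, b_only, neither)
    p = fisher_exact_p(both, a_only, b_only, neither)
    return PairTest(
        gene_a=gene_a, gene_b=gene_b, both=both, a_only=a_only, b_only=b_only,
        neither=neither, odds_ratio=orr, odds_ratio_haldane=haldane, p=p,
    )


def mutex_screen(am: AlterationMatrix, genes: list[str] | None = None) -> list[PairTest]:
    """All unordered gene pairs tested, BH-adjusted across the screen; the
    star flag marks p < 0.05 (figure convention)."""
    genes = list(am.calls.index) if genes is None else list(dict.fromkeys(genes))
    if len(genes) < 2:
        raise ValueError("need >= 2 genes")
    tests = [
        mutual_exclusivity(am, genes[i], genes[j])
        for i in range(len(genes))
        for j in range(i + 1, len(genes))
    ]
    qs = bh_adjust([t.p for t in tests])
    for t, q in zip(tests, qs):
        t.q = float(q)
        t.star = t.p < 0.05
    return tests


def pair_tests_frame(tests: list[PairTest]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": t.gene_a, "gene_b": t.gene_b, "both": t.both,
                "a_only": t.a_only, "b_only": t.b_only, "neither": t.neither,
                "odds_ratio": t.odds_ratio, "odds_ratio_haldane": t.odds_ratio_haldane,
                "p": t.p, "q": t.q, "label": t.label, "star": t.star,
            }
            for t in tests
        ]
    )
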