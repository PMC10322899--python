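"""Simulated gene-dropout robustness benchmark for signature scores.

For each dropout size k, random k-subsets of a signature's genes are removed,
the score is recomputed from the remaining genes, and correlated with the
"ground truth" score computed from the full gene list across samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import ScoreVector, SignatureModel, classify_coverage, score
from .studydata import ExpressionMatrix


@dataclass
class MissingnessResult:
    """Per-k benchmark outcome: one correlation per sampled gene subset."""

    k: int
    correlations: np.ndarray
    subsets: list[tuple[str, ...]]
    seed: int
    correlation_type: str = "pearson"

    @property
    def n_combinations(self) -> int:
        return len(self.correlations)

    @property
    def mean_corr(self) -> float:
        return float(np.mean(self.correlations))

    @property
    def median_corr(self) -> float:
        return float(np.median(self.correlations))


def _distinct_subsets(genes: list[str], k: int, n_combinations: int, rng) -> list[tuple[str, ...]]:
    """Distinct k-subsets: exhaustive when the subset space is small, else
    rejection-sampled without replacement."""
    m = len(genes)
    total = comb(m, k)
    if total <= n_combinations:
        return [tuple(c) for c in combinations(genes, k)]
    seen: set[tuple[int, ...]] = set()
    out: list[tuple[str, ...]] = []
    while len(out) < n_combinations:
        idx = tuple(sorted(rng.choice(m, size=k, replace=False).tolist()))
        if idx in seen:
            continue
        seen.add(idx)
        out.append(tuple(genes[i] for i in idx))
    return out


def _corr(x: np.ndarray, y: np.ndarray, how: str) -> float:
    if how == "pearson":
        return float(stats.pearsonr(x, y)[0])
    if how == "spearman":
        return float(stats.spearmanr(x, y)[0])
    raise ValueError(f"correlation must be 'pearson' or 'spearman', got {how!r}")


def benchmark_missingness(
    sig: SignatureModel,
    matrix: ExpressionMatrix,
    k_min: int = 1,
    k_max: int = 5,
    n_combinations: int = 100,
    seed: int = 0,
    correlation: str = "pearson",
) -> list[MissingnessResult]:
    """Dropout benchmark over k in [k_min, k_max].

    Requires the signature fully present (every gene a 1-to-1 match) so that
    the full-gene ground-truth score is computable.  k=0 is allowed as a
    sanity mode and yields correlations identically 1.  Deterministic given
    the seed; each k draws from its own child stream, so extending the k
    range does not perturb existing results.
    """
    m = len(sig)
    if not 0 <= k_min <= k_max:
        raise ValueError("need 0 <= k_min <= k_max")
    if k_max >= m:
        raise ValueError(f"k_max={k_max} must be < signature size {m}")
    if matrix.data.shape[1] < 3:
        raise ValueError("correlation undefined with < 3 samples")
    report = classify_coverage(sig, matrix)
    if report.n_single < m:
        raise ValueError(
            f"signature {sig.name!r} not fully present: "
            f"{report.n_missing} missing, {report.n_multiple} multiple"
        )

    full = score(sig, matrix).scores.to_numpy()
    genes = sig.genes
    results: list[MissingnessResult] = []
    for k in range(k_min, k_max + 1):
        rng = np.random.default_rng([seed, k])
        if k == 0:
            subsets: list[tuple[str, ...]] = [()]
        else:
            subsets = _distinct_subsets(genes, k, n_combinations, rng)
        corrs = np.empty(len(subsets))
        for i, sub in enumerate(subsets):
            if not sub:
                corrs[i] = 1.0
                continue
            reduced = score(sig.subset(set(sub)), matrix).scores.to_numpy()
            corrs[i] = _corr(reduced, full, correlation)
        results.append(
            MissingnessResult(
                k=k, correlations=corrs, subsets=subsets, seed=seed,
                correlation_type=correlation,
            )
        )
    return results


def summarize_missingness(results: list[MissingnessResult]) -> pd.DataFrame:
    """One row per k: n, mean, median, 5th and 95th percentile of correlations."""
    if not results:
        raise ValueError("no missingness results to summarize")
    rows = []
    for r in results:
        if r.n_combinations == 0:
            raise ValueError(f"empty correlation vector at k={r.k}")
        rows.append(
            {
                "k": r.k,
                "n_combinations": r.n_combinations,
                "mean_corr": r.mean_corr,
                "median_corr": r.median_corr,
                "q05": float(np.quantile(r.correlations, 0.05)),
                "q95": float(np.quantile(r.correlations, 0.95)),
            }
        )
    return pd.DataFrame(rows)


def score_with_dropout(
    sig: SignatureModel, matrix: ExpressionMatrix, dropped: set[str]
) -> ScoreVector:
    """Score after removing specific genes (the single-subset primitive)."""
    return score(sig.subset(dropped), matrix) if dropped else score(sig, matrix)
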