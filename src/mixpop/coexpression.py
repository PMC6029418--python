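"""Per-sub-population co-expression screen with Bonferroni control.

Within each expression sub-population, every non-index gene is correlated
(Pearson) with the index gene across that sub-population's patients. A
gene is significant when its two-sided p-value beats the Bonferroni
gene-level threshold alpha_global / n_genes_tested. The three significant
gene sets are summarised as the seven regions of a three-way Venn
partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .assignment import LABELS
from .cohort import Cohort

logger = logging.getLogger(__name__)


@dataclass
class CorrelationRecord:
    gene: str
    subpopulation: str
    r: float
    p: float
    significant: bool


@dataclass
class VennPartition:
    """Counts of the seven non-empty regions of three sets."""

    low_only: int
    intermediate_only: int
    high_only: int
    low_intermediate: int
    low_high: int
    intermediate_high: int
    all_three: int

    @property
    def totals(self) -> dict:
        return {
            "low": self.low_only + self.low_intermediate + self.low_high + self.all_three,
            "intermediate": self.intermediate_only
            + self.low_intermediate
            + self.intermediate_high
            + self.all_three,
            "high": self.high_only + self.low_high + self.intermediate_high + self.all_three,
        }


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided t-test p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman_r(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, _ = stats.spearmanr(x, y)
    # p from the same t transform as the Pearson screen, for consistency
    n = x.size
    rho = float(np.clip(rho, -1.0, 1.0))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return rho, float(p)


def bonferroni_threshold(alpha_global: float, n_tests: int) -> float:
    """Per-test significance level alpha_global / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    if not 0 < alpha_global <= 1:
        raise ValueError("alpha_global must lie in (0, 1]")
    return alpha_global / n_tests


def _pearson_rows(block: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Pearson r and two-sided p of each row of ``block`` vs y."""
    n = y.size
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    bc = block - block.mean(axis=1, keepdims=True)
    sb = np.sqrt((bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (bc @ yc) / (sb * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(r) == 1.0] = 0.0
    p[~np.isfinite(r)] = np.nan
    return r, p


def screen(
    cohort: Cohort,
    labels,
    alpha_global: float = 0.01,
    alpha_gene: float | None = None,
) -> dict:
    """Correlate every non-index gene with the index gene per sub-population.

    ``labels`` is the per-patient assignment (aligned to the expression
    matrix's patient order); unassigned patients take part in no screen.
    The gene-level threshold is Bonferroni-derived from the number of
    genes actually tested unless ``alpha_gene`` overrides it. Sub-
    populations with fewer than 3 patients are skipped with a warning.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.size != cohort.expression.n_patients:
        raise ValueError("labels must align with expression matrix patients")
    idx = cohort.expression.gene_ids.index(cohort.index_gene)
    others = [g for g in range(cohort.expression.n_genes) if g != idx]
    n_tests = len(others)
    if n_tests == 0:
        raise ValueError("no genes to test besides the index gene")
    threshold = (
        alpha_gene if alpha_gene is not None else bonferroni_threshold(alpha_global, n_tests)
    )

    values = cohort.expression.values
    results: dict[str, list[CorrelationRecord]] = {}
    for name in LABELS:
        mask = labels == name
        if mask.sum() < 3:
            logger.warning(
                "subpopulation %s has %d patients (<3); screen skipped", name, mask.sum()
            )
            continue
        y = values[idx, mask]
        if np.std(y) == 0:
            logger.warning("index gene constant in subpopulation %s; screen skipped", name)
            continue
        block = values[np.array(others)][:, mask]
        r, p = _pearson_rows(block, y)
        recs = []
        for row, gi in enumerate(others):
            gene = cohort.expression.gene_ids[gi]
            sig = bool(np.isfinite(p[row]) and p[row] < threshold)
            recs.append(
                CorrelationRecord(
                    gene=gene,
                    subpopulation=name,
                    r=float(r[row]),
                    p=float(p[row]),
                    significant=sig,
                )
            )
        results[name] = recs
    return results


def significant_sets(results: dict) -> dict:
    return {
        name: {rec.gene for rec in recs if rec.significant}
        for name, recs in results.items()
    }


def venn_partition(low: set, intermediate: set, high: set) -> VennPartition:
    """Exact region counts of the three-way Venn diagram."""
    low, intermediate, high = set(low), set(intermediate), set(high)
    triple = low & intermediate & high
    return VennPartition(
        low_only=len(low - intermediate - high),
        intermediate_only=len(intermediate - low - high),
        high_only=len(high - low - intermediate),
        low_intermediate=len((low & intermediate) - triple),
        low_high=len((low & high) - triple),
        intermediate_high=len((intermediate & high) - triple),
        all_three=len(triple),
    )
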