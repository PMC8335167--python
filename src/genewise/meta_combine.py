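"""Fisher's-method combination of the two gene tests and the selection rules.

Per gene, the two method p-values p_A and p_B are combined by Fisher's
statistic x^2 = -2 * (ln p_A + ln p_B), referred to a chi-squared
distribution with 2k degrees of freedom (k = 2 methods, so 4 df).  Three
selection rules are applied, all with strict inequalities:

* **nominal intersection** — genes with p < alpha (default 0.05) in *both*
  methods; the intersection size n is the divisor of the next rule;
* **meta Bonferroni** — intersection genes with combined p < alpha / n,
  where n is recomputed from the intersection at run time;
* **stringent dual threshold** — genes below alpha / n_tested in both
  methods, with n_tested the tested-gene count of the set-based method.

Gene-test p-values flagged as upper bounds (zero Monte-Carlo exceedances)
are combined at their bound value 1/N and the combined result inherits the
bound flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats

from .gene_tests import GeneTestResult

__all__ = [
    "MetaGeneResult",
    "SelectionThresholds",
    "fisher_combine",
    "intersect_nominal",
    "bonferroni_threshold",
    "select_meta_significant",
    "stringent_intersect",
    "meta_analyse",
]


@dataclass
class MetaGeneResult:
    """One gene's pair of method p-values and their Fisher combination."""

    gene: str
    p_a: float
    p_b: float
    fisher_stat: float
    df: int
    meta_p: float
    in_intersection: bool = False
    passes_meta_bonferroni: bool = False
    passes_stringent: bool = False
    is_bound: bool = False


@dataclass
class SelectionThresholds:
    """Significance levels for the three selection rules.

    ``n_shared`` (meta-Bonferroni divisor) and ``n_tested_b`` (stringent
    divisor) are filled in at run time from the data being analysed.
    """

    nominal_alpha: float = 0.05
    meta_alpha: float = 0.05
    stringent_alpha: float = 0.05
    n_shared: int | None = None
    n_tested_b: int | None = None

    def __post_init__(self) -> None:
        for a in (self.nominal_alpha, self.meta_alpha, self.stringent_alpha):
            if not (0.0 < a < 1.0):
                raise ValueError(f"alpha must be in (0, 1), got {a}")


def fisher_combine(pvec: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's combined probability test.

    Returns ``(stat, df, meta_p)`` with stat = -2 * sum(ln p_i), df = 2k and
    meta_p the upper chi-squared tail of stat at df degrees of freedom.
    For a single p-value the combination is the identity (the 2-df tail of
    -2 ln p is exactly p).
    """
    if len(pvec) == 0:
        raise ValueError("pvec must be non-empty")
    for p in pvec:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-values must lie in (0, 1], got {p}")
    stat = -2.0 * sum(math.log(p) for p in pvec)
    df = 2 * len(pvec)
    return stat, df, float(stats.chi2.sf(stat, df=df))


def _p_map(results: Sequence[GeneTestResult] | Mapping[str, float]) -> dict[str, float]:
    if isinstance(results, Mapping):
        return dict(results)
    return {r.gene: r.empirical_p for r in results}


def _bound_map(results) -> dict[str, bool]:
    if isinstance(results, Mapping):
        return {g: False for g in results}
    return {r.gene: r.is_upper_bound for r in results}


def intersect_nominal(results_a, results_b, alpha: float = 0.05) -> tuple[list[str], int]:
    """Genes significant at ``p < alpha`` in both methods, sorted by name."""
    pa, pb = _p_map(results_a), _p_map(results_b)
    shared = sorted(g for g in pa.keys() & pb.keys() if pa[g] < alpha and pb[g] < alpha)
    return shared, len(shared)


def bonferroni_threshold(alpha: float, n: int) -> float:
    if n < 1:
        raise ValueError("n must be >= 1")
    return alpha / n


def select_meta_significant(meta_results: Sequence[MetaGeneResult],
                            threshold: float) -> list[MetaGeneResult]:
    """Rows with combined p strictly below ``threshold``, ascending by meta p."""
    kept = [r for r in meta_results if r.meta_p < threshold]
    return sorted(kept, key=lambda r: (r.meta_p, r.gene))


def stringent_intersect(results_a, results_b, alpha: float = 0.05,
                        n_tested_b: int = 1) -> list[str]:
    """Genes below the per-method Bonferroni threshold alpha/n in both methods."""
    if n_tested_b < 1:
        raise ValueError("n_tested_b must be >= 1")
    thr = bonferroni_threshold(alpha, n_tested_b)
    pa, pb = _p_map(results_a), _p_map(results_b)
    return sorted(g for g in pa.keys() & pb.keys() if pa[g] < thr and pb[g] < thr)


def meta_analyse(results_a, results_b,
                 thresholds: SelectionThresholds | None = None) -> list[MetaGeneResult]:
    """Full phase-II analysis on the genes tested by both methods.

    Computes the nominal intersection, Fisher-combines every intersection
    gene, recomputes the meta-Bonferroni divisor from the intersection size,
    and applies the stringent dual-threshold rule.  Returns one row per
    intersection gene, sorted ascending by combined p.
    """
    if thresholds is None:
        thresholds = SelectionThresholds()
    pa, pb = _p_map(results_a), _p_map(results_b)
    ba, bb = _bound_map(results_a), _bound_map(results_b)

    shared, n_shared = intersect_nominal(results_a, results_b, thresholds.nominal_alpha)
    thresholds.n_shared = n_shared
    if thresholds.n_tested_b is None:
        thresholds.n_tested_b = len(pb)
    meta_thr = bonferroni_threshold(thresholds.meta_alpha, max(n_shared, 1))
    stringent = set(stringent_intersect(results_a, results_b,
                                        thresholds.stringent_alpha, thresholds.n_tested_b))

    rows: list[MetaGeneResult] = []
    for g in shared:
        stat, df, meta_p = fisher_combine([pa[g], pb[g]])
        rows.append(MetaGeneResult(
            gene=g, p_a=pa[g], p_b=pb[g], fisher_stat=stat, df=df, meta_p=meta_p,
            in_intersection=True,
            passes_meta_bonferroni=meta_p < meta_thr,
            passes_stringent=g in stringent,
            is_bound=ba.get(g, False) or bb.get(g, False),
        ))
    return sorted(rows, key=lambda r: (r.meta_p, r.gene))
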