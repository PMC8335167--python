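"""Hypergeometric over-representation analysis of a gene list.

For a pathway with S genes inside the reference universe of N genes, and a
target list of m genes of which J fall in the pathway, the enrichment
p-value is a hypergeometric tail.  Two tail conventions are exposed:

* ``at_least`` — P(X >= J), the standard over-representation p-value
  (the default);
* ``greater_than`` — P(X > J) = 1 - sum_{i<=J} C(S,i) C(N-S, m-i) / C(N,m),
  i.e. the strictly-greater tail, available for exact compatibility with
  tools that print the formula that way.

Pathways are size-filtered *after* intersecting their membership with the
universe (default 20-300 in-universe genes), and pathways with p < alpha
(default 0.05) form the risk subset.  No multiple-testing correction is
applied to pathway p-values.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import hypergeom

from .io_formats import GeneSetCollection

__all__ = ["Tail", "EnrichmentConfig", "PathwayResult",
           "hypergeom_tail", "filter_pathways", "run_ora"]


class Tail(str, enum.Enum):
    AT_LEAST = "at_least"          # P(X >= J)
    GREATER_THAN = "greater_than"  # P(X > J)


@dataclass
class EnrichmentConfig:
    min_size: int = 20
    max_size: int = 300
    alpha: float = 0.05
    tail: Tail = Tail.AT_LEAST

    def __post_init__(self) -> None:
        self.tail = Tail(self.tail)
        if self.min_size > self.max_size:
            raise ValueError("min_size must be <= max_size")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PathwayResult:
    pathway_id: str
    name: str
    S: int                 # pathway genes within the universe
    J: int                 # overlap with the target list
    overlap_genes: list[str]
    p: float


def hypergeom_tail(N: int, S: int, m: int, J,
                   tail: Tail | str = Tail.AT_LEAST):
    """Hypergeometric tail probability for an overlap of J.

    X ~ Hypergeom(population N, successes S, draws m).  ``at_least`` returns
    P(X >= J); ``greater_than`` returns P(X > J).  Exact for any practical
    N (scipy evaluates the pmf in log-gamma space).  ``J`` may be a scalar
    or an array of overlap counts (an array is returned in the latter case).
    """
    import numpy as np

    tail = Tail(tail)
    if not (0 <= S <= N and 0 <= m <= N):
        raise ValueError("require 0 <= S <= N and 0 <= m <= N")
    j_arr = np.asarray(J)
    if np.any((j_arr < 0) | (j_arr > min(S, m))):
        raise ValueError("require 0 <= J <= min(S, m)")
    k = j_arr if tail is Tail.GREATER_THAN else j_arr - 1
    out = np.clip(hypergeom.sf(k, N, S, m), 0.0, 1.0)
    return out if j_arr.ndim else float(out)


def filter_pathways(collection: GeneSetCollection, universe: Sequence[str],
                    config: EnrichmentConfig | None = None) -> GeneSetCollection:
    """Keep pathways whose in-universe membership size lies in [min, max].

    Membership lists are first intersected with the universe (the statistic
    is only coherent on genes that could have been selected); the returned
    collection carries the in-universe members.
    """
    if config is None:
        config = EnrichmentConfig()
    uni = set(universe)
    kept: list[tuple[str, str, list[str]]] = []
    for set_id, name, members in collection:
        in_uni = [g for g in members if g in uni]
        if config.min_size <= len(in_uni) <= config.max_size:
            kept.append((set_id, name, in_uni))
    return GeneSetCollection(kept)


def run_ora(targets: Sequence[str], universe: Sequence[str],
            collection: GeneSetCollection,
            config: EnrichmentConfig | None = None
            ) -> tuple[list[PathwayResult], list[PathwayResult]]:
    """Over-representation analysis of ``targets`` against ``collection``.

    Returns ``(all_results, risk_subset)``; both sorted ascending by p,
    the risk subset restricted to p < alpha.  Target genes outside the
    universe are dropped with a warning; an empty effective target list is
    degenerate (every p is the trivial tail) and also warned about.
    """
    if config is None:
        config = EnrichmentConfig()
    uni_list = list(dict.fromkeys(universe))
    if not uni_list:
        raise ValueError("reference universe is empty")
    uni = set(uni_list)
    stray = [g for g in dict.fromkeys(targets) if g not in uni]
    if stray:
        warnings.warn(f"{len(stray)} target gene(s) outside the universe dropped: "
                      f"{stray[:5]}", stacklevel=2)
    eff_targets = [g for g in dict.fromkeys(targets) if g in uni]
    if not eff_targets:
        warnings.warn("empty effective target list: enrichment is degenerate",
                      stacklevel=2)
    m = len(eff_targets)
    N = len(uni_list)
    tset = set(eff_targets)

    results: list[PathwayResult] = []
    for set_id, name, members in filter_pathways(collection, uni_list, config):
        overlap = [g for g in members if g in tset]
        results.append(PathwayResult(
            pathway_id=set_id, name=name, S=len(members), J=len(overlap),
            overlap_genes=overlap,
            p=hypergeom_tail(N, len(members), m, len(overlap), config.tail),
        ))
    results.sort(key=lambda r: (r.p, r.pathway_id))
    risk = [r for r in results if r.p < config.alpha]
    return results, risk
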