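"""Top-quantile extraction and per-protein occurrence enrichment.

Given the list of a focal pathway's scores against the rest of the genome,
the top quantile (default 1%) is extracted and each focal protein's number
of appearances among those top pairs is compared with the count expected if
appearances were spread evenly over the K focal proteins (E = T/K for T top
pairs). The deviation is summarized as a signed fold change — O/E when
over-represented, -(E/O) when under — and tested per protein with a 1-df
chi-squared goodness-of-fit of (O, T-O) against (E, T-E).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .erc import ERCMatrix
from .io import PairScoreRecord

__all__ = [
    "TopQuantileSet",
    "EnrichmentResult",
    "focal_pairs",
    "top_quantile",
    "occurrence_enrichment",
    "signed_fold_change",
]


def focal_pairs(matrix: ERCMatrix, focal) -> list[PairScoreRecord]:
    """All scored pairs with at least one member in ``focal`` (the
    pathway-vs-genome score list that top-quantile analysis starts from)."""
    focal_set = {g for g in focal if g in matrix}
    if not focal_set:
        raise ValueError("no focal genes present in the matrix")
    fidx = matrix.index_of(sorted(focal_set))
    mask = np.zeros(matrix.n_genes, dtype=bool)
    mask[fidx] = True
    records = []
    S = matrix.fterc
    genes = matrix.genes
    for i in range(matrix.n_genes):
        row = S[i]
        for j in range(i + 1, matrix.n_genes):
            if (mask[i] or mask[j]) and not np.isnan(row[j]):
                records.append(
                    PairScoreRecord(gene_a=genes[i], gene_b=genes[j], fterc=float(row[j]))
                )
    return records


@dataclass
class TopQuantileSet:
    """The top fraction q of a score list, with deterministic tie-breaking."""

    q: float
    cutoff: float
    records: list[PairScoreRecord]
    n_total: int

    @property
    def T(self) -> int:
        return len(self.records)


def top_quantile(pairs: list[PairScoreRecord], q: float = 0.01) -> TopQuantileSet:
    """Select the top ceil(q*N) records by score, descending.

    Ties at the cutoff are broken by lexicographic pair id so the selection
    is deterministic.
    """
    if not pairs:
        raise ValueError("empty pair list")
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    ordered = sorted(pairs, key=lambda r: (-r.fterc, r.gene_a, r.gene_b))
    T = math.ceil(q * len(ordered))
    top = ordered[:T]
    return TopQuantileSet(q=q, cutoff=top[-1].fterc, records=top, n_total=len(ordered))


def signed_fold_change(observed: float, expected: float) -> float:
    """Fold change signed by direction: O/E if O >= E, else -(E/O).

    Never lands in (-1, 1); O = E gives +1. O = 0 yields -inf (flagged by
    the caller).
    """
    if expected <= 0:
        raise ValueError("expected count must be positive")
    if observed >= expected:
        return observed / expected
    if observed == 0:
        return float("-inf")
    return -(expected / observed)


@dataclass
class EnrichmentResult:
    """Per-focal-protein occurrence enrichment in a top-quantile set.

    ``table`` columns: protein, observed, expected, fold, chi2, p,
    direction (over/under/ns), zero_flag for proteins never seen in the top
    set (fold is the -inf sentinel; excluded from plots).
    """

    table: pd.DataFrame
    T: int
    K: int

    @property
    def expected(self) -> float:
        return self.T / self.K

    def for_protein(self, protein: str) -> pd.Series:
        return self.table.set_index("protein").loc[protein]


def occurrence_enrichment(
    top: TopQuantileSet,
    focal,
    alpha: float = 0.05,
    require_focal: bool = True,
    double_count: bool = True,
) -> EnrichmentResult:
    """Count each focal protein's appearances among the top pairs.

    With ``double_count`` (default) a pair whose two members are both focal
    increments both proteins' observed counts, while the expected count per
    protein remains E = T/K — so the observed column can sum to more than T.
    Chi-squared is per protein, one-vs-rest, no continuity or
    multiple-testing correction; ``direction`` is assigned at raw p < alpha.
    """
    focal_list = list(dict.fromkeys(focal))
    K = len(focal_list)
    if K < 2:
        raise ValueError("need at least 2 focal proteins")
    focal_set = set(focal_list)
    if require_focal:
        bad = [r for r in top.records if not ({r.gene_a, r.gene_b} & focal_set)]
        if bad:
            raise ValueError(
                f"{len(bad)} top pair(s) contain no focal gene; build the "
                "top set from focal_pairs() or pass require_focal=False"
            )

    O = dict.fromkeys(focal_list, 0)
    for rec in top.records:
        hits = [g for g in (rec.gene_a, rec.gene_b) if g in focal_set]
        if not double_count:
            hits = hits[:1]
        for g in hits:
            O[g] += 1

    T = top.T
    E = T / K
    rows = []
    for g in focal_list:
        o = O[g]
        fold = signed_fold_change(o, E)
        chi2 = (o - E) ** 2 / E + ((T - o) - (T - E)) ** 2 / (T - E)
        p = float(stats.chi2.sf(chi2, df=1))
        if p < alpha:
            direction = "over" if o > E else ("under" if o < E else "ns")
        else:
            direction = "ns"
        rows.append(
            {
                "protein": g,
                "observed": o,
                "expected": E,
                "fold": fold,
                "chi2": chi2,
                "p": p,
                "direction": direction,
                "zero_flag": o == 0,
            }
        )
    return EnrichmentResult(table=pd.DataFrame(rows), T=T, K=K)
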