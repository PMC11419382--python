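"""Protein-complex coevolution benchmark.

Real complexes (a CORUM-like catalogue, size >= 3) are scored by their mean
pairwise integrated ERC and compared against representation-matched random
complexes: simulated sets whose sizes follow the real size distribution and
whose genes are drawn with probability proportional to each gene's frequency
of complex membership, so promiscuous subunits appear in the null as often
as in the catalogue. Empirical p-values are computed within same-size null
strata (pair count, and hence the variance of a mean pairwise score, depends
on size), corrected with Benjamini-Hochberg, and the discriminative power of
a scoring scheme is summarized by a precision-recall curve normalized to the
precision at 100% recall (the real-complex prevalence), i.e. fold change in
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from sklearn.metrics import precision_recall_curve
from statsmodels.stats.multitest import multipletests

from .erc import ERCMatrix
from .io import GeneSet, GeneSetCollection
from .permutation import group_mean_erc

__all__ = [
    "ComplexResult",
    "PRCurve",
    "simulate_null_complexes",
    "complex_empirical_p",
    "bh_fdr",
    "precision_recall_foldchange",
]


def simulate_null_complexes(
    real_complexes: GeneSetCollection,
    n_sim: int = 100_000,
    seed: int = 0,
    weighted: bool = True,
) -> list[list[str]]:
    """Representation-matched random complexes.

    Each simulated complex draws its size from the real complexes' empirical
    size distribution and samples that many distinct genes with probability
    proportional to membership frequency across the catalogue (uniform when
    ``weighted=False``). Weighted sampling without replacement uses the
    Gumbel top-k trick. Deterministic given ``seed``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    counts: dict[str, int] = {}
    sizes = []
    for gs in real_complexes:
        sizes.append(gs.size)
        for g in gs.members:
            counts[g] = counts.get(g, 0) + 1
    if not sizes:
        raise ValueError("no real complexes supplied")
    genes = np.array(list(counts))
    weights = np.array([counts[g] for g in genes], dtype=float)
    if not weighted:
        weights = np.ones_like(weights)
    logw = np.log(weights)

    rng = np.random.default_rng(seed)
    sim_sizes = rng.choice(np.array(sizes), size=n_sim, replace=True)
    out: list[list[str]] = []
    for k in sim_sizes:
        keys = logw + rng.gumbel(size=genes.size)
        idx = np.argpartition(-keys, int(k) - 1)[: int(k)]
        out.append(list(genes[idx]))
    return out


@dataclass
class ComplexResult:
    name: str
    size: int
    mean_erc: float
    n_pairs: int
    p_empirical: float
    p_is_floor: bool
    n_null: int
    q: float = float("nan")
    significant: bool = False

    @property
    def p_report(self) -> str:
        if self.p_is_floor:
            return f"<{1.0 / self.n_null:g}"
        return f"{self.p_empirical:g}"


def _null_strata_means(
    matrix: ERCMatrix, null_sets: list[list[str]]
) -> dict[int, np.ndarray]:
    """Null means keyed by *effective* size: the number of member genes
    actually present in the matrix (ortholog missingness shrinks sets)."""
    strata: dict[int, list[float]] = {}
    for s in null_sets:
        try:
            mean, _ = group_mean_erc(matrix, s)
        except ValueError:
            continue  # null set with no scored pairs contributes nothing
        present = sum(g in matrix for g in dict.fromkeys(s))
        strata.setdefault(present, []).append(mean)
    return {k: np.asarray(v) for k, v in strata.items()}


def complex_empirical_p(
    matrix: ERCMatrix,
    complexes: GeneSetCollection,
    null_sets: list[list[str]],
    min_size: int = 3,
    alpha: float = 0.05,
) -> list[ComplexResult]:
    """Empirical p per complex against the size-matched null stratum.

    p = proportion of same-size null complexes whose mean integrated ERC is
    >= the observed mean ("equivalent or more extreme"). Complexes smaller
    than ``min_size`` or with no scored pairs are excluded with a warning.
    BH q-values and FDR-``alpha`` significance flags are filled in.
    """
    strata = _null_strata_means(matrix, null_sets)
    results: list[ComplexResult] = []
    for gs in complexes:
        if gs.size < min_size:
            continue
        try:
            mean, n_pairs = group_mean_erc(matrix, gs.members)
        except ValueError:
            warnings.warn(f"complex '{gs.name}' has no scored pairs; excluded")
            continue
        present = len([g for g in dict.fromkeys(gs.members) if g in matrix])
        null = strata.get(present)
        if null is None or null.size == 0:
            warnings.warn(
                f"complex '{gs.name}': no size-{present} null stratum; excluded"
            )
            continue
        count = int(np.sum(null >= mean))
        results.append(
            ComplexResult(
                name=gs.name,
                size=gs.size,
                mean_erc=mean,
                n_pairs=n_pairs,
                p_empirical=count / null.size,
                p_is_floor=count == 0,
                n_null=int(null.size),
            )
        )
    if results:
        qvals, n_sig = bh_fdr([r.p_empirical for r in results], alpha=alpha)
        for r, q in zip(results, qvals):
            r.q = float(q)
            r.significant = bool(q <= alpha)
    return results


def bh_fdr(pvals, alpha: float = 0.05) -> tuple[np.ndarray, int]:
    """Benjamini-Hochberg step-up q-values and the count significant at alpha."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, int(reject.sum())


@dataclass
class PRCurve:
    """Precision-recall curve with precision normalized to its value at
    100% recall (the prevalence of real complexes in the ranked list)."""

    recall: np.ndarray
    precision: np.ndarray
    base_precision: float
    fold_change: np.ndarray = field(init=False)

    def __post_init__(self):
        self.fold_change = self.precision / self.base_precision

    def fold_at_recall(self, r: float) -> float:
        """Fold-change precision at the first threshold reaching recall >= r.

        At r = 1 this is the call-everything endpoint, where precision is
        the prevalence and fold change is 1 by construction.
        """
        if r >= 1.0:
            return float(self.fold_change[-1])
        i = int(np.searchsorted(self.recall, r, side="left"))
        if i >= self.recall.size:
            raise ValueError(f"recall {r} never reached")
        return float(self.fold_change[i])


def precision_recall_foldchange(
    real_scores, null_scores
) -> PRCurve:
    """PR curve distinguishing real from simulated complexes by mean score.

    Real complexes are the positive class; precision at full recall equals
    the prevalence n_real / (n_real + n_null), so fold change is 1 there by
    construction.
    """
    real = np.asarray(list(real_scores), dtype=float)
    null = np.asarray(list(null_scores), dtype=float)
    if real.size == 0 or null.size == 0:
        raise ValueError("both real and null score lists must be non-empty")
    y = np.concatenate([np.ones(real.size), np.zeros(null.size)])
    scores = np.concatenate([real, null])
    precision, recall, _ = precision_recall_curve(y, scores)
    # sklearn appends the (precision=1, recall=0) endpoint; drop it and order
    # by increasing recall for a conventional curve.
    precision, recall = precision[:-1][::-1], recall[:-1][::-1]
    base = real.size / (real.size + null.size)
    # call-everything endpoint: recall 1 at prevalence precision, so the
    # fold-change normalization point is always on the curve
    recall = np.append(recall, 1.0)
    precision = np.append(precision, base)
    return PRCurve(recall=recall, precision=precision, base_precision=base)
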