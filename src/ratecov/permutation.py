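"""Permutation tests for elevated mean ERC within and between gene sets.

The one-group test compares the observed mean pairwise score of a gene set
against the means of ``n_perm`` random sets of the same size drawn from the
whole scored universe; the empirical p is the plain proportion of null means
at least as large as the observed one, so the smallest nonzero reportable
value is 1/n_perm (1e-5 at the conventional 100,000 permutations). A zero
count is reported as the floor "<1/n_perm" rather than p = 0 being taken
literally.

The two-group test holds one set fixed and replaces the other with random
genes, in both directions, and conservatively reports the larger of the two
one-sided p-values. Replacement draws come from the full universe including
the held set's members (self-pairs are excluded from means).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .erc import ERCMatrix

__all__ = [
    "PermutationResult",
    "group_mean_erc",
    "permute_within",
    "permute_between",
]

DEFAULT_N_PERM = 100_000
_CHUNK_CELLS = 4_000_000  # keep sampling buffers ~tens of MB


def group_mean_erc(matrix: ERCMatrix, genes) -> tuple[float, int]:
    """Mean over scored within-set pairs and the number of such pairs.

    Absent pairs are excluded from both numerator and denominator.
    """
    present = [g for g in dict.fromkeys(genes) if g in matrix]
    if len(present) < 2:
        raise ValueError(
            f"need >= 2 genes present in the matrix, got {len(present)}"
        )
    idx = matrix.index_of(present)
    sub = matrix.fterc[np.ix_(idx, idx)]
    iu, ju = np.triu_indices(len(idx), k=1)
    vals = sub[iu, ju]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no scored pairs within the gene set")
    return float(vals.mean()), int(vals.size)


@dataclass
class PermutationResult:
    observed_mean: float
    n_pairs_observed: int
    null_mean: float
    null_sd: float
    p_empirical: float
    p_is_floor: bool
    n_perm: int
    seed: int
    sub_results: tuple["PermutationResult", ...] = field(default=(), repr=False)

    @property
    def sd_distance(self) -> float:
        """How many null SDs the observed mean sits above the null mean."""
        if self.null_sd == 0:
            return float("nan")
        return (self.observed_mean - self.null_mean) / self.null_sd

    @property
    def p_report(self) -> str:
        """p formatted with the floor convention ("<1/n_perm" when 0 hits)."""
        if self.p_is_floor:
            return f"<{1.0 / self.n_perm:g}"
        return f"{self.p_empirical:g}"

    def to_dict(self) -> dict:
        return {
            "observed_mean": self.observed_mean,
            "n_pairs_observed": self.n_pairs_observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "p_empirical": self.p_empirical,
            "p_report": self.p_report,
            "p_is_floor": self.p_is_floor,
            "sd_distance": self.sd_distance,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def _sample_distinct(
    rng: np.random.Generator, n_draws: int, universe_size: int, m: int
) -> np.ndarray:
    """(n_draws, m) matrix of distinct uniform indices per row.

    Random-key argpartition: the m smallest of U i.i.d. uniforms index a
    uniformly random m-subset.
    """
    keys = rng.random((n_draws, universe_size))
    return np.argpartition(keys, m - 1, axis=1)[:, :m]


def _null_means_within(
    matrix: ERCMatrix,
    universe_idx: np.ndarray,
    m: int,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    iu, ju = np.triu_indices(m, k=1)
    S = matrix.fterc
    means = np.empty(n_perm)
    chunk = max(1, _CHUNK_CELLS // max(universe_idx.size, 1))
    done = 0
    while done < n_perm:
        c = min(chunk, n_perm - done)
        picks = universe_idx[_sample_distinct(rng, c, universe_idx.size, m)]
        vals = S[picks[:, iu], picks[:, ju]]  # (c, n_pairs)
        with np.errstate(invalid="ignore"):
            means[done : done + c] = np.nanmean(vals, axis=1)
        done += c
    return means


def permute_within(
    matrix: ERCMatrix,
    genes,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    exclude_group: bool = False,
) -> PermutationResult:
    """One-group permutation test of elevated mean within-set ERC.

    The null universe is every gene with at least one scored pair; by
    default it includes the tested genes themselves (``exclude_group=True``
    removes them). Deterministic given ``seed``.
    """
    observed, n_pairs = group_mean_erc(matrix, genes)
    present = [g for g in dict.fromkeys(genes) if g in matrix]
    m = len(present)

    universe_mask = matrix.scored_gene_mask()
    if exclude_group:
        universe_mask[matrix.index_of(present)] = False
    universe_idx = np.flatnonzero(universe_mask)
    if universe_idx.size < m:
        raise ValueError(
            f"universe ({universe_idx.size} genes) smaller than group ({m})"
        )

    rng = np.random.default_rng(seed)
    null = _null_means_within(matrix, universe_idx, m, n_perm, rng)
    finite = null[~np.isnan(null)]
    count = int(np.sum(finite >= observed))
    return PermutationResult(
        observed_mean=observed,
        n_pairs_observed=n_pairs,
        null_mean=float(finite.mean()) if finite.size else float("nan"),
        null_sd=float(finite.std(ddof=1)) if finite.size > 1 else float("nan"),
        p_empirical=count / n_perm,
        p_is_floor=count == 0,
        n_perm=n_perm,
        seed=seed,
    )


def _cross_mean(S: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> float:
    sub = S[np.ix_(ia, ib)].astype(float, copy=True)
    same = ia[:, None] == ib[None, :]
    sub[same] = np.nan
    vals = sub[~np.isnan(sub)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def _null_means_between(
    S: np.ndarray,
    held_idx: np.ndarray,
    m_replace: int,
    universe_idx: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    means = np.empty(n_perm)
    chunk = max(1, _CHUNK_CELLS // max(universe_idx.size, 1))
    done = 0
    held_col = held_idx[:, None, None]  # for self-pair masking
    while done < n_perm:
        c = min(chunk, n_perm - done)
        picks = universe_idx[_sample_distinct(rng, c, universe_idx.size, m_replace)]
        # vals[h, k, j] = S[held_h, picks[k, j]]
        vals = S[held_idx][:, picks]  # (|held|, c, m_replace)
        vals = np.where(held_col == picks[None, :, :], np.nan, vals)
        with np.errstate(invalid="ignore"):
            means[done : done + c] = np.nanmean(vals, axis=(0, 2))
        done += c
    return means


def permute_between(
    matrix: ERCMatrix,
    set_a,
    set_b,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> PermutationResult:
    """Two-group permutation test on the mean of cross-set pair scores.

    Runs both replacement schemes (hold A / randomize B and hold B /
    randomize A) and returns the result with the HIGHER p; both one-sided
    sub-results are kept in ``sub_results``.
    """
    a = [g for g in dict.fromkeys(set_a) if g in matrix]
    b = [g for g in dict.fromkeys(set_b) if g in matrix]
    if not a or not b:
        raise ValueError("both sets need at least one gene present in the matrix")
    if set(a) == set(b):
        raise ValueError("sets are identical; cross-set ERC is undefined")

    S = matrix.fterc
    ia, ib = matrix.index_of(a), matrix.index_of(b)
    observed = _cross_mean(S, ia, ib)
    if np.isnan(observed):
        raise ValueError("no scored cross-set pairs")
    n_pairs = int(np.sum(~np.isnan(S[np.ix_(ia, ib)])) - np.sum(ia[:, None] == ib[None, :]))

    universe_idx = np.flatnonzero(matrix.scored_gene_mask())
    rng = np.random.default_rng(seed)
    subs = []
    for held, m_replace in ((ia, len(b)), (ib, len(a))):
        if universe_idx.size < m_replace:
            raise ValueError("universe smaller than replacement set")
        null = _null_means_between(S, held, m_replace, universe_idx, n_perm, rng)
        finite = null[~np.isnan(null)]
        count = int(np.sum(finite >= observed))
        subs.append(
            PermutationResult(
                observed_mean=observed,
                n_pairs_observed=n_pairs,
                null_mean=float(finite.mean()) if finite.size else float("nan"),
                null_sd=float(finite.std(ddof=1)) if finite.size > 1 else float("nan"),
                p_empirical=count / n_perm,
                p_is_floor=count == 0,
                n_perm=n_perm,
                seed=seed,
            )
        )
    worst = max(subs, key=lambda r: r.p_empirical)
    return PermutationResult(
        observed_mean=worst.observed_mean,
        n_pairs_observed=worst.n_pairs_observed,
        null_mean=worst.null_mean,
        null_sd=worst.null_sd,
        p_empirical=worst.p_empirical,
        p_is_floor=worst.p_is_floor,
        n_perm=n_perm,
        seed=seed,
        sub_results=tuple(subs),
    )
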