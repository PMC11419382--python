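"""Relative evolutionary rates (RERs) from branch-length tables.

A gene's branch lengths confound three things: the branch's genome-wide
time/rate profile, the gene's overall rate, and the branch-specific rate
deviation that carries coevolution signal. The RER isolates the third by a
centered log-ratio against the genome-wide master profile:

    raw[g, b] = ln((L[g, b] + eps) / (A_b + eps))
    R[g, b]   = raw[g, b] - mean over the gene's usable branches of raw[g, .]

Division by the per-branch average A_b removes the shared branch profile;
row-centering removes the gene's overall rate. The result is scale-free:
multiplying a gene's whole row by any c > 0 leaves R unchanged (exactly so
when eps = 0 and all lengths are positive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BranchLengthTable

__all__ = ["MasterProfile", "RERMatrix", "master_profile", "compute_rer"]


@dataclass
class MasterProfile:
    """Per-branch genome-wide average branch length for one clade."""

    clade_id: str
    means: pd.Series        # A_b, indexed by branch_id
    counts: pd.Series       # genes contributing per branch
    usable: pd.Series       # counts >= min_genes_per_branch

    @property
    def branches(self) -> list[str]:
        return list(self.means.index)


@dataclass
class RERMatrix:
    """Genes x branches centered log-ratio rates for one clade.

    Rows mean to zero (within 1e-10) over each gene's present usable
    branches; NaN marks missing or unusable entries.
    """

    clade_id: str
    rer: pd.DataFrame
    n_usable: pd.Series     # usable present branches per retained gene

    @property
    def genes(self) -> list[str]:
        return list(self.rer.index)

    @property
    def branches(self) -> list[str]:
        return list(self.rer.columns)


def master_profile(
    table: BranchLengthTable, min_genes_per_branch: int = 10
) -> MasterProfile:
    """Arithmetic mean branch length per branch over genes present there.

    Branches supported by fewer than ``min_genes_per_branch`` genes are
    flagged unusable (their average is too noisy to normalize against).
    """
    if table.lengths.empty:
        raise ValueError(f"empty branch table for clade '{table.clade_id}'")
    means = table.lengths.mean(axis=0, skipna=True)
    counts = table.lengths.notna().sum(axis=0)
    usable = counts >= min_genes_per_branch
    if not usable.any():
        raise ValueError(
            f"clade '{table.clade_id}': no branch has >= "
            f"{min_genes_per_branch} contributing genes"
        )
    return MasterProfile(
        clade_id=table.clade_id, means=means, counts=counts, usable=usable
    )


def compute_rer(
    table: BranchLengthTable,
    master: MasterProfile,
    epsilon: float = 1e-6,
    min_branches: int = 4,
) -> RERMatrix:
    """Centered log-ratio RERs of ``table`` against ``master``.

    ``epsilon`` (substitutions/site) is added to numerator and denominator so
    zero-length branches remain usable. Genes with fewer than
    ``min_branches`` usable present branches are dropped with a warning
    (downstream Fisher weighting needs n - 3 >= 1).
    """
    if table.clade_id != master.clade_id:
        raise ValueError(
            f"clade mismatch: table '{table.clade_id}' vs master "
            f"'{master.clade_id}'"
        )
    df = table.lengths.reindex(columns=master.branches)
    L = df.to_numpy(dtype=float)
    A = master.means.to_numpy(dtype=float)
    usable = master.usable.to_numpy(dtype=bool)

    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.log((L + epsilon) / (A[None, :] + epsilon))
    raw[:, ~usable] = np.nan

    n_usable = np.sum(~np.isnan(raw), axis=1)
    keep = n_usable >= min_branches
    if not keep.all():
        dropped = [g for g, k in zip(df.index, keep) if not k]
        warnings.warn(
            f"clade '{table.clade_id}': dropped {len(dropped)} gene(s) with "
            f"< {min_branches} usable branches: {dropped[:5]}"
        )
    raw = raw[keep]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        centered = raw - np.nanmean(raw, axis=1, keepdims=True)

    genes = df.index[keep]
    return RERMatrix(
        clade_id=table.clade_id,
        rer=pd.DataFrame(centered, index=genes, columns=master.branches),
        n_usable=pd.Series(n_usable[keep], index=genes),
    )
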