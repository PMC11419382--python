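"""Synthetic multi-clade branch-length tables with planted coevolving modules.

The generative model works on the log scale that the downstream relative
evolutionary rate (RER) transform uses, so the planted module correlation is
exact by construction. For clade c with master branch lengths A_b, gene g
receives

    L[g, b] = A_b * s_g * exp(sigma * d_g[b])

where log s_g ~ Normal(0, gene_scale_sd^2) is a gene-wide rate scalar, and
the per-branch deviation of a gene in module m with target correlation rho is

    d_g[b] = sqrt(rho) * f_m[b] + sqrt(1 - rho) * e_g[b]

with f (shared within the module, drawn fresh per clade) and e (private to
the gene) i.i.d. standard normal. Background genes have rho = 0. Centered
log-ratio RERs of two module genes then have expected Pearson correlation
rho. Each (gene, clade) row is dropped with probability ``missing_prob``,
mimicking ortholog absence from a clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BranchLengthTable, CladeTree, parse_clade_tree

__all__ = [
    "Module",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_clade_tree",
    "simulate_branch_tables",
    "default_gene_ids",
]

#: Species counts of the five clade datasets the pipeline targets
#: (mammals, non-mammal vertebrates, drosophila, yeast, nematodes).
DEFAULT_SPECIES_PER_CLADE = (62, 39, 22, 18, 17)


def default_gene_ids(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


@dataclass(frozen=True)
class Module:
    """A planted coevolving gene module with target RER correlation rho."""

    name: str
    genes: tuple[str, ...]
    rho: float

    def __post_init__(self):
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"module '{self.name}': rho must be in [0, 1)")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"module '{self.name}': duplicate genes")


@dataclass
class SimulationConfig:
    n_genes: int = 300
    species_per_clade: tuple[int, ...] = DEFAULT_SPECIES_PER_CLADE
    modules: tuple[Module, ...] = ()
    sigma: float = 0.3
    gene_scale_sd: float = 0.3
    missing_prob: float = 0.15
    branch_missing_prob: float = 0.0
    allow_overlap: bool = False
    seed: int = 0

    @property
    def n_clades(self) -> int:
        return len(self.species_per_clade)

    def __post_init__(self):
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.gene_scale_sd < 0:
            raise ValueError("gene_scale_sd must be >= 0")
        for p in (self.missing_prob, self.branch_missing_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if any(s < 3 for s in self.species_per_clade):
            raise ValueError("each clade needs >= 3 species")
        if not self.allow_overlap:
            seen: set[str] = set()
            for mod in self.modules:
                overlap = seen & set(mod.genes)
                if overlap:
                    raise ValueError(
                        f"module '{mod.name}' overlaps earlier modules: "
                        f"{sorted(overlap)}; set allow_overlap=True to permit"
                    )
                seen |= set(mod.genes)

    def gene_ids(self) -> list[str]:
        ids = default_gene_ids(self.n_genes)
        extra = [g for m in self.modules for g in m.genes if g not in set(ids)]
        if extra:
            raise ValueError(f"module genes outside gene universe: {extra[:5]}")
        return ids


@dataclass
class SimulationTruth:
    """Ground truth of a simulation: module membership and realized factors."""

    config: SimulationConfig
    module_of_gene: dict[str, str]
    rho_of_gene: dict[str, float]
    shared_factors: dict[str, dict[str, np.ndarray]] = field(repr=False, default_factory=dict)

    def expected_pair_correlation(self, gene_a: str, gene_b: str) -> float:
        """Expected RER Pearson r: rho if both in the same module, else 0."""
        ma = self.module_of_gene.get(gene_a)
        mb = self.module_of_gene.get(gene_b)
        if ma is not None and ma == mb:
            return self.rho_of_gene[gene_a]
        return 0.0


def _random_topology(labels: list[str], rng: np.random.Generator) -> str:
    """Random rooted binary topology by successive random joins; every
    non-root edge gets a length drawn from exp(Normal(log 0.05, 0.5^2))."""

    def draw_len() -> float:
        return float(np.exp(rng.normal(np.log(0.05), 0.5)))

    nodes = [f"{lab}:{draw_len():.6f}" for lab in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{draw_len():.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({nodes[0]},{nodes[1]});"


def simulate_clade_tree(
    n_species: int, seed: int, clade_id: str = "clade"
) -> CladeTree:
    """Simulate a random rooted binary species tree with branch lengths."""
    if n_species < 3:
        raise ValueError("n_species must be >= 3")
    rng = np.random.default_rng(seed)
    labels = [f"{clade_id}_s{i:03d}" for i in range(1, n_species + 1)]
    return parse_clade_tree(_random_topology(labels, rng), clade_id)


def simulate_branch_tables(
    config: SimulationConfig,
) -> tuple[list[BranchLengthTable], SimulationTruth, list[CladeTree]]:
    """Generate one branch-length table per clade plus the ground truth.

    Deterministic: every stream of randomness derives from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    n_genes = len(genes)

    module_of_gene: dict[str, str] = {}
    rho_of_gene: dict[str, float] = {g: 0.0 for g in genes}
    for mod in config.modules:
        for g in mod.genes:
            module_of_gene[g] = mod.name
            rho_of_gene[g] = mod.rho

    # gene-wide rate scalars, shared across clades
    log_s = rng.normal(0.0, config.gene_scale_sd, size=n_genes)

    trees: list[CladeTree] = []
    tables: list[BranchLengthTable] = []
    shared_factors: dict[str, dict[str, np.ndarray]] = {}

    for ci, n_species in enumerate(config.species_per_clade):
        clade_id = f"clade{ci + 1}"
        tree_seed = int(rng.integers(0, 2**31 - 1))
        tree = simulate_clade_tree(n_species, tree_seed, clade_id)
        trees.append(tree)
        master = tree.branch_lengths().to_numpy()
        n_br = len(master)

        factors = {
            mod.name: rng.standard_normal(n_br) for mod in config.modules
        }
        shared_factors[clade_id] = factors

        private = rng.standard_normal((n_genes, n_br))
        dev = np.empty((n_genes, n_br))
        for gi, g in enumerate(genes):
            rho = rho_of_gene[g]
            if rho > 0:
                f = factors[module_of_gene[g]]
                dev[gi] = np.sqrt(rho) * f + np.sqrt(1.0 - rho) * private[gi]
            else:
                dev[gi] = private[gi]

        lengths = master[None, :] * np.exp(log_s[:, None] + config.sigma * dev)

        present = rng.random(n_genes) >= config.missing_prob
        if config.branch_missing_prob > 0:
            cell_mask = rng.random((n_genes, n_br)) < config.branch_missing_prob
            lengths = np.where(cell_mask, np.nan, lengths)

        df = pd.DataFrame(lengths, index=genes, columns=tree.branch_ids)
        df = df.loc[present]
        tables.append(BranchLengthTable(clade_id=clade_id, lengths=df))

    truth = SimulationTruth(
        config=config,
        module_of_gene=module_of_gene,
        rho_of_gene=rho_of_gene,
        shared_factors=shared_factors,
    )
    return tables, truth, trees
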