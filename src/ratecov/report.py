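"""Pipeline orchestration and paper-style matrix/edge exports.

``run_pipeline`` drives simulate -> RER -> ERC -> group tests ->
enrichment -> complex benchmark from one structured config, records every
seed, and writes a manifest with SHA-256 hashes of each output so reruns
can be verified byte-for-byte. All stage randomness derives from one root
seed via named substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import benchmark as bench
from .erc import ERCMatrix, build_erc_matrix, significance_threshold
from .io import (
    GeneSetCollection,
    read_branch_table,
    read_clade_tree,
    read_gene_sets,
    write_branch_table,
    write_pair_table,
)
from .permutation import permute_between, permute_within
from .rer import compute_rer, master_profile
from .simulate import Module, SimulationConfig, simulate_branch_tables

log = logging.getLogger("ratecov")

__all__ = ["RunConfig", "run_pipeline", "export_heatmap_matrix", "export_edge_list"]


def _substream(root_seed: int, name: str) -> int:
    h = hashlib.sha256(f"{root_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    # either simulate...
    simulate: dict | None = None
    # ...or load from disk: list of {clade_id, tree, table}
    clades: list[dict] = field(default_factory=list)
    gene_sets: str | None = None
    complexes: str | None = None
    n_min: int = 5
    min_genes_per_branch: int = 10
    n_perm: int = 10_000
    n_sim: int = 10_000
    q: float = 0.01
    k_sd: float = 2.0
    group_tests: list[str] = field(default_factory=list)
    between_tests: list[list[str]] = field(default_factory=list)
    focal_set: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate_paths(self) -> None:
        missing = []
        for c in self.clades:
            for key in ("tree", "table"):
                if not Path(c[key]).exists():
                    missing.append(c[key])
        for p in (self.gene_sets, self.complexes):
            if p is not None and not Path(p).exists():
                missing.append(p)
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


def _simulation_config(spec: dict, seed: int) -> SimulationConfig:
    modules = tuple(
        Module(name=m["name"], genes=tuple(m["genes"]), rho=float(m["rho"]))
        for m in spec.get("modules", [])
    )
    kwargs = {k: v for k, v in spec.items() if k != "modules"}
    if "species_per_clade" in kwargs:
        kwargs["species_per_clade"] = tuple(kwargs["species_per_clade"])
    return SimulationConfig(modules=modules, seed=seed, **kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages in dependency order; return the manifest."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "outputs": {}}

    def record(stage: str, path: Path):
        manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
        if stage not in manifest["stages"]:
            manifest["stages"].append(stage)

    # --- stage: acquire branch tables -----------------------------------
    if config.simulate is not None:
        sim_seed = _substream(config.seed, "simulate")
        log.info("simulate: seed=%d", sim_seed)
        sim_cfg = _simulation_config(config.simulate, sim_seed)
        tables, truth, trees = simulate_branch_tables(sim_cfg)
        for tree, table in zip(trees, tables):
            tpath = out / f"{tree.clade_id}.nwk"
            tree.write(tpath)
            record("simulate", tpath)
            bpath = out / f"{table.clade_id}.lengths.tsv"
            write_branch_table(table, bpath)
            record("simulate", bpath)
        truth_path = out / "truth.json"
        truth_path.write_text(
            json.dumps(
                {
                    "module_of_gene": truth.module_of_gene,
                    "rho_of_gene": truth.rho_of_gene,
                    "seed": sim_seed,
                },
                indent=1,
                sort_keys=True,
            )
        )
        record("simulate", truth_path)
    else:
        if not config.clades:
            raise ValueError("config needs either 'simulate' or 'clades'")
        tables = []
        for c in config.clades:
            tree = read_clade_tree(c["tree"], c["clade_id"])
            tables.append(read_branch_table(c["table"], tree))

    # --- stage: rer ------------------------------------------------------
    rers = []
    for table in tables:
        master = master_profile(table, config.min_genes_per_branch)
        rer = compute_rer(table, master)
        rers.append(rer)
        rpath = out / f"{table.clade_id}.rer.tsv"
        rer.rer.to_csv(rpath, sep="\t", index_label="gene", na_rep="")
        record("rer", rpath)

    # --- stage: erc ------------------------------------------------------
    matrix = build_erc_matrix(rers, n_min=config.n_min)
    epath = out / "erc_pairs.tsv"
    write_pair_table(matrix.to_records(), epath)
    record("erc", epath)
    summary = matrix.summary()
    summary["threshold_mean_plus_2sd"] = significance_threshold(matrix, config.k_sd)
    spath = out / "erc_summary.json"
    spath.write_text(json.dumps(summary, indent=1, sort_keys=True))
    record("erc", spath)

    sets = read_gene_sets(config.gene_sets) if config.gene_sets else None

    # --- stage: group tests ---------------------------------------------
    if sets is not None and (config.group_tests or config.between_tests):
        results = {}
        for name in config.group_tests:
            seed = _substream(config.seed, f"group:{name}")
            log.info("group-test %s: seed=%d", name, seed)
            results[name] = permute_within(
                matrix, sets[name].members, n_perm=config.n_perm, seed=seed
            ).to_dict()
        for pair in config.between_tests:
            a, b = pair
            seed = _substream(config.seed, f"between:{a}:{b}")
            log.info("between-test %s vs %s: seed=%d", a, b, seed)
            results[f"{a}|{b}"] = permute_between(
                matrix, sets[a].members, sets[b].members,
                n_perm=config.n_perm, seed=seed,
            ).to_dict()
        gpath = out / "group_tests.json"
        gpath.write_text(json.dumps(results, indent=1, sort_keys=True))
        record("group_tests", gpath)

    # --- stage: enrichment ----------------------------------------------
    if sets is not None and config.focal_set:
        focal = sets[config.focal_set].members
        pairs = enr.focal_pairs(matrix, focal)
        top = enr.top_quantile(pairs, q=config.q)
        result = enr.occurrence_enrichment(top, [g for g in focal if g in matrix])
        npath = out / "enrichment.tsv"
        result.table.to_csv(npath, sep="\t", index=False)
        record("enrichment", npath)

    # --- stage: complex benchmark ---------------------------------------
    if config.complexes:
        complexes = read_gene_sets(config.complexes).filter_min_size(3)
        seed = _substream(config.seed, "benchmark")
        log.info("benchmark: seed=%d", seed)
        nulls = bench.simulate_null_complexes(complexes, n_sim=config.n_sim, seed=seed)
        results = bench.complex_empirical_p(matrix, complexes, nulls)
        bpath = out / "benchmark.json"
        bpath.write_text(
            json.dumps(
                [
                    {
                        "name": r.name, "size": r.size, "mean_erc": r.mean_erc,
                        "p": r.p_empirical, "p_report": r.p_report,
                        "q": r.q, "significant": r.significant,
                    }
                    for r in results
                ],
                indent=1,
            )
        )
        record("benchmark", bpath)

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def export_heatmap_matrix(
    matrix: ERCMatrix, genes: list[str], threshold: float, path=None
) -> pd.DataFrame:
    """Square gene x gene score matrix with sub-threshold cells masked.

    Gene order is preserved from the input (pathway order); masked and
    absent cells are empty in the written TSV. Diagonal is masked.
    """
    idx = matrix.index_of(list(genes))  # KeyError for unknown genes
    sub = matrix.fterc[np.ix_(idx, idx)].astype(float, copy=True)
    sub[sub < threshold] = np.nan
    df = pd.DataFrame(sub, index=list(genes), columns=list(genes))
    if path is not None:
        df.to_csv(path, sep="\t", index_label="gene", na_rep="")
    return df


def export_edge_list(
    matrix: ERCMatrix, focal, partners, threshold: float, path=None
) -> pd.DataFrame:
    """Edge table (focal, partner, fterc) for scores >= threshold.

    Self-pairs (genes in both sets) are excluded. Used for network views
    where edge width encodes the score.
    """
    focal = [g for g in dict.fromkeys(focal) if g in matrix]
    partners = [g for g in dict.fromkeys(partners) if g in matrix]
    if not focal or not partners:
        raise ValueError("focal and partner sets must be non-empty")
    rows = []
    for f in focal:
        for p in partners:
            if f == p:
                continue
            v = matrix.erc(f, p)
            if not np.isnan(v) and v >= threshold:
                rows.append({"focal": f, "partner": p, "fterc": v})
    df = pd.DataFrame(rows, columns=["focal", "partner", "fterc"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
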