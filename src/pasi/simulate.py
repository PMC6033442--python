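"""Synthetic pathway collections and expression matrices for end-to-end testing.

The generator emulates the statistical regime the scoring method targets:
log-normal baseline intensities spanning several orders of magnitude,
individual (per-sample) variation that dominates the group effect, and a
multiplicative case-group effect restricted to the genes of designated
pathways.  Individual variation has three layers on the log scale:

* a global per-sample factor (array/library scaling residual),
* a per-sample, per-pathway factor (individuals differ coherently in
  pathway activity, e.g. immune activation state in blood), and
* independent gene x sample noise (biological + technical).

Pathway structure is generated as random directed graphs with a controlled
inhibiting-relation share (the KEGG-wide average is about 12%), a tunable
gene overlap between pathways, occasional multi-gene nodes and group nodes,
and is writable as KGML so the real parser is exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .expression import CASE, CONTROL, ExpressionMatrix, GeneMapping
from .kgml import GENE, GROUP, Pathway, PathwayNode, Relation, write_kgml

#: default collection size: with the conventional top-25 detection window
#: this reproduces the "top ~10% of tested pathways" geometry.
DEFAULT_N_PATHWAYS = 250


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    Effect and variation parameters are multiplicative (log-scale normal),
    matching microarray intensity behaviour; ``effect_size`` is the fold
    change applied to effect-pathway genes in case samples only.
    """

    n_pathways: int = DEFAULT_N_PATHWAYS
    nodes_per_pathway: tuple = (8, 25)
    relation_density: float = 1.3  # relations per node
    inhibition_fraction: float = 0.12
    n_genes_background: int = 500
    n_case: int = 13
    n_control: int = 11
    effect_pathways: tuple = ()
    effect_size: float = 1.0
    individual_sd: float = 0.2  # per-sample global factor, log scale
    gene_sd: float = 1.0  # per-gene baseline spread, log scale
    pathway_sd: float = 0.25  # per-sample per-pathway coherent variation
    noise_sd: float = 0.3  # independent gene x sample noise
    gene_overlap: float = 0.10  # chance a pathway gene is reused from another
    multi_gene_node_fraction: float = 0.10
    group_pathway_fraction: float = 0.10
    baseline_log_mean: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.nodes_per_pathway
        if not (1 <= lo <= hi):
            raise InputError("nodes_per_pathway must be an increasing positive range")
        if self.relation_density > lo - 1:
            raise InputError(
                f"relation density {self.relation_density} incompatible with "
                f"pathways of only {lo} nodes"
            )
        if self.effect_size < 1:
            raise InputError("effect_size must be >= 1 (fold change)")
        for name in ("n_pathways", "n_genes_background", "n_case", "n_control"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")


def pathway_id_for(index: int) -> str:
    """Stable KEGG-alike identifier of the index-th synthetic pathway."""
    return f"syn{index + 1:05d}"


def _sample_relations(rng, node_ids, n_rel, inhibition_fraction):
    n = len(node_ids)
    max_rel = n * (n - 1)
    if n_rel > max_rel:
        raise InputError(
            f"requested {n_rel} relations but only {max_rel} ordered pairs exist"
        )
    pair_idx = rng.choice(max_rel, size=n_rel, replace=False)
    n_inh = round(inhibition_fraction * n_rel)
    relations = []
    for j, idx in enumerate(pair_idx):
        a = int(idx) // (n - 1)
        b = int(idx) % (n - 1)
        b = b + 1 if b >= a else b
        subtype = "inhibition" if j < n_inh else "activation"
        relations.append(
            Relation(node_ids[a], node_ids[b], -1 if j < n_inh else +1, (subtype,))
        )
    return relations


def make_pathways(cfg: SimulationConfig, rng: np.random.Generator | None = None):
    """Generate ``cfg.n_pathways`` random pathways over a shared gene universe.

    Genes are mostly private to a pathway; with probability
    ``cfg.gene_overlap`` a node gene is drawn from the already-used pool,
    exercising multi-membership bookkeeping.  The inhibiting-relation count
    is fixed to ``round(target * n_relations)`` per pathway, so the realized
    share tracks the target to within rounding.
    """
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng([int(cfg.seed), 1])
    lo, hi = cfg.nodes_per_pathway
    used_genes: list = []
    next_gene = 10001
    pathways = []
    for i in range(cfg.n_pathways):
        n_nodes = int(rng.integers(lo, hi + 1))
        nodes = []
        gene_node_ids = []
        for j in range(n_nodes):
            n_members = 2 if rng.random() < cfg.multi_gene_node_fraction else 1
            members = set()
            while len(members) < n_members:
                if used_genes and rng.random() < cfg.gene_overlap:
                    members.add(int(rng.choice(used_genes)))
                else:
                    members.add(next_gene)
                    used_genes.append(next_gene)
                    next_gene += 1
            node_id = str(j + 1)
            nodes.append(PathwayNode(node_id, GENE, frozenset(members)))
            gene_node_ids.append(node_id)
        if n_nodes >= 2 and rng.random() < cfg.group_pathway_fraction:
            comp = [str(int(c) + 1) for c in rng.choice(n_nodes, size=2, replace=False)]
            members = frozenset().union(*(nodes[int(c) - 1].members for c in comp))
            nodes.append(PathwayNode(str(n_nodes + 1), GROUP, members, tuple(comp)))
        node_ids = [n.node_id for n in nodes]
        n_rel = round(cfg.relation_density * len(nodes))
        relations = _sample_relations(rng, node_ids, n_rel, cfg.inhibition_fraction)
        pathways.append(
            Pathway(pathway_id_for(i), f"Synthetic pathway {i + 1}", nodes, relations)
        )
    return pathways


def make_expression(
    cfg: SimulationConfig, pathways, rng: np.random.Generator | None = None
) -> ExpressionMatrix:
    """Simulate a linear-scale expression matrix for a pathway collection.

    Background genes belong to no pathway; pathway genes inherit the
    coherent individual-variation factor of their first (home) pathway.
    Genes appearing in any effect pathway are multiplied by
    ``cfg.effect_size`` in case samples only.
    """
    cfg.validate()
    ids = {p.pathway_id for p in pathways}
    missing = set(cfg.effect_pathways) - ids
    if missing:
        raise InputError(f"effect_pathways not in collection: {sorted(missing)}")
    rng = rng if rng is not None else np.random.default_rng([int(cfg.seed), 2])

    background = list(range(1, cfg.n_genes_background + 1))
    home: dict[int, int] = {}
    for pi, p in enumerate(pathways):
        for g in sorted(p.member_genes()):
            home.setdefault(g, pi)
    pathway_genes = sorted(home)
    genes = background + pathway_genes
    home_idx = np.array([-1] * len(background) + [home[g] for g in pathway_genes])

    effect_genes = set()
    for p in pathways:
        if p.pathway_id in cfg.effect_pathways:
            effect_genes |= p.member_genes()
    effect_mask = np.array([g in effect_genes for g in genes])

    n_s = cfg.n_case + cfg.n_control
    samples = [f"case_{i+1:03d}" for i in range(cfg.n_case)] + [
        f"ctrl_{i+1:03d}" for i in range(cfg.n_control)
    ]
    labels = pd.Series([CASE] * cfg.n_case + [CONTROL] * cfg.n_control, index=samples)

    g_base = rng.normal(0.0, cfg.gene_sd, size=len(genes))
    s_factor = rng.normal(0.0, cfg.individual_sd, size=n_s)
    pw_factor = rng.normal(0.0, cfg.pathway_sd, size=(len(pathways) + 1, n_s))
    pw_factor[-1] = 0.0  # background genes: no coherent pathway factor
    noise = rng.normal(0.0, cfg.noise_sd, size=(len(genes), n_s))

    log_x = (
        cfg.baseline_log_mean
        + g_base[:, None]
        + s_factor[None, :]
        + pw_factor[home_idx]
        + noise
    )
    if cfg.effect_size != 1.0:
        case_cols = np.array([lab == CASE for lab in labels])
        log_x[np.ix_(effect_mask, case_cols)] += math.log(cfg.effect_size)
    values = pd.DataFrame(np.exp(log_x), index=genes, columns=samples)
    return ExpressionMatrix(values, labels)


@dataclass
class SyntheticDataset:
    """A complete simulated study: matrix, pathway collection and its config."""

    expression: ExpressionMatrix
    pathways: list
    config: SimulationConfig

    @property
    def effect_pathway_ids(self) -> tuple:
        return tuple(self.config.effect_pathways)


def simulate(cfg: SimulationConfig) -> SyntheticDataset:
    pathways = make_pathways(cfg)
    return SyntheticDataset(make_expression(cfg, pathways), pathways, cfg)


def make_t1d1_like(
    seed: int,
    effect_size: float = 1.5,
    n_pathways: int = DEFAULT_N_PATHWAYS,
    **overrides,
) -> SyntheticDataset:
    """The standard 13 case + 11 control fixture with one designated effect
    pathway, mirroring the smallest real study design the method targets."""
    cfg = SimulationConfig(
        n_pathways=n_pathways,
        n_case=13,
        n_control=11,
        effect_pathways=(pathway_id_for(0),),
        effect_size=effect_size,
        seed=int(seed),
        **overrides,
    )
    return simulate(cfg)


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Write the dataset in the package's input formats.

    Emits ``expression.tsv`` (probe x sample), ``mapping.tsv`` (identity
    probe -> Entrez), ``labels.tsv`` and a ``kgml/`` directory; returns the
    paths.  Deterministic: the same dataset yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr_path = outdir / "expression.tsv"
    values = ds.expression.values.copy()
    values.index.name = "gene_id"
    values.to_csv(expr_path, sep="\t", float_format="%.6g")
    mapping_path = outdir / "mapping.tsv"
    with open(mapping_path, "w") as fh:
        for g in ds.expression.gene_ids:
            fh.write(f"{g}\t{g}\n")
    labels_path = outdir / "labels.tsv"
    with open(labels_path, "w") as fh:
        for sample, lab in ds.expression.labels.items():
            fh.write(f"{sample}\t{lab}\n")
    kgml_dir = outdir / "kgml"
    kgml_dir.mkdir(exist_ok=True)
    for p in ds.pathways:
        write_kgml(p, kgml_dir / f"{p.pathway_id}.xml")
    return {
        "expression": expr_path,
        "mapping": mapping_path,
        "labels": labels_path,
        "kgml_dir": kgml_dir,
    }
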