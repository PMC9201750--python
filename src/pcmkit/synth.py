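"""Synthetic study generator: posterior-like tree sets and trait tables
with known ground truth.

The generator emulates the structure of a shallow-radiation comparative
dataset: a ~26-tip time-calibrated ultrametric tree of height ~5 time
units, a pseudo-posterior of trees obtained by jittering node ages and
applying occasional nearest-neighbour interchanges, a phenotype block
(log body size + 5 log-shape ratios), environment blocks (vegetation /
temperature / precipitation PC-like axes plus univariate elevation), an
optional planted linear dependence of the shape block on the first
vegetation axis, and a clade-based two-group split at the root.  Every
output is a pure function of (config, seed), and the generating truth is
recorded so downstream estimates can be checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .traits import TraitMatrix
from .trees import PhyloTree, TreeSet, simulate_traits

__all__ = [
    "StudyConfig",
    "SyntheticStudy",
    "simulate_bd_tree",
    "pseudo_posterior",
    "generate_study",
]


@dataclass
class StudyConfig:
    """Conditions of a synthetic comparative study.

    Defaults mirror the scale of a small posterior-propagated analysis:
    26 species, tree height 5 time units, 100 posterior trees with ~10%
    age jitter and a 10% per-edge chance of a topology move.
    """

    n_tips: int = 26
    tree_height: float = 5.0
    birth: float = 1.0
    death: float = 0.0
    n_trees: int = 100
    age_jitter_cv: float = 0.1
    nni_prob: float = 0.1
    # phenotype: body size + 5 shape variables
    phenotype_model: str = "BM"
    phenotype_params: dict = field(default_factory=lambda: {"sigma2": 0.02})
    # environment: per-block axis counts and rates
    env_blocks: dict = field(default_factory=lambda: {
        "vegetation": {"n_axes": 3, "sigma2": 0.5},
        "temperature": {"n_axes": 2, "sigma2": 0.5},
        "precipitation": {"n_axes": 2, "sigma2": 0.5},
        "elevation": {"n_axes": 1, "sigma2": 0.5},
    })
    # planted effect of the first vegetation axis on every shape column
    shape_env_beta: float = 0.0
    # delete one shape cell to exercise regression imputation
    inject_missing: bool = False
    group_by_root_split: bool = True


@dataclass
class SyntheticStudy:
    treeset: TreeSet
    phenotype: TraitMatrix
    environment: TraitMatrix
    groups: pd.Series
    truth: dict
    config: StudyConfig
    seed: int


SHAPE_VARS = ["AG", "AL", "TbL", "FL", "PW"]

# planted shape-on-vegetation effect sizes; "strong" is calibrated to give
# roughly 0.9 power for the single-tree multivariate permutation test at the
# default noise level (26 tips, shape rate 0.02, vegetation rate 0.5)
BETA_NULL = 0.0
BETA_MODERATE = 0.05
BETA_STRONG = 0.10


def simulate_bd_tree(n_tips: int, birth: float = 1.0, death: float = 0.0,
                     seed=None, height: float | None = 5.0) -> PhyloTree:
    """Ultrametric birth-death tree conditioned on the tip count.

    The returned tree is rescaled to ``height`` (default 5 time units,
    matching a clade a few million years old) unless ``height`` is None.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if not (birth > death >= 0):
        raise ValueError("require birth > death >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    import random as _random

    from dendropy.model import birthdeath

    pyrng = _random.Random(int(rng.integers(2**31)))
    taxa = dendropy.TaxonNamespace([f"sp{i+1:02d}" for i in range(n_tips)])
    dtree = birthdeath.birth_death_tree(
        birth_rate=birth, death_rate=death, num_extant_tips=n_tips,
        taxon_namespace=taxa, rng=pyrng,
    )
    tree = PhyloTree.from_dendropy(dtree)
    # the simulator stops exactly at the n-th speciation; extend all pendant
    # edges by a sampled waiting time so no two tips are perfectly correlated
    extra = rng.exponential(1.0 / (n_tips * (birth + death)))
    length = tree.length.copy()
    length[: tree.n_tips] += extra
    tree = PhyloTree(tree.parent, length, tree.tip_labels)
    if height is not None:
        h = tree.height
        if h <= 0:
            raise RuntimeError("degenerate simulated tree")
        tree = PhyloTree(tree.parent, tree.length * (height / h), tree.tip_labels)
    return tree


def _nni(tree: PhyloTree, edge_child: int, rng: np.random.Generator) -> PhyloTree:
    """Nearest-neighbour interchange around the edge above ``edge_child``.

    Swaps one child of ``edge_child`` (an internal node) with its sibling;
    node ages are preserved, so branch lengths are recomputed from ages and
    the result stays ultrametric if the input was.
    """
    parent = tree.parent.copy()
    p = parent[edge_child]
    if p < 0 or edge_child < tree.n_tips:
        return tree
    siblings = [c for c in tree.children[p] if c != edge_child]
    if not siblings:
        return tree
    sib = siblings[int(rng.integers(len(siblings)))]
    child = tree.children[edge_child][int(rng.integers(len(tree.children[edge_child])))]
    # ages must stay ordered: the moved nodes keep their ages, so require
    # sib's age > edge_child's age (it becomes a child of edge_child)
    ages = tree.node_ages
    if sib >= tree.n_tips and ages[sib] <= ages[edge_child] + 1e-3 * tree.height:
        return tree
    parent[sib] = edge_child
    parent[child] = p
    length = np.empty_like(tree.length)
    for v in range(tree.n_nodes):
        length[v] = 0.0 if parent[v] < 0 else ages[v] - ages[parent[v]]
    if np.any(length < -1e-9):
        return tree
    return PhyloTree(parent, np.maximum(length, 0.0), list(tree.tip_labels))


def pseudo_posterior(tree: PhyloTree, n_trees: int, age_jitter_cv: float = 0.1,
                     nni_prob: float = 0.1, seed=None) -> TreeSet:
    """Emulate a Bayesian posterior sample by perturbing one base tree.

    Each replicate (i) rescales the tree height by a lognormal factor with
    coefficient of variation ``age_jitter_cv``, (ii) multiplicatively
    jitters each internal node's relative age with the same CV (clamped so
    children stay younger than parents and tips stay at the height), and
    (iii) applies a nearest-neighbour interchange independently at each
    internal edge with probability ``nni_prob``.
    """
    if age_jitter_cv < 0:
        raise ValueError("age_jitter_cv must be >= 0")
    if not (0 <= nni_prob <= 1):
        raise ValueError("nni_prob must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(age_jitter_cv**2))  # lognormal with mean 1, cv given
    mu = -0.5 * sigma**2
    out: list[PhyloTree] = []
    H = tree.height
    for _ in range(n_trees):
        t = tree
        if nni_prob > 0:
            for v in range(t.n_tips, t.n_nodes):
                if v != t.root and rng.random() < nni_prob:
                    t = _nni(t, v, rng)
        if age_jitter_cv > 0:
            # jitter age *increments* (waiting times between divergences on
            # each root-to-node path); increments stay positive, so no node
            # ever collides with its parent and conditioning is preserved
            ages0 = t.node_ages
            new_age = ages0.copy()
            deepest = 0.0
            for v in t._preorder():
                if v == t.root or v < t.n_tips:
                    continue
                inc = (ages0[v] - ages0[t.parent[v]]) * rng.lognormal(mu, sigma)
                new_age[v] = new_age[t.parent[v]] + inc
                deepest = max(deepest, new_age[v])
            # slack between the last divergence and the present
            max0 = ages0[t.n_tips:].max() if t.n_nodes > t.n_tips else 0.0
            A = deepest + (H - max0) * rng.lognormal(mu, sigma)
            newH = H * rng.lognormal(mu, sigma)   # realized height CV == cv
            ages = np.where(np.arange(t.n_nodes) < t.n_tips, A, new_age) / A * newH
            length = np.empty_like(t.length)
            for v in range(t.n_nodes):
                length[v] = 0.0 if t.parent[v] < 0 else ages[v] - ages[t.parent[v]]
            t = PhyloTree(t.parent.copy(), np.maximum(length, 0.0), list(t.tip_labels))
        else:
            t = t.copy()
        out.append(t)
    return TreeSet(trees=out, median_tree=tree.copy(), source="pseudo-posterior")


def root_bipartition(tree: PhyloTree) -> pd.Series:
    """Two-group labels from the two daughter clades of the root."""
    kids = tree.children[tree.root]
    first = set(tree.clade_tips(kids[0]))
    labels = ["north" if i in first else "south" for i in range(tree.n_tips)]
    return pd.Series(labels, index=list(tree.tip_labels), name="clade")


def generate_study(config: StudyConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate a complete synthetic comparative study.

    Phenotype and environment blocks are simulated on the base tree under
    the configured models; when ``shape_env_beta`` is non-zero the shape
    columns gain a linear dependence on the first vegetation axis on top of
    their phylogenetic noise.  The same (config, seed) always yields
    byte-identical output.
    """
    config = config or StudyConfig()
    rng = np.random.default_rng(seed)
    base = simulate_bd_tree(config.n_tips, config.birth, config.death,
                            seed=rng, height=config.tree_height)
    treeset = pseudo_posterior(base, config.n_trees, config.age_jitter_cv,
                               config.nni_prob, seed=rng)

    # environment blocks, independent phylogenetic signal per axis
    env_cols = {}
    env_truth = {}
    for block, spec in config.env_blocks.items():
        sim = simulate_traits(base, "BM", {"sigma2": spec["sigma2"]},
                              ntraits=spec["n_axes"], seed=rng)
        names = ([block] if spec["n_axes"] == 1
                 else [f"{block}_PC{k+1}" for k in range(spec["n_axes"])])
        for j, nm in enumerate(names):
            env_cols[nm] = sim.iloc[:, j]
        env_truth[block] = dict(spec)
    environment = TraitMatrix(pd.DataFrame(env_cols))

    # phenotype: ln(SVL) body size + 5 log-shape ratios
    pheno_sim = simulate_traits(
        base, config.phenotype_model, config.phenotype_params,
        ntraits=1 + len(SHAPE_VARS), seed=rng,
    )
    # simulated on log scale; emitted as raw measurements (mm) so that the
    # preparation path (log-ratio size correction) exactly inverts them
    pheno = pd.DataFrame(index=pheno_sim.index)
    log_svl = pheno_sim.iloc[:, 0] + np.log(55.0)  # ~55 mm lizards
    pheno["SVL"] = np.exp(log_svl)
    beta = float(config.shape_env_beta)
    driver = environment.data.get("vegetation_PC1")
    for j, var in enumerate(SHAPE_VARS, start=1):
        log_ratio = pheno_sim.iloc[:, j] + np.log(0.45)
        if beta != 0.0 and driver is not None:
            log_ratio = log_ratio + beta * driver
        pheno[var] = np.exp(log_svl + log_ratio)
    phenotype = TraitMatrix(pheno)

    if config.inject_missing:
        victim = phenotype.data.index[int(rng.integers(config.n_tips))]
        phenotype.data.loc[victim, "TbL"] = np.nan

    groups = root_bipartition(base)
    truth = {
        "seed": int(seed),
        "phenotype_model": config.phenotype_model,
        "phenotype_params": dict(config.phenotype_params),
        "shape_env_beta": beta,
        "env_blocks": env_truth,
        "group_sizes": groups.value_counts().to_dict(),
        "base_height": base.height,
    }
    return SyntheticStudy(treeset=treeset, phenotype=phenotype,
                          environment=environment, groups=groups,
                          truth=truth, config=config, seed=int(seed))
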