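"""Time-calibrated trees: I/O, node-time geometry, and model covariances.

Trees are rooted, with branch lengths in time units (typically millions of
years).  Node times are measured *forward* from the root (root age 0), so a
tip of an ultrametric tree sits at the tree height.  Three trait-evolution
models are supported through their implied tip covariance matrices:

* Brownian motion (BM): covariance of two tips equals the time shared on
  their root-to-tip paths.
* Ornstein-Uhlenbeck (OU): fixed-root form with pull strength ``alpha``;
  covariance decays with the patristic distance separating two tips.
* Early burst (EB / ACDC): the evolutionary rate decays as ``exp(r * t)``
  with ``r < 0``; implemented as a branch-length transform whose BM
  covariance is the EB covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "TreeSet",
    "CovMatrix",
    "read_tree_set",
    "read_tree",
    "bm_covariance",
    "ou_covariance",
    "eb_transform",
    "eb_rate_from_ratio",
    "simulate_traits",
]

ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Raised for malformed or inconsistent tree input."""


def _normalise_label(label: str) -> str:
    return label.strip().replace(" ", "_")


@dataclass
class PhyloTree:
    """A rooted tree stored as parent/length arrays in preorder.

    Nodes ``0 .. n_tips-1`` are tips (in ``tip_labels`` order); internal
    nodes follow.  ``parent[root] == -1`` and the root edge length is 0.
    """

    parent: np.ndarray          # (n_nodes,) int, -1 for root
    length: np.ndarray          # (n_nodes,) float, edge to parent
    tip_labels: list[str]

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.length = np.asarray(self.length, dtype=float)
        if np.any(self.length < -1e-12):
            raise TreeError("negative branch length")
        self.length = np.maximum(self.length, 0.0)
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise TreeError("tip labels are not unique")
        self.n_tips = len(self.tip_labels)
        self.n_nodes = len(self.parent)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeError("tree must have exactly one root")
        self.root = int(roots[0])
        # children lists
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0:
                self.children[p].append(v)
        # node ages (time from root), computed by a root-to-tip sweep
        ages = np.zeros(self.n_nodes)
        for v in self._preorder():
            p = self.parent[v]
            if p >= 0:
                ages[v] = ages[p] + self.length[v]
        self.node_ages = ages

    # -- geometry -----------------------------------------------------------

    def _preorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        return order

    def _postorder(self) -> list[int]:
        return self._preorder()[::-1]

    @property
    def height(self) -> float:
        """Maximum root-to-tip distance."""
        return float(self.node_ages[: self.n_tips].max())

    @property
    def tip_ages(self) -> np.ndarray:
        return self.node_ages[: self.n_tips].copy()

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        ages = self.node_ages[: self.n_tips]
        h = ages.max()
        return h > 0 and bool(np.all(np.abs(ages - h) <= rtol * h))

    def clade_tips(self, node: int) -> np.ndarray:
        """Indices of tips descending from ``node`` (the node itself if a tip)."""
        out: list[int] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < self.n_tips:
                out.append(v)
            else:
                stack.extend(self.children[v])
        return np.array(sorted(out), dtype=int)

    def mrca_age_matrix(self) -> np.ndarray:
        """Age of the MRCA for every tip pair; diagonal = tip depths."""
        n = self.n_tips
        S = np.zeros((n, n))
        # postorder merge of descendant tip lists; cross pairs coalesce here
        tipsets: dict[int, np.ndarray] = {}
        for v in self._postorder():
            if v < n:
                tipsets[v] = np.array([v])
                continue
            kids = [tipsets.pop(c) for c in self.children[v]]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    S[np.ix_(kids[a], kids[b])] = self.node_ages[v]
                    S[np.ix_(kids[b], kids[a])] = self.node_ages[v]
            tipsets[v] = np.concatenate(kids)
        np.fill_diagonal(S, self.node_ages[:n])
        return S

    # -- conversions --------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "PhyloTree":
        nodes = list(tree.preorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        labels = []
        for nd in tips:
            if nd.taxon is None or not nd.taxon.label:
                raise TreeError("unlabelled tip")
            labels.append(_normalise_label(nd.taxon.label))
        index = {id(nd): i for i, nd in enumerate(tips)}
        internal = [nd for nd in nodes if not nd.is_leaf()]
        for j, nd in enumerate(internal):
            index[id(nd)] = len(tips) + j
        parent = np.full(len(nodes), -1, dtype=int)
        length = np.zeros(len(nodes))
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                length[i] = nd.edge.length or 0.0
        return cls(parent=parent, length=length, tip_labels=labels)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            t = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"could not parse newick: {exc}") from exc
        return cls.from_dendropy(t)

    def to_newick(self) -> str:
        parts: dict[int, str] = {}
        for v in self._postorder():
            if v < self.n_tips:
                label = self.tip_labels[v].replace("_", " ")
                label = f"'{label}'" if " " in label else self.tip_labels[v]
                parts[v] = f"{label}:{self.length[v]:.10g}"
            else:
                inner = ",".join(parts.pop(c) for c in self.children[v])
                suffix = "" if v == self.root else f":{self.length[v]:.10g}"
                parts[v] = f"({inner}){suffix}"
        return parts[self.root] + ";"

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.parent.copy(), self.length.copy(), list(self.tip_labels))


@dataclass
class TreeSet:
    """An ordered sample of trees over one tip set (e.g. a Bayesian posterior)."""

    trees: list[PhyloTree]
    median_tree: PhyloTree | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.trees:
            raise TreeError("empty tree set")
        ref = set(self.trees[0].tip_labels)
        for i, t in enumerate(self.trees):
            if set(t.tip_labels) != ref:
                raise TreeError(f"tree {i} has a different tip set")
        if self.median_tree is not None and set(self.median_tree.tip_labels) != ref:
            raise TreeError("median tree has a different tip set")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> PhyloTree:
        return self.trees[i]

    @property
    def tip_labels(self) -> list[str]:
        return list(self.trees[0].tip_labels)

    def write(self, path, schema: str = "newick") -> None:
        if schema == "newick":
            with open(path, "w") as fh:
                for t in self.trees:
                    fh.write(t.to_newick() + "\n")
        elif schema == "nexus":
            tl = dendropy.TreeList.get(
                data="\n".join(t.to_newick() for t in self.trees), schema="newick"
            )
            tl.write(path=str(path), schema="nexus")
        else:
            raise ValueError(f"unknown schema {schema!r}")


@dataclass
class CovMatrix:
    """A labelled symmetric tip-covariance matrix."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValueError("covariance shape does not match labels")

    def reorder(self, labels: list[str]) -> "CovMatrix":
        idx = [self.labels.index(l) for l in labels]
        return CovMatrix(list(labels), self.values[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# I/O

def read_tree(path_or_string, schema: str = "newick") -> PhyloTree:
    """Read a single tree from a file path or a literal newick string."""
    s = str(path_or_string)
    if s.lstrip().startswith("(") or s.lstrip().startswith("["):
        return PhyloTree.from_newick(s)
    t = dendropy.Tree.get(path=s, schema=schema)
    return PhyloTree.from_dendropy(t)


def read_tree_set(
    path,
    schema: str = "newick",
    max_trees: int | None = None,
    seed: int | None = None,
    median_tree: PhyloTree | None = None,
) -> TreeSet:
    """Read a collection of trees, optionally subsampling without replacement.

    The subsample is uniform and reproducible for a given ``seed``; trees
    keep their file order.  Tip labels have whitespace normalised to
    underscores so they can be matched against trait-table species keys.
    """
    if max_trees is not None and max_trees < 1:
        raise ValueError("max_trees must be >= 1")
    try:
        tl = dendropy.TreeList.get(path=str(path), schema=schema)
    except Exception as exc:
        raise TreeError(f"could not parse {path}: {exc}") from exc
    trees = [PhyloTree.from_dendropy(t) for t in tl]
    if not trees:
        raise TreeError(f"no trees in {path}")
    if max_trees is not None and max_trees < len(trees):
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(trees), size=max_trees, replace=False))
        trees = [trees[i] for i in keep]
    return TreeSet(trees=trees, median_tree=median_tree, source=str(path))


# ---------------------------------------------------------------------------
# Covariances

def bm_covariance(tree: PhyloTree) -> CovMatrix:
    """Brownian-motion tip covariance: shared root-to-MRCA path length.

    Entry (i, j) is the total branch length common to the root-to-tip paths
    of tips i and j; the diagonal holds root-to-tip distances.
    """
    if tree.height <= 0:
        raise TreeError("zero-height tree has a degenerate BM covariance")
    return CovMatrix(list(tree.tip_labels), tree.mrca_age_matrix())


def ou_covariance(tree: PhyloTree, alpha: float) -> CovMatrix:
    """Fixed-root Ornstein-Uhlenbeck tip covariance with unit rate.

    ``V_ij = (1/(2a)) (1 - exp(-2a s_ij)) exp(-a d_ij)`` where ``s_ij`` is
    the time from root to the MRCA of i and j and ``d_ij`` their patristic
    distance after the MRCA.  As ``alpha -> 0`` this tends to the BM
    covariance.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    S = tree.mrca_age_matrix()
    depths = np.diag(S)
    D = depths[:, None] + depths[None, :] - 2.0 * S
    with np.errstate(over="ignore"):
        V = (-np.expm1(-2.0 * alpha * S)) / (2.0 * alpha) * np.exp(-alpha * D)
    return CovMatrix(list(tree.tip_labels), V)


def _eb_segment(r: float, t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
    """Integral of exp(r t) over [t1, t2]; stable as r -> 0."""
    if abs(r) < 1e-12:
        return t2 - t1
    return (np.exp(r * t2) - np.exp(r * t1)) / r


def eb_transform(tree: PhyloTree, r: float) -> PhyloTree:
    """Early-burst (ACDC) branch-length transform.

    The evolutionary rate is ``exp(r t)`` at root-relative time ``t``; each
    edge spanning [t1, t2] gets length ``(exp(r t2) - exp(r t1)) / r``, so
    the BM covariance of the transformed tree is the EB covariance.
    ``r = 0`` is the identity; ``r < 0`` is an early burst.
    """
    if r > 0:
        raise ValueError("early burst requires r <= 0")
    ages = tree.node_ages
    t2 = ages
    t1 = ages - tree.length
    new_len = _eb_segment(r, t1, t2)
    new_len[tree.root] = 0.0
    return PhyloTree(tree.parent.copy(), new_len, list(tree.tip_labels))


def eb_rate_from_ratio(g: float, height: float) -> float:
    """Map a rate ratio ``g = rate(present)/rate(root)`` to the EB rate r.

    ``g < 1`` gives a decelerating (early-burst) rate, ``r = ln(g)/height``.
    The convention mirrors ACDC parameterisations that express the rate decay
    as a present-to-root ratio rather than an exponent.
    """
    if g <= 0:
        raise ValueError("g must be > 0")
    if height <= 0:
        raise ValueError("height must be > 0")
    return float(np.log(g) / height)


def model_covariance(tree: PhyloTree, model: str, params: dict | None = None) -> CovMatrix:
    """Tip covariance for ``model`` in {BM, OU, EB} with unit base rate."""
    params = params or {}
    model = model.upper()
    if model == "BM":
        return bm_covariance(tree)
    if model == "OU":
        return ou_covariance(tree, params["alpha"])
    if model == "EB":
        return bm_covariance(eb_transform(tree, params["r"]))
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Simulation

def simulate_traits(
    tree: PhyloTree,
    model: str = "BM",
    params: dict | None = None,
    ntraits: int = 1,
    root_state: float | np.ndarray = 0.0,
    seed: int | np.random.Generator | None = None,
):
    """Simulate tip values under BM/OU/EB as a matrix-normal draw.

    The joint tip distribution is ``N(1 mu', R (x) V)`` with ``V`` the model
    tree covariance and ``R`` the trait rate matrix (``params['R']``) or
    ``sigma2 * I`` (``params['sigma2']``).  Returns a pandas DataFrame with
    tips as rows.
    """
    import pandas as pd

    params = dict(params or {})
    R = params.get("R")
    if R is None:
        sigma2 = params.get("sigma2", 1.0)
        R = np.eye(ntraits) * sigma2
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if R.shape != (p, p) or not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R must be a symmetric p x p matrix")
    w, U = np.linalg.eigh(R)
    if np.any(w < -1e-10 * max(1.0, w.max(initial=0.0))):
        raise ValueError("R must be positive semi-definite")
    LR = U @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    V = model_covariance(tree, model, params).values
    n = tree.n_tips
    # PSD square root of V (Cholesky with fallback to eigen factor)
    try:
        LV = np.linalg.cholesky(V + 1e-12 * np.trace(V) / n * np.eye(n))
    except np.linalg.LinAlgError:
        wv, Uv = np.linalg.eigh(V)
        LV = Uv @ np.diag(np.sqrt(np.clip(wv, 0.0, None)))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Z = rng.standard_normal((n, p))
    X = LV @ Z @ LR.T + np.atleast_1d(np.asarray(root_state, dtype=float))
    cols = [f"trait_{k+1}" for k in range(p)]
    return pd.DataFrame(X, index=list(tree.tip_labels), columns=cols)
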