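"""Maximum-likelihood tree search: multistart hill climbing over NNI moves.

The search is deliberately small-scale: starting trees come from
neighbour joining on Jukes–Cantor distances and from random-order
stepwise-addition maximum parsimony; each start is refined by
nearest-neighbour-interchange (NNI) hill climbing with branch-length
re-optimisation.  Bootstrap support is obtained by resampling alignment
columns, re-running a quick search per pseudoreplicate, and scoring the best
tree's bipartitions against the bootstrap swarm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .likelihood import Alignment, optimize_branch_lengths
from .phylo import Node, PhyloTree, TreeError, bipartitions
from .substitution import GTRModel

_FITCH_BITS = {"A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
               "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
               "B": 14, "D": 13, "H": 11, "V": 7,
               "N": 15, "-": 15, ".": 15, "?": 15}


@dataclass
class SearchConfig:
    """Tree-search settings.

    ``n_starts`` counts independent searches: one neighbour-joining start
    plus ``n_starts - 1`` random-order stepwise-addition parsimony starts.
    """

    n_starts: int = 10
    bootstrap_replicates: int = 0
    seed: int = 0
    branch_tol: float = 1e-6
    max_nni_rounds: int = 20


@dataclass
class MLSearchResult:
    tree: PhyloTree
    loglik: float
    start_logliks: list[float] = field(default_factory=list)
    supports: dict[frozenset, float] | None = None
    bootstrap_trees: list[PhyloTree] | None = None


# ---------------------------------------------------------------------------
# distances and starting trees

def jc_distance(a: str, b: str) -> float:
    """Jukes–Cantor distance between two aligned sequences.

    Computed over columns where both sequences carry an unambiguous base;
    saturated pairs (p >= 3/4) are capped just below saturation.
    """
    pa = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    pb = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    acgt = np.zeros(256, dtype=bool)
    for ch in "ACGT":
        acgt[ord(ch)] = True
    use = acgt[pa] & acgt[pb]
    n = int(use.sum())
    if n == 0:
        return 0.0
    p = float((pa[use] != pb[use]).mean())
    p = min(p, 0.749)
    return max(0.0, -0.75 * np.log(1.0 - 4.0 * p / 3.0))


def jc_distance_matrix(aln: Alignment) -> np.ndarray:
    n = len(aln)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jc_distance(aln.seqs[i], aln.seqs[j])
    return d


def nj_tree(aln: Alignment) -> PhyloTree:
    """Neighbour-joining starting tree (scikit-bio) on JC distances."""
    dm = DistanceMatrix(jc_distance_matrix(aln), ids=aln.names)
    tree = PhyloTree.from_newick(str(nj(dm)))
    for node in tree.postorder():  # NJ can emit small negative lengths
        if node.parent is not None:
            node.length = max(node.length, 1e-8)
    return tree


def _fitch_encode(aln: Alignment) -> dict[str, np.ndarray]:
    enc = {}
    lut = np.full(256, 15, dtype=np.uint8)
    for ch, bits in _FITCH_BITS.items():
        lut[ord(ch)] = bits
        lut[ord(ch.lower())] = bits
    for name, seq in zip(aln.names, aln.seqs):
        enc[name] = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    return enc


def parsimony_score(tree: PhyloTree, enc: dict[str, np.ndarray]) -> int:
    """Fitch parsimony length of a tree."""
    score = 0
    sets: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            sets[id(node)] = enc[node.name]
            continue
        acc = None
        for child in node.children:
            c = sets.pop(id(child))
            if acc is None:
                acc = c
                continue
            inter = acc & c
            empty = inter == 0
            score += int(empty.sum())
            acc = np.where(empty, acc | c, inter)
        sets[id(node)] = acc
    return score


def _attachment_edges(tree: PhyloTree) -> list[Node]:
    return tree.branches()


def _insert_on_edge(tree: PhyloTree, edge_child: Node, new_tip_name: str,
                    length: float = 0.05) -> None:
    """Split the branch above ``edge_child`` and hang a new tip (in place)."""
    parent = edge_child.parent
    mid = Node(None, edge_child.length / 2.0)
    edge_child.length /= 2.0
    idx = parent.children.index(edge_child)
    parent.children[idx] = mid
    mid.parent = parent
    mid.add_child(edge_child)
    mid.add_child(Node(new_tip_name, length))


def stepwise_parsimony_tree(aln: Alignment, rng: np.random.Generator) -> PhyloTree:
    """Random-addition-order stepwise parsimony starting tree."""
    if len(aln) < 3:
        raise TreeError("need at least 3 sequences")
    enc = _fitch_encode(aln)
    order = list(rng.permutation(aln.names))
    root = Node(None, 0.0)
    for name in order[:3]:
        root.add_child(Node(name, 0.05))
    tree = PhyloTree(root)
    for name in order[3:]:
        best_score, best_edge_idx = None, None
        edges = _attachment_edges(tree)
        for i in range(len(edges)):
            cand = tree.copy()
            _insert_on_edge(cand, cand.branches()[i], name)
            s = parsimony_score(cand, enc)
            if best_score is None or s < best_score:
                best_score, best_edge_idx = s, i
        _insert_on_edge(tree, tree.branches()[best_edge_idx], name)
    return tree


# ---------------------------------------------------------------------------
# NNI hill climbing

def nni_neighbors(tree: PhyloTree):
    """Yield all nearest-neighbour-interchange rearrangements of a tree."""
    post = list(tree.postorder())
    for vi, v in enumerate(post):
        if v.is_leaf or v.parent is None:
            continue
        u = v.parent
        n_sibs = len(u.children) - 1
        for si in range(n_sibs):
            for ci in range(len(v.children)):
                work = tree.copy()
                post2 = list(work.postorder())
                v2 = post2[vi]
                u2 = v2.parent
                sib2 = [c for c in u2.children if c is not v2][si]
                child2 = v2.children[ci]
                u2.children[u2.children.index(sib2)] = child2
                v2.children[ci] = sib2
                child2.parent, sib2.parent = u2, v2
                yield work


def _refine(tree: PhyloTree, aln: Alignment, model: GTRModel,
            config: SearchConfig) -> tuple[PhyloTree, float]:
    res = optimize_branch_lengths(tree, aln, model, tol=config.branch_tol)
    tree, current = res.tree, res.loglik
    for _ in range(config.max_nni_rounds):
        best_tree, best_ll = None, current
        for cand in nni_neighbors(tree):
            r = optimize_branch_lengths(cand, aln, model,
                                        tol=config.branch_tol, max_sweeps=2)
            if r.loglik > best_ll + config.branch_tol:
                best_tree, best_ll = r.tree, r.loglik
        if best_tree is None:
            break
        res = optimize_branch_lengths(best_tree, aln, model, tol=config.branch_tol)
        tree, current = res.tree, res.loglik
    return tree, current


def build_ml_tree(aln: Alignment, model: GTRModel,
                  config: SearchConfig | None = None) -> MLSearchResult:
    """Best ML tree over multistart NNI hill climbing, with optional bootstrap.

    Returns the highest-likelihood tree across all starts; its log-likelihood
    is >= each start's final log-likelihood by construction.
    """
    config = config or SearchConfig()
    if len(aln) < 3:
        raise TreeError("need at least 3 sequences to build a tree")
    rng = np.random.default_rng(config.seed)
    if len(aln) == 3:  # single unrooted topology; only lengths to fit
        root = Node(None, 0.0)
        for name in aln.names:
            root.add_child(Node(name, 0.05))
        res = optimize_branch_lengths(PhyloTree(root), aln, model,
                                      tol=config.branch_tol)
        return MLSearchResult(tree=res.tree, loglik=res.loglik,
                              start_logliks=[res.loglik])
    starts: list[PhyloTree] = [nj_tree(aln)]
    for _ in range(max(0, config.n_starts - 1)):
        starts.append(stepwise_parsimony_tree(aln, rng))
    best_tree, best_ll, start_lls = None, -np.inf, []
    for start in starts:
        tree, ll = _refine(start, aln, model, config)
        start_lls.append(ll)
        if ll > best_ll:
            best_tree, best_ll = tree, ll
    result = MLSearchResult(tree=best_tree, loglik=best_ll,
                            start_logliks=start_lls)
    if config.bootstrap_replicates > 0:
        boots = bootstrap_trees(aln, model, config.bootstrap_replicates, rng,
                                config)
        result.bootstrap_trees = boots
        result.supports = bipartition_support(best_tree, boots)
        _annotate_supports(best_tree, result.supports)
    return result


def bootstrap_trees(aln: Alignment, model: GTRModel, n_replicates: int,
                    rng, config: SearchConfig | None = None) -> list[PhyloTree]:
    """Column-resampled pseudoreplicate trees (quick single-start searches)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    quick = SearchConfig(n_starts=1, branch_tol=1e-4, max_nni_rounds=5,
                         seed=0)
    out = []
    for _ in range(n_replicates):
        cols = rng.integers(0, aln.n_sites, size=aln.n_sites)
        res_aln = Alignment(list(aln.names),
                            ["".join(s[c] for c in cols) for s in aln.seqs])
        tree, _ = _refine(nj_tree(res_aln), res_aln, model, quick)
        out.append(tree)
    return out


def bipartition_support(best_tree: PhyloTree,
                        boot_trees: list[PhyloTree]) -> dict[frozenset, float]:
    """Percent of bootstrap trees containing each bipartition of the best tree.

    All trees must share the same tip set; values are in [0, 100] and are
    invariant to tip order and rooting of either tree.
    """
    tips = set(best_tree.tip_names())
    for t in boot_trees:
        if set(t.tip_names()) != tips:
            raise TreeError("bootstrap tree tip set differs from best tree")
    target = bipartitions(best_tree)
    counts = dict.fromkeys(target, 0)
    for t in boot_trees:
        for split in bipartitions(t):
            if split in counts:
                counts[split] += 1
    n = max(len(boot_trees), 1)
    return {split: 100.0 * c / n for split, c in counts.items()}


def _annotate_supports(tree: PhyloTree, supports: dict[frozenset, float]) -> None:
    all_tips = frozenset(tree.tip_names())
    anchor = min(all_tips)
    below: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
            continue
        below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        side = below[id(node)]
        if anchor in side:
            side = all_tips - side
        if side in supports:
            node.support = supports[side]
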