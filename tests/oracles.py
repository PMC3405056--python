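"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the package's own fast paths: the
likelihood oracle enumerates internal-node states, the alignment oracle is a
plain dynamic program, and the bootstrap oracle derives bipartitions through
dendropy.  They are only feasible on tiny instances.
"""

from __future__ import annotations

import itertools
import math

import dendropy
import numpy as np

from caviarid.likelihood import Alignment
from caviarid.phylo import Node, PhyloTree
from caviarid.substitution import EigenGTR, GTRModel


def enumeration_loglik(tree: PhyloTree, aln: Alignment,
                       model: GTRModel) -> float:
    """Log-likelihood by exhaustive summation over internal-node states."""
    rates = model.category_rates()
    eig = EigenGTR.from_model(model)
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    tips = [n for n in nodes if n.is_leaf]
    state_idx = {c: i for i, c in enumerate("ACGT")}
    tip_states = {id(n): [state_idx[c] for c in aln.get(n.name)] for n in tips}
    pmats = {k: {id(n): eig.transition_matrices(n.length * r)
                 for n in nodes if n.parent is not None}
             for k, r in enumerate(rates)}
    total = 0.0
    for site in range(aln.n_sites):
        site_lik = 0.0
        for k in range(len(rates)):
            pk = pmats[k]
            for assign in itertools.product(range(4), repeat=len(internals)):
                amap = {id(n): s for n, s in zip(internals, assign)}

                def state(n):
                    return (amap[id(n)] if not n.is_leaf
                            else tip_states[id(n)][site])

                prob = model.pi[state(tree.root)]
                for n in nodes:
                    if n.parent is not None:
                        prob *= pk[id(n)][state(n.parent), state(n)]
                site_lik += prob / len(rates)
        total += math.log(site_lik)
    return total


def random_tree(names, rng: np.random.Generator,
                max_length: float = 0.5) -> PhyloTree:
    """Random topology by sequential random attachment, random lengths."""
    names = list(names)
    root = Node(None, 0.0)
    for name in names[:3]:
        root.add_child(Node(name, float(rng.uniform(0.01, max_length))))
    tree = PhyloTree(root)
    for name in names[3:]:
        branches = tree.branches()
        target = branches[int(rng.integers(0, len(branches)))]
        parent = target.parent
        mid = Node(None, target.length / 2.0)
        target.length /= 2.0
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add_child(target)
        mid.add_child(Node(name, float(rng.uniform(0.01, max_length))))
        tree = PhyloTree(tree.root)
    return tree


def random_instance(rng: np.random.Generator, max_tips: int = 5,
                    max_sites: int = 30):
    """A random (tree, alignment, model) triple for oracle comparison."""
    n_tips = int(rng.integers(3, max_tips + 1))
    n_sites = int(rng.integers(5, max_sites + 1))
    names = [f"t{i}" for i in range(n_tips)]
    tree = random_tree(names, rng)
    freqs = rng.dirichlet(np.ones(4) * 8)
    rates = rng.uniform(0.3, 4.0, 6)
    alpha = float(rng.uniform(0.2, 3.0)) if rng.random() < 0.7 else None
    model = GTRModel(freqs=tuple(freqs), rates=tuple(rates), alpha=alpha,
                     ncat=2)
    seqs = ["".join(rng.choice(list("ACGT"), size=n_sites)) for _ in names]
    return tree, Alignment(names, seqs), model


def smith_waterman_score(a: str, b: str, match: float, mismatch: float,
                         gap_open_total: float, gap_extend: float) -> float:
    """Plain affine-gap local alignment DP (Gotoh, three matrices).

    ``gap_open_total`` is the cost of a gap of length one; extending adds
    ``gap_extend`` per further position.
    """
    n, m = len(a), len(b)
    neg = -1e18
    h = np.zeros((n + 1, m + 1))
    e = np.full((n + 1, m + 1), neg)  # gap in a (vertical)
    f = np.full((n + 1, m + 1), neg)  # gap in b (horizontal)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i][j] = max(h[i - 1][j] + gap_open_total,
                          e[i - 1][j] + gap_extend)
            f[i][j] = max(h[i][j - 1] + gap_open_total,
                          f[i][j - 1] + gap_extend)
            sub = match if a[i - 1] == b[j - 1] else mismatch
            h[i][j] = max(0.0, h[i - 1][j - 1] + sub, e[i][j], f[i][j])
            best = max(best, h[i][j])
    return best


def dendropy_bipartition_support(best: PhyloTree, boots) -> dict:
    """Bootstrap support through dendropy's bipartition machinery."""
    taxa = dendropy.TaxonNamespace(sorted(best.tip_names()))

    def splits(tree: PhyloTree) -> set:
        dtree = dendropy.Tree.get(data=tree.to_newick(), schema="newick",
                                  taxon_namespace=taxa,
                                  preserve_underscores=True)
        dtree.encode_bipartitions()
        out = set()
        n_taxa = len(taxa)
        for bp in dtree.bipartition_encoding:
            mask = bp.split_bitmask
            tips = frozenset(taxa[i].label for i in range(n_taxa)
                             if mask & (1 << i))
            if 1 < len(tips) < n_taxa - 1:
                # canonical side: the one not containing the smallest label
                anchor = min(t.label for t in taxa)
                if anchor in tips:
                    tips = frozenset(t.label for t in taxa) - tips
                out.add(tips)
        return out

    target = splits(best)
    counts = dict.fromkeys(target, 0)
    for bt in boots:
        for s in splits(bt):
            if s in counts:
                counts[s] += 1
    return {s: 100.0 * c / len(boots) for s, c in counts.items()}
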