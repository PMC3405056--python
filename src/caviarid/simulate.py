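"""Sequence simulation along a phylogeny under GTR+Gamma.

Sites evolve independently; each site draws a gamma rate category once and
keeps it on every branch (the standard discrete-gamma assumption).  All
randomness flows through a :class:`numpy.random.Generator`, so identical
seeds give byte-identical alignments.
"""

from __future__ import annotations

import numpy as np

from .likelihood import Alignment
from .phylo import PhyloTree
from .substitution import STATES, EigenGTR, GTRModel


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _draw_states(p_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorised categorical draw: one state per row of ``p_rows`` (L, 4)."""
    cum = np.cumsum(p_rows, axis=1)
    u = rng.random(p_rows.shape[0])[:, None]
    return (u > cum[:, :3]).sum(axis=1).astype(np.int8)


def simulate_alignment(tree: PhyloTree, model: GTRModel, n_sites: int,
                       seed) -> Alignment:
    """Simulate one sequence per tip of ``tree``.

    The root sequence is drawn from the stationary distribution; each branch
    applies P(t * r_site) where r_site is the site's gamma category rate.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = _as_rng(seed)
    eig = EigenGTR.from_model(model)
    rates = model.category_rates()
    cats = rng.integers(0, len(rates), size=n_sites)
    root_states = _draw_states(np.tile(model.pi, (n_sites, 1)), rng)
    names: list[str] = []
    seqs: list[str] = []

    def descend(node, states: np.ndarray) -> None:
        if node.parent is not None:
            pmats = eig.transition_matrices(node.length * rates)  # (K, 4, 4)
            rows = pmats[cats, states, :]  # (L, 4)
            states = _draw_states(rows, rng)
        if node.is_leaf:
            names.append(node.name)
            seqs.append(states_to_seq(states))
        else:
            for child in node.children:
                descend(child, states)

    descend(tree.root, root_states)
    return Alignment(names, seqs)


def evolve_sequence(seq: str, t: float, model: GTRModel, rng) -> str:
    """Evolve a single sequence for branch length ``t`` (fresh site categories).

    Ambiguity codes and gaps are passed through unchanged.
    """
    rng = _as_rng(rng)
    eig = EigenGTR.from_model(model)
    rates = model.category_rates()
    codes = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    state_map = np.full(256, -1, dtype=np.int8)
    for i, ch in enumerate(STATES):
        state_map[ord(ch)] = i
    states = state_map[codes]
    known = states >= 0
    cats = rng.integers(0, len(rates), size=len(seq))
    pmats = eig.transition_matrices(t * rates)
    out = np.array(list(seq.upper()))
    if known.any():
        rows = pmats[cats[known], states[known], :]
        out[known] = np.array(list(STATES))[_draw_states(rows, rng)]
    return "".join(out)


def states_to_seq(states: np.ndarray) -> str:
    return "".join(STATES[s] for s in states)
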