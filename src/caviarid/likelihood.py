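"""Felsenstein-pruning likelihood for GTR+Gamma, with branch and shape fitting.

Partial likelihoods are propagated in arrays of shape ``(K, L, 4)`` (gamma
category, alignment column, nucleotide state) with per-site rescaling to avoid
underflow.  Ambiguity codes and gaps contribute a partial likelihood of one
for every compatible state (missing data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .phylo import Node, PhyloTree, TreeError
from .substitution import EigenGTR, GTRModel

IUPAC_STATES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", ".": "ACGT", "?": "ACGT",
}

_STATE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _conditional_table() -> tuple[np.ndarray, np.ndarray]:
    """Lookup tables: byte -> 4-vector of compatible states, byte validity."""
    table = np.zeros((256, 4))
    valid = np.zeros(256, dtype=bool)
    for code, states in IUPAC_STATES.items():
        vec = np.zeros(4)
        for s in states:
            vec[_STATE_INDEX[s]] = 1.0
        for ch in (code, code.lower()):
            table[ord(ch)] = vec
            valid[ord(ch)] = True
    return table, valid


_COND_TABLE, _VALID_BYTE = _conditional_table()


class AlignmentError(ValueError):
    """Raised for ragged or invalid alignments."""


@dataclass
class Alignment:
    """An ordered multiple sequence alignment over IUPAC DNA plus gaps."""

    names: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.seqs):
            raise AlignmentError("names and sequences differ in number")
        if len(set(self.names)) != len(self.names):
            raise AlignmentError("sequence names must be unique")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        for name, seq in zip(self.names, self.seqs):
            bad = {c for c in seq if not _VALID_BYTE[ord(c)]}
            if bad:
                raise AlignmentError(f"{name}: invalid characters {sorted(bad)}")
        self.seqs = [s.upper() for s in self.seqs]

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_sites(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def get(self, name: str) -> str:
        try:
            return self.seqs[self.names.index(name)]
        except ValueError:
            raise KeyError(name) from None

    def subset(self, names) -> "Alignment":
        return Alignment(list(names), [self.get(n) for n in names])

    def conditional(self, name: str) -> np.ndarray:
        """Tip conditional likelihoods, shape (L, 4)."""
        return sequence_conditionals(self.get(name))

    # -- FASTA I/O ---------------------------------------------------------
    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path) -> None:
        records = [SeqRecord(Seq(s), id=n, description="")
                   for n, s in zip(self.names, self.seqs)]
        SeqIO.write(records, str(path), "fasta")


def sequence_conditionals(seq: str) -> np.ndarray:
    """(L, 4) partial-likelihood matrix for a single sequence."""
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _COND_TABLE[codes]


def _compile(tree: PhyloTree, aln: Alignment) -> list[tuple[Node, list[Node]]]:
    names = set(aln.names)
    for tip in tree.tip_names():
        if tip not in names:
            raise TreeError(f"tip {tip!r} has no sequence in the alignment")
    return [(n, n.children) for n in tree.postorder()]


def tree_loglik(tree: PhyloTree, aln: Alignment, model: GTRModel,
                eig: EigenGTR | None = None) -> float:
    """Log-likelihood of an alignment on a tree under GTR+Gamma.

    The likelihood is averaged over the discrete gamma categories with equal
    weights.  Invariant under re-rooting (reversibility) and tip order.
    """
    if len(aln) == 0:
        raise AlignmentError("empty alignment")
    eig = eig or EigenGTR.from_model(model)
    rates = model.category_rates()
    ncat = len(rates)
    n_sites = aln.n_sites
    logscale = np.zeros(n_sites)
    partials: dict[int, np.ndarray] = {}
    for node, children in _compile(tree, aln):
        if not children:
            tipcond = aln.conditional(node.name)
            partials[id(node)] = np.broadcast_to(tipcond, (ncat, n_sites, 4)).copy()
            continue
        part = np.ones((ncat, n_sites, 4))
        for child in children:
            p = eig.transition_matrices(child.length * rates)  # (K, 4, 4)
            part *= np.einsum("kij,klj->kli", p, partials.pop(id(child)))
        # rescale per site across categories and states
        mx = part.max(axis=(0, 2))
        nz = mx > 0
        part[:, nz, :] /= mx[None, nz, None]
        with np.errstate(divide="ignore"):
            logscale[nz] += np.log(mx[nz])
        if not np.all(nz):
            raise AlignmentError("zero site likelihood (incompatible data)")
        partials[id(node)] = part
    root_part = partials[id(tree.root)]
    site_lik = np.einsum("kli,i->l", root_part, model.pi) / ncat
    return float(np.sum(np.log(site_lik) + logscale))


@dataclass
class BranchOptResult:
    tree: PhyloTree
    loglik: float
    n_sweeps: int


def optimize_branch_lengths(tree: PhyloTree, aln: Alignment, model: GTRModel,
                            tol: float = 1e-6, max_sweeps: int = 20,
                            max_length: float = 20.0) -> BranchOptResult:
    """Coordinate-wise branch-length optimisation (Brent per branch).

    Sweeps over all branches, maximising the full-tree log-likelihood in each
    branch length, until an entire sweep improves the log-likelihood by less
    than ``tol``.  The log-likelihood is non-decreasing versus the input.
    """
    work = tree.copy()
    eig = EigenGTR.from_model(model)
    current = tree_loglik(work, aln, model, eig)
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        before = current
        for node in work.branches():
            orig = node.length

            def neg(t: float, _node=node) -> float:
                _node.length = t
                return -tree_loglik(work, aln, model, eig)

            res = minimize_scalar(neg, bounds=(0.0, max_length),
                                  method="bounded",
                                  options={"xatol": 1e-10})
            if -res.fun >= current:
                node.length = float(res.x)
                current = -float(res.fun)
            else:  # bounded search regressed; keep the previous value
                node.length = orig
        if current - before < tol:
            break
    return BranchOptResult(tree=work, loglik=current, n_sweeps=sweeps)


@dataclass
class AlphaFitResult:
    alpha: float
    loglik: float
    at_bound: bool


def fit_alpha(tree: PhyloTree, aln: Alignment, model: GTRModel,
              bounds: tuple[float, float] = (0.02, 100.0),
              tol: float = 1e-6) -> AlphaFitResult:
    """Maximum-likelihood gamma shape on a fixed tree.

    Optimises log(alpha) by bounded Brent search.  A solution within 1% of
    either search bound is flagged ``at_bound`` (e.g. rate-homogeneous data
    push alpha to the upper bound).
    """
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError("invalid alpha bounds")

    def neg(log_a: float) -> float:
        return -tree_loglik(tree, aln, model.with_alpha(float(np.exp(log_a))))

    res = minimize_scalar(neg, bounds=(np.log(lo), np.log(hi)), method="bounded",
                          options={"xatol": tol})
    alpha = float(np.exp(res.x))
    at_bound = alpha <= lo * 1.01 or alpha >= hi * 0.99
    return AlphaFitResult(alpha=alpha, loglik=-float(res.fun), at_bound=at_bound)
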