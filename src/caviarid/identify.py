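"""Species identification of query barcode sequences.

Two independent lines of evidence are combined:

* a best-hit screen — percent identity of the query against every reference
  sequence of the marker under MegaBLAST-like local-alignment scoring; and
* maximum-likelihood placement — the query is attached at the midpoint of
  every edge of the marker's reference tree, the pendant branch length is
  optimised, and the edge with the highest attachment log-likelihood wins,
  with likelihood-weight ratios reported across edges.

The species caller is group-aware: species that the marker cannot resolve
(e.g. the *A. gueldenstaedtii* complex) are never called at species level;
queries landing among them receive the group call instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .likelihood import Alignment, sequence_conditionals
from .phylo import PhyloTree
from .refdb import ReferenceDB, SpeciesGroup
from .substitution import EigenGTR, GTRModel
from .treesearch import bipartition_support


@dataclass(frozen=True)
class AlignScoring:
    """Local-alignment scores (MegaBLAST-like defaults)."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0

    def aligner(self) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.match_score = self.match
        al.mismatch_score = self.mismatch
        al.open_gap_score = self.gap_open + self.gap_extend
        al.extend_gap_score = self.gap_extend
        return al


DEFAULT_SCORING = AlignScoring()

_ACGT = np.zeros(256, dtype=bool)
for _ch in "ACGTacgt":
    _ACGT[ord(_ch)] = True
_GAPLIKE = np.zeros(256, dtype=bool)
for _ch in "-.?":
    _GAPLIKE[ord(_ch)] = True


def percent_identity(query: str, reference: str,
                     scoring: AlignScoring = DEFAULT_SCORING
                     ) -> tuple[float, int, float]:
    """Identity over the best local alignment of two sequences.

    Returns ``(percent_identity, aligned_length, score)``; symmetric in its
    arguments.  Identity is matches over aligned columns (gap columns count
    against identity).
    """
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    aligner = scoring.aligner()
    alns = aligner.align(query.upper(), reference.upper())
    best = alns[0]
    counts = best.counts()
    aligned_len = counts.identities + counts.mismatches + counts.gaps
    if aligned_len == 0:
        return 0.0, 0, float(best.score)
    identity = 100.0 * counts.identities / aligned_len
    return identity, int(aligned_len), float(best.score)


def _columnwise_identity(query: str, refs: np.ndarray,
                         scoring: AlignScoring) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised identity of an in-coordinates query against a library matrix.

    ``refs`` is a (n_refs, L) uint8 byte matrix.  Columns where either side is
    gap-like are excluded; mismatches at ambiguity codes count as mismatches,
    matching the conservative behaviour of the alignment route on clean data.
    """
    q = np.frombuffer(query.upper().encode(), dtype=np.uint8)
    both = ~_GAPLIKE[q][None, :] & ~_GAPLIKE[refs]
    matches = ((refs == q[None, :]) & both).sum(axis=1).astype(float)
    lengths = both.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        identity = np.where(lengths > 0, 100.0 * matches / lengths, 0.0)
    score = matches * scoring.match + (lengths - matches) * scoring.mismatch
    return identity, lengths.astype(int), score


@dataclass(frozen=True)
class Hit:
    ref_id: str
    species: str
    identity: float
    aligned_length: int
    score: float


@dataclass
class HitReport:
    """Ranked reference hits (score-descending; ties broken by reference id)."""

    marker: str
    hits: list[Hit]

    @property
    def top(self) -> Hit:
        return self.hits[0]

    def tied_species(self, margin: float) -> frozenset:
        """Species of hits within ``margin`` identity points of the best hit."""
        best = self.top.identity
        return frozenset(h.species for h in self.hits
                         if best - h.identity <= margin)


def best_hits(query: str, db: ReferenceDB, marker: str,
              scoring: AlignScoring = DEFAULT_SCORING) -> HitReport:
    """Score a query against every reference sequence of a marker.

    Queries already in reference alignment coordinates (same length as the
    library) are scored by direct column comparison; anything else goes
    through the local aligner per reference.
    """
    refs = db.refs[marker]
    if not refs:
        raise ValueError(f"empty reference library for marker {marker}")
    aln = db.alignment(marker)
    if len(query) == aln.n_sites:
        mat = db.cache(("bytes", marker), lambda: np.vstack(
            [np.frombuffer(s.upper().encode(), dtype=np.uint8) for s in aln.seqs]))
        ident, lengths, scores = _columnwise_identity(query, mat, scoring)
        hits = [Hit(r.id, r.species, float(i), int(n), float(s))
                for r, i, n, s in zip(refs, ident, lengths, scores)]
    else:
        hits = []
        for r in refs:
            i, n, s = percent_identity(query, r.sequence, scoring)
            hits.append(Hit(r.id, r.species, i, n, s))
    hits.sort(key=lambda h: (-h.score, h.ref_id))
    return HitReport(marker=marker, hits=hits)


# ---------------------------------------------------------------------------
# maximum-likelihood placement

@dataclass(frozen=True)
class PlacementEdge:
    edge_id: str
    species_below: frozenset
    tip_name: str | None  # set when the edge is a pendant (tip) edge


@dataclass
class Placement:
    """Attachment of a query to one edge of the reference tree."""

    edge_id: str
    loglik: float
    pendant_length: float
    weights: dict  # edge_id -> likelihood-weight ratio (sums to 1)
    species_below: frozenset
    tip_name: str | None = None


class PlacementEngine:
    """Precomputed per-edge midpoint contexts for fast query placement.

    For every edge the conditional likelihood of the full reference alignment
    is split at the edge midpoint into the clade-side and rest-of-tree
    messages; their product is the context ``C``.  A query attaches with a
    pendant branch of length ``t``: per site, the likelihood is
    ``mean_k sum_m C[k,m] * (P(t r_k) q)[m]``, so evaluating an attachment
    costs one matrix contraction instead of a full pruning pass.
    """

    def __init__(self, tree: PhyloTree, aln: Alignment, model: GTRModel):
        self.model = model
        self.eig = EigenGTR.from_model(model)
        self.rates = model.category_rates()
        ncat, n_sites = len(self.rates), aln.n_sites
        pi = model.pi
        inside: dict[int, np.ndarray] = {}
        in_scale: dict[int, np.ndarray] = {}
        post = list(tree.postorder())
        for node in post:
            if node.is_leaf:
                cond = aln.conditional(node.name)
                inside[id(node)] = np.broadcast_to(
                    cond, (ncat, n_sites, 4)).copy()
                in_scale[id(node)] = np.zeros(n_sites)
                continue
            part = np.ones((ncat, n_sites, 4))
            sc = np.zeros(n_sites)
            for child in node.children:
                p = self.eig.transition_matrices(child.length * self.rates)
                part *= np.einsum("kij,klj->kli", p, inside[id(child)])
                sc += in_scale[id(child)]
            mx = part.max(axis=(0, 2))
            part /= mx[None, :, None]
            sc += np.log(mx)
            inside[id(node)] = part
            in_scale[id(node)] = sc
        # outside pass (root-to-tip); out[v] lives at parent(v), includes pi
        out: dict[int, np.ndarray] = {}
        out_scale: dict[int, np.ndarray] = {}
        msg: dict[int, np.ndarray] = {}
        for node in post:
            if node.parent is not None:
                p = self.eig.transition_matrices(node.length * self.rates)
                msg[id(node)] = np.einsum("kij,klj->kli", p, inside[id(node)])
        for node in reversed(post):  # preorder
            if node.parent is None:
                above = np.broadcast_to(pi, (ncat, n_sites, 4)).copy()
                above_scale = np.zeros(n_sites)
            else:
                p = self.eig.transition_matrices(node.length * self.rates)
                above = np.einsum("kij,kli->klj", p, out[id(node)])
                above_scale = out_scale[id(node)]
            for child in node.children:
                o = above.copy()
                sc = above_scale.copy()
                for sib in node.children:
                    if sib is child:
                        continue
                    o *= msg[id(sib)]
                    sc += in_scale[id(sib)]
                mx = o.max(axis=(0, 2))
                o /= mx[None, :, None]
                sc += np.log(mx)
                out[id(child)] = o
                out_scale[id(child)] = sc
        # midpoint contexts per edge
        edges: list[PlacementEdge] = []
        contexts: list[np.ndarray] = []
        scales: list[np.ndarray] = []
        species_by_tip = {}
        self._tips_below: dict[int, frozenset] = {}
        for node in post:
            if node.is_leaf:
                self._tips_below[id(node)] = frozenset([node.name])
            else:
                self._tips_below[id(node)] = frozenset().union(
                    *(self._tips_below[id(c)] for c in node.children))
        for idx, node in enumerate(post):
            if node.parent is None:
                continue
            half = self.eig.transition_matrices(
                0.5 * node.length * self.rates)
            down = np.einsum("kmj,klj->klm", half, inside[id(node)])
            up = np.einsum("kim,kli->klm", half, out[id(node)])
            ctx = down * up
            sc = in_scale[id(node)] + out_scale[id(node)]
            mx = ctx.max(axis=(0, 2))
            ctx /= mx[None, :, None]
            sc += np.log(mx)
            tips = self._tips_below[id(node)]
            edge = PlacementEdge(
                edge_id=node.name if node.is_leaf else f"edge{idx}",
                species_below=tips,
                tip_name=node.name if node.is_leaf else None)
            edges.append(edge)
            contexts.append(ctx)
            scales.append(sc)
        self.edges = edges
        self.contexts = np.stack(contexts)       # (E, K, L, 4)
        self.scales = np.stack(scales)           # (E, L)
        self.scale_sums = self.scales.sum(axis=1)
        self.ncat = ncat
        self.n_sites = n_sites
        self.grid = np.array([1e-6, 1e-4, 1e-3, 3e-3, 0.01, 0.03, 0.1, 0.3])
        self._grid_pt = np.stack(
            [self.eig.transition_matrices(t * self.rates)
             for t in self.grid]).transpose(0, 1, 3, 2).copy()  # (T, K, q, m)
        # contexts rearranged for batched matmul: (K*L, E, 4)
        self._ctx_bmm = np.ascontiguousarray(
            self.contexts.transpose(1, 2, 0, 3).reshape(
                ncat * n_sites, len(edges), 4))
        self.ref_loglik = self._reference_loglik()

    def _reference_loglik(self) -> float:
        # likelihood of the reference data from any edge context; used as a
        # construction self-check and exposed for diagnostics
        c = self.contexts[0].sum(axis=2).mean(axis=0)  # (L,)
        return float(np.sum(np.log(c) + self.scales[0]))

    def _site_logliks(self, qcond: np.ndarray, t: float,
                      edge_indices=None) -> np.ndarray:
        ctx = self.contexts if edge_indices is None else self.contexts[edge_indices]
        sc = self.scales if edge_indices is None else self.scales[edge_indices]
        p = self.eig.transition_matrices(t * self.rates)  # (K, 4, 4)
        w = np.einsum("kmq,lq->klm", p, qcond)            # (K, L, 4)
        v = np.einsum("eklm,klm->el", ctx, w) / self.ncat
        return np.log(np.clip(v, 1e-300, None)).sum(axis=1) + sc.sum(axis=1)

    def _edge_logliks_multi(self, qcond: np.ndarray, ts: np.ndarray,
                            edge_idx: int) -> np.ndarray:
        """Attachment log-likelihood on one edge for several pendant lengths."""
        p = self.eig.transition_matrices(np.asarray(ts)[:, None] * self.rates)
        w = np.einsum("tkmq,lq->tklm", p, qcond, optimize=True)
        v = np.einsum("klm,tklm->tl", self.contexts[edge_idx], w,
                      optimize=True) / self.ncat
        return (np.log(np.clip(v, 1e-300, None)).sum(axis=1)
                + self.scale_sums[edge_idx])

    def place(self, query: str, max_pendant: float = 2.0) -> Placement:
        qcond = sequence_conditionals(query.upper())
        # all edges x all grid pendant lengths via batched matmuls
        ncat, n_sites = self.ncat, self.n_sites
        n_grid, n_edges = len(self.grid), len(self.edges)
        w = qcond @ self._grid_pt                   # (T, K, L, 4)
        w2 = np.ascontiguousarray(
            w.transpose(1, 2, 3, 0).reshape(ncat * n_sites, 4, n_grid))
        v = (self._ctx_bmm @ w2).reshape(
            ncat, n_sites, n_edges, n_grid).sum(axis=0) / ncat  # (L, E, T)
        ll = (np.log(np.clip(v, 1e-300, None)).sum(axis=0).T
              + self.scale_sums[None, :])           # (T, E)
        per_edge = ll.max(axis=0)
        per_edge_t = self.grid[ll.argmax(axis=0)]
        best_idx = int(np.argmax(per_edge))
        # refine the pendant length on the winning edge by zooming grids
        t_best, ll_best = per_edge_t[best_idx], per_edge[best_idx]
        width = 4.0
        for _ in range(2):
            ts = np.clip(t_best * np.logspace(-np.log10(width), np.log10(width), 7),
                         1e-9, max_pendant)
            lls = self._edge_logliks_multi(qcond, ts, best_idx)
            j = int(np.argmax(lls))
            if lls[j] > ll_best:
                t_best, ll_best = float(ts[j]), float(lls[j])
            width = width ** 0.4
        per_edge[best_idx] = ll_best
        per_edge_t[best_idx] = t_best
        rel = np.exp(per_edge - per_edge.max())
        weights = rel / rel.sum()
        edge = self.edges[best_idx]
        return Placement(edge_id=edge.edge_id,
                         loglik=float(per_edge[best_idx]),
                         pendant_length=float(per_edge_t[best_idx]),
                         weights={e.edge_id: float(w)
                                  for e, w in zip(self.edges, weights)},
                         species_below=edge.species_below,
                         tip_name=edge.tip_name)


def placement_engine(db: ReferenceDB, marker: str,
                     model: GTRModel | None = None) -> PlacementEngine:
    model = model or db.model(marker)
    key = ("placement", marker, id(model))
    return db.cache(key, lambda: PlacementEngine(db.trees[marker],
                                                 db.alignment(marker), model))


def map_to_profile(query: str, db: ReferenceDB, marker: str,
                   hits: HitReport | None = None,
                   scoring: AlignScoring = DEFAULT_SCORING) -> str | None:
    """Express a query in the marker's reference alignment coordinates.

    Queries already at the aligned length pass through unchanged.  Otherwise
    the query is locally aligned to its best-hit reference and mapped through
    that reference's column coordinates; query-only insertions are discarded.
    Returns None when no usable alignment exists.
    """
    aln = db.alignment(marker)
    if len(query) == aln.n_sites:
        return query.upper()
    hits = hits or best_hits(query, db, marker, scoring)
    ref_seq = aln.get(hits.top.ref_id)
    ref_cols = [i for i, c in enumerate(ref_seq) if not _GAPLIKE[ord(c)]]
    degapped = "".join(ref_seq[i] for i in ref_cols)
    aligner = scoring.aligner()
    try:
        best = aligner.align(query.upper(), degapped)[0]
    except (ValueError, IndexError):
        return None
    out = ["-"] * aln.n_sites
    q_aln, r_aln = best.aligned
    for (qs, qe), (rs, re) in zip(q_aln, r_aln):
        for qi, ri in zip(range(qs, qe), range(rs, re)):
            out[ref_cols[ri]] = query[qi].upper()
    if all(c == "-" for c in out):
        return None
    return "".join(out)


def place_query(query: str, db: ReferenceDB, marker: str,
                model: GTRModel | None = None,
                hits: HitReport | None = None) -> Placement | None:
    """ML placement of a query on the marker's reference tree (or None)."""
    mapped = map_to_profile(query, db, marker, hits=hits)
    if mapped is None:
        return None
    engine = placement_engine(db, marker, model)
    placement = engine.place(mapped)
    placement.species_below = frozenset(
        db.species_of(marker, t) for t in placement.species_below)
    return placement


# ---------------------------------------------------------------------------
# bootstrap support (re-exported convenience over the tree-search machinery)

def bootstrap_support(best_tree: PhyloTree, bootstrap_trees) -> dict:
    """Per-node support: percent of bootstrap trees containing each bipartition."""
    return bipartition_support(best_tree, list(bootstrap_trees))


# ---------------------------------------------------------------------------
# species calling

@dataclass(frozen=True)
class CallThresholds:
    """Decision thresholds for species calling.

    ``min_identity`` anchors to the identity range regarded as a solid
    barcode match (98%); ``tie_margin`` is the identity band (percentage
    points) within which hits are treated as tied for group detection;
    ``min_support`` is the bootstrap percentage regarded as well supported.
    """

    min_identity: float = 98.0
    tie_margin: float = 0.5
    min_support: float = 90.0


DEFAULT_THRESHOLDS = CallThresholds()


@dataclass
class SpeciesCall:
    """Outcome of identifying one query at one marker."""

    marker: str
    kind: str                      # 'species' | 'group' | 'unresolved'
    species: str | None = None
    group: SpeciesGroup | None = None
    reason: str | None = None
    top_identity: float | None = None
    placement: Placement | None = None
    hits: HitReport | None = None

    @property
    def species_set(self) -> frozenset:
        if self.kind == "species":
            return frozenset({self.species})
        if self.kind == "group":
            return frozenset(self.group.members)
        return frozenset()

    @property
    def resolved(self) -> bool:
        return self.kind in ("species", "group")

    @property
    def display(self) -> str:
        if self.kind == "species":
            return self.species
        if self.kind == "group":
            return self.group.display
        return f"unresolved ({self.reason})"


def call_species(hits: HitReport, placement: Placement | None,
                 db: ReferenceDB, marker: str,
                 thresholds: CallThresholds = DEFAULT_THRESHOLDS) -> SpeciesCall:
    """Group-aware species call from hits plus placement.

    The candidate set is the union of near-tied best-hit species and the
    species of the placement edge's subtending clade.  A single candidate is
    called at species level unless its group is unresolvable at this marker,
    in which case the group is called; candidates spanning one unresolvable
    group give the group call; anything wider is unresolved.
    """
    base = dict(marker=marker, top_identity=hits.top.identity,
                placement=placement, hits=hits)
    if hits.top.identity < thresholds.min_identity:
        return SpeciesCall(kind="unresolved", reason="low_identity", **base)
    cands = set(hits.tied_species(thresholds.tie_margin))
    if placement is not None:
        cands |= set(placement.species_below)
    if len(cands) == 1:
        sp = next(iter(cands))
        group = db.group_of(sp, marker)
        if group is not None:
            return SpeciesCall(kind="group", group=group, **base)
        return SpeciesCall(kind="species", species=sp, **base)
    for g in db.groups:
        if g.unresolvable_at(marker) and cands <= set(g.members):
            return SpeciesCall(kind="group", group=g, **base)
    return SpeciesCall(kind="unresolved", reason="ambiguous", **base)
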