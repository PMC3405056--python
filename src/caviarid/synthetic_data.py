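"""Synthetic caviar-market surveys with known ground truth.

The generator emulates the structure of a marketplace barcoding survey:
a reference barcode panel simulated along a genus-level phylogeny (with the
*A. gueldenstaedtii* complex and *Scaphirhynchus* sitting on near-zero
branches so they are genuinely unresolvable), lots drawn from a market-label
distribution, a true mislabeling rate with a label-specific substitution
table, occasional pooling of eggs from several individuals (multiple
haplotypes per tin), and per-marker amplification dropout.  Random streams
are split hierarchically (survey -> lot -> egg) so one lot's draws never
perturb another's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phylo import PhyloTree
from .refdb import (DEFAULT_GROUPS, DEFAULT_POLICY, MARKERS, ReferenceDB,
                    ReferenceSequence, allowed_species, parse_label,
                    species_id, species_name)
from .simulate import evolve_sequence, simulate_alignment
from .substitution import GTRModel
from .workflow import EggRecord, Lot

#: Genus-level reference phylogeny (branch lengths in substitutions/site).
#: The gueldenstaedtii complex and the two Scaphirhynchus species sit on
#: near-zero branches: mtDNA cannot resolve them, by construction.
DEFAULT_SPECIES_TREE = (
    "(Esox_lucius:0.35,(Polyodon_spathula:0.10,"
    "((Scaphirhynchus_platorynchus:0.0002,Scaphirhynchus_albus:0.0002):0.08,"
    "(Huso_huso:0.06,((Acipenser_transmontanus:0.05,Acipenser_stellatus:0.045)"
    ":0.012,(Acipenser_ruthenus:0.04,(Acipenser_baerii:0.025,"
    "((Acipenser_gueldenstaedtii:0.0002,Acipenser_naccarii:0.0002):0.0002,"
    "Acipenser_persicus:0.0003):0.022):0.012):0.012):0.012):0.025):0.03):0.12);"
)

#: Market-label mix of a (synthetic) survey, weights proportional to how
#: often each product appears on the market.
DEFAULT_LABEL_FREQS = {
    "Beluga": 7,
    "Sevruga": 21,
    "Osetra (Acipenser baerii), farmed": 8,
    "Osetra (Acipenser gueldenstaedtii)": 7,
    "Osetra (Acipenser persicus)": 4,
    "Osetra": 14,
    "White (Acipenser transmontanus)": 6,
    "Paddlefish": 12,
    "Hackleback": 8,
    "American": 4,
    "Black Caviar": 1,
}

#: What a correctly labeled tin actually contains.
DEFAULT_TRUE_SPECIES = {
    "Beluga": {"Huso huso": 1.0},
    "Sevruga": {"Acipenser stellatus": 1.0},
    "Osetra (Acipenser baerii), farmed": {"Acipenser baerii": 1.0},
    "Osetra (Acipenser gueldenstaedtii)": {"Acipenser gueldenstaedtii": 1.0},
    "Osetra (Acipenser persicus)": {"Acipenser persicus": 1.0},
    "Osetra": {"Acipenser baerii": 0.5, "Acipenser gueldenstaedtii": 0.5},
    "White (Acipenser transmontanus)": {"Acipenser transmontanus": 1.0},
    "Paddlefish": {"Polyodon spathula": 1.0},
    "Hackleback": {"Scaphirhynchus platorynchus": 1.0},
    "American": {"Polyodon spathula": 0.5, "Acipenser transmontanus": 0.5},
    "Black Caviar": {"Acipenser stellatus": 1.0},
}

#: What a mislabeled tin contains instead, by label ("*" is the fallback):
#: cheaper or farmed species replace premium Caspian products, and a
#: non-acipenseriform substitute stands in for the worst fraud.
DEFAULT_SUBSTITUTIONS = {
    "Beluga": {"Acipenser gueldenstaedtii": 0.5, "Acipenser baerii": 0.5},
    "Sevruga": {"Polyodon spathula": 0.5, "Acipenser ruthenus": 0.3,
                "Acipenser gueldenstaedtii": 0.2},
    "Osetra (Acipenser baerii), farmed": {"Acipenser gueldenstaedtii": 1.0},
    "Osetra (Acipenser gueldenstaedtii)": {"Acipenser baerii": 1.0},
    "Osetra (Acipenser persicus)": {"Acipenser baerii": 1.0},
    "Osetra": {"Acipenser ruthenus": 0.5, "Esox lucius": 0.5},
    "White (Acipenser transmontanus)": {"Polyodon spathula": 1.0},
    "*": {"Esox lucius": 1.0},
}


@dataclass
class SimConfig:
    """Study conditions for one synthetic survey."""

    seed: int = 0
    n_lots: int = 90
    p_mislabel: float = 0.10
    label_freqs: dict = field(default_factory=lambda: dict(DEFAULT_LABEL_FREQS))
    true_species: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_SPECIES))
    substitutions: dict = field(
        default_factory=lambda: dict(DEFAULT_SUBSTITUTIONS))
    eggs_per_lot: int = 14
    pooling_prob: float = 0.10
    pooling_hap_weights: dict = field(default_factory=lambda: {2: 0.8, 3: 0.2})
    dropout: dict = field(
        default_factory=lambda: {"cytb": 0.03, "dloop": 0.05, "cox1": 0.0})
    channel_probs: dict = field(
        default_factory=lambda: {"in-store": 0.45, "internet": 0.55})
    year_probs: dict = field(default_factory=lambda: {2006: 0.44, 2008: 0.56})
    # reference-panel parameters
    species_tree: str = DEFAULT_SPECIES_TREE
    n_per_species: int = 2
    within_species_divergence: float = 0.002
    egg_branch: float = 0.003
    seq_len: dict = field(
        default_factory=lambda: {"cytb": 600, "dloop": 500, "cox1": 650})
    # gamma shapes: the two main markers use the shapes typical of sturgeon
    # cytb and control-region alignments; cox1 uses a generic fish value
    alpha: dict = field(
        default_factory=lambda: {"cytb": 0.223717, "dloop": 0.345333,
                                 "cox1": 0.25})
    rate_scale: dict = field(
        default_factory=lambda: {"cytb": 1.0, "dloop": 1.4, "cox1": 0.8})
    gtr_freqs: tuple = (0.27, 0.27, 0.15, 0.31)
    gtr_rates: tuple = (1.0, 6.0, 1.0, 1.0, 6.0, 1.0)
    ncat: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_mislabel <= 1.0:
            raise ValueError("p_mislabel must be in [0, 1]")
        for mk, p in self.dropout.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"dropout[{mk}] must be in [0, 1]")
        for mk, n in self.seq_len.items():
            if n < 100:
                raise ValueError(f"seq_len[{mk}] must be >= 100")

    def model(self, marker: str) -> GTRModel:
        return GTRModel(freqs=self.gtr_freqs, rates=self.gtr_rates,
                        alpha=self.alpha[marker], ncat=self.ncat)


@dataclass
class LotTruth:
    true_species: str
    mislabeled: bool
    label_text: str
    n_haplotypes: int
    haplotypes: dict            # marker -> list of sequences
    dropout: dict               # (egg_index, marker) -> bool


@dataclass
class GroundTruth:
    lots: dict = field(default_factory=dict)  # lot_id -> LotTruth

    @property
    def n_mislabeled(self) -> int:
        return sum(t.mislabeled for t in self.lots.values())


def _expand_species_tree(tree: PhyloTree, n_per: int,
                         within: float) -> PhyloTree:
    """Split every species tip into ``n_per`` reference-sequence tips."""
    work = tree.copy()
    for tip in work.tips():
        sid = tip.name
        if n_per == 1:
            tip.name = f"{sid}.1"
            continue
        tip.name = None
        for k in range(1, n_per + 1):
            child = tip.add_child(type(tip)(f"{sid}.{k}", within / 2.0))
            child.parent = tip
    return PhyloTree(work.root)


def generate_references(config: SimConfig) -> ReferenceDB:
    """Simulate the per-marker reference panels along the species tree.

    Deterministic in ``config.seed``; the same seed yields a byte-identical
    library.
    """
    base = PhyloTree.from_newick(config.species_tree)
    if base.n_tips < 2:
        raise ValueError("species tree needs at least two species")
    expanded = _expand_species_tree(base, config.n_per_species,
                                    config.within_species_divergence)
    ss = np.random.SeedSequence(entropy=(config.seed, 101))
    marker_seeds = ss.spawn(len(MARKERS))
    refs: dict[str, list[ReferenceSequence]] = {}
    trees: dict[str, PhyloTree] = {}
    models: dict[str, GTRModel] = {}
    for marker, mseed in zip(MARKERS, marker_seeds):
        scaled = expanded.copy()
        for node in scaled.postorder():
            node.length *= config.rate_scale[marker]
        model = config.model(marker)
        aln = simulate_alignment(scaled, model, config.seq_len[marker],
                                 np.random.default_rng(mseed))
        refs[marker] = [
            ReferenceSequence(name, species_name(name.rsplit(".", 1)[0]),
                              marker, seq)
            for name, seq in zip(aln.names, aln.seqs)]
        trees[marker] = scaled
        models[marker] = model
    return ReferenceDB(refs, trees, groups=DEFAULT_GROUPS,
                       policy=DEFAULT_POLICY, models=models)


def _weighted_choice(rng: np.random.Generator, table: dict):
    keys = list(table)
    w = np.array([table[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def _haplotype_set(config: SimConfig, db: ReferenceDB, species: str,
                   n_hap: int, rng: np.random.Generator) -> dict:
    """Per-marker haplotype sequences for one tin, distinct at cytb."""
    sid = species_id(species)
    haps: dict[str, list[str]] = {mk: [] for mk in MARKERS}
    for _ in range(n_hap):
        for attempt in range(25):
            cand = {mk: evolve_sequence(db.alignment(mk).get(f"{sid}.1"),
                                        config.egg_branch * config.rate_scale[mk],
                                        db.model(mk), rng)
                    for mk in MARKERS}
            if cand["cytb"] not in haps["cytb"]:
                break
        for mk in MARKERS:
            haps[mk].append(cand[mk])
    return haps


def generate_survey(config: SimConfig, db: ReferenceDB,
                    sequences: bool = True) -> tuple[list[Lot], GroundTruth]:
    """Draw one synthetic survey of ``config.n_lots`` tins.

    Each lot draws a label, a Bernoulli(p) mislabeling event, a true species
    (label-consistent or from the substitution table), a haplotype count from
    the pooling distribution, and per-egg per-marker dropout.  The ground
    truth records the mislabeling flag before dropout is applied.

    With ``sequences=False`` only labels, species and flags are drawn (lots
    carry no eggs); the per-lot random streams guarantee the flags are the
    ones the full generator would produce, which makes design-level checks
    of the generator cheap.
    """
    ss = np.random.SeedSequence(entropy=(config.seed, 202))
    lot_seeds = ss.spawn(config.n_lots)
    lots: list[Lot] = []
    truth = GroundTruth()
    for i, lseed in enumerate(lot_seeds):
        rng = np.random.default_rng(lseed)
        lot_id = f"L{i + 1:03d}"
        label_text = _weighted_choice(rng, config.label_freqs)
        label = parse_label(label_text)
        mislabeled = bool(rng.random() < config.p_mislabel)
        if mislabeled:
            table = config.substitutions.get(label_text,
                                             config.substitutions.get("*"))
            if table is None:
                raise ValueError(f"no substitution entry for {label_text!r}")
            true_sp = _weighted_choice(rng, table)
        else:
            true_sp = _weighted_choice(rng, config.true_species[label_text])
        allowed = allowed_species(label, db.policy, db.groups)
        if mislabeled == (true_sp in allowed):
            raise ValueError(
                f"substitution table inconsistent with label policy for "
                f"{label_text!r} -> {true_sp}")
        n_hap = 1
        if rng.random() < config.pooling_prob:
            n_hap = int(_weighted_choice(rng, config.pooling_hap_weights))
        n_hap = min(n_hap, config.eggs_per_lot)
        haps: dict = {mk: [] for mk in MARKERS}
        eggs: list[EggRecord] = []
        dropout_log: dict = {}
        if sequences:
            haps = _haplotype_set(config, db, true_sp, n_hap, rng)
        for e in range(config.eggs_per_lot if sequences else 0):
            hap_idx = e if e < n_hap else int(rng.integers(0, n_hap))
            outcomes = {}
            for mk in MARKERS:
                dropped = bool(rng.random() < config.dropout[mk])
                dropout_log[(e, mk)] = dropped
                outcomes[mk] = None if dropped else haps[mk][hap_idx]
            eggs.append(EggRecord(lot_id=lot_id, egg_index=e, outcomes=outcomes))
        channel = _weighted_choice(rng, config.channel_probs)
        year = int(_weighted_choice(rng, config.year_probs))
        lots.append(Lot(lot_id=lot_id, label=label, channel=channel,
                        year=year, eggs=eggs))
        truth.lots[lot_id] = LotTruth(
            true_species=true_sp, mislabeled=mislabeled,
            label_text=label_text, n_haplotypes=n_hap, haplotypes=haps,
            dropout=dropout_log)
    return lots, truth


def evaluate_survey(results, truth: GroundTruth) -> dict:
    """Verdict sensitivity/specificity of pipeline results against truth.

    Lots whose extraction failed end-to-end are excluded (no verdict is
    possible); sensitivity is over truly mislabeled lots, specificity over
    truly consistent ones.
    """
    tp = fp = tn = fn = 0
    for r in results:
        if not r.testable:
            continue
        true_flag = truth.lots[r.lot_id].mislabeled
        pred = r.is_mislabeled
        tp += pred and true_flag
        fp += pred and not true_flag
        tn += (not pred) and (not true_flag)
        fn += (not pred) and true_flag
    out = {"tp": tp, "fp": fp, "tn": tn, "fn": fn,
           "n_testable": tp + fp + tn + fn}
    out["sensitivity"] = tp / (tp + fn) if (tp + fn) else float("nan")
    out["specificity"] = tn / (tn + fp) if (tn + fp) else float("nan")
    return out
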