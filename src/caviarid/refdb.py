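"""Reference barcode library, trade-label grammar, and label policy.

This module holds everything the identification pipeline needs to know about
the reference side of the problem: per-marker aligned barcode libraries with
species metadata, per-marker reference trees, species groups that mtDNA
cannot resolve (e.g. the *Acipenser gueldenstaedtii* complex), and the policy
mapping a tin's trade label to the set of species it may legally contain.

Markets and species follow the North American caviar trade: "beluga"
(*Huso huso*), "sevruga" (*A. stellatus*), "osetra" (the *gueldenstaedtii*
complex plus farmed *A. baerii*), "white" (*A. transmontanus*), "paddlefish"
(*Polyodon spathula*), "hackleback" (*Scaphirhynchus platorynchus*) and
generic "american" products.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import yaml

from .likelihood import Alignment
from .phylo import PhyloTree
from .substitution import GTRModel

MARKERS = ("cytb", "dloop", "cox1")

MARKET_NAMES = ("beluga", "sevruga", "osetra", "white", "paddlefish",
                "hackleback", "american", "other")

#: Binomials the label parser recognises (trade-relevant Acipenseriformes
#: plus common substitutes seen in market surveys).
KNOWN_SPECIES = (
    "Huso huso",
    "Acipenser stellatus",
    "Acipenser gueldenstaedtii",
    "Acipenser naccarii",
    "Acipenser persicus",
    "Acipenser baerii",
    "Acipenser ruthenus",
    "Acipenser transmontanus",
    "Acipenser nudiventris",
    "Acipenser schrenckii",
    "Polyodon spathula",
    "Scaphirhynchus platorynchus",
    "Scaphirhynchus albus",
    "Esox lucius",
)

_GENUS_BY_INITIAL = {"a": "Acipenser", "h": "Huso", "p": "Polyodon",
                     "s": "Scaphirhynchus", "e": "Esox"}

#: Species whose caviar is legitimately traded (used for the permissive
#: "other" market bucket: an unparseable label is only called mislabeled when
#: the content is not an acipenseriform at all).
ACIPENSERIFORM_SPECIES = frozenset(s for s in KNOWN_SPECIES if s != "Esox lucius")


class ConfigError(ValueError):
    """Raised for incomplete or inconsistent policy/reference configuration."""


class ReferenceDBError(ValueError):
    """Raised when a reference library violates its invariants."""


def species_id(name: str) -> str:
    """Filesystem/tree-safe species identifier ('Acipenser_baerii')."""
    return name.replace(" ", "_")


def species_name(ident: str) -> str:
    return ident.replace("_", " ")


def abbreviate(name: str) -> str:
    genus, _, rest = name.partition(" ")
    return f"{genus[0]}. {rest}" if rest else name


# ---------------------------------------------------------------------------
# trade labels

@dataclass(frozen=True)
class TradeLabel:
    """A parsed product label.

    ``market`` is the trade name; ``claimed_species`` is an explicit binomial
    claim when the label carries one; ``origin`` keeps any other
    parenthesised qualifier verbatim (e.g. "Caspian Sea").
    """

    raw: str
    market: str
    claimed_species: str | None = None
    origin: str | None = None
    farmed: bool = False


_MARKET_ALIASES = {
    "beluga": "beluga", "sevruga": "sevruga",
    "osetra": "osetra", "ostera": "osetra", "ossetra": "osetra",
    "white": "white", "paddlefish": "paddlefish",
    "hackleback": "hackleback", "american": "american",
}

_LABEL_RE = re.compile(r"^\s*(?P<head>[^(]*?)\s*(?:\((?P<qual>[^)]*)\))?\s*$")


def _parse_species(text: str) -> str | None:
    text = text.strip().rstrip(".")
    if not text or " x " in f" {text.lower()} ":  # hybrid claims stay verbatim
        return None
    for sp in KNOWN_SPECIES:
        if text.lower() == sp.lower():
            return sp
    m = re.match(r"^([A-Za-z])\.?\s+([a-z]+)$", text)
    if m:
        genus = _GENUS_BY_INITIAL.get(m.group(1).lower())
        if genus:
            cand = f"{genus} {m.group(2).lower()}"
            if cand in KNOWN_SPECIES:
                return cand
    return None


def parse_label(raw: str) -> TradeLabel:
    """Parse a trade-label string; total on non-empty input.

    Grammar: ``Market (qualifier)[, farmed]`` where the qualifier is an
    explicit species claim when it parses as a known binomial (full or
    abbreviated like "A. baerii"), otherwise free origin text.  Unknown
    market names degrade to market="other".
    """
    if not raw or not raw.strip():
        raise ValueError("label text must be non-empty")
    text = raw.strip()
    farmed = bool(re.search(r"\bfarm(ed)?\b", text, re.IGNORECASE))
    text = re.sub(r",?\s*\bfarm(ed)?\b", "", text, flags=re.IGNORECASE).strip()
    m = _LABEL_RE.match(text)
    head = (m.group("head") or "").strip() if m else text
    qual = (m.group("qual") or "").strip() if m else ""
    first = re.split(r"[\s\-,/]+", head.lower(), maxsplit=1)[0] if head else ""
    market = _MARKET_ALIASES.get(first, "other")
    claimed: str | None = None
    origin: str | None = None
    if qual and qual.lower() not in {"unspecified", ""}:
        claimed = _parse_species(qual)
        if claimed is None:
            origin = qual
    if market == "other":
        claimed = None  # unparsed labels never carry a species claim
        origin = origin or (qual or None)
    return TradeLabel(raw=raw, market=market, claimed_species=claimed,
                      origin=origin, farmed=farmed)


def format_label(label: TradeLabel) -> str:
    """Canonical text for a label; ``parse_label(format_label(x))`` fixes x."""
    head = label.market.capitalize()
    qual = label.claimed_species or label.origin
    out = f"{head} ({qual})" if qual else head
    if label.farmed:
        out += ", farmed"
    return out


# ---------------------------------------------------------------------------
# species groups and label policy

@dataclass(frozen=True)
class SpeciesGroup:
    """A set of species that some markers cannot tell apart."""

    group_id: str
    members: frozenset
    unresolvable_markers: frozenset

    def __post_init__(self) -> None:
        for mk in self.unresolvable_markers:
            if mk not in MARKERS:
                raise ConfigError(f"group {self.group_id}: unknown marker {mk!r}")

    @property
    def display(self) -> str:
        return "/".join(abbreviate(s) for s in sorted(self.members))

    def unresolvable_at(self, marker: str) -> bool:
        return marker in self.unresolvable_markers


DEFAULT_GROUPS = (
    SpeciesGroup("gueldenstaedtii_complex",
                 frozenset({"Acipenser gueldenstaedtii", "Acipenser naccarii",
                            "Acipenser persicus"}),
                 frozenset(MARKERS)),
    SpeciesGroup("scaphirhynchus",
                 frozenset({"Scaphirhynchus platorynchus",
                            "Scaphirhynchus albus"}),
                 frozenset(MARKERS)),
)


def validate_groups(groups) -> None:
    seen: set[str] = set()
    for g in groups:
        overlap = seen & set(g.members)
        if overlap:
            raise ConfigError(f"species {sorted(overlap)} appear in multiple groups")
        seen |= set(g.members)


@dataclass(frozen=True)
class LabelPolicy:
    """Market name -> species a correctly labeled tin may contain.

    An explicit species claim on the label overrides the market-name set.
    """

    markets: dict = field(default_factory=dict)

    def allowed_for_market(self, market: str) -> frozenset:
        try:
            return frozenset(self.markets[market])
        except KeyError:
            raise ConfigError(f"no label policy for market {market!r}") from None


DEFAULT_POLICY = LabelPolicy(markets={
    "beluga": frozenset({"Huso huso"}),
    "sevruga": frozenset({"Acipenser stellatus"}),
    "osetra": frozenset({"Acipenser gueldenstaedtii", "Acipenser persicus",
                         "Acipenser baerii"}),
    "white": frozenset({"Acipenser transmontanus"}),
    "paddlefish": frozenset({"Polyodon spathula"}),
    "hackleback": frozenset({"Scaphirhynchus platorynchus"}),
    "american": frozenset({"Acipenser transmontanus", "Polyodon spathula",
                           "Scaphirhynchus platorynchus"}),
    "other": ACIPENSERIFORM_SPECIES,
})


def group_closure(species_set, groups, marker: str | None = None) -> frozenset:
    """Expand species by the groups that are unresolvable at ``marker``.

    With ``marker=None`` the closure uses every group (any-marker closure).
    """
    out = set(species_set)
    for g in groups:
        if marker is not None and not g.unresolvable_at(marker):
            continue
        if out & set(g.members):
            out |= set(g.members)
    return frozenset(out)


def allowed_species(label: TradeLabel, policy: LabelPolicy,
                    groups=DEFAULT_GROUPS, marker: str | None = None) -> frozenset:
    """Species consistent with a label, closed under mtDNA indistinguishability.

    A claimed species restricts the set to that species (plus any species the
    marker cannot separate from it); otherwise the market-name policy set
    applies, with the same closure.
    """
    if label.claimed_species is not None:
        base = frozenset({label.claimed_species})
    else:
        base = policy.allowed_for_market(label.market)
    return group_closure(base, groups, marker)


# ---------------------------------------------------------------------------
# reference library

@dataclass(frozen=True)
class ReferenceSequence:
    id: str
    species: str
    marker: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ReferenceDBError(f"{self.id}: empty sequence")
        if self.marker not in MARKERS:
            raise ReferenceDBError(f"{self.id}: unknown marker {self.marker!r}")


class ReferenceDB:
    """Per-marker aligned barcode library + reference trees + policy.

    Invariants (checked on construction):

    * every tree tip resolves to exactly one reference sequence of that marker
    * all sequences of one marker share the aligned length
    * (id, marker) pairs are unique
    * every group member species occurs in at least one reference sequence
    """

    def __init__(self, refs: dict, trees: dict, groups=DEFAULT_GROUPS,
                 policy: LabelPolicy = DEFAULT_POLICY,
                 models: dict | None = None):
        self.refs = {mk: list(seqs) for mk, seqs in refs.items()}
        self.trees = dict(trees)
        self.groups = tuple(groups)
        self.policy = policy
        self.models = dict(models or {})
        self._caches: dict = {}
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        validate_groups(self.groups)
        all_species = set()
        for marker, seqs in self.refs.items():
            ids = [r.id for r in seqs]
            dup = {i for i in ids if ids.count(i) > 1}
            if dup:
                raise ReferenceDBError(
                    f"duplicate reference ids at {marker}: {sorted(dup)}")
            lengths = {len(r.sequence) for r in seqs}
            if len(lengths) > 1:
                raise ReferenceDBError(
                    f"ragged alignment at {marker}: lengths {sorted(lengths)}")
            all_species |= {r.species for r in seqs}
            tree = self.trees.get(marker)
            if tree is None:
                raise ReferenceDBError(f"no reference tree for marker {marker}")
            tips = tree.tip_names()
            missing = set(tips) - set(ids)
            if missing:
                raise ReferenceDBError(
                    f"tree tips without reference sequence at {marker}: "
                    f"{sorted(missing)}")
            extra = set(ids) - set(tips)
            if extra:
                raise ReferenceDBError(
                    f"reference sequences missing from tree at {marker}: "
                    f"{sorted(extra)}")
        for g in self.groups:
            absent = set(g.members) - all_species
            if absent:
                raise ReferenceDBError(
                    f"group {g.group_id} members not in library: {sorted(absent)}")

    # -- access ------------------------------------------------------------
    @property
    def markers(self) -> list[str]:
        return list(self.refs)

    def alignment(self, marker: str) -> Alignment:
        key = ("aln", marker)
        if key not in self._caches:
            seqs = self.refs[marker]
            self._caches[key] = Alignment([r.id for r in seqs],
                                          [r.sequence for r in seqs])
        return self._caches[key]

    def species_of(self, marker: str, ref_id: str) -> str:
        key = ("spmap", marker)
        if key not in self._caches:
            self._caches[key] = {r.id: r.species for r in self.refs[marker]}
        return self._caches[key][ref_id]

    def model(self, marker: str) -> GTRModel:
        if marker not in self.models:
            raise ConfigError(f"no substitution model configured for {marker}")
        return self.models[marker]

    def group_of(self, species: str, marker: str) -> SpeciesGroup | None:
        for g in self.groups:
            if species in g.members and g.unresolvable_at(marker):
                return g
        return None

    def cache(self, key, build):
        if key not in self._caches:
            self._caches[key] = build()
        return self._caches[key]

    # -- I/O -----------------------------------------------------------------
    def write(self, outdir) -> None:
        """Write the library as FASTA + Newick + YAML config under ``outdir``."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for marker, seqs in self.refs.items():
            with open(out / f"refs_{marker}.fasta", "w") as fh:
                for r in seqs:
                    fh.write(f">{r.id}|{species_id(r.species)}|{r.marker}\n")
                    fh.write(r.sequence + "\n")
            self.trees[marker].write(out / f"tree_{marker}.nwk")
        cfg = {
            "markets": {mk: sorted(sp) for mk, sp in self.policy.markets.items()},
            "groups": [{"id": g.group_id, "members": sorted(g.members),
                        "unresolvable_markers": sorted(g.unresolvable_markers)}
                       for g in self.groups],
            "models": {mk: {"freqs": list(m.freqs), "rates": list(m.rates),
                            "alpha": m.alpha, "ncat": m.ncat}
                       for mk, m in self.models.items()},
        }
        with open(out / "refdb.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)


def _parse_fasta_header(header: str, path) -> tuple[str, str, str]:
    parts = header.split("|")
    if len(parts) != 3:
        raise ReferenceDBError(
            f"{path}: header {header!r} is not 'id|species|marker'")
    ident, species, marker = (p.strip() for p in parts)
    return ident, species_name(species), marker


def load_reference_db(fasta_paths: dict, newick_paths: dict,
                      config_path=None, metadata=None) -> ReferenceDB:
    """Load a reference library from per-marker FASTA + Newick + YAML config.

    FASTA headers are ``id|species|marker``; a ``metadata`` mapping
    ``id -> (species, marker)`` may override header metadata.  Violated
    invariants raise :class:`ReferenceDBError` naming the offending records.
    """
    from Bio import SeqIO

    refs: dict[str, list[ReferenceSequence]] = {}
    for marker, path in fasta_paths.items():
        seqs = []
        for rec in SeqIO.parse(str(path), "fasta"):
            header = rec.description if "|" in rec.description else rec.id
            ident, species, mk = _parse_fasta_header(header, path)
            if metadata and ident in metadata:
                species, mk = metadata[ident]
            if mk != marker:
                raise ReferenceDBError(
                    f"{path}: record {ident} declares marker {mk!r}, "
                    f"expected {marker!r}")
            seqs.append(ReferenceSequence(ident, species, mk, str(rec.seq).upper()))
        refs[marker] = seqs
    trees = {mk: PhyloTree.read(p) for mk, p in newick_paths.items()}
    groups, policy, models = DEFAULT_GROUPS, DEFAULT_POLICY, {}
    if config_path is not None:
        groups, policy, models = load_policy_config(config_path)
    return ReferenceDB(refs, trees, groups=groups, policy=policy, models=models)


def load_policy_config(path):
    """Read groups, label policy and per-marker models from a YAML file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    groups = tuple(
        SpeciesGroup(g["id"], frozenset(g["members"]),
                     frozenset(g["unresolvable_markers"]))
        for g in cfg.get("groups", []))
    markets = {mk: frozenset(sp) for mk, sp in cfg.get("markets", {}).items()}
    policy = LabelPolicy(markets=markets) if markets else DEFAULT_POLICY
    models = {mk: GTRModel(freqs=tuple(m["freqs"]), rates=tuple(m["rates"]),
                           alpha=m.get("alpha"), ncat=m.get("ncat", 4))
              for mk, m in cfg.get("models", {}).items()}
    return (groups or DEFAULT_GROUPS), policy, models
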