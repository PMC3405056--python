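"""Per-lot identification workflow: marker escalation and mislabel verdicts.

One purchased tin ("lot") is identified from a single egg first, using the
cytb barcode.  The control region (D-loop) is added when the label is an
"osetra" product or when the cytb call lands in the *A. baerii* /
*A. gueldenstaedtii* / *A. naccarii* / *A. persicus* complex, where cytb
alone cannot settle the label question; cox1 is the fallback when neither
cytb nor D-loop yields a sequence.  A lot whose identification contradicts
its label is only called mislabeled after confirmatory sequencing of
additional eggs (at least nine more when available), which also counts the
distinct haplotypes present in the tin — multiple haplotypes mean roe from
more than one individual was pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .identify import (AlignScoring, CallThresholds, DEFAULT_SCORING,
                       DEFAULT_THRESHOLDS, SpeciesCall, best_hits,
                       call_species, place_query)
from .likelihood import _VALID_BYTE
from .refdb import ReferenceDB, TradeLabel, allowed_species

#: cytb calls that trigger D-loop escalation: the Ponto-Caspian/Siberian
#: complex where D-loop adds resolution.
DLOOP_TRIGGER_SPECIES = frozenset({
    "Acipenser baerii", "Acipenser gueldenstaedtii",
    "Acipenser naccarii", "Acipenser persicus",
})

MARKER_ORDER = ("cytb", "dloop", "cox1")


@dataclass
class SurveyConfig:
    """Pipeline settings for a survey run."""

    thresholds: CallThresholds = DEFAULT_THRESHOLDS
    scoring: AlignScoring = DEFAULT_SCORING
    #: confirmatory eggs added when mislabeling is suspected
    confirm_additional: int = 9
    #: test every available egg instead of stopping at ``confirm_additional``
    confirm_all: bool = False
    dloop_trigger: frozenset = DLOOP_TRIGGER_SPECIES


DEFAULT_SURVEY_CONFIG = SurveyConfig()


@dataclass
class EggRecord:
    """Sequencing outcomes for one egg: marker -> sequence or None (failure).

    A key present with value ``None`` records an attempted amplification that
    failed; an absent key means the marker was never attempted.
    """

    lot_id: str
    egg_index: int
    outcomes: dict

    def __post_init__(self) -> None:
        if not self.outcomes:
            raise ValueError(f"egg {self.lot_id}/{self.egg_index}: "
                             "at least one marker must be attempted")
        for marker, seq in self.outcomes.items():
            if seq is None:
                continue
            bad = {c for c in seq if not _VALID_BYTE[ord(c)]}
            if bad:
                raise ValueError(
                    f"egg {self.lot_id}/{self.egg_index} {marker}: "
                    f"invalid characters {sorted(bad)}")

    def sequence(self, marker: str) -> str | None:
        return self.outcomes.get(marker)


@dataclass
class Lot:
    """One purchased tin with its label metadata and available eggs."""

    lot_id: str
    label: TradeLabel
    channel: str  # 'in-store' | 'internet'
    year: int
    eggs: list
    price_per_oz: float | None = None


@dataclass
class EggCallChain:
    """Marker-by-marker calls for one egg, in escalation order."""

    calls: dict = field(default_factory=dict)  # marker -> SpeciesCall | None
    order: list = field(default_factory=list)
    final: SpeciesCall | None = None
    final_marker: str | None = None

    @property
    def failed(self) -> bool:
        return all(c is None for c in self.calls.values())


@dataclass
class LotResult:
    """Final outcome for one lot."""

    lot_id: str
    verdict: str                 # consistent | mislabeled | mixed | unresolved
    #                            # | extraction-failed | error
    markers_used: list
    final_call: SpeciesCall | None
    n_eggs_tested: int
    n_haplotypes: int
    confirmation: str            # not-needed | confirmed | partial | none
    channel: str | None = None
    year: int | None = None
    notes: list = field(default_factory=list)

    @property
    def is_mislabeled(self) -> bool:
        """Headline flag: confirmed substitutions and mixed lots both count."""
        return self.verdict in ("mislabeled", "mixed")

    @property
    def testable(self) -> bool:
        return self.verdict not in ("extraction-failed", "error")


def needs_dloop(call: SpeciesCall | None, label: TradeLabel,
                trigger: frozenset = DLOOP_TRIGGER_SPECIES) -> bool:
    """Escalate to D-loop for osetra labels and complex-species cytb calls."""
    if label.market == "osetra":
        return True
    return call is not None and bool(call.species_set & trigger)


def identify_sequence(seq: str, db: ReferenceDB, marker: str,
                      config: SurveyConfig = DEFAULT_SURVEY_CONFIG) -> SpeciesCall:
    """Best-hit screen plus tree placement, combined into a species call."""
    hits = best_hits(seq, db, marker, config.scoring)
    placement = place_query(seq, db, marker, hits=hits)
    return call_species(hits, placement, db, marker, config.thresholds)


def run_egg(egg: EggRecord, label: TradeLabel, db: ReferenceDB,
            config: SurveyConfig = DEFAULT_SURVEY_CONFIG) -> EggCallChain:
    """Apply the marker-escalation workflow to one egg.

    cytb is attempted first; D-loop follows when cytb failed or
    :func:`needs_dloop` says so; cox1 is used only when neither cytb nor
    D-loop produced a resolved call.  Within the trigger complex a resolved
    D-loop call overrides the cytb call.
    """
    chain = EggCallChain()

    def attempt(marker: str) -> SpeciesCall | None:
        seq = egg.sequence(marker)
        if seq is None:
            if marker in egg.outcomes:  # attempted but failed to amplify
                chain.calls[marker] = None
            return None
        call = identify_sequence(seq, db, marker, config)
        chain.calls[marker] = call
        chain.order.append(marker)  # order lists markers that sequenced
        return call

    cytb = attempt("cytb")
    dloop = None
    if cytb is None or not cytb.resolved or needs_dloop(cytb, label,
                                                        config.dloop_trigger):
        dloop = attempt("dloop")
    cox1 = None
    if (cytb is None or not cytb.resolved) and (dloop is None
                                                or not dloop.resolved):
        cox1 = attempt("cox1")
    # final call: D-loop overrides cytb inside the trigger complex
    if dloop is not None and dloop.resolved and (
            cytb is None or not cytb.resolved
            or cytb.species_set & config.dloop_trigger):
        chain.final, chain.final_marker = dloop, "dloop"
    elif cytb is not None and cytb.resolved:
        chain.final, chain.final_marker = cytb, "cytb"
    elif cox1 is not None and cox1.resolved:
        chain.final, chain.final_marker = cox1, "cox1"
    else:
        for mk in MARKER_ORDER:  # keep an unresolved call for reporting
            if chain.calls.get(mk) is not None:
                chain.final, chain.final_marker = chain.calls[mk], mk
                break
    return chain


def count_haplotypes(sequences) -> int:
    """Distinct haplotypes among aligned sequences at one marker.

    Sequences are trimmed to the region covered by all of them and compared
    only at columns where every sequence has an unambiguous base, so two
    sequences differing only at an N (or any IUPAC ambiguity or gap) count as
    one haplotype.
    """
    import numpy as np

    seqs = [s.upper() for s in sequences if s]
    if not seqs:
        return 0
    length = min(len(s) for s in seqs)
    mat = np.vstack([np.frombuffer(s[:length].encode(), dtype=np.uint8)
                     for s in seqs])
    unamb = np.zeros(256, dtype=bool)
    for ch in "ACGT":
        unamb[ord(ch)] = True
    keep = unamb[mat].all(axis=0)
    return len({row.tobytes() for row in mat[:, keep]})


def _is_consistent(call: SpeciesCall, marker: str, label: TradeLabel,
                   db: ReferenceDB) -> bool:
    allowed = allowed_species(label, db.policy, db.groups, marker=marker)
    return call.species_set <= allowed


def confirm_lot(lot: Lot, initial_chain: EggCallChain, db: ReferenceDB,
                config: SurveyConfig = DEFAULT_SURVEY_CONFIG) -> LotResult:
    """Turn an initial egg call into a lot verdict, resampling on suspicion.

    A label-consistent initial call closes the lot on single-egg evidence.
    An inconsistent call triggers confirmatory sequencing of additional eggs
    (``confirm_additional`` more, or every available egg with
    ``confirm_all``); the lot is "mislabeled" only when every resolvable
    confirmatory call is inconsistent with the label, and "mixed" when
    consistent and inconsistent eggs co-occur.
    """
    label = lot.label
    markers_used: list[str] = list(initial_chain.order)
    notes: list[str] = []

    def result(verdict, n_eggs, n_hap, confirmation) -> LotResult:
        return LotResult(lot_id=lot.lot_id, verdict=verdict,
                         markers_used=markers_used,
                         final_call=initial_chain.final,
                         n_eggs_tested=n_eggs, n_haplotypes=n_hap,
                         confirmation=confirmation, channel=lot.channel,
                         year=lot.year, notes=notes)

    if initial_chain.final is None:
        notes.append("no marker yielded a sequence from the initial egg")
        return result("extraction-failed", 1, 0, "none")
    if not initial_chain.final.resolved:
        notes.append(f"initial call unresolved "
                     f"({initial_chain.final.reason})")
        return result("unresolved", 1, 0, "none")

    final, marker = initial_chain.final, initial_chain.final_marker
    if _is_consistent(final, marker, label, db):
        seq = lot.eggs[0].sequence(marker) if lot.eggs else None
        return result("consistent", 1, count_haplotypes([seq] if seq else []),
                      "not-needed")

    # suspected mislabeling: confirmatory eggs
    available = lot.eggs[1:]
    wanted = len(available) if config.confirm_all else config.confirm_additional
    extra = available[:wanted]
    statuses: list[bool] = []
    confirm_chains: list[EggCallChain] = []
    for egg in extra:
        chain = run_egg(egg, label, db, config)
        confirm_chains.append(chain)
        for mk in chain.order:
            if mk not in markers_used:
                markers_used.append(mk)
        if chain.final is not None and chain.final.resolved:
            statuses.append(_is_consistent(chain.final, chain.final_marker,
                                           label, db))
    n_eggs = 1 + len(extra)
    if len(extra) >= config.confirm_additional:
        confirmation = "confirmed"
    elif extra:
        confirmation = "partial"
    else:
        confirmation = "none"
    if len(extra) < config.confirm_additional:
        notes.append(f"only {len(extra)} confirmatory eggs available")

    # haplotypes at the deciding marker over all tested eggs
    tested = lot.eggs[:1 + len(extra)]
    hap_marker = ("cytb" if any(e.sequence("cytb") for e in tested)
                  else initial_chain.final_marker)
    hap_seqs = [e.sequence(hap_marker) for e in tested if e.sequence(hap_marker)]
    n_hap = count_haplotypes(hap_seqs)

    if statuses and any(statuses):
        if all(statuses):
            notes.append("confirmatory eggs contradict the initial call")
            return result("mixed", n_eggs, n_hap, confirmation)
        notes.append("lot contains label-consistent and inconsistent eggs")
        return result("mixed", n_eggs, n_hap, confirmation)
    return result("mislabeled", n_eggs, n_hap, confirmation)


def run_lot(lot: Lot, db: ReferenceDB,
            config: SurveyConfig = DEFAULT_SURVEY_CONFIG) -> LotResult:
    if not lot.eggs:
        return LotResult(lot_id=lot.lot_id, verdict="extraction-failed",
                         markers_used=[], final_call=None, n_eggs_tested=0,
                         n_haplotypes=0, confirmation="none",
                         channel=lot.channel, year=lot.year,
                         notes=["lot has no eggs"])
    chain = run_egg(lot.eggs[0], lot.label, db, config)
    return confirm_lot(lot, chain, db, config)


def run_survey(lots, db: ReferenceDB,
               config: SurveyConfig = DEFAULT_SURVEY_CONFIG) -> list[LotResult]:
    """Identify every lot; individual failures never abort the batch."""
    results = []
    for lot in lots:
        try:
            results.append(run_lot(lot, db, config))
        except Exception as exc:  # noqa: BLE001 - per-lot fault isolation
            results.append(LotResult(
                lot_id=lot.lot_id, verdict="error", markers_used=[],
                final_call=None, n_eggs_tested=0, n_haplotypes=0,
                confirmation="none", channel=lot.channel, year=lot.year,
                notes=[f"{type(exc).__name__}: {exc}"]))
    return results
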