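"""Encoded benchmark survey: a 92-tin caviar market test case.

This module encodes, with synthetic sequences, a complete marketplace survey
of 92 caviar tins purchased in-store and online over two years (2006/2008),
including the nine confirmed substitutions, the two tins that yielded no
DNA, one tin identifiable only through cox1 (a Northern Pike substitute),
and the amplification failures that shaped which lots could be sequenced for
the D-loop.  Lot numbering, labels, channels, years, substituted species,
egg counts and haplotype counts follow the published survey table; the
sequences themselves are simulated from the synthetic reference panel, so
the whole benchmark is reproducible offline.

Expected headline figures for the encoded survey:

* 90 of 92 lots testable (two extraction failures),
* 9 mislabeled lots (10.0%), all purchased online,
* 32 lots escalated to D-loop sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .refdb import MARKERS, ReferenceDB, parse_label, species_id
from .simulate import evolve_sequence
from .synthetic_data import SimConfig, generate_references
from .workflow import EggRecord, Lot, SurveyConfig

#: Seed fixing the benchmark's synthetic sequences (the benchmark is a fixed
#: dataset, not a random draw).
FIXTURE_SEED = 711

#: The benchmark tests every available egg of a suspect lot, reproducing the
#: published per-lot egg counts (10-14).
FIXTURE_SURVEY_CONFIG = SurveyConfig(confirm_all=True)

IN_STORE, INTERNET = "in-store", "internet"

# lot number -> (label text, channel, year)
_BELUGA = "Beluga (Huso huso)"
_SEVRUGA = "Sevruga (Acipenser stellatus)"
_BAERII = "Ostera (A. baerii), farmed"
_GUELD = "Ostera (A. gueldenstaedtii)"
_PERSICUS = "Osetra (A. persicus)"
_UNSPEC = "Osetra (unspecified)"
_WHITE = "White (A. transmontanus)"
_PADDLE = "Paddlefish (Polyodon spathula)"
_HACKLE = "Hackleback (Scaphirhynchus platorynchus)"
_AMERICAN = "American (unspecified)"

LOT_TABLE: dict[int, tuple[str, str, int]] = {
    # in-store 2006
    1: (_BELUGA, IN_STORE, 2006), 13: (_BELUGA, IN_STORE, 2006),
    3: (_SEVRUGA, IN_STORE, 2006), 6: (_SEVRUGA, IN_STORE, 2006),
    9: (_SEVRUGA, IN_STORE, 2006), 12: (_SEVRUGA, IN_STORE, 2006),
    18: (_SEVRUGA, IN_STORE, 2006),
    2: (_BAERII, IN_STORE, 2006), 8: (_BAERII, IN_STORE, 2006),
    14: ("Osetra (A. gueldenstaedii x A. baerii), farmed", IN_STORE, 2006),
    55: (_PERSICUS, IN_STORE, 2006),
    10: (_UNSPEC, IN_STORE, 2006),
    20: (_UNSPEC + ", farmed", IN_STORE, 2006),
    21: (_UNSPEC, IN_STORE, 2006),
    11: (_WHITE + ", farmed", IN_STORE, 2006), 15: (_WHITE, IN_STORE, 2006),
    4: (_PADDLE, IN_STORE, 2006), 16: (_PADDLE, IN_STORE, 2006),
    19: (_PADDLE, IN_STORE, 2006), 22: (_PADDLE, IN_STORE, 2006),
    5: (_HACKLE, IN_STORE, 2006), 7: (_HACKLE, IN_STORE, 2006),
    17: (_HACKLE, IN_STORE, 2006),
    # in-store 2008
    56: (_SEVRUGA, IN_STORE, 2008), 58: (_SEVRUGA, IN_STORE, 2008),
    71: (_SEVRUGA, IN_STORE, 2008), 92: (_SEVRUGA, IN_STORE, 2008),
    51: (_BAERII, IN_STORE, 2008), 54: (_BAERII, IN_STORE, 2008),
    85: (_BAERII, IN_STORE, 2008),
    44: (_UNSPEC, IN_STORE, 2008),
    47: (_UNSPEC + ", farmed", IN_STORE, 2008),
    48: (_UNSPEC + ", farmed", IN_STORE, 2008),
    53: (_UNSPEC + ", farmed", IN_STORE, 2008),
    70: (_UNSPEC, IN_STORE, 2008),
    45: (_WHITE + ", farmed", IN_STORE, 2008),
    90: (_WHITE + ", farmed", IN_STORE, 2008),
    43: (_PADDLE, IN_STORE, 2008), 50: (_PADDLE, IN_STORE, 2008),
    49: (_HACKLE, IN_STORE, 2008),
    46: (_AMERICAN, IN_STORE, 2008),
    # internet 2006
    23: (_BELUGA, INTERNET, 2006),
    30: ("Beluga", INTERNET, 2006),
    32: (_BELUGA, INTERNET, 2006),
    38: ("Beluga (Caspian Sea)", INTERNET, 2006),
    25: (_SEVRUGA, INTERNET, 2006), 28: (_SEVRUGA, INTERNET, 2006),
    31: (_SEVRUGA, INTERNET, 2006),
    33: ("Sevruga (Caspian/Black Sea)", INTERNET, 2006),
    36: ("Sevruga (Caspian Sea)", INTERNET, 2006),
    24: (_BAERII, INTERNET, 2006),
    27: (_GUELD, INTERNET, 2006),
    29: (_PERSICUS, INTERNET, 2006),
    34: (_UNSPEC, INTERNET, 2006),
    35: (_UNSPEC + ", farmed", INTERNET, 2006),
    40: (_WHITE + ", farmed", INTERNET, 2006),
    26: (_PADDLE, INTERNET, 2006),
    39: (_HACKLE, INTERNET, 2006),
    41: (_AMERICAN + ", farmed", INTERNET, 2006),
    # internet 2008
    57: (_BELUGA, INTERNET, 2008),
    60: (_SEVRUGA, INTERNET, 2008),
    64: ("Sevruga (Kazakhstan)", INTERNET, 2008),
    69: (_SEVRUGA, INTERNET, 2008),
    75: ("Sevruga", INTERNET, 2008),
    76: (_SEVRUGA, INTERNET, 2008), 77: (_SEVRUGA, INTERNET, 2008),
    84: (_SEVRUGA, INTERNET, 2008),
    81: (_BAERII, INTERNET, 2008), 94: (_BAERII, INTERNET, 2008),
    68: (_GUELD, INTERNET, 2008),
    82: (_GUELD + ", farmed", INTERNET, 2008),
    83: (_GUELD, INTERNET, 2008),
    86: (_GUELD + ", farmed", INTERNET, 2008),
    87: (_GUELD, INTERNET, 2008),
    93: (_GUELD + ", farmed", INTERNET, 2008),
    63: (_PERSICUS, INTERNET, 2008), 73: (_PERSICUS, INTERNET, 2008),
    62: (_UNSPEC, INTERNET, 2008),
    65: (_UNSPEC + ", farmed", INTERNET, 2008),
    67: (_UNSPEC, INTERNET, 2008),
    61: (_PADDLE, INTERNET, 2008), 66: (_PADDLE, INTERNET, 2008),
    72: (_PADDLE, INTERNET, 2008), 80: (_PADDLE, INTERNET, 2008),
    89: (_PADDLE, INTERNET, 2008),
    74: (_HACKLE, INTERNET, 2008), 79: (_HACKLE, INTERNET, 2008),
    91: (_HACKLE, INTERNET, 2008),
    59: (_AMERICAN, INTERNET, 2008),
    88: (_AMERICAN + ", farmed", INTERNET, 2008),
    95: ("Caviar Substitute", INTERNET, 2008),
    96: ("Caspian Sea Black Caviar", INTERNET, 2008),
}

#: Confirmed substitutions: lot -> (true species, eggs tested, haplotypes).
MISLABELED: dict[int, tuple[str, int, int]] = {
    30: ("Acipenser gueldenstaedtii", 14, 1),
    33: ("Polyodon spathula", 14, 1),
    36: ("Acipenser gueldenstaedtii", 10, 2),
    38: ("Acipenser baerii", 10, 1),
    64: ("Acipenser ruthenus", 10, 2),
    75: ("Polyodon spathula", 10, 2),
    81: ("Acipenser gueldenstaedtii", 10, 1),
    93: ("Acipenser baerii", 10, 1),
    96: ("Esox lucius", 11, 2),
}

#: Tins that yielded no DNA at any marker.
EXTRACTION_FAILED = frozenset({94, 95})

#: The pike tin: cytb and D-loop primers fail; cox1 carries the call.
COX1_ONLY = frozenset({96})

#: Lots whose D-loop amplification failed (so only cytb informs the call).
DLOOP_FAILED = frozenset({20, 44, 47})

#: True species of correctly labeled lots, per label class.
_CONSISTENT_SPECIES = {
    _BELUGA: "Huso huso", "Beluga": "Huso huso",
    "Beluga (Caspian Sea)": "Huso huso",
    _SEVRUGA: "Acipenser stellatus", "Sevruga": "Acipenser stellatus",
    "Sevruga (Caspian/Black Sea)": "Acipenser stellatus",
    "Sevruga (Caspian Sea)": "Acipenser stellatus",
    "Sevruga (Kazakhstan)": "Acipenser stellatus",
    _BAERII: "Acipenser baerii",
    _GUELD: "Acipenser gueldenstaedtii",
    _GUELD + ", farmed": "Acipenser gueldenstaedtii",
    "Osetra (A. gueldenstaedii x A. baerii), farmed": "Acipenser gueldenstaedtii",
    _PERSICUS: "Acipenser persicus",
    _WHITE: "Acipenser transmontanus",
    _WHITE + ", farmed": "Acipenser transmontanus",
    _PADDLE: "Polyodon spathula",
    _HACKLE: "Scaphirhynchus platorynchus",
    _AMERICAN: "Polyodon spathula",
    _AMERICAN + ", farmed": "Polyodon spathula",
    "Caviar Substitute": "Acipenser stellatus",  # moot: no DNA extracted
    "Caspian Sea Black Caviar": "Acipenser stellatus",
}

#: Farmed "unspecified osetra" tins carry Siberian sturgeon; wild ones carry
#: Russian sturgeon.
_UNSPEC_FARMED_SPECIES = "Acipenser baerii"
_UNSPEC_WILD_SPECIES = "Acipenser gueldenstaedtii"


@dataclass
class ExpectedSurvey:
    """Headline figures the encoded benchmark must reproduce."""

    n_lots: int = 92
    n_testable: int = 90
    n_mislabeled: int = 9
    mislabeling_rate_percent: float = 10.0
    n_dloop_lots: int = 32
    mislabeled_lot_ids: frozenset = frozenset(str(n) for n in MISLABELED)
    extraction_failed_ids: frozenset = frozenset(str(n) for n in
                                                 EXTRACTION_FAILED)
    mislabeled_channel: str = INTERNET
    expected_calls: dict = field(default_factory=lambda: {
        str(n): (sp, n_eggs, n_hap)
        for n, (sp, n_eggs, n_hap) in MISLABELED.items()})


def benchmark_reference_db(seed: int = FIXTURE_SEED) -> ReferenceDB:
    """The synthetic reference panel backing the benchmark survey."""
    return generate_references(SimConfig(seed=seed))


def _true_species(lot_no: int, label_text: str) -> str:
    if lot_no in MISLABELED:
        return MISLABELED[lot_no][0]
    if label_text.startswith(_UNSPEC):
        return (_UNSPEC_FARMED_SPECIES if "farmed" in label_text
                else _UNSPEC_WILD_SPECIES)
    return _CONSISTENT_SPECIES[label_text]


def encode_benchmark_survey(db: ReferenceDB | None = None,
                            seed: int = FIXTURE_SEED,
                            config: SimConfig | None = None
                            ) -> tuple[list[Lot], ExpectedSurvey]:
    """Build the 92-tin benchmark survey with synthetic egg sequences.

    Each lot's eggs are simulated descendants of its true species' reference
    haplotype; amplification failures (including the two no-DNA tins and the
    cox1-only pike tin) are encoded as failed marker outcomes.  Deterministic
    in ``seed``.
    """
    config = config or SimConfig(seed=seed)
    db = db or generate_references(config)
    lots: list[Lot] = []
    for lot_no in sorted(LOT_TABLE):
        label_text, channel, year = LOT_TABLE[lot_no]
        label = parse_label(label_text)
        lot_id = str(lot_no)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=(seed, 303, lot_no)))
        true_sp = _true_species(lot_no, label_text)
        n_eggs, n_hap = (MISLABELED[lot_no][1], MISLABELED[lot_no][2]) \
            if lot_no in MISLABELED else (1, 1)
        haps = _fixture_haplotypes(config, db, true_sp, n_hap, rng)
        eggs = []
        for e in range(n_eggs):
            hap_idx = 1 if (n_hap > 1 and e == 1) else 0
            if lot_no in EXTRACTION_FAILED:
                outcomes = {mk: None for mk in MARKERS}
            elif lot_no in COX1_ONLY:
                outcomes = {"cytb": None, "dloop": None,
                            "cox1": haps["cox1"][hap_idx]}
            elif e == 0:
                outcomes = {"cytb": haps["cytb"][hap_idx],
                            "dloop": (None if lot_no in DLOOP_FAILED
                                      else haps["dloop"][hap_idx]),
                            "cox1": haps["cox1"][hap_idx]}
            else:  # confirmatory eggs are sequenced for cytb only
                outcomes = {"cytb": haps["cytb"][hap_idx]}
            eggs.append(EggRecord(lot_id=lot_id, egg_index=e,
                                  outcomes=outcomes))
        lots.append(Lot(lot_id=lot_id, label=label, channel=channel,
                        year=year, eggs=eggs))
    return lots, ExpectedSurvey()


def _fixture_haplotypes(config: SimConfig, db: ReferenceDB, species: str,
                        n_hap: int, rng: np.random.Generator) -> dict:
    sid = species_id(species)
    haps: dict[str, list[str]] = {mk: [] for mk in MARKERS}
    for _ in range(n_hap):
        for _attempt in range(25):
            cand = {mk: evolve_sequence(
                db.alignment(mk).get(f"{sid}.1"),
                config.egg_branch * config.rate_scale[mk],
                db.model(mk), rng) for mk in MARKERS}
            if (cand["cytb"] not in haps["cytb"]
                    and cand["cox1"] not in haps["cox1"]):
                break
        for mk in MARKERS:
            haps[mk].append(cand[mk])
    return haps
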