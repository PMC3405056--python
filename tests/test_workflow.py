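"""Marker escalation, confirmatory resampling and lot verdicts."""

import pytest

from caviarid.market_fixture import FIXTURE_SURVEY_CONFIG
from caviarid.refdb import parse_label
from caviarid.workflow import (EggRecord, Lot, count_haplotypes, needs_dloop,
                               run_egg, run_lot, run_survey)
from caviarid.identify import SpeciesCall


def _call(species_set, kind="species"):
    call = SpeciesCall(marker="cytb", kind=kind)
    if kind == "species":
        call.species = next(iter(species_set))
    else:
        from caviarid.refdb import DEFAULT_GROUPS
        call.group = next(g for g in DEFAULT_GROUPS
                          if species_set <= g.members)
    return call


class TestNeedsDloop:
    def test_sevruga_with_stellatus_call(self):
        call = _call({"Acipenser stellatus"})
        assert not needs_dloop(call, parse_label("Sevruga"))

    def test_any_osetra_label(self):
        call = _call({"Acipenser stellatus"})
        assert needs_dloop(call, parse_label("Osetra (unspecified)"))
        assert needs_dloop(None, parse_label("Ostera (A. baerii)"))

    def test_beluga_with_baerii_call(self):
        call = _call({"Acipenser baerii"})
        assert needs_dloop(call, parse_label("Beluga (Caspian Sea)"))

    def test_group_call_triggers(self):
        call = _call(frozenset({"Acipenser gueldenstaedtii",
                                "Acipenser naccarii",
                                "Acipenser persicus"}), kind="group")
        assert needs_dloop(call, parse_label("Beluga"))


class TestRunEgg:
    def test_cox1_fallback_identifies_pike(self, ref_db):
        """cytb and D-loop fail; the cox1 route still names the substitute."""
        cox1 = ref_db.alignment("cox1").get("Esox_lucius.1")
        egg = EggRecord("x", 0, {"cytb": None, "dloop": None, "cox1": cox1})
        chain = run_egg(egg, parse_label("Caspian Sea Black Caviar"), ref_db)
        assert chain.final_marker == "cox1"
        assert chain.final.species == "Esox lucius"
        assert chain.order == ["cox1"]

    def test_dloop_overrides_cytb_within_complex(self, ref_db):
        """A cytb call in the baerii/gueldenstaedtii complex defers to the
        D-loop identification."""
        cytb = ref_db.alignment("cytb").get("Acipenser_baerii.1")
        dloop = ref_db.alignment("dloop").get("Acipenser_baerii.1")
        egg = EggRecord("x", 0, {"cytb": cytb, "dloop": dloop})
        chain = run_egg(egg, parse_label("Beluga"), ref_db)
        assert chain.order == ["cytb", "dloop"]
        assert chain.final_marker == "dloop"
        assert chain.final.species == "Acipenser baerii"

    def test_all_markers_failed(self, ref_db):
        egg = EggRecord("x", 0, {"cytb": None, "dloop": None, "cox1": None})
        chain = run_egg(egg, parse_label("Sevruga"), ref_db)
        assert chain.final is None and chain.failed

    def test_no_escalation_for_clean_sevruga(self, ref_db):
        cytb = ref_db.alignment("cytb").get("Acipenser_stellatus.1")
        dloop = ref_db.alignment("dloop").get("Acipenser_stellatus.1")
        egg = EggRecord("x", 0, {"cytb": cytb, "dloop": dloop})
        chain = run_egg(egg, parse_label("Sevruga"), ref_db)
        assert chain.order == ["cytb"]
        assert chain.final_marker == "cytb"


class TestCountHaplotypes:
    def test_identical_sequences(self):
        assert count_haplotypes(["ACGTACGT"] * 10) == 1

    def test_two_variants(self):
        seqs = ["ACGTACGT"] * 8 + ["ACGAACGT"] * 2
        assert count_haplotypes(seqs) == 2

    def test_ambiguity_masking(self):
        """Differences confined to an N column do not split haplotypes."""
        assert count_haplotypes(["ACGTACGT", "ACGNACGT"]) == 1
        assert count_haplotypes(["ACGTACGT", "ACGNACGT", "ACGAACGT"]) == 1

    def test_common_region_trimming(self):
        assert count_haplotypes(["ACGTAC", "ACGT"]) == 1

    def test_empty(self):
        assert count_haplotypes([]) == 0


class TestLotVerdicts:
    def test_consistent_lot_closes_on_one_egg(self, ref_db, benchmark_results):
        r = next(r for r in benchmark_results if r.lot_id == "1")
        assert r.verdict == "consistent"
        assert r.n_eggs_tested == 1
        assert r.confirmation == "not-needed"

    def test_mislabeled_lot_requires_confirmation(self, benchmark_results):
        for r in benchmark_results:
            if r.verdict == "mislabeled":
                assert r.n_eggs_tested >= 10
                assert r.confirmation == "confirmed"

    def test_haplotype_counts_on_benchmark(self, benchmark, benchmark_results):
        _, expected = benchmark
        by_id = {r.lot_id: r for r in benchmark_results}
        for lot_id, (species, n_eggs, n_hap) in \
                expected.expected_calls.items():
            r = by_id[lot_id]
            assert r.n_eggs_tested == n_eggs
            assert r.n_haplotypes == n_hap
            assert species in r.final_call.species_set

    def test_extraction_failures_reported(self, benchmark_results):
        failed = {r.lot_id for r in benchmark_results
                  if r.verdict == "extraction-failed"}
        assert failed == {"94", "95"}

    def test_verdict_invariant_to_egg_order(self, ref_db, benchmark):
        lots, _ = benchmark
        lot30 = next(l for l in lots if l.lot_id == "30")
        base = run_lot(lot30, ref_db, FIXTURE_SURVEY_CONFIG)
        shuffled = Lot(lot_id=lot30.lot_id, label=lot30.label,
                       channel=lot30.channel, year=lot30.year,
                       eggs=list(reversed(lot30.eggs)))
        again = run_lot(shuffled, ref_db, FIXTURE_SURVEY_CONFIG)
        assert again.verdict == base.verdict == "mislabeled"
        assert again.n_haplotypes == base.n_haplotypes

    def test_partial_confirmation_when_few_eggs(self, ref_db):
        """A suspect lot with only 3 eggs keeps its verdict but is flagged
        as partially confirmed."""
        cytb = ref_db.alignment("cytb").get("Polyodon_spathula.1")
        eggs = [EggRecord("p", i, {"cytb": cytb}) for i in range(3)]
        lot = Lot(lot_id="p", label=parse_label("Sevruga"),
                  channel="internet", year=2008, eggs=eggs)
        r = run_lot(lot, ref_db)
        assert r.verdict == "mislabeled"
        assert r.confirmation == "partial"
        assert r.n_eggs_tested == 3


def test_run_survey_empty_input(ref_db):
    assert run_survey([], ref_db) == []


def test_run_survey_isolates_lot_failures(ref_db):
    """A malformed lot is reported as an error without aborting the batch."""
    cytb = ref_db.alignment("cytb").get("Huso_huso.1")
    good = Lot(lot_id="ok", label=parse_label("Beluga"), channel="internet",
               year=2006, eggs=[EggRecord("ok", 0, {"cytb": cytb})])
    bad = Lot(lot_id="bad", label=None, channel="internet", year=2006,
              eggs=[EggRecord("bad", 0, {"cytb": cytb})])
    results = run_survey([good, bad], ref_db)
    assert [r.verdict for r in results] == ["consistent", "error"]
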