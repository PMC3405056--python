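"""Identity screening, ML placement and group-aware species calling."""

import numpy as np
import pytest

from caviarid.identify import (AlignScoring, best_hits, call_species,
                               percent_identity, place_query,
                               placement_engine)
from caviarid.phylo import bipartitions
from caviarid.refdb import species_id
from caviarid.simulate import evolve_sequence
from caviarid.treesearch import SearchConfig, build_ml_tree
from caviarid.likelihood import Alignment

from oracles import smith_waterman_score

CYTB = "cytb"
DLOOP = "dloop"


def _query_from(ref_db, species, marker=CYTB, t=0.003, seed=0):
    base = ref_db.alignment(marker).get(f"{species_id(species)}.1")
    return evolve_sequence(base, t, ref_db.model(marker),
                           np.random.default_rng(seed))


class TestPercentIdentity:
    def test_identical_sequences(self):
        seq = "ACGT" * 125
        ident, length, _ = percent_identity(seq, seq)
        assert ident == 100.0 and length == 500

    def test_ten_mismatches_in_500(self):
        a = "A" * 500
        b = "C" * 10 + "A" * 490
        ident, length, _ = percent_identity(a, b)
        assert length == 490  # local alignment trims the mismatched prefix
        # embed mismatches so the local alignment must keep them
        a = ("ACGT" * 125)
        b = a[:100] + "T" + a[101:200] + "A" + a[201:]
        b = list(a)
        for pos in range(40, 440, 40):
            b[pos] = "A" if a[pos] != "A" else "C"
        ident, length, _ = percent_identity(a, "".join(b))
        assert ident == pytest.approx(98.0)
        assert length == 500

    def test_symmetry(self, rng):
        for _ in range(5):
            a = "".join(rng.choice(list("ACGT"), 60))
            b = "".join(rng.choice(list("ACGT"), 50))
            assert percent_identity(a, b) == percent_identity(b, a)

    def test_score_matches_dp_oracle(self, rng):
        scoring = AlignScoring()
        for _ in range(12):
            a = "".join(rng.choice(list("ACGT"), int(rng.integers(20, 60))))
            b = "".join(rng.choice(list("ACGT"), int(rng.integers(20, 60))))
            _, _, score = percent_identity(a, b, scoring)
            oracle = smith_waterman_score(
                a, b, scoring.match, scoring.mismatch,
                scoring.gap_open + scoring.gap_extend, scoring.gap_extend)
            assert score == pytest.approx(oracle)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            percent_identity("", "ACGT")


class TestBestHits:
    def test_exact_reference_ranks_first(self, ref_db):
        ref = ref_db.refs[CYTB][0]
        report = best_hits(ref.sequence, ref_db, CYTB)
        assert report.top.ref_id == ref.id
        assert report.top.identity == 100.0
        scores = [h.score for h in report.hits]
        assert scores == sorted(scores, reverse=True)
        assert len(report.hits) == len(ref_db.refs[CYTB])

    def test_foreign_query_reported_below_threshold(self, ref_db, rng):
        query = "".join(rng.choice(list("ACGT"),
                                   ref_db.alignment(CYTB).n_sites))
        report = best_hits(query, ref_db, CYTB)
        assert report.top.identity < 98.0
        assert report.hits  # report still returned

    def test_simulated_queries_hit_their_species(self, ref_db):
        hits_ok = 0
        species = ["Huso huso", "Acipenser stellatus", "Polyodon spathula",
                   "Esox lucius", "Acipenser ruthenus"]
        n_rep = 40
        for i in range(n_rep):
            sp = species[i % len(species)]
            q = _query_from(ref_db, sp, seed=1000 + i)
            if best_hits(q, ref_db, CYTB).top.species == sp:
                hits_ok += 1
        assert hits_ok / n_rep >= 0.95


class TestPlacement:
    def test_identical_query_lands_on_its_tip(self, ref_db):
        tip = f"{species_id('Huso huso')}.1"
        query = ref_db.alignment(CYTB).get(tip)
        placement = place_query(query, ref_db, CYTB)
        assert placement.tip_name == tip
        assert placement.pendant_length < 1e-4

    def test_weight_ratios_sum_to_one(self, ref_db):
        q = _query_from(ref_db, "Acipenser stellatus", seed=3)
        placement = place_query(q, ref_db, CYTB)
        assert sum(placement.weights.values()) == pytest.approx(1.0)
        assert placement.pendant_length >= 0

    def test_agrees_with_de_novo_ml_tree(self, ref_db, gtr_model):
        """On a small subset, placement puts the query next to the same tip
        a full ML re-optimisation with the query included chooses."""
        names = ["Huso_huso.1", "Acipenser_stellatus.1",
                 "Polyodon_spathula.1", "Esox_lucius.1"]
        aln = ref_db.alignment(CYTB)
        sub = Alignment(names, [aln.get(n) for n in names])
        query = _query_from(ref_db, "Acipenser stellatus", seed=7)
        res = build_ml_tree(Alignment(sub.names + ["query"],
                                      sub.seqs + [query]),
                            ref_db.model(CYTB).with_alpha(None),
                            SearchConfig(n_starts=3, seed=2))
        assert frozenset({"Acipenser_stellatus.1", "query"}) in \
            bipartitions(res.tree) | {
                frozenset(res.tree.tip_names()) - s
                for s in bipartitions(res.tree)}


class TestCallSpecies:
    def test_clean_species_call(self, ref_db):
        q = _query_from(ref_db, "Acipenser stellatus", seed=11)
        hits = best_hits(q, ref_db, CYTB)
        call = call_species(hits, place_query(q, ref_db, CYTB, hits=hits),
                            ref_db, CYTB)
        assert call.kind == "species"
        assert call.species == "Acipenser stellatus"
        assert call.top_identity >= 98.0

    @pytest.mark.parametrize("species", ["Acipenser gueldenstaedtii",
                                         "Acipenser naccarii"])
    def test_complex_members_get_group_call(self, ref_db, species):
        q = _query_from(ref_db, species, seed=13)
        hits = best_hits(q, ref_db, CYTB)
        call = call_species(hits, place_query(q, ref_db, CYTB, hits=hits),
                            ref_db, CYTB)
        assert call.kind == "group"
        assert call.group.group_id == "gueldenstaedtii_complex"

    def test_persicus_never_called_at_species_level(self, ref_db):
        """Even a perfect persicus match yields the complex group call."""
        q = ref_db.alignment(DLOOP).get("Acipenser_persicus.1")
        hits = best_hits(q, ref_db, DLOOP)
        call = call_species(hits, place_query(q, ref_db, DLOOP, hits=hits),
                            ref_db, DLOOP)
        assert call.kind == "group"
        assert "Acipenser persicus" in call.species_set

    def test_low_identity_is_unresolved(self, ref_db, rng):
        q = "".join(rng.choice(list("ACGT"), ref_db.alignment(CYTB).n_sites))
        hits = best_hits(q, ref_db, CYTB)
        call = call_species(hits, place_query(q, ref_db, CYTB, hits=hits),
                            ref_db, CYTB)
        assert call.kind == "unresolved"
        assert call.reason == "low_identity"

    def test_determinism(self, ref_db):
        q = _query_from(ref_db, "Acipenser baerii", seed=17)
        calls = []
        for _ in range(2):
            hits = best_hits(q, ref_db, CYTB)
            call = call_species(hits, place_query(q, ref_db, CYTB, hits=hits),
                                ref_db, CYTB)
            calls.append((call.kind, call.display, call.top_identity))
        assert calls[0] == calls[1]


def test_group_members_never_called_at_species_level_in_bulk(ref_db):
    """Queries simulated from unresolvable-group tips give zero species-level
    calls; queries from clean species are called correctly."""
    group_species = ["Acipenser gueldenstaedtii", "Acipenser naccarii",
                     "Acipenser persicus", "Scaphirhynchus platorynchus"]
    clean_species = ["Huso huso", "Acipenser stellatus", "Acipenser baerii",
                     "Polyodon spathula", "Acipenser ruthenus",
                     "Acipenser transmontanus", "Esox lucius"]
    correct = total = 0
    for i in range(700):
        sp = clean_species[i % len(clean_species)]
        q = _query_from(ref_db, sp, seed=5000 + i)
        hits = best_hits(q, ref_db, CYTB)
        call = call_species(hits, place_query(q, ref_db, CYTB, hits=hits),
                            ref_db, CYTB)
        total += 1
        correct += (call.kind == "species" and call.species == sp)
    assert correct / total >= 0.95
    for i in range(300):
        sp = group_species[i % len(group_species)]
        q = _query_from(ref_db, sp, seed=6000 + i)
        hits = best_hits(q, ref_db, CYTB)
        call = call_species(hits, place_query(q, ref_db, CYTB, hits=hits),
                            ref_db, CYTB)
        assert call.kind != "species"


def test_placement_engine_reference_likelihood(ref_db):
    """The engine's internal split of the reference likelihood must agree
    with a direct pruning computation."""
    from caviarid.likelihood import tree_loglik

    engine = placement_engine(ref_db, CYTB)
    direct = tree_loglik(ref_db.trees[CYTB], ref_db.alignment(CYTB),
                         ref_db.model(CYTB))
    assert engine.ref_loglik == pytest.approx(direct, abs=1e-6)
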