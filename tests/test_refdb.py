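"""Trade-label grammar, label policy and reference-library invariants."""

import pytest

from caviarid.refdb import (DEFAULT_GROUPS, DEFAULT_POLICY, LabelPolicy,
                            ConfigError, ReferenceDBError, ReferenceSequence,
                            allowed_species, format_label, load_reference_db,
                            parse_label)
from caviarid.phylo import PhyloTree
from caviarid.refdb import ReferenceDB


class TestParseLabel:
    def test_explicit_species_claim(self):
        label = parse_label("Osetra (A. baerii)")
        assert label.market == "osetra"
        assert label.claimed_species == "Acipenser baerii"
        assert label.origin is None

    def test_origin_qualifier(self):
        label = parse_label("Beluga (Caspian Sea)")
        assert label.market == "beluga"
        assert label.claimed_species is None
        assert label.origin == "Caspian Sea"

    def test_empty_label_rejected(self):
        with pytest.raises(ValueError):
            parse_label("")

    def test_unknown_market_degrades_to_other(self):
        label = parse_label("XYZ roe")
        assert label.market == "other"
        assert label.claimed_species is None

    def test_misspelling_normalises(self):
        assert parse_label("Ostera (A. baerii)").market == "osetra"
        assert parse_label("Osetra").market == "osetra"

    def test_farmed_flag(self):
        assert parse_label("Osetra (A. baerii), farmed").farmed
        assert not parse_label("Osetra (A. baerii)").farmed

    def test_hybrid_claim_kept_as_origin(self):
        label = parse_label("Osetra (A. gueldenstaedii x A. baerii)")
        assert label.market == "osetra"
        assert label.claimed_species is None
        assert "x" in label.origin

    @pytest.mark.parametrize("raw", [
        "Beluga", "Sevruga (Acipenser stellatus)", "Osetra (Caspian Sea)",
        "Hackleback (Scaphirhynchus platorynchus), farmed", "Paddlefish",
    ])
    def test_parse_format_round_trip(self, raw):
        label = parse_label(raw)
        assert parse_label(format_label(label)) == \
            parse_label(format_label(parse_label(format_label(label))))


class TestAllowedSpecies:
    def test_sevruga_market_set(self):
        label = parse_label("Sevruga")
        assert allowed_species(label, DEFAULT_POLICY) == \
            frozenset({"Acipenser stellatus"})

    def test_osetra_unspecified_contains_market_set(self):
        allowed = allowed_species(parse_label("Osetra (unspecified)"),
                                  DEFAULT_POLICY)
        assert {"Acipenser gueldenstaedtii", "Acipenser persicus",
                "Acipenser baerii"} <= allowed
        # any extras come only from indistinguishability closure
        assert allowed - {"Acipenser gueldenstaedtii", "Acipenser persicus",
                          "Acipenser baerii"} <= {"Acipenser naccarii"}

    def test_claimed_species_overrides_market(self):
        allowed = allowed_species(parse_label("Osetra (A. baerii)"),
                                  DEFAULT_POLICY)
        assert allowed == frozenset({"Acipenser baerii"})

    def test_claimed_species_expands_by_group_at_marker(self):
        allowed = allowed_species(parse_label("Osetra (A. gueldenstaedtii)"),
                                  DEFAULT_POLICY, DEFAULT_GROUPS,
                                  marker="dloop")
        assert allowed == frozenset({"Acipenser gueldenstaedtii",
                                     "Acipenser naccarii",
                                     "Acipenser persicus"})

    def test_missing_market_is_config_error(self):
        with pytest.raises(ConfigError):
            allowed_species(parse_label("Beluga"),
                            LabelPolicy(markets={"sevruga": set()}))

    def test_monotone_in_policy(self):
        """Adding a species to a market set never removes an allowed one."""
        small = LabelPolicy(markets={"sevruga": {"Acipenser stellatus"}})
        big = LabelPolicy(markets={
            "sevruga": {"Acipenser stellatus", "Acipenser ruthenus"}})
        label = parse_label("Sevruga")
        assert allowed_species(label, small) <= allowed_species(label, big)


class TestReferenceDB:
    def test_synthetic_library_is_valid(self, ref_db):
        for marker in ("cytb", "dloop", "cox1"):
            aln = ref_db.alignment(marker)
            assert len(set(aln.names)) == len(aln)
            assert set(ref_db.trees[marker].tip_names()) == set(aln.names)

    def test_round_trip_write_load(self, ref_db, tmp_path):
        ref_db.write(tmp_path / "db")
        markers = list(ref_db.refs)
        loaded = load_reference_db(
            {mk: tmp_path / "db" / f"refs_{mk}.fasta" for mk in markers},
            {mk: tmp_path / "db" / f"tree_{mk}.nwk" for mk in markers},
            config_path=tmp_path / "db" / "refdb.yaml")
        for mk in markers:
            assert loaded.alignment(mk).seqs == ref_db.alignment(mk).seqs
            assert loaded.alignment(mk).names == ref_db.alignment(mk).names
            from caviarid.phylo import robinson_foulds
            assert robinson_foulds(loaded.trees[mk], ref_db.trees[mk]) == 0
        assert loaded.policy.markets == ref_db.policy.markets
        assert {g.group_id for g in loaded.groups} == \
            {g.group_id for g in ref_db.groups}
        assert loaded.model("cytb").alpha == pytest.approx(
            ref_db.model("cytb").alpha)

    def test_missing_tip_sequence_names_the_tip(self):
        refs = {"cytb": [ReferenceSequence("x1", "Huso huso", "cytb", "ACGT")]}
        tree = PhyloTree.from_newick("(x1:0.1,x2:0.1);")
        with pytest.raises(ReferenceDBError, match="x2"):
            ReferenceDB(refs, {"cytb": tree}, groups=())

    def test_duplicate_id_rejected(self):
        refs = {"cytb": [
            ReferenceSequence("x1", "Huso huso", "cytb", "ACGT"),
            ReferenceSequence("x1", "Huso huso", "cytb", "ACGT")]}
        tree = PhyloTree.from_newick("(x1:0.1,y:0.1);")
        with pytest.raises(ReferenceDBError, match="duplicate"):
            ReferenceDB(refs, {"cytb": tree}, groups=())

    def test_ragged_alignment_rejected(self):
        refs = {"cytb": [
            ReferenceSequence("x1", "Huso huso", "cytb", "ACGT"),
            ReferenceSequence("x2", "Huso huso", "cytb", "ACG")]}
        tree = PhyloTree.from_newick("(x1:0.1,x2:0.1);")
        with pytest.raises(ReferenceDBError, match="ragged"):
            ReferenceDB(refs, {"cytb": tree}, groups=())

    def test_group_member_missing_from_library_rejected(self, ref_db):
        refs = {"cytb": [ReferenceSequence("x1", "Huso huso", "cytb", "ACGT")]}
        tree = PhyloTree.from_newick("(x1:0.1);")
        with pytest.raises(ReferenceDBError, match="gueldenstaedtii"):
            ReferenceDB(refs, {"cytb": tree}, groups=DEFAULT_GROUPS)
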