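"""Swinger rule algebra and transcript detection."""

import itertools

import pytest
from hypothesis import given, strategies as st

import swingrna as sw
from swingrna.errors import InputError
from swingrna.swinger import BASES, SwingerRule

RULES = sw.enumerate_rules()


class TestRuleSpace:
    def test_exactly_23_rules(self):
        assert len(RULES) == 23
        assert len({r.images for r in RULES}) == 23

    def test_9_symmetric_14_asymmetric(self):
        sym = [r for r in RULES if r.rule_class == "symmetric"]
        asym = [r for r in RULES if r.rule_class == "asymmetric"]
        assert (len(sym), len(asym)) == (9, 14)
        assert all(r.is_involution for r in sym)
        assert not any(r.is_involution for r in asym)

    def test_equals_all_permutations_minus_identity(self):
        brute = {p for p in itertools.permutations(BASES)
                 if p != tuple(BASES)}
        assert {r.images for r in RULES} == brute

    def test_closed_under_composition_with_identity(self):
        universe = {r.images for r in RULES} | {tuple(BASES)}
        for a in RULES:
            for b in RULES:
                c = a.compose(b)
                images = tuple(BASES) if c is None else c.images
                assert images in universe

    def test_closed_under_conjugation(self):
        names = {r.name for r in RULES}
        assert {sw.conjugate_by_complement(r).name for r in RULES} == names


class TestParseRule:
    def test_three_cycle(self):
        r = sw.parse_rule("C->T->G->C")
        assert r.mapping == {"A": "A", "C": "T", "T": "G", "G": "C"}

    def test_single_swap(self):
        r = sw.parse_rule("A<->T")
        assert r.mapping == {"A": "T", "T": "A", "C": "C", "G": "G"}

    def test_round_trip_all_23(self):
        for rule in RULES:
            assert sw.parse_rule(rule.name) == rule

    @pytest.mark.parametrize("bad", ["A->C", "A<->A", "A->C->G->T",
                                     "X<->Y", "", "A-C", "A<->C-G<->G"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(InputError):
            sw.parse_rule(bad)


class TestApplyRule:
    def test_direct_substitution(self):
        assert sw.apply_rule("ACGT", "A<->C") == "CAGT"

    def test_u_normalised_n_passthrough(self):
        assert sw.apply_rule("ACGUN", "A<->C") == "CAGTN"

    @given(st.text(alphabet="ACGTN", max_size=50))
    def test_length_and_non_acgt_positions_preserved(self, seq):
        for rule in RULES[:4]:
            out = sw.apply_rule(seq, rule)
            assert len(out) == len(seq)
            assert all(
                (a == "N") == (b == "N") for a, b in zip(seq, out)
            )

    def test_involutions_self_invert(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 100))
        for rule in RULES:
            if rule.is_involution:
                assert sw.apply_rule(sw.apply_rule(seq, rule), rule) == seq

    def test_cycle_order(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 60))
        for rule in RULES:
            if rule.is_involution:
                continue
            k = len(rule._cycles()[0])
            out = seq
            for _ in range(k):
                out = sw.apply_rule(out, rule)
            assert out == seq

    def test_gc_preserved_exactly_by_gc_stable_rules(self, rng):
        """GC content survives a rule iff the rule maps {G,C} onto {G,C}.

        Base counts 10/20/40/80 have pairwise-distinct pair sums, so any
        rule moving a non-GC base into {G,C} must change the GC count.
        """
        seq = list("A" * 10 + "C" * 20 + "G" * 40 + "T" * 80)
        rng.shuffle(seq)
        seq = "".join(seq)
        gc = sum(b in "GC" for b in seq)
        for rule in RULES:
            stable = {rule["G"], rule["C"]} == {"G", "C"}
            out_gc = sum(b in "GC" for b in rule.apply(seq))
            if stable:
                assert out_gc == gc, rule.name
            else:
                assert out_gc != gc, rule.name


class TestConjugate:
    def test_boxed_rule_pair(self):
        assert sw.conjugate_by_complement("C->T->G->C").name == "A->C->G->A"

    def test_involution_over_all_rules(self):
        for rule in RULES:
            twice = sw.conjugate_by_complement(sw.conjugate_by_complement(rule))
            assert twice == rule

    def test_matches_composition_definition(self):
        comp = SwingerRule(("T", "G", "C", "A"))  # the WC complement
        for rule in RULES:
            direct = sw.conjugate_by_complement(rule)
            composed = comp.compose(rule.compose(comp))
            assert composed == direct


@pytest.fixture(scope="module")
def sim():
    return sw.simulate_swinger_reads(sw.SimulationConfig(
        seed=42, n_reads=60, planted_rule="C->T->G->C",
    ))


@pytest.fixture(scope="module")
def detector(sim):
    return sw.SwingerDetector(sim.genome)


class TestDetection:
    def test_exact_substring_is_identity_hit(self, sim, detector):
        read = sim.genome[500:540]
        hits = detector.detect(read)
        assert hits[0].rule == "identity"
        assert hits[0].aligned_fraction == 1.0
        assert hits[0].identity == 1.0
        assert (hits[0].start, hits[0].end) == (501, 540)
        assert all(h.rule == "identity" for h in hits)

    def test_planted_rule_recovered_at_interval(self, sim, detector):
        rule = sw.parse_rule("A->G->T->A")
        read = rule.apply(sim.genome[2000:2040])
        hits = detector.detect(read)
        assert hits[0].rule == "A->G->T->A"
        assert hits[0].strand == "+"
        assert (hits[0].start, hits[0].end) == (2001, 2040)

    def test_minus_strand_reports_conjugate(self, sim, detector):
        rule = sw.parse_rule("A->G->T->A")
        read = sw.revcomp(rule.apply(sim.genome[3000:3040]))
        hits = detector.detect(read)
        assert hits[0].rule == sw.conjugate_by_complement(rule).name
        assert hits[0].strand == "-"
        assert (hits[0].start, hits[0].end) == (3001, 3040)

    def test_truth_table_recovered(self, sim, detector):
        hits = detector.detect_all(sim.reads)
        merged = hits.merge(sim.truth, on="read_id",
                            suffixes=("_det", "_true"))
        assert (merged["rule_det"] == merged["rule_true"]).all()
        assert (merged["start_det"] == merged["start_true"]).all()

    def test_regular_read_never_called_swinger(self, sim, detector):
        read = sw.revcomp(sim.genome[4000:4040])
        hits = detector.detect(read)
        assert hits and hits[0].rule == "identity"
        assert hits[0].strand == "-"

    def test_short_read_rejected(self, detector):
        with pytest.raises(InputError):
            detector.detect("ACGT")

    def test_thresholds_respected(self, sim):
        det = sw.SwingerDetector(sim.genome, coverage_min=0.9,
                                 identity_min=0.95)
        # a read whose second half is garbage cannot reach 90% coverage
        read = sim.genome[100:120] + "C" * 20
        hits = [h for h in det.detect(read)]
        for h in hits:
            assert h.aligned_fraction >= 0.9
            assert h.identity >= 0.95


class TestSummary:
    def test_24_rows_identity_plus_23(self, rng):
        sim = sw.simulate_swinger_reads(sw.SimulationConfig(
            seed=9, n_reads=40, planted_rule="A<->C",
        ))
        det = sw.SwingerDetector(sim.genome)
        summary = sw.summarize_hits(det.detect_all(sim.reads))
        assert len(summary) == 24
        assert summary.iloc[0]["rule"] == "identity"
        assert summary["n"].sum() == 40
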