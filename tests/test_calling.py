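"""Demultiplexing, read profiling, species clustering and genotyping."""

import itertools

import numpy as np
import pytest

from hetdna import calling, simulate as sim
from hetdna.calling import (
    BarcodeTable,
    CallingError,
    MarkerProfile,
    Product,
    ReadRecord,
    Species,
    call_read_profile,
    cluster_species,
    demultiplex,
    product_genotype,
    qc_event,
)


def _table(rng, n=3):
    return BarcodeTable(sim.make_barcode_table([f"rec{i:02d}" for i in range(n)], rng))


def _amplicon(barcode, uf, ur, insert):
    return barcode + uf + insert + sim._rc(ur) + sim._rc(barcode)


def _bc(table, rid):
    return table.frame.loc[table.frame["id"] == rid, "barcode"].iloc[0]


class TestDemultiplex:
    def test_exact_barcode_and_primer(self, rng, small_substrate):
        recipient = small_substrate[0]
        table = _table(rng)
        bc = _bc(table, "rec02")
        read = ReadRecord("r1", _amplicon(
            bc, sim.UNIVERSAL_FWD_FULL, sim.UNIVERSAL_REV_FULL, recipient))
        assigned, unassigned = demultiplex([read], table)
        assert not unassigned
        assert list(assigned) == [("rec02", Product.P_FULL)]

    def test_three_mismatches_unassigned(self, rng, small_substrate):
        recipient = small_substrate[0]
        table = _table(rng)
        bc = list(_bc(table, "rec00"))
        for i in range(3):
            bc[i] = "A" if bc[i] != "A" else "C"
        read = ReadRecord("r1", _amplicon(
            "".join(bc), sim.UNIVERSAL_FWD_TRUNC, sim.UNIVERSAL_REV_TRUNC, recipient))
        assigned, unassigned = demultiplex([read], table)
        assert not assigned
        assert len(unassigned) == 1

    def test_two_mismatches_still_assigned_reverse_orientation(
        self, rng, small_substrate
    ):
        recipient = small_substrate[0]
        table = _table(rng)
        bc = list(_bc(table, "rec01"))
        for i in range(2):
            bc[i] = "A" if bc[i] != "A" else "C"
        amp = _amplicon(
            "".join(bc), sim.UNIVERSAL_FWD_TRUNC, sim.UNIVERSAL_REV_TRUNC, recipient)
        read = ReadRecord("r1", sim._rc(amp))
        assigned, unassigned = demultiplex([read], table)
        assert list(assigned) == [("rec01", Product.P_TRUNC)]

    def test_duplicate_barcodes_rejected(self, rng):
        df = sim.make_barcode_table(["a", "b"], rng)
        df.loc[df["id"] == "b", "barcode"] = df[df["id"] == "a"]["barcode"].iloc[0]
        with pytest.raises(CallingError, match="duplicate"):
            BarcodeTable(df)

    def test_simulated_reads_assignment_rate(self, rng, small_substrate):
        """>= 99% of reads with 0.5% error land in their true bin."""
        _, _, pair, break_site, marker_map = small_substrate
        params = sim.MechanismParams.clean()
        events = sim.simulate_dsbr(params, marker_map, break_site, 5, rng)
        df = sim.make_barcode_table([e.event_id for e in events], rng)
        table = BarcodeTable(df)
        bc = {r.id: r.barcode for r in df.itertuples()}
        reads = []
        for ev in events:
            obs = sim.observe_colony(ev, params, rng)
            reads.extend(sim.emit_reads(
                obs, pair, marker_map, bc[ev.event_id],
                depth=10, error_rate=0.005, rng=rng))
        assigned, _ = demultiplex(reads, table)
        correct = total = 0
        for (rid, product), rlist in assigned.items():
            for r in rlist:
                total += 1
                true_rid, true_product, *_ = r.read_id.split("|")
                correct += rid == true_rid and product.value == true_product
        assert total >= 0.99 * len(reads)
        assert correct / total >= 0.99


class TestCallReadProfile:
    def test_pure_donor_read_all_D(self, small_substrate):
        _, donor, pair, _, marker_map = small_substrate
        prof = call_read_profile(ReadRecord("r", donor), pair, marker_map)
        assert prof.calls == ("D",) * len(marker_map)

    def test_spliced_chimera_half_R_half_D(self, small_substrate):
        recipient, donor, pair, _, marker_map = small_substrate
        m8 = marker_map.markers[8]
        # splice at the recipient coordinate of marker 9's column
        insert = recipient[: m8.pos_recipient] + donor[m8.pos_donor :]
        prof = call_read_profile(ReadRecord("r", insert), pair, marker_map)
        assert prof.calls == ("R",) * 8 + ("D",) * 8

    def test_non_parental_base_called_N(self, small_substrate):
        recipient, _, pair, _, marker_map = small_substrate
        m = marker_map.markers[3]
        bad = {"A", "C", "G", "T"} - {m.recipient_base, m.donor_base}
        seq = list(recipient)
        seq[m.pos_recipient] = sorted(bad)[0]
        prof = call_read_profile(ReadRecord("r", "".join(seq)), pair, marker_map)
        expected = ["R"] * len(marker_map)
        expected[3] = "N"
        assert prof.calls == tuple(expected)

    def test_garbage_read_flagged_all_N(self, small_substrate, rng):
        _, _, pair, _, marker_map = small_substrate
        junk = "".join(rng.choice(list("ACGT"), size=500))
        prof = call_read_profile(ReadRecord("r", junk), pair, marker_map)
        assert prof.qc_fail
        assert set(prof.calls) == {"N"}


class TestClusterSpecies:
    def test_single_species(self):
        profs = [MarkerProfile(("R",) * 4)] * 10
        species = cluster_species(profs)
        assert len(species) == 1
        assert species[0].support == 10
        assert species[0].fraction == pytest.approx(1.0)

    def test_two_species_split(self):
        x = MarkerProfile(("R", "R", "R", "R"))
        y = MarkerProfile(("D", "D", "D", "R"))
        species = cluster_species([x] * 6 + [y] * 6)
        assert sorted(s.support for s in species) == [6, 6]
        assert abs(sum(s.fraction for s in species) - 1.0) < 1e-9

    def test_n_compatible_profile_merges(self):
        x = MarkerProfile(("R", "D", "R", "R"))
        xn = MarkerProfile(("R", "N", "R", "R"))
        species = cluster_species([x] * 9 + [xn])
        assert len(species) == 1
        assert species[0].support == 10
        assert species[0].profile.calls == x.calls  # N filled from consensus

    def test_min_reads_enforced(self):
        with pytest.raises(CallingError, match="at least"):
            cluster_species([MarkerProfile(("R",))] * 2)


class TestQCAndGenotype:
    def _sp(self, calls, support, fraction):
        return Species(MarkerProfile(tuple(calls)), support, fraction)

    def test_one_and_two_major_pass(self):
        a = [self._sp("RRRR", 10, 1.0)]
        b = [self._sp("RRRR", 6, 0.5), self._sp("DDDD", 6, 0.5)]
        assert qc_event(a, b).passed

    def test_three_major_fail(self):
        sp = [self._sp("RRRR", 8, 0.4), self._sp("DDDD", 7, 0.35),
              self._sp("RRDD", 5, 0.25)]
        verdict = qc_event(sp, [self._sp("RRRR", 10, 1.0)])
        assert not verdict.passed
        assert verdict.major_counts["P_TRUNC"] == 3

    def test_singleton_error_species_ignored(self):
        sp = [self._sp("RRRR", 10, 0.5), self._sp("DDDD", 9, 0.45),
              self._sp("RDRD", 1, 0.05)]
        assert qc_event(sp, [self._sp("RRRR", 10, 1.0)]).passed

    def test_hetdna_diagnosis_from_two_species(self):
        s1 = self._sp("DDDDRRRR", 10, 0.5)
        s2 = self._sp("DDDDDDRR", 10, 0.5)
        call = product_genotype([s1, s2], Product.P_TRUNC)
        assert call.genotype == tuple("DDDDHHRR")

    def test_single_species_never_H(self):
        call = product_genotype([self._sp("RRRR", 10, 1.0)])
        assert call.genotype == ("R",) * 4
        assert "H" not in call.genotype

    def test_merge_rule_table_exhaustive(self):
        """H iff the two major species disagree R-vs-D; N yields the non-N
        call; checked over all 16 call pairs."""
        expected = {
            ("R", "R"): "R", ("D", "D"): "D", ("H", "H"): "H", ("N", "N"): "N",
            ("R", "D"): "H", ("D", "R"): "H",
            ("R", "N"): "R", ("N", "R"): "R",
            ("D", "N"): "D", ("N", "D"): "D",
            ("H", "N"): "H", ("N", "H"): "H",
            ("R", "H"): "H", ("H", "R"): "H",
            ("D", "H"): "H", ("H", "D"): "H",
        }
        for (a, b), want in expected.items():
            s1 = self._sp((a, "R"), 5, 0.5)
            s2 = self._sp((b, "R"), 5, 0.5)
            got = product_genotype([s1, s2]).genotype[0]
            assert got == want, (a, b)


class TestRoundTrip:
    def test_error_free_round_trip_exact(self, rng, small_substrate):
        """demultiplex -> profile -> cluster -> genotype reproduces simulated
        genotypes exactly at error rate 0, across mechanism classes."""
        _, _, pair, break_site, marker_map = small_substrate
        params = sim.MechanismParams.clean()
        center = break_site.cut_center
        events = (
            sim.simulate_dsbr(params, marker_map, break_site, 60, rng)
            + sim.simulate_dsbr(
                sim.MechanismParams.clean(p_back_migration=1.0),
                marker_map, break_site, 40, rng)
            + sim.simulate_mr_nick(params, marker_map, center, 40, rng)
            + sim.simulate_gap(params, marker_map, (center - 60, center + 60), 30, rng)
            + sim.simulate_dloop_cleavage(params, marker_map, break_site, 30, rng)
        )
        for i, ev in enumerate(events):  # unique ids across mechanism groups
            ev.event_id = f"ev{i:04d}"
        df = sim.make_barcode_table([e.event_id for e in events], rng)
        table = BarcodeTable(df)
        bc = {r.id: r.barcode for r in df.itertuples()}
        truth, reads = {}, []
        for ev in events:
            obs = sim.observe_colony(ev, params, rng)
            truth[ev.event_id] = obs.product_calls()
            reads.extend(sim.emit_reads(
                obs, pair, marker_map, bc[ev.event_id], depth=4, rng=rng))
        assigned, unassigned = demultiplex(reads, table)
        assert not unassigned
        for ev in events:
            for product, want in zip((Product.P_TRUNC, Product.P_FULL),
                                     truth[ev.event_id]):
                profiles = [
                    call_read_profile(r, pair, marker_map)
                    for r in assigned[(ev.event_id, product)]
                ]
                got = product_genotype(cluster_species(profiles), product)
                assert got.genotype == want.genotype, ev.event_id

    def test_noisy_round_trip_accuracy(self, rng, small_substrate):
        """Per-marker genotype accuracy >= 99% at 1% error, depth 20."""
        _, _, pair, break_site, marker_map = small_substrate
        params = sim.MechanismParams.clean()
        events = sim.simulate_dsbr(params, marker_map, break_site, 25, rng)
        df = sim.make_barcode_table([e.event_id for e in events], rng)
        table = BarcodeTable(df)
        bc = {r.id: r.barcode for r in df.itertuples()}
        truth, reads = {}, []
        for ev in events:
            obs = sim.observe_colony(ev, params, rng)
            truth[ev.event_id] = obs.product_calls()
            reads.extend(sim.emit_reads(
                obs, pair, marker_map, bc[ev.event_id],
                depth=20, error_rate=0.01, rng=rng))
        assigned, _ = demultiplex(reads, table)
        ok = tot = 0
        for ev in events:
            for product, want in zip((Product.P_TRUNC, Product.P_FULL),
                                     truth[ev.event_id]):
                profiles = [
                    call_read_profile(r, pair, marker_map)
                    for r in assigned[(ev.event_id, product)]
                ]
                got = product_genotype(cluster_species(profiles), product)
                tot += len(want.genotype)
                ok += sum(a == b for a, b in zip(got.genotype, want.genotype))
        assert ok / tot >= 0.99
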