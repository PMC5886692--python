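"""Event classification, complexity features, and initiation inference."""

from collections import Counter

import numpy as np
import pytest

from hetdna import simulate as sim
from hetdna.classify import (
    Allele,
    EventClass,
    GapExpansion,
    LesionType,
    Orientation,
    SymmetricTag,
    classify_induced,
    extract_features,
    infer_initiation,
    two_sided_orientation,
)
from hetdna.substrate import Side
from hetdna.tracts import segment_event

from conftest import pc, TRUNC, FULL


def _classify(mm, bs, gt, gf):
    ev = segment_event(pc(TRUNC, gt), pc(FULL, gf), mm)
    return classify_induced(ev, bs, mm)


class TestClassifyInduced:
    def test_canonical_two_sided(self, toy8):
        mm, bs = toy8
        call = _classify(mm, bs, "RRHHDDDD", "DDDDHHRR")
        assert call.klass is EventClass.TWO_SIDED
        assert call.features.hetdna_sides == {Side.UPSTREAM, Side.DOWNSTREAM}

    def test_one_sided_left(self, toy8):
        mm, bs = toy8
        call = _classify(mm, bs, "RHHHDDDD", "DDDDRRRR")
        assert call.klass is EventClass.ONE_SIDED_LEFT

    def test_one_sided_right(self, toy8):
        mm, bs = toy8
        call = _classify(mm, bs, "RRRRDDDD", "DDDDHHRR")
        assert call.klass is EventClass.ONE_SIDED_RIGHT

    def test_displaced_transition_with_displacement_bp(self, toy8):
        mm, bs = toy8
        # both tracts downstream of the break; inter-product transition at
        # the m6/m7 midpoint (325) vs break at 225 -> displacement 100
        call = _classify(mm, bs, "RRRRHHDD", "DDDDDDHH")
        assert call.klass is EventClass.DISPLACED_TRANSITION
        assert call.features.transition_displaced
        assert call.features.displacement_bp == pytest.approx(100.0)

    def test_conversion_only(self, toy8):
        mm, bs = toy8
        call = _classify(mm, bs, "RRDDDDDD", "DDDDDDRR")
        assert call.klass is EventClass.CONVERSION_ONLY

    def test_donor_only(self, toy8):
        mm, bs = toy8
        call = _classify(mm, bs, "RRRRDHDD", "DDDDRRRR")
        assert call.klass is EventClass.DONOR_ONLY

    def test_two_sided_with_donor_alteration_stays_two_sided(self, toy8):
        mm, bs = toy8
        call = _classify(mm, bs, "RRHHDDHD", "DDDDHHRR")
        assert call.klass is EventClass.TWO_SIDED
        assert len(call.features.donor_alterations) == 1

    def test_every_event_gets_exactly_one_class(self, toy8, rng):
        """Exhaustiveness fuzz: any genotype pair yields one class."""
        mm, bs = toy8
        states = np.array(list("RDHN"))
        for _ in range(3000):
            gt = "".join(rng.choice(states, size=8, p=[0.3, 0.3, 0.25, 0.15]))
            gf = "".join(rng.choice(states, size=8, p=[0.3, 0.3, 0.25, 0.15]))
            if set(gt) == {"N"} or set(gf) == {"N"}:
                continue
            call = _classify(mm, bs, gt, gf)
            assert isinstance(call.klass, EventClass)


class TestFeatures:
    def _features(self, mm, bs, gt, gf):
        ev = segment_event(pc(TRUNC, gt), pc(FULL, gf), mm)
        return extract_features(ev, bs.cut_center, mm)

    def test_single_snp_loss_downstream(self, toy8):
        mm, bs = toy8
        # P_FULL: break-adjacent conversion at m5 only
        feats = self._features(mm, bs, "RRHHDDDD", "DDDDDHHR")
        assert feats.gap_expansion_downstream is GapExpansion.SINGLE_SNP
        assert feats.gap_expansion_upstream is GapExpansion.NONE

    def test_multi_snp_gap_expansion(self, toy8):
        mm, bs = toy8
        feats = self._features(mm, bs, "RRHHDDDD", "DDDDDDDH")
        assert feats.gap_expansion_downstream is GapExpansion.MULTI_SNP

    def test_upstream_gap_expansion(self, toy8):
        mm, bs = toy8
        feats = self._features(mm, bs, "RHDDDDDD", "DDDDHHRR")
        assert feats.gap_expansion_upstream is GapExpansion.MULTI_SNP

    def test_restoration_and_conversion_patches(self, toy8):
        mm, bs = toy8
        feats = self._features(mm, bs, "RHRHDDDD", "DDDDHDHR")
        assert feats.n_restoration_patches == 1
        assert feats.n_conversion_patches == 1

    def test_terminal_symmetric_tagged(self, toy8):
        mm, bs = toy8
        # symmetric hetDNA (m1-m2 in both) at the distal end of trunc's
        # asymmetric upstream tract
        feats = self._features(mm, bs, "HHHHDDDD", "HHDDHHRR")
        tags = [tag for tag, *_ in feats.symmetric_regions]
        assert tags == [SymmetricTag.TERMINAL]

    def test_interstitial_symmetric_tagged(self, toy8):
        mm, bs = toy8
        # symmetric run at m7 embedded inside full's tract (hetDNA beyond)
        feats = self._features(mm, bs, "RRHHDDHD", "DDDDHHHH")
        tags = [tag for tag, *_ in feats.symmetric_regions]
        assert tags == [SymmetricTag.INTERSTITIAL]


class TestSimulatorAgreement:
    @pytest.mark.parametrize(
        "mechanism,params_kw",
        [
            ("dsbr", {}),
            ("backmig", {"p_back_migration": 1.0}),
            ("dloop", {}),
        ],
    )
    def test_induced_mechanisms_match_truth(
        self, small_substrate, rng, mechanism, params_kw
    ):
        *_, break_site, mm = small_substrate
        params = sim.MechanismParams.clean(**params_kw)
        if mechanism == "dloop":
            events = sim.simulate_dloop_cleavage(params, mm, break_site, 200, rng)
        else:
            events = sim.simulate_dsbr(params, mm, break_site, 200, rng)
        for ev in events:
            se = segment_event(*ev.product_calls(), mm)
            call = classify_induced(se, break_site, mm)
            assert call.klass is ev.truth.class_truth

    def test_back_migration_always_one_sided(self, small_substrate, rng):
        *_, break_site, mm = small_substrate
        params = sim.MechanismParams.clean(
            p_back_migration=1.0,
            resection_len_dist=sim.BpDist("constant", 300),
        )
        events = sim.simulate_dsbr(params, mm, break_site, 200, rng)
        for ev in events:
            se = segment_event(*ev.product_calls(), mm)
            call = classify_induced(se, break_site, mm)
            assert call.klass in (
                EventClass.ONE_SIDED_LEFT, EventClass.ONE_SIDED_RIGHT)

    @pytest.mark.parametrize("mechanism", ["nick", "gap"])
    def test_spontaneous_mechanisms_match_truth(
        self, small_substrate, rng, mechanism
    ):
        *_, break_site, mm = small_substrate
        params = sim.MechanismParams.clean()
        c = break_site.cut_center
        if mechanism == "nick":
            events = sim.simulate_mr_nick(params, mm, c, 200, rng)
        else:
            events = sim.simulate_gap(params, mm, (c - 60, c + 60), 200, rng)
        for ev in events:
            se = segment_event(*ev.product_calls(), mm)
            call = infer_initiation(se, mm)
            assert call.klass is ev.truth.class_truth


class TestOrientationLaw:
    def test_nick_directed_never_flips(self, small_substrate, rng):
        *_, break_site, mm = small_substrate
        params = sim.MechanismParams.clean()
        events = sim.simulate_dsbr(params, mm, break_site, 2000, rng)
        flips = 0
        for ev in events:
            se = segment_event(*ev.product_calls(), mm)
            o = two_sided_orientation(se, break_site.cut_center, mm)
            flips += o is Orientation.FLIPPED
        assert flips == 0

    def test_random_ligated_flip_fraction_in_binomial_ci(
        self, small_substrate, rng
    ):
        *_, break_site, mm = small_substrate
        params = sim.MechanismParams.clean(
            resolution_mode=sim.ResolutionMode.RANDOM_LIGATED)
        events = sim.simulate_dsbr(params, mm, break_site, 1000, rng)
        counts = Counter()
        for ev in events:
            se = segment_event(*ev.product_calls(), mm)
            o = two_sided_orientation(se, break_site.cut_center, mm)
            if o is not None:
                counts[o] += 1
        n = counts[Orientation.STANDARD] + counts[Orientation.FLIPPED]
        from scipy.stats import binom

        lo, hi = binom.interval(0.99, n, 0.5)
        assert lo <= counts[Orientation.FLIPPED] <= hi


class TestInferInitiation:
    def test_dsb_pattern_with_interstitial_conversion(self, toy8):
        mm, _ = toy8
        # asymmetric tracts m1-m3 (trunc) and m6-m8 (full), conversion at
        # m4-m5 between them: inferred break at the conversion-tract centre
        ev = segment_event(pc(TRUNC, "HHHDDDDD"), pc(FULL, "DDDDDHHH"), mm)
        call = infer_initiation(ev, mm)
        assert call.klass is EventClass.TWO_SIDED
        assert call.initiation.lesion_type is LesionType.DSB
        assert call.initiation.inferred_position == pytest.approx((200 + 250) / 2)
        assert call.initiation.inferred_allele is Allele.RECIPIENT

    def test_dsb_pattern_donor_initiated(self, toy8):
        mm, _ = toy8
        # mirrored pattern: hetDNA in donor-derived regions of both products
        ev = segment_event(pc(TRUNC, "RRRRHHDD"), pc(FULL, "DDHHRRRR"), mm)
        call = infer_initiation(ev, mm)
        assert call.initiation.lesion_type is LesionType.DSB
        assert call.initiation.inferred_allele is Allele.DONOR

    def test_nick_pattern(self, toy8):
        mm, _ = toy8
        # clean junction in P_FULL at m4/m5 midpoint; single tract adjacent
        # to it in trunc's donor-derived (downstream) arm
        ev = segment_event(pc(TRUNC, "RRRRHHDD"), pc(FULL, "DDDDRRRR"), mm)
        call = infer_initiation(ev, mm)
        assert call.klass is EventClass.NICK_LIKE
        assert call.initiation.lesion_type is LesionType.NICK
        assert call.initiation.inferred_position == pytest.approx(225.0)

    def test_gap_pattern(self, toy8):
        mm, _ = toy8
        # symmetric tract at m4-m5 in both products, asymmetric extension in
        # P_FULL only
        ev = segment_event(pc(TRUNC, "RRRHHDDD"), pc(FULL, "DDDHHHHR"), mm)
        call = infer_initiation(ev, mm)
        assert call.klass is EventClass.GAP_LIKE
        assert call.initiation.lesion_type is LesionType.GAP
        assert call.initiation.inferred_position == pytest.approx((200 + 250) / 2)

    def test_uninterpretable_pattern(self, toy8):
        mm, _ = toy8
        ev = segment_event(pc(TRUNC, "RHRHRHRH"), pc(FULL, "HRHRHRHR"), mm)
        call = infer_initiation(ev, mm)
        assert call.klass is EventClass.UNINTERPRETABLE
        assert call.initiation.lesion_type is LesionType.INDETERMINATE

    def test_break_position_recovery(self, small_substrate, rng):
        """>= 95% of clean simulated spontaneous DSB events place the
        inferred break within one inter-marker interval of truth."""
        *_, mm = small_substrate
        lo, hi = mm.homology_span
        spacing = max(np.diff(mm.positions))
        params = sim.MechanismParams.clean()
        hits = n = 0
        for _ in range(300):
            b = rng.uniform(lo + 150, hi - 150)
            allele = "RECIPIENT_D5" if rng.random() < 0.5 else "DONOR_D3"
            ev = sim.simulate_dsbr(params, mm, b, 1, rng, broken_allele=allele)[0]
            se = segment_event(*ev.product_calls(), mm)
            call = infer_initiation(se, mm)
            n += 1
            if (
                call.initiation is not None
                and call.initiation.inferred_position is not None
                and abs(call.initiation.inferred_position - b) <= spacing
            ):
                hits += 1
        assert hits / n >= 0.95

    def test_in_3prime_half_flag(self, toy8):
        mm, _ = toy8
        ev = segment_event(pc(TRUNC, "HHHDDDDD"), pc(FULL, "DDDDDHHH"), mm)
        call = infer_initiation(ev, mm)
        assert call.initiation.in_3prime_half == (
            call.initiation.inferred_position >= sum(mm.homology_span) / 2)
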