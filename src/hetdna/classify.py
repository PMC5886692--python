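"""Mechanistic classification of crossover events from hetDNA patterns.

Induced events (known break) are binned into the mutually exclusive classes
observed in the assay: two-sided asymmetric hetDNA (the canonical
double-strand-break repair signature), one-sided hetDNA, a displaced
donor/recipient hetDNA transition, hetDNA confined to donor-derived
sequence, conversion-only products, or uninterpretable patterns.  Complexity
features (gap expansion, restoration/conversion interruptions, terminal vs
interstitial symmetric hetDNA, donor alterations) are extracted alongside.

Spontaneous events (no known break) are matched against the hetDNA patterns
predicted for the three candidate initiating lesions: a DSB (reciprocal
asymmetric tracts with a transition), a nick (one asymmetric tract adjacent
to the crossover point, in donor-derived context), or a single-strand gap
(a symmetric tract at the crossover point with an asymmetric extension in
one product).  The initiating lesion's allele and position are inferred
where the pattern allows; these labels are descriptive — the same patterns
also arise among break-induced events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .calling import Product
from .substrate import BreakSite, MarkerMap, Side
from .tracts import (
    Context,
    SegmentedEvent,
    Tract,
    TractKind,
    TractSide,
    _region_origin,
    extract_tracts,
)


class EventClass(str, Enum):
    TWO_SIDED = "TWO_SIDED"
    ONE_SIDED_LEFT = "ONE_SIDED_LEFT"
    ONE_SIDED_RIGHT = "ONE_SIDED_RIGHT"
    DISPLACED_TRANSITION = "DISPLACED_TRANSITION"
    DONOR_ONLY = "DONOR_ONLY"
    CONVERSION_ONLY = "CONVERSION_ONLY"
    NICK_LIKE = "NICK_LIKE"
    GAP_LIKE = "GAP_LIKE"
    UNINTERPRETABLE = "UNINTERPRETABLE"


class GapExpansion(str, Enum):
    NONE = "NONE"
    SINGLE_SNP = "SINGLE_SNP"
    MULTI_SNP = "MULTI_SNP"


class SymmetricTag(str, Enum):
    TERMINAL = "TERMINAL"
    INTERSTITIAL = "INTERSTITIAL"


class LesionType(str, Enum):
    DSB = "DSB"
    NICK = "NICK"
    GAP = "GAP"
    INDETERMINATE = "INDETERMINATE"


class Allele(str, Enum):
    RECIPIENT = "RECIPIENT_D5"
    DONOR = "DONOR_D3"
    INDETERMINATE = "INDETERMINATE"


class Orientation(str, Enum):
    STANDARD = "STANDARD"  # hetDNA upstream in P_TRUNC / downstream in P_FULL
    FLIPPED = "FLIPPED"


@dataclass
class EventFeatures:
    gap_expansion_upstream: GapExpansion = GapExpansion.NONE
    gap_expansion_downstream: GapExpansion = GapExpansion.NONE
    n_restoration_patches: int = 0
    n_conversion_patches: int = 0
    symmetric_regions: list[tuple[SymmetricTag, int, int]] = field(default_factory=list)
    donor_alterations: list[Tract] = field(default_factory=list)
    hetdna_sides: set[Side] = field(default_factory=set)
    transition_displaced: bool = False
    displacement_bp: float = 0.0


@dataclass
class InitiationCall:
    lesion_type: LesionType
    inferred_allele: Allele
    inferred_position: float | None
    in_3prime_half: bool | None
    position_interval: tuple[float, float] | None = None


@dataclass
class EventCall:
    event_id: str
    klass: EventClass
    features: EventFeatures
    tracts: list[Tract]
    anchor: float
    initiation: InitiationCall | None = None
    orientation: Orientation | None = None


def _h_markers(event: SegmentedEvent, product: Product) -> set[int]:
    call = event.trunc if product is Product.P_TRUNC else event.full
    return {i for i, c in enumerate(call.genotype) if c == "H"}


def _runs(indices: set[int]) -> list[tuple[int, int]]:
    """Maximal runs of consecutive marker indices."""
    out = []
    for i in sorted(indices):
        if out and i == out[-1][1] + 1:
            out[-1] = (out[-1][0], i)
        else:
            out.append((i, i))
    return out


def _recipient_context_h_sides(
    event: SegmentedEvent, anchor: float, marker_map: MarkerMap
) -> tuple[set[Side], bool]:
    """Sides carrying recipient-context hetDNA, plus whether any
    donor-context hetDNA exists."""
    pos = marker_map.positions
    sides: set[Side] = set()
    donor_h = False
    for product in (Product.P_TRUNC, Product.P_FULL):
        for i in _h_markers(event, product):
            upstream = pos[i] < anchor
            origin = _region_origin(product, upstream)
            if origin is Context.RECIPIENT_DERIVED:
                sides.add(Side.UPSTREAM if upstream else Side.DOWNSTREAM)
            else:
                donor_h = True
    return sides, donor_h


# ---------------------------------------------------------------------------
# feature extraction


def _break_adjacent_conversion(
    event: SegmentedEvent, side: Side, anchor: float, marker_map: MarkerMap
) -> GapExpansion:
    """Gap-expansion signature: a conversion run that includes the
    break-flanking marker on that side of the anchor, within the product
    whose recipient-derived flank covers that side."""
    pos = marker_map.positions
    if side is Side.UPSTREAM:
        call = event.trunc
        side_idx = [i for i in range(len(pos)) if pos[i] < anchor]
        if not side_idx:
            return GapExpansion.NONE
        flank = max(side_idx)
        step = -1  # break-distal direction
    else:
        call = event.full
        side_idx = [i for i in range(len(pos)) if pos[i] >= anchor]
        if not side_idx:
            return GapExpansion.NONE
        flank = min(side_idx)
        step = 1  # break-distal direction
    if call.genotype[flank] != "D":
        return GapExpansion.NONE
    # walk away from the anchor while the donor call persists; step is the
    # direction toward the anchor, so -step moves break-distally
    run = 0
    i = flank
    while i in side_idx and call.genotype[i] == "D":
        run += 1
        i += step
    if i not in side_idx:
        # the run reaches the homology border: the whole arm reads donor,
        # which is a parental flank (or flipped product), not conversion
        return GapExpansion.NONE
    return GapExpansion.SINGLE_SNP if run == 1 else GapExpansion.MULTI_SNP


def _symmetric_tags(
    event: SegmentedEvent, anchor: float, marker_map: MarkerMap
) -> list[tuple[SymmetricTag, int, int]]:
    ht = _h_markers(event, Product.P_TRUNC)
    hf = _h_markers(event, Product.P_FULL)
    shared = ht & hf
    if not shared:
        return []
    asym = (ht | hf) - shared
    out = []
    for first, last in _runs(shared):
        # terminal: contiguous with an asymmetric run on its break-proximal
        # side and no hetDNA beyond its break-distal end
        pos = marker_map.positions
        distal_is_up = pos[first] < anchor and pos[last] < anchor
        if distal_is_up:
            proximal_neighbor = last + 1
            beyond = {i for i in ht | hf if i < first}
        else:
            proximal_neighbor = first - 1
            beyond = {i for i in ht | hf if i > last}
        terminal = proximal_neighbor in asym and not beyond
        out.append(
            (SymmetricTag.TERMINAL if terminal else SymmetricTag.INTERSTITIAL,
             first, last)
        )
    return out


def extract_features(
    event: SegmentedEvent,
    anchor: float,
    marker_map: MarkerMap,
    tracts: list[Tract] | None = None,
) -> EventFeatures:
    if tracts is None:
        tracts = extract_tracts(event, anchor, marker_map)
    feats = EventFeatures()
    feats.gap_expansion_upstream = _break_adjacent_conversion(
        event, Side.UPSTREAM, anchor, marker_map
    )
    feats.gap_expansion_downstream = _break_adjacent_conversion(
        event, Side.DOWNSTREAM, anchor, marker_map
    )
    feats.n_restoration_patches = sum(
        1 for t in tracts if t.kind is TractKind.RESTORATION_PATCH
    )
    # interior conversion: a conversion tract strictly between two hetDNA
    # tracts of the same product
    by_product: dict[Product, list[Tract]] = {}
    for t in tracts:
        by_product.setdefault(t.product_id, []).append(t)
    n_conv_patches = 0
    for product, plist in by_product.items():
        h_idx = sorted(
            i
            for t in plist
            if t.kind in (TractKind.HETDNA, TractKind.SYMMETRIC_HETDNA)
            for i in range(t.first_marker, t.last_marker + 1)
        )
        if not h_idx:
            continue
        for t in plist:
            if t.kind is TractKind.CONVERSION and any(
                i < t.first_marker for i in h_idx
            ) and any(i > t.last_marker for i in h_idx):
                n_conv_patches += 1
    feats.n_conversion_patches = n_conv_patches
    feats.symmetric_regions = _symmetric_tags(event, anchor, marker_map)
    feats.donor_alterations = [
        t
        for t in tracts
        if t.context is Context.DONOR_DERIVED
        and t.kind in (TractKind.HETDNA, TractKind.SYMMETRIC_HETDNA, TractKind.CONVERSION)
    ]
    feats.hetdna_sides, _ = _recipient_context_h_sides(event, anchor, marker_map)
    return feats


# ---------------------------------------------------------------------------
# induced-event classification


def _displaced_transition(
    event: SegmentedEvent, anchor: float, marker_map: MarkerMap
) -> float | None:
    """If both products carry hetDNA wholly on one side of the anchor with a
    clean inter-product transition, return the transition position."""
    pos = marker_map.positions
    ht = _h_markers(event, Product.P_TRUNC)
    hf = _h_markers(event, Product.P_FULL)
    if not ht or not hf or (ht & hf):
        return None
    all_pos = [pos[i] for i in ht | hf]
    if not (all(p < anchor for p in all_pos) or all(p >= anchor for p in all_pos)):
        return None
    if max(ht) < min(hf):
        inner_left, inner_right = max(ht), min(hf)
    elif max(hf) < min(ht):
        inner_left, inner_right = max(hf), min(ht)
    else:
        return None  # interleaved
    return (pos[inner_left] + pos[inner_right]) / 2


def classify_induced(
    event: SegmentedEvent,
    break_site: BreakSite,
    marker_map: MarkerMap,
    event_id: str = "",
) -> EventCall:
    """Assign one of the induced-event classes, in fixed precedence order."""
    anchor = break_site.cut_center
    tracts = extract_tracts(event, anchor, marker_map)
    feats = extract_features(event, anchor, marker_map, tracts)
    sides, donor_h = _recipient_context_h_sides(event, anchor, marker_map)
    any_h = bool(_h_markers(event, Product.P_TRUNC) | _h_markers(event, Product.P_FULL))
    any_conv = any(t.kind is TractKind.CONVERSION for t in tracts)
    if not any_h:
        klass = EventClass.CONVERSION_ONLY if any_conv else EventClass.UNINTERPRETABLE
    elif not sides:
        klass = EventClass.DONOR_ONLY
    elif sides == {Side.UPSTREAM, Side.DOWNSTREAM}:
        klass = EventClass.TWO_SIDED
    else:
        displaced_at = _displaced_transition(event, anchor, marker_map)
        if displaced_at is not None:
            klass = EventClass.DISPLACED_TRANSITION
            feats.transition_displaced = True
            feats.displacement_bp = abs(displaced_at - anchor)
        elif sides == {Side.UPSTREAM}:
            klass = EventClass.ONE_SIDED_LEFT
        elif sides == {Side.DOWNSTREAM}:
            klass = EventClass.ONE_SIDED_RIGHT
        else:  # pragma: no cover - sides is always a subset handled above
            klass = EventClass.UNINTERPRETABLE
    return EventCall(
        event_id=event_id,
        klass=klass,
        features=feats,
        tracts=tracts,
        anchor=anchor,
    )


def two_sided_orientation(
    event: SegmentedEvent, anchor: float, marker_map: MarkerMap
) -> Orientation | None:
    """Which product carries the upstream tract of a two-sided pattern.

    STANDARD is the nick-directed-resolution arrangement: hetDNA upstream of
    the break in ``P_TRUNC`` and downstream in ``P_FULL``.  Returns None if
    the event is not a clean two-sided pattern.
    """
    pos = marker_map.positions
    ht = _h_markers(event, Product.P_TRUNC)
    hf = _h_markers(event, Product.P_FULL)
    if not ht or not hf or (ht & hf):
        return None
    t_up = all(pos[i] < anchor for i in ht)
    t_dn = all(pos[i] >= anchor for i in ht)
    f_up = all(pos[i] < anchor for i in hf)
    f_dn = all(pos[i] >= anchor for i in hf)
    if t_up and f_dn:
        return Orientation.STANDARD
    if t_dn and f_up:
        return Orientation.FLIPPED
    return None


# ---------------------------------------------------------------------------
# spontaneous-event initiation inference


def _clean_junction(
    event: SegmentedEvent, product: Product, marker_map: MarkerMap
) -> float | None:
    """Crossover point of a product with a clean parental flank structure
    (one upstream-parental run followed by one downstream-parental run)."""
    segments = (
        event.segments_trunc if product is Product.P_TRUNC else event.segments_full
    )
    up_state, dn_state = ("R", "D") if product is Product.P_TRUNC else ("D", "R")
    if len(segments) != 2:
        return None
    if segments[0].state != up_state or segments[1].state != dn_state:
        return None
    pos = marker_map.positions
    return (pos[segments[0].last_marker] + pos[segments[1].first_marker]) / 2


def _marker_interval(marker_map: MarkerMap, i: int, j: int) -> float:
    """Local inter-marker distance used as the adjacency tolerance."""
    pos = marker_map.positions
    return abs(pos[j] - pos[i])


def infer_initiation(
    event: SegmentedEvent, marker_map: MarkerMap, event_id: str = ""
) -> EventCall:
    """Infer the initiating lesion of a spontaneous crossover event.

    DSB pattern: disjoint asymmetric tracts in the two products with a
    transition between them; the break is placed at the transition midpoint,
    or at the centre of an interstitial conversion tract separating the
    tracts.  The broken allele is the one whose sequence the hetDNA replaced
    (the minor contribution).  NICK: a single asymmetric tract adjacent to
    the crossover point, in donor-derived context, in one product only.
    GAP: a symmetric tract at the crossover point with an asymmetric
    extension in exactly one product.
    """
    pos = marker_map.positions
    lo, hi = marker_map.homology_span
    mid = (lo + hi) / 2
    ht = _h_markers(event, Product.P_TRUNC)
    hf = _h_markers(event, Product.P_FULL)

    def finish(
        klass: EventClass,
        lesion: LesionType,
        allele: Allele,
        position: float | None,
        interval: tuple[float, float] | None = None,
    ) -> EventCall:
        anchor = position if position is not None else (lo + hi) / 2
        tracts = extract_tracts(event, anchor, marker_map)
        feats = extract_features(event, anchor, marker_map, tracts)
        initiation = InitiationCall(
            lesion_type=lesion,
            inferred_allele=allele,
            inferred_position=position,
            in_3prime_half=(position >= mid) if position is not None else None,
            position_interval=interval,
        )
        return EventCall(
            event_id=event_id,
            klass=klass,
            features=feats,
            tracts=tracts,
            anchor=anchor,
            initiation=initiation,
        )

    if not ht and not hf:
        # conversion-only or parental
        has_conv = False
        for call, product in ((event.trunc, Product.P_TRUNC), (event.full, Product.P_FULL)):
            junction = _clean_junction(event, product, marker_map)
            if junction is None:
                has_conv = True  # extra segments without hetDNA = conversion
        klass = EventClass.CONVERSION_ONLY if has_conv else EventClass.UNINTERPRETABLE
        return finish(klass, LesionType.INDETERMINATE, Allele.INDETERMINATE, None)

    shared = ht & hf
    if ht and hf and shared:
        # candidate GAP: symmetric tract with an asymmetric extension in
        # exactly one product
        asym_t = ht - shared
        asym_f = hf - shared
        sym_runs = _runs(shared)
        if len(sym_runs) == 1 and (bool(asym_t) != bool(asym_f)):
            first, last = sym_runs[0]
            asym = asym_t or asym_f
            adjacent = (min(asym) == last + 1) or (max(asym) == first - 1)
            if adjacent and len(_runs(asym)) == 1:
                position = (pos[first] + pos[last]) / 2
                return finish(
                    EventClass.GAP_LIKE,
                    LesionType.GAP,
                    Allele.INDETERMINATE,
                    position,
                    interval=(float(pos[first]), float(pos[last] + 1)),
                )
        return finish(
            EventClass.UNINTERPRETABLE, LesionType.INDETERMINATE,
            Allele.INDETERMINATE, None,
        )

    if ht and hf:
        # candidate DSB: disjoint, non-interleaved asymmetric tracts
        if max(ht) < min(hf):
            left_h, right_h = ht, hf
            broken = Allele.RECIPIENT  # trunc tract upstream: hetDNA replaced
            # recipient sequence (standard orientation)
        elif max(hf) < min(ht):
            left_h, right_h = hf, ht
            broken = Allele.DONOR
        else:
            return finish(
                EventClass.UNINTERPRETABLE, LesionType.INDETERMINATE,
                Allele.INDETERMINATE, None,
            )
        e, s = max(left_h), min(right_h)
        between = list(range(e + 1, s))
        if between:
            position = (pos[between[0]] + pos[between[-1]]) / 2
            interval = (float(pos[between[0]]), float(pos[between[-1]] + 1))
        else:
            position = (pos[e] + pos[s]) / 2
            interval = (float(pos[e]), float(pos[s] + 1))
        return finish(EventClass.TWO_SIDED, LesionType.DSB, broken, position, interval)

    # exactly one product with hetDNA: candidate NICK
    h_product = Product.P_TRUNC if ht else Product.P_FULL
    h_set = ht or hf
    other = Product.P_FULL if h_product is Product.P_TRUNC else Product.P_TRUNC
    junction = _clean_junction(event, other, marker_map)
    runs = _runs(h_set)
    if junction is not None and len(runs) == 1:
        first, last = runs[0]
        # adjacency: nearest tract end within one inter-marker interval of
        # the crossover point
        d = min(abs(pos[first] - junction), abs(pos[last] - junction))
        spacing = (hi - lo) / max(len(pos) - 1, 1)
        upstream = pos[first] < junction
        origin = _region_origin(h_product, upstream)
        if d <= 1.5 * spacing and origin is Context.DONOR_DERIVED:
            nicked = (
                Allele.RECIPIENT if origin is Context.DONOR_DERIVED else Allele.DONOR
            )
            return finish(
                EventClass.NICK_LIKE, LesionType.NICK, nicked, junction
            )
    return finish(
        EventClass.UNINTERPRETABLE, LesionType.INDETERMINATE,
        Allele.INDETERMINATE, None,
    )
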