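"""Segmentation of product genotypes and hetDNA/conversion tract extraction.

A crossover product is recipient-derived on one side of the exchange point
and donor-derived on the other (``P_TRUNC``: recipient upstream / donor
downstream; ``P_FULL``: the reverse).  Against that parental-flank structure,
an ``H`` run marks unrepaired heteroduplex DNA, a donor run inside
recipient-derived sequence marks gene conversion, and a recipient run
interrupting a hetDNA tract marks a restoration patch.  Tract length on each
side of the anchoring break is measured to the most break-distal transition
from heteroduplex (or converted) DNA back to parental sequence, placing each
transition at the midpoint of the flanking marker interval, or at the
homology border when the outermost informative marker is terminal.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .calling import Product, ProductCall
from .substrate import MarkerMap, Side


class TractKind(str, Enum):
    HETDNA = "HETDNA"
    CONVERSION = "CONVERSION"
    RESTORATION_PATCH = "RESTORATION_PATCH"
    SYMMETRIC_HETDNA = "SYMMETRIC_HETDNA"


class TractSide(str, Enum):
    UPSTREAM = "UPSTREAM"
    DOWNSTREAM = "DOWNSTREAM"
    SPANNING = "SPANNING"


class Context(str, Enum):
    RECIPIENT_DERIVED = "RECIPIENT_DERIVED"
    DONOR_DERIVED = "DONOR_DERIVED"


@dataclass(frozen=True)
class Segment:
    state: str  # R, D or H
    first_marker: int  # 0-based marker index, inclusive
    last_marker: int  # inclusive
    bp_span: tuple[int, int]  # half-open, recipient frame

    @property
    def n_markers(self) -> int:
        return self.last_marker - self.first_marker + 1


@dataclass(frozen=True)
class Tract:
    kind: TractKind
    side: TractSide
    context: Context
    product_id: Product
    first_marker: int
    last_marker: int
    bp_span: tuple[int, int]

    @property
    def length_bp(self) -> int:
        return self.bp_span[1] - self.bp_span[0]


class TractError(ValueError):
    pass


def segment_product(
    call: ProductCall, marker_map: MarkerMap
) -> tuple[list[Segment], list[int]]:
    """Maximal runs of identical state over the informative markers.

    N markers are absorbed into a run when the nearest non-N calls on both
    sides agree; otherwise they are excluded and reported.  Returns
    ``(segments, excluded_marker_indices)``.
    """
    calls = list(call.genotype)
    n = len(calls)
    if n != len(marker_map):
        raise TractError("genotype length does not match marker map")
    informative = [i for i, c in enumerate(calls) if c != "N"]
    if not informative:
        raise TractError("all-N genotype vector")
    resolved = calls[:]
    excluded: list[int] = []
    for i, c in enumerate(calls):
        if c != "N":
            continue
        left = next((resolved[j] for j in range(i - 1, -1, -1) if calls[j] != "N"), None)
        right = next((calls[j] for j in range(i + 1, n) if calls[j] != "N"), None)
        if left is not None and right is not None and left == right:
            resolved[i] = left
        else:
            excluded.append(i)
    segments: list[Segment] = []
    pos = marker_map.positions
    run_start = None
    for i in range(n + 1):
        state = resolved[i] if i < n and i not in excluded else None
        if run_start is not None and (state is None or state != resolved[run_start]):
            segments.append(
                Segment(
                    state=resolved[run_start],
                    first_marker=run_start,
                    last_marker=prev,
                    bp_span=(pos[run_start], pos[prev] + 1),
                )
            )
            run_start = None
        if state is not None and run_start is None:
            run_start = i
        if state is not None:
            prev = i
    return segments, excluded


def _flank_orientation(product_id: Product) -> tuple[str, str]:
    """(upstream parental call, downstream parental call) for a CO product."""
    if product_id is Product.P_FULL:
        return "D", "R"
    return "R", "D"  # P_TRUNC and default


def _region_origin(product_id: Product, upstream_of_anchor: bool) -> Context:
    up_state, _ = _flank_orientation(product_id)
    if upstream_of_anchor:
        return (
            Context.RECIPIENT_DERIVED if up_state == "R" else Context.DONOR_DERIVED
        )
    return Context.DONOR_DERIVED if up_state == "R" else Context.RECIPIENT_DERIVED


def _segment_side(seg: Segment, anchor: float) -> TractSide:
    if seg.bp_span[1] <= anchor:
        return TractSide.UPSTREAM
    if seg.bp_span[0] > anchor:
        return TractSide.DOWNSTREAM
    return TractSide.SPANNING


def _parental_call(context: Context) -> str:
    return "R" if context is Context.RECIPIENT_DERIVED else "D"


def _split_at_anchor(
    segments: list[Segment], anchor: float, pos: list[int]
) -> list[Segment]:
    """Split non-H runs that span the anchor: a donor run continuing across
    the break mixes parental flank with break-adjacent conversion, which
    belong to different regions.  H runs are left intact (a single hetDNA
    tract may legitimately cross the anchor after branch migration)."""
    out = []
    for seg in segments:
        if seg.state == "H" or not (seg.bp_span[0] < anchor <= seg.bp_span[1] - 1):
            out.append(seg)
            continue
        left = [i for i in range(seg.first_marker, seg.last_marker + 1) if pos[i] < anchor]
        right = [i for i in range(seg.first_marker, seg.last_marker + 1) if pos[i] >= anchor]
        if not left or not right:
            out.append(seg)
            continue
        out.append(Segment(seg.state, left[0], left[-1], (pos[left[0]], pos[left[-1]] + 1)))
        out.append(Segment(seg.state, right[0], right[-1], (pos[right[0]], pos[right[-1]] + 1)))
    return out


def _segments_to_tracts(
    segments: list[Segment], product_id: Product, anchor: float, pos: list[int] | None = None
) -> list[Tract]:
    if pos is not None:
        segments = _split_at_anchor(segments, anchor, pos)
    tracts = []
    for k, seg in enumerate(segments):
        side = _segment_side(seg, anchor)
        if side is TractSide.SPANNING:
            # origin taken from the side holding most of the segment
            mid = (seg.bp_span[0] + seg.bp_span[1]) / 2
            context = _region_origin(product_id, mid < anchor)
        else:
            context = _region_origin(product_id, side is TractSide.UPSTREAM)
        parental = _parental_call(context)
        if seg.state == "H":
            tracts.append(
                Tract(
                    TractKind.HETDNA,
                    side,
                    context,
                    product_id,
                    seg.first_marker,
                    seg.last_marker,
                    seg.bp_span,
                )
            )
        elif seg.state != parental:
            # non-parental homoduplex: conversion within this region
            tracts.append(
                Tract(
                    TractKind.CONVERSION,
                    side,
                    context,
                    product_id,
                    seg.first_marker,
                    seg.last_marker,
                    seg.bp_span,
                )
            )
        else:
            # parental run flanked by H on both sides = restoration patch
            if (
                0 < k < len(segments) - 1
                and segments[k - 1].state == "H"
                and segments[k + 1].state == "H"
            ):
                tracts.append(
                    Tract(
                        TractKind.RESTORATION_PATCH,
                        side,
                        context,
                        product_id,
                        seg.first_marker,
                        seg.last_marker,
                        seg.bp_span,
                    )
                )
    return tracts


@dataclass
class SegmentedEvent:
    trunc: ProductCall
    full: ProductCall
    segments_trunc: list[Segment]
    segments_full: list[Segment]
    excluded_trunc: list[int]
    excluded_full: list[int]


def segment_event(
    trunc: ProductCall, full: ProductCall, marker_map: MarkerMap
) -> SegmentedEvent:
    st, et = segment_product(trunc, marker_map)
    sf, ef = segment_product(full, marker_map)
    return SegmentedEvent(trunc, full, st, sf, et, ef)


def extract_tracts(
    event: SegmentedEvent, anchor: float, marker_map: MarkerMap
) -> list[Tract]:
    """All hetDNA / conversion / restoration tracts of one event.

    H segments occupying identical marker positions in both products are
    relabelled symmetric hetDNA (both interacting duplexes heteroduplex at
    the same position).
    """
    lo, hi = marker_map.homology_span
    if not lo <= anchor <= hi:
        raise TractError(f"anchor {anchor} outside homology span [{lo},{hi}]")
    pos = marker_map.positions
    tracts = _segments_to_tracts(event.segments_trunc, Product.P_TRUNC, anchor, pos)
    tracts += _segments_to_tracts(event.segments_full, Product.P_FULL, anchor, pos)
    h_markers = {
        Product.P_TRUNC: set(),
        Product.P_FULL: set(),
    }
    for t in tracts:
        if t.kind is TractKind.HETDNA:
            h_markers[t.product_id].update(range(t.first_marker, t.last_marker + 1))
    shared = h_markers[Product.P_TRUNC] & h_markers[Product.P_FULL]
    out = []
    for t in tracts:
        markers = set(range(t.first_marker, t.last_marker + 1))
        if t.kind is TractKind.HETDNA and markers <= shared:
            other = (
                h_markers[Product.P_FULL]
                if t.product_id is Product.P_TRUNC
                else h_markers[Product.P_TRUNC]
            )
            if markers <= other:
                t = Tract(
                    TractKind.SYMMETRIC_HETDNA,
                    t.side,
                    t.context,
                    t.product_id,
                    t.first_marker,
                    t.last_marker,
                    t.bp_span,
                )
        out.append(t)
    return out


# ---------------------------------------------------------------------------
# tract length under the "most break-distal transition" definition


def _informative_markers(
    call: ProductCall, product_id: Product, anchor: float, marker_map: MarkerMap
) -> set[int]:
    """Marker indices that are heteroduplex, or that carry the non-parental
    allele for their region (donor call in recipient-derived sequence or
    recipient call in donor-derived sequence)."""
    out = set()
    pos = marker_map.positions
    for i, c in enumerate(call.genotype):
        upstream = pos[i] < anchor
        origin = _region_origin(product_id, upstream)
        if c == "H" or (c in "RD" and c != _parental_call(origin)):
            out.add(i)
    return out


def hetdna_length(
    event: SegmentedEvent,
    side: Side,
    anchor: float,
    marker_map: MarkerMap,
) -> float:
    """hetDNA length on one side of the anchor, in bp.

    The length runs from the anchor to the midpoint between the most
    break-distal informative marker (heteroduplex, or a non-parental call
    for its region, in either product) and the next marker beyond it; when
    that marker is the outermost marker, the length extends to the homology
    border.  Returns 0 when the side carries no hetDNA or conversion.
    """
    pos = marker_map.positions
    lo, hi = marker_map.homology_span
    if side is Side.UPSTREAM:
        side_markers = {i for i in range(len(pos)) if pos[i] < anchor}
    else:
        side_markers = {i for i in range(len(pos)) if pos[i] >= anchor}
    if not side_markers:
        raise TractError(f"no markers on side {side.value}")
    informative = sorted(
        (
            _informative_markers(event.trunc, Product.P_TRUNC, anchor, marker_map)
            | _informative_markers(event.full, Product.P_FULL, anchor, marker_map)
        )
        & side_markers
    )
    if not informative:
        return 0.0
    if side is Side.UPSTREAM:
        outer = min(informative)
        if outer == 0:
            transition = float(lo)
        else:
            transition = (pos[outer] + pos[outer - 1]) / 2
        return anchor - transition
    outer = max(informative)
    if outer == len(pos) - 1:
        transition = float(hi)
    else:
        transition = (pos[outer] + pos[outer + 1]) / 2
    return transition - anchor


def total_hetdna_length(
    event: SegmentedEvent, anchor: float, marker_map: MarkerMap
) -> float:
    """Span between the most break-distal transitions on the two sides."""
    up = hetdna_length(event, Side.UPSTREAM, anchor, marker_map)
    dn = hetdna_length(event, Side.DOWNSTREAM, anchor, marker_map)
    if up == 0.0 and dn == 0.0:
        raise TractError("event contains no hetDNA or conversion")
    return up + dn


def tract_table(event_id: str, tracts: list[Tract]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": event_id,
            "product": [t.product_id.value for t in tracts],
            "kind": [t.kind.value for t in tracts],
            "context": [t.context.value for t in tracts],
            "side": [t.side.value for t in tracts],
            "first_marker": [t.first_marker for t in tracts],
            "last_marker": [t.last_marker for t in tracts],
            "length_bp": [t.length_bp for t in tracts],
        }
    )
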