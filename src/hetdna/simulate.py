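"""Strand-resolved simulator of crossover mechanisms, colony segregation
and read generation.

Events are simulated at marker resolution with bp-valued interval endpoints:
each crossover product is a duplex of two strands, each strand a vector of
parental alleles (R/D) over the marker map.  Heteroduplex DNA is a region
where the two strands disagree; after the first post-recombination round of
replication the two strands segregate into two colony lineages, which is why
an unrepaired hetDNA tract is observed as two read species per product.
Full nucleotide sequences are realised only when reads are emitted.

Mechanisms:

* ``simulate_dsbr`` — canonical double-strand-break repair: resection on
  both sides forms a hetDNA tract per side; optional 3'-end loss (gap
  expansion), break-adjacent single-SNP loss, D-loop back-migration, HJ
  migration (terminal symmetric hetDNA, or a displaced transition),
  template switching and patch repair; resolution either nick-directed
  (fixed tract orientation) or random on ligated junctions.
* ``simulate_mr_nick`` — Meselson-Radding nick initiation: a single
  asymmetric tract in donor-derived context adjacent to the crossover point.
* ``simulate_gap`` — single-strand gap initiation: symmetric hetDNA across
  the gap plus an asymmetric extension in one product.
* ``simulate_dloop_cleavage`` — D-loop processing before extension of the
  invading end; the reciprocal product arises by an SDSA-like annealing and
  looks one- or two-sided depending on which end was extended.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

from .calling import Product, ProductCall, ReadRecord
from .classify import EventClass, Orientation
from .substrate import AllelePair, BreakSite, MarkerMap

UNIVERSAL_FWD_FULL = "CTTTTTACGCCCACAACAAGAACC"
UNIVERSAL_REV_FULL = "GCTTGGGAGTTGGGAATTGAAGTT"
UNIVERSAL_FWD_TRUNC = "ACGAGCTCGAATTCATCGATGATA"
UNIVERSAL_REV_TRUNC = "TCACTTTTGCCCTGGAACTTAGTG"

_COMP = str.maketrans("ACGT", "TGCA")


def _rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class Mechanism(str, Enum):
    DSBR = "DSBR"
    MR_NICK = "MR_NICK"
    GAP = "GAP"
    DLOOP_CLEAVAGE = "DLOOP_CLEAVAGE"


# ---------------------------------------------------------------------------
# parameter distributions


@dataclass(frozen=True)
class BpDist:
    """A distribution over non-negative bp extents.

    kinds: ``constant`` (value), ``geometric`` (mean), ``uniform`` (low,
    high).
    """

    kind: str = "geometric"
    mean: float = 1000.0
    low: float = 0.0
    high: float = 0.0

    def sample(self, rng: np.random.Generator) -> int:
        if self.kind == "constant":
            return int(self.mean)
        if self.kind == "geometric":
            if self.mean <= 0:
                return 0
            return int(rng.geometric(1.0 / self.mean))
        if self.kind == "uniform":
            return int(rng.uniform(self.low, self.high))
        raise ValueError(f"unknown distribution kind: {self.kind}")


class ResolutionMode(str, Enum):
    NICK_DIRECTED = "NICK_DIRECTED"
    RANDOM_LIGATED = "RANDOM_LIGATED"


@dataclass(frozen=True)
class MechanismParams:
    """Knobs of the mechanism models.

    Single-SNP-loss defaults are the efficiencies measured for the
    break-flanking SNPs (49% upstream, 94% downstream), which track the
    identity of the terminal mismatch; the restoration bias default is the
    observed 26:11 restoration:conversion split among repaired mismatches.
    """

    resection_len_dist: BpDist = BpDist("geometric", 1000.0)
    p_end_loss: float = 0.15
    end_loss_extent_dist: BpDist = BpDist("geometric", 150.0)
    p_single_snp_loss_upstream: float = 0.49
    p_single_snp_loss_downstream: float = 0.94
    invasion_extent_dist: BpDist = BpDist("geometric", 1000.0)
    p_back_migration: float = 0.0
    hj_migration_dist: BpDist = BpDist("constant", 0.0)
    p_template_switch: float = 0.0
    switch_extent_dist: BpDist = BpDist("geometric", 300.0)
    resolution_mode: ResolutionMode = ResolutionMode.NICK_DIRECTED
    p_patch_repair: float = 0.0
    p_restoration_given_repair: float = 26 / 37
    p_daughter_loss: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_end_loss",
            "p_single_snp_loss_upstream",
            "p_single_snp_loss_downstream",
            "p_back_migration",
            "p_template_switch",
            "p_patch_repair",
            "p_restoration_given_repair",
            "p_daughter_loss",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")

    @classmethod
    def clean(cls, **overrides) -> "MechanismParams":
        """All optional complexity off: the textbook mechanism."""
        base = dict(
            p_end_loss=0.0,
            p_single_snp_loss_upstream=0.0,
            p_single_snp_loss_downstream=0.0,
            p_back_migration=0.0,
            hj_migration_dist=BpDist("constant", 0.0),
            p_template_switch=0.0,
            p_patch_repair=0.0,
            p_daughter_loss=0.0,
        )
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# event record


@dataclass
class Duplex:
    """Two strands of parental-allele calls over the markers."""

    top: list[str]
    bottom: list[str]

    @classmethod
    def uniform(cls, n: int, allele: str) -> "Duplex":
        return cls(top=[allele] * n, bottom=[allele] * n)

    def set_het(self, idx: list[int], minority: str) -> None:
        for i in idx:
            self.top[i] = minority
            # bottom keeps background allele

    def set_both(self, idx: list[int], allele: str) -> None:
        for i in idx:
            self.top[i] = allele
            self.bottom[i] = allele

    def genotype(self) -> tuple[str, ...]:
        out = []
        for t, b in zip(self.top, self.bottom):
            out.append(t if t == b else "H")
        return tuple(out)


@dataclass
class TruthRecord:
    break_pos: float | None = None
    broken_allele: str = "RECIPIENT_D5"
    resection_up: int = 0
    resection_dn: int = 0
    end_loss_up: int = 0
    end_loss_dn: int = 0
    single_snp_loss_up: bool = False
    single_snp_loss_dn: bool = False
    invasion_side: str = ""
    back_migration: bool = False
    hj_migration_bp: int = 0
    displaced_to: float | None = None
    symmetric_interval: tuple[float, float] | None = None
    template_switch_interval: tuple[float, float] | None = None
    repaired_markers: list[tuple[int, str]] = field(default_factory=list)
    orientation: Orientation = Orientation.STANDARD
    het_interval_up: tuple[float, float] | None = None
    het_interval_dn: tuple[float, float] | None = None
    extended_end: str = ""  # D-loop cleavage: which end was extended
    nick_host: str = ""  # MR/gap: product hosting the asymmetric tract
    class_truth: EventClass = EventClass.UNINTERPRETABLE


@dataclass
class SimulatedEvent:
    event_id: str
    mechanism: Mechanism
    truth: TruthRecord
    trunc: Duplex
    full: Duplex

    def product_calls(self) -> tuple[ProductCall, ProductCall]:
        """Noiseless marker-level genotypes (both lineages observed)."""
        return (
            ProductCall(Product.P_TRUNC, self.trunc.genotype(), 2),
            ProductCall(Product.P_FULL, self.full.genotype(), 2),
        )


def _markers_in(marker_map: MarkerMap, lo: float, hi: float) -> list[int]:
    return [i for i, p in enumerate(marker_map.positions) if lo <= p < hi]


def _clamp(x: float, lo: float, hi: float) -> float:
    return max(lo, min(hi, x))


# ---------------------------------------------------------------------------
# DSBR


def _truth_class(
    truth: TruthRecord, marker_map: MarkerMap, trunc: Duplex, full: Duplex
) -> EventClass:
    """Expected noiseless observed class, given the generated duplexes."""
    gt, gf = trunc.genotype(), full.genotype()
    pos = marker_map.positions
    b = truth.displaced_to if truth.displaced_to is not None else truth.break_pos
    anchor = truth.break_pos
    ht = {i for i, c in enumerate(gt) if c == "H"}
    hf = {i for i, c in enumerate(gf) if c == "H"}
    if not ht and not hf:
        any_conv = any(
            c == "D" and pos[i] < anchor for i, c in enumerate(gt)
        ) or any(c == "D" and pos[i] >= anchor for i, c in enumerate(gf))
        return EventClass.CONVERSION_ONLY if any_conv else EventClass.UNINTERPRETABLE
    if truth.displaced_to is not None and ht and hf:
        allp = [pos[i] for i in ht | hf]
        if all(p < anchor for p in allp) or all(p >= anchor for p in allp):
            return EventClass.DISPLACED_TRANSITION
    # recipient-context hetDNA sides under the event's orientation
    if truth.orientation is Orientation.STANDARD:
        up = any(pos[i] < anchor for i in ht)
        dn = any(pos[i] >= anchor for i in hf)
        donor_side = any(pos[i] >= anchor for i in ht) or any(
            pos[i] < anchor for i in hf
        )
    else:
        up = any(pos[i] < anchor for i in hf)
        dn = any(pos[i] >= anchor for i in ht)
        donor_side = any(pos[i] >= anchor for i in hf) or any(
            pos[i] < anchor for i in ht
        )
    if truth.orientation is Orientation.FLIPPED:
        # hetDNA sits in donor-derived sequence of both products
        return EventClass.DONOR_ONLY if (ht or hf) else EventClass.CONVERSION_ONLY
    if up and dn:
        return EventClass.TWO_SIDED
    if up:
        return EventClass.ONE_SIDED_LEFT
    if dn:
        return EventClass.ONE_SIDED_RIGHT
    if donor_side:
        return EventClass.DONOR_ONLY
    return EventClass.UNINTERPRETABLE


def simulate_dsbr(
    params: MechanismParams,
    marker_map: MarkerMap,
    break_site: BreakSite | float,
    n: int,
    rng: np.random.Generator | None = None,
    broken_allele: str = "RECIPIENT_D5",
) -> list[SimulatedEvent]:
    """Canonical DSB repair with optional complexity, resolved as a CO.

    ``broken_allele='DONOR_D3'`` mirrors the pattern (spontaneous initiation
    in the donor), which at marker level equals the flipped orientation.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    b = break_site.cut_center if isinstance(break_site, BreakSite) else float(break_site)
    lo, hi = marker_map.homology_span
    nm = len(marker_map)
    events = []
    for k in range(n):
        t = TruthRecord(break_pos=b, broken_allele=broken_allele)
        t.resection_up = params.resection_len_dist.sample(rng)
        t.resection_dn = params.resection_len_dist.sample(rng)
        het_up = (_clamp(b - t.resection_up, lo, hi), b)
        het_dn = (b, _clamp(b + t.resection_dn, lo, hi))
        conv_up = conv_dn = None
        if rng.random() < params.p_end_loss:
            t.end_loss_up = params.end_loss_extent_dist.sample(rng)
            conv_up = (_clamp(b - t.end_loss_up, lo, hi), b)
            het_up = (het_up[0], min(het_up[1], conv_up[0]))
        if rng.random() < params.p_end_loss:
            t.end_loss_dn = params.end_loss_extent_dist.sample(rng)
            conv_dn = (b, _clamp(b + t.end_loss_dn, lo, hi))
            het_dn = (max(het_dn[0], conv_dn[1]), het_dn[1])
        t.single_snp_loss_up = rng.random() < params.p_single_snp_loss_upstream
        t.single_snp_loss_dn = rng.random() < params.p_single_snp_loss_downstream
        t.invasion_side = "UPSTREAM" if rng.random() < 0.5 else "DOWNSTREAM"
        if rng.random() < params.p_back_migration:
            t.back_migration = True
            if t.invasion_side == "UPSTREAM":
                het_up = (b, b)
            else:
                het_dn = (b, b)
        sym = None
        hj = params.hj_migration_dist.sample(rng)
        t.hj_migration_bp = hj
        if hj > 0:
            # outward migration of one distal HJ: terminal symmetric hetDNA
            if rng.random() < 0.5 and het_up[1] > het_up[0]:
                sym = (_clamp(het_up[0] - hj, lo, hi), het_up[0])
            elif het_dn[1] > het_dn[0]:
                sym = (het_dn[1], _clamp(het_dn[1] + hj, lo, hi))
            t.symmetric_interval = sym
        elif hj < 0:
            # migration of one HJ past the break: both tracts one side
            direction = 1 if rng.random() < 0.5 else -1
            shift = -hj
            tpos = _clamp(b + direction * shift, lo, hi)
            t.displaced_to = tpos
            if direction > 0:
                het_up = (b, tpos)  # swept region: trunc-borne tract
                het_dn = (tpos, _clamp(tpos + t.resection_dn, lo, hi))
            else:
                het_dn = (tpos, b)
                het_up = (_clamp(tpos - t.resection_up, lo, hi), tpos)
        t.het_interval_up = het_up
        t.het_interval_dn = het_dn
        ts = None
        if rng.random() < params.p_template_switch:
            ext = params.switch_extent_dist.sample(rng)
            # place the switch footprint in a donor-derived region
            if rng.random() < 0.5:  # downstream donor region (P_TRUNC side)
                start = rng.uniform(max(b, het_dn[1]), hi) if het_dn[1] < hi else b
                ts = (start, _clamp(start + ext, lo, hi))
                ts_product = "P_TRUNC"
            else:
                stop = rng.uniform(lo, min(b, het_up[0])) if het_up[0] > lo else b
                ts = (_clamp(stop - ext, lo, hi), stop)
                ts_product = "P_FULL"
            t.template_switch_interval = ts
        flipped = (
            params.resolution_mode is ResolutionMode.RANDOM_LIGATED
            and rng.random() < 0.5
        )
        if broken_allele == "DONOR_D3":
            flipped = not flipped
        t.orientation = Orientation.FLIPPED if flipped else Orientation.STANDARD

        trunc = _background(marker_map, Product.P_TRUNC, b)
        full = _background(marker_map, Product.P_FULL, b)
        if t.displaced_to is not None:
            # both tracts on the displacement side: the swept tract stays
            # with the product whose flank it adjoins
            host_up, host_dn = (trunc, full) if not flipped else (full, trunc)
            host_up.set_het(_markers_in(marker_map, *het_up), _minority(host_up, marker_map, het_up))
            host_dn.set_het(_markers_in(marker_map, *het_dn), _minority(host_dn, marker_map, het_dn))
        else:
            host_up, host_dn = (trunc, full) if not flipped else (full, trunc)
            host_up.set_het(_markers_in(marker_map, *het_up), _minority(host_up, marker_map, het_up))
            host_dn.set_het(_markers_in(marker_map, *het_dn), _minority(host_dn, marker_map, het_dn))
        if conv_up:
            host_up.set_both(_markers_in(marker_map, *conv_up), "D")
        if conv_dn:
            host_dn.set_both(_markers_in(marker_map, *conv_dn), "D")
        if t.single_snp_loss_up and not conv_up:
            idx = _markers_in(marker_map, lo, b)
            if idx:
                host_up.set_both([idx[-1]], "D")
        if t.single_snp_loss_dn and not conv_dn:
            idx = _markers_in(marker_map, b, hi)
            if idx:
                host_dn.set_both([idx[0]], "D")
        if sym:
            for dup in (trunc, full):
                dup.set_het(
                    _markers_in(marker_map, *sym), _minority(dup, marker_map, sym)
                )
        if ts:
            host = trunc if ts_product == "P_TRUNC" else full
            host.set_het(_markers_in(marker_map, *ts), "R")
        _patch_repair(params, rng, marker_map, t, trunc, full, b, flipped)
        t.class_truth = _truth_class(t, marker_map, trunc, full)
        events.append(SimulatedEvent(f"dsbr_{k:05d}", Mechanism.DSBR, t, trunc, full))
    return events


def _background(marker_map: MarkerMap, product: Product, junction: float) -> Duplex:
    alleles = []
    for p in marker_map.positions:
        if product is Product.P_TRUNC:
            alleles.append("R" if p < junction else "D")
        else:
            alleles.append("D" if p < junction else "R")
    return Duplex(top=list(alleles), bottom=list(alleles))


def _minority(dup: Duplex, marker_map: MarkerMap, interval: tuple[float, float]) -> str:
    """The allele the invading strand contributes within an interval: the
    opposite of the duplex background there."""
    idx = _markers_in(marker_map, *interval)
    if not idx:
        return "R"
    bg = dup.bottom[idx[0]]
    return "D" if bg == "R" else "R"


def _patch_repair(
    params: MechanismParams,
    rng: np.random.Generator,
    marker_map: MarkerMap,
    t: TruthRecord,
    trunc: Duplex,
    full: Duplex,
    b: float,
    flipped: bool,
) -> None:
    if params.p_patch_repair <= 0:
        return
    for name, dup in (("P_TRUNC", trunc), ("P_FULL", full)):
        for i in range(len(marker_map)):
            if dup.top[i] == dup.bottom[i]:
                continue
            if rng.random() >= params.p_patch_repair:
                continue
            restore = rng.random() < params.p_restoration_given_repair
            # restoration returns both strands to the background (bottom)
            # allele of the invaded region; conversion fixes the invader
            target = dup.bottom[i] if restore else dup.top[i]
            dup.set_both([i], target)
            t.repaired_markers.append((i, "RESTORATION" if restore else "CONVERSION"))


# ---------------------------------------------------------------------------
# nick / gap / D-loop cleavage


def simulate_mr_nick(
    params: MechanismParams,
    marker_map: MarkerMap,
    nick_position: float,
    n: int,
    rng: np.random.Generator | None = None,
) -> list[SimulatedEvent]:
    """Meselson-Radding nick initiation: one asymmetric hetDNA tract in
    donor-derived context adjacent to the crossover point."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    lo, hi = marker_map.homology_span
    tpos = float(nick_position)
    if not lo <= tpos <= hi:
        raise ValueError("nick outside homology")
    events = []
    for k in range(n):
        t = TruthRecord(break_pos=tpos)
        ext = params.invasion_extent_dist.sample(rng)
        trunc = _background(marker_map, Product.P_TRUNC, tpos)
        full = _background(marker_map, Product.P_FULL, tpos)
        if rng.random() < 0.5:
            t.nick_host = "P_TRUNC"  # tract in trunc's donor (downstream) arm
            het = (tpos, _clamp(tpos + ext, lo, hi))
            trunc.set_het(_markers_in(marker_map, *het), "R")
        else:
            t.nick_host = "P_FULL"  # tract in full's donor (upstream) arm
            het = (_clamp(tpos - ext, lo, hi), tpos)
            full.set_het(_markers_in(marker_map, *het), "R")
        t.het_interval_up = het
        has_marker = bool(_markers_in(marker_map, *het))
        t.class_truth = (
            EventClass.NICK_LIKE if has_marker else EventClass.UNINTERPRETABLE
        )
        events.append(SimulatedEvent(f"nick_{k:05d}", Mechanism.MR_NICK, t, trunc, full))
    return events


def simulate_gap(
    params: MechanismParams,
    marker_map: MarkerMap,
    gap_interval: tuple[float, float],
    n: int,
    rng: np.random.Generator | None = None,
) -> list[SimulatedEvent]:
    """Gap initiation: symmetric hetDNA across the gap plus an asymmetric
    extension in exactly one product.  A zero-length gap degenerates to the
    nick pattern."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    lo, hi = marker_map.homology_span
    g0, g1 = float(gap_interval[0]), float(gap_interval[1])
    if not (lo <= g0 <= g1 <= hi):
        raise ValueError("gap outside homology")
    events = []
    for k in range(n):
        t = TruthRecord(break_pos=(g0 + g1) / 2)
        ext = params.invasion_extent_dist.sample(rng)
        trunc = _background(marker_map, Product.P_TRUNC, g0)
        full = _background(marker_map, Product.P_FULL, g1)
        sym_idx = _markers_in(marker_map, g0, g1)
        trunc.set_het(sym_idx, "R")
        full.set_het(sym_idx, "R")
        t.symmetric_interval = (g0, g1)
        if rng.random() < 0.5:
            t.nick_host = "P_TRUNC"  # extension into trunc's upstream arm
            het = (_clamp(g0 - ext, lo, hi), g0)
            trunc.set_het(_markers_in(marker_map, *het), "D")
        else:
            t.nick_host = "P_FULL"  # extension into full's downstream arm
            het = (g1, _clamp(g1 + ext, lo, hi))
            full.set_het(_markers_in(marker_map, *het), "D")
        t.het_interval_up = het
        has_sym = bool(sym_idx)
        has_asym = bool(_markers_in(marker_map, *het))
        if has_sym and has_asym:
            t.class_truth = EventClass.GAP_LIKE
        elif has_asym:
            t.class_truth = EventClass.NICK_LIKE
        else:
            t.class_truth = EventClass.UNINTERPRETABLE
        events.append(SimulatedEvent(f"gap_{k:05d}", Mechanism.GAP, t, trunc, full))
    return events


def simulate_dloop_cleavage(
    params: MechanismParams,
    marker_map: MarkerMap,
    break_site: BreakSite | float,
    n: int,
    rng: np.random.Generator | None = None,
) -> list[SimulatedEvent]:
    """D-loop nicking before extension of the invading end.

    The invasion-bearing product keeps its hetDNA tract; the reciprocal
    product forms by an SDSA-like annealing whose extended end is chosen at
    random: extending the cleaved recipient end leaves hetDNA on one side
    only, while extending the donor end yields a pattern indistinguishable
    from canonical two-sided repair.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    b = break_site.cut_center if isinstance(break_site, BreakSite) else float(break_site)
    lo, hi = marker_map.homology_span
    events = []
    for k in range(n):
        t = TruthRecord(break_pos=b)
        t.invasion_side = "UPSTREAM" if rng.random() < 0.5 else "DOWNSTREAM"
        r1 = params.invasion_extent_dist.sample(rng)
        r2 = params.invasion_extent_dist.sample(rng)
        trunc = _background(marker_map, Product.P_TRUNC, b)
        full = _background(marker_map, Product.P_FULL, b)
        if t.invasion_side == "UPSTREAM":
            het1 = (_clamp(b - r1, lo, hi), b)
            trunc.set_het(_markers_in(marker_map, *het1), "D")
            second_host, het2 = full, (b, _clamp(b + r2, lo, hi))
        else:
            het1 = (b, _clamp(b + r1, lo, hi))
            full.set_het(_markers_in(marker_map, *het1), "D")
            second_host, het2 = trunc, (_clamp(b - r2, lo, hi), b)
        t.het_interval_up = het1
        t.extended_end = "RECIPIENT" if rng.random() < 0.5 else "DONOR"
        if t.extended_end == "DONOR":
            second_host.set_het(
                _markers_in(marker_map, *het2),
                _minority(second_host, marker_map, het2),
            )
            t.het_interval_dn = het2
        one = _markers_in(marker_map, *het1)
        two = _markers_in(marker_map, *het2) if t.extended_end == "DONOR" else []
        if one and two:
            t.class_truth = EventClass.TWO_SIDED
        elif one or two:
            side_up = (het1 if one else het2)[1] <= b
            t.class_truth = (
                EventClass.ONE_SIDED_LEFT if side_up else EventClass.ONE_SIDED_RIGHT
            )
        else:
            t.class_truth = EventClass.UNINTERPRETABLE
        events.append(
            SimulatedEvent(f"dloop_{k:05d}", Mechanism.DLOOP_CLEAVAGE, t, trunc, full)
        )
    return events


# ---------------------------------------------------------------------------
# colony segregation and reads


@dataclass
class ColonyObservation:
    event_id: str
    species_trunc: list[tuple[str, ...]]  # strand allele vectors
    species_full: list[tuple[str, ...]]

    def product_calls(self) -> tuple[ProductCall, ProductCall]:
        out = []
        for product, species in (
            (Product.P_TRUNC, self.species_trunc),
            (Product.P_FULL, self.species_full),
        ):
            if len(species) == 1:
                genotype = tuple(species[0])
            else:
                genotype = tuple(
                    a if a == b else "H" for a, b in zip(species[0], species[1])
                )
            out.append(ProductCall(product, genotype, len(species)))
        return out[0], out[1]


def observe_colony(
    event: SimulatedEvent,
    params: MechanismParams,
    rng: np.random.Generator | None = None,
) -> ColonyObservation:
    """Replicate each product duplex into its two strand-faithful lineages;
    with probability ``p_daughter_loss`` only one lineage seeds the colony,
    rendering any hetDNA invisible."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    out = []
    for dup in (event.trunc, event.full):
        lineages = [tuple(dup.top), tuple(dup.bottom)]
        if rng.random() < params.p_daughter_loss:
            lineages = [lineages[rng.integers(2)]]
        elif lineages[0] == lineages[1]:
            lineages = [lineages[0]]
        out.append(lineages)
    return ColonyObservation(event.event_id, out[0], out[1])


def realize_sequence(
    species: tuple[str, ...], pair: AllelePair, marker_map: MarkerMap
) -> str:
    """Nucleotide sequence of one species: recipient backbone with donor
    bases at D markers; the donor's 6-bp insertion is included when the
    marker nearest the insertion point is donor-derived."""
    seq = list(pair.recipient_seq)
    for m, allele in zip(marker_map.markers, species):
        if allele == "D":
            seq[m.pos_recipient] = m.donor_base
    if marker_map.insertion_marker is not None:
        ins_pos, ins_seq = marker_map.insertion_marker
        nearest = min(
            range(len(marker_map)),
            key=lambda i: abs(marker_map.positions[i] - ins_pos),
        )
        if species[nearest] == "D":
            seq.insert(ins_pos, ins_seq)
    return "".join(seq)


def emit_reads(
    obs: ColonyObservation,
    pair: AllelePair,
    marker_map: MarkerMap,
    barcode: str,
    depth: int = 20,
    error_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[ReadRecord]:
    """FASTQ-style reads for one colony: per species, ``depth`` reads of
    barcode + universal primer + product sequence + reverse-complemented
    primer/barcode, with uniform substitution errors."""
    rng = rng if rng is not None else np.random.default_rng(0)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    bases = np.array(list("ACGT"))
    reads = []
    for product, species_list, uf, ur in (
        ("P_TRUNC", obs.species_trunc, UNIVERSAL_FWD_TRUNC, UNIVERSAL_REV_TRUNC),
        ("P_FULL", obs.species_full, UNIVERSAL_FWD_FULL, UNIVERSAL_REV_FULL),
    ):
        for si, species in enumerate(species_list):
            insert = realize_sequence(species, pair, marker_map)
            amplicon = barcode + uf + insert + _rc(ur) + _rc(barcode)
            for ri in range(depth):
                seq = np.array(list(amplicon))
                if error_rate > 0:
                    mask = rng.random(len(seq)) < error_rate
                    if mask.any():
                        seq[mask] = bases[rng.integers(0, 4, mask.sum())]
                read = "".join(seq)
                if rng.random() < 0.5:
                    read = _rc(read)
                reads.append(
                    ReadRecord(
                        read_id=f"{obs.event_id}|{product}|sp{si}|{ri}",
                        sequence=read,
                        quality="I" * len(read),
                    )
                )
    return reads


def generate_barcodes(
    n: int, rng: np.random.Generator, length: int = 16, min_dist: int = 5
) -> list[str]:
    """Random barcodes with pairwise Hamming distance >= ``min_dist``."""
    bases = np.array(list("ACGT"))
    out: list[str] = []
    guard = 0
    while len(out) < n:
        cand = "".join(rng.choice(bases, size=length))
        if all(
            sum(a != b for a, b in zip(cand, prev)) >= min_dist for prev in out
        ):
            out.append(cand)
        guard += 1
        if guard > 100_000:
            raise RuntimeError("cannot satisfy barcode separation")
    return out


def make_barcode_table(event_ids: list[str], rng: np.random.Generator) -> pd.DataFrame:
    """Sample sheet for a simulated cohort: one barcode per recombinant,
    product identity carried by the universal primer pair."""
    barcodes = generate_barcodes(len(event_ids), rng)
    rows = []
    for ev, bc in zip(event_ids, barcodes):
        rows.append((ev, bc, "P_TRUNC", UNIVERSAL_FWD_TRUNC, UNIVERSAL_REV_TRUNC))
        rows.append((ev, bc, "P_FULL", UNIVERSAL_FWD_FULL, UNIVERSAL_REV_FULL))
    return pd.DataFrame(
        rows, columns=["id", "barcode", "product", "universal_fwd", "universal_rev"]
    )


# ---------------------------------------------------------------------------
# fluctuation assay


def simulate_fluctuation(
    rate: float,
    n_cells: float,
    n_cultures: int,
    seed: int | np.random.Generator = 0,
) -> list[int]:
    """Luria-Delbrück mutant counts under the branching approximation:
    mutations per culture ~ Poisson(rate * N); each mutation's clone size is
    N/j with j uniform over the N cell divisions, giving the characteristic
    heavy (jackpot) tail."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = rate * n_cells
    if m > 1e4:
        raise ValueError("rate * n_cells too large for tractable simulation")
    counts = []
    for _ in range(n_cultures):
        k = rng.poisson(m)
        total = 0
        if k:
            u = rng.random(k)
            total = int(np.minimum(np.floor(1.0 / u), n_cells).sum())
        counts.append(total)
    return counts


def truth_table(events: list[SimulatedEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        t = ev.truth
        rows.append(
            {
                "event_id": ev.event_id,
                "mechanism": ev.mechanism.value,
                "class_truth": t.class_truth.value,
                "break_pos": t.break_pos,
                "broken_allele": t.broken_allele,
                "orientation": t.orientation.value,
                "resection_up": t.resection_up,
                "resection_dn": t.resection_dn,
                "het_up_start": t.het_interval_up[0] if t.het_interval_up else None,
                "het_up_stop": t.het_interval_up[1] if t.het_interval_up else None,
                "het_dn_start": t.het_interval_dn[0] if t.het_interval_dn else None,
                "het_dn_stop": t.het_interval_dn[1] if t.het_interval_dn else None,
                "end_loss_up": t.end_loss_up,
                "end_loss_dn": t.end_loss_dn,
                "single_snp_loss_up": t.single_snp_loss_up,
                "single_snp_loss_dn": t.single_snp_loss_dn,
                "back_migration": t.back_migration,
                "hj_migration_bp": t.hj_migration_bp,
                "displaced_to": t.displaced_to,
                "extended_end": t.extended_end,
                "nick_host": t.nick_host,
            }
        )
    return pd.DataFrame(rows)
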