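import numpy as np
import pytest

from hetdna.calling import Product, ProductCall
from hetdna.substrate import (
    BreakSite,
    Marker,
    MarkerMap,
    Side,
    derive_marker_map,
    locate_break,
)
from hetdna.synthetic_references import build_substrate_pair, small_substrate_pair


@pytest.fixture(scope="session")
def small_substrate():
    """Scaled-down substrate pair (16 markers, ~0.9 kb) with break and map."""
    recipient, donor, pair = small_substrate_pair()
    break_site = locate_break(pair)
    marker_map = derive_marker_map(pair, break_site)
    return recipient, donor, pair, break_site, marker_map


@pytest.fixture(scope="session")
def full_substrate():
    """Full-design substrate pair (82 markers, ~4.1 kb)."""
    recipient, donor, pair = build_substrate_pair()
    break_site = locate_break(pair)
    marker_map = derive_marker_map(pair, break_site)
    return recipient, donor, pair, break_site, marker_map


def make_toy_map(positions, break_pos, span=None):
    """Marker map at explicit positions with a point break, for hand cases."""
    span = span or (0, max(positions) + 50)
    markers = tuple(
        Marker(
            index=i + 1,
            pos_recipient=p,
            pos_donor=p,
            recipient_base="A",
            donor_base="G",
            side=Side.UPSTREAM if p < break_pos else Side.DOWNSTREAM,
            dist_to_break=int(abs(p - break_pos)),
        )
        for i, p in enumerate(positions)
    )
    up = [p for p in positions if p < break_pos]
    dn = [p for p in positions if p >= break_pos]
    return MarkerMap(
        markers=markers,
        break_interval=(up[-1] + 1 if up else int(break_pos),
                        dn[0] if dn else int(break_pos)),
        insertion_marker=None,
        homology_span=span,
    )


def make_toy_break(pos):
    return BreakSite(
        cut_center=float(pos),
        three_prime_end_left=int(pos),
        three_prime_end_right=int(pos),
        recognition_site_span=(int(pos), int(pos)),
    )


def pc(product, genotype):
    return ProductCall(product, tuple(genotype), 2)


@pytest.fixture
def toy8():
    """Eight markers at 50..400, break at 225 (between m4 and m5)."""
    positions = [50 * i for i in range(1, 9)]
    return make_toy_map(positions, 225.0, span=(0, 450)), make_toy_break(225.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20180326)


TRUNC = Product.P_TRUNC
FULL = Product.P_FULL
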