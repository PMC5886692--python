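"""Synthetic reconstruction of the crossover-assay substrate pair.

The real recipient (*lys2delta5'*) and donor (*lys2delta3'*) alleles are not
bundled with this package; this module builds a synthetic stand-in pair that
matches the published design parameters:

* ~4.1 kb of shared homology;
* 82 engineered SNPs at ~50-bp intervals;
* a single cleavable 18-bp I-SceI site near the centre of the recipient;
* the two break-flanking SNPs each 8 bp from a 3' end of the staggered cut;
* the donor site inactivated by a 6-bp insertion (CCATAA) placed immediately
  after the 4-nt overhang region.

A scaled-down variant (fewer markers, shorter homology) is provided for
read-level tests where alignment volume matters.
"""

from __future__ import annotations

import numpy as np

from .substrate import (
    ISCEI_MOTIF,
    _NICK_BOTTOM_OFFSET,
    _NICK_TOP_OFFSET,
    AllelePair,
    make_allele_pair,
)

DONOR_INSERTION = "CCATAA"

_BASES = np.array(list("ACGT"))
_SUB = {"A": "G", "C": "T", "G": "A", "T": "C"}  # transition-style swap


def _random_dna(rng: np.random.Generator, n: int, forbid: str) -> str:
    """Random sequence free of the forbidden motif (either strand)."""
    comp = str.maketrans("ACGT", "TGCA")
    rc = forbid.translate(comp)[::-1]
    while True:
        seq = "".join(rng.choice(_BASES, size=n))
        if forbid not in seq and rc not in seq:
            return seq


def marker_positions(
    n_markers: int, spacing: int, motif_start: int
) -> list[int]:
    """SNP positions: one flanking SNP 8 bp from each 3' end of the cut,
    the rest at fixed intervals outward."""
    left_flank = motif_start + _NICK_BOTTOM_OFFSET - 8
    right_flank = motif_start + _NICK_TOP_OFFSET + 8
    half = n_markers // 2
    up = [left_flank - spacing * k for k in range(half - 1, 0, -1)] + [left_flank]
    dn = [right_flank] + [right_flank + spacing * k for k in range(1, n_markers - half)]
    return up + dn


def build_substrate_pair(
    n_markers: int = 82,
    spacing: int = 50,
    flank: int = 60,
    seed: int = 20180326,
) -> tuple[str, str, AllelePair]:
    """Synthetic recipient/donor pair following the published design.

    Returns ``(recipient_seq, donor_seq, AllelePair)``.  Defaults yield a
    ~4.1 kb homology with 82 SNPs; pass smaller values for a toy pair.
    """
    rng = np.random.default_rng(seed)
    half = n_markers // 2
    motif_start = flank + (half - 1) * spacing + 8 - _NICK_BOTTOM_OFFSET
    positions = marker_positions(n_markers, spacing, motif_start)
    length = positions[-1] + flank + 1
    while True:
        recipient = list(_random_dna(rng, length, ISCEI_MOTIF))
        recipient[motif_start : motif_start + len(ISCEI_MOTIF)] = ISCEI_MOTIF
        recipient = "".join(recipient)
        # motif insertion could create a second copy at the seams; re-draw if so
        if recipient.count(ISCEI_MOTIF) == 1:
            break
    donor = list(recipient)
    for p in positions:
        donor[p] = _SUB[donor[p]]
    insert_at = motif_start + _NICK_TOP_OFFSET  # right after the overhang region
    donor = "".join(donor[:insert_at]) + DONOR_INSERTION + "".join(donor[insert_at:])
    pair = make_allele_pair(recipient, donor)
    return recipient, donor, pair


def small_substrate_pair(seed: int = 20180326) -> tuple[str, str, AllelePair]:
    """Scaled-down pair (16 markers, ~0.9 kb) for read-level tests."""
    return build_substrate_pair(n_markers=16, spacing=50, flank=60, seed=seed)
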