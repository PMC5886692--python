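"""Recombination substrate model: allele pair, SNP marker map, break site.

The assay recombines two truncated alleles of a gene that share a ~4 kb
homology region: a *recipient* allele carrying a cleavable I-SceI site and a
*donor* allele in which the site is inactivated by a 6-bp insertion.  The
donor additionally carries dense engineered silent SNPs (~1 per 50 bp) that
serve as genotyping markers.  All downstream coordinates (markers, breaks,
tracts, lengths) live in the recipient homology frame, 0-based half-open.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import edlib
import pandas as pd
from Bio import SeqIO

# 18-bp I-SceI recognition sequence.  Cleavage leaves 4-nt 3' overhangs
# (ATAA): top-strand nick after offset 9, bottom-strand nick after offset 5.
ISCEI_MOTIF = "TAGGGATAACAGGGTAAT"
_NICK_TOP_OFFSET = 9
_NICK_BOTTOM_OFFSET = 5

_DNA_RE = re.compile(r"^[ACGT]+$")


class Side(str, Enum):
    UPSTREAM = "UPSTREAM"
    DOWNSTREAM = "DOWNSTREAM"


class SubstrateError(ValueError):
    """Raised when substrate sequences violate the assay's assumptions."""


@dataclass(frozen=True)
class AllelePair:
    """The two homologous substrate sequences plus their alignment.

    ``alignment_columns`` maps each recipient position to the aligned donor
    position; positions covered by a donor-only insertion are bridged so the
    mapping is monotone non-decreasing.
    """

    recipient_seq: str
    donor_seq: str
    homology_span_recipient: tuple[int, int]
    homology_span_donor: tuple[int, int]
    # per recipient position: aligned donor position (monotone)
    offset_table: tuple[int, ...] = field(repr=False)
    # substitution columns: (pos_recipient, recipient_base, donor_base)
    substitutions: tuple[tuple[int, str, str], ...] = field(repr=False)
    # donor-only insertions: (pos_recipient_after_which, inserted_seq)
    insertions: tuple[tuple[int, str], ...] = field(repr=False)
    identity: float = 1.0

    def map_donor_coordinate(self, pos_recipient: int) -> int:
        """Aligned donor position for a recipient position (monotone)."""
        lo, hi = self.homology_span_recipient
        if not lo <= pos_recipient < hi:
            raise SubstrateError(
                f"position {pos_recipient} outside recipient homology [{lo},{hi})"
            )
        return self.offset_table[pos_recipient - lo]


@dataclass(frozen=True)
class BreakSite:
    """An I-SceI double-strand break in the recipient frame.

    The two nick positions bound the 4-nt 3'-overhang region; ``cut_center``
    is its midpoint.  ``three_prime_end_left < three_prime_end_right``.
    """

    cut_center: float
    three_prime_end_left: int
    three_prime_end_right: int
    recognition_site_span: tuple[int, int]

    def to_json(self) -> str:
        return json.dumps(
            {
                "cut_center": self.cut_center,
                "three_prime_end_left": self.three_prime_end_left,
                "three_prime_end_right": self.three_prime_end_right,
                "recognition_site_span": list(self.recognition_site_span),
            }
        )


@dataclass(frozen=True)
class Marker:
    index: int  # ordinal 1..M, left to right
    pos_recipient: int
    pos_donor: int
    recipient_base: str
    donor_base: str
    side: Side
    dist_to_break: int


@dataclass(frozen=True)
class MarkerMap:
    markers: tuple[Marker, ...]
    break_interval: tuple[int, int]  # between the two break-flanking markers
    insertion_marker: tuple[int, str] | None  # donor-only 6-bp insertion
    homology_span: tuple[int, int]

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def positions(self) -> list[int]:
        return [m.pos_recipient for m in self.markers]

    def side_markers(self, side: Side) -> list[Marker]:
        return [m for m in self.markers if m.side is side]

    def flanking(self, break_site: BreakSite) -> tuple[Marker, Marker]:
        """The nearest marker on each side of the cut center."""
        up = [m for m in self.markers if m.pos_recipient < break_site.cut_center]
        dn = [m for m in self.markers if m.pos_recipient > break_site.cut_center]
        if not up or not dn:
            raise SubstrateError("break is not flanked by markers on both sides")
        return up[-1], dn[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [m.index for m in self.markers],
                "pos_recipient": [m.pos_recipient for m in self.markers],
                "pos_donor": [m.pos_donor for m in self.markers],
                "recipient_base": [m.recipient_base for m in self.markers],
                "donor_base": [m.donor_base for m in self.markers],
                "side": [m.side.value for m in self.markers],
                "dist_to_break": [m.dist_to_break for m in self.markers],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _read_single_fasta(path: str | Path) -> str:
    path = Path(path)
    if not path.exists():
        raise SubstrateError(f"missing file: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise SubstrateError(f"{path}: expected exactly 1 record, found {len(records)}")
    return str(records[0].seq).upper()


def _merge_insertion_fragments(
    recipient: str, donor: str, fragments: list[tuple[int, int, int]]
) -> tuple[tuple[int, str], ...]:
    """Collapse donor-only gap fragments into logical insertions.

    Optimal alignments may split one biological insertion into adjacent gap
    fragments separated by a matched base or two.  Fragments whose recipient
    positions lie within 3 bp are re-expressed, when possible, as a single
    equivalent insertion at one point.
    """
    if not fragments:
        return ()
    clusters: list[list[tuple[int, int, int]]] = [[fragments[0]]]
    for frag in fragments[1:]:
        if frag[0] - clusters[-1][-1][0] <= 3:
            clusters[-1].append(frag)
        else:
            clusters.append([frag])
    out: list[tuple[int, str]] = []
    for cluster in clusters:
        if len(cluster) == 1:
            rpos, dpos, n = cluster[0]
            out.append((rpos, donor[dpos : dpos + n]))
            continue
        p1, d1, _ = cluster[0]
        pk, dk, nk = cluster[-1]
        seg = donor[d1 : dk + nk]
        extra = len(seg) - (pk - p1)
        merged = None
        for q in range(p1, pk + 1):
            cand = recipient[p1:q] + seg[q - p1 : q - p1 + extra] + recipient[q:pk]
            if cand == seg:
                merged = (q, seg[q - p1 : q - p1 + extra])
                break
        if merged is None:  # not shift-equivalent: keep fragments as-is
            for rpos, dpos, n in cluster:
                out.append((rpos, donor[dpos : dpos + n]))
        else:
            out.append(merged)
    return tuple(out)


def _align_pair(recipient: str, donor: str) -> AllelePair:
    """Global alignment of the two substrates; derives the column structure."""
    res = edlib.align(recipient, donor, task="path", mode="NW")
    cigar = res["cigar"]
    alen = 0
    rpos = dpos = 0
    offset_table: list[int] = []
    substitutions: list[tuple[int, str, str]] = []
    fragments: list[tuple[int, int, int]] = []  # (rpos, dpos, length)
    for n, op in re.findall(r"(\d+)([=XID])", cigar):
        n = int(n)
        alen += n
        if op == "=":
            offset_table.extend(range(dpos, dpos + n))
            rpos += n
            dpos += n
        elif op == "X":
            for k in range(n):
                substitutions.append(
                    (rpos + k, recipient[rpos + k], donor[dpos + k])
                )
            offset_table.extend(range(dpos, dpos + n))
            rpos += n
            dpos += n
        elif op == "D":  # extra bases in donor (donor-only insertion)
            fragments.append((rpos, dpos, n))
            dpos += n
        else:  # 'I': extra bases in recipient (donor-side deletion); bridge
            offset_table.extend([dpos] * n)
            rpos += n
    insertions = _merge_insertion_fragments(recipient, donor, fragments)
    identity = 1.0 - res["editDistance"] / alen
    return AllelePair(
        recipient_seq=recipient,
        donor_seq=donor,
        homology_span_recipient=(0, len(recipient)),
        homology_span_donor=(0, len(donor)),
        offset_table=tuple(offset_table),
        substitutions=tuple(substitutions),
        insertions=tuple(insertions),
        identity=identity,
    )


def load_allele_pair(
    recipient_fasta: str | Path,
    donor_fasta: str | Path,
    min_identity: float = 0.90,
) -> AllelePair:
    """Load and validate the recipient/donor substrate pair from FASTA."""
    recipient = _read_single_fasta(recipient_fasta)
    donor = _read_single_fasta(donor_fasta)
    return make_allele_pair(recipient, donor, min_identity=min_identity)


def make_allele_pair(
    recipient: str, donor: str, min_identity: float = 0.90
) -> AllelePair:
    """Build a validated AllelePair from in-memory sequences."""
    for name, seq in (("recipient", recipient), ("donor", donor)):
        if not _DNA_RE.match(seq):
            raise SubstrateError(f"{name} sequence contains non-ACGT characters")
    pair = _align_pair(recipient, donor)
    if pair.identity < min_identity:
        raise SubstrateError(
            f"alignment identity {pair.identity:.3f} below {min_identity:.2f}; "
            "wrong substrate inputs?"
        )
    return pair


def locate_break(pair: AllelePair, recognition_motif: str = ISCEI_MOTIF) -> BreakSite:
    """Locate the unique cleavable recognition site in the recipient.

    The two staggered nicks produce a 4-nt 3'-overhang region
    ``[three_prime_end_left, three_prime_end_right)``.
    """
    motif = recognition_motif.upper()
    n = pair.recipient_seq.count(motif)
    if n == 0:
        raise SubstrateError("recognition motif absent from recipient")
    if n > 1:
        raise SubstrateError(f"recognition motif occurs {n} times in recipient")
    if motif in pair.donor_seq:
        raise SubstrateError("donor site is cleavable; it must be inactivated")
    start = pair.recipient_seq.index(motif)
    left = start + _NICK_BOTTOM_OFFSET
    right = start + _NICK_TOP_OFFSET
    return BreakSite(
        cut_center=(left + right) / 2.0,
        three_prime_end_left=left,
        three_prime_end_right=right,
        recognition_site_span=(start, start + len(motif)),
    )


def derive_marker_map(pair: AllelePair, break_site: BreakSite) -> MarkerMap:
    """Turn aligned substitutions into break-anchored genotyping markers.

    The donor's 6-bp insertion is recorded separately and never becomes a
    marker.  ``dist_to_break`` is the distance to the nearer of the two
    3' ends of the cut.
    """
    lo, hi = pair.homology_span_recipient
    if not lo <= break_site.cut_center < hi:
        raise SubstrateError("break site outside homology span")
    if not pair.substitutions:
        raise SubstrateError("no markers: substrate pair has zero substitutions")
    if len(pair.insertions) > 1:
        raise SubstrateError(
            f"expected at most one donor insertion, found {len(pair.insertions)}"
        )
    markers = []
    for i, (pos, rbase, dbase) in enumerate(sorted(pair.substitutions), start=1):
        side = Side.UPSTREAM if pos < break_site.cut_center else Side.DOWNSTREAM
        dist = min(
            abs(pos - break_site.three_prime_end_left),
            abs(pos - break_site.three_prime_end_right),
        )
        markers.append(
            Marker(
                index=i,
                pos_recipient=pos,
                pos_donor=pair.map_donor_coordinate(pos),
                recipient_base=rbase,
                donor_base=dbase,
                side=side,
                dist_to_break=dist,
            )
        )
    up = [m for m in markers if m.side is Side.UPSTREAM]
    dn = [m for m in markers if m.side is Side.DOWNSTREAM]
    if up and dn:
        break_interval = (up[-1].pos_recipient + 1, dn[0].pos_recipient)
    else:  # break at the very edge of the marker set
        c = int(break_site.cut_center)
        break_interval = (c, c)
    insertion = pair.insertions[0] if pair.insertions else None
    return MarkerMap(
        markers=tuple(markers),
        break_interval=break_interval,
        insertion_marker=insertion,
        homology_span=pair.homology_span_recipient,
    )


def map_donor_coordinate(pair: AllelePair, pos_recipient: int) -> int:
    """Functional wrapper around :meth:`AllelePair.map_donor_coordinate`."""
    return pair.map_donor_coordinate(pos_recipient)
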