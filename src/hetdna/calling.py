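"""Barcode demultiplexing, per-read marker profiling, species clustering,
and hetDNA-aware product genotyping.

Each crossover recombinant yields two PCR products (the doubly-truncated
``P_TRUNC`` allele and the reconstituted full-length ``P_FULL`` allele),
amplified with barcoded primers and sequenced as circular consensus (CCS)
reads.  Because recombinants are recovered in a mismatch-repair-deficient
background, a product whose duplex contained heteroduplex DNA segregates two
distinct read haplotypes ("species"); a position at which the two major
species carry the two different parental SNP alleles is diagnostic of hetDNA
and is called ``H``.

CCS reads are treated as flat-quality: FASTQ quality strings are parsed but
never used.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import edlib
import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

from .substrate import AllelePair, MarkerMap

BARCODE_LEN = 16
MAX_BARCODE_MISMATCH = 2
MIN_BARCODE_SEPARATION = 5
MIN_PROFILE_IDENTITY = 0.80


class Product(str, Enum):
    P_TRUNC = "P_TRUNC"  # lys2delta5'delta3' (doubly truncated) product
    P_FULL = "P_FULL"  # reconstituted full-length LYS2 product
    UNKNOWN = "UNKNOWN"


class Call(str, Enum):
    R = "R"  # recipient allele
    D = "D"  # donor allele
    H = "H"  # heteroduplex (both alleles present across major species)
    N = "N"  # no call


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    quality: str | None = None
    product_hint: Product = Product.UNKNOWN


@dataclass(frozen=True)
class MarkerProfile:
    calls: tuple[str, ...]  # over markers, values in {R, D, N}
    qc_fail: bool = False

    def __len__(self) -> int:
        return len(self.calls)


@dataclass
class Species:
    profile: MarkerProfile
    support: int
    fraction: float = 0.0


@dataclass
class ProductCall:
    product_id: Product
    genotype: tuple[str, ...]  # over markers, values in {R, D, H, N}
    n_major_species: int
    qc_pass: bool = True


@dataclass
class QCVerdict:
    passed: bool
    major_counts: dict[str, int]
    reason: str = ""


class CallingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# barcode table and demultiplexing


@dataclass
class BarcodeTable:
    """Sample sheet: per-recombinant barcode plus product-specific universal
    primer pairs.  Columns: id, barcode, product, universal_fwd, universal_rev.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        needed = {"id", "barcode", "product", "universal_fwd", "universal_rev"}
        missing = needed - set(self.frame.columns)
        if missing:
            raise CallingError(f"barcode table missing columns: {sorted(missing)}")
        bcs = list(self.frame["barcode"])
        if len(set(bcs)) != len(set(zip(self.frame["id"], self.frame["product"]))):
            # one barcode per recombinant is fine (shared across products),
            # but two recombinants must never share a barcode
            by_id = self.frame.groupby("barcode")["id"].nunique()
            if (by_id > 1).any():
                raise CallingError("duplicate barcode assigned to different recombinants")
        uniq = sorted(set(bcs))
        for i, a in enumerate(uniq):
            for b in uniq[i + 1 :]:
                if _hamming(a, b) < MIN_BARCODE_SEPARATION:
                    raise CallingError(
                        f"barcodes {a} and {b} closer than Hamming "
                        f"{MIN_BARCODE_SEPARATION}"
                    )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "BarcodeTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(x != y for x, y in zip(a, b))


def _best_barcode(lead: str, barcodes: dict[str, str]) -> tuple[str | None, str]:
    """Unique barcode id within MAX_BARCODE_MISMATCH of the leading 16 nt."""
    hits = []
    for bc_id, bc in barcodes.items():
        d = _hamming(lead, bc)
        if d <= MAX_BARCODE_MISMATCH:
            hits.append((d, bc_id))
    if not hits:
        return None, "no barcode within distance"
    hits.sort()
    if len(hits) > 1 and hits[0][0] == hits[1][0]:
        return None, "ambiguous barcode"
    return hits[0][1], ""


def _match_primer(read: str, primer: str, offset: int, tol: int = 4) -> bool:
    window = read[offset : offset + len(primer)]
    return len(window) == len(primer) and _hamming(window, primer) <= tol


def demultiplex(
    reads: list[ReadRecord], table: BarcodeTable
) -> tuple[dict[tuple[str, Product], list[ReadRecord]], list[tuple[ReadRecord, str]]]:
    """Assign reads to (recombinant, product) bins by leading barcode and
    universal-primer flank, trying both read orientations.

    Returns (assignments, unassigned) where unassigned carries a reason per
    read; nothing is dropped silently.  Assigned reads are returned in the
    orientation that matched (barcode at the 5' end).
    """
    barcodes = {}
    primer_pairs: dict[tuple[str, str], list[tuple[str, Product]]] = {}
    for row in table.frame.itertuples():
        key = f"{row.id}"
        barcodes.setdefault(key, row.barcode)
        primer_pairs.setdefault((row.universal_fwd, row.universal_rev), []).append(
            (key, Product(row.product))
        )
    assigned: dict[tuple[str, Product], list[ReadRecord]] = {}
    unassigned: list[tuple[ReadRecord, str]] = []
    for read in reads:
        hit = None
        for seq in (read.sequence, reverse_complement(read.sequence)):
            bc_id, why = _best_barcode(seq[:BARCODE_LEN], barcodes)
            if bc_id is None:
                continue
            # identify the product by which universal forward primer follows
            # the barcode
            product = None
            for (uf, _ur), members in primer_pairs.items():
                if _match_primer(seq, uf, BARCODE_LEN):
                    for m_id, m_product in members:
                        if m_id == bc_id:
                            product = m_product
                    break
            if product is None:
                continue
            hit = (bc_id, product, seq)
            break
        if hit is None:
            unassigned.append((read, "no unambiguous barcode/primer match"))
            continue
        bc_id, product, oriented = hit
        rec = ReadRecord(read.read_id, oriented, read.quality, product)
        assigned.setdefault((bc_id, product), []).append(rec)
    return assigned, unassigned


# ---------------------------------------------------------------------------
# per-read marker profiling


def _column_bases(ref: str, read: str, positions: list[int]) -> list[str] | None:
    """Base observed in the read at each reference position, via an
    infix alignment of the reference into the read.  None if identity is
    below MIN_PROFILE_IDENTITY."""
    res = edlib.align(ref, read, task="path", mode="HW")
    alen = sum(int(n) for n, _ in re.findall(r"(\d+)([=XID])", res["cigar"]))
    if 1.0 - res["editDistance"] / alen < MIN_PROFILE_IDENTITY:
        return None
    tpos = res["locations"][0][0]
    qpos = 0
    want = iter(sorted(positions))
    nxt = next(want, None)
    out: dict[int, str] = {}
    for n, op in re.findall(r"(\d+)([=XID])", res["cigar"]):
        n = int(n)
        if op in "=X":
            while nxt is not None and qpos <= nxt < qpos + n:
                out[nxt] = read[tpos + (nxt - qpos)]
                nxt = next(want, None)
            qpos += n
            tpos += n
        elif op == "I":  # extra bases in reference: deletion in the read
            while nxt is not None and qpos <= nxt < qpos + n:
                out[nxt] = "-"
                nxt = next(want, None)
            qpos += n
        else:  # 'D': extra bases in the read
            tpos += n
    return [out.get(p, "-") for p in sorted(positions)]


def call_read_profile(
    read: ReadRecord, pair: AllelePair, marker_map: MarkerMap
) -> MarkerProfile:
    """Call R/D/N at every marker of one read.

    The read is aligned to both parental references; the higher-identity
    alignment frames the marker columns.  A marker is R if the read carries
    the recipient base, D for the donor base, N otherwise (including a
    deletion at the column).
    """
    positions_r = [m.pos_recipient for m in marker_map.markers]
    positions_d = [m.pos_donor for m in marker_map.markers]
    res_r = edlib.align(pair.recipient_seq, read.sequence, mode="HW")
    res_d = edlib.align(pair.donor_seq, read.sequence, mode="HW")
    if res_r["editDistance"] <= res_d["editDistance"]:
        bases = _column_bases(pair.recipient_seq, read.sequence, positions_r)
        order = sorted(range(len(positions_r)), key=lambda i: positions_r[i])
    else:
        bases = _column_bases(pair.donor_seq, read.sequence, positions_d)
        order = sorted(range(len(positions_d)), key=lambda i: positions_d[i])
    if bases is None:
        return MarkerProfile(calls=("N",) * len(marker_map), qc_fail=True)
    calls = ["N"] * len(marker_map)
    for rank, midx in enumerate(order):
        m = marker_map.markers[midx]
        base = bases[rank]
        if base == m.recipient_base:
            calls[midx] = "R"
        elif base == m.donor_base:
            calls[midx] = "D"
    return MarkerProfile(calls=tuple(calls))


# ---------------------------------------------------------------------------
# species clustering and product genotype


def _compatible(consensus: list[str], calls: tuple[str, ...]) -> bool:
    return all(c == "N" or k == "N" or c == k for c, k in zip(consensus, calls))


def cluster_species(
    profiles: list[MarkerProfile], min_reads: int = 3
) -> list[Species]:
    """Group read profiles into haplotype species.

    Profiles are grouped by exact equality on non-N calls; an N matches
    anything and a profile joins the compatible group with the largest
    support (ties broken toward the earlier-created group).  Species are
    returned sorted by support, descending.
    """
    if not profiles:
        raise CallingError("no profiles to cluster")
    if len(profiles) < min_reads:
        raise CallingError(
            f"need at least {min_reads} reads per product, got {len(profiles)}"
        )
    clusters: list[tuple[list[str], int]] = []  # (consensus, support)
    for prof in profiles:
        best = None
        for ci, (consensus, support) in enumerate(clusters):
            if _compatible(consensus, prof.calls):
                if best is None or support > clusters[best][1]:
                    best = ci
        if best is None:
            clusters.append((list(prof.calls), 1))
        else:
            consensus, support = clusters[best]
            for i, c in enumerate(prof.calls):
                if consensus[i] == "N":
                    consensus[i] = c
            clusters[best] = (consensus, support + 1)
    total = sum(s for _, s in clusters)
    species = [
        Species(MarkerProfile(tuple(cons)), support, support / total)
        for cons, support in clusters
    ]
    species.sort(key=lambda s: -s.support)
    return species


def qc_event(
    species_trunc: list[Species],
    species_full: list[Species],
    major_fraction: float = 0.10,
) -> QCVerdict:
    """A recombinant passes QC when neither product has more than two major
    species (major: support >= 2 and fraction >= ``major_fraction``).  More
    than two major species signals a spurious/mixed colony."""
    counts = {}
    for name, species in (("P_TRUNC", species_trunc), ("P_FULL", species_full)):
        counts[name] = sum(
            1 for s in species if s.support >= 2 and s.fraction >= major_fraction
        )
    if any(c > 2 for c in counts.values()):
        return QCVerdict(False, counts, "more than two major species")
    return QCVerdict(True, counts)


def major_species(
    species: list[Species], major_fraction: float = 0.10
) -> list[Species]:
    return [s for s in species if s.support >= 2 and s.fraction >= major_fraction]


def product_genotype(
    species: list[Species],
    product_id: Product = Product.UNKNOWN,
    major_fraction: float = 0.10,
) -> ProductCall:
    """Merge the (one or two) major species into a per-marker genotype.

    With two major species, an R-vs-D disagreement at a marker is diagnostic
    of heteroduplex DNA there (call H); a disagreement against N takes the
    non-N call; minor species are ignored.
    """
    majors = major_species(species, major_fraction)
    if not majors:
        raise CallingError("no major species for product")
    if len(majors) == 1:
        genotype = majors[0].profile.calls
    else:
        a, b = majors[0].profile.calls, majors[1].profile.calls
        merged = []
        for x, y in zip(a, b):
            if x == y:
                merged.append(x)
            elif x == "N":
                merged.append(y)
            elif y == "N":
                merged.append(x)
            else:
                merged.append("H")
        genotype = tuple(merged)
    return ProductCall(
        product_id=product_id,
        genotype=genotype,
        n_major_species=len(majors),
    )


# ---------------------------------------------------------------------------
# I/O helpers


def read_fastx(path: str | Path) -> list[ReadRecord]:
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    out = []
    for rec in SeqIO.parse(str(path), fmt):
        qual = None
        if fmt == "fastq":
            quals = rec.letter_annotations.get("phred_quality")
            qual = "".join(chr(q + 33) for q in quals) if quals else None
        out.append(ReadRecord(rec.id, str(rec.seq).upper(), qual))
    return out


def write_unassigned(
    unassigned: list[tuple[ReadRecord, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for read, reason in unassigned:
            fh.write(f"@{read.read_id} {reason}\n{read.sequence}\n+\n")
            fh.write((read.quality or "I" * len(read.sequence)) + "\n")
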