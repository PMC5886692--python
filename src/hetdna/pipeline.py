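"""Run orchestration: simulate / call / classify / stats stages with a
validated config, a run manifest, and deterministic outputs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, classify, simulate, stats, synthetic_references, tracts
from .calling import BarcodeTable, Product, ProductCall
from .substrate import derive_marker_map, load_allele_pair, locate_break

log = logging.getLogger("hetdna")

_KNOWN_KEYS = {
    "recipient_fasta",
    "donor_fasta",
    "reads",
    "barcode_table",
    "out_dir",
    "seed",
    "n_events",
    "mechanism",
    "depth",
    "error_rate",
    "n_markers",
    "marker_spacing",
    "min_reads",
    "major_fraction",
    "mode_anchor",
    "fluctuation_tsv",
    "log_level",
}


@dataclass
class RunConfig:
    out_dir: str
    seed: int
    recipient_fasta: str | None = None
    donor_fasta: str | None = None
    reads: str | None = None
    barcode_table: str | None = None
    n_events: int = 20
    mechanism: str = "DSBR"
    depth: int = 20
    error_rate: float = 0.0
    n_markers: int = 16
    marker_spacing: int = 50
    min_reads: int = 3
    major_fraction: float = 0.10
    mode_anchor: str = "induced"  # or "spontaneous"
    fluctuation_tsv: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in raw or "seed" not in raw:
            raise ValueError("config requires out_dir and seed")
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _write_fasta(path: Path, name: str, seq: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def _stage_simulate(cfg: RunConfig, out: Path, manifest: dict) -> None:
    rng = np.random.default_rng(cfg.seed)
    recipient, donor, pair = synthetic_references.build_substrate_pair(
        n_markers=cfg.n_markers, spacing=cfg.marker_spacing, seed=cfg.seed
    )
    break_site = locate_break(pair)
    marker_map = derive_marker_map(pair, break_site)
    params = simulate.MechanismParams.clean(seed=cfg.seed)
    mech = cfg.mechanism.upper()
    if mech == "DSBR":
        events = simulate.simulate_dsbr(params, marker_map, break_site, cfg.n_events, rng)
    elif mech == "MR_NICK":
        events = simulate.simulate_mr_nick(
            params, marker_map, break_site.cut_center, cfg.n_events, rng
        )
    elif mech == "GAP":
        lo, hi = marker_map.homology_span
        g = break_site.cut_center
        events = simulate.simulate_gap(params, marker_map, (g - 60, g + 60), cfg.n_events, rng)
    elif mech == "DLOOP_CLEAVAGE":
        events = simulate.simulate_dloop_cleavage(
            params, marker_map, break_site, cfg.n_events, rng
        )
    else:
        raise ValueError(f"unknown mechanism: {cfg.mechanism}")
    table = simulate.make_barcode_table([e.event_id for e in events], rng)
    reads = []
    bc_by_id = {r.id: r.barcode for r in table.itertuples()}
    for ev in events:
        obs = simulate.observe_colony(ev, params, rng)
        reads.extend(
            simulate.emit_reads(
                obs, pair, marker_map, bc_by_id[ev.event_id],
                depth=cfg.depth, error_rate=cfg.error_rate, rng=rng,
            )
        )
    _write_fasta(out / "recipient.fasta", "recipient_synthetic", recipient)
    _write_fasta(out / "donor.fasta", "donor_synthetic", donor)
    table.to_csv(out / "barcodes.tsv", sep="\t", index=False)
    simulate.truth_table(events).to_csv(out / "truth.tsv", sep="\t", index=False)
    with open(out / "reads.fastq", "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
    manifest["n_events_simulated"] = len(events)
    manifest["n_reads_simulated"] = len(reads)
    log.info("simulated %d events, %d reads", len(events), len(reads))


def _stage_call(cfg: RunConfig, out: Path, manifest: dict) -> None:
    recipient = cfg.recipient_fasta or str(out / "recipient.fasta")
    donor = cfg.donor_fasta or str(out / "donor.fasta")
    reads_path = cfg.reads or str(out / "reads.fastq")
    table_path = cfg.barcode_table or str(out / "barcodes.tsv")
    pair = load_allele_pair(recipient, donor)
    break_site = locate_break(pair)
    marker_map = derive_marker_map(pair, break_site)
    table = BarcodeTable.read_tsv(table_path)
    reads = calling.read_fastx(reads_path)
    assigned, unassigned = calling.demultiplex(reads, table)
    genotype_rows = []
    qc_rows = []
    recombinants = sorted({rid for rid, _ in assigned})
    for rid in recombinants:
        species = {}
        for product in (Product.P_TRUNC, Product.P_FULL):
            plist = assigned.get((rid, product), [])
            profiles = [
                calling.call_read_profile(r, pair, marker_map) for r in plist
            ]
            try:
                species[product] = calling.cluster_species(
                    profiles, min_reads=cfg.min_reads
                )
            except calling.CallingError:
                species[product] = None
        if species[Product.P_TRUNC] is None or species[Product.P_FULL] is None:
            qc_rows.append((rid, False, "missing or underpowered product"))
            continue
        verdict = calling.qc_event(
            species[Product.P_TRUNC], species[Product.P_FULL],
            major_fraction=cfg.major_fraction,
        )
        qc_rows.append((rid, verdict.passed, verdict.reason))
        if not verdict.passed:
            continue
        calls = {
            p: calling.product_genotype(species[p], p, cfg.major_fraction)
            for p in (Product.P_TRUNC, Product.P_FULL)
        }
        for i in range(len(marker_map)):
            genotype_rows.append(
                (
                    rid,
                    i + 1,
                    calls[Product.P_TRUNC].genotype[i],
                    calls[Product.P_FULL].genotype[i],
                )
            )
    pd.DataFrame(
        genotype_rows, columns=["event_id", "marker", "P_TRUNC", "P_FULL"]
    ).to_csv(out / "genotypes.tsv", sep="\t", index=False)
    pd.DataFrame(qc_rows, columns=["event_id", "qc_pass", "reason"]).to_csv(
        out / "qc.tsv", sep="\t", index=False
    )
    calling.write_unassigned(unassigned, out / "unassigned.fastq")
    manifest["n_reads_in"] = len(reads)
    manifest["n_reads_unassigned"] = len(unassigned)
    manifest["n_recombinants_called"] = len(
        set(r for r, *_ in genotype_rows)
    )
    log.info(
        "called %d recombinants (%d reads unassigned)",
        manifest["n_recombinants_called"], len(unassigned),
    )


def load_genotypes(path: str | Path) -> dict[str, tuple[ProductCall, ProductCall]]:
    df = pd.read_csv(path, sep="\t", dtype={"event_id": str})
    out = {}
    for rid, grp in df.groupby("event_id", sort=True):
        grp = grp.sort_values("marker")
        out[str(rid)] = (
            ProductCall(Product.P_TRUNC, tuple(grp["P_TRUNC"]), 2),
            ProductCall(Product.P_FULL, tuple(grp["P_FULL"]), 2),
        )
    return out


def _stage_classify(cfg: RunConfig, out: Path, manifest: dict) -> None:
    recipient = cfg.recipient_fasta or str(out / "recipient.fasta")
    donor = cfg.donor_fasta or str(out / "donor.fasta")
    pair = load_allele_pair(recipient, donor)
    break_site = locate_break(pair)
    marker_map = derive_marker_map(pair, break_site)
    calls = load_genotypes(out / "genotypes.tsv")
    rows = []
    events_json = []
    for rid, (trunc, full) in calls.items():
        try:
            event = tracts.segment_event(trunc, full, marker_map)
        except tracts.TractError:
            rows.append({"event_id": rid, "klass": "UNINTERPRETABLE"})
            continue
        if cfg.mode_anchor == "spontaneous":
            call = classify.infer_initiation(event, marker_map, event_id=rid)
        else:
            call = classify.classify_induced(event, break_site, marker_map, event_id=rid)
        row = {
            "event_id": rid,
            "klass": call.klass.value,
            "gap_expansion_upstream": call.features.gap_expansion_upstream.value,
            "gap_expansion_downstream": call.features.gap_expansion_downstream.value,
            "n_restoration_patches": call.features.n_restoration_patches,
            "n_conversion_patches": call.features.n_conversion_patches,
            "n_donor_alterations": len(call.features.donor_alterations),
            "anchor": call.anchor,
        }
        if call.initiation is not None:
            row["lesion_type"] = call.initiation.lesion_type.value
            row["inferred_allele"] = call.initiation.inferred_allele.value
            row["inferred_position"] = call.initiation.inferred_position
        rows.append(row)
        events_json.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out / "classification.tsv", sep="\t", index=False)
    with open(out / "events.json", "w") as fh:
        json.dump(events_json, fh, indent=1)
    manifest["n_events_classified"] = len(rows)
    manifest["class_counts"] = df["klass"].value_counts().to_dict() if len(df) else {}
    log.info("classified %d events", len(rows))


def _stage_stats(cfg: RunConfig, out: Path, manifest: dict) -> None:
    recipient = cfg.recipient_fasta or str(out / "recipient.fasta")
    donor = cfg.donor_fasta or str(out / "donor.fasta")
    pair = load_allele_pair(recipient, donor)
    break_site = locate_break(pair)
    marker_map = derive_marker_map(pair, break_site)
    calls = load_genotypes(out / "genotypes.tsv")
    cls = pd.read_csv(out / "classification.tsv", sep="\t", dtype={"event_id": str})
    anchors = dict(zip(cls["event_id"], cls["anchor"]))
    events, anchor_list = [], []
    for rid, (trunc, full) in calls.items():
        try:
            ev = tracts.segment_event(trunc, full, marker_map)
        except tracts.TractError:
            continue
        events.append(ev)
        anchor_list.append(float(anchors.get(rid, break_site.cut_center)))
    report: dict = {"class_counts": cls["klass"].value_counts().to_dict()}
    try:
        med = stats.median_summary(events, anchor_list, marker_map)
        report["medians_bp"] = {
            "upstream": med.median_upstream,
            "downstream": med.median_downstream,
            "total": med.median_total,
            "side_sum": med.side_sum,
            "n": med.n_total,
        }
    except stats.StatsError:
        report["medians_bp"] = None
    if cfg.fluctuation_tsv:
        fl = pd.read_csv(cfg.fluctuation_tsv, sep="\t")
        est = stats.lea_coulson_rate(
            fl["mutant_count"], float(fl["viable_cells"].mean())
        )
        report["rate"] = {
            "rate": est.rate,
            "m_hat": est.m_hat,
            "ci95": list(est.ci95) if est.ci95 else None,
            "flagged": est.flagged,
        }
    with open(out / "stats.json", "w") as fh:
        json.dump(report, fh, indent=1)
    manifest["stats"] = report
    log.info("stats written")


def write_report(out: Path) -> None:
    """Class-count and median tables plus per-event profile strips (SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cls = pd.read_csv(out / "classification.tsv", sep="\t", dtype={"event_id": str})
    counts = cls["klass"].value_counts()
    counts.rename("n_events").to_csv(out / "class_counts.tsv", sep="\t")
    geno = pd.read_csv(out / "genotypes.tsv", sep="\t", dtype={"event_id": str})
    events = list(geno.groupby("event_id", sort=True))
    if events:
        colors = {"R": "#ffffff", "D": "#222222", "H": "#999999", "N": "#d62728"}
        fig, axes = plt.subplots(
            len(events), 2, figsize=(8, 0.4 * len(events) + 1), squeeze=False
        )
        for ax_row, (rid, grp) in zip(axes, events):
            grp = grp.sort_values("marker")
            for ax, col in zip(ax_row, ("P_TRUNC", "P_FULL")):
                for x, c in enumerate(grp[col]):
                    ax.add_patch(
                        plt.Rectangle((x, 0), 1, 1, color=colors.get(c, "#d62728"),
                                      ec="#888888", lw=0.2)
                    )
                ax.set_xlim(0, len(grp))
                ax.set_ylim(0, 1)
                ax.set_xticks([])
                ax.set_yticks([])
                ax.set_ylabel(str(rid), rotation=0, fontsize=5, ha="right", va="center")
        axes[0][0].set_title("P_TRUNC", fontsize=7)
        axes[0][1].set_title("P_FULL", fontsize=7)
        fig.savefig(out / "profiles.svg", format="svg")
        plt.close(fig)


STAGES = {"simulate": _stage_simulate, "call": _stage_call,
          "classify": _stage_classify, "stats": _stage_stats}
_ORDER = ["simulate", "call", "classify", "stats"]


def run_pipeline(cfg: RunConfig, mode: str = "all") -> dict:
    """Execute the requested stage(s); returns the run manifest."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if mode not in set(_ORDER) | {"all"}:
        raise ValueError(f"unknown mode: {mode}")
    if mode != "simulate" and cfg.reads is None and not (out / "reads.fastq").exists():
        if mode in {"call"}:
            raise ValueError("call mode needs reads (config or prior simulate)")
    stages = _ORDER if mode == "all" else [mode]
    manifest: dict = {
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "stages": stages,
    }
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    try:
        for stage in stages:
            STAGES[stage](cfg, out, manifest)
        if "classify" in stages:
            write_report(out)
    finally:
        log.removeHandler(fh)
        fh.close()
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True)
    return manifest
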