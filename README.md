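# hetdna

Heteroduplex-DNA (hetDNA) tract mapping for mitotic crossover products, with
a strand-resolved simulator of the recombination mechanisms that produce
them.

## The problem

When a double-strand break (DSB) is repaired by homologous recombination,
single strands from the broken (recipient) and intact (donor) molecules pair
to form heteroduplex DNA. In a mismatch-repair-deficient background this
footprint survives: after the first post-recombination replication the two
strands of a hetDNA-containing product segregate into two daughter lineages,
so a sequenced colony shows **two read species** for that product, and a
marker position carrying *both* parental SNP alleles is diagnostic of
hetDNA.

The assay this package models recombines two truncated alleles of a yeast
gene sharing ~4.1 kb of homology: a recipient allele with a cleavable
I-SceI site and a donor allele carrying 82 silent SNPs at ~50-bp intervals
plus a 6-bp insertion that inactivates its cut site. Only a crossover (CO)
reconstitutes a functional gene, and both reciprocal products are recovered
and sequenced as barcoded long-read amplicons. The position of hetDNA in
the two products relative to the break discriminates repair mechanisms:

* **two-sided asymmetric hetDNA** — one tract on each side of the break, in
  opposite products: the canonical DSB-repair (double Holliday junction)
  signature; under nick-directed junction resolution the upstream tract is
  always in the doubly-truncated product and the downstream tract in the
  full-length product,
* **one-sided hetDNA** — expected from D-loop back-migration or from
  processing of the strand-invasion intermediate before extension,
* **nick pattern** — a single asymmetric tract in donor-derived sequence
  adjacent to the crossover point (Meselson–Radding initiation),
* **gap pattern** — symmetric hetDNA (both products heteroduplex at the
  same markers) flanked by an asymmetric extension in one product,

plus complexity features: gap expansion (break-adjacent conversion of one
or several SNPs), restoration/conversion patches inside tracts, terminal vs
interstitial symmetric hetDNA, and template-switch footprints in
donor-derived sequence.

Spontaneous CO rates are estimated from fluctuation assays with the
Lea–Coulson method of the median: the expected events per culture `m`
solves `r̃/m − ln m = 1.24` for the median mutant count `r̃`, and the rate
is `m/N` per cell per generation.

## What the package provides

| module | role |
| --- | --- |
| `hetdna.substrate` | load the allele pair, align it, derive the SNP marker map and the I-SceI break site |
| `hetdna.calling` | barcode demultiplexing, per-read R/D/N profiling against both references, species clustering, QC, hetDNA-aware product genotypes |
| `hetdna.tracts` | segmentation into R/D/H runs, tract extraction with context, break-distal tract-length measurement |
| `hetdna.classify` | mechanistic event classes, complexity features, initiating-lesion inference for spontaneous events |
| `hetdna.stats` | tract-length medians, Fisher/chi-square/Mann-Whitney, Lea–Coulson rate with 95% CI |
| `hetdna.simulate` | strand-resolved mechanism simulator (DSBR, nick, gap, D-loop cleavage), colony segregation, read emission, fluctuation counts |
| `hetdna.pipeline` / CLI `hetdna` | `simulate`, `call`, `classify`, `stats`, `all` stages with deterministic, manifest-tracked runs |

The real substrate sequences are not distributed; `hetdna.synthetic_references`
reconstructs a synthetic stand-in pair from the published design parameters
(4.1 kb homology, 82 SNPs at ~50 bp, flanking SNPs 8 bp from the 3' ends of
the staggered cut, 6-bp CCATAA donor insertion).

## Worked example

```python
import numpy as np
from hetdna import (MechanismParams, classify_induced, derive_marker_map,
                    locate_break, segment_event, simulate_dsbr)
from hetdna.synthetic_references import build_substrate_pair

recipient, donor, pair = build_substrate_pair()   # synthetic full design
break_site = locate_break(pair)
marker_map = derive_marker_map(pair, break_site)
print(len(marker_map), marker_map.flanking(break_site)[0].dist_to_break)
# 82 8    <- 82 markers; flanking SNP 8 bp from a 3' end of the cut

rng = np.random.default_rng(1)
events = simulate_dsbr(MechanismParams.clean(), marker_map, break_site, 3, rng)
for ev in events:
    seg = segment_event(*ev.product_calls(), marker_map)
    call = classify_induced(seg, break_site, marker_map)
    print(ev.event_id, call.klass.value)
# dsbr_00000 TWO_SIDED
# dsbr_00001 TWO_SIDED
# dsbr_00002 TWO_SIDED
```

Three clean DSB-repair events all show the canonical two-sided pattern:
hetDNA upstream of the break in the doubly-truncated product and downstream
in the full-length product.

An end-to-end run (simulate reads → call genotypes → classify → stats):

```bash
cat > run.yaml <<EOF
out_dir: runs/demo
seed: 11
n_events: 8
depth: 20
error_rate: 0.005
EOF
hetdna all --config run.yaml
```

writes `genotypes.tsv`, `classification.tsv`, `class_counts.tsv`,
`stats.json`, per-event profile strips (`profiles.svg`) and a run manifest.

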