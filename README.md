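# mlpaprobe

Probe design for **multiplex ligation-dependent probe amplification (MLPA)**
and its methylation-specific variant (**MS-MLPA**).

In MLPA, each assay probe is a pair of oligos that hybridize side by side on
a denatured target: the **LPO** (left probe oligo, a universal PCR-primer
sequence followed by the left hybridizing sequence, LHS) and the **RPO**
(right probe oligo: right hybridizing sequence RHS, an optional stuffer, and
the binding site for the right universal primer). Only when both halves
hybridize adjacently can ligase seal the nick; the ligated product is then
amplified with one universal primer pair, so peak height reports target copy
number. In MS-MLPA the probe-target hybrid additionally contains a site for
a methylation-sensitive restriction enzyme (e.g. HhaI, GCGC): unmethylated
targets are digested and yield no amplicon, so the assay reads out
methylation instead of copy number.

Designing such probes by hand is slow and error prone. `mlpaprobe`
automates it for any genome the user supplies:

* **candidate enumeration** — every (ligation position, LHS length, RHS
  length) window cut from the target;
* **physical-chemical screening** — nearest-neighbor melting temperature
  (unified NN parameters, 16.6·log₁₀[Na⁺] salt correction), GC content, and
  ΔG heuristics for hairpins and self-dimers, against user thresholds;
* **composite scoring** — sub-scores for Tm, ΔG, GC and the ligation-site
  base, each in [0, 1], multiplied into a final score in [0, 1] (1 = best).
  A probe set whose target base immediately after the left primer is an
  adenosine amplifies with 2–3-fold lower signal: its score is multiplied
  by 0.5 but it is never rejected for that reason alone;
* **uniqueness & variation test** — each half must occur exactly once,
  colinearly, in a local genome (k-mer seed-and-verify, both strands), and
  the hybrid footprint must not overlap known variants (VCF/BED);
* **MS-MLPA filter** — the four admissibility rules: exactly one
  methylation-sensitive site in LHS+RHS; no extra sites anywhere in the
  single-stranded LPO/RPO; ≥ 4 hybridizing nt flanking the site on each
  side; no SNP inside the site;
* **stuffer design** — a seeded generator plus a four-criteria verifier
  (no secondary structure, no genome homology, no methylation-sensitive
  restriction site, no cross-interaction between stuffer+primer unions),
  and amplicon-length planning for electrophoretic multiplexes;
* **standalone verification** — physical-chemical property reports for
  user-defined probes (no uniqueness/variation testing, which does not
  apply to manually placed probes such as SNP-genotyping designs).

## Worked example

Generate a toy genome with an embedded target and known SNPs, then design
MS-MLPA probes against it:

```bash
mlpaprobe fixtures --seed 1 --n-targets 1 --genome-len 4000 --n-variants 6 --out fx

cat > cfg.yaml <<EOF
tm_min: 50
tm_opt: 55
gc_min: 0.3
gc_max: 0.7
lhs_len_range: [21, 24]
rhs_len_range: [21, 24]
EOF

mlpaprobe design --targets fx/targets.fa --genome fx/genome.fa \
    --variants fx/variants.vcf --enzyme HhaI --config cfg.yaml --out out
```

which prints

```
INFO mlpaprobe.pipeline: target_1: 1216 candidate windows
INFO mlpaprobe.pipeline: target_1: 62 candidates passed physical-chemical screening
INFO mlpaprobe.pipeline: target_1: 56 of 62 probe sets pass the MS-MLPA filter
target_1: 62 probe set(s), 1154 failed candidate(s)
reports written to out
```

`out/probe_sets.tsv` lists every surviving probe set sorted by score, e.g.

```
rank  ligation_pos_1based  lhs_len  rhs_len  final_score  tm_lhs  tm_rhs  amplicon_len
   1                   86       24       22     0.076236   52.37   56.92            88
   2                   88       22       22     0.065789   55.45   55.04            86
```

Each row carries the four sub-scores, the assembled LPO/RPO sequences with
universal primers, the unique genomic locus, and — when an enzyme is
selected — the recognition site position and the MS-MLPA verdict
(`out/probe_sets_msmlpa.tsv` is the filtered view; coordinates are 1-based
inclusive). `out/failed_probe_sets.tsv` records every rejected candidate
and the workflow step at which it failed. The modest top score here is
honest: a short random toy target simply contains no candidate that is
simultaneously at the Tm optimum, mid-GC and structure-free.

Other commands: `mlpaprobe verify --probes probes.tsv` (batch
physical-chemical report for user probes), `mlpaprobe stuffers --lengths
12,16,20 --seed 7 --out st` (verified stuffer set as FASTA + TSV report).
Everything is also available as a library:

```python
from mlpaprobe import RunConfig, ScreenConfig, design
results = design(RunConfig(genome="fx/genome.fa", enzyme="HhaI"), "fx/targets.fa")
```

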