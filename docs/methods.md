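# Methods

## Assay model

An MLPA probe set is modelled as a pair (LHS, RHS) of target-complementary
halves meeting at a ligation position, embedded in two synthetic oligos:
LPO = left universal primer + LHS; RPO = RHS + stuffer (or bead tag) +
right-primer binding site. A probe set is usable when (i) both halves
hybridize stably and specifically at one genomic locus, (ii) neither oligo
is trapped in secondary structure or dimers, and (iii), for MS-MLPA, the
probe-target hybrid carries exactly one admissible methylation-sensitive
restriction site. The package encodes these requirements as a hard
pass/fail screen, a soft composite score, and the four-rule restriction
filter, in that order; candidates with a final score of 0 are never carried
into the (more expensive) uniqueness and variation tests.

## Thermodynamics

Melting temperatures use the unified DNA/DNA nearest-neighbor parameter set
(ΔH, ΔS per stacked dinucleotide plus terminal initiation terms), shipped
as `data/nn_params.tsv` so an alternative table can be swapped in without
code changes. Tm = 1000·ΔH / (ΔS + R·ln(CT/4)) − 273.15 +
16.6·log₁₀[Na⁺], with defaults 0.05 M Na⁺, 2.5·10⁻⁷ M total strands. The
NN model is refused below 8 nt where it is unreliable. The engine choice is
deliberately an open substitution — different established Tm programs
disagree by a few degrees, and users who calibrate wet-lab protocols to a
specific program should verify shortlisted probes with it; the minimum Tm
is therefore a user parameter, not a constant.

Hairpins are restricted to perfect ungapped stems of ≥ 3 bp closing loops
of ≥ 3 nt: ΔG = stem stack terms (at the configured temperature, default
37 °C) + a hairpin-loop initiation penalty from `data/hairpin_loops.tsv`
(37 °C values; linear interpolation between tabulated sizes, logarithmic
Jacobson–Stockmayer extrapolation beyond; loop penalties are not
re-evaluated at other temperatures). No internal loops or bulges are
modelled; this under-predicts some real structures, but every prediction is
verifiable by exhaustive enumeration, and the test suite holds the search
to that oracle for all lengths ≤ 14. Dimers score every run of ≥ 3
consecutive complementary pairs in antiparallel register as a duplex
(stacks + two initiation terms); the most negative value is reported, and
`dimer_dg(a, b) == dimer_dg(b, a)` exactly because the parameter table is
symmetric under reverse complement. Both functions return "none" rather
than a positive ΔG when no stable (ΔG < 0) structure exists.

## Scoring

Sub-scores, each in [0, 1]:

* **s_tm** — piecewise linear: 0 at the user minimum `tm_min`, 1 at
  `tm_opt` (default `tm_min`+5 °C). Above the optimum the score stays 1
  unless an explicit `tm_max` is configured (then it falls to 0 there).
  Rationale: the assay constraint the protocol states is a *minimum* Tm; a
  default upper penalty would invent a limit nobody specified. The
  per-half minimum governs (the weaker half limits ligation).
* **s_gc** — tent over the configured window [gc_min, gc_max] (defaults
  0.35–0.65), peaking at the midpoint, per-half minimum.
* **s_dg** — 1 at ΔG = 0 (or no structure) falling linearly to 0 at the
  configured floor, evaluated over hairpin and self-dimer of both halves;
  worst structure governs. Floors default to −3 kcal/mol (hairpin) and
  −8 kcal/mol (dimer).
* **s_lig** — lookup on the 5′ base of the RHS (the base immediately 3′ of
  the nick, which the ligase contacts): {G: 1.0, A: 1.0, T: 0.75, C: 0.5}.
  No published per-base table exists for this preference; the default
  encodes the qualitative ranking and is config-replaceable.

The final score is the **product** of the four sub-scores (configurable to
`min` or `mean`). Product keeps the score in [0, 1], makes any zero
sub-score fatal — matching the rule that only candidates with score > 0
proceed — and is monotone in each component. If the target base
immediately following the left primer (the first LHS base) is adenosine,
the final score is multiplied by exactly 0.5, reflecting the 2–3-fold
signal loss observed for such probes; the adjustment never rejects a
candidate by itself, and only the left junction is examined. Ranking is by
descending final score with deterministic tie-breaks (ascending ligation
position, then total hybrid length); candidate enumeration order is fixed
for the same reason.

## Uniqueness and variation

Uniqueness is exact full-length matching: a k-mer index (default k = 15)
seeds both halves on both strands, matches are verified against the genome
string, and a candidate is unique iff each half hits exactly once and the
two hits are adjacent and co-oriented at one locus. Mismatch-tolerant
homology (a BLAT-like "significant homolog" cutoff) is out of scope; exact
matching is a stricter-is-safer substitute and the documented limitation.
Variant intervals (VCF, converted to 0-based half-open on read, or BED) are
intersected with the hybrid footprint; in genomic MLPA any overlap drops
the candidate, while in MS-MLPA mode the overlap list is carried forward
and rule 4 of the restriction filter drops only variants inside the
recognition site — a footprint SNP outside the site changes hybridization
risk, which the report still records, but not the digestion readout the
MS-filter view is built around.

## MS-MLPA filter

Rule 1 counts recognition sites (IUPAC-expanded, both strands for
non-palindromic recognitions, overlapping matches included, palindromes
reported once) in the concatenation LHS+RHS, so a site spanning the
ligation nick counts once — the probe-target hybrid is contiguous on the
target; reports flag this interpretation when it fires. Rule 2 scans the
full single-stranded LPO and RPO (some methylation-sensitive enzymes nick
single-stranded DNA at a low rate) and fails when the observed site count
exceeds the count attributable to the hybrid site — i.e. when a
primer/stuffer/tag junction creates a new site. A nick-spanning hybrid
site appears in neither single-stranded oligo, so its attributable count
is zero. Rule 3 requires ≥ 4 hybridizing nt between each recognition-site
edge and the nearer *outer* end of the hybrid (the nick is not an end).
Rule 4 considers SNP-kind variants by default; indels are togglable.

The packaged enzyme table (HhaI, HpaII, AciI, HpyCH4IV, ClaI) is validated
on load: type II cutting strictly inside the recognition site, and — for
methylation-sensitive entries — exactly one CpG dinucleotide (a multi-CpG
site makes partially methylated targets ambiguous). Users can extend it
via TSV; invalid entries are rejected with per-entry messages.

## Stuffers

The generator rejection-samples CpG-free sequences with GC in [0.4, 0.6];
CpG-freedom guarantees no methylation-sensitive site can form inside a
stuffer (sites at junctions remain possible and are caught by
verification). Verification applies the four criteria to the two
stuffer+primer union sequences: hairpin ΔG ≥ −3 kcal/mol; no exact k-mer
match (k = 15) to any supplied genome — the deliberate, stricter
operationalization of "no significant homolog", re-runnable against new
assemblies; no methylation-sensitive recognition site; pairwise
cross-dimer ΔG ≥ −8 kcal/mol against every peer's unions. Generation is
deterministic per seed, verifies each new member against all previously
accepted ones, and aborts with per-criterion failure statistics if the
attempt cap is reached. The stuffer sits in the RPO between RHS and the
right-primer binding site. Amplicon planning emits evenly spaced target
lengths and the implied per-probe stuffer lengths, refusing infeasible
geometries.

## Synthetic data

The fixture generator writes a uniform-random toy genome, targets cut
verbatim from it (so every enumerated candidate has a known unique locus),
and a VCF of planted SNPs at recorded positions; output is byte-identical
per seed. It emulates the *combinatorial* structure of real design runs —
window enumeration, locus uniqueness, variant overlap — not the base
composition, repeat content or SNP density of real genomes: passing tests
demonstrate the rules are applied correctly, not that any particular
genome yields high-scoring probes. Test scenarios that need controlled
site counts use CpG-free backgrounds with recognition sites planted behind
TT/TT borders, which makes the expected site count of every window exact.
Problem sizes throughout (3–4 kb toy genomes, 110–120 nt targets, 21–30 nt
halves, 10-stuffer sets) are chosen so a full design run completes in
about a second while still exercising every code path.

## Numerical and degenerate-input choices

All coordinates are 0-based half-open internally; reports print 1-based
inclusive. N in a target disqualifies any window containing it. Candidate
windows shorter than 8 nt cannot occur with valid length ranges ≥ 8;
`ScreenConfig` validates its own invariants on construction. Equal final
scores rank by position, never by dict order. ΔG "none" (no structure) maps
to the sub-score peak. Empty variant sets, absent genomes (uniqueness test
skipped) and zero-length stuffers (shortest amplicon) are all legal inputs.

## Known limitations

Exact-match uniqueness misses near-identical paralogs; no partition
function or bulged structures in folding; no digestion-efficiency or
hemi-methylation modelling; no multiplex-wide Tm balancing; bead-mode tags
are user-supplied, not designed. The published phage-derived stuffer set is
not bundled; the generator + verifier produce an equivalent, auditable set,
and imported stuffers can be re-verified with the same code.
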