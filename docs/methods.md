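# Methods

## Scope and model

`codonlens` treats a genome or gene as a bag of codons read in frame from
validated coding sequences. All statistics derive from one tally: the
integer count of each of the 64 codons. Genome-level usage is
length-weighted (all occurrences tallied, then normalized), not averaged
per gene, so long genes contribute proportionally. Stop codons are counted
but excluded from the overall-usage denominator by default, so frequencies
refer to the 61 amino-acid-calling codons; an include-stops option exists.
Codons are handled internally in RNA letters (DNA input normalized on
read); the standard genetic code is the default and the only table the
shipped analyses use, though any NCBI table can be loaded.

**Relative usage** is a per-family probability (sums to 1 within each
synonymous family), not RSCU (mean 1). The two are monotonically related
within a family; RSCU is emitted as a derived column for interoperability
because external tables often expect it, but every internal computation
uses the probability form.

**CAI** follows the classic relative-adaptiveness construction: within each
family, w(c) = count(c) / max family count, with zero counts replaced by a
pseudocount of 0.5 occurrences before normalization — large enough to keep
w finite, small enough not to distort common codons. A gene's CAI is the
geometric mean of w over its codons, computed in log space to avoid
underflow on long genes. Stops and the single-codon families (AUG, UGG,
whose w ≡ 1 carries no information) are excluded from the mean by default;
both exclusions are configurable since conventions differ. The default
reference set is the host's whole-genome CDS counts, reproducible from one
input file; a highly-expressed gene set (ribosomal proteins, an expression
dataset) can be supplied instead and will generally shift the whole CAI
scale downward — distribution *means* are therefore comparable only within
one reference choice, which is why the CAI summary records its reference
label. The normal fit reported with a CAI distribution is the maximum
likelihood Gaussian (μ = mean, σ = population SD); the summary also reports
the sample SD separately.

## Rarity, overuse and strain coverage

Rarity is always defined against the **host** profile: rare means overall
host usage ≤0.5%, semi-rare ≤1.0%. The boundary comparison defaults to ≤
(usage *at* the threshold is scarce) with a strict-< option, because
published descriptions of these cutoffs vary between "less than" and "or
less"; the resolved operator is echoed in every output. Overuse compares a
query's overall (or relative) frequency to the host's; the default flag is
ratio ≥2. Codons a host never uses get a pseudocount-backed frequency
(0.5 / host coding total) rather than producing infinite ratios, and are
flagged `host_absent`. Genome-vs-genome comparison and per-gene diagnosis
share one code path with different query profiles.

Strain coverage is set arithmetic plus weighting: the flagged codons of a
gene report are partitioned by the supplemented-tRNA set, and the covered
fraction is weighted by each scarce (rare/semi-rare) codon's usage within
the gene, since relief is proportional to the drain removed. An empty
flagged set is vacuously fully covered.

## Harmonization

Manual codon optimization is made algorithmic and reproducible:

1. Per amino acid, target frequencies are the host's relative usage with
   forbidden-class codons (default: rare and semi-rare) removed and the
   remainder renormalized.
2. Integer codon counts for the gene's positions come from
   largest-remainder rounding (ties: higher target, then alphabetical),
   which attains the minimal L1 deviation from the real-valued targets.
3. Positions receive codons by a Bresenham-style even interleaving
   (deterministic, byte-stable output) or a seeded shuffle for sequence
   diversity.

The protein and length are preserved exactly and stop codons are never
touched. One situation requires a documented relaxation: a host can have an
amino acid whose *entire* family is scarce (e.g. both Cys codons under 1%
in a balanced genome — also true of real *E. coli*). Eliminating every
synonymous option for a needed residue is impossible, so such families keep
the host's most-used codon; the relaxation is warned about and recorded in
`relaxed_families`. The low-level allocator retains the strict
all-forbidden error for callers that want it. Optional motif avoidance
(restriction sites, vendor-forbidden sequences) swaps synonymous codons
locally, up to a bounded number of passes, and reports residual hits rather
than failing silently. `verify_harmonization` independently re-checks every
invariant and is run on all CLI output.

Achieved-vs-target deviation per family is bounded by one codon's worth
(1/positions) from rounding; it is reported, not thresholded, because
"roughly matched" has no canonical cutoff.

## The synthetic generator

The generator exists so that every stage is testable without downloads. It
emulates two regimes: a balanced bacterial-like host (coding GC ≈0.50,
preferred codons used ~57% of the time within their families) and an
AT-extreme anaerobic-fungus-like source (coding GC ≈0.28, preferred usage
~83%, preferred codons forced to each family's AT-richest member).

Per family, the preferred codon receives the target concentration jittered
by `preference_sd` (default 0.08), reproducing the ±8–9% across-family
spread real genomes show around their mean; the remaining mass is spread by
a seeded Dirichlet draw weighted toward codons whose GC content is close to
the GC target (softness β = 4, Dirichlet mass 20 — fixed design constants).
Which codon is preferred is itself a GC-weighted seeded draw unless forced,
so a balanced host prefers a realistic mixture of AT- and GC-leaning codons
and shares a nontrivial subset of preferences with an AT-extreme source.

The AT regime additionally uses an AT-shifted amino-acid composition:
baseline average proteome frequencies reweighted by exp(η · AT-fraction of
the residue's most AT-rich codon), η = 1. This reflects the documented
proteome skew of AT-rich genomes toward Lys/Asn/Ile/Leu/Phe and is what
allows a handful of AT codons (AAU, UUA, AAA) to reach ~20% of all coding
codons collectively — an effect synonymous choice alone cannot produce.
With these settings the generated source lands at ~27–29% coding GC and
~83±6% preferred usage without further adjustment.

Genes are sampled i.i.d. per position (amino acid from the composition,
codon from the family distribution) — synonymous choice does not vary with
expression level, matching organisms whose usage is uniform across genes.
Lengths are lognormal (default mean 400 codons, shape 0.3). An AUG start
and one uniform stop are appended *outside* the composition model; tests
that check parameter recovery strip them first, since they add one Met per
gene. What the generator does **not** emulate: expression-level
compartmentalized codon usage (as in fast-growing bacteria), codon-pair and
dinucleotide bias, gene structure (introns/UTRs), and GC heterogeneity
along chromosomes. Passing tests therefore demonstrate correctness of the
statistics and the harmonization algebra under a realistic bias regime, not
fidelity to any particular real genome.

## Numerical and interface choices

- Frequencies conserve exactly: Σ overall = 1 over coding codons, Σ
  relative = 1 per counted family (checked to 1e-12); zero-count families
  are listed as undefined rather than carrying 0/0 artifacts.
- Preferred-codon ties break alphabetically and carry a tie flag;
  preference-concentration SD uses n−1 (recorded, so either convention can
  be checked externally).
- Log- and product-domain CAI agree to 1e-10 on genes up to ~1000 codons.
- QC distinguishes failing defects (out-of-frame, internal stop, ambiguity
  letters) from a tolerated missing terminal stop; policies are strict
  (abort), skip (drop + count) and keep (retain flagged, truncating
  out-of-frame records at the last complete codon). Codons containing N are
  excluded from counts, never guessed.
- Tables are written with fixed float precision so repeated runs are
  byte-identical; every CLI run writes a resolved-config JSON sidecar so
  flagging thresholds are auditable.

## Problem sizes

The test suite and `scripts/acceptance.py` use genome sizes of 150–300
genes at 250–400 mean codons (≈40k–120k codons per genome). At these sizes
per-codon sampling error is ≲0.15% absolute, an order of magnitude below
the 0.5%/1% rarity boundaries and the 2-fold overuse contrast being
measured, so the qualitative pipeline outcomes are stable across seeds;
single-codon counts near a threshold can still move by one or two between
seeds, which is why counts (e.g. codons overused ≥2-fold, typically 8–13
under the default regimes) are reported rather than asserted to a point
value.

## Known limitations

- CAI distribution means depend strongly on the reference-set choice;
  whole-genome references yield higher self-CAI than highly-expressed-gene
  references. Cross-study comparison of absolute CAI values requires
  matching references.
- Rarity thresholds are fractions of the whole-genome codon pool; they do
  not model tRNA gene copy number or charging dynamics directly.
- Harmonization optimizes frequency match only; it does not consider mRNA
  secondary structure, 5′ ramps, codon-pair effects or synthesis
  constraints beyond motif avoidance.
- Per-gene usage percentages on genes shorter than ~30 codons are unstable
  and are warned about.
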