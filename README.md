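# codonlens

Host-aware codon-utilization diagnostics and harmonization for heterologous
expression.

## The problem

Genes from organisms with extreme nucleotide composition — anaerobic gut
fungi such as *Piromyces*, with coding regions around 28% GC, are the
motivating case — often fail to express in model hosts like *E. coli*, and
can even poison the host: heavy use of codons that are rare in the host
drains scarce tRNA pools, stalling translation of essential genes. The
standard codon adaptation index (CAI) does not expose this failure mode,
because it summarizes adaptation as a single geometric mean and says nothing
about *which* codons are overused or how scarce they are in the host.

`codonlens` gives molecular biologists and strain engineers the
codon-resolution view: it compares overall and relative (within-family)
codon usage between a source organism and an expression host, classifies
host codons as rare (≤0.5% of coding codons), semi-rare (≤1%) or common,
flags codons a gene or genome overuses ≥2-fold relative to the host, scores
CAI distributions, checks what a tRNA-supplemented strain (e.g.
BL21-CodonPlus RIPL: AGA, AUA, CCC, CUA) would actually cover, and rewrites
genes so their codon frequencies match the host.

## The statistics

For a codon *c* with count *n(c)* in a gene or genome:

- **overall usage**: *f(c) = n(c) / Σ n* over all coding (non-stop) codons;
- **relative usage**: *r(c) = n(c) / Σ n(c′)* over the synonymous family of
  *c* (a per-family probability; RSCU is available as a derived column);
- **preferred codon**: argmax of *r* within each of the 18 degenerate
  families; the mean ± SD of the preferred codon's *r* measures how
  concentrated an organism's synonymous choice is;
- **relative adaptiveness**: *w(c) = r(c) / max r* within the family,
  fitted on a reference CDS set with a 0.5 pseudocount for unseen codons;
- **CAI**: geometric mean of *w* over a gene's codons (stops and the
  single-codon families Met/Trp excluded), computed in log space;
- **overuse ratio**: *f_query(c) / f_host(c)*, flagged at ≥2-fold;
- **harmonization**: per amino acid, the gene's positions are reassigned
  codon counts by largest-remainder rounding of the host's relative usage
  with rare/semi-rare codons excluded, preserving the protein exactly.

## Worked example

Everything is runnable without downloads via the built-in simulator, which
generates CDS collections with controlled GC content and codon-preference
concentration. Emulate an AT-rich fungal source (GC 0.28, preferred codons
used 83% of the time) against a balanced host (GC 0.50, 57%):

```
codonlens simulate --n-genes 100 --mean-len 200 --preference 0.57 --gc 0.50 --seed 0 -o host.fasta
codonlens simulate --n-genes 100 --mean-len 200 --preference 0.83 --gc 0.28 --at-preferred --seed 1 -o fungal.fasta
codonlens compare --query fungal.fasta --host host.fasta --mode overall -o ratios.tsv
codonlens cai --cds fungal.fasta --host host.fasta -o cai.tsv
```

`ratios.tsv` lists all 61 coding codons; the most overused ones here are

```
codon amino_acid  query_freq  host_freq    ratio host_rarity
  UUA          L      0.0663     0.0001 665.8938        rare
  AGU          S      0.0524     0.0033  15.6984        rare
  AGA          R      0.0477     0.0057   8.3924   semi-rare
  ACA          T      0.0379     0.0100   3.8022   semi-rare
  AUA          I      0.0515     0.0176   2.9186      common
```

with 12 codons overused ≥2-fold in total (echoed in
`ratios.tsv.config.json`). The fungal genes' CAI distribution against this
host (`cai.tsv.summary.json`):

```
{"n_genes": 100, "mean": 0.327, "median": 0.331, "sd": 0.039,
 "gaussian_mu": 0.327, "gaussian_sigma": 0.039, ...}
```

i.e. a low, tight CAI distribution — yet the CAI alone never names UUA, AGU
or AGA as the codons doing the damage. `codonlens diagnose` produces the
per-gene version of this report (with optional `--supplement AGA,AUA,CCC,CUA`
to check strain coverage), and

```
codonlens harmonize --gene fungal.fasta --host host.fasta -o harmonized.fasta
```

rewrites each gene to the host's relative usage with rare and semi-rare
codons eliminated, emitting a verification report (protein identity, zero
forbidden codons, length preservation) alongside the FASTA.

Real genomes work the same way: point the commands at CDS FASTA files
extracted from GenBank or JGI annotations
(`scripts/reproduce_genomes.py` bundles the full cross-genome analysis for
a host/source pair you have downloaded).

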