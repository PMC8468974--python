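#!/usr/bin/env python
"""Recompute genome-scale codon-usage statistics from real CDS collections.

This is the opt-in counterpart to scripts/acceptance.py: it takes locally
downloaded CDS FASTA files (e.g. the E. coli K-12 MG1655 CDS set from
GenBank U00096.3 and the Piromyces indianae CDS set from Mycocosm piromy1)
and recomputes the cross-genome statistics the toolkit exists for: CAI
distribution means, preferred-codon sharing and concentration, >2-fold
overused codon count, the collective usage of the most AT-skewed abundant
codons, coding GC, and host rarity classes.  Nothing is downloaded; paths
must point at files you have already obtained.

Usage:
    python scripts/reproduce_genomes.py \
        --host-cds ecoli_u00096.3_cds.fna \
        --source-cds piromy1_cds.fna \
        [--extra-cds yeast_cds.fna] \
        [--gene atoB.fna] \
        --out results/genomes.json
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import codonlens as cl

TOP_AT_CODONS = ("AAU", "UUA", "AAA")
SCARCE_OF_INTEREST = ("AGA", "AUA", "UCA", "AGU")


def load(path):
    records, summary = cl.read_cds_fasta(path, qc_policy="skip")
    return records, summary


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--host-cds", required=True, type=Path,
                        help="expression-host CDS FASTA (e.g. E. coli U00096.3)")
    parser.add_argument("--source-cds", required=True, type=Path,
                        help="source-organism CDS FASTA (e.g. piromy1)")
    parser.add_argument("--extra-cds", type=Path, default=None,
                        help="optional third genome for preferred-codon sharing "
                             "(e.g. S. cerevisiae)")
    parser.add_argument("--gene", type=Path, default=None,
                        help="optional FASTA of individual genes to diagnose")
    parser.add_argument("--reference", type=Path, default=None,
                        help="optional highly-expressed host gene set for the "
                             "CAI reference (default: whole host CDS set)")
    parser.add_argument("--out", type=Path, required=True)
    args = parser.parse_args()

    code = cl.standard_code()
    host_genes, host_qc = load(args.host_cds)
    src_genes, src_qc = load(args.source_cds)
    host_counts = cl.aggregate(host_genes)
    src_counts = cl.aggregate(src_genes)
    host = cl.usage_profile(host_counts, code, source_label=str(args.host_cds))
    src = cl.usage_profile(src_counts, code, source_label=str(args.source_cds))

    ref_counts = host_counts
    if args.reference:
        ref_counts = cl.aggregate(load(args.reference)[0])
    model = cl.fit_adaptiveness(ref_counts, code)

    host_cai = cl.cai_distribution(host_genes, model, code, bins=50)
    src_cai = cl.cai_distribution(src_genes, model, code, bins=50)
    host_conc = cl.preference_concentration(host, code)
    src_conc = cl.preference_concentration(src, code)
    shared = cl.shared_preferred(src, host, code)
    ratios = cl.usage_ratio(src, host, "overall")
    rarity = cl.classify_rarity(host)

    out = {
        "host_qc": host_qc.as_dict(),
        "source_qc": src_qc.as_dict(),
        "host_self_cai_mean": round(host_cai.mean, 4),
        "host_self_cai_median": round(host_cai.median, 4),
        "source_cai_mean_vs_host": round(src_cai.mean, 4),
        "source_cai_median_vs_host": round(src_cai.median, 4),
        "host_preferred_codon_usage_pct": round(100 * host_conc.mean, 1),
        "host_preferred_codon_usage_sd_pct": round(100 * host_conc.sd, 1),
        "source_preferred_codon_usage_pct": round(100 * src_conc.mean, 1),
        "source_preferred_codon_usage_sd_pct": round(100 * src_conc.sd, 1),
        "shared_preferred_codons_of_18": shared.count,
        "shared_preferred_amino_acids": list(shared.amino_acids),
        "n_codons_overused_2fold": sum(e.overused for e in ratios.values()),
        "overused_codons": sorted(
            c for c, e in ratios.items() if e.overused
        ),
        "source_top3_at_codon_usage_pct": round(
            100 * sum(src.overall[c] for c in TOP_AT_CODONS), 1
        ),
        "host_top3_at_codon_usage_pct": round(
            100 * sum(host.overall[c] for c in TOP_AT_CODONS), 1
        ),
        "source_coding_gc_pct": round(100 * cl.gc_content(src_genes), 1),
        "host_coding_gc_pct": round(100 * cl.gc_content(host_genes), 1),
        "host_rarity_of_interest": {
            c: rarity.class_of[c] for c in SCARCE_OF_INTEREST
        },
    }

    if args.extra_cds:
        extra = cl.usage_profile(
            cl.aggregate(load(args.extra_cds)[0]), code,
            source_label=str(args.extra_cds),
        )
        out["extra_shared_preferred_codons_of_18"] = cl.shared_preferred(
            extra, host, code
        ).count
        out["extra_preferred_codon_usage_pct"] = round(
            100 * cl.preference_concentration(extra, code).mean, 1
        )

    if args.gene:
        genes, _ = load(args.gene)
        out["gene_reports"] = []
        for g in genes:
            report = cl.gene_diagnostics(g, host, model, rarity=rarity, code=code)
            out["gene_reports"].append(report.as_dict())

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(out, indent=2) + "\n")
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
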