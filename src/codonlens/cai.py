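"""Codon adaptation index: relative adaptiveness, per-gene scores, distributions.

The relative adaptiveness of a codon, w, is its usage in a reference CDS set
divided by the maximum usage within its synonymous family, so every family's
most-used codon has w = 1.  A gene's CAI is the geometric mean of w over its
codons, computed in log space for underflow safety.  Stop codons and the
single-codon families (AUG/Met, UGG/Trp, whose w is identically 1) are
excluded from the mean by default, following the classic convention.

By default the reference set is the host's whole-genome CDS counts; a
highly-expressed gene set (e.g. ribosomal proteins) can be supplied instead
wherever a :class:`~codonlens.codon_usage.CodonCounts` is accepted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .codon_usage import CodonCounts, EmptyInputError, count_codons
from .genetic_code import GeneticCode, standard_code
from .sequence_io import CdsRecord


class UndefinedScoreError(ValueError):
    """A gene had no scorable codons."""


@dataclass(frozen=True)
class AdaptivenessModel:
    """Per-codon relative adaptiveness values fitted from a reference CDS set."""

    w: Mapping[str, float]
    reference_label: str
    pseudocount: float
    excluded_codons: FrozenSet[str]


def fit_adaptiveness(
    reference: CodonCounts,
    code: Optional[GeneticCode] = None,
    pseudocount: float = 0.5,
    reference_label: str = "",
    exclude_single_codon_families: bool = True,
) -> AdaptivenessModel:
    """Fit w values: per family, count / family-max, zeros backed by a pseudocount.

    The pseudocount (default 0.5 occurrences) keeps w finite for codons the
    reference never uses without distorting common codons.
    """
    code = code or standard_code()
    if reference.n_codons == 0:
        raise EmptyInputError("adaptiveness model requires a non-empty reference")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")

    w: Dict[str, float] = {}
    for aa, family in code.families.items():
        adj = {c: max(reference.counts[c], 0) or pseudocount for c in family}
        if all(reference.counts[c] == 0 for c in family):
            warnings.warn(
                f"family {aa} absent from reference; w set from pseudocounts"
            )
        fam_max = max(adj.values())
        for c in family:
            w[c] = adj[c] / fam_max

    excluded = set(code.stop_codons)
    if exclude_single_codon_families:
        excluded |= {
            next(iter(f)) for f in code.families.values() if len(f) == 1
        }
    return AdaptivenessModel(
        w=w,
        reference_label=reference_label,
        pseudocount=pseudocount,
        excluded_codons=frozenset(excluded),
    )


def cai_score(
    record: CdsRecord,
    model: AdaptivenessModel,
    code: Optional[GeneticCode] = None,
) -> float:
    """Geometric mean of w over the record's scorable codons."""
    counts = count_codons(record)
    log_sum = 0.0
    n = 0
    for codon, k in counts.counts.items():
        if k == 0 or codon in model.excluded_codons:
            continue
        log_sum += k * math.log(model.w[codon])
        n += k
    if n == 0:
        raise UndefinedScoreError(
            f"record {record.id!r} has no scorable codons (all excluded or empty)"
        )
    return math.exp(log_sum / n)


@dataclass(frozen=True)
class CaiDistribution:
    """Per-gene CAI values with summary statistics and a normal fit."""

    per_gene: Mapping[str, float]
    mean: float
    median: float
    sd: float
    min: float
    max: float
    gaussian_fit: Tuple[float, float]
    histogram: Tuple[Tuple[float, ...], Tuple[int, ...]]
    failed_ids: Tuple[str, ...] = ()

    def summary(self) -> dict:
        return {
            "n_genes": len(self.per_gene),
            "mean": self.mean,
            "median": self.median,
            "sd": self.sd,
            "min": self.min,
            "max": self.max,
            "gaussian_mu": self.gaussian_fit[0],
            "gaussian_sigma": self.gaussian_fit[1],
            "n_failed": len(self.failed_ids),
        }


def cai_distribution(
    records: Sequence[CdsRecord],
    model: AdaptivenessModel,
    code: Optional[GeneticCode] = None,
    bins: int = 50,
) -> CaiDistribution:
    """Score every gene and summarize the distribution.

    The Gaussian fit is the maximum-likelihood normal (mu = mean, sigma =
    population SD of per-gene scores); the reported ``sd`` is the sample SD.
    Genes that cannot be scored are excluded and listed.
    """
    per_gene: Dict[str, float] = {}
    failed: List[str] = []
    for r in records:
        try:
            per_gene[r.id] = cai_score(r, model, code)
        except UndefinedScoreError:
            failed.append(r.id)
    if len(per_gene) < 2:
        raise EmptyInputError("CAI distribution requires at least 2 scorable genes")

    values = np.array(list(per_gene.values()))
    mu, sigma = stats.norm.fit(values)
    hist_counts, edges = np.histogram(values, bins=bins)
    return CaiDistribution(
        per_gene=per_gene,
        mean=float(values.mean()),
        median=float(np.median(values)),
        sd=float(values.std(ddof=1)),
        min=float(values.min()),
        max=float(values.max()),
        gaussian_fit=(float(mu), float(sigma)),
        histogram=(tuple(map(float, edges)), tuple(map(int, hist_counts))),
        failed_ids=tuple(failed),
    )
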