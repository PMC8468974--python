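"""Cross-organism codon-usage comparison and per-gene heterologous-risk reports.

Rarity is always defined against the *host* genome profile: a codon is rare
if its overall host usage is at or below 0.5% of coding codons, semi-rare at
or below 1% (boundaries and the <=/< operator are configurable).  Overuse
compares a query's usage to the host's, flagging codons used 2-fold or more
(default) — genome-vs-genome for landscape comparisons, gene-vs-host-genome
for per-gene diagnostics, through the same code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .cai import AdaptivenessModel, UndefinedScoreError, cai_score
from .codon_usage import (
    CodonCounts,
    UsageProfile,
    count_codons,
    preferred_codons,
    usage_profile,
)
from .genetic_code import GeneticCode, standard_code, validate_codon
from .sequence_io import CdsRecord

RARE = "rare"
SEMI_RARE = "semi-rare"
COMMON = "common"


class ConfigurationError(ValueError):
    """Incompatible or invalid comparison configuration."""


@dataclass(frozen=True)
class Thresholds:
    """Flagging thresholds shared across comparisons.

    ``operator`` controls the rarity boundary comparison: ``"le"`` (default,
    usage <= threshold is rare) or ``"lt"``.  ``overuse`` is a fold-ratio;
    ``overuse_strict`` selects > instead of >= at the boundary.
    """

    rare: float = 0.005
    semirare: float = 0.010
    overuse: float = 2.0
    operator: str = "le"
    overuse_strict: bool = False

    def __post_init__(self):
        if not (0 < self.rare < self.semirare):
            raise ConfigurationError(
                "need 0 < rare_threshold < semirare_threshold, got "
                f"{self.rare} / {self.semirare}"
            )
        if self.operator not in ("le", "lt"):
            raise ConfigurationError(f"operator must be 'le' or 'lt', got {self.operator!r}")

    def _cmp(self, usage: float, bound: float) -> bool:
        return usage <= bound if self.operator == "le" else usage < bound

    def overused(self, ratio: float) -> bool:
        return ratio > self.overuse if self.overuse_strict else ratio >= self.overuse


@dataclass(frozen=True)
class RarityClassification:
    """Every coding codon assigned to exactly one of rare/semi-rare/common."""

    rare_threshold: float
    semirare_threshold: float
    class_of: Mapping[str, str]
    operator: str = "le"

    def codons_in_class(self, cls: str) -> FrozenSet[str]:
        return frozenset(c for c, k in self.class_of.items() if k == cls)


def classify_rarity(
    host: UsageProfile,
    thresholds: Optional[Thresholds] = None,
    code: Optional[GeneticCode] = None,
) -> RarityClassification:
    """Partition the host's coding codons by overall-usage rarity."""
    thresholds = thresholds or Thresholds()
    code = code or standard_code()
    class_of: Dict[str, str] = {}
    for codon in code.coding_codons:
        u = host.overall.get(codon, 0.0)
        if thresholds._cmp(u, thresholds.rare):
            class_of[codon] = RARE
        elif thresholds._cmp(u, thresholds.semirare):
            class_of[codon] = SEMI_RARE
        else:
            class_of[codon] = COMMON
    return RarityClassification(
        rare_threshold=thresholds.rare,
        semirare_threshold=thresholds.semirare,
        class_of=class_of,
        operator=thresholds.operator,
    )


@dataclass(frozen=True)
class RatioEntry:
    codon: str
    amino_acid: str
    query_freq: float
    host_freq: float
    ratio: float
    overused: bool
    underused: bool
    host_absent: bool


def _pseudo_freq(profile: UsageProfile, pseudocount: float = 0.5) -> float:
    """Frequency floor for codons a profile never observed."""
    total = profile.coding_total()
    if total:
        return pseudocount / total
    positive = [v for v in profile.overall.values() if v > 0]
    return min(positive) / 2 if positive else pseudocount


def usage_ratio(
    query: UsageProfile,
    host: UsageProfile,
    mode: str = "overall",
    thresholds: Optional[Thresholds] = None,
    code: Optional[GeneticCode] = None,
) -> Dict[str, RatioEntry]:
    """Per-codon query/host usage ratios with 2-fold flags in both directions.

    ``mode`` selects overall or relative (within-family) frequencies.  Codons
    the host never uses get a pseudocount-backed host frequency and are
    flagged ``host_absent`` instead of producing infinite ratios.
    """
    if mode not in ("overall", "relative"):
        raise ConfigurationError(f"mode must be 'overall' or 'relative', got {mode!r}")
    if query.denominator_policy != host.denominator_policy:
        raise ConfigurationError(
            "profiles built with different denominator policies: "
            f"{query.denominator_policy} vs {host.denominator_policy}"
        )
    thresholds = thresholds or Thresholds()
    code = code or standard_code()
    floor = _pseudo_freq(host)

    out: Dict[str, RatioEntry] = {}
    for codon in code.coding_codons:
        if mode == "overall":
            q = query.overall.get(codon, 0.0)
            h = host.overall.get(codon, 0.0)
        else:
            q = query.relative.get(codon)
            h = host.relative.get(codon)
            if q is None or h is None:
                continue  # family unobserved in one of the profiles
        host_absent = h == 0.0
        h_eff = h if h > 0 else floor
        ratio = q / h_eff
        out[codon] = RatioEntry(
            codon=codon,
            amino_acid=code.codon_to_aa[codon],
            query_freq=q,
            host_freq=h,
            ratio=ratio,
            overused=thresholds.overused(ratio),
            underused=q > 0 and thresholds.overused(1.0 / ratio),
            host_absent=host_absent,
        )
    return out


@dataclass(frozen=True)
class SharedPreferred:
    count: int
    amino_acids: Tuple[str, ...]
    n_families_compared: int


def shared_preferred(
    a: UsageProfile,
    b: UsageProfile,
    code: Optional[GeneticCode] = None,
) -> SharedPreferred:
    """Amino acids (among the degenerate 18) whose preferred codon coincides."""
    code = code or standard_code()
    pa = preferred_codons(a, code)
    pb = preferred_codons(b, code)
    degenerate = code.degenerate_amino_acids()
    compared = [aa for aa in degenerate if aa in pa and aa in pb]
    uncovered = set(degenerate) - set(compared)
    if uncovered:
        warnings.warn(
            f"families not covered by both profiles excluded: {sorted(uncovered)}"
        )
    shared = tuple(
        sorted(aa for aa in compared if pa[aa].codon == pb[aa].codon)
    )
    return SharedPreferred(
        count=len(shared), amino_acids=shared, n_families_compared=len(compared)
    )


@dataclass(frozen=True)
class OverusedCodon:
    codon: str
    amino_acid: str
    gene_usage_pct: float
    host_usage_pct: float
    ratio: float
    rarity: str


@dataclass(frozen=True)
class GeneReport:
    """Per-gene heterologous-expression diagnostic against a host."""

    gene_id: str
    cai: Optional[float]
    n_codons: int
    overused_codons: Tuple[OverusedCodon, ...]
    n_rare_used: int
    n_semirare_used: int
    summary_flags: Tuple[str, ...]

    def as_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "cai": self.cai,
            "n_codons": self.n_codons,
            "overused_codons": [vars(c).copy() for c in self.overused_codons],
            "n_rare_used": self.n_rare_used,
            "n_semirare_used": self.n_semirare_used,
            "summary_flags": list(self.summary_flags),
        }


#: gene usage (%) of a host-rare/semi-rare codon above which the gene is
#: summarized as leaning heavily on scarce tRNAs (the regime where a single
#: codon at ~1.7% of a gene measurably taxes the host).
HEAVY_RARE_USE_PCT = 1.0


def gene_diagnostics(
    record: CdsRecord,
    host: UsageProfile,
    model: Optional[AdaptivenessModel] = None,
    thresholds: Optional[Thresholds] = None,
    rarity: Optional[RarityClassification] = None,
    code: Optional[GeneticCode] = None,
    min_codons: int = 30,
) -> GeneReport:
    """Diagnose one gene against the host: CAI plus overused-codon listing.

    The gene's own overall usage (as a percentage of its codons) is compared
    with host overall usage; codons at or above the overuse fold-threshold
    are listed with their host rarity class.
    """
    thresholds = thresholds or Thresholds()
    code = code or standard_code()
    rarity = rarity or classify_rarity(host, thresholds, code)

    gene_counts = count_codons(record)
    gene_profile = usage_profile(
        gene_counts, code, denominator_policy=host.denominator_policy,
        source_label=record.id,
    )
    if gene_counts.coding_total(code) < min_codons:
        warnings.warn(
            f"gene {record.id!r} has fewer than {min_codons} codons; "
            "usage percentages are unstable"
        )

    ratios = usage_ratio(gene_profile, host, "overall", thresholds, code)
    overused = tuple(
        OverusedCodon(
            codon=e.codon,
            amino_acid=e.amino_acid,
            gene_usage_pct=100.0 * e.query_freq,
            host_usage_pct=100.0 * e.host_freq,
            ratio=e.ratio,
            rarity=rarity.class_of[e.codon],
        )
        for e in sorted(ratios.values(), key=lambda e: (-e.ratio, e.codon))
        if e.overused and e.query_freq > 0
    )

    used = {c for c, n in gene_counts.counts.items() if n > 0 and c in rarity.class_of}
    n_rare = sum(1 for c in used if rarity.class_of[c] == RARE)
    n_semirare = sum(1 for c in used if rarity.class_of[c] == SEMI_RARE)

    flags: List[str] = []
    if any(
        o.rarity in (RARE, SEMI_RARE) and o.gene_usage_pct >= HEAVY_RARE_USE_PCT
        for o in overused
    ):
        flags.append("uses-rare-codon-heavily")
    if overused:
        flags.append("overuses-host-codons")

    cai_value: Optional[float] = None
    if model is not None:
        try:
            cai_value = cai_score(record, model, code)
        except UndefinedScoreError:
            flags.append("cai-undefined")

    return GeneReport(
        gene_id=record.id,
        cai=cai_value,
        n_codons=gene_counts.coding_total(code),
        overused_codons=overused,
        n_rare_used=n_rare,
        n_semirare_used=n_semirare,
        summary_flags=tuple(flags),
    )


@dataclass(frozen=True)
class CoverageSummary:
    """How much of a gene's flagged scarce-codon burden a tRNA-supplemented
    strain covers."""

    covered: Tuple[str, ...]
    uncovered: Tuple[str, ...]
    flagged_scarce_usage_pct: float
    covered_usage_fraction: float
    fully_covered: bool


def strain_coverage(
    report: GeneReport, supplemented_codons: Iterable[str]
) -> CoverageSummary:
    """Partition a report's flagged codons by a strain's supplemented tRNA set.

    The usage fraction weighs each flagged rare/semi-rare codon by its gene
    usage, so "covered" reflects relief of the actual scarce-tRNA drain.  An
    empty flagged set is vacuously fully covered.
    """
    supplement = {validate_codon(c) for c in supplemented_codons}
    flagged = [o.codon for o in report.overused_codons]
    covered = tuple(c for c in flagged if c in supplement)
    uncovered = tuple(c for c in flagged if c not in supplement)

    scarce = [o for o in report.overused_codons if o.rarity in (RARE, SEMI_RARE)]
    scarce_total = sum(o.gene_usage_pct for o in scarce)
    scarce_covered = sum(o.gene_usage_pct for o in scarce if o.codon in supplement)
    return CoverageSummary(
        covered=covered,
        uncovered=uncovered,
        flagged_scarce_usage_pct=scarce_total,
        covered_usage_fraction=(
            scarce_covered / scarce_total if scarce_total > 0 else 1.0
        ),
        fully_covered=len(uncovered) == 0,
    )
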