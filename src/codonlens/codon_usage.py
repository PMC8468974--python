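"""Codon counting and usage statistics at gene and genome level.

Two usage notions are computed from tallied codon occurrences:

* *overall usage* — a codon's frequency among all counted coding codons;
* *relative usage* — its frequency within its own synonymous family
  (a per-family probability summing to 1, not RSCU; RSCU is available as a
  derived column in :func:`usage_table`).

Genome-level usage is length-weighted: all occurrences across all genes are
tallied first, then normalized.  Stop codons are counted but excluded from
the overall-usage denominator by default, so statistics refer to the 61
amino-acid-calling codons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .genetic_code import ALL_CODONS, RNA_BASES, GeneticCode, standard_code
from .sequence_io import CdsRecord

EXCLUDE_STOPS = "exclude-stops"
INCLUDE_STOPS = "include-stops"


class EmptyInputError(ValueError):
    """No countable codons / records supplied."""


@dataclass(frozen=True)
class CodonCounts:
    """Integer occurrences of each of the 64 codons over ``n_genes`` records."""

    counts: Mapping[str, int]
    n_genes: int
    n_codons: int

    def __post_init__(self):
        full = {c: int(self.counts.get(c, 0)) for c in ALL_CODONS}
        object.__setattr__(self, "counts", full)
        if sum(full.values()) != self.n_codons:
            raise ValueError("n_codons does not equal the sum of counts")

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        merged = {c: self.counts[c] + other.counts[c] for c in ALL_CODONS}
        return CodonCounts(
            counts=merged,
            n_genes=self.n_genes + other.n_genes,
            n_codons=self.n_codons + other.n_codons,
        )

    def coding_total(self, code: GeneticCode) -> int:
        return sum(n for c, n in self.counts.items() if c not in code.stop_codons)


def count_codons(record: CdsRecord) -> CodonCounts:
    """Tally codon occurrences in one record.

    Codons containing ambiguity letters are excluded from all counts rather
    than guessed; a trailing partial codon (keep-policy input) is ignored.
    """
    seq = record.seq
    counts: Dict[str, int] = {}
    n = 0
    for i in range(0, 3 * (len(seq) // 3), 3):
        codon = seq[i : i + 3]
        if any(b not in RNA_BASES for b in codon):
            continue
        counts[codon] = counts.get(codon, 0) + 1
        n += 1
    return CodonCounts(counts=counts, n_genes=1, n_codons=n)


def aggregate(records: Sequence[CdsRecord]) -> CodonCounts:
    """Sum codon counts over a record collection (length-weighted tally)."""
    records = list(records)
    if not records:
        raise EmptyInputError("cannot aggregate an empty record list")
    total = count_codons(records[0])
    for r in records[1:]:
        total = total + count_codons(r)
    return total


@dataclass(frozen=True)
class UsageProfile:
    """Overall and per-family relative codon frequencies.

    ``relative`` covers only codons of families with at least one counted
    occurrence; families absent from the data are listed in
    ``zero_count_families`` rather than carrying 0/0 artifacts.
    """

    overall: Mapping[str, float]
    relative: Mapping[str, float]
    source_label: str
    denominator_policy: str
    zero_count_families: FrozenSet[str] = frozenset()
    counts: Optional[CodonCounts] = None

    def coding_total(self, code: Optional[GeneticCode] = None) -> Optional[int]:
        if self.counts is None:
            return None
        return self.counts.coding_total(code or standard_code())


def usage_profile(
    counts: CodonCounts,
    code: Optional[GeneticCode] = None,
    denominator_policy: str = EXCLUDE_STOPS,
    source_label: str = "",
) -> UsageProfile:
    """Derive overall and relative usage from tallied counts."""
    code = code or standard_code()
    if denominator_policy not in (EXCLUDE_STOPS, INCLUDE_STOPS):
        raise ValueError(f"unknown denominator policy {denominator_policy!r}")
    if counts.n_codons == 0:
        raise EmptyInputError("usage profile requires at least one counted codon")

    if denominator_policy == EXCLUDE_STOPS:
        denom = counts.coding_total(code)
        overall = {
            c: (counts.counts[c] / denom if c not in code.stop_codons else 0.0)
            for c in ALL_CODONS
        }
    else:
        denom = counts.n_codons
        overall = {c: counts.counts[c] / denom for c in ALL_CODONS}
    if denom == 0:
        raise EmptyInputError("no coding codons under the chosen denominator policy")

    relative: Dict[str, float] = {}
    zero_families = set()
    for aa, family in code.families.items():
        fam_total = sum(counts.counts[c] for c in family)
        if fam_total == 0:
            zero_families.add(aa)
            continue
        for c in family:
            relative[c] = counts.counts[c] / fam_total
    return UsageProfile(
        overall=overall,
        relative=relative,
        source_label=source_label,
        denominator_policy=denominator_policy,
        zero_count_families=frozenset(zero_families),
        counts=counts,
    )


@dataclass(frozen=True)
class PreferredCodon:
    codon: str
    relative_usage: float
    tie: bool


def preferred_codons(
    profile: UsageProfile, code: Optional[GeneticCode] = None
) -> Dict[str, PreferredCodon]:
    """Argmax of relative usage per family; alphabetical tie-break, tie-flagged.

    Families with zero counts are excluded (they are listed on the profile).
    """
    code = code or standard_code()
    out: Dict[str, PreferredCodon] = {}
    for aa, family in code.families.items():
        scored = sorted(
            ((c, profile.relative[c]) for c in family if c in profile.relative),
            key=lambda cv: (-cv[1], cv[0]),
        )
        if not scored:
            continue
        best_codon, best_val = scored[0]
        tie = len(scored) > 1 and math.isclose(
            scored[1][1], best_val, rel_tol=0, abs_tol=1e-12
        )
        out[aa] = PreferredCodon(codon=best_codon, relative_usage=best_val, tie=tie)
    return out


@dataclass(frozen=True)
class PreferenceConcentration:
    """Mean/SD of the preferred codon's relative usage over degenerate families."""

    mean: float
    sd: float
    n_families: int
    ddof: int
    missing_families: Tuple[str, ...] = ()


def preference_concentration(
    profile: UsageProfile,
    code: Optional[GeneticCode] = None,
    ddof: int = 1,
) -> PreferenceConcentration:
    """How concentrated synonymous choice is on each family's preferred codon.

    Computed over the amino acids with more than one codon (18 in the
    standard code).  SD uses ``ddof`` (default sample SD, n-1), recorded in
    the result so either convention can be checked.
    """
    code = code or standard_code()
    pref = preferred_codons(profile, code)
    degenerate = code.degenerate_amino_acids()
    values = [pref[aa].relative_usage for aa in degenerate if aa in pref]
    missing = tuple(aa for aa in degenerate if aa not in pref)
    if missing:
        import warnings

        warnings.warn(
            f"families with zero counts excluded from concentration: {missing}"
        )
    if not values:
        raise EmptyInputError("no degenerate families with counts")
    n = len(values)
    mean = sum(values) / n
    if n - ddof > 0:
        var = sum((v - mean) ** 2 for v in values) / (n - ddof)
    else:
        var = 0.0
    return PreferenceConcentration(
        mean=mean, sd=math.sqrt(var), n_families=n, ddof=ddof, missing_families=missing
    )


def gc_content(records: Sequence[CdsRecord] | CdsRecord) -> float:
    """(G+C)/(A+C+G+U) over the concatenated sequences; ambiguity letters ignored."""
    if isinstance(records, CdsRecord):
        records = [records]
    gc = total = 0
    for r in records:
        for b in r.seq:
            if b in RNA_BASES:
                total += 1
                if b in "GC":
                    gc += 1
    if total == 0:
        raise EmptyInputError("no unambiguous bases to compute GC content from")
    return gc / total


def rscu(counts: CodonCounts, code: Optional[GeneticCode] = None) -> Dict[str, float]:
    """Relative synonymous codon usage: observed / expected-under-uniform.

    Provided as a derived statistic for interoperability with external
    tables; the package's own analyses use per-family probabilities.
    """
    code = code or standard_code()
    out: Dict[str, float] = {}
    for aa, family in code.families.items():
        fam_total = sum(counts.counts[c] for c in family)
        if fam_total == 0:
            continue
        expected = fam_total / len(family)
        for c in family:
            out[c] = counts.counts[c] / expected
    return out


def usage_table(
    profile: UsageProfile, code: Optional[GeneticCode] = None
) -> pd.DataFrame:
    """Flat per-codon table: codon, amino_acid, count, overall/relative, preferred, RSCU."""
    code = code or standard_code()
    pref = preferred_codons(profile, code)
    pref_codons = {p.codon for p in pref.values()}
    counts = profile.counts
    rscu_col = rscu(counts, code) if counts is not None else {}
    rows = []
    for codon in ALL_CODONS:
        aa = code.codon_to_aa[codon]
        rows.append(
            {
                "codon": codon,
                "amino_acid": aa,
                "count": counts.counts[codon] if counts is not None else None,
                "overall_freq": profile.overall.get(codon, 0.0),
                "relative_freq": profile.relative.get(codon, float("nan")),
                "is_preferred": codon in pref_codons,
                "rscu": rscu_col.get(codon, float("nan")),
            }
        )
    return pd.DataFrame(rows)
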