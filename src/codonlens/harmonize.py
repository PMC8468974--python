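"""Codon harmonization: synonymous rewriting toward host relative usage.

Each gene is rewritten so that, amino acid by amino acid, the multiset of
codons used matches the host's relative usage as closely as integer counts
allow, while codons of forbidden rarity classes (rare and semi-rare by
default) are eliminated entirely.  The protein is preserved exactly and the
length never changes.

The allocation rule is largest-remainder rounding of the renormalized host
targets; position assignment is a deterministic even interleaving (or a
seeded shuffle).  Optional motif avoidance swaps synonymous codons locally
to remove unwanted sites (e.g. restriction sites) and reports any residual
hits rather than failing silently.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .codon_usage import UsageProfile
from .genetic_code import GeneticCode, normalize_rna, split_codons, standard_code
from .host_compare import RARE, SEMI_RARE, ConfigurationError, RarityClassification
from .sequence_io import CdsRecord


@dataclass(frozen=True)
class HarmonizationConfig:
    """Knobs for the rewriting procedure.

    ``forbidden_classes`` names the host rarity classes to eliminate; the
    default removes both rare (<=0.5% host usage) and semi-rare (<=1%)
    codons.  ``assignment_mode`` is ``"deterministic"`` (stable interleaved
    output) or ``"seeded-random"``.  ``forbidden_motifs`` are nucleotide
    strings (DNA or RNA, length >= 4) to purge via local synonymous swaps.
    """

    forbidden_classes: FrozenSet[str] = frozenset({RARE, SEMI_RARE})
    assignment_mode: str = "deterministic"
    seed: int = 0
    forbidden_motifs: Tuple[str, ...] = ()
    max_repair_passes: int = 3

    def __post_init__(self):
        if self.assignment_mode not in ("deterministic", "seeded-random"):
            raise ConfigurationError(
                f"unknown assignment mode {self.assignment_mode!r}"
            )
        motifs = tuple(normalize_rna(m) for m in self.forbidden_motifs)
        for m in motifs:
            if len(m) < 4 or any(b not in "ACGU" for b in m):
                raise ConfigurationError(f"invalid forbidden motif {m!r}")
        object.__setattr__(self, "forbidden_motifs", motifs)


@dataclass(frozen=True)
class HarmonizedGene:
    original_id: str
    new_seq: str
    per_aa_deviation: float
    eliminated: int
    motif_hits_remaining: int
    #: families whose codons are all of forbidden classes in the host, where
    #: the host's most-used codon had to be retained (e.g. Cys in hosts whose
    #: two Cys codons are both semi-rare)
    relaxed_families: Tuple[str, ...] = ()


def allocate_codons(
    n_positions: int,
    family_target: Mapping[str, float],
    forbidden: Set[str] = frozenset(),
) -> Dict[str, int]:
    """Integer codon counts matching target frequencies by largest remainder.

    Forbidden codons get 0 and the remaining targets are renormalized.
    Ties in the fractional remainder go to the higher target, then
    alphabetically.
    """
    if n_positions < 0:
        raise ValueError("n_positions must be non-negative")
    allowed = {c: t for c, t in family_target.items() if c not in forbidden}
    if not allowed:
        raise ConfigurationError(
            f"all codons of the family are forbidden: {sorted(family_target)}"
        )
    total = sum(allowed.values())
    if total <= 0:
        # host never uses any allowed codon: fall back to uniform over allowed
        allowed = {c: 1.0 for c in allowed}
        total = float(len(allowed))
    targets = {c: t / total for c, t in allowed.items()}

    quotas = {c: n_positions * t for c, t in targets.items()}
    alloc = {c: math.floor(q) for c, q in quotas.items()}
    short = n_positions - sum(alloc.values())
    by_remainder = sorted(
        targets,
        key=lambda c: (-(quotas[c] - alloc[c]), -targets[c], c),
    )
    for c in by_remainder[:short]:
        alloc[c] += 1
    full = {c: 0 for c in family_target}
    full.update(alloc)
    return full


def _interleave(alloc: Mapping[str, int]) -> List[str]:
    """Spread an allocated codon multiset evenly over positions.

    Bresenham-style credit accumulation: each position goes to the codon
    whose cumulative entitlement is furthest ahead of what it has received,
    ties broken alphabetically.  Deterministic and order-stable.
    """
    n = sum(alloc.values())
    codons = sorted(c for c, k in alloc.items() if k > 0)
    if not codons:
        return []
    share = {c: alloc[c] / n for c in codons}
    credit = {c: 0.0 for c in codons}
    remaining = {c: alloc[c] for c in codons}
    out: List[str] = []
    for _ in range(n):
        for c in codons:
            if remaining[c] > 0:
                credit[c] += share[c]
        pick = min(
            (c for c in codons if remaining[c] > 0),
            key=lambda c: (-credit[c], c),
        )
        out.append(pick)
        credit[pick] -= 1.0
        remaining[pick] -= 1
    return out


def _forbidden_codons(
    rarity: RarityClassification, classes: FrozenSet[str]
) -> FrozenSet[str]:
    return frozenset(
        c for c, k in rarity.class_of.items() if k in classes
    )


def effective_forbidden(
    rarity: RarityClassification,
    classes: FrozenSet[str],
    host: UsageProfile,
    code: GeneticCode,
) -> Tuple[FrozenSet[str], Tuple[str, ...]]:
    """Forbidden codon set with per-family relaxation where unavoidable.

    An amino acid the protein needs cannot have its entire family forbidden:
    for such families the host's most-used (highest relative usage) codon is
    exempted, mirroring the only option a manual optimizer has.  Returns the
    usable forbidden set and the relaxed family names.
    """
    forbidden = set(_forbidden_codons(rarity, classes))
    relaxed = []
    for aa in sorted(code.families):
        family = code.families[aa]
        if family <= forbidden:
            keep = min(
                family, key=lambda c: (-host.relative.get(c, 0.0), c)
            )
            forbidden.discard(keep)
            relaxed.append(aa)
    return frozenset(forbidden), tuple(relaxed)


def _max_deviation(
    assigned: Sequence[str],
    positions_by_aa: Mapping[str, List[int]],
    host: UsageProfile,
    forbidden: FrozenSet[str],
    code: GeneticCode,
) -> float:
    """Max |achieved - renormalized target| relative frequency over families."""
    worst = 0.0
    for aa, positions in positions_by_aa.items():
        family = code.families[aa]
        allowed = {
            c: host.relative.get(c, 0.0) for c in family if c not in forbidden
        }
        total = sum(allowed.values())
        if total <= 0:
            allowed = {c: 1.0 for c in allowed}
            total = float(len(allowed))
        targets = {c: t / total for c, t in allowed.items()}
        n = len(positions)
        got = {c: 0 for c in family}
        for i in positions:
            got[assigned[i]] += 1
        for c in family:
            achieved = got[c] / n
            worst = max(worst, abs(achieved - targets.get(c, 0.0)))
    return worst


def harmonize_gene(
    record: CdsRecord,
    host: UsageProfile,
    rarity: RarityClassification,
    config: Optional[HarmonizationConfig] = None,
    code: Optional[GeneticCode] = None,
) -> HarmonizedGene:
    """Rewrite a gene's synonymous codons to match host relative usage.

    Stop codons are left untouched.  Requires the host profile to cover every
    amino-acid family the gene uses.  Families whose codons are all of
    forbidden classes keep the host's most-used codon (warned and recorded
    in ``relaxed_families``).
    """
    config = config or HarmonizationConfig()
    code = code or standard_code()
    codons = list(split_codons(record.seq))
    rng = np.random.default_rng(config.seed)

    positions_by_aa: Dict[str, List[int]] = {}
    for i, c in enumerate(codons):
        aa = code.codon_to_aa[c]
        if aa == "*":
            continue
        positions_by_aa.setdefault(aa, []).append(i)

    forbidden, relaxed_all = effective_forbidden(
        rarity, config.forbidden_classes, host, code
    )
    relaxed = tuple(aa for aa in relaxed_all if aa in positions_by_aa)
    if relaxed:
        warnings.warn(
            f"{record.id!r}: families {relaxed} have only forbidden-class "
            "codons in the host; their most-used codon was retained"
        )

    eliminated = sum(1 for c in codons if c in forbidden)
    new_codons = list(codons)
    for aa, positions in positions_by_aa.items():
        family = code.families[aa]
        if all(c not in host.relative for c in family):
            raise ConfigurationError(
                f"host profile does not cover family {aa} used by {record.id!r}"
            )
        targets = {c: host.relative.get(c, 0.0) for c in family}
        alloc = allocate_codons(len(positions), targets, forbidden)
        assigned = _interleave(alloc)
        if config.assignment_mode == "seeded-random":
            rng.shuffle(assigned)
        for pos, codon in zip(positions, assigned):
            new_codons[pos] = codon

    new_seq = "".join(new_codons)
    hits = _motif_hits(new_seq, config.forbidden_motifs)
    if hits and config.forbidden_motifs:
        new_seq, hits = _repair_motifs(
            new_seq, config, forbidden, code, host
        )
        new_codons = list(split_codons(new_seq))
        if hits:
            warnings.warn(
                f"{record.id!r}: {hits} forbidden-motif hit(s) remain after "
                f"{config.max_repair_passes} repair passes"
            )

    deviation = _max_deviation(
        new_codons, positions_by_aa, host, forbidden, code
    )
    return HarmonizedGene(
        original_id=record.id,
        new_seq=new_seq,
        per_aa_deviation=deviation,
        eliminated=eliminated,
        motif_hits_remaining=hits,
        relaxed_families=relaxed,
    )


def _motif_hits(seq: str, motifs: Sequence[str]) -> int:
    n = 0
    for m in motifs:
        start = 0
        while True:
            i = seq.find(m, start)
            if i < 0:
                break
            n += 1
            start = i + 1
    return n


def _repair_motifs(
    seq: str,
    config: HarmonizationConfig,
    forbidden: FrozenSet[str],
    code: GeneticCode,
    host: UsageProfile,
) -> Tuple[str, int]:
    """Swap synonymous codons locally to remove forbidden motifs."""
    for _ in range(config.max_repair_passes):
        changed = False
        for m in config.forbidden_motifs:
            i = seq.find(m)
            while i >= 0:
                fixed = False
                first_codon = i // 3
                last_codon = (i + len(m) - 1) // 3
                for ci in range(first_codon, last_codon + 1):
                    old = seq[3 * ci : 3 * ci + 3]
                    aa = code.codon_to_aa[old]
                    if aa == "*":
                        continue
                    alts = sorted(
                        (c for c in code.families[aa]
                         if c != old and c not in forbidden),
                        key=lambda c: (-host.relative.get(c, 0.0), c),
                    )
                    for alt in alts:
                        cand = seq[: 3 * ci] + alt + seq[3 * ci + 3 :]
                        if cand.find(m, max(0, i - len(m)), i + len(m) + 1) < 0:
                            seq = cand
                            fixed = changed = True
                            break
                    if fixed:
                        break
                i = seq.find(m, i + 1 if not fixed else i)
        if not changed:
            break
    return seq, _motif_hits(seq, config.forbidden_motifs)


@dataclass(frozen=True)
class VerificationReport:
    passed: bool
    checks: Mapping[str, bool]
    details: Mapping[str, object]

    def as_dict(self) -> dict:
        return {
            "passed": self.passed,
            "checks": dict(self.checks),
            "details": {k: v for k, v in self.details.items()},
        }


def verify_harmonization(
    original: CdsRecord,
    result: HarmonizedGene,
    host: UsageProfile,
    rarity: RarityClassification,
    config: Optional[HarmonizationConfig] = None,
    code: Optional[GeneticCode] = None,
) -> VerificationReport:
    """Independently re-check every invariant of a harmonized gene.

    Checks protein identity, absence of forbidden-class codons, length
    preservation and residual motif hits; any failure is listed by name.
    """
    config = config or HarmonizationConfig()
    code = code or standard_code()
    forbidden, _ = effective_forbidden(
        rarity, config.forbidden_classes, host, code
    )

    new_codons = split_codons(result.new_seq)
    checks = {
        "protein_identity": code.translate(result.new_seq)
        == code.translate(original.seq),
        "no_forbidden_codons": not any(c in forbidden for c in new_codons),
        "length_preserved": len(result.new_seq) == len(original.seq),
        "motifs_resolved": _motif_hits(result.new_seq, config.forbidden_motifs)
        == result.motif_hits_remaining,
    }
    offending = sorted({c for c in new_codons if c in forbidden})
    return VerificationReport(
        passed=all(checks.values()),
        checks=checks,
        details={
            "per_aa_deviation": result.per_aa_deviation,
            "eliminated": result.eliminated,
            "forbidden_codons_found": offending,
            "motif_hits_remaining": result.motif_hits_remaining,
        },
    )
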