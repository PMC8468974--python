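"""Seed-deterministic synthetic CDS collections with controllable codon bias.

The generator emulates two regimes seen in real genomes: a balanced
bacterial-like host (coding GC near 0.50, preferred codons used ~57% of the
time within their families) and an extremely AT-rich anaerobic-fungus-like
source (coding GC near 0.28, preferred codons used ~83% of the time).  Genes
are sampled i.i.d. per position — synonymous choice does not vary with
expression level, matching the uniform-across-genes usage of AT-rich
anaerobic fungi — with an AUG start and a single stop appended outside the
composition model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .codon_usage import UsageProfile, EXCLUDE_STOPS
from .genetic_code import GeneticCode, codon_gc, standard_code
from .host_compare import ConfigurationError
from .sequence_io import CdsRecord

#: Average amino-acid composition of well-annotated proteomes (fractions).
DEFAULT_AA_COMPOSITION: Mapping[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

#: Sharpness of the GC-target weighting for non-preferred codons.
_GC_WEIGHT_BETA = 4.0
#: Dirichlet concentration mass for spreading non-preferred usage.
_DIRICHLET_MASS = 20.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic CDS collection.

    ``preference_concentration`` is the target relative usage of each
    family's preferred codon (must exceed 1/family-size to be realizable);
    ``gc_target`` steers both which codon is preferred and how the rest of
    each family's mass is spread.  Lengths are lognormal around
    ``mean_length`` codons with shape ``length_dispersion``.
    """

    n_genes: int = 300
    mean_length: int = 400
    length_dispersion: float = 0.3
    gc_target: float = 0.5
    preference_concentration: float = 0.57
    preference_sd: float = 0.08
    preferred_map: Optional[Mapping[str, str]] = None
    amino_acid_composition: Optional[Mapping[str, float]] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.mean_length < 10:
            raise ConfigurationError("mean_length must be >= 10 codons")
        if not 0.0 <= self.gc_target <= 1.0:
            raise ConfigurationError("gc_target must be in [0, 1]")
        if not (1.0 / 6.0) <= self.preference_concentration <= 1.0:
            raise ConfigurationError(
                "preference_concentration must be in [1/6, 1]"
            )
        if self.preference_sd < 0:
            raise ConfigurationError("preference_sd must be non-negative")

    def composition(self) -> Dict[str, float]:
        comp = dict(self.amino_acid_composition or DEFAULT_AA_COMPOSITION)
        total = sum(comp.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            comp = {aa: v / total for aa, v in comp.items()}
        return comp

    def as_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "mean_length": self.mean_length,
            "length_dispersion": self.length_dispersion,
            "gc_target": self.gc_target,
            "preference_concentration": self.preference_concentration,
            "preference_sd": self.preference_sd,
            "preferred_map": dict(self.preferred_map) if self.preferred_map else None,
            "amino_acid_composition": dict(self.amino_acid_composition)
            if self.amino_acid_composition
            else None,
            "seed": self.seed,
        }


def at_biased_composition(
    eta: float = 1.0, code: Optional[GeneticCode] = None
) -> Dict[str, float]:
    """Amino-acid composition skewed toward residues with AT-rich codons.

    Extremely AT-biased genomes shift their proteomes toward amino acids
    whose codons can be AT-rich (Lys, Asn, Ile, Leu, Phe, Tyr), which is why
    a handful of AT codons can collectively reach ~19% of all coding codons
    in such organisms.  Each amino acid's baseline frequency is weighted by
    ``exp(eta * AT-fraction of its most AT-rich codon)`` and renormalized;
    ``eta=1`` reproduces that regime.
    """
    code = code or standard_code()
    weights = {
        aa: DEFAULT_AA_COMPOSITION[aa]
        * math.exp(eta * (1.0 - min(codon_gc(c) for c in family)))
        for aa, family in code.families.items()
    }
    total = sum(weights.values())
    return {aa: w / total for aa, w in sorted(weights.items())}


def at_richest_preferred_map(code: Optional[GeneticCode] = None) -> Dict[str, str]:
    """Force every family's preferred codon to its most AT-rich member."""
    code = code or standard_code()
    return {
        aa: min(family, key=lambda c: (codon_gc(c), c))
        for aa, family in code.families.items()
    }


def gc_richest_preferred_map(code: Optional[GeneticCode] = None) -> Dict[str, str]:
    """Force every family's preferred codon to its most GC-rich member."""
    code = code or standard_code()
    return {
        aa: min(family, key=lambda c: (-codon_gc(c), c))
        for aa, family in code.families.items()
    }


def generate_host_profile(
    spec: SyntheticSpec, code: Optional[GeneticCode] = None
) -> UsageProfile:
    """Construct a genome-scale usage profile with the spec's bias regime.

    Per family the preferred codon receives ``preference_concentration`` of
    the relative mass, jittered per family by ``preference_sd`` so that the
    across-family mean/SD of preferred usage emulates real genomes (which
    balance around their mean with roughly +/-8-9% spread); the remainder is
    split among the other codons by a seeded Dirichlet draw whose weights
    favor codons whose GC content is close to ``gc_target``.  Which codon is
    preferred is a seeded draw with the same GC weighting unless
    ``preferred_map`` forces it.  Overall usage is the amino-acid
    composition times relative usage.  Deterministic under the spec's seed.
    """
    code = code or standard_code()
    rng = np.random.default_rng(spec.seed)
    comp = spec.composition()
    conc = spec.preference_concentration
    pref_map = dict(spec.preferred_map or {})

    relative: Dict[str, float] = {}
    for aa in sorted(code.families):
        family = sorted(code.families[aa])
        k = len(family)
        if k == 1:
            relative[family[0]] = 1.0
            continue
        if conc < 1.0 / k - 1e-12:
            raise ConfigurationError(
                f"preference_concentration {conc} infeasible for the "
                f"{k}-codon family {aa} (needs >= 1/{k})"
            )
        gc_weights = np.array(
            [math.exp(-_GC_WEIGHT_BETA * abs(codon_gc(c) - spec.gc_target))
             for c in family]
        )
        if aa in pref_map:
            preferred = pref_map[aa]
            if preferred not in family:
                raise ConfigurationError(
                    f"preferred_map assigns {preferred} outside family {aa}"
                )
        else:
            preferred = family[
                rng.choice(k, p=gc_weights / gc_weights.sum())
            ]
        conc_f = float(
            np.clip(rng.normal(conc, spec.preference_sd), 1.0 / k, 0.97)
        )
        others = [c for c in family if c != preferred]
        weights = np.array(
            [math.exp(-_GC_WEIGHT_BETA * abs(codon_gc(c) - spec.gc_target))
             for c in others]
        )
        alpha = _DIRICHLET_MASS * weights / weights.sum()
        rest = rng.dirichlet(alpha) * (1.0 - conc_f)
        if rest.size and rest.max() > conc_f:
            # degenerate draw would dethrone the preferred codon: flatten
            rest = np.full(len(others), (1.0 - conc_f) / len(others))
        relative[preferred] = conc_f
        for c, v in zip(others, rest):
            relative[c] = float(v)

    overall: Dict[str, float] = {c: 0.0 for c in code.codon_to_aa}
    for aa, family in code.families.items():
        for c in family:
            overall[c] = comp[aa] * relative[c]
    total = sum(overall.values())
    overall = {c: v / total for c, v in overall.items()}

    return UsageProfile(
        overall=overall,
        relative=relative,
        source_label=f"synthetic(gc={spec.gc_target},pref={conc},seed={spec.seed})",
        denominator_policy=EXCLUDE_STOPS,
        counts=None,
    )


def _family_samplers(
    profile: UsageProfile, code: GeneticCode
) -> Dict[str, Tuple[List[str], np.ndarray]]:
    samplers = {}
    for aa in sorted(code.families):
        family = sorted(code.families[aa])
        p = np.array([profile.relative.get(c, 0.0) for c in family])
        if p.sum() <= 0:
            raise ConfigurationError(f"profile does not cover family {aa}")
        samplers[aa] = (family, p / p.sum())
    return samplers


def generate_biased_gene(
    protein: str,
    profile: UsageProfile,
    seed: int,
    code: Optional[GeneticCode] = None,
    record_id: str = "gene",
    add_start_stop: bool = True,
    stop_usage: Optional[Mapping[str, float]] = None,
) -> CdsRecord:
    """Back-translate a protein by sampling codons from a usage profile."""
    code = code or standard_code()
    if not protein:
        raise ValueError("protein must be non-empty")
    bad = sorted(set(protein) - set(code.families))
    if bad:
        raise ValueError(f"unknown amino acid letters: {bad}")
    rng = np.random.default_rng(seed)
    samplers = _family_samplers(profile, code)
    codons = [_sample_codon(samplers[aa], rng) for aa in protein]
    if add_start_stop:
        codons.insert(0, "AUG")
        codons.append(_sample_stop(code, stop_usage, rng))
    return CdsRecord(id=record_id, seq="".join(codons))


def _sample_codon(sampler: Tuple[List[str], np.ndarray], rng) -> str:
    family, p = sampler
    return family[rng.choice(len(family), p=p)]


def _sample_stop(code: GeneticCode, stop_usage, rng) -> str:
    stops = sorted(code.stop_codons)
    if stop_usage:
        p = np.array([stop_usage.get(s, 0.0) for s in stops])
        p = p / p.sum()
    else:
        p = np.full(len(stops), 1.0 / len(stops))
    return stops[rng.choice(len(stops), p=p)]


def generate_genome(
    profile: UsageProfile,
    spec: SyntheticSpec,
    code: Optional[GeneticCode] = None,
) -> List[CdsRecord]:
    """Sample a QC-clean CDS collection from a usage profile.

    Gene lengths are lognormal around ``spec.mean_length`` codons; each
    position's amino acid comes from the composition and its codon from the
    family's relative usage.  Every gene gets an AUG start and one stop, so
    a genome contributes exactly one extra Met codon per gene beyond the
    composition model.
    """
    code = code or standard_code()
    rng = np.random.default_rng(spec.seed + 1)  # distinct stream from the profile draw
    comp = spec.composition()
    aas = sorted(comp)
    p_aa = np.array([comp[a] for a in aas])
    p_aa = p_aa / p_aa.sum()
    samplers = _family_samplers(profile, code)

    sigma = spec.length_dispersion
    mu = math.log(spec.mean_length) - sigma**2 / 2.0

    records: List[CdsRecord] = []
    width = len(str(spec.n_genes))
    for g in range(spec.n_genes):
        length = max(10, int(round(rng.lognormal(mu, sigma))))
        idx = rng.choice(len(aas), size=length, p=p_aa)
        codons = np.empty(length, dtype=object)
        for ai in np.unique(idx):
            family, p = samplers[aas[ai]]
            mask = idx == ai
            picks = rng.choice(len(family), size=int(mask.sum()), p=p)
            codons[mask] = [family[j] for j in picks]
        seq = "AUG" + "".join(codons) + _sample_stop(code, None, rng)
        records.append(CdsRecord(id=f"syn_{g + 1:0{width}d}", seq=seq))
    return records
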