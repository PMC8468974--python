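import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import codonlens as cl
from codonlens.harmonize import (
    HarmonizationConfig,
    _motif_hits,
    allocate_codons,
    effective_forbidden,
)
from codonlens.host_compare import RARE, SEMI_RARE, ConfigurationError, Thresholds
from codonlens.codon_usage import CodonCounts
from tests.conftest import fungal_like_spec, random_cds


def counts_from(mapping):
    return CodonCounts(counts=mapping, n_genes=1, n_codons=sum(mapping.values()))


def brute_force_min_l1(n, targets):
    """All integer compositions of n; return the minimal L1 deviation."""
    codons = sorted(targets)
    best = math.inf
    for combo in itertools.product(range(n + 1), repeat=len(codons)):
        if sum(combo) != n:
            continue
        dev = sum(abs(k - n * targets[c]) for k, c in zip(combo, codons))
        best = min(best, dev)
    return best


class TestAllocateCodons:
    def test_exact_proportions(self):
        alloc = allocate_codons(10, {"CUG": 0.5, "CUU": 0.3, "CUC": 0.2})
        assert alloc == {"CUG": 5, "CUU": 3, "CUC": 2}

    def test_tie_breaks_alphabetically(self):
        assert allocate_codons(3, {"AAA": 0.5, "AAG": 0.5}) == {"AAA": 2, "AAG": 1}

    def test_forbidden_codons_get_zero_and_targets_renormalize(self):
        alloc = allocate_codons(
            10, {"AGA": 0.5, "CGU": 0.3, "CGC": 0.2}, forbidden={"AGA"}
        )
        assert alloc["AGA"] == 0
        assert sum(alloc.values()) == 10
        assert alloc == {"AGA": 0, "CGU": 6, "CGC": 4}

    def test_all_forbidden_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError, match="forbidden"):
            allocate_codons(5, {"UGU": 0.5, "UGC": 0.5}, forbidden={"UGU", "UGC"})

    def test_counts_always_sum_to_positions(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 7))
            raw = rng.dirichlet([1.0] * k)
            targets = {f"C{i}": float(p) for i, p in enumerate(raw)}
            n = int(rng.integers(0, 40))
            assert sum(allocate_codons(n, targets).values()) == n

    def test_matches_brute_force_minimal_l1(self, rng):
        # largest-remainder rounding attains the minimal L1 deviation;
        # exhaustively verified for families of <= 3 codons and n <= 10
        for _ in range(40):
            k = int(rng.integers(2, 4))
            raw = rng.dirichlet([1.0] * k)
            targets = {f"C{i}": float(p) for i, p in enumerate(raw)}
            n = int(rng.integers(1, 11))
            alloc = allocate_codons(n, targets)
            dev = sum(abs(alloc[c] - n * targets[c]) for c in targets)
            assert dev == pytest.approx(brute_force_min_l1(n, targets), abs=1e-9)


@given(
    n=st.integers(min_value=0, max_value=60),
    weights=st.lists(
        st.floats(min_value=0.01, max_value=1.0), min_size=2, max_size=6
    ),
)
@settings(derandomize=True, deadline=None)
def test_allocation_is_exact_and_nonnegative(n, weights):
    total = sum(weights)
    targets = {f"C{i}": w / total for i, w in enumerate(weights)}
    alloc = allocate_codons(n, targets)
    assert sum(alloc.values()) == n
    assert all(v >= 0 for v in alloc.values())
    # every count is within one of its real-valued quota
    assert all(abs(alloc[c] - n * targets[c]) < 1.0 for c in targets)


def host_and_rarity(code, seed=3):
    spec = cl.SyntheticSpec(n_genes=150, mean_length=250, seed=seed)
    genome = cl.generate_genome(cl.generate_host_profile(spec, code), spec, code)
    counts = cl.aggregate(genome)
    profile = cl.usage_profile(counts, code)
    return profile, cl.classify_rarity(profile), counts


class TestHarmonizeGene:
    def test_rare_arginines_eliminated_protein_preserved(self, code):
        host, rarity, _ = host_and_rarity(code)
        gene = cl.CdsRecord(id="g", seq="AUG" + "AGA" * 30 + "UAA")
        result = cl.harmonize_gene(gene, host, rarity)
        assert "AGA" not in [
            result.new_seq[i : i + 3] for i in range(0, len(result.new_seq), 3)
        ] or rarity.class_of["AGA"] == "common"
        assert code.translate(result.new_seq) == code.translate(gene.seq)
        assert len(result.new_seq) == len(gene.seq)

    def test_deterministic_mode_is_byte_stable(self, rng, code):
        host, rarity, _ = host_and_rarity(code)
        gene = random_cds(rng, 200, code)
        r1 = cl.harmonize_gene(gene, host, rarity)
        r2 = cl.harmonize_gene(gene, host, rarity)
        assert r1.new_seq == r2.new_seq

    def test_seeded_random_mode_reproducible_and_protein_preserving(self, rng, code):
        host, rarity, _ = host_and_rarity(code)
        gene = random_cds(rng, 200, code)
        cfg = HarmonizationConfig(assignment_mode="seeded-random", seed=17)
        r1 = cl.harmonize_gene(gene, host, rarity, cfg)
        r2 = cl.harmonize_gene(gene, host, rarity, cfg)
        assert r1.new_seq == r2.new_seq
        assert code.translate(r1.new_seq) == code.translate(gene.seq)
        other = cl.harmonize_gene(
            gene, host, rarity, HarmonizationConfig(
                assignment_mode="seeded-random", seed=18
            )
        )
        assert other.new_seq != r1.new_seq  # different seed, different interleaving

    def test_idempotent_on_harmonized_input(self, rng, code):
        host, rarity, _ = host_and_rarity(code)
        gene = random_cds(rng, 300, code)
        once = cl.harmonize_gene(gene, host, rarity)
        twice = cl.harmonize_gene(
            cl.CdsRecord(id="h", seq=once.new_seq), host, rarity
        )
        assert twice.new_seq == once.new_seq

    def test_achieved_frequencies_match_allocation_per_family(self, rng, code):
        host, rarity, _ = host_and_rarity(code)
        gene = random_cds(rng, 500, code)
        result = cl.harmonize_gene(gene, host, rarity)
        forbidden, _ = effective_forbidden(
            rarity, frozenset({RARE, SEMI_RARE}), host, code
        )
        codons = [result.new_seq[i : i + 3] for i in range(0, len(result.new_seq), 3)]
        original = [gene.seq[i : i + 3] for i in range(0, len(gene.seq), 3)]
        for aa in code.degenerate_amino_acids():
            positions = [i for i, c in enumerate(original) if code.codon_to_aa[c] == aa]
            if not positions:
                continue
            targets = {c: host.relative.get(c, 0.0) for c in code.families[aa]}
            expected = allocate_codons(len(positions), targets, forbidden)
            got = {c: 0 for c in code.families[aa]}
            for i in positions:
                got[codons[i]] += 1
            assert got == expected

    def test_per_aa_deviation_within_rounding_bound(self, rng, code):
        host, rarity, _ = host_and_rarity(code)
        gene = random_cds(rng, 400, code)
        result = cl.harmonize_gene(gene, host, rarity)
        # largest-remainder rounding puts every family within one codon of target
        original = [gene.seq[i : i + 3] for i in range(0, len(gene.seq), 3)]
        fam_sizes = [
            sum(1 for c in original if code.codon_to_aa[c] == aa)
            for aa in code.degenerate_amino_acids()
        ]
        min_positions = min(n for n in fam_sizes if n > 0)
        assert result.per_aa_deviation <= 1.0 / min_positions + 1e-9

    def test_uncovered_family_rejected(self, code):
        host = cl.usage_profile(counts_from({"AAA": 10, "AAG": 2}), code)
        rarity = cl.classify_rarity(host)
        gene = cl.CdsRecord(id="g", seq="UUUAAA")
        with pytest.raises(ConfigurationError, match="cover"):
            cl.harmonize_gene(gene, host, rarity)

    def test_fully_forbidden_family_relaxed_with_warning(self, code):
        # a host whose two Cys codons are both semi-rare cannot drop Cys:
        # its most-used codon must be retained
        counts = {"UGU": 18, "UGC": 14, "AAA": 1968}
        host = cl.usage_profile(counts_from(counts), code)
        rarity = cl.classify_rarity(host)
        assert rarity.class_of["UGU"] == SEMI_RARE
        gene = cl.CdsRecord(id="g", seq="UGCUGUAAA")
        with pytest.warns(UserWarning, match="retained"):
            result = cl.harmonize_gene(gene, host, rarity)
        assert result.relaxed_families == ("C",)
        assert code.translate(result.new_seq) == code.translate(gene.seq)
        assert "UGU" in result.new_seq  # the more-used Cys codon was kept


class TestMotifAvoidance:
    def test_motif_removed_by_synonymous_swap(self, code):
        host, rarity, _ = host_and_rarity(code)
        cfg = HarmonizationConfig(forbidden_motifs=("AGAUCU",))  # BglII site
        gene = cl.CdsRecord(id="g", seq="AUG" + "AAAUUA" * 40 + "UAA")
        result = cl.harmonize_gene(gene, host, rarity, cfg)
        assert result.motif_hits_remaining == _motif_hits(
            result.new_seq, cfg.forbidden_motifs
        )
        assert code.translate(result.new_seq) == code.translate(gene.seq)

    def test_motifs_accept_dna_spelling(self):
        cfg = HarmonizationConfig(forbidden_motifs=("AGATCT",))
        assert cfg.forbidden_motifs == ("AGAUCU",)

    def test_invalid_motif_rejected(self):
        with pytest.raises(ConfigurationError):
            HarmonizationConfig(forbidden_motifs=("AG",))


class TestVerifyHarmonization:
    def test_closure_on_random_gene_host_pairs(self, rng, code):
        host, rarity, _ = host_and_rarity(code)
        for i in range(30):
            gene = random_cds(rng, int(rng.integers(30, 200)), code, f"g{i}")
            result = cl.harmonize_gene(gene, host, rarity)
            report = cl.verify_harmonization(gene, result, host, rarity)
            assert report.passed, report.as_dict()

    def test_inserted_forbidden_codon_fails_check(self, rng, code):
        host, rarity, _ = host_and_rarity(code)
        rare_codons = sorted(rarity.codons_in_class(RARE))
        if not rare_codons:
            pytest.skip("synthetic host happens to have no rare codons")
        bad = rare_codons[0]
        aa = code.codon_to_aa[bad]
        gene = random_cds(rng, 100, code)
        result = cl.harmonize_gene(gene, host, rarity)
        # replace a synonymous position with the forbidden codon
        codons = [result.new_seq[i : i + 3] for i in range(0, len(result.new_seq), 3)]
        spot = next(
            (i for i, c in enumerate(codons) if code.codon_to_aa[c] == aa), None
        )
        if spot is None:
            codons[1] = bad  # non-synonymous tamper: protein check must fail
        else:
            codons[spot] = bad
        tampered = cl.HarmonizedGene(
            original_id=result.original_id,
            new_seq="".join(codons),
            per_aa_deviation=result.per_aa_deviation,
            eliminated=result.eliminated,
            motif_hits_remaining=result.motif_hits_remaining,
        )
        report = cl.verify_harmonization(gene, tampered, host, rarity)
        assert not report.passed

    def test_non_synonymous_swap_fails_protein_identity(self, rng, code):
        host, rarity, _ = host_and_rarity(code)
        gene = random_cds(rng, 100, code)
        result = cl.harmonize_gene(gene, host, rarity)
        mutated = "AAA" + result.new_seq[3:]  # AUG start -> Lys
        tampered = cl.HarmonizedGene(
            original_id=result.original_id,
            new_seq=mutated,
            per_aa_deviation=result.per_aa_deviation,
            eliminated=result.eliminated,
            motif_hits_remaining=result.motif_hits_remaining,
        )
        report = cl.verify_harmonization(gene, tampered, host, rarity)
        assert not report.checks["protein_identity"]


def test_harmonization_improves_cai_of_at_rich_genes(code):
    """Genes biased toward AT-rich (often host-scarce) codons score higher
    after harmonization against the host model."""
    host_spec = cl.SyntheticSpec(n_genes=150, mean_length=250, seed=3)
    host_genome = cl.generate_genome(
        cl.generate_host_profile(host_spec, code), host_spec, code
    )
    host_counts = cl.aggregate(host_genome)
    host = cl.usage_profile(host_counts, code)
    rarity = cl.classify_rarity(host)
    model = cl.fit_adaptiveness(host_counts, code)

    src_spec = fungal_like_spec(seed=9, n_genes=40, mean_length=200)
    src_genome = cl.generate_genome(
        cl.generate_host_profile(src_spec, code), src_spec, code
    )
    improved = 0
    for gene in src_genome:
        result = cl.harmonize_gene(gene, host, rarity)
        new = cl.CdsRecord(id=gene.id, seq=result.new_seq)
        if cl.cai_score(new, model, code) >= cl.cai_score(gene, model, code):
            improved += 1
    assert improved == len(src_genome)
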