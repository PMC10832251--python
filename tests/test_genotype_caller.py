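"""Genotype caller: anchor location, codon classification, FASTA round trips."""

import itertools

import numpy as np
import pytest

from kdrkit.genotype_caller import (
    AmbiguousAnchorError,
    FastaInputError,
    call_all_sites,
    call_site,
    classify_codon,
    genotype_fasta,
    locate_anchor,
)
from kdrkit.reference_model import (
    Genotype,
    IUPAC_EXPANSION,
    reverse_complement,
)
from kdrkit.synthetic import (
    SimulationConfig,
    demo_truth_table,
    render_consensus,
    render_sequences,
    simulate_genotype_counts,
)

IUPAC_LETTERS = sorted(set(IUPAC_EXPANSION) - {"X"})


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# locate_anchor
# ---------------------------------------------------------------------------

class TestLocateAnchor:
    def test_exact_match_on_reference(self, model, layout):
        site = model.site("L1014F")
        m = locate_anchor(layout.cdna, site, max_mismatches=0)
        assert m.strand == "forward"
        assert m.position == layout.codon_starts["L1014F"] - 18
        assert m.mismatches == 0

    def test_reverse_complement_query_found_with_strand_flag(self, model, layout):
        site = model.site("T929I")
        fwd = locate_anchor(layout.cdna, site)
        rc = locate_anchor(reverse_complement(layout.cdna), site)
        assert rc.strand == "reverse-complement"
        # position is reported on the forward coordinates of the rc query
        assert rc.position == len(layout.cdna) - (fwd.position + 20)

    def test_bruteforce_hamming_oracle(self, model):
        """One embedded guide, optional substitution: position and count match
        a brute-force sliding-window Hamming scan."""
        site = model.site("M918T")
        guide = site.guide_sequence
        rng = np.random.default_rng(7)
        for trial in range(20):
            flank_a, flank_b = random_dna(rng, 60), random_dna(rng, 60)
            mutated = list(guide)
            n_subs = trial % 2
            if n_subs:
                i = int(rng.integers(len(guide)))
                mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
            query = flank_a + "".join(mutated) + site.wild_codon + flank_b

            # oracle: plain Hamming over every window
            best = min(
                range(len(query) - len(guide) + 1),
                key=lambda s: sum(
                    a != b for a, b in zip(guide, query[s : s + len(guide)])
                ),
            )
            hamming = sum(a != b for a, b in zip(guide, query[best : best + len(guide)]))
            if hamming > 1:
                continue  # substitution landed so the oracle itself is ambiguous

            match = locate_anchor(query, site, max_mismatches=1)
            assert match.position == best == len(flank_a)
            assert match.mismatches == hamming
            if hamming == 1:
                assert locate_anchor(query, site, max_mismatches=0) is None

    def test_no_match_returns_none(self, model):
        assert locate_anchor("ACGT" * 30, model.site("L1014F")) is None

    def test_equal_matches_raise_ambiguity_error(self, model):
        site = model.site("M918T")
        query = "TTTT" + site.guide_sequence + "GGGG" + site.guide_sequence + "AAAA"
        with pytest.raises(AmbiguousAnchorError) as exc:
            locate_anchor(query, site, max_mismatches=1)
        assert len(exc.value.positions) == 2

    def test_codon_variation_under_guide_tail_is_free(self, model):
        # the L1014F guide ends on the codon's variable base: a resistant (T),
        # susceptible (C) or het (Y) base there must not count as a mismatch
        site = model.site("L1014F")
        context = site.guide_sequence[:-1]
        for base, expect_geno in (("C", Genotype.SS), ("T", Genotype.RR), ("Y", Genotype.RS)):
            query = "GGAACCA" + context + base + "TTGTGGTAAGTTGACGAAC"
            match = locate_anchor(query, site, max_mismatches=0)
            assert match is not None and match.mismatches == 0
            assert call_site(query, site).genotype is expect_geno

    def test_input_validation(self, model):
        with pytest.raises(ValueError):
            locate_anchor("", model.sites[0])
        with pytest.raises(ValueError):
            locate_anchor("ACGT", model.sites[0], max_mismatches=-1)


# ---------------------------------------------------------------------------
# codon classification
# ---------------------------------------------------------------------------

def brute_classify(site, codon):
    """Oracle: expand the whole codon and intersect with {wild, mutant}."""
    expansions = {
        "".join(t)
        for t in itertools.product(*[sorted(IUPAC_EXPANSION[b]) for b in codon])
    }
    if expansions == {site.wild_codon}:
        return Genotype.SS
    if expansions == {site.mutant_codon}:
        return Genotype.RR
    if expansions == {site.wild_codon, site.mutant_codon}:
        return Genotype.RS
    return Genotype.INDETERMINATE


class TestClassifyCodon:
    @pytest.mark.parametrize(
        "site_name,codon,expected",
        [
            ("L1014F", "CTT", Genotype.SS),
            ("L1014F", "YTT", Genotype.RS),
            ("L1014F", "TTT", Genotype.RR),
            ("L1014H", "CWT", Genotype.RS),
            ("L1014H", "CAT", Genotype.RR),
            ("M918T", "AYG", Genotype.RS),
            ("T929I", "ATA", Genotype.RR),
            ("L1014F", "HTT", Genotype.INDETERMINATE),  # triple ambiguity: conservative
            ("L1014F", "NTT", Genotype.INDETERMINATE),
            ("L1014F", "GTT", Genotype.INDETERMINATE),  # a third allele
            ("L1014F", "CTA", Genotype.INDETERMINATE),  # non-variable position off
            ("L1014F", "CYT", Genotype.INDETERMINATE),  # ambiguity off the variable base
        ],
    )
    def test_examples(self, model, site_name, codon, expected):
        assert classify_codon(model.site(site_name), codon) is expected

    def test_full_iupac_space_matches_bruteforce(self, model):
        """Every codon over the full IUPAC alphabet agrees with the
        expansion-intersection oracle, for all four sites."""
        for site in model.sites:
            for codon in map("".join, itertools.product(IUPAC_LETTERS, repeat=3)):
                assert classify_codon(site, codon) is brute_classify(site, codon), (
                    site.name, codon,
                )


# ---------------------------------------------------------------------------
# whole-sequence calls
# ---------------------------------------------------------------------------

class TestCallAllSites:
    def test_wild_reference_is_all_SS(self, model, layout):
        rep = call_all_sites(layout.cdna, model)
        assert [c.genotype for c in rep.calls] == [Genotype.SS] * 4
        assert rep.input_kind == "cDNA"

    def test_mixed_genotypes_called_correctly(self, model):
        genotypes = {"L1014F": Genotype.RR, "T929I": Genotype.RS}
        seq = render_consensus(genotypes, model, form="cDNA")
        rep = call_all_sites(seq, model)
        assert rep.call("L1014F").genotype is Genotype.RR
        assert rep.call("T929I").genotype is Genotype.RS
        assert rep.call("M918T").genotype is Genotype.SS
        assert rep.call("L1014H").genotype is Genotype.SS

    def test_gdna_detected_and_calls_match_cdna(self, model):
        genotypes = {"M918T": Genotype.RS, "L1014H": Genotype.RR}
        cdna = render_consensus(genotypes, model, form="cDNA")
        gdna = render_consensus(genotypes, model, form="gDNA")
        rep_c = call_all_sites(cdna, model)
        rep_g = call_all_sites(gdna, model)
        assert rep_c.input_kind == "cDNA"
        assert rep_g.input_kind == "gDNA"
        assert [c.genotype for c in rep_c.calls] == [c.genotype for c in rep_g.calls]

    def test_strand_invariance_over_all_single_site_genotypes(self, model):
        for site in model.sites:
            for g in (Genotype.SS, Genotype.RS, Genotype.RR):
                seq = render_consensus({site.name: g}, model)
                fwd = call_all_sites(seq, model)
                rev = call_all_sites(reverse_complement(seq), model)
                assert [c.genotype for c in fwd.calls] == [c.genotype for c in rev.calls]
                assert fwd.call(site.name).genotype is g

    def test_site_restriction(self, model, layout):
        rep = call_all_sites(layout.cdna, model, sites=["L1014F"])
        assert [c.site_name for c in rep.calls] == ["L1014F"]

    def test_sequence_without_vssc_region_is_all_indeterminate(self, model):
        rng = np.random.default_rng(11)
        rep = call_all_sites(random_dna(rng, 300), model)
        assert all(c.genotype is Genotype.INDETERMINATE for c in rep.calls)
        assert rep.input_kind == "unknown"


class TestGenotypeFasta:
    def test_truth_table_recovered_exactly(self, model, tmp_path):
        """Noise-free synthetic flies: 100% concordance with the generator truth."""
        config = SimulationConfig(seed=42, n_individuals=20, kdr_allele_frequency=0.4)
        _counts, truth = simulate_genotype_counts(config, model)
        fasta = tmp_path / "flies.fasta"
        render_sequences(truth, model, form="cDNA", fasta_path=fasta)
        frame = genotype_fasta(fasta, model)
        for _, row in frame.iterrows():
            assert row["genotype"] == truth.genotype(row["sequence_id"], row["site"]).value

    def test_demo_fixture_round_trip(self, model, tmp_path):
        truth = demo_truth_table(model)
        fasta = tmp_path / "demo.fasta"
        render_sequences(truth, model, form="cDNA", fasta_path=fasta)
        frame = genotype_fasta(fasta, model)
        assert len(frame) == 6 * 4
        for _, row in frame.iterrows():
            assert row["genotype"] == truth.genotype(row["sequence_id"], row["site"]).value

    def test_empty_fasta_is_io_error(self, model, tmp_path):
        empty = tmp_path / "empty.fasta"
        empty.write_text("")
        with pytest.raises(FastaInputError):
            genotype_fasta(empty, model)
        with pytest.raises(FastaInputError):
            genotype_fasta(tmp_path / "missing.fasta", model)

    def test_duplicate_ids_are_suffixed_with_warning(self, model, layout, tmp_path):
        fasta = tmp_path / "dup.fasta"
        fasta.write_text(f">fly\n{layout.cdna}\n>fly\n{layout.cdna}\n")
        with pytest.warns(UserWarning, match="duplicate"):
            frame = genotype_fasta(fasta, model)
        assert set(frame["sequence_id"]) == {"fly", "fly__2"}
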