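"""The scenario generator: determinism, identity targets, ground truth."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from maltpipe.core_seq import GeneSequence, global_align, percent_identity, translate_cds
from maltpipe.io import write_fasta
from maltpipe.synthetic import (
    ConfigError,
    FamilyParams,
    ScenarioConfig,
    apply_gene_conversion,
    make_scenario,
    simulate_backcross_tetrads,
    simulate_gene_family,
    simulate_pool_counts,
)


class TestGeneFamily:
    def test_target_identity_one_gives_identical_genes(self):
        genes, ancestor = simulate_gene_family(
            FamilyParams(n_genes=3, cds_length=300, target_nt_identity=1.0, seed=1)
        )
        assert all(g.seq == ancestor.seq for g in genes)

    def test_realized_identity_within_two_points_of_target(self, small_family):
        genes, _ = small_family
        for g1, g2 in itertools.combinations(genes, 2):
            ident = percent_identity(global_align(g1, g2))
            assert 78.0 <= ident <= 82.0, (g1.id, g2.id, ident)

    def test_family_members_are_clean_cds(self, small_family):
        genes, _ = small_family
        for g in genes:
            t = translate_cds(g)
            assert t.clean and t.protein.startswith("M")

    def test_same_seed_gives_byte_identical_fasta(self, tmp_path):
        paths = []
        for run in ("a", "b"):
            genes, _ = simulate_gene_family(FamilyParams(seed=42))
            p = tmp_path / f"{run}.fasta"
            write_fasta(genes, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigError):
            FamilyParams(cds_length=100)  # not a codon multiple
        with pytest.raises(ConfigError):
            FamilyParams(target_nt_identity=0.0)


class TestGeneConversion:
    def test_whole_gene_tract_yields_donor(self, small_family):
        genes, _ = small_family
        out = apply_gene_conversion(genes[0], genes[1], (1, len(genes[0].seq)))
        assert out.seq == genes[1].seq

    def test_length_one_tract_changes_at_most_one_site(self, small_family):
        genes, _ = small_family
        out = apply_gene_conversion(genes[0], genes[1], (10, 10))
        diffs = [i for i, (x, y) in enumerate(zip(out.seq, genes[0].seq)) if x != y]
        assert diffs in ([], [9])

    @given(start=st.integers(1, 1600), length=st.integers(1, 240))
    def test_diffs_confined_to_tract(self, start, length, small_family):
        genes, _ = small_family
        recipient, donor = genes[0], genes[1]
        end = min(start + length - 1, len(recipient.seq))
        out = apply_gene_conversion(recipient, donor, (start, end))
        for i in range(len(out.seq)):
            if start - 1 <= i <= end - 1:
                assert out.seq[i] == donor.seq[i]
            else:
                assert out.seq[i] == recipient.seq[i]

    def test_idempotent_for_fixed_tract(self, small_family):
        genes, _ = small_family
        once = apply_gene_conversion(genes[0], genes[1], (50, 120))
        twice = apply_gene_conversion(once, genes[1], (50, 120))
        assert once.seq == twice.seq

    def test_out_of_bounds_tract_rejected(self, small_family):
        genes, _ = small_family
        from maltpipe.core_seq import InputError

        with pytest.raises(InputError):
            apply_gene_conversion(genes[0], genes[1], (0, 10))


class TestBackcrossTetrads:
    def test_fifteen_tetrads_give_thirty_thirty(self):
        table, _ = simulate_backcross_tetrads(15, 10, causal_index=0, seed=1)
        spores = table[[f"spore{i}" for i in range(1, 5)]].to_numpy().ravel()
        assert (spores == "positive").sum() == 30
        assert (spores == "negative").sum() == 30

    def test_single_tetrad_always_two_two(self):
        for seed in range(20):
            table, _ = simulate_backcross_tetrads(1, 3, causal_index=1, seed=seed)
            spores = table.iloc[0][["spore1", "spore2", "spore3", "spore4"]]
            assert sorted(spores) == ["negative", "negative", "positive", "positive"]

    def test_every_marker_segregates_two_two_within_tetrads(self):
        _, genotypes = simulate_backcross_tetrads(50, 8, causal_index=2, seed=5)
        assert (genotypes.sum(axis=1) == 2).all()

    def test_unlinked_marker_uncorrelated_with_phenotype(self):
        table, genotypes = simulate_backcross_tetrads(
            1000, 5, causal_index=0, seed=8
        )
        flat = genotypes.reshape(-1, 5)
        pheno = flat[:, 0]
        r = np.corrcoef(pheno, flat[:, 3])[0, 1]
        assert abs(r) < 0.1


class TestPoolCounts:
    def test_pure_pool_no_error_gives_all_alt_reads(self):
        geno = np.ones((30, 5), dtype=np.int8)
        pc = simulate_pool_counts(
            geno, np.zeros((30, 5), dtype=np.int8),
            positions=np.arange(1, 6) * 100, contig="chrI",
            coverage=50, error_rate=0.0, seed=1,
        )
        assert (pc.df["pos_ref"] == 0).all()
        assert (pc.df["neg_alt"] == 0).all()

    def test_half_frequency_concentrates_at_high_depth(self):
        geno = np.zeros((30, 4), dtype=np.int8)
        geno[:15] = 1
        pc = simulate_pool_counts(
            geno, geno.copy(), positions=np.arange(1, 5) * 100, contig="chrI",
            coverage=10_000, error_rate=0.0, seed=2,
        )
        freq = pc.df["pos_alt"] / (pc.df["pos_alt"] + pc.df["pos_ref"])
        assert np.allclose(freq, 0.5, atol=0.02)

    def test_same_seed_identical_table(self):
        geno = np.ones((10, 3), dtype=np.int8)
        kwargs = dict(
            positions=np.arange(1, 4) * 10, contig="chrI",
            coverage=30, error_rate=0.01, seed=9,
        )
        a = simulate_pool_counts(geno, geno, **kwargs)
        b = simulate_pool_counts(geno, geno, **kwargs)
        assert a.df.equals(b.df)

    def test_nonpositive_coverage_rejected(self):
        geno = np.ones((2, 2), dtype=np.int8)
        with pytest.raises(ConfigError):
            simulate_pool_counts(
                geno, geno, positions=np.array([1, 2]), contig="c", coverage=0
            )


class TestScenario:
    def test_default_scenario_truth_is_self_consistent(self):
        s = make_scenario(seed=21)
        assert s.truth.conversion is not None
        lo, hi = s.truth.conversion.tract
        recipient = next(g for g in s.panel if g.id == s.truth.conversion.recipient_id)
        donor = next(g for g in s.panel if g.id == s.truth.conversion.donor_id)
        assert s.candidate.seq[lo - 1 : hi] == donor.seq[lo - 1 : hi]
        assert s.candidate.seq[: lo - 1] == recipient.seq[: lo - 1]
        pos = s.truth.marker_positions[s.truth.causal_marker_index]
        assert s.truth.causal_window[0] <= pos <= s.truth.causal_window[1]

    def test_null_scenario_has_no_tract_on_candidate(self):
        from maltpipe.chimera import scan_gene_family

        s = make_scenario(ScenarioConfig(causal=False), seed=22)
        assert s.truth.conversion is None
        report = scan_gene_family(s.candidate, s.panel)
        assert report.tracts == ()

    def test_emitted_files_reproducible_per_seed(self, tmp_path):
        for d in ("one", "two"):
            make_scenario(seed=33, out_dir=tmp_path / d)
        for name in ("candidate.fasta", "panel.fasta", "tetrads.tsv",
                     "pool_counts.tsv", "truth.json"):
            assert (tmp_path / "one" / name).read_bytes() == (
                tmp_path / "two" / name
            ).read_bytes(), name
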