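"""Ground-truth fidelity and determinism of the synthetic-data generators."""
import numpy as np
import pytest

from relict import synthetic_data as sd
from relict.io import read_vcf_calls
from relict.te_landscape import k2p
from relict.variant_filters import HET


class TestGenomeSpecValidation:
    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            sd.GenomeSpec(theta=1.0)
        with pytest.raises(ValueError):
            sd.GenomeSpec(theta=0.001, theta_hemi=0.002)
        with pytest.raises(ValueError):
            sd.GenomeSpec(contig_length_bp=0)
        with pytest.raises(ValueError):
            sd.GenomeSpec(hemi_depth_multiplier=1.5)


class TestGenDiploidGenome:
    def test_theta_zero_plants_no_het(self):
        spec = sd.GenomeSpec(n_autosomal_contigs=2, n_hemizygous_contigs=0,
                             contig_length_bp=50_000, theta=0.0, theta_hemi=0.0, seed=2)
        truth = sd.gen_diploid_genome(spec)
        assert all(c.het_pos.size == 0 for c in truth.contigs)
        assert all(truth.hap1[n] == truth.hap2[n] for n in truth.hap1)

    def test_planted_het_count_binomial(self):
        """theta=0.005 over 1 Mb of non-repeat sequence: 5,000 +- 3 SD."""
        spec = sd.GenomeSpec(n_autosomal_contigs=2, n_hemizygous_contigs=0,
                             contig_length_bp=500_000, theta=0.005,
                             repeat_fraction=0.0, seed=3)
        truth = sd.gen_diploid_genome(spec)
        n_het = sum(c.het_pos.size for c in truth.contigs)
        sd3 = 3 * np.sqrt(1e6 * 0.005 * 0.995)
        assert abs(n_het - 5000) < sd3

    def test_hemizygous_depth_is_multiplier_times_autosomal(self):
        spec = sd.GenomeSpec(n_autosomal_contigs=1, n_hemizygous_contigs=1,
                             contig_length_bp=50_000,
                             gc_by_contig=[0.35, 0.35],
                             depth_intercept=20.0, depth_slope=97.142857,
                             depth_noise_sd=0.0, seed=4)
        truth = sd.gen_diploid_genome(spec)
        auto, hemi = truth.contigs
        assert auto.expected_depth == pytest.approx(54.0)
        assert hemi.expected_depth == pytest.approx(27.0)

    def test_het_avoids_repeats_and_haplotypes_differ_at_planted_sites(self, small_genome):
        for c in small_genome.contigs:
            h1 = small_genome.hap1[c.name]
            h2 = small_genome.hap2[c.name]
            for s, e in c.repeats:
                assert not ((c.het_pos >= s) & (c.het_pos < e)).any()
            diffs = np.array([i for i, (a, b) in enumerate(zip(h1, h2)) if a != b])
            assert np.array_equal(diffs, c.het_pos)

    def test_truth_files_round_trip(self, small_genome, tmp_path):
        paths = sd.write_genome(small_genome, tmp_path)
        calls = read_vcf_calls(paths["truth_vcf"])
        assert len(calls) == sum(c.het_pos.size for c in small_genome.contigs)
        from relict.io import read_bed, read_depth_track, read_fasta
        assert len(read_bed(paths["repeats"])) == len(small_genome.repeat_bed)
        assert read_fasta(paths["hap1"]) == small_genome.hap1
        track = read_depth_track(paths["depth"])
        assert len(track) == len(small_genome.depth_track)


class TestEmitVcf:
    def test_no_artifacts_records_equal_planted(self, small_genome, tmp_path):
        sidecar = sd.emit_vcf(small_genome, "illumina", tmp_path / "i.vcf")
        calls = read_vcf_calls(tmp_path / "i.vcf")
        assert sidecar.empty
        assert len(calls) == sum(c.het_pos.size for c in small_genome.contigs)
        assert all(c.genotype == HET for c in calls)

    def test_low_depth_artifact_flagged(self, small_genome, tmp_path):
        sidecar = sd.emit_vcf(small_genome, "illumina", tmp_path / "i.vcf", n_low_dp=1)
        assert list(sidecar["flag"]) == ["should_be_filtered"]
        calls = read_vcf_calls(tmp_path / "i.vcf")
        flagged = {(r.contig, r.pos) for r in sidecar.itertuples(index=False)}
        bad = [c for c in calls if (c.contig, c.pos) in flagged]
        assert bad[0].depth == 14

    def test_unbalanced_artifact_flagged_ont(self, small_genome, tmp_path):
        sidecar = sd.emit_vcf(small_genome, "ont", tmp_path / "o.vcf", n_unbalanced=1)
        assert list(sidecar["flag"]) == ["should_not_be_het"]
        calls = read_vcf_calls(tmp_path / "o.vcf")
        flagged = {(r.contig, r.pos) for r in sidecar.itertuples(index=False)}
        bad = [c for c in calls if (c.contig, c.pos) in flagged]
        assert bad[0].alt_fraction is not None and bad[0].alt_fraction < 0.20

    def test_unknown_platform(self, small_genome, tmp_path):
        with pytest.raises(ValueError, match="platform"):
            sd.emit_vcf(small_genome, "pacbio", tmp_path / "p.vcf")

    def test_unbalanced_requires_ont(self, small_genome, tmp_path):
        with pytest.raises(ValueError, match="allele-balance"):
            sd.emit_vcf(small_genome, "illumina", tmp_path / "i.vcf", n_unbalanced=1)


class TestGenTECopies:
    def _spec(self, te_consensus, copies):
        fam = sd.TEFamily("rnd-1_family-12", "LINE", te_consensus)
        return sd.TESimSpec(families=[fam], copies=copies, seed=5)

    def test_target_zero_copy_identical(self, te_consensus):
        spec = self._spec(te_consensus, [sd.TECopySpec("rnd-1_family-12", 0.0, 400)])
        records, _, truth = sd.gen_te_copies(spec, {"ctg001": 10_000})
        assert records[0].copy_seq == records[0].cons_seq
        assert truth["realized_divergence"].iloc[0] == 0.0

    def test_realized_divergence_within_tolerance(self, te_consensus):
        spec = self._spec(te_consensus, [sd.TECopySpec("rnd-1_family-12", 0.10, 1000)])
        records, _, truth = sd.gen_te_copies(spec, {"ctg001": 10_000})
        realized = truth["realized_divergence"].iloc[0]
        assert abs(realized - 0.10) < 0.01
        # truth value equals an independent recomputation on the emitted pair
        assert k2p(records[0].copy_seq, records[0].cons_seq).d == pytest.approx(realized)

    def test_bed_length_conservation(self, te_consensus):
        copies = [sd.TECopySpec("rnd-1_family-12", 0.05, n) for n in (100, 200, 300)]
        spec = self._spec(te_consensus, copies)
        _, bed, _ = sd.gen_te_copies(spec, {"ctg001": 10_000})
        assert int((bed["end"] - bed["start"]).sum()) == 600

    def test_target_beyond_horizon_rejected(self):
        with pytest.raises(ValueError, match="0.5"):
            sd.TECopySpec("f", 0.6, 100)

    def test_non_acgt_consensus_rejected(self):
        with pytest.raises(ValueError, match="ACGT"):
            sd.TEFamily("f", "LINE", "ACGTN")


class TestGenOrthologAlignments:
    def test_zero_length_branches_identical_sequences(self, rng):
        genes = sd.gen_ortholog_alignments("(A:0.0,B:0.0);", n_genes=3,
                                           codons_per_gene=50, rng=rng)
        for gene in genes.values():
            assert gene["A"] == gene["B"]

    def test_expected_third_position_distance(self, rng):
        """Total path 0.28 -> median third-position K80 within 10%."""
        from relict.divergence_clock import species_matrix
        genes = sd.gen_ortholog_alignments("(A:0.14,B:0.14);", n_genes=100,
                                           codons_per_gene=200, rng=rng)
        m = species_matrix(genes)
        assert m.matrix.loc["A", "B"] == pytest.approx(0.28, rel=0.10)

    def test_invalid_n_genes(self):
        with pytest.raises(ValueError):
            sd.gen_ortholog_alignments("(A:0.1,B:0.1);", n_genes=0)


class TestCoalescent:
    def test_constant_ne_expectation(self):
        """E[H] = 4*Ne*mu; realized within 3 analytic SE."""
        spec = sd.CoalescentSpec(epochs=[(0, 250_000)], mu=1.3e-9,
                                 seq_length_bp=5_000_000, n_segments=500, seed=6)
        result = sd.simulate_pairwise_coalescent(spec)
        expected = 4 * 250_000 * 1.3e-9
        seg_len = result.segment_length
        m = 2 * 2 * 250_000 * 1.3e-9 * seg_len
        var_per_seg = m + (2 * 1.3e-9 * seg_len * 2 * 250_000) ** 2
        se = np.sqrt(spec.n_segments * var_per_seg) / result.total_length
        assert abs(result.het_rate - expected) < 3 * se

    def test_tiny_ne_limit_no_het(self):
        spec = sd.CoalescentSpec(epochs=[(0, 1e-6)], mu=1.3e-9,
                                 seq_length_bp=100_000, n_segments=10, seed=7)
        result = sd.simulate_pairwise_coalescent(spec)
        assert result.het_positions.size == 0

    def test_decline_scenario_has_older_tmrca(self):
        """Population decline (large ancestral Ne) vs constant recent Ne."""
        const = sd.CoalescentSpec(epochs=[(0, 50_000)], seq_length_bp=1_000_000,
                                  n_segments=200, seed=8)
        decline = sd.CoalescentSpec(epochs=[(0, 50_000), (100_000, 2_000_000)],
                                    seq_length_bp=1_000_000, n_segments=200, seed=8)
        t_const = sd.simulate_pairwise_coalescent(const).tmrca.mean()
        t_decl = sd.simulate_pairwise_coalescent(decline).tmrca.mean()
        assert t_decl > t_const

    def test_epoch_validation(self):
        with pytest.raises(ValueError):
            sd.CoalescentSpec(epochs=[])
        with pytest.raises(ValueError):
            sd.CoalescentSpec(epochs=[(10, 1000)])
        with pytest.raises(ValueError):
            sd.CoalescentSpec(epochs=[(0, 1000), (0, 500)])
        with pytest.raises(ValueError):
            sd.CoalescentSpec(epochs=[(0, -5)])


class TestDeterminism:
    def test_fixed_seed_byte_identical_outputs(self, tmp_path, te_consensus):
        spec = sd.GenomeSpec(n_autosomal_contigs=1, n_hemizygous_contigs=1,
                             contig_length_bp=30_000, seed=11)
        for run in ("a", "b"):
            d = tmp_path / run
            truth = sd.gen_diploid_genome(spec)
            sd.write_genome(truth, d)
            sd.emit_vcf(truth, "ont", d / "ont.vcf", n_low_dp=2)
            tspec = sd.TESimSpec(
                families=[sd.TEFamily("f1", "LINE", te_consensus)],
                copies=[sd.TECopySpec("f1", 0.1, 500)], seed=12,
            )
            recs, _, _ = sd.gen_te_copies(tspec, truth)
            sd.write_te_align(recs, d / "x.align")
        for name in ("hap1.fa", "truth.vcf", "depth.tsv", "ont.vcf", "x.align"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


class TestGenCodingPairs:
    def test_pairs_are_in_frame_and_mostly_identical(self, rng):
        genes = sd.gen_coding_pairs(500, rng, het_syn_rate=0.01)
        a, b = genes[0]
        assert len(a) == len(b) == 1500
        mismatches = sum(x != y for x, y in zip(a, b))
        assert mismatches < 25

    def test_rates_scale_with_parameters(self, rng):
        low = sum(
            sum(x != y for x, y in zip(*g))
            for g in sd.gen_coding_pairs(20_000, rng, het_syn_rate=0.01)
        )
        high = sum(
            sum(x != y for x, y in zip(*g))
            for g in sd.gen_coding_pairs(20_000, rng, het_syn_rate=0.1)
        )
        assert high > 5 * low
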