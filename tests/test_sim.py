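"""Synthetic-study generator: determinism, SNP density, count model."""

import numpy as np
import pytest

from hybridase.motif_bind import gomer_pbound
from hybridase.seqmap import UNINFORMATIVE, classify_read, pair_alleles
from hybridase.sim import (PlantSpec, SimConfig, SimConfigError, plant_motifs,
                           random_motif, simulate_counts, simulate_reads,
                           simulate_strains, simulate_study, write_strain_fastas,
                           read_strain_fastas)


def count_diffs(a, b):
    return sum(1 for x, y in zip(a, b) if x != y)


class TestSimulateStrains:
    def test_zero_snp_rate_identical_strains(self):
        cfg = SimConfig(n_genes=5, snp_rate=0.0, seed=1)
        seqs, _ = simulate_strains(cfg)
        for g in cfg.genes:
            proms = {seqs[s][g]["promoter"] for s in cfg.strains}
            assert len(proms) == 1

    def test_same_seed_byte_identical_fasta(self, tmp_path):
        for d in ("a", "b"):
            cfg = SimConfig(n_genes=20, frac_cis=0.2, seed=9)
            study = simulate_study(cfg)
            write_strain_fastas(study.sequences, tmp_path / d)
        for s in ("S1", "S2", "S3", "S4"):
            assert (tmp_path / "a" / f"{s}.fasta").read_bytes() == \
                   (tmp_path / "b" / f"{s}.fasta").read_bytes()

    def test_pairwise_snp_density_matches_rate(self):
        cfg = SimConfig(n_genes=1000, promoter_len=200, orf_len=10, snp_rate=0.005, seed=3)
        seqs, _ = simulate_strains(cfg)
        diffs = [count_diffs(seqs["S1"][g]["promoter"], seqs["S2"][g]["promoter"])
                 for g in cfg.genes]
        n_bp = 1000 * 200
        expected = 0.005 * 200
        se = np.sqrt(0.005 * 0.995 * n_bp) / 1000
        assert abs(np.mean(diffs) - expected) < 3 * se

    def test_equal_lengths_substitution_only(self):
        cfg = SimConfig(n_genes=10, seed=4)
        seqs, _ = simulate_strains(cfg)
        for g in cfg.genes:
            lens = {len(seqs[s][g]["orf"]) for s in cfg.strains}
            assert lens == {cfg.orf_len}

    def test_invalid_config_rejected(self):
        with pytest.raises(SimConfigError):
            SimConfig(n_genes=0)
        with pytest.raises(SimConfigError):
            SimConfig(n_genes=5, dispersion=-1)

    def test_fasta_round_trip(self, tmp_path):
        cfg = SimConfig(n_genes=6, seed=2)
        seqs, _ = simulate_strains(cfg)
        write_strain_fastas(seqs, tmp_path)
        back = read_strain_fastas([tmp_path / f"{s}.fasta" for s in cfg.strains])
        assert back == seqs


class TestPlantMotifs:
    def test_no_disruption_identical_sites_everywhere(self):
        cfg = SimConfig(n_genes=10, snp_rate=0.0, seed=5)
        seqs, truth = simulate_strains(cfg)
        motif = random_motif("tf", 8, np.random.default_rng(0))
        plant_motifs(seqs, motif, cfg.genes[:4], truth, seed=5)
        for g in cfg.genes[:4]:
            off = truth.plant_offsets["tf"][g]
            sites = {seqs[s][g]["promoter"][off:off + 8] for s in cfg.strains}
            assert sites == {motif.consensus()}

    def test_disrupted_allele_binds_less(self):
        cfg = SimConfig(n_genes=10, snp_rate=0.0, seed=6)
        seqs, truth = simulate_strains(cfg)
        motif = random_motif("tf", 8, np.random.default_rng(1), sharpness=0.9)
        plant_motifs(seqs, motif, cfg.genes[:5], truth, disrupt_in_strain="S2", seed=6)
        for g in cfg.genes[:5]:
            intact = gomer_pbound(motif, seqs["S1"][g]["promoter"])
            broken = gomer_pbound(motif, seqs["S2"][g]["promoter"])
            assert intact > broken
        assert not truth.intact["tf"]["S2"].any()
        assert truth.intact["tf"]["S1"].all()

    def test_planted_site_recoverable_by_argmax_scan(self):
        cfg = SimConfig(n_genes=3, promoter_len=200, snp_rate=0.0, seed=7)
        seqs, truth = simulate_strains(cfg)
        motif = random_motif("tf", 8, np.random.default_rng(2), sharpness=0.95)
        plant_motifs(seqs, motif, cfg.genes, truth, seed=7)
        from hybridase.motif_bind import site_probabilities
        for g in cfg.genes:
            sp = site_probabilities(motif, seqs["S1"][g]["promoter"])
            best = int(np.argmax(sp["+"]))
            assert best == truth.plant_offsets["tf"][g]

    def test_motif_longer_than_promoter_rejected(self):
        cfg = SimConfig(n_genes=2, promoter_len=5, seed=8)
        seqs, truth = simulate_strains(cfg)
        motif = random_motif("tf", 8, np.random.default_rng(3))
        with pytest.raises(ValueError, match="longer"):
            plant_motifs(seqs, motif, cfg.genes[:1], truth, seed=8)


class TestSimulateCounts:
    def test_cis_effect_doubles_allele_ratio(self):
        cfg = SimConfig(n_genes=400, n_strains=2, n_replicates=10, dispersion=0.01,
                        frac_cis=1.0, cis_log2_effect=1.0, seed=10,
                        library_size_range=(80_000.0, 80_000.0))
        _, truth = simulate_strains(cfg)
        table = simulate_counts(truth, cfg)
        m1 = table.counts["S1xS2"]["S1"].mean(axis=1)
        m2 = table.counts["S1xS2"]["S2"].mean(axis=1)
        eff = np.array([truth.cis_effect(g, "S1", "S2") for g in truth.genes])
        ratio = np.log2((m1 + 0.5) / (m2 + 0.5))
        assert abs(np.mean(ratio[eff > 0]) - 1.0) < 0.1
        assert abs(np.mean(ratio[eff < 0]) + 1.0) < 0.1

    def test_poisson_limit_variance_equals_mean(self):
        cfg = SimConfig(n_genes=2000, n_strains=2, n_replicates=3, dispersion=0.0,
                        baseline_sigma=0.0, seed=11,
                        library_size_range=(400_000.0, 400_000.0))
        _, truth = simulate_strains(cfg)
        table = simulate_counts(truth, cfg)
        col = table.counts["S1xS2"]["S1"]
        # across genes with equal means, dispersion index should be ~1
        vals = col.to_numpy().ravel()
        assert abs(vals.var() / vals.mean() - 1.0) < 0.1

    def test_column_sums_within_library_range(self):
        cfg = SimConfig(n_genes=500, seed=12)
        study = simulate_study(cfg)
        lo, hi = 0.9 * 500 * 200, 1.1 * 500 * 200
        sums = study.table.counts.sum(axis=0)
        assert ((sums > lo * 0.95) & (sums < hi * 1.05)).all()

    def test_determinism(self):
        cfg = SimConfig(n_genes=50, frac_cis=0.3, seed=13)
        t1 = simulate_study(cfg).table.counts
        t2 = simulate_study(cfg).table.counts
        assert t1.equals(t2)


class TestSimulateReads:
    def setup_method(self):
        self.cfg = SimConfig(n_genes=10, n_strains=2, orf_len=300, seed=14)
        self.seqs, self.truth = simulate_strains(self.cfg)
        self.pairs = {}
        for g in self.truth.genes:
            self.pairs.update(pair_alleles({g: self.seqs["S1"][g]},
                                           {g: self.seqs["S2"][g]}, ("S1", "S2")))

    def test_error_free_reads_recover_allele(self):
        reads = simulate_reads(self.seqs, {g: {"S1": 20, "S2": 20} for g in self.truth.genes},
                               read_len=100, error_rate=0.0, seed=2)
        wrong = informative = 0
        for _, row in reads.iterrows():
            got = classify_read(row["read"], self.pairs[row["gene"]])
            if got != UNINFORMATIVE:
                informative += 1
                wrong += got != row["allele"]
        assert informative > 0 and wrong == 0

    def test_identical_alleles_all_uninformative(self):
        cfg = SimConfig(n_genes=3, n_strains=2, snp_rate=0.0, orf_len=200, seed=15)
        seqs, truth = simulate_strains(cfg)
        pairs = {}
        for g in truth.genes:
            pairs.update(pair_alleles({g: seqs["S1"][g]}, {g: seqs["S2"][g]}, ("S1", "S2")))
        reads = simulate_reads(seqs, {g: {"S1": 5} for g in truth.genes},
                               read_len=80, seed=3)
        assert all(classify_read(r, pairs[g]) == UNINFORMATIVE
                   for g, r in zip(reads["gene"], reads["read"]))

    def test_low_error_rate_low_misclassification(self):
        reads = simulate_reads(self.seqs, {g: {"S1": 250, "S2": 250} for g in self.truth.genes},
                               read_len=100, error_rate=0.01, seed=4)
        wrong = informative = 0
        for _, row in reads.iterrows():
            got = classify_read(row["read"], self.pairs[row["gene"]])
            if got != UNINFORMATIVE:
                informative += 1
                wrong += got != row["allele"]
        assert informative > 500
        assert wrong / informative < 0.01

    def test_read_longer_than_orf_rejected(self):
        with pytest.raises(ValueError):
            simulate_reads(self.seqs, {self.truth.genes[0]: {"S1": 1}},
                           read_len=400, seed=5)
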