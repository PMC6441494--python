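import json

import numpy as np
import pytest

from cico import mirna_seeds
from cico.io_formats import GenomicInterval
from cico.synthetic_data import (
    SimConfig,
    correlated_rpkm_pairs,
    generate_conservation_track,
    generate_dataset,
    largest_remainder,
    plant_seed_sites,
)


class TestLargestRemainder:
    def test_class_mix_realized_exactly(self):
        out = largest_remainder(100, {"genic_exonic": 0.97, "other": 0.03})
        assert out == {"genic_exonic": 97, "other": 3}

    def test_total_preserved(self):
        out = largest_remainder(150, {"a": 0.97, "b": 0.01, "c": 0.01, "d": 0.01})
        assert sum(out.values()) == 150 and out["a"] == 146


class TestDeterminism:
    def test_same_seed_identical_manifest(self):
        config = SimConfig(n_chroms=1, chrom_length=120_000, n_genes=30,
                           n_circ=12, library_size=5_000, n_mirnas=4,
                           n_seed_circs=2, n_orf_circs=2)
        a = generate_dataset(config, seed=3)
        b = generate_dataset(config, seed=3)
        assert json.dumps(a.manifest, sort_keys=True) == \
            json.dumps(b.manifest, sort_keys=True)
        assert a.genome == b.genome
        assert a.reads["PP_1"] == b.reads["PP_1"]

    def test_different_seed_differs(self):
        config = SimConfig(n_chroms=1, chrom_length=120_000, n_genes=30,
                           n_circ=12, library_size=5_000, n_mirnas=4,
                           n_seed_circs=2, n_orf_circs=2)
        a = generate_dataset(config, seed=3)
        b = generate_dataset(config, seed=4)
        assert a.genome != b.genome


class TestManifestConsistency:
    def test_class_counts_match_config_mix(self, small_bundle):
        counts = small_bundle.manifest["class_counts"]
        assert sum(counts.values()) == small_bundle.config.n_circ
        expected = largest_remainder(small_bundle.config.n_circ,
                                     small_bundle.config.class_mix)
        assert counts == expected

    def test_trajectory_labels_consistent_with_thresholds(self, small_bundle):
        """Planted labels re-derive from planted per-population RPKM."""
        from cico.diffexpr import classify_trajectory
        for info in small_bundle.manifest["circs"].values():
            if not info["expressed"]:
                assert info["trajectory"] is None
                continue
            r = info["rpkm"]
            pops = list(small_bundle.config.populations)
            fc1 = (r[pops[1]] + 1e-9) / (r[pops[0]] + 1e-9)
            fc2 = (r[pops[2]] + 1e-9) / (r[pops[1]] + 1e-9)
            assert classify_trajectory(fc1, fc2) == info["trajectory"]

    def test_library_sizes_are_exact(self, small_bundle):
        for sample, reads in small_bundle.reads.items():
            assert len(reads) == small_bundle.config.library_size


class TestPlantSeedSites:
    MIRNA = "UGAGGUAGUAGGUUGUAUAGUU"

    def seq(self, n=400, seed=5):
        rng = np.random.default_rng(seed)
        return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

    def test_zero_sites_unchanged(self):
        s = self.seq()
        assert plant_seed_sites(s, self.MIRNA, 0) == s

    @pytest.mark.parametrize("category", ["8mer", "7mer-m8", "7mer-A1", "6mer"])
    def test_exact_site_counts_by_construction(self, category, rng):
        edited = plant_seed_sites(self.seq(), self.MIRNA, 3, category=category,
                                  rng=rng)
        matches = mirna_seeds.scan(edited, self.MIRNA, circular=True)
        assert len(matches) == 3
        assert all(m.category == category for m in matches)

    def test_junction_spanning_site(self, rng):
        edited = plant_seed_sites(self.seq(), self.MIRNA, 2, category="8mer",
                                  rng=rng, junction_site=True)
        matches = mirna_seeds.scan(edited, self.MIRNA, circular=True)
        assert len(matches) == 2
        assert any(m.start == len(edited) - 3 for m in matches)

    def test_over_capacity_rejected(self, rng):
        with pytest.raises(ValueError, match="cannot place"):
            plant_seed_sites(self.seq(n=60), self.MIRNA, 10, rng=rng)


class TestConservationTrackGenerator:
    def test_no_noise_no_elevation_is_constant(self):
        track = generate_conservation_track(
            {"chr1": 2000}, [], elevation=0.0, base_level=0.3, noise_sd=0.0,
            seed=0)
        mean, n = track.mean("chr1", 0, 2000)
        assert mean == pytest.approx(0.3) and n == 2000

    def test_planted_interval_mean_within_clt_bound(self):
        iv = GenomicInterval("chr1", 500, 1500)
        track = generate_conservation_track(
            {"chr1": 3000}, [iv], elevation=0.5, base_level=0.1, noise_sd=0.2,
            seed=42)
        mean, _ = track.mean("chr1", 500, 1500)
        assert abs(mean - 0.6) < 3 * 0.2 / np.sqrt(1000)

    def test_masked_span_carries_no_score(self):
        track = generate_conservation_track(
            {"chr1": 2000}, [], elevation=0.0, base_level=0.0, noise_sd=0.1,
            seed=0, masked_intervals=[GenomicInterval("chr1", 0, 100)])
        _, n = track.mean("chr1", 0, 100)
        assert n == 0


def test_correlated_pairs_target_rho():
    x, y = correlated_rpkm_pairs(1000, rho=0.8, seed=1)
    r = np.corrcoef(np.log2(x), np.log2(y))[0, 1]
    assert abs(r - 0.8) < 0.05


def test_planted_rpkm_inverts_rpkm_formula(small_bundle):
    """Planted RPKM, library size and exonic length reproduce the planted
    count through the RPKM definition."""
    lib = small_bundle.config.library_size
    circs = {c.circ_id: c for c in small_bundle.truth_circs}
    pops = small_bundle.config.populations
    n_checked = 0
    for circ_id, info in small_bundle.manifest["circs"].items():
        if not info["expressed"]:
            continue
        length = sum(e - s for s, e in info["exons"])
        # noiseless bundle: count implied by RPKM must be a whole number
        for pop in pops:
            implied = info["rpkm"][pop] * (lib * 1e-6) * (length * 1e-3)
            assert implied == pytest.approx(round(implied), abs=1e-6)
        n_checked += 1
    assert n_checked > 0
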