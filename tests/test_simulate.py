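import json

import numpy as np
import pytest

from sweepscan.fst_stats import allele_freq_matrix, wc_theta_sites
from sweepscan.haplo_io import load_panel
from sweepscan.simulate import (
    SweepSimConfig,
    gen_island_snp_panel,
    gen_sweep_panel,
    write_fixture_set,
)


def ratio_of_sums_theta(panel):
    P, n = allele_freq_matrix(panel, panel.populations)
    a, b = wc_theta_sites(P, n)
    return a.sum() / (a + b).sum()


class TestIslandPanel:
    def test_target_fst_recovered(self):
        panel = gen_island_snp_panel(4, 100, 0.10, 1000, seed=1)
        assert 0.08 <= ratio_of_sums_theta(panel) <= 0.12

    def test_panmixia_limit(self):
        panel = gen_island_snp_panel(4, 100, 1e-6, 500, seed=2)
        assert abs(ratio_of_sums_theta(panel)) <= 0.01

    def test_deterministic_under_seed(self):
        p1 = gen_island_snp_panel(3, 20, 0.2, 50, seed=9)
        p2 = gen_island_snp_panel(3, 20, 0.2, 50, seed=9)
        np.testing.assert_array_equal(p1.haplotypes, p2.haplotypes)
        assert [s.site_id for s in p1.sites] == [s.site_id for s in p2.sites]

    def test_per_site_theta_distribution_centred_on_target(self):
        # the ratio-of-sums estimate is the generator's calibration contract;
        # the per-site ratio distribution is right-skewed, so its median sits
        # below the target while the mean matches
        panel = gen_island_snp_panel(4, 100, 0.10, 5000, seed=3)
        P, n = allele_freq_matrix(panel, panel.populations)
        a, b = wc_theta_sites(P, n)
        tot = a + b
        theta = a[tot != 0] / tot[tot != 0]
        assert abs(theta.mean() - 0.10) <= 0.02
        assert 0.05 <= np.median(theta) <= 0.12

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            gen_island_snp_panel(4, 100, 1.5, 100)
        with pytest.raises(ValueError):
            gen_island_snp_panel(1, 100, 0.1, 100)


def small_cfg(**kw):
    base = dict(n_demes=1, deme_size_N=200, n_sites=80, region_bp=400_000,
                n_generations=50, sample_per_deme=40, migration_m=0.0,
                init_sweep_freq_f0=0.2, seed=0)
    base.update(kw)
    return SweepSimConfig(**base)


class TestSweepPanel:
    def test_neutral_drift_is_a_martingale(self):
        """With s = 0 the sweep-site frequency is a drift martingale: the mean
        final frequency across replicates stays at f0 (within 3 SE)."""
        finals = []
        for seed in range(40):
            _, _, truth = gen_sweep_panel(small_cfg(sel_coefficient_s=0.0, seed=seed))
            finals.append(truth.final_sweep_freq[0])
        finals = np.array(finals)
        se = finals.std(ddof=1) / np.sqrt(len(finals))
        assert abs(finals.mean() - 0.2) <= 3 * se + 1e-9

    def test_selection_drives_frequency_up(self):
        """s=0.05 over 200 generations from f0=0.05: logistic growth clears 0.5."""
        finals = []
        for seed in range(12):
            cfg = SweepSimConfig(n_demes=1, deme_size_N=1000, n_sites=60,
                                 region_bp=300_000, n_generations=200,
                                 sample_per_deme=40, migration_m=0.0,
                                 sel_coefficient_s=0.05, init_sweep_freq_f0=0.05,
                                 seed=seed)
            _, _, truth = gen_sweep_panel(cfg)
            finals.append(truth.final_sweep_freq[0])
        assert np.mean(finals) > 0.5

    def test_final_frequency_monotone_in_s(self):
        means = []
        for s in (0.0, 0.05, 0.15):
            finals = [
                gen_sweep_panel(small_cfg(sel_coefficient_s=s, seed=seed))[2]
                .final_sweep_freq[0]
                for seed in range(10)
            ]
            means.append(np.mean(finals))
        assert means[0] < means[1] < means[2]

    def test_sweep_core_haplotype_longer_than_neutral(self):
        """Hitchhiking: the swept core's EHH at 0.25 cM exceeds the mean EHH of
        same-frequency cores in a matched neutral panel (paired replicates)."""
        from sweepscan.ehh import CoreRegion, ehh, enumerate_core_haplotypes

        wins = trials = 0
        for seed in range(5):
            cfg = SweepSimConfig(n_demes=1, deme_size_N=500, n_sites=600,
                                 region_bp=1_500_000, n_generations=60,
                                 sample_per_deme=100, migration_m=0.0, seed=seed)
            swept, gmap_s, truth = gen_sweep_panel(cfg)
            neutral, gmap_n, _ = gen_sweep_panel(
                SweepSimConfig(**{**cfg.__dict__, "sel_coefficient_s": 0.0}))
            sw = truth.sweep_site_index
            if sw is None:
                continue
            core = CoreRegion((sw,))
            target = next(
                h for h in enumerate_core_haplotypes(swept, core, None, min_freq=0)
                if h.allele_string == swept.sites[sw].allele1 and h.n_carriers >= 2
            )
            x = int(swept.positions_bp[sw] + 250_000)
            e_sweep = ehh(swept, target, "downstream", x)
            # neutral: same-frequency single-site cores
            vals = []
            for j in range(100, neutral.n_sites - 100):
                col = neutral.haplotypes[:, j]
                f = col.mean()
                if abs(f - target.frequency) > 0.1:
                    continue
                haps = enumerate_core_haplotypes(neutral, CoreRegion((j,)), None, min_freq=0)
                h = next((hh for hh in haps if hh.n_carriers >= 2
                          and abs(hh.frequency - f) < 1e-9), None)
                if h is None:
                    continue
                vals.append(ehh(neutral, h, "downstream",
                                int(neutral.positions_bp[j] + 250_000)))
                if len(vals) >= 30:
                    break
            if not vals:
                continue
            trials += 1
            wins += e_sweep > np.mean(vals)
        assert trials >= 3
        assert wins >= trials - 1

    def test_monomorphic_sites_removed_and_truth_consistent(self):
        panel, gmap, truth = gen_sweep_panel(small_cfg(seed=4, sel_coefficient_s=0.1))
        freqs = panel.haplotypes.mean(axis=0)
        assert np.all((freqs > 0) & (freqs < 1))
        if truth.sweep_site_index is not None:
            assert panel.sites[truth.sweep_site_index].pos_bp == truth.sweep_pos_bp
            assert len(truth.sweep_core_string) == len(truth.sweep_core_site_ids)

    def test_deterministic_under_seed(self):
        p1, _, t1 = gen_sweep_panel(small_cfg(seed=6))
        p2, _, t2 = gen_sweep_panel(small_cfg(seed=6))
        np.testing.assert_array_equal(p1.haplotypes, p2.haplotypes)
        assert t1.final_sweep_freq == t2.final_sweep_freq


class TestFixtureSet:
    def test_roundtrip_all_formats(self, tmp_path):
        panel, gmap, truth = gen_sweep_panel(small_cfg(seed=8))
        out = str(tmp_path / "fx")
        manifest = write_fixture_set(panel, gmap, truth, out,
                                     formats=("vcf", "impute", "tsv"))
        for fname, fmt in (("panel.vcf", "phased-vcf"), ("panel.tsv", "tsv"),
                           ("panel", "impute-hls")):
            back = load_panel(f"{out}/{fname}", fmt, f"{out}/pops.tsv")
            np.testing.assert_array_equal(back.haplotypes, panel.haplotypes)

    def test_manifest_lists_expected_files(self, tmp_path):
        panel, gmap, truth = gen_sweep_panel(small_cfg(seed=8))
        manifest = write_fixture_set(panel, gmap, truth, str(tmp_path / "fx"),
                                     formats=("tsv",))
        assert set(manifest) == {"panel.tsv", "pops.tsv", "map.txt", "truth.json"}
        truth_back = json.loads((tmp_path / "fx" / "truth.json").read_text())
        assert truth_back["sweep_pos_bp"] == truth.sweep_pos_bp

    def test_checksums_stable_under_seed(self, tmp_path):
        m = []
        for sub in ("a", "b"):
            panel, gmap, truth = gen_sweep_panel(small_cfg(seed=8))
            m.append(write_fixture_set(panel, gmap, truth, str(tmp_path / sub),
                                       formats=("vcf", "tsv")))
        assert m[0] == m[1]
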