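"""Synthetic-data generators: determinism, calibration, planted structure."""

import warnings

import numpy as np
import pandas as pd
import pytest

from plastisphere_n2o import ecology as eco
from plastisphere_n2o import rates
from plastisphere_n2o import simulate as sim
from plastisphere_n2o.isotopocule import annotate_measurements


@pytest.fixture(scope="module")
def cfg():
    return sim.default_scenario()


class TestDeterminism:
    def test_isotopes_bit_identical(self, cfg):
        a, ta = sim.gen_isotopes(cfg, 5)
        b, tb = sim.gen_isotopes(cfg, 5)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)

    def test_otu_bit_identical(self, cfg):
        a, _, _ = sim.gen_otu_table(cfg, 5)
        b, _, _ = sim.gen_otu_table(cfg, 5)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self, cfg):
        a, _ = sim.gen_isotopes(cfg, 5)
        b, _ = sim.gen_isotopes(cfg, 6)
        assert not a.equals(b)

    def test_ct_raman_ipt_identical(self, cfg):
        small = sim.default_scenario(n_cells_per_group=2)
        assert sim.gen_ct_table(cfg, 1)[0].equals(sim.gen_ct_table(cfg, 1)[0])
        s1, _ = sim.gen_raman(small, 1)
        s2, _ = sim.gen_raman(small, 1)
        assert all(np.array_equal(x.intensities, y.intensities) for x, y in zip(s1, s2))
        assert sim.gen_ipt(cfg, 1)[0].equals(sim.gen_ipt(cfg, 1)[0])


class TestIsotopes:
    def test_fraction_mode_noise_free_hits_forward_model(self):
        groups = (
            sim.GroupSpec("G", "plastisphere", 4, true_fractions=(1.0, 0.0, 0.0)),
        )
        cfg = sim.ScenarioConfig(groups=groups, site_delta_sd=0.0, d18o_sd=0.0)
        iso, truth = sim.gen_isotopes(cfg, 0)
        ann = annotate_measurements(iso)
        assert np.allclose(ann["sp"], 3.0, atol=1e-9)
        assert np.allclose(iso["d18O"], 38.66, atol=1e-9)
        assert np.allclose(truth["f_BD"], 1.0)

    def test_default_group_means_inside_printed_ranges(self, cfg):
        iso, _ = sim.gen_isotopes(cfg, 42)
        ann = annotate_measurements(iso)
        plast = ann[ann["habitat"] == "plastisphere"]
        bulk = ann[ann["habitat"] == "bulk"]
        assert 15.56 <= plast["sp"].mean() <= 26.21
        assert 64.14 <= plast["d18O"].mean() <= 77.82
        assert 7.53 - 1.0 <= bulk["sp"].mean() <= 8.68 + 1.0
        assert 55.62 <= bulk["d18O"].mean() <= 59.93

    def test_design_sizes(self, cfg):
        iso, _ = sim.gen_isotopes(cfg, 0)
        n = iso.groupby("group").size()
        assert n["BW"] == 5
        assert all(n[g] == 3 for g in ("PE", "PS", "PP", "PVC"))

    def test_offsimplex_fractions_rejected(self):
        with pytest.raises(ValueError):
            sim.GroupSpec("G", "bulk", 2, true_fractions=(0.5, 0.2, 0.2))


class TestOtu:
    def test_higher_plastisphere_richness(self, cfg):
        otu, _, truth = sim.gen_otu_table(cfg, 8)
        labels = otu.index.map(truth["habitat"])
        rich = (otu > 0).sum(axis=1).groupby(labels).mean()
        assert rich["plastisphere"] > rich["bulk"]

    def test_zero_separation_null_anosim(self):
        cfg0 = sim.default_scenario(separation=0.0, richness_penalty=0.0, hub_factor_sd=0.0)
        otu, _, truth = sim.gen_otu_table(cfg0, 3)
        labels = otu.index.map(truth["habitat"]).to_numpy()
        res = eco.anosim(eco.bray_curtis(otu), labels, n_perm=199, seed=1)
        assert res["R"] < 0.5

    def test_strong_separation_anosim(self, cfg):
        otu, _, truth = sim.gen_otu_table(cfg, 8)
        labels = otu.index.map(truth["habitat"]).to_numpy()
        res = eco.anosim(eco.bray_curtis(otu), labels, n_perm=999, seed=1)
        assert res["R"] > 0.8
        assert res["p"] <= 0.001

    def test_planted_hubs_recovered_as_keystones(self, cfg):
        otu, markers, truth = sim.gen_otu_table(cfg, 8)
        labels = otu.index.map(truth["habitat"]).to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = eco.build_network(
                otu.loc[labels == "plastisphere"], markers=markers, n_perm=499, seed=2
            )
        ks = eco.keystone_taxa(net, top_k=5)
        assert (ks["marker"] == "bnirK").sum() >= 3
        assert sum(t in truth["hubs"]["plastisphere"] for t in ks["taxon"]) >= 3


class TestCt:
    def test_zero_noise_exact_ratios(self):
        from plastisphere_n2o import qpcr

        cfg0 = sim.default_scenario(ct_sd=0.0)
        ct, _ = sim.gen_ct_table(cfg0, 0)
        norm = qpcr.normalize_to_16S(qpcr.ct_table_to_abundance(ct))
        r = qpcr.nir_nos_ratio(norm)
        bulk = r[r.index.str.startswith("BW")]
        plast = r[~r.index.str.startswith("BW")]
        assert np.allclose(plast, 1.8, rtol=1e-6)
        assert np.allclose(bulk, 0.37, rtol=1e-6)

    def test_default_ratios_inside_bands(self, cfg):
        from plastisphere_n2o import qpcr

        ct, _ = sim.gen_ct_table(cfg, 21)
        norm = qpcr.normalize_to_16S(qpcr.ct_table_to_abundance(ct))
        r = qpcr.nir_nos_ratio(norm)
        bulk = r[r.index.str.startswith("BW")].mean()
        plast = r[~r.index.str.startswith("BW")].mean()
        assert 1.5 <= plast <= 2.3
        assert 0.33 <= bulk <= 0.41


class TestRamanGen:
    def test_truth_sidecar_consistent(self):
        cfg2 = sim.default_scenario(n_cells_per_group=2)
        spectra, truth = sim.gen_raman(cfg2, 4)
        assert len(spectra) == len(truth)
        implied = truth["true_cd_area"] / (truth["true_cd_area"] + truth["true_ch_area"])
        assert np.allclose(implied, truth["true_cd_ratio"], atol=1e-12)

    def test_group_difference_detectable(self):
        """Bulk-like (0.09) vs plastisphere-like (0.25) cohorts separate
        under a rank test at 40 cells per group."""
        from scipy.stats import mannwhitneyu

        from plastisphere_n2o.raman import process_spectra

        groups = (
            sim.GroupSpec("bulklike", "bulk", 1, sp_range=(7, 9), d18o_range=(55, 60), cd_ratio_mean=0.09),
            sim.GroupSpec("plastlike", "plastisphere", 1, sp_range=(15, 26), d18o_range=(64, 78), cd_ratio_mean=0.25),
        )
        cfg = sim.ScenarioConfig(groups=groups, n_cells_per_group=40)
        spectra, _ = sim.gen_raman(cfg, 9)
        cells = process_spectra(spectra)
        a = cells.loc[cells["group"] == "bulklike", "cd_ratio"]
        b = cells.loc[cells["group"] == "plastlike", "cd_ratio"]
        assert mannwhitneyu(a, b).pvalue < 1e-6
        assert b.mean() > a.mean()


class TestIpt:
    def test_configured_share_recovered(self, cfg):
        ipt, _ = sim.gen_ipt(cfg, 6)
        shares = [
            rates.denit_anammox_share(
                rates.IPTMeasurement(r.sample_id, r.t29, r.t30, r.fn)
            )["share_denitrification"]
            for r in ipt.itertuples()
        ]
        assert np.mean(shares) == pytest.approx(cfg.denit_share, abs=0.02)

    def test_acetylene_pairs_embed_f_r(self, cfg):
        _, c2h2 = sim.gen_ipt(cfg, 6)
        ratios = [
            rates.n2o_reduction_ratio(rates.AcetylenePair(r.n2o_without_c2h2, r.n2o_with_c2h2))
            for r in c2h2.itertuples()
        ]
        assert np.allclose(ratios, 0.75, atol=1e-9)

    def test_pure_denitrification_hits_binomial_expectation(self):
        cfg1 = sim.default_scenario(denit_share=1.0)
        ipt, _ = sim.gen_ipt(cfg1, 2)
        r = ipt.iloc[0]
        assert r.t29 == pytest.approx(2 * r.t30 * (1 - r.fn) / r.fn)
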