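"""Balding-Nichols panel drift, HWE/admixed individuals, read-depth model."""

import numpy as np
import pytest

from bgakit import (
    SimConfig,
    Thresholds,
    call_genotypes,
    simulate_individuals,
    simulate_panel,
    simulate_read_depths,
)
from bgakit.simulate import default_locus_efficiencies


class TestPanelDrift:
    def test_fst_zero_copies_ancestral(self):
        panel, p0 = simulate_panel(SimConfig(seed=1, fst=0.0, n_populations=3))
        for pop in panel.population_names:
            np.testing.assert_array_equal(panel.freq.loc[pop].to_numpy(), p0)

    def test_beta_mean_is_ancestral(self):
        """E[p_pop] = p0: Monte-Carlo over many drifted populations."""
        cfg = SimConfig(seed=2, fst=0.3, n_populations=2000, n_loci=4, cohort_size=1)
        panel, p0 = simulate_panel(cfg)
        means = panel.freq.to_numpy().mean(axis=0)
        sd_mean = np.sqrt(0.3 * p0 * (1 - p0) / 2000)
        assert (np.abs(means - p0) < 5 * sd_mean).all()

    def test_moment_estimator_recovers_fst(self):
        """Wright's FST from simulated frequencies matches the configured F."""
        k, F = 10, 0.2
        cfg = SimConfig(seed=3, fst=F, n_populations=k, n_loci=3000, cohort_size=1)
        panel, _ = simulate_panel(cfg)
        freqs = panel.freq.to_numpy()
        s2 = freqs.var(axis=0, ddof=1)
        pbar = freqs.mean(axis=0)
        fst_hat = s2.sum() / (pbar * (1 - pbar)).sum()
        # ratio-of-sums estimator has expectation ~ F / (1 - F/k)
        assert fst_hat == pytest.approx(F / (1 - F / k), abs=0.03)

    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=5)
        p1, a1 = simulate_panel(cfg)
        p2, a2 = simulate_panel(cfg)
        assert (p1.freq.to_numpy() == p2.freq.to_numpy()).all()
        np.testing.assert_array_equal(a1, a2)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SimConfig(fst=1.5)
        with pytest.raises(ValueError):
            SimConfig(ancestral_freq_range=(0.9, 0.1))


class TestIndividuals:
    def test_het_fraction_at_half(self, sim_panel):
        panel, _ = sim_panel
        # overwrite one population with p = 0.5 everywhere via a constructed panel
        from bgakit import SimConfig as SC
        from bgakit import simulate_panel as sp

        flat, _ = sp(SC(seed=6, fst=0.0, ancestral_freq_range=(0.499999, 0.500001),
                        n_populations=1, n_loci=56))
        profs = simulate_individuals(flat, "POP1", 2000, seed=7)
        hets = np.mean([[g[0] != g[1] for g in p.calls.values()] for p in profs])
        assert hets == pytest.approx(0.5, abs=0.01)

    def test_admixed_het_fraction_closed_form(self):
        """p_A = 0.9, p_B = 0.1 -> P(het) = 0.9*0.9 + 0.1*0.1 = 0.82."""
        from bgakit import SimConfig as SC
        from bgakit import simulate_panel as sp

        panel, _ = sp(SC(seed=8, fst=0.0, n_populations=2, n_loci=200))
        panel.freq.loc["POP1"] = 0.9
        panel.freq.loc["POP2"] = 0.1
        adm = simulate_individuals(panel, "POP1", 200, seed=9,
                                   admixed_pair=("POP1", "POP2"))
        hets = np.mean([[g[0] != g[1] for g in p.calls.values()] for p in adm])
        assert hets == pytest.approx(0.82, abs=0.01)

    def test_empty_request(self, sim_panel):
        panel, _ = sim_panel
        assert simulate_individuals(panel, "POP1", 0, seed=1) == []

    def test_truth_labels(self, sim_panel):
        panel, _ = sim_panel
        g = simulate_individuals(panel, "POP2", 1, seed=2)[0]
        assert g.truth_population == "META2"
        adm = simulate_individuals(panel, "POP1", 1, seed=2,
                                   admixed_pair=("POP1", "POP2"))[0]
        assert adm.truth_population == "POP1xPOP2"

    def test_deterministic_under_seed(self, sim_panel):
        panel, _ = sim_panel
        a = simulate_individuals(panel, "POP1", 3, seed=11)
        b = simulate_individuals(panel, "POP1", 3, seed=11)
        assert [p.calls for p in a] == [p.calls for p in b]


class TestReadDepths:
    def test_mean_depth_scales_linearly_with_input(self, sim_panel):
        panel, _ = sim_panel
        cfg = SimConfig(seed=0, n_low_efficiency=0)
        g = simulate_individuals(panel, "POP1", 1, seed=12)[0]
        totals = {}
        for pg in (1000.0, 500.0):
            depths = [
                simulate_read_depths(g, panel, cfg, seed=100 + r, input_dna_pg=pg)
                for r in range(60)
            ]
            totals[pg] = np.mean([
                sum(d.total_depth(lid) for lid in panel.locus_ids) for d in depths
            ])
        assert totals[500.0] / totals[1000.0] == pytest.approx(0.5, abs=0.05)

    def test_low_efficiency_loci_lowest_depth_and_first_to_drop(self, sim_panel):
        panel, _ = sim_panel
        cfg = SimConfig(seed=0)  # first 3 loci at 0.1x efficiency
        eff = default_locus_efficiencies(cfg)
        assert (eff[:3] == 0.1).all() and (eff[3:] == 1.0).all()
        g = simulate_individuals(panel, "POP1", 1, seed=13)[0]
        low_ids = panel.locus_ids[:3]
        depths = [simulate_read_depths(g, panel, cfg, seed=200 + r, input_dna_pg=62.5)
                  for r in range(40)]
        med = {lid: np.median([d.total_depth(lid) for d in depths])
               for lid in panel.locus_ids}
        assert max(med[l] for l in low_ids) < min(med[l] for l in panel.locus_ids[3:])
        missing_low = sum(lid not in d.depths for d in depths for lid in low_ids)
        missing_high = sum(lid not in d.depths for d in depths for lid in panel.locus_ids[3:6])
        assert missing_low > missing_high

    def test_het_split_unbiased(self, sim_panel):
        panel, _ = sim_panel
        cfg = SimConfig(seed=0, n_low_efficiency=0, depth_mean_at_1ng=300.0)
        profs = simulate_individuals(panel, "POP1", 50, seed=14)
        fracs = []
        for r, g in enumerate(profs):
            d = simulate_read_depths(g, panel, cfg, seed=300 + r)
            for lid, call in g.calls.items():
                if call[0] != call[1] and lid in d.depths:
                    counts = d.depths[lid]
                    a1 = sorted(counts)[0]
                    fracs.append(counts[a1] / sum(counts.values()))
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.01)

    def test_negative_input_rejected(self, sim_panel):
        panel, _ = sim_panel
        g = simulate_individuals(panel, "POP1", 1, seed=15)[0]
        with pytest.raises(ValueError):
            simulate_read_depths(g, panel, SimConfig(), seed=1, input_dna_pg=-5.0)

    def test_end_to_end_genotype_recovery(self, sim_panel):
        """simulate -> read depths -> call recovers >= 99% of true genotypes at 1 ng."""
        panel, _ = sim_panel
        cfg = SimConfig(seed=0, depth_mean_at_1ng=500.0, n_low_efficiency=0)
        profs = simulate_individuals(panel, "POP1", 20, seed=16)
        match = total = 0
        for r, g in enumerate(profs):
            adp = simulate_read_depths(g, panel, cfg, seed=400 + r)
            called = call_genotypes(adp, Thresholds(), panel_loci=panel.locus_ids)
            for lid, truth in g.calls.items():
                total += 1
                if called.calls.get(lid) == truth:
                    match += 1
        assert match / total >= 0.99
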