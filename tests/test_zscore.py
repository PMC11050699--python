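"""Z-score outlier test: exact moments, hand-derived z values, decisions, admixture."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from bgakit import (
    GenotypeProfile,
    Locus,
    Population,
    ReferencePanel,
    ZTestConfig,
    admixture_hypothesis,
    loglik_moments,
    predict_by_zscore,
    simulate_individuals,
    z_score,
    z_scores_from_codes,
)

LN2 = math.log(2.0)


def _panel(freqs: dict[str, list[float]], metas=None):
    n_loci = len(next(iter(freqs.values())))
    loci = [Locus(f"rs{i}", "A", "G") for i in range(n_loci)]
    metas = metas or {name: name for name in freqs}
    pops = [Population(name, metas[name], 100) for name in freqs]
    freq = pd.DataFrame.from_dict(freqs, orient="index", columns=[l.id for l in loci])
    return ReferencePanel(loci=loci, populations=pops, freq=freq, floor_applied=True)


def _profile(calls, sample="s1"):
    return GenotypeProfile(sample_id=sample, calls=calls, n_panel_loci=len(calls))


class TestMoments:
    def test_single_locus_half(self):
        """p = 0.5: outcomes ln(1/4) w.p. 1/2 and ln(1/2) w.p. 1/2."""
        mu, var = loglik_moments([0.5])
        assert mu == pytest.approx(-1.5 * LN2, abs=1e-12)
        assert math.sqrt(var) == pytest.approx(0.5 * LN2, abs=1e-12)

    def test_additive_over_loci(self):
        mu1, var1 = loglik_moments([0.3])
        muL, varL = loglik_moments([0.3] * 7)
        assert muL == pytest.approx(7 * mu1, rel=1e-12)
        assert varL == pytest.approx(7 * var1, rel=1e-12)

    def test_near_fixed_locus_variance_vanishes(self):
        _, v1 = loglik_moments([1 - 1e-4])
        _, v2 = loglik_moments([1 - 1e-6])
        assert v2 < v1 < 0.05
        assert v2 < 1e-3

    def test_boundary_frequency_errors(self):
        with pytest.raises(ValueError, match="floor"):
            loglik_moments([0.5, 1.0])

    def test_matches_monte_carlo(self):
        """mu and var equal the Monte-Carlo moments of the simulated log-likelihood."""
        rng = np.random.default_rng(21)
        p = rng.uniform(0.1, 0.9, 20)
        mu, var = loglik_moments(p)
        n = 20_000
        codes = (rng.random((n, 20)) < p).astype(int) + (rng.random((n, 20)) < p).astype(int)
        lnq = np.stack([2 * np.log(p), np.log(2 * p * (1 - p)), 2 * np.log1p(-p)])
        lobs = lnq[(2 - codes), np.arange(20)].sum(axis=1)
        assert lobs.mean() == pytest.approx(mu, abs=4 * math.sqrt(var / n))
        assert lobs.var() == pytest.approx(var, rel=0.05)


class TestZScore:
    def test_het_at_half_is_minus_one(self):
        panel = _panel({"P1": [0.5]})
        assert z_score(_profile({"rs0": ("A", "G")}), panel, "P1") == pytest.approx(-1.0)

    def test_hom_at_half_is_plus_one(self):
        panel = _panel({"P1": [0.5]})
        assert z_score(_profile({"rs0": ("A", "A")}), panel, "P1") == pytest.approx(1.0)

    def test_four_het_loci_minus_sqrt_L(self):
        panel = _panel({"P1": [0.5] * 4})
        g = _profile({f"rs{i}": ("A", "G") for i in range(4)})
        assert z_score(g, panel, "P1") == pytest.approx(-2.0)

    def test_locus_order_invariance(self, sim_panel_floored):
        g = simulate_individuals(sim_panel_floored, "POP1", 1, seed=3)[0]
        z1 = z_score(g, sim_panel_floored, "POP1")
        rev = GenotypeProfile(
            sample_id=g.sample_id,
            calls=dict(reversed(list(g.calls.items()))),
            n_panel_loci=g.n_panel_loci,
        )
        assert z_score(rev, sim_panel_floored, "POP1") == pytest.approx(z1, rel=1e-12)

    def test_log_base_invariance_of_codes_route(self):
        """z computed from the vectorised code route matches the profile route."""
        panel = _panel({"P1": [0.3, 0.6, 0.8]})
        g = _profile({"rs0": ("A", "A"), "rs1": ("A", "G"), "rs2": ("G", "G")})
        z_api = z_score(g, panel, "P1")
        codes = np.array([[2, 1, 0]], dtype=float)
        z_vec = z_scores_from_codes(codes, np.array([0.3, 0.6, 0.8]))[0]
        assert z_api == pytest.approx(z_vec, rel=1e-12)

    def test_monotone_separation_with_fst(self):
        """Mean z against a wrong population grows with divergence."""
        from bgakit import SimConfig, apply_frequency_floor, simulate_panel

        means = []
        for fst in (0.05, 0.2):
            panel, _ = simulate_panel(SimConfig(seed=4, fst=fst, n_populations=2))
            fl = apply_frequency_floor(panel)
            profs = simulate_individuals(panel, "POP1", 50, seed=8)
            zs = [z_score(g, fl, "POP2") for g in profs]
            means.append(np.mean(zs))
        assert means[1] > means[0]


class TestPredict:
    def test_only_plausible_population_accepted(self):
        panel = _panel(
            {"EUR": [0.9] * 20, "AFR": [0.05] * 20},
            metas={"EUR": "Europe", "AFR": "Africa"},
        )
        g = _profile({f"rs{i}": ("A", "A") for i in range(18)} |
                     {f"rs{i}": ("A", "G") for i in range(18, 20)})
        r = predict_by_zscore(g, panel, pool_metapopulations=False)
        assert r.accepted_set == ["EUR"]
        assert r.decision.status == "predicted" and r.decision.label == "EUR"

    def test_identical_populations_inconclusive(self):
        panel = _panel(
            {"P1": [0.5] * 16, "P2": [0.5] * 16},
            metas={"P1": "Europe", "P2": "Asia"},
        )
        g = _profile({f"rs{i}": ("A", "G") for i in range(8)} |
                     {f"rs{i}": ("A", "A") for i in range(8, 12)} |
                     {f"rs{i}": ("G", "G") for i in range(12, 16)})
        r = predict_by_zscore(g, panel, pool_metapopulations=False)
        assert set(r.accepted_set) == {"P1", "P2"}
        assert r.decision.status == "inconclusive"
        assert (r.lr_comparisons["ci_lower"] <= 0).all()

    def test_implausible_everywhere_rejected(self):
        panel = _panel({"P1": [0.95] * 30, "P2": [0.9] * 30})
        g = _profile({f"rs{i}": ("G", "G") for i in range(30)})
        r = predict_by_zscore(g, panel, pool_metapopulations=False)
        assert r.accepted_set == []
        assert r.decision.status == "rejected"

    def test_metapopulation_pooling_labels(self, sim_panel_floored):
        g = simulate_individuals(sim_panel_floored, "POP1", 1, seed=12)[0]
        r = predict_by_zscore(g, sim_panel_floored)
        assert set(r.z.index) == {"META1", "META2", "META3"}


class TestAdmixture:
    def test_identity_when_parents_equal(self):
        panel = _panel({"P1": [0.4] * 6})
        g = _profile({f"rs{i}": ("A", "G") for i in range(6)})
        with pytest.warns(UserWarning, match="single-population"):
            z_ab = admixture_hypothesis(g, panel, "P1", "P1")
        assert z_ab == pytest.approx(z_score(g, panel, "P1"), rel=1e-12)

    def test_admixed_het_probability_closed_form(self):
        # p_A = 0.9, p_B = 0.1 -> P(het) = 0.9*0.9 + 0.1*0.1 = 0.82
        pa, pb = 0.9, 0.1
        assert pa * (1 - pb) + pb * (1 - pa) == pytest.approx(0.82)
        panel = _panel({"A": [0.9], "B": [0.1]})
        g_het = _profile({"rs0": ("A", "G")})
        # observed het log-prob under the admixed model is ln(0.82)
        mu_like = admixture_hypothesis(g_het, panel, "A", "B")
        assert np.isfinite(mu_like)

    def test_admixed_profiles_fit_admixture_hypothesis_best(self):
        """First-generation A x B profiles get lower z under A x B than under A or B."""
        from bgakit import SimConfig, apply_frequency_floor, simulate_panel

        panel, _ = simulate_panel(SimConfig(seed=6, fst=0.2, n_populations=2))
        fl = apply_frequency_floor(panel)
        adm = simulate_individuals(panel, "POP1", 60, seed=13,
                                   admixed_pair=("POP1", "POP2"))
        wins = 0
        for g in adm:
            z_ab = admixture_hypothesis(g, fl, "POP1", "POP2")
            z_a = z_score(g, fl, "POP1")
            z_b = z_score(g, fl, "POP2")
            if z_ab < min(z_a, z_b):
                wins += 1
        assert wins > 30  # majority of 60
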