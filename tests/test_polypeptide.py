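"""Two-cleavage-site polypeptide model and usage classification."""

import numpy as np
import pytest

from proteokin.polypeptide import (FragmentSet, UsageTrajectory,
                                   build_polypeptide_model,
                                   classify_usage_behavior,
                                   cleavage_site_usage, mean_fragment_length,
                                   search_behaviors, simulate_polypeptide)

TIMES = np.linspace(15.0, 240.0, 16)


class TestFragmentSet:
    def test_roster_has_six_species(self):
        eng = build_polypeptide_model(FragmentSet())
        assert len(eng.species) == 6

    def test_inconsistent_lengths_rejected(self):
        with pytest.raises(ValueError):
            FragmentSet(lengths={"S": 24, "A": 8, "B": 7, "Cfrag": 8,
                                 "AB": 15, "BC": 15})
        with pytest.raises(ValueError):
            FragmentSet(lengths={"S": 23, "A": 8, "B": 7, "Cfrag": 8,
                                 "AB": 16, "BC": 15})

    def test_residue_conservation_along_trajectory(self):
        fs = FragmentSet()
        traj = simulate_polypeptide(fs, 40.0, TIMES)
        eng = traj.engine
        w = eng.moiety_weights()
        residues = traj.states @ w
        assert np.allclose(residues, 40.0 * fs.lengths["S"], rtol=1e-6)

    def test_capacity_scales_inversely_with_length(self):
        eng = build_polypeptide_model(FragmentSet(C=100.0))
        caps = dict(zip(eng.species, eng.cap))
        assert caps["S"] == 100.0
        assert caps["A"] == pytest.approx(100.0 * 23 / 8)


class TestUsage:
    def test_symmetric_sites_share_half_each(self):
        u = cleavage_site_usage(simulate_polypeptide(FragmentSet(), 40.0,
                                                     TIMES))
        assert np.allclose(u.relative[:, 1:], 0.5, atol=1e-6)
        assert np.all(np.diff(u.cumulative, axis=1) >= -1e-12)

    def test_silent_site_takes_no_share(self):
        fs = FragmentSet(site_rates=(1.0, 0.0))
        u = cleavage_site_usage(simulate_polypeptide(fs, 40.0, TIMES))
        assert np.allclose(u.relative[0, 1:], 1.0)
        assert np.allclose(u.flux[1], 0.0)

    def test_matches_flux_integration_oracle(self):
        # brute-force: cumulative counts re-integrated on a 10x finer grid
        fs = FragmentSet(transport_scale={"S": 1.0, "A": 0.2, "B": 1.6,
                                          "Cfrag": 0.09, "AB": 0.3,
                                          "BC": 0.06}, kp=15.0,
                         site_rates=(1.0, 0.2))
        fine = np.linspace(1.0, 240.0, 480)
        uf = cleavage_site_usage(simulate_polypeptide(fs, 40.0, fine))
        coarse = np.linspace(1.0, 240.0, 48)
        uc = cleavage_site_usage(simulate_polypeptide(fs, 40.0, coarse))
        for s in (0, 1):
            assert uc.cumulative[s, -1] == pytest.approx(
                uf.cumulative[s, -1], rel=5e-3)


class TestClassification:
    @pytest.mark.parametrize("f1, f2, label", [
        (lambda t: np.ones_like(t), lambda t: np.ones_like(t), "flat"),
        (lambda t: 1 - 0.002 * t, lambda t: 1 - 0.003 * t, "both_decrease"),
        (lambda t: 1 + 0.002 * t, lambda t: 1 + 0.003 * t, "both_increase"),
        (lambda t: 1 + 0.003 * t, lambda t: 1 - 0.003 * t, "divergent"),
    ])
    def test_labels_follow_slope_oracle(self, f1, f2, label):
        t = np.linspace(0, 300, 31)
        flux = np.vstack([f1(t), f2(t)])
        fold = flux / flux[:, [0]]
        u = UsageTrajectory(t, flux, np.zeros_like(flux),
                            np.full_like(flux, 0.5), fold)
        assert classify_usage_behavior(u) == label

    def test_deadband_absorbs_small_drift(self):
        t = np.linspace(0, 300, 31)
        flux = np.vstack([1 + 0.0001 * t, 1 - 0.0001 * t])
        u = UsageTrajectory(t, flux, np.zeros_like(flux),
                            np.full_like(flux, 0.5), flux / flux[:, [0]])
        assert classify_usage_behavior(u) == "flat"

    def test_requires_three_points(self):
        t = np.array([0.0, 10.0])
        flux = np.ones((2, 2))
        u = UsageTrajectory(t, flux, flux, flux, flux)
        with pytest.raises(ValueError):
            classify_usage_behavior(u)


class TestSearch:
    def test_seeded_search_is_reproducible(self):
        a = search_behaviors(n_samples=30, seed=42, stop_when_complete=False)
        b = search_behaviors(n_samples=30, seed=42, stop_when_complete=False)
        assert a[1] == b[1]
        assert a[0].keys() == b[0].keys()

    def test_symmetric_point_prior_yields_only_flat(self):
        # a degenerate prior pinned at slow symmetric kinetics: fluxes stay
        # level over the window, so every sample classifies as flat
        from proteokin.inference import Prior, PriorSet
        prior = PriorSet(vin=Prior("uniform", 5.0, 5.0 + 1e-9),
                         kp=Prior("uniform", 2000.0, 2000.0 + 1e-9))
        base = FragmentSet(KaS=2.0, KiS=150.0, KiP=100.0)
        ex, counts, _ = search_behaviors(prior, n_samples=5, seed=1,
                                         base=base, S0=400.0,
                                         stop_when_complete=False)
        assert set(ex) == {"flat"}
        assert counts["flat"] == 5


class TestFragmentLength:
    def test_complete_digestion_limit(self):
        # long digestion of a fast-cutting substrate ends near the
        # equal-molar terminal mixture (A, B, C): mean = 23/3 residues
        fs = FragmentSet(vin=200.0, kon=0.3, vout=20.0, tau=2.0)
        t = np.linspace(60.0, 4000.0, 12)
        mfl = mean_fragment_length(simulate_polypeptide(fs, 5.0, t))
        assert mfl[-1] == pytest.approx(23 / 3, rel=0.05)

    def test_single_cleavage_products_weighted_mean(self):
        # early on, only first-pass products exist; the mean lies between
        # the shortest (7) and longest (15) fragments
        fs = FragmentSet()
        mfl = mean_fragment_length(simulate_polypeptide(fs, 40.0,
                                                        [5.0, 10.0]))
        assert 7.0 <= mfl[-1] <= 15.0

    def test_undefined_before_any_product(self):
        fs = FragmentSet(kp=0.0001)
        mfl = mean_fragment_length(simulate_polypeptide(fs, 0.0, [5.0]))
        assert np.isnan(mfl[0])
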