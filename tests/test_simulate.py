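"""Simulation protocol tests: equilibria, sweeps, communities, ensembles."""

import numpy as np
import pandas as pd
import pytest

from rmeco import (
    CommunityState,
    HostSpec,
    LHSRanges,
    ModelParams,
    PhageSpec,
    analytic_equilibria,
    build_community,
    classify_outcome,
    ensemble_summary,
    integrate_to_equilibrium,
    lhs_sample,
    rm_set,
    sweep_supply,
    total_abundance_curve,
    viral_persistence_threshold,
)
from rmeco.simulate import SweepResult

from conftest import GRID


def single_host_community(n_rm=0):
    host = HostSpec("h", rm_set(*[f"r{i}" for i in range(n_rm)]), per_rm_cost=0.05)
    return [host], [PhageSpec("p", host_index=0)]


class TestIntegrateToEquilibrium:
    def test_virus_free_closed_form(self):
        hosts, phages = single_host_community()
        params = ModelParams().with_(S=1e6, delta_b=0.1)
        init = CommunityState(N=1e6, B=np.array([1e4]), P=np.array([0.0]))
        state, ok = integrate_to_equilibrium("general", hosts, phages, params, init)
        assert ok
        assert state.B[0] == pytest.approx(1e7, rel=1e-6)
        assert state.N == pytest.approx(params.delta_b / params.alpha, rel=1e-6)

    def test_viral_equilibrium_matches_closed_form(self):
        hosts, phages = single_host_community(n_rm=1)
        params = ModelParams().with_(S=1e7)
        assert params.S > viral_persistence_threshold(params, hosts[0])
        expected = analytic_equilibria(params, hosts[0], with_virus=True)
        init = CommunityState(N=1e6, B=np.array([1e4]), P=np.array([1e4]))
        state, _ = integrate_to_equilibrium("general", hosts, phages, params, init)
        assert state.B[0] == pytest.approx(expected.B[0], rel=1e-6)
        assert state.P[0] == pytest.approx(expected.P[0], rel=1e-6)
        assert state.N == pytest.approx(expected.N, rel=1e-6)

    @pytest.mark.parametrize("kind", ["general", "parallel", "memory"])
    def test_steady_state_independent_of_initial_conditions(self, kind):
        """Equilibria from inits spanning 1e2-1e6 cells/ml agree."""
        hosts, phages = build_community(2, "subset", kind)
        params = ModelParams().with_(S=1e6, m_v=0.75)
        finals = []
        for x0 in (1e2, 1e6):
            init = CommunityState(
                N=x0, B=np.full(2, x0), P=np.full(len(phages), x0)
            )
            state, _ = integrate_to_equilibrium(kind, hosts, phages, params, init)
            finals.append(np.concatenate([[state.N], state.B, state.P]))
        a, b = finals
        np.testing.assert_allclose(a, b, rtol=1e-4, atol=1e-3)

    def test_insufficient_horizon_reports_nonconvergence(self):
        hosts, phages = single_host_community()
        params = ModelParams().with_(S=1e6)
        init = CommunityState(N=0.0, B=np.array([10.0]), P=np.array([0.0]))
        _, ok = integrate_to_equilibrium("general", hosts, phages, params, init, t_max=1.0)
        assert not ok

    def test_bad_rel_tol_rejected(self):
        hosts, phages = single_host_community()
        init = CommunityState(N=0.0, B=np.array([10.0]), P=np.array([0.0]))
        with pytest.raises(ValueError):
            integrate_to_equilibrium("general", hosts, phages, ModelParams(), init, rel_tol=0)


class TestBuildCommunity:
    def test_subset_arrangement_nests(self):
        hosts, _ = build_community(3, "subset", "general")
        assert [len(h.rm_set) for h in hosts] == [1, 2, 3]
        assert hosts[0].rm_set < hosts[1].rm_set < hosts[2].rm_set

    def test_unique_arrangement_is_pairwise_disjoint(self):
        hosts, _ = build_community(3, "unique", "general")
        assert [len(h.rm_set) for h in hosts] == [1, 2, 3]
        for i in range(3):
            for j in range(i + 1, 3):
                assert not (hosts[i].rm_set & hosts[j].rm_set)

    def test_memory_phages_carry_host_methylome(self):
        hosts, phages = build_community(2, "subset", "memory")
        for h, p in zip(hosts, phages):
            assert p.methylation == h.rm_set

    def test_single_level_memory(self):
        hosts, phages = build_community(1, "subset", "memory")
        assert len(hosts) == len(phages) == 1
        assert phages[0].methylation == hosts[0].rm_set == rm_set("r1")

    def test_general_has_single_phage(self):
        _, phages = build_community(3, "subset", "general")
        assert len(phages) == 1

    def test_zero_level_optional(self):
        hosts, _ = build_community(2, "subset", "general", include_zero_level=True)
        assert [len(h.rm_set) for h in hosts] == [0, 1, 2]

    def test_unknown_arrangement_rejected(self):
        with pytest.raises(ValueError, match="arrangement"):
            build_community(2, "mosaic", "general")


class TestClassifyOutcome:
    @pytest.mark.parametrize(
        "B, expected",
        [
            ((1e6, 0.0), "monoculture"),
            ((1e6, 1e5), "coexistence"),
            ((1e-9, 1e6), "monoculture"),
            ((1e-9, 1e-9), "collapse"),
            ((1e6, 1e-9, 1e5), "exclusion-of-1"),
        ],
    )
    def test_labels(self, B, expected):
        state = CommunityState(N=1.0, B=np.array(B), P=np.zeros(1))
        persists, label = classify_outcome(state, extinction_threshold=1.0)
        assert label == expected
        assert persists.tolist() == [b >= 1.0 for b in B]

    def test_threshold_must_be_positive(self):
        state = CommunityState(N=1.0, B=np.ones(1), P=np.zeros(1))
        with pytest.raises(ValueError):
            classify_outcome(state, extinction_threshold=0.0)


class TestLHS:
    RANGES = LHSRanges(ranges={"phi": (1e-8, 1e-5), "r_e": (10, 1e4), "beta": (10, 100)})

    def test_values_within_ranges(self):
        table = lhs_sample(64, self.RANGES, seed=3)
        for name, (lo, hi) in self.RANGES.ranges.items():
            assert table[name].between(lo, hi).all()

    def test_one_sample_per_stratum_per_dimension(self):
        n = 50
        table = lhs_sample(n, self.RANGES, seed=7)
        for name, (lo, hi) in self.RANGES.ranges.items():
            vals = table[name].to_numpy()
            if name in self.RANGES.log_uniform:
                u = (np.log10(vals) - np.log10(lo)) / (np.log10(hi) - np.log10(lo))
            else:
                u = (vals - lo) / (hi - lo)
            counts = np.bincount(np.floor(u * n).astype(int), minlength=n)
            assert (counts == 1).all()

    def test_deterministic_given_seed(self):
        t1 = lhs_sample(20, self.RANGES, seed=11)
        t2 = lhs_sample(20, self.RANGES, seed=11)
        pd.testing.assert_frame_equal(t1, t2)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            LHSRanges(ranges={"phi": (1e-5, 1e-8)})
        with pytest.raises(ValueError):
            LHSRanges(ranges={"r_e": (-1.0, 10.0)})


def _synthetic_sweep(S, abundances, kind="general"):
    """Build a SweepResult directly from given host abundances."""
    states = [
        CommunityState(N=1.0, B=np.asarray(row, dtype=float), P=np.zeros(1))
        for row in abundances
    ]
    n_hosts = len(abundances[0])
    return SweepResult(
        kind=kind,
        S=np.asarray(S, dtype=float),
        states=states,
        converged=np.ones(len(S), dtype=bool),
        host_ids=[f"host_{i + 1}rm" for i in range(n_hosts)],
        phage_ids=["phage"],
    )


class TestEnsembleSummary:
    def test_identical_sweeps_have_zero_iqr(self):
        sw = _synthetic_sweep([1.0, 2.0], [[5.0, 1.0], [6.0, 2.0]])
        summary = ensemble_summary([sw] * 10)
        np.testing.assert_allclose(summary.median[:, :2], [[5, 1], [6, 2]])
        np.testing.assert_allclose(summary.q25, summary.q75)

    def test_quantiles_match_sorted_order_oracle(self):
        rng = np.random.default_rng(0)
        draws = rng.uniform(0, 1e6, size=1000)
        sweeps = [_synthetic_sweep([1.0], [[v, 2 * v]]) for v in draws]
        summary = ensemble_summary(sweeps)
        s = np.sort(draws)

        def interp_q(q):  # linear interpolation of order statistics
            pos = q * (len(s) - 1)
            lo = int(np.floor(pos))
            return s[lo] + (pos - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])

        assert summary.median[0, 0] == pytest.approx(interp_q(0.5))
        assert summary.q25[0, 0] == pytest.approx(interp_q(0.25))
        assert summary.q75[0, 0] == pytest.approx(interp_q(0.75))
        assert (summary.q25 <= summary.median).all()
        assert (summary.median <= summary.q75).all()

    def test_mismatched_grids_rejected(self):
        s1 = _synthetic_sweep([1.0, 2.0], [[1, 1], [1, 1]])
        s2 = _synthetic_sweep([1.0, 3.0], [[1, 1], [1, 1]])
        with pytest.raises(ValueError, match="same S grid"):
            ensemble_summary([s1, s2])


class TestSweepRegimes:
    """The three nutrient-supply regimes of the pairwise competition."""

    def test_low_supply_competition_monoculture(self, general_sweep):
        sw, _, _ = general_sweep
        persists, label = classify_outcome(sw.states[0])
        assert label == "monoculture"
        assert persists[0] and not persists[1]

    def test_high_supply_general_excludes_competition_specialist(self, general_sweep):
        sw, _, _ = general_sweep
        persists, _ = classify_outcome(sw.states[-1])
        assert not persists[0] and persists[1]

    def test_mid_supply_coexistence(self, general_sweep):
        sw, _, _ = general_sweep
        labels = [classify_outcome(s)[1] for s in sw.states]
        assert "coexistence" in labels
        # ordering: monoculture regime precedes coexistence precedes exclusion
        first_co = labels.index("coexistence")
        assert all(lab == "monoculture" for lab in labels[:first_co])

    def test_high_supply_parallel_coexists(self, parallel_sweep):
        sw, _, _ = parallel_sweep
        persists, label = classify_outcome(sw.states[-1])
        assert label == "coexistence"
        assert persists.all()

    def test_defense_specialist_dominates_high_supply(self, parallel_sweep, memory_sweep):
        for sweep_fixture in (parallel_sweep, memory_sweep):
            sw, _, _ = sweep_fixture
            final = sw.states[-1]
            assert final.B[1] > final.B[0]

    def test_virus_persists_iff_supply_above_threshold(self):
        """Single-host phage persistence toggles exactly at S_crit."""
        hosts, phages = single_host_community(n_rm=1)
        params = ModelParams()
        s_crit = viral_persistence_threshold(params, hosts[0])
        for factor, expect in ((0.2, False), (5.0, True)):
            p = params.with_(S=factor * s_crit)
            init = CommunityState(N=1e6, B=np.array([1e4]), P=np.array([1e4]))
            state, _ = integrate_to_equilibrium("general", hosts, phages, p, init)
            assert (state.P[0] > 1.0) == expect

    def test_sweep_requires_increasing_grid(self):
        hosts, phages = single_host_community()
        with pytest.raises(ValueError, match="strictly increasing"):
            sweep_supply("general", hosts, phages, ModelParams(), np.array([1e5, 1e4]))


class TestMemoryEscalation:
    def test_dominant_rmpg_nondecreasing_in_supply(self, memory3_subset_sweep):
        sw, _, _ = memory3_subset_sweep
        curve = total_abundance_curve(sw)
        assert (np.diff(curve["dominant_rmpg"]) >= 0).all()

    def test_subset_excludes_low_rmpg_hosts_at_high_supply(self, memory3_subset_sweep):
        sw, _, _ = memory3_subset_sweep
        persists, _ = classify_outcome(sw.states[-1])
        assert persists[2]
        assert not persists[0] and not persists[1]

    def test_unique_sets_retain_all_hosts_at_high_supply(self, memory3_unique_sweep):
        sw, _, _ = memory3_unique_sweep
        persists, label = classify_outcome(sw.states[-1])
        assert persists.all()
        assert label == "coexistence"

    def test_unique_sets_carry_more_total_biomass(
        self, memory3_subset_sweep, memory3_unique_sweep
    ):
        sub, _, _ = memory3_subset_sweep
        uni, _, _ = memory3_unique_sweep
        total_sub = sub.host_abundances()[-1].sum()
        total_uni = uni.host_abundances()[-1].sum()
        assert total_uni > total_sub


class TestTotalAbundanceCurve:
    def test_general_and_parallel_scaling_identical(self, general3_sweep, parallel3_sweep):
        gen, _, _ = general3_sweep
        par, _, _ = parallel3_sweep
        cg = total_abundance_curve(gen)
        cp = total_abundance_curve(par)
        assert (cg["dominant_rmpg"] == cp["dominant_rmpg"]).all()
        np.testing.assert_allclose(
            cg["total_abundance"], cp["total_abundance"], rtol=2e-2
        )

    def test_memory_scaling_decreases_with_methylation(self):
        """Stronger virion methylation flattens the abundance gains."""
        hosts, phages = build_community(2, "subset", "memory")
        grid = GRID[::2]
        curves = {}
        for m_v in (0.5, 0.9):
            sw = sweep_supply("memory", hosts, phages, ModelParams().with_(m_v=m_v), grid)
            curves[m_v] = total_abundance_curve(sw)
        hi = curves[0.9]
        lo = curves[0.5]
        # at matched supply, the more-methylated community has no more biomass
        assert (hi["total_abundance"] <= lo["total_abundance"] * 1.02).all()

    def test_sweep_frame_shape(self, general_sweep):
        sw, hosts, phages = general_sweep
        df = sw.to_frame()
        assert len(df) == len(sw.S) * (1 + len(hosts) + len(phages))
        assert set(df["population"]) == {"nutrient", "host_1rm", "host_2rm", "phage"}
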