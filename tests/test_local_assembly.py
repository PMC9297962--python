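"""Forward-time Moran community dynamics."""

import numpy as np
import pytest
from scipy import stats

from ecoassembly import AssemblyParams, LocalCommunity, run_assembly
from ecoassembly.local_assembly import NonconvergenceError


def make_comm(meta, seed=0, **kw):
    defaults = dict(J=200, m=0.01, nu=0.0, model="neutral", Lambda_target=0.75)
    defaults.update(kw)
    return LocalCommunity(meta, AssemblyParams(seed=seed, **defaults))


class TestInitialization:
    def test_monodominance_starts_with_single_most_abundant_species(self, small_meta):
        comm = make_comm(small_meta, init_mode="monodominance", J=100)
        dominant = int(np.argmax(small_meta.abundance_array))
        assert set(comm.demes.tolist()) == {dominant}
        assert comm.richness() == 1
        assert comm.Lambda == 0.0

    def test_any_init_has_all_founder_flags_and_lambda_zero(self, small_meta):
        comm = make_comm(small_meta, seed=4)
        assert comm.founder.all()
        assert comm.Lambda == 0.0
        assert len(comm.demes) == 200

    def test_metacommunity_sample_frequencies_match_multinomial_oracle(self, small_meta):
        """Initial composition is a multinomial draw on regional proportions."""
        J, reps = 400, 40
        counts = np.zeros(small_meta.S_M)
        for i in range(reps):
            comm = make_comm(small_meta, seed=i, J=J)
            counts += np.bincount(comm.demes, minlength=small_meta.S_M)
        p = small_meta.abundance_array / small_meta.J_M
        expected = p * J * reps
        keep = expected >= 5  # chi-square validity
        chi2 = np.sum((counts[keep] - expected[keep]) ** 2 / expected[keep])
        # lump the tail so totals match
        chi2 += (counts[~keep].sum() - expected[~keep].sum()) ** 2 / expected[~keep].sum()
        dof = keep.sum()
        assert stats.chi2.sf(chi2, dof) > 1e-4


class TestDeathWeights:
    def test_neutral_weights_are_uniform(self, small_meta):
        comm = make_comm(small_meta, J=500)
        w = comm.death_weights()
        assert np.allclose(w, 1 / 500)

    def test_filtering_at_optimum_is_uniform(self, small_meta):
        comm = make_comm(small_meta, model="filtering", s_E=1.0, z_E=0.0)
        comm.traits[:] = 0.0  # every individual exactly at the optimum
        w = comm.death_weights()
        assert np.allclose(w, 1 / comm.J)
        assert w.sum() == pytest.approx(1.0)

    def test_competition_kernel_matches_hand_evaluation(self, small_meta):
        """Three species z=(0,0,5), equal abundance, s_E=1: raw weight is
        exp(-(z - z_bar)^2) with z_bar = 5/3; the z=5 individuals are safest."""
        comm = make_comm(small_meta, J=300, model="competition", s_E=1.0, seed=1)
        comm.demes = np.repeat([0, 1, 2], 100).astype(np.int64)
        comm.traits[:3] = [0.0, 0.0, 5.0]
        w = comm.death_weights()
        z_bar = 5 / 3
        raw = np.exp(-((np.array([0.0, 0.0, 5.0]) - z_bar) ** 2) / 1.0)
        expected = np.repeat(raw, 100)
        expected /= expected.sum()
        assert np.allclose(w, expected)
        assert w[200] == min(w)  # z=5 furthest from the mean

    def test_invalid_strength_rejected(self):
        with pytest.raises(ValueError):
            AssemblyParams(J=10, m=0.1, model="filtering", s_E=0.0)


class TestStep:
    def test_pure_immigration_always_draws_from_metacommunity(self, small_meta):
        comm = make_comm(small_meta, m=1.0, seed=3)
        before = comm.demes.copy()
        for _ in range(50):
            comm.step()
        # every change introduced a metacommunity species
        assert all(sp < small_meta.S_M for sp in comm.demes)
        assert comm.step_count == 50
        assert (before != comm.demes).sum() <= 50

    def test_absorbing_monodominance_with_no_immigration(self, small_meta):
        comm = make_comm(small_meta, m=0.0, nu=0.0, init_mode="monodominance")
        sp = comm.demes[0]
        for _ in range(200):
            comm.step()
        assert set(comm.demes.tolist()) == {sp}

    def test_community_size_constant(self, small_meta):
        comm = make_comm(small_meta, J=150, m=0.05, nu=0.01, seed=9)
        for _ in range(300):
            comm.step()
            assert len(comm.demes) == 150

    def test_drift_only_richness_never_increases(self, small_meta):
        comm = make_comm(small_meta, m=0.0, nu=0.0, seed=10)
        richness = [comm.richness()]
        for _ in range(2000):
            comm.step()
            richness.append(comm.richness())
        assert all(b <= a for a, b in zip(richness, richness[1:]))


class TestSpeciation:
    def test_zero_rate_never_speciates(self, small_meta):
        comm = make_comm(small_meta, nu=0.0, seed=5)
        for _ in range(500):
            comm.step()
        assert len(comm.traits) == small_meta.S_M

    def test_new_species_has_abundance_one_and_parent_record(self, small_meta):
        comm = make_comm(small_meta, nu=1.0, m=0.0, seed=6)
        comm.step()
        new_id = len(comm.traits) - 1
        assert new_id >= small_meta.S_M
        counts = comm.species_counts()
        assert counts[new_id] == 1
        hist = comm.histories[new_id]
        assert hist.origin == "local_speciation"
        assert hist.parent is not None
        assert comm.phylo_records[0][0] == new_id

    def test_offspring_trait_variance_matches_ratio(self, small_meta):
        """Trait innovation variance is sigma2_M / (lam (1 + eps)) = 2 here."""
        comm = make_comm(small_meta, nu=1.0, m=0.0, seed=7, J=500)
        diffs = []
        for _ in range(3000):
            comm.step()
            child, parent, _ = comm.phylo_records[-1]
            diffs.append(comm.traits[child] - comm.traits[parent])
        assert np.var(diffs) == pytest.approx(2.0, rel=0.1)


class TestLambdaAndRun:
    def test_lambda_zero_target_returns_initial_state(self, small_meta):
        comm = make_comm(small_meta, Lambda_target=0.0, seed=8)
        before = comm.demes.copy()
        comm.run()
        assert comm.step_count == 0
        assert (comm.demes == before).all()

    def test_lambda_monotone_and_bounded(self, small_meta):
        comm = make_comm(small_meta, seed=11, J=100)
        last = 0.0
        for _ in range(500):
            comm.step()
            assert 0.0 <= comm.Lambda <= 1.0
            assert comm.Lambda >= last
            last = comm.Lambda
        comm.run(lambda_target=1.0)
        assert comm.Lambda == 1.0
        assert not comm.founder.any()

    def test_max_step_guard_raises_with_lambda_reached(self, small_meta):
        comm = make_comm(small_meta, seed=12, J=400)
        with pytest.raises(NonconvergenceError) as exc:
            comm.run(lambda_target=0.9, max_steps=10)
        assert 0 <= exc.value.lambda_reached < 0.9

    def test_identical_seeds_identical_histories(self, small_meta):
        p = dict(J=150, m=0.02, nu=1e-3, Lambda_target=0.8)
        c1, h1 = run_assembly(small_meta, AssemblyParams(seed=21, **p))
        c2, h2 = run_assembly(small_meta, AssemblyParams(seed=21, **p))
        assert (c1.demes == c2.demes).all()
        assert c1.step_count == c2.step_count
        assert {k: v.trajectory for k, v in h1.items()} == {
            k: v.trajectory for k, v in h2.items()
        }

    def test_immigration_only_equilibrium_matches_multinomial_oracle(self, small_meta):
        """With m=1 each deme's final occupant is an independent regional
        draw, so composition over replicates is multinomial."""
        J, reps = 200, 25
        counts = np.zeros(small_meta.S_M)
        for i in range(reps):
            comm = make_comm(small_meta, m=1.0, seed=100 + i, J=J)
            comm.run(lambda_target=1.0)
            counts += np.bincount(comm.demes, minlength=small_meta.S_M)
        p = small_meta.abundance_array / small_meta.J_M
        expected = p * J * reps
        keep = expected >= 5
        chi2 = np.sum((counts[keep] - expected[keep]) ** 2 / expected[keep])
        chi2 += (counts[~keep].sum() - expected[~keep].sum()) ** 2 / expected[~keep].sum()
        assert stats.chi2.sf(chi2, keep.sum()) > 1e-4


class TestExports:
    def test_history_table_has_expected_rows(self, small_meta):
        comm, hist = run_assembly(
            small_meta, AssemblyParams(J=100, m=0.05, nu=0.01, seed=30)
        )
        tab = comm.history_table()
        assert set(tab.columns) >= {
            "species_id", "origin", "first_colonization_step",
            "colonization_count", "trajectory",
        }
        assert len(tab) == len(hist)

    def test_local_phylogeny_newick_parses(self, small_meta):
        import dendropy

        comm = make_comm(small_meta, nu=0.05, m=0.1, seed=31, J=100)
        for _ in range(500):
            comm.step()
        nwk = comm.local_phylogeny_newick()
        if nwk:  # speciation occurred
            for line in nwk.splitlines():
                dendropy.Tree.get(data=line, schema="newick")
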