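"""Tests of the individual-based Wright-Fisher model with niches."""

import numpy as np
import pytest

from hgtsweep.ibm import (
    CommunityState,
    IBMParams,
    SimulationError,
    allocate_resources,
    community_metrics,
    init_community,
    migrate_step,
    niche_weights,
    reproduce,
    run,
    transfer_step,
)


def explicit_state(focal, background, niche, count, n=1):
    """A CommunityState with explicit rows only (empty anonymous buckets)."""
    return CommunityState(
        focal=np.asarray(focal, np.int64),
        background=np.asarray(background, np.int64),
        niche=np.asarray(niche, np.int64),
        count=np.asarray(count, np.int64),
        bucket=np.zeros((n, 2), np.int64),
        next_id=int(np.max(background)) + 1,
    )


class TestInit:
    def test_clonal_start(self):
        st = init_community(IBMParams(N=500, C0=1.0, t_end=0))
        d_f, d_bg, dr = community_metrics(st)
        assert (d_f, d_bg, dr) == (1.0, 1.0, 1.0)

    def test_maximally_diverse_start(self):
        st = init_community(IBMParams(N=500, C0=0.0, t_end=0))
        d_f, d_bg, _ = community_metrics(st)
        assert d_f == pytest.approx(500.0)
        assert d_bg == pytest.approx(500.0)

    def test_exact_carrier_count(self):
        p = IBMParams(N=10**6, C0=1000 / 10**6, t_end=0)
        st = init_community(p)
        assert st.carriers == 1000
        assert st.N == 10**6

    def test_unstartable_sweep_warns(self):
        with pytest.warns(UserWarning, match="cannot start"):
            init_community(IBMParams(N=100, C0=1e-4, t_end=0))


class TestNicheWeights:
    def test_single_niche(self):
        assert niche_weights(IBMParams(N=10, n=1)).tolist() == [1.0]

    def test_full_specialization(self):
        sig = niche_weights(IBMParams(N=10, n=5, z=1.0), niche=2)
        assert sig[2] == 1.0 and sig.sum() == pytest.approx(1.0)
        assert np.count_nonzero(sig) == 1

    def test_uniform_competition(self):
        sig = niche_weights(IBMParams(N=10, n=5, z=0.2), niche=0)
        assert np.allclose(sig, 0.2)

    def test_rows_sum_to_one(self):
        p = IBMParams(N=10, n=7, z=0.6)
        for q in range(7):
            assert niche_weights(p, q).sum() == pytest.approx(1.0)


class TestAllocateResources:
    def test_sole_competitor_takes_whole_share(self):
        p = IBMParams(N=1, n=1)
        st = explicit_state([2], [2], [0], [1])
        assert allocate_resources(st, p).R_i[0] == pytest.approx(1.0)

    def test_symmetry(self):
        p = IBMParams(N=20, n=1, s=0.0)
        st = explicit_state([2, 3], [2, 3], [0, 0], [10, 10])
        R = allocate_resources(st, p).R_i
        assert R[0] == pytest.approx(R[1])

    def test_selection_ratio_single_niche(self):
        # per-capita resources of carriers vs non-carriers are (1+s) : 1
        p = IBMParams(N=100, n=1, s=0.07)
        st = explicit_state([1, 2], [1, 2], [0, 0], [40, 60])
        tab = allocate_resources(st, p)
        assert tab.R_i[0] / tab.R_i[1] == pytest.approx(1.07)

    def test_resource_conservation_per_niche(self):
        # occupied niches hand out exactly their N/n share
        p = IBMParams(N=120, n=3, z=0.5, s=0.1)
        st = explicit_state([1, 2, 3, 4], [1, 2, 3, 4], [0, 1, 2, 1], [30, 40, 25, 25], n=3)
        tab = allocate_resources(st, p)
        handed_out = st.count[:, None] * tab.R_ij
        assert np.allclose(handed_out.sum(axis=0), 120 / 3)
        assert np.allclose(tab.R_i, tab.R_ij.sum(axis=1))
        assert np.allclose(tab.sigma_ij.sum(axis=1), 1.0)

    def test_empty_niche_share_forfeited(self):
        p = IBMParams(N=100, n=2, z=1.0)
        st = explicit_state([2], [2], [0], [100], n=2)
        tab = allocate_resources(st, p)
        assert tab.Omega[1] == 0.0
        # total resources = only the occupied niche's share
        assert (st.count * tab.R_i).sum() == pytest.approx(50.0)


class TestReproduce:
    def test_exact_size_conservation(self):
        p = IBMParams(N=1000, s=0.1, C0=0.3, t_end=0)
        rng = np.random.default_rng(1)
        st = init_community(p, rng)
        for _ in range(20):
            st = reproduce(st, allocate_resources(st, p), rng, p)
            assert st.N == 1000

    def test_mean_carrier_increment_matches_selection_term(self):
        # one-generation expectation s C (1-C) N / (1+sC), the ODE drift
        N, s, C = 1000, 0.2, 0.3
        p = IBMParams(N=N, s=s, C0=C, t_end=0)
        rng = np.random.default_rng(7)
        incs = np.empty(10**4)
        for k in range(len(incs)):
            st = init_community(p, rng)
            c0 = st.carriers
            st = reproduce(st, allocate_resources(st, p), rng, p)
            incs[k] = st.carriers - c0
        expected = s * C * (1 - C) * N / (1 + s * C)
        se = incs.std() / np.sqrt(len(incs))
        assert abs(incs.mean() - expected) < 3 * se

    def test_neutral_heterozygosity_decay(self):
        # classical Wright-Fisher: E[H_t] = (1 - 1/N)^t H_0
        N, T, reps = 300, 60, 400
        p = IBMParams(N=N, t_end=0)
        H = np.empty(reps)
        for k in range(reps):
            st = init_community(IBMParams(N=N, t_end=0, seed=k))
            rng = np.random.default_rng(10_000 + k)
            for _ in range(T):
                st = reproduce(st, allocate_resources(st, p), rng, p)
            cnt = np.concatenate([st.count, st.bucket_lineage_counts()])
            H[k] = 1.0 - (cnt * (cnt - 1.0)).sum() / (N * (N - 1))
        theory = (1 - 1 / N) ** T
        se = H.std() / np.sqrt(reps)
        assert abs(H.mean() - theory) < 4 * se

    def test_no_resources_is_an_error(self):
        p = IBMParams(N=10, n=1)
        st = explicit_state([2], [2], [0], [10])
        tab = allocate_resources(st, p)
        tab.R_i = np.zeros_like(tab.R_i)
        with pytest.raises(SimulationError):
            reproduce(st, tab, np.random.default_rng(0), p)


class TestTransfer:
    def test_no_donors(self):
        p = IBMParams(N=100, r=0.5, C0=0.0, t_end=0)
        st = init_community(p)
        _, flux = transfer_step(st, np.random.default_rng(0), p)
        assert flux == 0

    def test_no_transfer_rate(self):
        p = IBMParams(N=100, r=0.0, C0=0.5, t_end=0)
        st = init_community(p)
        _, flux = transfer_step(st, np.random.default_rng(0), p)
        assert flux == 0

    def test_expected_conversions(self):
        # E[conversions] = r C (1-C) N, the compartment transition rate
        N, C, r = 5000, 0.4, 1e-2
        p = IBMParams(N=N, r=r, C0=C, t_end=0)
        rng = np.random.default_rng(11)
        flux = np.empty(10**4)
        for k in range(len(flux)):
            st = init_community(p, rng)
            _, flux[k] = transfer_step(st, rng, p)
        expected = r * C * (1 - C) * N
        se = flux.std() / np.sqrt(len(flux))
        assert abs(flux.mean() - expected) < 3 * se

    def test_converted_cells_keep_background(self):
        p = IBMParams(N=100, r=1.0, C0=0.5, t_end=0)
        st = explicit_state([1, 7], [1, 7], [0, 0], [50, 50])
        st, flux = transfer_step(st, np.random.default_rng(3), p)
        converted = (st.focal == 1) & (st.background == 7)
        assert flux > 0 and st.count[converted].sum() == flux


class TestMigrate:
    def test_no_migration_is_identity(self):
        p = IBMParams(N=100, m=0.0, C0=0.5, t_end=0)
        st = init_community(p)
        before = st.count.copy()
        st = migrate_step(st, np.random.default_rng(0), p)
        assert np.array_equal(st.count, before)

    def test_total_replacement(self):
        p = IBMParams(N=200, m=1.0, C0=0.5, t_end=0)
        st = init_community(p)
        st = migrate_step(st, np.random.default_rng(0), p)
        assert st.carrier_fraction == 0.0
        assert st.N == 200

    def test_expected_carrier_replacement(self):
        # uniform thinning removes m C N carriers per generation on average
        N, m, C = 5000, 0.05, 0.4
        p = IBMParams(N=N, m=m, C0=C, t_end=0)
        rng = np.random.default_rng(13)
        loss = np.empty(5000)
        for k in range(len(loss)):
            st = init_community(p, rng)
            c0 = st.carriers
            st = migrate_step(st, rng, p)
            loss[k] = c0 - st.carriers
            assert st.N == N
        expected = m * C * N
        se = loss.std() / np.sqrt(len(loss))
        assert abs(loss.mean() - expected) < 3 * se


class TestRun:
    def test_seed_determinism(self):
        p = IBMParams(N=2000, s=0.05, r=1e-3, m=0.02, C0=0.05, n=3, z=0.5,
                      t_end=300, seed=42)
        a = run(p)
        b = run(p)
        assert a.equals(b)

    def test_different_seeds_differ(self):
        kw = dict(N=2000, s=0.05, r=1e-3, m=0.02, C0=0.05, t_end=200)
        a = run(IBMParams(**kw, seed=1))
        b = run(IBMParams(**kw, seed=2))
        assert not a.C.equals(b.C)

    def test_series_layout(self):
        p = IBMParams(N=500, s=0.02, C0=0.1, t_end=50, seed=0)
        df = run(p, metrics_every=10)
        assert list(df.columns) == ["generation", "C", "flux_realized", "D_f", "D_bg", "DR"]
        assert len(df) == 51
        assert df.D_f.notna()[df.generation % 10 == 0].all()
        assert np.isfinite(df.DR.iloc[-1])

    def test_selection_fixes_the_allele_without_migration(self):
        # carriers fix in at least 19 of 20 communities
        fixed = 0
        for k in range(20):
            p = IBMParams(N=10**5, s=0.05, m=0.0, r=0.0, C0=1e-2,
                          t_end=600, seed=1000 + k)
            df = run(p, metrics_every=600)
            fixed += df.C.iloc[-1] == 1.0
        assert fixed >= 19

    def test_mean_trajectory_tracks_the_ode(self):
        # law of large numbers: replicate-mean C(t) follows the compartment ODE
        from hgtsweep import SweepParams, integrate

        t_end, reps = 400, 20
        kw = dict(N=10**4, s=0.05, m=0.02, r=1e-4, C0=0.01)
        series = [
            run(IBMParams(**kw, t_end=t_end, seed=500 + k), metrics_every=t_end).C.values
            for k in range(reps)
        ]
        mean_C = np.mean(series, axis=0)
        sd_C = np.std(series, axis=0) / np.sqrt(reps)
        ode = integrate(
            SweepParams(**kw), t_end, output_grid=np.arange(t_end + 1)
        ).C
        late = slice(50, None)  # skip the noise-dominated start
        assert np.all(np.abs(mean_C[late] - ode[late]) < 4 * sd_C[late] + 0.02)


class TestParams:
    def test_foreign_niche_preference_warns(self):
        with pytest.warns(UserWarning, match="foreign niches"):
            IBMParams(N=10, n=10, z=0.05)

    @pytest.mark.parametrize(
        "kw",
        [dict(N=0), dict(n=0), dict(z=1.5), dict(r=-0.1), dict(m=2.0),
         dict(C0=-0.5), dict(s=-0.2), dict(t_end=-1)],
    )
    def test_domain_violations(self, kw):
        base = dict(N=10, n=1, z=1.0, r=0.0, m=0.0, C0=0.0, s=0.0, t_end=1)
        base.update(kw)
        with pytest.raises(ValueError):
            IBMParams(**base)
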