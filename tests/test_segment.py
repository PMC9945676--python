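import itertools

import numpy as np
import pytest

from dmrseg import segment as sg

from conftest import make_dataset


def brute_force_map_path(model, y):
    """Exhaustive argmax of the joint P(Y, X) over all K^T state sequences."""
    y = np.asarray(y, dtype=float)
    T, K = len(y), model.n_states
    logB = model.log_emission(y)
    with np.errstate(divide="ignore"):
        logA = np.log(model.A)
        logpi = np.log(model.pi)
    paths = np.array(list(itertools.product(range(K), repeat=T)), dtype=np.int64)
    lp = logpi[paths[:, 0]] + logB[np.arange(T), paths].sum(axis=1)
    if T > 1:
        lp = lp + logA[paths[:, :-1], paths[:, 1:]].sum(axis=1)
    best = paths[int(np.argmax(lp))]
    return [model.state_names[j] for j in best]


def random_model(rng, n_states=3):
    A = rng.dirichlet(np.full(n_states, 2.0), size=n_states)
    pi = rng.dirichlet(np.ones(n_states))
    states = [sg.EmissionSpec(f"s{j}", rng.normal(0, 0.4), rng.uniform(0.02, 0.3))
              for j in range(n_states)]
    return sg.HMMModel(states=states, A=A, pi=pi)


def track(y, scale="beta"):
    y = np.asarray(y, dtype=float)
    return sg.ObservationTrack("chr1", np.arange(len(y)), y, scale=scale)


class TestMethylationRatio:
    @pytest.mark.parametrize("nc,nbs,expected", [(5, 10, 0.5), (0, 7, 0.0)])
    def test_ratio(self, nc, nbs, expected):
        assert sg.methylation_ratio(nc, nbs) == expected

    def test_zero_coverage_is_missing(self):
        assert np.isnan(sg.methylation_ratio(0, 0))

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            sg.methylation_ratio(7, 5)


class TestObservationTrack:
    def test_group_mean_difference(self):
        ds = make_dataset(["chr1"], [100],
                          nbs=[[10, 10, 10, 10]], nc=[[8, 6, 2, 4]])
        tracks = sg.build_observation_tracks(ds, ["s1", "s2"], ["s3", "s4"])
        assert tracks[0].y[0] == pytest.approx(0.4)

    def test_identical_counts_give_zero(self):
        ds = make_dataset(["chr1"] * 2, [100, 200],
                          nbs=[[10, 10], [20, 20]], nc=[[3, 3], [11, 11]])
        tracks = sg.build_observation_tracks(ds, ["s1"], ["s2"])
        assert np.allclose(tracks[0].y, 0.0)

    def test_m_scale_half_maps_to_zero(self):
        ds = make_dataset(["chr1"], [100], nbs=[[10, 10]], nc=[[5, 5]])
        tracks = sg.build_observation_tracks(ds, ["s1"], ["s2"], scale="M")
        assert tracks[0].y[0] == pytest.approx(0.0)

    def test_zero_coverage_sample_excluded_from_group_mean(self):
        ds = make_dataset(["chr1"], [100], nbs=[[10, 0, 10]], nc=[[8, 0, 2]])
        tracks = sg.build_observation_tracks(ds, ["s1", "s2"], ["s3"])
        assert tracks[0].y[0] == pytest.approx(0.6)

    def test_cpg_dropped_when_whole_group_uncovered(self):
        ds = make_dataset(["chr1"] * 2, [100, 200],
                          nbs=[[10, 10], [0, 10]], nc=[[5, 5], [0, 5]])
        tracks = sg.build_observation_tracks(ds, ["s1"], ["s2"])
        assert len(tracks[0]) == 1 and tracks[0].site_index[0] == 0

    def test_empty_or_overlapping_groups_rejected(self):
        ds = make_dataset(["chr1"], [100], nbs=[[10, 10]], nc=[[5, 5]])
        with pytest.raises(ValueError):
            sg.build_observation_tracks(ds, [], ["s2"])
        with pytest.raises(ValueError):
            sg.build_observation_tracks(ds, ["s1"], ["s1"])


class TestDefaultEmissions:
    @pytest.mark.parametrize("n_states,scale,means,sds", [
        (3, "beta", {"equal": 0.0, "hyper": 0.3, "hypo": -0.3},
         {"equal": 0.08, "hyper": 0.06, "hypo": 0.06}),
        (5, "beta", {"equal": 0.0, "hypo1": -0.25, "hypo2": -0.5,
                     "hyper1": 0.25, "hyper2": 0.5},
         {"equal": 0.08, "hypo1": 0.06, "hypo2": 0.06, "hyper1": 0.06, "hyper2": 0.06}),
        (3, "M", {"equal": 0.0, "hyper": 1.7, "hypo": -1.7},
         {"equal": 0.5, "hyper": 0.5, "hypo": 0.5}),
    ])
    def test_defaults(self, n_states, scale, means, sds):
        spec = {s.name: s for s in sg.default_emissions(n_states, scale)}
        assert {k: v.mean for k, v in spec.items()} == means
        assert {k: v.sd for k, v in spec.items()} == sds

    def test_unsupported_configuration(self):
        with pytest.raises(ValueError):
            sg.default_emissions(4, "beta")


class TestViterbi:
    def test_single_observation_decodes_to_densest_state(self):
        model = sg.default_model()
        model.pi = np.full(3, 1 / 3)
        assert sg.viterbi_decode(model, track([0.3])) == ["hyper"]
        assert sg.viterbi_decode(model, track([0.0])) == ["equal"]

    def test_matches_exhaustive_search(self, rng):
        for _ in range(60):
            model = random_model(rng)
            T = int(rng.integers(1, 9))
            y = rng.normal(0, 0.4, T)
            assert sg.viterbi_decode(model, track(y, "M")) == \
                brute_force_map_path(model, y)

    def test_matches_hmmlearn(self, rng):
        from hmmlearn.hmm import GaussianHMM

        model = sg.default_model()
        y = np.clip(rng.normal(0, 0.25, 300), -1, 1)
        ref = GaussianHMM(n_components=3, covariance_type="diag", init_params="")
        ref.startprob_ = model.pi
        ref.transmat_ = model.A
        ref.means_ = np.array([[s.mean] for s in model.states])
        ref.covars_ = np.array([[s.sd**2] for s in model.states])
        _, ref_path = ref.decode(y[:, None])
        assert sg.viterbi_decode(model, track(y)) == \
            [model.state_names[j] for j in ref_path]

    def test_non_finite_observation_rejected(self):
        with pytest.raises(ValueError):
            sg.viterbi_decode(sg.default_model(), track([0.1, np.nan]))


class TestBaumWelch:
    def test_loglik_non_decreasing(self, rng):
        model = sg.default_model()
        y = np.clip(rng.normal(0, 0.2, 300), -1, 1)
        _, trace = sg.fit_transitions_baum_welch(model, [track(y)], max_iter=15)
        assert (np.diff(trace) >= -1e-8).all()

    def test_loglik_matches_hmmlearn(self, rng):
        from hmmlearn.hmm import GaussianHMM

        model = sg.default_model()
        y = np.clip(rng.normal(0, 0.25, 200), -1, 1)
        ref = GaussianHMM(n_components=3, covariance_type="diag", init_params="")
        ref.startprob_ = model.pi
        ref.transmat_ = model.A
        ref.means_ = np.array([[s.mean] for s in model.states])
        ref.covars_ = np.array([[s.sd**2] for s in model.states])
        assert sg.log_likelihood(model, [track(y)]) == pytest.approx(
            ref.score(y[:, None]), abs=1e-8)

    def test_zero_track_strengthens_equal_self_transition(self):
        model = sg.default_model()
        fitted, _ = sg.fit_transitions_baum_welch(model, [track(np.zeros(100))],
                                                  max_iter=10)
        i = fitted.state_names.index("equal")
        assert fitted.A[i, i] > model.A[i, i]

    def test_emissions_untouched_by_default(self, rng):
        model = sg.default_model()
        before = [(s.mean, s.sd) for s in model.states]
        fitted, _ = sg.fit_transitions_baum_welch(
            model, [track(np.clip(rng.normal(0, 0.3, 150), -1, 1))], max_iter=5)
        assert [(s.mean, s.sd) for s in fitted.states] == before
        assert not np.allclose(fitted.A, model.A)  # transitions did move

    def test_all_tracks_empty_is_an_error(self):
        with pytest.raises(ValueError):
            sg.fit_transitions_baum_welch(sg.default_model(), [])

    def test_unspecified_emissions_recover_cluster_structure(self, rng):
        y = np.concatenate([rng.normal(0, 0.05, 400),
                            rng.normal(0.4, 0.05, 100),
                            rng.normal(-0.4, 0.05, 100)])
        rng.shuffle(y)
        model = sg.fit_unspecified_emissions([track(np.clip(y, -1, 1))], seed=0)
        names = set(model.state_names)
        assert names == {"equal", "hypo", "hyper"}
        spec = {s.name: s.mean for s in model.states}
        assert abs(spec["equal"]) < 0.1 and spec["hyper"] > 0.25 and spec["hypo"] < -0.25


class TestRegions:
    def _decoded(self, states, nbs=None, nc=None):
        T = len(states)
        nbs = nbs if nbs is not None else [[10, 10]] * T
        nc = nc if nc is not None else [[3, 7]] * T
        ds = make_dataset(["chr1"] * T, (np.arange(T) + 1) * 100, nbs=nbs, nc=nc)
        tr = sg.ObservationTrack("chr1", np.arange(T), np.zeros(T))
        return ds, tr, list(states)

    def test_runs_merge(self):
        ds, tr, states = self._decoded(["equal", "hyper", "hyper", "equal"])
        regions = sg.merge_state_runs(ds, tr, states)
        assert [r.n_cpgs for r in regions] == [1, 2, 1]
        assert [r.state for r in regions] == ["equal", "hyper", "equal"]
        assert (regions[1].start_pos, regions[1].end_pos) == (200, 300)

    def test_counts_aggregate_over_members(self):
        ds, tr, states = self._decoded(["hyper", "hyper"],
                                       nbs=[[10, 9], [20, 19]], nc=[[3, 2], [7, 6]])
        (region,) = sg.merge_state_runs(ds, tr, states)
        assert region.nbs.tolist() == [30, 28]
        assert region.nc.tolist() == [10, 8]

    def test_uniform_states_give_single_region(self):
        ds, tr, states = self._decoded(["equal"] * 7)
        assert len(sg.merge_state_runs(ds, tr, states)) == 1

    def test_partition_and_count_conservation(self, rng):
        T = 200
        states = [["equal", "hypo", "hyper"][j] for j in rng.integers(0, 3, T)]
        nbs = rng.integers(1, 40, (T, 3))
        nc = rng.binomial(nbs, 0.4)
        ds, tr, _ = self._decoded(states, nbs=nbs, nc=nc)
        regions = sg.merge_state_runs(ds, tr, states)
        assert sum(r.n_cpgs for r in regions) == T
        assert np.concatenate([r.site_indices for r in regions]).tolist() == list(range(T))
        assert sum(r.nbs.sum() for r in regions) == nbs.sum()
        assert sum(r.nc.sum() for r in regions) == nc.sum()

    def test_label_symmetry_under_sign_flip(self, rng):
        # default A/pi are symmetric under the hypo<->hyper permutation, so
        # negating the observations mirrors the decoded labels; additionally
        # swapping the hypo/hyper emission means restores the original labels
        model = sg.default_model()
        y = np.clip(rng.normal(0, 0.25, 250), -1, 1)
        flip = {"hypo": "hyper", "hyper": "hypo", "equal": "equal"}
        path = sg.viterbi_decode(model, track(y))
        assert sg.viterbi_decode(model, track(-y)) == [flip[s] for s in path]
        swapped = sg.HMMModel(
            states=[sg.EmissionSpec(s.name, -s.mean, s.sd) for s in model.states],
            A=model.A, pi=model.pi)
        assert sg.viterbi_decode(swapped, track(-y)) == path


class TestCandidateSelection:
    def _regions(self, states, widths):
        out = []
        for state, w in zip(states, widths):
            out.append(sg.Region(chrom="chr1", start_pos=1, end_pos=w, state=state,
                                 site_indices=np.arange(w), nbs=np.array([w]),
                                 nc=np.array([0])))
        return out

    def test_hypo_hyper_mode_drops_equal(self):
        regions = self._regions(["equal", "hyper", "hypo", "equal"], [3, 3, 3, 3])
        kept = sg.select_candidate_regions(regions, mode="hypo_hyper")
        assert [r.state for r in kept] == ["hyper", "hypo"]

    def test_five_state_families_are_candidates(self):
        regions = self._regions(["equal", "hypo2", "hyper1"], [2, 2, 2])
        kept = sg.select_candidate_regions(regions, mode="hypo_hyper")
        assert [r.state for r in kept] == ["hypo2", "hyper1"]

    def test_min_cpgs_reproduces_gt25_filter(self):
        regions = self._regions(["hyper", "hyper"], [3, 30])
        kept = sg.select_candidate_regions(regions, min_cpgs=26)
        assert len(kept) == 1 and kept[0].n_cpgs == 30

    def test_all_mode_is_identity(self):
        regions = self._regions(["equal", "hyper"], [1, 2])
        assert sg.select_candidate_regions(regions) == regions

    def test_caller_supplied_candidate_states(self):
        regions = self._regions(["s0", "s1", "s2"], [2, 2, 2])
        kept = sg.select_candidate_regions(regions, mode="hypo_hyper",
                                           candidate_states=["s1"])
        assert [r.state for r in kept] == ["s1"]
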