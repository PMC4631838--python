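import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intmod.representation import GMM
from intmod.restraints import (
    NuisanceParams,
    PosteriorScorer,
    RestraintParams,
    connectivity_score,
    crosslink_likelihood,
    em_score,
    excluded_volume_score,
    forward_model,
    gmm_overlap,
    redundancy_weight,
    sigma_prior,
)
from intmod.sampling import ModelState


def mc_forward_model(d, si, sj, l, n, seed=0):
    """Monte-Carlo oracle: sample points uniformly in both spheres."""
    r = np.random.default_rng(seed)

    def ball(radius, size):
        v = r.normal(size=(size, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        return v * radius * r.random(size)[:, None] ** (1 / 3)

    u = ball(si, n)
    v = ball(sj, n) + np.array([d, 0.0, 0.0])
    return float((np.linalg.norm(u - v, axis=1) <= l).mean())


class TestForwardModel:
    def test_far_apart_is_exactly_zero(self):
        assert forward_model(50.0, 1.0, 1.0, 21.0) == 0.0

    def test_coincident_small_spheres_exactly_one(self):
        assert forward_model(0.0, 1.0, 1.0, 21.0) == 1.0

    @pytest.mark.parametrize(
        "d,si,sj,l",
        [(21.0, 5.0, 5.0, 21.0), (10.0, 3.0, 7.0, 12.0), (15.0, 8.0, 2.0, 18.0)],
    )
    def test_matches_monte_carlo(self, d, si, sj, l):
        n = 200_000
        mc = mc_forward_model(d, si, sj, l, n)
        se = np.sqrt(mc * (1 - mc) / n)
        assert abs(forward_model(d, si, sj, l) - mc) < 3 * se + 1e-9

    @settings(max_examples=30, deadline=None)
    @given(
        si=st.floats(0.5, 12.0),
        sj=st.floats(0.5, 12.0),
        l=st.floats(2.0, 30.0),
    )
    def test_monotone_nonincreasing_in_distance(self, si, sj, l):
        ds = np.linspace(0, 50, 40)
        f = forward_model(ds, si, sj, l)
        assert np.all(np.diff(f) <= 1e-10)
        assert np.all((f >= 0) & (f <= 1))

    @settings(max_examples=30, deadline=None)
    @given(
        d=st.floats(0.0, 40.0),
        si=st.floats(0.5, 12.0),
        sj=st.floats(0.5, 12.0),
    )
    def test_monotone_nondecreasing_in_linker_length(self, d, si, sj):
        ls = np.linspace(1, 40, 30)
        f = np.array([forward_model(d, si, sj, l) for l in ls])
        assert np.all(np.diff(f) >= -1e-10)

    def test_rejects_invalid_radii(self):
        with pytest.raises(ValueError):
            forward_model(5.0, 0.0, 1.0, 21.0)


class TestLikelihood:
    def test_formula_endpoints(self):
        assert crosslink_likelihood(1.0, 0.05) == pytest.approx(0.95)
        assert crosslink_likelihood(0.0, 0.05) == pytest.approx(0.05)

    def test_half_is_fixed_point_for_any_psi(self):
        for psi in (0.01, 0.2, 0.3):
            assert crosslink_likelihood(0.5, psi) == pytest.approx(0.5)

    def test_redundancy_weight_capped(self):
        assert redundancy_weight(1) == 1.0
        assert redundancy_weight(4) == 3.0
        assert redundancy_weight(1000) == 4.0


class TestGmmOverlap:
    def test_identical_unit_gaussians_closed_form(self):
        g = GMM(np.ones(1), np.zeros((1, 3)), np.eye(3)[None])
        assert gmm_overlap(g, g) == pytest.approx((4 * np.pi) ** -1.5, abs=1e-9)

    def test_closed_form_matches_grid_integration(self):
        a = GMM(np.array([0.7, 0.3]), np.array([[0, 0, 0], [4, 1, 0]]),
                np.stack([np.eye(3), 2 * np.eye(3)]))
        b = GMM(np.array([1.0]), np.array([[1.0, 0.0, 0.0]]), 1.5 * np.eye(3)[None])
        ax = np.arange(-12, 16, 0.4)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
        numeric = (a.density(pts) * b.density(pts)).sum() * 0.4**3
        assert gmm_overlap(a, b) == pytest.approx(numeric, rel=1e-3)

    def test_distant_means_vanish(self):
        a = GMM(np.ones(1), np.zeros((1, 3)), np.eye(3)[None])
        b = GMM(np.ones(1), np.array([[1000.0, 0, 0]]), np.eye(3)[None])
        assert gmm_overlap(a, b) < 1e-30

    def test_symmetric_on_random_mixtures(self, rng):
        def rand_gmm(k):
            covs = []
            for _ in range(k):
                a = rng.normal(size=(3, 3))
                covs.append(a @ a.T + 2 * np.eye(3))
            return GMM(rng.random(k), rng.normal(scale=5, size=(k, 3)), np.stack(covs))

        for _ in range(5):
            a, b = rand_gmm(3), rand_gmm(2)
            assert gmm_overlap(a, b) == pytest.approx(gmm_overlap(b, a), rel=1e-12)


class TestEmScore:
    def test_identical_mixtures_score_zero(self, rng):
        for _ in range(5):
            k = int(rng.integers(1, 4))
            covs = []
            for _ in range(k):
                a = rng.normal(size=(3, 3))
                covs.append(a @ a.T + 2 * np.eye(3))
            g = GMM(rng.random(k) + 0.1, rng.normal(scale=8, size=(k, 3)), np.stack(covs))
            assert em_score(g, g) == pytest.approx(0.0, abs=1e-9)

    def test_displaced_model_scores_high(self):
        g = GMM(np.ones(1), np.zeros((1, 3)), 4 * np.eye(3)[None])
        far = GMM(np.ones(1), np.array([[200.0, 0, 0]]), 4 * np.eye(3)[None])
        assert em_score(far, g) > 100.0

    def test_cc_matches_grid_integration_on_2v2_fixture(self):
        m = GMM(np.array([0.6, 0.4]), np.array([[0, 0, 0], [6, 0, 0]]),
                np.stack([4 * np.eye(3), 6 * np.eye(3)]))
        d = GMM(np.array([0.5, 0.5]), np.array([[1, 1, 0], [5, -1, 0]]),
                np.stack([5 * np.eye(3), 5 * np.eye(3)]))
        ax = np.arange(-14, 20, 0.4)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
        fm, fd = m.density(pts), d.density(pts)
        cc_numeric = 2 * (fm * fd).sum() / ((fm**2).sum() + (fd**2).sum())
        cc_closed = np.exp(-em_score(m, d, scale=1.0))
        assert cc_closed == pytest.approx(cc_numeric, abs=1e-3)


class TestStructuralPriors:
    def test_separated_beads_have_zero_excluded_volume(self):
        centers = np.array([[0, 0, 0], [10.0, 0, 0]])
        assert excluded_volume_score(centers, np.array([3.0, 3.0])) == 0.0

    def test_overlapping_beads_penalized_harmonically(self):
        centers = np.array([[0, 0, 0], [4.0, 0, 0]])
        # overlap = 3 + 3 - 4 = 2 -> 0.5 * 2^2
        assert excluded_volume_score(centers, np.array([3.0, 3.0])) == pytest.approx(2.0)

    def test_connectivity_threshold_rule(self):
        assert connectivity_score(np.array([24.0]), np.array([3.0]), np.array([3.0])) == 0.0
        assert connectivity_score(np.array([25.0]), np.array([3.0]), np.array([3.0])) == pytest.approx(0.5)

    def test_sigma_prior_flat_inside_bounds(self):
        assert sigma_prior(50.0) == 0.0
        assert sigma_prior(-1.0) == np.inf
        assert sigma_prior(101.0) == np.inf


class TestPosteriorScorer:
    def test_single_link_score_value(self, toy):
        """A fully satisfied link (f = 1) with psi = 0.05 and weight 1
        contributes -log 0.95."""
        model = toy["model"]
        xl = [x for x in toy["xlset"] if x.n_spectra == 1][0]
        from intmod.xl_dataset import CrossLinkSet

        scorer = PosteriorScorer(model, CrossLinkSet.from_links([xl]))
        state = ModelState.reference(model)
        # place sigma large enough that f -> 1 cannot be guaranteed; instead
        # compute with a forced distance-0 configuration via the raw formula
        f = 1.0
        expected = -np.log(crosslink_likelihood(f, 0.05))
        assert expected == pytest.approx(0.0513, abs=1e-4)
        d = scorer.link_distances(state)
        sig = state.nuisances.sigma
        f_real = forward_model(d[0], sig, sig, scorer.xl_length[0])
        manual = -redundancy_weight(xl.n_spectra) * np.log(
            crosslink_likelihood(f_real, 0.05)
        )
        assert scorer.crosslink_score(state) == pytest.approx(float(manual), abs=1e-9)

    def test_joint_score_is_sum_of_per_link_terms(self, toy, truth_state):
        from intmod.xl_dataset import CrossLinkSet

        model = toy["model"]
        links = toy["xlset"].links[:10]
        whole = PosteriorScorer(model, CrossLinkSet.from_links(links))
        total = whole.crosslink_score(truth_state)
        parts = sum(
            PosteriorScorer(model, CrossLinkSet.from_links([xl])).crosslink_score(truth_state)
            for xl in links
        )
        assert total == pytest.approx(parts, abs=1e-9)

    def test_matches_naive_loop_evaluation(self, toy, truth_state):
        """Independent re-implementation: loop over links, evaluate the
        forward model and likelihood one by one."""
        model, xlset = toy["model"], toy["xlset"]
        scorer = PosteriorScorer(model, xlset)
        st = truth_state
        sig = st.nuisances.sigma
        naive = 0.0
        for xl in xlset:
            a = model.endpoint_coords(st, [model.endpoint_of(xl.protein1, xl.residue1)])[0]
            b = model.endpoint_coords(st, [model.endpoint_of(xl.protein2, xl.residue2)])[0]
            d = float(np.linalg.norm(a - b))
            f = forward_model(d, sig, sig, 21.0)
            psi = st.nuisances.psi[xl.xl_class or "intra_module"]
            w = min(1.0 + np.log2(xl.n_spectra), 4.0)
            naive += -w * np.log(crosslink_likelihood(f, psi))
        assert scorer.crosslink_score(st) == pytest.approx(naive, abs=1e-9)

    def test_breakdown_total_is_sum_of_terms(self, toy_scorer, truth_state):
        bd = toy_scorer.evaluate(truth_state)
        manual = (
            bd.crosslink + bd.em + bd.excluded_volume + bd.connectivity + bd.linear + bd.sigma_prior
        )
        assert bd.total == pytest.approx(manual, abs=1e-9)

    def test_moving_violated_link_closer_lowers_score(self, toy):
        from intmod.xl_dataset import CrossLink, CrossLinkSet

        model = toy["model"]
        # link between two mobile bodies, far apart after displacement
        xl = CrossLink("C", 10, "D", 10, 1, "t")
        scorer = PosteriorScorer(model, CrossLinkSet.from_links([xl]))
        st = ModelState.reference(model)
        st.nuisances = NuisanceParams(sigma=30.0)  # keep f > 0 at both distances
        ci = [i for i, b in enumerate(model.rigid_bodies) if b.name == "C"][0]
        far = st.copy()
        far.trans[ci] = far.trans[ci] + np.array([40.0, 0, 0])
        nearer = st.copy()  # reference distance, inside the sensitive range
        assert scorer.crosslink_score(nearer) < scorer.crosslink_score(far)

    def test_scores_finite_for_random_states_in_box(self, toy, toy_scorer, rng):
        from intmod.sampling import random_initial_state

        model = toy["model"]
        g = toy["data_gmm"]
        lo, hi = g.means.min(0) - 20, g.means.max(0) + 20
        for _ in range(10):
            st = random_initial_state(model, rng, lo, hi)
            st.nuisances.sigma = float(rng.uniform(0.5, 100.0))
            bd = toy_scorer.evaluate(st)
            assert np.isfinite(bd.total)

    def test_out_of_bounds_sigma_is_rejected_with_infinite_score(self, toy_scorer, truth_state):
        st = truth_state.copy()
        st.nuisances = NuisanceParams(sigma=150.0)
        assert toy_scorer.evaluate(st).total == np.inf

    def test_params_validation(self):
        with pytest.raises(ValueError):
            RestraintParams(l_xl=-1.0)
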