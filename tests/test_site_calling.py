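import itertools

import numpy as np
import pytest
from scipy.stats import norm

from regland import site_calling as hmm
from regland.footprints import Footprint


def random_params(rng):
    t = rng.dirichlet([5, 1], size=2)
    means = np.sort(rng.normal(0, 1, 2))
    sds = rng.uniform(0.2, 1.5, 2)
    pi = rng.dirichlet([1, 1])
    return hmm.HmmParams(transition=t, initial=pi, means=means, sds=sds)


def enumerate_loglik(params, values):
    """Brute-force sum over all 2^L state paths (independent oracle)."""
    L = len(values)
    total = 0.0
    for path in itertools.product([0, 1], repeat=L):
        p = params.initial[path[0]] * norm.pdf(values[0], params.means[path[0]], params.sds[path[0]])
        for t in range(1, L):
            p *= params.transition[path[t - 1], path[t]]
            p *= norm.pdf(values[t], params.means[path[t]], params.sds[path[t]])
        total += p
    return np.log(total)


def enumerate_viterbi(params, values):
    L = len(values)
    best, best_lp = None, -np.inf
    for path in itertools.product([0, 1], repeat=L):
        lp = np.log(params.initial[path[0]]) + norm.logpdf(
            values[0], params.means[path[0]], params.sds[path[0]]
        )
        for t in range(1, L):
            lp += np.log(params.transition[path[t - 1], path[t]])
            lp += norm.logpdf(values[t], params.means[path[t]], params.sds[path[t]])
        if lp > best_lp:
            best, best_lp = path, lp
    return np.array(best)


class TestParams:
    def test_non_stochastic_transition(self):
        with pytest.raises(ValueError):
            hmm.HmmParams(
                transition=np.array([[0.5, 0.6], [0.5, 0.5]]),
                initial=np.array([0.5, 0.5]),
                means=np.array([0.0, 1.0]),
                sds=np.array([1.0, 1.0]),
            )

    def test_ordered(self):
        p = hmm.HmmParams(
            transition=np.array([[0.7, 0.3], [0.4, 0.6]]),
            initial=np.array([0.2, 0.8]),
            means=np.array([1.0, 0.0]),
            sds=np.array([0.5, 0.1]),
        ).ordered()
        assert p.means[0] < p.means[1]
        assert p.sds[0] == 0.1

    def test_json_roundtrip(self, tmp_path):
        p = random_params(np.random.default_rng(0))
        path = tmp_path / "p.json"
        p.to_json(path)
        q = hmm.HmmParams.from_json(path)
        assert np.allclose(p.transition, q.transition)
        assert np.allclose(p.means, q.means)


class TestForward:
    def test_single_state_chain(self):
        p = hmm.HmmParams(
            transition=np.array([[1.0, 0.0], [0.0, 1.0]]),
            initial=np.array([1.0, 0.0]),
            means=np.array([0.0, 5.0]),
            sds=np.array([1.0, 1.0]),
        )
        values = np.array([0.1, -0.2, 0.3])
        expected = norm.logpdf(values, 0.0, 1.0).sum()
        assert hmm.forward_loglik(p, values) == pytest.approx(expected, abs=1e-10)

    def test_matches_enumeration_L3(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = random_params(rng)
            values = rng.normal(0, 1, 3)
            assert hmm.forward_loglik(p, values) == pytest.approx(
                enumerate_loglik(p, values), abs=1e-9
            )

    def test_append_bound(self):
        rng = np.random.default_rng(2)
        p = random_params(rng)
        values = rng.normal(0, 1, 10)
        extra = 0.5
        base = hmm.forward_loglik(p, values)
        ext = hmm.forward_loglik(p, np.append(values, extra))
        dens = [norm.logpdf(extra, p.means[s], p.sds[s]) for s in (0, 1)]
        assert min(dens) - 1e-9 <= ext - base <= max(dens) + 1e-9

    def test_forward_backward_consistency(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = random_params(rng)
            values = rng.normal(0, 1, 50)
            f = hmm.forward_loglik(p, values)
            b = hmm.backward_loglik(p, values)
            assert f == pytest.approx(b, abs=1e-6)

    def test_posterior_normalized(self):
        rng = np.random.default_rng(4)
        p = random_params(rng)
        values = rng.normal(0, 1, 80)
        post = hmm.posterior_site_probability(p, values)
        assert ((post >= 0) & (post <= 1)).all()


class TestViterbi:
    def test_matches_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = random_params(rng)
            L = int(rng.integers(2, 13))
            values = rng.normal(0, 1, L)
            got = hmm.viterbi_path(p, values)
            assert np.array_equal(got, enumerate_viterbi(p, values))


class TestFit:
    def sample_chain(self, seed, L=2000, means=(0.02, 0.4), sd=0.02):
        rng = np.random.default_rng(seed)
        T = np.array([[0.97, 0.03], [0.08, 0.92]])
        state, vals = 0, []
        for _ in range(L):
            vals.append(rng.normal(means[state], sd))
            state = rng.choice(2, p=T[state])
        return np.array(vals)

    def test_parameter_recovery(self):
        vals = self.sample_chain(7)
        params, _ = hmm.fit_hmm(vals, seed=0)
        assert abs(params.means[0] - 0.02) / 0.02 < 0.2
        assert abs(params.means[1] - 0.4) / 0.4 < 0.2

    def test_monotone_loglik(self):
        vals = self.sample_chain(8, L=500)
        _, trace = hmm.fit_hmm(vals, seed=0, tol=0.0, max_iter=50)
        diffs = np.diff(trace)
        assert (diffs >= -1e-8).all()

    def test_determinism(self):
        vals = self.sample_chain(9, L=300)
        p1, _ = hmm.fit_hmm(vals, seed=3, init="random")
        p2, _ = hmm.fit_hmm(vals, seed=3, init="random")
        assert np.allclose(p1.transition, p2.transition)
        assert np.allclose(p1.means, p2.means)

    def test_constant_input_error(self):
        with pytest.raises(ValueError, match="classification"):
            hmm.fit_hmm(np.ones(100), seed=0)


def step_params(lo=0.0, hi=1.0, sd=0.05):
    return hmm.HmmParams(
        transition=np.array([[0.95, 0.05], [0.05, 0.95]]),
        initial=np.array([0.5, 0.5]),
        means=np.array([lo, hi]),
        sds=np.array([sd, sd]),
    )


def make_fp(values):
    values = np.asarray(values, float)
    return Footprint("p", "c", 0, labels=np.arange(values.size) - 115, mi=values)


class TestDecode:
    def test_no_sites(self):
        params = step_params(hi=10.0)  # site state far above the data
        fp = make_fp(np.zeros(60))
        assert hmm.decode_sites(fp, params) == []

    def test_merge_gap_rule(self):
        signal = np.zeros(60)
        signal[10:20] = 1.0
        signal[22:32] = 1.0  # separated by 2 background positions
        fp = make_fp(signal)
        params = step_params()
        two = hmm.decode_sites(fp, params, merge_gap=1)
        one = hmm.decode_sites(fp, params, merge_gap=3)
        assert len(two) == 2
        assert len(one) == 1
        assert (one[0].start, one[0].end) == (10, 32)

    def test_min_len_drop(self):
        signal = np.zeros(60)
        signal[10:13] = 1.0
        fp = make_fp(signal)
        assert hmm.decode_sites(fp, step_params(), min_len=4) == []
        assert len(hmm.decode_sites(fp, step_params(), min_len=3)) == 1

    def test_boundary_recovery(self, simulated_repressor):
        """Called repressor interval within +-3 bp of the true site."""
        window, _, _, _, fp = simulated_repressor
        params, _ = hmm.fit_hmm(fp.mi_smoothed, seed=0)
        calls = [c for c in hmm.decode_sites(fp, params) if c.sign == hmm.SIGN_REPRESSOR]
        assert len(calls) == 1
        assert abs(calls[0].label_start - (-75)) <= 3
        assert abs(calls[0].label_end - (-60)) <= 3

    def test_viterbi_mode(self):
        signal = np.zeros(60)
        signal[20:40] = 1.0
        fp = make_fp(signal)
        calls = hmm.decode_sites(fp, step_params(), use_viterbi=True)
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end) == (20, 40)


class TestSiteSign:
    def make_call(self, start=10, end=15):
        return hmm.BindingSiteCall(
            promoter="p", condition="c", start=start, end=end,
            label_start=start - 115, label_end=end - 115,
            mean_mi=0.1, mean_posterior=0.9,
        )

    def test_all_positive_repressor(self):
        shift = np.zeros((30, 4))
        shift[:, 1:] = 0.5
        call = hmm.site_sign(self.make_call(), shift)
        assert call.sign == hmm.SIGN_REPRESSOR

    def test_all_negative_activator(self):
        shift = np.zeros((30, 4))
        shift[:, 1:] = -0.5
        call = hmm.site_sign(self.make_call(), shift)
        assert call.sign == hmm.SIGN_ACTIVATOR

    def test_all_missing_undetermined(self):
        shift = np.full((30, 4), np.nan)
        shift[:, 0] = 0.0
        call = hmm.site_sign(self.make_call(), shift)
        assert call.sign == hmm.SIGN_UNDETERMINED

    def test_sigma_overlap(self):
        shift = np.zeros((160, 4))
        shift[:, 1:] = 0.5
        inside = hmm.site_sign(self.make_call(start=100, end=110), shift)  # labels [-15,-5)
        outside = hmm.site_sign(self.make_call(start=10, end=20), shift)   # labels [-105,-95)
        assert inside.sigma_overlap
        assert not outside.sigma_overlap


def test_bed_output(tmp_path):
    call = hmm.BindingSiteCall(
        promoter="p1", condition="c", start=5, end=20,
        label_start=-110, label_end=-95, mean_mi=0.1, mean_posterior=0.876,
        sign=hmm.SIGN_REPRESSOR,
    )
    path = tmp_path / "sites.bed"
    hmm.write_sites_bed([call], path)
    line = path.read_text().strip().split("\t")
    assert line[:4] == ["p1", "5", "20", hmm.SIGN_REPRESSOR]
    assert line[4] == "876"
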