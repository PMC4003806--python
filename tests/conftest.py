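import numpy as np
import pytest

from bsahmm.markers import MarkerSite, MarkerTrack


@pytest.fixture
def rng():
    return np.random.default_rng(20140319)


@pytest.fixture
def small_track():
    """Five well-spaced sites on one chromosome, balanced counts."""
    return MarkerTrack.from_arrays(
        "chrI",
        positions=[100, 200, 300, 400, 500],
        superior=[10, 11, 9, 10, 12],
        total=[20, 22, 20, 20, 24],
    )


def make_track(positions, superior, total, chrom="chrI", qualities=None):
    return MarkerTrack.from_arrays(chrom, positions, superior, total, qualities)


@pytest.fixture
def make_track_fn():
    return make_track


def enumerate_posteriors(track, em, tr):
    """Brute-force smoothing posteriors by summing over all 2^L state paths.

    Independent oracle for forward-backward: path probability is the product
    of the initial probability, per-interval transition probabilities and
    per-site beta-binomial emissions; the P-state posterior at a site is the
    total probability of paths in state P there, normalized by the total
    over all paths.
    """
    from itertools import product

    from bsahmm.emission import betabinom_log_pmf
    from bsahmm.hmm import stay_probabilities

    L = len(track)
    k = track.superior
    n = track.total
    e = np.empty((2, L))  # state 0 = N, 1 = P
    e[0] = np.exp(np.atleast_1d(betabinom_log_pmf(k, n, em.alpha_n, em.beta_n)))
    e[1] = np.exp(np.atleast_1d(betabinom_log_pmf(k, n, em.alpha_p, em.beta_p)))
    pi = np.array([tr.pi_n, tr.pi_p])
    if L > 1:
        tau_n, tau_p = stay_probabilities(track.positions, tr)
    total = 0.0
    in_p = np.zeros(L)
    for path in product((0, 1), repeat=L):
        w = pi[path[0]] * e[path[0], 0]
        for i in range(1, L):
            prev, cur = path[i - 1], path[i]
            if prev == 0:
                w *= tau_n[i - 1] if cur == 0 else 1.0 - tau_n[i - 1]
            else:
                w *= tau_p[i - 1] if cur == 1 else 1.0 - tau_p[i - 1]
            w *= e[cur, i]
        total += w
        for i, st in enumerate(path):
            if st == 1:
                in_p[i] += w
    return in_p / total


@pytest.fixture
def brute_force_posteriors():
    return enumerate_posteriors


def random_instance(rng, L, max_gap=50_000, max_n=30):
    """A random small HMM instance: track + emission + transition params."""
    from bsahmm.emission import EmissionParams
    from bsahmm.hmm import TransitionParams

    gaps = rng.integers(1, max_gap, size=L)
    positions = np.cumsum(gaps) + 1
    n = rng.integers(1, max_n, size=L)
    k = rng.integers(0, n + 1)
    track = MarkerTrack.from_arrays("rnd", positions, k, n)
    em = EmissionParams(
        alpha_n=float(rng.uniform(0.5, 50)),
        beta_n=float(rng.uniform(0.5, 50)),
        alpha_p=float(rng.uniform(1, 50)),
        beta_p=float(rng.uniform(0.5, 5)),
    )
    pi_p = float(rng.uniform(0.1, 0.9))
    tr = TransitionParams(
        r=float(10 ** rng.uniform(-7, -4)),
        s=float(rng.uniform(0.3, 3.0)),
        pi_n=1.0 - pi_p,
        pi_p=pi_p,
    )
    return track, em, tr


@pytest.fixture
def random_instance_fn():
    return random_instance
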