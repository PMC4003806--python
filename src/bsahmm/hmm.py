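"""Two-state linkage HMM: transitions, forward-backward smoothing, region calling.

Hidden states per marker site: P (phenotype-linked, superior-allele skewed
counts) and N (neutral, ~50/50 counts).  Linkage disequilibrium enters
through distance-dependent transition probabilities: over an inter-marker
gap of l bp the chain stays in its state with probability e^(-r*l)
(e^(-r*l*s) for the P state), where r is a per-bp recombination-scale rate
(default 3.5e-6).  Nearby markers are therefore very likely to share a
state, and state persistence decays exponentially with distance.

Posteriors are exact smoothing probabilities from a scaled forward-backward
pass with beta-binomial emissions; with two states the linkage probability
P(P_i | D) / (P(P_i | D) + P(N_i | D)) is simply the normalized P-state
posterior.  Significant markers (posterior > cutoff, default 0.95) are
grouped into maximal consecutive runs to form called regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .emission import EmissionParams, betabinom_log_pmf
from .markers import MarkerTrack

__all__ = [
    "TransitionParams",
    "PosteriorTrack",
    "LinkedRegion",
    "stay_probabilities",
    "forward_backward",
    "call_linked_regions",
]


@dataclass(frozen=True)
class TransitionParams:
    """Distance-decay transition model.

    r: recombination-scale rate per bp; s: extra exponent scale applied in
    the P state (1.0 = symmetric states); (pi_n, pi_p): initial state
    distribution of each chromosome's chain.
    """

    r: float = 3.5e-6
    s: float = 1.0
    pi_n: float = 0.5
    pi_p: float = 0.5

    def __post_init__(self) -> None:
        if not (self.r > 0):
            raise ValueError(f"r must be positive, got {self.r}")
        if not (self.s > 0):
            raise ValueError(f"s must be positive, got {self.s}")
        if not (0 < self.pi_n < 1 and 0 < self.pi_p < 1):
            raise ValueError("initial probabilities must lie in (0,1)")
        if abs(self.pi_n + self.pi_p - 1.0) > 1e-9:
            raise ValueError("pi_n + pi_p must equal 1")


@dataclass
class PosteriorTrack:
    """Per-site P-state (linkage) posteriors aligned with a marker track."""

    chrom: str
    positions: np.ndarray
    posterior_p: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.posterior_p = np.asarray(self.posterior_p, dtype=float)
        if self.positions.shape != self.posterior_p.shape:
            raise ValueError("positions and posteriors must align")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class LinkedRegion:
    """A maximal run of significant markers, spanning first to last marker."""

    chrom: str
    start_pos: int
    end_pos: int
    n_markers: int
    max_posterior: float
    mean_posterior: float

    def __post_init__(self) -> None:
        if self.start_pos > self.end_pos:
            raise ValueError("start_pos must be <= end_pos")
        if self.n_markers < 1:
            raise ValueError("a region holds at least one marker")

    @property
    def size_bp(self) -> int:
        return self.end_pos - self.start_pos + 1

    def contains_pos(self, x: int) -> bool:
        return self.start_pos <= x <= self.end_pos


def stay_probabilities(
    positions, params: TransitionParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval probabilities of staying in N and in P.

    For an inter-marker distance l: stay-in-N = e^(-r*l), stay-in-P =
    e^(-r*l*s); the probability of switching states is the complement.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size < 2:
        raise ValueError("need at least 2 positions")
    gaps = np.diff(pos)
    if np.any(gaps <= 0):
        raise ValueError("positions must be strictly increasing")
    tau_n = np.exp(-params.r * gaps)
    tau_p = np.exp(-params.r * gaps * params.s)
    return tau_n, tau_p


def forward_backward(
    track: MarkerTrack, em: EmissionParams, tr: TransitionParams
) -> PosteriorTrack:
    """Exact smoothing posteriors of the 2-state chain over one chromosome.

    Scaled (per-site normalized) forward-backward with heterogeneous,
    distance-dependent transitions; emissions are max-shifted per site so
    the recursion stays in a safe floating range even at high coverage and
    extreme shape parameters.
    """
    L = len(track)
    if L == 0:
        raise ValueError(f"empty track {track.chrom}")
    k = track.superior
    n = track.total
    le_n = np.atleast_1d(betabinom_log_pmf(k, n, em.alpha_n, em.beta_n))
    le_p = np.atleast_1d(betabinom_log_pmf(k, n, em.alpha_p, em.beta_p))
    shift = np.maximum(le_n, le_p)
    e_n = np.exp(le_n - shift)
    e_p = np.exp(le_p - shift)

    if L == 1:
        num = tr.pi_p * e_p[0]
        den = tr.pi_n * e_n[0] + num
        return PosteriorTrack(track.chrom, track.positions, np.array([num / den]))

    tau_n, tau_p = stay_probabilities(track.positions, tr)
    tau_n = tau_n.tolist()
    tau_p = tau_p.tolist()
    en = e_n.tolist()
    ep = e_p.tolist()

    # scaled forward pass
    f_n = [0.0] * L
    f_p = [0.0] * L
    fn = tr.pi_n * en[0]
    fp = tr.pi_p * ep[0]
    c = fn + fp
    f_n[0], f_p[0] = fn / c, fp / c
    scales = [c]
    for i in range(1, L):
        tn, tp = tau_n[i - 1], tau_p[i - 1]
        fn = (f_n[i - 1] * tn + f_p[i - 1] * (1.0 - tp)) * en[i]
        fp = (f_n[i - 1] * (1.0 - tn) + f_p[i - 1] * tp) * ep[i]
        c = fn + fp
        f_n[i], f_p[i] = fn / c, fp / c
        scales.append(c)

    # scaled backward pass and posterior combination
    post = [0.0] * L
    bn = bp = 1.0
    num = f_p[L - 1] * bp
    post[L - 1] = num / (f_n[L - 1] * bn + num)
    for i in range(L - 2, -1, -1):
        tn, tp = tau_n[i], tau_p[i]
        wn = en[i + 1] * bn
        wp = ep[i + 1] * bp
        bn = (tn * wn + (1.0 - tn) * wp) / scales[i + 1]
        bp = ((1.0 - tp) * wn + tp * wp) / scales[i + 1]
        num = f_p[i] * bp
        post[i] = num / (f_n[i] * bn + num)

    return PosteriorTrack(track.chrom, track.positions, np.array(post))


def call_linked_regions(
    post: PosteriorTrack, cutoff: float = 0.95
) -> list[LinkedRegion]:
    """Group maximal runs of markers with posterior > cutoff into regions.

    A single sub-threshold marker breaks a run (no gap tolerance); regions
    are returned in genomic order and may be empty.
    """
    if not (0.0 <= cutoff < 1.0 or math.isclose(cutoff, 1.0)):
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    sig = post.posterior_p > cutoff
    regions: list[LinkedRegion] = []
    i = 0
    L = len(post)
    while i < L:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < L and sig[j + 1]:
            j += 1
        chunk = post.posterior_p[i : j + 1]
        regions.append(
            LinkedRegion(
                chrom=post.chrom,
                start_pos=int(post.positions[i]),
                end_pos=int(post.positions[j]),
                n_markers=j - i + 1,
                max_posterior=float(chunk.max()),
                mean_posterior=float(chunk.mean()),
            )
        )
        i = j + 1
    return regions
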