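"""Beta-binomial emission model and neutral-parameter estimation.

Each hidden state emits the superior-parent read count n_A at a site through
a beta-binomial: neutral sites with shapes (alpha_n, beta_n) concentrated
near a 50/50 allele balance, phenotype-linked sites with (alpha_p, beta_p)
skewed toward the superior allele.  The alpha_p/beta_p ratio is the
stringency knob of the caller: beta_p is conventionally fixed at 1 and
alpha_p raised to demand stronger allele-frequency deviations.

Neutral shapes are estimated from the data by the method of moments on the
per-site allele fractions, optionally refined after a first decoding pass by
excluding sites already called linked (most of a genome is neutral, so the
remainder is a clean neutral sample).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import betabinom

__all__ = [
    "EmissionParams",
    "EstimationError",
    "betabinom_log_pmf",
    "estimate_neutral_params_mom",
    "refine_neutral_params",
]

#: Concentration (alpha+beta) cap used when data are at or below binomial dispersion.
MAX_CONCENTRATION = 1e6

_RHO_EPS = 1e-6


class EstimationError(ValueError):
    """Raised when neutral emission parameters cannot be estimated."""


@dataclass(frozen=True)
class EmissionParams:
    """Beta-binomial shape parameters for the neutral (N) and linked (P) states.

    Defaults: alpha_p=10, beta_p=1 (permissive stringency; 15 and 30 are the
    common stricter presets); neutral shapes are placeholders until fitted.
    """

    alpha_n: float = 1.0
    beta_n: float = 1.0
    alpha_p: float = 10.0
    beta_p: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha_n", "beta_n", "alpha_p", "beta_p"):
            v = getattr(self, name)
            if not (v > 0 and np.isfinite(v)):
                raise ValueError(f"{name} must be positive and finite, got {v}")

    @property
    def stringency(self) -> float:
        """alpha_p / beta_p ratio."""
        return self.alpha_p / self.beta_p

    def with_neutral(self, alpha_n: float, beta_n: float) -> "EmissionParams":
        return replace(self, alpha_n=float(alpha_n), beta_n=float(beta_n))


def betabinom_log_pmf(k, n, alpha: float, beta: float):
    """log P(n_A = k | n, alpha, beta) for the beta-binomial.

    Accepts scalars or arrays for ``k`` and ``n``; shapes must be positive
    and every k within [0, n].
    """
    if not (alpha > 0 and beta > 0):
        raise ValueError(f"shape parameters must be positive, got {alpha}, {beta}")
    k = np.asarray(k)
    n = np.asarray(n)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("k must satisfy 0 <= k <= n")
    out = betabinom.logpmf(k, n, alpha, beta)
    return float(out) if out.ndim == 0 else out


def _pooled_fractions(tracks) -> tuple[np.ndarray, np.ndarray]:
    """Per-site allele fractions p_i and coverages n_i across tracks (n_i >= 1)."""
    ks, ns = [], []
    for t in tracks:
        ks.append(t.superior)
        ns.append(t.total)
    k = np.concatenate(ks) if ks else np.array([], dtype=np.int64)
    n = np.concatenate(ns) if ns else np.array([], dtype=np.int64)
    mask = n >= 1
    return k[mask] / n[mask], n[mask].astype(float)


def estimate_neutral_params_mom(tracks) -> tuple[float, float]:
    """Method-of-moments estimate of the neutral shapes (alpha_n, beta_n).

    With p_i = superior/total, the intraclass correlation rho of a
    beta-binomial satisfies Var(p) = mu(1-mu)(1 + (n-1) rho)/n; solving with
    the mean coverage n-bar gives rho-hat, then alpha+beta = 1/rho - 1
    (capped at :data:`MAX_CONCENTRATION` for data at or below binomial
    dispersion) and alpha = mu * (alpha+beta).
    """
    p, n = _pooled_fractions(tracks)
    if p.size < 2:
        raise EstimationError(f"need >= 2 covered sites, got {p.size}")
    mu = float(np.mean(p))
    if mu <= 0.0 or mu >= 1.0:
        raise EstimationError(f"degenerate allele fractions (mean {mu})")
    v = float(np.var(p, ddof=1))
    nbar = float(np.mean(n))
    if nbar <= 1.0:
        rho = _RHO_EPS
    else:
        rho = (v * nbar / (mu * (1.0 - mu)) - 1.0) / (nbar - 1.0)
    rho = min(max(rho, _RHO_EPS), 1.0 - _RHO_EPS)
    conc = min(1.0 / rho - 1.0, MAX_CONCENTRATION)
    alpha_n = mu * conc
    beta_n = conc - alpha_n
    return alpha_n, beta_n


def refine_neutral_params(
    tracks,
    params: EmissionParams,
    transition,
    cutoff: float = 0.95,
) -> tuple[float, float]:
    """Re-estimate the neutral shapes excluding sites already called linked.

    Runs one forward-backward pass per track with the current parameters,
    drops every site whose linkage posterior exceeds ``cutoff`` and repeats
    the method of moments on the remainder.  If (nearly) everything is
    excluded the step-1 estimates are returned with a warning.
    """
    from .hmm import forward_backward
    from .markers import MarkerTrack

    kept_tracks = []
    for t in tracks:
        if len(t) == 0:
            continue
        post = forward_backward(t, params, transition).posterior_p
        keep = post <= cutoff
        kept_tracks.append(
            MarkerTrack(t.chrom, [s for s, k in zip(t.sites, keep) if k])
        )
    try:
        return estimate_neutral_params_mom(kept_tracks)
    except EstimationError:
        warnings.warn(
            "all (or nearly all) sites called linked at the refinement step; "
            "keeping step-1 neutral estimates",
            stacklevel=2,
        )
        return params.alpha_n, params.beta_n
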