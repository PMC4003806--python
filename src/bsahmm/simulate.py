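"""Synthetic bulk-segregant experiment generator.

One dataset is a single artificial chromosome (default 750 kbp) with
uniformly placed polymorphic marker sites, one of which is chosen as the
causal site.  Haploid segregants are produced by recombining the two
parental genomes: the starting parent is a fair coin flip and meiotic
crossovers fall as a Poisson process along the chromosome (default 0.37
cM/kb, i.e. intensity 3.7e-6 breakpoints per bp — the small-distance
Haldane limit).  The selected pool is built by accepting each candidate
segregant with probability PSC if it carries the superior allele at the
causal site and 1-PSC otherwise, until the target pool size n is reached;
since carriers arise with prior 1/2, the expected carrier fraction of the
pool equals PSC.  Pooled sequencing then draws, per marker, reads sampling
segregants uniformly with replacement, each reported allele flipped with
the sequencing error rate (default 0.01).

Defaults reproduce the standard study conditions: 750 kbp, 2500 markers,
n = 30 segregants, coverage c = 200 per site (fixed; Poisson optional).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .markers import MarkerTrack, write_marker_table

__all__ = [
    "SimulationConfig",
    "SimulatedPool",
    "draw_marker_map",
    "simulate_segregant",
    "select_pool",
    "sequence_pool",
    "simulate_dataset",
]

#: hard cap on pool-construction attempts (guards degenerate acceptance setups)
MAX_POOL_ATTEMPTS_PER_SEGREGANT = 10_000


def cm_per_kb_to_rate(crossover_rate_cm_per_kb: float) -> float:
    """Convert a cM/kb genetic map density to a per-bp crossover intensity."""
    return crossover_rate_cm_per_kb / 100.0 / 1000.0


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic bulk-segregant experiment."""

    chrom_length: int = 750_000
    n_markers: int = 2500
    n_segregants: int = 30
    coverage: int = 200
    psc: float = 0.95
    crossover_rate: float = 0.37  # cM per kb
    seq_error: float = 0.01
    coverage_mode: str = "fixed"  # "fixed" | "poisson"
    chrom: str = "sim1"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_markers < 2:
            raise ValueError("need at least 2 markers")
        if self.n_markers > self.chrom_length:
            raise ValueError("cannot place more markers than base pairs")
        if not (0.0 < self.psc <= 1.0):
            raise ValueError(f"psc must lie in (0, 1], got {self.psc}")
        if not (0.0 <= self.seq_error < 0.5):
            raise ValueError(f"seq_error must lie in [0, 0.5), got {self.seq_error}")
        if self.crossover_rate < 0:
            raise ValueError("crossover_rate must be non-negative")
        if self.coverage_mode not in ("fixed", "poisson"):
            raise ValueError(f"unknown coverage_mode {self.coverage_mode!r}")
        if self.n_segregants < 1 or self.coverage < 1:
            raise ValueError("n_segregants and coverage must be positive")


@dataclass
class SimulatedPool:
    """Output of one synthetic experiment, with full ground truth."""

    config: SimulationConfig
    positions: np.ndarray
    causal_index: int
    origin_matrix: np.ndarray  # (n_segregants, n_markers) bool; True = superior origin
    carrier: np.ndarray  # per pooled segregant: carries superior allele at causal site
    counts: MarkerTrack

    @property
    def causal_pos(self) -> int:
        return int(self.positions[self.causal_index])

    @property
    def carrier_fraction(self) -> float:
        return float(np.mean(self.carrier))

    def write_counts(self, sink) -> None:
        write_marker_table([self.counts], sink)


def draw_marker_map(
    length: int, n_markers: int, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Place ``n_markers`` distinct positions uniformly in [1, length], pick a causal one."""
    if n_markers > length:
        raise ValueError("cannot place more markers than base pairs")
    positions = np.sort(rng.choice(length, size=n_markers, replace=False) + 1)
    causal_index = int(rng.integers(n_markers))
    return positions, causal_index


def simulate_segregant(
    positions: np.ndarray,
    chrom_length: int,
    crossover_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One haploid recombinant: boolean superior-parent origin at each marker.

    Starting parent ~ Bernoulli(1/2); crossover breakpoints are a Poisson
    process with intensity crossover_rate/100/1000 per bp over the
    chromosome; parental origin alternates at each breakpoint.
    """
    rho = cm_per_kb_to_rate(crossover_rate)
    start_superior = bool(rng.random() < 0.5)
    n_breaks = rng.poisson(rho * chrom_length)
    if n_breaks == 0:
        return np.full(len(positions), start_superior, dtype=bool)
    breaks = np.sort(rng.uniform(1.0, float(chrom_length), size=n_breaks))
    parity = np.searchsorted(breaks, positions) % 2
    return np.where(parity == 0, start_superior, not start_superior)


def select_pool(
    config: SimulationConfig,
    positions: np.ndarray,
    causal_index: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Build the selected pool by PSC-biased acceptance sampling.

    Candidates are drawn until ``n_segregants`` are accepted; a carrier of
    the superior allele at the causal marker is accepted with probability
    PSC, a non-carrier with 1-PSC.  Returns (origin_matrix, carrier flags).
    """
    n = config.n_segregants
    origins = np.empty((n, len(positions)), dtype=bool)
    carrier = np.empty(n, dtype=bool)
    accepted = 0
    attempts = 0
    max_attempts = MAX_POOL_ATTEMPTS_PER_SEGREGANT * n
    while accepted < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"pool construction did not converge after {max_attempts} attempts "
                f"(psc={config.psc})"
            )
        seg = simulate_segregant(
            positions, config.chrom_length, config.crossover_rate, rng
        )
        is_carrier = bool(seg[causal_index])
        p_accept = config.psc if is_carrier else 1.0 - config.psc
        if rng.random() < p_accept:
            origins[accepted] = seg
            carrier[accepted] = is_carrier
            accepted += 1
    return origins, carrier


def sequence_pool(
    origin_matrix: np.ndarray,
    coverage: int,
    seq_error: float,
    coverage_mode: str,
    rng: np.random.Generator,
    positions: np.ndarray,
    chrom: str = "sim1",
) -> MarkerTrack:
    """Error-prone pooled sequencing of the selected pool.

    Each read at a marker samples a pooled segregant uniformly with
    replacement and reports its allele, flipped with probability
    ``seq_error``.  With pool superior-origin fraction f at the marker, the
    superior read count is Binomial(total, f(1-e) + (1-f)e) — drawn directly
    in that collapsed form, which is distributionally identical to per-read
    simulation.
    """
    n_markers = origin_matrix.shape[1]
    f = origin_matrix.mean(axis=0)
    if coverage_mode == "fixed":
        totals = np.full(n_markers, coverage, dtype=np.int64)
    elif coverage_mode == "poisson":
        totals = rng.poisson(coverage, size=n_markers).astype(np.int64)
    else:
        raise ValueError(f"unknown coverage_mode {coverage_mode!r}")
    p_sup = f * (1.0 - seq_error) + (1.0 - f) * seq_error
    superior = rng.binomial(totals, p_sup)
    return MarkerTrack.from_arrays(chrom, positions, superior, totals)


def simulate_dataset(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedPool:
    """Run one full synthetic experiment (map, pool selection, sequencing)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    positions, causal_index = draw_marker_map(
        config.chrom_length, config.n_markers, rng
    )
    origins, carrier = select_pool(config, positions, causal_index, rng)
    counts = sequence_pool(
        origins,
        config.coverage,
        config.seq_error,
        config.coverage_mode,
        rng,
        positions,
        chrom=config.chrom,
    )
    return SimulatedPool(
        config=config,
        positions=positions,
        causal_index=causal_index,
        origin_matrix=origins,
        carrier=carrier,
        counts=counts,
    )


def write_truth(pool: SimulatedPool, sink: str | Path) -> None:
    """Write the ground-truth causal position and pool composition as TSV."""
    with open(sink, "wt", encoding="utf-8") as fh:
        fh.write("KEY\tVALUE\n")
        fh.write(f"chrom\t{pool.config.chrom}\n")
        fh.write(f"causal_pos\t{pool.causal_pos}\n")
        fh.write(f"causal_index\t{pool.causal_index}\n")
        fh.write(f"carrier_fraction\t{pool.carrier_fraction:.6f}\n")
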