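"""Performance metrics over synthetic datasets and the replicate benchmark runner.

A prediction for one dataset is scored against the known causal position by
three quantities: whether some called region contains the causal site
(recovery), the size in bp of that region, and the number of called regions
that do not contain the causal site (false positives).  Containment is
strict — a region adjacent to but not covering the causal position counts
as a false positive.

``run_benchmark`` repeats simulate-fit-score over independently seeded
replicates for each requested setting and aggregates recovery rate, mean
causal-region size and mean false-positive count with Monte-Carlo standard
errors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .emission import EmissionParams
from .hmm import LinkedRegion, TransitionParams
from .model import BsaLinkageModel
from .simulate import SimulatedPool, SimulationConfig, simulate_dataset

__all__ = ["EvalResult", "score_predictions", "run_replicates", "run_benchmark"]


@dataclass(frozen=True)
class EvalResult:
    """Score of one dataset's predictions against the true causal position."""

    recovered: bool
    causal_region_size: int | None
    fp_count: int
    all_region_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        expected = len(self.all_region_sizes) - (1 if self.recovered else 0)
        if self.fp_count != expected:
            raise ValueError("fp_count inconsistent with region count")


def score_predictions(
    regions: Sequence[LinkedRegion], causal_pos: int
) -> EvalResult:
    """Score called regions: recovery, causal-region size, false positives."""
    regions = list(regions)
    for a, b in zip(regions, regions[1:]):
        if a.chrom == b.chrom and b.start_pos <= a.end_pos:
            raise ValueError(
                f"regions overlap or are unsorted: {a.chrom}:{a.start_pos}-{a.end_pos} "
                f"vs {b.chrom}:{b.start_pos}-{b.end_pos}"
            )
    causal_size = None
    recovered = False
    for r in regions:
        if r.contains_pos(causal_pos):
            recovered = True
            causal_size = r.size_bp
            break
    fp = len(regions) - (1 if recovered else 0)
    return EvalResult(
        recovered=recovered,
        causal_region_size=causal_size,
        fp_count=fp,
        all_region_sizes=tuple(r.size_bp for r in regions),
    )


def _replicate_rng(master_seed: int, replicate: int) -> np.random.Generator:
    # deterministic per-replicate stream: master seed + replicate index
    return np.random.default_rng(np.random.SeedSequence([master_seed, replicate]))


def run_replicates(
    config: SimulationConfig,
    n_replicates: int = 100,
    master_seed: int = 0,
    emission: EmissionParams | None = None,
    transition: TransitionParams | None = None,
    cutoff: float = 0.95,
) -> list[EvalResult]:
    """Simulate, fit and score ``n_replicates`` independent datasets."""
    results = []
    for rep in range(n_replicates):
        rng = _replicate_rng(master_seed, rep)
        pool: SimulatedPool = simulate_dataset(replace(config, seed=None), rng)
        model = BsaLinkageModel(
            [pool.counts], emission=emission, transition=transition, cutoff=cutoff
        )
        fit = model.fit()
        results.append(score_predictions(fit.regions, pool.causal_pos))
    return results


def summarize(results: Sequence[EvalResult]) -> dict:
    """Aggregate replicate scores with Monte-Carlo standard errors."""
    n = len(results)
    rec = np.array([r.recovered for r in results], dtype=float)
    fp = np.array([r.fp_count for r in results], dtype=float)
    sizes = np.array(
        [r.causal_region_size for r in results if r.causal_region_size is not None],
        dtype=float,
    )
    rate = float(rec.mean())
    out = {
        "n_replicates": n,
        "recovery_rate": rate,
        "recovery_rate_se": float(np.sqrt(rate * (1 - rate) / n)),
        "mean_fp": float(fp.mean()),
        "mean_fp_se": float(fp.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        "mean_causal_region_size": float(sizes.mean()) if sizes.size else float("nan"),
        "mean_causal_region_size_se": (
            float(sizes.std(ddof=1) / np.sqrt(sizes.size))
            if sizes.size > 1
            else float("nan")
        ),
    }
    return out


def run_benchmark(
    settings: Sequence[dict],
    n_replicates: int = 100,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Run the replicate benchmark over a grid of settings.

    Each setting dict may override any :class:`SimulationConfig` field plus
    the model knobs ``alpha_p``, ``beta_p``, ``r``, ``s`` and ``cutoff``.
    Returns one aggregate row per setting.
    """
    rows = []
    for i, setting in enumerate(settings):
        setting = dict(setting)
        alpha_p = setting.pop("alpha_p", 10.0)
        beta_p = setting.pop("beta_p", 1.0)
        r = setting.pop("r", 3.5e-6)
        s = setting.pop("s", 1.0)
        cutoff = setting.pop("cutoff", 0.95)
        config = SimulationConfig(**setting)
        results = run_replicates(
            config,
            n_replicates=n_replicates,
            master_seed=master_seed + i,
            emission=EmissionParams(alpha_p=alpha_p, beta_p=beta_p),
            transition=TransitionParams(r=r, s=s),
            cutoff=cutoff,
        )
        row = {
            "n_markers": config.n_markers,
            "n_segregants": config.n_segregants,
            "coverage": config.coverage,
            "psc": config.psc,
            "alpha_p": alpha_p,
            "beta_p": beta_p,
            "r": r,
            "cutoff": cutoff,
        }
        row.update(summarize(results))
        rows.append(row)
    return pd.DataFrame(rows)
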