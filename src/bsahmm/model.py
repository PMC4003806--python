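"""Model/Results interface for the bulk-segregant linkage HMM.

:class:`BsaLinkageModel` is built from marker allele-count data (tracks, a
DataFrame or a TSV path) plus emission/transition settings; ``fit()`` runs
the full two-step pipeline — optional marker filters, method-of-moments fit
of the neutral beta-binomial, a first posterior decoding, re-estimation of
the neutral shapes excluding sites already called linked, a final decoding
and region calling — and returns a :class:`BsaLinkageResults` carrying the
posteriors, the called regions, both neutral parameter sets and a run
report.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import IO, Sequence

import numpy as np

from . import markers as mk
from .emission import EmissionParams, estimate_neutral_params_mom, refine_neutral_params
from .hmm import (
    LinkedRegion,
    PosteriorTrack,
    TransitionParams,
    call_linked_regions,
    forward_backward,
)

__all__ = ["FilterConfig", "BsaLinkageModel", "BsaLinkageResults"]


@dataclass(frozen=True)
class FilterConfig:
    """Marker-level filters applied before fitting, in the order
    quality -> coverage -> spacing.

    ``None`` disables a filter.  The conventional settings for real pooled
    sequencing data are quality >= 40, coverage within [20, 100] and 30 bp
    minimum spacing; simulated data is normally left unfiltered.
    """

    min_quality: float | None = None
    min_cov: int | None = None
    max_cov: int | None = None
    min_spacing_bp: int | None = None

    @classmethod
    def real_data_defaults(cls) -> "FilterConfig":
        return cls(min_quality=40.0, min_cov=20, max_cov=100, min_spacing_bp=30)

    def apply(self, track: mk.MarkerTrack) -> tuple[mk.MarkerTrack, dict[str, int]]:
        counts = {"input": len(track)}
        if self.min_quality is not None:
            track = mk.filter_by_quality(track, self.min_quality)
            counts["after_quality"] = len(track)
        if self.min_cov is not None or self.max_cov is not None:
            lo = 0 if self.min_cov is None else self.min_cov
            hi = np.iinfo(np.int64).max if self.max_cov is None else self.max_cov
            track = mk.filter_by_coverage(track, lo, hi)
            counts["after_coverage"] = len(track)
        if self.min_spacing_bp is not None:
            track = mk.filter_by_spacing(track, self.min_spacing_bp)
            counts["after_spacing"] = len(track)
        return track, counts


class BsaLinkageModel:
    """Linkage HMM over pooled allele counts from a bulk-segregant cross.

    Parameters
    ----------
    tracks
        Marker tracks (one per chromosome).
    emission
        Beta-binomial shapes; the neutral pair is re-estimated from the data
        during ``fit`` so only (alpha_p, beta_p) matter here.
    transition
        Distance-decay transition parameters (r, s, initial distribution).
    cutoff
        Posterior threshold for calling a marker significantly linked.
    filters
        Optional :class:`FilterConfig`; default applies no filters.
    """

    def __init__(
        self,
        tracks: Sequence[mk.MarkerTrack],
        emission: EmissionParams | None = None,
        transition: TransitionParams | None = None,
        cutoff: float = 0.95,
        filters: FilterConfig | None = None,
    ) -> None:
        if not (0.0 <= cutoff <= 1.0):
            raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
        self.tracks = list(tracks)
        self.emission = emission if emission is not None else EmissionParams()
        self.transition = transition if transition is not None else TransitionParams()
        self.cutoff = float(cutoff)
        self.filters = filters

    @classmethod
    def from_table(cls, source: str | Path | IO[str], **kwargs) -> "BsaLinkageModel":
        """Build from the canonical marker TSV."""
        return cls(mk.read_marker_table(source), **kwargs)

    @classmethod
    def from_dataframe(cls, df, **kwargs) -> "BsaLinkageModel":
        """Build from a DataFrame with columns CHROM, POS, SUPERIOR_COUNT, TOTAL_COUNT[, QUAL]."""
        return cls(mk.tracks_from_dataframe(df), **kwargs)

    def fit(self, refine: bool = True) -> "BsaLinkageResults":
        """Run filters, the two-step neutral fit and the final decoding."""
        filtered: list[mk.MarkerTrack] = []
        filter_counts: dict[str, dict[str, int]] = {}
        for t in self.tracks:
            if self.filters is not None:
                ft, counts = self.filters.apply(t)
            else:
                ft, counts = t, {"input": len(t)}
            filtered.append(ft)
            filter_counts[t.chrom] = counts

        nonempty = [t for t in filtered if len(t) > 0]
        if not nonempty:
            warnings.warn("no markers survive filtering; returning empty results")
            return BsaLinkageResults(
                model=self,
                tracks=filtered,
                posteriors=[],
                regions=[],
                params_step1=self.emission,
                params=self.emission,
                filter_counts=filter_counts,
            )

        a1, b1 = estimate_neutral_params_mom(nonempty)
        params1 = self.emission.with_neutral(a1, b1)
        if refine:
            a2, b2 = refine_neutral_params(
                nonempty, params1, self.transition, self.cutoff
            )
            params2 = self.emission.with_neutral(a2, b2)
        else:
            params2 = params1

        posteriors: list[PosteriorTrack] = []
        regions: list[LinkedRegion] = []
        for t in filtered:
            if len(t) == 0:
                posteriors.append(
                    PosteriorTrack(t.chrom, np.array([], dtype=np.int64), np.array([]))
                )
                continue
            post = forward_backward(t, params2, self.transition)
            posteriors.append(post)
            regions.extend(call_linked_regions(post, self.cutoff))

        return BsaLinkageResults(
            model=self,
            tracks=filtered,
            posteriors=posteriors,
            regions=regions,
            params_step1=params1,
            params=params2,
            filter_counts=filter_counts,
        )


@dataclass
class BsaLinkageResults:
    """Fitted posteriors, called regions and parameter estimates."""

    model: BsaLinkageModel
    tracks: list[mk.MarkerTrack]
    posteriors: list[PosteriorTrack]
    regions: list[LinkedRegion]
    params_step1: EmissionParams
    params: EmissionParams
    filter_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def n_markers(self) -> int:
        return sum(len(t) for t in self.tracks)

    @property
    def n_significant(self) -> int:
        return int(
            sum((p.posterior_p > self.model.cutoff).sum() for p in self.posteriors)
        )

    def posterior_frame(self):
        """Per-site posteriors as a tidy DataFrame."""
        import pandas as pd

        recs = []
        for t, p in zip(self.tracks, self.posteriors):
            for s, q in zip(t, p.posterior_p):
                recs.append((s.chrom, s.pos, s.superior_count, s.total_count, q))
        return pd.DataFrame(
            recs,
            columns=["CHROM", "POS", "SUPERIOR_COUNT", "TOTAL_COUNT", "POSTERIOR"],
        )

    def to_posterior_table(self, sink) -> None:
        mk.write_posterior_table(self.tracks, [p.posterior_p for p in self.posteriors], sink)

    def to_bed(self, sink) -> None:
        mk.write_regions_bed(self.regions, sink)

    def report(self) -> dict:
        """Machine-readable run report (parameters of both fit steps, filter counts)."""
        return {
            "cutoff": self.model.cutoff,
            "transition": asdict(self.model.transition),
            "emission_step1": asdict(self.params_step1),
            "emission_final": asdict(self.params),
            "filter_counts": self.filter_counts,
            "n_markers": self.n_markers,
            "n_significant": self.n_significant,
            "n_regions": len(self.regions),
        }

    def summary(self) -> str:
        """Human-readable summary of the fit and the called regions."""
        lines = [
            "Bulk-segregant linkage HMM results",
            "==================================",
            f"markers: {self.n_markers} on {len(self.tracks)} chromosome(s); "
            f"significant (posterior > {self.model.cutoff:g}): {self.n_significant}",
            f"transition: r={self.model.transition.r:g}, s={self.model.transition.s:g}",
            f"neutral fit step 1: alpha_N={self.params_step1.alpha_n:.4g}, "
            f"beta_N={self.params_step1.beta_n:.4g}",
            f"neutral fit final : alpha_N={self.params.alpha_n:.4g}, "
            f"beta_N={self.params.beta_n:.4g}",
            f"linked state: alpha_P={self.params.alpha_p:g}, beta_P={self.params.beta_p:g} "
            f"(stringency {self.params.stringency:g})",
            f"called regions: {len(self.regions)}",
        ]
        if self.regions:
            lines.append("")
            lines.append(
                f"{'chrom':<10}{'start':>10}{'end':>10}{'size_bp':>10}"
                f"{'markers':>9}{'max_post':>10}{'mean_post':>10}"
            )
            for r in self.regions:
                lines.append(
                    f"{r.chrom:<10}{r.start_pos:>10}{r.end_pos:>10}{r.size_bp:>10}"
                    f"{r.n_markers:>9}{r.max_posterior:>10.4f}{r.mean_posterior:>10.4f}"
                )
        return "\n".join(lines)
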