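"""Three-step trimming of models to match density maps.

Step 1 removes residues whose smoothed local map correlation (and, for
predicted models, smoothed confidence) falls below an adaptive cutoff.
Step 2 strips weak residues from segment ends at a higher cutoff and drops
segments shorter than the smoothing window.  Step 3 drops whole segments
whose mean correlation is far below that of the better segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .confidence import residue_plddt
from .density import DensityMap, ResidueProfile, chain_breaks, local_cc, smooth_track
from .model_io import AtomicModel


class AllResiduesTrimmedError(Exception):
    """Trimming removed every residue; carries the step-by-step report."""

    def __init__(self, report: "TrimReport"):
        super().__init__("trimming removed every residue")
        self.report = report


@dataclass
class TrimParams:
    """Named parameters of the trimming procedure with their typical values.

    ``minimum_domain_length`` doubles as the smoothing window.  With the
    defaults the step-3 scale is 0.8^2 = 0.64 and the step-3 offset is
    2 * 0.15 = 0.3.
    """

    minimum_domain_length: int = 10
    cc_sd_ratio: float = 3.0
    cc_sd_ratio_end: float = 2.0
    reasonable_cc_ratio: float = 0.8
    reasonable_cc_diff: float = 0.15
    use_plddt: bool = False
    require_both_tracks: bool = True  # step-1 conjunction rule when use_plddt
    mask_radius: float = 2.5
    resolution: float = 3.0

    def __post_init__(self) -> None:
        if self.cc_sd_ratio <= 0 or self.cc_sd_ratio_end <= 0:
            raise ValueError("sd-ratio multipliers must be positive")
        if not (0 < self.reasonable_cc_ratio <= 1):
            raise ValueError("reasonable_cc_ratio must be in (0, 1]")
        if self.minimum_domain_length < 1:
            raise ValueError("minimum_domain_length must be >= 1")

    @property
    def step3_scale(self) -> float:
        return self.reasonable_cc_ratio ** 2

    @property
    def step3_offset(self) -> float:
        return 2.0 * self.reasonable_cc_diff


@dataclass
class Segment:
    """A run of consecutive residues with no chain break inside."""

    chain_id: str
    start: int
    end: int
    indices: list[int]
    mean_cc: float = 0.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start must not exceed end")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class TrimReport:
    n_input: int = 0
    cc_cutoff: float = float("nan")
    plddt_cutoff: float = float("nan")
    end_cutoff: float = float("nan")
    segment_cutoff: float = float("nan")
    removed_step1: int = 0
    removed_step2_ends: int = 0
    removed_step2_short: int = 0
    removed_step3: int = 0
    n_output: int = 0
    segments_kept: list[tuple[str, int, int]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "cc_cutoff": self.cc_cutoff,
            "plddt_cutoff": self.plddt_cutoff,
            "end_cutoff": self.end_cutoff,
            "segment_cutoff": self.segment_cutoff,
            "removed_step1": self.removed_step1,
            "removed_step2_ends": self.removed_step2_ends,
            "removed_step2_short": self.removed_step2_short,
            "removed_step3": self.removed_step3,
            "n_output": self.n_output,
            "segments_kept": self.segments_kept,
        }


def top_half_cutoff(values: np.ndarray, k: float) -> float:
    """Mean minus k standard deviations of the highest half of the values.

    The highest half is the top ceil(n/2) values after descending sort;
    the standard deviation is the sample sd (ddof 1), taken as 0 when the
    half has fewer than 2 values.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot compute a cutoff from an empty value set")
    n_top = int(np.ceil(values.size / 2))
    top = np.sort(values)[::-1][:n_top]
    sd = float(np.std(top, ddof=1)) if n_top >= 2 else 0.0
    return float(np.mean(top)) - k * sd


def step1_remove_low(profile: ResidueProfile, params: TrimParams
                     ) -> tuple[np.ndarray, TrimReport]:
    """Keep-mask after removing residues below the smoothed-track cutoffs.

    A residue is removed iff its smoothed cc is strictly below the cc cutoff
    AND (when ``use_plddt``) its smoothed confidence is strictly below the
    confidence cutoff (configurable to OR via ``require_both_tracks``).
    Cutoffs come from :func:`top_half_cutoff` with ``cc_sd_ratio`` over the
    smoothed tracks.
    """
    if profile.smoothed_cc is None:
        raise ValueError("profile has no smoothed_cc; smooth before step 1")
    report = TrimReport(n_input=len(profile))
    cc_cutoff = top_half_cutoff(profile.smoothed_cc, params.cc_sd_ratio)
    report.cc_cutoff = cc_cutoff
    low_cc = profile.smoothed_cc < cc_cutoff
    if params.use_plddt:
        if profile.smoothed_plddt is None:
            raise ValueError("use_plddt requires a smoothed confidence track")
        plddt_cutoff = top_half_cutoff(profile.smoothed_plddt, params.cc_sd_ratio)
        report.plddt_cutoff = plddt_cutoff
        low_plddt = profile.smoothed_plddt < plddt_cutoff
        removed = (low_cc & low_plddt) if params.require_both_tracks \
            else (low_cc | low_plddt)
    else:
        removed = low_cc
    report.removed_step1 = int(removed.sum())
    return ~removed, report


def build_segments(profile: ResidueProfile, mask: np.ndarray) -> list[Segment]:
    """Contiguous runs of kept residues, never spanning chain breaks."""
    if profile.segment_ids is None:
        raise ValueError("profile lacks segment ids (chain-break labels)")
    segments: list[Segment] = []
    current: list[int] = []

    def close() -> None:
        if current:
            segments.append(Segment(
                chain_id=profile.keys[current[0]][0],
                start=profile.keys[current[0]][1],
                end=profile.keys[current[-1]][1],
                indices=list(current),
            ))
            current.clear()

    for i in range(len(profile)):
        if not mask[i]:
            close()
            continue
        if current and profile.segment_ids[i] != profile.segment_ids[current[-1]]:
            close()
        current.append(i)
    close()
    for seg in segments:
        seg.mean_cc = float(np.mean(profile.local_cc[seg.indices]))
    return segments


def step2_trim_ends(mask: np.ndarray, profile: ResidueProfile, params: TrimParams
                    ) -> tuple[np.ndarray, TrimReport]:
    """Strip weak residues from segment ends, then drop short segments.

    The end cutoff is :func:`top_half_cutoff` with ``cc_sd_ratio_end`` over
    the raw cc values of the residues surviving step 1.  From each end of
    each segment, residues are stripped while both the raw and the smoothed
    cc are strictly below that cutoff.  Segments left shorter than the
    smoothing window (``minimum_domain_length``) are removed entirely.
    """
    report = TrimReport(n_input=int(np.asarray(mask).sum()))
    mask = np.asarray(mask, dtype=bool).copy()
    surviving = np.where(mask)[0]
    if surviving.size == 0:
        return mask, report
    end_cutoff = top_half_cutoff(profile.local_cc[surviving], params.cc_sd_ratio_end)
    report.end_cutoff = end_cutoff

    def weak(i: int) -> bool:
        return (profile.local_cc[i] < end_cutoff
                and profile.smoothed_cc[i] < end_cutoff)

    for segment in build_segments(profile, mask):
        idx = segment.indices
        lo, hi = 0, len(idx) - 1
        while lo <= hi and weak(idx[lo]):
            mask[idx[lo]] = False
            report.removed_step2_ends += 1
            lo += 1
        while hi >= lo and weak(idx[hi]):
            mask[idx[hi]] = False
            report.removed_step2_ends += 1
            hi -= 1

    for segment in build_segments(profile, mask):
        if len(segment) < params.minimum_domain_length:
            mask[segment.indices] = False
            report.removed_step2_short += len(segment)
    return mask, report


def step3_drop_weak_segments(segments: list[Segment], params: TrimParams
                             ) -> tuple[list[Segment], float]:
    """Drop segments with mean cc strictly below the adaptive segment cutoff.

    m is the mean of the top ceil(n/2) segment mean-cc values; the cutoff is
    max(reasonable_cc_ratio^2 * m, m - 2 * reasonable_cc_diff).
    """
    if not segments:
        raise ValueError("no segments to evaluate")
    means = np.array([s.mean_cc for s in segments])
    n_top = int(np.ceil(means.size / 2))
    m = float(np.mean(np.sort(means)[::-1][:n_top]))
    cutoff = max(params.step3_scale * m, m - params.step3_offset)
    kept = [s for s in segments if not (s.mean_cc < cutoff)]
    return kept, cutoff


def trim_to_map(model: AtomicModel, density: DensityMap,
                params: TrimParams | None = None,
                profile: ResidueProfile | None = None
                ) -> tuple[AtomicModel, TrimReport]:
    """Run the full three-step trim of a model against a map.

    ``profile`` may carry a precomputed per-residue cc track; otherwise
    :func:`itermodel.density.local_cc` is invoked.  Returns the trimmed
    model and a report of all cutoffs and per-step removal counts.
    """
    params = params or TrimParams()
    if profile is None:
        profile = local_cc(model, density, mask_radius=params.mask_radius,
                           resolution=params.resolution)
    if profile.segment_ids is None:
        profile.segment_ids = chain_breaks(model)
    window = params.minimum_domain_length
    profile.window = window
    profile.smoothed_cc = smooth_track(profile.local_cc, window, profile.segment_ids)
    if params.use_plddt:
        if profile.plddt is None:
            profile.plddt = residue_plddt(model)
        profile.smoothed_plddt = smooth_track(profile.plddt, window,
                                              profile.segment_ids)

    mask1, rep1 = step1_remove_low(profile, params)
    mask2, rep2 = step2_trim_ends(mask1, profile, params)

    report = TrimReport(
        n_input=len(profile),
        cc_cutoff=rep1.cc_cutoff,
        plddt_cutoff=rep1.plddt_cutoff,
        end_cutoff=rep2.end_cutoff,
        removed_step1=rep1.removed_step1,
        removed_step2_ends=rep2.removed_step2_ends,
        removed_step2_short=rep2.removed_step2_short,
    )

    segments = build_segments(profile, mask2)
    if not segments:
        report.n_output = 0
        raise AllResiduesTrimmedError(report)
    kept_segments, seg_cutoff = step3_drop_weak_segments(segments, params)
    report.segment_cutoff = seg_cutoff
    report.removed_step3 = sum(len(s) for s in segments) - sum(
        len(s) for s in kept_segments)
    report.segments_kept = [(s.chain_id, s.start, s.end) for s in kept_segments]

    kept_keys = [profile.keys[i] for s in kept_segments for i in s.indices]
    report.n_output = len(kept_keys)
    if not kept_keys:
        raise AllResiduesTrimmedError(report)
    return model.select_residues(kept_keys), report
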