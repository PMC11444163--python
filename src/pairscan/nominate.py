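"""Multi-omics candidate regulatory-element nomination.

Within a window around a gene of interest, bins must simultaneously show
(a) high cohort-wide copy number and further copy gain after treatment,
(b) recurrent hypomethylation, and (c) the required transcription-factor /
histone peak evidence. Passing bins are merged into candidate regions and
checked for chromatin-loop support against the gene's promoter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ampclass import SvCall
from .cnscan import BinCnMatrix
from .genome import BinGrid, GenomicTrack, Region, overlap_bp

__all__ = [
    "NominationConfig",
    "Candidate",
    "build_cn_tracks",
    "nominate_candidates",
    "loop_support",
]


@dataclass
class NominationConfig:
    """Thresholds for candidate nomination.

    The underlying evidence criteria are qualitative; these quantitative
    defaults are conservative and are echoed in the output provenance.
    """

    window: Region
    cn_sum_percentile: float = 0.8  # within-window percentile the CN-sum must reach
    min_cn_gain: float = 1.0  # summed (post - pre) copies over pairs
    min_rhmr_recurrence: float = 1.0
    required_peaks: tuple[str, ...] = ("FOXA1", "H3K27ac")
    peak_mode: str = "all"  # "all" or "any" of the required tracks
    merge_gap: int = 1000  # bp
    min_width: int = 1000  # bp
    track_bin_fraction: float = 0.5  # interval must cover this much of a bin

    def __post_init__(self) -> None:
        if self.peak_mode not in ("all", "any"):
            raise ValueError(f"peak_mode must be 'all' or 'any', got {self.peak_mode!r}")
        if not (0.0 <= self.cn_sum_percentile <= 1.0):
            raise ValueError("cn_sum_percentile must be in [0, 1]")


@dataclass
class Candidate:
    region: Region
    evidence: dict[str, float] = field(default_factory=dict)
    loop_supported: bool | None = None


def build_cn_tracks(
    pre: BinCnMatrix,
    post: BinCnMatrix,
    pairs: list[tuple[str, str]],
    svs: list[SvCall] | None = None,
    new_td_by_pair: bool = True,
) -> dict[str, np.ndarray]:
    """Per-bin evidence tracks from the copy-number and SV call sets.

    Returns ``cn_sum`` (copy number summed over all samples of both
    matrices), ``cn_gain`` (post - pre summed over pairs), ``dup_count``
    (duplication events overlapping each bin), and ``dup_new`` (pairs whose
    post sample has an overlapping duplication while the pre sample has
    none).
    """
    grid = pre.grid
    cn_sum = np.nansum(pre.values, axis=1) + np.nansum(post.values, axis=1)
    icols = [pre.column(a) for a, _ in pairs]
    jcols = [post.column(b) for _, b in pairs]
    d = post.values[:, jcols] - pre.values[:, icols]
    cn_gain = np.nansum(d, axis=1)

    dup_count = np.zeros(grid.n_bins)
    dup_new = np.zeros(grid.n_bins)
    if svs:
        dup_bins_by_sample: dict[str, set[int]] = {}
        for sv in svs:
            if sv.svtype != "DUP" or not sv.intrachromosomal:
                continue
            span = sv.span
            if span.chrom not in grid.genome.chrom_lengths:
                continue
            clipped = Region(
                span.chrom, span.start, min(span.end, grid.genome.length_of(span.chrom))
            )
            first, last = grid.bin_span(clipped)
            dup_count[first:last] += 1.0
            dup_bins_by_sample.setdefault(sv.sample_id, set()).update(
                range(first, last)
            )
        if new_td_by_pair:
            for pre_id, post_id in pairs:
                pre_bins = dup_bins_by_sample.get(pre_id, set())
                post_bins = dup_bins_by_sample.get(post_id, set())
                for b in post_bins - pre_bins:
                    dup_new[b] += 1.0
    return {
        "cn_sum": cn_sum,
        "cn_gain": cn_gain,
        "dup_count": dup_count,
        "dup_new": dup_new,
    }


def nominate_candidates(
    grid: BinGrid,
    cn_tracks: dict[str, np.ndarray],
    rhmr: GenomicTrack,
    peaks: dict[str, GenomicTrack],
    config: NominationConfig,
) -> list[Candidate]:
    """Merge bins satisfying every configured criterion into candidates.

    Bins within the window must reach the CN-sum percentile (computed over
    the window), the minimum summed copy gain, the minimum hypomethylation
    recurrence, and the required peak evidence (all-of or any-of). Passing
    bins separated by <= merge_gap are merged; merged regions narrower than
    min_width are dropped. Output is in genomic order with per-criterion
    evidence (mean track values over the candidate) attached.
    """
    for name in config.required_peaks:
        if name not in peaks:
            raise ValueError(f"required peak track {name!r} is missing")
    grid.genome.validate_region(config.window)
    first, last = grid.bin_span(config.window)
    win = slice(first, last)

    cn_sum = cn_tracks["cn_sum"]
    cn_gain = cn_tracks["cn_gain"]
    win_sum = cn_sum[win]
    threshold_sum = float(np.quantile(win_sum[np.isfinite(win_sum)],
                                      config.cn_sum_percentile))
    frac = config.track_bin_fraction
    rhmr_bins = rhmr.to_bins(grid, min_fraction=frac)
    peak_bins = {name: track.to_bins(grid, min_fraction=frac) > 0
                 for name, track in peaks.items()}

    ok = np.zeros(grid.n_bins, dtype=bool)
    ok[win] = True
    ok &= cn_sum >= threshold_sum
    ok &= cn_gain >= config.min_cn_gain
    ok &= rhmr_bins >= config.min_rhmr_recurrence
    if config.required_peaks:
        stack = np.vstack([peak_bins[name] for name in config.required_peaks])
        ok &= stack.all(axis=0) if config.peak_mode == "all" else stack.any(axis=0)

    idx = np.flatnonzero(ok)
    candidates: list[Candidate] = []
    if idx.size == 0:
        return candidates
    # merge runs of passing bins with gaps <= merge_gap (within one chromosome)
    gap_bins = config.merge_gap // grid.bin_size
    runs: list[tuple[int, int]] = []
    run_start = idx[0]
    prev = idx[0]
    for b in idx[1:]:
        if b - prev - 1 <= gap_bins and grid.chrom_index[b] == grid.chrom_index[prev]:
            prev = b
            continue
        runs.append((run_start, prev + 1))
        run_start = b
        prev = b
    runs.append((run_start, prev + 1))

    for a, b in runs:
        region = grid.region_of_bins(a, b)
        if region.length < config.min_width:
            continue
        ev = {
            "cn_sum_mean": float(np.nanmean(cn_sum[a:b])),
            "cn_gain_mean": float(np.nanmean(cn_gain[a:b])),
            "rhmr_max": float(np.max(rhmr_bins[a:b])),
            "dup_count_max": float(np.max(cn_tracks.get("dup_count",
                                                        np.zeros(grid.n_bins))[a:b])),
            "cn_sum_threshold": threshold_sum,
        }
        for name, hit in peak_bins.items():
            ev[f"peak_{name}"] = float(hit[a:b].any())
        candidates.append(Candidate(region, ev))
    return candidates


def loop_support(
    candidates: list[Candidate],
    loops: list[tuple[Region, Region]],
    promoter: Region,
) -> list[Candidate]:
    """Flag candidates with a chromatin loop to the promoter.

    True iff some loop has one anchor overlapping the candidate and the
    other anchor overlapping the promoter (a loop with both anchors on the
    candidate does not count).
    """
    for cand in candidates:
        supported = False
        for a1, a2 in loops:
            if (overlap_bp(a1, cand.region) > 0 and overlap_bp(a2, promoter) > 0) or (
                overlap_bp(a2, cand.region) > 0 and overlap_bp(a1, promoter) > 0
            ):
                supported = True
                break
        cand.loop_supported = supported
    return candidates
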