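"""Genome-wide binned paired copy-number differential scan.

Per-sample segmented copy-number profiles are projected onto a fixed bin
grid (length-weighted average of intersecting segments), then each bin is
tested for copy gain (post > pre) and loss (post < pre) across patient
pairs with the Wilcoxon signed-rank test. Nominal p-values are reported
alongside Benjamini-Hochberg q-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import BinGrid, GenomeDef, Region
from .stats import (
    EXACT_N_MAX,
    bh_adjust,
    signed_rank_exact_tail,
    spearman,
    wilcoxon_signed_rank,
)

__all__ = [
    "SegmentProfile",
    "BinCnMatrix",
    "project_segments",
    "project_cohort",
    "paired_bin_scan",
    "locus_summary",
    "region_mean_copy",
]


@dataclass
class SegmentProfile:
    """Segmented copy-number profile of one sample.

    ``segments`` maps chromosome -> (starts, ends, copy_number) arrays;
    segments within a chromosome must be sorted and non-overlapping.
    """

    sample_id: str
    segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    purity: float | None = None
    ploidy: float | None = None

    def __post_init__(self) -> None:
        clean = {}
        for chrom, (s, e, cn) in self.segments.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            cn = np.asarray(cn, dtype=float)
            order = np.argsort(s, kind="mergesort")
            s, e, cn = s[order], e[order], cn[order]
            if np.any(e <= s):
                raise ValueError(f"{self.sample_id}/{chrom}: coordinate inversion")
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"{self.sample_id}/{chrom}: overlapping segments")
            if not np.all(np.isfinite(cn)) or np.any(cn < 0):
                raise ValueError(f"{self.sample_id}/{chrom}: invalid copy number")
            clean[chrom] = (s, e, cn)
        self.segments = clean

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        sample_id: str,
        purity: float | None = None,
        ploidy: float | None = None,
    ) -> "SegmentProfile":
        """Build from a SEG-like frame (columns chrom, start, end, copy_number)."""
        sub = df[df["sample"] == sample_id] if "sample" in df.columns else df
        segs = {
            chrom: (
                g["start"].to_numpy(),
                g["end"].to_numpy(),
                g["copy_number"].to_numpy(),
            )
            for chrom, g in sub.groupby("chrom", sort=False)
        }
        return cls(sample_id, segs, purity=purity, ploidy=ploidy)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, (s, e, cn) in self.segments.items():
            for a, b, c in zip(s, e, cn):
                rows.append((self.sample_id, chrom, int(a), int(b), float(c)))
        return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "copy_number"])


@dataclass
class BinCnMatrix:
    """Per-bin copy number for a set of samples, with a coverage mask."""

    grid: BinGrid
    sample_ids: list[str]
    values: np.ndarray  # bins x samples
    mask: np.ndarray  # bins x samples, True = insufficient coverage

    def __post_init__(self) -> None:
        if self.values.shape != (self.grid.n_bins, len(self.sample_ids)):
            raise ValueError("values shape mismatch")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape mismatch")

    def column(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)


def project_segments(
    profile: SegmentProfile,
    grid: BinGrid,
    min_covered_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Project one segment profile onto a bin grid.

    The bin value is the length-weighted average copy number of intersecting
    segments; bins whose covered fraction falls below
    ``min_covered_fraction`` are masked. An empty profile yields an
    all-masked column, not an error.

    Returns
    -------
    values, mask : ndarray
        Length ``grid.n_bins``; masked entries hold NaN.
    """
    weighted = np.zeros(grid.n_bins)
    covered = np.zeros(grid.n_bins)
    bs = grid.bin_size
    for chrom, (starts, ends, cns) in profile.segments.items():
        if chrom not in grid.genome.chrom_lengths:
            raise ValueError(f"profile chromosome {chrom!r} not in grid genome")
        off = grid.offsets[chrom]
        L = grid.genome.length_of(chrom)
        for s, e, cn in zip(starts, ends, cns):
            e = min(int(e), L)
            s = int(s)
            if e <= s:
                continue
            b0 = s // bs
            b1 = (e - 1) // bs
            idx = np.arange(off + b0, off + b1 + 1)
            ov = np.minimum(grid.ends[idx], e) - np.maximum(grid.starts[idx], s)
            weighted[idx] += cn * ov
            covered[idx] += ov
    mask = covered < min_covered_fraction * grid.widths
    values = np.full(grid.n_bins, np.nan)
    ok = covered > 0
    values[ok] = weighted[ok] / covered[ok]
    values[mask] = np.nan
    return values, mask


def project_cohort(
    profiles: list[SegmentProfile],
    grid: BinGrid,
    min_covered_fraction: float = 0.5,
) -> BinCnMatrix:
    """Stack per-sample projections into a bins x samples matrix."""
    vals = np.empty((grid.n_bins, len(profiles)))
    mask = np.empty((grid.n_bins, len(profiles)), dtype=bool)
    for j, prof in enumerate(profiles):
        v, m = project_segments(prof, grid, min_covered_fraction)
        vals[:, j] = v
        mask[:, j] = m
    return BinCnMatrix(grid, [p.sample_id for p in profiles], vals, mask)


def _tie_term_rows(absd: np.ndarray) -> np.ndarray:
    """Per-row sum(t^3 - t) over groups of tied finite values (NaN ignored)."""
    out = np.zeros(absd.shape[0])
    srt = np.sort(absd, axis=1)  # NaNs sort to the end
    same = srt[:, 1:] == srt[:, :-1]
    rows = np.flatnonzero(same.any(axis=1))
    for i in rows:
        vals = srt[i][np.isfinite(srt[i])]
        _, t = np.unique(vals, return_counts=True)
        out[i] = float((t**3 - t).sum())
    return out


def paired_bin_scan(
    pre: BinCnMatrix,
    post: BinCnMatrix,
    pairs: list[tuple[str, str]],
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Per-bin paired signed-rank scan for copy gain and loss.

    Parameters
    ----------
    pre, post : BinCnMatrix
        Projections of the pre- and post-treatment profiles on a shared grid.
    pairs : list of (pre_sample, post_sample)
        One pair per patient.
    min_pairs : int
        Bins with fewer informative (unmasked in both members) pairs are
        reported untested (NaN p-values).

    Returns
    -------
    DataFrame with columns bin, chrom, start, end, n_pairs, p_gain, p_loss,
    q_gain, q_loss, median_delta. Bins where every informative pair has a
    zero difference get p = 1 (no evidence).
    """
    if pre.grid is not post.grid and pre.grid.n_bins != post.grid.n_bins:
        raise ValueError("pre and post matrices must share a grid")
    grid = pre.grid
    if not pairs:
        raise ValueError("no valid pairs supplied")
    icols = [pre.column(a) for a, _ in pairs]
    jcols = [post.column(b) for _, b in pairs]
    d = post.values[:, jcols] - pre.values[:, icols]
    informative = np.isfinite(d)
    n_informative = informative.sum(axis=1)

    absd = np.abs(d)
    absd[absd == 0.0] = np.nan  # zero differences are dropped from the test
    nz = np.isfinite(absd)
    m = nz.sum(axis=1)

    with np.errstate(invalid="ignore"):
        ranks = sps.rankdata(absd, axis=1, nan_policy="omit")
    pos = nz & (d > 0)
    w_plus = np.nansum(np.where(pos, ranks, 0.0), axis=1)

    mu = m * (m + 1) / 4.0
    var = m * (m + 1) * (2 * m + 1) / 24.0 - _tie_term_rows(absd) / 48.0
    sd = np.sqrt(np.maximum(var, 0.0))

    p_gain = np.full(grid.n_bins, np.nan)
    p_loss = np.full(grid.n_bins, np.nan)
    tested = n_informative >= min_pairs
    approx = tested & (m > EXACT_N_MAX) & (sd > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_gain[approx] = sps.norm.sf((w_plus[approx] - mu[approx] - 0.5) / sd[approx])
        p_loss[approx] = sps.norm.cdf((w_plus[approx] - mu[approx] + 0.5) / sd[approx])

    # exact / degenerate / tied small-n bins, handled row by row
    slow = np.flatnonzero(tested & ~approx)
    for i in slow:
        di = d[i][informative[i]]
        p_gain[i] = wilcoxon_signed_rank(di, alternative="greater").p_value
        p_loss[i] = wilcoxon_signed_rank(di, alternative="less").p_value
    np.clip(p_gain, np.nextafter(0, 1), 1.0, out=p_gain, where=np.isfinite(p_gain))
    np.clip(p_loss, np.nextafter(0, 1), 1.0, out=p_loss, where=np.isfinite(p_loss))

    with np.errstate(invalid="ignore"):
        median_delta = np.where(
            n_informative > 0,
            np.nanmedian(np.where(informative, d, np.nan), axis=1),
            np.nan,
        )

    return pd.DataFrame(
        {
            "bin": np.arange(grid.n_bins),
            "chrom": grid.chroms,
            "start": grid.starts,
            "end": grid.ends,
            "n_pairs": n_informative,
            "p_gain": p_gain,
            "p_loss": p_loss,
            "q_gain": bh_adjust(p_gain),
            "q_loss": bh_adjust(p_loss),
            "median_delta": median_delta,
        }
    )


def region_mean_copy(profile: SegmentProfile, region: Region) -> float:
    """Length-weighted mean copy number of a profile over a region."""
    if region.chrom not in profile.segments:
        raise ValueError(
            f"region {region} not covered by any segment of {profile.sample_id}"
        )
    s, e, cn = profile.segments[region.chrom]
    ov = np.minimum(e, region.end) - np.maximum(s, region.start)
    ov = np.clip(ov, 0, None)
    total = ov.sum()
    if total == 0:
        raise ValueError(
            f"region {region} not covered by any segment of {profile.sample_id}"
        )
    return float((cn * ov).sum() / total)


@dataclass
class LocusSummary:
    region: Region
    pre_values: np.ndarray
    post_values: np.ndarray
    statistic: float
    p_gain: float
    p_loss: float
    p_two_sided: float


def locus_summary(
    pre_profiles: list[SegmentProfile],
    post_profiles: list[SegmentProfile],
    pairs: list[tuple[str, str]],
    region: Region,
) -> LocusSummary:
    """Paired copy-number summary of a single locus.

    Computes per-sample length-weighted mean copy over ``region`` and the
    paired signed-rank test in both directions. Use
    :func:`pairscan.stats.spearman` for copy-vs-expression comparisons.
    """
    pre_by_id = {p.sample_id: p for p in pre_profiles}
    post_by_id = {p.sample_id: p for p in post_profiles}
    pre_vals, post_vals = [], []
    for a, b in pairs:
        pre_vals.append(region_mean_copy(pre_by_id[a], region))
        post_vals.append(region_mean_copy(post_by_id[b], region))
    pre_arr = np.asarray(pre_vals)
    post_arr = np.asarray(post_vals)
    gain = wilcoxon_signed_rank(post_arr, pre_arr, alternative="greater")
    loss = wilcoxon_signed_rank(post_arr, pre_arr, alternative="less")
    two = wilcoxon_signed_rank(post_arr, pre_arr, alternative="two_sided")
    return LocusSummary(
        region, pre_arr, post_arr, gain.statistic, gain.p_value, loss.p_value, two.p_value
    )
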