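"""Amplification calls and tandem-duplication (TD) overlap classification.

A sample is called amplified when the length-weighted mean copy of the gene
OR of its enhancer reaches the threshold (default >= 4, inclusive).
Duplication-type structural variants overlapping the locus mark the
amplification as TD-backed; amplifications without an underlying TD are a
signature of other mechanisms (e.g. extrachromosomal DNA, which tends to
reach higher copy levels).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cnscan import SegmentProfile, region_mean_copy
from .genome import Region, overlap_bp
from .stats import RankSumResult, rank_sum_test

__all__ = [
    "SvCall",
    "AmpCall",
    "call_amplification",
    "td_overlap",
    "compare_cn_by_td",
    "new_td_events",
]

SV_TYPES = {"DUP", "DEL", "INV", "TRA", "INS", "BND"}


@dataclass(frozen=True)
class SvCall:
    sample_id: str
    breakend1: Region
    breakend2: Region
    svtype: str

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")

    @property
    def intrachromosomal(self) -> bool:
        return self.breakend1.chrom == self.breakend2.chrom

    @property
    def span(self) -> Region:
        """Interval between the outermost breakend coordinates (intrachromosomal)."""
        if not self.intrachromosomal:
            raise ValueError("span undefined for interchromosomal events")
        start = min(self.breakend1.start, self.breakend2.start)
        end = max(self.breakend1.end, self.breakend2.end)
        return Region(self.breakend1.chrom, start, end)


@dataclass
class AmpCall:
    sample_id: str
    gene_copy: float
    enhancer_copy: float
    status: str  # "amplified" | "nonamplified"
    td_backed_gene: bool = False
    td_backed_enhancer: bool = False

    @property
    def amplified(self) -> bool:
        return self.status == "amplified"

    @property
    def td_backed(self) -> bool:
        return self.td_backed_gene or self.td_backed_enhancer


def call_amplification(
    profile: SegmentProfile,
    gene: Region,
    enhancer: Region,
    threshold: float = 4.0,
    svs: list[SvCall] | None = None,
    containment: bool = False,
) -> AmpCall:
    """Amplification status of a gene/enhancer pair in one sample.

    Amplified iff gene copy >= threshold OR enhancer copy >= threshold
    (inclusive). When ``svs`` for this sample are provided, TD backing per
    region is annotated via :func:`td_overlap`.
    """
    gene_copy = region_mean_copy(profile, gene)
    enh_copy = region_mean_copy(profile, enhancer)
    status = "amplified" if (gene_copy >= threshold or enh_copy >= threshold) else "nonamplified"
    td_gene = td_enh = False
    if svs is not None:
        sample_svs = [s for s in svs if s.sample_id == profile.sample_id]
        _, td_gene = td_overlap(sample_svs, gene, containment=containment)
        _, td_enh = td_overlap(sample_svs, enhancer, containment=containment)
    return AmpCall(profile.sample_id, gene_copy, enh_copy, status, td_gene, td_enh)


def td_overlap(
    svs: list[SvCall],
    region: Region,
    containment: bool = False,
) -> tuple[int, bool]:
    """Count DUP-type calls whose span overlaps (or contains) a region.

    Overlap means >= 1 bp shared (the default); ``containment=True``
    requires the duplication span to cover the whole region.
    """
    count = 0
    for sv in svs:
        if sv.svtype != "DUP" or not sv.intrachromosomal:
            continue
        span = sv.span
        if containment:
            if span.contains(region):
                count += 1
        elif overlap_bp(span, region) > 0:
            count += 1
    return count, count > 0


@dataclass
class TdCnComparison:
    p_value: float
    median_td_free: float
    median_td_backed: float
    n_td_free: int
    n_td_backed: int
    direction: str  # which group has higher copies


def compare_cn_by_td(
    amp_calls: list[AmpCall],
    copy_attr: str = "gene_copy",
) -> TdCnComparison:
    """Rank-sum comparison of copy number between TD-free and TD-backed calls.

    Restricted to amplified samples (the question is which mechanism backs
    an amplification). Requires >= 2 samples per group.
    """
    amped = [c for c in amp_calls if c.amplified]
    free = [getattr(c, copy_attr) for c in amped if not c.td_backed]
    backed = [getattr(c, copy_attr) for c in amped if c.td_backed]
    if len(free) < 2 or len(backed) < 2:
        raise ValueError(
            f"need >=2 samples per group (TD-free {len(free)}, TD-backed {len(backed)})"
        )
    res: RankSumResult = rank_sum_test(free, backed)
    direction = {
        "x_higher": "td_free_higher",
        "y_higher": "td_backed_higher",
        "tied": "tied",
    }[res.direction]
    return TdCnComparison(
        res.p_value, res.median_x, res.median_y, len(free), len(backed), direction
    )


def new_td_events(
    pre_svs: list[SvCall],
    post_svs: list[SvCall],
    pairs: list[tuple[str, str]],
    region: Region,
    containment: bool = False,
) -> pd.DataFrame:
    """Pairs gaining a duplication over a region after treatment.

    A pair is flagged iff the post sample has >= 1 DUP overlapping the
    region and the pre sample has none.
    """
    pre_by: dict[str, list[SvCall]] = defaultdict(list)
    post_by: dict[str, list[SvCall]] = defaultdict(list)
    pre_ids = {a for a, _ in pairs}
    post_ids = {b for _, b in pairs}
    for sv in pre_svs:
        if sv.sample_id not in pre_ids:
            raise ValueError(f"unpaired pre sample {sv.sample_id!r}")
        pre_by[sv.sample_id].append(sv)
    for sv in post_svs:
        if sv.sample_id not in post_ids:
            raise ValueError(f"unpaired post sample {sv.sample_id!r}")
        post_by[sv.sample_id].append(sv)
    rows = []
    for pre_id, post_id in pairs:
        n_pre, has_pre = td_overlap(pre_by.get(pre_id, []), region, containment)
        n_post, has_post = td_overlap(post_by.get(post_id, []), region, containment)
        rows.append((pre_id, post_id, n_pre, n_post, has_post and not has_pre))
    return pd.DataFrame(
        rows, columns=["pre_sample", "post_sample", "n_td_pre", "n_td_post", "gained"]
    )
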