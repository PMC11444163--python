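"""Treatment-emergent mutation logic.

Works on annotated somatic call sets (variant calling and annotation are
upstream; we consume their output). Presence/absence of a variant is
decided on exact (chrom, pos, ref, alt) identity within the call set; an
optional callable-regions mask can veto "newly arising" claims at sites
that were not assessable in the pre-treatment sample.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd
import numpy as np

from .genome import Region
from .stats import spearman

__all__ = [
    "MutationCall",
    "PROTEIN_ALTERING_CLASSES",
    "IMPACT_CLASSES",
    "qualifying_mutations",
    "emergent_noncoding",
    "recurrent_mutations",
    "vaf_purity_delta",
]

IMPACT_CLASSES = frozenset(
    {
        "missense",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift",
        "inframe_indel",
        "splice_donor",
        "splice_acceptor",
        "synonymous",
        "noncoding",
    }
)

#: classes predicted to change the protein sequence (loss-of-function and missense)
PROTEIN_ALTERING_CLASSES = frozenset(
    {
        "missense",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift",
        "inframe_indel",
        "splice_donor",
        "splice_acceptor",
    }
)


@dataclass(frozen=True)
class MutationCall:
    sample_id: str
    region: Region  # 1 bp for SNVs, ref span for indels
    ref: str
    alt: str
    gene: str | None
    impact: str
    protein_change: str | None = None
    vaf: float = np.nan

    def __post_init__(self) -> None:
        if self.impact not in IMPACT_CLASSES:
            raise ValueError(f"unknown impact class {self.impact!r}")
        if np.isfinite(self.vaf) and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"VAF out of range: {self.vaf}")

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        """Identity used for presence/absence comparisons."""
        return (self.region.chrom, self.region.start, self.ref, self.alt)


def _by_sample(calls: list[MutationCall]) -> dict[str, list[MutationCall]]:
    out: dict[str, list[MutationCall]] = defaultdict(list)
    for c in calls:
        out[c.sample_id].append(c)
    return out


def _check_paired(by_sample: dict, pairs: list[tuple[str, str]], which: int) -> None:
    known = {p[which] for p in pairs}
    for sid in by_sample:
        if sid not in known:
            raise ValueError(f"sample {sid!r} is not in the pair map")


@dataclass
class EmergenceResult:
    gene_counts: pd.DataFrame  # gene, n_pairs (pairs with >=1 qualifying mutation)
    provenance: pd.DataFrame  # per qualifying mutation


def qualifying_mutations(
    pre_calls: list[MutationCall],
    post_calls: list[MutationCall],
    pairs: list[tuple[str, str]],
    protein_altering_classes: frozenset[str] = PROTEIN_ALTERING_CLASSES,
    pre_callable_mask: dict[str, list[Region]] | None = None,
) -> EmergenceResult:
    """Rank genes by pairs carrying >=1 qualifying (new, protein-altering) mutation.

    A mutation qualifies iff it is called in the post sample, has no call at
    the same (chrom, pos, ref, alt) in the paired pre sample, and its impact
    class is protein-altering. Ties in the ranking are broken
    lexicographically by gene symbol. If ``pre_callable_mask`` is given
    (sample -> callable regions), post-only calls at sites not callable in
    the pre sample are vetoed.
    """
    pre_by = _by_sample(pre_calls)
    post_by = _by_sample(post_calls)
    _check_paired(pre_by, pairs, 0)
    _check_paired(post_by, pairs, 1)

    rows = []
    gene_pairs: dict[str, set[str]] = defaultdict(set)
    for pre_id, post_id in pairs:
        pre_sites = {c.site_key for c in pre_by.get(pre_id, [])}
        for call in post_by.get(post_id, []):
            if call.impact not in protein_altering_classes:
                continue
            if call.site_key in pre_sites:
                continue
            if pre_callable_mask is not None:
                callable_regions = pre_callable_mask.get(pre_id, [])
                if not any(r.overlaps(call.region) for r in callable_regions):
                    continue
            gene = call.gene or "."
            gene_pairs[gene].add(pre_id)
            pre_vaf = np.nan  # absent pre by definition
            rows.append(
                (gene, pre_id, post_id, str(call.region), call.ref, call.alt,
                 call.impact, call.protein_change, pre_vaf, call.vaf)
            )
    counts = pd.DataFrame(
        sorted(((g, len(s)) for g, s in gene_pairs.items()),
               key=lambda t: (-t[1], t[0])),
        columns=["gene", "n_pairs"],
    )
    prov = pd.DataFrame(
        rows,
        columns=["gene", "pre_sample", "post_sample", "site", "ref", "alt",
                 "impact", "protein_change", "pre_vaf", "post_vaf"],
    )
    return EmergenceResult(counts, prov)


def emergent_noncoding(
    pre_calls: list[MutationCall],
    post_calls: list[MutationCall],
    pairs: list[tuple[str, str]],
    naive_calls: list[MutationCall],
    min_pairs: int = 2,
) -> pd.DataFrame:
    """Recurrent noncoding mutations newly arising after treatment.

    Retains noncoding variants newly arising in >=1 pair and absent from
    every treatment-naive call set; reports those recurrent across
    ``min_pairs`` or more pairs.
    """
    pre_by = _by_sample(pre_calls)
    post_by = _by_sample(post_calls)
    naive_sites = {c.site_key for c in naive_calls}

    emergent_pairs: dict[tuple, set[str]] = defaultdict(set)
    example: dict[tuple, MutationCall] = {}
    for pre_id, post_id in pairs:
        pre_sites = {c.site_key for c in pre_by.get(pre_id, [])}
        for call in post_by.get(post_id, []):
            if call.impact != "noncoding":
                continue
            key = call.site_key
            if key in pre_sites or key in naive_sites:
                continue
            emergent_pairs[key].add(pre_id)
            example.setdefault(key, call)
    rows = [
        (key[0], key[1], key[2], key[3], len(p), sorted(p))
        for key, p in emergent_pairs.items()
        if len(p) >= min_pairs
    ]
    rows.sort(key=lambda r: (r[0], r[1]))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "ref", "alt", "n_pairs", "pair_ids"]
    )


def recurrent_mutations(
    calls: list[MutationCall],
    sample_to_patient: dict[str, str] | None = None,
    min_samples: int = 2,
    protein_coding_only: bool = True,
) -> pd.DataFrame:
    """Unique (gene, protein_change) variants seen in >= ``min_samples`` samples.

    Counting is at the sample level; when ``sample_to_patient`` is given the
    number of distinct patients is reported alongside (a variant observed in
    3 samples, 2 from one patient, counts as 3 samples / 2 patients).
    """
    groups: dict[tuple[str, str], set[str]] = defaultdict(set)
    for c in calls:
        if protein_coding_only and c.impact not in PROTEIN_ALTERING_CLASSES:
            continue
        if c.gene is None or c.protein_change is None:
            continue
        groups[(c.gene, c.protein_change)].add(c.sample_id)
    rows = []
    for (gene, pchange), samples in groups.items():
        if len(samples) < min_samples:
            continue
        n_patients = (
            len({sample_to_patient[s] for s in samples})
            if sample_to_patient is not None
            else np.nan
        )
        rows.append((gene, pchange, len(samples), n_patients, sorted(samples)))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return pd.DataFrame(
        rows, columns=["gene", "protein_change", "n_samples", "n_patients", "samples"]
    )


@dataclass
class VafPurityResult:
    per_pair: pd.DataFrame  # pair, mean_delta_vaf, delta_purity, n_shared
    rho: float
    p_value: float
    degenerate: bool = False


def vaf_purity_delta(
    pre_calls: list[MutationCall],
    post_calls: list[MutationCall],
    pairs: list[tuple[str, str]],
    purities: dict[str, float],
) -> VafPurityResult:
    """Per-pair mean VAF change of shared mutations vs purity change.

    The Spearman correlation across pairs diagnoses the purity confound on
    VAF comparisons: when it is strong, shared-mutation VAF shifts mostly
    track purity, motivating analyses restricted to newly arising calls.
    """
    pre_by = _by_sample(pre_calls)
    post_by = _by_sample(post_calls)
    rows = []
    for pre_id, post_id in pairs:
        pre_map = {c.site_key: c.vaf for c in pre_by.get(pre_id, [])}
        deltas = [
            c.vaf - pre_map[c.site_key]
            for c in post_by.get(post_id, [])
            if c.site_key in pre_map
            and np.isfinite(c.vaf)
            and np.isfinite(pre_map[c.site_key])
        ]
        if not deltas:
            continue
        rows.append(
            (
                f"{pre_id}|{post_id}",
                float(np.mean(deltas)),
                purities[post_id] - purities[pre_id],
                len(deltas),
            )
        )
    per_pair = pd.DataFrame(
        rows, columns=["pair", "mean_delta_vaf", "delta_purity", "n_shared"]
    )
    if len(per_pair) == 0:
        return VafPurityResult(per_pair, np.nan, np.nan, degenerate=True)
    if len(per_pair) < 2:
        return VafPurityResult(per_pair, np.nan, np.nan, degenerate=True)
    rho, p = spearman(per_pair["mean_delta_vaf"], per_pair["delta_purity"])
    return VafPurityResult(per_pair, rho, p)
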