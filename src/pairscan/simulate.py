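"""Synthetic paired-cohort generator.

Emulates the statistical structure the downstream analyses assume: ~45
patients sampled before treatment and again at progression; purity-scaled
variant allele fractions; segmented copy-number profiles with a spiked
amplified locus (tandem-duplication-backed or TD-free); negative-binomial
paired expression with patient, batch, and purity effects plus designated
treatment-responsive genes; isoform splits of one gene; evidence tracks
containing a plantable candidate-enhancer region; and survival times with a
configurable expression-group x treatment interaction.

All randomness flows from a single seed; each component draws from its own
fixed sub-stream, so generating a subset of components reproduces exactly
what a full run would have produced for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .ampclass import SvCall
from .cnscan import SegmentProfile, region_mean_copy
from .genome import GenomeDef, GenomicTrack, Region
from .mutscan import MutationCall

__all__ = [
    "SpikeSpec",
    "HotspotSpec",
    "MutationSpec",
    "ExpressionSpec",
    "IsoformSpec",
    "TrackSpec",
    "SurvivalSpec",
    "CohortConfig",
    "PairedCohort",
    "simulate_cohort",
    "write_fixture",
    "nb_counts",
]

_COMPONENTS = ("meta", "segments", "mutations", "expression", "isoforms",
               "tracks", "survival")

DEFAULT_GENOME = GenomeDef.from_lengths(
    {"chr1": 5_000_000, "chr2": 5_000_000, "chrX": 5_000_000}
)

# locus layout on the toy chrX (all inside the default spiked locus)
DEFAULT_SPIKE = Region("chrX", 2_250_000, 2_350_000)
DEFAULT_ENHANCER = Region("chrX", 2_255_000, 2_262_000)
DEFAULT_PROMOTER = Region("chrX", 2_272_000, 2_274_000)
DEFAULT_GENE = Region("chrX", 2_272_000, 2_330_000)
DEFAULT_PLANT = Region("chrX", 2_337_800, 2_343_300)


@dataclass
class SpikeSpec:
    """A recurrent post-treatment copy-number gain at one locus."""

    region: Region = DEFAULT_SPIKE
    extra_copies: float = 3.0
    fraction_of_pairs: float = 0.6
    mechanism: str = "td"  # "td" or "focal_no_td"
    baseline_extra: float = 2.0  # pre-existing amplification amplitude
    baseline_fraction: float = 0.5  # samples carrying the baseline amplification
    baseline_td_fraction: float = 0.65  # baseline amplifications backed by a TD

    def __post_init__(self) -> None:
        if self.mechanism not in ("td", "focal_no_td"):
            raise ValueError(f"unknown spike mechanism {self.mechanism!r}")
        for frac in (self.fraction_of_pairs, self.baseline_fraction,
                     self.baseline_td_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("spike fractions must be in [0, 1]")


@dataclass
class HotspotSpec:
    """A recurrently emerging coding hotspot mutation."""

    gene: str = "AR"
    protein_change: str = "L702H"
    offset: int = 10_000  # bp into the gene region
    emergence_prob: float = 0.05
    clonal_fraction: float = 1.0
    impact: str = "missense"

    def __post_init__(self) -> None:
        if not 0.0 <= self.emergence_prob <= 1.0:
            raise ValueError("emergence_prob must be in [0, 1]")
        if not 0.0 < self.clonal_fraction <= 1.0:
            raise ValueError("clonal_fraction must be in (0, 1]")


@dataclass
class MutationSpec:
    """Background somatic small-variant model."""

    n_trunk: int = 20  # shared pre/post calls per patient
    n_private: int = 8  # additional calls per sample
    depth: int = 100
    class_probs: dict[str, float] = field(
        default_factory=lambda: {"missense": 0.2, "synonymous": 0.15, "noncoding": 0.65}
    )


@dataclass
class ExpressionSpec:
    """Negative-binomial paired expression model."""

    n_genes: int = 1000
    mean_log2_mu: float = 5.0
    mean_log2_sd: float = 2.0
    dispersion_log_mean: float = float(np.log(0.1))
    dispersion_log_sd: float = 0.5
    # post-vs-pre log2 fold changes on the tumor component
    lfc: dict[str, float] = field(
        default_factory=lambda: {"SSTR1": -1.5, "TRPM8": -1.2, "LMO3": 1.0, "SFRP5": 1.0}
    )
    # designated responsive genes are well-expressed receptors/TFs, not
    # genes at the detection floor: fix their baseline and dispersion
    responsive_log2_mean: float = 7.0
    responsive_dispersion: float = 0.1
    dosage_genes: tuple[str, ...] = ("AR",)  # expression scales with local copy / 2
    # treatment-responsive genes are modeled as tumor-restricted (negligible
    # stromal expression), so purity dilutes their signal toward ~zero rather
    # than toward an unrelated stromal level
    tumor_restricted_stromal_fraction: float = 0.05
    patient_sd: float = 0.3  # log2 patient random effect
    batch_sd: float = 0.25  # log2 per-gene batch offsets
    library_sd: float = 0.2  # log-normal library size factors

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("need at least 10 genes")


@dataclass
class IsoformSpec:
    """Two-transcript split of one gene, with one designated converter pair."""

    gene: str = "AR"
    transcripts: tuple[str, str] = ("AR-FL", "AR-V7")
    pre_fractions: tuple[float, float] = (0.95, 0.05)
    post_fractions: tuple[float, float] = (0.95, 0.05)
    converter_patient: int | None = 0
    converter_pre: tuple[float, float] = (0.999, 0.001)
    converter_post: tuple[float, float] = (0.393, 0.607)
    concentration: float = 400.0  # Dirichlet concentration of per-sample noise


@dataclass
class TrackSpec:
    """Evidence tracks with one plantable candidate region."""

    planted: Region = DEFAULT_PLANT
    rhmr_recurrence: float = 20.0
    n_background: int = 30
    background_width: tuple[int, int] = (2_000, 6_000)
    background_recurrence_mean: float = 2.0
    peak_names: tuple[str, ...] = ("AR", "FOXA1", "HOXB13", "H3K27ac")
    planted_peaks: tuple[str, ...] = ("FOXA1", "HOXB13", "H3K27ac")  # no AR signal
    n_background_loops: int = 5


@dataclass
class SurvivalSpec:
    """Exponential survival with an expression-group x treatment interaction."""

    baseline_hazard: float = 0.02  # events per month
    treatment_log_hr: float = -0.7  # benefit of the targeted therapy
    group_low_log_hr: float = 0.2
    interaction_log_hr: float = 0.8  # low-expression tumors lose treatment benefit
    censor_range: tuple[float, float] = (12.0, 72.0)

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")


@dataclass
class CohortConfig:
    """Full description of a synthetic paired cohort."""

    n_patients: int = 45
    purity_range: tuple[float, float] = (0.2, 0.9)
    batches: tuple[str, ...] = ("batchA", "batchB")
    genome: GenomeDef = field(default_factory=lambda: DEFAULT_GENOME)
    gene_region: Region = DEFAULT_GENE
    enhancer_region: Region = DEFAULT_ENHANCER
    promoter_region: Region = DEFAULT_PROMOTER
    spike: SpikeSpec = field(default_factory=SpikeSpec)
    hotspots: tuple[HotspotSpec, ...] = (
        HotspotSpec(protein_change="L702H", offset=10_000, emergence_prob=0.045),
        HotspotSpec(protein_change="H875Y", offset=20_000, emergence_prob=0.045),
        HotspotSpec(protein_change="T878A", offset=20_500, emergence_prob=0.02),
    )
    mutations: MutationSpec = field(default_factory=MutationSpec)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    isoforms: IsoformSpec = field(default_factory=IsoformSpec)
    tracks: TrackSpec = field(default_factory=TrackSpec)
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    segment_mean_length: int = 250_000
    segment_cn_sd: float = 0.4
    n_background_svs: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("need at least 1 patient")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("purity range must satisfy 0 < low <= high <= 1")
        for name, region in (("spike", self.spike.region),
                             ("gene", self.gene_region),
                             ("enhancer", self.enhancer_region),
                             ("promoter", self.promoter_region),
                             ("planted track", self.tracks.planted)):
            if not self.genome.contains_region(region):
                raise ValueError(f"{name} region {region} outside the genome")

    @classmethod
    def from_dict(cls, payload: dict) -> "CohortConfig":
        """Build a config from plain nested dicts (YAML-friendly).

        Sub-sections (spike, expression, ...) may be dicts; regions may be
        "chrN:start-end" strings; the genome a {chrom: length} mapping.
        """
        def region(v):
            if isinstance(v, Region):
                return v
            chrom, _, span = str(v).partition(":")
            start, _, end = span.partition("-")
            return Region(chrom, int(start), int(end))

        sub = {
            "spike": SpikeSpec, "mutations": MutationSpec,
            "expression": ExpressionSpec, "isoforms": IsoformSpec,
            "tracks": TrackSpec, "survival": SurvivalSpec,
        }
        kwargs = {}
        for key, value in payload.items():
            if key in sub and isinstance(value, dict):
                value = dict(value)
                for rkey in ("region", "planted"):
                    if rkey in value:
                        value[rkey] = region(value[rkey])
                kwargs[key] = sub[key](**value)
            elif key == "genome" and isinstance(value, dict):
                kwargs[key] = GenomeDef.from_lengths(
                    {k: int(v) for k, v in value.items()}
                )
            elif key.endswith("_region"):
                kwargs[key] = region(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def null(cls, n_patients: int = 40, seed: int = 0, **kwargs) -> "CohortConfig":
        """A cohort with every treatment effect switched off."""
        cfg = cls(
            n_patients=n_patients,
            spike=SpikeSpec(fraction_of_pairs=0.0, baseline_fraction=0.0),
            hotspots=(),
            expression=ExpressionSpec(lfc={}, dosage_genes=()),
            survival=SurvivalSpec(treatment_log_hr=0.0, group_low_log_hr=0.0,
                                  interaction_log_hr=0.0),
            seed=seed,
            **kwargs,
        )
        return cfg


@dataclass
class PairedCohort:
    """All simulated data for one cohort."""

    config: CohortConfig
    meta: pd.DataFrame  # sample sheet
    profiles: dict[str, SegmentProfile]
    mutations: list[MutationCall]
    svs: list[SvCall]
    counts: pd.DataFrame  # genes x samples
    transcript_table: pd.DataFrame
    rhmr: GenomicTrack | None
    peaks: dict[str, GenomicTrack]
    loops: list[tuple[Region, Region]]
    survival: pd.DataFrame

    @property
    def pairs(self) -> list[tuple[str, str]]:
        pre = self.meta[self.meta["timepoint"] == "pre"].set_index("patient_id")
        post = self.meta[self.meta["timepoint"] == "post"].set_index("patient_id")
        return [
            (pre.loc[p, "sample_id"], post.loc[p, "sample_id"])
            for p in sorted(pre.index)
        ]

    def profiles_for(self, timepoint: str) -> list[SegmentProfile]:
        ids = self.meta.loc[self.meta["timepoint"] == timepoint, "sample_id"]
        return [self.profiles[s] for s in ids]

    def calls_for(self, timepoint: str) -> list[MutationCall]:
        ids = set(self.meta.loc[self.meta["timepoint"] == timepoint, "sample_id"])
        return [c for c in self.mutations if c.sample_id in ids]

    def svs_for(self, timepoint: str) -> list[SvCall]:
        ids = set(self.meta.loc[self.meta["timepoint"] == timepoint, "sample_id"])
        return [s for s in self.svs if s.sample_id in ids]


def _component_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_COMPONENTS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_COMPONENTS, children)}


def nb_counts(rng: np.random.Generator, mean, dispersion) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draws with mean ``mean`` and
    variance ``mean + dispersion * mean^2``."""
    mean = np.asarray(mean, dtype=float)
    disp = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    lam = np.where(
        disp > 1e-10,
        rng.gamma(np.maximum(1.0 / np.maximum(disp, 1e-10), 1e-12), 1.0) *
        np.maximum(disp, 1e-10) * mean,
        mean,
    )
    return rng.poisson(lam)


def _simulate_meta(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    lo, hi = config.purity_range
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        for tp in ("pre", "post"):
            rows.append(
                {
                    "sample_id": f"{pid}-{tp}",
                    "patient_id": pid,
                    "timepoint": tp,
                    "purity": float(np.round(rng.uniform(lo, hi), 4)),
                    "batch": config.batches[int(rng.integers(len(config.batches)))],
                    "arsi_exposed": 0 if tp == "pre" else 1,
                }
            )
    return pd.DataFrame(rows)


def _random_segments(
    rng: np.random.Generator, L: int, mean_len: int, cn_sd: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_break = rng.poisson(max(L / mean_len - 1, 0))
    breaks = np.sort(rng.integers(1, L, size=n_break)) if n_break else np.empty(0, int)
    bounds = np.concatenate([[0], np.unique(breaks), [L]]).astype(np.int64)
    starts, ends = bounds[:-1], bounds[1:]
    cn = np.maximum(2.0 + rng.normal(0.0, cn_sd, size=starts.size), 0.05)
    return starts, ends, cn


def _add_copies(
    segs: tuple[np.ndarray, np.ndarray, np.ndarray], region: Region, extra: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split segments at the region bounds and add ``extra`` copies inside."""
    starts, ends, cn = segs
    new_s, new_e, new_c = [], [], []
    for s, e, c in zip(starts, ends, cn):
        pieces = sorted({s, e, min(max(region.start, s), e), min(max(region.end, s), e)})
        for a, b in zip(pieces[:-1], pieces[1:]):
            inside = a >= region.start and b <= region.end
            new_s.append(a)
            new_e.append(b)
            new_c.append(c + extra if inside else c)
    return (np.asarray(new_s, dtype=np.int64), np.asarray(new_e, dtype=np.int64),
            np.asarray(new_c))


def _simulate_segments(
    config: CohortConfig, meta: pd.DataFrame, rng: np.random.Generator
) -> tuple[dict[str, SegmentProfile], list[SvCall]]:
    spike = config.spike
    profiles: dict[str, SegmentProfile] = {}
    svs: list[SvCall] = []
    patients = sorted(meta["patient_id"].unique())
    spiked_pairs = {
        p: bool(rng.random() < spike.fraction_of_pairs) for p in patients
    }

    def td_call(sample_id: str, region: Region) -> SvCall:
        pad1 = int(rng.integers(1_000, 20_000))
        pad2 = int(rng.integers(1_000, 20_000))
        L = config.genome.length_of(region.chrom)
        s = max(0, region.start - pad1)
        e = min(L, region.end + pad2)
        return SvCall(
            sample_id,
            Region(region.chrom, s, s + 1),
            Region(region.chrom, e - 1, e),
            "DUP",
        )

    for _, row in meta.iterrows():
        sid, tp, pid = row["sample_id"], row["timepoint"], row["patient_id"]
        segs = {}
        for chrom in config.genome.chrom_names:
            segs[chrom] = _random_segments(
                rng, config.genome.length_of(chrom),
                config.segment_mean_length, config.segment_cn_sd,
            )
        has_baseline = rng.random() < spike.baseline_fraction
        if has_baseline and spike.baseline_extra > 0:
            segs[spike.region.chrom] = _add_copies(
                segs[spike.region.chrom], spike.region, spike.baseline_extra
            )
            if rng.random() < spike.baseline_td_fraction:
                svs.append(td_call(sid, spike.region))
        if tp == "post" and spiked_pairs[pid] and spike.extra_copies > 0:
            segs[spike.region.chrom] = _add_copies(
                segs[spike.region.chrom], spike.region, spike.extra_copies
            )
            if spike.mechanism == "td":
                svs.append(td_call(sid, spike.region))
        # background SVs (mixture of DUP/DEL elsewhere)
        for _ in range(rng.poisson(config.n_background_svs)):
            chrom = config.genome.chrom_names[
                int(rng.integers(len(config.genome.chrom_names)))
            ]
            L = config.genome.length_of(chrom)
            s = int(rng.integers(0, L - 100_000))
            w = int(rng.integers(10_000, 100_000))
            svtype = "DUP" if rng.random() < 0.5 else "DEL"
            svs.append(
                SvCall(sid, Region(chrom, s, s + 1),
                       Region(chrom, s + w - 1, s + w), svtype)
            )
        profiles[sid] = SegmentProfile(
            sid, segs, purity=row["purity"], ploidy=2.0
        )
    return profiles, svs


def _vaf_draw(rng, purity: float, depth: int, clonal_fraction: float = 1.0,
              local_copy: float = 2.0) -> float:
    """Purity/copy mixing: one mutated copy among local_copy tumor copies,
    diluted by 2 normal copies per non-tumor cell."""
    p_true = clonal_fraction * purity / (local_copy * purity + 2.0 * (1.0 - purity))
    p_true = min(max(p_true, 0.0), 1.0)
    return float(rng.binomial(depth, p_true)) / depth


def _simulate_mutations(
    config: CohortConfig, meta: pd.DataFrame, rng: np.random.Generator
) -> list[MutationCall]:
    spec = config.mutations
    classes = list(spec.class_probs)
    probs = np.asarray([spec.class_probs[c] for c in classes])
    probs = probs / probs.sum()
    gene_pool = _gene_names(config.expression.n_genes)
    calls: list[MutationCall] = []
    chrom_names = config.genome.chrom_names

    def random_call(sample_id: str, purity: float) -> MutationCall:
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        pos = int(rng.integers(0, config.genome.length_of(chrom) - 1))
        impact = classes[int(rng.choice(len(classes), p=probs))]
        ref, alt = "ACGT"[int(rng.integers(4))], "ACGT"[int(rng.integers(4))]
        if alt == ref:
            alt = "ACGT"[(("ACGT".index(ref)) + 1) % 4]
        gene = None
        pchange = None
        if impact != "noncoding":
            gene = gene_pool[int(rng.integers(len(gene_pool)))]
            pchange = f"A{int(rng.integers(1, 900))}V"
        vaf = _vaf_draw(rng, purity, spec.depth)
        return MutationCall(sample_id, Region(chrom, pos, pos + 1), ref, alt,
                            gene, impact, pchange, vaf)

    purity = meta.set_index("sample_id")["purity"]
    for pid, grp in meta.groupby("patient_id", sort=True):
        pre_id = grp.loc[grp["timepoint"] == "pre", "sample_id"].iloc[0]
        post_id = grp.loc[grp["timepoint"] == "post", "sample_id"].iloc[0]
        # truncal mutations shared by both timepoints (same site, own VAF draw)
        for _ in range(spec.n_trunk):
            proto = random_call(pre_id, purity[pre_id])
            calls.append(proto)
            calls.append(
                MutationCall(post_id, proto.region, proto.ref, proto.alt,
                             proto.gene, proto.impact, proto.protein_change,
                             _vaf_draw(rng, purity[post_id], spec.depth))
            )
        for sid in (pre_id, post_id):
            for _ in range(rng.poisson(spec.n_private)):
                calls.append(random_call(sid, purity[sid]))
        for hs in config.hotspots:
            if rng.random() < hs.emergence_prob:
                pos = config.gene_region.start + hs.offset
                calls.append(
                    MutationCall(
                        post_id,
                        Region(config.gene_region.chrom, pos, pos + 1),
                        "T", "C", hs.gene, hs.impact, hs.protein_change,
                        _vaf_draw(rng, purity[post_id], spec.depth,
                                  hs.clonal_fraction),
                    )
                )
    return calls


def _gene_names(n_genes: int) -> list[str]:
    specials = ["AR", "SSTR1", "TRPM8", "LMO3", "SFRP5", "FOXA1", "HOXB13"]
    return specials[:n_genes] + [
        f"G{i:04d}" for i in range(n_genes - min(len(specials), n_genes))
    ]


def _simulate_expression(
    config: CohortConfig,
    meta: pd.DataFrame,
    profiles: dict[str, SegmentProfile] | None,
    rng: np.random.Generator,
) -> pd.DataFrame:
    spec = config.expression
    genes = _gene_names(spec.n_genes)
    n_genes = len(genes)
    samples = meta["sample_id"].tolist()
    n_samples = len(samples)
    patients = sorted(meta["patient_id"].unique())

    tumor_mean = np.maximum(2.0 ** rng.normal(spec.mean_log2_mu, spec.mean_log2_sd,
                                              n_genes), 1.0)
    stromal_mean = tumor_mean[rng.permutation(n_genes)]
    dispersion = np.exp(rng.normal(spec.dispersion_log_mean, spec.dispersion_log_sd,
                                   n_genes))
    patient_eff = rng.normal(0.0, spec.patient_sd, size=(n_genes, len(patients)))
    batch_eff = rng.normal(0.0, spec.batch_sd, size=(n_genes, len(config.batches)))
    library = np.exp(rng.normal(0.0, spec.library_sd, n_samples))

    lfc = np.zeros(n_genes)
    for gname, value in spec.lfc.items():
        if gname in genes:
            gi = genes.index(gname)
            lfc[gi] = value
            tumor_mean[gi] = 2.0**spec.responsive_log2_mean
            dispersion[gi] = spec.responsive_dispersion
            stromal_mean[gi] = spec.tumor_restricted_stromal_fraction * tumor_mean[gi]
    for gname in spec.dosage_genes:
        # dosage-driven genes are the tumor's dominant drivers: well
        # expressed in cancer cells and near-absent in the stroma
        if gname in genes:
            gi = genes.index(gname)
            tumor_mean[gi] = 2.0**spec.responsive_log2_mean
            dispersion[gi] = spec.responsive_dispersion
            stromal_mean[gi] = spec.tumor_restricted_stromal_fraction * tumor_mean[gi]

    pat_index = {p: k for k, p in enumerate(patients)}
    batch_index = {b: k for k, b in enumerate(config.batches)}
    mu = np.empty((n_genes, n_samples))
    for j, (_, row) in enumerate(meta.iterrows()):
        p = row["purity"]
        is_post = 1.0 if row["timepoint"] == "post" else 0.0
        tumor = tumor_mean * 2.0 ** (lfc * is_post)
        if profiles is not None:
            for gname in spec.dosage_genes:
                if gname in genes:
                    gi = genes.index(gname)
                    copy = region_mean_copy(profiles[row["sample_id"]],
                                            config.gene_region)
                    tumor = tumor.copy()
                    tumor[gi] *= copy / 2.0
        mix = p * tumor + (1.0 - p) * stromal_mean
        mu[:, j] = (
            library[j]
            * mix
            * 2.0 ** (patient_eff[:, pat_index[row["patient_id"]]]
                      + batch_eff[:, batch_index[row["batch"]]])
        )
    counts = nb_counts(rng, mu, dispersion[:, None])
    return pd.DataFrame(counts, index=genes, columns=samples)


def _simulate_isoforms(
    config: CohortConfig, meta: pd.DataFrame, counts: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    spec = config.isoforms
    if spec.gene not in counts.index:
        return pd.DataFrame(columns=["transcript_id", "gene"])
    patients = sorted(meta["patient_id"].unique())
    converter = (
        patients[spec.converter_patient]
        if spec.converter_patient is not None and spec.converter_patient < len(patients)
        else None
    )
    totals = counts.loc[spec.gene]
    rows = {t: [] for t in spec.transcripts}
    for _, row in meta.iterrows():
        is_post = row["timepoint"] == "post"
        if row["patient_id"] == converter:
            base = spec.converter_post if is_post else spec.converter_pre
        else:
            base = spec.post_fractions if is_post else spec.pre_fractions
        w = rng.dirichlet(np.asarray(base) * spec.concentration)
        total = float(totals[row["sample_id"]])
        for t, frac in zip(spec.transcripts, w):
            rows[t].append(total * frac)
    out = pd.DataFrame(rows, index=meta["sample_id"]).T
    out.insert(0, "gene", spec.gene)
    out.insert(0, "transcript_id", out.index)
    return out.reset_index(drop=True)


def _random_interval(rng, genome: GenomeDef, width_range) -> Region:
    chrom = genome.chrom_names[int(rng.integers(len(genome.chrom_names)))]
    w = int(rng.integers(width_range[0], width_range[1]))
    s = int(rng.integers(0, genome.length_of(chrom) - w))
    return Region(chrom, s, s + w)


def _simulate_tracks(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[GenomicTrack, dict[str, GenomicTrack], list[tuple[Region, Region]]]:
    spec = config.tracks
    # recurrently hypomethylated regions
    regions = [spec.planted]
    scores = [spec.rhmr_recurrence]
    for _ in range(spec.n_background):
        regions.append(_random_interval(rng, config.genome, spec.background_width))
        scores.append(1.0 + rng.poisson(spec.background_recurrence_mean))
    rhmr = GenomicTrack(regions, np.asarray(scores), name="rHMR")

    peaks: dict[str, GenomicTrack] = {}
    for name in spec.peak_names:
        p_regions = [config.promoter_region, config.enhancer_region]
        p_scores = [10.0, 10.0]
        if name in spec.planted_peaks:
            p_regions.append(spec.planted)
            p_scores.append(8.0)
        for _ in range(spec.n_background):
            p_regions.append(_random_interval(rng, config.genome,
                                              (500, 2_500)))
            p_scores.append(float(1 + rng.poisson(3)))
        peaks[name] = GenomicTrack(p_regions, np.asarray(p_scores), name=name)

    loops: list[tuple[Region, Region]] = [(spec.planted, config.promoter_region)]
    for _ in range(spec.n_background_loops):
        a = _random_interval(rng, config.genome, (2_000, 8_000))
        b_off = int(rng.integers(50_000, 500_000))
        L = config.genome.length_of(a.chrom)
        s = min(a.end + b_off, L - 5_000)
        loops.append((a, Region(a.chrom, s, s + 5_000)))
    return rhmr, peaks, loops


def _simulate_survival(
    config: CohortConfig, meta: pd.DataFrame, counts: pd.DataFrame | None,
    rng: np.random.Generator,
) -> pd.DataFrame:
    spec = config.survival
    post = meta[meta["timepoint"] == "post"]
    target = "SSTR1"
    if counts is not None and target in counts.index:
        expr = counts.loc[target, post["sample_id"]].astype(float)
        low = (expr <= expr.median()).to_numpy()
    else:
        low = rng.random(len(post)) < 0.5
    rows = []
    for (_, row), is_low in zip(post.iterrows(), low):
        treated = rng.random() < 0.5
        log_hr = (
            spec.treatment_log_hr * treated
            + spec.group_low_log_hr * is_low
            + spec.interaction_log_hr * treated * is_low
        )
        hazard = spec.baseline_hazard * np.exp(log_hr)
        t = rng.exponential(1.0 / hazard)
        censor = rng.uniform(*spec.censor_range)
        rows.append(
            {
                "sample_id": row["sample_id"],
                "time_months": float(np.round(min(t, censor), 4)),
                "event": int(t <= censor),
                "treatment_after_biopsy": "ARSI" if treated else "other",
            }
        )
    return pd.DataFrame(rows)


def simulate_cohort(
    config: CohortConfig,
    seed: int | None = None,
    components: tuple[str, ...] = _COMPONENTS,
) -> PairedCohort:
    """Generate a paired cohort; deterministic given the seed.

    ``components`` restricts generation (e.g. ``("meta", "segments")`` for
    copy-number-only studies); each component draws from its own seed
    sub-stream, so restricted runs reproduce the full run's values.
    """
    seed = config.seed if seed is None else seed
    rngs = _component_rngs(seed)
    meta = _simulate_meta(config, rngs["meta"])

    profiles: dict[str, SegmentProfile] = {}
    svs: list[SvCall] = []
    if "segments" in components:
        profiles, svs = _simulate_segments(config, meta, rngs["segments"])
    mutations: list[MutationCall] = []
    if "mutations" in components:
        mutations = _simulate_mutations(config, meta, rngs["mutations"])
    counts = pd.DataFrame()
    if "expression" in components:
        counts = _simulate_expression(
            config, meta, profiles if profiles else None, rngs["expression"]
        )
    transcript_table = pd.DataFrame(columns=["transcript_id", "gene"])
    if "isoforms" in components and not counts.empty:
        transcript_table = _simulate_isoforms(config, meta, counts, rngs["isoforms"])
    rhmr, peaks, loops = None, {}, []
    if "tracks" in components:
        rhmr, peaks, loops = _simulate_tracks(config, rngs["tracks"])
    survival = pd.DataFrame(columns=["sample_id", "time_months", "event",
                                     "treatment_after_biopsy"])
    if "survival" in components:
        survival = _simulate_survival(
            config, meta, counts if not counts.empty else None, rngs["survival"]
        )
    return PairedCohort(
        config, meta, profiles, mutations, svs, counts, transcript_table,
        rhmr, peaks, loops, survival,
    )


def write_fixture(cohort: PairedCohort, directory) -> list[Path]:
    """Write every cohort component in its external format.

    Re-reading the files reproduces the cohort's data model; repeated runs
    at a fixed seed are byte-identical.
    """
    from . import io as pio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def record(path: Path) -> Path:
        written.append(path)
        return path

    pio.write_genome(cohort.config.genome, record(directory / "genome.tsv"))
    pio.write_samples(cohort.meta, record(directory / "samples.tsv"))
    if cohort.profiles:
        ordered = [cohort.profiles[s] for s in cohort.meta["sample_id"]]
        pio.write_seg(ordered, record(directory / "segments.seg.tsv"))
    vcf_dir = directory / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    by_sample: dict[str, list[MutationCall]] = {
        s: [] for s in cohort.meta["sample_id"]
    }
    for c in cohort.mutations:
        by_sample[c.sample_id].append(c)
    if cohort.mutations:
        for sid in cohort.meta["sample_id"]:
            pio.write_vcf(by_sample[sid], record(vcf_dir / f"{sid}.vcf"))
    pio.write_sv_bedpe(cohort.svs, record(directory / "svs.bedpe"))
    if not cohort.counts.empty:
        pio.write_matrix(cohort.counts, record(directory / "expression.tsv"))
    if len(cohort.transcript_table):
        cohort.transcript_table.to_csv(
            record(directory / "transcripts.tsv"), sep="\t", index=False,
            float_format="%.6g",
        )
    if cohort.rhmr is not None:
        tracks_dir = directory / "tracks"
        tracks_dir.mkdir(exist_ok=True)
        pio.write_bed_track(cohort.rhmr, record(tracks_dir / "rhmr.bed"))
        for name, track in cohort.peaks.items():
            pio.write_bed_track(track, record(tracks_dir / f"peak_{name}.bed"))
        pio.write_loops_bedpe(cohort.loops, record(directory / "loops.bedpe"))
    if len(cohort.survival):
        pio.write_survival(cohort.survival, record(directory / "survival.tsv"))
    return written
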