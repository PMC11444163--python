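"""Readers and writers for the external formats the pipeline touches.

Conventions: BED/BEDPE/SEG are 0-based half-open (matching the internal
model); VCF positions are 1-based and converted at this boundary. Malformed
lines raise :class:`ParseError` naming the file and line number. Every
``write_* -> read_*`` round trip is the identity on the data model.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .ampclass import SvCall
from .cnscan import SegmentProfile
from .genome import GenomeDef, GenomicTrack, Region
from .mutscan import MutationCall
from .scores import GeneSet

__all__ = [
    "ParseError",
    "read_genome",
    "write_genome",
    "read_seg",
    "write_seg",
    "read_vcf",
    "write_vcf",
    "read_sv_bedpe",
    "write_sv_bedpe",
    "read_loops_bedpe",
    "write_loops_bedpe",
    "read_bed_track",
    "write_bed_track",
    "read_gmt",
    "write_gmt",
    "read_samples",
    "write_samples",
    "read_survival",
    "write_survival",
]


class ParseError(ValueError):
    """A malformed input line, with file and line number."""

    def __init__(self, path, line_no: int, message: str) -> None:
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


def _check_coords(path, line_no, chrom, start, end, genome: GenomeDef | None) -> None:
    if start < 0 or end <= start:
        raise ParseError(path, line_no, f"coordinate inversion: {chrom}:{start}-{end}")
    if genome is not None:
        if chrom not in genome:
            raise ParseError(path, line_no, f"unknown chromosome {chrom!r}")
        if end > genome.length_of(chrom):
            raise ParseError(
                path, line_no, f"{chrom}:{start}-{end} exceeds chromosome length"
            )


# --- genome -----------------------------------------------------------------

def read_genome(path) -> GenomeDef:
    """Chromosome-length TSV (chrom, length)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ParseError(path, i, "expected 2 columns (chrom, length)")
            try:
                lengths[fields[0]] = int(fields[1])
            except ValueError:
                raise ParseError(path, i, f"bad length {fields[1]!r}") from None
    return GenomeDef.from_lengths(lengths)


def write_genome(genome: GenomeDef, path) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            fh.write(f"{chrom}\t{genome.length_of(chrom)}\n")


# --- SEG-like copy-number segments -----------------------------------------

SEG_COLUMNS = ["sample", "chrom", "start", "end", "copy_number"]


def read_seg(path, genome: GenomeDef | None = None) -> dict[str, SegmentProfile]:
    """SEG-like TSV (sample, chrom, start, end, copy_number), 0-based half-open."""
    rows = []
    with open(path) as fh:
        header = None
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if header is None:
                header = fields
                if header != SEG_COLUMNS:
                    raise ParseError(path, i, f"expected columns {SEG_COLUMNS}")
                continue
            if len(fields) != 5:
                raise ParseError(path, i, f"expected 5 columns, got {len(fields)}")
            try:
                start, end = int(fields[2]), int(fields[3])
                cn = float(fields[4])
            except ValueError:
                raise ParseError(path, i, "non-numeric coordinate or copy number") from None
            _check_coords(path, i, fields[1], start, end, genome)
            if not np.isfinite(cn) or cn < 0:
                raise ParseError(path, i, f"invalid copy number {fields[4]!r}")
            rows.append((fields[0], fields[1], start, end, cn))
    df = pd.DataFrame(rows, columns=SEG_COLUMNS)
    return {
        sid: SegmentProfile.from_frame(df, sid)
        for sid in df["sample"].unique()
    }


def write_seg(profiles: list[SegmentProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SEG_COLUMNS) + "\n")
        for prof in profiles:
            for chrom, (s, e, cn) in prof.segments.items():
                for a, b, c in zip(s, e, cn):
                    fh.write(f"{prof.sample_id}\t{chrom}\t{a}\t{b}\t{c:.6g}\n")


# --- minimal VCF ------------------------------------------------------------

_VCF_HEADER = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=IMPACT,Number=1,Type=String,Description="Impact class">',
    '##INFO=<ID=PHGVS,Number=1,Type=String,Description="Protein change">',
    '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">',
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
]


def read_vcf(path, sample_id: str | None = None,
             genome: GenomeDef | None = None) -> list[MutationCall]:
    """Minimal somatic VCF: CHROM POS ID REF ALT QUAL FILTER INFO with INFO
    keys GENE, IMPACT, PHGVS, VAF. POS is 1-based; the internal start is
    POS - 1. The sample defaults to the file stem."""
    if sample_id is None:
        sample_id = Path(path).stem.removesuffix(".vcf")
    calls: list[MutationCall] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ParseError(path, i, f"expected 8 columns, got {len(fields)}")
            chrom, pos_s, _, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            try:
                pos = int(pos_s)
            except ValueError:
                raise ParseError(path, i, f"bad POS {pos_s!r}") from None
            if pos < 1:
                raise ParseError(path, i, f"POS must be >= 1, got {pos}")
            start = pos - 1
            end = start + max(len(ref), 1)
            _check_coords(path, i, chrom, start, end, genome)
            info = {}
            for item in fields[7].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    info[k] = v
            if "IMPACT" not in info:
                raise ParseError(path, i, "missing mandatory INFO key IMPACT")
            gene = info.get("GENE") or None
            gene = None if gene == "." else gene
            pchange = info.get("PHGVS") or None
            pchange = None if pchange == "." else pchange
            try:
                vaf = float(info["VAF"]) if "VAF" in info else np.nan
            except ValueError:
                raise ParseError(path, i, f"bad VAF {info['VAF']!r}") from None
            try:
                calls.append(
                    MutationCall(
                        sample_id, Region(chrom, start, end), ref, alt,
                        gene, info["IMPACT"], pchange, vaf
                    )
                )
            except ValueError as exc:
                raise ParseError(path, i, str(exc)) from None
    return calls


def write_vcf(calls: list[MutationCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(_VCF_HEADER) + "\n")
        for c in sorted(calls, key=lambda c: (c.region.chrom, c.region.start)):
            info = (
                f"GENE={c.gene or '.'};IMPACT={c.impact};"
                f"PHGVS={c.protein_change or '.'}"
            )
            if np.isfinite(c.vaf):
                info += f";VAF={c.vaf:.6g}"
            fh.write(
                f"{c.region.chrom}\t{c.region.start + 1}\t.\t{c.ref}\t{c.alt}"
                f"\t.\tPASS\t{info}\n"
            )


# --- BEDPE (structural variants and loops) ----------------------------------

_BEDPE_SV_COLS = 11  # chrom1 start1 end1 chrom2 start2 end2 name score strand1 strand2 svtype


def _parse_bedpe_line(path, i, line, n_min, genome):
    fields = line.rstrip("\n").split("\t")
    if len(fields) < n_min:
        raise ParseError(path, i, f"expected >= {n_min} columns, got {len(fields)}")
    try:
        s1, e1 = int(fields[1]), int(fields[2])
        s2, e2 = int(fields[4]), int(fields[5])
    except ValueError:
        raise ParseError(path, i, "non-integer coordinate") from None
    _check_coords(path, i, fields[0], s1, e1, genome)
    _check_coords(path, i, fields[3], s2, e2, genome)
    return fields, Region(fields[0], s1, e1), Region(fields[3], s2, e2)


def read_sv_bedpe(path, genome: GenomeDef | None = None) -> list[SvCall]:
    """Structural-variant BEDPE; the name column carries the sample id and
    column 11 the SV type."""
    svs: list[SvCall] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            fields, r1, r2 = _parse_bedpe_line(path, i, line, _BEDPE_SV_COLS, genome)
            try:
                svs.append(SvCall(fields[6], r1, r2, fields[10]))
            except ValueError as exc:
                raise ParseError(path, i, str(exc)) from None
    return svs


def write_sv_bedpe(svs: list[SvCall], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore"
            "\tstrand1\tstrand2\tsvtype\n"
        )
        for sv in svs:
            b1, b2 = sv.breakend1, sv.breakend2
            fh.write(
                f"{b1.chrom}\t{b1.start}\t{b1.end}\t{b2.chrom}\t{b2.start}\t{b2.end}"
                f"\t{sv.sample_id}\t.\t.\t.\t{sv.svtype}\n"
            )


def read_loops_bedpe(path, genome: GenomeDef | None = None) -> list[tuple[Region, Region]]:
    """Chromatin-loop BEDPE (two anchors; extra columns ignored)."""
    loops = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            _, r1, r2 = _parse_bedpe_line(path, i, line, 6, genome)
            loops.append((r1, r2))
    return loops


def write_loops_bedpe(loops: list[tuple[Region, Region]], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\n")
        for a, b in loops:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\n")


# --- BED4 scored tracks ------------------------------------------------------

def read_bed_track(path, name: str = "", genome: GenomeDef | None = None) -> GenomicTrack:
    """BED4 (chrom, start, end, score), 0-based half-open. A BED3 line gets
    score 1."""
    regions, scores = [], []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith(("#", "track")) or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(path, i, "expected >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
                score = float(fields[3]) if len(fields) > 3 else 1.0
            except ValueError:
                raise ParseError(path, i, "bad coordinate or score") from None
            _check_coords(path, i, fields[0], start, end, genome)
            regions.append(Region(fields[0], start, end))
            scores.append(score)
    return GenomicTrack(regions, np.asarray(scores), name=name or Path(path).stem)


def write_bed_track(track: GenomicTrack, path) -> None:
    with open(path, "w") as fh:
        for region, score in zip(track.regions, track.scores):
            fh.write(f"{region.chrom}\t{region.start}\t{region.end}\t{score:.6g}\n")


# --- GMT gene sets -----------------------------------------------------------

def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(path, i, "GMT needs name, description, >= 1 gene")
            try:
                sets.append(GeneSet(fields[0], tuple(fields[2:])))
            except ValueError as exc:
                raise ParseError(path, i, str(exc)) from None
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "."] + list(gs.genes)) + "\n")


# --- sample sheet and survival table ----------------------------------------

SAMPLE_COLUMNS = ["sample_id", "patient_id", "timepoint", "purity", "batch", "arsi_exposed"]
SURVIVAL_COLUMNS = ["sample_id", "time_months", "event", "treatment_after_biopsy"]


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str,
                                                         "patient_id": str,
                                                         "batch": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(path, 1, f"missing mandatory column(s) {missing}")
    bad = ~df["timepoint"].isin(["pre", "post"])
    if bad.any():
        raise ParseError(path, int(np.flatnonzero(bad)[0]) + 2,
                         "timepoint must be 'pre' or 'post'")
    if ((df["purity"] < 0) | (df["purity"] > 1)).any():
        raise ParseError(path, 1, "purity out of [0, 1]")
    return df


def write_samples(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=SAMPLE_COLUMNS)


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(path, 1, f"missing mandatory column(s) {missing}")
    if (df["time_months"] <= 0).any():
        raise ParseError(path, 1, "non-positive survival time")
    if not set(df["event"].unique()) <= {0, 1}:
        raise ParseError(path, 1, "event must be 0/1")
    return df


def write_survival(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=SURVIVAL_COLUMNS)


# --- expression matrices -----------------------------------------------------

def read_matrix(path, index_col: str = "gene") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if index_col not in df.columns:
        raise ParseError(path, 1, f"missing index column {index_col!r}")
    return df.set_index(index_col)


def write_matrix(df: pd.DataFrame, path, index_label: str = "gene",
                 float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=float_format)
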