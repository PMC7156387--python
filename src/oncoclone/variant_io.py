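"""Readers/writers for the tabular formats the pipeline consumes.

Internal coordinates are 1-based inclusive (VCF convention). Segment files
are BED-like on disk (0-based half-open) and converted on read. The TSV
dialect is UTF-8, tab-separated, with a single '#'-prefixed header line.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

TUMOUR_CLASSES = ("primary", "contralateral_ovary", "distant_metastasis")
CONSEQUENCES = ("synonymous", "missense", "nonsense", "splice", "indel", "other")
HAPLOTYPES = ("A", "B", "unknown")

VARIANT_COLUMNS = (
    "variant_id", "chrom", "pos", "ref", "alt", "gene", "consequence",
    "context96", "driver", "region_id", "depth", "alt_count",
)
REGION_COLUMNS = ("region_id", "patient_id", "tumour_class", "site", "purity")
SEGMENT_COLUMNS = ("region_id", "chrom", "start", "end", "major_cn", "minor_cn", "haplotype")


@dataclass(frozen=True)
class Region:
    """One sequenced tumour region (multi-region sampling unit)."""

    region_id: str
    patient_id: str
    tumour_class: str
    site: str = ""
    purity: float = 1.0

    def __post_init__(self) -> None:
        if self.tumour_class not in TUMOUR_CLASSES:
            raise ValueError(f"unknown tumour class {self.tumour_class!r}")
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity must be in (0,1], got {self.purity}")

    def is_metastasis(self, contralateral_as_met: bool = True) -> bool:
        if self.tumour_class == "distant_metastasis":
            return True
        return self.tumour_class == "contralateral_ovary" and contralateral_as_met


@dataclass(frozen=True)
class VariantCall:
    """One somatic SNV or indel (site-level record, region-independent)."""

    variant_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = ""
    consequence: str = "other"
    context96: str = ""  # channel name, SNVs only
    driver: bool = False

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.variant_id}: ref == alt")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"{self.variant_id}: unknown consequence {self.consequence!r}")
        if self.context96 and not self.is_snv:
            raise ValueError(
                f"{self.variant_id}: context96 is only defined for SNVs"
            )

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class RegionObservation:
    """Read support for one variant in one region."""

    variant_id: str
    region_id: str
    depth: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.depth < 0 or self.alt_count < 0:
            raise ValueError(f"{self.variant_id}/{self.region_id}: negative counts")
        if self.alt_count > self.depth:
            raise ValueError(
                f"{self.variant_id}/{self.region_id}: alt_count {self.alt_count} "
                f"> depth {self.depth}"
            )

    @property
    def vaf(self) -> float:
        if self.depth == 0:
            return float("nan")
        return self.alt_count / self.depth


@dataclass(frozen=True)
class SegmentCN:
    """Allele-specific copy-number segment, 1-based inclusive coordinates."""

    region_id: str
    chrom: str
    start: int
    end: int
    major_cn: int
    minor_cn: int
    major_haplotype: str = "unknown"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.major_cn < self.minor_cn:
            raise ValueError(
                f"major_cn {self.major_cn} < minor_cn {self.minor_cn} "
                f"({self.region_id} {self.chrom}:{self.start}-{self.end})"
            )
        if self.major_cn < 0 or self.minor_cn < 0:
            raise ValueError("negative copy number")
        if self.major_haplotype not in HAPLOTYPES:
            raise ValueError(f"unknown haplotype {self.major_haplotype!r}")

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn

    def covers(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


# ---------------------------------------------------------------------------
# TSV readers/writers


def _read_tsv(path: str | Path, columns: Sequence[str]) -> Iterable[tuple[int, dict]]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = None
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if header is None:
                if not row[0].startswith("#"):
                    raise ValueError(f"{path}:{lineno}: missing '#'-prefixed header")
                header = [row[0].lstrip("#")] + row[1:]
                missing = set(columns) - set(header)
                if missing:
                    raise ValueError(f"{path}:{lineno}: missing columns {sorted(missing)}")
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            yield lineno, dict(zip(header, row))


def _write_tsv(path: str | Path, columns: Sequence[str], rows: Iterable[Sequence]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["#" + columns[0]] + list(columns[1:]))
        for row in rows:
            writer.writerow(row)


def read_regions(path: str | Path) -> list[Region]:
    regions = []
    for lineno, rec in _read_tsv(path, REGION_COLUMNS):
        try:
            regions.append(
                Region(
                    region_id=rec["region_id"],
                    patient_id=rec["patient_id"],
                    tumour_class=rec["tumour_class"],
                    site=rec["site"],
                    purity=float(rec["purity"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    seen: dict[tuple[str, str], int] = {}
    for r in regions:
        key = (r.patient_id, r.region_id)
        if key in seen:
            raise ValueError(f"{path}: duplicate region {r.region_id} for {r.patient_id}")
        seen[key] = 1
    return regions


def write_regions(regions: Sequence[Region], path: str | Path) -> None:
    _write_tsv(
        path,
        REGION_COLUMNS,
        ((r.region_id, r.patient_id, r.tumour_class, r.site, repr(r.purity)) for r in regions),
    )


def read_variant_table(
    path: str | Path,
    format: str = "tsv",
    regions: Sequence[Region] | None = None,
) -> tuple[list[VariantCall], list[RegionObservation]]:
    """Read a variant table into site-level calls plus per-region observations.

    ``format`` is ``"tsv"`` (long-format dialect written by this package) or
    ``"vcf"`` (multi-sample VCF v4.2 with per-sample AD/DP; sample names are
    region ids; multi-allelic records are split). If ``regions`` is given,
    observations for unknown region ids are rejected.
    """
    if format == "tsv":
        return _read_variants_tsv(path, regions)
    if format == "vcf":
        return _read_variants_vcf(path, regions)
    raise ValueError(f"unknown format {format!r}")


def _known_region_ids(regions: Sequence[Region] | None) -> set[str] | None:
    return None if regions is None else {r.region_id for r in regions}


def _read_variants_tsv(
    path: str | Path, regions: Sequence[Region] | None
) -> tuple[list[VariantCall], list[RegionObservation]]:
    known = _known_region_ids(regions)
    variants: dict[str, VariantCall] = {}
    observations: list[RegionObservation] = []
    for lineno, rec in _read_tsv(path, VARIANT_COLUMNS):
        try:
            call = VariantCall(
                variant_id=rec["variant_id"],
                chrom=rec["chrom"],
                pos=int(rec["pos"]),
                ref=rec["ref"],
                alt=rec["alt"],
                gene=rec["gene"],
                consequence=rec["consequence"],
                context96=rec["context96"],
                driver=rec["driver"].lower() in ("1", "true"),
            )
            obs = RegionObservation(
                variant_id=rec["variant_id"],
                region_id=rec["region_id"],
                depth=int(rec["depth"]),
                alt_count=int(rec["alt_count"]),
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        if known is not None and obs.region_id not in known:
            raise ValueError(f"{path}:{lineno}: unknown region {obs.region_id!r}")
        prev = variants.setdefault(call.variant_id, call)
        if prev != call:
            raise ValueError(
                f"{path}:{lineno}: inconsistent site fields for {call.variant_id}"
            )
        observations.append(obs)
    return list(variants.values()), observations


def write_variant_table(
    variants: Sequence[VariantCall],
    observations: Sequence[RegionObservation],
    path: str | Path,
) -> None:
    by_id = {v.variant_id: v for v in variants}
    rows = []
    for obs in observations:
        v = by_id[obs.variant_id]
        rows.append(
            (
                v.variant_id, v.chrom, v.pos, v.ref, v.alt, v.gene, v.consequence,
                v.context96, int(v.driver), obs.region_id, obs.depth, obs.alt_count,
            )
        )
    _write_tsv(path, VARIANT_COLUMNS, rows)


def _read_variants_vcf(
    path: str | Path, regions: Sequence[Region] | None
) -> tuple[list[VariantCall], list[RegionObservation]]:
    from cyvcf2 import VCF

    known = _known_region_ids(regions)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if known is not None:
        unknown = [s for s in samples if s not in known]
        if unknown:
            raise ValueError(f"{path}: unknown regions in VCF samples: {unknown}")
    variants: list[VariantCall] = []
    observations: list[RegionObservation] = []
    for rec in vcf:
        depths = rec.format("DP")[:, 0].astype(int)
        ad = rec.format("AD").astype(int)
        for alt_idx, alt in enumerate(rec.ALT):  # split multi-allelics
            vid = f"{rec.CHROM}_{rec.POS}_{rec.REF}_{alt}"
            ctx = rec.INFO.get("TRICTX") or ""
            is_snv = len(rec.REF) == 1 and len(alt) == 1
            variants.append(
                VariantCall(
                    variant_id=vid,
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    gene=rec.INFO.get("GENE") or "",
                    consequence=rec.INFO.get("CONSEQ") or ("other" if is_snv else "indel"),
                    context96=ctx if is_snv else "",
                    driver=bool(rec.INFO.get("DRIVER") or False),
                )
            )
            for sample, depth, counts in zip(samples, depths, ad):
                observations.append(
                    RegionObservation(
                        variant_id=vid,
                        region_id=sample,
                        depth=int(depth),
                        alt_count=int(counts[alt_idx + 1]),
                    )
                )
    return variants, observations


def write_vcf(
    variants: Sequence[VariantCall],
    observations: Sequence[RegionObservation],
    path: str | Path,
) -> None:
    """Write a minimal multi-sample VCF v4.2 (AD/DP per sample)."""
    region_ids = sorted({o.region_id for o in observations})
    obs_map = {(o.variant_id, o.region_id): o for o in observations}
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CONSEQ,Number=1,Type=String,Description="Consequence class">',
        '##INFO=<ID=TRICTX,Number=1,Type=String,Description="96-channel trinucleotide channel">',
        '##INFO=<ID=DRIVER,Number=0,Type=Flag,Description="Driver gene mutation">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ]
    chroms = []
    for v in variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    lines.extend(f"##contig=<ID={c}>" for c in chroms)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(region_ids)
    )
    for v in sorted(variants, key=lambda v: (chroms.index(v.chrom), v.pos)):
        info = []
        if v.gene:
            info.append(f"GENE={v.gene}")
        info.append(f"CONSEQ={v.consequence}")
        if v.context96:
            info.append(f"TRICTX={v.context96}")
        if v.driver:
            info.append("DRIVER")
        cols = [v.chrom, str(v.pos), v.variant_id, v.ref, v.alt, ".", "PASS",
                ";".join(info) or ".", "DP:AD"]
        for rid in region_ids:
            o = obs_map[(v.variant_id, rid)]
            cols.append(f"{o.depth}:{o.depth - o.alt_count},{o.alt_count}")
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_segments(path: str | Path) -> list[SegmentCN]:
    """Read BED-like allele-specific copy-number segments.

    On-disk coordinates are 0-based half-open; internal are 1-based
    inclusive. Overlapping segments within one region are rejected.
    """
    segments = []
    for lineno, rec in _read_tsv(path, SEGMENT_COLUMNS):
        try:
            bed_start, bed_end = int(rec["start"]), int(rec["end"])
            segments.append(
                SegmentCN(
                    region_id=rec["region_id"],
                    chrom=rec["chrom"],
                    start=bed_start + 1,
                    end=bed_end,
                    major_cn=int(rec["major_cn"]),
                    minor_cn=int(rec["minor_cn"]),
                    major_haplotype=rec["haplotype"],
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not segments:
        log.warning("%s: empty segment file", path)
        return []
    ordered = sorted(segments, key=lambda s: (s.region_id, s.chrom, s.start))
    for prev, cur in zip(ordered, ordered[1:]):
        if (prev.region_id, prev.chrom) == (cur.region_id, cur.chrom) and cur.start <= prev.end:
            raise ValueError(
                f"{path}: overlapping segments in {cur.region_id} {cur.chrom}: "
                f"{prev.start}-{prev.end} and {cur.start}-{cur.end}"
            )
    return segments


def write_segments(segments: Sequence[SegmentCN], path: str | Path) -> None:
    _write_tsv(
        path,
        SEGMENT_COLUMNS,
        (
            (s.region_id, s.chrom, s.start - 1, s.end, s.major_cn, s.minor_cn,
             s.major_haplotype)
            for s in segments
        ),
    )


def lookup_cn(
    segments: Sequence[SegmentCN], region_id: str, chrom: str, pos: int
) -> tuple[int, int, str]:
    """Copy-number state at a position: covering segment or diploid default.

    Positions not covered by any segment of the region fall back to the
    normal diploid state (major 1, minor 1, haplotype unknown) with a
    logged warning.
    """
    for seg in segments:
        if seg.region_id == region_id and seg.covers(chrom, pos):
            return seg.major_cn, seg.minor_cn, seg.major_haplotype
    log.warning("no segment covers %s %s:%d; assuming diploid", region_id, chrom, pos)
    return 1, 1, "unknown"
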