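"""Reading and writing the pipeline's file formats.

Three formats are handled:

* multi-sample VCF 4.x (via pysam), with per-sample ``AD``/``DP`` fields
  and QC annotations (CLPM, ASMD, MAPQ, BASEQ) in INFO;
* a wide TSV count matrix with one row per site and paired
  ``<sample>.alt`` / ``<sample>.depth`` columns;
* BED-like copy-number segment tables (ASCAT/Battenberg style).

Internally everything is 1-based inclusive; BED-dialect copy-number input
(0-based half-open) is converted on read.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .cohort import (
    QC_KEYS,
    CohortError,
    CohortTable,
    CopyNumberProfile,
    SampleMeta,
    VariantSite,
    empty_cohort,
    merge_sites,
)

TSV_FIXED_COLUMNS = ["chrom", "pos", "ref", "alt", "variant_class"]


class ParseError(CohortError):
    """Malformed input record, with file and line context."""


def _check_metadata(metadata: Sequence[SampleMeta]) -> list[SampleMeta]:
    metadata = list(metadata)
    ids = [m.sample_id for m in metadata]
    if len(set(ids)) != len(ids):
        raise CohortError("duplicate sample_id in metadata")
    return metadata


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------

def _vcf_header(table: CohortTable) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(s.chrom for s in table.sites):
        header.contigs.add(chrom)
    header.info.add("VC", 1, "String", "Variant class")
    for key in QC_KEYS:
        header.info.add(key, 1, "Float", f"{key} quality annotation")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    for sid in table.sample_ids:
        header.add_sample(sid)
    return header


def write_cohort_vcf(table: CohortTable, path: str | os.PathLike) -> None:
    table = table.sorted()
    header = _vcf_header(table)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, site in enumerate(table.sites):
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                alleles=(site.ref, site.alt),
            )
            rec.info["VC"] = site.variant_class
            for key in QC_KEYS:
                if key in site.qc:
                    rec.info[key] = float(site.qc[key])
            for j, sid in enumerate(table.sample_ids):
                a = int(table.alt[i, j])
                d = int(table.depth[i, j])
                rec.samples[sid]["AD"] = (d - a, a)
                rec.samples[sid]["DP"] = d
            out.write(rec)


def _read_one_vcf(path: str) -> tuple[list[VariantSite], list[str], np.ndarray, np.ndarray]:
    sites: list[VariantSite] = []
    alts: list[list[int]] = []
    deps: list[list[int]] = []
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"{path}: cannot open as VCF: {exc}") from exc
    with vf:
        sids = list(vf.header.samples)
        for n, rec in enumerate(vf, start=1):
            try:
                if rec.alts is None or len(rec.alts) != 1:
                    raise CohortError("expected exactly one ALT allele")
                qc = {k: float(rec.info[k]) for k in QC_KEYS if k in rec.info}
                vc = rec.info.get("VC", "")
                site = VariantSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    variant_class=str(vc) if vc else "",
                    qc=qc,
                )
                row_a, row_d = [], []
                for sid in sids:
                    fmt = rec.samples[sid]
                    dp = fmt.get("DP")
                    ad = fmt.get("AD")
                    if dp is None and ad is not None:
                        dp = sum(x for x in ad if x is not None)
                    a = 0
                    if ad is not None and len(ad) >= 2 and ad[1] is not None:
                        a = int(ad[1])
                    row_a.append(a)
                    row_d.append(int(dp) if dp is not None else 0)
            except (CohortError, TypeError, ValueError) as exc:
                raise ParseError(f"{path}: record {n}: {exc}") from exc
            sites.append(site)
            alts.append(row_a)
            deps.append(row_d)
    a = np.asarray(alts, dtype=np.int64).reshape(len(sites), len(sids))
    d = np.asarray(deps, dtype=np.int64).reshape(len(sites), len(sids))
    return sites, sids, a, d


# ----------------------------------------------------------------------
# TSV
# ----------------------------------------------------------------------

def write_cohort_tsv(table: CohortTable, path: str | os.PathLike) -> None:
    """Wide TSV: fixed site columns, QC columns, then <sid>.alt/<sid>.depth."""
    table = table.sorted()
    data: dict[str, list] = {
        "chrom": [s.chrom for s in table.sites],
        "pos": [s.pos for s in table.sites],
        "ref": [s.ref for s in table.sites],
        "alt": [s.alt for s in table.sites],
        "variant_class": [s.variant_class for s in table.sites],
    }
    for key in QC_KEYS:
        data[key] = [s.qc.get(key, np.nan) for s in table.sites]
    for j, sid in enumerate(table.sample_ids):
        data[f"{sid}.alt"] = table.alt[:, j]
        data[f"{sid}.depth"] = table.depth[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def _read_one_tsv(path: str) -> tuple[list[VariantSite], list[str], np.ndarray, np.ndarray]:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: cannot parse TSV: {exc}") from exc
    for col in ("chrom", "pos", "ref", "alt"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    sids = []
    for col in df.columns:
        if col.endswith(".alt"):
            sid = col[: -len(".alt")]
            if f"{sid}.depth" not in df.columns:
                raise ParseError(f"{path}: column {sid}.depth missing for {col}")
            sids.append(sid)
    sites = []
    for n, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            qc = {
                k: float(d[k])
                for k in QC_KEYS
                if k in d and pd.notna(d[k])
            }
            vc = d.get("variant_class", "")
            sites.append(
                VariantSite(
                    chrom=str(d["chrom"]),
                    pos=int(d["pos"]),
                    ref=str(d["ref"]),
                    alt=str(d["alt"]),
                    variant_class="" if pd.isna(vc) else str(vc),
                    qc=qc,
                )
            )
        except (CohortError, TypeError, ValueError) as exc:
            raise ParseError(f"{path}: line {n}: {exc}") from exc
    if sites:
        alt = df[[f"{s}.alt" for s in sids]].to_numpy(dtype=np.int64)
        dep = df[[f"{s}.depth" for s in sids]].to_numpy(dtype=np.int64)
    else:
        alt = np.zeros((0, len(sids)), dtype=np.int64)
        dep = np.zeros((0, len(sids)), dtype=np.int64)
    return sites, sids, alt, dep


# ----------------------------------------------------------------------
# Public cohort API
# ----------------------------------------------------------------------

def read_cohort(
    variant_paths: Sequence[str | os.PathLike],
    format: str,
    metadata: Sequence[SampleMeta],
) -> CohortTable:
    """Assemble a cohort table from one or more variant files.

    Sites are deduplicated on (chrom, pos, ref, alt) and returned in
    canonical sorted order; a sample with no record at a site gets
    alt=0 at depth=0 (no coverage).
    """
    metadata = _check_metadata(metadata)
    if format not in ("vcf", "tsv"):
        raise CohortError(f"unknown format {format!r}")
    if not variant_paths:
        return empty_cohort(metadata)
    reader = _read_one_vcf if format == "vcf" else _read_one_tsv
    return merge_sites((reader(str(p)) for p in variant_paths), metadata)


def write_cohort(table: CohortTable, path: str | os.PathLike, format: str) -> None:
    if format == "vcf":
        write_cohort_vcf(table, path)
    elif format == "tsv":
        write_cohort_tsv(table, path)
    else:
        raise CohortError(f"unknown format {format!r}")


# ----------------------------------------------------------------------
# Copy number
# ----------------------------------------------------------------------

def read_copy_number(
    path: str | os.PathLike,
    purity: float = 1.0,
    coordinates: str = "bed",
    sample_id: str | None = None,
) -> CopyNumberProfile:
    """Read a BED-like segment table into a :class:`CopyNumberProfile`.

    ``coordinates`` declares the input dialect: ``"bed"`` (0-based
    half-open, the default for ASCAT/Battenberg-style exports) or
    ``"one_based"`` (already 1-based inclusive).  Internally everything
    is 1-based inclusive.
    """
    if coordinates not in ("bed", "one_based"):
        raise CohortError(f"unknown coordinate dialect {coordinates!r}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "start", "end", "total_cn", "minor_cn"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    segments = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if coordinates == "bed":
            start += 1  # half-open end becomes the inclusive end as-is
        segments.append((str(row.chrom), start, end, int(row.total_cn), int(row.minor_cn)))
    sid = sample_id or os.path.splitext(os.path.basename(str(path)))[0]
    return CopyNumberProfile(sample_id=sid, purity=purity, segments=segments)


def write_copy_number(profile: CopyNumberProfile, path: str | os.PathLike) -> None:
    """Write segments as BED-dialect TSV (0-based half-open)."""
    rows = [
        {"chrom": c, "start": s - 1, "end": e, "total_cn": t, "minor_cn": m}
        for c, s, e, t, m in profile.segments
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "total_cn", "minor_cn"]).to_csv(
        path, sep="\t", index=False
    )
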