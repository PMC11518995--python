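"""Core containers for multi-sample variant read-count cohorts.

The central object is :class:`CohortTable`: an ordered list of variant
sites crossed with an ordered list of samples, holding alt-read and total
depth counts for every (site, sample) pair.  Samples carry a tissue role
(tumour, normal kidney, blood, or panel normal) so downstream stages can
select the right columns without positional conventions.

All genomic coordinates are 1-based inclusive throughout the package.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

VARIANT_CLASSES = ("SNV", "DNV", "insertion", "deletion", "duplication")
TISSUE_ROLES = ("tumour", "normal_kidney", "blood", "panel_normal")

#: QC annotation keys the quality-filter cascade understands.
QC_KEYS = ("CLPM", "ASMD", "MAPQ", "BASEQ")


class CohortError(ValueError):
    """Raised for malformed or inconsistent cohort data."""


def infer_variant_class(ref: str, alt: str) -> str:
    """Infer the variant class from allele lengths.

    Equal-length substitutions are SNV (length 1) or DNV (length > 1,
    a multi-nucleotide substitution counted as a single event).  Length
    changes are insertions/deletions; tandem duplications cannot be
    told apart from generic insertions without the flanking sequence,
    so they must be labelled explicitly by the caller.
    """
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "DNV"
    return "insertion" if len(alt) > len(ref) else "deletion"


@dataclass
class VariantSite:
    """One substitution or indel locus.

    ``qc`` maps annotation names (CLPM, ASMD, MAPQ, BASEQ, ...) to numeric
    values; annotations are optional but the quality filter flags SNVs
    that lack them.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str = ""
    qc: dict[str, float] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise CohortError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise CohortError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if not self.variant_class:
            self.variant_class = infer_variant_class(self.ref, self.alt)
        if self.variant_class not in VARIANT_CLASSES:
            raise CohortError(f"unknown variant_class {self.variant_class!r}")
        self._check_class_consistency()

    def _check_class_consistency(self) -> None:
        lr, la = len(self.ref), len(self.alt)
        vc = self.variant_class
        ok = {
            "SNV": lr == 1 and la == 1,
            "DNV": lr == la and lr > 1,
            "insertion": la > lr,
            "duplication": la > lr,
            "deletion": lr > la,
        }[vc]
        if not ok:
            raise CohortError(
                f"variant_class {vc} inconsistent with alleles "
                f"{self.ref}>{self.alt} at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity used for deduplication and deterministic ordering."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return self.variant_class == "SNV"

    def label(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class SampleMeta:
    """Sample identity plus its tissue role in the analysis."""

    sample_id: str
    tissue_role: str
    mean_coverage: float | None = None

    def __post_init__(self) -> None:
        if self.tissue_role not in TISSUE_ROLES:
            raise CohortError(
                f"tissue_role {self.tissue_role!r} not one of {TISSUE_ROLES}"
            )


def _site_sort_key(site: VariantSite) -> tuple:
    # Lexicographic on (chrom, pos, ref, alt); chromosome names compared
    # as strings so ordering is reproducible without a genome dictionary.
    return site.key


@dataclass
class CohortTable:
    """Sites x samples matrix of allele counts.

    ``alt`` and ``depth`` are integer arrays of shape
    ``(n_sites, n_samples)``; a depth of 0 means "no coverage" and the
    VAF there is undefined (NaN), which is distinct from a confidently
    reference-homozygous 0/N observation.
    """

    sites: list[VariantSite]
    samples: list[SampleMeta]
    alt: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.alt = np.asarray(self.alt, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        shape = (len(self.sites), len(self.samples))
        if self.alt.shape != shape or self.depth.shape != shape:
            raise CohortError(
                f"count matrices {self.alt.shape}/{self.depth.shape} do not "
                f"match {shape} (sites x samples)"
            )
        if (self.alt < 0).any() or (self.depth < 0).any():
            raise CohortError("negative read counts")
        if (self.alt > self.depth).any():
            raise CohortError("alt_reads exceeds depth")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise CohortError("duplicate sample_id in cohort")

    # -- basic geometry -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise CohortError(f"unknown sample {sample_id!r}") from None

    def samples_with_role(self, role: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.tissue_role == role]

    # -- derived quantities ---------------------------------------------
    def vaf(self) -> np.ndarray:
        """VAF matrix with NaN wherever depth is 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            v = self.alt / self.depth
        v[self.depth == 0] = np.nan
        return v

    # -- subsetting -----------------------------------------------------
    def subset_sites(self, mask: np.ndarray | Sequence[int]) -> "CohortTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CohortTable(
            sites=[self.sites[i] for i in idx],
            samples=list(self.samples),
            alt=self.alt[idx, :],
            depth=self.depth[idx, :],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "CohortTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return CohortTable(
            sites=list(self.sites),
            samples=[self.samples[i] for i in idx],
            alt=self.alt[:, idx],
            depth=self.depth[:, idx],
        )

    def sorted(self) -> "CohortTable":
        """Return a copy with sites in canonical (chrom,pos,ref,alt) order."""
        order = sorted(range(self.n_sites), key=lambda i: _site_sort_key(self.sites[i]))
        return self.subset_sites(np.asarray(order, dtype=int))

    def site_index(self) -> dict[tuple, int]:
        return {s.key: i for i, s in enumerate(self.sites)}

    def equals(self, other: "CohortTable") -> bool:
        """Exact equality of sites, sample metadata and counts."""
        return (
            [s.key for s in self.sites] == [s.key for s in other.sites]
            and [s.variant_class for s in self.sites]
            == [s.variant_class for s in other.sites]
            and self.samples == other.samples
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.depth, other.depth)
        )


def empty_cohort(samples: Sequence[SampleMeta] = ()) -> CohortTable:
    n = len(samples)
    return CohortTable([], list(samples), np.zeros((0, n)), np.zeros((0, n)))


def merge_sites(
    per_file: Iterable[tuple[list[VariantSite], list[str], np.ndarray, np.ndarray]],
    samples: Sequence[SampleMeta],
) -> CohortTable:
    """Union per-file site lists into one deduplicated, sorted table.

    ``per_file`` yields (sites, sample_ids, alt, depth) blocks.  Sites are
    deduplicated on (chrom, pos, ref, alt); a (site, sample) pair absent
    from every block gets alt=0 at depth=0 ("no coverage"), never a
    fabricated reference call.
    """
    samples = list(samples)
    order = {m.sample_id: j for j, m in enumerate(samples)}
    site_map: dict[tuple, VariantSite] = {}
    blocks = []
    for sites, sids, alt, depth in per_file:
        for s in sids:
            if s not in order:
                raise CohortError(f"sample {s!r} not declared in metadata")
        blocks.append((sites, sids, np.asarray(alt), np.asarray(depth)))
        for site in sites:
            prev = site_map.get(site.key)
            if prev is None:
                site_map[site.key] = site
            else:
                # keep first record, merge any extra qc annotations
                for k, v in site.qc.items():
                    prev.qc.setdefault(k, v)
    keys = sorted(site_map)
    row = {k: i for i, k in enumerate(keys)}
    alt = np.zeros((len(keys), len(samples)), dtype=np.int64)
    depth = np.zeros_like(alt)
    for sites, sids, a, d in blocks:
        cols = [order[s] for s in sids]
        for i, site in enumerate(sites):
            r = row[site.key]
            for jj, c in enumerate(cols):
                alt[r, c] = a[i, jj]
                depth[r, c] = d[i, jj]
    return CohortTable([site_map[k] for k in keys], samples, alt, depth)


# ----------------------------------------------------------------------
# Copy number
# ----------------------------------------------------------------------

@dataclass
class CopyNumberProfile:
    """Per-tumour copy-number segments with tumour purity.

    Segments are (chrom, start, end, total_cn, minor_cn) in 1-based
    inclusive coordinates.  Positions not covered by any segment fall
    back to ``default_cn`` (diploid heterozygous, (2, 1)); the patient
    modelled here is female, so X is treated like an autosome.
    """

    sample_id: str
    purity: float = 1.0
    segments: list[tuple[str, int, int, int, int]] = field(default_factory=list)
    default_cn: tuple[int, int] = (2, 1)

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise CohortError(f"purity {self.purity} outside [0, 1]")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, total, minor in self.segments:
            if start < 1 or end < start:
                raise CohortError(f"bad segment bounds {chrom}:{start}-{end}")
            if minor < 0 or total < minor:
                raise CohortError(
                    f"total_cn {total} < minor_cn {minor} at {chrom}:{start}-{end}"
                )
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise CohortError(f"overlapping segments on {chrom}")
        self._index: dict[str, tuple[list[int], list[tuple[int, int, int]]]] = {}
        for chrom in by_chrom:
            segs = sorted(
                (s, e, t, m) for c, s, e, t, m in self.segments if c == chrom
            )
            self._index[chrom] = (
                [s for s, *_ in segs],
                [(e, t, m) for _, e, t, m in segs],
            )

    def cn_at(self, chrom: str, pos: int) -> tuple[int, int]:
        """Total/minor copy number at a coordinate; total over the genome."""
        entry = self._index.get(chrom)
        if entry is None:
            return self.default_cn
        starts, rest = entry
        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0:
            end, total, minor = rest[i]
            if pos <= end:
                return (total, minor)
        return self.default_cn


def cn_at(profile: CopyNumberProfile, chrom: str, pos: int) -> tuple[int, int]:
    """Functional alias for :meth:`CopyNumberProfile.cn_at`."""
    return profile.cn_at(chrom, pos)
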