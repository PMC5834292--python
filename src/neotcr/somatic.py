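"""Tumor/normal somatic variant calling from per-site pileup observations.

The caller evaluates every non-reference allele observed in the tumor pileup
against six criteria commonly used by exome pipelines:

(i)   supporting bases must have Phred base quality >= 15,
(ii)  sequence depth >= 10 in each sample,
(iii) tumor variant depth >= 4,
(iv)  tumor variant allele frequency (VAF) >= 10%,
(v)   normal VAF < 2% (strict),
(vi)  one-sided Fisher exact p < 0.05 (strict) for alt enrichment in tumor.

Before any counting, reads with mapping quality < 30 or with a per-read
mismatch fraction above 5% of the read length are excluded, mirroring the
post-alignment hygiene filters of a BWA/Picard pipeline (alignment itself is
upstream and out of scope).

Coordinates are 1-based VCF-style; multi-allelic sites emit one record per
alt allele, alts ordered lexicographically.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

#: Identifiers of the six calling criteria, in their conventional order.
CRITERIA = (
    "base_quality",
    "depth",
    "variant_depth",
    "tumor_vaf",
    "normal_vaf",
    "fisher_p",
)


@dataclass(frozen=True)
class ReadObservation:
    """A single read's contribution to one pileup column.

    ``base`` is the observed allele: a single nucleotide for a substitution,
    or a longer/shorter VCF-style allele string for an indel observation.
    """

    base: str
    base_quality: int
    mapping_quality: int
    read_length: int
    mismatch_count: int = 0

    def __post_init__(self) -> None:
        if not self.base:
            raise ValueError("observation base must be non-empty")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.mismatch_count < 0 or self.mismatch_count > self.read_length:
            raise ValueError("mismatch_count must be in [0, read_length]")
        if self.base_quality < 0 or self.mapping_quality < 0:
            raise ValueError("qualities must be non-negative")


@dataclass
class PileupSite:
    """Per-site tumor and normal read observations."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    tumor_obs: list[ReadObservation] = field(default_factory=list)
    normal_obs: list[ReadObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if not self.ref_allele:
            raise ValueError("ref_allele must be non-empty")

    @classmethod
    def from_counts(
        cls,
        chrom: str,
        pos: int,
        ref: str,
        alt: str,
        tumor_alt: int,
        tumor_depth: int,
        normal_alt: int,
        normal_depth: int,
        base_quality: int = 40,
        mapping_quality: int = 60,
        read_length: int = 100,
    ) -> "PileupSite":
        """Build a site from pre-filtered aggregate counts.

        All synthesized observations carry high qualities so that only the
        count-based criteria (ii)-(vi) discriminate.
        """
        if tumor_alt > tumor_depth or normal_alt > normal_depth:
            raise ValueError("alt depth cannot exceed total depth")

        def obs(base: str, n: int) -> list[ReadObservation]:
            return [
                ReadObservation(base, base_quality, mapping_quality, read_length)
                for _ in range(n)
            ]

        return cls(
            chrom,
            pos,
            ref,
            tumor_obs=obs(alt, tumor_alt) + obs(ref, tumor_depth - tumor_alt),
            normal_obs=obs(alt, normal_alt) + obs(ref, normal_depth - normal_alt),
        )


@dataclass(frozen=True)
class CallingParams:
    """Thresholds of the six calling criteria and the read pre-filters.

    Defaults are the conventional exome-pipeline values; VAF and p-value
    bounds keep their stated inclusivity: tumor VAF >= ``min_tumor_vaf``,
    normal VAF strictly below ``max_normal_vaf``, Fisher p strictly below
    ``max_fisher_p``.
    """

    min_base_quality: int = 15
    min_depth: int = 10
    min_variant_depth: int = 4
    min_tumor_vaf: float = 0.10
    max_normal_vaf: float = 0.02
    max_fisher_p: float = 0.05
    min_mapping_quality: int = 30
    max_mismatch_fraction: float = 0.05
    fisher_alternative: str = "greater"  # or "two-sided"

    def __post_init__(self) -> None:
        for name in ("min_tumor_vaf", "max_normal_vaf", "max_fisher_p", "max_mismatch_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.fisher_alternative not in ("greater", "two-sided"):
            raise ValueError("fisher_alternative must be 'greater' or 'two-sided'")


@dataclass
class SomaticVariant:
    """A candidate call with its depths, VAFs, Fisher p and criterion flags."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    tumor_depth: int
    tumor_alt_depth: int
    normal_depth: int
    normal_alt_depth: int
    tumor_vaf: float
    normal_vaf: float
    fisher_p: float
    criterion_flags: dict[str, bool]

    @property
    def is_pass(self) -> bool:
        return all(self.criterion_flags.get(c, False) for c in CRITERIA)

    @property
    def failed_criteria(self) -> list[str]:
        return [c for c in CRITERIA if not self.criterion_flags.get(c, False)]

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


def filter_read(obs: ReadObservation, params: CallingParams = CallingParams()) -> bool:
    """Return True iff the read passes the mapping-quality and mismatch filters.

    Reads with mapping quality below ``min_mapping_quality`` or with a
    mismatch fraction strictly above ``max_mismatch_fraction`` of the read
    length are excluded from all counting.
    """
    if obs.read_length <= 0:
        raise ValueError("read_length must be positive")
    if obs.mapping_quality < params.min_mapping_quality:
        return False
    return obs.mismatch_count <= params.max_mismatch_fraction * obs.read_length


def fisher_exact_p(
    tumor_alt: int,
    tumor_ref: int,
    normal_alt: int,
    normal_ref: int,
    alternative: str = "greater",
) -> float:
    """Fisher exact p-value for the 2x2 table tumor/normal x alt/ref.

    Computed exactly from integer hypergeometric terms: with both margins
    fixed, the number of tumor alt reads X follows a hypergeometric
    distribution; ``alternative='greater'`` returns P(X >= observed), the
    one-sided test for alt-allele enrichment in tumor. ``'two-sided'`` sums
    the probability of every table no more likely than the observed one.
    The only rounding is the final big-integer division, so the result is
    correct to double precision.
    """
    counts = (tumor_alt, tumor_ref, normal_alt, normal_ref)
    if any(c < 0 for c in counts):
        raise ValueError(f"counts must be non-negative, got {counts}")
    n_tumor = tumor_alt + tumor_ref  # tumor row margin
    k_alt = tumor_alt + normal_alt  # alt column margin
    total = sum(counts)
    if total == 0:
        raise ValueError("at least one margin must be positive")

    lo = max(0, n_tumor - (total - k_alt))
    hi = min(k_alt, n_tumor)

    def term(k: int) -> int:
        return math.comb(k_alt, k) * math.comb(total - k_alt, n_tumor - k)

    denom = math.comb(total, n_tumor)
    if alternative == "greater":
        num = sum(term(k) for k in range(tumor_alt, hi + 1))
    elif alternative == "two-sided":
        observed = term(tumor_alt)
        num = sum(t for k in range(lo, hi + 1) if (t := term(k)) <= observed)
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    return min(1.0, num / denom)


def _filtered_allele_counts(
    obs_list: Iterable[ReadObservation], params: CallingParams
) -> Counter:
    """Allele counts over observations surviving read and base-quality filters."""
    counts: Counter = Counter()
    for obs in obs_list:
        if filter_read(obs, params) and obs.base_quality >= params.min_base_quality:
            counts[obs.base] += 1
    return counts


def evaluate_site(
    site: PileupSite, params: CallingParams = CallingParams()
) -> list[SomaticVariant]:
    """Evaluate all six criteria for every non-reference tumor allele.

    Returns one :class:`SomaticVariant` per alt allele with at least one
    quality-passing tumor observation, PASS or not, alts in lexicographic
    order. Use :func:`call_site` for PASS calls only.
    """
    t_counts = _filtered_allele_counts(site.tumor_obs, params)
    n_counts = _filtered_allele_counts(site.normal_obs, params)
    t_depth = sum(t_counts.values())
    n_depth = sum(n_counts.values())

    out: list[SomaticVariant] = []
    for alt in sorted(a for a in t_counts if a != site.ref_allele):
        t_alt = t_counts[alt]
        n_alt = n_counts.get(alt, 0)
        t_vaf = t_alt / t_depth if t_depth else 0.0
        n_vaf = n_alt / n_depth if n_depth else 0.0
        p = fisher_exact_p(
            t_alt, t_depth - t_alt, n_alt, n_depth - n_alt,
            alternative=params.fisher_alternative,
        )
        flags = {
            "base_quality": t_alt >= 1,
            "depth": t_depth >= params.min_depth and n_depth >= params.min_depth,
            "variant_depth": t_alt >= params.min_variant_depth,
            "tumor_vaf": t_vaf >= params.min_tumor_vaf,
            "normal_vaf": n_vaf < params.max_normal_vaf,
            "fisher_p": p < params.max_fisher_p,
        }
        ref, alt_n, pos = normalize_alleles(site.pos, site.ref_allele, alt)
        out.append(
            SomaticVariant(
                chrom=site.chrom,
                pos=pos,
                ref_allele=ref,
                alt_allele=alt_n,
                tumor_depth=t_depth,
                tumor_alt_depth=t_alt,
                normal_depth=n_depth,
                normal_alt_depth=n_alt,
                tumor_vaf=t_vaf,
                normal_vaf=n_vaf,
                fisher_p=p,
                criterion_flags=flags,
            )
        )
    return out


def call_site(
    site: PileupSite, params: CallingParams = CallingParams()
) -> list[SomaticVariant]:
    """Somatic calls at one site: the alt alleles passing all six criteria."""
    return [v for v in evaluate_site(site, params) if v.is_pass]


def call_cohort(
    sites: Sequence[PileupSite],
    params: CallingParams = CallingParams(),
    emit_all: bool = False,
) -> list[SomaticVariant]:
    """Call every site and return records sorted by (chrom, pos, alt).

    With ``emit_all`` the output also contains non-PASS records (used for
    VCF FILTER annotation); duplicate (chrom, pos, ref, alt) records among
    the emitted calls indicate malformed input and raise.
    """
    calls: list[SomaticVariant] = []
    for site in sites:
        calls.extend(evaluate_site(site, params) if emit_all else call_site(site, params))
    calls.sort(key=lambda v: (v.chrom, v.pos, v.alt_allele))
    seen: set = set()
    for v in calls:
        if v.key() in seen:
            raise RuntimeError(f"duplicate call emitted for {v.key()}")
        seen.add(v.key())
    return calls


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[str, str, int]:
    """Trim shared prefix/suffix of a ref/alt pair, VCF left-aligned style.

    A common suffix is removed first, then the common prefix (keeping at
    least one base of each allele and shifting ``pos`` right across the
    trimmed prefix). SNVs pass through unchanged.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return ref, alt, pos


# ---------------------------------------------------------------------------
# Tabular input dialects
# ---------------------------------------------------------------------------

PILEUP_COLUMNS = ("chrom", "pos", "ref", "base", "base_qual", "mapq", "read_len", "n_mismatch")
COUNTS_COLUMNS = (
    "chrom", "pos", "ref", "alt",
    "tumor_alt", "tumor_depth", "normal_alt", "normal_depth",
)


def read_pileup_tsv(path: str | Path) -> dict[tuple[str, int, str], list[ReadObservation]]:
    """Read the per-observation pileup dialect (one row per read base).

    Columns (tab-separated, with header): chrom, pos, ref, base, base_qual,
    mapq, read_len, n_mismatch. An optional leading ``sample`` column is
    tolerated and ignored (tumor and normal live in separate files).
    """
    path = Path(path)
    sites: dict[tuple[str, int, str], list[ReadObservation]] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header and header[0] == "sample":
            header = header[1:]
            skip = 1
        else:
            skip = 0
        if tuple(header) != PILEUP_COLUMNS:
            raise ValueError(
                f"{path}: expected columns {PILEUP_COLUMNS}, got {tuple(header)}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")[skip:]
            if len(fields) != len(PILEUP_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(PILEUP_COLUMNS)} fields")
            chrom, pos, ref, base, bq, mq, rl, nm = fields
            key = (chrom, int(pos), ref)
            sites.setdefault(key, []).append(
                ReadObservation(base, int(bq), int(mq), int(rl), int(nm))
            )
    return sites


def sites_from_pileup_tsvs(tumor_path: str | Path, normal_path: str | Path) -> list[PileupSite]:
    """Merge tumor and normal observation tables into sorted pileup sites."""
    tumor = read_pileup_tsv(tumor_path)
    normal = read_pileup_tsv(normal_path)
    keys = sorted(set(tumor) | set(normal))
    return [
        PileupSite(c, p, r, tumor.get((c, p, r), []), normal.get((c, p, r), []))
        for c, p, r in keys
    ]


def sites_from_counts_tsv(path: str | Path) -> list[PileupSite]:
    """Read the aggregate-counts dialect for pre-filtered data.

    Columns: chrom, pos, ref, alt, tumor_alt, tumor_depth, normal_alt,
    normal_depth. Observations are synthesized at uniformly high quality so
    only criteria (ii)-(vi) act.
    """
    path = Path(path)
    sites: list[PileupSite] = []
    with path.open() as fh:
        header = tuple(fh.readline().rstrip("\n").split("\t"))
        if header != COUNTS_COLUMNS:
            raise ValueError(f"{path}: expected columns {COUNTS_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != len(COUNTS_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(COUNTS_COLUMNS)} fields")
            sites.append(
                PileupSite.from_counts(
                    f[0], int(f[1]), f[2], f[3],
                    int(f[4]), int(f[5]), int(f[6]), int(f[7]),
                )
            )
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

def write_vcf(
    variants: Sequence[SomaticVariant],
    path: str | Path,
    params: CallingParams = CallingParams(),
) -> None:
    """Write calls as VCF v4.2 with depth/VAF/Fisher INFO fields.

    FILTER is PASS for variants meeting all six criteria; otherwise it names
    each violated criterion.
    """
    header = pysam.VariantHeader()
    for crit in CRITERIA:
        header.filters.add(crit, None, None, f"failed calling criterion: {crit}")
    header.info.add("TDP", 1, "Integer", "Tumor depth after read/base filters")
    header.info.add("TAD", 1, "Integer", "Tumor alt allele depth")
    header.info.add("NDP", 1, "Integer", "Normal depth after read/base filters")
    header.info.add("NAD", 1, "Integer", "Normal alt allele depth")
    header.info.add("TVAF", 1, "Float", "Tumor variant allele frequency")
    header.info.add("NVAF", 1, "Float", "Normal variant allele frequency")
    header.info.add("FISHP", 1, "Float", "One-sided Fisher exact p (tumor alt enrichment)")
    for chrom in dict.fromkeys(v.chrom for v in variants):
        header.contigs.add(chrom)

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in variants:
            rec = vcf.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                alleles=(v.ref_allele, v.alt_allele),
                info={
                    "TDP": v.tumor_depth,
                    "TAD": v.tumor_alt_depth,
                    "NDP": v.normal_depth,
                    "NAD": v.normal_alt_depth,
                    "TVAF": round(v.tumor_vaf, 6),
                    "NVAF": round(v.normal_vaf, 6),
                    "FISHP": v.fisher_p,
                },
            )
            if v.is_pass:
                rec.filter.add("PASS")
            else:
                for crit in v.failed_criteria:
                    rec.filter.add(crit)
            vcf.write(rec)
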