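"""Read GWAS-catalog-style association tables and apply inclusion filters.

The input dialect is the NHGRI GWAS catalog TSV: one row per reported
SNP-trait association, with free-text trait and sample-ancestry columns.
This module parses those rows into typed records, applies the study-level
exclusions (platform below 100,000 SNPs, copy-number-variant sections,
family-based discovery designs) and the association-level p-value threshold
(P < 1e-5 by default, P < 1e-7 for the stringent rerun), and maps free text
onto phenotype categories and ancestry strata.

Rows with unparseable positions or p-values are *retained* with missing-value
markers and logged, never silently dropped, so that exclusion counts can be
audited downstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .config import (
    DEFAULT_ANCESTRY_KEYWORDS,
    DEFAULT_DIALECT,
    DEFAULT_PHENOTYPE_KEYWORDS,
    REQUIRED_LOGICAL_COLUMNS,
)

logger = logging.getLogger(__name__)

STUDY_DESIGNS = ("standard_gwas", "cnv", "family_based", "meta_analysis")


class CatalogFormatError(ValueError):
    """Raised when a required column is missing from the catalog file."""


@dataclass
class AssociationRecord:
    """One catalog row: a reported SNP-trait association."""

    study_id: str
    pubmed_id: str
    trait_text: str
    snp_id: str
    chrom: str | None
    pos: int | None
    p_value: float | None
    reported_genes: list[str] = field(default_factory=list)
    ancestry_text: str = ""
    haplotype_flag: bool = False

    @property
    def mappable(self) -> bool:
        """True when the row carries a usable genomic position."""
        return self.chrom is not None and self.pos is not None


@dataclass
class StudyRecord:
    study_id: str
    design: str = "standard_gwas"
    platform_snp_count: int = 0
    discovery_ancestry: str = "other_mixed"

    def __post_init__(self) -> None:
        if self.design not in STUDY_DESIGNS:
            raise ValueError(f"unknown study design {self.design!r}")
        if self.platform_snp_count < 0:
            raise ValueError("platform_snp_count must be >= 0")


@dataclass
class PhenotypeConfig:
    """Keyword list for one phenotype category; order in a list of these
    configs is the tie-break priority."""

    phenotype: str
    keywords: list[str]

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError(f"phenotype {self.phenotype!r} needs >=1 keyword")
        self.keywords = [k.lower() for k in self.keywords]


def default_phenotype_configs() -> list[PhenotypeConfig]:
    return [PhenotypeConfig(p, list(kws)) for p, kws in DEFAULT_PHENOTYPE_KEYWORDS.items()]


# --------------------------------------------------------------------------
# parsing helpers

_PLATFORM_COUNT_RE = re.compile(r"\[\s*([\d,~>]+)")


def _parse_platform_count(text: str) -> int:
    """Pull the SNPs-passing-QC count out of e.g. ``Affymetrix [500,568]``."""
    if not text:
        return 0
    m = _PLATFORM_COUNT_RE.search(text)
    if not m:
        return 0
    digits = re.sub(r"[^\d]", "", m.group(1))
    return int(digits) if digits else 0


def _parse_float(value: str) -> float | None:
    try:
        p = float(value)
    except (TypeError, ValueError):
        return None
    return p if 0.0 < p <= 1.0 else None


def _parse_pos(value: str) -> int | None:
    try:
        pos = int(str(value).replace(",", ""))
    except (TypeError, ValueError):
        return None
    return pos if pos >= 1 else None


def _split_genes(value: str) -> list[str]:
    if not value or value.upper() in {"NR", "NA", "NONE", "INTERGENIC"}:
        return []
    return [g.strip() for g in re.split(r"[,;]", value) if g.strip()]


def read_catalog(
    path,
    dialect: dict[str, str] | None = None,
) -> tuple[list[AssociationRecord], list[StudyRecord]]:
    """Parse a catalog TSV into association and study records.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    dialect
        Map from logical column names (``study_id``, ``trait``, ...) to the
        physical headers in this file.  Defaults to the public 2011-era
        catalog header set.

    Returns one :class:`AssociationRecord` per row (rows with unparseable
    fields keep ``None`` markers) and one :class:`StudyRecord` per distinct
    study identifier.

    Raises
    ------
    CatalogFormatError
        If a required logical column is not present in the file.
    """
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty and df.columns.size == 0:
        logger.warning("catalog file %s is empty", path)
        return [], []
    for logical in REQUIRED_LOGICAL_COLUMNS:
        if dialect[logical] not in df.columns:
            raise CatalogFormatError(
                f"catalog is missing required column {dialect[logical]!r} "
                f"(logical field {logical!r})"
            )
    if df.empty:
        logger.warning("catalog file %s has a header but no rows", path)

    col = {k: dialect[k] for k in dialect}
    has_platform = col["platform"] in df.columns
    has_design = col.get("design") and col["design"] in df.columns
    has_genes = col["reported_genes"] in df.columns

    records: list[AssociationRecord] = []
    studies: dict[str, StudyRecord] = {}
    n_bad_pos = n_bad_p = 0
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        snp = row[col["snp_id"]].strip()
        pos = _parse_pos(row[col["pos"]])
        pval = _parse_float(row[col["p_value"]])
        if pos is None:
            n_bad_pos += 1
        if pval is None:
            n_bad_p += 1
        chrom = row[col["chrom"]].strip().removeprefix("chr") or None
        rec = AssociationRecord(
            study_id=row[col["study_id"]].strip(),
            pubmed_id=row[col["pubmed_id"]].strip(),
            trait_text=row[col["trait"]].strip(),
            snp_id=snp,
            chrom=chrom,
            pos=pos if chrom is not None else None,
            p_value=pval,
            reported_genes=_split_genes(row[col["reported_genes"]]) if has_genes else [],
            ancestry_text=row[col["ancestry"]].strip(),
            haplotype_flag=(";" in snp or " x " in snp.lower()),
        )
        records.append(rec)
        sid = rec.study_id
        if sid not in studies:
            studies[sid] = StudyRecord(
                study_id=sid,
                design=(row[col["design"]].strip() or "standard_gwas")
                if has_design
                else "standard_gwas",
                platform_snp_count=_parse_platform_count(row[col["platform"]])
                if has_platform
                else 0,
                discovery_ancestry=assign_ancestry(rec.ancestry_text),
            )
    if n_bad_pos or n_bad_p:
        logger.warning(
            "retained %d rows with unparseable positions and %d with "
            "unparseable p-values (flagged, not dropped)",
            n_bad_pos,
            n_bad_p,
        )
    return records, list(studies.values())


def write_catalog(
    records: list[AssociationRecord],
    studies: list[StudyRecord],
    path,
    dialect: dict[str, str] | None = None,
) -> None:
    """Serialize records back to the catalog TSV dialect (ingest inverse)."""
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    by_study = {s.study_id: s for s in studies}
    rows = []
    for r in records:
        study = by_study.get(r.study_id)
        rows.append(
            {
                dialect["study_id"]: r.study_id,
                dialect["trait"]: r.trait_text,
                dialect["snp_id"]: r.snp_id,
                dialect["chrom"]: r.chrom if r.chrom is not None else "",
                dialect["pos"]: "" if r.pos is None else str(r.pos),
                dialect["p_value"]: "" if r.p_value is None else repr(r.p_value),
                dialect["reported_genes"]: ", ".join(r.reported_genes),
                dialect["ancestry"]: r.ancestry_text,
                dialect["platform"]: (
                    f"[{study.platform_snp_count:,}]" if study else "[0]"
                ),
                dialect["design"]: study.design if study else "standard_gwas",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# filters

@dataclass
class StudyFilterResult:
    kept: list[StudyRecord]
    excluded: list[tuple[StudyRecord, str]]  # (study, reason code)

    @property
    def excluded_ids(self) -> set[str]:
        return {s.study_id for s, _ in self.excluded}


def filter_studies(
    studies: list[StudyRecord], min_snps: int = 100_000
) -> StudyFilterResult:
    """Partition studies into kept / excluded with machine-readable reasons.

    Exclusion reasons: ``too_few_snps`` (discovery platform assayed fewer
    than ``min_snps`` SNPs — strict inequality), ``cnv``, ``family_based``.
    Meta-analyses reporting novel variants are kept.
    """
    kept, excluded = [], []
    for s in studies:
        if s.design == "cnv":
            excluded.append((s, "cnv"))
        elif s.design == "family_based":
            excluded.append((s, "family_based"))
        elif s.platform_snp_count < min_snps:
            excluded.append((s, "too_few_snps"))
        else:
            kept.append(s)
    return StudyFilterResult(kept=kept, excluded=excluded)


@dataclass
class AssociationFilterResult:
    kept: list[AssociationRecord]
    n_excluded_threshold: int
    n_missing_p: int


def filter_associations(
    records: list[AssociationRecord], p_threshold: float = 1e-5
) -> AssociationFilterResult:
    """Keep associations with ``p_value < p_threshold`` (strict).

    Records with a missing p-value are excluded and counted separately.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie in (0, 1)")
    kept, n_thr, n_missing = [], 0, 0
    for r in records:
        if r.p_value is None:
            n_missing += 1
        elif r.p_value < p_threshold:
            kept.append(r)
        else:
            n_thr += 1
    return AssociationFilterResult(kept, n_thr, n_missing)


# --------------------------------------------------------------------------
# free-text classification

def assign_phenotype(
    trait_text: str, configs: list[PhenotypeConfig] | None = None
) -> str | None:
    """Map a free-text trait to a phenotype category, or None if unmatched.

    Matching is case-insensitive substring search; when several phenotypes
    match, the first in config order wins (declared priority).
    """
    configs = configs if configs is not None else default_phenotype_configs()
    if not configs:
        raise ValueError("phenotype config must be non-empty")
    text = trait_text.lower()
    for cfg in configs:
        if any(kw in text for kw in cfg.keywords):
            return cfg.phenotype
    logger.debug("trait %r matched no phenotype keyword", trait_text)
    return None


def assign_ancestry(
    ancestry_text: str, keywords: dict[str, list[str]] | None = None
) -> str:
    """Map free-text sample descriptions to an ancestry stratum.

    A description naming exactly one ancestry group maps to it; naming
    several distinct groups (or none that we recognise) maps to
    ``other_mixed``.  Only European and African strata are analysed
    separately; everything else contributes to the pooled stratum only.
    """
    keywords = keywords or DEFAULT_ANCESTRY_KEYWORDS
    text = ancestry_text.lower()
    hits = [grp for grp, kws in keywords.items() if any(kw in text for kw in kws)]
    if len(hits) == 1:
        return hits[0]
    return "other_mixed"


def normalize(
    records: list[AssociationRecord],
    configs: list[PhenotypeConfig] | None = None,
    ancestry_keywords: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Tabulate records with phenotype / ancestry assignments attached.

    Unassignable traits get phenotype ``None`` and are retained so that the
    audit trail is complete; downstream set building ignores them.
    """
    rows = []
    for r in records:
        rows.append(
            {
                "study_id": r.study_id,
                "pubmed_id": r.pubmed_id,
                "trait": r.trait_text,
                "phenotype": assign_phenotype(r.trait_text, configs),
                "snp_id": r.snp_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "p_value": r.p_value,
                "reported_genes": list(r.reported_genes),
                "ancestry": assign_ancestry(r.ancestry_text, ancestry_keywords),
                "haplotype_flag": r.haplotype_flag,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "study_id",
            "pubmed_id",
            "trait",
            "phenotype",
            "snp_id",
            "chrom",
            "pos",
            "p_value",
            "reported_genes",
            "ancestry",
            "haplotype_flag",
        ],
    )
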