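"""Analysis configuration: phenotype keywords, ancestry keywords, thresholds.

Six cardiovascular-risk phenotype categories are analysed: blood pressure
(BP), coronary artery disease (CAD), type 2 diabetes (T2D), obesity, blood
lipids, and chronic kidney disease (CKD).  Free-text catalog traits are
mapped onto these categories by case-insensitive keyword search; the keyword
lists are configuration, not code, because the underlying trait vocabulary
varies between catalog releases.  Ties are broken by the declared phenotype
priority order (the order of ``phenotype_keywords``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: Canonical phenotype category labels, in priority order for trait matching.
PHENOTYPES: tuple[str, ...] = ("BP", "CAD", "T2D", "Obesity", "Lipids", "CKD")

#: Ancestry strata used for stratified analyses.
STRATA: tuple[str, ...] = ("pooled", "european", "african")

DEFAULT_PHENOTYPE_KEYWORDS: dict[str, list[str]] = {
    "BP": ["blood pressure", "hypertension", "systolic", "diastolic"],
    "CAD": [
        "coronary",
        "myocardial infarction",
        "cardiovascular disease",
        "angina",
    ],
    "T2D": ["type 2 diabetes", "glucose", "insulin", "glycated", "hba1c"],
    "Obesity": ["obesity", "body mass index", "bmi", "waist", "adiposity", "weight"],
    "Lipids": ["cholesterol", "lipid", "triglyceride", "hdl", "ldl"],
    "CKD": [
        "kidney",
        "renal",
        "glomerular filtration",
        "egfr",
        "creatinine",
        "albuminuria",
    ],
}

DEFAULT_ANCESTRY_KEYWORDS: dict[str, list[str]] = {
    "european": ["european", "caucasian", "white", "finnish", "icelandic"],
    "african": ["african"],
    "asian": ["asian", "chinese", "japanese", "korean", "han", "indian"],
}

#: Extended MHC region, GRCh37 coordinates (chr6:28,477,797-33,448,354).
#: A config value, not a constant of the method: the span is genome-build
#: specific and the HLA exclusion only needs *an* interval to act on.
DEFAULT_MHC_REGION: tuple[str, int, int] = ("6", 28_477_797, 33_448_354)

#: Column-name map for the public 2011-era GWAS catalog header set.
DEFAULT_DIALECT: dict[str, str] = {
    "study_id": "PUBMEDID",
    "pubmed_id": "PUBMEDID",
    "trait": "DISEASE/TRAIT",
    "snp_id": "SNPS",
    "chrom": "CHR_ID",
    "pos": "CHR_POS",
    "p_value": "P-VALUE",
    "reported_genes": "REPORTED GENE(S)",
    "ancestry": "INITIAL SAMPLE DESCRIPTION",
    "platform": "PLATFORM [SNPS PASSING QC]",
    # Optional: absent from the public header; emitted by the simulator so
    # that CNV / family-based decoy studies are machine-readable.
    "design": "STUDY DESIGN",
}

#: Columns that must be resolvable for ingest to proceed.
REQUIRED_LOGICAL_COLUMNS: tuple[str, ...] = (
    "study_id",
    "trait",
    "snp_id",
    "chrom",
    "pos",
    "p_value",
    "ancestry",
)


@dataclass
class AnalysisConfig:
    """Bundle of tunables for one analysis run."""

    phenotype_keywords: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_PHENOTYPE_KEYWORDS.items()}
    )
    ancestry_keywords: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_ANCESTRY_KEYWORDS.items()}
    )
    mhc_region: tuple[str, int, int] = DEFAULT_MHC_REGION
    p_threshold: float = 1e-5
    min_platform_snps: int = 100_000
    #: Gene-pool size N for significance tests; None = count the distinct
    #: non-MHC positional genes actually ingested.
    pool_size: int | None = None
    dialect: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_DIALECT))
    #: Reference (epidemiological) network edges; None = complete 6-clique.
    reference_edges: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        for phen, kws in self.phenotype_keywords.items():
            if not kws:
                raise ValueError(f"phenotype {phen!r} has no keywords")


def load_config(path: str) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a YAML file.

    Any omitted key keeps its default.  Recognised keys mirror the
    ``AnalysisConfig`` fields; ``mhc_region`` may be given either as a
    ``[chrom, start, end]`` list or a ``chr6:START-END`` string.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key in (
        "phenotype_keywords",
        "ancestry_keywords",
        "p_threshold",
        "min_platform_snps",
        "pool_size",
        "dialect",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "mhc_region" in raw:
        kwargs["mhc_region"] = parse_region(raw["mhc_region"])
    if "reference_edges" in raw:
        kwargs["reference_edges"] = [tuple(e) for e in raw["reference_edges"]]
    return AnalysisConfig(**kwargs)


def parse_region(value) -> tuple[str, int, int]:
    """Normalize ``chr6:100-200`` / ``[chrom, start, end]`` to a tuple."""
    if isinstance(value, str):
        chrom, _, span = value.partition(":")
        start, _, end = span.partition("-")
        chrom = chrom.removeprefix("chr")
        return chrom, int(start.replace(",", "")), int(end.replace(",", ""))
    chrom, start, end = value
    return str(chrom).removeprefix("chr"), int(start), int(end)
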