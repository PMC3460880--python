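"""Seeded synthetic GWAS catalogs with planted pleiotropy and ground truth.

The generator emulates the three inputs of the pipeline — an association
table in the catalog TSV dialect, a gene annotation, and the implicit
phenotype structure — at a desk scale (a few hundred genes) while keeping
the *shape* of the real data: six phenotype categories, a European-dominated
ancestry mix, SNPs placed both inside genes and intergenically, association
p-values straddling the stringent threshold, an MHC-like flagged block, and
decoy studies that violate each inclusion rule.

Every quantity the pipeline should recover is recorded in a
:class:`GroundTruth` object built *alongside* the catalog, so recovery tests
compare pipeline output against construction-time truth, not against a rerun
of the pipeline.  Intergenic SNPs are placed in gaps whose two flanking
genes are known, and both flanks enter the expected gene sets — the
flanking-rule side effect is part of the truth, not noise.

Defaults are fixed at roughly one tenth of the real catalog snapshot the
method was designed for: a 410-gene pool, per-phenotype list sizes
9/10/14/22/14/11 (BP/CAD/T2D/Obesity/Lipids/CKD), ancestry mix 76% European
/ 5% African / 19% other, and a 44% intergenic SNP fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .catalog_io import write_catalog  # noqa: F401  (CLI convenience re-export)
from .config import DEFAULT_DIALECT, PHENOTYPES
from .gene_mapping import GeneModel

DEFAULT_GENES_PER_PHENOTYPE = {
    "BP": 9,
    "CAD": 10,
    "T2D": 14,
    "Obesity": 22,
    "Lipids": 14,
    "CKD": 11,
}

DEFAULT_ANCESTRY_MIX = {"european": 0.76, "african": 0.05, "other_mixed": 0.19}

_ANCESTRY_TEXT = {
    "european": "up to 4,000 European ancestry individuals",
    "african": "1,200 African American individuals",
    "other_mixed": "2,100 Han Chinese and European individuals",
}

_TRAIT_TEXT = {
    "BP": "Systolic blood pressure",
    "CAD": "Coronary heart disease",
    "T2D": "Type 2 diabetes",
    "Obesity": "Body mass index",
    "Lipids": "LDL cholesterol",
    "CKD": "Glomerular filtration rate (creatinine)",
}


@dataclass
class SimulationConfig:
    n_genes: int = 410
    genes_per_phenotype: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENES_PER_PHENOTYPE)
    )
    #: (gene symbol, phenotype combination) pairs to plant; symbols may name
    #: annotation genes or use the generator's G#### naming.
    planted_pleiotropy: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    ancestry_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ANCESTRY_MIX))
    intergenic_fraction: float = 0.44
    #: log-uniform sampling range for signal p-values; straddles 1e-7 so the
    #: stringent rerun prunes some signals.
    p_value_range: tuple[float, float] = (1e-12, 1e-6)
    studies_per_phenotype: int = 3
    n_chromosomes: int = 4
    mhc_block: int = 5
    #: number of deliberately overlapping gene pairs (within-rule edge case)
    overlapping_pairs: int = 0
    include_decoys: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 <= self.intergenic_fraction <= 1.0:
            raise ValueError("intergenic_fraction must lie in [0, 1]")
        if sum(self.genes_per_phenotype.values()) > self.n_genes:
            raise ValueError("per-phenotype list sizes exceed n_genes")


@dataclass
class GroundTruth:
    """Construction-time truth for one simulated catalog."""

    #: phenotype combination -> genes planted across exactly that combination
    planted: dict[tuple[str, ...], set[str]]
    #: phenotype -> full expected positional gene set after all filters
    #: (includes flanking-rule side-effect genes)
    expected_gene_sets: dict[str, set[str]]
    #: study_id -> machine-readable exclusion reason
    expected_excluded_studies: dict[str, str]
    #: associations emitted above the p threshold (to be filtered out)
    expected_excluded_association_count: int
    #: genes excluded by the MHC filter
    expected_mhc_excluded: set[str]

    @property
    def expected_list_sizes(self) -> dict[str, int]:
        return {p: len(g) for p, g in self.expected_gene_sets.items()}

    def expected_overlap_combinations(self) -> set[tuple[str, ...]]:
        """Every phenotype combination (size >= 2) with a non-empty expected
        intersection, derived from the expected gene sets."""
        from itertools import combinations

        labels = [p for p in PHENOTYPES if p in self.expected_gene_sets]
        out = set()
        for k in range(2, len(labels) + 1):
            for combo in combinations(labels, k):
                if set.intersection(*(self.expected_gene_sets[p] for p in combo)):
                    out.add(combo)
        return out

    def to_json(self, path) -> None:
        payload = {
            "planted": {";".join(c): sorted(g) for c, g in self.planted.items()},
            "expected_gene_sets": {p: sorted(g) for p, g in self.expected_gene_sets.items()},
            "expected_excluded_studies": self.expected_excluded_studies,
            "expected_excluded_association_count": self.expected_excluded_association_count,
            "expected_mhc_excluded": sorted(self.expected_mhc_excluded),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# --------------------------------------------------------------------------
# annotation

def simulate_annotation(
    config: SimulationConfig,
) -> tuple[list[GeneModel], tuple[str, int, int]]:
    """Lay out non-overlapping genes plus an MHC-flagged block.

    Regular genes go on chromosomes ``1..n_chromosomes``; the MHC block (if
    any) sits on chromosome 6 and the returned region tuple spans it.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    genes: list[GeneModel] = []
    per_chrom = -(-config.n_genes // config.n_chromosomes)  # ceil
    idx = 0
    for c in range(1, config.n_chromosomes + 1):
        cursor = 10_000
        for _ in range(per_chrom):
            if idx >= config.n_genes:
                break
            length = int(rng.integers(5_000, 20_000))
            gap = int(rng.integers(5_000, 50_000))
            start = cursor
            end = start + length
            genes.append(GeneModel(f"G{idx:04d}", str(c), start, end))
            if idx < config.overlapping_pairs:
                # partner gene straddling the first one's right half
                mid = start + length // 2
                genes.append(GeneModel(f"G{idx:04d}ov", str(c), mid, end + 2_000))
                end += 2_000
            cursor = end + gap
            idx += 1
    mhc_region = ("6", 0, 0)
    if config.mhc_block > 0:
        cursor = 1_000_000
        first = cursor
        for j in range(config.mhc_block):
            length = int(rng.integers(3_000, 8_000))
            genes.append(
                GeneModel(f"HLA_SYN{j}", "6", cursor, cursor + length, mhc_flag=True)
            )
            cursor += length + 2_000
        mhc_region = ("6", first, cursor)
    return genes, mhc_region


def write_annotation_bed(genes: list[GeneModel], path) -> None:
    """Serialize gene models as 4-column BED (back to 0-based half-open)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.symbol}\n")


# --------------------------------------------------------------------------
# catalog

def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def simulate_catalog(
    config: SimulationConfig, genes: list[GeneModel]
) -> tuple[pd.DataFrame, GroundTruth]:
    """Emit a catalog table (TSV dialect) and its ground truth.

    Per phenotype, ``genes_per_phenotype`` *target* genes receive one SNP
    each, distributed round-robin over that phenotype's studies.  Fill genes
    are allocated disjointly across phenotypes, so with no planted
    pleiotropy and ``intergenic_fraction = 0`` the expected overlap set is
    empty (negative control).  Planted genes receive one SNP per phenotype
    of their combination.  Decoy studies violating each inclusion rule, an
    above-threshold association, an MHC-gene association and an unmatched
    trait are appended when ``include_decoys`` is set.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    by_symbol = {g.symbol: g for g in genes}
    regular = [g for g in genes if not g.mhc_flag]
    order = {g.symbol: i for i, g in enumerate(genes)}

    planted_by_phen: dict[str, list[str]] = {p: [] for p in PHENOTYPES}
    planted: dict[tuple[str, ...], set[str]] = {}
    for sym, combo in config.planted_pleiotropy:
        if sym not in by_symbol:
            raise ValueError(f"planted gene {sym!r} absent from annotation")
        combo = tuple(combo)
        planted.setdefault(combo, set()).add(sym)
        for p in combo:
            planted_by_phen[p].append(sym)

    planted_syms = {s for syms in planted_by_phen.values() for s in syms}
    fill_pool = [g.symbol for g in regular if g.symbol not in planted_syms]
    rng.shuffle(fill_pool)

    # target genes per phenotype: planted first, disjoint fills after
    targets: dict[str, list[str]] = {}
    cursor = 0
    for p in PHENOTYPES:
        want = config.genes_per_phenotype.get(p, 0)
        fills = max(0, want - len(planted_by_phen[p]))
        targets[p] = planted_by_phen[p] + fill_pool[cursor : cursor + fills]
        cursor += fills

    anc_labels = list(config.ancestry_mix)
    anc_probs = np.array([config.ancestry_mix[a] for a in anc_labels], dtype=float)
    anc_probs /= anc_probs.sum()

    rows: list[dict] = []
    expected_sets: dict[str, set[str]] = {p: set() for p in PHENOTYPES}
    snp_counter = 1
    study_counter = 1

    def _emit(study_id, trait, phen, gene_sym, ancestry, p_value, platform, design):
        nonlocal snp_counter
        g = by_symbol[gene_sym]
        intergenic = rng.random() < config.intergenic_fraction
        mapped = {gene_sym}
        if intergenic:
            # place the SNP in the gap right of the gene; right flank is the
            # next gene on the chromosome, if any — a documented side effect
            same_chrom = [x for x in genes if x.chrom == g.chrom]
            nxt = min(
                (x for x in same_chrom if x.start > g.end),
                key=lambda x: x.start,
                default=None,
            )
            hi = nxt.start - 1 if nxt is not None else g.end + 10_000
            pos = int(rng.integers(g.end + 1, max(g.end + 2, hi)))
            if nxt is not None:
                mapped.add(nxt.symbol)
        else:
            pos = int(rng.integers(g.start, g.end + 1))
        rows.append(
            {
                "study_id": study_id,
                "trait": trait,
                "snp_id": f"rs{snp_counter:06d}",
                "chrom": g.chrom,
                "pos": pos,
                "p_value": p_value,
                "reported_genes": gene_sym,
                "ancestry": ancestry,
                "platform": platform,
                "design": design,
            }
        )
        snp_counter += 1
        return mapped

    lo, hi = config.p_value_range
    for p in PHENOTYPES:
        n_studies = config.studies_per_phenotype
        studies = []
        for _ in range(n_studies):
            anc = anc_labels[int(rng.choice(len(anc_labels), p=anc_probs))]
            studies.append(
                {
                    "id": f"9{study_counter:06d}",
                    "ancestry": _ANCESTRY_TEXT[anc],
                    "platform": f"Illumina [{int(rng.integers(300_000, 1_000_001)):,}]",
                    "design": "meta_analysis" if rng.random() < 0.2 else "standard_gwas",
                }
            )
            study_counter += 1
        for i, sym in enumerate(targets[p]):
            st = studies[i % n_studies]
            mapped = _emit(
                st["id"],
                _TRAIT_TEXT[p],
                p,
                sym,
                st["ancestry"],
                _log_uniform(rng, lo, hi),
                st["platform"],
                st["design"],
            )
            expected_sets[p] |= mapped

    truth_excluded: dict[str, str] = {}
    n_excluded_assoc = 0
    mhc_excluded: set[str] = set()
    if config.include_decoys:
        decoys = [
            ("family_based", f"Illumina [{500_000:,}]", "family_based"),
            ("cnv", f"Affymetrix [{600_000:,}]", "cnv"),
            ("too_few_snps", "Affymetrix [90,000]", "standard_gwas"),
        ]
        decoy_gene = regular[-1].symbol
        for reason, platform, design in decoys:
            sid = f"9{study_counter:06d}"
            study_counter += 1
            _emit(
                sid,
                _TRAIT_TEXT["CAD"],
                "CAD",
                decoy_gene,
                _ANCESTRY_TEXT["european"],
                _log_uniform(rng, lo, hi),
                platform,
                design,
            )
            truth_excluded[sid] = reason
        # above-threshold association inside an otherwise kept study
        weak_sid = f"9{study_counter:06d}"
        study_counter += 1
        _emit(
            weak_sid,
            _TRAIT_TEXT["Lipids"],
            "Lipids",
            regular[-2].symbol,
            _ANCESTRY_TEXT["european"],
            _log_uniform(rng, 1.1e-5, 1e-4),
            f"Illumina [{550_000:,}]",
            "standard_gwas",
        )
        n_excluded_assoc += 1
        # MHC-gene association: mapped gene must be filtered out
        mhc_genes = [g for g in genes if g.mhc_flag]
        if mhc_genes:
            sid = f"9{study_counter:06d}"
            study_counter += 1
            rows.append(
                {
                    "study_id": sid,
                    "trait": _TRAIT_TEXT["BP"],
                    "snp_id": f"rs{snp_counter:06d}",
                    "chrom": mhc_genes[0].chrom,
                    "pos": mhc_genes[0].start + 10,
                    "p_value": _log_uniform(rng, lo, hi),
                    "reported_genes": mhc_genes[0].symbol,
                    "ancestry": _ANCESTRY_TEXT["european"],
                    "platform": f"Illumina [{620_000:,}]",
                    "design": "standard_gwas",
                }
            )
            snp_counter += 1
            mhc_excluded.add(mhc_genes[0].symbol)
        # trait matching no phenotype keyword
        sid = f"9{study_counter:06d}"
        study_counter += 1
        rows.append(
            {
                "study_id": sid,
                "trait": "Height",
                "snp_id": f"rs{snp_counter:06d}",
                "chrom": regular[0].chrom,
                "pos": regular[0].start + 1,
                "p_value": _log_uniform(rng, lo, hi),
                "reported_genes": regular[0].symbol,
                "ancestry": _ANCESTRY_TEXT["european"],
                "platform": f"Illumina [{700_000:,}]",
                "design": "standard_gwas",
            }
        )
        snp_counter += 1

    df = pd.DataFrame(
        {
            DEFAULT_DIALECT["study_id"]: [r["study_id"] for r in rows],
            DEFAULT_DIALECT["trait"]: [r["trait"] for r in rows],
            DEFAULT_DIALECT["snp_id"]: [r["snp_id"] for r in rows],
            DEFAULT_DIALECT["chrom"]: [r["chrom"] for r in rows],
            DEFAULT_DIALECT["pos"]: [str(r["pos"]) for r in rows],
            DEFAULT_DIALECT["p_value"]: [repr(r["p_value"]) for r in rows],
            DEFAULT_DIALECT["reported_genes"]: [r["reported_genes"] for r in rows],
            DEFAULT_DIALECT["ancestry"]: [r["ancestry"] for r in rows],
            DEFAULT_DIALECT["platform"]: [r["platform"] for r in rows],
            DEFAULT_DIALECT["design"]: [r["design"] for r in rows],
        }
    )
    truth = GroundTruth(
        planted=planted,
        expected_gene_sets=expected_sets,
        expected_excluded_studies=truth_excluded,
        expected_excluded_association_count=n_excluded_assoc,
        expected_mhc_excluded=mhc_excluded,
    )
    return df, truth


# --------------------------------------------------------------------------
# null ensemble

def simulate_null_ensemble(
    config: SimulationConfig,
    replicates: int,
    weights: np.ndarray | None = None,
    seed: int | None = None,
) -> Iterator[dict[str, list[str]]]:
    """Stream of gene-list draws with no planted pleiotropy.

    Each replicate draws, for every phenotype in ``genes_per_phenotype``, an
    independent sample without replacement from the ``n_genes`` pool —
    uniformly, or weight-proportionally when ``weights`` is given.  Any
    overlap between the lists is pure chance, which is what calibration
    studies need.  Reproducible for a fixed seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    from .significance import weighted_sample_memberships

    rng = np.random.default_rng(config.seed if seed is None else seed)
    pool = [f"G{i:04d}" for i in range(config.n_genes)]
    w = np.ones(config.n_genes) if weights is None else np.asarray(weights, dtype=float)
    sizes = config.genes_per_phenotype
    for _ in range(replicates):
        draw: dict[str, list[str]] = {}
        for phen, n in sizes.items():
            mem = weighted_sample_memberships(rng, w, n, 1)[0]
            draw[phen] = [pool[i] for i in np.flatnonzero(mem)]
        yield draw
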