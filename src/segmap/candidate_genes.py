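"""Three-stage candidate-gene triage for a fine-mapped region.

Stage 1 drops genes whose annotation consists only of hypothetical
descriptors.  Stage 2 keeps genes carrying at least one qualifying sequence
variant (upstream/exonic InDels and exonic nonsynonymous SNPs whose
delta-index exceeds a threshold) and totals the variants.  Stage 3 keeps
genes with a High seed-expression category in the database table; the final
list additionally requires a High assay category.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import InputError
from .intervals import Interval

__all__ = [
    "GeneRecord",
    "FilterReport",
    "flag_hypothetical",
    "classify_variant_region",
    "count_qualifying_variants",
    "run_cascade",
]

EXPRESSION_LEVELS = ("High", "Medium", "Low", "Very low", "no data")

# a clause is "hypothetical" iff it is nothing more than one of these shapes
_HYPOTHETICAL_CLAUSE = re.compile(
    r"^(conserved\s+)?hypothetical\s+(conserved\s+)?(protein|gene)$",
    re.IGNORECASE,
)


def flag_hypothetical(annotation: str | None) -> bool:
    """True iff every semicolon-separated clause is a bare hypothetical
    descriptor; any clause naming a domain, similarity, or function wins."""
    if annotation is None or not annotation.strip():
        return True
    clauses = [c.strip() for c in annotation.split(";") if c.strip()]
    if not clauses:
        return True
    return all(
        _HYPOTHETICAL_CLAUSE.match(re.sub(r"\s+", " ", c)) is not None
        for c in clauses
    )


@dataclass
class GeneRecord:
    gene_id: str
    annotation: str
    indels: int = 0
    snps: int = 0
    expr_db: str = "no data"
    expr_assay: str | None = None
    span: Interval | None = None
    strand: str = "+"

    def __post_init__(self):
        if self.indels < 0 or self.snps < 0:
            raise InputError(f"{self.gene_id}: negative variant count")
        if self.expr_db not in EXPRESSION_LEVELS:
            raise InputError(f"{self.gene_id}: unknown expression level {self.expr_db!r}")
        if self.expr_assay is not None and self.expr_assay not in EXPRESSION_LEVELS:
            raise InputError(
                f"{self.gene_id}: unknown assay expression level {self.expr_assay!r}"
            )

    @property
    def hypothetical(self) -> bool:
        return flag_hypothetical(self.annotation)

    @property
    def n_variants(self) -> int:
        return self.indels + self.snps


@dataclass
class FilterReport:
    n_region: int
    n_hypothetical: int
    n_annotated: int
    n_variant_genes: int
    n_variations: int
    high_db_genes: list[str]
    final_candidates: list[str]
    stage1_ids: list[str] = field(default_factory=list)
    stage2_ids: list[str] = field(default_factory=list)


def classify_variant_region(
    position: int,
    gene_span: Interval,
    exon_spans: list[Interval],
    upstream_length: int = 2000,
    strand: str = "+",
) -> str:
    """Classify a variant as 'upstream', 'exonic', or 'other' for one gene."""
    if strand not in {"+", "-"}:
        raise InputError(f"bad strand {strand!r}")
    for ex in exon_spans:
        if not gene_span.contains_interval(ex):
            raise InputError(f"exon {ex} outside gene span {gene_span}")
        if ex.contains(position):
            return "exonic"
    if strand == "+":
        if gene_span.start - upstream_length <= position < gene_span.start:
            return "upstream"
    else:
        if gene_span.end < position <= gene_span.end + upstream_length:
            return "upstream"
    return "other"


def count_qualifying_variants(
    variants: pd.DataFrame, delta_threshold: float = 0.8
) -> pd.DataFrame:
    """Per-gene qualifying InDel and nonsynonymous-SNP counts.

    ``variants`` columns: gene_id, variant_class (SNP/InDel), region
    (upstream/exonic/other), nonsynonymous (bool, SNPs only), delta.
    A variant qualifies iff delta > delta_threshold (strict) and, for InDels,
    region is upstream or exonic; for SNPs, region is exonic and the change
    is nonsynonymous.
    """
    df = variants.copy()
    df["qualifies"] = df["delta"] > delta_threshold
    is_indel = df["variant_class"].str.lower() == "indel"
    indel_ok = df["qualifies"] & is_indel & df["region"].isin(["upstream", "exonic"])
    snp_ok = (
        df["qualifies"]
        & ~is_indel
        & (df["region"] == "exonic")
        & df.get("nonsynonymous", pd.Series(True, index=df.index)).astype(bool)
    )
    out = pd.DataFrame(
        {
            "indels": indel_ok.groupby(df["gene_id"]).sum(),
            "snps": snp_ok.groupby(df["gene_id"]).sum(),
        }
    ).astype(int)
    out.index.name = "gene_id"
    return out.reset_index()


def run_cascade(
    genes: list[GeneRecord],
    delta_threshold: float = 0.8,
    variants: pd.DataFrame | None = None,
) -> FilterReport:
    """Annotation filter -> variant filter -> expression filter.

    When a per-variant table is supplied, per-gene counts are recomputed at
    ``delta_threshold``; otherwise the counts stored on the records (already
    thresholded upstream) are used.
    """
    if not genes:
        raise InputError("gene list is empty")

    if variants is not None:
        counts = count_qualifying_variants(variants, delta_threshold)
        lookup = counts.set_index("gene_id")
        genes = [
            GeneRecord(
                gene_id=g.gene_id,
                annotation=g.annotation,
                indels=int(lookup["indels"].get(g.gene_id, 0)),
                snps=int(lookup["snps"].get(g.gene_id, 0)),
                expr_db=g.expr_db,
                expr_assay=g.expr_assay,
                span=g.span,
                strand=g.strand,
            )
            for g in genes
        ]

    stage1 = [g for g in genes if not g.hypothetical]
    stage2 = [g for g in stage1 if g.n_variants > 0]
    n_variations = sum(g.n_variants for g in stage2)
    stage3 = [g for g in stage2 if g.expr_db == "High"]
    final = [g for g in stage3 if g.expr_assay is None or g.expr_assay == "High"]
    return FilterReport(
        n_region=len(genes),
        n_hypothetical=len(genes) - len(stage1),
        n_annotated=len(stage1),
        n_variant_genes=len(stage2),
        n_variations=n_variations,
        high_db_genes=[g.gene_id for g in stage3],
        final_candidates=[g.gene_id for g in final],
        stage1_ids=[g.gene_id for g in stage1],
        stage2_ids=[g.gene_id for g in stage2],
    )
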