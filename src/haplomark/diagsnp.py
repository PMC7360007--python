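"""Discovery of single SNPs diagnostic of one haplotype group.

A strict diagnostic candidate carries an allele that is fixed in the target
group and absent from every other group, whose members in turn share a
single fixed background allele ("private and invariant").  The search
covers the gene interval first, then a flanking window on either side.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .model import HET, MISSING, GenotypeMatrix, PanelError, VariantSite
from .hapgroup import HaplotypeClassification


@dataclass(frozen=True)
class GeneInterval:
    """1-based inclusive gene span on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise PanelError(f"invalid gene interval {self.chrom}:{self.start}-{self.end}")


@dataclass(frozen=True)
class DiagnosticCandidate:
    site: VariantSite
    target_group: int
    target_allele: str
    background_allele: str
    distance_to_gene: int
    purity: float
    background_purity: float
    strict: bool
    provenance: str  # "in" (gene-internal) or "flank"


def gene_distance(site: VariantSite, gene: GeneInterval) -> int:
    """Distance in bp from the nearest gene boundary; 0 inside the gene."""
    if site.chrom != gene.chrom:
        raise PanelError(
            f"site {site.id} and gene interval {gene.chrom} are on different chromosomes"
        )
    if gene.start <= site.pos <= gene.end:
        return 0
    return gene.start - site.pos if site.pos < gene.start else site.pos - gene.end


def find_diagnostic(
    matrix: GenotypeMatrix,
    classification: HaplotypeClassification,
    target_group: int,
    gene: GeneInterval,
    flank_bp: int = 10_000,
    min_purity: float = 1.0,
    include_rare: bool = False,
) -> list:
    """Rank candidate sites diagnostic of ``target_group``.

    Background samples are the members of all other groups; rare and
    unclassified samples join the background only when ``include_rare``.
    Strict candidates (purity and background purity both 1, single allele
    each side) rank first, by proximity to the gene, then position.
    """
    if flank_bp < 0:
        raise PanelError("flank_bp must be >= 0")
    target = classification.group(target_group)
    if not target.members:
        raise PanelError(f"target group {target_group} has no members")
    background_samples = [
        s for g in classification.groups if g.group_id != target_group for s in g.members
    ]
    if include_rare:
        background_samples += list(classification.rare) + list(classification.unclassified)
    if not background_samples:
        raise PanelError("no background samples to compare against")

    t_idx = [matrix.sample_index(s) for s in target.members]
    b_idx = [matrix.sample_index(s) for s in background_samples]

    candidates = []
    for j, site in enumerate(matrix.sites):
        if site.chrom != gene.chrom:
            continue
        distance = gene_distance(site, gene)
        if distance > flank_bp:
            continue
        t_col = matrix.calls[t_idx, j]
        b_col = matrix.calls[b_idx, j]
        t_valid = t_col[(t_col != MISSING) & (t_col != HET)]
        b_valid = b_col[(b_col != MISSING) & (b_col != HET)]
        if t_valid.size == 0 or b_valid.size == 0:
            continue
        t_alleles, t_counts = np.unique(t_valid, return_counts=True)
        b_alleles, b_counts = np.unique(b_valid, return_counts=True)
        target_allele = str(t_alleles[np.argmax(t_counts)])
        background_allele = str(b_alleles[np.argmax(b_counts)])
        if target_allele == background_allele:
            continue
        purity = float(t_counts.max() / t_valid.size)
        background_purity = float(b_counts.max() / b_valid.size)
        if purity < min_purity or background_purity < min_purity:
            continue
        if target_allele in b_alleles:
            continue  # target allele leaks into the background: not private
        strict = (
            purity == 1.0
            and background_purity == 1.0
            and len(t_alleles) == 1
            and len(b_alleles) == 1
        )
        candidates.append(
            DiagnosticCandidate(
                site=site,
                target_group=target_group,
                target_allele=target_allele,
                background_allele=background_allele,
                distance_to_gene=distance,
                purity=purity,
                background_purity=background_purity,
                strict=strict,
                provenance="in" if distance == 0 else "flank",
            )
        )
    candidates.sort(key=lambda c: (not c.strict, c.distance_to_gene, c.site.pos))
    return candidates
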