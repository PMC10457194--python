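"""Peak-to-gene annotation with promoter/exon/intron/intergenic feature classes.

Follows the HOMER-style convention used for NF-kB binding-site annotation:
peaks are classified by their summit with priority
promoter > exon > intron > intergenic, the promoter window defaults to
-1 kb..+100 bp around the TSS in gene orientation, and every peak is assigned
to the gene whose TSS is nearest to the summit (unbounded by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneRecord",
    "GenomeAnnotation",
    "AnnotatedPeak",
    "AnnotationParams",
    "annotate_peak",
    "peaks_to_genes",
    "union_gene_lists",
]


@dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    tss_bp: int
    tes_bp: int
    exons: list[tuple[int, int]]  # genomic half-open intervals, sorted

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.strand == "+" and self.tss_bp >= self.tes_bp:
            raise ValueError(f"{self.gene_id}: + strand requires tss < tes")
        if self.strand == "-" and self.tss_bp <= self.tes_bp:
            raise ValueError(f"{self.gene_id}: - strand requires tss > tes")

    @property
    def span(self) -> tuple[int, int]:
        """Genomic half-open span of the gene body."""
        lo = min(self.tss_bp, self.tes_bp)
        hi = max(self.tss_bp, self.tes_bp)
        return lo, hi + 1

    def tss_distance(self, pos: int) -> int:
        """Signed distance of ``pos`` from the TSS in gene orientation.

        Negative = upstream of the TSS.
        """
        return pos - self.tss_bp if self.strand == "+" else self.tss_bp - pos


@dataclass
class GenomeAnnotation:
    chromosomes: dict[str, int]
    genes: list[GeneRecord]
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        seen = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene id {g.gene_id}")
            seen.add(g.gene_id)
            if g.chrom not in self.chromosomes:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            lo, hi = g.span
            if lo < 0 or hi > self.chromosomes[g.chrom]:
                raise ValueError(f"{g.gene_id} outside chromosome bounds")
        self._build_index()

    def _build_index(self) -> None:
        by_chrom: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        self._index = {}
        for chrom, genes in by_chrom.items():
            # sort by (tss, gene_id) so equidistant ties resolve to the
            # lexicographically smaller id deterministically
            genes = sorted(genes, key=lambda g: (g.tss_bp, g.gene_id))
            self._index[chrom] = (np.array([g.tss_bp for g in genes]), genes)

    def nearest_tss_gene(self, chrom: str, pos: int) -> GeneRecord | None:
        entry = self._index.get(chrom)
        if entry is None:
            return None
        tss, genes = entry
        i = int(np.searchsorted(tss, pos))
        best, best_d = None, None
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(genes):
                d = abs(pos - int(tss[j]))
                if best is None or d < best_d or (d == best_d and genes[j].gene_id < best.gene_id):
                    best, best_d = genes[j], d
        return best

    def genes_on(self, chrom: str) -> list[GeneRecord]:
        entry = self._index.get(chrom)
        return entry[1] if entry else []


@dataclass
class AnnotationParams:
    promoter_upstream_bp: int = 1000
    promoter_downstream_bp: int = 100
    max_tss_distance: float = float("inf")


@dataclass
class AnnotatedPeak:
    peak: object  # Peak
    feature: str  # promoter | exon | intron | intergenic
    assigned_gene_id: str | None
    distance_to_tss_bp: int | None


def annotate_peak(peak, genome: GenomeAnnotation, params: AnnotationParams | None = None) -> AnnotatedPeak:
    """Classify one peak by its summit and assign the nearest-TSS gene."""
    params = params or AnnotationParams()
    if peak.chrom not in genome.chromosomes:
        raise ValueError(f"unknown chromosome {peak.chrom}")
    summit = peak.summit_bp

    promoter_gene = None
    for g in genome.genes_on(peak.chrom):
        d = g.tss_distance(summit)
        if -params.promoter_upstream_bp <= d <= params.promoter_downstream_bp:
            if promoter_gene is None or abs(d) < abs(promoter_gene.tss_distance(summit)) or (
                abs(d) == abs(promoter_gene.tss_distance(summit)) and g.gene_id < promoter_gene.gene_id
            ):
                promoter_gene = g
    if promoter_gene is not None:
        return AnnotatedPeak(peak, "promoter", promoter_gene.gene_id,
                             promoter_gene.tss_distance(summit))

    host = None
    for g in genome.genes_on(peak.chrom):
        lo, hi = g.span
        if lo <= summit < hi:
            if host is None or abs(g.tss_distance(summit)) < abs(host.tss_distance(summit)) or (
                abs(g.tss_distance(summit)) == abs(host.tss_distance(summit)) and g.gene_id < host.gene_id
            ):
                host = g
    if host is not None:
        in_exon = any(s <= summit < e for s, e in host.exons)
        return AnnotatedPeak(peak, "exon" if in_exon else "intron",
                             host.gene_id, host.tss_distance(summit))

    g = genome.nearest_tss_gene(peak.chrom, summit)
    if g is not None and abs(g.tss_distance(summit)) <= params.max_tss_distance:
        return AnnotatedPeak(peak, "intergenic", g.gene_id, g.tss_distance(summit))
    return AnnotatedPeak(peak, "intergenic", None, None)


def peaks_to_genes(peaks, genome: GenomeAnnotation, params: AnnotationParams | None = None) -> dict[str, list[AnnotatedPeak]]:
    """Map a PeakSet to genes; keys are assigned gene ids, values the peaks.

    The gene *set* of the call is ``set(result)``; multiplicity is the list
    length per gene.
    """
    out: dict[str, list[AnnotatedPeak]] = {}
    for p in peaks:
        ap = annotate_peak(p, genome, params)
        if ap.assigned_gene_id is not None:
            out.setdefault(ap.assigned_gene_id, []).append(ap)
    return out


def union_gene_lists(rep1: set, rep2: set) -> set:
    """Combine two annotated gene lists (set union)."""
    return set(rep1) | set(rep2)
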