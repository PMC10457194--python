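"""Readers and writers for the package's plain-text interchange formats.

BED6 tag files (0-based half-open, strand in column 6), GTF gene models
(1-based, ``gene_id`` attribute required), TSV count/metadata/truth tables
and YAML configs.  ``write_fixture``/``read_fixture`` round-trip a full
:class:`~kappacascade.simdata.SimulatedDataset` losslessly.
"""

from __future__ import annotations

import re
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotate import GeneRecord, GenomeAnnotation
from .diffexpr import CountMatrix, SampleMeta
from .peakcall import PeakSet, TagLibrary
from .simdata import SimConfig, SimTruth, SimulatedDataset

__all__ = [
    "write_tags_bed", "read_tags_bed",
    "write_gtf", "read_gtf",
    "write_counts", "read_counts",
    "write_peaks_bed",
    "write_fixture", "read_fixture",
]


def write_tags_bed(lib: TagLibrary, path) -> None:
    path = Path(path)
    try:
        with path.open("w") as fh:
            for chrom in sorted(lib.positions):
                for strand in ("+", "-"):
                    for p in lib.positions[chrom][strand]:
                        fh.write(f"{chrom}\t{p}\t{p + 1}\ttag\t0\t{strand}\n")
    except OSError as e:
        raise OSError(f"failed writing tag BED {path}: {e}") from e


def read_tags_bed(path, chrom_lengths: dict[str, int], *, sample_id: str,
                  assay: str, factor: str | None, time_h: int, replicate: int) -> TagLibrary:
    path = Path(path)
    tab = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand"],
                      dtype={"chrom": str, "start": np.int64, "strand": str})
    positions: dict[str, dict[str, np.ndarray]] = {
        c: {"+": np.empty(0, dtype=np.int64), "-": np.empty(0, dtype=np.int64)}
        for c in chrom_lengths
    }
    for (chrom, strand), grp in tab.groupby(["chrom", "strand"]):
        positions.setdefault(chrom, {"+": np.empty(0, dtype=np.int64),
                                     "-": np.empty(0, dtype=np.int64)})
        positions[chrom][strand] = np.sort(grp.start.values.astype(np.int64))
    return TagLibrary(sample_id=sample_id, assay=assay, factor=factor,
                      time_h=time_h, replicate=replicate,
                      chrom_lengths=chrom_lengths, positions=positions)


def write_gtf(genome: GenomeAnnotation, path) -> None:
    with Path(path).open("w") as fh:
        for g in genome.genes:
            lo, hi = g.span
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(f"{g.chrom}\tkappacascade\tgene\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t{attrs}\n")
            for s, e in g.exons:
                fh.write(f"{g.chrom}\tkappacascade\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")


_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')


def read_gtf(path, chrom_lengths: dict[str, int]) -> GenomeAnnotation:
    tab = pd.read_csv(Path(path), sep="\t", header=None, comment="#",
                      names=["chrom", "source", "feature", "start", "end",
                             "score", "strand", "frame", "attrs"],
                      dtype={"chrom": str})
    genes: dict[str, dict] = {}
    for row in tab.itertuples():
        m = _GENE_ID_RE.search(row.attrs)
        if not m:
            raise ValueError(f"GTF record lacks gene_id attribute: {row}")
        gid = m.group(1)
        rec = genes.setdefault(gid, {"chrom": row.chrom, "strand": row.strand,
                                     "span": None, "exons": []})
        if row.feature == "gene":
            rec["span"] = (row.start - 1, row.end)
        elif row.feature == "exon":
            rec["exons"].append((row.start - 1, row.end))
    out = []
    for gid, rec in genes.items():
        lo, hi = rec["span"]
        if rec["strand"] == "+":
            tss, tes = lo, hi - 1
        else:
            tss, tes = hi - 1, lo
        out.append(GeneRecord(gene_id=gid, chrom=rec["chrom"], strand=rec["strand"],
                              tss_bp=tss, tes_bp=tes, exons=sorted(rec["exons"])))
    return GenomeAnnotation(chrom_lengths, out)


def write_counts(cm: CountMatrix, counts_path, meta_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene")
    pd.DataFrame([asdict(s) if hasattr(s, "__dataclass_fields__") else vars(s)
                  for s in cm.samples]).to_csv(meta_path, sep="\t", index=False)


def read_counts(counts_path, meta_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
    meta = pd.read_csv(meta_path, sep="\t")
    samples = [SampleMeta(sample_id=str(r.sample_id), genotype=r.genotype,
                          treatment=r.treatment, time_h=int(r.time_h),
                          replicate=int(r.replicate), assay=r.assay)
               for r in meta.itertuples()]
    return CountMatrix(counts.astype(np.int64), samples)


def write_peaks_bed(ps: PeakSet, path) -> None:
    """BED6+4: name=peak id, score=tag count, then fold, p, q columns."""
    with Path(path).open("w") as fh:
        for i, p in enumerate(ps):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t{p.tag_count}\t.\t"
                     f"{p.fold_enrichment:.6g}\t{p.pvalue:.6g}\t{p.qvalue:.6g}\t{p.summit_bp}\n")


def write_fixture(ds: SimulatedDataset, outdir) -> Path:
    """Write a dataset as BED/GTF/TSV/YAML files; round-trips losslessly."""
    outdir = Path(outdir)
    (outdir / "tags").mkdir(parents=True, exist_ok=True)
    cfg = ds.config
    with (outdir / "config.yaml").open("w") as fh:
        yaml.safe_dump(_config_to_dict(cfg), fh)
    write_gtf(ds.genome, outdir / "genes.gtf")
    for lib in ds.tags:
        write_tags_bed(lib, outdir / "tags" / f"{lib.sample_id}.bed")
    pd.DataFrame([
        {"sample_id": lib.sample_id, "assay": lib.assay, "factor": lib.factor or "",
         "time_h": lib.time_h, "replicate": lib.replicate}
        for lib in ds.tags
    ]).to_csv(outdir / "tag_samples.tsv", sep="\t", index=False)
    write_counts(ds.counts, outdir / "counts.tsv", outdir / "samples.tsv")
    st = ds.truth.site_table.copy()
    st.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    gt = ds.truth.gene_table.copy()
    gt["linked_sites"] = gt.linked_sites.map(lambda v: ",".join(v))
    gt.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    return outdir


def _config_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["site_location_mix"] = list(cfg.site_location_mix)
    d["chip_panel"] = [list(x) for x in cfg.chip_panel]
    d["atac_times"] = list(cfg.atac_times)
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "site_location_mix" in d:
        d["site_location_mix"] = tuple(d["site_location_mix"])
    if "chip_panel" in d:
        d["chip_panel"] = tuple((f, int(t)) for f, t in d["chip_panel"])
    if "atac_times" in d:
        d["atac_times"] = tuple(int(t) for t in d["atac_times"])
    return SimConfig(**d)


def read_fixture(indir) -> SimulatedDataset:
    indir = Path(indir)
    with (indir / "config.yaml").open() as fh:
        cfg = config_from_dict(yaml.safe_load(fh))
    genome = read_gtf(indir / "genes.gtf", cfg.chrom_lengths)
    tag_meta = pd.read_csv(indir / "tag_samples.tsv", sep="\t",
                           keep_default_na=False)
    tags = []
    for r in tag_meta.itertuples():
        tags.append(read_tags_bed(
            indir / "tags" / f"{r.sample_id}.bed", cfg.chrom_lengths,
            sample_id=str(r.sample_id), assay=r.assay,
            factor=r.factor or None, time_h=int(r.time_h), replicate=int(r.replicate)))
    counts = read_counts(indir / "counts.tsv", indir / "samples.tsv")
    st = pd.read_csv(indir / "truth_sites.tsv", sep="\t")
    gt = pd.read_csv(indir / "truth_genes.tsv", sep="\t", keep_default_na=False)
    gt["linked_sites"] = gt.linked_sites.map(lambda v: v.split(",") if v else [])
    truth = SimTruth(site_table=st, gene_table=gt)
    return SimulatedDataset(config=cfg, genome=genome, truth=truth,
                            tags=tags, counts=counts)
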