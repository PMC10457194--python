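"""Strand-aware sliding-window ChIP/ATAC peak calling.

The caller reproduces a CisGenome-style window scan: a ``window_bp`` window
slides along each chromosome at ``step_bp``; a window is a *candidate* when it
holds at least ``min_reads`` tag 5' positions with at least
``min_reads_per_strand`` on each strand (the strand rule is skipped for ATAC
libraries, which have no binding-site strand geometry).  Candidate windows are
tested against a Poisson background whose rate is the maximum of the global
tag density and the depth-scaled matched-input count in the same window;
Benjamini-Hochberg q-values are computed across candidates, windows with
q <= fdr_max and input fold-enrichment >= min_fold_vs_input survive, and
surviving windows closer than ``merge_gap_bp`` are merged into peaks.  A final
factor-specific fold filter (10x for RelA, 5x for Rel in the defaults used
downstream) is applied on merged peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TagLibrary",
    "PeakCallParams",
    "Peak",
    "PeakSet",
    "call_peaks",
    "intersect_replicates",
    "overlap_fraction",
]


@dataclass
class TagLibrary:
    """Strand-split read 5'-position collections for one sequencing sample.

    ``positions[chrom][strand]`` holds a sorted int64 array of 0-based 5'
    coordinates; ``strand`` is "+" or "-".
    """

    sample_id: str
    assay: str  # chip | input | atac
    factor: str | None
    time_h: float
    replicate: int
    chrom_lengths: dict[str, int]
    positions: dict[str, dict[str, np.ndarray]]

    def __post_init__(self) -> None:
        if self.assay not in ("chip", "input", "atac"):
            raise ValueError(f"unknown assay {self.assay!r}")
        for chrom, strands in self.positions.items():
            length = self.chrom_lengths[chrom]
            for s in ("+", "-"):
                arr = np.asarray(strands.get(s, np.empty(0, dtype=np.int64)), dtype=np.int64)
                if arr.size and (arr[0] < 0 or arr[-1] >= length):
                    raise ValueError(f"tag position outside {chrom} (length {length})")
                if arr.size > 1 and np.any(np.diff(arr) < 0):
                    arr = np.sort(arr)
                strands[s] = arr

    @property
    def total_tags(self) -> int:
        return sum(int(a.size) for st in self.positions.values() for a in st.values())

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def counts_in(self, chrom: str, starts: np.ndarray, ends: np.ndarray, strand: str | None = None):
        """Tag counts in half-open windows [start, end) on one chromosome."""
        strands = ("+", "-") if strand is None else (strand,)
        total = np.zeros(len(starts), dtype=np.int64)
        chrom_pos = self.positions.get(chrom, {})
        for s in strands:
            arr = chrom_pos.get(s)
            if arr is None or arr.size == 0:
                continue
            total += np.searchsorted(arr, ends, side="left") - np.searchsorted(arr, starts, side="left")
        return total


@dataclass
class PeakCallParams:
    window_bp: int = 200
    min_reads: int = 4
    min_reads_per_strand: int = 2
    fdr_max: float = 0.1
    min_fold_vs_input: float = 2.0
    merge_gap_bp: int = 200
    factor_fold_filter: float | None = None  # RelA: 10, Rel: 5
    step_bp: int = 25

    # convention used throughout: "more than tenfold/fivefold changed compared
    # to input" is evaluated as fold_enrichment >= threshold on merged peaks
    FACTOR_FOLD: dict = field(default_factory=lambda: {"RelA": 10.0, "Rel": 5.0})

    def __post_init__(self) -> None:
        if self.window_bp < 1 or self.step_bp < 1:
            raise ValueError("window_bp and step_bp must be >= 1")
        if not (0 < self.fdr_max <= 1):
            raise ValueError("fdr_max must be in (0, 1]")

    @classmethod
    def for_factor(cls, factor: str | None, **kw) -> "PeakCallParams":
        p = cls(**kw)
        if factor is not None and p.factor_fold_filter is None:
            p.factor_fold_filter = p.FACTOR_FOLD.get(factor)
        return p


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    summit_bp: int
    tag_count: int
    input_count_scaled: float
    pvalue: float
    qvalue: float

    @property
    def fold_enrichment(self) -> float:
        return (self.tag_count + 1.0) / (self.input_count_scaled + 1.0)

    def overlaps(self, other: "Peak") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class PeakSet:
    peaks: list[Peak]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (p.chrom, p.start, p.end, p.summit_bp, p.tag_count,
             p.input_count_scaled, p.fold_enrichment, p.pvalue, p.qvalue)
            for p in self.peaks
        ]
        return pd.DataFrame(
            rows,
            columns=["chrom", "start", "end", "summit", "tag_count",
                     "input_scaled", "fold_enrichment", "pvalue", "qvalue"],
        )


def _candidate_windows(lib: TagLibrary, input_lib: TagLibrary | None, params: PeakCallParams):
    """Per-chromosome candidate window table (pre-FDR)."""
    genome_len = lib.genome_length
    total = lib.total_tags
    lam_floor = total / genome_len * params.window_bp if genome_len else 0.0
    scale = None
    if input_lib is not None:
        if input_lib.total_tags == 0:
            raise ValueError("input library supplied but has zero tags")
        scale = total / input_lib.total_tags
    recs = []
    for chrom in sorted(lib.chrom_lengths):
        length = lib.chrom_lengths[chrom]
        if length < params.window_bp:
            continue
        starts = np.arange(0, length - params.window_bp + 1, params.step_bp, dtype=np.int64)
        ends = starts + params.window_bp
        plus = lib.counts_in(chrom, starts, ends, "+")
        minus = lib.counts_in(chrom, starts, ends, "-")
        tot = plus + minus
        mask = tot >= params.min_reads
        if lib.assay != "atac":
            mask &= (plus >= params.min_reads_per_strand) & (minus >= params.min_reads_per_strand)
        if input_lib is not None:
            in_scaled = input_lib.counts_in(chrom, starts, ends).astype(float) * scale
        else:
            in_scaled = np.full(len(starts), lam_floor)
        lam = np.maximum(lam_floor, in_scaled)
        # p-values over EVERY scanned window: adjusting candidates only would
        # couple the strand-balance selection with the total-count null and
        # destroy FDR control on pure background
        pval = stats.poisson.sf(tot - 1, lam)
        recs.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "count": tot, "input_scaled": in_scaled, "pvalue": pval,
            "candidate": mask,
        }))
    cols = ["chrom", "start", "end", "count", "input_scaled", "pvalue", "candidate"]
    if not recs:
        return pd.DataFrame(columns=cols)
    return pd.concat(recs, ignore_index=True)


def _merge_windows(win: pd.DataFrame, params: PeakCallParams) -> list[Peak]:
    peaks: list[Peak] = []
    for chrom, grp in win.groupby("chrom", sort=True):
        grp = grp.sort_values("start", kind="mergesort").reset_index(drop=True)
        runs: list[list[int]] = []
        cur: list[int] = []
        cur_end = -1
        for i in range(len(grp)):
            s, e = int(grp.start[i]), int(grp.end[i])
            if cur and s - cur_end >= params.merge_gap_bp:
                runs.append(cur)
                cur = []
            cur.append(i)
            cur_end = max(cur_end, e)
        if cur:
            runs.append(cur)
        for run in runs:
            sub = grp.iloc[run]
            best = int(sub["count"].values.argmax())  # leftmost max
            brow = sub.iloc[best]
            peaks.append(Peak(
                chrom=chrom,
                start=int(sub.start.min()),
                end=int(sub.end.max()),
                summit_bp=int(brow.start) + params.window_bp // 2,
                tag_count=int(brow["count"]),
                input_count_scaled=float(brow.input_scaled),
                pvalue=float(sub.pvalue.min()),
                qvalue=float(sub.qvalue.min()),
            ))
    return peaks


def call_peaks(sample: TagLibrary, input_lib: TagLibrary | None, params: PeakCallParams) -> PeakSet:
    """Call peaks on one tag library; deterministic given inputs.

    Returns an empty :class:`PeakSet` for an empty library.
    """
    if sample.assay == "input":
        raise ValueError("cannot call peaks on an input library")
    prov = {
        "sample": sample.sample_id,
        "input": input_lib.sample_id if input_lib is not None else None,
        "params": vars(params).copy(),
    }
    if sample.total_tags == 0:
        return PeakSet([], prov)
    win = _candidate_windows(sample, input_lib, params)
    if win.empty:
        return PeakSet([], prov)
    # BH across all scanned windows; q propagated as minimum over merged
    # constituents
    win["qvalue"] = multipletests(win.pvalue.values, method="fdr_bh")[1]
    win = win[win.candidate & (win.qvalue <= params.fdr_max)]
    fold = (win["count"] + 1.0) / (win.input_scaled + 1.0)
    win = win[fold >= params.min_fold_vs_input]
    if win.empty:
        return PeakSet([], prov)
    peaks = _merge_windows(win, params)
    if params.factor_fold_filter is not None:
        peaks = [p for p in peaks if p.fold_enrichment >= params.factor_fold_filter]
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return PeakSet(peaks, prov)


def intersect_replicates(a: PeakSet, b: PeakSet) -> PeakSet:
    """Replicate-common peaks: peaks of ``a`` overlapping >= 1 bp a peak of ``b``.

    Each overlapping (a, b) pair is reported as the union interval with the
    pair minimum of tag count and fold enrichment (conservative), then the
    union intervals are re-merged where they overlap.
    """
    b_by_chrom = b.by_chrom()
    merged_rows: list[Peak] = []
    for pa in a:
        for pb in b_by_chrom.get(pa.chrom, []):
            if pa.overlaps(pb):
                lo, hi = (pa, pb) if pa.tag_count <= pb.tag_count else (pb, pa)
                merged_rows.append(Peak(
                    chrom=pa.chrom,
                    start=min(pa.start, pb.start),
                    end=max(pa.end, pb.end),
                    summit_bp=pa.summit_bp,
                    tag_count=lo.tag_count,
                    input_count_scaled=lo.input_count_scaled,
                    pvalue=max(pa.pvalue, pb.pvalue),
                    qvalue=max(pa.qvalue, pb.qvalue),
                ))
    merged_rows.sort(key=lambda p: (p.chrom, p.start))
    out: list[Peak] = []
    for p in merged_rows:
        if out and out[-1].overlaps(p):
            prev = out[-1]
            keep = prev if prev.tag_count >= p.tag_count else p
            out[-1] = Peak(
                chrom=prev.chrom,
                start=min(prev.start, p.start),
                end=max(prev.end, p.end),
                summit_bp=keep.summit_bp,
                tag_count=keep.tag_count,
                input_count_scaled=keep.input_count_scaled,
                pvalue=min(prev.pvalue, p.pvalue),
                qvalue=min(prev.qvalue, p.qvalue),
            )
        else:
            out.append(p)
    prov = {"replicates": [a.provenance, b.provenance]}
    return PeakSet(out, prov)


def overlap_fraction(query: PeakSet, reference: PeakSet) -> float:
    """Fraction of query peaks overlapping (>= 1 bp) any reference peak."""
    if len(query) == 0:
        warnings.warn("overlap_fraction: empty query peak set; returning 0.0")
        return 0.0
    ref_by_chrom = reference.by_chrom()
    hit = 0
    for p in query:
        if any(p.overlaps(r) for r in ref_by_chrom.get(p.chrom, [])):
            hit += 1
    return hit / len(query)
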