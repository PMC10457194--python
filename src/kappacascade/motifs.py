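"""Known-motif scanning and enrichment for peaks and promoter windows.

Position weight matrices are scored as log-odds (bits) against a background
base composition on both strands; a sequence scores a hit when its best
window reaches the motif threshold.  Enrichment of a foreground sequence set
against a background set is a hypergeometric upper tail on
sequences-with-at-least-one-hit, BH-adjusted across motifs.  Built-in PWMs
cover the NF-kB kB consensus (GGGRNNYYCC), the PU.1/Sfpi1 ETS core and an
IRF core, shipped in JASPAR text format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PWM",
    "EnrichmentResult",
    "ScanHit",
    "load_builtin_pwms",
    "load_jaspar",
    "scan",
    "enrich",
    "promoter_window_sequences",
    "shuffle_sequences",
]

_BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class PWM:
    name: str
    matrix: np.ndarray  # 4 x L base probabilities (A, C, G, T rows)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    min_logodds_bits: float = 6.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError("PWM must be 4 x L with L >= 4")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def logodds(self) -> np.ndarray:
        """5 x L log2-odds with an all-zero row for N."""
        with np.errstate(divide="ignore"):
            lo = np.log2(np.maximum(self.matrix, 1e-9) / self.background[:, None])
        return np.vstack([lo, np.zeros(self.length)])

    @property
    def max_score(self) -> float:
        return float(self.logodds()[:4].max(axis=0).sum())


@dataclass
class ScanHit:
    seq_id: str
    hit: bool
    best_score: float
    too_short: bool = False


def _encode(seq: str) -> np.ndarray:
    idx = np.full(len(seq), 4, dtype=np.int8)  # N by default
    s = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    for i, b in enumerate(_BASES):
        idx[s == ord(b)] = i
    return idx


def _best_score(idx: np.ndarray, lo: np.ndarray) -> float:
    L = lo.shape[1]
    n = len(idx) - L + 1
    if n <= 0:
        return -np.inf
    scores = np.zeros(n)
    for j in range(L):
        scores += lo[idx[j:j + n], j]
    return float(scores.max())


def scan(sequences: dict[str, str], pwm: PWM) -> list[ScanHit]:
    """Best log-odds score per sequence over both strands; hit at threshold."""
    lo = pwm.logodds()
    out = []
    for sid, seq in sequences.items():
        if len(seq) < pwm.length:
            out.append(ScanHit(sid, False, -np.inf, too_short=True))
            continue
        fwd = _encode(seq)
        rev = _encode(reverse_complement(seq))
        best = max(_best_score(fwd, lo), _best_score(rev, lo))
        out.append(ScanHit(sid, best >= pwm.min_logodds_bits, best))
    return out


@dataclass
class EnrichmentResult:
    motif: str
    fg_hits: int
    fg_total: int
    bg_hits: int
    bg_total: int
    pvalue: float
    qvalue: float = np.nan


def enrich(fg: dict[str, str], bg: dict[str, str], pwms: list[PWM]) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment of foreground hit counts.

    Universe = fg + bg pooled; draws = |fg|; successes = pooled hits.
    """
    if not pwms:
        return []
    if not fg or not bg:
        raise ValueError("foreground and background must be non-empty")
    if set(fg) & set(bg):
        raise ValueError("foreground and background identifiers overlap")
    results = []
    M = len(fg) + len(bg)
    N = len(fg)
    for pwm in pwms:
        fg_hits = sum(h.hit for h in scan(fg, pwm))
        bg_hits = sum(h.hit for h in scan(bg, pwm))
        K = fg_hits + bg_hits
        p = float(stats.hypergeom.sf(fg_hits - 1, M, K, N))
        results.append(EnrichmentResult(pwm.name, fg_hits, N, bg_hits, len(bg), p))
    qs = multipletests([r.pvalue for r in results], method="fdr_bh")[1]
    for r, q in zip(results, qs):
        r.qvalue = float(q)
    return results


def promoter_window_sequences(genes, sequences: dict[str, str],
                              window: tuple[int, int] = (-400, 100)) -> dict[str, str]:
    """Strand-oriented promoter sequences around each gene's TSS.

    ``window`` is (upstream, downstream) in gene orientation; the default
    -400..+100 yields 500-bp sequences.  Windows running off a chromosome
    end are truncated and flagged by a trailing '*' on the id.
    """
    up, down = window
    out: dict[str, str] = {}
    for g in genes:
        chrom_seq = sequences[g.chrom]
        L = len(chrom_seq)
        if g.strand == "+":
            lo, hi = g.tss_bp + up, g.tss_bp + down
        else:
            lo, hi = g.tss_bp - down + 1, g.tss_bp - up + 1
        truncated = lo < 0 or hi > L
        lo_c, hi_c = max(lo, 0), min(hi, L)
        seq = chrom_seq[lo_c:hi_c]
        if g.strand == "-":
            seq = reverse_complement(seq)
        out[g.gene_id + ("*" if truncated else "")] = seq
    return out


def shuffle_sequences(sequences: dict[str, str], seed: int = 0) -> dict[str, str]:
    """Per-sequence base shuffle; a composition-matched background helper."""
    rng = np.random.default_rng(seed)
    return {f"shuf_{k}": "".join(rng.permutation(list(v))) for k, v in sequences.items()}


def load_jaspar(handle, min_logodds_bits: float = 6.0, pseudocount: float = 0.01) -> list[PWM]:
    """Parse JASPAR-format PFMs (via Bio.motifs) into probability PWMs."""
    out = []
    for m in bio_motifs.parse(handle, "jaspar"):
        counts = np.array([m.counts[b] for b in _BASES], dtype=float) + pseudocount
        probs = counts / counts.sum(axis=0, keepdims=True)
        out.append(PWM(name=m.name or m.matrix_id, matrix=probs,
                       min_logodds_bits=min_logodds_bits))
    return out


def load_builtin_pwms(min_logodds_bits: float = 6.0) -> list[PWM]:
    ref = resources.files("kappacascade").joinpath("data/motifs_builtin.jaspar")
    with ref.open() as fh:
        return load_jaspar(fh, min_logodds_bits=min_logodds_bits)
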