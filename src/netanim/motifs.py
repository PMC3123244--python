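"""Promoter motif over-representation.

Promoters (a fixed length upstream of each TSS) are scanned with position
weight matrices by log-odds score on both strands; a motif "hits" a
promoter if any window scores at or above the threshold (80% of the
motif's maximal achievable log-odds by default).  Over-representation of
each motif in a foreground promoter set against a genome-wide background
set is the ratio of hit fractions, with a one-sided Fisher exact p-value
and Benjamini-Hochberg adjustment; records are ranked by ratio (the
primary ordering), ties broken by p.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats as st
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "MotifMatrix",
    "read_meme_motifs",
    "extract_upstream",
    "scan_pwm",
    "has_hit",
    "overrepresentation",
]

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MotifMatrix:
    """Pseudocount-regularised base probabilities per motif position.

    ``probs`` has shape (length, 4) over A, C, G, T; every row sums to 1
    and contains no zeros.  ``background`` is the assumed genomic base
    composition used in the log-odds denominator.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError(f"motif {self.motif_id}: probs must be (length, 4)")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"motif {self.motif_id}: rows must sum to 1")
        if (probs <= 0).any():
            raise ValueError(f"motif {self.motif_id}: zero probability after pseudocount")
        if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-6):
            raise ValueError(f"motif {self.motif_id}: invalid background")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 0.01,
    ) -> "MotifMatrix":
        counts = np.asarray(counts, dtype=float) + pseudocount
        probs = counts / counts.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
        return cls(motif_id, probs, bg)


def read_meme_motifs(path: str | Path, pseudocount: float = 0.01) -> list[MotifMatrix]:
    """Read motifs from a MEME minimal-format file.

    The file's background letter frequencies are used when present,
    uniform otherwise.  Probabilities are pseudocount-regularised so no
    cell is zero.
    """
    with open(path, encoding="utf-8") as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out = []
    for m in parsed:
        counts = np.array([[m.counts[b][i] for b in BASES] for i in range(m.length)])
        bg = np.array([m.background[b] for b in BASES], dtype=float)
        if not math.isclose(bg.sum(), 1.0, abs_tol=1e-6):
            bg = np.full(4, 0.25)
        out.append(MotifMatrix.from_counts(m.name, counts, bg, pseudocount))
    return out


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_upstream(
    genome: dict[str, str] | str | Path,
    coords: pd.DataFrame,
    length: int = 1000,
) -> dict[str, str]:
    """Promoter sequences upstream of each TSS.

    ``coords`` columns: contig, tss (1-based), strand (+/-), gene.  Plus
    strand promoters are bases [tss-length, tss-1]; minus strand, bases
    [tss+1, tss+length] reverse-complemented.  Promoters are truncated at
    contig bounds with a logged length; a TSS off the contig is an error
    naming the gene.
    """
    if not isinstance(genome, dict):
        genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome), "fasta")}
    promoters: dict[str, str] = {}
    for _, row in coords.iterrows():
        gene, contig, strand = row["gene"], row["contig"], row["strand"]
        tss = int(row["tss"])
        if contig not in genome:
            raise ValueError(f"gene {gene}: contig {contig!r} not in genome")
        seq = genome[contig]
        if tss < 1 or tss > len(seq):
            raise ValueError(f"gene {gene}: TSS {tss} off contig {contig} (length {len(seq)})")
        if strand == "+":
            start = max(tss - length, 1)
            promoter = seq[start - 1 : tss - 1]
        elif strand == "-":
            end = min(tss + length, len(seq))
            promoter = revcomp(seq[tss : end])
        else:
            raise ValueError(f"gene {gene}: invalid strand {strand!r}")
        if len(promoter) < length:
            log.warning("gene %s: promoter truncated to %d nt at contig bound", gene, len(promoter))
        promoters[gene] = promoter
    return promoters


def scan_pwm(
    seq: str,
    motif: MotifMatrix,
    score_threshold: float | None = None,
) -> list[tuple[int, str, float]]:
    """Log-odds scan of one sequence, both strands.

    Returns ``(position, strand, score)`` hits with 1-based positions on
    the forward sequence; windows containing ``N`` are skipped.  The
    default threshold is 80% of the motif's maximal achievable score.  A
    motif longer than the sequence yields an empty list.
    """
    if score_threshold is None:
        score_threshold = 0.8 * motif.max_score
    seq = seq.upper()
    w = motif.length
    if w > len(seq):
        return []
    lo = motif.log_odds
    idx = np.full(len(seq), -1, dtype=int)
    for i, b in enumerate(BASES):
        idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    lo_rc = lo[::-1, ::-1]  # reverse complement of the matrix
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    valid = (windows >= 0).all(axis=1)  # windows with N (or other ambiguity) skipped
    cols = np.arange(w)
    safe = np.where(windows < 0, 0, windows)
    fwd = lo[cols, safe].sum(axis=1)
    rev = lo_rc[cols, safe].sum(axis=1)
    hits = []
    for pos in np.flatnonzero(valid):
        if fwd[pos] >= score_threshold:
            hits.append((int(pos) + 1, "+", float(fwd[pos])))
        if rev[pos] >= score_threshold:
            hits.append((int(pos) + 1, "-", float(rev[pos])))
    return hits


def has_hit(seq: str, motif: MotifMatrix, score_threshold: float | None = None) -> bool:
    return bool(scan_pwm(seq, motif, score_threshold))


def overrepresentation(
    fg_promoters: dict[str, str],
    bg_promoters: dict[str, str],
    motif_list: list[MotifMatrix],
    score_threshold_fraction: float = 0.8,
) -> pd.DataFrame:
    """Per-motif over-representation of foreground vs background promoters.

    A promoter counts as hit if it contains at least one window at or
    above the motif's threshold (presence/absence, not hit counts).  The
    ratio is fg hit fraction / bg hit fraction; p is the one-sided Fisher
    exact test on the 2x2 (fg/bg x hit/no-hit) table, adjusted by
    Benjamini-Hochberg.  Motifs absent everywhere are dropped with a log
    message; a zero background fraction with foreground hits yields an
    infinite ratio, sorted first.  Output sorted by ratio descending,
    ties by p ascending.
    """
    rows = []
    for motif in motif_list:
        thr = score_threshold_fraction * motif.max_score
        fg_with = sum(has_hit(s, motif, thr) for s in fg_promoters.values())
        bg_with = sum(has_hit(s, motif, thr) for s in bg_promoters.values())
        fg_total, bg_total = len(fg_promoters), len(bg_promoters)
        if fg_with == 0 and bg_with == 0:
            log.info("motif %s has no hits anywhere; dropped", motif.motif_id)
            continue
        fg_frac = fg_with / fg_total if fg_total else 0.0
        bg_frac = bg_with / bg_total if bg_total else 0.0
        ratio = math.inf if bg_frac == 0 else fg_frac / bg_frac
        table = [[fg_with, fg_total - fg_with], [bg_with, bg_total - bg_with]]
        _, p = st.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "motif_id": motif.motif_id,
                "fg_with_hit": fg_with, "fg_total": fg_total,
                "bg_with_hit": bg_with, "bg_total": bg_total,
                "fg_fraction": fg_frac, "bg_fraction": bg_frac,
                "ratio": ratio, "p": float(p),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["motif_id", "fg_with_hit", "fg_total", "bg_with_hit", "bg_total",
                     "fg_fraction", "bg_fraction", "ratio", "p", "p_adj"]
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    df = df.sort_values(["ratio", "p"], ascending=[False, True], kind="mergesort")
    return df.reset_index(drop=True)
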