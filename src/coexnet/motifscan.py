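"""Position-weight-matrix scanning of promoter sequences.

A binding motif is represented as a 4 x L log2-odds matrix against a
uniform background.  A window of sequence scores the sum of its per-position
weights; the *relative* score rescales that raw score onto [0, 1] between
the matrix's minimum and maximum attainable scores, and a hit is any window
whose relative score reaches the threshold (default 80%).  Both strands are
scanned by default, with reverse-strand hits mapped back to forward
coordinates (0-based, half-open windows).

Promoters are taken as the 1000 bp immediately upstream of a gene's
transcription start site (reverse-complemented for minus-strand genes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PWM",
    "MotifHit",
    "pwm_from_counts",
    "parse_jaspar",
    "scan",
    "scan_promoters",
    "extract_promoters",
    "reverse_complement",
]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """Log2-odds position weight matrix over the DNA alphabet (rows A,C,G,T)."""

    weights: np.ndarray  # 4 x L
    probabilities: np.ndarray  # 4 x L column-stochastic frequencies
    name: str = ""

    def __post_init__(self) -> None:
        if self.weights.shape[0] != 4 or self.weights.ndim != 2 or self.weights.shape[1] < 1:
            raise ValueError("PWM weights must be a 4 x L matrix with L >= 1")

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.weights.min(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.weights.argmax(axis=0))

    def relative_score(self, raw: float) -> float:
        span = self.max_score - self.min_score
        if span == 0:
            return 1.0
        return (raw - self.min_score) / span

    def reverse_complement(self) -> "PWM":
        return PWM(
            weights=self.weights[::-1, ::-1].copy(),
            probabilities=self.probabilities[::-1, ::-1].copy(),
            name=self.name,
        )


@dataclass(frozen=True)
class MotifHit:
    """One PWM match; offset is 0-based on the forward strand."""

    seq_id: str
    offset: int
    strand: str
    score: float
    relative_score: float
    match: str


def pwm_from_counts(
    count_matrix, pseudocount: float = 0.8, name: str = ""
) -> PWM:
    """Log2-odds PWM from a 4 x L base-count matrix against uniform background.

    Frequencies are (count + pseudocount/4) / (column_total + pseudocount);
    weights are log2(freq / 0.25).  Accepts an array or a DataFrame indexed
    by A/C/G/T.
    """
    if isinstance(count_matrix, pd.DataFrame):
        missing = [b for b in ALPHABET if b not in count_matrix.index]
        if missing:
            raise ValueError(f"count matrix missing rows: {missing}")
        counts = count_matrix.loc[list(ALPHABET)].to_numpy(dtype=float)
    else:
        counts = np.asarray(count_matrix, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError("count matrix must have exactly 4 rows (A, C, G, T)")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0)
    if np.any(totals + pseudocount <= 0):
        raise ValueError("every column needs a positive total (or pseudocount)")
    freqs = (counts + pseudocount / 4.0) / (totals + pseudocount)
    with np.errstate(divide="ignore"):
        weights = np.log2(freqs / 0.25)
    return PWM(weights=weights, probabilities=freqs, name=name)


def parse_jaspar(path, pseudocount: float = 0.8) -> PWM:
    """Read the first motif of a JASPAR-format matrix file into a PWM."""
    from Bio import motifs

    with open(path) as handle:
        motif = motifs.read(handle, "jaspar")
    counts = np.array([motif.counts[b] for b in ALPHABET], dtype=float)
    return pwm_from_counts(counts, pseudocount=pseudocount, name=motif.matrix_id or motif.name)


def _encode(seq: str) -> np.ndarray:
    """Sequence to integer codes; anything outside A/C/G/T becomes -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.size, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def _scan_one_strand(codes: np.ndarray, pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """Raw window scores and a validity mask (windows containing N skipped)."""
    L = pwm.length
    n_windows = codes.size - L + 1
    if n_windows <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    scores = np.zeros(n_windows)
    safe = np.where(windows >= 0, windows, 0)
    for j in range(L):
        scores += pwm.weights[safe[:, j], j]
    return scores, valid


def scan(
    seq: str,
    pwm: PWM,
    min_relative: float = 0.80,
    both_strands: bool = True,
    seq_id: str = "",
) -> list[MotifHit]:
    """All PWM hits in a sequence at or above the relative-score threshold.

    Windows containing non-ACGT characters are skipped.  Reverse-strand
    windows are scored against the reverse complement and reported at their
    forward-strand offset; hits sort by offset then strand.
    """
    if not 0.0 <= min_relative <= 1.0:
        raise ValueError("min_relative must lie in [0, 1]")
    codes = _encode(seq)
    L = pwm.length
    hits: list[MotifHit] = []
    span = pwm.max_score - pwm.min_score

    def _collect(p: PWM, strand: str) -> None:
        scores, valid = _scan_one_strand(codes, p)
        rel = (scores - pwm.min_score) / span if span > 0 else np.ones_like(scores)
        for off in np.flatnonzero(valid & (rel >= min_relative)):
            hits.append(
                MotifHit(
                    seq_id=seq_id,
                    offset=int(off),
                    strand=strand,
                    score=float(scores[off]),
                    relative_score=float(rel[off]),
                    match=seq[off : off + L].upper(),
                )
            )

    _collect(pwm, "+")
    if both_strands:
        # Scoring the forward sequence with the reverse-complement PWM is
        # equivalent to scoring the reverse strand; offsets stay forward.
        _collect(pwm.reverse_complement(), "-")
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_promoters(
    sequences: dict[str, str],
    pwm: PWM,
    min_relative: float = 0.80,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Scan a promoter set; returns a tidy hit table (one row per hit)."""
    rows = [
        {
            "seq_id": h.seq_id,
            "offset": h.offset,
            "strand": h.strand,
            "score": h.score,
            "relative_score": h.relative_score,
            "match": h.match,
        }
        for seq_id, seq in sequences.items()
        for h in scan(seq, pwm, min_relative, both_strands, seq_id=seq_id)
    ]
    return pd.DataFrame(
        rows, columns=["seq_id", "offset", "strand", "score", "relative_score", "match"]
    )


def extract_promoters(
    gene_table: pd.DataFrame,
    sequences: dict[str, str],
    upstream: int = 1000,
) -> dict[str, str]:
    """Per-gene promoter: ``upstream`` bases 5' of the transcription start site.

    ``gene_table`` columns: gene_id, seq_id, tss (0-based), strand.  Plus
    strand: [tss - upstream, tss); minus strand: reverse complement of
    (tss, tss + upstream].  Promoters truncated at contig edges trigger a
    warning; a TSS outside its contig is an error.
    """
    out: dict[str, str] = {}
    for _, row in gene_table.iterrows():
        gene, seq_id, tss, strand = (
            row["gene_id"], row["seq_id"], int(row["tss"]), row["strand"],
        )
        seq = sequences.get(seq_id)
        if seq is None:
            raise KeyError(f"no sequence named {seq_id!r}")
        if not 0 <= tss <= len(seq):
            raise ValueError(f"TSS {tss} outside sequence {seq_id!r} for gene {gene!r}")
        if strand == "+":
            start = tss - upstream
            if start < 0:
                warnings.warn(f"promoter of {gene!r} truncated to {tss} bases at contig start")
                start = 0
            promoter = seq[start:tss]
        elif strand == "-":
            end = tss + 1 + upstream
            if end > len(seq):
                warnings.warn(
                    f"promoter of {gene!r} truncated to {len(seq) - tss - 1} bases at contig end"
                )
                end = len(seq)
            promoter = reverse_complement(seq[tss + 1 : end])
        else:
            raise ValueError(f"unknown strand {strand!r} for gene {gene!r}")
        out[gene] = promoter
    return out
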