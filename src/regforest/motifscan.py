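"""Promoter motif scanning with exact log-odds p-values.

Scans promoter sequences with JASPAR-style position frequency matrices and
emits a binary TF-binding incidence matrix at a per-site p-value threshold.
The null distribution of the log-odds score of a random background word is
computed exactly by dynamic programming over discretized column scores, so
site p-values carry no sampling error (only a bounded discretization error).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: complement of base index i is 3 - i under the A,C,G,T ordering
UNIFORM_BG = np.full(4, 0.25)

MAX_MOTIF_LENGTH = 30


@dataclass(frozen=True)
class MotifPFM:
    """A position frequency matrix: 4 x L nonnegative counts (rows A,C,G,T)."""

    motif_id: str
    matrix: np.ndarray
    name: str = ""

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4:
            raise ValueError(f"PFM {self.motif_id}: matrix must be 4 x L")
        if m.shape[1] < 1:
            raise ValueError(f"PFM {self.motif_id}: empty matrix")
        if (m < 0).any():
            raise ValueError(f"PFM {self.motif_id}: negative counts")
        if (m.sum(axis=0) == 0).any():
            raise ValueError(f"PFM {self.motif_id}: all-zero column")
        object.__setattr__(self, "matrix", m)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        """Highest-count base at each position (ties broken toward A<C<G<T)."""
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif_id: str
    offset: int  # 0-based window start on the forward strand of the promoter
    strand: str  # '+' or '-'
    score: float  # log2 odds
    p_value: float


@dataclass
class BindingMatrix:
    """Binary regulator x gene incidence (1 = at least one site)."""

    regulators: list
    genes: list
    bits: np.ndarray

    def __post_init__(self):
        self.bits = np.asarray(self.bits)
        if self.bits.shape != (len(self.regulators), len(self.genes)):
            raise ValueError("bits shape does not match axes")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("binding matrix entries must be 0/1")
        self.bits = self.bits.astype(np.int8)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bits, index=self.regulators, columns=self.genes)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BindingMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def genes_bound_by(self, regulator) -> list:
        r = self.regulators.index(regulator)
        return [g for g, b in zip(self.genes, self.bits[r]) if b]


def read_jaspar(path) -> list[MotifPFM]:
    """Read PFMs from a JASPAR-format file (one or more motifs)."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    out = []
    for rec in records:
        mat = np.array([rec.counts[b] for b in BASES], dtype=float)
        out.append(MotifPFM(rec.matrix_id or rec.name, mat, rec.name or ""))
    return out


def write_jaspar(pfms: Iterable[MotifPFM], path) -> None:
    with open(path, "w") as fh:
        for p in pfms:
            fh.write(f">{p.motif_id} {p.name or p.motif_id}\n")
            for i, b in enumerate(BASES):
                row = " ".join(f"{v:g}" for v in p.matrix[i])
                fh.write(f"{b} [ {row} ]\n")


def pfm_to_pwm(
    pfm: MotifPFM,
    pseudocount: float = 0.1,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Convert counts to a log2-odds position weight matrix.

    Each column's counts get ``pseudocount`` distributed proportionally to the
    background composition before normalization; entries are
    ``log2(p_base / background_base)``.
    """
    bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any():
        raise ValueError("background must be 4 positive probabilities")
    if not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must sum to 1")
    counts = pfm.matrix
    probs = (counts + pseudocount * bg[:, None]) / (counts.sum(axis=0) + pseudocount)
    return np.log2(probs / bg[:, None])


@dataclass
class ScoreDistribution:
    """Exact null PMF of a PWM score on a random background word.

    Scores are discretized to ``granularity`` bits; ``pmf[i]`` is the
    probability of integer score ``min_score + i`` (in granularity units) and
    ``sf[i]`` the probability of a score >= that value.
    """

    granularity: float
    min_score: int  # integer units
    pmf: np.ndarray
    sf: np.ndarray
    int_matrix: np.ndarray = field(repr=False)  # 4 x L discretized scores

    def score_to_pvalue(self, int_score: int) -> float:
        idx = int_score - self.min_score
        if idx < 0:
            return 1.0
        if idx >= len(self.sf):
            return float(self.sf[-1])
        return float(self.sf[idx])

    def hit_probability(self, p_thresh: float) -> float:
        """Exact per-position, per-strand probability that a background word
        scores with p-value strictly below ``p_thresh``."""
        below = self.sf < p_thresh
        if not below.any():
            return 0.0
        return float(self.sf[np.argmax(below)])


def score_distribution(
    pwm: np.ndarray,
    background: np.ndarray | None = None,
    granularity: float = 1e-3,
    max_length: int = MAX_MOTIF_LENGTH,
) -> ScoreDistribution:
    """Exact PMF of the PWM score of an i.i.d. background word, by column-wise
    convolution on an integer score lattice."""
    bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)
    pwm = np.asarray(pwm, dtype=float)
    if not np.isfinite(pwm).all():
        raise ValueError("PWM contains non-finite entries")
    L = pwm.shape[1]
    if L > max_length:
        raise ValueError(f"motif length {L} exceeds maximum {max_length}")
    S = np.rint(pwm / granularity).astype(np.int64)
    col_min = S.min(axis=0)
    col_max = S.max(axis=0)
    total_min = int(col_min.sum())
    width = int((col_max - col_min).sum()) + 1
    pmf = np.zeros(width)
    pmf[0] = 1.0
    filled = 1
    for j in range(L):
        span = int(col_max[j] - col_min[j])
        new = np.zeros(filled + span)
        for b in range(4):
            off = int(S[b, j] - col_min[j])
            new[off : off + filled] += bg[b] * pmf[:filled]
        filled += span
        pmf[: len(new)] = new
    pmf = pmf[:filled]
    sf = np.cumsum(pmf[::-1])[::-1]
    # guard against tiny negative drift; survival values live in (0, 1]
    np.clip(sf, 0.0, 1.0, out=sf)
    return ScoreDistribution(granularity, total_min, pmf, sf, S)


def _encode(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def scan_sequence(
    sequence: str,
    pwm: np.ndarray,
    distribution: ScoreDistribution,
    p_thresh: float = 1e-4,
    motif_id: str = "motif",
    gene_id: str = "gene",
) -> list[MotifHit]:
    """Score every window on both strands; emit hits with p-value < p_thresh.

    Windows containing a base outside {A,C,G,T} are skipped. Minus-strand
    hits are reported at the window's forward-strand start offset.
    """
    S = distribution.int_matrix
    L = S.shape[1]
    x = _encode(sequence)
    n = len(x) - L + 1
    if n <= 0:
        return []
    valid = np.ones(n, dtype=bool)
    scores_f = np.zeros(n, dtype=np.int64)
    scores_r = np.zeros(n, dtype=np.int64)
    # reverse-complement matrix: base b at window pos j pairs with 3-b at L-1-j
    S_rc = S[::-1, ::-1]
    xs = np.clip(x, 0, 3)
    for j in range(L):
        col = x[j : j + n]
        valid &= col >= 0
        scores_f += S[xs[j : j + n], j]
        scores_r += S_rc[xs[j : j + n], j]
    hits: list[MotifHit] = []
    for strand, scores in (("+", scores_f), ("-", scores_r)):
        for i in np.nonzero(valid)[0]:
            p = distribution.score_to_pvalue(int(scores[i]))
            if p < p_thresh:
                hits.append(
                    MotifHit(
                        gene_id=gene_id,
                        motif_id=motif_id,
                        offset=int(i),
                        strand=strand,
                        score=float(scores[i]) * distribution.granularity,
                        p_value=p,
                    )
                )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_promoters(
    promoters: Mapping[str, str],
    pfms: Sequence[MotifPFM],
    p_thresh: float = 1e-4,
    pseudocount: float = 0.1,
    background: np.ndarray | None = None,
) -> tuple[list[MotifHit], BindingMatrix]:
    """Scan every promoter with every PFM and build the binding matrix."""
    all_hits: list[MotifHit] = []
    for pfm in pfms:
        pwm = pfm_to_pwm(pfm, pseudocount=pseudocount, background=background)
        dist = score_distribution(pwm, background=background)
        for gene, seq in promoters.items():
            all_hits.extend(
                scan_sequence(seq, pwm, dist, p_thresh, motif_id=pfm.motif_id, gene_id=gene)
            )
    matrix = build_binding_matrix(
        all_hits, [p.motif_id for p in pfms], list(promoters.keys())
    )
    return all_hits, matrix


def build_binding_matrix(
    hits: Iterable[MotifHit], regulators: Sequence[str], genes: Sequence[str]
) -> BindingMatrix:
    """bit(r, g) = 1 iff at least one hit; idempotent under duplicates."""
    regulators = list(regulators)
    genes = list(genes)
    r_idx = {r: i for i, r in enumerate(regulators)}
    g_idx = {g: i for i, g in enumerate(genes)}
    bits = np.zeros((len(regulators), len(genes)), dtype=np.int8)
    for h in hits:
        if h.motif_id not in r_idx:
            raise KeyError(f"unknown regulator id in hits: {h.motif_id}")
        if h.gene_id not in g_idx:
            raise KeyError(f"unknown gene id in hits: {h.gene_id}")
        bits[r_idx[h.motif_id], g_idx[h.gene_id]] = 1
    return BindingMatrix(regulators, genes, bits)


def extract_promoters(
    tss_table: pd.DataFrame,
    genome: Mapping[str, str],
    flank: int = 2000,
) -> dict[str, str]:
    """Extract the [tss - flank, tss + flank) window around each TSS.

    ``tss_table`` needs columns gene_id, chrom, tss, strand. Coordinates are
    0-based half-open. Minus-strand promoters are reverse-complemented so the
    sequence reads 5'->3' relative to the gene. Windows are truncated at
    chromosome ends with a warning.
    """
    out: dict[str, str] = {}
    comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    for row in tss_table.itertuples(index=False):
        chrom = str(row.chrom)
        if chrom not in genome:
            raise KeyError(f"unknown chromosome: {chrom}")
        seq = str(genome[chrom])
        start, end = row.tss - flank, row.tss + flank
        if start < 0 or end > len(seq):
            warnings.warn(
                f"promoter window for {row.gene_id} truncated at chromosome end",
                stacklevel=2,
            )
            start, end = max(start, 0), min(end, len(seq))
        window = seq[start:end]
        if row.strand == "-":
            window = window.translate(comp)[::-1]
        out[str(row.gene_id)] = window
    return out


def hits_to_bed(hits: Iterable[MotifHit], motif_lengths: Mapping[str, int]) -> pd.DataFrame:
    """Hits as BED6: chrom=gene, start/end 0-based half-open, name=motif,
    score = -log10 p (capped at 1000), strand."""
    rows = []
    for h in hits:
        L = motif_lengths[h.motif_id]
        rows.append(
            (
                h.gene_id,
                h.offset,
                h.offset + L,
                h.motif_id,
                min(1000.0, -np.log10(max(h.p_value, 1e-300))),
                h.strand,
            )
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
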