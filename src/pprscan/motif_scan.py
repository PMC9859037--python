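"""FIMO-style motif scanner with exact p-values.

An IUPAC consensus becomes a position frequency matrix, then a log-odds
matrix in bits against a 0-order background.  The null distribution of
the total window score is computed exactly by dynamic programming over
a discretized score grid (position-wise convolution of per-column score
distributions), giving a p-value for every achievable score.  Scanning
scores every window on the requested strands, converts scores to
p-values, applies Benjamini-Hochberg q-values over all scored windows,
and ranks gene targets by their best hit p-value.

Defaults mirror FIMO where a choice is needed: report threshold
p <= 1e-4, matrix pseudocount 0.1, 1000 score bins, BH q-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import AnnotatedGenome, GeneFeature, SequenceRecord
from .recognition_code import SET_FROM_IUPAC, ConsensusMotif

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Background:
    """0-order background: probabilities for A, C, G, T."""

    frequencies: tuple[float, float, float, float]

    def __post_init__(self):
        freqs = np.asarray(self.frequencies, dtype=float)
        if freqs.shape != (4,) or np.any(freqs <= 0):
            raise ValueError("background needs 4 strictly positive frequencies")
        if abs(freqs.sum() - 1.0) > 1e-12:
            raise ValueError("background frequencies must sum to 1")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.frequencies, dtype=float)


def estimate_background(seqs: list[SequenceRecord], mode: str = "from_data") -> Background:
    """Mononucleotide background, ML with +1 pseudocount per base, or uniform."""
    if mode == "uniform":
        return Background((0.25, 0.25, 0.25, 0.25))
    if mode != "from_data":
        raise ValueError(f"unknown background mode {mode!r}")
    if not seqs:
        raise ValueError("from_data background requires at least one sequence")
    counts = np.ones(4)
    for rec in seqs:
        for b, i in _BASE_INDEX.items():
            counts[i] += rec.residues.count(b)
    return Background(tuple(counts / counts.sum()))


@dataclass(frozen=True)
class FrequencyMatrix:
    """Per-position nucleotide probabilities (width x 4, columns A,C,G,T)."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4 or p.shape[0] == 0:
            raise ValueError("frequency matrix must be (width, 4) and non-empty")
        if np.any(p < 0) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("each position must be a probability distribution")
        object.__setattr__(self, "probs", p)

    @property
    def width(self) -> int:
        return self.probs.shape[0]


@dataclass(frozen=True)
class LogOddsMatrix:
    """Per-position log2 odds scores in bits (width x 4)."""

    scores: np.ndarray
    motif_id: str = "motif"

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2 or s.shape[1] != 4 or not np.all(np.isfinite(s)):
            raise ValueError("log-odds matrix must be finite (width, 4)")
        object.__setattr__(self, "scores", s)

    @property
    def width(self) -> int:
        return self.scores.shape[0]

    def reverse_complement(self) -> "LogOddsMatrix":
        return LogOddsMatrix(self.scores[::-1, ::-1].copy(), self.motif_id)


def iupac_to_frequency_matrix(consensus: ConsensusMotif | str) -> FrequencyMatrix:
    """IUPAC word -> matrix; allowed bases share each column's mass equally."""
    word = consensus.iupac if isinstance(consensus, ConsensusMotif) else consensus
    if not word:
        raise ValueError("empty consensus")
    probs = np.zeros((len(word), 4))
    for i, sym in enumerate(word.upper()):
        allowed = SET_FROM_IUPAC.get(sym)
        if allowed is None:
            raise ValueError(f"invalid IUPAC symbol {sym!r} at position {i + 1}")
        for b in allowed:
            probs[i, _BASE_INDEX[b]] = 1.0 / len(allowed)
    return FrequencyMatrix(probs)


def log_odds(matrix: FrequencyMatrix, bg: Background, pseudo: float = 0.1,
             motif_id: str = "motif") -> LogOddsMatrix:
    """score(i,b) = log2((p(b|i) + a*bg(b)) / ((1+a)*bg(b))), a = pseudocount."""
    if pseudo < 0:
        raise ValueError("pseudocount must be non-negative")
    bga = bg.array
    num = matrix.probs + pseudo * bga
    den = (1.0 + pseudo) * bga
    # zero-probability bases clamp to a large negative finite score so the
    # matrix stays usable with pseudocount 0 (the disallowed base simply
    # can never win)
    scores = np.log2(np.maximum(num, 1e-10) / den)
    return LogOddsMatrix(scores, motif_id)


# --- exact null score distribution ------------------------------------------

@dataclass
class ScoreDistribution:
    """Exact null distribution of the total window score on an integer grid.

    Integer score k corresponds to real score ~ min_score + k * bin_size;
    ``pmf[k]`` is its null probability and ``survival[k] = P(score >= k)``.
    ``int_scores`` holds each column's discretized scores so that scanning
    and the null use the identical grid.
    """

    granularity: int
    offset: int                 # lowest integer score on the grid (always 0)
    pmf: np.ndarray
    survival: np.ndarray
    bin_size: float
    min_score: float
    int_scores: np.ndarray      # (width, 4) integer column scores

    def pvalue_of_int(self, int_score) -> np.ndarray:
        """Survival at the given integer score(s), clipped to the grid."""
        k = np.clip(np.asarray(int_score, dtype=int), 0, len(self.survival) - 1)
        return self.survival[k]


def exact_score_distribution(lom: LogOddsMatrix, bg: Background,
                             granularity: int = 1000) -> ScoreDistribution:
    """Exact DP null distribution of the window score under the background.

    Column scores are discretized to integers on a grid of
    (max_total - min_total) / granularity; the pmf of the total integer
    score is the position-wise convolution of per-column distributions
    weighted by the background.
    """
    if granularity < 100:
        raise ValueError("granularity must be at least 100 bins")
    scores = lom.scores
    w = scores.shape[0]
    if w == 0:
        raise ValueError("zero-width matrix")
    col_min = scores.min(axis=1)
    col_max = scores.max(axis=1)
    score_range = float(col_max.sum() - col_min.sum())
    if score_range <= 0:  # every word scores identically
        pmf = np.array([1.0])
        return ScoreDistribution(granularity, 0, pmf, np.array([1.0]), 1.0,
                                 float(col_min.sum()), np.zeros((w, 4), dtype=int))
    bin_size = score_range / granularity
    int_scores = np.rint((scores - col_min[:, None]) / bin_size).astype(int)
    bga = bg.array
    max_total = int(int_scores.max(axis=1).sum())
    pmf = np.zeros(max_total + 1)
    pmf[0] = 1.0
    top = 0
    for i in range(w):
        new = np.zeros(top + int(int_scores[i].max()) + 1)
        for b in range(4):
            k = int(int_scores[i, b])
            new[k : k + top + 1] += bga[b] * pmf[: top + 1]
        top = len(new) - 1
        pmf = np.zeros(max_total + 1)
        pmf[: top + 1] = new
    pmf = pmf[: top + 1]
    survival = np.cumsum(pmf[::-1])[::-1]
    survival = np.minimum(survival, 1.0)
    return ScoreDistribution(granularity, 0, pmf, survival, bin_size,
                             float(col_min.sum()), int_scores)


def exact_score_distribution_general(scores: np.ndarray, bg: np.ndarray,
                                     granularity: int = 1000):
    """Same DP over an arbitrary alphabet (used for protein profile nulls).

    Returns (int_scores, survival, bin_size, min_score).
    """
    scores = np.asarray(scores, dtype=float)
    bg = np.asarray(bg, dtype=float)
    w, k = scores.shape
    col_min = scores.min(axis=1)
    score_range = float(scores.max(axis=1).sum() - col_min.sum())
    if score_range <= 0:
        return np.zeros((w, k), dtype=int), np.array([1.0]), 1.0, float(col_min.sum())
    bin_size = score_range / granularity
    int_scores = np.rint((scores - col_min[:, None]) / bin_size).astype(int)
    max_total = int(int_scores.max(axis=1).sum())
    pmf = np.zeros(max_total + 1)
    pmf[0] = 1.0
    top = 0
    for i in range(w):
        new = np.zeros(top + int(int_scores[i].max()) + 1)
        for a in range(k):
            s = int(int_scores[i, a])
            new[s : s + top + 1] += bg[a] * pmf[: top + 1]
        top = len(new) - 1
        pmf = np.zeros(max_total + 1)
        pmf[: top + 1] = new
    survival = np.cumsum(pmf[: top + 1][::-1])[::-1]
    return int_scores, np.minimum(survival, 1.0), bin_size, float(col_min.sum())


# --- scanning ----------------------------------------------------------------

@dataclass
class Hit:
    motif_id: str
    sequence_name: str
    start: int
    stop: int
    strand: str
    score: float
    p_value: float
    q_value: float | None = None
    matched_sequence: str = ""
    gene_name: str | None = None


def _encode(seq: str) -> np.ndarray:
    """Map A,C,G,T -> 0..3 and anything else (N, ambiguity) -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_int_scores(codes: np.ndarray, dist: ScoreDistribution,
                       bg: Background, skip_ambiguous: bool) -> np.ndarray:
    """Integer score of every window; ambiguous positions score the
    background-expected column score (or mark the window for skipping)."""
    w = dist.int_scores.shape[0]
    n_win = len(codes) - w + 1
    expected = np.rint(dist.int_scores @ bg.array).astype(int)  # per column
    colmat = np.hstack([dist.int_scores, expected[:, None]])    # (w, 5)
    total = np.zeros(n_win, dtype=np.int64)
    ambiguous = np.zeros(n_win, dtype=bool)
    for i in range(w):
        cw = codes[i : i + n_win]
        total += colmat[i, cw]
        ambiguous |= cw == 4
    if skip_ambiguous:
        total[ambiguous] = -1
    return total


def scan(lom: LogOddsMatrix, dist: ScoreDistribution, target,
         bg: Background, strands: str = "both", p_threshold: float = 1e-4,
         skip_ambiguous: bool = False) -> list[Hit]:
    """Score every window of the target on the requested strands.

    P-values come from the exact null distribution; q-values are BH over
    all scored windows (both strands).  Hits with p <= p_threshold are
    returned, reverse-strand hits in forward coordinates with strand "-"
    and a reverse-complemented matched sequence.
    """
    if strands not in ("both", "forward"):
        raise ValueError("strands must be 'both' or 'forward'")
    if isinstance(target, AnnotatedGenome):
        seqs = [target.sequence]
    elif isinstance(target, SequenceRecord):
        seqs = [target]
    else:
        seqs = list(target)
    w = lom.width
    if all(len(s) < w for s in seqs):
        warnings.warn("all target sequences are shorter than the motif; no hits")
        return []

    rc_dist_int = dist.int_scores[::-1, ::-1]  # same grid, reverse complement
    raw: list[tuple] = []       # (seq_name, start0, strand, int_score, window)
    pvals: list[float] = []
    for rec in seqs:
        if len(rec) < w:
            continue
        codes = _encode(rec.residues)
        fwd = _window_int_scores(codes, dist, bg, skip_ambiguous)
        strand_sets = [("+", fwd)]
        if strands == "both":
            rc = ScoreDistribution(dist.granularity, 0, dist.pmf, dist.survival,
                                   dist.bin_size, dist.min_score, rc_dist_int)
            strand_sets.append(("-", _window_int_scores(codes, rc, bg, skip_ambiguous)))
        for strand, ints in strand_sets:
            for pos in range(len(ints)):
                k = ints[pos]
                if k < 0:
                    continue
                p = float(dist.pvalue_of_int(k))
                raw.append((rec.id, pos, strand, int(k)))
                pvals.append(p)
    if not raw:
        return []
    qvals = bh_qvalues(pvals)
    hits = []
    seq_by_id = {s.id: s.residues for s in seqs}
    for (name, pos, strand, k), p, q in zip(raw, pvals, qvals):
        if p > p_threshold:
            continue
        window = seq_by_id[name][pos : pos + w]
        matched = reverse_complement(window) if strand == "-" else window
        score = dist.min_score + k * dist.bin_size
        hits.append(Hit(lom.motif_id, name, pos + 1, pos + w, strand,
                        score, p, q, matched))
    hits.sort(key=lambda h: (h.p_value, h.sequence_name, h.start, h.strand))
    return hits


def bh_qvalues(pvals) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


# --- target ranking ----------------------------------------------------------

@dataclass(frozen=True)
class RankedTarget:
    gene: str
    best_p: float
    best_q: float | None
    n_hits: int
    best_position: int
    best_strand: str


@dataclass
class TargetRanking:
    rows: list[RankedTarget] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)


def assign_genes(hits: list[Hit], genome: AnnotatedGenome) -> None:
    """Label each hit with the gene(s) it overlaps; 'intergenic' otherwise.

    A hit overlapping several features keeps a comma-joined label; the
    per-feature assignment is redone in rank_targets.
    """
    for h in hits:
        names = [f.name for f in genome.features if f.overlaps(h.start, h.stop)]
        h.gene_name = ",".join(names) if names else "intergenic"


def rank_targets(hits: list[Hit], genome: AnnotatedGenome,
                 top_n: int = 20) -> TargetRanking:
    """Per-gene best-p ranking: each hit counts for every feature it
    overlaps (>= 1 bp, strand-agnostic); intergenic hits pool under
    'intergenic'.  Rows sort by best p-value, ties by gene name."""
    per_gene: dict[str, list[Hit]] = {}
    for h in hits:
        genes = [f.name for f in genome.features if f.overlaps(h.start, h.stop)]
        for g in genes or ["intergenic"]:
            per_gene.setdefault(g, []).append(h)
    rows = []
    for gene, gene_hits in per_gene.items():
        best = min(gene_hits, key=lambda h: (h.p_value, h.start))
        rows.append(RankedTarget(gene, best.p_value, best.q_value,
                                 len(gene_hits), best.start, best.strand))
    rows.sort(key=lambda r: (r.best_p, r.gene))
    return TargetRanking(rows[:top_n])


def write_ranking_tsv(ranking: TargetRanking, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tbest_p\tbest_q\tn_hits\tbest_position\tstrand\n")
        for r in ranking.rows:
            q = "" if r.best_q is None else f"{r.best_q:.5e}"
            fh.write(f"{r.gene}\t{r.best_p:.5e}\t{q}\t{r.n_hits}\t"
                     f"{r.best_position}\t{r.best_strand}\n")


# --- MEME minimal motif format ----------------------------------------------

def write_meme_motif(matrix: FrequencyMatrix, bg: Background, path,
                     motif_id: str = "motif") -> None:
    """Write the matrix as a MEME minimal-format motif block."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A %.6f C %.6f G %.6f T %.6f\n\n" % tuple(bg.frequencies))
        fh.write(f"MOTIF {motif_id}\n")
        fh.write(f"letter-probability matrix: alength= 4 w= {matrix.width}\n")
        for row in matrix.probs:
            fh.write("  ".join(f"{v:.6f}" for v in row) + "\n")


def read_meme_motif(path) -> tuple[FrequencyMatrix, Background, str]:
    """Read the first motif of a MEME minimal-format file."""
    bg = Background((0.25, 0.25, 0.25, 0.25))
    motif_id = "motif"
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        lines = iter(fh.read().splitlines())
    for line in lines:
        stripped = line.strip()
        if stripped.startswith("Background letter frequencies"):
            vals = next(lines).split()
            freq = {vals[i]: float(vals[i + 1]) for i in range(0, len(vals), 2)}
            bg = Background(tuple(freq[b] for b in BASES))
        elif stripped.startswith("MOTIF"):
            motif_id = stripped.split()[1]
        elif stripped.startswith("letter-probability matrix"):
            parts = stripped.split()
            width = int(parts[parts.index("w=") + 1])
            for _ in range(width):
                rows.append([float(x) for x in next(lines).split()])
            break
    if width is None:
        raise ValueError(f"{path}: no letter-probability matrix found")
    return FrequencyMatrix(np.asarray(rows)), bg, motif_id
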