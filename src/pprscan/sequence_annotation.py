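"""Sequence-only PPR motif detection: profile scoring plus tandem chaining.

For proteins without a usable structure, every window of the protein is
scored against a PPR profile (per-position log-odds over the 20 amino
acids, half-bits) and assigned an exact window p-value under a null of
residues drawn i.i.d. from the query protein's own composition.  A
dynamic program then selects a non-overlapping subset of windows that
maximizes total significance with a score offset per window and a bonus
for tandem spacing — repeats occur in tandem, and exploiting that is
what separates repeat detection from single-motif search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import SequenceRecord
from .motif_scan import exact_score_distribution_general
from .structure_annotation import PPRAnnotation, PPRMotif

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

# 35-aa PPR scaffold template; positions 5 and 35 are the recognition-code
# positions and vary across real motifs.  Shared with the synthetic
# generator so sequence-mode detection recovers generated proteins.
PPR_SCAFFOLD = "VVTYNTLISGLCKAGRVDEALELFREMKEKGLKPN"
assert len(PPR_SCAFFOLD) == 35


@dataclass(frozen=True)
class PPRProfile:
    """Per-position amino-acid log-odds profile in half-bits (width x 20)."""

    scores: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2 or s.shape[1] != 20 or s.shape[0] < 10:
            raise ValueError("profile must be (width >= 10, 20)")
        if not np.all(np.isfinite(s)):
            raise ValueError("profile scores must be finite")
        object.__setattr__(self, "scores", s)

    @property
    def width(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class WindowScore:
    start_residue: int        # 1-based
    raw_score: float          # half-bits
    window_pvalue: float


def default_profile(scaffold: str = PPR_SCAFFOLD,
                    pseudo_freq: float = 0.05) -> PPRProfile:
    """Log-odds profile from a consensus scaffold with pseudo-frequencies.

    Column frequencies put mass 1 on the scaffold residue, smoothed with
    ``pseudo_freq`` on every amino acid; scores are half-bits against a
    uniform 1/20 composition.
    """
    w = len(scaffold)
    freqs = np.full((w, 20), pseudo_freq)
    for i, aa in enumerate(scaffold.upper()):
        freqs[i, _AA_INDEX[aa]] += 1.0
    freqs /= freqs.sum(axis=1, keepdims=True)
    return PPRProfile(2.0 * np.log2(freqs / (1.0 / 20.0)))


def load_profile(path) -> PPRProfile:
    """Read a profile file: a width line then a width x 20 score TSV."""
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip() and not ln.startswith("#")]
    width = int(lines[0].split()[-1])
    rows = [[float(x) for x in ln.split("\t")] for ln in lines[1 : width + 1]]
    return PPRProfile(np.asarray(rows))


def write_profile(profile: PPRProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# columns: {AA_ALPHABET}\nwidth\t{profile.width}\n")
        for row in profile.scores:
            fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def _protein_background(residues: str) -> np.ndarray:
    """Residue frequencies of the query protein, +1 pseudocount per letter."""
    counts = np.ones(20)
    for aa in residues:
        i = _AA_INDEX.get(aa)
        if i is not None:
            counts[i] += 1
    return counts / counts.sum()


def score_windows(seq: SequenceRecord, profile: PPRProfile,
                  granularity: int = 1000) -> list[WindowScore]:
    """Score every window of the protein; exact p-values from the DP null.

    The null draws residues i.i.d. from the query protein's own
    composition, so the p-value asks how surprising the window is within
    this protein.  Sequences shorter than the profile yield no windows.
    """
    w = profile.width
    residues = seq.residues
    if len(residues) < w:
        return []
    bg = _protein_background(residues)
    int_scores, survival, bin_size, min_score = exact_score_distribution_general(
        profile.scores, bg, granularity
    )
    codes = np.array([_AA_INDEX.get(a, -1) for a in residues], dtype=int)
    expected = np.rint(int_scores @ bg).astype(int)      # unknown residues
    colmat = np.hstack([int_scores, expected[:, None]])  # code -1 -> last col
    n_win = len(residues) - w + 1
    total = np.zeros(n_win, dtype=np.int64)
    for i in range(w):
        total += colmat[i, codes[i : i + n_win]]
    out = []
    for pos in range(n_win):
        k = min(int(total[pos]), len(survival) - 1)
        p = float(survival[k])
        raw = min_score + total[pos] * bin_size
        out.append(WindowScore(pos + 1, raw, p))
    return out


def chain_repeats(windows: list[WindowScore], width: int,
                  offset: float = 2.0, tandem_bonus: float = 1.0,
                  slack: int = 6, min_windows: int = 1,
                  protein_id: str = "protein") -> PPRAnnotation:
    """Select tandem repeats by dynamic programming.

    Maximizes sum(-log10 p - offset) over a non-overlapping window
    subset, plus ``tandem_bonus`` for each adjacent selected pair whose
    starts differ by width +/- slack.  Returns an empty annotation when
    the best total is <= 0 or fewer than ``min_windows`` windows win.
    Ties break toward higher score, then smaller start.
    """
    if not windows:
        return PPRAnnotation(protein_id, [])
    wins = sorted(windows, key=lambda x: x.start_residue)
    n = len(wins)
    value = np.array([-np.log10(x.window_pvalue) - offset for x in wins])
    starts = np.array([x.start_residue for x in wins])
    best = np.full(n, -np.inf)    # best chain total ending at j (j selected)
    prev = np.full(n, -1, dtype=int)
    for j in range(n):
        best[j] = value[j]
        for i in range(j):
            if starts[i] + width > starts[j]:
                continue  # overlap
            diff = starts[j] - starts[i]
            bonus = tandem_bonus if abs(diff - width) <= slack else 0.0
            cand = best[i] + bonus + value[j]
            if cand > best[j] + 1e-12:
                best[j] = cand
                prev[j] = i
    j_best = int(np.argmax(best))
    if best[j_best] <= 0:
        return PPRAnnotation(protein_id, [])
    chain = []
    j = j_best
    while j >= 0:
        chain.append(j)
        j = prev[j]
    chain.reverse()
    if len(chain) < min_windows:
        return PPRAnnotation(protein_id, [])
    motifs = [
        PPRMotif(k + 1, int(starts[j]), int(starts[j]) + width - 1,
                 source="sequence")
        for k, j in enumerate(chain)
    ]
    return PPRAnnotation(protein_id, motifs)


def annotate_sequence(seq: SequenceRecord, profile: PPRProfile | None = None,
                      offset: float = 2.0, tandem_bonus: float = 1.0,
                      slack: int = 6) -> PPRAnnotation:
    """Convenience: score_windows then chain_repeats with defaults."""
    profile = profile or default_profile()
    windows = score_windows(seq, profile)
    return chain_repeats(windows, profile.width, offset, tandem_bonus,
                         slack, protein_id=seq.id)
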