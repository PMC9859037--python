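"""The PPR recognition code: from per-motif residue pairs to an IUPAC word.

The 5th and 35th residues of each ~35-aa PPR motif determine the
nucleotide that motif prefers; reading the motifs N->C and emitting one
IUPAC symbol per motif yields the protein's predicted RNA binding word
(N-terminal motif pairs with the 5' nucleotide).  The code table is
data, not code: a TSV shipped with the package provides a default drawn
from the combinatorial code described for plant PPR proteins, and any
table can be supplied in its place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from .io_formats import SequenceRecord
from .structure_annotation import PPRAnnotation

WILDCARD = "."

# subset of {A,C,G,T} <-> IUPAC degenerate symbol
IUPAC_FROM_SET = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}
SET_FROM_IUPAC = {sym: s for s, sym in IUPAC_FROM_SET.items()}


@dataclass
class CodeTable:
    """Mapping from ordered (aa5, aa35) pairs to nucleotide subsets."""

    entries: dict[tuple[str, str], frozenset] = field(default_factory=dict)
    default_for_unknown: frozenset = frozenset("ACGT")

    def __post_init__(self):
        for (a5, a35), nts in self.entries.items():
            if not nts:
                raise ValueError(f"code entry ({a5},{a35}) maps to the empty set")
            if not set(nts) <= set("ACGT"):
                raise ValueError(f"code entry ({a5},{a35}): bad nucleotides {nts}")

    def invert(self) -> dict[frozenset, list[tuple[str, str]]]:
        """Nucleotide subset -> residue pairs mapping to exactly that subset."""
        inv: dict[frozenset, list[tuple[str, str]]] = {}
        for pair, nts in self.entries.items():
            if WILDCARD in pair:
                continue
            inv.setdefault(frozenset(nts), []).append(pair)
        for pairs in inv.values():
            pairs.sort()
        return inv


@dataclass(frozen=True)
class ConsensusMotif:
    """The protein's predicted binding word, one IUPAC symbol per motif."""

    iupac: str
    motif_indices: tuple[int, ...]

    def __post_init__(self):
        if len(self.iupac) != len(self.motif_indices):
            raise ValueError("iupac string and motif indices must be parallel")
        bad = set(self.iupac) - set(SET_FROM_IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC symbols: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.iupac)


def load_code_table(path=None) -> CodeTable:
    """Load a code table TSV (aa5, aa35, nucleotides); default: packaged table."""
    if path is None:
        text = resources.files("pprscan.data").joinpath("code_table.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    entries = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"code table line not 3 columns: {line!r}")
        a5, a35, nts = (p.strip() for p in parts)
        a5 = WILDCARD if a5 in (".", "·") else a5.upper()
        a35 = WILDCARD if a35 in (".", "·") else a35.upper()
        entries[(a5, a35)] = frozenset(nts.upper().replace("U", "T"))
    return CodeTable(entries)


def extract_code_residues(annotation: PPRAnnotation,
                          seq: SequenceRecord) -> list[tuple[str | None, str | None]]:
    """Per-motif (aa5, aa35) residues; positions beyond the protein are absent.

    For a motif starting at residue s, aa5 is the protein residue at
    position s+4 and aa35 the residue at s+34 (which may fall past the
    motif's own end, e.g. inside the next motif's first helix or a
    linker).  Absent residues are recorded as None, never invented.
    """
    n = len(seq.residues)
    pairs = []
    for m in annotation.motifs:
        if m.start_residue < 1 or m.start_residue > n:
            raise ValueError(
                f"motif {m.index} start {m.start_residue} outside protein (len {n})"
            )
        p5, p35 = m.start_residue + 4, m.start_residue + 34
        aa5 = seq.residues[p5 - 1] if p5 <= n else None
        aa35 = seq.residues[p35 - 1] if p35 <= n else None
        pairs.append((aa5, aa35))
    return pairs


def code_lookup(pair: tuple[str | None, str | None], table: CodeTable) -> frozenset:
    """Nucleotide subset for a residue pair; never empty.

    Exact pair first, then wildcard patterns most-specific first, then
    the table's default.  A missing residue maps to the default.
    """
    aa5, aa35 = pair
    if aa5 is None or aa35 is None:
        return table.default_for_unknown
    for key in ((aa5, aa35), (aa5, WILDCARD), (WILDCARD, aa35), (WILDCARD, WILDCARD)):
        if key in table.entries:
            return table.entries[key]
    return table.default_for_unknown


def build_consensus(annotation: PPRAnnotation, seq: SequenceRecord,
                    table: CodeTable, reverse: bool = False) -> ConsensusMotif:
    """Translate an annotation into its IUPAC consensus word.

    One symbol per motif, N->C order onto 5'->3' (PPR modular
    recognition); ``reverse=True`` flips the orientation.
    """
    if not annotation.motifs:
        raise ValueError("no motifs: cannot build a consensus")
    pairs = extract_code_residues(annotation, seq)
    symbols = [IUPAC_FROM_SET[frozenset(code_lookup(p, table))] for p in pairs]
    indices = [m.index for m in annotation.motifs]
    if reverse:
        symbols, indices = symbols[::-1], indices[::-1]
    return ConsensusMotif("".join(symbols), tuple(indices))


def write_consensus(consensus: ConsensusMotif, path, motif_id: str = "consensus") -> None:
    """Write the consensus as a one-record FASTA-like motif file."""
    with open(path, "w") as fh:
        fh.write(f">{motif_id}\n{consensus.iupac}\n")
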