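"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are 1-based inclusive (GenBank/FIMO convention).
Nucleotide sequences are normalized to the DNA alphabet at read time
(U -> T), so one internal alphabet serves both genome and transcript
scanning.  No science lives here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO


class FormatError(ValueError):
    """Malformed or empty input file."""


NUCLEOTIDES = "ACGT"

HIT_TABLE_COLUMNS = [
    "motif_id",
    "sequence_name",
    "start",
    "stop",
    "strand",
    "score",
    "p_value",
    "q_value",
    "matched_sequence",
    "gene_name",
]


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence; residues are upper-case amino acids or DNA."""

    id: str
    description: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise FormatError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneFeature:
    """A gene on a genome, 1-based inclusive coordinates."""

    name: str
    start: int
    stop: int
    strand: str

    def __post_init__(self):
        if not 1 <= self.start <= self.stop:
            raise FormatError(
                f"feature {self.name!r}: invalid span {self.start}..{self.stop}"
            )
        if self.strand not in "+-":
            raise FormatError(f"feature {self.name!r}: strand must be + or -")

    def overlaps(self, start: int, stop: int) -> bool:
        return self.start <= stop and start <= self.stop


@dataclass
class AnnotatedGenome:
    sequence: SequenceRecord
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = False

    def __post_init__(self):
        length = len(self.sequence)
        kept, names = [], {}
        for feat in self.features:
            if feat.stop > length:
                warnings.warn(
                    f"feature {feat.name!r} extends beyond the sequence "
                    f"({feat.stop} > {length}); rejected"
                )
                continue
            name = feat.name
            if name in names:
                names[name] += 1
                feat = GeneFeature(
                    f"{name}_{names[name]}", feat.start, feat.stop, feat.strand
                )
            else:
                names[name] = 1
            kept.append(feat)
        self.features = kept


def _normalize_nt(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path, nucleotide: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file; with ``nucleotide=True``, map U->T.

    Duplicate ids are suffixed (``id_2``, ...) with a warning.
    """
    path = Path(path)
    records = []
    seen: dict[str, int] = {}
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    for rec in parsed:
        residues = str(rec.seq).upper().replace(" ", "")
        if nucleotide:
            residues = _normalize_nt(residues)
        rid = rec.id
        if rid in seen:
            seen[rid] += 1
            warnings.warn(f"duplicate FASTA id {rid!r}; suffixed")
            rid = f"{rid}_{seen[rec.id]}"
        else:
            seen[rid] = 1
        records.append(SequenceRecord(rid, rec.description, residues))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description and rec.description != rec.id else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_genbank_genome(path) -> AnnotatedGenome:
    """Read a GenBank flat file into an annotated genome.

    Features of type gene/CDS/tRNA/rRNA are extracted with 1-based
    inclusive coordinates; strand comes from complement() notation and
    the circular flag from the LOCUS line.
    """
    path = Path(path)
    try:
        rec = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise FormatError(f"{path}: no GenBank record found") from None
    seq = _normalize_nt(str(rec.seq))
    if not seq:
        raise FormatError(f"{path}: GenBank record has no sequence")
    features = []
    seen_spans = set()
    for feat in rec.features:
        if feat.type not in ("gene", "CDS", "tRNA", "rRNA"):
            continue
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("locus_tag") or quals.get("product") or [feat.type])[0]
        start = int(feat.location.start) + 1  # Biopython is 0-based half-open
        stop = int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        key = (name, start, stop)
        if key in seen_spans:  # gene + CDS pairs describe the same locus
            continue
        seen_spans.add(key)
        features.append(GeneFeature(name, start, stop, strand))
    circular = rec.annotations.get("topology", "linear") == "circular"
    genome_seq = SequenceRecord(rec.id or rec.name, rec.description, seq)
    return AnnotatedGenome(genome_seq, features, circular)


def read_feature_tsv(path) -> list[GeneFeature]:
    """Read the 4-column feature dialect: name, start, stop, strand."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["name", "start", "stop", "strand"],
        comment="#", dtype={"name": str, "strand": str},
    )
    return [
        GeneFeature(str(name), int(start), int(stop), str(strand))
        for name, start, stop, strand in df.itertuples(index=False, name=None)
    ]


def read_genome(fasta_path, features_path=None, circular: bool = False) -> AnnotatedGenome:
    """Assemble an AnnotatedGenome from FASTA plus an optional feature TSV."""
    seq = read_fasta(fasta_path, nucleotide=True)[0]
    features = read_feature_tsv(features_path) if features_path else []
    return AnnotatedGenome(seq, features, circular)


def write_feature_tsv(features: Iterable[GeneFeature], path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.name}\t{f.start}\t{f.stop}\t{f.strand}\n")


# --- C-alpha structure input -------------------------------------------------

def read_calpha_structure(path, chain: str | None = None):
    """Read CA atoms of one chain from a PDB file into a StructureModel.

    Residues are ordered by residue number within the first chain unless
    a chain id is given; altloc duplicates keep the first CA seen.
    """
    import gemmi

    from .structure_annotation import StructureModel

    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise FormatError(f"{path}: no model in PDB file")
    model = st[0]
    target = None
    for ch in model:
        if chain is None or ch.name == chain:
            target = ch
            break
    if target is None:
        raise FormatError(f"{path}: chain {chain!r} not found")
    numbers, names, coords = [], [], []
    seen = set()
    for res in target:
        if res.het_flag == "H":
            continue
        ca = res.find_atom("CA", "*")
        if ca is None:
            continue
        num = res.seqid.num
        if num in seen:
            warnings.warn(f"altloc/duplicate residue {num}; keeping first CA")
            continue
        seen.add(num)
        numbers.append(num)
        names.append(gemmi.find_tabulated_residue(res.name).one_letter_code.upper()
                     if gemmi.find_tabulated_residue(res.name) else "X")
        coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
    if not numbers:
        raise FormatError(f"{path}: no CA atoms found")
    order = np.argsort(numbers, kind="stable")
    return StructureModel(
        residue_numbers=np.asarray(numbers)[order],
        residue_names="".join(names[i] for i in order),
        ca_coordinates=np.asarray(coords, dtype=float)[order],
    )


def write_calpha_pdb(structure, path, chain: str = "A") -> None:
    """Write a CA-only PDB file (poly-ALA names unless one-letter known)."""
    three = {
        "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
        "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
        "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
        "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    }
    with open(path, "w") as fh:
        for i, (num, aa, xyz) in enumerate(
            zip(structure.residue_numbers, structure.residue_names,
                structure.ca_coordinates), start=1
        ):
            res3 = three.get(aa, "ALA")
            fh.write(
                f"ATOM  {i:5d}  CA  {res3} {chain}{num:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")


# --- hit tables --------------------------------------------------------------

def write_hits_table(hits, path) -> None:
    """Write hits as TSV with fixed columns; floats as 6-sig-digit scientific."""
    rows = []
    for h in hits:
        rows.append(
            {
                "motif_id": h.motif_id,
                "sequence_name": h.sequence_name,
                "start": h.start,
                "stop": h.stop,
                "strand": h.strand,
                "score": f"{h.score:.5e}",
                "p_value": f"{h.p_value:.5e}",
                "q_value": "" if h.q_value is None else f"{h.q_value:.5e}",
                "matched_sequence": h.matched_sequence,
                "gene_name": getattr(h, "gene_name", "") or "",
            }
        )
    df = pd.DataFrame(rows, columns=HIT_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_hits_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"motif_id": str, "sequence_name": str})
    missing = set(HIT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: hit table missing columns {sorted(missing)}")
    return df
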