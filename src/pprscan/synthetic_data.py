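"""Synthetic inputs with known truth for every stage of the pipeline.

Three generators emulate the study's inputs: PPR proteins whose 5th/35th
motif residues encode a chosen RNA target word; ideal antiparallel
helix-hairpin (solenoid) Cα coordinate sets; and mitochondrial-genome-
like backgrounds (AT-rich, ~16.6 kb, circular gene map) with consensus
sites planted at known positions.  Every generator is a pure function of
(parameters, seed) — identical calls give byte-identical outputs — and
validates its emitted truth before returning it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_formats import (AnnotatedGenome, GeneFeature, SequenceRecord,
                         write_calpha_pdb, write_fasta, write_feature_tsv)
from .motif_scan import Background, reverse_complement
from .recognition_code import (SET_FROM_IUPAC, CodeTable, build_consensus,
                               load_code_table)
from .sequence_annotation import PPR_SCAFFOLD
from .structure_annotation import (HelixSegment, PPRAnnotation, PPRMotif,
                                   StructureModel)

# Human-mitochondrial-like base composition (AT-rich light/heavy average).
MITO_BACKGROUND = Background((0.31, 0.31, 0.13, 0.25))
MITO_GENOME_LENGTH = 16569

# distinct sub-stream ids so each generator has its own named stream
_STREAM_PROTEIN, _STREAM_SOLENOID, _STREAM_GENOME = 11, 23, 37


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass
class SyntheticTruth:
    """Planted parameters recorded alongside a generated dataset."""

    planted_target: str = ""
    motif_starts: list[int] = field(default_factory=list)
    planted_sites: list[tuple[str, int, str]] = field(default_factory=list)
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


# --- PPR protein encoding a target word -------------------------------------

def generate_ppr_protein(target: str, table: CodeTable | None = None,
                         scaffold: str = PPR_SCAFFOLD, seed: int = 0,
                         protein_id: str = "synthetic_ppr"):
    """Protein of tandem 35-aa scaffold copies whose code residues spell
    ``target``; returns (record, truth annotation, truth).

    For each target symbol a (aa5, aa35) pair mapping to exactly that
    nucleotide set is drawn (seeded) from the inverted code table and
    written into positions 5 and 35 of that motif's scaffold copy.
    """
    table = table or load_code_table()
    target = target.upper().replace("U", "T")
    if not target:
        raise ValueError("empty target word")
    inv = table.invert()
    rng = _rng(seed, _STREAM_PROTEIN)
    width = len(scaffold)
    pieces, motifs = [], []
    for k, sym in enumerate(target):
        wanted = SET_FROM_IUPAC.get(sym)
        if wanted is None:
            raise ValueError(f"invalid nucleotide symbol {sym!r} in target")
        pairs = inv.get(frozenset(wanted))
        if not pairs:
            raise ValueError(
                f"nucleotide {sym!r} is unreachable: no code-table pair maps "
                f"to exactly {{{','.join(sorted(wanted))}}}"
            )
        aa5, aa35 = pairs[int(rng.integers(len(pairs)))]
        motif_seq = scaffold[:4] + aa5 + scaffold[5:34] + aa35
        pieces.append(motif_seq)
        start = k * width + 1
        motifs.append(PPRMotif(k + 1, start, start + width - 1,
                               aa5=aa5, aa35=aa35, source="sequence"))
    record = SequenceRecord(protein_id, "synthetic PPR protein", "".join(pieces))
    annotation = PPRAnnotation(protein_id, motifs)
    truth = SyntheticTruth(planted_target=target,
                           motif_starts=[m.start_residue for m in motifs],
                           seed=seed)
    # generation-time self-check: the planted code must decode to the target
    decoded = build_consensus(annotation, record, table).iupac
    if decoded != target:
        raise AssertionError(f"self-check failed: planted {target}, decoded {decoded}")
    return record, annotation, truth


# --- ideal solenoid coordinates ----------------------------------------------

_HELIX_RISE = 1.5       # Å per residue
_HELIX_TWIST = 100.0    # degrees per residue
_HELIX_RADIUS = 2.3     # Å


def _helix_points(n: int, origin: np.ndarray, direction: float) -> np.ndarray:
    """Ideal alpha-helix Cα trace along +/-z starting at ``origin``."""
    j = np.arange(n)
    theta = np.radians(_HELIX_TWIST) * j
    pts = np.empty((n, 3))
    pts[:, 0] = origin[0] + _HELIX_RADIUS * np.cos(theta)
    pts[:, 1] = origin[1] + _HELIX_RADIUS * np.sin(theta)
    pts[:, 2] = origin[2] + direction * _HELIX_RISE * j
    return pts


def _arc_points(p: np.ndarray, q: np.ndarray, n_points: int,
                bulge: np.ndarray, spacing: float = 3.8) -> np.ndarray:
    """``n_points`` intermediate Cα positions on a circular arc from p to q.

    The arc bulges toward ``bulge`` and keeps consecutive points near the
    peptide spacing, so loop/linker residues never satisfy the helix
    distance criteria (d(i,i+2) comes out well above 6 Å).
    """
    chord_vec = q - p
    chord = float(np.linalg.norm(chord_vec))
    n_seg = n_points + 1
    path = n_seg * spacing
    if path <= chord * 1.01:          # nearly straight: fall back to a line
        ts = np.linspace(0.0, 1.0, n_seg + 1)[1:-1]
        return p + np.outer(ts, chord_vec)
    e1 = chord_vec / chord
    b = bulge - (bulge @ e1) * e1
    e2 = b / np.linalg.norm(b)
    # half-angle phi from arc length = chord requirement: sin(phi)/phi = c/path
    lo, hi = 1e-6, np.pi - 1e-6
    for _ in range(80):
        phi = 0.5 * (lo + hi)
        if np.sin(phi) / phi > chord / path:
            lo = phi
        else:
            hi = phi
    radius = chord / (2.0 * np.sin(phi))
    mid = 0.5 * (p + q)
    center = mid - radius * np.cos(phi) * e2
    alphas = -phi + (2.0 * phi / n_seg) * np.arange(1, n_seg)
    return center + radius * (np.outer(np.sin(alphas), e1) + np.outer(np.cos(alphas), e2))


def generate_ideal_solenoid(n_motifs: int, helix_len_a: int = 12,
                            helix_len_b: int = 11, loop_len: int = 4,
                            linker_len: int = 8, pack_sep: float = 10.0,
                            stack_sep: float = 9.0, jitter_sd: float = 0.1,
                            seed: int = 0, sequence: str | None = None):
    """Ideal PPR solenoid Cα trace with per-motif truth spans.

    Each motif is an antiparallel hairpin: helix A up +z, a short arc
    loop, helix B down -z displaced ``pack_sep`` in x; motifs stack along
    y at ``stack_sep`` with an arc linker between them, giving a motif
    start spacing of ``helix_len_a + loop_len + helix_len_b + linker_len``
    residues (35 with defaults, matching generate_ppr_protein).  A small
    seeded Gaussian jitter (sd ``jitter_sd`` Å) perturbs all coordinates.
    """
    if n_motifs < 1:
        raise ValueError("n_motifs must be >= 1")
    rng = _rng(seed, _STREAM_SOLENOID)
    period = helix_len_a + loop_len + helix_len_b + linker_len
    coords: list[np.ndarray] = []
    motifs: list[PPRMotif] = []
    z_top = (helix_len_a - 1) * _HELIX_RISE
    prev_end_point = None
    for k in range(n_motifs):
        y0 = k * stack_sep
        a_pts = _helix_points(helix_len_a, np.array([0.0, y0, 0.0]), +1.0)
        b_pts = _helix_points(helix_len_b, np.array([pack_sep, y0, z_top]), -1.0)
        if prev_end_point is not None:   # linker from previous motif, bulge -z
            coords.append(_arc_points(prev_end_point, a_pts[0], linker_len,
                                      np.array([0.0, 0.0, -1.0])))
        loop_pts = _arc_points(a_pts[-1], b_pts[0], loop_len,
                               np.array([0.0, 0.0, 1.0]))
        coords.extend([a_pts, loop_pts, b_pts])
        start = k * period + 1
        helix_a = HelixSegment(start, start + helix_len_a - 1, (0.0, 0.0, 1.0))
        b_start = start + helix_len_a + loop_len
        helix_b = HelixSegment(b_start, b_start + helix_len_b - 1, (0.0, 0.0, -1.0))
        motifs.append(PPRMotif(k + 1, helix_a.start_residue, helix_b.end_residue,
                               helix_a=helix_a, helix_b=helix_b, source="structure"))
        prev_end_point = b_pts[-1]
    # trailing linker keeps the chain length at period * n_motifs
    if linker_len > 0:
        tail_to = prev_end_point + np.array([-pack_sep, 0.0, -z_top])
        coords.append(_arc_points(prev_end_point, tail_to, linker_len - 1,
                                  np.array([0.0, 0.0, -1.0])))
        coords.append(tail_to[None, :])
    xyz = np.vstack(coords)
    xyz = xyz + rng.normal(0.0, jitter_sd, size=xyz.shape)
    n_res = xyz.shape[0]
    if sequence is None:
        sequence = (PPR_SCAFFOLD * (n_res // 35 + 1))[:n_res]
    if len(sequence) != n_res:
        raise ValueError(f"sequence length {len(sequence)} != {n_res} residues")
    structure = StructureModel(np.arange(1, n_res + 1), sequence, xyz)
    truth = PPRAnnotation("synthetic_solenoid", motifs)
    if truth.motifs[-1].end_residue > n_res:     # generation-time self-check
        raise AssertionError("truth spans exceed emitted coordinates")
    return structure, truth


# --- background genome with planted sites ------------------------------------

def generate_mito_genome(length: int = MITO_GENOME_LENGTH,
                         bg: Background = MITO_BACKGROUND,
                         genes: list | None = None,
                         planted: list | None = None,
                         seed: int = 0, circular: bool = True,
                         genome_id: str = "synthetic_mito"):
    """AT-rich i.i.d. background genome with features and planted sites.

    ``planted`` holds (word, position, strand) triples; "-" strand words
    are reverse-complemented before substitution so the forward strand
    carries their complement.  Overlapping planted sites are an error.
    Returns (AnnotatedGenome, SyntheticTruth).
    """
    rng = _rng(seed, _STREAM_GENOME)
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length, p=bg.array)
    planted = planted or []
    spans = []
    for word, pos, strand in planted:
        word = word.upper().replace("U", "T")
        if not set(word) <= set("ACGT"):
            raise ValueError(f"planted word {word!r} must be over A,C,G,T")
        if not 1 <= pos <= length - len(word) + 1:
            raise ValueError(f"planted site at {pos} does not fit in the genome")
        spans.append((pos, pos + len(word) - 1))
    spans_sorted = sorted(spans)
    for (s1, e1), (s2, e2) in zip(spans_sorted, spans_sorted[1:]):
        if s2 <= e1:
            raise ValueError("planted sites overlap")
    for word, pos, strand in planted:
        word = word.upper().replace("U", "T")
        inserted = reverse_complement(word) if strand == "-" else word
        seq[pos - 1 : pos - 1 + len(word)] = list(inserted)
    residues = "".join(seq)
    features = [
        f if isinstance(f, GeneFeature) else GeneFeature(*f)
        for f in (genes or [])
    ]
    genome = AnnotatedGenome(
        SequenceRecord(genome_id, "synthetic mitochondrial-like genome", residues),
        features, circular,
    )
    truth = SyntheticTruth(
        planted_sites=[(genome_id, pos, strand) for _, pos, strand in planted],
        seed=seed,
    )
    for word, pos, strand in planted:     # generation-time self-check
        word = word.upper().replace("U", "T")
        want = reverse_complement(word) if strand == "-" else word
        got = residues[pos - 1 : pos - 1 + len(word)]
        if got != want:
            raise AssertionError(f"planted site at {pos} not found in emitted genome")
    return genome, truth


def default_gene_map(length: int = MITO_GENOME_LENGTH,
                     n_genes: int = 10) -> list[GeneFeature]:
    """An evenly spaced mito-like gene map (n_genes genes, ~60% coverage)."""
    names = ["mt-nd1", "mt-nd2", "mt-co1", "mt-co2", "mt-atp8", "mt-atp6",
             "mt-co3", "mt-nd4", "mt-nd5", "mt-cyb", "mt-nd6", "mt-nd3"]
    step = length // n_genes
    features = []
    for i in range(n_genes):
        start = i * step + step // 5 + 1
        stop = start + int(step * 0.6)
        features.append(GeneFeature(names[i % len(names)], start,
                                    min(stop, length), "+" if i % 3 else "-"))
    return features


# --- fixture sets ------------------------------------------------------------

def make_fixtures(out_dir, target: str = "GATTACAGATTA", seed: int = 1,
                  genome_length: int = MITO_GENOME_LENGTH,
                  planted_gene: str = "mt-co1") -> dict:
    """Write a complete, consistent fixture set to ``out_dir``.

    Emits protein FASTA, solenoid PDB, genome FASTA + feature TSV and a
    truth JSON; the target word is planted inside ``planted_gene``.
    Returns the paths plus in-memory objects.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protein, annotation, protein_truth = generate_ppr_protein(target, seed=seed)
    structure, solenoid_truth = generate_ideal_solenoid(
        len(target), seed=seed, sequence=protein.residues
    )
    genes = default_gene_map(genome_length)
    gene = next(f for f in genes if f.name == planted_gene)
    rng = _rng(seed, 53)
    pos = int(rng.integers(gene.start, gene.stop - len(target) + 2))
    genome, genome_truth = generate_mito_genome(
        genome_length, genes=genes, planted=[(target, pos, "+")], seed=seed
    )
    truth = SyntheticTruth(
        planted_target=target,
        motif_starts=protein_truth.motif_starts,
        planted_sites=genome_truth.planted_sites,
        seed=seed,
    )
    paths = {
        "protein_fasta": out / "protein.fasta",
        "structure_pdb": out / "structure.pdb",
        "genome_fasta": out / "genome.fasta",
        "features_tsv": out / "features.tsv",
        "truth_json": out / "truth.json",
    }
    write_fasta([protein], paths["protein_fasta"])
    write_calpha_pdb(structure, paths["structure_pdb"])
    write_fasta([genome.sequence], paths["genome_fasta"])
    write_feature_tsv(genome.features, paths["features_tsv"])
    truth.to_json(paths["truth_json"])
    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "protein": protein,
        "annotation": annotation,
        "structure": structure,
        "genome": genome,
        "truth": truth,
        "planted_gene": planted_gene,
        "planted_position": pos,
    }
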