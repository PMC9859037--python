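"""Pipeline orchestration: annotate -> encode -> scan -> rank.

Runs the full inference chain from a PPR protein to its ranked
mitochondrial targets, persisting every intermediate (annotation TSV,
consensus motif file, MEME matrix, hit TSV, ranking TSV) so that each
stage's output is independently loadable by its module's reader.  The
run is deterministic given the config; the report echoes parameters and
input checksums for auditability.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .io_formats import (AnnotatedGenome, read_calpha_structure, read_fasta,
                         read_genbank_genome, read_genome, write_hits_table)
from .motif_scan import (Background, assign_genes, estimate_background,
                         exact_score_distribution, iupac_to_frequency_matrix,
                         log_odds, rank_targets, scan, write_meme_motif,
                         write_ranking_tsv)
from .recognition_code import (ConsensusMotif, build_consensus,
                               extract_code_residues, load_code_table,
                               write_consensus)
from .sequence_annotation import annotate_sequence, default_profile, load_profile
from .structure_annotation import (HelixGeometryParams, annotate_structure,
                                   annotation_to_tsv)

log = logging.getLogger("pprscan")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


class NoMotifsFound(RuntimeError):
    """Annotation produced no motifs: an explicit empty-result stop."""


@dataclass
class RunConfig:
    """Everything a run needs; exactly one annotation mode is active."""

    genome_path: str = ""
    genome_features: str | None = None    # TSV next to a FASTA genome
    mode: str = "structure"               # structure | sequence | provided
    protein_fasta: str | None = None
    structure_pdb: str | None = None
    consensus: str | None = None          # for mode=provided
    code_table: str | None = None
    profile_path: str | None = None
    out_dir: str = "pprscan_out"
    p_threshold: float = 1e-4
    background_mode: str = "from_data"
    strands: str = "both"
    granularity: int = 1000
    pseudocount: float = 0.1
    top_n: int = 20
    reverse_code: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("structure", "sequence", "provided"):
            raise PipelineError(f"config: unknown annotation mode {self.mode!r}")
        if self.mode == "provided":
            if not self.consensus:
                raise PipelineError("config: mode 'provided' needs a consensus")
        else:
            if not self.protein_fasta:
                raise PipelineError(f"config: mode {self.mode!r} needs protein_fasta")
            if self.mode == "structure" and not self.structure_pdb:
                raise PipelineError("config: mode 'structure' needs structure_pdb")
        if not self.genome_path:
            raise PipelineError("config: genome_path is required")
        for label, p in (
            ("genome_path", self.genome_path),
            ("genome_features", self.genome_features),
            ("protein_fasta", self.protein_fasta),
            ("structure_pdb", self.structure_pdb),
            ("code_table", self.code_table),
            ("profile_path", self.profile_path),
        ):
            if p and not Path(p).exists():
                raise PipelineError(f"config: {label} {p!r} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunReport:
    status: str
    motif_count: int = 0
    consensus: str = ""
    matrix_width: int = 0
    hit_count: int = 0
    top_targets: list[dict] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)
    version: str = __version__
    input_checksums: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_genome(config: RunConfig) -> AnnotatedGenome:
    path = Path(config.genome_path)
    text_head = path.read_text(errors="ignore")[:5]
    if text_head.startswith(">"):
        return read_genome(path, config.genome_features)
    return read_genbank_genome(path)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full chain and persist all intermediates to out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums = {
        Path(p).name: _sha256(p)
        for p in (config.genome_path, config.genome_features,
                  config.protein_fasta, config.structure_pdb, config.code_table)
        if p
    }

    # -- annotate ------------------------------------------------------------
    annotation = None
    consensus: ConsensusMotif
    if config.mode == "provided":
        log.info("stage annotate: consensus provided (%s)", config.consensus)
        word = config.consensus.upper().replace("U", "T")
        consensus = ConsensusMotif(word, tuple(range(1, len(word) + 1)))
        motif_count = len(word)
    else:
        try:
            protein = read_fasta(config.protein_fasta)[0]
            if config.mode == "structure":
                structure = read_calpha_structure(config.structure_pdb)
                annotation = annotate_structure(
                    structure, HelixGeometryParams(), protein_id=protein.id
                )
            else:
                profile = (load_profile(config.profile_path)
                           if config.profile_path else default_profile())
                annotation = annotate_sequence(protein, profile)
        except Exception as exc:
            raise PipelineError(f"annotate: {exc}") from exc
        log.info("stage annotate (%s): %d motifs", config.mode, len(annotation))
        if not annotation.motifs:
            raise NoMotifsFound(
                f"annotation mode {config.mode!r} found no PPR motifs"
            )

        # -- encode ----------------------------------------------------------
        try:
            table = load_code_table(config.code_table)
            pairs = extract_code_residues(annotation, protein)
            annotation = annotation.with_code_residues(pairs)
            consensus = build_consensus(annotation, protein, table,
                                        reverse=config.reverse_code)
        except Exception as exc:
            raise PipelineError(f"encode: {exc}") from exc
        annotation_to_tsv(annotation, out / "annotation.tsv")
        motif_count = len(annotation)
        log.info("stage encode: consensus %s", consensus.iupac)
    write_consensus(consensus, out / "consensus.fasta")

    # -- matrix / scan -------------------------------------------------------
    try:
        genome = _load_genome(config)
        bg = estimate_background([genome.sequence], config.background_mode)
        matrix = iupac_to_frequency_matrix(consensus)
        lom = log_odds(matrix, bg, config.pseudocount)
        dist = exact_score_distribution(lom, bg, config.granularity)
        write_meme_motif(matrix, bg, out / "motif.meme")
        hits = scan(lom, dist, genome, bg, strands=config.strands,
                    p_threshold=config.p_threshold)
        assign_genes(hits, genome)
    except (PipelineError, NoMotifsFound):
        raise
    except Exception as exc:
        raise PipelineError(f"scan: {exc}") from exc
    log.info("stage scan: %d hits at p <= %g", len(hits), config.p_threshold)
    write_hits_table(hits, out / "hits.tsv")

    # -- rank ----------------------------------------------------------------
    ranking = rank_targets(hits, genome, config.top_n)
    write_ranking_tsv(ranking, out / "ranking.tsv")
    log.info("stage rank: top gene %s",
             ranking.rows[0].gene if ranking.rows else "(none)")

    report = RunReport(
        status="ok",
        motif_count=motif_count,
        consensus=consensus.iupac,
        matrix_width=matrix.width,
        hit_count=len(hits),
        top_targets=[asdict(r) for r in ranking.rows],
        parameters={k: v for k, v in asdict(config).items()},
        input_checksums=checksums,
    )
    report.to_json(out / "report.json")
    return report
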