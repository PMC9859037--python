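"""Structure-based PPR motif annotation from C-alpha coordinates.

PPR motifs are ~35-residue repeats folding into a hairpin of two
antiparallel alpha-helices; tandem arrays stack into a solenoid and bind
RNA one nucleotide per repeat.  This module assigns helices from Cα-only
distance criteria (P-SEA style, robust on predicted models that lack
reliable full-atom geometry), pairs consecutive helices into hairpins,
and numbers the accepted motifs 1..n from the N-terminus.  A Kabsch
least-squares superposition is provided for comparing structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# P-SEA-style Cα distance criteria for an alpha-helix.  An ideal helix
# (rise 1.5 Å/residue, 100 deg twist, 2.3 Å radius) has d(i,i+2) = 5.43 Å
# and d(i,i+3) = 5.05 Å; tolerances admit predicted-model distortion.
HELIX_D2 = 5.45
HELIX_D3 = 5.10


@dataclass
class HelixGeometryParams:
    """Thresholds for Cα-only helix assignment and hairpin pairing."""

    d2_tol: float = 0.55          # |d(i,i+2) - 5.45| bound, Å
    d3_tol: float = 0.50          # |d(i,i+3) - 5.10| bound, Å
    min_helix_len: int = 4        # residues
    loop_max: int = 6             # max residues between hairpin helices
    antiparallel_tol_deg: float = 50.0   # axis angle window around 180 deg
    pack_max: float = 12.0        # max helix centroid separation, Å
    motif_min_len: int = 25       # motif span bounds, residues
    motif_max_len: int = 45


@dataclass
class StructureModel:
    """Cα trace of one chain: residue numbers, one-letter names, coordinates (Å)."""

    residue_numbers: np.ndarray
    residue_names: str
    ca_coordinates: np.ndarray

    def __post_init__(self):
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.ca_coordinates = np.asarray(self.ca_coordinates, dtype=float)
        n = len(self.residue_numbers)
        if len(self.residue_names) != n or self.ca_coordinates.shape != (n, 3):
            raise ValueError("residue numbers, names and coordinates must align")
        if n > 1 and not np.all(np.diff(self.residue_numbers) > 0):
            raise ValueError("residue numbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residue_numbers)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a rigidly transformed copy (x -> R x + t)."""
        return StructureModel(
            self.residue_numbers.copy(),
            self.residue_names,
            self.ca_coordinates @ np.asarray(rotation).T + np.asarray(translation),
        )


@dataclass(frozen=True)
class HelixSegment:
    start_residue: int
    end_residue: int
    axis: tuple[float, float, float]

    @property
    def length(self) -> int:
        return self.end_residue - self.start_residue + 1


@dataclass(frozen=True)
class PPRMotif:
    index: int
    start_residue: int
    end_residue: int
    helix_a: HelixSegment | None = None
    helix_b: HelixSegment | None = None
    aa5: str | None = None
    aa35: str | None = None
    source: str = "structure"

    @property
    def span(self) -> tuple[int, int]:
        return (self.start_residue, self.end_residue)


@dataclass
class PPRAnnotation:
    """Ordered N->C list of PPR motifs on one protein."""

    protein_id: str
    motifs: list[PPRMotif] = field(default_factory=list)

    def __post_init__(self):
        for i, m in enumerate(self.motifs, start=1):
            if m.index != i:
                raise ValueError("motif indices must be consecutive from 1")
        for a, b in zip(self.motifs, self.motifs[1:]):
            if b.start_residue <= a.end_residue:
                raise ValueError("motifs must not overlap and must be N->C ordered")

    def __len__(self) -> int:
        return len(self.motifs)

    def with_code_residues(self, pairs) -> "PPRAnnotation":
        motifs = [
            PPRMotif(m.index, m.start_residue, m.end_residue, m.helix_a,
                     m.helix_b, aa5, aa35, m.source)
            for m, (aa5, aa35) in zip(self.motifs, pairs)
        ]
        return PPRAnnotation(self.protein_id, motifs)


def _principal_axis(points: np.ndarray) -> np.ndarray:
    """Unit principal component of a point cloud, oriented first -> last point."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if axis @ (points[-1] - points[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def assign_helices(structure: StructureModel,
                   params: HelixGeometryParams | None = None) -> list[HelixSegment]:
    """Find maximal alpha-helical segments from Cα distance geometry.

    A window starting at residue i is helix-like when d(i,i+2) and
    d(i,i+3) both fall within tolerance of ideal helix values and the
    residue numbering is gap-free across the window.  Maximal runs of
    helix-like windows become segments (a run i=a..b covers residues
    a..b+3); segments shorter than ``min_helix_len`` are dropped.
    """
    params = params or HelixGeometryParams()
    n = len(structure)
    if n < max(5, params.min_helix_len):
        return []
    xyz = structure.ca_coordinates
    nums = structure.residue_numbers
    d2 = np.linalg.norm(xyz[2:] - xyz[:-2], axis=1)          # d(i, i+2)
    d3 = np.linalg.norm(xyz[3:] - xyz[:-3], axis=1)          # d(i, i+3)
    contiguous3 = nums[3:] - nums[:-3] == 3
    ok = (
        (np.abs(d2[:-1] - HELIX_D2) <= params.d2_tol)
        & (np.abs(d3 - HELIX_D3) <= params.d3_tol)
        & contiguous3
    )
    spans: list[list[int]] = []          # covered residue-index spans
    i = 0
    while i < len(ok):
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(ok) and ok[j + 1]:
            j += 1
        spans.append([i, j + 3])
        i = j + 1
    # merge runs split by an isolated failing window (coverage overlapping
    # or separated by <= 2 residues); real inter-helix loops are wider.
    # Never merge across a residue-numbering gap.
    merged: list[list[int]] = []
    for span in spans:
        if (merged and span[0] <= merged[-1][1] + 2
                and nums[span[0]] - nums[merged[-1][1]] == span[0] - merged[-1][1]):
            merged[-1][1] = max(merged[-1][1], span[1])
        else:
            merged.append(span)
    # hysteresis end-extension: grow each segment by residues whose local
    # geometry still looks helical under mildly relaxed tolerances, so a
    # marginally failing boundary window does not trim the helix
    def _near(dist: float, ideal: float, tol: float) -> bool:
        return abs(dist - ideal) <= tol

    def _extends(cand: int, inner1: int, inner2: int) -> bool:
        d2c = float(np.linalg.norm(xyz[inner1] - xyz[cand]))
        d3c = float(np.linalg.norm(xyz[inner2] - xyz[cand]))
        return (
            (_near(d2c, HELIX_D2, params.d2_tol) and _near(d3c, HELIX_D3, 1.5 * params.d3_tol))
            or (_near(d3c, HELIX_D3, params.d3_tol) and _near(d2c, HELIX_D2, 1.5 * params.d2_tol))
        )

    for span in merged:
        while (span[0] > 0 and nums[span[0]] - nums[span[0] - 1] == 1
               and span[0] + 2 < n
               and _extends(span[0] - 1, span[0] + 1, span[0] + 2)):
            span[0] -= 1
        while (span[1] < n - 1 and nums[span[1] + 1] - nums[span[1]] == 1
               and span[1] - 2 >= 0
               and _extends(span[1] + 1, span[1] - 1, span[1] - 2)):
            span[1] += 1

    segments: list[HelixSegment] = []
    for first, last in merged:
        if last - first + 1 >= params.min_helix_len:
            axis = _principal_axis(xyz[first : last + 1])
            segments.append(
                HelixSegment(int(nums[first]), int(nums[last]), tuple(axis))
            )
    return segments


def detect_ppr_hairpins(helices: list[HelixSegment], structure: StructureModel,
                        params: HelixGeometryParams | None = None,
                        protein_id: str = "protein") -> PPRAnnotation:
    """Pair consecutive helices into antiparallel hairpins (PPR motifs).

    Greedy N->C pairing: consecutive helices (i, i+1) form one motif when
    the inter-helix loop is short, the axes are antiparallel within the
    configured window, the helix centroids pack closely, and the total
    span falls within the motif length bounds.  Each helix joins at most
    one motif; accepted motifs are numbered 1..n from the N-terminus.
    """
    params = params or HelixGeometryParams()
    num_to_idx = {int(num): k for k, num in enumerate(structure.residue_numbers)}
    xyz = structure.ca_coordinates

    def centroid(seg: HelixSegment) -> np.ndarray:
        lo, hi = num_to_idx[seg.start_residue], num_to_idx[seg.end_residue]
        return xyz[lo : hi + 1].mean(axis=0)

    motifs: list[PPRMotif] = []
    i = 0
    while i + 1 < len(helices):
        a, b = helices[i], helices[i + 1]
        loop = b.start_residue - a.end_residue - 1
        cosang = float(np.clip(np.dot(a.axis, b.axis), -1.0, 1.0))
        angle = np.degrees(np.arccos(cosang))
        pack = float(np.linalg.norm(centroid(a) - centroid(b)))
        span = b.end_residue - a.start_residue + 1
        if (
            loop <= params.loop_max
            and angle >= 180.0 - params.antiparallel_tol_deg
            and pack <= params.pack_max
            and params.motif_min_len <= span <= params.motif_max_len
        ):
            motifs.append(
                PPRMotif(len(motifs) + 1, a.start_residue, b.end_residue,
                         helix_a=a, helix_b=b, source="structure")
            )
            i += 2      # a helix joins at most one motif
        else:
            i += 1
    return PPRAnnotation(protein_id, motifs)


def annotate_structure(structure: StructureModel,
                       params: HelixGeometryParams | None = None,
                       protein_id: str = "protein") -> PPRAnnotation:
    """Convenience: assign_helices then detect_ppr_hairpins."""
    helices = assign_helices(structure, params)
    return detect_ppr_hairpins(helices, structure, params, protein_id)


def superpose(coords_a, coords_b) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of b onto a (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ b_i + translation`` best fits ``a_i``; the rotation is
    proper (det = +1) and rmsd is the root-mean-square residual in Å.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("point sets must be equal-length (n, 3) arrays")
    if a.shape[0] < 3:
        raise ValueError("at least 3 points are required")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ca - rotation @ cb
    fitted = b0 @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - a0) ** 2, axis=1))))
    return rotation, translation, rmsd


def annotation_to_tsv(annotation: PPRAnnotation, path) -> None:
    """Dump an annotation as TSV: index, spans, helix spans, code residues."""
    with open(path, "w") as fh:
        fh.write("index\tstart\tend\thelixA_span\thelixB_span\taa5\taa35\n")
        for m in annotation.motifs:
            ha = f"{m.helix_a.start_residue}-{m.helix_a.end_residue}" if m.helix_a else "."
            hb = f"{m.helix_b.start_residue}-{m.helix_b.end_residue}" if m.helix_b else "."
            fh.write(
                f"{m.index}\t{m.start_residue}\t{m.end_residue}\t{ha}\t{hb}\t"
                f"{m.aa5 or '.'}\t{m.aa35 or '.'}\n"
            )
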