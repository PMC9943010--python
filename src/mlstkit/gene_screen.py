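"""Presence/absence screening of target genes in assemblies.

Built around the four histidine-utilization genes (*hutH*, *hutU*, *hutI*,
*hutG*) whose chain converts histidine to glutamate: a strain is scored
"capable" of glutamate synthesis from histidine only when all four genes are
present, since any missing link breaks the pathway
(hutH: histidine→urocanate, hutU: urocanate→imidazolone propionate,
hutI: →formiminoglutamate, hutG: →glutamate).

A gene is present when its best hit reaches both an identity and a coverage
threshold (defaults 0.80 / 0.70). Nucleotide references are screened by exact
substring search plus local alignment on both strands; protein references by
local alignment against all six translation frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

DEFAULT_ID_THRESHOLD = 0.80
DEFAULT_COV_THRESHOLD = 0.70

HUT_ROLES = {
    "hutH": "histidine -> urocanate",
    "hutU": "urocanate -> imidazolone propionate",
    "hutI": "imidazolone propionate -> formiminoglutamate",
    "hutG": "formiminoglutamate -> glutamate",
}

_NUC_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class GeneRef:
    """A reference gene for screening (nucleotide or protein sequence)."""

    gene: str
    sequence: str
    role: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.gene}: empty reference sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def is_protein(self) -> bool:
        return bool(set(self.sequence) - _NUC_ALPHABET)


@dataclass(frozen=True)
class GeneHit:
    contig: str
    start: int  # 0-based half-open, forward strand, nucleotide coordinates
    end: int
    strand: str
    identity: float
    coverage: float


@dataclass(frozen=True)
class GeneResult:
    gene: str
    present: bool
    identity: float
    coverage: float
    hit: GeneHit | None


@dataclass
class GeneScreenResult:
    strain: str
    genes: dict[str, GeneResult]

    def presence(self) -> dict[str, bool]:
        return {g: r.present for g, r in self.genes.items()}


def load_gene_refs(path) -> list[GeneRef]:
    """Load references from FASTA; alphabet decides nucleotide vs protein."""
    refs = [
        GeneRef(gene=rec.id, sequence=str(rec.seq), role=HUT_ROLES.get(rec.id, ""))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not refs:
        raise ValueError(f"{path}: no reference sequences")
    return refs


def _nucleotide_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _alignment_identity_coverage(alignment, ref_length: int) -> tuple[float, float, int, int]:
    """(identity over aligned columns, reference coverage, target start, target end)."""
    counts = alignment.counts()
    aligned_cols = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / aligned_cols if aligned_cols else 0.0
    q_start, q_end = alignment.aligned[0][0][0], alignment.aligned[0][-1][1]
    coverage = (q_end - q_start) / ref_length
    t_start, t_end = alignment.aligned[1][0][0], alignment.aligned[1][-1][1]
    return identity, coverage, t_start, t_end


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _screen_nucleotide(assembly: dict[str, str], ref: GeneRef) -> GeneHit | None:
    # exact occurrence short-circuits the alignment scan
    for contig, seq in assembly.items():
        idx = seq.find(ref.sequence)
        if idx != -1:
            return GeneHit(contig, idx, idx + len(ref.sequence), "+", 1.0, 1.0)
        idx = seq.find(_revcomp(ref.sequence))
        if idx != -1:
            return GeneHit(contig, idx, idx + len(ref.sequence), "-", 1.0, 1.0)

    aligner = _nucleotide_aligner()
    best: GeneHit | None = None
    best_score = 0.0
    for contig, seq in assembly.items():
        for strand in "+-":
            target = seq if strand == "+" else _revcomp(seq)
            alignments = aligner.align(ref.sequence, target)
            if len(alignments) == 0 or alignments.score <= 0:
                continue
            identity, coverage, t_start, t_end = _alignment_identity_coverage(
                alignments[0], len(ref.sequence)
            )
            if strand == "-":
                t_start, t_end = len(seq) - t_end, len(seq) - t_start
            score = identity * coverage
            if score > best_score:
                best_score = score
                best = GeneHit(contig, t_start, t_end, strand, identity, coverage)
    return best


def _screen_protein(assembly: dict[str, str], ref: GeneRef) -> GeneHit | None:
    aligner = _protein_aligner()
    best: GeneHit | None = None
    best_score = 0.0
    for contig, seq in assembly.items():
        for strand in "+-":
            oriented = seq if strand == "+" else _revcomp(seq)
            for frame in range(3):
                sub = oriented[frame:]
                sub = sub[: len(sub) - len(sub) % 3]
                if not sub:
                    continue
                protein = str(Seq(sub).translate())
                # align against each stop-free segment
                offset = 0
                for segment in protein.split("*"):
                    if len(segment) >= 10:  # skip hopeless scraps
                        alignments = aligner.align(ref.sequence, segment)
                        if len(alignments) and alignments.score > 0:
                            identity, coverage, t_start, t_end = (
                                _alignment_identity_coverage(alignments[0], len(ref.sequence))
                            )
                            score = identity * coverage
                            if score > best_score:
                                aa_start = offset + t_start
                                aa_end = offset + t_end
                                nt_start = frame + 3 * aa_start
                                nt_end = frame + 3 * aa_end
                                if strand == "-":
                                    nt_start, nt_end = (
                                        len(seq) - nt_end,
                                        len(seq) - nt_start,
                                    )
                                best_score = score
                                best = GeneHit(
                                    contig, nt_start, nt_end, strand, identity, coverage
                                )
                    offset += len(segment) + 1
    return best


def screen_gene(
    assembly: dict[str, str],
    ref: GeneRef,
    id_threshold: float = DEFAULT_ID_THRESHOLD,
    cov_threshold: float = DEFAULT_COV_THRESHOLD,
) -> GeneResult:
    """Screen one assembly for one reference gene.

    The best hit over all contigs/strands (six frames for protein references)
    is scored by identity × coverage; the gene is present iff identity and
    coverage both reach their thresholds.
    """
    hit = (
        _screen_protein(assembly, ref)
        if ref.is_protein
        else _screen_nucleotide(assembly, ref)
    )
    if hit is None:
        return GeneResult(gene=ref.gene, present=False, identity=0.0, coverage=0.0, hit=None)
    present = hit.identity >= id_threshold and hit.coverage >= cov_threshold
    return GeneResult(
        gene=ref.gene, present=present, identity=hit.identity, coverage=hit.coverage, hit=hit
    )


def screen_assembly(
    assembly: dict[str, str],
    refs: Sequence[GeneRef],
    strain: str = "strain",
    id_threshold: float = DEFAULT_ID_THRESHOLD,
    cov_threshold: float = DEFAULT_COV_THRESHOLD,
) -> GeneScreenResult:
    return GeneScreenResult(
        strain=strain,
        genes={
            ref.gene: screen_gene(assembly, ref, id_threshold, cov_threshold)
            for ref in refs
        },
    )


def hut_status(screen: GeneScreenResult) -> dict:
    """Glutamate-from-histidine capability verdict for one strain.

    Capable iff all four hut genes are present — the pathway is a chain, so
    any missing gene breaks it.
    """
    required = ("hutH", "hutU", "hutI", "hutG")
    missing = [g for g in required if g not in screen.genes]
    if missing:
        raise ValueError(f"{screen.strain}: screen lacks genes {missing}")
    flags = {g: screen.genes[g].present for g in required}
    return {
        "strain": screen.strain,
        "capable": all(flags.values()),
        **flags,
    }


def st_gene_association(
    st_by_strain: dict[str, int | None],
    screens: Sequence[GeneScreenResult],
) -> tuple[pd.DataFrame, pd.DataFrame, list[int]]:
    """Associate hut capability with STs.

    Returns (per-strain table, per-gene summary counts, list of STs whose
    members are uniformly incapable). Strains present in only one input are
    excluded with a warning.
    """
    screen_by_strain = {s.strain: s for s in screens}
    common = [s for s in screen_by_strain if s in st_by_strain]
    dropped = (set(screen_by_strain) | set(st_by_strain)) - set(common)
    if dropped:
        logger.warning("st_gene_association: excluded strains %s", sorted(dropped))

    rows = []
    for strain in common:
        verdict = hut_status(screen_by_strain[strain])
        verdict["st"] = st_by_strain[strain]
        rows.append(verdict)
    table = pd.DataFrame(
        rows, columns=["strain", "st", "capable", "hutH", "hutU", "hutI", "hutG"]
    )

    summary = pd.DataFrame(
        {
            "n_strains": [len(table)],
            **{g: [int(table[g].sum())] for g in ("hutH", "hutU", "hutI", "hutG")},
        }
    )

    flagged = []
    for st, group in table.dropna(subset=["st"]).groupby("st"):
        if not group["capable"].any():
            flagged.append(int(st))
    return table, summary, sorted(flagged)
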