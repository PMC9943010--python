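"""In-silico MLST typing of genome assemblies.

For each scheme locus the typer locates the locus in the assembly (exact
substring search for every known allele on both strands, with an infix-
alignment fallback for divergent alleles), extracts the sequence in database
orientation, calls the allele (exact / novel / missing / ambiguous), and
derives the sequence type from the combination of allele numbers.

Two novel-allele policies are supported: ``extend`` assigns new allele and ST
numbers by continuation (``max + 1``), growing the database as public MLST
registries do; ``strict`` leaves the database untouched and reports novel
sequences without a number.

Coordinates are 0-based half-open on the contig's forward strand; extracted
sequences are reported in database orientation (reverse-complemented for
minus-strand hits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .scheme_db import (
    AlleleProfile,
    LocusAlleleSet,
    MLSTDatabase,
    VALID_BASES,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 0.90


class AmbiguousLocusError(RuntimeError):
    """Two or more non-overlapping qualifying hits for one locus."""


@dataclass(frozen=True)
class LocusHit:
    locus: str
    contig: str
    start: int
    end: int
    strand: str
    sequence: str  # oriented to match the allele database
    identity: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad hit coordinates [{self.start}, {self.end})")


@dataclass(frozen=True)
class AlleleCall:
    locus: str
    status: str  # exact | novel | missing | ambiguous
    allele_number: int | None
    hit: LocusHit | None


@dataclass
class TypingResult:
    strain: str
    scheme: str
    calls: dict[str, AlleleCall]
    st: int | None
    st_status: str  # known | novel | undefined

    @property
    def profile(self) -> dict[str, int] | None:
        if any(c.allele_number is None for c in self.calls.values()):
            return None
        return {locus: c.allele_number for locus, c in self.calls.items()}


def read_assembly(path: str | Path) -> dict[str, str]:
    """Load a (multi-)contig assembly FASTA as {contig id: uppercase sequence}."""
    return {
        record.id: str(record.seq).upper()
        for record in SeqIO.parse(str(path), "fasta")
    }


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _overlap(a: LocusHit, b: LocusHit) -> bool:
    return a.contig == b.contig and a.start < b.end and b.start < a.end


def _resolve_hits(hits: list[LocusHit]) -> LocusHit:
    """Return the single best hit, or raise if distinct loci compete.

    Hits at non-overlapping positions are genuinely ambiguous. Mutually
    overlapping hits (e.g. forward and reverse matches over the same span)
    are resolved deterministically: highest identity, then plus strand,
    then leftmost.
    """
    if len(hits) == 1:
        return hits[0]
    for i, a in enumerate(hits):
        for b in hits[i + 1 :]:
            if not _overlap(a, b):
                raise AmbiguousLocusError(
                    f"{a.locus}: non-overlapping hits at "
                    f"{a.contig}:{a.start} and {b.contig}:{b.start}"
                )
    return sorted(
        hits, key=lambda h: (-h.identity, h.strand != "+", h.contig, h.start)
    )[0]


def locate_locus(
    assembly: dict[str, str],
    locus: str,
    allele_set: LocusAlleleSet,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> LocusHit | None:
    """Locate one scheme locus in an assembly.

    Stage 1 searches every known allele verbatim on both strands; a unique
    occurrence returns immediately with identity 1.0. Stage 2 falls back to
    infix alignment (full allele against each contig/strand) and accepts the
    best span if its identity is at least ``min_identity``. Returns None when
    the locus cannot be found; raises :class:`AmbiguousLocusError` when two
    or more non-overlapping spans qualify equally.
    """
    if not allele_set.alleles:
        raise ValueError(f"{locus}: empty allele set")

    exact: list[LocusHit] = []
    for contig, seq in assembly.items():
        for number, allele in allele_set.alleles.items():
            for start in _find_all(seq, allele):
                exact.append(
                    LocusHit(
                        locus=locus,
                        contig=contig,
                        start=start,
                        end=start + len(allele),
                        strand="+",
                        sequence=allele,
                        identity=1.0,
                    )
                )
            rc = _revcomp(allele)
            for start in _find_all(seq, rc):
                exact.append(
                    LocusHit(
                        locus=locus,
                        contig=contig,
                        start=start,
                        end=start + len(allele),
                        strand="-",
                        sequence=allele,
                        identity=1.0,
                    )
                )
    if exact:
        return _resolve_hits(exact)

    # Stage 2: infix alignment of every known allele against every contig and
    # strand; identity is measured over the full allele length.
    best: list[LocusHit] = []
    best_identity = min_identity
    for contig, seq in assembly.items():
        for strand in "+-":
            target = seq if strand == "+" else _revcomp(seq)
            for number, allele in allele_set.alleles.items():
                max_dist = int(len(allele) * (1.0 - min_identity)) + 1
                aln = edlib.align(allele, target, mode="HW", task="locations", k=max_dist)
                if aln["editDistance"] < 0:
                    continue
                identity = 1.0 - aln["editDistance"] / len(allele)
                if identity + 1e-12 < best_identity:
                    continue
                loc_start, loc_end = aln["locations"][0]
                loc_end += 1  # edlib end is inclusive
                if strand == "+":
                    start, end = loc_start, loc_end
                    extracted = seq[start:end]
                else:
                    start, end = len(seq) - loc_end, len(seq) - loc_start
                    extracted = _revcomp(seq[start:end])
                hit = LocusHit(
                    locus=locus,
                    contig=contig,
                    start=start,
                    end=end,
                    strand=strand,
                    sequence=extracted,
                    identity=identity,
                )
                if identity > best_identity + 1e-12:
                    best = [hit]
                    best_identity = identity
                else:
                    best.append(hit)
    if not best:
        return None
    # drop duplicate spans found via different database alleles
    unique = list({(h.contig, h.start, h.end, h.strand): h for h in best}.values())
    return _resolve_hits(unique)


def call_allele(
    hit: LocusHit | None,
    allele_set: LocusAlleleSet,
    mode: str = "extend",
) -> AlleleCall:
    """Call the allele for one locus hit.

    No hit → missing. Exact database sequence → exact with its number.
    Otherwise the sequence is novel: in ``extend`` mode it is registered by
    continuation numbering; in ``strict`` mode it is reported without a
    number and the database is untouched. Hits containing ambiguous bases can
    never be exact and are never registered.
    """
    if mode not in ("strict", "extend"):
        raise ValueError(f"unknown mode {mode!r}")
    if hit is None:
        return AlleleCall(locus=allele_set.locus, status="missing", allele_number=None, hit=None)
    seq = hit.sequence.upper()
    number = allele_set.number_of(seq)
    if number is not None:
        return AlleleCall(locus=allele_set.locus, status="exact", allele_number=number, hit=hit)
    if set(seq) - VALID_BASES:
        logger.warning(
            "%s: hit at %s:%d contains ambiguous bases; reported novel, not registered",
            allele_set.locus, hit.contig, hit.start,
        )
        return AlleleCall(locus=allele_set.locus, status="novel", allele_number=None, hit=hit)
    if mode == "extend":
        number, _ = allele_set.register(seq)
        return AlleleCall(locus=allele_set.locus, status="novel", allele_number=number, hit=hit)
    return AlleleCall(locus=allele_set.locus, status="novel", allele_number=None, hit=hit)


def type_assembly(
    assembly: dict[str, str],
    db: MLSTDatabase,
    strain: str = "strain",
    mode: str = "extend",
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> TypingResult:
    """Type one assembly against a scheme database.

    All loci are called; when every call carries an allele number the profile
    is looked up in (extend: or registered into) the profile table. The ST
    status is ``known`` for a registered profile, ``novel`` for a new one
    (numbered only in extend mode), and ``undefined`` when any locus call
    lacks an allele number.
    """
    calls: dict[str, AlleleCall] = {}
    for locus in db.scheme.loci:
        allele_set = db.alleles[locus]
        try:
            hit = locate_locus(assembly, locus, allele_set, min_identity=min_identity)
        except AmbiguousLocusError:
            calls[locus] = AlleleCall(
                locus=locus, status="ambiguous", allele_number=None, hit=None
            )
            continue
        calls[locus] = call_allele(hit, allele_set, mode=mode)

    numbers = {locus: c.allele_number for locus, c in calls.items()}
    if any(n is None for n in numbers.values()):
        return TypingResult(strain=strain, scheme=db.scheme.name, calls=calls,
                            st=None, st_status="undefined")
    profile = AlleleProfile.from_dict(numbers, db.scheme)
    existing = db.profiles.st_of(profile)
    if existing is not None:
        return TypingResult(strain=strain, scheme=db.scheme.name, calls=calls,
                            st=existing, st_status="known")
    if mode == "extend":
        st, _ = db.profiles.register(profile)
        return TypingResult(strain=strain, scheme=db.scheme.name, calls=calls,
                            st=st, st_status="novel")
    return TypingResult(strain=strain, scheme=db.scheme.name, calls=calls,
                        st=None, st_status="novel")


def type_collection(
    assemblies: list[tuple[str, dict[str, str]]],
    db: MLSTDatabase,
    mode: str = "extend",
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[TypingResult]:
    """Type an ordered collection of assemblies against one shared database.

    Novel alleles and STs are numbered incrementally in input order, so a
    rerun on the same ordered input reproduces the numbering exactly. The
    partition of strains into STs does not depend on the order (only the
    labels of novel STs do).
    """
    results = []
    for strain, assembly in assemblies:
        result = type_assembly(assembly, db, strain=strain, mode=mode,
                               min_identity=min_identity)
        if result.st_status == "novel":
            logger.warning("%s: novel ST %s", strain, result.st)
        results.append(result)
    return results


def typing_table(results: list[TypingResult]) -> pd.DataFrame:
    """Long-format per-locus typing table (one row per strain × locus)."""
    rows = []
    for r in results:
        for locus, call in r.calls.items():
            h = call.hit
            rows.append(
                {
                    "strain": r.strain,
                    "scheme": r.scheme,
                    "locus": locus,
                    "status": call.status,
                    "allele": call.allele_number,
                    "contig": h.contig if h else None,
                    "start": h.start if h else None,
                    "end": h.end if h else None,
                    "strand": h.strand if h else None,
                    "identity": h.identity if h else None,
                    "st": r.st,
                    "st_status": r.st_status,
                }
            )
    return pd.DataFrame(rows)


def st_table(results: list[TypingResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"strain": r.strain, "scheme": r.scheme, "st": r.st, "st_status": r.st_status}
            for r in results
        ]
    )
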