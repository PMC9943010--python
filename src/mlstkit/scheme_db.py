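"""MLST scheme databases: locus definitions, allele sets, and ST profile tables.

An MLST scheme is an ordered list of housekeeping loci. For each locus a
database maps allele numbers (positive integers) to nucleotide sequences;
a profile table maps sequence-type (ST) numbers to complete allele-number
profiles. Both maps are bijections and grow monotonically: novel alleles
and STs always receive ``max(existing) + 1``, mirroring how public MLST
registries extend their numbering.

File formats follow the PubMLST conventions: per-locus allele FASTA with
headers ``<locus>_<number>`` and a tab-delimited profile table whose first
column is ``ST`` followed by one column per locus in scheme order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")


class SchemeFormatError(ValueError):
    """Raised for malformed scheme, allele, or profile input."""


# Builtin scheme definitions. P1 and S1 use the same loci (only concatenation
# order differs), so only P1 is instantiated. S2 loci are full genes; the
# remaining schemes use internal gene fragments.
_BUILTIN_SCHEMES = {
    "P1": (["glpF", "ilvD", "pta", "purH", "pycA", "rpoD", "tpiA"], "fragment"),
    "S2": (
        ["gyrA", "gyrB", "purH", "glpF", "pycA", "ilvD", "rpoD", "tpiA", "pta"],
        "full_gene",
    ),
    "S3": (["gyrB", "adk", "pycA", "pyrE", "sucC", "mutL", "aroE"], "fragment"),
    "L1": (["adk", "ccpA", "glpF", "gmk", "ilvD", "pur", "spo0A", "tpi"], "fragment"),
}


@dataclass(frozen=True)
class SchemeDefinition:
    """A named MLST scheme: ordered loci plus per-scheme locus mode.

    ``locus_mode`` is ``"fragment"`` (fixed-length internal fragments; equal
    allele lengths enforced) or ``"full_gene"`` (whole ORFs; lengths may vary).
    """

    name: str
    loci: tuple[str, ...]
    locus_mode: str = "fragment"

    def __post_init__(self) -> None:
        if not self.loci:
            raise SchemeFormatError("scheme must define at least one locus")
        if len(set(self.loci)) != len(self.loci):
            raise SchemeFormatError(f"duplicate locus names in scheme {self.name!r}")
        if self.locus_mode not in ("fragment", "full_gene"):
            raise SchemeFormatError(f"unknown locus_mode {self.locus_mode!r}")
        object.__setattr__(self, "loci", tuple(self.loci))


def builtin_scheme(name: str) -> SchemeDefinition:
    """Return one of the builtin scheme definitions (P1, S2, S3, L1)."""
    try:
        loci, mode = _BUILTIN_SCHEMES[name]
    except KeyError:
        raise KeyError(
            f"no builtin scheme {name!r}; available: {sorted(_BUILTIN_SCHEMES)}"
        ) from None
    return SchemeDefinition(name=name, loci=tuple(loci), locus_mode=mode)


def builtin_scheme_names() -> list[str]:
    return list(_BUILTIN_SCHEMES)


def load_scheme_definition(path: str | Path) -> SchemeDefinition:
    """Load a scheme definition from a YAML config file.

    Expected keys: ``name`` (str), ``loci`` (ordered list of locus names) and
    optionally ``locus_mode``.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "name" not in data or "loci" not in data:
        raise SchemeFormatError(f"{path}: scheme config needs 'name' and 'loci'")
    loci = data["loci"]
    if not isinstance(loci, list) or not loci:
        raise SchemeFormatError(f"{path}: 'loci' must be a non-empty list")
    return SchemeDefinition(
        name=str(data["name"]),
        loci=tuple(str(x) for x in loci),
        locus_mode=data.get("locus_mode", "fragment"),
    )


def write_scheme_definition(scheme: SchemeDefinition, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "name": scheme.name,
                "loci": list(scheme.loci),
                "locus_mode": scheme.locus_mode,
            },
            fh,
            sort_keys=False,
        )


def _validate_sequence(seq: str, *, where: str) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise SchemeFormatError(
            f"{where}: sequence contains non-ACGT characters {sorted(bad)}"
        )
    return seq


@dataclass
class LocusAlleleSet:
    """Bijective allele-number → sequence map for one locus.

    In fragment mode (``enforce_equal_length=True``) every allele must have
    the same length; full-gene loci may carry length variation.
    """

    locus: str
    alleles: dict[int, str] = field(default_factory=dict)
    enforce_equal_length: bool = True

    def __post_init__(self) -> None:
        clean: dict[int, str] = {}
        for number, seq in self.alleles.items():
            clean[int(number)] = _validate_sequence(
                seq, where=f"{self.locus} allele {number}"
            )
        self.alleles = clean
        self._seq_to_number = {}
        for number, seq in self.alleles.items():
            if number < 1:
                raise SchemeFormatError(
                    f"{self.locus}: allele numbers must be positive, got {number}"
                )
            if seq in self._seq_to_number:
                raise SchemeFormatError(
                    f"{self.locus}: alleles {self._seq_to_number[seq]} and {number} "
                    "share the same sequence"
                )
            self._seq_to_number[seq] = number
        self._check_lengths()

    def _check_lengths(self) -> None:
        if self.enforce_equal_length and self.alleles:
            lengths = {len(s) for s in self.alleles.values()}
            if len(lengths) > 1:
                raise SchemeFormatError(
                    f"{self.locus}: unequal allele lengths {sorted(lengths)} "
                    "in fragment mode"
                )

    def __len__(self) -> int:
        return len(self.alleles)

    def __contains__(self, seq: str) -> bool:
        return seq.upper() in self._seq_to_number

    @property
    def length(self) -> int | None:
        """Common allele length (fragment mode) or None if empty/variable."""
        lengths = {len(s) for s in self.alleles.values()}
        return lengths.pop() if len(lengths) == 1 else None

    def number_of(self, seq: str) -> int | None:
        return self._seq_to_number.get(seq.upper())

    def sequence_of(self, number: int) -> str:
        return self.alleles[number]

    def register(self, seq: str) -> tuple[int, bool]:
        """Return the allele number for ``seq``, registering it if novel.

        Novel sequences get ``max(existing) + 1`` (1 for an empty set).
        Idempotent: re-registering returns the same number with is_new=False.
        """
        seq = _validate_sequence(seq, where=f"{self.locus} candidate allele")
        existing = self._seq_to_number.get(seq)
        if existing is not None:
            return existing, False
        if self.enforce_equal_length and self.alleles:
            expect = self.length
            if expect is not None and len(seq) != expect:
                raise SchemeFormatError(
                    f"{self.locus}: candidate length {len(seq)} != allele "
                    f"length {expect}"
                )
        number = max(self.alleles, default=0) + 1
        self.alleles[number] = seq
        self._seq_to_number[seq] = number
        return number, True


def register_allele(allele_set: LocusAlleleSet, seq: str) -> tuple[int, bool]:
    """Functional alias for :meth:`LocusAlleleSet.register`."""
    return allele_set.register(seq)


def load_allele_fasta(
    path: str | Path, locus: str | None = None, *, enforce_equal_length: bool = True
) -> LocusAlleleSet:
    """Load a PubMLST-style per-locus allele FASTA (headers ``locus_N``)."""
    path = Path(path)
    alleles: dict[int, str] = {}
    inferred_locus = locus
    for record in SeqIO.parse(str(path), "fasta"):
        name, _, num = record.id.rpartition("_")
        if not name or not num.isdigit():
            raise SchemeFormatError(
                f"{path}: header {record.id!r} does not match '<locus>_<number>'"
            )
        if inferred_locus is None:
            inferred_locus = name
        elif name != inferred_locus:
            raise SchemeFormatError(
                f"{path}: header locus {name!r} != expected {inferred_locus!r}"
            )
        number = int(num)
        if number in alleles:
            raise SchemeFormatError(f"{path}: duplicate allele number {record.id}")
        alleles[number] = str(record.seq)
    if not alleles:
        logger.warning("%s: empty allele FASTA", path)
    return LocusAlleleSet(
        locus=inferred_locus or path.stem,
        alleles=alleles,
        enforce_equal_length=enforce_equal_length,
    )


def write_allele_fasta(allele_set: LocusAlleleSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=f"{allele_set.locus}_{number}", description="")
        for number, seq in sorted(allele_set.alleles.items())
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class AlleleProfile:
    """A complete locus → allele-number assignment for one scheme."""

    calls: tuple[tuple[str, int], ...]

    @classmethod
    def from_dict(cls, calls: dict[str, int], scheme: SchemeDefinition) -> "AlleleProfile":
        missing = set(scheme.loci) - set(calls)
        extra = set(calls) - set(scheme.loci)
        if missing or extra:
            raise SchemeFormatError(
                f"profile loci mismatch for scheme {scheme.name}: "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        return cls(calls=tuple((locus, int(calls[locus])) for locus in scheme.loci))

    def as_dict(self) -> dict[str, int]:
        return dict(self.calls)

    def numbers(self) -> tuple[int, ...]:
        return tuple(n for _, n in self.calls)

    def loci(self) -> tuple[str, ...]:
        return tuple(l for l, _ in self.calls)


@dataclass
class ProfileTable:
    """Bijective ST-number → allele-profile registry for one scheme."""

    scheme: SchemeDefinition
    profiles: dict[int, AlleleProfile] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._profile_to_st: dict[AlleleProfile, int] = {}
        for st, profile in self.profiles.items():
            if st < 1:
                raise SchemeFormatError(f"ST numbers must be positive, got {st}")
            if profile in self._profile_to_st:
                raise SchemeFormatError(
                    f"STs {self._profile_to_st[profile]} and {st} share a profile"
                )
            self._profile_to_st[profile] = st

    def __len__(self) -> int:
        return len(self.profiles)

    def st_of(self, profile: AlleleProfile) -> int | None:
        return self._profile_to_st.get(profile)

    def register(self, profile: AlleleProfile) -> tuple[int, bool]:
        """Return the ST for a profile, assigning ``max(existing)+1`` if novel."""
        if set(profile.loci()) != set(self.scheme.loci):
            raise SchemeFormatError(
                f"profile loci {profile.loci()} do not match scheme "
                f"{self.scheme.name} loci {self.scheme.loci}"
            )
        existing = self._profile_to_st.get(profile)
        if existing is not None:
            return existing, False
        st = max(self.profiles, default=0) + 1
        self.profiles[st] = profile
        self._profile_to_st[profile] = st
        return st, True


def register_profile(table: ProfileTable, profile: AlleleProfile) -> tuple[int, bool]:
    """Functional alias for :meth:`ProfileTable.register`."""
    return table.register(profile)


def load_profile_table(path: str | Path, scheme: SchemeDefinition) -> ProfileTable:
    """Load a TSV profile table with header ``ST <tab> locus1 ... locusK``."""
    path = Path(path)
    profiles: dict[int, AlleleProfile] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise SchemeFormatError(f"{path}: empty profile table")
    header = lines[0].split("\t")
    if header[0] != "ST":
        raise SchemeFormatError(f"{path}: first column must be 'ST', got {header[0]!r}")
    loci = header[1:]
    if set(loci) != set(scheme.loci):
        raise SchemeFormatError(
            f"{path}: profile columns {loci} do not match scheme loci {scheme.loci}"
        )
    for line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != len(header):
            raise SchemeFormatError(f"{path}: ragged row {line!r}")
        st = int(fields[0])
        calls = {locus: int(v) for locus, v in zip(loci, fields[1:])}
        if st in profiles:
            raise SchemeFormatError(f"{path}: duplicate ST {st}")
        profiles[st] = AlleleProfile.from_dict(calls, scheme)
    return ProfileTable(scheme=scheme, profiles=profiles)


def write_profile_table(table: ProfileTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ST\t" + "\t".join(table.scheme.loci) + "\n")
        for st in sorted(table.profiles):
            calls = table.profiles[st].as_dict()
            fh.write(
                str(st)
                + "\t"
                + "\t".join(str(calls[locus]) for locus in table.scheme.loci)
                + "\n"
            )


@dataclass
class MLSTDatabase:
    """A scheme definition together with its allele sets and profile table."""

    scheme: SchemeDefinition
    alleles: dict[str, LocusAlleleSet]
    profiles: ProfileTable

    def __post_init__(self) -> None:
        missing = set(self.scheme.loci) - set(self.alleles)
        if missing:
            raise SchemeFormatError(
                f"database for scheme {self.scheme.name} lacks allele sets "
                f"for loci {sorted(missing)}"
            )

    @classmethod
    def empty(cls, scheme: SchemeDefinition) -> "MLSTDatabase":
        enforce = scheme.locus_mode == "fragment"
        return cls(
            scheme=scheme,
            alleles={
                locus: LocusAlleleSet(locus=locus, enforce_equal_length=enforce)
                for locus in scheme.loci
            },
            profiles=ProfileTable(scheme=scheme),
        )

    @classmethod
    def load(cls, scheme: SchemeDefinition, directory: str | Path) -> "MLSTDatabase":
        """Load ``<locus>.fasta`` per locus plus ``profiles.tsv`` from a directory."""
        directory = Path(directory)
        enforce = scheme.locus_mode == "fragment"
        alleles = {
            locus: load_allele_fasta(
                directory / f"{locus}.fasta", locus, enforce_equal_length=enforce
            )
            for locus in scheme.loci
        }
        profile_path = directory / "profiles.tsv"
        if profile_path.exists():
            profiles = load_profile_table(profile_path, scheme)
        else:
            profiles = ProfileTable(scheme=scheme)
        return cls(scheme=scheme, alleles=alleles, profiles=profiles)

    def save(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for locus in self.scheme.loci:
            p = directory / f"{locus}.fasta"
            write_allele_fasta(self.alleles[locus], p)
            written.append(p)
        p = directory / "profiles.tsv"
        write_profile_table(self.profiles, p)
        written.append(p)
        p = directory / "scheme.yaml"
        write_scheme_definition(self.scheme, p)
        written.append(p)
        return written


def concatenate_profile(
    profile: AlleleProfile,
    sets: dict[str, LocusAlleleSet] | Iterable[LocusAlleleSet],
    scheme: SchemeDefinition,
) -> str:
    """Join a profile's allele sequences in the scheme's locus order.

    This is the concatenation used for exporting per-ST sequences to external
    tree builders; no separators are inserted.
    """
    if not isinstance(sets, dict):
        sets = {s.locus: s for s in sets}
    calls = profile.as_dict()
    parts = []
    for locus in scheme.loci:
        number = calls[locus]
        try:
            parts.append(sets[locus].sequence_of(number))
        except KeyError:
            raise SchemeFormatError(
                f"allele {locus}_{number} not present in database"
            ) from None
    return "".join(parts)
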