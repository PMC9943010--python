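"""Synthetic study populations with known ground truth.

Generates everything the downstream stages consume — per-locus allele pools
derived from a stop-free ancestral ORF by point mutation with a controllable
synonymous/non-synonymous balance, a strain population with a planted
ST-frequency distribution, and genome assemblies embedding the planted
alleles on random strands between random flanking sequence — plus a truth
table recording every planted allele, ST, placement, and *hut*-gene genotype.

Defaults emulate the study population this package was built around:
39 food-isolate genomes carrying 31 distinct sequence types under a 7-locus
housekeeping scheme, with 7 strains carrying deletions of the *hutH*/*hutI*/
*hutG* histidine-utilization genes (always retaining *hutU*). Knockouts are
planted clonally (whole STs at a time), reflecting that gene loss is a
lineage trait.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scheme_db import (
    AlleleProfile,
    LocusAlleleSet,
    MLSTDatabase,
    ProfileTable,
    SchemeDefinition,
)

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
BASES = "ACGT"

HUT_GENES = ("hutH", "hutU", "hutI", "hutG")
# Deterministic seeds for the synthetic hut reference ORFs; fixed so the
# reference set is identical across runs and configs.
_HUT_SEEDS = {"hutH": 11, "hutU": 22, "hutI": 33, "hutG": 44}
_HUT_LENGTH = 900


class SimulationError(RuntimeError):
    """Raised when the generator cannot satisfy the requested configuration."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    ``mutation_rate`` is the expected substitutions per site between the
    ancestor and each derived allele; ``syn_bias`` is the probability that an
    introduced substitution is synonymous (0.7 by default, giving dN/dS well
    below 1 as expected for housekeeping genes under purifying selection).
    ``st_frequencies`` is an optional probability vector over the planted STs
    used to assign the strains that remain after each ST has received one
    strain; None means uniform.
    """

    seed: int = 0
    n_loci: int = 7
    locus_length: int = 450
    n_alleles_per_locus: int = 6
    mutation_rate: float = 0.01
    syn_bias: float = 0.7
    n_strains: int = 39
    n_STs: int = 31
    st_frequencies: Sequence[float] | None = None
    flank_length: int = 300
    hut_knockout_fraction: float = 7 / 39
    hut_knockout_genes: tuple[str, ...] = ("hutH", "hutI", "hutG")
    contig_split: bool = True
    scheme_name: str = "SYN"

    def __post_init__(self) -> None:
        if self.locus_length % 3 != 0:
            raise ValueError("locus_length must be a multiple of 3")
        for name in ("n_loci", "locus_length", "n_alleles_per_locus", "n_strains", "n_STs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_STs > self.n_strains:
            raise ValueError("n_STs cannot exceed n_strains")
        if self.st_frequencies is not None:
            freqs = np.asarray(self.st_frequencies, dtype=float)
            if len(freqs) != self.n_STs:
                raise ValueError("st_frequencies length must equal n_STs")
            if abs(freqs.sum() - 1.0) > 1e-9:
                raise ValueError("st_frequencies must sum to 1")
        unknown = set(self.hut_knockout_genes) - set(HUT_GENES)
        if unknown:
            raise ValueError(f"unknown hut genes {sorted(unknown)}")
        if "hutU" in self.hut_knockout_genes:
            raise ValueError("hutU is retained in all strains; cannot knock out")

    def loci(self) -> tuple[str, ...]:
        return tuple(f"locus{i + 1:02d}" for i in range(self.n_loci))

    def scheme(self) -> SchemeDefinition:
        return SchemeDefinition(name=self.scheme_name, loci=self.loci())


@dataclass
class Placement:
    """Where one planted feature landed in the emitted assembly."""

    feature: str  # locus or hut gene name
    contig: str
    start: int  # 0-based half-open, forward strand
    end: int
    strand: str  # '+' or '-'


@dataclass
class StrainTruth:
    strain: str
    profile: AlleleProfile
    st: int
    hut_present: dict[str, bool]
    placements: list[Placement] = field(default_factory=list)


@dataclass
class TruthTable:
    """Ground truth for one simulated population."""

    strains: list[StrainTruth]
    polymorphic_sites: dict[str, int]  # per-locus count over the allele pool

    def st_of(self, strain: str) -> int:
        return next(s.st for s in self.strains if s.strain == strain)

    def planted_sts(self) -> dict[str, int]:
        return {s.strain: s.st for s in self.strains}

    def knockout_strains(self) -> list[str]:
        return [s.strain for s in self.strains if not all(s.hut_present.values())]

    def knockout_sts(self) -> set[int]:
        return {s.st for s in self.strains if not all(s.hut_present.values())}

    def write_tsv(self, path: str | Path, loci: Sequence[str]) -> None:
        with open(path, "w") as fh:
            cols = ["strain", "ST", *loci, *HUT_GENES]
            fh.write("\t".join(cols) + "\n")
            for s in self.strains:
                calls = s.profile.as_dict()
                row = [s.strain, str(s.st)]
                row += [str(calls[locus]) for locus in loci]
                row += ["1" if s.hut_present[g] else "0" for g in HUT_GENES]
                fh.write("\t".join(row) + "\n")


def _random_orf(rng: np.random.Generator, length: int) -> str:
    """A random in-frame coding sequence with no stop codons."""
    n_codons = length // 3
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def _synonymous_options(codon: str, pos: int) -> list[str]:
    aa = _TABLE.forward_table[codon]
    out = []
    for b in BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if alt not in STOP_CODONS and _TABLE.forward_table[alt] == aa:
            out.append(b)
    return out


def _nonsynonymous_options(codon: str, pos: int) -> list[str]:
    aa = _TABLE.forward_table[codon]
    out = []
    for b in BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if alt not in STOP_CODONS and _TABLE.forward_table[alt] != aa:
            out.append(b)
    return out


def _mutate_orf(
    seq: str, n_subs: int, syn_bias: float, rng: np.random.Generator, max_tries: int = 200
) -> str:
    """Apply ``n_subs`` substitutions at distinct sites, keeping the ORF stop-free.

    Each substitution is synonymous with probability ``syn_bias`` (when the
    drawn site offers a synonymous single-base change; otherwise the site is
    redrawn), non-synonymous otherwise.
    """
    n_sites = len(seq)
    chars = list(seq)
    mutated: set[int] = set()
    for _ in range(n_subs):
        placed = False
        for _attempt in range(max_tries):
            site = int(rng.integers(0, n_sites))
            if site in mutated:
                continue
            codon_start = site - site % 3
            codon = "".join(chars[codon_start : codon_start + 3])
            pos = site - codon_start
            want_syn = rng.random() < syn_bias
            options = (
                _synonymous_options(codon, pos)
                if want_syn
                else _nonsynonymous_options(codon, pos)
            )
            if not options:
                continue
            chars[site] = options[int(rng.integers(0, len(options)))]
            mutated.add(site)
            placed = True
            break
        if not placed:
            raise SimulationError(
                "could not place a substitution with the requested synonymous "
                "bias; try a longer locus or lower mutation count"
            )
    return "".join(chars)


def count_pool_polymorphic_sites(seqs: Sequence[str]) -> int:
    if not seqs:
        return 0
    length = len(seqs[0])
    return sum(1 for i in range(length) if len({s[i] for s in seqs}) > 1)


def generate_allele_pool(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, LocusAlleleSet], dict[str, str], dict[str, int]]:
    """Derive per-locus allele pools from random stop-free ancestral ORFs.

    Returns (pools, ancestors, per-locus polymorphic-site counts). Each allele
    differs from its ancestor by at least one substitution and all alleles of
    a locus are pairwise distinct.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pools: dict[str, LocusAlleleSet] = {}
    ancestors: dict[str, str] = {}
    poly: dict[str, int] = {}
    for locus in cfg.loci():
        ancestor = _random_orf(rng, cfg.locus_length)
        alleles: dict[int, str] = {1: ancestor}
        seen = {ancestor}
        for number in range(2, cfg.n_alleles_per_locus + 1):
            for _attempt in range(100):
                n_subs = max(1, int(rng.binomial(cfg.locus_length, cfg.mutation_rate)))
                candidate = _mutate_orf(ancestor, n_subs, cfg.syn_bias, rng)
                if candidate not in seen:
                    break
            else:
                raise SimulationError(
                    f"{locus}: could not derive {cfg.n_alleles_per_locus} distinct "
                    "alleles; increase mutation_rate or locus_length"
                )
            alleles[number] = candidate
            seen.add(candidate)
        pools[locus] = LocusAlleleSet(locus=locus, alleles=alleles)
        ancestors[locus] = ancestor
        poly[locus] = count_pool_polymorphic_sites(list(alleles.values()))
    return pools, ancestors, poly


def generate_population(
    cfg: SimulationConfig,
    pools: dict[str, LocusAlleleSet],
    rng: np.random.Generator | None = None,
    polymorphic_sites: dict[str, int] | None = None,
) -> tuple[TruthTable, ProfileTable]:
    """Plant ``n_STs`` distinct profiles and assign strains to them.

    Every ST receives at least one strain (so exactly ``n_STs`` distinct STs
    appear among the strains); the remaining strains are drawn from
    ``st_frequencies`` (uniform when unset). Hut knockouts are planted whole
    STs at a time until the knockout strain budget is spent.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    scheme = cfg.scheme()
    n_combinations = 1
    for locus in scheme.loci:
        n_combinations *= len(pools[locus])
        if n_combinations >= cfg.n_STs:
            break
    if n_combinations < cfg.n_STs:
        raise SimulationError(
            f"cannot plant {cfg.n_STs} distinct STs from "
            f"{n_combinations} possible allele combinations"
        )

    profiles: list[AlleleProfile] = []
    seen: set[tuple[int, ...]] = set()
    for _ in range(cfg.n_STs):
        for _attempt in range(1000):
            combo = tuple(
                int(rng.choice(sorted(pools[locus].alleles))) for locus in scheme.loci
            )
            if combo not in seen:
                break
        else:
            raise SimulationError("could not draw distinct ST profiles")
        seen.add(combo)
        profiles.append(
            AlleleProfile.from_dict(dict(zip(scheme.loci, combo)), scheme)
        )

    table = ProfileTable(scheme=scheme)
    for p in profiles:
        table.register(p)

    # one strain per ST, then the remainder by st_frequencies
    st_assignment = list(range(1, cfg.n_STs + 1))
    freqs = (
        np.full(cfg.n_STs, 1.0 / cfg.n_STs)
        if cfg.st_frequencies is None
        else np.asarray(cfg.st_frequencies, dtype=float)
    )
    extra = rng.choice(
        np.arange(1, cfg.n_STs + 1), size=cfg.n_strains - cfg.n_STs, p=freqs
    )
    st_assignment.extend(int(x) for x in extra)
    rng.shuffle(st_assignment)

    n_knockout = int(round(cfg.hut_knockout_fraction * cfg.n_strains))
    knockout_sts: set[int] = set()
    if n_knockout > 0:
        st_order = rng.permutation(np.arange(1, cfg.n_STs + 1))
        budget = n_knockout
        for st in st_order:
            members = st_assignment.count(int(st))
            if members <= budget:
                knockout_sts.add(int(st))
                budget -= members
            if budget == 0:
                break

    strains = []
    width = len(str(cfg.n_strains))
    for i, st in enumerate(st_assignment):
        name = f"strain{i + 1:0{width}d}"
        knocked = st in knockout_sts
        hut_present = {
            g: not (knocked and g in cfg.hut_knockout_genes) for g in HUT_GENES
        }
        strains.append(
            StrainTruth(
                strain=name,
                profile=table.profiles[st],
                st=st,
                hut_present=hut_present,
            )
        )
    truth = TruthTable(strains=strains, polymorphic_sites=polymorphic_sites or {})
    return truth, table


def hut_reference_genes() -> dict[str, str]:
    """The four synthetic hut reference ORFs (~900 bp, stop-free, fixed seeds).

    These are arbitrary coding sequences used to exercise identity/coverage
    screening logic; they are not biological *B. subtilis* sequences.
    """
    return {
        gene: _random_orf(np.random.default_rng(seed), _HUT_LENGTH)
        for gene, seed in _HUT_SEEDS.items()
    }


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def assemble_genome(
    strain: StrainTruth,
    pools: dict[str, LocusAlleleSet],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    max_retries: int = 20,
) -> list[tuple[str, str]]:
    """Emit contigs for one strain, embedding planted alleles and hut genes.

    Each planted allele appears exactly once, flanked by random sequence, on a
    random strand (reverse-complemented on minus). The hut genes present per
    the truth record are embedded as a cassette. With ``contig_split`` the
    features are distributed over at least two contigs. Flanks that create a
    spurious exact occurrence of any pool allele are regenerated.
    """
    hut_refs = hut_reference_genes()
    calls = strain.profile.as_dict()

    for _retry in range(max_retries):
        features: list[tuple[str, str, str]] = []  # (name, oriented seq, strand)
        for locus in cfg.loci():
            seq = pools[locus].sequence_of(calls[locus])
            strand = "+" if rng.random() < 0.5 else "-"
            features.append((locus, seq if strand == "+" else _revcomp(seq), strand))
        cassette_strand = "+" if rng.random() < 0.5 else "-"
        hut_order = HUT_GENES if cassette_strand == "+" else tuple(reversed(HUT_GENES))
        for gene in hut_order:
            if strain.hut_present[gene]:
                seq = hut_refs[gene]
                features.append(
                    (gene, seq if cassette_strand == "+" else _revcomp(seq), cassette_strand)
                )

        n_contigs = int(rng.integers(2, 4)) if cfg.contig_split else 1
        n_contigs = min(n_contigs, len(features))
        bins: list[list[tuple[str, str, str]]] = [[] for _ in range(n_contigs)]
        for i, feat in enumerate(features):
            bins[i % n_contigs].append(feat)

        contigs: list[tuple[str, str]] = []
        placements: list[Placement] = []
        for ci, feats in enumerate(bins):
            name = f"{strain.strain}_contig{ci + 1}"
            parts: list[str] = []
            pos = 0
            for fname, oriented, strand in feats:
                flank = _random_bases(rng, cfg.flank_length)
                parts.append(flank)
                pos += len(flank)
                placements.append(
                    Placement(
                        feature=fname,
                        contig=name,
                        start=pos,
                        end=pos + len(oriented),
                        strand=strand,
                    )
                )
                parts.append(oriented)
                pos += len(oriented)
            parts.append(_random_bases(rng, cfg.flank_length))
            contigs.append((name, "".join(parts)))

        if _spurious_hits(contigs, pools, calls):
            continue
        strain.placements = placements
        return contigs
    raise SimulationError(
        f"{strain.strain}: flanks kept producing spurious allele matches "
        f"after {max_retries} retries"
    )


def _spurious_hits(
    contigs: list[tuple[str, str]],
    pools: dict[str, LocusAlleleSet],
    calls: dict[str, int],
) -> bool:
    """True if any pool allele occurs a wrong number of times in the genome."""
    for locus, pool in pools.items():
        for number, seq in pool.alleles.items():
            expected = 1 if calls.get(locus) == number else 0
            count = 0
            rc = _revcomp(seq)
            for _, contig in contigs:
                count += contig.count(seq) + contig.count(rc)
                if count > expected:
                    return True
            if count != expected:
                return True
    return False


@dataclass
class SimulationResult:
    config: SimulationConfig
    db: MLSTDatabase
    truth: TruthTable
    genomes: dict[str, list[tuple[str, str]]]
    ancestors: dict[str, str]

    def write_outputs(self, outdir: str | Path) -> dict[str, Path]:
        """Write database, truth table, genomes, and config; return the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        db_dir = outdir / "db"
        self.db.save(db_dir)
        paths["db"] = db_dir

        truth_path = outdir / "truth.tsv"
        self.truth.write_tsv(truth_path, self.config.loci())
        paths["truth"] = truth_path

        placements_path = outdir / "placements.tsv"
        with open(placements_path, "w") as fh:
            fh.write("strain\tfeature\tcontig\tstart\tend\tstrand\n")
            for s in self.truth.strains:
                for p in s.placements:
                    fh.write(
                        f"{s.strain}\t{p.feature}\t{p.contig}\t{p.start}\t{p.end}\t{p.strand}\n"
                    )
        paths["placements"] = placements_path

        genome_dir = outdir / "genomes"
        genome_dir.mkdir(exist_ok=True)
        for strain, contigs in self.genomes.items():
            p = genome_dir / f"{strain}.fasta"
            SeqIO.write(
                [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs],
                str(p),
                "fasta",
            )
        paths["genomes"] = genome_dir

        hut_path = outdir / "hut_references.fasta"
        SeqIO.write(
            [
                SeqRecord(Seq(seq), id=gene, description="synthetic reference ORF")
                for gene, seq in hut_reference_genes().items()
            ],
            str(hut_path),
            "fasta",
        )
        paths["hut_references"] = hut_path

        cfg_path = outdir / "config.yaml"
        with open(cfg_path, "w") as fh:
            cfg = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.config).items()
            }
            yaml.safe_dump(cfg, fh, sort_keys=False)
        paths["config"] = cfg_path
        for key, p in paths.items():
            logger.info("simulate: wrote %s -> %s", key, p)
        return paths


def simulate(cfg: SimulationConfig) -> SimulationResult:
    """Run the full generator: pools, population, and per-strain assemblies."""
    rng = np.random.default_rng(cfg.seed)
    pools, ancestors, poly = generate_allele_pool(cfg, rng)
    truth, table = generate_population(cfg, pools, rng, polymorphic_sites=poly)
    genomes = {
        s.strain: assemble_genome(s, pools, cfg, rng) for s in truth.strains
    }
    db = MLSTDatabase(scheme=cfg.scheme(), alleles=pools, profiles=table)
    return SimulationResult(
        config=cfg, db=db, truth=truth, genomes=genomes, ancestors=ancestors
    )
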