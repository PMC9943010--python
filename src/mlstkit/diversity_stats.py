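"""Per-locus and per-scheme diversity statistics for MLST scheme comparison.

Implements the quantities used to compare typing schemes:

* polymorphic-site counts over aligned allele or strain sequences;
* typing efficiency — the number of alleles per polymorphic site;
* the Hunter–Gaston discriminatory index,
  ``D = 1 − Σ_j n_j(n_j−1) / (N(N−1))``, the probability that two strains
  drawn at random (without replacement) from the population carry
  different types;
* Nei–Gojobori (1986) counting of synonymous and non-synonymous
  substitutions with Jukes–Cantor correction, and per-gene dN/dS as the
  ratio of mean pairwise dN to mean pairwise dS.

All functions operate on plain sequences/counts, so they apply equally to
fragment and full-gene loci.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
BASES = "ACGT"


@dataclass
class LocusStats:
    locus: str
    n_strains: int
    n_alleles: int
    length: int | None
    n_polymorphic_sites: int
    typing_efficiency: float | None  # None when the locus is monomorphic
    discriminatory_power: float
    dN: float | None
    dS: float | None
    dnds: float | None  # None when dS == 0 or undefined


@dataclass
class SchemeSummary:
    scheme: str
    n_strains: int
    n_STs: int
    mean_D: float
    min_D: float
    max_D: float
    mean_dnds: float | None


def count_polymorphic_sites(seqs: Sequence[str]) -> int:
    """Number of columns with ≥2 distinct states among equal-length sequences."""
    if not seqs:
        raise ValueError("need at least one sequence")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must have equal length")
    return sum(1 for i in range(length) if len({s[i] for s in seqs}) > 1)


def typing_efficiency(n_alleles: int, n_polymorphic_sites: int) -> float | None:
    """Alleles per polymorphic site; None (undefined) for a monomorphic locus."""
    if n_alleles < 0 or n_polymorphic_sites < 0:
        raise ValueError("counts must be non-negative")
    if n_polymorphic_sites == 0:
        return None
    return n_alleles / n_polymorphic_sites


def discriminatory_power(type_counts: Iterable[int]) -> float:
    """Hunter–Gaston discriminatory index over a multiset of group sizes.

    ``type_counts`` are the sizes n_j of each type group; N = Σ n_j must be
    at least 2. Returns the probability that two strains sampled without
    replacement belong to different types.
    """
    counts = [int(c) for c in type_counts]
    if any(c < 1 for c in counts):
        raise ValueError("group sizes must be positive")
    n = sum(counts)
    if n < 2:
        raise ValueError("need at least two strains")
    concordant = sum(c * (c - 1) for c in counts)
    return 1.0 - concordant / (n * (n - 1))


@lru_cache(maxsize=None)
def _codon_site_fractions(codon: str) -> tuple[float, float]:
    """Potential (synonymous, non-synonymous) sites of one sense codon.

    Per position, the synonymous fraction is the number of single-base
    changes preserving the amino acid divided by 3; changes creating a stop
    codon count as non-synonymous.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon}")
    aa = _TABLE.forward_table[codon]
    syn = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS and _TABLE.forward_table[alt] == aa:
                syn += 1.0
    syn /= 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _codon_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """Observed (synonymous, non-synonymous) differences between two codons.

    All minimal substitution pathways between the codons are enumerated and
    averaged; pathways passing through a stop codon are skipped (when every
    pathway is blocked, all pathways are used so the difference count is
    still defined).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        syn = nonsyn = 0.0
        current = c1
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            if nxt in STOP_CODONS or current in STOP_CODONS:
                nonsyn += 1.0  # involving a stop: treated as non-synonymous
            elif _TABLE.forward_table[current] == _TABLE.forward_table[nxt]:
                syn += 1.0
            else:
                nonsyn += 1.0
            current = nxt
        return syn, nonsyn

    paths = [walk(order, allow_stops=False) for order in permutations(diff_pos)]
    valid = [p for p in paths if p is not None]
    if not valid:
        valid = [walk(order, allow_stops=True) for order in permutations(diff_pos)]
    syn = sum(p[0] for p in valid) / len(valid)
    nonsyn = sum(p[1] for p in valid) / len(valid)
    return syn, nonsyn


def _jukes_cantor(p: float) -> float | None:
    """JC-corrected distance; None when p ≥ 3/4 (correction undefined)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class PairwiseDnDs:
    Sd: float
    Nd: float
    S: float
    N: float
    pS: float
    pN: float
    dS: float | None
    dN: float | None


def nei_gojobori_pair(
    seq1: str, seq2: str, jukes_cantor: bool = True
) -> PairwiseDnDs:
    """Nei–Gojobori (1986) synonymous/non-synonymous counts for two sequences.

    Both sequences must be equal-length in-frame coding sequences without
    internal stop codons. Potential sites S and N are averaged over the two
    sequences; observed differences are resolved by averaging over minimal
    substitution pathways. With ``jukes_cantor=False`` the returned dS/dN are
    the uncorrected proportions pS/pN (useful for oracle checks).
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ValueError("sequences must have equal length")
    if len(seq1) % 3 != 0:
        raise ValueError("length must be divisible by 3")
    s1 = n1 = s2 = n2 = 0.0
    Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            raise ValueError(f"internal stop codon at position {i}")
        a, b = _codon_site_fractions(c1)
        s1 += a
        n1 += b
        a, b = _codon_site_fractions(c2)
        s2 += a
        n2 += b
        sd, nd = _codon_pair_differences(c1, c2)
        Sd += sd
        Nd += nd
    S = (s1 + s2) / 2.0
    N = (n1 + n2) / 2.0
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    if jukes_cantor:
        dS = _jukes_cantor(pS)
        dN = _jukes_cantor(pN)
    else:
        dS, dN = pS, pN
    return PairwiseDnDs(Sd=Sd, Nd=Nd, S=S, N=N, pS=pS, pN=pN, dS=dS, dN=dN)


def gene_dnds(
    seqs: Sequence[str],
    jukes_cantor: bool = True,
    distinct_only: bool = False,
) -> tuple[float | None, float | None, float | None]:
    """Per-gene (dN, dS, dN/dS) as means over all unordered sequence pairs.

    With ``distinct_only`` the computation runs over distinct sequences
    (allele representatives) instead of one sequence per strain. Pairs whose
    corrected distance is undefined (p ≥ 3/4) are excluded with a logged
    count. The ratio is mean(dN)/mean(dS); it is None when mean dS is 0 (no
    synonymous divergence) or no pair is defined.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    pool: Sequence[str] = sorted(set(seqs)) if distinct_only else list(seqs)
    if len(pool) < 2:
        return 0.0, 0.0, None
    dns, dss = [], []
    skipped = 0
    for a, b in combinations(pool, 2):
        pair = nei_gojobori_pair(a, b, jukes_cantor=jukes_cantor)
        if pair.dN is None or pair.dS is None:
            skipped += 1
            continue
        dns.append(pair.dN)
        dss.append(pair.dS)
    if skipped:
        logger.warning("gene_dnds: %d pair(s) with undefined distance excluded", skipped)
    if not dns:
        return None, None, None
    mean_dn = sum(dns) / len(dns)
    mean_ds = sum(dss) / len(dss)
    ratio = mean_dn / mean_ds if mean_ds > 0 else None
    return mean_dn, mean_ds, ratio


def locus_stats(
    locus: str,
    strain_seqs: Sequence[str],
    jukes_cantor: bool = True,
    distinct_only: bool = False,
) -> LocusStats:
    """All per-locus statistics from one sequence per strain."""
    n = len(strain_seqs)
    distinct = sorted(set(strain_seqs))
    n_alleles = len(distinct)
    lengths = {len(s) for s in strain_seqs}
    length = lengths.pop() if len(lengths) == 1 else None
    if length is not None:
        n_poly = count_polymorphic_sites(distinct)
    else:
        n_poly = 0
        logger.warning("%s: unequal sequence lengths; polymorphic sites not counted", locus)
    from collections import Counter

    counts = Counter(strain_seqs)
    d = discriminatory_power(counts.values())
    if n_alleles > 1 and length is not None and length % 3 == 0:
        dn, ds, ratio = gene_dnds(
            strain_seqs, jukes_cantor=jukes_cantor, distinct_only=distinct_only
        )
    else:
        dn = ds = ratio = None
    return LocusStats(
        locus=locus,
        n_strains=n,
        n_alleles=n_alleles,
        length=length,
        n_polymorphic_sites=n_poly,
        typing_efficiency=typing_efficiency(n_alleles, n_poly),
        discriminatory_power=d,
        dN=dn,
        dS=ds,
        dnds=ratio,
    )


def scheme_summary(
    scheme: str,
    st_labels: Sequence[int | None],
    per_locus: Sequence[LocusStats],
) -> SchemeSummary:
    """Scheme-level roll-up: distinct STs and unweighted means across loci.

    ``st_labels`` holds one ST per typed strain (None entries — strains with
    undefined ST — are excluded from the ST count).
    """
    sts = [s for s in st_labels if s is not None]
    ds = [ls.discriminatory_power for ls in per_locus]
    ratios = [ls.dnds for ls in per_locus if ls.dnds is not None]
    return SchemeSummary(
        scheme=scheme,
        n_strains=len(st_labels),
        n_STs=len(set(sts)),
        mean_D=sum(ds) / len(ds) if ds else float("nan"),
        min_D=min(ds) if ds else float("nan"),
        max_D=max(ds) if ds else float("nan"),
        mean_dnds=sum(ratios) / len(ratios) if ratios else None,
    )


def locus_stats_frame(stats: Sequence[LocusStats], scheme: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scheme": scheme,
                "locus": s.locus,
                "length": s.length,
                "n_strains": s.n_strains,
                "n_alleles": s.n_alleles,
                "polymorphic_sites": s.n_polymorphic_sites,
                "typing_efficiency": s.typing_efficiency,
                "discriminatory_power": s.discriminatory_power,
                "dN": s.dN,
                "dS": s.dS,
                "dnds": s.dnds,
            }
            for s in stats
        ]
    )
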