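"""Ground-truth generator: determinism, planted structure, and ORF constraints."""

from collections import Counter

import numpy as np
import pytest
from Bio.Seq import Seq

from mlstkit.synthetic_data import (
    HUT_GENES,
    SimulationConfig,
    assemble_genome,
    generate_allele_pool,
    generate_population,
    hut_reference_genes,
    simulate,
)

SMALL = dict(n_loci=2, locus_length=90, n_alleles_per_locus=3,
             n_strains=6, n_STs=4, flank_length=50)


def _translate(seq):
    return str(Seq(seq).translate())


class TestAllelePool:
    def test_deterministic_across_runs(self):
        cfg = SimulationConfig(seed=7, **SMALL)
        pools1, anc1, poly1 = generate_allele_pool(cfg)
        pools2, anc2, poly2 = generate_allele_pool(cfg)
        assert anc1 == anc2
        assert poly1 == poly2
        assert {l: p.alleles for l, p in pools1.items()} == {
            l: p.alleles for l, p in pools2.items()
        }

    def test_ancestors_are_stop_free_orfs(self):
        cfg = SimulationConfig(seed=7, **SMALL)
        pools, ancestors, _ = generate_allele_pool(cfg)
        for locus, anc in ancestors.items():
            assert len(anc) % 3 == 0
            assert "*" not in _translate(anc)
            for seq in pools[locus].alleles.values():
                assert "*" not in _translate(seq)

    def test_alleles_distinct_and_differ_from_ancestor(self):
        cfg = SimulationConfig(seed=7, **SMALL)
        pools, ancestors, _ = generate_allele_pool(cfg)
        for locus, pool in pools.items():
            seqs = list(pool.alleles.values())
            assert len(set(seqs)) == len(seqs)
            for number, seq in pool.alleles.items():
                if number > 1:
                    assert seq != ancestors[locus]

    def test_single_allele_pool_is_monomorphic(self):
        cfg = SimulationConfig(seed=7, n_loci=2, locus_length=90,
                               n_alleles_per_locus=1, n_strains=3, n_STs=1)
        _, _, poly = generate_allele_pool(cfg)
        assert all(v == 0 for v in poly.values())

    def test_pure_synonymous_bias_gives_zero_nonsyn_changes(self):
        """With syn_bias=1 every substitution must preserve the protein.

        Verified by an independent codon-path check: translate ancestor and
        allele and compare residue by residue.
        """
        cfg = SimulationConfig(seed=11, n_loci=2, locus_length=300,
                               n_alleles_per_locus=4, n_strains=4, n_STs=2,
                               mutation_rate=0.02, syn_bias=1.0)
        pools, ancestors, _ = generate_allele_pool(cfg)
        for locus, pool in pools.items():
            anc_protein = _translate(ancestors[locus])
            for seq in pool.alleles.values():
                assert seq != ancestors[locus] or pool.number_of(seq) == 1
                assert _translate(seq) == anc_protein


class TestPopulation:
    def test_study_shape_39_strains_31_sts(self, study_sim):
        truth = study_sim.truth
        assert len(truth.strains) == 39
        assert len({s.st for s in truth.strains}) == 31
        profiles = {s.profile for s in truth.strains}
        assert len(profiles) == 31

    def test_every_st_has_at_least_one_strain(self, study_sim):
        counts = Counter(s.st for s in study_sim.truth.strains)
        assert set(counts) == set(range(1, 32))
        assert all(c >= 1 for c in counts.values())

    def test_degenerate_frequencies_single_st(self):
        cfg = SimulationConfig(seed=5, n_loci=2, locus_length=90,
                               n_alleles_per_locus=3, n_strains=5, n_STs=1,
                               hut_knockout_fraction=0.0)
        pools, _, _ = generate_allele_pool(cfg)
        truth, _ = generate_population(cfg, pools)
        assert len({s.profile for s in truth.strains}) == 1

    def test_reproducible_truth_table(self):
        cfg = SimulationConfig(seed=9, **SMALL)
        pools, _, _ = generate_allele_pool(cfg)
        t1, _ = generate_population(cfg, pools)
        t2, _ = generate_population(cfg, pools)
        assert [(s.strain, s.st, s.hut_present) for s in t1.strains] == [
            (s.strain, s.st, s.hut_present) for s in t2.strains
        ]

    def test_impossible_st_count_rejected(self):
        cfg = SimulationConfig(seed=5, n_loci=1, locus_length=90,
                               n_alleles_per_locus=2, n_strains=5, n_STs=5)
        pools, _, _ = generate_allele_pool(cfg)
        with pytest.raises(Exception, match="distinct"):
            generate_population(cfg, pools)

    def test_knockouts_planted_clonally(self, study_sim):
        """Every planted knockout ST is uniformly knocked out."""
        truth = study_sim.truth
        ko_sts = truth.knockout_sts()
        for s in truth.strains:
            expected_ko = s.st in ko_sts
            assert all(s.hut_present[g] for g in HUT_GENES) != expected_ko
            assert s.hut_present["hutU"]  # hutU always retained


class TestAssembly:
    def test_each_planted_allele_occurs_exactly_once(self, study_sim):
        """Brute-force substring scan of the emitted FASTA."""
        cfg = study_sim.config
        for strain in study_sim.truth.strains[:5]:
            genome = "".join(seq for _, seq in study_sim.genomes[strain.strain])
            calls = strain.profile.as_dict()
            for locus in cfg.loci():
                allele = study_sim.db.alleles[locus].sequence_of(calls[locus])
                rc = str(Seq(allele).reverse_complement())
                assert genome.count(allele) + genome.count(rc) == 1

    def test_placements_match_contig_slices(self, study_sim):
        strain = study_sim.truth.strains[0]
        contigs = dict(study_sim.genomes[strain.strain])
        refs = hut_reference_genes()
        calls = strain.profile.as_dict()
        for p in strain.placements:
            embedded = contigs[p.contig][p.start : p.end]
            if p.strand == "-":
                embedded = str(Seq(embedded).reverse_complement())
            if p.feature in calls:
                expected = study_sim.db.alleles[p.feature].sequence_of(calls[p.feature])
            else:
                expected = refs[p.feature]
            assert embedded == expected

    def test_contig_split_distributes_features(self, study_sim):
        for strain in study_sim.truth.strains[:3]:
            assert len(study_sim.genomes[strain.strain]) >= 2

    def test_knockout_removes_gene_body(self, study_sim):
        refs = hut_reference_genes()
        for strain in study_sim.truth.strains:
            genome = "".join(seq for _, seq in study_sim.genomes[strain.strain])
            for gene in HUT_GENES:
                seq = refs[gene]
                rc = str(Seq(seq).reverse_complement())
                occurrences = genome.count(seq) + genome.count(rc)
                assert occurrences == (1 if strain.hut_present[gene] else 0)

    def test_single_gene_knockout_config(self):
        cfg = SimulationConfig(seed=2, n_loci=2, locus_length=90,
                               n_alleles_per_locus=3, n_strains=4, n_STs=2,
                               hut_knockout_fraction=0.5,
                               hut_knockout_genes=("hutH",))
        res = simulate(cfg)
        ko = res.truth.knockout_strains()
        assert ko
        for s in res.truth.strains:
            if s.strain in ko:
                assert not s.hut_present["hutH"]
                assert s.hut_present["hutU"] and s.hut_present["hutI"] and s.hut_present["hutG"]

    def test_simulation_outputs_roundtrip(self, small_sim, tmp_path):
        from mlstkit.scheme_db import MLSTDatabase, load_scheme_definition

        paths = small_sim.write_outputs(tmp_path)
        scheme = load_scheme_definition(paths["db"] / "scheme.yaml")
        db = MLSTDatabase.load(scheme, paths["db"])
        assert db.scheme == small_sim.db.scheme
        for locus in scheme.loci:
            assert db.alleles[locus].alleles == small_sim.db.alleles[locus].alleles
        assert db.profiles.profiles == small_sim.db.profiles.profiles
        assert paths["truth"].exists() and paths["genomes"].is_dir()

    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        cfg = SimulationConfig(seed=13, **SMALL)
        out1, out2 = tmp_path / "a", tmp_path / "b"
        simulate(cfg).write_outputs(out1)
        simulate(cfg).write_outputs(out2)
        files1 = sorted(p.relative_to(out1) for p in out1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(out2) for p in out2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (out1 / rel).read_bytes() == (out2 / rel).read_bytes()


class TestHutReferences:
    def test_fixed_and_stop_free(self):
        refs1 = hut_reference_genes()
        refs2 = hut_reference_genes()
        assert refs1 == refs2
        assert set(refs1) == set(HUT_GENES)
        for seq in refs1.values():
            assert len(seq) == 900
            assert "*" not in _translate(seq)
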