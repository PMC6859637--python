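"""Generator correctness: determinism, calibration, and fixture content."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from organopept import (
    AMINO_ACIDS,
    SimConfig,
    build_binding_model,
    build_reference_fixture,
    filter_somatic,
    generate_expression,
    generate_mutations,
    generate_proteome,
    simulate_evidence,
    write_proteome_fasta,
)
from organopept.synthetic import (
    ConfigurationError,
    _random_peptides,
    parse_mutation_label,
)


def _fasta_bytes(proteome):
    buf = io.StringIO()
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [SeqRecord(Seq(p.sequence), id=p.protein_id, description="")
         for p in proteome],
        buf,
        "fasta",
    )
    return buf.getvalue()


class TestProteome:
    def test_empty_proteome_is_valid(self):
        cfg = SimConfig(n_proteins=0)
        assert generate_proteome(cfg) == []

    def test_byte_identical_given_seed(self):
        cfg = SimConfig(n_proteins=50, protein_length_range=(100, 500), seed=1)
        a = _fasta_bytes(generate_proteome(cfg))
        b = _fasta_bytes(generate_proteome(cfg))
        assert a == b

    def test_lengths_within_range_one_gene_per_protein(self, proteome,
                                                       small_config):
        lo, hi = small_config.protein_length_range
        assert all(lo <= p.length <= hi for p in proteome)
        assert len({p.gene_id for p in proteome}) == len(proteome)

    def test_seeds_differ_but_length_statistics_agree(self):
        """Different seeds give different sequences with matching length
        distributions (uniform on the configured range)."""
        means = []
        seqs = []
        for seed in range(20):
            cfg = SimConfig(n_proteins=50, protein_length_range=(100, 500),
                            seed=seed)
            prot = generate_proteome(cfg)
            means.append(np.mean([p.length for p in prot]))
            seqs.append(frozenset(p.sequence for p in prot))
        assert len(set(seqs)) == 20
        # uniform(100,500): mean 300, sd of a 50-protein mean ~ 16.3
        assert abs(np.mean(means) - 300) < 3 * 115.5 / np.sqrt(50 * 20)

    def test_invalid_range_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(protein_length_range=(500, 100))


class TestMutations:
    def test_zero_decoys_all_pass_filter(self, proteome):
        cfg = SimConfig(n_proteins=60, n_mutations=80, decoy_fraction=0.0,
                        seed=3)
        muts = generate_mutations(proteome, cfg)
        retained, rejected = filter_somatic(muts)
        assert len(retained) == len(muts)
        assert rejected.empty

    def test_decoy_fraction_recovered(self, proteome):
        """Observed rejected fraction lies in the binomial 99% CI of the
        configured decoy fraction."""
        cfg = SimConfig(n_proteins=60, n_mutations=200, decoy_fraction=0.5,
                        seed=5)
        muts = generate_mutations(proteome, cfg)
        _, rejected = filter_somatic(muts)
        p_hat = len(rejected) / len(muts)
        half = 2.576 * np.sqrt(0.5 * 0.5 / len(muts))
        assert abs(p_hat - 0.5) < half
        # constructed truth column matches the filter exactly
        assert (len(muts) - len(rejected)) == muts["truth_passes_filter"].sum()

    def test_pure_missense_mix_gives_substitutions(self, proteome):
        cfg = SimConfig(
            n_proteins=60, n_mutations=40,
            consequence_mix={"missense": 1.0}, seed=7,
        )
        muts = generate_mutations(proteome, cfg)
        assert (muts["consequence"] == "missense").all()
        assert (muts["alt_aa"] != muts["ref_aa"]).all()
        assert muts["alt_aa"].str.len().eq(1).all()

    def test_too_many_mutations_rejected(self):
        cfg_small = SimConfig(n_proteins=1, protein_length_range=(11, 12),
                              seed=1)
        prot = generate_proteome(cfg_small)
        cfg = SimConfig(n_proteins=1, n_mutations=10_000)
        with pytest.raises(ConfigurationError):
            generate_mutations(prot, cfg)


class TestBindingModel:
    def test_best_background_peptide_rank_at_floor(self, model, small_config):
        """The top-scoring background peptide has rank <= 100/N by the
        empirical-rank definition."""
        allotype = small_config.allotypes[0]
        peps = _random_peptides(np.random.default_rng(0), 2000, 9)
        scores = model.score(peps, allotype)
        best = peps[int(np.argmax(scores))]
        # rank of any peptide >= all of background except possibly a few
        bg = model._backgrounds[(allotype, 9)]
        if scores.max() >= bg[-1]:
            assert model.rank(best, allotype) <= 100.0 / len(bg)

    def test_equal_scores_share_rank(self, model, small_config):
        allotype = small_config.allotypes[0]
        # anagram peptides with identical mapped residues score identically
        pep = "ACDEFGHIK"
        assert model.rank(pep, allotype) == model.rank(pep, allotype)
        s = model.score([pep, pep], allotype)
        assert s[0] == s[1]

    def test_background_ranks_approximately_uniform(self, model, small_config):
        """KS test of fresh random-peptide ranks against uniform, at the
        two-sample effective size (fresh n vs background N share the same
        empirical reference)."""
        allotype = small_config.allotypes[1]
        rng = np.random.default_rng(42)
        peps = _random_peptides(rng, 4000, 9)
        ranks = model.rank_many(peps, allotype)
        assert ranks.min() > 0 and ranks.max() <= 100
        n, N = len(peps), model.background_size
        n_eff = n * N / (n + N)
        crit = 1.628 / np.sqrt(n_eff)  # alpha = 0.01
        stat = stats.kstest(ranks / 100.0, "uniform").statistic
        assert stat < crit

    def test_length_outside_8_11_rejected(self, model, small_config):
        with pytest.raises(ValueError):
            model.rank("ACDEFGH", small_config.allotypes[0])
        with pytest.raises(ValueError):
            model.rank("ACDEFGHIKLMN", small_config.allotypes[0])

    def test_subset_preserves_ranks(self, model, small_config):
        sub = model.subset(small_config.allotypes[:1])
        pep = "ACDEFGHIK"
        assert sub.rank(pep, small_config.allotypes[0]) == model.rank(
            pep, small_config.allotypes[0]
        )


class TestEvidence:
    def test_no_dropout_all_replicates_detect(self, proteome, expression,
                                              model):
        from organopept import DetectionModel

        cfg = SimConfig(
            n_proteins=60, peptide_pool_size=1500, background_size=1000,
            allotypes=("HLA-A*01:01", "HLA-B*07:02", "HLA-C*04:01"),
            detection_model=DetectionModel(dropout=0.0, leak_rate=0.0),
            seed=11,
        )
        evidence, truth = simulate_evidence(proteome, expression, model, cfg)
        n_bio, n_tech = cfg.replicate_design
        per_pep = evidence.groupby("peptide").size()
        assert (per_pep == n_bio * n_tech).all()
        assert set(per_pep.index) == truth.presented_set("untreated")

    def test_missing_expression_names_gene(self, proteome, model,
                                           small_config):
        expr = pd.DataFrame(
            {"gene_id": [p.gene_id for p in proteome[1:]],
             "expression": 5.0}
        )
        with pytest.raises(KeyError, match=proteome[0].gene_id):
            simulate_evidence(proteome, expr, model, small_config)

    def test_chymo_bias_shifts_c_termini(self, proteome, expression, model):
        """With a positive chymotrypsin bias the IFNγ-condition presented
        set has a higher chymotrypsin-like fraction than untreated, in
        every seed tried."""
        from organopept import TreatmentEffects, chymo_fraction

        wins = 0
        for seed in range(10):
            cfg = SimConfig(
                n_proteins=60, peptide_pool_size=1500, background_size=1000,
                allotypes=("HLA-A*01:01", "HLA-B*07:02", "HLA-C*04:01"),
                conditions=("untreated", "IFNg"),
                treatment_effects=TreatmentEffects(chymo_bias=2.0),
                seed=100 + seed,
            )
            _, truth = simulate_evidence(proteome, expression, model, cfg)
            f_u = chymo_fraction(truth.presented_set("untreated"))
            f_i = chymo_fraction(truth.presented_set("IFNg"))
            wins += f_i > f_u
        assert wins == 10


class TestPaperFixture:
    def test_candidate_count_is_612(self, fixture_data):
        assert len(fixture_data["candidates"]) == 612

    def test_three_detected_records_match_published_ligands(self, fixture_data):
        det = fixture_data["candidates"][fixture_data["candidates"]["detected"]]
        assert len(det) == 3
        t2 = fixture_data["detected_neoantigens"]
        assert set(t2["mut_peptide"]) == {
            "IQEERDERHKR", "SVDANTTL", "RYVENQRHTI"
        }
        assert set(t2["wt_peptide"]) == {
            "IQEERDERHKT", "SVDANTKL", "RYVESQRHTI"
        }
        assert set(det["gene_id"]) == {"U2SURP", "MED25", "FMO5"}

    def test_wt_context_embeds_ligand_exactly_once(self, fixture_data):
        contexts = {c.gene_id: c.sequence for c in fixture_data["wt_contexts"]}
        for _, row in fixture_data["detected_neoantigens"].iterrows():
            seq = contexts[row["gene"]]
            assert seq.count(row["wt_peptide"]) == 1
            assert row["mut_peptide"] not in seq
            _, pos, _ = parse_mutation_label(row["mutation"])
            offset = next(
                i for i, (a, b) in enumerate(
                    zip(row["wt_peptide"], row["mut_peptide"])) if a != b
            )
            # the mutated residue sits at its printed 1-based position
            assert seq[pos - 1] == row["wt_peptide"][offset]

    def test_per_line_split_proportional_to_loads(self, fixture_data):
        split = fixture_data["candidates"]["pdo"].value_counts()
        assert split.sum() == 612
        assert split["CRC-01"] == 193 and split["CRC-04"] == 82

    def test_fixture_deterministic(self):
        a = build_reference_fixture()
        b = build_reference_fixture()
        pd.testing.assert_frame_equal(a["candidates"], b["candidates"])
        assert [c.sequence for c in a["wt_contexts"]] == [
            c.sequence for c in b["wt_contexts"]
        ]
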