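"""Presence calling, counting, mapping, overlap and correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from organopept import (
    DetectionModel,
    ProteinRecord,
    SimConfig,
    build_binding_model,
    call_presence,
    count_unique_peptides,
    generate_expression,
    generate_proteome,
    intensity_correlation,
    map_source_proteins,
    normalized_appearance,
    pairwise_overlap,
    simulate_evidence,
)
from organopept.peptidome import peptide_protein_occurrences


def _evidence(detections, peptide="PEPTIDEK", intensity=1000.0):
    """Evidence rows for one peptide from (bio, tech) detection pairs."""
    return pd.DataFrame(
        [
            dict(peptide=peptide, sample_id="s1", condition="untreated",
                 bio_rep=b, tech_rep=t, intensity=intensity, hla_class="I")
            for b, t in detections
        ]
    )


class TestPresenceCriterion:
    def test_split_across_bio_reps_is_absent(self):
        """Detections in tech 1 of bio 1 and tech 2 of bio 2 only: no
        single biological replicate has both technical replicates."""
        presence = call_presence(_evidence([(1, 1), (2, 2)]))
        assert presence.empty

    def test_both_techs_of_one_bio_is_present(self):
        presence = call_presence(_evidence([(1, 1), (1, 2)]))
        assert len(presence) == 1

    def test_exhaustive_replicate_truth_table(self):
        """All 16 detection patterns over 2 bio x 2 tech match the
        brute-force evaluation of the criterion."""
        cells = [(1, 1), (1, 2), (2, 1), (2, 2)]
        for mask in itertools.product([0, 1], repeat=4):
            detections = [c for c, m in zip(cells, mask) if m]
            expected = any(
                all((b, t) in detections for t in (1, 2)) for b in (1, 2)
            )
            if not detections:
                assert call_presence(_evidence([])).empty
                continue
            presence = call_presence(_evidence(detections))
            assert (len(presence) == 1) is expected, mask

    def test_median_over_detecting_replicates(self):
        ev = pd.concat(
            [
                _evidence([(1, 1)], intensity=100.0),
                _evidence([(1, 2)], intensity=200.0),
                _evidence([(2, 1)], intensity=1000.0),
            ]
        )
        presence = call_presence(ev)
        assert presence["median_intensity"].iloc[0] == 200.0

    def test_three_tech_reps_is_design_error(self):
        ev = _evidence([(1, 1), (1, 2)])
        ev.loc[1, "tech_rep"] = 3
        with pytest.raises(ValueError, match="design error"):
            call_presence(ev)

    def test_monotone_adding_detection_never_removes_presence(self):
        base = [(1, 1), (1, 2)]
        p0 = call_presence(_evidence(base))
        p1 = call_presence(_evidence(base + [(2, 1)]))
        assert set(p0["peptide"]) <= set(p1["peptide"])


class TestCounting:
    def test_hla2_length_rule(self):
        ev = pd.concat(
            [
                _evidence([(1, 1), (1, 2)], peptide="A" * 11),
                _evidence([(1, 1), (1, 2)], peptide="C" * 12),
                _evidence([(1, 1), (1, 2)], peptide="D" * 15),
            ]
        )
        ev["hla_class"] = "II"
        counts = count_unique_peptides(call_presence(ev), "II")
        assert counts.iloc[0] == 2

    def test_hla1_counts_all_lengths(self):
        ev = pd.concat(
            [
                _evidence([(1, 1), (1, 2)], peptide="A" * L)
                for L in range(8, 15)
            ]
        )
        counts = count_unique_peptides(call_presence(ev), "I")
        assert counts.iloc[0] == 7

    def test_no_dropout_counts_equal_ground_truth(self):
        cfg = SimConfig(
            n_proteins=50, peptide_pool_size=1200, background_size=1000,
            allotypes=("HLA-A*01:01", "HLA-B*07:02"),
            detection_model=DetectionModel(dropout=0.0, leak_rate=0.0),
            seed=23,
        )
        proteome = generate_proteome(cfg)
        expression = generate_expression(proteome, cfg)
        model = build_binding_model(cfg.allotypes, cfg)
        evidence, truth = simulate_evidence(proteome, expression, model, cfg)
        counts = count_unique_peptides(call_presence(evidence), "I")
        assert counts.iloc[0] == len(truth.presented_set("untreated"))


class TestSourceProteinMapping:
    def test_unique_and_multi_mapping(self):
        prots = [
            ProteinRecord("P1", "G1", "AAAWCDEFGHKKK"),
            ProteinRecord("P2", "G2", "MMMWCDEFGHYYY"),
            ProteinRecord("P3", "G3", "QQQNPRSTVWQQQ"),
        ]
        res = map_source_proteins(
            ["WCDEFGH", "NPRSTVW", "QQQNPRS", "AAAWCDE", "WWWWWWWW"], prots
        )
        # WCDEFGH maps to P1+P2 (multimapper); the others are unique to
        # P3, P3, P1; WWWWWWWW is unmapped
        assert res["multimappers"] == ["WCDEFGH"]
        assert res["unmapped"] == ["WWWWWWWW"]
        assert res["n_source_proteins"] == 2

    def test_matches_brute_force_scan(self, proteome):
        rng = np.random.default_rng(5)
        peptides = []
        for _ in range(200):
            prot = proteome[int(rng.integers(len(proteome)))]
            L = int(rng.integers(8, 12))
            s = int(rng.integers(0, prot.length - L + 1))
            peptides.append(prot.sequence[s : s + L])
        res = map_source_proteins(peptides, proteome)
        occ = peptide_protein_occurrences(peptides, proteome)
        expected = {
            ids[0] for ids in occ.values() if len(ids) == 1
        }
        assert res["n_source_proteins"] == len(expected)


class TestOverlap:
    def _presence(self, peptides, intensities=None):
        n = len(peptides)
        return pd.DataFrame(
            dict(
                peptide=peptides, sample_id="s", condition="untreated",
                hla_class="I",
                median_intensity=intensities if intensities is not None
                else [100.0] * n,
                n_detections=[4] * n,
            )
        )

    def test_identical_sets_full_overlap(self):
        a = self._presence(["AAAAAAAA", "CCCCCCCC"])
        res = pairwise_overlap(a, a.copy())
        assert res["shared"] == 2
        assert res["pct_of_a"] == res["pct_of_b"] == 100.0

    def test_disjoint_sets_zero_overlap(self):
        a = self._presence(["AAAAAAAA"])
        b = self._presence(["CCCCCCCC"])
        assert pairwise_overlap(a, b)["shared"] == 0

    def test_empty_presence_reports_missing(self):
        a = self._presence([])
        b = self._presence(["CCCCCCCC"])
        assert np.isnan(pairwise_overlap(a, b)["pct_of_a"])

    def test_shared_allotype_binders_overlap_more(self):
        """Two samples sharing one allotype: overlap among binders of the
        shared allotype exceeds overlap among binders of non-shared
        allotypes, across seeds."""
        wins = trials = 0
        for seed in range(10):
            base = SimConfig(
                n_proteins=50, peptide_pool_size=1500, background_size=1000,
                allotypes=("HLA-A*01:01", "HLA-B*07:02", "HLA-C*04:01"),
                seed=seed,
            )
            proteome = generate_proteome(base)
            expression = generate_expression(proteome, base)
            model = build_binding_model(base.allotypes, base)
            presences = {}
            for sample, allos in [
                ("sA", ("HLA-A*01:01", "HLA-B*07:02")),
                ("sB", ("HLA-A*01:01", "HLA-C*04:01")),
            ]:
                cfg = SimConfig(
                    n_proteins=50, peptide_pool_size=1500,
                    background_size=1000, allotypes=allos,
                    sample_id=sample, seed=seed + 1000,
                )
                ev, _ = simulate_evidence(
                    proteome, expression, model.subset(allos), cfg
                )
                presences[sample] = call_presence(ev)
            res = pairwise_overlap(
                presences["sA"], presences["sB"], predictor=model,
                allotypes_a=("HLA-A*01:01", "HLA-B*07:02"),
                allotypes_b=("HLA-A*01:01", "HLA-C*04:01"),
                shared_allotypes=("HLA-A*01:01",),
            )
            if not np.isnan(res["shared_allotype_binder_overlap_pct"]) and \
               not np.isnan(res["non_shared_allotype_binder_overlap_pct"]):
                trials += 1
                wins += (
                    res["shared_allotype_binder_overlap_pct"]
                    > res["non_shared_allotype_binder_overlap_pct"]
                )
        assert trials >= 8 and wins == trials


class TestIntensityCorrelation:
    def _presence(self, peptides, intensities):
        return pd.DataFrame(
            dict(peptide=peptides, sample_id="s", condition="untreated",
                 hla_class="I", median_intensity=intensities,
                 n_detections=4)
        )

    def test_self_correlation_is_one(self):
        peps = [f"PEP{i:03d}AAA" for i in range(10)]
        a = self._presence(peps, np.linspace(100, 1e6, 10))
        assert intensity_correlation(a, a.copy()) == pytest.approx(1.0)

    def test_permuted_intensities_near_zero(self):
        rng = np.random.default_rng(3)
        n = 2000
        peps = [f"P{i:05d}AA" for i in range(n)]
        x = 10 ** rng.uniform(2, 6, n)
        a = self._presence(peps, x)
        b = self._presence(peps, rng.permutation(x))
        assert abs(intensity_correlation(a, b)) < 3 / np.sqrt(n)

    def test_too_few_copresent_rejected(self):
        a = self._presence(["AAAAAAAA"], [1.0])
        with pytest.raises(ValueError, match="co-present"):
            intensity_correlation(a, a.copy())


class TestNormalizedAppearance:
    def test_arithmetic(self):
        prot = ProteinRecord("P1", "G1", "A" * 500)
        # 5 distinct peptides uniquely mapping to P1
        peps = ["A" * L for L in (8, 9, 10, 11, 12)]
        presence = pd.DataFrame(
            dict(peptide=peps, sample_id="s", condition="untreated",
                 hla_class="I", median_intensity=1.0, n_detections=4)
        )
        expr = pd.DataFrame({"gene_id": ["G1"], "expression": [5.0]})
        res = normalized_appearance(presence, [prot], expr)
        row = res["per_gene"].iloc[0]
        assert row["n_peptides"] == 5
        assert row["appearance"] == pytest.approx(5 / 500)

    def test_gene_without_peptides_zero(self, proteome, expression):
        presence = pd.DataFrame(
            columns=["peptide", "sample_id", "condition", "hla_class",
                     "median_intensity", "n_detections"]
        )
        res = normalized_appearance(presence, proteome, expression)
        assert (res["per_gene"]["appearance"] == 0).all()

    def test_positive_rank_correlation_with_expression(self):
        """Presentation probability increases with expression, so
        appearance correlates positively with expression in every seed."""
        wins = 0
        for seed in range(10):
            cfg = SimConfig(
                n_proteins=50, peptide_pool_size=2000, background_size=1000,
                allotypes=("HLA-A*01:01", "HLA-B*07:02"), seed=seed + 200,
            )
            proteome = generate_proteome(cfg)
            expression = generate_expression(proteome, cfg)
            model = build_binding_model(cfg.allotypes, cfg)
            ev, _ = simulate_evidence(proteome, expression, model, cfg)
            res = normalized_appearance(call_presence(ev), proteome,
                                        expression)
            wins += res["spearman_r"] > 0
        assert wins == 10
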