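"""Replicate-aware immunopeptidome assembly and descriptive statistics.

MS evidence arrives as one row per detected peptide per technical
replicate.  Presence is binary: a peptide is present in a sample/
condition iff it was detected in BOTH technical replicates of at least
one biological replicate.  On the assembled presence matrix this module
computes the descriptive statistics of an immunopeptidome study:
per-sample unique-peptide counts (all lengths for HLA-I, >=12 aa for
HLA-II), uniquely-mapping source proteins, pairwise peptidome overlaps
(optionally restricted to predicted binders of shared versus non-shared
allotypes), intensity correlations between HLA-matched samples, and
length-normalized peptide appearance per gene against expression.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import ProteinRecord

PRESENCE_KEYS = ["peptide", "sample_id", "condition", "hla_class"]

#: Minimum length counted for HLA class II peptides.
HLA_II_MIN_LENGTH = 12

#: Percentile-rank threshold below which a peptide counts as a
#: (weak-or-strong) predicted binder.
BINDER_RANK_THRESHOLD = 2.0


def call_presence(evidence: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate-level evidence to per-sample presence.

    Returns one row per (peptide, sample, condition, HLA class) that
    satisfies the presence criterion — detected in both technical
    replicates of at least one biological replicate — with the median
    raw intensity across all detecting technical replicates of that
    sample/condition.
    """
    if len(evidence) == 0:
        return pd.DataFrame(
            columns=PRESENCE_KEYS + ["median_intensity", "n_detections"]
        )
    if evidence["tech_rep"].nunique() > 2 or evidence["tech_rep"].max() > 2:
        raise ValueError(
            "design error: more than 2 technical replicates per biological "
            "replicate"
        )
    dup = evidence.duplicated(
        subset=PRESENCE_KEYS + ["bio_rep", "tech_rep"]
    )
    if dup.any():
        raise ValueError("duplicate evidence rows for one technical replicate")

    both_tech = (
        evidence.groupby(PRESENCE_KEYS + ["bio_rep"], sort=False)["tech_rep"]
        .nunique()
        .eq(2)
        .groupby(level=PRESENCE_KEYS, sort=False)
        .any()
    )
    agg = evidence.groupby(PRESENCE_KEYS, sort=False).agg(
        median_intensity=("intensity", "median"),
        n_detections=("intensity", "size"),
    )
    present = agg[both_tech.reindex(agg.index, fill_value=False)]
    return present.reset_index()


def count_unique_peptides(
    presence: pd.DataFrame,
    hla_class: str = "I",
    hla2_min_length: int = HLA_II_MIN_LENGTH,
) -> pd.Series:
    """Unique present peptides per (sample, condition).

    All peptide lengths count for HLA class I; class II counts are
    restricted to peptides of at least ``hla2_min_length`` residues.
    """
    sub = presence[presence["hla_class"] == hla_class]
    if hla_class == "II":
        sub = sub[sub["peptide"].str.len() >= hla2_min_length]
    return sub.groupby(["sample_id", "condition"])["peptide"].nunique()


def peptide_protein_occurrences(
    peptides: Sequence[str], proteome: Sequence[ProteinRecord]
) -> dict[str, list[str]]:
    """Protein ids containing each peptide as a substring."""
    out: dict[str, list[str]] = {p: [] for p in set(peptides)}
    for prot in proteome:
        seq = prot.sequence
        for pep in out:
            if pep in seq:
                out[pep].append(prot.protein_id)
    return out


def map_source_proteins(
    peptides: Sequence[str], proteome: Sequence[ProteinRecord]
) -> dict:
    """Count source proteins to which peptides uniquely map.

    A peptide contributes only if it occurs in exactly one protein of
    the proteome; the source-protein count is the number of distinct
    proteins receiving at least one uniquely mapping peptide.  Peptides
    found in several proteins are listed as multimappers, peptides
    absent from the proteome as unmapped; neither contributes.
    """
    occ = peptide_protein_occurrences(peptides, proteome)
    unique_map = {p: ids[0] for p, ids in occ.items() if len(ids) == 1}
    return {
        "n_source_proteins": len(set(unique_map.values())),
        "peptide_to_protein": unique_map,
        "multimappers": sorted(p for p, ids in occ.items() if len(ids) > 1),
        "unmapped": sorted(p for p, ids in occ.items() if not ids),
    }


def _present_set(presence: pd.DataFrame) -> set[str]:
    return set(presence["peptide"])


def pairwise_overlap(
    presence_a: pd.DataFrame,
    presence_b: pd.DataFrame,
    predictor=None,
    allotypes_a: Sequence[str] | None = None,
    allotypes_b: Sequence[str] | None = None,
    shared_allotypes: Sequence[str] | None = None,
    binder_threshold: float = BINDER_RANK_THRESHOLD,
) -> dict:
    """Peptidome overlap between two samples of the same HLA class.

    Always reports the shared peptide count and its percentage of each
    sample's total.  Given a rank predictor and the two samples' HLA
    allotype lists, additionally restricts to peptides predicted to
    bind (best rank < ``binder_threshold``) the shared versus the
    non-shared allotypes and reports the overlap of each partition —
    shared-allotype binders overlap far more than non-shared ones when
    allotypes drive presentation.
    """
    classes = set(presence_a["hla_class"]) | set(presence_b["hla_class"])
    if len(classes) > 1:
        raise ValueError("overlap requires a single HLA class")
    set_a, set_b = _present_set(presence_a), _present_set(presence_b)
    shared = set_a & set_b
    result = {
        "shared": len(shared),
        "pct_of_a": 100.0 * len(shared) / len(set_a) if set_a else np.nan,
        "pct_of_b": 100.0 * len(shared) / len(set_b) if set_b else np.nan,
    }
    if predictor is None or shared_allotypes is None:
        return result

    def binder_subset(peps: set[str], allotypes: Sequence[str]) -> set[str]:
        if not allotypes:
            return set()
        peps_l = sorted(p for p in peps if 8 <= len(p) <= 11)
        if not peps_l:
            return set()
        ranks = np.min(
            [predictor.rank_many(peps_l, a) for a in allotypes], axis=0
        )
        return {p for p, r in zip(peps_l, ranks) if r < binder_threshold}

    non_shared_a = [a for a in (allotypes_a or []) if a not in shared_allotypes]
    non_shared_b = [a for a in (allotypes_b or []) if a not in shared_allotypes]
    for label, al_a, al_b in [
        ("shared_allotype", shared_allotypes, shared_allotypes),
        ("non_shared_allotype", non_shared_a, non_shared_b),
    ]:
        ba, bb = binder_subset(set_a, al_a), binder_subset(set_b, al_b)
        inter = ba & bb
        result[f"{label}_binder_overlap_pct"] = (
            100.0 * len(inter) / min(len(ba), len(bb))
            if ba and bb
            else np.nan
        )
    return result


def intensity_correlation(
    presence_a: pd.DataFrame,
    presence_b: pd.DataFrame,
    log10: bool = True,
) -> float:
    """Pearson r of median raw intensities over co-present peptides.

    Peptides present in only one sample are excluded.  Raw intensities
    span decades, so the correlation is computed on log10 values by
    default.
    """
    a = presence_a.set_index("peptide")["median_intensity"]
    b = presence_b.set_index("peptide")["median_intensity"]
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} co-present peptides; need at least 3"
        )
    x, y = a[common].to_numpy(float), b[common].to_numpy(float)
    if log10:
        x, y = np.log10(x), np.log10(y)
    return float(stats.pearsonr(x, y).statistic)


def normalized_appearance(
    presence: pd.DataFrame,
    proteome: Sequence[ProteinRecord],
    expression: pd.DataFrame,
    expression_cutoffs: Sequence[float] = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0),
) -> dict:
    """Length-normalized peptide appearance per gene versus expression.

    The appearance of a gene is the number of distinct present peptides
    uniquely mapping to its protein divided by the protein length.
    Reports the per-gene table, Pearson and Spearman correlations of
    appearance with expression, and — per expression cutoff — the
    number of genes at or below the cutoff from which at least one
    peptide was presented (the low-expression presentation curve).
    """
    by_prot = {p.protein_id: p for p in proteome}
    for p in proteome:
        if p.length == 0:
            raise ValueError(f"zero-length protein {p.protein_id}")
    mapping = map_source_proteins(
        sorted(set(presence["peptide"])), proteome
    )["peptide_to_protein"]
    counts: dict[str, int] = {}
    for pep, prot_id in mapping.items():
        counts[prot_id] = counts.get(prot_id, 0) + 1
    rows = []
    expr_map = dict(zip(expression["gene_id"], expression["expression"]))
    for prot in proteome:
        n = counts.get(prot.protein_id, 0)
        rows.append(
            dict(
                gene_id=prot.gene_id,
                n_peptides=n,
                protein_length=prot.length,
                appearance=n / prot.length,
                expression=expr_map.get(prot.gene_id, np.nan),
            )
        )
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["expression"])
    pearson = spearman = np.nan
    if len(valid) >= 3 and valid["appearance"].nunique() > 1:
        pearson = float(
            stats.pearsonr(valid["expression"], valid["appearance"]).statistic
        )
        spearman = float(
            stats.spearmanr(valid["expression"], valid["appearance"]).statistic
        )
    curve = {
        float(c): int(
            ((valid["expression"] <= c) & (valid["n_peptides"] > 0)).sum()
        )
        for c in expression_cutoffs
    }
    return {
        "per_gene": table,
        "pearson_r": pearson,
        "spearman_r": spearman,
        "low_expression_curve": curve,
    }
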