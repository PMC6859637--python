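"""Detection-versus-prediction neoantigen funnel and rank summaries.

The funnel counts candidate mutations at successive stages: all
non-silent mutations able to generate neoantigen sequences; those
predicted to encode at least one strong HLA-I binder (best percentile
rank < 0.5 across autologous allotypes); the subset in detectably
expressed genes (mean expression > 0); and, on a separate lane, the
mutations whose ligands were actually detected by MS.  Detected
neoantigens are deliberately NOT required to be predicted binders —
detected-but-unpredicted mutations are counted separately rather than
forced into subset semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

#: Percentile-rank thresholds (strict inequalities).
STRONG_RANK_THRESHOLD = 0.5
WEAK_RANK_THRESHOLD = 2.0


class RankCall(NamedTuple):
    rank: float
    allotype: str


def best_rank(
    peptide: str, allotypes: Sequence[str], predictor
) -> RankCall:
    """Lowest percentile rank of a peptide across allotypes.

    Ties resolve to the same rank value; the reported allotype is the
    alphabetically first among the minimizers.
    """
    if not allotypes:
        raise ValueError("at least one allotype required")
    ranks = {a: float(predictor.rank(peptide, a)) for a in allotypes}
    lowest = min(ranks.values())
    winner = min(a for a, r in ranks.items() if r == lowest)
    return RankCall(lowest, winner)


def classify_binder(rank: float) -> str:
    """Strong binder below rank 0.5, weak below 2, else non-binder."""
    if not 0 < rank <= 100:
        raise ValueError(f"rank {rank} outside (0, 100]")
    if rank < STRONG_RANK_THRESHOLD:
        return "strong"
    if rank < WEAK_RANK_THRESHOLD:
        return "weak"
    return "non-binder"


@dataclass(frozen=True)
class FunnelSummary:
    """Counts and percentages at each funnel stage."""

    n_candidate_mutations: int
    n_strong_binder_mutations: int
    n_expressed_strong_binder_mutations: int
    n_ms_detected_mutations: int
    n_detected_unpredicted: int

    def __post_init__(self) -> None:
        if not (
            self.n_candidate_mutations
            >= self.n_strong_binder_mutations
            >= self.n_expressed_strong_binder_mutations
        ):
            raise ValueError("funnel stages must be monotone")
        if self.n_ms_detected_mutations > self.n_candidate_mutations:
            raise ValueError("detected mutations exceed candidates")

    def _pct(self, n: int) -> float:
        if self.n_candidate_mutations == 0:
            return float("nan")
        return 100.0 * n / self.n_candidate_mutations

    @property
    def pct_strong(self) -> float:
        return self._pct(self.n_strong_binder_mutations)

    @property
    def pct_expressed_strong(self) -> float:
        return self._pct(self.n_expressed_strong_binder_mutations)

    @property
    def pct_detected(self) -> float:
        return self._pct(self.n_ms_detected_mutations)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(
            pct_strong=round(self.pct_strong, 2),
            pct_expressed_strong=round(self.pct_expressed_strong, 2),
            pct_detected=round(self.pct_detected, 2),
        )
        return d


def funnel_from_flags(
    mutations: pd.DataFrame, detected_ids: Iterable[str]
) -> FunnelSummary:
    """Assemble a funnel from mutation-level flags.

    ``mutations`` needs columns mutation_id, predicted_strong and
    expressed; ``detected_ids`` are the MS-detected neoantigen
    mutations.
    """
    detected = set(detected_ids)
    unknown = detected - set(mutations["mutation_id"])
    if unknown:
        raise ValueError(f"detected mutations not in candidate table: {unknown}")
    strong = mutations["predicted_strong"].astype(bool)
    expressed = mutations["expressed"].astype(bool)
    strong_ids = set(mutations.loc[strong, "mutation_id"])
    return FunnelSummary(
        n_candidate_mutations=len(mutations),
        n_strong_binder_mutations=int(strong.sum()),
        n_expressed_strong_binder_mutations=int((strong & expressed).sum()),
        n_ms_detected_mutations=len(detected),
        n_detected_unpredicted=len(detected - strong_ids),
    )


def build_funnel(
    candidates: pd.DataFrame,
    predictor,
    allotypes: Sequence[str],
    expression: pd.DataFrame,
    detected_hits: pd.DataFrame,
) -> FunnelSummary:
    """Build the funnel from candidate peptides and a rank predictor.

    ``candidates`` has one row per candidate peptide with columns
    mutation_id, gene_id and peptide.  A mutation counts as a strong
    binder if any of its candidate peptides has best rank < 0.5 across
    the autologous allotypes; as expressed if its source gene's mean
    expression exceeds zero; as detected if it appears in
    ``detected_hits`` (output of the detection-matching stage).
    """
    expr_map = dict(zip(expression["gene_id"], expression["expression"]))
    missing = sorted(set(candidates["gene_id"]) - set(expr_map))
    if missing:
        raise KeyError(f"missing expression for gene(s): {missing[:5]}")

    peptides = candidates["peptide"].tolist()
    ranks = np.min(
        [predictor.rank_many(peptides, a) for a in allotypes], axis=0
    )
    per_pep = candidates.assign(best_rank=ranks)
    by_mut = per_pep.groupby("mutation_id").agg(
        best_rank=("best_rank", "min"), gene_id=("gene_id", "first")
    )
    flags = pd.DataFrame(
        {
            "mutation_id": by_mut.index,
            "predicted_strong": (by_mut["best_rank"] < STRONG_RANK_THRESHOLD).values,
            "expressed": (by_mut["gene_id"].map(expr_map) > 0).values,
        }
    )
    detected = set(detected_hits["mutation_id"]) if len(detected_hits) else set()
    return funnel_from_flags(flags, detected)


def rank_summary(
    peptides: Sequence[str], allotypes: Sequence[str], predictor
) -> dict:
    """Best-rank distribution of a detected peptide set.

    Reports the fraction of peptides with best rank < 0.5 (strong),
    < 2 (weak or strong), and the median best rank.
    """
    peps = list(peptides)
    if not peps:
        raise ValueError("empty peptide set")
    ranks = np.min([predictor.rank_many(peps, a) for a in allotypes], axis=0)
    return {
        "n": len(peps),
        "fraction_lt_strong": float(np.mean(ranks < STRONG_RANK_THRESHOLD)),
        "fraction_lt_weak": float(np.mean(ranks < WEAK_RANK_THRESHOLD)),
        "median_rank": float(np.median(ranks)),
        "ranks": ranks,
    }


def cta_scan(
    presence: pd.DataFrame,
    gene_list: Iterable[str],
    peptide_gene_map: Mapping[str, str],
) -> pd.DataFrame:
    """Peptides whose source genes belong to a gene list (e.g. the
    cancer/testis antigens), per sample and HLA class."""
    genes = set(gene_list)
    out = presence.copy()
    out["gene_id"] = out["peptide"].map(peptide_gene_map)
    hits = out[out["gene_id"].isin(genes)]
    cols = ["peptide", "sample_id", "condition", "hla_class", "gene_id"]
    return hits[cols].reset_index(drop=True)


def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list, one symbol per line, '#' comments allowed."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
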