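"""Differential peptide presentation between treatment conditions.

The workflow mirrors standard label-free proteomics practice: log2
intensities per biological replicate are width-normalized per column
(median centred, scaled by the Gaussian-equivalent interquartile
width), missing values are imputed from a down-shifted narrow Gaussian
(width 20% of the column SD, down-shift 1.8 SDs by default), peptides
are tested with paired t-tests across biological replicates, and
p-values receive Benjamini-Hochberg FDR correction.  A peptide is
significant iff q <= 0.05 and |log2 fold change| >= 1 (a 2-fold
change).  Results are annotated with IFNγ-inducibility of the source
gene and the chymotrypsin-like C-terminus flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import CHYMO_C_TERMINI

#: IQR of a standard normal: divides the interquartile range to give a
#: Gaussian-consistent scale estimate.
GAUSSIAN_IQR = 1.349

#: Default down-shift of the imputation Gaussian, in column SD units.
DEFAULT_IMPUTATION_SHIFT = 1.8

#: Default width of the imputation Gaussian as a fraction of column SD.
DEFAULT_IMPUTATION_WIDTH = 0.2

Q_THRESHOLD = 0.05
LOG2_FOLD_THRESHOLD = 1.0

STAGES = ("raw-log2", "normalized", "imputed")


@dataclass(frozen=True)
class IntensityMatrix:
    """Peptides x replicate-columns matrix of log2 intensities.

    Columns are identified by ``(condition, bio_rep)``; missingness is
    NaN.  The ``stage`` records where the matrix sits in the
    raw-log2 -> normalized -> imputed chain; stage transitions only move
    forward and the imputed stage has no missing cells.
    """

    values: pd.DataFrame  # columns: MultiIndex (condition, bio_rep)
    stage: str = "raw-log2"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def conditions(self) -> list[str]:
        return sorted({c for c, _ in self.values.columns})


def build_intensity_matrix(
    evidence: pd.DataFrame, agg: str = "mean"
) -> IntensityMatrix:
    """Assemble a raw-log2 matrix from replicate-level evidence.

    Each cell is the log2 of the aggregated raw intensity over the
    detecting technical replicates of one biological replicate; cells
    with no detection are missing.
    """
    g = (
        evidence.groupby(["peptide", "condition", "bio_rep"])["intensity"]
        .agg(agg)
        .unstack(["condition", "bio_rep"])
    )
    return IntensityMatrix(values=np.log2(g), stage="raw-log2")


def normalize_matrix(m: IntensityMatrix) -> IntensityMatrix:
    """Width normalization: centre each column at its median and scale
    by IQR/1.349.

    After normalization every column has median exactly 0 and unit
    Gaussian-equivalent width; on realistic simulated data values fall
    within [-10, 10].  Location/scale-equivariant: an affine transform
    of a column yields identical output.
    """
    if m.stage != "raw-log2":
        raise ValueError(f"expected stage raw-log2, got {m.stage}")
    out = m.values.copy()
    for col in out.columns:
        observed = out[col].dropna()
        if len(observed) < 4:
            raise ValueError(
                f"column {col} has {len(observed)} observed values; "
                "need at least 4 for width normalization"
            )
        q1, med, q3 = observed.quantile([0.25, 0.5, 0.75])
        width = (q3 - q1) / GAUSSIAN_IQR
        if width == 0:
            raise ValueError(f"column {col} has zero interquartile range")
        out[col] = (out[col] - med) / width
    return IntensityMatrix(values=out, stage="normalized")


def impute_missing(
    m: IntensityMatrix,
    seed: int,
    shift: float = DEFAULT_IMPUTATION_SHIFT,
    width: float = DEFAULT_IMPUTATION_WIDTH,
) -> IntensityMatrix:
    """Impute missing cells from a down-shifted narrow Gaussian.

    Each missing cell of column c is drawn from
    Normal(mean_c - shift * sd_c, (width * sd_c)^2) where mean_c and
    sd_c are the column's observed mean and SD — the standard proteomics
    assumption that missingness reflects abundances below the detection
    limit.  Observed cells are untouched; draws are reproducible by
    seed.
    """
    if m.stage != "normalized":
        raise ValueError(f"expected stage normalized, got {m.stage}")
    rng = np.random.default_rng(seed)
    out = m.values.copy()
    for col in out.columns:
        observed = out[col].dropna()
        if observed.empty:
            raise ValueError(f"column {col} is entirely missing")
        missing = out[col].isna()
        if not missing.any():
            continue
        mu, sd = float(observed.mean()), float(observed.std(ddof=1))
        out.loc[missing, col] = rng.normal(
            mu - shift * sd, width * sd, size=int(missing.sum())
        )
    return IntensityMatrix(values=out, stage="imputed")


def test_differential(
    m: IntensityMatrix,
    treated: str,
    untreated: str,
    mode: str = "paired",
) -> pd.DataFrame:
    """Per-peptide differential test between two conditions.

    Paired mode pairs biological replicates by index across conditions
    (requiring identical replicate sets); ``mode="welch"`` runs an
    unpaired unequal-variance test for unbalanced designs.  The log2
    fold change is the mean treated-minus-untreated difference of
    normalized values; q-values are Benjamini-Hochberg; a peptide is
    significant iff q <= 0.05 and |log2FC| >= 1.
    """
    if m.stage != "imputed":
        raise ValueError(f"expected stage imputed, got {m.stage}")
    cols_t = sorted(b for c, b in m.values.columns if c == treated)
    cols_u = sorted(b for c, b in m.values.columns if c == untreated)
    if not cols_t or not cols_u:
        raise ValueError("both conditions must be present in the matrix")
    if mode == "paired":
        if cols_t != cols_u:
            raise ValueError(
                "unpaired replicate design: biological replicates "
                f"{cols_t} vs {cols_u}; use mode='welch'"
            )
        if len(cols_t) < 2:
            raise ValueError("paired test needs >= 2 replicate pairs")
        x = m.values[[(treated, b) for b in cols_t]].to_numpy(float)
        y = m.values[[(untreated, b) for b in cols_u]].to_numpy(float)
        res = stats.ttest_rel(x, y, axis=1)
        lfc = (x - y).mean(axis=1)
    elif mode == "welch":
        x = m.values[[(treated, b) for b in cols_t]].to_numpy(float)
        y = m.values[[(untreated, b) for b in cols_u]].to_numpy(float)
        res = stats.ttest_ind(x, y, axis=1, equal_var=False)
        lfc = x.mean(axis=1) - y.mean(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pvals = np.asarray(res.pvalue)
    # identical paired values give 0/0 -> NaN; no evidence of change
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = pd.DataFrame(
        {
            "peptide": m.values.index,
            "log2_fold_change": lfc,
            "p_value": pvals,
            "q_value": qvals,
        }
    )
    out["significant"] = (out["q_value"] <= Q_THRESHOLD) & (
        out["log2_fold_change"].abs() >= LOG2_FOLD_THRESHOLD
    )
    return out.reset_index(drop=True)


def chymo_fraction(peptides: Iterable[str]) -> float:
    """Fraction of peptides with a chymotrypsin-like C-terminal residue
    (A, F, I, L, M, V or Y)."""
    peps = list(peptides)
    if not peps:
        raise ValueError("empty peptide set")
    return sum(p[-1] in CHYMO_C_TERMINI for p in peps) / len(peps)


def annotate_results(
    results: pd.DataFrame,
    ifng_gene_set: Iterable[str],
    peptide_gene_map: Mapping[str, str],
) -> tuple[pd.DataFrame, dict]:
    """Flag IFNγ-inducible source genes and chymotrypsin-like ligands.

    Peptides with no gene mapping get a missing IFNγ flag and are
    excluded from the gene-set counts.  The summary reports up/down
    counts among significant IFNγ-inducible peptides and the overall
    chymotrypsin-like fraction.
    """
    gene_set = set(ifng_gene_set)
    out = results.copy()
    genes = out["peptide"].map(peptide_gene_map)
    out["gene_id"] = genes
    out["ifng_inducible"] = pd.array(
        [None if g is None or (isinstance(g, float) and np.isnan(g))
         else g in gene_set for g in genes],
        dtype="boolean",
    )
    out["chymo_like"] = out["peptide"].str[-1].isin(CHYMO_C_TERMINI)
    sig_ifng = out[(out["ifng_inducible"] == True) & out["significant"]]  # noqa: E712
    summary = {
        "n_significant": int(out["significant"].sum()),
        "n_up": int((out["significant"] & (out["log2_fold_change"] > 0)).sum()),
        "n_down": int(
            (out["significant"] & (out["log2_fold_change"] < 0)).sum()
        ),
        "ifng_up": int((sig_ifng["log2_fold_change"] > 0).sum()),
        "ifng_down": int((sig_ifng["log2_fold_change"] < 0).sum()),
        "chymo_fraction": chymo_fraction(out["peptide"]),
    }
    return out, summary


def volcano_data(results: pd.DataFrame) -> list[dict]:
    """Volcano-plot coordinates (log2FC, -log10 q) per peptide."""
    return [
        dict(
            peptide=r.peptide,
            log2_fold_change=float(r.log2_fold_change),
            neg_log10_q=float(-np.log10(max(r.q_value, 1e-300))),
            significant=bool(r.significant),
        )
        for r in results.itertuples()
    ]
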