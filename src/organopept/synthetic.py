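"""Synthetic immunopeptidomics data with known ground truth.

This module generates every input the analysis pipeline consumes — a
proteome with expression levels, somatic mutations with read-support
evidence, a peptide/HLA-allotype percentile-rank binding model, and
replicate-structured MS evidence tables with treatment effects — so the
whole pipeline runs end-to-end with no external download and every
recovery test can compare against simulated truth.

It also packages a small in-print fixture: the per-organoid candidate
mutation table (612 non-silent candidate mutations across five lines)
with the three MS-detected neoantigen mutations (U2SURP T224R,
MED25 K422T, FMO5 S423N), their wild-type/mutant ligands and percentile
ranks, embedded in synthetic wild-type protein contexts.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# ---------------------------------------------------------------------------
# Constants
# ---------------------------------------------------------------------------

#: The 20 standard amino acids; no ambiguity codes (U/B/Z/X) are ever emitted.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: C-terminal residues defining chymotrypsin-like ligands.
CHYMO_C_TERMINI = frozenset("AFILMVY")

#: Ligand lengths handled by the class I binding model.
HLA_I_LENGTHS = (8, 9, 10, 11)

CONSEQUENCES = ("missense", "frameshift", "stop_gain", "splice_site", "silent")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DetectionModel:
    """Parameters of the peptide presentation/detection process.

    Presentation probability increases with predicted binding strength
    (low percentile rank) and with log-expression of the source gene;
    each technical replicate then independently drops a presented
    peptide with probability ``dropout``.  Genes with zero expression
    emit peptides at the small ``leak_rate`` (mirroring peptides seen
    by MS from transcripts below the RNA-seq detection limit).
    """

    rank_weight: float = 1.6
    expr_weight: float = 0.25
    intercept: float = -4.0
    dropout: float = 0.2
    leak_rate: float = 0.002


@dataclass(frozen=True)
class IntensityModel:
    """Log-normal raw MS intensity: log2 intensity ~ N(location, scale)."""

    location: float = 22.0
    scale: float = 1.5
    bio_noise_sd: float = 0.3
    tech_noise_sd: float = 0.15


@dataclass(frozen=True)
class TreatmentEffects:
    """Systematic condition effects applied when simulating evidence.

    IFNγ raises HLA abundance (scaling presentation probability),
    upregulates IFNγ-inducible source genes and shifts C-terminal
    residue usage toward chymotrypsin-like ligands; the MEK inhibitor
    has no systematic effect.
    """

    hla_scale: float = 1.3
    ifng_fold_change: float = 4.0
    chymo_bias: float = 1.5
    ifng_gene_fraction: float = 0.10


@dataclass(frozen=True)
class SimConfig:
    """Complete, seedable description of one simulated sample.

    Defaults are scaled to a single patient-derived organoid line: a
    few hundred proteins, a non-silent mutation load in the range seen
    in microsatellite-stable colorectal cancer (~80–210 per line), up
    to six class I allotypes, and two technical replicates nested in
    two biological replicates per condition.
    """

    n_proteins: int = 200
    protein_length_range: tuple[int, int] = (100, 500)
    n_mutations: int = 120
    consequence_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "missense": 0.80,
            "frameshift": 0.05,
            "stop_gain": 0.04,
            "splice_site": 0.04,
            "silent": 0.07,
        }
    )
    allotypes: tuple[str, ...] = (
        "HLA-A*01:01",
        "HLA-A*02:01",
        "HLA-B*07:02",
        "HLA-B*08:01",
        "HLA-C*04:01",
        "HLA-C*07:01",
    )
    background_size: int = 5000
    detection_model: DetectionModel = field(default_factory=DetectionModel)
    intensity_model: IntensityModel = field(default_factory=IntensityModel)
    treatment_effects: TreatmentEffects = field(default_factory=TreatmentEffects)
    replicate_design: tuple[int, int] = (2, 2)  # (biological, technical)
    conditions: tuple[str, ...] = ("untreated",)
    decoy_fraction: float = 0.3
    clonal_fraction: float = 0.93
    peptide_pool_size: int = 8000
    zero_expression_fraction: float = 0.15
    sample_id: str = "SIM-01"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.protein_length_range
        if lo > hi:
            raise ConfigurationError(
                f"protein_length_range min {lo} exceeds max {hi}"
            )
        if lo < max(HLA_I_LENGTHS):
            raise ConfigurationError("proteins must be at least 11 aa long")
        if self.n_proteins < 0 or self.n_mutations < 0:
            raise ConfigurationError("counts must be non-negative")
        total = sum(self.consequence_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"consequence_mix must sum to 1 (got {total})"
            )
        unknown = set(self.consequence_mix) - set(CONSEQUENCES)
        if unknown:
            raise ConfigurationError(f"unknown consequence classes: {unknown}")
        if not 1 <= len(self.allotypes) <= 6:
            raise ConfigurationError("1-6 allotypes per sample")
        if self.background_size < 1000:
            raise ConfigurationError("background_size must be >= 1000")
        n_bio, n_tech = self.replicate_design
        if n_bio < 1 or n_tech < 1:
            raise ConfigurationError("replicate design counts must be >= 1")
        if not 0 <= self.decoy_fraction <= 1:
            raise ConfigurationError("decoy_fraction must be in [0,1]")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), default=list, indent=2)


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent deterministic generators derived from one seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Proteome and expression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """One protein (one gene per protein) with its amino-acid sequence."""

    protein_id: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-standard residues in sequence: {bad}")

    @property
    def length(self) -> int:
        return len(self.sequence)


def generate_proteome(config: SimConfig) -> list[ProteinRecord]:
    """Generate a synthetic proteome of random-sequence proteins.

    Sequences are uniform over the 20 standard residues, lengths uniform
    within the configured range, one gene per protein.  Reproducible
    given the config seed.
    """
    rng = _child_rngs(config.seed, 1)[0]
    lo, hi = config.protein_length_range
    records = []
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(
            np.array(list(AMINO_ACIDS))[rng.integers(0, 20, size=length)]
        )
        records.append(
            ProteinRecord(
                protein_id=f"PROT{i:04d}", gene_id=f"GENE{i:04d}", sequence=seq
            )
        )
    return records


def write_proteome_fasta(proteome: Sequence[ProteinRecord], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.protein_id, description=f"gene={p.gene_id}")
        for p in proteome
    ]
    SeqIO.write(records, str(path), "fasta")


def read_proteome_fasta(path: str | Path) -> list[ProteinRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = re.search(r"gene=(\S+)", rec.description)
        gene = m.group(1) if m else rec.id
        out.append(ProteinRecord(rec.id, gene, str(rec.seq)))
    return out


def generate_expression(
    proteome: Sequence[ProteinRecord], config: SimConfig
) -> pd.DataFrame:
    """Gene-level log2-normalized expression with explicit zeros.

    A configurable fraction of genes is exactly zero (undetectable by
    3'-RNA-seq); the rest follow a truncated normal on the log2 scale.
    """
    rng = _child_rngs(config.seed, 2)[1]
    genes = [p.gene_id for p in proteome]
    values = np.clip(rng.normal(5.0, 2.5, size=len(genes)), 0.0, None)
    zero_mask = rng.random(len(genes)) < config.zero_expression_fraction
    values[zero_mask] = 0.0
    return pd.DataFrame({"gene_id": genes, "expression": np.round(values, 4)})


# ---------------------------------------------------------------------------
# Somatic mutations
# ---------------------------------------------------------------------------

#: Columns of the variant table produced by :func:`generate_mutations`.
VARIANT_COLUMNS = [
    "variant_id", "sample_id", "variant_class", "consequence",
    "protein_id", "gene_id", "aa_pos", "ref_aa", "alt_aa",
    "vaf_tumor", "var_reads_tumor", "depth_tumor",
    "vaf_germline", "var_reads_germline", "depth_germline",
    "ccf", "cds", "nt_pos", "ref_nt", "alt_nt",
    "truth_passes_filter", "truth_clonal",
]

_CODON_CHOICES: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    """Amino acid -> codons under the standard genetic code."""
    if _CODON_CHOICES:
        return _CODON_CHOICES
    bases = "ACGT"
    for a in bases:
        for b in bases:
            for c in bases:
                codon = a + b + c
                aa = str(Seq(codon).translate())
                if aa != "*":
                    _CODON_CHOICES.setdefault(aa, []).append(codon)
    return _CODON_CHOICES


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """A CDS encoding ``protein`` (random synonymous codons) plus a stop."""
    table = _codon_table()
    codons = [table[aa][int(rng.integers(len(table[aa])))] for aa in protein]
    return "".join(codons) + "TAA"


def _passing_read_support(rng: np.random.Generator) -> dict:
    vaf_t = float(rng.uniform(0.15, 0.95))
    depth_t = int(rng.integers(40, 200))
    reads_t = max(6, int(round(vaf_t * depth_t)))
    reads_t = min(reads_t, depth_t)
    vaf_t = reads_t / depth_t
    reads_g = int(rng.integers(0, 2))
    # keep germline VAF within the contamination bound (reads/depth <= 2.5%)
    depth_g = int(rng.integers(40 if reads_g else 25, 200))
    return dict(
        vaf_tumor=round(vaf_t, 4), var_reads_tumor=reads_t, depth_tumor=depth_t,
        vaf_germline=round(reads_g / depth_g, 4), var_reads_germline=reads_g,
        depth_germline=depth_g,
    )


def _decoy_read_support(rng: np.random.Generator, variant_class: str) -> dict:
    """Read support constructed to fail exactly the chosen retention rule."""
    sup = _passing_read_support(rng)
    rules = ["tumor_vaf", "tumor_reads", "germline_vaf", "germline_depth",
             "germline_reads"]
    if variant_class == "indel":
        rules.append("tumor_depth")
    rule = rules[int(rng.integers(len(rules)))]
    if rule == "tumor_vaf":
        depth = int(rng.integers(150, 300))
        reads = max(6, int(round(depth * rng.uniform(0.03, 0.09))))
        sup.update(depth_tumor=depth, var_reads_tumor=reads,
                   vaf_tumor=round(reads / depth, 4))
    elif rule == "tumor_reads":
        depth = int(rng.integers(20, 40))
        reads = int(rng.integers(3, 6))
        sup.update(depth_tumor=depth, var_reads_tumor=reads,
                   vaf_tumor=round(max(reads / depth, 0.10), 4))
    elif rule == "germline_vaf":
        depth = int(rng.integers(50, 120))
        reads = max(int(np.ceil(depth * 0.03)), 3)
        reads = min(reads, 5)  # keep the reads rule satisfied
        depth = min(depth, int(reads / 0.026))  # force vaf > 2.5%
        depth = max(depth, 25)
        sup.update(depth_germline=depth, var_reads_germline=reads,
                   vaf_germline=round(reads / depth, 4))
    elif rule == "germline_depth":
        depth = int(rng.integers(5, 25))
        sup.update(depth_germline=depth, var_reads_germline=0,
                   vaf_germline=0.0)
    elif rule == "germline_reads":
        depth = int(rng.integers(250, 500))
        reads = int(rng.integers(6, 10))  # vaf stays <= 2.5% at this depth
        sup.update(depth_germline=depth, var_reads_germline=reads,
                   vaf_germline=round(reads / depth, 4))
    elif rule == "tumor_depth":
        depth = int(rng.integers(6, 15))
        reads = max(6, int(round(depth * 0.5)))
        reads = min(reads, depth)
        sup.update(depth_tumor=depth, var_reads_tumor=reads,
                   vaf_tumor=round(reads / depth, 4))
    return sup


def generate_mutations(
    proteome: Sequence[ProteinRecord], config: SimConfig
) -> pd.DataFrame:
    """Simulate somatic variant calls with protein-level consequences.

    Each call carries tumor/germline read support; a ``decoy_fraction``
    of calls is constructed to fail the somatic retention filter, the
    rest to pass, and the truth is recorded per row.  Cancer cell
    fractions are drawn so that ``clonal_fraction`` of calls are clonal
    (CCF > 0.7).  Non-silent calls carry the mutant protein consequence
    (alt residue for missense; CDS and nucleotide edit for frameshift).
    """
    if not proteome:
        raise ValueError("proteome must be non-empty")
    rng = _child_rngs(config.seed, 3)[2]
    total_positions = sum(p.length for p in proteome)
    if config.n_mutations > total_positions:
        raise ConfigurationError(
            f"n_mutations {config.n_mutations} exceeds mutable positions "
            f"{total_positions}"
        )

    classes = sorted(config.consequence_mix)
    probs = np.array([config.consequence_mix[c] for c in classes])
    rows = []
    used: set[tuple[str, int]] = set()
    for i in range(config.n_mutations):
        consequence = classes[int(rng.choice(len(classes), p=probs))]
        while True:
            prot = proteome[int(rng.integers(len(proteome)))]
            aa_pos = int(rng.integers(1, prot.length + 1))
            if (prot.protein_id, aa_pos) not in used:
                used.add((prot.protein_id, aa_pos))
                break
        ref_aa = prot.sequence[aa_pos - 1]
        alt_aa, cds, nt_pos, ref_nt, alt_nt = "", "", 0, "", ""
        variant_class = "snv"
        if consequence == "missense":
            choices = [a for a in AMINO_ACIDS if a != ref_aa]
            alt_aa = choices[int(rng.integers(len(choices)))]
        elif consequence == "frameshift":
            variant_class = "indel"
            cds = back_translate(prot.sequence, rng)
            nt_pos = (aa_pos - 1) * 3 + 1
            ref_nt = cds[nt_pos - 1]
            alt_nt = ""  # single-nucleotide deletion

        is_decoy = rng.random() < config.decoy_fraction
        support = (
            _decoy_read_support(rng, variant_class)
            if is_decoy
            else _passing_read_support(rng)
        )
        truth_clonal = rng.random() < config.clonal_fraction
        ccf = (
            float(rng.uniform(0.705, 1.15))
            if truth_clonal
            else float(rng.uniform(0.05, 0.7))
        )
        rows.append(
            dict(
                variant_id=f"VAR{i:05d}",
                sample_id=config.sample_id,
                variant_class=variant_class,
                consequence=consequence,
                protein_id=prot.protein_id,
                gene_id=prot.gene_id,
                aa_pos=aa_pos,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                ccf=round(ccf, 4),
                cds=cds,
                nt_pos=nt_pos,
                ref_nt=ref_nt,
                alt_nt=alt_nt,
                truth_passes_filter=not is_decoy,
                truth_clonal=truth_clonal,
                **support,
            )
        )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


# ---------------------------------------------------------------------------
# Binding model
# ---------------------------------------------------------------------------

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_AA_LOOKUP = np.full(128, -1, dtype=np.int8)
for _aa, _i in _AA_INDEX.items():
    _AA_LOOKUP[ord(_aa)] = _i


def _length_mapping(length: int) -> np.ndarray:
    """Map peptide positions of a given length onto the 9 PWM columns.

    The first four residues map to columns 0-3 and the last five (four
    for 8-mers) to the C-terminal columns; extra central residues of
    10/11-mers bulge out of the groove and are ignored.  Returns, per
    mapped peptide position, its PWM column (-1 = unmapped).
    """
    if length not in HLA_I_LENGTHS:
        raise ValueError(f"peptide length {length} outside 8-11")
    cols = np.full(length, -1, dtype=int)
    cols[:4] = [0, 1, 2, 3]
    if length == 8:
        cols[4:] = [5, 6, 7, 8]
    else:
        cols[-5:] = [4, 5, 6, 7, 8]
    return cols


class BindingModel:
    """Synthetic per-allotype peptide binding model with empirical ranks.

    Each allotype is a 9-position position-weight matrix with 2-3 anchor
    positions; peptides of length 8-11 are scored through a deterministic
    position mapping.  The percentile rank of a peptide for an allotype is
    calibrated empirically: rank = 100 x (number of background peptides of
    the same length scoring >= the peptide) / background size, floored at
    half a background count so fresh peptides that outscore the whole
    background still get a positive rank.  Ranks lie in (0, 100]; random
    peptides receive approximately uniform ranks; equal scores share a rank.
    """

    def __init__(
        self,
        allotypes: Sequence[str],
        pwms: Mapping[str, np.ndarray],
        backgrounds: Mapping[tuple[str, int], np.ndarray],
        background_size: int,
    ) -> None:
        self.allotypes = tuple(allotypes)
        self._pwms = dict(pwms)
        self._backgrounds = dict(backgrounds)  # sorted score arrays
        self.background_size = background_size

    # -- scoring ----------------------------------------------------------
    def score(self, peptides: Sequence[str], allotype: str) -> np.ndarray:
        """PWM scores for equal-length peptides against one allotype."""
        pwm = self._pwms[allotype]
        peps = list(peptides)
        if not peps:
            return np.empty(0)
        length = len(peps[0])
        if any(len(p) != length for p in peps):
            raise ValueError("score() requires equal-length peptides")
        cols = _length_mapping(length)
        raw = np.frombuffer("".join(peps).encode("ascii"), dtype=np.uint8)
        idx = _AA_LOOKUP[raw.reshape(len(peps), length)]
        if (idx < 0).any():
            raise ValueError("non-standard residue in peptide")
        mapped = cols >= 0
        return pwm[cols[mapped][None, :], idx[:, mapped]].sum(axis=1)

    def rank(self, peptide: str, allotype: str) -> float:
        return float(self.rank_many([peptide], allotype)[0])

    def rank_many(self, peptides: Sequence[str], allotype: str) -> np.ndarray:
        """Empirical percentile ranks; vectorized over one allotype."""
        peps = list(peptides)
        out = np.empty(len(peps))
        by_len: dict[int, list[int]] = {}
        for i, p in enumerate(peps):
            by_len.setdefault(len(p), []).append(i)
        for length, idxs in by_len.items():
            if length not in HLA_I_LENGTHS:
                raise ValueError(f"peptide length {length} outside 8-11")
            bg = self._backgrounds[(allotype, length)]
            scores = self.score([peps[i] for i in idxs], allotype)
            # count of background scores >= score
            n_ge = len(bg) - np.searchsorted(bg, scores, side="left")
            ranks = 100.0 * np.maximum(n_ge, 0.5) / len(bg)
            out[np.array(idxs)] = ranks
        return out

    def best_ranks(self, peptides: Sequence[str]) -> np.ndarray:
        """Lowest rank across all allotypes, per peptide."""
        all_ranks = np.stack(
            [self.rank_many(peptides, a) for a in self.allotypes]
        )
        return all_ranks.min(axis=0)

    def subset(self, allotypes: Sequence[str]) -> "BindingModel":
        """A view of the model restricted to a subset of allotypes."""
        missing = set(allotypes) - set(self.allotypes)
        if missing:
            raise KeyError(f"unknown allotypes: {sorted(missing)}")
        return BindingModel(
            allotypes,
            {a: self._pwms[a] for a in allotypes},
            {k: v for k, v in self._backgrounds.items() if k[0] in set(allotypes)},
            self.background_size,
        )


def _random_peptides(
    rng: np.random.Generator, n: int, length: int
) -> list[str]:
    aa = np.array(list(AMINO_ACIDS))
    mat = aa[rng.integers(0, 20, size=(n, length))]
    return ["".join(row) for row in mat]


def build_binding_model(
    allotypes: Sequence[str], config: SimConfig
) -> BindingModel:
    """Build the synthetic PWM binding model for a set of allotypes.

    Anchor structure: each allotype gets 2-3 anchor columns (always the
    second and last position, optionally position 3) with one strongly
    and two moderately preferred residues; non-anchor columns carry mild
    random preferences.
    """
    if not allotypes:
        raise ValueError("at least one allotype required")
    rng = _child_rngs(config.seed, 4)[3]
    pwms: dict[str, np.ndarray] = {}
    backgrounds: dict[tuple[str, int], np.ndarray] = {}
    for allotype in allotypes:
        pwm = rng.normal(0.0, 0.3, size=(9, 20))
        n_anchors = int(rng.integers(2, 4))
        anchor_cols = [1, 8] if n_anchors == 2 else [1, 2, 8]
        for col in anchor_cols:
            residues = rng.choice(20, size=3, replace=False)
            pwm[col, residues[0]] += 3.0
            pwm[col, residues[1:]] += 1.5
        pwms[allotype] = pwm
    model = BindingModel(allotypes, pwms, backgrounds, config.background_size)
    for allotype in allotypes:
        for length in HLA_I_LENGTHS:
            peps = _random_peptides(rng, config.background_size, length)
            model._backgrounds[(allotype, length)] = np.sort(
                model.score(peps, allotype)
            )
    return model


# ---------------------------------------------------------------------------
# MS evidence simulation
# ---------------------------------------------------------------------------

EVIDENCE_COLUMNS = [
    "peptide", "sample_id", "condition", "bio_rep", "tech_rep",
    "intensity", "hla_class", "gene_id", "protein_id",
]


@dataclass
class GroundTruth:
    """Simulated truth for recovery tests.

    ``true_presented`` maps condition -> DataFrame (peptide, gene_id,
    protein_id, probability) of peptides actually presented in that
    condition; ``true_neoantigen_mutations`` maps mutation id -> list of
    presented mutant ligands (each neoantigen ligand originates from
    exactly one mutation).
    """

    true_presented: dict[str, pd.DataFrame]
    true_neoantigen_mutations: dict[str, list[str]]

    def presented_set(self, condition: str) -> set[str]:
        return set(self.true_presented[condition]["peptide"])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_presented": {
                c: df.to_dict(orient="records")
                for c, df in sorted(self.true_presented.items())
            },
            "true_neoantigen_mutations": {
                k: v for k, v in sorted(self.true_neoantigen_mutations.items())
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def ifng_gene_set(
    proteome: Sequence[ProteinRecord], config: SimConfig
) -> set[str]:
    """The simulated IFNγ-inducible genes: the deterministic leading
    fraction of the sorted gene list (so analysis code can annotate
    results without peeking at hidden state)."""
    genes_sorted = sorted({p.gene_id for p in proteome})
    n = int(round(config.treatment_effects.ifng_gene_fraction * len(genes_sorted)))
    return set(genes_sorted[:n])


def _sample_windows(
    proteome: Sequence[ProteinRecord],
    n: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sample candidate ligand windows (length 8-11) across the proteome."""
    lengths = np.array([p.length for p in proteome], dtype=float)
    weights = lengths / lengths.sum()
    prot_idx = rng.choice(len(proteome), size=n, p=weights)
    pep_lens = rng.choice(HLA_I_LENGTHS, size=n)
    rows = []
    seen = set()
    for pi, L in zip(prot_idx, pep_lens):
        prot = proteome[int(pi)]
        L = int(L)
        if prot.length < L:
            continue
        start = int(rng.integers(0, prot.length - L + 1))
        pep = prot.sequence[start : start + L]
        if pep in seen:
            continue
        seen.add(pep)
        rows.append((pep, prot.gene_id, prot.protein_id))
    return pd.DataFrame(rows, columns=["peptide", "gene_id", "protein_id"])


def simulate_evidence(
    proteome: Sequence[ProteinRecord],
    expression: pd.DataFrame,
    model: BindingModel,
    config: SimConfig,
    candidates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a replicate-structured MS evidence table.

    Candidate windows are drawn across the proteome and presented with
    probability increasing in binding strength (low percentile rank) and
    log-expression; presented peptides are observed per technical
    replicate with independent dropout and log-normal raw intensities.
    The IFNγ condition applies the configured treatment effects; the MEK
    inhibitor condition none.  Optional ``candidates`` (columns
    mutation_id, peptide, gene_id, protein_id) are mutant neoantigen
    ligands given the same presentation model; mutations with a
    presented ligand are recorded as true neoantigen mutations.

    Returns the evidence table (one row per detected peptide x condition
    x biological x technical replicate) and the ground truth.
    """
    expr_map = dict(zip(expression["gene_id"], expression["expression"]))
    for prot in proteome:
        if prot.gene_id not in expr_map:
            raise KeyError(f"missing expression for gene {prot.gene_id}")

    rng = _child_rngs(config.seed, 6)[4]
    det = config.detection_model
    eff = config.treatment_effects
    inten = config.intensity_model

    pool = _sample_windows(proteome, config.peptide_pool_size, rng)
    pool["source"] = "proteome"
    pool["mutation_id"] = ""
    if candidates is not None and len(candidates):
        cand = candidates.copy()
        for col in ("gene_id", "protein_id"):
            if col not in cand.columns:
                cand[col] = ""
        cand = cand[["peptide", "gene_id", "protein_id", "mutation_id"]]
        cand["source"] = "neoantigen"
        pool = pd.concat(
            [pool[~pool["peptide"].isin(cand["peptide"])], cand],
            ignore_index=True,
        )

    best_rank = model.best_ranks(pool["peptide"].tolist())
    base_expr = pool["gene_id"].map(expr_map).fillna(5.0).to_numpy(float)
    chymo = np.array([p[-1] in CHYMO_C_TERMINI for p in pool["peptide"]])

    is_ifng_gene = pool["gene_id"].isin(ifng_gene_set(proteome, config)).to_numpy()

    n_bio, n_tech = config.replicate_design
    evidence_rows: list[dict] = []
    truth_presented: dict[str, pd.DataFrame] = {}
    neo_mutations: dict[str, list[str]] = {}

    base_log2 = rng.normal(inten.location, inten.scale, size=len(pool))

    for condition in config.conditions:
        expr = base_expr.copy()
        if condition == "IFNg":
            expr = np.where(
                is_ifng_gene & (expr > 0),
                expr + np.log2(eff.ifng_fold_change),
                expr,
            )
        logit = (
            det.intercept
            + det.rank_weight * (-np.log10(best_rank / 100.0))
            + det.expr_weight * expr
        )
        prob = _sigmoid(logit)
        prob = np.where(expr <= 0, det.leak_rate, prob)
        if condition == "IFNg":
            prob = prob * eff.hla_scale
            prob = np.where(chymo, prob * eff.chymo_bias, prob)
            prob = np.clip(prob, 0.0, 1.0)
        presented = rng.random(len(pool)) < prob
        pres = pool.loc[presented, ["peptide", "gene_id", "protein_id",
                                    "mutation_id", "source"]].copy()
        pres["probability"] = np.round(prob[presented], 6)
        truth_presented[condition] = pres.reset_index(drop=True)

        for _, row in pres.iterrows():
            if row["source"] == "neoantigen":
                neo_mutations.setdefault(row["mutation_id"], [])
                if row["peptide"] not in neo_mutations[row["mutation_id"]]:
                    neo_mutations[row["mutation_id"]].append(row["peptide"])

        pres_idx = np.flatnonzero(presented)
        fold = np.zeros(len(pres_idx))
        if condition == "IFNg":
            fold = np.where(
                is_ifng_gene[pres_idx], np.log2(eff.ifng_fold_change), 0.0
            )
        for j, (pool_i, row) in enumerate(zip(pres_idx, pres.itertuples())):
            for b in range(1, n_bio + 1):
                bio_noise = rng.normal(0.0, inten.bio_noise_sd)
                for t in range(1, n_tech + 1):
                    if rng.random() < det.dropout:
                        continue
                    log2_i = (
                        base_log2[pool_i]
                        + fold[j]
                        + bio_noise
                        + rng.normal(0.0, inten.tech_noise_sd)
                    )
                    evidence_rows.append(
                        dict(
                            peptide=row.peptide,
                            sample_id=config.sample_id,
                            condition=condition,
                            bio_rep=b,
                            tech_rep=t,
                            intensity=round(float(2.0 ** log2_i), 2),
                            hla_class="I",
                            gene_id=row.gene_id,
                            protein_id=row.protein_id,
                        )
                    )

    evidence = pd.DataFrame(evidence_rows, columns=EVIDENCE_COLUMNS)
    truth = GroundTruth(
        true_presented=truth_presented,
        true_neoantigen_mutations=neo_mutations,
    )
    return evidence, truth


# ---------------------------------------------------------------------------
# In-print fixture (five organoid lines, Tables 1-2)
# ---------------------------------------------------------------------------

#: Non-silent mutation load per organoid line.
PDO_MUTATION_LOADS = {
    "CRC-01": 208, "CRC-03": 106, "CRC-04": 89, "CRC-05": 180, "CRC-08": 78,
}

#: Total candidate mutations able to generate predictable neoantigen
#: sequences (non-silent, excluding splice-site and stop-gain).
N_CANDIDATE_MUTATIONS = 612

#: Mutations predicted to encode at least one strong binder, and the
#: subset of those in detectably expressed genes.
N_STRONG_BINDER_MUTATIONS = 304
N_EXPRESSED_STRONG_MUTATIONS = 196

#: The three MS-detected neoantigens with their published ligands and
#: lowest percentile ranks across autologous allotypes.
PUBLISHED_NEOANTIGENS = pd.DataFrame(
    [
        ("CRC-01", "U2SURP", 11, "T224R", "IQEERDERHKT", "IQEERDERHKR",
         75.8495, 5.7765),
        ("CRC-01", "MED25", 8, "K422T", "SVDANTKL", "SVDANTTL",
         0.5336, 0.1586),
        ("CRC-04", "FMO5", 10, "S423N", "RYVESQRHTI", "RYVENQRHTI",
         0.31911, 0.2692),
    ],
    columns=["pdo", "gene", "peptide_length", "mutation", "wt_peptide",
             "mut_peptide", "wt_rank", "mut_rank"],
)

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_mutation_label(label: str) -> tuple[str, int, str]:
    """Parse a protein mutation label like ``T224R`` -> (ref, pos, alt)."""
    m = _MUTATION_RE.match(label)
    if not m:
        raise ValueError(f"cannot parse mutation label {label!r}")
    return m.group(1), int(m.group(2)), m.group(3)


def _largest_remainder_split(loads: Mapping[str, int], total: int) -> dict[str, int]:
    """Distribute ``total`` across keys proportionally to ``loads``."""
    keys = sorted(loads)
    load_sum = sum(loads.values())
    exact = {k: loads[k] * total / load_sum for k in keys}
    base = {k: int(np.floor(exact[k])) for k in keys}
    short = total - sum(base.values())
    order = sorted(keys, key=lambda k: exact[k] - base[k], reverse=True)
    for k in order[:short]:
        base[k] += 1
    return base


def _build_wt_context(
    row: pd.Series, rng: np.random.Generator, forbidden: Sequence[str]
) -> str:
    """Synthetic wild-type protein embedding the WT ligand at its printed
    residue position, with random flanks long enough that all 8-11-mer
    windows around the mutation exist."""
    _ref, pos, _alt = parse_mutation_label(row["mutation"])
    wt_pep = row["wt_peptide"]
    # locate the mutated residue within the WT peptide: the unique position
    # where wt and mutant ligand differ
    offset = next(
        i for i, (a, b) in enumerate(zip(wt_pep, row["mut_peptide"])) if a != b
    )
    start = pos - offset  # 1-based start of the WT peptide in the protein
    assert start >= 1
    tail_len = 30
    total_len = start - 1 + len(wt_pep) + tail_len
    for _ in range(100):
        aa = np.array(list(AMINO_ACIDS))
        seq = "".join(aa[rng.integers(0, 20, size=total_len)])
        seq = seq[: start - 1] + wt_pep + seq[start - 1 + len(wt_pep):]
        if seq.count(wt_pep) != 1:
            continue
        if any(p in seq for p in forbidden):
            continue
        return seq
    raise RuntimeError("failed to build a clean fixture context")


def build_reference_fixture(seed: int = 612) -> dict[str, pd.DataFrame | list[ProteinRecord]]:
    """Assemble the in-print fixture in memory.

    Returns a dict with:

    ``candidates``
        612 candidate mutations across the five lines, distributed
        proportionally to each line's non-silent load (largest-remainder
        rounding), annotated with MS-detection status (exactly the three
        published neoantigen mutations are detected), predicted
        strong-binder status (304 mutations) and source-gene expression
        status (196 expressed strong-binder mutations).
    ``detected_neoantigens``
        the three detected neoantigen records verbatim.
    ``wt_contexts``
        synthetic wild-type proteins embedding each WT ligand at its
        printed residue position.
    ``mutations``
        protein-level missense records for the three detected mutations.
    """
    rng = np.random.default_rng(seed)
    split = _largest_remainder_split(PDO_MUTATION_LOADS, N_CANDIDATE_MUTATIONS)

    detected = {
        (r["pdo"], r["gene"]): r for _, r in PUBLISHED_NEOANTIGENS.iterrows()
    }
    rows = []
    i = 0
    for pdo in sorted(split):
        for j in range(split[pdo]):
            rows.append(dict(
                mutation_id=f"MUT{i:04d}", pdo=pdo,
                gene_id=f"{pdo.replace('-', '')}_G{j:03d}",
                consequence="missense", detected=False,
            ))
            i += 1
    candidates = pd.DataFrame(rows)
    # overwrite the first records of CRC-01/CRC-04 with the real detections
    for (pdo, gene), rec in sorted(detected.items()):
        idx = candidates.index[
            (candidates["pdo"] == pdo) & ~candidates["detected"]
        ][0]
        candidates.loc[idx, ["gene_id", "detected"]] = [gene, True]

    # strong-binder and expression annotation consistent with the funnel:
    # 304 strong-binder mutations, 196 of them in expressed genes.  The
    # MED25 and FMO5 detections are strong binders from expressed genes;
    # the U2SURP detection (rank 5.78) is not predicted to bind.
    strong_ranks = {"MED25": 0.1586, "FMO5": 0.2692}
    is_det = candidates["detected"]
    det_strong = candidates["gene_id"].isin(strong_ranks)
    n_more_strong = N_STRONG_BINDER_MUTATIONS - int(det_strong.sum())
    eligible = candidates.index[~is_det]
    strong_idx = list(candidates.index[det_strong]) + list(
        eligible[:n_more_strong]
    )
    candidates["predicted_strong"] = candidates.index.isin(strong_idx)
    strong_all = candidates.index[candidates["predicted_strong"]]
    n_expr_strong = N_EXPRESSED_STRONG_MUTATIONS
    expr_strong = list(candidates.index[det_strong]) + [
        i for i in strong_all if i not in set(candidates.index[det_strong])
    ][: n_expr_strong - int(det_strong.sum())]
    candidates["expressed"] = candidates.index.isin(expr_strong)
    # non-strong genes: expressed status irrelevant to the funnel; mark the
    # detected-but-unpredicted U2SURP gene expressed (its ligand was seen)
    candidates.loc[is_det, "expressed"] = True

    forbidden = PUBLISHED_NEOANTIGENS["mut_peptide"].tolist()
    contexts = []
    mut_rows = []
    for _, row in PUBLISHED_NEOANTIGENS.iterrows():
        seq = _build_wt_context(row, rng, forbidden)
        prot_id = f"{row['gene']}_ctx"
        contexts.append(ProteinRecord(prot_id, row["gene"], seq))
        ref, pos, alt = parse_mutation_label(row["mutation"])
        mid = candidates.loc[
            (candidates["gene_id"] == row["gene"]) & candidates["detected"],
            "mutation_id",
        ].iloc[0]
        mut_rows.append(dict(
            mutation_id=mid, protein_id=prot_id, gene_id=row["gene"],
            consequence="missense", aa_pos=pos, ref_aa=ref, alt_aa=alt,
            mutation=row["mutation"],
        ))
    return {
        "candidates": candidates,
        "detected_neoantigens": PUBLISHED_NEOANTIGENS.copy(),
        "wt_contexts": contexts,
        "mutations": pd.DataFrame(mut_rows),
    }


def emit_reference_fixture(out_dir: str | Path, seed: int = 612) -> Path:
    """Write the in-print fixture to ``out_dir`` (TSV + FASTA)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fx = build_reference_fixture(seed=seed)
    fx["candidates"].to_csv(out / "candidates.tsv", sep="\t", index=False)
    fx["detected_neoantigens"].to_csv(out / "detected_neoantigens.tsv", sep="\t", index=False)
    fx["mutations"].to_csv(out / "mutations.tsv", sep="\t", index=False)
    write_proteome_fasta(fx["wt_contexts"], out / "wt_contexts.fasta")
    return out
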