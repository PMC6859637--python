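"""Mutant protein construction, neoantigen candidate enumeration, and
matching of MS-detected peptides to somatic mutations.

Candidate neoantigens for HLA class I are every 8-11-mer window of a
mutant protein that overlaps at least one mutated residue and differs
from the aligned wild-type window.  Splice-site and stop-gain mutations
generate no predictable candidate sequence and are excluded; silent
changes trivially so.  A detected peptide is called a neoantigen hit
only if it spans a mutated position in some mutant protein and occurs
nowhere in the wild-type proteome — a peptide present anywhere in the
wild type cannot be mutation-specific.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .synthetic import ProteinRecord

#: Ligand lengths enumerated for HLA class I.
DEFAULT_LENGTHS = (8, 9, 10, 11)

#: Consequence classes that can generate predictable neoantigen sequences.
CANDIDATE_CONSEQUENCES = frozenset({"missense", "frameshift", "stop_loss"})


@dataclass(frozen=True)
class ProteinMutation:
    """A protein-level somatic mutation.

    ``aa_pos`` is the 1-based residue index of the first affected
    residue; ``cds`` plus the nucleotide edit (``nt_pos``/``ref_nt``/
    ``alt_nt``) are required for frameshifts so the shifted reading
    frame can be translated.
    """

    mutation_id: str
    protein_id: str
    consequence: str  # missense | frameshift | stop_loss
    aa_pos: int
    ref_aa: str = ""
    alt_aa: str = ""
    cds: str = ""
    nt_pos: int = 0
    ref_nt: str = ""
    alt_nt: str = ""


@dataclass(frozen=True)
class CandidatePeptide:
    """One candidate neoantigen window of a mutant protein."""

    sequence: str
    source_mutation: str
    start: int  # 1-based start in the mutant protein
    mutated_offsets: frozenset[int] = field(default_factory=frozenset)

    @property
    def length(self) -> int:
        return len(self.sequence)


def translate_mutant_cds(
    cds: str, nt_pos: int, ref_nt: str, alt_nt: str
) -> str:
    """Translate the mutant reading frame from the edited codon onward.

    The edit replaces ``ref_nt`` (possibly several nucleotides) at
    1-based ``nt_pos`` with ``alt_nt`` (possibly empty: a deletion).
    Translation uses the standard genetic code, starts at the codon
    containing ``nt_pos`` and proceeds until the first stop codon,
    which is excluded.  If no stop is reached a truncation warning is
    issued and the tail runs to the end of the CDS.
    """
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if cds[nt_pos - 1 : nt_pos - 1 + len(ref_nt)] != ref_nt:
        raise ValueError(
            f"reference allele mismatch at CDS position {nt_pos}"
        )
    mutant = cds[: nt_pos - 1] + alt_nt + cds[nt_pos - 1 + len(ref_nt):]
    codon_start = ((nt_pos - 1) // 3) * 3
    frame = mutant[codon_start:]
    frame = frame[: len(frame) - len(frame) % 3]
    translated = str(Seq(frame).translate())
    stop = translated.find("*")
    if stop == -1:
        warnings.warn(
            "no stop codon downstream of the edit; tail truncated at CDS end",
            stacklevel=2,
        )
        return translated
    return translated[:stop]


def apply_protein_mutation(
    wt: ProteinRecord, m: ProteinMutation
) -> tuple[str, set[int]]:
    """Build the mutant protein sequence and its mutated positions.

    Returns ``(mutant_sequence, mutated_positions)`` with positions
    1-based in the mutant sequence.  Missense replaces one residue;
    frameshift keeps the wild type up to the residue before the edit
    and appends the shifted-frame translation (every tail residue is
    mutated); stop-loss appends the translated read-through tail.
    """
    if m.consequence not in CANDIDATE_CONSEQUENCES:
        raise ValueError(
            f"no protein change for consequence {m.consequence!r}"
        )
    if m.aa_pos < 1 or m.aa_pos > wt.length:
        raise ValueError(f"aa_pos {m.aa_pos} outside protein {wt.protein_id}")
    if m.ref_aa and wt.sequence[m.aa_pos - 1] != m.ref_aa:
        raise ValueError(
            f"reference residue mismatch at {wt.protein_id}:{m.aa_pos} "
            f"(expected {m.ref_aa}, found {wt.sequence[m.aa_pos - 1]})"
        )
    if m.consequence == "missense":
        if not m.alt_aa:
            raise ValueError("missense mutation requires alt_aa")
        mut = (
            wt.sequence[: m.aa_pos - 1] + m.alt_aa + wt.sequence[m.aa_pos:]
        )
        return mut, {m.aa_pos}
    if m.consequence == "frameshift":
        if not m.cds:
            raise ValueError("frameshift mutation requires a CDS")
        tail = translate_mutant_cds(m.cds, m.nt_pos, m.ref_nt, m.alt_nt)
        mut = wt.sequence[: m.aa_pos - 1] + tail
        mutated = set(range(m.aa_pos, m.aa_pos + len(tail)))
        return mut, mutated
    # stop_loss: read-through tail appended after the wild-type terminus
    if not m.cds:
        raise ValueError("stop_loss mutation requires a CDS")
    tail = translate_mutant_cds(m.cds, m.nt_pos, m.ref_nt, m.alt_nt)
    mut = wt.sequence + tail
    mutated = set(range(wt.length + 1, wt.length + len(tail) + 1))
    return mut, mutated


def enumerate_candidates(
    wt_seq: str,
    mut_seq: str,
    mutated_positions: Iterable[int],
    source_mutation: str = "",
    lengths: Sequence[int] = DEFAULT_LENGTHS,
) -> list[CandidatePeptide]:
    """Enumerate mutation-spanning candidate windows of the mutant protein.

    Every window of each requested length that overlaps at least one
    mutated (1-based) position and differs from the wild-type window
    aligned at the same start is a candidate; candidates are
    deduplicated by sequence and clipped at the protein termini.
    """
    mutated = sorted(set(mutated_positions))
    if not mutated:
        raise ValueError("mutated_positions must be non-empty")
    if not mut_seq:
        raise ValueError("mutant sequence is empty")
    out: list[CandidatePeptide] = []
    seen: set[str] = set()
    n = len(mut_seq)
    for L in lengths:
        for pos in mutated:
            lo = max(1, pos - L + 1)
            hi = min(pos, n - L + 1)
            for start in range(lo, hi + 1):
                window = mut_seq[start - 1 : start - 1 + L]
                if window in seen:
                    continue
                wt_window = wt_seq[start - 1 : start - 1 + L]
                if window == wt_window:
                    continue
                offsets = frozenset(
                    p - start for p in mutated if start <= p <= start + L - 1
                )
                seen.add(window)
                out.append(
                    CandidatePeptide(window, source_mutation, start, offsets)
                )
    return out


def enumerate_for_mutation(
    wt: ProteinRecord,
    m: ProteinMutation,
    lengths: Sequence[int] = DEFAULT_LENGTHS,
) -> list[CandidatePeptide]:
    """Mutant construction + enumeration for one mutation.

    Returns an empty list for consequence classes excluded from
    candidate generation (silent, splice-site, stop-gain).
    """
    if m.consequence not in CANDIDATE_CONSEQUENCES:
        return []
    mut_seq, mutated = apply_protein_mutation(wt, m)
    return enumerate_candidates(
        wt.sequence, mut_seq, mutated, m.mutation_id, lengths
    )


def candidates_to_frame(candidates: Iterable[CandidatePeptide]) -> pd.DataFrame:
    rows = [
        dict(
            peptide=c.sequence,
            mutation_id=c.source_mutation,
            length=c.length,
            start=c.start,
            mutated_offsets=",".join(str(o) for o in sorted(c.mutated_offsets)),
        )
        for c in candidates
    ]
    return pd.DataFrame(
        rows, columns=["peptide", "mutation_id", "length", "start",
                       "mutated_offsets"]
    )


def _collapse_il(s: str) -> str:
    return s.replace("I", "L")


@dataclass(frozen=True)
class MutantRecord:
    """A realized mutant protein with its mutated positions."""

    mutation_id: str
    protein_id: str
    sequence: str
    mutated_positions: frozenset[int]


def mutant_records_from_table(
    mutations: pd.DataFrame, proteome: Mapping[str, ProteinRecord]
) -> list[MutantRecord]:
    """Build :class:`MutantRecord` objects from a protein-mutation table."""
    records = []
    for _, row in mutations.iterrows():
        m = ProteinMutation(
            mutation_id=row["mutation_id"],
            protein_id=row["protein_id"],
            consequence=row["consequence"],
            aa_pos=int(row["aa_pos"]),
            ref_aa=row.get("ref_aa", ""),
            alt_aa=row.get("alt_aa", ""),
            cds=row.get("cds", "") or "",
            nt_pos=int(row.get("nt_pos", 0) or 0),
            ref_nt=row.get("ref_nt", "") or "",
            alt_nt=row.get("alt_nt", "") or "",
        )
        if m.consequence not in CANDIDATE_CONSEQUENCES:
            continue
        wt = proteome[m.protein_id]
        seq, mutated = apply_protein_mutation(wt, m)
        records.append(
            MutantRecord(m.mutation_id, m.protein_id, seq, frozenset(mutated))
        )
    return records


def match_detected_to_mutations(
    detected_peptides: Iterable[str],
    wt_proteome: Sequence[ProteinRecord],
    mutant_records: Sequence[MutantRecord],
    collapse_il: bool = False,
) -> pd.DataFrame:
    """Match MS-detected peptides to mutations.

    A detected peptide of any length (HLA class I or II) is a neoantigen
    hit iff it occurs in some mutant protein spanning at least one
    mutated position and occurs nowhere in the wild-type proteome.
    With ``collapse_il`` leucine and isoleucine (indistinguishable by
    MS) are treated as identical during matching.

    Returns a table of ``(peptide, mutation_id, protein_id)`` hits.
    """
    norm = _collapse_il if collapse_il else (lambda s: s)
    # single haystack for whole-proteome wild-type occurrence checks
    wt_join = "|".join(norm(p.sequence) for p in wt_proteome)
    hits = []
    for pep in sorted(set(detected_peptides)):
        npep = norm(pep)
        if npep in wt_join:
            continue
        for rec in mutant_records:
            seq = norm(rec.sequence)
            start = seq.find(npep)
            while start != -1:
                span = range(start + 1, start + len(pep) + 1)
                if any(p in rec.mutated_positions for p in span):
                    hits.append(
                        dict(peptide=pep, mutation_id=rec.mutation_id,
                             protein_id=rec.protein_id)
                    )
                    break
                start = seq.find(npep, start + 1)
    return pd.DataFrame(hits, columns=["peptide", "mutation_id", "protein_id"])
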