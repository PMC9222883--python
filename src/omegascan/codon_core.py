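"""Genetic-code tables, codon-alignment validation and cleaning, codon
frequencies, and substitution-class bookkeeping.

A protein-coding alignment enters the pipeline as an in-frame FASTA file
(outgroup first).  Everything downstream — the codon substitution models,
the per-site FEL scan, the reports — operates on a :class:`CodonAlignment`
whose columns are codons, cleaned so that no gap codons and no stop codons
remain.  Codon indices reported anywhere in the package are 1-based on the
cleaned alignment; :func:`remove_gap_codons` returns the column map back to
the original coordinates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = "TCAG"
GAP_CODON = "---"
STOP = "*"

__all__ = [
    "GeneticCode",
    "CodonAlignment",
    "CodonFrequencies",
    "SubstitutionClassStats",
    "STANDARD_CODE",
    "validate_cds_alignment",
    "remove_gap_codons",
    "strip_terminal_stops",
    "classify_position_changes",
    "f3x4_frequencies",
    "f1x4_frequencies",
    "equal_frequencies",
    "read_fasta_codon_alignment",
    "write_fasta_codon_alignment",
]


@dataclass(frozen=True)
class GeneticCode:
    """A 64-codon translation table.

    ``table`` maps each codon (a 3-letter string over T/C/A/G) to a one-letter
    amino-acid symbol, with ``"*"`` marking stop codons.  ``id`` follows the
    NCBI numbering (``1`` = standard code, the ``icode 0`` setting of codeml).
    """

    table: dict[str, str]
    id: int = 1

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"genetic code must map all 64 codons, got {len(self.table)}")

    @property
    def sense_codons(self) -> tuple[str, ...]:
        """Sense codons in fixed T<C<A<G lexicographic order (codeml order)."""
        return tuple(c for c in all_codons() if self.table[c] != STOP)

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in all_codons() if self.table[c] == STOP)

    def is_stop(self, codon: str) -> bool:
        return self.table[codon] == STOP

    def translate(self, codon: str) -> str:
        return self.table[codon]


def all_codons() -> tuple[str, ...]:
    return tuple("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3))


def _standard_code() -> GeneticCode:
    ncbi = CodonTable.unambiguous_dna_by_id[1]
    table = {c: ncbi.forward_table.get(c, STOP) for c in all_codons()}
    return GeneticCode(table=table, id=1)


STANDARD_CODE = _standard_code()


@dataclass
class CodonAlignment:
    """An in-frame codon alignment: ordered taxa and per-taxon codon lists.

    The first sequence is the reference (by convention the outgroup).  Codons
    are 3-letter strings over T/C/A/G or the gap codon ``---``.
    """

    taxa: list[str]
    codons: list[list[str]]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.codons):
            raise ValueError("taxa and sequence counts differ")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxon names: {dupes}")
        lengths = {len(row) for row in self.codons}
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal codon counts: {sorted(lengths)}")
        for taxon, row in zip(self.taxa, self.codons):
            if any(len(codon) != 3 for codon in row):
                raise ValueError(
                    f"sequence {taxon!r} has a partial codon: length not divisible by 3"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return len(self.codons[0]) if self.codons else 0

    @property
    def reference(self) -> str:
        return self.taxa[0]

    def sequence(self, taxon: str) -> list[str]:
        return self.codons[self.taxa.index(taxon)]

    def column(self, index: int) -> list[str]:
        """Codon column at 0-based ``index`` across all taxa."""
        return [row[index] for row in self.codons]

    def subset_columns(self, indices: Sequence[int]) -> "CodonAlignment":
        return CodonAlignment(
            taxa=list(self.taxa),
            codons=[[row[i] for i in indices] for row in self.codons],
        )

    def fingerprint_text(self) -> str:
        """Canonical text form used for task fingerprints."""
        return "\n".join(f"{t}\t{''.join(row)}" for t, row in zip(self.taxa, self.codons))


def _chunk_codons(seq: str, name: str) -> list[str]:
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence {name!r} length {len(seq)} is not divisible by 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def read_fasta_codon_alignment(path) -> CodonAlignment:
    """Read an aligned FASTA file into a :class:`CodonAlignment`.

    Headers are taken verbatim up to the first whitespace.  All sequences must
    have equal length divisible by three.
    """
    taxa: list[str] = []
    rows: list[list[str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        rows.append(_chunk_codons(str(rec.seq).upper().replace("U", "T"), rec.id))
    if not taxa:
        raise ValueError(f"no sequences found in {path}")
    return CodonAlignment(taxa=taxa, codons=rows)


def write_fasta_codon_alignment(alignment: CodonAlignment, path) -> None:
    records = [
        SeqRecord(Seq("".join(row)), id=taxon, description="")
        for taxon, row in zip(alignment.taxa, alignment.codons)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Validation and cleaning
# ---------------------------------------------------------------------------

_VALID_CHARS = set("TCAG-N")


def validate_cds_alignment(
    alignment: CodonAlignment, code: GeneticCode = STANDARD_CODE
) -> list[str]:
    """Check an alignment for analysis-readiness; return a list of violations.

    Reported per sequence: stop codons (internal or terminal), characters
    outside ``{T,C,A,G,-,N}``, and partially gapped (frame-breaking) codons.
    An empty list means the alignment can be cleaned and analysed.  Unequal
    sequence lengths are a hard error raised at construction, not a report
    entry.
    """
    violations: list[str] = []
    for taxon, row in zip(alignment.taxa, alignment.codons):
        for j, codon in enumerate(row, start=1):
            bad = set(codon) - _VALID_CHARS
            if bad:
                violations.append(
                    f"{taxon}: codon {j} ({codon}) contains invalid characters {sorted(bad)}"
                )
                continue
            if "-" in codon and codon != GAP_CODON:
                violations.append(
                    f"{taxon}: codon {j} ({codon}) is partially gapped (frame-breaking gap)"
                )
                continue
            if codon == GAP_CODON or "N" in codon:
                continue
            if code.is_stop(codon):
                kind = "terminal" if j == len(row) else "internal"
                violations.append(f"{taxon}: {kind} stop codon {codon} at codon {j}")
    return violations


def remove_gap_codons(
    alignment: CodonAlignment,
) -> tuple[CodonAlignment, list[int]]:
    """Drop every codon column that is gapped or ambiguous in any sequence.

    A column is removed when any taxon carries the gap codon ``---`` or a
    codon containing ``N`` (ambiguity is treated like a gap so that every
    downstream test sees identical data).  Returns the cleaned alignment and
    the strictly increasing column map ``cleaned index -> original 0-based
    index``.  Idempotent: cleaning a clean alignment is the identity.
    """
    keep: list[int] = []
    for j in range(alignment.n_codons):
        column = alignment.column(j)
        for codon in column:
            if "-" in codon and codon != GAP_CODON:
                raise ValueError(
                    f"frame-breaking gap in codon column {j + 1}: {codon!r}"
                )
        if any(codon == GAP_CODON or "N" in codon for codon in column):
            continue
        keep.append(j)
    return alignment.subset_columns(keep), keep


def strip_terminal_stops(
    alignment: CodonAlignment, code: GeneticCode = STANDARD_CODE
) -> CodonAlignment:
    """Drop the final codon column if any sequence ends in a stop codon.

    Terminal stops are rejected by :func:`validate_cds_alignment`; this
    explicit utility is for inputs that still carry them.
    """
    if alignment.n_codons == 0:
        return alignment
    last = alignment.column(alignment.n_codons - 1)
    if any(c not in (GAP_CODON,) and "N" not in c and code.is_stop(c) for c in last):
        return alignment.subset_columns(range(alignment.n_codons - 1))
    return alignment


# ---------------------------------------------------------------------------
# Substitution classes of the genetic code
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubstitutionClassStats:
    """Counts of synonymous vs nonsynonymous single-nucleotide codon pairs
    at one codon position.

    All 96 unordered pairs of codons differing only at the given position are
    enumerated (16 backgrounds x 6 nucleotide pairs).  A pair is synonymous
    iff both codons encode the same amino acid or both are stops; every
    sense<->stop change is nonsynonymous.  Percentages are rounded to the
    nearest integer.
    """

    position: int
    n_pairs: int
    n_synonymous: int
    n_nonsynonymous: int

    @property
    def pct_synonymous(self) -> int:
        return round(100.0 * self.n_synonymous / self.n_pairs)

    @property
    def pct_nonsynonymous(self) -> int:
        return round(100.0 * self.n_nonsynonymous / self.n_pairs)


def classify_position_changes(
    code: GeneticCode = STANDARD_CODE, position: int = 1
) -> SubstitutionClassStats:
    """Classify all single-nucleotide codon changes at one codon position.

    Under the standard code this yields 96% nonsynonymous changes at the
    first position, ~99% at the second, and 33% at the third (synonymous:
    4%, ~1%, 67%).
    """
    if position not in (1, 2, 3):
        raise ValueError(f"codon position must be 1, 2 or 3, got {position}")
    p = position - 1
    n_syn = n_nonsyn = 0
    for background in itertools.product(NUCLEOTIDES, repeat=2):
        for a, b in itertools.combinations(NUCLEOTIDES, 2):
            codon_a = background[:p] + (a,) + background[p:]
            codon_b = background[:p] + (b,) + background[p:]
            aa_a = code.translate("".join(codon_a))
            aa_b = code.translate("".join(codon_b))
            if aa_a == aa_b:
                n_syn += 1
            else:
                n_nonsyn += 1
    return SubstitutionClassStats(
        position=position,
        n_pairs=n_syn + n_nonsyn,
        n_synonymous=n_syn,
        n_nonsynonymous=n_nonsyn,
    )


# ---------------------------------------------------------------------------
# Codon frequencies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodonFrequencies:
    """Equilibrium frequencies over the sense codons of a genetic code.

    ``pi`` is aligned with ``code.sense_codons`` (61 entries for the standard
    code), non-negative and summing to one.  ``estimator`` records how the
    vector was obtained (``equal``, ``F1x4`` or ``F3x4``).
    """

    pi: np.ndarray
    code: GeneticCode
    estimator: str = "F3x4"

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        n = len(self.code.sense_codons)
        if pi.shape != (n,):
            raise ValueError(f"pi must have length {n}, got {pi.shape}")
        if (pi < 0).any():
            raise ValueError("codon frequencies must be non-negative")
        if not np.isclose(pi.sum(), 1.0, atol=1e-9):
            raise ValueError(f"codon frequencies must sum to 1, got {pi.sum()}")

    def frequency(self, codon: str) -> float:
        return float(self.pi[self.code.sense_codons.index(codon)])


def equal_frequencies(code: GeneticCode = STANDARD_CODE) -> CodonFrequencies:
    n = len(code.sense_codons)
    return CodonFrequencies(pi=np.full(n, 1.0 / n), code=code, estimator="equal")


def f1x4_frequencies(
    alignment: CodonAlignment, code: GeneticCode = STANDARD_CODE
) -> CodonFrequencies:
    """F1x4 codon frequencies: one nucleotide frequency vector pooled over
    all three codon positions (codeml's ``CodonFreq = 1``)."""
    counts = np.zeros(4)
    nuc_index = {n: i for i, n in enumerate(NUCLEOTIDES)}
    for row in alignment.codons:
        for codon in row:
            if codon == GAP_CODON or "N" in codon:
                continue
            for nuc in codon:
                counts[nuc_index[nuc]] += 1
    if counts.sum() == 0:
        raise ValueError("empty alignment: no countable codons")
    freqs = counts / counts.sum()
    pi = np.array(
        [freqs[nuc_index[c[0]]] * freqs[nuc_index[c[1]]] * freqs[nuc_index[c[2]]]
         for c in code.sense_codons]
    )
    total = pi.sum()
    if total <= 0:
        raise ValueError("all sense-codon frequencies are zero under F1x4")
    return CodonFrequencies(pi=pi / total, code=code, estimator="F1x4")


def f3x4_frequencies(
    alignment: CodonAlignment, code: GeneticCode = STANDARD_CODE
) -> CodonFrequencies:
    """F3x4 codon frequencies (the ``CodonFreq = 2`` estimator of codeml).

    Nucleotide frequencies are tallied separately at each of the three codon
    positions over all sequences; each sense codon's frequency is the product
    of its three position-specific nucleotide frequencies, renormalized over
    the sense codons.  Gap and ambiguous codons are skipped.
    """
    counts = np.zeros((3, 4))
    nuc_index = {n: i for i, n in enumerate(NUCLEOTIDES)}
    for row in alignment.codons:
        for codon in row:
            if codon == GAP_CODON or "N" in codon:
                continue
            for pos, nuc in enumerate(codon):
                counts[pos, nuc_index[nuc]] += 1
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("empty alignment: no countable codons")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, nuc_index[c[0]]] * freqs[1, nuc_index[c[1]]] * freqs[2, nuc_index[c[2]]]
            for c in code.sense_codons
        ]
    )
    total = pi.sum()
    if total <= 0:
        raise ValueError("all sense-codon frequencies are zero under F3x4")
    return CodonFrequencies(pi=pi / total, code=code, estimator="F3x4")
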