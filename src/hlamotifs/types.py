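"""Core domain types: allele names, samples, PWMs, count matrices, backgrounds.

Peptides are plain uppercase strings over the canonical alphabet; the
:class:`SampleDataset` and the validators here enforce the constraints.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, N_AA, is_canonical

MIN_PEPTIDE_LENGTH = 8
MAX_PEPTIDE_LENGTH = 14

#: Peptide lengths that are deconvoluted and scored.
CORE_LENGTHS = (9, 10)


class PeptideError(ValueError):
    pass


def validate_peptide(sequence: str,
                     min_len: int = MIN_PEPTIDE_LENGTH,
                     max_len: int = MAX_PEPTIDE_LENGTH) -> str:
    """Uppercase, check alphabet and length bounds; return the sequence."""
    seq = sequence.upper()
    if not is_canonical(seq):
        raise PeptideError(f"non-canonical residue in {sequence!r}")
    if not min_len <= len(seq) <= max_len:
        raise PeptideError(
            f"peptide length {len(seq)} outside [{min_len}, {max_len}]")
    return seq


_ALLELE_RE = re.compile(
    r"^(?:HLA-)?([ABC])\*?(\d{2}):?(\d{2})$"
)


@dataclass(frozen=True, order=True)
class AlleleName:
    """A 4-digit HLA class I allele, e.g. HLA-A02:01.

    Parses the compact (``A0201``), colon (``A02:01``) and prefixed
    (``HLA-A02:01``) dialects; the canonical internal form is compact.
    """

    locus: str
    group: str
    protein: str

    def __post_init__(self):
        if self.locus not in ("A", "B", "C"):
            raise ValueError(f"unknown HLA-I locus {self.locus!r}")
        if not (len(self.group) == 2 and self.group.isdigit()
                and len(self.protein) == 2 and self.protein.isdigit()):
            raise ValueError(
                f"allele fields must be 2-digit strings, got "
                f"{self.group!r}:{self.protein!r}")

    @classmethod
    def parse(cls, text: str) -> "AlleleName":
        m = _ALLELE_RE.match(text.strip().upper())
        if m is None:
            raise ValueError(f"cannot parse HLA allele {text!r}")
        return cls(m.group(1), m.group(2), m.group(3))

    @property
    def compact(self) -> str:
        return f"{self.locus}{self.group}{self.protein}"

    @property
    def colon(self) -> str:
        return f"HLA-{self.locus}{self.group}:{self.protein}"

    def __str__(self) -> str:
        return self.compact


@dataclass
class SampleDataset:
    """One pooled immunopeptidomics sample: genotype plus peptides by length."""

    sample_id: str
    genotype: frozenset
    peptides_by_length: dict = field(default_factory=dict)

    def __post_init__(self):
        self.genotype = frozenset(
            a if isinstance(a, AlleleName) else AlleleName.parse(a)
            for a in self.genotype)
        if not 1 <= len(self.genotype) <= 6:
            raise ValueError(
                f"sample {self.sample_id}: genotype must have 1-6 alleles")
        for locus in "ABC":
            n = sum(1 for a in self.genotype if a.locus == locus)
            if n > 2:
                raise ValueError(
                    f"sample {self.sample_id}: {n} HLA-{locus} alleles (max 2)")
        clean: dict[int, list[str]] = {}
        for length, peps in self.peptides_by_length.items():
            seen, uniq = set(), []
            for p in peps:
                p = validate_peptide(p)
                if len(p) != length:
                    raise ValueError(
                        f"peptide {p} filed under length {length}")
                if p not in seen:
                    seen.add(p)
                    uniq.append(p)
            clean[int(length)] = uniq
        self.peptides_by_length = clean

    def peptides(self, length: int) -> list[str]:
        return self.peptides_by_length.get(length, [])


def _check_rows_normalized(matrix: np.ndarray, tol: float, what: str):
    if np.any(matrix < -1e-12):
        raise ValueError(f"{what}: negative entries")
    sums = matrix.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > tol):
        raise ValueError(f"{what}: positions not normalized (sums {sums})")


@dataclass
class PWM:
    """Position weight matrix: ``matrix[i, a]`` = P(residue a at position i+1).

    Positions index rows (P1..PL); residues index columns in the global
    alphabetical order.
    """

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != N_AA:
            raise ValueError(f"PWM must be (L, 20), got {self.matrix.shape}")
        _check_rows_normalized(self.matrix, 1e-9, "PWM")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def uniform(cls, length: int) -> "PWM":
        return cls(np.full((length, N_AA), 1.0 / N_AA))

    @classmethod
    def from_peptides(cls, peptides: list[str],
                      pseudocount: float = 0.0) -> "PWM":
        """Per-position empirical frequencies with an optional flat
        pseudocount added to every residue at every position."""
        counts = count_matrix(peptides)
        m = counts.counts + pseudocount
        return cls(m / m.sum(axis=1, keepdims=True))


@dataclass
class CountMatrix:
    """Per-position residue counts for n peptides of one length."""

    counts: np.ndarray
    n: float

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != N_AA:
            raise ValueError("counts must be (L, 20)")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        sums = self.counts.sum(axis=1)
        if np.any(np.abs(sums - self.n) > 1e-6):
            raise ValueError(f"position counts {sums} do not sum to n={self.n}")

    @property
    def length(self) -> int:
        return self.counts.shape[0]


def count_matrix(peptides: list[str]) -> CountMatrix:
    if not peptides:
        raise ValueError("no peptides")
    L = len(peptides[0])
    counts = np.zeros((L, N_AA))
    for pep in peptides:
        if len(pep) != L:
            raise ValueError("mixed peptide lengths")
        for i, c in enumerate(pep):
            counts[i, AA_INDEX[c]] += 1
    return CountMatrix(counts, float(len(peptides)))


@dataclass
class BackgroundFrequencies:
    """A residue frequency vector q over the 20 amino acids."""

    q: np.ndarray

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (N_AA,):
            raise ValueError("background must have 20 entries")
        if np.any(self.q <= 0):
            raise ValueError("background entries must be > 0")
        if abs(self.q.sum() - 1.0) > 1e-9:
            raise ValueError("background does not sum to 1")

    def __getitem__(self, residue: str) -> float:
        return float(self.q[AA_INDEX[residue]])

    @classmethod
    def uniform(cls) -> "BackgroundFrequencies":
        return cls(np.full(N_AA, 1.0 / N_AA))


@dataclass
class PredictionRecord:
    """A scored peptide: per-allele scores, the best allele and its score S,
    and the empirical P-value of S against the proteome background."""

    peptide: str
    per_allele_scores: dict
    best_allele: AlleleName
    best_score: float
    empirical_p: float
    rank: int | None = None

    def __post_init__(self):
        best = max(self.per_allele_scores.values())
        if abs(self.per_allele_scores[self.best_allele] - best) > 1e-12:
            raise ValueError("best_allele does not attain the maximum score")
        if not 0 < self.empirical_p <= 1:
            raise ValueError("empirical_p must be in (0, 1]")
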