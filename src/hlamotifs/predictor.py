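"""Per-allele PWM models with BLOSUM62 pseudocounts, MS background
estimation at non-anchor positions, peptide scoring with empirical
P-values, missense neo-antigen enumeration and ranking, and benchmark
metrics (AUC, PP1%).

The score of a peptide (X_1..X_N) under an allele PWM p and background q
is S = (1/N) Σ_i ln(p[i][X_i] / q[X_i]); a sample-level prediction takes
the maximum S over the sample's alleles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .alphabet import AA_INDEX, N_AA, encode_peptides
from .blosum import BLOSUM62_CONDITIONAL
from .types import (AlleleName, BackgroundFrequencies, PWM,
                    PredictionRecord, count_matrix)

#: Alleles with residue specificity at P4-P7, excluded from the MS
#: background estimate.
DEFAULT_BACKGROUND_EXCLUDED = frozenset(
    AlleleName.parse(a) for a in
    ["A0201", "A0205", "A0206", "A0220", "A2501", "A2601", "A2902",
     "B0801", "B1401", "B1402", "C0303", "C0704"])

#: Alleles whose motifs legitimately end in R/K, exempt from the tryptic
#: signature filter.
TRYPTIC_EXCEPTIONS = frozenset(
    AlleleName.parse(a) for a in ["A0301", "A3101"])


@dataclass
class PseudocountParams:
    beta: float = 200.0

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be > 0")

    @property
    def rho(self) -> np.ndarray:
        """Conditional substitution probabilities rho[B][A] = P(A|B)."""
        return BLOSUM62_CONDITIONAL


@dataclass
class AlleleModel:
    """Pseudocounted per-allele PWMs, one per trained peptide length."""

    allele: AlleleName
    pwms: dict          # length -> PWM
    n_train: dict       # length -> training peptide count

    def __post_init__(self):
        for L, pwm in self.pwms.items():
            if pwm.length != L:
                raise ValueError(f"{self.allele}: PWM length mismatch at {L}")
            if self.n_train.get(L, 0) < 1:
                raise ValueError(f"{self.allele}: n_train < 1 for length {L}")

    @property
    def lengths(self):
        return sorted(self.pwms)


@dataclass(frozen=True)
class MutationRecord:
    """A somatic missense mutation on a protein (1-based position)."""

    protein_id: str
    sequence: str
    position: int
    ref: str
    alt: str

    def __post_init__(self):
        if not 1 <= self.position <= len(self.sequence):
            raise ValueError(f"position {self.position} outside protein")
        if self.sequence[self.position - 1] != self.ref:
            raise ValueError(
                f"{self.protein_id}:{self.position} is "
                f"{self.sequence[self.position - 1]}, not {self.ref}")
        if self.ref == self.alt:
            raise ValueError("ref and alt residues are identical")


@dataclass
class BenchmarkResult:
    auc: float
    pp1: float
    ranks: dict = field(default_factory=dict)


def estimate_ms_background(pools: dict, excluded: frozenset | None = None
                           ) -> BackgroundFrequencies:
    """Mean residue frequencies at non-anchor positions P4-P7 of 9-mers,
    averaged (unweighted) across non-excluded alleles.

    Zero entries are floored at 1e-4 and the vector renormalized, so
    cysteine-depleted pools cannot produce -inf scores downstream.
    """
    if excluded is None:
        excluded = DEFAULT_BACKGROUND_EXCLUDED
    per_allele = []
    for allele, peptides in sorted(pools.items()):
        if allele in excluded:
            continue
        peptides = [p for p in peptides if len(p) == 9]
        if not peptides:
            continue
        counts = count_matrix(sorted(peptides)).counts[3:7].sum(axis=0)
        per_allele.append(counts / counts.sum())
    if not per_allele:
        raise ValueError("no alleles left for background estimation")
    q = np.mean(per_allele, axis=0)
    q = np.maximum(q / q.sum(), 1e-4)
    return BackgroundFrequencies(q / q.sum())


def proteome_frequencies(proteome: dict) -> BackgroundFrequencies:
    """Residue frequencies over all canonical residues of a proteome."""
    counts = np.zeros(N_AA)
    for seq in proteome.values():
        for c in seq:
            idx = AA_INDEX.get(c)
            if idx is not None:
                counts[idx] += 1
    if counts.sum() == 0:
        raise ValueError("proteome contains no canonical residues")
    counts = np.maximum(counts / counts.sum(), 1e-6)
    return BackgroundFrequencies(counts / counts.sum())


def pearson_r(q1: BackgroundFrequencies, q2: BackgroundFrequencies) -> float:
    v1, v2 = q1.q, q2.q
    if np.std(v1) < 1e-12 or np.std(v2) < 1e-12:
        raise ValueError("zero-variance frequency vector")
    return float(np.corrcoef(v1, v2)[0, 1])


def build_allele_pwm(peptides: list[str],
                     params: PseudocountParams | None = None) -> PWM:
    """Pseudocounted PWM: p = (α·f + β·g) / (α + β) per position, with
    f the observed frequencies, g = f·ρ the BLOSUM62-implied frequencies,
    α = n − 1 the data weight and β the pseudocount weight."""
    params = params or PseudocountParams()
    cm = count_matrix(peptides)
    n = cm.n
    f = cm.counts / n
    g = f @ params.rho                     # g[i, A] = Σ_B f[i, B]·ρ[B][A]
    alpha = n - 1.0
    p = (alpha * f + params.beta * g) / (alpha + params.beta)
    return PWM(p / p.sum(axis=1, keepdims=True))


def score_peptide(peptide: str, pwm: PWM, q: BackgroundFrequencies) -> float:
    """S = (1/N) Σ_i ln(p[i][x_i] / q[x_i]); natural logarithm."""
    if len(peptide) != pwm.length:
        raise ValueError(
            f"peptide length {len(peptide)} != PWM length {pwm.length}")
    idx = [AA_INDEX[c] for c in peptide]
    p = pwm.matrix[np.arange(pwm.length), idx]
    return float(np.mean(np.log(p / q.q[idx])))


def _score_batch(peptides: list[str], pwm: PWM,
                 q: BackgroundFrequencies) -> np.ndarray:
    X = encode_peptides(peptides)
    logratio = np.log(np.maximum(pwm.matrix, 1e-300)) - np.log(q.q)[None, :]
    return logratio[np.arange(X.shape[1])[None, :], X].mean(axis=1)


def best_scores(peptides: list[str], models: list[AlleleModel],
                q: BackgroundFrequencies
                ) -> tuple[np.ndarray, list[AlleleName], np.ndarray]:
    """Max-over-alleles score for equal-length peptides; returns the
    score vector, allele order, and the (n_alleles, n) score matrix."""
    L = len(peptides[0])
    usable = [m for m in models if L in m.pwms]
    if not usable:
        raise ValueError(f"no model covers length {L}")
    alleles = [m.allele for m in usable]
    scores = np.vstack([_score_batch(peptides, m.pwms[L], q) for m in usable])
    return scores.max(axis=0), alleles, scores


def background_score_distribution(proteome: dict, models: list[AlleleModel],
                                  q: BackgroundFrequencies, length: int,
                                  n: int = 100_000, seed: int = 0
                                  ) -> np.ndarray:
    """Max-over-alleles scores of n random proteome peptides, sorted."""
    from .io import sample_random_peptides
    decoys = sample_random_peptides(proteome, length, n, seed)
    s, _, _ = best_scores(decoys, models, q)
    return np.sort(s)


def empirical_pvalues(scores: np.ndarray,
                      background_sorted: np.ndarray) -> np.ndarray:
    """(1 + #{background >= S}) / (1 + N_background) per score."""
    nb = len(background_sorted)
    if nb == 0:
        raise ValueError("empty background score distribution")
    n_ge = nb - np.searchsorted(background_sorted, scores, side="left")
    return (1.0 + n_ge) / (1.0 + nb)


def predict(peptides: list[str], models: list[AlleleModel],
            q: BackgroundFrequencies,
            background_scores: dict) -> list[PredictionRecord]:
    """Score peptides (max over alleles) with empirical P-values.

    ``background_scores`` maps length -> sorted max-over-allele score
    array precomputed with the same models. Records are sorted by
    descending score, ties broken lexicographically by peptide.
    """
    records = []
    by_length: dict[int, list[str]] = {}
    for pep in peptides:
        by_length.setdefault(len(pep), []).append(pep)
    for L, peps in by_length.items():
        if L not in background_scores:
            raise ValueError(f"no background scores for length {L}")
        best, alleles, matrix = best_scores(peps, models, q)
        pvals = empirical_pvalues(best, np.asarray(background_scores[L]))
        for j, pep in enumerate(peps):
            per_allele = {a: float(matrix[i, j])
                          for i, a in enumerate(alleles)}
            k = int(np.argmax(matrix[:, j]))
            records.append(PredictionRecord(
                pep, per_allele, alleles[k], float(best[j]),
                float(pvals[j])))
    records.sort(key=lambda r: (-r.best_score, r.peptide))
    for rank, r in enumerate(records, start=1):
        r.rank = rank
    return records


def enumerate_missense_candidates(mutation: MutationRecord,
                                  lengths=(9, 10)) -> list[str]:
    """All length-L windows of the mutated protein that cover the
    mutation site, with the alt residue substituted."""
    seq = mutation.sequence
    pos = mutation.position        # 1-based
    mutated = seq[:pos - 1] + mutation.alt + seq[pos:]
    out = []
    for L in lengths:
        lo = max(1, pos - L + 1)
        hi = min(pos, len(seq) - L + 1)
        for start in range(lo, hi + 1):
            out.append(mutated[start - 1:start - 1 + L])
    return out


def rank_neoantigens(mutations: list[MutationRecord],
                     models: list[AlleleModel], q: BackgroundFrequencies,
                     background_scores: dict, lengths=(9, 10),
                     include_c: bool = False) -> list[PredictionRecord]:
    """Enumerate, deduplicate and rank all missense candidate peptides.

    Only HLA-A and HLA-B models are used unless ``include_c`` is set
    (HLA-C alleles are weakly expressed and excluded by default).
    """
    usable = [m for m in models
              if include_c or m.allele.locus in ("A", "B")]
    if not usable:
        raise ValueError("no HLA-A/B allele models available")
    lengths = tuple(L for L in lengths
                    if any(L in m.pwms for m in usable))
    candidates: list[str] = []
    seen: set[str] = set()
    for mut in mutations:
        for pep in enumerate_missense_candidates(mut, lengths):
            if pep not in seen:
                seen.add(pep)
                candidates.append(pep)
    return predict(candidates, usable, q, background_scores)


def evaluate(scored: list[tuple[float, bool]]) -> BenchmarkResult:
    """AUC (rank statistic, ties count 1/2) and PP1% (positives among the
    top ceil(1% · n) scores, divided by that count)."""
    scores = np.array([s for s, _ in scored], dtype=float)
    labels = np.array([bool(l) for _, l in scored])
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    ranks = rankdata(scores)       # average ranks handle ties as 1/2
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    k = math.ceil(0.01 * len(scores))
    order = np.argsort(-scores, kind="stable")
    pp1 = labels[order[:k]].sum() / k
    return BenchmarkResult(float(auc), float(pp1))


def filter_tryptic_signature(peptides: list[str], allele: AlleleName,
                             exceptions: frozenset | None = None
                             ) -> list[str]:
    """Remove peptides ending in R/K (tryptic digestion signature) for
    all alleles except those whose motifs genuinely prefer R/K at PΩ."""
    if exceptions is None:
        exceptions = TRYPTIC_EXCEPTIONS
    if allele in exceptions:
        return list(peptides)
    return [p for p in peptides if p[-1] not in ("R", "K")]
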