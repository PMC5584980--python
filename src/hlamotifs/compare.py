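"""Motif similarity: squared Euclidean distance between PWMs, the
similarity threshold rule, the Bayesian likelihood (BLiC) column score,
and empirical P-values against a reference motif compendium.

The working metric throughout the pipeline is the length-normalized
squared Euclidean distance

    D² = (1/L) Σ_i Σ_A (M[i,A] − M'[i,A])²

with motifs called similar when D² ≤ T (default T = 0.078).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .alphabet import N_AA
from .types import BackgroundFrequencies, CountMatrix, PWM, AlleleName

DEFAULT_THRESHOLD = 0.078


@dataclass
class SimilarityConfig:
    T: float = DEFAULT_THRESHOLD
    metric: str = "euclidean"        # {"euclidean", "blic"}
    blic_alpha: np.ndarray = field(
        default_factory=lambda: np.ones(N_AA))
    background: BackgroundFrequencies = field(
        default_factory=BackgroundFrequencies.uniform)

    def __post_init__(self):
        self.blic_alpha = np.asarray(self.blic_alpha, dtype=float)
        if self.T < 0:
            raise ValueError("threshold T must be non-negative")
        if self.metric not in ("euclidean", "blic"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if np.any(self.blic_alpha <= 0):
            raise ValueError("Dirichlet hyper-parameters must be > 0")


@dataclass
class ReferenceMotifLibrary:
    """Per-allele reference PWMs with their supporting ligand counts."""

    entries: dict  # AlleleName -> (PWM, n_ligands)

    def __post_init__(self):
        for allele, (pwm, n) in self.entries.items():
            if n < 1:
                raise ValueError(f"{allele}: n_ligands must be >= 1")

    def eligible(self, allele: AlleleName, min_ligands: int = 20) -> bool:
        """True when the allele's motif rests on more than ``min_ligands``
        unique ligands (the semi-supervised eligibility rule)."""
        entry = self.entries.get(allele)
        return entry is not None and entry[1] > min_ligands

    def __len__(self):
        return len(self.entries)


def motif_distance(m1: PWM, m2: PWM) -> float:
    """Length-normalized squared Euclidean distance between two PWMs."""
    if m1.length != m2.length:
        raise ValueError(
            f"cannot compare PWMs of lengths {m1.length} and {m2.length}")
    diff = m1.matrix - m2.matrix
    return float((diff * diff).sum() / m1.length)


def is_similar(m1: PWM, m2: PWM,
               config: SimilarityConfig | None = None) -> bool:
    config = config or SimilarityConfig()
    return motif_distance(m1, m2) <= config.T


def _log_dirichlet_multinomial(counts: np.ndarray, alpha: np.ndarray) -> float:
    """log P_Dir(c) = log ∫ Π p_j^{c_j} Dir(p; α) dp, without the
    multinomial coefficient."""
    return float(
        gammaln(alpha.sum()) - gammaln(counts.sum() + alpha.sum())
        + (gammaln(counts + alpha) - gammaln(alpha)).sum())


def blic_similarity(c1: CountMatrix, c2: CountMatrix,
                    config: SimilarityConfig | None = None) -> float:
    """BLiC score between two motif count matrices; higher = more similar.

    Per position the score combines a joint-vs-independent Bayes factor
    under a Dirichlet(α) prior with a common-source-vs-background term:

        score_i = log[P_Dir(c1+c2) / (P_Dir(c1)·P_Dir(c2))]
                + log[P_Dir(c1+c2) / P_bg(c1+c2)]

    Multinomial coefficients are omitted uniformly in all three terms.
    """
    config = config or SimilarityConfig()
    if c1.length != c2.length:
        raise ValueError("count matrices must have equal lengths")
    alpha = config.blic_alpha
    log_q = np.log(config.background.q)
    total = 0.0
    for i in range(c1.length):
        a, b = c1.counts[i], c2.counts[i]
        joint = a + b
        if joint.sum() <= 0:
            raise ValueError(f"position {i + 1}: zero total counts")
        lp_joint = _log_dirichlet_multinomial(joint, alpha)
        lp_a = _log_dirichlet_multinomial(a, alpha)
        lp_b = _log_dirichlet_multinomial(b, alpha)
        lp_bg = float((joint * log_q).sum())
        total += (lp_joint - lp_a - lp_b) + (lp_joint - lp_bg)
    return total


def _similarity(m1: PWM, m2: PWM, config: SimilarityConfig,
                n1: float, n2: float) -> float:
    """Signed similarity under the configured metric: always
    'larger = more similar' (Euclidean distances are negated)."""
    if config.metric == "euclidean":
        return -motif_distance(m1, m2)
    c1 = CountMatrix(m1.matrix * n1, n1)
    c2 = CountMatrix(m2.matrix * n2, n2)
    return blic_similarity(c1, c2, config)


def empirical_similarity_pvalue(m_i: PWM, m_j: PWM,
                                library: ReferenceMotifLibrary,
                                exclude: AlleleName | None = None,
                                config: SimilarityConfig | None = None,
                                n_i: float = 100.0,
                                n_j: float = 100.0) -> float:
    """Empirical P-value of the similarity between motifs m_i and m_j.

    The observed similarity is ranked against the similarities of m_i to
    every reference motif (the allele m_i is annotated to excluded);
    P = (1 + #{references at least as similar}) / (1 + N_ref), so P is
    never exactly 0.
    """
    config = config or SimilarityConfig()
    refs = [(allele, pwm, n) for allele, (pwm, n) in library.entries.items()
            if allele != exclude]
    if not refs:
        raise ValueError("reference library is empty after exclusion")
    s_obs = _similarity(m_i, m_j, config, n_i, n_j)
    n_hits = sum(
        1 for _, pwm, n in refs
        if _similarity(m_i, pwm, config, n_i, float(n)) >= s_obs)
    return (1 + n_hits) / (1 + len(refs))
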