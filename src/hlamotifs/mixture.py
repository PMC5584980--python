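"""EM fitting of a mixture of position-independent PWMs to a pooled
peptide list, BIC model selection over the number of motifs, and the
two-stage per-sample deconvolution.

The model: each peptide x of length L is generated by first picking a
motif k with probability w_k and then drawing residue x_i independently
at each position from pwm_k[i].  The E-step computes responsibilities
r_ik ∝ w_k · Π_i pwm_k[i][x_i]; the M-step re-estimates each PWM from
responsibility-weighted counts with a small Dirichlet smoothing count γ
per residue per position (EM needs strictly positive emissions), and
w_k as the mean responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .alphabet import N_AA, encode_peptides, one_hot
from .types import PWM, SampleDataset


@dataclass
class DeconvConfig:
    seed: int = 0
    n_restarts: int = 5
    max_iter: int = 500
    rel_tol: float = 1e-6
    gamma: float = 0.1          # Dirichlet smoothing count in the M-step
    k_selection: str = "bic"    # {"fixed", "bic"}
    trash: bool = False         # extra fixed-uniform component for
                                # contaminants (on in the sample pipeline)

    def __post_init__(self):
        if self.n_restarts < 1 or self.max_iter < 1:
            raise ValueError("n_restarts and max_iter must be positive")
        if not 0 < self.rel_tol < 1:
            raise ValueError("rel_tol must be in (0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")


@dataclass
class MixtureModel:
    """K motif PWMs with mixing weights and per-peptide responsibilities.

    When fitted with a trash component, ``weights`` and the
    responsibility matrix have one extra (last) column for it;
    ``trash_weight`` is then set and ``K`` still counts only motifs.
    """

    pwms: list[PWM]
    weights: np.ndarray
    responsibilities: np.ndarray
    log_likelihood: float
    n: int
    ll_trace: list[float] = field(default_factory=list)
    trash_weight: float | None = None
    bic: float | None = None
    all_bics: dict[int, float] | None = None

    def __post_init__(self):
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixing weights do not sum to 1")
        if np.any(np.abs(self.responsibilities.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("responsibility rows do not sum to 1")
        if not np.isfinite(self.log_likelihood):
            raise ValueError("log-likelihood is not finite")

    @property
    def K(self) -> int:
        return len(self.pwms)


def _em_run(flat: np.ndarray, L: int, K: int, gamma: float, max_iter: int,
            rel_tol: float, rng: np.random.Generator, trash: bool = False):
    """One EM run seeded from K randomly chosen peptides.

    Each component PWM starts as a blend of the uniform distribution and
    the one-hot profile of its seed peptide; a purely symmetric start
    (all components near the data mean) is a saddle point EM cannot
    leave, so symmetry must be broken in sequence space.
    """
    n = flat.shape[0]
    # farthest-first seeding: random first seed, then repeatedly take the
    # peptide with the lowest likelihood under the current seed profiles
    # (random peptide seeds collide on the same motif too often at K>3)
    lam = 0.3
    seeds = [int(rng.integers(n))]
    while len(seeds) < K:
        pwm_s = (1 - lam) / N_AA + lam * flat[seeds].reshape(-1, L, N_AA)
        seed_logp = np.log(pwm_s).reshape(len(seeds), L * N_AA)
        fit = (flat @ seed_logp.T).max(axis=1)
        fit[seeds] = np.inf
        seeds.append(int(np.argmin(fit)))
    pwms = (1 - lam) / N_AA + lam * flat[seeds].reshape(K, L, N_AA)
    n_comp = K + 1 if trash else K
    w = np.full(n_comp, 1.0 / n_comp)
    trash_logp = -L * np.log(N_AA)   # fixed uniform emissions

    def e_step(pwms, w):
        logp = np.log(np.maximum(pwms, 1e-300)).reshape(K, L * N_AA)
        log_joint = flat @ logp.T
        if trash:
            log_joint = np.column_stack(
                [log_joint, np.full(n, trash_logp)])
        log_joint = log_joint + np.log(np.maximum(w, 1e-300))
        lse = logsumexp(log_joint, axis=1)
        return np.exp(log_joint - lse[:, None]), float(lse.sum())

    R, ll = e_step(pwms, w)
    ll_prev = -np.inf
    trace = []
    for _ in range(max_iter):
        # M-step (the trash component, if any, updates only its weight)
        Nk = R.sum(axis=0)
        counts = R[:, :K].T @ flat               # (K, L*20)
        pwms = (counts.reshape(K, L, N_AA) + gamma)
        pwms /= pwms.sum(axis=2, keepdims=True)
        w = Nk / n
        # E-step
        R, ll = e_step(pwms, w)
        trace.append(ll)
        if ll - ll_prev < rel_tol * abs(ll_prev) and np.isfinite(ll_prev):
            break
        ll_prev = ll
    return pwms, w, R, ll, trace


def fit_mixture(peptides: list[str], K: int,
                config: DeconvConfig | None = None) -> MixtureModel:
    """Fit a K-component PWM mixture by EM, best of ``n_restarts`` runs."""
    config = config or DeconvConfig()
    if K < 1:
        raise ValueError("K must be >= 1")
    if len(peptides) < K:
        raise ValueError(f"need at least K={K} peptides, got {len(peptides)}")
    # canonicalize input order so results are exactly invariant to
    # permutations of the peptide list (the seeding is data-dependent)
    order = np.array(sorted(range(len(peptides)), key=peptides.__getitem__))
    X = encode_peptides([peptides[i] for i in order])
    L = X.shape[1]
    flat = one_hot(X)

    if K == 1 and not config.trash:
        # closed form: single PWM = smoothed empirical frequencies
        counts = flat.sum(axis=0).reshape(L, N_AA) + config.gamma
        pwm = counts / counts.sum(axis=1, keepdims=True)
        ll = float((flat @ np.log(np.maximum(pwm, 1e-300)).reshape(-1)).sum())
        return MixtureModel([PWM(pwm)], np.ones(1),
                            np.ones((len(peptides), 1)), ll, len(peptides),
                            ll_trace=[ll])

    best = None
    for restart in range(config.n_restarts):
        rng = np.random.default_rng([config.seed, K, restart])
        pwms, w, R, ll, trace = _em_run(flat, L, K, config.gamma,
                                        config.max_iter, config.rel_tol,
                                        rng, trash=config.trash)
        if best is None or ll > best[3]:
            best = (pwms, w, R, ll, trace)
    pwms, w, R, ll, trace = best
    R_out = np.empty_like(R)
    R_out[order] = R
    return MixtureModel([PWM(pwms[k]) for k in range(K)], w, R_out, ll,
                        len(peptides), ll_trace=trace,
                        trash_weight=float(w[K]) if config.trash else None)


def bic_score(model: MixtureModel, L: int) -> float:
    """BIC = -2 logL + ν ln(n) with ν = (K-1) + K·L·19 free parameters
    (a trash component, having fixed emissions, adds one weight)."""
    n_comp = model.K + (model.trash_weight is not None)
    nu = (n_comp - 1) + model.K * L * (N_AA - 1)
    return -2.0 * model.log_likelihood + nu * np.log(model.n)


def select_num_motifs(peptides: list[str], K_max: int,
                      config: DeconvConfig | None = None) -> MixtureModel:
    """Fit K = 1..K_max and return the model minimizing BIC (ties -> smaller K)."""
    config = config or DeconvConfig()
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    L = len(peptides[0])
    bics: dict[int, float] = {}
    best_model = None
    for K in range(1, min(K_max, len(peptides)) + 1):
        model = fit_mixture(peptides, K, config)
        bics[K] = bic_score(model, L)
        if best_model is None or bics[K] < bics[best_model.K]:
            best_model = model
    best_model.bic = bics[best_model.K]
    best_model.all_bics = bics
    return best_model


def assign_peptides(model: MixtureModel,
                    peptides: list[str]) -> list[tuple[str, int]]:
    """Hard-assign each peptide to its argmax-responsibility motif
    (ties break to the lowest motif index). Peptides captured by the
    trash component, when one was fitted, get index -1."""
    if model.responsibilities.shape[0] != len(peptides):
        raise ValueError("model was not fitted on these peptides")
    idx = np.argmax(model.responsibilities, axis=1)
    if model.trash_weight is not None:
        idx = np.where(idx == model.K, -1, idx)
    return [(pep, int(k)) for pep, k in zip(peptides, idx)]


def deconvolve_sample(sample: SampleDataset, length: int,
                      config: DeconvConfig | None = None
                      ) -> tuple[MixtureModel, MixtureModel]:
    """Two-stage deconvolution of one sample at one peptide length.

    Stage 1 fixes the number of motifs to the number of distinct HLA-A
    plus HLA-B alleles (these loci dominate the eluted pool); stage 2
    re-runs with the number of motifs selected by BIC up to genotype
    size + 1 (one extra component may absorb contaminants).
    """
    config = config or DeconvConfig()
    if not sample.genotype:
        raise ValueError("sample has an empty genotype")
    peptides = sample.peptides(length)
    if not peptides:
        raise ValueError(f"sample {sample.sample_id} has no {length}-mers")
    k1 = sum(1 for a in sample.genotype if a.locus in ("A", "B"))
    stage1 = fit_mixture(peptides, max(k1, 1), config)
    stage2 = select_num_motifs(peptides, len(sample.genotype) + 1, config)
    return stage1, stage2
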