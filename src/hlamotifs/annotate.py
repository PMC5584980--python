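"""Mapping deconvoluted motifs to HLA-I alleles from genotype
co-occurrence across samples — no binding-affinity predictions anywhere.

Four rules are applied in passes until a fixed point:

1. an allele shared by several samples is matched to the unique clique
   of mutually similar motifs, one per sharing sample;
2. when one sample's genotype exceeds another's by exactly one allele,
   the one motif without a counterpart maps to the extra allele;
3. a sample with exactly one motif and one allele left pairs them;
4. an allele already annotated elsewhere is recognized in further
   samples by similarity to all of its annotated motifs.

After every rule, motifs mapped to the same allele whose pairwise
distances exceed T are eliminated (returned to the unannotated set).
A semi-supervised pass can additionally seed annotations from a
reference motif library (alleles with >20 known ligands).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .compare import (ReferenceMotifLibrary, SimilarityConfig,
                      motif_distance)
from .types import AlleleName, PWM, SampleDataset


@dataclass(frozen=True)
class Motif:
    """One deconvoluted motif of one sample at one peptide length."""

    sample_id: str
    index: int
    pwm: PWM
    peptides: tuple

    @property
    def n(self) -> int:
        return len(self.peptides)

    @property
    def key(self) -> tuple[str, int]:
        return (self.sample_id, self.index)


@dataclass
class MotifCatalog:
    """All motifs of a cohort for one peptide length, keyed by sample."""

    length: int
    motifs_by_sample: dict = field(default_factory=dict)

    def __post_init__(self):
        for sid, motifs in self.motifs_by_sample.items():
            seen = set()
            for m in motifs:
                for pep in m.peptides:
                    if pep in seen:
                        raise ValueError(
                            f"{sid}: peptide {pep} assigned to two motifs")
                    seen.add(pep)

    def motifs(self, sample_id: str) -> list[Motif]:
        return self.motifs_by_sample.get(sample_id, [])

    def all_motifs(self) -> list[Motif]:
        return [m for motifs in self.motifs_by_sample.values()
                for m in motifs]

    def get(self, key: tuple[str, int]) -> Motif:
        sid, idx = key
        return self.motifs_by_sample[sid][idx]


def catalog_from_models(models: dict, length: int) -> MotifCatalog:
    """Build a catalog from {sample_id: (MixtureModel, peptides)} using
    hard (argmax-responsibility) peptide assignment."""
    from .mixture import assign_peptides
    by_sample = {}
    for sid, (model, peptides) in models.items():
        assignment = assign_peptides(model, peptides)
        groups: dict[int, list[str]] = {k: [] for k in range(model.K)}
        for pep, k in assignment:
            if k >= 0:               # trash-captured peptides drop out
                groups[k].append(pep)
        by_sample[sid] = [
            Motif(sid, k, model.pwms[k], tuple(groups[k]))
            for k in range(model.K)]
    return MotifCatalog(length, by_sample)


@dataclass
class AnnotationState:
    assignments: dict = field(default_factory=dict)   # key -> AlleleName
    provenance: dict = field(default_factory=dict)    # key -> rule label

    def annotate(self, key: tuple[str, int], allele: AlleleName, rule: str):
        if key in self.assignments:
            raise ValueError(f"motif {key} already annotated")
        self.assignments[key] = allele
        self.provenance[key] = rule

    def unannotate(self, key: tuple[str, int]):
        self.assignments.pop(key, None)
        self.provenance.pop(key, None)

    def allele_motifs(self, allele: AlleleName) -> list[tuple[str, int]]:
        return sorted(k for k, a in self.assignments.items() if a == allele)

    def annotated_alleles(self) -> set:
        return set(self.assignments.values())

    def sample_allele(self, sample_id: str, allele: AlleleName) -> bool:
        return any(k[0] == sample_id and a == allele
                   for k, a in self.assignments.items())

    def unannotated_motifs(self, catalog: MotifCatalog,
                           sample_id: str) -> list[Motif]:
        return [m for m in catalog.motifs(sample_id)
                if m.key not in self.assignments]


def _within(m1: Motif, m2: Motif, T: float) -> bool:
    return motif_distance(m1.pwm, m2.pwm) <= T


def _find_cliques(per_sample: list[list[Motif]], T: float,
                  limit: int = 2) -> list[list[Motif]]:
    """Selections of one motif per sample with all pairs within T.
    Stops after `limit` cliques (only existence/uniqueness is needed)."""
    cliques: list[list[Motif]] = []

    def extend(chosen: list[Motif], rest: list[list[Motif]]):
        if len(cliques) >= limit:
            return
        if not rest:
            cliques.append(list(chosen))
            return
        for cand in rest[0]:
            if all(_within(cand, c, T) for c in chosen):
                chosen.append(cand)
                extend(chosen, rest[1:])
                chosen.pop()

    extend([], per_sample)
    return cliques


def rule1_shared_allele(catalog: MotifCatalog, samples: list[SampleDataset],
                        state: AnnotationState,
                        config: SimilarityConfig) -> int:
    """Annotate alleles shared by >=2 samples via a unique cross-sample
    clique of mutually similar unannotated motifs (one per sharing sample)."""
    n_new = 0
    alleles = sorted({a for s in samples for a in s.genotype})
    for allele in alleles:
        if allele in state.annotated_alleles():
            continue
        sharing = [s for s in samples if allele in s.genotype]
        if len(sharing) < 2:
            continue
        per_sample = [state.unannotated_motifs(catalog, s.sample_id)
                      for s in sharing]
        if any(not motifs for motifs in per_sample):
            continue
        cliques = _find_cliques(per_sample, config.T)
        if len(cliques) == 1:
            for motif in cliques[0]:
                state.annotate(motif.key, allele, "rule1")
                n_new += 1
    return n_new


def rule2_all_but_one(catalog: MotifCatalog, samples: list[SampleDataset],
                      state: AnnotationState,
                      config: SimilarityConfig) -> int:
    """When sample A carries exactly one allele that sample B lacks and
    exactly one of A's motifs has no similar motif in B, map that motif
    to the extra allele."""
    n_new = 0
    for sa, sb in itertools.permutations(samples, 2):
        extra = sa.genotype - sb.genotype
        if len(extra) != 1:
            continue
        allele = next(iter(extra))
        if state.sample_allele(sa.sample_id, allele):
            continue
        b_motifs = catalog.motifs(sb.sample_id)
        unmatched = [m for m in catalog.motifs(sa.sample_id)
                     if not any(_within(m, mb, config.T) for mb in b_motifs)]
        if len(unmatched) == 1 and unmatched[0].key not in state.assignments:
            state.annotate(unmatched[0].key, allele, "rule2")
            n_new += 1
    return n_new


def rule3_last_remaining(catalog: MotifCatalog, samples: list[SampleDataset],
                         state: AnnotationState) -> int:
    """A sample with exactly one unannotated motif and exactly one
    unannotated allele pairs them."""
    n_new = 0
    for s in samples:
        free_motifs = state.unannotated_motifs(catalog, s.sample_id)
        free_alleles = [a for a in s.genotype
                        if not state.sample_allele(s.sample_id, a)]
        if len(free_motifs) == 1 and len(free_alleles) == 1:
            state.annotate(free_motifs[0].key, free_alleles[0], "rule3")
            n_new += 1
    return n_new


def rule4_propagate(catalog: MotifCatalog, samples: list[SampleDataset],
                    state: AnnotationState,
                    config: SimilarityConfig) -> int:
    """Recognize an already-annotated allele in further samples: annotate
    the unique unannotated motif similar to all of the allele's motifs."""
    n_new = 0
    for allele in sorted(state.annotated_alleles()):
        anchors = [catalog.get(k) for k in state.allele_motifs(allele)]
        for s in samples:
            if allele not in s.genotype:
                continue
            if state.sample_allele(s.sample_id, allele):
                continue
            candidates = [
                m for m in state.unannotated_motifs(catalog, s.sample_id)
                if all(_within(m, anc, config.T) for anc in anchors)]
            if len(candidates) == 1:
                state.annotate(candidates[0].key, allele, "rule4")
                n_new += 1
    return n_new


def eliminate_inconsistencies(state: AnnotationState, catalog: MotifCatalog,
                              config: SimilarityConfig) -> int:
    """While any two motifs mapped to the same allele are farther than T
    apart, drop the motif with the largest mean distance to the others
    (ties drop all tied motifs — a mutually inconsistent pair loses both)."""
    n_removed = 0
    for allele in sorted(state.annotated_alleles()):
        while True:
            keys = state.allele_motifs(allele)
            if len(keys) < 2:
                break
            pwms = [catalog.get(k).pwm for k in keys]
            dist = np.array([[motif_distance(p, q) for q in pwms]
                             for p in pwms])
            if dist.max() <= config.T:
                break
            mean_d = dist.sum(axis=1) / (len(keys) - 1)
            worst = mean_d.max()
            for i, k in enumerate(keys):
                if mean_d[i] >= worst - 1e-12:
                    state.unannotate(k)
                    n_removed += 1
    return n_removed


def annotate_unsupervised(catalog: MotifCatalog,
                          samples: list[SampleDataset],
                          config: SimilarityConfig | None = None,
                          state: AnnotationState | None = None
                          ) -> AnnotationState:
    """Apply rules 1-4 with inconsistency elimination after each rule,
    looping until a full pass adds no annotation."""
    config = config or SimilarityConfig()
    state = state or AnnotationState()
    max_passes = len(catalog.all_motifs()) + 1
    for _ in range(max_passes):
        n_new = 0
        n_new += rule1_shared_allele(catalog, samples, state, config)
        eliminate_inconsistencies(state, catalog, config)
        n_new += rule2_all_but_one(catalog, samples, state, config)
        eliminate_inconsistencies(state, catalog, config)
        n_new += rule3_last_remaining(catalog, samples, state)
        eliminate_inconsistencies(state, catalog, config)
        n_new += rule4_propagate(catalog, samples, state, config)
        eliminate_inconsistencies(state, catalog, config)
        if n_new == 0:
            break
    return state


def annotate_semisupervised(state: AnnotationState, catalog: MotifCatalog,
                            library: ReferenceMotifLibrary,
                            samples: list[SampleDataset],
                            config: SimilarityConfig | None = None
                            ) -> AnnotationState:
    """Seed annotations from reference motifs (alleles with >20 known
    ligands): in each sample, an unannotated allele is matched when
    exactly one unannotated motif is within T of its reference PWM.
    The unsupervised pass is then re-run to exploit the new anchors."""
    config = config or SimilarityConfig()
    for s in samples:
        for allele in sorted(s.genotype):
            if state.sample_allele(s.sample_id, allele):
                continue
            if not library.eligible(allele):
                continue
            ref_pwm, _ = library.entries[allele]
            hits = [m for m in state.unannotated_motifs(catalog, s.sample_id)
                    if motif_distance(m.pwm, ref_pwm) <= config.T]
            if len(hits) == 1:
                state.annotate(hits[0].key, allele, "semi")
    eliminate_inconsistencies(state, catalog, config)
    return annotate_unsupervised(catalog, samples, config, state)


def pool_allele_peptides(state: AnnotationState,
                         catalog: MotifCatalog) -> dict:
    """Union of assigned peptides over all motifs annotated to each allele."""
    pools: dict[AlleleName, set] = {}
    for key, allele in state.assignments.items():
        pools.setdefault(allele, set()).update(catalog.get(key).peptides)
    return pools


def build_reference_pwm(peptides: list[str]) -> PWM:
    """Reference-style PWM: per-position frequencies with a flat count of
    1 added for every residue at every position."""
    return PWM.from_peptides(peptides, pseudocount=1.0)
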