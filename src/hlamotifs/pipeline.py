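"""End-to-end helpers: cohort deconvolution -> motif catalog ->
annotation -> per-allele pools -> trained predictor. These tie the
modules together for the CLI, the validation harness and the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotate import (AnnotationState, MotifCatalog, catalog_from_models,
                       annotate_unsupervised, pool_allele_peptides)
from .compare import SimilarityConfig, motif_distance
from .mixture import DeconvConfig, deconvolve_sample
from .predictor import (AlleleModel, PseudocountParams,
                        build_allele_pwm, estimate_ms_background)
from .types import PWM, AlleleName, SampleDataset
from .synth import Cohort, CONTAMINANT_LABEL


def deconvolve_cohort(samples: list[SampleDataset], length: int,
                      config: DeconvConfig | None = None,
                      use_trash: bool = True) -> MotifCatalog:
    """Two-stage deconvolution of every sample; the catalog is built
    from the stage-2 (BIC-selected) models.

    The pipeline fits each mixture with the fixed-uniform trash
    component so proteome contaminants are captured rather than folded
    into binding motifs."""
    from dataclasses import replace
    config = config or DeconvConfig()
    if use_trash and not config.trash:
        config = replace(config, trash=True)
    models = {}
    for sample in samples:
        _, stage2 = deconvolve_sample(sample, length, config)
        models[sample.sample_id] = (stage2, sample.peptides(length))
    return catalog_from_models(models, length)


def run_annotation(samples: list[SampleDataset], length: int = 9,
                   deconv: DeconvConfig | None = None,
                   sim: SimilarityConfig | None = None
                   ) -> tuple[MotifCatalog, AnnotationState, dict]:
    """Deconvolve, annotate, and pool: the full unsupervised pipeline
    for one peptide length."""
    catalog = deconvolve_cohort(samples, length, deconv)
    state = annotate_unsupervised(catalog, samples, sim)
    pools = pool_allele_peptides(state, catalog)
    return catalog, state, pools


def train_models(pools_by_length: dict,
                 params: PseudocountParams | None = None) -> list[AlleleModel]:
    """Build one pseudocounted AlleleModel per allele from pooled
    peptides, ``pools_by_length``: {length: {allele: peptide set}}."""
    params = params or PseudocountParams()
    per_allele: dict[AlleleName, dict] = {}
    for length, pools in pools_by_length.items():
        for allele, peptides in pools.items():
            if peptides:
                per_allele.setdefault(allele, {})[length] = sorted(peptides)
    return [
        AlleleModel(allele,
                    {L: build_allele_pwm(peps, params)
                     for L, peps in by_len.items()},
                    {L: len(peps) for L, peps in by_len.items()})
        for allele, by_len in sorted(per_allele.items())]


@dataclass
class AnnotationScore:
    """Comparison of an annotation against a cohort's ground truth."""

    n_annotated: int = 0
    n_correct: int = 0
    n_false: int = 0
    missing_alleles: list = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_annotated if self.n_annotated else 0.0


def motif_truth_label(cohort: Cohort, sample_id: str,
                      peptides: tuple) -> str:
    """Majority ground-truth label of a motif's assigned peptides."""
    lookup = dict(cohort.labels[sample_id])
    votes: dict[str, int] = {}
    for pep in peptides:
        lab = lookup.get(pep)
        if lab is not None:
            votes[lab] = votes.get(lab, 0) + 1
    return max(votes, key=lambda k: (votes[k], k)) if votes else ""


def score_annotation(state: AnnotationState, catalog: MotifCatalog,
                     cohort: Cohort) -> AnnotationScore:
    """An annotation (sample, motif) -> allele counts as correct when the
    motif's majority truth label is that allele."""
    score = AnnotationScore()
    annotated_pairs = set()
    for (sid, idx), allele in state.assignments.items():
        truth_label = motif_truth_label(cohort, sid,
                                        catalog.get((sid, idx)).peptides)
        score.n_annotated += 1
        if truth_label == allele.compact:
            score.n_correct += 1
            annotated_pairs.add((sid, allele.compact))
        else:
            score.n_false += 1
    for sample in cohort.samples:
        for allele in sample.genotype:
            if (sample.sample_id, allele.compact) not in annotated_pairs:
                score.missing_alleles.append(
                    (sample.sample_id, allele.compact))
    return score


def pooled_pwms(pools: dict, length: int) -> dict:
    """Per-allele empirical-frequency PWMs from pooled peptides."""
    out = {}
    for allele, peptides in pools.items():
        peps = [p for p in peptides if len(p) == length]
        if peps:
            out[allele] = PWM.from_peptides(sorted(peps))
    return out


def oracle_match_pools(catalog: MotifCatalog, cohort: Cohort,
                       sample_ids=None) -> dict:
    """Pool motif peptides per allele by matching each deconvolved motif
    to the nearest truth PWM (ground-truth oracle, no annotation)."""
    length = catalog.length
    truth = cohort.truth
    pools: dict[AlleleName, set] = {}
    for sid, motifs in catalog.motifs_by_sample.items():
        if sample_ids is not None and sid not in sample_ids:
            continue
        genotype = next(s.genotype for s in cohort.samples
                        if s.sample_id == sid)
        for m in motifs:
            best = min(genotype,
                       key=lambda a: motif_distance(m.pwm,
                                                    truth.pwm(a, length)))
            if motif_distance(m.pwm, truth.pwm(best, length)) <= 0.078:
                pools.setdefault(best, set()).update(m.peptides)
    return pools
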