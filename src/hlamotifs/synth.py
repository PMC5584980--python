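"""Synthetic immunopeptidomics cohorts with known ground truth.

The generator emulates the structure of pooled HLA-I elution data:
per-allele truth PWMs with strong anchor residues at P2 and the
C-terminal position, near-background middle positions, multi-allele
samples whose genotypes overlap by design, cysteine under-detection in
the sampled (not truth) peptides, uniform-residue contaminants, a
reference motif library, and a random proteome with missense mutation
tables (optionally with a planted neo-antigen).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, HUMAN_PROTEOME_FREQS, N_AA
from .annotate import build_reference_pwm
from .compare import ReferenceMotifLibrary
from .types import AlleleName, PWM, SampleDataset
from .predictor import MutationRecord

CONTAMINANT_LABEL = "contaminant"

#: Default cysteine detection factor applied to sampled peptides.
CYS_DEPLETION = 0.2

#: Default anchor probability mass on the anchor residue.
ANCHOR_PROB = 0.9


@dataclass
class TruthSpec:
    """Ground-truth allele motifs: per (allele, length) PWMs plus the
    anchor bookkeeping needed to reason about separability."""

    alleles: list
    pwms: dict                      # (AlleleName, length) -> PWM
    anchors: dict                   # AlleleName -> (P2 residue, PΩ residue)
    background: np.ndarray = field(
        default_factory=lambda: HUMAN_PROTEOME_FREQS.copy())

    def pwm(self, allele: AlleleName, length: int) -> PWM:
        return self.pwms[(allele, length)]

    @property
    def lengths(self):
        return sorted({L for _, L in self.pwms})


@dataclass
class CohortDesign:
    """Sample genotypes and sampling conditions for one synthetic cohort."""

    samples: list                   # (sample_id, [allele strings])
    peptides_per_sample: int = 3000
    mixing_weights: dict | None = None   # sample_id -> weight vector
    contaminant_fraction: float = 0.0
    lengths: tuple = (9,)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.contaminant_fraction < 1:
            raise ValueError("contaminant_fraction must be in [0, 1)")


#: Dirichlet concentration of non-anchor truth columns around the
#: background; finite values give each allele the weak residual
#: middle-position specificity real motifs show.
MIDDLE_CONCENTRATION = 100.0


def _anchored_pwm(length: int, anchor2: str, anchor_last: str,
                  background: np.ndarray,
                  anchor_prob: float = ANCHOR_PROB,
                  rng: np.random.Generator | None = None,
                  middle_concentration: float | None = MIDDLE_CONCENTRATION
                  ) -> PWM:
    matrix = np.tile(background, (length, 1))
    if rng is not None and middle_concentration is not None:
        for pos in range(length):
            col = rng.dirichlet(background * middle_concentration)
            matrix[pos] = np.maximum(col, 1e-6)
    for pos, residue in ((1, anchor2), (length - 1, anchor_last)):
        col = background.copy()
        col[AA_INDEX[residue]] = 0.0
        col = (1.0 - anchor_prob) * col / col.sum()
        col[AA_INDEX[residue]] = anchor_prob
        matrix[pos] = col
    return PWM(matrix / matrix.sum(axis=1, keepdims=True))


def generate_truth(n_alleles: int | None = None,
                   alleles: list | None = None,
                   lengths=(9,), seed: int = 0,
                   anchor_prob: float = ANCHOR_PROB,
                   confusable_pairs: int = 0) -> TruthSpec:
    """Draw anchor residue pairs without replacement so all truth motifs
    are well separated (pairwise D² far above the similarity threshold),
    unless confusable pairs are requested.

    A confusable pair reuses the previous allele's anchors with a small
    middle-position perturbation, giving D² below the threshold.
    """
    if alleles is not None:
        alleles = [a if isinstance(a, AlleleName) else AlleleName.parse(a)
                   for a in alleles]
        n_alleles = len(alleles)
    elif n_alleles is None:
        raise ValueError("give n_alleles or an allele list")
    else:
        names = []
        for i in range(n_alleles):
            locus = "ABC"[i % 3]
            names.append(AlleleName(locus, f"{(i // 3) + 1:02d}", "01"))
        alleles = names
    if n_alleles < 1:
        raise ValueError("n_alleles must be >= 1")

    rng = np.random.default_rng(seed)
    # anchors never use cysteine: its detection is depleted in sampling
    usable = [a for a in AMINO_ACIDS if a != "C"]
    n_distinct = n_alleles - confusable_pairs
    if n_distinct <= len(usable):
        # distinct anchor residues at BOTH positions: any two alleles of
        # one genotype then differ at P2 and PΩ, keeping the per-sample
        # mixture well separated
        p2 = rng.choice(len(usable), size=n_distinct, replace=False)
        pL = rng.choice(len(usable), size=n_distinct, replace=False)
        chosen = [(usable[a], usable[b]) for a, b in zip(p2, pL)]
    else:
        pairs = [(a, b) for a in usable for b in usable]
        if n_distinct > len(pairs):
            raise ValueError("more alleles than distinguishable anchor pairs")
        chosen = [pairs[i] for i in
                  rng.choice(len(pairs), size=n_distinct, replace=False)]

    background = HUMAN_PROTEOME_FREQS.copy()
    anchors: dict[AlleleName, tuple[str, str]] = {}
    pwms: dict = {}
    for i, allele in enumerate(alleles):
        if i < n_distinct:
            a2, aL = chosen[i]
        else:
            # confusable: reuse another allele's anchors; the independent
            # weak middle-position draw keeps the pair within the
            # similarity threshold but not identical
            a2, aL = chosen[(i - n_distinct) % n_distinct]
        anchors[allele] = (a2, aL)
        for L in lengths:
            pwms[(allele, L)] = _anchored_pwm(L, a2, aL, background,
                                              anchor_prob, rng=rng)
    return TruthSpec(alleles, pwms, anchors, background)


def _sampling_matrix(pwm: PWM, cys_depletion: float) -> np.ndarray:
    """Per-position sampling distribution: the truth PWM with cysteine
    detection depleted, renormalized (the bias is in the data)."""
    m = pwm.matrix.copy()
    m[:, AA_INDEX["C"]] *= cys_depletion
    return m / m.sum(axis=1, keepdims=True)


def _draw_peptides(matrix: np.ndarray, n: int,
                   rng: np.random.Generator) -> list[str]:
    L = matrix.shape[0]
    cum = matrix.cumsum(axis=1)
    u = rng.random((n, L))
    codes = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    return ["".join(AMINO_ACIDS[c] for c in row) for row in codes]


@dataclass
class Cohort:
    """A generated cohort: samples plus the ground-truth sidecar."""

    truth: TruthSpec
    design: CohortDesign
    samples: list                   # list[SampleDataset]
    labels: dict                    # sample_id -> list[(peptide, label)]

    def label_of(self, sample_id: str, peptide: str) -> str | None:
        for pep, lab in self.labels[sample_id]:
            if pep == peptide:
                return lab
        return None


def generate_cohort(truth: TruthSpec, design: CohortDesign,
                    out_dir=None, cys_depletion: float = CYS_DEPLETION
                    ) -> Cohort:
    """Sample each sample's peptides from its alleles' truth PWMs
    (uniform mixing weights unless given), inject uniform-residue
    contaminants, and optionally write manifest/peptide files plus a
    truth sidecar JSON."""
    rng = np.random.default_rng(design.seed)
    samples, labels = [], {}
    for sid, genotype in design.samples:
        genotype = [a if isinstance(a, AlleleName) else AlleleName.parse(a)
                    for a in genotype]
        for a in genotype:
            if not any((a, L) in truth.pwms for L in design.lengths):
                raise ValueError(f"allele {a} absent from truth spec")
        n_total = design.peptides_per_sample
        n_cont = int(round(design.contaminant_fraction * n_total))
        n_true = n_total - n_cont
        weights = None
        if design.mixing_weights is not None:
            weights = np.asarray(design.mixing_weights[sid], dtype=float)
            weights = weights / weights.sum()
        else:
            weights = np.full(len(genotype), 1.0 / len(genotype))
        pep_label: list[tuple[str, str]] = []
        by_length: dict[int, list[str]] = {L: [] for L in design.lengths}
        for L in design.lengths:
            counts = rng.multinomial(n_true // len(design.lengths), weights)
            for allele, m in zip(genotype, counts):
                mat = _sampling_matrix(truth.pwm(allele, L), cys_depletion)
                for pep in _draw_peptides(mat, int(m), rng):
                    pep_label.append((pep, allele.compact))
                    by_length[L].append(pep)
            n_cont_L = n_cont // len(design.lengths)
            uniform = np.full((L, N_AA), 1.0 / N_AA)
            for pep in _draw_peptides(uniform, n_cont_L, rng):
                pep_label.append((pep, CONTAMINANT_LABEL))
                by_length[L].append(pep)
        samples.append(SampleDataset(sid, frozenset(genotype), by_length))
        labels[sid] = pep_label
    cohort = Cohort(truth, design, samples, labels)
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: Cohort, out_dir: Path):
    from .io import write_manifest
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in cohort.samples:
        fname = f"{sample.sample_id}.txt"
        with open(out_dir / fname, "w") as fh:
            for L in sorted(sample.peptides_by_length):
                for pep in sample.peptides(L):
                    fh.write(pep + "\n")
        rows.append((sample.sample_id, fname, sorted(sample.genotype)))
    write_manifest(out_dir / "manifest.tsv", rows)
    sidecar = {
        "alleles": [a.compact for a in cohort.truth.alleles],
        "anchors": {a.compact: list(cohort.truth.anchors[a])
                    for a in cohort.truth.alleles},
        "truth_pwms": {
            f"{a.compact}:{L}": cohort.truth.pwm(a, L).matrix.tolist()
            for (a, L) in cohort.truth.pwms},
        "labels": {sid: labs for sid, labs in cohort.labels.items()},
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(sidecar, fh)


def generate_reference_library(truth: TruthSpec, alleles_subset,
                               ligand_counts, seed: int = 0,
                               pad_to: int = 0, length: int = 9
                               ) -> ReferenceMotifLibrary:
    """Build reference motifs by sampling ligands from truth PWMs, plus
    optional padding motifs from fresh random anchors so the compendium
    reaches a chosen size (e.g. 107 for P-value denominators of 108)."""
    rng = np.random.default_rng(seed)
    entries = {}
    for allele in alleles_subset:
        allele = (allele if isinstance(allele, AlleleName)
                  else AlleleName.parse(allele))
        n = (ligand_counts[allele] if isinstance(ligand_counts, dict)
             else int(ligand_counts))
        peps = _draw_peptides(truth.pwm(allele, length).matrix, n, rng)
        entries[allele] = (build_reference_pwm(peps), n)
    usable = [a for a in AMINO_ACIDS if a != "C"]
    i = 0
    while len(entries) < pad_to:
        name = AlleleName("ABC"[i % 3], f"{(i // 3) % 100:02d}",
                          f"{90 + (i // 300) % 10:02d}")
        i += 1
        if name in entries:
            continue
        a2, aL = rng.choice(usable), rng.choice(usable)
        pwm = _anchored_pwm(length, str(a2), str(aL), truth.background)
        peps = _draw_peptides(pwm.matrix, 50, rng)
        entries[name] = (build_reference_pwm(peps), 50)
    return ReferenceMotifLibrary(entries)


def generate_proteome_and_mutations(n_proteins: int, protein_length: int,
                                    n_mutations: int, seed: int = 0,
                                    truth: TruthSpec | None = None,
                                    plant_allele=None,
                                    plant_length: int = 9):
    """Random human-like proteome plus a missense mutation table.

    With ``plant_allele`` set, one window is rewritten so that applying
    one of the mutations yields a peptide drawn from that allele's truth
    PWM (a planted neo-antigen); the peptide is returned as third value.
    """
    rng = np.random.default_rng(seed)
    proteome = {}
    for i in range(n_proteins):
        codes = rng.choice(N_AA, size=protein_length,
                           p=HUMAN_PROTEOME_FREQS)
        proteome[f"prot{i + 1}"] = "".join(AMINO_ACIDS[c] for c in codes)

    planted_peptide = None
    mutations: list[MutationRecord] = []
    if plant_allele is not None:
        if truth is None:
            raise ValueError("planting a neo-antigen requires a truth spec")
        allele = (plant_allele if isinstance(plant_allele, AlleleName)
                  else AlleleName.parse(plant_allele))
        # the planted peptide must match the allele's anchors: a real
        # MS-detected neo-antigen binds by construction
        a2, aL = truth.anchors[allele]
        while True:
            pep = _draw_peptides(truth.pwm(allele, plant_length).matrix,
                                 1, rng)[0]
            if pep[1] == a2 and pep[-1] == aL:
                break
        pid = "prot1"
        seq = proteome[pid]
        start = protein_length // 2          # 0-based window start
        offset = plant_length // 2           # mutation inside the window
        pos = start + offset                 # 0-based mutation site
        alt = pep[offset]
        ref_choices = [a for a in AMINO_ACIDS if a != alt]
        ref = str(rng.choice(ref_choices))
        planted = seq[:start] + pep + seq[start + plant_length:]
        planted = planted[:pos] + ref + planted[pos + 1:]
        proteome[pid] = planted
        mutations.append(MutationRecord(pid, planted, pos + 1, ref, alt))
        planted_peptide = pep

    pids = sorted(proteome)
    while len(mutations) < n_mutations + (plant_allele is not None):
        pid = pids[rng.integers(len(pids))]
        seq = proteome[pid]
        pos = int(rng.integers(1, len(seq) + 1))
        ref = seq[pos - 1]
        if ref not in AA_INDEX:
            continue
        alt = str(rng.choice([a for a in AMINO_ACIDS if a != ref]))
        mutations.append(MutationRecord(pid, seq, pos, ref, alt))
    return proteome, mutations, planted_peptide


# ---------------------------------------------------------------------------
# The standard "standard" cohort preset: 10 samples over 15 alleles with
# genotype overlaps guaranteeing that annotation rules 1-3 each fire.
# B5701 occurs only in S4, whose genotype is S3's plus B5701 (rule 2);
# C0702 occurs only in S10 (rule 3 once its other alleles are annotated);
# every other allele is shared by >=2 samples (rule 1).
# ---------------------------------------------------------------------------

STANDARD_GENOTYPES = [
    ("S1", ["A0101", "A0201", "B0702", "B0801", "C0304"]),
    ("S2", ["A0101", "A0301", "B0801", "B1501", "C0401"]),
    ("S3", ["A0201", "A2402", "B0801", "C0401"]),
    ("S4", ["A0201", "A2402", "B0801", "B5701", "C0401"]),
    ("S5", ["A6801", "A1101", "B2705", "C0304"]),
    ("S6", ["A6801", "A0101", "B4001", "B0702", "C0401"]),
    ("S7", ["A1101", "A0301", "B2705", "B1501", "C0304"]),
    ("S8", ["A6801", "A2402", "B4001", "B2705", "C0304"]),
    ("S9", ["A1101", "A0301", "B1501", "B0801", "C0401"]),
    ("S10", ["A0101", "A0201", "B0702", "B1501", "C0702"]),
]

STANDARD_ALLELES = sorted({a for _, g in STANDARD_GENOTYPES for a in g})


def standard_truth(seed: int = 0, lengths=(9,)) -> TruthSpec:
    return generate_truth(alleles=STANDARD_ALLELES, lengths=lengths,
                          seed=seed)


def standard_cohort(seed: int = 0, peptides_per_sample: int = 3000,
                      contaminant_fraction: float = 0.0,
                      lengths=(9,), out_dir=None) -> Cohort:
    """The standard test cohort: 10 samples, 15 alleles, 9-mers."""
    truth = standard_truth(seed=seed, lengths=lengths)
    design = CohortDesign(STANDARD_GENOTYPES,
                          peptides_per_sample=peptides_per_sample,
                          contaminant_fraction=contaminant_fraction,
                          lengths=lengths, seed=seed)
    return generate_cohort(truth, design, out_dir=out_dir)
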