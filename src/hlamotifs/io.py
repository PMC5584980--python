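"""Readers and writers for peptide lists, manifests, FASTA proteomes and
PWM files, plus decoy sampling from a proteome.

File formats
------------
* peptide list: plain text, one peptide per line, no header
* manifest: TSV with header ``sample_id  peptide_file  alleles`` (alleles
  comma-separated, any accepted allele dialect)
* PWM: TSV; first line ``#PWM length=<L> alphabet=ACDEFGHIKLMNPQRSTVWY``,
  then 20 rows (residue, then L probabilities, positions P1..PL)
* proteome: FASTA
* mutation table: TSV ``protein_id  position  ref  alt`` (1-based)
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .alphabet import AA_INDEX, AMINO_ACIDS, N_AA, is_canonical
from .types import (MAX_PEPTIDE_LENGTH, MIN_PEPTIDE_LENGTH, AlleleName,
                    PWM, SampleDataset)

logger = logging.getLogger("hlamotifs")


class EmptyDatasetError(ValueError):
    pass


class PWMFormatError(ValueError):
    pass


def read_peptide_list(path, min_len: int = MIN_PEPTIDE_LENGTH,
                      max_len: int = MAX_PEPTIDE_LENGTH) -> dict[int, list[str]]:
    """Read one peptide per line, uppercase, drop non-canonical tokens,
    deduplicate, and group by length. Dropped counts are logged."""
    path = Path(path)
    n_read = n_dropped = n_duplicate = 0
    by_length: dict[int, list[str]] = {}
    seen: dict[int, set] = {}
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if not token:
                continue
            n_read += 1
            pep = token.upper()
            if not is_canonical(pep) or not min_len <= len(pep) <= max_len:
                n_dropped += 1
                continue
            L = len(pep)
            if pep in seen.setdefault(L, set()):
                n_duplicate += 1
                continue
            seen[L].add(pep)
            by_length.setdefault(L, []).append(pep)
    logger.info("%s: read %d, dropped %d, deduplicated %d",
                path.name, n_read, n_dropped, n_duplicate)
    if not by_length:
        raise EmptyDatasetError(f"no valid peptides in {path}")
    return by_length


def read_manifest(path) -> list[SampleDataset]:
    """Read a sample manifest TSV and load each sample's peptide list.

    Peptide file paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    samples: list[SampleDataset] = []
    ids_seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["sample_id", "peptide_file", "alleles"]:
            raise ValueError(
                f"manifest header must be sample_id/peptide_file/alleles, "
                f"got {header}")
        for line in fh:
            if not line.strip():
                continue
            sid, pep_file, alleles = line.rstrip("\n").split("\t")[:3]
            sid = sid.strip()
            if sid in ids_seen:
                raise ValueError(f"duplicate sample_id {sid!r}")
            ids_seen.add(sid)
            genotype = frozenset(
                AlleleName.parse(a) for a in alleles.split(",") if a.strip())
            pep_path = Path(pep_file.strip())
            if not pep_path.is_absolute():
                pep_path = path.parent / pep_path
            peptides = read_peptide_list(pep_path)
            samples.append(SampleDataset(sid, genotype, peptides))
    return samples


def write_manifest(path, rows: list[tuple[str, str, list[AlleleName]]]):
    with open(path, "w") as fh:
        fh.write("sample_id\tpeptide_file\talleles\n")
        for sid, pep_file, alleles in rows:
            fh.write(f"{sid}\t{pep_file}\t"
                     + ",".join(a.compact for a in sorted(alleles)) + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {protein_id: uppercase sequence}.

    The id is the first whitespace-delimited token of the header.
    """
    proteome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in proteome:
            raise ValueError(f"duplicate FASTA id {record.id!r}")
        proteome[record.id] = str(record.seq).upper()
    if not proteome:
        raise ValueError(f"no FASTA records in {path}")
    return proteome


def write_fasta(path, proteome: dict[str, str]):
    with open(path, "w") as fh:
        for pid, seq in proteome.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def sample_random_peptides(proteome: dict[str, str], length: int, n: int,
                           seed: int) -> list[str]:
    """Draw n peptides uniformly (with replacement) over all length-L
    windows of the proteome composed only of canonical residues."""
    windows: list[tuple[str, int]] = []
    for pid, seq in proteome.items():
        ok = np.fromiter((c in AA_INDEX for c in seq), dtype=bool,
                         count=len(seq))
        if len(seq) < length:
            continue
        # window valid iff all positions canonical
        valid = np.ones(len(seq) - length + 1, dtype=bool)
        for off in range(length):
            valid &= ok[off:off + len(valid)]
        windows.extend((pid, int(s)) for s in np.nonzero(valid)[0])
    if not windows:
        raise ValueError(f"proteome has no canonical window of length {length}")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(windows), size=n)
    return [proteome[windows[i][0]][windows[i][1]:windows[i][1] + length]
            for i in picks]


def write_pwm(path, pwm: PWM):
    """Write a PWM as residues-by-positions TSV (see module docstring)."""
    with open(path, "w") as fh:
        fh.write(f"#PWM length={pwm.length} alphabet={AMINO_ACIDS}\n")
        for a, residue in enumerate(AMINO_ACIDS):
            vals = "\t".join(f"{pwm.matrix[i, a]:.12g}"
                             for i in range(pwm.length))
            fh.write(f"{residue}\t{vals}\n")


def read_pwm(path) -> PWM:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#PWM "):
            raise PWMFormatError(f"{path}: missing #PWM header")
        fields = dict(kv.split("=") for kv in header[5:].split())
        L = int(fields["length"])
        if fields.get("alphabet") != AMINO_ACIDS:
            raise PWMFormatError(f"{path}: unexpected alphabet")
        matrix = np.zeros((L, N_AA))
        rows_seen = []
        for line in fh:
            if not line.strip():
                continue
            parts = line.split("\t")
            residue = parts[0].strip()
            if residue not in AA_INDEX:
                raise PWMFormatError(f"{path}: unknown residue row {residue!r}")
            values = [float(v) for v in parts[1:]]
            if len(values) != L:
                raise PWMFormatError(
                    f"{path}: row {residue} has {len(values)} columns, "
                    f"expected {L}")
            matrix[:, AA_INDEX[residue]] = values
            rows_seen.append(residue)
    if len(rows_seen) != N_AA or set(rows_seen) != set(AMINO_ACIDS):
        raise PWMFormatError(f"{path}: expected 20 residue rows, "
                             f"got {len(rows_seen)}")
    sums = matrix.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise PWMFormatError(f"{path}: position sums deviate from 1: {sums}")
    return PWM(matrix / sums[:, None])


def write_reference_library(directory, library):
    """Write a reference motif library: one PWM file per allele plus an
    index.tsv of (allele, n_ligands)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "index.tsv", "w") as fh:
        fh.write("allele\tn_ligands\n")
        for allele, (pwm, n) in sorted(library.entries.items()):
            write_pwm(directory / f"{allele.compact}.pwm", pwm)
            fh.write(f"{allele.compact}\t{n}\n")


def read_reference_library(directory):
    from .compare import ReferenceMotifLibrary
    from .types import AlleleName
    directory = Path(directory)
    entries = {}
    with open(directory / "index.tsv") as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            name, n = line.rstrip("\n").split("\t")[:2]
            allele = AlleleName.parse(name)
            entries[allele] = (read_pwm(directory / f"{name}.pwm"), int(n))
    return ReferenceMotifLibrary(entries)


def read_mutation_table(path, proteome: dict[str, str]):
    """Read a mutation TSV into MutationRecord objects (see predictor)."""
    from .predictor import MutationRecord
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["protein_id", "position", "ref", "alt"]:
            raise ValueError(f"unexpected mutation table header {header}")
        for line in fh:
            if not line.strip():
                continue
            pid, pos, ref, alt = line.rstrip("\n").split("\t")[:4]
            if pid not in proteome:
                raise ValueError(f"mutation references unknown protein {pid!r}")
            records.append(MutationRecord(pid, proteome[pid], int(pos),
                                          ref.strip(), alt.strip()))
    return records


def write_mutation_table(path, records):
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tref\talt\n")
        for r in records:
            fh.write(f"{r.protein_id}\t{r.position}\t{r.ref}\t{r.alt}\n")
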