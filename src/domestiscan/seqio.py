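"""Shared data model and format IO.

Everything downstream works on :class:`LocusAlignment` (gap-aware aligned
sequences for one locus, with per-sample population labels), built from a
FASTA alignment plus a two-column population map.  All coordinates reported
at any interface are 1-based inclusive; missing data is ``N`` or ``-``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

VALID_CHARS = set("ACGT-N")
MISSING = {"-", "N"}


class AlignmentError(ValueError):
    """Sequences do not form a valid alignment."""


class PopmapError(ValueError):
    """Sample ids missing from, or duplicated in, the population map."""


class InsufficientSampleError(ValueError):
    """Fewer sequences than the statistic requires."""


@dataclass
class PopulationMap:
    """Sample → population assignment (japonica / indica / wild / outgroup / other)."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        non_outgroup = [p for p in self.assignments.values() if p != "outgroup"]
        if not non_outgroup:
            raise PopmapError("population map needs at least one non-outgroup sample")

    def __getitem__(self, sample: str) -> str:
        return self.assignments[sample]

    def __contains__(self, sample: str) -> bool:
        return sample in self.assignments

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PopulationMap":
        """Read a two-column TSV (sample_id, population); a header row is optional."""
        assignments: dict[str, str] = {}
        with open(path) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                if row[0] == "sample_id":
                    continue
                sid, pop = row[0].strip(), row[1].strip()
                if sid in assignments:
                    raise PopmapError(f"duplicate sample id {sid!r}")
                assignments[sid] = pop
        return cls(assignments)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tpopulation\n")
            for sid, pop in self.assignments.items():
                fh.write(f"{sid}\t{pop}\n")


@dataclass
class LocusAlignment:
    """Aligned sequences for one locus with population labels.

    ``coordinate_offset`` is the 1-based chromosome position of alignment
    column 1, so reported site positions are ``offset + column_index``.
    """

    locus_id: str
    samples: list[str]
    populations: dict[str, str]
    sequences: list[str]
    coordinate_offset: int = 1

    def __post_init__(self) -> None:
        if not self.samples:
            raise AlignmentError("alignment has no sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        if self.length < 1:
            raise AlignmentError("alignment length must be >= 1")
        for sample in self.samples:
            if sample not in self.populations:
                raise PopmapError(f"sample {sample!r} has no population label")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n(self) -> int:
        return len(self.samples)

    def population_of(self, sample: str) -> str:
        return self.populations[sample]

    def subset(self, populations: Iterable[str] | None = None,
               samples: Iterable[str] | None = None) -> "LocusAlignment":
        """Restrict to the given populations (or explicit sample list), keeping order."""
        if samples is not None:
            keep = [s for s in self.samples if s in set(samples)]
        else:
            pops = set(populations or [])
            keep = [s for s in self.samples if self.populations[s] in pops]
        if not keep:
            raise InsufficientSampleError("no samples left after subsetting")
        idx = {s: i for i, s in enumerate(self.samples)}
        return LocusAlignment(
            locus_id=self.locus_id,
            samples=keep,
            populations={s: self.populations[s] for s in keep},
            sequences=[self.sequences[idx[s]] for s in keep],
            coordinate_offset=self.coordinate_offset,
        )

    def slice_columns(self, start: int, stop: int) -> "LocusAlignment":
        """Columns ``start:stop`` (0-based half-open, as for Python slices)."""
        return LocusAlignment(
            locus_id=self.locus_id,
            samples=list(self.samples),
            populations=dict(self.populations),
            sequences=[s[start:stop] for s in self.sequences],
            coordinate_offset=self.coordinate_offset + start,
        )

    def to_array(self) -> np.ndarray:
        """(n_samples, L) array of single characters."""
        return np.array([list(s) for s in self.sequences], dtype="U1")


@dataclass
class GenotypeMatrix:
    """Biallelic genotypes, samples x sites, coded 0/1 with -1 for missing."""

    samples: list[str]
    site_ids: list[str]
    genotypes: np.ndarray  # int8, shape (n_samples, n_sites)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.site_ids)):
            raise ValueError("genotype matrix shape does not match labels")
        if self.genotypes.shape[1] and np.any((self.genotypes == -1).all(axis=1)):
            raise ValueError("all-missing sample in genotype matrix")

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\t" + "\t".join(self.site_ids) + "\n")
            for i, s in enumerate(self.samples):
                row = ["." if g == -1 else str(int(g)) for g in self.genotypes[i]]
                fh.write(s + "\t" + "\t".join(row) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            site_ids = header[1:]
            samples, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                samples.append(parts[0])
                rows.append([-1 if v == "." else int(v) for v in parts[1:]])
        return cls(samples, site_ids, np.array(rows, dtype=np.int8))


def _normalize(seq: str) -> str:
    """Upper-case; anything outside {A,C,G,T,-} becomes N."""
    out = []
    for ch in seq.upper():
        out.append(ch if ch in VALID_CHARS else "N")
    return "".join(out)


def read_fasta_alignment(path: str | Path, popmap: PopulationMap,
                         locus_id: str | None = None,
                         coordinate_offset: int = 1) -> LocusAlignment:
    """Read an aligned FASTA into a :class:`LocusAlignment`.

    Every record id must appear in ``popmap``; records must be equal length.
    Bases are upper-cased and unknown characters mapped to N.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    samples, sequences = [], []
    for rec in records:
        if rec.id not in popmap:
            raise PopmapError(f"sample {rec.id!r} not in population map")
        samples.append(rec.id)
        sequences.append(_normalize(str(rec.seq)))
    if len({len(s) for s in sequences}) != 1:
        raise AlignmentError(f"unequal sequence lengths in {path}")
    return LocusAlignment(
        locus_id=locus_id or Path(path).stem,
        samples=samples,
        populations={s: popmap[s] for s in samples},
        sequences=sequences,
        coordinate_offset=coordinate_offset,
    )


def write_fasta_alignment(aln: LocusAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, seq in zip(aln.samples, aln.sequences):
            fh.write(f">{sample}\n{seq}\n")


# Column order for LocusStats TSV reports; floats printed at 6 decimals.
STATS_COLUMNS = ["locus_id", "population", "n", "L_eff", "S",
                 "pi", "theta_w", "tajima_d", "hap_count", "hap_div"]


def write_tsv_report(stats: Sequence, path: str | Path) -> None:
    """One row per (locus, population) with the fixed STATS_COLUMNS header.

    ``stats`` holds :class:`domestiscan.diversity.LocusStats`; an empty list
    writes a header-only file.  Undefined Tajima's D is written as ``NA``.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(STATS_COLUMNS) + "\n")
        for st in stats:
            vals = []
            for col in STATS_COLUMNS:
                v = getattr(st, col)
                if v is None:
                    vals.append("NA")
                elif isinstance(v, float):
                    vals.append(f"{v:.6f}")
                else:
                    vals.append(str(v))
            fh.write("\t".join(vals) + "\n")


def read_tsv_report(path: str | Path) -> list[dict]:
    """Parse a report written by :func:`write_tsv_report` back to dicts."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            for k in ("n", "L_eff", "S", "hap_count"):
                row[k] = int(row[k])
            for k in ("pi", "theta_w", "hap_div", "tajima_d"):
                row[k] = None if row[k] == "NA" else float(row[k])
            out.append(row)
    return out
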