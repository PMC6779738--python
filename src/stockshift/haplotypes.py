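"""Haplotype panels, per-individual observation tables and partition counts.

The analysis works on mtDNA control-region haplotypes treated as atomic,
named alleles (the Atlantic green turtle ``CM-A*`` nomenclature). A
:class:`HaplotypePanel` defines the allele universe as a set of named,
equal-length nucleotide sequences; sequencing output that has already been
trimmed to the panel length is collapsed onto the panel by exact string
matching. Per-individual capture records (ID, calendar year, straight
carapace length, haplotype) support recapture bookkeeping — a recaptured
individual counts once per capture year — and partitioning into the
year-set x size-class samples the downstream statistics consume.

File formats: FASTA for panels/sequences (via Bio.SeqIO), CSV for
observation tables (``id,year,scl_cm,haplotype``) and count tables
(``haplotype,count``). UTF-8, comma delimiter, ``.`` decimal; lines starting
with ``#`` are treated as comments.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError, EmptyPartitionError

logger = logging.getLogger(__name__)

#: IUPAC nucleotide one-letter codes (plus gap) accepted in panel sequences.
IUPAC_NUCLEOTIDES = frozenset("ACGTURYSWKMBDHVN-")

#: Unambiguous bases; only positions where both sequences are unambiguous
#: enter pairwise-difference counts (see :mod:`stockshift.popgen`).
UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class HaplotypePanel:
    """Named, equal-length haplotype sequences defining the allele universe.

    Parameters
    ----------
    entries
        Mapping from haplotype name to nucleotide sequence. Sequences are
        stored upper-case. All sequences must have the same length, use
        IUPAC nucleotide codes, and be unique (a duplicate sequence would
        make exact-match collapsing ambiguous).
    """

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        normalized = {str(k): str(v).upper() for k, v in self.entries.items()}
        if not normalized:
            raise DataError("haplotype panel is empty")
        lengths = {len(s) for s in normalized.values()}
        if len(lengths) != 1:
            raise DataError(f"panel sequences have unequal lengths: {sorted(lengths)}")
        for name, seq in normalized.items():
            bad = set(seq) - IUPAC_NUCLEOTIDES
            if bad:
                raise DataError(
                    f"panel haplotype {name!r} contains non-IUPAC characters: {sorted(bad)}"
                )
        seen: dict[str, str] = {}
        for name, seq in normalized.items():
            if seq in seen:
                raise DataError(
                    f"ambiguous panel: haplotypes {seen[seq]!r} and {name!r} share a sequence"
                )
            seen[seq] = name
        object.__setattr__(self, "entries", normalized)

    @property
    def length(self) -> int:
        """Common sequence length (474 bp for the control-region panels used here)."""
        return len(next(iter(self.entries.values())))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def __contains__(self, name: object) -> bool:
        return name in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "HaplotypePanel":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self.entries.items()
        ]
        SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class ObservationRecord:
    """One capture event: individual, calendar year, size, haplotype."""

    individual_id: str
    year: int
    scl_cm: float
    haplotype: str

    def __post_init__(self) -> None:
        if self.scl_cm <= 0:
            raise DataError(
                f"record {self.individual_id!r}/{self.year}: SCL must be positive, "
                f"got {self.scl_cm}"
            )


@dataclass(frozen=True)
class ObservationTable:
    """Per-individual capture records with recapture structure.

    The same individual may appear in several years (a recapture) but at
    most once per year. ``year_range`` bounds plausible calendar years;
    records outside it are rejected at construction.
    """

    records: tuple[ObservationRecord, ...]
    year_range: tuple[int, int] = (1990, 2100)
    panel: HaplotypePanel | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        records = tuple(self.records)
        lo, hi = self.year_range
        seen: set[tuple[str, int]] = set()
        for rec in records:
            if not lo <= rec.year <= hi:
                raise DataError(
                    f"record {rec.individual_id!r}: year {rec.year} outside [{lo}, {hi}]"
                )
            key = (rec.individual_id, rec.year)
            if key in seen:
                raise DataError(
                    f"individual {rec.individual_id!r} appears twice in year {rec.year}"
                )
            seen.add(key)
            if self.panel is not None and rec.haplotype not in self.panel:
                raise DataError(
                    f"record {rec.individual_id!r}/{rec.year}: haplotype "
                    f"{rec.haplotype!r} not in panel"
                )
        object.__setattr__(self, "records", records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def individuals(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(r.individual_id for r in self.records))

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        year_range: tuple[int, int] = (1990, 2100),
        panel: HaplotypePanel | None = None,
    ) -> "ObservationTable":
        df = pd.read_csv(path, comment="#")
        required = {"id", "year", "scl_cm", "haplotype"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"{path}: missing columns {sorted(missing)}")
        records = tuple(
            ObservationRecord(str(row.id), int(row.year), float(row.scl_cm), str(row.haplotype))
            for row in df.itertuples()
        )
        return cls(records, year_range=year_range, panel=panel)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [(r.individual_id, r.year, r.scl_cm, r.haplotype) for r in self.records],
            columns=["id", "year", "scl_cm", "haplotype"],
        )
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class HaplotypeCounts:
    """Haplotype counts for one named sample partition."""

    label: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        cleaned: dict[str, int] = {}
        for name, c in self.counts.items():
            c_int = int(c)
            if c_int != c or c_int < 0:
                raise DataError(f"partition {self.label!r}: count for {name!r} is {c}")
            if c_int > 0:
                cleaned[str(name)] = c_int
        object.__setattr__(self, "counts", cleaned)

    @property
    def n(self) -> int:
        """Total sample size (sum of counts)."""
        return sum(self.counts.values())

    @property
    def haplotypes(self) -> tuple[str, ...]:
        return tuple(self.counts)

    @classmethod
    def from_csv(cls, path: str | Path, label: str | None = None) -> "HaplotypeCounts":
        df = pd.read_csv(path, comment="#")
        if not {"haplotype", "count"} <= set(df.columns):
            raise DataError(f"{path}: expected columns haplotype,count")
        counts = dict(zip(df["haplotype"].astype(str), df["count"].astype(int)))
        return cls(label or Path(path).stem, counts)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.counts.items()), columns=["haplotype", "count"]
        ).to_csv(path, index=False)


def collapse_to_haplotypes(
    sequences: Mapping[str, str], panel: HaplotypePanel, label: str = "collapsed"
) -> tuple[HaplotypeCounts, list[str]]:
    """Assign trimmed sequences to panel haplotypes by exact matching.

    Each input sequence is matched character-for-character (case-insensitive)
    against the panel; matches are tallied, non-matching sequences are
    returned by name in ``unmatched`` and never silently dropped. Fuzzy or
    nearest-haplotype assignment is deliberately not offered: sequences are
    expected to arrive already assembled, aligned and trimmed to the panel
    length.

    Returns
    -------
    (counts, unmatched)
        Haplotype counts over matched sequences and the names of sequences
        that matched no panel entry.
    """
    seq_to_name = {seq: name for name, seq in panel.entries.items()}
    tally: Counter[str] = Counter()
    unmatched: list[str] = []
    for name, seq in sequences.items():
        s = str(seq).upper()
        if len(s) != panel.length:
            raise DataError(
                f"sequence {name!r} has length {len(s)}, panel length is {panel.length}"
            )
        hit = seq_to_name.get(s)
        if hit is None:
            unmatched.append(str(name))
        else:
            tally[hit] += 1
    if unmatched:
        logger.info("collapse: %d sequence(s) matched no panel haplotype", len(unmatched))
    return HaplotypeCounts(label, dict(tally)), unmatched


def expand_recaptures(observations: ObservationTable) -> ObservationTable:
    """Normalize a table to one record per (individual, year) capture event.

    Recaptured individuals are treated as additional observations: an
    individual captured in 2007, 2010 and 2015 contributes three records,
    one per capture year, all carrying its single mtDNA haplotype. The
    genotype must be constant per individual; conflicting haplotypes for one
    ID are a hard error (mtDNA does not change between captures). The
    operation is idempotent.
    """
    by_individual: dict[str, str] = {}
    for rec in observations.records:
        prev = by_individual.setdefault(rec.individual_id, rec.haplotype)
        if prev != rec.haplotype:
            raise DataError(
                f"individual {rec.individual_id!r} has conflicting haplotypes "
                f"{prev!r} and {rec.haplotype!r}"
            )
    ordered = tuple(
        sorted(observations.records, key=lambda r: (r.individual_id, r.year))
    )
    n_recaptures = len(ordered) - len(by_individual)
    if n_recaptures:
        logger.info(
            "expand_recaptures: %d individuals, %d recapture event(s), %d records",
            len(by_individual), n_recaptures, len(ordered),
        )
    return ObservationTable(ordered, year_range=observations.year_range, panel=observations.panel)


def partition(
    observations: ObservationTable,
    years: Iterable[int],
    max_scl: float | None = None,
    label: str | None = None,
) -> HaplotypeCounts:
    """Tally haplotypes over records in a year set, optionally below a size cutoff.

    The size filter is strictly ``scl < max_scl`` (a 50.0 cm animal is
    excluded by a 50.0 cm cutoff, matching the "<50.0 cm" recent-recruit
    convention); the year filter is set membership, so paired years like
    {2006, 2007} pool naturally.

    Raises
    ------
    EmptyPartitionError
        If no record satisfies the filters — downstream statistics must not
        run on an empty sample.
    """
    year_set = set(int(y) for y in years)
    if not year_set:
        raise DataError("partition: empty year set")
    tally: Counter[str] = Counter()
    dropped = 0
    for rec in observations.records:
        if rec.year not in year_set:
            dropped += 1
            continue
        if max_scl is not None and not rec.scl_cm < max_scl:
            dropped += 1
            continue
        tally[rec.haplotype] += 1
    if label is None:
        yrs = sorted(year_set)
        label = f"{yrs[0]}-{yrs[-1]}" if len(yrs) > 1 else str(yrs[0])
        if max_scl is not None:
            label += f"_lt{max_scl:g}cm"
    if not tally:
        raise EmptyPartitionError(f"partition {label!r} selected no records")
    logger.debug("partition %s: kept %d records, dropped %d", label, sum(tally.values()), dropped)
    return HaplotypeCounts(label, dict(tally))
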