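"""Reference-pool and count-table I/O.

Reads the equimolar reference pool (FASTA), per-sample count tables (TSV),
and derives filtered count tables from SAM/BAM alignments against the pool.
Sequences are stored DNA-style over {A,C,G,T}; U residues on input are
canonicalized to T so that RNA references and DNA reads mix freely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO as _biopython_seqio

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: minimum sequence length accepted into a pool (terminal-feature encoding
#: needs three bases from each end)
MIN_POOL_SEQ_LEN = 6


def canonicalize_sequence(seq: str, ident: str = "<sequence>") -> str:
    """Uppercase, U→T. Raises ValueError on empty or non-ACGTU input."""
    s = str(seq).upper().replace("U", "T")
    if not s:
        raise ValueError(f"record {ident!r} has an empty sequence")
    bad = sorted(set(s) - VALID_BASES)
    if bad:
        raise ValueError(
            f"record {ident!r} contains non-ACGTU characters: {''.join(bad)}"
        )
    return s


@dataclass
class ReferencePool:
    """An ordered set of species of known (equimolar) composition.

    Parameters
    ----------
    entries
        Ordered ``(id, sequence)`` pairs. Ids must be unique and non-empty;
        sequences are canonicalized to uppercase ACGT and must be at least
        ``MIN_POOL_SEQ_LEN`` long.
    name
        Free-text label (defaults to the source file stem when read from
        FASTA).
    """

    entries: list[tuple[str, str]]
    name: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        canon = []
        for ident, seq in self.entries:
            if not ident:
                raise ValueError("pool entry with empty id")
            if ident in seen:
                raise ValueError(f"duplicate sequence id {ident!r}")
            seen.add(ident)
            s = canonicalize_sequence(seq, ident)
            if len(s) < MIN_POOL_SEQ_LEN:
                raise ValueError(
                    f"sequence {ident!r} is shorter than {MIN_POOL_SEQ_LEN} nt"
                )
            canon.append((ident, s))
        self.entries = canon
        self._index = {ident: seq for ident, seq in canon}

    @property
    def ids(self) -> list[str]:
        return [ident for ident, _ in self.entries]

    @property
    def sequences(self) -> dict[str, str]:
        return dict(self._index)

    def sequence(self, ident: str) -> str:
        return self._index[ident]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, ident: str) -> bool:
        return ident in self._index

    def __iter__(self):
        return iter(self.entries)

    def min_length(self) -> int:
        return min(len(s) for _, s in self.entries)

    def lengths(self) -> pd.Series:
        return pd.Series({i: len(s) for i, s in self.entries}, name="length")

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for ident, seq in self.entries:
                fh.write(f">{ident}\n{seq}\n")


class CountTable:
    """Species × sample matrix of non-negative counts.

    Raw counts are integers; corrected pseudo-counts may be real-valued.
    Column (sample) order is preserved.
    """

    def __init__(self, values: pd.DataFrame):
        values = values.copy()
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate species ids: {dups}")
        for col in values.columns:
            converted = pd.to_numeric(values[col], errors="coerce")
            if converted.isna().any():
                row = values.index[converted.isna()][0]
                raise ValueError(
                    f"non-numeric value at species {row!r}, sample {col!r}"
                )
            values[col] = converted.astype(float)
        if (values.to_numpy() < 0).any():
            rows, cols = np.nonzero(values.to_numpy() < 0)
            raise ValueError(
                "negative value at species "
                f"{values.index[rows[0]]!r}, sample {values.columns[cols[0]]!r}"
            )
        self.values = values

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column_sums(self) -> pd.Series:
        return self.values.sum(axis=0)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, m = self.shape
        return f"<{type(self).__name__} {n} species x {m} samples>"


def read_fasta(path) -> ReferencePool:
    """Read a reference pool from FASTA, preserving record order."""
    path = Path(path)
    entries = []
    for record in _biopython_seqio.parse(str(path), "fasta"):
        entries.append((record.id, str(record.seq)))
    if not entries:
        raise ValueError(f"no FASTA records in {path}")
    return ReferencePool(entries=entries, name=path.stem)


def read_count_table(path, pool: ReferencePool | None = None) -> CountTable:
    """Read a TSV count table (first column species id, header = samples).

    If ``pool`` is given, species absent from the pool are a hard error and
    pool species missing from the table are filled with zeros (logged).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    table = CountTable(df)
    if pool is not None:
        unknown = [s for s in table.species if s not in pool]
        if unknown:
            raise ValueError(f"species not in reference pool: {unknown}")
        missing = [s for s in pool.ids if s not in df.index]
        if missing:
            log.info("filling %d pool species absent from %s with 0",
                     len(missing), path)
            filler = pd.DataFrame(0.0, index=missing, columns=df.columns)
            df = pd.concat([df, filler]).loc[pool.ids]
            table = CountTable(df)
    return table


def write_count_table(table: CountTable, path) -> None:
    """Write a TSV that round-trips losslessly through read_count_table."""
    df = table.values.copy()
    # serialize exact integers without a trailing ".0"
    if (df.to_numpy() == np.round(df.to_numpy())).all():
        df = df.astype("int64")
    df.to_csv(path, sep="\t", index_label="id")


def counts_from_alignments(
    path,
    pool: ReferencePool,
    min_len: int = 15,
    max_len: int = 40,
    sample_name: str | None = None,
) -> CountTable:
    """Derive a one-sample count table from SAM/BAM alignments to the pool.

    A primary alignment is counted when it is mapped, unique, and its
    aligned query length (soft-clips excluded) lies within
    ``[min_len, max_len]``. Uniqueness is taken from the NH tag when
    present (NH == 1) and otherwise from MAPQ >= 5, covering both aligner
    dialects. Secondary and supplementary records are never counted.
    """
    path = Path(path)
    counts = {ident: 0 for ident in pool.ids}
    tallies = {"unmapped": 0, "secondary_supplementary": 0,
               "multimapped": 0, "length": 0, "counted": 0}
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for ref in af.references:
            if ref not in pool:
                raise ValueError(
                    f"alignment reference {ref!r} absent from pool "
                    f"{pool.name or '<unnamed>'}"
                )
        for read in af:
            if read.is_unmapped:
                tallies["unmapped"] += 1
                continue
            if read.is_secondary or read.is_supplementary:
                tallies["secondary_supplementary"] += 1
                continue
            if read.has_tag("NH"):
                unique = read.get_tag("NH") == 1
            else:
                unique = read.mapping_quality >= 5
            if not unique:
                tallies["multimapped"] += 1
                continue
            qlen = read.query_alignment_length
            if qlen < min_len or qlen > max_len:
                tallies["length"] += 1
                continue
            counts[read.reference_name] += 1
            tallies["counted"] += 1
    log.info("alignment filter tallies for %s: %s", path.name, tallies)
    if tallies["counted"] == 0:
        log.warning("no alignments passed filters in %s", path.name)
    column = sample_name or path.stem
    df = pd.DataFrame({column: pd.Series(counts, dtype=float)})
    return CountTable(df.loc[pool.ids])
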