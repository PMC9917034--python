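"""Readers and writers for substrate FASTA, peptide identification tables and
MHC class I prediction tables.

This module is the only place file dialects are handled. Peptide tables are
long-format CSV/TSV, one row per (sample, peptide-form), the shape exported by
proteomic search engines after peptide-spectrum matching; rows that share an
identical (sample, sequence, modifications) key have their intensities summed
on read. Modification strings use the ``name@k`` syntax with ``k`` 1-based
within the peptide (e.g. ``Deamidation (NQ)@3``); a dialect adapter maps
inline mass tags such as ``(+0.98)`` to the named modification.

An absent intensity column switches the downstream pipeline to count mode
(each peptide-form contributes 1).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import ConfigError, FormatError, ValidationError

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: residues on which a deamidation call is legal: the amide forms (N, Q) and
#: the acid forms (D, E) that search engines report for the deamidated peptide
_DEAMIDATABLE = frozenset("NQDE")

MOD_DEAMIDATION = "deamidation"
MOD_OXIDATION = "oxidation"
MOD_OTHER = "other"


@dataclass(frozen=True)
class SubstrateRecord:
    """The protein being digested; the coordinate frame for everything downstream."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"substrate {self.id!r}: empty sequence")
        for i, ch in enumerate(self.sequence, start=1):
            if ch not in _AA_SET:
                raise ValidationError(
                    f"substrate {self.id!r}: illegal residue {ch!r} at position {i}"
                )

    @property
    def L(self) -> int:
        return len(self.sequence)


class Modification(NamedTuple):
    """A variable modification at a 1-based position within the peptide."""

    position: int
    name: str


@dataclass(frozen=True)
class PeptideObservation:
    """One identified peptide-form in one sample.

    ``intensity`` is the ion-current area; ``None`` means the table carried no
    intensity column and the pipeline runs in count mode.
    """

    sample_id: str
    sequence: str
    modifications: tuple[Modification, ...] = ()
    intensity: float | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValidationError("peptide sequence must be non-empty")
        for mod in self.modifications:
            if not 1 <= mod.position <= len(self.sequence):
                raise ValidationError(
                    f"modification position {mod.position} outside peptide "
                    f"{self.sequence!r} (length {len(self.sequence)})"
                )
            if mod.name == MOD_DEAMIDATION:
                residue = self.sequence[mod.position - 1]
                if residue not in _DEAMIDATABLE:
                    raise ValidationError(
                        f"deamidation declared on residue {residue!r} at peptide "
                        f"position {mod.position}; expected one of N, Q, D, E"
                    )
        if self.intensity is not None and self.intensity < 0:
            raise ValidationError("intensity must be non-negative")


@dataclass(frozen=True)
class PredictionRecord:
    """One (allele, peptide) percentile-rank prediction, IEDB convention
    (lower rank = stronger predicted binding)."""

    allele: str
    peptide: str
    percentile_rank: float
    score: float | None = None

    def __post_init__(self) -> None:
        if not 0.01 <= self.percentile_rank <= 100:
            raise ValidationError(
                f"percentile rank {self.percentile_rank} outside [0.01, 100] "
                f"for {self.allele} / {self.peptide}"
            )
        if not 8 <= len(self.peptide) <= 14:
            raise ValidationError(
                f"peptide {self.peptide!r} length {len(self.peptide)} outside [8, 14]"
            )


@dataclass(frozen=True)
class TableDialect:
    """Column names and separator for a peptide-table flavour.

    The default header is ``sample,peptide,modifications,area``. ``sep=None``
    chooses tab for ``.tsv``/``.tab`` paths and comma otherwise.
    """

    sample_col: str = "sample"
    peptide_col: str = "peptide"
    mods_col: str = "modifications"
    intensity_col: str = "area"
    sep: str | None = None


DEFAULT_DIALECT = TableDialect()


@dataclass(frozen=True)
class PredictionDialect:
    allele_col: str = "allele"
    peptide_col: str = "peptide"
    rank_col: str = "percentile_rank"
    score_col: str = "score"
    sep: str | None = None

    #: IEDB-export column spellings accepted without configuration
    rank_aliases: tuple[str, ...] = ("percentile_rank", "rank", "percentile rank")


def _resolve_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


# --------------------------------------------------------------------------- FASTA


def read_fasta(path: str | Path) -> list[SubstrateRecord]:
    """Read a (multi-record) FASTA file into substrate records.

    Sequences are upper-cased and a trailing ``*`` stop is stripped.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        records.append(SubstrateRecord(id=rec.id, sequence=seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


# ------------------------------------------------------------------- peptide table

# "Deamidation (NQ)@3", "oxidation@5", "Deamidation@2"
_MOD_AT_RE = re.compile(r"^\s*(?P<name>[^@]+?)\s*@\s*(?P<pos>\d+)\s*$")
# PEAKS-style inline mass tags
_MASS_TAG_NAMES = {
    "+0.98": MOD_DEAMIDATION,
    "+.98": MOD_DEAMIDATION,
    "+15.99": MOD_OXIDATION,
    "+16.00": MOD_OXIDATION,
}


def _canonical_mod_name(raw: str) -> str:
    low = raw.strip().lower()
    if "deamid" in low:
        return MOD_DEAMIDATION
    if "oxid" in low:
        return MOD_OXIDATION
    tag = raw.strip().strip("()")
    if tag in _MASS_TAG_NAMES:
        return _MASS_TAG_NAMES[tag]
    return MOD_OTHER


def parse_modifications(mods: str, context: str = "") -> tuple[Modification, ...]:
    """Parse a ``;``-separated modification string into typed modifications.

    Unparseable entries are kept with name :data:`MOD_OTHER` at position 1 and
    logged, so no information silently disappears.
    """
    if mods is None or (isinstance(mods, float) and pd.isna(mods)) or str(mods).strip() == "":
        return ()
    out: list[Modification] = []
    for token in str(mods).split(";"):
        token = token.strip()
        if not token:
            continue
        m = _MOD_AT_RE.match(token)
        if m is None:
            logger.warning("unparseable modification %r%s; recorded as 'other'",
                           token, f" ({context})" if context else "")
            out.append(Modification(1, MOD_OTHER))
            continue
        name = _canonical_mod_name(m.group("name"))
        if name == MOD_OTHER and "other" not in m.group("name").lower():
            logger.warning("unrecognized modification name %r%s; recorded as 'other'",
                           m.group("name"), f" ({context})" if context else "")
        out.append(Modification(int(m.group("pos")), name))
    return tuple(out)


def format_modifications(mods: Sequence[Modification]) -> str:
    return ";".join(f"{m.name}@{m.position}" for m in mods)


def read_peptide_table(
    path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> list[PeptideObservation]:
    """Read a long-format peptide identification table.

    Rows with an empty peptide are dropped and logged. Duplicate
    (sample, sequence, modifications) rows have their intensities summed, with
    a logged note. A missing intensity column switches to count mode
    (``intensity=None`` on every observation).
    """
    path = Path(path)
    sep = _resolve_sep(path, dialect.sep)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, na_values=[])
    for col in (dialect.sample_col, dialect.peptide_col):
        if col not in df.columns:
            raise ConfigError(f"{path}: mandatory column {col!r} missing "
                              f"(found {list(df.columns)})")
    has_mods = dialect.mods_col in df.columns
    has_intensity = dialect.intensity_col in df.columns
    if has_intensity and (df[dialect.intensity_col].str.strip() == "").all():
        # an entirely empty intensity column is count mode, same as no column
        has_intensity = False

    merged: dict[tuple, PeptideObservation] = {}
    n_dropped = 0
    n_merged = 0
    for idx, row in df.iterrows():
        peptide = row[dialect.peptide_col].strip().upper()
        if not peptide:
            n_dropped += 1
            logger.info("DROP empty-peptide row %d of %s", idx, path)
            continue
        sample = row[dialect.sample_col]
        mods = parse_modifications(row[dialect.mods_col] if has_mods else "",
                                   context=f"{path} row {idx}")
        intensity: float | None = None
        if has_intensity:
            raw = row[dialect.intensity_col].strip()
            if raw == "" or raw.lower() == "nan":
                logger.warning("missing intensity in row %d of %s; treated as 0", idx, path)
                intensity = 0.0
            else:
                intensity = float(raw)
        key = (sample, peptide, tuple(sorted(mods)))
        if key in merged:
            n_merged += 1
            prev = merged[key]
            new_intensity = None
            if intensity is not None or prev.intensity is not None:
                new_intensity = (prev.intensity or 0.0) + (intensity or 0.0)
            merged[key] = PeptideObservation(sample, peptide, prev.modifications,
                                             new_intensity)
        else:
            merged[key] = PeptideObservation(sample, peptide, mods, intensity)
    if n_merged:
        logger.info("%s: summed intensities of %d duplicate peptide-form rows",
                    path, n_merged)
    if n_dropped:
        logger.info("%s: dropped %d empty-peptide rows", path, n_dropped)
    return list(merged.values())


def write_peptide_table(
    observations: Iterable[PeptideObservation], path: str | Path
) -> None:
    """Write observations as RFC-4180-quoted CSV with the default header."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
        writer.writerow(["sample", "peptide", "modifications", "area"])
        for obs in observations:
            writer.writerow([
                obs.sample_id,
                obs.sequence,
                format_modifications(obs.modifications),
                "" if obs.intensity is None else repr(float(obs.intensity)),
            ])


# ---------------------------------------------------------------- prediction table


def read_prediction_table(
    path: str | Path, dialect: PredictionDialect = PredictionDialect()
) -> list[PredictionRecord]:
    """Read an MHC-I prediction table (allele, peptide, percentile_rank[, score]).

    Ranks outside [0.01, 100] raise a validation error — they are never
    silently clamped.
    """
    path = Path(path)
    sep = _resolve_sep(path, dialect.sep)
    df = pd.read_csv(path, sep=sep)
    df.columns = [str(c).strip().lower() for c in df.columns]
    rank_col = dialect.rank_col
    if rank_col not in df.columns:
        for alias in dialect.rank_aliases:
            if alias in df.columns:
                rank_col = alias
                break
    for col in (dialect.allele_col, dialect.peptide_col, rank_col):
        if col not in df.columns:
            raise ConfigError(f"{path}: mandatory column {col!r} missing "
                              f"(found {list(df.columns)})")
    records = []
    for _, row in df.iterrows():
        score = None
        if dialect.score_col in df.columns and pd.notna(row[dialect.score_col]):
            score = float(row[dialect.score_col])
        records.append(PredictionRecord(
            allele=str(row[dialect.allele_col]).strip(),
            peptide=str(row[dialect.peptide_col]).strip().upper(),
            percentile_rank=float(row[rank_col]),
            score=score,
        ))
    return records


def write_prediction_table(
    records: Iterable[PredictionRecord], path: str | Path
) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
        writer.writerow(["allele", "peptide", "percentile_rank", "score"])
        for rec in records:
            writer.writerow([rec.allele, rec.peptide, rec.percentile_rank,
                             "" if rec.score is None else rec.score])
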