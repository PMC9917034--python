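"""Anchor observed peptides onto the substrate sequence.

Deamidation (Q→E, N→D) changes the residue letter the search engine reports,
so mapping must revert it to find the germline position. Oxidation is
mass-only and never affects matching. Coordinates are 1-based inclusive
[start, end]; peptide bond *i* is the bond between residues *i* and *i+1*, so
the bond index equals the P1 position of protease nomenclature.

A peptide that matches nowhere is an "irrelevant" peptide (not derived from
the substrate) and lands in the unmapped report; a peptide matching more than
one location is flagged ambiguous and handled by the table-level policy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import pandas as pd

from .errors import ConfigError
from .io_tables import (
    MOD_DEAMIDATION,
    PeptideObservation,
    SubstrateRecord,
)

logger = logging.getLogger(__name__)

#: deamidated letter -> germline letter
_REVERT = {"E": "Q", "D": "N"}

DeamidationMode = Literal["declared-only", "infer-all"]
AmbiguityPolicy = Literal["distribute", "first", "drop-ambiguous"]


@dataclass(frozen=True)
class LocatedPeptide:
    """An observed peptide anchored to substrate coordinates.

    ``deamidation_sites`` are the substrate positions where the observed
    residue is the deamidated form of the substrate residue.
    ``count_weight`` is the share of one peptide-species this copy represents
    (1 for a unique match, 1/m after distributing an m-fold ambiguous match);
    it is the per-peptide weight used in count mode.
    """

    substrate_id: str
    start: int
    end: int
    observed_sequence: str
    germline_sequence: str
    deamidation_sites: tuple[int, ...] = ()
    intensity: float | None = None
    sample_id: str = ""
    ambiguous: bool = False
    count_weight: float = 1.0
    relative_abundance: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def form_key(self) -> tuple:
        """Peptide-form identity: coordinates plus deamidation state."""
        return (self.substrate_id, self.start, self.end, self.deamidation_sites)


def _revertible_positions(
    obs: PeptideObservation, mode: DeamidationMode
) -> frozenset[int]:
    """0-based peptide positions where an E/D may be reverted to Q/N."""
    if mode == "infer-all":
        return frozenset(
            i for i, ch in enumerate(obs.sequence) if ch in _REVERT
        )
    if mode == "declared-only":
        return frozenset(
            m.position - 1
            for m in obs.modifications
            if m.name == MOD_DEAMIDATION and obs.sequence[m.position - 1] in _REVERT
        )
    raise ConfigError(f"unknown deamidation mode {mode!r}")


def locate_peptide(
    obs: PeptideObservation,
    substrate: SubstrateRecord,
    deamidation_mode: DeamidationMode = "declared-only",
) -> list[LocatedPeptide]:
    """Return every substrate location the peptide matches.

    A position matches when each residue equals the substrate residue, or is
    an E/D at a revertible position whose germline form (Q/N) equals the
    substrate residue. An empty list means the peptide is not a product of
    this substrate.
    """
    pep = obs.sequence
    seq = substrate.sequence
    n, L = len(pep), substrate.L
    revertible = _revertible_positions(obs, deamidation_mode)

    hits: list[LocatedPeptide] = []
    for s in range(L - n + 1):
        sites: list[int] = []
        for k in range(n):
            target = seq[s + k]
            if pep[k] == target:
                continue
            if k in revertible and _REVERT.get(pep[k]) == target:
                sites.append(s + k + 1)  # substrate position, 1-based
                continue
            break
        else:
            hits.append(LocatedPeptide(
                substrate_id=substrate.id,
                start=s + 1,
                end=s + n,
                observed_sequence=pep,
                germline_sequence=seq[s:s + n],
                deamidation_sites=tuple(sites),
                intensity=obs.intensity,
                sample_id=obs.sample_id,
            ))
    if len(hits) > 1:
        hits = [replace(h, ambiguous=True) for h in hits]
    return hits


def map_table(
    observations: Iterable[PeptideObservation],
    substrate: SubstrateRecord,
    policy: AmbiguityPolicy = "distribute",
    deamidation_mode: DeamidationMode = "declared-only",
) -> tuple[list[LocatedPeptide], pd.DataFrame]:
    """Map a whole observation table; returns located peptides and the
    unmapped report (columns: sample, peptide, intensity, reason).

    Ambiguity policies: ``distribute`` splits intensity (and count weight)
    equally across matches, ``first`` keeps the left-most match, and
    ``drop-ambiguous`` sends the observation to the unmapped report.
    """
    if policy not in ("distribute", "first", "drop-ambiguous"):
        raise ConfigError(f"unknown ambiguity policy {policy!r}")

    located: list[LocatedPeptide] = []
    unmapped: list[dict] = []
    for obs in observations:
        hits = locate_peptide(obs, substrate, deamidation_mode)
        if not hits:
            logger.info("UNMAPPED no-match sample=%s peptide=%s", obs.sample_id,
                        obs.sequence)
            unmapped.append({"sample": obs.sample_id, "peptide": obs.sequence,
                             "intensity": obs.intensity, "reason": "no-match"})
            continue
        if len(hits) == 1:
            located.append(hits[0])
            continue
        if policy == "drop-ambiguous":
            logger.info("UNMAPPED ambiguous sample=%s peptide=%s matches=%d",
                        obs.sample_id, obs.sequence, len(hits))
            unmapped.append({"sample": obs.sample_id, "peptide": obs.sequence,
                             "intensity": obs.intensity, "reason": "ambiguous"})
        elif policy == "first":
            located.append(hits[0])
        else:  # distribute
            m = len(hits)
            for h in hits:
                located.append(replace(
                    h,
                    intensity=None if h.intensity is None else h.intensity / m,
                    count_weight=h.count_weight / m,
                ))
    report = pd.DataFrame(unmapped, columns=["sample", "peptide", "intensity",
                                             "reason"])
    return located, report


def write_unmapped_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False)
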