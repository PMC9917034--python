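"""Per-sample degradome summaries.

* TIC normalization: each peptide's abundance as a percentage of the summed
  ion current of all substrate-derived peptides in its sample.
* Cleavage profile: hydrolysis-event weights per peptide bond. A located
  peptide contributes an event at bond ``start-1`` (its N-terminal cut) and at
  bond ``end`` (its C-terminal cut); substrate termini are not hydrolysis
  events, so a peptide starting at 1 or ending at L contributes nothing on
  that side.
* Terminal matrix: 20x20 counts of (first residue, last residue) combinations.
* Activity signature: the fraction of hydrolysis events whose P1 residue falls
  in the chymotryptic-like, tryptic-like, caspase-like or remaining class,
  with an availability correction dividing each fraction by the share of
  substrate bonds in that class.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, StateError
from .io_tables import AMINO_ACIDS, SubstrateRecord
from .mapping import LocatedPeptide

Weighting = Literal["count", "tic"]

#: default P1 residue classes, matching the LLVY / LRR / LLE fluorogenic
#: substrate specificities of the three proteasome catalytic activities
P1_CLASSES: dict[str, frozenset[str]] = {
    "chymotryptic": frozenset("FYWLM"),
    "tryptic": frozenset("KR"),
    "caspase": frozenset("DE"),
}
CLASS_ORDER = ("chymotryptic", "tryptic", "caspase", "other")


def classify_p1(residue: str, classes: Mapping[str, frozenset[str]] = P1_CLASSES) -> str:
    for name, members in classes.items():
        if residue in members:
            return name
    return "other"


# ------------------------------------------------------------------ normalization


def tic_normalize(located: Sequence[LocatedPeptide]) -> list[LocatedPeptide]:
    """Attach ``relative_abundance`` (percent of sample TIC) to each peptide.

    Grouping is per (sample_id, substrate_id). In count mode (no intensities)
    each peptide-form contributes its count weight instead of an ion current.
    """
    totals: dict[tuple[str, str], float] = {}
    for lp in located:
        value = lp.intensity if lp.intensity is not None else lp.count_weight
        key = (lp.sample_id, lp.substrate_id)
        totals[key] = totals.get(key, 0.0) + value
    out = []
    for lp in located:
        value = lp.intensity if lp.intensity is not None else lp.count_weight
        total = totals[(lp.sample_id, lp.substrate_id)]
        rel = 100.0 * value / total if total > 0 else 0.0
        out.append(replace(lp, relative_abundance=rel))
    return out


# --------------------------------------------------------------- cleavage profile


@dataclass(frozen=True)
class CleavageProfile:
    """Hydrolysis-event weights over bonds 1..L-1 of one substrate."""

    substrate_id: str
    counts: np.ndarray  # index i-1 holds bond i
    weighting: Weighting

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        """Counts normalized to the total number of hydrolysis events;
        all-zero when there are no events."""
        total = self.total
        if total == 0:
            return np.zeros_like(self.counts)
        return self.counts / total

    def to_frame(self, substrate: SubstrateRecord) -> pd.DataFrame:
        bonds = np.arange(1, len(self.counts) + 1)
        return pd.DataFrame({
            "bond_position": bonds,
            "P1_residue": [substrate.sequence[i - 1] for i in bonds],
            "count": self.counts,
            "frequency": self.frequencies,
        })


def cleavage_profile(
    located: Sequence[LocatedPeptide],
    substrate: SubstrateRecord,
    weighting: Weighting = "count",
) -> CleavageProfile:
    """Count hydrolysis events per bond, weighted per peptide-species (count)
    or by TIC-relative abundance (tic)."""
    if weighting not in ("count", "tic"):
        raise ConfigError(f"unknown weighting {weighting!r}")
    counts = np.zeros(substrate.L - 1, dtype=float)
    for lp in located:
        if lp.substrate_id != substrate.id:
            raise ConfigError(
                f"peptide mapped to {lp.substrate_id!r}, profile is for {substrate.id!r}"
            )
        if weighting == "tic":
            if lp.relative_abundance is None:
                raise StateError("tic weighting requires tic_normalize first")
            w = lp.relative_abundance
        else:
            w = lp.count_weight
        if lp.start > 1:
            counts[lp.start - 2] += w
        if lp.end < substrate.L:
            counts[lp.end - 1] += w
    return CleavageProfile(substrate.id, counts, weighting)


# ---------------------------------------------------------------- terminal matrix


@dataclass(frozen=True)
class TerminalMatrix:
    """20x20 matrix of peptide counts indexed by (first residue, last residue)."""

    counts: np.ndarray
    alphabet: str = AMINO_ACIDS

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def normalized(self) -> np.ndarray:
        total = self.total
        if total == 0:
            return np.zeros_like(self.counts)
        return self.counts / total

    def to_frame(self, normalized: bool = False) -> pd.DataFrame:
        data = self.normalized if normalized else self.counts
        idx = list(self.alphabet)
        return pd.DataFrame(data, index=idx, columns=idx)


def terminal_matrix(located: Sequence[LocatedPeptide]) -> TerminalMatrix:
    """One increment per located peptide at (observed first, observed last)."""
    index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    counts = np.zeros((20, 20), dtype=float)
    for lp in located:
        counts[index[lp.observed_sequence[0]], index[lp.observed_sequence[-1]]] += \
            lp.count_weight
    return TerminalMatrix(counts)


# ------------------------------------------------------------- candidate filtering


def filter_mhc1_candidates(
    located: Sequence[LocatedPeptide],
    length_range: tuple[int, int] = (9, 10),
) -> list[LocatedPeptide]:
    """Retain peptides whose length falls in the closed MHC-I ligand range."""
    lo, hi = length_range
    if lo > hi:
        raise ConfigError(f"inverted length range {length_range}")
    return [lp for lp in located if lo <= lp.length <= hi]


# -------------------------------------------------------------- activity signature


@dataclass(frozen=True)
class ActivitySignature:
    """Catalytic-phenotype summary of a cleavage profile.

    ``event_fractions``: share of hydrolysis events per P1 class.
    ``availability``: share of substrate bonds per P1 class.
    ``weights``: availability-corrected event fractions, renormalized to 1 —
    the substrate-composition-independent activity estimate.
    """

    event_fractions: dict[str, float]
    availability: dict[str, float]
    weights: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "event_fractions": self.event_fractions,
            "availability": self.availability,
            "weights": self.weights,
        }


def bond_class_availability(
    substrate: SubstrateRecord,
    classes: Mapping[str, frozenset[str]] = P1_CLASSES,
) -> dict[str, float]:
    """Fraction of the substrate's L-1 bonds whose P1 residue is in each class."""
    n_bonds = substrate.L - 1
    counts = {name: 0 for name in (*classes, "other")}
    for i in range(1, substrate.L):  # bond i has P1 residue i
        counts[classify_p1(substrate.sequence[i - 1], classes)] += 1
    return {name: c / n_bonds for name, c in counts.items()}


def activity_signature(
    profile: CleavageProfile,
    substrate: SubstrateRecord,
    classes: Mapping[str, frozenset[str]] = P1_CLASSES,
) -> ActivitySignature:
    """Summarize a cleavage profile into P1-class event fractions and
    availability-corrected weights."""
    if profile.total == 0:
        raise StateError("activity signature undefined for a profile with no events")
    class_names = (*classes, "other")
    event = {name: 0.0 for name in class_names}
    for i, w in enumerate(profile.counts, start=1):
        if w:
            event[classify_p1(substrate.sequence[i - 1], classes)] += float(w)
    total = sum(event.values())
    fractions = {name: v / total for name, v in event.items()}
    availability = bond_class_availability(substrate, classes)
    raw = {
        name: (fractions[name] / availability[name]) if availability[name] > 0 else 0.0
        for name in class_names
    }
    norm = sum(raw.values())
    weights = {name: v / norm for name, v in raw.items()}
    return ActivitySignature(fractions, availability, weights)
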