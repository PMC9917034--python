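"""HLA class I annotation of ligand candidates.

Candidates are joined with percentile-rank predictions over an allele panel
(default: 27 class I alleles, shipped as editable YAML). Ranks follow the
IEDB convention — lower is stronger — and binding strength is classified on
configurable thresholds (high <= 0.5, moderate <= 2, low <= 10, else non).

Because trained neural-network MHC predictors are out of scope, the module
also provides a self-contained position-specific scoring matrix (PSSM) scorer
with empirical percentile calibration against seeded random background
peptides. It is a deterministic test double for an external predictor —
outputs produced with it are labelled ``pssm-internal`` — and real analyses
should ingest an external prediction table instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, StateError, ValidationError
from .io_tables import AMINO_ACIDS, PredictionRecord
from .mapping import LocatedPeptide

logger = logging.getLogger(__name__)

LABELS = ("MS-associated", "MS-protective", "unlabeled")
DEFAULT_THRESHOLDS = (0.5, 2.0, 10.0)
BINDER_CLASSES = ("high", "moderate", "low", "non")
RANK_FLOOR = 0.01


# ------------------------------------------------------------------- allele panel


@dataclass(frozen=True)
class AllelePanel:
    alleles: tuple[str, ...]
    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(set(self.alleles)) != len(self.alleles):
            raise ValidationError("allele names must be unique")
        for allele, label in self.labels.items():
            if label not in LABELS:
                raise ValidationError(f"unknown label {label!r} for {allele}")

    def label(self, allele: str) -> str:
        return self.labels.get(allele, "unlabeled")

    def __len__(self) -> int:
        return len(self.alleles)


def load_panel(path: str | Path) -> AllelePanel:
    """Load an allele panel from YAML (``alleles: [{allele, label}, ...]``)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    entries = raw["alleles"]
    alleles = tuple(e["allele"] for e in entries)
    labels = {e["allele"]: e.get("label", "unlabeled") for e in entries}
    return AllelePanel(alleles, labels)


def default_panel() -> AllelePanel:
    """The shipped 27-allele class I panel."""
    ref = resources.files("degradomics.data") / "default_panel.yaml"
    with resources.as_file(ref) as path:
        return load_panel(path)


# -------------------------------------------------------------------- PSSM scorer


@dataclass
class PssmModel:
    """Position-specific scoring matrix with empirical rank calibration.

    ``weights`` is (motif_length, 20) of per-position log-odds; the percentile
    of a score is computed against ``calibration`` — the sorted scores of M
    seeded random background peptides.
    """

    length: int
    weights: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(20, 1.0 / 20)
    )
    calibration: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.length, 20):
            raise ValidationError(
                f"weights shape {self.weights.shape} != ({self.length}, 20)"
            )
        if not np.isfinite(self.weights).all():
            raise ValidationError("PSSM weights must be finite")
        if self.calibration is not None:
            self.calibration = np.sort(np.asarray(self.calibration, dtype=float))
            if self.calibration.size < 1000:
                raise ValidationError("calibration needs at least 1000 background scores")


_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def pssm_score(peptide: str, model: PssmModel) -> float:
    """Sum of per-position weights for the peptide's residues."""
    if len(peptide) != model.length:
        raise ValidationError(
            f"peptide length {len(peptide)} != motif length {model.length}"
        )
    try:
        idx = [_AA_INDEX[ch] for ch in peptide]
    except KeyError as exc:
        raise ValidationError(f"illegal residue {exc.args[0]!r} in {peptide!r}") from exc
    return float(model.weights[np.arange(model.length), idx].sum())


def calibrate(model: PssmModel, m: int = 10_000, rng: np.random.Generator | None = None,
              seed: int | None = None) -> PssmModel:
    """Attach an empirical calibration of ``m`` random background peptides."""
    if m < 1000:
        raise ValidationError("calibration needs at least 1000 background scores")
    if rng is None:
        rng = np.random.default_rng(seed)
    draws = rng.choice(20, size=(m, model.length), p=model.background)
    scores = model.weights[np.arange(model.length)[None, :], draws].sum(axis=1)
    model.calibration = np.sort(scores)
    return model


def build_random_model(
    length: int, seed: int | np.random.SeedSequence, m: int = 10_000
) -> PssmModel:
    """A seeded random PSSM (weights ~ N(0,1), uniform background), calibrated."""
    rng = np.random.default_rng(seed)
    model = PssmModel(length=length, weights=rng.normal(size=(length, 20)))
    return calibrate(model, m=m, rng=rng)


def build_panel_models(
    panel: AllelePanel, lengths: Sequence[int] = (9, 10), seed: int = 0,
    m: int = 10_000,
) -> dict[tuple[str, int], PssmModel]:
    """One seeded PSSM per (allele, motif length); child seeds are spawned
    deterministically from the single top-level seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(panel.alleles) * len(lengths))
    models = {}
    k = 0
    for allele in panel.alleles:
        for length in lengths:
            models[(allele, length)] = build_random_model(length, children[k], m=m)
            k += 1
    return models


def percentile_rank(score: float, model: PssmModel) -> float:
    """Empirical percentile rank of a score in [0.01, 100]; lower = stronger.

    rank = max(0.01, 100 * (#background strictly greater + 0.5 * ties) / M).
    """
    if model.calibration is None:
        raise StateError("model is not calibrated; call calibrate() first")
    cal = model.calibration
    m = cal.size
    right = np.searchsorted(cal, score, side="right")
    left = np.searchsorted(cal, score, side="left")
    greater = m - right
    ties = right - left
    return max(RANK_FLOOR, 100.0 * (greater + 0.5 * ties) / m)


# ------------------------------------------------------------------ classification


def classify_binder(
    rank: float, thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
) -> str:
    """Map a percentile rank to high/moderate/low/non on increasing thresholds."""
    if not (0 < thresholds[0] < thresholds[1] < thresholds[2]):
        raise ConfigError(f"thresholds must be strictly increasing: {thresholds}")
    if not RANK_FLOOR <= rank <= 100:
        raise ValidationError(f"rank {rank} outside [{RANK_FLOOR}, 100]")
    for cls, cut in zip(BINDER_CLASSES, thresholds):
        if rank <= cut:
            return cls
    return "non"


# --------------------------------------------------------------------- annotation


@dataclass(frozen=True)
class AnnotatedCandidate:
    """One (peptide-form, allele) annotation row."""

    peptide: LocatedPeptide
    allele: str
    percentile_rank: float | None  # None = missing prediction
    binder_class: str  # "high"/"moderate"/"low"/"non" or "missing"
    label: str
    source: str  # "external" or "pssm-internal"


def _display_name(lp: LocatedPeptide) -> str:
    tag = "+deam" if lp.deamidation_sites else ""
    return f"{lp.observed_sequence}{tag}"


def annotate_candidates(
    candidates: Sequence[LocatedPeptide],
    panel: AllelePanel,
    predictions: Sequence[PredictionRecord] | None = None,
    models: Mapping[tuple[str, int], PssmModel] | None = None,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
) -> tuple[list[AnnotatedCandidate], pd.DataFrame]:
    """Cross-join candidates with the allele panel.

    Ranks come from an external prediction table when given, otherwise from
    the internal PSSM models. A (peptide, allele) pair with no prediction is
    annotated ``missing`` — never fabricated. Deamidated forms are annotated
    as distinct peptides (the observed, deamidated sequence is what a
    predictor sees).

    Returns the annotation records and the peptide x allele rank matrix
    (cells: percentile rank or "missing").
    """
    if predictions is None and models is None:
        raise ConfigError("provide either a prediction table or internal models")
    lookup: dict[tuple[str, str], float] = {}
    if predictions is not None:
        for rec in predictions:
            lookup[(rec.allele, rec.peptide)] = rec.percentile_rank
    source = "external" if predictions is not None else "pssm-internal"

    warned: set = set()
    records: list[AnnotatedCandidate] = []
    # deduplicate identical peptide-forms for the matrix while annotating all
    for lp in candidates:
        pep = lp.observed_sequence
        for allele in panel.alleles:
            rank: float | None = None
            if predictions is not None:
                rank = lookup.get((allele, pep))
            elif models is not None:
                model = models.get((allele, len(pep)))
                if model is not None:
                    rank = percentile_rank(pssm_score(pep, model), model)
            if rank is None:
                if (allele, len(pep)) not in warned:
                    warned.add((allele, len(pep)))
                    logger.warning("MISSING prediction allele=%s peptide_length=%d",
                                   allele, len(pep))
                cls = "missing"
            else:
                cls = classify_binder(rank, thresholds)
            records.append(AnnotatedCandidate(
                peptide=lp, allele=allele, percentile_rank=rank,
                binder_class=cls, label=panel.label(allele), source=source,
            ))

    names = []
    seen = set()
    for lp in candidates:
        name = _display_name(lp)
        if name not in seen:
            seen.add(name)
            names.append(name)
    matrix = pd.DataFrame(index=names, columns=list(panel.alleles), dtype=object)
    for rec in records:
        matrix.loc[_display_name(rec.peptide), rec.allele] = (
            "missing" if rec.percentile_rank is None else rec.percentile_rank
        )
    matrix.index.name = "peptide"
    return records, matrix
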