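"""Pairwise comparison of peptide repertoires between proteasome conditions.

Peptide-forms are keyed by substrate coordinates plus deamidation state (a
deamidated form is a separate point unless explicitly collapsed). Abundances
are TIC-relative percentages; a form absent from a condition is ND (not
detected) — a categorical outcome, never imputed as 0 or infinity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd

from .errors import ConfigError, StateError
from .mapping import LocatedPeptide

ND = "ND"


@dataclass(frozen=True)
class ConditionComparison:
    """One peptide-form compared between conditions A and B."""

    key: tuple  # (substrate_id, start, end, deamidation_sites)
    sequence: str  # observed (deamidated) form
    rel_a: float | None  # percent of TIC in A; None = ND
    rel_b: float | None

    @property
    def status(self) -> str:
        if self.rel_a is not None and self.rel_b is not None:
            return "both"
        return "only_a" if self.rel_a is not None else "only_b"

    @property
    def ratio(self) -> float | None:
        """B/A fold change; defined only when detected in both conditions."""
        if self.status != "both":
            return None
        return self.rel_b / self.rel_a

    @property
    def start(self) -> int:
        return self.key[1]

    @property
    def end(self) -> int:
        return self.key[2]

    @property
    def deamidation_sites(self) -> tuple[int, ...]:
        return self.key[3]


def _aggregate(
    located: Sequence[LocatedPeptide], collapse_deamidation: bool
) -> tuple[dict[tuple, float], dict[tuple, str]]:
    rel: dict[tuple, float] = {}
    seqs: dict[tuple, str] = {}
    for lp in located:
        if lp.relative_abundance is None:
            raise StateError("compare_conditions requires tic_normalize first")
        key = lp.form_key()
        if collapse_deamidation:
            key = key[:3] + ((),)
        rel[key] = rel.get(key, 0.0) + lp.relative_abundance
        # prefer the germline sequence when deamidation state is collapsed
        seq = lp.germline_sequence if collapse_deamidation else lp.observed_sequence
        seqs.setdefault(key, seq)
    return rel, seqs


def compare_conditions(
    located_a: Sequence[LocatedPeptide],
    located_b: Sequence[LocatedPeptide],
    collapse_deamidation: bool = False,
) -> tuple[list[ConditionComparison], dict[str, int]]:
    """Compare two TIC-normalized repertoires on the same substrate.

    Returns per-form comparisons sorted by max(rel_a, rel_b) descending (ties
    by start position), and the overlap summary
    ``{"both": n, "only_a": n, "only_b": n}``.
    """
    substrates_a = {lp.substrate_id for lp in located_a}
    substrates_b = {lp.substrate_id for lp in located_b}
    if substrates_a and substrates_b and substrates_a != substrates_b:
        raise ConfigError(
            f"substrate mismatch: {sorted(substrates_a)} vs {sorted(substrates_b)}"
        )
    rel_a, seq_a = _aggregate(located_a, collapse_deamidation)
    rel_b, seq_b = _aggregate(located_b, collapse_deamidation)
    comparisons = []
    for key in set(rel_a) | set(rel_b):
        comparisons.append(ConditionComparison(
            key=key,
            sequence=seq_a.get(key, seq_b.get(key, "")),
            rel_a=rel_a.get(key),
            rel_b=rel_b.get(key),
        ))
    comparisons.sort(key=lambda c: (-max(c.rel_a or 0.0, c.rel_b or 0.0), c.start))
    summary = {"both": 0, "only_a": 0, "only_b": 0}
    for c in comparisons:
        summary[c.status] += 1
    return comparisons, summary


def enrichment_report(
    comparisons: Sequence[ConditionComparison],
    subset_filter: Callable[[ConditionComparison], bool]
    | Iterable[LocatedPeptide]
    | None = None,
) -> pd.DataFrame:
    """Per-peptide fold-change table, optionally restricted to a subset
    (e.g. the 9–10-mer MHC-I candidate set).

    ND is reported as the literal token "ND"; a one-sided detection is
    reported as ``ND(only_a)`` / ``ND(only_b)`` in the ratio column.
    """
    if subset_filter is None:
        selected = list(comparisons)
    elif callable(subset_filter):
        selected = [c for c in comparisons if subset_filter(c)]
    else:
        keys = {lp.form_key() for lp in subset_filter}
        selected = [c for c in comparisons if c.key in keys]
    rows = []
    for c in selected:
        rows.append({
            "start": c.start,
            "end": c.end,
            "sequence": c.sequence,
            "deamidation": ";".join(map(str, c.deamidation_sites)),
            "rel_a_pct": ND if c.rel_a is None else c.rel_a,
            "rel_b_pct": ND if c.rel_b is None else c.rel_b,
            "ratio": c.ratio if c.status == "both" else f"{ND}({c.status})",
            "status": c.status,
        })
    return pd.DataFrame(rows, columns=["start", "end", "sequence", "deamidation",
                                       "rel_a_pct", "rel_b_pct", "ratio", "status"])


def plot_comparison(
    comparisons: Sequence[ConditionComparison],
    summary: dict[str, int],
    path,
    label_a: str = "condition A",
    label_b: str = "condition B",
) -> None:
    """Log-log abundance scatter with an overlap side panel (optional figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    both = [(c.rel_a, c.rel_b) for c in comparisons if c.status == "both"]
    fig, (ax1, ax2) = plt.subplots(
        1, 2, figsize=(8, 4), gridspec_kw={"width_ratios": [3, 1]}
    )
    if both:
        xs, ys = zip(*both)
        ax1.scatter(xs, ys, s=12, alpha=0.6, edgecolors="none")
    ax1.set_xscale("log")
    ax1.set_yscale("log")
    ax1.set_xlabel(f"{label_a} (% TIC)")
    ax1.set_ylabel(f"{label_b} (% TIC)")
    ax1.set_title("shared peptide-forms")
    ax2.bar(["both", "only A", "only B"],
            [summary["both"], summary["only_a"], summary["only_b"]])
    ax2.set_title("overlap")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
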