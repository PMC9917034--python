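"""Offline adapter for the IEDB MHC-I prediction tools.

``format_request`` builds the POST payload the IEDB tools API expects;
``parse_response`` converts the tools' tab-separated result into typed
prediction records that :func:`degradomics.hla.annotate_candidates` consumes.
No network call is made here — submitting the request is left to the caller.
"""

from __future__ import annotations

from typing import Sequence

from .io_tables import PredictionRecord

IEDB_MHCI_URL = "http://tools-cluster-interface.iedb.org/tools_api/mhci/"


def format_request(
    peptides: Sequence[str],
    alleles: Sequence[str],
    method: str = "recommended",
) -> dict:
    """POST form fields for the IEDB MHC-I tools endpoint.

    Peptides must share a length per request; the allele/length lists are
    repeated pairwise as the API requires.
    """
    lengths = {len(p) for p in peptides}
    if len(lengths) != 1:
        raise ValueError(f"IEDB requests are per-length; got lengths {sorted(lengths)}")
    length = lengths.pop()
    return {
        "method": method,
        "sequence_text": "\n".join(peptides),
        "allele": ",".join(alleles),
        "length": ",".join(str(length) for _ in alleles),
    }


def parse_response(text: str) -> list[PredictionRecord]:
    """Parse the IEDB tools TSV response (columns include ``allele``,
    ``peptide`` and a percentile-rank column)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    header = [h.strip().lower() for h in lines[0].split("\t")]
    rank_col = next(
        (h for h in header if "percentile" in h or h == "rank"), None
    )
    if rank_col is None or "allele" not in header or "peptide" not in header:
        raise ValueError(f"unrecognized IEDB response header: {header}")
    records = []
    for ln in lines[1:]:
        row = dict(zip(header, ln.split("\t")))
        score = row.get("score")
        records.append(PredictionRecord(
            allele=row["allele"],
            peptide=row["peptide"].upper(),
            percentile_rank=float(row[rank_col]),
            score=float(score) if score not in (None, "", "-") else None,
        ))
    return records
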