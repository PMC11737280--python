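"""Specimen identification by highest-CCI lookup against a reference database."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from maldicci.cci import CCIConfig, cci
from maldicci.preprocess import ProcessedSpectrum
from maldicci.refdb import ReferenceDatabase

#: confusion categories for an evaluated query
TP, TN, FP, FN = "TP", "TN", "FP", "FN"

DEFAULT_THRESHOLD = -14.0


@dataclass(frozen=True)
class MatchResult:
    """Outcome of identifying one specimen from its selected replicate spectra."""

    specimen_id: str
    spots_used: tuple[int, ...]
    best_reference_spectrum_id: Optional[str]
    best_species: Optional[str]
    best_log10cci: float
    decision: str  # "identified" | "no_identification"


def best_match(
    scores: np.ndarray, ref_ids: Sequence[str]
) -> tuple[int, float]:
    """Index and value of the maximal score; ties go to the first (lowest id)."""
    idx = int(np.argmax(scores))
    return idx, float(scores[idx])


def identify_specimen(
    spectra: Sequence[ProcessedSpectrum],
    db: ReferenceDatabase,
    threshold: float = DEFAULT_THRESHOLD,
    specimen_id: str | None = None,
    spots_used: Sequence[int] | None = None,
    config: CCIConfig | None = None,
) -> MatchResult:
    """Identify one specimen from its replicate spectra.

    The result is the reference spectrum with the highest CCI over all
    (selected spot x reference) pairs; the specimen is identified iff the
    best log10(CCI) is >= threshold (equality identifies).
    """
    if not spectra:
        raise ValueError("need at least one query spectrum")
    if len(db) == 0:
        raise ValueError("reference database is empty")
    config = config or CCIConfig()

    best_val = -np.inf
    best_ref: Optional[str] = None
    for query in sorted(spectra, key=lambda s: s.spectrum_id):
        for ref in db.spectra:  # already sorted by spectrum_id
            value = cci(query, ref, config).log10cci
            if value > best_val:
                best_val = value
                best_ref = ref.spectrum_id

    identified = best_val >= threshold
    return MatchResult(
        specimen_id=specimen_id or "specimen",
        spots_used=tuple(spots_used or ()),
        best_reference_spectrum_id=best_ref if identified else None,
        best_species=db.species_of(best_ref) if identified and best_ref else None,
        best_log10cci=float(best_val),
        decision="identified" if identified else "no_identification",
    )


def classify_result(
    match: MatchResult, true_species: str, db_species_set: set[str]
) -> str:
    """Confusion category of an identification against the true species label.

    TP: identified as the true species.  FP: identified as another species.
    TN: no identification and the true species is not in the database.
    FN: no identification although the true species is in the database.
    """
    if match.decision == "identified":
        return TP if match.best_species == true_species else FP
    return TN if true_species not in db_species_set else FN


__all__ = [
    "TP", "TN", "FP", "FN",
    "DEFAULT_THRESHOLD",
    "MatchResult",
    "identify_specimen",
    "classify_result",
    "best_match",
]
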