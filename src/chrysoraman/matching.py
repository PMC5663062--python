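"""Cultivar identification by pattern matching, and tentative compound assignment.

A query pattern is compared with each library pattern by pairing peaks whose
positions agree within a tolerance window (default 4 cm^-1) and scoring the
paired normalized intensities with an unmatched-mass-penalized cosine:

    score = sum over pairs (q_i * r_i) / (||q|| * ||r||)

where the norms run over *all* peaks of each pattern, so unmatched peaks
dilute the score without contributing to it. A pattern matched against
itself scores exactly 1; patterns with no peaks within tolerance score 0.
Near-duplicate single-peak cultivars (732 vs 733 cm^-1) both score 1 against
a single-peak query, and are separated by the total-position-deviation
tie-break.

Tentative compound assignment looks each peak up in a reference-band table:
point references match within the table's tolerance (default 3 cm^-1, the
window within which e.g. 1017-1023 cm^-1 peaks are all attributed to the
1020 cm^-1 crocetin band), interval references match by containment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .spectra import (
    AssignmentTable,
    PeakPattern,
    SpectralLibrary,
    ValidationError,
)

__all__ = [
    "MatchResult",
    "CompoundAssignment",
    "match_pattern",
    "identify",
    "assign_compounds",
]


@dataclass
class MatchResult:
    """Similarity of a query pattern to one library cultivar."""

    cultivar: str
    score: float
    matched_pairs: list[tuple[float, float]]  # (query position, library position)
    total_position_deviation: float

    def __post_init__(self) -> None:
        if not 0 <= self.score <= 1 + 1e-12:
            raise ValidationError(f"score out of [0, 1]: {self.score}")


@dataclass
class CompoundAssignment:
    """One peak tentatively attributed to a reference compound band."""

    position: float
    compound: str
    compound_class: str
    vibration: str
    reference: float | tuple[float, float]
    deviation: float
    ambiguous: bool = False


def match_pattern(
    query: PeakPattern, reference: PeakPattern, tolerance: float = 4.0
) -> MatchResult:
    """Score two patterns by tolerance-window pairing + penalized cosine.

    Peaks are paired greedily, one-to-one, in order of increasing position
    difference; only pairs within ``tolerance`` cm^-1 are allowed.
    """
    if not query.peaks or not reference.peaks:
        raise ValidationError("cannot match empty patterns")
    candidates = sorted(
        (abs(q.position - r.position), qi, ri)
        for qi, q in enumerate(query.peaks)
        for ri, r in enumerate(reference.peaks)
        if abs(q.position - r.position) <= tolerance
    )
    used_q: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, qi, ri in candidates:
        if qi in used_q or ri in used_r:
            continue
        used_q.add(qi)
        used_r.add(ri)
        pairs.append((qi, ri))
    pairs.sort()
    q_norm = math.sqrt(sum(p.normalized_intensity**2 for p in query.peaks))
    r_norm = math.sqrt(sum(p.normalized_intensity**2 for p in reference.peaks))
    dot = sum(
        query.peaks[qi].normalized_intensity * reference.peaks[ri].normalized_intensity
        for qi, ri in pairs
    )
    score = min(dot / (q_norm * r_norm), 1.0)
    return MatchResult(
        cultivar=reference.cultivar,
        score=score,
        matched_pairs=[
            (query.peaks[qi].position, reference.peaks[ri].position) for qi, ri in pairs
        ],
        total_position_deviation=float(
            sum(abs(query.peaks[qi].position - reference.peaks[ri].position)
                for qi, ri in pairs)
        ),
    )


def identify(
    query: PeakPattern, library: SpectralLibrary, tolerance: float = 4.0
) -> list[MatchResult]:
    """Rank every library cultivar against the query.

    Sorted by score descending; ties broken by smaller total position
    deviation, then lexicographic cultivar name. The full ranking is
    returned — the top entry is the identification.
    """
    if len(library) == 0:
        raise ValidationError("cannot identify against an empty library")
    results = [match_pattern(query, pattern, tolerance) for pattern in library]
    results.sort(key=lambda m: (-m.score, m.total_position_deviation, m.cultivar))
    return results


def assign_compounds(
    pattern: PeakPattern, table: AssignmentTable | None = None
) -> list[CompoundAssignment]:
    """Tentatively attribute each peak to reference compound bands.

    Every table entry whose point reference lies within ``table.tolerance``
    of the peak, or whose interval contains it, yields one assignment.
    Entries sharing an identical reference (e.g. two monoterpenes quoted at
    the same band) are all returned, flagged ambiguous. Peaks matching no
    entry yield nothing.
    """
    if table is None:
        from .library import reference_assignments

        table = reference_assignments()
    assignments: list[CompoundAssignment] = []
    for peak in pattern.peaks:
        matches: list[CompoundAssignment] = []
        for entry in table.entries:
            if entry.is_interval:
                lo, hi = entry.reference
                if lo <= peak.position <= hi:
                    matches.append(
                        CompoundAssignment(
                            position=peak.position,
                            compound=entry.compound,
                            compound_class=entry.compound_class,
                            vibration=entry.vibration,
                            reference=entry.reference,
                            deviation=0.0,
                        )
                    )
            else:
                deviation = abs(peak.position - entry.reference)
                if deviation <= table.tolerance:
                    matches.append(
                        CompoundAssignment(
                            position=peak.position,
                            compound=entry.compound,
                            compound_class=entry.compound_class,
                            vibration=entry.vibration,
                            reference=entry.reference,
                            deviation=deviation,
                        )
                    )
        by_reference: dict[object, int] = {}
        for m in matches:
            by_reference[m.reference] = by_reference.get(m.reference, 0) + 1
        for m in matches:
            m.ambiguous = by_reference[m.reference] > 1
        assignments.extend(matches)
    return assignments
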