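"""Lineage classification against a diagnostic band-pattern table.

This module mechanises the manual scoring of gel lanes: an observed list of
band sizes is matched against a table of expected patterns, one per
lineage, with an absolute size tolerance. The built-in table holds the
assay's three diagnostic outcomes for Pocillopora damicornis typing:

==================  =======================
lineage             expected bands (bp)
==================  =======================
Type alpha          84, 116, 389
Type beta           92, 110, 116, 389
other Pocillopora   92, 116, 389
==================  =======================

Band multiplicity is ignored when matching — a gel lane cannot reveal how
many co-migrating fragments form one band — so classification works on
distinct sizes only.
"""

from __future__ import annotations

import enum
from collections import Counter, OrderedDict
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import ConfigError, DataError
from .insilico_pcr import (
    DEFAULT_3PRIME_EXACT,
    DEFAULT_MAX_MISMATCH,
    DEFAULT_MAX_PRODUCT,
    amplify,
)
from .seq_core import PDAM_F, PDAM_R, Primer, SeqRecord
from .virtual_digest import ALU_I, Band, BandPattern, Enzyme, band_pattern, digest


class Call(str, enum.Enum):
    """Closed enumeration of assay outcomes."""

    TYPE_ALPHA = "TYPE_ALPHA"
    TYPE_BETA = "TYPE_BETA"
    OTHER_POCILLOPORA = "OTHER_POCILLOPORA"
    NO_AMPLIFICATION = "NO_AMPLIFICATION"
    UNKNOWN_PATTERN = "UNKNOWN_PATTERN"
    MULTI_AMPLICON = "MULTI_AMPLICON"


#: lineage-label aliases -> lineage call
_CALL_FOR_LABEL: dict[str, Call] = {
    "typealpha": Call.TYPE_ALPHA,
    "type_alpha": Call.TYPE_ALPHA,
    "alpha": Call.TYPE_ALPHA,
    "typebeta": Call.TYPE_BETA,
    "type_beta": Call.TYPE_BETA,
    "beta": Call.TYPE_BETA,
    "otherpocillopora": Call.OTHER_POCILLOPORA,
    "other_pocillopora": Call.OTHER_POCILLOPORA,
    "other": Call.OTHER_POCILLOPORA,
}


def call_for_label(label: str) -> Call:
    """Map a table entry label to its lineage call (UNKNOWN if unmapped)."""
    return _CALL_FOR_LABEL.get(label.replace("-", "_").lower(), Call.UNKNOWN_PATTERN)


DEFAULT_TOLERANCE_BP = 2


def _sizes_match(
    observed: Sequence[int], expected: Sequence[int], tolerance_bp: int
) -> bool:
    """One-to-one pairing of distinct sizes, every pair within tolerance.

    Both lists are distinct and sorted; for interval-style constraints the
    order-preserving pairing is optimal, so a greedy sorted comparison
    decides matchability.
    """
    if len(observed) != len(expected):
        return False
    return all(abs(o - e) <= tolerance_bp for o, e in zip(sorted(observed), sorted(expected)))


def _distance(observed: Sequence[int], expected: Sequence[int]) -> float:
    """Diagnostic distance: max paired deviation, or inf on a count mismatch."""
    if len(observed) != len(expected):
        return float("inf")
    if not observed:
        return 0.0
    return float(max(abs(o - e) for o, e in zip(sorted(observed), sorted(expected))))


@dataclass(frozen=True)
class PatternTable:
    """Expected band pattern per lineage, with a matching tolerance.

    Construction fails unless all entries are pairwise distinguishable at
    ``tolerance_bp`` — i.e. no observed lane could ever match two entries.
    """

    entries: "OrderedDict[str, BandPattern]"
    tolerance_bp: int = DEFAULT_TOLERANCE_BP
    provenance: str = "user"

    def __post_init__(self) -> None:
        if self.tolerance_bp < 0:
            raise ConfigError("tolerance_bp must be >= 0")
        labels = list(self.entries)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                sa, sb = self.entries[a].sizes, self.entries[b].sizes
                if len(sa) == len(sb) and all(
                    # one lane within tolerance of both entries exists iff
                    # every corresponding pair is within 2*tolerance
                    abs(x - y) <= 2 * self.tolerance_bp
                    for x, y in zip(sorted(sa), sorted(sb))
                ):
                    raise ConfigError(
                        f"pattern table entries {a!r} and {b!r} are not "
                        f"distinguishable at tolerance {self.tolerance_bp} bp"
                    )

    def labels(self) -> list[str]:
        return list(self.entries)


def _pattern(sizes_with_mult: Sequence[tuple[int, int]]) -> BandPattern:
    return BandPattern(
        bands=tuple(Band(size=s, multiplicity=m) for s, m in sizes_with_mult),
        resolution_bp=0,
        min_detectable_bp=0,
    )


def builtin_table(tolerance_bp: int = DEFAULT_TOLERANCE_BP) -> PatternTable:
    """The assay's published diagnostic key.

    In-silico digestion shows the 116 bp band of Type alpha and of other
    Pocillopora is doubled (two co-migrating fragments); multiplicity is
    recorded but plays no role in matching.
    """
    entries: "OrderedDict[str, BandPattern]" = OrderedDict(
        [
            ("TypeAlpha", _pattern([(84, 1), (116, 2), (389, 1)])),
            ("TypeBeta", _pattern([(92, 1), (110, 1), (116, 1), (389, 1)])),
            ("OtherPocillopora", _pattern([(92, 1), (116, 2), (389, 1)])),
        ]
    )
    return PatternTable(entries=entries, tolerance_bp=tolerance_bp, provenance="builtin")


@dataclass(frozen=True)
class LineageCall:
    """Classification result with per-entry distance diagnostics."""

    call: Call
    lineage: Optional[str]
    matched_sizes: Optional[tuple[int, ...]]
    observed_sizes: tuple[int, ...]
    distances: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lineage_calls = {Call.TYPE_ALPHA, Call.TYPE_BETA, Call.OTHER_POCILLOPORA}
        if (self.call in lineage_calls) != (self.matched_sizes is not None):
            raise DataError("matched pattern must be present iff a lineage was called")


def classify_pattern(observed: Sequence[int], table: PatternTable) -> LineageCall:
    """Score an observed band-size list against the pattern table.

    An empty observation is NO_AMPLIFICATION. Otherwise the distinct
    observed sizes must pair one-to-one with an entry's sizes, each pair
    within the table tolerance; exactly one matching entry yields that
    lineage, none (or — impossible for a validated table — several) yields
    UNKNOWN_PATTERN.
    """
    if any(s <= 0 for s in observed):
        raise DataError(f"band sizes must be positive, got {list(observed)}")
    distinct = sorted(set(observed))
    if not distinct:
        return LineageCall(
            call=Call.NO_AMPLIFICATION,
            lineage=None,
            matched_sizes=None,
            observed_sizes=(),
        )
    distances = {
        label: _distance(distinct, pat.sizes) for label, pat in table.entries.items()
    }
    matches = [
        label
        for label, pat in table.entries.items()
        if _sizes_match(distinct, pat.sizes, table.tolerance_bp)
    ]
    if len(matches) == 1:
        label = matches[0]
        return LineageCall(
            call=call_for_label(label),
            lineage=label,
            matched_sizes=tuple(table.entries[label].sizes),
            observed_sizes=tuple(distinct),
            distances=distances,
        )
    return LineageCall(
        call=Call.UNKNOWN_PATTERN,
        lineage=None,
        matched_sizes=None,
        observed_sizes=tuple(distinct),
        distances=distances,
    )


def type_sequence(
    template: SeqRecord,
    fwd: Primer = PDAM_F,
    rev: Primer = PDAM_R,
    enzyme: Enzyme = ALU_I,
    table: Optional[PatternTable] = None,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    require_3prime_exact: int = DEFAULT_3PRIME_EXACT,
    max_product: int = DEFAULT_MAX_PRODUCT,
    min_detectable_bp: int = 0,
) -> LineageCall:
    """Run the full in-silico assay on one template.

    Amplify with the primer pair; zero products is NO_AMPLIFICATION and
    several is MULTI_AMPLICON (an ambiguous lane). A single product is
    digested, collapsed to exact in-silico band sizes (resolution 0) and
    classified against the table.
    """
    if table is None:
        table = builtin_table()
    products = amplify(
        template, fwd, rev, max_mismatch, require_3prime_exact, max_product
    )
    if not products:
        return LineageCall(
            call=Call.NO_AMPLIFICATION,
            lineage=None,
            matched_sizes=None,
            observed_sizes=(),
        )
    if len(products) > 1:
        return LineageCall(
            call=Call.MULTI_AMPLICON,
            lineage=None,
            matched_sizes=None,
            observed_sizes=(),
        )
    frags = digest(products[0].sequence, enzyme, parent_id=template.id)
    pattern = band_pattern(frags, resolution_bp=0, min_detectable_bp=min_detectable_bp)
    return classify_pattern(pattern.sizes, table)


@dataclass(frozen=True)
class BatchResult:
    record_id: str
    call: Optional[LineageCall]
    error: Optional[str] = None


def type_batch(
    templates: Sequence[SeqRecord], **settings
) -> tuple[list[BatchResult], Counter]:
    """Type every template, collecting per-record errors instead of failing.

    Returns results in input order plus a histogram of calls.
    """
    results: list[BatchResult] = []
    summary: Counter = Counter()
    for record in templates:
        try:
            call = type_sequence(record, **settings)
        except Exception as exc:  # noqa: BLE001 - per-record isolation
            results.append(BatchResult(record_id=record.id, call=None, error=str(exc)))
            continue
        results.append(BatchResult(record_id=record.id, call=call))
        summary[call.call] += 1
    return results, summary
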