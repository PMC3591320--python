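"""Discovery of lineage-diagnostic indels and in-silico assay evaluation.

A diagnostic indel is a maximal run of alignment columns that is gapped in
every row of exactly one lineage and ungapped in every row of all other
lineages (a lineage-fixed deletion), or the converse (a lineage-fixed
insertion). Such fixed length differences are what make a PCR-RFLP assay
possible: they shift fragment sizes consistently within a lineage.

``evaluate_assay`` runs the full pipeline — amplify, digest, band pattern —
for one template per lineage and asks whether every pair of lineages ends
up with distinguishable band patterns at a stated gel resolution.
"""

from __future__ import annotations

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
from .seq_core import GAP, GappedAlignment, Primer, SeqRecord
from .virtual_digest import BandPattern, Enzyme, band_pattern, digest

CONTEXT_BP = 10

NO_AMPLIFICATION = "NO_AMPLIFICATION"
DISCORDANT = "DISCORDANT"


@dataclass(frozen=True)
class DiagnosticIndel:
    """A lineage-fixed insertion or deletion found in a labelled alignment.

    ``columns`` is the half-open alignment column range; ``support`` is the
    fraction of in-lineage rows showing the state (1.0 for a diagnostic
    call). ``context`` holds up to 10 consensus bases flanking each side.
    """

    lineage: str
    kind: str  # "deletion" or "insertion"
    length: int
    columns: tuple[int, int]
    support: float
    context: tuple[str, str]

    def __post_init__(self) -> None:
        if self.length != self.columns[1] - self.columns[0] or self.length < 1:
            raise DataError("indel length must equal its column-range width (>= 1)")


def _column_consensus(alignment: GappedAlignment, col: int) -> str:
    counts = Counter(
        row.residues[col] for row in alignment.rows if row.residues[col] != GAP
    )
    if not counts:
        return GAP
    # deterministic tie-break: highest count, then alphabetical
    return min(counts, key=lambda b: (-counts[b], b))


def _context(alignment: GappedAlignment, start: int, end: int) -> tuple[str, str]:
    left = "".join(
        _column_consensus(alignment, c) for c in range(max(0, start - CONTEXT_BP), start)
    )
    right = "".join(
        _column_consensus(alignment, c)
        for c in range(end, min(alignment.n_columns, end + CONTEXT_BP))
    )
    return left.replace(GAP, ""), right.replace(GAP, "")


def discover_diagnostic_indels(
    alignment: GappedAlignment, min_length: int = 1
) -> list[DiagnosticIndel]:
    """Find all lineage-fixed indels of at least ``min_length`` columns.

    Every row must carry a lineage label and at least two distinct labels
    must be present. A column supports a deletion for lineage L when all L
    rows are gapped and no other row is; the converse marks an insertion.
    Maximal runs of such columns are reported, sorted by column then
    lineage. Diagnosticity is strict: 100% in-lineage, 0% out-of-lineage.
    """
    unlabelled = [row.id for row in alignment.rows if not row.label]
    if unlabelled:
        raise DataError(f"unlabelled alignment rows: {unlabelled}")
    lineages = sorted({row.label for row in alignment.rows})
    if len(lineages) < 2:
        raise DataError("diagnostic indel discovery needs at least two lineages")

    rows_by_lineage = {
        lin: [row for row in alignment.rows if row.label == lin] for lin in lineages
    }
    indels: list[DiagnosticIndel] = []
    for lineage in lineages:
        inside = rows_by_lineage[lineage]
        outside = [row for row in alignment.rows if row.label != lineage]
        for kind, gap_in, gap_out in (("deletion", True, False), ("insertion", False, True)):
            run_start: Optional[int] = None
            for col in range(alignment.n_columns + 1):
                hit = False
                if col < alignment.n_columns:
                    hit = all(
                        (row.residues[col] == GAP) == gap_in for row in inside
                    ) and all(
                        (row.residues[col] == GAP) == gap_out for row in outside
                    )
                if hit and run_start is None:
                    run_start = col
                elif not hit and run_start is not None:
                    if col - run_start >= min_length:
                        indels.append(
                            DiagnosticIndel(
                                lineage=lineage,
                                kind=kind,
                                length=col - run_start,
                                columns=(run_start, col),
                                support=1.0,
                                context=_context(alignment, run_start, col),
                            )
                        )
                    run_start = None
    indels = _resolve_dual_calls(indels, rows_by_lineage)
    indels.sort(key=lambda d: (d.columns[0], d.lineage, d.kind))
    return indels


def _resolve_dual_calls(
    indels: list[DiagnosticIndel],
    rows_by_lineage: dict[str, list],
) -> list[DiagnosticIndel]:
    """Collapse the two-lineage ambiguity onto one call per column range.

    With exactly two lineages, a gap run fixed in one lineage is equally a
    deletion there and an insertion in the other; both descriptions pass
    the fixed-difference test. The reported call is the minority lineage's
    (its state deviates from the alignment consensus); on a tie the
    deletion reading wins.
    """
    by_range: dict[tuple[int, int], list[DiagnosticIndel]] = {}
    for indel in indels:
        by_range.setdefault(indel.columns, []).append(indel)
    resolved = []
    for group in by_range.values():
        if len(group) == 1:
            resolved.extend(group)
            continue
        group.sort(
            key=lambda d: (len(rows_by_lineage[d.lineage]), d.kind != "deletion")
        )
        resolved.append(group[0])
    return resolved


def patterns_equivalent(a: Sequence[int], b: Sequence[int], resolution_bp: int) -> bool:
    """True when two distinct-size lists would merge into one pattern.

    Two patterns are indistinguishable at a resolution when they have the
    same number of distinct sizes and each pair of corresponding (sorted)
    sizes co-migrates, i.e. differs by at most ``resolution_bp``.
    """
    a, b = sorted(a), sorted(b)
    if len(a) != len(b):
        return False
    return all(abs(x - y) <= resolution_bp for x, y in zip(a, b))


@dataclass(frozen=True)
class AssayEvaluation:
    """Predicted per-lineage band patterns and pairwise distinguishability."""

    patterns: "OrderedDict[str, Optional[BandPattern]]"
    flags: dict[str, str]
    resolution_bp: int
    matrix: dict[tuple[str, str], bool] = field(init=False)
    distinguishable: bool = field(init=False)

    def __post_init__(self) -> None:
        lineages = list(self.patterns)
        matrix: dict[tuple[str, str], bool] = {}
        for i, a in enumerate(lineages):
            for b in lineages[i + 1 :]:
                pa = self.patterns[a].sizes if self.patterns[a] else []
                pb = self.patterns[b].sizes if self.patterns[b] else []
                distinct = not patterns_equivalent(pa, pb, self.resolution_bp)
                matrix[(a, b)] = distinct
                matrix[(b, a)] = distinct
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(
            self, "distinguishable", all(matrix.values()) if matrix else True
        )


def _group_by_lineage(
    templates: Sequence[tuple[SeqRecord, str]]
) -> "OrderedDict[str, list[SeqRecord]]":
    groups: "OrderedDict[str, list[SeqRecord]]" = OrderedDict()
    for record, label in templates:
        if not label:
            raise DataError(f"template {record.id!r} has no lineage label")
        groups.setdefault(label, []).append(record)
    return groups


def evaluate_assay(
    templates: Sequence[tuple[SeqRecord, str]],
    fwd: Primer,
    rev: Primer,
    enzyme: Enzyme,
    resolution_bp: int = 0,
    min_detectable_bp: int = 0,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    require_3prime_exact: int = DEFAULT_3PRIME_EXACT,
    max_product: int = DEFAULT_MAX_PRODUCT,
) -> AssayEvaluation:
    """Predict the assay outcome for labelled templates with one enzyme.

    For each lineage the first template is amplified, digested and collapsed
    to a band pattern; additional same-lineage templates are cross-checked
    and a discordant lineage is flagged rather than failing. A lineage whose
    template gives no amplicon is flagged ``NO_AMPLIFICATION`` (its pattern
    is None); a template giving more than one amplicon is an error.
    """
    if not templates:
        raise DataError("evaluate_assay needs at least one labelled template")
    groups = _group_by_lineage(templates)
    patterns: "OrderedDict[str, Optional[BandPattern]]" = OrderedDict()
    flags: dict[str, str] = {}
    for lineage, records in groups.items():
        lineage_patterns: list[Optional[BandPattern]] = []
        for record in records:
            products = amplify(
                record, fwd, rev, max_mismatch, require_3prime_exact, max_product
            )
            if len(products) > 1:
                raise DataError(
                    f"template {record.id!r} yields {len(products)} amplicons; "
                    "cannot evaluate"
                )
            if not products:
                lineage_patterns.append(None)
                continue
            frags = digest(products[0].sequence, enzyme, parent_id=record.id)
            lineage_patterns.append(
                band_pattern(frags, resolution_bp, min_detectable_bp)
            )
        first = lineage_patterns[0]
        patterns[lineage] = first
        if first is None:
            flags[lineage] = NO_AMPLIFICATION
        for other in lineage_patterns[1:]:
            same = (
                other is not None
                and first is not None
                and patterns_equivalent(first.sizes, other.sizes, resolution_bp)
            ) or (other is None and first is None)
            if not same:
                flags[lineage] = DISCORDANT
    return AssayEvaluation(patterns=patterns, flags=flags, resolution_bp=resolution_bp)


def select_enzyme(
    templates: Sequence[tuple[SeqRecord, str]],
    fwd: Primer,
    rev: Primer,
    catalog: Sequence[Enzyme],
    resolution_bp: int = 0,
    **pcr_settings,
) -> list[tuple[Enzyme, AssayEvaluation]]:
    """Rank candidate enzymes by diagnostic power on labelled templates.

    Sort key: number of distinguishable lineage pairs (descending), then
    total band count (ascending; simpler gels first), then enzyme name.
    """
    if not catalog:
        raise ConfigError("enzyme catalog must not be empty")
    ranked = []
    for enzyme in catalog:
        evaluation = evaluate_assay(
            templates, fwd, rev, enzyme, resolution_bp, **pcr_settings
        )
        n_pairs = sum(
            1 for (a, b), ok in evaluation.matrix.items() if a < b and ok
        )
        n_bands = sum(
            len(p.bands) for p in evaluation.patterns.values() if p is not None
        )
        ranked.append(((-n_pairs, n_bands, enzyme.name), enzyme, evaluation))
    ranked.sort(key=lambda item: item[0])
    return [(enzyme, evaluation) for _, enzyme, evaluation in ranked]
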