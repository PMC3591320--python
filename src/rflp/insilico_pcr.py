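"""In-silico PCR: primer-site search, amplicon extraction, specificity screen.

A primer anneals at a template position when every base pairs under IUPAC
set-intersection within a mismatch budget, and its 3'-terminal bases match
exactly (the polymerase-extension anchor). Amplicons are predicted from all
productive plus-strand forward / minus-strand reverse site pairs; product
length is reported the way PCR products are sized, from the forward primer's
5' base through the base pairing the reverse primer's 5' base inclusive.
Templates are treated as linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seq_core import Primer, SeqRecord, bases_match, reverse_complement

# Default stringency: the assay relies on exact, unique primer binding.
DEFAULT_MAX_MISMATCH = 0
DEFAULT_3PRIME_EXACT = 3
DEFAULT_MAX_PRODUCT = 5000


@dataclass(frozen=True)
class PrimerSite:
    """A primer binding site in plus-strand, 0-based half-open coordinates."""

    template_id: str
    strand: str  # '+' or '-'
    start: int
    end: int
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product on the template's plus strand."""

    template_id: str
    start: int
    end: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start

    def __len__(self) -> int:
        return self.length


def _scan(
    template: str,
    query: str,
    max_mismatch: int,
    anchor: int,
    anchor_at_start: bool,
) -> list[tuple[int, int]]:
    """All (start, mismatches) where ``query`` matches ``template`` in place.

    ``anchor`` bases at the query end given by ``anchor_at_start`` must match
    exactly (they model the primer's 3' terminus and do not consume budget).
    """
    n, m = len(template), len(query)
    hits: list[tuple[int, int]] = []
    anchor = min(anchor, m)
    for i in range(n - m + 1):
        mism = 0
        ok = True
        for j in range(m):
            if bases_match(query[j], template[i + j]):
                continue
            in_anchor = j < anchor if anchor_at_start else j >= m - anchor
            if in_anchor:
                ok = False
                break
            mism += 1
            if mism > max_mismatch:
                ok = False
                break
        if ok:
            hits.append((i, mism))
    return hits


def find_primer_sites(
    template: SeqRecord,
    primer: Primer,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    require_3prime_exact: int = DEFAULT_3PRIME_EXACT,
) -> list[PrimerSite]:
    """Locate all annealing sites of ``primer`` on both strands of ``template``.

    Returns sites sorted by start. On the plus strand the primer's 3' end is
    the rightmost base of the bound region; on the minus strand (where the
    primer matches the reverse complement) it is the leftmost base in
    plus-strand coordinates.
    """
    if len(primer) > len(template):
        return []
    sites: list[PrimerSite] = []
    for start, mism in _scan(
        template.residues, primer.sequence, max_mismatch, require_3prime_exact, False
    ):
        sites.append(PrimerSite(template.id, "+", start, start + len(primer), mism))
    rc = reverse_complement(primer.sequence)
    for start, mism in _scan(
        template.residues, rc, max_mismatch, require_3prime_exact, True
    ):
        sites.append(PrimerSite(template.id, "-", start, start + len(primer), mism))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def amplify(
    template: SeqRecord,
    fwd: Primer,
    rev: Primer,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    require_3prime_exact: int = DEFAULT_3PRIME_EXACT,
    max_product: int = DEFAULT_MAX_PRODUCT,
) -> list[Amplicon]:
    """Predict PCR products of the primer pair on ``template``.

    One amplicon is returned per plus-strand forward site paired with a
    downstream minus-strand reverse site; the symmetric orientation (reverse
    primer on the plus strand upstream of a minus-strand forward site) is
    reported too, so amplification commutes with reverse-complementing the
    template. Products never exceed ``max_product`` bp. An empty list means
    no amplification; multiple products are returned as-is for downstream
    stages to flag. Coordinates and sequences always refer to the plus strand.
    """
    fwd_sites = find_primer_sites(template, fwd, max_mismatch, require_3prime_exact)
    rev_sites = find_primer_sites(template, rev, max_mismatch, require_3prime_exact)
    upstream_downstream_pairs = [
        (f, r)
        for f in fwd_sites
        if f.strand == "+"
        for r in rev_sites
        if r.strand == "-"
    ] + [
        (r, f)
        for r in rev_sites
        if r.strand == "+"
        for f in fwd_sites
        if f.strand == "-"
    ]
    products: list[Amplicon] = []
    for up, down in upstream_downstream_pairs:
        if down.start < up.end:
            continue  # downstream site must not overlap the upstream one
        length = down.end - up.start
        if length > max_product:
            continue
        products.append(
            Amplicon(
                template_id=template.id,
                start=up.start,
                end=down.end,
                sequence=template.residues[up.start : down.end],
            )
        )
    products.sort(key=lambda a: (a.start, a.length))
    return products


@dataclass(frozen=True)
class SpecificityReport:
    """Off-target amplification predicted for a primer pair."""

    amplicons_by_record: dict[str, tuple[Amplicon, ...]]
    passed: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "passed",
            all(not hits for hits in self.amplicons_by_record.values()),
        )


def specificity_screen(
    fwd: Primer,
    rev: Primer,
    off_targets: list[SeqRecord],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    require_3prime_exact: int = DEFAULT_3PRIME_EXACT,
    max_product: int = DEFAULT_MAX_PRODUCT,
) -> SpecificityReport:
    """Check that the primer pair yields no product on any off-target record.

    The screen passes when every off-target record gives an empty amplicon
    list, mirroring the requirement that the assay's primers must not
    amplify non-target genera.
    """
    report = {
        rec.id: tuple(
            amplify(rec, fwd, rev, max_mismatch, require_3prime_exact, max_product)
        )
        for rec in off_targets
    }
    return SpecificityReport(amplicons_by_record=report)
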