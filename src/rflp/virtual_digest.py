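"""Virtual restriction digestion and gel band-pattern prediction.

Digestion is modelled as complete: every occurrence of the recognition site
produces a cut. Sites are searched on the plus strand with IUPAC-aware
matching; for palindromic sites (such as AluI's AGCT) this is equivalent to
a double-strand search. Fragment sizes are then collapsed into the band
pattern a gel would show: fragments below the detection floor vanish and
sizes within the gel's resolution co-migrate into a single band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import yaml

from .errors import ConfigError, DataError
from .seq_core import ALPHABET, bases_match, reverse_complement

logger = logging.getLogger(__name__)

MIN_SITE_LENGTH = 4

# Gel-emulation preset: a 4% agarose gel resolves ~4 bp in the 100-400 bp
# range (it separates 110 from 116 bp) and small fragments run off / stain
# too faintly below ~50 bp.
GEL_RESOLUTION_BP = 4
GEL_MIN_DETECTABLE_BP = 50


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: recognition site plus top-strand cut offset.

    ``cut_offset`` counts bases from the site's start to the cut point, so
    AluI (AG^CT) has site ``"AGCT"`` and offset 2.
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigError("enzyme name must be non-empty")
        object.__setattr__(self, "site", self.site.upper())
        if len(self.site) < MIN_SITE_LENGTH:
            raise ConfigError(
                f"enzyme {self.name!r}: site {self.site!r} shorter than "
                f"{MIN_SITE_LENGTH} bp"
            )
        bad = set(self.site) - ALPHABET
        if bad:
            raise ConfigError(
                f"enzyme {self.name!r}: illegal site characters {sorted(bad)}"
            )
        if not 0 <= self.cut_offset <= len(self.site):
            raise ConfigError(
                f"enzyme {self.name!r}: cut offset {self.cut_offset} outside "
                f"[0, {len(self.site)}]"
            )

    @property
    def is_palindromic(self) -> bool:
        return self.site == reverse_complement(self.site)


#: Built-in AluI: blunt cutter, AG^CT.
ALU_I = Enzyme("AluI", "AGCT", 2)

BUILTIN_ENZYMES: dict[str, Enzyme] = {ALU_I.name: ALU_I}


@dataclass(frozen=True)
class FragmentSet:
    """Ordered digestion products of one parent sequence."""

    parent_id: str
    fragments: tuple[str, ...]
    cut_positions: tuple[int, ...]

    @property
    def lengths(self) -> list[int]:
        return [len(f) for f in self.fragments]

    @property
    def parent_length(self) -> int:
        return sum(self.lengths)


def find_recognition_sites(seq: str, enzyme: Enzyme) -> list[int]:
    """Start positions of every (possibly overlapping) site occurrence."""
    m = len(enzyme.site)
    starts = []
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        if all(bases_match(enzyme.site[k], window[k]) for k in range(m)):
            if "N" in window:
                logger.warning(
                    "site for %s at %d overlaps an N; treating as a match",
                    enzyme.name,
                    i,
                )
            starts.append(i)
    return starts


def digest(seq: str, enzyme: Enzyme, parent_id: str = "seq") -> FragmentSet:
    """Completely digest ``seq`` with ``enzyme``.

    Returns fragments in left-to-right template order. A sequence without
    any recognition site comes back as a single fragment.
    """
    if not seq:
        raise DataError("cannot digest an empty sequence")
    seq = seq.upper()
    if not enzyme.is_palindromic:
        logger.warning(
            "enzyme %s has a non-palindromic site; minus-strand nicking is "
            "not modelled",
            enzyme.name,
        )
    cuts = sorted(
        {
            start + enzyme.cut_offset
            for start in find_recognition_sites(seq, enzyme)
            if 0 < start + enzyme.cut_offset < len(seq)
        }
    )
    bounds = [0, *cuts, len(seq)]
    fragments = tuple(seq[a:b] for a, b in zip(bounds, bounds[1:]))
    return FragmentSet(parent_id=parent_id, fragments=fragments, cut_positions=tuple(cuts))


@dataclass(frozen=True)
class Band:
    size: int
    multiplicity: int


@dataclass(frozen=True)
class BandPattern:
    """Detectable gel bands: ascending distinct sizes with multiplicities."""

    bands: tuple[Band, ...]
    resolution_bp: int
    min_detectable_bp: int

    @property
    def sizes(self) -> list[int]:
        """Distinct band sizes, ascending."""
        return [b.size for b in self.bands]

    def __bool__(self) -> bool:
        return bool(self.bands)


def band_pattern(
    fragments: Union[FragmentSet, Iterable[int]],
    resolution_bp: int = 0,
    min_detectable_bp: int = 0,
) -> BandPattern:
    """Collapse fragment sizes into the band pattern a gel would display.

    Sizes below ``min_detectable_bp`` are dropped; remaining sizes are
    merged by single linkage — adjacent sizes differing by at most
    ``resolution_bp`` co-migrate — and each group becomes one band whose
    size is the group mean rounded to the nearest bp and whose multiplicity
    is the group count. Raising the resolution can only merge further, so
    the number of bands is monotone non-increasing in ``resolution_bp``.
    """
    if resolution_bp < 0:
        raise ConfigError("resolution_bp must be >= 0")
    lengths: Sequence[int]
    if isinstance(fragments, FragmentSet):
        lengths = fragments.lengths
    else:
        lengths = list(fragments)
    sizes = sorted(s for s in lengths if s >= min_detectable_bp)
    bands: list[Band] = []
    i = 0
    while i < len(sizes):
        j = i + 1
        while j < len(sizes) and sizes[j] - sizes[j - 1] <= resolution_bp:
            j += 1
        group = sizes[i:j]
        bands.append(Band(size=round(sum(group) / len(group)), multiplicity=len(group)))
        i = j
    return BandPattern(
        bands=tuple(bands),
        resolution_bp=resolution_bp,
        min_detectable_bp=min_detectable_bp,
    )


def load_enzymes(path: str | Path) -> list[Enzyme]:
    """Load enzyme definitions from a YAML list of ``{name, site, cut}``.

    The built-in AluI needs no file; this loader supports user catalogs for
    enzyme selection. Order is preserved; invalid entries raise
    :class:`~rflp.errors.ConfigError` naming the enzyme.
    """
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if raw is None:
        return []
    if not isinstance(raw, list):
        raise ConfigError(f"enzyme config {path}: expected a YAML list")
    enzymes = []
    for entry in raw:
        if not isinstance(entry, dict) or not {"name", "site", "cut"} <= set(entry):
            raise ConfigError(
                f"enzyme config {path}: each entry needs name/site/cut keys, got {entry!r}"
            )
        name = str(entry["name"])
        try:
            cut = int(entry["cut"])
        except (TypeError, ValueError):
            raise ConfigError(f"enzyme {name!r}: cut must be an integer") from None
        enzymes.append(Enzyme(name=name, site=str(entry["site"]), cut_offset=cut))
    return enzymes


def get_enzyme(name: str, catalog: Sequence[Enzyme] = ()) -> Enzyme:
    """Resolve an enzyme by name from a catalog, falling back to built-ins."""
    for enz in catalog:
        if enz.name == name:
            return enz
    try:
        return BUILTIN_ENZYMES[name]
    except KeyError:
        raise ConfigError(f"unknown enzyme {name!r}") from None
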