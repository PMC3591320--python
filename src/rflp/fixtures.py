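"""Seeded synthetic templates reproducing the assay's fragment geometry.

Real templates are mitochondrial control-region sequences of Pocillopora
corals; this module generates stand-ins with the same amplicon and digest
arithmetic so every pipeline stage is testable offline:

* reference ("other Pocillopora") amplicon, 713 bp, laid out as four
  segments of 92, 116, 116 and 389 bp with an AluI site (AG^CT) straddling
  each junction — digest gives [92, 116, 116, 389];
* Type alpha variant: an 8 bp deletion inside segment 1 (amplicon 705 bp,
  digest [84, 116, 116, 389]);
* Type beta variant: a 6 bp deletion inside segment 2 (amplicon 707 bp,
  digest [92, 110, 116, 389]).

The forward primer occupies the amplicon's first 20 bp, the reverse-primer
binding region its last 20 bp. Filler sequence is random but constrained:
no stray AluI site anywhere, no second primer binding site on either
strand, and neither deletion may create a new site. Which 116 bp segment
carries the beta deletion is a convention of this generator (the published
band pattern is identical either way), as are the exact indel positions.

All output is a deterministic function of the seed.
"""

from __future__ import annotations

import random

from .errors import ConfigError, DataError, FixtureError
from .insilico_pcr import amplify
from .seq_core import (
    PDAM_F,
    PDAM_R,
    AlignmentRow,
    GappedAlignment,
    SeqRecord,
    reverse_complement,
)

BASES = "ACGT"
SITE = "AGCT"

#: reference amplicon segment lengths; junction AluI sites sit across the
#: boundaries (…AG | CT…), so complete digestion returns exactly these.
SEG_LENGTHS = (92, 116, 116, 389)
REFERENCE_AMPLICON_LENGTH = sum(SEG_LENGTHS)  # 713

#: deletion windows in reference-amplicon coordinates (half-open)
ALPHA_DELETION = (40, 48)  # 8 bp inside segment 1
BETA_DELETION = (147, 153)  # 6 bp centred in segment 2

DEFAULT_FLANK = 50
MAX_ATTEMPTS = 64

_RC_PDAM_R = reverse_complement(PDAM_R.sequence)
_FWD = PDAM_F.sequence
_MOTIFS = (_FWD, PDAM_R.sequence, _RC_PDAM_R, reverse_complement(_FWD))


def _filler(rng: random.Random, n: int) -> str:
    """Random bases that never complete an AluI site with their own suffix."""
    out: list[str] = []
    for _ in range(n):
        choices = BASES
        if len(out) >= 3 and "".join(out[-3:]) == "AGC":
            choices = "ACG"
        out.append(rng.choice(choices))
    return "".join(out)


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def _junction_site_starts() -> list[int]:
    starts, pos = [], 0
    for seg in SEG_LENGTHS[:-1]:
        pos += seg
        starts.append(pos - 2)  # site spans [cut-2, cut+2)
    return starts


def _delete(seq: str, window: tuple[int, int]) -> str:
    return seq[: window[0]] + seq[window[1] :]


def _layout_ok(template: str, flank: int) -> bool:
    """All geometric constraints for the reference template and its variants."""
    amp = template[flank : flank + REFERENCE_AMPLICON_LENGTH]
    expected = [flank + s for s in _junction_site_starts()]
    if _find_all(template, SITE) != expected:
        return False
    # deletions must not create a new site across their junction
    for window in (ALPHA_DELETION, BETA_DELETION):
        variant = (
            template[: flank + window[0]] + template[flank + window[1] :]
        )
        shift = window[1] - window[0]
        if _find_all(variant, SITE) != [
            p if p < flank + window[0] else p - shift for p in expected
        ]:
            return False
    # unique primer geometry: forward once (at the amplicon start), reverse
    # complement once (at the amplicon end), no binding in any other
    # orientation anywhere
    if _find_all(template, _FWD) != [flank]:
        return False
    if _find_all(template, _RC_PDAM_R) != [
        flank + REFERENCE_AMPLICON_LENGTH - len(_RC_PDAM_R)
    ]:
        return False
    if _find_all(template, PDAM_R.sequence) or _find_all(
        template, reverse_complement(_FWD)
    ):
        return False
    return amp.startswith(_FWD) and amp.endswith(_RC_PDAM_R)


def make_reference_template(seed: int = 1, flank: int = DEFAULT_FLANK) -> SeqRecord:
    """Deterministic reference ("other Pocillopora") template.

    The 713 bp amplicon sits between ``flank`` bp of non-amplified context
    on each side. Amplification yields exactly one product and AluI digest
    of that product gives fragments [92, 116, 116, 389].
    """
    if flank < 0:
        raise ConfigError("flank must be >= 0")
    for attempt in range(MAX_ATTEMPTS):
        rng = random.Random(seed * 10007 + attempt)
        seg1 = _FWD + _filler(rng, SEG_LENGTHS[0] - len(_FWD) - 2) + "AG"
        seg2 = "CT" + _filler(rng, SEG_LENGTHS[1] - 4) + "AG"
        seg3 = "CT" + _filler(rng, SEG_LENGTHS[2] - 4) + "AG"
        seg4 = "CT" + _filler(rng, SEG_LENGTHS[3] - 2 - len(_RC_PDAM_R)) + _RC_PDAM_R
        template = (
            _filler(rng, flank) + seg1 + seg2 + seg3 + seg4 + _filler(rng, flank)
        )
        if _layout_ok(template, flank):
            return SeqRecord(
                id=f"other-ref-s{seed}",
                residues=template,
                description=f"synthetic reference template (seed={seed}, flank={flank})",
            )
    raise FixtureError(
        f"could not satisfy layout constraints after {MAX_ATTEMPTS} attempts (seed={seed})"
    )


def amplicon_region(record: SeqRecord) -> tuple[int, int]:
    """Locate the amplicon inside a fixture template by its primer motifs."""
    starts = _find_all(record.residues, _FWD)
    ends = _find_all(record.residues, _RC_PDAM_R)
    if len(starts) != 1 or len(ends) != 1:
        raise DataError(f"record {record.id!r} is not a fixture template")
    return starts[0], ends[0] + len(_RC_PDAM_R)


def make_variant(reference: SeqRecord, lineage: str) -> SeqRecord:
    """Derive a Type alpha or Type beta template from a reference fixture.

    "alpha" removes the 8 bp window in segment 1; "beta" removes the 6 bp
    window in segment 2. Band-size arithmetic follows directly: the deleted
    fragment shrinks, the other three are untouched.
    """
    windows = {"alpha": ALPHA_DELETION, "beta": BETA_DELETION}
    if lineage not in windows:
        raise DataError(f"unknown lineage {lineage!r}; expected 'alpha' or 'beta'")
    amp_start, _ = amplicon_region(reference)
    lo, hi = windows[lineage]
    residues = _delete(reference.residues, (amp_start + lo, amp_start + hi))
    return SeqRecord(
        id=reference.id.replace("other-ref", f"{lineage}-ref"),
        residues=residues,
        description=f"synthetic Type {lineage} template derived from {reference.id}",
    )


def make_decoy(seed: int = 1, length: int = 1000) -> SeqRecord:
    """A random non-target sequence with no primer binding site on either strand.

    Stands in for the mitochondrial genomes of non-Pocillopora pocilloporid
    genera, which the assay's primers must not amplify.
    """
    if length < 100:
        raise ConfigError("decoy length must be >= 100")
    for attempt in range(MAX_ATTEMPTS):
        rng = random.Random(seed * 20011 + attempt)
        residues = "".join(rng.choice(BASES) for _ in range(length))
        if not any(_find_all(residues, motif) for motif in _MOTIFS):
            return SeqRecord(
                id=f"decoy-s{seed}",
                residues=residues,
                description=f"synthetic off-target sequence (seed={seed})",
            )
    raise FixtureError("could not generate a primer-free decoy")


def _protected_mask(record: SeqRecord) -> set[int]:
    """Template positions whose mutation could change assay geometry.

    Protects both primer regions, every AluI junction site, and (in the
    reference) the two deletion windows so that same-seed lineages stay
    column-compatible.
    """
    start, end = amplicon_region(record)
    protected: set[int] = set()
    protected.update(range(start, start + len(_FWD)))
    protected.update(range(end - len(_RC_PDAM_R), end))
    for site_start in _find_all(record.residues, SITE):
        protected.update(range(site_start, site_start + len(SITE)))
    amp_len = end - start
    if amp_len == REFERENCE_AMPLICON_LENGTH:
        for lo, hi in (ALPHA_DELETION, BETA_DELETION):
            protected.update(range(start + lo, start + hi))
    return protected


def _mutate(
    residues: str, rng: random.Random, noise_rate: float, protected: set[int]
) -> str:
    """Per-base substitution noise that never creates a forbidden motif."""
    out = list(residues)
    for i in range(len(out)):
        if i in protected or rng.random() >= noise_rate:
            continue
        alternatives = [b for b in BASES if b != out[i]]
        rng.shuffle(alternatives)
        original = out[i]
        for base in alternatives:
            out[i] = base
            window = "".join(out[max(0, i - 3) : i + 4])
            if SITE not in window:
                break
            out[i] = original
    return "".join(out)


def make_panel(
    n_alpha: int,
    n_beta: int,
    n_other: int,
    noise_rate: float = 0.01,
    seed: int = 1,
    flank: int = DEFAULT_FLANK,
) -> list[tuple[SeqRecord, str]]:
    """A labelled panel of templates emulating a typed sample collection.

    Each member is its lineage's fixture template with independent
    substitution noise applied outside the protected motifs (primer
    regions, AluI junctions, deletion windows), so its digest geometry is
    identical to the noiseless progenitor's.
    """
    if not 0 <= noise_rate <= 0.05:
        raise ConfigError(f"noise_rate {noise_rate} outside [0, 0.05]")
    reference = make_reference_template(seed, flank)
    progenitors = {
        "alpha": make_variant(reference, "alpha"),
        "beta": make_variant(reference, "beta"),
        "other": reference,
    }
    masks = {lin: _protected_mask(rec) for lin, rec in progenitors.items()}
    panel: list[tuple[SeqRecord, str]] = []
    member = 0
    for lineage, count in (("alpha", n_alpha), ("beta", n_beta), ("other", n_other)):
        progenitor = progenitors[lineage]
        for i in range(count):
            member += 1
            rng = random.Random(seed * 1000003 + member)
            residues = _mutate(progenitor.residues, rng, noise_rate, masks[lineage])
            panel.append(
                (
                    SeqRecord(
                        id=f"{lineage}-{i + 1:03d}-s{seed}",
                        residues=residues,
                        description=f"synthetic panel member, true lineage {lineage}",
                    ),
                    lineage,
                )
            )
    return panel


def make_alignment(
    seed: int = 1, rows_per_label: int = 2, noise_rate: float = 0.01
) -> GappedAlignment:
    """A gapped alignment of amplicon-region rows for indel discovery.

    Rows are the three lineage amplicons placed in reference coordinates:
    alpha rows carry an 8-column gap run, beta rows a 6-column run, and
    "other" rows none. No aligner runs — the gap columns are the known
    deletion windows. Same-label rows differ by filler substitutions.
    """
    if rows_per_label < 1:
        raise ConfigError("rows_per_label must be >= 1")
    reference = make_reference_template(seed)
    amp_start, amp_end = amplicon_region(reference)
    ref_amp = reference.residues[amp_start:amp_end]
    mask = {
        p - amp_start
        for p in _protected_mask(reference)
        if amp_start <= p < amp_end
    }
    rows: list[AlignmentRow] = []
    counter = 0
    for label in ("other", "alpha", "beta"):
        for i in range(rows_per_label):
            counter += 1
            rng = random.Random(seed * 3000017 + counter)
            # first "other" row is the exact reference amplicon
            residues = (
                ref_amp
                if label == "other" and i == 0
                else _mutate(ref_amp, rng, noise_rate, mask)
            )
            if label == "alpha":
                lo, hi = ALPHA_DELETION
                residues = residues[:lo] + "-" * (hi - lo) + residues[hi:]
            elif label == "beta":
                lo, hi = BETA_DELETION
                residues = residues[:lo] + "-" * (hi - lo) + residues[hi:]
            rows.append(
                AlignmentRow(
                    id=f"{label}-row-{i + 1}-s{seed}", residues=residues, label=label
                )
            )
    return GappedAlignment(rows=tuple(rows))


def fixture_amplicon(record: SeqRecord) -> str:
    """Convenience: the single predicted amplicon sequence of a fixture."""
    products = amplify(record, PDAM_F, PDAM_R)
    if len(products) != 1:
        raise DataError(
            f"fixture {record.id!r} produced {len(products)} amplicons, expected 1"
        )
    return products[0].sequence
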