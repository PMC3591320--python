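"""Virtual digestion, band-pattern collapse, enzyme config loading."""

import random

import pytest
import yaml
from Bio.Restriction import AluI as BioAluI
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from rflp.errors import ConfigError, DataError
from rflp.fixtures import fixture_amplicon
from rflp.seq_core import IUPAC_SETS
from rflp.virtual_digest import (
    ALU_I,
    Enzyme,
    band_pattern,
    digest,
    get_enzyme,
    load_enzymes,
)


def brute_force_digest(seq: str, site: str, cut_offset: int) -> list[int]:
    """Independent scan-and-split oracle (IUPAC-aware site match)."""
    cuts = []
    for i in range(len(seq) - len(site) + 1):
        window = seq[i : i + len(site)]
        if all(set(IUPAC_SETS[s]) & set(IUPAC_SETS[w]) for s, w in zip(site, window)):
            cut = i + cut_offset
            if 0 < cut < len(seq):
                cuts.append(cut)
    bounds = [0] + sorted(set(cuts)) + [len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


class TestDigest:
    def test_overlapping_sites_all_cut(self):
        assert digest("AGCTAGCT", ALU_I).lengths == [2, 4, 2]

    def test_no_site_single_fragment(self):
        frags = digest("TTTTTTTT", ALU_I)
        assert frags.lengths == [8]
        assert frags.cut_positions == ()

    @pytest.mark.parametrize(
        "lineage,expected",
        [
            ("alpha", [84, 116, 116, 389]),
            ("beta", [92, 110, 116, 389]),
            ("other", [92, 116, 116, 389]),
        ],
    )
    def test_fixture_amplicon_fragments(self, lineage, expected, alpha, beta, reference):
        record = {"alpha": alpha, "beta": beta, "other": reference}[lineage]
        frags = digest(fixture_amplicon(record), ALU_I)
        assert frags.lengths == expected
        assert sum(frags.lengths) == len(fixture_amplicon(record))

    def test_conservation_and_concatenation(self, reference):
        amp = fixture_amplicon(reference)
        frags = digest(amp, ALU_I)
        assert "".join(frags.fragments) == amp
        assert frags.parent_length == len(amp)

    def test_idempotent_reconstruction(self, reference):
        amp = fixture_amplicon(reference)
        frags = digest(amp, ALU_I)
        assert digest("".join(frags.fragments), ALU_I).cut_positions == frags.cut_positions

    def test_matches_brute_force_on_random_sequences(self):
        rng = random.Random(11)
        for _ in range(20):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 1000)))
            assert digest(seq, ALU_I).lengths == brute_force_digest(seq, "AGCT", 2)

    def test_matches_biopython_restriction(self, alpha, beta, reference):
        for record in (alpha, beta, reference):
            amp = fixture_amplicon(record)
            bio_fragments = [len(f) for f in BioAluI.catalyse(Seq(amp))]
            assert digest(amp, ALU_I).lengths == bio_fragments

    def test_iupac_site_in_template_cuts(self):
        # N intersects every site base: ANCT matches AGCT, cut after offset 2
        assert digest("TTTANCTTTT", ALU_I).lengths == [5, 5]

    def test_empty_sequence_rejected(self):
        with pytest.raises(DataError):
            digest("", ALU_I)


class TestBandPattern:
    def test_alpha_pattern_at_resolution_zero(self):
        pattern = band_pattern([84, 116, 116, 389])
        assert [(b.size, b.multiplicity) for b in pattern.bands] == [
            (84, 1), (116, 2), (389, 1)
        ]

    def test_beta_pattern_has_four_distinct_bands(self):
        assert band_pattern([92, 110, 116, 389]).sizes == [92, 110, 116, 389]

    def test_empty_fragment_list(self):
        assert band_pattern([]).bands == ()

    def test_min_detectable_floor(self):
        assert band_pattern([30, 84, 389], min_detectable_bp=50).sizes == [84, 389]

    def test_gel_preset_still_resolves_110_from_116(self):
        pattern = band_pattern([92, 110, 116, 389], resolution_bp=4, min_detectable_bp=50)
        assert len(pattern.bands) == 4

    def test_comigration_merges_to_group_mean(self):
        pattern = band_pattern([100, 103, 390], resolution_bp=4)
        assert [(b.size, b.multiplicity) for b in pattern.bands] == [(102, 2), (390, 1)]

    @given(
        sizes=st.lists(st.integers(min_value=1, max_value=1000), min_size=0, max_size=30),
        res_lo=st.integers(min_value=0, max_value=20),
        res_delta=st.integers(min_value=0, max_value=20),
    )
    @settings(derandomize=True)
    def test_band_count_monotone_in_resolution(self, sizes, res_lo, res_delta):
        lo = band_pattern(sizes, resolution_bp=res_lo)
        hi = band_pattern(sizes, resolution_bp=res_lo + res_delta)
        assert len(hi.bands) <= len(lo.bands)

    @given(
        sizes=st.lists(st.integers(min_value=1, max_value=1000), min_size=1, max_size=30),
        res=st.integers(min_value=0, max_value=30),
    )
    @settings(derandomize=True)
    def test_adjacent_bands_separated_by_more_than_resolution(self, sizes, res):
        pattern = band_pattern(sizes, resolution_bp=res)
        out = pattern.sizes
        assert all(b - a > res for a, b in zip(out, out[1:]))
        assert sum(b.multiplicity for b in pattern.bands) == len(sizes)


class TestEnzymeConfig:
    def test_builtin_alui(self):
        assert (ALU_I.site, ALU_I.cut_offset) == ("AGCT", 2)
        assert ALU_I.is_palindromic

    def test_config_matching_builtin(self, tmp_path):
        p = tmp_path / "enzymes.yaml"
        p.write_text(yaml.safe_dump([{"name": "AluI", "site": "AGCT", "cut": 2}]))
        (enz,) = load_enzymes(p)
        assert enz == ALU_I

    def test_cut_offset_out_of_bounds(self, tmp_path):
        p = tmp_path / "enzymes.yaml"
        p.write_text(yaml.safe_dump([{"name": "BadI", "site": "AGCT", "cut": 9}]))
        with pytest.raises(ConfigError, match="BadI"):
            load_enzymes(p)

    def test_short_site_rejected(self):
        with pytest.raises(ConfigError, match="shorter"):
            Enzyme("TinyI", "AGC", 1)

    def test_two_enzymes_order_preserved(self, tmp_path):
        p = tmp_path / "enzymes.yaml"
        p.write_text(
            yaml.safe_dump(
                [
                    {"name": "NarI", "site": "GGCGCC", "cut": 2},
                    {"name": "AluI", "site": "AGCT", "cut": 2},
                ]
            )
        )
        assert [e.name for e in load_enzymes(p)] == ["NarI", "AluI"]

    def test_get_enzyme_unknown(self):
        with pytest.raises(ConfigError, match="NoSuchEnzyme"):
            get_enzyme("NoSuchEnzyme")
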