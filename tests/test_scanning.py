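"""Anchored scanning, expected hits, anchoring specificity, conservation filter."""
import re

import numpy as np
import pytest

from ctermotif import (
    BackgroundComposition,
    OrthologGroup,
    SequenceRecord,
    anchoring_specificity_factor,
    conserved_occurrence_filter,
    expected_hits,
    generate_decoy_proteome,
    match_at_cterm,
    parse_prosite,
    scan_database,
)
from ctermotif.alphabet import AMINO_ACIDS
from ctermotif.scanning import hits_to_dataframe


def _rec(tail, sid="s", pad=20):
    return SequenceRecord(sid, "A" * pad + tail)


class TestCTermMatch:
    def test_aav2_peptide_matches_at_615_621(self, ddx3eq_pattern):
        rec = SequenceRecord("aav2_rep78", "A" * 614 + "DDCIFEQ")
        hit = match_at_cterm(ddx3eq_pattern, rec)
        assert hit is not None
        assert (hit.start, hit.end, hit.peptide) == (615, 621, "DDCIFEQ")
        assert hit.anchored and hit.end == len(rec)

    @pytest.mark.parametrize(
        "tail, matches",
        [
            ("DDCIFEQ", True),   # AAV2 Rep78 C-terminus
            ("EDDAMEQ", True),   # enterovirus D protease 2A (E allowed at position 1)
            ("DDIMWEQ", True),   # human Cep57L1
            ("DECIFEQ", False),  # degenerate: E at the strictly conserved position 2
            ("DDCPFEQ", False),  # proline at an excluded position
            ("DDCIFEA", False),  # wrong terminal residue
        ],
    )
    def test_printed_heptapeptides(self, ddx3eq_pattern, tail, matches):
        assert (match_at_cterm(ddx3eq_pattern, _rec(tail)) is not None) is matches

    def test_internal_occurrence_does_not_match_anchored(self, ddx3eq_pattern):
        rec = SequenceRecord("s", "AA" + "DDCIFEQ" + "GGGG")
        assert match_at_cterm(ddx3eq_pattern, rec) is None
        assert scan_database(ddx3eq_pattern, [rec]) == []

    def test_record_shorter_than_pattern_is_no_match(self, ddx3eq_pattern):
        assert match_at_cterm(ddx3eq_pattern, SequenceRecord("s", "EQ")) is None

    def test_unknown_residue_policy(self, ddx3eq_pattern):
        # X fails fixed and inclusion elements, fails exclusions conservatively
        assert match_at_cterm(ddx3eq_pattern, _rec("XDCIFEQ")) is None
        assert match_at_cterm(ddx3eq_pattern, _rec("DDXIFEQ")) is None
        # ...but satisfies a wildcard
        wild = parse_prosite("D-x-Q>")
        assert match_at_cterm(wild, _rec("DXQ")) is not None


class TestScanDatabase:
    def test_hits_in_input_order(self, ddx3eq_pattern):
        db = [_rec("DDCIFEQ", "hit1"), _rec("DECIFEQ", "miss"), _rec("EDDAMEQ", "hit2")]
        hits = scan_database(ddx3eq_pattern, db)
        assert [h.seq_id for h in hits] == ["hit1", "hit2"]
        assert all(h.end == len(db[0]) for h in hits)

    def test_empty_database(self, ddx3eq_pattern):
        assert scan_database(ddx3eq_pattern, []) == []

    def test_unanchored_leftmost_nonoverlapping(self):
        pat = parse_prosite("A-A")
        (h1, h2) = scan_database(pat, [SequenceRecord("s", "AAAAG")])
        assert (h1.start, h1.end, h2.start, h2.end) == (1, 2, 3, 4)

    def test_matches_regex_oracle_on_random_databases(self):
        """Hand matcher agrees with the re module on >= 1000 random instances."""
        rng = np.random.default_rng(42)
        pattern_texts = [
            "[DEP]-D-{P}-{P}-{P}-E-Q>", "D-D-x(3)-E-Q>", "Q>", "[ST]-x-{PG}",
            "A-A", "x-[DE]-x", "{P}-{P}-Q>",
        ]
        n_checked = 0
        for text in pattern_texts:
            pattern = parse_prosite(text)
            regex = re.compile(pattern.regex)
            for _ in range(200):
                L = int(rng.integers(1, 30))
                seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
                rec = SequenceRecord("r", seq)
                ours = [(h.start, h.end) for h in scan_database(pattern, [rec])]
                theirs = [
                    (m.start() + 1, m.end()) for m in regex.finditer(seq)
                ]
                assert ours == theirs, f"{text} on {seq}"
                n_checked += 1
        assert n_checked >= 1000

    def test_anchored_hits_end_at_sequence_end(self, ddx3eq_pattern):
        rng = np.random.default_rng(7)
        db = [
            SequenceRecord(f"r{i}",
                           "".join(rng.choice(list(AMINO_ACIDS), size=int(rng.integers(7, 40)))))
            for i in range(300)
        ]
        for h in scan_database(ddx3eq_pattern, db):
            assert h.end == len(next(r for r in db if r.id == h.seq_id))


class TestExpectedHits:
    BG = BackgroundComposition(
        {a: (0.04 if a == "Q" else 0.96 / 19) for a in AMINO_ACIDS},
        n_proteins=1000, mean_length=600,
    )

    def test_single_fixed_q_closed_form(self):
        pat = parse_prosite("Q>")
        assert expected_hits(pat, self.BG, anchored=True) == pytest.approx(40.0)
        assert expected_hits(pat, self.BG, anchored=False) == pytest.approx(24_000.0)

    def test_all_wildcard_anchored_equals_n_proteins(self):
        pat = parse_prosite("x-x-x")
        assert expected_hits(pat, self.BG, anchored=True) == pytest.approx(1000)

    def test_anchored_never_exceeds_unanchored(self, ddx3eq_pattern):
        a = expected_hits(ddx3eq_pattern, self.BG, anchored=True)
        u = expected_hits(ddx3eq_pattern, self.BG, anchored=False)
        assert a <= u
        bg_eq = BackgroundComposition(self.BG.freqs, 1000, mean_length=7)
        assert expected_hits(ddx3eq_pattern, bg_eq, anchored=True) == pytest.approx(
            expected_hits(ddx3eq_pattern, bg_eq, anchored=False)
        )

    def test_pattern_longer_than_mean_length_is_an_error(self):
        bg = BackgroundComposition(self.BG.freqs, 10, mean_length=3)
        with pytest.raises(ValueError, match="shorter than the pattern"):
            expected_hits(parse_prosite("Q-Q-Q-Q>"), bg)

    def test_per_protein_exact_mode(self):
        pat = parse_prosite("Q")  # unanchored single position
        got = expected_hits(pat, self.BG, anchored=False, lengths=[10, 20, 5])
        assert got == pytest.approx((10 + 20 + 5) * 0.04)

    def test_monte_carlo_decoy_agreement(self):
        """Observed anchored hit counts stay within 3 SE of expectation in
        >= 99% of seeded decoy proteomes (n_proteins = 10,000 each)."""
        pat = parse_prosite("[DE]-x-Q>")
        comp = {a: 1 / 20 for a in AMINO_ACIDS}
        P = (2 / 20) * 1.0 * (1 / 20)  # per-protein anchored match probability
        n = 10_000
        expected = n * P
        se = np.sqrt(n * P * (1 - P))
        ok = 0
        runs = 100
        for seed in range(runs):
            decoys = generate_decoy_proteome(n, (30, 60), comp, seed=seed)
            bg = BackgroundComposition(comp, n_proteins=n, mean_length=45)
            assert expected_hits(pat, bg, anchored=True) == pytest.approx(expected)
            observed = len(scan_database(pat, decoys))
            ok += abs(observed - expected) <= 3 * se
        assert ok / runs >= 0.99


class TestAnchoringSpecificity:
    def test_average_human_protein_single_residue_motif(self):
        assert anchoring_specificity_factor(600, 1) == 600.0

    def test_motif_spanning_whole_protein_gains_nothing(self):
        assert anchoring_specificity_factor(7, 7) == 1.0

    def test_seven_residue_motif(self):
        assert anchoring_specificity_factor(600, 7) == 594.0

    def test_invalid_lengths(self):
        with pytest.raises(ValueError):
            anchoring_specificity_factor(5, 7)
        with pytest.raises(ValueError):
            anchoring_specificity_factor(5, 0)


def _hit(sid):
    return [h for h in scan_database(parse_prosite("Q>"), [_rec("Q", sid, pad=5)])][0]


class TestConservationFilter:
    def _groups(self):
        return [
            OrthologGroup("g1", (("a", "human"), ("b", "mouse"), ("c", "frog"))),
            OrthologGroup("g2", (("d", "human"),)),
        ]

    def test_motif_in_two_of_three_species_retained(self):
        hits = [_hit("a"), _hit("b")]
        kept = conserved_occurrence_filter(hits, self._groups(), min_others=1)
        assert [h.seq_id for h in kept] == ["a", "b"]

    def test_singleton_group_hit_removed(self):
        assert conserved_occurrence_filter([_hit("d")], self._groups(), 1) == []

    def test_min_others_zero_is_identity_on_grouped_hits(self):
        hits = [_hit("a"), _hit("d")]
        assert conserved_occurrence_filter(hits, self._groups(), 0) == hits

    def test_ungrouped_hit_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            kept = conserved_occurrence_filter([_hit("zzz")], self._groups(), 0)
        assert kept == [] and "zzz" in caplog.text

    def test_sequence_in_two_groups_is_an_error(self):
        groups = self._groups() + [OrthologGroup("g3", (("a", "human"),))]
        with pytest.raises(ValueError, match="two groups|appears in groups"):
            conserved_occurrence_filter([_hit("a")], groups, 1)

    def test_filter_is_idempotent(self):
        hits = [_hit("a"), _hit("b"), _hit("d")]
        once = conserved_occurrence_filter(hits, self._groups(), 1)
        twice = conserved_occurrence_filter(once, self._groups(), 1)
        assert once == twice

    def test_hits_table_columns_and_flags(self):
        hits = [_hit("a"), _hit("b"), _hit("d")]
        kept = conserved_occurrence_filter(hits, self._groups(), 1)
        df = hits_to_dataframe(hits, self._groups(), kept)
        assert list(df.columns) == [
            "seq_id", "start", "end", "peptide", "group_id",
            "retained_by_conservation_filter",
        ]
        assert df["retained_by_conservation_filter"].tolist() == [1, 1, 0]
        assert df["group_id"].tolist() == ["g1", "g1", "g2"]
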