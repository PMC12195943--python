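"""Cleavage-rule engine: site enumeration, release modes, oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capripep import CleavageRule, Enzyme, ProteinSequence, cut_sites, digest
from capripep.digestion import C_TERMINAL, N_TERMINAL, load_enzyme_table
from capripep.errors import ConfigError

LETTERS = sorted("ACDEFGHIKLMNPQRSTVWY")


def brute_force_sites(residues: str, enzymes) -> list[int]:
    """Independent per-boundary oracle: test every inter-residue boundary
    against every rule of every enzyme."""
    n = len(residues)
    sites = set()
    for p in range(1, n):  # boundary between residue p and p+1 (1-based)
        for enzyme in enzymes:
            for rule in enzyme.rules:
                if rule.side == C_TERMINAL:
                    if (residues[p - 1] == rule.target_residue
                            and residues[p] not in rule.blocked_by_next):
                        sites.add(p)
                else:
                    if (residues[p] == rule.target_residue
                            and residues[p - 1] not in rule.blocked_by_next):
                        sites.add(p)
    return sorted(sites)


class TestRuleValidation:
    def test_default_table_rule_counts(self, enzymes_by_name):
        assert len(enzymes_by_name["pepsin"].rules) == 2
        assert len(enzymes_by_name["trypsin"].rules) == 2
        assert len(enzymes_by_name["chymotrypsin A"].rules) == 8

    def test_empty_rule_list_rejected(self):
        with pytest.raises(ConfigError, match="empty rule list"):
            Enzyme(name="noop", ec_number="0", rules=())

    def test_duplicate_rule_rejected(self):
        rules = (CleavageRule("K", C_TERMINAL), CleavageRule("K", C_TERMINAL))
        with pytest.raises(ConfigError, match="duplicate"):
            Enzyme(name="dup", ec_number="0", rules=rules)

    def test_invalid_residue_rejected(self):
        with pytest.raises(ConfigError):
            CleavageRule("J", C_TERMINAL)

    def test_config_error_names_key_path(self, tmp_path):
        p = tmp_path / "enzymes.yaml"
        p.write_text(
            "enzymes:\n  - name: broken\n    rules:\n"
            "      - {residue: K, side: sideways}\n"
        )
        with pytest.raises(ConfigError, match=r"enzymes\[0\]"):
            load_enzyme_table(p)

    def test_blocked_by_next_suppresses_cut(self, tmp_path):
        p = tmp_path / "enzymes.yaml"
        p.write_text(
            "enzymes:\n  - name: trypsin-strict\n    ec: 3.4.21.4\n    rules:\n"
            "      - {residue: K, side: C-terminal, blocked_by_next: [P]}\n"
            "      - {residue: R, side: C-terminal}\n"
        )
        (tryp_strict,) = load_enzyme_table(p)
        seq = ProteinSequence(id="s", residues="AKPR")
        # K|P blocked; only the site after R... R is terminal, so no site
        # after it either -- but the boundary before R? C-terminal rules only.
        assert cut_sites(seq, [tryp_strict]) == []
        seq2 = ProteinSequence(id="s2", residues="AKPRG")
        assert cut_sites(seq2, [tryp_strict]) == [4]


class TestCutSites:
    def test_single_lysine(self, trypsin):
        seq = ProteinSequence(id="s", residues="AKF")
        assert cut_sites(seq, [trypsin]) == [2]

    def test_pepsin_two_sites(self, pepsin):
        seq = ProteinSequence(id="s", residues="AFLG")
        assert cut_sites(seq, [pepsin]) == [2, 3]

    def test_terminal_residue_never_cuts(self, trypsin):
        assert cut_sites(ProteinSequence(id="s", residues="AGK"), [trypsin]) == []

    def test_n_terminal_rule_on_first_residue_never_cuts(self, enzymes_by_name):
        chymo = enzymes_by_name["chymotrypsin A"]
        assert cut_sites(ProteinSequence(id="s", residues="IAG"), [chymo]) == []
        # interior I cuts before it
        assert 1 in cut_sites(ProteinSequence(id="s", residues="AIG"), [chymo])

    def test_matches_brute_force_on_random_sequences(self, enzymes):
        rng = np.random.default_rng(11)
        for _ in range(50):
            residues = "".join(rng.choice(LETTERS, 30))
            seq = ProteinSequence(id="r", residues=residues)
            assert cut_sites(seq, enzymes) == brute_force_sites(residues, enzymes)

    def test_adding_an_enzyme_never_removes_sites(self, enzymes):
        rng = np.random.default_rng(13)
        for _ in range(20):
            residues = "".join(rng.choice(LETTERS, 40))
            seq = ProteinSequence(id="r", residues=residues)
            partial_sets = [set(cut_sites(seq, enzymes[:k]))
                            for k in range(1, len(enzymes) + 1)]
            for smaller, larger in zip(partial_sets, partial_sets[1:]):
                assert smaller <= larger


class TestDigest:
    def test_complete_single_cut(self, trypsin):
        result = digest(ProteinSequence(id="s", residues="AKF"), [trypsin])
        assert [p.sequence for p in result.peptides] == ["AK", "F"]
        assert [(p.start, p.end) for p in result.peptides] == [(1, 2), (3, 3)]

    def test_complete_two_cuts(self, pepsin):
        result = digest(ProteinSequence(id="s", residues="AFLG"), [pepsin])
        assert [p.sequence for p in result.peptides] == ["AF", "L", "G"]

    def test_no_matching_residue_yields_whole_sequence(self, trypsin):
        result = digest(ProteinSequence(id="s", residues="GGAG"), [trypsin])
        assert [p.sequence for p in result.peptides] == ["GGAG"]

    def test_partial_enumerates_all_boundary_pairs(self, trypsin):
        result = digest(ProteinSequence(id="s", residues="AKRG"), [trypsin],
                        mode="partial")
        assert {p.sequence for p in result.peptides} == {
            "AK", "R", "G", "AKR", "RG", "AKRG"
        }
        # brute force: boundaries {0,2,3,4}, all ordered pairs
        boundaries = [0, 2, 3, 4]
        expected = {
            ("AKRG"[lo:hi], lo + 1, hi)
            for lo, hi in itertools.combinations(boundaries, 2)
        }
        assert set(result.peptides) == expected

    def test_partial_superset_of_complete(self, enzymes):
        rng = np.random.default_rng(17)
        for _ in range(20):
            residues = "".join(rng.choice(LETTERS, 25))
            seq = ProteinSequence(id="r", residues=residues)
            comp = set(digest(seq, enzymes, mode="complete").peptides)
            part = set(digest(seq, enzymes, mode="partial").peptides)
            assert comp <= part

    def test_partial_interval_count_is_choose_k_plus_2_2(self, trypsin):
        # k cut sites -> C(k+2, 2) intervals, checked by construction
        for k in range(7):
            residues = "A" + "KA" * k  # k interior lysines, none terminal
            seq = ProteinSequence(id="r", residues=residues)
            result = digest(seq, [trypsin], mode="partial")
            assert len(result.cut_sites) == k
            assert result.n_intervals == (k + 2) * (k + 1) // 2

    def test_complete_peptide_count_is_sites_plus_one(self, enzymes):
        rng = np.random.default_rng(19)
        for _ in range(20):
            residues = "".join(rng.choice(LETTERS, 30))
            seq = ProteinSequence(id="r", residues=residues)
            result = digest(seq, enzymes)
            assert result.n_intervals == len(result.cut_sites) + 1

    def test_determinism(self, enzymes):
        seq = ProteinSequence(id="s", residues="MKWYPFLAGRID")
        assert digest(seq, enzymes) == digest(seq, enzymes)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.text(alphabet=LETTERS, min_size=1, max_size=60))
    def test_complete_fragments_concatenate_to_source(self, residues):
        """Complete-mode peptides partition the protein for any input."""
        seq = ProteinSequence(id="h", residues=residues)
        from capripep import default_enzymes

        result = digest(seq, default_enzymes())
        assert "".join(p.sequence for p in result.peptides) == residues
        starts = [p.start for p in result.peptides]
        ends = [p.end for p in result.peptides]
        assert starts[0] == 1 and ends[-1] == len(residues)
        assert all(s == e + 1 for s, e in zip(starts[1:], ends))
        for p in result.peptides:
            assert residues[p.start - 1 : p.end] == p.sequence

    def test_cross_check_against_pyteomics_cleave(self, trypsin):
        """Independent implementation check: our complete-mode trypsin
        fragments match pyteomics' cleavage on the same no-exception rule."""
        from pyteomics import parser as pt_parser

        rng = np.random.default_rng(23)
        for _ in range(20):
            residues = "".join(rng.choice(LETTERS, 35))
            seq = ProteinSequence(id="r", residues=residues)
            ours = set(digest(seq, [trypsin]).sequences())
            theirs = pt_parser.cleave(residues, r"(?<=[KR])", missed_cleavages=0)
            assert ours == set(theirs)
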