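"""Signature parsing, match enumeration, architecture selection, CTM, GFF3."""

import random

import pytest

from cysdom.seq_core import SequenceRecord
from cysdom.signature import (
    DEFAULT_SIGNATURE,
    CysteineSignature,
    DomainMatch,
    ScanConfig,
    SignatureParseError,
    annotate,
    detect_ctm,
    enumerate_matches,
    find_partial_matches,
    parse_signature,
    read_gff3,
    select_architecture,
    write_gff3,
)

from conftest import brute_force_best_subset, brute_force_matches, random_protein

TOY_DOMAIN = (
    "C" + "A" * 4 + "C" + "A" * 5 + "C" + "A" * 4 + "C" + "A" + "C"
    + "A" * 4 + "C" + "A" * 3 + "C" + "A" * 9 + "C" + "A" * 2 + "C" + "A"
)  # minimal-gap realization of the default signature, 42 residues


class TestParse:
    def test_default_signature_string(self):
        sig = parse_signature(
            "C-x(4)-C-x(5)-C-x(4,6)-C-x(1)-C-x(4,5)-C-x(3,4)-C-x(9,10)-C-x(2,3)-C-x(1)"
        )
        assert sig == DEFAULT_SIGNATURE
        assert sig.n_cys == 9

    def test_two_cys_signature(self):
        sig = parse_signature("C-x(0)-C-x(1)")
        assert sig.gaps == ((0, 0),) and sig.trailing_gap == (1, 1)

    def test_case_insensitive_and_round_trip(self):
        sig = parse_signature("c-X(2,3)-c")
        assert sig.trailing_gap == (0, 0)
        assert parse_signature(sig.to_spec()) == sig
        assert parse_signature(DEFAULT_SIGNATURE.to_spec()) == DEFAULT_SIGNATURE

    @pytest.mark.parametrize(
        "bad",
        ["C-x(5,3)-C", "C", "x(3)-C-x(2)-C", "C-x(2)-x(3)-C", "C-q(3)-C", "C-C"],
    )
    def test_malformed_rejected(self, bad):
        with pytest.raises(SignatureParseError):
            parse_signature(bad)

    def test_error_reports_offset(self):
        with pytest.raises(SignatureParseError, match="offset"):
            parse_signature("C-x(5,3)-C")


class TestEnumerate:
    def test_toy_domain_single_match(self):
        rec = SequenceRecord(id="toy", residues=TOY_DOMAIN)
        (m,) = enumerate_matches(rec)
        assert (m.start, m.end) == (0, 42)
        assert m.cys_positions == (0, 5, 11, 16, 18, 23, 27, 37, 40)
        assert m.complete and m.prefix_len == 9

    def test_no_cysteines_no_matches(self):
        assert enumerate_matches(SequenceRecord(id="a", residues="AAAA")) == []

    def test_matches_anchor_on_cysteines(self, rng):
        for _ in range(20):
            seq = random_protein(rng, 300, 0.15)
            for m in enumerate_matches(SequenceRecord(id="r", residues=seq)):
                assert all(seq[p] == "C" for p in m.cys_positions)
                assert m.start == m.cys_positions[0]
                assert m.end == m.cys_positions[-1] + 1 + DEFAULT_SIGNATURE.trailing_gap[0]
                for (a, b), (lo, hi) in zip(
                    zip(m.cys_positions, m.cys_positions[1:]), DEFAULT_SIGNATURE.gaps
                ):
                    assert lo <= b - a - 1 <= hi
                    assert "C" not in seq[a + 1 : b]

    @pytest.mark.parametrize("allow_cys", [False, True])
    def test_equals_brute_force_oracle(self, rng, allow_cys):
        """DFS enumeration == exhaustive cysteine-tuple enumeration."""
        for _ in range(150):
            length = rng.randint(30, 500)
            seq = random_protein(rng, length, rng.uniform(0.05, 0.20))
            rec = SequenceRecord(id="r", residues=seq)
            got = [m.cys_positions for m in enumerate_matches(rec, allow_cys_in_spacer=allow_cys)]
            assert sorted(got) == brute_force_matches(seq, DEFAULT_SIGNATURE, allow_cys)
            assert got == sorted(got)  # lexicographic output order

    def test_gap_widening_monotonicity(self, rng):
        """Widening any gap range never loses matches."""
        base = DEFAULT_SIGNATURE
        for _ in range(10):
            seq = random_protein(rng, 400, 0.15)
            rec = SequenceRecord(id="r", residues=seq)
            n_base = len(enumerate_matches(rec, base))
            for k in range(len(base.gaps)):
                gaps = list(base.gaps)
                lo, hi = gaps[k]
                gaps[k] = (max(0, lo - 1), hi + 1)
                wider = CysteineSignature(gaps=tuple(gaps), trailing_gap=base.trailing_gap)
                assert len(enumerate_matches(rec, wider)) >= n_base


def _mk(start, end, seq_id="s"):
    return DomainMatch(
        seq_id=seq_id,
        start=start,
        end=end,
        cys_positions=(start, end - 2),
        complete=True,
        prefix_len=9,
    )


class TestSelectArchitecture:
    def test_disjoint_matches_all_retained(self):
        ms = [_mk(0, 10), _mk(20, 30)]
        assert select_architecture(ms) == sorted(ms, key=lambda m: m.start)

    def test_tie_break_prefers_leftmost(self):
        left, right = _mk(0, 10), _mk(1, 11)
        assert select_architecture([right, left]) == [left]

    def test_mixed_seq_ids_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            select_architecture([_mk(0, 10, "a"), _mk(20, 30, "b")])

    def test_equals_exhaustive_subset_oracle(self, rng):
        """DP == brute force over all subsets, 500 fuzz cases."""
        for _ in range(500):
            n = rng.randint(0, 12)
            ms = []
            for _k in range(n):
                start = rng.randint(0, 60)
                ms.append(_mk(start, start + rng.randint(2, 25)))
            got = select_architecture(ms)
            exp_n, exp_keys = brute_force_best_subset(ms)
            assert len(got) == exp_n
            assert [(m.start, m.end) for m in got] == exp_keys


class TestPartials:
    def test_truncated_domain_detected(self):
        # keep the first 5 skeleton cysteines, then diverge (no more Cys)
        prefix = TOY_DOMAIN[:19]  # through the 5th cysteine at position 18
        seq = prefix + "A" * 23
        (p,) = find_partial_matches(SequenceRecord(id="t", residues=seq), min_prefix=4)
        assert not p.complete
        assert p.prefix_len == 5
        assert p.cys_positions == (0, 5, 11, 16, 18)
        assert (p.start, p.end) == (0, 19)

    def test_prefix_length_five_matches_prefix_signature_oracle(self):
        """A detected partial is exactly a match of the truncated signature."""
        prefix_sig = DEFAULT_SIGNATURE.prefix(5)
        seq = TOY_DOMAIN[:19] + "A" * 23
        rec = SequenceRecord(id="t", residues=seq)
        (p,) = find_partial_matches(rec, min_prefix=4)
        oracle = brute_force_matches(seq, prefix_sig)
        assert p.cys_positions in oracle

    def test_all_alanine_no_partials(self):
        assert find_partial_matches(SequenceRecord(id="a", residues="A" * 50)) == []

    def test_masked_regions_excluded(self):
        seq = TOY_DOMAIN[:19] + "A" * 23
        rec = SequenceRecord(id="t", residues=seq)
        assert find_partial_matches(rec, mask=[(0, 42)]) == []

    def test_min_prefix_out_of_range(self):
        rec = SequenceRecord(id="t", residues=TOY_DOMAIN)
        with pytest.raises(ValueError):
            find_partial_matches(rec, min_prefix=1)
        with pytest.raises(ValueError):
            find_partial_matches(rec, min_prefix=9)

    def test_complete_domains_are_not_partials(self):
        rec = SequenceRecord(id="t", residues=TOY_DOMAIN)
        assert find_partial_matches(rec, min_prefix=4) == []


class TestCtm:
    def test_basic_detection(self):
        seq = TOY_DOMAIN + "GG" + "CAACAAAP" + "GG"
        rec = SequenceRecord(id="t", residues=seq)
        (m,) = enumerate_matches(rec)
        ctm = detect_ctm(rec, [m], window=20)
        assert ctm.present
        assert rec.residues[ctm.cxxc_start] == "C"
        assert rec.residues[ctm.cxxc_start + 3] == "C"
        assert rec.residues[ctm.proline_pos] == "P"
        assert ctm.proline_pos - (ctm.cxxc_start + 3) == 4

    def test_no_proline_within_window(self):
        seq = TOY_DOMAIN + "CAAC" + "A" * 30 + "P"
        rec = SequenceRecord(id="t", residues=seq)
        (m,) = enumerate_matches(rec)
        assert not detect_ctm(rec, [m], window=20).present

    def test_nothing_after_last_domain(self):
        rec = SequenceRecord(id="t", residues=TOY_DOMAIN)
        (m,) = enumerate_matches(rec)
        assert not detect_ctm(rec, [m]).present

    def test_cxc_with_cys_inside_not_cxxc(self):
        seq = TOY_DOMAIN + "CCCCAAAP"  # contains C-CC-C but no C-X2-C pair
        rec = SequenceRecord(id="t", residues=seq)
        (m,) = enumerate_matches(rec)
        assert not detect_ctm(rec, [m], window=20).present


class TestAnnotateAndGff:
    def test_empty_cysteine_protein(self):
        arch = annotate(SequenceRecord(id="a", residues="AGAGAGAG"))
        assert arch.domains == () and not arch.ctm.present

    def test_architecture_invariants_on_random_sequences(self, rng):
        for _ in range(30):
            seq = random_protein(rng, 400, 0.15)
            arch = annotate(SequenceRecord(id="r", residues=seq))
            comp = arch.complete_domains
            for a, b in zip(comp, comp[1:]):
                assert a.end <= b.start
            for p in arch.partial_domains:
                assert all(not (p.start < c.end and c.start < p.end) for c in comp)
            if arch.ctm.present and comp:
                assert arch.ctm.cxxc_start >= max(c.end for c in comp)

    def test_gff3_round_trip(self, tmp_path, rng):
        recs = [
            SequenceRecord(id=f"r{i}", residues=random_protein(rng, 300, 0.15))
            for i in range(10)
        ]
        archs = {r.id: annotate(r) for r in recs}
        path = tmp_path / "d.gff3"
        write_gff3(archs.values(), path)
        assert path.read_text().startswith("##gff-version 3\n")
        back = read_gff3(path)
        for seq_id, arch in archs.items():
            if arch.domains or arch.ctm.present:
                assert back[seq_id].domains == arch.domains
                assert back[seq_id].ctm == arch.ctm

    def test_gff3_coordinates_one_based_inclusive(self, tmp_path):
        rec = SequenceRecord(id="toy", residues=TOY_DOMAIN)
        path = tmp_path / "toy.gff3"
        write_gff3([annotate(rec)], path)
        line = [l for l in path.read_text().splitlines() if "antistasin" in l][0]
        fields = line.split("\t")
        assert (fields[3], fields[4]) == ("1", "42")

    def test_empty_architecture_header_only(self, tmp_path):
        path = tmp_path / "e.gff3"
        write_gff3([], path)
        assert path.read_text() == "##gff-version 3\n"
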