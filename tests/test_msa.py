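"""Alignment engines, the column/residue lookup, and alignment reloading."""

import stat

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import random_profile_set
from oracles import exhaustive_alignment_score
from ringeralign.msa import (
    AlignmentError,
    AlignmentIndex,
    align,
    align_external,
    build_lookup,
    nw_align,
    reload_alignment,
    sub_score,
)
from ringeralign.ringer_io import ResidueId
from ringeralign.seqextract import ExtractedSequence, extract_sequence


def _seq(label, letters, start=1, chain="A"):
    from ringeralign.restypes import ONE_TO_THREE

    prov = [ResidueId(chain, start + i, res_name=ONE_TO_THREE.get(c, "UNK"))
            for i, c in enumerate(letters)]
    return ExtractedSequence(label, letters, prov)


# ---------------------------------------------------------------- pairwise NW


def test_identical_sequences_align_without_gaps():
    ai = align([_seq("a", "MKTAYIA"), _seq("b", "MKTAYIA")])
    assert ai.rows == {"a": "MKTAYIA", "b": "MKTAYIA"}
    for col in range(1, 8):
        assert ai.lookup("a", col).res_num == col
        assert ai.lookup("b", col).res_num == col


def test_single_deletion_opens_gap_at_missing_letter():
    ai = align([_seq("a", "ACDEFG"), _seq("b", "ACEFG")])
    assert ai.rows["a"] == "ACDEFG"
    assert ai.rows["b"] == "AC-EFG"


@pytest.mark.parametrize("seed", range(8))
def test_nw_score_matches_biopython_aligner(seed):
    """Gotoh scores agree with Bio.Align.PairwiseAligner as an independent oracle."""
    from Bio import Align

    rng = np.random.default_rng(seed)
    alpha = "ARNDCQEGHILKMFPSTWYV"
    a = "".join(rng.choice(list(alpha), size=rng.integers(5, 20)))
    b = "".join(rng.choice(list(alpha), size=rng.integers(5, 20)))
    score, ra, rb = nw_align(a, b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -1
    assert score == pytest.approx(aligner.score(a, b))
    assert ra.replace("-", "") == a and rb.replace("-", "") == b


@pytest.mark.parametrize("seed", range(12))
def test_nw_matches_exhaustive_enumeration(seed):
    """Optimal score equals full enumeration of all affine-gap alignments."""
    rng = np.random.default_rng(100 + seed)
    alpha = list("ACDE")
    n, m = int(rng.integers(1, 7)), int(rng.integers(1, 7))
    a = "".join(rng.choice(alpha, size=n))
    b = "".join(rng.choice(alpha, size=m))
    score, _, _ = nw_align(a, b)
    assert score == pytest.approx(exhaustive_alignment_score(a, b, sub_score))


def test_nw_matches_exhaustive_at_length_eight():
    rng = np.random.default_rng(42)
    for _ in range(3):
        a = "".join(rng.choice(list("ACDE"), size=8))
        b = "".join(rng.choice(list("ACDE"), size=8))
        score, _, _ = nw_align(a, b)
        assert score == pytest.approx(exhaustive_alignment_score(a, b, sub_score))


def test_x_scores_zero():
    assert sub_score("X", "W") == 0.0
    assert sub_score("A", "X") == 0.0


# ------------------------------------------------------------------- lookup


def test_lookup_example_and_reverse():
    prov = [ResidueId("A", 93, res_name="ASP"), ResidueId("A", 95, res_name="SER")]
    ai = build_lookup({"m": "D-S"}, {"m": prov})
    assert ai.lookup("m", 1).res_num == 93
    assert ai.lookup("m", 2) is None
    assert ai.lookup("m", 3).res_num == 95
    assert ai.reverse("m", prov[1]) == 3


def test_lookup_length_mismatch_names_row():
    with pytest.raises(AlignmentError, match="'m'"):
        build_lookup({"m": "DES"}, {"m": [ResidueId("A", 1, res_name="ASP")]})


@pytest.mark.parametrize("seed", range(5))
def test_lookup_reverse_mutual_inverse_fuzz(seed):
    rng = np.random.default_rng(seed)
    pset = random_profile_set(rng, "a", n_residues=10)
    other = random_profile_set(rng, "b", n_residues=10)
    seqs = [extract_sequence(pset), extract_sequence(other)]
    ai = align(seqs)
    for label in ai.labels:
        cols = []
        for col in range(1, ai.column_count + 1):
            rid = ai.lookup(label, col)
            if rid is not None:
                assert ai.reverse(label, rid) == col
                cols.append(col)
        # monotonicity: residue columns strictly increase with sequence position
        assert cols == sorted(cols)
        # residue conservation: every provenance entry appears exactly once
        seq = next(s for s in seqs if s.model_label == label)
        assert len(cols) == len(seq.provenance)


# --------------------------------------------------------------- progressive


def test_three_way_progressive_alignment_properties():
    seqs = [
        _seq("h", "MKLVDEFGHIK"),
        _seq("c", "MKLDEFGHK"),
        _seq("t", "MKLVDEGHIK"),
    ]
    ai = align(seqs)
    assert set(ai.rows) == {"h", "c", "t"}
    for s in seqs:
        assert ai.rows[s.model_label].replace("-", "") == s.letters


def test_align_requires_two_nonempty():
    with pytest.raises(AlignmentError, match="at least two"):
        align([_seq("a", "MK")])
    with pytest.raises(AlignmentError, match="empty"):
        align([_seq("a", "MK"), ExtractedSequence("b", "", [])])


# ------------------------------------------------------------------ external


def _stub_aligner(tmp_path, body: str) -> str:
    path = tmp_path / "fake_aligner"
    path.write_text("#!/bin/sh\n" + body)
    path.chmod(path.stat().st_mode | stat.S_IEXEC)
    return str(path)


def test_external_engine_contract_v5(tmp_path):
    # stub obeys `-align in -output out` and emits a valid alignment
    exe = _stub_aligner(
        tmp_path,
        'printf ">a\\nAC-DE\\n>b\\nACWDE\\n" > "$4"\n',
    )
    seqs = [_seq("a", "ACDE"), _seq("b", "ACWDE")]
    ai = align(seqs, engine="external", executable=exe)
    assert ai.rows == {"a": "AC-DE", "b": "ACWDE"}


def test_external_engine_nonzero_exit_carries_stderr(tmp_path):
    exe = _stub_aligner(tmp_path, 'echo "boom" >&2\nexit 3\n')
    with pytest.raises(AlignmentError, match="boom"):
        align([_seq("a", "ACDE"), _seq("b", "ACDE")],
              engine="external", executable=exe)


def test_external_engine_mutating_output_rejected(tmp_path):
    exe = _stub_aligner(
        tmp_path, 'printf ">a\\nACDF\\n>b\\nACDE\\n" > "$4"\n')
    with pytest.raises(AlignmentError, match="mismatch at ungapped position 4"):
        align([_seq("a", "ACDE"), _seq("b", "ACDE")],
              engine="external", executable=exe)


def test_external_engine_missing_executable():
    with pytest.raises(AlignmentError, match="not found"):
        align_external([_seq("a", "ACDE"), _seq("b", "ACDE")],
                       executable="definitely-not-an-aligner-xyz")


# -------------------------------------------------------------------- reload


def test_save_reload_identity(tmp_path):
    seqs = [_seq("a", "ACDEFG"), _seq("b", "ACEFG")]
    ai = align(seqs)
    f = ai.write_alignment_fasta(tmp_path / "aln.fasta")
    ai2 = reload_alignment(f, seqs)
    assert ai2.rows == ai.rows
    assert ai2.to_lookup_frame().equals(ai.to_lookup_frame())


def test_reload_accepts_gap_shift_edit(tmp_path):
    seqs = [_seq("a", "ACDEFG"), _seq("b", "ACEFG")]
    f = tmp_path / "edited.fasta"
    f.write_text(">a\nACDEFG\n>b\n-ACEFG\n")  # letters preserved, gaps moved
    ai = reload_alignment(f, seqs)
    assert ai.rows["b"] == "-ACEFG"
    assert ai.lookup("b", 1) is None
    assert ai.lookup("b", 2).res_num == 1


def test_reload_rejects_letter_deletion(tmp_path):
    seqs = [_seq("a", "ACDEFG"), _seq("b", "ACEFG")]
    f = tmp_path / "edited.fasta"
    f.write_text(">a\nACDEFG\n>b\nAC-FG-\n")  # 'E' deleted
    with pytest.raises(AlignmentError, match="mismatch"):
        reload_alignment(f, seqs)


@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=12),
       st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=12))
def test_alignment_conserves_residues_property(a, b):
    """For arbitrary sequences the builtin engine never loses or mutates letters."""
    ai = align([_seq("p", a), _seq("q", b, chain="B")])
    assert ai.rows["p"].replace("-", "") == a
    assert ai.rows["q"].replace("-", "") == b
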