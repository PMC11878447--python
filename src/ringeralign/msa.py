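"""Multiple sequence alignment and residue re-indexing.

Homologous structures number residues differently (mutations, deletions,
renumbering offsets), so profiles cannot be compared by author residue
number.  Sequences extracted from the Ringer output are aligned, and every
residue is re-indexed by its alignment column; the bidirectional lookup
between columns and original (chain, residue number) identities is the
:class:`AlignmentIndex`.

Two alignment engines are provided:

* ``external`` — shells out to a MUSCLE-compatible executable
  (``<aligner> -align in.fasta -output out.fasta``; a ``dialect="v3"``
  hook switches to the older ``-in/-out`` flags).  This is the recommended
  engine for production comparisons.
* ``builtin`` — a self-contained progressive aligner (pairwise global
  Needleman–Wunsch with the Gotoh affine-gap recurrence, BLOSUM62,
  gap open −10 / extend −1, guide order by descending pairwise identity)
  so the pipeline runs without any external binary.

A gap of length k costs open + (k−1)·extend.  Traceback tie-breaking is
deterministic: diagonal, then up (gap in the second sequence), then left.
Either way the alignment is validated: ungapping each output row must
reproduce the input sequence exactly, otherwise a hard error is raised.
"""

from __future__ import annotations

import csv
import shutil
import subprocess
import tempfile
from pathlib import Path

import pandas as pd
from Bio.Align import substitution_matrices

from .ringer_io import ResidueId
from .seqextract import ExtractedSequence, read_fasta, write_fasta

GAP = "-"
GAP_OPEN = -10.0
GAP_EXTEND = -1.0

_NEG = float("-inf")
_B62 = substitution_matrices.load("BLOSUM62")
_B62_ALPHA = set(_B62.alphabet)


class AlignmentError(RuntimeError):
    """Raised when an aligner fails or its output loses/mutates residues."""


def sub_score(a: str, b: str) -> float:
    """BLOSUM62 substitution score; 'X' and unknown letters score 0."""
    if a == "X" or b == "X" or a not in _B62_ALPHA or b not in _B62_ALPHA:
        return 0.0
    return float(_B62[a, b])


# ---------------------------------------------------------------------------
# pairwise / profile Gotoh core


def _gotoh(n: int, m: int, score) -> tuple[float, list[str]]:
    """Affine-gap global alignment over an n x m score function.

    Returns (best score, ops) where ops is a start-to-end list of 'D'
    (consume one of each), 'U' (consume from the first object, gap in the
    second) and 'L' (gap in the first, consume from the second).  Ties are
    broken preferring the match state, then 'U', then 'L'.
    """
    # state 0 = M (diagonal), 1 = Ix (up), 2 = Iy (left)
    S = [[[_NEG] * 3 for _ in range(m + 1)] for _ in range(n + 1)]
    P: list[list[list[int]]] = [[[-1] * 3 for _ in range(m + 1)] for _ in range(n + 1)]
    S[0][0][0] = 0.0
    for i in range(1, n + 1):
        S[i][0][1] = GAP_OPEN + (i - 1) * GAP_EXTEND
        P[i][0][1] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        S[0][j][2] = GAP_OPEN + (j - 1) * GAP_EXTEND
        P[0][j][2] = 0 if j == 1 else 2

    def argbest(cands: list[float]) -> tuple[float, int]:
        best, idx = _NEG, -1
        for k, v in enumerate(cands):  # order encodes the tie-break
            if v > best:
                best, idx = v, k
        return best, idx

    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                s = score(i - 1, j - 1)
                best, k = argbest([S[i - 1][j - 1][0], S[i - 1][j - 1][1],
                                   S[i - 1][j - 1][2]])
                if best > _NEG:
                    S[i][j][0] = best + s
                    P[i][j][0] = k
            if i > 0 and j >= 0 and not (i >= 1 and j == 0):  # interior Ix
                best, k = argbest([S[i - 1][j][0] + GAP_OPEN,
                                   S[i - 1][j][1] + GAP_EXTEND,
                                   S[i - 1][j][2] + GAP_OPEN])
                if j > 0 and best > S[i][j][1]:
                    S[i][j][1] = best
                    P[i][j][1] = k
            if j > 0 and i > 0:
                best, k = argbest([S[i][j - 1][0] + GAP_OPEN,
                                   S[i][j - 1][1] + GAP_OPEN,
                                   S[i][j - 1][2] + GAP_EXTEND])
                if best > S[i][j][2]:
                    S[i][j][2] = best
                    P[i][j][2] = k

    final, state = argbest(list(S[n][m]))
    ops: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        prev = P[i][j][state]
        if state == 0:
            ops.append("D")
            i, j = i - 1, j - 1
        elif state == 1:
            ops.append("U")
            i -= 1
        else:
            ops.append("L")
            j -= 1
        state = prev
    ops.reverse()
    return final, ops


def nw_align(a: str, b: str) -> tuple[float, str, str]:
    """Global pairwise alignment of two sequences; returns (score, row_a, row_b)."""
    score, ops = _gotoh(len(a), len(b), lambda i, j: sub_score(a[i], b[j]))
    ra, rb = [], []
    i = j = 0
    for op in ops:
        if op == "D":
            ra.append(a[i]); rb.append(b[j]); i += 1; j += 1
        elif op == "U":
            ra.append(a[i]); rb.append(GAP); i += 1
        else:
            ra.append(GAP); rb.append(b[j]); j += 1
    return score, "".join(ra), "".join(rb)


def _pairwise_identity(a: str, b: str) -> float:
    _, ra, rb = nw_align(a, b)
    matches = sum(1 for x, y in zip(ra, rb) if x == y and x != GAP)
    return matches / max(len(a), len(b), 1)


def _align_seq_to_rows(rows: list[str], seq: str) -> tuple[list[str], str]:
    """Align one sequence against existing gapped rows (profile alignment).

    A letter scores against a column as the mean BLOSUM62 score over the
    column's non-gap letters.  Returns (rows with new gap columns inserted,
    gapped new row).
    """
    cols = ["".join(r[c] for r in rows) for c in range(len(rows[0]))]
    col_letters = [[ch for ch in col if ch != GAP] for col in cols]

    def score(i: int, j: int) -> float:
        letters = col_letters[i]
        if not letters:
            return 0.0
        return sum(sub_score(c, seq[j]) for c in letters) / len(letters)

    _, ops = _gotoh(len(cols), len(seq), score)
    new_rows = ["" for _ in rows]
    new_seq_row = []
    i = j = 0
    for op in ops:
        if op == "D":
            for k, r in enumerate(rows):
                new_rows[k] += r[i]
            new_seq_row.append(seq[j])
            i += 1; j += 1
        elif op == "U":  # profile column vs gap in new sequence
            for k, r in enumerate(rows):
                new_rows[k] += r[i]
            new_seq_row.append(GAP)
            i += 1
        else:  # gap column inserted into the profile
            for k in range(len(rows)):
                new_rows[k] += GAP
            new_seq_row.append(seq[j])
            j += 1
    return new_rows, "".join(new_seq_row)


def align_builtin(seqs: list[ExtractedSequence]) -> dict[str, str]:
    """Progressive multiple alignment; returns {label: gapped row}."""
    labels = [s.model_label for s in seqs]
    letters = {s.model_label: s.letters for s in seqs}
    if len(seqs) == 2:
        order = list(labels)
    else:
        ident = {}
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                ident[(a, b)] = ident[(b, a)] = _pairwise_identity(
                    letters[a], letters[b])
        first = max(
            ((a, b) for i, a in enumerate(labels) for b in labels[i + 1:]),
            key=lambda p: (ident[p], ),
        )
        order = [first[0], first[1]]
        remaining = [l for l in labels if l not in order]
        while remaining:
            nxt = max(
                remaining,
                key=lambda l: (sum(ident[(l, o)] for o in order) / len(order),
                               -remaining.index(l)),
            )
            order.append(nxt)
            remaining.remove(nxt)

    _, r0, r1 = nw_align(letters[order[0]], letters[order[1]])
    rows = [r0, r1]
    row_labels = [order[0], order[1]]
    for label in order[2:]:
        rows, new_row = _align_seq_to_rows(rows, letters[label])
        rows.append(new_row)
        row_labels.append(label)
    aligned = dict(zip(row_labels, rows))
    return {l: aligned[l] for l in labels}  # restore input order


def align_external(
    seqs: list[ExtractedSequence],
    executable: str = "muscle",
    dialect: str = "v5",
    workdir: str | Path | None = None,
) -> dict[str, str]:
    """Run a MUSCLE-compatible aligner via subprocess and parse its FASTA."""
    exe = shutil.which(executable) or executable
    if not Path(exe).exists() and shutil.which(executable) is None:
        raise AlignmentError(f"aligner executable not found: {executable!r}")
    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    wd = Path(ctx.name) if ctx else Path(workdir)
    try:
        fin = wd / "msa_input.fasta"
        fout = wd / "msa_output.fasta"
        write_fasta(seqs, fin)
        if dialect == "v3":
            cmd = [exe, "-in", str(fin), "-out", str(fout)]
        else:
            cmd = [exe, "-align", str(fin), "-output", str(fout)]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise AlignmentError(
                f"aligner exited with status {proc.returncode}: {proc.stderr.strip()}"
            )
        if not fout.exists():
            raise AlignmentError(f"aligner produced no output file: {proc.stderr.strip()}")
        rows = read_fasta(fout)
    finally:
        if ctx:
            ctx.cleanup()
    missing = [s.model_label for s in seqs if s.model_label not in rows]
    if missing:
        raise AlignmentError(f"aligner output is missing sequences: {missing}")
    return {s.model_label: rows[s.model_label] for s in seqs}


class AlignmentIndex:
    """MSA rows plus the bidirectional column <-> residue lookup.

    Columns are 1-based everywhere (file names, lookup CSV, plot titles).
    ``lookup(label, col)`` returns the :class:`ResidueId` occupying that
    cell or ``None`` for a gap; ``reverse(label, rid)`` returns the column
    holding a residue.
    """

    def __init__(self, rows: dict[str, str], provenances: dict[str, list[ResidueId]]):
        lengths = {len(r) for r in rows.values()}
        if len(lengths) != 1:
            raise AlignmentError(f"rows have unequal lengths: {sorted(lengths)}")
        self.column_count: int = lengths.pop()
        self.rows: dict[str, str] = dict(rows)
        self._lookup: dict[tuple[str, int], ResidueId] = {}
        self._reverse: dict[tuple[str, tuple[str, int, str]], int] = {}
        for label, row in rows.items():
            prov = provenances[label]
            ungapped = row.replace(GAP, "")
            if len(ungapped) != len(prov):
                raise AlignmentError(
                    f"row {label!r}: {len(ungapped)} aligned letters but "
                    f"{len(prov)} provenance entries"
                )
            pos = 0
            for col, ch in enumerate(row, start=1):
                if ch == GAP:
                    continue
                rid = prov[pos]
                self._lookup[(label, col)] = rid
                self._reverse[(label, rid.key())] = col
                pos += 1

    @property
    def labels(self) -> list[str]:
        return list(self.rows)

    def lookup(self, label: str, col: int) -> ResidueId | None:
        if not 1 <= col <= self.column_count:
            raise IndexError(f"column {col} out of range 1..{self.column_count}")
        return self._lookup.get((label, col))

    def reverse(self, label: str, rid: ResidueId) -> int | None:
        return self._reverse.get((label, rid.key()))

    def write_alignment_fasta(self, path: str | Path) -> Path:
        return write_fasta(self.rows, path)

    def to_lookup_frame(self) -> pd.DataFrame:
        recs = []
        for (label, col), rid in sorted(
            self._lookup.items(), key=lambda kv: (kv[0][1], kv[0][0])
        ):
            recs.append(
                dict(msa_pos=col, model_label=label, chain=rid.chain_id,
                     res_num=rid.res_num, icode=rid.icode, res_name=rid.res_name)
            )
        return pd.DataFrame.from_records(
            recs, columns=["msa_pos", "model_label", "chain", "res_num",
                           "icode", "res_name"]
        )

    def write_lookup_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_lookup_frame().to_csv(path, index=False,
                                      quoting=csv.QUOTE_MINIMAL)
        return path


def build_lookup(
    rows: dict[str, str], provenances: dict[str, list[ResidueId]]
) -> AlignmentIndex:
    """Build the column <-> residue lookup from gapped rows and provenance."""
    return AlignmentIndex(rows, provenances)


def _validate_rows(rows: dict[str, str], seqs: list[ExtractedSequence]) -> None:
    for s in seqs:
        ungapped = rows[s.model_label].replace(GAP, "")
        if ungapped != s.letters:
            pos = next(
                (k for k, (x, y) in enumerate(zip(ungapped, s.letters)) if x != y),
                min(len(ungapped), len(s.letters)),
            )
            raise AlignmentError(
                f"alignment row {s.model_label!r} does not reproduce its input "
                f"sequence (first mismatch at ungapped position {pos + 1}: "
                f"{ungapped[pos:pos+1]!r} vs {s.letters[pos:pos+1]!r})"
            )


def align(
    seqs: list[ExtractedSequence],
    engine: str = "builtin",
    executable: str = "muscle",
    dialect: str = "v5",
) -> AlignmentIndex:
    """Align extracted sequences and build the residue re-indexing table.

    Raises :class:`AlignmentError` if fewer than two non-empty sequences
    are given, the external aligner fails, or any engine's output loses or
    mutates residues.
    """
    if len(seqs) < 2:
        raise AlignmentError("need at least two sequences to align")
    for s in seqs:
        if not s.letters:
            raise AlignmentError(f"sequence {s.model_label!r} is empty")
    if engine == "builtin":
        rows = align_builtin(seqs)
    elif engine == "external":
        rows = align_external(seqs, executable=executable, dialect=dialect)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    _validate_rows(rows, seqs)
    return build_lookup(rows, {s.model_label: s.provenance for s in seqs})


def reload_alignment(path: str | Path, seqs: list[ExtractedSequence]) -> AlignmentIndex:
    """Rebuild the index from a saved (possibly hand-edited) alignment FASTA.

    Edits may only move gaps; any edit that deletes or mutates a letter is
    rejected with the first mismatch position.
    """
    rows = read_fasta(path)
    missing = [s.model_label for s in seqs if s.model_label not in rows]
    if missing:
        raise AlignmentError(f"{path}: alignment is missing sequences {missing}")
    rows = {s.model_label: rows[s.model_label] for s in seqs}
    _validate_rows(rows, seqs)
    return build_lookup(rows, {s.model_label: s.provenance for s in seqs})
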