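"""Sequence extraction from Ringer profile sets, with provenance.

Ringer output only covers residues that have at least one chi dihedral, so
the extracted sequence has holes wherever the model contains Gly/Ala or
unbuilt stretches.  The default mode mirrors that faithfully; an optional
fill mode plugs integer numbering gaps with 'X' so downstream alignment is
less fragile around Gly/Ala-rich regions.  Every letter keeps a pointer
back to its originating (chain, residue number, insertion code, name).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .ringer_io import ResidueId, StructureProfileSet

FASTA_WRAP = 60


@dataclass
class ExtractedSequence:
    """One-letter sequence of a model plus per-letter residue provenance."""

    model_label: str
    letters: str
    provenance: list[ResidueId]

    def __post_init__(self) -> None:
        if len(self.letters) != len(self.provenance):
            raise ValueError(
                f"{self.model_label}: {len(self.letters)} letters but "
                f"{len(self.provenance)} provenance entries"
            )

    def __len__(self) -> int:
        return len(self.letters)


def extract_sequence(
    pset: StructureProfileSet, fill_numbering_gaps: bool = False
) -> ExtractedSequence:
    """Build the one-letter sequence of a profile set in residue-number order.

    With ``fill_numbering_gaps`` every missing integer residue number
    between consecutive present residues becomes an 'X' whose provenance
    entry carries res_name ``UNK`` (these fillers never match a profile, so
    they stay inert downstream).
    """
    letters: list[str] = []
    prov: list[ResidueId] = []
    prev: ResidueId | None = None
    for rid in pset.residue_ids():
        if fill_numbering_gaps and prev is not None:
            for missing in range(prev.res_num + 1, rid.res_num):
                letters.append("X")
                prov.append(ResidueId(chain_id=rid.chain_id, res_num=missing,
                                      icode="", res_name="UNK"))
        letters.append(rid.one_letter)
        prov.append(rid)
        prev = rid
    return ExtractedSequence(pset.model_label, "".join(letters), prov)


def write_fasta(seqs: list[ExtractedSequence] | dict[str, str], path: str | Path) -> Path:
    """Write sequences (possibly gapped strings) as FASTA, wrapped at 60 cols."""
    if isinstance(seqs, dict):
        records = list(seqs.items())
    else:
        records = [(s.model_label, s.letters) for s in seqs]
    labels = [lab for lab, _ in records]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate FASTA headers in {labels}")
    path = Path(path)
    with open(path, "w") as fh:
        for label, seq in records:
            fh.write(f">{label}\n")
            for i in range(0, len(seq), FASTA_WRAP):
                fh.write(seq[i : i + FASTA_WRAP] + "\n")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered {header: sequence} map; gaps preserved.

    Headers are taken up to the first whitespace.  Duplicate headers are a
    hard error (they would make the alignment lookup ambiguous).
    """
    records: dict[str, str] = {}
    label: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if label is not None:
                    records[label] = "".join(chunks)
                label = line[1:].split()[0] if line[1:].split() else ""
                if label in records:
                    raise ValueError(f"{path}: duplicate FASTA header {label!r}")
                chunks = []
            else:
                if label is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line)
    if label is not None:
        records[label] = "".join(chunks)
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_provenance_csv(seqs: list[ExtractedSequence], path: str | Path) -> Path:
    """Sidecar table mapping each sequence position to its source residue."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["model_label", "seq_pos", "chain", "res_num", "icode", "res_name"])
        for seq in seqs:
            for pos, rid in enumerate(seq.provenance, start=1):
                w.writerow([seq.model_label, pos, rid.chain_id, rid.res_num,
                            rid.icode, rid.res_name])
    return path
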