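"""Reading and writing the Ringer CSV dialect.

Ringer samples an electron-density map on a uniform circle of positions
generated by rotating a side chain about each chi dihedral, and reports one
row per (residue, map type, chi) holding the sigma values at every sampled
angle.  This module parses those rows into per-chain
:class:`StructureProfileSet` containers (each chain of a multi-chain
structure becomes its own model) and writes them back out.

Dialect: ``<residue descriptor>,<map type>,<chi label>,<sigma>,...,<sigma>``
where the residue descriptor is a whitespace-separated triple of residue
name, chain id, and residue number (optionally followed by an insertion
code, e.g. ``93A``), in any token order.  The angle grid is inferred from
the number of sigma fields: ``step = 360 / n_fields`` starting at 0 deg.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .restypes import chi_count, one_letter

logger = logging.getLogger(__name__)

DEFAULT_MAP_TYPE = "2mFo-DFc"

_CHI_RE = re.compile(r"^\s*chi\s*([1-4])\s*$", re.IGNORECASE)
# residue-number token: integer with optional single-letter insertion code
_RESNUM_RE = re.compile(r"^(-?\d+)([A-Za-z]?)$")


class RingerParseError(ValueError):
    """Raised when a Ringer CSV file cannot be parsed."""


@dataclass(frozen=True)
class AngleGrid:
    """Uniform circular sampling grid shared by all profiles of one file.

    ``step_deg`` is stored as an exact rational so that grids whose step is
    not a whole number of degrees (e.g. 140 samples) stay exact; the
    invariant ``step_deg * n_samples == 360`` always holds.
    """

    n_samples: int
    start_deg: Fraction = Fraction(0)
    step_deg: Fraction = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError(f"need at least 4 samples, got {self.n_samples}")
        if self.step_deg is None:
            object.__setattr__(self, "step_deg", Fraction(360, self.n_samples))
        if self.step_deg * self.n_samples != 360:
            raise ValueError(
                f"step_deg * n_samples must equal 360, got "
                f"{self.step_deg} * {self.n_samples}"
            )

    def angles(self) -> np.ndarray:
        """Sample angles in degrees, ``start + k*step`` for k in [0, n)."""
        return np.asarray(
            [float(self.start_deg + k * self.step_deg) for k in range(self.n_samples)]
        )


@dataclass(frozen=True, order=True)
class ResidueId:
    """Author identity of one residue: chain, number, insertion code, name."""

    chain_id: str
    res_num: int
    icode: str = ""
    res_name: str = "UNK"

    @property
    def one_letter(self) -> str:
        return one_letter(self.res_name)

    def key(self) -> tuple[str, int, str]:
        """Positional key (chain, number, icode) used for B-factor mapping."""
        return (self.chain_id, self.res_num, self.icode)

    def __str__(self) -> str:  # e.g. "ASP A 93" / "ASP A 93B"
        return f"{self.res_name} {self.chain_id} {self.res_num}{self.icode}"


@dataclass
class ChiProfile:
    """Sigma values around one chi dihedral of one residue."""

    residue: ResidueId
    chi_index: int
    sigmas: np.ndarray
    map_type: str = DEFAULT_MAP_TYPE

    def __post_init__(self) -> None:
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if not 1 <= self.chi_index <= 4:
            raise ValueError(f"chi_index must be in 1..4, got {self.chi_index}")
        if np.isnan(self.sigmas).any():
            raise ValueError(f"profile {self.residue} chi{self.chi_index} has NaNs")


@dataclass
class StructureProfileSet:
    """All chi profiles of one chain of one structure (one model).

    Residues are kept sorted by (res_num, icode); chains of multi-chain
    structures are split into separate sets so each chain is an independent
    line of evidence.
    """

    model_label: str
    grid: AngleGrid
    source_file: str = ""
    residues: list[tuple[ResidueId, list[ChiProfile]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[tuple[tuple[str, int, str], int], ChiProfile] = {}
        for rid, profs in self.residues:
            for p in profs:
                self._reindex(rid, p)
        self.residues.sort(key=lambda t: (t[0].res_num, t[0].icode))

    def _reindex(self, rid: ResidueId, prof: ChiProfile) -> None:
        key = (rid.key(), prof.chi_index)
        if key in self._index:
            raise RingerParseError(
                f"duplicate profile for {rid} chi{prof.chi_index} "
                f"in model {self.model_label!r}"
            )
        if len(prof.sigmas) != self.grid.n_samples:
            raise RingerParseError(
                f"profile {rid} chi{prof.chi_index} has {len(prof.sigmas)} "
                f"samples, grid expects {self.grid.n_samples}"
            )
        self._index[key] = prof

    def add(self, rid: ResidueId, prof: ChiProfile) -> None:
        self._reindex(rid, prof)
        for existing, profs in self.residues:
            if existing.key() == rid.key():
                profs.append(prof)
                profs.sort(key=lambda p: p.chi_index)
                return
        self.residues.append((rid, [prof]))
        self.residues.sort(key=lambda t: (t[0].res_num, t[0].icode))

    def get(self, rid: ResidueId, chi_index: int) -> ChiProfile | None:
        """Profile for (residue, chi), or None if absent."""
        return self._index.get((rid.key(), chi_index))

    def residue_ids(self) -> list[ResidueId]:
        return [rid for rid, _ in self.residues]

    def __len__(self) -> int:
        return len(self.residues)


def _parse_residue_descriptor(text: str) -> ResidueId | None:
    """Parse 'ASP A 93' (tokens in any order, optional icode) or None."""
    tokens = text.split()
    if len(tokens) != 3:
        return None
    res_name = chain = None
    res_num = icode = None
    for tok in tokens:
        if res_name is None and len(tok) == 3 and tok.isalpha():
            res_name = tok.upper()
            continue
        m = _RESNUM_RE.match(tok)
        if res_num is None and m:
            res_num = int(m.group(1))
            icode = m.group(2).upper()
            continue
        if chain is None and 1 <= len(tok) <= 2 and not tok.isdigit():
            chain = tok
            continue
        return None
    if res_name is None or chain is None or res_num is None:
        return None
    return ResidueId(chain_id=chain, res_num=res_num, icode=icode, res_name=res_name)


def parse_ringer_csv(
    path: str | Path,
    map_type_filter: str = DEFAULT_MAP_TYPE,
    model_label: str | None = None,
) -> list[StructureProfileSet]:
    """Read a Ringer CSV file into one :class:`StructureProfileSet` per chain.

    Parameters
    ----------
    path
        CSV file as written by Ringer (or :func:`write_ringer_csv`).
    map_type_filter
        Only rows with this map type are kept (default ``2mFo-DFc``).
    model_label
        Base label for the output sets; defaults to the file stem.  Chain
        ids are appended as ``<label>_<chain>``.

    Returns
    -------
    list of StructureProfileSet, one per chain, in chain-id order.

    Raises
    ------
    RingerParseError
        on an empty file, zero parseable rows, inconsistent sigma-field
        counts, or duplicate (residue, chi, map) rows.
    """
    path = Path(path)
    base = model_label if model_label is not None else path.stem
    n_sigma: int | None = None
    skipped_rows = 0
    other_map_rows = 0
    per_chain: dict[str, list[tuple[ResidueId, int, np.ndarray]]] = {}

    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 7:  # descriptor, map, chi, >=4 sigmas
                skipped_rows += 1
                logger.warning("%s:%d: too few fields, row skipped", path, lineno)
                continue
            rid = _parse_residue_descriptor(row[0])
            chi_m = _CHI_RE.match(row[2])
            if rid is None or chi_m is None:
                skipped_rows += 1
                logger.warning(
                    "%s:%d: unparseable residue/chi descriptor %r, row skipped",
                    path, lineno, row[:3],
                )
                continue
            sigma_fields = row[3:]
            if n_sigma is None:
                n_sigma = len(sigma_fields)
            elif len(sigma_fields) != n_sigma:
                raise RingerParseError(
                    f"{path}:{lineno}: row has {len(sigma_fields)} sigma fields, "
                    f"expected {n_sigma}"
                )
            if row[1].strip() != map_type_filter:
                other_map_rows += 1
                continue
            try:
                sigmas = np.array([float(v) for v in sigma_fields], dtype=float)
            except ValueError:
                skipped_rows += 1
                logger.warning("%s:%d: non-numeric sigma field, row skipped", path, lineno)
                continue
            per_chain.setdefault(rid.chain_id, []).append(
                (rid, int(chi_m.group(1)), sigmas)
            )

    if n_sigma is None:
        raise RingerParseError(f"{path}: empty file or no parseable data rows")
    if not per_chain:
        raise RingerParseError(
            f"{path}: no parseable rows with map type {map_type_filter!r}"
        )
    if skipped_rows:
        logger.warning("%s: skipped %d unparseable rows", path, skipped_rows)

    grid = AngleGrid(n_samples=n_sigma)
    sets: list[StructureProfileSet] = []
    for chain in sorted(per_chain):
        pset = StructureProfileSet(
            model_label=f"{base}_{chain}", grid=grid, source_file=str(path)
        )
        pset.n_skipped_rows = skipped_rows  # type: ignore[attr-defined]
        for rid, chi, sigmas in per_chain[chain]:
            if chi > max(1, chi_count(rid.res_name)) and chi_count(rid.res_name) > 0:
                logger.warning(
                    "%s: chi%d row for %s exceeds its chi count, kept as-is", path, chi, rid
                )
            pset.add(rid, ChiProfile(residue=rid, chi_index=chi, sigmas=sigmas,
                                     map_type=map_type_filter))
        sets.append(pset)
    return sets


def write_ringer_csv(sets: Iterable[StructureProfileSet], path: str | Path) -> Path:
    """Write profile sets back to the Ringer CSV dialect.

    Row order is deterministic: (chain, res_num, icode, chi_index).  All
    sets must share one grid.  Sigma values are written with :func:`repr`
    precision so a parse -> write -> parse round trip is numerically exact.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("no profile sets to write")
    grid = sets[0].grid
    for s in sets[1:]:
        if s.grid != grid:
            raise ValueError(
                f"mixed grids: {s.model_label} has {s.grid}, expected {grid}"
            )
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for pset in sets:
            for rid, profs in pset.residues:
                for prof in profs:
                    writer.writerow(
                        [str(rid), prof.map_type, f"chi{prof.chi_index}"]
                        + [np.format_float_positional(v, trim="0") for v in prof.sigmas]
                    )
    return path


def iter_profiles(pset: StructureProfileSet) -> Iterator[ChiProfile]:
    for _, profs in pset.residues:
        yield from profs
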