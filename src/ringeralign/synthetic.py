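"""Synthetic Ringer-CSV fixtures with known rotamer-peak ground truth.

The generator emulates what real homolog comparisons look like at the level
this pipeline consumes: per-residue, per-chi sigma profiles built as
mixtures of wrapped Gaussian peaks centred on rotamer angles (60/180/300
deg) plus i.i.d. Gaussian noise, for a pair of "homolog" chains that may
differ by a residue-renumbering offset, substitutions, deletions and
planted extra (or removed) rotamer peaks.  Each planted difference is
recorded in a ground-truth table so downstream peak counting and
subtraction can be validated end to end.

Default conditions: 100 residues on a 5 deg grid, renumbering offset +11
between the two chains, 10 residues with a planted extra chi1 rotamer
(heights 0.5-0.9 sigma), per-sample noise sigma 0.05.  Primary rotamer
peaks are drawn at 3.5-4.5 sigma with Gaussian width 10 deg, typical of
well-ordered side chains in high-resolution 2mFo-DFc density; the 10 deg
width keeps the above-0.3-sigma flank of even the tallest peak well inside
the 30 deg merge radius, so peak counts are sharply defined.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .restypes import CHI_COUNTS, ROTAMERIC, chi_count
from .ringer_io import (
    AngleGrid,
    ChiProfile,
    ResidueId,
    StructureProfileSet,
    write_ringer_csv,
)

ROTAMER_CENTERS = (60.0, 180.0, 300.0)
PRIMARY_HEIGHT_RANGE = (3.5, 4.5)   # sigma
EXTRA_HEIGHT_RANGE = (0.5, 0.9)     # sigma, weak alternate conformers
PEAK_WIDTH_DEG = 10.0


@dataclass
class PeakSpec:
    center_deg: float
    height_sigma: float
    width_deg: float = PEAK_WIDTH_DEG

    def __post_init__(self) -> None:
        if self.height_sigma < 0:
            raise ValueError("peak height must be >= 0")
        if not 0 <= self.center_deg < 360:
            raise ValueError("peak center must be in [0, 360)")


@dataclass
class ModelEdits:
    """Differences of one model relative to the shared base construction."""

    renumber_offset: int = 0
    substitutions: dict[int, str] = field(default_factory=dict)  # base res_num -> new name
    deletions: tuple[int, ...] = ()                              # base res_nums removed
    extra_peaks: dict[tuple[int, int], list[PeakSpec]] = field(default_factory=dict)
    removed_peaks: tuple[tuple[int, int], ...] = ()              # (base res_num, chi)


@dataclass
class SyntheticSpec:
    """Complete, seed-determined recipe for one synthetic homolog pair."""

    n_residues: int = 100
    start_res_num: int = 10
    chain_id: str = "A"
    n_samples: int = 72  # 5 deg grid
    noise_sigma: float = 0.05
    noise_floor: float | None = None  # optional truncation, e.g. -0.2
    seed: int = 0
    residues: list[tuple[int, str]] = field(default_factory=list)
    base_peaks: dict[tuple[int, int], list[PeakSpec]] = field(default_factory=dict)
    edits_a: ModelEdits = field(default_factory=ModelEdits)
    edits_b: ModelEdits = field(default_factory=ModelEdits)
    label_a: str = "modelA"
    label_b: str = "modelB"

    @property
    def grid(self) -> AngleGrid:
        return AngleGrid(n_samples=self.n_samples)

    def to_json(self, path: str | Path) -> Path:
        d = dataclasses.asdict(self)
        d["base_peaks"] = {f"{n},{c}": v for (n, c), v in d["base_peaks"].items()}
        for e in ("edits_a", "edits_b"):
            d[e]["extra_peaks"] = {
                f"{n},{c}": v for (n, c), v in d[e]["extra_peaks"].items()
            }
        path = Path(path)
        path.write_text(json.dumps(d, indent=1, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticSpec":
        raw = json.loads(Path(path).read_text())

        def mk_edits(d: dict) -> ModelEdits:
            return ModelEdits(
                renumber_offset=d.get("renumber_offset", 0),
                substitutions={int(k): v for k, v in d.get("substitutions", {}).items()},
                deletions=tuple(d.get("deletions", ())),
                extra_peaks={_key(k): [PeakSpec(**p) for p in v]
                             for k, v in d.get("extra_peaks", {}).items()},
                removed_peaks=tuple(tuple(t) for t in d.get("removed_peaks", ())),
            )

        def _key(k):
            if isinstance(k, str):
                a, b = k.strip("()").split(",")
                return (int(a), int(b))
            return tuple(k)

        raw["edits_a"] = mk_edits(raw.get("edits_a", {}))
        raw["edits_b"] = mk_edits(raw.get("edits_b", {}))
        raw["residues"] = [tuple(t) for t in raw.get("residues", [])]
        raw["base_peaks"] = {_key(k): [PeakSpec(**p) for p in v]
                             for k, v in raw.get("base_peaks", {}).items()}
        return cls(**raw)


def default_pair_spec(
    seed: int = 0,
    n_residues: int = 100,
    renumber_offset: int = 11,
    n_extra_rotamers: int = 10,
    noise_sigma: float = 0.05,
    n_substitutions: int = 0,
    n_deletions: int = 0,
) -> SyntheticSpec:
    """Concrete homolog-pair recipe: random sequence, one primary rotamer
    peak per chi, and ``n_extra_rotamers`` residues with a planted weak
    extra chi1 peak in model B."""
    rng = np.random.default_rng(seed)
    start = 10
    names = [str(rng.choice(ROTAMERIC)) for _ in range(n_residues)]
    residues = [(start + i, names[i]) for i in range(n_residues)]
    base_peaks: dict[tuple[int, int], list[PeakSpec]] = {}
    primary_center: dict[tuple[int, int], float] = {}
    for num, name in residues:
        for chi in range(1, chi_count(name) + 1):
            c = float(rng.choice(ROTAMER_CENTERS))
            h = float(rng.uniform(*PRIMARY_HEIGHT_RANGE))
            base_peaks[(num, chi)] = [PeakSpec(c, h)]
            primary_center[(num, chi)] = c

    candidates = [num for num, name in residues]  # every residue has chi1
    extra_nums = sorted(rng.choice(candidates, size=n_extra_rotamers,
                                   replace=False).tolist())
    extra_peaks: dict[tuple[int, int], list[PeakSpec]] = {}
    for num in extra_nums:
        others = [c for c in ROTAMER_CENTERS if c != primary_center[(num, 1)]]
        c = float(rng.choice(others))
        h = float(rng.uniform(*EXTRA_HEIGHT_RANGE))
        extra_peaks[(num, 1)] = [PeakSpec(c, h)]

    subs: dict[int, str] = {}
    if n_substitutions:
        free = [n for n in candidates if n not in extra_nums]
        for num in rng.choice(free, size=n_substitutions, replace=False).tolist():
            current = dict(residues)[num]
            subs[int(num)] = str(rng.choice([n for n in ROTAMERIC if n != current]))
    dels: tuple[int, ...] = ()
    if n_deletions:
        free = [n for n in candidates if n not in extra_nums and n not in subs]
        dels = tuple(sorted(rng.choice(free, size=n_deletions,
                                       replace=False).tolist()))

    return SyntheticSpec(
        n_residues=n_residues,
        start_res_num=start,
        noise_sigma=noise_sigma,
        seed=seed,
        residues=residues,
        base_peaks=base_peaks,
        edits_a=ModelEdits(),
        edits_b=ModelEdits(renumber_offset=renumber_offset,
                           substitutions=subs, deletions=dels,
                           extra_peaks=extra_peaks),
    )


def wrapped_gaussian(angles: np.ndarray, peak: PeakSpec) -> np.ndarray:
    """Gaussian bump on the circle, summed over one wrap in each direction."""
    total = np.zeros_like(angles, dtype=float)
    for k in (-1, 0, 1):
        d = angles - peak.center_deg + 360.0 * k
        total += peak.height_sigma * np.exp(-(d ** 2) / (2.0 * peak.width_deg ** 2))
    return total


def _model_peaks(
    spec: SyntheticSpec, edits: ModelEdits
) -> dict[tuple[int, int], list[PeakSpec]]:
    """Per-(base res_num, chi) peak lists for one model after edits."""
    out: dict[tuple[int, int], list[PeakSpec]] = {}
    sub_rng = np.random.default_rng([spec.seed, 97])
    for num, name in spec.residues:
        if num in edits.deletions:
            continue
        name = edits.substitutions.get(num, name)
        for chi in range(1, chi_count(name) + 1):
            peaks = list(spec.base_peaks.get((num, chi), []))
            if not peaks:
                # chi introduced by a substitution: draw a primary rotamer
                c = float(sub_rng.choice(ROTAMER_CENTERS))
                h = float(sub_rng.uniform(*PRIMARY_HEIGHT_RANGE))
                peaks = [PeakSpec(c, h)]
            if (num, chi) in edits.removed_peaks:
                peaks = peaks[:1]  # removal keeps only the primary peak
            peaks = peaks + edits.extra_peaks.get((num, chi), [])
            out[(num, chi)] = peaks
    return out


def _build_model(
    spec: SyntheticSpec, edits: ModelEdits, label: str, stream: int
) -> StructureProfileSet:
    peaks = _model_peaks(spec, edits)
    angles = spec.grid.angles()
    noise_rng = np.random.default_rng([spec.seed, stream])
    names = {num: edits.substitutions.get(num, name)
             for num, name in spec.residues}
    pset = StructureProfileSet(model_label=label, grid=spec.grid)
    for (num, chi), plist in sorted(peaks.items()):
        sigmas = np.zeros_like(angles)
        for p in plist:
            sigmas = sigmas + wrapped_gaussian(angles, p)
        if spec.noise_sigma > 0:
            sigmas = sigmas + noise_rng.normal(0.0, spec.noise_sigma, len(angles))
        if spec.noise_floor is not None:
            sigmas = np.maximum(sigmas, spec.noise_floor)
        rid = ResidueId(chain_id=spec.chain_id,
                        res_num=num + edits.renumber_offset,
                        res_name=names[num])
        pset.add(rid, ChiProfile(residue=rid, chi_index=chi, sigmas=sigmas))
    if len(pset) == 0:
        raise ValueError("edits removed every residue of the model")
    return pset


def ground_truth(spec: SyntheticSpec) -> pd.DataFrame:
    """True per-residue, per-chi peak counts and signed differences.

    One row per (aligned residue, chi) present in both models; columns
    carry each model's author residue number so renumbering offsets are
    explicit.
    """
    pa = _model_peaks(spec, spec.edits_a)
    pb = _model_peaks(spec, spec.edits_b)
    names_a = {num: spec.edits_a.substitutions.get(num, name)
               for num, name in spec.residues}
    names_b = {num: spec.edits_b.substitutions.get(num, name)
               for num, name in spec.residues}
    recs = []
    for num, _ in spec.residues:
        for chi in range(1, 5):
            if (num, chi) not in pa or (num, chi) not in pb:
                continue
            ca, cb = len(pa[(num, chi)]), len(pb[(num, chi)])
            recs.append(dict(
                res_num_a=num + spec.edits_a.renumber_offset,
                res_num_b=num + spec.edits_b.renumber_offset,
                res_name_a=names_a[num], res_name_b=names_b[num],
                chi=chi, peaks_a=ca, peaks_b=cb, diff=ca - cb,
            ))
    return pd.DataFrame.from_records(recs)


@dataclass
class GeneratedPair:
    csv_a: Path
    csv_b: Path
    truth_csv: Path
    spec_json: Path
    set_a: StructureProfileSet
    set_b: StructureProfileSet
    truth: pd.DataFrame


def generate_pair(spec: SyntheticSpec, out_dir: str | Path) -> GeneratedPair:
    """Write the two Ringer CSVs, the ground-truth table and the spec JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    set_a = _build_model(spec, spec.edits_a, spec.label_a, stream=1)
    set_b = _build_model(spec, spec.edits_b, spec.label_b, stream=2)
    csv_a = write_ringer_csv([set_a], out_dir / f"{spec.label_a}.csv")
    csv_b = write_ringer_csv([set_b], out_dir / f"{spec.label_b}.csv")
    truth = ground_truth(spec)
    truth_csv = out_dir / "ground_truth.csv"
    truth.to_csv(truth_csv, index=False)
    spec_json = spec.to_json(out_dir / "synthetic_spec.json")
    return GeneratedPair(csv_a, csv_b, truth_csv, spec_json, set_a, set_b, truth)


def write_template_pdb(pset: StructureProfileSet, path: str | Path) -> Path:
    """Minimal synthetic CA-only PDB matching a profile set's numbering.

    A stand-in for a real coordinate file: one CA atom per residue on an
    arbitrary extended trace, with proper fixed-column formatting so the
    B-factor writer can target it.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for serial, rid in enumerate(pset.residue_ids(), start=1):
            x, y, z = 3.8 * serial, 0.0, 0.0
            fh.write(
                f"ATOM  {serial:5d}  CA  {rid.res_name:>3s} {rid.chain_id}"
                f"{rid.res_num:4d}{rid.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{20.00:6.2f}"
                f"          {'C':>2s}\n"
            )
        fh.write("END\n")
    return path
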