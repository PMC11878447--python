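"""Rendering: aligned Ringer plots and per-residue scores in PDB B-factors.

Plots overlay the sigma-vs-angle profiles of all models at one alignment
column, with the conventional guide lines (solid 0 sigma, gray dashed 0.3
sigma evidence cutoff, black dashed 1 sigma modeling threshold).  Scores
are pushed onto a structure by rewriting the temperature-factor field
(columns 61-66) of ATOM/HETATM records in a template PDB, leaving every
other byte untouched, so a molecular viewer can colour the surface by
profile similarity or peak-count difference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .compare import ResidueScore
from .msa import AlignmentIndex
from .ringer_io import AngleGrid, ChiProfile, ResidueId

logger = logging.getLogger(__name__)

GUIDE_CUTOFF = 0.3  # sigma, evidence cutoff for alternate conformers
GUIDE_MODEL = 1.0   # sigma, conventional modeling threshold
BFACTOR_SENTINEL = -1.0
_BF_MIN, _BF_MAX = -99.99, 999.99  # %6.2f field limits

# fixed palette for auto-assigned model colours
AUTO_COLORS = list(plt.get_cmap("tab10").colors)


@dataclass
class PlotSpec:
    """Options for one aligned Ringer plot (one MSA column, one chi)."""

    msa_pos: int
    chi: int
    out_dir: Path = Path(".")
    colors: dict[str, str] | None = None  # model_label -> colour, else auto
    fmt: str = "svg"
    threshold_sigma: float = GUIDE_CUTOFF
    dpi: int = 150


def build_figure(
    profiles: dict[str, ChiProfile | None],
    grid: AngleGrid,
    spec: PlotSpec,
) -> "plt.Figure":
    """Build the overlay figure for one column (callers own closing it)."""
    angles = grid.angles()
    fig, ax = plt.subplots(figsize=(5.0, 3.2))
    idx = 0
    for label, prof in profiles.items():
        if prof is None:
            continue
        if spec.colors and label in spec.colors:
            color = spec.colors[label]
        else:
            color = AUTO_COLORS[idx % len(AUTO_COLORS)]
        idx += 1
        rid = prof.residue
        ax.plot(angles, prof.sigmas, color=color,
                label=f"{label} {rid.chain_id}{rid.res_num}{rid.icode}")
    ax.axhline(0.0, color="black", linestyle="-", linewidth=0.8)
    ax.axhline(spec.threshold_sigma, color="gray", linestyle="--", linewidth=0.8)
    ax.axhline(GUIDE_MODEL, color="black", linestyle="--", linewidth=0.8)
    ax.set_xlim(0, 360)
    ax.set_xticks(range(0, 361, 60))
    ax.set_xlabel(f"χ{spec.chi} angle (°)")
    ax.set_ylabel("σ")
    ax.set_title(f"MSA position {spec.msa_pos}, χ{spec.chi}")
    ax.legend(fontsize=7, frameon=False)
    fig.tight_layout()
    return fig


def plot_column(
    profiles: dict[str, ChiProfile | None],
    grid: AngleGrid,
    spec: PlotSpec,
) -> Path | None:
    """Save the aligned Ringer plot ``msa<pos>_chi<k>.<ext>`` for one column.

    Returns the file path, or None (with a log entry) when every model is
    absent at this column.  SVG output is byte-deterministic across runs.
    """
    if all(p is None for p in profiles.values()):
        logger.info("msa position %d chi%d: no profiles, plot skipped",
                    spec.msa_pos, spec.chi)
        return None
    out_dir = Path(spec.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"msa{spec.msa_pos}_chi{spec.chi}.{spec.fmt}"
    with matplotlib.rc_context({"svg.hashsalt": "ringeralign"}):
        fig = build_figure(profiles, grid, spec)
        fig.savefig(path, dpi=spec.dpi, metadata={"Date": None}
                    if spec.fmt == "svg" else None)
        plt.close(fig)
    return path


def median_cc_map(
    scores: list[ResidueScore], ai: AlignmentIndex, model_label: str
) -> dict[ResidueId, float]:
    """Per-residue median CC values keyed by the chosen model's residues."""
    out: dict[ResidueId, float] = {}
    for sc in scores:
        if sc.median_cc is None:
            continue
        rid = ai.lookup(model_label, sc.msa_pos)
        if rid is not None:
            out[rid] = sc.median_cc
    return out


def peak_diff_map(
    scores: list[ResidueScore], ai: AlignmentIndex,
    model_a: str, model_b: str, chi: int,
    on_model: str | None = None,
) -> dict[ResidueId, float]:
    """Per-residue signed peak-count differences (a minus b) for one chi,
    keyed by the residues of ``on_model`` (default ``model_a``, the
    structure receiving the surface map)."""
    on_model = on_model or model_a
    out: dict[ResidueId, float] = {}
    for sc in scores:
        diff = sc.peak_diff.get((model_a, model_b, chi))
        if diff is None:
            diff_rev = sc.peak_diff.get((model_b, model_a, chi))
            diff = -diff_rev if diff_rev is not None else None
        if diff is None:
            continue
        rid = ai.lookup(on_model, sc.msa_pos)
        if rid is not None:
            out[rid] = float(diff)
    return out


def write_bfactor_pdb(
    template_pdb: str | Path,
    values: dict[ResidueId, float] | dict[tuple[str, int, str], float],
    out_path: str | Path,
    sentinel: float = BFACTOR_SENTINEL,
) -> Path:
    """Rewrite the temperature-factor field of a PDB with per-residue values.

    Every ATOM/HETATM record of a scored residue (matched on chain, author
    residue number and insertion code; all altlocs get the same value) has
    columns 61-66 replaced by the value formatted ``%6.2f``; unscored
    residues receive ``sentinel``.  Values outside the field range
    [-99.99, 999.99] are clamped with a warning.  All other bytes are
    copied verbatim from the template.
    """
    keyed: dict[tuple[str, int, str], float] = {}
    for k, v in values.items():
        key = k.key() if isinstance(k, ResidueId) else (k[0], int(k[1]), k[2])
        keyed[key] = float(v)

    def fmt(v: float) -> str:
        if not _BF_MIN <= v <= _BF_MAX:
            clamped = min(max(v, _BF_MIN), _BF_MAX)
            warnings.warn(
                f"B-factor value {v} outside [{_BF_MIN}, {_BF_MAX}], "
                f"clamped to {clamped}", stacklevel=2)
            v = clamped
        return f"{v:6.2f}"

    template_pdb = Path(template_pdb)
    out_path = Path(out_path)
    out_lines: list[str] = []
    with open(template_pdb) as fh:
        for line in fh:
            if line.startswith(("ATOM  ", "HETATM")) and len(line.rstrip("\n")) >= 66:
                chain = line[21]
                res_num = int(line[22:26])
                icode = line[26].strip()
                value = keyed.get((chain, res_num, icode), sentinel)
                line = line[:60] + fmt(value) + line[66:]
            out_lines.append(line)
    with open(out_path, "w") as fh:
        fh.writelines(out_lines)
    return out_path


def read_bfactors(pdb_path: str | Path) -> dict[tuple[str, int, str], float]:
    """Extract the per-residue temperature factor from a PDB (first atom wins)."""
    out: dict[tuple[str, int, str], float] = {}
    with open(pdb_path) as fh:
        for line in fh:
            if line.startswith(("ATOM  ", "HETATM")) and len(line.rstrip("\n")) >= 66:
                key = (line[21], int(line[22:26]), line[26].strip())
                out.setdefault(key, float(line[60:66]))
    return out
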