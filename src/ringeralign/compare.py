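"""Quantitative comparison of aligned Ringer profiles.

For every alignment column and chi angle this module extracts the sigma
profiles of all models, detects peaks on the circular angle grid, subtracts
peak counts between model pairs (a per-residue flexibility-difference
statistic), and computes pairwise Pearson correlation coefficients whose
per-column median summarises local map similarity.

Conventions:

* A peak is a sample strictly greater than both circular neighbours
  (plateaus count once, at their leftmost sample) with height at or above
  ``threshold_sigma``.  The default cutoff is 0.3 sigma — the accepted
  evidence level for alternate conformers in 2mFo-DFc maps.
* Peaks closer than ``min_separation_deg`` (default 30 deg, about one
  rotamer well) are merged keeping the higher peak; ties keep the smaller
  angle.  All distances wrap at 0/360 deg.
* Correlations are computed on raw, unclipped sigma values; a CC is
  undefined (and excluded from medians, never imputed as 0) when either
  profile is constant or shorter than 3 samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .msa import AlignmentIndex
from .ringer_io import ChiProfile, StructureProfileSet

SIGMA_THRESHOLD_DEFAULT = 0.3  # evidence cutoff for alternate conformers
MIN_SEPARATION_DEFAULT = 30.0  # deg, ~ one rotamer well


@dataclass(frozen=True)
class Peak:
    angle_deg: float
    height_sigma: float


@dataclass
class PeakSet:
    """Detected peaks of one profile, with the parameters that produced them."""

    model_label: str
    residue_str: str
    chi_index: int
    threshold_sigma: float
    peaks: list[Peak]

    @property
    def count(self) -> int:
        return len(self.peaks)

    @property
    def angles(self) -> list[float]:
        return [p.angle_deg for p in self.peaks]


@dataclass
class CompareParams:
    """Tunable knobs of the comparison stage (echoed into output headers)."""

    chis: tuple[int, ...] = (1, 2, 3, 4)
    threshold_sigma: float = SIGMA_THRESHOLD_DEFAULT
    min_separation_deg: float = MIN_SEPARATION_DEFAULT
    smooth_window: int = 1  # odd sample count; 1 = off


@dataclass
class ResidueScore:
    """All per-column results: peak counts/diffs and CCs per model pair."""

    msa_pos: int
    # (model,) -> per chi peak count, None where the profile is absent
    peak_count: dict[tuple[str, int], int | None] = field(default_factory=dict)
    # (model_a, model_b, chi) -> signed count difference or None
    peak_diff: dict[tuple[str, str, int], int | None] = field(default_factory=dict)
    # (model_a, model_b, chi) -> CC or None (undefined)
    cc: dict[tuple[str, str, int], float | None] = field(default_factory=dict)
    median_cc: float | None = None
    per_chi_median_cc: dict[int, float | None] = field(default_factory=dict)


def circular_distance(a: float, b: float) -> float:
    """Shortest angular distance between two angles in degrees."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def circular_smooth(y: np.ndarray, window: int) -> np.ndarray:
    """Circular moving average with an odd window (window=1 is a no-op)."""
    if window == 1:
        return y
    if window < 1 or window % 2 == 0:
        raise ValueError(f"smooth_window must be odd and >= 1, got {window}")
    half = window // 2
    padded = np.concatenate([y[-half:], y, y[:half]])
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def pearson_cc(a: np.ndarray, b: np.ndarray) -> float | None:
    """Product-moment correlation of two sigma vectors, or None if undefined.

    Undefined when the vectors are shorter than 3 samples or either is
    constant.  The value is computed as sign(c) * sqrt(c^2 / (Sa*Sb)) on
    centred vectors, which is algebraically the standard formula but
    returns exactly +/-1.0 for perfectly (anti)correlated inputs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 3:
        return None
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    ax = a - a.mean()
    bx = b - b.mean()
    c = float(np.dot(ax, bx))
    denom = float(np.dot(ax, ax)) * float(np.dot(bx, bx))
    r = math.copysign(math.sqrt(c * c / denom), c)
    return max(-1.0, min(1.0, r))


def detect_peaks(
    profile: ChiProfile | np.ndarray,
    grid=None,
    threshold_sigma: float = SIGMA_THRESHOLD_DEFAULT,
    min_separation_deg: float = MIN_SEPARATION_DEFAULT,
    smooth_window: int = 1,
    model_label: str = "",
) -> PeakSet:
    """Detect peaks on a circular sigma profile.

    Accepts either a :class:`ChiProfile` (grid taken from it unless given)
    or a bare sigma vector plus an :class:`AngleGrid`.
    """
    if min_separation_deg >= 180.0:
        raise ValueError(
            f"min_separation_deg must be < 180 (got {min_separation_deg}); "
            "anything larger would merge opposite rotamer wells"
        )
    if isinstance(profile, ChiProfile):
        sigmas = profile.sigmas
        residue_str = str(profile.residue)
        chi_index = profile.chi_index
    else:
        sigmas = np.asarray(profile, dtype=float)
        residue_str = ""
        chi_index = 0
    if grid is None:
        raise ValueError("grid must be provided (profiles do not carry one)")
    angles = grid.angles()
    n = len(sigmas)
    if n != grid.n_samples:
        raise ValueError(f"profile has {n} samples, grid expects {grid.n_samples}")

    y = circular_smooth(sigmas, smooth_window)

    candidates: list[Peak] = []
    if np.ptp(y) > 0:
        for i in range(n):
            if y[(i - 1) % n] == y[i]:
                continue  # not the leftmost sample of its plateau
            j = i
            while y[(j + 1) % n] == y[i]:
                j = (j + 1) % n
            if y[(i - 1) % n] < y[i] and y[(j + 1) % n] < y[i]:
                if y[i] >= threshold_sigma:
                    candidates.append(Peak(float(angles[i]), float(y[i])))

    # merge: keep higher peaks, drop any candidate within min_separation of
    # an already-kept one; ties prefer the smaller angle
    kept: list[Peak] = []
    for pk in sorted(candidates, key=lambda p: (-p.height_sigma, p.angle_deg)):
        if all(circular_distance(pk.angle_deg, q.angle_deg) >= min_separation_deg
               for q in kept):
            kept.append(pk)
    kept.sort(key=lambda p: p.angle_deg)
    return PeakSet(model_label=model_label, residue_str=residue_str,
                   chi_index=chi_index, threshold_sigma=threshold_sigma,
                   peaks=kept)


def peak_subtract(pa: PeakSet, pb: PeakSet) -> int:
    """Signed peak-count difference count(a) - count(b) for one residue/chi."""
    if pa.threshold_sigma != pb.threshold_sigma:
        raise ValueError(
            f"threshold mismatch: {pa.threshold_sigma} vs {pb.threshold_sigma}"
        )
    return pa.count - pb.count


def column_profiles(
    ai: AlignmentIndex,
    sets: list[StructureProfileSet],
    msa_pos: int,
    chi_index: int,
) -> dict[str, ChiProfile | None]:
    """Per-model profile at one alignment column and chi (None = absent).

    Absent covers gap cells, numbering-gap fillers ('X'/UNK cells) and
    residues whose type lacks the requested chi.  The grids of all present
    profiles must agree.
    """
    by_label = {s.model_label: s for s in sets}
    grids = {s.grid for s in sets}
    if len(grids) > 1:
        raise ValueError(f"profile sets are on different angle grids: {grids}")
    out: dict[str, ChiProfile | None] = {}
    for label in ai.labels:
        pset = by_label.get(label)
        if pset is None:
            out[label] = None
            continue
        rid = ai.lookup(label, msa_pos)
        out[label] = None if rid is None else pset.get(rid, chi_index)
    return out


def _median(values: list[float]) -> float | None:
    return float(np.median(values)) if values else None


def score_columns(
    ai: AlignmentIndex,
    sets: list[StructureProfileSet],
    params: CompareParams | None = None,
) -> list[ResidueScore]:
    """Score every alignment column: peak counts, pairwise diffs and CCs.

    The per-column ``median_cc`` is the median over all defined pairwise
    CCs across the requested chi angles (per-chi medians are kept too,
    since chi1 and chi2 are often mapped separately).  Columns with no
    comparable pair yield an all-missing score.
    """
    params = params or CompareParams()
    if len(sets) < 2:
        raise ValueError("need at least two models to compare")
    labels = [s.model_label for s in sets if s.model_label in ai.rows]
    peak_cache: dict[tuple[str, int, int], PeakSet | None] = {}
    scores: list[ResidueScore] = []
    grid = sets[0].grid

    for pos in range(1, ai.column_count + 1):
        score = ResidueScore(msa_pos=pos)
        all_ccs: list[float] = []
        for chi in params.chis:
            profs = column_profiles(ai, sets, pos, chi)
            psets: dict[str, PeakSet | None] = {}
            for label in labels:
                prof = profs.get(label)
                if prof is None:
                    psets[label] = None
                    score.peak_count[(label, chi)] = None
                    continue
                key = (label, pos, chi)
                if key not in peak_cache:
                    peak_cache[key] = detect_peaks(
                        prof, grid=grid,
                        threshold_sigma=params.threshold_sigma,
                        min_separation_deg=params.min_separation_deg,
                        smooth_window=params.smooth_window,
                        model_label=label,
                    )
                psets[label] = peak_cache[key]
                score.peak_count[(label, chi)] = peak_cache[key].count
            chi_ccs: list[float] = []
            for i, la in enumerate(labels):
                for lb in labels[i + 1:]:
                    pa, pb = psets[la], psets[lb]
                    if pa is None or pb is None:
                        score.peak_diff[(la, lb, chi)] = None
                        score.cc[(la, lb, chi)] = None
                        continue
                    score.peak_diff[(la, lb, chi)] = peak_subtract(pa, pb)
                    cc = pearson_cc(profs[la].sigmas, profs[lb].sigmas)
                    score.cc[(la, lb, chi)] = cc
                    if cc is not None:
                        chi_ccs.append(cc)
            score.per_chi_median_cc[chi] = _median(chi_ccs)
            all_ccs.extend(chi_ccs)
        score.median_cc = _median(all_ccs)
        scores.append(score)
    return scores


def scores_to_frame(scores: list[ResidueScore]) -> pd.DataFrame:
    """Long-format scores table: one row per (msa_pos, chi, model pair)."""
    recs = []
    for sc in scores:
        for (la, lb, chi), diff in sc.peak_diff.items():
            recs.append(dict(
                msa_pos=sc.msa_pos, chi=chi, model_a=la, model_b=lb,
                cc=sc.cc[(la, lb, chi)],
                peaks_a=sc.peak_count.get((la, chi)),
                peaks_b=sc.peak_count.get((lb, chi)),
                peak_diff=diff,
                median_cc=sc.median_cc,
            ))
    return pd.DataFrame.from_records(
        recs, columns=["msa_pos", "chi", "model_a", "model_b", "cc",
                       "peaks_a", "peaks_b", "peak_diff", "median_cc"]
    )


def write_scores_csv(
    scores: list[ResidueScore], path: str | Path,
    params: CompareParams | None = None,
) -> Path:
    """Write the long-format scores table with parameters echoed as comments."""
    params = params or CompareParams()
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# chis={','.join(map(str, params.chis))}\n")
        fh.write(f"# threshold_sigma={params.threshold_sigma}\n")
        fh.write(f"# min_separation_deg={params.min_separation_deg}\n")
        fh.write(f"# smooth_window={params.smooth_window}\n")
        scores_to_frame(scores).to_csv(fh, index=False)
    return path
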