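"""Substitution-rate profile and evolutionarily constrained region calling.

Per filtered column the relative substitution score is SS divided by the
number of informative sequences (sequences with an amino acid there);
columns with fewer than two informative sequences cannot show a
substitution and get relative score 0.  The track is normalised by its mean
(so 1 marks the protein-average rate) and smoothed with a centred 11-column
moving average followed by two 7-column passes, windows truncated at the
array ends.

ECRs are the valleys of the smoothed track: local minima below a threshold
(default 1.0, the normalised mean), extended on each side to the nearest
sign change of the discrete second difference — the inflection points where
the valley's curvature ends — or to the array end.  Overlapping calls are
merged, keeping the deepest minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .alignment import FilteredAlignment, map_to_reference
from .ancestral import ColumnStates
from .errors import DegenerateProfileError

__all__ = ["ConstraintProfile", "EcrRegion", "compute_profile", "moving_average",
           "call_ecrs", "regions_to_reference", "render_outputs"]


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with windows truncated at the array ends.

    Truncation (mean over the available part of the window) preserves both
    track length and constant signals.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    x = np.asarray(x, dtype=float)
    half = window // 2
    padded = np.concatenate([np.zeros(half), x, np.zeros(half)])
    kernel = np.ones(window)
    sums = np.convolve(padded, kernel, mode="valid")
    counts = np.convolve(
        np.concatenate([np.zeros(half), np.ones(len(x)), np.zeros(half)]),
        kernel, mode="valid",
    )
    return sums / counts


@dataclass
class ConstraintProfile:
    """Per-column conservation tracks over the filtered alignment."""

    ss: np.ndarray
    n_informative: np.ndarray
    relative: np.ndarray
    normalized: np.ndarray
    smoothed: np.ndarray
    window: int = 11
    smooth_window: int = 7
    smooth_passes: int = 2

    @property
    def length(self) -> int:
        return len(self.ss)


@dataclass(frozen=True)
class EcrRegion:
    """A called constrained region.

    Columns are 1-based inclusive filtered-alignment coordinates;
    ``start_ref``/``end_ref`` are reference residue numbers once mapped
    (None when the region lies wholly in a reference gap).
    """

    start_col: int
    end_col: int
    min_col: int
    min_value: float
    start_ref: int | None = None
    end_ref: int | None = None

    @property
    def n_columns(self) -> int:
        return self.end_col - self.start_col + 1


def compute_profile(columns: list[ColumnStates], filtered: FilteredAlignment,
                    window: int = 11, smooth_window: int = 7,
                    smooth_passes: int = 2) -> ConstraintProfile:
    """Build the relative / normalised / smoothed tracks from column scores."""
    if len(columns) != filtered.length:
        raise ValueError(
            f"{len(columns)} column reconstructions for a filtered alignment "
            f"of length {filtered.length}"
        )
    ss = np.array([c.column_ss for c in columns], dtype=float)
    n_inf = np.array([c.n_informative for c in columns], dtype=int)
    relative = np.where(n_inf >= 2, ss / np.maximum(n_inf, 1), 0.0)
    mean = relative.mean()
    if mean == 0:
        raise DegenerateProfileError(
            "every column is perfectly conserved; relative rates are undefined "
            "(is the input alignment invariant?)"
        )
    normalized = relative / mean
    smoothed = moving_average(normalized, window)
    for _ in range(smooth_passes):
        smoothed = moving_average(smoothed, smooth_window)
    return ConstraintProfile(ss=ss, n_informative=n_inf, relative=relative,
                             normalized=normalized, smoothed=smoothed,
                             window=window, smooth_window=smooth_window,
                             smooth_passes=smooth_passes)


def _local_minima(s: np.ndarray) -> list[int]:
    """Interior local minima (0-based); equal-value plateaus yield their
    lower-median column.  Array ends never qualify."""
    n = len(s)
    minima = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and s[j + 1] == s[i]:
            j += 1
        if i > 0 and j < n - 1 and s[i - 1] > s[i] and s[j + 1] > s[i]:
            minima.append((i + j) // 2)
        i = j + 1
    return minima


def call_ecrs(profile: ConstraintProfile | np.ndarray,
              minimum_threshold: float = 1.0) -> list[EcrRegion]:
    """Call constrained regions on the smoothed track.

    Minima at or above ``minimum_threshold`` are discarded; each surviving
    minimum is extended to the nearest second-difference sign change on each
    side (or the array end); overlapping regions merge, keeping the deepest
    minimum.  Returns regions sorted by start column (1-based).
    """
    s = profile.smoothed if isinstance(profile, ConstraintProfile) else np.asarray(profile, float)
    n = len(s)
    if n < 3:
        return []
    d2 = np.empty(n)
    d2[1:-1] = s[:-2] - 2 * s[1:-1] + s[2:]
    d2[0], d2[-1] = d2[1], d2[-2]
    regions: list[EcrRegion] = []
    for m in _local_minima(s):
        if s[m] >= minimum_threshold:
            continue
        left = 0
        for i in range(m - 1, 0, -1):
            if d2[i] == 0 or (d2[i] < 0) != (d2[i + 1] < 0):
                left = i
                break
        right = n - 1
        for i in range(m + 1, n - 1):
            if d2[i] == 0 or (d2[i] < 0) != (d2[i - 1] < 0):
                right = i
                break
        regions.append(EcrRegion(start_col=left + 1, end_col=right + 1,
                                 min_col=m + 1, min_value=float(s[m])))
    regions.sort(key=lambda r: (r.start_col, r.end_col))
    merged: list[EcrRegion] = []
    for region in regions:
        if merged and region.start_col <= merged[-1].end_col:
            prev = merged[-1]
            deepest = min(prev, region, key=lambda r: (r.min_value, r.min_col))
            merged[-1] = EcrRegion(
                start_col=prev.start_col,
                end_col=max(prev.end_col, region.end_col),
                min_col=deepest.min_col,
                min_value=deepest.min_value,
            )
        else:
            merged.append(region)
    return merged


def regions_to_reference(regions: list[EcrRegion],
                         filtered: FilteredAlignment) -> list[EcrRegion]:
    """Attach reference-protein coordinates to called regions.

    A boundary on a reference gap moves inward to the nearest reference
    residue; a region entirely inside a reference gap keeps alignment
    coordinates but gets None reference bounds.
    """
    out = []
    for region in regions:
        cols = range(region.start_col, region.end_col + 1)
        refs = [map_to_reference(filtered, c) for c in cols]
        defined = [r for r in refs if r is not None]
        if defined:
            out.append(replace(region, start_ref=defined[0], end_ref=defined[-1]))
        else:
            out.append(replace(region, start_ref=None, end_ref=None))
    return out


# ---------------------------------------------------------------------------
# output rendering


def _ecr_flags(profile: ConstraintProfile, regions: list[EcrRegion]) -> np.ndarray:
    flags = np.zeros(profile.length, dtype=bool)
    for region in regions:
        flags[region.start_col - 1:region.end_col] = True
    return flags


def render_outputs(profile: ConstraintProfile, regions: list[EcrRegion],
                   filtered: FilteredAlignment, outdir, stem: str = "analysis",
                   plot: bool = True) -> dict[str, str]:
    """Write the three result tables (TSV) and the profile plot (PNG + SVG).

    Tables mirror the standard result layout: per-filtered-column scores with
    region flags, per-raw-column scores, and the aligned sequences preceded
    by the three coordinate-index rows.  Output is deterministic: identical
    inputs give byte-identical TSVs.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    flags = _ecr_flags(profile, regions)
    fmt = lambda v: format(v, ".10g")

    # --- substitution scores over the filtered alignment
    path = outdir / f"{stem}.substitution_scores.tsv"
    ref_res = filtered.alignment.reference.residues
    with open(path, "w") as fh:
        fh.write("reference_index\tfiltered_index\treference_residue\t"
                 "substitution_score\tn_informative\trelative\tnormalized\t"
                 "smoothed\tecr\n")
        for k in range(profile.length):
            ref = filtered.reference_index[k]
            fh.write("\t".join([
                "" if ref is None else str(ref),
                str(k + 1),
                ref_res[k],
                fmt(profile.ss[k]),
                str(int(profile.n_informative[k])),
                fmt(profile.relative[k]),
                fmt(profile.normalized[k]),
                fmt(profile.smoothed[k]),
                "1" if flags[k] else "0",
            ]) + "\n")
    written["substitution_scores"] = str(path)

    # --- raw substitution scores over the unfiltered alignment
    path = outdir / f"{stem}.raw_substitution_scores.tsv"
    raw = filtered.raw or filtered.alignment
    raw_ref = raw.reference.residues
    by_raw = {raw_col: k for k, raw_col in enumerate(filtered.kept_columns)}
    ref_counter = 0
    with open(path, "w") as fh:
        fh.write("raw_index\treference_index\treference_residue\t"
                 "substitution_score\n")
        for raw_col in range(1, raw.length + 1):
            ch = raw_ref[raw_col - 1]
            if ch != "-":
                ref_counter += 1
            k = by_raw.get(raw_col)
            fh.write("\t".join([
                str(raw_col),
                str(ref_counter) if ch != "-" else "",
                ch,
                fmt(profile.ss[k]) if k is not None else "",
            ]) + "\n")
    written["raw_substitution_scores"] = str(path)

    # --- aligned sequences with the three index header rows
    path = outdir / f"{stem}.aligned_sequences.tsv"
    with open(path, "w") as fh:
        ref_track, filt_track, raw_track = [], [], []
        ref_counter = 0
        for raw_col in range(1, raw.length + 1):
            if raw_ref[raw_col - 1] != "-":
                ref_counter += 1
                ref_track.append(str(ref_counter))
            else:
                ref_track.append("")
            k = by_raw.get(raw_col)
            filt_track.append(str(k + 1) if k is not None else "")
            raw_track.append(str(raw_col))
        fh.write("reference_index\t" + "\t".join(ref_track) + "\n")
        fh.write("filtered_index\t" + "\t".join(filt_track) + "\n")
        fh.write("raw_index\t" + "\t".join(raw_track) + "\n")
        for rec in raw.records:
            fh.write(rec.id + "\t" + "\t".join(rec.residues) + "\n")
    written["aligned_sequences"] = str(path)

    if plot:
        written.update(_render_plot(profile, regions, filtered, outdir, stem))
    return written


def _render_plot(profile, regions, filtered, outdir, stem):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3.2))
    x = np.arange(1, profile.length + 1)
    ax.plot(x, profile.smoothed, color="red", lw=1.2,
            label="relative substitution rate (smoothed)")
    ax.axhline(1.0, color="grey", lw=0.6, ls="--")
    top = float(profile.smoothed.max())
    bar_y = top * 1.05
    for region in regions:
        ax.plot([region.start_col, region.end_col], [bar_y, bar_y],
                color="gold", lw=6, solid_capstyle="butt")
    ax.set_xlabel("filtered alignment column")
    ax.set_ylabel("relative substitution rate")
    ax.set_xlim(1, profile.length)

    # reference residue numbers along the top
    sec = ax.secondary_xaxis("top")
    ticks, labels = [], []
    step = max(1, profile.length // 8)
    for k in range(0, profile.length, step):
        ref = filtered.reference_index[k]
        if ref is not None:
            ticks.append(k + 1)
            labels.append(str(ref))
    sec.set_xticks(ticks)
    sec.set_xticklabels(labels)
    sec.set_xlabel("reference protein index")
    fig.tight_layout()

    written = {}
    for ext in ("png", "svg"):
        path = outdir / f"{stem}.profile.{ext}"
        fig.savefig(path, dpi=150, metadata={"Date": None} if ext == "svg" else None)
        written[f"plot_{ext}"] = str(path)
    plt.close(fig)
    return written
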