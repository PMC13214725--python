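"""Detection-frequency analyses on the pre-imputation mask.

DIA missingness is informative: a protein consistently detected in one
group and absent in another carries a presence/absence signal that
intensity statistics (computed on imputed values) cannot see.  This module
counts detections per (group, day) cell, splits differential proteins into
an intensity-driven track (reliably quantified in both compared conditions:
detected in >= 2/3 replicates per genotype, or >= 4/6 in pooled class
cells) and a detection-driven track (reliability fails but the detection
frequencies differ clearly), and flags two qualitative patterns:

* on/off — detected in (essentially) all replicates of one tolerance class
  at both days and (essentially) none of the other class at both days;
* switch-like — mirror-image crossover: high detection at baseline falling
  by the stress day in one class, with the inverse trajectory in the other.

Everything here is a deterministic function of the detection mask; imputed
values never count as detections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import IntensityMatrix, SampleDesign, ValidationError

TRACKS = ("intensity_driven", "detection_driven", "none")


@dataclass
class DetectionProfile:
    """Per-protein detected/total counts for each (group, day) cell."""

    protein_id: str
    counts: dict  # (group, day) -> (detected, total)

    def proportion(self, group, day) -> float:
        k, n = self.counts[(group, day)]
        return k / n

    def cell_str(self, group, day) -> str:
        k, n = self.counts[(group, day)]
        return f"{k}/{n}"


def detection_counts(mask: pd.DataFrame, design: SampleDesign,
                     level: str = "class") -> list[DetectionProfile]:
    """Tally detections per protein per (group, day) cell.

    ``level="genotype"`` counts within each genotype (k/3 by default);
    ``level="class"`` pools the genotypes of a tolerance class (k/6).
    """
    if level not in ("genotype", "class"):
        raise ValidationError(f"level must be 'genotype' or 'class', got {level!r}")
    unknown = mask.columns.difference(design.table.index)
    if len(unknown):
        raise ValidationError(f"sample(s) in mask absent from design: {list(unknown)[:5]}")
    meta = design.table.loc[mask.columns]
    key_col = "genotype" if level == "genotype" else "tolerance_class"
    cells = {}
    for (g, d), sub in meta.groupby([key_col, "day"], observed=True):
        cells[(g, int(d))] = mask.columns.get_indexer(sub.index)
    arr = mask.to_numpy(dtype=bool)
    profiles = []
    for i, pid in enumerate(mask.index):
        counts = {
            cell: (int(arr[i, cols].sum()), len(cols)) for cell, cols in cells.items()
        }
        profiles.append(DetectionProfile(protein_id=pid, counts=counts))
    return profiles


def _reliable(profile: DetectionProfile, condition_cells, min_frac: float) -> bool:
    """Reliability rule over the cells of one condition (all must pass)."""
    for cell in condition_cells:
        k, n = profile.counts[cell]
        if k < np.ceil(min_frac * n) - 1e-9:
            return False
    return True


def classify_track(profile: DetectionProfile, condition_a, condition_b,
                   min_frac: float = 2.0 / 3.0,
                   freq_delta_min: float = 0.5) -> str:
    """Assign a differential protein to a quantification track.

    ``condition_a``/``condition_b`` are lists of (group, day) cells making
    up the two sides of the contrast.  ``intensity_driven`` iff the
    reliability rule (detected in >= ``min_frac`` of replicates in every
    cell: 2/3 per genotype, 4/6 pooled) holds in BOTH conditions; otherwise
    ``detection_driven`` iff the detection-frequency difference between the
    conditions is >= ``freq_delta_min``; else ``none``.
    """
    cond_a = list(condition_a)
    cond_b = list(condition_b)
    if _reliable(profile, cond_a, min_frac) and _reliable(profile, cond_b, min_frac):
        return "intensity_driven"

    def pooled_prop(cells):
        k = sum(profile.counts[c][0] for c in cells)
        n = sum(profile.counts[c][1] for c in cells)
        return k / n

    if abs(pooled_prop(cond_a) - pooled_prop(cond_b)) >= freq_delta_min - 1e-12:
        return "detection_driven"
    return "none"


def contrast_conditions(design: SampleDesign, contrast: str, level: str = "class"):
    """The two (group, day) cell lists compared by a standard contrast."""
    days = sorted(design.table["day"].unique())
    d_lo, d_hi = days[0], days[-1]

    def cells(klass, day):
        if level == "class":
            return [(klass, day)]
        meta = design.table
        genos = sorted(meta.loc[meta["tolerance_class"] == klass, "genotype"].unique())
        return [(g, day) for g in genos]

    if contrast == "baseline_class":
        return cells("tolerant", d_lo), cells("sensitive", d_lo)
    if contrast == "sensitive_day":
        return cells("sensitive", d_hi), cells("sensitive", d_lo)
    if contrast == "tolerant_day":
        return cells("tolerant", d_hi), cells("tolerant", d_lo)
    if contrast == "interaction":
        # reliability must hold in every cell for a trustworthy interaction
        return (cells("tolerant", d_lo) + cells("tolerant", d_hi),
                cells("sensitive", d_lo) + cells("sensitive", d_hi))
    raise ValidationError(f"unknown contrast {contrast!r}")


def annotate_tracks(daps: pd.DataFrame, mask: pd.DataFrame, design: SampleDesign,
                    contrast: str, level: str = "class",
                    min_frac: float = 2.0 / 3.0,
                    freq_delta_min: float = 0.5) -> pd.DataFrame:
    """Fill the ``track`` column of a DAP table from the detection mask."""
    cond_a, cond_b = contrast_conditions(design, contrast, level=level)
    profiles = {p.protein_id: p
                for p in detection_counts(mask.loc[daps.index], design, level=level)}
    out = daps.copy()
    out["track"] = [
        classify_track(profiles[pid], cond_a, cond_b,
                       min_frac=min_frac, freq_delta_min=freq_delta_min)
        for pid in out.index
    ]
    return out


def find_on_off(profiles, design: SampleDesign, on_min: int | None = None,
                off_max: int = 0) -> pd.DataFrame:
    """Binary presence/absence candidates across tolerance classes.

    Flags proteins detected in >= ``on_min`` replicates (default: all) of
    one class at BOTH days and <= ``off_max`` (default 0) in the other
    class at BOTH days.  Returns a table with the on-class and the per-cell
    k/n counts.
    """
    days = sorted(design.table["day"].unique())
    classes = sorted(design.table["tolerance_class"].unique())
    rows = []
    for prof in profiles:
        for on_class in classes:
            off_class = [c for c in classes if c != on_class][0]
            totals = [prof.counts[(on_class, d)][1] for d in days]
            need = on_min if on_min is not None else min(totals)
            on_ok = all(prof.counts[(on_class, d)][0] >= min(need, prof.counts[(on_class, d)][1])
                        for d in days)
            off_ok = all(prof.counts[(off_class, d)][0] <= off_max for d in days)
            if on_ok and off_ok:
                rows.append({
                    "protein_id": prof.protein_id,
                    "on_class": on_class,
                    **{f"{c}_day{d}": prof.cell_str(c, d)
                       for c in classes for d in days},
                })
                break
    return pd.DataFrame(rows, columns=["protein_id", "on_class"] + [
        f"{c}_day{d}" for c in classes for d in days]).set_index("protein_id") \
        if rows else _empty_pattern_table(classes, days, ["on_class"])


def find_switch_like(profiles, design: SampleDesign,
                     high_min: float = 2.0 / 3.0,
                     low_max: float = 1.0 / 3.0) -> pd.DataFrame:
    """Mirror-image detection crossovers between tolerance classes.

    Flags proteins where one class is high at baseline (detection proportion
    >= ``high_min``) and low at the stress day (<= ``low_max``) while the
    other class shows the inverse, in either orientation.  The returned
    table reports the orientation (which class was high at baseline) and
    per-cell k/n counts.
    """
    days = sorted(design.table["day"].unique())
    d_lo, d_hi = days[0], days[-1]
    classes = sorted(design.table["tolerance_class"].unique())
    rows = []
    for prof in profiles:
        for high_class in classes:
            other = [c for c in classes if c != high_class][0]
            a0 = prof.proportion(high_class, d_lo)
            a6 = prof.proportion(high_class, d_hi)
            b0 = prof.proportion(other, d_lo)
            b6 = prof.proportion(other, d_hi)
            if (a0 >= high_min and a6 <= low_max and
                    b0 <= low_max and b6 >= high_min):
                rows.append({
                    "protein_id": prof.protein_id,
                    "high_at_baseline": high_class,
                    **{f"{c}_day{d}": prof.cell_str(c, d)
                       for c in classes for d in days},
                })
                break
    return pd.DataFrame(rows, columns=["protein_id", "high_at_baseline"] + [
        f"{c}_day{d}" for c in classes for d in days]).set_index("protein_id") \
        if rows else _empty_pattern_table(classes, days, ["high_at_baseline"])


def _empty_pattern_table(classes, days, extra_cols):
    cols = extra_cols + [f"{c}_day{d}" for c in classes for d in days]
    return pd.DataFrame(columns=cols, index=pd.Index([], name="protein_id"))


def profiles_from_matrix(matrix: IntensityMatrix, design: SampleDesign,
                         level: str = "class") -> list[DetectionProfile]:
    """Detection profiles straight from a matrix's (pre-imputation) mask."""
    return detection_counts(matrix.mask, design, level=level)
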