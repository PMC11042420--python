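"""Spread categories and alpha/beta/gamma clonality classes.

A mutation present in a single field is *alpha*; a mutation spread over
several fields with consistently low VAFs is *beta*; one spread with a
high median VAF is *gamma*. Presence is gated by a VAF threshold
(default 0.01) and optionally a minimum read depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .organ_io import GROUPS, MutationRecord, OrganMap, VafMatrix

SPREAD_CATEGORIES = (
    "private",
    "regional_2_10",
    "regional_11_20",
    "widespread_21_30",
    "widespread_gt30",
)

CLASSES = ("alpha", "beta", "gamma")


@dataclass(frozen=True)
class MutationClassCall:
    mutation_id: str
    n_fields_present: int
    spread: str
    median_vaf_present: float
    frac_fields_below_high: float
    class_label: str
    mixed_warning: bool = False


def presence_matrix(
    vafs: VafMatrix, vaf_threshold: float = 0.01, min_depth: int | None = None
) -> np.ndarray:
    """Boolean mutations x fields matrix: VAF >= threshold (and depth gate)."""
    if not (0.0 < vaf_threshold < 1.0):
        raise ValidationError(
            f"vaf_threshold must lie in the open interval (0, 1), got {vaf_threshold}"
        )
    present = (vafs.values >= vaf_threshold) & vafs.mask
    if min_depth is not None:
        if vafs.depth is None:
            raise ValidationError("min_depth requested but the matrix has no depths")
        present &= vafs.depth >= min_depth
    return present


def spread_category(n_fields_present: int) -> str:
    if n_fields_present == 0:
        raise ValidationError("mutation absent everywhere")
    if n_fields_present < 0:
        raise ValidationError("negative field count")
    if n_fields_present == 1:
        return "private"
    if n_fields_present <= 10:
        return "regional_2_10"
    if n_fields_present <= 20:
        return "regional_11_20"
    if n_fields_present <= 30:
        return "widespread_21_30"
    return "widespread_gt30"


def classify_mutation(
    presence_row: np.ndarray,
    vaf_row: np.ndarray,
    mutation_id: str = "",
    high_vaf: float = 0.20,
    consistency: float = 0.90,
) -> MutationClassCall:
    """Classify one mutation from its per-field presence and VAF vectors.

    alpha: private. gamma: median VAF over present fields strictly above
    ``high_vaf``. beta: at least ``consistency`` of present fields below
    ``high_vaf``; remaining cases are beta with a mixed warning.
    """
    presence_row = np.asarray(presence_row, dtype=bool)
    vaf_row = np.asarray(vaf_row, dtype=float)
    n = int(presence_row.sum())
    if n == 0:
        raise ValidationError(f"mutation {mutation_id!r} absent everywhere")
    present_vafs = vaf_row[presence_row]
    med = float(np.median(present_vafs))
    frac_below = float(np.mean(present_vafs < high_vaf))
    spread = spread_category(n)
    mixed = False
    if n == 1:
        label = "alpha"
    elif med > high_vaf:
        label = "gamma"
    else:
        label = "beta"
        if frac_below < consistency:
            mixed = True
    return MutationClassCall(
        mutation_id=mutation_id,
        n_fields_present=n,
        spread=spread,
        median_vaf_present=med,
        frac_fields_below_high=frac_below,
        class_label=label,
        mixed_warning=mixed,
    )


def classify_all(
    vafs: VafMatrix,
    vaf_threshold: float = 0.01,
    high_vaf: float = 0.20,
    consistency: float = 0.90,
    min_depth: int | None = None,
) -> list[MutationClassCall]:
    """Classify every mutation present in at least one field.

    Mutations absent everywhere at the threshold are skipped (they carry no
    class); callers needing strict coverage should check the lengths.
    """
    present = presence_matrix(vafs, vaf_threshold, min_depth)
    calls = []
    for i, mid in enumerate(vafs.mutation_ids):
        if not present[i].any():
            continue
        calls.append(
            classify_mutation(
                present[i], vafs.values[i], mid, high_vaf=high_vaf, consistency=consistency
            )
        )
    return calls


def calls_to_frame(calls: Sequence[MutationClassCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mutation_id": [c.mutation_id for c in calls],
            "n_fields_present": [c.n_fields_present for c in calls],
            "spread": [c.spread for c in calls],
            "median_vaf_present": [c.median_vaf_present for c in calls],
            "frac_fields_below_high": [c.frac_fields_below_high for c in calls],
            "class_label": [c.class_label for c in calls],
            "mixed_warning": [c.mixed_warning for c in calls],
        }
    )


def trend_annotation(
    vafs: VafMatrix,
    organ_map: OrganMap,
    calls: Sequence[MutationClassCall],
    vaf_threshold: float = 0.01,
) -> pd.DataFrame:
    """Monotone-trend flag across NU/LGIN -> HGIN -> UC group median VAFs.

    Descriptive only: a mutation is flagged 'increasing' when the medians of
    its present-field VAFs are strictly increasing along the ordered groups
    (groups with no present field break the trend).
    """
    present = presence_matrix(vafs, vaf_threshold)
    group_cols = {g: [j for j, gg in enumerate(organ_map.groups) if gg == g] for g in GROUPS}
    rows = []
    index_of = {m: i for i, m in enumerate(vafs.mutation_ids)}
    for c in calls:
        i = index_of[c.mutation_id]
        meds = []
        for g in GROUPS:
            cols = group_cols[g]
            sel = [j for j in cols if present[i, j]]
            meds.append(float(np.median(vafs.values[i, sel])) if sel else np.nan)
        increasing = (
            not any(np.isnan(m) for m in meds)
            and meds[0] < meds[1] < meds[2]
        )
        rows.append({"mutation_id": c.mutation_id, "group_medians": meds, "increasing": increasing})
    return pd.DataFrame(rows)


def class_summary(
    calls: Sequence[MutationClassCall],
    records: Sequence[MutationRecord],
    organ_map: OrganMap,
    vafs: VafMatrix,
    vaf_threshold: float = 0.01,
    hist_bins: int = 20,
) -> dict[str, pd.DataFrame]:
    """Per-field counts by class, per-group burden, driver fractions, VAF histograms."""
    rec_by_id = {r.mutation_id: r for r in records}
    present = presence_matrix(vafs, vaf_threshold)
    index_of = {m: i for i, m in enumerate(vafs.mutation_ids)}

    # per-field class counts
    counts = np.zeros((len(organ_map), len(CLASSES)), dtype=int)
    for c in calls:
        i = index_of[c.mutation_id]
        k = CLASSES.index(c.class_label)
        counts[present[i], k] += 1
    per_field = pd.DataFrame(counts, columns=list(CLASSES))
    per_field.insert(0, "field_id", organ_map.field_ids)
    per_field.insert(1, "group", organ_map.groups)
    per_field["total"] = counts.sum(axis=1)

    # per-group burden (box-plot stats over per-field totals)
    burden_rows = []
    for g in GROUPS:
        totals = per_field.loc[per_field["group"] == g, "total"].to_numpy(dtype=float)
        if totals.size == 0:
            continue
        q1, q2, q3 = np.percentile(totals, [25, 50, 75])
        burden_rows.append(
            {
                "group": g,
                "n_fields": totals.size,
                "median": q2,
                "q1": q1,
                "q3": q3,
                "min": totals.min(),
                "max": totals.max(),
            }
        )
    per_group = pd.DataFrame(burden_rows)

    # driver fraction and pooled VAF histograms per class
    driver_rows = []
    hist_frames = []
    edges = np.linspace(0.0, 1.0, hist_bins + 1)
    for k, label in enumerate(CLASSES):
        sel = [c for c in calls if c.class_label == label]
        n_drv = sum(rec_by_id[c.mutation_id].is_cosmic_driver for c in sel)
        driver_rows.append(
            {
                "class_label": label,
                "n_mutations": len(sel),
                "n_driver": n_drv,
                "driver_fraction": n_drv / len(sel) if sel else 0.0,
            }
        )
        pooled = np.concatenate(
            [
                vafs.values[index_of[c.mutation_id], present[index_of[c.mutation_id]]]
                for c in sel
            ]
        ) if sel else np.empty(0)
        h, _ = np.histogram(pooled, bins=edges)
        hist_frames.append(
            pd.DataFrame(
                {
                    "class_label": label,
                    "bin_left": edges[:-1],
                    "bin_right": edges[1:],
                    "count": h,
                }
            )
        )
    return {
        "per_field": per_field,
        "per_group": per_group,
        "driver_fractions": pd.DataFrame(driver_rows),
        "vaf_histograms": pd.concat(hist_frames, ignore_index=True),
    }
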