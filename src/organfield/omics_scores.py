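"""Downstream omics statistics: imputation, differential and monotonic
feature selection, and single-sample gene-set enrichment (ssGSEA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError


@dataclass
class AbundanceMatrix:
    """Features x samples abundances; missing entries are NaN."""

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    groups: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError("abundance matrix shape mismatch")
        if len(self.groups) != len(self.sample_ids):
            raise ValidationError("group labels must cover all samples")
        observed = self.values[~np.isnan(self.values)]
        if observed.size and observed.min() < 0:
            raise ValidationError("abundances must be non-negative")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def samples_in_group(self, group: str) -> np.ndarray:
        return np.asarray([g == group for g in self.groups])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class PathwaySet:
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"pathway {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"pathway {self.name!r} has duplicate members")


@dataclass
class EnrichmentScores:
    values: np.ndarray
    pathway_names: list[str]
    sample_ids: list[str]
    normalized: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.pathway_names, columns=self.sample_ids)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_gmt(path) -> list[PathwaySet]:
    """GMT: name <tab> description <tab> member1 <tab> member2 ..."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"GMT line {ln}: need name, description, members")
            members = tuple(dict.fromkeys(p for p in parts[2:] if p))
            out.append(PathwaySet(name=parts[0], members=members))
    return out


def write_gmt(pathways: Sequence[PathwaySet], path) -> None:
    with open(path, "w") as fh:
        for p in pathways:
            fh.write("\t".join([p.name, "na", *p.members]) + "\n")


def read_abundance_matrix(path, groups: Mapping[str, str] | None = None) -> AbundanceMatrix:
    """TSV with feature_id index column and one column per sample.

    ``groups`` maps sample id -> group label; when omitted, an optional
    second header line is not supported and every sample gets group 'na'.
    Empty cells are missing.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    sample_ids = [str(c) for c in df.columns]
    if groups is None:
        labels = ["na"] * len(sample_ids)
    else:
        missing = [s for s in sample_ids if s not in groups]
        if missing:
            raise ValidationError(f"samples without a group label: {missing}")
        labels = [groups[s] for s in sample_ids]
    return AbundanceMatrix(
        values=df.to_numpy(dtype=float),
        feature_ids=[str(i) for i in df.index],
        sample_ids=sample_ids,
        groups=labels,
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def impute_half_min(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Replace every missing value with half the dataset-wide observed minimum."""
    vals = matrix.values
    observed = vals[~np.isnan(vals)]
    if observed.size == 0:
        raise ValidationError("cannot impute an all-missing matrix")
    fill = float(observed.min()) / 2.0
    out = np.where(np.isnan(vals), fill, vals)
    return replace(matrix, values=out)


def differential_features(
    matrix: AbundanceMatrix,
    group_a: str,
    group_b: str,
    equal_var: bool = False,
    p_cutoff: float = 0.05,
    fold_cutoff: float = 1.5,
) -> pd.DataFrame:
    """Two-sample t-test on log2 abundances plus a linear fold-change rule.

    A feature is flagged when p < ``p_cutoff`` and the ratio of group means
    (computed on the linear scale) exceeds ``fold_cutoff`` in either
    direction. Welch's test by default. Set ``fold_cutoff=0`` to disable
    the fold criterion.
    """
    sel_a = matrix.samples_in_group(group_a)
    sel_b = matrix.samples_in_group(group_b)
    if sel_a.sum() < 2 or sel_b.sum() < 2:
        raise ValidationError("need at least two samples per group")
    if matrix.missing_mask.any():
        raise ValidationError("impute missing values before testing")
    A = matrix.values[:, sel_a]
    B = matrix.values[:, sel_b]
    with np.errstate(divide="ignore"):
        la, lb = np.log2(A), np.log2(B)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_a / mean_b
        log2fc = np.log2(fc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = scipy.stats.ttest_ind(la, lb, axis=1, equal_var=equal_var).pvalue
    # zero variance in both groups: p=1 when means are equal
    degenerate = np.isnan(p)
    p = np.where(degenerate & np.isclose(mean_a, mean_b), 1.0, p)
    p = np.where(np.isnan(p), 0.0, p)
    fold_ok = (
        np.ones_like(p, dtype=bool)
        if fold_cutoff == 0
        else (np.maximum(fc, 1.0 / fc) > fold_cutoff)
    )
    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "log2fc": log2fc,
            "p": p,
            "flag": (p < p_cutoff) & fold_ok,
        }
    )


def monotonic_features(
    matrix: AbundanceMatrix,
    ordered_groups: Sequence[str] = ("NU_LGIN", "HGIN", "UC"),
    reference: str = "control",
    eps: float = 0.0,
) -> dict[str, list[str]]:
    """Features whose group means change strictly monotonically.

    'up': means strictly increase along ``ordered_groups`` and every group
    mean exceeds the reference mean (by more than ``eps``); 'down' is the
    mirror image.
    """
    if matrix.missing_mask.any():
        raise ValidationError("impute missing values before trend selection")
    sels = [matrix.samples_in_group(g) for g in ordered_groups]
    ref_sel = matrix.samples_in_group(reference)
    if not ref_sel.any() or any(not s.any() for s in sels):
        raise ValidationError("every ordered group and the reference must be non-empty")
    means = np.column_stack([matrix.values[:, s].mean(axis=1) for s in sels])
    ref = matrix.values[:, ref_sel].mean(axis=1)
    inc = np.all(np.diff(means, axis=1) > eps, axis=1) & np.all(means > (ref + eps)[:, None], axis=1)
    dec = np.all(np.diff(means, axis=1) < -eps, axis=1) & np.all(means < (ref - eps)[:, None], axis=1)
    feats = np.asarray(matrix.feature_ids)
    return {"up": list(feats[inc]), "down": list(feats[dec])}


def ssgsea(
    matrix: AbundanceMatrix,
    pathways: Sequence[PathwaySet],
    weight_exponent: float = 0.75,
    normalize: bool = False,
) -> EnrichmentScores:
    """Single-sample enrichment scores (integral of the weighted ECDF gap).

    Per sample, features are ranked by abundance (descending walk, mid-rank
    tie values); the score is the sum over the ranked list of the weighted
    in-set ECDF minus the out-set ECDF. Pathway members absent from the
    matrix are dropped (with a warning); pathways with fewer than two
    remaining members are dropped. A pathway equal to the whole feature set
    has an empty complement and is an error.
    """
    if matrix.missing_mask.any():
        raise ValidationError("impute missing values before ssGSEA")
    n, m = matrix.values.shape
    feat_index = {f: i for i, f in enumerate(matrix.feature_ids)}
    kept: list[PathwaySet] = []
    member_idx: list[np.ndarray] = []
    for p in pathways:
        idx = [feat_index[f] for f in p.members if f in feat_index]
        if len(idx) < len(p.members):
            warnings.warn(
                f"pathway {p.name!r}: {len(p.members) - len(idx)} member(s) "
                "absent from the matrix", stacklevel=2,
            )
        if len(idx) >= n:
            raise ValidationError(
                f"pathway {p.name!r} covers the entire feature set (empty complement)"
            )
        if len(idx) < 2:
            warnings.warn(f"pathway {p.name!r} dropped (<2 members present)", stacklevel=2)
            continue
        kept.append(p)
        member_idx.append(np.asarray(idx))
    scores = np.zeros((len(kept), m))
    for j in range(m):
        col = matrix.values[:, j]
        ranks = scipy.stats.rankdata(col)  # ascending, mid-rank ties
        order = np.argsort(-col, kind="stable")
        w = ranks[order] ** weight_exponent
        for k, idx in enumerate(member_idx):
            in_set = np.zeros(n, dtype=bool)
            in_set[idx] = True
            s = in_set[order]
            win = np.where(s, w, 0.0)
            num = np.cumsum(win)
            num /= num[-1]
            den = np.cumsum(~s) / float(n - s.sum())
            scores[k, j] = float((num - den).sum())
    if normalize:
        span = scores.max() - scores.min()
        if span > 0:
            scores = scores / span
    return EnrichmentScores(
        values=scores,
        pathway_names=[p.name for p in kept],
        sample_ids=list(matrix.sample_ids),
        normalized=normalize,
    )
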