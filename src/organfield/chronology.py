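"""Branching-process chronology: expected VAF sequences, (a, b) fits,
inversion to proliferation rate and mutation age, and phase assignment.

Model: a mutant clone of age ``t`` grows as exp(rho * t) with rho = lambda*s
and seeds secondary clones into other fields by a Poisson process of
intensity nu. With a = rho*t, b = nu*t and c = 2 * cells haploid genomes,
the expected VAF of the i-th clone (i = 0 primary) is

    EV_0 = exp(a) / c
    EV_i = exp(a) * (b / (a+b))**i * P(i, a+b) / c          (i >= 1)

where P(i, x) is the regularized lower incomplete gamma function with
integer shape i. Under the migration law nu = nu0 * rho**sigma the pair
(a, b) inverts to (rho, t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize
from scipy.special import gammainc

from .errors import ValidationError
from .organ_io import MutationRecord, VafMatrix


@dataclass(frozen=True)
class ChronologyConfig:
    sigma: float = 6.0
    nu0: float = 1.0
    cells: float = 5e3
    i_max: int = 25
    a_max: float = 50.0
    b_max: float = 50.0
    phase_cutoff_years: float = 5.0
    presence_threshold: float = 0.01
    expected_detections: float = 0.5  # kappa of the private-mutation fallback

    def __post_init__(self) -> None:
        if self.sigma <= 1:
            raise ValidationError("sigma must exceed 1")
        if self.nu0 <= 0:
            raise ValidationError("nu0 must be positive")
        if self.cells < 1:
            raise ValidationError("cells must be >= 1")
        if self.i_max < 1:
            raise ValidationError("i_max must be >= 1")

    @property
    def c(self) -> float:
        """Haploid genome count of the uroprogenitor pool."""
        return 2.0 * self.cells


@dataclass(frozen=True)
class MutationFit:
    mutation_id: str
    a: float
    b: float
    sse: float
    rho: float
    t: float
    sel_proxy: float
    phase: str
    n_fields_fit: int
    flags: tuple[str, ...] = ()


def expected_vaf_sequence(a: float, b: float, c: float, i_max: int) -> np.ndarray:
    """EV_i for i = 0..i_max; log-space products for numerical stability."""
    if a < 0 or b < 0:
        raise ValidationError("a and b must be non-negative")
    if c <= 0:
        raise ValidationError("c must be positive")
    if i_max < 0:
        raise ValidationError("i_max must be >= 0")
    out = np.zeros(i_max + 1)
    out[0] = math.exp(a) / c
    if i_max == 0 or b == 0:
        return out
    i = np.arange(1, i_max + 1, dtype=float)
    x = a + b
    with np.errstate(divide="ignore"):
        log_p = np.log(gammainc(i, x))
        log_ev = a + i * (math.log(b) - math.log(x)) + log_p - math.log(c)
    out[1:] = np.exp(log_ev)
    return out


def _sse(params: np.ndarray, obs: np.ndarray, c: float, cfg: ChronologyConfig) -> float:
    a = min(max(params[0], 0.0), cfg.a_max)
    b = min(max(params[1], 0.0), cfg.b_max)
    ev = expected_vaf_sequence(a, b, c, len(obs) - 1)
    pen = (max(0.0, params[0] - cfg.a_max) + max(0.0, -params[0])
           + max(0.0, params[1] - cfg.b_max) + max(0.0, -params[1]))
    return float(((ev - obs) ** 2).sum()) * (1.0 + pen) + pen * 1e-6


def fit_ab(
    vaf_row: np.ndarray,
    config: ChronologyConfig = ChronologyConfig(),
    mask: np.ndarray | None = None,
) -> tuple[float, float, float, int, tuple[str, ...]]:
    """Estimate (a, b) for one mutation from its per-field VAFs.

    Present-field VAFs (>= presence threshold) are sorted in descending
    order and paired with EV_0, EV_1, ...; (a, b) minimizes the sum of
    squared differences on [0, a_max] x [0, b_max]. Deterministic
    multistart Nelder-Mead followed by bounded coordinate refinement.

    Returns ``(a, b, sse, n_fields_fit, flags)``.
    """
    vaf_row = np.asarray(vaf_row, dtype=float)
    present = vaf_row >= config.presence_threshold
    if mask is not None:
        present &= np.asarray(mask, dtype=bool)
    obs = np.sort(vaf_row[present])[::-1]
    if obs.size == 0:
        raise ValidationError("all VAFs below the presence threshold")
    c = config.c
    if obs.size == 1:
        a = max(0.0, math.log(obs[0] * c))
        return a, 0.0, 0.0, 1, ("b_unidentifiable",)

    a0 = float(np.clip(math.log(max(obs[0], 1e-12) * c), 0.0, config.a_max))
    r = obs[1] / obs[0] if obs[0] > 0 else 0.5
    r = min(max(r, 1e-3), 1 - 1e-3)
    b0 = float(np.clip(r * max(a0, 1e-6) / (1.0 - r), 1e-3, config.b_max))
    starts = [
        (a0, b0),
        (a0, 1.0),
        (1.0, 1.0),
        (config.a_max / 2.0, config.b_max / 2.0),
        (a0, config.b_max / 2.0),
    ]
    best = None
    for s in starts:
        res = scipy.optimize.minimize(
            _sse, np.asarray(s, dtype=float), args=(obs, c, config),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-14, "maxiter": 2000},
        )
        a_hat = float(np.clip(res.x[0], 0.0, config.a_max))
        b_hat = float(np.clip(res.x[1], 0.0, config.b_max))
        val = _sse(np.array([a_hat, b_hat]), obs, c, config)
        if best is None or val < best[0]:
            best = (val, a_hat, b_hat, res.success)
    _, a_hat, b_hat, converged = best

    # bounded coordinate refinement (three sweeps)
    for _ in range(3):
        res_a = scipy.optimize.minimize_scalar(
            lambda a: _sse(np.array([a, b_hat]), obs, c, config),
            bounds=(0.0, config.a_max), method="bounded",
            options={"xatol": 1e-10},
        )
        a_hat = float(res_a.x)
        res_b = scipy.optimize.minimize_scalar(
            lambda b: _sse(np.array([a_hat, b]), obs, c, config),
            bounds=(0.0, config.b_max), method="bounded",
            options={"xatol": 1e-10},
        )
        b_hat = float(res_b.x)
    sse = _sse(np.array([a_hat, b_hat]), obs, c, config)
    flags = () if converged else ("optimizer_not_converged",)
    return a_hat, b_hat, float(sse), int(obs.size), flags


def invert_to_age(
    a: float, b: float, config: ChronologyConfig = ChronologyConfig()
) -> tuple[float, float]:
    """(rho, t) from (a, b) under the migration law nu = nu0 * rho**sigma."""
    if a <= 0 or b <= 0:
        raise ValidationError("age inversion requires a > 0 and b > 0")
    expo = 1.0 / (config.sigma - 1.0)
    rho = (b / (a * config.nu0)) ** expo
    t = a ** (1.0 + expo) * (config.nu0 / b) ** expo
    return float(rho), float(t)


def fallback_age_private(
    a: float, config: ChronologyConfig = ChronologyConfig()
) -> tuple[float, float, float]:
    """(rho, t, b_eff) for a private mutation (b unidentifiable).

    Non-observation bound: the expected number of *detectable* secondary
    clones, nu0 * rho**(sigma-1) * (a - a_thr) with a_thr = log(threshold*c),
    is pinned at ``expected_detections``; together with a = rho*t this
    yields a deterministic (rho, t).
    """
    if a <= 0:
        raise ValidationError("fallback requires a > 0")
    a_thr = math.log(config.presence_threshold * config.c)
    slack = max(a - a_thr, 1e-3)
    rho = (config.expected_detections / (config.nu0 * slack)) ** (1.0 / (config.sigma - 1.0))
    t = a / rho
    b_eff = config.expected_detections * a / slack
    return float(rho), float(t), float(b_eff)


def assign_phase(t: float, config: ChronologyConfig = ChronologyConfig()) -> str:
    """'progressive' strictly below the cutoff, else 'dormant'."""
    if t < 0:
        raise ValidationError("age must be non-negative")
    return "progressive" if t < config.phase_cutoff_years else "dormant"


def fit_mutations(
    vafs: VafMatrix,
    config: ChronologyConfig = ChronologyConfig(),
) -> pd.DataFrame:
    """Per-mutation chronology fits over a whole VAF matrix.

    Mutations absent everywhere at the presence threshold are skipped.
    Private mutations use the non-observation fallback for (rho, t).
    """
    rows = []
    for i, mid in enumerate(vafs.mutation_ids):
        row = np.where(vafs.mask[i], vafs.values[i], 0.0)
        if not (row >= config.presence_threshold).any():
            continue
        a, b, sse, n_fit, flags = fit_ab(row, config, mask=vafs.mask[i])
        if a > 0 and b > 0:
            rho, t = invert_to_age(a, b, config)
            sel = a / b
        elif a > 0:
            rho, t, b_eff = fallback_age_private(a, config)
            sel = a / b_eff
            flags = flags + ("age_from_fallback",)
        else:
            rho, t, sel = 0.0, 0.0, np.nan
            flags = flags + ("degenerate_fit",)
        rows.append(
            {
                "mutation_id": mid,
                "a": a,
                "b": b,
                "sse": sse,
                "rho": rho,
                "t": t,
                "sel_proxy": sel,
                "phase": assign_phase(t, config),
                "n_fields_fit": n_fit,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)


def cells_scan(
    vafs: VafMatrix,
    config: ChronologyConfig = ChronologyConfig(),
    cells_grid: Sequence[float] = (1e2, 1e3, 5e3, 1e4, 1e5),
) -> pd.DataFrame:
    """Total fit SSE for each candidate uroprogenitor cell count."""
    rows = []
    for cells in cells_grid:
        cfg = replace(config, cells=float(cells))
        fits = fit_mutations(vafs, cfg)
        rows.append({"cells": float(cells), "total_sse": float(fits["sse"].sum()),
                     "n_mutations": len(fits)})
    df = pd.DataFrame(rows)
    df["is_best"] = df["total_sse"] == df["total_sse"].min()
    return df


def chronology_report(
    fits: pd.DataFrame,
    calls: pd.DataFrame,
    records: Sequence[MutationRecord],
    vafs: VafMatrix,
    config: ChronologyConfig = ChronologyConfig(),
) -> dict[str, pd.DataFrame]:
    """Cohort summaries: ages per class, per-phase burdens and VAFs."""
    rec_by_id = {r.mutation_id: r for r in records}
    merged = fits.merge(
        calls[["mutation_id", "class_label"]], on="mutation_id", how="left"
    )
    merged["coding_effect"] = [
        rec_by_id[m].coding_effect if m in rec_by_id else "unknown"
        for m in merged["mutation_id"]
    ]

    age_rows = []
    for label, grp in merged.groupby("class_label"):
        t = grp["t"].to_numpy()
        age_rows.append(
            {
                "class_label": label,
                "n": len(grp),
                "median_age": float(np.median(t)),
                "q1_age": float(np.percentile(t, 25)),
                "q3_age": float(np.percentile(t, 75)),
                "median_sel_proxy": float(np.nanmedian(grp["sel_proxy"].to_numpy())),
            }
        )

    idx_of = {m: i for i, m in enumerate(vafs.mutation_ids)}
    phase_rows = []
    for phase, grp in merged.groupby("phase"):
        pooled = []
        for m in grp["mutation_id"]:
            i = idx_of[m]
            sel = vafs.mask[i] & (vafs.values[i] >= config.presence_threshold)
            pooled.append(vafs.values[i, sel])
        pooled = np.concatenate(pooled) if pooled else np.empty(0)
        phase_rows.append(
            {
                "phase": phase,
                "n_mutations": len(grp),
                "n_silent": int((grp["coding_effect"] == "silent").sum()),
                "n_non_silent": int((grp["coding_effect"] == "non_silent").sum()),
                "median_vaf": float(np.median(pooled)) if pooled.size else np.nan,
                "median_age": float(np.median(grp["t"])),
            }
        )

    return {
        "ages_by_class": pd.DataFrame(age_rows),
        "phases": pd.DataFrame(phase_rows),
        "per_mutation": merged,
    }
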