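"""Substitution spectra, 96-motif catalogs and signature-weight refitting.

Weights are the solution of the simplex-constrained least-squares problem

    min_H (W H - V)' (W H - V)   s.t.  H >= 0,  sum(H) = 1

solved by non-negative least squares on an augmented system with a large
penalty row enforcing the sum constraint, followed by an exact KKT polish
on the active set. Significance of individual signatures is assessed by a
multinomial bootstrap of the catalog.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .organ_io import (
    CANONICAL_MOTIFS,
    COMPLEMENT,
    MOTIF_INDEX,
    SUBSTITUTION_CLASSES,
    MutationRecord,
)

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SpectrumCatalog:
    """6-class and (optional) 96-motif mutation counts for a selection of SNVs."""

    counts6: np.ndarray
    n: int
    counts96: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts6 = np.asarray(self.counts6, dtype=float)
        if self.counts6.shape != (6,):
            raise ValidationError("counts6 must be a 6-vector")
        if self.counts6.sum() != self.n:
            raise ValidationError("counts6 must sum to n")
        if self.counts96 is not None:
            self.counts96 = np.asarray(self.counts96, dtype=float)
            if self.counts96.shape != (96,):
                raise ValidationError("counts96 must be a 96-vector")
            if self.counts96.sum() != self.n:
                raise ValidationError("counts96 must sum to n")

    @property
    def V(self) -> np.ndarray:
        """96-motif catalog normalized to the probability simplex."""
        if self.counts96 is None:
            raise ValidationError("catalog has no 96-motif counts")
        if self.n == 0:
            raise ValidationError("empty catalog has no simplex representation")
        return self.counts96 / self.n


@dataclass
class SignatureMatrix:
    """Column-stochastic 96 x K signature matrix."""

    W: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != 96:
            raise ValidationError("W must be 96 x K")
        if self.W.shape[1] == 0:
            raise ValidationError("signature matrix needs at least one column")
        if self.W.shape[1] != len(self.labels):
            raise ValidationError("label count does not match K")
        if (self.W < 0).any():
            raise ValidationError("W has negative entries")
        if np.abs(self.W.sum(axis=0) - 1.0).max() > 1e-6:
            raise ValidationError("W columns must sum to 1 within 1e-6")
        self.W = self.W / self.W.sum(axis=0)

    @property
    def K(self) -> int:
        return self.W.shape[1]


@dataclass
class WeightResult:
    H: np.ndarray
    objective: float
    labels: list[str]
    boot_p: np.ndarray | None = None
    B: int | None = None
    seed: int | None = None

    def to_series(self) -> pd.Series:
        return pd.Series(self.H, index=self.labels)


# ---------------------------------------------------------------------------
# catalogs
# ---------------------------------------------------------------------------


def pyrimidine_substitution(ref: str, alt: str) -> str:
    """Map an SNV to its pyrimidine-reference substitution class."""
    if ref in ("C", "T"):
        sub = f"{ref}>{alt}"
    else:
        sub = f"{COMPLEMENT[ref]}>{COMPLEMENT[alt]}"
    if sub not in SUBSTITUTION_CLASSES:
        raise ValidationError(f"not a substitution: {ref}>{alt}")
    return sub


def pyrimidine_motif(ref: str, alt: str, context: str) -> str:
    """Canonical motif label for an SNV, reverse-complementing purine refs."""
    if context[1] != ref:
        raise ValidationError(f"context {context!r} center does not match ref {ref!r}")
    if ref in ("C", "T"):
        sub = f"{ref}>{alt}"
        five, three = context[0], context[2]
    else:
        sub = f"{COMPLEMENT[ref]}>{COMPLEMENT[alt]}"
        five, three = COMPLEMENT[context[2]], COMPLEMENT[context[0]]
    return f"{five}[{sub}]{three}"


def _select(records: Sequence[MutationRecord], selection) -> list[MutationRecord]:
    snvs = [r for r in records if r.is_snv]
    if selection is None:
        return snvs
    sel = set(selection)
    return [r for r in snvs if r.mutation_id in sel]


def substitution_spectrum(
    records: Sequence[MutationRecord], selection: Iterable[str] | None = None
) -> SpectrumCatalog:
    """6-class substitution counts over the selected SNVs."""
    snvs = _select(records, selection)
    counts = np.zeros(6)
    for r in snvs:
        counts[SUBSTITUTION_CLASSES.index(pyrimidine_substitution(r.ref, r.alt))] += 1
    return SpectrumCatalog(counts6=counts, n=len(snvs))


def context_catalog96(
    records: Sequence[MutationRecord],
    selection: Iterable[str] | None = None,
    on_missing: str = "error",
) -> SpectrumCatalog:
    """96-motif catalog; purine-reference SNVs are reverse-complemented.

    ``on_missing``: 'error' raises listing mutations without context;
    'skip' drops them.
    """
    snvs = _select(records, selection)
    missing = [r.mutation_id for r in snvs if r.context is None]
    if missing:
        if on_missing == "error":
            raise ValidationError(
                f"{len(missing)} SNV(s) without trinucleotide context, e.g. {missing[:5]}"
            )
        if on_missing != "skip":
            raise ValueError(f"unknown on_missing {on_missing!r}")
        snvs = [r for r in snvs if r.context is not None]
    counts96 = np.zeros(96)
    counts6 = np.zeros(6)
    for r in snvs:
        motif = pyrimidine_motif(r.ref, r.alt, r.context)
        counts96[MOTIF_INDEX[motif]] += 1
        counts6[SUBSTITUTION_CLASSES.index(motif[2:5])] += 1
    return SpectrumCatalog(counts6=counts6, n=len(snvs), counts96=counts96)


def catalog_from_counts96(counts96: np.ndarray) -> SpectrumCatalog:
    """Build a catalog directly from a 96-vector of motif counts."""
    counts96 = np.asarray(counts96, dtype=float)
    counts6 = counts96.reshape(6, 16).sum(axis=1)
    return SpectrumCatalog(counts6=counts6, n=int(counts96.sum()), counts96=counts96)


# ---------------------------------------------------------------------------
# simplex-constrained quadratic fit
# ---------------------------------------------------------------------------


def _kkt_polish(W: np.ndarray, V: np.ndarray, H: np.ndarray, iters: int = 50) -> np.ndarray:
    """Exact equality-constrained solve on the positive support of H.

    Solves min ||W_S h - V|| s.t. sum(h) = 1 restricted to the support S,
    dropping negative coordinates until feasible.
    """
    K = W.shape[1]
    support = H > 1e-12
    if not support.any():
        support[int(np.argmin(((W - V[:, None]) ** 2).sum(axis=0)))] = True
    for _ in range(iters):
        idx = np.flatnonzero(support)
        Ws = W[:, idx]
        # KKT system for min ||Ws h - V||^2 s.t. 1'h = 1
        A = Ws.T @ Ws
        ones = np.ones(len(idx))
        M = np.block([[A, ones[:, None]], [ones[None, :], np.zeros((1, 1))]])
        rhs = np.concatenate([Ws.T @ V, [1.0]])
        try:
            sol = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError:
            sol, *_ = np.linalg.lstsq(M, rhs, rcond=None)
        h = sol[: len(idx)]
        if (h >= -1e-12).all():
            out = np.zeros(K)
            out[idx] = np.clip(h, 0.0, None)
            s = out.sum()
            return out / s if s > 0 else out
        support[idx[np.argmin(h)]] = False
        if not support.any():
            break
    return H


def fit_signature_weights(
    V: np.ndarray,
    W: SignatureMatrix,
    strict: bool = True,
    penalty: float = 1e4,
) -> WeightResult:
    """Simplex-constrained least-squares weights of the signatures for V."""
    V = np.asarray(V, dtype=float)
    if V.shape != (96,):
        raise ValidationError("V must be a 96-vector")
    if W.K == 0:
        raise ValidationError("signature matrix has no columns")
    s = V.sum()
    if abs(s - 1.0) > 1e-8:
        if strict:
            raise ValidationError(f"V sums to {s:.10f}, not 1 (strict mode)")
        if s <= 0:
            raise ValidationError("V has non-positive mass")
        V = V / s
    aug_A = np.vstack([W.W, np.full((1, W.K), penalty)])
    aug_b = np.concatenate([V, [penalty]])
    H0, _ = scipy.optimize.nnls(aug_A, aug_b)
    H = _kkt_polish(W.W, V, H0)
    resid = W.W @ H - V
    objective = float(resid @ resid)
    # candidate from the raw NNLS solution, renormalized; keep the better one
    s0 = H0.sum()
    if s0 > 0:
        H0n = H0 / s0
        r0 = W.W @ H0n - V
        if float(r0 @ r0) < objective:
            H, objective = H0n, float(r0 @ r0)
    return WeightResult(H=H, objective=objective, labels=list(W.labels))


def projected_gradient_weights(
    V: np.ndarray, W: np.ndarray, iters: int = 200_000, tol: float = 1e-16
) -> np.ndarray:
    """Slow projected-gradient reference solver (test oracle)."""
    V = np.asarray(V, dtype=float)
    W = np.asarray(W, dtype=float)
    K = W.shape[1]
    H = np.full(K, 1.0 / K)
    L = np.linalg.norm(W.T @ W, 2)
    step = 1.0 / L
    last = np.inf
    for it in range(iters):
        grad = 2.0 * W.T @ (W @ H - V)
        H = _project_simplex(H - step * grad)
        if it % 500 == 0:
            r = W @ H - V
            obj = float(r @ r)
            if last - obj < tol:
                break
            last = obj
    return H


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u * np.arange(1, len(v) + 1) > (css - 1))[0][-1]
    theta = (css[rho] - 1.0) / (rho + 1)
    return np.maximum(v - theta, 0.0)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_signature_pvalues(
    catalog: SpectrumCatalog,
    W: SignatureMatrix,
    B: int = 2000,
    seed: int = 0,
    w0: float = 0.01,
    mode: str = "null",
    alpha: float = 0.005,
) -> WeightResult:
    """Bootstrap the catalog and derive per-signature empirical p-values.

    Each replicate resamples the ``n`` mutations with replacement (equivalent
    to a multinomial draw over the observed motif distribution) and refits H.

    ``mode='null'`` (default): p_k = fraction of replicates with h_k <= w0 —
    the probability that signature k's contribution is not robustly above
    background. ``mode='literal'``: p_k = fraction of replicate weights >=
    the observed weight; descriptive only (it is ~0.5 for any stable weight
    and is not calibrated against a null).
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    if catalog.n == 0:
        raise ValidationError("cannot bootstrap an empty catalog")
    if mode not in ("null", "literal"):
        raise ValueError(f"unknown mode {mode!r}")
    observed = fit_signature_weights(catalog.V, W)
    rng = np.random.default_rng(seed)
    V = catalog.V
    hits = np.zeros(W.K)
    for _ in range(B):
        counts = rng.multinomial(catalog.n, V)
        Vb = counts / catalog.n
        Hb = fit_signature_weights(Vb, W).H
        if mode == "null":
            hits += Hb <= w0
        else:
            hits += Hb >= observed.H
    boot_p = hits / B
    return WeightResult(
        H=observed.H,
        objective=observed.objective,
        labels=list(W.labels),
        boot_p=boot_p,
        B=B,
        seed=seed,
    )


def significant_signatures(result: WeightResult, alpha: float = 0.005) -> list[str]:
    if result.boot_p is None:
        raise ValidationError("result carries no bootstrap p-values")
    return [lab for lab, p in zip(result.labels, result.boot_p) if p < alpha]


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------


def _table_log_prob(table: np.ndarray) -> float:
    """Log-probability of an r x c table under fixed-margin hypergeometric."""
    from scipy.special import gammaln

    table = np.asarray(table, dtype=float)
    n = table.sum()
    return float(
        gammaln(table.sum(axis=1) + 1).sum()
        + gammaln(table.sum(axis=0) + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def _enumerate_tables(row_margins, col_margins):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(row_margins), len(col_margins)

    def rec(i, cols_left, rows):
        if i == r - 1:
            last = np.asarray(cols_left)
            if (last >= 0).all():
                yield rows + [last]
            return
        target = row_margins[i]

        def fill(j, remaining, row):
            if j == c - 1:
                if 0 <= remaining <= cols_left[j]:
                    yield row + [remaining]
                return
            for v in range(min(remaining, cols_left[j]) + 1):
                yield from fill(j + 1, remaining - v, row + [v])

        for row in fill(0, target, []):
            new_left = [cl - v for cl, v in zip(cols_left, row)]
            yield from rec(i + 1, new_left, rows + [np.asarray(row)])

    yield from rec(0, list(col_margins), [])


def exact_rxc_test(
    table: np.ndarray,
    seed: int = 2024,
    n_mc: int = 100_000,
    enumerate_below: int = 30,
) -> float:
    """Fisher-style exact test for an r x c contingency table.

    2x2 tables use :func:`scipy.stats.fisher_exact`. Larger tables are
    enumerated exactly when the grand total is at most ``enumerate_below``,
    otherwise a fixed-seed Monte-Carlo over fixed-margin tables is used
    (probability-ordering statistic, >= ``n_mc`` tables).
    """
    table = np.asarray(table, dtype=int)
    if (table < 0).any():
        raise ValidationError("table entries must be non-negative")
    if table.shape == (2, 2):
        return float(scipy.stats.fisher_exact(table)[1])
    row_m = table.sum(axis=1)
    col_m = table.sum(axis=0)
    obs_lp = _table_log_prob(table)
    tol = 1e-9
    if table.sum() <= enumerate_below:
        p = 0.0
        for t in _enumerate_tables(list(row_m), list(col_m)):
            lp = _table_log_prob(np.asarray(t))
            if lp <= obs_lp + tol:
                p += np.exp(lp)
        return float(min(p, 1.0))
    # Monte-Carlo: permute category labels to draw fixed-margin tables
    rng = np.random.default_rng(seed)
    cats = np.repeat(np.arange(table.shape[1]), col_m)
    groups = np.repeat(np.arange(table.shape[0]), row_m)
    hits = 1  # add-one (include the observed table)
    for _ in range(n_mc):
        perm = rng.permutation(cats)
        t = np.zeros_like(table)
        np.add.at(t, (groups, perm), 1)
        if _table_log_prob(t) <= obs_lp + tol:
            hits += 1
    return hits / (n_mc + 1)


def compare_groups(
    data: Mapping[str, object],
    mode: str,
    seed: int = 2024,
) -> pd.DataFrame:
    """Statistical comparison of catalogs or weights across >= 2 groups.

    mode='spectrum': ``data`` maps group -> 6-vector of substitution counts;
    returns a one-row frame with the exact-test p-value.
    mode='motif': ``data`` maps group (exactly two) -> per-sample motif
    frequency matrix (n_samples x 96); per-motif rank-sum p with BH FDR.
    mode='weights': ``data`` maps group -> per-sample weight matrix
    (n_samples x K); Kruskal-Wallis per signature.
    """
    if len(data) < 2:
        raise ValidationError("need at least two groups")
    for g, v in data.items():
        if np.asarray(v).size == 0:
            raise ValidationError(f"group {g!r} is empty")
    if mode == "spectrum":
        table = np.vstack([np.asarray(v, dtype=int) for v in data.values()])
        p = exact_rxc_test(table, seed=seed)
        return pd.DataFrame({"test": ["exact_rxc"], "p": [p]})
    if mode == "motif":
        if len(data) != 2:
            raise ValidationError("mode='motif' is a two-sample comparison")
        (ga, A), (gb, Bm) = data.items()
        A = np.asarray(A, dtype=float)
        Bm = np.asarray(Bm, dtype=float)
        ps = []
        for j in range(A.shape[1]):
            a, b = A[:, j], Bm[:, j]
            if np.ptp(np.concatenate([a, b])) == 0:
                ps.append(1.0)
            else:
                ps.append(
                    float(
                        scipy.stats.mannwhitneyu(
                            a, b, alternative="two-sided", use_continuity=True,
                            method="asymptotic",
                        ).pvalue
                    )
                )
        rej, p_adj, _, _ = multipletests(ps, method="fdr_bh")
        return pd.DataFrame(
            {
                "motif": list(CANONICAL_MOTIFS)[: A.shape[1]],
                "p": ps,
                "fdr": p_adj,
                "significant": rej,
            }
        )
    if mode == "weights":
        mats = {g: np.asarray(v, dtype=float) for g, v in data.items()}
        K = next(iter(mats.values())).shape[1]
        rows = []
        for k in range(K):
            samples = [m[:, k] for m in mats.values()]
            if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
                p = 1.0
            else:
                try:
                    p = float(scipy.stats.kruskal(*samples).pvalue)
                except ValueError:  # all values identical
                    p = 1.0
            rows.append({"signature_index": k, "p": p})
        return pd.DataFrame(rows)
    raise ValueError(f"unknown mode {mode!r}")


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Step-up BH adjusted p-values (kept thin over statsmodels)."""
    return multipletests(list(pvalues), method="fdr_bh")[1]
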