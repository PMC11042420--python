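"""Synthetic whole-organ datasets with known ground truth.

Clone VAFs across the field grid follow the same branching-with-immigration
structure as the chronology estimator: a primary clone of deterministic
size exp(rho*t) in its seed field, secondary clones seeded by a Poisson
process of intensity nu on [0, t], each landing in a distinct field.
Observed VAFs add binomial read sampling at ~300X; trinucleotide contexts
are drawn from a signature mixture; omics tables carry planted monotone
trends.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .omics_scores import AbundanceMatrix
from .organ_io import (
    CANONICAL_MOTIFS,
    FieldInfo,
    MutationRecord,
    OrganMap,
    VafMatrix,
    write_field_annotations,
    write_mutation_table,
)
from .signatures import SignatureMatrix, SpectrumCatalog, catalog_from_counts96


@dataclass(frozen=True)
class CloneSpec:
    """Generating parameters of one mutant clone."""

    mutation_id: str
    rho: float  # proliferation rate lambda*s (1/year)
    nu: float  # immigration intensity (1/year)
    t: float  # age (years)
    seed_field: str
    class_label: str = "alpha"

    def __post_init__(self) -> None:
        if self.rho < 0 or self.nu < 0 or self.t < 0:
            raise ValidationError("rho, nu and t must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground-truth container for recovery tests."""

    clone_specs: list[CloneSpec]
    signature_ids: list[int]
    config: dict
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "config": self.config,
                "signature_ids": self.signature_ids,
                "clones": [dataclasses.asdict(c) for c in self.clone_specs],
            },
            indent=1,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# clone-level simulation
# ---------------------------------------------------------------------------


def simulate_clone_field_vafs(
    spec: CloneSpec,
    n_fields: int,
    cells: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """True per-field VAF vector for one clone; returns (vafs, n_cap_events).

    Secondary clones occupy distinct fields drawn uniformly without
    replacement; once fields run out, later clones merge into the last
    seeded field. VAFs are clone size / (2*cells), capped at 0.5.
    """
    if n_fields < 1:
        raise ValidationError("n_fields must be >= 1")
    c = 2.0 * cells
    sizes = np.zeros(n_fields)
    seed_idx = 0  # caller maps positions onto actual field ids
    sizes[seed_idx] = math.exp(spec.rho * spec.t)
    n_secondary = int(rng.poisson(spec.nu * spec.t)) if spec.nu * spec.t > 0 else 0
    if n_secondary > 0:
        times = np.sort(rng.uniform(0.0, spec.t, size=n_secondary))
        clone_sizes = np.exp(spec.rho * (spec.t - times))
        others = rng.permutation(np.arange(1, n_fields))
        k = min(n_secondary, len(others))
        sizes[others[:k]] = clone_sizes[:k]
        if n_secondary > k and k > 0:
            sizes[others[k - 1]] += clone_sizes[k:].sum()
    vafs = sizes / c
    n_capped = int((vafs > 0.5).sum())
    return np.minimum(vafs, 0.5), n_capped


# ---------------------------------------------------------------------------
# whole-organ simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimOrganConfig:
    n_rows: int = 5
    n_cols: int = 8
    n_fields: int = 38
    n_alpha: int = 1000
    n_beta: int = 50
    n_gamma: int = 30
    cells: float = 5e3
    coverage_mean: float = 300.0
    coverage_sd: float = 85.0
    min_depth: int = 30
    silent_fraction: float = 0.25
    # per-class generating ranges: age (years), a = rho*t, immigration nu
    alpha_age: tuple[float, float] = (10.0, 30.0)
    alpha_a: tuple[float, float] = (5.5, 7.5)
    beta_age: tuple[float, float] = (4.0, 8.0)
    beta_a: tuple[float, float] = (6.2, 7.2)
    beta_nu: tuple[float, float] = (3.0, 5.0)
    gamma_age: tuple[float, float] = (1.0, 3.0)
    gamma_a: tuple[float, float] = (7.8, 8.5)
    gamma_nu: tuple[float, float] = (150.0, 400.0)

    def __post_init__(self) -> None:
        if self.n_fields > self.n_rows * self.n_cols:
            raise ValidationError(
                f"{self.n_fields} fields do not fit a "
                f"{self.n_rows}x{self.n_cols} grid"
            )
        if min(self.n_alpha, self.n_beta, self.n_gamma) < 0:
            raise ValidationError("class counts must be >= 0")


def default_histology(row: int, col: int) -> str:
    """Planted spatial gradient: UC corner, HGIN ring, NU/LGIN elsewhere."""
    d = max(row, col)
    if d <= 1:
        return "UC"
    if d == 2:
        return "HGIN"
    return "LGIN" if (row + col) % 5 == 0 else "NU"


def make_organ_map(config: SimOrganConfig) -> OrganMap:
    fields = []
    n = 0
    for r in range(config.n_rows):
        for c in range(config.n_cols):
            if n >= config.n_fields:
                break
            n += 1
            fields.append(
                FieldInfo(
                    field_id=f"F{n:02d}", row=r, col=c, histology=default_histology(r, c)
                )
            )
    return OrganMap(fields)


def _motif_to_variant(motif_idx: int) -> tuple[str, str, str]:
    """(ref, alt, context) for a canonical motif (pyrimidine strand)."""
    motif = CANONICAL_MOTIFS[motif_idx]  # e.g. "A[C>T]G"
    five, ref, alt, three = motif[0], motif[2], motif[4], motif[6]
    return ref, alt, five + ref + three


def simulate_whole_organ(
    config: SimOrganConfig = SimOrganConfig(),
    signature_mixture: np.ndarray | None = None,
    signature_matrix: SignatureMatrix | None = None,
    seed: int = 7,
) -> tuple[list[MutationRecord], VafMatrix, OrganMap, SyntheticTruth]:
    """Generate a full synthetic organ with planted alpha/beta/gamma classes."""
    rng = np.random.default_rng(seed)
    organ_map = make_organ_map(config)
    fids = organ_map.field_ids
    if signature_matrix is None:
        signature_matrix = cosmic_like_signature_matrix()
    if signature_mixture is None:
        signature_mixture = default_signature_mixture(signature_matrix.K)
    signature_mixture = np.asarray(signature_mixture, dtype=float)
    if signature_mixture.shape != (signature_matrix.K,) or abs(signature_mixture.sum() - 1) > 1e-8:
        raise ValidationError("signature mixture must be a simplex K-vector")

    specs: list[CloneSpec] = []
    n_total = config.n_alpha + config.n_beta + config.n_gamma
    plan = (
        [("alpha", config.alpha_age, config.alpha_a, None)] * config.n_alpha
        + [("beta", config.beta_age, config.beta_a, config.beta_nu)] * config.n_beta
        + [("gamma", config.gamma_age, config.gamma_a, config.gamma_nu)] * config.n_gamma
    )
    width = len(str(max(n_total, 1)))
    for i, (label, age_rng, a_rng, nu_rng) in enumerate(plan):
        t = rng.uniform(*age_rng)
        a = rng.uniform(*a_rng)
        nu = 0.0 if nu_rng is None else rng.uniform(*nu_rng)
        specs.append(
            CloneSpec(
                mutation_id=f"m{i + 1:0{width}d}",
                rho=a / t,
                nu=nu,
                t=t,
                seed_field=fids[rng.integers(len(fids))],
                class_label=label,
            )
        )

    records: list[MutationRecord] = []
    sig_ids: list[int] = []
    values = np.zeros((n_total, len(fids)))
    mask = np.zeros_like(values, dtype=bool)
    depth_mat = np.zeros_like(values)
    fid_pos = {f: j for j, f in enumerate(fids)}
    for i, spec in enumerate(specs):
        true_vafs, _ = simulate_clone_field_vafs(spec, len(fids), config.cells, rng)
        # position 0 of the clone vector is the seed field; the remaining
        # positions were already randomized, map them onto the other fields
        order = [fid_pos[spec.seed_field]] + [
            j for j in range(len(fids)) if j != fid_pos[spec.seed_field]
        ]
        placed = np.zeros(len(fids))
        placed[order] = true_vafs
        depth = np.maximum(
            np.round(rng.normal(config.coverage_mean, config.coverage_sd, len(fids))),
            config.min_depth,
        )
        reads = rng.binomial(depth.astype(int), np.minimum(placed, 1.0))
        obs = reads / depth
        observed = reads > 0
        values[i] = np.where(observed, obs, 0.0)
        mask[i] = observed
        depth_mat[i] = np.where(observed, depth, 0.0)

        k = int(rng.choice(signature_matrix.K, p=signature_mixture))
        motif = int(rng.choice(96, p=signature_matrix.W[:, k]))
        ref, alt, context = _motif_to_variant(motif)
        sig_ids.append(k)
        records.append(
            MutationRecord(
                mutation_id=spec.mutation_id,
                gene=f"G{i + 1:0{width}d}",
                chrom=str(1 + i % 22),
                pos=1000 * (i + 1) + 1,
                ref=ref,
                alt=alt,
                variant_type="SNV",
                coding_effect="silent" if rng.random() < config.silent_fraction else "non_silent",
                context=context,
            )
        )

    vafs = VafMatrix(values, mask, [s.mutation_id for s in specs], fids, depth=depth_mat)
    truth = SyntheticTruth(
        clone_specs=specs,
        signature_ids=sig_ids,
        config=dataclasses.asdict(config),
        seed=seed,
    )
    return records, vafs, organ_map, truth


def write_dataset(
    records: Sequence[MutationRecord],
    vafs: VafMatrix,
    organ_map: OrganMap,
    truth: SyntheticTruth,
    out_dir,
) -> dict[str, Path]:
    """Write mutations.tsv (long dialect), fields.tsv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mutations": out / "mutations.tsv",
        "fields": out / "fields.tsv",
        "truth": out / "truth.json",
    }
    write_mutation_table(records, vafs, paths["mutations"], dialect="long")
    write_field_annotations(organ_map, paths["fields"])
    paths["truth"].write_text(truth.to_json())
    return paths


# ---------------------------------------------------------------------------
# signature fixtures
# ---------------------------------------------------------------------------


def cosmic_like_signature_matrix(
    K: int = 30, seed: int = 2024, support: int = 6, concentration: float = 0.5
) -> SignatureMatrix:
    """A 96 x K column-stochastic matrix in the COSMIC v2 layout.

    Each signature is a peaked Dirichlet draw over a small random motif
    support (real signatures are similarly sparse); this stands in for the
    downloaded catalog in tests and simulations.
    """
    rng = np.random.default_rng(seed)
    W = np.zeros((96, K))
    for k in range(K):
        idx = rng.choice(96, size=support, replace=False)
        W[idx, k] = rng.dirichlet(np.full(support, concentration))
    return SignatureMatrix(W=W, labels=[f"Signature {k + 1}" for k in range(K)])


def default_signature_mixture(K: int) -> np.ndarray:
    """Sparse mixture concentrated on a few signatures (sums to 1)."""
    h = np.zeros(K)
    h[0] = 0.5
    h[min(5, K - 1)] += 0.3
    h[min(11, K - 1)] += 0.2
    return h / h.sum()


def simulate_catalog(
    mixture: np.ndarray, W: SignatureMatrix, n: int, seed: int = 0
) -> SpectrumCatalog:
    """n motifs drawn from the mixture distribution W @ mixture."""
    mixture = np.asarray(mixture, dtype=float)
    if n < 1:
        raise ValidationError("n must be >= 1")
    if mixture.shape != (W.K,) or abs(mixture.sum() - 1.0) > 1e-8 or (mixture < 0).any():
        raise ValidationError("mixture must be a simplex K-vector")
    rng = np.random.default_rng(seed)
    probs = W.W @ mixture
    counts = rng.multinomial(n, probs / probs.sum())
    return catalog_from_counts96(counts)


# ---------------------------------------------------------------------------
# omics fixtures
# ---------------------------------------------------------------------------


def simulate_omics(
    n_features: int = 500,
    group_sizes: Mapping[str, int] | None = None,
    n_monotone_up: int = 20,
    n_monotone_down: int = 20,
    effect: float = 1.0,
    noise_sd: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[AbundanceMatrix, dict[str, list[str]]]:
    """Abundance matrix with planted monotone trends (log2-scale effects).

    Planted 'up' features gain ``effect`` log2 units per ordered group step
    control -> NU_LGIN -> HGIN -> UC; 'down' features lose it. Noise is
    log-normal; missingness is completely at random.
    """
    if group_sizes is None:
        group_sizes = {"control": 4, "NU_LGIN": 6, "HGIN": 5, "UC": 5}
    order = ["control", "NU_LGIN", "HGIN", "UC"]
    if any(group_sizes.get(g, 0) < 2 for g in order):
        raise ValidationError("each group needs at least two samples")
    if n_monotone_up + n_monotone_down > n_features:
        raise ValidationError("more planted features than features")
    rng = np.random.default_rng(seed)
    groups: list[str] = []
    for g in order:
        groups.extend([g] * group_sizes[g])
    n_samples = len(groups)
    step = np.asarray([order.index(g) for g in groups], dtype=float)

    base = rng.uniform(3.0, 8.0, size=n_features)
    log2_vals = np.tile(base[:, None], (1, n_samples))
    up_idx = np.arange(n_monotone_up)
    down_idx = np.arange(n_monotone_up, n_monotone_up + n_monotone_down)
    log2_vals[up_idx] += effect * step[None, :]
    log2_vals[down_idx] -= effect * step[None, :]
    if noise_sd > 0:
        log2_vals = log2_vals + rng.normal(0.0, noise_sd, size=log2_vals.shape)
    values = np.power(2.0, log2_vals)
    if missing_rate > 0:
        values[rng.random(values.shape) < missing_rate] = np.nan
    feature_ids = [f"feat{i + 1:04d}" for i in range(n_features)]
    matrix = AbundanceMatrix(
        values=values,
        feature_ids=feature_ids,
        sample_ids=[f"s{i + 1:02d}" for i in range(n_samples)],
        groups=groups,
    )
    truth = {
        "up": [feature_ids[i] for i in up_idx],
        "down": [feature_ids[i] for i in down_idx],
    }
    return matrix, truth
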