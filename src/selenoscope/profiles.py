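"""Short-series dose-profile clustering of differentially expressed genes.

Genes are summarized as a short series of per-dose-group log2 ratios to
the baseline group and matched by Pearson correlation against a library
of integer model profiles — every trajectory of length *d* that starts
at 0 and moves by at most *c* units between consecutive doses, with the
constant profile excluded.  When the pool exceeds the profile budget
*m*, a greedy max-min selection under the correlation distance
1 − r keeps a maximally spread library (the budget of 100 used here
exceeds the d = 4, c = 1 pool, so selection is a no-op at the default
design).  A gene is retained in its best-matching profile only when the
correlation is strictly above ``min_r`` (default 0.88).

Profile significance is assessed against a permutation null that
shuffles each gene's series entries beyond the anchored baseline and
re-assigns, with Bonferroni correction across profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from selenoscope.datamodel import ExpressionMatrix, GroupDesign, ValidationError
from selenoscope.preprocess import NormalizedMatrix

__all__ = [
    "Profile",
    "generate_candidate_profiles",
    "select_model_profiles",
    "build_dose_series",
    "assign_genes",
    "profile_significance",
]


@dataclass(frozen=True)
class Profile:
    index: int
    levels: tuple[int, ...]


def generate_candidate_profiles(d: int, c: int = 1) -> list[Profile]:
    """All integer profiles of length d, starting at 0, steps in [−c, c].

    The constant (all-zero-change) profile is excluded; order is the
    lexicographic order of the step sequences, so output is deterministic.
    There are (2c+1)^(d−1) − 1 profiles.
    """
    if d < 2:
        raise ValidationError("profiles need at least 2 dose points")
    if c < 1:
        raise ValidationError("maximum unit change c must be ≥ 1")
    profiles: list[Profile] = []
    for steps in product(range(-c, c + 1), repeat=d - 1):
        levels = tuple(np.concatenate([[0], np.cumsum(steps)]).tolist())
        if all(v == 0 for v in levels):
            continue
        profiles.append(Profile(index=len(profiles), levels=levels))
    return profiles


def _profile_distance(a: tuple[int, ...], b: tuple[int, ...]) -> float:
    ra = np.asarray(a, dtype=float)
    rb = np.asarray(b, dtype=float)
    r = np.corrcoef(ra, rb)[0, 1]
    return 1.0 - float(r)


def select_model_profiles(candidates: list[Profile], m: int = 100) -> list[Profile]:
    """Pick up to m model profiles by greedy max-min correlation distance.

    Seeded from the candidate with the largest summed distance to all
    others; each subsequent pick maximizes its minimum distance to the
    already-selected set.  Ties break toward the lower candidate index.
    """
    if m < 1:
        raise ValidationError("m must be ≥ 1")
    if len(candidates) <= m:
        return list(candidates)
    n = len(candidates)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _profile_distance(candidates[i].levels, candidates[j].levels)
            dist[i, j] = dist[j, i] = d
    seed = int(np.argmax(dist.sum(axis=1)))  # argmax takes first on ties
    chosen = [seed]
    while len(chosen) < m:
        min_d = dist[:, chosen].min(axis=1)
        min_d[chosen] = -np.inf
        chosen.append(int(np.argmax(min_d)))
    return [candidates[i] for i in sorted(chosen)]


def build_dose_series(
    norm_matrix: NormalizedMatrix | ExpressionMatrix,
    design: GroupDesign,
    gene_subset: list[str],
    dose_order: list[str],
) -> pd.DataFrame:
    """Per-gene series of log2 mean ratios to the first (baseline) group.

    Entry for group g is log2((mean_g + 1)/(mean_baseline + 1)); the
    first entry is 0 by construction.  Returns genes × dose-groups.
    """
    data = norm_matrix.data if isinstance(norm_matrix, NormalizedMatrix) else norm_matrix.data
    if len(dose_order) < 2:
        raise ValidationError("dose_order needs at least 2 groups")
    for g in dose_order:
        if g not in design.group_dose:
            raise ValidationError(f"group {g!r} absent from design")
    missing = [g for g in gene_subset if g not in data.index]
    if missing:
        raise ValidationError(f"genes absent from matrix: {missing[:5]}")
    sub = data.loc[gene_subset]
    means = {}
    for g in dose_order:
        samples = [s for s in design.samples_of(g) if s in sub.columns]
        if not samples:
            raise ValidationError(f"group {g!r} has no samples in the matrix")
        means[g] = sub[samples].mean(axis=1)
    base = means[dose_order[0]]
    series = pd.DataFrame(
        {g: np.log2((means[g] + 1.0) / (base + 1.0)) for g in dose_order}
    )
    series.index = sub.index
    return series


def assign_genes(
    series: pd.DataFrame, library: list[Profile], min_r: float = 0.88
) -> pd.DataFrame:
    """Assign each gene series to its best-correlated model profile.

    Returns a DataFrame indexed by gene with columns profile_index,
    pearson_r and retained.  A gene is retained only when its best
    correlation is strictly greater than ``min_r``; zero-variance series
    are unassigned (profile_index −1, r = NaN).
    """
    if not library:
        raise ValidationError("profile library is empty")
    d = len(library[0].levels)
    if series.shape[1] != d:
        raise ValidationError(
            f"series length {series.shape[1]} ≠ profile length {d}"
        )
    levels = np.asarray([p.levels for p in library], dtype=float)
    lv_centered = levels - levels.mean(axis=1, keepdims=True)
    lv_norm = np.linalg.norm(lv_centered, axis=1)

    values = series.to_numpy(dtype=float)
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered @ lv_centered.T) / np.outer(norms, lv_norm)
    best = np.nanargmax(np.where(np.isnan(r), -np.inf, r), axis=1)
    best_r = r[np.arange(len(values)), best]
    degenerate = norms == 0
    result = pd.DataFrame(
        {
            "profile_index": np.where(degenerate, -1, [library[b].index for b in best]),
            "pearson_r": np.where(degenerate, np.nan, best_r),
            "retained": np.where(degenerate, False, best_r > min_r),
        },
        index=series.index,
    )
    result["profile_index"] = result["profile_index"].astype(int)
    result["retained"] = result["retained"].astype(bool)
    return result


def profile_significance(
    assignments: pd.DataFrame,
    series: pd.DataFrame,
    library: list[Profile],
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    min_r: float = 0.88,
) -> pd.DataFrame:
    """Permutation significance of per-profile gene counts.

    The null shuffles each gene's series entries beyond the anchored
    first (baseline) entry and re-assigns; p = (1 + #{null count ≥
    observed}) / (1 + n_perm).  A profile is significant when its p-value
    clears alpha after Bonferroni correction across the library.
    """
    if n_perm < 100:
        raise ValidationError("use at least 100 permutations")
    rng = np.random.default_rng(seed)
    n_profiles = len(library)
    observed = np.zeros(n_profiles, dtype=int)
    retained = assignments[assignments["retained"]]
    index_pos = {p.index: k for k, p in enumerate(library)}
    for pi, cnt in retained["profile_index"].value_counts().items():
        observed[index_pos[int(pi)]] += int(cnt)

    values = series.to_numpy(dtype=float)
    exceed = np.zeros(n_profiles, dtype=int)
    null_total = np.zeros(n_profiles, dtype=float)
    tail = values[:, 1:]
    for _ in range(n_perm):
        perm = np.array([rng.permutation(row) for row in tail])
        shuffled = pd.DataFrame(
            np.column_stack([values[:, 0], perm]),
            index=series.index,
            columns=series.columns,
        )
        null_assign = assign_genes(shuffled, library, min_r=min_r)
        null_counts = np.zeros(n_profiles, dtype=int)
        kept = null_assign[null_assign["retained"]]
        for pi, cnt in kept["profile_index"].value_counts().items():
            null_counts[index_pos[int(pi)]] += int(cnt)
        exceed += null_counts >= observed
        null_total += null_counts
    pvalues = (1.0 + exceed) / (1.0 + n_perm)
    significant = pvalues * n_profiles < alpha  # Bonferroni
    return pd.DataFrame(
        {
            "profile_index": [p.index for p in library],
            "observed_count": observed,
            "expected_count": null_total / n_perm,
            "p_value": pvalues,
            "significant": significant,
        }
    )
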