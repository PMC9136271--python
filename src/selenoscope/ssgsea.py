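"""Single-sample gene-set enrichment (ssGSEA) scoring.

For each sample, genes are ranked by expression (descending; ties broken
by gene identifier so results are deterministic).  The enrichment score
of a set is the summed difference, walked down the ranked list, between
the weighted empirical distribution of in-set genes — weights are the
rank magnitudes raised to ``tau`` — and the unweighted distribution of
out-of-set genes.  Scores therefore depend only on within-sample ranks.

``tau = 0.25`` is the published ssGSEA convention; ``tau = 0`` weights
every in-set gene equally, which makes small examples hand-checkable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from selenoscope.datamodel import (
    ExpressionMatrix,
    GeneSetCollection,
    ValidationError,
)
from selenoscope.preprocess import NormalizedMatrix

__all__ = ["ssgsea_score", "score_sd_filter"]


def ssgsea_score(
    norm_matrix: NormalizedMatrix | ExpressionMatrix,
    gene_sets: GeneSetCollection,
    tau: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Score every gene set in every sample; returns sets × samples.

    Sets are silently intersected with the matrix genes; sets with empty
    intersection, or covering every gene, are dropped with a warning.
    With ``normalize=True`` all scores are divided by the global score
    range (the cross-sample normalization some ssGSEA implementations
    apply); the default leaves raw scores.
    """
    data = norm_matrix.data if isinstance(norm_matrix, NormalizedMatrix) else norm_matrix.data
    gene_index = {g: i for i, g in enumerate(data.index)}
    n_genes = len(gene_index)

    usable: dict[str, np.ndarray] = {}
    for name in gene_sets.set_names:
        members = [g for g in gene_sets[name] if g in gene_index]
        if not members:
            warnings.warn(f"gene set {name!r} has no overlap with the matrix; dropped")
            continue
        if len(members) >= n_genes:
            warnings.warn(f"gene set {name!r} covers every gene; dropped")
            continue
        mask = np.zeros(n_genes, dtype=bool)
        mask[[gene_index[g] for g in members]] = True
        usable[name] = mask
    if not usable:
        raise ValidationError("no usable gene set after intersection")

    # deterministic ranking: descending expression, gene id as tie-break
    gene_order_key = np.argsort(np.asarray(data.index.astype(str)))
    tie_rank = np.empty(n_genes)
    tie_rank[gene_order_key] = np.arange(n_genes)

    scores = pd.DataFrame(
        index=list(usable), columns=list(data.columns), dtype=float
    )
    values = data.to_numpy(dtype=float)
    for j, sample in enumerate(data.columns):
        order = np.lexsort((tie_rank, -values[:, j]))  # descending, stable ties
        rank_magnitude = np.arange(n_genes, 0, -1, dtype=float)  # N..1 down the list
        weights = rank_magnitude**tau
        for name, mask in usable.items():
            in_set = mask[order]
            w_in = np.where(in_set, weights, 0.0)
            p_in = np.cumsum(w_in) / w_in.sum()
            p_out = np.cumsum(~in_set) / (n_genes - mask.sum())
            scores.loc[name, sample] = float(np.sum(p_in - p_out))
    if normalize:
        rng = scores.to_numpy().max() - scores.to_numpy().min()
        if rng > 0:
            scores = scores / rng
    scores.attrs["tau"] = tau
    scores.attrs["normalized"] = normalize
    return scores


def score_sd_filter(
    score_matrix: pd.DataFrame, sd_max: float = 0.1, normalize: bool = True
) -> pd.DataFrame:
    """Retain gene sets whose across-sample score SD is ≤ ``sd_max``.

    Scores are first divided by the global (max − min) range so the SD
    threshold is scale-free; ``normalize=False`` applies the threshold to
    raw scores.  As written this keeps the *low*-variance sets — it is a
    stability filter for display, not a feature selector.
    """
    if score_matrix.shape[1] < 2:
        raise ValidationError("SD filter needs at least 2 samples")
    work = score_matrix
    if normalize:
        rng = score_matrix.to_numpy().max() - score_matrix.to_numpy().min()
        if rng == 0:
            warnings.warn("degenerate score range 0; all sets retained")
            return score_matrix.copy()
        work = score_matrix / rng
    sd = work.std(axis=1, ddof=1)
    return score_matrix.loc[sd <= sd_max]
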