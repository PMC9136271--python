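"""Normalization and the differential-expression screen.

Size factors follow the median-of-ratios convention: each sample's factor
is the median, over genes positive in every sample, of that sample's
count divided by the gene's geometric mean across samples.  The DE screen
is deliberately simple — a two-sided rank-sum test per gene with
Benjamini–Hochberg correction within the contrast and a log2 fold change
of group means (pseudocount 1) — and is recorded as such in its output
metadata; it produces the gene lists that the downstream dose-profile and
enrichment stages consume, it is not a negative-binomial GLM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from selenoscope.datamodel import ExpressionMatrix, GroupDesign, ValidationError
from selenoscope.switch import wilcoxon_rank_sum

__all__ = ["NormalizedMatrix", "median_of_ratios_normalize", "de_screen"]

DE_METHOD_TAG = "rank-sum + BH (median-of-ratios normalized means, pseudocount 1)"


@dataclass
class NormalizedMatrix:
    """An expression matrix divided column-wise by per-sample size factors."""

    matrix: ExpressionMatrix
    size_factors: pd.Series
    method: str = "median-of-ratios"

    @property
    def data(self) -> pd.DataFrame:
        return self.matrix.data

    @property
    def gene_ids(self) -> list[str]:
        return self.matrix.gene_ids

    @property
    def sample_ids(self) -> list[str]:
        return self.matrix.sample_ids


def median_of_ratios_normalize(
    matrix: ExpressionMatrix, pseudocount: float = 0.0
) -> NormalizedMatrix:
    """Median-of-ratios size-factor normalization.

    Parameters
    ----------
    matrix
        Raw counts, genes × samples, at least two samples.
    pseudocount
        Added to every count before computing factors when no gene is
        positive in all samples (otherwise ignored if zero).
    """
    if len(matrix.sample_ids) < 2:
        raise ValidationError("normalization needs at least 2 samples")
    counts = matrix.values + pseudocount
    reference = (counts > 0).all(axis=1)
    if not reference.any():
        raise ValidationError(
            "no gene is positive in every sample; re-run with a pseudocount "
            "(e.g. pseudocount=0.5)"
        )
    ref = counts[reference]
    log_geo_mean = np.log(ref).mean(axis=1, keepdims=True)
    ratios = np.log(ref) - log_geo_mean
    factors = np.exp(np.median(ratios, axis=0))
    size_factors = pd.Series(factors, index=matrix.sample_ids, name="size_factor")
    normalized = ExpressionMatrix(matrix.data / factors)
    return NormalizedMatrix(normalized, size_factors)


def de_screen(
    norm_matrix: NormalizedMatrix | ExpressionMatrix,
    design: GroupDesign,
    baseline: str,
    treatment: str,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene baseline-vs-treatment screen at FDR < 0.05, |log2FC| > 1.

    Returns a DataFrame indexed by gene with columns log2fc, pvalue,
    qvalue and pass.  P-values come from the two-sided rank-sum test;
    q-values are BH-adjusted within this contrast only.
    """
    data = norm_matrix.data if isinstance(norm_matrix, NormalizedMatrix) else norm_matrix.data
    for group in (baseline, treatment):
        if group not in design.group_dose:
            raise ValidationError(f"group {group!r} absent from design")
    base_samples = [s for s in design.samples_of(baseline) if s in data.columns]
    treat_samples = [s for s in design.samples_of(treatment) if s in data.columns]
    if len(base_samples) < 3 or len(treat_samples) < 3:
        raise ValidationError("both groups need at least 3 samples")

    base = data[base_samples].to_numpy()
    treat = data[treat_samples].to_numpy()
    log2fc = np.log2((treat.mean(axis=1) + 1.0) / (base.mean(axis=1) + 1.0))
    pvalues = np.array(
        [wilcoxon_rank_sum(base[i], treat[i])[1] for i in range(base.shape[0])]
    )
    _, qvalues, _, _ = multipletests(pvalues, method="fdr_bh")
    passed = (qvalues < fdr_threshold) & (np.abs(log2fc) > lfc_threshold)
    result = pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvalues, "qvalue": qvalues, "pass": passed},
        index=data.index,
    )
    result.attrs["method"] = DE_METHOD_TAG
    result.attrs["contrast"] = f"{treatment} vs {baseline}"
    return result
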