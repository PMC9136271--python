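"""Thresholded Pearson correlation screens between omic layers.

Each screen tests all cross-layer feature pairs (genes vs OTUs, pathway
scores vs OTUs, OTUs vs phenotypes) with the sample Pearson coefficient
and its asymptotic two-sided p-value from the t transform
t = r·sqrt((n−2)/(1−r²)).  An edge passes when p < p_max and
|r| > r_min, both strict.  Two preset threshold pairs mirror the study:
the general screen (p < 0.05, |r| > 0.6) and a stricter selenoprotein
screen (p < 0.01, r > 0.6).

The pathway↔OTU screen applies flat all-against-all testing with
Benjamini–Hochberg correction (a deliberate, metadata-recorded
simplification of hierarchical all-against-all testing).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from selenoscope.datamodel import OtuTable, PhenotypeTable, ValidationError

__all__ = [
    "pearson_with_p",
    "screen",
    "otu_phenotype_screen",
    "log_relative_abundance",
    "PRESETS",
]

#: named threshold presets: (r_min, p_max)
PRESETS = {
    "general": (0.6, 0.05),
    "selenoprotein": (0.6, 0.01),
}


def log_relative_abundance(
    otu_table: OtuTable, pseudocount: float = 1e-6
) -> pd.DataFrame:
    """log10 of per-sample OTU proportions, the variance-stabilized layer
    for correlation screens (compositional counts are heavy-tailed on the
    linear scale)."""
    return np.log10(otu_table.relative_abundance() + pseudocount)


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pearson r with its asymptotic two-sided p after pairwise deletion.

    Returns (r, p, n) where n counts the complete pairs.  |r| = 1 gives
    p = 0; zero variance in either variable raises a ValidationError.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValidationError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-12:  # exact linear relation up to rounding
        return float(np.sign(r)), 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p), n


def _edges(
    a: pd.DataFrame,
    b: pd.DataFrame,
    layer_a: str,
    layer_b: str,
) -> list[dict]:
    """All-against-all Pearson edges between rows of a and rows of b."""
    records = []
    for fa in a.index:
        xa = a.loc[fa].to_numpy(dtype=float)
        for fb in b.index:
            xb = b.loc[fb].to_numpy(dtype=float)
            try:
                r, p, n = pearson_with_p(xa, xb)
            except ValidationError as err:
                if "zero variance" in str(err):
                    warnings.warn(f"edge {fa!r}~{fb!r} suppressed: {err}")
                    continue
                raise
            records.append(
                {
                    "feature_a": fa,
                    "layer_a": layer_a,
                    "feature_b": fb,
                    "layer_b": layer_b,
                    "n": n,
                    "r": r,
                    "p": p,
                }
            )
    return records


def screen(
    layer_a_matrix: pd.DataFrame,
    layer_b_matrix: pd.DataFrame,
    r_min: float = 0.6,
    p_max: float = 0.05,
    correction: str = "none",
    layer_a: str = "a",
    layer_b: str = "b",
) -> pd.DataFrame:
    """Cross-layer correlation screen (features in rows, samples in columns).

    Both matrices must share their sample columns (same names, any
    order).  Pass requires p < p_max and |r| > r_min, strictly; with
    ``correction='bh'`` the p criterion applies to BH-adjusted q-values.
    Edges are returned sorted by |r| descending.
    """
    if r_min < 0:
        raise ValidationError("r_min must be ≥ 0")
    if not 0 < p_max <= 1:
        raise ValidationError("p_max must lie in (0, 1]")
    shared = [s for s in layer_a_matrix.columns if s in set(layer_b_matrix.columns)]
    if len(shared) < 3:
        raise ValidationError("fewer than 3 shared samples")
    a = layer_a_matrix[shared]
    b = layer_b_matrix[shared]
    records = _edges(a, b, layer_a, layer_b)
    edges = pd.DataFrame.from_records(
        records,
        columns=["feature_a", "layer_a", "feature_b", "layer_b", "n", "r", "p"],
    )
    if len(edges):
        if correction == "bh":
            edges["q"] = multipletests(edges["p"], method="fdr_bh")[1]
            crit_p = edges["q"]
        elif correction == "none":
            edges["q"] = np.nan
            crit_p = edges["p"]
        else:
            raise ValidationError(f"unknown correction {correction!r}")
        edges["pass"] = (crit_p < p_max) & (edges["r"].abs() > r_min)
        edges = edges.sort_values("r", key=lambda s: s.abs(), ascending=False)
        edges = edges.reset_index(drop=True)
    else:
        edges["q"] = pd.Series(dtype=float)
        edges["pass"] = pd.Series(dtype=bool)
    edges.attrs["thresholds"] = {"r_min": r_min, "p_max": p_max, "correction": correction}
    return edges


def otu_phenotype_screen(
    otu_table: OtuTable, phenotypes: PhenotypeTable
) -> pd.DataFrame:
    """Signed correlations between OTU relative abundances and phenotypes.

    No pass threshold is applied — every defined edge is emitted with its
    sign, magnitude and p-value; constant OTUs are suppressed.  Samples
    missing a phenotype are dropped pairwise for that phenotype.
    """
    rel = otu_table.relative_abundance()
    records = []
    for pheno in phenotypes.data.columns:
        y = phenotypes.data[pheno].reindex(rel.columns).to_numpy(dtype=float)
        for otu in rel.index:
            x = rel.loc[otu].to_numpy(dtype=float)
            try:
                r, p, n = pearson_with_p(x, y)
            except ValidationError as err:
                if "zero variance" in str(err):
                    continue
                raise
            records.append(
                {
                    "feature_a": otu,
                    "layer_a": "otu",
                    "feature_b": pheno,
                    "layer_b": "phenotype",
                    "n": n,
                    "r": r,
                    "p": p,
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=["feature_a", "layer_a", "feature_b", "layer_b", "n", "r", "p"],
    )
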