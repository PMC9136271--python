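"""Switched ON/OFF gene detection across dietary groups.

A gene is OFF in a group when its within-group median expression equals
zero and the group standard deviation stays within a tightness bound
(default 1.0 counts); it is ON when the median is positive.  A gene
*switches on* for a treatment when it is OFF in the baseline group and ON
in that treatment, with the difference supported by a two-sided rank-sum
test at P < alpha; switching off is the mirror image.

The rank-sum test is exact (full enumeration over group assignments,
mid-ranks for ties) for pooled sizes up to 14 and falls back to the
normal approximation with tie and continuity corrections above that.

The companion variance filter drops genes whose across-sample variance
exceeds ``factor`` times the quartile deviation (semi-interquartile
range).  Note the two scales differ — variance is squared-units, the
quartile deviation linear — so on count-scale data the rule is extremely
aggressive; it is therefore a standalone stage rather than an implicit
part of :func:`detect_switches`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from selenoscope.datamodel import ExpressionMatrix, GroupDesign, ValidationError

__all__ = [
    "StateCall",
    "quartile_deviation_filter",
    "wilcoxon_rank_sum",
    "call_group_state",
    "detect_switches",
]

EXACT_SIZE_BOUND = 14  # pooled size at or below which the exact null is enumerated

ON = "ON"
OFF = "OFF"
INDETERMINATE = "INDETERMINATE"


@dataclass
class StateCall:
    gene_id: str
    group_label: str
    state: str
    group_median: float
    group_sd: float


def quartile_deviation_filter(
    matrix: ExpressionMatrix,
    factor: float = 1.5,
    design: GroupDesign | None = None,
    per_group: bool = False,
) -> tuple[list[str], list[str]]:
    """Split genes into (retained, filtered) by the variance/QD rule.

    A gene is filtered out iff its sample variance is *strictly* greater
    than ``factor`` × quartile deviation, where the quartile deviation is
    (Q3 − Q1)/2 with linear-interpolation quartiles.  By default both
    statistics run over all samples; with ``per_group=True`` a gene is
    filtered when the rule fires in any group.
    """
    values = matrix.values
    if values.shape[1] < 4:
        raise ValidationError("quartile filter needs at least 4 samples")

    def fires(block: np.ndarray) -> np.ndarray:
        v = block.var(axis=1, ddof=1)
        q1 = np.percentile(block, 25, axis=1)
        q3 = np.percentile(block, 75, axis=1)
        qd = (q3 - q1) / 2.0
        return v > factor * qd

    if per_group:
        if design is None:
            raise ValidationError("per_group filtering needs a design")
        mask = np.zeros(values.shape[0], dtype=bool)
        cols = {s: i for i, s in enumerate(matrix.sample_ids)}
        for group in design.groups:
            idx = [cols[s] for s in design.samples_of(group) if s in cols]
            if len(idx) >= 4:
                mask |= fires(values[:, idx])
    else:
        mask = fires(values)
    genes = np.asarray(matrix.gene_ids)
    return list(genes[~mask]), list(genes[mask])


def _u_statistic(ranks_x: np.ndarray, nx: int) -> float:
    return float(ranks_x.sum() - nx * (nx + 1) / 2.0)


def wilcoxon_rank_sum(
    x: np.ndarray, y: np.ndarray, mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided rank-sum (Mann–Whitney) test with exact small-sample null.

    Returns ``(U, p)``.  U is the larger of the two one-sided
    Mann–Whitney statistics (pairs won by either group, ties counting one
    half), so both U and p are symmetric in the two samples.  The exact
    branch enumerates every assignment of the pooled values into the two
    groups and scores two-sided extremity by |U − n1·n2/2|, which handles
    ties correctly through mid-ranks.  Identical pooled values give p = 1
    (degenerate data).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValidationError("both samples must be non-empty")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    ux = _u_statistic(ranks[:nx], nx)
    u = max(ux, nx * ny - ux)

    if np.ptp(pooled) == 0:
        return u, 1.0

    exact = mode == "exact" or (mode == "auto" and nx + ny <= EXACT_SIZE_BOUND)
    if exact:
        # doubled mid-ranks are integers; extremity of 2U' about its center
        # 2·n1·n2/2 = n1·n2 compares exactly on the doubled scale
        r2 = np.round(2 * ranks).astype(np.int64)
        offset = nx * (nx + 1)  # 2U' = Σ doubled ranks of x-subset − nx(nx+1)
        dev_obs = abs(int(round(2 * u)) * 2 - 2 * nx * ny)
        count = 0
        total = comb(nx + ny, nx)
        for subset in combinations(range(nx + ny), nx):
            u2 = int(r2[list(subset)].sum()) - offset
            if abs(2 * u2 - 2 * nx * ny) >= dev_obs:
                count += 1
        return u, count / total
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return u, float(res.pvalue)


def call_group_state(values: np.ndarray, sd_bound: float = 1.0) -> tuple[str, float, float]:
    """State call for one gene in one group: (state, median, sd)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("state call needs at least 2 values")
    if (values < 0).any():
        raise ValidationError("expression values must be non-negative")
    median = float(np.median(values))
    sd = float(values.std(ddof=1))
    if median > 0:
        return ON, median, sd
    if sd <= sd_bound:
        return OFF, median, sd
    return INDETERMINATE, median, sd


def detect_switches(
    matrix: ExpressionMatrix,
    design: GroupDesign,
    alpha: float = 0.05,
    factor: float | None = None,
    sd_bound: float = 1.0,
    bh_correct: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Find genes that switch ON or OFF between baseline and treatments.

    Parameters
    ----------
    matrix
        Expression matrix (normalized counts recommended).
    design
        Group design naming the baseline group.
    alpha
        Significance level for the rank-sum test (raw p by default).
    factor
        When given, apply :func:`quartile_deviation_filter` with this
        factor before state calling; ``None`` (default) assumes any
        variance filtering happened upstream.
    sd_bound
        Maximum group standard deviation for an OFF call.
    bh_correct
        Apply Benjamini–Hochberg across candidate switch tests before
        thresholding at ``alpha``.

    Returns
    -------
    (switches, states)
        ``switches``: one row per (gene, treatment group) switch event,
        sorted by (direction, gene, group).  ``states``: per gene × group
        state calls with medians and SDs.
    """
    baseline = design.baseline_group
    if len(design.samples_of(baseline)) < 2:
        raise ValidationError("baseline group needs at least 2 samples")

    work = matrix
    if factor is not None:
        retained, _ = quartile_deviation_filter(matrix, factor=factor)
        work = matrix.subset_genes(retained)

    cols = {s: i for i, s in enumerate(work.sample_ids)}
    groups = design.groups
    group_idx = {
        g: [cols[s] for s in design.samples_of(g) if s in cols] for g in groups
    }
    values = work.values
    genes = work.gene_ids

    # vectorized state calls per group
    state_rows = []
    medians: dict[str, np.ndarray] = {}
    states: dict[str, np.ndarray] = {}
    for g in groups:
        block = values[:, group_idx[g]]
        med = np.median(block, axis=1)
        sd = block.std(axis=1, ddof=1)
        st = np.where(med > 0, ON, np.where(sd <= sd_bound, OFF, INDETERMINATE))
        medians[g], states[g] = med, st
        for i, gene in enumerate(genes):
            state_rows.append((gene, g, st[i], med[i], sd[i]))
    states_df = pd.DataFrame(
        state_rows, columns=["gene", "group", "state", "median", "sd"]
    )

    treatments = [g for g in groups if g != baseline]
    records = []
    for t in treatments:
        on_candidates = np.flatnonzero((states[baseline] == OFF) & (states[t] == ON))
        off_candidates = np.flatnonzero((states[baseline] == ON) & (states[t] == OFF))
        for direction, cand in (
            ("switched_on", on_candidates),
            ("switched_off", off_candidates),
        ):
            for i in cand:
                u, p = wilcoxon_rank_sum(
                    values[i, group_idx[baseline]], values[i, group_idx[t]]
                )
                records.append(
                    {
                        "gene": genes[i],
                        "direction": direction,
                        "treatment_group": t,
                        "U": u,
                        "pvalue": p,
                        "baseline_median": medians[baseline][i],
                        "treatment_median": medians[t][i],
                        "baseline_state": OFF if direction == "switched_on" else ON,
                        "treatment_state": ON if direction == "switched_on" else OFF,
                    }
                )
    switches = pd.DataFrame.from_records(
        records,
        columns=[
            "gene",
            "direction",
            "treatment_group",
            "U",
            "pvalue",
            "baseline_median",
            "treatment_median",
            "baseline_state",
            "treatment_state",
        ],
    )
    if len(switches):
        crit = switches["pvalue"].to_numpy()
        if bh_correct:
            from statsmodels.stats.multitest import multipletests

            crit = multipletests(crit, method="fdr_bh")[1]
            switches["qvalue"] = crit
        switches = switches[crit < alpha]
        switches = switches.sort_values(
            ["direction", "gene", "treatment_group"]
        ).reset_index(drop=True)
    return switches, states_df
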