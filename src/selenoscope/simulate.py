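"""Dose-structured synthetic data with planted truth.

Emulates a five-group dietary selenium trial: a Se-deficient basal diet
(SD), selenium yeast at three doses (SY0.15/SY0.30/SY0.45) and sodium
selenite at the highest dose (SS0.45), ten birds per group.  Measured
dietary Se doses and the group means of the laying rate default to the
values reported for the emulated trial; per-bird laying-rate noise uses
the printed SEMs scaled by sqrt(5) (five replicate cages per group).

Expression is negative-binomial with a single dispersion.  Planted
features:

* ``switched_on`` genes — essentially silent (NB mean 0.05, so the group
  median is 0 and the group SD stays ≤ 1) everywhere except one randomly
  chosen SY group where the NB mean is 50;
* ``switched_off`` genes — the mirror image;
* three dose-trend classes over the SY gradient mirroring selenoprotein
  dose-response patterns: monotone decrease under supplementation, a
  peak at the lowest SY dose, and a monotone increase with dose
  (two-fold amplitude each).  The selenite group sits at the basal level
  so the trends live on the yeast gradient only.

OTUs start from a Dirichlet base composition (log-normal concentration);
linked OTUs receive a latent log-abundance equal to ρ times a
standardized driver (a planted gene's log expression or a phenotype)
plus sqrt(1−ρ²) noise, and counts are drawn multinomially at a fixed
depth of 50,000 reads per sample.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from selenoscope.datamodel import (
    ExpressionMatrix,
    GeneSetCollection,
    GroupDesign,
    OtuTable,
    PhenotypeTable,
    ValidationError,
    write_design,
    write_expression_matrix,
    write_gene_sets,
    write_otu_table,
    write_phenotypes,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_expression",
    "simulate_phenotypes",
    "simulate_otus",
    "make_fixture_bundle",
]

#: measured dietary Se dose (mg/kg) per group in the emulated design
DEFAULT_DOSES = {
    "SD": 0.056,
    "SY0.15": 0.211,
    "SY0.30": 0.377,
    "SY0.45": 0.552,
    "SS0.45": 0.480,
}

#: laying rate (%) group means after 12 weeks in the emulated trial
DEFAULT_LAYING_MEANS = {
    "SD": 63.52,
    "SY0.15": 65.97,
    "SY0.30": 71.96,
    "SY0.45": 65.16,
    "SS0.45": 63.47,
}

#: per-bird laying-rate SD: printed SEM × sqrt(5 replicates)
DEFAULT_LAYING_SDS = {
    g: sem * np.sqrt(5.0)
    for g, sem in {
        "SD": 3.14,
        "SY0.15": 1.08,
        "SY0.30": 0.83,
        "SY0.45": 1.55,
        "SS0.45": 1.16,
    }.items()
}

SY_GRADIENT = ["SD", "SY0.15", "SY0.30", "SY0.45"]

# trend multipliers over the SY gradient, two-fold amplitude
PATTERN_SHAPES = {
    "pattern1": {"SD": 2.0, "SY0.15": 1.2, "SY0.30": 1.1, "SY0.45": 1.0, "SS0.45": 2.0},
    "pattern2": {"SD": 1.0, "SY0.15": 2.0, "SY0.30": 1.5, "SY0.45": 1.0, "SS0.45": 1.0},
    "pattern3": {"SD": 1.0, "SY0.15": 1.3, "SY0.30": 1.6, "SY0.45": 2.0, "SS0.45": 1.0},
}


@dataclass
class SimConfig:
    """Parameters of the synthetic study; defaults emulate the trial design."""

    group_doses: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DOSES))
    baseline_group: str = "SD"
    n_per_group: int = 10
    n_genes: int = 2000
    n_otus: int = 200
    nb_dispersion: float = 0.2
    n_switch_on: int = 20
    n_switch_off: int = 20
    n_trend_genes: int = 30  # per pattern class
    n_linked_otus: int = 10
    rho: float = 0.8
    switch_on_mean: float = 50.0
    off_state_mean: float = 0.05
    baseline_log_mean: float = float(np.log(100.0))
    baseline_log_sd: float = 1.0
    sequencing_depth: int = 50_000
    laying_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LAYING_MEANS)
    )
    laying_sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LAYING_SDS))
    se_intercept: float = 0.1
    se_slope: float = 1.5
    se_noise_sd: float = 0.08
    depth_variation: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1 < self.rho < 1:
            raise ValidationError("rho must lie in (−1, 1)")
        if any(d < 0 for d in self.group_doses.values()):
            raise ValidationError("doses must be non-negative")
        planted = self.n_switch_on + self.n_switch_off + 3 * self.n_trend_genes
        if planted > self.n_genes:
            raise ValidationError(
                f"{planted} planted genes exceed n_genes={self.n_genes}"
            )

    @property
    def groups(self) -> list[str]:
        return list(self.group_doses)

    def design(self) -> GroupDesign:
        sample_to_group = {
            f"{g}_{k + 1:02d}": g for g in self.groups for k in range(self.n_per_group)
        }
        return GroupDesign(sample_to_group, dict(self.group_doses), self.baseline_group)


@dataclass
class SimTruth:
    """Planted-feature bookkeeping for recovery experiments."""

    genes: dict[str, dict]  # gene → {role, target_groups, group_means}
    otus: dict[str, dict]  # otu → {driver, driver_layer, rho}
    phenotypes: dict[str, dict]  # phenotype → generation parameters

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        doc = json.loads(text)
        return cls(genes=doc["genes"], otus=doc["otus"], phenotypes=doc["phenotypes"])

    def genes_with_role(self, role: str) -> list[str]:
        return sorted(g for g, info in self.genes.items() if info["role"] == role)


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative binomial with var = mean + dispersion·mean²."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size).astype(np.int64)


def _rng_for(config: SimConfig, stream: str) -> np.random.Generator:
    # crc32 is stable across processes (str hash is not)
    tag = zlib.crc32(stream.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([config.seed % (2**31), tag]))


def simulate_expression(config: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Simulate the genes × samples count matrix with planted truth."""
    rng = _rng_for(config, "expression")
    design = config.design()
    samples = design.sample_ids
    groups = config.groups
    sy_groups = [g for g in groups if g.startswith("SY")]

    n = config.n_genes
    gene_ids = [f"G{i + 1:05d}" for i in range(n)]
    base_means = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    )

    # assign roles to the leading genes, then shuffle identities
    roles: list[tuple[str, str | None]] = []
    for _ in range(config.n_switch_on):
        roles.append(("switched_on", str(rng.choice(sy_groups))))
    for _ in range(config.n_switch_off):
        roles.append(("switched_off", str(rng.choice(sy_groups))))
    for pattern in PATTERN_SHAPES:
        roles.extend((pattern, None) for _ in range(config.n_trend_genes))
    roles.extend(("null", None) for _ in range(n - len(roles)))
    order = rng.permutation(n)
    gene_roles = {gene_ids[order[i]]: roles[i] for i in range(n)}

    truth_genes: dict[str, dict] = {}
    counts = np.zeros((n, len(samples)), dtype=np.int64)
    col_of_group = {
        g: [i for i, s in enumerate(samples) if design.sample_to_group[s] == g]
        for g in groups
    }
    for i, gene in enumerate(gene_ids):
        role, target = gene_roles[gene]
        group_means: dict[str, float] = {}
        for g in groups:
            if role == "null":
                m = base_means[i]
            elif role == "switched_on":
                m = config.switch_on_mean if g == target else config.off_state_mean
            elif role == "switched_off":
                m = config.off_state_mean if g == target else config.switch_on_mean
            else:
                m = base_means[i] * PATTERN_SHAPES[role][g]
            group_means[g] = m
            counts[i, col_of_group[g]] = _nb_draw(
                rng, m, config.nb_dispersion, len(col_of_group[g])
            )
        if role != "null":
            truth_genes[gene] = {
                "role": role,
                "target_groups": [target] if target else SY_GRADIENT[1:],
                "group_means": group_means,
            }

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=samples)
    )
    truth = SimTruth(genes=truth_genes, otus={}, phenotypes={})
    return matrix, truth


def simulate_phenotypes(config: SimConfig) -> tuple[PhenotypeTable, dict]:
    """Laying rate (%) per group mean and ileal Se content linear in dose."""
    rng = _rng_for(config, "phenotypes")
    design = config.design()
    rows = {}
    for s in design.sample_ids:
        g = design.sample_to_group[s]
        laying = rng.normal(config.laying_means[g], config.laying_sds[g])
        laying = float(np.clip(laying, 0.0, 100.0))
        se = rng.normal(
            config.se_intercept + config.se_slope * config.group_doses[g],
            config.se_noise_sd,
        )
        rows[s] = {"laying_rate": laying, "se_content": max(se, 0.0)}
    table = PhenotypeTable(pd.DataFrame.from_dict(rows, orient="index"))
    truth = {
        "laying_rate": {"group_means": dict(config.laying_means)},
        "se_content": {
            "intercept": config.se_intercept,
            "slope": config.se_slope,
            "noise_sd": config.se_noise_sd,
        },
    }
    return table, truth


def simulate_otus(
    config: SimConfig,
    expression: ExpressionMatrix,
    phenotypes: PhenotypeTable,
) -> tuple[OtuTable, dict]:
    """OTU counts with linked features tracking planted genes/phenotypes."""
    rng = _rng_for(config, "otus")
    samples = expression.sample_ids
    if list(phenotypes.sample_ids) != samples:
        raise ValidationError("expression and phenotype samples must align")

    n_otus = config.n_otus
    otu_ids = [f"OTU{i + 1:04d}" for i in range(n_otus)]
    concentration = np.exp(rng.normal(0.0, 1.0, size=n_otus))
    base = rng.dirichlet(concentration, size=len(samples)).T  # otus × samples

    # choose drivers: planted genes with across-sample variation, plus phenotypes
    planted_pool = sorted(
        g
        for g in expression.gene_ids
        if g in _planted_driver_pool(expression, config)
    )
    truth_otus: dict[str, dict] = {}
    log_abundance = np.log(base + 1e-12)
    n_linked = min(config.n_linked_otus, n_otus)
    linked_idx = rng.choice(n_otus, size=n_linked, replace=False)
    pheno_cols = list(phenotypes.data.columns)
    for k, oi in enumerate(linked_idx):
        if k < max(1, n_linked - len(pheno_cols) * 2) and planted_pool:
            driver_name = str(planted_pool[int(rng.integers(len(planted_pool)))])
            driver_layer = "gene"
            driver = np.log2(
                expression.data.loc[driver_name].to_numpy(dtype=float) + 1.0
            )
        else:
            driver_name = pheno_cols[k % len(pheno_cols)]
            driver_layer = "phenotype"
            driver = phenotypes.data[driver_name].to_numpy(dtype=float)
        z = (driver - driver.mean()) / driver.std()
        noise = rng.normal(size=len(samples))
        latent = config.rho * z + np.sqrt(1.0 - config.rho**2) * noise
        log_abundance[oi] = np.log(base[oi].mean() + 1e-12) + latent
        truth_otus[otu_ids[oi]] = {
            "driver": driver_name,
            "driver_layer": driver_layer,
            "rho": config.rho,
        }

    composition = np.exp(log_abundance)
    composition /= composition.sum(axis=0, keepdims=True)
    depth = config.sequencing_depth
    counts = np.zeros((n_otus, len(samples)), dtype=np.int64)
    for j in range(len(samples)):
        d = depth
        if config.depth_variation:
            d = int(depth * np.exp(rng.normal(0.0, 0.3)))
        counts[:, j] = rng.multinomial(d, composition[:, j])
    table = OtuTable(pd.DataFrame(counts, index=otu_ids, columns=samples))
    return table, truth_otus


def _planted_driver_pool(expression: ExpressionMatrix, config: SimConfig) -> set[str]:
    """Genes with enough spread to act as OTU drivers: top-variance planted ids.

    Uses the log-scale variance of the matrix itself so the pool is a
    deterministic function of the data (roles are recovered from the
    matrix rather than passed, keeping the signature spec-shaped).
    """
    logged = np.log2(expression.values + 1.0)
    variances = logged.var(axis=1)
    n_planted = config.n_switch_on + config.n_switch_off + 3 * config.n_trend_genes
    top = np.argsort(variances)[::-1][: max(n_planted, 1)]
    genes = np.asarray(expression.gene_ids)
    return set(genes[top])


def make_fixture_bundle(outdir: str | Path, config: SimConfig) -> dict[str, Path]:
    """Simulate everything and write a runnable file bundle.

    Writes counts.tsv, otus.tsv, design.tsv, phenotypes.tsv, sets.gmt
    and truth.json into ``outdir``; returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = config.design()
    expression, truth = simulate_expression(config)
    phenotypes, pheno_truth = simulate_phenotypes(config)
    otus, otu_truth = simulate_otus(config, expression, phenotypes)
    truth.phenotypes = pheno_truth
    truth.otus = otu_truth

    rng = _rng_for(config, "gene_sets")
    sets: dict[str, list[str]] = {}
    for role in ("switched_on", "switched_off", "pattern1", "pattern2", "pattern3"):
        members = truth.genes_with_role(role)
        if members:
            sets[f"PLANTED_{role.upper()}"] = members
    all_genes = np.asarray(expression.gene_ids)
    for k in range(10):
        members = rng.choice(all_genes, size=30, replace=False)
        sets[f"RANDOM_{k + 1:02d}"] = sorted(members.tolist())
    collection = GeneSetCollection(
        sets, {name: "synthetic gene set" for name in sets}
    )

    paths = {
        "counts": outdir / "counts.tsv",
        "otus": outdir / "otus.tsv",
        "design": outdir / "design.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "gene_sets": outdir / "sets.gmt",
        "truth": outdir / "truth.json",
    }
    write_expression_matrix(expression, paths["counts"])
    write_otu_table(otus, paths["otus"])
    write_design(design, paths["design"])
    write_phenotypes(phenotypes, paths["phenotypes"])
    write_gene_sets(collection, paths["gene_sets"])
    paths["truth"].write_text(truth.to_json() + "\n")
    return paths
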