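"""Synthetic NanoString-like count panels and CTC enumeration tables.

The count generator emulates the structure of a fixed ~770-gene cancer
panel profiled in a small tumor cohort (18 tumor, 4 control samples by
default) with digital counts:

* gene-specific baseline expression drawn log-normally around
  ``baseline_mean``, so the same high-expression genes dominate the top
  ranks of every sample — as on a real panel — rather than top ranks
  being sampling noise;
* negative-binomial counts around each gene's mean (overdispersion
  ``dispersion``), the standard model for digital counting noise;
* a ``low_count_mass`` fraction of genes drawn from a near-zero
  Poisson(0.5) component so the <=2 QC floor removes a nontrivial set of
  data points;
* optional planted genes engineered to satisfy selection criterion A
  (tumor means multiplied up), B (forced into the top 10 of >=1 tumor
  sample and out of every control's top 10) or C (top 20 of >=5 tumor
  samples and of exactly one control), with the planting recorded as
  ground truth for recovery experiments.

The enumeration generator produces zero-inflated, heavy-tailed
two-method count tables spanning the observed 0–4007 range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enumeration import EnumerationTable
from .selection import (
    CountMatrix,
    CriterionParams,
    qc_filter,
    rank_within_sample,
)

PLANTED_CLASSES = ("A", "B", "C", "background")


@dataclass(frozen=True)
class SpikeSpec:
    """How many genes to plant for one criterion and how strongly.

    ``effect_multiplier`` scales tumor-sample means for criterion A
    spikes; B and C spikes are placed by direct rank forcing, for which
    the multiplier only needs to be > 1.
    """

    target_criterion: str
    n_spiked: int
    effect_multiplier: float = 8.0

    def __post_init__(self) -> None:
        if self.target_criterion not in ("A", "B", "C"):
            raise ValueError("target_criterion must be one of A, B, C")
        if self.n_spiked < 1:
            raise ValueError("n_spiked must be >= 1")
        if self.effect_multiplier <= 1.0:
            raise ValueError("effect_multiplier must be > 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one synthetic count panel.

    Defaults match the study layout: a 770-gene panel, 18 tumor and 4
    control samples.  ``gene_mean_sigma`` is the log-scale spread of
    gene baseline means (the panel's dynamic range).
    """

    n_genes: int = 770
    n_tumor: int = 18
    n_control: int = 4
    baseline_mean: float = 50.0
    dispersion: float = 0.1
    gene_mean_sigma: float = 1.5
    low_count_mass: float = 0.15
    spike_specs: Sequence[SpikeSpec] = field(default_factory=tuple)
    seed: int = 0
    assay: str = "plasma"

    def __post_init__(self) -> None:
        if self.n_tumor < 1 or self.n_control < 1:
            raise ValueError("need n_tumor >= 1 and n_control >= 1")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be positive")
        if not 0.0 <= self.low_count_mass <= 1.0:
            raise ValueError("low_count_mass must lie in [0, 1]")
        total_spiked = sum(s.n_spiked for s in self.spike_specs)
        if self.n_genes < total_spiked:
            raise ValueError("n_genes must cover all spiked genes")


@dataclass
class GroundTruth:
    """Planted class per gene: A, B, C or background."""

    classes: pd.Series

    def genes_of(self, planted_class: str) -> list:
        if planted_class not in PLANTED_CLASSES:
            raise ValueError(f"unknown planted class {planted_class!r}")
        return list(self.classes.index[self.classes == planted_class])

    def to_tsv(self, path) -> None:
        self.classes.rename("planted_class").rename_axis("gene_id").to_csv(
            path, sep="\t"
        )

    @classmethod
    def read_tsv(cls, path) -> "GroundTruth":
        frame = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(frame["planted_class"])


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """Negative-binomial draws with mean ``mean`` and var mean + disp*mean^2."""
    r = 1.0 / dispersion
    p = r / (r + np.asarray(mean, dtype=float))
    return rng.negative_binomial(r, p)


def generate_count_matrix(
    config: SimulationConfig,
) -> tuple[CountMatrix, GroundTruth]:
    """Generate one synthetic panel plus its planting ground truth.

    Deterministic given ``(config, config.seed)``.  Planted B and C genes
    are rank-forced and then verified against the default QC floor and
    top-10/top-20 thresholds; a configuration too degenerate to honour
    the placement raises rather than silently mislabelling ground truth.
    """
    rng = np.random.default_rng(config.seed)
    n_genes, n_tumor, n_control = config.n_genes, config.n_tumor, config.n_control
    n_samples = n_tumor + n_control
    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    sample_ids = [f"T{i + 1:02d}" for i in range(n_tumor)] + [
        f"C{i + 1:02d}" for i in range(n_control)
    ]
    groups = pd.Series(
        ["tumor"] * n_tumor + ["control"] * n_control, index=sample_ids
    )

    # assign planted genes, then the low-count component among the rest
    classes = pd.Series("background", index=pd.Index(gene_ids, name="gene_id"))
    order = rng.permutation(n_genes)
    cursor = 0
    spiked = {}
    for spec in config.spike_specs:
        idx = order[cursor : cursor + spec.n_spiked]
        cursor += spec.n_spiked
        spiked.setdefault(spec.target_criterion, [])
        for i in idx:
            classes.iloc[i] = spec.target_criterion
            spiked[spec.target_criterion].append((i, spec))
    background_idx = order[cursor:]
    n_low = int(round(config.low_count_mass * n_genes))
    low_idx = background_idx[:n_low] if n_low else np.array([], dtype=int)

    # gene-specific baseline means; planted genes sit at the panel median
    # so their behaviour is governed by the planting, not by mean luck
    log_noise = rng.standard_normal(n_genes)
    means = config.baseline_mean * np.exp(config.gene_mean_sigma * log_noise)
    for cls_genes in spiked.values():
        for i, _ in cls_genes:
            means[i] = config.baseline_mean

    mu = np.tile(means[:, None], (1, n_samples))
    for i, spec in spiked.get("A", []):
        mu[i, :n_tumor] *= spec.effect_multiplier
    counts = _nb_counts(rng, mu, config.dispersion).astype(np.int64)
    if len(low_idx):
        counts[low_idx, :] = rng.poisson(0.5, size=(len(low_idx), n_samples))

    params = CriterionParams()
    tumor_cols = np.arange(n_tumor)
    control_cols = np.arange(n_tumor, n_samples)

    # criterion B planting: above the current column maximum in one tumor
    # sample (round robin), guaranteed out of every control's top 10
    for j, (i, _) in enumerate(spiked.get("B", [])):
        s = tumor_cols[j % n_tumor]
        counts[i, s] = counts[:, s].max() + 1
    # criterion C planting: above the maximum in five tumor samples and in
    # exactly one control (the <=1-control allowance is exercised, which
    # also keeps C genes out of criterion B by construction)
    for j, (i, _) in enumerate(spiked.get("C", [])):
        for step in range(params.min_tumor_c):
            s = tumor_cols[(j * params.min_tumor_c + step) % n_tumor]
            counts[i, s] = counts[:, s].max() + 1
        c = control_cols[j % n_control]
        counts[i, c] = counts[:, c].max() + 1

    # clamp plantings out of forbidden control top lists
    _clamp_controls(counts, spiked, control_cols, params, n_control)

    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        groups,
        config.assay,
    )
    if spiked:
        _verify_planting(cm, spiked, gene_ids, n_tumor, params)
    return cm, GroundTruth(classes)


def _clamp_controls(counts, spiked, control_cols, params, n_control) -> None:
    for c_pos, c in enumerate(control_cols):
        col = counts[:, c]
        median = int(np.median(col))
        for i, _ in spiked.get("B", []):
            kth = np.sort(col)[-params.top_b]
            if col[i] >= kth:
                counts[i, c] = median
                col = counts[:, c]
        for j, (i, _) in enumerate(spiked.get("C", [])):
            if c_pos == j % n_control:
                continue  # the one allowed control
            kth = np.sort(col)[-params.top_c]
            if col[i] >= kth:
                counts[i, c] = median
                col = counts[:, c]


def _verify_planting(cm, spiked, gene_ids, n_tumor, params) -> None:
    rm = rank_within_sample(qc_filter(cm, params.floor))
    ranks = rm.ranks
    tumor = ranks.columns[:n_tumor]
    control = ranks.columns[n_tumor:]
    for i, _ in spiked.get("B", []):
        g = gene_ids[i]
        ok = (ranks.loc[g, tumor] <= params.top_b).any() and not (
            (ranks.loc[g, control] <= params.top_b).fillna(False).any()
        )
        if not ok:
            raise RuntimeError(f"criterion-B planting failed for {g}")
    for i, _ in spiked.get("C", []):
        g = gene_ids[i]
        n_t = int((ranks.loc[g, tumor] <= params.top_c).sum())
        n_c = int((ranks.loc[g, control] <= params.top_c).fillna(False).sum())
        if n_t < params.min_tumor_c or n_c > params.max_control_c:
            raise RuntimeError(f"criterion-C planting failed for {g}")


#: per-(diagnosis, method) positivity probabilities observed in the study
DEFAULT_POSITIVITY = {
    ("NSCLC", "uni"): 0.4,
    ("NSCLC", "quad"): 0.2,
    ("SCLC", "uni"): 0.6,
    ("SCLC", "quad"): 0.8,
}


@dataclass(frozen=True)
class EnumerationSimConfig:
    """Conditions for a synthetic two-method enumeration table.

    Counts are zero-inflated: zero with probability 1 - positivity_prob,
    otherwise a log-normal magnitude rounded to an integer >= 1.  The
    default log-normal (median e^3 ~ 20, sigma 2) spans the observed
    1–4007 dynamic range.
    """

    n_per_group: int = 10
    positivity_prob: Mapping = field(
        default_factory=lambda: dict(DEFAULT_POSITIVITY)
    )
    magnitude_mu: float = 3.0
    magnitude_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for key, p in self.positivity_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"positivity_prob{key} must lie in [0, 1]")
        if self.magnitude_sigma <= 0:
            raise ValueError("magnitude_sigma must be positive")


def generate_enumeration_table(config: EnumerationSimConfig) -> EnumerationTable:
    """One synthetic patient record per row, both methods' counts drawn
    independently per the zero-inflated magnitude law."""
    rng = np.random.default_rng(config.seed)
    rows = []
    pid = 0
    for diagnosis in ("NSCLC", "SCLC"):
        for _ in range(config.n_per_group):
            pid += 1
            row = {
                "patient_id": f"P{pid:03d}",
                "diagnosis": diagnosis,
                "histology_stage": "synthetic",
            }
            for method, col in (
                ("uni", "unicapture_count"),
                ("quad", "quadcapture_count"),
            ):
                p = config.positivity_prob.get((diagnosis, method), 0.0)
                if rng.random() < p:
                    mag = rng.lognormal(config.magnitude_mu, config.magnitude_sigma)
                    row[col] = max(1, int(round(mag)))
                else:
                    row[col] = 0
            rows.append(row)
    return EnumerationTable(pd.DataFrame(rows))
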