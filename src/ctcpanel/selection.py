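"""Rank-based tumor-specificity selection for NanoString count panels.

Preprocessing mirrors the study workflow for a fixed cancer-gene panel
profiled in tumor and control samples: extreme low counts (<= a floor of
2 by default) are removed as below the platform detection threshold, and
the surviving counts are ranked within each sample.  Ranking makes every
downstream comparison invariant to monotone per-sample normalisation, so
batch effects and vendor normalisation drop out by construction.

Three tumor-specificity criteria are then applied per assay (plasma
cell-free RNA, or CTC-derived mRNA):

* **A** — consistently higher expression in tumors: the gene's per-sample
  quantile score exceeds its own cross-sample mean in at least 75% of
  tumor samples while falling below it in at least 75% of controls;
* **B** — first-tier rare cancer-specific events: ranked in the top 10 of
  at least one tumor sample and of no control;
* **C** — second-tier events: ranked in the top 20 of at least five tumor
  samples and of at most one control.

Genes satisfying at least two (assay, criterion) pairs overall are
reported as selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GROUPS = ("tumor", "control")
ASSAYS = ("plasma", "ctc")
CRITERIA = ("A", "B", "C")


@dataclass(frozen=True)
class CriterionParams:
    """Tunable thresholds of the preprocessing and selection rules.

    Defaults are the study's printed values: QC floor of 2 counts, 75%
    tumor/control consistency for criterion A, top-10 for B, top-20 in
    >=5 tumors / <=1 control for C, and inclusion at >=2 combined hits.
    """

    floor: int = 2
    tumor_frac_a: float = 0.75
    control_frac_a: float = 0.75
    top_b: int = 10
    top_c: int = 20
    min_tumor_c: int = 5
    max_control_c: int = 1
    min_hits_combined: int = 2

    def __post_init__(self) -> None:
        if self.floor < 0:
            raise ValueError("floor must be >= 0")
        for name in ("tumor_frac_a", "control_frac_a"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        for name in ("top_b", "top_c", "min_tumor_c", "min_hits_combined"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.max_control_c < 0:
            raise ValueError("max_control_c must be >= 0")


def _validate_labels(values: pd.DataFrame, labels: pd.Series, allowed, what):
    labels = labels.astype(str)
    missing = [s for s in values.columns if s not in labels.index]
    if missing:
        raise ValueError(f"samples without a {what} label: {missing}")
    labels = labels.loc[values.columns]
    bad = set(labels) - set(allowed)
    if bad:
        raise ValueError(f"{what} labels must be in {allowed}; got {sorted(bad)}")
    return labels


class _LabeledMatrix:
    """Genes x samples values plus per-sample group and assay labels."""

    _value_attr = "values_frame"

    def __init__(self, values: pd.DataFrame, groups, assays="plasma"):
        values = pd.DataFrame(values).copy()
        if values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        values.index = values.index.astype(str)
        values.columns = values.columns.astype(str)
        if isinstance(assays, str):
            assays = pd.Series(assays, index=values.columns)
        self.values_frame = values
        self.groups = _validate_labels(values, pd.Series(groups), GROUPS, "group")
        self.assays = _validate_labels(values, pd.Series(assays), ASSAYS, "assay")

    @property
    def gene_ids(self) -> list:
        return list(self.values_frame.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values_frame.columns)

    @property
    def n_genes(self) -> int:
        return len(self.values_frame.index)

    @property
    def n_samples(self) -> int:
        return len(self.values_frame.columns)

    def samples_of(self, assay: str, group: str | None = None) -> list:
        if assay not in ASSAYS:
            raise ValueError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
        sel = self.assays == assay
        if not sel.any():
            raise ValueError(f"no samples with assay {assay!r}")
        if group is not None:
            sel &= self.groups == group
        return list(self.values_frame.columns[sel.to_numpy()])


class CountMatrix(_LabeledMatrix):
    """Nonnegative integer counts, genes x samples, with group/assay labels."""

    def __init__(self, counts: pd.DataFrame, groups, assays="plasma"):
        arr = np.asarray(counts, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("counts must be finite")
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            raise ValueError("counts must be nonnegative integers")
        counts = pd.DataFrame(counts).astype(np.int64)
        super().__init__(counts, groups, assays)

    @property
    def counts(self) -> pd.DataFrame:
        return self.values_frame

    @classmethod
    def read_tsv(cls, counts_path, labels_path) -> "CountMatrix":
        """Load from a counts TSV (first column gene_id) plus a sidecar
        label TSV with columns sample_id, group, assay."""
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        labels = pd.read_csv(labels_path, sep="\t", dtype=str).set_index("sample_id")
        return cls(counts, labels["group"], labels["assay"])

    def to_tsv(self, counts_path, labels_path) -> None:
        self.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
        pd.DataFrame(
            {"group": self.groups, "assay": self.assays}
        ).rename_axis("sample_id").to_csv(labels_path, sep="\t")

    def subset_assay(self, assay: str) -> "CountMatrix":
        cols = self.samples_of(assay)
        return CountMatrix(
            self.counts[cols], self.groups.loc[cols], self.assays.loc[cols]
        )


class MaskedCounts(_LabeledMatrix):
    """Counts after the QC floor; removed entries are NaN (MISSING)."""

    def __init__(self, values: pd.DataFrame, groups, assays="plasma", floor: int = 2):
        super().__init__(values.astype(float), groups, assays)
        self.floor = floor

    @property
    def n_removed(self) -> int:
        return int(self.values_frame.isna().to_numpy().sum())


class RankMatrix(_LabeledMatrix):
    """Per-sample descending fractional ranks (1 = highest count).

    QC-removed entries stay NaN; ``retained_per_sample`` gives G_s, the
    number of ranked genes in each sample.
    """

    @property
    def ranks(self) -> pd.DataFrame:
        return self.values_frame

    @property
    def retained_per_sample(self) -> pd.Series:
        return self.ranks.notna().sum(axis=0)


class QuantileMatrix(_LabeledMatrix):
    """Per-sample quantile scores in [0, 1]; 1 = most expressed.

    Rank r among G retained genes maps to (G - r) / (G - 1) (a lone
    retained gene scores 1); MISSING entries score 0, mirroring the
    below-detection-threshold-set-to-zero convention.
    """

    @property
    def scores(self) -> pd.DataFrame:
        return self.values_frame


def qc_filter(cm: CountMatrix, floor: int = 2) -> MaskedCounts:
    """Mask extreme low counts (<= ``floor``) as MISSING.

    Dimensions are unchanged; only individual (gene, sample) cells are
    removed, exactly as the platform QC discards data points rather than
    whole genes.
    """
    if floor < 0:
        raise ValueError("floor must be >= 0")
    vals = cm.counts.astype(float).mask(cm.counts <= floor)
    return MaskedCounts(vals, cm.groups, cm.assays, floor=floor)


def rank_within_sample(masked: MaskedCounts) -> RankMatrix:
    """Rank retained counts within each sample, highest count = rank 1.

    Ties receive the mean of the tied positions.  A sample with every
    gene removed cannot be ranked and raises a ValueError naming it.
    """
    vals = masked.values_frame
    empty = vals.columns[vals.isna().all(axis=0)]
    if len(empty):
        raise ValueError(
            f"sample(s) with no retained genes after QC: {list(empty)}"
        )
    ranks = vals.rank(axis=0, ascending=False, method="average", na_option="keep")
    return RankMatrix(ranks, masked.groups, masked.assays)


def quantile_scores(rm: RankMatrix) -> QuantileMatrix:
    """Map ranks to [0, 1] quantile scores comparable across samples.

    Samples retain different numbers of genes after QC, so raw ranks are
    not comparable; the score (G_s - rank) / (G_s - 1) is.  MISSING
    entries map to 0.
    """
    g = rm.retained_per_sample.astype(float)
    denom = (g - 1.0).replace(0.0, np.nan)
    scores = rm.ranks.rsub(g, axis=1).div(denom, axis=1)
    # a sample with a single retained gene scores it 1 by convention
    single = g == 1.0
    if single.any():
        scores.loc[:, single[single].index] = rm.ranks.loc[
            :, single[single].index
        ].notna() * 1.0
    scores = scores.fillna(0.0)
    return QuantileMatrix(scores, rm.groups, rm.assays)


def _frac_threshold(frac: float, n: int) -> int:
    # ceil with protection against float fuzz (0.75*18 must give 14, not 15)
    return int(math.ceil(round(frac * n, 9)))


def criterion_a(q: QuantileMatrix, params: CriterionParams, assay: str) -> set:
    """Consistently tumor-elevated genes (criterion A).

    For each gene, m(g) is the mean of its quantile scores over all
    samples of the assay (tumor and control pooled; MISSING as 0).  The
    gene is selected when its score strictly exceeds m(g) in at least
    ceil(tumor_frac_a * n_tumor) tumor samples and falls strictly below
    m(g) in at least ceil(control_frac_a * n_control) controls.
    """
    tumor = q.samples_of(assay, "tumor")
    control = q.samples_of(assay, "control")
    if not tumor or not control:
        raise ValueError(f"assay {assay!r} needs >=1 tumor and >=1 control sample")
    cols = q.samples_of(assay)
    scores = q.scores[cols]
    m = scores.mean(axis=1)
    n_above = scores[tumor].gt(m, axis=0).sum(axis=1)
    n_below = scores[control].lt(m, axis=0).sum(axis=1)
    need_t = _frac_threshold(params.tumor_frac_a, len(tumor))
    need_c = _frac_threshold(params.control_frac_a, len(control))
    hit = (n_above >= need_t) & (n_below >= need_c)
    return set(scores.index[hit])


def _topk(rm: RankMatrix, cols: list, k: int) -> pd.DataFrame:
    # NaN (MISSING) never counts as top-k; fractional ranks compare <= k
    return rm.ranks[cols].le(k).fillna(False)


def criterion_b(rm: RankMatrix, params: CriterionParams, assay: str) -> set:
    """First-tier rare cancer-specific events (criterion B).

    Top-``top_b`` rank in at least one tumor sample and in no control.
    """
    tumor = rm.samples_of(assay, "tumor")
    control = rm.samples_of(assay, "control")
    if not tumor or not control:
        raise ValueError(f"assay {assay!r} needs >=1 tumor and >=1 control sample")
    in_tumor = _topk(rm, tumor, params.top_b).any(axis=1)
    in_control = _topk(rm, control, params.top_b).any(axis=1)
    return set(rm.ranks.index[in_tumor & ~in_control])


def criterion_c(rm: RankMatrix, params: CriterionParams, assay: str) -> set:
    """Second-tier rare cancer-specific events (criterion C).

    Top-``top_c`` rank in at least ``min_tumor_c`` tumor samples and in
    at most ``max_control_c`` controls (both boundaries inclusive).
    """
    tumor = rm.samples_of(assay, "tumor")
    control = rm.samples_of(assay, "control")
    if not tumor or not control:
        raise ValueError(f"assay {assay!r} needs >=1 tumor and >=1 control sample")
    n_tumor = _topk(rm, tumor, params.top_c).sum(axis=1)
    n_control = _topk(rm, control, params.top_c).sum(axis=1)
    hit = (n_tumor >= params.min_tumor_c) & (n_control <= params.max_control_c)
    return set(rm.ranks.index[hit])


def evaluate_criteria(
    cm: CountMatrix, params: CriterionParams | None = None, assay: str | None = None
) -> dict:
    """Run QC, ranking and all three criteria on one assay's counts.

    Returns ``{gene_id: subset of {"A", "B", "C"}}`` over every gene in
    the matrix (empty set where nothing fires).
    """
    params = params or CriterionParams()
    if assay is None:
        assays = sorted(set(cm.assays))
        if len(assays) != 1:
            raise ValueError("matrix holds several assays; pass assay explicitly")
        assay = assays[0]
    masked = qc_filter(cm, params.floor)
    rm = rank_within_sample(masked)
    q = quantile_scores(rm)
    hits = {g: set() for g in cm.gene_ids}
    for name, sel in (
        ("A", criterion_a(q, params, assay)),
        ("B", criterion_b(rm, params, assay)),
        ("C", criterion_c(rm, params, assay)),
    ):
        for g in sel:
            hits[g].add(name)
    return hits


class SelectionReport:
    """Per-gene criterion flags per assay and the combined verdict.

    Wraps a frame with columns ``gene_id, plasma_flags, ctc_flags,
    total_hits, included``, sorted by total_hits descending then gene id.
    """

    COLUMNS = ("gene_id", "plasma_flags", "ctc_flags", "total_hits", "included")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing report columns: {missing}")
        self.frame = frame.reset_index(drop=True)

    @property
    def included_genes(self) -> list:
        return list(self.frame.loc[self.frame["included"], "gene_id"])

    def flags(self, gene_id: str) -> dict:
        row = self.frame[self.frame["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(f"no gene {gene_id!r} in report")
        row = row.iloc[0]
        return {
            "plasma": set(row["plasma_flags"].split(",")) - {""},
            "ctc": set(row["ctc_flags"].split(",")) - {""},
            "total_hits": int(row["total_hits"]),
            "included": bool(row["included"]),
        }

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "SelectionReport":
        frame = pd.read_csv(path, sep="\t", keep_default_na=False)
        frame["included"] = frame["included"].astype(bool)
        return cls(frame)


def _flag_string(flags: Iterable[str]) -> str:
    return ",".join(c for c in CRITERIA if c in set(flags))


def combine_criteria(
    flags_plasma: Mapping[str, Iterable],
    flags_ctc: Mapping[str, Iterable],
    params: CriterionParams | None = None,
) -> SelectionReport:
    """Combine per-assay criterion flags into the >=2-hits verdict.

    ``total_hits`` counts distinct (assay, criterion) pairs; a gene is
    included when that count reaches ``min_hits_combined``.
    """
    params = params or CriterionParams()
    if set(flags_plasma) != set(flags_ctc):
        raise ValueError("plasma and CTC flag maps cover different gene universes")
    rows = []
    for gene in flags_plasma:
        fp = set(flags_plasma[gene]) & set(CRITERIA)
        fc = set(flags_ctc[gene]) & set(CRITERIA)
        total = len(fp) + len(fc)
        rows.append(
            {
                "gene_id": str(gene),
                "plasma_flags": _flag_string(fp),
                "ctc_flags": _flag_string(fc),
                "total_hits": total,
                "included": total >= params.min_hits_combined,
            }
        )
    frame = pd.DataFrame(rows).sort_values(
        ["total_hits", "gene_id"], ascending=[False, True]
    )
    return SelectionReport(frame)


def select_genes(
    plasma: CountMatrix, ctc: CountMatrix, params: CriterionParams | None = None
) -> SelectionReport:
    """Full pipeline: criteria on each assay's matrix, then combination."""
    params = params or CriterionParams()
    return combine_criteria(
        evaluate_criteria(plasma, params, "plasma"),
        evaluate_criteria(ctc, params, "ctc"),
        params,
    )
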