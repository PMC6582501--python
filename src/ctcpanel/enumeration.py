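"""Two-method circulating tumor cell (CTC) enumeration analytics.

A blood draw is processed by two capture assays — ``uni`` (EpCAM-only
immunomagnetic capture, the standard CellSearch assay) and ``quad`` (an
EpCAM/HER2/EGFR/MUC-1 ferrofluid cocktail) — and the number of CTCs
identified by each is recorded per patient.  This module computes the
derived analytics: positivity calls at a count cutoff, per-method and
per-histology detection rates, either-method detection, inter-method
concordance, and a paired nonparametric comparison of the two methods'
counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

METHODS = ("uni", "quad")
DIAGNOSES = ("NSCLC", "SCLC")

#: column holding each method's count in the table dialect
COUNT_COLUMNS = {"uni": "unicapture_count", "quad": "quadcapture_count"}

REQUIRED_COLUMNS = (
    "patient_id",
    "diagnosis",
    "unicapture_count",
    "quadcapture_count",
)


@dataclass(frozen=True)
class RateResult:
    """A proportion reported as positives / total.

    ``fraction`` is exactly ``positives / total``; ``total`` is always the
    size of the stratum the rate was computed over, so 4/10 prints as the
    familiar "4 of 10 patients (40%)".
    """

    positives: int
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("RateResult requires total > 0")
        if not 0 <= self.positives <= self.total:
            raise ValueError("positives must lie in [0, total]")

    @property
    def fraction(self) -> float:
        return self.positives / self.total

    def to_dict(self) -> dict:
        return {
            "positives": self.positives,
            "total": self.total,
            "fraction": self.fraction,
        }

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.positives}/{self.total} ({100 * self.fraction:.0f}%)"


@dataclass(frozen=True)
class PairedTestResult:
    """Outcome of the paired two-method count comparison.

    ``degenerate`` is set when no informative (nonzero-difference) pairs
    exist; the p-value is then reported as 1.0 by convention.
    """

    p_value: float
    n_informative: int
    statistic: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "p_value": self.p_value,
            "informative_pairs": self.n_informative,
            "statistic": self.statistic,
            "degenerate": self.degenerate,
        }


class EnumerationTable:
    """Per-patient two-method CTC counts with diagnosis labels.

    Thin validated wrapper around a :class:`pandas.DataFrame` with columns
    ``patient_id, diagnosis, histology_stage, unicapture_count,
    quadcapture_count``.  Counts must be nonnegative integers and the
    diagnosis one of ``NSCLC``/``SCLC``.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        if "histology_stage" not in frame.columns:
            frame["histology_stage"] = ""
        frame["patient_id"] = frame["patient_id"].astype(str)
        if frame["patient_id"].duplicated().any():
            dupes = frame.loc[frame["patient_id"].duplicated(), "patient_id"]
            raise ValueError(f"duplicate patient ids: {sorted(set(dupes))}")
        bad_dx = set(frame["diagnosis"]) - set(DIAGNOSES)
        if bad_dx:
            raise ValueError(
                f"diagnosis labels must be in {DIAGNOSES}; got {sorted(bad_dx)}"
            )
        for col in COUNT_COLUMNS.values():
            vals = frame[col]
            arr = np.asarray(vals, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{col} contains non-finite values")
            if np.any(arr < 0) or np.any(arr != np.floor(arr)):
                raise ValueError(f"{col} must hold nonnegative integers")
            frame[col] = arr.astype(np.int64)
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_by_dx = self.frame["diagnosis"].value_counts().to_dict()
        return f"EnumerationTable({len(self)} patients, {n_by_dx})"

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "EnumerationTable":
        return cls(pd.DataFrame(list(records)))

    @classmethod
    def read_tsv(cls, path) -> "EnumerationTable":
        frame = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
        return cls(frame)

    def to_tsv(self, path) -> None:
        cols = ["patient_id", "diagnosis", "histology_stage"]
        cols += list(COUNT_COLUMNS.values())
        self.frame[cols].to_csv(path, sep="\t", index=False)

    def record(self, patient_id: str) -> pd.Series:
        """Return the single record for ``patient_id``."""
        hit = self.frame[self.frame["patient_id"] == str(patient_id)]
        if hit.empty:
            raise KeyError(f"no record for patient {patient_id!r}")
        return hit.iloc[0]

    def subset(self, diagnosis: str) -> pd.DataFrame:
        _check_diagnosis(diagnosis)
        sub = self.frame[self.frame["diagnosis"] == diagnosis]
        if sub.empty:
            raise ValueError(f"no records with diagnosis {diagnosis!r}")
        return sub


def _check_method(method: str) -> str:
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return COUNT_COLUMNS[method]


def _check_diagnosis(diagnosis: str) -> None:
    if diagnosis not in DIAGNOSES:
        raise ValueError(
            f"unknown diagnosis {diagnosis!r}; expected one of {DIAGNOSES}"
        )


def _check_cutoff(cutoff: int) -> None:
    if cutoff < 1 or int(cutoff) != cutoff:
        raise ValueError("cutoff must be a positive integer")


def positivity(record: Mapping, method: str, cutoff: int = 1) -> bool:
    """Positivity call: the chosen method's count is >= ``cutoff``."""
    col = _check_method(method)
    _check_cutoff(cutoff)
    return int(record[col]) >= cutoff


def detection_rate(
    table: EnumerationTable, method: str, cutoff: int, diagnosis: str
) -> RateResult:
    """Fraction of ``diagnosis`` patients positive by ``method`` at ``cutoff``."""
    col = _check_method(method)
    _check_cutoff(cutoff)
    sub = table.subset(diagnosis)
    positives = int((sub[col] >= cutoff).sum())
    return RateResult(positives=positives, total=len(sub))


def either_method_rate(
    table: EnumerationTable, cutoff: int, diagnosis: str
) -> RateResult:
    """Fraction of ``diagnosis`` patients positive by at least one method."""
    _check_cutoff(cutoff)
    sub = table.subset(diagnosis)
    pos = (sub[COUNT_COLUMNS["uni"]] >= cutoff) | (
        sub[COUNT_COLUMNS["quad"]] >= cutoff
    )
    return RateResult(positives=int(pos.sum()), total=len(sub))


def concordance_rate(table: EnumerationTable, cutoff: int) -> RateResult:
    """Fraction of all patients for whom the two methods' calls agree.

    Agreement means both positive or both negative at ``cutoff``; both
    diagnoses are pooled.
    """
    _check_cutoff(cutoff)
    if len(table) == 0:
        raise ValueError("empty enumeration table")
    frame = table.frame
    uni_pos = frame[COUNT_COLUMNS["uni"]] >= cutoff
    quad_pos = frame[COUNT_COLUMNS["quad"]] >= cutoff
    agree = uni_pos == quad_pos
    return RateResult(positives=int(agree.sum()), total=len(frame))


def _signed_rank_pmf(ranks: np.ndarray) -> np.ndarray:
    """Exact null pmf of the positive-rank sum W+ for given |difference| ranks.

    Ranks are fractional (mean-tie) so they are multiples of 1/2; the
    distribution is built over doubled-rank integer units by dynamic
    programming over the 2^n equiprobable sign assignments.  Index ``w``
    of the returned array is the probability that 2*W+ equals ``w``.
    """
    weights = np.rint(2 * np.asarray(ranks, dtype=float)).astype(int)
    total = int(weights.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for w in weights:
        nxt = pmf.copy()
        nxt[w:] += pmf[: total + 1 - w]
        pmf = nxt / 2.0
    return pmf


def exact_signed_rank_p(differences: np.ndarray) -> tuple[float, float]:
    """Two-sided exact Wilcoxon signed-rank p-value for nonzero differences.

    Returns ``(statistic, p)`` where the statistic is ``min(W+, W-)``.
    The p-value is ``min(1, 2*min(P(W+ <= w), P(W+ >= w)))`` under the
    exact null distribution (all sign assignments equiprobable), with
    mean ranks for tied absolute differences.
    """
    d = np.asarray(differences, dtype=float)
    if np.any(d == 0):
        raise ValueError("differences must be nonzero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks.sum() - w_plus)
    pmf = _signed_rank_pmf(ranks)
    w2 = int(round(2 * w_plus))
    lower = float(pmf[: w2 + 1].sum())
    upper = float(pmf[w2:].sum())
    p = min(1.0, 2.0 * min(lower, upper))
    return min(w_plus, w_minus), p


def paired_count_test(
    table: EnumerationTable, diagnosis: str, exact_limit: int = 25
) -> PairedTestResult:
    """Wilcoxon signed-rank comparison of the two methods' paired counts.

    Zero-difference pairs are dropped (Wilcoxon's original treatment).
    With at most ``exact_limit`` informative pairs the exact null
    distribution is used; beyond that, the normal approximation.  If no
    informative pairs remain the comparison is degenerate: p is reported
    as 1.0 with a warning and the ``degenerate`` flag set.
    """
    sub = table.subset(diagnosis)
    if len(sub) < 2:
        raise ValueError("paired test needs at least 2 records in the stratum")
    d = (
        sub[COUNT_COLUMNS["uni"]].to_numpy()
        - sub[COUNT_COLUMNS["quad"]].to_numpy()
    ).astype(float)
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn(
            "no informative pairs (all differences zero); p-value degenerate",
            stacklevel=2,
        )
        return PairedTestResult(1.0, 0, 0.0, degenerate=True)
    if nz.size <= exact_limit:
        statistic, p = exact_signed_rank_p(nz)
    else:  # pragma: no cover - large-sample path exercised via direct call
        res = stats.wilcoxon(
            nz, zero_method="wilcox", alternative="two-sided", method="approx"
        )
        statistic, p = float(res.statistic), float(res.pvalue)
    return PairedTestResult(float(p), int(nz.size), float(statistic))
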