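"""Monosaccharide composition bookkeeping and outlier flagging.

Compositions are mol% tables (one row per sample, one column per sugar)
of the TFA-hydrolysable matrix-polysaccharide fraction.  Replicate
wild-type reference leaves define, per sugar, a null level of relative
variability; the screen flags a sample when its relative percent
difference from the batch baseline exceeds a k*sigma threshold (k = 4 by
default, roughly a 99.99% band under normality) for at least one of the
four major sugars.

Convention: the reference variability "mu +/- sigma" is the mean and
unbiased standard deviation of the *absolute* relative percent deviations
of reference leaves from their batch reference mean.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SUGARS",
    "MAJOR_SUGARS",
    "ReferenceVariability",
    "ThresholdSet",
    "OutlierReport",
    "DEFAULT_REFERENCE_VARIABILITY",
    "DEFAULT_THRESHOLDS",
    "validate_composition",
    "load_composition",
    "reference_variability",
    "thresholds_from_sigma",
    "percent_differences",
    "flag_sugar_outliers",
    "validation_rate",
    "combine_outlier_sets",
]

log = logging.getLogger(__name__)

SUGARS = ("Fuc", "Rha", "Ara", "Gal", "Glc", "Xyl", "GlcA", "GalA")
MAJOR_SUGARS = ("Ara", "Gal", "Glc", "Xyl")


@dataclass
class ReferenceVariability:
    """Per-sugar mean/sd of absolute relative percent deviations among references."""

    mu: dict[str, float]
    sigma: dict[str, float]
    n_references: int = 0

    def __post_init__(self) -> None:
        for s, v in self.sigma.items():
            if v < 0:
                raise ValueError(f"negative sigma for {s}")


@dataclass
class ThresholdSet:
    """Per-sugar relative-percent flagging thresholds."""

    thresholds: dict[str, float]
    k_sigma: float = 4.0

    def __getitem__(self, sugar: str) -> float:
        return self.thresholds[sugar]


#: relative-percent variability of the major cell-wall sugars measured
#: across replicate wild-type reference leaves of a rice screening
#: population (mean +/- sd of absolute relative deviations).
DEFAULT_REFERENCE_VARIABILITY = ReferenceVariability(
    mu={"Ara": 3.3, "Gal": 12.5, "Glc": 14.2, "Xyl": 4.8},
    sigma={"Ara": 2.3, "Gal": 8.5, "Glc": 9.2, "Xyl": 3.0},
)

#: 4-sigma flagging thresholds derived from the unrounded reference sigmas
DEFAULT_THRESHOLDS = ThresholdSet(
    thresholds={"Ara": 9.1, "Gal": 34.0, "Glc": 36.6, "Xyl": 12.1}, k_sigma=4.0
)


def validate_composition(table: pd.DataFrame, require_sum: bool = True) -> pd.DataFrame:
    """Validate a mol% composition table (index = sample id, columns = sugars)."""
    present = [s for s in SUGARS if s in table.columns]
    if not present:
        raise ValueError(f"no sugar columns found; expected among {SUGARS}")
    vals = table[present].to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("negative mol% in composition table")
    if require_sum and len(present) == len(SUGARS):
        sums = vals.sum(axis=1)
        bad = (sums <= 95) | (sums >= 105)
        if bad.any():
            ids = table.index[bad].tolist()
            raise ValueError(f"per-sample mol% sums outside (95, 105) for {ids}")
    return table[present]


def load_composition(path: str | Path) -> pd.DataFrame:
    """Read a composition CSV ("sample_id,Fuc,Rha,Ara,Gal,Glc,Xyl,GlcA,GalA")."""
    df = pd.read_csv(path, dtype={"sample_id": str}).set_index("sample_id")
    return validate_composition(df)


def reference_variability(
    table: pd.DataFrame,
    ref_ids: Iterable[str],
    grouping: Mapping[str, str] | None = None,
    sugars: Iterable[str] = MAJOR_SUGARS,
) -> ReferenceVariability:
    """Reference variability from replicate reference compositions.

    Each reference's relative percent deviation is taken from its batch's
    reference mean; mu and sigma are the mean and unbiased sd of the
    absolute deviations pooled across batches.  Batches with fewer than 2
    references contribute nothing (logged).
    """
    ref_ids = [r for r in ref_ids]
    if len(ref_ids) < 2:
        raise ValueError("at least 2 reference samples required")
    missing = [r for r in ref_ids if r not in table.index]
    if missing:
        raise ValueError(f"reference ids missing from composition table: {missing}")
    grouping = grouping or {r: "default" for r in ref_ids}
    by_batch: dict[str, list[str]] = {}
    for r in ref_ids:
        by_batch.setdefault(grouping.get(r, "default"), []).append(r)

    sugars = list(sugars)
    devs: dict[str, list[float]] = {s: [] for s in sugars}
    n_used = 0
    for batch, members in sorted(by_batch.items()):
        if len(members) < 2:
            log.info("batch %s has %d reference(s); skipped", batch, len(members))
            continue
        sub = table.loc[members, sugars]
        mean = sub.mean(axis=0)
        if (mean <= 0).any():
            raise ValueError(f"zero batch reference mean in batch {batch}")
        rel = 100.0 * (sub - mean) / mean
        for s in sugars:
            devs[s].extend(np.abs(rel[s].to_numpy()))
        n_used += len(members)
    if n_used == 0:
        raise ValueError("no batch contributed >= 2 references")
    mu = {s: float(np.mean(devs[s])) for s in sugars}
    sigma = {s: float(np.std(devs[s], ddof=1)) for s in sugars}
    return ReferenceVariability(mu=mu, sigma=sigma, n_references=n_used)


def thresholds_from_sigma(var: ReferenceVariability, k: float = 4.0) -> ThresholdSet:
    """k-sigma flagging thresholds, one per sugar."""
    if k <= 0:
        raise ValueError("k must be positive")
    return ThresholdSet(
        thresholds={s: k * sig for s, sig in var.sigma.items()}, k_sigma=k
    )


def percent_differences(
    values: pd.DataFrame,
    baseline: pd.Series | pd.DataFrame,
    batch_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Relative percent difference of each sample from its batch baseline.

    ``baseline`` is either one per-sugar mean (Series) applied to every
    sample, or a per-batch table (index = batch id) with ``batch_of``
    mapping sample id -> batch id.
    """
    if isinstance(baseline, pd.Series):
        base = pd.DataFrame(
            np.tile(baseline[values.columns].to_numpy(dtype=float), (len(values), 1)),
            index=values.index,
            columns=values.columns,
        )
    else:
        if batch_of is None:
            raise ValueError("per-batch baselines require a batch_of mapping")
        batches = [batch_of[sid] for sid in values.index]
        base = baseline.loc[batches, values.columns].set_axis(values.index)
    zero = (base <= 0).any(axis=0)
    if zero.any():
        raise ValueError(
            f"non-positive baseline for sugar(s) {list(base.columns[zero])}"
        )
    return 100.0 * (values - base) / base


@dataclass
class OutlierReport:
    """Per-sample sugar percent differences, triggered sugars and flags."""

    differences: pd.DataFrame  # samples x sugars, relative %
    triggered: dict[str, list[str]]  # sample id -> sugars exceeding threshold
    flagged: list[str]
    thresholds: ThresholdSet
    summary: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = self.differences.copy()
        df["triggered_sugars"] = [
            ";".join(self.triggered.get(sid, [])) for sid in df.index
        ]
        df["flagged"] = [sid in set(self.flagged) for sid in df.index]
        return df

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, sep="\t", float_format="%.17g", index_label="sample_id")
        with open(path.with_suffix(".summary.json"), "w") as fh:
            json.dump(
                {
                    "thresholds": {k: float(v) for k, v in self.thresholds.thresholds.items()},
                    "k_sigma": self.thresholds.k_sigma,
                    "n_flagged": len(self.flagged),
                    "flagged": sorted(self.flagged),
                    **self.summary,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def flag_sugar_outliers(
    diffs: pd.DataFrame,
    thresholds: ThresholdSet,
    major_sugars: Iterable[str] = MAJOR_SUGARS,
) -> OutlierReport:
    """Flag samples whose |percent difference| >= threshold for any major sugar.

    The comparison is closed (>=): a difference exactly at the threshold
    flags the sample.
    """
    major_sugars = list(major_sugars)
    missing = [s for s in major_sugars if s not in thresholds.thresholds]
    if missing:
        raise ValueError(f"thresholds missing for sugars: {missing}")
    missing_cols = [s for s in major_sugars if s not in diffs.columns]
    if missing_cols:
        raise ValueError(f"difference table missing sugars: {missing_cols}")
    triggered: dict[str, list[str]] = {}
    for sid, row in diffs.iterrows():
        hits = [s for s in major_sugars if abs(row[s]) >= thresholds[s]]
        if hits:
            triggered[str(sid)] = hits
    flagged = sorted(triggered)
    return OutlierReport(
        differences=diffs,
        triggered=triggered,
        flagged=flagged,
        thresholds=thresholds,
        summary={"n_samples": int(len(diffs))},
    )


def validation_rate(confirmed: int, analyzed: int, exact: bool = False) -> float:
    """Percent of analyzed candidates that were confirmed.

    Reported rounded to the nearest integer percent by default; pass
    ``exact=True`` for the unrounded value.
    """
    if analyzed <= 0:
        raise ValueError("analyzed count must be positive")
    if not 0 <= confirmed <= analyzed:
        raise ValueError("confirmed must be between 0 and analyzed")
    rate = 100.0 * confirmed / analyzed
    return rate if exact else float(round(rate))


def combine_outlier_sets(set_a: Iterable[str], set_b: Iterable[str]) -> dict[str, int]:
    """Union/intersection bookkeeping for two outlier candidate sets."""
    a, b = set(set_a), set(set_b)
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_intersection": len(a & b),
        "n_union": len(a | b),
    }
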