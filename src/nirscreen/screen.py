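"""Batch-wise iterative Mahalanobis consensus screen.

One screening iteration picks a random leaf from the batch, uses its
replicate scans as the reference set, computes the Mahalanobis distance of
every other leaf in score space, and shortlists the top fraction with the
largest distances.  Iterations repeat with fresh references; leaves that
recur in the shortlist across iterations (``min_hits`` of them, by default
all) are called consensus outliers — candidates for wet-lab composition
analysis.

Replicate-scan convention: the primary scan of leaf "X" is the row with
sample id "X"; repeated scans are rows "X#s2", "X#s3", ... (see
:func:`nirscreen.spectra.base_id`).  Only leaves with at least
``reference_scan_count`` scans are eligible as references; ranking is over
primary scans only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .chemometrics import ScoreMatrix, build_reference, fit_pca, mahalanobis_distance
from .preprocess import PreprocessConfig, preprocess_pipeline
from .spectra import SpectraSet, base_id

__all__ = [
    "ScreenConfig",
    "IterationRecord",
    "MahalanobisScreenReport",
    "choose_references",
    "screen_iteration",
    "consensus_outliers",
    "screen_batch",
]


@dataclass
class ScreenConfig:
    """Screen parameters: iterations, shortlist fraction, score dimension.

    Defaults mirror the screening protocol: 5 iterations, top 5% shortlist,
    4 principal-component scores against 5 replicate reference scans, and a
    consensus call requiring presence in every iteration.
    """

    n_iterations: int = 5
    top_fraction: float = 0.05
    n_components: int = 4
    reference_scan_count: int = 5
    min_hits: int | None = None  # None -> n_iterations
    seed: int = 0
    #: covariance stabilization for the tiny reference sets (5 scans vs 4
    #: score dimensions): Ledoit-Wolf shrinkage toward the scaled identity.
    #: A float fixes the intensity; 0 disables it.
    covariance_shrinkage: float | str = "lw"

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must be in (0, 1)")
        if self.min_hits is None:
            self.min_hits = self.n_iterations
        if not 1 <= self.min_hits <= self.n_iterations:
            raise ValueError("min_hits must be in [1, n_iterations]")
        if self.n_components >= self.reference_scan_count:
            raise ValueError(
                "n_components must be strictly fewer than reference_scan_count"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class IterationRecord:
    reference_id: str
    ranked: list[tuple[str, float]]  # (sample_id, distance), descending distance
    shortlist: list[str]


@dataclass
class MahalanobisScreenReport:
    batch_id: str
    config: dict
    iterations: list[IterationRecord]
    consensus: list[tuple[str, int]]  # (sample_id, hit count)

    @property
    def consensus_ids(self) -> list[str]:
        return [sid for sid, _ in self.consensus]

    def to_dict(self) -> dict:
        return {
            "batch_id": self.batch_id,
            "config": self.config,
            "iterations": [
                {
                    "reference_id": it.reference_id,
                    "ranked": [[sid, float(d)] for sid, d in it.ranked],
                    "shortlist": list(it.shortlist),
                }
                for it in self.iterations
            ],
            "consensus_outliers": [
                {"sample_id": sid, "hits": int(n)} for sid, n in self.consensus
            ],
        }

    def save(self, path: str | Path) -> None:
        """Write the report JSON plus one ranked-distance CSV per iteration."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
        for k, it in enumerate(self.iterations, start=1):
            df = pd.DataFrame(it.ranked, columns=["sample_id", "distance"])
            df.to_csv(path.with_suffix(f".iter{k}.csv"), index=False, float_format="%.17g")


def choose_references(batch_sample_ids: list[str], n_iterations: int, seed: int) -> list[str]:
    """Draw ``n_iterations`` distinct reference leaves uniformly at random.

    The candidate list is sorted before drawing, so the choice depends only
    on the seed and the set of ids, not their order.
    """
    ids = sorted(set(batch_sample_ids))
    if len(ids) <= n_iterations:
        raise ValueError(
            f"need more than {n_iterations} samples to draw {n_iterations} references; "
            f"got {len(ids)}"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(ids), size=n_iterations, replace=False)
    return [ids[i] for i in picked]


def _shortlist_size(n_eligible: int, top_fraction: float) -> int:
    return math.ceil(top_fraction * n_eligible)


def screen_iteration(
    scores: ScoreMatrix,
    ref_id: str,
    cfg: ScreenConfig,
    replicate_scores: ScoreMatrix,
) -> IterationRecord:
    """One Mahalanobis ranking pass against a single reference leaf.

    ``scores`` holds one row per eligible (primary-scan) leaf;
    ``replicate_scores`` the reference leaf's repeated scans.  The
    reference's own scans are excluded from the ranking.  Ties in distance
    are broken by ascending sample id.
    """
    if replicate_scores.scores.shape[0] != cfg.reference_scan_count:
        raise ValueError(
            f"reference {ref_id!r} has {replicate_scores.scores.shape[0]} scans; "
            f"config expects {cfg.reference_scan_count}"
        )
    ref = build_reference(
        replicate_scores, list(replicate_scores.sample_ids), cfg.n_components
    )
    eligible_ids = [sid for sid in scores.sample_ids if base_id(sid) != ref_id]
    queries = scores.select(eligible_ids).truncate(cfg.n_components)
    d = mahalanobis_distance(ref, queries, shrinkage=cfg.covariance_shrinkage)
    order = sorted(range(len(eligible_ids)), key=lambda i: (-d[i], eligible_ids[i]))
    ranked = [(eligible_ids[i], float(d[i])) for i in order]
    k = _shortlist_size(len(eligible_ids), cfg.top_fraction)
    shortlist = [sid for sid, _ in ranked[:k]]
    return IterationRecord(reference_id=ref_id, ranked=ranked, shortlist=shortlist)


def consensus_outliers(
    iterations: list[IterationRecord], min_hits: int
) -> list[tuple[str, int]]:
    """Samples appearing in >= min_hits shortlists, most-recurrent first."""
    if not iterations:
        raise ValueError("at least one iteration required")
    counts: dict[str, int] = {}
    for it in iterations:
        for sid in it.shortlist:
            counts[sid] = counts.get(sid, 0) + 1
    hits = [(sid, n) for sid, n in counts.items() if n >= min_hits]
    return sorted(hits, key=lambda t: (-t[1], t[0]))


def screen_batch(
    sset: SpectraSet,
    batch_id: str,
    cfg: ScreenConfig | None = None,
    pp_cfg: PreprocessConfig | None = None,
) -> MahalanobisScreenReport:
    """Full screen of one batch: preprocess, PCA, iterate, consensus.

    The batch PCA is fit on every scan of the batch (replicate reference
    scans included); references are drawn among leaves that carry at least
    ``reference_scan_count`` scans.
    """
    cfg = cfg or ScreenConfig()
    pp_cfg = pp_cfg or PreprocessConfig()
    batch = sset.batch(batch_id)
    processed, _centering = preprocess_pipeline(batch, pp_cfg)
    _model, scores = fit_pca(processed)

    by_base: dict[str, list[str]] = {}
    for sid in scores.sample_ids:
        by_base.setdefault(base_id(sid), []).append(sid)
    candidates = [b for b, rows in by_base.items() if len(rows) >= cfg.reference_scan_count]
    if len(candidates) <= cfg.n_iterations:
        raise ValueError(
            f"batch {batch_id!r} has {len(candidates)} reference-eligible leaves "
            f"(>= {cfg.reference_scan_count} scans each); need more than "
            f"{cfg.n_iterations}. Supply replicate scans for candidate references."
        )
    primary_ids = [sid for sid in scores.sample_ids if base_id(sid) == sid]
    primary_scores = scores.select(primary_ids)

    refs = choose_references(candidates, cfg.n_iterations, cfg.seed)
    iterations = []
    for ref_id in refs:
        scan_ids = sorted(by_base[ref_id])[: cfg.reference_scan_count]
        iterations.append(
            screen_iteration(primary_scores, ref_id, cfg, scores.select(scan_ids))
        )
    consensus = consensus_outliers(iterations, cfg.min_hits)
    return MahalanobisScreenReport(
        batch_id=batch_id,
        config=cfg.to_dict(),
        iterations=iterations,
        consensus=consensus,
    )
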