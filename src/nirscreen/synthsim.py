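"""Synthetic leaf FT-NIR populations with known ground truth.

Each sugar gets a smooth basis spectrum (a sum of broad Gaussian overtone
bands); a leaf's absorbance is the composition-weighted mixture of the
basis spectra times a batch gain, plus a sloped baseline and white noise:

    A(v) = gain_b * sum_s (c_s / 100) * B_s(v) + offset + slope * v + eps

Compositions are drawn per sugar around a batch-shifted base value with a
controlled coefficient of variation (lognormal, then renormalized to 100
mol%).  Natural variation is not independent across sugars: most of it is
driven by shared latent factors (developmental stage and co-regulated
polysaccharide synthesis couple e.g. Ara with Xyl through arabinoxylan
stoichiometry, and the pectic sugars with each other), with only a small
independent per-sugar residual.  A chosen fraction of leaves are planted
composition outliers: one major sugar is shifted by a multiple of its own
population sigma — a single-sugar lesion points away from the correlated
natural manifold, which is what makes it spectrally distinctive.

Every scan samples one location on a leaf, and tissue is heterogeneous:
the composition seen by a single scan is the leaf composition times a
small per-scan lognormal jitter (``scan_cv_fraction`` of the population
CV).  Designated reference leaves receive replicate scans (same leaf
composition and gain; fresh location jitter, baseline and noise),
emulating the scanned-five-times reference protocol whose whole point is
to capture representative within-leaf variability.  Everything is
recorded in :class:`SimTruth`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .composition import MAJOR_SUGARS, SUGARS
from .spectra import SCAN_SEP, SpectraSet

__all__ = [
    "SimConfig",
    "SimTruth",
    "make_basis",
    "simulate_population",
    "simulate_calibration_set",
]

#: typical rice leaf matrix-polysaccharide composition, mol%
DEFAULT_COMPOSITION_BASE = {
    "Fuc": 0.5,
    "Rha": 1.5,
    "Ara": 12.0,
    "Gal": 6.0,
    "Glc": 28.0,
    "Xyl": 44.0,
    "GlcA": 3.0,
    "GalA": 5.0,
}

#: per-sugar population coefficient of variation (fraction).  Low-abundance
#: matrix sugars vary proportionally more between individuals than the
#: dominant structural sugars, giving each major sugar a comparable
#: absolute mol% spread.
DEFAULT_COMPOSITION_CV = {
    "Fuc": 0.20,
    "Rha": 0.20,
    "Ara": 0.09,
    "Gal": 0.15,
    "Glc": 0.042,
    "Xyl": 0.027,
    "GlcA": 0.08,
    "GalA": 0.06,
}


@dataclass
class SimConfig:
    """Generator settings for one synthetic screening population."""

    seed: int = 0
    n_batches: int = 1
    lines_per_batch: int = 50
    samples_per_line: int = 8
    grid_lo: float = 3600.0
    grid_hi: float = 9200.0
    grid_step: float = 8.0
    n_bands_per_sugar: int = 6
    baseline_offset_range: tuple[float, float] = (0.0, 0.05)
    baseline_slope_range: tuple[float, float] = (-8e-6, 8e-6)
    noise_sd: float = 0.002
    batch_effect_sd: float = 0.03
    composition_base: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION_BASE)
    )
    composition_cv: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION_CV)
    )
    scan_cv_fraction: float = 0.15  # within-leaf (per-scan) CV as a fraction of population CV
    factor_share: float = 0.0  # fraction of log-variance carried by shared latent factors
    line_effect_share: float = 0.75  # fraction of log-variance shared by sibling leaves of a line
    #: bounds (in sigma units) on normal biological variation: per sugar,
    #: and on the joint standardized deviation radius across sugars.
    #: Samples are "normal" by construction — deviations beyond these are
    #: exactly what the planted, truth-labeled outliers represent.
    deviation_clip: float = 2.0
    deviation_radius: float = 2.6
    outlier_fraction: float = 0.01
    n_outliers: int | None = None  # exact count; overrides outlier_fraction
    outlier_shift_sigmas: float = 6.0
    reference_scan_count: int = 5
    n_reference_candidates: int = 8

    def __post_init__(self) -> None:
        total = sum(self.composition_base.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"composition_base sums to {total}, expected 100")
        for s, cv in self.composition_cv.items():
            if not 0 <= cv <= 1:
                raise ValueError(f"composition_cv[{s}]={cv} outside [0, 1]")
        if not 0 <= self.outlier_fraction <= 1:
            raise ValueError("outlier_fraction must be in [0, 1]")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_hi - self.grid_lo) / self.grid_step)) + 1
        return self.grid_lo + self.grid_step * np.arange(n)

    @property
    def samples_per_batch(self) -> int:
        return self.lines_per_batch * self.samples_per_line

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline_offset_range"] = list(self.baseline_offset_range)
        d["baseline_slope_range"] = list(self.baseline_slope_range)
        return d


@dataclass
class SimTruth:
    """Ground truth of a simulated population."""

    composition: pd.DataFrame  # one row per leaf, true mol%
    outliers: list[dict]  # sample_id, sugar, shift_sigmas, relative_shift_pct
    batch_params: dict[str, dict]
    basis: np.ndarray  # sugars x channels
    grid: np.ndarray
    sugars: list[str]

    @property
    def outlier_ids(self) -> list[str]:
        return [o["sample_id"] for o in self.outliers]

    def to_json(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "composition": {
                "index": self.composition.index.tolist(),
                "columns": self.composition.columns.tolist(),
                "values": self.composition.to_numpy().tolist(),
            },
            "outliers": self.outliers,
            "batch_params": self.batch_params,
            "basis": self.basis.tolist(),
            "grid": self.grid.tolist(),
            "sugars": list(self.sugars),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        comp = pd.DataFrame(
            payload["composition"]["values"],
            index=payload["composition"]["index"],
            columns=payload["composition"]["columns"],
        )
        return cls(
            composition=comp,
            outliers=payload["outliers"],
            batch_params=payload["batch_params"],
            basis=np.asarray(payload["basis"], float),
            grid=np.asarray(payload["grid"], float),
            sugars=list(payload["sugars"]),
        )


def make_basis(
    seed: int,
    grid: np.ndarray,
    sugars: list[str] | int = len(SUGARS),
    n_bands: int = 6,
    max_tries: int = 200,
) -> np.ndarray:
    """Per-sugar basis spectra: sums of broad Gaussian bands.

    Band centers are uniform in [4000, 9000] cm^-1, widths uniform in
    [50, 300] cm^-1, amplitudes positive.  One band per sugar — its
    characteristic overtone/combination band — is placed inside a
    sugar-specific subwindow of the range, so every component has a
    distinguishing spectral feature (the chemical premise that makes NIR
    quantification of individual sugars possible at all); the remaining
    bands fall anywhere.  Basis spectra are resampled until every
    pairwise correlation is below 0.95.
    """
    if isinstance(sugars, int):
        n_sugars = sugars
    else:
        n_sugars = len(sugars)
    rng = np.random.default_rng(seed)
    grid = np.asarray(grid, float)
    windows = np.linspace(4200.0, 8800.0, n_sugars + 1)

    def one(k: int) -> np.ndarray:
        centers = rng.uniform(4000.0, 9000.0, n_bands)
        widths = rng.uniform(50.0, 300.0, n_bands)
        amps = rng.uniform(0.2, 1.0, n_bands)
        # characteristic band in this sugar's own window
        centers[0] = rng.uniform(windows[k], windows[k + 1])
        widths[0] = rng.uniform(60.0, 150.0)
        amps[0] = rng.uniform(0.6, 1.0)
        return np.sum(
            amps[:, None] * np.exp(-0.5 * ((grid[None, :] - centers[:, None]) / widths[:, None]) ** 2),
            axis=0,
        )

    basis = np.stack([one(k) for k in range(n_sugars)])
    for _ in range(max_tries):
        corr = np.corrcoef(basis)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        if abs(corr[i, j]) < 0.95:
            return basis
        k = int(max(i, j))
        basis[k] = one(k)
    raise RuntimeError("could not generate sufficiently distinct basis spectra")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal factors with the given CV."""
    if cv == 0:
        return np.ones(() if size is None else size)
    s2 = math.log1p(cv**2)
    return rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2), size=size)


#: fixed co-regulation sign patterns over (Fuc, Rha, Ara, Gal, Glc, Xyl,
#: GlcA, GalA): a hemicellulose factor (arabinoxylan up at the expense of
#: the hexoses) and a pectin factor (pectic sugars together).
_FACTOR_PATTERNS = np.array(
    [
        [-1, -1, +1, -1, -1, +1, +1, -1],
        [+1, +1, +1, +1, -1, -1, -1, +1],
    ],
    dtype=float,
)


def _standardized_deviations(
    rng: np.random.Generator,
    n: int,
    n_sugars: int,
    factor_share: float,
    clip: float = np.inf,
) -> np.ndarray:
    """Unit-scale per-sugar log deviations with latent-factor correlation.

    Latent draws are clipped at ``clip`` sigmas: normal biological
    variation is bounded by construction, so that "outlier" is a
    well-defined label reserved for the planted composition shifts.
    """
    f = np.clip(rng.standard_normal((n, _FACTOR_PATTERNS.shape[0])), -clip, clip)
    shared = (f @ _FACTOR_PATTERNS) / math.sqrt(_FACTOR_PATTERNS.shape[0])
    resid = np.clip(rng.standard_normal((n, n_sugars)), -clip, clip)
    return math.sqrt(factor_share) * shared + math.sqrt(1.0 - factor_share) * resid


def _population_factors(
    rng: np.random.Generator,
    cvs: np.ndarray,
    line_of: np.ndarray,
    factor_share: float,
    line_effect_share: float,
    clip: float = np.inf,
    radius: float = np.inf,
) -> np.ndarray:
    """Correlated unit-mean multiplicative composition factors (leaves x sugars).

    Per-sugar log-variance is split three ways: a line-level effect shared
    by sibling leaves (genotype plus shared growth microenvironment), a
    leaf-level residual, and — within each of those — a latent-factor
    component correlating the sugars.  Each sugar's marginal CV equals
    ``cvs``.
    """
    sig = np.sqrt(np.log1p(cvs**2))
    lines, line_idx = np.unique(line_of, return_inverse=True)
    z_line = _standardized_deviations(rng, lines.size, cvs.size, factor_share)
    z_leaf = _standardized_deviations(rng, line_of.size, cvs.size, factor_share)
    z = (
        math.sqrt(line_effect_share) * z_line[line_idx]
        + math.sqrt(1.0 - line_effect_share) * z_leaf
    )
    # the bounds apply to the leaf's total deviation, not the components
    z = np.clip(z, -clip, clip)
    r = np.linalg.norm(z, axis=1, keepdims=True)
    np.divide(radius, r, out=r, where=r > radius)
    z = z * np.where(r < 1.0, r, 1.0)
    return np.exp(sig * z - sig**2 / 2.0)


def simulate_population(cfg: SimConfig) -> tuple[SpectraSet, pd.DataFrame, SimTruth]:
    """Generate a full population: spectra, composition table, ground truth.

    Sample ids follow "<line>-<rep>" (e.g. "0007-3"); replicate reference
    scans append the scan suffix (e.g. "0007-3#s2").
    """
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid
    sugars = list(SUGARS)
    basis = make_basis(int(rng.integers(2**31)), grid, sugars, cfg.n_bands_per_sugar)

    rows_absorbance: list[np.ndarray] = []
    rows_meta: list[dict] = []
    comp_records: dict[str, np.ndarray] = {}
    outlier_records: list[dict] = []
    batch_params: dict[str, dict] = {}

    def baseline_and_noise() -> np.ndarray:
        offset = rng.uniform(*cfg.baseline_offset_range)
        slope = rng.uniform(*cfg.baseline_slope_range)
        return offset + slope * (grid - grid[0]) + rng.normal(0.0, cfg.noise_sd, grid.size)

    line_counter = 0
    for b in range(cfg.n_batches):
        batch_id = f"B{b + 1:02d}"
        gain = 1.0 + rng.normal(0.0, cfg.batch_effect_sd)
        comp_shift = {
            s: float(_lognormal_factors(rng, cfg.batch_effect_sd, None))
            for s in sugars
        }
        batch_params[batch_id] = {"gain": gain, "composition_shift": comp_shift}
        base = np.array([cfg.composition_base[s] * comp_shift[s] for s in sugars])
        base *= 100.0 / base.sum()

        sample_ids = []
        line_ids = []
        reps = []
        for l in range(cfg.lines_per_batch):
            line_counter += 1
            line = f"{line_counter:04d}"
            for r in range(cfg.samples_per_line):
                sample_ids.append(f"{line}-{r + 1}")
                line_ids.append(line)
                reps.append(r + 1)
        n = len(sample_ids)

        cvs = np.array([cfg.composition_cv[s] for s in sugars])
        comp = base[None, :] * _population_factors(
            rng,
            cvs,
            np.asarray(line_ids),
            cfg.factor_share,
            cfg.line_effect_share,
            cfg.deviation_clip,
            cfg.deviation_radius,
        )

        # reference candidates first, so planted outliers never collide
        ref_pool = sorted(
            rng.choice(n, size=min(cfg.n_reference_candidates, n), replace=False)
        )
        ref_set = set(int(i) for i in ref_pool)
        if cfg.n_outliers is not None:
            n_out = cfg.n_outliers
        else:
            n_out = int(round(cfg.outlier_fraction * n))
        eligible = np.array([i for i in range(n) if i not in ref_set])
        out_idx = rng.choice(eligible, size=n_out, replace=False) if n_out else np.array([], int)
        major_pos = [sugars.index(s) for s in MAJOR_SUGARS]
        for i in out_idx:
            sp = major_pos[int(rng.integers(len(major_pos)))]
            sign = 1.0 if rng.random() < 0.5 else -1.0
            kcv = cfg.outlier_shift_sigmas * cvs[sp]
            for _attempt in range(2):
                old = comp[i, sp]
                row_sum = comp[i].sum()
                # target displacement of k population sigmas AFTER closure:
                # renormalizing to 100 mol% claws back part of any raw
                # shift (severely so for abundant sugars), so solve for
                # the raw delta that survives it.  The landing point is at
                # least k sigmas beyond the batch base as well as beyond
                # the sample's own draw: a k-sigma outlier lies k sigmas
                # outside the population, wherever it started.
                landing = sign * kcv * base[sp] + (old if sign * (old - base[sp]) > 0 else base[sp])
                target = landing - old
                denom = row_sum - old - target
                delta = target * row_sum / denom if denom > 0 else target
                # keep the shift also >= k sigmas of the sample's own value
                if abs(delta) < kcv * old:
                    delta = sign * kcv * old
                new = old + delta
                if new > 0.02 * base[sp]:
                    break
                sign = 1.0  # a full negative shift would wipe out the sugar
            comp[i, sp] = new
            outlier_records.append(
                {
                    "sample_id": sample_ids[int(i)],
                    "sugar": sugars[sp],
                    "shift_sigmas": float(cfg.outlier_shift_sigmas),
                    "relative_shift_pct": float(100.0 * (new - old) / old),
                }
            )
        comp *= 100.0 / comp.sum(axis=1, keepdims=True)

        scan_cvs = cvs * cfg.scan_cv_fraction

        def scan_spectrum(leaf_comp: np.ndarray) -> np.ndarray:
            sigj = np.sqrt(np.log1p(scan_cvs**2))
            zj = np.clip(rng.standard_normal(sigj.size), -cfg.deviation_clip, cfg.deviation_clip)
            jitter = np.exp(sigj * zj - sigj**2 / 2.0)
            c = leaf_comp * jitter
            c = 100.0 * c / c.sum()
            return gain * (c / 100.0) @ basis + baseline_and_noise()

        for i, sid in enumerate(sample_ids):
            role = "reference" if i in ref_set else "unknown"
            rows_absorbance.append(scan_spectrum(comp[i]))
            rows_meta.append(
                {
                    "sample_id": sid,
                    "batch_id": batch_id,
                    "line_id": line_ids[i],
                    "replicate": reps[i],
                    "role": role,
                }
            )
            comp_records[sid] = comp[i]
            if i in ref_set:
                for k in range(2, cfg.reference_scan_count + 1):
                    rows_absorbance.append(scan_spectrum(comp[i]))
                    rows_meta.append(
                        {
                            "sample_id": f"{sid}{SCAN_SEP}{k}",
                            "batch_id": batch_id,
                            "line_id": line_ids[i],
                            "replicate": reps[i],
                            "role": "reference",
                        }
                    )

    sset = SpectraSet(
        grid=grid,
        absorbance=np.vstack(rows_absorbance),
        meta=pd.DataFrame(rows_meta),
        processing_log=[{"step": "simulated", "seed": cfg.seed}],
    )
    comp_table = pd.DataFrame.from_dict(comp_records, orient="index", columns=sugars)
    comp_table.index.name = "sample_id"
    truth = SimTruth(
        composition=comp_table,
        outliers=outlier_records,
        batch_params=batch_params,
        basis=basis,
        grid=grid,
        sugars=sugars,
    )
    return sset, comp_table, truth


def simulate_calibration_set(
    n_samples: int = 206,
    seed: int = 0,
    noise_sd: float | None = None,
    outlier_fraction: float = 0.15,
) -> tuple[SpectraSet, pd.DataFrame, SimTruth]:
    """Single-batch calibration population, enriched in composition outliers.

    Emulates bootstrapping the calibration set from screen outliers plus
    references: a sizeable fraction of leaves carry large compositional
    shifts, widening the mol% range the regression is trained on.
    """
    cfg = SimConfig(
        seed=seed,
        n_batches=1,
        lines_per_batch=n_samples,
        samples_per_line=1,
        outlier_fraction=outlier_fraction,
        n_reference_candidates=0,
    )
    if noise_sd is not None:
        cfg.noise_sd = noise_sd
    return simulate_population(cfg)
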