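"""Inverse HSP estimation from swelling data by constrained R² maximization.

The physical premise: the better a solvent swells a cross-linked polymer,
the closer the solvent sits to the polymer in Hansen space.  So across a
panel of solvents, % swelling and the Hansen distance Ra should be
*negatively* and roughly linearly correlated.  The polymer's unknown HSP
triple is the candidate point that makes this linear anti-correlation
strongest: we maximize the R² of the ordinary least-squares line of Ra on
% swelling, restricted to candidates whose correlation is negative, over the
box [2.5, 40]³ MPa^1/2 (the range of typical HSP values).

The search is a deterministic coarse-to-fine grid scan (vectorized over the
full box, then refined around the coarse optimum), optionally polished by a
seeded multi-start bounded quasi-Newton step.  Grid search makes the
procedure reproducible and makes near-flat objectives visible: all grid
points within ``plateau_tolerance`` of the optimum are reported, and any
fitted component that lands exactly on a box bound is flagged — a boundary
solution signals limited identifiability, not a confident estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .core import HSPVector, ra_distance_many
from .errors import (
    DegenerateDataError,
    EstimationFailureError,
    MissingValueError,
    ValidationError,
)
from .swelling import SwellingDataset

DEFAULT_BOUNDS = (2.5, 40.0)


@dataclass(frozen=True)
class SolventTable:
    """Named solvents with their handbook HSP triples."""

    entries: dict[str, HSPVector]
    sources: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("solvent table must not be empty")

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __getitem__(self, name: str) -> HSPVector:
        try:
            return self.entries[name]
        except KeyError:
            raise MissingValueError(
                f"solvent {name!r} is not in the solvent table "
                f"(known: {sorted(self.entries)})"
            ) from None

    def subset(self, names) -> "SolventTable":
        return SolventTable(
            entries={n: self[n] for n in names},
            sources={n: self.sources.get(n, "") for n in names},
        )

    def hsp_matrix(self, names) -> np.ndarray:
        return np.array([tuple(self[n]) for n in names], dtype=float)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SolventTable":
        df = pd.read_csv(path, comment="#", skipinitialspace=True)
        required = {"name", "delta_d", "delta_p", "delta_hb"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"solvent CSV is missing columns {sorted(missing)}")
        entries: dict[str, HSPVector] = {}
        sources: dict[str, str] = {}
        for idx, row in df.iterrows():
            name = str(row["name"]).strip()
            if name in entries:
                raise ValidationError(f"duplicate solvent name {name!r} (row {idx})")
            try:
                entries[name] = HSPVector(
                    float(row["delta_d"]), float(row["delta_p"]), float(row["delta_hb"])
                )
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"row {idx} ({name!r}): {exc}") from exc
            sources[name] = str(row.get("source", "") or "")
        return cls(entries=entries, sources=sources)

    @classmethod
    def default(cls) -> "SolventTable":
        """The shipped handbook table (hexane, diethyl ether, chloroform,
        acetone, ethyl acetate, isopropanol, water)."""
        with resources.as_file(
            resources.files("hspscreen.data") / "solvents.csv"
        ) as p:
            return cls.from_csv(p)


@dataclass(frozen=True)
class EstimationConfig:
    """Search settings for the constrained R² maximization.

    ``bounds`` applies to every HSP component; ``coarse_step`` is the global
    scan resolution, ``refine_step`` the local resolution around the coarse
    optimum.  ``multistart_count > 0`` adds seeded L-BFGS-B polish runs from
    random interior starts (off by default: the grid alone reproduces
    published workflows deterministically).
    """

    bounds: tuple[float, float] = DEFAULT_BOUNDS
    coarse_step: float = 0.5
    refine_step: float = 0.05
    plateau_tolerance: float = 1e-6
    multistart_count: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not lo < hi:
            raise ValidationError(f"bounds lower must be < upper, got {self.bounds}")
        if self.coarse_step <= 0 or self.refine_step <= 0:
            raise ValidationError("grid steps must be > 0")
        if self.plateau_tolerance < 0:
            raise ValidationError("plateau_tolerance must be >= 0")
        if self.multistart_count < 0:
            raise ValidationError("multistart_count must be >= 0")


@dataclass(frozen=True)
class EstimationResult:
    """Outcome of one HSP fit."""

    hsp: HSPVector
    r_squared: float
    slope_sign: str  # "negative" | "positive"
    boundary_flags: tuple[bool, bool, bool]
    plateau: tuple[HSPVector, ...]
    per_solvent_ra: dict[str, float]
    residuals: dict[str, float]
    solvents_used: tuple[str, ...]

    @property
    def on_boundary(self) -> bool:
        return any(self.boundary_flags)


def _score_candidates(grid: np.ndarray, solvent_hsps: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Signed objective for candidate HSP points, vectorized.

    Returns +R² where Ra and swelling are negatively correlated and -R²
    where positively correlated, so any maximizer rejects positive-slope
    candidates.  Zero where Ra has no variance across solvents.
    """
    ra = ra_distance_many(grid, solvent_hsps)  # (..., n_solv)
    rc = ra - ra.mean(axis=-1, keepdims=True)
    yc = y - y.mean()
    y_norm = float(np.sqrt((yc**2).sum()))
    num = rc @ yc
    ra_norm = np.sqrt((rc**2).sum(axis=-1))
    # candidates whose Ra is (numerically) constant across solvents carry no
    # signal; score them zero instead of amplifying rounding noise
    valid = ra_norm > 1e-9 * max(1.0, float(np.abs(ra).max()))
    den = ra_norm * y_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(valid, num / np.where(valid, den, 1.0), 0.0)
    return np.where(r < 0, r**2, -(r**2))


def objective_r2(
    candidate: HSPVector,
    swelling_means: dict[str, float],
    solvents: SolventTable,
) -> float:
    """Signed fit score of one candidate polymer HSP.

    Computes Ra from the candidate to each solvent, fits the least-squares
    line of Ra on % swelling, and returns R² if the correlation is negative
    (physically sensible) or -R² if positive.
    """
    names = list(swelling_means)
    if len(names) < 3:
        raise ValidationError(
            f"need at least 3 solvents to constrain 3 HSP components, got {len(names)}"
        )
    if len(names) < 5:
        warnings.warn(
            f"only {len(names)} solvents: the fit is weakly constrained",
            stacklevel=2,
        )
    y = np.array([swelling_means[n] for n in names], dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateDataError("swelling has zero variance across solvents")
    score = _score_candidates(candidate.as_array(), solvents.hsp_matrix(names), y)
    return float(score)


def _axis(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    ax = lo + step * np.arange(n)
    if ax[-1] < hi - 1e-9:  # include the upper bound even off-grid
        ax = np.append(ax, hi)
    return ax


def _grid(axes: list[np.ndarray]) -> np.ndarray:
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=-1)


def _best_index(scores: np.ndarray) -> int:
    # grids are built in lexicographic (d, p, hb) order, so the first argmax
    # is the lexicographically smallest exact tie
    return int(np.argmax(scores))


def estimate_hsp(
    dataset: SwellingDataset,
    solvents: SolventTable | None = None,
    config: EstimationConfig | None = None,
) -> EstimationResult:
    """Fit a polymer's HSP triple to per-solvent mean swelling.

    Excluded solvents (reactive with the polymer, or user-flagged) are
    dropped before fitting.  Deterministic for a fixed config; exact ties
    resolve to the lexicographically smallest (δd, δp, δhb).

    Raises
    ------
    EstimationFailureError
        If no candidate in the box achieves a negative swelling–distance
        correlation.
    """
    solvents = solvents or SolventTable.default()
    config = config or EstimationConfig()
    means = dataset.solvent_means()
    names = list(means)
    if len(names) < 3:
        raise ValidationError(
            f"need at least 3 non-excluded solvents, got {len(names)} "
            f"(excluded: {dict(dataset.excluded)})"
        )
    missing = [n for n in names if n not in solvents]
    if missing:
        raise MissingValueError(f"no HSP entry for solvent(s) {missing}")
    y = np.array([means[n] for n in names], dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateDataError("swelling has zero variance across solvents")
    S = solvents.hsp_matrix(names)
    lo, hi = config.bounds

    # coarse scan of the whole box
    coarse_ax = _axis(lo, hi, config.coarse_step)
    coarse_grid = _grid([coarse_ax] * 3)
    coarse_scores = _score_candidates(coarse_grid, S, y)
    i = _best_index(coarse_scores)
    if coarse_scores[i] <= 0:
        raise EstimationFailureError(
            "every candidate HSP gives a non-negative swelling-Ra correlation; "
            "the dataset contradicts the swelling model "
            f"(best signed score {coarse_scores[i]:.4f})"
        )
    best = coarse_grid[i]

    # local refinement around the coarse optimum
    axes = [
        _axis(max(best[k] - config.coarse_step, lo),
              min(best[k] + config.coarse_step, hi),
              config.refine_step)
        for k in range(3)
    ]
    refine_grid = _grid(axes)
    refine_scores = _score_candidates(refine_grid, S, y)
    j = _best_index(refine_scores)
    best = refine_grid[j]
    best_score = float(refine_scores[j])

    if config.multistart_count > 0:
        best, best_score = _polish_multistart(best, best_score, S, y, config)

    plateau = _collect_plateau(
        [(coarse_grid, coarse_scores), (refine_grid, refine_scores)],
        best_score,
        config.plateau_tolerance,
    )
    boundary = tuple(
        bool(abs(best[k] - lo) < 1e-9 or abs(best[k] - hi) < 1e-9) for k in range(3)
    )
    hsp = HSPVector(*np.round(best, 10))
    ra = ra_distance_many(best, S)
    residuals = _line_residuals(y, ra)
    return EstimationResult(
        hsp=hsp,
        r_squared=abs(best_score),
        slope_sign="negative" if best_score > 0 else "positive",
        boundary_flags=boundary,
        plateau=plateau,
        per_solvent_ra={n: float(r) for n, r in zip(names, ra)},
        residuals={n: float(r) for n, r in zip(names, residuals)},
        solvents_used=tuple(names),
    )


def _polish_multistart(best, best_score, S, y, config: EstimationConfig):
    """Seeded L-BFGS-B restarts; keeps the grid optimum unless strictly better."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds

    def neg(x):
        return -float(_score_candidates(x, S, y))

    starts = [best] + list(rng.uniform(lo, hi, size=(config.multistart_count, 3)))
    x_best, s_best = np.asarray(best, float), best_score
    for x0 in starts:
        res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=[(lo, hi)] * 3)
        if -res.fun > s_best + 1e-12:
            x_best, s_best = np.clip(res.x, lo, hi), -float(res.fun)
    return x_best, s_best


def _collect_plateau(scored_grids, best_score, tol) -> tuple[HSPVector, ...]:
    seen: dict[tuple, HSPVector] = {}
    for grid, scores in scored_grids:
        mask = scores >= best_score - tol
        for point in grid[mask]:
            key = tuple(np.round(point, 10))
            if key not in seen:
                seen[key] = HSPVector(*key)
    return tuple(seen[k] for k in sorted(seen))


def _line_residuals(y: np.ndarray, ra: np.ndarray) -> np.ndarray:
    """Residuals of the OLS line of Ra on % swelling (the reporting axis:
    swelling is the measured predictor, Ra the modelled response)."""
    slope, intercept = np.polyfit(y, ra, 1)
    return ra - (slope * y + intercept)


@dataclass(frozen=True)
class RepetitionEstimate:
    """Per-repetition fits plus their component-wise average.

    Independent repetition experiments are fitted separately and the fitted
    HSPs averaged — repeats of the whole experiment, not pooled replicates.
    ``boundary_flags`` is the component-wise OR across repetitions.
    """

    results: tuple[EstimationResult, ...]
    mean_hsp: HSPVector

    @property
    def boundary_flags(self) -> tuple[bool, bool, bool]:
        return tuple(
            any(r.boundary_flags[k] for r in self.results) for k in range(3)
        )


def estimate_per_repetition(
    datasets: list[SwellingDataset],
    solvents: SolventTable | None = None,
    config: EstimationConfig | None = None,
) -> RepetitionEstimate:
    """Fit each repetition dataset and average the fitted HSP triples."""
    if not datasets:
        raise ValidationError("need at least one repetition dataset")
    results = tuple(estimate_hsp(d, solvents, config) for d in datasets)
    mean = np.mean([r.hsp.as_array() for r in results], axis=0)
    return RepetitionEstimate(results=results, mean_hsp=HSPVector(*mean))


def load_reference_swelling() -> SwellingDataset:
    """The shipped cutin swelling experiment: seven solvents, two independent
    repetitions, water pre-flagged as chemically altering (hydrolysis)."""
    with resources.as_file(
        resources.files("hspscreen.data") / "cutin_swelling.csv"
    ) as p:
        return SwellingDataset.from_csv(p)
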