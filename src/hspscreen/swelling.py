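"""Volumetric swelling observations and replicate summaries.

A cross-linked polymer cannot be dissolved, so affinity for a solvent is
quantified by the degree of swelling after immersion:

    % swelling = 100 * (V_after - V_before) / V_before

Samples cut as rectangular slabs are measured with a caliper before and
after immersion; volumes are the slab products.  Irregular geometries must
be supplied as volumes directly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ValidationError

#: Recognised reasons for excluding a solvent from HSP estimation.
#: ``chemical_alteration`` encodes the case where the solvent reacts with the
#: polymer (hydrolysis, transesterification), so the swollen structure is no
#: longer the same polymer and the observation is not comparable.
EXCLUSION_REASONS = ("chemical_alteration", "user")


def volume_from_dimensions(length: float, width: float, thickness: float) -> float:
    """Volume of a rectangular slab from its caliper dimensions."""
    for name, v in (("length", length), ("width", width), ("thickness", thickness)):
        if not np.isfinite(v) or v <= 0:
            raise ValidationError(f"{name} must be > 0, got {v!r}")
    return length * width * thickness


def percent_swelling(v_before: float, v_after: float) -> float:
    """Volumetric swelling degree in percent.

    Unit-independent: any common rescaling of both volumes cancels.
    """
    if not np.isfinite(v_before) or v_before <= 0:
        raise ValidationError(f"v_before must be > 0, got {v_before!r}")
    if not np.isfinite(v_after) or v_after <= 0:
        raise ValidationError(f"v_after must be > 0, got {v_after!r}")
    return 100.0 * (v_after - v_before) / v_before


@dataclass(frozen=True)
class SwellingObservation:
    """One immersion measurement: a solvent, a replicate id and the outcome.

    Either ``percent`` is given directly, or both volumes are given and the
    percent swelling is derived.
    """

    solvent: str
    replicate: int
    percent: float
    v_before: float | None = None
    v_after: float | None = None

    def __post_init__(self) -> None:
        if not self.solvent:
            raise ValidationError("solvent name must be non-empty")
        if not np.isfinite(self.percent) or self.percent <= -100.0:
            raise ValidationError(
                f"percent swelling must be finite and > -100, got {self.percent!r}"
            )

    @classmethod
    def from_volumes(
        cls, solvent: str, replicate: int, v_before: float, v_after: float
    ) -> "SwellingObservation":
        return cls(
            solvent=solvent,
            replicate=replicate,
            percent=percent_swelling(v_before, v_after),
            v_before=v_before,
            v_after=v_after,
        )


@dataclass(frozen=True)
class SwellingDataset:
    """A set of swelling observations plus solvent exclusion flags.

    ``excluded`` maps solvent name to a reason code from
    :data:`EXCLUSION_REASONS`.  Excluded solvents stay in the dataset (they
    are real measurements, reported in summaries) but are dropped before HSP
    estimation.
    """

    observations: tuple[SwellingObservation, ...]
    excluded: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.observations:
            raise ValidationError("dataset must contain at least one observation")
        seen: set[tuple[str, int]] = set()
        for obs in self.observations:
            key = (obs.solvent, obs.replicate)
            if key in seen:
                raise ValidationError(
                    f"duplicate replicate id {obs.replicate} for solvent {obs.solvent!r}"
                )
            seen.add(key)
        for name, reason in self.excluded.items():
            if reason not in EXCLUSION_REASONS:
                raise ValidationError(
                    f"unknown exclusion reason {reason!r} for {name!r}; "
                    f"expected one of {EXCLUSION_REASONS}"
                )

    # -- views -------------------------------------------------------------

    @property
    def solvents(self) -> tuple[str, ...]:
        out: list[str] = []
        for obs in self.observations:
            if obs.solvent not in out:
                out.append(obs.solvent)
        return tuple(out)

    @property
    def active_solvents(self) -> tuple[str, ...]:
        return tuple(s for s in self.solvents if s not in self.excluded)

    def solvent_means(self, include_excluded: bool = False) -> dict[str, float]:
        """Per-solvent mean percent swelling (excluded solvents dropped
        unless requested)."""
        means: dict[str, float] = {}
        for name in self.solvents:
            if not include_excluded and name in self.excluded:
                continue
            values = [o.percent for o in self.observations if o.solvent == name]
            means[name] = float(np.mean(values))
        return means

    def with_excluded(self, solvents, reason: str = "user") -> "SwellingDataset":
        """Return a copy with additional solvents flagged for exclusion."""
        if isinstance(solvents, str):
            solvents = [solvents]
        unknown = [s for s in solvents if s not in self.solvents]
        if unknown:
            raise ValidationError(f"cannot exclude unknown solvent(s): {unknown}")
        merged = dict(self.excluded)
        merged.update({s: reason for s in solvents})
        return replace(self, excluded=merged)

    def split_replicates(self) -> list["SwellingDataset"]:
        """Split into one dataset per replicate id, preserving exclusions.

        Independent repetition experiments are fitted separately and their
        fitted HSPs averaged, so estimation consumes one dataset per
        repetition.
        """
        ids = sorted({o.replicate for o in self.observations})
        out = []
        for rid in ids:
            obs = tuple(o for o in self.observations if o.replicate == rid)
            excl = {s: r for s, r in self.excluded.items() if any(o.solvent == s for o in obs)}
            out.append(SwellingDataset(observations=obs, excluded=excl))
        return out

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path | io.IOBase) -> "SwellingDataset":
        """Read a swelling CSV.

        Required columns: ``solvent``, ``replicate`` and either
        ``percent_swelling`` or both ``v_before`` and ``v_after``.  An
        optional ``exclude`` column carries a reason code on any row of a
        solvent to flag it.
        """
        df = pd.read_csv(path, comment="#", skipinitialspace=True)
        df.columns = [c.strip() for c in df.columns]
        for col in ("solvent", "replicate"):
            if col not in df.columns:
                raise ValidationError(f"swelling CSV is missing column {col!r}")
        has_pct = "percent_swelling" in df.columns
        has_vol = "v_before" in df.columns and "v_after" in df.columns
        if not (has_pct or has_vol):
            raise ValidationError(
                "swelling CSV needs either a percent_swelling column or "
                "both v_before and v_after"
            )
        observations = []
        excluded: dict[str, str] = {}
        for idx, row in df.iterrows():
            solvent = str(row["solvent"]).strip()
            try:
                replicate = int(row["replicate"])
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"row {idx}: non-integer replicate id") from exc
            try:
                if has_pct and not pd.isna(row["percent_swelling"]):
                    obs = SwellingObservation(
                        solvent=solvent,
                        replicate=replicate,
                        percent=float(row["percent_swelling"]),
                    )
                elif has_vol:
                    obs = SwellingObservation.from_volumes(
                        solvent, replicate, float(row["v_before"]), float(row["v_after"])
                    )
                else:
                    raise ValidationError("no swelling value")
            except ValidationError as exc:
                raise ValidationError(f"row {idx} ({solvent!r}): {exc}") from exc
            observations.append(obs)
            if "exclude" in df.columns and isinstance(row["exclude"], str):
                reason = row["exclude"].strip()
                if reason:
                    excluded[solvent] = reason
        return cls(observations=tuple(observations), excluded=excluded)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "solvent": o.solvent,
                "replicate": o.replicate,
                "percent_swelling": o.percent,
                "exclude": self.excluded.get(o.solvent, ""),
            }
            for o in self.observations
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def summarize_replicates(dataset: SwellingDataset) -> pd.DataFrame:
    """Per-solvent mean and sample (n-1) standard deviation of % swelling.

    Returns a DataFrame indexed by solvent with columns ``n``, ``mean`` and
    ``sd``; ``sd`` is NaN for a single replicate (no spread is estimable).
    Excluded solvents are summarized too — exclusion governs estimation, not
    reporting.
    """
    if not dataset.observations:
        raise DegenerateDataError("empty swelling dataset")
    rows = {}
    for name in dataset.solvents:
        values = np.array(
            [o.percent for o in dataset.observations if o.solvent == name], dtype=float
        )
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else np.nan
        rows[name] = {"n": len(values), "mean": float(values.mean()), "sd": sd}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "solvent"
    df["n"] = df["n"].astype(int)
    return df


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as tabulated values conventionally are
    (banker's rounding would turn 5.65 into 5.6, not 5.7)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def format_mean_sd(mean: float, sd: float, ndigits: int = 1) -> str:
    """Display helper: ``mean ± sd`` at fixed decimals, ``mean`` alone if the
    sd is unavailable. Full precision is always retained internally."""
    m = round_half_up(mean, ndigits)
    m_txt = f"{m:g}"
    if sd is None or np.isnan(sd):
        return m_txt
    return f"{m_txt} ± {round_half_up(sd, ndigits):g}"
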