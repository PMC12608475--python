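"""Food-component HSP databases and polymer reference records.

Two granularities are first-class:

* component level — individual substances with a group label, enabling the
  mean-of-Ra computation (distance per substance, then averaged per group);
* summary level — group mean ± sd HSP triples, the granularity typically
  published, enabling Ra-of-mean screening with propagated uncertainty.

Screening reports always state which granularity they used, because the two
differ by a Jensen gap: the mean of distances is at least the distance to
the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import HSPVector, RoSpec
from .errors import MissingValueError, ValidationError

#: Conventional report ordering of the six food-component groups.
CANONICAL_GROUP_ORDER = (
    "carbohydrates",
    "fats",
    "amino_acids",
    "vitamins",
    "polar_essential_oil",
    "nonpolar_essential_oil",
)


@dataclass(frozen=True)
class ComponentRecord:
    """One food component: a name, a group label and an HSP triple."""

    name: str
    group: str
    hsp: HSPVector

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("component name must be non-empty")
        if not self.group:
            raise ValidationError(f"component {self.name!r}: group label must be non-empty")


@dataclass(frozen=True)
class GroupSummary:
    """Group-level HSP statistics, optionally with a mean Ra to a polymer."""

    group: str
    n: int | None
    mean_hsp: HSPVector
    sd_hsp: tuple[float, float, float] | None = None
    mean_ra: float | None = None
    sd_ra: float | None = None

    def __post_init__(self) -> None:
        if not self.group:
            raise ValidationError("group label must be non-empty")
        if self.n is not None and self.n < 1:
            raise ValidationError(f"group {self.group!r}: n must be >= 1")
        if self.sd_hsp is not None and any(s < 0 or not math.isfinite(s) for s in self.sd_hsp):
            raise ValidationError(f"group {self.group!r}: sds must be finite and >= 0")
        for label, v in (("mean_ra", self.mean_ra), ("sd_ra", self.sd_ra)):
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValidationError(f"group {self.group!r}: {label} must be >= 0")


@dataclass(frozen=True)
class PolymerRecord:
    """A polymer with its HSP and (optionally) an interaction-radius rule.

    ``hsp`` may be None for a shipped placeholder entry; using such a record
    raises a clear error telling the user to supply values.
    """

    name: str
    hsp: HSPVector | None
    ro: RoSpec | None = None
    source: str = ""

    def require_hsp(self) -> HSPVector:
        if self.hsp is None:
            raise MissingValueError(
                f"polymer {self.name!r} is a placeholder without HSP values; "
                "supply delta_d, delta_p, delta_hb (and Ro) for it"
            )
        return self.hsp

    def require_ro(self) -> RoSpec:
        if self.ro is None:
            raise MissingValueError(
                f"polymer {self.name!r} has no interaction radius: supply a "
                "numeric Ro or a reference solvent"
            )
        return self.ro


# ---------------------------------------------------------------------------
# component-level databases


def load_components(path: str | Path) -> list[ComponentRecord]:
    """Read a component-level CSV (columns name, group, delta_d, delta_p,
    delta_hb).  Duplicate names within a group are rejected."""
    df = pd.read_csv(path, comment="#", skipinitialspace=True)
    required = {"name", "group", "delta_d", "delta_p", "delta_hb"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"component CSV is missing columns {sorted(missing)}")
    if df.empty:
        raise ValidationError("component CSV contains no rows")
    records: list[ComponentRecord] = []
    seen: set[tuple[str, str]] = set()
    for idx, row in df.iterrows():
        name = str(row["name"]).strip()
        group = str(row["group"]).strip()
        key = (group, name)
        if key in seen:
            raise ValidationError(f"row {idx}: duplicate component {name!r} in group {group!r}")
        seen.add(key)
        try:
            hsp = HSPVector(
                float(row["delta_d"]), float(row["delta_p"]), float(row["delta_hb"])
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"row {idx} ({name!r}): {exc}") from exc
        records.append(ComponentRecord(name=name, group=group, hsp=hsp))
    return records


def write_components(records: list[ComponentRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "name": r.name,
                "group": r.group,
                "delta_d": r.hsp.delta_d,
                "delta_p": r.hsp.delta_p,
                "delta_hb": r.hsp.delta_hb,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def summarize_groups(
    components: list[ComponentRecord],
    single_component_sd: str = "absent",
) -> list[GroupSummary]:
    """Component-wise mean and sample (n-1) sd of HSP triples per group.

    ``single_component_sd`` controls the degenerate n=1 case: ``"absent"``
    reports no sd, ``"zero"`` reports (0, 0, 0).
    """
    if not components:
        raise ValidationError("cannot summarize an empty component list")
    if single_component_sd not in ("absent", "zero"):
        raise ValidationError(f"unknown single_component_sd {single_component_sd!r}")
    groups: dict[str, list[ComponentRecord]] = {}
    for rec in components:
        groups.setdefault(rec.group, []).append(rec)
    out = []
    for group in sort_groups(groups):
        hsps = np.array([tuple(r.hsp) for r in groups[group]], dtype=float)
        n = len(hsps)
        mean = HSPVector(*hsps.mean(axis=0))
        if n > 1:
            sd = tuple(np.std(hsps, axis=0, ddof=1))
        else:
            sd = (0.0, 0.0, 0.0) if single_component_sd == "zero" else None
        out.append(GroupSummary(group=group, n=n, mean_hsp=mean, sd_hsp=sd))
    return out


def sort_groups(names) -> list[str]:
    """Canonical six-group order first, unknown groups alphabetically after."""
    known = [g for g in CANONICAL_GROUP_ORDER if g in names]
    extra = sorted(set(names) - set(CANONICAL_GROUP_ORDER))
    return known + extra


# ---------------------------------------------------------------------------
# summary-level databases


def load_group_summaries(path: str | Path) -> list[GroupSummary]:
    """Read a summary-level CSV (columns group, n, mean_d, sd_d, mean_p,
    sd_p, mean_hb, sd_hb; optional mean_ra, sd_ra)."""
    df = pd.read_csv(path, comment="#", skipinitialspace=True)
    required = {"group", "mean_d", "mean_p", "mean_hb"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"group-summary CSV is missing columns {sorted(missing)}")
    if df.empty:
        raise ValidationError("group-summary CSV contains no rows")
    out = []
    for idx, row in df.iterrows():
        group = str(row["group"]).strip()

        def _opt(col, row=row):
            if col in row.index and not pd.isna(row[col]):
                return float(row[col])
            return None

        try:
            mean = HSPVector(float(row["mean_d"]), float(row["mean_p"]), float(row["mean_hb"]))
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"row {idx} ({group!r}): {exc}") from exc
        sds = (_opt("sd_d"), _opt("sd_p"), _opt("sd_hb"))
        sd_hsp = tuple(float(s) for s in sds) if all(s is not None for s in sds) else None
        n = _opt("n")
        out.append(
            GroupSummary(
                group=group,
                n=int(n) if n is not None else None,
                mean_hsp=mean,
                sd_hsp=sd_hsp,
                mean_ra=_opt("mean_ra"),
                sd_ra=_opt("sd_ra"),
            )
        )
    return out


def load_reference_group_summaries() -> list[GroupSummary]:
    """The shipped six food-component groups (47 substances: carbohydrates,
    fats and lipids, amino acids, vitamins, polar and non-polar essential-oil
    components) with published mean ± sd HSPs and their mean Ra to cutin."""
    with resources.as_file(
        resources.files("hspscreen.data") / "food_group_summaries.csv"
    ) as p:
        return load_group_summaries(p)


def load_example_components() -> list[ComponentRecord]:
    """Shipped synthetic component-level example database (illustrative
    values, not measured substances)."""
    with resources.as_file(
        resources.files("hspscreen.data") / "example_components_synthetic.csv"
    ) as p:
        return load_components(p)


# ---------------------------------------------------------------------------
# polymers


def load_polymers(path: str | Path) -> list[PolymerRecord]:
    """Read a polymer CSV (columns name, delta_d, delta_p, delta_hb and
    optionally ro [numeric] or ro_solvent [reference name], source).

    Rows with all three HSP cells blank load as placeholders that error with
    instructions when used.
    """
    df = pd.read_csv(path, comment="#", skipinitialspace=True)
    if "name" not in df.columns:
        raise ValidationError("polymer CSV is missing a 'name' column")
    out = []
    for idx, row in df.iterrows():
        name = str(row["name"]).strip()
        cells = [row.get(c) for c in ("delta_d", "delta_p", "delta_hb")]
        if all(pd.isna(c) for c in cells):
            hsp = None
        else:
            try:
                hsp = HSPVector(*(float(c) for c in cells))
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"row {idx} ({name!r}): {exc}") from exc
        ro: RoSpec | None = None
        if "ro" in df.columns and not pd.isna(row["ro"]):
            ro = RoSpec.numeric(float(row["ro"]))
        elif "ro_solvent" in df.columns and isinstance(row.get("ro_solvent"), str) and row["ro_solvent"].strip():
            ro = RoSpec.from_solvent(row["ro_solvent"].strip())
        source = str(row.get("source", "") or "")
        out.append(PolymerRecord(name=name, hsp=hsp, ro=ro, source=source))
    return out


def load_reference_polymers() -> list[PolymerRecord]:
    """Shipped polymer records: cutin (swelling-estimated HSP, Ro = distance
    to hexane), PLA (literature HSP, Ro user-supplied) and a PHB placeholder."""
    with resources.as_file(resources.files("hspscreen.data") / "polymers.csv") as p:
        return load_polymers(p)
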