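"""Serialization and text rendering of screening reports.

JSON round-trips losslessly; markdown renders a groups × (Ra, RED, verdict)
table for humans.  The schema carries a version so downstream consumers can
detect layout changes.
"""

from __future__ import annotations

import json

from .components import PolymerRecord
from .core import HSPVector, RoSpec, Verdict
from .errors import ValidationError
from .screening import ComparisonReport, ScreeningReport, ScreeningRow

SCHEMA_VERSION = 1

_VERDICT_WORDING = {
    Verdict.COMPATIBLE: "high affinity",
    Verdict.INCOMPATIBLE: "poor compatibility",
    Verdict.BORDERLINE: "borderline",
}


def report_to_dict(report: ScreeningReport) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "polymer": {
            "name": report.polymer.name,
            "hsp": list(report.polymer.hsp) if report.polymer.hsp else None,
            "source": report.polymer.source,
        },
        "ro_value": report.ro_value,
        "mode": report.mode,
        "provenance": report.provenance,
        "rows": [
            {
                "group": r.group,
                "n": r.n,
                "mean_ra": r.mean_ra,
                "sd_ra": r.sd_ra,
                "red": r.red,
                "sd_red": r.sd_red,
                "verdict": r.verdict.value,
            }
            for r in report.rows
        ],
    }


def report_from_dict(data: dict) -> ScreeningReport:
    if data.get("schema_version") != SCHEMA_VERSION:
        raise ValidationError(
            f"unsupported report schema version {data.get('schema_version')!r}"
        )
    poly = data["polymer"]
    polymer = PolymerRecord(
        name=poly["name"],
        hsp=HSPVector(*poly["hsp"]) if poly.get("hsp") else None,
        ro=RoSpec.numeric(data["ro_value"]),
        source=poly.get("source", ""),
    )
    rows = tuple(
        ScreeningRow(
            group=r["group"],
            n=r["n"],
            mean_ra=r["mean_ra"],
            sd_ra=r["sd_ra"],
            red=r["red"],
            sd_red=r["sd_red"],
            verdict=Verdict(r["verdict"]),
        )
        for r in data["rows"]
    )
    return ScreeningReport(
        polymer=polymer,
        ro_value=data["ro_value"],
        mode=data["mode"],
        rows=rows,
        provenance=data.get("provenance", {}),
    )


def report_to_json(report: ScreeningReport, indent: int = 2) -> str:
    return json.dumps(report_to_dict(report), indent=indent)


def report_from_json(text: str) -> ScreeningReport:
    return report_from_dict(json.loads(text))


def _markdown_table(header: list[str], rows: list[list[str]]) -> str:
    widths = [max(len(h), *(len(r[i]) for r in rows)) if rows else len(h)
              for i, h in enumerate(header)]
    def fmt(cells):
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
    lines = [fmt(header), "|" + "|".join("-" * (w + 2) for w in widths) + "|"]
    lines += [fmt(r) for r in rows]
    return "\n".join(lines)


def _pm(value: float | None, sd: float | None, ndigits: int = 2) -> str:
    if value is None:
        return "-"
    if sd is None:
        return f"{value:.{ndigits}f}"
    return f"{value:.{ndigits}f} ± {sd:.{ndigits}f}"


def render_report(report: ScreeningReport, fmt: str = "markdown") -> str:
    """Render a screening report as ``markdown`` or ``json`` text."""
    if fmt == "json":
        return report_to_json(report)
    if fmt != "markdown":
        raise ValidationError(f"unknown report format {fmt!r}")
    band = report.provenance.get("borderline_band")
    rows = [
        [
            r.group,
            _pm(r.mean_ra, r.sd_ra),
            _pm(r.red, r.sd_red),
            _VERDICT_WORDING[r.verdict],
        ]
        for r in report.rows
    ]
    header = ["group", "Ra (MPa^1/2)", "RED", "verdict"]
    lines = [
        f"## Compatibility screen: {report.polymer.name}",
        "",
        f"Ro = {report.ro_value:.2f} MPa^1/2, mode = {report.mode}"
        + (f", borderline band = ±{band:g} around RED = 1" if band is not None else ""),
        "",
        _markdown_table(header, rows),
    ]
    return "\n".join(lines)


def render_comparison(comparison: ComparisonReport, fmt: str = "markdown") -> str:
    """Render a multi-polymer comparison (groups × polymers RED table plus
    the per-group lowest-RED ranking)."""
    if fmt == "json":
        return json.dumps(
            {
                "schema_version": SCHEMA_VERSION,
                "reports": [report_to_dict(r) for r in comparison.reports],
                "ranking": comparison.ranking,
            },
            indent=2,
        )
    if fmt != "markdown":
        raise ValidationError(f"unknown report format {fmt!r}")
    names = [rep.polymer.name for rep in comparison.reports]
    groups = [r.group for r in comparison.reports[0].rows]
    rows = []
    for g in groups:
        cells = [g]
        for rep in comparison.reports:
            r = rep.row(g)
            cells.append(_pm(r.red, r.sd_red))
        cells.append(comparison.ranking[g])
        rows.append(cells)
    header = ["group"] + [f"RED {n}" for n in names] + ["lowest RED"]
    return "\n".join(
        [
            "## Polymer comparison (RED per food-component group)",
            "",
            _markdown_table(header, rows),
        ]
    )
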