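"""Config readers/writers and report rendering.

The canonical on-disk form of a strategy is a hierarchical YAML/JSON
document (schema v1, see ``docs/config_schema.md``); flat per-table CSVs
are accepted as an alternative import path.  Stored numbers are always
unformatted integers or decimal strings; thousands separators exist only in
rendered plain-text tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Any, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import yaml

from .comparator import ComparisonReport, DialysisArm
from .core import (
    AdverseEventProfile,
    CohortSpec,
    CostReport,
    CurrencyRate,
    GlobalTariff,
    RegimenLine,
    StrategyDefinition,
    TreatmentItem,
)
from .money import ValidationError, as_rational
from .montecarlo import SimulationResult

__all__ = [
    "SchemaError",
    "read_strategy",
    "write_strategy",
    "read_dialysis_arm",
    "read_rate",
    "strategy_from_dict",
    "strategy_to_dict",
    "strategy_from_csv_dir",
    "RenderedReport",
    "TableBlock",
    "render_report",
]

SCHEMA_VERSION = 1


class SchemaError(ValidationError):
    """A config document violates the schema; the message carries the location."""


# ---------------------------------------------------------------------------
# Parsing helpers
# ---------------------------------------------------------------------------

def _require_mapping(node: Any, path: str) -> Mapping[str, Any]:
    if not isinstance(node, Mapping):
        raise SchemaError(f"{path}: expected a mapping, got {type(node).__name__}")
    return node


def _check_fields(node: Mapping[str, Any], allowed: set, required: set, path: str) -> None:
    unknown = set(node) - allowed
    if unknown:
        raise SchemaError(f"{path}: unknown field(s) {sorted(unknown)}")
    missing = required - set(node)
    if missing:
        raise SchemaError(f"{path}: missing required field(s) {sorted(missing)}")


def _as_int(value: Any, path: str) -> int:
    if isinstance(value, bool) or not isinstance(value, (int, str)):
        raise SchemaError(f"{path}: expected an integer, got {value!r}")
    try:
        return int(value)
    except ValueError:
        raise SchemaError(f"{path}: expected an integer, got {value!r}") from None


def _as_fraction(value: Any, path: str) -> Fraction:
    try:
        return as_rational(value)
    except (ValueError, TypeError):
        raise SchemaError(f"{path}: expected a number, got {value!r}") from None


def _parse_regimen_line(node: Any, path: str) -> RegimenLine:
    node = _require_mapping(node, path)
    allowed = {
        "drug_name", "dosage_form", "units_per_day", "unit_price",
        "n_eligible", "duration_days", "cohort_daily_cost_override",
    }
    _check_fields(node, allowed, {"drug_name"}, path)
    override = node.get("cohort_daily_cost_override")
    try:
        return RegimenLine(
            drug_name=str(node["drug_name"]),
            dosage_form=str(node.get("dosage_form", "")),
            units_per_day=_as_fraction(node.get("units_per_day", 0), f"{path}.units_per_day"),
            unit_price=_as_int(node.get("unit_price", 0), f"{path}.unit_price"),
            n_eligible=_as_int(node.get("n_eligible", 0), f"{path}.n_eligible"),
            duration_days=_as_int(node.get("duration_days", 365), f"{path}.duration_days"),
            cohort_daily_cost_override=(
                None if override is None else _as_int(override, f"{path}.cohort_daily_cost_override")
            ),
        )
    except SchemaError:
        raise
    except ValidationError as exc:
        raise SchemaError(f"{path}: {exc}") from None


def _parse_item(node: Any, path: str) -> TreatmentItem:
    node = _require_mapping(node, path)
    allowed = {"kind", "label", "units_per_day", "unit_price", "duration"}
    _check_fields(node, allowed, {"kind", "label", "unit_price"}, path)
    try:
        return TreatmentItem(
            kind=str(node["kind"]),
            label=str(node["label"]),
            unit_price=_as_int(node["unit_price"], f"{path}.unit_price"),
            duration=_as_fraction(node.get("duration", 0), f"{path}.duration"),
            units_per_day=_as_fraction(node.get("units_per_day", 0), f"{path}.units_per_day"),
        )
    except SchemaError:
        raise
    except ValidationError as exc:
        raise SchemaError(f"{path}: {exc}") from None


def _parse_event(node: Any, path: str) -> AdverseEventProfile:
    node = _require_mapping(node, path)
    _check_fields(node, {"name", "probability", "items"}, {"name", "probability"}, path)
    items = node.get("items", [])
    if not isinstance(items, Sequence) or isinstance(items, (str, bytes)):
        raise SchemaError(f"{path}.items: expected a list")
    try:
        return AdverseEventProfile(
            name=str(node["name"]),
            probability=_as_fraction(node["probability"], f"{path}.probability"),
            items=tuple(_parse_item(it, f"{path}.items[{i}]") for i, it in enumerate(items)),
        )
    except SchemaError:
        raise
    except ValidationError as exc:
        raise SchemaError(f"{path}: {exc}") from None


def _parse_cohort(node: Any, path: str) -> CohortSpec:
    node = _require_mapping(node, path)
    _check_fields(node, {"n_patients", "horizon_days", "patient_weight_kg"}, {"n_patients"}, path)
    try:
        return CohortSpec(
            n_patients=_as_int(node["n_patients"], f"{path}.n_patients"),
            horizon_days=_as_int(node.get("horizon_days", 365), f"{path}.horizon_days"),
            patient_weight_kg=_as_fraction(node.get("patient_weight_kg", 70), f"{path}.patient_weight_kg"),
        )
    except SchemaError:
        raise
    except ValidationError as exc:
        raise SchemaError(f"{path}: {exc}") from None


_TOP_LEVEL_FIELDS = {
    "schema_version", "name", "currency_rate_irr_per_usd", "cohort",
    "hospitalization", "maintenance_lines", "adverse_events", "misc_lines",
    "dialysis",
}


def strategy_from_dict(doc: Mapping[str, Any]) -> StrategyDefinition:
    """Build a validated strategy from a parsed config document."""
    doc = _require_mapping(doc, "$")
    _check_fields(doc, _TOP_LEVEL_FIELDS, {"name", "cohort"}, "$")
    version = doc.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise SchemaError(f"$.schema_version: unsupported version {version!r}")
    cohort = _parse_cohort(doc["cohort"], "$.cohort")

    hospitalization = None
    if doc.get("hospitalization") is not None:
        node = _require_mapping(doc["hospitalization"], "$.hospitalization")
        _check_fields(node, {"k_value", "multiplier"}, {"k_value", "multiplier"}, "$.hospitalization")
        try:
            hospitalization = GlobalTariff(
                k_value=_as_int(node["k_value"], "$.hospitalization.k_value"),
                multiplier=_as_int(node["multiplier"], "$.hospitalization.multiplier"),
            )
        except SchemaError:
            raise
        except ValidationError as exc:
            raise SchemaError(f"$.hospitalization: {exc}") from None

    def lines(key: str) -> Tuple[RegimenLine, ...]:
        raw = doc.get(key, [])
        if not isinstance(raw, Sequence) or isinstance(raw, (str, bytes)):
            raise SchemaError(f"$.{key}: expected a list")
        return tuple(_parse_regimen_line(n, f"$.{key}[{i}]") for i, n in enumerate(raw))

    raw_events = doc.get("adverse_events", [])
    if not isinstance(raw_events, Sequence) or isinstance(raw_events, (str, bytes)):
        raise SchemaError("$.adverse_events: expected a list")
    events = tuple(_parse_event(n, f"$.adverse_events[{i}]") for i, n in enumerate(raw_events))

    return StrategyDefinition(
        name=str(doc["name"]),
        cohort=cohort,
        hospitalization=hospitalization,
        maintenance_lines=lines("maintenance_lines"),
        adverse_events=events,
        misc_lines=lines("misc_lines"),
    )


def _load_document(path: Union[str, Path], fmt: Optional[str] = None) -> Mapping[str, Any]:
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "yaml"
    text = path.read_text()
    doc = json.loads(text) if fmt == "json" else yaml.safe_load(text)
    return _require_mapping(doc, "$")


def read_strategy(path: Union[str, Path], fmt: Optional[str] = None) -> StrategyDefinition:
    """Read and validate a strategy config (YAML by default, JSON by extension)."""
    return strategy_from_dict(_load_document(path, fmt))


def read_rate(path: Union[str, Path], default: int = 12260) -> CurrencyRate:
    """The currency rate declared in a config file, or the study-year default."""
    doc = _load_document(path)
    return CurrencyRate(as_rational(doc.get("currency_rate_irr_per_usd", default)))


def read_dialysis_arm(path: Union[str, Path]) -> DialysisArm:
    """Read the optional hemodialysis comparator block of a config file."""
    doc = _load_document(path)
    if doc.get("dialysis") is None:
        raise SchemaError("$.dialysis: no dialysis comparator block in this config")
    node = _require_mapping(doc["dialysis"], "$.dialysis")
    allowed = {"session_tariff", "sessions_per_year", "adjunct_annual_per_patient", "name"}
    _check_fields(node, allowed, {"session_tariff"}, "$.dialysis")
    cohort = _parse_cohort(_require_mapping(doc, "$")["cohort"], "$.cohort")
    try:
        return DialysisArm(
            session_tariff=_as_int(node["session_tariff"], "$.dialysis.session_tariff"),
            sessions_per_year=_as_int(node.get("sessions_per_year", 156), "$.dialysis.sessions_per_year"),
            adjunct_annual_per_patient=_as_int(
                node.get("adjunct_annual_per_patient", 0), "$.dialysis.adjunct_annual_per_patient"
            ),
            name=str(node.get("name", "hemodialysis")),
            cohort=cohort,
        )
    except SchemaError:
        raise
    except ValidationError as exc:
        raise SchemaError(f"$.dialysis: {exc}") from None


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _format_rational(x: Fraction) -> Union[int, str]:
    """Integers stay integers; other rationals become exact strings.

    Decimal notation is used when the denominator divides a power of ten
    (0.21 stays "0.21"); otherwise the a/b form is written.  Both parse
    back exactly.
    """
    if x.denominator == 1:
        return int(x)
    d = x.denominator
    for p in (2, 5):
        while d % p == 0:
            d //= p
    if d == 1:
        # terminating decimal
        sign = "-" if x < 0 else ""
        exp = 0
        scaled = abs(x)
        while scaled.denominator != 1:
            scaled *= 10
            exp += 1
        digits = str(scaled.numerator).rjust(exp + 1, "0")
        return f"{sign}{digits[:-exp]}.{digits[-exp:]}"
    return f"{x.numerator}/{x.denominator}"


def _line_to_dict(line: RegimenLine) -> Dict[str, Any]:
    out: Dict[str, Any] = {
        "drug_name": line.drug_name,
        "dosage_form": line.dosage_form,
        "units_per_day": _format_rational(line.units_per_day),
        "unit_price": line.unit_price,
        "n_eligible": line.n_eligible,
        "duration_days": line.duration_days,
    }
    if line.cohort_daily_cost_override is not None:
        out["cohort_daily_cost_override"] = line.cohort_daily_cost_override
    return out


def strategy_to_dict(strategy: StrategyDefinition) -> Dict[str, Any]:
    doc: Dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "name": strategy.name,
        "cohort": {
            "n_patients": strategy.cohort.n_patients,
            "horizon_days": strategy.cohort.horizon_days,
            "patient_weight_kg": _format_rational(strategy.cohort.patient_weight_kg),
        },
    }
    if strategy.hospitalization is not None:
        doc["hospitalization"] = {
            "k_value": strategy.hospitalization.k_value,
            "multiplier": strategy.hospitalization.multiplier,
        }
    doc["maintenance_lines"] = [_line_to_dict(line) for line in strategy.maintenance_lines]
    doc["adverse_events"] = [
        {
            "name": ae.name,
            "probability": _format_rational(ae.probability),
            "items": [
                {
                    "kind": it.kind,
                    "label": it.label,
                    "units_per_day": _format_rational(it.units_per_day),
                    "unit_price": it.unit_price,
                    "duration": _format_rational(it.duration),
                }
                for it in ae.items
            ],
        }
        for ae in strategy.adverse_events
    ]
    doc["misc_lines"] = [_line_to_dict(line) for line in strategy.misc_lines]
    return doc


def write_strategy(
    strategy: StrategyDefinition,
    path: Union[str, Path],
    fmt: Optional[str] = None,
    rate: Optional[CurrencyRate] = None,
    dialysis: Optional[DialysisArm] = None,
) -> None:
    """Write a strategy (plus optional rate and comparator blocks) to disk."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "yaml"
    doc = strategy_to_dict(strategy)
    if rate is not None:
        doc["currency_rate_irr_per_usd"] = _format_rational(rate.irr_per_usd)
    if dialysis is not None:
        doc["dialysis"] = {
            "session_tariff": dialysis.session_tariff,
            "sessions_per_year": dialysis.sessions_per_year,
            "adjunct_annual_per_patient": dialysis.adjunct_annual_per_patient,
            "name": dialysis.name,
        }
    if fmt == "json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False, allow_unicode=True))


# ---------------------------------------------------------------------------
# CSV import
# ---------------------------------------------------------------------------

def strategy_from_csv_dir(directory: Union[str, Path]) -> StrategyDefinition:
    """Assemble a strategy from flat per-table CSVs.

    Expects ``strategy.csv`` (key,value pairs: name, n_patients,
    horizon_days, k_value, multiplier), ``maintenance.csv`` and ``misc.csv``
    (regimen-line columns), ``adverse_events.csv`` (name, probability) and
    ``ae_items.csv`` (event plus treatment-item columns).  Values are read
    as text and parsed exactly.
    """
    import pandas as pd

    directory = Path(directory)

    def read(name: str, required: bool = True) -> Optional["pd.DataFrame"]:
        f = directory / name
        if not f.exists():
            if required:
                raise SchemaError(f"{f}: missing table")
            return None
        return pd.read_csv(f, dtype=str).fillna("")

    meta_df = read("strategy.csv")
    meta = dict(zip(meta_df["key"], meta_df["value"]))
    cohort = CohortSpec(
        n_patients=_as_int(meta.get("n_patients", ""), "strategy.csv:n_patients"),
        horizon_days=_as_int(meta.get("horizon_days", 365), "strategy.csv:horizon_days"),
    )
    hospitalization = None
    if "k_value" in meta:
        hospitalization = GlobalTariff(
            k_value=_as_int(meta["k_value"], "strategy.csv:k_value"),
            multiplier=_as_int(meta.get("multiplier", 1), "strategy.csv:multiplier"),
        )

    def lines_from(df: Optional["pd.DataFrame"], where: str) -> Tuple[RegimenLine, ...]:
        if df is None or df.empty:
            return ()
        out = []
        for i, row in df.iterrows():
            node = {k: v for k, v in row.items() if v != ""}
            out.append(_parse_regimen_line(node, f"{where}[{i}]"))
        return tuple(out)

    events_df = read("adverse_events.csv", required=False)
    items_df = read("ae_items.csv", required=False)
    events: List[AdverseEventProfile] = []
    if events_df is not None:
        for i, row in events_df.iterrows():
            name = row["name"]
            items: Tuple[TreatmentItem, ...] = ()
            if items_df is not None:
                sub = items_df[items_df["event"] == name]
                items = tuple(
                    _parse_item(
                        {k: v for k, v in r.items() if k != "event" and v != ""},
                        f"ae_items.csv[{j}]",
                    )
                    for j, r in sub.iterrows()
                )
            events.append(
                AdverseEventProfile(
                    name=name,
                    probability=_as_fraction(row["probability"], f"adverse_events.csv[{i}].probability"),
                    items=items,
                )
            )

    return StrategyDefinition(
        name=str(meta.get("name", directory.name)),
        cohort=cohort,
        hospitalization=hospitalization,
        maintenance_lines=lines_from(read("maintenance.csv", required=False), "maintenance.csv"),
        adverse_events=tuple(events),
        misc_lines=lines_from(read("misc.csv", required=False), "misc.csv"),
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TableBlock:
    title: str
    header: Tuple[str, ...]
    rows: Tuple[Tuple[Any, ...], ...]


@dataclass(frozen=True)
class RenderedReport:
    blocks: Tuple[TableBlock, ...]
    format: str
    json_obj: Dict[str, Any]

    def to_text(self) -> str:
        if self.format == "json":
            return json.dumps(self.json_obj, indent=2)
        sep = self.format == "tsv"
        out: List[str] = []
        for block in self.blocks:
            cells = [list(block.header)] + [
                [self._fmt(c, raw=sep) for c in row] for row in block.rows
            ]
            if sep:
                out.append(block.title)
                out.extend("\t".join(str(c) for c in row) for row in cells)
            else:
                widths = [max(len(str(r[i])) for r in cells) for i in range(len(block.header))]
                out.append(block.title)
                out.append("  ".join(str(c).ljust(w) for c, w in zip(cells[0], widths)).rstrip())
                out.append("  ".join("-" * w for w in widths))
                for row in cells[1:]:
                    out.append(
                        "  ".join(
                            str(c).ljust(w) if i == 0 else str(c).rjust(w)
                            for i, (c, w) in enumerate(zip(row, widths))
                        ).rstrip()
                    )
            out.append("")
        return "\n".join(out).rstrip() + "\n"

    @staticmethod
    def _fmt(cell: Any, raw: bool) -> str:
        if isinstance(cell, bool):
            return str(cell)
        if isinstance(cell, int) and not raw:
            return f"{cell:,}"
        if isinstance(cell, float):
            return f"{cell:,.2f}" if not raw else repr(cell)
        return str(cell)


_COMPONENT_LABELS = {
    "hospitalization": "Initial hospitalization for transplantation",
    "maintenance": "Immunosuppressive agents",
    "adverse_events": "Treatment of adverse events",
    "miscellaneous": "Miscellaneous medicines",
    "dialysis": "Dialysis",
    "adjunct_treatment": "Adjunct treatment",
}


def _cost_report_blocks(r: CostReport) -> Tuple[TableBlock, ...]:
    rows = [
        (_COMPONENT_LABELS.get(k, k), v, r.component_totals_usd[k])
        for k, v in r.component_totals_irr.items()
    ]
    rows.append(("Total costs", r.total_irr, r.total_usd))
    rows.append(("Total cost per patient", r.per_patient_irr, r.per_patient_usd))
    blocks = [
        TableBlock(
            title=f"Cost summary — {r.strategy_name} (n = {r.n_patients:,})",
            header=("Component", "IRR", "USD"),
            rows=tuple(rows),
        )
    ]
    if r.per_event_breakdown:
        ae_rows = [
            (
                name,
                _format_rational(b.expected_per_patient / b.unit_cost_per_patient)
                if b.unit_cost_per_patient
                else 0,
                b.unit_cost_per_patient,
                b.expected_display,
                b.cohort_total,
            )
            for name, b in r.per_event_breakdown.items()
        ]
        ae_rows.append(
            (
                "Total",
                "",
                sum(b.unit_cost_per_patient for b in r.per_event_breakdown.values()),
                sum(b.expected_display for b in r.per_event_breakdown.values()),
                sum(b.cohort_total for b in r.per_event_breakdown.values()),
            )
        )
        blocks.append(
            TableBlock(
                title="Adverse events",
                header=("Event", "Probability", "Unit cost/patient (IRR)",
                        "Expected/patient (IRR)", "Cohort total (IRR)"),
                rows=tuple(ae_rows),
            )
        )
    return tuple(blocks)


def _cost_report_json(r: CostReport) -> Dict[str, Any]:
    return {
        "strategy": r.strategy_name,
        "n_patients": r.n_patients,
        "irr_per_usd": _format_rational(r.rate.irr_per_usd),
        "component_totals_irr": dict(r.component_totals_irr),
        "component_totals_usd": dict(r.component_totals_usd),
        "total_irr": r.total_irr,
        "total_usd": r.total_usd,
        "per_patient_irr": r.per_patient_irr,
        "per_patient_usd": r.per_patient_usd,
        "component_shares": r.component_shares,
        "adverse_events": {
            name: {
                "unit_cost_per_patient_irr": b.unit_cost_per_patient,
                "expected_per_patient_irr": b.expected_display,
                "cohort_total_irr": b.cohort_total,
            }
            for name, b in r.per_event_breakdown.items()
        },
    }


def _simulation_blocks(r: SimulationResult) -> Tuple[TableBlock, ...]:
    rows = (
        ("Replicates", r.config.n_replicates, ""),
        ("Patients per replicate", r.config.n_patients, ""),
        ("Seed", r.config.seed, ""),
        ("Analytic expectation (IRR/patient)", float(r.analytic_expectation), ""),
        ("Grand mean (IRR/patient)", float(r.grand_mean), ""),
        ("Min replicate mean", float(r.min_mean), ""),
        ("Max replicate mean", float(r.max_mean), ""),
        ("SD of replicate means", r.sd_of_means, ""),
    )
    return (TableBlock("Monte Carlo simulation", ("Quantity", "Value", ""), rows),)


def _simulation_json(r: SimulationResult) -> Dict[str, Any]:
    return {
        "n_replicates": r.config.n_replicates,
        "n_patients": r.config.n_patients,
        "seed": r.config.seed,
        "analytic_expectation_irr": float(r.analytic_expectation),
        "grand_mean_irr": float(r.grand_mean),
        "min_replicate_mean_irr": float(r.min_mean),
        "max_replicate_mean_irr": float(r.max_mean),
        "sd_of_replicate_means_irr": r.sd_of_means,
    }


def _comparison_blocks(r: ComparisonReport) -> Tuple[TableBlock, ...]:
    rows = (
        ("Total (IRR)", r.total_irr_a, r.total_irr_b, r.incremental_total_irr),
        ("Per patient (IRR)", r.per_patient_irr_a, r.per_patient_irr_b, r.incremental_per_patient_irr),
        ("Per-patient ratio B/A", "", "", round(r.per_patient_ratio_decimal, 4)),
    )
    delta_rows = tuple(
        (_COMPONENT_LABELS.get(k, k), v) for k, v in r.component_deltas_irr.items()
    )
    blocks = [
        TableBlock(
            title=f"Strategy comparison — {r.name_a} (A) vs {r.name_b} (B)",
            header=("Quantity", "A", "B", "B - A"),
            rows=rows,
        ),
        TableBlock("Component deltas (IRR, B - A)", ("Component", "Delta"), delta_rows),
    ]
    return tuple(blocks)


def _comparison_json(r: ComparisonReport) -> Dict[str, Any]:
    return {
        "a": r.name_a,
        "b": r.name_b,
        "total_irr": {"a": r.total_irr_a, "b": r.total_irr_b},
        "per_patient_irr": {"a": r.per_patient_irr_a, "b": r.per_patient_irr_b},
        "incremental_total_irr": r.incremental_total_irr,
        "incremental_per_patient_irr": r.incremental_per_patient_irr,
        "incremental_total_usd": r.incremental_total_usd,
        "incremental_per_patient_usd": r.incremental_per_patient_usd,
        "per_patient_ratio": r.per_patient_ratio_decimal,
        "component_deltas_irr": dict(r.component_deltas_irr),
        "warnings": list(r.warnings),
    }


def render_report(
    report: Union[CostReport, SimulationResult, ComparisonReport],
    format: str = "plain",
) -> RenderedReport:
    """Render any report object as plain text, TSV, or JSON.

    Rendering never alters stored values: every numeric cell is the exact
    report field (after the documented display rounding, which the report
    itself already carries).
    """
    if format not in ("plain", "tsv", "json"):
        raise ValidationError(f"unknown render format {format!r}")
    if isinstance(report, CostReport):
        blocks, obj = _cost_report_blocks(report), _cost_report_json(report)
    elif isinstance(report, SimulationResult):
        blocks, obj = _simulation_blocks(report), _simulation_json(report)
    elif isinstance(report, ComparisonReport):
        blocks, obj = _comparison_blocks(report), _comparison_json(report)
    else:
        raise ValidationError(f"cannot render object of type {type(report).__name__}")
    return RenderedReport(blocks=blocks, format=format, json_obj=obj)
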