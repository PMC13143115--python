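"""Delimited-text readers and writers for menu tables, target tables and
group/category maps.

Menu tables are UTF-8 CSV or TSV (autodetected from the header line, or
forced via a dialect config).  Canonical column names pair each nutrient
with a basis suffix: ``kcal_100g`` / ``kcal_serv`` and so on; serving size
is ``serving_size_g``.  A dialect config maps arbitrary source headers onto
these canonical names so heterogeneous exports can be adapted without code
changes.  Empty cells are missing values, never zero.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

from .model import (
    Basis,
    GroupMap,
    MealClass,
    MenuDataError,
    MenuItem,
    NUTRIENT_FIELDS,
    NutrientVector,
    PizzaStyle,
    Programme,
    Provenance,
    RestaurantType,
    TargetSpec,
    ValueKind,
)

logger = logging.getLogger(__name__)

#: Suffix for each basis in canonical menu-table headers.
BASIS_SUFFIX = {Basis.PER100G: "_100g", Basis.PER_SERVING: "_serv"}

META_COLUMNS = [
    "restaurant",
    "item_name",
    "subcategory",
    "limited_time",
    "pizza_style",
    "pizza_size_label",
    "pizza_diameter_in",
    "declared_servings",
    "target_category_label",
    "serving_size_g",
]

NUTRIENT_COLUMNS = [
    f"{n}{BASIS_SUFFIX[b]}" for b in (Basis.PER100G, Basis.PER_SERVING) for n in NUTRIENT_FIELDS
]

#: Canonical column order for menu tables.
MENU_COLUMNS = META_COLUMNS + NUTRIENT_COLUMNS + ["provenance"]


@dataclass
class Dialect:
    """Maps source-file headers onto canonical menu-table columns.

    ``columns`` maps source header -> canonical name; unmapped headers that
    are already canonical pass through, anything else is ignored with a
    warning.  ``sep`` forces a delimiter; by default it is sniffed from the
    header line.
    """

    columns: dict[str, str] = field(default_factory=dict)
    sep: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Dialect":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(columns=raw.get("columns", {}), sep=raw.get("sep"))


def _sniff_sep(path: Path) -> str:
    header = path.open(encoding="utf-8").readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def _parse_float(cell: str, col: str, row: int) -> Optional[float]:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise MenuDataError(f"cannot parse {col}={cell!r} as a number (row {row})")


def _parse_bool(cell: str) -> bool:
    return cell.strip().lower() in {"1", "true", "yes", "y"}


def _parse_provenance(cell: str) -> dict[str, Provenance]:
    prov: dict[str, Provenance] = {}
    for part in cell.split(";"):
        part = part.strip()
        if part:
            key, _, val = part.partition("=")
            prov[key] = Provenance(val)
    return prov


def read_menu_table(
    path: str | Path, dialect: Optional[Dialect] = None
) -> list[MenuItem]:
    """Read a delimited menu table into :class:`MenuItem` records.

    Empty cells become missing values.  All values read from the file get
    ``reported`` provenance unless the file carries an explicit provenance
    column (as written by :func:`write_menu_table`).  Row numbers (1-based
    data rows) are retained for error reporting.
    """
    path = Path(path)
    dialect = dialect or Dialect()
    sep = dialect.sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    df = df.rename(columns=dialect.columns)
    unknown = [c for c in df.columns if c not in MENU_COLUMNS]
    if unknown:
        logger.warning("ignoring unrecognised columns %s in %s", unknown, path)
        df = df.drop(columns=unknown)

    items: list[MenuItem] = []
    seen: set[tuple[str, str]] = set()
    for idx, rec in enumerate(df.to_dict("records"), start=1):
        get = lambda c: str(rec.get(c, "")).strip()  # noqa: E731
        vectors = {}
        for basis in (Basis.PER100G, Basis.PER_SERVING):
            vec = NutrientVector()
            for n in NUTRIENT_FIELDS:
                col = f"{n}{BASIS_SUFFIX[basis]}"
                if col in rec:
                    vec.set(n, _parse_float(get(col), col, idx))
            vectors[basis] = vec
        serving = _parse_float(get("serving_size_g"), "serving_size_g", idx)
        declared = _parse_float(get("declared_servings"), "declared_servings", idx)
        style = get("pizza_style") or None
        item = MenuItem(
            restaurant=get("restaurant"),
            item_name=get("item_name"),
            subcategory=get("subcategory"),
            limited_time=_parse_bool(get("limited_time")),
            pizza_style=PizzaStyle(style) if style else None,
            pizza_size_label=get("pizza_size_label") or None,
            pizza_diameter=_parse_float(get("pizza_diameter_in"), "pizza_diameter_in", idx),
            declared_servings=int(declared) if declared is not None else None,
            per100g=vectors[Basis.PER100G],
            per_serving=vectors[Basis.PER_SERVING],
            serving_size=serving,
            target_category_label=get("target_category_label") or None,
            row=idx,
        )
        for basis in (Basis.PER100G, Basis.PER_SERVING):
            item.vector(basis).validate(f"(row {idx})")
            for n in item.vector(basis).present():
                item.provenance[f"{basis.value}.{n}"] = Provenance.REPORTED
        if serving is not None:
            item.provenance["serving_size"] = Provenance.REPORTED
        if "provenance" in rec and get("provenance"):
            item.provenance.update(_parse_provenance(get("provenance")))
        key = (item.restaurant, item.item_name)
        if key in seen:
            warnings.warn(
                f"duplicate (restaurant, item_name) {key} at row {idx}; both kept",
                stacklevel=2,
            )
        seen.add(key)
        items.append(item)
    return items


def _format_value(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)  # full precision round trip
    return str(v)


def menu_frame(items: Iterable[MenuItem]) -> pd.DataFrame:
    """Render menu items as a canonical-column string DataFrame."""
    rows = []
    for it in items:
        rec = {
            "restaurant": it.restaurant,
            "item_name": it.item_name,
            "subcategory": it.subcategory,
            "limited_time": _format_value(it.limited_time),
            "pizza_style": it.pizza_style.value if it.pizza_style else "",
            "pizza_size_label": it.pizza_size_label or "",
            "pizza_diameter_in": _format_value(it.pizza_diameter),
            "declared_servings": _format_value(it.declared_servings),
            "target_category_label": it.target_category_label or "",
            "serving_size_g": _format_value(it.serving_size),
        }
        for basis in (Basis.PER100G, Basis.PER_SERVING):
            for n in NUTRIENT_FIELDS:
                rec[f"{n}{BASIS_SUFFIX[basis]}"] = _format_value(it.vector(basis).get(n))
        rec["provenance"] = ";".join(
            f"{k}={v.value}" for k, v in sorted(it.provenance.items())
        )
        rows.append(rec)
    return pd.DataFrame(rows, columns=MENU_COLUMNS)


def write_menu_table(items: Iterable[MenuItem], path: str | Path) -> None:
    menu_frame(items).to_csv(path, index=False, encoding="utf-8")


def read_target_table(path: str | Path) -> list[TargetSpec]:
    """Read a target table (CSV/TSV or YAML list) into TargetSpecs.

    Invariant violations (e.g. a sugar target on a per-serving basis, a
    non-positive value) are hard errors naming the offending row.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        raw = yaml.safe_load(path.read_text()) or []
        records = [dict(r) for r in raw]
    else:
        sep = _sniff_sep(path)
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        records = df.to_dict("records")
    if not records:
        warnings.warn(f"empty target table {path}", stacklevel=2)
        return []
    specs = []
    for idx, rec in enumerate(records, start=1):
        try:
            specs.append(
                TargetSpec(
                    target_id=str(rec["target_id"]),
                    programme=Programme(str(rec["programme"]).strip()),
                    category_name=str(rec["category_name"]).strip(),
                    nutrient=str(rec["nutrient"]).strip(),
                    basis=Basis(str(rec["basis"]).strip()),
                    value=float(rec["value"]),
                    value_kind=ValueKind(str(rec.get("value_kind") or "average").strip()),
                )
            )
        except (MenuDataError, ValueError, KeyError) as exc:
            raise MenuDataError(f"invalid target table row {idx}: {exc}") from exc
    return specs


def write_target_table(specs: Iterable[TargetSpec], path: str | Path) -> None:
    rows = [
        {
            "target_id": s.target_id,
            "programme": s.programme.value,
            "category_name": s.category_name,
            "nutrient": s.nutrient,
            "basis": s.basis.value,
            "value": repr(s.value),
            "value_kind": s.value_kind.value,
        }
        for s in specs
    ]
    cols = ["target_id", "programme", "category_name", "nutrient", "basis", "value", "value_kind"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, encoding="utf-8")


def read_group_map(path: str | Path) -> GroupMap:
    """Read a YAML group map: restaurant -> type, subcategory -> meal class."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return GroupMap(
        restaurant_type={
            k: RestaurantType(v) for k, v in (raw.get("restaurant_type") or {}).items()
        },
        meal_class={
            k: MealClass(v) for k, v in (raw.get("meal_class") or {}).items()
        },
    )


def write_group_map(groups: GroupMap, path: str | Path) -> None:
    raw = {
        "restaurant_type": {k: v.value for k, v in groups.restaurant_type.items()},
        "meal_class": {k: v.value for k, v in groups.meal_class.items()},
    }
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


def write_outputs(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    *,
    overwrite: bool = False,
    metadata: Optional[dict] = None,
) -> list[Path]:
    """Write named result tables as CSV plus a run-metadata YAML file.

    Data files are byte-stable for identical inputs: the metadata file
    carries the timestamp and a content hash of every table, so reruns can
    be compared by hashing the data files alone.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    hashes = {}
    for name, df in tables.items():
        target = out_dir / f"{name}.csv"
        if target.exists() and not overwrite:
            raise FileExistsError(f"{target} exists; pass overwrite=True to replace")
        csv_bytes = df.to_csv(index=False).encode("utf-8")
        target.write_bytes(csv_bytes)
        hashes[name] = hashlib.sha256(csv_bytes).hexdigest()
        written.append(target)
    meta = dict(metadata or {})
    meta["written_utc"] = datetime.now(timezone.utc).isoformat()
    meta["table_sha256"] = hashes
    meta_path = out_dir / "run_metadata.yaml"
    meta_path.write_text(yaml.safe_dump(json.loads(json.dumps(meta)), sort_keys=True))
    written.append(meta_path)
    return written
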