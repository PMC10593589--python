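"""Reading, writing, and the column dictionary.

Cohorts are ingested from plain delimited text with a header, translated
through a column dictionary — a YAML mapping from the pipeline's canonical
field names to the input file's column names, with category recodes where
the input uses different labels.  Surveys distributed as SAS transport
files can be converted with ``pandas.read_sas(path).to_csv(...)`` before
ingestion; the pipeline itself only ever reads text.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from phenodii import phenoage as pa
from phenodii.dii import load_dii_parameters

__all__ = ["ColumnDictionary", "IOError_", "read_cohort", "write_cohort", "write_results"]

#: Canonical non-nutrient fields a full analysis needs.
CANONICAL_FIELDS = (
    "id",
    "stratum",
    "psu",
    "weight",
    "chron_age",
    "sex",
    "race",
    "education",
    "income_poverty_ratio",
    "exercise",
    "smoking",
    "drinking",
    "bmi",
    "energy",
    *pa.BIOMARKER_FIELDS,
)

NUMERIC_FIELDS = {
    "weight",
    "chron_age",
    "income_poverty_ratio",
    "bmi",
    "energy",
    *pa.BIOMARKER_FIELDS,
}


class IOError_(ValueError):
    pass


@dataclass(frozen=True)
class ColumnDictionary:
    """Canonical-field → input-column mapping with optional recodes.

    ``columns`` maps canonical names (and ``nut_<nutrient>`` names) to the
    input header; a canonical field may be mapped to ``null`` to mark it
    explicitly absent.  ``recodes`` maps a canonical field to an
    input-value → canonical-label dictionary.
    """

    columns: dict[str, str | None]
    recodes: dict[str, dict[str, str]] = field(default_factory=dict)

    @classmethod
    def identity(cls, nutrient_names: list[str] | None = None) -> "ColumnDictionary":
        if nutrient_names is None:
            nutrient_names = load_dii_parameters().names
        cols = {f: f for f in CANONICAL_FIELDS}
        cols.update({f"nut_{n}": f"nut_{n}" for n in nutrient_names})
        return cls(columns=cols)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnDictionary":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(columns=raw.get("columns", {}), recodes=raw.get("recodes", {}))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump({"columns": self.columns, "recodes": self.recodes}, sort_keys=True)
        )


def read_cohort(
    path: str | Path,
    dictionary: ColumnDictionary | None = None,
    sep: str = ",",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read a delimited cohort table through a column dictionary.

    Returns the canonical-named frame plus a per-field count of cells that
    failed numeric parsing and became missing.  A mapped column absent
    from the header, or duplicate participant ids, are hard errors.
    """
    if dictionary is None:
        dictionary = ColumnDictionary.identity()
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)
    out = {}
    unparseable: dict[str, int] = {}
    for canonical, source in dictionary.columns.items():
        if source is None:
            continue
        if source not in raw.columns:
            raise IOError_(f"input lacks mapped column {source!r} (for {canonical!r})")
        col = raw[source]
        if canonical in NUMERIC_FIELDS or canonical.startswith("nut_"):
            # exact strtod parsing; pd.to_numeric's fast path can be 1 ulp off
            def _parse(cell):
                if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                    return np.nan
                try:
                    return float(cell)
                except ValueError:
                    return np.nan

            parsed = col.map(_parse).astype(float)
            bad = int((parsed.isna() & col.notna()).sum())
            if bad:
                unparseable[canonical] = bad
            out[canonical] = parsed
        else:
            if canonical in dictionary.recodes:
                col = col.map(dictionary.recodes[canonical]).astype(object)
            out[canonical] = col
    frame = pd.DataFrame(out)
    if "id" in frame.columns and frame["id"].duplicated().any():
        raise IOError_("duplicate participant ids in input")
    return frame, unparseable


def write_cohort(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a cohort table as delimited text.

    Floats use the shortest exact decimal representation, so a
    write-then-read round trip reproduces values bit for bit.
    """
    df.to_csv(path, sep=sep, index=False)


def write_results(
    bundle: dict[str, object],
    out_dir: str | Path,
    seed: int | None = None,
    config: dict | None = None,
    sep: str = "\t",
) -> list[Path]:
    """Write an analysis bundle as delimited text with deterministic order.

    Emits exclusion_log, table1, table2, table3, forest and a run_metadata
    JSON carrying the seed, a config hash and the DII parameter-table
    version, so two runs on the same inputs are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("exclusion_log", "table1", "table2", "table3", "forest"):
        obj = bundle.get(name)
        if obj is None:
            continue
        path = out / f"{name}.tsv"
        obj.to_csv(path, sep=sep, index=False, float_format="%.10g")
        written.append(path)
    cfg_hash = hashlib.sha256(
        json.dumps(config or {}, sort_keys=True, default=str).encode()
    ).hexdigest()
    meta = {
        "seed": seed,
        "config_sha256": cfg_hash,
        "dii_parameter_version": bundle.get("dii_version", ""),
        "n_analyzed": int(len(bundle["cohort"])) if "cohort" in bundle else None,
    }
    meta_path = out / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    written.append(meta_path)
    return written
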