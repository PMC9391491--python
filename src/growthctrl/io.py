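"""Serialization: condition-table CSV, run config YAML, parameter JSON.

All formats are plain text: CSV with a header row, UTF-8, '.' decimal; the
parameter document is version-stamped JSON with canonical (sorted, fixed
separator) serialization so byte-identical round trips hash stably.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .biosynthesis import ConditionTable
from .errors import DomainError

PARAMS_DOC_VERSION = 1

CONDITION_COLUMNS = ["aa", "conc_uM", "enzyme_uM", "demand_uM_per_s",
                     "exchange_lit_uM_per_s", "kcat_lit_per_s"]


def write_condition_table(cond: ConditionTable, path: str | Path) -> None:
    rows = [{"aa": aa,
             "conc_uM": cond.aa_conc[aa],
             "enzyme_uM": cond.enzyme_conc[aa],
             "demand_uM_per_s": cond.demand[aa],
             "exchange_lit_uM_per_s": cond.v_exchange_lit.get(aa, 0.0),
             "kcat_lit_per_s": cond.kcat_lit.get(aa, 1.0)}
            for aa in cond.aa_conc]
    pd.DataFrame(rows, columns=CONDITION_COLUMNS).to_csv(path, index=False)


def read_condition_table(path: str | Path, name: str | None = None) -> ConditionTable:
    df = pd.read_csv(path)
    missing = set(CONDITION_COLUMNS) - set(df.columns)
    if missing:
        raise DomainError(f"condition table {path} is missing columns: {sorted(missing)}")
    return ConditionTable(
        name=name or Path(path).stem,
        aa_conc=dict(zip(df["aa"], df["conc_uM"].astype(float))),
        enzyme_conc=dict(zip(df["aa"], df["enzyme_uM"].astype(float))),
        demand=dict(zip(df["aa"], df["demand_uM_per_s"].astype(float))),
        v_exchange_lit=dict(zip(df["aa"], df["exchange_lit_uM_per_s"].astype(float))),
        kcat_lit=dict(zip(df["aa"], df["kcat_lit_per_s"].astype(float))),
    )


_KNOWN_TOP_LEVEL = {"version", "biosynthesis", "transport", "pheno", "charging",
                    "ppgpp", "transcription", "attenuation", "residuals", "meta"}


def canonical_json(doc: dict) -> str:
    return json.dumps(doc, sort_keys=True, separators=(",", ":"), allow_nan=False)


def doc_hash(doc: dict) -> str:
    return hashlib.sha256(canonical_json(doc).encode()).hexdigest()


def write_params_doc(doc: dict, path: str | Path) -> None:
    doc = {"version": PARAMS_DOC_VERSION, **doc}
    _validate_doc(doc)
    Path(path).write_text(canonical_json(doc) + "\n")


def read_params_doc(path: str | Path) -> dict:
    doc = json.loads(Path(path).read_text())
    _validate_doc(doc)
    if doc.get("version") != PARAMS_DOC_VERSION:
        raise DomainError(f"unsupported parameter document version {doc.get('version')!r}")
    return doc


def _validate_doc(doc: Any) -> None:
    if not isinstance(doc, dict):
        raise DomainError("parameter document must be a JSON object")
    unknown = set(doc) - _KNOWN_TOP_LEVEL
    if unknown:
        raise DomainError(f"unknown parameter document fields: {sorted(unknown)}")


def load_run_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise DomainError("run config must be a YAML mapping")
    return cfg
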