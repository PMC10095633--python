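"""Dataset and result I/O.

Titration CSV dialect: header ``lt_molar,response`` with one row per
titration point.  Composition metadata lives in a sidecar JSON next to
the CSV (``<stem>.meta.json``) with keys ``pt_molar``, ``alpha_lb``,
``mw_gmol``, ``kp_lb_lw``, ``response_kind`` and optionally
``ground_truth``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .apparent import TitrationDataset

__all__ = ["read_titration_csv", "write_titration_csv", "sidecar_path"]

_META_KEYS = ("pt_molar", "alpha_lb", "mw_gmol", "kp_lb_lw", "response_kind", "ground_truth")

#: significant digits for all numeric CSV output
CSV_DIGITS = 12


def sidecar_path(csv_path: str | Path) -> Path:
    """Metadata file accompanying a titration CSV: ``<stem>.meta.json``."""
    p = Path(csv_path)
    return p.with_name(p.stem + ".meta.json")


def read_titration_csv(path: str | Path, metadata: Optional[dict] = None) -> TitrationDataset:
    """Parse a titration CSV (and its sidecar metadata) into a dataset.

    ``metadata`` overrides anything found in the sidecar; ``pt_molar``
    must come from one of the two.  Malformed files raise ``ValueError``
    naming the offending row or column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("lt_molar", "response"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if len(df) < 3:
        raise ValueError(f"{path}: need at least 3 rows, found {len(df)}")
    for col in ("lt_molar", "response"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 2  # 1-based incl. header
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {row}")
        df[col] = vals
    neg = df["lt_molar"] <= 0
    if neg.any():
        row = int(np.argmax(neg.to_numpy())) + 2
        raise ValueError(f"{path}: lt_molar must be > 0 (line {row})")

    meta: dict = {}
    side = sidecar_path(path)
    if side.exists():
        meta.update(json.loads(side.read_text()))
    if metadata:
        meta.update(metadata)
    unknown = set(meta) - set(_META_KEYS)
    if unknown:
        raise ValueError(f"{side}: unknown metadata keys {sorted(unknown)}")
    if "pt_molar" not in meta:
        raise ValueError(
            f"{path}: pt_molar not found in sidecar metadata ({side}) or overrides"
        )
    return TitrationDataset(
        lt_values=df["lt_molar"].to_numpy(),
        observed=df["response"].to_numpy(),
        pt_molar=float(meta["pt_molar"]),
        response_kind=meta.get("response_kind", "saturation"),
        alpha_lb=float(meta.get("alpha_lb", 0.0)),
        mw_gmol=meta.get("mw_gmol"),
        kp_lb_lw=meta.get("kp_lb_lw"),
        ground_truth=meta.get("ground_truth"),
    )


def write_titration_csv(dataset: TitrationDataset, path: str | Path) -> Path:
    """Write a dataset as CSV plus sidecar metadata JSON; returns the CSV path."""
    path = Path(path)
    df = pd.DataFrame({"lt_molar": dataset.lt_values, "response": dataset.observed})
    # datasets roundtrip losslessly; tabular report output uses CSV_DIGITS
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "pt_molar": dataset.pt_molar,
        "alpha_lb": dataset.alpha_lb,
        "response_kind": dataset.response_kind,
    }
    if dataset.mw_gmol is not None:
        meta["mw_gmol"] = dataset.mw_gmol
    if dataset.kp_lb_lw is not None:
        meta["kp_lb_lw"] = dataset.kp_lb_lw
    if dataset.ground_truth is not None:
        meta["ground_truth"] = dataset.ground_truth
    sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")
    return path
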