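"""The effective lung ventilation area ratio, ELVAR = (L − I) / L.

L is the lung voxel count from segmentation, I the interstitial voxel
count from enhancement; their ratio complement is a unitless fraction in
[0, 1] that falls as the interstitial compartment grows.  The whole-volume
value is computed from the global counts — not as a mean of per-slice
ratios — and reported to four decimal places.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, is_dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .interstitial_enhancement import InterstitialMap
from .lung_segmentation import LungSegmentation

__all__ = ["SliceCounts", "ElvarResult", "compute_elvar", "elvar_report"]

REPORT_COLUMNS = ["provenance", "L", "I", "elvar", "params_fingerprint"]


@dataclass(frozen=True)
class SliceCounts:
    slice_index: int
    L_s: int
    I_s: int
    elvar_s: float | None  # None where the slice contains no lung


@dataclass
class ElvarResult:
    L: int
    I: int
    elvar: float | None  # None iff L == 0 (undefined, never NaN)
    per_slice: list[SliceCounts]
    params_fingerprint: str
    provenance: str

    @property
    def defined(self) -> bool:
        return self.elvar is not None

    def to_record(self) -> dict:
        return {
            "provenance": self.provenance,
            "L": self.L,
            "I": self.I,
            "elvar": None if self.elvar is None else round(self.elvar, 4),
            "params_fingerprint": self.params_fingerprint,
        }


def _fingerprint(*objs) -> str:
    parts = []
    for o in objs:
        if is_dataclass(o) and not isinstance(o, type):
            parts.append(json.dumps(asdict(o), sort_keys=True, default=str))
        else:
            parts.append(repr(o))
    return hashlib.sha256("|".join(parts).encode()).hexdigest()[:16]


def compute_elvar(
    seg: LungSegmentation, imap: InterstitialMap, provenance: str = ""
) -> ElvarResult:
    """Whole-volume and per-slice ELVAR from a matched segmentation pair.

    Raises if the masks live on different lattices or I exceeds L (an
    upstream invariant violation).  ``elvar`` is ``None`` when the lung
    mask is empty; slices without lung carry an undefined per-slice value
    but contribute zero to the global counts.
    """
    lung = seg.lung_mask
    inter = imap.interstitium_mask
    if lung.shape != inter.shape or lung.grid_ref != inter.grid_ref:
        raise ValueError("segmentation and interstitial map are bound to different lattices")
    if (inter.data & ~lung.data).any():
        raise ValueError("interstitium mask extends outside the lung mask")

    L = lung.popcount()
    I = inter.popcount()
    if I > L:
        raise ValueError(f"I={I} exceeds L={L}")

    per_slice = []
    for k in range(lung.shape[0]):
        L_s = int(lung.data[k].sum())
        I_s = int(inter.data[k].sum())
        per_slice.append(
            SliceCounts(k, L_s, I_s, (L_s - I_s) / L_s if L_s > 0 else None)
        )

    return ElvarResult(
        L=L,
        I=I,
        elvar=(L - I) / L if L > 0 else None,
        per_slice=per_slice,
        params_fingerprint=_fingerprint(seg.params_used, imap.params_used),
        provenance=provenance,
    )


def elvar_report(results: Sequence[ElvarResult], out_path: str | Path) -> tuple[Path, Path]:
    """Write a CSV + JSON report, one row per volume, stable column order.

    ``out_path`` may carry either extension; both files are written next
    to each other and their paths returned as (csv, json).
    """
    if not results:
        raise ValueError("need at least one result to report")
    out_path = Path(out_path)
    base = out_path.with_suffix("")
    csv_path, json_path = base.with_suffix(".csv"), base.with_suffix(".json")

    records = [r.to_record() for r in results]
    df = pd.DataFrame.from_records(records, columns=REPORT_COLUMNS)
    df.to_csv(csv_path, index=False, float_format="%.4f")
    json_path.write_text(json.dumps(records, indent=2) + "\n")
    return csv_path, json_path


def report_from_json(json_path: str | Path, out_csv: str | Path) -> Path:
    """Regenerate the CSV report from a saved JSON record (byte-stable)."""
    records = json.loads(Path(json_path).read_text())
    df = pd.DataFrame.from_records(records, columns=REPORT_COLUMNS)
    out_csv = Path(out_csv)
    df.to_csv(out_csv, index=False, float_format="%.4f")
    return out_csv
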