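"""Time-course CSV serialization.

Schema: columns time_h, biomass_g_l, product_g_l, then glucose_g_l /
nitrogen_g_l / phosphorous_g_l for whichever substrates are present, and
volume_l for fed-batch runs. Metadata travels in '#'-prefixed header lines
as a single JSON object. A missing substrate column means that substrate
was not measured (absent, not zero).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import SUBSTRATES, TimeCourse

__all__ = ["read_timecourse", "write_timecourse"]

_CORE = {"time_h", "biomass_g_l", "product_g_l"}


def write_timecourse(tc: TimeCourse, path: str | Path) -> None:
    path = Path(path)
    cols = {"time_h": tc.times, "biomass_g_l": tc.biomass,
            "product_g_l": tc.product}
    for name in SUBSTRATES:
        if name in tc.substrates:
            cols[f"{name}_g_l"] = tc.substrates[name]
    if tc.volume is not None:
        cols["volume_l"] = tc.volume
    df = pd.DataFrame(cols)
    with path.open("w") as fh:
        if tc.metadata:
            fh.write("# " + json.dumps(tc.metadata, default=_jsonable) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_timecourse(path: str | Path) -> TimeCourse:
    path = Path(path)
    metadata = {}
    with path.open() as fh:
        header = []
        for line in fh:
            if line.startswith("#"):
                header.append(line[1:].strip())
            else:
                break
    if header:
        try:
            metadata = json.loads("\n".join(header))
        except json.JSONDecodeError:
            metadata = {"header": header}
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = _CORE - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    t = df["time_h"].to_numpy(float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ValueError(
            f"{path}: time not strictly increasing at data row {bad[0] + 2}"
        )
    substrates = {
        name: df[f"{name}_g_l"].to_numpy(float)
        for name in SUBSTRATES
        if f"{name}_g_l" in df.columns
    }
    volume = df["volume_l"].to_numpy(float) if "volume_l" in df.columns else None
    return TimeCourse(
        times=t,
        biomass=df["biomass_g_l"].to_numpy(float),
        product=df["product_g_l"].to_numpy(float),
        substrates=substrates,
        volume=volume,
        metadata=metadata,
    )
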