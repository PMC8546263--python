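"""CSV interchange for model parameter sets and measurement tables.

Parameter CSVs carry one row per shell with columns
``model,R_mm,r_mm,h_mm,theta1_rad,theta2_rad,theta_rad`` (fields unused
by a model left empty).  Angles are radians on disk and in memory;
degrees exist only as a CLI convenience flag.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from plaquegeom.geometry_models import Model1Params, Model2Params

__all__ = ["read_params_csv", "write_params_csv", "PARAM_COLUMNS"]

PARAM_COLUMNS = [
    "model",
    "R_mm",
    "r_mm",
    "h_mm",
    "theta1_rad",
    "theta2_rad",
    "theta_rad",
]


def read_params_csv(path: str | Path) -> list[Model1Params | Model2Params]:
    """Read a parameter CSV into validated parameter objects."""
    frame = pd.read_csv(path)
    missing = [c for c in PARAM_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"parameter CSV missing columns: {missing}")
    out: list[Model1Params | Model2Params] = []
    for _, row in frame.iterrows():
        model = int(row["model"])
        R, r, h = float(row["R_mm"]), float(row["r_mm"]), float(row["h_mm"])
        if model == 1:
            th1 = float(row["theta1_rad"]) if np.isfinite(row["theta1_rad"]) else 0.0
            th2 = float(row["theta2_rad"]) if np.isfinite(row["theta2_rad"]) else 0.0
            out.append(Model1Params(R, r, h, th1, th2))
        elif model == 2:
            out.append(Model2Params(R, r, h, float(row["theta_rad"])))
        else:
            raise ValueError(f"unknown model id {model}; expected 1 or 2")
    return out


def write_params_csv(
    params: list[Model1Params | Model2Params], path: str | Path
) -> None:
    """Write parameter objects to the interchange CSV layout."""
    rows = []
    for p in params:
        if isinstance(p, Model1Params):
            rows.append(
                {
                    "model": 1,
                    "R_mm": p.R,
                    "r_mm": p.r,
                    "h_mm": p.h,
                    "theta1_rad": p.theta1,
                    "theta2_rad": p.theta2,
                    "theta_rad": None,
                }
            )
        else:
            rows.append(
                {
                    "model": 2,
                    "R_mm": p.R,
                    "r_mm": p.r,
                    "h_mm": p.h,
                    "theta1_rad": None,
                    "theta2_rad": None,
                    "theta_rad": p.theta,
                }
            )
    pd.DataFrame(rows, columns=PARAM_COLUMNS).to_csv(path, index=False)
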