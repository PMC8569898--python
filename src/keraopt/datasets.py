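"""Embedded study tables.

Three fixtures ship with the package, digit-exact to the published tables
they transcribe:

* ``pbd_table1`` — the 12-run Plackett-Burman screening of six medium salts
  with the measured amino-acid response (ug/g CFK) and replicate SDs;
* ``rccd_table2`` — the 40-run replicated rotatable central composite design
  over KH2PO4, NH4Cl and incubation time, with observed responses, the
  published model-predicted columns, and the 22/18 training/validation
  flags used for holdback;
* ``isolate_screening`` — keratinase activity and amino-acid release for the
  six candidate isolates.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .design import DesignMatrix, Factor, ResponseTable

__all__ = ["load_fixture", "FIXTURES"]

FIXTURES = ("pbd_table1", "rccd_table2", "isolate_screening")


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("keraopt").joinpath("data", f"{name}.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def _factors(name: str) -> list[Factor]:
    frame = _read(name)
    return [
        Factor(r["name"], r["units"], float(r["center"]), float(r["step"]))
        for _, r in frame.iterrows()
    ]


def load_fixture(name: str):
    """Return an embedded table by name.

    ``pbd_table1`` and ``rccd_table2`` return ``(DesignMatrix,
    ResponseTable, DataFrame)`` where the frame is the raw table (including
    published predicted columns); ``isolate_screening`` returns a DataFrame
    of per-isolate keratinase activity and amino-acid release.
    """
    if name == "pbd_table1":
        factors = _factors("pbd_factors")
        frame = _read("pbd_table1")
        design = DesignMatrix(
            factors=factors,
            coded=frame[[f.name for f in factors]].to_numpy(float),
            design_kind="plackett_burman",
        )
        resp = ResponseTable(
            response=frame["response"].to_numpy(float),
            sd=frame["sd"].to_numpy(float),
            run_id=frame["run"].to_numpy(int),
        )
        return design, resp, frame
    if name == "rccd_table2":
        factors = _factors("rccd_factors")
        frame = _read("rccd_table2")
        design = DesignMatrix(
            factors=factors,
            coded=frame[[f"x_{f.name}" for f in factors]].to_numpy(float),
            point_type=frame["point_type"].to_numpy(object),
            replicate_id=frame["replicate_id"].to_numpy(int),
            design_kind="ccd",
        )
        resp = ResponseTable(
            response=frame["response"].to_numpy(float),
            sd=frame["sd"].to_numpy(float),
            subset=frame["subset"].to_numpy(object),
            run_id=frame["run"].to_numpy(int),
        )
        return design, resp, frame
    if name == "isolate_screening":
        return _read("isolate_screening")
    raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
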