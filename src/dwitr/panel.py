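"""Long-format longitudinal panel container and delimited-text I/O.

A panel holds one row per patient per grid time with the counting-process
bookkeeping needed by the visit-intensity model (at-risk indicator ``at_risk``
and visit indicator ``obs``), the binary treatment ``A``, the outcome ``Y``
(missing wherever the patient was not observed), the baseline confounders
``K1`` (continuous), ``K2`` (binary), ``K3`` (continuous), the time-varying
mediator ``Z`` and the tailoring variable ``Q``.

The on-disk format is plain CSV with the header
``id,time,at_risk,obs,A,Y,K1,K2,K3,Z,Q``; a missing outcome is an empty
field.  Times are written with full repr precision so a written grid
round-trips bit-for-bit.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import PanelSchemaError

PANEL_COLUMNS = ["id", "time", "at_risk", "obs", "A", "Y", "K1", "K2", "K3", "Z", "Q"]

_FLOAT_COLS = ["time", "Y", "K1", "K3", "Z", "Q"]
_INT_COLS = ["at_risk", "obs", "A", "K2"]


@dataclass
class LongitudinalPanel:
    """Person-time records for one cohort.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per (patient, grid time), columns :data:`PANEL_COLUMNS`.
    latent : bool
        True for simulator output before visit masking: ``Y`` is present at
        every grid time and ``obs`` is not yet meaningful.
    """

    data: pd.DataFrame
    latent: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        """Check schema and the counting-process invariants.

        Raises
        ------
        PanelSchemaError
            On missing/extra columns, a visit outside the risk set
            (``obs=1`` with ``at_risk=0``), or duplicated (id, time) pairs.
        """
        missing = [c for c in PANEL_COLUMNS if c not in self.data.columns]
        extra = [c for c in self.data.columns if c not in PANEL_COLUMNS]
        if missing or extra:
            raise PanelSchemaError(
                f"panel columns mismatch: missing={missing} extra={extra}"
            )
        df = self.data
        bad = (df["obs"] == 1) & (df["at_risk"] == 0)
        if bad.any():
            rows = df.index[bad].tolist()[:5]
            raise PanelSchemaError(
                f"obs=1 requires at_risk=1; violated at rows {rows}"
            )
        if not df["obs"].isin([0, 1]).all():
            raise PanelSchemaError("obs must be 0/1")
        if df.duplicated(subset=["id", "time"]).any():
            dup = df[df.duplicated(subset=["id", "time"])].index.tolist()[:5]
            raise PanelSchemaError(f"duplicate (id, time) pairs at rows {dup}")

    # ------------------------------------------------------------------ #
    @property
    def n_patients(self) -> int:
        return self.data["id"].nunique()

    @property
    def patients(self) -> np.ndarray:
        return self.data["id"].unique()

    def visit_counts(self) -> pd.Series:
        """Number of observation times per patient (zero-visit patients kept)."""
        return self.data.groupby("id", sort=True)["obs"].sum()

    def analysis_rows(self) -> pd.DataFrame:
        """Rows entering the outcome estimating equation: obs=1 and Y present."""
        df = self.data
        return df[(df["obs"] == 1) & df["Y"].notna()]

    # ------------------------------------------------------------------ #
    def to_csv(self, path) -> None:
        write_panel(self, path)

    @classmethod
    def from_csv(cls, path) -> "LongitudinalPanel":
        return read_panel(path)


def write_panel(panel: LongitudinalPanel, path) -> None:
    """Write a panel as CSV; missing ``Y`` becomes an empty field.

    ``repr``-precision floats guarantee the grid times survive a round trip
    exactly.
    """
    df = panel.data[PANEL_COLUMNS]
    df.to_csv(path, index=False, float_format=None, na_rep="")


def read_panel(path) -> LongitudinalPanel:
    """Read and validate a panel written by :func:`write_panel`.

    Raises
    ------
    PanelSchemaError
        If the header does not match the schema, fields are non-numeric, or
        panel invariants fail (the offending row numbers are named).
    """
    try:
        df = pd.read_csv(path, header=0)
    except (ValueError, OSError) as exc:  # pragma: no cover - passthrough
        raise PanelSchemaError(f"cannot read panel at {path}: {exc}") from exc
    if list(df.columns) != PANEL_COLUMNS:
        raise PanelSchemaError(
            f"header {list(df.columns)} does not match {PANEL_COLUMNS}"
        )
    for col in _FLOAT_COLS:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise PanelSchemaError(f"non-numeric values in column {col}") from exc
    for col in _INT_COLS:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise PanelSchemaError(f"non-numeric values in column {col}")
        df[col] = vals.astype(np.int64)
    return LongitudinalPanel(df)


def panel_to_string(panel: LongitudinalPanel) -> str:
    buf = io.StringIO()
    write_panel(panel, buf)
    return buf.getvalue()
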