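"""Age-band lookup tables (mortality, case fatality, utility weights, incidence).

Tables are stored as half-open-in-spirit inclusive bands ``[age_lo, age_hi]``
with one value per band, optionally stratified by sex.  CSV round-tripping
uses the canonical columns ``age_lo, age_hi, sex, value`` (``sex`` is ``M``,
``F`` or ``all``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError

__all__ = ["AgeBandTable", "SexAgeBandTable", "read_table_csv", "write_table_csv"]


@dataclass(frozen=True)
class AgeBandTable:
    """Piecewise-constant values over inclusive age bands.

    Parameters
    ----------
    age_lo, age_hi : arrays of band bounds, sorted, non-overlapping.
    values : array of band values.
    extend_upper : if True, ages above the last band reuse the last value
        (used for case-fatality bands that stop at 75-84 while the model
        runs to 89).
    """

    age_lo: np.ndarray
    age_hi: np.ndarray
    values: np.ndarray
    extend_upper: bool = False

    def __post_init__(self) -> None:
        lo = np.asarray(self.age_lo, dtype=float)
        hi = np.asarray(self.age_hi, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if not (lo.shape == hi.shape == vals.shape) or lo.ndim != 1 or lo.size == 0:
            raise ConfigurationError("age band table needs equal-length 1-d age_lo/age_hi/values")
        if np.any(np.diff(lo) <= 0):
            raise ConfigurationError("age bands must be sorted by age_lo")
        if np.any(hi < lo):
            raise ConfigurationError("age_hi must be >= age_lo in every band")
        object.__setattr__(self, "age_lo", lo)
        object.__setattr__(self, "age_hi", hi)
        object.__setattr__(self, "values", vals)

    def lookup(self, age):
        """Return the band value for ``age`` (scalar or array)."""
        a = np.asarray(age, dtype=float)
        idx = np.searchsorted(self.age_lo, a, side="right") - 1
        below = idx < 0
        idx = np.clip(idx, 0, len(self.values) - 1)
        above = a > self.age_hi[idx]
        if self.extend_upper:
            # only ages beyond the *last* band are forgiven
            above &= idx < len(self.values) - 1
        if np.any(below) or np.any(above):
            bad = np.atleast_1d(a)[np.atleast_1d(below | above)][0]
            raise DomainError(f"age {bad} outside table coverage [{self.age_lo[0]}, {self.age_hi[-1]}]")
        out = self.values[idx]
        return float(out) if np.isscalar(age) else out

    @classmethod
    def constant(cls, value: float, age_lo: float = 0.0, age_hi: float = 120.0) -> "AgeBandTable":
        return cls(np.array([age_lo]), np.array([age_hi]), np.array([value]))


@dataclass(frozen=True)
class SexAgeBandTable:
    """Per-sex pair of :class:`AgeBandTable` with a vectorised lookup."""

    male: AgeBandTable
    female: AgeBandTable

    def lookup(self, male_mask, age):
        """Vectorised lookup; ``male_mask`` is boolean (True = male)."""
        m = np.asarray(male_mask, dtype=bool)
        a = np.asarray(age, dtype=float)
        if m.ndim == 0:
            table = self.male if bool(m) else self.female
            return table.lookup(float(a))
        out = np.empty(a.shape, dtype=float)
        if m.any():
            out[m] = self.male.lookup(a[m])
        if (~m).any():
            out[~m] = self.female.lookup(a[~m])
        return out

    @classmethod
    def constant(cls, value: float, age_lo: float = 0.0, age_hi: float = 120.0) -> "SexAgeBandTable":
        t = AgeBandTable.constant(value, age_lo, age_hi)
        return cls(male=t, female=t)

    @classmethod
    def from_bands(cls, bands, male_values, female_values, extend_upper=False) -> "SexAgeBandTable":
        lo = np.array([b[0] for b in bands], dtype=float)
        hi = np.array([b[1] for b in bands], dtype=float)
        return cls(
            male=AgeBandTable(lo, hi, np.asarray(male_values, dtype=float), extend_upper),
            female=AgeBandTable(lo, hi, np.asarray(female_values, dtype=float), extend_upper),
        )


def write_table_csv(path, table: SexAgeBandTable) -> None:
    rows = []
    for sex, t in (("M", table.male), ("F", table.female)):
        for lo, hi, v in zip(t.age_lo, t.age_hi, t.values):
            rows.append({"age_lo": lo, "age_hi": hi, "sex": sex, "value": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_table_csv(path, extend_upper: bool = False) -> SexAgeBandTable:
    df = pd.read_csv(path)
    required = {"age_lo", "age_hi", "sex", "value"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"table CSV must have columns {sorted(required)}")
    tables = {}
    for sex in ("M", "F"):
        sub = df[df["sex"].isin([sex, "all"])].sort_values("age_lo")
        if sub.empty:
            raise ConfigurationError(f"table CSV missing rows for sex {sex!r}")
        tables[sex] = AgeBandTable(
            sub["age_lo"].to_numpy(), sub["age_hi"].to_numpy(), sub["value"].to_numpy(), extend_upper
        )
    return SexAgeBandTable(male=tables["M"], female=tables["F"])
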