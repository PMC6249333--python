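"""Per-specimen morphometric measurement tables.

Measurements are linear distances in micrometres taken on individual
specimens (here: chalcidoid wasps), one row per specimen, one column per
measurement variable.  Variables are named by short dotted codes such as
``hea.b`` (head breadth) or ``pol.l`` (distance between the posterior
ocelli).  The module reads and writes delimited text, derives ratio
series, summarises per-species ranges, and provides a Bland–Altman
agreement check used to verify that different gaugers (or measurement
campaigns) produce comparable values.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Controlled vocabulary of measurement codes (micrometres).
MEASUREMENT_CODES: tuple[str, ...] = (
    "ant.l", "clv.b", "eye.b", "eye.d", "eye.h", "eye.l", "fm3.b",
    "fm3.l", "fwi.b", "fwi.l", "gst.b", "gst.l", "hea.b", "hea.h",
    "hea.l", "mav.l", "msc.b", "msc.l", "msp.l", "mss.l", "ool.l",
    "pdl.b", "pdl.l", "plc.d", "pol.l", "ppd.l", "scp.l", "sct.l",
    "stv.l", "tmp.l", "upf.l",
)

SIDES = ("left", "right", "unknown")


class ValidationError(ValueError):
    """A measurement table violated an invariant."""


@dataclass
class MeasurementTable:
    """Specimens x measurement variables, values in micrometres.

    Parameters
    ----------
    data :
        Float DataFrame indexed by specimen id with one column per
        measurement code.  Missing cells are NaN; stored values must be
        strictly positive and finite.
    species :
        Species label per specimen (same index as ``data``).
    side :
        Body side each specimen was measured on: ``left``, ``right`` or
        ``unknown``.  Metadata only; no correction is applied.
    """

    data: pd.DataFrame
    species: pd.Series
    side: pd.Series
    unknown_variables: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate specimen ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate variable codes: {dups}")
        values = self.data.to_numpy()
        bad = ~(np.isnan(values) | ((values > 0) & np.isfinite(values)))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                "non-positive or non-finite measurement for specimen "
                f"{self.data.index[i]!r}, variable {self.data.columns[j]!r}: "
                f"{values[i, j]!r}"
            )
        self.species = self.species.reindex(self.data.index).astype(str)
        self.side = self.side.reindex(self.data.index).fillna("unknown").astype(str)
        bad_side = sorted(set(self.side) - set(SIDES))
        if bad_side:
            raise ValidationError(f"invalid side flags: {bad_side}")
        self.unknown_variables = tuple(
            c for c in self.data.columns if c not in MEASUREMENT_CODES
        )

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def specimen_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def n_specimens(self) -> int:
        return len(self.data)

    def subset(self, species: Iterable[str]) -> "MeasurementTable":
        """Restrict to specimens belonging to the given species labels."""
        wanted = set(species)
        missing = wanted - set(self.species)
        if missing:
            raise KeyError(f"species not present in table: {sorted(missing)}")
        mask = self.species.isin(wanted)
        return MeasurementTable(
            data=self.data.loc[mask].copy(),
            species=self.species.loc[mask].copy(),
            side=self.side.loc[mask].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeasurementTable):
            return NotImplemented
        return (
            self.data.equals(other.data)
            and self.species.equals(other.species)
            and self.side.equals(other.side)
        )


@dataclass(frozen=True)
class RatioSeries:
    """Per-specimen quotient of two measurement variables (dimensionless)."""

    numerator: str
    denominator: str
    values: pd.Series
    n_excluded: int = 0

    @property
    def name(self) -> str:
        return f"{self.numerator}/{self.denominator}"


@dataclass(frozen=True)
class RangeSummary:
    """Observed [min, max] for one variable or ratio within one group."""

    group: str
    name: str
    minimum: float
    maximum: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"range summary for {self.name!r} uses no specimens")
        if self.minimum > self.maximum:
            raise ValidationError(f"min > max for {self.group}/{self.name}")


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement between two paired measurement series.

    ``bias`` is the mean difference (second series minus first),
    ``sd_diff`` the sample standard deviation of the differences, and
    ``loa_low``/``loa_high`` the limits of agreement at bias -/+ 1.96 sd.
    """

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


def read_measurement_table(
    source,
    sep: str = ",",
    id_col: str = "specimen_id",
    species_col: str = "species",
    side_col: str = "side",
) -> MeasurementTable:
    """Read a delimited per-specimen measurement table.

    The file must have a header row; ``id_col`` and ``species_col`` are
    required, ``side_col`` is optional (defaults to ``unknown``).  All
    remaining columns are treated as measurement variables.  Empty cells
    and ``NA`` denote missing values; any other non-numeric or
    non-positive cell raises :class:`ValidationError` naming the specimen
    and variable.
    """
    raw = pd.read_csv(
        source, sep=sep, dtype=str, keep_default_na=False, na_values=["", "NA"]
    )
    for col in (id_col, species_col):
        if col not in raw.columns:
            raise ValidationError(f"required column {col!r} missing from header")
    ids = raw[id_col].astype(str)
    species = raw[species_col].astype(str)
    if side_col in raw.columns:
        side = raw[side_col].fillna("unknown").astype(str)
    else:
        side = pd.Series(["unknown"] * len(raw))
    meta = {id_col, species_col, side_col}
    var_cols = [c for c in raw.columns if c not in meta]
    numeric = pd.DataFrame(index=ids, columns=var_cols, dtype=float)
    for col in var_cols:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            spec = ids[bad].iloc[0]
            raise ValidationError(
                f"non-numeric value {raw[col][bad].iloc[0]!r} for specimen "
                f"{spec!r}, variable {col!r}"
            )
        # convert through Python float() — correctly-rounded, unlike the
        # fast to_numeric parser — so text round-trips are exact
        numeric[col] = [
            float(x) if isinstance(x, str) else np.nan for x in raw[col]
        ]
    species.index = ids
    side.index = ids
    return MeasurementTable(data=numeric, species=species, side=side)


def write_measurement_table(
    table: MeasurementTable,
    target,
    sep: str = ",",
    id_col: str = "specimen_id",
    species_col: str = "species",
    side_col: str = "side",
) -> None:
    """Write a table in the same delimited layout ``read_measurement_table`` reads.

    Missing cells are written as empty fields.
    """
    out = pd.DataFrame(
        {
            id_col: table.data.index,
            species_col: table.species.to_numpy(),
            side_col: table.side.to_numpy(),
        }
    )
    for col in table.variables:
        out[col] = table.data[col].to_numpy()
    # %.17g guarantees exact binary round-trips through text
    out.to_csv(target, sep=sep, index=False, na_rep="", float_format="%.17g")


def compute_ratio(
    table: MeasurementTable, numerator: str, denominator: str
) -> RatioSeries:
    """Per-specimen ratio ``numerator / denominator``.

    Specimens missing either value are excluded and counted in
    ``n_excluded``.
    """
    for code in (numerator, denominator):
        if code not in table.variables:
            raise KeyError(f"variable {code!r} not present in table")
    num = table.data[numerator]
    den = table.data[denominator]
    ok = num.notna() & den.notna()
    values = (num[ok] / den[ok]).rename(f"{numerator}/{denominator}")
    return RatioSeries(
        numerator=numerator,
        denominator=denominator,
        values=values,
        n_excluded=int((~ok).sum()),
    )


def summarize_ranges(
    table: MeasurementTable,
    ratios: Sequence[RatioSeries] = (),
    group_by: str = "species",
) -> list[RangeSummary]:
    """Min/max per group for every measurement variable and given ratio.

    These ranges feed directly into quantitative key descriptors: the key
    retains a taxon whenever an entered value falls inside its range.
    """
    if group_by != "species":
        raise ValueError("grouping is by species label")
    summaries: list[RangeSummary] = []
    for group in sorted(table.species.unique()):
        mask = table.species == group
        if not mask.any():
            raise ValidationError(f"empty group {group!r}")
        sub = table.data.loc[mask]
        for var in table.variables:
            col = sub[var].dropna()
            if len(col) == 0:
                continue
            summaries.append(
                RangeSummary(
                    group=group,
                    name=var,
                    minimum=float(col.min()),
                    maximum=float(col.max()),
                    n=int(len(col)),
                )
            )
        for ratio in ratios:
            col = ratio.values.loc[ratio.values.index.intersection(sub.index)].dropna()
            if len(col) == 0:
                continue
            summaries.append(
                RangeSummary(
                    group=group,
                    name=ratio.name,
                    minimum=float(col.min()),
                    maximum=float(col.max()),
                    n=int(len(col)),
                )
            )
    return summaries


def ranges_to_frame(summaries: Sequence[RangeSummary]) -> pd.DataFrame:
    """Range summaries as a tidy DataFrame (columns: group, name, min, max, n)."""
    return pd.DataFrame(
        [
            {
                "group": s.group,
                "name": s.name,
                "min": s.minimum,
                "max": s.maximum,
                "n": s.n,
            }
            for s in summaries
        ]
    )


def write_range_summaries(summaries: Sequence[RangeSummary], target) -> None:
    ranges_to_frame(summaries).to_csv(target, index=False)


def bland_altman_agreement(
    series_a: Sequence[float], series_b: Sequence[float]
) -> BlandAltmanResult:
    """Bland–Altman agreement between two paired series.

    Computes the mean difference (bias), the sample SD of the
    differences, and the conventional 1.96-SD limits of agreement.  Used
    to confirm that a new gauger's measurements are interchangeable with
    an earlier gauger's before pooling their data.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be one-dimensional and equally long")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("series must be pairwise complete (no missing values)")
    n = len(a)
    if n < 2:
        raise ValueError("at least 2 pairs are required (SD undefined otherwise)")
    diff = b - a
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=n,
    )


def table_to_csv_string(table: MeasurementTable) -> str:
    buf = io.StringIO()
    write_measurement_table(table, buf)
    return buf.getvalue()
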