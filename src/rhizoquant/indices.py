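"""Germination phytotoxicity indices and frass-composition metrics.

Germination indices compare a treated sample to a distilled-water control::

    GERIR% = 100 * (G1 / G2) * (R1 / R2)     (root-based)
    GERIS% = 100 * (G1 / G2) * (S1 / S2)     (shoot-based)

where G1/G2 are germinated-seed counts and R (S) are mean root (shoot)
lengths of sample and control.  Values below a threshold — 50% in the
classical convention, 70% or 80% in stricter ones — flag the extract as
phytotoxic; values above 100% indicate stimulation and are deliberately not
capped.

Composition metrics operate on small tables of frass / frass-extract
chemistry (four frass types GNT, GT, WNT, WT under solid, "as-such" 1:5 and
equilibrated 1:2 extraction): the organic C / total N ratio that separates
amendment-like from fertilizer-like materials, the organic-matter estimate
from organic carbon (van Bemmelen-style factor 1.724), field ranges such as
the electrical-conductivity span of the extracts, and relative percent
differences between entries.  Reference tables for the four frass types are
packaged as CSV fixtures and loadable via :func:`load_composition_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GerminationRecord",
    "PhytotoxVerdict",
    "geri_r",
    "geri_s",
    "classify_phytotoxicity",
    "cn_ratio",
    "organic_matter_from_carbon",
    "field_range",
    "percent_lower",
    "load_composition_table",
    "COMPOSITION_TABLES",
]

#: Organic matter (%) = organic carbon (%) x this factor.
ORGANIC_MATTER_FACTOR = 1.724

#: Packaged composition fixtures: frass solids and the two extract types.
COMPOSITION_TABLES = ("solid_frass", "as_extracts", "e_extracts")

_TABLE_FILES = {
    "solid_frass": "table_solid_frass.csv",
    "as_extracts": "table_as_extracts.csv",
    "e_extracts": "table_e_extracts.csv",
}


@dataclass(frozen=True)
class GerminationRecord:
    """Counts and mean organ lengths for one sample/control pair.

    G1, G2: germinated-seed counts (sample, control); R1, R2: mean root
    lengths in mm; S1, S2: mean shoot lengths in mm.
    """

    G1: float
    G2: float
    R1: float = 0.0
    R2: float = 0.0
    S1: float = 0.0
    S2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("G1", "G2", "R1", "R2", "S1", "S2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def geri_r(rec: GerminationRecord) -> float:
    """Root-based germination index GERIR, in percent (not capped at 100)."""
    if rec.G2 <= 0 or rec.R2 <= 0:
        raise ValueError("GERIR needs G2 > 0 and R2 > 0 (control)")
    return 100.0 * (rec.G1 / rec.G2) * (rec.R1 / rec.R2)


def geri_s(rec: GerminationRecord) -> float:
    """Shoot-based germination index GERIS, in percent (not capped at 100)."""
    if rec.G2 <= 0 or rec.S2 <= 0:
        raise ValueError("GERIS needs G2 > 0 and S2 > 0 (control)")
    return 100.0 * (rec.G1 / rec.G2) * (rec.S1 / rec.S2)


@dataclass(frozen=True)
class PhytotoxVerdict:
    phytotoxic: bool
    index_percent: float
    threshold_percent: float


def classify_phytotoxicity(geri: float, threshold: float = 50.0) -> PhytotoxVerdict:
    """Phytotoxic iff the germination index falls below the threshold.

    Conventional thresholds are 50% (classical), 70% and 80% (stricter);
    any value in (0, 100] is accepted.
    """
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    return PhytotoxVerdict(phytotoxic=geri < threshold,
                           index_percent=float(geri),
                           threshold_percent=float(threshold))


def cn_ratio(organic_c: float, total_n: float) -> float:
    """Organic carbon / total nitrogen ratio (both in % of dry matter)."""
    if total_n <= 0:
        raise ValueError("total N must be positive")
    return organic_c / total_n


def organic_matter_from_carbon(organic_c: float) -> float:
    """Organic matter (%) estimated as organic carbon (%) x 1.724."""
    if organic_c < 0:
        raise ValueError("organic carbon must be non-negative")
    return organic_c * ORGANIC_MATTER_FACTOR


def field_range(table: pd.DataFrame, field: str,
                subset: Iterable[str] | None = None) -> tuple[float, float]:
    """(min, max) of ``field`` over the (optionally subset) table rows.

    ``table`` is indexed by sample id; ``subset`` selects row ids.  Raises
    on an empty subset or missing values in the selected rows.
    """
    rows = table if subset is None else table.loc[list(subset)]
    if len(rows) == 0:
        raise ValueError("empty subset")
    col = rows[field]
    if col.isna().any():
        raise ValueError(f"field {field!r} missing for some selected rows")
    return float(col.min()), float(col.max())


def percent_lower(a: float, b: float) -> float:
    """How much lower ``a`` is than reference ``b``: 100 * (b - a) / b."""
    if b <= 0:
        raise ValueError("reference value must be positive")
    return 100.0 * (b - a) / b


def load_composition_table(name: str) -> pd.DataFrame:
    """Load a packaged composition table, indexed by frass type id.

    ``name`` is one of ``"solid_frass"`` (solid frass chemistry),
    ``"as_extracts"`` (1:5 extracts at native water content) or
    ``"e_extracts"`` (1:2 extracts after equilibration to 85% water).
    Censored entries (below detection) are NaN.
    """
    try:
        fname = _TABLE_FILES[name]
    except KeyError:
        raise ValueError(f"unknown table {name!r}; choose from {COMPOSITION_TABLES}")
    with resources.files("rhizoquant.data").joinpath(fname).open("r") as fh:
        df = pd.read_csv(fh, index_col="sample")
    return df
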