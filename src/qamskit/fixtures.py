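"""Packaged study datasets.

The development and validation of the method rests on nine small printed
tables (screening runs, response-surface runs and ANOVA, calibration curves,
correction factors under varied conditions, relative retentions, and batch
contents). They ship verbatim as CSV inside the package and load as pandas
DataFrames; downstream modules treat them as data, never re-derive them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .exceptions import ConfigurationError
from .peaktable import ReferenceStandard, SamplePrep

__all__ = [
    "FIXTURE_NAMES",
    "load_fixture",
    "default_standards",
    "default_sample_prep",
]

#: fixture name -> (csv file, columns read as text)
_FIXTURES: dict[str, tuple[str, tuple[str, ...]]] = {
    "pbd_table1": ("pbd_table1.csv", ()),
    "ccd_table2": ("ccd_table2.csv", ()),
    "anova_table3": ("anova_table3.csv", ("term", "significance")),
    "linearity_table4": ("linearity_table4.csv", ("component_id",)),
    "cf_table5": ("cf_table5.csv", ()),
    "cf_columns_table6": ("cf_columns_table6.csv", ("column_id",)),
    "cf_instruments_table7": ("cf_instruments_table7.csv", ("instrument_id",)),
    "rrt_table8": ("rrt_table8.csv", ("instrument_id", "column_id")),
    # batch labels are opaque strings, kept exactly as printed
    "contents_table9": ("contents_table9.csv", ("batch",)),
}

FIXTURE_NAMES = tuple(_FIXTURES)


def load_fixture(table_name: str) -> pd.DataFrame:
    """Return one packaged dataset by name (see :data:`FIXTURE_NAMES`)."""
    try:
        filename, text_cols = _FIXTURES[table_name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {table_name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    with resources.files("qamskit.data").joinpath(filename).open("r") as fh:
        return pd.read_csv(fh, dtype={c: str for c in text_cols}, keep_default_na=False)


# Mixed reference solution composition and sample-prep constants used
# throughout: 0.1008 / 0.1005 / 0.1505 mg/mL of L1 / L3 / L4, and 0.5 g of
# powder extracted into 50 mL.
_STANDARD_CONCENTRATIONS = {"L1": 0.1008, "L3": 0.1005, "L4": 0.1505}


def default_standards() -> dict[str, ReferenceStandard]:
    return {
        cid: ReferenceStandard(component_id=cid, concentration=conc)
        for cid, conc in _STANDARD_CONCENTRATIONS.items()
    }


def default_sample_prep() -> SamplePrep:
    return SamplePrep(sample_mass=0.5, extract_volume=50.0)


def require_columns(df: pd.DataFrame, columns: tuple[str, ...], context: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{context}: missing column(s) {missing}")


def pbd_design():
    """The printed 12-run screening campaign as a DesignMatrix with response.

    The printed matrix is loaded as data rather than regenerated: it contains
    a repeated factor setting (runs 7 and 11) and therefore is not the
    textbook PB12 projection that :func:`qamskit.doe.make_pbd12` constructs.
    """
    from .doe import DesignMatrix, screening_factors

    df = load_fixture("pbd_table1")
    factors = screening_factors()
    actual = df[[f.name for f in factors]].to_numpy(dtype=float)
    return DesignMatrix.from_actual(factors, actual, df["resolution"].to_numpy(dtype=float))


def ccd_design():
    """The printed 13-run central-composite campaign as a DesignMatrix with response."""
    from .doe import DesignMatrix, rsm_factors

    df = load_fixture("ccd_table2")
    factors = rsm_factors()
    actual = df[[f.name for f in factors]].to_numpy(dtype=float)
    return DesignMatrix.from_actual(factors, actual, df["resolution"].to_numpy(dtype=float))
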