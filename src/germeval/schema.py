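"""Trait descriptor schemes, table validation, sigma-binning and one-hot encoding.

The central objects are:

* :class:`TraitDefinition` / :class:`TraitScheme` — the descriptor dictionary
  (trait names, categorical class lists, quantitative units), with the 17-trait
  IPGRI cardamom scheme bundled as :func:`default_scheme`;
* :class:`AccessionTable` — a validated accessions x traits table of raw values;
* :class:`BinningScheme` — the ten-level mean/SD stratification used to turn a
  quantitative trait into an ordinal class variable (level 1 below mean - 2*SD,
  then steps of 0.5*SD, level 10 at or above mean + 2*SD);
* :func:`encode_indicators` — expansion into a one-hot 0/1 indicator matrix
  with one column per (trait, class) pair.

Indicator matrices are plain :class:`pandas.DataFrame` objects with a
two-level column MultiIndex ``(trait, class)`` and accession ids as index.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DegenerateScaleError, SchemaError, TableValidationError

CATEGORICAL = "categorical"
QUANTITATIVE = "quantitative"

#: Number of sigma-bin levels for quantitative traits.
N_LEVELS = 10


@dataclass(frozen=True)
class TraitDefinition:
    """One descriptor: a named trait with either a class list or units.

    Parameters
    ----------
    name:
        Unique trait name within a scheme.
    ipgri_code:
        Descriptor code in the IPGRI catalogue (informational).
    kind:
        ``"categorical"`` or ``"quantitative"``.
    classes:
        Ordered class labels; required (>= 2) for categorical traits, empty
        for quantitative ones.
    units:
        Measurement units; required for quantitative traits.
    decimals:
        Recording precision of a quantitative trait (0 = integer counts).
    """

    name: str
    ipgri_code: str = ""
    kind: str = CATEGORICAL
    classes: tuple[str, ...] = ()
    units: str = ""
    decimals: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (CATEGORICAL, QUANTITATIVE):
            raise SchemaError(f"trait {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == CATEGORICAL:
            if len(self.classes) < 2:
                raise SchemaError(
                    f"categorical trait {self.name!r} needs >= 2 classes"
                )
            if len(set(self.classes)) != len(self.classes):
                raise SchemaError(f"trait {self.name!r}: duplicate class labels")
        else:
            if not self.units:
                raise SchemaError(
                    f"quantitative trait {self.name!r} needs non-empty units"
                )

    @property
    def is_quantitative(self) -> bool:
        return self.kind == QUANTITATIVE

    @property
    def n_classes(self) -> int:
        """Number of indicator columns this trait contributes."""
        return N_LEVELS if self.is_quantitative else len(self.classes)


@dataclass(frozen=True)
class TraitScheme:
    """An ordered collection of trait definitions with unique names."""

    traits: tuple[TraitDefinition, ...]

    def __post_init__(self) -> None:
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise SchemaError("trait names must be unique within a scheme")

    def __iter__(self):
        return iter(self.traits)

    def __len__(self) -> int:
        return len(self.traits)

    def __getitem__(self, name: str) -> TraitDefinition:
        for t in self.traits:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.traits]

    @property
    def categorical(self) -> list[TraitDefinition]:
        return [t for t in self.traits if not t.is_quantitative]

    @property
    def quantitative(self) -> list[TraitDefinition]:
        return [t for t in self.traits if t.is_quantitative]

    @property
    def n_indicator_columns(self) -> int:
        return sum(t.n_classes for t in self.traits)


def default_scheme() -> TraitScheme:
    """The 17-trait IPGRI descriptor scheme for cardamom.

    Fifteen categorical descriptors plus two quantitative ones (cluster
    internodal length in cm, capsules per cluster as counts).
    """
    c = TraitDefinition
    return TraitScheme((
        c("Height of the plant", "7.1.4", classes=("<2 m", "2-3 m", ">3 m")),
        c("Number of stems per plant", "7.1.5", classes=("<15", "16-30", "31-45", ">45")),
        c("Stem color", "7.1.6", classes=("Light green", "Green", "Yellow")),
        c("Rhizome color", "7.1.8",
          classes=("White", "Light purple", "Light green", "Dark green", "Pale light purple")),
        c("Shape of the leaf", "7.1.10", classes=("Lanceolate", "Oblong", "Oval")),
        c("Pubescence of the leaf", "7.1.12", classes=("Glabra", "Dense", "Spaced")),
        c("Panicle type", "7.2.4", classes=("Creeping", "Semi-erect", "Erect")),
        c("Number of panicles per stem", "7.2.6", classes=("1", "2", ">3")),
        c("Number of panicles per plant", "7.2.5", classes=("<10", "11-20", "21-30", ">31")),
        c("Panicle length", "7.2.7", classes=("<50 cm", "51-75 cm", "76-100 cm", ">100 cm")),
        c("Number of clusters per panicle", "7.2.8", classes=("<20", "20-30", "30-40")),
        c("Cluster internodal length", "7.2.10", kind=QUANTITATIVE, units="cm", decimals=1),
        c("Panicle branching", "7.2.11", classes=("Presence", "Absence")),
        c("Panicle branching pattern", "7.2.11.1", classes=("Proximal", "Not branching pattern")),
        c("Number of capsules per cluster", "7.2.20", kind=QUANTITATIVE, units="count", decimals=0),
        c("Capsule form", "7.2.21", classes=("Ellipsoid", "Globose", "Ovoid")),
        c("Capsule color", "7.2.23", classes=("Yellow", "Green", "Dark green", "Light green")),
    ))


# ---------------------------------------------------------------------------
# scheme serialization

def scheme_to_yaml(scheme: TraitScheme) -> str:
    """Serialize a scheme to YAML (round-trips with :func:`scheme_from_yaml`)."""
    payload = [
        {
            "name": t.name,
            "ipgri_code": t.ipgri_code,
            "kind": t.kind,
            "classes": list(t.classes),
            "units": t.units,
            "decimals": t.decimals,
        }
        for t in scheme
    ]
    return yaml.safe_dump(payload, sort_keys=False, allow_unicode=True)


def scheme_from_yaml(text: str) -> TraitScheme:
    payload = yaml.safe_load(text)
    if not isinstance(payload, list):
        raise SchemaError("scheme YAML must be a list of trait mappings")
    traits = tuple(
        TraitDefinition(
            name=entry["name"],
            ipgri_code=entry.get("ipgri_code", ""),
            kind=entry.get("kind", CATEGORICAL),
            classes=tuple(entry.get("classes") or ()),
            units=entry.get("units", ""),
            decimals=int(entry.get("decimals", 0)),
        )
        for entry in payload
    )
    return TraitScheme(traits)


# ---------------------------------------------------------------------------
# accession tables

@dataclass(frozen=True)
class AccessionTable:
    """Validated accessions x traits table.

    ``data`` has accession ids as index (unique, in input order) and one
    column per scheme trait; categorical cells hold class labels, quantitative
    cells hold finite non-negative floats.
    """

    data: pd.DataFrame

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n(self) -> int:
        return len(self.data)

    def subset(self, ids: Iterable[str]) -> "AccessionTable":
        ids = list(ids)
        missing = [i for i in ids if i not in self.data.index]
        if missing:
            raise TableValidationError(f"unknown accession ids: {missing}")
        return AccessionTable(self.data.loc[ids])


def validate_table(data: pd.DataFrame, scheme: TraitScheme) -> AccessionTable:
    """Check a raw DataFrame against a scheme and wrap it.

    Raises :class:`SchemaError` for missing trait columns and
    :class:`TableValidationError` for duplicate ids, unknown class labels,
    missing cells, or non-numeric / negative quantitative values, naming the
    offending row and column.
    """
    missing_cols = [t.name for t in scheme if t.name not in data.columns]
    if missing_cols:
        raise SchemaError(f"missing trait columns: {missing_cols}")

    dup = data.index[data.index.duplicated()].unique().tolist()
    if dup:
        raise TableValidationError(f"duplicate accession ids: {dup}")

    out = {}
    for trait in scheme:
        col = data[trait.name]
        if col.isna().any():
            rows = data.index[col.isna()].tolist()
            raise TableValidationError(
                f"missing values for trait {trait.name!r} in rows {rows}"
            )
        if trait.is_quantitative:
            numeric = pd.to_numeric(col, errors="coerce")
            bad = data.index[numeric.isna()].tolist()
            if bad:
                raise TableValidationError(
                    f"non-numeric value for quantitative trait {trait.name!r} "
                    f"in rows {bad}"
                )
            vals = numeric.astype(float)
            if not np.all(np.isfinite(vals)) or (vals < 0).any():
                bad = data.index[~np.isfinite(vals) | (vals < 0)].tolist()
                raise TableValidationError(
                    f"quantitative trait {trait.name!r} must be finite and "
                    f">= 0; offending rows {bad}"
                )
            out[trait.name] = vals
        else:
            labels = col.astype(str)
            unknown = ~labels.isin(trait.classes)
            if unknown.any():
                row = data.index[unknown][0]
                val = labels[unknown].iloc[0]
                raise TableValidationError(
                    f"unknown class {val!r} for trait {trait.name!r} in row "
                    f"{row!r}; allowed classes: {list(trait.classes)}"
                )
            out[trait.name] = labels
    frame = pd.DataFrame(out, index=data.index.astype(str))
    frame.index.name = "accession_id"
    return AccessionTable(frame[scheme.names])


def load_accession_table(path: str | Path | io.TextIOBase,
                         scheme: TraitScheme) -> AccessionTable:
    """Read a CSV/TSV accession table (first column = accession id) and validate.

    The delimiter is sniffed from the extension (``.tsv`` -> tab, else comma).
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, index_col=0)
    raw.index = raw.index.astype(str)
    return validate_table(raw, scheme)


def write_accession_table(table: AccessionTable, path: str | Path) -> None:
    table.data.to_csv(path)


# ---------------------------------------------------------------------------
# sigma binning

@dataclass(frozen=True)
class BinningScheme:
    """Ten-level stratification of a quantitative trait around its mean.

    Boundary k (k = 1..9) sits at ``mean + (-2 + 0.5*(k-1)) * sd``; level 1 is
    everything below ``mean - 2*sd`` and level 10 everything at or above
    ``mean + 2*sd``.  Interior levels are half-open ``[lower, upper)``
    intervals of width ``0.5*sd``.
    """

    mean: float
    sd: float
    boundaries: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean) or not np.isfinite(self.sd):
            raise DegenerateScaleError("mean/sd must be finite")
        if self.sd <= 0:
            raise DegenerateScaleError("sd must be positive for sigma-binning")
        if not self.boundaries:
            bounds = tuple(
                float(self.mean + (-2.0 + 0.5 * k) * self.sd) for k in range(9)
            )
            object.__setattr__(self, "boundaries", bounds)
        if len(self.boundaries) != 9 or np.any(np.diff(self.boundaries) <= 0):
            raise DegenerateScaleError("boundaries must be 9 strictly increasing cuts")

    @property
    def n_levels(self) -> int:
        return N_LEVELS


def make_binning(values: Sequence[float]) -> BinningScheme:
    """Fit a :class:`BinningScheme` from observed values (sample SD, n-1)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2 or not np.all(np.isfinite(arr)):
        raise DegenerateScaleError("need >= 2 finite values to fit a binning")
    sd = float(np.std(arr, ddof=1))
    if sd == 0.0:
        raise DegenerateScaleError("constant input: sd is zero")
    return BinningScheme(mean=float(np.mean(arr)), sd=sd)


def assign_level(x: float | np.ndarray, b: BinningScheme) -> int | np.ndarray:
    """Map value(s) to levels 1..10 (left-closed interior intervals)."""
    lev = np.searchsorted(np.asarray(b.boundaries), np.asarray(x, dtype=float),
                          side="right") + 1
    if np.ndim(x) == 0:
        return int(lev)
    return lev.astype(int)


# ---------------------------------------------------------------------------
# indicator encoding

def level_labels() -> list[str]:
    """Class labels used for the ten quantitative bin levels."""
    return [f"L{k}" for k in range(1, N_LEVELS + 1)]


def fit_binnings(table: AccessionTable, scheme: TraitScheme
                 ) -> dict[str, BinningScheme]:
    """Fit a sigma-binning for every quantitative trait from the table itself."""
    return {
        t.name: make_binning(table.data[t.name].to_numpy(dtype=float))
        for t in scheme.quantitative
    }


def encode_indicators(table: AccessionTable, scheme: TraitScheme,
                      bins: Mapping[str, BinningScheme] | None = None
                      ) -> pd.DataFrame:
    """Expand a table into a one-hot 0/1 indicator matrix.

    Column order follows scheme order then class order; each quantitative
    trait contributes ten level columns (``L1``..``L10``).  ``bins`` may be
    omitted, in which case binnings are fit from the table.
    """
    if bins is None:
        bins = fit_binnings(table, scheme)
    for t in scheme.quantitative:
        if t.name not in bins:
            raise SchemaError(f"no binning provided for quantitative trait {t.name!r}")

    n = table.n
    blocks = []
    for trait in scheme:
        if trait.is_quantitative:
            classes = level_labels()
            levels = assign_level(
                table.data[trait.name].to_numpy(dtype=float), bins[trait.name]
            )
            codes = np.asarray(levels) - 1
        else:
            classes = list(trait.classes)
            index = {c: i for i, c in enumerate(classes)}
            codes = table.data[trait.name].map(index).to_numpy()
        block = np.zeros((n, len(classes)), dtype=np.int8)
        block[np.arange(n), codes] = 1
        cols = pd.MultiIndex.from_product([[trait.name], classes],
                                          names=["trait", "class"])
        blocks.append(pd.DataFrame(block, index=table.data.index, columns=cols))
    return pd.concat(blocks, axis=1)


def decode_indicators(matrix: pd.DataFrame, scheme: TraitScheme) -> pd.DataFrame:
    """Invert :func:`encode_indicators` by argmax within each trait block.

    Categorical traits recover their class labels; quantitative traits
    recover their bin-level labels (``L1``..``L10``), not the raw values.
    """
    out = {}
    for trait in scheme:
        block = matrix[trait.name]
        out[trait.name] = block.columns[np.argmax(block.to_numpy(), axis=1)]
    return pd.DataFrame(out, index=matrix.index)


def indicator_matrix_to_csv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write an indicator matrix with ``trait|class`` compound headers."""
    flat = matrix.copy()
    flat.columns = [f"{t}|{c}" for t, c in matrix.columns]
    flat.to_csv(path)
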