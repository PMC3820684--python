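"""Length-frequency catch tables for multi-gear selectivity estimation.

A catch table holds counts (or per-gear normalised frequencies) of fish by
1-cm length class for several capture methods at once: gillnets of known
mesh size and free-form "predator" gears such as a piscivorous bird whose
diet has been reconstructed from pellets.  Gears are identified by short
labels; labels of the form ``G<mesh>`` (e.g. ``G14``, ``G21.5``) are parsed
as mesh nets with the mesh size in mm, any other label must be declared as
a predator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GearSpec",
    "CatchTable",
    "CatchTableError",
    "read_catch_table",
    "write_catch_table",
    "normalize",
    "load_perch_catches",
]

_MESH_ID = re.compile(r"^G(\d+(?:\.\d+)?)$")


class CatchTableError(ValueError):
    """Raised for invalid catch-table contents or layouts."""


@dataclass(frozen=True)
class GearSpec:
    """One capture method: a mesh net (``family='mesh'``) or a predator.

    Parameters
    ----------
    id : str
        Short gear label, unique within a table (e.g. ``"G14"``, ``"GC"``).
    family : {'mesh', 'predator'}
    mesh_size : float, optional
        Bar mesh size in mm; required (and > 0) iff ``family='mesh'``.
    """

    id: str
    family: str
    mesh_size: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("mesh", "predator"):
            raise CatchTableError(
                f"gear {self.id!r}: family must be 'mesh' or 'predator', "
                f"got {self.family!r}"
            )
        if self.family == "mesh":
            if self.mesh_size is None or not np.isfinite(self.mesh_size) \
                    or self.mesh_size <= 0:
                raise CatchTableError(
                    f"mesh gear {self.id!r} needs a finite positive mesh_size "
                    f"(mm), got {self.mesh_size!r}"
                )
        elif self.mesh_size is not None:
            raise CatchTableError(
                f"predator gear {self.id!r} must not carry a mesh_size"
            )

    @classmethod
    def from_id(cls, gear_id: str,
                declarations: Mapping[str, dict] | None = None) -> "GearSpec":
        """Build a spec from a column label, honouring explicit declarations."""
        if declarations and gear_id in declarations:
            d = declarations[gear_id]
            return cls(id=gear_id, family=d.get("family", "predator"),
                       mesh_size=d.get("mesh_size"))
        m = _MESH_ID.match(gear_id)
        if m:
            return cls(id=gear_id, family="mesh", mesh_size=float(m.group(1)))
        raise CatchTableError(
            f"gear id {gear_id!r} is not of the form 'G<mesh-mm>' and has no "
            f"predator/mesh declaration"
        )


class CatchTable:
    """Counts (or normalised frequencies) by length class x gear.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative values; index = representative lengths in cm (strictly
        increasing), columns = gear ids matching ``gears``.
    gears : sequence of GearSpec
    is_normalized : bool
        True when each gear column has been divided by its own sum.
    """

    def __init__(self, counts: pd.DataFrame, gears: Sequence[GearSpec],
                 is_normalized: bool = False) -> None:
        gears = list(gears)
        ids = [g.id for g in gears]
        if len(set(ids)) != len(ids):
            raise CatchTableError(f"duplicate gear ids: {ids}")
        if list(counts.columns) != ids:
            raise CatchTableError(
                f"column labels {list(counts.columns)} do not match gear ids {ids}"
            )
        idx = np.asarray(counts.index, dtype=float)
        if len(idx) == 0:
            raise CatchTableError("table has no length classes")
        if not np.all(np.diff(idx) > 0):
            raise CatchTableError("length classes must be strictly increasing")
        values = counts.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise CatchTableError("non-finite entries in catch table")
        neg = np.argwhere(values < 0)
        if neg.size:
            j, i = neg[0]
            raise CatchTableError(
                f"negative count at (gear={ids[i]!r}, "
                f"length_class={idx[j]:g}): {values[j, i]}"
            )
        if is_normalized:
            sums = values.sum(axis=0)
            bad = np.where(np.abs(sums - 1.0) > 1e-9)[0]
            if bad.size:
                raise CatchTableError(
                    f"is_normalized=True but column {ids[bad[0]]!r} sums to "
                    f"{sums[bad[0]]!r}"
                )
        self._df = pd.DataFrame(values, index=pd.Index(idx, name="length_class"),
                                columns=list(ids))
        self.gears = gears
        self.is_normalized = bool(is_normalized)

    # -- accessors ---------------------------------------------------------
    @property
    def counts(self) -> pd.DataFrame:
        """The values as a DataFrame (length class x gear)."""
        return self._df

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def length_classes(self) -> np.ndarray:
        return self._df.index.to_numpy()

    @property
    def gear_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def n_classes(self) -> int:
        return self._df.shape[0]

    @property
    def n_gears(self) -> int:
        return self._df.shape[1]

    def gear(self, gear_id: str) -> GearSpec:
        for g in self.gears:
            if g.id == gear_id:
                return g
        raise KeyError(
            f"unknown gear {gear_id!r}; known: {self.gear_ids}"
        )

    def column_totals(self) -> pd.Series:
        return self._df.sum(axis=0)

    def grand_total(self) -> float:
        return float(self._df.to_numpy().sum())

    def equals(self, other: "CatchTable", tol: float = 1e-12) -> bool:
        return (
            self.gear_ids == other.gear_ids
            and self.gears == other.gears
            and self.is_normalized == other.is_normalized
            and np.allclose(self.length_classes, other.length_classes,
                            rtol=0, atol=tol)
            and np.allclose(self.values, other.values, rtol=0, atol=tol)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "frequencies" if self.is_normalized else "counts"
        return (f"<CatchTable {self.n_classes} length classes x "
                f"{self.n_gears} gears ({kind})>")


def normalize(table: CatchTable) -> CatchTable:
    """Divide each gear column by its own sum (per-gear frequencies).

    The per-gear conditional length distribution is what the selectivity
    likelihood actually constrains; dividing out the column totals removes
    unknown, gear-specific fishing powers.  Zero cells stay zero.
    """
    if table.is_normalized:
        raise CatchTableError("table is already normalized")
    sums = table.counts.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise CatchTableError(
            f"cannot normalize: gear column {zero.index[0]!r} is all zero"
        )
    return CatchTable(table.counts / sums, table.gears, is_normalized=True)


# ---------------------------------------------------------------------------
# delimited-text I/O


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _scan_metadata(path: Path) -> tuple[dict, int]:
    """Read ``# key: value`` comment headers; return (metadata, n header lines)."""
    meta: dict = {}
    n = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta, n


def read_catch_table(source, layout: str = "wide",
                     gear_declarations: Mapping[str, dict] | None = None,
                     ) -> CatchTable:
    """Read a catch table from delimited text (CSV, or TSV by extension).

    Parameters
    ----------
    source : path-like
    layout : {'wide', 'long'}
        Wide: first column ``length_class``, remaining columns one per gear.
        Long: columns ``gear, length_class, count`` in any row order.
    gear_declarations : mapping, optional
        ``id -> {'family': ..., 'mesh_size': ...}`` for ids not matching the
        ``G<mesh>`` pattern.  A ``# predators: ID[,ID...]`` comment header in
        the file declares predator gears the same way.

    Returns
    -------
    CatchTable
        With ``is_normalized`` taken from a ``# normalized: true`` header
        (absent means counts).
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    meta, skip = _scan_metadata(path)
    decls = dict(gear_declarations or {})
    for pid in filter(None, (s.strip() for s in
                             meta.get("predators", "").split(","))):
        decls.setdefault(pid, {"family": "predator"})
    is_norm = meta.get("normalized", "false").lower() == "true"
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, skiprows=skip)

    if layout == "wide":
        if df.columns[0] != "length_class":
            raise CatchTableError(
                f"wide layout needs first column 'length_class', got "
                f"{df.columns[0]!r}"
            )
        df = df.set_index("length_class").sort_index()
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise CatchTableError(f"duplicate length class {dup:g}")
        gears = [GearSpec.from_id(str(c), decls) for c in df.columns]
        wide = df
    elif layout == "long":
        required = {"gear", "length_class", "count"}
        if not required.issubset(df.columns):
            raise CatchTableError(
                f"long layout needs columns {sorted(required)}, got "
                f"{list(df.columns)}"
            )
        dup = df.duplicated(subset=["gear", "length_class"])
        if dup.any():
            row = df[dup].iloc[0]
            raise CatchTableError(
                f"duplicate (gear, length_class) pair "
                f"({row['gear']!r}, {row['length_class']:g})"
            )
        wide = (df.pivot(index="length_class", columns="gear", values="count")
                  .fillna(0.0).sort_index())
        order = list(dict.fromkeys(df["gear"]))  # first-appearance order
        wide = wide[order]
        wide.columns = [str(c) for c in wide.columns]
        gears = [GearSpec.from_id(c, decls) for c in wide.columns]
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")

    table = CatchTable(wide, gears, is_normalized=is_norm)
    sums = table.counts.sum(axis=0)
    if (sums <= 0).any():
        bad = sums.index[sums <= 0][0]
        raise CatchTableError(f"gear column {bad!r} has no catches")
    return table


def write_catch_table(table: CatchTable, dest, layout: str = "wide") -> None:
    """Write a table as delimited text; ``read_catch_table`` round-trips it.

    Metadata (normalisation flag, predator declarations) travels in ``#``
    comment headers so the file remains a plain CSV/TSV.
    """
    if not isinstance(table, CatchTable):
        raise TypeError("expected a CatchTable")
    if table.n_gears == 0:
        raise CatchTableError("refusing to write a table with no gears")
    path = Path(dest)
    sep = _sep_for(path)
    predators = [g.id for g in table.gears if g.family == "predator"]
    header = [f"# normalized: {'true' if table.is_normalized else 'false'}"]
    if predators:
        header.append("# predators: " + ",".join(predators))
    fmt = lambda x: repr(float(x))  # repr round-trips doubles exactly
    lines = list(header)
    if layout == "wide":
        lines.append(sep.join(["length_class"] + table.gear_ids))
        for lc, row in zip(table.length_classes, table.values):
            lines.append(sep.join([f"{lc:g}"] + [fmt(v) for v in row]))
    elif layout == "long":
        lines.append(sep.join(["gear", "length_class", "count"]))
        for i, gid in enumerate(table.gear_ids):
            for lc, v in zip(table.length_classes, table.values[:, i]):
                lines.append(sep.join([gid, f"{lc:g}", fmt(v)]))
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_perch_catches() -> CatchTable:
    """The bundled Curonian Lagoon European perch dataset.

    Catch numbers by 1-cm length class (2-35 cm) for eight gillnets
    (14-45 mm mesh) and Great Cormorants ("GC", lengths reconstructed from
    pellets); 4663 fish in total, 3766 of them taken by cormorants.
    """
    path = Path(__file__).parent / "datasets" / "perch_curonian_lagoon.csv"
    return read_catch_table(path, layout="wide")
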