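"""Mapping from SCP-ECG diagnostic statements to ordinal critical values.

Each of the 71 SCP-ECG statement codes carries exactly one critical value:
0 (no risk) < 1 (low risk) < 2 (medium risk) < 3 (high risk). A record with
several statements receives the maximum value over its statements, so a
normal-rhythm annotation never masks a co-occurring high-risk finding and
every record lands in exactly one class.
"""

from __future__ import annotations

import ast
from importlib import resources

import pandas as pd

__all__ = [
    "CRITICAL_VALUES",
    "MappingTable",
    "UnknownStatementError",
    "UnlabelableRecordError",
    "load_mapping",
    "statement_to_value",
    "record_value",
    "parse_scp_codes",
    "label_dataset",
]

#: the four ordered risk levels
CRITICAL_VALUES = (0, 1, 2, 3)

_EXPECTED_TOTAL = 71
_EXPECTED_CLASS_SIZES = {0: 3, 1: 28, 2: 26, 3: 14}


class UnknownStatementError(KeyError):
    """A statement code absent from the mapping table."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code

    def __str__(self):
        return f"unknown SCP-ECG statement code: {self.code!r}"


class UnlabelableRecordError(ValueError):
    """A record whose statement set yields no critical value."""


class MappingTable:
    """Immutable association of statement code -> critical value."""

    def __init__(self, frame: pd.DataFrame):
        self._frame = frame
        self._lookup: dict[str, int] = dict(
            zip(frame["code"], frame["critical_value"].astype(int)))

    def __len__(self) -> int:
        return len(self._lookup)

    def __contains__(self, code: str) -> bool:
        return code in self._lookup

    def __getitem__(self, code: str) -> int:
        try:
            return self._lookup[code]
        except KeyError:
            raise UnknownStatementError(code) from None

    @property
    def codes(self) -> list[str]:
        return list(self._lookup)

    def class_sizes(self) -> dict[int, int]:
        """Number of codes mapped to each critical value."""
        sizes = {v: 0 for v in CRITICAL_VALUES}
        for v in self._lookup.values():
            sizes[v] += 1
        return sizes

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()


def load_mapping() -> MappingTable:
    """Load the packaged statement -> critical-value table and validate it.

    Raises ``ValueError`` naming the offending code if the resource is
    corrupted (duplicate code, out-of-range value, wrong partition).
    """
    with resources.files("cardiov.data").joinpath(
            "critical_value_map.csv").open() as fh:
        frame = pd.read_csv(fh, dtype={"code": str, "critical_value": int})
    frame["code"] = frame["code"].str.strip()
    dup = frame["code"][frame["code"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicated statement code in mapping table: "
                         f"{dup.iloc[0]!r}")
    bad = frame.loc[~frame["critical_value"].isin(CRITICAL_VALUES), "code"]
    if not bad.empty:
        raise ValueError(f"statement code {bad.iloc[0]!r} has a critical value "
                         f"outside 0..3")
    table = MappingTable(frame)
    if len(table) != _EXPECTED_TOTAL:
        raise ValueError(f"mapping table must hold {_EXPECTED_TOTAL} codes, "
                         f"found {len(table)}")
    sizes = table.class_sizes()
    if sizes != _EXPECTED_CLASS_SIZES:
        raise ValueError(f"mapping table class sizes {sizes} differ from the "
                         f"expected partition {_EXPECTED_CLASS_SIZES}")
    return table


def statement_to_value(code: str, table: MappingTable) -> int:
    """Critical value of a single statement code (raises on unknown codes)."""
    return table[code.strip()]


def record_value(codes, table: MappingTable) -> int:
    """Critical value of a record: the maximum over its known statements.

    Raises :class:`UnlabelableRecordError` when the set is empty or no code
    is known.
    """
    values = [table[c] for c in (str(c).strip() for c in codes) if c in table]
    if not values:
        raise UnlabelableRecordError(
            f"no known statement among {sorted(str(c) for c in codes)!r}")
    return max(values)


def parse_scp_codes(raw) -> set[str]:
    """Parse a PTB-XL ``scp_codes`` cell into a set of statement codes.

    The cell is the string form of a dict mapping code -> likelihood; the
    likelihood is ignored (every listed code counts).
    """
    if isinstance(raw, dict):
        return {str(k).strip() for k in raw}
    if isinstance(raw, (set, list, tuple)):
        return {str(c).strip() for c in raw}
    parsed = ast.literal_eval(str(raw))
    if isinstance(parsed, dict):
        return {str(k).strip() for k in parsed}
    return {str(c).strip() for c in parsed}


def label_dataset(metadata: pd.DataFrame, table: MappingTable,
                  scp_column: str = "scp_codes"):
    """Assign one critical value per record of a PTB-XL-shaped metadata table.

    Parameters
    ----------
    metadata : DataFrame indexed by record id (or with any index), carrying a
        ``scp_codes`` column in PTB-XL's serialized-dict form.
    table : the statement mapping.

    Returns
    -------
    labels : Series of critical values indexed like ``metadata``, only for
        labelable records.
    counts : dict value -> number of records.
    unlabelable : list of index entries that could not be labeled (reported,
        never silently dropped).
    """
    labels = {}
    unlabelable = []
    for idx, raw in metadata[scp_column].items():
        try:
            labels[idx] = record_value(parse_scp_codes(raw), table)
        except (UnlabelableRecordError, ValueError, SyntaxError):
            unlabelable.append(idx)
    series = pd.Series(labels, dtype=int)
    series = series.reindex([i for i in metadata.index if i in labels])
    counts = {v: int((series == v).sum()) for v in CRITICAL_VALUES}
    return series, counts, unlabelable
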