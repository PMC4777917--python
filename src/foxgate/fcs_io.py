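"""Reading and writing flow-cytometry event data.

Two on-disk dialects are supported: FCS 2.0 ("analog", FACSCalibur-style)
and FCS 3.0 ("digital", LSR Fortessa-style), list mode only, plus a plain
CSV representation.  Channel names in a file are mapped onto the six
semantic roles the pipeline uses (FSC, SSC, CD4, CD45RO, CD25, FOXP3).

Values are always read *as stored*: no de-logging or rescaling happens
here.  All transforms (boundary removal, log, standardization) are owned
by :mod:`foxgate.preprocess`, which tracks them through
``EventTable.scale_state``.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical channel-role order used by every array in the package.
ROLES = ("FSC", "SSC", "CD4", "CD45RO", "CD25", "FOXP3")

#: Roles measured by fluorescence (log-transformable); FSC/SSC are scatter.
FLUOR_ROLES = ("CD4", "CD45RO", "CD25", "FOXP3")

DIALECTS = ("analog", "digital")


class ChannelMapError(KeyError):
    """A required channel role is missing or ambiguous."""


@dataclass(frozen=True)
class ChannelMap:
    """Mapping from the six semantic roles to instrument channel names."""

    roles: dict[str, str]

    def __post_init__(self) -> None:
        missing = [r for r in ROLES if r not in self.roles]
        if missing:
            raise ChannelMapError(f"channel map missing roles: {missing}")
        names = list(self.roles.values())
        if len(set(names)) != len(names):
            raise ChannelMapError(f"channel names not unique: {names}")

    def name(self, role: str) -> str:
        return self.roles[role]

    @classmethod
    def default(cls) -> "ChannelMap":
        return cls({"FSC": "FSC-A", "SSC": "SSC-A", "CD4": "FL3-A",
                    "CD45RO": "FL1-A", "CD25": "FL2-A", "FOXP3": "FL4-A"})

    @classmethod
    def from_pairs(cls, pairs: list[str]) -> "ChannelMap":
        """Build from ``role=channel`` strings (CLI ``--channel-map``)."""
        roles = {}
        for p in pairs:
            role, _, name = p.partition("=")
            roles[role.strip()] = name.strip()
        return cls(roles)


@dataclass
class EventTable:
    """Rectangular event-by-channel data, the pipeline's universal currency.

    Parameters
    ----------
    values
        ``(n_events, 6)`` float array, columns ordered as :data:`ROLES`.
    dialect
        ``"analog"`` or ``"digital"``; decides boundary thresholds later.
    scale_state
        Per-role state, one of ``raw``, ``logged``, ``standardized``.
    metadata
        Free-form provenance (source path, generator seed, ...).
    """

    values: np.ndarray
    dialect: str
    scale_state: dict[str, str] = field(default_factory=lambda: {r: "raw" for r in ROLES})
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(ROLES):
            raise ValueError(f"values must be (n, {len(ROLES)}), got {self.values.shape}")
        if self.dialect not in DIALECTS:
            raise ValueError(f"dialect must be one of {DIALECTS}, got {self.dialect!r}")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def column(self, role: str) -> np.ndarray:
        return self.values[:, ROLES.index(role)]

    def is_raw(self) -> bool:
        return all(s == "raw" for s in self.scale_state.values())

    def copy(self) -> "EventTable":
        return EventTable(self.values.copy(), self.dialect,
                          dict(self.scale_state), dict(self.metadata))

    def subset(self, index: np.ndarray) -> "EventTable":
        return EventTable(self.values[index], self.dialect,
                          dict(self.scale_state), dict(self.metadata))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(ROLES))


# ---------------------------------------------------------------------------
# FCS container: HEADER + delimited TEXT segment + binary DATA segment.
# ---------------------------------------------------------------------------

_VERSION_DIALECT = {"FCS2.0": "analog", "FCS3.0": "digital", "FCS3.1": "digital"}


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise ValueError("empty FCS TEXT segment")
    delim = raw[0:1].decode("latin-1")
    body = raw.decode("latin-1")[1:]
    if body.endswith(delim):
        body = body[:-1]
    # Doubled delimiters escape a literal delimiter inside a value.
    sentinel = "\x00\x01"
    body = body.replace(delim + delim, sentinel)
    parts = [p.replace(sentinel, delim) for p in body.split(delim)]
    if len(parts) % 2:
        parts = parts[:-1]
    return {parts[i].strip().upper(): parts[i + 1] for i in range(0, len(parts), 2)}


def _np_dtype(keywords: dict[str, str], n_par: int) -> np.dtype:
    datatype = keywords.get("$DATATYPE", "F").upper()
    byteord = keywords.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    order = "<" if little else ">"
    bits = {int(keywords.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)}
    if len(bits) != 1:
        raise ValueError(f"mixed per-parameter bit widths unsupported: {bits}")
    nbytes = bits.pop() // 8
    if datatype == "F":
        return np.dtype(f"{order}f4")
    if datatype == "D":
        return np.dtype(f"{order}f8")
    if datatype == "I":
        return np.dtype(f"{order}u{nbytes}")
    raise ValueError(f"unsupported $DATATYPE {datatype!r}")


def read_fcs(path: str | Path, channel_map: ChannelMap | None = None,
             dialect: str | None = None) -> EventTable:
    """Read a list-mode FCS 2.0/3.x file and map channels to roles.

    Parameters
    ----------
    channel_map
        Role-to-channel-name mapping; defaults to :meth:`ChannelMap.default`.
    dialect
        Override the version-derived dialect (2.0 -> analog, 3.x -> digital).
    """
    channel_map = channel_map or ChannelMap.default()
    data = Path(path).read_bytes()
    version = data[0:6].decode("ascii", errors="replace")
    if version not in _VERSION_DIALECT:
        raise ValueError(f"unsupported FCS version {version!r}")
    text_start, text_end = int(data[10:18]), int(data[18:26])
    keywords = _parse_text_segment(data[text_start:text_end + 1])

    data_start = int(data[26:34] or b"0") or int(keywords.get("$BEGINDATA", 0))
    data_end = int(data[34:42] or b"0") or int(keywords.get("$ENDDATA", 0))
    if keywords.get("$MODE", "L").upper() != "L":
        raise ValueError("only list-mode ($MODE=L) FCS data is supported")

    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    names = [keywords.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    dtype = _np_dtype(keywords, n_par)

    raw = data[data_start:data_end + 1]
    arr = np.frombuffer(raw[: n_par * n_tot * dtype.itemsize], dtype=dtype)
    arr = arr.reshape(n_tot, n_par).astype(np.float64)

    cols = []
    for role in ROLES:
        name = channel_map.name(role)
        if name not in names:
            raise ChannelMapError(
                f"channel {name!r} for role {role!r} not present in file "
                f"(channels: {names})")
        cols.append(arr[:, names.index(name)])
    values = np.column_stack(cols) if n_tot else np.empty((0, len(ROLES)))
    inferred = dialect or _VERSION_DIALECT[version]
    return EventTable(values, inferred, metadata={
        "source": str(path), "fcs_version": version, "channels": names})


def write_fcs(table: EventTable, path: str | Path, version: str = "FCS3.0",
              channel_map: ChannelMap | None = None) -> None:
    """Write a raw-scale table as a list-mode FCS file ($DATATYPE F)."""
    if version not in _VERSION_DIALECT:
        raise ValueError(f"unsupported FCS version {version!r}")
    if not table.is_raw():
        raise ValueError(
            "only raw-scale tables may be written to FCS; transformed data "
            "must not masquerade as instrument data")
    channel_map = channel_map or ChannelMap.default()
    names = [channel_map.name(r) for r in ROLES]
    n_tot, n_par = table.n_events, len(ROLES)
    payload = table.values.astype("<f4").tobytes()

    delim = "/"
    kw = {
        "$MODE": "L", "$DATATYPE": "F", "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par), "$TOT": str(n_tot), "$NEXTDATA": "0",
    }
    for i, name in enumerate(names, start=1):
        kw[f"$P{i}N"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = "262144"
    # Data offset depends on TEXT length which depends on the offset digits;
    # iterate to the fixed point (stabilizes in <= 3 passes).
    header_len = 58
    text_start = header_len

    def render(begin: int) -> str:
        kw["$BEGINDATA"] = str(begin)
        kw["$ENDDATA"] = str(max(begin + len(payload) - 1, 0))
        return delim + delim.join(
            f"{k}{delim}{v.replace(delim, delim * 2)}" for k, v in kw.items()) + delim

    begin_data = 0
    for _ in range(5):
        text = render(begin_data)
        new_begin = text_start + len(text)
        if new_begin == begin_data:
            break
        begin_data = new_begin
    text = render(begin_data)
    text_end = text_start + len(text) - 1
    data_end = begin_data + len(payload) - 1 if payload else 0
    header = (f"{version}    "
              f"{text_start:>8d}{text_end:>8d}"
              f"{begin_data if payload else 0:>8d}{max(data_end, 0):>8d}"
              f"{0:>8d}{0:>8d}")
    assert len(header) == header_len, len(header)
    Path(path).write_bytes(header.encode("ascii") + text.encode("latin-1") + payload)


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

LABEL_COLUMN = "label"


def write_csv(table: EventTable, path: str | Path,
              labels: np.ndarray | None = None) -> None:
    """Write events (and an optional ground-truth/label column) as CSV."""
    df = table.to_dataframe()
    if labels is not None:
        if len(labels) != table.n_events:
            raise ValueError("labels length must match event count")
        df[LABEL_COLUMN] = labels
    header = (f"# dialect={table.dialect} "
              f"seed={table.metadata.get('seed', 'NA')}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> tuple[EventTable, np.ndarray | None]:
    """Read a CSV written by :func:`write_csv`; returns (table, labels|None)."""
    with open(path) as fh:
        first = fh.readline()
        dialect = "analog"
        if first.startswith("#"):
            for tok in first[1:].split():
                if tok.startswith("dialect="):
                    dialect = tok.split("=", 1)[1]
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    missing = [r for r in ROLES if r not in df.columns]
    if missing:
        raise ChannelMapError(f"CSV missing role columns: {missing}")
    labels = df[LABEL_COLUMN].to_numpy() if LABEL_COLUMN in df.columns else None
    table = EventTable(df[list(ROLES)].to_numpy(float), dialect,
                       metadata={"source": str(path)})
    return table, labels
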