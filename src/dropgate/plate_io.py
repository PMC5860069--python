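"""Reading and writing QuantaSoft-style droplet amplitude CSV files.

Bio-Rad's QuantaSoft exports one amplitude CSV per well, with a header row
and one droplet per data row. Header matching is whitespace-insensitive and
case-insensitive, so both ``Ch1 Amplitude`` and ``Ch1Amplitude`` dialects
are accepted. An optional vendor ``Cluster`` column of integer codes, or a
``Class`` column of label names (as written by :func:`write_classified_csv`),
populates the droplet labels.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DropgateError, FormatError, NamingError
from .model import ALL_LABELS, DropletTable, Plate, canonical_well_name

DEFAULT_CH1_HEADER = "Ch1 Amplitude"
DEFAULT_CH2_HEADER = "Ch2 Amplitude"

#: Default vendor cluster-code map. The vendor's code semantics are not
#: standardised; this convention (1→NN, 2→PN, 3→NP, 4→PP, anything else →
#: Unclassified) is explicit and overridable rather than silently assumed.
DEFAULT_CLUSTER_CODE_MAP: dict[int, str] = {1: "NN", 2: "PN", 3: "NP", 4: "PP"}


def _norm_header(header: str) -> str:
    return re.sub(r"\s+", "", str(header)).lower()


def _numeric_column(series: pd.Series, name: str) -> np.ndarray:
    # float() per cell is correctly rounded, so written amplitudes
    # round-trip exactly; pandas' fast to_numeric parser is not.
    raw = series.to_numpy(dtype=object)
    values = np.empty(raw.size, dtype=np.float64)
    for row, cell in enumerate(raw):
        try:
            values[row] = float(cell)
        except (TypeError, ValueError):
            values[row] = np.nan
        if not np.isfinite(values[row]):
            raise FormatError(
                f"non-numeric amplitude {cell!r} in column {name!r} "
                f"at data row {row + 1}"
            )
    return values


def parse_amplitude_csv(
    source: str | Path | IO[str],
    *,
    ch1_header: str = DEFAULT_CH1_HEADER,
    ch2_header: str = DEFAULT_CH2_HEADER,
    cluster_code_map: Mapping[int, str] | None = None,
    require_class: bool = False,
) -> DropletTable:
    """Parse a droplet amplitude CSV into a :class:`DropletTable`.

    Parameters
    ----------
    source
        Path or open text stream of a comma-separated file with a header row
        containing at least the two amplitude columns.
    ch1_header, ch2_header
        Canonical amplitude column names; matching ignores whitespace and case.
    cluster_code_map
        Mapping of vendor ``Cluster`` integer codes to label names; defaults
        to :data:`DEFAULT_CLUSTER_CODE_MAP`. Unknown codes map to
        ``Unclassified``.
    require_class
        If true, a ``Class`` column must be present (used when re-reading
        classified droplets for quantification).
    """
    try:
        df = pd.read_csv(source, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise FormatError("empty input: no header row") from None
    columns = {_norm_header(c): c for c in df.columns}

    missing = [h for h in (ch1_header, ch2_header) if _norm_header(h) not in columns]
    if missing:
        raise FormatError(f"missing amplitude column {missing[0]!r}")
    ch1 = _numeric_column(df[columns[_norm_header(ch1_header)]], ch1_header)
    ch2 = _numeric_column(df[columns[_norm_header(ch2_header)]], ch2_header)

    labels = None
    if "class" in columns:
        raw = df[columns["class"]].fillna("Unclassified").astype(str).str.strip()
        unknown = set(raw) - set(ALL_LABELS)
        if unknown:
            raise FormatError(f"unknown class names in 'Class' column: {sorted(unknown)}")
        labels = raw.to_numpy()
    elif require_class:
        raise FormatError("missing 'Class' column in classified input")
    elif "cluster" in columns:
        code_map = dict(DEFAULT_CLUSTER_CODE_MAP if cluster_code_map is None else cluster_code_map)
        codes = pd.to_numeric(df[columns["cluster"]], errors="coerce")
        labels = np.array(
            [
                code_map.get(int(c), "Unclassified") if np.isfinite(c) else "Unclassified"
                for c in codes.to_numpy(dtype=np.float64)
            ]
        )
    return DropletTable(ch1, ch2, labels)


def write_amplitude_csv(table: DropletTable, dest: str | Path | None = None) -> str | None:
    """Write amplitudes only, in the QuantaSoft export dialect."""
    df = pd.DataFrame({DEFAULT_CH1_HEADER: table.ch1, DEFAULT_CH2_HEADER: table.ch2})
    text = df.to_csv(index=False)
    if dest is None:
        return text
    Path(dest).write_text(text)
    return None


def write_classified_csv(table: DropletTable, dest: str | Path | None = None) -> str | None:
    """Write amplitudes plus a ``Class`` column of label names.

    The numeric rendering round-trips exactly: parsing the output yields
    bit-identical amplitudes and identical labels.
    """
    text = table.to_frame().to_csv(index=False)
    if dest is None:
        return text
    Path(dest).write_text(text)
    return None


def well_name_from_filename(filename: str | Path) -> str:
    """Extract the canonical well name from a per-well export filename.

    QuantaSoft exports one amplitude file per well with the well token
    embedded, e.g. ``EXP_A01_Amplitude.csv``. The token must match
    ``[A-H](0?[1-9]|1[0-2])`` delimited by underscores, dots or dashes.
    """
    base = Path(filename).name
    for token in re.split(r"[_\-.]", base):
        try:
            return canonical_well_name(token)
        except ValueError:
            continue
    raise NamingError(f"no well token (e.g. A01) found in filename {base!r}")


def load_plate(paths: Iterable[str | Path], **parse_kwargs) -> Plate:
    """Assemble per-well amplitude files into a :class:`Plate`.

    One well per file, insertion order = input order. Any per-file error is
    re-raised with the filename prepended; duplicate well names are an error.
    """
    plate = Plate()
    for path in paths:
        try:
            name = well_name_from_filename(path)
            table = parse_amplitude_csv(path, **parse_kwargs)
            plate.add_well(name, table)
        except DropgateError as exc:
            raise type(exc)(f"{path}: {exc}") from exc
        except ValueError as exc:  # duplicate well from Plate.add_well
            raise FormatError(f"{path}: {exc}") from exc
    return plate
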