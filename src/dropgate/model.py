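"""Core data model: droplet tables, class labels, wells and plates.

A droplet digital PCR (ddPCR) well partitions a sample into ~20 000
nanolitre droplets; each droplet is measured in two fluorescence channels.
Droplets are classified by channel positivity into four classes — the first
letter encodes Channel 1, the second Channel 2:

* ``NN`` — negative in both channels,
* ``NP`` — positive only in Channel 2,
* ``PN`` — positive only in Channel 1,
* ``PP`` — positive in both channels,

plus ``Rain`` (ambiguous droplets of intermediate fluorescence, excluded
from counting) and ``Unclassified`` (not yet gated).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping

import numpy as np


class ClassLabel(str, enum.Enum):
    """Droplet class by channel positivity (first letter = Channel 1)."""

    NN = "NN"
    NP = "NP"
    PN = "PN"
    PP = "PP"
    RAIN = "Rain"
    UNCLASSIFIED = "Unclassified"


#: The four positive/negative cluster labels, in canonical order.
CLUSTER_LABELS: tuple[str, ...] = ("NN", "NP", "PN", "PP")
#: All recognised labels.
ALL_LABELS: tuple[str, ...] = CLUSTER_LABELS + ("Rain", "Unclassified")
#: Labels counted as positive in Channel 1 / Channel 2. Rain and
#: Unclassified are never positive in either channel.
CH1_POSITIVE: frozenset[str] = frozenset({"PN", "PP"})
CH2_POSITIVE: frozenset[str] = frozenset({"NP", "PP"})

_LABEL_DTYPE = "U12"


def as_label_array(labels: Iterable[str] | np.ndarray, n: int | None = None) -> np.ndarray:
    """Coerce ``labels`` to a validated fixed-width string array."""
    arr = np.asarray(
        [l.value if isinstance(l, ClassLabel) else l for l in np.asarray(labels).ravel()],
        dtype=_LABEL_DTYPE,
    )
    unknown = set(arr.tolist()) - set(ALL_LABELS)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    if n is not None and arr.size != n:
        raise ValueError(f"expected {n} labels, got {arr.size}")
    return arr


@dataclass(frozen=True)
class DropletTable:
    """Per-droplet two-channel fluorescence amplitudes with a class label.

    Amplitudes are stored as finite float64 arrays of equal length; every
    droplet carries exactly one label (``Unclassified`` by default).
    """

    ch1: np.ndarray
    ch2: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        ch1 = np.asarray(self.ch1, dtype=np.float64).ravel()
        ch2 = np.asarray(self.ch2, dtype=np.float64).ravel()
        if ch1.shape != ch2.shape:
            raise ValueError(
                f"amplitude columns have unequal length ({ch1.size} vs {ch2.size})"
            )
        if ch1.size and not (np.isfinite(ch1).all() and np.isfinite(ch2).all()):
            raise ValueError("amplitudes must be finite real numbers")
        if self.labels is None:
            labels = np.full(ch1.shape, "Unclassified", dtype=_LABEL_DTYPE)
        else:
            labels = as_label_array(self.labels, n=ch1.size)
        for name, value in (("ch1", ch1), ("ch2", ch2), ("labels", labels)):
            object.__setattr__(self, name, value)

    def __len__(self) -> int:
        return int(self.ch1.size)

    @property
    def amplitudes(self) -> np.ndarray:
        """(n, 2) array of (Channel 1, Channel 2) amplitude points."""
        return np.column_stack([self.ch1, self.ch2])

    def with_labels(self, labels: Iterable[str] | np.ndarray) -> "DropletTable":
        """Return a new table with identical amplitudes and the given labels."""
        return DropletTable(self.ch1, self.ch2, as_label_array(labels, n=len(self)))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"Ch1 Amplitude": self.ch1, "Ch2 Amplitude": self.ch2, "Class": self.labels}
        )


def concat_tables(tables: Iterable[DropletTable]) -> DropletTable:
    """Concatenate droplet tables (e.g. to pool wells for plate-level gating)."""
    tables = list(tables)
    if not tables:
        return DropletTable(np.empty(0), np.empty(0))
    return DropletTable(
        np.concatenate([t.ch1 for t in tables]),
        np.concatenate([t.ch2 for t in tables]),
        np.concatenate([t.labels for t in tables]),
    )


_WELL_TOKEN_RE = re.compile(r"^([A-Ha-h])(0?[1-9]|1[0-2])$")


def canonical_well_name(name: str) -> str:
    """Normalise a well name to zero-padded canonical form (``a1`` → ``A01``).

    Raises ``ValueError`` if ``name`` is not a valid 96-well name (rows A–H,
    columns 1–12).
    """
    m = _WELL_TOKEN_RE.match(str(name).strip())
    if m is None:
        raise ValueError(f"invalid well name: {name!r}")
    return f"{m.group(1).upper()}{int(m.group(2)):02d}"


class Plate:
    """Ordered collection of wells (well name → :class:`DropletTable`).

    Well names are unique and canonicalised; iteration order is insertion
    order. ``metadata`` is a free-form dict (experiment name, assay names,
    simulation ground truth, ...).
    """

    def __init__(
        self,
        wells: Mapping[str, DropletTable] | Iterable[tuple[str, DropletTable]] | None = None,
        metadata: Mapping | None = None,
    ) -> None:
        self._wells: dict[str, DropletTable] = {}
        self.metadata: dict = dict(metadata or {})
        items = wells.items() if isinstance(wells, Mapping) else (wells or [])
        for name, table in items:
            self.add_well(name, table)

    def add_well(self, name: str, table: DropletTable) -> None:
        canon = canonical_well_name(name)
        if canon in self._wells:
            raise ValueError(f"duplicate well name: {canon}")
        self._wells[canon] = table

    def __getitem__(self, name: str) -> DropletTable:
        return self._wells[canonical_well_name(name)]

    def __contains__(self, name: str) -> bool:
        try:
            return canonical_well_name(name) in self._wells
        except ValueError:
            return False

    def __len__(self) -> int:
        return len(self._wells)

    def __iter__(self) -> Iterator[str]:
        return iter(self._wells)

    @property
    def names(self) -> list[str]:
        return list(self._wells)

    def items(self) -> Iterator[tuple[str, DropletTable]]:
        return iter(self._wells.items())

    def total_droplets(self) -> int:
        return sum(len(t) for t in self._wells.values())

    def map(self, fn: Callable[[DropletTable], DropletTable]) -> "Plate":
        """Apply a table → table operation to every well independently."""
        return Plate(((name, fn(t)) for name, t in self.items()), metadata=self.metadata)

    def pooled(self) -> DropletTable:
        """All wells concatenated into one table, in plate order."""
        return concat_tables(t for _, t in self.items())

    def with_pooled_labels(self, labels: np.ndarray) -> "Plate":
        """Distribute labels computed on :meth:`pooled` back onto the wells."""
        labels = as_label_array(labels, n=self.total_droplets())
        out = Plate(metadata=self.metadata)
        offset = 0
        for name, table in self.items():
            out.add_well(name, table.with_labels(labels[offset : offset + len(table)]))
            offset += len(table)
        return out

    def pooled_apply(self, fn: Callable[[DropletTable], DropletTable]) -> "Plate":
        """Apply a table → table operation to the pooled plate, then split back.

        Used for refinement steps whose statistics should be estimated from
        all wells jointly rather than per well.
        """
        refined = fn(self.pooled())
        return self.with_pooled_labels(refined.labels)
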