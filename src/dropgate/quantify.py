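"""Poisson quantification: from gated droplet counts to copies/µl.

Target molecules are assumed Poisson-distributed across droplets, so a
positive droplet may contain more than one copy. With ``P`` positive
droplets out of ``R`` accepted droplets of volume ``V`` µl each, the
occupancy estimate ``λ̂ = −ln(1 − P/R)`` converts to a concentration

    ĉ = −ln(1 − P/R) / V   [copies/µl],

the maximum-likelihood inversion of ``P/R = 1 − e^{−cV}``. The default
droplet volume is 0.85 nl = 8.5 × 10⁻⁴ µl.

Fractional abundance (mutant allelic fraction) is reported as
``conc_ch1 / (conc_ch1 + conc_ch2)`` with Channel 1 = mutant by convention.
Rain and Unclassified droplets are ambiguous, not negative: by default they
are excluded from both ``P`` and ``R`` (``exclude_rain=False`` counts them
as negatives instead).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import EmptyWellError, SaturationError
from .model import ALL_LABELS, DropletTable, Plate

DEFAULT_DROPLET_VOLUME_UL = 8.5e-4  # 0.85 nl


def class_counts(table: DropletTable) -> dict[str, int]:
    """Tally droplets per label over all six labels; values sum to len(table)."""
    counts = dict.fromkeys(ALL_LABELS, 0)
    labels, n = np.unique(table.labels, return_counts=True)
    counts.update({str(l): int(c) for l, c in zip(labels, n)})
    return counts


def target_concentration(
    P: int, R: int, V_ul: float = DEFAULT_DROPLET_VOLUME_UL
) -> float:
    """Estimate target concentration (copies/µl) from positive-droplet counts.

    Evaluates ``−ln(1 − P/R) / V_ul`` for ``P`` positive droplets among
    ``R`` accepted droplets of volume ``V_ul`` microlitres.
    """
    if not V_ul > 0:
        raise ValueError(f"droplet volume must be positive, got {V_ul}")
    R = int(R)
    P = int(P)
    if R == 0:
        raise EmptyWellError("no accepted droplets in well")
    if not 0 <= P <= R:
        raise ValueError(f"need 0 <= P <= R, got P={P}, R={R}")
    if P == R:
        raise SaturationError(
            f"all {R} accepted droplets positive; concentration unbounded"
        )
    return -math.log1p(-P / R) / V_ul


@dataclass(frozen=True)
class QuantResult:
    """Gated counts and Poisson concentration estimates for one well."""

    counts: dict[str, int]
    accepted_total: int
    ch1_positive: int
    ch2_positive: int
    droplet_volume_ul: float
    conc_ch1: float
    conc_ch2: float
    fractional_abundance: float | None  # None when both concentrations are 0


def quantify_well(
    table: DropletTable,
    V_ul: float = DEFAULT_DROPLET_VOLUME_UL,
    exclude_rain: bool = True,
) -> QuantResult:
    """Quantify one labelled well: counts, per-channel copies/µl, allelic fraction."""
    counts = class_counts(table)
    P1 = counts["PN"] + counts["PP"]
    P2 = counts["NP"] + counts["PP"]
    R = counts["NN"] + counts["NP"] + counts["PN"] + counts["PP"]
    if not exclude_rain:
        R += counts["Rain"] + counts["Unclassified"]
    conc1 = target_concentration(P1, R, V_ul)
    conc2 = target_concentration(P2, R, V_ul)
    total = conc1 + conc2
    fa = conc1 / total if total > 0 else None
    return QuantResult(counts, R, P1, P2, V_ul, conc1, conc2, fa)


SUMMARY_COLUMNS = [
    "Well",
    "NN",
    "NP",
    "PN",
    "PP",
    "Rain",
    "Unclassified",
    "AcceptedDroplets",
    "Ch1Positives",
    "Ch2Positives",
    "Ch1ConcCopiesPerUl",
    "Ch2ConcCopiesPerUl",
    "FractionalAbundance",
    "Status",
]


def summarize_plate(
    plate: Plate,
    V_ul: float = DEFAULT_DROPLET_VOLUME_UL,
    exclude_rain: bool = True,
) -> pd.DataFrame:
    """One row of quantification results per well, in plate order.

    Wells that cannot be quantified (saturated, or no accepted droplets) are
    reported with an error message in the ``Status`` column rather than
    aborting the plate.
    """
    rows = []
    for well, table in plate.items():
        counts = class_counts(table)
        P1 = counts["PN"] + counts["PP"]
        P2 = counts["NP"] + counts["PP"]
        R = counts["NN"] + counts["NP"] + counts["PN"] + counts["PP"]
        if not exclude_rain:
            R += counts["Rain"] + counts["Unclassified"]
        conc = {}
        problems = []
        for channel, P in (("ch1", P1), ("ch2", P2)):
            try:
                conc[channel] = target_concentration(P, R, V_ul)
            except (SaturationError, EmptyWellError) as exc:
                conc[channel] = math.nan
                problems.append(f"{channel}: {exc}")
        total = conc["ch1"] + conc["ch2"]
        fa = conc["ch1"] / total if math.isfinite(total) and total > 0 else math.nan
        rows.append(
            {
                "Well": well,
                **{k: counts[k] for k in ("NN", "NP", "PN", "PP", "Rain", "Unclassified")},
                "AcceptedDroplets": R,
                "Ch1Positives": P1,
                "Ch2Positives": P2,
                "Ch1ConcCopiesPerUl": conc["ch1"],
                "Ch2ConcCopiesPerUl": conc["ch2"],
                "FractionalAbundance": fa,
                "Status": "ok" if not problems else "; ".join(problems),
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def write_summary_csv(summary: pd.DataFrame, dest=None) -> str | None:
    """Render the plate summary as CSV (concentrations to 4 significant figures)."""
    from pathlib import Path

    text = summary.to_csv(index=False, float_format="%.4g")
    if dest is None:
        return text
    Path(dest).write_text(text)
    return None
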