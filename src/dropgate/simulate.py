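"""Synthetic ddPCR wells with known ground truth.

The generator is the statistical mirror of the analysis model: target
molecules of the two channels are independently Poisson-distributed across
droplets, so each droplet's true class follows the occupancy probabilities
of :func:`class_probabilities`; fluorescence amplitudes are drawn from a
per-class bivariate Gaussian (rotation/shear allowed, emulating the "lean"
of the PN cluster and "lift" of the NP cluster seen in noisy cfDNA data);
and a small fraction of droplets is replaced by rain placed along the
segments between cluster means. PCR kinetics, probe chemistry, and
droplet-volume variability are not modelled.

:func:`simulate_kras_series` reproduces a mutant-titration plate design:
triplicate wells at a fixed mutant fraction over increasing total input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import DropletTable, Plate
from .quantify import DEFAULT_DROPLET_VOLUME_UL

#: Default cluster geometry (fluorescence units), resembling a typical
#: two-channel amplitude plot: negatives bottom-left, Channel-1 positives
#: bottom-right, Channel-2 positives top-left, double positives top-right.
DEFAULT_CLUSTER_MEANS: dict[str, tuple[float, float]] = {
    "NN": (2000.0, 1500.0),
    "PN": (9000.0, 1800.0),
    "NP": (2500.0, 7500.0),
    "PP": (9500.0, 8000.0),
}
DEFAULT_CLUSTER_SD = 300.0
#: Share of droplets replaced by rain: ~0.1% of a well, i.e. a few tens of
#: ambiguous droplets out of ~20 000, typical of a well-optimised assay.
DEFAULT_RAIN_FRACTION = 1e-3
#: Gaussian jitter (fluorescence units) orthogonal to the rain segment.
DEFAULT_RAIN_JITTER_SD = 150.0

#: Total-concentration series (copies/µl) standing for 1, 4, 16 and 64 ng
#: of human genomic DNA: ~330 haploid copies per ng diluted into a 20 µl
#: reaction gives ~15 copies/µl per ng of input.
DEFAULT_TOTAL_COPIES_SERIES: tuple[float, ...] = (15.0, 60.0, 240.0, 960.0)

_CLASS_ORDER = ("NN", "NP", "PN", "PP")


def class_probabilities(
    conc_ch1: float, conc_ch2: float, V_ul: float = DEFAULT_DROPLET_VOLUME_UL
) -> tuple[float, float, float, float]:
    """Droplet class probabilities (pNN, pNP, pPN, pPP) under Poisson occupancy.

    Each channel's target occupies a droplet with probability
    ``1 − exp(−c·V)``, independently of the other channel; the four class
    probabilities are the products and sum to 1.
    """
    if conc_ch1 < 0 or conc_ch2 < 0:
        raise ValueError("concentrations must be non-negative")
    if not V_ul > 0:
        raise ValueError(f"droplet volume must be positive, got {V_ul}")
    p1 = -np.expm1(-conc_ch1 * V_ul)
    p2 = -np.expm1(-conc_ch2 * V_ul)
    return (
        float((1 - p1) * (1 - p2)),
        float((1 - p1) * p2),
        float(p1 * (1 - p2)),
        float(p1 * p2),
    )


def _shear(cov: np.ndarray, A: np.ndarray) -> np.ndarray:
    return A @ cov @ A.T


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth description of one simulated well.

    ``lean_shear`` tilts the PN cluster (Channel 2 rises with Channel 1) and
    ``lift_shear`` tilts the NP cluster, phenomenological stand-ins for the
    probe cross-hybridisation artefacts seen in real data.
    """

    conc_ch1: float
    conc_ch2: float
    n_droplets: int = 20_000
    droplet_volume_ul: float = DEFAULT_DROPLET_VOLUME_UL
    cluster_means: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLUSTER_MEANS)
    )
    cluster_covariances: Mapping[str, np.ndarray] | None = None
    lean_shear: float = 0.0
    lift_shear: float = 0.0
    rain_fraction: float = DEFAULT_RAIN_FRACTION
    rain_jitter_sd: float = DEFAULT_RAIN_JITTER_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conc_ch1 < 0 or self.conc_ch2 < 0:
            raise ValueError("concentrations must be non-negative")
        if not self.n_droplets > 0:
            raise ValueError("n_droplets must be positive")
        if not self.droplet_volume_ul > 0:
            raise ValueError("droplet_volume_ul must be positive")
        if not 0 <= self.rain_fraction < 1:
            raise ValueError("rain_fraction must be in [0, 1)")
        if set(self.cluster_means) != set(_CLASS_ORDER):
            raise ValueError(f"cluster_means must define exactly {_CLASS_ORDER}")
        for lab, cov in self.resolved_covariances().items():
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError(f"covariance for {lab} is not positive-definite")

    def resolved_covariances(self) -> dict[str, np.ndarray]:
        """Per-class covariance matrices with lean/lift shear applied."""
        if self.cluster_covariances is None:
            base = {
                lab: np.eye(2) * DEFAULT_CLUSTER_SD**2 for lab in _CLASS_ORDER
            }
        else:
            base = {
                lab: np.asarray(self.cluster_covariances[lab], dtype=np.float64)
                for lab in _CLASS_ORDER
            }
        if self.lean_shear:
            base["PN"] = _shear(base["PN"], np.array([[1.0, 0.0], [self.lean_shear, 1.0]]))
        if self.lift_shear:
            base["NP"] = _shear(base["NP"], np.array([[1.0, self.lift_shear], [0.0, 1.0]]))
        return base


def simulate_well(config: SimulationConfig) -> tuple[DropletTable, np.ndarray]:
    """Draw one well; returns (unclassified table, ground-truth labels).

    Each droplet's true class is drawn from :func:`class_probabilities` and
    its amplitude from that class's bivariate Gaussian. A ``rain_fraction``
    share of droplets is instead placed uniformly along the segment between
    two distinct class means, with Gaussian jitter orthogonal to the
    segment, and carries the truth label ``Rain``. Output is a deterministic
    function of the config (including the seed).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_droplets
    probs = np.array(
        class_probabilities(config.conc_ch1, config.conc_ch2, config.droplet_volume_ul)
    )
    means = np.array([config.cluster_means[lab] for lab in _CLASS_ORDER], dtype=np.float64)
    covs = config.resolved_covariances()
    chol = np.array([np.linalg.cholesky(covs[lab]) for lab in _CLASS_ORDER])

    idx = rng.choice(4, size=n, p=probs)
    z = rng.standard_normal((n, 2))
    amps = np.empty((n, 2))
    for j in range(4):
        member = idx == j
        amps[member] = means[j] + z[member] @ chol[j].T
    truth = np.array(_CLASS_ORDER, dtype="U12")[idx]

    if config.rain_fraction > 0:
        rain = rng.random(n) < config.rain_fraction
        n_rain = int(rain.sum())
        if n_rain:
            a = rng.integers(0, 4, n_rain)
            b = (a + rng.integers(1, 4, n_rain)) % 4
            t = rng.random(n_rain)
            seg = means[b] - means[a]
            length = np.linalg.norm(seg, axis=1, keepdims=True)
            unit = seg / length
            orth = np.column_stack([-unit[:, 1], unit[:, 0]])
            jitter = rng.normal(0.0, config.rain_jitter_sd, n_rain)
            amps[rain] = means[a] + t[:, None] * seg + orth * jitter[:, None]
            truth[rain] = "Rain"

    return DropletTable(amps[:, 0], amps[:, 1]), truth


def _well_name(index: int) -> str:
    if not 0 <= index < 96:
        raise ValueError("a 96-well plate holds at most 96 wells")
    return f"{chr(ord('A') + index // 12)}{index % 12 + 1:02d}"


def simulate_kras_series(
    mutant_fraction: float = 0.05,
    total_copies_series: Sequence[float] = DEFAULT_TOTAL_COPIES_SERIES,
    replicates: int = 3,
    seed: int = 0,
    **well_config,
) -> Plate:
    """Simulate a mutant-titration plate: replicate wells per input level.

    Per well, ``conc_ch1 = mutant_fraction × total`` (Channel 1 = mutant)
    and ``conc_ch2 = (1 − mutant_fraction) × total``. Wells are named
    A01, A02, ... in series-major order and seeded as ``seed + well index``
    so wells are independent and the plate is reproducible. Ground truth is
    stored in ``plate.metadata``: ``mutant_fraction``,
    ``true_concentrations`` (well → (c1, c2)), ``total_copies`` (well →
    total) and ``truth_labels`` (well → label array).

    Extra keyword arguments are forwarded to :class:`SimulationConfig`
    (e.g. ``n_droplets``, ``rain_fraction``, ``lean_shear``).
    """
    if not 0 < mutant_fraction < 1:
        raise ValueError(f"mutant_fraction must be in (0, 1), got {mutant_fraction}")
    if not replicates > 0:
        raise ValueError("replicates must be positive")
    plate = Plate(
        metadata={
            "mutant_fraction": mutant_fraction,
            "true_concentrations": {},
            "total_copies": {},
            "truth_labels": {},
        }
    )
    index = 0
    for total in total_copies_series:
        for _ in range(replicates):
            c1 = mutant_fraction * total
            c2 = (1 - mutant_fraction) * total
            config = SimulationConfig(conc_ch1=c1, conc_ch2=c2, seed=seed + index, **well_config)
            table, truth = simulate_well(config)
            well = _well_name(index)
            plate.add_well(well, table)
            plate.metadata["true_concentrations"][well] = (c1, c2)
            plate.metadata["total_copies"][well] = float(total)
            plate.metadata["truth_labels"][well] = truth
            index += 1
    return plate
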