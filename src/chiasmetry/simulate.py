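"""Seeded synthetic pollen-mother-cell (PMC) datasets.

The generator emulates the statistical structure of metaphase-I chiasma
scoring and pachytene focus counting:

* per bivalent, with probability ``univalent_rate`` the pair falls apart
  into univalents (0 chiasmata); otherwise the chiasma count is drawn
  from a zero-truncated Poisson, honouring the obligate-crossover rule
  (at least one CO per bivalent that stays paired);
* each chiasma lands on arm 1 or 2 uniformly (arms treated as equal
  length) and its relative position is Beta(alpha, beta) on [0, 1] from
  centromere to telomere — a right-skewed Beta gives distal localization,
  a left-skewed one proximal;
* an optional hard-core interference rule redraws same-arm positions
  until all pairwise distances reach ``interference_min_distance``
  (bounded attempts; the best draw is kept and the bivalent flagged when
  the bound is hit);
* focus counts for MLH1 and MUS81 are independent Poisson per cell on
  two distinct synthetic slides, mirroring the separate-slide design.

Presets parameterize four regimes after the published *Allium* samples
(distal-localized A. cepa, proximal-localized A. fistulosum, and the two
hybrid regimes), calibrating the Beta shape to each sample's regional
count proportions and the truncated-Poisson rate to its chiasmata per
bivalent. All draws flow from one ``numpy`` Generator seeded from the
config, so identical configs give identical datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .datasets import allium_chiasma_region_counts, allium_foci_totals
from .localization import RegionBoundaries, classify_position
from .records import BivalentRecord, ChiasmaRecord, FociRecord, SampleMeta
from .localization import classify_bivalent


class ConfigurationError(ValueError):
    """A simulation configuration that cannot be honoured."""


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one synthetic PMC sample.

    ``chiasma_mean`` is the rate (lambda) of the zero-truncated Poisson
    for per-bivalent chiasma counts; the realized mean per paired
    bivalent is ``lambda / (1 - exp(-lambda))``. Positions are
    Beta(position_alpha, position_beta). ``interference_min_distance`` is
    the minimum allowed |Δ rel_pos| between chiasmata sharing an arm
    (0 disables the rule).
    """

    sample_id: str
    n_cells: int
    chiasma_mean: float
    position_alpha: float
    position_beta: float
    foci_lambda_mlh1: float
    foci_lambda_mus81: float
    n_cells_foci_per_marker: int
    seed: int = 0
    n_bivalents_per_cell: int = 8
    univalent_rate: float = 0.0
    interference_min_distance: float = 0.0

    def __post_init__(self):
        if self.n_cells < 1 or self.n_bivalents_per_cell < 1:
            raise ConfigurationError("n_cells and n_bivalents_per_cell must be >= 1")
        if self.chiasma_mean <= 0:
            raise ConfigurationError("chiasma_mean must be positive")
        if not (0.0 <= self.univalent_rate < 1.0):
            raise ConfigurationError("univalent_rate must lie in [0, 1)")
        if self.position_alpha <= 0 or self.position_beta <= 0:
            raise ConfigurationError("Beta shape parameters must be positive")
        if not (0.0 <= self.interference_min_distance < 0.5):
            raise ConfigurationError(
                "interference_min_distance must lie in [0, 0.5)"
            )
        if self.foci_lambda_mlh1 < 0 or self.foci_lambda_mus81 < 0:
            raise ConfigurationError("focus-count lambdas must be non-negative")
        if self.n_cells_foci_per_marker < 1:
            raise ConfigurationError("n_cells_foci_per_marker must be >= 1")


def _draw_zero_truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson draws by rejection of zeros (exact)."""
    out = rng.poisson(lam, size=size)
    while True:
        zero = out == 0
        if not zero.any():
            return out
        out[zero] = rng.poisson(lam, size=int(zero.sum()))


def _draw_arm_positions(
    rng: np.random.Generator,
    k: int,
    alpha: float,
    beta: float,
    min_distance: float,
    max_attempts: int = 100,
) -> tuple[np.ndarray, bool]:
    """Positions for k chiasmata on one arm under hard-core interference.

    Returns (positions, flagged); flagged means the attempt cap was hit
    and the best (largest minimum spacing) draw was kept.
    """
    if min_distance <= 0 or k < 2:
        return rng.beta(alpha, beta, size=k), False
    if (k - 1) * min_distance >= 1.0:
        raise ConfigurationError(
            f"{k} chiasmata with min distance {min_distance} cannot fit on one arm"
        )
    best, best_sep = None, -1.0
    for _ in range(max_attempts):
        pos = rng.beta(alpha, beta, size=k)
        sep = float(np.min(np.diff(np.sort(pos))))
        if sep >= min_distance:
            return pos, False
        if sep > best_sep:
            best, best_sep = pos, sep
    return best, True


def simulate_chiasmata(
    config: SimulationConfig,
    boundaries: RegionBoundaries = RegionBoundaries(),
) -> tuple[list[ChiasmaRecord], list[BivalentRecord]]:
    """Draw the chiasma and bivalent tables for one synthetic sample."""
    rng = np.random.default_rng(config.seed)
    chiasmata: list[ChiasmaRecord] = []
    bivalents: list[BivalentRecord] = []
    for ci in range(config.n_cells):
        cell_id = f"c{ci + 1:03d}"
        for bi in range(config.n_bivalents_per_cell):
            bivalent_id = f"b{bi + 1}"
            if config.univalent_rate > 0 and rng.random() < config.univalent_rate:
                bivalents.append(
                    BivalentRecord(
                        sample_id=config.sample_id,
                        cell_id=cell_id,
                        bivalent_id=bivalent_id,
                        chiasma_count=0,
                        configuration="univalent_pair",
                    )
                )
                continue
            k = int(_draw_zero_truncated_poisson(rng, config.chiasma_mean, 1)[0])
            arms = rng.integers(1, 3, size=k)
            recs: list[ChiasmaRecord] = []
            flagged = False
            for arm in (1, 2):
                k_arm = int((arms == arm).sum())
                if k_arm == 0:
                    continue
                pos, flag = _draw_arm_positions(
                    rng,
                    k_arm,
                    config.position_alpha,
                    config.position_beta,
                    config.interference_min_distance,
                )
                flagged = flagged or flag
                recs.extend(
                    ChiasmaRecord(
                        sample_id=config.sample_id,
                        cell_id=cell_id,
                        bivalent_id=bivalent_id,
                        arm_id=arm,
                        rel_pos=float(p),
                    )
                    for p in pos
                )
            configuration, subtype = classify_bivalent(recs, boundaries)
            if flagged:
                subtype += "; interference_unmet"
            chiasmata.extend(recs)
            bivalents.append(
                BivalentRecord(
                    sample_id=config.sample_id,
                    cell_id=cell_id,
                    bivalent_id=bivalent_id,
                    chiasma_count=k,
                    configuration=configuration,
                    subtype=subtype,
                )
            )
    return chiasmata, bivalents


def simulate_foci(config: SimulationConfig) -> list[FociRecord]:
    """Poisson focus counts per cell, each marker on its own slide."""
    rng = np.random.default_rng(config.seed + 1)  # independent of chiasma stream
    records: list[FociRecord] = []
    for marker, lam in (
        ("MLH1", config.foci_lambda_mlh1),
        ("MUS81", config.foci_lambda_mus81),
    ):
        counts = rng.poisson(lam, size=config.n_cells_foci_per_marker)
        records.extend(
            FociRecord(
                sample_id=config.sample_id,
                slide_id=f"slide_{marker}",
                cell_id=f"{marker.lower()}_c{ci + 1:03d}",
                marker=marker,
                count=int(n),
            )
            for ci, n in enumerate(counts)
        )
    return records


def region_proportions(
    alpha: float, beta: float, boundaries: RegionBoundaries = RegionBoundaries()
) -> tuple[float, float, float]:
    """Analytic (Beta-CDF) region probabilities for given shape parameters."""
    lo = stats.beta.cdf(boundaries.lower, alpha, beta)
    hi = stats.beta.cdf(boundaries.upper, alpha, beta)
    return float(lo), float(hi - lo), float(1.0 - hi)


def calibrate_beta(
    target_proportions: tuple[float, float, float],
    boundaries: RegionBoundaries = RegionBoundaries(),
    tol: float = 1e-4,
) -> tuple[float, float]:
    """Find Beta shapes whose region probabilities match the targets.

    Nelder–Mead on log-shape parameters from several starts, minimizing
    the squared error between the analytic region probabilities and the
    targets; returns shapes achieving error <= ``tol`` or the best found
    with a warning.
    """
    targets = np.asarray(target_proportions, dtype=float)
    if targets.shape != (3,):
        raise ValueError("need exactly three target proportions")
    if ((targets <= 0) | (targets >= 1)).any():
        raise ValueError("target proportions must lie strictly in (0, 1)")
    targets = targets / targets.sum()

    def objective(log_shapes: np.ndarray) -> float:
        a, b = np.exp(log_shapes)
        props = np.array(region_proportions(a, b, boundaries))
        return float(((props - targets) ** 2).sum())

    starts = [
        (0.0, 0.0),
        (np.log(0.5), np.log(2.0)),
        (np.log(2.0), np.log(0.5)),
        (np.log(5.0), np.log(1.0)),
        (np.log(1.0), np.log(5.0)),
        (np.log(3.0), np.log(3.0)),
    ]
    best_x, best_f = None, np.inf
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-14}
        )
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    if best_f > tol:
        warnings.warn(
            f"Beta calibration residual {best_f:.3g} exceeds tolerance {tol:.3g}; "
            "returning best parameters found"
        )
    a, b = np.exp(best_x)
    return float(a), float(b)


def ztp_rate_for_mean(target_mean: float) -> float:
    """Invert lambda / (1 - exp(-lambda)) = target mean (target > 1)."""
    if target_mean <= 1.0:
        raise ValueError("zero-truncated Poisson mean must exceed 1")

    def f(lam: float) -> float:
        return lam / (1.0 - np.exp(-lam)) - target_mean

    return float(optimize.brentq(f, 1e-9, max(10.0, 5.0 * target_mean)))


_PRESET_SAMPLES = {
    "cepa_like": "A_cepa",
    "fistulosum_like": "A_fistulosum",
    "diploid_hybrid_like": "F1_diploid",
    "triploid_hybrid_like": "F1_triploid",
}

_preset_cache: dict[str, SimulationConfig] = {}


def preset_names() -> tuple[str, ...]:
    return tuple(_PRESET_SAMPLES)


def preset(
    name: str,
    seed: int = 0,
    n_cells: int | None = None,
) -> SimulationConfig:
    """A ready-made config emulating one of the published regimes.

    Beta shapes are calibrated to the sample's regional count proportions,
    the truncated-Poisson rate to its chiasmata per scored bivalent, the
    univalent rate to the shortfall of scored bivalents against
    8 per cell, and the focus lambdas to the per-marker per-cell means.
    """
    if name not in _PRESET_SAMPLES:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(_PRESET_SAMPLES)}"
        )
    if name not in _preset_cache:
        sample = _PRESET_SAMPLES[name]
        chi = allium_chiasma_region_counts().loc[sample]
        foc = allium_foci_totals().loc[sample]
        counts = np.array([chi.proximal, chi.interstitial, chi.distal], dtype=float)
        props = tuple(counts / counts.sum())
        alpha, beta = calibrate_beta(props)
        paired_mean = counts.sum() / chi.n_bivalents
        univ = max(0.0, 1.0 - chi.n_bivalents / (8.0 * chi.n_cells))
        _preset_cache[name] = SimulationConfig(
            sample_id=sample,
            n_cells=int(chi.n_cells),
            chiasma_mean=ztp_rate_for_mean(float(paired_mean)),
            position_alpha=alpha,
            position_beta=beta,
            univalent_rate=float(univ),
            foci_lambda_mlh1=float(foc.mlh1_signals / foc.mlh1_cells),
            foci_lambda_mus81=float(foc.mus81_signals / foc.mus81_cells),
            n_cells_foci_per_marker=int(
                round((foc.mlh1_cells + foc.mus81_cells) / 2)
            ),
            seed=0,
        )
    cfg = replace(_preset_cache[name], seed=seed)
    if n_cells is not None:
        cfg = replace(cfg, n_cells=n_cells)
    return cfg


def sample_meta_for(config: SimulationConfig) -> SampleMeta:
    return SampleMeta(
        sample_id=config.sample_id,
        display_label=config.sample_id.replace("_", " "),
        expected_bivalents_per_cell=config.n_bivalents_per_cell,
    )
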