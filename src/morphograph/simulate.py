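"""Planted-morphotype trait-table simulator.

Generates specimen tables with the statistical structure the pipeline
assumes: groups of specimens whose morphometric traits follow group-specific
allometric relationships ``trait = a_g * TL^b_g * exp(eps)`` and whose scale
counts follow group-specific Poisson (optionally negative-binomial)
distributions.  Group signal is planted on the *corrected* scale — the log
shape ratios and log1p counts the pipeline actually clusters — so the
``separation`` knob has a direct geometric meaning there.

Separation convention
---------------------
Group centers are drawn isotropically in the corrected trait space and
rescaled so the minimum pairwise center distance equals
``separation * noise_sd * sqrt(P)``; ``noise_sd * sqrt(P)`` is the
within-group RMS radius, the scale on which nearest-neighbor geometry mixes
clusters.  ``separation = 0`` plants no group signal; values around 1 give
heavily overlapping clouds; values >= 3 give clouds whose k-NN graphs are
nearly group-pure.  The total-length column carries no group offset by
default (size is not treated as diagnostic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import MERISTIC, MORPHOMETRIC, TraitTable

# Plausible trait vocabulary for a pitviper-like dataset: 13 linear
# measurements (TL is the size denominator) and 8 scale counts.
MORPHOMETRIC_NAMES = [
    "TL", "SVL", "TAL", "MBW", "MBH", "CW", "CH", "HL", "HW", "HH", "HE",
    "HP", "HN",
]
MERISTIC_NAMES = ["ven", "SC", "MID", "IOS", "so", "PO", "SL", "IL"]

# Baseline log shape ratios ln(trait/TL) for the named morphometrics (SVL is
# most of the body; head and girth measurements are a few percent of TL) and
# baseline count means for the named scale rows.
_BASE_LOG_RATIO = {
    "SVL": -0.15, "TAL": -1.9, "MBW": -3.0, "MBH": -3.1, "CW": -3.6,
    "CH": -3.7, "HL": -2.9, "HW": -3.2, "HH": -3.4, "HE": -4.2, "HP": -4.4,
    "HN": -4.6,
}
_BASE_COUNT_MEAN = {
    "ven": 160.0, "SC": 32.0, "MID": 23.0, "IOS": 8.0, "so": 10.0,
    "PO": 3.0, "SL": 9.0, "IL": 11.0,
}


class SimulationError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass
class SimulationConfig:
    """Study conditions for a planted-morphotype dataset.

    ``separation`` is expressed in within-group RMS-radius units on the
    corrected scale (see module docstring); ``noise_sd`` is the residual SD
    of the log shape ratios.  ``allometry_exponents`` maps (group, trait) to
    the exponent ``b`` of ``trait ~ TL^b`` (default 1.0, isometry; values
    away from 1 leak extra size-driven variance into the shape ratios).
    ``species_scheme`` controls the taxonomy column: ``aligned`` (one species
    per planted group), ``shuffled`` (labels randomly permuted across
    specimens), or ``split`` (each group split into two nominal species).
    """

    n_specimens: int = 484
    n_groups: int = 12
    proportions: list[float] | None = None
    n_morphometric: int = 13
    n_meristic: int = 8
    separation: float = 3.0
    noise_sd: float = 0.08
    tl_log_mean: float = math.log(450.0)
    tl_log_sd: float = 0.25
    allometry_exponents: dict | None = None
    meristic_base_means: list[float] | None = None
    meristic_dispersion: float | None = None
    species_scheme: str = "aligned"
    seed: int = 0
    _trait_names: tuple[list[str], list[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_specimens < 2 * self.n_groups:
            raise SimulationError("need at least 2 specimens per group")
        if self.separation < 0:
            raise SimulationError("separation must be >= 0")
        if self.noise_sd <= 0:
            raise SimulationError("noise_sd must be > 0")
        if not 1 <= self.n_morphometric:
            raise SimulationError("need at least the TL morphometric trait")
        if self.species_scheme not in ("aligned", "shuffled", "split"):
            raise SimulationError(f"unknown species_scheme {self.species_scheme!r}")
        if self.proportions is not None:
            if len(self.proportions) != self.n_groups:
                raise SimulationError("proportions length must equal n_groups")
            if abs(sum(self.proportions) - 1.0) > 1e-9 or min(self.proportions) <= 0:
                raise SimulationError("proportions must be positive and sum to 1")
        morpho = [
            MORPHOMETRIC_NAMES[i] if i < len(MORPHOMETRIC_NAMES) else f"M{i}"
            for i in range(self.n_morphometric)
        ]
        meri = [
            MERISTIC_NAMES[i] if i < len(MERISTIC_NAMES) else f"C{i}"
            for i in range(self.n_meristic)
        ]
        object.__setattr__(self, "_trait_names", (morpho, meri))

    @property
    def morphometric_names(self) -> list[str]:
        return list(self._trait_names[0])

    @property
    def meristic_names(self) -> list[str]:
        return list(self._trait_names[1])


@dataclass
class SimulatedDataset:
    """A trait table plus the planted ground truth behind it."""

    trait_table: TraitTable
    planted_labels: np.ndarray
    species_labels: np.ndarray
    config: SimulationConfig
    group_centers: np.ndarray  # (G, P-1) corrected-scale offsets, TL excluded


def _group_sizes(n: int, proportions: list[float]) -> np.ndarray:
    """Largest-remainder apportionment of n specimens to groups."""
    raw = np.asarray(proportions) * n
    sizes = np.floor(raw).astype(int)
    remainder = n - sizes.sum()
    order = np.argsort(-(raw - sizes), kind="stable")
    sizes[order[:remainder]] += 1
    return sizes


def _planted_centers(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Group centers on the corrected scale, TL column excluded."""
    g = config.n_groups
    p_signal = (config.n_morphometric - 1) + config.n_meristic
    p_total = config.n_morphometric + config.n_meristic
    centers = rng.standard_normal((g, p_signal))
    if g == 1 or config.separation == 0:
        return np.zeros((g, p_signal))
    diffs = centers[:, None, :] - centers[None, :, :]
    dist = np.sqrt((diffs**2).sum(-1))
    min_dist = dist[np.triu_indices(g, k=1)].min()
    target = config.separation * config.noise_sd * math.sqrt(p_total)
    return centers * (target / min_dist)


def simulate_morphotypes(config: SimulationConfig) -> SimulatedDataset:
    """Draw one planted-morphotype dataset under the given study conditions."""
    rng = np.random.default_rng(config.seed)
    n, g = config.n_specimens, config.n_groups
    proportions = config.proportions or [1.0 / g] * g
    sizes = _group_sizes(n, proportions)
    groups = np.repeat(np.arange(g), sizes)
    order = rng.permutation(n)  # interleave groups in row order
    groups = groups[order]

    centers = _planted_centers(config, rng)
    morpho, meri = config.morphometric_names, config.meristic_names
    tl_name = morpho[0]
    non_tl = morpho[1:]

    ln_tl = rng.normal(config.tl_log_mean, config.tl_log_sd, size=n)
    tl = np.exp(ln_tl)
    data = {tl_name: tl}

    exponents = config.allometry_exponents or {}
    for j, t in enumerate(non_tl):
        base = _BASE_LOG_RATIO.get(t, -1.0 - 0.2 * j)
        b = np.array([exponents.get((gi, t), exponents.get(t, 1.0))
                      for gi in range(g)])
        eps = rng.normal(0.0, config.noise_sd, size=n)
        ln_trait = base + centers[groups, j] + b[groups] * ln_tl + eps
        data[t] = np.exp(ln_trait)

    base_means = config.meristic_base_means or [
        _BASE_COUNT_MEAN.get(t, 10.0) for t in meri
    ]
    if min(base_means) <= 0:
        raise SimulationError("meristic base means must be > 0")
    for j, t in enumerate(meri):
        offset = centers[groups, (config.n_morphometric - 1) + j]
        lam = np.expm1(np.log1p(base_means[j]) + offset)
        lam = np.clip(lam, 0.05, None)
        if config.meristic_dispersion is None:
            counts = rng.poisson(lam)
        else:
            # Gamma-Poisson mixture = negative binomial with dispersion r.
            r = config.meristic_dispersion
            counts = rng.poisson(rng.gamma(r, lam / r))
        data[t] = counts.astype(float)

    species = _species_labels(groups, config.species_scheme, rng)
    ids = [f"spec_{i:04d}" for i in range(n)]
    values = pd.DataFrame(data, index=pd.Index(ids, name="specimen_id"))
    kinds = {t: MORPHOMETRIC for t in morpho}
    kinds.update({t: MERISTIC for t in meri})
    table = TraitTable(
        values=values, trait_kind=kinds, tl_name=tl_name,
        species=pd.Series(species, index=values.index, name="species"),
    )
    return SimulatedDataset(
        trait_table=table, planted_labels=groups, species_labels=species,
        config=config, group_centers=centers,
    )


def _species_labels(groups: np.ndarray, scheme: str,
                    rng: np.random.Generator) -> np.ndarray:
    aligned = np.array([f"sp_{gi:02d}" for gi in groups])
    if scheme == "aligned":
        return aligned
    if scheme == "shuffled":
        return aligned[rng.permutation(len(aligned))]
    # split: each planted group is nominally two species
    halves = np.empty(len(groups), dtype=object)
    for gi in np.unique(groups):
        idx = np.flatnonzero(groups == gi)
        half = rng.permutation(len(idx)) < len(idx) // 2
        for i, is_a in zip(idx, half):
            halves[i] = f"sp_{gi:02d}{'a' if is_a else 'b'}"
    return halves.astype(str)


def default_porthidium_like(seed: int = 0, **overrides) -> SimulatedDataset:
    """The shipped end-to-end fixture: 484 specimens, 21 traits, 12 groups.

    Dimensions mirror a genus-scale pitviper dataset (13 morphometric + 8
    pholidosis traits); 12 planted groups at moderate separation (3
    RMS-radius units).  The fixture matches dimensions and data types only,
    not any real measurement values.
    """
    params = dict(n_specimens=484, n_groups=12, n_morphometric=13,
                  n_meristic=8, separation=3.0, seed=seed)
    params.update(overrides)
    return simulate_morphotypes(SimulationConfig(**params))
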