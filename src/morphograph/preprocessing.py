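"""Trait-table ingestion and allometric size correction.

Specimens are rows, traits are columns. Continuous linear measurements
(morphometric traits, in mm) are size-corrected as log shape ratios
``ln(trait / TL)`` against a designated total-length column; integer scale
counts (meristic / pholidosis traits) are variance-homogenized as
``ln(x + 1)``. The corrected matrix is then standardized column-wise to
zero mean and unit sample variance so every trait carries equal weight in
the downstream morphospace graph.

The total-length column itself is kept as a feature, transformed as
``ln(TL)``: dividing TL by itself would produce a constant column, while a
log size axis preserves the body-size signal that is a known axis of
ecological divergence in squamates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MORPHOMETRIC = "morphometric"
MERISTIC = "meristic"


class TraitTableError(ValueError):
    """Raised when a trait table or its configuration is invalid."""


@dataclass
class TraitTable:
    """Validated specimen-by-trait records.

    Parameters
    ----------
    values : pandas.DataFrame
        One row per specimen (index = specimen id, order preserved),
        one column per declared trait.
    trait_kind : dict
        Maps every trait name to ``"morphometric"`` or ``"meristic"``.
    tl_name : str
        Name of the total-length column (the allometric denominator).
    species : pandas.Series or None
        Optional taxonomy label per specimen, aligned with ``values``.
    """

    values: pd.DataFrame
    trait_kind: dict[str, str]
    tl_name: str
    species: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_specimens(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    @property
    def trait_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def specimen_ids(self) -> list[str]:
        return list(self.values.index)

    def validate(self) -> None:
        v = self.values
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise TraitTableError(
                f"need at least 2 specimens and 2 traits, got {v.shape}"
            )
        if v.index.duplicated().any():
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise TraitTableError(f"duplicate specimen ids: {dupes}")
        undeclared = [c for c in v.columns if c not in self.trait_kind]
        if undeclared:
            raise TraitTableError(f"traits without a declared kind: {undeclared}")
        bad_kind = {
            t: k for t, k in self.trait_kind.items()
            if t in v.columns and k not in (MORPHOMETRIC, MERISTIC)
        }
        if bad_kind:
            raise TraitTableError(f"unknown trait kinds: {bad_kind}")
        if self.tl_name not in v.columns:
            raise TraitTableError(f"total-length column {self.tl_name!r} not present")
        if self.trait_kind[self.tl_name] != MORPHOMETRIC:
            raise TraitTableError(
                f"total-length column {self.tl_name!r} must be morphometric"
            )
        if v.isna().any().any():
            cells = [
                (str(idx), col)
                for idx, row in v.iterrows()
                for col in v.columns
                if pd.isna(row[col])
            ]
            raise TraitTableError(f"missing values at (specimen, trait): {cells[:20]}")
        for t in v.columns:
            col = v[t].to_numpy(dtype=float)
            if self.trait_kind[t] == MORPHOMETRIC:
                if not (col > 0).all():
                    raise TraitTableError(
                        f"morphometric trait {t!r} has non-positive values"
                    )
            else:
                if not ((col >= 0) & (col == np.round(col))).all():
                    raise TraitTableError(
                        f"meristic trait {t!r} must hold non-negative integers"
                    )

    def subset_traits(self, traits: list[str]) -> pd.DataFrame:
        """Raw values for a trait subset (TL always available separately)."""
        return self.values[list(traits)]


@dataclass
class CorrectedMatrix:
    """Allometrically corrected, column-standardized feature matrix.

    ``X`` has one row per specimen and one column per retained trait; each
    column has mean 0 and sample variance 1 (ddof=1) unless it was dropped
    as constant.  ``correction_log`` records the transform applied per trait.
    """

    X: np.ndarray
    trait_names: list[str]
    specimen_ids: list[str]
    species: list | None = None
    correction_log: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.X).all():
            raise TraitTableError("corrected matrix contains non-finite entries")
        if self.X.shape != (len(self.specimen_ids), len(self.trait_names)):
            raise TraitTableError("corrected matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.X, index=pd.Index(self.specimen_ids, name="specimen_id"),
            columns=self.trait_names,
        )


def load_trait_config(path: str | Path) -> dict:
    """Read a YAML/JSON trait declaration (tl_name, kinds, id/species columns)."""
    with open(path, "r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    return config


def _config_kinds(config: dict) -> dict[str, str]:
    if "trait_kind" in config:
        return dict(config["trait_kind"])
    kinds: dict[str, str] = {}
    for t in config.get("morphometric", []):
        kinds[t] = MORPHOMETRIC
    for t in config.get("meristic", []):
        kinds[t] = MERISTIC
    return kinds


def read_trait_table(path: str | Path, config: dict) -> TraitTable:
    """Read a specimen CSV and validate it against a trait declaration.

    ``config`` keys: ``tl_name`` (required), ``id_column`` (default
    ``specimen_id``), ``species_column`` (optional), and either
    ``trait_kind`` (name -> kind mapping) or ``morphometric``/``meristic``
    name lists.
    """
    id_col = config.get("id_column", "specimen_id")
    species_col = config.get("species_column")
    tl_name = config["tl_name"]
    kinds = _config_kinds(config)
    if not kinds:
        raise TraitTableError("config declares no traits")

    raw = pd.read_csv(path, dtype=str)
    missing = [c for c in [id_col, *kinds] if c not in raw.columns]
    if species_col and species_col not in raw.columns:
        missing.append(species_col)
    if missing:
        raise TraitTableError(f"input {path} is missing declared columns: {missing}")

    values = pd.DataFrame(index=raw[id_col])
    for t in kinds:
        numeric = pd.to_numeric(raw[t], errors="coerce")
        bad = numeric.isna() & raw[t].notna() | raw[t].isna()
        if bad.any():
            cells = [(raw[id_col].iloc[i], t) for i in np.flatnonzero(bad)]
            raise TraitTableError(
                f"non-numeric or missing trait cells (specimen, trait): {cells[:20]}"
            )
        values[t] = numeric.to_numpy(dtype=float)
    species = None
    if species_col:
        species = pd.Series(raw[species_col].to_numpy(), index=values.index,
                            name=species_col)
    return TraitTable(values=values, trait_kind=kinds, tl_name=tl_name,
                      species=species)


def allometric_correct(table: TraitTable) -> np.ndarray:
    """Size-correct raw traits onto the log scale.

    Morphometric traits other than TL become log shape ratios
    ``ln(trait/TL)``; TL becomes ``ln(TL)``; meristic counts become
    ``ln(x + 1)``.  Returns the corrected (un-standardized) N x P matrix in
    the table's column order.
    """
    v = table.values
    tl = v[table.tl_name].to_numpy(dtype=float)
    if not (tl > 0).all():
        raise TraitTableError("total length must be strictly positive")
    out = np.empty((table.n_specimens, table.n_traits), dtype=float)
    for j, t in enumerate(table.trait_names):
        col = v[t].to_numpy(dtype=float)
        if table.trait_kind[t] == MORPHOMETRIC:
            if not (col > 0).all():
                raise TraitTableError(f"morphometric trait {t!r} must be > 0")
            out[:, j] = np.log(col) if t == table.tl_name else np.log(col / tl)
        else:
            if (col < 0).any():
                raise TraitTableError(f"meristic trait {t!r} must be >= 0")
            out[:, j] = np.log1p(col)
    return out


def standardize(
    matrix: np.ndarray,
    trait_names: list[str] | None = None,
    specimen_ids: list[str] | None = None,
    species: list | None = None,
    on_constant: str = "error",
    correction_log: dict[str, str] | None = None,
) -> CorrectedMatrix:
    """Center each column to mean 0 and scale to unit sample SD (ddof=1).

    Constant columns cannot be scaled: ``on_constant="error"`` (default)
    raises, ``"drop"`` removes them with a logged warning.
    """
    M = np.asarray(matrix, dtype=float)
    if not np.isfinite(M).all():
        raise TraitTableError("cannot standardize: non-finite entries present")
    n, p = M.shape
    if trait_names is None:
        trait_names = [f"trait_{j}" for j in range(p)]
    if specimen_ids is None:
        specimen_ids = [f"specimen_{i}" for i in range(n)]
    sd = M.std(axis=0, ddof=1)
    constant = sd <= 0
    if constant.any():
        names = [trait_names[j] for j in np.flatnonzero(constant)]
        if on_constant == "drop":
            logger.warning("dropping constant columns before scaling: %s", names)
        else:
            raise TraitTableError(
                f"zero-variance columns cannot be scaled: {names} "
                "(pass on_constant='drop' to remove them)"
            )
    keep = ~constant
    X = (M[:, keep] - M[:, keep].mean(axis=0)) / sd[keep]
    log = dict(correction_log or {})
    for j in np.flatnonzero(constant):
        log[trait_names[j]] = log.get(trait_names[j], "") + " [dropped: constant]"
    return CorrectedMatrix(
        X=X,
        trait_names=[trait_names[j] for j in np.flatnonzero(keep)],
        specimen_ids=list(specimen_ids),
        species=list(species) if species is not None else None,
        correction_log=log,
    )


def preprocess(table: TraitTable, on_constant: str = "error") -> CorrectedMatrix:
    """Full correction pipeline: allometric transform then standardization."""
    corrected = allometric_correct(table)
    log = {}
    for t in table.trait_names:
        if table.trait_kind[t] == MERISTIC:
            log[t] = "ln(x+1), standardized"
        elif t == table.tl_name:
            log[t] = "ln(TL), standardized"
        else:
            log[t] = f"ln(x/{table.tl_name}), standardized"
    species = list(table.species) if table.species is not None else None
    return standardize(
        corrected,
        trait_names=table.trait_names,
        specimen_ids=table.specimen_ids,
        species=species,
        on_constant=on_constant,
        correction_log=log,
    )
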