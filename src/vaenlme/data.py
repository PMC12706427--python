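"""Long-format dataset representation and covariate coding.

The on-disk dialect is the NONMEM-style long format used across population
pharmacokinetics: one row per event, columns ``ID``, ``TIME``, ``DV`` for
observations, ``AMT`` for dose amounts, an optional ``EVID`` flag and one
column per covariate (constant within an individual).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataFormatError",
    "ValidationError",
    "CovariateSpec",
    "Individual",
    "PopulationDataset",
    "read_long_csv",
    "write_long_csv",
    "transform_covariates",
    "apply_covariate_meta",
]


class DataFormatError(ValueError):
    """Raised when a file does not conform to the long-format dialect."""


class ValidationError(ValueError):
    """Raised when parsed content violates a dataset invariant."""


@dataclass(frozen=True)
class CovariateSpec:
    """How one raw covariate column is coded into the design.

    Parameters
    ----------
    name
        Column name in the raw file.
    kind
        ``"continuous"`` or ``"categorical"``.
    transform
        ``"none"`` or ``"log_centered"`` (continuous only): the coded value is
        ``log(value / population mean)``, so an individual at the population
        mean codes to 0.
    reference_level
        For categorical covariates, the level coded 0. Defaults to the
        lexicographically smallest level.
    """

    name: str
    kind: str = "continuous"
    transform: str = "none"
    reference_level: object | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValidationError(f"unknown covariate kind {self.kind!r}")
        if self.transform not in ("none", "log_centered"):
            raise ValidationError(f"unknown covariate transform {self.transform!r}")
        if self.kind == "categorical" and self.transform != "none":
            raise ValidationError("categorical covariates take transform='none'")


@dataclass
class Individual:
    """One subject: observation sequence, dose events and coded covariates."""

    id: object
    times: np.ndarray
    observations: np.ndarray
    doses: list[tuple[float, float]] = field(default_factory=list)
    covariates: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.observations = np.asarray(self.observations, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.times.shape != self.observations.shape:
            raise ValidationError(
                f"individual {self.id}: {self.times.size} times but "
                f"{self.observations.size} observations"
            )
        if self.times.size < 1:
            raise ValidationError(f"individual {self.id}: needs at least one observation")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"individual {self.id}: times must be strictly increasing")
        if any(t < 0 for t, _ in self.doses):
            raise ValidationError(f"individual {self.id}: negative dose time")
        if not np.all(np.isfinite(self.covariates)):
            raise ValidationError(f"individual {self.id}: missing/non-finite covariate")

    @property
    def n_obs(self) -> int:
        return int(self.times.size)


@dataclass
class PopulationDataset:
    individuals: list[Individual]
    covariate_names: list[str] = field(default_factory=list)
    covariate_meta: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.individuals) < 1:
            raise ValidationError("dataset needs at least one individual")
        nc = len(self.covariate_names)
        for ind in self.individuals:
            if ind.covariates.size != nc:
                raise ValidationError(
                    f"individual {ind.id}: expected {nc} coded covariates, "
                    f"got {ind.covariates.size}"
                )

    @property
    def N(self) -> int:
        return len(self.individuals)

    @property
    def Ntot(self) -> int:
        return int(sum(ind.n_obs for ind in self.individuals))

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)

    def covariate_matrix(self) -> np.ndarray:
        """Coded covariates stacked as an (N, nc) design block."""
        if self.n_covariates == 0:
            return np.zeros((self.N, 0))
        return np.vstack([ind.covariates for ind in self.individuals])

    def all_observations(self) -> np.ndarray:
        return np.concatenate([ind.observations for ind in self.individuals])


def transform_covariates(
    raw: dict[str, Sequence], specs: Sequence[CovariateSpec]
) -> tuple[np.ndarray, list[dict]]:
    """Code raw per-individual covariate values into design columns.

    ``raw`` maps covariate name -> one value per individual. Continuous
    covariates with ``log_centered`` are coded ``log(value / mean)`` with the
    arithmetic mean over individuals as the centering constant, frozen into
    the returned metadata. Binary categorical covariates become one 0/1
    indicator (1 = non-reference level); covariates with more than two levels
    expand to one indicator per non-reference level.

    Returns
    -------
    coded : (N, nc_coded) array
    meta : list of per-column records with the information needed to code a
        new individual identically (see :func:`apply_covariate_meta`).
    """
    n = None
    for spec in specs:
        if spec.name not in raw:
            raise ValidationError(f"missing raw covariate {spec.name!r}")
        m = len(raw[spec.name])
        if n is None:
            n = m
        elif m != n:
            raise ValidationError("raw covariate columns differ in length")
    columns: list[np.ndarray] = []
    meta: list[dict] = []
    for spec in specs:
        values = raw[spec.name]
        if spec.kind == "continuous":
            arr = np.asarray(values, dtype=float)
            if np.any(~np.isfinite(arr)):
                raise ValidationError(f"covariate {spec.name!r}: non-finite value")
            if spec.transform == "log_centered":
                if np.any(arr <= 0):
                    raise ValidationError(
                        f"covariate {spec.name!r}: log_centered requires positive values"
                    )
                center = float(np.mean(arr))
                columns.append(np.log(arr / center))
                meta.append(
                    {"name": spec.name, "kind": "continuous",
                     "transform": "log_centered", "center": center}
                )
            else:
                columns.append(arr)
                meta.append({"name": spec.name, "kind": "continuous", "transform": "none"})
        else:
            levels = sorted({str(v) for v in values})
            if len(levels) < 2:
                raise ValidationError(
                    f"covariate {spec.name!r}: categorical needs at least two levels"
                )
            ref = str(spec.reference_level) if spec.reference_level is not None else levels[0]
            if ref not in levels:
                raise ValidationError(
                    f"covariate {spec.name!r}: reference level {ref!r} not observed"
                )
            others = [lv for lv in levels if lv != ref]
            strv = np.asarray([str(v) for v in values])
            for lv in others:
                name = spec.name if len(levels) == 2 else f"{spec.name}={lv}"
                columns.append((strv == lv).astype(float))
                meta.append(
                    {"name": name, "kind": "categorical", "raw_name": spec.name,
                     "level": lv, "reference_level": ref}
                )
    coded = np.column_stack(columns) if columns else np.zeros((n or 0, 0))
    return coded, meta


def apply_covariate_meta(raw: dict[str, Sequence], meta: Sequence[dict]) -> np.ndarray:
    """Code new individuals with centering constants frozen in ``meta``."""
    columns = []
    for rec in meta:
        if rec["kind"] == "continuous":
            arr = np.asarray(raw[rec["name"]], dtype=float)
            if rec["transform"] == "log_centered":
                if np.any(arr <= 0):
                    raise ValidationError(
                        f"covariate {rec['name']!r}: log_centered requires positive values"
                    )
                columns.append(np.log(arr / rec["center"]))
            else:
                columns.append(arr)
        else:
            strv = np.asarray([str(v) for v in raw[rec["raw_name"]]])
            columns.append((strv == rec["level"]).astype(float))
    return np.column_stack(columns)


_DEFAULT_COLUMNS = {"id": "ID", "time": "TIME", "dv": "DV", "amt": "AMT", "evid": "EVID"}


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and np.isnan(v):
        return True
    s = str(v).strip()
    return s in ("", ".", "nan", "NaN", "NA")


def read_long_csv(
    path,
    covariate_specs: Sequence[CovariateSpec] = (),
    column_map: dict[str, str] | None = None,
) -> PopulationDataset:
    """Read a NONMEM-style long-format CSV into a :class:`PopulationDataset`.

    Rows with a non-empty ``AMT`` are dose events; rows with a non-empty
    ``DV`` are observations; an ``EVID`` column, when present, overrides that
    inference (EVID=1 dose, EVID=0 observation). ``.`` and empty cells are
    both treated as missing. Covariate columns must be constant within an ID;
    coding (log-centering, reference levels) follows ``covariate_specs``.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    for key in ("id", "time", "dv"):
        if cols[key] not in df.columns:
            raise DataFormatError(f"missing mandatory column {cols[key]!r}")
    has_amt = cols["amt"] in df.columns
    has_evid = cols["evid"] in df.columns

    # raw covariates, one value per individual, in file order of first appearance
    ids_in_order: list[str] = []
    for v in df[cols["id"]]:
        if v not in ids_in_order:
            ids_in_order.append(v)
    raw_cov: dict[str, list] = {spec.name: [] for spec in covariate_specs}
    per_id = {i: df[df[cols["id"]] == i] for i in ids_in_order}
    for spec in covariate_specs:
        if spec.name not in df.columns:
            raise DataFormatError(f"missing covariate column {spec.name!r}")
        for i in ids_in_order:
            vals = {str(v).strip() for v in per_id[i][spec.name]}
            if len(vals) != 1:
                raise ValidationError(
                    f"covariate {spec.name!r} varies within ID {i} "
                    "(time-dependent covariates are unsupported)"
                )
            raw_cov[spec.name].append(vals.pop())

    if covariate_specs:
        coded, meta = transform_covariates(raw_cov, covariate_specs)
        names = [rec["name"] for rec in meta]
    else:
        coded, meta, names = np.zeros((len(ids_in_order), 0)), [], []

    individuals = []
    for row_i, ident in enumerate(ids_in_order):
        sub = per_id[ident]
        times, obs, doses = [], [], []
        for idx, row in sub.iterrows():
            t = float(row[cols["time"]])
            dv = row[cols["dv"]]
            amt = row[cols["amt"]] if has_amt else None
            if has_evid and not _is_missing(row[cols["evid"]]):
                evid = int(float(row[cols["evid"]]))
                if evid == 1:
                    if _is_missing(amt):
                        raise ValidationError(f"row {idx}: EVID=1 but AMT is empty")
                    doses.append((t, float(amt)))
                    continue
                if _is_missing(dv):
                    raise ValidationError(f"row {idx}: EVID=0 but DV is empty")
                times.append(t)
                obs.append(float(dv))
                continue
            if not _is_missing(amt):
                doses.append((t, float(amt)))
            elif not _is_missing(dv):
                times.append(t)
                obs.append(float(dv))
            else:
                raise ValidationError(f"row {idx}: both DV and AMT are empty")
        individuals.append(
            Individual(id=ident, times=np.asarray(times), observations=np.asarray(obs),
                       doses=doses, covariates=coded[row_i])
        )
    return PopulationDataset(individuals, covariate_names=names, covariate_meta=meta)


def write_long_csv(dataset: PopulationDataset, path, raw_covariates: pd.DataFrame | None = None) -> None:
    """Write the dataset back to the long-format dialect.

    Coded covariates are written as-is (one column per coded name) unless a
    ``raw_covariates`` frame (index aligned with individual order) is given.
    """
    rows = []
    for i, ind in enumerate(dataset.individuals):
        if raw_covariates is not None:
            cov = dict(raw_covariates.iloc[i])
        else:
            cov = dict(zip(dataset.covariate_names, ind.covariates))
        for t, amt in ind.doses:
            rows.append({"ID": ind.id, "TIME": t, "DV": ".", "AMT": amt, "EVID": 1, **cov})
        for t, x in zip(ind.times, ind.observations):
            rows.append({"ID": ind.id, "TIME": t, "DV": x, "AMT": ".", "EVID": 0, **cov})
    pd.DataFrame(rows).to_csv(path, index=False)
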