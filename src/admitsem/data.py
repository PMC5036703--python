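"""Practice-level data model, CSV input/output, and derived quantities.

The unit of observation is a GP practice.  Each practice carries

* ``J`` clinical quality indicators as numerator/denominator count pairs
  ``(Z, N)`` — e.g. diabetes patients meeting a blood-pressure target out
  of the registered diabetes patients eligible for the indicator;
* ``K`` patient-survey access indicators ``(W, V)`` — patients rating an
  aspect of access as poor out of all surveyed patients;
* an unplanned (emergency) admission count ``Y`` with an expected count
  ``E`` defining the relative risk ``Y/E``;
* covariates: income-deprivation score ``D``, age-standardised diabetes
  morbidity rate ``Mrate``, FTE GPs per 1000 patients ``S1`` and practice
  list size in thousands ``S2``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PracticeTable",
    "CrosswalkMatrix",
    "StandardizationRecord",
    "SchemaError",
    "ValidationError",
    "read_practice_table",
    "write_practice_table",
    "read_crosswalk",
    "write_crosswalk",
    "standardize_covariates",
    "compute_expected_counts",
]


class SchemaError(ValueError):
    """A required column is missing or the schema mapping is malformed."""


class ValidationError(ValueError):
    """Input values violate the data model's invariants."""


@dataclass(frozen=True)
class PracticeTable:
    """Validated practice-level dataset.

    Attributes
    ----------
    practice_id : list of str
        Practice labels, length ``I``.
    Z, N : int arrays, shape (I, J)
        Quality-indicator numerators and denominators.
    W, V : int arrays, shape (I, K)
        Access-indicator numerators and denominators.
    Y : int array, shape (I,)
        Emergency admission counts.
    E : float array, shape (I,), or None
        Expected admissions (see :func:`compute_expected_counts`).
    D, Mrate, S1, S2 : float arrays, shape (I,)
        Deprivation, morbidity rate, GP supply, list size (in 000s).
    """

    practice_id: list[str]
    Z: np.ndarray
    N: np.ndarray
    W: np.ndarray
    V: np.ndarray
    Y: np.ndarray
    D: np.ndarray
    Mrate: np.ndarray
    S1: np.ndarray
    S2: np.ndarray
    E: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("Z", "N", "W", "V", "Y"):
            arr = np.asarray(getattr(self, name))
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.all(arr == np.round(arr)):
                    raise ValidationError(f"{name} must contain integer counts")
                arr = arr.astype(np.int64)
            object.__setattr__(self, name, arr.astype(np.int64))
        for name in ("D", "Mrate", "S1", "S2"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.E is not None:
            object.__setattr__(self, "E", np.asarray(self.E, dtype=float))
        self.validate()

    # -- shape accessors -------------------------------------------------
    @property
    def I(self) -> int:  # noqa: E743 - conventional symbol for practice count
        return len(self.practice_id)

    @property
    def J(self) -> int:
        return self.Z.shape[1]

    @property
    def K(self) -> int:
        return self.W.shape[1]

    def validate(self) -> None:
        I = self.I
        if I < 1:
            raise ValidationError("need at least one practice")
        if self.Z.shape != self.N.shape or self.Z.ndim != 2:
            raise ValidationError("Z and N must be I x J matrices of equal shape")
        if self.W.shape != self.V.shape or self.W.ndim != 2:
            raise ValidationError("W and V must be I x K matrices of equal shape")
        if self.Z.shape[0] != I or self.W.shape[0] != I:
            raise ValidationError("indicator matrices must have one row per practice")
        for vec in ("Y", "D", "Mrate", "S1", "S2"):
            if getattr(self, vec).shape != (I,):
                raise ValidationError(f"{vec} must have length I={I}")
        if np.any(self.N < 1):
            bad = [self.practice_id[i] for i in np.unique(np.where(self.N < 1)[0])]
            raise ValidationError(f"quality denominators must be >= 1 (practices {bad})")
        if np.any(self.V < 1):
            bad = [self.practice_id[i] for i in np.unique(np.where(self.V < 1)[0])]
            raise ValidationError(f"access denominators must be >= 1 (practices {bad})")
        if np.any(self.Z < 0) or np.any(self.Z > self.N):
            rows, cols = np.where((self.Z < 0) | (self.Z > self.N))
            msgs = [f"practice {self.practice_id[r]}, indicator {c + 1}" for r, c in zip(rows, cols)]
            raise ValidationError("quality numerator outside [0, N] at " + "; ".join(msgs))
        if np.any(self.W < 0) or np.any(self.W > self.V):
            rows, cols = np.where((self.W < 0) | (self.W > self.V))
            msgs = [f"practice {self.practice_id[r]}, indicator {c + 1}" for r, c in zip(rows, cols)]
            raise ValidationError("access numerator outside [0, V] at " + "; ".join(msgs))
        if np.any(self.Y < 0):
            bad = [self.practice_id[i] for i in np.where(self.Y < 0)[0]]
            raise ValidationError(f"negative admission count for practices {bad}")
        if self.E is not None:
            if self.E.shape != (I,):
                raise ValidationError("E must have length I")
            if np.any(self.E <= 0):
                bad = [self.practice_id[i] for i in np.where(self.E <= 0)[0]]
                raise ValidationError(f"expected counts must be positive (practices {bad})")

    # -- conversion ------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray | list] = {"practice_id": list(self.practice_id)}
        for j in range(self.J):
            cols[f"z{j + 1}"] = self.Z[:, j]
            cols[f"n{j + 1}"] = self.N[:, j]
        for k in range(self.K):
            cols[f"w{k + 1}"] = self.W[:, k]
            cols[f"v{k + 1}"] = self.V[:, k]
        cols["y"] = self.Y
        if self.E is not None:
            cols["expected"] = self.E
        cols["deprivation"] = self.D
        cols["morbidity"] = self.Mrate
        cols["gp_supply"] = self.S1
        cols["list_size"] = self.S2
        return pd.DataFrame(cols)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema: dict | None = None) -> "PracticeTable":
        schema = dict(DEFAULT_SCHEMA, **(schema or {}))
        scalar_keys = ["practice_id", "y", "deprivation", "morbidity", "gp_supply", "list_size"]
        for key in scalar_keys:
            if schema[key] not in df.columns:
                raise SchemaError(f"missing column '{schema[key]}' (mapped from '{key}')")

        def gather(prefix_key: str) -> np.ndarray:
            prefix = schema[prefix_key]
            names = []
            idx = 1
            while f"{prefix}{idx}" in df.columns:
                names.append(f"{prefix}{idx}")
                idx += 1
            if not names:
                raise SchemaError(f"no columns found with prefix '{prefix}' (mapped from '{prefix_key}')")
            block = df[names].to_numpy()
            return block

        def as_counts(block: np.ndarray, what: str) -> np.ndarray:
            arr = np.asarray(block, dtype=float)
            if np.any(~np.isfinite(arr)) or np.any(arr != np.round(arr)):
                raise ValidationError(f"{what} columns must contain integers")
            return arr.astype(np.int64)

        Z = as_counts(gather("quality_num_prefix"), "quality numerator")
        N = as_counts(gather("quality_den_prefix"), "quality denominator")
        W = as_counts(gather("access_num_prefix"), "access numerator")
        V = as_counts(gather("access_den_prefix"), "access denominator")
        if Z.shape[1] != N.shape[1]:
            raise SchemaError("quality numerator/denominator column counts differ")
        if W.shape[1] != V.shape[1]:
            raise SchemaError("access numerator/denominator column counts differ")
        E = None
        if schema.get("expected") and schema["expected"] in df.columns:
            E = df[schema["expected"]].to_numpy(dtype=float)
        return cls(
            practice_id=[str(p) for p in df[schema["practice_id"]]],
            Z=Z,
            N=N,
            W=W,
            V=V,
            Y=as_counts(df[schema["y"]].to_numpy(), "admission count"),
            E=E,
            D=df[schema["deprivation"]].to_numpy(dtype=float),
            Mrate=df[schema["morbidity"]].to_numpy(dtype=float),
            S1=df[schema["gp_supply"]].to_numpy(dtype=float),
            S2=df[schema["list_size"]].to_numpy(dtype=float),
        )


#: Default logical-name -> CSV column mapping.  Indicator columns are found
#: by prefix + 1-based index (z1, z2, ..., n1, ..., w1, ..., v1, ...).
DEFAULT_SCHEMA = {
    "practice_id": "practice_id",
    "y": "y",
    "expected": "expected",
    "deprivation": "deprivation",
    "morbidity": "morbidity",
    "gp_supply": "gp_supply",
    "list_size": "list_size",
    "quality_num_prefix": "z",
    "quality_den_prefix": "n",
    "access_num_prefix": "w",
    "access_den_prefix": "v",
}


def read_practice_table(path, schema: dict | None = None) -> PracticeTable:
    """Read and validate a practice table from a CSV file.

    Raises :class:`SchemaError` when a mapped column is absent and
    :class:`ValidationError` when counts violate invariants (the message
    names the offending practices/columns).
    """
    df = pd.read_csv(path)
    return PracticeTable.from_dataframe(df, schema)


def write_practice_table(table: PracticeTable, path) -> None:
    table.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# covariate standardization
# ---------------------------------------------------------------------------

_COVARIATES = ("D", "Mrate", "S1", "S2")


@dataclass(frozen=True)
class StandardizationRecord:
    """Means and SDs used to standardize covariates (for back-transformation)."""

    means: dict[str, float]
    sds: dict[str, float]

    def to_json(self) -> str:
        return json.dumps({"means": self.means, "sds": self.sds}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StandardizationRecord":
        obj = json.loads(text)
        return cls(means=obj["means"], sds=obj["sds"])


def standardize_covariates(table: PracticeTable) -> tuple[PracticeTable, StandardizationRecord]:
    """Return a copy of ``table`` with covariates centred and scaled to unit SD.

    Sample SDs use the ``ddof=1`` convention.  A zero-variance covariate is an
    error because the regression coefficient would be unidentified.
    """
    if table.I < 2:
        raise ValidationError("standardization needs at least two practices")
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    new = {}
    for name in _COVARIATES:
        x = getattr(table, name)
        mu = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            raise ValidationError(f"covariate {name} has zero variance; cannot standardize")
        means[name] = mu
        sds[name] = sd
        new[name] = (x - mu) / sd
    return replace(table, **new), StandardizationRecord(means=means, sds=sds)


def compute_expected_counts(table: PracticeTable, basis: str = "diabetes_register") -> PracticeTable:
    """Attach expected admission counts ``E`` proportional to an exposure basis.

    ``E_i = b_i * (sum Y / sum b)`` so that ``sum E = sum Y`` exactly: the
    relative risk ``nu_i = 1`` for every practice is then the no-effect
    reference.  The basis is either the diabetes register size (the
    per-practice mean of the quality denominators, the natural exposure for
    diabetes-related admissions) or the raw practice list size.
    """
    if basis == "diabetes_register":
        b = table.N.mean(axis=1)
    elif basis == "list_size":
        b = np.asarray(table.S2, dtype=float)
    else:
        raise ValueError(f"unknown basis '{basis}'; use 'diabetes_register' or 'list_size'")
    if np.any(b <= 0):
        bad = [table.practice_id[i] for i in np.where(b <= 0)[0]]
        raise ValidationError(f"exposure basis must be strictly positive (practices {bad})")
    total_y = float(table.Y.sum())
    if total_y <= 0:
        raise ValidationError("cannot standardize expected counts: total admissions is zero")
    E = b * (total_y / b.sum())
    return replace(table, E=E)


# ---------------------------------------------------------------------------
# crosswalk
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrosswalkMatrix:
    """Area-by-practice population-share matrix (row-stochastic).

    ``weights[l, i]`` is the proportion of area ``l``'s population registered
    at practice ``i``.  Rows whose raw sum falls short of 1 (partial coverage)
    are renormalized; the raw sums are kept as ``covered_fraction``.
    """

    area_id: list[str]
    practice_id: list[str]
    weights: np.ndarray
    covered_fraction: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape != (len(self.area_id), len(self.practice_id)):
            raise ValidationError("weights must be L x I matching area/practice labels")
        if np.any(w < 0):
            raise ValidationError("crosswalk weights must be nonnegative")
        sums = w.sum(axis=1)
        if np.any(sums <= 0):
            bad = [self.area_id[l] for l in np.where(sums <= 0)[0]]
            raise ValidationError(f"crosswalk rows with zero total weight: {bad}")
        object.__setattr__(self, "weights", w / sums[:, None])
        object.__setattr__(self, "covered_fraction", np.minimum(sums, 1.0))

    @property
    def L(self) -> int:
        return len(self.area_id)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for l, area in enumerate(self.area_id):
            for i, prac in enumerate(self.practice_id):
                if self.weights[l, i] > 0:
                    rows.append((area, prac, self.weights[l, i] * self.covered_fraction[l]))
        return pd.DataFrame(rows, columns=["area_id", "practice_id", "weight"])


def read_crosswalk(path, practice_order: list[str] | None = None) -> CrosswalkMatrix:
    """Read a long-format crosswalk CSV (columns area_id, practice_id, weight)."""
    df = pd.read_csv(path)
    for col in ("area_id", "practice_id", "weight"):
        if col not in df.columns:
            raise SchemaError(f"crosswalk CSV missing column '{col}'")
    practices = practice_order or sorted(df["practice_id"].astype(str).unique())
    p_index = {p: i for i, p in enumerate(practices)}
    areas = list(dict.fromkeys(df["area_id"].astype(str)))
    a_index = {a: l for l, a in enumerate(areas)}
    w = np.zeros((len(areas), len(practices)))
    for _, row in df.iterrows():
        p = str(row["practice_id"])
        if p not in p_index:
            raise ValidationError(f"crosswalk references unknown practice '{p}'")
        w[a_index[str(row["area_id"])], p_index[p]] += float(row["weight"])
    return CrosswalkMatrix(area_id=areas, practice_id=practices, weights=w)


def write_crosswalk(xwalk: CrosswalkMatrix, path) -> None:
    xwalk.to_dataframe().to_csv(path, index=False)
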