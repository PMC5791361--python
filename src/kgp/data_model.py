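"""Core domain types and delimited-text I/O.

The analysis pipeline revolves around four containers:

``GenotypeMatrix``
    individuals × markers SNP dosages (copies of the counted allele,
    0/1/2) with an explicit missingness mask.  This is the ``M`` of the
    prediction equation ŷ = Xβ̂ + Mα̂.
``Pedigree``
    parent-offspring records (sire/dam, stock origin, generation) from
    which the numerator relationship matrix A is built.
``PhenotypeTable``
    per-individual trait records: body weight (kg), fork length (cm),
    condition index k = scale·W/L³, plus fixed-effect levels.
``KinshipMatrix``
    a symmetric relationship matrix — pedigree (A) or genomic (G) —
    together with the normalisation constant φ used for a genomic matrix.

Two genotype text dialects are supported: a "wide" CSV (rows =
individuals, columns = markers, missing = ``NA``) and a DArT-style
one-row-per-marker CSV (rows = markers, columns = individuals,
missing = ``-``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "Pedigree",
    "PhenotypeTable",
    "KinshipMatrix",
    "read_genotypes",
    "write_genotypes",
    "read_pedigree",
    "write_pedigree",
    "read_phenotypes",
    "write_phenotypes",
    "read_kinship",
    "write_kinship",
    "condition_index",
    "CONDITION_INDEX_SCALE",
]

#: Default scale applied to W/L^3 so that kg and cm inputs land on a
#: convenient magnitude (population mean ~15 rather than ~1.5e-5).
CONDITION_INDEX_SCALE = 1e6

UNKNOWN_PARENT = "0"


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


# ---------------------------------------------------------------------------
# GenotypeMatrix
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """SNP dosage matrix with missingness mask.

    Parameters
    ----------
    individual_ids, marker_ids
        Unique ordered identifiers for rows and columns.
    dosages
        ``(n_individuals, n_markers)`` float array counting copies of
        the counted allele.  Raw data are integer 0/1/2; after
        imputation real-valued dosages are permitted (``real_valued``).
    missing_mask
        Boolean array of the same shape; True marks a missing call.
        Values under the mask are ignored (conventionally 0).
    real_valued
        Set after imputation; relaxes the {0,1,2} value check.
    """

    individual_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray
    missing_mask: np.ndarray
    real_valued: bool = False

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        n, m = self.dosages.shape
        if len(self.individual_ids) != n or len(self.marker_ids) != m:
            raise ValidationError("id lists do not match dosage shape")
        if self.missing_mask.shape != self.dosages.shape:
            raise ValidationError("missing_mask shape differs from dosages")
        if len(set(self.individual_ids)) != n:
            raise ValidationError("duplicate individual ids")
        if len(set(self.marker_ids)) != m:
            raise ValidationError("duplicate marker ids")
        obs = self.dosages[~self.missing_mask]
        if obs.size and not self.real_valued:
            if not np.isin(obs, (0.0, 1.0, 2.0)).all():
                bad = obs[~np.isin(obs, (0.0, 1.0, 2.0))][:5]
                raise ValidationError(f"non-{{0,1,2}} dosages present: {bad}")
        if obs.size and self.real_valued:
            if obs.min() < 0 or obs.max() > 2:
                raise ValidationError("real-valued dosages outside [0, 2]")

    # -- convenience -------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def to_float(self) -> np.ndarray:
        """Dosages as a float array with NaN at missing entries."""
        out = self.dosages.astype(float).copy()
        out[self.missing_mask] = np.nan
        return out

    @classmethod
    def from_float(
        cls,
        arr: np.ndarray,
        individual_ids: Sequence[str],
        marker_ids: Sequence[str],
        real_valued: bool = False,
    ) -> "GenotypeMatrix":
        """Build from a NaN-coded float array."""
        arr = np.asarray(arr, dtype=float)
        mask = np.isnan(arr)
        dos = np.where(mask, 0.0, arr)
        return cls(list(individual_ids), list(marker_ids), dos, mask, real_valued)

    def select_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.individual_ids,
            [self.marker_ids[j] for j in index],
            self.dosages[:, index],
            self.missing_mask[:, index],
            self.real_valued,
        )

    def select_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            [self.individual_ids[i] for i in index],
            self.marker_ids,
            self.dosages[index, :],
            self.missing_mask[index, :],
            self.real_valued,
        )

    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls."""
        return 1.0 - self.missing_mask.mean(axis=0)


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


@dataclass
class Pedigree:
    """Parent-offspring records.

    Stored as a DataFrame with columns ``id``, ``sire``, ``dam``,
    ``stock_origin``, ``generation``; unknown parents are ``None``.
    Construction validates acyclicity, parent closure and assigns
    generation indices (founders = 0).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records.copy()
        for col in ("id", "sire", "dam"):
            df[col] = df[col].map(
                lambda v: None
                if v is None or (isinstance(v, float) and np.isnan(v)) or str(v) in ("", UNKNOWN_PARENT)
                else str(v)
            )
        if "stock_origin" not in df.columns:
            df["stock_origin"] = "unknown"
        ids = df["id"].tolist()
        if any(i is None for i in ids):
            raise ValidationError("pedigree contains an empty id")
        if len(set(ids)) != len(ids):
            dup = df["id"][df["id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate pedigree id: {dup}")
        known = set(ids)
        for col in ("sire", "dam"):
            for parent in df[col]:
                if parent is not None and parent not in known:
                    raise ValidationError(f"{col} '{parent}' has no own record")
        order, gen = self._toposort(df)
        df["generation"] = df["id"].map(gen)
        self.records = df.reset_index(drop=True)
        self._topo_order = order

    @staticmethod
    def _toposort(df: pd.DataFrame) -> tuple[list[str], dict[str, int]]:
        parents = {
            r.id: [p for p in (r.sire, r.dam) if p is not None]
            for r in df.itertuples()
        }
        gen: dict[str, int] = {}
        state: dict[str, int] = {}  # 0 visiting, 1 done
        order: list[str] = []

        def visit(node: str, stack: list[str]) -> int:
            if node in gen:
                return gen[node]
            if state.get(node) == 0:
                cyc = stack[stack.index(node):] + [node]
                raise ValidationError(f"pedigree cycle: {' -> '.join(cyc)}")
            state[node] = 0
            stack.append(node)
            g = 0
            for p in parents[node]:
                g = max(g, visit(p, stack) + 1)
            stack.pop()
            state[node] = 1
            gen[node] = g
            order.append(node)
            return g

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * len(parents) + 100))
        try:
            for node in parents:
                visit(node, [])
        finally:
            sys.setrecursionlimit(old)
        return order, gen

    # -- accessors ---------------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return self.records["id"].tolist()

    def topological_order(self) -> list[str]:
        """Ids sorted so every parent precedes its offspring."""
        return list(self._topo_order)

    def parents_of(self, ind: str) -> tuple[str | None, str | None]:
        row = self.records.loc[self.records["id"] == ind].iloc[0]
        return row["sire"], row["dam"]

    def founders(self) -> list[str]:
        df = self.records
        return df.loc[df["sire"].isna() & df["dam"].isna(), "id"].tolist()

    def families(self) -> pd.Series:
        """Full-sib family label '(sire,dam)' per individual (index = id)."""
        df = self.records
        lab = df.apply(
            lambda r: f"{r['sire']}x{r['dam']}"
            if r["sire"] is not None or r["dam"] is not None
            else "founder",
            axis=1,
        )
        lab.index = df["id"]
        return lab

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# PhenotypeTable
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeTable:
    """Per-individual trait records (weight kg, length cm, condition index)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        if "id" not in df.columns:
            raise ValidationError("phenotype table needs an 'id' column")
        df["id"] = df["id"].astype(str)
        if df["id"].duplicated().any():
            raise ValidationError("duplicate phenotype ids")
        for col in ("weight", "length"):
            if col in df.columns:
                vals = df[col].dropna()
                if (vals <= 0).any():
                    raise ValidationError(f"non-positive {col} present")
        self.data = df.reset_index(drop=True)

    @property
    def ids(self) -> list[str]:
        return self.data["id"].tolist()

    def trait(self, name: str) -> pd.Series:
        s = self.data[name].astype(float)
        s.index = self.data["id"]
        return s

    def check_condition_consistency(
        self, scale: float = CONDITION_INDEX_SCALE, rtol: float = 0.05
    ) -> bool:
        """True if condition_index ≈ scale·W/L³ on every complete row.

        Real data should satisfy this; simulated tables where the
        condition index is drawn independently will not, by design.
        """
        df = self.data
        needed = {"weight", "length", "condition_index"}
        if not needed.issubset(df.columns):
            return True
        sub = df.dropna(subset=list(needed))
        if sub.empty:
            return True
        expected = scale * sub["weight"] / sub["length"] ** 3
        return bool(np.allclose(sub["condition_index"], expected, rtol=rtol))


def condition_index(
    weight: float | np.ndarray,
    length: float | np.ndarray,
    scale: float = CONDITION_INDEX_SCALE,
) -> float | np.ndarray:
    """Body condition index k = scale·W/L³.

    With weight in kg and fork length in cm the default scale of 1e6
    brings the index to a magnitude of ~15 for a harvest-size fish
    (e.g. W=3.0 kg, L=58.2 cm → 15.22).
    """
    weight = np.asarray(weight, dtype=float)
    length = np.asarray(length, dtype=float)
    if (weight <= 0).any() or (length <= 0).any():
        raise ValueError("weight and length must be positive")
    out = scale * weight / length**3
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# KinshipMatrix
# ---------------------------------------------------------------------------


@dataclass
class KinshipMatrix:
    """Symmetric relationship matrix with provenance.

    ``kind`` is ``"pedigree"`` (numerator relationship matrix A) or
    ``"genomic"`` (marker-derived G); ``phi`` stores the VanRaden
    normalisation constant 1/Σ2p(1−p) for a genomic matrix (None for A).
    """

    ids: list[str]
    values: np.ndarray
    kind: str = "pedigree"
    phi: float | None = None

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError("kinship matrix shape does not match ids")
        if len(set(self.ids)) != n:
            raise ValidationError("duplicate kinship ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError("kinship matrix is not symmetric")
        if self.kind not in ("pedigree", "genomic"):
            raise ValidationError(f"unknown kinship kind: {self.kind}")

    def subset(self, ids: Sequence[str]) -> "KinshipMatrix":
        pos = {v: i for i, v in enumerate(self.ids)}
        try:
            idx = np.array([pos[str(i)] for i in ids])
        except KeyError as e:
            raise ValidationError(f"id {e} not in kinship matrix") from None
        return KinshipMatrix(
            [str(i) for i in ids], self.values[np.ix_(idx, idx)], self.kind, self.phi
        )

    @property
    def n(self) -> int:
        return len(self.ids)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_SENTINELS = {"wide_csv": "NA", "dart_onerow": "-"}


def read_genotypes(
    path: str | Path, dialect: str = "wide_csv", missing: str | None = None
) -> GenotypeMatrix:
    """Read a genotype matrix from delimited text.

    ``wide_csv``: one row per individual, header = marker ids, first
    column = individual id, missing cells ``NA``.  ``dart_onerow``: one
    row per marker (DArT single-row score export), columns =
    individuals, missing ``-``.
    """
    if dialect not in _SENTINELS:
        raise ValueError(f"unknown dialect: {dialect!r}")
    sentinel = _SENTINELS[dialect] if missing is None else missing
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if dialect == "dart_onerow":
        df = df.T  # -> individuals × markers
    individual_ids = [str(i) for i in df.index]
    marker_ids = [str(c) for c in df.columns]
    raw = df.to_numpy()
    mask = raw == sentinel
    flat = pd.Series(raw[~mask].ravel(), dtype=str).str.strip()
    vals = pd.to_numeric(flat, errors="coerce")
    if vals.isna().any():
        k = int(vals.index[vals.isna()][0])
        i, j = np.nonzero(~mask)
        i, j = int(i[k]), int(j[k])
        raise ValidationError(
            f"malformed dosage {raw[i, j]!r} at individual "
            f"{individual_ids[i]!r}, marker {marker_ids[j]!r}"
        )
    dos = np.zeros(raw.shape, dtype=float)
    dos[~mask] = vals.to_numpy()
    return GenotypeMatrix(individual_ids, marker_ids, dos, mask)


def write_genotypes(
    g: GenotypeMatrix, path: str | Path, dialect: str = "wide_csv"
) -> None:
    if dialect not in _SENTINELS:
        raise ValueError(f"unknown dialect: {dialect!r}")
    sentinel = _SENTINELS[dialect]

    dos = g.dosages
    if np.equal(np.mod(dos[~g.missing_mask], 1), 0).all():
        text = np.char.mod("%d", dos.astype(int))
    else:
        text = np.array([[repr(float(v)) for v in row] for row in dos], dtype=object)
    cells = np.where(g.missing_mask, sentinel, text).astype(object)
    df = pd.DataFrame(cells, index=g.individual_ids, columns=g.marker_ids)
    if dialect == "dart_onerow":
        df = df.T
        df.index.name = "marker"
    else:
        df.index.name = "id"
    df.to_csv(path)


def read_pedigree(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "sire", "dam"}
    if not required.issubset(df.columns):
        raise ValidationError(f"pedigree file needs columns {sorted(required)}")
    df = df.replace({"sire": {"": None, UNKNOWN_PARENT: None},
                     "dam": {"": None, UNKNOWN_PARENT: None}})
    return Pedigree(df)


def write_pedigree(p: Pedigree, path: str | Path) -> None:
    df = p.records.copy()
    for col in ("sire", "dam"):
        df[col] = df[col].map(lambda v: UNKNOWN_PARENT if v is None else v)
    df[["id", "sire", "dam", "stock_origin"]].to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path)
    return PhenotypeTable(df)


def write_phenotypes(t: PhenotypeTable, path: str | Path) -> None:
    t.data.to_csv(path, index=False)


def read_kinship(path: str | Path, kind: str = "genomic") -> KinshipMatrix:
    df = pd.read_csv(path, index_col=0)
    phi = None
    if "__phi__" in df.columns:
        phi = float(df["__phi__"].iloc[0])
        df = df.drop(columns="__phi__")
    return KinshipMatrix([str(i) for i in df.index], df.to_numpy(), kind, phi)


def write_kinship(k: KinshipMatrix, path: str | Path) -> None:
    df = pd.DataFrame(k.values, index=k.ids, columns=k.ids)
    if k.phi is not None:
        df["__phi__"] = k.phi
    df.index.name = "id"
    df.to_csv(path)
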