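"""Input formats and the aligned dose-response dataset.

Three external artifacts feed an analysis: a features x samples expression
matrix (raw RNA-seq counts or log2 intensities), a sample metadata table
mapping sample identifiers to administered doses, and gene sets in GMT
format. :func:`align_dataset` joins the first two into a validated
:class:`DoseResponseDataset` whose sample order is canonical (by dose, then
sample id) so downstream results never depend on file order.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OMICS_TYPES = ("counts", "log_intensity")

__all__ = [
    "DoseResponseDataset",
    "GeneSet",
    "GeneSetCollection",
    "read_expression_matrix",
    "read_metadata",
    "read_gmt",
    "write_gmt",
    "align_dataset",
]


class InputValidationError(ValueError):
    """An input file violates the format contract."""


@dataclass(frozen=True)
class GeneSet:
    """A named collection of feature identifiers (genes, metabolites...)."""

    name: str
    members: frozenset[str]
    description: str = ""
    id: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)

    def intersect(self, features: Iterable[str]) -> list[str]:
        """Members present in `features`, in the order features are given."""
        return [f for f in features if f in self.members]


class GeneSetCollection:
    """An ordered collection of uniquely named gene sets."""

    def __init__(self, sets: Iterable[GeneSet] = ()):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            self.add(s)

    def add(self, geneset: GeneSet) -> None:
        if geneset.name in self._sets:
            raise ValueError(f"duplicate gene set name {geneset.name!r}")
        self._sets[geneset.name] = geneset

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)


@dataclass
class DoseResponseDataset:
    """Expression matrix aligned with a per-sample dose vector.

    Parameters
    ----------
    expression
        Features x samples matrix; raw counts (``omics_type="counts"``) or
        log2 intensities (``omics_type="log_intensity"``).
    doses
        One non-negative dose per sample, indexed by sample id, in the
        experiment's original units.
    omics_type
        ``"counts"`` or ``"log_intensity"``.
    feature_id_kind
        Free-text description of the feature namespace (e.g. gene symbol).
    """

    expression: pd.DataFrame
    doses: pd.Series
    omics_type: str
    feature_id_kind: str = "feature"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.omics_type not in OMICS_TYPES:
            raise ValueError(
                f"omics_type must be one of {OMICS_TYPES}, got {self.omics_type!r}"
            )
        if set(self.expression.columns) != set(self.doses.index):
            raise ValueError("expression samples and dose samples differ")
        if (np.asarray(self.doses, dtype=float) < 0).any():
            raise ValueError("doses must be non-negative")
        if self.omics_type == "counts":
            vals = self.expression.to_numpy()
            if (vals < 0).any():
                raise InputValidationError("counts matrix contains negative values")
            if not np.allclose(vals, np.round(vals)):
                raise InputValidationError("counts matrix contains non-integer values")
        n_levels = self.n_dose_levels
        if n_levels < 2:
            raise ValueError("at least 2 distinct dose levels are required")
        # Spline fits want >= 4 distinct doses and linear trends >= 3; fewer
        # is allowed but recorded as a warning state.
        if n_levels < 3:
            self.warnings.append(
                f"only {n_levels} distinct dose levels: linear trends need >= 3"
            )
        elif n_levels < 4:
            self.warnings.append(
                f"only {n_levels} distinct dose levels: cubic splines need >= 4"
            )

    @property
    def n_features(self) -> int:
        return self.expression.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def dose_levels(self) -> np.ndarray:
        """Sorted unique dose values."""
        return np.unique(np.asarray(self.doses, dtype=float))

    @property
    def n_dose_levels(self) -> int:
        return self.dose_levels.size

    @property
    def samples(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def features(self) -> list[str]:
        return list(self.expression.index)


def _sniff_delimiter(path: Path) -> str:
    """Pick tab or comma; reject files where neither clearly applies."""
    with open(path, newline="") as fh:
        header = fh.readline()
    has_tab, has_comma = "\t" in header, "," in header
    if has_tab and not has_comma:
        return "\t"
    if has_comma and not has_tab:
        return ","
    if has_tab and has_comma:
        try:
            return csv.Sniffer().sniff(header, delimiters="\t,").delimiter
        except csv.Error:
            raise InputValidationError(
                f"{path}: ambiguous delimiter (both tab and comma present)"
            ) from None
    raise InputValidationError(f"{path}: no tab or comma delimiter found in header")


def read_expression_matrix(
    path: str | Path, omics_type: str = "counts"
) -> pd.DataFrame:
    """Read a delimited features x samples matrix.

    First column holds feature ids, header row holds sample ids. Counts are
    validated to be non-negative integers when ``omics_type="counts"``.
    """
    path = Path(path)
    if omics_type not in OMICS_TYPES:
        raise ValueError(f"omics_type must be one of {OMICS_TYPES}")
    sep = _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if raw.columns.duplicated().any():
        dups = sorted(set(raw.columns[raw.columns.duplicated()]))
        raise InputValidationError(f"{path}: duplicate sample ids: {dups}")
    if raw.index.duplicated().any():
        dups = sorted(set(raw.index[raw.index.duplicated()]))
        raise InputValidationError(f"{path}: duplicate feature ids: {dups}")
    mat = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns.astype(str))
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            feat = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise InputValidationError(
                f"{path}: non-numeric value {raw.loc[feat, col]!r} "
                f"at feature {feat!r}, sample {col!r}"
            )
        if converted.isna().any():
            feat = raw.index[converted.isna().to_numpy().nonzero()[0][0]]
            raise InputValidationError(
                f"{path}: missing value at feature {feat!r}, sample {col!r}"
            )
        values[:, j] = converted.to_numpy(dtype=float)
    if omics_type == "counts":
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise InputValidationError(
                f"{path}: negative count at feature {raw.index[i]!r}, "
                f"sample {raw.columns[j]!r}"
            )
        if not np.allclose(values, np.round(values)):
            i, j = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise InputValidationError(
                f"{path}: non-integer count {values[i, j]} at feature "
                f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
            )
    mat = pd.DataFrame(values, index=raw.index.astype(str), columns=raw.columns.astype(str))
    return mat


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata table: sample id + dose (+ extra covariates).

    Returns a DataFrame indexed by sample id with a ``dose`` column; any
    extra columns are preserved untouched (only dose is modeled).
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    meta = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in meta.columns}
    if "dose" not in cols:
        raise InputValidationError(f"{path}: required column 'dose' not found")
    sample_col = cols.get("sample", meta.columns[0])
    if sample_col == cols["dose"]:
        raise InputValidationError(f"{path}: no sample id column")
    meta = meta.rename(columns={sample_col: "sample", cols["dose"]: "dose"})
    meta["sample"] = meta["sample"].astype(str)
    if meta["sample"].duplicated().any():
        dups = sorted(set(meta["sample"][meta["sample"].duplicated()]))
        raise InputValidationError(f"{path}: duplicate sample ids: {dups}")
    meta["dose"] = pd.to_numeric(meta["dose"], errors="raise")
    if (meta["dose"] < 0).any():
        bad = meta.loc[meta["dose"] < 0, "sample"].iloc[0]
        raise InputValidationError(f"{path}: negative dose for sample {bad!r}")
    return meta.set_index("sample")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets from a GMT file (name, description, members...)."""
    path = Path(path)
    collection = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputValidationError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields "
                    f"(name, description, members), got {len(fields)}"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise InputValidationError(
                    f"{path}:{lineno}: gene set {name!r} has no members"
                )
            collection.add(
                GeneSet(name=name, description=description, members=frozenset(members))
            )
    return collection


def write_gmt(collection: GeneSetCollection | Iterable[GeneSet], path: str | Path) -> None:
    """Write gene sets to a GMT file; members sorted for a canonical form."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def align_dataset(
    expression: pd.DataFrame,
    metadata: pd.DataFrame | Mapping[str, float],
    omics_type: str = "counts",
    feature_id_kind: str = "feature",
) -> DoseResponseDataset:
    """Intersect matrix samples with metadata samples and canonicalize order.

    Samples present in only one input are dropped (logged); sample order is
    canonicalized by (dose, sample id). Idempotent: re-aligning an aligned
    dataset's pieces gives back identical content.
    """
    if isinstance(metadata, Mapping):
        dose_map = pd.Series(metadata, dtype=float, name="dose")
    else:
        dose_map = metadata["dose"].astype(float)
    dose_map.index = dose_map.index.astype(str)
    shared = sorted(set(expression.columns) & set(dose_map.index))
    if not shared:
        raise InputValidationError(
            "no shared sample ids between expression matrix and metadata"
        )
    dropped_expr = sorted(set(expression.columns) - set(shared))
    dropped_meta = sorted(set(dose_map.index) - set(shared))
    if dropped_expr:
        logger.info("dropping %d matrix samples without dose: %s", len(dropped_expr), dropped_expr)
    if dropped_meta:
        logger.info("dropping %d metadata samples without expression: %s", len(dropped_meta), dropped_meta)
    order = sorted(shared, key=lambda s: (float(dose_map[s]), s))
    return DoseResponseDataset(
        expression=expression[order].copy(),
        doses=dose_map[order].copy(),
        omics_type=omics_type,
        feature_id_kind=feature_id_kind,
    )
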