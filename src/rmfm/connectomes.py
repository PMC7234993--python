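"""Connectome containers and plain-text I/O.

The data model shared by every stage of the pipeline: a parcellation
(region metadata with hemisphere, intrinsic-network label, and contralateral
homologue pairing), a structural connectome (symmetric non-negative weight
matrix, e.g. streamline counts from tractography), and a functional
connectome (Pearson correlation matrix, optionally Fisher-z transformed).

On-disk formats are diffable delimited text: a parcellation TSV with header
``region_id name hemisphere network homologue_id`` and square numeric TSV
blocks for matrices (one comment header line naming the parcellation file).
An HDF5 container (datasets ``/weights``, ``/labels``) is supported when
h5py is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Parcellation",
    "StructuralConnectome",
    "FunctionalConnectome",
    "ConnectomeFormatError",
    "ConnectomeValidationError",
    "read_parcellation",
    "write_parcellation",
    "read_matrix",
    "write_matrix",
    "normalize_sc",
]

_SYMMETRY_TOL = 1e-8
_STRICT_SYMMETRY_TOL = 1e-10


class ConnectomeFormatError(ValueError):
    """A file or table does not have the expected layout."""


class ConnectomeValidationError(ValueError):
    """A structural invariant of the data model is violated."""


@dataclass(frozen=True)
class Parcellation:
    """Region metadata for an N-parcel cortical parcellation.

    Parameters
    ----------
    region_ids : ndarray of int
        Contiguous 0-based region indices ``0..N-1``.
    names : ndarray of str
        Human-readable parcel names.
    hemispheres : ndarray of str
        ``"left"`` or ``"right"`` per region.
    networks : ndarray of str
        Intrinsic-network label per region (e.g. one of seven canonical
        resting-state networks).
    homologue_ids : ndarray of int
        Index of the contralateral homologous parcel, or ``-1`` if none.
        Pairing must be symmetric.
    """

    region_ids: np.ndarray
    names: np.ndarray
    hemispheres: np.ndarray
    networks: np.ndarray
    homologue_ids: np.ndarray

    def __post_init__(self) -> None:
        rid = np.asarray(self.region_ids, dtype=int)
        object.__setattr__(self, "region_ids", rid)
        object.__setattr__(self, "names", np.asarray(self.names, dtype=object))
        object.__setattr__(
            self, "hemispheres", np.asarray(self.hemispheres, dtype=object)
        )
        object.__setattr__(self, "networks", np.asarray(self.networks, dtype=object))
        hom = np.asarray(self.homologue_ids, dtype=int)
        object.__setattr__(self, "homologue_ids", hom)
        n = rid.size
        if len({len(rid), len(self.names), len(self.hemispheres),
                len(self.networks), len(hom)}) != 1:
            raise ConnectomeFormatError("parcellation columns have unequal lengths")
        if np.unique(rid).size != n:
            raise ConnectomeValidationError("duplicate region_ids")
        if not np.array_equal(np.sort(rid), np.arange(n)):
            raise ConnectomeFormatError(
                "region_ids must be contiguous 0..N-1 with no gaps"
            )
        bad_hemi = set(self.hemispheres) - {"left", "right"}
        if bad_hemi:
            raise ConnectomeValidationError(f"unknown hemisphere labels: {bad_hemi}")
        # symmetric homologue pairing: homologue(homologue(i)) == i
        order = np.argsort(rid)
        hom_sorted = hom[order]
        for i, h in enumerate(hom_sorted):
            if h < 0:
                continue
            if h >= n or hom_sorted[h] != i:
                raise ConnectomeValidationError(
                    f"homologue pairing is not symmetric at region {i} -> {h}"
                )

    @property
    def n_regions(self) -> int:
        return self.region_ids.size

    def network_members(self, network: str) -> np.ndarray:
        """Region indices belonging to ``network`` (in region-id order)."""
        order = np.argsort(self.region_ids)
        nets = self.networks[order]
        return np.nonzero(nets == network)[0]

    @property
    def network_labels(self) -> list[str]:
        """Distinct network labels, in first-appearance order."""
        seen: dict[str, None] = {}
        order = np.argsort(self.region_ids)
        for lab in self.networks[order]:
            seen.setdefault(lab, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        order = np.argsort(self.region_ids)
        return pd.DataFrame(
            {
                "region_id": self.region_ids[order],
                "name": self.names[order],
                "hemisphere": self.hemispheres[order],
                "network": self.networks[order],
                "homologue_id": self.homologue_ids[order],
            }
        )


def _check_square(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ConnectomeFormatError(f"matrix must be square, got shape {values.shape}")
    if values.shape[0] < 2:
        raise ConnectomeValidationError("connectome needs at least 2 regions")
    if not np.all(np.isfinite(values)):
        raise ConnectomeValidationError("matrix contains non-finite entries")
    return values


def _symmetrize(values: np.ndarray, tol: float = _SYMMETRY_TOL) -> np.ndarray:
    asym = np.max(np.abs(values - values.T)) if values.size else 0.0
    if asym > tol:
        raise ConnectomeValidationError(
            f"matrix asymmetry {asym:.3g} exceeds tolerance {tol:.3g}"
        )
    return 0.5 * (values + values.T)


@dataclass(frozen=True)
class StructuralConnectome:
    """Symmetric non-negative weight matrix over cortical parcels.

    Weights are in arbitrary streamline-count-like units; entry (i, j) is
    the anatomical connection strength between parcels i and j. The
    diagonal is zero (self-connections are carried by the recurrent model
    term, not the connectome).
    """

    weights: np.ndarray
    parcellation: Parcellation
    normalized: bool = False
    degenerate: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        w = _check_square(self.weights)
        w = _symmetrize(w, _STRICT_SYMMETRY_TOL)
        if np.any(w < 0):
            raise ConnectomeValidationError("structural weights must be non-negative")
        if np.any(np.abs(np.diag(w)) > 0):
            raise ConnectomeValidationError("structural connectome diagonal must be 0")
        if w.shape[0] != self.parcellation.n_regions:
            raise ConnectomeValidationError(
                f"matrix size {w.shape[0]} != parcellation size "
                f"{self.parcellation.n_regions}"
            )
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class FunctionalConnectome:
    """Symmetric functional-connectivity matrix.

    ``space="r"`` holds Pearson correlations (unit diagonal, off-diagonal in
    [-1, 1]); ``space="z"`` holds Fisher-z transformed values.
    """

    values: np.ndarray
    parcellation: Parcellation
    space: str = "r"

    def __post_init__(self) -> None:
        v = _check_square(self.values)
        v = _symmetrize(v, _SYMMETRY_TOL)
        if self.space not in ("r", "z"):
            raise ConnectomeValidationError(f"unknown FC space {self.space!r}")
        if self.space == "r":
            off = v[~np.eye(v.shape[0], dtype=bool)]
            if off.size and (off.min() < -1.0 - 1e-12 or off.max() > 1.0 + 1e-12):
                raise ConnectomeValidationError(
                    "r-space FC entries must lie in [-1, 1]"
                )
            v = v.copy()
            np.fill_diagonal(v, 1.0)
        if v.shape[0] != self.parcellation.n_regions:
            raise ConnectomeValidationError(
                f"matrix size {v.shape[0]} != parcellation size "
                f"{self.parcellation.n_regions}"
            )
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


_PARC_COLUMNS = ["region_id", "name", "hemisphere", "network", "homologue_id"]


def read_parcellation(path) -> Parcellation:
    """Read a parcellation TSV.

    The table must have columns ``region_id``, ``name``, ``hemisphere``,
    ``network``, ``homologue_id``; homologue_id of -1 (or empty) means no
    contralateral partner. A header comment ``# index_base: 1`` marks 1-based
    on-disk indices, converted to the 0-based internal convention.
    """
    index_base = 0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "index_base" in first:
        index_base = int(first.split(":", 1)[1])
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _PARC_COLUMNS if c not in df.columns]
    if missing:
        raise ConnectomeFormatError(f"parcellation file missing columns: {missing}")
    hom = df["homologue_id"].fillna(-1 + index_base).astype(int).to_numpy()
    rid = df["region_id"].astype(int).to_numpy() - index_base
    hom = np.where(hom - index_base >= 0, hom - index_base, -1)
    return Parcellation(
        region_ids=rid,
        names=df["name"].astype(str).to_numpy(),
        hemispheres=df["hemisphere"].astype(str).to_numpy(),
        networks=df["network"].astype(str).to_numpy(),
        homologue_ids=hom,
    )


def write_parcellation(parc: Parcellation, path) -> None:
    parc.to_frame().to_csv(path, sep="\t", index=False)


def read_matrix(path, kind: str, parcellation: Parcellation):
    """Read a square matrix from TSV (or HDF5) and validate it.

    Parameters
    ----------
    kind : {"sc", "fc"}
        Whether to validate as a structural or functional connectome.
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as f:
            values = np.asarray(f["weights"])
    else:
        values = np.loadtxt(path, comments="#", delimiter="\t", ndmin=2)
    values = _check_square(values)
    values = _symmetrize(values, _SYMMETRY_TOL)
    if kind == "sc":
        return StructuralConnectome(weights=values, parcellation=parcellation)
    if kind == "fc":
        return FunctionalConnectome(values=values, parcellation=parcellation, space="r")
    raise ValueError(f"kind must be 'sc' or 'fc', got {kind!r}")


def write_matrix(conn, path, parcellation_file: str = "") -> None:
    """Write a connectome matrix as a TSV block with a comment header."""
    values = conn.weights if isinstance(conn, StructuralConnectome) else conn.values
    header = f"parcellation: {parcellation_file}" if parcellation_file else "connectome"
    np.savetxt(path, values, delimiter="\t", header=header, fmt="%.17g")


def normalize_sc(sc: StructuralConnectome) -> StructuralConnectome:
    """Scale weights by the global maximum so the largest entry is 1.

    Makes the fitted global coupling G comparable across connectomes of
    different raw weight scales. An all-zero connectome passes through
    unchanged with ``degenerate=True`` and a warning.
    """
    wmax = float(sc.weights.max()) if sc.weights.size else 0.0
    if wmax <= 0.0:
        warnings.warn("structural connectome has no positive weights; "
                      "normalization skipped", stacklevel=2)
        return replace(sc, normalized=True, degenerate=True)
    return StructuralConnectome(
        weights=sc.weights / wmax, parcellation=sc.parcellation, normalized=True
    )
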