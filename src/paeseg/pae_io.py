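"""Reading, validation and symmetrization of predicted aligned error matrices.

AlphaFold-family structure predictors emit, alongside each model, a matrix of
predicted aligned errors (PAE): entry (i, j) estimates the positional error
in angstroms of residue j when the predicted structure is aligned to the true
structure on residue i.  Residue pairs inside one compact, well-packed domain
have low mutual PAE, while pairs in two independently placed domains have
high PAE — which is exactly the signal domain segmentation exploits.

Several JSON dialects are in circulation (ColabFold, the AlphaFold database,
older flat-array exports).  This module reads the common ones, validates the
matrix, and produces the symmetrized matrix ``(pae + pae.T) / 2`` that the
segmentation algorithm consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PAE_HARD_CAP",
    "PaeFormatError",
    "PaeMatrix",
    "read_pae",
    "read_pae_text",
    "symmetrize",
    "write_pae",
]

# Producers cap PAE well below this (AlphaFold2 at 31.75 A); anything above
# 40 A cannot have come from a real predictor and is rejected as malformed.
PAE_HARD_CAP = 40.0


class PaeFormatError(ValueError):
    """Raised for unrecognized or malformed PAE input."""


@dataclass
class PaeMatrix:
    """A square matrix of expected pairwise positional errors for one chain.

    Parameters
    ----------
    protein_id
        Stable identifier, by default the stem of the file the matrix was
        read from.
    values
        ``(L, L)`` array of non-negative errors in angstroms.
    symmetrized
        True once the matrix has been replaced by ``(M + M.T) / 2``.
    """

    protein_id: str
    values: np.ndarray
    symmetrized: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1] or arr.shape[0] == 0:
            raise PaeFormatError(
                f"malformed PAE: expected a square matrix, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise PaeFormatError("malformed PAE: non-finite entries")
        if arr.min() < 0 or arr.max() > PAE_HARD_CAP:
            raise PaeFormatError(
                "malformed PAE: entries outside [0, "
                f"{PAE_HARD_CAP:g}] A (min {arr.min():g}, max {arr.max():g})"
            )
        if self.symmetrized and not np.array_equal(arr, arr.T):
            raise ValueError("symmetrized flag set but matrix is not symmetric")
        self.values = arr

    @property
    def length(self) -> int:
        """Number of residues L."""
        return self.values.shape[0]


def _as_matrix(raw: object) -> np.ndarray:
    """Convert a nested JSON list to a square float array or raise."""
    try:
        arr = np.asarray(raw, dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise PaeFormatError(f"malformed PAE: ragged or non-numeric matrix ({exc})") from exc
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise PaeFormatError(f"malformed PAE: expected square matrix, got shape {arr.shape}")
    return arr


def _reshape_flat(obj: dict, key: str) -> np.ndarray:
    """Older AFDB dialect: flat score array plus residue index arrays."""
    flat = np.asarray(obj[key], dtype=np.float64)
    n = flat.size
    length = int(round(np.sqrt(n)))
    if length * length != n:
        raise PaeFormatError(f"malformed PAE: flat array of length {n} is not a square")
    res1 = np.asarray(obj.get("residue1", []), dtype=np.int64)
    if res1.size == n:
        # index arrays tell us the layout; verify row-major ordering
        order = np.argsort(np.asarray(obj["residue1"], dtype=np.int64), kind="stable")
        flat = flat[order]
    return flat.reshape(length, length)


def read_pae(path: str | Path, protein_id: str | None = None) -> PaeMatrix:
    """Read a PAE matrix from any of the supported JSON dialects.

    Supported dialects, detected by key and tried in order:

    a. object with key ``"pae"`` holding an L x L array (ColabFold);
    b. object, possibly wrapped in a one-element list, with key
       ``"predicted_aligned_error"`` holding an L x L array (AlphaFold DB);
    c. object with a flat ``"pae"`` / ``"predicted_aligned_error"`` array
       plus residue index arrays, reshaped to L x L (older AFDB exports).

    Multi-chain inputs are accepted as one concatenated chain; the
    segmentation algorithm is chain-agnostic.

    Returns a :class:`PaeMatrix` with ``symmetrized=False``; ``protein_id``
    defaults to the file stem.
    """
    path = Path(path)
    with open(path) as fh:
        obj = json.load(fh)
    if isinstance(obj, list) and len(obj) == 1 and isinstance(obj[0], dict):
        obj = obj[0]
    if not isinstance(obj, dict):
        raise PaeFormatError("unrecognized PAE dialect: top-level JSON is not an object")

    values: np.ndarray | None = None
    for key in ("pae", "predicted_aligned_error"):
        if key not in obj:
            continue
        raw = obj[key]
        if isinstance(raw, list) and raw and isinstance(raw[0], list):
            values = _as_matrix(raw)
        else:
            values = _reshape_flat(obj, key)
        break
    if values is None:
        raise PaeFormatError(
            "unrecognized PAE dialect: no 'pae' or 'predicted_aligned_error' key "
            f"(found keys: {sorted(obj)})"
        )
    return PaeMatrix(protein_id=protein_id or path.stem, values=values)


def read_pae_text(path: str | Path, protein_id: str | None = None) -> PaeMatrix:
    """Read a plain whitespace-delimited L x L matrix (fixture format)."""
    path = Path(path)
    values = np.loadtxt(path, dtype=np.float64, ndmin=2)
    return PaeMatrix(protein_id=protein_id or path.stem, values=values)


def write_pae(pae: PaeMatrix, path: str | Path) -> None:
    """Write ``pae`` as dialect-(a) JSON (``{"pae": [[...], ...]}``).

    Float values survive the JSON round trip bit-for-bit (repr round trip).
    """
    with open(path, "w") as fh:
        json.dump({"pae": pae.values.tolist()}, fh)


def symmetrize(pae: PaeMatrix) -> PaeMatrix:
    """Return the symmetrized matrix ``(M + M.T) / 2``.

    The operation is idempotent and leaves the diagonal unchanged; the
    result compares exactly equal to its own transpose.
    """
    sym = (pae.values + pae.values.T) / 2.0
    return PaeMatrix(protein_id=pae.protein_id, values=sym, symmetrized=True)
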