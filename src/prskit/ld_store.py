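"""Quantized, upper-triangular, contiguous-CSR LD matrix store.

The linkage-disequilibrium (LD) matrix of M variants is symmetric with a
unit diagonal, so only the strictly upper-triangular part is kept.  Each
row ``i`` stores the correlations of variant ``i`` with a *contiguous* run
of variants immediately to its right (``i+1 .. i+n_i``) — the structure
produced by windowed (banded) or block-diagonal sparsity masks.  The runs
are concatenated row-major into one long 1-D ``data`` array, delimited by
an index-pointer array ``indptr`` of length ``M+1`` (CSR without a column
index, because columns are implied by contiguity).

Entries may be held as floats or quantized to ``int16``/``int8`` via scale
quantization: ``q = round(r * s)`` with ``s = 2**(b-1) - 1`` the largest
representable positive value of the signed b-bit integer, and
``r ≈ q / s`` on the way back.  The worst-case round-trip error is
``1/(2s)`` (≈0.004 for int8, ≈1.5e-5 for int16).

On disk the store is a hierarchical, chunked, compressed Zarr group::

    matrix/    data, indptr
    metadata/  rsid, chr, pos, cm, a1, a2, maf, ldscore
    (root attributes: dtype, scale, estimator, sample size, ancestry, ...)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "QuantizationSpec",
    "LDStore",
    "quantize",
    "dequantize",
    "write_store",
    "read_store",
    "row_neighbors",
]

#: metadata columns every store carries, in canonical order
METADATA_COLUMNS = ("rsid", "chr", "pos", "cm", "a1", "a2", "maf", "ldscore")

_INT_BITS = {"int8": 8, "int16": 16}
_FLOAT_EPS = {"float32": float(np.finfo(np.float32).eps),
              "float64": float(np.finfo(np.float64).eps)}


@dataclass(frozen=True)
class QuantizationSpec:
    """Storage data type for LD entries and its scale-quantization factor.

    For integer types the scale is ``s = 2**(b-1) - 1`` (127 for int8,
    32767 for int16), chosen so that a correlation of exactly 1 maps to
    the largest representable value instead of overflowing.  Float types
    use the identity scale.
    """

    dtype_name: str

    def __post_init__(self):
        if self.dtype_name not in ("float64", "float32", "int16", "int8"):
            raise ValueError(f"unsupported LD data type: {self.dtype_name!r}")

    @property
    def is_integer(self) -> bool:
        return self.dtype_name in _INT_BITS

    @property
    def bits(self) -> int:
        if self.is_integer:
            return _INT_BITS[self.dtype_name]
        return 64 if self.dtype_name == "float64" else 32

    @property
    def scale(self) -> float:
        if self.is_integer:
            return float(2 ** (self.bits - 1) - 1)
        return 1.0

    @property
    def resolution(self) -> float:
        """Spacing between representable correlation values."""
        if self.is_integer:
            return 1.0 / self.scale
        return _FLOAT_EPS[self.dtype_name]

    @property
    def numpy_dtype(self) -> np.dtype:
        return np.dtype(self.dtype_name)


def quantize(values, spec: QuantizationSpec):
    """Map correlations in [-1, 1] to scaled integers: ``round(r * s)``.

    Rounding is round-half-to-even (numpy's default), so e.g. 0.5 * 127
    = 63.5 rounds to 64.  Values outside [-1, 1] are rejected: Pearson
    correlations cannot exceed unity, so such inputs indicate a bug
    upstream rather than data to be clipped silently.
    """
    if not spec.is_integer:
        raise ValueError("quantize requires an integer QuantizationSpec")
    values = np.asarray(values, dtype=np.float64)
    if values.size and np.nanmax(np.abs(values)) > 1.0 + 1e-12:
        bad = float(np.nanmax(np.abs(values)))
        raise ValueError(f"correlation magnitude {bad} exceeds 1; cannot quantize")
    q = np.rint(np.clip(values, -1.0, 1.0) * spec.scale)
    return q.astype(spec.numpy_dtype)


def dequantize(q, spec: QuantizationSpec, precision: str = "float64"):
    """Invert scale quantization: ``r = q / s`` in the requested precision."""
    q = np.asarray(q)
    out_dtype = np.float64 if precision == "float64" else np.float32
    if not spec.is_integer:
        return q.astype(out_dtype)
    return (q.astype(out_dtype) / out_dtype(spec.scale)).astype(out_dtype)


@dataclass
class LDStore:
    """In-memory handle for the triangular contiguous-CSR LD matrix.

    ``data`` holds either quantized integers (lazy / dequantize-on-the-fly
    mode) or already-dequantized floats (eager mode); ``spec`` records the
    storage type either way, so the two modes are interchangeable.
    """

    data: np.ndarray
    indptr: np.ndarray
    metadata: pd.DataFrame
    spec: QuantizationSpec
    attrs: dict = field(default_factory=dict)
    precision: str = "float64"

    def __post_init__(self):
        self.indptr = np.asarray(self.indptr, dtype=np.int64)
        M = self.n_variants
        if len(self.indptr) != M + 1:
            raise ValueError("indptr must have length M+1")
        if self.indptr[0] != 0 or self.indptr[-1] != len(self.data):
            raise ValueError("indptr must start at 0 and end at len(data)")
        if np.any(np.diff(self.indptr) < 0):
            raise ValueError("indptr must be non-decreasing")
        counts = np.diff(self.indptr)
        if np.any(np.arange(M) + counts > M - 1 + 1e-9):
            raise ValueError("row runs extend past the last variant")
        if len(self.metadata) != M and M > 0:
            raise ValueError("metadata length does not match variant count")

    # ------------------------------------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.metadata)

    @property
    def is_quantized(self) -> bool:
        return np.issubdtype(self.data.dtype, np.integer)

    def row_neighbors(self, i: int):
        """Right-neighbor correlations of variant ``i``.

        Returns ``(start_col, values)`` where ``values[k]`` is the
        correlation between variants ``i`` and ``start_col + k`` and
        ``start_col = i + 1``.  Empty for rows with no stored run.
        """
        M = self.n_variants
        if not (0 <= i < M):
            raise IndexError(f"variant index {i} out of range [0, {M})")
        lo, hi = self.indptr[i], self.indptr[i + 1]
        vals = self.data[lo:hi]
        if self.is_quantized:
            vals = dequantize(vals, self.spec, self.precision)
        return i + 1, vals

    def dequantized_data(self) -> np.ndarray:
        """The full data array as floats (a copy when stored quantized)."""
        if self.is_quantized:
            return dequantize(self.data, self.spec, self.precision)
        return self.data

    def to_eager(self, precision: Optional[str] = None) -> "LDStore":
        """Materialize a float-valued copy of this store."""
        precision = precision or self.precision
        return LDStore(
            data=dequantize(self.data, self.spec, precision)
            if self.is_quantized
            else self.data.astype(precision),
            indptr=self.indptr,
            metadata=self.metadata,
            spec=self.spec,
            attrs=dict(self.attrs),
            precision=precision,
        )

    def subset_range(self, lo: int, hi: int) -> "LDStore":
        """Slice out variants [lo, hi) as a standalone store.

        Valid only when no stored run crosses the cut (true for
        chromosome boundaries, since correlations are never computed
        across chromosomes)."""
        counts = np.diff(self.indptr)
        ends = np.arange(self.n_variants) + counts
        if np.any(ends[lo:hi] > hi - 1):
            raise ValueError(f"stored rows cross the boundary at [{lo}, {hi})")
        data = self.data[self.indptr[lo]: self.indptr[hi]]
        indptr = self.indptr[lo: hi + 1] - self.indptr[lo]
        attrs = dict(self.attrs)
        blocks = attrs.get("blocks")
        if blocks:
            attrs["blocks"] = [[b0 - lo, b1 - lo] for b0, b1 in blocks
                               if b0 >= lo and b1 <= hi]
        return LDStore(data=data, indptr=indptr,
                       metadata=self.metadata.iloc[lo:hi].reset_index(drop=True),
                       spec=self.spec, attrs=attrs, precision=self.precision)

    def chromosomes(self) -> list[tuple[int, int, int]]:
        """(chromosome, start index, stop index) for each chromosome run."""
        chrom = self.metadata["chr"].to_numpy()
        bounds = np.concatenate(
            [[0], np.nonzero(np.diff(chrom) != 0)[0] + 1, [self.n_variants]]
        )
        return [(int(chrom[lo]), int(lo), int(hi))
                for lo, hi in zip(bounds[:-1], bounds[1:])]

    # ------------------------------------------------------------------
    def upper_csr(self, dtype=None) -> sp.csr_matrix:
        """The strictly upper-triangular part U as a scipy CSR matrix.

        Column indices are reconstructed from the contiguity invariant.
        When the store is quantized, the CSR holds the *raw integers*;
        callers that need correlations divide by ``spec.scale``.
        """
        M = self.n_variants
        counts = np.diff(self.indptr)
        starts = np.arange(M, dtype=np.int64) + 1
        indices = np.concatenate(
            [np.arange(s, s + c, dtype=np.int64) for s, c in zip(starts, counts)]
        ) if M else np.empty(0, dtype=np.int64)
        data = self.data if dtype is None else self.data.astype(dtype)
        return sp.csr_matrix((data, indices, self.indptr), shape=(M, M))

    def symmetric_offdiag_csr(self, precision: Optional[str] = None) -> sp.csr_matrix:
        """U + Uᵀ with dequantized float entries (diagonal excluded)."""
        precision = precision or self.precision
        U = self.upper_csr(dtype=precision)
        if self.is_quantized:
            U = U.multiply(1.0 / self.spec.scale).astype(precision)
        S = (U + U.T).tocsr()
        return S.astype(precision)

    def to_dense(self, precision: str = "float64") -> np.ndarray:
        """Reconstruct the dense symmetric LD matrix (debugging / oracles)."""
        S = self.symmetric_offdiag_csr(precision).toarray()
        np.fill_diagonal(S, 1.0)
        return S


def from_dense(
    R: np.ndarray,
    metadata: Optional[pd.DataFrame] = None,
    spec: QuantizationSpec = QuantizationSpec("float64"),
    mask: Optional[np.ndarray] = None,
    attrs: Optional[dict] = None,
) -> LDStore:
    """Build an LDStore from a dense symmetric matrix (test/oracle helper).

    ``mask`` is an optional boolean matrix; row ``i`` stores columns
    ``i+1 .. j_max`` where ``j_max`` is the right-most masked-in column
    (interior zeros inside the run are stored explicitly, preserving the
    contiguity invariant).
    """
    R = np.asarray(R, dtype=np.float64)
    M = R.shape[0]
    rows = []
    indptr = np.zeros(M + 1, dtype=np.int64)
    for i in range(M):
        if mask is None:
            j_max = M - 1
        else:
            cols = np.nonzero(mask[i, i + 1:])[0]
            j_max = i + 1 + cols[-1] if cols.size else i
        run = R[i, i + 1: j_max + 1]
        rows.append(run)
        indptr[i + 1] = indptr[i] + len(run)
    data = np.concatenate(rows) if rows else np.empty(0)
    if spec.is_integer:
        data = quantize(data, spec)
    else:
        data = data.astype(spec.numpy_dtype)
    if metadata is None:
        metadata = default_metadata(M)
    return LDStore(data=data, indptr=indptr, metadata=metadata, spec=spec,
                   attrs=dict(attrs or {}))


def default_metadata(M: int, chrom: int = 1) -> pd.DataFrame:
    """Placeholder variant metadata for synthetic / test stores."""
    return pd.DataFrame(
        {
            "rsid": [f"rs{i}" for i in range(M)],
            "chr": np.full(M, chrom, dtype=np.int64),
            "pos": np.arange(1, M + 1, dtype=np.int64) * 1000,
            "cm": np.arange(M, dtype=np.float64) * 0.01,
            "a1": ["A"] * M,
            "a2": ["G"] * M,
            "maf": np.full(M, 0.25),
            "ldscore": np.ones(M),
        }
    )


# ----------------------------------------------------------------------
# On-disk Zarr hierarchy
# ----------------------------------------------------------------------

_DEFAULT_CHUNK_BYTES = 1 << 20  # ~1 MB chunks


def _chunks_for(arr: np.ndarray) -> tuple:
    itemsize = max(arr.dtype.itemsize, 1)
    n = max(_DEFAULT_CHUNK_BYTES // itemsize, 1)
    return (int(min(max(len(arr), 1), n)),)


def write_store(ld: LDStore, path) -> None:
    """Persist an LDStore as a chunked, Zstandard-compressed Zarr group."""
    import numcodecs
    import zarr

    if len(ld.metadata) != ld.n_variants:
        raise ValueError("metadata length does not match variant count")
    comp = numcodecs.Zstd(level=7)
    root = zarr.open_group(str(path), mode="w", zarr_format=2)
    matrix = root.create_group("matrix")
    matrix.create_array("data", data=ld.data, chunks=_chunks_for(ld.data),
                        compressors=comp)
    matrix.create_array("indptr", data=ld.indptr,
                        chunks=_chunks_for(ld.indptr), compressors=comp)
    meta = root.create_group("metadata")
    for col in METADATA_COLUMNS:
        arr = ld.metadata[col].to_numpy()
        if arr.dtype == object:
            arr = arr.astype(str)
        meta.create_array(col, data=arr, chunks=_chunks_for(arr))
    attrs = dict(ld.attrs)
    attrs["dtype"] = ld.spec.dtype_name
    attrs["scale"] = ld.spec.scale
    attrs["chunk_bytes"] = _DEFAULT_CHUNK_BYTES
    attrs["compressor"] = "zstd"
    root.attrs.update(attrs)


def read_store(path, precision: str = "float64",
               dequantize_eagerly: bool = True) -> LDStore:
    """Open an on-disk store.

    With ``dequantize_eagerly`` the data array is converted to floats of
    the requested precision up front; otherwise (dequantize-on-the-fly)
    the raw integers are kept and downstream row access dequantizes the
    slices it touches on demand.  The two modes agree numerically within
    float rounding.
    """
    import zarr

    try:
        root = zarr.open_group(str(path), mode="r")
    except Exception as exc:  # pragma: no cover - zarr error classes vary
        raise FileNotFoundError(f"cannot open LD store at {path}: {exc}") from exc

    attrs = dict(root.attrs)
    dtype_name = attrs.pop("dtype", None)
    if dtype_name is None:
        raise ValueError(f"store at {path} lacks a 'dtype' attribute")
    try:
        spec = QuantizationSpec(dtype_name)
    except ValueError as exc:
        raise ValueError(f"store at {path}: {exc}") from exc
    stored_scale = attrs.pop("scale", spec.scale)
    if abs(stored_scale - spec.scale) > 1e-9:
        raise ValueError(
            f"store at {path}: scale attribute {stored_scale} does not match "
            f"dtype {dtype_name} (expected {spec.scale})"
        )

    try:
        data = root["matrix/data"][:]
        indptr = root["matrix/indptr"][:]
    except KeyError as exc:
        raise ValueError(f"store at {path} is missing matrix arrays") from exc

    meta = {}
    for col in METADATA_COLUMNS:
        try:
            meta[col] = root[f"metadata/{col}"][:]
        except KeyError as exc:
            raise ValueError(f"store at {path} is missing metadata/{col}") from exc
    metadata = pd.DataFrame(meta)
    if len(metadata) + 1 != len(indptr):
        raise ValueError(f"store at {path}: metadata/indptr length mismatch")

    if spec.is_integer and dequantize_eagerly:
        data = dequantize(data, spec, precision)
    elif not spec.is_integer:
        data = data.astype(np.float64 if precision == "float64" else np.float32)

    return LDStore(data=data, indptr=indptr, metadata=metadata, spec=spec,
                   attrs=attrs, precision=precision)


def row_neighbors(ld: LDStore, i: int):
    """Functional alias for :meth:`LDStore.row_neighbors`."""
    return ld.row_neighbors(i)


def export_dense_text(ld: LDStore, path) -> None:
    """Debug export: dense symmetric matrix as whitespace-delimited text."""
    np.savetxt(path, ld.to_dense(), fmt="%.8g")
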