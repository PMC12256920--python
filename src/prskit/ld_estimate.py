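"""LD matrix estimation from genotype panels.

Pairwise Pearson correlations between variant dosages are computed under a
sparsity mask — either *windowed* (all pairs within a centimorgan radius on
the same chromosome) or *block-diagonal* (all pairs inside predefined LD
blocks) — and assembled into the triangular contiguous-CSR
:class:`~prskit.ld_store.LDStore`.

Two missing-data policies are supported.  Mean imputation replaces missing
dosages by the variant's observed mean before a single correlation pass
over all samples; because every entry is then computed from the same
completed matrix, block-diagonal masks yield (near) positive semi-definite
matrices.  Pairwise-complete estimation instead drops samples missing at
either variant of a pair; entries are then estimated on disjoint subsets
of the data, which can push the smallest eigenvalue well below zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ld_store import LDStore, QuantizationSpec, quantize

__all__ = [
    "GenotypePanel",
    "SparsityMask",
    "variant_filters",
    "build_mask",
    "pairwise_correlation",
    "compute_ld",
    "read_ld_blocks",
]

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class GenotypePanel:
    """N x M dosage matrix plus a variant map (BIM-compatible).

    ``dosages`` holds allele-1 dosages in [0, 2], NaN marking missing
    calls.  The variant map must contain columns ``rsid, chr, pos, cm,
    a1, a2`` with centimorgan positions non-decreasing per chromosome.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: Sequence[str] = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        if not np.issubdtype(self.dosages.dtype, np.floating):
            self.dosages = self.dosages.astype(np.float64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be an N x M matrix")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant map length does not match dosage columns")
        if not len(self.samples):
            self.samples = [f"I{i}" for i in range(self.dosages.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(minor-allele count, minor-allele frequency) per variant."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        n_obs = np.sum(~np.isnan(self.dosages), axis=0)
        maf = np.minimum(freq, 1.0 - freq)
        mac = maf * 2.0 * n_obs
        return mac, maf

    def subset(self, idx: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
        )

    @classmethod
    def from_plink(cls, prefix) -> "GenotypePanel":
        from . import plink

        dosages, bim, fam = plink.read_bed(prefix)
        return cls(dosages=dosages, variants=bim, samples=list(fam["iid"]))


@dataclass
class SparsityMask:
    """Which variant pairs enter the LD matrix.

    ``kind='windowed'``: pair (i, j) included iff same chromosome and
    ``|cm_j - cm_i| <= window_cm``.  ``kind='block'``: pair included iff
    both variants fall in the same half-open variant-index interval.
    Either way each row's included columns form a contiguous run to the
    right of the diagonal, which the CSR layout requires.
    """

    kind: str
    window_cm: Optional[float] = None
    blocks: Optional[list[tuple[int, int]]] = None
    #: right-most included column per row (inclusive); row i stores i+1..row_end[i]
    row_end: Optional[np.ndarray] = None

    def run_counts(self) -> np.ndarray:
        return self.row_end - np.arange(len(self.row_end))


def variant_filters(panel: GenotypePanel, mac_min: int = 20,
                    maf_min: float = 0.0,
                    drop_ambiguous: bool = False) -> np.ndarray:
    """Indices of variants passing MAC/MAF/strand-ambiguity filters.

    Strand-ambiguous variants are A/T or C/G pairs, whose orientation
    cannot be resolved between datasets.
    """
    mac, maf = panel.allele_counts()
    keep = (mac >= mac_min) & (maf >= maf_min)
    if drop_ambiguous:
        a1 = panel.variants["a1"].str.upper()
        a2 = panel.variants["a2"].str.upper()
        ambiguous = [
            (x, y) in _AMBIGUOUS for x, y in zip(a1, a2)
        ]
        keep &= ~np.asarray(ambiguous)
    return np.nonzero(keep)[0]


def read_ld_blocks(path) -> pd.DataFrame:
    """Read a 3-column whitespace-delimited block file (chr, start, stop)."""
    blocks = pd.read_csv(path, sep=r"\s+", names=["chr", "start", "stop"],
                         comment="#", dtype={"chr": str})
    blocks["chr"] = (
        blocks["chr"].str.replace("chr", "", regex=False).astype(np.int64)
    )
    return blocks


def blocks_to_index_intervals(variants: pd.DataFrame,
                              blocks: pd.DataFrame) -> list[tuple[int, int]]:
    """Map base-pair block boundaries to half-open variant-index intervals.

    A variant belongs to a block when ``start <= pos < stop`` on the same
    chromosome.  Variants falling outside every block become singleton
    intervals (their LD rows carry no off-diagonal entries).
    """
    chrom = variants["chr"].to_numpy()
    pos = variants["pos"].to_numpy()
    M = len(variants)
    assignment = np.full(M, -1, dtype=np.int64)
    for b, (bc, bs, be) in enumerate(zip(blocks["chr"], blocks["start"],
                                         blocks["stop"])):
        inside = (chrom == bc) & (pos >= bs) & (pos < be)
        assignment[inside] = b
    intervals: list[tuple[int, int]] = []
    i = 0
    while i < M:
        if assignment[i] == -1:
            intervals.append((i, i + 1))
            i += 1
        else:
            j = i
            while j < M and assignment[j] == assignment[i]:
                j += 1
            intervals.append((i, j))
            i = j
    return intervals


def build_mask(panel: GenotypePanel, kind: str,
               window_cm: Optional[float] = None,
               blocks: Optional[pd.DataFrame] = None,
               block_intervals: Optional[Sequence[tuple[int, int]]] = None,
               ) -> SparsityMask:
    """Construct a windowed or block-diagonal sparsity mask."""
    M = panel.n_variants
    chrom = panel.variants["chr"].to_numpy()
    if kind == "windowed":
        if window_cm is None or window_cm <= 0:
            raise ValueError("windowed mask requires window_cm > 0")
        cm = panel.variants["cm"].to_numpy(dtype=np.float64)
        for c in np.unique(chrom):
            sel = cm[chrom == c]
            if np.any(np.diff(sel) < 0):
                raise ValueError("centimorgan positions must be "
                                 "non-decreasing within a chromosome")
        row_end = np.arange(M, dtype=np.int64)
        # cM coordinates restart across chromosomes: window per segment
        boundaries = np.concatenate(
            [[0], np.nonzero(np.diff(chrom) != 0)[0] + 1, [M]]
        )
        for lo, hi in zip(boundaries[:-1], boundaries[1:]):
            seg = cm[lo:hi]
            ends = np.searchsorted(seg, seg + window_cm, side="right") - 1
            row_end[lo:hi] = ends + lo
        return SparsityMask(kind="windowed", window_cm=window_cm,
                            row_end=row_end)
    if kind == "block":
        if block_intervals is None:
            if blocks is None:
                raise ValueError("block mask requires block boundaries")
            block_intervals = blocks_to_index_intervals(panel.variants, blocks)
        intervals = sorted(tuple(b) for b in block_intervals)
        covered = 0
        for lo, hi in intervals:
            if lo != covered or hi <= lo:
                raise ValueError("blocks must tile the variant index range "
                                 "contiguously")
            covered = hi
        if covered != M:
            raise ValueError("blocks must cover all variants")
        row_end = np.empty(M, dtype=np.int64)
        for lo, hi in intervals:
            row_end[lo:hi] = hi - 1
        return SparsityMask(kind="block", blocks=list(intervals),
                            row_end=row_end)
    raise ValueError(f"unknown mask kind: {kind!r}")


def _complete_dosages(dosages: np.ndarray) -> np.ndarray:
    """Mean-impute missing entries column-wise (no copy when complete)."""
    if not np.isnan(dosages).any():
        return dosages
    filled = dosages.copy()
    with np.errstate(invalid="ignore"):
        means = np.nanmean(filled, axis=0)
    nan_rows, nan_cols = np.nonzero(np.isnan(filled))
    filled[nan_rows, nan_cols] = means[nan_cols]
    return filled


def pairwise_correlation(panel: GenotypePanel, i: int, j: int,
                         policy: str = "mean_impute") -> float:
    """Pearson correlation between variants i and j under a missing-data
    policy, clipped to [-1, 1]."""
    xi = panel.dosages[:, i]
    xj = panel.dosages[:, j]
    if policy == "mean_impute":
        xi = np.where(np.isnan(xi), np.nanmean(xi), xi)
        xj = np.where(np.isnan(xj), np.nanmean(xj), xj)
    elif policy == "pairwise_complete":
        ok = ~np.isnan(xi) & ~np.isnan(xj)
        xi, xj = xi[ok], xj[ok]
    else:
        raise ValueError(f"unknown missing-data policy: {policy!r}")
    if len(xi) < 2:
        raise ValueError("need at least 2 informative samples")
    si, sj = np.std(xi), np.std(xj)
    if si == 0 or sj == 0:
        raise ValueError(f"zero variance at variant {i if si == 0 else j}; "
                         "correlation undefined")
    r = float(np.mean((xi - xi.mean()) * (xj - xj.mean())) / (si * sj))
    return float(np.clip(r, -1.0, 1.0))


def compute_ld(panel: GenotypePanel, mask: SparsityMask,
               policy: str = "mean_impute",
               qspec: QuantizationSpec = QuantizationSpec("float64"),
               sample_size: Optional[int] = None,
               ancestry: str = "synthetic") -> LDStore:
    """Estimate the masked LD matrix and assemble the triangular CSR store.

    MAF and LD-score metadata are computed from the same (policy-completed)
    data that produced the correlations.
    """
    M = panel.n_variants
    row_end = mask.row_end
    counts = row_end - np.arange(M)
    indptr = np.zeros(M + 1, dtype=np.int64)
    indptr[1:] = np.cumsum(counts)

    if policy == "mean_impute":
        X = _complete_dosages(panel.dosages).astype(np.float32)
        mu = X.mean(axis=0, dtype=np.float64)
        sd = X.std(axis=0, dtype=np.float64)
        if np.any(sd == 0):
            bad = int(np.nonzero(sd == 0)[0][0])
            raise ValueError(f"zero variance at variant {bad}; "
                             "correlation undefined")
        Z = X
        Z -= mu.astype(np.float32)
        Z /= sd.astype(np.float32)
        data = np.empty(indptr[-1], dtype=np.float64)
        if mask.kind == "block":
            # one Gram product per block
            for blo, bhi in mask.blocks:
                if bhi - blo < 2:
                    continue
                C = (Z[:, blo:bhi].T @ Z[:, blo:bhi]).astype(np.float64)
                C /= panel.n_samples
                for i in range(blo, bhi):
                    lo, hi = indptr[i], indptr[i + 1]
                    data[lo:hi] = np.clip(C[i - blo, i - blo + 1:], -1.0, 1.0)
        else:
            for i in range(M):
                lo, hi = indptr[i], indptr[i + 1]
                if hi > lo:
                    block = Z[:, i + 1: row_end[i] + 1]
                    dots = (Z[:, i] @ block).astype(np.float64)
                    data[lo:hi] = np.clip(dots / panel.n_samples, -1.0, 1.0)
    elif policy == "pairwise_complete":
        data = np.empty(indptr[-1], dtype=np.float64)
        for i in range(M):
            lo = indptr[i]
            for k, j in enumerate(range(i + 1, row_end[i] + 1)):
                data[lo + k] = pairwise_correlation(panel, i, j, policy)
    else:
        raise ValueError(f"unknown missing-data policy: {policy!r}")

    if qspec.is_integer:
        stored = quantize(data, qspec)
    else:
        stored = data.astype(qspec.numpy_dtype)

    _, maf = panel.allele_counts()
    # LD score: 1 (self) + sum of r^2 over stored neighbors (both directions)
    ldscore = np.ones(M)
    for i in range(M):
        lo, hi = indptr[i], indptr[i + 1]
        r2 = data[lo:hi] ** 2
        ldscore[i] += r2.sum()
        np.add.at(ldscore, np.arange(i + 1, row_end[i] + 1), r2)

    metadata = pd.DataFrame({
        "rsid": panel.variants["rsid"].to_numpy(),
        "chr": panel.variants["chr"].to_numpy(),
        "pos": panel.variants["pos"].to_numpy(),
        "cm": panel.variants["cm"].to_numpy(),
        "a1": panel.variants["a1"].to_numpy(),
        "a2": panel.variants["a2"].to_numpy(),
        "maf": maf,
        "ldscore": ldscore,
    })
    attrs = {
        "estimator": mask.kind,
        "estimator_params": (
            {"window_cm": mask.window_cm} if mask.kind == "windowed"
            else {"n_blocks": len(mask.blocks)}
        ),
        "blocks": [list(b) for b in mask.blocks] if mask.blocks else None,
        "missing_policy": policy,
        "sample_size": int(sample_size or panel.n_samples),
        "ancestry": ancestry,
    }
    return LDStore(data=stored, indptr=indptr, metadata=metadata, spec=qspec,
                   attrs=attrs)
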