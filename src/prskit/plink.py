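"""Minimal PLINK 1 BED/BIM/FAM reader and writer.

Only the variant-major (SNP-major) BED layout is supported, which is what
plink 1.9/2 emit by default.  Genotypes decode to allele-1 dosages in
{0, 1, 2} with NaN for missing calls:

    bits 00 -> 2 copies of A1   (homozygous first allele)
    bits 01 -> missing
    bits 10 -> 1 copy of A1     (heterozygous)
    bits 11 -> 0 copies of A1   (homozygous second allele)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> dosage of allele 1 (NaN = missing)
_DECODE = np.array([2.0, np.nan, 1.0, 0.0])

BIM_COLUMNS = ["chr", "rsid", "cm", "pos", "a1", "a2"]
FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]


def read_bim(prefix) -> pd.DataFrame:
    return pd.read_csv(f"{prefix}.bim", sep=r"\s+", names=BIM_COLUMNS,
                       dtype={"a1": str, "a2": str, "rsid": str})


def read_fam(prefix) -> pd.DataFrame:
    return pd.read_csv(f"{prefix}.fam", sep=r"\s+", names=FAM_COLUMNS,
                       dtype={"fid": str, "iid": str})


def read_bed(prefix) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Read a BED/BIM/FAM triple.

    Returns ``(dosages, bim, fam)`` where ``dosages`` is an N x M float
    array of allele-1 dosages with NaN marking missing genotypes.
    """
    bim = read_bim(prefix)
    fam = read_fam(prefix)
    n, m = len(fam), len(bim)
    raw = np.fromfile(f"{prefix}.bed", dtype=np.uint8)
    if raw[:3].tobytes() != _MAGIC:
        raise ValueError(f"{prefix}.bed is not a variant-major PLINK BED file")
    bytes_per_variant = (n + 3) // 4
    body = raw[3:]
    if len(body) != bytes_per_variant * m:
        raise ValueError(f"{prefix}.bed has unexpected size for {n} samples "
                         f"x {m} variants")
    body = body.reshape(m, bytes_per_variant)
    # unpack 2-bit codes, sample-within-byte is little-endian (LSB first)
    codes = np.zeros((m, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    dosages = _DECODE[codes[:, :n]].T  # -> N x M
    return np.ascontiguousarray(dosages), bim, fam


def write_bed(prefix, dosages: np.ndarray, bim: pd.DataFrame,
              fam: pd.DataFrame) -> None:
    """Write a BED/BIM/FAM triple from an N x M allele-1 dosage matrix."""
    prefix = str(prefix)
    dosages = np.asarray(dosages, dtype=np.float64)
    n, m = dosages.shape
    if len(bim) != m or len(fam) != n:
        raise ValueError("bim/fam lengths do not match the dosage matrix")
    # dosage -> 2-bit code
    codes = np.full((m, n), 0b01, dtype=np.uint8)  # missing by default
    d = dosages.T
    codes[d == 2] = 0b00
    codes[d == 1] = 0b10
    codes[d == 0] = 0b11
    bytes_per_variant = (n + 3) // 4
    padded = np.zeros((m, bytes_per_variant * 4), dtype=np.uint8)
    padded[:, :n] = codes
    body = np.zeros((m, bytes_per_variant), dtype=np.uint8)
    for k in range(4):
        body |= padded[:, k::4] << (2 * k)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_MAGIC)
        body.tofile(fh)
    bim[BIM_COLUMNS].to_csv(f"{prefix}.bim", sep="\t", header=False,
                            index=False)
    fam[FAM_COLUMNS].to_csv(f"{prefix}.fam", sep="\t", header=False,
                            index=False)


def default_fam(n: int) -> pd.DataFrame:
    return pd.DataFrame({
        "fid": [f"F{i}" for i in range(n)],
        "iid": [f"I{i}" for i in range(n)],
        "father": ["0"] * n,
        "mother": ["0"] * n,
        "sex": [0] * n,
        "phenotype": [-9] * n,
    })


def exists(prefix) -> bool:
    return all(Path(f"{prefix}{ext}").exists() for ext in (".bed", ".bim", ".fam"))
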