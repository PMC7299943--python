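"""PLINK1 bed/bim/fam reader and writer.

Variant-major .bed only (magic bytes 0x6c 0x1b, mode 0x01).  Two-bit codes
per PLINK1 convention, with the first sample of each variant in the two
low-order bits of the first byte:

    00 -> homozygous A1 (dosage 2; dosage counts the A1/alternate allele)
    01 -> missing
    10 -> heterozygous (dosage 1)
    11 -> homozygous A2 (dosage 0)

The simulator has no genome, so .bim positions are synthetic consecutive
1-based integers on chromosome 1, with alleles written as A1='A', A2='G'.
"""

from __future__ import annotations

import hashlib
import os

import numpy as np
import pandas as pd

from . import __version__
from .simdata import MISSING, GenotypeMatrix, Pedigree, UNKNOWN

MAGIC = bytes((0x6C, 0x1B))
MODE_VARIANT_MAJOR = 0x01

# dosage -> 2-bit code and back
_CODE_OF_DOSAGE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
_DOSAGE_OF_CODE = np.array([2, MISSING, 1, 0], dtype=np.int8)


class PlinkFormatError(ValueError):
    pass


def header_comment(seed=None, inputs=()) -> str:
    """Standard provenance line for text outputs: version, seed, input hashes."""
    parts = [f"kinpred={__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    for path in inputs:
        try:
            digest = hashlib.md5(open(path, "rb").read()).hexdigest()[:12]
            parts.append(f"{os.path.basename(path)}={digest}")
        except OSError:
            parts.append(f"{os.path.basename(path)}=unreadable")
    return " ".join(parts)


def write_plink(
    genotypes: GenotypeMatrix, prefix, pedigree: Pedigree | None = None
) -> None:
    """Write <prefix>.bed/.bim/.fam; round-trips dosages and ids exactly."""
    n, m = genotypes.n_individuals, genotypes.n_snps

    # .fam — family/parents/sex from the pedigree when given
    if pedigree is not None:
        ped = pedigree.table.set_index("iid")
        rows = []
        for iid in genotypes.ids:
            r = ped.loc[iid]
            sex = 1 if r["sex"] == "M" else 2
            rows.append((r["family_id"], iid, r["sire"], r["dam"], sex, -9))
    else:
        rows = [(iid, iid, UNKNOWN, UNKNOWN, 0, -9) for iid in genotypes.ids]
    pd.DataFrame(rows).to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)

    # .bim — synthetic coordinates on chromosome 1
    with open(f"{prefix}.bim", "w") as fh:
        for k, snp in enumerate(genotypes.snp_ids):
            fh.write(f"1\t{snp}\t0\t{k + 1}\tA\tG\n")

    # .bed — variant-major, 4 samples per byte, LSB first
    codes = np.empty((m, n), dtype=np.uint8)
    dosages_t = genotypes.dosages.T
    for dosage, code in _CODE_OF_DOSAGE.items():
        codes[dosages_t == dosage] = code
    n_bytes = (n + 3) // 4
    padded = np.zeros((m, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    ).astype(np.uint8)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(MAGIC)
        fh.write(bytes((MODE_VARIANT_MAJOR,)))
        fh.write(packed.tobytes())


def read_plink(prefix) -> GenotypeMatrix:
    """Read <prefix>.bed/.bim/.fam into a GenotypeMatrix (missing -> -1)."""
    fam = pd.read_csv(
        f"{prefix}.fam", sep=r"\s+", header=None, dtype=str,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
    )
    try:
        bim = pd.read_csv(
            f"{prefix}.bim", sep=r"\s+", header=None, dtype=str,
            names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        )
    except pd.errors.EmptyDataError:
        bim = pd.DataFrame(columns=["chrom", "snp", "cm", "pos", "a1", "a2"])
    n, m = len(fam), len(bim)
    with open(f"{prefix}.bed", "rb") as fh:
        raw = fh.read()
    if raw[:2] != MAGIC:
        raise PlinkFormatError(
            f"bad .bed magic bytes {raw[:2].hex()}; expected {MAGIC.hex()}"
        )
    if len(raw) < 3 or raw[2] != MODE_VARIANT_MAJOR:
        raise PlinkFormatError(
            "only variant-major .bed (mode 0x01) is supported"
        )
    n_bytes = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * n_bytes:
        raise PlinkFormatError(
            f".bed holds {body.size} data bytes; expected {m * n_bytes} "
            f"({m} variants x {n_bytes} bytes)"
        )
    body = body.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0b11
    codes[:, 1::4] = (body >> 2) & 0b11
    codes[:, 2::4] = (body >> 4) & 0b11
    codes[:, 3::4] = (body >> 6) & 0b11
    dosages = _DOSAGE_OF_CODE[codes[:, :n]].T
    return GenotypeMatrix(
        fam["iid"].to_numpy(dtype=object),
        bim["snp"].to_numpy(dtype=object),
        dosages,
    )
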