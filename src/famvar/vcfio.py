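"""File I/O: phased VCF import/export and pedigree/result TSVs.

Conventions: VCF positions are 1-based (internal locus indices 0-based);
phased genotypes are written maternal allele first (``Am|Af``), matching
the ordered-genotype convention used throughout the package.  Output
headers record the package version, the seed and a hash of the
generating configuration so every file is traceable to its run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .founders import HaplotypePanel

__all__ = [
    "read_founder_vcf",
    "write_vcf",
    "write_pedigree_tsv",
    "config_hash",
]

logger = logging.getLogger(__name__)


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def read_founder_vcf(path: str | Path) -> HaplotypePanel:
    """Load phased biallelic genotypes from a VCF as a founder panel.

    Unphased or multiallelic records are skipped (counts logged).  The
    two haplotype columns of each sample are taken in VCF order, first
    column treated as the maternal haplotype.  Raises if no usable
    records remain.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    rows = []
    n_unphased = n_multi = 0
    for record in vcf:
        if len(record.ALT) != 1 or len(record.REF) != 1 or len(record.ALT[0]) != 1:
            n_multi += 1
            continue
        gts = record.genotype.array()  # (n_samples, 3): allele0, allele1, phased
        if not np.all(gts[:, 2] == 1):
            n_unphased += 1
            continue
        if np.any(gts[:, :2] < 0):
            n_unphased += 1
            continue
        rows.append(gts[:, :2].reshape(-1))  # haplotypes interleaved per sample
    if n_unphased or n_multi:
        logger.info(
            "skipped %d unphased/incomplete and %d multiallelic records",
            n_unphased,
            n_multi,
        )
    if not rows:
        raise ValueError(f"no phased biallelic records in {path}")
    hap = np.array(rows, dtype=np.uint8).T  # (2 n_samples, n_loci)
    freqs = hap.mean(axis=0)
    return HaplotypePanel(
        haplotypes=hap, allele_freqs=freqs, positions=np.arange(hap.shape[1])
    )


def write_vcf(
    maternal: np.ndarray,
    paternal: np.ndarray,
    path: str | Path,
    sample_ids: list[str] | None = None,
    meta: dict | None = None,
) -> Path:
    """Write phased genotypes as a minimal VCF 4.2 text file.

    ``maternal``/``paternal`` are (n, L) haplotype matrices; the GT field
    is ``Am|Af``.  Loci become consecutive 1-based positions on a single
    synthetic contig.
    """
    maternal = np.asarray(maternal, dtype=np.uint8)
    paternal = np.asarray(paternal, dtype=np.uint8)
    if maternal.shape != paternal.shape:
        raise ValueError("haplotype matrices must have equal shape")
    n, n_loci = maternal.shape
    if sample_ids is None:
        sample_ids = [f"ind{i}" for i in range(n)]
    path = Path(path)
    from . import __version__

    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=famvar {__version__}\n")
        fh.write("##phasing=full;maternal allele first (Am|Af)\n")
        if meta:
            for k, v in sorted(meta.items()):
                fh.write(f"##famvar_{k}={v}\n")
        fh.write(f"##contig=<ID=1,length={n_loci + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for j in range(n_loci):
            gts = "\t".join(
                f"{maternal[i, j]}|{paternal[i, j]}" for i in range(n)
            )
            fh.write(f"1\t{j + 1}\tsnp{j}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")
    return path


def write_pedigree_tsv(
    frame: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> Path:
    """Write a pedigree/phenotype table with a commented provenance header.

    Expected columns: id, father, mother, sex, generation, phenotype
    (extra columns pass through).  Deterministic column order.
    """
    path = Path(path)
    lead = [c for c in ("id", "father", "mother", "sex", "generation", "phenotype") if c in frame.columns]
    rest = [c for c in frame.columns if c not in lead]
    frame = frame[lead + rest]
    from . import __version__

    with path.open("w") as fh:
        fh.write(f"# famvar {__version__}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        if config is not None:
            fh.write(f"# config_hash: {config_hash(config)}\n")
        frame.to_csv(fh, sep="\t", index=False)
    return path


def population_pedigree_frame(history) -> pd.DataFrame:
    """Flatten a generation history into one pedigree table.

    Ids are ``g{generation}_{index}``; founder parent links are empty.
    """
    rows = []
    for pop in history:
        gen = pop.generation
        for i in range(pop.n):
            mid = pop.mother_id[i]
            fid = pop.father_id[i]
            rows.append(
                {
                    "id": f"g{gen}_{i}",
                    "father": f"g{gen - 1}_{fid}" if fid >= 0 else "",
                    "mother": f"g{gen - 1}_{mid}" if mid >= 0 else "",
                    "sex": "F" if pop.sex[i] == 0 else "M",
                    "generation": gen,
                    "phenotype": float(pop.phenotype[i]),
                }
            )
    return pd.DataFrame(rows)
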