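"""Readers and writers: complex NIfTI pairs + JSON sidecars, parameter-map
NIfTI sets, cohort TSVs and a minimal VCF genotype reader.

All writes are atomic (write to a temporary file in the target directory,
then rename), so partially written outputs are never parseable as complete.
Complex echo stacks are stored as ``<stem>_real.nii.gz`` /
``<stem>_imag.nii.gz`` 3-D volumes (echo along the third axis) with a
``<stem>.json`` sidecar holding the protocol.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np
import pandas as pd

from .types import Cohort, MultiEchoImage, ParameterMaps, Protocol

__all__ = [
    "atomic_write_bytes",
    "atomic_write_text",
    "write_nifti",
    "read_nifti",
    "write_multiecho",
    "read_multiecho",
    "write_parameter_maps",
    "read_parameter_maps",
    "write_cohort",
    "read_cohort",
    "read_vcf_genotypes",
    "write_json",
]

_MAP_NAMES = ("rho_w", "rho_f", "field_map", "r2star", "mask")


def atomic_write_bytes(path: Union[str, Path], payload: bytes) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(payload)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_text(path: Union[str, Path], text: str) -> None:
    atomic_write_bytes(path, text.encode("utf-8"))


def write_json(path: Union[str, Path], obj) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_nifti(path: Union[str, Path], data: np.ndarray, dtype=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype) if dtype else np.asarray(data), np.eye(4))
    # atomic: save under a temporary name with the same compression suffix,
    # then rename into place
    suffix = "".join(path.suffixes)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=suffix)
    os.close(fd)
    try:
        nib.save(img, tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_nifti(path: Union[str, Path]) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing NIfTI file: {path}")
    return np.asarray(nib.load(str(path)).get_fdata())


def write_multiecho(image: MultiEchoImage, stem: Union[str, Path]) -> None:
    """Write ``<stem>_real.nii.gz``, ``<stem>_imag.nii.gz`` and ``<stem>.json``."""
    stem = Path(stem)
    write_nifti(stem.parent / f"{stem.name}_real.nii.gz", image.data.real, dtype=np.float64)
    write_nifti(stem.parent / f"{stem.name}_imag.nii.gz", image.data.imag, dtype=np.float64)
    write_json(stem.parent / f"{stem.name}.json", image.protocol.to_sidecar())


def read_multiecho(stem: Union[str, Path]) -> MultiEchoImage:
    """Read a complex echo stack written by :func:`write_multiecho`.

    Raises when a component is missing or the sidecar echo count disagrees
    with the volumes.
    """
    stem = Path(stem)
    real_path = stem.parent / f"{stem.name}_real.nii.gz"
    imag_path = stem.parent / f"{stem.name}_imag.nii.gz"
    sidecar_path = stem.parent / f"{stem.name}.json"
    for p in (real_path, imag_path, sidecar_path):
        if not p.exists():
            raise FileNotFoundError(f"missing component: {p}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    protocol = Protocol.from_sidecar(sidecar)
    real = read_nifti(real_path)
    imag = read_nifti(imag_path)
    if real.shape != imag.shape:
        raise ValueError("real/imaginary volumes have different shapes")
    if real.ndim != 3 or real.shape[2] != protocol.n_echo:
        raise ValueError(
            f"echo-count mismatch: volumes have {real.shape[-1] if real.ndim == 3 else '?'}"
            f" echoes, sidecar lists {protocol.n_echo}"
        )
    return MultiEchoImage(data=real + 1j * imag, protocol=protocol)


def write_parameter_maps(maps: ParameterMaps, stem: Union[str, Path]) -> None:
    stem = Path(stem)
    for name in _MAP_NAMES:
        arr = getattr(maps, name)
        dtype = np.uint8 if name == "mask" else np.float64
        write_nifti(stem.parent / f"{stem.name}_{name}.nii.gz", arr, dtype=dtype)


def read_parameter_maps(stem: Union[str, Path]) -> ParameterMaps:
    stem = Path(stem)
    arrays = {}
    for name in _MAP_NAMES:
        arrays[name] = read_nifti(stem.parent / f"{stem.name}_{name}.nii.gz")
    arrays["mask"] = arrays["mask"] > 0.5
    return ParameterMaps(**arrays)


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------


def write_cohort(cohort: Cohort, directory: Union[str, Path]) -> None:
    """Write samples.tsv (covariates/traits/diagnoses), genotypes.tsv and
    variants.tsv under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    samples = pd.concat(
        [
            cohort.covariates,
            cohort.traits.add_prefix("trait_"),
            cohort.diagnoses.astype(int).add_prefix("dx_"),
        ],
        axis=1,
    )
    samples.index.name = "sample_id"
    atomic_write_text(directory / "samples.tsv", samples.to_csv(sep="\t"))
    geno = cohort.genotypes.copy()
    geno.index.name = "sample_id"
    atomic_write_text(directory / "genotypes.tsv", geno.to_csv(sep="\t"))
    variants = pd.DataFrame({"variant_id": cohort.mafs.index, "maf": cohort.mafs.values})
    atomic_write_text(directory / "variants.tsv", variants.to_csv(sep="\t", index=False))


def _read_table(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"missing table: {path}")
    sep = "\t" if path.suffix != ".csv" else ","
    return pd.read_csv(path, sep=sep)


def read_cohort(directory: Union[str, Path]) -> Cohort:
    """Read a cohort written by :func:`write_cohort` (TSV dialect; CSV accepted)."""
    directory = Path(directory)
    samples = _read_table(directory / "samples.tsv")
    if samples["sample_id"].duplicated().any():
        dupes = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicated sample ids: {dupes}")
    samples = samples.set_index("sample_id")
    geno = _read_table(directory / "genotypes.tsv")
    if geno["sample_id"].duplicated().any():
        raise ValueError("duplicated sample ids in genotype table")
    geno = geno.set_index("sample_id")
    if set(geno.index) != set(samples.index):
        raise ValueError("sample ids differ between samples.tsv and genotypes.tsv")
    geno = geno.loc[samples.index]
    bad = ~geno.isin([0, 1, 2]).to_numpy()
    if bad.any():
        raise ValueError("malformed genotype values (must be 0/1/2)")
    variants = _read_table(directory / "variants.tsv").set_index("variant_id")["maf"]

    trait_cols = [c for c in samples.columns if c.startswith("trait_")]
    dx_cols = [c for c in samples.columns if c.startswith("dx_")]
    cov_cols = [c for c in samples.columns if c not in trait_cols + dx_cols]
    return Cohort(
        genotypes=geno,
        mafs=variants.reindex(geno.columns),
        covariates=samples[cov_cols],
        traits=samples[trait_cols].rename(columns=lambda c: c[len("trait_") :]),
        diagnoses=samples[dx_cols].rename(columns=lambda c: c[len("dx_") :]).astype(bool),
    )


def read_vcf_genotypes(path: Union[str, Path], missing_code: int = -1) -> pd.DataFrame:
    """Minimal VCF genotype reader (GT field only, diploid allele counts).

    ``0/0 -> 0``, ``0/1``/``1/0`` -> 1, ``1/1 -> 2``, ``./.`` -> the explicit
    ``missing_code``. Phasing separators are treated identically to ``/``.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing VCF: {path}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, columns = [], []
    for variant in vcf:
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        counts = np.full(len(samples), missing_code, dtype=int)
        for i, gt in enumerate(variant.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) == 2:
                counts[i] = int(sum(1 for a in alleles if a > 0))
        ids.append(vid)
        columns.append(counts)
    vcf.close()
    if not ids:
        raise ValueError(f"no variants in {path}")
    return pd.DataFrame(np.column_stack(columns), index=samples, columns=ids)
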