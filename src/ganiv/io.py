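"""Delimited-text and VCF input/output.

Datasets travel as TSV matrices with a YAML sidecar recording the
generating specification and seed.  Genotypes may also arrive as a VCF;
biallelic SNP records are converted to alternate-allele dosage (0/1/2),
indels and missing-ALT records are dropped, and missing genotypes are
imputed to the column mean downstream.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "write_dataset_tsv",
    "read_dataset_tsv",
    "read_delimited_matrix",
    "vcf_to_dosage",
]


def _spec_dict(obj):
    if dataclasses.is_dataclass(obj):
        return {
            k: _spec_dict(v) for k, v in dataclasses.asdict(obj).items()
        }
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _spec_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_spec_dict(v) for v in obj]
    return obj


def write_dataset_tsv(ds, path) -> Path:
    """Write a simulated dataset as TSV plus a ``.spec.yaml`` sidecar."""
    path = Path(path)
    cols = {"sample_id": np.arange(ds.Z.shape[0])}
    for j in range(ds.Z.shape[1]):
        cols[f"snp_{j}"] = ds.Z[:, j].astype(int)
    cols["G"] = ds.G
    cols["Y"] = ds.Y
    for name in ("U", "h_vals", "y0"):
        val = getattr(ds, name, None)
        if val is not None:
            cols[name] = val
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    spec = {
        "seed": int(ds.seed),
        "n": int(ds.Z.shape[0]),
        "n_snps": int(ds.Z.shape[1]),
        "noise_spec": _spec_dict(getattr(ds, "noise_spec", None)),
        "causal_spec": _spec_dict(getattr(ds, "causal_spec", None)),
        "alpha0": _spec_dict(getattr(ds, "alpha0", None)),
        "alpha1": _spec_dict(getattr(ds, "alpha1", None)),
    }
    with open(path.with_suffix(path.suffix + ".spec.yaml"), "w") as fh:
        yaml.safe_dump(spec, fh)
    return path


def read_dataset_tsv(path) -> dict:
    """Read a dataset TSV (and its sidecar, if present) into arrays."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    snp_cols = [c for c in df.columns if c.startswith("snp_")]
    out = {
        "Z": df[snp_cols].to_numpy(dtype=float),
        "G": df["G"].to_numpy(dtype=float) if "G" in df else None,
        "Y": df["Y"].to_numpy(dtype=float) if "Y" in df else None,
    }
    for opt in ("U", "h_vals", "y0"):
        out[opt] = df[opt].to_numpy(dtype=float) if opt in df else None
    sidecar = path.with_suffix(path.suffix + ".spec.yaml")
    if sidecar.exists():
        with open(sidecar) as fh:
            out["spec"] = yaml.safe_load(fh)
    return out


def read_delimited_matrix(path, id_column: str = "sample_id"):
    """Read a TSV with a sample-id column; returns (ids, columns, matrix)."""
    df = pd.read_csv(path, sep="\t")
    if id_column in df.columns:
        ids = df[id_column].to_numpy()
        df = df.drop(columns=[id_column])
    else:
        ids = np.arange(len(df))
    return ids, list(df.columns), df.to_numpy(dtype=float)


def vcf_to_dosage(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Alternate-allele dosage matrix from a VCF.

    Keeps biallelic SNP records only (indels and missing-ALT dropped);
    missing genotypes are imputed to the variant mean dosage.  Returns
    ``(dosages, variant_ids, sample_ids)``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, ids = [], []
    for var in vcf:
        if len(var.ALT) != 1 or not var.ALT[0] or var.ALT[0] == ".":
            continue
        if len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue  # indel
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (gts012=False maps 3->unknown)
        d = np.asarray(var.gt_types, dtype=float)
        d[d == 2] = np.nan  # cyvcf2 default: 2 is UNKNOWN, 3 is hom-alt
        d[d == 3] = 2.0
        if np.isnan(d).all():
            continue
        m = np.nanmean(d)
        d = np.where(np.isnan(d), m, d)
        rows.append(d)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    if not rows:
        raise ValueError("no biallelic SNP records in VCF")
    return np.asarray(rows).T, ids, samples
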