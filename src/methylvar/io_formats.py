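"""Readers/writers for every external file the pipeline touches.

TSV is the canonical interchange: marker matrices are individuals-by-
markers with the individual id in the first column and marker ids as the
header.  PLINK bed/bim/fam is accepted read-only for genotypes through a
small 2-bit decoder.  Weight files are two-column TSV with ``#key=value``
metadata lines carrying the training anchors.  Result objects serialize
to a versioned JSON schema plus a human-readable TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .scoring import WeightSet

__all__ = [
    "read_marker_matrix",
    "write_marker_matrix",
    "read_plink_bed",
    "read_weights",
    "write_weights",
    "write_report",
    "read_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = "1.0"


def _validate_range(values: np.ndarray, lo: float, hi: float, ids, cols, what: str):
    bad = np.argwhere((values < lo) | (values > hi))
    if len(bad):
        cells = [f"(row {ids[i]}, column {cols[j]}: {values[i, j]!r})" for i, j in bad[:10]]
        raise ValueError(f"{what} values outside [{lo}, {hi}]: " + "; ".join(cells))


def read_marker_matrix(path, kind: str, value_type: str = "auto"):
    """Read an individuals-by-markers TSV/CSV.

    ``kind`` is ``'genotype'`` (dosages validated to [0, 2]) or
    ``'methylation'`` (betas validated to [0, 1]; ``value_type='auto'``
    accepts M-values when any entry falls outside [0, 1] by more than a
    rounding margin, ``'beta'`` forces the range check, ``'mvalue'``
    skips it).  Returns ``(values, individual_ids, marker_ids)``.
    """
    if kind not in ("methylation", "genotype"):
        raise ValueError("kind must be 'methylation' or 'genotype'")
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, header=0, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected an id column plus at least one marker column")
    ids = df.iloc[:, 0].to_numpy(dtype=str)
    if len(np.unique(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate individual ids")
    cols = np.asarray(df.columns[1:], dtype=str)
    if len(np.unique(cols)) != len(cols):
        raise ValueError(f"{path}: duplicate marker ids")
    try:
        values = df.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric marker values ({exc})") from None
    if np.any(~np.isfinite(values)):
        raise ValueError(f"{path}: missing or non-finite marker values")
    if kind == "genotype":
        _validate_range(values, 0.0, 2.0, ids, cols, "genotype dosage")
    elif value_type == "beta" or (
        value_type == "auto" and values.min() >= -1e-9 and values.max() <= 1 + 1e-9
    ):
        _validate_range(values, 0.0, 1.0, ids, cols, "methylation beta")
    return values, ids, cols


def write_marker_matrix(path, values, individual_ids, marker_ids) -> None:
    df = pd.DataFrame(np.asarray(values, dtype=float), columns=np.asarray(marker_ids))
    df.insert(0, "iid", np.asarray(individual_ids))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def align_by_ids(id_lists, mode: str = "strict"):
    """Align individual id vectors across files.

    ``mode='strict'`` requires identical id sets (any mismatch raises);
    ``mode='intersect'`` keeps the common ids and reports the dropped
    ones.  Returns ``(common_ids, [row-index array per input], dropped)``
    with the common ids in the order of the first input.
    """
    if mode not in ("strict", "intersect"):
        raise ValueError("mode must be 'strict' or 'intersect'")
    sets = [set(map(str, ids)) for ids in id_lists]
    common = set.intersection(*sets)
    dropped = sorted(set.union(*sets) - common)
    if mode == "strict" and dropped:
        raise ValueError(f"individual ids do not match across files: {dropped[:10]}")
    order = [str(i) for i in id_lists[0] if str(i) in common]
    indexers = []
    for ids in id_lists:
        pos = {str(v): k for k, v in enumerate(ids)}
        indexers.append(np.array([pos[i] for i in order], dtype=int))
    return np.array(order), indexers, dropped


# ----------------------------------------------------------------------
# PLINK binary genotypes (read-only adapter)

_BED_MAGIC = b"\x6c\x1b\x01"  # SNP-major bed file
# 2-bit codes -> dosage of the A1 allele; 0b01 is missing
_BED_CODE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink_bed(prefix, impute_missing: bool = False):
    """Decode PLINK ``prefix.bed/.bim/.fam`` to an A1-dosage matrix.

    Returns ``(dosages, individual_ids, snp_ids)`` with dosages counting
    the A1 allele of the .bim file.  Missing genotypes are fatal unless
    ``impute_missing`` replaces them with the per-SNP mean dosage.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None)
    n, p = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK bed file")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if len(body) != bytes_per_snp * p:
        raise ValueError(f"{prefix}.bed: truncated (expected {bytes_per_snp * p} data bytes)")
    blocks = body.reshape(p, bytes_per_snp)
    # unpack 2-bit fields, little-endian within each byte
    shifts = np.arange(4) * 2
    codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(p, -1)[:, :n]
    G = _BED_CODE[codes].T  # n x p
    if np.isnan(G).any():
        if not impute_missing:
            raise ValueError(
                f"{prefix}.bed contains missing genotypes; pass impute_missing=True "
                "to mean-impute (off by default)"
            )
        mean = np.nanmean(G, axis=0)
        idx = np.where(np.isnan(G))
        G[idx] = mean[idx[1]]
    iids = fam.iloc[:, 1].to_numpy(dtype=str)
    snps = bim.iloc[:, 1].to_numpy(dtype=str)
    return G, iids, snps


# ----------------------------------------------------------------------
# weight files


def write_weights(ws: WeightSet, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"#source={ws.source}\n")
        if ws.train_pheno_mean is not None:
            fh.write(f"#train_pheno_mean={ws.train_pheno_mean!r}\n")
        if ws.train_pheno_sd is not None:
            fh.write(f"#train_pheno_sd={ws.train_pheno_sd!r}\n")
        fh.write("marker_id\tweight\n")
        for m, w in zip(ws.marker_ids, ws.weights):
            fh.write(f"{m}\t{float(w)!r}\n")


def read_weights(path) -> WeightSet:
    meta = {}
    rows = []
    with open(path) as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key] = val
                continue
            if not header_seen:
                header_seen = True  # column header line
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: malformed weight line {line!r}")
            rows.append(parts)
    if not rows:
        raise ValueError(f"{path}: no weights found")
    ids = np.array([r[0] for r in rows])
    w = np.array([float(r[1]) for r in rows])
    return WeightSet(
        marker_ids=ids,
        weights=w,
        source=meta.get("source", ""),
        train_pheno_mean=float(meta["train_pheno_mean"]) if "train_pheno_mean" in meta else None,
        train_pheno_sd=float(meta["train_pheno_sd"]) if "train_pheno_sd" in meta else None,
    )


# ----------------------------------------------------------------------
# result reports


def write_report(result, path_prefix) -> dict:
    """Serialize a fitted result object to ``<prefix>.json`` + ``<prefix>.tsv``.

    Any object exposing ``to_dict()`` (BayesRResults, RemlFit,
    BivariateFit, ScoreReport, PhewasTable) is accepted; the JSON carries
    a schema version and deterministic key order.
    """
    if not hasattr(result, "to_dict"):
        raise TypeError(f"{type(result).__name__} is not serializable (no to_dict)")
    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "result_type": type(result).__name__,
        "data": result.to_dict(),
    }
    try:
        text = json.dumps(payload, indent=1, sort_keys=True, allow_nan=False)
    except ValueError:
        # NaN/inf are legal fit outputs (e.g. a p-value underflow guard)
        text = json.dumps(payload, indent=1, sort_keys=True)
    except TypeError as exc:
        raise TypeError(f"unserializable field in {type(result).__name__}: {exc}") from None
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    json_path = prefix.with_suffix(".json")
    json_path.write_text(text + "\n")
    tsv_path = prefix.with_suffix(".tsv")
    _report_tsv(result, tsv_path)
    return {"json": str(json_path), "tsv": str(tsv_path)}


def _report_tsv(result, path) -> None:
    d = result.to_dict()
    rows = []
    for key, val in sorted(d.items()):
        if isinstance(val, dict):
            for k2, v2 in sorted(val.items()):
                rows.append((f"{key}.{k2}", _fmt(v2)))
        else:
            rows.append((key, _fmt(val)))
    with open(path, "w") as fh:
        fh.write("field\tvalue\n")
        for k, v in rows:
            fh.write(f"{k}\t{v}\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    if isinstance(v, (list, dict)):
        return json.dumps(v)
    return str(v)


def read_report(path) -> dict:
    """Load a report JSON; returns ``{'schema_version', 'result_type', 'data'}``."""
    with open(path) as fh:
        payload = json.load(fh)
    for key in ("schema_version", "result_type", "data"):
        if key not in payload:
            raise ValueError(f"{path}: not a report file (missing {key!r})")
    return payload
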