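"""Reading and writing study matrices, labels, parameters and reports.

Study matrices are plain delimited text (tab or comma, auto-detected):
a header row of gene symbols and one row per sample.  Studies are aligned
by intersecting their gene symbols; genes present in only some studies
are dropped and logged.  Fitted parameters round-trip through a small
versioned JSON format with explicit ``k,m,p`` index keys.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import NetworkParams, OmicsStack

__all__ = [
    "read_stack",
    "write_stack",
    "save_params",
    "load_params",
    "write_loss_history",
    "write_selection",
]

logger = logging.getLogger(__name__)

PARAMS_FORMAT_VERSION = 1
#: Numeric formatting used by every writer, chosen so write->read
#: round-trips double precision exactly.
FLOAT_FMT = "%.17g"


def _read_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ("," if "," in header else "\t")
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any() and not df.isna().to_numpy().any():
        bad = np.argwhere(numeric.isna().to_numpy())
        r, c = bad[0]
        raise ValueError(
            f"non-numeric cell in {path} at data row {r + 1}, column '{df.columns[c]}'"
        )
    if numeric.isna().to_numpy().any():
        bad = np.argwhere(numeric.isna().to_numpy())
        r, c = bad[0]
        raise ValueError(
            f"missing value in {path} at data row {r + 1}, column '{df.columns[c]}'"
        )
    return numeric


def read_stack(study_paths: Sequence[str | Path], labels_path: str | Path) -> OmicsStack:
    """Load per-study matrices plus a labels file into an aligned stack.

    Gene columns are intersected across studies (keeping the first
    study's order); a manifest of dropped symbols is logged.  The labels
    file holds one 0/1 per line, matching the shared sample count.
    """
    frames = [_read_matrix(p) for p in study_paths]
    if not frames:
        raise ValueError("at least one study matrix is required")
    common = [g for g in frames[0].columns if all(g in f.columns for f in frames[1:])]
    if not common:
        raise ValueError("studies share no gene symbols")
    dropped = sorted(
        {g for f in frames for g in f.columns if g not in common}
    )
    if dropped:
        logger.info(
            "dropped %d gene(s) absent from some study: %s", len(dropped), ", ".join(dropped)
        )
    n = frames[0].shape[0]
    for p, f in zip(study_paths, frames):
        if f.shape[0] != n:
            raise ValueError(
                f"{p} has {f.shape[0]} samples, expected {n}: all studies must share samples"
            )
    matrices = [f[common].to_numpy(dtype=float) for f in frames]

    labels = np.loadtxt(labels_path, dtype=float, ndmin=1)
    if labels.shape[0] != n:
        raise ValueError(
            f"labels file has {labels.shape[0]} entries but studies have {n} samples"
        )
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be 0/1")
    study_ids = [Path(p).stem for p in study_paths]
    return OmicsStack.from_matrices(
        matrices, labels.astype(int), gene_ids=common, study_ids=study_ids
    )


def write_stack(
    stack: OmicsStack,
    outdir: str | Path,
    truth: np.ndarray | None = None,
) -> list[Path]:
    """Write one TSV per study plus labels (and optional truth) files.

    Only the first feature channel is written (the text interchange
    format is one value per gene per study).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for m, sid in enumerate(stack.study_ids):
        df = pd.DataFrame(stack.values[:, :, m, 0], columns=stack.gene_ids)
        path = outdir / f"{sid}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
        written.append(path)
    labels_path = outdir / "labels.txt"
    np.savetxt(labels_path, stack.labels, fmt="%d")
    written.append(labels_path)
    if truth is not None:
        truth_path = outdir / "truth.tsv"
        pd.DataFrame(
            {"gene_id": stack.gene_ids, "is_signal": np.asarray(truth).astype(int)}
        ).to_csv(truth_path, sep="\t", index=False)
        written.append(truth_path)
    return written


def save_params(params: NetworkParams, path: str | Path) -> None:
    """Serialize parameters as JSON with explicit index keys."""
    k, m, p = params.v.shape
    payload = {
        "format_version": PARAMS_FORMAT_VERSION,
        "shape": {"n_genes": k, "n_hidden": m, "n_features": p},
        "v": {
            f"{i},{j},{q}": params.v[i, j, q]
            for i in range(k)
            for j in range(m)
            for q in range(p)
        },
        "w": {f"{i},{j}": params.w[i, j] for i in range(k) for j in range(m)},
        "beta0": params.beta0,
        "beta": {str(i): params.beta[i] for i in range(k)},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_params(path: str | Path) -> NetworkParams:
    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != PARAMS_FORMAT_VERSION:
        raise ValueError(f"unsupported params format version: {version!r}")
    shape = payload["shape"]
    k, m, p = shape["n_genes"], shape["n_hidden"], shape["n_features"]
    v = np.empty((k, m, p))
    for key, value in payload["v"].items():
        i, j, q = map(int, key.split(","))
        v[i, j, q] = value
    w = np.empty((k, m))
    for key, value in payload["w"].items():
        i, j = map(int, key.split(","))
        w[i, j] = value
    beta = np.empty(k)
    for key, value in payload["beta"].items():
        beta[int(key)] = value
    return NetworkParams(v=v, w=w, beta0=float(payload["beta0"]), beta=beta)


def write_loss_history(history: Sequence[float], path: str | Path) -> None:
    """Machine-readable training trace: epoch and penalized loss per line."""
    df = pd.DataFrame({"epoch": np.arange(len(history)), "loss": history})
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_selection(
    params: NetworkParams,
    gene_ids: Sequence[str],
    eps: float,
    path: str | Path,
) -> None:
    """Per-gene coefficient magnitudes and selection calls as TSV."""
    df = pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "beta_hat": params.beta,
            "selected": (np.abs(params.beta) > eps).astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
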