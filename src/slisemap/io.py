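"""CSV/JSON readers and writers: datasets in, solutions out, losslessly.

A solution directory holds plain-text artefacts only (diffable, no binary
formats): ``Z.csv`` and ``B.csv`` with full float precision, ``data.csv``
with the standardized features/targets, and ``metadata.json`` with the
family, penalties, radius, seed, standardization parameters and the final
loss.  ``read_solution`` recomputes the loss from the stored matrices and
refuses to load if it disagrees with the stored value (tamper check).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Embedding, LocalModelBank, SlisemapSolution
from .data import Dataset, LINEAR, LOGISTIC

__all__ = ["read_dataset", "write_solution", "read_solution"]

_VERSION = "slisemap-solution-1"
_LOSS_TOL = 1e-8


def read_dataset(path, target, *, family: str = LINEAR,
                 standardize_target="auto") -> Dataset:
    """Read a CSV with a header row into a standardized :class:`Dataset`.

    ``target`` is a column name (regression / binary probability) or a
    list of per-class probability columns (the positive class last).
    """
    df = pd.read_csv(path)
    targets = [target] if isinstance(target, str) else list(target)
    for t in targets:
        if t not in df.columns:
            raise ValueError(f"target column {t!r} not in {list(df.columns)}")
    feat_cols = [c for c in df.columns if c not in targets]
    X = df[feat_cols]
    if not all(np.issubdtype(d, np.number) for d in X.dtypes):
        bad = [c for c, d in zip(feat_cols, X.dtypes) if not np.issubdtype(d, np.number)]
        raise ValueError(f"non-numeric feature column(s): {bad}")
    if df[feat_cols + targets].isna().any().any():
        rows = df.index[df[feat_cols + targets].isna().any(axis=1)][:20].tolist()
        raise ValueError(f"missing values in rows {rows}")
    fam = LOGISTIC if family in ("logistic", LOGISTIC) else LINEAR
    Y = df[targets].to_numpy(dtype=float)
    if fam == LOGISTIC and Y.shape[1] == 2:
        Y = Y[:, 1:]
    return Dataset.from_raw(
        X.to_numpy(dtype=float), Y, feature_names=feat_cols,
        target_names=targets[-1:] if fam == LOGISTIC else targets,
        family=fam, standardize_target=standardize_target,
    )


def _save_matrix(path: Path, M: np.ndarray, header: list[str] | None = None):
    df = pd.DataFrame(M, columns=header)
    df.to_csv(path, index=False, float_format="%.17g")


def write_solution(solution: SlisemapSolution, directory) -> Path:
    """Serialise a solution as a directory of CSV matrices + JSON metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ds = solution.dataset
    emb, bank = solution.embedding, solution.models
    _save_matrix(directory / "Z.csv", emb.Z,
                 [f"z{k}" for k in range(emb.d)])
    _save_matrix(directory / "B.csv", bank.B,
                 [f"b{k}" for k in range(bank.p)])
    data = pd.DataFrame(ds.X, columns=ds.feature_names)
    for j, name in enumerate(ds.target_names or [f"y{j}" for j in range(ds.o)]):
        data[f"target:{name}"] = ds.Y[:, j]
    data.to_csv(directory / "data.csv", index=False, float_format="%.17g")
    meta = {
        "version": _VERSION,
        "family": bank.family,
        "lambda_lasso": bank.lambda_lasso,
        "lambda_ridge": bank.lambda_ridge,
        "penalize_intercept": bank.penalize_intercept,
        "d": emb.d,
        "r": emb.r,
        "squared_kernel": emb.squared_kernel,
        "seed": solution.seed,
        "loss": solution.loss,
        "optimizer_trace": [[int(a), float(b)] for a, b in solution.optimizer_trace],
        "feature_names": ds.feature_names,
        "target_names": ds.target_names,
        "x_mean": ds.x_mean.tolist(),
        "x_scale": ds.x_scale.tolist(),
        "y_mean": None if ds.y_mean is None else ds.y_mean.tolist(),
        "y_scale": None if ds.y_scale is None else ds.y_scale.tolist(),
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=1))
    return directory


def read_solution(directory) -> SlisemapSolution:
    """Load a solution directory; fails if the recomputed loss disagrees
    with the stored one or the version tag is unknown."""
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    if meta.get("version") != _VERSION:
        raise ValueError(f"unsupported solution version {meta.get('version')!r}")
    Z = pd.read_csv(directory / "Z.csv").to_numpy(dtype=float)
    B = pd.read_csv(directory / "B.csv").to_numpy(dtype=float)
    data = pd.read_csv(directory / "data.csv")
    feat = meta["feature_names"]
    X = data[feat].to_numpy(dtype=float)
    Y = data[[c for c in data.columns if c.startswith("target:")]].to_numpy(dtype=float)
    ds = Dataset(
        X=X, Y=Y, feature_names=feat,
        x_mean=np.asarray(meta["x_mean"]), x_scale=np.asarray(meta["x_scale"]),
        y_mean=None if meta["y_mean"] is None else np.asarray(meta["y_mean"]),
        y_scale=None if meta["y_scale"] is None else np.asarray(meta["y_scale"]),
        family=meta["family"], target_names=meta["target_names"],
    )
    solution = SlisemapSolution(
        dataset=ds,
        embedding=Embedding(Z, d=meta["d"], r=meta["r"],
                            squared_kernel=meta["squared_kernel"]),
        models=LocalModelBank(B, family=meta["family"],
                              lambda_lasso=meta["lambda_lasso"],
                              lambda_ridge=meta["lambda_ridge"],
                              penalize_intercept=meta["penalize_intercept"]),
        loss=float(meta["loss"]),
        seed=meta["seed"],
        optimizer_trace=[tuple(t) for t in meta["optimizer_trace"]],
    )
    recomputed = solution.recompute_loss()
    if abs(recomputed - solution.loss) > _LOSS_TOL * max(1.0, abs(solution.loss)):
        raise ValueError(
            f"stored loss {solution.loss} != recomputed {recomputed}; "
            "the solution directory is inconsistent or has been modified"
        )
    return solution
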