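"""Reading and writing area-level tables, plus survey-support helpers.

The on-disk format is one delimited text file with a header and one row
per domain:

    domain_id, y, nu, x0_<name>..., x1_<name>..., cov_<j>_<k>...

where the ``cov_j_k`` columns (1 <= j <= k <= q1) store the upper triangle
of the measurement-error covariance matrix row-major by j then k.
"""

from __future__ import annotations

import os
import tempfile

import numpy as np
import pandas as pd
import yaml

from .data import AreaData, DataError


class ParseError(ValueError):
    pass


def _cov_columns(q1: int):
    return [f"cov_{j}_{k}" for j in range(1, q1 + 1) for k in range(j, q1 + 1)]


def write_area_table(data: AreaData, path, sep: str = ",", x0_names=None,
                     x1_names=None) -> None:
    """Write a dataset as delimited text (atomic: write then rename)."""
    q0, q1 = data.q0, data.q1
    if x0_names is None:
        x0_names = [f"x0_{i + 1}" for i in range(q0)]
    if x1_names is None:
        x1_names = [f"x1_{i + 1}" for i in range(q1)]
    cols = {"domain_id": data.domain_id, "y": data.y.astype(int), "nu": data.nu}
    for i, name in enumerate(x0_names):
        cols[name] = data.X0[:, i]
    for i, name in enumerate(x1_names):
        cols[name] = data.X1[:, i]
    for name, (j, k) in zip(
        _cov_columns(q1),
        [(j, k) for j in range(q1) for k in range(j, q1)],
    ):
        cols[name] = data.Sigma[:, j, k]
    frame = pd.DataFrame(cols)
    atomic_write_text(path, frame.to_csv(index=False, sep=sep))


def read_area_table(path, sep: str = ",") -> AreaData:
    """Parse an area table; validation errors name the offending row/column."""
    try:
        frame = pd.read_csv(path, sep=sep)
    except Exception as exc:  # noqa: BLE001 - surface as a parse error
        raise ParseError(f"cannot read {path}: {exc}") from exc
    for col in ("domain_id", "y", "nu"):
        if col not in frame.columns:
            raise ParseError(f"missing required column '{col}'")
    x0_cols = [c for c in frame.columns if c.startswith("x0_")]
    x1_cols = [c for c in frame.columns if c.startswith("x1_")]
    cov_cols = [c for c in frame.columns if c.startswith("cov_")]
    q1 = len(x1_cols)
    expected = _cov_columns(q1)
    if sorted(cov_cols) != sorted(expected):
        raise ParseError(
            f"expected covariance columns {expected} for q1={q1}, "
            f"found {sorted(cov_cols)}"
        )
    D = len(frame)
    Sigma = np.zeros((D, q1, q1))
    for name in expected:
        _, j, k = name.split("_")
        j, k = int(j) - 1, int(k) - 1
        Sigma[:, j, k] = frame[name].to_numpy(dtype=float)
        Sigma[:, k, j] = Sigma[:, j, k]
    for d in range(D):
        if np.linalg.eigvalsh(Sigma[d])[0] < -1e-10:
            raise ParseError(
                f"row {d + 1} (domain_id={frame['domain_id'].iloc[d]}): "
                "covariance matrix is not positive semidefinite"
            )
    y = frame["y"].to_numpy()
    nu = frame["nu"].to_numpy(dtype=float)
    for d in range(D):
        if y[d] < 0 or y[d] != int(y[d]):
            raise ParseError(
                f"row {d + 1}, column 'y': must be a nonnegative integer"
            )
        if nu[d] <= 0:
            raise ParseError(f"row {d + 1}, column 'nu': must be positive")
    try:
        return AreaData(
            y=y.astype(int),
            nu=nu,
            X0=frame[x0_cols].to_numpy(dtype=float).reshape(D, len(x0_cols)),
            X1=frame[x1_cols].to_numpy(dtype=float).reshape(D, q1),
            Sigma=Sigma,
            domain_id=frame["domain_id"].astype(str).to_numpy(),
        )
    except DataError as exc:
        raise ParseError(str(exc)) from exc


def ht_covariance(var_j: float, var_k: float, var_diff: float) -> float:
    """Covariance of two direct estimators from their variances.

    Uses cov(x_j, x_k) = (var(x_j) + var(x_k) - var(x_j - x_k)) / 2, the
    polarization identity applied to design-based (Horvitz-Thompson)
    variance estimates.
    """
    if var_j < 0 or var_k < 0 or var_diff < 0:
        raise ValueError("variance inputs must be nonnegative")
    return 0.5 * (var_j + var_k - var_diff)


def scale_domain_size(N, n) -> np.ndarray:
    """Scale population sizes to the magnitude of the sample sizes.

    Returns N_d / delta with delta = sum(N) / sum(n), so the scaled values
    are exposure-like covariates that keep exponential-link fits stable.
    """
    N = np.asarray(N, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(N <= 0) or np.any(n <= 0):
        raise ValueError("population and sample sizes must be positive")
    delta = float(np.sum(N)) / float(np.sum(n))
    return N / delta


def atomic_write_text(path, text: str) -> None:
    """Write text to ``path`` atomically (temporary file + rename)."""
    path = os.fspath(path)
    d = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", text=True)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_manifest(path, payload: dict) -> None:
    """Write a reproducibility manifest (config, seeds, versions) as YAML."""
    from . import __version__

    payload = dict(payload)
    payload.setdefault("mepm_version", __version__)
    payload.setdefault("numpy_version", np.__version__)
    atomic_write_text(path, yaml.safe_dump(payload, sort_keys=True))
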