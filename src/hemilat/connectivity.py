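"""Fisher-z functional connectivity from parcellated time series.

The resting-state functional connectivity (rsFC) between two parcels is the
Pearson correlation of their time series, Fisher r-to-z transformed. The
whole-brain mean connectivity (mFC) — the average z over all unique parcel
pairs — is carried downstream as a nuisance covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "compute_fc",
    "mean_whole_brain_fc",
    "load_timeseries",
    "load_censor_mask",
    "write_matrix",
    "read_matrix",
]

#: correlations are clipped to +/-(1 - R_CLIP) before atanh so a perfectly
#: correlated pair yields a large finite z instead of infinity
R_CLIP = 1e-7


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric P x P Fisher-z connectivity matrix; diagonal is NaN.

    Self-connectivity is undefined, so the diagonal is stored as NaN and
    every consumer must (and does) skip it.
    """

    z: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError(f"z must be square, got shape {z.shape}")
        off = ~np.eye(z.shape[0], dtype=bool)
        if not np.allclose(z[off], z.T[off], atol=1e-10, equal_nan=True):
            raise ValueError("z must be symmetric off the diagonal")
        if not np.all(np.isfinite(z[off])):
            raise ValueError("off-diagonal z values must be finite")
        object.__setattr__(self, "z", z)

    @property
    def n_parcels(self) -> int:
        return self.z.shape[0]


def compute_fc(
    data: np.ndarray, censor_mask: np.ndarray | None = None
) -> ConnectivityMatrix:
    """Pearson-correlate parcel time series and Fisher-z transform.

    Parameters
    ----------
    data
        T x P matrix (timepoints by parcels).
    censor_mask
        Optional boolean vector of length T; True marks retained volumes.
        Censored volumes are dropped before the correlation.

    Raises
    ------
    ValueError
        If fewer than 3 volumes survive censoring or any retained column
        is constant (correlation undefined).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("time series must be a 2-D T x P matrix")
    if censor_mask is not None:
        censor_mask = np.asarray(censor_mask, dtype=bool)
        if censor_mask.shape != (data.shape[0],):
            raise ValueError(
                f"censor mask length {censor_mask.shape} does not match "
                f"T={data.shape[0]}"
            )
        data = data[censor_mask]
    t = data.shape[0]
    if t < 3:
        raise ValueError(f"need at least 3 volumes after censoring, got {t}")
    constant = np.flatnonzero(np.ptp(data, axis=0) == 0)
    if constant.size:
        raise ValueError(
            f"parcel {constant[0]} has a constant time series after censoring"
        )
    r = np.corrcoef(data, rowvar=False)
    r = np.clip(r, -1.0 + R_CLIP, 1.0 - R_CLIP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, np.nan)
    return ConnectivityMatrix(z)


def mean_whole_brain_fc(fc: ConnectivityMatrix) -> float:
    """Mean Fisher-z over all P(P-1)/2 unique off-diagonal pairs (mFC)."""
    iu = np.triu_indices(fc.n_parcels, k=1)
    return float(fc.z[iu].mean())


def load_timeseries(path: str | Path) -> np.ndarray:
    """Read a T x P delimited-text matrix, tolerating an optional header row."""
    path = Path(path)
    delim = "\t" if path.suffix in (".tsv", ".txt") else ","
    try:
        return np.loadtxt(path, delimiter=delim, ndmin=2)
    except ValueError:
        return np.loadtxt(path, delimiter=delim, skiprows=1, ndmin=2)


def load_censor_mask(path: str | Path) -> np.ndarray:
    """Read a one-column 0/1 censor file (1 = volume retained)."""
    vals = np.loadtxt(path, ndmin=1)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("censor file must contain only 0 and 1")
    return vals.astype(bool)


def write_matrix(fc: ConnectivityMatrix, path: str | Path) -> None:
    np.savetxt(path, fc.z, delimiter=",", fmt="%.10g")


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    return ConnectivityMatrix(np.loadtxt(path, delimiter=","))
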