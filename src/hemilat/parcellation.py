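"""Bilateral parcellation bookkeeping: hemispheres, homotopic pairs, networks.

A scheme describes a bilateral atlas with an even number of parcels P,
exactly P/2 per hemisphere, and a homotopic-partner mapping that is an
involution crossing hemispheres (every parcel has exactly one mirror
partner on the other side). Network labels (e.g. ``"FPN"``) group parcels
into resting-state networks; a homotopic pair belongs to a network only
when BOTH members carry the label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ParcelScheme",
    "SchemeError",
    "load_scheme",
    "write_scheme",
    "make_synthetic_scheme",
    "default_scheme_path",
]

_REQUIRED_COLUMNS = ("parcel_id", "label", "hemisphere", "partner_id", "network")


class SchemeError(ValueError):
    """Raised when a parcellation scheme violates a structural invariant."""


@dataclass(frozen=True)
class ParcelScheme:
    """Validated bilateral parcellation scheme.

    Parameters
    ----------
    table
        One row per parcel with columns ``parcel_id`` (0-based, contiguous),
        ``label``, ``hemisphere`` ("L"/"R"), ``partner_id`` and ``network``.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        _validate(self.table)

    @property
    def n_parcels(self) -> int:
        return len(self.table)

    @property
    def networks(self) -> list[str]:
        return sorted(self.table["network"].unique())

    @cached_property
    def _hemi_array(self) -> np.ndarray:
        return (
            self.table.sort_values("parcel_id")["hemisphere"].to_numpy().astype("U1")
        )

    @cached_property
    def _partner_array(self) -> np.ndarray:
        return self.table.sort_values("parcel_id")["partner_id"].to_numpy()

    @cached_property
    def _network_array(self) -> np.ndarray:
        return self.table.sort_values("parcel_id")["network"].to_numpy()

    def hemisphere_ids(self, hemisphere: str) -> np.ndarray:
        """Parcel ids in one hemisphere, ascending."""
        if hemisphere not in ("L", "R"):
            raise SchemeError(f"hemisphere must be 'L' or 'R', got {hemisphere!r}")
        return np.flatnonzero(self._hemi_array == hemisphere)

    @cached_property
    def _homotopic_pairs(self) -> tuple[tuple[int, int], ...]:
        partner = self._partner_array
        return tuple(
            (int(i), int(partner[i])) for i in self.hemisphere_ids("L")
        )

    def homotopic_pairs(self) -> list[tuple[int, int]]:
        """All homotopic pairs as ``(left_id, right_id)``, ascending left id.

        Every parcel appears in exactly one pair, so the result is a
        partition of the scheme into P/2 pairs.
        """
        return list(self._homotopic_pairs)

    def network_pairs(self, network: str) -> list[tuple[int, int]]:
        """Homotopic pairs whose members BOTH belong to ``network``."""
        nets = self._network_array
        if network not in nets:
            raise SchemeError(f"unknown network label {network!r}")
        return [
            (l, r)
            for l, r in self._homotopic_pairs
            if nets[l] == network and nets[r] == network
        ]

    def asymmetric_network_pairs(self) -> list[tuple[int, int]]:
        """Homotopic pairs whose members carry different network labels.

        These pairs are silently excluded by the both-members rule of
        :meth:`network_pairs`; listing them keeps the exclusion auditable.
        """
        nets = self._network_array
        return [(l, r) for l, r in self._homotopic_pairs if nets[l] != nets[r]]


def _validate(table: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemeError(f"scheme table missing columns: {missing}")
    p = len(table)
    if p == 0 or p % 2:
        raise SchemeError(f"parcel count must be positive and even, got {p}")
    ids = table["parcel_id"].to_numpy()
    if not np.array_equal(np.sort(ids), np.arange(p)):
        raise SchemeError("parcel_id must be the contiguous range 0..P-1")
    hemi = table.set_index("parcel_id")["hemisphere"]
    bad_hemi = hemi[~hemi.isin(["L", "R"])]
    if len(bad_hemi):
        raise SchemeError(
            f"hemisphere must be 'L' or 'R'; parcel {bad_hemi.index[0]} has "
            f"{bad_hemi.iloc[0]!r}"
        )
    n_left = int((hemi == "L").sum())
    if n_left != p // 2:
        raise SchemeError(
            f"expected {p // 2} parcels per hemisphere, found {n_left} left"
        )
    partner = table.set_index("parcel_id")["partner_id"]
    for i in partner.index:
        j = partner[i]
        if not (0 <= j < p):
            raise SchemeError(f"parcel {i}: partner_id {j} out of range")
        if j == i:
            raise SchemeError(f"parcel {i} is its own partner (self-partner)")
        if partner[j] != i:
            raise SchemeError(
                f"partner mapping is not an involution at parcel {i} "
                f"(partner[{i}]={j} but partner[{j}]={partner[j]})"
            )
        if hemi[i] == hemi[j]:
            raise SchemeError(
                f"parcel {i} and partner {j} are both in hemisphere {hemi[i]}"
            )


def load_scheme(path: str | Path, one_based: bool = False) -> ParcelScheme:
    """Load and validate a scheme from delimited text.

    The file is comma- or tab-delimited with a header carrying at least
    ``parcel_id``, ``label``, ``hemisphere`` and ``network``. If
    ``partner_id`` is absent, the default bilateral packing
    ``partner[i] = i + P/2`` for the first-half (left) block is assumed.
    Set ``one_based=True`` when the file indexes parcels from 1.
    """
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    table = pd.read_csv(path, sep=sep)
    if "parcel_id" not in table.columns:
        raise SchemeError("scheme file has no parcel_id column")
    table["parcel_id"] = table["parcel_id"].astype(int)
    if one_based:
        table["parcel_id"] -= 1
        if "partner_id" in table.columns:
            table["partner_id"] = table["partner_id"].astype(int) - 1
    if "partner_id" not in table.columns:
        p = len(table)
        table = table.sort_values("parcel_id").reset_index(drop=True)
        table["partner_id"] = (table["parcel_id"] + p // 2) % p
    table["partner_id"] = table["partner_id"].astype(int)
    table["hemisphere"] = table["hemisphere"].astype(str).str.strip()
    table["network"] = table["network"].astype(str).str.strip()
    return ParcelScheme(table[list(_REQUIRED_COLUMNS)].reset_index(drop=True))


def write_scheme(scheme: ParcelScheme, path: str | Path) -> None:
    """Write a scheme as CSV; ``load_scheme`` round-trips it exactly."""
    scheme.table.sort_values("parcel_id").to_csv(path, index=False)


def make_synthetic_scheme(
    n_parcels: int = 60,
    n_network_pairs: int = 10,
    network: str = "FPN",
    other_network: str = "OTHER",
) -> ParcelScheme:
    """Build a synthetic bilateral scheme with an embedded network subset.

    Left parcels occupy ids ``0..P/2-1``, right parcels ``P/2..P-1``, and
    ``partner[i] = i + P/2``. The first ``n_network_pairs`` homotopic pairs
    are labelled ``network`` on both sides; the rest get ``other_network``.
    """
    if n_parcels % 2:
        raise SchemeError("n_parcels must be even")
    half = n_parcels // 2
    if not 0 <= n_network_pairs <= half:
        raise SchemeError("n_network_pairs must be in [0, P/2]")
    rows = []
    for i in range(n_parcels):
        left = i < half
        pair_index = i if left else i - half
        net = network if pair_index < n_network_pairs else other_network
        rows.append(
            {
                "parcel_id": i,
                "label": f"{'L' if left else 'R'}_{pair_index:03d}",
                "hemisphere": "L" if left else "R",
                "partner_id": (i + half) % n_parcels,
                "network": net,
            }
        )
    return ParcelScheme(pd.DataFrame(rows))


def default_scheme_path() -> Path:
    """Path of the bundled synthetic 360-parcel scheme (180 per hemisphere).

    The file is generated by :func:`make_synthetic_scheme` with 24 FPN
    pairs; it mimics the shape of a bilateral multimodal atlas but makes
    no claim about any real atlas's network membership.
    """
    return Path(__file__).parent / "data" / "scheme360_synthetic.csv"
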