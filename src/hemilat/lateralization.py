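"""Homotopic lateralization indices from Fisher-z connectivity.

For a homotopic parcel pair (L, R) two edge families are summed:

* heterotopic (he): connectivity from each parcel to every parcel of the
  OPPOSITE hemisphere except its homotopic partner — P/2 - 1 edges per side;
* intrahemispheric (intra): connectivity from each parcel to every other
  parcel of its OWN hemisphere — P/2 - 1 edges per side.

Each family yields a laterality index

    LI = (L - R) / |L + R|

so LI_he and LI_intra are positive when the left member interacts more
strongly and negative when the right one does. Network-level indices are
unweighted means of the pair indices over homotopic pairs whose members
both belong to the network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hemilat.connectivity import ConnectivityMatrix
from hemilat.parcellation import ParcelScheme

__all__ = [
    "LateralityRecord",
    "NetworkLaterality",
    "heterotopic_sums",
    "intra_sums",
    "laterality_index",
    "pair_laterality",
    "network_laterality",
    "li_difference",
    "pair_table",
]

#: |L + R| below this is treated as a vanishing denominator: the index is
#: flagged undefined (NaN) rather than allowed to blow up
EPS_DENOMINATOR = 1e-12


@dataclass(frozen=True)
class LateralityRecord:
    """Per-pair sums and indices for one homotopic parcel pair."""

    left_id: int
    right_id: int
    he_left: float
    he_right: float
    intra_left: float
    intra_right: float
    li_he: float
    li_intra: float
    defined_he: bool
    defined_intra: bool


@dataclass(frozen=True)
class NetworkLaterality:
    """Network-averaged indices with exclusion accounting."""

    network: str
    li_he: float
    li_intra: float
    n_pairs_used_he: int
    n_pairs_used_intra: int
    n_pairs_excluded_he: int
    n_pairs_excluded_intra: int


def _check_pair(scheme: ParcelScheme, pair: tuple[int, int]) -> None:
    left, right = pair
    p = scheme.n_parcels
    if not (
        0 <= left < p
        and 0 <= right < p
        and scheme._hemi_array[left] == "L"
        and scheme._partner_array[left] == right
    ):
        raise ValueError(f"{pair} is not a (left, right) homotopic pair of the scheme")


def _pair_sums(
    z: np.ndarray, scheme: ParcelScheme, pairs: list[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized he/intra sums for a list of homotopic pairs.

    Row sums over a hemisphere block minus the excluded edge (partner for
    he, NaN self-edge handled by nansum for intra).
    """
    left_ids = scheme.hemisphere_ids("L")
    right_ids = scheme.hemisphere_ids("R")
    lefts = np.array([p[0] for p in pairs])
    rights = np.array([p[1] for p in pairs])
    he_l = z[np.ix_(lefts, right_ids)].sum(axis=1) - z[lefts, rights]
    he_r = z[np.ix_(rights, left_ids)].sum(axis=1) - z[rights, lefts]
    intra_l = np.nansum(z[np.ix_(lefts, left_ids)], axis=1)
    intra_r = np.nansum(z[np.ix_(rights, right_ids)], axis=1)
    return he_l, he_r, intra_l, intra_r


def heterotopic_sums(
    fc: ConnectivityMatrix, scheme: ParcelScheme, pair: tuple[int, int]
) -> tuple[float, float]:
    """Sums of heterotopic z for one homotopic pair.

    heL sums z from the left parcel to all right-hemisphere parcels except
    its partner; heR symmetrically from the right parcel to the left
    hemisphere. Each sum has P/2 - 1 terms.
    """
    _check_pair(scheme, pair)
    left, right = pair
    left_ids = scheme.hemisphere_ids("L")
    right_ids = scheme.hemisphere_ids("R")
    he_left = float(fc.z[left, right_ids[right_ids != right]].sum())
    he_right = float(fc.z[right, left_ids[left_ids != left]].sum())
    return he_left, he_right


def intra_sums(
    fc: ConnectivityMatrix, scheme: ParcelScheme, pair: tuple[int, int]
) -> tuple[float, float]:
    """Sums of within-hemisphere z for one homotopic pair (P/2 - 1 terms each)."""
    _check_pair(scheme, pair)
    left, right = pair
    left_ids = scheme.hemisphere_ids("L")
    right_ids = scheme.hemisphere_ids("R")
    intra_left = float(fc.z[left, left_ids[left_ids != left]].sum())
    intra_right = float(fc.z[right, right_ids[right_ids != right]].sum())
    return intra_left, intra_right


def laterality_index(numer_left: float, numer_right: float) -> tuple[float, bool]:
    """(L - R) / |L + R| with a vanishing-denominator guard.

    Returns ``(li, defined)``; when |L + R| < 1e-12 the index is undefined
    (NaN, defined=False) instead of raising — signed z sums can cancel.
    """
    if not (math.isfinite(numer_left) and math.isfinite(numer_right)):
        raise ValueError("sums must be finite")
    denom = abs(numer_left + numer_right)
    if denom < EPS_DENOMINATOR:
        return float("nan"), False
    return (numer_left - numer_right) / denom, True


def pair_laterality(
    fc: ConnectivityMatrix, scheme: ParcelScheme, pair: tuple[int, int]
) -> LateralityRecord:
    """Assemble he/intra sums and both indices for one homotopic pair."""
    he_l, he_r = heterotopic_sums(fc, scheme, pair)
    in_l, in_r = intra_sums(fc, scheme, pair)
    li_he, def_he = laterality_index(he_l, he_r)
    li_in, def_in = laterality_index(in_l, in_r)
    return LateralityRecord(
        left_id=pair[0],
        right_id=pair[1],
        he_left=he_l,
        he_right=he_r,
        intra_left=in_l,
        intra_right=in_r,
        li_he=li_he,
        li_intra=li_in,
        defined_he=def_he,
        defined_intra=def_in,
    )


def network_laterality(
    fc: ConnectivityMatrix, scheme: ParcelScheme, network: str
) -> NetworkLaterality:
    """Unweighted mean of pair indices over the network's homotopic pairs.

    Only pairs whose two members both carry the network label enter; pairs
    with an undefined index (vanishing denominator) are excluded from the
    corresponding mean and counted.
    """
    pairs = scheme.network_pairs(network)
    if not pairs:
        raise ValueError(f"network {network!r} has no both-member homotopic pairs")
    he_l, he_r, in_l, in_r = _pair_sums(fc.z, scheme, pairs)
    den_he = np.abs(he_l + he_r)
    den_in = np.abs(in_l + in_r)
    def_he = den_he >= EPS_DENOMINATOR
    def_in = den_in >= EPS_DENOMINATOR
    li_he = (he_l - he_r)[def_he] / den_he[def_he]
    li_in = (in_l - in_r)[def_in] / den_in[def_in]
    if li_he.size == 0 and li_in.size == 0:
        raise ValueError(f"network {network!r} has zero usable pairs")
    return NetworkLaterality(
        network=network,
        li_he=float(li_he.mean()) if li_he.size else float("nan"),
        li_intra=float(li_in.mean()) if li_in.size else float("nan"),
        n_pairs_used_he=int(def_he.sum()),
        n_pairs_used_intra=int(def_in.sum()),
        n_pairs_excluded_he=int(len(pairs) - def_he.sum()),
        n_pairs_excluded_intra=int(len(pairs) - def_in.sum()),
    )


def li_difference(
    post: NetworkLaterality, base: NetworkLaterality
) -> tuple[float, float]:
    """Within-subject longitudinal change, post minus baseline.

    Positive values mean a leftward shift of the index.
    """
    if post.network != base.network:
        raise ValueError(
            f"network mismatch: {post.network!r} vs {base.network!r}"
        )
    return post.li_he - base.li_he, post.li_intra - base.li_intra


def pair_table(fc: ConnectivityMatrix, scheme: ParcelScheme) -> pd.DataFrame:
    """Per-pair LI table over every homotopic pair of the scheme."""
    rows = [
        pair_laterality(fc, scheme, p).__dict__ for p in scheme.homotopic_pairs()
    ]
    return pd.DataFrame(rows)
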