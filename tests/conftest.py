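import numpy as np
import pandas as pd
import pytest

from hemilat.connectivity import ConnectivityMatrix
from hemilat.parcellation import ParcelScheme, make_synthetic_scheme


@pytest.fixture
def toy_scheme() -> ParcelScheme:
    """6 parcels, 3 homotopic pairs (0,3) (1,4) (2,5); first 2 pairs FPN."""
    return make_synthetic_scheme(6, 2)


@pytest.fixture
def mixed_network_scheme() -> ParcelScheme:
    """Pair (0,3) both FPN; pair (1,4) mixed FPN/OTHER; pair (2,5) OTHER."""
    table = pd.DataFrame(
        {
            "parcel_id": range(6),
            "label": [f"p{i}" for i in range(6)],
            "hemisphere": ["L", "L", "L", "R", "R", "R"],
            "partner_id": [3, 4, 5, 0, 1, 2],
            "network": ["FPN", "FPN", "OTHER", "FPN", "OTHER", "OTHER"],
        }
    )
    return ParcelScheme(table)


def constant_matrix(p: int, value: float) -> ConnectivityMatrix:
    z = np.full((p, p), value, dtype=float)
    np.fill_diagonal(z, np.nan)
    return ConnectivityMatrix(z)


def random_symmetric_matrix(p: int, rng: np.random.Generator) -> ConnectivityMatrix:
    z = rng.normal(0.2, 0.4, (p, p))
    z = (z + z.T) / 2
    np.fill_diagonal(z, np.nan)
    return ConnectivityMatrix(z)


def brute_force_pair(z: np.ndarray, scheme: ParcelScheme, pair):
    """Independent edge-list oracle: loop over every (i, j) entry once."""
    left, right = pair
    hemi = scheme.table.sort_values("parcel_id")["hemisphere"].tolist()
    he_l = he_r = in_l = in_r = 0.0
    for j in range(len(z)):
        # the homotopic edge (left, right) belongs to neither sum: he
        # excludes the partner by definition, intra stays within hemisphere
        if j not in (left, right):
            if hemi[j] == "R":
                he_l += z[left, j]
                in_r += z[right, j]
            else:
                he_r += z[right, j]
                in_l += z[left, j]
    return he_l, he_r, in_l, in_r


def swap_hemispheres(z: np.ndarray, scheme: ParcelScheme) -> np.ndarray:
    """Relabel hemispheres by permuting every parcel with its partner."""
    perm = scheme.table.sort_values("parcel_id")["partner_id"].to_numpy()
    return z[np.ix_(perm, perm)]
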