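"""Packaged per-breed tables for the three continental goat data sets.

The package ships one CSV per continent with the published per-breed
values: breed identity and sampling coordinates, sample size, observed and
expected heterozygosity, Fis, Fst against the Iranian Markhoz reference
breed, and the geodesic distance (km) from the sampling site to Ganj Dareh.
Fst and distance are absent (empty fields) for the three South African
commercial breeds, which lack a published Fst/distance entry, and Fst is
absent for the Markhoz reference itself.  The F_ROH column exists in the
schema but is unpopulated here (those coefficients come from a separate
runs-of-homozygosity study and are supplied by the user when available).

Files are integrity-checked against frozen SHA-256 digests on load.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from typing import Mapping, NamedTuple

import pandas as pd

from .io import BREED_COLUMNS, DIVERSITY_COLUMNS

__all__ = ["CONTINENTS", "FixtureTables", "FixtureIntegrityError", "load_fixture_tables"]

CONTINENTS = ("europe", "africa", "asia")

_SHA256 = {
    "breeds_europe.csv": "d41e81bd86f2c393326787f7a2f53dee040d35fbbc77282f1dc65f99f7f1b69d",
    "breeds_africa.csv": "6f0b3744f8127064b787c089757e22a6b27e9066d5966a15326cb88d79d71c69",
    "breeds_asia.csv": "d615f62062e3c703daf0483e002efc99c83cbd689f1a014dc64efc2bc787976d",
}


class FixtureIntegrityError(RuntimeError):
    """Packaged fixture content does not match its frozen checksum."""


class FixtureTables(NamedTuple):
    """Breed metadata and diversity statistics for one continent."""

    breeds: pd.DataFrame
    diversity: pd.DataFrame


def _read_checked(name: str) -> bytes:
    data = resources.files("capricline.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _SHA256[name]:
        raise FixtureIntegrityError(
            f"{name}: checksum mismatch (got {digest[:12]}..., "
            f"expected {_SHA256[name][:12]}...)"
        )
    return data


def load_fixture_tables() -> Mapping[str, FixtureTables]:
    """Load the packaged continental tables.

    Returns a mapping ``continent -> (breeds, diversity)`` where ``breeds``
    carries identity/coordinates/sample size and ``diversity`` the per-breed
    statistics plus the distance-to-origin column.  Row counts: 40 European,
    43 African, 22 Asian breeds.
    """
    import io as _io

    out: dict[str, FixtureTables] = {}
    for continent in CONTINENTS:
        raw = _read_checked(f"breeds_{continent}.csv")
        df = pd.read_csv(_io.BytesIO(raw))
        df["breed_id"] = df["breed_id"].astype(str)
        breeds = df[list(BREED_COLUMNS)].copy()
        diversity = df[list(DIVERSITY_COLUMNS)].copy()
        out[continent] = FixtureTables(breeds, diversity)
    return out
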