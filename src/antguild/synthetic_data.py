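"""Packaged fixtures and synthetic input generators.

Everything the pipeline needs ships inside the package as small plain-text
fixtures: per-species seasonal foraging curves and a 17-knot resource
curve (documented synthetic approximations of the published seasonal
figures), a baseline monthly temperature series, and Gaussian stand-ins
for the per-species thermal performance curves.  A random-phenology
generator provides property-test inputs with the same statistical
structure (annually periodic, non-negative, max-normalized).
"""

from __future__ import annotations

import hashlib
from importlib import resources

import numpy as np
import yaml

from .patch_dynamics import SpeciesTraits
from .phenology import (
    DAYS_PER_YEAR,
    PhenologyCurve,
    TemperatureSeries,
    ThermalResponse,
    normalize,
)

__all__ = [
    "SPECIES",
    "SPECIES_LABELS",
    "load_fixture_phenologies",
    "load_temperature_series",
    "load_thermal_responses",
    "default_traits",
    "generate_random_phenology",
    "fixture_sha256",
]

#: Canonical species keys, ordered from most subordinate to most dominant.
SPECIES = ("n_faisonensis", "a_rudis", "p_imparis")
SPECIES_LABELS = {
    "n_faisonensis": "Nylanderia faisonensis",
    "a_rudis": "Aphaenogaster rudis",
    "p_imparis": "Prenolepis imparis",
}

_FIXTURES = resources.files(__package__) / "fixtures"


def _read_table(name: str) -> np.ndarray:
    path = _FIXTURES / name
    try:
        text = path.read_text()
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"missing packaged fixture file {name!r}") from exc
    rows = [
        [float(tok) for tok in line.split()]
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not rows:
        raise ValueError(f"fixture file {name!r} contains no data rows")
    return np.asarray(rows, dtype=float)


def fixture_sha256(name: str) -> str:
    """Hash of a packaged fixture file, for reproducibility manifests."""
    return hashlib.sha256((_FIXTURES / name).read_bytes()).hexdigest()


def load_fixture_phenologies() -> dict[str, PhenologyCurve]:
    """Foraging curves for the three species plus the resource curve.

    Returns a dict with one normalized curve per species key plus
    ``"resource"`` (the 17-knot food-availability curve).
    """
    curves: dict[str, PhenologyCurve] = {}
    for key in SPECIES:
        tab = _read_table(f"foraging_{key}.tsv")
        curves[key] = normalize(PhenologyCurve(tab[:, 0], tab[:, 1]))
    tab = _read_table("resource_sigma.tsv")
    curves["resource"] = normalize(PhenologyCurve(tab[:, 0], tab[:, 1]))
    return curves


def load_temperature_series() -> TemperatureSeries:
    tab = _read_table("temperature_monthly.tsv")
    if tab.shape[0] != 12:
        raise ValueError("temperature fixture must have 12 monthly rows")
    return TemperatureSeries(tab[:, 1])


def load_thermal_responses() -> dict[str, ThermalResponse]:
    path = _FIXTURES / "thermal_response.yaml"
    try:
        spec = yaml.safe_load(path.read_text())
    except FileNotFoundError as exc:
        raise FileNotFoundError("missing packaged fixture file 'thermal_response.yaml'") from exc
    out = {}
    for key in SPECIES:
        if key not in spec:
            raise ValueError(f"thermal_response.yaml lacks an entry for {key!r}")
        out[key] = ThermalResponse(float(spec[key]["t_opt"]), float(spec[key]["width"]), name=key)
    return out


# Trait table for the three-species guild, subordinate to dominant.
# Discovery and clearance rates are relative to the N. faisonensis standard;
# the P. imparis discovery rate is only bounded (< 2.2) by the source data,
# so a configurable default of 1.0 is used, reflecting that this species
# competes through dominance and fast clearance rather than discovery.
# Foragers per colony follow observed average colony sizes (the midpoint of
# 125-150 for N. faisonensis).
_TRAIT_TABLE = {
    "n_faisonensis": dict(rank=1, r=1.0, c=1.0, w=0.1, a=137.5),
    "a_rudis": dict(rank=2, r=2.2, c=6.0, w=1.3, a=300.0),
    "p_imparis": dict(rank=3, r=1.0, c=17.0, w=0.7, a=1200.0),
}


def default_traits(r_p_imparis: float = 1.0) -> list[SpeciesTraits]:
    """The three-species trait set with packaged foraging phenologies."""
    curves = load_fixture_phenologies()
    traits = []
    for key in SPECIES:
        row = dict(_TRAIT_TABLE[key])
        if key == "p_imparis":
            row["r"] = r_p_imparis
        traits.append(
            SpeciesTraits(
                name=key,
                dominance_rank=row["rank"],
                r=row["r"],
                c=row["c"],
                w=row["w"],
                a=row["a"],
                foraging=curves[key],
            )
        )
    return traits


def generate_random_phenology(
    shape: str,
    peak_days,
    widths,
    rng: np.random.Generator,
    n_knots: int = 24,
) -> PhenologyCurve:
    """Random periodic activity curve for property tests.

    Builds a sum of periodic Gaussian bumps ("unimodal": one peak,
    "bimodal": two) with jittered amplitudes, samples it on an evenly
    spaced knot grid and max-normalizes.
    """
    peak_days = np.atleast_1d(np.asarray(peak_days, dtype=float))
    widths = np.atleast_1d(np.asarray(widths, dtype=float))
    if np.any(widths <= 0):
        raise ValueError("widths must be positive")
    n_peaks = {"unimodal": 1, "bimodal": 2}.get(shape)
    if n_peaks is None:
        raise ValueError(f"unknown shape {shape!r}")
    if peak_days.size != n_peaks:
        raise ValueError(f"{shape} curve needs {n_peaks} peak day(s)")
    widths = np.broadcast_to(widths, (n_peaks,))
    days = np.linspace(0.0, DAYS_PER_YEAR, n_knots, endpoint=False)
    values = np.zeros(n_knots)
    for mu, sd in zip(peak_days, widths):
        amp = rng.uniform(0.5, 1.0)
        # periodic distance to the peak
        d = np.abs(days - mu)
        d = np.minimum(d, DAYS_PER_YEAR - d)
        values += amp * np.exp(-0.5 * (d / sd) ** 2)
    return normalize(PhenologyCurve(days, values))
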