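"""Reduced ion mobility, RIP-relative drift times and peak annotation.

In drift-tube ion mobility spectrometry an ion's drift time ``td`` through a
tube of length ``L`` under field ``E = U/L`` defines its mobility
``K = L / (td * E)``.  Normalising to standard temperature and pressure gives
the reduced mobility

    K0 = K * (273 / T) * (P / 760)    [cm^2/Vs]

a transferable descriptor that can be compared across instruments.  Because
``K0`` is inversely proportional to drift time, a single calibrant ion with
known ``(dt_rel, K0)`` converts any RIP-relative drift time to ``K0`` without
knowing the tube geometry.

This module houses the packaged reference library of common hop terpenes and
terpene alcohols (monomer and proton-bound cluster-ion drift times with their
reduced mobilities) and utilities to detect and annotate peaks in a
RIP-normalised spectrum.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage


# --------------------------------------------------------------------------
# drift-tube physics

@dataclass(frozen=True)
class DriftTubeSpec:
    """Geometry and state of the IMS drift tube.

    Defaults describe a 9.8 cm tube at 5 kV operated at 90 degC; pressure
    defaults to 760 Torr so the P/760 correction is unity.
    """

    length_cm: float = 9.8
    voltage_v: float = 5000.0
    temperature_k: float = 363.15
    pressure_torr: float = 760.0

    def __post_init__(self) -> None:
        for name in ("length_cm", "voltage_v", "temperature_k", "pressure_torr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def field_v_per_cm(self) -> float:
        return self.voltage_v / self.length_cm


def reduced_mobility(td_s: float, tube: DriftTubeSpec | None = None) -> float:
    """Reduced mobility K0 (cm^2/Vs) from an absolute drift time in seconds.

    K = L / (td * E) with E = U/L, i.e. K = L^2 / (td * U), then
    K0 = K * (273/T) * (P/760).  The 273 constant is used verbatim (the
    conventional reduced-mobility normalisation), not 273.15.
    """
    tube = tube or DriftTubeSpec()
    if td_s <= 0:
        raise ValueError("drift time must be strictly positive")
    k = tube.length_cm**2 / (td_s * tube.voltage_v)
    return k * (273.0 / tube.temperature_k) * (tube.pressure_torr / 760.0)


def k0_from_anchor(
    dt_rel: float, anchor: tuple[float, float] = (1.258, 1.630)
) -> float:
    """K0 of an ion from its RIP-relative drift time and a calibrant anchor.

    Since K0 is inversely proportional to drift time (and the RIP drift time
    cancels in the ratio), ``K0 = k0_a * dt_rel_a / dt_rel``.  The default
    anchor is the shared monoterpene monomer ion at dt_rel 1.258 with
    K0 = 1.630 cm^2/Vs.
    """
    dt_rel_a, k0_a = anchor
    if dt_rel <= 0 or dt_rel_a <= 0 or k0_a <= 0:
        raise ValueError("drift times and mobilities must be strictly positive")
    return k0_a * dt_rel_a / dt_rel


# --------------------------------------------------------------------------
# reference library

@dataclass
class ReferenceEntry:
    """Library record for one compound.

    ``dt_rel`` holds the RIP-relative drift times of all observed ion species
    (monomer first, then cluster ions), ``k0`` the aligned reduced mobilities.
    ``match_quality`` is the informational EI-MS spectral-match score (0-100)
    reported by the instrument software; it is metadata only.
    """

    name: str
    molecular_mass: float
    rt_ms: float
    rt_ims: float
    dt_rel: list[float] = field(default_factory=list)
    k0: list[float] = field(default_factory=list)
    match_quality: float | None = None

    def __post_init__(self) -> None:
        if len(self.dt_rel) != len(self.k0):
            raise ValueError("dt_rel and k0 must be aligned")
        if any(d <= 1.0 for d in self.dt_rel):
            raise ValueError("product ions drift slower than the RIP (dt_rel > 1)")
        if list(self.dt_rel) != sorted(self.dt_rel):
            raise ValueError("dt_rel must be sorted ascending")


#: Identified terpenes / terpene alcohols of hop with monomer and cluster-ion
#: RIP-relative drift times and reduced mobilities (cm^2/Vs).
DEFAULT_LIBRARY: list[ReferenceEntry] = [
    ReferenceEntry("alpha-pinene", 136.23, 5.47, 5.52,
                   [1.258, 1.745, 1.767, 1.818], [1.630, 1.175, 1.160, 1.128], 90),
    ReferenceEntry("beta-pinene", 136.23, 6.11, 6.17,
                   [1.258, 1.735, 1.808], [1.630, 1.182, 1.134], 93),
    ReferenceEntry("beta-myrcene", 136.23, 6.23, 6.30,
                   [1.258, 1.769, 1.795], [1.630, 1.159, 1.142], 91),
    ReferenceEntry("limonene", 136.23, 6.82, 6.88,
                   [1.258, 1.736, 1.795], [1.630, 1.181, 1.142], 38),
    ReferenceEntry("linalool", 154.25, 7.78, 7.87,
                   [1.258, 1.736, 1.787], [1.630, 1.181, 1.147], 46),
    ReferenceEntry("beta-caryophyllene", 204.36, 12.11, 12.32,
                   [1.494, 1.586], [1.372, 1.293], 96),
    ReferenceEntry("alpha-humulene", 204.36, 12.56, 12.82,
                   [1.552], [1.321], 90),
]

#: Calibration anchor: the monoterpene monomer ion (dt_rel, K0).
MONOTERPENE_MONOMER_ANCHOR: tuple[float, float] = (1.258, 1.630)


def save_library(entries: list[ReferenceEntry], path) -> None:
    """Write a reference library to CSV (drift-time lists semicolon-joined)."""
    rows = [
        {
            "name": e.name,
            "mass": e.molecular_mass,
            "rt_ms": e.rt_ms,
            "rt_ims": e.rt_ims,
            "dt_rel": ";".join(f"{d:g}" for d in e.dt_rel),
            "k0": ";".join(f"{k:g}" for k in e.k0),
            "match_quality": e.match_quality,
        }
        for e in entries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_library(path) -> list[ReferenceEntry]:
    """Read a reference library from the CSV dialect written by save_library."""
    df = pd.read_csv(path)
    entries = []
    for _, r in df.iterrows():
        entries.append(
            ReferenceEntry(
                name=str(r["name"]),
                molecular_mass=float(r["mass"]),
                rt_ms=float(r["rt_ms"]),
                rt_ims=float(r["rt_ims"]),
                dt_rel=[float(x) for x in str(r["dt_rel"]).split(";")],
                k0=[float(x) for x in str(r["k0"]).split(";")],
                match_quality=None if pd.isna(r.get("match_quality")) else float(r["match_quality"]),
            )
        )
    return entries


def library_to_frame(entries: list[ReferenceEntry] | None = None) -> pd.DataFrame:
    """Reference library as a tidy DataFrame, one row per ion species."""
    entries = entries if entries is not None else DEFAULT_LIBRARY
    rows = []
    for e in entries:
        for i, (d, k) in enumerate(zip(e.dt_rel, e.k0)):
            rows.append(
                {"name": e.name, "mass": e.molecular_mass, "rt_ms": e.rt_ms,
                 "rt_ims": e.rt_ims, "species": "monomer" if i == 0 else f"cluster{i}",
                 "dt_rel": d, "k0": k}
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# peak detection & annotation

@dataclass(frozen=True)
class Peak:
    rt: float
    dt_rel: float
    intensity: float


@dataclass(frozen=True)
class Annotation:
    peak: Peak
    name: str  # compound name or "unknown"
    species_dt_rel: float | None = None
    distance: float | None = None  # combined normalised distance


def detect_peaks(cube, min_intensity: float, neighborhood: int = 3) -> list[Peak]:
    """Local maxima of a (RT x DT) intensity matrix above a threshold.

    A cell is a peak if it equals the maximum of its square neighborhood of
    half-width ``neighborhood`` grid steps and exceeds ``min_intensity``.
    Returned sorted by RT, then drift time.
    """
    x = np.asarray(cube.intensities)
    size = 2 * int(neighborhood) + 1
    local_max = ndimage.maximum_filter(x, size=size, mode="nearest")
    mask = (x == local_max) & (x > min_intensity)
    peaks = [
        Peak(float(cube.rt_axis[i]), float(cube.dt_axis[j]), float(x[i, j]))
        for i, j in zip(*np.nonzero(mask))
    ]
    peaks.sort(key=lambda p: (p.rt, p.dt_rel))
    return peaks


def annotate(
    peaks: list[Peak],
    library: list[ReferenceEntry] | None = None,
    rt_tol: float = 0.1,
    dt_tol: float = 0.01,
) -> list[Annotation]:
    """Assign peaks to library entries by RT and RIP-relative drift time.

    A peak matches an entry iff |rt - rt_ims| <= rt_tol and some ion species
    satisfies |dt_rel - entry dt_rel| <= dt_tol.  Ties are broken by the
    smallest combined normalised distance |drt|/rt_tol + |ddt|/dt_tol.
    Unmatched peaks are labelled "unknown".  Deterministic and invariant to
    library ordering.
    """
    if rt_tol <= 0 or dt_tol <= 0:
        raise ValueError("tolerances must be strictly positive")
    library = library if library is not None else DEFAULT_LIBRARY
    out = []
    for p in peaks:
        best: tuple[float, str, str, float] | None = None  # (dist, name, _, dt)
        for e in library:
            drt = abs(p.rt - e.rt_ims)
            if drt > rt_tol:
                continue
            for d in e.dt_rel:
                ddt = abs(p.dt_rel - d)
                if ddt > dt_tol:
                    continue
                dist = drt / rt_tol + ddt / dt_tol
                cand = (dist, e.name, "", d)
                if best is None or cand < best:
                    best = cand
        if best is None:
            out.append(Annotation(p, "unknown"))
        else:
            out.append(Annotation(p, best[1], best[3], best[0]))
    return out


def implied_rip_mobility(entries: list[ReferenceEntry] | None = None) -> float:
    """Mean of k0 * dt_rel over all library species: the implied RIP K0."""
    df = library_to_frame(entries)
    return float((df["k0"] * df["dt_rel"]).mean())
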