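"""Synthetic paired HS-GC-IMS / HS-GC-MS data with hop-like structure.

No public raw data exist for the hop volatilomics study this package models,
so every downstream stage is exercised on simulated data cubes that carry the
statistical structure the analysis assumes:

* a reactant ion peak (RIP) in every IMS drift spectrum, depleted by exactly
  the summed product-ion charge (charge conservation, capped at 95 %
  depletion so the RIP stays abundant);
* monomer and proton-bound cluster ("dimer") ions per compound, the dimer
  fraction following the saturating law c / (c + threshold) so the
  dimer/monomer ratio grows with concentration;
* monoterpene vs sesquiterpene drift-time zones and EI fragment patterns
  (m/z 136/121/93/69 vs 204/121/93/69), with extreme myrcene dominance;
* an early-eluting RT marker peak present in every run (the retention-time
  anchor used for alignment);
* retention-time and drift-time jitter between runs, with the RT jitter of
  the IMS and MS cube of one injection identical (both detectors see the
  same column);
* a composition <-> alpha-acid correlation: high-alpha samples are richer in
  alpha-/beta-pinene, myrcene, limonene and beta-caryophyllene and poorer in
  linalool and alpha-humulene, so a regression of alpha-acid content on the
  spectral fingerprint is recoverable.

One root seed drives everything; per-run substreams are derived by counter,
so adding samples never perturbs earlier ones and equal configurations give
bit-identical cubes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chemometrics import assign_alpha_group
from .preprocess import IMSCube, MSCube


class ConfigurationError(ValueError):
    """A simulation request is inconsistent with the configured grids."""


ALPHA_LO = 1.0
ALPHA_HI = 18.1
#: fractional swing of a correlated compound's mean over the alpha range
ALPHA_EFFECT = 0.7


# --------------------------------------------------------------------------
# compound library

@dataclass(frozen=True)
class CompoundSpec:
    """Simulation blueprint for one volatile compound.

    ``dt_rel_species`` lists the RIP-relative drift times of its ion species
    (monomer first, cluster ions after); ``fragment_pattern`` maps unit m/z
    channels to relative abundance with the base peak at 1.0;
    ``dimer_threshold`` is the concentration at which half the ion charge
    sits in cluster ions; ``alpha_sign`` encodes the direction of the
    compound's association with alpha-acid content (+1, -1 or 0);
    ``base_mean`` is the compound's concentration scale at mid-range alpha
    (arbitrary units).
    """

    name: str
    molecular_mass: float
    rt_true: float
    dt_rel_species: tuple[float, ...]
    fragment_pattern: dict[int, float]
    dimer_threshold: float
    class_tag: str  # monoterpene | sesquiterpene | terpene-alcohol | ketone | marker
    base_mean: float = 1.0
    alpha_sign: int = 0
    rt_ms_true: float | None = None

    def __post_init__(self) -> None:
        vals = list(self.fragment_pattern.values())
        if not vals or any(v < 0 or v > 1 for v in vals):
            raise ValueError("fragment abundances must lie in [0, 1]")
        if sum(1 for v in vals if v == 1.0) != 1:
            raise ValueError("exactly one fragment channel must be the base peak (1.0)")
        if any(d <= 1.0 for d in self.dt_rel_species):
            raise ValueError("product ions drift slower than the RIP (dt_rel > 1)")

    @property
    def rt_ms(self) -> float:
        return self.rt_ms_true if self.rt_ms_true is not None else self.rt_true


def _terp(mz: dict[int, float]) -> dict[int, float]:
    return dict(mz)


#: Default compound library: the seven identified terpenes / terpenoids with
#: their measured retention times and RIP-relative drift times, three methyl
#: ketones, and the early-eluting RT marker.  EI fragment patterns are
#: stylised (base peak plus characteristic fragments within the m/z 50-550
#: scan range), not measured spectra.
DEFAULT_COMPOUNDS: list[CompoundSpec] = [
    CompoundSpec("alpha-pinene", 136.23, 5.52, (1.258, 1.745, 1.767, 1.818),
                 _terp({93: 1.0, 92: 0.55, 121: 0.30, 136: 0.25, 77: 0.30, 69: 0.20}),
                 dimer_threshold=0.8, class_tag="monoterpene",
                 base_mean=0.8, alpha_sign=+1, rt_ms_true=5.47),
    CompoundSpec("beta-pinene", 136.23, 6.17, (1.258, 1.735, 1.808),
                 _terp({93: 1.0, 69: 0.35, 121: 0.22, 136: 0.15, 79: 0.25}),
                 dimer_threshold=0.8, class_tag="monoterpene",
                 base_mean=0.8, alpha_sign=+1, rt_ms_true=6.11),
    CompoundSpec("beta-myrcene", 136.23, 6.30, (1.258, 1.769, 1.795),
                 _terp({93: 1.0, 69: 0.80, 121: 0.15, 136: 0.10, 53: 0.25}),
                 dimer_threshold=20.0, class_tag="monoterpene",
                 base_mean=50.0, alpha_sign=+1, rt_ms_true=6.23),
    CompoundSpec("limonene", 136.23, 6.88, (1.258, 1.736, 1.795),
                 _terp({68: 1.0, 93: 0.70, 67: 0.55, 121: 0.25, 136: 0.30}),
                 dimer_threshold=1.5, class_tag="monoterpene",
                 base_mean=1.5, alpha_sign=+1, rt_ms_true=6.82),
    CompoundSpec("linalool", 154.25, 7.87, (1.258, 1.736, 1.787),
                 _terp({71: 1.0, 93: 0.80, 55: 0.45, 121: 0.30, 136: 0.15}),
                 dimer_threshold=1.2, class_tag="terpene-alcohol",
                 base_mean=1.2, alpha_sign=-1, rt_ms_true=7.78),
    CompoundSpec("beta-caryophyllene", 204.36, 12.32, (1.494, 1.586),
                 _terp({93: 1.0, 133: 0.60, 69: 0.55, 121: 0.40, 204: 0.20}),
                 dimer_threshold=2.0, class_tag="sesquiterpene",
                 base_mean=2.0, alpha_sign=+1, rt_ms_true=12.11),
    CompoundSpec("alpha-humulene", 204.36, 12.82, (1.552, 1.70),
                 _terp({93: 1.0, 80: 0.50, 121: 0.45, 69: 0.40, 204: 0.25}),
                 dimer_threshold=1.5, class_tag="sesquiterpene",
                 base_mean=1.5, alpha_sign=-1, rt_ms_true=12.56),
    CompoundSpec("2-butanone", 72.11, 1.80, (1.10, 1.22),
                 _terp({57: 1.0, 72: 0.35}),
                 dimer_threshold=0.6, class_tag="ketone", base_mean=0.6),
    CompoundSpec("2-hexanone", 100.16, 3.50, (1.18, 1.38),
                 _terp({58: 1.0, 85: 0.40, 100: 0.25}),
                 dimer_threshold=0.6, class_tag="ketone", base_mean=0.6),
    CompoundSpec("2-nonanone", 142.24, 8.90, (1.30, 1.55),
                 _terp({58: 1.0, 71: 0.50, 142: 0.20}),
                 dimer_threshold=0.6, class_tag="ketone", base_mean=0.6),
    # early-eluting RT anchor, present with fixed intensity in every run;
    # its single EI channel sits at the low edge of the scan range
    CompoundSpec("rt-marker", 44.01, 0.50, (1.12,),
                 _terp({50: 1.0}),
                 dimer_threshold=np.inf, class_tag="marker", base_mean=1.0),
]

MARKER_RT = 0.50


# --------------------------------------------------------------------------
# sample metadata

@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    cultivar: str
    year: int
    alpha_acid: float  # % w/w
    group: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", assign_alpha_group(self.alpha_acid))


_CULTIVAR_POOL = [
    "Citra", "Lubelski", "Strisselspalter", "Vic Secret", "Eldorado",
    "Hallertau", "Saaz", "Cascade", "Magnum", "Tettnang", "Perle", "Amarillo",
]


def make_sample_table(
    n_samples: int,
    alpha_range: tuple[float, float] = (ALPHA_LO, ALPHA_HI),
    n_cultivars: int = 8,
    seed: int = 0,
) -> list[SampleMeta]:
    """Sample metadata spanning the requested alpha-acid range.

    Alpha-acid values are an even sweep over the range with small jitter, so
    the low/middle/high groups are all populated whenever the range crosses
    the group thresholds; cultivars and harvest years (2015-2018) are drawn
    at random.  Deterministic under ``seed``.
    """
    lo, hi = alpha_range
    if n_samples < 2:
        raise ValueError("need at least two samples")
    if not (ALPHA_LO <= lo < hi <= ALPHA_HI):
        raise ValueError(f"alpha range must satisfy {ALPHA_LO} <= lo < hi <= {ALPHA_HI}")
    rng = np.random.default_rng(seed)
    alpha = np.linspace(lo, hi, n_samples)
    alpha = np.clip(alpha + rng.uniform(-0.2, 0.2, n_samples), lo, hi)
    cultivars = [_CULTIVAR_POOL[i % len(_CULTIVAR_POOL)] for i in range(n_cultivars)]
    order = rng.permutation(n_samples)
    metas = []
    for pos, idx in enumerate(order):
        metas.append(SampleMeta(
            sample_id=f"S{pos:03d}",
            cultivar=cultivars[int(rng.integers(len(cultivars)))],
            year=int(rng.integers(2015, 2019)),
            alpha_acid=float(round(alpha[idx], 2)),
        ))
    return metas


def metadata_frame(samples: list[SampleMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample_id": s.sample_id, "cultivar": s.cultivar, "year": s.year,
          "alpha_acid": s.alpha_acid, "group": s.group} for s in samples]
    )


# --------------------------------------------------------------------------
# concentration model

def expected_concentration(alpha_acid: float, spec: CompoundSpec) -> float:
    """Noise-free mean concentration of a compound at a given alpha-acid level.

    A strictly monotone affine function of alpha-acid: positive-sign
    compounds rise from (1 - ALPHA_EFFECT) to (1 + ALPHA_EFFECT) times their
    base mean over the alpha range, negative-sign compounds fall, ketones and
    the marker are flat.
    """
    rel = (alpha_acid - ALPHA_LO) / (ALPHA_HI - ALPHA_LO)
    return spec.base_mean * (1.0 + spec.alpha_sign * ALPHA_EFFECT * (2.0 * rel - 1.0))


def _effect_rng(seed: int, tag: str, compound: str) -> np.random.Generator:
    return np.random.default_rng(
        [seed & 0x7FFFFFFF, zlib.crc32(tag.encode()), zlib.crc32(compound.encode())]
    )


def concentration_model(
    meta: SampleMeta,
    library: list[CompoundSpec] | None = None,
    seed: int = 0,
    noise_sd: float = 0.06,
    cultivar_sd: float = 0.04,
    year_sd: float = 0.02,
) -> dict[str, float]:
    """Per-compound concentrations (arbitrary units) for one sample.

    The expectation is the affine alpha-acid trend of
    :func:`expected_concentration`; on top sit multiplicative lognormal
    cultivar and harvest-year random effects (shared by all samples of the
    same cultivar/year under one seed) and per-sample lognormal noise.  All
    multiplicative terms carry the -sigma^2/2 correction, so the expectation
    over seeds equals the configured mean exactly.  The RT marker is excluded
    (its intensity is fixed instrument-side).
    """
    library = library if library is not None else DEFAULT_COMPOUNDS
    if not library:
        raise ValueError("compound library is empty")
    rng = np.random.default_rng(
        [seed & 0x7FFFFFFF, zlib.crc32(meta.sample_id.encode()), 3]
    )
    out: dict[str, float] = {}
    for spec in library:
        if spec.class_tag == "marker":
            continue
        mean = expected_concentration(meta.alpha_acid, spec)
        c = mean
        if cultivar_sd > 0:
            g = _effect_rng(seed, f"cultivar:{meta.cultivar}", spec.name)
            c *= np.exp(g.normal(0.0, cultivar_sd) - cultivar_sd**2 / 2)
        if year_sd > 0:
            g = _effect_rng(seed, f"year:{meta.year}", spec.name)
            c *= np.exp(g.normal(0.0, year_sd) - year_sd**2 / 2)
        if noise_sd > 0:
            c *= np.exp(rng.normal(0.0, noise_sd) - noise_sd**2 / 2)
        out[spec.name] = float(c)
    return out


# --------------------------------------------------------------------------
# simulation configuration

@dataclass(frozen=True)
class SimConfig:
    """Grids, noise levels and the root seed of one simulated study.

    Desk-scale defaults: 800 RT points (0-16 min, 0.02 min step) x 256
    RIP-relative drift-time points (0.9-2.1) for IMS and 501 unit m/z
    channels (50-550) for EI-MS, duplicate injections per sample.
    """

    n_samples: int = 65
    n_replicates: int = 2
    rt_start: float = 0.0
    rt_stop: float = 16.0
    rt_step: float = 0.02
    dt_rel_min: float = 0.9
    dt_rel_max: float = 2.1
    n_dt: int = 256
    rip_dt_ms: float = 7.5  # raw RIP drift time; sets the raw DT axis scale
    mz_min: int = 50
    mz_max: int = 550
    total_charge: float = 1000.0
    intensity_gain: float = 6.0
    ms_gain: float = 1.0
    marker_amplitude: float = 80.0
    rt_sigma: float = 0.06  # min, chromatographic peak width
    dt_sigma: float = 1.5  # grid steps, drift peak width
    noise_sd_additive: float = 0.1
    noise_sd_multiplicative: float = 0.01
    rt_jitter_sd: float = 0.03  # min
    dt_jitter_sd: float = 0.8  # grid steps at the RIP (multiplicative drift scaling)
    max_depletion: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rt_step <= 0 or self.dt_rel_min >= self.dt_rel_max or self.n_dt < 2:
            raise ValueError("grids must be strictly increasing")
        if self.rt_jitter_sd < 0 or self.dt_jitter_sd < 0:
            raise ValueError("jitter SDs must be non-negative")

    @property
    def rt_axis(self) -> np.ndarray:
        return np.arange(self.rt_start, self.rt_stop, self.rt_step)

    @property
    def dt_rel_grid(self) -> np.ndarray:
        return np.linspace(self.dt_rel_min, self.dt_rel_max, self.n_dt)

    @property
    def dt_axis_raw(self) -> np.ndarray:
        """Raw drift-time axis (ms); the RIP sits at dt_rel 1.0."""
        return self.dt_rel_grid * self.rip_dt_ms

    @property
    def rip_position(self) -> int:
        """Nominal RIP index: the grid point closest to dt_rel 1.0."""
        return int(np.argmin(np.abs(self.dt_rel_grid - 1.0)))

    @property
    def mz_axis(self) -> np.ndarray:
        return np.arange(self.mz_min, self.mz_max + 1, dtype=float)


def _injection_rng(config: SimConfig, sample_index: int, replicate: int
                   ) -> np.random.Generator:
    # one substream per injection, derived by counter: shared by the IMS and
    # MS simulators so both see the identical RT jitter
    return np.random.default_rng(
        [config.seed & 0x7FFFFFFF, 1000 + sample_index, replicate]
    )


def _noise_rng(config: SimConfig, sample_index: int, replicate: int, branch: int
               ) -> np.random.Generator:
    return np.random.default_rng(
        [config.seed & 0x7FFFFFFF, 500_000 + sample_index, replicate, branch]
    )


def _injection_jitter(config: SimConfig, sample_index: int, replicate: int
                      ) -> tuple[float, float]:
    rng = _injection_rng(config, sample_index, replicate)
    rt_j = rng.normal(0.0, config.rt_jitter_sd) if config.rt_jitter_sd > 0 else 0.0
    dt_j = rng.normal(0.0, config.dt_jitter_sd) if config.dt_jitter_sd > 0 else 0.0
    return float(rt_j), float(dt_j)


def _dt_profile(n_dt: int, center: float, sigma: float) -> np.ndarray:
    idx = np.arange(n_dt)
    prof = np.exp(-0.5 * ((idx - center) / sigma) ** 2)
    return prof / prof.sum()


def _validate_rts(library: list[CompoundSpec], config: SimConfig, use_ms: bool) -> None:
    rt = config.rt_axis
    for spec in library:
        r = spec.rt_ms if use_ms else spec.rt_true
        if not (rt[0] <= r <= rt[-1]):
            raise ConfigurationError(
                f"compound {spec.name!r} RT {r} min outside the simulated gradient")


# --------------------------------------------------------------------------
# cube simulators

def simulate_ims_cube(
    samples: list[SampleMeta],
    concentrations: dict[str, dict[str, float]],
    config: SimConfig,
    library: list[CompoundSpec] | None = None,
) -> list[IMSCube]:
    """Simulate IMS runs (``n_replicates`` per sample).

    Each run holds the RIP, the fixed RT marker and, per compound, separable
    2D Gaussian peaks at (rt_true + jitter, each ion species).  The ion
    charge available per RT row is fixed: the RIP carries whatever the
    product ions have not consumed (depletion capped so the RIP never drops
    below 1 - max_depletion of the total).  Cluster-ion ("dimer") intensity
    follows the saturating fraction c / (c + dimer_threshold).
    """
    library = library if library is not None else DEFAULT_COMPOUNDS
    _validate_rts(library, config, use_ms=False)
    rt = config.rt_axis
    n_dt = config.n_dt
    dt_step_rel = (config.dt_rel_max - config.dt_rel_min) / (n_dt - 1)
    cubes = []
    for i, meta in enumerate(samples):
        conc = concentrations[meta.sample_id]
        for rep in range(config.n_replicates):
            rt_j, dt_j = _injection_jitter(config, i, rep)
            # drift-field fluctuation: all drift times scale by (1 + eps),
            # parameterised so the RIP moves by dt_j grid steps
            dt_eps = dt_j * dt_step_rel
            products = np.zeros((len(rt), n_dt))
            for spec in library:
                if spec.class_tag == "marker":
                    amp = config.marker_amplitude
                else:
                    c = conc.get(spec.name, 0.0)
                    if c <= 0:
                        continue
                    amp = config.intensity_gain * c
                g_rt = amp * np.exp(-0.5 * ((rt - (spec.rt_true + rt_j)) / config.rt_sigma) ** 2)
                if len(spec.dt_rel_species) > 1 and np.isfinite(spec.dimer_threshold):
                    c_eff = conc.get(spec.name, 0.0)
                    f_dimer = c_eff / (c_eff + spec.dimer_threshold)
                else:
                    f_dimer = 0.0
                n_dimer = max(len(spec.dt_rel_species) - 1, 1)
                for k, d in enumerate(spec.dt_rel_species):
                    share = (1.0 - f_dimer) if k == 0 else f_dimer / n_dimer
                    if share <= 0:
                        continue
                    center = (d * (1 + dt_eps) - config.dt_rel_min) / dt_step_rel
                    prof = _dt_profile(n_dt, center, config.dt_sigma)
                    products += np.outer(g_rt * share, prof)
            # cap depletion, then give the RIP the remaining charge per row
            row_tot = products.sum(axis=1)
            cap = config.max_depletion * config.total_charge
            over = row_tot > cap
            if np.any(over):
                products[over] *= (cap / row_tot[over])[:, None]
                row_tot = products.sum(axis=1)
            rip_center = (1.0 * (1 + dt_eps) - config.dt_rel_min) / dt_step_rel
            rip_prof = _dt_profile(n_dt, rip_center, config.dt_sigma)
            intens = products + np.outer(config.total_charge - row_tot, rip_prof)
            if config.noise_sd_multiplicative > 0 or config.noise_sd_additive > 0:
                nrng = _noise_rng(config, i, rep, branch=1)
                if config.noise_sd_multiplicative > 0:
                    intens = intens * np.exp(nrng.normal(0, config.noise_sd_multiplicative))
                if config.noise_sd_additive > 0:
                    intens = intens + nrng.normal(0, config.noise_sd_additive, intens.shape)
            cubes.append(IMSCube(intensities=intens, rt_axis=rt.copy(),
                                 dt_axis=config.dt_axis_raw,
                                 sample_id=meta.sample_id, replicate=rep,
                                 provenance=[{"step": "simulate_ims", "seed": config.seed}]))
    return cubes


def simulate_ms_cube(
    samples: list[SampleMeta],
    concentrations: dict[str, dict[str, float]],
    config: SimConfig,
    library: list[CompoundSpec] | None = None,
) -> list[MSCube]:
    """Simulate EI-MS runs coupled to the IMS runs of the same injections.

    Each compound contributes its fragment pattern scaled by concentration at
    a Gaussian RT profile on unit m/z channels; the RT jitter of each run is
    drawn from the same injection substream as the IMS simulator, so the two
    cubes of one injection share it exactly.
    """
    library = library if library is not None else DEFAULT_COMPOUNDS
    _validate_rts(library, config, use_ms=True)
    for spec in library:
        for mz in spec.fragment_pattern:
            if not (config.mz_min <= mz <= config.mz_max):
                raise ConfigurationError(
                    f"fragment m/z {mz} of {spec.name!r} outside scan range "
                    f"{config.mz_min}-{config.mz_max}")
    rt = config.rt_axis
    mz_axis = config.mz_axis
    cubes = []
    for i, meta in enumerate(samples):
        conc = concentrations[meta.sample_id]
        for rep in range(config.n_replicates):
            rt_j, _ = _injection_jitter(config, i, rep)
            intens = np.zeros((len(rt), len(mz_axis)))
            for spec in library:
                if spec.class_tag == "marker":
                    amp = config.marker_amplitude
                else:
                    c = conc.get(spec.name, 0.0)
                    if c <= 0:
                        continue
                    amp = config.ms_gain * c
                g_rt = amp * np.exp(-0.5 * ((rt - (spec.rt_ms + rt_j)) / config.rt_sigma) ** 2)
                pat = np.zeros(len(mz_axis))
                for mz, ab in spec.fragment_pattern.items():
                    pat[int(mz) - config.mz_min] += ab
                intens += np.outer(g_rt, pat)
            if config.noise_sd_multiplicative > 0 or config.noise_sd_additive > 0:
                nrng = _noise_rng(config, i, rep, branch=2)
                if config.noise_sd_multiplicative > 0:
                    intens = intens * np.exp(nrng.normal(0, config.noise_sd_multiplicative))
                if config.noise_sd_additive > 0:
                    intens = np.clip(
                        intens + nrng.normal(0, config.noise_sd_additive, intens.shape),
                        0.0, None)
            cubes.append(MSCube(intensities=intens, rt_axis=rt.copy(),
                                mz_axis=mz_axis.copy(),
                                sample_id=meta.sample_id, replicate=rep,
                                provenance=[{"step": "simulate_ms", "seed": config.seed}]))
    return cubes


def simulate_study(
    config: SimConfig,
    library: list[CompoundSpec] | None = None,
    alpha_range: tuple[float, float] = (ALPHA_LO, ALPHA_HI),
    conc_noise_sd: float = 0.06,
    include_ms: bool = True,
) -> tuple[list[SampleMeta], list[IMSCube], list[MSCube]]:
    """One full synthetic study: metadata, concentrations, paired cube sets."""
    library = library if library is not None else DEFAULT_COMPOUNDS
    samples = make_sample_table(config.n_samples, alpha_range, seed=config.seed)
    conc = {
        m.sample_id: concentration_model(m, library, seed=config.seed,
                                         noise_sd=conc_noise_sd)
        for m in samples
    }
    ims = simulate_ims_cube(samples, conc, config, library)
    ms = simulate_ms_cube(samples, conc, config, library) if include_ms else []
    return samples, ims, ms


# --------------------------------------------------------------------------
# container I/O

def write_hdf5(path, ims_cubes: list[IMSCube], ms_cubes: list[MSCube],
               samples: list[SampleMeta] | None = None) -> None:
    """Write cube sets to one HDF5 container.

    Layout: /ims/<sample>/<replicate> and /ms/<sample>/<replicate> groups,
    each holding ``intensities`` plus its axis vectors; sample metadata as a
    root-level attribute-free table under /meta.
    """
    import h5py

    with h5py.File(path, "w") as f:
        for kind, cubes in (("ims", ims_cubes), ("ms", ms_cubes)):
            for c in cubes:
                g = f.create_group(f"{kind}/{c.sample_id}/{c.replicate}")
                g.create_dataset("intensities", data=c.intensities)
                g.create_dataset("rt_axis", data=c.rt_axis)
                if kind == "ims":
                    g.create_dataset("dt_axis", data=c.dt_axis)
                    g.attrs["dt_normalized"] = c.dt_normalized
                else:
                    g.create_dataset("mz_axis", data=c.mz_axis)
                    g.attrs["log_scale"] = c.log_scale
        if samples:
            df = metadata_frame(samples)
            g = f.create_group("meta")
            for col in df.columns:
                data = df[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                g.create_dataset(col, data=data)


def read_hdf5(path) -> tuple[list[IMSCube], list[MSCube], pd.DataFrame | None]:
    """Read a container written by :func:`write_hdf5`."""
    import h5py

    ims: list[IMSCube] = []
    ms: list[MSCube] = []
    meta = None
    with h5py.File(path, "r") as f:
        for sid in sorted(f.get("ims", {})):
            for rep in sorted(f[f"ims/{sid}"], key=int):
                g = f[f"ims/{sid}/{rep}"]
                ims.append(IMSCube(intensities=g["intensities"][()],
                                   rt_axis=g["rt_axis"][()], dt_axis=g["dt_axis"][()],
                                   sample_id=sid, replicate=int(rep),
                                   dt_normalized=bool(g.attrs.get("dt_normalized", False))))
        for sid in sorted(f.get("ms", {})):
            for rep in sorted(f[f"ms/{sid}"], key=int):
                g = f[f"ms/{sid}/{rep}"]
                ms.append(MSCube(intensities=g["intensities"][()],
                                 rt_axis=g["rt_axis"][()], mz_axis=g["mz_axis"][()],
                                 sample_id=sid, replicate=int(rep),
                                 log_scale=bool(g.attrs.get("log_scale", False))))
        if "meta" in f:
            cols = {}
            for col in f["meta"]:
                data = f[f"meta/{col}"][()]
                if data.dtype.kind == "S":
                    data = data.astype(str)
                cols[col] = data
            meta = pd.DataFrame(cols)
    return ims, ms, meta


def cube_to_long_csv(cube, path) -> None:
    """Long-format CSV export (rt, axis2, intensity) for small cubes."""
    from .preprocess import second_axis

    axis2 = second_axis(cube)
    name = "dt" if isinstance(cube, IMSCube) else "mz"
    rt_col = np.repeat(cube.rt_axis, len(axis2))
    ax_col = np.tile(axis2, len(cube.rt_axis))
    pd.DataFrame({"rt": rt_col, name: ax_col,
                  "intensity": cube.intensities.ravel()}).to_csv(path, index=False)
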