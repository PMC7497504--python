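"""Spectral preprocessing for paired GC-IMS / GC-MS data cubes.

Each sample run is a 2D intensity matrix over retention time (RT, minutes)
and a second axis: drift time (IMS) or unit m/z channels (EI-MS).  The chain
implemented here turns a set of raw replicate cubes into the unfolded,
column-centred matrix consumed by the chemometric layer:

IMS branch: Savitzky-Golay smoothing -> RIP detection and drift-time
normalisation (RIP at 1.0) -> interpolation onto a common RIP-relative grid
-> RT alignment to an early-eluting marker peak -> region extraction
(default 1.3-15 min) -> replicate averaging -> unfolding -> mean centering
(Pareto scaling optionally, for regression).

MS branch: smoothing -> RT alignment -> log10(1+x) transform -> region
extraction -> replicate averaging -> unfolding -> mean centering.

Every operation is pure (returns a new cube) and appends a provenance record,
so a processed cube carries a machine-readable log of what produced it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter


class DetectionError(RuntimeError):
    """A required spectral feature (RIP, marker peak) could not be located."""


class AlignmentError(RuntimeError):
    """RT alignment failed: no marker peak above threshold in the window."""


class RegionError(ValueError):
    """Region extraction produced an empty cube."""


# --------------------------------------------------------------------------
# cube containers

@dataclass
class _Cube:
    intensities: np.ndarray  # (n_rt, n_second)
    rt_axis: np.ndarray  # minutes
    sample_id: str = ""
    replicate: int = 0
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.rt_axis = np.asarray(self.rt_axis, dtype=float)
        second = self._second_axis()
        if self.intensities.shape != (len(self.rt_axis), len(second)):
            raise ValueError("intensity matrix dimensions must match axes")
        for ax in (self.rt_axis, second):
            if len(ax) > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError("axes must be strictly increasing")

    def _second_axis(self) -> np.ndarray:
        raise NotImplementedError

    def _with(self, step: str, **changes) -> "_Cube":
        new = replace(self, **changes)
        new.provenance = [*self.provenance, {"step": step, **{
            k: v for k, v in changes.items()
            if isinstance(v, (int, float, str, bool))
        }}]
        return new


@dataclass
class IMSCube(_Cube):
    """One IMS run: intensities over (RT, drift time).

    ``dt_axis`` is in raw drift-time units until :func:`normalize_dt_to_rip`
    rescales it to dimensionless RIP-relative units (``dt_normalized``).
    """

    dt_axis: np.ndarray = None  # type: ignore[assignment]
    dt_normalized: bool = False

    def __post_init__(self) -> None:
        self.dt_axis = np.asarray(self.dt_axis, dtype=float)
        super().__post_init__()

    def _second_axis(self) -> np.ndarray:
        return self.dt_axis


@dataclass
class MSCube(_Cube):
    """One EI-MS run: intensities over (RT, unit m/z channel)."""

    mz_axis: np.ndarray = None  # type: ignore[assignment]
    log_scale: bool = False

    def __post_init__(self) -> None:
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        super().__post_init__()

    def _second_axis(self) -> np.ndarray:
        return self.mz_axis


def second_axis(cube: _Cube) -> np.ndarray:
    return cube._second_axis()


# --------------------------------------------------------------------------
# operations

def smooth_sg(cube: _Cube, window: int = 7, polyorder: int = 2) -> _Cube:
    """Savitzky-Golay smoothing along the RT axis of every trace.

    Reduces random noise while leaving polynomial trends up to ``polyorder``
    untouched.  ``window`` must be odd and larger than ``polyorder``.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if window > cube.intensities.shape[0]:
        raise ValueError("window exceeds RT axis length")
    sm = savgol_filter(cube.intensities, window, polyorder, axis=0)
    return cube._with("smooth_sg", intensities=sm)


def find_rip(cube: IMSCube) -> int:
    """Drift-time index of the reactant ion peak.

    The RIP is present in every RT row, so the median intensity over RT has
    its global maximum at the RIP position regardless of analyte peaks.
    """
    if cube.intensities.size == 0:
        raise DetectionError("empty cube")
    profile = np.median(cube.intensities, axis=0)
    if np.ptp(profile) <= 0:
        raise DetectionError("flat drift profile: no RIP maximum")
    return int(np.argmax(profile))


def find_rip_apex(cube: IMSCube) -> float:
    """RIP position as a fractional drift-time index.

    Parabolic refinement of :func:`find_rip` around the apex of the
    median-over-RT profile; sub-grid precision keeps the intense RIP aligned
    across runs after normalisation.
    """
    i = find_rip(cube)
    profile = np.median(cube.intensities, axis=0)
    if 0 < i < len(profile) - 1:
        y0, y1, y2 = profile[i - 1:i + 2]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            return i + float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
    return float(i)


def normalize_dt_to_rip(cube: IMSCube, rip_index: float) -> IMSCube:
    """Rescale the drift-time axis to RIP-relative units (RIP at 1.0).

    ``rip_index`` may be fractional (from :func:`find_rip_apex`); the RIP
    drift time is then interpolated between grid points.
    """
    if not 0 <= rip_index <= len(cube.dt_axis) - 1:
        raise ValueError("rip_index out of range")
    rip_dt = float(np.interp(rip_index, np.arange(len(cube.dt_axis)), cube.dt_axis))
    if rip_dt <= 0:
        raise ValueError("RIP drift time must be strictly positive")
    new = cube._with("normalize_dt_to_rip", dt_axis=cube.dt_axis / rip_dt,
                     dt_normalized=True)
    new.provenance[-1]["rip_index"] = float(rip_index)
    return new


def align_rt(
    cube: _Cube,
    marker_rt_nominal: float = 0.5,
    search_window: float = 0.3,
    min_intensity: float = 0.0,
    rip_exclude: float = 1.05,
) -> _Cube:
    """Shift the RT dimension so the marker peak lands at its nominal RT.

    The marker apex is the maximum of the summed intensity within
    ``marker_rt_nominal +/- search_window``.  On a RIP-normalised IMS cube
    only drift-time columns above ``rip_exclude`` enter the sum: the total
    ion current of an IMS spectrum is flat (the RIP absorbs whatever the
    product ions gain), so the marker is only visible in the product-ion
    region.  The cube is resampled onto its own RT grid after a rigid shift;
    the corrective shift applied to the RT dimension (negative of the
    detected displacement) is recorded in provenance as ``shift_min``.
    """
    rt = cube.rt_axis
    sel = (rt >= marker_rt_nominal - search_window) & (rt <= marker_rt_nominal + search_window)
    if not np.any(sel):
        raise AlignmentError("search window outside RT axis")
    if isinstance(cube, IMSCube) and cube.dt_normalized:
        cols = cube.dt_axis > rip_exclude
        if not np.any(cols):
            cols = np.ones(len(cube.dt_axis), dtype=bool)
    else:
        cols = np.ones(cube.intensities.shape[1], dtype=bool)
    profile = cube.intensities[np.ix_(sel, cols)].sum(axis=1)
    if profile.max() <= min_intensity:
        raise AlignmentError("no marker peak above threshold in window")
    apex_idx = int(np.argmax(profile))
    apex_rt = rt[sel][apex_idx]
    # parabolic refinement of the apex between grid points
    if 0 < apex_idx < len(profile) - 1:
        y0, y1, y2 = profile[apex_idx - 1:apex_idx + 2]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            frac = 0.5 * (y0 - y2) / denom
            step = rt[sel][1] - rt[sel][0] if len(rt[sel]) > 1 else 0.0
            apex_rt = apex_rt + np.clip(frac, -0.5, 0.5) * step
    displacement = float(apex_rt - marker_rt_nominal)
    # sample the old cube at rt + displacement: moves the marker apex to nominal
    shifted = np.empty_like(cube.intensities)
    for j in range(cube.intensities.shape[1]):
        shifted[:, j] = np.interp(rt + displacement, rt, cube.intensities[:, j])
    new = cube._with("align_rt", intensities=shifted)
    new.provenance[-1]["shift_min"] = -displacement
    return new


def interpolate_dt(cube: IMSCube, target_dt_axis: np.ndarray) -> IMSCube:
    """Linearly interpolate every RT row onto a common drift-time grid."""
    target = np.asarray(target_dt_axis, dtype=float)
    if target.min() < cube.dt_axis.min() or target.max() > cube.dt_axis.max():
        raise ValueError("target axis requests extrapolation")
    out = np.empty((cube.intensities.shape[0], len(target)))
    for i in range(cube.intensities.shape[0]):
        out[i] = np.interp(target, cube.dt_axis, cube.intensities[i])
    return cube._with("interpolate_dt", intensities=out, dt_axis=target)


def log_transform(cube: MSCube) -> MSCube:
    """Elementwise log10(1 + x); compresses the dynamic range so the dominant
    myrcene signal does not drown minor components."""
    if np.any(cube.intensities < 0):
        raise ValueError("log transform requires non-negative intensities")
    return cube._with("log_transform",
                      intensities=np.log10(1.0 + cube.intensities),
                      log_scale=True)


def extract_region(cube: _Cube, rt_lo: float = 1.3, rt_hi: float = 15.0) -> _Cube:
    """Keep RT rows in the closed interval [rt_lo, rt_hi]."""
    if rt_lo >= rt_hi:
        raise ValueError("rt_lo must be below rt_hi")
    sel = (cube.rt_axis >= rt_lo) & (cube.rt_axis <= rt_hi)
    if not np.any(sel):
        raise RegionError("no RT points inside the requested region")
    new = cube._with("extract_region", intensities=cube.intensities[sel],
                     rt_axis=cube.rt_axis[sel])
    new.provenance[-1].update({"rt_lo": rt_lo, "rt_hi": rt_hi})
    return new


def average_replicates(cubes: list[_Cube]) -> _Cube:
    """Cellwise mean of replicate runs of one sample (common grid required)."""
    if not cubes:
        raise ValueError("no cubes to average")
    ref = cubes[0]
    for c in cubes[1:]:
        if (not np.array_equal(c.rt_axis, ref.rt_axis)
                or not np.array_equal(second_axis(c), second_axis(ref))):
            raise ValueError("replicates are not on a common grid")
        if c.sample_id != ref.sample_id:
            raise ValueError("replicates belong to different samples")
    mean = np.mean([c.intensities for c in cubes], axis=0)
    new = ref._with("average_replicates", intensities=mean, replicate=-1)
    new.provenance[-1]["n_replicates"] = len(cubes)
    return new


# --------------------------------------------------------------------------
# unfolding and column scaling

@dataclass
class UnfoldedMatrix:
    """Samples x flattened-feature matrix with the back-map to (RT, axis2).

    Row-major flattening: RT is the outer index, the second axis the inner
    one, so column ``j`` corresponds to
    ``(rt_axis[j // len(second)], second[j % len(second)])``.
    """

    X: np.ndarray  # (n_samples, n_rt * n_second)
    sample_ids: list[str]
    rt_axis: np.ndarray
    second_axis: np.ndarray
    second_name: str  # "dt_rel" or "mz"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.sample_ids),
                            len(self.rt_axis) * len(self.second_axis)):
            raise ValueError("matrix shape inconsistent with axes")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def column_coords(self, j: int) -> tuple[float, float]:
        """(RT, second-axis) coordinates of feature column j."""
        n2 = len(self.second_axis)
        return float(self.rt_axis[j // n2]), float(self.second_axis[j % n2])

    def refold(self, vector: np.ndarray) -> np.ndarray:
        """Inverse of the flattening for any feature-length vector."""
        v = np.asarray(vector).ravel()
        if v.size != self.n_features:
            raise ValueError("vector length does not match the column map")
        return v.reshape(len(self.rt_axis), len(self.second_axis))


def save_unfolded(matrix: UnfoldedMatrix, path) -> None:
    """Serialize an unfolded matrix with its column back-map to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=matrix.X)
        f.create_dataset("sample_ids",
                         data=np.asarray(matrix.sample_ids, dtype="S"))
        f.create_dataset("rt_axis", data=matrix.rt_axis)
        f.create_dataset("second_axis", data=matrix.second_axis)
        f.attrs["second_name"] = matrix.second_name


def load_unfolded(path) -> UnfoldedMatrix:
    """Read an unfolded matrix written by :func:`save_unfolded`."""
    import h5py

    with h5py.File(path, "r") as f:
        return UnfoldedMatrix(
            X=f["X"][()],
            sample_ids=[s.decode() for s in f["sample_ids"][()]],
            rt_axis=f["rt_axis"][()],
            second_axis=f["second_axis"][()],
            second_name=str(f.attrs["second_name"]),
        )


def unfold(cubes: list[_Cube]) -> UnfoldedMatrix:
    """Flatten one cube per sample into the samples x features matrix."""
    if not cubes:
        raise ValueError("no cubes to unfold")
    ref = cubes[0]
    for c in cubes[1:]:
        if (not np.array_equal(c.rt_axis, ref.rt_axis)
                or not np.array_equal(second_axis(c), second_axis(ref))):
            raise ValueError("cubes are not on a common grid")
    X = np.stack([c.intensities.ravel(order="C") for c in cubes])
    name = "dt_rel" if isinstance(ref, IMSCube) else "mz"
    return UnfoldedMatrix(X, [c.sample_id for c in cubes], ref.rt_axis.copy(),
                          second_axis(ref).copy(), name)


class ColumnScaler:
    """Column centering with optional Pareto scaling, fit on training rows.

    Pareto scaling divides each mean-centred column by the square root of its
    (sample) standard deviation, damping the dominance of intense signals
    without amplifying pure-noise channels as much as autoscaling would.
    Zero-variance columns are passed through unscaled so the refold map keeps
    its full length.  Stored parameters let test rows be transformed with the
    training fit.
    """

    def __init__(self, pareto: bool = False):
        self.pareto = pareto
        self.means_: np.ndarray | None = None
        self.scales_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "ColumnScaler":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least two rows to fit column statistics")
        self.means_ = X.mean(axis=0)
        if self.pareto:
            sd = X.std(axis=0, ddof=1)
            scale = np.sqrt(sd)
            scale[scale == 0] = 1.0
            self.scales_ = scale
        else:
            self.scales_ = np.ones(X.shape[1])
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.means_ is None:
            raise RuntimeError("scaler is not fitted")
        return (np.asarray(X, dtype=float) - self.means_) / self.scales_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        if self.means_ is None:
            raise RuntimeError("scaler is not fitted")
        return np.asarray(X, dtype=float) * self.scales_ + self.means_


def mean_center(X: np.ndarray) -> tuple[np.ndarray, ColumnScaler]:
    """Column mean-centering; returns the matrix and the fitted scaler."""
    sc = ColumnScaler(pareto=False)
    return sc.fit_transform(X), sc


def pareto_scale(X: np.ndarray) -> tuple[np.ndarray, ColumnScaler]:
    """Mean-centering followed by Pareto scaling (divide by sqrt(column SD))."""
    sc = ColumnScaler(pareto=True)
    return sc.fit_transform(X), sc


# --------------------------------------------------------------------------
# branch pipelines

def preprocess_ims(
    cubes: list[IMSCube],
    sg_window: int = 7,
    sg_polyorder: int = 2,
    target_dt_axis: np.ndarray | None = None,
    marker_rt: float = 0.5,
    marker_window: float = 0.3,
    rt_lo: float = 1.3,
    rt_hi: float = 15.0,
) -> list[IMSCube]:
    """Full per-run IMS chain up to (and excluding) replicate averaging.

    smooth -> RIP-normalise DT -> interpolate onto a common RIP-relative grid
    -> align RT to the marker -> extract the informative RT region.
    If ``target_dt_axis`` is None a common grid is built from the overlap of
    the normalised axes at the resolution of the first cube.
    """
    normed = []
    for c in cubes:
        c = smooth_sg(c, sg_window, sg_polyorder)
        c = normalize_dt_to_rip(c, find_rip_apex(c))
        normed.append(c)
    if target_dt_axis is None:
        lo = max(c.dt_axis.min() for c in normed)
        hi = min(c.dt_axis.max() for c in normed)
        target_dt_axis = np.linspace(lo, hi, len(normed[0].dt_axis))
    out = []
    for c in normed:
        c = interpolate_dt(c, target_dt_axis)
        c = align_rt(c, marker_rt, marker_window)
        c = extract_region(c, rt_lo, rt_hi)
        out.append(c)
    return out


def preprocess_ms(
    cubes: list[MSCube],
    sg_window: int = 7,
    sg_polyorder: int = 2,
    marker_rt: float = 0.5,
    marker_window: float = 0.3,
    rt_lo: float = 1.3,
    rt_hi: float = 15.0,
) -> list[MSCube]:
    """Full per-run MS chain: smooth -> align RT -> log10(1+x) -> extract."""
    out = []
    for c in cubes:
        c = smooth_sg(c, sg_window, sg_polyorder)
        c = align_rt(c, marker_rt, marker_window)
        # smoothing ringing can undershoot zero; intensities are physical
        c = c._with("clip_negative", intensities=np.clip(c.intensities, 0.0, None))
        c = log_transform(c)
        c = extract_region(c, rt_lo, rt_hi)
        out.append(c)
    return out


def average_by_sample(cubes: list[_Cube]) -> list[_Cube]:
    """Group replicate cubes by sample_id (input order preserved) and average."""
    order: list[str] = []
    groups: dict[str, list[_Cube]] = {}
    for c in cubes:
        if c.sample_id not in groups:
            order.append(c.sample_id)
            groups[c.sample_id] = []
        groups[c.sample_id].append(c)
    return [average_replicates(groups[s]) for s in order]


def write_provenance(cubes: list[_Cube], path) -> None:
    """Dump provenance logs as JSON lines, one record per step per cube."""
    with open(path, "w") as fh:
        for c in cubes:
            for rec in c.provenance:
                fh.write(json.dumps(
                    {"sample_id": c.sample_id, "replicate": c.replicate, **rec},
                    sort_keys=True) + "\n")
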