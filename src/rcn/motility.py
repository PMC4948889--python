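"""Collective-migration metrics from gridded velocity fields.

Conventions: the wound-closure direction is +x; the lateral direction is y.
Velocity fields are regular 2-D grids of PIV vectors (positions in um,
velocities in um/min).  The lateral correlation function

    C(r) = <u(r') u(r' + r)> / [ <u(r')^2> <u(r' + r)^2> ]^(1/2)

is computed over the lateral fluctuation u (lateral velocity minus its field
mean), averaged over all vector pairs at separation r.  The correlation
length is the distance at which C(r) decays to a negligible level; the
movement-angle map is the per-frame distribution of angles between PIV
vectors and the wound-closure direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VelocityField", "CorrelationProfile",
    "lateral_fluctuations", "correlation_profile", "correlation_length",
    "movement_angle_map", "leading_edge_speed",
    "read_velocity_fields", "write_velocity_fields",
]


@dataclass
class VelocityField:
    """One PIV frame: regular grid positions (um) and velocities (um/min)."""

    x: np.ndarray  # (ny, nx) grid x-positions
    y: np.ndarray  # (ny, nx) grid y-positions
    u: np.ndarray  # (ny, nx) velocity toward wound closure (+x)
    v: np.ndarray  # (ny, nx) lateral velocity (+y)
    time_min: float = 0.0

    def __post_init__(self) -> None:
        arrs = [np.asarray(a, dtype=float) for a in (self.x, self.y, self.u, self.v)]
        self.x, self.y, self.u, self.v = arrs
        if not all(a.shape == self.x.shape and a.ndim == 2 for a in arrs):
            raise ValueError("x, y, u, v must share one 2-D grid shape")
        if not all(np.all(np.isfinite(a)) for a in arrs):
            raise ValueError("velocity field contains non-finite values")
        dx = np.diff(self.x, axis=1)
        dy = np.diff(self.y, axis=0)
        if dx.size and not np.allclose(dx, dx.flat[0]):
            raise ValueError("grid must be regular along x")
        if dy.size and not np.allclose(dy, dy.flat[0]):
            raise ValueError("grid must be regular along y")

    @property
    def spacing(self) -> float:
        """Grid spacing (um)."""
        if self.x.shape[1] > 1:
            return float(self.x[0, 1] - self.x[0, 0])
        return float(self.y[1, 0] - self.y[0, 0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x.ravel(), "y": self.y.ravel(),
                             "u": self.u.ravel(), "v": self.v.ravel()})


@dataclass
class CorrelationProfile:
    """Binned lateral correlation C(r) for one frame."""

    r: np.ndarray       # bin-center separations (um); r[0] = 0
    c: np.ndarray       # correlation values; c[0] = 1
    time_min: float = 0.0
    length: float | None = None     # derived correlation length (um)
    truncated: bool = False         # True when C never became negligible

    def __post_init__(self) -> None:
        if self.c[0] < 1 - 1e-9:
            raise ValueError("C(0) must be 1 for a nondegenerate field")


def lateral_fluctuations(field: VelocityField) -> np.ndarray:
    """Lateral velocity minus its field mean; zero-mean by construction."""
    if field.v.size < 2:
        raise ValueError("need at least two vectors")
    return field.v - field.v.mean()


def correlation_profile(field: VelocityField,
                        bin_width: float | None = None) -> CorrelationProfile:
    """Normalized two-point correlation of the lateral fluctuations.

    Pairs of grid points are binned by separation distance (default bin width
    = grid spacing); each bin's correlation is the mean pair product
    normalized by the root-mean-square fluctuation of the two pair members.
    """
    u = lateral_fluctuations(field)
    if np.allclose(u, 0.0):
        raise ValueError("zero-variance lateral fluctuations: "
                         "correlation undefined")
    if bin_width is None:
        bin_width = field.spacing
    pts = np.column_stack([field.x.ravel(), field.y.ravel()])
    uu = u.ravel()
    n = len(uu)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    prod = uu[:, None] * uu[None, :]
    sq = uu ** 2
    sq_pair_a = np.broadcast_to(sq[:, None], (n, n))
    sq_pair_b = np.broadcast_to(sq[None, :], (n, n))

    bins = np.round(d / bin_width).astype(int)
    nb = bins.max() + 1
    flat = bins.ravel()
    num = np.bincount(flat, weights=prod.ravel(), minlength=nb)
    den_a = np.bincount(flat, weights=sq_pair_a.ravel(), minlength=nb)
    den_b = np.bincount(flat, weights=sq_pair_b.ravel(), minlength=nb)
    count = np.bincount(flat, minlength=nb)
    valid = count > 0
    c = np.full(nb, np.nan)
    c[valid] = num[valid] / np.sqrt(den_a[valid] * den_b[valid])
    r = np.arange(nb) * bin_width
    return CorrelationProfile(r[valid], c[valid], time_min=field.time_min)


def _profile_length(prof: CorrelationProfile, method: str,
                    threshold: float) -> tuple[float, bool]:
    r, c = prof.r, prof.c
    if method == "efold":
        level = np.exp(-1.0)
    elif method == "threshold":
        level = threshold
    elif method == "zero":
        level = 0.0
    else:
        raise ValueError(f"unknown correlation-length method {method!r}")
    below = np.nonzero(c < level)[0]
    if len(below) == 0:
        if method == "zero":
            # Das-style fallback: first drop below the small threshold
            return _profile_length(prof, "threshold", threshold)
        return float(r[-1]), True
    i = below[0]
    if i == 0:
        return float(r[0] if r[0] > 0 else r[1] if len(r) > 1 else 0.0), False
    # linear interpolation of the crossing
    r0, r1 = r[i - 1], r[i]
    c0, c1 = c[i - 1], c[i]
    frac = (c0 - level) / (c0 - c1) if c0 != c1 else 0.0
    return float(r0 + frac * (r1 - r0)), False


def correlation_length(profiles: CorrelationProfile | Sequence[CorrelationProfile],
                       exclusion_min: float = 60.0,
                       method: str = "efold",
                       threshold: float = 0.05) -> float:
    """Average correlation length (um) over a sequence of frames.

    Frames earlier than ``exclusion_min`` minutes are excluded (the first
    hour after the scratch).  Per-frame length: the interpolated distance at
    which C(r) first drops below 1/e (default), below an absolute
    ``threshold``, or below zero ("zero", with the threshold as fallback
    when no crossing occurs).  Profiles whose correlation never becomes
    negligible contribute their field extent and set ``truncated``.
    """
    if isinstance(profiles, CorrelationProfile):
        profiles = [profiles]
    kept = [p for p in profiles if p.time_min >= exclusion_min]
    if not kept:
        raise ValueError("no profiles remain after the exclusion window")
    lengths = []
    for p in kept:
        p.length, p.truncated = _profile_length(p, method, threshold)
        lengths.append(p.length)
    return float(np.mean(lengths))


def movement_angle_map(fields: VelocityField | Sequence[VelocityField],
                       bin_deg: float = 5.0) -> pd.DataFrame:
    """Fraction of PIV vectors per movement angle, one row per frame.

    The movement angle is the angle between a velocity vector and the
    wound-closure direction (0 deg), binned over (-180, 180] with
    ``bin_deg``-wide bins centered on multiples of ``bin_deg``.  Rows are
    normalized to 1; zero-magnitude vectors are excluded and their count is
    stored in ``df.attrs['excluded_zero_vectors']``.
    """
    if isinstance(fields, VelocityField):
        fields = [fields]
    if not fields:
        raise ValueError("need at least one frame")
    nbins = int(round(360.0 / bin_deg))
    if abs(nbins * bin_deg - 360.0) > 1e-9:
        raise ValueError("bin width must divide 360 degrees")
    # bin k holds angles nearest k*bin_deg (mod 360); report centers in (-180, 180]
    centers = (bin_deg * np.arange(nbins) + 180.0) % 360.0 - 180.0
    centers = np.where(centers == -180.0, 180.0, centers)
    order = np.argsort(centers)
    rows, times, n_zero = [], [], 0
    for f in fields:
        u, v = f.u.ravel(), f.v.ravel()
        keep = np.hypot(u, v) > 0
        n_zero += int((~keep).sum())
        ang = np.degrees(np.arctan2(v[keep], u[keep]))
        idx = np.round(ang / bin_deg).astype(int) % nbins
        hist = np.bincount(idx, minlength=nbins).astype(float)
        if hist.sum() > 0:
            hist /= hist.sum()
        rows.append(hist[order])
        times.append(f.time_min)
    df = pd.DataFrame(rows, index=pd.Index(times, name="time_min"),
                      columns=pd.Index(centers[order], name="angle_deg"))
    df.attrs["excluded_zero_vectors"] = n_zero
    return df


def leading_edge_speed(mask_stack: np.ndarray,
                       frame_interval_min: float,
                       pixel_size_um: float = 1.0) -> tuple[float, bool]:
    """Average leading-front speed (um/h) from binary fluorescence masks.

    The front advances along +x (columns).  Per frame, the front position is
    the foremost occupied column averaged over rows; the speed is the
    field-of-view traversal distance over the time the average front takes
    to reach the last column.  When the front never reaches the end of the
    field of view, a least-squares slope of front position versus time is
    returned instead and the flag is True.

    Returns (speed_um_per_h, slope_fallback_used).
    """
    masks = np.asarray(mask_stack).astype(bool)
    if masks.ndim != 3 or masks.shape[0] < 2:
        raise ValueError("need a stack of at least two 2-D masks")
    if frame_interval_min <= 0 or pixel_size_um <= 0:
        raise ValueError("frame interval and pixel size must be positive")
    n_frames, _, n_cols = masks.shape
    fronts = np.empty(n_frames)
    for i, m in enumerate(masks):
        occupied = m.any(axis=1)
        if not occupied.any():
            raise ValueError(f"frame {i} contains no fluorescence")
        foremost = np.argmax(m[occupied, ::-1], axis=1)
        fronts[i] = np.mean(n_cols - 1 - foremost)
    t_min = frame_interval_min * np.arange(n_frames)
    reach = np.nonzero(fronts >= n_cols - 1)[0]
    start = fronts[0]
    if len(reach) > 0 and reach[0] > 0:
        i = reach[0]
        speed = (n_cols - 1 - start) * pixel_size_um / (t_min[i] / 60.0)
        return float(speed), False
    slope = np.polyfit(t_min, fronts, 1)[0]  # px/min
    return float(slope * pixel_size_um * 60.0), True


# ---------------------------------------------------------------------------
# file I/O: one delimited text file per frame (columns x, y, u, v)
# ---------------------------------------------------------------------------

def write_velocity_fields(fields: Sequence[VelocityField], outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, f in enumerate(fields):
        p = outdir / f"frame_{i:04d}_t{int(round(f.time_min)):05d}min.csv"
        f.to_frame().to_csv(p, index=False)
        paths.append(p)
    return paths


def read_velocity_fields(paths: Sequence, times_min: Sequence[float] | None = None
                         ) -> list[VelocityField]:
    """Read per-frame delimited text files with columns x, y, u, v.

    Frame times default to those encoded in the filenames written by
    :func:`write_velocity_fields` (``...t<minutes>min``), else the file index.
    """
    fields = []
    for i, p in enumerate(sorted(Path(q) for q in paths)):
        df = pd.read_csv(p)
        xs = np.sort(df["x"].unique())
        ys = np.sort(df["y"].unique())
        piv = df.set_index(["y", "x"]).sort_index()
        shape = (len(ys), len(xs))
        x, y = np.meshgrid(xs, ys)
        u = piv["u"].to_numpy().reshape(shape)
        v = piv["v"].to_numpy().reshape(shape)
        if times_min is not None:
            t = float(times_min[i])
        else:
            name = p.stem
            t = float(name.split("_t")[-1][:-3]) if "_t" in name and \
                name.endswith("min") else float(i)
        fields.append(VelocityField(x, y, u, v, time_min=t))
    return fields
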