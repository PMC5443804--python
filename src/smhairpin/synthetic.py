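"""Synthetic-data generators for every pipeline stage.

Each generator emulates the statistical structure its downstream analysis
assumes, with ground-truth labels attached, so that event detection,
model fitting and statistics can be validated without instrument data:

- ``gen_fd_curves``: retraction force-distance curves with WLC-shaped
  specific ruptures on a polydisperse PEG tether (Lc ~ Normal, rupture
  force ~ Normal), short-range nonspecific adhesion, and Gaussian
  instrument noise, at a configurable specific yield (the experimental
  yield was ~8-10%).
- ``gen_intensity_traces``: framed fluorescence traces with one-step
  bursts whose true dwell times are lognormal, quantized to whole frames
  (100 ms in the experiment).
- ``gen_topograph``: AFM height maps with fibril ridges, spherical caps
  and flat disks composed by height-field maximum plus Gaussian surface
  roughness.
- ``gen_dihedral_traj``: multi-state von Mises dihedral trajectories with
  known state occupancies (test harness for the dPCA landscape).
- ``gen_cg_dimer``: toy Go-model hairpin-monomer (H-M) and
  hairpin-hairpin (H-H) dimers whose inter-chain contact counts follow
  the reported hydrogen-bond counts (five H-bonds plus a Lys-Asp salt
  bridge for H-M; four H-bonds for H-H).

All generators are bitwise-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import ROOM_TEMPERATURE_K
from .dpca import DihedralTrajectory
from .dwell import IntensityTrace
from .errors import ParameterError
from .force import ForceDistanceCurve, WLCParams, wlc_extension, wlc_force
from .mcpull import CGModel, Contact
from .morphology import Topograph

__all__ = [
    "FDGenParams",
    "TraceGenParams",
    "TopoGenParams",
    "TopoFeature",
    "DihedralGenParams",
    "DihedralState",
    "gen_fd_curves",
    "gen_intensity_traces",
    "gen_dwell_dataset",
    "gen_topograph",
    "gen_particle_field",
    "gen_dihedral_traj",
    "gen_cg_dimer",
    "PRESETS",
]

#: Study presets: Table-1-level ground truth for the two probed systems.
PRESETS = {
    "HM": {
        "rupture_mean": 164.0, "rupture_sd": 17.0,   # pN
        "lifetime_mean_ms": 617.0,
        "lc_mean": 33.0, "lc_sd": 5.0,               # nm (PEG polydispersity)
        "n_force_events": 180, "n_dwell_events": 297,
    },
    "HH": {
        "rupture_mean": 100.0, "rupture_sd": 6.0,
        "lifetime_mean_ms": 344.0,
        "lc_mean": 33.0, "lc_sd": 5.0,
        "n_force_events": 175, "n_dwell_events": 274,
    },
}

#: Lognormal shape parameter used for dwell-time generation.  The printed
#: lifetime tables report only means; this shape gives the broad,
#: right-skewed histograms characteristic of single-molecule dwell data.
DEFAULT_DWELL_SIGMA = 0.8


# ===========================================================================
# force-distance curves
# ===========================================================================

@dataclass(frozen=True)
class FDGenParams:
    """Force-distance curve generator parameters.

    Defaults follow the H-M experimental conditions: 9% specific yield,
    PEG tether Lc ~ Normal(33, 5) nm, 10 pN instrument noise, 500 nm/s
    retraction.
    """

    n_curves: int = 2000
    rupture_mean: float = 164.0     # pN
    rupture_sd: float = 17.0        # pN
    lc_mean: float = 33.0           # nm
    lc_sd: float = 5.0              # nm
    lp: float = 0.38                # nm, tether persistence length
    temperature: float = ROOM_TEMPERATURE_K
    specific_fraction: float = 0.09
    noise_sd: float = 10.0          # pN
    nonspecific_fraction: float = 0.2
    retraction_speed: float = 500.0  # nm/s
    seed: int = 0
    dx_nm: float = 0.05             # distance sampling step

    def __post_init__(self):
        if self.specific_fraction + self.nonspecific_fraction > 1.0:
            raise ParameterError("specific + nonspecific fraction must be <= 1")
        if not (0 <= self.specific_fraction <= 1 and 0 <= self.nonspecific_fraction <= 1):
            raise ParameterError("fractions must lie in [0, 1]")
        for name in ("rupture_mean", "lc_mean", "lp", "temperature",
                     "retraction_speed", "dx_nm"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.rupture_sd < 0 or self.lc_sd < 0 or self.noise_sd < 0:
            raise ParameterError("spreads must be >= 0")
        if self.lc_sd >= self.lc_mean:
            raise ParameterError("lc_sd must be smaller than lc_mean")
        if self.n_curves < 1:
            raise ParameterError("n_curves must be >= 1")


def _truncated_normal(rng, mean, sd, size, low=0.0):
    """Normal draws conditioned on > low (rejection; spreads here are narrow)."""
    if sd == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size=size)
    bad = out <= low
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= low
    return out


def gen_fd_curves(params: FDGenParams):
    """Generate labelled retraction curves.

    Returns ``(curves, truth)`` where truth is a list of dicts with the
    per-curve kind ('specific' | 'nonspecific' | 'noise') and, for specific
    curves, the true rupture force, contour length and rupture distance.
    Exactly ``round(n_curves * specific_fraction)`` curves are specific.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_curves
    n_spec = int(round(n * params.specific_fraction))
    n_nonspec = int(round(n * params.nonspecific_fraction))
    n_nonspec = min(n_nonspec, n - n_spec)

    kinds = np.array(["specific"] * n_spec + ["nonspecific"] * n_nonspec
                     + ["noise"] * (n - n_spec - n_nonspec))
    rng.shuffle(kinds)

    x_max = params.lc_mean + 4.0 * params.lc_sd + 10.0
    x = np.arange(0.0, x_max, params.dx_nm)

    curves, truth = [], []
    for idx, kind in enumerate(kinds):
        f = rng.normal(0.0, params.noise_sd, size=x.size) if params.noise_sd > 0 \
            else np.zeros_like(x)
        record = {"kind": str(kind), "curve_id": f"curve_{idx:05d}"}
        if kind == "specific":
            lc = float(_truncated_normal(rng, params.lc_mean, params.lc_sd, ()))
            fr = float(_truncated_normal(rng, params.rupture_mean, params.rupture_sd, ()))
            wlc = WLCParams(Lp=params.lp, Lc=lc, temperature=params.temperature)
            x_rup = wlc_extension(fr, wlc)
            attached = x < x_rup
            f[attached] += wlc_force(x[attached], wlc)
            record.update(Fr=fr, Lc=lc, x_rupture=float(x_rup))
        elif kind == "nonspecific":
            # triangular short-range adhesion peak within 10 nm of contact
            peak_x = rng.uniform(1.0, 5.0)
            peak_f = rng.uniform(30.0, 120.0)
            end_x = min(2.0 * peak_x, 9.5)
            rise = x <= peak_x
            fall = (x > peak_x) & (x < end_x)
            f[rise] += peak_f * x[rise] / peak_x
            f[fall] += peak_f * (end_x - x[fall]) / (end_x - peak_x)
            record.update(peak_x=float(peak_x), peak_f=float(peak_f))
        curves.append(ForceDistanceCurve(
            distance=x.copy(), force=f,
            retraction_speed=params.retraction_speed,
            id=record["curve_id"],
        ))
        truth.append(record)
    return curves, truth


# ===========================================================================
# fluorescence intensity traces
# ===========================================================================

@dataclass(frozen=True)
class TraceGenParams:
    """Intensity-trace generator parameters (lognormal dwell times).

    ``dwell_logmu``/``dwell_logsigma`` parameterise the ln-space normal.
    Use :meth:`from_mean` to specify the distribution mean instead
    (mu = ln m - sigma^2/2).
    """

    n_traces: int = 10
    frame_ms: float = 100.0
    duration_s: float = 120.0
    dwell_logmu: float = math.log(617.0) - 0.5 * DEFAULT_DWELL_SIGMA ** 2
    dwell_logsigma: float = DEFAULT_DWELL_SIGMA
    burst_rate: float = 0.05        # events per second per trace
    signal_level: float = 1000.0    # a.u.
    background_sd: float = 30.0     # a.u.
    seed: int = 0

    def __post_init__(self):
        if self.frame_ms <= 0 or self.duration_s <= 0:
            raise ParameterError("frame_ms and duration_s must be positive")
        n_frames = self.duration_s * 1000.0 / self.frame_ms
        if abs(n_frames - round(n_frames)) > 1e-9:
            raise ParameterError("duration must be an integral number of frames")
        if self.dwell_logsigma < 0:
            raise ParameterError("dwell_logsigma must be >= 0")
        if self.burst_rate < 0 or self.signal_level <= 0 or self.background_sd < 0:
            raise ParameterError("invalid burst/signal parameters")

    @classmethod
    def from_mean(cls, mean_ms: float, sigma: float = DEFAULT_DWELL_SIGMA, **kw):
        if mean_ms <= 0:
            raise ParameterError("mean_ms must be positive")
        return cls(dwell_logmu=math.log(mean_ms) - 0.5 * sigma ** 2,
                   dwell_logsigma=sigma, **kw)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * 1000.0 / self.frame_ms))


def _place_bursts(rng, params: TraceGenParams, n_bursts: int):
    """Sample one trace with ``n_bursts`` non-overlapping interior bursts.

    Returns ``(intensity, events)``; events are dicts with the true
    (continuous) dwell, the quantized frame count and a sub-resolution flag.
    """
    nf = params.n_frames
    y = rng.normal(0.0, params.background_sd, size=nf) if params.background_sd > 0 \
        else np.zeros(nf)
    events = []
    occupied = np.zeros(nf, dtype=bool)
    occupied[0] = occupied[-1] = True  # keep bursts off the boundaries
    for _ in range(n_bursts):
        dwell = float(rng.lognormal(params.dwell_logmu, params.dwell_logsigma))
        n_on = max(int(round(dwell / params.frame_ms)), 1)
        sub_res = dwell < params.frame_ms
        if n_on + 4 >= nf:
            continue  # dwell longer than the trace; skip
        placed = False
        for _attempt in range(200):
            start = int(rng.integers(1, nf - n_on - 1))
            span = slice(max(start - 2, 0), min(start + n_on + 2, nf))
            if not occupied[span].any():
                occupied[span] = True
                y[start:start + n_on] += params.signal_level
                events.append({"start_frame": start, "n_frames": n_on,
                               "dwell_true_ms": dwell,
                               "dwell_quantized_ms": n_on * params.frame_ms,
                               "sub_resolution": sub_res})
                placed = True
                break
        if not placed:
            continue  # trace too crowded; event dropped
    return y, events


def gen_intensity_traces(params: TraceGenParams):
    """Generate labelled traces; burst counts per trace are Poisson.

    Returns ``(traces, truth)`` with truth a list (per trace) of event
    dicts carrying true and quantized dwells.
    """
    rng = np.random.default_rng(params.seed)
    traces, truth = [], []
    for idx in range(params.n_traces):
        n_bursts = int(rng.poisson(params.burst_rate * params.duration_s))
        y, events = _place_bursts(rng, params, n_bursts)
        traces.append(IntensityTrace(intensity=y, frame_ms=params.frame_ms,
                                     id=f"trace_{idx:04d}"))
        truth.append(events)
    return traces, truth


def gen_dwell_dataset(n_events: int, mean_ms: float,
                      sigma: float = DEFAULT_DWELL_SIGMA,
                      frame_ms: float = 100.0, duration_s: float = 120.0,
                      events_per_trace: int = 5, seed: int = 0,
                      signal_level: float = 1000.0, background_sd: float = 30.0):
    """Generate traces holding exactly ``n_events`` bursts in total.

    Convenience preset used for lifetime-recovery studies where the event
    count of the experiment (e.g. n = 297 for H-M) must be matched exactly.
    """
    if n_events < 1:
        raise ParameterError("n_events must be >= 1")
    params = TraceGenParams.from_mean(
        mean_ms, sigma, n_traces=1, frame_ms=frame_ms, duration_s=duration_s,
        signal_level=signal_level, background_sd=background_sd, seed=seed)
    rng = np.random.default_rng(seed)
    traces, truth = [], []
    remaining = n_events
    idx = 0
    while remaining > 0:
        want = min(events_per_trace, remaining)
        y, events = _place_bursts(rng, params, want)
        while len(events) < want:  # extremely unlikely; re-draw the trace
            y, events = _place_bursts(rng, params, want)
        traces.append(IntensityTrace(intensity=y, frame_ms=frame_ms,
                                     id=f"trace_{idx:04d}"))
        truth.append(events)
        remaining -= len(events)
        idx += 1
    return traces, truth


# ===========================================================================
# AFM topographs
# ===========================================================================

@dataclass(frozen=True)
class TopoFeature:
    """One rendered surface feature.

    ``shape``: 'cap' (spherical cap), 'disk' (flat-topped plateau) or
    'fibril' (elliptical-section ridge across the whole field at ``angle``
    radians).  ``size_nm`` is the lateral diameter (caps/disks) or ridge
    width (fibril); ``position`` is the (row, col) center in pixels.
    """

    shape: str
    height_nm: float
    size_nm: float
    position: tuple[float, float]
    angle: float = 0.0

    def __post_init__(self):
        if self.shape not in ("cap", "disk", "fibril"):
            raise ParameterError(f"unknown feature shape {self.shape!r}")
        if self.height_nm < 0:
            raise ParameterError("feature heights must be >= 0")
        if self.size_nm <= 0:
            raise ParameterError("feature lateral size must be positive")


@dataclass(frozen=True)
class TopoGenParams:
    grid: tuple[int, int] = (512, 512)
    pixel_nm: float = 2.0
    features: tuple = ()
    roughness_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.pixel_nm <= 0:
            raise ParameterError("pixel_nm must be positive")
        if self.roughness_sd < 0:
            raise ParameterError("roughness_sd must be >= 0")
        ny, nx = self.grid
        for feat in self.features:
            r, c = feat.position
            if not (0 <= r < ny and 0 <= c < nx):
                raise ParameterError(f"feature at {feat.position} outside grid")


def _render_feature(feat: TopoFeature, yy, xx, pixel_nm):
    """Height field of one feature on the pixel grid (nm)."""
    dy = (yy - feat.position[0]) * pixel_nm
    dx = (xx - feat.position[1]) * pixel_nm
    h = feat.height_nm
    if feat.shape == "cap":
        a = feat.size_nm / 2.0
        r2 = dy ** 2 + dx ** 2
        sphere_r = (a ** 2 + h ** 2) / (2.0 * h) if h > 0 else np.inf
        z = np.zeros_like(dy)
        inside = r2 < a ** 2
        if h > 0:
            z[inside] = np.sqrt(np.maximum(sphere_r ** 2 - r2[inside], 0.0)) \
                - (sphere_r - h)
        return np.maximum(z, 0.0)
    if feat.shape == "disk":
        a = feat.size_nm / 2.0
        return np.where(dy ** 2 + dx ** 2 <= a ** 2, h, 0.0)
    # fibril: ridge with elliptical cross-section, axis through position at angle
    w = feat.size_nm / 2.0
    dist = np.abs(-np.sin(feat.angle) * dx + np.cos(feat.angle) * dy)
    z = np.zeros_like(dist)
    inside = dist < w
    z[inside] = h * np.sqrt(1.0 - (dist[inside] / w) ** 2)
    return z


def gen_topograph(params: TopoGenParams) -> Topograph:
    """Render features (composed by max, never summed) plus roughness."""
    ny, nx = params.grid
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    z = np.zeros((ny, nx))
    for feat in params.features:
        z = np.maximum(z, _render_feature(feat, yy, xx, params.pixel_nm))
    if params.roughness_sd > 0:
        rng = np.random.default_rng(params.seed)
        z = z + rng.normal(0.0, params.roughness_sd, size=z.shape)
    return Topograph(heights=z, pixel_nm=params.pixel_nm)


def gen_particle_field(shape: str, n: int, height_mean: float, height_sd: float,
                       size_nm: float = 30.0, grid=(512, 512), pixel_nm: float = 2.0,
                       roughness_sd: float = 0.05, seed: int = 0):
    """A topograph with ``n`` non-overlapping identical-shape particles.

    Particles sit on a jittered lattice so regions never merge; heights are
    drawn Normal(height_mean, height_sd) truncated positive.  Returns
    ``(Topograph, true_heights)``.
    """
    rng = np.random.default_rng(seed)
    ny, nx = grid
    size_px = size_nm / pixel_nm
    cell = int(np.ceil(size_px * 1.8))
    rows = max((ny - cell) // cell, 1)
    cols = max((nx - cell) // cell, 1)
    if rows * cols < n:
        raise ParameterError(
            f"grid holds at most {rows * cols} non-overlapping particles, need {n}")
    slots = [(r, c) for r in range(rows) for c in range(cols)]
    chosen = rng.choice(len(slots), size=n, replace=False)
    heights = _truncated_normal(rng, height_mean, height_sd, n)
    features = []
    jitter = max(cell - size_px - 2, 0) / 2.0
    for k, slot_idx in enumerate(chosen):
        r, c = slots[slot_idx]
        cy = (r + 0.5) * cell + cell / 2.0 + rng.uniform(-jitter, jitter)
        cx = (c + 0.5) * cell + cell / 2.0 + rng.uniform(-jitter, jitter)
        cy = float(np.clip(cy, size_px, ny - size_px - 1))
        cx = float(np.clip(cx, size_px, nx - size_px - 1))
        features.append(TopoFeature(shape=shape, height_nm=float(heights[k]),
                                    size_nm=size_nm, position=(cy, cx)))
    topo = gen_topograph(TopoGenParams(grid=grid, pixel_nm=pixel_nm,
                                       features=tuple(features),
                                       roughness_sd=roughness_sd, seed=seed + 1))
    return topo, heights.tolist()


# ===========================================================================
# dihedral trajectories
# ===========================================================================

@dataclass(frozen=True)
class DihedralState:
    centers_deg: tuple          # one angle center per dihedral
    concentration: float        # von Mises kappa (inf-like = tight)
    occupancy: float


@dataclass(frozen=True)
class DihedralGenParams:
    n_frames: int = 10000
    states: tuple = ()
    n_residues: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1 or self.n_residues < 3:
            raise ParameterError("need n_frames >= 1 and n_residues >= 3")
        if not self.states:
            raise ParameterError("at least one state is required")
        occ = sum(s.occupancy for s in self.states)
        if not math.isclose(occ, 1.0, abs_tol=1e-9):
            raise ParameterError(f"state occupancies must sum to 1, got {occ}")
        n_angles = 2 * self.n_residues
        for s in self.states:
            if len(s.centers_deg) != n_angles:
                raise ParameterError(
                    f"state centers must have {n_angles} angles (phi/psi per residue)")
            if any(not (-180.0 < c <= 180.0) for c in s.centers_deg):
                raise ParameterError("state centers must lie in (-180, 180]")
            if s.concentration < 0:
                raise ParameterError("concentration must be >= 0")


def _wrap_deg(a):
    """Wrap to (-180, 180]."""
    out = (np.asarray(a) + 180.0) % 360.0 - 180.0
    out[out == -180.0] = 180.0
    return out


def gen_dihedral_traj(params: DihedralGenParams):
    """Sample a phi/psi trajectory from the von Mises state mixture.

    Terminal residues (first and last) are flagged in ``terminal_mask``.
    Returns ``(DihedralTrajectory, state_labels)``.
    """
    rng = np.random.default_rng(params.seed)
    occ = np.array([s.occupancy for s in params.states])
    state_idx = rng.choice(len(params.states), size=params.n_frames, p=occ)
    n_angles = 2 * params.n_residues
    angles = np.empty((params.n_frames, n_angles))
    for k, state in enumerate(params.states):
        rows = state_idx == k
        n_rows = int(rows.sum())
        if n_rows == 0:
            continue
        centers = np.deg2rad(np.asarray(state.centers_deg))
        if state.concentration == 0:
            samp = np.broadcast_to(centers, (n_rows, n_angles)).copy()
        else:
            samp = rng.vonmises(centers, state.concentration,
                                size=(n_rows, n_angles))
        angles[rows] = _wrap_deg(np.rad2deg(samp))
    labels = [(res, name) for res in range(params.n_residues)
              for name in ("phi", "psi")]
    terminal = np.zeros(n_angles, dtype=bool)
    terminal[0:2] = True
    terminal[-2:] = True
    traj = DihedralTrajectory(angles=angles, labels=labels, terminal_mask=terminal)
    return traj, state_idx


# ===========================================================================
# coarse-grained dimers
# ===========================================================================

#: peptide sequences (one-letter): monomer and turn-linked hairpin.
MONOMER_SEQ = "CHQKLVFFAED"                      # 11 residues
HAIRPIN_SEQ = "CHQKLVFFAED" + "YNGK" + "HQKLVFFAED"  # 25 residues

CA_SPACING = 0.38       # nm, virtual Calpha-Calpha bond
STRAND_SEP = 1.0        # nm between hairpin strands (room for intercalation)
INTERFACE_GAP = 0.55    # nm between facing strands of the H-H interface
CONTACT_DEPTH = 3.0     # kBT per inter-chain H-bond contact (salt bridge 2x)
INTRA_DEPTH = 6.0       # kBT per intra-hairpin contact (cooperative fold)


def _hairpin_coords(y0=0.0, z0=0.0):
    """25-bead hairpin: two antiparallel strands joined by a 4-bead turn."""
    a = CA_SPACING
    pts = []
    for i in range(11):                       # strand 1 (C + 10)
        pts.append((i * a, y0, z0))
    x_end = 10 * a
    turn = [(x_end + 0.30, y0 + 0.15 * STRAND_SEP, z0),
            (x_end + 0.45, y0 + 0.40 * STRAND_SEP, z0),
            (x_end + 0.45, y0 + 0.60 * STRAND_SEP, z0),
            (x_end + 0.30, y0 + 0.85 * STRAND_SEP, z0)]
    pts.extend(turn)                          # beads 11-14
    for j in range(10):                       # strand 2, antiparallel
        pts.append(((9 - j) * a, y0 + STRAND_SEP, z0))
    return np.array(pts)


def _intra_contacts(offset):
    """Three cross-strand contacts holding the hairpin fold."""
    pairs = [(2, 22), (5, 19), (8, 16)]
    return [(offset + i, offset + j) for i, j in pairs]


def gen_cg_dimer(kind: str) -> CGModel:
    """Build the toy H-M or H-H dimer.

    H-M: 25-bead hairpin plus an 11-bead monomer intercalated antiparallel
    between the hairpin strands; 5 inter-chain contacts plus a
    double-strength Lys-Asp salt-bridge contact, and 3 intra-hairpin
    contacts.  H-H: two hairpins side by side with 4 inter-chain contacts
    across the facing strands (each hairpin keeps its 3 intra contacts).
    Pulling groups are the N-terminal (Cys) beads of each chain.
    """
    if kind not in ("HM", "HH"):
        raise ParameterError(f"kind must be 'HM' or 'HH', got {kind!r}")
    hp = _hairpin_coords()
    a = CA_SPACING
    if kind == "HM":
        # antiparallel intercalated monomer: N-terminus away from the
        # hairpin N-terminus, half a spacing offset so the chain clears the turn
        mono = np.array([((9.5 - i) * a, STRAND_SEP / 2.0, 0.0)
                         for i in range(11)])
        coords = np.vstack([hp, mono])
        chain_of = np.array([0] * 25 + [1] * 11)
        # five backbone H-bond contacts, monomer <-> both hairpin strands
        inter_pairs = [(1, 25 + 8), (4, 25 + 5), (7, 25 + 2),
                       (18, 25 + 3), (21, 25 + 6)]
        # Lys-Asp salt bridge: hairpin Lys (bead 3) - monomer C-terminal Asp
        salt_pair = (3, 25 + 10)
        contacts = []
        for i, j in _intra_contacts(0):
            contacts.append(_native_contact(coords, i, j, INTRA_DEPTH, "intra"))
        for i, j in inter_pairs:
            contacts.append(_native_contact(coords, i, j, CONTACT_DEPTH, "inter"))
        contacts.append(_native_contact(coords, *salt_pair,
                                        2.0 * CONTACT_DEPTH, "saltbridge"))
        pulling = (0, 25)
    else:
        hp2 = _hairpin_coords(y0=STRAND_SEP + INTERFACE_GAP)
        coords = np.vstack([hp, hp2])
        chain_of = np.array([0] * 25 + [1] * 25)
        # four H-bond contacts between the facing strands, x-aligned pairs
        inter_pairs = [(16, 25 + 8), (18, 25 + 6), (20, 25 + 4), (22, 25 + 2)]
        contacts = []
        for i, j in _intra_contacts(0) + _intra_contacts(25):
            contacts.append(_native_contact(coords, i, j, INTRA_DEPTH, "intra"))
        for i, j in inter_pairs:
            contacts.append(_native_contact(coords, i, j, CONTACT_DEPTH, "inter"))
        pulling = (0, 25)

    bonds = []
    start = 0
    for chain_len in np.bincount(chain_of):
        for i in range(start, start + chain_len - 1):
            r0 = float(np.linalg.norm(coords[i + 1] - coords[i]))
            bonds.append((i, i + 1, r0, 300.0))
        start += chain_len
    return CGModel(coords=coords, chain_of=chain_of, bonds=bonds,
                   contacts=contacts, pulling_groups=pulling)


def _native_contact(coords, i, j, depth, cls) -> Contact:
    r0 = float(np.linalg.norm(coords[j] - coords[i]))
    return Contact(i=i, j=j, r0=r0, depth=depth, cls=cls)
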